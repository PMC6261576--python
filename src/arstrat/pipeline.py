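"""End-to-end orchestration and report tables.

``run_pipeline`` chains the stages — simulate (or load) a cohort, filter
complete cases, compute the three score scales and their terciles,
cluster with k-means and Ward, evaluate every labeling with the four
discriminators, compute the kappa matrix and alphas, derive score
cut-offs — and writes one CSV/JSON per report table.  The run is a pure
function of the configuration: identical config gives byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import agreement, clustering, cutoffs, discriminant, scales
from .cohort import (
    ARPHYS_ITEMS,
    BINARY_COVARIATES,
    CONTINUOUS_COVARIATES,
    SYMPTOM_ITEMS,
    Cohort,
    filter_complete_cases,
    read_cohort,
    write_cohort,
)
from .errors import ArstratError, ConfigurationError
from .synthetic import GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)

METHOD_NAMES = ("kmc", "ahc", "arphys", "tss17", "vas")


def distribution_table(labelings: dict) -> pd.DataFrame:
    """Counts, percentages (2 dp) and cumulated frequencies per method.

    One row per (method, severity class); within a method the counts sum
    to n and the percentages to 100.
    """
    if not labelings:
        raise ConfigurationError("no labelings given")
    rows = []
    for method, labels in labelings.items():
        labels = np.asarray(labels)
        n = len(labels)
        if n == 0:
            raise ConfigurationError(f"labeling {method!r} is empty")
        counts = np.bincount(labels, minlength=3)[:3]
        cum = counts.cumsum()
        for lab in range(3):
            rows.append(
                {
                    "method": method,
                    "severity": scales.SEVERITY_NAMES[lab],
                    "count": int(counts[lab]),
                    "percent": round(100.0 * counts[lab] / n, 2),
                    "cumulated_count": int(cum[lab]),
                    "cumulated_percent": round(100.0 * cum[lab] / n, 2),
                }
            )
    return pd.DataFrame(rows)


_CATEGORICAL = set(BINARY_COVARIATES) | {"sex", "region"}


def group_comparison(cohort: Cohort, labels, variables=None) -> pd.DataFrame:
    """Compare covariates across the three severity groups.

    Continuous and ordinal variables get per-group means with standard
    errors of the mean and a tie-corrected Kruskal-Wallis test;
    categorical variables get per-group counts/percentages and a Pearson
    chi-square test.
    """
    labels = np.asarray(labels)
    if len(labels) != len(cohort):
        raise ConfigurationError("labels must align with the cohort")
    groups = [np.flatnonzero(labels == lab) for lab in range(3)]
    if any(len(g) == 0 for g in groups):
        raise ConfigurationError("every severity group must be non-empty")
    if variables is None:
        variables = (
            CONTINUOUS_COVARIATES
            + SYMPTOM_ITEMS
            + ("sex",)
            + BINARY_COVARIATES
            + ("region",)
        )
    rows = []
    df = cohort.data
    for var in variables:
        if var not in df.columns:
            raise ConfigurationError(f"variable {var!r} not in schema")
        col = df[var]
        per_group = [col.iloc[g].dropna() for g in groups]
        row: dict = {"variable": var}
        if var in _CATEGORICAL:
            levels = sorted(pd.concat(per_group).unique())
            table = np.array([[int((pg == lv).sum()) for lv in levels] for pg in per_group])
            keep = table.sum(axis=0) > 0
            table = table[:, keep]
            if table.shape[1] < 2:
                stat, p = 0.0, 1.0
            else:
                stat, p, _, _ = stats.chi2_contingency(table, correction=False)
            ref = levels[-1]
            for lab, pg in zip(scales.SEVERITY_NAMES, per_group):
                row[f"{lab}_count"] = int((pg == ref).sum())
                row[f"{lab}_percent"] = round(100.0 * float((pg == ref).mean()), 2)
            row.update(type="categorical", statistic=float(stat), p_value=float(p))
        else:
            vals = [pg.to_numpy(dtype=float) for pg in per_group]
            if all(np.array_equal(v, vals[0]) for v in vals[1:]):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.kruskal(*vals)
            for lab, v in zip(scales.SEVERITY_NAMES, vals):
                row[f"{lab}_mean"] = float(v.mean())
                row[f"{lab}_se"] = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan
            row.update(type="continuous", statistic=float(stat), p_value=float(p))
        rows.append(row)
    return pd.DataFrame(rows)


def compute_labelings(cohort: Cohort, seed: int = 0) -> tuple[dict, pd.DataFrame, clustering.StandardizedMatrix]:
    """The five severity labelings of a complete-case cohort.

    Returns ``(labelings, score_table, standardized_matrix)`` with the
    clusters already severity-ordered (reference: TSS-17).
    """
    score_df = scales.score_table(cohort)
    std = clustering.standardize(cohort.symptom_matrix(), variables=SYMPTOM_ITEMS)
    tss = score_df["tss17"].to_numpy()
    kmc = clustering.cluster_cohort(std, "kmeans", seed=seed, reference_scores=tss)
    ahc = clustering.cluster_cohort(std, "ahc", reference_scores=tss)
    labelings = {
        "kmc": kmc.labels,
        "ahc": ahc.labels,
        "arphys": score_df["arphys_tercile"].to_numpy(),
        "tss17": score_df["tss17_tercile"].to_numpy(),
        "vas": score_df["vas_tercile"].to_numpy(),
    }
    return labelings, score_df, std


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_pipeline(config, outdir=None) -> dict:
    """Execute the full analysis chain and write the report bundle.

    ``config`` is a mapping or YAML path with keys ``generator`` (passed
    to :class:`GeneratorConfig`) or ``input_csv``, plus optional ``seed``,
    ``bandwidths``, ``default_bandwidth``, ``repeatability_runs``,
    ``outdir``.  Returns the in-memory bundle; every table is also
    written as CSV/JSON under ``outdir``.
    """
    cfg = _load_config(config)
    outdir = Path(outdir or cfg.get("outdir", "arstrat_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stage = "configure"
    try:
        stage = "cohort"
        if "input_csv" in cfg:
            cohort = read_cohort(cfg["input_csv"])
        elif "generator" in cfg:
            gen = GeneratorConfig(**{**cfg["generator"], "seed": int(cfg["generator"].get("seed", seed))})
            cohort, _ = generate_cohort(gen)
        else:
            raise ConfigurationError("config needs 'generator' or 'input_csv'")
        write_cohort(cohort, outdir / "cohort.csv")

        stage = "complete-case filter"
        retained, excluded = filter_complete_cases(cohort)
        missing_report = None
        if len(excluded) and len(retained):
            from .cohort import compare_included_excluded

            missing_report = compare_included_excluded(retained, excluded)
            missing_report.to_csv(outdir / "missing_data_comparison.csv", index=False)

        stage = "scoring and stratification"
        labelings, score_df, std = compute_labelings(retained, seed=seed)
        score_df.to_csv(outdir / "scores.csv", index=False)
        labels_df = pd.DataFrame({"id": retained.ids.to_numpy(), **labelings})
        labels_df.to_csv(outdir / "labels.csv", index=False)
        for name, labs in labelings.items():
            if np.unique(labs).size < 3:
                logger.warning("labeling %s does not cover all 3 classes", name)

        table1 = distribution_table(labelings)
        table1.to_csv(outdir / "table1_distribution.csv", index=False)

        stage = "discriminant evaluation"
        report = discriminant.evaluate_all(
            std.values,
            labelings,
            bandwidths=tuple(cfg.get("bandwidths", (0.4, 0.6, 0.8, 1.0))),
            default_bandwidth=float(cfg.get("default_bandwidth", 0.8)),
        )
        report.table.to_csv(outdir / "table2_discrimination.csv", index=False)
        if report.bandwidth_sensitivity is not None:
            report.bandwidth_sensitivity.to_csv(outdir / "bandwidth_sensitivity.csv", index=False)
        canon = discriminant.canonical_variance_proportions(
            std.values, labelings["arphys"]
        )

        stage = "group comparison"
        table3 = group_comparison(retained, labelings["arphys"])
        table3.to_csv(outdir / "table3_group_comparison.csv", index=False)

        stage = "agreement and reliability"
        kappa = agreement.kappa_matrix(labelings)
        kappa.to_csv(outdir / "table4_kappa.csv")
        items = retained.data
        reliability = {
            "cronbach_alpha_arphys": agreement.cronbach_alpha(items[list(ARPHYS_ITEMS)]),
            "cronbach_alpha_tss17": agreement.cronbach_alpha(items[list(SYMPTOM_ITEMS)]),
            "canonical_variance_proportions_arphys": [float(v) for v in canon],
        }

        stage = "repeatability"
        n_runs = int(cfg.get("repeatability_runs", 10))
        repeat = {
            method: clustering.repeatability(
                std.values,
                method,
                n_runs=n_runs,
                seed=seed + 100,
                reference_scores=score_df["tss17"].to_numpy(),
            )
            for method in ("kmeans", "ahc")
        }

        stage = "cut-off derivation"
        rule, agree_frac = cutoffs.derive_cutoffs(
            score_df["arphys"].to_numpy(), labelings["arphys"], score_max=20
        )
        rule_dict = {
            "mild_max": rule.mild_max,
            "moderate_max": rule.moderate_max,
            "scale_max": rule.scale_max,
            "agreement": agree_frac,
        }
        with open(outdir / "cutoff_rule.json", "w") as fh:
            json.dump(rule_dict, fh, indent=2, sort_keys=True)
        with open(outdir / "reliability.json", "w") as fh:
            json.dump({**reliability, "repeatability_percent": repeat}, fh, indent=2, sort_keys=True)

        stage = "run log"
        cfg_hash = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()
        log = {
            "config_hash": cfg_hash,
            "seed": seed,
            "n_input": len(cohort),
            "n_retained": len(retained),
            "n_excluded": len(excluded),
        }
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
    except ArstratError as exc:
        raise ArstratError(f"pipeline failed at stage '{stage}': {exc}") from exc

    return {
        "cohort": cohort,
        "retained": retained,
        "excluded": excluded,
        "scores": score_df,
        "labelings": labelings,
        "distribution": table1,
        "discrimination": report,
        "group_comparison": table3,
        "missing_data_comparison": missing_report,
        "kappa": kappa,
        "reliability": reliability,
        "repeatability": repeat,
        "cutoff_rule": rule,
        "cutoff_agreement": agree_frac,
        "run_log": log,
    }
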