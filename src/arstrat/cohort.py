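"""Patient-cohort data model, CSV I/O, validation and complete-case filtering.

A cohort is a table of patients, each described by 17 physician-rated
symptoms on a 0-4 Likert scale, a patient-reported visual analogue scale
(VAS, 0-100), and clinical/demographic covariates.  Missing values are
represented as NaN in memory and as empty cells (or ``NA``) on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, SchemaError, ValidationError

#: The 17 physician-rated symptom items, in canonical column order.
SYMPTOM_ITEMS: tuple[str, ...] = (
    "nasal_congestion",
    "nasal_obstruction",
    "rhinorrhea",
    "nasal_itching",
    "sneezing",
    "headache",
    "tiredness",
    "loss_of_appetite",
    "irritability",
    "lacrimation",
    "eye_itching",
    "painful_throat",
    "cough",
    "itching_throat",
    "earache",
    "daily_activity_alteration",
    "sleep_alteration",
)

#: The five items of the physician score (ARPhyS): four nasal symptoms
#: plus ocular pruritus.  Each is rated 0-4, so the score spans 0-20.
ARPHYS_ITEMS: tuple[str, ...] = (
    "nasal_obstruction",
    "rhinorrhea",
    "sneezing",
    "nasal_itching",
    "eye_itching",
)

#: Binary history / sensitization covariates (serialized 0/1).
BINARY_COVARIATES: tuple[str, ...] = (
    "rural",
    "asthma",
    "conjunctivitis",
    "atopic_dermatitis",
    "food_allergy",
    "hives",
    "spt_positive",
    "ige_positive",
    "ait",
)

#: Non-negative continuous covariates.
CONTINUOUS_COVARIATES: tuple[str, ...] = ("age", "onset", "episode_duration")

REGION_LEGEND: dict[int, str] = {
    1: "center",
    2: "east",
    3: "north-west",
    4: "paris-agglomeration",
    5: "south-east",
    6: "south-west",
    7: "west",
}

#: Full canonical column order for cohort CSV files.
COLUMNS: tuple[str, ...] = (
    ("id",)
    + SYMPTOM_ITEMS
    + ("vas", "age", "sex")
    + ("rural", "onset", "episode_duration")
    + (
        "asthma",
        "conjunctivitis",
        "atopic_dermatitis",
        "food_allergy",
        "hives",
        "spt_positive",
        "ige_positive",
        "ait",
        "region",
    )
)

#: Default field set whose completeness defines a "complete case".
DEFAULT_REQUIRED_FIELDS: tuple[str, ...] = SYMPTOM_ITEMS + ("vas",)


@dataclass
class Cohort:
    """An ordered collection of patient records plus a provenance tag.

    ``data`` holds one row per patient with the canonical columns; symptom
    and VAS cells may be NaN (missing).  Row order is stable across a
    write/read round-trip.
    """

    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> pd.Series:
        return self.data["id"]

    def symptom_matrix(self) -> np.ndarray:
        """n x 17 float matrix of Likert ratings (NaN where missing)."""
        return self.data.loc[:, list(SYMPTOM_ITEMS)].to_numpy(dtype=float)

    def incomplete_mask(self, required=DEFAULT_REQUIRED_FIELDS) -> np.ndarray:
        """Boolean vector: True where any required field is missing."""
        sub = self.data.loc[:, list(required)]
        return sub.isna().any(axis=1).to_numpy()

    def validate(self) -> "Cohort":
        """Check every record invariant; raise ValidationError on breach."""
        df = self.data
        missing_cols = [c for c in COLUMNS if c not in df.columns]
        if missing_cols:
            raise SchemaError(f"missing columns: {missing_cols}")
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise ValidationError(f"duplicate patient id {dup!r}")
        for col in SYMPTOM_ITEMS:
            vals = df[col]
            bad = vals.notna() & ~vals.isin([0, 1, 2, 3, 4])
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"Likert rating outside 0-4 in column {col!r}, row {row}"
                    f" (value {vals.iloc[row]!r})",
                    row=row,
                    column=col,
                )
        vas = df["vas"]
        bad = vas.notna() & ((vas < 0) | (vas > 100))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"VAS outside [0, 100] in row {row} (value {vas.iloc[row]!r})",
                row=row,
                column="vas",
            )
        for col in CONTINUOUS_COVARIATES:
            vals = df[col]
            bad = vals.notna() & (vals < 0)
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"negative value in column {col!r}, row {row}", row=row, column=col
                )
        sex = df["sex"]
        bad = sex.notna() & ~sex.isin(["F", "M"])
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(f"sex must be 'F' or 'M', row {row}", row=row, column="sex")
        for col in BINARY_COVARIATES:
            vals = df[col]
            bad = vals.notna() & ~vals.isin([0, 1])
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"binary covariate {col!r} must be 0/1, row {row}", row=row, column=col
                )
        region = df["region"]
        bad = region.notna() & ~region.isin(list(REGION_LEGEND))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(f"region code outside 1-7, row {row}", row=row, column="region")
        return self


def _coerce_columns(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    numeric = (
        list(SYMPTOM_ITEMS)
        + ["vas"]
        + list(CONTINUOUS_COVARIATES)
        + list(BINARY_COVARIATES)
        + ["region"]
    )
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["id"] = df["id"].astype(str)
    df["sex"] = df["sex"].astype("string").astype(object).where(df["sex"].notna(), np.nan)
    return df.loc[:, list(COLUMNS)]


def read_cohort(path, schema: tuple[str, ...] = COLUMNS) -> Cohort:
    """Read a cohort CSV, validate it, and return a :class:`Cohort`.

    The file must carry a header naming exactly the schema columns
    (order-insensitive).  Empty cells and ``NA`` become missing values.
    """
    df = pd.read_csv(path, na_values=["", "NA"], keep_default_na=False, dtype=str)
    unknown = [c for c in df.columns if c not in schema]
    if unknown:
        raise SchemaError(f"unknown columns in {path}: {unknown}")
    absent = [c for c in schema if c not in df.columns]
    if absent:
        raise SchemaError(f"columns absent from {path}: {absent}")
    cohort = Cohort(_coerce_columns(df), provenance=str(path))
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort as UTF-8 comma-separated text with a header row.

    Missing values serialize as empty cells; booleans as 0/1; numbers with
    ``repr`` precision so that read_cohort round-trips field-for-field.
    """
    df = cohort.data.loc[:, list(COLUMNS)].copy()
    for col in list(BINARY_COVARIATES) + ["region"]:
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    for col in SYMPTOM_ITEMS:
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, index=False, na_rep="")


def filter_complete_cases(
    cohort: Cohort, required=DEFAULT_REQUIRED_FIELDS
) -> tuple[Cohort, Cohort]:
    """Partition a cohort into (retained, excluded) by completeness.

    A record is retained iff none of the ``required`` fields is missing.
    The two parts are disjoint and together exhaust the input, preserving
    the original row order within each part.
    """
    required = tuple(required)
    if len(required) == 0:
        raise ConfigurationError("required field set must be non-empty")
    absent = [c for c in required if c not in cohort.data.columns]
    if absent:
        raise SchemaError(f"required fields not in schema: {absent}")
    mask = cohort.incomplete_mask(required)
    retained = Cohort(cohort.data.loc[~mask], provenance=cohort.provenance + "|complete")
    excluded = Cohort(cohort.data.loc[mask], provenance=cohort.provenance + "|incomplete")
    return retained, excluded


_CATEGORICAL_VARS = set(BINARY_COVARIATES) | {"sex", "region"}


def compare_included_excluded(
    retained: Cohort, excluded: Cohort, variables=None
) -> pd.DataFrame:
    """Compare covariate distributions between retained and excluded patients.

    Categorical variables get group proportions and a Pearson chi-square
    test; continuous variables get group means and a Wilcoxon rank-sum
    (Mann-Whitney) test.  Returns one row per variable.
    """
    if len(retained) == 0 or len(excluded) == 0:
        raise ConfigurationError("both cohorts must be non-empty")
    if variables is None:
        variables = BINARY_COVARIATES + ("sex",) + CONTINUOUS_COVARIATES
    rows = []
    for var in variables:
        if var not in retained.data.columns:
            raise SchemaError(f"variable {var!r} not in schema")
        a = retained.data[var].dropna()
        b = excluded.data[var].dropna()
        if var in _CATEGORICAL_VARS:
            levels = sorted(set(a.unique()) | set(b.unique()))
            table = np.array(
                [[int((a == lv).sum()) for lv in levels], [int((b == lv).sum()) for lv in levels]]
            )
            if table.shape[1] < 2:  # identical constant in both groups
                stat, p = 0.0, 1.0
            else:
                stat, p, _, _ = stats.chi2_contingency(table, correction=False)
            ref = levels[-1]
            summary_a = float((a == ref).mean())
            summary_b = float((b == ref).mean())
            kind = "categorical"
        else:
            if np.array_equal(np.sort(a), np.sort(b)):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            summary_a = float(a.mean())
            summary_b = float(b.mean())
            kind = "continuous"
        rows.append(
            {
                "variable": var,
                "type": kind,
                "retained": summary_a,
                "excluded": summary_b,
                "statistic": float(stat),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)
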