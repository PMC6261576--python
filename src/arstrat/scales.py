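"""Score-based severity measures and their three-class categorizations.

Three scales are supported:

* **ARPhyS** — physician score: sum of five items (nasal obstruction,
  rhinorrhea, sneezing, nasal pruritus, ocular pruritus), range 0-20.
* **TSS-17** — total symptom score: sum of all 17 items, range 0-68.
* **VAS** — the patient's 0-100 visual analogue rating, used as-is.

Each scale is split into terciles with the rank-statistic convention
``group = floor(rank * 3 / (n + 1))`` where tied values all take the
lowest rank of their tie block, so ties fall into the lower category and
group sizes need not be equal.  A fixed integer cut-off rule (mild <= 8,
moderate 9-11, severe >= 12 for ARPhyS) is also provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ARPHYS_ITEMS, SYMPTOM_ITEMS, Cohort
from .errors import ConfigurationError, MissingDataError, ValidationError

logger = logging.getLogger(__name__)


class SeverityLabel(IntEnum):
    """Ordered severity categories: mild < moderate < severe."""

    MILD = 0
    MODERATE = 1
    SEVERE = 2


SEVERITY_NAMES = ("mild", "moderate", "severe")


@dataclass(frozen=True)
class CutoffRule:
    """Integer thresholds mapping a total score to mild/moderate/severe.

    ``score <= mild_max`` is mild, ``mild_max < score <= moderate_max`` is
    moderate, anything larger is severe.  Defaults reproduce the published
    ARPhyS rule (mild 0-8, moderate 9-11, severe 12-20).
    """

    mild_max: int = 8
    moderate_max: int = 11
    scale_max: int = 20

    def __post_init__(self):
        if not (0 <= self.mild_max < self.moderate_max < self.scale_max):
            raise ConfigurationError(
                f"require 0 <= mild_max < moderate_max < scale_max, "
                f"got ({self.mild_max}, {self.moderate_max}, {self.scale_max})"
            )


def _sum_items(cohort_or_df, items, name: str) -> np.ndarray:
    df = cohort_or_df.data if isinstance(cohort_or_df, Cohort) else cohort_or_df
    sub = df.loc[:, list(items)]
    if sub.isna().any().any():
        bad = sub.isna().any(axis=1)
        raise MissingDataError(
            f"{name} requires all constituent items; {int(bad.sum())} record(s) "
            "have missing ratings (exclude incomplete cases first)"
        )
    return sub.to_numpy(dtype=float).sum(axis=1).astype(int)


def arphys_score(cohort) -> np.ndarray:
    """Physician score: integer sum of the five core items, in [0, 20]."""
    return _sum_items(cohort, ARPHYS_ITEMS, "ARPhyS")


def tss17_score(cohort) -> np.ndarray:
    """Total symptom score: integer sum of all 17 items, in [0, 68]."""
    return _sum_items(cohort, SYMPTOM_ITEMS, "TSS-17")


def vas_score(cohort) -> np.ndarray:
    """The raw VAS values (0-100); missing values are rejected."""
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    vas = df["vas"]
    if vas.isna().any():
        raise MissingDataError("VAS missing for some records; filter complete cases first")
    return vas.to_numpy(dtype=float)


def tercile_categorize(scores, groups: int = 3) -> np.ndarray:
    """Split scores into rank-based groups with ties assigned downward.

    Each score lands in group ``floor(rank * groups / (n + 1))`` using
    1-based ranks where every member of a tie block takes the block's
    lowest rank.  With ``groups=3`` the groups map to mild/moderate/severe
    in ascending score order.  If all scores are identical every patient
    is assigned the lowest group (a warning is logged).
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n < groups:
        raise ConfigurationError(f"need at least {groups} scores, got {n}")
    if np.isnan(scores).any():
        raise MissingDataError("scores contain missing values")
    ranks = stats.rankdata(scores, method="min")
    labels = np.floor(ranks * groups / (n + 1)).astype(int)
    labels = np.minimum(labels, groups - 1)
    if labels.max() == 0 and n > 1 and np.unique(scores).size == 1:
        logger.warning("all %d scores identical; every patient assigned the lowest group", n)
    return labels


def classify_by_cutoffs(scores, rule: CutoffRule = CutoffRule()) -> np.ndarray:
    """Apply a fixed integer cut-off rule to one score or a score vector."""
    arr = np.atleast_1d(np.asarray(scores))
    if np.isnan(arr.astype(float)).any():
        raise MissingDataError("scores contain missing values")
    if (arr < 0).any() or (arr > rule.scale_max).any():
        bad = arr[(arr < 0) | (arr > rule.scale_max)][0]
        raise ValidationError(f"score {bad} outside [0, {rule.scale_max}]")
    labels = np.where(arr <= rule.mild_max, 0, np.where(arr <= rule.moderate_max, 1, 2))
    if np.isscalar(scores) or np.ndim(scores) == 0:
        return SeverityLabel(int(labels[0]))
    return labels.astype(int)


def score_table(cohort: Cohort) -> pd.DataFrame:
    """Per-patient scores plus the tercile and cut-off labelings.

    Columns: id, arphys, tss17, vas, tercile labels for each scale
    (``*_tercile``) and the fixed-rule ARPhyS label (``arphys_cutoff``).
    """
    arphys = arphys_score(cohort)
    tss = tss17_score(cohort)
    vas = vas_score(cohort)
    return pd.DataFrame(
        {
            "id": cohort.ids.to_numpy(),
            "arphys": arphys,
            "tss17": tss,
            "vas": vas,
            "arphys_tercile": tercile_categorize(arphys),
            "tss17_tercile": tercile_categorize(tss),
            "vas_tercile": tercile_categorize(vas),
            "arphys_cutoff": classify_by_cutoffs(arphys),
        }
    )
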