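"""Derive integer score cut-offs that best reproduce a tercile labeling.

An exhaustive search over all threshold pairs (c1, c2) finds the rule
``score <= c1 -> mild, score <= c2 -> moderate, else severe`` that
minimizes disagreement with the given three-class labeling.  Applied to
the physician score this is the procedure behind the published mild <= 8
/ moderate 9-11 / severe >= 12 rule.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError
from .scales import CutoffRule


def derive_cutoffs(scores, tercile_labels, score_max: int = 20, weighted: bool = False):
    """Best integer cut-off pair and its achieved agreement fraction.

    Searches all 0 <= c1 < c2 < score_max; disagreement is the plain
    misclassification count (``weighted=True`` uses the absolute label
    distance instead).  Ties break toward smaller c1 then smaller c2.
    Returns ``(CutoffRule, agreement)``.
    """
    scores = np.asarray(scores)
    labels = np.asarray(tercile_labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ConfigurationError("scores and labels must be aligned 1-D vectors")
    if score_max < 2:
        raise ConfigurationError("score_max must be at least 2")
    present = np.unique(labels)
    if len(present) < 3:
        raise ConfigurationError(f"degenerate labeling: classes present {present}")
    if not np.array_equal(scores, scores.astype(int)):
        raise ConfigurationError("scores must be integers")
    scores = scores.astype(int)
    if scores.min() < 0 or scores.max() > score_max:
        raise ConfigurationError(f"scores outside [0, {score_max}]")

    # distribution of true labels at each integer score value
    counts = np.zeros((score_max + 1, 3), dtype=float)
    for lab in range(3):
        counts[:, lab] = np.bincount(scores[labels == lab], minlength=score_max + 1)
    cum = counts.cumsum(axis=0)  # cum[s, lab] = #{score <= s with label lab}
    total = counts.sum(axis=0)

    dist = np.abs(np.subtract.outer(np.arange(3), np.arange(3))).astype(float)
    cost_of = dist if weighted else (dist > 0).astype(float)

    best = None
    for c1 in range(score_max):
        for c2 in range(c1 + 1, score_max):
            # predicted mild: score <= c1; moderate: c1 < score <= c2; severe above
            in_mild = cum[c1]
            in_mod = cum[c2] - cum[c1]
            in_sev = total - cum[c2]
            cost = (
                (cost_of[0] * in_mild).sum()
                + (cost_of[1] * in_mod).sum()
                + (cost_of[2] * in_sev).sum()
            )
            key = (cost, c1, c2)
            if best is None or key < best:
                best = key
    cost, c1, c2 = best
    agreement = 1.0 - cost / len(scores) if not weighted else None
    if weighted:
        miss = _misclassified(scores, labels, c1, c2)
        agreement = 1.0 - miss / len(scores)
    return CutoffRule(mild_max=c1, moderate_max=c2, scale_max=score_max), float(agreement)


def _misclassified(scores, labels, c1, c2) -> int:
    pred = np.where(scores <= c1, 0, np.where(scores <= c2, 1, 2))
    return int((pred != labels).sum())
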