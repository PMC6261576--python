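"""Inter-method agreement (Cohen's kappa) and score reliability (alpha)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .errors import ConfigurationError, ValidationError


def cohen_kappa(labels_a, labels_b, weights: str | None = None) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    Unweighted by default; ``weights='linear'`` gives the linear-weighted
    variant for ordered categories.  When both labelings are identical
    and constant, expected agreement is 1 and kappa is returned as 1.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigurationError("labelings must be 1-D vectors of equal length")
    if len(a) == 0:
        raise ConfigurationError("labelings are empty")
    if np.array_equal(a, b) and np.unique(a).size == 1:
        return 1.0  # p_e = 1 convention: perfect and trivially expected
    return float(cohen_kappa_score(a, b, weights=weights))


def kappa_matrix(labelings: dict, weights: str | None = None) -> pd.DataFrame:
    """Symmetric matrix of pairwise kappas over named labelings."""
    names = list(labelings)
    n = {name: len(np.asarray(v)) for name, v in labelings.items()}
    if len(set(n.values())) != 1:
        raise ConfigurationError(f"labelings cover different patient sets: {n}")
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            k = cohen_kappa(labelings[a], labelings[b], weights=weights)
            mat.loc[a, b] = mat.loc[b, a] = k
    return mat


def cronbach_alpha(item_matrix) -> float:
    """Internal-consistency reliability of a k-item summed score.

    ``alpha = k/(k-1) * (1 - sum_j var(item_j) / var(total))`` with
    sample (n-1) variances, computed on the raw item scores.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 2:
        raise ConfigurationError("need an n x k matrix with n >= 2, k >= 2")
    if np.isnan(X).any():
        raise ValidationError("item matrix contains missing values")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValidationError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - X.var(axis=0, ddof=1).sum() / total_var))
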