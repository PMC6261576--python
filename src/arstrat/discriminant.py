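"""Gaussian and kernel-density discriminant evaluation of severity labelings.

How well can the three severity classes of a given labeling be told apart
from the 17 standardized symptom items?  Four discriminators are
evaluated — Fisher linear (pooled covariance), quadratic (per-class
covariance), and kernel-density classifiers with an equal (pooled metric)
or unequal (per-class metric) bandwidth — each reporting the
resubstitution error and the leave-one-out cross-validation error.

Conventions pinned here: priors are equal across the three classes by
default (a proportional option exists); the pooled covariance uses the
n - g denominator; a ridge of ``1e-6 * trace/p`` is added to any
numerically singular covariance; argmax ties break toward the more
severe class (clinically conservative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import ConfigurationError, ValidationError

_COND_LIMIT = 1e8
_RIDGE_SCALE = 1e-6

DISCRIMINATORS = ("linear", "quadratic", "kde_equal", "kde_unequal")


def _resolve_priors(priors, counts) -> np.ndarray:
    g = len(counts)
    if priors is None or priors == "equal":
        p = np.full(g, 1.0 / g)
    elif priors == "proportional":
        p = counts / counts.sum()
    else:
        p = np.asarray(priors, dtype=float)
        if p.shape != (g,) or (p < 0).any():
            raise ConfigurationError("priors must be g non-negative values")
        p = p / p.sum()
    return p


def _regularize(cov: np.ndarray) -> tuple[np.ndarray, float]:
    """Add the trace-scaled ridge if the covariance is ill-conditioned."""
    p = cov.shape[0]
    if not np.isfinite(cov).all():
        raise ValidationError("covariance contains non-finite entries")
    eps = 0.0
    try:
        cond = np.linalg.cond(cov)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        eps = _RIDGE_SCALE * np.trace(cov) / p
        if eps <= 0:
            raise ValidationError("covariance degenerate even for ridge regularization")
        cov = cov + eps * np.eye(p)
    # fail loudly if still not positive-definite
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("covariance singular after ridge regularization") from exc
    return cov, eps


def _class_stats(X, y):
    classes = np.unique(y)
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    counts = np.array([(y == c).sum() for c in classes])
    return classes, means, counts


@dataclass
class DiscriminantModel:
    """A fitted Gaussian discriminant (linear or quadratic)."""

    kind: str
    classes: np.ndarray
    means: np.ndarray  # g x p
    priors: np.ndarray  # g
    pooled_cov: np.ndarray | None = None
    class_covs: np.ndarray | None = None  # g x p x p
    ridge: float = 0.0

    def log_scores(self, X) -> np.ndarray:
        """Per-class Gaussian log-density + log-prior (n x g)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        g, p = self.means.shape
        out = np.empty((X.shape[0], g))
        with np.errstate(divide="ignore"):
            logpriors = np.log(self.priors)
        for k in range(g):
            cov = self.pooled_cov if self.kind == "linear" else self.class_covs[k]
            chol = np.linalg.cholesky(cov)
            diff = X - self.means[k]
            sol = np.linalg.solve(chol, diff.T)
            maha = (sol**2).sum(axis=0)
            logdet = 2.0 * np.log(np.diag(chol)).sum()
            out[:, k] = logpriors[k] - 0.5 * (p * np.log(2 * np.pi) + logdet + maha)
        return out

    def posterior(self, X) -> np.ndarray:
        s = self.log_scores(X)
        return np.exp(s - logsumexp(s, axis=1, keepdims=True))

    def predict(self, X) -> np.ndarray:
        return _argmax_severe(self.log_scores(X), self.classes)


def _argmax_severe(scores: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Row argmax with ties resolved toward the most severe class."""
    g = scores.shape[1]
    idx = g - 1 - np.argmax(scores[:, ::-1], axis=1)
    return classes[idx]


def fit_linear_discriminant(X, y, priors="equal") -> DiscriminantModel:
    """Fisher LDA: class means with one pooled within-class covariance."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, means, counts = _class_stats(X, y)
    if len(classes) < 2:
        raise ConfigurationError("need at least 2 classes")
    if (counts < 2).any():
        small = classes[counts < 2][0]
        raise ValidationError(f"class {small!r} has fewer than 2 members")
    n, p = X.shape
    scatter = np.zeros((p, p))
    for c, mu in zip(classes, means):
        dev = X[y == c] - mu
        scatter += dev.T @ dev
    pooled = scatter / (n - len(classes))
    pooled, ridge = _regularize(pooled)
    return DiscriminantModel(
        kind="linear",
        classes=classes,
        means=means,
        priors=_resolve_priors(priors, counts),
        pooled_cov=pooled,
        ridge=ridge,
    )


def fit_quadratic_discriminant(X, y, priors="equal") -> DiscriminantModel:
    """QDA: per-class covariances, full Gaussian log-density + log-prior."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, means, counts = _class_stats(X, y)
    if len(classes) < 2:
        raise ConfigurationError("need at least 2 classes")
    if (counts < 2).any():
        small = classes[counts < 2][0]
        raise ValidationError(f"class {small!r} has a single member; covariance undefined")
    covs, ridges = [], []
    for c in classes:
        sub = X[y == c]
        cov = np.cov(sub, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        cov, eps = _regularize(cov)
        covs.append(cov)
        ridges.append(eps)
    return DiscriminantModel(
        kind="quadratic",
        classes=classes,
        means=means,
        priors=_resolve_priors(priors, counts),
        class_covs=np.stack(covs),
        ridge=float(max(ridges)),
    )


# ---------------------------------------------------------------------------
# Kernel-density discrimination


def _metric_covs(X, y, classes, pooled: bool) -> list[np.ndarray]:
    """Kernel metric per class: pooled within-class cov, or each class's own."""
    n, p = X.shape
    if pooled:
        scatter = np.zeros((p, p))
        for c in classes:
            dev = X[y == c] - X[y == c].mean(axis=0)
            scatter += dev.T @ dev
        dof = n - len(classes)
        if dof < 1 or not scatter.any():
            # within-class covariance undefined (or zero): Euclidean metric
            return [np.eye(p)] * len(classes)
        cov, _ = _regularize(scatter / dof)
        return [cov] * len(classes)
    covs = []
    for c in classes:
        sub = X[y == c]
        if sub.shape[0] < 2:
            raise ValidationError(f"class {c!r} has fewer than 2 members")
        cov, _ = _regularize(np.atleast_2d(np.cov(sub, rowvar=False, ddof=1)))
        covs.append(cov)
    return covs


def _kde_class_logdens(train, test, cov, h, self_pairs=None):
    """log of the normal-kernel density estimate of one class at ``test``.

    ``self_pairs`` maps test rows to the train row that is the same
    observation; those kernel terms are excluded (leave-one-out).
    """
    p = train.shape[1]
    chol = np.linalg.cholesky(cov)
    wt_train = np.linalg.solve(chol, train.T).T
    wt_test = np.linalg.solve(chol, test.T).T
    d2 = (
        (wt_test**2).sum(axis=1)[:, None]
        + (wt_train**2).sum(axis=1)[None, :]
        - 2.0 * wt_test @ wt_train.T
    )
    np.maximum(d2, 0.0, out=d2)
    logk = -d2 / (2.0 * h**2)
    n_terms = np.full(test.shape[0], train.shape[0], dtype=float)
    if self_pairs is not None:
        rows, cols = self_pairs
        logk[rows, cols] = -np.inf
        n_terms[rows] -= 1.0
    const = -0.5 * p * np.log(2 * np.pi) - p * np.log(h) - np.log(np.diag(chol)).sum()
    with np.errstate(divide="ignore"):
        out = const + logsumexp(logk, axis=1) - np.log(n_terms)
    out[n_terms == 0] = -np.inf
    return out


def kde_classify(
    train_features,
    train_labels,
    test_features,
    bandwidth: float,
    pooled: bool = True,
    priors="equal",
    exclude_self: bool = False,
) -> np.ndarray:
    """Classify by class-conditional Gaussian-kernel density estimates.

    The class score is ``prior * (1/n_k) * sum_i K_h(x - x_i)`` over the
    class-k training points, with the kernel metric the pooled
    within-class covariance (``pooled=True``, "equal bandwidth") or each
    class's own covariance (``pooled=False``, "unequal bandwidth").
    ``exclude_self=True`` (test set == training set) drops each point's
    own kernel term, giving leave-one-out predictions.
    """
    if bandwidth <= 0:
        raise ConfigurationError(f"bandwidth must be positive, got {bandwidth}")
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    T = np.atleast_2d(np.asarray(test_features, dtype=float))
    classes, _, counts = _class_stats(X, y)
    if (counts < 1).any():
        raise ValidationError("every class needs at least one training point")
    pr = _resolve_priors(priors, counts)
    covs = _metric_covs(X, y, classes, pooled)
    scores = np.empty((T.shape[0], len(classes)))
    with np.errstate(divide="ignore"):
        logpr = np.log(pr)
    for k, c in enumerate(classes):
        idx = np.flatnonzero(y == c)
        self_pairs = None
        if exclude_self:
            rows = idx  # test row i corresponds to train row i
            cols = np.arange(len(idx))
            self_pairs = (rows, cols)
        scores[:, k] = logpr[k] + _kde_class_logdens(X[idx], T, covs[k], bandwidth, self_pairs)
    return _argmax_severe(scores, classes)


# ---------------------------------------------------------------------------
# Error rates


def resubstitution_error(model_or_predictions, X=None, y=None) -> float:
    """Fraction of training points misclassified."""
    if isinstance(model_or_predictions, DiscriminantModel):
        pred = model_or_predictions.predict(X)
    else:
        pred = np.asarray(model_or_predictions)
    y = np.asarray(y)
    if len(y) == 0:
        raise ConfigurationError("no observations")
    return float((pred != y).mean())


def loo_cv_error(X, y, kind: str, bandwidth: float | None = None, priors="equal") -> float:
    """Leave-one-out cross-validation error of one discriminator.

    For each observation the classifier is refit without it (for the
    kernel classifiers, its own kernel term is excluded) and the held-out
    point is classified; exactly n refits.  The Gaussian refits use exact
    rank-one downdates of the class means and scatters, which reproduces
    a literal refit to floating-point accuracy.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if n < 3:
        raise ConfigurationError("need at least 3 observations")
    classes, means, counts = _class_stats(X, y)
    if (counts < 2).any():
        small = classes[counts < 2][0]
        raise ValidationError(f"class {small!r} has a single member; cannot leave it out")
    if kind in ("kde_equal", "kde_unequal"):
        if bandwidth is None:
            raise ConfigurationError("kernel discriminators need a bandwidth")
        pred = kde_classify(
            X, y, X, bandwidth, pooled=(kind == "kde_equal"), priors=priors, exclude_self=True
        )
        return float((pred != y).mean())
    if kind not in ("linear", "quadratic"):
        raise ConfigurationError(f"unknown discriminator kind {kind!r}")

    g = len(classes)
    cls_index = {c: k for k, c in enumerate(classes)}
    scatters = np.stack(
        [(X[y == c] - means[k]).T @ (X[y == c] - means[k]) for k, c in enumerate(classes)]
    )
    pooled_scatter = scatters.sum(axis=0)
    pr = _resolve_priors(priors, counts)
    with np.errstate(divide="ignore"):
        logpr = np.log(pr)

    errors = 0
    for i in range(n):
        c = cls_index[y[i]]
        nk = counts[c]
        mu = means[c]
        mu_new = (nk * mu - X[i]) / (nk - 1)
        dev = X[i] - mu
        downdate = (nk / (nk - 1)) * np.outer(dev, dev)
        means_i = means.copy()
        means_i[c] = mu_new
        scores = np.empty(g)
        if kind == "linear":
            cov = (pooled_scatter - downdate) / (n - 1 - g)
            cov, _ = _regularize(cov)
            chol = np.linalg.cholesky(cov)
            for k in range(g):
                sol = np.linalg.solve(chol, X[i] - means_i[k])
                scores[k] = logpr[k] - 0.5 * (sol**2).sum()
        else:
            for k in range(g):
                if k == c:
                    if nk - 1 < 2:
                        raise ValidationError(
                            f"class {classes[c]!r} drops to a single member during LOO"
                        )
                    cov = (scatters[c] - downdate) / (nk - 2)
                else:
                    cov = scatters[k] / (counts[k] - 1)
                cov, _ = _regularize(cov)
                chol = np.linalg.cholesky(cov)
                sol = np.linalg.solve(chol, X[i] - means_i[k])
                logdet = 2.0 * np.log(np.diag(chol)).sum()
                scores[k] = logpr[k] - 0.5 * (logdet + (sol**2).sum())
        pred = _argmax_severe(scores[None, :], classes)[0]
        errors += int(pred != y[i])
    return errors / n


def canonical_variance_proportions(X, y, ridge: bool = True) -> np.ndarray:
    """Eigenvalue shares of the between-class scatter in the within metric.

    With g classes there are at most g-1 canonical discriminant
    components; the returned proportions sum to 1, the first being the
    share of between-class variability the leading component explains.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, means, counts = _class_stats(X, y)
    g, p = means.shape
    if g < 2:
        raise ConfigurationError("need at least 2 classes")
    grand = X.mean(axis=0)
    B = np.zeros((p, p))
    for k in range(g):
        d = means[k] - grand
        B += counts[k] * np.outer(d, d)
    W = np.zeros((p, p))
    for k, c in enumerate(classes):
        dev = X[y == c] - means[k]
        W += dev.T @ dev
    W, _ = _regularize(W) if ridge else (W, 0.0)
    from scipy.linalg import eigh

    vals = eigh(B, W, eigvals_only=True)
    vals = np.clip(vals[::-1][: g - 1], 0.0, None)
    total = vals.sum()
    if total == 0:
        raise ValidationError("between-class scatter is zero; classes coincide")
    return vals / total


# ---------------------------------------------------------------------------
# The full evaluation grid


@dataclass
class DiscriminationReport:
    """Error / LOO-CV error for every labeling x discriminator pair.

    ``table`` is long-form (labeling, discriminator, error_rate,
    cv_error_rate); ``bandwidth_sensitivity`` holds the kernel CV error
    across the bandwidth grid; ``best_by_discriminator`` names the
    labeling with minimal CV error for each discriminator.
    """

    table: pd.DataFrame
    bandwidth: float
    n: int
    bandwidth_sensitivity: pd.DataFrame | None = None
    best_by_discriminator: dict = field(default_factory=dict)

    def cell(self, labeling: str, discriminator: str) -> tuple[float, float]:
        row = self.table[
            (self.table.labeling == labeling) & (self.table.discriminator == discriminator)
        ].iloc[0]
        return float(row.error_rate), float(row.cv_error_rate)


def evaluate_all(
    features,
    labelings: dict,
    bandwidths=(0.4, 0.6, 0.8, 1.0),
    default_bandwidth: float = 0.8,
    priors="equal",
) -> DiscriminationReport:
    """Fill the labeling x discriminator grid of error and LOO-CV rates.

    ``features`` is the n x p standardized symptom matrix shared by all
    labelings.  The kernel discriminators additionally run the bandwidth
    grid for a sensitivity table, reporting the default bandwidth in the
    main grid.
    """
    X = np.asarray(features, dtype=float) if not hasattr(features, "values") else features.values
    n = X.shape[0]
    names = list(labelings)
    for name in names:
        if len(np.asarray(labelings[name])) != n:
            raise ConfigurationError(f"labeling {name!r} does not cover the same patients")
    rows, sens_rows = [], []
    best = {}
    for disc in DISCRIMINATORS:
        for name in names:
            y = np.asarray(labelings[name])
            if disc == "linear":
                model = fit_linear_discriminant(X, y, priors)
                err = resubstitution_error(model, X, y)
                cv = loo_cv_error(X, y, "linear", priors=priors)
            elif disc == "quadratic":
                model = fit_quadratic_discriminant(X, y, priors)
                err = resubstitution_error(model, X, y)
                cv = loo_cv_error(X, y, "quadratic", priors=priors)
            else:
                pooled = disc == "kde_equal"
                pred = kde_classify(X, y, X, default_bandwidth, pooled=pooled, priors=priors)
                err = float((pred != y).mean())
                cv = loo_cv_error(X, y, disc, bandwidth=default_bandwidth, priors=priors)
                for h in bandwidths:
                    if h == default_bandwidth:
                        cv_h = cv
                    else:
                        cv_h = loo_cv_error(X, y, disc, bandwidth=h, priors=priors)
                    sens_rows.append(
                        {"labeling": name, "discriminator": disc, "bandwidth": h, "cv_error_rate": cv_h}
                    )
            rows.append(
                {
                    "labeling": name,
                    "discriminator": disc,
                    "error_rate": err,
                    "cv_error_rate": cv,
                }
            )
        sub = [r for r in rows if r["discriminator"] == disc]
        best[disc] = min(sub, key=lambda r: r["cv_error_rate"])["labeling"]
    return DiscriminationReport(
        table=pd.DataFrame(rows),
        bandwidth=default_bandwidth,
        n=n,
        bandwidth_sensitivity=pd.DataFrame(sens_rows) if sens_rows else None,
        best_by_discriminator=best,
    )
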