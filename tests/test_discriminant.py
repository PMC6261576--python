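import numpy as np
import pytest
from scipy import stats

from arstrat.discriminant import (
    canonical_variance_proportions,
    evaluate_all,
    fit_linear_discriminant,
    fit_quadratic_discriminant,
    kde_classify,
    loo_cv_error,
    resubstitution_error,
)
from arstrat.errors import ConfigurationError, ValidationError


def nine_point_fixture():
    """Three fixed 2-D classes of three points each."""
    X = np.array(
        [
            [0.0, 0.0], [0.5, 0.2], [-0.3, 0.4],
            [3.0, 3.0], [3.5, 2.8], [2.7, 3.3],
            [6.0, 0.0], [6.4, 0.5], [5.8, -0.4],
        ]
    )
    y = np.repeat([0, 1, 2], 3)
    return X, y


def test_lda_boundary_at_midpoint_of_symmetric_classes():
    X = np.array([[-1.2], [-1.0], [-0.8], [0.8], [1.0], [1.2]])
    y = np.array([0, 0, 0, 1, 1, 1])
    model = fit_linear_discriminant(X, y)
    assert model.predict([[0.5]])[0] == 1
    assert model.predict([[-0.5]])[0] == 0


def test_lda_zero_resubstitution_error_on_separated_blobs():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(c, 0.3, size=(20, 2)) for c in ([0, 0], [8, 0], [0, 8])])
    y = np.repeat([0, 1, 2], 20)
    model = fit_linear_discriminant(X, y)
    assert resubstitution_error(model, X, y) == 0.0


def test_lda_posteriors_match_gaussian_density_oracle():
    """Posterior from the model equals direct evaluation of shared-covariance
    Gaussian densities through scipy.stats.multivariate_normal."""
    X, y = nine_point_fixture()
    model = fit_linear_discriminant(X, y)
    # independent pooled covariance (n - g denominator)
    pooled = sum(
        (X[y == c] - X[y == c].mean(axis=0)).T @ (X[y == c] - X[y == c].mean(axis=0))
        for c in range(3)
    ) / (len(X) - 3)
    test_points = np.array([[1.0, 1.0], [4.0, 2.0], [5.0, 1.0]])
    dens = np.column_stack(
        [
            stats.multivariate_normal.pdf(test_points, mean=X[y == c].mean(axis=0), cov=pooled)
            for c in range(3)
        ]
    )
    expected = dens / dens.sum(axis=1, keepdims=True)  # equal priors
    assert np.allclose(model.posterior(test_points), expected, atol=1e-10)


def test_qda_reduces_to_lda_when_class_covariances_equal():
    rng = np.random.default_rng(1)
    base = rng.normal(size=(15, 2))
    base -= base.mean(axis=0)
    X = np.vstack([base + [0, 0], base + [4, 0], base + [0, 4]])
    y = np.repeat([0, 1, 2], 15)
    lda = fit_linear_discriminant(X, y)
    qda = fit_quadratic_discriminant(X, y)
    grid = rng.normal(scale=3, size=(50, 2)) + [1.5, 1.5]
    assert np.array_equal(lda.predict(grid), qda.predict(grid))


def test_qda_separates_narrow_and_wide_classes_by_variance():
    # class 0 ~ N(0,1), class 1 ~ N(0,9): near 0 -> narrow, far -> wide
    rng = np.random.default_rng(2)
    X = np.concatenate([rng.normal(0, 1, 200), rng.normal(0, 3, 200)])[:, None]
    y = np.repeat([0, 1], 200)
    model = fit_quadratic_discriminant(X, y)
    pred_near, pred_far = model.predict([[0.1], [6.0]])
    assert pred_near == 0 and pred_far == 1
    # hand-evaluated density comparison at the same points
    s0, s1 = X[:200].std(ddof=1), X[200:].std(ddof=1)
    m0, m1 = X[:200].mean(), X[200:].mean()
    for x, pred in [(0.1, pred_near), (6.0, pred_far)]:
        d0 = stats.norm.pdf(x, m0, s0)
        d1 = stats.norm.pdf(x, m1, s1)
        assert (d1 > d0) == (pred == 1)


def test_single_member_class_is_an_error():
    X = np.array([[0.0], [1.0], [5.0]])
    y = np.array([0, 0, 1])
    with pytest.raises(ValidationError):
        fit_quadratic_discriminant(X, y)
    with pytest.raises(ValidationError):
        fit_linear_discriminant(X, y)


def test_kde_one_point_per_class_assigns_nearest():
    train = np.array([[0.0, 0], [5, 0], [0, 5]])
    y = np.array([0, 1, 2])
    test = np.array([[0.4, 0.4], [4.5, 0.2], [1.0, 4.0]])
    pred = kde_classify(train, y, test, bandwidth=1.0, pooled=True)
    assert pred.tolist() == [0, 1, 2]


def test_kde_tiny_bandwidth_resubstitution_is_zero():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(30, 2))
    y = rng.integers(0, 3, size=30)
    pred = kde_classify(X, y, X, bandwidth=1e-3, pooled=True)
    assert (pred == y).all()  # own kernel dominates at distinct points


def test_kde_two_term_kernel_sum_hand_checked():
    """1-D: class 0 = {0, 0.5}, class 1 = {4}; densities at x=1 computed
    directly from the normal-kernel formula decide the assignment."""
    train = np.array([[0.0], [0.5], [4.0]])
    y = np.array([0, 0, 1])
    h = 1.0
    # pooled within-class variance: scatter 0.125 over (3 - 2) dof
    v = 0.125
    k = lambda d2: np.exp(-d2 / (2 * h**2 * v)) / np.sqrt(2 * np.pi * v * h**2)
    f0 = 0.5 * (k((1.0 - 0) ** 2) + k((1.0 - 0.5) ** 2))
    f1 = k((1.0 - 4.0) ** 2)
    expected = 0 if f0 > f1 else 1
    pred = kde_classify(train, y, [[1.0]], bandwidth=h, pooled=True)
    assert pred[0] == expected == 0


def test_kde_rejects_nonpositive_bandwidth():
    with pytest.raises(ConfigurationError):
        kde_classify(np.zeros((3, 1)), np.array([0, 1, 2]), np.zeros((1, 1)), bandwidth=0.0)


def test_kde_huge_bandwidth_classifies_by_priors():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(60, 3))
    y = rng.integers(0, 3, size=60)
    pred = kde_classify(X, y, X, bandwidth=1e6, pooled=True, priors=(0.5, 0.3, 0.2))
    assert (pred == 0).all()


def test_resubstitution_error_counts():
    y = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 2, 2, 2])
    pred = y.copy()
    pred[:3] = 1  # 3 wrong of 12
    assert resubstitution_error(pred, y=y) == pytest.approx(0.25)
    assert resubstitution_error(y, y=y) == 0.0
    assert resubstitution_error((y + 1) % 3, y=y) == 1.0


def test_loo_zero_for_widely_separated_1d_classes():
    X = np.array([[0.0], [1.0], [10.0], [11.0]])
    y = np.array([0, 0, 1, 1])
    assert loo_cv_error(X, y, "linear") == 0.0


@pytest.mark.parametrize("kind", ["linear", "quadratic"])
def test_loo_equals_brute_force_refit_oracle(kind):
    """LOO via downdates equals literally refitting without each point
    through the public fit API, on n <= 50 instances."""
    rng = np.random.default_rng(5)
    X = np.vstack([rng.normal(c, 1.2, size=(15, 3)) for c in ([0, 0, 0], [2, 0, 1], [0, 2, 2])])
    y = np.repeat([0, 1, 2], 15)
    fit = fit_linear_discriminant if kind == "linear" else fit_quadratic_discriminant
    errors = 0
    for i in range(len(X)):
        keep = np.delete(np.arange(len(X)), i)
        model = fit(X[keep], y[keep])
        errors += int(model.predict(X[i : i + 1])[0] != y[i])
    assert loo_cv_error(X, y, kind) == pytest.approx(errors / len(X))


def test_kde_loo_matches_independent_kernel_recomputation():
    """KDE LOO excludes each point's own kernel term; an independent direct
    evaluation of the class kernel sums gives the same error."""
    rng = np.random.default_rng(6)
    X = rng.normal(size=(30, 2))
    y = np.repeat([0, 1, 2], 10)
    h = 0.8
    # full-sample pooled metric, as the classifier defines it
    pooled = sum(
        (X[y == c] - X[y == c].mean(axis=0)).T @ (X[y == c] - X[y == c].mean(axis=0))
        for c in range(3)
    ) / (len(X) - 3)
    vinv = np.linalg.inv(pooled * h**2)
    norm = 1.0 / np.sqrt(np.linalg.det(2 * np.pi * h**2 * pooled))
    errors = 0
    for i in range(len(X)):
        scores = []
        for c in range(3):
            members = [j for j in np.flatnonzero(y == c) if j != i]
            dens = np.mean(
                [norm * np.exp(-0.5 * (X[i] - X[j]) @ vinv @ (X[i] - X[j])) for j in members]
            )
            scores.append(dens / 3)
        pred = max(range(3), key=lambda c: (scores[c], c))
        errors += int(pred != y[i])
    assert loo_cv_error(X, y, "kde_equal", bandwidth=h) == pytest.approx(errors / len(X))


def test_kde_loo_error_at_least_resubstitution_with_small_bandwidth():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(40, 2))
    y = rng.integers(0, 3, size=40)
    h = 0.05
    resub = (kde_classify(X, y, X, h, pooled=True) != y).mean()
    cv = loo_cv_error(X, y, "kde_equal", bandwidth=h)
    assert resub == pytest.approx(0.0)
    assert cv >= resub


@pytest.mark.parametrize("kind", ["linear", "quadratic", "kde_equal", "kde_unequal"])
def test_translation_invariance_of_decisions(kind):
    rng = np.random.default_rng(8)
    X = np.vstack([rng.normal(c, 1.0, size=(12, 2)) for c in ([0, 0], [3, 0], [0, 3])])
    y = np.repeat([0, 1, 2], 12)
    shift = np.array([123.4, -56.7])
    if kind in ("linear", "quadratic"):
        fit = fit_linear_discriminant if kind == "linear" else fit_quadratic_discriminant
        a = fit(X, y).predict(X)
        b = fit(X + shift, y).predict(X + shift)
    else:
        pooled = kind == "kde_equal"
        a = kde_classify(X, y, X, 0.8, pooled=pooled)
        b = kde_classify(X + shift, y, X + shift, 0.8, pooled=pooled)
    assert np.array_equal(a, b)


def test_lda_invariant_under_invertible_affine_maps():
    rng = np.random.default_rng(9)
    X = np.vstack([rng.normal(c, 1.0, size=(15, 3)) for c in ([0, 0, 0], [3, 1, 0], [0, 3, 2])])
    y = np.repeat([0, 1, 2], 15)
    A = np.array([[2.0, 0.3, 0], [-0.5, 1.5, 0.2], [0.1, 0, 0.8]])
    b = np.array([5.0, -2.0, 7.0])
    base = fit_linear_discriminant(X, y).predict(X)
    mapped = fit_linear_discriminant(X @ A.T + b, y).predict(X @ A.T + b)
    assert np.array_equal(base, mapped)


def test_qda_invariant_under_rotation_and_translation():
    rng = np.random.default_rng(10)
    X = np.vstack([rng.normal(c, 1.0, size=(15, 2)) for c in ([0, 0], [3, 1], [0, 3])])
    y = np.repeat([0, 1, 2], 15)
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    base = fit_quadratic_discriminant(X, y).predict(X)
    mapped = fit_quadratic_discriminant(X @ R.T + 4.0, y).predict(X @ R.T + 4.0)
    assert np.array_equal(base, mapped)


def test_canonical_proportions_rank_one_for_collinear_means():
    rng = np.random.default_rng(11)
    X = np.vstack([rng.normal([c, 0], 0.5, size=(40, 2)) for c in (0.0, 5.0, 10.0)])
    y = np.repeat([0, 1, 2], 40)
    props = canonical_variance_proportions(X, y)
    assert len(props) == 2
    assert props.sum() == pytest.approx(1.0, abs=1e-9)
    assert props[0] > 0.99


def test_canonical_proportions_split_evenly_for_equilateral_means():
    rng = np.random.default_rng(12)
    centers = 10 * np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
    X = np.vstack([rng.normal(c, 1.0, size=(1000, 2)) for c in centers])
    y = np.repeat([0, 1, 2], 1000)
    props = canonical_variance_proportions(X, y)
    assert props[0] == pytest.approx(0.5, abs=0.05)


def test_evaluate_all_grid_is_consistent(analysis_bundle):
    std = analysis_bundle["std"]
    labelings = analysis_bundle["labelings"]
    report = evaluate_all(std.values, labelings, bandwidths=(0.8,), default_bandwidth=0.8)
    table = report.table
    assert len(table) == 5 * 4
    assert ((table.error_rate >= 0) & (table.error_rate <= 1)).all()
    assert ((table.cv_error_rate >= 0) & (table.cv_error_rate <= 1)).all()
    # kde rows: CV error cannot beat resubstitution (own-kernel dominance)
    kde_rows = table[table.discriminator.str.startswith("kde")]
    assert (kde_rows.cv_error_rate >= kde_rows.error_rate - 1e-12).all()
    # reported cell equals a direct call for the k-means/linear pair
    model = fit_linear_discriminant(std.values, labelings["kmc"])
    direct = resubstitution_error(model, std.values, labelings["kmc"])
    assert report.cell("kmc", "linear")[0] == pytest.approx(direct)
    assert direct < 0.10  # clusters are compact in their own feature space


def test_evaluate_all_rejects_mismatched_patient_sets(analysis_bundle):
    std = analysis_bundle["std"]
    labelings = dict(analysis_bundle["labelings"])
    labelings["vas"] = labelings["vas"][:-1]
    with pytest.raises(ConfigurationError):
        evaluate_all(std.values, labelings)
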