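"""Repeated-measures ANOVA with Greenhouse-Geisser correction, stepwise
regression, and Pearson correlation — checked against independent oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from footkin.stats import pearson_r, rm_anova_gg, stepwise_regression


def _oracle_rm_anova(X):
    """Brute-force sums-of-squares oracle with eigenvalue-based epsilon."""
    n, k = X.shape
    grand = X.mean()
    ss_cond = sum(n * (X[:, j].mean() - grand) ** 2 for j in range(k))
    ss_err = 0.0
    for i in range(n):
        for j in range(k):
            ss_err += (X[i, j] - X[i].mean() - X[:, j].mean() + grand) ** 2
    F = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    S = np.cov(X, rowvar=False, ddof=1)
    C = np.eye(k) - 1.0 / k
    lam = np.linalg.eigvalsh(C @ S @ C)
    eps = lam.sum() ** 2 / ((k - 1) * (lam**2).sum())
    return F, min(eps, 1.0)


def test_matches_sums_of_squares_oracle_on_random_matrices():
    rng = np.random.default_rng(0)
    for _ in range(25):
        X = rng.normal(size=(5, 4)) * rng.uniform(0.5, 3.0)
        res = rm_anova_gg(X)
        F, eps = _oracle_rm_anova(X)
        assert res.F == pytest.approx(F, abs=1e-10)
        assert res.epsilon_gg == pytest.approx(eps, abs=1e-10)


def test_two_conditions_epsilon_exactly_one_and_f_equals_t_squared():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(18, 2))
    res = rm_anova_gg(X)
    assert res.epsilon_gg == 1.0
    t, p = sps.ttest_rel(X[:, 0], X[:, 1])
    assert res.F == pytest.approx(t**2, rel=1e-12)
    assert res.p_uncorrected == pytest.approx(p, rel=1e-10)


def test_agrees_with_pingouin_oracle():
    """Independent cross-check of F, uncorrected p, epsilon and GG p."""
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(7)
    n, k = 18, 4
    X = rng.normal(size=(n, k)) + np.array([0.0, 1.0, 1.5, 3.0])
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "cond": np.tile(np.arange(k), n),
            "y": X.ravel(),
        }
    )
    aov = pingouin.rm_anova(
        data=df, dv="y", within="cond", subject="subject", correction=True
    )
    res = rm_anova_gg(X)
    assert res.F == pytest.approx(float(aov["F"].iloc[0]), rel=1e-9)
    assert res.epsilon_gg == pytest.approx(float(aov["eps"].iloc[0]), rel=1e-9)
    assert res.p_gg == pytest.approx(float(aov["p_GG_corr"].iloc[0]), rel=1e-6)


def test_epsilon_bounds_and_compound_symmetry():
    """Compound-symmetric data keeps the epsilon estimate near 1."""
    rng = np.random.default_rng(42)
    n, k = 18, 4
    eps_vals = []
    for _ in range(100):
        subj = rng.normal(scale=2.0, size=(n, 1))
        X = subj + rng.normal(size=(n, k))
        res = rm_anova_gg(X)
        assert 1.0 / (k - 1) - 1e-12 <= res.epsilon_gg <= 1.0 + 1e-12
        eps_vals.append(res.epsilon_gg)
    assert 0.8 <= np.mean(eps_vals) <= 1.0


def test_null_type_one_error_rate_with_gg_correction():
    """Type-I error at alpha = 0.05 within [0.03, 0.07] over 2000
    simulated null cohorts (n = 18, k = 4)."""
    rng = np.random.default_rng(20240917)
    n, k, reps = 18, 4, 2000
    hits = 0
    for _ in range(reps):
        X = rng.normal(size=(n, k))
        if rm_anova_gg(X).p_gg < 0.05:
            hits += 1
    assert 0.03 <= hits / reps <= 0.07


def test_pairwise_bonferroni_never_below_raw_and_capped():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(10, 3)) + np.array([0.0, 2.0, 0.1])
    res = rm_anova_gg(X)
    m = 3
    for i in range(3):
        for j in range(i + 1, 3):
            t, p_raw = sps.ttest_rel(X[:, i], X[:, j])
            assert res.pairwise_p[i, j] >= p_raw - 1e-15
            assert res.pairwise_p[i, j] == pytest.approx(min(1.0, m * p_raw), rel=1e-12)


def test_anova_input_validation():
    with pytest.raises(ValueError, match="complete"):
        rm_anova_gg(np.array([[1.0, np.nan], [2.0, 3.0]]))
    with pytest.raises(ValueError, match="conditions"):
        rm_anova_gg(np.ones((5, 1)))
    with pytest.raises(ValueError, match="subjects"):
        rm_anova_gg(np.ones((1, 3)))


# --- stepwise regression -----------------------------------------------------


def test_collinear_single_predictor_selected_r2_one():
    rng = np.random.default_rng(5)
    x = rng.normal(size=30)
    X = np.column_stack([x, rng.normal(size=30)])
    res = stepwise_regression(2.0 * x - 1.0, X)
    assert res.selected[0] == 0
    assert res.r_squared == pytest.approx(1.0, abs=1e-12)


def test_planted_predictor_selected_first_and_r2_plausible():
    rng = np.random.default_rng(11)
    n = 18
    X = rng.normal(size=(n, 4))
    y = 0.75 * X[:, 0] + rng.normal(scale=0.5, size=n)
    res = stepwise_regression(y, X)
    assert res.selected[0] == 0
    # generative R^2 = 0.75^2 / (0.75^2 + 0.25) ~ 0.69; allow wide MC spread
    assert 0.4 <= res.r_squared <= 0.95


def test_thresholds_of_one_reduce_to_full_ols():
    rng = np.random.default_rng(13)
    n, p = 30, 4
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    res = stepwise_regression(y, X, entry_p=1.0, removal_p=1.0)
    assert sorted(res.selected) == list(range(p))
    A = np.column_stack([np.ones(n), X])
    beta = np.linalg.lstsq(A, y, rcond=None)[0]
    rss = np.sum((y - A @ beta) ** 2)
    tss = np.sum((y - y.mean()) ** 2)
    assert res.r_squared == pytest.approx(1 - rss / tss, abs=1e-10)
    assert res.adj_r_squared <= res.r_squared


def test_pure_noise_rarely_admits_predictors():
    rng = np.random.default_rng(17)
    n, p, reps = 18, 4, 200
    nonempty = 0
    for _ in range(reps):
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        if stepwise_regression(y, X).selected:
            nonempty += 1
    # forward step tests 4 candidates at p <= 0.05: expected admission rate
    # ~1 - 0.95^4 ~ 0.19 under independence
    assert 0.05 <= nonempty / reps <= 0.35


def test_rank_deficient_design_raises():
    rng = np.random.default_rng(19)
    x = rng.normal(size=20)
    X = np.column_stack([x, x])  # duplicated predictor
    with pytest.raises(np.linalg.LinAlgError):
        stepwise_regression(x + rng.normal(size=20), X, entry_p=1.0, removal_p=1.0)


def test_too_few_observations_raise():
    with pytest.raises(ValueError, match="observations|need n"):
        stepwise_regression(np.ones(4), np.ones((4, 4)))


# --- Pearson correlation -----------------------------------------------------


def test_perfect_anticorrelation():
    x = np.arange(10.0)
    r, p = pearson_r(x, -x)
    assert r == pytest.approx(-1.0)
    assert p == 0.0


def test_orthogonal_vectors_zero_correlation():
    x = np.array([1.0, -1.0, 1.0, -1.0])
    y = np.array([1.0, 1.0, -1.0, -1.0])
    r, p = pearson_r(x, y)
    assert r == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_matches_scipy_pearsonr():
    rng = np.random.default_rng(23)
    x, y = rng.normal(size=18), rng.normal(size=18)
    r, p = pearson_r(x, y)
    ref = sps.pearsonr(x, y)
    assert r == pytest.approx(ref.statistic, rel=1e-12)
    assert p == pytest.approx(ref.pvalue, rel=1e-9)


def test_monte_carlo_bivariate_normal_mean_r():
    rng = np.random.default_rng(29)
    rho, n, reps = -0.6, 18, 5000
    cov = np.array([[1.0, rho], [rho, 1.0]])
    L = np.linalg.cholesky(cov)
    rs = []
    for _ in range(reps):
        z = rng.normal(size=(n, 2)) @ L.T
        rs.append(pearson_r(z[:, 0], z[:, 1])[0])
    assert -0.65 <= np.mean(rs) <= -0.55


def test_pearson_input_validation():
    with pytest.raises(ValueError, match="n >= 3"):
        pearson_r([1.0, 2.0], [3.0, 4.0])
    with pytest.raises(ValueError, match="variance"):
        pearson_r(np.ones(5), np.arange(5.0))
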