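import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from arsmicro import (
    ValidationError,
    adjusted_permanova,
    extreme_quartile_contrast,
    pcoa,
)
from arsmicro.community import bca_interval, gower_center


def euclid_dm(points, ids=None):
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    d = squareform(pdist(arr))
    return DistanceMatrix(d, ids=ids or [f"s{i}" for i in range(d.shape[0])])


def naive_oneway_f(d, groups):
    """Classical one-way PERMANOVA pseudo-F from raw pairwise distances."""
    n = d.shape[0]
    ss_t = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_w = 0.0
    for g in np.unique(groups):
        idx = np.nonzero(groups == g)[0]
        sub = d[np.ix_(idx, idx)]
        ss_w += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    a = len(np.unique(groups))
    return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def test_permanova_matches_naive_oneway_oracle():
    """Two groups coded 0/1 as exposure, no covariates: pseudo-F equals the
    classical one-way statistic computed from raw distances, and skbio's."""
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(6, 3))
    groups = np.array([0, 0, 0, 1, 1, 1])
    dm = euclid_dm(pts)
    res = adjusted_permanova(dm, groups.astype(float), n_perm=9, seed=0)
    assert res.pseudo_F == pytest.approx(naive_oneway_f(dm.data, groups), abs=1e-10)

    from skbio.stats.distance import permanova as skbio_permanova

    ref = skbio_permanova(dm, grouping=[str(g) for g in groups], permutations=9)
    assert res.pseudo_F == pytest.approx(ref["test statistic"], abs=1e-10)


def test_permanova_p_matches_exhaustive_enumeration():
    """Permutation p agrees with exact enumeration of all 5! relabelings."""
    rng = np.random.default_rng(8)
    pts = rng.normal(size=(5, 2))
    exposure = np.array([0.1, 0.5, 0.9, 1.4, 2.0])
    dm = euclid_dm(pts)
    res = adjusted_permanova(dm, exposure, n_perm=4999, seed=1)

    g = gower_center(dm.data)
    n = 5

    def f_of(e):
        x = np.column_stack([np.ones(n), e])
        q, _ = np.linalg.qr(x)
        tr_full = np.trace(q.T @ g @ q)
        one = np.ones((n, 1)) / np.sqrt(n)
        tr_red = (one.T @ g @ one).item()  # intercept-only hat
        ss_exp = tr_full - tr_red
        ss_res = np.trace(g) - tr_full
        return (ss_exp / 1) / (ss_res / (n - 2))

    f_obs = f_of(exposure)
    count = sum(
        f_of(exposure[list(p)]) >= f_obs - 1e-12
        for p in itertools.permutations(range(n))
    )
    exact_p = count / 120
    assert res.pseudo_F == pytest.approx(f_obs, abs=1e-10)
    assert res.p_value == pytest.approx(exact_p, abs=0.02)


def test_permanova_p_floor_and_bounds():
    rng = np.random.default_rng(2)
    pts = np.concatenate([rng.normal(size=10), rng.normal(size=10) + 50])
    exposure = (np.arange(20) >= 10).astype(float)
    res = adjusted_permanova(euclid_dm(pts), exposure, n_perm=9, seed=0)
    assert 1 / 10 <= res.p_value <= 1.0
    assert res.pseudo_F >= 0


def test_permanova_covariate_adjustment_removes_confounded_signal():
    """Exposure that merely copies a covariate explains nothing once the
    covariate enters first (sequential SS)."""
    rng = np.random.default_rng(7)
    cov = rng.normal(size=30)
    pts = np.column_stack([cov, rng.normal(size=30) * 0.1])
    exposure = cov + rng.normal(size=30) * 1e-6
    dm = euclid_dm(pts)
    unadj = adjusted_permanova(dm, exposure, n_perm=99, seed=0)
    adj = adjusted_permanova(
        dm, exposure, covariates=pd.DataFrame({"c": cov}), n_perm=99, seed=0
    )
    assert unadj.pseudo_F > 100 * adj.pseudo_F


def test_permanova_relabeling_invariance():
    rng = np.random.default_rng(11)
    pts = rng.normal(size=(12, 3))
    exposure = rng.normal(size=12)
    dm = euclid_dm(pts)
    perm = rng.permutation(12)
    dm2 = DistanceMatrix(dm.data[np.ix_(perm, perm)], ids=[f"s{i}" for i in range(12)])
    r1 = adjusted_permanova(dm, exposure, n_perm=499, seed=3)
    r2 = adjusted_permanova(dm2, exposure[perm], n_perm=499, seed=3)
    assert r1.pseudo_F == pytest.approx(r2.pseudo_F, abs=1e-10)
    assert abs(r1.p_value - r2.p_value) < 0.08


def test_permanova_freedman_lane_scheme_agrees_roughly():
    rng = np.random.default_rng(17)
    pts = rng.normal(size=(24, 3))
    exposure = rng.normal(size=24)
    cov = pd.DataFrame({"c": rng.normal(size=24)})
    dm = euclid_dm(pts)
    p_raw = adjusted_permanova(dm, exposure, cov, n_perm=499, seed=0).p_value
    p_fl = adjusted_permanova(
        dm, exposure, cov, n_perm=499, seed=0, scheme="fl"
    ).p_value
    assert abs(p_raw - p_fl) < 0.15


def test_permanova_error_cases():
    dm = euclid_dm(np.arange(6.0))
    with pytest.raises(ValidationError, match="constant"):
        adjusted_permanova(dm, np.ones(6), n_perm=9)
    exposure = np.arange(6.0)
    collinear = pd.DataFrame({"dup": exposure * 2.0})
    with pytest.raises(ValidationError, match="collinear"):
        adjusted_permanova(dm, exposure, collinear, n_perm=9)
    # sequential table shape
    res = adjusted_permanova(
        dm, exposure, pd.DataFrame({"c": [1, 0, 1, 0, 1, 0.5]}), n_perm=9
    )
    assert list(res.table["term"]) == ["c", "exposure", "residual"]
    assert res.df["residual"] == 6 - 3


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


def test_pcoa_recovers_line_and_reconstructs_distances():
    rng = np.random.default_rng(5)
    x = np.sort(rng.uniform(0, 10, size=15))
    dm = euclid_dm(x)
    res = pcoa(dm)
    r = np.corrcoef(res.coordinates[:, 0], x)[0, 1]
    assert abs(r) > 0.999
    # Euclidean input: coordinates reproduce the distances
    recon = squareform(pdist(res.coordinates[:, res.eigenvalues[: res.coordinates.shape[1]] > 0]))
    np.testing.assert_allclose(recon, dm.data, atol=1e-8)
    np.testing.assert_allclose(res.coordinates.mean(axis=0), 0, atol=1e-10)


def test_pcoa_equilateral_symmetry_and_proportions():
    d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
    res = pcoa(DistanceMatrix(d, ids=list("abc")))
    assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])
    assert res.eigenvalues[0] > 0
    pos = res.proportion_explained[res.eigenvalues > 0]
    assert pos.sum() == pytest.approx(1.0)
    assert (np.diff(res.eigenvalues) <= 1e-12).all()  # decreasing order


def test_pcoa_matches_reference_implementation():
    from skbio.stats.ordination import pcoa as skbio_pcoa

    rng = np.random.default_rng(19)
    pts = rng.normal(size=(10, 4))
    dm = euclid_dm(pts)
    ours = pcoa(dm)
    ref = skbio_pcoa(dm, number_of_dimensions=3)
    for k in range(3):
        ours_axis = ours.coordinates[:, k]
        ref_axis = ref.samples.iloc[:, k].to_numpy()
        assert abs(np.corrcoef(ours_axis, ref_axis)[0, 1]) == pytest.approx(1.0, abs=1e-8)


def test_pcoa_rejects_all_zero():
    with pytest.raises(ValidationError):
        pcoa(DistanceMatrix(np.zeros((3, 3)), ids=list("abc")))


# ---------------------------------------------------------------------------
# extreme-quartile contrast with BCa bootstrap
# ---------------------------------------------------------------------------


def quartile_vector(n1, n4, n_other=0):
    return np.array([1] * n1 + [4] * n4 + [2] * n_other)


def test_contrast_degenerate_distances_collapse_ci():
    n = 8
    d = np.full((n, n), 0.7)
    np.fill_diagonal(d, 0.0)
    dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])
    with pytest.warns(UserWarning, match="degenerate"):
        qc = extreme_quartile_contrast(dm, quartile_vector(4, 4), n_boot=100, seed=0)
    assert qc.mean_distance == qc.ci_low == qc.ci_high == 0.7


def test_contrast_z0_near_zero_for_smooth_statistic():
    rng = np.random.default_rng(23)
    dm = euclid_dm(rng.normal(size=30))
    qc = extreme_quartile_contrast(dm, quartile_vector(15, 15), n_boot=4000, seed=1)
    assert abs(qc.z0) < 0.12
    assert qc.ci_low <= qc.mean_distance <= qc.ci_high


def test_contrast_matches_scipy_bca_reference():
    """Subject-resampling BCa interval agrees with an independent reference
    (scipy's multi-sample BCa bootstrap of the same statistic)."""
    from scipy.stats import bootstrap as scipy_bootstrap

    rng = np.random.default_rng(29)
    d = euclid_dm(rng.normal(size=26))
    q = quartile_vector(13, 13)
    qc = extreme_quartile_contrast(d, q, n_boot=6000, seed=2)

    i1 = np.nonzero(q == 1)[0]
    i4 = np.nonzero(q == 4)[0]

    def stat(a, b):
        return d.data[np.ix_(a.astype(int), b.astype(int))].mean()

    ref = scipy_bootstrap(
        (i1, i4), stat, method="BCa", n_resamples=6000, vectorized=False, rng=3
    )
    spread = np.std(ref.bootstrap_distribution)
    assert qc.ci_low == pytest.approx(ref.confidence_interval.low, abs=0.3 * spread)
    assert qc.ci_high == pytest.approx(ref.confidence_interval.high, abs=0.3 * spread)


def test_bca_interval_formula_against_scipy_one_sample():
    """bca_interval applied to a plain mean matches scipy's BCa."""
    from scipy.stats import bootstrap as scipy_bootstrap

    rng = np.random.default_rng(31)
    x = rng.exponential(size=60)
    boot = np.array(
        [rng.choice(x, size=60, replace=True).mean() for _ in range(4000)]
    )
    jack = np.array([np.delete(x, k).mean() for k in range(60)])
    lo, hi, z0, a = bca_interval(boot, x.mean(), jack)
    ref = scipy_bootstrap((x,), np.mean, method="BCa", n_resamples=4000, rng=5)
    se = np.std(boot)
    assert lo == pytest.approx(ref.confidence_interval.low, abs=0.25 * se)
    assert hi == pytest.approx(ref.confidence_interval.high, abs=0.25 * se)


def test_contrast_requires_populated_extremes():
    dm = euclid_dm(np.arange(6.0))
    with pytest.raises(ValidationError):
        extreme_quartile_contrast(dm, np.array([1, 2, 2, 3, 3, 4]), n_boot=10)
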