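"""Distance-based community inference.

Three procedures operating on a pairwise community distance matrix:

* covariate-adjusted PERMANOVA — a permutation test of an exposure term
  conditional on nuisance covariates, built on the Gower-centered
  inner-product matrix ``G = -1/2 J (D o D) J`` and sequential
  (covariates-first) sums of squares via projection traces ``tr(H G)``;
* principal coordinates analysis (PCoA) — metric embedding of the distance
  matrix via eigendecomposition of ``G``;
* an extreme-quartile mean-distance contrast with a bias-corrected and
  accelerated (BCa) bootstrap confidence interval, resampling subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from skbio.stats.distance import DistanceMatrix

from .io import ValidationError


# ---------------------------------------------------------------------------
# shared linear-algebra helpers
# ---------------------------------------------------------------------------


def gower_center(d: np.ndarray) -> np.ndarray:
    """G = -1/2 J (D o D) J with J the centering projector."""
    a = -0.5 * d**2
    row = a.mean(axis=0, keepdims=True)
    col = a.mean(axis=1, keepdims=True)
    return a - row - col + a.mean()


def _hat_trace(x: np.ndarray, g: np.ndarray) -> tuple[float, int]:
    """tr(H G) for the hat matrix of design x, plus rank(x)."""
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    rank = int((diag > diag.max() * 1e-10).sum()) if diag.size else 0
    q = q[:, :rank]
    return float(np.einsum("ij,jk,ik->", q.T, g, q.T)), rank


# ---------------------------------------------------------------------------
# adjusted PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    """Pseudo-F and permutation p-value for the exposure term, with the
    sequential decomposition table (term, df, SS, pseudo_F, p)."""

    pseudo_F: float
    p_value: float
    n_permutations: int
    terms: list[str]
    df: dict[str, int]
    table: pd.DataFrame = field(repr=False, default=None)


def adjusted_permanova(
    dm: DistanceMatrix,
    exposure: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    n_perm: int = 10_000,
    seed: int | None = 0,
    scheme: str = "raw-exposure",
) -> PermanovaResult:
    """Permutation test of a (typically continuous) exposure on a distance
    matrix, conditional on covariates.

    The decomposition is sequential with covariates entered first, so the
    exposure pseudo-F is ``(SS_exposure / df_exp) / (SS_residual / df_res)``
    with SS terms computed as projection traces against the Gower-centered
    matrix.  Permutation schemes: ``"raw-exposure"`` permutes the exposure
    column holding covariates fixed; ``"fl"`` (Freedman-Lane) permutes the
    residuals of the exposure regressed on the covariates.  The p-value
    convention counts the observed statistic: ``p = (1 + b) / (1 + B)``.
    """
    d = dm.data
    n = d.shape[0]
    exposure = np.asarray(exposure, dtype=float)
    if exposure.shape != (n,):
        raise ValidationError("exposure length does not match distance matrix")
    if np.ptp(exposure) == 0:
        raise ValidationError("exposure is constant; no contrast to test")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if scheme not in ("raw-exposure", "fl"):
        raise ValidationError(f"unknown permutation scheme {scheme!r}")

    intercept = np.ones((n, 1))
    if covariates is not None and covariates.shape[1] > 0:
        cov = np.asarray(covariates, dtype=float)
        if cov.shape[0] != n:
            raise ValidationError("covariate rows do not match distance matrix")
        cov_names = list(covariates.columns)
    else:
        cov = np.empty((n, 0))
        cov_names = []
    x_reduced = np.hstack([intercept, cov])
    x_full = np.hstack([x_reduced, exposure[:, None]])
    rank_full = np.linalg.matrix_rank(x_full)
    if rank_full < x_full.shape[1]:
        # find collinear columns by incremental rank
        collinear, r = [], 0
        names = ["intercept", *cov_names, "exposure"]
        for k in range(x_full.shape[1]):
            rk = np.linalg.matrix_rank(x_full[:, : k + 1])
            if rk == r:
                collinear.append(names[k])
            r = rk
        raise ValidationError(f"design matrix rank deficient; collinear: {collinear}")

    g = gower_center(d)
    ss_total = float(np.trace(g))
    tr_reduced, rank_reduced = _hat_trace(x_reduced, g)
    df_exp = x_full.shape[1] - rank_reduced
    df_res = n - x_full.shape[1]
    if df_res <= 0:
        raise ValidationError("no residual degrees of freedom")

    def exposure_f(expo: np.ndarray) -> float:
        tr_full, _ = _hat_trace(np.hstack([x_reduced, expo[:, None]]), g)
        ss_exp = tr_full - tr_reduced
        ss_res = ss_total - tr_full
        return (ss_exp / df_exp) / (ss_res / df_res)

    f_obs = exposure_f(exposure)

    if scheme == "fl":
        # Freedman-Lane on the reduced model: permute exposure residuals
        beta, *_ = np.linalg.lstsq(x_reduced, exposure, rcond=None)
        fitted = x_reduced @ beta
        resid = exposure - fitted
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if scheme == "raw-exposure":
            expo_p = exposure[perm]
        else:
            expo_p = fitted + resid[perm]
        if exposure_f(expo_p) >= f_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)

    # sequential per-term table (each covariate in order, then exposure)
    rows = []
    x_cur = intercept
    tr_cur, rank_cur = _hat_trace(x_cur, g)
    for name, col in zip(cov_names, cov.T):
        x_nxt = np.hstack([x_cur, col[:, None]])
        tr_nxt, rank_nxt = _hat_trace(x_nxt, g)
        rows.append((name, rank_nxt - rank_cur, tr_nxt - tr_cur))
        x_cur, tr_cur, rank_cur = x_nxt, tr_nxt, rank_nxt
    tr_full, _ = _hat_trace(x_full, g)
    rows.append(("exposure", df_exp, tr_full - tr_cur))
    ss_res = ss_total - tr_full
    ms_res = ss_res / df_res
    table = pd.DataFrame(rows, columns=["term", "df", "SS"])
    table["pseudo_F"] = (table["SS"] / table["df"]) / ms_res
    table["p"] = np.nan
    table.loc[table["term"] == "exposure", "p"] = p
    table = pd.concat(
        [
            table,
            pd.DataFrame(
                [("residual", df_res, ss_res, np.nan, np.nan)], columns=table.columns
            ),
        ],
        ignore_index=True,
    )
    return PermanovaResult(
        pseudo_F=float(f_obs),
        p_value=float(p),
        n_permutations=n_perm,
        terms=[*cov_names, "exposure"],
        df={**{nm: int(dfk) for nm, dfk, _ in rows}, "residual": df_res},
        table=table,
    )


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


@dataclass
class PcoaResult:
    """Sample coordinates on positive-eigenvalue axes, all eigenvalues in
    decreasing order (negatives reported, not corrected), and the share of
    positive inertia explained per axis."""

    sample_ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix) -> PcoaResult:
    """Classical metric scaling: eigendecomposition of the Gower-centered
    inner-product matrix; coordinates are eigenvectors scaled by the square
    root of their (positive) eigenvalues."""
    d = dm.data
    if np.all(d == 0):
        raise ValidationError("all-zero distance matrix")
    g = gower_center(d)
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), abs(vals[-1])) * 1e-12
    pos = vals > tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    coords -= coords.mean(axis=0, keepdims=True)  # numerically recenter
    prop = vals / vals[pos].sum()
    return PcoaResult(list(dm.ids), coords, vals, prop)


# ---------------------------------------------------------------------------
# extreme-quartile contrast with BCa bootstrap
# ---------------------------------------------------------------------------


@dataclass
class QuartileContrast:
    """Mean pairwise distance over (Q1, Q4) sample pairs with a BCa 95%
    bootstrap interval (subject-level resampling)."""

    mean_distance: float
    ci_low: float
    ci_high: float
    n_boot: int
    z0: float = 0.0
    acceleration: float = 0.0


def _cross_mean(d: np.ndarray, i1: np.ndarray, i4: np.ndarray) -> float:
    return float(d[np.ix_(i1, i4)].mean())


def bca_interval(
    boot: np.ndarray, observed: float, jackknife: np.ndarray, level: float = 0.95
) -> tuple[float, float, float, float]:
    """BCa bounds from bootstrap replicates and jackknife leave-one-out
    statistics.  Returns (low, high, z0, acceleration)."""
    n_boot = boot.size
    frac = np.clip((boot < observed).mean(), 1 / (2 * n_boot), 1 - 1 / (2 * n_boot))
    z0 = norm.ppf(frac)
    jk_dev = jackknife.mean() - jackknife
    denom = (jk_dev**2).sum() ** 1.5
    a = (jk_dev**3).sum() / (6 * denom) if denom > 0 else 0.0
    alpha = (1 - level) / 2
    lo_hi = []
    for z_alpha in (norm.ppf(alpha), norm.ppf(1 - alpha)):
        adj = z0 + (z0 + z_alpha) / (1 - a * (z0 + z_alpha))
        lo_hi.append(float(np.quantile(boot, norm.cdf(adj))))
    return lo_hi[0], lo_hi[1], float(z0), float(a)


def extreme_quartile_contrast(
    dm: DistanceMatrix,
    quartiles: Sequence[int],
    n_boot: int = 2_000,
    seed: int | None = 0,
) -> QuartileContrast:
    """Mean distance between all (Q1 sample, Q4 sample) pairs, with a 95%
    BCa interval from resampling subjects (not pairs) with replacement
    within each extreme quartile."""
    q = np.asarray(quartiles)
    d = dm.data
    if q.shape[0] != d.shape[0]:
        raise ValidationError("quartile labels do not match distance matrix")
    i1 = np.nonzero(q == 1)[0]
    i4 = np.nonzero(q == 4)[0]
    if i1.size < 2 or i4.size < 2:
        raise ValidationError("extreme quartiles must each contain >= 2 samples")
    observed = _cross_mean(d, i1, i4)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        r1 = rng.choice(i1, size=i1.size, replace=True)
        r4 = rng.choice(i4, size=i4.size, replace=True)
        boot[b] = _cross_mean(d, r1, r4)

    if np.ptp(boot) == 0 and boot[0] == observed:
        warnings.warn("degenerate bootstrap distribution; CI collapses to point")
        return QuartileContrast(observed, observed, observed, n_boot)

    jack = []
    for k in range(i1.size):
        jack.append(_cross_mean(d, np.delete(i1, k), i4))
    for k in range(i4.size):
        jack.append(_cross_mean(d, i1, np.delete(i4, k)))
    lo, hi, z0, a = bca_interval(boot, observed, np.asarray(jack))
    return QuartileContrast(observed, lo, hi, n_boot, z0, a)
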