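"""Per-OTU differential abundance via a two-part zero-inflated
logistic-normal (ZILN) regression with minimax-concave-penalty (MCP)
selection of exposure-associated OTUs.

Model, per OTU j with design row ``X_i`` (intercept, ln-arsenic exposure,
specific gravity, feeding indicators):

* zero part — presence indicator ``Delta_ij ~ Bernoulli(pi_ij)`` with
  ``logit(pi_ij) = X_i . gamma_j``, fit by logistic score equations;
* positive part — ``logit(Y_ij) | Delta_ij = 1 ~ Normal(X_i . beta_j,
  sigma2_j)``, fit by least-squares score equations, with robust
  (HC0 sandwich) standard errors.

Taxa are treated as working-independent; robustness to the inter-taxon
correlation induced by the shared phylogeny comes from the sandwich
variances rather than a tree-structured working correlation.

Selection: the exposure coefficients {beta_j,exposure} are refit jointly
under the MCP

    P(b; lambda, gamma) = lambda|b| - b^2/(2 gamma)   for |b| <= gamma lambda
                        = gamma lambda^2 / 2          otherwise

by coordinate descent; because taxa are working-independent, the update is
the closed-form univariate MCP threshold on the covariate-partialled,
standardized exposure.  ``lambda`` is tuned by an extended BIC (per-variable
penalty ``log N + 2 zeta log m``) that controls family-wise false selection
across the many candidate OTUs; ``zeta = 0`` recovers the classical BIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import ValidationError


def logit_transform(y):
    """log(y / (1 - y)): the additive log-ratio of one OTU against the rest
    of the composition.  Defined only on (0, 1) — zeros belong to the zero
    part of the model, never here."""
    arr = np.asarray(y, dtype=float)
    if ((arr <= 0) | (arr >= 1)).any():
        raise ValidationError("logit requires values strictly inside (0, 1)")
    out = np.log(arr / (1 - arr))
    return float(out) if out.ndim == 0 else out


@dataclass
class ZilnConfig:
    """mcp_gamma: MCP concavity (> 1; 3 is the standard default).
    mcp_lambda_grid: explicit penalty grid, or None for a 50-point
        log-spaced grid from lambda_max (smallest lambda zeroing every
        effect) down to lambda_max / 100.
    min_prevalence: minimum fraction of nonzero samples for an OTU to be
        modeled at all.
    tuning: "bic" (extended BIC over the grid) or "fixed_lambda".
    ebic_zeta: weight of the 2*zeta*log(m) extended-BIC term (0 = plain BIC).
    """

    mcp_lambda_grid: Optional[np.ndarray] = None
    mcp_gamma: float = 3.0
    min_prevalence: float = 0.1
    tuning: str = "bic"
    fixed_lambda: float = 0.0
    ebic_zeta: float = 1.0

    def __post_init__(self):
        if self.mcp_gamma <= 1:
            raise ValidationError("mcp_gamma must exceed 1")
        if self.tuning not in ("bic", "fixed_lambda"):
            raise ValidationError(f"unknown tuning {self.tuning!r}")


@dataclass
class ZilnFit:
    """Coefficients and selection results for all modeled OTUs.

    ``gamma``/``beta`` are (otu x coefficient) frames (zero part /
    positive part); ``penalized_beta`` holds the MCP-refit exposure effect,
    zero for unselected OTUs.
    """

    otu_ids: list[str]
    design_columns: list[str]
    exposure_col: str
    gamma: pd.DataFrame
    beta: pd.DataFrame
    robust_se: pd.DataFrame
    sigma2: pd.Series
    prevalence: pd.Series
    penalized_beta: pd.Series
    selected: pd.Series
    lambda_selected: float
    lambda_grid: np.ndarray
    excluded: list[str] = field(default_factory=list)
    nonconverged: list[str] = field(default_factory=list)

    @property
    def selected_otus(self) -> list[str]:
        return [o for o in self.otu_ids if self.selected[o]]


def mcp_threshold(z: float, lam: float, gamma: float) -> float:
    """Closed-form MCP solution of min_b (b - z)^2 / 2 + P(b; lam, gamma)
    for a standardized covariate (unit curvature)."""
    if abs(z) > gamma * lam:
        return z
    soft = np.sign(z) * max(abs(z) - lam, 0.0)
    return soft / (1.0 - 1.0 / gamma)


def _partial_out(nuisance: np.ndarray, v: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(nuisance, v, rcond=None)
    return v - nuisance @ beta


def fit_ziln(
    Y: np.ndarray,
    X: pd.DataFrame,
    otu_ids: Sequence[str],
    exposure_col: str = "ln_arsenic",
    config: ZilnConfig | None = None,
) -> ZilnFit:
    """Fit the two-part model per OTU, then MCP-refit the exposure effects.

    ``Y`` is the (samples x OTUs) relative-abundance matrix (rows sum to 1);
    ``X`` is the design with an intercept column and ``exposure_col``.
    OTUs below ``min_prevalence`` or with fewer than 2 positive samples are
    excluded with a warning.
    """
    config = config or ZilnConfig()
    Y = np.asarray(Y, dtype=float)
    if exposure_col not in X.columns:
        raise ValidationError(f"design lacks exposure column {exposure_col!r}")
    n = Y.shape[0]
    if X.shape[0] != n:
        raise ValidationError("design rows do not match abundance rows")
    Xmat = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xmat) < Xmat.shape[1]:
        raise ValidationError("design matrix is rank deficient")
    cols = list(X.columns)
    e = cols.index(exposure_col)
    p = len(cols)

    kept, excluded, nonconv = [], [], []
    gamma_rows, beta_rows, se_rows = [], [], []
    sigma2, prevalence = {}, {}
    # partialled quantities cached for the MCP stage
    part_x, part_y, npos_map = {}, {}, {}

    for j, otu in enumerate(otu_ids):
        yj = Y[:, j]
        delta = yj > 0
        prev = float(delta.mean())
        npos = int(delta.sum())
        if prev < config.min_prevalence or npos < 2:
            excluded.append(otu)
            continue
        if npos <= p:
            warnings.warn(f"OTU {otu}: too few positive samples to fit; excluded")
            excluded.append(otu)
            continue
        kept.append(otu)
        prevalence[otu] = prev

        # zero part: logistic score equations on presence/absence
        if delta.all():
            gamma_rows.append(np.full(p, np.nan))  # no zeros: part degenerate
        else:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    logit_fit = sm.Logit(delta.astype(float), Xmat).fit(
                        disp=0, maxiter=100
                    )
                if not logit_fit.mle_retvals.get("converged", True):
                    nonconv.append(otu)
                gamma_rows.append(np.asarray(logit_fit.params))
            except Exception:
                nonconv.append(otu)
                gamma_rows.append(np.full(p, np.nan))

        # positive part: least squares on logit relative abundance
        z = logit_transform(yj[delta])
        Xp = Xmat[delta]
        ols = sm.OLS(z, Xp).fit(cov_type="HC0")
        beta_rows.append(np.asarray(ols.params))
        se_rows.append(np.asarray(ols.bse))
        resid = z - Xp @ ols.params
        sigma2[otu] = float(resid @ resid / max(npos - p, 1))

        nuisance = np.delete(Xp, e, axis=1)
        part_x[otu] = _partial_out(nuisance, Xp[:, e])
        part_y[otu] = _partial_out(nuisance, z)
        npos_map[otu] = npos

    if not kept:
        raise ValidationError("no OTU passes the prevalence filter")

    gamma = pd.DataFrame(gamma_rows, index=kept, columns=cols)
    beta = pd.DataFrame(beta_rows, index=kept, columns=cols)
    robust_se = pd.DataFrame(se_rows, index=kept, columns=cols)

    # ---- MCP stage on the standardized, partialled exposure --------------
    z_std, scale, rss0 = {}, {}, {}
    for otu in kept:
        x, y = part_x[otu], part_y[otu]
        nj = npos_map[otu]
        sd = np.sqrt(x @ x / nj)
        if sd <= 0:
            z_std[otu], scale[otu] = 0.0, 1.0
            rss0[otu] = float(y @ y)
            continue
        xs = x / sd
        z_std[otu] = float(xs @ y / nj)  # standardized LS coefficient
        scale[otu] = float(sd)
        rss0[otu] = float(y @ y)

    abs_z = np.array([abs(z_std[o]) for o in kept])
    lam_max = abs_z.max() if abs_z.max() > 0 else 1.0
    if config.mcp_lambda_grid is not None:
        grid = np.asarray(config.mcp_lambda_grid, dtype=float)
    else:
        grid = np.geomspace(lam_max, lam_max / 100, 50)

    def solve(lam: float) -> dict[str, float]:
        return {
            o: mcp_threshold(z_std[o], lam, config.mcp_gamma) / scale[o]
            for o in kept
        }

    if config.tuning == "fixed_lambda":
        lam_star = float(config.fixed_lambda)
    else:
        m = len(kept)
        n_total = sum(npos_map.values())
        per_var = np.log(n_total) + 2 * config.ebic_zeta * np.log(max(m, 2))
        best = (np.inf, grid[0])
        for lam in sorted(grid, reverse=True):  # prefer sparser on ties
            bic = 0.0
            k = 0
            for o in kept:
                b_std = mcp_threshold(z_std[o], lam, config.mcp_gamma)
                nj = npos_map[o]
                rss = rss0[o] - 2 * b_std * z_std[o] * nj + b_std**2 * nj
                bic += nj * np.log(max(rss, 1e-300) / nj)
                k += b_std != 0.0
            bic += per_var * k
            if bic < best[0] - 1e-12:
                best = (bic, lam)
        lam_star = float(best[1])

    pen = solve(lam_star)
    penalized_beta = pd.Series(pen, index=kept)
    selected = penalized_beta != 0.0

    return ZilnFit(
        otu_ids=kept,
        design_columns=cols,
        exposure_col=exposure_col,
        gamma=gamma,
        beta=beta,
        robust_se=robust_se,
        sigma2=pd.Series(sigma2),
        prevalence=pd.Series(prevalence),
        penalized_beta=penalized_beta,
        selected=selected,
        lambda_selected=lam_star,
        lambda_grid=grid,
        excluded=excluded,
        nonconverged=nonconv,
    )


def classify_direction(fit: ZilnFit) -> pd.Series:
    """Sign of the penalized exposure effect for each selected OTU
    ('positive' / 'negative')."""
    out = {}
    for otu in fit.selected_otus:
        out[otu] = "positive" if fit.penalized_beta[otu] > 0 else "negative"
    return pd.Series(out, dtype=object)


@dataclass
class TaxonSummary:
    """Exposure effects averaged over the member OTUs of one taxon (the
    lowest assigned rank of each OTU's lineage)."""

    taxon: str
    aggregated_beta: float
    n_otus: int
    direction: str  # positive | negative | mixed | zero


_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


def lowest_assigned_rank(lineage: Optional[str]) -> str:
    """Deepest non-empty rank of a Greengenes-style lineage string."""
    if not lineage:
        return "unclassified"
    best = "unclassified"
    for part in lineage.split(";"):
        part = part.strip()
        for pref in _RANK_PREFIXES:
            if part.startswith(pref) and part[len(pref):]:
                best = part
    return best


def aggregate_by_taxon(
    fit: ZilnFit,
    taxonomy: Optional[dict[str, str]],
    which: str = "selected",
) -> list[TaxonSummary]:
    """Group OTUs by lowest assigned taxonomic rank and average their
    penalized exposure effects.  ``which``: aggregate 'selected' OTUs only
    (default) or 'all' modeled OTUs."""
    if which == "selected":
        otus = fit.selected_otus
    elif which == "all":
        otus = fit.otu_ids
    else:
        raise ValidationError(f"unknown aggregation scope {which!r}")
    groups: dict[str, list[str]] = {}
    for otu in otus:
        taxon = lowest_assigned_rank((taxonomy or {}).get(otu))
        groups.setdefault(taxon, []).append(otu)
    summaries = []
    for taxon in sorted(groups):
        betas = fit.penalized_beta[groups[taxon]].to_numpy()
        signs = set(np.sign(betas[betas != 0]))
        if len(signs) > 1:
            direction = "mixed"
        elif signs == {1.0}:
            direction = "positive"
        elif signs == {-1.0}:
            direction = "negative"
        else:
            direction = "zero"
        summaries.append(
            TaxonSummary(taxon, float(betas.mean()), len(betas), direction)
        )
    return summaries


def fit_table(fit: ZilnFit, taxonomy: Optional[dict[str, str]] = None) -> pd.DataFrame:
    """Per-OTU results table (otu, taxon, prevalence, zero/positive-part
    exposure coefficients, robust SE, penalized effect, selection flag)."""
    e = fit.exposure_col
    rows = []
    for otu in fit.otu_ids:
        pen = fit.penalized_beta[otu]
        rows.append(
            {
                "otu_id": otu,
                "taxon": lowest_assigned_rank((taxonomy or {}).get(otu)),
                "prevalence": fit.prevalence[otu],
                "gamma_exposure": fit.gamma.loc[otu, e],
                "beta_exposure": fit.beta.loc[otu, e],
                "robust_se": fit.robust_se.loc[otu, e],
                "penalized_beta": pen,
                "selected": bool(fit.selected[otu]),
                "direction": "positive" if pen > 0 else "negative" if pen < 0 else "",
            }
        )
    return pd.DataFrame(rows)
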