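"""Exposure and count-table preprocessing.

Covers the detection-limit substitution rule for censored urinary arsenic,
the natural-log exposure transform, feeding categorization and the four
sex x feeding analysis strata, single rarefaction of the OTU table to a
common depth, relative abundances, and the median/quartile exposure
groupings used by the ordination and distance-contrast analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .io import ExposureRecord, OtuTable, ValidationError


@dataclass
class PreprocessConfig:
    """Knobs for the preprocessing stage.

    lod_ugL: assay limit of detection in ug/L (default 0.05); censored
        values are substituted at half this value.
    rarefaction_depth: target reads per sample, or "auto" = minimum row sum.
    rarefaction_seed: seed for the single rarefaction draw.
    quantile_rule: numpy quantile method for quartile boundaries
        ("linear" = interpolation of order statistics, the common default).
    """

    lod_ugL: float = 0.05
    rarefaction_depth: int | str = "auto"
    rarefaction_seed: int = 0
    quantile_rule: str = "linear"

    def __post_init__(self):
        if self.lod_ugL <= 0:
            raise ValidationError("lod_ugL must be positive")


@dataclass(frozen=True)
class StratumLabel:
    """One of the four analysis strata: sex x (formula-fed vs exclusively
    breastfed), where formula-fed pools combination and exclusive formula."""

    sex: str  # "male" | "female"
    feeding_group: str  # "formula_fed" | "exclusive_breast"

    def __str__(self) -> str:
        return f"{self.feeding_group}_{self.sex}"


ALL_STRATA = (
    StratumLabel("male", "formula_fed"),
    StratumLabel("female", "formula_fed"),
    StratumLabel("male", "exclusive_breast"),
    StratumLabel("female", "exclusive_breast"),
)


# ---------------------------------------------------------------------------
# exposure
# ---------------------------------------------------------------------------


def substitute_lod(
    arsenic_ugL: float, below_lod: bool, lod_ugL: float = 0.05
) -> float:
    """Replace a below-detection-limit concentration by LOD/2.

    Detected values pass through unchanged; a detected value <= 0 is invalid.
    Idempotent and monotone non-decreasing in the input.
    """
    if lod_ugL <= 0:
        raise ValidationError("lod_ugL must be positive")
    if below_lod:
        return lod_ugL / 2.0
    if arsenic_ugL <= 0:
        raise ValidationError(
            f"detected arsenic concentration must be positive, got {arsenic_ugL}"
        )
    return float(arsenic_ugL)


def substitute_lod_records(
    records: Iterable[ExposureRecord], lod_ugL: float = 0.05
) -> list[ExposureRecord]:
    """Apply the LOD/2 substitution to every record (non-destructively)."""
    return [
        replace(r, arsenic_ugL=substitute_lod(r.arsenic_ugL, r.below_lod, lod_ugL))
        for r in records
    ]


def log_exposure(arsenic_ugL) -> np.ndarray | float:
    """Natural log of concentration; inputs must be positive (guaranteed
    after LOD substitution)."""
    arr = np.asarray(arsenic_ugL, dtype=float)
    if (arr <= 0).any():
        raise ValidationError("arsenic concentration must be positive for log")
    out = np.log(arr)
    return float(out) if out.ndim == 0 else out


def assign_feeding(ever_breastmilk: bool, ever_formula: bool) -> str:
    """Map feeding-history flags to the three dietary categories."""
    if ever_breastmilk and not ever_formula:
        return "exclusive_breast"
    if ever_formula and not ever_breastmilk:
        return "exclusive_formula"
    if ever_breastmilk and ever_formula:
        return "combination"
    raise ValidationError("infant must have received breastmilk, formula, or both")


def feeding_group(feeding: str) -> str:
    """Pool combination and exclusive formula into 'formula_fed'."""
    if feeding == "exclusive_breast":
        return "exclusive_breast"
    if feeding in ("combination", "exclusive_formula"):
        return "formula_fed"
    raise ValidationError(f"unknown feeding category {feeding!r}")


def stratify(records: Iterable[ExposureRecord]) -> dict[StratumLabel, list[str]]:
    """Partition subjects with known sex into the four analysis strata.

    Formula-fed = combination plus exclusively formula-fed.  Subjects with
    unreported sex are excluded from stratified analyses (they remain in the
    unstratified, all-subjects analysis).
    """
    strata: dict[StratumLabel, list[str]] = {s: [] for s in ALL_STRATA}
    for r in records:
        if r.sex == "unreported":
            continue
        strata[StratumLabel(r.sex, feeding_group(r.feeding))].append(r.sample_id)
    return strata


# ---------------------------------------------------------------------------
# count table
# ---------------------------------------------------------------------------


def rarefy(table: OtuTable, depth: int, seed: int = 0) -> OtuTable:
    """Subsample every sample, uniformly without replacement, to ``depth``
    reads.  A single rarefaction; deterministic given the seed."""
    depth = int(depth)
    if depth <= 0:
        raise ValidationError("rarefaction depth must be positive")
    row_sums = table.counts.sum(axis=1)
    short = np.nonzero(row_sums < depth)[0]
    if short.size:
        names = [table.sample_ids[i] for i in short]
        raise ValidationError(
            f"rarefaction depth {depth} exceeds total counts of samples {names}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.counts.shape[0]):
        row = table.counts[i]
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return OtuTable(list(table.sample_ids), list(table.otu_ids), out, table.taxonomy)


def auto_depth(table: OtuTable) -> int:
    """Minimum sequencing depth across samples (the rarefaction target)."""
    return int(table.counts.sum(axis=1).min())


def relative_abundance(table: OtuTable) -> np.ndarray:
    """Row-normalize counts to proportions (each row sums to 1)."""
    totals = table.counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValidationError("cannot normalize a sample with zero total counts")
    return table.counts / totals


# ---------------------------------------------------------------------------
# exposure groupings
# ---------------------------------------------------------------------------


def median_split(arsenic_ugL: np.ndarray) -> tuple[np.ndarray, float]:
    """Split subjects at the median concentration (values equal to the
    median go to the lower group).  Returns (labels in {0: <=median,
    1: >median}, median)."""
    arr = np.asarray(arsenic_ugL, dtype=float)
    if arr.size < 2:
        raise ValidationError("median split needs at least 2 samples")
    if np.ptp(arr) == 0:
        raise ValidationError("all concentrations identical: degenerate split")
    med = float(np.median(arr))
    return (arr > med).astype(int), med


def quartile_assign(
    arsenic_ugL: np.ndarray, quantile_rule: str = "linear"
) -> np.ndarray:
    """Assign each sample a quartile index 1..4 of the concentration
    distribution.  Boundary ties go to the lower quartile."""
    arr = np.asarray(arsenic_ugL, dtype=float)
    if arr.size < 8:
        raise ValidationError("quartile assignment needs at least 8 samples")
    if np.ptp(arr) == 0:
        raise ValidationError("all concentrations identical: degenerate quartiles")
    q1, q2, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method=quantile_rule)
    # values equal to a boundary fall in the lower quartile
    return (1 + (arr > q1).astype(int) + (arr > q2) + (arr > q3)).astype(int)
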