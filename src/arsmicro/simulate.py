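"""Synthetic infant-cohort generator.

Produces datasets with the statistical structure the analysis assumes —
zero-inflated compositional counts linked to a phylogeny, a log-normal
urinary-arsenic exposure with detection-limit censoring and feeding-group
mean shifts, sex and feeding strata with realistic margins — plus a planted
ground truth (which OTUs respond to exposure, at what size, and in which
sex x feeding stratum) for power and recovery studies.

Data-generating model for counts (mirrors the analysis model): per sample i
and OTU j, presence ``Delta_ij ~ Bernoulli(expit(a_j + g_j * lnAs_i *
1{stratum}))``; conditional on presence, logit-abundance ``~ Normal(m_j +
b_j * lnAs_i * 1{stratum}, sigma^2)``.  The positive abundances are closed
to a composition, multiplied by a log-normal read depth and rounded by
largest remainder so row sums are preserved exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.special import expit
from scipy.stats import truncnorm
from skbio import TreeNode

from .io import ExposureRecord, OtuTable, Phylogeny, ValidationError
from .preprocess import StratumLabel, feeding_group

# Cohort margins used as defaults: 204 subjects; sex 118 male / 81 female /
# 5 unreported; feeding 146 exclusively breastfed / 49 combination /
# 9 exclusively formula-fed, with sex and feeding independent (the observed
# feeding distributions are nearly identical by sex).
SEX_PROBS = {"male": 118 / 204, "female": 81 / 204, "unreported": 5 / 204}
FEEDING_PROBS = {
    "exclusive_breast": 146 / 204,
    "combination": 49 / 204,
    "exclusive_formula": 9 / 204,
}
# Log-normal exposure: group arithmetic means 0.5 / 0.9 / 1.2 ug/L with a
# common sdlog of 0.9, giving a breastfed median ~0.33 ug/L, an overall
# median near 0.36-0.4 ug/L and ~1.5% of draws below the 0.05 ug/L LOD.
_SDLOG = 0.9
EXPOSURE_MEAN_UGL = {
    "exclusive_breast": 0.5,
    "combination": 0.9,
    "exclusive_formula": 1.2,
}


@dataclass
class EffectSpec:
    """Planted exposure effect: ``n_affected`` OTUs receive a per-unit
    ln-arsenic shift of ``effect_size`` on logit-abundance and
    ``zero_effect_size`` on presence log-odds, confined to
    ``affected_stratum`` (None = every sample).  Half the affected OTUs get
    a positive sign, half negative."""

    n_affected: int = 10
    effect_size: float = 1.0
    zero_effect_size: float = 1.0
    affected_stratum: Optional[StratumLabel] = None


@dataclass
class SimulationSpec:
    """Full description of one synthetic cohort."""

    n_samples: int = 204
    n_otus: int = 100
    tree_shape: str = "random_coalescent"  # or "balanced"
    sex_probs: dict = field(default_factory=lambda: dict(SEX_PROBS))
    feeding_probs: dict = field(default_factory=lambda: dict(FEEDING_PROBS))
    exposure_mean_ugL: dict = field(
        default_factory=lambda: dict(EXPOSURE_MEAN_UGL)
    )
    exposure_sdlog: float = _SDLOG
    lod_ugL: float = 0.05
    effect: EffectSpec = field(default_factory=EffectSpec)
    zero_logodds_mean: float = 0.0  # baseline presence log-odds across OTUs
    zero_logodds_sd: float = 1.5
    abundance_mean: float = -4.0  # baseline mean logit-abundance across OTUs
    abundance_sd: float = 1.0
    abundance_sigma: float = 1.0  # residual sd of logit-abundance
    depth_meanlog: float = float(np.log(30_000))  # min depth lands ~10-12k
    depth_sdlog: float = 0.3
    otus_per_genus: int = 5
    seed: int = 0

    def __post_init__(self):
        for probs in (self.sex_probs, self.feeding_probs):
            if abs(sum(probs.values()) - 1) > 1e-9:
                raise ValidationError("probabilities must sum to 1")
        if self.effect.n_affected > self.n_otus:
            raise ValidationError("more affected OTUs than OTUs")


@dataclass
class SyntheticDataset:
    table: OtuTable
    records: list[ExposureRecord]
    tree: Phylogeny
    truth: dict


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------


def simulate_tree(n_otus: int, shape: str = "random_coalescent", seed: int = 0) -> Phylogeny:
    """Random binary tree over tips OTU_1..n with exponential branch
    lengths.  ``balanced`` builds a (near-)perfect binary topology."""
    if n_otus < 2:
        raise ValidationError("a tree needs at least 2 tips")
    rng = np.random.default_rng(seed)
    labels = [f"OTU_{k + 1}" for k in range(n_otus)]

    def leaf(name):
        return TreeNode(name=name, length=float(rng.exponential(0.1)))

    if shape == "random_coalescent":
        nodes = [leaf(nm) for nm in labels]
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            right = nodes.pop(j)
            left = nodes.pop(i)
            parent = TreeNode(length=float(rng.exponential(0.1)))
            parent.extend([left, right])
            nodes = nodes + [parent]
        root = nodes[0]
    elif shape == "balanced":
        def build(names):
            if len(names) == 1:
                return leaf(names[0])
            mid = (len(names) + 1) // 2
            parent = TreeNode(length=float(rng.exponential(0.1)))
            parent.extend([build(names[:mid]), build(names[mid:])])
            return parent
        root = build(labels)
    else:
        raise ValidationError(f"unknown tree shape {shape!r}")
    root.length = None
    return Phylogeny(root, rooted=True)


# ---------------------------------------------------------------------------
# exposure & covariates
# ---------------------------------------------------------------------------


def simulate_exposure(spec: SimulationSpec, seed: int | None = None) -> list[ExposureRecord]:
    """Draw sex, feeding category, censored log-normal urinary arsenic and
    truncated-normal specific gravity for every subject."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_samples
    sexes = rng.choice(
        list(spec.sex_probs), size=n, p=list(spec.sex_probs.values())
    )
    feedings = rng.choice(
        list(spec.feeding_probs), size=n, p=list(spec.feeding_probs.values())
    )
    sdlog = spec.exposure_sdlog
    # meanlog chosen so the group arithmetic mean matches the spec:
    # E[X] = exp(mu + sdlog^2/2)
    meanlog = {
        g: np.log(m) - sdlog**2 / 2 for g, m in spec.exposure_mean_ugL.items()
    }
    sg_dist = truncnorm(
        (0.99 - 1.015) / 0.005, (1.05 - 1.015) / 0.005, loc=1.015, scale=0.005
    )
    records = []
    for i in range(n):
        arsenic = float(rng.lognormal(meanlog[feedings[i]], sdlog))
        records.append(
            ExposureRecord(
                sample_id=f"S{i + 1:04d}",
                arsenic_ugL=arsenic,
                below_lod=arsenic < spec.lod_ugL,
                specific_gravity=float(sg_dist.rvs(random_state=rng)),
                sex=str(sexes[i]),
                feeding=str(feedings[i]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def largest_remainder_round(weights: np.ndarray, total: int) -> np.ndarray:
    """Round ``weights / weights.sum() * total`` to integers that sum to
    ``total`` exactly, by the largest-remainder rule."""
    target = weights / weights.sum() * total
    floors = np.floor(target).astype(np.int64)
    short = int(total - floors.sum())
    if short:
        order = np.argsort(-(target - floors), kind="stable")
        floors[order[:short]] += 1
    return floors


def _default_taxonomy(otu_ids: list[str], per_genus: int) -> dict[str, str]:
    phyla = ("Firmicutes", "Bacteroidetes", "Actinobacteria", "Proteobacteria")
    tax = {}
    for k, otu in enumerate(otu_ids):
        g = k // per_genus
        tax[otu] = (
            f"k__Bacteria;p__{phyla[g % len(phyla)]};c__;o__;f__;g__Genus{g + 1}"
        )
    return tax


def simulate_counts(
    tree: Phylogeny,
    records: list[ExposureRecord],
    spec: SimulationSpec,
    seed: int | None = None,
) -> tuple[OtuTable, dict]:
    """Generate the count table and the planted ground truth."""
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    otu_ids = [t.name for t in tree.tree.tips()]
    m = len(otu_ids)
    n = len(records)

    a = rng.normal(spec.zero_logodds_mean, spec.zero_logodds_sd, size=m)
    mu = rng.normal(spec.abundance_mean, spec.abundance_sd, size=m)

    eff = spec.effect
    affected = np.sort(rng.choice(m, size=eff.n_affected, replace=False))
    signs = np.where(np.arange(eff.n_affected) % 2 == 0, 1.0, -1.0)
    beta = np.zeros(m)
    gamma = np.zeros(m)
    beta[affected] = signs * eff.effect_size
    gamma[affected] = signs * eff.zero_effect_size

    ln_as = np.log([max(r.arsenic_ugL, spec.lod_ugL / 2) for r in records])
    ln_as_c = ln_as - ln_as.mean()  # centered so effects do not shift margins
    if eff.affected_stratum is None:
        in_stratum = np.ones(n)
    else:
        lab = eff.affected_stratum
        in_stratum = np.array(
            [
                float(
                    r.sex == lab.sex and feeding_group(r.feeding) == lab.feeding_group
                )
                for r in records
            ]
        )

    depths = np.maximum(
        rng.lognormal(spec.depth_meanlog, spec.depth_sdlog, size=n), 100
    ).astype(np.int64)

    counts = np.zeros((n, m), dtype=np.int64)
    resampled = 0
    for i in range(n):
        dose = ln_as_c[i] * in_stratum[i]
        for _attempt in range(100):
            pres = rng.random(m) < expit(a + gamma * dose)
            if pres.any():
                break
            resampled += 1
        else:
            raise RuntimeError("could not generate a non-empty sample")
        eps = rng.normal(0.0, spec.abundance_sigma, size=m)
        w = np.where(pres, expit(mu + beta * dose + eps), 0.0)
        counts[i] = largest_remainder_round(w, int(depths[i]))
        if counts[i].sum() == 0:  # pathological rounding guard
            counts[i, np.argmax(w)] = int(depths[i])

    table = OtuTable(
        [r.sample_id for r in records],
        otu_ids,
        counts,
        taxonomy=_default_taxonomy(otu_ids, spec.otus_per_genus),
    )
    truth = {
        "affected_otus": [otu_ids[k] for k in affected],
        "effect_sizes": {otu_ids[k]: float(beta[k]) for k in affected},
        "zero_effect_sizes": {otu_ids[k]: float(gamma[k]) for k in affected},
        "affected_stratum": (
            None if eff.affected_stratum is None else str(eff.affected_stratum)
        ),
        "resampled_samples": resampled,
    }
    return table, truth


def simulate_dataset(spec: SimulationSpec | None = None) -> SyntheticDataset:
    """Tree + exposure records + counts + truth, fully determined by
    ``spec.seed``."""
    spec = spec or SimulationSpec()
    ss = np.random.SeedSequence(spec.seed)
    s_tree, s_expo, s_counts = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)]
    tree = simulate_tree(spec.n_otus, spec.tree_shape, seed=s_tree)
    records = simulate_exposure(spec, seed=s_expo)
    table, truth = simulate_counts(tree, records, spec, seed=s_counts)
    return SyntheticDataset(table, records, tree, truth)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write table.tsv, metadata.csv, tree.nwk and truth.json."""
    from pathlib import Path

    from .io import write_metadata, write_otu_table, write_tree

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_otu_table(ds.table, out / "table.tsv")
    write_metadata(ds.records, out / "metadata.csv")
    write_tree(ds.tree, out / "tree.nwk")
    (out / "truth.json").write_text(json.dumps(ds.truth, indent=2))
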