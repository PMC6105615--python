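"""End-to-end orchestration: ingest -> preprocess -> distances ->
PERMANOVA / PCoA / quartile contrast -> ZILN -> reports.

The full cohort and each of the four sex x feeding strata are analyzed with
two covariate-adjustment sets (feeding + specific gravity, and specific
gravity only).  Stratified analyses reuse submatrices of the single
cohort-wide distance matrix, so all groups share one rarefaction draw.
A machine-readable run manifest records the configuration snapshot, every
seed, input digests and per-stage timings.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import community, gunifrac, preprocess, ziln
from .io import (
    ExposureRecord,
    OtuTable,
    Phylogeny,
    align_inputs,
    read_metadata,
    read_otu_table,
    read_tree,
)
from .preprocess import ALL_STRATA, PreprocessConfig, StratumLabel


@dataclass
class PipelineConfig:
    """Analysis configuration (all seeds explicit for reproducibility)."""

    otu_table: str = "table.tsv"
    otu_format: str = "tsv"
    metadata: str = "metadata.csv"
    tree: str = "tree.nwk"
    outdir: str = "results"
    lod_ugL: float = 0.05
    rarefaction_depth: int | str = "auto"
    rarefaction_seed: int = 0
    quantile_rule: str = "linear"
    alpha: float = 0.5
    n_perm: int = 10_000
    permanova_seed: int = 0
    permutation_scheme: str = "raw-exposure"
    n_boot: int = 2_000
    bootstrap_seed: int = 0
    min_stratum_n: int = 10  # below this, distance-based tests are skipped
    ziln_min_prevalence: float = 0.1

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    software_version: str
    input_digests: dict
    groups: dict = field(default_factory=dict)  # per-group outputs + stats
    timings_s: dict = field(default_factory=dict)
    rarefaction_depth: int = 0
    n_samples: int = 0
    n_otus: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _feeding_design(records: list[ExposureRecord], stratum: Optional[StratumLabel]) -> pd.DataFrame:
    """Feeding covariates for the adjusted model.

    Unstratified: treatment-coded indicators with exclusive breastfeeding as
    reference.  Within formula-fed strata: a single formula-exclusivity
    indicator (exclusively formula vs breast milk with supplementation).
    Within breastfed strata feeding is constant, so no column.
    """
    if stratum is None:
        return pd.DataFrame(
            {
                "combination": [float(r.feeding == "combination") for r in records],
                "exclusive_formula": [
                    float(r.feeding == "exclusive_formula") for r in records
                ],
            }
        )
    if stratum.feeding_group == "formula_fed":
        return pd.DataFrame(
            {
                "exclusive_formula": [
                    float(r.feeding == "exclusive_formula") for r in records
                ]
            }
        )
    return pd.DataFrame(index=range(len(records)))


def _drop_constant(df: pd.DataFrame) -> pd.DataFrame:
    keep = [c for c in df.columns if df[c].nunique() > 1]
    return df[keep]


def _analyze_group(
    name: str,
    sample_ids: list[str],
    dm,
    rel_abund: np.ndarray,
    table: OtuTable,
    records: list[ExposureRecord],
    cfg: PipelineConfig,
    stratum: Optional[StratumLabel],
    outdir: Path,
) -> dict:
    """All distance-based tests plus the ZILN fit for one sample group."""
    out: dict = {"n": len(sample_ids), "skipped": []}
    idx = {r.sample_id: k for k, r in enumerate(records)}
    recs = [records[idx[s]] for s in sample_ids]
    arsenic = np.array([r.arsenic_ugL for r in recs])
    ln_as = preprocess.log_exposure(arsenic)
    sg = pd.DataFrame({"specific_gravity": [r.specific_gravity for r in recs]})

    if len(sample_ids) < cfg.min_stratum_n:
        out["skipped"].append(f"group too small (n={len(sample_ids)})")
        return out

    sub_dm = dm.filter(sample_ids)
    gdir = outdir / name
    gdir.mkdir(parents=True, exist_ok=True)

    # PERMANOVA under both adjustment sets
    out["permanova"] = {}
    feeding = _drop_constant(_feeding_design(recs, stratum))
    adjust_sets = {
        "feeding_and_sg": pd.concat([feeding.reset_index(drop=True), sg], axis=1),
        "sg_only": sg,
    }
    for adj_name, cov in adjust_sets.items():
        res = community.adjusted_permanova(
            sub_dm,
            ln_as,
            covariates=cov,
            n_perm=cfg.n_perm,
            seed=cfg.permanova_seed,
            scheme=cfg.permutation_scheme,
        )
        res.table.to_csv(gdir / f"permanova_{adj_name}.tsv", sep="\t", index=False)
        out["permanova"][adj_name] = {
            "pseudo_F": res.pseudo_F,
            "p_value": res.p_value,
            "n_permutations": res.n_permutations,
        }

    # PCoA + median-split labels for plotting
    ord_res = community.pcoa(sub_dm)
    labels, med = preprocess.median_split(arsenic)
    coords = pd.DataFrame(
        ord_res.coordinates[:, : min(5, ord_res.coordinates.shape[1])],
        index=sample_ids,
    )
    coords.columns = [f"PC{k + 1}" for k in range(coords.shape[1])]
    coords["median_group"] = np.where(labels == 1, f">{med:.2f}", f"<={med:.2f}")
    coords.index.name = "sample_id"
    coords.to_csv(gdir / "pcoa_coordinates.tsv", sep="\t")
    out["pcoa"] = {
        "median_ugL": med,
        "proportion_explained_PC1_PC2": [
            float(ord_res.proportion_explained[0]),
            float(ord_res.proportion_explained[1]),
        ],
    }

    # extreme-quartile contrast
    if len(sample_ids) >= 8:
        quart = preprocess.quartile_assign(arsenic, cfg.quantile_rule)
        contrast = community.extreme_quartile_contrast(
            sub_dm, quart, n_boot=cfg.n_boot, seed=cfg.bootstrap_seed
        )
        out["quartile_contrast"] = {
            "mean_distance": contrast.mean_distance,
            "ci_low": contrast.ci_low,
            "ci_high": contrast.ci_high,
            "n_boot": contrast.n_boot,
        }
        (gdir / "quartile_contrast.json").write_text(
            json.dumps(out["quartile_contrast"], indent=2)
        )
    else:
        out["skipped"].append("quartile contrast (fewer than 8 samples)")

    # ZILN differential abundance
    sub_table = table.select_samples(sample_ids)
    sub_rel = preprocess.relative_abundance(sub_table)
    design = pd.concat(
        [
            pd.DataFrame({"intercept": np.ones(len(sample_ids))}),
            pd.DataFrame({"ln_arsenic": ln_as}),
            sg.reset_index(drop=True),
            feeding.reset_index(drop=True),
        ],
        axis=1,
    )
    try:
        fit = ziln.fit_ziln(
            sub_rel,
            design,
            sub_table.otu_ids,
            config=ziln.ZilnConfig(min_prevalence=cfg.ziln_min_prevalence),
        )
    except Exception as exc:
        out["skipped"].append(f"ZILN fit failed: {exc}")
        return out
    ziln.fit_table(fit, table.taxonomy).to_csv(
        gdir / "ziln_otus.tsv", sep="\t", index=False
    )
    directions = ziln.classify_direction(fit)
    taxa = ziln.aggregate_by_taxon(fit, table.taxonomy)
    pd.DataFrame([asdict(t) for t in taxa]).to_csv(
        gdir / "ziln_taxa.tsv", sep="\t", index=False
    )
    out["ziln"] = {
        "n_modeled": len(fit.otu_ids),
        "n_selected": int(fit.selected.sum()),
        "n_positive": int((directions == "positive").sum()),
        "n_negative": int((directions == "negative").sum()),
        "lambda": fit.lambda_selected,
        "selected_otus": fit.selected_otus,
    }
    return out


def run_all(
    cfg: PipelineConfig,
    table: OtuTable | None = None,
    records: list[ExposureRecord] | None = None,
    tree: Phylogeny | None = None,
) -> RunManifest:
    """Execute the whole analysis.  Inputs are read from the configured
    paths unless passed in-memory (the synthetic path used by tests)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    digests = {}
    t0 = time.perf_counter()
    if table is None or records is None or tree is None:
        table = read_otu_table(cfg.otu_table, cfg.otu_format)
        records = read_metadata(cfg.metadata)
        tree = read_tree(cfg.tree)
        digests = {
            "otu_table": _digest(cfg.otu_table),
            "metadata": _digest(cfg.metadata),
            "tree": _digest(cfg.tree),
        }
    table, records, tree, report = align_inputs(table, records, tree)
    timings["ingest"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    records = preprocess.substitute_lod_records(records, cfg.lod_ugL)
    depth = (
        preprocess.auto_depth(table)
        if cfg.rarefaction_depth == "auto"
        else int(cfg.rarefaction_depth)
    )
    rare = preprocess.rarefy(table, depth, cfg.rarefaction_seed)
    rel = preprocess.relative_abundance(rare)
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if not tree.rooted:
        tree = gunifrac.midpoint_root(tree)
    profile = gunifrac.branch_profiles(tree, rare)
    dm = gunifrac.distance_matrix(profile, gunifrac.GUniFracParams(cfg.alpha))
    gunifrac.write_distance_matrix(dm, outdir / "gunifrac_distances.tsv")
    timings["distances"] = time.perf_counter() - t0

    strata = preprocess.stratify(records)
    groups: dict[str, tuple[list[str], Optional[StratumLabel]]] = {
        "all_subjects": ([r.sample_id for r in records], None)
    }
    for lab in ALL_STRATA:
        groups[str(lab)] = (strata[lab], lab)

    manifest = RunManifest(
        config=asdict(cfg),
        seeds={
            "rarefaction": cfg.rarefaction_seed,
            "permanova": cfg.permanova_seed,
            "bootstrap": cfg.bootstrap_seed,
        },
        software_version=_version(),
        input_digests=digests,
        rarefaction_depth=depth,
        n_samples=len(records),
        n_otus=len(table.otu_ids),
    )
    for name, (ids, stratum) in groups.items():
        t0 = time.perf_counter()
        manifest.groups[name] = _analyze_group(
            name, ids, dm, rel, rare, records, cfg, stratum, outdir
        )
        timings[name] = time.perf_counter() - t0
    manifest.timings_s = {k: round(v, 3) for k, v in timings.items()}
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _version() -> str:
    try:
        return _pkg_version("arsmicro")
    except Exception:
        return "unknown"


def report(manifest: RunManifest | str | Path) -> str:
    """Human-readable markdown summary of a completed run.  Idempotent."""
    if not isinstance(manifest, RunManifest):
        doc = json.loads(Path(manifest).read_text())
        manifest = RunManifest(**doc)
    if not manifest.groups:
        raise ValueError("manifest has no analyzed groups; run incomplete")
    lines = [
        "# Exposure-microbiome association run",
        "",
        f"- software version: {manifest.software_version}",
        f"- samples: {manifest.n_samples}, OTUs: {manifest.n_otus}, "
        f"rarefaction depth: {manifest.rarefaction_depth}",
        f"- seeds: {manifest.seeds}",
        "",
        "## PERMANOVA (exposure term)",
        "",
        "| group | n | adjustment | pseudo-F | p |",
        "|---|---|---|---|---|",
    ]
    for name, g in manifest.groups.items():
        for adj, res in (g.get("permanova") or {}).items():
            lines.append(
                f"| {name} | {g['n']} | {adj} | "
                f"{res['pseudo_F']:.3f} | {res['p_value']:.4g} |"
            )
    lines += ["", "## Extreme-quartile distance contrast", ""]
    for name, g in manifest.groups.items():
        qc = g.get("quartile_contrast")
        if qc:
            lines.append(
                f"- {name}: mean {qc['mean_distance']:.4f} "
                f"(95% BCa {qc['ci_low']:.4f}-{qc['ci_high']:.4f})"
            )
    lines += ["", "## ZILN selection", ""]
    for name, g in manifest.groups.items():
        z = g.get("ziln")
        if not z:
            continue
        if z["n_selected"] == 0:
            lines.append(f"- {name}: no OTUs selected")
        else:
            lines.append(
                f"- {name}: {z['n_selected']} OTUs selected "
                f"({z['n_positive']} positive, {z['n_negative']} negative): "
                + ", ".join(z["selected_otus"])
            )
    for name, g in manifest.groups.items():
        for reason in g.get("skipped", []):
            lines.append(f"- note: {name}: skipped {reason}")
    return "\n".join(lines) + "\n"
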