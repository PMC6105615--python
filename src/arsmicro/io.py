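"""Readers, writers and mutual-consistency alignment for the three input
artifacts of the analysis: an OTU count table, per-sample exposure metadata,
and a phylogenetic tree over the OTUs.

Supported on-disk dialects
--------------------------
* OTU table: TSV with samples as rows (first column ``sample_id``, remaining
  columns OTU ids), or BIOM v1 JSON (dense or sparse).
* Metadata: CSV with columns ``sample_id, sex, feeding, arsenic_ugL,
  below_lod, specific_gravity``.
* Tree: Newick, tip labels = OTU ids.

All readers transparently accept gzip-compressed files (``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import io as _io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from skbio import TreeNode

SEX_LEVELS = ("male", "female", "unreported")
FEEDING_LEVELS = ("exclusive_breast", "combination", "exclusive_formula")

METADATA_COLUMNS = (
    "sample_id",
    "sex",
    "feeding",
    "arsenic_ugL",
    "below_lod",
    "specific_gravity",
)


class FormatError(ValueError):
    """The file cannot be parsed in the declared dialect."""


class ValidationError(ValueError):
    """The file parses but violates a data invariant."""


class ConsistencyError(ValueError):
    """The three artifacts do not describe a common set of samples/OTUs."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class OtuTable:
    """Integer count matrix (samples x OTUs) with optional taxonomy.

    Invariants: unique sample and OTU ids, counts >= 0, every sample row
    sum > 0.  ``taxonomy`` maps OTU id -> Greengenes-style lineage string
    (``k__...;p__...;...;g__...``).
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    taxonomy: Optional[dict[str, str]] = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.validate()

    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in OTU table")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise FormatError("duplicate OTU ids in OTU table")
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                bad = np.argwhere(~np.isclose(self.counts, np.round(self.counts)))
                i, j = bad[0]
                raise ValidationError(
                    f"non-integer count at sample {self.sample_ids[i]!r}, "
                    f"OTU {self.otu_ids[j]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"OTU {self.otu_ids[j]!r}"
            )
        row_sums = self.counts.sum(axis=1)
        if (row_sums == 0).any():
            empty = [s for s, t in zip(self.sample_ids, row_sums) if t == 0]
            raise ValidationError(f"samples with zero total counts: {empty}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def select_samples(self, sample_ids: list[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(list(sample_ids), list(self.otu_ids),
                        self.counts[idx, :], self.taxonomy)


@dataclass
class ExposureRecord:
    """Per-sample urinary-arsenic exposure and covariates.

    ``arsenic_ugL`` is total urinary arsenic in micrograms per liter;
    ``below_lod`` flags values censored at the assay detection limit;
    ``specific_gravity`` is the unitless urine density ratio used as a
    dilution-adjustment covariate.
    """

    sample_id: str
    arsenic_ugL: float
    below_lod: bool
    specific_gravity: float
    sex: str = "unreported"
    feeding: str = "exclusive_breast"

    def __post_init__(self):
        if self.sex not in SEX_LEVELS:
            raise ValidationError(
                f"sample {self.sample_id!r}: sex {self.sex!r} not in {SEX_LEVELS}"
            )
        if self.feeding not in FEEDING_LEVELS:
            raise ValidationError(
                f"sample {self.sample_id!r}: feeding {self.feeding!r} not one of "
                f"{FEEDING_LEVELS}"
            )
        if not (0.99 < self.specific_gravity < 1.05):
            raise ValidationError(
                f"sample {self.sample_id!r}: specific gravity "
                f"{self.specific_gravity} outside (0.99, 1.05)"
            )


@dataclass
class Phylogeny:
    """A tree over OTUs with branch lengths, thin wrapper over skbio TreeNode."""

    tree: TreeNode
    rooted: bool = False

    def __post_init__(self):
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
            if not np.isfinite(node.length) or node.length < 0:
                raise ValidationError(
                    f"branch above {node.name!r} has invalid length {node.length}"
                )

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.tree.copy(), self.rooted)


# ---------------------------------------------------------------------------
# OTU table IO
# ---------------------------------------------------------------------------


def read_otu_table(path, format: str = "tsv") -> OtuTable:
    """Read an OTU count table from TSV or BIOM v1 JSON.

    The TSV dialect has samples as rows; the first column is ``sample_id``
    and the header row gives OTU ids.  The parse is lossless for integer
    counts.
    """
    if format == "tsv":
        return _read_otu_tsv(path)
    if format == "biom_json":
        return _read_otu_biom(path)
    raise ValueError(f"unknown OTU table format {format!r}")


def _read_otu_tsv(path) -> OtuTable:
    with _open_text(path) as fh:
        text = fh.read()
    if not text.strip():
        raise FormatError(f"empty OTU table file: {path}")
    header = text.splitlines()[0].rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        raise FormatError("duplicate sample or OTU ids in OTU table")
    try:
        df = pd.read_csv(_io.StringIO(text), sep="\t", index_col=0)
    except Exception as exc:  # malformed TSV
        raise FormatError(f"cannot parse OTU table {path}: {exc}") from exc
    if df.index.name != "sample_id":
        raise FormatError(
            f"OTU table first column must be 'sample_id', got {df.index.name!r}"
        )
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError("duplicate sample or OTU ids in OTU table")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValidationError(
                f"non-numeric count in OTU column {col!r}, sample "
                f"{bad.index[0]!r}"
            )
    return OtuTable(
        sample_ids=[str(s) for s in df.index],
        otu_ids=[str(o) for o in df.columns],
        counts=df.to_numpy(),
    )


def _read_otu_biom(path) -> OtuTable:
    with _open_text(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"cannot parse BIOM JSON {path}: {exc}") from exc
    for key in ("rows", "columns", "data", "matrix_type", "shape"):
        if key not in doc:
            raise FormatError(f"BIOM JSON missing required field {key!r}")
    # BIOM convention: rows = observations (OTUs), columns = samples.
    otu_ids = [str(r["id"]) for r in doc["rows"]]
    sample_ids = [str(c["id"]) for c in doc["columns"]]
    n_otu, n_samp = doc["shape"]
    mat = np.zeros((n_otu, n_samp))
    if doc["matrix_type"] == "dense":
        mat[:] = np.asarray(doc["data"])
    elif doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        raise FormatError(f"unsupported BIOM matrix_type {doc['matrix_type']!r}")
    taxonomy = None
    if any(r.get("metadata") and r["metadata"].get("taxonomy") for r in doc["rows"]):
        taxonomy = {}
        for r in doc["rows"]:
            tax = (r.get("metadata") or {}).get("taxonomy")
            if tax is not None:
                taxonomy[str(r["id"])] = (
                    "; ".join(tax) if isinstance(tax, (list, tuple)) else str(tax)
                )
    return OtuTable(sample_ids, otu_ids, mat.T, taxonomy)


def write_otu_table(table: OtuTable, path) -> None:
    """Write an OTU table in the TSV dialect (samples as rows)."""
    df = table.to_frame()
    df.index.name = "sample_id"
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# metadata IO
# ---------------------------------------------------------------------------

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def read_metadata(path) -> list[ExposureRecord]:
    """Read per-sample exposure metadata from CSV.

    Blank sex is permitted (records flagged ``unreported``); feeding must be
    one of the three defined categories.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    records = []
    for _, row in df.iterrows():
        try:
            arsenic = float(row["arsenic_ugL"])
        except ValueError as exc:
            raise ValidationError(
                f"sample {row['sample_id']!r}: non-numeric arsenic "
                f"{row['arsenic_ugL']!r}"
            ) from exc
        blod = row["below_lod"].strip().lower()
        if blod in _TRUE:
            below_lod = True
        elif blod in _FALSE:
            below_lod = False
        else:
            raise ValidationError(
                f"sample {row['sample_id']!r}: below_lod {row['below_lod']!r} "
                "is not boolean"
            )
        sex = row["sex"].strip().lower() or "unreported"
        records.append(
            ExposureRecord(
                sample_id=str(row["sample_id"]),
                arsenic_ugL=arsenic,
                below_lod=below_lod,
                specific_gravity=float(row["specific_gravity"]),
                sex=sex,
                feeding=row["feeding"].strip(),
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sample ids in metadata")
    return records


def write_metadata(records: list[ExposureRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "sex": "" if r.sex == "unreported" else r.sex,
                "feeding": r.feeding,
                "arsenic_ugL": r.arsenic_ugL,
                "below_lod": r.below_lod,
                "specific_gravity": r.specific_gravity,
            }
            for r in records
        ]
    )
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# tree IO
# ---------------------------------------------------------------------------


def read_tree(path) -> Phylogeny:
    with _open_text(path) as fh:
        try:
            tree = TreeNode.read(fh, format="newick", convert_underscores=False)
        except Exception as exc:
            raise FormatError(f"cannot parse Newick tree {path}: {exc}") from exc
    # A strictly bifurcating root with two children is treated as rooted.
    rooted = len(tree.children) == 2
    return Phylogeny(tree, rooted=rooted)


def write_tree(phylogeny: Phylogeny, path) -> None:
    with _open_text(path, "wt") as fh:
        phylogeny.tree.write(fh, format="newick")


# ---------------------------------------------------------------------------
# consistency alignment & sample accounting
# ---------------------------------------------------------------------------


@dataclass
class AlignmentReport:
    """Ids dropped while intersecting the three artifacts."""

    dropped_samples_table: list[str] = field(default_factory=list)
    dropped_samples_metadata: list[str] = field(default_factory=list)
    dropped_otus_table: list[str] = field(default_factory=list)
    dropped_tips_tree: list[str] = field(default_factory=list)


def align_inputs(
    table: OtuTable, records: list[ExposureRecord], tree: Phylogeny
) -> tuple[OtuTable, list[ExposureRecord], Phylogeny, AlignmentReport]:
    """Intersect sample sets, prune the tree to the table's OTUs, and put
    everything in lexicographic order.  Idempotent."""
    meta_ids = {r.sample_id for r in records}
    common = sorted(set(table.sample_ids) & meta_ids)
    if not common:
        raise ConsistencyError("no samples shared between OTU table and metadata")
    tip_set = set(tree.tip_names)
    common_otus = sorted(set(table.otu_ids) & tip_set)
    if not common_otus:
        raise ConsistencyError("no OTUs shared between OTU table and tree")

    report = AlignmentReport(
        dropped_samples_table=sorted(set(table.sample_ids) - set(common)),
        dropped_samples_metadata=sorted(meta_ids - set(common)),
        dropped_otus_table=sorted(set(table.otu_ids) - set(common_otus)),
        dropped_tips_tree=sorted(tip_set - set(common_otus)),
    )

    frame = table.to_frame().loc[common, common_otus]
    aligned_table = OtuTable(common, common_otus, frame.to_numpy(), table.taxonomy)

    by_id = {r.sample_id: r for r in records}
    aligned_records = [replace(by_id[s]) for s in common]

    if report.dropped_tips_tree:
        pruned = tree.tree.shear(common_otus)
        pruned.prune()
        aligned_tree = Phylogeny(pruned, rooted=len(pruned.children) == 2)
    else:
        aligned_tree = tree.copy()
    return aligned_table, aligned_records, aligned_tree, report


def exclude_failures(
    sample_ids: list[str], failed_ids: set[str] | list[str]
) -> tuple[list[str], list[str]]:
    """Sample accounting: drop samples flagged as sequencing failures.

    Returns (kept, dropped); order of kept ids is preserved.
    """
    failed = set(failed_ids)
    kept = [s for s in sample_ids if s not in failed]
    dropped = [s for s in sample_ids if s in failed]
    return kept, dropped
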