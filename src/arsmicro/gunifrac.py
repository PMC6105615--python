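"""Midpoint rooting and generalized UniFrac distances.

The generalized UniFrac family indexes phylogeny-aware community
dissimilarity by an exponent ``alpha`` in [0, 1]:

    d^(alpha)(A, B) =
        sum_i b_i (p_i^A + p_i^B)^alpha |p_i^A - p_i^B| / (p_i^A + p_i^B)
        -----------------------------------------------------------------
        sum_i b_i (p_i^A + p_i^B)^alpha

where the sum runs over tree edges i with branch length b_i and p_i^X is
the fraction of sample X's reads descending from edge i; edges with
p_i^A + p_i^B = 0 contribute 0 to both sums.  alpha = 1 recovers the
normalized weighted UniFrac; alpha -> 0 upweights rare lineages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio.stats.distance import DistanceMatrix

from .io import OtuTable, Phylogeny, ValidationError


@dataclass
class GUniFracParams:
    """alpha: abundance-weighting exponent in [0, 1] (default 0.5, the
    standard compromise between rare- and abundant-lineage emphasis)."""

    alpha: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must lie in [0, 1], got {self.alpha}")


@dataclass
class BranchProfile:
    """Per-edge branch lengths and per-sample descendant read proportions.

    branch_lengths: vector over all non-root edges.
    descendant_proportion: (samples x edges) matrix; entry (A, i) is the
        fraction of sample A's reads on tips below edge i.
    """

    sample_ids: list[str]
    branch_lengths: np.ndarray
    descendant_proportion: np.ndarray


def midpoint_root(phylogeny: Phylogeny) -> Phylogeny:
    """Root the tree at the midpoint of the longest tip-to-tip path.

    Total tree length is preserved; rooting an already midpoint-rooted tree
    leaves the topology unchanged.  Ties between equally long tip-to-tip
    paths are broken by lexicographic tip-pair order, so the result is
    deterministic.
    """
    tree = phylogeny.tree.copy()
    if tree.count(tips=True) < 2:
        raise ValidationError("midpoint rooting needs at least 2 tips")
    total = sum(n.length or 0.0 for n in tree.traverse(include_self=False))
    if total <= 0:
        raise ValidationError("cannot midpoint-root a zero-length tree")

    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    order = sorted(range(len(ids)), key=lambda k: ids[k])
    best, pair = -1.0, None
    for ii, i in enumerate(order):
        for j in order[ii + 1 :]:
            if dm.data[i, j] > best + 1e-15:
                best, pair = float(dm.data[i, j]), (ids[i], ids[j])
    a_name, b_name = sorted(pair)
    half = best / 2.0

    # walk upward from tip a; if the midpoint is past the LCA it lies within
    # the first `half` of the path from b instead (symmetry of the midpoint)
    def locate(tip_name: str):
        node = tree.find(tip_name)
        cum = 0.0
        while node.parent is not None:
            edge = node.length or 0.0
            if cum + edge >= half - 1e-12:
                return node, min(max(half - cum, 0.0), edge)
            cum += edge
            node = node.parent
        return None, None

    a_tip = tree.find(a_name)
    b_tip = tree.find(b_name)
    lca = tree.lowest_common_ancestor([a_tip, b_tip])
    node, above = locate(a_name if a_tip.accumulate_to_ancestor(lca) >= half else b_name)
    if node is None:  # numerically degenerate; midpoint at the current root
        rooted = tree
    else:
        rooted = tree.root_at(node, above=above)
    new_total = sum(n.length or 0.0 for n in rooted.traverse(include_self=False))
    if not np.isclose(total, new_total):
        raise RuntimeError("midpoint rooting changed total tree length")
    return Phylogeny(rooted, rooted=len(rooted.children) == 2)


def branch_profiles(phylogeny: Phylogeny, table: OtuTable) -> BranchProfile:
    """Compute b_i and p_i^A for every edge of a rooted tree.

    Tip set of the tree must be a subset of the table's OTUs; table OTUs
    absent from the tree contribute nothing to any edge (they should have
    been pruned during alignment).
    """
    if not phylogeny.rooted:
        raise ValidationError("branch profiles require a rooted tree")
    tree = phylogeny.tree
    otu_index = {o: j for j, o in enumerate(table.otu_ids)}
    counts = table.counts.astype(float)
    totals = counts.sum(axis=1, keepdims=True)

    edges = [n for n in tree.postorder(include_self=False)]
    n_samples = counts.shape[0]
    b = np.empty(len(edges))
    # per-edge descendant counts, accumulated bottom-up
    node_counts: dict[int, np.ndarray] = {}
    desc = np.empty((n_samples, len(edges)))
    for e, node in enumerate(edges):
        if node.is_tip():
            if node.name not in otu_index:
                raise ValidationError(
                    f"tree tip {node.name!r} not present in OTU table"
                )
            c = counts[:, otu_index[node.name]].copy()
        else:
            c = np.zeros(n_samples)
            for child in node.children:
                c += node_counts[id(child)]
        node_counts[id(node)] = c
        b[e] = node.length or 0.0
        desc[:, e] = c
    profile = desc / totals
    return BranchProfile(list(table.sample_ids), b, profile)


def _pair_distance(
    b: np.ndarray, pa: np.ndarray, pb: np.ndarray, alpha: float
) -> float:
    s = pa + pb
    mask = s > 0
    if not mask.any():
        raise ValidationError("both samples have empty branch profiles")
    s = s[mask]
    diff = np.abs(pa[mask] - pb[mask])
    w = b[mask] * s**alpha
    denom = w.sum()
    if denom == 0:
        return 0.0
    return float((w * (diff / s)).sum() / denom)


def gunifrac_distance(
    profile: BranchProfile, a, b, params: GUniFracParams | None = None
) -> float:
    """Generalized UniFrac distance between two samples (by id or index)."""
    params = params or GUniFracParams()
    if profile.branch_lengths.size == 0:
        raise ValidationError("empty branch profile")
    ia = profile.sample_ids.index(a) if isinstance(a, str) else int(a)
    ib = profile.sample_ids.index(b) if isinstance(b, str) else int(b)
    return _pair_distance(
        profile.branch_lengths,
        profile.descendant_proportion[ia],
        profile.descendant_proportion[ib],
        params.alpha,
    )


def distance_matrix(
    profile: BranchProfile, params: GUniFracParams | None = None
) -> DistanceMatrix:
    """All-pairs generalized UniFrac distances, vectorized over edges."""
    params = params or GUniFracParams()
    P = profile.descendant_proportion
    bl = profile.branch_lengths
    n = P.shape[0]
    if n < 2:
        raise ValidationError("distance matrix needs at least 2 samples")
    if bl.size == 0:
        raise ValidationError("empty branch profile")
    D = np.zeros((n, n))
    alpha = params.alpha
    for i in range(n - 1):
        S = P[i] + P[i + 1 :]  # (n-i-1, E)
        diff = np.abs(P[i] - P[i + 1 :])
        pos = S > 0
        W = np.where(pos, bl * np.where(pos, S, 1.0) ** alpha, 0.0)
        ratio = np.where(pos, diff / np.where(pos, S, 1.0), 0.0)
        denom = W.sum(axis=1)
        num = (W * ratio).sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
        D[i, i + 1 :] = d
        D[i + 1 :, i] = d
    return DistanceMatrix(D, ids=profile.sample_ids)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    """Square TSV with header ids (first column = sample id)."""
    import pandas as pd

    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")
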