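import itertools

import numpy as np
import pytest

from arsmicro import (
    GUniFracParams,
    OtuTable,
    ValidationError,
    branch_profiles,
    distance_matrix,
    gunifrac_distance,
    midpoint_root,
    simulate_tree,
)
from arsmicro.io import Phylogeny

from conftest import tree_from_newick


def tip_depths(tree):
    return {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}


def brute_force_longest_path(tree):
    """Independent exhaustive search over all tip pairs."""
    tips = list(tree.tips())
    best = 0.0
    for a, b in itertools.combinations(tips, 2):
        best = max(best, a.distance(b))
    return best


def total_length(tree):
    return sum(n.length or 0.0 for n in tree.traverse(include_self=False))


# ---------------------------------------------------------------------------
# midpoint rooting
# ---------------------------------------------------------------------------


def test_midpoint_two_tips():
    phy = tree_from_newick("(A:1,B:3);", rooted=False)
    rooted = midpoint_root(phy)
    depths = tip_depths(rooted.tree)
    assert depths["A"] == pytest.approx(2.0)
    assert depths["B"] == pytest.approx(2.0)


def test_midpoint_idempotent_and_length_preserving():
    phy = tree_from_newick("((A:1,B:2):0.5,(C:1.5,D:1):0.75);")
    once = midpoint_root(phy)
    twice = midpoint_root(once)
    assert total_length(once.tree) == pytest.approx(total_length(phy.tree))
    d1, d2 = tip_depths(once.tree), tip_depths(twice.tree)
    for tip in d1:
        assert d1[tip] == pytest.approx(d2[tip])


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_midpoint_halves_longest_path_random_trees(seed):
    phy = simulate_tree(6, "random_coalescent", seed=seed)
    longest = brute_force_longest_path(phy.tree)
    rooted = midpoint_root(phy)
    max_depth = max(tip_depths(rooted.tree).values())
    assert max_depth == pytest.approx(longest / 2)


def test_midpoint_rejects_zero_length_tree():
    phy = tree_from_newick("(A:0,B:0);", rooted=False)
    with pytest.raises(ValidationError):
        midpoint_root(phy)


# ---------------------------------------------------------------------------
# branch profiles
# ---------------------------------------------------------------------------


def star_table(counts):
    return OtuTable(
        [f"s{i}" for i in range(len(counts))],
        ["A", "B", "C"],
        np.asarray(counts),
    )


def test_branch_profile_star_concentrated():
    phy = tree_from_newick("(A:1,B:1,C:1);", rooted=True)
    prof = branch_profiles(phy, star_table([[7, 0, 0], [0, 3, 3]]))
    # sample 0: everything under A's edge, nothing elsewhere
    a_col = [t.name for t in phy.tree.postorder(include_self=False)].index("A")
    np.testing.assert_allclose(prof.descendant_proportion[0, a_col], 1.0)
    assert prof.descendant_proportion[0].sum() == pytest.approx(1.0)


def test_branch_profile_root_children_split():
    phy = tree_from_newick("((A:1):1,(B:1):1);", rooted=True)
    table = OtuTable(["s"], ["A", "B"], np.array([[5, 5]]))
    prof = branch_profiles(phy, table)
    # both root-child edges carry exactly half of the reads
    internal = [
        e
        for e, node in enumerate(phy.tree.postorder(include_self=False))
        if not node.is_tip()
    ]
    np.testing.assert_allclose(prof.descendant_proportion[0, internal], 0.5)


def test_branch_profile_matches_naive_ancestor_walk(default_dataset):
    """Oracle: accumulate each tip's counts onto every ancestor edge."""
    rng = np.random.default_rng(5)
    phy = simulate_tree(6, seed=7)
    counts = rng.integers(0, 30, size=(4, 6))
    counts[:, 0] += 1  # keep rows nonzero
    table = OtuTable([f"s{i}" for i in range(4)], [f"OTU_{j+1}" for j in range(6)], counts)
    prof = branch_profiles(phy, table)

    edges = list(phy.tree.postorder(include_self=False))
    expected = np.zeros_like(prof.descendant_proportion)
    totals = counts.sum(axis=1)
    for j, otu in enumerate(table.otu_ids):
        tip = phy.tree.find(otu)
        node = tip
        while node.parent is not None:
            expected[:, edges.index(node)] += counts[:, j]
            node = node.parent
    expected /= totals[:, None]
    np.testing.assert_allclose(prof.descendant_proportion, expected)
    np.testing.assert_allclose(prof.branch_lengths, [e.length for e in edges])


def test_branch_profile_requires_rooted():
    phy = tree_from_newick("(A:1,B:1,C:1);", rooted=False)
    with pytest.raises(ValidationError):
        branch_profiles(phy, star_table([[1, 1, 1]]))


# ---------------------------------------------------------------------------
# generalized UniFrac distance
# ---------------------------------------------------------------------------

FIXTURE_NEWICK = "((A:1,B:2):0.5,(C:1.5,D:1):0.75);"


def fixture_profile(counts):
    phy = tree_from_newick(FIXTURE_NEWICK, rooted=True)
    table = OtuTable(
        [f"s{i}" for i in range(len(counts))], list("ABCD"), np.asarray(counts)
    )
    return branch_profiles(phy, table)


def oracle_gunifrac(pa, pb, alpha):
    """Independent edge-by-edge evaluation on the hard-coded fixture tree.

    Edge table (descendant tip sets and branch lengths) written out by hand
    for ((A:1,B:2):0.5,(C:1.5,D:1):0.75).
    """
    edges = [
        ({0}, 1.0),  # A
        ({1}, 2.0),  # B
        ({0, 1}, 0.5),  # AB
        ({2}, 1.5),  # C
        ({3}, 1.0),  # D
        ({2, 3}, 0.75),  # CD
    ]
    num = den = 0.0
    for tips, b in edges:
        qa = sum(pa[t] for t in tips)
        qb = sum(pb[t] for t in tips)
        s = qa + qb
        if s <= 0:
            continue
        w = b * s**alpha
        num += w * abs(qa - qb) / s
        den += w
    return num / den


@pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
def test_gunifrac_matches_hand_computation(alpha):
    counts = [[4, 0, 1, 0], [0, 2, 2, 1]]
    prof = fixture_profile(counts)
    got = gunifrac_distance(prof, 0, 1, GUniFracParams(alpha))
    pa = np.array(counts[0]) / 5
    pb = np.array(counts[1]) / 5
    assert got == pytest.approx(oracle_gunifrac(pa, pb, alpha), abs=1e-12)


def test_gunifrac_identity_and_disjoint_support():
    prof = fixture_profile([[3, 1, 0, 0], [3, 1, 0, 0]])
    assert gunifrac_distance(prof, 0, 1) == 0.0
    # equal-branch two-tip star, all reads on opposite tips -> 1 for any alpha
    phy = tree_from_newick("(A:1,B:1);", rooted=True)
    table = OtuTable(["x", "y"], ["A", "B"], np.array([[9, 0], [0, 4]]))
    prof2 = branch_profiles(phy, table)
    for alpha in (0.0, 0.3, 1.0):
        assert gunifrac_distance(prof2, "x", "y", GUniFracParams(alpha)) == pytest.approx(1.0)


def test_gunifrac_symmetric_and_bounded():
    rng = np.random.default_rng(3)
    counts = rng.integers(1, 20, size=(5, 4))
    prof = fixture_profile(counts)
    dm = distance_matrix(prof, GUniFracParams(0.5))
    assert (dm.data >= 0).all() and (dm.data <= 1).all()
    np.testing.assert_allclose(dm.data, dm.data.T)
    for i, j in itertools.combinations(range(5), 2):
        assert dm.data[i, j] == pytest.approx(
            gunifrac_distance(prof, i, j, GUniFracParams(0.5)), abs=1e-12
        )


def test_distance_matrix_identical_samples_and_equivariance():
    prof = fixture_profile([[2, 2, 1, 0]] * 3)
    assert np.all(distance_matrix(prof).data == 0)

    rng = np.random.default_rng(9)
    counts = rng.integers(1, 20, size=(4, 4))
    dm = distance_matrix(fixture_profile(counts))
    perm = [2, 0, 3, 1]
    dm_perm = distance_matrix(fixture_profile(counts[perm]))
    np.testing.assert_allclose(dm_perm.data, dm.data[np.ix_(perm, perm)])


def test_alpha_one_matches_reference_weighted_unifrac():
    """alpha = 1 reproduces the normalized weighted UniFrac of an
    independent reference implementation on a 5-tip fixture."""
    from skbio import TreeNode
    from skbio.diversity.beta import weighted_unifrac

    newick = "(((A:0.4,B:0.7):0.3,C:1.2):0.5,(D:0.8,E:0.3):0.9);"
    rng = np.random.default_rng(21)
    counts = rng.integers(0, 40, size=(4, 5))
    counts[:, 0] += 1
    phy = tree_from_newick(newick, rooted=True)
    table = OtuTable(
        [f"s{i}" for i in range(4)], list("ABCDE"), counts
    )
    prof = branch_profiles(phy, table)
    ref_tree = TreeNode.read([newick])
    for i, j in itertools.combinations(range(4), 2):
        ref = weighted_unifrac(
            counts[i], counts[j], taxa=list("ABCDE"), tree=ref_tree, normalized=True
        )
        got = gunifrac_distance(prof, i, j, GUniFracParams(1.0))
        assert got == pytest.approx(ref, abs=1e-10)


def test_branch_length_scale_invariance_and_continuity():
    rng = np.random.default_rng(13)
    counts = rng.integers(0, 15, size=(3, 4)) + [[1, 0, 0, 0]] * 3
    prof = fixture_profile(counts)
    scaled = fixture_profile(counts)
    scaled.branch_lengths = scaled.branch_lengths * 7.3
    for alpha in (0.0, 0.5, 1.0):
        a = gunifrac_distance(prof, 0, 2, GUniFracParams(alpha))
        b = gunifrac_distance(scaled, 0, 2, GUniFracParams(alpha))
        assert a == pytest.approx(b, abs=1e-12)
    d1 = gunifrac_distance(prof, 0, 1, GUniFracParams(0.5))
    d2 = gunifrac_distance(prof, 0, 1, GUniFracParams(0.5 + 1e-6))
    assert abs(d1 - d2) < 1e-4
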