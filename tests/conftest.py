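import numpy as np
import pytest

from arsmicro import (
    ExposureRecord,
    OtuTable,
    Phylogeny,
    SimulationSpec,
    simulate_dataset,
)
from skbio import TreeNode


@pytest.fixture
def small_table():
    return OtuTable(
        sample_ids=["s1", "s2"],
        otu_ids=["OTU_1", "OTU_2", "OTU_3"],
        counts=np.array([[5, 0, 5], [0, 10, 0]]),
    )


@pytest.fixture
def records_from_counts():
    """Build ExposureRecords from (sex, feeding) count dictionaries."""

    def _build(counts: dict[tuple[str, str], int]) -> list[ExposureRecord]:
        records, k = [], 0
        for (sex, feeding), n in counts.items():
            for _ in range(n):
                k += 1
                records.append(
                    ExposureRecord(
                        sample_id=f"s{k}",
                        arsenic_ugL=0.4,
                        below_lod=False,
                        specific_gravity=1.015,
                        sex=sex,
                        feeding=feeding,
                    )
                )
        return records

    return _build


def tree_from_newick(newick: str, rooted: bool | None = None) -> Phylogeny:
    tree = TreeNode.read([newick], convert_underscores=False)
    if rooted is None:
        rooted = len(tree.children) == 2
    return Phylogeny(tree, rooted=rooted)


@pytest.fixture(scope="session")
def default_dataset():
    """One mid-size synthetic cohort shared by read-only tests."""
    return simulate_dataset(SimulationSpec(seed=11, n_samples=120, n_otus=50))
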