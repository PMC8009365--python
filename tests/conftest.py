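import warnings

import numpy as np
import pytest

from biomeshift import BiomeAvailability, NZ_BIOMES, OccupancyMatrix, Phylogeny

# non-ultrametric test trees trigger an informational warning; silence it
warnings.filterwarnings("ignore", message="tree is not ultrametric")


@pytest.fixture(autouse=True)
def _quiet_nonultrametric():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def two_biomes():
    return BiomeAvailability(("F", "O"))


@pytest.fixture
def nz():
    return NZ_BIOMES


@pytest.fixture
def three_tip_tree():
    return Phylogeny.from_newick("((A:0.6,B:0.9):0.4,C:1.2);")


@pytest.fixture
def three_tip_occ():
    return OccupancyMatrix(
        ["A", "B", "C"], ("F", "O"), np.array([[1, 0], [1, 1], [0, 1]])
    )


@pytest.fixture
def balanced_tree_32():
    """A balanced ultrametric 32-tip tree of height 5."""

    def build(labels, depth):
        if len(labels) == 1:
            return f"{labels[0]}:1"
        half = len(labels) // 2
        return f"({build(labels[:half], depth - 1)},{build(labels[half:], depth - 1)}):1"

    labels = [f"t{i}" for i in range(32)]
    return Phylogeny.from_newick(build(labels, 5)[: -2] + ";")
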