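import numpy as np
import pytest

from skelevol.phylo import Phylogeny, read_tree
from skelevol.synthdata import sim_pure_birth


@pytest.fixture
def three_tip_tree() -> Phylogeny:
    return read_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


def random_tree(n: int, rng: np.random.Generator, crown_age: float = 1.0) -> Phylogeny:
    return Phylogeny(sim_pure_birth(n, crown_age, rng))


@pytest.fixture
def star_tree_10() -> Phylogeny:
    import warnings

    newick = "(" + ",".join(f"s{i}:1" for i in range(10)) + ");"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # polytomy resolution
        return read_tree(newick)
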