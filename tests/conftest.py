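import numpy as np
import pytest

from otukit import GenotypeMatrix, LocusMeta
from otukit.simulate import (default_study, hybrid_study, kinship_study,
                             simulate_populations)


def make_gm(genotypes, pops=None, ids=None, loci=None, **meta):
    """Build a small GenotypeMatrix with defaulted metadata."""
    g = np.asarray(genotypes)
    n, L = g.shape
    ids = ids or [f"ind{i}" for i in range(n)]
    pops = pops or ["pop1"] * n
    if loci is None:
        loci = [LocusMeta(clone_id=f"c{j}", snp_position=j,
                          rep_avg=meta.get("rep_avg", 1.0),
                          call_rate=1.0,
                          read_depth=meta.get("read_depth", 20.0))
                for j in range(L)]
    return GenotypeMatrix(g, ids, pops, loci)


@pytest.fixture(scope="session")
def study():
    """One seeded run of the five-site / three-group study emulation."""
    gm, truth = simulate_populations(default_study(n_loci=600, seed=11))
    return gm, truth


@pytest.fixture(scope="session")
def hybrid_small():
    """Scaled-down two-pool design with one F1 and one F1xP0 backcross."""
    gm, truth = simulate_populations(hybrid_study(n_loci=250, seed=7))
    return gm, truth


@pytest.fixture(scope="session")
def kin_small():
    gm, truth = simulate_populations(kinship_study(n_loci=1000, seed=13))
    return gm, truth
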