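import numpy as np
import pytest

from pterochron.clockdating import ClockModelSpec
from pterochron.formats import GeneAlignment, read_newick_dated
from pterochron.synthdata import (
    SimulationSpec,
    gen_alignments,
    gen_branch_rates,
    gen_chronogram,
)


@pytest.fixture(scope="session")
def small_tree():
    """Balanced 4-taxon chronogram, root 100 Ma."""
    return read_newick_dated("((A:50,B:50):50,(C:80,D:80):20);")


@pytest.fixture(scope="session")
def demo_tree():
    from pterochron.example import pteropod_demo_tree

    return pteropod_demo_tree()


@pytest.fixture(scope="session")
def sim_bundle():
    """A deterministic 12-taxon simulation: tree, rates, alignments."""
    spec = SimulationSpec(
        seed=11, n_extant_taxa=12, root_age=100.0,
        clock=ClockModelSpec("CIR", mean_rate=0.01),
        n_genes=5, gene_length_min=80, gene_length_max=120,
        missing_prob=0.15, gamma_shape=None, gamma_categories=1,
    )
    tree = gen_chronogram(spec)
    rates = gen_branch_rates(tree, spec.clock, seed=12)
    genes = gen_alignments(tree, rates, spec)
    return spec, tree, rates, genes


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_alignment(gene_id: str, rows: dict) -> GeneAlignment:
    return GeneAlignment(gene_id=gene_id, rows=rows)
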