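"""Shared fixtures: small synthetic communities built at test time."""

import numpy as np
import pytest

from leaderbin import simdata
from leaderbin.core import Contig, ContigSet


@pytest.fixture(scope="session")
def small_genome():
    """One 130 kbp genome with the default 40 markers."""
    return simdata.generate_genomes(1, 130_000, 40, 300, gc=0.5, seed=7)[0]


@pytest.fixture(scope="session")
def genome_pair():
    """Two marker-bearing genomes with distinct GC content."""
    return simdata.generate_genomes(2, 130_000, 40, 300, gc=[0.3, 0.7], seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_contig(cid, seq, prov=None, depths=()):
    return Contig(id=cid, sequence=seq, provenance=prov,
                  depths=np.asarray(depths, dtype=float))


@pytest.fixture(scope="session")
def twin_community():
    """Factory: composition-twin pair with anticorrelated abundances, S=12.

    The two genomes share tetranucleotide statistics (Markov twins), so
    composition alone cannot separate them; their depth trajectories are
    anticorrelated across the 12 samples, and the pooled (summed) depth
    is identical for both — pooling destroys the only separating signal.
    """
    def _make(seed: int):
        ga = simdata.generate_genomes(1, 130_000, 40, 300, gc=0.5,
                                      seed=1000 + seed)[0]
        gb = simdata.composition_twin(ga, seed=2000 + seed)
        prof_a = np.array([30.0, 3.0] * 6)
        prof_b = np.array([3.0, 30.0] * 6)
        contigs = []
        for g, prof, s in ((ga, prof_a, 1), (gb, prof_b, 2)):
            t = simdata.emulate_tslr_bins(
                [g], (1000, 2000), 0.0, seed=3000 + 10 * seed + s,
                depths={g.id: prof}, depth_noise=True)
            contigs.extend(t[g.id])
        return ContigSet(contigs), {ga.id: ga, gb.id: gb}
    return _make


@pytest.fixture()
def plain_contigs():
    """A tiny contig set with explicit depths, no provenance."""
    return ContigSet([
        make_contig("c1", "ACGT" * 300, depths=[10.0, 2.0]),
        make_contig("c2", "GGCC" * 800, depths=[20.0, 1.0]),
    ])
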