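"""Simulator contracts: genomes, twins, abundances, coverage, emulators."""

import numpy as np
import pytest

from leaderbin import _seq, simdata
from leaderbin.core import ContigSet


class TestGenerateGenomes:
    def test_construction_contract(self, small_genome):
        g = small_genome
        assert len(g) == 130_000
        assert len(g.markers) == 40
        assert sorted(m.family_id for m in g.markers) == list(range(40))
        gc = sum(b in "GC" for b in g.sequence) / len(g)
        assert 0.47 <= gc <= 0.53

    def test_determinism(self):
        a = simdata.generate_genomes(2, 130_000, 40, 300, gc=0.5, seed=3)
        b = simdata.generate_genomes(2, 130_000, 40, 300, gc=0.5, seed=3)
        for ga, gb in zip(a, b):
            assert ga.sequence == gb.sequence
            assert ga.markers == gb.markers

    def test_sizing_error(self):
        with pytest.raises(ValueError, match="too small"):
            simdata.generate_genomes(1, 1000, 40, 300, seed=0)

    @pytest.mark.parametrize("trial", range(10))
    def test_marker_disjointness_brute_force(self, trial):
        """Marker loci never overlap, checked by an O(m^2) interval scan."""
        rng = np.random.default_rng(trial)
        m = int(rng.integers(2, 12))
        mlen = int(rng.integers(50, 200))
        g = simdata.generate_genomes(1, m * mlen * 10 + int(rng.integers(0, 5000)),
                                     m, mlen, gc=0.5, seed=trial)[0]
        ivals = [(mk.start, mk.end) for mk in g.markers]
        for i in range(len(ivals)):
            for j in range(i + 1, len(ivals)):
                s1, e1 = ivals[i]
                s2, e2 = ivals[j]
                assert e1 <= s2 or e2 <= s1

    def test_marker_divergence_between_genomes(self):
        """Same family differs ~5+5% between genomes, identical length."""
        a, b = simdata.generate_genomes(2, 130_000, 4, 300, gc=0.5, seed=9)
        for ma, mb in zip(sorted(a.markers, key=lambda m: m.family_id),
                          sorted(b.markers, key=lambda m: m.family_id)):
            sa = a.sequence[ma.start:ma.end]
            sb = b.sequence[mb.start:mb.end]
            diff = sum(x != y for x, y in zip(sa, sb)) / len(sa)
            assert 0.01 < diff < 0.25


class TestCompositionTwin:
    def test_tetranucleotide_profile_preserved(self):
        from leaderbin.binning import tetranucleotide_features
        from leaderbin.core import Contig
        g = simdata.generate_genomes(1, 200_000, 0, 300, gc=0.45, seed=5)[0]
        tw = simdata.composition_twin(g, seed=6)
        vecs = tetranucleotide_features(
            ContigSet([Contig("a", g.sequence), Contig("b", tw.sequence)])
        ).to_numpy()
        assert np.abs(vecs[0] - vecs[1]).sum() < 0.05

    def test_homopolymer_fixed_point(self):
        from leaderbin.core import Genome
        hp = Genome(id="h", sequence="A" * 500, markers=[])
        tw = simdata.composition_twin(hp, seed=0)
        assert tw.sequence == hp.sequence

    @pytest.mark.parametrize("seed", range(10))
    def test_ani_below_90_percent(self, seed):
        from leaderbin import derep
        from leaderbin.core import Contig
        g = simdata.generate_genomes(1, 60_000, 0, 300, gc=0.5, seed=seed)[0]
        tw = simdata.composition_twin(g, seed=seed + 100)
        est = derep.sketch_ani(ContigSet([Contig("a", g.sequence)]),
                               ContigSet([Contig("b", tw.sequence)]))
        assert est.ani < 0.90

    def test_markers_replanted(self, small_genome):
        tw = simdata.composition_twin(small_genome, seed=1)
        assert sorted(m.family_id for m in tw.markers) == list(range(40))
        tw.validate()


class TestSampleAbundances:
    def test_zero_variance_uniform(self):
        ab = simdata.sample_abundances(8, 5, sigma_log=0.0, seed=0)
        assert np.allclose(ab.values, 1 / 8)

    def test_perfect_autocorrelation(self):
        ab = simdata.sample_abundances(6, 10, sigma_log=1.5, rho=1.0, seed=2)
        assert np.allclose(ab.values, ab.values[:, [0]])

    def test_columns_sum_to_one(self):
        ab = simdata.sample_abundances(20, 7, sigma_log=2.0, rho=0.3, seed=4)
        assert np.allclose(ab.values.sum(axis=0), 1.0, atol=1e-9)
        assert (ab.values >= 0).all()

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            simdata.sample_abundances(3, 3, sigma_log=-0.1)

    @pytest.mark.parametrize("rho", [0.0, 0.5, 0.9])
    def test_lag1_autocorrelation_recovered(self, rho):
        """Empirical lag-1 autocorrelation of log-abundances ~ rho."""
        ab = simdata.sample_abundances(50, 200, sigma_log=1.0, rho=rho, seed=8)
        logs = np.log(ab.values)
        logs = logs - logs.mean(axis=1, keepdims=True)
        num = (logs[:, 1:] * logs[:, :-1]).sum()
        den = (logs ** 2).sum()
        assert abs(num / den - rho) < 0.1


class TestSimulateCoverage:
    def test_uniform_mean(self, small_genome):
        f = simdata.simulate_coverage(small_genome, 0.1, 100, "uniform", seed=2)
        assert abs(f.mean() - 10) / 10 < 0.02

    def test_zero_abundance(self, small_genome):
        f = simdata.simulate_coverage(small_genome, 0.0, 100, "uniform", seed=2)
        assert not f.depth.any()

    def test_unknown_profile(self, small_genome):
        with pytest.raises(ValueError, match="unknown bias profile"):
            simdata.simulate_coverage(small_genome, 0.1, 100, "nanopore")

    @pytest.mark.parametrize("seed", range(10))
    def test_transposase_more_low_coverage(self, small_genome, seed):
        """Bias profile drives more bases below half the mean depth."""
        u = simdata.simulate_coverage(small_genome, 0.1, 100, "uniform", seed=seed)
        t = simdata.simulate_coverage(small_genome, 0.1, 100, "transposase", seed=seed)
        half = 0.5 * u.mean()
        assert (t.depth < half).mean() > (u.depth < half).mean()

    def test_transposase_mean_preserved(self, small_genome):
        t = simdata.simulate_coverage(small_genome, 0.1, 100, "transposase", seed=1)
        assert abs(t.mean() - 10) / 10 < 0.05


class TestEmulateAssembly:
    def test_constant_field_single_contig(self, small_genome):
        f = simdata.CoverageField(small_genome.id,
                                  np.full(len(small_genome), 50.0))
        cs = simdata.emulate_assembly(small_genome, f, seed=0)
        assert len(cs) == 1
        assert cs[0].sequence == small_genome.sequence
        assert cs[0].provenance == (small_genome.id, 0, len(small_genome))

    def test_manual_zero_window_two_contigs(self, small_genome):
        d = np.full(len(small_genome), 50.0)
        d[10_000:12_000] = 0.0
        cs = simdata.emulate_assembly(
            small_genome, simdata.CoverageField(small_genome.id, d), seed=0)
        assert [c.provenance for c in cs] == [
            (small_genome.id, 0, 10_000),
            (small_genome.id, 12_000, len(small_genome)),
        ]

    @pytest.mark.parametrize("trial", range(50))
    def test_contig_count_matches_run_scan(self, small_genome, trial):
        """Emitted contigs equal a brute-force scan of depth runs."""
        rng = np.random.default_rng(trial)
        d = rng.poisson(3.0, 20_000).astype(float)
        field = simdata.CoverageField(small_genome.id, d)
        cs = simdata.emulate_assembly(small_genome, field, break_depth=2.0,
                                      min_contig=500, seed=trial)
        # independent scan
        n = 0
        run = 0
        for v in d:
            if v >= 2.0:
                run += 1
            else:
                n += run >= 500
                run = 0
        n += run >= 500
        assert len(cs) == n

    def test_conservation_without_errors(self, small_genome, rng):
        d = rng.poisson(4.0, len(small_genome)).astype(float)
        cs = simdata.emulate_assembly(
            small_genome, simdata.CoverageField(small_genome.id, d), seed=1)
        for c in cs:
            gid, s, e = c.provenance
            assert c.sequence == small_genome.sequence[s:e]

    def test_depths_from_multiple_fields(self, small_genome):
        f1 = simdata.CoverageField(small_genome.id, np.full(len(small_genome), 5.0))
        f2 = simdata.CoverageField(small_genome.id, np.full(len(small_genome), 7.0))
        cs = simdata.emulate_assembly(small_genome, [f1, f2], seed=0)
        assert len(cs) == 1
        assert np.allclose(cs[0].depths, [5.0, 7.0])


class TestEmulateTslrBins:
    def test_exact_substrings_at_zero_error(self, small_genome):
        t = simdata.emulate_tslr_bins([small_genome], error_rate=0.0, seed=4)
        for c in t[small_genome.id]:
            gid, s, e = c.provenance
            assert c.sequence == small_genome.sequence[s:e]

    def test_full_tiling(self, small_genome):
        t = simdata.emulate_tslr_bins([small_genome], seed=4)
        covered = sum(len(c) for c in t[small_genome.id])
        assert covered >= 0.99 * len(small_genome)

    def test_error_rate_recovered(self):
        """Injected 0.1% substitutions recovered by direct comparison on >= 1 Mbp."""
        genomes = simdata.generate_genomes(2, 600_000, 0, 300, gc=0.5, seed=6)
        t = simdata.emulate_tslr_bins(genomes, error_rate=0.001, seed=7)
        n_bases = n_diff = 0
        for g in genomes:
            for c in t[g.id]:
                gid, s, e = c.provenance
                src = g.sequence[s:e]
                n_bases += len(src)
                n_diff += sum(x != y for x, y in zip(c.sequence, src))
        assert n_bases >= 1_000_000
        # every injected substitution changes the base, so the expected
        # observed difference count is exactly rate * bases
        exp = 0.001 * n_bases
        sd = np.sqrt(n_bases * 0.001 * 0.999)
        assert abs(n_diff - exp) <= 3 * sd

    def test_error_rate_bounds(self, small_genome):
        with pytest.raises(ValueError):
            simdata.emulate_tslr_bins([small_genome], error_rate=0.5)


def test_smooth_depth_preserves_mean():
    rng = np.random.default_rng(1)
    d = rng.poisson(5.0, 10_000).astype(float)
    sm = simdata.smooth_depth(d, 100)
    assert abs(sm.mean() - d.mean()) < 0.05
    assert sm.shape == d.shape
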