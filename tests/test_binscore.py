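"""Completeness/redundancy/abundance arithmetic, scoring, selection, tiers."""

import numpy as np
import pytest

from leaderbin import binscore, simdata
from leaderbin.binscore import BinQuality, ScoreWeights
from leaderbin.core import Contig, ContigSet


def whole_genome_bin(genome, depths=(10.0,)):
    return ContigSet([Contig("c0", genome.sequence,
                             provenance=(genome.id, 0, len(genome)),
                             depths=np.asarray(depths, float))])


def fragment(genome, start, end, cid="f0", depths=(1.0,)):
    return Contig(cid, genome.sequence[start:end],
                  provenance=(genome.id, start, end),
                  depths=np.asarray(depths, float))


class TestCompletenessRedundancy:
    def test_full_bin_complete(self, small_genome):
        gmap = {small_genome.id: small_genome}
        bin_ = whole_genome_bin(small_genome)
        assert binscore.completeness(bin_, gmap, 40) == 1.0
        assert binscore.redundancy(bin_, gmap, 40) == 0.0

    def test_partial_definition_arithmetic(self, small_genome):
        """A bin holding 34 of 40 families scores C = 0.85."""
        gmap = {small_genome.id: small_genome}
        loci = sorted(small_genome.markers, key=lambda m: m.family_id)
        cs = ContigSet([fragment(small_genome, m.start, m.end, f"f{i}")
                        for i, m in enumerate(loci[:34])])
        assert binscore.completeness(cs, gmap, 40) == pytest.approx(0.85)

    def test_duplicated_families(self, small_genome):
        """Two duplicated families of 40 give R = 0.05."""
        gmap = {small_genome.id: small_genome}
        loci = sorted(small_genome.markers, key=lambda m: m.family_id)
        contigs = [fragment(small_genome, m.start, m.end, f"f{i}")
                   for i, m in enumerate(loci)]
        contigs += [fragment(small_genome, loci[0].start, loci[0].end, "dup0"),
                    fragment(small_genome, loci[1].start, loci[1].end, "dup1")]
        assert binscore.redundancy(ContigSet(contigs), gmap, 40) == pytest.approx(0.05)

    def test_union_of_two_genomes(self, genome_pair):
        """Merging two complete genomes: C = 1 and every family duplicated."""
        gmap = {g.id: g for g in genome_pair}
        cs = ContigSet([Contig(f"w{i}", g.sequence,
                               provenance=(g.id, 0, len(g)),
                               depths=np.array([1.0]))
                        for i, g in enumerate(genome_pair)])
        assert binscore.completeness(cs, gmap, 40) == 1.0
        assert binscore.redundancy(cs, gmap, 40) == 1.0

    def test_marker_must_be_fully_contained(self, small_genome):
        gmap = {small_genome.id: small_genome}
        m = small_genome.markers[0]
        cut = fragment(small_genome, m.start + 1, m.end + 500, "cut")
        assert binscore.completeness(ContigSet([cut]), gmap, 40) == 0.0

    @pytest.mark.parametrize("trial", range(20))
    def test_random_subsets_match_interval_scan(self, small_genome, trial):
        """Completeness equals an independent containment scan on random 60% windows."""
        gmap = {small_genome.id: small_genome}
        rng = np.random.default_rng(trial)
        L = len(small_genome)
        pieces = []
        for i in range(4):
            w = int(0.15 * L)
            s = int(rng.integers(0, L - w))
            pieces.append(fragment(small_genome, s, s + w, f"p{i}"))
        cs = ContigSet(pieces)
        expected_fams = set()
        for m in small_genome.markers:
            for p in pieces:
                _, s, e = p.provenance
                if s <= m.start and m.end <= e:
                    expected_fams.add(m.family_id)
                    break
        assert binscore.completeness(cs, gmap, 40) == pytest.approx(
            len(expected_fams) / 40)

    def test_zero_markers_rejected(self, small_genome):
        with pytest.raises(ValueError):
            binscore.completeness(ContigSet(), {}, 0)


class TestBinAbundance:
    def test_single_contig(self):
        cs = ContigSet([Contig("c", "A" * 100, depths=np.array([10.0]))])
        assert binscore.bin_abundance(cs, 0) == 10.0

    def test_length_weighted_mean(self):
        cs = ContigSet([Contig("a", "A" * 1000, depths=np.array([10.0])),
                        Contig("b", "C" * 3000, depths=np.array([20.0]))])
        assert binscore.bin_abundance(cs, 0) == pytest.approx(17.5)

    def test_empty_bin_rejected(self):
        with pytest.raises(ValueError):
            binscore.bin_abundance(ContigSet(), 0)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_direct_formula(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(2, 12))
        lens = rng.integers(100, 5000, n)
        deps = rng.uniform(0, 50, n)
        cs = ContigSet([Contig(f"c{i}", "A" * int(lens[i]),
                               depths=np.array([deps[i]])) for i in range(n)])
        expected = float((lens * deps).sum() / lens.sum())
        assert binscore.bin_abundance(cs, 0) == pytest.approx(expected)


class TestScoreAndSelection:
    def test_maximal_score(self):
        q = BinQuality("b", C=1.0, R=0.0, A=30.0, A_max=30.0)
        assert binscore.score_bin(q) == pytest.approx(11.0)

    def test_direct_arithmetic(self):
        q = BinQuality("b", C=0.85, R=0.05, A=1.0, A_max=10.0)
        assert binscore.score_bin(q) == pytest.approx(1.8)

    def test_invalid_amax(self):
        with pytest.raises(ValueError):
            binscore.score_bin(BinQuality("b", 1, 0, 1, 0.0))

    def test_monotonicity_finite_differences(self):
        base = BinQuality("b", C=0.8, R=0.1, A=5.0, A_max=10.0)
        s0 = binscore.score_bin(base)
        assert binscore.score_bin(BinQuality("b", 0.81, 0.1, 5.0, 10.0)) > s0
        assert binscore.score_bin(BinQuality("b", 0.8, 0.11, 5.0, 10.0)) < s0
        assert binscore.score_bin(BinQuality("b", 0.8, 0.1, 5.1, 10.0)) > s0

    def test_ranking_matches_brute_force(self):
        rng = np.random.default_rng(5)
        bins = [BinQuality(f"b{i:02d}", C=float(rng.uniform(0, 1)),
                           R=float(rng.uniform(0, 0.3)),
                           A=float(rng.uniform(0, 40)), A_max=40.0)
                for i in range(20)]
        for b in bins:
            b.score = binscore.score_bin(b)
        ranked = sorted(bins, key=lambda b: -b.score)
        brute = sorted(bins, key=lambda b: -(b.C - b.R + 10 * b.A / b.A_max))
        assert [b.bin_id for b in ranked] == [b.bin_id for b in brute]

    def test_selection_basic(self):
        rng = np.random.default_rng(1)
        bins = []
        for i in range(10):
            c = 0.9 if i < 5 else 0.5
            b = BinQuality(f"b{i}", C=c, R=0.0, A=float(rng.uniform(1, 10)),
                           A_max=10.0)
            b.score = binscore.score_bin(b)
            bins.append(b)
        sel, short = binscore.select_reference_bins(bins, k=5)
        assert not short
        assert sel == [b.bin_id for b in
                       sorted(bins[:5], key=lambda b: -b.score)]

    def test_selection_tie_break_on_completeness(self):
        b1 = BinQuality("x", C=0.90, R=0.0, A=5.0, A_max=10.0)
        b2 = BinQuality("y", C=0.95, R=0.05, A=5.0, A_max=10.0)
        b1.score = binscore.score_bin(b1)
        b2.score = binscore.score_bin(b2)
        assert b1.score == pytest.approx(b2.score)
        sel, _ = binscore.select_reference_bins([b1, b2], k=2)
        assert sel == ["y", "x"]

    def test_short_of_k_flagged(self):
        b = BinQuality("only", C=0.9, R=0.0, A=1.0, A_max=1.0)
        b.score = binscore.score_bin(b)
        sel, short = binscore.select_reference_bins([b], k=5)
        assert sel == ["only"] and short

    @pytest.mark.parametrize("trial", range(100))
    def test_selection_matches_brute_force(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(1, 25))
        bins = []
        for i in range(n):
            b = BinQuality(f"b{i:02d}", C=float(rng.uniform(0.5, 1.0)),
                           R=float(rng.uniform(0, 0.2)),
                           A=float(rng.uniform(0, 20)), A_max=20.0)
            b.score = binscore.score_bin(b)
            bins.append(b)
        sel, short = binscore.select_reference_bins(bins, k=5,
                                                    min_completeness=0.85)
        brute = sorted([b for b in bins if b.C > 0.85],
                       key=lambda b: (-b.score, -b.C, b.bin_id))[:5]
        assert sel == [b.bin_id for b in brute]
        assert short == (sum(b.C > 0.85 for b in bins) < 5)


class TestQualityTier:
    @pytest.mark.parametrize("c,cont,tier", [
        (0.95, 0.02, binscore.HIGH_QUALITY),
        (0.72, 0.08, binscore.MEDIUM),
        (0.90, 0.02, binscore.MEDIUM),   # boundary: strictly greater required
        (0.95, 0.05, binscore.MEDIUM),   # boundary: strictly below required
        (0.70, 0.05, binscore.FAIL),
        (0.95, 0.50, binscore.FAIL),
    ])
    def test_tier_boundaries(self, c, cont, tier):
        assert binscore.quality_tier(c, cont) == tier

    def test_tier_counts_match_threshold_scan(self):
        rng = np.random.default_rng(3)
        table = [(float(rng.uniform(0, 1)), float(rng.uniform(0, 0.2)))
                 for _ in range(200)]
        tiers = [binscore.quality_tier(c, r) for c, r in table]
        n_hq = sum(c > 0.9 and r < 0.05 for c, r in table)
        n_med = sum((c > 0.7 and r < 0.1) and not (c > 0.9 and r < 0.05)
                    for c, r in table)
        assert tiers.count(binscore.HIGH_QUALITY) == n_hq
        assert tiers.count(binscore.MEDIUM) == n_med


class TestAssessBins:
    def test_full_pipeline_single_genome(self, small_genome):
        gmap = {small_genome.id: small_genome}
        cs = whole_genome_bin(small_genome)
        quals = binscore.assess_bins({"c0": "binA"}, cs, gmap, 40)
        q = quals[0]
        assert (q.C, q.R) == (1.0, 0.0)
        assert q.A == q.A_max == 10.0
        assert q.score == pytest.approx(11.0)
        assert q.tier == binscore.HIGH_QUALITY
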