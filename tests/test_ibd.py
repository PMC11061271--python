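"""IBS states, the w-statistic, cM interpolation and IBD segment calling."""

import numpy as np
import pytest

import famseg as fs
from famseg.errors import DataFormatError
from oracles import quadratic_w


def make_site(pos, g1, g2, chrom="1", flt="PASS", dp=(30, 30), gq=(99, 99),
              cm=None):
    return fs.VariantSite(chrom=chrom, pos=pos, genotypes=(g1, g2),
                          filter=flt, depth=dp, genotype_quality=gq, cm=cm)


class TestFilter:
    def test_depth_threshold_is_strict(self):
        site = make_site(100, 0, 0, dp=(10, 60))
        assert fs.filter_sites([site]) == []
        assert fs.filter_sites([make_site(100, 0, 0, dp=(11, 60))]) != []

    def test_gq_threshold_is_strict(self):
        assert fs.filter_sites([make_site(1, 0, 0, gq=(50, 99))]) == []
        assert fs.filter_sites([make_site(1, 0, 0, gq=(51, 99))]) != []

    def test_non_pass_missing_and_non_snv_removed(self):
        sites = [
            make_site(1, 0, 0, flt="LowQual"),
            make_site(2, None, 0),
            make_site(3, 0, 0),
        ]
        indel = fs.VariantSite(chrom="1", pos=4, genotypes=(0, 0),
                               ref="AT", alt="A")
        assert [s.pos for s in fs.filter_sites(sites + [indel])] == [3]

    def test_empty_input(self):
        assert fs.filter_sites([]) == []


class TestIbsState:
    @pytest.mark.parametrize("g1,g2", [(a, b) for a in range(3)
                                       for b in range(3)])
    def test_matches_allele_multiset_intersection(self, g1, g2):
        def alleles(g):
            return ["a"] * g + ["A"] * (2 - g)
        a1, a2 = alleles(g1), alleles(g2)
        shared = 0
        pool = list(a2)
        for x in a1:
            if x in pool:
                pool.remove(x)
                shared += 1
        assert fs.ibs_state(g1, g2) == shared

    def test_missing_dosage_rejected(self):
        with pytest.raises(DataFormatError):
            fs.ibs_state(None, 1)


class TestNeighborhoodW:
    def test_extremes(self):
        concordant = [make_site(i * 1000, 1, 1) for i in range(50)]
        assert fs.neighborhood_w(concordant, 25) == 0.0
        discordant = [make_site(i * 1000, 0, 2) for i in range(50)]
        assert fs.neighborhood_w(discordant, 25) == 1.0

    def test_single_discordant_site_in_window(self):
        sites = [make_site(1000 + i, 1, 1) for i in range(50)]
        sites[10] = make_site(1010, 0, 2)
        assert fs.neighborhood_w(sites, 25) == pytest.approx(0.02)

    def test_matches_quadratic_recount(self):
        rng = np.random.default_rng(3)
        sites = []
        for chrom in ("1", "2"):
            pos = np.sort(rng.choice(5_000_000, 800, replace=False)) + 1
            for p in pos:
                sites.append(make_site(int(p), int(rng.integers(3)),
                                       int(rng.integers(3)), chrom=chrom))
        fast = fs.neighborhood_w_all(sites, radius_bp=1_000_000)
        slow = quadratic_w(sites, radius_bp=1_000_000)
        assert np.allclose(fast, slow, atol=1e-12)

    def test_exclude_self_option(self):
        sites = [make_site(i, 0, 2) for i in range(1, 11)]
        sites[0] = make_site(1, 1, 1)
        w_with = fs.neighborhood_w(sites, 0, include_self=True)
        w_without = fs.neighborhood_w(sites, 0, include_self=False)
        assert w_with == pytest.approx(0.9)
        assert w_without == pytest.approx(1.0)

    def test_index_out_of_range(self):
        with pytest.raises(DataFormatError):
            fs.neighborhood_w([make_site(1, 0, 0)], 5)


class TestInterpolateCm:
    def test_midpoint_and_exact_map_points(self):
        gmap = fs.GeneticMap(points={"1": (np.array([0.0, 1e6]),
                                           np.array([0.0, 1.0]))})
        sites = [make_site(500_000, 0, 0), make_site(1_000_000, 0, 0)]
        fs.interpolate_cm(sites, gmap)
        assert sites[0].cm == pytest.approx(0.5)
        assert sites[1].cm == pytest.approx(1.0)

    def test_matches_analytic_piecewise_map(self):
        knots_bp = np.array([0.0, 2e6, 5e6, 9e6])
        knots_cm = np.array([0.0, 1.0, 5.0, 6.0])
        gmap = fs.GeneticMap(points={"7": (knots_bp, knots_cm)})
        rng = np.random.default_rng(8)
        pos = rng.integers(1, 9_000_000, 500)
        got = gmap.cm_at("7", pos)
        expect = np.interp(pos, knots_bp, knots_cm)
        assert np.max(np.abs(got - expect)) < 1e-9

    def test_extrapolates_with_terminal_rate(self):
        gmap = fs.GeneticMap(points={"1": (np.array([1e6, 2e6]),
                                           np.array([1.0, 3.0]))})
        # terminal rate is 2 cM/Mb on both sides
        assert gmap.cm_at("1", 3e6) == pytest.approx(5.0)
        assert gmap.cm_at("1", 0.5e6) == pytest.approx(0.0)

    def test_unknown_chromosome_raises(self):
        gmap = fs.GeneticMap(points={"1": (np.array([0.0, 1e6]),
                                           np.array([0.0, 1.0]))})
        with pytest.raises(DataFormatError):
            gmap.cm_at("2", 100)

    def test_uniform_map_covers_everything(self):
        gmap = fs.GeneticMap.uniform(1.0)
        assert gmap.cm_at("GL000220.1", 2_500_000) == pytest.approx(2.5)
        assert gmap.pos_at("X", 2.5) == pytest.approx(2_500_000)


class TestCallSegments:
    def test_identical_genotypes_give_single_full_segment(self):
        rng = np.random.default_rng(4)
        pos = np.sort(rng.choice(5_000_000, 500, replace=False)) + 1
        sites = [make_site(int(p), int(g), int(g))
                 for p, g in zip(pos, rng.integers(0, 3, 500))]
        fs.interpolate_cm(sites, fs.GeneticMap.uniform(1.0))
        segs = fs.call_segments(sites)
        assert len(segs) == 1
        assert segs[0].n_variants == 500
        assert segs[0].start_pos == int(pos[0])
        assert segs[0].end_pos == int(pos[-1])
        assert segs[0].max_w == 0.0

    def test_run_of_99_variants_rejected(self):
        """One variant short of the minimum count: no call even though the
        run spans more than 1 cM with w = 0."""
        pos = np.linspace(1, 2_000_000, 99).astype(int)
        sites = [make_site(int(p), 1, 1) for p in pos]
        fs.interpolate_cm(sites, fs.GeneticMap.uniform(1.0))
        assert fs.call_segments(sites) == []
        sites100 = [make_site(int(p), 1, 1)
                    for p in np.linspace(1, 2_000_000, 100).astype(int)]
        fs.interpolate_cm(sites100, fs.GeneticMap.uniform(1.0))
        assert len(fs.call_segments(sites100)) == 1

    def test_short_genetic_span_rejected(self):
        pos = np.arange(1, 150_001, 1000)  # 150 variants over 0.15 cM
        sites = [make_site(int(p), 1, 1) for p in pos]
        fs.interpolate_cm(sites, fs.GeneticMap.uniform(1.0))
        assert fs.call_segments(sites) == []

    def test_missing_cm_raises(self):
        with pytest.raises(DataFormatError):
            fs.call_segments([make_site(1, 0, 0)])

    def test_symmetry_under_sample_swap(self):
        spec = fs.PairSimSpec(chrom_length_bp=20_000_000,
                              planted_segments=((5_000_000, 5.0),), seed=12)
        sites = fs.filter_sites(fs.simulate_pair(spec))
        fs.interpolate_cm(sites, fs.GeneticMap.uniform(1.0))
        segs = fs.call_segments(sites)
        swapped = [fs.VariantSite(chrom=s.chrom, pos=s.pos,
                                  genotypes=(s.genotypes[1], s.genotypes[0]),
                                  filter=s.filter,
                                  depth=(s.depth[1], s.depth[0]),
                                  genotype_quality=(s.genotype_quality[1],
                                                    s.genotype_quality[0]),
                                  ref=s.ref, alt=s.alt, cm=s.cm)
                   for s in sites]
        assert fs.call_segments(swapped) == segs

    def test_called_segments_satisfy_invariants(self):
        spec = fs.PairSimSpec(chrom_length_bp=30_000_000,
                              planted_segments=((4_000_000, 6.0),
                                                (20_000_000, 4.0)),
                              seed=5)
        sites = fs.filter_sites(fs.simulate_pair(spec))
        fs.interpolate_cm(sites, fs.GeneticMap.uniform(1.0))
        segs = fs.call_segments(sites)
        assert segs
        for s in segs:
            assert s.n_variants >= 100
            assert s.length_cm >= 1.0
            assert s.max_w <= 0.005
            assert s.end_cm - s.start_cm == pytest.approx(s.length_cm)
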