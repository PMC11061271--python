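"""Full-likelihood Bayes factor, combination, sensitivity surface, contour."""

import math

import numpy as np
import pytest

import famseg as fs
from famseg.errors import DataFormatError, PedigreeError
from famseg.pedigree import (AFFECTED, CARRIER, FEMALE, MALE, NON_CARRIER,
                             UNAFFECTED, UNKNOWN, UNTESTED)
from conftest import make_individual as I
from oracles import brute_force_flb, random_disease_model, random_pedigree


class TestComputeFlb:
    def test_singleton_proband_is_uninformative(self):
        pen = fs.PenetranceModel.constant(0.7, 0.02)
        model = fs.DiseaseModel(penetrance=pen)
        ped = fs.Pedigree("S", [I("x", sex=MALE, aff=AFFECTED, age=45,
                                  car=CARRIER, proband=True)])
        assert fs.compute_flb(ped, model).flb == pytest.approx(1.0, abs=1e-12)

    def test_equal_penetrance_gives_unit_flb(self):
        rng = np.random.default_rng(17)
        pen = fs.PenetranceModel.constant(0.4, 0.4)
        model = fs.DiseaseModel(penetrance=pen, allele_frequency=0.01)
        for _ in range(10):
            ped = random_pedigree(rng, 6, consistent_genotypes=True)
            ped = _with_proband(ped)
            if ped is None:
                continue
            assert fs.compute_flb(ped, model).flb == \
                pytest.approx(1.0, abs=1e-9)

    def test_matches_enumeration_on_toy_family(self):
        """Fully typed 5-member pedigree with 50% vs 5% penetrance."""
        pen = fs.PenetranceModel.constant(0.5, 0.05)
        model = fs.DiseaseModel(penetrance=pen, allele_frequency=0.001)
        ped = fs.Pedigree("T", [
            I("f", sex=MALE, aff=AFFECTED, age=55, car=CARRIER),
            I("m", sex=FEMALE, aff=UNAFFECTED, age=53, car=NON_CARRIER),
            I("c1", "f", "m", MALE, AFFECTED, 30, CARRIER, proband=True),
            I("c2", "f", "m", FEMALE, AFFECTED, 28, CARRIER),
            I("c3", "f", "m", FEMALE, UNAFFECTED, 26, NON_CARRIER),
        ])
        got = fs.compute_flb(ped, model).flb
        assert got == pytest.approx(brute_force_flb(ped, model), rel=1e-9)
        assert got > 1.0

    def test_matches_enumeration_on_random_families(self):
        rng = np.random.default_rng(31)
        checked = 0
        while checked < 25:
            ped = _with_proband(random_pedigree(rng, int(rng.integers(3, 8)),
                                                consistent_genotypes=True))
            if ped is None:
                continue
            model = random_disease_model(rng)
            got = fs.compute_flb(ped, model).flb
            assert got == pytest.approx(brute_force_flb(ped, model), rel=1e-9)
            checked += 1

    def test_unlinked_uninformative_member_cancels(self, default_model):
        """Adding a founder with no data and no descendants multiplies both
        hypotheses' likelihoods equally, leaving the FLB unchanged."""
        ped = fs.Pedigree("B", [
            I("f", sex=MALE, aff=AFFECTED, age=50, car=CARRIER),
            I("m", sex=FEMALE, aff=UNAFFECTED, age=70, car=NON_CARRIER),
            I("c", "f", "m", FEMALE, AFFECTED, 30, CARRIER, proband=True),
        ])
        base = fs.compute_flb(ped, default_model).flb
        extended = fs.Pedigree("B", ped.members + [
            I("extra", sex=MALE, aff=UNKNOWN, age=None, car=UNTESTED)])
        assert fs.compute_flb(extended, default_model).flb == \
            pytest.approx(base, rel=1e-12)

    def test_requires_unique_affected_carrier_proband(self, default_model):
        no_proband = fs.Pedigree("X", [I("a", sex=MALE, aff=AFFECTED,
                                         age=50, car=CARRIER)])
        with pytest.raises(PedigreeError):
            fs.compute_flb(no_proband, default_model)
        unaffected = fs.Pedigree("X", [I("a", sex=MALE, aff=UNAFFECTED,
                                         age=50, car=CARRIER, proband=True)])
        with pytest.raises(PedigreeError):
            fs.compute_flb(unaffected, default_model)


class TestCombineAndThresholds:
    def test_reported_per_family_scores_combine_to_reported_product(self):
        """12.10 x 8.13 = 98.37, matching the published combined score of
        98.40 computed from unrounded inputs."""
        r1 = fs.FLBResult.from_log(math.log(12.10), "family1")
        r2 = fs.FLBResult.from_log(math.log(8.13), "family2")
        combined = fs.combine_flb([r1, r2])
        assert combined.flb == pytest.approx(98.373, abs=1e-3)
        assert abs(combined.flb - 98.40) < 0.05

    def test_threshold_classification(self):
        assert fs.evidence_level(8.13) == "supporting"
        assert fs.evidence_level(12.10) == "supporting"
        assert fs.evidence_level(98.37) == "strong"
        assert fs.evidence_level(8.0) == "none"
        assert fs.evidence_level(16.0) == "supporting"

    def test_single_and_neutral_results(self):
        r = fs.FLBResult.from_log(math.log(5.0), "only")
        assert fs.combine_flb([r]).flb == pytest.approx(5.0)
        neutral = fs.FLBResult.from_log(0.0, "neutral")
        assert fs.combine_flb([r, neutral]).flb == pytest.approx(5.0)
        with pytest.raises(DataFormatError):
            fs.combine_flb([])

    def test_multiplicative_over_independent_families(self, strong_pedigree,
                                                      trio, default_model):
        r1 = fs.compute_flb(strong_pedigree, default_model)
        r2 = fs.compute_flb(trio, default_model)
        combined = fs.combine_flb([r1, r2])
        assert combined.flb == pytest.approx(r1.flb * r2.flb, rel=1e-12)
        assert combined.log_flb == pytest.approx(r1.log_flb + r2.log_flb)


@pytest.fixture(scope="module")
def surface(strong_pedigree, incidence_tables):
    carrier, population = incidence_tables
    return fs.sensitivity_analysis(
        strong_pedigree, carrier, population,
        factor_grid=np.linspace(0.5, 1.5, 9),
        excess_grid=np.linspace(0.0, 1.0, 9))


class TestSensitivity:
    def test_no_excess_means_no_evidence(self, surface):
        """At excess 0 carrier rates equal non-carrier rates: FLB = 1."""
        assert np.allclose(surface.flb_values[:, 0], 1.0, atol=1e-9)

    def test_baseline_cell_equals_unperturbed_flb(self, surface,
                                                  strong_pedigree,
                                                  default_model):
        direct = fs.compute_flb(strong_pedigree, default_model).flb
        assert surface.baseline_flb() == pytest.approx(direct, rel=1e-9)

    def test_flb_nondecreasing_in_excess(self, surface):
        """More carrier excess risk -> stronger co-segregation evidence on a
        co-segregating family."""
        diffs = np.diff(surface.flb_values, axis=1)
        assert np.all(diffs >= -1e-9)

    def test_grid_out_of_range_rejected(self, strong_pedigree,
                                        incidence_tables):
        carrier, population = incidence_tables
        with pytest.raises(DataFormatError):
            fs.sensitivity_analysis(strong_pedigree, carrier, population,
                                    factor_grid=[0.2, 1.0],
                                    excess_grid=[0.0, 1.0])


class TestContour:
    def test_constant_surface_has_no_contour(self):
        grid = fs.SensitivityGrid(np.linspace(0.5, 1.5, 5),
                                  np.linspace(0, 1, 5),
                                  np.ones((5, 5)))
        assert fs.flb_contour(grid, 16.0) == []

    def test_linear_surface_gives_analytic_isoline(self):
        xs = np.linspace(0.5, 1.5, 11)
        ys = np.linspace(0.0, 1.0, 11)
        Z = np.tile(ys * 32.0, (11, 1))
        lines = fs.flb_contour(fs.SensitivityGrid(xs, ys, Z), 16.0)
        pts = [p for line in lines for p in line]
        assert pts
        for _x, e in pts:
            assert e == pytest.approx(0.5, abs=1e-12)

    def test_contour_points_re_evaluate_to_level(self, strong_pedigree,
                                                 incidence_tables):
        from oracles import bilinear_eval
        carrier, population = incidence_tables
        grid = fs.sensitivity_analysis(
            strong_pedigree, carrier, population,
            factor_grid=np.linspace(0.5, 1.5, 9),
            excess_grid=np.linspace(0.0, 1.0, 9))
        lines = fs.flb_contour(grid, 16.0)
        pts = [p for line in lines for p in line]
        assert pts, "strong family should cross FLB = 16 somewhere"
        for x, y in pts:
            val = bilinear_eval(grid.factors, grid.excess_fractions,
                                grid.flb_values, x, y)
            assert abs(val - 16.0) < 1e-6

    def test_degenerate_grid_rejected(self):
        with pytest.raises(DataFormatError):
            fs.flb_contour(fs.SensitivityGrid(np.array([1.0]),
                                              np.array([0.0, 1.0]),
                                              np.ones((1, 2))), 16.0)


def _with_proband(ped):
    """Mark a random-ish affected carrier as proband, or None if none exists."""
    for m in ped.members:
        if m.affected == AFFECTED and m.carrier_status == CARRIER:
            return ped.replaced(updates={m.id: {"is_proband": True}})
    return None
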