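"""Tests of the fractionator, nucleator, CE, and group statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plaquetrack.stereology import (
    SamplingDesign,
    default_design,
    estimate_total,
    fractionator_count,
    fractionator_count_at,
    group_comparisons,
    nucleator_area,
    percent_decrease,
    schmitz_hof_ce,
    surface_area_per_section,
)
from plaquetrack.synthetic import SectionPopulation, make_section_population

from conftest import fisher_exact_oracle


def manual_population(rows, n_sections=1, region=(1000.0, 1000.0), thickness=40.0):
    frame = pd.DataFrame(rows, columns=["section", "x", "y", "z", "z_lo", "z_hi"])
    frame["radius"] = 5.0
    frame["area"] = math.pi * 25.0
    return SectionPopulation(
        frame=frame, n_sections=n_sections, region_um=region, thickness_um=thickness
    )


class TestDesign:
    def test_paper_style_design_fractions(self):
        d = default_design()
        assert d.asf == pytest.approx(0.16)  # (200x200)/(500x500)
        assert d.hsf == pytest.approx(0.5)  # 20/40
        assert d.ssf == pytest.approx(0.25)

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            SamplingDesign(counting_frame=(600.0, 200.0))
        with pytest.raises(ValueError):
            SamplingDesign(disector_height=39.0, guard_zone=2.0)
        with pytest.raises(ValueError):
            SamplingDesign(ssf=0.0)


class TestFractionatorRules:
    def test_empty_section_counts_zero(self):
        pop = manual_population([])
        design = SamplingDesign(ssf=1.0)
        assert fractionator_count_at(pop, design, 0, (0.0, 0.0)) == 0

    def test_exclusion_edge_not_counted(self):
        """A counting point exactly on the frame's left/bottom edge is out."""
        design = SamplingDesign(ssf=1.0)
        on_left_edge = manual_population([[0, 0.0, 100.0, 10.0, 5.0, 15.0]])
        assert fractionator_count_at(on_left_edge, design, 0, (0.0, 0.0)) == 0
        just_inside = manual_population([[0, 1.0, 100.0, 10.0, 5.0, 15.0]])
        assert fractionator_count_at(just_inside, design, 0, (0.0, 0.0)) == 1

    def test_guard_zone_and_containment_rules(self):
        design = SamplingDesign(ssf=1.0)
        in_guard = manual_population([[0, 50.0, 50.0, 1.0, 0.5, 1.5]])
        assert fractionator_count_at(in_guard, design, 0, (0.0, 0.0)) == 0
        below_disector = manual_population([[0, 50.0, 50.0, 30.0, 25.0, 35.0]])
        assert fractionator_count_at(below_disector, design, 0, (0.0, 0.0)) == 0
        not_contained = manual_population([[0, 50.0, 50.0, 10.0, -1.0, 15.0]])
        assert fractionator_count_at(not_contained, design, 0, (0.0, 0.0)) == 0
        counted = manual_population([[0, 50.0, 50.0, 10.0, 5.0, 15.0]])
        assert fractionator_count_at(counted, design, 0, (0.0, 0.0)) == 1

    def test_frame_larger_than_region_rejected(self):
        pop = manual_population([], region=(100.0, 100.0))
        with pytest.raises(ValueError):
            fractionator_count_at(pop, default_design(), 0, (0.0, 0.0))

    def test_matches_per_plaque_bruteforce(self, rng):
        """Vectorized counting equals applying the rules plaque by plaque."""
        pop = make_section_population(8, (1500.0, 1500.0), 25.0, seed=9)
        design = default_design()
        for trial in range(10):
            start = int(rng.integers(4))
            offset = (float(rng.uniform(0, 500)), float(rng.uniform(0, 500)))
            expected = 0
            period = 4
            sampled = set(range(start % period, pop.n_sections, period))
            for _, row in pop.frame.iterrows():
                if int(row.section) not in sampled:
                    continue
                u = (row.x - offset[0]) % design.grid[0]
                v = (row.y - offset[1]) % design.grid[1]
                if not (0 < u <= 200 and 0 < v <= 200):
                    continue
                if not (2.0 <= row.z < 22.0):
                    continue
                if row.z_lo < 0 or row.z_hi > 40.0:
                    continue
                expected += 1
            assert fractionator_count_at(pop, design, start, offset) == expected


class TestEstimator:
    def test_zero_count_zero_estimate(self):
        assert estimate_total(0, default_design()) == 0.0

    def test_hand_arithmetic_example(self):
        """sum_Q=12 with ssf=1/4, asf=0.16, hsf=0.5 scales to 600."""
        d = SamplingDesign()
        assert estimate_total(12, d) == pytest.approx(12 * 4 * 6.25 * 2)

    def test_unbiased_over_grid_offsets(self):
        pop = make_section_population(24, (2000.0, 2000.0), 10.0, seed=42)
        d = default_design()
        ests = [
            estimate_total(fractionator_count(pop, d, seed=s)[0], d)
            for s in range(200)
        ]
        assert abs(np.mean(ests) / pop.total_count - 1.0) < 0.05

    def test_halving_ssf_halves_count_not_estimate(self):
        pop = make_section_population(24, (2000.0, 2000.0), 10.0, seed=11)
        full = SamplingDesign(ssf=1.0)
        half = SamplingDesign(ssf=0.5)
        q_full = np.mean([fractionator_count(pop, full, seed=s)[0] for s in range(100)])
        q_half = np.mean([fractionator_count(pop, half, seed=s)[0] for s in range(100)])
        assert q_half / q_full == pytest.approx(0.5, abs=0.07)
        n_full = np.mean(
            [estimate_total(fractionator_count(pop, full, seed=s)[0], full) for s in range(100)]
        )
        n_half = np.mean(
            [estimate_total(fractionator_count(pop, half, seed=s)[0], half) for s in range(100)]
        )
        assert n_half / n_full == pytest.approx(1.0, abs=0.07)


class TestCE:
    @pytest.mark.parametrize("q,expected", [(16, 0.25), (1, 1.0), (100, 0.1)])
    def test_inverse_sqrt(self, q, expected):
        assert schmitz_hof_ce(q) == pytest.approx(expected)

    def test_zero_count_undefined(self):
        with pytest.raises(ValueError):
            schmitz_hof_ce(0)


class TestNucleator:
    def test_circle_exact(self):
        assert nucleator_area([10, 10, 10, 10]) == pytest.approx(math.pi * 100)

    def test_zero_rays_zero_area(self):
        assert nucleator_area([0, 0, 0, 0]) == 0.0

    def test_mixed_rays(self):
        assert nucleator_area([3, 4, 3, 4]) == pytest.approx(math.pi * 12.5)

    def test_negative_ray_rejected(self):
        with pytest.raises(ValueError):
            nucleator_area([1, 2, -3, 4])


class TestSurfaceArea:
    def test_product(self):
        assert surface_area_per_section(10, 100) == 1000.0
        assert surface_area_per_section(0, 123.0) == 0.0

    def test_matches_population_ground_truth(self):
        pop = make_section_population(25, (2000.0, 2000.0), 10.0, seed=2)
        per_section = pop.total_count / pop.n_sections
        mean_area = float(pop.frame["area"].mean())
        truth = 10.0 * 4.0 * 300.0  # density * region mm^2 * mean area
        est = surface_area_per_section(per_section, mean_area)
        assert est == pytest.approx(truth, rel=0.1)


class TestFisherExact:
    def test_matches_enumeration_on_small_tables(self, rng):
        for _ in range(60):
            table = rng.integers(0, 13, size=(2, 2))
            if table.sum() == 0 or table.sum(axis=1).min() == 0:
                continue
            _, p_impl = stats.fisher_exact(table)
            assert p_impl == pytest.approx(fisher_exact_oracle(table), abs=1e-9)

    def test_balanced_mortality_not_significant(self):
        report = group_comparisons(
            mortality_tables={"treatment": np.array([[2, 11], [2, 18]])}
        )
        assert report["mortality"]["treatment"]["p_value"] > 0.05


class TestGroupComparisons:
    def test_identical_groups(self):
        df = pd.DataFrame(
            {"group": ["CTL"] * 3 + ["FUS"] * 3, "count": [300.0] * 6}
        )
        rep = group_comparisons(subject_metrics=df)
        assert rep["metrics"]["count"]["p_value"] == pytest.approx(1.0)
        assert rep["metrics"]["count"]["percent_decrease"] == 0.0

    def test_percent_decrease_of_printed_group_means(self):
        """9270 vs 15350 um^2 is a 39.6% decrease (40% at integer rounding)."""
        assert percent_decrease(15350.0, 9270.0) == pytest.approx(39.6, abs=0.05)
        assert round(percent_decrease(15350.0, 9270.0)) == 40

    def test_weight_anova_main_effects(self, rng):
        rows = []
        for g, shift in (("Tg", 4.0), ("nTg", 0.0)):
            for tn in range(1, 6):
                for _ in range(6):
                    rows.append(
                        {"group": g, "treatment_number": tn,
                         "value": rng.normal(shift, 1.0)}
                    )
        rep = group_comparisons(weights=pd.DataFrame(rows))
        assert rep["weights_anova"]["p_group"] < 0.001
        assert rep["weights_anova"]["p_treatment_number"] > 0.05

    def test_too_few_subjects_rejected(self):
        df = pd.DataFrame({"group": ["CTL", "FUS", "FUS"], "count": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            group_comparisons(subject_metrics=df)
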