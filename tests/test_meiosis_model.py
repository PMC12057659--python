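"""Tests of the sequential asymmetric segregation model."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.proportion import proportion_confint

from stellate_drive.meiosis_model import (
    MeiosisParams,
    drive_strength_from_cytology,
    estimate_cytology_params,
    expected_spermatid_composition,
    fraction_Y_among_Ste,
    simulate_meioses,
)
from stellate_drive.synthetic_study import gen_telophase_counts

probs = st.floats(0.0, 1.0)


def composition_oracle(p1, q, p2):
    """Exhaustive enumeration of the branching tree (independent oracle).

    Sums expected class counts over the 2x2x2x2 outcomes of (MI asymmetric,
    cosegregation side, MII asymmetry of the Y-side and X-side divisions).
    """
    totals = {"x_ste": 0.0, "y_ste": 0.0}
    for asym, y_side, y_asym2, x_asym2 in itertools.product([0, 1], repeat=4):
        prob = (
            (p1 if asym else 1 - p1)
            * (q if y_side else 1 - q)
            * (p2 if y_asym2 else 1 - p2)
            * (p2 if x_asym2 else 1 - p2)
        )
        if prob == 0.0:
            continue
        y_sec_ste = (asym and y_side) or not asym
        x_sec_ste = (asym and not y_side) or not asym
        y_count = (1 if y_asym2 else 2) if y_sec_ste else 0
        x_count = (1 if x_asym2 else 2) if x_sec_ste else 0
        totals["y_ste"] += prob * y_count
        totals["x_ste"] += prob * x_count
    return totals


class TestExpectedComposition:
    def test_idealized_two_x_one_y(self):
        comp = expected_spermatid_composition(MeiosisParams(1, 1, 1, 1))
        assert comp.as_dict() == {"x_ste": 0.0, "x_noste": 2.0, "y_ste": 1.0, "y_noste": 1.0}

    def test_fully_symmetric_all_inherit(self):
        comp = expected_spermatid_composition(MeiosisParams(0, 0.5, 0, 1))
        assert comp.x_ste == pytest.approx(2.0)
        assert comp.y_ste == pytest.approx(2.0)

    def test_derived_generic_values(self):
        comp = expected_spermatid_composition(MeiosisParams(0.8, 0.8, 0.8, 1))
        assert comp.y_ste == pytest.approx(1.008)
        assert comp.x_ste == pytest.approx(0.432)

    @given(p1=probs, q=probs, p2=probs)
    @settings(max_examples=200)
    def test_matches_enumeration_oracle(self, p1, q, p2):
        comp = expected_spermatid_composition(MeiosisParams(p1, q, p2, 1.0))
        oracle = composition_oracle(p1, q, p2)
        assert comp.x_ste == pytest.approx(oracle["x_ste"], abs=1e-12)
        assert comp.y_ste == pytest.approx(oracle["y_ste"], abs=1e-12)

    @given(p1=probs, q=probs, p2=probs)
    @settings(max_examples=200)
    def test_totals(self, p1, q, p2):
        comp = expected_spermatid_composition(MeiosisParams(p1, q, p2, 1.0))
        assert comp.total == pytest.approx(4.0)
        assert comp.x_total == pytest.approx(2.0)
        assert comp.y_total == pytest.approx(2.0)

    @pytest.mark.parametrize("kwargs", [{"p1": -0.1}, {"p1": 0.5, "q": 1.2}])
    def test_invalid_params(self, kwargs):
        full = {"p1": 0.5, "q": 0.5, "p2": 0.5, "k": 1.0, **kwargs}
        with pytest.raises(ValueError):
            MeiosisParams(**full)


class TestFractionYAmongSte:
    def test_perfect_cosegregation(self):
        assert fraction_Y_among_Ste(MeiosisParams(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_no_chromosome_preference(self):
        for p1 in (0.0, 0.3, 0.9):
            assert fraction_Y_among_Ste(MeiosisParams(p1, 0.5, 0.7, 1)) == pytest.approx(0.5)

    def test_derived_value_in_observed_band(self):
        # within the 70-90% band reported for protein-positive spermatids
        assert fraction_Y_among_Ste(MeiosisParams(0.8, 0.8, 0.8, 1)) == pytest.approx(0.7)

    @given(p1=st.floats(0.0, 0.99), q=probs, p2a=probs, p2b=probs)
    @settings(max_examples=200)
    def test_invariant_to_meiosis_ii(self, p1, q, p2a, p2b):
        fa = fraction_Y_among_Ste(MeiosisParams(p1, q, p2a, 1))
        fb = fraction_Y_among_Ste(MeiosisParams(p1, q, p2b, 1))
        assert fa == pytest.approx(fb, abs=1e-12)

    def test_always_defined_on_valid_domain(self):
        # (2 - p2)(2 - p1) >= 1 for probabilities, so the fraction exists
        for p1 in (0.0, 0.5, 1.0):
            for p2 in (0.0, 1.0):
                f = fraction_Y_among_Ste(MeiosisParams(p1, 0.7, p2, 1.0))
                assert 0.0 <= f <= 1.0


class TestDriveStrength:
    def test_idealized_two_thirds(self):
        assert drive_strength_from_cytology(MeiosisParams(1, 1, 1, 1)) == pytest.approx(2 / 3)

    def test_no_killing_is_mendelian(self):
        assert drive_strength_from_cytology(MeiosisParams(0.9, 0.9, 0.9, 0.0)) == pytest.approx(0.5)

    def test_derived_generic_value(self):
        t = drive_strength_from_cytology(MeiosisParams(0.8, 0.8, 0.8, 1.0))
        assert t == pytest.approx(1.568 / 2.560)

    @given(p1=probs, p2=st.floats(0.01, 1.0), q1=probs, q2=probs)
    @settings(max_examples=200)
    def test_monotone_in_cosegregation(self, p1, p2, q1, q2):
        # p2 > 0 keeps clear of the degenerate all-killed corner (p1=p2=0, k=1)
        lo, hi = sorted([q1, q2])
        t_lo = drive_strength_from_cytology(MeiosisParams(p1, lo, p2, 1.0))
        t_hi = drive_strength_from_cytology(MeiosisParams(p1, hi, p2, 1.0))
        assert t_hi >= t_lo - 1e-12

    @given(p1=probs, q=st.floats(0.5, 1.0), p2=st.floats(0.01, 1.0), k1=probs, k2=probs)
    @settings(max_examples=200)
    def test_monotone_in_penetrance(self, p1, q, p2, k1, k2):
        lo, hi = sorted([k1, k2])
        t_lo = drive_strength_from_cytology(MeiosisParams(p1, q, p2, lo))
        t_hi = drive_strength_from_cytology(MeiosisParams(p1, q, p2, hi))
        assert t_hi >= t_lo - 1e-12

    def test_all_killed_error(self):
        with pytest.raises(ValueError):
            drive_strength_from_cytology(MeiosisParams(0.0, 0.5, 0.0, 1.0))


def class_count_sd(pi, p2):
    """Exact per-meiosis SD of a protein-positive class count (0, 1 or 2).

    The count is 0 unless the secondary carries protein (probability pi),
    then 2 - Bernoulli(p2); second moment pi*(4 - 3*p2).
    """
    mean = pi * (2.0 - p2)
    second = pi * (4.0 - 3.0 * p2)
    return np.sqrt(second - mean**2)


class TestSimulateMeioses:
    def test_idealized_single_meiosis_exact(self):
        sample = simulate_meioses(MeiosisParams(1, 1, 1, 1), 1, seed=0)
        assert sample.counts == {"x_ste": 0, "x_noste": 2, "y_ste": 1, "y_noste": 1}
        assert sample.surviving == {"x_ste": 0, "x_noste": 2, "y_ste": 0, "y_noste": 1}

    def test_deterministic_under_seed(self):
        p = MeiosisParams(0.7, 0.6, 0.8, 0.9)
        a = simulate_meioses(p, 5000, seed=42)
        b = simulate_meioses(p, 5000, seed=42)
        assert a == b
        c = simulate_meioses(p, 5000, seed=43)
        assert c != a

    def test_converges_to_closed_form(self):
        p = MeiosisParams(0.8, 0.7, 0.75, 1.0)
        n = 50_000
        sample = simulate_meioses(p, n, seed=7)
        comp = expected_spermatid_composition(p)
        pi_y = p.p1 * p.q + 1 - p.p1
        pi_x = p.p1 * (1 - p.q) + 1 - p.p1
        for cls, pi in (("y_ste", pi_y), ("x_ste", pi_x)):
            mean = sample.counts[cls] / n
            se = class_count_sd(pi, p.p2) / np.sqrt(n)
            assert abs(mean - getattr(comp, cls)) < 4 * se

    def test_killing_reduces_only_ste_classes(self):
        p = MeiosisParams(0.8, 0.7, 0.75, 0.5)
        sample = simulate_meioses(p, 10_000, seed=3)
        assert sample.surviving["x_noste"] == sample.counts["x_noste"]
        assert sample.surviving["y_noste"] == sample.counts["y_noste"]
        assert sample.surviving["x_ste"] <= sample.counts["x_ste"]
        assert sample.surviving["y_ste"] <= sample.counts["y_ste"]


class TestEstimateCytologyParams:
    def test_mle_is_sample_fraction(self):
        mi = {"asymmetric_coseg_Y": 60, "asymmetric_coseg_X": 20, "symmetric": 20}
        mii = {"asymmetric": 75, "symmetric": 25}
        est = estimate_cytology_params(mi, mii)
        assert est.p1 == pytest.approx(0.8)
        assert est.q == pytest.approx(0.75)
        assert est.p2 == pytest.approx(0.75)
        assert est.p1_ci[0] < 0.8 < est.p1_ci[1]

    def test_boundary_all_asymmetric(self):
        est = estimate_cytology_params(
            {"asymmetric_coseg_Y": 70, "asymmetric_coseg_X": 30, "symmetric": 0},
            {"asymmetric": 50, "symmetric": 0},
        )
        assert est.p1 == 1.0
        assert est.p1_ci[1] == pytest.approx(1.0)
        assert est.p1_ci[0] < 1.0  # one-sided interval at the boundary

    def test_zero_asymmetric_flags_q_undefined(self):
        est = estimate_cytology_params(
            {"asymmetric_coseg_Y": 0, "asymmetric_coseg_X": 0, "symmetric": 40},
            {"asymmetric": 10, "symmetric": 30},
        )
        assert not est.q_defined
        assert est.q is None

    def test_interval_coverage(self):
        """Exact intervals cover the truth in at least 93% of replicates."""
        p1, q, p2 = 0.82, 0.73, 0.80
        n_rep, n_cells = 1000, 500
        hits = {"p1": 0, "q": 0, "p2": 0}
        for i in range(n_rep):
            mi = gen_telophase_counts(n_cells, p1, q, stage="MI", seed=2 * i)
            mii = gen_telophase_counts(n_cells, p2, stage="MII", seed=2 * i + 1)
            est = estimate_cytology_params(mi, mii)
            hits["p1"] += est.p1_ci[0] <= p1 <= est.p1_ci[1]
            hits["q"] += est.q_defined and est.q_ci[0] <= q <= est.q_ci[1]
            hits["p2"] += est.p2_ci[0] <= p2 <= est.p2_ci[1]
        for name, h in hits.items():
            assert h / n_rep >= 0.93, name

    def test_accepts_scoring_table_objects(self):
        mi = gen_telophase_counts(200, 0.8, 0.7, stage="MI", seed=0)
        mii = gen_telophase_counts(200, 0.8, stage="MII", seed=1)
        est = estimate_cytology_params(mi, mii)
        assert 0.0 <= est.p1 <= 1.0
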