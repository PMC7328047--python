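"""Lattice indexing: lamellar regression, ratio fits, classification."""

import math

import numpy as np
import pytest

from mesoswell import (
    CUBIC_RATIO_SETS,
    CurveSpec,
    PhaseSpec,
    classify_phase,
    compose_coexistence,
    find_peaks,
    generate_pattern,
    index_lamellar,
    index_ratio_lattice,
    rank_cubic_candidates,
    subtract_background,
)
from mesoswell.peaks import Peak, PeakList
from tests.conftest import noise_scale_for_snr


def peaklist(qs):
    return PeakList([Peak(q, 1.0, 1.0, 0.004) for q in qs])


class TestLamellarIndexing:
    def test_exact_orders_give_zero_uncertainty_and_intercept(self):
        q1 = 2 * math.pi / 94.0
        fit = index_lamellar(peaklist([q1, 2 * q1, 3 * q1]))
        assert fit.d == pytest.approx(94.0, abs=1e-9)
        assert fit.d_uncertainty == pytest.approx(0.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.assigned_orders == (1, 2, 3)

    def test_per_reflection_d_spread_matches_hand_calculation(self):
        qs = (0.0670, 0.1335, 0.2010)
        fit = index_lamellar(peaklist(qs))
        expected = [2 * math.pi * n / q for n, q in zip((1, 2, 3), qs)]
        np.testing.assert_allclose(fit.per_reflection_d, expected, rtol=1e-12)
        np.testing.assert_allclose(fit.per_reflection_d, (93.78, 94.13, 93.78), atol=5e-3)
        assert fit.d_uncertainty == pytest.approx(np.std(expected, ddof=1))

    def test_missing_third_order_recovered_with_gap(self):
        q1 = 2 * math.pi / 80.0
        fit = index_lamellar(peaklist([q1, 2 * q1, 4 * q1]))
        assert fit.assigned_orders == (1, 2, 4)
        assert fit.d == pytest.approx(80.0, rel=1e-9)

    def test_hexagonal_ratios_rejected(self):
        qs = [0.10 * r for r in (1, math.sqrt(3), 2, math.sqrt(7), 3)]
        assert index_lamellar(peaklist(qs), tolerance_rel=0.01) is None

    def test_single_peak_is_no_fit(self):
        assert index_lamellar(peaklist([0.1])) is None

    def test_sem_option_shrinks_uncertainty(self):
        qs = (0.0670, 0.1335, 0.2010)
        std = index_lamellar(peaklist(qs), uncertainty="std").d_uncertainty
        sem = index_lamellar(peaklist(qs), uncertainty="sem").d_uncertainty
        assert sem == pytest.approx(std / math.sqrt(3))


class TestRatioLattice:
    def test_hexagonal_example(self):
        qs = [0.10 * r for r in (1, math.sqrt(3), 2, math.sqrt(7), 3)]
        fit = index_ratio_lattice(peaklist(qs))
        assert fit.q1 == pytest.approx(0.10, rel=1e-9)
        assert fit.a == pytest.approx(4 * math.pi / (math.sqrt(3) * 0.10), rel=1e-9)
        assert fit.n_matched == 5

    def test_single_peak_no_fit(self):
        assert index_ratio_lattice(peaklist([0.1])) is None

    def test_cubic_set_lattice_parameter(self):
        a = 120.0
        qs = [r * 2 * math.pi / a for r in CUBIC_RATIO_SETS["Pn3m"]]
        fit = index_ratio_lattice(peaklist(qs), CUBIC_RATIO_SETS["Pn3m"],
                                  lattice="cubic", label="Pn3m")
        assert fit.a == pytest.approx(a, rel=1e-9)


class TestClassifyPhase:
    def test_pure_lamellar_single_fit_no_coexistence(self, lamellar_94):
        peaks = find_peaks(subtract_background(lamellar_94))
        out = classify_phase(peaks)
        assert out.phase_names == ("lamellar",)
        assert not out.coexistence
        assert out.fits[0].d == pytest.approx(94.0, rel=1e-3)

    def test_lamellar_ratios_outrank_hexagonal_subset(self):
        # 1,2,3 also sit inside the hexagonal ratio sequence; parsimony must win
        q1 = 2 * math.pi / 60.0
        out = classify_phase(peaklist([q1, 2 * q1, 3 * q1]))
        assert out.fits[0].phase_name == "lamellar"

    def test_hexagonal_pattern_classified_hexagonal(self, hexagonal_7255):
        peaks = find_peaks(subtract_background(hexagonal_7255))
        out = classify_phase(peaks)
        assert out.fits[0].phase_name == "hexagonal"
        assert out.fits[0].a == pytest.approx(72.55, rel=1e-3)

    def test_coexistence_recovers_both_lattices(self):
        cs = CurveSpec()
        curve = compose_coexistence(
            [
                generate_pattern(PhaseSpec("lamellar", 60.0), cs),
                generate_pattern(PhaseSpec("hexagonal", 72.55, n_orders=5), cs),
            ]
        )
        peaks = find_peaks(subtract_background(curve), min_separation=0.003)
        out = classify_phase(peaks)
        assert out.coexistence
        by_name = {f.phase_name: f for f in out.fits}
        assert by_name["lamellar"].d == pytest.approx(60.0, abs=0.5)
        assert by_name["hexagonal"].a == pytest.approx(72.55, abs=0.5)
        assert len(out.unassigned_peaks) == 0

    def test_every_peak_in_exactly_one_bucket(self):
        cs = CurveSpec(noise_scale=1.0, seed=5)
        curve = compose_coexistence(
            [
                generate_pattern(PhaseSpec("lamellar", 60.0), cs),
                generate_pattern(PhaseSpec("hexagonal", 72.55, n_orders=5), cs),
            ]
        )
        peaks = find_peaks(subtract_background(curve), min_separation=0.003)
        out = classify_phase(peaks)
        buckets = [set(f.matched_indices) for f in out.fits]
        unassigned_q = set(np.round(out.unassigned_peaks.q, 10))
        assigned = set().union(*buckets) if buckets else set()
        for i, j in zip(range(len(buckets)), range(1, len(buckets))):
            assert not buckets[i] & buckets[j]
        for k in range(len(peaks)):
            qk = round(peaks.peaks[k].q_center, 10)
            assert (k in assigned) != (qk in unassigned_q)

    def test_cubic_candidates_ranked_generator_first(self):
        cs = CurveSpec()
        curve = generate_pattern(PhaseSpec("cubic", 120.0, n_orders=6,
                                           ratio_set=CUBIC_RATIO_SETS["Pn3m"]), cs)
        peaks = find_peaks(subtract_background(curve))
        out = classify_phase(peaks)
        assert out.fits[0].phase_name == "cubic"
        assert len(out.cubic_candidates) >= 2
        assert out.cubic_candidates[0].space_group_label == "Pn3m"
        assert out.cubic_candidates[0].a == pytest.approx(120.0, rel=1e-3)

    def test_cubic_needs_three_matches(self):
        cands = rank_cubic_candidates(peaklist([0.1, 0.1415]))
        assert all(c.n_matched >= 3 for c in cands)

    def test_empty_peaklist_raises(self):
        with pytest.raises(ValueError):
            classify_phase(PeakList())


class TestNoisyRoundTrip:
    @pytest.mark.parametrize(
        "spec,param_of",
        [
            (PhaseSpec("lamellar", 85.0), lambda f: f.d),
            (PhaseSpec("hexagonal", 72.55, n_orders=5), lambda f: f.a),
        ],
        ids=["lamellar", "hexagonal"],
    )
    def test_median_relative_error_below_half_percent(self, spec, param_of):
        base = CurveSpec()
        ns = noise_scale_for_snr(spec, base, 20.0)
        errs = []
        for seed in range(25):
            curve = generate_pattern(spec, CurveSpec(noise_scale=ns, seed=seed))
            peaks = find_peaks(subtract_background(curve))
            out = classify_phase(peaks)
            assert out.fits[0].phase_name == spec.phase_type
            errs.append(abs(param_of(out.fits[0]) - spec.lattice_parameter)
                        / spec.lattice_parameter)
        assert np.median(errs) < 0.005
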