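"""Forward model: reflection positions, determinism, noise, swelling laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mesoswell import (
    CurveSpec,
    PhaseSpec,
    SwellingLaw,
    compose_coexistence,
    generate_pattern,
    generate_swelling_series,
    swelling_repeat_distance,
)


class TestPeakCenters:
    def test_lamellar_orders_at_2pi_n_over_d(self):
        spec = PhaseSpec("lamellar", 94.0, n_orders=3)
        np.testing.assert_allclose(
            spec.peak_centers, [0.06684, 0.13368, 0.20053], atol=5e-6
        )

    def test_hexagonal_ratio_sequence(self):
        # q1 = 0.10 1/A corresponds to a = 4 pi / (sqrt(3) * 0.10)
        a = 4 * math.pi / (math.sqrt(3) * 0.10)
        spec = PhaseSpec("hexagonal", a, n_orders=5)
        np.testing.assert_allclose(
            spec.peak_centers, [0.10, 0.17321, 0.20, 0.26458, 0.30], atol=5e-6
        )

    def test_peak_outside_grid_names_reflection(self):
        with pytest.raises(ValueError, match="reflection"):
            generate_pattern(
                PhaseSpec("lamellar", 94.0, n_orders=12), CurveSpec(q_max=0.3)
            )


class TestDeterminismAndNoise:
    def test_same_seed_bitwise_identical(self):
        spec = PhaseSpec("lamellar", 80.0)
        cs = CurveSpec(noise_scale=1.5, seed=42)
        c1, c2 = generate_pattern(spec, cs), generate_pattern(spec, cs)
        assert np.array_equal(c1.intensity, c2.intensity)

    def test_different_seed_differs(self):
        spec = PhaseSpec("lamellar", 80.0)
        c1 = generate_pattern(spec, CurveSpec(noise_scale=1.5, seed=1))
        c2 = generate_pattern(spec, CurveSpec(noise_scale=1.5, seed=2))
        assert not np.array_equal(c1.intensity, c2.intensity)

    def test_noiseless_equals_background_plus_peaks(self):
        spec = PhaseSpec("lamellar", 80.0)
        cs = CurveSpec(noise_scale=0.0)
        curve = generate_pattern(spec, cs)
        # Lorentzian tails reach a couple of percent of the local background
        # at 0.05 1/A from a peak; beyond that the curve is pure background
        away = np.abs(curve.q[:, None] - spec.peak_centers[None, :]).min(axis=1) > 0.05
        np.testing.assert_allclose(
            curve.intensity[away], cs.background(curve.q)[away], rtol=0.03
        )

    @pytest.mark.parametrize("phase_type,param", [("lamellar", 94.0), ("hexagonal", 72.55)])
    def test_noiseless_maxima_within_one_grid_step(self, phase_type, param):
        spec = PhaseSpec(phase_type, param, n_orders=3)
        curve = generate_pattern(spec, CurveSpec())
        dq = curve.dq
        for c in spec.peak_centers:
            window = np.abs(curve.q - c) < 0.01
            q_max = curve.q[window][np.argmax(curve.intensity[window])]
            assert abs(q_max - c) <= dq


class TestCoexistence:
    def test_single_curve_weight_one_is_identity(self, lamellar_94):
        out = compose_coexistence([lamellar_94], [1.0])
        np.testing.assert_array_equal(out.intensity, lamellar_94.intensity)

    def test_union_of_ground_truth_centers(self, hexagonal_7255):
        lam = generate_pattern(PhaseSpec("lamellar", 60.0), CurveSpec())
        out = compose_coexistence([lam, hexagonal_7255])
        assert len(out.metadata["true_peak_centers"]) == 3 + 5

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            compose_coexistence([])

    def test_mismatched_grids_raise(self, lamellar_94):
        other = generate_pattern(PhaseSpec("lamellar", 94.0), CurveSpec(n_points=400))
        with pytest.raises(ValueError, match="grid"):
            compose_coexistence([lamellar_94, other])


class TestSwellingLaws:
    def test_ideal_dilution_pure_hydrocarbon(self):
        law = SwellingLaw("ideal_dilution", d_hc=27.1)
        assert swelling_repeat_distance(law, 50.0) == pytest.approx(54.2)

    def test_near_dry_limit_approaches_d_hc(self):
        law = SwellingLaw("ideal_dilution", d_hc=27.1)
        assert swelling_repeat_distance(law, 1e-6) == pytest.approx(27.1, rel=1e-6)

    def test_bridging_cap_plateau_value(self):
        law = SwellingLaw("bridging_capped", d_hc=27.1, d_w_max=67.0)
        assert swelling_repeat_distance(law, 85.0) == pytest.approx(94.1)

    def test_hydration_out_of_range_raises(self):
        law = SwellingLaw("ideal_dilution", d_hc=27.1)
        for bad in (0.0, 100.0, -5.0, 120.0):
            with pytest.raises(ValueError):
                swelling_repeat_distance(law, bad)

    @settings(derandomize=True, max_examples=50)
    @given(
        w1=st.floats(1.0, 98.0),
        w2=st.floats(1.0, 98.0),
        d_hc=st.floats(10.0, 40.0),
        cap=st.floats(5.0, 100.0),
        hg=st.floats(0.0, 0.5),
    )
    def test_monotone_and_capped(self, w1, w2, d_hc, cap, hg):
        lo, hi = sorted((w1, w2))
        for law in (
            SwellingLaw("ideal_dilution", d_hc=d_hc,
                        headgroup_volume_fraction_of_lipid=hg),
            SwellingLaw("bridging_capped", d_hc=d_hc, d_w_max=cap,
                        headgroup_volume_fraction_of_lipid=hg),
        ):
            d_lo, d_hi = (swelling_repeat_distance(law, w) for w in (lo, hi))
            assert d_hi >= d_lo - 1e-9
            if law.law_type == "bridging_capped":
                assert d_hi <= d_hc + cap + 1e-9

    def test_series_points_carry_d_w(self):
        law = SwellingLaw("bridging_capped", d_hc=27.1, d_w_max=67.0)
        series = generate_swelling_series(law, [50, 60, 70, 80])
        for p in series.points:
            assert p.d_w == pytest.approx(p.d - 27.1)
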