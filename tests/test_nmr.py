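"""Signal integration, the acyl-composition equations and total lipid."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seedlipid import nmr
from seedlipid.errors import (
    DegenerateInputError,
    InconsistentIntegralsError,
    RangeError,
    ValidationError,
)
from seedlipid.synthetic import AcylMixture, simulate_nmr

positive_area = st.floats(0.05, 50.0, allow_nan=False)


def flat_spectrum(value=1.0, lo=0.0, hi=6.0, n=601):
    ppm = np.linspace(hi, lo, n)
    return nmr.NMRSpectrum(ppm=ppm, intensity=np.full(n, value))


class TestIntegrateRegion:
    def test_rectangle_area(self):
        area = nmr.integrate_region(flat_spectrum(1.0), (2.0, 2.2), baseline="none")
        assert area == pytest.approx(0.2, abs=1e-12)

    def test_all_zero_intensity(self):
        assert nmr.integrate_region(flat_spectrum(0.0), (1.0, 2.0), baseline="none") == 0.0

    def test_lorentzian_against_dense_quadrature(self):
        """Area of a truncated Lorentzian vs a 10x-resolution oracle."""
        h, w, c = 1.0, 0.01, 3.0
        lorentz = lambda x: h / (1.0 + ((x - c) / w) ** 2)
        ppm = np.linspace(6.0, 0.0, 8192)
        spec = nmr.NMRSpectrum(ppm=ppm, intensity=lorentz(ppm))
        area = nmr.integrate_region(spec, (c - 0.1, c + 0.1), baseline="none")
        dense = np.linspace(c - 0.1, c + 0.1, 81920)
        oracle = np.trapezoid(lorentz(dense), dense)
        truncated = 2 * h * w * np.arctan(0.1 / w)  # analytic area inside the window
        assert area == pytest.approx(oracle, rel=1e-4)
        assert area == pytest.approx(truncated, rel=1e-3)
        # the window captures all but ~6% of the full-line area pi*h*w
        assert area / (np.pi * h * w) == pytest.approx(0.937, abs=0.02)

    def test_endpoint_linear_baseline_removes_offset_and_tilt(self):
        ppm = np.linspace(6.0, 0.0, 4001)
        peak = np.exp(-0.5 * ((ppm - 3.0) / 0.02) ** 2)
        tilt = 0.7 + 0.1 * ppm
        spec = nmr.NMRSpectrum(ppm=ppm, intensity=peak + tilt)
        clean = nmr.NMRSpectrum(ppm=ppm, intensity=peak)
        a = nmr.integrate_region(spec, (2.7, 3.3), baseline="endpoint-linear")
        b = nmr.integrate_region(clean, (2.7, 3.3), baseline="none")
        assert a == pytest.approx(b, rel=1e-6)

    def test_window_outside_range_raises(self):
        with pytest.raises(RangeError):
            nmr.integrate_region(flat_spectrum(), (7.0, 8.0))

    def test_negative_net_area_floors_at_zero(self):
        spec = flat_spectrum(-1.0)
        assert nmr.integrate_region(spec, (1.0, 2.0), baseline="none") == 0.0


class TestAssignAndIntegrate:
    def test_eleven_positive_areas_for_pea_oil_spectrum(self, pea_oil_spectrum):
        table = nmr.assign_and_integrate(pea_oil_spectrum, baseline="none")
        assert len(table.areas) == 11
        assert all(v > 0 for v in table.areas.values())

    def test_order_independence(self, pea_oil_spectrum):
        fwd = nmr.assign_and_integrate(
            pea_oil_spectrum, nmr.default_assignments(), baseline="none"
        )
        rev = nmr.assign_and_integrate(
            pea_oil_spectrum, nmr.default_assignments()[::-1], baseline="none"
        )
        assert fwd.areas == rev.areas

    def test_overlapping_windows_rejected(self, pea_oil_spectrum):
        bad = [
            nmr.SignalAssignment("A", (1.0, 2.0)),
            nmr.SignalAssignment("B", (1.5, 2.5)),
        ]
        with pytest.raises(ValidationError):
            nmr.assign_and_integrate(pea_oil_spectrum, bad)

    def test_error_names_failing_label(self, pea_oil_spectrum):
        bad = [nmr.SignalAssignment("Z", (8.0, 9.0))]
        with pytest.raises(RangeError, match="'Z'"):
            nmr.assign_and_integrate(pea_oil_spectrum, bad)


class TestNormalizeIntegrals:
    def test_two_equal_areas(self):
        out = nmr.normalize_integrals(nmr.IntegralTable({"A": 1.0, "B": 1.0}))
        assert out.areas == {"A": 50.0, "B": 50.0}
        assert out.normalized

    @given(st.dictionaries(st.sampled_from(nmr.SIGNAL_LABELS), positive_area,
                           min_size=2, max_size=11))
    def test_output_always_sums_to_100(self, areas):
        out = nmr.normalize_integrals(nmr.IntegralTable(areas))
        assert sum(out.areas.values()) == pytest.approx(100.0, abs=1e-9)

    def test_idempotent(self):
        once = nmr.normalize_integrals(nmr.IntegralTable({"A": 3.0, "B": 9.0}))
        twice = nmr.normalize_integrals(once)
        assert twice.areas == pytest.approx(once.areas)

    def test_all_zero_table_rejected(self):
        with pytest.raises(DegenerateInputError):
            nmr.normalize_integrals(nmr.IntegralTable({"A": 0.0, "B": 0.0}))


class TestAcylComposition:
    def test_hand_computed_mixture(self):
        table = nmr.IntegralTable({"A": 1.60, "B": 2.0, "C": 3.60, "E": 0.75, "F": 2.25})
        comp = nmr.acyl_composition(table)
        assert comp.as_tuple() == pytest.approx((25.0, 30.0, 35.0, 10.0), abs=1e-12)

    def test_saturated_only(self):
        table = nmr.IntegralTable({"A": 0.0, "B": 2.0, "C": 0.0, "E": 0.0, "F": 3.0})
        assert nmr.acyl_composition(table).as_tuple() == pytest.approx((0, 0, 0, 100))

    def test_pure_linoleic(self):
        table = nmr.IntegralTable({"A": 2.0, "B": 2.0, "C": 4.0, "E": 0.0, "F": 3.0})
        assert nmr.acyl_composition(table).as_tuple() == pytest.approx((0, 100, 0, 0))

    @given(A=positive_area, B=positive_area, C=positive_area,
           E=positive_area, F=positive_area)
    def test_four_classes_always_sum_to_100(self, A, B, C, E, F):
        """The four equations are algebraically complementary."""
        table = nmr.IntegralTable({"A": A, "B": B, "C": C, "E": E, "F": F})
        try:
            comp = nmr.acyl_composition(table, tol=0.0)
        except InconsistentIntegralsError:
            return  # random ratios need not be physical; the identity is tested below
        assert sum(comp.as_tuple()) == pytest.approx(100.0, abs=1e-9)

    @given(A=positive_area, B=positive_area, C=positive_area,
           E=positive_area, F=positive_area)
    def test_raw_equations_sum_to_100_even_outside_bounds(self, A, B, C, E, F):
        omega3 = E / (F + E)
        raw = [
            100 * omega3,
            100 * (A / B - 2 * omega3),
            100 * (C / (2 * B) - A / B + omega3),
            100 * (1 - C / (2 * B)),
        ]
        assert sum(raw) == pytest.approx(100.0, abs=1e-8)

    @given(k=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, k):
        base = {"A": 1.60, "B": 2.0, "C": 3.60, "E": 0.75, "F": 2.25}
        scaled = nmr.IntegralTable({key: k * v for key, v in base.items()})
        comp = nmr.acyl_composition(scaled)
        assert comp.as_tuple() == pytest.approx((25, 30, 35, 10), rel=1e-9)

    def test_small_negative_clipped_and_renormalized(self):
        # A/B slightly below 2*E/(E+F): linoleic marginally negative
        table = nmr.IntegralTable({"A": 0.99, "B": 2.0, "C": 3.0, "E": 1.0, "F": 3.0})
        comp = nmr.acyl_composition(table)
        assert min(comp.as_tuple()) == 0.0
        assert sum(comp.as_tuple()) == pytest.approx(100.0)

    def test_large_violation_raises(self):
        table = nmr.IntegralTable({"A": 0.1, "B": 2.0, "C": 3.0, "E": 3.0, "F": 1.0})
        with pytest.raises(InconsistentIntegralsError):
            nmr.acyl_composition(table)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            nmr.acyl_composition(nmr.IntegralTable({"A": 1, "B": 0, "C": 1, "E": 1, "F": 1}))
        with pytest.raises(DegenerateInputError):
            nmr.acyl_composition(nmr.IntegralTable({"A": 1, "B": 1, "C": 1, "E": 0, "F": 0}))


class TestParameterRecovery:
    MIXTURES = [
        (0.25, 0.30, 0.35, 0.10),
        (0.20, 0.35, 0.30, 0.15),
        (0.05, 0.15, 0.55, 0.25),
        (0.30, 0.40, 0.20, 0.10),
        (0.10, 0.10, 0.10, 0.70),
    ]

    @pytest.mark.parametrize("fractions", MIXTURES)
    def test_noiseless_recovery_within_half_point(self, fractions):
        spec = simulate_nmr(AcylMixture(*fractions), 80.0, 7.0, 0.0, seed=0)
        table = nmr.assign_and_integrate(spec, baseline="none")
        comp = nmr.acyl_composition(table)
        truth = tuple(100 * f for f in fractions)
        assert comp.as_tuple() == pytest.approx(truth, abs=0.5)

    def test_recovery_error_grows_with_noise(self, default_mixture):
        truth = np.array([100 * f for f in default_mixture.as_tuple()])

        def max_err(noise_sd, seed=21):
            spec = simulate_nmr(default_mixture, 80.0, 7.0, noise_sd, seed=seed)
            comp = nmr.acyl_composition(
                nmr.assign_and_integrate(spec, baseline="none"), tol=50.0
            )
            return np.abs(np.array(comp.as_tuple()) - truth).max()

        errs = [max_err(s) for s in (0.0, 2.0, 20.0)]
        assert errs[0] < errs[1] < errs[2]


class TestTotalLipid:
    def test_self_reference_is_100(self, pea_oil_spectrum):
        t = nmr.assign_and_integrate(pea_oil_spectrum, baseline="none")
        res = nmr.total_lipid(t, 7.0, t, 7.0)
        assert res.total_lipid_pct == pytest.approx(100.0)

    def test_linear_in_sample_areas(self, pea_oil_spectrum):
        ref = nmr.assign_and_integrate(pea_oil_spectrum, baseline="none")
        sample = nmr.IntegralTable({k: 0.05 * v for k, v in ref.areas.items()})
        res = nmr.total_lipid(sample, 7.0, ref, 7.0)
        assert res.total_lipid_pct == pytest.approx(5.0)

    def test_recovers_synthetic_lipid_fraction(self, default_mixture, pea_oil_spectrum):
        sample_spec = simulate_nmr(default_mixture, 1.12, 7.0, 0.0, seed=0)
        st_ = nmr.assign_and_integrate(sample_spec, baseline="none")
        rt = nmr.assign_and_integrate(pea_oil_spectrum, baseline="none")
        res = nmr.total_lipid(st_, 7.0, rt, 7.0)
        assert res.total_lipid_pct == pytest.approx(1.12, abs=0.02)

    def test_invariant_to_common_rescaling_and_mass(self, pea_oil_spectrum):
        ref = nmr.assign_and_integrate(pea_oil_spectrum, baseline="none")
        sample = nmr.IntegralTable({k: 0.02 * v for k, v in ref.areas.items()})
        base = nmr.total_lipid(sample, 5.0, ref, 7.0).total_lipid_pct
        scaled = nmr.total_lipid(
            nmr.IntegralTable({k: 3.5 * v for k, v in sample.areas.items()}), 5.0,
            nmr.IntegralTable({k: 3.5 * v for k, v in ref.areas.items()}), 7.0,
        ).total_lipid_pct
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_normalized_tables_rejected(self, pea_oil_spectrum):
        raw = nmr.assign_and_integrate(pea_oil_spectrum, baseline="none")
        norm = nmr.normalize_integrals(raw)
        with pytest.raises(ValidationError):
            nmr.total_lipid(norm, 7.0, raw, 7.0)

    def test_zero_reference_rejected(self):
        zero = nmr.IntegralTable({"A": 0.0})
        sample = nmr.IntegralTable({"A": 1.0})
        with pytest.raises(DegenerateInputError):
            nmr.total_lipid(sample, 7.0, zero, 7.0)


class TestSpectrumValidation:
    def test_ascending_axis_reordered(self):
        spec = nmr.NMRSpectrum(ppm=np.array([0.0, 1.0, 2.0]),
                               intensity=np.array([1.0, 2.0, 3.0]))
        assert spec.ppm.tolist() == [2.0, 1.0, 0.0]
        assert spec.intensity.tolist() == [3.0, 2.0, 1.0]

    def test_non_monotonic_axis_rejected(self):
        with pytest.raises(ValidationError):
            nmr.NMRSpectrum(ppm=np.array([0.0, 2.0, 1.0]),
                            intensity=np.zeros(3))

    def test_non_finite_intensity_rejected(self):
        with pytest.raises(ValidationError):
            nmr.NMRSpectrum(ppm=np.array([2.0, 1.0]),
                            intensity=np.array([1.0, np.nan]))
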