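"""Unit and property tests for the modified Beer-Lambert inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nirsox.exceptions import DataError, NumericalError, ValidationError
from nirsox.mbll import (DEVICE_WAVELENGTHS, AttenuationSeries, ConcentrationSeries,
                         ExtinctionTable, PathlengthSpec, RawRecording,
                         delta_attenuation, derive_oxy_bv, solve_concentrations)
from _oracles import normal_equations


def _design(eps, path):
    L = np.array([path.path_cm(w) for w in DEVICE_WAVELENGTHS])
    return eps.design_matrix() * L[:, None] * 1e-3


def _recording(intensity_fn, n=700, baseline=(0.0, 600.0)):
    """1 Hz single-detector recording: intensity_fn(t) per wavelength."""
    t = np.arange(float(n))
    inten = np.array([[intensity_fn(t, w) for w in DEVICE_WAVELENGTHS]])
    return RawRecording(time=t, intensity=inten, baseline_window=baseline)


class TestDeltaAttenuation:
    @pytest.mark.parametrize("scale, expected", [
        (1.0, 0.0),              # I == I_o
        (0.1, 1.0),              # one decade
        (0.5, np.log10(2.0)),    # -log10(0.5), independently 0.3010...
    ])
    def test_constant_scaling(self, scale, expected):
        def fn(t, w):
            i = np.full_like(t, 2.0)
            i[600:] *= scale
            return i
        att = delta_attenuation(_recording(fn))
        assert np.allclose(att.delta_a[:, 600:], expected, atol=1e-12)
        assert np.allclose(att.delta_a[:, :600], 0.0, atol=1e-12)

    def test_baseline_mean_defines_reference(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(1.0, 0.01, size=700)

        att = delta_attenuation(_recording(lambda t, w: 3.0 * noise))
        # I_o is the baseline-mean intensity, so I/I_o averages to 1 there
        assert abs((10 ** -att.delta_a[0, :600]).mean() - 1.0) < 1e-9

    def test_detector_mean_averages_log_domain(self):
        t = np.arange(700.0)
        i1 = np.full((3, 700), 1.0)
        i2 = np.full((3, 700), 5.0)  # gain difference between detectors
        i1[:, 600:] = 0.1
        i2[:, 600:] = 0.5 * 5.0
        rec = RawRecording(time=t, intensity=np.array([i1, i2]))
        att = delta_attenuation(rec, detector="mean")
        assert np.allclose(att.delta_a[:, 600:], (1.0 + np.log10(2.0)) / 2.0)

    def test_nonpositive_intensity_names_sample(self):
        def fn(t, w):
            i = np.ones_like(t)
            i[650] = 0.0
            return i
        with pytest.raises(DataError, match="650"):
            delta_attenuation(_recording(fn))

    def test_empty_baseline_window(self):
        with pytest.raises(ValidationError, match="baseline"):
            delta_attenuation(_recording(lambda t, w: np.ones_like(t),
                                         baseline=(1e5, 2e5)))


class TestSolveConcentrations:
    def test_zero_attenuation_gives_zero(self, eps, path):
        att = AttenuationSeries(time=np.arange(5.0), delta_a=np.zeros((3, 5)))
        sol = solve_concentrations(att, eps, path)
        assert np.allclose(sol.dc_hb, 0) and np.allclose(sol.dc_hbo2, 0)
        assert np.allclose(sol.residual, 0)

    def test_forward_inverse_round_trip(self, eps, path):
        true = np.array([[1.0], [2.0]])  # (dC_Hb, dC_HbO2) uM
        att = AttenuationSeries(time=np.zeros(1), delta_a=_design(eps, path) @ true)
        sol = solve_concentrations(att, eps, path)
        assert abs(sol.dc_hb[0] - 1.0) < 1e-9
        assert abs(sol.dc_hbo2[0] - 2.0) < 1e-9

    def test_perturbed_system_matches_normal_equations(self, eps, path):
        design = _design(eps, path)
        da = design @ np.array([[1.0], [2.0]])
        da[1] *= 1.01  # +1% on the isosbestic equation -> inconsistent system
        att = AttenuationSeries(time=np.zeros(1), delta_a=da)
        sol = solve_concentrations(att, eps, path)
        expected = normal_equations(design, da[:, 0])
        assert abs(sol.dc_hb[0] - expected[0]) < 1e-9
        assert abs(sol.dc_hbo2[0] - expected[1]) < 1e-9
        assert sol.residual[0] > 0

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(alpha=st.floats(-50, 50, allow_nan=False),
           c_hb=st.floats(-5, 5), c_hbo2=st.floats(-5, 5))
    def test_linearity(self, eps, path, alpha, c_hb, c_hbo2):
        design = _design(eps, path)
        da = design @ np.array([[c_hb], [c_hbo2]])
        base = solve_concentrations(
            AttenuationSeries(time=np.zeros(1), delta_a=da), eps, path)
        scaled = solve_concentrations(
            AttenuationSeries(time=np.zeros(1), delta_a=alpha * da), eps, path)
        assert scaled.dc_hb[0] == pytest.approx(alpha * base.dc_hb[0], abs=1e-8)
        assert scaled.dc_hbo2[0] == pytest.approx(alpha * base.dc_hbo2[0], abs=1e-8)

    def test_rank_deficient_design_rejected(self, path):
        # proportional columns -> unsolvable chromophore separation
        eps_bad = ExtinctionTable.__new__(ExtinctionTable)
        object.__setattr__(eps_bad, "wavelengths", np.array(DEVICE_WAVELENGTHS))
        object.__setattr__(eps_bad, "eps_hb", np.array([1.0, 1.0, 1.0]))
        object.__setattr__(eps_bad, "eps_hbo2", np.array([2.0, 2.0, 2.0]))
        att = AttenuationSeries(time=np.zeros(1), delta_a=np.ones((3, 1)))
        with pytest.raises(NumericalError, match="cond"):
            solve_concentrations(att, eps_bad, path)


class TestDeriveOxyBv:
    @pytest.mark.parametrize("hbo2, hb, oxy, bv", [
        (2.0, 1.0, 1.0, 3.0),
        (0.0, 0.0, 0.0, 0.0),
        (-1.0, 1.0, -2.0, 0.0),
    ])
    def test_examples(self, hbo2, hb, oxy, bv):
        conc = ConcentrationSeries(time=np.zeros(1), dc_hb=np.array([hb]),
                                   dc_hbo2=np.array([hbo2]))
        out = derive_oxy_bv(conc)
        assert out.d_oxy[0] == oxy and out.d_bv[0] == bv

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(hb=st.floats(-10, 10), hbo2=st.floats(-10, 10))
    def test_identities(self, hb, hbo2):
        out = derive_oxy_bv(ConcentrationSeries(
            time=np.zeros(1), dc_hb=np.array([hb]), dc_hbo2=np.array([hbo2])))
        assert out.d_oxy[0] + out.d_bv[0] == pytest.approx(2 * hbo2, abs=1e-12)
        assert out.d_bv[0] - out.d_oxy[0] == pytest.approx(2 * hb, abs=1e-12)


class TestExtinctionTable:
    def test_isosbestic_proximity(self, eps):
        rel = {}
        for w in DEVICE_WAVELENGTHS:
            hb, hbo2 = eps.eps_at(w)
            rel[w] = abs(hb - hbo2) / hbo2
        assert rel[805.0] < 0.10
        assert rel[805.0] < rel[735.0] and rel[805.0] < rel[850.0]

    def test_wrong_isosbestic_rejected(self):
        with pytest.raises(ValidationError, match="isosbestic"):
            ExtinctionTable(wavelengths=np.array(DEVICE_WAVELENGTHS),
                            eps_hb=np.array([1.0, 2.0, 0.7]),
                            eps_hbo2=np.array([1.0, 1.0, 1.0]))
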