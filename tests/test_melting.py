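"""State classification, two-state fits, and concentration transforms."""

import math

import numpy as np
import pandas as pd
import pytest

from cgdnafold.melting import (
    FitError,
    MeltFit,
    classify_states,
    concentration_transform,
    denatured_fraction_curve,
    fit_two_state,
    tm_at_concentration,
)
from cgdnafold.sampler import Trajectory


def _toy_trajectory(per_t_partners, temperatures, n_res=4):
    """Build a minimal Trajectory from per-temperature partner frames."""
    rows = []
    partners = []
    for block, (t, frames) in enumerate(zip(temperatures, per_t_partners)):
        for k, p in enumerate(frames):
            n_pairs = sum(1 for r in range(n_res) if p[r] > r)
            rows.append((block, k, t, *([0.0] * 9), n_pairs))
            partners.append(p)
    frames = pd.DataFrame(
        rows, columns=["block", "sweep", "temperature_c",
                       "U_b", "U_a", "U_d", "U_exc", "U_bp", "U_bs", "U_cs",
                       "U_el", "U_total", "n_pairs"])
    return Trajectory(frames=frames, partners=np.array(partners, dtype=np.int16),
                      seed=0, final_system=None)


FOLDED = [3, 2, 1, 0]
HALF = [3, -1, -1, 0]      # 1 of 2 native pairs: U by the <=1-pair rule
NONE = [-1, -1, -1, -1]


class TestClassification:
    def test_all_native_frames_are_folded(self):
        traj = _toy_trajectory([[FOLDED] * 10], [40.0])
        out = classify_states(traj, np.array(FOLDED), burnin_fraction=0.0)
        assert out["f_F"].iloc[0] == 1.0
        assert out["f_U"].iloc[0] == 0.0

    def test_zero_or_one_pair_is_unfolded(self):
        traj = _toy_trajectory([[NONE] * 5 + [HALF] * 5], [80.0])
        out = classify_states(traj, np.array(FOLDED), burnin_fraction=0.0)
        assert out["f_U"].iloc[0] == 1.0

    def test_half_native_stem_is_intermediate(self):
        # 3 of 4 reference pairs needs a 6-residue reference
        ref = np.array([5, 4, 3, 2, 1, 0])
        part = np.array([5, 4, -1, -1, 1, 0], dtype=np.int16)  # 2 of 3 pairs
        traj = _toy_trajectory([[list(part)] * 8], [60.0], n_res=6)
        out = classify_states(traj, ref, burnin_fraction=0.0)
        assert out["f_I"].iloc[0] == 1.0

    def test_partition_sums_to_one(self):
        frames = [[FOLDED] * 4 + [HALF] * 3 + [NONE] * 3]
        traj = _toy_trajectory(frames, [55.0])
        out = classify_states(traj, np.array(FOLDED), burnin_fraction=0.0)
        assert out[["f_F", "f_I", "f_U"]].sum(axis=1).iloc[0] == pytest.approx(1.0)

    def test_burnin_discarded(self):
        traj = _toy_trajectory([[NONE] * 5 + [FOLDED] * 5], [30.0])
        out = classify_states(traj, np.array(FOLDED), burnin_fraction=0.5)
        assert out["f_F"].iloc[0] == 1.0

    def test_insufficient_frames_error(self):
        from cgdnafold.melting import InsufficientSamplingError

        traj = _toy_trajectory([[FOLDED] * 3], [30.0])
        with pytest.raises(InsufficientSamplingError):
            classify_states(traj, np.array(FOLDED), min_frames=5)


def _logistic_fractions(tms, dts, temps, n=10000, rng=None):
    f_f = 1.0 / (1.0 + np.exp((temps - tms) / dts))
    if rng is not None:
        f_f = rng.binomial(n, f_f) / n
    return pd.DataFrame({
        "temperature_c": temps,
        "f_F": f_f,
        "f_U": 1.0 - f_f,
        "f_I": 0.0,
        "f_bp": 1.0 - f_f,
        "n_frames": n,
    })


class TestTwoStateFit:
    def test_recovers_noiseless_parameters(self):
        temps = np.linspace(40, 80, 15)
        data = _logistic_fractions(60.0, 3.0, temps)
        fit = fit_two_state(data)
        assert fit.tm1 == pytest.approx(60.0, abs=0.1)
        assert fit.dt1 == pytest.approx(3.0, abs=0.05)
        assert fit.f_i == 0.0

    def test_recovery_under_binomial_noise(self):
        """With 200 frames/temperature the fitted Tm stays within 1 C in
        at least 95% of replicates (simulation-study oracle)."""
        temps = np.linspace(45, 75, 13)
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            data = _logistic_fractions(60.0, 3.0, temps, n=200, rng=rng)
            fit = fit_two_state(data)
            hits += abs(fit.tm1 - 60.0) <= 1.0
        assert hits / n_rep >= 0.95

    def test_constant_half_flagged_degenerate(self):
        temps = np.linspace(40, 80, 9)
        data = pd.DataFrame({
            "temperature_c": temps, "f_F": 0.5, "f_U": 0.5,
            "f_I": 0.0, "f_bp": 0.5, "n_frames": 100})
        fit = fit_two_state(data)
        assert fit.degenerate

    def test_too_few_temperatures_rejected(self):
        temps = np.linspace(40, 80, 4)
        with pytest.raises(FitError):
            fit_two_state(_logistic_fractions(60.0, 3.0, temps))


class TestDenaturedFraction:
    def test_reduces_to_one_minus_ff_without_intermediate(self):
        fit = MeltFit(tm1=60.0, dt1=3.0, tm2=60.0, dt2=3.0, f_i=0.0)
        t = np.linspace(30, 90, 50)
        f, _ = denatured_fraction_curve(fit, t)
        ff = 1.0 / (1.0 + np.exp((t - 60.0) / 3.0))
        np.testing.assert_allclose(f, 1.0 - ff, rtol=1e-12)

    def test_logistic_limits(self):
        fit = MeltFit(tm1=50.0, dt1=4.0, tm2=70.0, dt2=4.0, f_i=0.4)
        f, _ = denatured_fraction_curve(fit, np.array([-1000.0, 1000.0]))
        assert f[0] == pytest.approx(0.0, abs=1e-12)
        assert f[1] == pytest.approx(1.0, abs=1e-12)

    def test_two_transition_derivative_has_two_peaks(self):
        fit = MeltFit(tm1=45.0, dt1=2.0, tm2=75.0, dt2=2.0, f_i=0.5)
        t = np.linspace(20, 100, 2001)
        _, df = denatured_fraction_curve(fit, t)
        peaks = [t[i] for i in range(1, len(t) - 1)
                 if df[i] > df[i - 1] and df[i] > df[i + 1]]
        assert len(peaks) == 2
        assert peaks[0] == pytest.approx(45.0, abs=0.5)
        assert peaks[1] == pytest.approx(75.0, abs=0.5)

    def test_mid_plateau_at_f_i(self):
        fit = MeltFit(tm1=40.0, dt1=1.5, tm2=90.0, dt2=1.5, f_i=0.35)
        f, _ = denatured_fraction_curve(fit, np.array([65.0]))
        assert f[0] == pytest.approx(0.35, abs=1e-6)


class TestConcentrationTransform:
    def test_identity_at_lambda_one(self):
        f = np.linspace(0, 1, 11)
        np.testing.assert_allclose(concentration_transform(f, 1.0), f)

    def test_fixed_points(self):
        for lam in (1.0, 3.0, 10.0):
            assert concentration_transform(0.0, lam) == 0.0
            assert concentration_transform(1.0, lam) == 1.0

    def test_direct_evaluation(self):
        assert concentration_transform(0.5, 10.0) == pytest.approx(10.0 / 11.0)

    def test_monotone_in_f_and_lambda(self):
        f = np.linspace(0.01, 0.99, 30)
        g1 = concentration_transform(f, 2.0)
        g2 = concentration_transform(f, 8.0)
        assert np.all(np.diff(g1) > 0)
        assert np.all(g2 > g1)

    def test_composition_is_product(self):
        f = np.linspace(0.05, 0.95, 12)
        ab = concentration_transform(concentration_transform(f, 2.5), 4.0)
        np.testing.assert_allclose(ab, concentration_transform(f, 10.0),
                                   rtol=1e-12)

    def test_dilution_only(self):
        with pytest.raises(ValueError):
            concentration_transform(0.5, 0.5)
        with pytest.raises(ValueError):
            tm_at_concentration(60.0, 3.0, 0.9)

    def test_preserves_unit_interval(self):
        f = np.linspace(0, 1, 101)
        g = concentration_transform(f, 50.0)
        assert np.all((g >= 0) & (g <= 1))


class TestTransformProperties:
    """Property-based checks of the dilution transform."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(f=st.floats(0.0, 1.0), lam=st.floats(1.0, 1e3))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_stays_in_unit_interval_and_grows(self, f, lam):
        g = float(concentration_transform(f, lam))
        assert 0.0 <= g <= 1.0
        assert g >= f - 1e-12      # dilution only denatures further

    @given(f=st.floats(0.001, 0.999), l1=st.floats(1.0, 30.0),
           l2=st.floats(1.0, 30.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_composition_property(self, f, l1, l2):
        a = concentration_transform(concentration_transform(f, l1), l2)
        b = concentration_transform(f, l1 * l2)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-12)


class TestTmShift:
    def test_identity_at_lambda_one(self):
        assert tm_at_concentration(55.0, 3.0, 1.0) == 55.0

    def test_closed_form_shift(self):
        shift = tm_at_concentration(60.0, 3.0, 10.0) - 60.0
        assert shift == pytest.approx(-3.0 * math.log(10.0), rel=1e-12)
        assert shift == pytest.approx(-6.91, abs=0.01)

    def test_consistency_with_transformed_curve_refit(self):
        """Internal-consistency oracle: refitting the lambda-transformed
        melting curve reproduces the closed-form Tm shift."""
        from scipy.optimize import curve_fit

        tm, dt, lam = 62.0, 3.5, 8.0
        t = np.linspace(35, 90, 200)
        f = 1.0 - 1.0 / (1.0 + np.exp((t - tm) / dt))
        f_lo = concentration_transform(f, lam)
        # refit the folded fraction at the lower concentration
        def ff(tt, tm_, dt_):
            return 1.0 / (1.0 + np.exp((tt - tm_) / dt_))

        popt, _ = curve_fit(ff, t, 1.0 - f_lo, p0=[60.0, 3.0])
        expected = tm_at_concentration(tm, dt, lam)
        assert popt[0] == pytest.approx(expected, abs=0.35)
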