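"""Melting-curve analysis: state classification, two-state fits, and
strand-concentration transforms.

Frames sampled at each ladder temperature are classified as folded (F:
secondary structure consistent with the lowest-temperature prediction,
operationalised as >= 80% of the reference base pairs present), unfolded
(U: at most one base pair) or intermediate (I: anything else).  The
folded/unfolded fractions follow logistic temperature profiles

    f_F(T) = 1 / (1 + exp((T - Tm1)/dT1))
    f_U(T) = 1 / (1 + exp((T - Tm2)/dT2))

whose midpoints are the melting temperatures of the two transitions
(F -> I and I -> U); without an intermediate only one Tm exists and the
denatured-base-pair fraction is f(T) = 1 - f_F(T).

For bimolecular (duplex) systems simulated at a high strand
concentration c_s_h, the curve at a lower concentration c_s follows from
the dilution transform with lambda = c_s_h / c_s:

    f(T; c_s) = lambda f / (1 + (lambda - 1) f),
    Tm(c_s)   = Tm(c_s_h) - dT1 ln(lambda).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .sampler import Trajectory

__all__ = [
    "MeltFit",
    "FitError",
    "InsufficientSamplingError",
    "classify_states",
    "fit_two_state",
    "denatured_fraction_curve",
    "concentration_transform",
    "tm_at_concentration",
]


class InsufficientSamplingError(RuntimeError):
    """Too few equilibrium frames at some ladder temperature."""


class FitError(RuntimeError):
    """Two-state fit failed; carries the per-temperature residual table."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


@dataclass
class MeltFit:
    """Fitted two-state (optionally three-state) melting parameters."""

    tm1: float                    # deg C
    dt1: float
    tm2: float | None = None
    dt2: float | None = None
    f_i: float = 0.0              # denatured-bp fraction at the I maximum
    table: pd.DataFrame | None = None
    cov1: np.ndarray | None = None
    cov2: np.ndarray | None = None
    degenerate: bool = False

    @property
    def tm(self) -> float:
        """Single melting temperature (two-state systems)."""
        return self.tm1


def _frame_native_fraction(partners: np.ndarray, ref_pairs: list) -> np.ndarray:
    """Per-frame fraction of reference pairs present."""
    if not ref_pairs:
        return np.zeros(len(partners))
    hits = np.zeros(len(partners))
    for (i, j) in ref_pairs:
        hits += partners[:, i] == j
    return hits / len(ref_pairs)


def reference_pairs_from_partner(partner: np.ndarray) -> list:
    return [(int(r), int(partner[r])) for r in range(len(partner))
            if partner[r] > r]


def classify_states(trajectory: Trajectory, reference_partner: np.ndarray,
                    burnin_fraction: float = 0.5,
                    folded_fraction: float = 0.8,
                    min_frames: int = 5) -> pd.DataFrame:
    """Per-temperature state fractions (f_F, f_I, f_U) over equilibrium frames.

    The first ``burnin_fraction`` of each temperature block is discarded.
    Also reports the mean denatured-base-pair fraction ``f_bp`` used to
    locate f_I.  The three fractions always partition (sum to 1).
    """
    ref_pairs = reference_pairs_from_partner(np.asarray(reference_partner))
    frames = trajectory.frames
    partners = trajectory.partners
    rows = []
    for block, sub in frames.groupby("block"):
        idx = sub.index.to_numpy()
        keep = idx[int(math.floor(len(idx) * burnin_fraction)):]
        if len(keep) < min_frames:
            raise InsufficientSamplingError(
                f"only {len(keep)} equilibrium frames in block {block}")
        part = partners[keep]
        n_pairs = frames.loc[keep, "n_pairs"].to_numpy()
        native = _frame_native_fraction(part, ref_pairs)
        is_f = native >= folded_fraction
        is_u = (n_pairs <= 1) & ~is_f
        f_f = float(np.mean(is_f))
        f_u = float(np.mean(is_u))
        # denatured-bp fraction from the pair count (the experimental
        # melting observable is register-agnostic hypochromicity)
        ratio = np.clip(n_pairs / max(len(ref_pairs), 1), 0.0, 1.0)
        rows.append({
            "temperature_c": float(sub["temperature_c"].iloc[0]),
            "f_F": f_f,
            "f_U": f_u,
            "f_I": 1.0 - f_f - f_u,
            "f_bp": float(np.mean(1.0 - ratio)),
            "n_frames": len(keep),
        })
    return pd.DataFrame(rows).sort_values("temperature_c").reset_index(drop=True)


def _logistic(t, tm, dt):
    return 1.0 / (1.0 + np.exp(np.clip((t - tm) / dt, -500, 500)))


def _fit_logistic(t, f, n, label):
    if np.ptp(f) < 0.2:
        return None, None     # no transition covered
    sigma = np.sqrt(np.clip(f * (1.0 - f), 0.25 / np.asarray(n), None)
                    / np.asarray(n))
    tm0 = float(t[np.argmin(np.abs(f - 0.5))])
    try:
        popt, pcov = curve_fit(
            _logistic, t, f, p0=[tm0, 3.0], sigma=sigma,
            absolute_sigma=False, maxfev=20000,
            bounds=([t.min() - 50.0, 0.5], [t.max() + 50.0, 45.0]))
    except RuntimeError as exc:
        resid = pd.DataFrame({"temperature_c": t, label: f})
        raise FitError(f"logistic fit of {label} failed: {exc}", resid)
    return popt, pcov


def _isotonic_crossing(t, f, w, level):
    """Temperature where the isotonic (monotone non-decreasing)
    regression of f(T) crosses ``level``, by linear interpolation."""
    from scipy.optimize import isotonic_regression

    iso = isotonic_regression(np.asarray(f, dtype=float),
                              weights=np.asarray(w, dtype=float)).x
    above = np.nonzero(iso >= level)[0]
    if len(above) == 0:
        return float(t[-1])
    i = int(above[0])
    if i == 0:
        return float(t[0])
    f0, f1 = iso[i - 1], iso[i]
    if f1 <= f0:
        return float(0.5 * (t[i - 1] + t[i]))
    return float(t[i - 1] + (level - f0) / (f1 - f0) * (t[i] - t[i - 1]))


def fit_two_state(fractions: pd.DataFrame,
                  intermediate_threshold: float = 0.5) -> MeltFit:
    """Two-state melting fit of the denatured-base-pair fraction f(T).

    The melting temperature is the half-denaturation point: the 0.5
    crossing of the isotonic (monotone) regression of f(T) — a robust
    median-type statistic.  The transition width dT then comes from a
    weighted logistic fit (1 - f_F form, Tm fixed); with an intermediate
    (I-state fraction peaking above ``intermediate_threshold``) the two
    transitions cross f_I/2 and (1+f_I)/2 and the two-logistic
    combination supplies the widths.  Weights are binomial standard
    errors.  A curve with no visible transition is flagged degenerate.
    """
    if len(fractions) < 5:
        raise FitError("need at least 5 ladder temperatures spanning the "
                       "transition", fractions)
    t = fractions["temperature_c"].to_numpy(dtype=float)
    n = fractions["n_frames"].to_numpy(dtype=float)
    f_bp = fractions["f_bp"].to_numpy(dtype=float)
    if np.ptp(f_bp) < 0.2:
        # no transition inside the window: the crossing is a ladder-edge
        # bound, reported but flagged degenerate
        return MeltFit(tm1=_isotonic_crossing(t, f_bp, n, 0.5),
                       dt1=float("nan"), table=fractions, degenerate=True)
    popt_f, pcov_f = _fit_logistic(t, fractions["f_F"].to_numpy(), n, "f_F")
    popt_u, pcov_u = _fit_logistic(t, fractions["f_U"].to_numpy(), n, "f_U")

    i_peak = int(np.argmax(fractions["f_I"].to_numpy()))
    has_intermediate = float(fractions["f_I"].iloc[i_peak]) > intermediate_threshold
    sigma = np.sqrt(np.clip(f_bp * (1.0 - f_bp), 0.04, None) / n)
    tm0 = float(t[np.argmin(np.abs(f_bp - 0.5))])

    if not has_intermediate:
        tm = _isotonic_crossing(t, f_bp, n, 0.5)

        def model(tt, dt):
            return 1.0 - _logistic(tt, tm, dt)

        try:
            popt, pcov = curve_fit(model, t, f_bp, p0=[5.0], sigma=sigma,
                                   maxfev=20000, bounds=([0.5], [45.0]))
        except RuntimeError as exc:
            raise FitError(f"two-state fit failed: {exc}", fractions)
        return MeltFit(tm1=tm, dt1=float(popt[0]),
                       tm2=tm, dt2=float(popt[0]),
                       f_i=0.0, table=fractions, cov1=pcov, cov2=pcov_u)

    # two transitions: f = 1 - [fI fF(Tm1) + (1-fI) fU(Tm2)]
    f_i = float(np.clip(fractions["f_bp"].iloc[i_peak], 0.05, 0.95))
    tm1 = _isotonic_crossing(t, f_bp, n, f_i / 2.0)
    tm2 = _isotonic_crossing(t, f_bp, n, (1.0 + f_i) / 2.0)
    if tm2 < tm1:
        tm1, tm2 = tm2, tm1

    def model2(tt, dt1, dt2):
        return 1.0 - (f_i * _logistic(tt, tm1, dt1)
                      + (1.0 - f_i) * _logistic(tt, tm2, dt2))

    try:
        popt, pcov = curve_fit(model2, t, f_bp, p0=[4.0, 4.0], sigma=sigma,
                               maxfev=40000,
                               bounds=([0.5, 0.5], [45.0, 45.0]))
    except RuntimeError as exc:
        raise FitError(f"three-state fit failed: {exc}", fractions)
    return MeltFit(tm1=tm1, dt1=float(popt[0]), tm2=tm2, dt2=float(popt[1]),
                   f_i=f_i, table=fractions, cov1=pcov, cov2=pcov_u)


def denatured_fraction_curve(fit: MeltFit, t_grid: np.ndarray):
    """Denatured-base-pair fraction f(T) and its analytic derivative df/dT.

    With no intermediate (f_I = 0) this is f = 1 - f_F.  With an
    intermediate, the two logistic transitions combine so that f rises
    from 0 through a plateau at f_I (around the I-state maximum, between
    Tm1 and Tm2) to 1.
    """
    t = np.asarray(t_grid, dtype=float)
    ff = _logistic(t, fit.tm1, fit.dt1)
    dff = -ff * (1.0 - ff) / fit.dt1
    if fit.f_i == 0.0 or fit.tm2 is None:
        return 1.0 - ff, -dff
    fu = _logistic(t, fit.tm2, fit.dt2)
    dfu = -fu * (1.0 - fu) / fit.dt2
    f = 1.0 - (fit.f_i * ff + (1.0 - fit.f_i) * fu)
    dfdt = -(fit.f_i * dff + (1.0 - fit.f_i) * dfu)
    return f, dfdt


def concentration_transform(f, lam: float):
    """Dilution transform of the denatured fraction (lambda = c_s_h/c_s >= 1)."""
    if lam < 1.0:
        raise ValueError("transform is derived for dilution (lambda >= 1)")
    f = np.asarray(f, dtype=float)
    if np.any(f < 0.0) or np.any(f > 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    return lam * f / (1.0 + (lam - 1.0) * f)


def tm_at_concentration(tm_high: float, dt1: float, lam: float) -> float:
    """Closed-form melting-temperature shift under dilution:
    Tm(c_s) = Tm(c_s_h) - dT1 ln(lambda)."""
    if lam < 1.0:
        raise ValueError("transform is derived for dilution (lambda >= 1)")
    return tm_high - dt1 * math.log(lam)
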