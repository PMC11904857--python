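"""Sodium-current analysis: peak extraction, I-V, conductance transform,
and Boltzmann fits of steady-state activation and inactivation.

Conventions (documented choices where the measurement protocol leaves them
open):

* inward current is negative; peaks are the signed extremum of largest
  magnitude inside the step window after baseline correction;
* baseline = mean of the final 5 ms of the pre-step window, per sweep;
* the reversal potential is interpolated from the I-V zero crossing unless
  supplied by the caller;
* voltages within +/-2.5 mV of the reversal potential (half the standard
  5 mV increment) are excluded from the conductance transform;
* the activation fit uses the ascending Boltzmann 1/(1+exp((V1/2-V)/k)),
  the inactivation (availability) fit the descending form
  1/(1+exp((V-V1/2)/k)); k > 0 in both.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .errors import DegenerateDataError, FitFailureError, NoReversalError
from .records import BoltzmannFit, GVCurve, IVCurve, SweepFamily

__all__ = [
    "smooth_family",
    "peak_currents",
    "estimate_reversal",
    "conductance_curve",
    "fit_boltzmann_activation",
    "availability_curve",
    "fit_boltzmann_inactivation",
    "peak_density",
    "analyze_na_family",
    "analyze_inact_family",
]

BASELINE_MS = 5.0
VREV_EXCLUSION_MV = 2.5
K_BOUNDS = (0.5, 30.0)


def smooth_family(family: SweepFamily, cutoff_khz: float = 5.0) -> SweepFamily:
    """Instrument-style low-pass: Savitzky-Golay smoothing of every sweep.

    The window is sized so the effective bandwidth roughly matches a
    ``cutoff_khz`` analog filter at the family's sampling rate.  Applied by
    the analysis wrappers before peak extraction so that the max-|I| peak
    pick is not dominated by the most extreme white-noise sample.
    """
    fs = family.protocol.sampling_rate
    window = max(5, 2 * int(round(fs / cutoff_khz)) + 1)
    window = min(window, family.sweeps.shape[0]
                 if family.sweeps.shape[0] % 2 else family.sweeps.shape[0] - 1)
    smoothed = savgol_filter(family.sweeps, window_length=window, polyorder=2,
                             axis=0)
    return SweepFamily(time_ms=family.time_ms, sweeps=smoothed,
                       step_voltages=family.step_voltages,
                       capacitance=family.capacitance,
                       protocol=family.protocol, step_onset=family.step_onset,
                       meta=family.meta)


def _baseline_correct(family: SweepFamily) -> np.ndarray:
    t = family.time_ms
    lo = max(family.step_onset - BASELINE_MS, t[0])
    pre = (t >= lo) & (t < family.step_onset)
    if not pre.any():
        return family.sweeps
    return family.sweeps - family.sweeps[pre].mean(axis=0)


def peak_currents(family: SweepFamily) -> IVCurve:
    """Signed peak current per sweep within the step window (pA)."""
    t = family.time_ms
    lo, hi = family.step_window
    sel = (t >= lo) & (t <= hi)
    if not sel.any():
        raise DegenerateDataError("empty step window")
    corrected = _baseline_correct(family)[sel]
    idx = np.argmax(np.abs(corrected), axis=0)
    peaks = corrected[idx, np.arange(corrected.shape[1])]
    return IVCurve(voltages=family.step_voltages, peak_current=peaks,
                   capacitance=family.capacitance)


def estimate_reversal(iv: IVCurve, extrapolate: bool = False,
                      max_extrapolation_mv: float = 15.0) -> float:
    """Reversal potential from the zero crossing of the positive limb (mV).

    Searches voltages above the current-density minimum for the first
    negative-to-nonnegative sign change and linearly interpolates.  With
    ``extrapolate=True`` a curve whose rising positive limb stops short of
    zero is extended linearly through its last two points, provided the
    projected crossing lies within ``max_extrapolation_mv`` of the last
    tested voltage (the step protocol may end just below the reversal).
    """
    i = iv.peak_current
    start = int(np.argmin(i))
    for j in range(start, i.size - 1):
        if i[j] < 0.0 <= i[j + 1]:
            v0, v1 = iv.voltages[j], iv.voltages[j + 1]
            if i[j + 1] == i[j]:
                return float(v0)
            return float(v0 - i[j] * (v1 - v0) / (i[j + 1] - i[j]))
    if extrapolate and i.size >= 2:
        i0, i1 = i[-2], i[-1]
        v0, v1 = iv.voltages[-2], iv.voltages[-1]
        if i1 > i0 and i1 < 0:  # rising limb still below zero
            v_rev = v1 - i1 * (v1 - v0) / (i1 - i0)
            if v_rev <= v1 + max_extrapolation_mv:
                return float(v_rev)
    raise NoReversalError("I-V curve has no zero crossing on its "
                          "positive-voltage limb")


def conductance_curve(iv: IVCurve, v_rev: float) -> GVCurve:
    """Chord-conductance transform G = I/(V - V_rev), in nS.

    Voltages within +/-2.5 mV of ``v_rev`` are excluded (recorded in
    ``excluded_voltages``).  ``normalized`` is G / max(G).
    """
    keep = np.abs(iv.voltages - v_rev) >= VREV_EXCLUSION_MV
    v = iv.voltages[keep]
    g = iv.peak_current[keep] / (v - v_rev)  # pA/mV == nS
    gmax = g.max() if g.size else 0.0
    if gmax <= 0:
        raise DegenerateDataError("all-zero conductance; cannot normalize")
    return GVCurve(voltages=v, conductance=g, normalized=g / gmax,
                   excluded_voltages=iv.voltages[~keep], kind="activation")


def _boltzmann_asc(v, v_half, k):
    return 1.0 / (1.0 + np.exp((v_half - v) / k))


def _boltzmann_desc(v, v_half, k):
    return 1.0 / (1.0 + np.exp((v - v_half) / k))


def _init_v_half(v: np.ndarray, y: np.ndarray, descending: bool) -> float:
    """Deterministic initializer: voltage at half-maximum by interpolation."""
    yy = y[::-1] if descending else y
    vv = v[::-1] if descending else v
    above = yy >= 0.5
    if above.all() or not above.any():
        return float(v[np.argmin(np.abs(y - 0.5))])
    j = int(np.argmax(above))  # first index at/above half
    if j == 0:
        return float(vv[0])
    y0, y1 = yy[j - 1], yy[j]
    v0, v1 = vv[j - 1], vv[j]
    if y1 == y0:
        return float(v0)
    return float(v0 + (0.5 - y0) * (v1 - v0) / (y1 - y0))


def _fit(v: np.ndarray, y: np.ndarray, descending: bool,
         free_amplitude: bool, sigma: np.ndarray | None = None
         ) -> BoltzmannFit:
    v = np.asarray(v, dtype=float)
    y = np.asarray(y, dtype=float)
    if v.size < 6:
        raise FitFailureError("need >= 6 points spanning the transition")
    base = _boltzmann_desc if descending else _boltzmann_asc
    p0 = [_init_v_half(v, y, descending), 6.0]
    lo = [v.min() - 100.0, K_BOUNDS[0]]
    hi = [v.max() + 100.0, K_BOUNDS[1]]
    if free_amplitude:
        model = lambda vv, vh, k, a: a * base(vv, vh, k)  # noqa: E731
        p0, lo, hi = p0 + [max(y.max(), 1e-6)], lo + [1e-6], hi + [10.0 * max(y.max(), 1.0)]
    else:
        model = base
    try:
        popt, _ = curve_fit(model, v, y, p0=p0, bounds=(lo, hi),
                            sigma=sigma, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"Boltzmann fit failed: {exc}") from exc
    resid = y - model(v, *popt)
    return BoltzmannFit(
        v_half=float(popt[0]), k=float(popt[1]),
        direction="inactivation" if descending else "activation",
        rss=float(np.sum(resid ** 2)), n_points=int(v.size),
        g_max=float(popt[2]) if free_amplitude else 1.0)


def fit_boltzmann_activation(gv: GVCurve, free_amplitude: bool = False,
                             sigma: np.ndarray | None = None) -> BoltzmannFit:
    """Least-squares ascending Boltzmann fit of the normalized G-V curve.

    ``sigma`` optionally carries per-point uncertainties (e.g. inverse
    driving force, since chord-conductance noise scales with
    1/|V - V_rev|).
    """
    return _fit(gv.voltages, gv.normalized, descending=False,
                free_amplitude=free_amplitude, sigma=sigma)


def availability_curve(family: SweepFamily) -> GVCurve:
    """Normalized test-pulse peak magnitude versus prepulse voltage."""
    iv = peak_currents(family)
    mag = np.abs(iv.peak_current)
    top = mag.max()
    if top <= 0:
        raise DegenerateDataError("all test-pulse peaks are zero")
    return GVCurve(voltages=iv.voltages, conductance=mag / top,
                   normalized=mag / top, kind="availability")


def fit_boltzmann_inactivation(avail: GVCurve, free_amplitude: bool = False,
                               sigma: np.ndarray | None = None
                               ) -> BoltzmannFit:
    """Least-squares descending Boltzmann fit of the availability curve."""
    return _fit(avail.voltages, avail.normalized, descending=True,
                free_amplitude=free_amplitude, sigma=sigma)


def peak_density(iv: IVCurve) -> float:
    """Signed current density of maximal magnitude (pA/pF)."""
    d = iv.density
    if d.size == 0:
        raise DegenerateDataError("empty I-V curve")
    return float(d[np.argmax(np.abs(d))])


def analyze_na_family(family: SweepFamily, v_rev: float | None = None,
                      smooth: bool = True) -> dict:
    """Full activation-side analysis of one cell's step family.

    The family is low-pass smoothed (instrument-style) before peak
    extraction; the Boltzmann fit runs with a free amplitude and
    driving-force weights, both of which de-sensitize the fitted midpoint
    to the noise amplification of the conductance transform near the
    reversal potential.  Returns a flat dict: v_rev_est, peak_density,
    v_half_act, k_act, rss_act.
    """
    if smooth:
        family = smooth_family(family)
    iv = peak_currents(family)
    if v_rev is None:
        v_rev_est = estimate_reversal(iv, extrapolate=True)
    else:
        v_rev_est = float(v_rev)
    gv = conductance_curve(iv, v_rev_est)
    sigma = 1.0 / np.abs(gv.voltages - v_rev_est)
    fit = fit_boltzmann_activation(gv, free_amplitude=True, sigma=sigma)
    return {"v_rev_est": v_rev_est, "peak_density": peak_density(iv),
            "v_half_act": fit.v_half, "k_act": fit.k, "rss_act": fit.rss}


def analyze_inact_family(family: SweepFamily, smooth: bool = True) -> dict:
    """Availability analysis of one cell's two-pulse family."""
    if smooth:
        family = smooth_family(family)
    avail = availability_curve(family)
    fit = fit_boltzmann_inactivation(avail)
    return {"v_half_inact": fit.v_half, "k_inact": fit.k,
            "rss_inact": fit.rss}
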