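"""Action-potential parameter extraction from paced current-clamp traces.

Per beat: resting potential is the mean of the 50 ms pre-stimulus window;
APA = peak - resting; upstroke velocity is the maximum of a Savitzky-Golay
smoothed dV/dt on the rising phase; depolarization time runs from stimulus
onset to the peak; APDx runs from the max-dV/dt instant to the linearly
interpolated downward crossing of (peak - x% * APA).  Parameters (not
traces) are averaged across accepted beats.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .errors import NoAPError
from .records import APParams, VoltageTrace

__all__ = ["ap_parameters"]

REST_WINDOW_MS = 50.0
MIN_PEAK_ABOVE_REST_MV = 10.0
APD_LEVELS = (30, 50, 90)


def _crossing_time(t: np.ndarray, v: np.ndarray, level: float,
                   start: int) -> float | None:
    """First downward crossing of ``level`` at/after index ``start``."""
    for i in range(start, v.size - 1):
        if v[i] >= level > v[i + 1]:
            frac = (v[i] - level) / (v[i] - v[i + 1])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    return None


def _beat_params(t: np.ndarray, v: np.ndarray, dvdt: np.ndarray,
                 stim: float, win_end: float) -> dict | None:
    pre = (t >= stim - REST_WINDOW_MS) & (t < stim)
    if not pre.any():
        return None
    rest = float(v[pre].mean())

    sel = np.flatnonzero((t >= stim) & (t < win_end))
    if sel.size < 3:
        return None
    i_peak = sel[np.argmax(v[sel])]
    peak = float(v[i_peak])
    if peak < rest + MIN_PEAK_ABOVE_REST_MV:
        return None
    apa = peak - rest

    rise = np.arange(sel[0], i_peak + 1)
    if rise.size < 2:
        return None
    # earliest sample within float tolerance of the max keeps the choice
    # deterministic on uniform-slope (triangle-like) upstrokes
    d = dvdt[rise]
    top = d.max()
    i_up = rise[np.flatnonzero(d >= top - 1e-9 * max(abs(top), 1.0))[0]]

    out = {"apa": apa, "resting_potential": rest,
           "upstroke_velocity": float(dvdt[i_up]),
           "depolarization_time": float(t[i_peak] - stim)}
    t_up = float(t[i_up])
    for x in APD_LEVELS:
        level = peak - (x / 100.0) * apa
        tc = _crossing_time(t, v, level, i_peak)
        if tc is None or tc >= win_end:
            return None  # incomplete repolarization inside the beat window
        out[f"apd{x}"] = tc - t_up
    return out


def ap_parameters(trace: VoltageTrace, sg_window: int = 5) -> APParams:
    """Extract per-cell AP parameters, averaged across accepted beats.

    Beats lacking a peak 10 mV above rest, or failing to repolarize through
    all APD levels before the next stimulus, are rejected (counted in
    ``rejected_beats``).  Raises :class:`NoAPError` if every beat fails.
    """
    if trace.stimulus_times.size == 0:
        raise NoAPError("trace has no stimulus markers")
    t, v = trace.time_ms, trace.voltage_mv
    dt = float(t[1] - t[0])
    win = min(sg_window, v.size if v.size % 2 else v.size - 1)
    dvdt = savgol_filter(v, window_length=max(win, 5), polyorder=2,
                         deriv=1, delta=dt)  # mV/ms == V/s

    stims = np.sort(trace.stimulus_times)
    bounds = np.append(stims[1:], t[-1] + dt)
    beats, rejected = [], 0
    for stim, win_end in zip(stims, bounds):
        b = _beat_params(t, v, dvdt, float(stim), float(win_end))
        if b is None:
            rejected += 1
        else:
            beats.append(b)
    if not beats:
        raise NoAPError(f"all {rejected} beat(s) rejected")

    mean = {k: float(np.mean([b[k] for b in beats])) for k in beats[0]}
    return APParams(apa=mean["apa"], apd30=mean["apd30"],
                    apd50=mean["apd50"], apd90=mean["apd90"],
                    upstroke_velocity=mean["upstroke_velocity"],
                    depolarization_time=mean["depolarization_time"],
                    resting_potential=mean["resting_potential"],
                    n_beats_averaged=len(beats), rejected_beats=rejected)
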