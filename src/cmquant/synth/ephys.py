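"""Generators for voltage-clamp current families and paced action potentials."""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator

from ..errors import InvalidProtocolError
from ..presets import APTargets, GatingPreset, InactProtocol, VClampProtocol
from ..records import SweepFamily, VoltageTrace
from . import gating

__all__ = ["simulate_vclamp_family", "simulate_inactivation_family",
           "simulate_ap_trace"]


def _time_axis(total_ms: float, fs_khz: float) -> np.ndarray:
    n = int(round(total_ms * fs_khz)) + 1
    return np.arange(n) / fs_khz


def simulate_vclamp_family(preset: GatingPreset,
                           protocol: VClampProtocol | None = None,
                           noise_sd: float = 0.0,
                           seed: int | None = None) -> SweepFamily:
    """Simulate the depolarizing-step current family.

    Each sweep holds ``baseline_duration`` ms at the holding potential
    followed by ``step_duration`` ms at the step voltage.  ``noise_sd`` is a
    fraction of the family's global (noiseless) peak magnitude; Gaussian
    noise of that standard deviation is added to every sample.
    """
    protocol = VClampProtocol() if protocol is None else protocol
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    voltages = protocol.step_voltages
    fs = protocol.sampling_rate
    t = _time_axis(protocol.baseline_duration + protocol.step_duration, fs)
    onset = protocol.baseline_duration
    in_step = t >= onset

    m0 = float(gating.m_inf(protocol.holding, preset))
    h0 = float(gating.h_inf(protocol.holding, preset))
    i_hold = gating.steady_current(protocol.holding, preset)

    sweeps = np.empty((t.size, voltages.size))
    for j, v in enumerate(voltages):
        trace = np.full(t.size, i_hold)
        trace[in_step] = gating.step_current(t[in_step] - onset, float(v),
                                             preset, m0, h0)
        sweeps[:, j] = trace

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        scale = noise_sd * np.max(np.abs(sweeps))
        sweeps = sweeps + rng.normal(0.0, scale, size=sweeps.shape)

    return SweepFamily(time_ms=t, sweeps=sweeps, step_voltages=voltages,
                       capacitance=preset.capacitance, protocol=protocol,
                       step_onset=onset,
                       meta={"preset": preset.to_dict(), "noise_sd": noise_sd,
                             "seed": seed, "modality": "na"})


def simulate_inactivation_family(preset: GatingPreset,
                                 protocol: InactProtocol | None = None,
                                 noise_sd: float = 0.0,
                                 seed: int | None = None) -> SweepFamily:
    """Simulate the two-pulse availability family.

    The long prepulse is not sampled; the availability ``h`` at its end is
    computed in closed form and seeds the recorded test-pulse sweep.  Each
    sweep holds ``baseline_duration`` ms of prepulse steady current followed
    by the test step.
    """
    protocol = InactProtocol() if protocol is None else protocol
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    voltages = protocol.prepulse_voltages
    fs = protocol.sampling_rate
    t = _time_axis(protocol.baseline_duration + protocol.test_duration, fs)
    onset = protocol.baseline_duration
    in_step = t >= onset

    h_hold = float(gating.h_inf(protocol.holding, preset))
    sweeps = np.empty((t.size, voltages.size))
    for j, vp in enumerate(voltages):
        h_pre = gating.prepulse_availability(float(vp),
                                             protocol.prepulse_duration,
                                             preset, h_hold)
        m_pre = float(gating.m_inf(float(vp), preset))
        trace = np.full(t.size, preset.g_max * m_pre ** 3 * h_pre
                        * (float(vp) - preset.v_rev))
        trace[in_step] = gating.step_current(
            t[in_step] - onset, protocol.test_voltage, preset, m_pre, h_pre)
        sweeps[:, j] = trace

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        scale = noise_sd * np.max(np.abs(sweeps))
        sweeps = sweeps + rng.normal(0.0, scale, size=sweeps.shape)

    return SweepFamily(time_ms=t, sweeps=sweeps, step_voltages=voltages,
                       capacitance=preset.capacitance, protocol=protocol,
                       step_onset=onset,
                       meta={"preset": preset.to_dict(), "noise_sd": noise_sd,
                             "seed": seed, "modality": "inact"})


def _beat_waveform(rel_t: np.ndarray, targets: APTargets) -> np.ndarray:
    """Voltage of one beat as a function of time since stimulus onset (ms).

    Half-cosine upstroke of duration ``rise_time`` after ``latency``; the
    maximal dV/dt therefore falls exactly at the upstroke midpoint, from
    which the APD anchors are laid out.  Repolarization is a monotone PCHIP
    through the (APDx, repolarization level) anchors down to rest.
    """
    rest = targets.resting_potential
    peak = rest + targets.apa
    t_up0 = targets.latency
    t_peak = t_up0 + targets.rise_time
    t_dvdt = t_up0 + targets.rise_time / 2.0  # max-dV/dt instant

    knots_t = np.array([
        t_peak,
        t_dvdt + targets.apd30,
        t_dvdt + targets.apd50,
        t_dvdt + targets.apd90,
        t_dvdt + targets.apd90 + 0.35 * targets.apd90,
    ])
    knots_v = np.array([
        peak,
        peak - 0.30 * targets.apa,
        peak - 0.50 * targets.apa,
        peak - 0.90 * targets.apa,
        rest,
    ])
    repol = PchipInterpolator(knots_t, knots_v)

    v = np.full(rel_t.shape, rest, dtype=float)
    rising = (rel_t >= t_up0) & (rel_t < t_peak)
    v[rising] = rest + targets.apa * 0.5 * (
        1.0 - np.cos(np.pi * (rel_t[rising] - t_up0) / targets.rise_time))
    falling = (rel_t >= t_peak) & (rel_t <= knots_t[-1])
    v[falling] = repol(rel_t[falling])
    return v


def simulate_ap_trace(targets: APTargets, n_beats: int = 5,
                      pacing_hz: float = 1.0, noise_sd: float = 0.0,
                      seed: int | None = None,
                      sampling_rate: float = 20.0,
                      pre_window: float = 100.0) -> VoltageTrace:
    """Simulate a paced current-clamp recording with known AP parameters.

    ``noise_sd`` is an absolute voltage noise in mV.  The trace starts with
    ``pre_window`` ms of rest before the first stimulus.
    """
    if n_beats < 1:
        raise InvalidProtocolError("n_beats must be >= 1")
    if pacing_hz <= 0 or sampling_rate <= 0:
        raise InvalidProtocolError("pacing_hz and sampling_rate must be > 0")
    period = 1000.0 / pacing_hz
    beat_span = (targets.latency + targets.rise_time / 2.0
                 + 1.35 * targets.apd90)
    if period <= beat_span:
        raise InvalidProtocolError(
            f"pacing period {period:.0f} ms shorter than beat span "
            f"{beat_span:.0f} ms")

    total = pre_window + n_beats * period
    t = _time_axis(total, sampling_rate)
    stim = pre_window + period * np.arange(n_beats)
    v = np.full(t.size, targets.resting_potential, dtype=float)
    for s in stim:
        sel = (t >= s) & (t < s + period)
        v[sel] = _beat_waveform(t[sel] - s, targets)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=v.shape)

    return VoltageTrace(time_ms=t, voltage_mv=v, stimulus_times=stim,
                        sampling_rate=sampling_rate,
                        meta={"targets": targets.to_dict(),
                              "noise_sd": noise_sd, "seed": seed,
                              "pacing_hz": pacing_hz, "modality": "ap"})
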