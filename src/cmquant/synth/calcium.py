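"""Generator for paced ratiometric calcium-transient recordings."""

from __future__ import annotations

import numpy as np

from ..errors import InvalidProtocolError, OverlappingTransientError
from ..presets import TransientTargets
from ..records import FluorescenceTrace

__all__ = ["kernel", "kernel_peak_time", "simulate_calcium_recording"]


def kernel_peak_time(targets: TransientTargets) -> float:
    """Closed-form time of the kernel maximum: tau_rise*ln(1+tau_decay/tau_rise)."""
    return targets.tau_rise * np.log(1.0 + targets.tau_decay / targets.tau_rise)


def kernel(t: np.ndarray, targets: TransientTargets) -> np.ndarray:
    """Normalized rise-times-decay transient kernel, maximum exactly A.

    g(t) = (1 - exp(-t/tau_rise)) * exp(-t/tau_decay) for t >= 0, scaled so
    its maximum equals ``targets.amplitude``.
    """
    t = np.asarray(t, dtype=float)
    g = np.where(t >= 0,
                 (1.0 - np.exp(-np.maximum(t, 0.0) / targets.tau_rise))
                 * np.exp(-np.maximum(t, 0.0) / targets.tau_decay),
                 0.0)
    t_star = kernel_peak_time(targets)
    g_max = ((1.0 - np.exp(-t_star / targets.tau_rise))
             * np.exp(-t_star / targets.tau_decay))
    return targets.amplitude * g / g_max


def simulate_calcium_recording(targets: TransientTargets,
                               pacing_hz: float = 0.2,
                               duration: float = 150.0,
                               noise_sd: float = 0.0,
                               seed: int | None = None,
                               sampling_rate: float = 1000.0,
                               first_stimulus: float = 2.0) -> FluorescenceTrace:
    """Simulate a paced Fura-2-like ratio recording.

    Stimuli start at ``first_stimulus`` s and repeat at ``pacing_hz``; all
    stimuli within ``duration`` are delivered.  ``noise_sd`` is a fraction of
    the transient amplitude.  Raises if transients would overlap (kernel not
    decayed below 1% of amplitude within one pacing period).
    """
    if pacing_hz <= 0 or sampling_rate <= 0 or duration <= 0:
        raise InvalidProtocolError("pacing, sampling and duration must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    period = 1.0 / pacing_hz
    if targets.amplitude > 0:
        tail = kernel(np.array([period]), targets)[0]
        if tail > 0.01 * targets.amplitude:
            raise OverlappingTransientError(
                f"kernel retains {tail / targets.amplitude:.1%} of amplitude "
                f"after one pacing period of {period:g} s")

    n = int(round(duration * sampling_rate)) + 1
    t = np.arange(n) / sampling_rate
    n_stim = int(np.floor((duration - first_stimulus) / period)) + 1
    stim = first_stimulus + period * np.arange(n_stim)

    f = np.full(n, targets.baseline, dtype=float)
    for s in stim:
        f += kernel(t - s, targets)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd * max(targets.amplitude, 1e-12),
                           size=f.shape)

    return FluorescenceTrace(time_s=t, ratio=f, stimulus_times=stim,
                             pacing_hz=pacing_hz,
                             meta={"targets": targets.to_dict(),
                                   "noise_sd": noise_sd, "seed": seed,
                                   "sampling_rate": sampling_rate,
                                   "modality": "ca"})
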