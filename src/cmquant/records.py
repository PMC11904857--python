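"""Record types shared between generators and analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .presets import VClampProtocol, InactProtocol

__all__ = [
    "SweepFamily",
    "VoltageTrace",
    "FluorescenceTrace",
    "MultiChannelImage",
    "IntensityProfile",
    "IVCurve",
    "GVCurve",
    "BoltzmannFit",
    "APParams",
    "AveragedTransient",
    "TransientParams",
    "MorphometryResult",
    "GroupComparison",
    "Cohort",
]


@dataclass
class SweepFamily:
    """A voltage-clamp current family: one sweep per step voltage.

    ``sweeps`` has shape (n_samples, n_steps), in pA, sampled uniformly on
    ``time_ms``.  ``step_onset`` marks where the step (or test pulse) begins
    on the time axis; the preceding samples are the baseline window.
    """

    time_ms: np.ndarray
    sweeps: np.ndarray
    step_voltages: np.ndarray
    capacitance: float
    protocol: VClampProtocol | InactProtocol
    step_onset: float = 5.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.sweeps = np.asarray(self.sweeps, dtype=float)
        self.step_voltages = np.asarray(self.step_voltages, dtype=float)
        if self.sweeps.shape != (self.time_ms.size, self.step_voltages.size):
            raise ValueError("sweeps must be (n_samples, n_steps)")
        if self.capacitance <= 0:
            raise ValueError("capacitance must be > 0")

    @property
    def dt(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    @property
    def step_window(self) -> tuple[float, float]:
        if isinstance(self.protocol, InactProtocol):
            dur = self.protocol.test_duration
        else:
            dur = self.protocol.step_duration
        return (self.step_onset, self.step_onset + dur)


@dataclass
class VoltageTrace:
    """Current-clamp membrane-potential recording with stimulus markers."""

    time_ms: np.ndarray
    voltage_mv: np.ndarray
    stimulus_times: np.ndarray  # ms
    sampling_rate: float        # kHz
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.voltage_mv = np.asarray(self.voltage_mv, dtype=float)
        self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
        if self.time_ms.shape != self.voltage_mv.shape:
            raise ValueError("time and voltage must have equal length")


@dataclass
class FluorescenceTrace:
    """Paced ratiometric fluorescence recording (time in seconds)."""

    time_s: np.ndarray
    ratio: np.ndarray
    stimulus_times: np.ndarray  # s
    pacing_hz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
        if self.time_s.shape != self.ratio.shape:
            raise ValueError("time and ratio must have equal length")


@dataclass
class MultiChannelImage:
    """Stack of co-registered 2-D channels with physical pixel size."""

    channels: np.ndarray       # (n_channels, rows, cols)
    pixel_size: float          # um / px
    channel_labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 3:
            raise ValueError("channels must be (n_channels, rows, cols)")
        if len(self.channel_labels) != self.channels.shape[0]:
            raise ValueError("one label per channel required")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    def channel(self, key: int | str) -> np.ndarray:
        if isinstance(key, str):
            key = self.channel_labels.index(key)
        return self.channels[key]


@dataclass
class IntensityProfile:
    """Multi-channel 1-D intensity profile sampled along a line."""

    positions: np.ndarray      # um, uniform, strictly increasing
    intensity: np.ndarray      # (n_channels, n_samples)
    channel_labels: list[str]
    line: tuple                # ((r0, c0), (r1, c1)) in px
    pixel_size: float          # um / px (sampling step)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensity = np.atleast_2d(np.asarray(self.intensity, dtype=float))
        if self.intensity.shape[1] != self.positions.size:
            raise ValueError("intensity must be (n_channels, n_samples)")

    def channel(self, key: int | str) -> np.ndarray:
        if isinstance(key, str):
            key = self.channel_labels.index(key)
        return self.intensity[key]


@dataclass
class IVCurve:
    """Peak current and current density versus step voltage."""

    voltages: np.ndarray       # mV, strictly increasing
    peak_current: np.ndarray   # pA, signed
    capacitance: float         # pF

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.peak_current = np.asarray(self.peak_current, dtype=float)
        if np.any(np.diff(self.voltages) <= 0):
            raise ValueError("voltages must be strictly increasing")
        if self.capacitance <= 0:
            raise ValueError("capacitance must be > 0")

    @property
    def density(self) -> np.ndarray:
        """Signed current density, pA/pF."""
        return self.peak_current / self.capacitance


@dataclass
class GVCurve:
    """Normalized conductance (or availability) versus voltage."""

    voltages: np.ndarray
    conductance: np.ndarray    # nS for G-V; unitless for availability
    normalized: np.ndarray     # unitless in [0, ~1]
    excluded_voltages: np.ndarray = field(default_factory=lambda: np.array([]))
    kind: str = "activation"   # "activation" | "availability"

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.conductance = np.asarray(self.conductance, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        self.excluded_voltages = np.asarray(self.excluded_voltages, dtype=float)


@dataclass
class BoltzmannFit:
    """Result of a two-parameter Boltzmann least-squares fit."""

    v_half: float
    k: float
    direction: str             # "activation" | "inactivation"
    rss: float
    n_points: int
    g_max: float = 1.0         # fitted amplitude when free, else 1.0

    def predict(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if self.direction == "activation":
            return self.g_max / (1.0 + np.exp((self.v_half - v) / self.k))
        return self.g_max / (1.0 + np.exp((v - self.v_half) / self.k))


@dataclass
class APParams:
    """Per-cell action-potential parameters averaged across beats."""

    apa: float                  # mV
    apd30: float                # ms
    apd50: float                # ms
    apd90: float                # ms
    upstroke_velocity: float    # V/s
    depolarization_time: float  # ms, stimulus onset -> peak
    resting_potential: float    # mV
    n_beats_averaged: int
    rejected_beats: int = 0

    def to_dict(self) -> dict:
        return {
            "apa": self.apa, "apd30": self.apd30, "apd50": self.apd50,
            "apd90": self.apd90, "upstroke_velocity": self.upstroke_velocity,
            "depolarization_time": self.depolarization_time,
            "resting_potential": self.resting_potential,
            "n_beats_averaged": self.n_beats_averaged,
        }


@dataclass
class AveragedTransient:
    """Stimulus-aligned mean calcium transient for one cell."""

    rel_time: np.ndarray        # s, 0 at stimulus; starts < 0
    mean_ratio: np.ndarray
    n_transients: int
    baseline: float

    def __post_init__(self) -> None:
        self.rel_time = np.asarray(self.rel_time, dtype=float)
        self.mean_ratio = np.asarray(self.mean_ratio, dtype=float)
        if self.n_transients < 1:
            raise ValueError("n_transients must be >= 1")
        if self.rel_time[0] > 0:
            raise ValueError("rel_time must include a pre-stimulus window")


@dataclass
class TransientParams:
    """Full calcium-transient parameter set for one cell (times in s)."""

    amplitude: float
    tp10: float
    tp50: float
    tp: float
    tb10: float
    tb50: float
    transient_duration: float
    time_to_baseline: float
    release_velocity: float     # ratio units / s
    return_velocity: float      # ratio units / s (magnitude)
    auc_release: float          # ratio units * s
    auc_recovery: float         # ratio units * s
    censored: bool = False

    def to_dict(self) -> dict:
        return {
            "amplitude": self.amplitude, "tp10": self.tp10, "tp50": self.tp50,
            "tp": self.tp, "tb10": self.tb10, "tb50": self.tb50,
            "transient_duration": self.transient_duration,
            "time_to_baseline": self.time_to_baseline,
            "release_velocity": self.release_velocity,
            "return_velocity": self.return_velocity,
            "auc_release": self.auc_release,
            "auc_recovery": self.auc_recovery,
            "censored": self.censored,
        }


@dataclass
class MorphometryResult:
    """Striation morphometry summary for one profile/image."""

    actin_shift: float | None = None       # um
    zdisk_width: float | None = None       # um (mean FWHM)
    band_lengths: dict = field(default_factory=dict)  # label -> um
    normalized_intensity: float | None = None
    n_periods_used: int = 0
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {"actin_shift": self.actin_shift, "zdisk_width": self.zdisk_width,
             "normalized_intensity": self.normalized_intensity,
             "n_periods_used": self.n_periods_used,
             "flags": ";".join(self.flags)}
        for label, v in self.band_lengths.items():
            d[f"band_length_{label}"] = v
        return d


@dataclass
class GroupComparison:
    """Two-group summary and Mann-Whitney result for one parameter."""

    parameter: str
    group1: str
    group2: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    sem1: float
    sem2: float
    u_statistic: float
    p_value: float
    stars: str

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter, "group1": self.group1,
            "group2": self.group2, "n1": self.n1, "n2": self.n2,
            "mean1": self.mean1, "mean2": self.mean2, "sd1": self.sd1,
            "sd2": self.sd2, "sem1": self.sem1, "sem2": self.sem2,
            "u_statistic": self.u_statistic, "p_value": self.p_value,
            "stars": self.stars,
        }


@dataclass
class Cohort:
    """Synthetic recordings for one group plus exact generator ground truth."""

    group_label: str
    cells: list                 # per-cell recordings (modality-specific)
    ground_truth: list          # per-cell generator parameter objects
    seed: int
    modality: str = ""

    def __post_init__(self) -> None:
        if len(self.cells) != len(self.ground_truth):
            raise ValueError("one ground-truth entry per cell required")
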