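"""Gating presets, stimulation protocols, and generator target sets.

The default donor gating values below are plausible placeholders for an
iPSC-derived cardiomyocyte fast sodium current; absolute midpoints, slopes
and conductances are NOT measured quantities.  Only the *relative* effects
encoded in the mutant presets are meaningful: the R1267Q-like preset applies
a rigid +5 mV depolarizing translation of activation gating together with a
reduced maximal conductance, and the V2264M-like preset applies a rigid
-11 mV hyperpolarizing translation of inactivation gating.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

from .errors import InvalidProtocolError, InvalidTargetError

__all__ = [
    "GatingPreset",
    "VClampProtocol",
    "InactProtocol",
    "APTargets",
    "TransientTargets",
    "StriationGeometry",
    "donor_preset",
    "r1267q_preset",
    "v2264m_preset",
    "default_vclamp_protocol",
    "default_inact_protocol",
    "default_ap_targets",
    "default_transient_targets",
    "default_striation_geometry",
]


@dataclass(frozen=True)
class GatingPreset:
    """Parameters of the m^3*h sodium-conductance generator for one group.

    Voltages in mV, conductance in nS, time constants in ms, capacitance in
    pF.  ``k_act``/``k_inact`` are Boltzmann slope factors (> 0).
    """

    v_half_act: float = -35.0
    k_act: float = 6.0
    v_half_inact: float = -78.0
    k_inact: float = 6.0
    g_max: float = 20.0
    v_rev: float = 65.0
    tau_m_max: float = 0.5
    tau_h_max: float = 12.0
    capacitance: float = 30.0
    label: str = "donor"

    def __post_init__(self) -> None:
        if self.k_act <= 0 or self.k_inact <= 0:
            raise ValueError("slope factors k_act/k_inact must be > 0")
        if self.g_max <= 0:
            raise ValueError("g_max must be > 0")
        if self.capacitance <= 0:
            raise ValueError("capacitance must be > 0")
        if self.tau_m_max <= 0 or self.tau_h_max <= 0:
            raise ValueError("time constants must be > 0")

    def shifted(self, d_act: float = 0.0, d_inact: float = 0.0,
                g_scale: float = 1.0, label: str | None = None) -> "GatingPreset":
        """Rigidly translate gating midpoints and/or scale conductance."""
        return replace(
            self,
            v_half_act=self.v_half_act + d_act,
            v_half_inact=self.v_half_inact + d_inact,
            g_max=self.g_max * g_scale,
            label=self.label if label is None else label,
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class VClampProtocol:
    """Depolarizing step family for the I-V / activation measurement."""

    holding: float = -100.0
    step_start: float = -80.0
    step_stop: float = 60.0
    step_increment: float = 5.0
    step_duration: float = 40.0
    sampling_rate: float = 50.0  # kHz
    baseline_duration: float = 5.0  # ms recorded before the step

    def __post_init__(self) -> None:
        if self.step_increment <= 0:
            raise InvalidProtocolError("step_increment must be > 0")
        if self.step_start >= self.step_stop:
            raise InvalidProtocolError("step_start must be < step_stop")
        if not (20.0 <= self.sampling_rate <= 50.0):
            raise InvalidProtocolError("sampling_rate must lie in [20, 50] kHz")
        if self.step_duration <= 0 or self.baseline_duration < 0:
            raise InvalidProtocolError("durations must be positive")

    @property
    def step_voltages(self):
        import numpy as np

        n = int(round((self.step_stop - self.step_start) / self.step_increment)) + 1
        return self.step_start + self.step_increment * np.arange(n)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class InactProtocol:
    """Two-pulse availability protocol: long prepulse then fixed test step."""

    prepulse_start: float = -120.0
    prepulse_stop: float = 0.0
    prepulse_increment: float = 5.0
    prepulse_duration: float = 500.0
    test_voltage: float = -15.0
    test_duration: float = 20.0
    holding: float = -100.0
    sampling_rate: float = 50.0  # kHz
    baseline_duration: float = 5.0  # ms of prepulse tail recorded before test

    def __post_init__(self) -> None:
        if self.prepulse_increment <= 0:
            raise InvalidProtocolError("prepulse_increment must be > 0")
        if self.prepulse_start >= self.prepulse_stop:
            raise InvalidProtocolError("prepulse_start must be < prepulse_stop")
        if not (20.0 <= self.sampling_rate <= 50.0):
            raise InvalidProtocolError("sampling_rate must lie in [20, 50] kHz")
        if self.prepulse_duration <= 0 or self.test_duration <= 0:
            raise InvalidProtocolError("durations must be > 0")

    @property
    def prepulse_voltages(self):
        import numpy as np

        n = int(round((self.prepulse_stop - self.prepulse_start)
                      / self.prepulse_increment)) + 1
        return self.prepulse_start + self.prepulse_increment * np.arange(n)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class APTargets:
    """Target parameters of the parametric paced action-potential waveform."""

    apa: float = 100.0          # mV
    apd30: float = 120.0        # ms
    apd50: float = 180.0        # ms
    apd90: float = 300.0        # ms
    resting_potential: float = -75.0  # mV
    rise_time: float = 2.0      # ms, half-cosine upstroke duration
    latency: float = 1.0        # ms, stimulus-to-upstroke delay
    label: str = "donor"

    def __post_init__(self) -> None:
        if not (0 < self.apd30 < self.apd50 < self.apd90):
            raise InvalidTargetError("require 0 < APD30 < APD50 < APD90")
        if self.apa <= 0:
            raise InvalidTargetError("APA must be > 0")
        if self.rise_time <= 0 or self.latency < 0:
            raise InvalidTargetError("rise_time must be > 0, latency >= 0")
        if self.apd30 <= self.rise_time / 2:
            raise InvalidTargetError("APD30 must exceed half the rise time")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TransientTargets:
    """Target parameters of the paced calcium-transient kernel."""

    amplitude: float = 0.30     # Fura-2 ratio units
    tau_rise: float = 0.05      # s
    tau_decay: float = 0.40     # s
    baseline: float = 1.0       # ratio units
    label: str = "donor"

    def __post_init__(self) -> None:
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise InvalidTargetError("tau_rise and tau_decay must be > 0")
        if self.amplitude < 0:
            raise InvalidTargetError("amplitude must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class StriationGeometry:
    """Geometry of the synthetic two-channel striated image.

    ``channel_kinds`` selects the pattern per channel: ``"zdisk"`` (periodic
    Gaussian ridges), ``"actin"`` (complementary bands whose minima sit at
    ridge positions translated by ``actin_shift``) or ``"band"``
    (inter-ridge Gaussian bands of FWHM ``band_length``).
    """

    period: float = 1.9            # um
    zdisk_sigma: float = 0.15      # um
    actin_shift: float = 0.20      # um
    band_length: float = 0.8       # um (FWHM of "band" channels)
    pixel_size: float = 0.1        # um/px
    image_size: tuple = (64, 190)  # (rows, cols) px
    channel_gains: tuple = (1.0, 1.0)
    channel_kinds: tuple = ("zdisk", "actin")
    channel_labels: tuple = ("phalloidin", "cardiac_actin")
    photons: float | None = None   # photons per intensity unit; None = noiseless
    label: str = "donor"

    def __post_init__(self) -> None:
        if not (0 < self.zdisk_sigma < self.period / 2):
            raise ValueError("require 0 < zdisk_sigma < period/2")
        if abs(self.actin_shift) >= self.period / 2:
            raise ValueError("require |actin_shift| < period/2")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not (len(self.channel_gains) == len(self.channel_kinds)
                == len(self.channel_labels)):
            raise ValueError("channel gains/kinds/labels must align")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_size"] = list(self.image_size)
        d["channel_gains"] = list(self.channel_gains)
        d["channel_kinds"] = list(self.channel_kinds)
        d["channel_labels"] = list(self.channel_labels)
        return d


def donor_preset() -> GatingPreset:
    """Reference ('donor') gating preset."""
    return GatingPreset()


def r1267q_preset(base: GatingPreset | None = None) -> GatingPreset:
    """Arrhythmogenic-variant-like preset: +5 mV rigid depolarizing shift of
    activation gating plus reduced maximal conductance."""
    base = donor_preset() if base is None else base
    return base.shifted(d_act=+5.0, g_scale=0.55, label="R1267Q")


def v2264m_preset(base: GatingPreset | None = None) -> GatingPreset:
    """Restrictive-variant-like preset: -11 mV rigid hyperpolarizing shift of
    inactivation gating."""
    base = donor_preset() if base is None else base
    return base.shifted(d_inact=-11.0, label="V2264M")


def default_vclamp_protocol() -> VClampProtocol:
    return VClampProtocol()


def default_inact_protocol() -> InactProtocol:
    return InactProtocol()


def default_ap_targets() -> APTargets:
    return APTargets()


def default_transient_targets() -> TransientTargets:
    return TransientTargets()


def default_striation_geometry() -> StriationGeometry:
    return StriationGeometry()
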