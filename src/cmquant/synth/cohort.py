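"""Cohort builder: per-cell parameter jitter around group presets."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..errors import ConfigError
from ..presets import (APTargets, GatingPreset, InactProtocol,
                       StriationGeometry, TransientTargets, VClampProtocol)
from ..records import Cohort
from .calcium import simulate_calcium_recording
from .ephys import (simulate_ap_trace, simulate_inactivation_family,
                    simulate_vclamp_family)
from .imaging import simulate_striation_image

__all__ = ["CohortVariability", "make_cohort", "MODALITIES"]

MODALITIES = ("na", "inact", "ap", "ca", "image")


@dataclass(frozen=True)
class CohortVariability:
    """Inter-cell spread: multiplicative log-normal on amplitudes and time
    scales (coefficient of variation ``cv``), additive Gaussian on voltages
    (``voltage_sd`` mV)."""

    cv: float = 0.05
    voltage_sd: float = 1.0

    @classmethod
    def none(cls) -> "CohortVariability":
        return cls(cv=0.0, voltage_sd=0.0)


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = float(np.sqrt(np.log(1.0 + cv ** 2)))
    return float(rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma))


def _jitter_preset(preset: GatingPreset, rng: np.random.Generator,
                   var: CohortVariability) -> GatingPreset:
    return replace(
        preset,
        g_max=preset.g_max * _lognormal_factor(rng, var.cv),
        v_half_act=preset.v_half_act + rng.normal(0.0, var.voltage_sd)
        if var.voltage_sd > 0 else preset.v_half_act,
        v_half_inact=preset.v_half_inact + rng.normal(0.0, var.voltage_sd)
        if var.voltage_sd > 0 else preset.v_half_inact,
    )


def _jitter_ap(targets: APTargets, rng: np.random.Generator,
               var: CohortVariability) -> APTargets:
    dur = _lognormal_factor(rng, var.cv)  # common factor keeps APD ordering
    return replace(
        targets,
        apa=targets.apa * _lognormal_factor(rng, var.cv),
        apd30=targets.apd30 * dur,
        apd50=targets.apd50 * dur,
        apd90=targets.apd90 * dur,
        resting_potential=targets.resting_potential
        + (rng.normal(0.0, var.voltage_sd) if var.voltage_sd > 0 else 0.0),
    )


def _jitter_transient(targets: TransientTargets, rng: np.random.Generator,
                      var: CohortVariability) -> TransientTargets:
    tscale = _lognormal_factor(rng, var.cv)
    return replace(
        targets,
        amplitude=targets.amplitude * _lognormal_factor(rng, var.cv),
        tau_rise=targets.tau_rise * tscale,
        tau_decay=targets.tau_decay * tscale,
    )


def _jitter_geometry(geom: StriationGeometry, rng: np.random.Generator,
                     var: CohortVariability) -> StriationGeometry:
    gains = tuple(g * _lognormal_factor(rng, var.cv)
                  for g in geom.channel_gains)
    return replace(geom, channel_gains=gains)


def make_cohort(group_presets: list, n_cells: int, modality: str,
                seed: int = 0, noise_sd: float = 0.0,
                variability: CohortVariability | None = None,
                protocol: VClampProtocol | InactProtocol | None = None,
                **sim_kwargs) -> list[Cohort]:
    """Generate one :class:`Cohort` per preset, ``n_cells`` cells each.

    Cell ``i`` of group ``g`` uses the derived seed ``seed + g*n_cells + i``;
    parameter jitter and recording noise draw from independent streams spawned
    from that seed, so regeneration from (seed, presets) is bit-identical.
    """
    if not group_presets:
        raise ConfigError("group_presets must be non-empty")
    if n_cells < 1:
        raise ConfigError("n_cells must be >= 1")
    if modality not in MODALITIES:
        raise ConfigError(f"unknown modality {modality!r}; "
                          f"choose from {MODALITIES}")
    variability = CohortVariability() if variability is None else variability

    cohorts = []
    for g, preset in enumerate(group_presets):
        cells, truth = [], []
        for i in range(n_cells):
            cell_seed = seed + g * n_cells + i
            param_rng = np.random.default_rng([cell_seed, 0])
            noise_seed = [cell_seed, 1]
            if modality in ("na", "inact"):
                cell_preset = _jitter_preset(preset, param_rng, variability)
                sim = (simulate_vclamp_family if modality == "na"
                       else simulate_inactivation_family)
                rec = sim(cell_preset, protocol, noise_sd=noise_sd,
                          seed=noise_seed, **sim_kwargs)
            elif modality == "ap":
                cell_preset = _jitter_ap(preset, param_rng, variability)
                rec = simulate_ap_trace(cell_preset, noise_sd=noise_sd,
                                        seed=noise_seed, **sim_kwargs)
            elif modality == "ca":
                cell_preset = _jitter_transient(preset, param_rng, variability)
                rec = simulate_calcium_recording(cell_preset, noise_sd=noise_sd,
                                                 seed=noise_seed, **sim_kwargs)
            else:  # image
                cell_preset = _jitter_geometry(preset, param_rng, variability)
                rec = simulate_striation_image(cell_preset, seed=noise_seed)
            cells.append(rec)
            truth.append({"params": cell_preset, "seed": cell_seed})
        cohorts.append(Cohort(group_label=getattr(preset, "label", f"group{g}"),
                              cells=cells, ground_truth=truth, seed=seed,
                              modality=modality))
    return cohorts
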