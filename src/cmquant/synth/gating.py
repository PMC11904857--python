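"""m^3*h gating kinetics used by the voltage-clamp generators.

Activation gate ``m``: Boltzmann steady state centered on ``v_half_act`` with
a bell-shaped voltage-dependent time constant centered on the same midpoint,
so every voltage-dependent term of the m gate translates rigidly with
``v_half_act``.  Inactivation gate ``h``: Boltzmann steady state centered on
``v_half_inact``; its relaxation time constant is voltage-independent
(``tau_h_max``).  Keeping tau_h flat makes the peak-conductance transform an
exact function of (V - v_half_act) on depolarizing steps, which is what
guarantees that rigid midpoint translations propagate unchanged into the
downstream Boltzmann fits.
"""

from __future__ import annotations

import numpy as np

from ..presets import GatingPreset

TAU_M_FLOOR = 0.05  # ms; keeps relaxation finite far from the midpoint


def m_inf(v, preset: GatingPreset):
    """Steady-state activation, ascending Boltzmann."""
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp((preset.v_half_act - v) / preset.k_act))


def h_inf(v, preset: GatingPreset):
    """Steady-state availability, descending Boltzmann."""
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp((v - preset.v_half_inact) / preset.k_inact))


def tau_m(v, preset: GatingPreset):
    """Bell-shaped activation time constant (ms), peaked at v_half_act."""
    v = np.asarray(v, dtype=float)
    return TAU_M_FLOOR + preset.tau_m_max / np.cosh(
        (v - preset.v_half_act) / (2.0 * preset.k_act))


def tau_h(v, preset: GatingPreset):
    """Inactivation time constant (ms); voltage-independent by design."""
    return np.full_like(np.asarray(v, dtype=float), preset.tau_h_max)


def step_current(t_ms, v_step, preset: GatingPreset, m0: float, h0: float):
    """Closed-form current (pA) during a voltage step.

    Both gates relax mono-exponentially from (m0, h0) toward their steady
    states at ``v_step``; I = g_max * m^3 * h * (V - v_rev) with g_max in nS
    and voltages in mV, giving pA.
    """
    t = np.asarray(t_ms, dtype=float)
    mi = float(m_inf(v_step, preset))
    hi = float(h_inf(v_step, preset))
    tm = float(tau_m(v_step, preset))
    th = float(tau_h(np.asarray(v_step), preset))
    m = mi + (m0 - mi) * np.exp(-t / tm)
    h = hi + (h0 - hi) * np.exp(-t / th)
    return preset.g_max * m ** 3 * h * (v_step - preset.v_rev)


def steady_current(v, preset: GatingPreset) -> float:
    """Steady-state window current at a holding voltage (pA)."""
    return float(preset.g_max * m_inf(v, preset) ** 3 * h_inf(v, preset)
                 * (np.asarray(v, dtype=float) - preset.v_rev))


def prepulse_availability(v_pre, duration_ms: float, preset: GatingPreset,
                          h0: float) -> float:
    """h at the end of a prepulse, relaxing from h0 toward h_inf(v_pre)."""
    hi = float(h_inf(v_pre, preset))
    th = float(preset.tau_h_max)
    return hi + (h0 - hi) * float(np.exp(-duration_ms / th))
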