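"""Independent brute-force oracles used by the test suite.

Everything here recomputes expected values from first principles (dense
time-stepping, closed forms, exhaustive enumeration) without calling the
code paths under test.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def euler_vclamp_peak(v_step: float, *, v_half_act: float, k_act: float,
                      v_half_inact: float, k_inact: float, g_max: float,
                      v_rev: float, tau_m_max: float, tau_h_max: float,
                      holding: float = -100.0, duration: float = 40.0,
                      dt: float = 1e-4) -> float:
    """Signed peak current of one depolarizing step by dense forward Euler."""
    m = 1.0 / (1.0 + np.exp((v_half_act - holding) / k_act))
    h = 1.0 / (1.0 + np.exp((holding - v_half_inact) / k_inact))
    mi = 1.0 / (1.0 + np.exp((v_half_act - v_step) / k_act))
    hi = 1.0 / (1.0 + np.exp((v_step - v_half_inact) / k_inact))
    tm = 0.05 + tau_m_max / np.cosh((v_step - v_half_act) / (2.0 * k_act))
    th = tau_h_max
    best = 0.0
    for _ in range(int(round(duration / dt))):
        m += dt * (mi - m) / tm
        h += dt * (hi - h) / th
        i = g_max * m ** 3 * h * (v_step - v_rev)
        if abs(i) > abs(best):
            best = i
    return best


def euler_availability(v_pre: float, *, v_half_inact: float, k_inact: float,
                       tau_h_max: float, holding: float = -100.0,
                       prepulse_ms: float = 500.0, dt: float = 0.01) -> float:
    """h at prepulse end by dense forward Euler from the holding level."""
    h = 1.0 / (1.0 + np.exp((holding - v_half_inact) / k_inact))
    hi = 1.0 / (1.0 + np.exp((v_pre - v_half_inact) / k_inact))
    for _ in range(int(round(prepulse_ms / dt))):
        h += dt * (hi - h) / tau_h_max
    return h


def calcium_kernel_oracle(amplitude: float, tau_rise: float, tau_decay: float,
                          baseline: float = 0.0, fs: float = 10_000.0,
                          t_max: float = 4.0) -> dict:
    """Brute-force transient parameters of the analytic kernel at dense fs.

    Rebuilds the kernel from its formula, normalizes so the maximum equals
    ``amplitude``, and finds peak/crossings/AUCs by dense scanning.
    """
    t = np.arange(int(round(t_max * fs)) + 1) / fs
    g = (1.0 - np.exp(-t / tau_rise)) * np.exp(-t / tau_decay)
    f = baseline + amplitude * g / g.max()

    i_pk = int(np.argmax(f))
    amp = f[i_pk] - baseline
    tp = t[i_pk]

    def up_cross(level):
        i = int(np.argmax(f[:i_pk + 1] >= level))
        if i == 0:
            return 0.0
        frac = (level - f[i - 1]) / (f[i] - f[i - 1])
        return t[i - 1] + frac / fs

    def down_cross(level):
        for i in range(i_pk, t.size - 1):
            if f[i] >= level > f[i + 1]:
                frac = (f[i] - level) / (f[i] - f[i + 1])
                return t[i] + frac / fs
        return None

    tp10 = up_cross(baseline + 0.10 * amp)
    tp50 = up_cross(baseline + 0.50 * amp)
    tb10_t = down_cross(baseline + 0.90 * amp)
    tb50_t = down_cross(baseline + 0.50 * amp)
    t90 = down_cross(baseline + 0.10 * amp)

    yb = f - baseline
    auc_release = np.trapezoid(yb[t <= tp], t[t <= tp])
    sel = (t >= tp) & (t <= t90)
    auc_recovery = np.trapezoid(yb[sel], t[sel])
    dfdt = np.gradient(f, t)
    return {
        "amplitude": amp, "tp10": tp10, "tp50": tp50, "tp": tp,
        "tb10": tb10_t - tp, "tb50": tb50_t - tp,
        "transient_duration": t90, "time_to_baseline": t90 - tp,
        "release_velocity": float(dfdt[:i_pk + 1].max()),
        "return_velocity": float(-dfdt[i_pk:].min()),
        "auc_release": float(auc_release),
        "auc_recovery": float(auc_recovery),
    }


def mw_permutation(a, b) -> tuple[float, float]:
    """Mann-Whitney by exhaustive relabeling: U = min(U1,U2), two-sided p.

    p = P(U1 <= U_obs) + P(U1 >= n1*n2 - U_obs) over all C(n, n1)
    labelings of the pooled sample (midranks), clipped to 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n, n1 = pooled.size, a.size
    n2 = n - n1
    # midranks by sorting
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    sv = pooled[order]
    while i < n:
        j = i
        while j + 1 < n and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1

    u1_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    u_obs = min(u1_obs, n1 * n2 - u1_obs)
    u_hi = n1 * n2 - u_obs
    count = 0
    for subset in combinations(range(n), n1):
        u1 = ranks[list(subset)].sum() - n1 * (n1 + 1) / 2.0
        if u1 <= u_obs + 1e-9 or u1 >= u_hi - 1e-9:
            count += 1
    return float(u_obs), min(1.0, count / comb(n, n1))
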