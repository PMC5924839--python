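"""Vectorized Euler sweep over many (g_K,lt, g_K,A) pairs at once.

Building a spiking-pattern map requires tens of thousands of independent
simulations; running them as one NumPy-vectorized Euler integration (all
conductance pairs advanced in lock-step) keeps the full 201 x 201 default
map buildable in about a minute on one CPU.  The per-step arithmetic is
identical to :func:`sdhspike.model.simulate`; agreement between the two
paths is asserted in the test suite.

Only the quantities needed for classification are recorded: the spike
count during the stimulus window and the (interpolated) times of the
first three threshold crossings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import NeuronParameters, StimulusProtocol, steady_state, time_constants

__all__ = ["SpikeStats", "sweep_spike_stats"]


@dataclass
class SpikeStats:
    """Per-simulation spike summary from a vectorized sweep.

    ``t1``, ``t2``, ``t3`` are the times (ms after stimulus onset) of the
    first three spikes, NaN where fewer spikes occurred.  ``v_pre`` is the
    membrane potential at the end of the settle phase.
    """

    n_spikes: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    t3: np.ndarray
    v_pre: np.ndarray
    b_onset: np.ndarray  # A-type availability at stimulus onset


def sweep_spike_stats(g_lt, g_A,
                      params: NeuronParameters = NeuronParameters(),
                      protocol: StimulusProtocol = StimulusProtocol(),
                      threshold: float = 0.0,
                      reset: float | None = None) -> SpikeStats:
    """Simulate every (g_lt[i], g_A[i]) pair and summarize its spikes.

    Spikes are upward crossings of ``threshold`` during the stimulus
    window; after a spike the trace must fall below ``reset`` (default:
    the threshold itself) before another spike can be registered.  Spike
    times are linearly interpolated between steps.

    Raises ``FloatingPointError`` if any trajectory becomes non-finite,
    naming the first offending conductance pair.
    """
    g_lt = np.atleast_1d(np.asarray(g_lt, dtype=float))
    g_A = np.atleast_1d(np.asarray(g_A, dtype=float))
    if g_lt.shape != g_A.shape:
        raise ValueError("g_lt and g_A must have the same shape")
    n = g_lt.size
    if reset is None:
        reset = threshold

    p = params
    dt = protocol.dt
    n_settle, n_stim = protocol.n_settle, protocol.n_stim

    V = np.full(n, p.E_leak)
    _, w0, z0, a0, b0 = steady_state(p.E_leak, p)
    w = np.full(n, float(w0))
    z = np.full(n, float(z0))
    a = np.full(n, float(a0))
    b = np.full(n, float(b0))

    n_spikes = np.zeros(n, dtype=np.int64)
    t1 = np.full(n, np.nan)
    t2 = np.full(n, np.nan)
    t3 = np.full(n, np.nan)
    armed = np.ones(n, dtype=bool)

    def step(V, w, z, a, b, I):
        m = 0.5 * (1.0 + np.tanh((V - p.beta_m) / p.gamma_m))
        I_ion = (p.gbar_Na * m * (V - p.E_Na)
                 + p.gbar_Kdr * w * (V - p.E_K)
                 + (g_lt * z + g_A * a**4 * b) * (V - p.E_K)
                 + p.gbar_leak * (V - p.E_leak))
        _, w_inf, z_inf, a_inf, b_inf = steady_state(V, p)
        tau_w, tau_z, tau_a, tau_b = time_constants(V, p)
        V_new = V + dt * (I - I_ion) / p.C
        w_new = w + dt * p.phi_w * (w_inf - w) / tau_w
        z_new = z + dt * p.phi_z * (z_inf - z) / tau_z
        a_new = a + dt * p.phi_a * (a_inf - a) / tau_a
        b_new = b + dt * p.phi_b * (b_inf - b) / tau_b
        return V_new, w_new, z_new, a_new, b_new

    for i in range(n_settle):
        V, w, z, a, b = step(V, w, z, a, b, protocol.I_pre)
    _check_finite(V, g_lt, g_A, "settle phase")

    v_pre = V.copy()
    b_onset = b.copy()

    I_on = protocol.I_pre + protocol.I_stim
    for i in range(n_stim):
        V_prev = V
        V, w, z, a, b = step(V, w, z, a, b, I_on)
        # re-arm once the trace has fallen back below the reset level
        armed |= V < reset
        crossed = armed & (V_prev < threshold) & (V >= threshold)
        if crossed.any():
            frac = (threshold - V_prev[crossed]) / (V[crossed] - V_prev[crossed])
            t_cross = (i + frac) * dt
            cnt = n_spikes[crossed]
            idx = np.flatnonzero(crossed)
            t1[idx[cnt == 0]] = t_cross[cnt == 0]
            t2[idx[cnt == 1]] = t_cross[cnt == 1]
            t3[idx[cnt == 2]] = t_cross[cnt == 2]
            n_spikes[idx] += 1
            armed[idx] = False
    _check_finite(V, g_lt, g_A, "stimulus phase")

    return SpikeStats(n_spikes=n_spikes, t1=t1, t2=t2, t3=t3,
                      v_pre=v_pre, b_onset=b_onset)


def _check_finite(V: np.ndarray, g_lt: np.ndarray, g_A: np.ndarray, phase: str) -> None:
    bad = ~np.isfinite(V)
    if bad.any():
        j = int(np.flatnonzero(bad)[0])
        raise FloatingPointError(
            f"simulation diverged during {phase} at "
            f"(g_K,lt = {g_lt[j]:g}, g_K,A = {g_A[j]:g}) mS/cm^2"
        )
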