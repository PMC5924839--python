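"""Modified Morris-Lecar model of a superficial dorsal horn neuron.

The model is a single-compartment conductance-based neuron with an
instantaneously activating sodium current, a delayed-rectifier potassium
current, a leak current, and two additional potassium currents whose
maximal densities are the quantities of interest:

* ``g_K,lt`` -- a low-threshold, non-inactivating (Kv1-type) conductance
  gated by the variable ``z``;
* ``g_K,A`` -- an inactivating A-type conductance with activation ``a``
  (fourth power) and inactivation ``b``.

Membrane potential obeys

    C dV/dt = I - gbar_Na m_inf(V) (V - E_Na) - gbar_Kdr w (V - E_K)
                - gbar_Klt z (V - E_K) - gbar_KA a^4 b (V - E_K)
                - gbar_leak (V - E_leak)

and each gating variable x in {w, z, a, b} relaxes to its voltage-dependent
steady state with dx/dt = phi_x (x_inf(V) - x) / tau_x(V).  Integration is
forward Euler with a fixed step (default 0.1 ms), preceded by a settle
phase that brings the model to steady state before stimulus onset.

All quantities are carried in the units used throughout the module:
ms, mV, uA/cm^2, mS/cm^2 and uF/cm^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "NeuronParameters",
    "StimulusProtocol",
    "StateVector",
    "SimulationResult",
    "steady_state",
    "time_constants",
    "derivatives",
    "resting_state",
    "simulate",
    "save_trace",
    "load_trace",
]


@dataclass(frozen=True)
class NeuronParameters:
    """Biophysical constants of the model.

    Defaults are the published constants of the modified Morris-Lecar
    model; only ``gbar_Klt`` and ``gbar_KA`` are varied in a typical
    study.
    """

    C: float = 2.0            # membrane capacitance, uF/cm^2
    E_Na: float = 50.0        # mV
    E_K: float = -100.0       # mV
    E_leak: float = -70.0     # mV
    gbar_Na: float = 20.0     # mS/cm^2
    gbar_Kdr: float = 20.0    # mS/cm^2
    gbar_leak: float = 2.0    # mS/cm^2
    gbar_Klt: float = 0.0     # mS/cm^2, low-threshold Kv1-type
    gbar_KA: float = 0.0      # mS/cm^2, A-type
    phi_w: float = 0.15
    phi_z: float = 0.15
    phi_a: float = 1.0
    phi_b: float = 1.0
    beta_m: float = -1.2      # mV
    beta_w: float = -10.0     # mV
    beta_z: float = -21.0     # mV
    gamma_m: float = 18.0     # mV
    gamma_w: float = 10.0     # mV
    gamma_z: float = 15.0     # mV

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("capacitance C must be positive")
        for name in ("gbar_Na", "gbar_Kdr", "gbar_leak", "gbar_Klt", "gbar_KA"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("gamma_m", "gamma_w", "gamma_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **kwargs) -> "NeuronParameters":
        d = asdict(self)
        d.update(kwargs)
        return NeuronParameters(**d)


@dataclass(frozen=True)
class StimulusProtocol:
    """Settle-then-stimulate current-clamp protocol.

    ``I_pre`` is a subthreshold pre-pulse applied throughout the settle
    phase and kept on during stimulation (total applied current during the
    stimulus is ``I_pre + I_stim``); it sets the pre-stimulus membrane
    potential and thereby the availability of the A-type conductance.
    """

    I_stim: float = 60.0          # uA/cm^2
    I_pre: float = 0.0            # uA/cm^2
    settle_duration: float = 250.0  # ms
    stim_duration: float = 400.0    # ms
    dt: float = 0.1                 # ms

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.settle_duration <= 0 or self.stim_duration <= 0:
            raise ValueError("durations must be positive")

    @property
    def n_settle(self) -> int:
        return int(round(self.settle_duration / self.dt))

    @property
    def n_stim(self) -> int:
        return int(round(self.stim_duration / self.dt))

    def replace(self, **kwargs) -> "StimulusProtocol":
        d = asdict(self)
        d.update(kwargs)
        return StimulusProtocol(**d)


@dataclass
class StateVector:
    V: float
    w: float
    z: float
    a: float
    b: float


def steady_state(V, params: NeuronParameters = NeuronParameters()):
    """Steady-state activation/inactivation values at potential ``V``.

    Returns ``(m_inf, w_inf, z_inf, a_inf, b_inf)``.  ``m``, ``w`` and
    ``z`` follow the Morris-Lecar 0.5*(1+tanh((V-beta)/gamma)) form; the
    A-type gates use Boltzmann curves (half-activation -60 mV, slope
    8.5 mV for ``a``; half-inactivation -78 mV, slope 6 mV for ``b``).
    Accepts scalars or arrays.
    """
    V = np.asarray(V, dtype=float)
    m = 0.5 * (1.0 + np.tanh((V - params.beta_m) / params.gamma_m))
    w = 0.5 * (1.0 + np.tanh((V - params.beta_w) / params.gamma_w))
    z = 0.5 * (1.0 + np.tanh((V - params.beta_z) / params.gamma_z))
    a = 1.0 / (1.0 + np.exp(-(V + 60.0) / 8.5))
    b = 1.0 / (1.0 + np.exp((V + 78.0) / 6.0))
    return m, w, z, a, b


def time_constants(V, params: NeuronParameters = NeuronParameters()):
    """Voltage-dependent time constants ``(tau_w, tau_z, tau_a, tau_b)`` in ms.

    ``tau_b`` is 19 ms above -63 mV and a double-exponential below; the
    boundary point V = -63 is assigned to the double-exponential branch.
    """
    V = np.asarray(V, dtype=float)
    tau_w = 1.0 / np.cosh((V - params.beta_w) / (2.0 * params.gamma_w))
    tau_z = 1.0 / np.cosh((V - params.beta_z) / (2.0 * params.gamma_z))
    tau_a = 1.0 / (np.exp((V + 35.82) / 19.69) + np.exp(-(V + 79.69) / 12.7)) + 0.37
    tau_b = np.where(
        V > -63.0,
        19.0,
        1.0 / (np.exp((V + 46.05) / 5.0) + np.exp(-(V + 238.4) / 37.45)),
    )
    return tau_w, tau_z, tau_a, tau_b


def _membrane_current(V, w, z, a, b, params: NeuronParameters):
    """Total ionic current (uA/cm^2) flowing out of the membrane."""
    m = 0.5 * (1.0 + np.tanh((V - params.beta_m) / params.gamma_m))
    I_Na = params.gbar_Na * m * (V - params.E_Na)
    I_Kdr = params.gbar_Kdr * w * (V - params.E_K)
    I_Klt = params.gbar_Klt * z * (V - params.E_K)
    I_KA = params.gbar_KA * a**4 * b * (V - params.E_K)
    I_leak = params.gbar_leak * (V - params.E_leak)
    return I_Na + I_Kdr + I_Klt + I_KA + I_leak


def derivatives(state: StateVector, I_applied: float,
                params: NeuronParameters = NeuronParameters()) -> StateVector:
    """Time derivatives of the state under applied current ``I_applied``."""
    V, w, z, a, b = state.V, state.w, state.z, state.a, state.b
    dV = (I_applied - _membrane_current(V, w, z, a, b, params)) / params.C
    _, w_inf, z_inf, a_inf, b_inf = steady_state(V, params)
    tau_w, tau_z, tau_a, tau_b = time_constants(V, params)
    return StateVector(
        V=float(dV),
        w=float(params.phi_w * (w_inf - w) / tau_w),
        z=float(params.phi_z * (z_inf - z) / tau_z),
        a=float(params.phi_a * (a_inf - a) / tau_a),
        b=float(params.phi_b * (b_inf - b) / tau_b),
    )


def resting_state(params: NeuronParameters = NeuronParameters(),
                  I_applied: float = 0.0,
                  V_lo: float = -90.0, V_hi: float = -20.0) -> StateVector:
    """Resting fixed point with all gates at steady state (bisection on V)."""

    def f(V):
        _, w, z, a, b = steady_state(V, params)
        return I_applied - _membrane_current(V, w, z, a, b, params)

    lo, hi = V_lo, V_hi
    flo = f(lo)
    if flo * f(hi) > 0:
        raise ValueError("no sign change in the search bracket; no resting point found")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if flo * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
            flo = f(lo)
    V = 0.5 * (lo + hi)
    _, w, z, a, b = steady_state(V, params)
    return StateVector(V=float(V), w=float(w), z=float(z), a=float(a), b=float(b))


@dataclass
class SimulationResult:
    """Full trajectory of one simulation.

    ``times`` are in ms relative to stimulus onset (the settle phase has
    negative times); arrays all share the same length.
    """

    times: np.ndarray
    V: np.ndarray
    w: np.ndarray
    z: np.ndarray
    a: np.ndarray
    b: np.ndarray
    params: NeuronParameters
    protocol: StimulusProtocol

    @property
    def pre_stimulus_potential(self) -> float:
        """Membrane potential at the last settle step (mV)."""
        idx = np.searchsorted(self.times, 0.0)
        return float(self.V[max(idx - 1, 0)])


def simulate(params: NeuronParameters = NeuronParameters(),
             protocol: StimulusProtocol = StimulusProtocol()) -> SimulationResult:
    """Run the settle + stimulus protocol with forward Euler.

    The state is initialized at V = E_leak with gates at steady state for
    that potential; the settle phase (current ``I_pre``) then brings the
    model to its steady state before the stimulus (``I_pre + I_stim``)
    turns on at t = 0.

    Raises ``FloatingPointError`` if the state becomes non-finite,
    reporting the offending step.
    """
    dt = protocol.dt
    n_settle, n_stim = protocol.n_settle, protocol.n_stim
    n_total = n_settle + n_stim + 1

    V = np.empty(n_total)
    w = np.empty(n_total)
    z = np.empty(n_total)
    a = np.empty(n_total)
    b = np.empty(n_total)

    V[0] = params.E_leak
    _, w[0], z[0], a[0], b[0] = steady_state(V[0], params)

    for i in range(n_total - 1):
        I = protocol.I_pre if i < n_settle else protocol.I_pre + protocol.I_stim
        Vi, wi, zi, ai, bi = V[i], w[i], z[i], a[i], b[i]
        dV = (I - _membrane_current(Vi, wi, zi, ai, bi, params)) / params.C
        _, w_inf, z_inf, a_inf, b_inf = steady_state(Vi, params)
        tau_w, tau_z, tau_a, tau_b = time_constants(Vi, params)
        V[i + 1] = Vi + dt * dV
        w[i + 1] = wi + dt * params.phi_w * (w_inf - wi) / tau_w
        z[i + 1] = zi + dt * params.phi_z * (z_inf - zi) / tau_z
        a[i + 1] = ai + dt * params.phi_a * (a_inf - ai) / tau_a
        b[i + 1] = bi + dt * params.phi_b * (b_inf - bi) / tau_b
        if not np.isfinite(V[i + 1]):
            raise FloatingPointError(
                f"simulation diverged at step {i + 1} "
                f"(t = {(i + 1 - n_settle) * dt:.1f} ms after stimulus onset)"
            )

    times = (np.arange(n_total) - n_settle) * dt
    return SimulationResult(times=times, V=V, w=w, z=z, a=a, b=b,
                            params=params, protocol=protocol)


def save_trace(result: SimulationResult, path: str | Path,
               include_gating: bool = True) -> None:
    """Write a trace as delimited text (time_ms, V_mV[, w, z, a, b]) with a
    JSON sidecar echoing parameters and protocol."""
    path = Path(path)
    cols = [result.times, result.V]
    header = "time_ms,V_mV"
    if include_gating:
        cols += [result.w, result.z, result.a, result.b]
        header += ",w,z,a,b"
    np.savetxt(path, np.column_stack(cols), delimiter=",", header=header, comments="")
    sidecar = {
        "params": asdict(result.params),
        "protocol": asdict(result.protocol),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_trace(path: str | Path) -> SimulationResult:
    """Read a trace written by :func:`save_trace`."""
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        params = NeuronParameters(**meta["params"])
        protocol = StimulusProtocol(**meta["protocol"])
    else:
        params, protocol = NeuronParameters(), StimulusProtocol()
    n = data.shape[0]
    gating = data.shape[1] >= 6
    empty = np.full(n, np.nan)
    return SimulationResult(
        times=data[:, 0], V=data[:, 1],
        w=data[:, 2] if gating else empty,
        z=data[:, 3] if gating else empty,
        a=data[:, 4] if gating else empty,
        b=data[:, 5] if gating else empty,
        params=params, protocol=protocol,
    )
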