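"""Membrane current densities and Hodgkin-Huxley gating kinetics.

This module is the single source of truth for the membrane model shared by
the compartmental cable solver and the coupled (whole-FEM) solver.  The
membrane is a specific capacitance ``cm`` in parallel with a leak
conductance ``gl`` (in series with its reversal ``El``) and, optionally,
the classic squid-axon potassium and sodium conductances gated by the
``n``, ``m`` and ``h`` open probabilities.

Unit conventions
----------------
All public quantities are SI: potentials in volts, conductances per area in
S/m^2, capacitance per area in F/m^2, current densities in A/m^2, time in
seconds.  The Hodgkin-Huxley rate expressions are evaluated literally in
their historical mV / ms regime; the conversion happens at this module's
boundary and nowhere else.  The gating voltage ``vtilde`` (mV) is the
*opposite* of the deviation of the membrane potential from its resting
value: ``vtilde = -(Vm - Vrest) * 1e3``.

Helpers :func:`uF_per_cm2`, :func:`mS_per_cm2` and :func:`ohm_cm` accept
the unit habits of the neurophysiology literature
(1 uF/cm^2 = 0.01 F/m^2, 1 mS/cm^2 = 10 S/m^2, 1 Ohm.cm = 0.01 Ohm.m).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MembraneParams",
    "GateState",
    "uF_per_cm2",
    "mS_per_cm2",
    "S_per_cm2",
    "ohm_cm",
    "mV",
    "vtilde_from_vm",
    "hh_rates",
    "gate_steady_state",
    "resting_gates",
    "step_gates",
    "ionic_conductance",
    "membrane_current_density",
]


# ---------------------------------------------------------------------------
# unit helpers (literature units -> SI)

def uF_per_cm2(x: float) -> float:
    """Specific capacitance: uF/cm^2 -> F/m^2."""
    return x * 1e-2


def mS_per_cm2(x: float) -> float:
    """Specific conductance: mS/cm^2 -> S/m^2."""
    return x * 10.0


def S_per_cm2(x: float) -> float:
    """Specific conductance: S/cm^2 -> S/m^2."""
    return x * 1e4


def ohm_cm(x: float) -> float:
    """Resistivity: Ohm.cm -> Ohm.m."""
    return x * 1e-2


def mV(x: float) -> float:
    """Potential: mV -> V."""
    return x * 1e-3


@dataclass(frozen=True)
class MembraneParams:
    """Electrical constants of a patch of membrane (SI units).

    Defaults are the passive set used throughout the bundled MEA scenarios:
    cm = 1 uF/cm^2, gl = 1e-4 mS/cm^2, El = -65 mV, ionic currents off.
    The active maxima/reversals default to the classic squid-axon values
    (gK = 36 mS/cm^2, gNa = 120 mS/cm^2, EK = -77 mV, ENa = +50 mV) and
    only enter when ``active`` is true.
    """

    cm: float = uF_per_cm2(1.0)
    gl: float = mS_per_cm2(1e-4)
    El: float = mV(-65.0)
    gK_bar: float = mS_per_cm2(36.0)
    gNa_bar: float = mS_per_cm2(120.0)
    EK: float = mV(-77.0)
    ENa: float = mV(50.0)
    active: bool = False

    def __post_init__(self):
        if not self.cm > 0:
            raise ValueError(f"cm must be > 0, got {self.cm}")
        for name in ("gl", "gK_bar", "gNa_bar"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    def passive(self) -> "MembraneParams":
        return replace(self, active=False)


@dataclass(frozen=True)
class GateState:
    """Open probabilities of the n, m, h gates (scalars or arrays)."""

    n: np.ndarray | float
    m: np.ndarray | float
    h: np.ndarray | float

    def __post_init__(self):
        for name in ("n", "m", "h"):
            x = np.asarray(getattr(self, name))
            if np.any(x < 0) or np.any(x > 1):
                raise ValueError(f"gate {name} outside [0, 1]")


def vtilde_from_vm(vm: np.ndarray | float, vrest: float) -> np.ndarray | float:
    """Gating voltage (mV): the opposite of the deviation of Vm from rest.

    ``vm`` and ``vrest`` in volts.
    """
    return -(np.asarray(vm, dtype=float) - vrest) * 1e3


def _expm1_ratio(x):
    """x / (exp(x) - 1), with the analytic limit 1 at x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x != 0.0
    out[nz] = x[nz] / np.expm1(x[nz])
    return out


def hh_rates(vtilde):
    """Hodgkin-Huxley rate constants (ms^-1) at gating voltage ``vtilde`` (mV).

    The removable singularities of alpha_n (at vtilde = -10 mV) and alpha_m
    (at vtilde = -25 mV) are filled with their analytic limits (0.1 and 1.0
    ms^-1 respectively), so the functions are total and continuous.

    Returns ``(alpha_n, beta_n, alpha_m, beta_m, alpha_h, beta_h)``,
    each with the shape of ``vtilde``.
    """
    v = np.asarray(vtilde, dtype=float)
    # alpha_n = 0.01 (v+10) / (exp((v+10)/10) - 1) = 0.1 * x/(e^x - 1), x=(v+10)/10
    an = 0.1 * _expm1_ratio((v + 10.0) / 10.0)
    bn = 0.125 * np.exp(v / 80.0)
    # alpha_m = 0.1 (v+25) / (exp((v+25)/10) - 1) = 1.0 * x/(e^x - 1), x=(v+25)/10
    am = 1.0 * _expm1_ratio((v + 25.0) / 10.0)
    bm = 4.0 * np.exp(v / 18.0)
    ah = 0.07 * np.exp(v / 20.0)
    bh = 1.0 / (np.exp((v + 30.0) / 10.0) + 1.0)
    return an, bn, am, bm, ah, bh


def gate_steady_state(alpha, beta):
    """Fixed point alpha/(alpha+beta) of dx/dt = alpha (1-x) - beta x."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    denom = alpha + beta
    if np.any(denom <= 0):
        raise ValueError("gate_steady_state undefined: alpha + beta <= 0")
    return alpha / denom


def resting_gates(vrest: float, vrest_ref: float | None = None) -> GateState:
    """Gate state at steady state for a declared resting potential.

    ``vrest`` is the membrane potential (V); the gating voltage at rest is 0
    by definition (vtilde measures deviation from rest), so this evaluates
    the steady states at vtilde = 0 regardless of ``vrest``.
    """
    an, bn, am, bm, ah, bh = hh_rates(0.0)
    return GateState(
        n=float(gate_steady_state(an, bn)),
        m=float(gate_steady_state(am, bm)),
        h=float(gate_steady_state(ah, bh)),
    )


def step_gates(state: GateState, vtilde, dt_ms: float) -> GateState:
    """One backward-Euler step of the gating ODEs.

    ``x' = (x + dt a) / (1 + dt (a + b))`` keeps x in [0, 1] for any
    dt > 0 and any finite vtilde (the update is a convex-like combination
    of x and the steady state).  ``dt_ms`` in milliseconds, matching the
    ms^-1 rates.
    """
    if not dt_ms > 0:
        raise ValueError("dt must be > 0")
    an, bn, am, bm, ah, bh = hh_rates(vtilde)

    def upd(x, a, b):
        return (np.asarray(x, dtype=float) + dt_ms * a) / (1.0 + dt_ms * (a + b))

    return GateState(n=upd(state.n, an, bn), m=upd(state.m, am, bm),
                     h=upd(state.h, ah, bh))


def ionic_conductance(gates: GateState, p: MembraneParams):
    """Voltage-gated conductances (S/m^2): ``gK = gK_bar n^4``, ``gNa = gNa_bar m^3 h``."""
    n = np.asarray(gates.n, dtype=float)
    m = np.asarray(gates.m, dtype=float)
    h = np.asarray(gates.h, dtype=float)
    return p.gK_bar * n ** 4, p.gNa_bar * m ** 3 * h


def membrane_current_density(vm_new, vm_old, dt: float, gates: GateState | None,
                             p: MembraneParams):
    """Membrane current densities (A/m^2) over a backward-difference step.

    ``vm_new``/``vm_old`` are membrane potentials Vint - V (volts) at the
    new and previous time, ``dt`` in seconds.  Components:

    * capacitive  Ic = cm (vm_new - vm_old) / dt
    * leak        Il = gl (vm_new - El)
    * potassium   IK = gK_bar n^4 (vm_new - EK)      (active only)
    * sodium      INa = gNa_bar m^3 h (vm_new - ENa) (active only)

    Sign convention: positive = outward (intracellular -> extracellular).
    Returns ``(Im, Ic, Il, IK, INa)`` with ``Im`` the exact sum of the
    reported components.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    vm_new = np.asarray(vm_new, dtype=float)
    vm_old = np.asarray(vm_old, dtype=float)
    Ic = p.cm * (vm_new - vm_old) / dt
    Il = p.gl * (vm_new - p.El)
    if p.active:
        if gates is None:
            raise ValueError("active membrane requires a GateState")
        gK, gNa = ionic_conductance(gates, p)
        IK = gK * (vm_new - p.EK)
        INa = gNa * (vm_new - p.ENa)
    else:
        IK = np.zeros_like(Ic)
        INa = np.zeros_like(Ic)
    Im = Ic + Il + IK + INa
    return Im, Ic, Il, IK, INa
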