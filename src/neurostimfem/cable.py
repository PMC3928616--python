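"""Compartmental cable-equation simulation in a precomputed extracellular field.

The neuron is discretized into electrical compartments linked by axial
conductances through the intracellular resistivity Ra.  The extracellular
potential enters the spatially discretized cable equation only through
differences between neighboring compartments (the discrete second spatial
difference — the activating term), so adding a constant to the field leaves
the response unchanged:

    cm_i A_i dVm_i/dt + I_ion,i A_i
        = sum_j g_ij [ (Vm_j + e_j(t)) - (Vm_i + e_i(t)) ],

with ``e_i(t) = Ve_i * f(t)`` the extracellular potential at compartment i
(quasi-static separability) and sealed (no axial flux) ends.  Time stepping
is first-order backward Euler; with active membranes the Hodgkin-Huxley
gates are advanced with the previous step's membrane potential, which keeps
every step a single linear sparse solve without losing the first-order
accuracy of the scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .membrane import (GateState, MembraneParams, ionic_conductance, resting_gates,
                       step_gates, vtilde_from_vm)

__all__ = [
    "Section", "Morphology", "CompartmentalModel", "Waveform", "VmTrace",
    "ThresholdResult", "straight_fiber", "fiber_with_soma", "read_swc",
    "compartmentalize", "simulate", "auto_timestep", "find_threshold",
]


@dataclass
class Section:
    """An unbranched run of 3D points with per-point diameters (meters)."""

    points: np.ndarray          # (n, 3)
    diameters: np.ndarray       # (n,)
    parent: int = -1            # index of parent section, -1 for root
    parent_end: int = 1         # 0 = attach at parent start, 1 = at parent end

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.diameters = np.broadcast_to(
            np.asarray(self.diameters, dtype=float), (len(self.points),)).copy()
        if len(self.points) < 2:
            raise ValueError("a section needs at least two points")
        if np.any(self.diameters <= 0):
            raise ValueError("diameters must be > 0")

    @property
    def arclength(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclength[-1])


@dataclass
class Morphology:
    """A connected, acyclic tree of sections."""

    sections: list[Section]

    def __post_init__(self):
        for i, s in enumerate(self.sections):
            if s.parent >= i:
                raise ValueError("sections must be listed parents-first")
        roots = sum(1 for s in self.sections if s.parent == -1)
        if roots != 1:
            raise ValueError(f"morphology must have exactly one root, got {roots}")

    @property
    def total_length(self) -> float:
        return sum(s.length for s in self.sections)


def straight_fiber(length: float, diameter: float, origin=(0.0, 0.0, 0.0),
                   axis=(0.0, 1.0, 0.0)) -> Morphology:
    """A straight uniform fiber (default along +y), e.g. 260 um x 2 um."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    pts = np.asarray(origin, dtype=float) + np.outer([0.0, length], axis)
    return Morphology([Section(points=pts, diameters=diameter)])


def fiber_with_soma(length: float, fiber_diameter: float, soma_diameter: float,
                    origin=(0.0, 0.0, 0.0), axis=(0.0, 1.0, 0.0)) -> Morphology:
    """A fiber with a soma (wide cylindrical stretch of its own diameter) at its midpoint.

    The soma is modeled as a chain of compartments of diameter
    ``soma_diameter`` and axial extent ``soma_diameter`` centered on the
    fiber axis, flanked by the two fiber arms.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    o = np.asarray(origin, dtype=float)
    arm = (length - soma_diameter) / 2.0
    if arm <= 0:
        raise ValueError("soma longer than the fiber")
    p0, p1, p2, p3 = (o, o + arm * axis, o + (arm + soma_diameter) * axis,
                      o + length * axis)
    s0 = Section(points=np.array([p0, p1]), diameters=fiber_diameter)
    s1 = Section(points=np.array([p1, p2]), diameters=soma_diameter, parent=0)
    s2 = Section(points=np.array([p2, p3]), diameters=fiber_diameter, parent=1)
    return Morphology([s0, s1, s2])


def read_swc(path) -> Morphology:
    """Read an SWC morphology (id, type, x, y, z, radius, parent; microns)."""
    ids, xyz, radius, parent = [], [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            ids.append(int(f[0])); xyz.append([float(f[2]), float(f[3]), float(f[4])])
            radius.append(float(f[5])); parent.append(int(f[6]))
    idx = {i: k for k, i in enumerate(ids)}
    xyz = np.asarray(xyz) * 1e-6
    radius = np.asarray(radius) * 1e-6
    children: dict[int, list[int]] = {}
    for k, p in enumerate(parent):
        if p != -1:
            children.setdefault(idx[p], []).append(k)
    # split into unbranched sections at branch points
    sections: list[Section] = []
    sec_of_node: dict[int, int] = {}
    root = parent.index(-1)

    def walk(start, parent_sec):
        pts, dia = [xyz[start]], [2 * radius[start]]
        node = start
        while True:
            kids = children.get(node, [])
            if len(kids) == 1 and node != start or (node == start and len(kids) == 1):
                node = kids[0]
                pts.append(xyz[node]); dia.append(2 * radius[node])
                if len(children.get(node, [])) != 1:
                    break
            else:
                break
        if len(pts) == 1:
            pts.append(xyz[node] + 1e-9)
            dia.append(dia[0])
        sections.append(Section(points=np.asarray(pts), diameters=np.asarray(dia),
                                parent=parent_sec))
        me = len(sections) - 1
        for kid in children.get(node, []):
            walk(kid, me)

    walk(root, -1)
    return Morphology(sections)


@dataclass
class CompartmentalModel:
    """Electrical compartments plus axial conductances (SI units)."""

    centers: np.ndarray          # (n, 3) m
    lengths: np.ndarray          # (n,) m
    diameters: np.ndarray        # (n,) m
    areas: np.ndarray            # (n,) lateral membrane area, m^2
    edges: np.ndarray            # (k, 2) int compartment pairs
    g_axial: np.ndarray          # (k,) S
    Ra: float                    # Ohm.m
    params: MembraneParams = dfield(default_factory=MembraneParams)
    section_of: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.centers)

    def laplacian(self) -> sp.csr_matrix:
        if not len(self.edges):
            return sp.csr_matrix((self.n, self.n))
        i, j = self.edges.T
        g = self.g_axial
        n = self.n
        rows = np.concatenate([i, j, i, j])
        cols = np.concatenate([j, i, i, j])
        vals = np.concatenate([-g, -g, g, g])
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def compartmentalize(m: Morphology, dx: float, Ra: float = 1.0,
                     params: MembraneParams | None = None) -> CompartmentalModel:
    """Split a morphology into compartments of length <= dx.

    Axial conductance between adjacent compartments combines the two
    half-compartment resistances in series (harmonic combination across a
    diameter change): ``g = 1 / (Ra l_i / (2 a_i) + Ra l_j / (2 a_j))`` with
    ``a = pi d^2 / 4`` the cross-section.  ``Ra`` in Ohm.m.
    """
    if not dx > 0:
        raise ValueError("dx must be > 0")
    params = params or MembraneParams()
    centers, lengths, diams, sec_of = [], [], [], []
    first_last: list[tuple[int, int]] = []
    for si, s in enumerate(m.sections):
        L = s.length
        nseg = max(1, int(math.ceil(L / dx - 1e-9)))
        arc = s.arclength
        edges_s = np.linspace(0.0, L, nseg + 1)
        mids = 0.5 * (edges_s[:-1] + edges_s[1:])
        ctr = np.column_stack([np.interp(mids, arc, s.points[:, k]) for k in range(3)])
        dia = np.interp(mids, arc, s.diameters)
        i0 = len(centers)
        centers.extend(ctr)
        lengths.extend(np.diff(edges_s))
        diams.extend(dia)
        sec_of.extend([si] * nseg)
        first_last.append((i0, i0 + nseg - 1))

    centers = np.asarray(centers)
    lengths = np.asarray(lengths)
    diams = np.asarray(diams)
    areas = np.pi * diams * lengths

    def half_res(i):
        return Ra * (lengths[i] / 2.0) / (np.pi * diams[i] ** 2 / 4.0)

    edges, g_ax = [], []
    for si, s in enumerate(m.sections):
        a, b = first_last[si]
        for i in range(a, b):
            edges.append((i, i + 1))
            g_ax.append(1.0 / (half_res(i) + half_res(i + 1)))
        if s.parent >= 0:
            pa, pb = first_last[s.parent]
            j = pb if s.parent_end == 1 else pa
            edges.append((j, a))
            g_ax.append(1.0 / (half_res(j) + half_res(a)))
    return CompartmentalModel(centers=centers, lengths=lengths, diameters=diams,
                              areas=areas,
                              edges=np.asarray(edges, dtype=int).reshape(-1, 2),
                              g_axial=np.asarray(g_ax), Ra=Ra, params=params,
                              section_of=np.asarray(sec_of, dtype=int))


@dataclass
class Waveform:
    """Piecewise-constant stimulation time course f(t), zero outside its segments.

    ``segments`` is a list of ``(t_start, t_end, value)`` in seconds; a
    cathodal pulse is value -1, an anodal pulse +1 (multiplied by the field).
    """

    segments: list[tuple[float, float, float]]

    def __call__(self, t):
        # backward Euler evaluates the source at the end of each step, so a
        # pulse over [t0, t1] must include its right endpoint: f(t1) drives
        # the step ending exactly at the end of the pulse
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for t0, t1, v in self.segments:
            out = np.where((t > t0) & (t <= t1), v, out)
        return out if out.ndim else float(out)

    @classmethod
    def rect(cls, delay: float, duration: float, value: float = 1.0) -> "Waveform":
        return cls(segments=[(delay, delay + duration, value)])

    def scaled(self, amplitude: float) -> "Waveform":
        return Waveform([(t0, t1, amplitude * v) for t0, t1, v in self.segments])


@dataclass
class VmTrace:
    """Membrane potential (V) on a time grid (s) for every compartment."""

    times: np.ndarray            # (T,)
    vm: np.ndarray               # (T, n)

    def at_time(self, t: float) -> np.ndarray:
        k = int(np.argmin(np.abs(self.times - t)))
        return self.vm[k]

    def to_csv(self, path):
        header = "time_s," + ",".join(f"c{i}" for i in range(self.vm.shape[1]))
        np.savetxt(path, np.column_stack([self.times, self.vm]),
                   delimiter=",", header=header, comments="")

    def to_hdf5(self, path):
        import h5py
        with h5py.File(path, "w") as fh:
            fh.create_dataset("times", data=self.times)
            fh.create_dataset("vm", data=self.vm)


def simulate(model: CompartmentalModel, Ve, w: Waveform, dt: float, T: float,
             V_init: float, vrest: float | None = None,
             gates0: GateState | None = None) -> VmTrace:
    """Backward-Euler integration of the compartmental cable equation.

    ``Ve``: extracellular potential (V) at each compartment center, or a
    callable ``Ve(t) -> array`` for genuinely time-varying fields (then
    ``w`` is still applied multiplicatively).  ``V_init`` initializes Vm
    everywhere; ``vrest`` (default ``V_init``) is the reference for the
    Hodgkin-Huxley gating voltage when the membrane is active.
    """
    n = model.n
    p = model.params
    callable_ve = callable(Ve)
    if not callable_ve:
        Ve = np.asarray(Ve, dtype=float)
        if Ve.shape != (n,):
            raise ValueError(f"Ve must have shape ({n},), got {Ve.shape}")
    if not dt > 0:
        raise ValueError("dt must be > 0")
    L = model.laplacian().tocsc()
    A = model.areas
    C = p.cm * A / dt
    vrest = V_init if vrest is None else vrest

    nsteps = int(round(T / dt))
    times = np.arange(nsteps + 1) * dt
    vm = np.empty((nsteps + 1, n))
    vm[0] = V_init

    gates = None
    if p.active:
        gates = gates0 or resting_gates(vrest)
        gates = GateState(n=np.broadcast_to(np.asarray(gates.n, float), (n,)).copy(),
                          m=np.broadcast_to(np.asarray(gates.m, float), (n,)).copy(),
                          h=np.broadcast_to(np.asarray(gates.h, float), (n,)).copy())

    I = sp.identity(n, format="csc")
    solver = None
    v = vm[0].copy()
    for k in range(nsteps):
        t_new = times[k + 1]
        if p.active:
            gates = step_gates(gates, vtilde_from_vm(v, vrest), dt * 1e3)
            gK, gNa = ionic_conductance(gates, p)
            g_tot = p.gl + gK + gNa
            r_ion = p.gl * p.El + gK * p.EK + gNa * p.ENa
            M = sp.diags(C + A * g_tot) + L
            solver = spla.factorized(M.tocsc())
        else:
            g_tot = p.gl
            r_ion = p.gl * p.El
            if solver is None:
                M = sp.diags(C + A * g_tot) + L
                solver = spla.factorized(M.tocsc())
        ve_now = np.asarray(Ve(t_new), dtype=float) if callable_ve else Ve
        e = ve_now * float(w(t_new))
        rhs = C * v + A * r_ion - L @ e
        v = solver(rhs)
        if not np.all(np.isfinite(v)):
            raise FloatingPointError(f"non-finite membrane potential at step {k + 1}"
                                     f" (t = {t_new:.6g} s)")
        vm[k + 1] = v
    return VmTrace(times=times, vm=vm)


def auto_timestep(model: CompartmentalModel, Ve, w: Waveform, T: float,
                  V_init: float, dt0: float, dt_floor: float = 1e-6,
                  rtol: float = 0.01) -> float:
    """Largest dt in {dt0, dt0/10, ...} whose solution agrees with dt/10.

    Agreement is measured at the end-time compartment with the largest
    |Vm - V_init| (relative difference < ``rtol``, normalized by the peak
    deviation).  Raises if the criterion is still unmet at ``dt_floor``.
    """
    dt = dt0
    while True:
        coarse = simulate(model, Ve, w, dt, T, V_init).vm[-1]
        fine = simulate(model, Ve, w, dt / 10.0, T, V_init).vm[-1]
        dev = np.abs(fine - V_init)
        scale = dev.max()
        if scale == 0.0:
            return dt
        i = int(np.argmax(dev))
        if abs(coarse[i] - fine[i]) / scale < rtol:
            return dt
        if dt / 10.0 < dt_floor:
            raise RuntimeError(
                f"timestep criterion unmet at floor {dt_floor:g} s "
                f"(achieved relative difference {abs(coarse[i]-fine[i])/scale:.3g})")
        dt /= 10.0


@dataclass
class ThresholdResult:
    amplitude: float
    converged: bool
    above_bracket: bool
    iterations: int


def find_threshold(model: CompartmentalModel, Ve, pulse: Waveform, detect: float,
                   bracket: tuple[float, float], tol: float = 0.01,
                   dt: float = 5e-5, T: float | None = None, V_init: float = -65e-3,
                   max_iter: int = 60) -> ThresholdResult:
    """Bisection (dichotomy) on the global stimulus amplitude for a spike.

    A spike is any compartment's Vm exceeding ``detect`` (V) at any time.
    ``bracket = (lo, hi)`` must satisfy: no spike at lo.  If hi does not
    elicit a spike the result is flagged ``above_bracket`` rather than
    raising.  ``tol`` is the relative bracket width at convergence.
    """
    lo, hi = bracket
    if T is None:
        T = max(t1 for _, t1, _ in pulse.segments) + 5e-3

    def spikes(amp: float) -> bool:
        tr = simulate(model, Ve, pulse.scaled(amp), dt, T, V_init)
        return bool(np.any(tr.vm > detect))

    if spikes(lo):
        raise ValueError("lower bracket already elicits a spike")
    if not spikes(hi):
        return ThresholdResult(amplitude=hi, converged=False, above_bracket=True,
                               iterations=0)
    it = 0
    while (hi - lo) / hi > tol and it < max_iter:
        mid = 0.5 * (lo + hi)
        if spikes(mid):
            hi = mid
        else:
            lo = mid
        it += 1
    return ThresholdResult(amplitude=hi, converged=(hi - lo) / hi <= tol,
                           above_bracket=False, iterations=it)
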