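"""Whole-FEM thin-film pathway: coupled intra/extracellular Poisson problems.

The neuron membrane is a zero-thickness interface: instead of meshing the
membrane volume, the degrees of freedom on the membrane surface are
duplicated so the extracellular potential V and the intracellular
potential Vint are independent fields with separate traces, coupled only
through the membrane current density

    Im = cm d(Vint - V)/dt + gl (Vint - V - El) [+ IK + INa],

which enters the extracellular weak form as an inflow (+Im) and the
intracellular weak form with the opposite sign.  One backward-Euler step
of the pair is a single monolithic symmetric sparse solve; with active
membranes the Hodgkin-Huxley gates are advanced with the previous step's
membrane potential (staggering keeps the step linear).  The stimulation
electrode's Robin boundary condition is time dependent, Vref = V0 f(t).

The membrane mass is lumped (row sums), so membrane currents and gate
variables live pointwise on interface nodes; testing the intracellular
equation with the constant function then shows the discrete closed-membrane
balance  ∮ Im dS = 0  holds to solver precision at every step.

Both fields use linear Lagrange elements; the mesh is refined near the
membrane, which is also what the linear-element route requires of the
interface region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem import FESpace
from .field import BoundaryCondition, ConductivityMap
from .mesh import Mesh, triangle_areas
from .membrane import (GateState, MembraneParams, ionic_conductance,
                       resting_gates, step_gates, vtilde_from_vm)
from .cable import Waveform

__all__ = ["CoupledProblem", "CoupledState", "MembraneProfile",
           "build_coupled_problem", "step", "solve_transient",
           "extract_membrane_profile", "membrane_current_integrals"]


@dataclass
class CoupledProblem:
    """Assembled two-domain problem with duplicated membrane dofs.

    Degrees of freedom are ordered [extracellular nodes | intracellular
    nodes]; nodes on the membrane appear once in each block (duplication),
    carrying the per-side traces of V and Vint.
    """

    mesh: Mesh
    sigma_ext: float
    sigma_int: float
    membrane: MembraneParams
    bcs: dict[str, BoundaryCondition]
    stim_tag: str
    V0: float
    # assembled structure
    ext_nodes: np.ndarray = dfield(repr=False, default=None)
    int_nodes: np.ndarray = dfield(repr=False, default=None)
    mem_nodes: np.ndarray = dfield(repr=False, default=None)
    mem_ext_dof: np.ndarray = dfield(repr=False, default=None)
    mem_int_dof: np.ndarray = dfield(repr=False, default=None)
    K_ext: sp.csr_matrix = dfield(repr=False, default=None)
    K_int: sp.csr_matrix = dfield(repr=False, default=None)
    R_ext: sp.csr_matrix = dfield(repr=False, default=None)
    b_stim_unit: np.ndarray = dfield(repr=False, default=None)
    b_fixed: np.ndarray = dfield(repr=False, default=None)
    mem_lump: np.ndarray = dfield(repr=False, default=None)

    @property
    def n_ext(self) -> int:
        return len(self.ext_nodes)

    @property
    def n_int(self) -> int:
        return len(self.int_nodes)

    @property
    def ndof(self) -> int:
        return self.n_ext + self.n_int


def build_coupled_problem(mesh: Mesh, sigma_ext: float, sigma_int: float,
                          membrane: MembraneParams,
                          bcs: dict[str, BoundaryCondition], stim_tag: str,
                          V0: float, element_orders: tuple[int, int] = (1, 1)
                          ) -> CoupledProblem:
    """Assemble the coupled problem on a mesh with an embedded membrane.

    ``sigma_int`` is the intracellular conductivity (= 1/Ra in SI units);
    ``V0`` scales the stimulation Robin reference, Vref = V0 f(t).
    ``element_orders`` other than (1, 1) are rejected: this implementation
    resolves both domains with linear elements on a membrane-refined mesh.
    """
    for tag in ("intracellular", "extracellular"):
        if tag not in mesh.subdomain_tags:
            raise ValueError(f"mesh lacks subdomain tag '{tag}'")
    if "membrane" not in mesh.facet_tags:
        raise ValueError("mesh lacks the 'membrane' facet tag")
    if element_orders != (1, 1):
        raise NotImplementedError("only linear/linear element orders are "
                                  "supported by the coupled solver")
    if stim_tag not in bcs or bcs[stim_tag].kind != "robin":
        raise ValueError(f"stimulation tag '{stim_tag}' must carry a robin BC")

    it = mesh.subdomain_tags["intracellular"]
    et = mesh.subdomain_tags["extracellular"]
    mem_tris = mesh.facet_tags["membrane"]
    ext_nodes = np.unique(mesh.tets[et].ravel())
    int_nodes = np.unique(mesh.tets[it].ravel())
    mem_nodes = np.unique(mem_tris.ravel())

    # local numbering
    ext_of = {int(n): k for k, n in enumerate(ext_nodes)}
    int_of = {int(n): k for k, n in enumerate(int_nodes)}
    mem_ext = np.array([ext_of[int(n)] for n in mem_nodes], dtype=np.int64)
    mem_int = np.array([int_of[int(n)] for n in mem_nodes], dtype=np.int64)

    space = FESpace(mesh, 1)
    sig = np.empty(mesh.n_tets)
    sig[et] = sigma_ext
    sig[it] = sigma_int
    K_full_ext = _restrict(space.assemble_stiffness(
        np.where(np.isin(np.arange(mesh.n_tets), et), sigma_ext, 0.0)), ext_nodes)
    K_full_int = _restrict(space.assemble_stiffness(
        np.where(np.isin(np.arange(mesh.n_tets), it), sigma_int, 0.0)), int_nodes)

    # exterior Robin terms and the unit-stimulus load
    R_ext = sp.csr_matrix((len(ext_nodes), len(ext_nodes)))
    b_stim = np.zeros(len(ext_nodes))
    b_fixed = np.zeros(len(ext_nodes))
    for tag, bc in bcs.items():
        if bc.kind != "robin":
            if bc.kind == "dirichlet":
                raise NotImplementedError("dirichlet exterior BCs are not "
                                          "supported in the coupled solver; "
                                          "use a high-g robin BC")
            continue
        tris = mesh.facet_tags[tag]
        M = _restrict(space.assemble_boundary_mass(tris), ext_nodes)
        load = space.assemble_boundary_load(tris)[ext_nodes]
        R_ext = R_ext + bc.g * M
        if tag == stim_tag:
            b_stim += bc.g * load          # times V0 f(t)
        elif bc.V0 != 0.0:
            b_fixed += bc.g * bc.V0 * load
    lump = space.lumped_boundary_mass(mem_tris)[mem_nodes]

    return CoupledProblem(mesh=mesh, sigma_ext=sigma_ext, sigma_int=sigma_int,
                          membrane=membrane, bcs=bcs, stim_tag=stim_tag, V0=V0,
                          ext_nodes=ext_nodes, int_nodes=int_nodes,
                          mem_nodes=mem_nodes, mem_ext_dof=mem_ext,
                          mem_int_dof=mem_int, K_ext=K_full_ext,
                          K_int=K_full_int, R_ext=R_ext,
                          b_stim_unit=b_stim, b_fixed=b_fixed, mem_lump=lump)


def _restrict(A: sp.spmatrix, nodes: np.ndarray) -> sp.csr_matrix:
    return A.tocsr()[nodes, :][:, nodes]


@dataclass
class CoupledState:
    """Fields at one time instant (dofs in problem-local numbering)."""

    time: float
    V: np.ndarray          # extracellular nodal potentials
    Vint: np.ndarray       # intracellular nodal potentials
    gates: GateState | None

    def vm_membrane(self, problem: CoupledProblem) -> np.ndarray:
        """Membrane potential Vint - V on the interface nodes."""
        return (self.Vint[problem.mem_int_dof] - self.V[problem.mem_ext_dof])


def initial_state(problem: CoupledProblem, vrest: float | None = None
                  ) -> CoupledState:
    """Rest: V = 0, Vint = resting potential, gates at their fixed point."""
    p = problem.membrane
    vrest = p.El if vrest is None else vrest
    nm = len(problem.mem_nodes)
    gates = None
    if p.active:
        g0 = resting_gates(vrest)
        gates = GateState(n=np.full(nm, g0.n), m=np.full(nm, g0.m),
                          h=np.full(nm, g0.h))
    return CoupledState(time=0.0, V=np.zeros(problem.n_ext),
                        Vint=np.full(problem.n_int, vrest), gates=gates)


class _StepOperator:
    """Factorized monolithic matrix for a fixed dt (reused across steps)."""

    def __init__(self, problem: CoupledProblem, dt: float,
                 a_mem: np.ndarray):
        ne, ni = problem.n_ext, problem.n_int
        aw = a_mem * problem.mem_lump        # lumped membrane conductance, S
        D_ee = sp.coo_matrix((aw, (problem.mem_ext_dof, problem.mem_ext_dof)),
                             shape=(ne, ne))
        D_ii = sp.coo_matrix((aw, (problem.mem_int_dof, problem.mem_int_dof)),
                             shape=(ni, ni))
        C_ei = sp.coo_matrix((aw, (problem.mem_ext_dof, problem.mem_int_dof)),
                             shape=(ne, ni))
        A = sp.bmat([[problem.K_ext + problem.R_ext + D_ee, -C_ei],
                     [-C_ei.T, problem.K_int + D_ii]], format="csc")
        self.solver = spla.factorized(A)
        self.A = A


def step(problem: CoupledProblem, state: CoupledState, f_t: float, dt: float,
         operator: _StepOperator | None = None) -> CoupledState:
    """One implicit step of the coupled system to time ``state.time + dt``.

    ``f_t`` is the stimulation time course evaluated at the new time.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    p = problem.membrane
    vm_old = state.vm_membrane(problem)
    gates = state.gates
    if p.active:
        gates = step_gates(gates, vtilde_from_vm(vm_old, p.El), dt * 1e3)
        gK, gNa = ionic_conductance(gates, p)
        g_tot = p.gl + gK + gNa
        r = p.cm / dt * vm_old + p.gl * p.El + gK * p.EK + gNa * p.ENa
    else:
        g_tot = np.full(len(vm_old), p.gl)
        r = p.cm / dt * vm_old + p.gl * p.El
    a = p.cm / dt + g_tot
    if operator is None or p.active:
        operator = _StepOperator(problem, dt, a)
    ne = problem.n_ext
    rhs = np.zeros(problem.ndof)
    rhs[:ne] = problem.b_fixed + problem.V0 * float(f_t) * problem.b_stim_unit
    w = problem.mem_lump * r
    np.subtract.at(rhs[:ne], problem.mem_ext_dof, w)
    rhs_int = np.zeros(problem.n_int)
    np.add.at(rhs_int, problem.mem_int_dof, w)
    rhs[ne:] = rhs_int
    x = operator.solver(rhs)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError(f"coupled solve produced non-finite values at "
                                 f"t = {state.time + dt:.6g} s")
    return CoupledState(time=state.time + dt, V=x[:ne], Vint=x[ne:],
                        gates=gates)


def solve_transient(problem: CoupledProblem, waveform: Waveform, dt: float,
                    T: float, snapshot_times=None, vrest: float | None = None
                    ) -> list[CoupledState]:
    """Run the coupled solver over [0, T]; returns the requested snapshots.

    ``snapshot_times`` defaults to the final time only.  With a passive
    membrane and fixed dt the monolithic matrix is factorized once.
    """
    state = initial_state(problem, vrest)
    nsteps = int(round(T / dt))
    snaps_wanted = sorted(snapshot_times) if snapshot_times is not None else [T]
    out: list[CoupledState] = []
    op = None
    if not problem.membrane.active:
        a = np.full(len(problem.mem_nodes),
                    problem.membrane.cm / dt + problem.membrane.gl)
        op = _StepOperator(problem, dt, a)
    si = 0
    for k in range(nsteps):
        t_new = (k + 1) * dt
        state = step(problem, state, float(waveform(t_new)), dt, operator=op)
        while si < len(snaps_wanted) and t_new >= snaps_wanted[si] - dt / 2:
            out.append(state)
            si += 1
    if not out:
        out.append(state)
    return out


def membrane_current_integrals(problem: CoupledProblem, state: CoupledState,
                               prev: CoupledState, dt: float
                               ) -> tuple[float, float]:
    """(∮ Im dS, ∮ |Im| dS) over the closed membrane at this step (A)."""
    p = problem.membrane
    vm_new = state.vm_membrane(problem)
    vm_old = prev.vm_membrane(problem)
    from .membrane import membrane_current_density
    Im, *_ = membrane_current_density(vm_new, vm_old, dt,
                                      state.gates, p)
    w = problem.mem_lump
    return float(np.sum(w * Im)), float(np.sum(w * np.abs(Im)))


@dataclass
class MembraneProfile:
    """Membrane potential sampled along a path on the interface."""

    arclength: np.ndarray      # strictly increasing coordinate (m)
    vm: np.ndarray             # (V)
    side: str                  # "bottom" (facing electrode) or "top"


def extract_membrane_profile(problem: CoupledProblem, state: CoupledState,
                             side: str, axis=(0.0, 1.0, 0.0),
                             origin=None, band_deg: float = 50.0,
                             nbins: int | None = None) -> MembraneProfile:
    """Vm profile along the membrane on the electrode-facing or opposite side.

    Interface nodes are assigned an arclength coordinate by projection on
    the neuron axis and split by the angle of their radial offset: nodes
    within ``band_deg`` of straight down (-z) belong to the "bottom"
    (electrode-facing) side, within the same band of +z to the "top".
    Nodes are averaged in arclength bins so the coordinate is strictly
    increasing.
    """
    if side not in ("bottom", "top"):
        raise ValueError("side must be 'bottom' or 'top'")
    mesh = problem.mesh
    nodes = mesh.nodes[problem.mem_nodes]
    d = np.asarray(axis, dtype=float)
    d /= np.linalg.norm(d)
    if origin is None:
        origin = nodes.mean(axis=0)
    rel = nodes - origin
    s = rel @ d
    radial = rel - np.outer(s, d)
    rnorm = np.linalg.norm(radial, axis=1)
    rnorm[rnorm == 0] = 1.0
    cos_down = -radial[:, 2] / rnorm          # 1 = straight toward substrate
    want = cos_down if side == "bottom" else -cos_down
    sel = want >= math.cos(math.radians(band_deg))
    if not np.any(sel):
        raise ValueError(f"no membrane nodes on the {side} side within "
                         f"{band_deg} degrees")
    vm = state.vm_membrane(problem)[sel]
    ss = s[sel]
    if nbins is None:
        nbins = max(20, int(math.sqrt(sel.sum()) * 2))
    edges = np.linspace(ss.min() - 1e-12, ss.max() + 1e-12, nbins + 1)
    idx = np.digitize(ss, edges) - 1
    arc, vals = [], []
    for b in range(nbins):
        m = idx == b
        if m.any():
            arc.append(ss[m].mean())
            vals.append(vm[m].mean())
    return MembraneProfile(arclength=np.asarray(arc), vm=np.asarray(vals),
                           side=side)
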