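"""Quasi-static extracellular potential: Poisson solve with electrode BCs.

Solves ``-div(sigma grad V) = 0`` on a tagged tetrahedral mesh with, per
facet tag, one of three boundary conditions:

* ``insulating``  — homogeneous Neumann, ``sigma grad V . n = 0``;
* ``robin``       — electrode-electrolyte interface with finite surface
  conductance ``g`` (S/m^2): ``sigma grad V . n + g V = g V0``, ``V0`` the
  metal-side potential;
* ``dirichlet``   — fixed potential (the infinitely conductive limit).

Any exterior facet tag without an entry is insulating.  The surface
conductance may also be given as an electrode impedance ``Z`` (Ohm) via
``BoundaryCondition.robin_from_impedance`` (g = 1 / (Z S_elec)).

Current convention: :func:`integrate_boundary_current` returns
``int sigma grad V . n ds`` with ``n`` the outward normal — the current
injected *into* the medium through that surface (positive = anodic
source).  Summed over all conducting boundaries this vanishes.  On Robin
boundaries the integral is evaluated through the boundary condition itself,
``int g (V0 - V) ds``, which is exact for the continuous solution and far
more accurate in the discrete one than differentiating V; the
gradient-quadrature version remains available as
:func:`gradient_boundary_current` for cross-checks and non-Robin tags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem import FESpace, PointLocator
from .mesh import Mesh

__all__ = [
    "ConductivityMap", "BoundaryCondition", "FieldProblem", "FieldSolution",
    "solve_field", "integrate_boundary_current", "gradient_boundary_current",
    "calibrate_stimulus", "sample_potential",
]


@dataclass(frozen=True)
class ConductivityMap:
    """Conductivity (S/m) per subdomain tag, with a default for untagged tets."""

    default: float | None = 0.2
    by_tag: dict[str, float] = dfield(default_factory=dict)

    def __post_init__(self):
        for tag, s in self.by_tag.items():
            if not s > 0:
                raise ValueError(f"conductivity for '{tag}' must be > 0, got {s}")
        if self.default is not None and not self.default > 0:
            raise ValueError("default conductivity must be > 0")

    def per_tet(self, mesh: Mesh) -> np.ndarray:
        if self.default is None:
            sig = np.full(mesh.n_tets, np.nan)
        else:
            sig = np.full(mesh.n_tets, float(self.default))
        for tag, s in self.by_tag.items():
            if tag not in mesh.subdomain_tags:
                raise KeyError(f"subdomain tag '{tag}' not in mesh")
            sig[mesh.subdomain_tags[tag]] = s
        if np.any(np.isnan(sig)):
            raise ValueError("some tetrahedra have no conductivity "
                             "(no default and not covered by any tag)")
        return sig


@dataclass(frozen=True)
class BoundaryCondition:
    """One of insulating | robin | dirichlet (see module docstring)."""

    kind: str
    g: float = 0.0          # surface conductance, S/m^2 (robin)
    V0: float = 0.0         # metal-side potential, V (robin)
    V: float = 0.0          # fixed potential, V (dirichlet)

    def __post_init__(self):
        if self.kind not in ("insulating", "robin", "dirichlet"):
            raise ValueError(f"unknown BC kind {self.kind!r}")
        if self.kind == "robin" and not self.g > 0:
            raise ValueError(f"robin BC requires g > 0, got {self.g}")

    @classmethod
    def insulating(cls) -> "BoundaryCondition":
        return cls(kind="insulating")

    @classmethod
    def robin(cls, g: float, V0: float = 0.0) -> "BoundaryCondition":
        return cls(kind="robin", g=g, V0=V0)

    @classmethod
    def robin_from_impedance(cls, Z: float, area: float,
                             V0: float = 0.0) -> "BoundaryCondition":
        """Robin BC from electrode impedance Z (Ohm) and area (m^2)."""
        return cls(kind="robin", g=1.0 / (Z * area), V0=V0)

    @classmethod
    def dirichlet(cls, V: float = 0.0) -> "BoundaryCondition":
        return cls(kind="dirichlet", V=V)


@dataclass
class FieldProblem:
    """A Poisson boundary-value problem on a tagged mesh.

    ``element_order`` defaults to quadratic Lagrange; linear is the choice
    for large meshes and for the coupled (whole-FEM) pathway.
    """

    mesh: Mesh
    conductivity: ConductivityMap = dfield(default_factory=ConductivityMap)
    bcs: dict[str, BoundaryCondition] = dfield(default_factory=dict)
    element_order: int = 2

    def __post_init__(self):
        for tag in self.bcs:
            if tag not in self.mesh.facet_tags:
                raise KeyError(f"BC tag '{tag}' not in mesh facet tags "
                               f"{sorted(self.mesh.facet_tags)}")
        if not any(bc.kind in ("robin", "dirichlet") for bc in self.bcs.values()):
            raise ValueError("ill-posed problem: need at least one robin or "
                             "dirichlet boundary condition")

    def with_bc(self, tag: str, bc: BoundaryCondition) -> "FieldProblem":
        bcs = dict(self.bcs)
        bcs[tag] = bc
        return FieldProblem(mesh=self.mesh, conductivity=self.conductivity,
                            bcs=bcs, element_order=self.element_order)


@dataclass
class FieldSolution:
    """Finite-element solution: coefficients (V) over a Lagrange space.

    ``K`` and ``b`` are the assembled (Robin-augmented) operator and load;
    they allow variationally consistent boundary-flux recovery on
    Dirichlet tags via the residual.
    """

    problem: FieldProblem
    space: FESpace
    u: np.ndarray
    K: sp.csr_matrix | None = None
    b: np.ndarray | None = None
    _locator: PointLocator | None = None

    def locator(self) -> PointLocator:
        if self._locator is None:
            self._locator = PointLocator(self.problem.mesh)
        return self._locator

    def evaluate(self, points) -> np.ndarray:
        """Finite-element interpolation of V at interior points."""
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        tet, lam = self.locator().locate(points)
        if np.any(tet < 0):
            bad = points[tet < 0]
            raise ValueError(f"{len(bad)} point(s) outside the meshed domain, "
                             f"first: {bad[0].tolist()}")
        return self.space.eval_in_tets(self.u, tet, np.clip(lam, 0.0, 1.0))


_DIRECT_DOF_LIMIT = 400_000


def solve_field(problem: FieldProblem, rtol: float = 1e-8) -> FieldSolution:
    """Galerkin solve with Lagrange elements of the requested order.

    Direct sparse factorization below ``_DIRECT_DOF_LIMIT`` degrees of
    freedom, conjugate gradients with an incomplete-factorization
    preconditioner above it.
    """
    mesh = problem.mesh
    space = FESpace(mesh, problem.element_order)
    sig = problem.conductivity.per_tet(mesh)
    K = space.assemble_stiffness(sig).tolil()
    b = np.zeros(space.ndof)
    dirichlet_dofs, dirichlet_vals = [], []
    K = K.tocsr()
    for tag, bc in problem.bcs.items():
        tris = mesh.facet_tags[tag]
        if not len(tris):
            continue
        if bc.kind == "robin":
            K = K + bc.g * space.assemble_boundary_mass(tris)
            if bc.V0 != 0.0:
                b += bc.g * bc.V0 * space.assemble_boundary_load(tris)
        elif bc.kind == "dirichlet":
            dofs = space.facet_dof_set(tris)
            dirichlet_dofs.append(dofs)
            dirichlet_vals.append(np.full(len(dofs), bc.V))
    if dirichlet_dofs:
        fixed = np.concatenate(dirichlet_dofs)
        vals = np.concatenate(dirichlet_vals)
        fixed, order = np.unique(fixed, return_index=True)
        vals = vals[order]
        free = np.setdiff1d(np.arange(space.ndof), fixed, assume_unique=False)
        u = np.zeros(space.ndof)
        u[fixed] = vals
        Kcsc = K.tocsc()
        rhs = b[free] - Kcsc[:, fixed][free, :] @ vals
        Kff = Kcsc[free, :][:, free]
        u[free] = _linear_solve(Kff.tocsc(), rhs, rtol)
        sol = u
    else:
        sol = _linear_solve(K.tocsc(), b, rtol)
    return FieldSolution(problem=problem, space=space, u=sol, K=K.tocsr(), b=b)


def _linear_solve(A: sp.csc_matrix, b: np.ndarray, rtol: float) -> np.ndarray:
    if A.shape[0] <= _DIRECT_DOF_LIMIT:
        x = spla.splu(A).solve(b)
    else:
        ilu = spla.spilu(A, drop_tol=1e-5, fill_factor=10)
        M = spla.LinearOperator(A.shape, ilu.solve)
        x, info = spla.cg(A, b, rtol=rtol, maxiter=5000, M=M)
        if info != 0:
            raise RuntimeError(f"CG did not converge (info={info})")
    res = np.linalg.norm(A @ x - b)
    scale = max(np.linalg.norm(b), 1e-300)
    if b.any() and res / scale > max(1e3 * rtol, 1e-5):
        raise RuntimeError(f"linear solver did not converge: relative residual "
                           f"{res / scale:.3g}")
    return x


def integrate_boundary_current(sol: FieldSolution, tag: str) -> float:
    """Signed current (A) injected into the medium through the tagged surface.

    Robin tags use the boundary condition itself (``int g (V0 - V) ds``);
    Dirichlet tags use the residual of the assembled system (the
    variationally consistent flux); plain Neumann tags fall back to
    gradient quadrature.
    """
    problem = sol.problem
    if tag not in problem.mesh.facet_tags:
        raise KeyError(f"tag '{tag}' not in mesh facet tags")
    bc = problem.bcs.get(tag, BoundaryCondition.insulating())
    tris = problem.mesh.facet_tags[tag]
    if not len(tris):
        return 0.0
    if bc.kind == "robin":
        load = sol.space.assemble_boundary_load(tris)
        area = load.sum()
        return float(bc.g * (bc.V0 * area - load @ sol.u))
    if bc.kind == "dirichlet" and sol.K is not None:
        # residual rows on the fixed dofs carry int sigma grad(V).n phi_i ds
        dofs = sol.space.facet_dof_set(tris)
        resid = sol.K[dofs, :] @ sol.u - sol.b[dofs]
        return float(resid.sum())
    return gradient_boundary_current(sol, tag)


def gradient_boundary_current(sol: FieldSolution, tag: str) -> float:
    """``int sigma grad V . n ds`` over the tagged facets by quadrature."""
    mesh = sol.problem.mesh
    tris = mesh.facet_tags[tag]
    owners_list = mesh.facet_owners(tris)
    if any(len(o) == 0 for o in owners_list):
        raise ValueError(f"tag '{tag}' has facets that are not tet faces")
    if any(len(o) > 1 for o in owners_list):
        raise ValueError(f"tag '{tag}' is an interior interface, not a boundary")
    owners = np.array([o[0] for o in owners_list], dtype=np.int64)
    sig = sol.problem.conductivity.per_tet(mesh)
    return sol.space.gradient_flux(sol.u, tris, owners, sig)


def calibrate_stimulus(problem: FieldProblem, stim_tag: str, I_target: float,
                       ground_tag: str | None = None
                       ) -> tuple[float, FieldSolution]:
    """Two-pass calibration of the stimulation V0 to a nominal current.

    Pass 1 solves with V0 = 1 V on ``stim_tag`` and measures the delivered
    current on the *larger* of the stimulation electrode and the return
    electrode (current-density integration is most trustworthy on the
    surface with the most facets).  Pass 2 rescales V0 by the target/measured
    ratio and re-solves; the problem is linear so one rescale is exact up to
    solver tolerance.  Returns ``(V0, solution)``.
    """
    mesh = problem.mesh
    bc = problem.bcs.get(stim_tag)
    if bc is None or bc.kind != "robin":
        raise ValueError(f"stimulation tag '{stim_tag}' must carry a robin BC")
    if ground_tag is None:
        candidates = [t for t, c in problem.bcs.items()
                      if t != stim_tag and c.kind in ("robin", "dirichlet")]
        if not candidates:
            raise ValueError("no return electrode found among the BCs")
        ground_tag = max(candidates, key=mesh.facet_area)
    p1 = problem.with_bc(stim_tag, replace(bc, V0=1.0))
    sol1 = solve_field(p1)
    if mesh.facet_area(ground_tag) > mesh.facet_area(stim_tag):
        I_meas = -integrate_boundary_current(sol1, ground_tag)
    else:
        I_meas = integrate_boundary_current(sol1, stim_tag)
    if I_meas == 0.0 or not math.isfinite(I_meas):
        raise RuntimeError(f"calibration failed: measured current {I_meas} "
                           f"with V0 = 1 V (disconnected electrode?)")
    V0 = I_target / I_meas
    p2 = problem.with_bc(stim_tag, replace(bc, V0=V0))
    return V0, solve_field(p2)


def approx_electrode_current(problem: FieldProblem, stim_tag: str,
                             V0: float) -> float:
    """High-impedance small-electrode estimate ``I = g V0 S_elec``.

    Valid when the potential in the medium in front of the electrode is
    small compared to V0; the two-pass calibrated integral is authoritative.
    """
    bc = problem.bcs[stim_tag]
    return bc.g * V0 * problem.mesh.facet_area(stim_tag)


def sample_potential(sol: FieldSolution, points, export_path=None) -> np.ndarray:
    """Interpolate V at the given points (e.g. compartment centers).

    Output order matches input order.  ``export_path`` writes a
    tab-separated file with columns x, y, z, V.
    """
    values = sol.evaluate(points)
    if export_path is not None:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        np.savetxt(export_path, np.column_stack([pts, values]), delimiter="\t",
                   header="x\ty\tz\tV", comments="")
    return values
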