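"""End-to-end MEA stimulation experiments and their comparison metrics.

Three reproducible scenarios, each generating its own fixtures
programmatically:

* :func:`run_focality` — profile of the stimulating potential 50 um above
  the stimulation electrode for the monopolar configuration versus the
  ground-surface configuration at increasing surface conductance g; the
  focality statistic is the full width at half maximum (FWHM) of the
  normalized profile.
* :func:`run_mirror_fiber` — hybrid pipeline on a 260-um passive fiber at
  z = 50 um over the stimulation electrode, -1 uA cathodic 1-ms pulse:
  the end-of-pulse membrane polarization is the mirror image of the
  extracellular potential centered on its spatial average.
* :func:`run_comparison` — hybrid versus whole-FEM (thin film) on the
  same mesh, for the uniform fiber and for the fiber with a 20-um soma;
  reports fiber-end agreement and bottom/top (electrode-facing/opposite)
  membrane-side asymmetry.

Default parameters are the bundled study conditions: sigma = 0.2 S/m,
g_GS = 500 S/m^2 (platinum-like), Ra = 100 Ohm.cm, cm = 1 uF/cm^2,
gl = 1e-4 mS/cm^2, El = -65 mV, passive membranes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np

from . import cable, coupled
from .cable import Waveform, compartmentalize, simulate, straight_fiber
from .field import (BoundaryCondition, ConductivityMap, FieldProblem,
                    calibrate_stimulus, sample_potential, solve_field)
from .geometry import (Feature, MEAParams, NeuronGeometrySpec,
                       build_mea_chamber, embed_neuron_surface)
from .membrane import MembraneParams, mS_per_cm2, mV, ohm_cm, uF_per_cm2

__all__ = [
    "FocalityConfig", "FocalityResult", "run_focality",
    "MirrorConfig", "MirrorReport", "run_mirror_fiber",
    "ComparisonConfig", "ComparisonReport", "run_comparison",
    "fwhm", "paper_membrane",
]


def paper_membrane() -> MembraneParams:
    """The passive parameter set of the bundled scenarios."""
    return MembraneParams(cm=uF_per_cm2(1.0), gl=mS_per_cm2(1e-4),
                          El=mV(-65.0), active=False)


PAPER_RA = ohm_cm(100.0)       # 1.0 Ohm.m
PAPER_SIGMA = 0.2              # S/m
PAPER_G_GS = 500.0             # S/m^2
PAPER_SIGMA_INT = 1.0 / PAPER_RA   # 1 S/m


# ---------------------------------------------------------------------------
# FWHM

def fwhm(s: np.ndarray, values: np.ndarray) -> float:
    """Full width at half maximum by linear interpolation.

    Requires a unique interior maximum with the half level crossed on both
    sides; raises ValueError otherwise.
    """
    s = np.asarray(s, dtype=float)
    v = np.asarray(values, dtype=float)
    imax = int(np.argmax(v))
    vmax = v[imax]
    if np.count_nonzero(v == vmax) > 1:
        raise ValueError("profile maximum is not unique")
    half = vmax / 2.0
    left = v[:imax + 1]
    right = v[imax:]
    if left.min() > half or right.min() > half:
        raise ValueError("half level not crossed on both sides of the peak")
    il = np.nonzero(left <= half)[0][-1]
    sl = np.interp(half, [v[il], v[il + 1]], [s[il], s[il + 1]])
    irr = np.nonzero(right <= half)[0][0] + imax
    sr = np.interp(half, [v[irr], v[irr - 1]], [s[irr], s[irr - 1]])
    return float(sr - sl)


# ---------------------------------------------------------------------------
# focality

@dataclass(frozen=True)
class FocalityConfig:
    mea: MEAParams = dfield(default_factory=MEAParams)
    sigma: float = PAPER_SIGMA
    g_stim: float = PAPER_G_GS
    g_sweep: tuple = (500.0, 5e3, 5e4)
    include_dirichlet_limit: bool = True
    monopolar_wall_g: float = PAPER_G_GS
    line_height: float = 50e-6
    line_length: float = 800e-6
    n_samples: int = 161
    element_order: int = 2
    h_stim: float = 4e-6
    h_max: float = 2.0e-4
    seed: int = 0


@dataclass
class FocalityResult:
    """Normalized potential profiles and their FWHM per configuration."""

    line: np.ndarray                          # sampling coordinate (m)
    profiles: dict[str, np.ndarray]           # config label -> normalized |V|
    fwhm: dict[str, float]                    # config label -> width (m)
    stim_tag: str


def _profile_line(cfg_mea: MEAParams, stim_tag: str, height: float,
                  length: float, n: int) -> np.ndarray:
    cx, cy = cfg_mea.electrode_center(stim_tag)
    xs = np.linspace(-length / 2, length / 2, n)
    return np.column_stack([cx + xs, np.full(n, cy), np.full(n, height)])


def run_focality(config: FocalityConfig = FocalityConfig()) -> FocalityResult:
    stim = config.mea.central_electrode
    line_feature = Feature(
        "segment",
        (tuple(_profile_line(config.mea, stim, config.line_height,
                             config.line_length, 2)[0]),
         tuple(_profile_line(config.mea, stim, config.line_height,
                             config.line_length, 2)[-1])),
        h=10e-6, grade=0.8)
    mesh = build_mea_chamber(config.mea, h_stim=config.h_stim,
                             h_max=config.h_max, seed=config.seed,
                             stim_tag=stim, extra_features=(line_feature,))
    pts = _profile_line(config.mea, stim, config.line_height,
                        config.line_length, config.n_samples)
    xs = pts[:, 0] - pts[config.n_samples // 2, 0]
    cond = ConductivityMap(default=config.sigma)
    stim_bc = BoundaryCondition.robin(config.g_stim, V0=1.0)

    def solve_with(bcs):
        problem = FieldProblem(mesh=mesh, conductivity=cond, bcs=bcs,
                               element_order=config.element_order)
        sol = solve_field(problem)
        v = sample_potential(sol, pts)
        return v / np.max(np.abs(v))

    profiles: dict[str, np.ndarray] = {}
    widths: dict[str, float] = {}
    # monopolar: distant ground on the chamber wall, substrate insulating
    profiles["monopolar"] = solve_with({
        stim: stim_bc,
        "lateral_wall": BoundaryCondition.robin(config.monopolar_wall_g, 0.0),
    })
    for g in config.g_sweep:
        profiles[f"ground_surface_g={g:g}"] = solve_with({
            stim: stim_bc,
            "ground_surface": BoundaryCondition.robin(g, 0.0),
        })
    if config.include_dirichlet_limit:
        profiles["ground_surface_dirichlet"] = solve_with({
            stim: stim_bc,
            "ground_surface": BoundaryCondition.dirichlet(0.0),
        })
    for label, prof in profiles.items():
        widths[label] = fwhm(xs, np.abs(prof))
    return FocalityResult(line=xs, profiles=profiles, fwhm=widths, stim_tag=stim)


# ---------------------------------------------------------------------------
# mirror response of a fiber (hybrid pathway)

@dataclass(frozen=True)
class MirrorConfig:
    mea: MEAParams = dfield(default_factory=MEAParams)
    sigma: float = PAPER_SIGMA
    g_gs: float = PAPER_G_GS
    g_stim: float = PAPER_G_GS
    I_target: float = -1e-6          # cathodic, A
    fiber_length: float = 260e-6
    fiber_diameter: float = 2e-6
    fiber_height: float = 50e-6
    dx: float = 1e-6                 # compartment length
    Ra: float = PAPER_RA
    pulse_duration: float = 1e-3
    dt: float = 5e-5
    element_order: int = 2
    h_stim: float = 4e-6
    h_max: float = 2.0e-4
    seed: int = 0


@dataclass
class MirrorReport:
    """Extracellular profile, end-of-pulse response, and mirror metrics."""

    y: np.ndarray                  # compartment coordinate along the fiber (m)
    ve: np.ndarray                 # extracellular potential at compartments (V)
    vm_end: np.ndarray             # membrane potential at pulse end (V)
    El: float
    mirror_error: float            # max |(Vm-El) + (Ve - mean Ve)| / p2p(Ve)
    correlation: float | None      # Pearson r of (Vm-El) vs -(Ve - mean)
    mean_deviation: float          # |mean(Vm-El)| / p2p(Ve)
    V0: float                      # calibrated stimulus voltage
    I_delivered: float             # ground-surface return current (A)


def run_mirror_fiber(config: MirrorConfig = MirrorConfig()) -> MirrorReport:
    stim = config.mea.central_electrode
    cx, cy = config.mea.electrode_center(stim)
    fiber = straight_fiber(config.fiber_length, config.fiber_diameter,
                           origin=(cx, cy - config.fiber_length / 2,
                                   config.fiber_height))
    model = compartmentalize(fiber, config.dx, Ra=config.Ra,
                             params=paper_membrane())
    line_feature = Feature("segment",
                           (tuple(model.centers[0]), tuple(model.centers[-1])),
                           h=8e-6, grade=0.6)
    mesh = build_mea_chamber(config.mea, h_stim=config.h_stim,
                             h_max=config.h_max, seed=config.seed,
                             stim_tag=stim, extra_features=(line_feature,))
    problem = FieldProblem(
        mesh=mesh, conductivity=ConductivityMap(default=config.sigma),
        bcs={stim: BoundaryCondition.robin(config.g_stim, V0=1.0),
             "ground_surface": BoundaryCondition.robin(config.g_gs, 0.0)},
        element_order=config.element_order)
    V0, sol = calibrate_stimulus(problem, stim, config.I_target)
    from .field import integrate_boundary_current
    I_gs = integrate_boundary_current(sol, "ground_surface")
    ve = sample_potential(sol, model.centers)
    p = model.params
    w = Waveform.rect(0.0, config.pulse_duration, 1.0)
    trace = simulate(model, ve, w, config.dt, config.pulse_duration, p.El)
    vm_end = trace.vm[-1]
    dev = vm_end - p.El
    ve_c = ve - ve.mean()
    p2p = ve_c.max() - ve_c.min()
    if p2p == 0.0:
        return MirrorReport(y=model.centers[:, 1], ve=ve, vm_end=vm_end,
                            El=p.El, mirror_error=0.0, correlation=None,
                            mean_deviation=0.0, V0=V0, I_delivered=I_gs)
    err = float(np.max(np.abs(dev + ve_c)) / p2p)
    r = float(np.corrcoef(dev, -ve_c)[0, 1])
    return MirrorReport(y=model.centers[:, 1], ve=ve, vm_end=vm_end, El=p.El,
                        mirror_error=err, correlation=r,
                        mean_deviation=float(abs(dev.mean()) / p2p),
                        V0=V0, I_delivered=I_gs)


# ---------------------------------------------------------------------------
# hybrid vs whole-FEM comparison

@dataclass(frozen=True)
class ComparisonConfig:
    mea: MEAParams = dfield(default_factory=MEAParams)
    sigma: float = PAPER_SIGMA
    sigma_int: float = PAPER_SIGMA_INT
    g_gs: float = PAPER_G_GS
    g_stim: float = PAPER_G_GS
    I_target: float = -1e-6
    fiber_length: float = 260e-6
    fiber_diameter: float = 2e-6
    soma_diameter: float = 20e-6
    fiber_height: float = 50e-6
    dx: float = 1e-6
    Ra: float = PAPER_RA
    pulse_duration: float = 1e-3
    dt: float = 5e-5
    h_stim: float = 5e-6
    h_neuron: float | None = None
    h_max: float = 2.0e-4
    seed: int = 0


@dataclass
class GeometryComparison:
    y_cable: np.ndarray
    vm_cable: np.ndarray
    bottom: coupled.MembraneProfile
    top: coupled.MembraneProfile
    p2p: float                      # peak-to-peak of the cable response (V)
    end_agreement: float            # max end mismatch / p2p
    asymmetry_y: np.ndarray         # common arclength grid
    asymmetry: np.ndarray           # |bottom - top| / p2p per station
    V0: float


@dataclass
class ComparisonReport:
    fiber: GeometryComparison
    soma: GeometryComparison


def _compare_geometry(config: ComparisonConfig, soma: bool) -> GeometryComparison:
    stim = config.mea.central_electrode
    cx, cy = config.mea.electrode_center(stim)
    spec = NeuronGeometrySpec.fiber_above(
        (cx, cy), config.fiber_height, config.fiber_length,
        config.fiber_diameter,
        soma_diameter=config.soma_diameter if soma else None)
    mesh = embed_neuron_surface(config.mea, spec, h_stim=config.h_stim,
                                h_neuron=config.h_neuron, h_max=config.h_max,
                                seed=config.seed, stim_tag=stim)
    bcs = {stim: BoundaryCondition.robin(config.g_stim, V0=1.0),
           "ground_surface": BoundaryCondition.robin(config.g_gs, 0.0)}
    # hybrid field: static solve on the SAME mesh with uniform extracellular
    # conductivity (the classical assumption that the neuron does not
    # perturb the field), two-pass calibrated to the nominal current
    static = FieldProblem(mesh=mesh,
                          conductivity=ConductivityMap(default=config.sigma),
                          bcs=bcs, element_order=1)
    V0, sol = calibrate_stimulus(static, stim, config.I_target)

    if soma:
        morph = cable.fiber_with_soma(config.fiber_length,
                                      config.fiber_diameter,
                                      config.soma_diameter,
                                      origin=(cx, cy - config.fiber_length / 2,
                                              config.fiber_height))
    else:
        morph = straight_fiber(config.fiber_length, config.fiber_diameter,
                               origin=(cx, cy - config.fiber_length / 2,
                                       config.fiber_height))
    model = compartmentalize(morph, config.dx, Ra=config.Ra,
                             params=paper_membrane())
    ve = sample_potential(sol, model.centers)
    p = model.params
    w = Waveform.rect(0.0, config.pulse_duration, 1.0)
    trace = simulate(model, ve, w, config.dt, config.pulse_duration, p.El)
    vm_cable = trace.vm[-1]
    p2p = float((vm_cable - p.El).max() - (vm_cable - p.El).min())

    problem = coupled.build_coupled_problem(
        mesh, sigma_ext=config.sigma, sigma_int=config.sigma_int,
        membrane=paper_membrane(),
        bcs={stim: BoundaryCondition.robin(config.g_stim, V0=1.0),
             "ground_surface": BoundaryCondition.robin(config.g_gs, 0.0)},
        stim_tag=stim, V0=V0)
    states = coupled.solve_transient(problem, w, config.dt,
                                     config.pulse_duration)
    end = states[-1]
    origin = np.array([cx, cy, config.fiber_height])
    bottom = coupled.extract_membrane_profile(problem, end, "bottom",
                                              origin=origin)
    top = coupled.extract_membrane_profile(problem, end, "top", origin=origin)

    y0 = model.centers[:, 1] - cy
    ends = (np.abs(y0 - y0.min()) < 10e-6) | (np.abs(y0 - y0.max()) < 10e-6)
    fem_b = np.interp(y0, bottom.arclength, bottom.vm)
    fem_t = np.interp(y0, top.arclength, top.vm)
    fem_mean = 0.5 * (fem_b + fem_t)
    end_agree = float(np.max(np.abs(fem_mean[ends] - vm_cable[ends])) / p2p)

    lo = max(bottom.arclength.min(), top.arclength.min())
    hi = min(bottom.arclength.max(), top.arclength.max())
    grid = np.linspace(lo, hi, 101)
    asym = np.abs(np.interp(grid, bottom.arclength, bottom.vm) -
                  np.interp(grid, top.arclength, top.vm)) / p2p
    return GeometryComparison(y_cable=y0, vm_cable=vm_cable, bottom=bottom,
                              top=top, p2p=p2p, end_agreement=end_agree,
                              asymmetry_y=grid, asymmetry=asym, V0=V0)


def run_comparison(config: ComparisonConfig = ComparisonConfig()
                   ) -> ComparisonReport:
    return ComparisonReport(fiber=_compare_geometry(config, soma=False),
                            soma=_compare_geometry(config, soma=True))
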