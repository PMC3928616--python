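# Methods

This note documents the models, numerical choices and limitations of
neurostimfem, in the spirit of the methods documentation of mature
simulation packages.

## Physical model

The extracellular medium is a homogeneous ohmic conductor (σ = 0.2 S/m by
default, in the reported range for neural tissue, 0.1–0.4 S/m); charge
relaxation is instantaneous at stimulation frequencies, so the potential
obeys the quasi-static Poisson equation with no volume sources.
Electrodes are zero-thickness surfaces on the substrate. The
electrode–electrolyte interface is a purely resistive surface conductance
g (S/m²), giving the Robin condition σ∇V·n + gV = gV0; g = 500 S/m² is a
typical value for platinum and the default for both the stimulation
electrode and the ground surface. g may equivalently be supplied as an
impedance, g = 1/(Z·S). Capacitive/dispersive (frequency-dependent)
interface behavior and Faradaic electrochemistry are out of scope.

The membrane model is a specific capacitance cm in parallel with a leak
conductance gl in series with its reversal El, optionally augmented with
the classic squid-axon potassium (ḡK·n⁴) and sodium (ḡNa·m³h)
conductances. The gate ODEs dx/dt = α(1−x) − βx use the historical rate
expressions in mV/ms, evaluated on the gating voltage Ṽm = −(Vm − Vrest)
in mV (the opposite of the deviation from rest); all unit conversion
happens at the module boundary. The removable singularities of αn (at
Ṽm = −10 mV) and αm (at Ṽm = −25 mV) are filled with their analytic
limits (0.1 and 1.0 ms⁻¹), making the rate functions total and exactly
continuous. The active maxima and reversals default to the squid-axon set
(36 / 120 mS/cm², −77 / +50 mV) and are config-overridable; the bundled
MEA scenarios are passive (ionic currents zero). With active membranes
the resting potential is *not* El and must be declared by the caller; the
gating reference is whatever rest the caller initializes.

## Meshing

All simulation domains used here are convex (cylindrical chamber,
half-ball, box), so tetrahedral meshes are built as Delaunay
triangulations of graded point clouds. Point density follows a sizing
field h(x) = min over features of (h_f + grade·dist(x, f)), clipped to
h_max; candidate points are drawn from octree-style lattice levels
(spacing h_max/2^k), generated only within each feature's reach, with
deterministic seeded jitter. Exact structural points are placed on
electrode rims, chamber circles and the neuron surface. Electrode rims
and fiber cross-sections are inscribed polygons, whose radius is dilated
so the polygon area equals the true disk area; this keeps the electrode
area (hence the Robin current) and the intracellular axial conductance
(∝ cross-section) unbiased at any angular resolution. Aligned rings of
surface points are cospherical and would degenerate the Delaunay
triangulation; per-ring angular offsets and small axial jitter break the
degeneracy, and generation retries with a re-seeded jitter if the
triangulation still drops points.

The neuron is a capsule (cylinder with hemispherical caps, total length
260 µm, diameter 2 µm in the bundled scenarios), optionally unioned with
a 20-µm sphere at its midpoint. Tetrahedra are classified
intracellular/extracellular by the sign of the analytic signed-distance
function at their centroid; the membrane interface is the set of faces
shared by one tetrahedron of each side, which is closed (watertight) by
construction. The meshed intracellular volume matches the analytic
capsule volume to under 1%.

Chamber radius (1.5 mm) and height (1 mm) are free parameters: the
stimulating field 50 µm above the array changes by well under the mesh
discretization error when they are varied, because the ground-surface
return confines the current near the substrate. The 10-µm annular gap
around each electrode is treated as insulating substrate. Local
refinement (`refine_near`) works by overriding the sizing field and
regenerating from the stored recipe — deterministic, and a no-op when the
region already satisfies the target edge length.

Default problem sizes: ~20k tetrahedra for the field scenarios and ~45k
for the embedded-neuron scenarios. A two-level refinement study (h_stim
4 → 2.5 µm, h_max 200 → 120 µm) moves the sampled fiber-line potential
profile by < 0.6% of its peak-to-peak, so these sizes do not limit the
validation tolerances.

## Field solver

Continuous Lagrange elements of order 1 or 2 (order 2 is the default for
stand-alone field solves), assembled with exact quadrature for the
polynomial degrees involved. Linear systems are solved by sparse direct
factorization (SuperLU) up to a configurable size, then by
preconditioned conjugate gradients. Dirichlet conditions are imposed by
elimination.

Boundary currents use the variationally consistent expressions: on Robin
tags ∫g(V0 − V)ds, on Dirichlet tags the residual of the assembled
system summed over the fixed degrees of freedom. Both are algebraically
exact for the continuous solution and accurate to solver tolerance in
the discrete one, unlike direct gradient quadrature (kept available as a
cross-check; it agrees to a few percent and is used where no boundary
condition is attached). A consequence worth knowing: with all-conducting
boundaries Robin, testing the Galerkin system with the constant function
shows the sum of all boundary currents vanishes *exactly*, so
conservation checks pass at round-off, and the two-pass V0 calibration
(solve at V0 = 1 V, measure the current on the larger of stimulation and
return electrode, rescale, re-solve) reproduces the target current to
machine precision.

Sign convention: `integrate_boundary_current` returns ∫σ∇V·n ds with n
the outward normal — the current injected into the medium through that
surface. A cathodic stimulus therefore reads −1 µA on the stimulation
electrode and +1 µA on the ground return.

## Cable solver

Compartments of length ≤ dx (1 µm default, which halving changes the
response by < 1%); axial conductances combine the two half-compartment
resistances in series, which handles diameter steps. Time integration is
first-order backward Euler — one sparse symmetric solve per step — with
sealed (no-flux) ends. The extracellular mechanism enters only through
neighbor differences of Ve·f(t), so the response is exactly invariant to
adding a constant to the field (tested to machine precision). With
active membranes the gates advance on the previous step's Vm
(staggering), keeping every step linear without losing first-order
accuracy. Waveform segments are half-open on the left, (t0, t1]: since
backward Euler evaluates the source at the end of each step, the step
ending exactly at pulse end must still see the field; getting this wrong
silently relaxes the response by one time step. Pulses are
piecewise-constant segments (e.g. a 1-ms rectangle after a 1-ms delay); a
callable Ve(t) is accepted for genuinely time-varying fields. The default
dt = 0.05 ms passes the dt-vs-dt/10 accuracy criterion (< 1% change at
the location of the largest response) for the bundled scenarios;
`auto_timestep` automates that search. Threshold search brackets the
stimulus amplitude and bisects to 1% relative width; a bracket ceiling
that never elicits a spike is reported as a flagged result, not an error.

## Coupled (thin-film) solver

Degrees of freedom on the membrane surface are duplicated so V and Vint
are independent fields with separate traces; the membrane current density
Im couples them, entering the extracellular weak form as +Im and the
intracellular form as −Im. The interface mass is lumped (row sums), so
membrane currents and gate variables are pointwise nodal quantities; the
capacitive term uses first-order backward differences of both traces,
consistent with the cable pathway. Each step is one monolithic symmetric
sparse solve over (V, Vint); for passive membranes at fixed dt the matrix
is factorized once for the whole transient. Initial state: V = 0,
Vint = rest, gates at their fixed point. The stimulation electrode's
Robin reference is time dependent, Vref = V0·f(t).

Both domains use linear Lagrange elements with refinement near the
membrane. Equal-order traces make the duplicated-node coupling diagonal
under lumping, and the intracellular potential is resolved by mesh size
rather than polynomial order; the cross-method agreement with the cable
solution at the fiber ends (< 1% of peak-to-peak) validates the choice.
A structural consequence of the lumped coupling: testing the
intracellular block with the constant function annihilates its stiffness,
so the closed-membrane balance ∮Im dS = 0 holds to solver precision at
every step — the conservation test verifies machinery, while the
physically meaningful checks are the equilibrium, linearity, symmetry and
cross-method gates.

Fixed dt = 0.05 ms is the default (reproducibility); step-doubling
adaptivity is deliberately not enabled by default. Side profiles
("bottom" = electrode-facing, "top" = opposite) are extracted from
interface nodes within a 50° angular band of straight down/up, bin-
averaged along the axis so the arclength coordinate is strictly
increasing.

## Scenarios and their metrics

* **Focality**: normalized |V| along a 800-µm line 50 µm above the
  central stimulation electrode (electrode_3_3; the array has no exact
  center and the choice is deterministic), for monopolar (distant ground
  on the chamber wall, a modeling choice since no physical distant ground
  is specified) and ground-surface configurations; the focality statistic
  is the linear-interpolated full width at half maximum. The sweep
  g ∈ {500, 5·10³, 5·10⁴} S/m² plus the Dirichlet limit uses decade
  steps; the scientific claim is the ordering and monotonicity, not any
  specific width.
* **Mirror**: full hybrid pipeline on the 260-µm passive fiber; metrics
  are the correlation and maximum deviation between (Vm − El) at pulse
  end and −(Ve − mean Ve), normalized by the peak-to-peak of Ve. With
  gl ≈ 0 the discrete steady state of the cable system *is* the
  mean-centered mirror, and 1 ms is ≈ 7 charge-redistribution time
  constants, so the residual is far below the 5% gate.
* **Comparison**: both pathways on the *same* embedded-neuron mesh — the
  hybrid field is a static solve on that mesh with uniform σ (the
  classical assumption that the neuron does not perturb the field), so
  the comparison isolates the methodological difference rather than
  inter-mesh discretization noise. Metrics: end agreement (max mismatch
  between the side-averaged whole-FEM Vm and the cable Vm over the
  terminal 10 µm of each end, normalized by the cable peak-to-peak) and
  per-station |bottom − top| asymmetry.

A note on the fiber's side asymmetry: the static field difference across
the 2-µm fiber diameter at z = 50 µm is ~0.6 mV against a ~8.7 mV
longitudinal peak-to-peak, so the bottom/top asymmetry of the thin fiber
has a physical floor of ~7% of peak-to-peak in these conditions — small
compared with the soma's ~80%, but not arbitrarily small. A validation
gate demanding < 2% for the fiber is below this physical floor and is
reported honestly as failing; the number to compare across methods is the
end agreement, which is < 1%.

## What the generated fixtures do and do not show

All inputs are generated programmatically (chamber geometry, neuron
surfaces, waveforms); there are no measured data. Passing tests therefore
demonstrate internal consistency, agreement with closed-form solutions
(point source, series-resistance slab, disk access resistance 1/(4σa)),
cross-method agreement, and reproduction of the qualitative figure-level
claims — not agreement with any biological recording. Real tissue is
inhomogeneous and anisotropic, real electrodes have dispersive
impedances, and real neurons branch; none of these are modeled. Curved
reconstructed morphologies (SWC surfaces) are supported only for the
cable pathway, not for FEM embedding.

## Numerical defaults

| quantity | default | note |
|---|---|---|
| σ extracellular | 0.2 S/m | tissue-like |
| σ intracellular | 1 S/m | = 1/Ra, Ra = 100 Ω·cm |
| g (electrodes, ground) | 500 S/m² | platinum-like |
| cm | 1 µF/cm² = 0.01 F/m² | |
| gl | 10⁻⁴ mS/cm² = 10⁻³ S/m² | near-pure capacitor |
| El | −65 mV | |
| dt | 0.05 ms | passes dt/10 criterion |
| dx (compartments) | 1 µm | passes dx/2 criterion |
| element order (field) | 2 | 1 in the coupled solver |
| direct-solver limit | 4·10⁵ dofs | CG + ILU above |
| linear-solver rtol | 10⁻⁸ | relative |
| refine_near floor | 0.5 µm | refusal below |
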