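# neurostimfem

Finite-element and cable-equation modeling of extracellular electrical
neural microstimulation, for neural-engineering researchers who design
microelectrode arrays (MEAs) and want to predict how a stimulating field
polarizes nearby neurons — without any proprietary FEM or simulation
software.

## What it computes

**The stimulating field.** The quasi-static extracellular potential V in a
conductive chamber obeys the Poisson equation

    -∇·(σ∇V) = 0,

with, on each boundary surface, either an insulating Neumann condition
(σ∇V·n = 0), a **Robin** electrode condition

    σ∇V·n + gV = g·V0,

where g (S/m²) is the surface conductance of the electrode–electrolyte
interface and V0 the metal-side voltage, or a Dirichlet condition (the
infinitely-conductive limit g → ∞). The stimulus V0 is calibrated in two
passes so the electrode delivers a nominal current (e.g. −1 µA cathodic).
The Robin condition is the point of the model: it resolves how the finite
surface conductance of a ground-surface return shapes and focalizes the
field, which a Dirichlet ground cannot.

**The neuron response**, by two complementary pathways:

* *Hybrid* — the field is solved without the neuron, sampled at the
  centers of the neuron's electrical compartments, and fed into the
  discretized cable equation (backward Euler; the extracellular potential
  enters through the second spatial difference along the neuron):

      cm·A_i·dVm_i/dt + I_ion,i·A_i = Σ_j g_ij[(Vm_j + Ve_j·f(t)) − (Vm_i + Ve_i·f(t))]

* *Whole-FEM (thin film)* — the neuron geometry is embedded in the mesh
  and the membrane is a zero-thickness interface carrying the current
  density Im = cm·d(Vint−V)/dt + gl·(Vint−V−El) (+ Hodgkin–Huxley IK and
  INa if active), coupling the extracellular and intracellular Poisson
  problems, which are solved monolithically at every time step. This
  resolves *sub-compartment* polarization — the difference between the
  electrode-facing and opposite sides of a thick cell body — which is
  invisible to any 1D cable model.

Membrane kinetics (passive leak plus the classic n⁴/m³h potassium and
sodium gates with their rate functions in the historical mV/ms form) live
in a single module shared by both pathways.

## Worked example

`python examples/soma_asymmetry.py` runs both pathways on the bundled MEA
scenario (60 electrodes of 10 µm diameter at 100 µm pitch, ground-surface
return with g = 500 S/m², σ = 0.2 S/m, −1 µA cathodic 1-ms pulse; passive
membrane with Ra = 100 Ω·cm, cm = 1 µF/cm², gl = 10⁻⁴ mS/cm²,
El = −65 mV) and prints:

```
--- uniform fiber ---
  cable response peak-to-peak: 8.65 mV
  whole-FEM vs cable mismatch at the fiber ends: 0.67% of p2p
  max bottom/top side asymmetry: 7.78% of p2p, at y = -5 um
--- fiber + 20-um soma ---
  cable response peak-to-peak: 8.69 mV
  whole-FEM vs cable mismatch at the fiber ends: 0.40% of p2p
  max bottom/top side asymmetry: 80.54% of p2p, at y = -0 um
```

Reading: for the thin (2 µm) fiber the two methods agree at the fiber
ends to well under a percent of the ~8.7 mV response, and the two sides
of the membrane stay close. Adding a 20-µm soma changes nothing for the
cable model, but the thin-film model shows the electrode-facing side of
the soma polarizing ~5× harder than the far side — an 80%-of-peak-to-peak
asymmetry centered exactly over the soma. The other examples demonstrate
field focality (`field_focality.py`), the mirror-image polarization of a
passive fiber (`mirror_fiber.py`), the analytic point-source validation
(`point_source_validation.py`) and bisection threshold search
(`threshold_search.py`).

A thin CLI wraps the same scenarios:

```
neurostimfem run {focality,mirror,comparison} --out DIR [--seed N]
neurostimfem mesh [--neuron] --out mea.msh
```

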