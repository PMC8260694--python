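# axomech

Coarse-grained models and mechanics of the membranes of myelinated axons.

Traumatic brain injury is frequently axonal injury, and one candidate
trigger is mechanoporation — the membrane around the axon tearing under
stretch. The two membrane systems that matter are the **myelin sheath**
(a multilamellar, glycolipid- and cholesterol-rich membrane wrapping the
axon) and the **node of Ranvier** (exposed axolemma densely packed with
voltage-gated sodium channels, ~3,000 channels/μm²). `axomech` builds
coarse-grained bead models of both as asymmetric lipid bilayers, computes
their structural descriptors, quantifies their mechanical response, and
maps bilayer rupture strains back to whole-axon deformations via
finite-element (FE) local-strain curves. Its audience is membrane
biophysicists and neuro-mechanics modellers who need a reproducible,
scriptable pipeline around (not including) molecular-dynamics engines.

## What it computes

**Composition.** Leaflet-resolved mole fractions over lipid species
(PC, PE, SM, PS, PI, glycolipid, cholesterol), with shipped `myelin` and
`node` presets, integer lipid counts by largest-remainder rounding, and
mole → class weight-fraction conversion
w_C = Σ_{s∈C} n_s·M_s / Σ_s n_s·M_s.

**Structure.** Bilayer thickness by the vertical-neighbour rule (each
phosphate head is paired with the opposing-leaflet head whose periodic
lateral Voronoi cell contains its projection; thickness is the mean |Δz|),
lipid–lipid contacts within 1.5 nm of the first tail bead (polar bead for
cholesterol), enrichment factors
Enrichment(L) = Ratio(L)_x / Ratio(L)_bulk in a shell of radius x, and the
water partition coefficient log₁₀ K_mem/wat against bulk water at
55.5 mol/L, with 5-block standard errors.

**Mechanics.** Surface tension from the diagonal pressure tensor,
γ = l_z·(P_zz − (P_xx+P_yy)/2) (1 bar·nm = 0.1 mN/m); areal strain
ε_A = A/A₀ − 1; the area compressibility modulus K_A = ∂γ/∂ε_A by
ordinary least squares over 4-block means at small strains (ε_A < 0.05);
uniaxial deformation schedules (fast pre-strain to 30%, then a slow
production rate); and rupture detection both as a jump in the
tension–strain series and as geometric pore detection on a lateral
occupancy grid.

**Multiscale mapping.** Given FE curves of cortex principal strains
(ε_x, ε_y) versus axonal strain at several strain rates, inverts them to
find, per rate, the smallest axonal strain whose local strain reaches a
bilayer rupture strain, and compares the resulting interval to an axonal
injury threshold (default 10%).

A synthetic-data module generates every input with known ground truth
(frames with planted pores and clusters, pressure series with a known
tension–strain slope, FE curves with analytic inverses), so the whole
pipeline is testable without simulation output.

## Worked example

```python
from axomech import (
    get_preset, class_weight_fractions, build_bilayer, thickness_voronoi,
    StrainPoint, fit_area_compressibility, axonal_strain_at_rupture,
    SynthPressureSpec, synth_pressure_series, SynthFESpec, synth_fe_curves,
)

myelin = get_preset("myelin")
print({k: round(v, 3) for k, v in sorted(class_weight_fractions(myelin).items())})
# {'CHOL': 0.288, 'GLYCO': 0.243, 'PC': 0.117, 'PE': 0.215,
#  'PI': 0.021, 'PS': 0.085, 'SM': 0.031}

frame = build_bilayer(myelin, n_lipids=2000, thickness=4.5, seed=0)
print(frame.box)                                   # [24. 24. 12.]
print(thickness_voronoi(frame).mean_thickness)     # 4.5

spec = SynthPressureSpec(k_a_true=339.0, noise_sd=2.0, seed=0)
points = [StrainPoint.from_samples(s, spec.reference_area)
          for s in synth_pressure_series(spec).values()]
fit = fit_area_compressibility(points)
print(f"K_A = {fit.k_a:.1f} +/- {fit.standard_error:.1f} mN/m")
# K_A = 338.5 +/- 4.7 mN/m

curves = synth_fe_curves(SynthFESpec(rates=(1, 20, 40), slopes=(3.0, 3.2, 3.5)))
mapping = axonal_strain_at_rupture(curves, rupture_strain=0.36,
                                   injury_threshold=0.10)
print(mapping.axonal_interval, mapping.verdict)
# (0.1028..., 0.12) no rupture at injury threshold
```

The first block converts the asymmetric myelin mole composition to overall
class weight fractions: cholesterol carries ~29% of the lipid weight and
glycolipids ~24%, the signature of myelin versus ordinary plasma
membranes. The second builds the standard 2,000-lipid patch in a
24 × 24 nm lateral box and confirms the head-to-head thickness. The third
recovers a known area compressibility modulus from synthetic
pressure-tensor data, and the last inverts three FE strain curves: a
bilayer that ruptures at 36% membrane strain corresponds to 10–12% axonal
strain, at the edge of proposed injury thresholds.

The same operations are available from the shell:

```sh
axomech build --preset myelin --n-lipids 2000 --out myelin.gro
axomech synth --out-dir fixtures/
axomech analyze fixtures/frames.gro --thickness --partition
axomech mech --ka fixtures/pressure_strain_0.0100.tsv \
             --ka fixtures/pressure_strain_0.0300.tsv \
             --ka fixtures/pressure_strain_0.0500.tsv
axomech map --curves fixtures/fe_curves.tsv --rupture 0.36 --threshold 0.10
```

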