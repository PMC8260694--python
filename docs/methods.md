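# Methods

## Membrane compositions

The myelin sheath and the node of Ranvier are represented as flat,
two-leaflet coarse-grained bilayers with asymmetric lipid compositions.
Each leaflet is a set of mole fractions over named species; a registry maps
every species to a lipid class (PC, PE, SM, PS, PI, GLYCO, CHOL, OTHER), a
molar mass, and the labels of its head and first-tail beads.

The `myelin` preset carries, in mol%: extracellular PC 7, PE 8, CHOL 43,
cerebroside (glycolipid) 39, SM 2, PS 1; cytoplasmic PC 11, PE 27, CHOL 44,
SM 3, PS 12. The cytoplasmic listing sums to 97; the residual 3% is
assigned to a PI-like anionic species, since anionic lipids beyond PS are
known to be present but their fraction is not quantified. The extracellular
listing already sums to 100, so it receives no residual. The `node` preset
is a plasma-membrane-like composition resolved to one representative
species per class (extracellular PC 36, PE 6, CHOL 31, SM 19, glycolipid 6,
other 2; cytoplasmic PC 17, PE 25, CHOL 29, SM 9, PS 11, PI 2, other 7).
One representative per class is sufficient because every analysis in this
package operates at class level; a full multi-species force-field topology
is out of scope.

### Species registry and molar masses

| species | class | M (g/mol) | representative |
|---------|-------|-----------|----------------|
| POPC | PC | 760.1 | PC 16:0/18:1 |
| POPE | PE | 718.0 | PE 16:0/18:1 |
| SSM | SM | 731.1 | SM d18:1/18:0 |
| POPS | PS | 761.8 | PS 16:0/18:1 |
| POPI | PI | 836.5 | PI 16:0/18:1 |
| GCER | GLYCO | 728.1 | galactosylceramide d18:1/18:0 |
| CHOL | CHOL | 386.7 | cholesterol |
| OTHR | OTHER | 750.0 | generic phospholipid |

Brain cerebroside pools span C16–C24 fatty acids; a mid-chain (C18)
representative was chosen so that the class-average mass of the glycolipid
pool stays realistic — a pure very-long-chain (C24) representative would
weight the glycolipid class several points above the experimentally
reported weight-fraction range. Class weight fractions combine the two
leaflets at a configurable mole ratio (default 1:1, matching the builder's
equal per-leaflet counts).

Integer lipid counts use largest-remainder rounding: counts sum exactly to
the requested total and each deviates from n·fraction by less than one;
remainder ties are broken in a seeded random order so results are
deterministic per seed.

## Builder

Lipids are placed on a jittered lattice, half per leaflet, in a square
lateral box of edge sqrt(area_per_lipid · n/2). The default area per lipid,
0.576 nm², reproduces the canonical 2,000-lipid patch in a 24 × 24 nm box.
The lattice distributes each leaflet's lipids over rows that each span the
full box width, so no contiguous hole is left when the count is not a
perfect square (a plain square lattice would leave a pore-like gap that the
pore detector rightly flags). Lateral jitter (default 0.1 nm, uniform)
breaks exact degeneracy without moving bead heights.

Each lipid contributes four beads — head, first tail, and two further tail
beads — at fixed fractions (1.0, 0.65, 0.40, 0.15) of the leaflet
half-thickness. Cholesterol is special-cased to (0.65, 0.45, 0.28, 0.12):
its hydroxyl bead buries near the glycerol level of neighbouring
phospholipids, not at the phosphate plane. This matters for contact and
enrichment analyses, whose reference beads must sit in a common plane for a
laterally homogeneous frame to look homogeneous in 3D shell counts.

Tiling replicates a patch laterally with unique molecule renumbering and
exact composition preservation. Multilayer stacking mirrors successive
units in z so that like faces meet, with apposition gaps of 1.7 nm
(extracellular) and 1.6 nm (cytoplasmic), the X-ray widths of the
respective aqueous spaces in central-nervous-system myelin; solvent of the
input frame is dropped (stacks are meant to be re-solvated).

Ion channels are represented as rigid placeholder cylinders of beads
(default radius 3 nm) spanning both leaflets, placed on a lateral grid with
at least 5 nm centre separation; lipids whose head falls inside a footprint
are deleted. The builder reports the achieved density rather than deciding
which reference area a target concentration refers to. Solvation fills
each region outside the membrane slab with water beads on jittered grids at
8.3 beads/nm³ (4-to-1 mapped water at ~1 g/mL; one grid per region so
partial boundary layers are not lost). Ion pairs replace randomly chosen
water beads, n = round(c·N_A·V_water) at the requested molarity (default
150 mM), plus cations to neutralize the net anionic lipid charge.

## Structural analyses

*Leaflet assignment* splits lipids by head-bead height about the midpoint
between the mean heights of the upper and lower halves of the z-sorted
heads. This is invariant under global translation and falls strictly
between two coplanar leaflets even when their counts differ (a plain
median would coincide with one of the planes).

*Thickness* pairs each phosphate head bead with the opposing-leaflet head
whose lateral periodic Voronoi cell contains its (x, y) projection. Because
a point lies in the Voronoi cell of its nearest generator, that partner is
exactly the nearest opposing head in periodic xy distance, computed here
with a periodic KD-tree; the result is identical to explicit tessellation
with image replication. Thickness is the mean |Δz| over both pairing
directions; cholesterol and glycolipids have no phosphate and are excluded
unless a proxy species list is supplied.

*Contacts and enrichment* use the first tail bead after the headgroup as
the per-lipid reference (the polar bead for cholesterol) and 3D periodic
distances. Enrichment of class L within a shell of radius x of a reference
(a lipid species/class, or the nearest protein bead) is the shell
composition divided by the bulk composition; bulk is per-leaflet by default
(switchable to whole-bilayer). Classes absent from the bulk are reported as
NaN, never zero, and an empty shell flags the whole result rather than
returning silent zeros. Default shell radii: 1.5 nm around lipids, 0.7 and
2.1 nm around proteins.

*Water partition* counts water molecules (beads × 4) inside the slab
bounded by the mean phosphate planes, divides by the slab volume minus a
protein-volume correction (the placeholder cylinder clipped to the slab, or
a supplied constant), and reports log₁₀ of the ratio to bulk water at
55.5 mol/L. A dry slab is flagged below detection (−inf), not silently
zeroed.

*Errors* come from contiguous block averaging: the series is split into
near-equal blocks (none dropped) and the standard error of the block means
is reported. The default is 5 blocks for structural series and 4 blocks
for the compressibility regression, mirroring the respective conventions;
both are parameters.

## Mechanics

Units are fixed: pressures in bar, lengths in nm, tensions in mN/m, with
γ = l_z·(P_zz − (P_xx+P_yy)/2) and 1 bar·nm = 0.1 mN/m. K_A is the OLS
slope of γ against ε_A over all (strain, block-mean) pairs; its standard
error is the regression slope's standard error (undefined for a two-point
fit, which is flagged NaN). Strains above 0.05 trigger a warning because
the γ–ε_A relation is only linear for small areal changes.

The deformation schedule is piecewise linear engineering strain along x: a
fast pre-deformation (default 1 × 10⁻⁵ nm/ps) to 30% strain, then a slow
production phase (2.5 × 10⁻⁶ or 25 × 10⁻⁶ nm/ps in the shipped protocol).

Rupture is detected two ways and reported side by side, since pore
formation relaxes lateral tension:

* **Tension jump.** Scanning the strain-sorted tension series, the first
  point falling more than k (default 5) trailing-window standard
  deviations below the trailing-window median (default window 11) is the
  rupture strain. The defaults were validated on synthetic step series:
  steps of 50% tension at 0.40 and 0.70 strain are localized to one grid
  spacing in ≥95% of seeded replicates at 5% relative noise, with zero
  false firings on step-free noisy ramps.
* **Geometric pores.** Lipid tail beads inside the hydrophobic slab
  (|z − midplane| < 40% of the phosphate-to-phosphate thickness) mark a
  lateral grid cell (default 0.5 nm) occupied when the cell centre lies
  within the occupancy radius (default 0.55 nm) of a bead. Connected empty
  components under periodic 4-connectivity with at least `min_pore_area`
  (default 1.0 nm²) of area are pores; the reported effective radius
  sqrt(area/π) is corrected upward by the occupancy radius, which erodes
  the void by exactly that margin. Water beads inside the slab within a
  component confirm it as water-filled. The area threshold implies a
  detection limit: pores of true radius below ~1.1 nm at the default
  parameters do not leave enough empty area and are not reported.

The per-rate rupture strain of a set of runs is the lowest detected value
at that rate; runs without a detection are ignored.

## Multiscale mapping

FE curves give cortex principal strains (ε_x, ε_y) versus axonal strain at
several strain rates. The scalar local strain is max(ε_x, ε_y) by default;
an areal form (1+ε_x)(1+ε_y) − 1 is provided because bilayer rupture is
driven by area growth, and both can be reported when the choice matters.
Per rate, the mapping returns the smallest axonal strain whose local strain
first reaches the rupture strain, by linear interpolation between samples;
curves may be non-monotone in local strain (viscoelastic cortex and tau
behaviour means higher rates need not produce higher local strains), and
the first crossing is the conservative, earliest-rupture choice. The
interval over rates is compared against a configurable axonal injury
threshold (default 0.10). The actual FE curves are consumed from user
tables; none are hard-coded.

## Synthetic data

The generators produce every pipeline input with known ground truth:

* frames are builder output optionally modified by a water-filled
  cylindrical pore (lipids removed within a lateral disc, hole filled with
  water beads at solvent density so both detection routes fire) and/or a
  composition cluster (species reassigned inside a disc to reach a known
  enrichment multiplier);
* pressure series impose γ = K_A·ε + Gaussian noise exactly by inverting
  the tension formula for the pressure anisotropy (P_zz = 1 bar,
  P_xx = P_yy);
* FE curves come from linear or saturating closed forms with analytic
  inverses.

Everything is bit-reproducible per seed, and the generators never call
analysis code. The frames emulate geometry only — flat leaflets, uniform
lateral jitter, vertical bead stacks — not thermal conformations,
undulations, protrusions or realistic area fluctuations. Passing tests
therefore demonstrate correctness of the geometric and statistical
operators, not agreement with simulated or experimental membranes;
quantities that require equilibrium MD sampling (absolute thickness of a
relaxed mixture, measured K_A, measured log K, rupture strains of real
bilayers) are validated property-based, not numerically.

## Numerical choices and test scales

Degenerate inputs raise typed errors (all-zero compositions, odd lipid
counts, zero gaps, singular one-strain fits, unsorted rupture series,
grids coarser than a quarter box). GRO files are written via MDAnalysis
with zero velocities and nm coordinates to three decimals; PDB in Å;
molecule identity on read is reconstructed from residue boundaries so
5-digit residue-id wrapping in large solvated systems cannot merge
molecules. Table readers auto-detect tab/comma/whitespace delimiters,
match headers case- and order-insensitively, and name the missing column
or offending row on error.

The shipped test suite keeps problem sizes at desk scale: patches of
128–2,000 lipids (one 5,000-lipid homogeneity check and one 15,000-lipid
protein-placement check), 50 brute-force oracle frames of ≤ 500 lipids,
200-replicate compressibility recovery at 40 samples per strain, and
100-replicate detector reliability runs. These finish in well under a
minute total; the same code paths scale to full-size systems (8,000-lipid
40 nm patches, ~138,000 water beads) in a few seconds each.

## Known limitations

No MD is performed: the package neither evaluates forces nor computes
pressure tensors from coordinates, and it does not generate force-field
topologies. The protein is a rigid placeholder cylinder (a real structure
can be imported as coordinates but is still treated as rigid). Leaflets
carry equal lipid counts despite unequal head areas; asymmetric-count
support would require an area-balancing criterion the current builder does
not implement. Enrichment around proteins uses nearest-bead distance,
which slightly favours large footprints over small ones at equal density.
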