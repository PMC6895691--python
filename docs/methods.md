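# Methods

## The modelling problem

A flexible multi-domain protein in solution — here an IgG antibody, two
Fab regions joined to an Fc through a disulphide-bridged hinge — adopts an
ensemble of conformations. Small-angle X-ray and neutron scattering give
one orientationally averaged curve *I(Q)* per contrast, so no single curve
determines the structure. The package's procedure is generative: sample
hinge conformers by Monte Carlo, score every conformer against both the
X-ray and the neutron curve, and characterise the population that survives
a cascade of physically motivated filters. The X-ray and neutron views
differ in exactly one respect that the model reproduces: the tightly bound
hydration monolayer scatters with the protein in X-rays but is nearly
invisible to neutrons in heavy-water buffer, so hydrated bead models are
fitted to SAXS and unhydrated ones to SANS.

## Conformer generation

Backbone φ/ψ angles of designated flexible residues are perturbed one at a
time by pivot moves (uniform step within ±30° by default); the rigid
bodies attached on either side of each flexible chain move as units, so
bond lengths, angles and all intra-domain geometry are preserved exactly.
The topology is treated as a tree (bodies joined by flexible chains);
hinge disulphides are cross-links and are therefore imposed as distance
constraints rather than bonds. Moves are accepted by a Metropolis
criterion at 300 K on a torsional-only energy
E = Σ K·(1 + cos(nφ − δ)) over the flexible torsions; the packaged
parameter set is a generic single 3-fold term (K = 0.8 kJ/mol, δ = 0) per
angle, replaceable by file. The energy's role is to bias sampling away
from torsional eclipses, not to reproduce a force field: the contract of
this stage is breadth of stereochemically valid conformers, and every
conformer is afterwards screened identically by the data. Sterically
clashing conformers (any non-bonded heavy-atom pair of distinct
bodies/chains closer than 0.22 nm, a conventional hard-sphere threshold)
are discarded at the point of generation. Three simulation designs are
packaged: `sim1` (upper hinge only), `sim2` (full hinge, unconstrained)
and `sim3` (full hinge with both hinge-cysteine Cα pairs required to stay
within 0.75 nm so that interchain disulphide bonding remains possible).

The moving side of a pivot is the lighter side — an arbitrary choice
(either side gives conformations identical up to a rigid motion) that
minimises coordinate displacement.

## Coarse-graining and curve calculation

Atoms are binned on a cubic grid anchored at the bounding-box minimum; a
cell with at least `cutoff` atoms (default 4) becomes one sphere at the
cell centre, with sphere volume equal to cell volume. The cube side is
found by bisection so that (number of spheres)·a³ reproduces the
unhydrated protein volume from a packaged consensus residue-volume table
(Chothia-type amino-acid volumes plus common monosaccharides) within 1%.
For X-ray contrast, N_w = round(0.3·M/(ρ_w·N_A·a³)) hydration spheres
(0.3 g water per g protein, water density 0.997 g/cm³ at 20 °C) are placed
in empty cells adjacent to the surface, ranked deterministically
(face-adjacent occupied neighbours first, then total occupied neighbours,
then lexicographic index), opening further adjacency shells if needed.

The Debye sum is evaluated either exactly or, by default, from a 0.05 nm
histogram of pair distances (agreement within 0.5% of the exact sum over
the fitted Q range); all spheres share the uniform-sphere form factor at
the common radius, so I(0) = N². Guinier and cross-section fits are
unweighted linear least squares of ln I (or ln I·Q) against Q²; the
default antibody windows are 0.15–0.28 (R_g), 0.31–0.47 (R_xs1, 0.31–0.51
for IgG4-like shapes) and 0.65–1.04 nm⁻¹ (R_xs2). P(r) is a direct
trapezoid quadrature of the sine transform on the measured Q support with
a cosine taper over the last 10% of the Q range to damp truncation
ringing; it requires the intensity to have decayed within the measured
window. The distance-distribution maximum dimension L is the largest r
with P above 1% of its peak.

## Fitting and filtering

Experimental points are matched to the nearest theoretical Q (ties to the
lower Q); the percentage R factor is minimised over the scale η by
golden-section search to 1e-6 relative tolerance around the closed-form
least-squares scale. Fits run to Q = 1.1 nm⁻¹ by default — the range where
antibody curves retain good signal — with the limit exposed as a
parameter.

The R-factor cutoff is data-driven. Two duplicate measurements of the
same protein give two R factors per model; scanning 200 candidate cutoffs
from the 99th down to the 1st percentile of the pooled values, models with
max(R_a, R_b) at or below the candidate are retained and the Pearson and
Spearman correlations of the retained (R_a, R_b) computed. While the
retained models differ by more than the measurement irreproducibility the
two rankings agree; the cutoff is the largest candidate at which both
coefficients fall below 0.5. Because the correlation trace is noisy for
ensembles of a few hundred models, a candidate counts as the crossing only
when both coefficients stay below threshold for three consecutive
candidates; the full trace is returned so the decision is auditable. The
procedure assumes the best fits are densely sampled, and warns when they
are not. Survivors then pass the disulphide filter (every constrained Cα
pair ≤ 0.75 nm) and the joint X-ray ∩ neutron intersection; filters
commute and are idempotent. Classification: α if d1 < 7 nm (boundary to
β), β1 if abs(d2 − d3) ≥ 1.5 nm, else β2. The 7 nm boundary separates the
two families seen in antibody ensembles; the 1.5 nm asymmetry threshold
sits between the ~1 nm spread of symmetric structures and the ~2.5 nm
asymmetry of extended ones, and both are configurable and recorded in the
output.

## What the synthetic generators emulate

`make_toy_antibody` builds three uniform-density spherical lobes with an
exactly specified centre-of-mass triangle (each lobe is recentred onto its
vertex), labelled Fab1/Fab2/Fc. The default lobe radii are (2.0, 2.0,
1.4) nm: the Fc lobe is made distinctly more compact than the Fabs so
that the three separations are identifiable from an orientationally
averaged curve. This is a deliberate departure from the near-equal sizes
of real Fab and Fc regions, and it is what makes parameter recovery
well-posed at desk scale: with three identical lobes the distance multiset
{d1, d2, d3} has an exact Fab/Fc-interchange twin with an *identical*
curve, the same degeneracy that makes the α and β clusters of a real IgG4
indistinguishable by scattering alone. Real antibodies break the tie with
hinge-connectivity constraints that the three-lobe toy does not possess.

`make_mini_antibody` is a miniature hinged construct with ideal backbone
geometry (N–Cα 0.1458, Cα–C 0.1525, C–N 0.1329 nm): two extended
8-residue linkers carrying two pseudo-cysteine Cα pairs, two rigid
poly-alanine Fab helices and a two-helix Fc. It exercises every Monte
Carlo contract (pivot rigidity, steric rejection, constraint modes) at
negligible cost.

`simulate_experiment` produces duplicate noisy curves from a model:
multiplicative Gaussian noise with σ(Q) growing linearly from a base
fraction (default 2%) at Q = 0 to four times that at Q_max = 1.5 nm⁻¹,
mimicking the weaker signal at high angle, plus an uncorrected flat
background drawn per duplicate (up to 0.3% of I(0) by default) — the
analogue of the instrument-dependent incoherent baselines that differ
between real repeat data sets. Default grids are 365 points (X-ray) and
45 points (neutron). In the pipeline the two members of a duplicate pair
additionally come from slightly different truth geometries
(`sample_variation`, default 0.25 nm X-ray and 0.1 nm neutron on each COM
separation): real duplicate pairs are different samples — two closely
related clones for X-rays, a concentration series with minor reversible
self-association for neutrons — and it is precisely this sample-to-sample
component, invisible in a direct curve comparison, that makes fit rankings
decorrelate near the noise floor. A perturbation of 0.25 nm changes the
simulated R_g by only a few hundredths of a nanometre, i.e. below the
reproducibility of real Guinier analyses.

What passing the synthetic tests does **not** show: instrument smearing,
inter-particle interference, buffer-subtraction artifacts, aggregation and
the internal scattering-density inhomogeneity of real proteins are all
absent, and the toy lobes have no internal flexibility. Recovery results
quantify the pipeline's statistical machinery, not the accuracy
achievable on any particular instrument.

## Numerical choices and degenerate inputs

Bisection for the cube side stops at 1% relative volume error (the sphere
count is a step function of a, so exact equality is not generally
attainable). The Guinier fit refuses non-positive intensities and
non-negative slopes and warns beyond Q·R_g = 1.5. P(r) refuses curves
that are non-positive everywhere; its R_g uses only the positive part of
P. The R-factor η search brackets [0.05, 20]× the least-squares scale;
the objective is convex in η. Identical duplicate R-factor vectors give
correlation 1 by convention (zero variance), hence the no-cutoff
sentinel. Alternate locations in PDB input resolve to highest occupancy,
then lowest altloc identifier; multi-model files use the first model.
Model pipelines are deterministic under a fixed seed: MC trajectories,
hydration placement, toy ensembles and simulated noise are all driven by
explicit generators.

## Default parameters

| parameter | default | note |
|---|---|---|
| grid cutoff | 4 atoms/cell | sparse-cell suppression; 1 for toy point models |
| hydration | 0.3 g/g, 26-neighbourhood | monolayer target |
| clash cutoff | 0.22 nm | non-bonded heavy atoms |
| MC step / T | 30°, 300 K | one angle per trial |
| disulphide limit | 0.75 nm | Cα–Cα, both hinge pairs |
| R-factor Q_max | 1.1 nm⁻¹ | flag to extend to 1.5 |
| cutoff threshold | r, r_s < 0.5 | sustained for 3 candidates |
| α/β boundary | d1 = 7 nm (→β) | β1/β2 at abs(d2−d3) = 1.5 nm |
| overlap rule | >50 heavy atoms ≤ 0.2 nm | per Fab, either Fc site |

## Known limitations

Volumes, not per-atom scattering lengths, set the bead model, so
contrast-variation (partial deuteration) studies are out of scope. The
torsional-only energy means ensemble *weights* are not Boltzmann-faithful;
only the filtered support of the ensemble is interpreted. The direct P(r)
transform is not an indirect-Fourier regulariser and needs data that decay
within the window. Region schemes must be supplied (or built from chain
identifiers); EU numbering is not assigned from sequence. mmCIF input,
missing-residue rebuilding and docking itself are not provided — ligand
poses must come from an external docking solution.
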