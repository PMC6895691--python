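# absasfit

Joint SAXS/SANS atomistic ensemble modelling of flexible multi-domain
proteins, built around antibody (IgG) Fab/Fc geometry.

Solution small-angle X-ray and neutron scattering yield one orientationally
averaged intensity curve *I(Q)* per contrast, far too little information to
invert directly into a structure. The strategy implemented here goes the
other way: generate a large library of stereochemically valid conformers of
a flexible protein by dihedral Monte Carlo, predict each conformer's X-ray
(hydrated) and neutron (unhydrated) curve, and keep only the conformers
consistent with *both* experiments plus the covalent constraints of the
molecule. For an antibody the survivors are summarised by the separations
between the centres of mass of its two Fab regions and the Fc region
(d1 = Fab1–Fab2, d2/d3 = Fab–Fc) and classified into a compact, symmetric
family (cluster α: d1 < 7 nm) and an extended family (cluster β, split into
asymmetric β1 and symmetric β2 by abs(d2 − d3)).

The package is intended for structural biologists who have solution
scattering curves of a hinged multi-domain protein and an atomistic
starting model, and want ensemble-filtered solution structures rather than
a single bead envelope.

## The core quantities

* **Guinier fit**: ln *I(Q)* = ln *I(0)* − *R*g²*Q*²/3 at low *Q* gives the
  radius of gyration; ln[*I(Q)·Q*] vs *Q*² over two higher-*Q* windows gives
  the cross-sectional radii *R*xs1 and *R*xs2.
* **Debye curve**: conformers are coarse-grained to equal spheres on a
  cubic grid (cell side optimised so total sphere volume matches the
  unhydrated protein volume; cells need ≥ 4 atoms by default). For X-ray
  contrast a hydration monolayer of 0.3 g water/g protein is added. Then
  *I(Q)* = *F*²(*Q*)[*N* + 2Σ<sub>i<j</sub> sin(*Q d<sub>ij</sub>*)/(*Q d<sub>ij</sub>*)].
* **Goodness of fit**: *R* = 100·Σ|*I*exp − η·*I*theor|/Σ|*I*exp|, with the
  scale η fitted by golden-section search; curves are compared after
  nearest-*Q* matching, by default only to *Q* = 1.1 nm⁻¹.
* **Data-driven cutoff**: two duplicate experimental curves give two *R*
  factors per model; scanning cutoffs downward, the accepted-fit threshold
  is where the Pearson and Spearman correlations of the two rankings drop
  below 0.5 — beyond that point the data cannot distinguish the models.
* **Filter cascade**: *R*-factor filter (per contrast) ∩ disulphide
  proximity (hinge Cys Cα pairs ≤ 0.75 nm) ∩ joint X-ray+neutron agreement,
  followed by α/β cluster classification and a stage-by-stage report.
* **Receptor overlap**: docked ligand templates (e.g. an Fcγ receptor) are
  superposed onto each survivor's Fc; a conformer conflicts with binding if
  more than 50 ligand heavy atoms come within 0.2 nm of either Fab.

## Worked example

Everything is testable without downloads: the `synthetic` module builds
toy antibodies with exact known geometry and simulates duplicate noisy
curve pairs. Running `python examples/04_joint_fit_and_filter.py`:

```
ensemble size        : 150
xray                 : R-factor cutoff none found
neutron              : R-factor cutoff 5.08%
joint-filter survivors: 26
survivor mean d1     : 8.81 nm (truth 9.5 nm)
modal cluster        : beta1
```

A 150-model ensemble spanning d1 ∈ [4, 12] nm was fitted against simulated
duplicate curves generated from a hidden truth structure with d1 = 9.5 nm
and abs(d2 − d3) = 2.5 nm. The duplicate comparison fixed the neutron
cutoff at 5.08% (for the small X-ray ensemble the rankings never
decorrelated, so no X-ray cutoff was imposed — the sentinel is reported,
not guessed); the joint filter kept 26 of 150 models whose mean Fab–Fab
separation recovers the truth geometry and whose modal cluster is the
extended asymmetric β1 family, matching the truth's classification. At the
default 500-model scale (see `scripts/acceptance.py`) both cutoffs are
found and the recovered mean d1 falls within 0.5 nm of truth.

The other examples show single capabilities: region distances and cluster
labels (`01`), coarse-graining, Guinier and P(r) analysis (`02`),
constrained hinge Monte Carlo (`03`), and the receptor-overlap rule (`05`).

A thin CLI mirrors the library (`absasfit distances|coarse-grain|guinier|
fit|cutoff|filter|mc|fixtures|run`); `absasfit run config.yaml` executes
the whole pipeline from a YAML configuration.

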