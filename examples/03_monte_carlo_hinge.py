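"""Constrained dihedral Monte Carlo on the mini-antibody fixture.

Two rigid 'Fab' helices and a two-helix 'Fc' are joined by two flexible
linkers; pivot moves on the linker phi/psi angles generate conformers,
clashing ones are discarded at generation, and (in the sim3 design) any
conformer whose pseudo-cysteine C-alpha pairs separate beyond 0.75 nm is
rejected - the in-silico analogue of requiring intact hinge disulphides.
"""

import numpy as np

from absasfit import config_for_preset, make_mini_antibody, region_distances, \
    run_mc

model, linkage, regions = make_mini_antibody(n_linker=8, seed=0)
config = config_for_preset("sim3", n_trials=3000, seed=17)
result = run_mc(model, linkage, config, region_scheme=regions)

c = result.counts
print(f"trials               : {c['generated']}")
print(f"energy-accepted      : {c['metropolis_accepted']}")
print(f"sterically acceptable: {c['sterically_acceptable']} "
      f"({100 * c['sterically_acceptable'] / c['generated']:.1f}%)")
print(f"disulphide-compatible: {c['constraint_satisfied']}")

d1 = [r.distances.d1 for r in result.records if r.accepted and r.distances]
print(f"emitted models       : {c['emitted']}, "
      f"Fab-Fab distance d1 = {np.mean(d1):.2f} +/- {np.std(d1):.2f} nm")
print()
print("Every emitted model keeps both C-alpha pairs within 0.75 nm; the d1")
print("spread shows how much conformational freedom the hinge retains under")
print("that constraint.")
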