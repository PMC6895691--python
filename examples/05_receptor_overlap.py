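"""Receptor-overlap scoring: can a ligand docked on the Fc coexist with the
Fab arms?

A ligand template is carried onto the model by superposing its reference Fc
atoms, then its heavy atoms within 0.2 nm of either Fab region are counted.
A model 'overlaps' when more than 50 atoms clash - the decision rule used
to rationalise weak Fc-receptor binding of conformations whose Fab arms
crowd the receptor site.
"""

import numpy as np

from absasfit import LigandPose, overlap_score
from absasfit.structures import AtomisticModel, RegionScheme

rng = np.random.default_rng(0)
blob = rng.normal(scale=0.8, size=(60, 3))


def make(coords, chains):
    n = len(coords)
    resnum = np.concatenate([np.arange(1, list(chains).count(c) + 1)
                             for c in dict.fromkeys(chains)])
    return AtomisticModel(
        coords=np.asarray(coords, float), element=np.full(n, "C", object),
        is_heavy=np.ones(n, bool), chain=np.asarray(chains, object),
        resnum=resnum, icode=np.full(n, "", object),
        resname=np.full(n, "ALA", object), atom_name=np.full(n, "CA", object))


model = make(np.vstack([blob, blob + [6, 0, 0], blob + [3, 5, 0]]),
             ["A"] * 60 + ["B"] * 60 + ["C"] * 60)
scheme = RegionScheme(intervals=[("A", 1, 60, "Fab1"), ("B", 1, 60, "Fab2"),
                                 ("C", 1, 60, "Fc")])

for n_contact in (50, 51):
    near = model.coords[model.chain == "A"][:n_contact] + 0.05
    far = np.tile([[60.0, 60, 60]], (60 - n_contact, 1)) \
        + np.arange(60 - n_contact)[:, None]
    ligand = make(np.vstack([near, far]), ["L"] * 60)
    res = overlap_score(model, ligand, scheme, cutoff=0.2, threshold=50)
    print(f"{n_contact} ligand atoms within 0.2 nm of Fab1 -> "
          f"overlap = {res.overlap}")
print()
print("The rule is strict: exactly 50 contacts is tolerated, 51 flags a")
print("steric conflict between the docked ligand and that Fab arm.")
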