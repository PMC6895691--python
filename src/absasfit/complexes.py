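"""Placement of docked ligand templates on the Fc and Fab-overlap scoring.

A docked template (e.g. a complement C1q head or an Fc-gamma receptor
bound to an Fc fragment) is carried onto each ensemble model by rigidly
superposing the template's Fc reference atoms onto the model's Fc.  The
placed ligand is then scored for steric overlap with the Fab regions: a
model 'overlaps' when more than ``threshold`` ligand heavy atoms lie within
``cutoff`` of either Fab (strictly greater than the threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import AtomisticModel, RegionScheme, rigid_transform_of

OVERLAP_CUTOFF_NM = 0.2
OVERLAP_THRESHOLD = 50


@dataclass
class LigandPose:
    """A ligand model plus the template-Fc atoms used for superposition.

    ``reference_map`` pairs (template reference index, model Fc index) used
    by the rigid superposition; ``site`` labels which of the two Fc sites
    the template occupies.
    """

    ligand: AtomisticModel
    template: AtomisticModel                      # template Fc (reference frame)
    site: str = "fc_site_1"

    def __post_init__(self) -> None:
        if self.ligand.n_atoms == 0:
            raise ValueError("ligand is empty")
        if self.template.n_atoms < 3:
            raise ValueError("need at least 3 template reference atoms")


@dataclass(frozen=True)
class OverlapResult:
    counts: dict                    # region label -> contact atom count
    overlap: bool
    cutoff: float
    threshold: int
    site: str = ""


def place_ligand(model: AtomisticModel, pose: LigandPose,
                 atom_map: list[tuple[int, int]]) -> tuple[AtomisticModel, float]:
    """Transform the ligand into the model frame via template-Fc superposition.

    ``atom_map`` pairs (template index, model index).  Returns the placed
    ligand and the superposition RMSD (nm).
    """
    R, t, rmsd = rigid_transform_of(pose.template, model, atom_map)
    placed = pose.ligand.with_coords(pose.ligand.coords @ R.T + t)
    return placed, rmsd


def overlap_score(model: AtomisticModel, placed_ligand: AtomisticModel,
                  scheme: RegionScheme, cutoff: float = OVERLAP_CUTOFF_NM,
                  threshold: int = OVERLAP_THRESHOLD,
                  site: str = "") -> OverlapResult:
    """Count ligand heavy atoms within ``cutoff`` of each Fab region.

    The per-Fab count is the number of ligand atoms (not atom pairs) whose
    nearest Fab heavy atom is within the cutoff; the overlap flag is true
    iff the count strictly exceeds ``threshold`` for either Fab.
    """
    lig_heavy = placed_ligand.coords[placed_ligand.is_heavy]
    if len(lig_heavy) == 0:
        raise ValueError("ligand has no heavy atoms")
    tree = cKDTree(lig_heavy)
    counts: dict[str, int] = {}
    for fab in ("Fab1", "Fab2"):
        sel = scheme.mask(model, fab) & model.is_heavy
        if not sel.any():
            raise ValueError(f"region {fab} has no heavy atoms")
        hits = tree.query_ball_point(model.coords[sel], r=cutoff)
        contact_atoms = set()
        for h in hits:
            contact_atoms.update(h)
        counts[fab] = len(contact_atoms)
    overlap = any(c > threshold for c in counts.values())
    return OverlapResult(counts=counts, overlap=overlap, cutoff=cutoff,
                         threshold=threshold, site=site)


def ensemble_overlap(models: list[AtomisticModel], poses: list[LigandPose],
                     scheme: RegionScheme,
                     atom_maps: list[list[tuple[int, int]]],
                     cutoff: float = OVERLAP_CUTOFF_NM,
                     threshold: int = OVERLAP_THRESHOLD
                     ) -> tuple[float, pd.DataFrame]:
    """Fraction (%) of models whose placed ligand overlaps either Fab.

    Each pose (one per Fc site) is placed on every model; a model counts as
    overlapping if any site/Fab combination exceeds the threshold.
    """
    if not models:
        raise ValueError("no models supplied")
    rows = []
    n_overlap = 0
    for model in models:
        worst = 0
        hit = False
        for pose, amap in zip(poses, atom_maps):
            placed, rmsd = place_ligand(model, pose, amap)
            res = overlap_score(model, placed, scheme, cutoff, threshold,
                                site=pose.site)
            worst = max(worst, *res.counts.values())
            hit = hit or res.overlap
        n_overlap += hit
        rows.append({"model_id": model.model_id, "max_contacts": worst,
                     "overlap": hit})
    frac = 100.0 * n_overlap / len(models)
    return frac, pd.DataFrame(rows)
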