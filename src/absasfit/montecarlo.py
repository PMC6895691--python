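"""Dihedral Monte Carlo ensemble generation.

Conformers are produced by pivot moves on backbone phi/psi angles of
designated flexible linker residues, while rigid bodies (e.g. Fab and Fc
regions) keep their internal geometry bit-identical.  Moves are accepted by
a Metropolis criterion on a torsional-only energy, then screened for steric
clashes (discarded at generation) and, optionally, for the disulphide
proximity constraint on designated cysteine pairs.

The molecular topology is a tree: rigid bodies are joined by flexible
chains, and any cross-links (hinge disulphides) are handled as distance
constraints rather than bonds, so a pivot always splits the structure into
two well-defined sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import AtomisticModel, CysPair, DistanceSummary, RegionScheme, \
    clash_check, disulphide_distances, region_distances

KB_KJ_PER_MOL_K = 0.008_314_462_618

# Generic single-term backbone torsion parameters (K in kJ/mol, n, delta in
# degrees).  These provide sampling breadth, not force-field fidelity; they
# are replaceable per run.
DEFAULT_TORSION_PARAMS: dict[str, list[tuple[float, int, float]]] = {
    "phi": [(0.8, 3, 0.0)],
    "psi": [(0.8, 3, 0.0)],
}

PRESETS = {
    # upper hinge only, no explicit disulphide constraint (one bond is
    # already present geometrically in the starting structure)
    "sim1": {"hinge": "upper", "constraint_mode": "none"},
    # full hinge, unconstrained
    "sim2": {"hinge": "full", "constraint_mode": "none"},
    # full hinge with the 0.75 nm C-alpha proximity constraint applied
    # during generation
    "sim3": {"hinge": "full", "constraint_mode": "during_generation"},
}

DEFAULT_SS_MAX_NM = 0.75


@dataclass
class FlexibleResidue:
    chain: str
    resnum: int
    angles: tuple[str, ...] = ("phi", "psi")

    def __post_init__(self) -> None:
        for a in self.angles:
            if a not in ("phi", "psi"):
                raise ValueError(f"unknown angle {a!r}")


@dataclass
class LinkageScheme:
    """Flexible residues, rigid bodies and their chain attachments.

    ``attachments[chain]`` names the rigid body joined at the 'start'
    (N-terminal) and 'end' (C-terminal) of each flexible chain; ``None``
    leaves that terminus free.
    """

    flexible: list[FlexibleResidue]
    rigid_bodies: dict[str, np.ndarray]
    attachments: dict[str, dict[str, str | None]]
    constrained_pairs: list[tuple[CysPair, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for name, idx in self.rigid_bodies.items():
            idx = np.asarray(idx, dtype=int)
            self.rigid_bodies[name] = idx
            s = set(idx.tolist())
            if seen & s:
                raise ValueError(f"rigid body {name!r} overlaps another body")
            seen |= s

    def move_pairs(self) -> list[tuple[str, int, str]]:
        return [(f.chain, f.resnum, a) for f in self.flexible for a in f.angles]

    def restricted(self, keep: set[tuple[str, int]]) -> "LinkageScheme":
        """Scheme with the flexible set limited to the given residues."""
        return replace(self, flexible=[f for f in self.flexible
                                       if (f.chain, f.resnum) in keep])


@dataclass
class MCConfig:
    n_trials: int
    temperature: float = 300.0           # K
    max_step_deg: float = 30.0
    clash_cutoff: float = 0.22           # nm
    constraint_mode: str = "during_generation"   # none|post_filter|during_generation
    ss_max_nm: float = DEFAULT_SS_MAX_NM
    seed: int = 0
    output_stride: int = 1

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0 < self.max_step_deg <= 180:
            raise ValueError("max_step_deg must be in (0, 180]")
        if self.constraint_mode not in ("none", "post_filter", "during_generation"):
            raise ValueError(f"unknown constraint mode {self.constraint_mode!r}")


@dataclass
class EnsembleRecord:
    model_id: str
    trial: int
    accepted: bool
    clash: bool
    constraint_ok: bool
    distances: DistanceSummary | None = None
    ss_distances: list[tuple[str, float]] = field(default_factory=list)
    path: str = ""


# ---------------------------------------------------------------------------
# Torsion geometry and energy
# ---------------------------------------------------------------------------

def dihedral_deg(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                 p3: np.ndarray) -> float:
    """Signed dihedral angle in degrees (IUPAC convention)."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _atom_index(model: AtomisticModel, chain: str, resnum: int,
                name: str) -> int | None:
    sel = np.flatnonzero((model.chain == chain) & (model.resnum == resnum)
                         & (model.atom_name == name))
    return int(sel[0]) if len(sel) else None


def backbone_dihedral(model: AtomisticModel, chain: str, resnum: int,
                      angle: str) -> float | None:
    """phi/psi of one residue in degrees, or None at a chain terminus."""
    if angle == "phi":
        quad = [(resnum - 1, "C"), (resnum, "N"), (resnum, "CA"), (resnum, "C")]
    elif angle == "psi":
        quad = [(resnum, "N"), (resnum, "CA"), (resnum, "C"), (resnum + 1, "N")]
    else:
        raise ValueError(f"unknown angle {angle!r}")
    idx = [_atom_index(model, chain, r, n) for r, n in quad]
    if any(i is None for i in idx):
        return None
    p = [model.coords[i] for i in idx]
    return dihedral_deg(*p)


def torsion_energy(model: AtomisticModel, scheme: LinkageScheme,
                   params: dict[str, list[tuple[float, int, float]]] | None = None
                   ) -> float:
    """E = sum K_n (1 + cos(n phi - delta)) over flexible backbone torsions.

    Torsions undefined at chain termini are skipped; a flexible angle whose
    parameter entry is missing raises.
    """
    params = params if params is not None else DEFAULT_TORSION_PARAMS
    e = 0.0
    for chain, resnum, angle in scheme.move_pairs():
        if angle not in params:
            raise KeyError(f"no torsion parameters for angle {angle!r}")
        value = backbone_dihedral(model, chain, resnum, angle)
        if value is None:
            continue
        for k, n, delta in params[angle]:
            e += k * (1.0 + np.cos(np.radians(n * value - delta)))
    return float(e)


# ---------------------------------------------------------------------------
# Pivot moves
# ---------------------------------------------------------------------------

def _chain_atoms(model: AtomisticModel, scheme: LinkageScheme,
                 chain: str) -> np.ndarray:
    in_body = np.zeros(model.n_atoms, dtype=bool)
    for idx in scheme.rigid_bodies.values():
        in_body[idx] = True
    return np.flatnonzero((model.chain == chain) & ~in_body)


def _reachable_through(scheme: LinkageScheme, start_body: str,
                       blocked_chain: str) -> tuple[set[str], set[str]]:
    """Bodies and flexible chains reachable from a body, not crossing
    ``blocked_chain``."""
    bodies = {start_body}
    chains: set[str] = set()
    frontier = [start_body]
    while frontier:
        body = frontier.pop()
        for chain, att in scheme.attachments.items():
            if chain == blocked_chain:
                continue
            ends = {att.get("start"), att.get("end")}
            if body in ends:
                if chain not in chains:
                    chains.add(chain)
                    for other in ends - {body, None}:
                        if other not in bodies:
                            bodies.add(other)
                            frontier.append(other)
    return bodies, chains


def _moving_set(model: AtomisticModel, scheme: LinkageScheme, chain: str,
                resnum: int, angle: str) -> tuple[np.ndarray, int, int]:
    """Atoms on the C-terminal side of the pivot bond, plus the pivot axis.

    Returns (end-side atom indices, axis atom i, axis atom j); rotation about
    the i->j bond moves the end side (or equivalently its complement).
    """
    if angle == "phi":
        i = _atom_index(model, chain, resnum, "N")
        j = _atom_index(model, chain, resnum, "CA")
        own_static = {"N", "CA", "H", "HN", "H1", "H2", "H3"}
    else:
        i = _atom_index(model, chain, resnum, "CA")
        j = _atom_index(model, chain, resnum, "C")
        # for psi only the carbonyl (and next residue) follow the rotation
        own_moving = {"O", "OXT"}
    if i is None or j is None:
        raise ValueError(f"missing backbone atoms for {chain}:{resnum} {angle}")

    catoms = _chain_atoms(model, scheme, chain)
    res = model.resnum[catoms]
    moving = list(catoms[res > resnum])
    same = catoms[res == resnum]
    if angle == "phi":
        moving.extend(a for a in same if model.atom_name[a] not in own_static)
    else:
        moving.extend(a for a in same if model.atom_name[a] in own_moving)
    end_body = scheme.attachments.get(chain, {}).get("end")
    if end_body is not None:
        bodies, chains = _reachable_through(scheme, end_body, chain)
        for b in bodies:
            moving.extend(scheme.rigid_bodies[b].tolist())
        for c in chains:
            moving.extend(_chain_atoms(model, scheme, c).tolist())
    return np.unique(np.asarray(moving, dtype=int)), i, j


def apply_pivot(model: AtomisticModel, scheme: LinkageScheme,
                residue: tuple[str, int], angle: str,
                delta_deg: float) -> AtomisticModel:
    """Rotate the smaller-mass side of a phi/psi pivot bond by ``delta_deg``.

    Bond lengths, bond angles and all intra-rigid-body geometry are exactly
    preserved (the rotation is rigid).
    """
    chain, resnum = residue
    if (chain, resnum, angle) not in scheme.move_pairs():
        raise ValueError(f"residue {chain}:{resnum} is not flexible for {angle}")
    end_side, i, j = _moving_set(model, scheme, chain, resnum, angle)
    masses = model.masses()
    all_idx = np.arange(model.n_atoms)
    start_side = np.setdiff1d(all_idx, end_side, assume_unique=False)
    if masses[end_side].sum() <= masses[start_side].sum():
        rotating, sign = end_side, 1.0
    else:
        rotating, sign = start_side, -1.0
    axis_point = model.coords[i]
    axis = model.coords[j] - model.coords[i]
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.radians(sign * delta_deg) * axis)
    coords = model.coords.copy()
    coords[rotating] = rot.apply(coords[rotating] - axis_point) + axis_point
    return model.with_coords(coords)


# ---------------------------------------------------------------------------
# Clash screening across the moving interface
# ---------------------------------------------------------------------------

def ensemble_clash(model: AtomisticModel, scheme: LinkageScheme,
                   cutoff: float) -> bool:
    """Any steric clash between distinct bodies/chains of the scheme."""
    groups: list[np.ndarray] = list(scheme.rigid_bodies.values())
    chains = sorted({f.chain for f in scheme.flexible})
    groups += [_chain_atoms(model, scheme, c) for c in chains]
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            if len(groups[a]) == 0 or len(groups[b]) == 0:
                continue
            hit, _ = clash_check(model, groups[a], groups[b], cutoff)
            if hit:
                return True
    return False


def _constraint_ok(model: AtomisticModel, scheme: LinkageScheme,
                   max_nm: float) -> bool:
    if not scheme.constrained_pairs:
        return True
    pairs = [p for p, _ in scheme.constrained_pairs]
    dists = disulphide_distances(model, pairs)
    limits = [limit if limit is not None else max_nm
              for _, limit in scheme.constrained_pairs]
    return all(d <= lim for (_, d), lim in zip(dists, limits))


# ---------------------------------------------------------------------------
# The Monte Carlo driver
# ---------------------------------------------------------------------------

@dataclass
class MCResult:
    records: list[EnsembleRecord]
    models: list[AtomisticModel]
    counts: dict[str, int]


def run_mc(start: AtomisticModel, scheme: LinkageScheme, config: MCConfig,
           region_scheme: RegionScheme | None = None,
           params: dict | None = None,
           outdir: str | None = None) -> MCResult:
    """Metropolis dihedral Monte Carlo with steric rejection.

    Per trial: a flexible (residue, angle) is chosen uniformly, perturbed by
    delta ~ U(-step, step), Metropolis-accepted on the torsional energy
    change, then clash-screened between the moving and static sides
    (clashing conformations are discarded at generation).  In
    ``during_generation`` constraint mode, conformations violating any
    constrained cysteine pair are likewise discarded.  Fully reproducible
    under the configured seed.  With ``outdir`` set, every emitted model is
    written as a PDB file there and the record carries its path.
    """
    from pathlib import Path

    from .structures import write_structure
    moves = scheme.move_pairs()
    if not moves:
        raise ValueError("scheme has no flexible residues")
    if ensemble_clash(start, scheme, config.clash_cutoff):
        raise ValueError("starting structure fails its own clash check")
    rng = np.random.default_rng(config.seed)
    kt = KB_KJ_PER_MOL_K * config.temperature
    current = start.copy()
    e_current = torsion_energy(current, scheme, params)
    records: list[EnsembleRecord] = []
    models: list[AtomisticModel] = []
    counts = {"generated": 0, "metropolis_accepted": 0,
              "sterically_acceptable": 0, "constraint_satisfied": 0,
              "emitted": 0}
    check_constraint_now = config.constraint_mode == "during_generation"
    for trial in range(config.n_trials):
        counts["generated"] += 1
        chain, resnum, angle = moves[rng.integers(len(moves))]
        delta = rng.uniform(-config.max_step_deg, config.max_step_deg)
        candidate = apply_pivot(current, scheme, (chain, resnum), angle, delta)
        e_new = torsion_energy(candidate, scheme, params)
        de = e_new - e_current
        metropolis = de <= 0 or rng.random() < np.exp(-de / kt)
        model_id = f"{start.model_id}_t{trial:06d}"
        if not metropolis:
            records.append(EnsembleRecord(model_id=model_id, trial=trial,
                                          accepted=False, clash=False,
                                          constraint_ok=True))
            continue
        counts["metropolis_accepted"] += 1
        if ensemble_clash(candidate, scheme, config.clash_cutoff):
            records.append(EnsembleRecord(model_id=model_id, trial=trial,
                                          accepted=False, clash=True,
                                          constraint_ok=True))
            continue
        counts["sterically_acceptable"] += 1
        ss_ok = _constraint_ok(candidate, scheme, config.ss_max_nm)
        if ss_ok:
            counts["constraint_satisfied"] += 1
        if check_constraint_now and not ss_ok:
            records.append(EnsembleRecord(model_id=model_id, trial=trial,
                                          accepted=False, clash=False,
                                          constraint_ok=False))
            continue
        current = candidate
        e_current = e_new
        rec = EnsembleRecord(model_id=model_id, trial=trial, accepted=True,
                             clash=False, constraint_ok=ss_ok)
        if scheme.constrained_pairs:
            rec.ss_distances = disulphide_distances(
                current, [p for p, _ in scheme.constrained_pairs])
        if region_scheme is not None:
            rec.distances = region_distances(current, region_scheme)
        records.append(rec)
        if counts["sterically_acceptable"] % max(1, config.output_stride) == 0:
            snapshot = current.with_coords(current.coords.copy(),
                                           model_id=model_id)
            models.append(snapshot)
            counts["emitted"] += 1
            if outdir is not None:
                path = Path(outdir) / f"{model_id}.pdb"
                path.parent.mkdir(parents=True, exist_ok=True)
                write_structure(snapshot, str(path))
                rec.path = str(path)
    return MCResult(records=records, models=models, counts=counts)


def config_for_preset(preset: str, n_trials: int, seed: int = 0,
                      **overrides) -> MCConfig:
    """MCConfig pre-filled from a named simulation design (sim1/sim2/sim3)."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    kwargs = {"constraint_mode": PRESETS[preset]["constraint_mode"]}
    kwargs.update(overrides)
    return MCConfig(n_trials=n_trials, seed=seed, **kwargs)
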