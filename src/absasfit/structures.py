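"""Atomistic structure handling: PDB I/O, region schemes, and geometric observables.

All coordinates are stored in nanometres; the Angstrom/nm conversion happens
once, at the file boundary.  Structures are plain arrays-of-columns rather
than an object per atom, so that every geometric operation (centres of mass,
clash detection, superposition) is vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import yaml
from scipy.spatial import cKDTree

ANGSTROM_PER_NM = 10.0

# Region labels recognised by the antibody distance analysis.
REGION_LABELS = ("Fab1", "Fab2", "Fc", "hinge", "other")


@dataclass
class AtomisticModel:
    """A set of atoms with identity and coordinates (nm).

    Columns are parallel numpy arrays of length ``n_atoms``.  ``is_heavy``
    is False only for hydrogen/deuterium.
    """

    coords: np.ndarray          # (N, 3) float, nm
    element: np.ndarray         # (N,) str, e.g. "C"
    is_heavy: np.ndarray        # (N,) bool
    chain: np.ndarray           # (N,) str
    resnum: np.ndarray          # (N,) int
    icode: np.ndarray           # (N,) str ("" if none)
    resname: np.ndarray         # (N,) str
    atom_name: np.ndarray       # (N,) str
    model_id: str = "model"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def masses(self) -> np.ndarray:
        """Standard atomic masses (g/mol) per atom."""
        return np.array([_atomic_mass(e) for e in self.element])

    def subset(self, idx: np.ndarray, model_id: str | None = None) -> "AtomisticModel":
        idx = np.asarray(idx)
        return AtomisticModel(
            coords=self.coords[idx],
            element=self.element[idx],
            is_heavy=self.is_heavy[idx],
            chain=self.chain[idx],
            resnum=self.resnum[idx],
            icode=self.icode[idx],
            resname=self.resname[idx],
            atom_name=self.atom_name[idx],
            model_id=model_id or self.model_id,
        )

    def with_coords(self, coords: np.ndarray, model_id: str | None = None) -> "AtomisticModel":
        return replace(self, coords=np.asarray(coords, dtype=float),
                       model_id=model_id or self.model_id)

    def copy(self) -> "AtomisticModel":
        return AtomisticModel(
            coords=self.coords.copy(), element=self.element.copy(),
            is_heavy=self.is_heavy.copy(), chain=self.chain.copy(),
            resnum=self.resnum.copy(), icode=self.icode.copy(),
            resname=self.resname.copy(), atom_name=self.atom_name.copy(),
            model_id=self.model_id,
        )


_MASS_CACHE: dict[str, float] = {}


def _atomic_mass(element: str) -> float:
    el = element.capitalize()
    if el not in _MASS_CACHE:
        g = gemmi.Element(el)
        if g.name == "X" and el != "X":
            raise ValueError(f"unknown element symbol {element!r}")
        _MASS_CACHE[el] = g.weight
    return _MASS_CACHE[el]


def molecular_mass(model: AtomisticModel) -> float:
    """Total molecular mass in g/mol."""
    return float(model.masses().sum())


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _validate_pdb_lines(path: str) -> None:
    """Fail early, naming the line, on records gemmi would silently mangle."""
    n_atom_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            n_atom_records += 1
            if len(line.rstrip("\n")) < 54:
                raise ValueError(f"{path}:{lineno}: truncated {rec} record")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError as err:
                raise ValueError(
                    f"{path}:{lineno}: unparseable coordinates in {rec} record"
                ) from err
            if line[21] == " ":
                raise ValueError(f"{path}:{lineno}: missing chain id")
    if n_atom_records == 0:
        raise ValueError(f"{path}: no ATOM/HETATM records found")


def read_structure(path: str, dialect: str = "pdb") -> AtomisticModel:
    """Read a PDB file into an :class:`AtomisticModel` (coordinates in nm).

    Only the first MODEL of a multi-model file is used.  Alternate locations
    are resolved to the highest occupancy, ties broken by the lowest altloc
    identifier.
    """
    if dialect != "pdb":
        raise ValueError(f"unsupported dialect {dialect!r}")
    _validate_pdb_lines(path)
    st = gemmi.read_pdb(path)
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]

    cols: dict[str, list] = {k: [] for k in
                             ("xyz", "element", "chain", "resnum", "icode",
                              "resname", "atom_name")}
    for chain in model:
        for residue in chain:
            # resolve altlocs: group atoms by name, keep best
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in residue:
                by_name.setdefault(atom.name, []).append(atom)
            for name, atoms in by_name.items():
                best = min(atoms, key=lambda a: (-a.occ, a.altloc or "~"))
                cols["xyz"].append([best.pos.x, best.pos.y, best.pos.z])
                cols["element"].append(best.element.name)
                cols["chain"].append(chain.name)
                cols["resnum"].append(residue.seqid.num)
                cols["icode"].append((residue.seqid.icode or "").strip())
                cols["resname"].append(residue.name)
                cols["atom_name"].append(name)
    coords = np.asarray(cols["xyz"], dtype=float) / ANGSTROM_PER_NM
    element = np.asarray(cols["element"], dtype=object)
    is_heavy = np.array([e.upper() not in ("H", "D") for e in element])
    return AtomisticModel(
        coords=coords, element=element, is_heavy=is_heavy,
        chain=np.asarray(cols["chain"], dtype=object),
        resnum=np.asarray(cols["resnum"], dtype=int),
        icode=np.asarray(cols["icode"], dtype=object),
        resname=np.asarray(cols["resname"], dtype=object),
        atom_name=np.asarray(cols["atom_name"], dtype=object),
        model_id=str(path),
    )


def write_structure(model: AtomisticModel, path: str) -> None:
    """Write a model as a single-model PDB file (nm converted back to A)."""
    st = gemmi.Structure()
    st.name = model.model_id
    md = gemmi.Model("1")
    chain_objs: dict[str, gemmi.Chain] = {}
    for i in range(model.n_atoms):
        cid = str(model.chain[i])
        if cid not in chain_objs:
            chain_objs[cid] = gemmi.Chain(cid)
        ch = chain_objs[cid]
        num = int(model.resnum[i])
        icode = str(model.icode[i]) or " "
        res = None
        if len(ch) > 0:
            last = ch[len(ch) - 1]
            if (last.seqid.num == num and (last.seqid.icode or " ") == icode
                    and last.name == str(model.resname[i])):
                res = last
        if res is None:
            res = gemmi.Residue()
            res.name = str(model.resname[i])
            res.seqid = gemmi.SeqId(num, icode)
            ch.add_residue(res)
            res = ch[len(ch) - 1]
        atom = gemmi.Atom()
        atom.name = str(model.atom_name[i])
        atom.element = gemmi.Element(str(model.element[i]))
        x, y, z = model.coords[i] * ANGSTROM_PER_NM
        atom.pos = gemmi.Position(x, y, z)
        atom.occ = 1.0
        res.add_atom(atom)
    for ch in chain_objs.values():
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(path)


# ---------------------------------------------------------------------------
# Region schemes
# ---------------------------------------------------------------------------

@dataclass
class RegionScheme:
    """Maps (chain, inclusive residue interval) -> region label.

    Intervals within one chain must not overlap.  The antibody distance
    analysis requires at least Fab1, Fab2 and Fc to be present.
    """

    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_chain: dict[str, list[tuple[int, int]]] = {}
        for chain, lo, hi, label in self.intervals:
            if lo > hi:
                raise ValueError(f"interval ({chain}, {lo}, {hi}) inverted")
            if label not in REGION_LABELS:
                raise ValueError(f"unknown region label {label!r}")
            for plo, phi in by_chain.get(chain, []):
                if lo <= phi and plo <= hi:
                    raise ValueError(
                        f"overlapping intervals on chain {chain}: "
                        f"({plo},{phi}) and ({lo},{hi})")
            by_chain.setdefault(chain, []).append((lo, hi))

    def add(self, chain: str, lo: int, hi: int, label: str) -> None:
        self.intervals.append((chain, lo, hi, label))
        self.__post_init__()

    def labels(self, model: AtomisticModel) -> np.ndarray:
        """Per-atom region labels; atoms outside all intervals get 'other'."""
        out = np.full(model.n_atoms, "other", dtype=object)
        for chain, lo, hi, label in self.intervals:
            sel = (model.chain == chain) & (model.resnum >= lo) & (model.resnum <= hi)
            out[sel] = label
        return out

    def mask(self, model: AtomisticModel, label: str) -> np.ndarray:
        return self.labels(model) == label

    def to_yaml(self, path: str) -> None:
        data = {"regions": [
            {"chain": c, "start": lo, "end": hi, "label": lab}
            for c, lo, hi, lab in self.intervals]}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path: str) -> "RegionScheme":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(intervals=[
            (str(r["chain"]), int(r["start"]), int(r["end"]), str(r["label"]))
            for r in data["regions"]])


# Default EU-numbering boundaries for an intact IgG: each Fab is one light
# chain plus its heavy chain up to residue 219, the hinge spans 220-238, and
# the Fc is everything from 239 onward on both heavy chains.  Glycan (HETATM)
# chains can be listed under ``extra_fc`` so they count towards the Fc.
FAB_END_EU = 219
FC_START_EU = 239


def antibody_scheme(heavy: tuple[str, str], light: tuple[str, str],
                    fab_end: int = FAB_END_EU, fc_start: int = FC_START_EU,
                    extra_fc: tuple[str, ...] = (),
                    max_resnum: int = 10_000) -> RegionScheme:
    """Build the default IgG region scheme from chain identifiers.

    ``heavy[i]`` is paired with ``light[i]`` to form Fab_i.
    """
    scheme = RegionScheme()
    for i, (h, l) in enumerate(zip(heavy, light), start=1):
        fab = f"Fab{i}"
        scheme.add(l, -999, max_resnum, fab)
        scheme.add(h, -999, fab_end, fab)
        scheme.add(h, fab_end + 1, fc_start - 1, "hinge")
        scheme.add(h, fc_start, max_resnum, "Fc")
    for c in extra_fc:
        scheme.add(c, -999, max_resnum, "Fc")
    return scheme


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceSummary:
    """Inter-region centre-of-mass separations (nm).

    d1 = Fab1-Fab2, d2 = Fab1-Fc, d3 = Fab2-Fc.  abs_diff = |d2 - d3| is the
    asymmetry monitor; the Fab1/Fab2 labelling is descriptive only.
    """

    d1: float
    d2: float
    d3: float

    @property
    def max_d23(self) -> float:
        return max(self.d2, self.d3)

    @property
    def min_d23(self) -> float:
        return min(self.d2, self.d3)

    @property
    def abs_diff(self) -> float:
        return abs(self.d2 - self.d3)


@dataclass(frozen=True)
class CysPair:
    """Two cysteine C-alpha atoms constrained to lie close (disulphide)."""

    a: tuple[str, int]   # (chain, residue number)
    b: tuple[str, int]
    label: str = ""


def center_of_mass(model: AtomisticModel, region: str, scheme: RegionScheme,
                   weighting: str = "mass") -> np.ndarray:
    """Centre of mass (nm) of one region; ``weighting`` is mass|geometric."""
    sel = scheme.mask(model, region)
    if not sel.any():
        raise ValueError(f"region {region!r} contains no atoms")
    xyz = model.coords[sel]
    if weighting == "geometric":
        return xyz.mean(axis=0)
    if weighting == "mass":
        w = model.masses()[sel]
        return (xyz * w[:, None]).sum(axis=0) / w.sum()
    raise ValueError(f"unknown weighting {weighting!r}")


def region_distances(model: AtomisticModel, scheme: RegionScheme,
                     weighting: str = "mass") -> DistanceSummary:
    """d1/d2/d3 centre-of-mass separations between Fab1, Fab2 and Fc."""
    coms = {r: center_of_mass(model, r, scheme, weighting)
            for r in ("Fab1", "Fab2", "Fc")}
    d1 = float(np.linalg.norm(coms["Fab1"] - coms["Fab2"]))
    d2 = float(np.linalg.norm(coms["Fab1"] - coms["Fc"]))
    d3 = float(np.linalg.norm(coms["Fab2"] - coms["Fc"]))
    return DistanceSummary(d1=d1, d2=d2, d3=d3)


def _find_ca(model: AtomisticModel, chain: str, resnum: int) -> int:
    sel = np.flatnonzero((model.chain == chain) & (model.resnum == resnum)
                         & (model.atom_name == "CA"))
    if len(sel) == 0:
        raise ValueError(f"no CA atom for residue {chain}:{resnum}")
    return int(sel[0])


def disulphide_distances(model: AtomisticModel,
                         pairs: list[CysPair]) -> list[tuple[str, float]]:
    """C-alpha / C-alpha distance (nm) for each constrained cysteine pair."""
    out = []
    for pair in pairs:
        ia = _find_ca(model, *pair.a)
        ib = _find_ca(model, *pair.b)
        d = float(np.linalg.norm(model.coords[ia] - model.coords[ib]))
        out.append((pair.label or f"{pair.a}-{pair.b}", d))
    return out


def clash_check(model: AtomisticModel, group_a: np.ndarray, group_b: np.ndarray,
                cutoff: float = 0.22,
                exclude_bonded: bool = True) -> tuple[bool, int]:
    """Detect heavy-atom contacts closer than ``cutoff`` (nm) between groups.

    Pairs within the same residue, or between sequence-adjacent residues of
    the same chain (covering 1-2/1-3 neighbours across a pivot bond), are
    excluded when ``exclude_bonded`` is set.
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("clash groups must be non-empty")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("clash groups must be disjoint")
    ha = group_a[model.is_heavy[group_a]]
    hb = group_b[model.is_heavy[group_b]]
    if len(ha) == 0 or len(hb) == 0:
        return False, 0
    tree_a = cKDTree(model.coords[ha])
    tree_b = cKDTree(model.coords[hb])
    pairs = tree_a.query_ball_tree(tree_b, r=cutoff)
    count = 0
    for i, neigh in enumerate(pairs):
        gi = ha[i]
        for j in neigh:
            gj = hb[j]
            if exclude_bonded and model.chain[gi] == model.chain[gj]:
                if abs(int(model.resnum[gi]) - int(model.resnum[gj])) <= 1:
                    continue
            count += 1
    return count > 0, count


def superpose(mobile: AtomisticModel, reference: AtomisticModel,
              atom_map: list[tuple[int, int]]) -> tuple[AtomisticModel, float]:
    """Least-squares rigid superposition (Kabsch; proper rotation only).

    ``atom_map`` pairs (mobile index, reference index).  Returns the whole
    mobile model transformed into the reference frame and the RMSD (nm) over
    the mapped atoms.
    """
    if len(atom_map) < 3:
        raise ValueError("need at least 3 mapped atom pairs")
    mi = np.array([m for m, _ in atom_map], dtype=int)
    ri = np.array([r for _, r in atom_map], dtype=int)
    P = mobile.coords[mi]
    Q = reference.coords[ri]
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - Pc, Q - Qc
    if np.linalg.matrix_rank(Q0, tol=1e-9) < 2:
        raise ValueError("mapped reference atoms are collinear/degenerate")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    new_coords = (mobile.coords - Pc) @ R.T + Qc
    rmsd = float(np.sqrt(np.mean(np.sum((new_coords[mi] - Q) ** 2, axis=1))))
    return mobile.with_coords(new_coords), rmsd


def rigid_transform_of(mobile: AtomisticModel, reference: AtomisticModel,
                       atom_map: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray, float]:
    """Rotation matrix, translation and RMSD of the superposition.

    ``x_new = R @ x + t`` maps mobile coordinates into the reference frame.
    """
    transformed, rmsd = superpose(mobile, reference, atom_map)
    mi = np.array([m for m, _ in atom_map], dtype=int)
    P = mobile.coords[mi]
    Pn = transformed.coords[mi]
    Pc, Pnc = P.mean(axis=0), Pn.mean(axis=0)
    H = (P - Pc).T @ (Pn - Pnc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = Pnc - R @ Pc
    return R, t, rmsd
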