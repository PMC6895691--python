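"""Synthetic fixtures with known ground truth.

Two families of toy systems make every pipeline stage testable without any
external structure or data download:

* ``make_toy_antibody`` - three dense pseudo-atomic lobes (two 'Fab', one
  'Fc') whose centre-of-mass triangle (d1, d2, d3) is specified exactly, for
  scattering/filtering tests;
* ``make_mini_antibody`` - a miniature hinged construct with ideal backbone
  geometry: two rigid poly-alanine 'Fab' helices and a two-helix 'Fc' joined
  by two extended linker chains, with two designated pseudo-cysteine C-alpha
  pairs, for Monte Carlo and constraint tests.

``simulate_experiment`` turns any model into a pair of duplicate noisy
scattering curves (hydrated X-ray or unhydrated neutron contrast).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coarse_grain import AVOGADRO, CM3_PER_NM3, SphereModel, add_hydration, \
    atoms_to_spheres
from .montecarlo import FlexibleResidue, LinkageScheme
from .scattering import NEUTRON, XRAY, ScatteringCurve, debye_curve
from .structures import AtomisticModel, CysPair, RegionScheme

PROTEIN_DENSITY = 1.35          # g/cm^3, typical globular protein

# Default simulated-instrument grids: a finely sampled X-ray curve and a
# sparse neutron curve, both to Q = 1.5 nm^-1.
XRAY_POINTS = 365
NEUTRON_POINTS = 45
Q_MAX_DEFAULT = 1.5

# Ideal backbone geometry (nm / degrees) used by the mini-antibody builder
BOND_N_CA = 0.1458
BOND_CA_C = 0.1525
BOND_C_N = 0.1329
BOND_C_O = 0.1229
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5


@dataclass
class ToySpec:
    """Three-lobe toy geometry: COM triangle (nm), lobe radii and density.

    ``lobe_radii`` orders the radii as (Fab1, Fab2, Fc); the slightly more
    compact Fc default reflects the real Fc region and breaks the exact
    Fab/Fc interchange degeneracy of three identical lobes.
    """

    d1: float = 8.0
    d2: float = 8.0
    d3: float = 8.0
    lobe_radii: tuple[float, float, float] = (2.0, 2.0, 1.4)
    points_per_lobe: int = 350
    seed: int = 0

    def __post_init__(self) -> None:
        d1, d2, d3 = self.d1, self.d2, self.d3
        if not (d1 < d2 + d3 and d2 < d1 + d3 and d3 < d1 + d2):
            raise ValueError(f"triangle inequality violated: {d1}, {d2}, {d3}")
        if isinstance(self.lobe_radii, (int, float)):
            self.lobe_radii = (float(self.lobe_radii),) * 3


def _uniform_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None]


def make_toy_antibody(spec: ToySpec) -> tuple[AtomisticModel, RegionScheme]:
    """Three uniform-density spherical lobes at the specified COM triangle.

    Each lobe is recentred so its centre of mass sits exactly on the target
    vertex, making the d1/d2/d3 ground truth exact.  Deterministic under the
    spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    x = (spec.d1 ** 2 + spec.d2 ** 2 - spec.d3 ** 2) / (2.0 * spec.d1)
    y = float(np.sqrt(max(spec.d2 ** 2 - x ** 2, 0.0)))
    coms = {"A": np.array([0.0, 0.0, 0.0]),
            "B": np.array([spec.d1, 0.0, 0.0]),
            "C": np.array([x, y, 0.0])}
    n = spec.points_per_lobe
    coords, chain, resnum = [], [], []
    for cid, radius in zip(("A", "B", "C"), spec.lobe_radii):
        pts = _uniform_ball(rng, n, radius)
        pts += coms[cid] - pts.mean(axis=0)
        coords.append(pts)
        chain.extend([cid] * n)
        resnum.extend(range(1, n + 1))
    coords = np.vstack(coords)
    n_tot = len(coords)
    model = AtomisticModel(
        coords=coords,
        element=np.full(n_tot, "C", dtype=object),
        is_heavy=np.ones(n_tot, dtype=bool),
        chain=np.asarray(chain, dtype=object),
        resnum=np.asarray(resnum, dtype=int),
        icode=np.full(n_tot, "", dtype=object),
        resname=np.full(n_tot, "ALA", dtype=object),
        atom_name=np.full(n_tot, "CA", dtype=object),
        model_id=f"toy_d{spec.d1:g}_{spec.d2:g}_{spec.d3:g}_s{spec.seed}",
    )
    scheme = RegionScheme(intervals=[("A", 1, n, "Fab1"), ("B", 1, n, "Fab2"),
                                     ("C", 1, n, "Fc")])
    return model, scheme


# ---------------------------------------------------------------------------
# Mini antibody with ideal backbone geometry
# ---------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float,
                angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom d from a-b-c internal
    coordinates."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg + 180.0)   # align with the IUPAC sign/zero
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(dih),
        bond * np.sin(ang) * np.sin(dih),
    ])
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def _build_backbone(n_res: int, phi: float, psi: float,
                    omega: float = 180.0) -> dict[str, np.ndarray]:
    """Backbone N/CA/C/O coordinates for an ideal-geometry peptide."""
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([BOND_N_CA, 0.0, 0.0])]
    ang = np.radians(ANGLE_N_CA_C)
    C = [CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for _ in range(1, n_res):
        N.append(_place_atom(N[-1], CA[-1], C[-1], BOND_C_N, ANGLE_CA_C_N, psi))
        CA.append(_place_atom(CA[-1], C[-1], N[-1], BOND_N_CA, ANGLE_C_N_CA, omega))
        C.append(_place_atom(C[-1], N[-1], CA[-1], BOND_CA_C, ANGLE_N_CA_C, phi))
    O = []
    for k in range(n_res):
        nxt_psi = psi if k < n_res - 1 else 180.0
        O.append(_place_atom(N[k], CA[k], C[k], BOND_C_O, ANGLE_CA_C_O,
                             nxt_psi + 180.0))
    return {"N": np.array(N), "CA": np.array(CA), "C": np.array(C),
            "O": np.array(O)}


def _chain_arrays(bb: dict[str, np.ndarray], chain_id: str, resname: str,
                  cys_residues: tuple[int, ...] = ()) -> dict[str, list]:
    n_res = len(bb["N"])
    out = {k: [] for k in ("xyz", "chain", "resnum", "resname", "atom_name")}
    for r in range(n_res):
        rname = "CYS" if (r + 1) in cys_residues else resname
        for name in ("N", "CA", "C", "O"):
            out["xyz"].append(bb[name][r])
            out["chain"].append(chain_id)
            out["resnum"].append(r + 1)
            out["resname"].append(rname)
            out["atom_name"].append(name)
    return out


def _orient_along_z(bb: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Rotate a built chain so its CA end-to-end vector lies along +z."""
    v = bb["CA"][-1] - bb["CA"][0]
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        R = np.eye(3)
    else:
        axis /= s
        ang = np.arccos(np.clip(np.dot(v, z), -1.0, 1.0))
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K
    origin = bb["CA"][0]
    return {k: (v_ - origin) @ R.T for k, v_ in bb.items()}


def make_mini_antibody(n_linker: int = 8,
                       seed: int = 0) -> tuple[AtomisticModel, LinkageScheme,
                                               RegionScheme]:
    """Miniature two-hinge construct for Monte Carlo tests.

    Two extended linker chains (A, B) of ``n_linker`` alanine residues with
    ideal backbone geometry run in parallel; rigid poly-alanine helices act
    as Fab1 (chain F), Fab2 (chain G) and a two-helix Fc (chains X, Y).
    Mid-linker residues on A and B are relabelled CYS and paired as the two
    constrained pseudo-disulphides.
    """
    if n_linker < 3:
        raise ValueError("n_linker must be >= 3")
    m1 = n_linker // 2
    m2 = min(m1 + 1, n_linker)

    link = _orient_along_z(_build_backbone(n_linker, phi=180.0, psi=180.0))
    helix = _orient_along_z(_build_backbone(8, phi=-57.0, psi=-47.0))

    sep = 0.55                                 # lateral chain separation, nm
    cols = {k: [] for k in ("xyz", "chain", "resnum", "resname", "atom_name")}

    def add(bb: dict[str, np.ndarray], shift: np.ndarray, chain_id: str,
            cys: tuple[int, ...] = ()) -> None:
        shifted = {k: v + shift for k, v in bb.items()}
        part = _chain_arrays(shifted, chain_id, "ALA", cys)
        for k in cols:
            cols[k].extend(part[k])

    add(link, np.array([0.0, 0.0, 0.0]), "A", cys=(m1, m2))
    add(link, np.array([sep, 0.0, 0.0]), "B", cys=(m1, m2))
    top = float(link["CA"][-1][2])
    helix_len = float(helix["CA"][-1][2])
    # Fab helices hang below the linker starts, the Fc pair sits above the
    # linker ends; offsets keep every inter-group gap well clear of the
    # clash cutoff.
    add(helix, np.array([0.0, 1.0, -helix_len - 1.0]), "F")
    add(helix, np.array([sep, -1.0, -helix_len - 1.0]), "G")
    add(helix, np.array([sep / 2 - 0.5, 0.0, top + 1.0]), "X")
    add(helix, np.array([sep / 2 + 0.5, 0.0, top + 1.0]), "Y")

    xyz = np.array(cols["xyz"])
    n_tot = len(xyz)
    model = AtomisticModel(
        coords=xyz,
        element=np.array([{"N": "N", "CA": "C", "C": "C", "O": "O"}[a]
                          for a in cols["atom_name"]], dtype=object),
        is_heavy=np.ones(n_tot, dtype=bool),
        chain=np.asarray(cols["chain"], dtype=object),
        resnum=np.asarray(cols["resnum"], dtype=int),
        icode=np.full(n_tot, "", dtype=object),
        resname=np.asarray(cols["resname"], dtype=object),
        atom_name=np.asarray(cols["atom_name"], dtype=object),
        model_id=f"mini_n{n_linker}_s{seed}",
    )
    chain_arr = model.chain
    bodies = {name: np.flatnonzero(chain_arr == cid)
              for name, cid in (("Fab1", "F"), ("Fab2", "G"))}
    bodies["Fc"] = np.flatnonzero((chain_arr == "X") | (chain_arr == "Y"))
    flexible = [FlexibleResidue(c, r) for c in ("A", "B")
                for r in range(1, n_linker + 1)]
    pairs = [
        (CysPair(("A", m1), ("B", m1), label=f"Cys{m1}-Cys{m1}"), 0.75),
        (CysPair(("A", m2), ("B", m2), label=f"Cys{m2}-Cys{m2}"), 0.75),
    ]
    scheme = LinkageScheme(
        flexible=flexible, rigid_bodies=bodies,
        attachments={"A": {"start": "Fab1", "end": "Fc"},
                     "B": {"start": "Fab2", "end": "Fc"}},
        constrained_pairs=pairs)
    regions = RegionScheme(intervals=[
        ("F", 1, 999, "Fab1"), ("G", 1, 999, "Fab2"),
        ("X", 1, 999, "Fc"), ("Y", 1, 999, "Fc"),
        ("A", 1, n_linker, "hinge"), ("B", 1, n_linker, "hinge")])
    return model, scheme, regions


# ---------------------------------------------------------------------------
# Simulated experiments
# ---------------------------------------------------------------------------

@dataclass
class SimulatedExperiment:
    """A duplicate pair of noisy curves plus the clean ground truth."""

    curve_a: ScatteringCurve
    curve_b: ScatteringCurve
    clean: ScatteringCurve
    spheres: SphereModel
    contrast: str
    noise_sigma_fraction: float
    background_fraction: float
    seed: int = 0


def effective_protein_mass(spheres: SphereModel) -> float:
    """Mass (g/mol) implied by the modelled volume at protein density."""
    v_protein = spheres.n_protein * spheres.cube_side ** 3
    return v_protein * CM3_PER_NM3 * PROTEIN_DENSITY * AVOGADRO


def coarse_grain_toy(model: AtomisticModel, contrast: str,
                     cube_side: float = 0.55, cutoff: int = 1,
                     hydration_ratio: float = 0.3) -> SphereModel:
    """Grid a toy model; hydrate for X-ray contrast (mass from volume)."""
    spheres = atoms_to_spheres(model, cube_side, cutoff=cutoff)
    if contrast == XRAY:
        spheres = add_hydration(spheres, effective_protein_mass(spheres),
                                hydration_ratio)
    elif contrast != NEUTRON:
        raise ValueError(f"unknown contrast {contrast!r}")
    return spheres


def simulate_experiment(model: AtomisticModel, contrast: str = XRAY,
                        q_points: int | None = None,
                        q_max: float = Q_MAX_DEFAULT,
                        noise_sigma_fraction: float = 0.01,
                        background_fraction: float = 0.0,
                        seed: int = 0,
                        cube_side: float = 0.55,
                        cutoff: int = 1) -> SimulatedExperiment:
    """Duplicate noisy scattering curves from a model with known truth.

    The model is coarse-grained (hydrated iff X-ray contrast), the Debye
    curve computed on the instrument grid, then each point multiplied by
    (1 + eps) with eps ~ N(0, sigma(Q)); sigma grows linearly from the base
    fraction at Q=0 to four times it at q_max, mimicking the weaker
    signal/noise at high Q.  Each duplicate additionally carries its own
    uncorrected flat background, drawn uniformly in [0, background_fraction]
    of I(0) - the analogue of the residual incoherent/instrumental baseline
    that differs between real repeat data sets.  The two duplicates carry
    independent noise and background.
    """
    if noise_sigma_fraction < 0:
        raise ValueError("noise must be >= 0")
    if q_points is None:
        q_points = XRAY_POINTS if contrast == XRAY else NEUTRON_POINTS
    spheres = coarse_grain_toy(model, contrast, cube_side, cutoff)
    q = np.linspace(q_max / q_points, q_max, q_points)
    clean = debye_curve(spheres, q, method="binned", contrast=contrast,
                        label=f"{model.model_id}_clean")
    rng = np.random.default_rng(seed)
    sigma = noise_sigma_fraction * (1.0 + 3.0 * q / q_max)
    i0 = spheres.n_spheres ** 2
    curves = []
    for dup in ("a", "b"):
        eps = rng.normal(0.0, 1.0, size=len(q)) * sigma
        bg = rng.uniform(0.0, background_fraction) * i0
        i_obs = clean.i * (1.0 + eps) + bg
        curves.append(ScatteringCurve(
            q=q.copy(), i=i_obs, sigma=clean.i * sigma, contrast=contrast,
            label=f"{model.model_id}_{contrast}_{dup}"))
    return SimulatedExperiment(
        curve_a=curves[0], curve_b=curves[1], clean=clean, spheres=spheres,
        contrast=contrast, noise_sigma_fraction=noise_sigma_fraction,
        background_fraction=background_fraction, seed=seed)


def toy_triangle_ensemble(n_models: int, seed: int,
                          d1_range: tuple[float, float] = (4.0, 12.0),
                          d23_range: tuple[float, float] = (5.0, 10.0),
                          lobe_radii: tuple[float, float, float] = (2.0, 2.0, 1.4),
                          points_per_lobe: int = 350) -> list[ToySpec]:
    """Random valid COM triangles spanning compact-to-extended geometries."""
    rng = np.random.default_rng(seed)
    specs: list[ToySpec] = []
    while len(specs) < n_models:
        d1 = rng.uniform(*d1_range)
        d2 = rng.uniform(*d23_range)
        d3 = rng.uniform(*d23_range)
        if not (d1 < d2 + d3 and d2 < d1 + d3 and d3 < d1 + d2):
            continue
        specs.append(ToySpec(d1=d1, d2=d2, d3=d3, lobe_radii=lobe_radii,
                             points_per_lobe=points_per_lobe,
                             seed=int(rng.integers(2 ** 31 - 1))))
    return specs
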