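"""Synthetic test-data generators.

Everything the validation pipeline consumes can be generated here
offline: toy protein-ligand complexes, matching restraint dictionaries,
"observed" density maps and reference metric corpora.  All generators
are pure functions of (spec, seed).

The bundled toy ligands are *synthetic* molecules: acyclic (tree)
topologies defined as Z-matrices, so that internal coordinates (bond
lengths, bond angles) can be perturbed independently and the Cartesian
coordinates rebuilt exactly.  "TL6" is a 6-heavy-atom triol
(glycerol-like size), "T11" an 11-heavy-atom branched heteroaromatic-
like tree (purine-like size).  Neither corresponds to a real chemical
component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .density import DensityGrid, GridSpec, calc_model_map
from .geometry import AngleRestraint, BondRestraint, CompRestraints, RestraintDictionary
from .model_io import Atom, LigandSelection, Structure
from .ranking import MetricSet

__all__ = [
    "ZEntry",
    "ToyComplexSpec",
    "TEMPLATES",
    "template_dictionary",
    "build_template",
    "make_toy_complex",
    "distort_ligand",
    "render_observed_map",
    "make_reference_corpus",
]


@dataclass(frozen=True)
class ZEntry:
    """One Z-matrix row: the atom is bonded to refs[0]; the angle is
    atom-refs[0]-refs[1]; the torsion atom-refs[0]-refs[1]-refs[2]."""

    name: str
    element: str
    refs: tuple[int, ...]  # () | (a,) | (a, b) | (a, b, c)
    bond: float = 0.0  # A
    bond_sigma: float = 0.02
    angle: float = 0.0  # degrees
    angle_sigma: float = 1.5
    torsion: float = 0.0  # degrees


# 6-atom triol: C1-C2-C3 backbone with a hydroxyl oxygen on each carbon.
_TL6 = (
    ZEntry("C1", "C", ()),
    ZEntry("C2", "C", (0,), 1.530),
    ZEntry("C3", "C", (1, 0), 1.530, 0.02, 112.0),
    ZEntry("O1", "O", (0, 1, 2), 1.420, 0.01, 109.5, 1.5, 60.0),
    ZEntry("O2", "O", (1, 0, 3), 1.420, 0.02, 109.5, 0.8, -60.0),
    ZEntry("O3", "O", (2, 1, 0), 1.420, 0.02, 109.5, 1.5, 180.0),
)

# 11-atom branched C/N/O tree, purine-sized but acyclic.
_T11 = (
    ZEntry("N1", "N", ()),
    ZEntry("C2", "C", (0,), 1.340),
    ZEntry("N3", "N", (1, 0), 1.330, 0.02, 120.0),
    ZEntry("C4", "C", (2, 1, 0), 1.350, 0.02, 118.0, 1.5, 180.0),
    ZEntry("C5", "C", (3, 2, 1), 1.400, 0.02, 122.0, 1.5, 180.0),
    ZEntry("C6", "C", (4, 3, 2), 1.390, 0.015, 117.0, 1.5, 180.0),
    ZEntry("N7", "N", (4, 3, 5), 1.380, 0.02, 110.0, 1.2, 120.0),
    ZEntry("C8", "C", (6, 4, 3), 1.370, 0.02, 105.0, 1.5, 180.0),
    ZEntry("N9", "N", (3, 2, 4), 1.360, 0.02, 125.0, 1.5, 150.0),
    ZEntry("N6", "N", (5, 4, 3), 1.340, 0.02, 120.0, 0.9, 180.0),
    ZEntry("O6", "O", (5, 4, 9), 1.240, 0.01, 121.0, 1.5, 180.0),
)

TEMPLATES: dict[str, tuple[ZEntry, ...]] = {"TL6": _TL6, "T11": _T11}


def _nerf_place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D bonded to a with angle D-a-b and torsion D-a-b-c."""
    theta = math.radians(angle_deg)
    phi = math.radians(torsion_deg)
    ab = b - a
    bc_hat = -ab / np.linalg.norm(ab)  # from b towards a, reversed chain sense
    n = np.cross(c - b, ab)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear torsion reference atoms")
    n_hat = n / nn
    m_hat = np.cross(n_hat, bc_hat)
    d_local = bond * np.array(
        [-math.cos(theta), math.sin(theta) * math.cos(phi), math.sin(theta) * math.sin(phi)]
    )
    return a + d_local[0] * bc_hat + d_local[1] * m_hat + d_local[2] * n_hat


def _build_cartesian(entries: Sequence[ZEntry],
                     bonds: Sequence[float], angles: Sequence[float]) -> np.ndarray:
    """Cartesian coordinates from a Z-matrix with supplied bond/angle
    values (torsions fixed at the template values)."""
    pos = np.zeros((len(entries), 3))
    for i, e in enumerate(entries):
        if i == 0:
            continue
        if i == 1:
            pos[1] = pos[e.refs[0]] + np.array([bonds[1], 0.0, 0.0])
            continue
        if i == 2:
            a, b = e.refs[0], e.refs[1]
            u = pos[b] - pos[a]
            u /= np.linalg.norm(u)
            v = np.array([-u[1], u[0], 0.0])
            nv = np.linalg.norm(v)
            v = np.array([0.0, 1.0, 0.0]) if nv < 1e-10 else v / nv
            th = math.radians(angles[2])
            pos[2] = pos[a] + bonds[2] * (math.cos(th) * u + math.sin(th) * v)
            continue
        a, b, c = e.refs
        pos[i] = _nerf_place(pos[a], pos[b], pos[c], bonds[i], angles[i], e.torsion)
    return pos


def build_template(comp_id: str) -> list[Atom]:
    """Toy ligand atoms in the canonical frame, exactly at the
    dictionary targets."""
    entries = TEMPLATES[comp_id]
    pos = _build_cartesian(entries, [e.bond for e in entries], [e.angle for e in entries])
    return [
        Atom(e.name, e.element, pos[i], occ=1.0, b=20.0, comp_id=comp_id, chain="B", seq_id=1)
        for i, e in enumerate(entries)
    ]


def template_dictionary(comp_ids: Sequence[str] = ("TL6", "T11")) -> RestraintDictionary:
    """Restraint dictionary for the bundled templates: targets and
    sigmas come straight from the Z-matrix definitions."""
    comps = []
    for cid in comp_ids:
        entries = TEMPLATES[cid]
        bonds = [
            BondRestraint(e.name, entries[e.refs[0]].name, e.bond, e.bond_sigma)
            for e in entries[1:]
        ]
        angles = [
            AngleRestraint(e.name, entries[e.refs[0]].name, entries[e.refs[1]].name,
                           e.angle, e.angle_sigma)
            for e in entries[2:]
        ]
        comps.append(CompRestraints(cid, [(e.name, e.element) for e in entries], bonds, angles))
    return RestraintDictionary(comps)


@dataclass
class ToyComplexSpec:
    """Parameters of a synthetic protein-ligand complex."""

    seed: int = 0
    n_pocket_atoms: int = 12
    ligand_template: str = "TL6"
    pocket_min_gap: float = 0.3  # A, vdW gap floor for placed pocket atoms
    b_range: tuple[float, float] = (15.0, 35.0)
    true_occupancy: float = 1.0
    rotate_ligand: bool = True

    def __post_init__(self) -> None:
        if self.pocket_min_gap <= -1.0:
            raise ValueError("pocket_min_gap must exceed -1 A")
        if min(self.b_range) < 0:
            raise ValueError("b_range must be non-negative")
        if not 0.0 <= self.true_occupancy <= 1.0:
            raise ValueError("true_occupancy must lie in [0, 1]")


_POCKET_ELEMENTS = ("C", "C", "N", "O")  # carbon-rich, like a protein pocket
_VDW = {"C": 1.90, "N": 1.70, "O": 1.60, "S": 1.95, "P": 1.95}


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


def make_toy_complex(spec: ToyComplexSpec) -> tuple[Structure, RestraintDictionary]:
    """Build a deterministic synthetic complex.

    The ligand sits exactly at its dictionary geometry (rigidly rotated
    and translated); pocket atoms are placed one per pseudo-residue on
    a polymer chain, rejection-sampled so that every ligand-pocket vdW
    gap is >= pocket_min_gap.
    """
    rng = np.random.default_rng(spec.seed)
    lig_atoms = build_template(spec.ligand_template)
    lig_pos = np.array([a.pos for a in lig_atoms])
    if spec.rotate_ligand:
        R = _random_rotation(rng)
        lig_pos = lig_pos @ R.T
    center = lig_pos.mean(axis=0)
    lig_pos = lig_pos - center + np.array([25.0, 25.0, 25.0])
    for a, p in zip(lig_atoms, lig_pos):
        a.pos = p
        a.b = float(rng.uniform(*spec.b_range))

    atoms: list[Atom] = []
    for i in range(spec.n_pocket_atoms):
        el = _POCKET_ELEMENTS[int(rng.integers(len(_POCKET_ELEMENTS)))]
        placed = False
        for _ in range(2000):
            # aim near the gap floor off a random ligand atom, so the
            # pocket actually hugs the ligand
            anchor = lig_atoms[int(rng.integers(len(lig_atoms)))]
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            d = _VDW[el] + _VDW[anchor.element] + spec.pocket_min_gap + float(rng.exponential(0.8))
            cand = anchor.pos + d * u
            gaps = [
                float(np.linalg.norm(cand - la.pos)) - _VDW[el] - _VDW[la.element]
                for la in lig_atoms
            ]
            prev_ok = all(
                np.linalg.norm(cand - pa.pos) >= 2.8 for pa in atoms
            )
            if min(gaps) >= spec.pocket_min_gap and prev_ok:
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place pocket atom with the requested gap")
        atoms.append(
            Atom(el, el, cand, occ=1.0, b=float(rng.uniform(*spec.b_range)),
                 comp_id="ALA", chain="A", seq_id=i + 1, is_polymer=True)
        )
    atoms.extend(lig_atoms)
    st = Structure(atoms=atoms, resolution_nominal=1.8, name=f"toy-{spec.ligand_template}-{spec.seed}")
    return st, template_dictionary()


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t minimizing ||R P + t - Q||."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, qc - R @ pc


def distort_ligand(
    lig: LigandSelection | Sequence[Atom],
    bond_sigma_mult: float = 1.0,
    angle_sigma_mult: float = 1.0,
    seed: int = 0,
) -> list[Atom]:
    """Perturb the ligand's internal coordinates and rebuild Cartesian.

    Each Z-matrix bond length gets N(0, (lambda*sigma_dict)^2) noise and
    each angle N(0, (mu*sigma_dict)^2); torsions are untouched.  The
    rebuilt molecule is superposed back onto the input frame, so
    lambda = mu = 0 reproduces the input coordinates.
    """
    if bond_sigma_mult < 0 or angle_sigma_mult < 0:
        raise ValueError("sigma multipliers must be >= 0")
    atoms = list(lig.atoms) if isinstance(lig, LigandSelection) else list(lig)
    comp_id = atoms[0].comp_id
    entries = TEMPLATES[comp_id]
    by_name = {a.name: a for a in atoms}
    order = [by_name[e.name] for e in entries]

    rng = np.random.default_rng(seed)
    bonds = [e.bond + bond_sigma_mult * e.bond_sigma * rng.normal() if i >= 1 else 0.0
             for i, e in enumerate(entries)]
    angles = [e.angle + angle_sigma_mult * e.angle_sigma * rng.normal() if i >= 2 else 0.0
              for i, e in enumerate(entries)]

    canonical = _build_cartesian(entries, [e.bond for e in entries], [e.angle for e in entries])
    distorted = _build_cartesian(entries, bonds, angles)
    current = np.array([a.pos for a in order])
    R, t = _kabsch(canonical, current)
    new_pos = distorted @ R.T + t
    return [replace(a, pos=new_pos[i].copy()) for i, a in enumerate(order)]


def render_observed_map(
    s: Structure,
    lig: LigandSelection,
    true_occupancy: float,
    noise_sigma: float = 0.0,
    grid: GridSpec | None = None,
    seed: int = 0,
) -> DensityGrid:
    """Synthesize the "observed" map: full model with the ligand at
    ``true_occupancy`` plus i.i.d. Gaussian grid noise."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if grid is None:
        grid = GridSpec.around_atoms(s.atoms)
    lig_keys = lig.atom_keys()
    env_map = calc_model_map([a for a in s.atoms if a.key() not in lig_keys], grid)
    lig_unit = calc_model_map(
        [replace(a, occ=1.0) for a in lig.atoms], grid
    )
    values = env_map.values + true_occupancy * lig_unit.values
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sigma, size=values.shape)
    return DensityGrid(np.asarray(grid.origin, float).copy(), grid.spacing, values)


DEFAULT_CORPUS_MEDIANS = {
    "cc_direct": 0.85,
    "cc_diff": -0.073,
    "z_worst": 1.6,
    "n_bad": 1,
}


def _poisson_rate_for_median(target: int) -> float:
    """Smallest-ish rate whose Poisson median equals ``target``; solved
    from the CDF (P(X <= target) pinned at 0.57 keeps the sample median
    stable at large n)."""
    from scipy.optimize import brentq
    from scipy.stats import poisson

    if target == 0:
        return float(brentq(lambda lam: poisson.cdf(0, lam) - 0.57, 1e-6, 10.0))
    return float(brentq(lambda lam: poisson.cdf(target, lam) - 0.57, 1e-6, 10.0 * target + 10))


def make_reference_corpus(
    n: int,
    seed: int = 0,
    target_medians: dict | None = None,
) -> list[MetricSet]:
    """Draw a synthetic reference corpus of ligand metrics.

    Families: cc_direct = 1 - 2*Beta(1, beta) (shifted Beta with the
    requested median), cc_diff ~ Normal(median, 0.15) clipped to
    [-1, 1], z_worst ~ LogNormal(ln median, 0.5), n_bad ~ Poisson with
    the rate solved from the requested integer median.
    """
    if n < 10:
        raise ValueError("corpus needs n >= 10")
    med = dict(DEFAULT_CORPUS_MEDIANS)
    if target_medians:
        med.update(target_medians)
    rng = np.random.default_rng(seed)

    half_gap = (1.0 - med["cc_direct"]) / 2.0
    beta_b = math.log(0.5) / math.log(1.0 - half_gap)
    cc_direct = 1.0 - 2.0 * rng.beta(1.0, beta_b, size=n)
    cc_diff = np.clip(rng.normal(med["cc_diff"], 0.15, size=n), -1.0, 1.0)
    z_worst = rng.lognormal(math.log(med["z_worst"]), 0.5, size=n)
    n_bad = rng.poisson(_poisson_rate_for_median(int(med["n_bad"])), size=n)
    r_nom = rng.uniform(1.0, 3.5, size=n)
    comp_pool = ("TL6", "T11", "AAA", "BBB", "CCC")

    return [
        MetricSet(
            accession=f"SYN{i:05d}",
            comp_id=comp_pool[int(rng.integers(len(comp_pool)))],
            cc_direct=float(np.clip(cc_direct[i], -1.0, 1.0)),
            cc_diff=float(cc_diff[i]),
            z_worst=float(z_worst[i]),
            n_bad=int(n_bad[i]),
            chain="B",
            seq_id=1,
            r_nom=float(r_nom[i]),
        )
        for i in range(n)
    ]
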