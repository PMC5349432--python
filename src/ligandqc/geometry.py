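"""Ligand internal-geometry scoring against a restraint dictionary.

Every bond length and bond angle of the ligand model is compared with
the dictionary target and its standard deviation to give a signed
Z-value, Z = (observed - target) / max(sigma, floor).  The sigma floors
(0.015 A for bonds, 1 deg for angles) guard against overconfident
claims from restraints with unrealistically tight sigmas; flooring can
only lower |Z|.  The summary statistic is Z-worst: the feature with the
largest absolute Z.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from gemmi import cif

from .model_io import Atom, LigandSelection

__all__ = [
    "BOND_SIGMA_FLOOR",
    "ANGLE_SIGMA_FLOOR",
    "BondRestraint",
    "AngleRestraint",
    "CompRestraints",
    "RestraintDictionary",
    "GeometryFeature",
    "GeometryZReport",
    "load_dictionary",
    "write_dictionary",
    "geometry_z",
    "z_worst_report",
    "likelihood_class",
]

BOND_SIGMA_FLOOR = 0.015  # Angstrom
ANGLE_SIGMA_FLOOR = 1.0  # degrees


@dataclass(frozen=True)
class BondRestraint:
    atom1: str
    atom2: str
    target: float  # A
    sigma: float  # A


@dataclass(frozen=True)
class AngleRestraint:
    atom1: str
    atom2: str
    atom3: str
    target: float  # degrees
    sigma: float  # degrees


@dataclass
class CompRestraints:
    """Restraints for one chemical component (comp-id)."""

    comp_id: str
    atoms: list[tuple[str, str]]  # (name, element)
    bonds: list[BondRestraint] = field(default_factory=list)
    angles: list[AngleRestraint] = field(default_factory=list)

    @property
    def n_heavy(self) -> int:
        return sum(1 for _, el in self.atoms if el.upper() != "H")

    def atom_names(self) -> set[str]:
        return {n for n, _ in self.atoms}

    def element_of(self, name: str) -> str:
        for n, el in self.atoms:
            if n == name:
                return el
        raise KeyError(name)

    def validate(self) -> None:
        names = self.atom_names()
        seen_b: set[frozenset[str]] = set()
        for b in self.bonds:
            if b.atom1 not in names or b.atom2 not in names:
                raise ValueError(
                    f"{self.comp_id}: bond {b.atom1}-{b.atom2} names an unknown atom"
                )
            if b.sigma <= 0:
                raise ValueError(f"{self.comp_id}: bond {b.atom1}-{b.atom2} has sigma <= 0")
            key = frozenset((b.atom1, b.atom2))
            if key in seen_b:
                raise ValueError(f"{self.comp_id}: duplicate restraint {b.atom1}-{b.atom2}")
            seen_b.add(key)
        seen_a: set[tuple[str, ...]] = set()
        for a in self.angles:
            for nm in (a.atom1, a.atom2, a.atom3):
                if nm not in names:
                    raise ValueError(
                        f"{self.comp_id}: angle {a.atom1}-{a.atom2}-{a.atom3} names unknown atom {nm}"
                    )
            if a.sigma <= 0:
                raise ValueError(
                    f"{self.comp_id}: angle {a.atom1}-{a.atom2}-{a.atom3} has sigma <= 0"
                )
            key = min((a.atom1, a.atom2, a.atom3), (a.atom3, a.atom2, a.atom1))
            if key in seen_a:
                raise ValueError(
                    f"{self.comp_id}: duplicate restraint {a.atom1}-{a.atom2}-{a.atom3}"
                )
            seen_a.add(key)


class RestraintDictionary:
    """Per-comp-id bond and angle restraints (monomer-library style)."""

    def __init__(self, comps: Iterable[CompRestraints] = ()) -> None:
        self._comps: dict[str, CompRestraints] = {}
        for c in comps:
            self.add(c)

    def add(self, comp: CompRestraints) -> None:
        comp.validate()
        self._comps[comp.comp_id] = comp

    def __contains__(self, comp_id: str) -> bool:
        return comp_id in self._comps

    def __getitem__(self, comp_id: str) -> CompRestraints:
        return self._comps[comp_id]

    def __iter__(self):
        return iter(self._comps.values())

    def __len__(self) -> int:
        return len(self._comps)

    def comp_ids(self) -> list[str]:
        return sorted(self._comps)


def load_dictionary(path: str | Path) -> RestraintDictionary:
    """Parse a monomer-library-style mmCIF restraint dictionary.

    Expects _chem_comp_atom, _chem_comp_bond (value_dist/value_dist_esd)
    and _chem_comp_angle (value_angle/value_angle_esd) categories; each
    data block contributes the comp-ids named in its rows.
    """
    doc = cif.read(str(path))
    comps: dict[str, CompRestraints] = {}

    def get_comp(comp_id: str) -> CompRestraints:
        if comp_id not in comps:
            comps[comp_id] = CompRestraints(comp_id, atoms=[])
        return comps[comp_id]

    for block in doc:
        atab = block.find("_chem_comp_atom.", ["comp_id", "atom_id", "type_symbol"])
        for row in atab:
            get_comp(row[0]).atoms.append((cif.as_string(row[1]), cif.as_string(row[2])))
        btab = block.find(
            "_chem_comp_bond.",
            ["comp_id", "atom_id_1", "atom_id_2", "value_dist", "value_dist_esd"],
        )
        if block.find_loop("_chem_comp_bond.comp_id") and not btab:
            # bond category present but missing the value/esd columns
            raise ValueError(f"{path}: bond restraints lack value_dist/value_dist_esd")
        for row in btab:
            if cif.is_null(row[3]) or cif.is_null(row[4]):
                raise ValueError(f"{path}: bond restraint with missing target/sigma")
            get_comp(row[0]).bonds.append(
                BondRestraint(
                    cif.as_string(row[1]), cif.as_string(row[2]),
                    cif.as_number(row[3]), cif.as_number(row[4]),
                )
            )
        gtab = block.find(
            "_chem_comp_angle.",
            ["comp_id", "atom_id_1", "atom_id_2", "atom_id_3", "value_angle", "value_angle_esd"],
        )
        if block.find_loop("_chem_comp_angle.comp_id") and not gtab:
            raise ValueError(f"{path}: angle restraints lack value_angle/value_angle_esd")
        for row in gtab:
            if cif.is_null(row[4]) or cif.is_null(row[5]):
                raise ValueError(f"{path}: angle restraint with missing target/sigma")
            get_comp(row[0]).angles.append(
                AngleRestraint(
                    cif.as_string(row[1]), cif.as_string(row[2]), cif.as_string(row[3]),
                    cif.as_number(row[4]), cif.as_number(row[5]),
                )
            )
    return RestraintDictionary(comps.values())


def write_dictionary(d: RestraintDictionary, path: str | Path) -> None:
    """Write restraints as a monomer-library-style mmCIF file."""
    doc = cif.Document()
    for comp in d:
        block = doc.add_new_block(f"comp_{comp.comp_id}")
        loop = block.init_loop("_chem_comp_atom.", ["comp_id", "atom_id", "type_symbol"])
        for name, el in comp.atoms:
            loop.add_row([comp.comp_id, name, el])
        if comp.bonds:
            loop = block.init_loop(
                "_chem_comp_bond.",
                ["comp_id", "atom_id_1", "atom_id_2", "value_dist", "value_dist_esd"],
            )
            for b in comp.bonds:
                loop.add_row([comp.comp_id, b.atom1, b.atom2, f"{b.target:.4f}", f"{b.sigma:.4f}"])
        if comp.angles:
            loop = block.init_loop(
                "_chem_comp_angle.",
                ["comp_id", "atom_id_1", "atom_id_2", "atom_id_3", "value_angle", "value_angle_esd"],
            )
            for a in comp.angles:
                loop.add_row(
                    [comp.comp_id, a.atom1, a.atom2, a.atom3, f"{a.target:.3f}", f"{a.sigma:.3f}"]
                )
    doc.write_file(str(path))


def geometry_z(
    observed: float, target: float, sigma: float, kind: Literal["bond", "angle"]
) -> float:
    """Signed Z-value with the sigma floor applied.

    floor = 0.015 A for bonds, 1.0 deg for angles;
    Z = (observed - target) / max(sigma, floor).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if kind == "bond":
        floor = BOND_SIGMA_FLOOR
    elif kind == "angle":
        floor = ANGLE_SIGMA_FLOOR
    else:
        raise ValueError(f"unknown feature kind {kind!r}")
    return (observed - target) / max(sigma, floor)


@dataclass
class GeometryFeature:
    kind: Literal["bond", "angle"]
    atoms: tuple[str, ...]
    observed: float
    target: float
    sigma_raw: float
    sigma_eff: float
    z: float


@dataclass
class GeometryZReport:
    """All scored bond/angle features plus the Z-worst summary."""

    features: list[GeometryFeature]
    z_worst: GeometryFeature | None
    n_features: int
    n_skipped: int = 0

    def to_json(self) -> str:
        def feat(f: GeometryFeature) -> dict:
            return {
                "kind": f.kind, "atoms": list(f.atoms), "observed": f.observed,
                "target": f.target, "sigma_raw": f.sigma_raw,
                "sigma_eff": f.sigma_eff, "z": f.z,
            }

        return json.dumps(
            {
                "n_features": self.n_features,
                "n_skipped": self.n_skipped,
                "z_worst": feat(self.z_worst) if self.z_worst else None,
                "features": [feat(f) for f in self.features],
            },
            indent=1,
        )

    def to_tsv(self) -> str:
        lines = ["kind\tatoms\tobserved\ttarget\tsigma_raw\tsigma_eff\tz"]
        for f in self.features:
            lines.append(
                f"{f.kind}\t{'-'.join(f.atoms)}\t{f.observed:.4f}\t{f.target:.4f}"
                f"\t{f.sigma_raw:.4f}\t{f.sigma_eff:.4f}\t{f.z:.3f}"
            )
        return "\n".join(lines) + "\n"


def bond_length(p1: np.ndarray, p2: np.ndarray) -> float:
    return float(np.linalg.norm(p2 - p1))


def bond_angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Angle at p2 in degrees, via arccos of the normalized dot product."""
    v1 = p1 - p2
    v2 = p3 - p2
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ZeroDivisionError("zero-length bond vector in angle computation")
    c = float(np.dot(v1, v2) / (n1 * n2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def z_worst_report(
    lig: LigandSelection | Sequence[Atom],
    dictionary: RestraintDictionary,
    comp_id: str | None = None,
) -> GeometryZReport:
    """Score every dictionary bond and angle of the ligand.

    Restraints involving hydrogen, or naming atoms absent from the
    model, are skipped with a warning and counted in ``n_skipped``.
    Z-worst is the feature with max |Z|; on a tie the first in (bonds
    before angles, dictionary order) wins.
    """
    if isinstance(lig, LigandSelection):
        atoms = lig.atoms
        comp_id = comp_id or lig.comp_id
    else:
        atoms = list(lig)
        if comp_id is None:
            if not atoms:
                raise ValueError("empty atom list and no comp_id")
            comp_id = atoms[0].comp_id
    comp = dictionary[comp_id]
    pos = {a.name: a.pos for a in atoms}
    hydrogens = {n for n, el in comp.atoms if el.upper() == "H"}

    features: list[GeometryFeature] = []
    n_skipped = 0
    for b in comp.bonds:
        names = (b.atom1, b.atom2)
        if any(n in hydrogens for n in names):
            n_skipped += 1
            continue
        if any(n not in pos for n in names):
            warnings.warn(f"bond {b.atom1}-{b.atom2}: atom missing from model; skipped")
            n_skipped += 1
            continue
        obs = bond_length(pos[b.atom1], pos[b.atom2])
        sig_eff = max(b.sigma, BOND_SIGMA_FLOOR)
        features.append(
            GeometryFeature("bond", names, obs, b.target, b.sigma, sig_eff,
                            geometry_z(obs, b.target, b.sigma, "bond"))
        )
    for a in comp.angles:
        names = (a.atom1, a.atom2, a.atom3)
        if any(n in hydrogens for n in names):
            n_skipped += 1
            continue
        if any(n not in pos for n in names):
            warnings.warn(f"angle {'-'.join(names)}: atom missing from model; skipped")
            n_skipped += 1
            continue
        try:
            obs = bond_angle(pos[a.atom1], pos[a.atom2], pos[a.atom3])
        except ZeroDivisionError:
            warnings.warn(f"angle {'-'.join(names)}: zero-length bond vector; skipped")
            n_skipped += 1
            continue
        sig_eff = max(a.sigma, ANGLE_SIGMA_FLOOR)
        features.append(
            GeometryFeature("angle", names, obs, a.target, a.sigma, sig_eff,
                            geometry_z(obs, a.target, a.sigma, "angle"))
        )

    worst: GeometryFeature | None = None
    for f in features:
        if worst is None or abs(f.z) > abs(worst.z):
            worst = f
    return GeometryZReport(features, worst, n_features=len(features), n_skipped=n_skipped)


def likelihood_class(z: float) -> tuple[str, float]:
    """Slider classification of a Z-value.

    |Z| <= 1 is "likely" (score 1), |Z| >= 5 "unlikely" (score 0),
    linear in between; returns (label, score).
    """
    az = abs(z)
    if az <= 1.0:
        return "likely", 1.0
    if az >= 5.0:
        return "unlikely", 0.0
    return "intermediate", (5.0 - az) / 4.0
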