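"""Ligand-environment contact analysis on heavy atoms.

Contacts are classified by the van der Waals gap
gap = distance - r_vdw(ligand atom) - r_vdw(environment atom)
into the four slider/dot categories: wide (> +0.25 A), close
(0 < gap <= 0.25), small-overlap (-0.4 <= gap <= 0) and bad
(gap < -0.4, the MolProbity clash convention).  Potentially
hydrogen-bonding N/O...N/O pairs have their gap relaxed by 0.2 A before
classification, since such approaches are favourable rather than
clashes.  The bad-contact count is the metric entering the ranking.

United-atom vdW radii on heavy atoms replace explicit-H dot-surface
analysis; absolute counts therefore differ from Probe's, but the
recorded quantity (an integer count of badly overlapping pairs) is the
same.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geometry import RestraintDictionary
from .model_io import Atom, AtomRef, LigandSelection, Structure

__all__ = [
    "DEFAULT_VDW",
    "ContactRecord",
    "ContactConfig",
    "find_contacts",
    "count_bad_contacts",
    "categorize_gap",
    "contacts_tsv",
]

#: United-atom van der Waals radii (A).
DEFAULT_VDW: dict[str, float] = {"C": 1.90, "N": 1.70, "O": 1.60, "S": 1.95, "P": 1.95}

HBOND_ELEMENTS = frozenset({"N", "O"})


@dataclass
class ContactConfig:
    radii: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW))
    default_radius: float = 1.7
    max_gap: float = 1.0
    bad_threshold: float = -0.4
    close_threshold: float = 0.25
    hbond_relaxation: float = 0.2
    relax_hbonds: bool = True


@dataclass
class ContactRecord:
    ligand_atom: Atom
    env_atom: Atom
    distance: float
    gap: float  # after any H-bond relaxation
    category: str  # wide | close | small-overlap | bad


def categorize_gap(gap: float, cfg: ContactConfig | None = None) -> str:
    """Category as a pure function of the (possibly relaxed) gap."""
    cfg = cfg or ContactConfig()
    if gap > cfg.close_threshold:
        return "wide"
    if gap > 0.0:
        return "close"
    if gap >= cfg.bad_threshold:
        return "small-overlap"
    return "bad"


def _vdw(element: str, cfg: ContactConfig) -> float:
    r = cfg.radii.get(element.capitalize())
    if r is None:
        warnings.warn(f"no vdW radius for element {element!r}; using {cfg.default_radius} A")
        r = cfg.default_radius
    return r


def _excluded_pairs(
    lig: LigandSelection,
    links: Sequence[tuple[AtomRef, AtomRef]],
    dictionary: RestraintDictionary | None,
) -> set[frozenset[AtomRef]]:
    """Pairs never reported: covalently linked pairs and 1-3 pairs
    reachable through a link via one dictionary bond on the ligand side."""
    lig_keys = lig.atom_keys()
    out: set[frozenset[AtomRef]] = set()
    bonded_to: dict[str, set[str]] = {}
    if dictionary is not None and lig.comp_id in dictionary:
        for b in dictionary[lig.comp_id].bonds:
            bonded_to.setdefault(b.atom1, set()).add(b.atom2)
            bonded_to.setdefault(b.atom2, set()).add(b.atom1)
    for r1, r2 in links:
        out.add(frozenset((r1, r2)))
        for lig_ref, env_ref in ((r1, r2), (r2, r1)):
            if lig_ref in lig_keys and env_ref not in lig_keys:
                for nb in bonded_to.get(lig_ref[2], ()):
                    out.add(frozenset(((lig_ref[0], lig_ref[1], nb), env_ref)))
    return out


def find_contacts(
    lig: LigandSelection,
    env: Sequence[Atom],
    cfg: ContactConfig | None = None,
    links: Sequence[tuple[AtomRef, AtomRef]] = (),
    dictionary: RestraintDictionary | None = None,
) -> list[ContactRecord]:
    """All ligand-environment heavy-atom pairs with gap <= max_gap,
    categorized; pairs related by a covalent link are excluded."""
    cfg = cfg or ContactConfig()
    excluded = _excluded_pairs(lig, links, dictionary)
    out: list[ContactRecord] = []
    for la in lig.atoms:
        if la.element.upper() == "H":
            continue
        rl = _vdw(la.element, cfg)
        for ea in env:
            if ea.element.upper() == "H":
                continue
            if frozenset((la.key(), ea.key())) in excluded:
                continue
            d = float(np.linalg.norm(la.pos - ea.pos))
            gap = d - rl - _vdw(ea.element, cfg)
            if (
                cfg.relax_hbonds
                and la.element.upper() in HBOND_ELEMENTS
                and ea.element.upper() in HBOND_ELEMENTS
            ):
                gap += cfg.hbond_relaxation
            if gap <= cfg.max_gap:
                out.append(ContactRecord(la, ea, d, gap, categorize_gap(gap, cfg)))
    out.sort(key=lambda c: (c.ligand_atom.name, c.env_atom.chain, c.env_atom.seq_id, c.env_atom.name))
    return out


def count_bad_contacts(contacts: Sequence[ContactRecord]) -> int:
    """Number of badly overlapping ligand-environment pairs (R_bumps input)."""
    return sum(1 for c in contacts if c.category == "bad")


def contacts_tsv(contacts: Sequence[ContactRecord]) -> str:
    lines = ["ligand_atom\tenv_atom\tdistance\tgap\tcategory"]
    for c in contacts:
        lines.append(
            f"{c.ligand_atom.name}\t{c.env_atom.chain}{c.env_atom.seq_id}:{c.env_atom.name}"
            f"\t{c.distance:.3f}\t{c.gap:.3f}\t{c.category}"
        )
    return "\n".join(lines) + "\n"
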