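"""Coordinate-file handling and ligand selection.

Reads PDB/mmCIF files into a lightweight atom list, enumerates the
non-polymer residues and applies the four ligand-selection criteria:
the candidate residue type must (i) not be an obsolete chemical
component, (ii) have no covalent LINK/struct_conn record, (iii) have no
atoms in alternate conformations and (iv) come from a structure whose
data are available and untwinned.  Among admissible types the one with
the most non-hydrogen atoms *in the restraint dictionary* wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import gemmi
import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .geometry import RestraintDictionary

__all__ = [
    "Atom",
    "Structure",
    "LigandSelection",
    "STANDARD_RESIDUES",
    "read_structure",
    "write_structure",
    "select_ligand",
    "neighbourhood",
    "read_obsolete_list",
]

#: Residue names never considered ligand candidates: water, the 20
#: standard amino acids and the standard (deoxy)ribonucleotides.
STANDARD_RESIDUES: frozenset[str] = frozenset(
    {
        "HOH", "WAT", "DOD",
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
        "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
        "TYR", "VAL",
        "A", "C", "G", "U", "DA", "DC", "DG", "DT", "DU",
    }
)


@dataclass
class Atom:
    """One atom site.

    ``altloc`` is a single character, ``""`` when the atom has no
    alternate location.  ``is_polymer`` marks atoms that belong to the
    macromolecule (protein/nucleic chain) as opposed to heteroatoms.
    """

    name: str
    element: str
    pos: np.ndarray  # shape (3,), Angstrom
    occ: float = 1.0
    b: float = 20.0
    altloc: str = ""
    comp_id: str = "UNK"
    chain: str = "A"
    seq_id: int = 1
    is_polymer: bool = False

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if not 0.0 <= self.occ <= 1.0:
            raise ValueError(f"occupancy {self.occ} outside [0, 1]")
        if self.b < 0:
            raise ValueError(f"negative B-factor {self.b}")
        if not self.element:
            raise ValueError("empty element symbol")

    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seq_id, self.name)


#: Reference to an atom inside a Structure: (chain, seq_id, atom name).
AtomRef = tuple[str, int, str]


@dataclass
class Structure:
    """A parsed coordinate file: atoms plus covalent-link records and
    the data-availability metadata consumed by selection criterion (iv)."""

    atoms: list[Atom] = field(default_factory=list)
    links: list[tuple[AtomRef, AtomRef]] = field(default_factory=list)
    data_meta: dict = field(default_factory=lambda: {"data_available": True, "twinned": False})
    resolution_nominal: float | None = None
    name: str = ""

    def linked_atom_refs(self) -> set[AtomRef]:
        out: set[AtomRef] = set()
        for a, b in self.links:
            out.add(a)
            out.add(b)
        return out

    def residues(self) -> dict[tuple[str, int, str], list[Atom]]:
        """Group atoms into residues keyed by (chain, seq_id, comp_id)."""
        groups: dict[tuple[str, int, str], list[Atom]] = {}
        for a in self.atoms:
            groups.setdefault((a.chain, a.seq_id, a.comp_id), []).append(a)
        return groups


@dataclass
class LigandSelection:
    """The chosen ligand instance plus the log of rejected candidates.

    ``rejections`` holds (candidate-description, reason-code) pairs;
    an empty ``atoms`` list means no admissible ligand was found.
    """

    comp_id: str = ""
    chain: str = ""
    seq_id: int = 0
    atoms: list[Atom] = field(default_factory=list)
    n_heavy: int = 0
    rejections: list[tuple[str, str]] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.atoms)

    def atom_keys(self) -> set[AtomRef]:
        return {a.key() for a in self.atoms}


def _altloc_str(a: gemmi.Atom) -> str:
    return a.altloc if a.altloc not in ("\x00", " ") else ""


def read_structure(path: str | Path, fmt: str = "auto") -> Structure:
    """Read a PDB or mmCIF coordinate file (model 1 only).

    Polymer/non-polymer classification uses the HETATM flag where
    present, falling back to the standard-residue list.  LINK (PDB) and
    _struct_conn (mmCIF) records populate ``Structure.links``; links
    naming absent atoms are kept (flagged dangling via a warning).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse coordinate file {path}: {exc}") from exc

    st.setup_entities()
    out = Structure(name=st.name or path.stem)
    if st.resolution and st.resolution > 0:
        out.resolution_nominal = float(st.resolution)

    if len(st) == 0:
        return out
    model = st[0]
    for chain in model:
        polymer_seqids = {r.seqid.num for r in chain.get_polymer()}
        for res in chain:
            het = res.het_flag  # 'A' ATOM, 'H' HETATM, '\0' unknown
            if het == "A":
                is_poly = True
            elif het == "H":
                is_poly = False
            else:
                is_poly = res.seqid.num in polymer_seqids or res.name in STANDARD_RESIDUES
            for at in res:
                elem = at.element.name
                if not elem or elem == "X":
                    warnings.warn(f"unknown element for atom {at.name} in {res.name}; kept")
                    elem = at.name[:1] or "C"
                out.atoms.append(
                    Atom(
                        name=at.name,
                        element=elem,
                        pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occ=min(max(float(at.occ), 0.0), 1.0),
                        b=max(float(at.b_iso), 0.0),
                        altloc=_altloc_str(at),
                        comp_id=res.name,
                        chain=chain.name,
                        seq_id=res.seqid.num,
                        is_polymer=is_poly,
                    )
                )

    present = {a.key() for a in out.atoms}
    for con in st.connections:
        if con.type == gemmi.ConnectionType.Hydrog:
            continue
        p1, p2 = con.partner1, con.partner2
        r1: AtomRef = (p1.chain_name, p1.res_id.seqid.num, p1.atom_name)
        r2: AtomRef = (p2.chain_name, p2.res_id.seqid.num, p2.atom_name)
        if r1 not in present or r2 not in present:
            warnings.warn(f"dangling link record {r1}--{r2}")
        out.links.append((r1, r2))
    return out


def write_structure(s: Structure, path: str | Path, fmt: str = "auto") -> None:
    """Write a Structure as PDB or mmCIF (by extension when ``auto``)."""
    path = Path(path)
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"

    st = gemmi.Structure()
    st.name = s.name or "ligandqc"
    st.cell = gemmi.UnitCell(200, 200, 200, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    if s.resolution_nominal:
        st.resolution = s.resolution_nominal
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for a in s.atoms:
        ch = chains.get(a.chain)
        if ch is None:
            ch = gemmi.Chain(a.chain)
            chains[a.chain] = ch
            model.add_chain(ch)
            ch = model[len(model) - 1]
            chains[a.chain] = ch
        res = None
        if len(ch) > 0 and ch[len(ch) - 1].seqid.num == a.seq_id and ch[len(ch) - 1].name == a.comp_id:
            res = ch[len(ch) - 1]
        if res is None:
            r = gemmi.Residue()
            r.name = a.comp_id
            r.seqid = gemmi.SeqId(a.seq_id, " ")
            r.het_flag = "A" if a.is_polymer else "H"
            ch.add_residue(r)
            res = ch[len(ch) - 1]
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.pos)
        at.occ = a.occ
        at.b_iso = a.b
        if a.altloc:
            at.altloc = a.altloc
        res.add_atom(at)
    st.add_model(model)
    st.setup_entities()
    for i, (r1, r2) in enumerate(s.links):
        con = gemmi.Connection()
        con.name = f"covale{i + 1}"
        con.type = gemmi.ConnectionType.Covale
        con.partner1 = gemmi.make_address(
            st[0][r1[0]], _find_res(st[0][r1[0]], r1[1]), _find_atom(st[0][r1[0]], r1[1], r1[2])
        )
        con.partner2 = gemmi.make_address(
            st[0][r2[0]], _find_res(st[0][r2[0]], r2[1]), _find_atom(st[0][r2[0]], r2[1], r2[2])
        )
        st.connections.append(con)
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


def _find_res(chain: gemmi.Chain, seq_id: int) -> gemmi.Residue:
    for res in chain:
        if res.seqid.num == seq_id:
            return res
    raise KeyError(f"residue {seq_id} not in chain {chain.name}")


def _find_atom(chain: gemmi.Chain, seq_id: int, name: str) -> gemmi.Atom:
    res = _find_res(chain, seq_id)
    for at in res:
        if at.name == name:
            return at
    raise KeyError(f"atom {name} not in residue {seq_id}")


def read_obsolete_list(path: str | Path) -> set[str]:
    """Read an obsolete comp-id list: one comp-id per line, '#' comments."""
    out: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.add(line.upper())
    return out


def select_ligand(
    s: Structure,
    dictionary: "RestraintDictionary",
    ccd_obsolete: Iterable[str] = (),
    exclude: frozenset[str] = STANDARD_RESIDUES,
) -> LigandSelection:
    """Pick the ligand of interest.

    Candidate residue types are the non-polymer comp-ids (minus waters
    and standard residues), ordered by descending dictionary non-H atom
    count, ties broken by comp-id; instances of a type are tried in
    (chain, seq_id) order.  Each instance must pass the four criteria;
    rejected candidates are logged with a reason code and the next one
    is considered.
    """
    obsolete = {c.upper() for c in ccd_obsolete}
    rejections: list[tuple[str, str]] = []

    candidates: dict[str, list[tuple[str, int, list[Atom]]]] = {}
    for (chain, seq, comp), atoms in s.residues().items():
        if comp in exclude or any(a.is_polymer for a in atoms):
            continue
        candidates.setdefault(comp, []).append((chain, seq, atoms))

    if not candidates:
        return LigandSelection(rejections=[("*", "no-ligand")])

    sized: list[tuple[int, str]] = []
    for comp in candidates:
        if comp not in dictionary:
            rejections.append((comp, "no-dictionary"))
            continue
        sized.append((dictionary[comp].n_heavy, comp))
    sized.sort(key=lambda t: (-t[0], t[1]))

    linked = s.linked_atom_refs()
    data_ok = bool(s.data_meta.get("data_available", True)) and not bool(
        s.data_meta.get("twinned", False)
    )
    for n_heavy, comp in sized:
        if comp in obsolete:
            rejections.append((comp, "obsolete"))
            continue
        for chain, seq, atoms in sorted(candidates[comp], key=lambda t: (t[0], t[1])):
            tag = f"{comp} {chain}{seq}"
            if any(a.key() in linked for a in atoms):
                rejections.append((tag, "link-record"))
                continue
            if any(a.altloc for a in atoms):
                rejections.append((tag, "alternate configurations"))
                continue
            if not data_ok:
                rejections.append((tag, "data unavailable or twinned"))
                continue
            return LigandSelection(
                comp_id=comp, chain=chain, seq_id=seq,
                atoms=sorted(atoms, key=lambda a: a.name),
                n_heavy=n_heavy, rejections=rejections,
            )
    if not rejections:
        rejections.append(("*", "no-ligand"))
    return LigandSelection(rejections=rejections)


def neighbourhood(s: Structure, lig: LigandSelection, radius: float) -> list[Atom]:
    """All non-ligand atoms within ``radius`` of any ligand atom,
    ordered by (chain, seq_id, atom name)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    lig_keys = lig.atom_keys()
    lig_pos = np.array([a.pos for a in lig.atoms])
    if lig_pos.size == 0:
        return []
    out: list[Atom] = []
    for a in s.atoms:
        if a.key() in lig_keys:
            continue
        d2 = np.min(np.sum((lig_pos - a.pos) ** 2, axis=1))
        if d2 <= radius * radius:
            out.append(a)
    out.sort(key=lambda a: (a.chain, a.seq_id, a.name))
    return out
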