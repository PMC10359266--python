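"""Structure model, mmCIF/PDB I/O, entity classification, and censuses.

The in-memory model is a thin, explicit hierarchy (Structure → Residue →
Atom) carrying author numbering, built from gemmi's parser. Entity
classification assigns every residue exactly one label (protein, water,
monatomic ion, phospholipid, sterol, retinal chromophore, or other het),
and censuses can be taken over the whole deposited assembly or per
protomer, with het groups attributed to the nearest protein chain.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from . import tables

logger = logging.getLogger(__name__)

ResidueKey = tuple[str, int, str]  # (chain_id, author seq number, insertion code)


class EntityClass:
    """Entity labels; every residue receives exactly one."""

    PROTEIN = "protein"
    WATER = "water"
    MONATOMIC_ION = "monatomic_ion"
    PHOSPHOLIPID = "phospholipid"
    STEROL = "sterol"
    RETINAL = "retinal"
    OTHER_HET = "other_het"

    ALL = (PROTEIN, WATER, MONATOMIC_ION, PHOSPHOLIPID, STEROL, RETINAL, OTHER_HET)


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # (3,) Å
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0,1] for {self.name}")
        if not self.element:
            raise ValueError(f"empty element symbol for atom {self.name}")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    comp_id: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.seq_num}{self.icode}:{self.comp_id}"

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def is_amino_acid(self) -> bool:
        return self.comp_id in tables.STANDARD_AA or self.comp_id in tables.PROTEIN_LIKE

    def one_letter(self) -> str | None:
        if self.comp_id in tables.STANDARD_AA:
            return tables.STANDARD_AA[self.comp_id]
        return tables.PROTEIN_LIKE.get(self.comp_id)


@dataclass
class Structure:
    id: str
    residues: list[Residue] = field(default_factory=list)
    # chain_id -> protomer index; covers every chain after parsing
    assembly: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[ResidueKey] = set()
        for r in self.residues:
            if r.key in seen:
                raise ValueError(f"duplicate residue key {r.key}")
            seen.add(r.key)

    # --- access helpers ---------------------------------------------------

    def chains(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if r.chain_id not in out:
                out.append(r.chain_id)
        return out

    def find(self, key: ResidueKey) -> Residue | None:
        for r in self.residues:
            if r.key == key:
                return r
        return None

    def protein_residues(self, chain: str | None = None) -> list[Residue]:
        return [
            r for r in self.residues
            if r.is_amino_acid() and (chain is None or r.chain_id == chain)
        ]

    def protein_chains(self) -> list[str]:
        out: list[str] = []
        for r in self.protein_residues():
            if r.chain_id not in out:
                out.append(r.chain_id)
        return out

    def sequence(self, chain: str | None = None) -> str:
        """One-letter sequence of a protein chain (default: first)."""
        if chain is None:
            chains = self.protein_chains()
            if not chains:
                raise ValueError("structure contains no protein residues")
            chain = chains[0]
        return "".join(r.one_letter() or "X" for r in self.protein_residues(chain))

    def n_protomers(self) -> int:
        return max(self.assembly.values(), default=-1) + 1

    def atom_coords(self) -> np.ndarray:
        return np.array(
            [a.coords for r in self.residues for a in r.atoms], dtype=float
        ).reshape(-1, 3)

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)


# --- parsing ----------------------------------------------------------------

_FORMATS = {
    "mmCIF": gemmi.CoorFormat.Mmcif,
    "PDB": gemmi.CoorFormat.Pdb,
    "auto": gemmi.CoorFormat.Detect,
}


def parse_structure(path: str | Path, dialect: str = "auto") -> Structure:
    """Read a coordinate file into a Structure.

    Atoms with zero occupancy are dropped. Within an altloc group (same
    atom name in one residue) only the highest-occupancy conformer is
    kept; ties go to the alphabetically first altloc. Author residue
    numbering is preserved.
    """
    path = Path(path)
    if dialect not in _FORMATS:
        raise ValueError(f"unknown dialect {dialect!r}; use mmCIF, PDB or auto")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[dialect])
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise ValueError(f"{path}: empty model")
    st.setup_entities()

    residues: list[Residue] = []
    model = st[0]
    for chain in model:
        for res in chain:
            picked: dict[str, gemmi.Atom] = {}
            for at in res:
                if at.occ <= 0.0:
                    continue
                prev = picked.get(at.name)
                # keep the higher occupancy; ties go to the alphabetically
                # first altloc (blank altloc sorts last)
                if prev is None or at.occ > prev.occ or (
                    at.occ == prev.occ and _alt_rank(at.altloc) < _alt_rank(prev.altloc)
                ):
                    picked[at.name] = at
            if not picked:
                continue
            atoms = [
                Atom(
                    serial=a.serial,
                    name=a.name,
                    element=a.element.name.upper(),
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=min(a.occ, 1.0),
                    altloc=a.altloc if a.altloc not in ("", "\0") else "",
                )
                for a in picked.values()
            ]
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_num=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    comp_id=res.name.strip(),
                    atoms=atoms,
                )
            )
    s = Structure(id=st.name or path.stem, residues=residues)
    s.assembly = _build_assembly(s)
    return s


def _alt_rank(altloc: str) -> str:
    return altloc if altloc not in ("", "\0") else "~"


def _build_assembly(s: Structure) -> dict[str, int]:
    """One protomer per protein chain; het-only chains join the nearest."""
    assembly: dict[str, int] = {}
    prot_chains = s.protein_chains()
    for i, ch in enumerate(prot_chains):
        assembly[ch] = i
    if not prot_chains:
        # het-only file (e.g. cavity dummy atoms): one pseudo-protomer
        return {ch: 0 for ch in s.chains()}
    prot_xyz = {
        ch: np.concatenate([r.coords() for r in s.protein_residues(ch)]) for ch in prot_chains
    }
    for ch in s.chains():
        if ch in assembly:
            continue
        xyz = np.concatenate([r.coords() for r in s.residues if r.chain_id == ch])
        best = min(
            prot_chains,
            key=lambda pc: float(np.min(np.linalg.norm(
                prot_xyz[pc][:, None, :] - xyz[None, :, :], axis=2))),
        )
        assembly[ch] = assembly[best]
    return assembly


# --- writing ----------------------------------------------------------------

def to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    for r in s.residues:
        ch = chain_map.get(r.chain_id)
        if ch is None:
            ch = gemmi.Chain(r.chain_id)
            chain_map[r.chain_id] = ch
        gr = gemmi.Residue()
        gr.name = r.comp_id
        gr.seqid = gemmi.SeqId(r.seq_num, r.icode or " ")
        if not r.is_amino_acid():
            gr.het_flag = "H"
        else:
            gr.het_flag = "A"
        for a in r.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element.capitalize())
            ga.pos = gemmi.Position(*a.coords)
            ga.occ = a.occupancy
            ga.serial = a.serial
            if a.altloc:
                ga.altloc = a.altloc
            gr.add_atom(ga)
        ch.add_residue(gr)
    for ch in chain_map.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(s: Structure, path: str | Path, dialect: str = "auto") -> None:
    """Write a Structure as PDB or mmCIF (by dialect or file suffix)."""
    path = Path(path)
    st = to_gemmi(s)
    if dialect == "auto":
        dialect = "mmCIF" if path.suffix.lower() in {".cif", ".mmcif"} else "PDB"
    if dialect == "PDB":
        st.write_pdb(str(path))
    elif dialect == "mmCIF":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# --- entity classification --------------------------------------------------

def classify_entities(
    s: Structure, overrides: dict[str, set[str]] | None = None
) -> dict[ResidueKey, str]:
    """Assign one EntityClass label to every residue.

    ``overrides`` maps an EntityClass label to extra component codes,
    e.g. ``{"phospholipid": {"XYZ"}}``. Unknown multi-atom het groups
    become ``other_het`` (with a logged warning); unknown single-atom
    het groups are monatomic ions.
    """
    tab = {
        EntityClass.WATER: set(tables.WATER_CODES),
        EntityClass.MONATOMIC_ION: set(tables.MONATOMIC_ION_CODES),
        EntityClass.PHOSPHOLIPID: set(tables.PHOSPHOLIPID_CODES),
        EntityClass.STEROL: set(tables.STEROL_CODES),
        EntityClass.RETINAL: set(tables.RETINAL_CODES) - {"LYR"},
    }
    if overrides:
        for label, codes in overrides.items():
            tab.setdefault(label, set()).update(codes)

    out: dict[ResidueKey, str] = {}
    for r in s.residues:
        if r.is_amino_acid():
            out[r.key] = EntityClass.PROTEIN
            continue
        for label in (
            EntityClass.WATER,
            EntityClass.MONATOMIC_ION,
            EntityClass.PHOSPHOLIPID,
            EntityClass.STEROL,
            EntityClass.RETINAL,
        ):
            if r.comp_id in tab.get(label, set()):
                out[r.key] = label
                break
        else:
            if len(r.atoms) == 1:
                out[r.key] = EntityClass.MONATOMIC_ION
            else:
                logger.warning("unknown het group %s classified as other_het", r.label)
                out[r.key] = EntityClass.OTHER_HET
    return out


def entity_census(
    s: Structure,
    scope: int | str | None = None,
    classification: dict[ResidueKey, str] | None = None,
) -> Counter:
    """Counts of residues per EntityClass.

    ``scope``: ``None``/"trimer"/"all" for the whole structure, or a
    protomer index. In protomer scope, het residues are attributed to
    the protomer whose protein atoms are nearest (minimum heteroatom
    distance).
    """
    cls = classification or classify_entities(s)
    if scope in (None, "trimer", "all"):
        return Counter(cls.values())
    k = int(scope)
    if k < 0 or k >= s.n_protomers():
        raise ValueError(f"invalid protomer index {k} (structure has {s.n_protomers()})")

    prot_xyz: dict[int, np.ndarray] = {}
    for ch, idx in s.assembly.items():
        res = s.protein_residues(ch)
        if res:
            xyz = np.concatenate([r.coords() for r in res])
            prot_xyz[idx] = (
                np.concatenate([prot_xyz[idx], xyz]) if idx in prot_xyz else xyz
            )

    counts: Counter = Counter()
    for r in s.residues:
        label = cls[r.key]
        if label == EntityClass.PROTEIN:
            if s.assembly[r.chain_id] == k:
                counts[label] += 1
            continue
        xyz = r.coords()
        nearest = min(
            prot_xyz,
            key=lambda i: float(
                np.min(np.linalg.norm(prot_xyz[i][:, None, :] - xyz[None, :, :], axis=2))
            ),
        )
        if nearest == k:
            counts[label] += 1
    return counts


def central_phospholipids(
    s: Structure, classification: dict[ResidueKey, str] | None = None
) -> list[ResidueKey]:
    """Phospholipids in the central inter-protomer pore of a trimer.

    A phospholipid counts as central when its centroid, projected on the
    membrane (xy) plane, falls inside the triangle spanned by the three
    protomer centroids. Requires exactly three protomers.
    """
    cls = classification or classify_entities(s)
    if s.n_protomers() != 3:
        raise ValueError("central-pore labeling is defined for trimers")
    cents = []
    for k in range(3):
        xyz = np.concatenate(
            [r.coords() for r in s.protein_residues() if s.assembly[r.chain_id] == k]
        )
        cents.append(xyz.mean(axis=0)[:2])
    tri = np.array(cents)

    def inside(p: np.ndarray) -> bool:
        a, b, c = tri
        s1 = np.cross(b - a, p - a)
        s2 = np.cross(c - b, p - b)
        s3 = np.cross(a - c, p - c)
        return bool((s1 >= 0 and s2 >= 0 and s3 >= 0) or (s1 <= 0 and s2 <= 0 and s3 <= 0))

    out = []
    for r in s.residues:
        if cls[r.key] == EntityClass.PHOSPHOLIPID and inside(r.coords().mean(axis=0)[:2]):
            out.append(r.key)
    return out


# --- reports ----------------------------------------------------------------

def census_report(s: Structure, per_protomer: bool = True) -> str:
    """Tab-separated census over the whole structure and each protomer."""
    cls = classify_entities(s)
    lines = ["scope\t" + "\t".join(EntityClass.ALL)]
    total = entity_census(s, None, cls)
    lines.append("all\t" + "\t".join(str(total[c]) for c in EntityClass.ALL))
    if per_protomer:
        for k in range(s.n_protomers()):
            c = entity_census(s, k, cls)
            lines.append(f"protomer_{k}\t" + "\t".join(str(c[l]) for l in EntityClass.ALL))
    return "\n".join(lines) + "\n"


def entity_map_json(s: Structure) -> str:
    cls = classify_entities(s)
    return json.dumps(
        {f"{k[0]}:{k[1]}{k[2]}": v for k, v in sorted(cls.items())},
        indent=1, sort_keys=True,
    )
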