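"""Protein–carbohydrate structure handling.

Parses PDB/mmCIF files (via gemmi), represents atoms and residues, and
extracts the two residue classes the stacking analysis needs: pyranose
sugar residues (with their C1–C6 carbon skeleton) and the planar rings of
aromatic side chains (Phe, Tyr, Trp, His).

Coordinates are in Å throughout; author chain IDs and 1-based residue
numbering are preserved verbatim.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "AtomSite",
    "StructureModel",
    "Residue",
    "AromaticRing",
    "SugarResidue",
    "IncompleteResidueWarning",
    "GeometryError",
    "RING_DEFINITIONS",
    "load_structure",
    "write_pdb",
    "select_sugar_residues",
    "select_aromatic_rings",
]


class IncompleteResidueWarning(UserWarning):
    """A residue was skipped because expected atoms are missing."""


class GeometryError(ValueError):
    """Raised for degenerate geometry (e.g. a zero-area ring plane)."""


#: Ring member atom names per aromatic residue type.  TRP contributes two
#: fused rings (5-membered pyrrole and 6-membered benzene); the shared
#: CD2/CE2 edge appears in both.
RING_DEFINITIONS: dict[str, tuple[tuple[str, tuple[str, ...]], ...]] = {
    "PHE": (("PHE-6", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")),),
    "TYR": (("TYR-6", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")),),
    "TRP": (
        ("TRP-5", ("CG", "CD1", "NE1", "CE2", "CD2")),
        ("TRP-6", ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")),
    ),
    "HIS": (("HIS-5", ("CG", "ND1", "CE1", "NE2", "CD2")),),
}

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass
class AtomSite:
    """One atom record: name, element, residue identity and position (Å)."""

    atom_name: str
    element: str
    residue_name: str
    residue_seq: int
    chain: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("position must be a finite 3-vector")
        if not self.element:
            raise ValueError("element must be non-empty")


@dataclass
class Residue:
    """A contiguous group of atoms sharing (chain, residue_seq, residue_name)."""

    chain: str
    seq: int
    name: str
    atoms: list[AtomSite]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seq, self.name)

    def atom(self, name: str) -> AtomSite | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None


@dataclass
class StructureModel:
    """An ordered atom collection plus optional refinement metadata."""

    atoms: list[AtomSite] = field(default_factory=list)
    resolution: float | None = None  # Å; None when absent, never 0
    r_factor: float | None = None
    id: str = ""

    def residues(self) -> list[Residue]:
        out: list[Residue] = []
        for a in self.atoms:
            if out and out[-1].key == (a.chain, a.residue_seq, a.residue_name):
                out[-1].atoms.append(a)
            else:
                out.append(Residue(a.chain, a.residue_seq, a.residue_name, [a]))
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a rigid-body transformed copy (x -> R x + t)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        atoms = [
            AtomSite(a.atom_name, a.element, a.residue_name, a.residue_seq,
                     a.chain, R @ a.position + t)
            for a in self.atoms
        ]
        return StructureModel(atoms, self.resolution, self.r_factor, self.id)


@dataclass
class AromaticRing:
    """One planar ring of an aromatic side chain.

    ``centroid`` is the mean of the member-atom positions; ``normal`` is the
    unit normal of the least-squares plane through them (sign fixed so the
    largest-magnitude component is positive).
    """

    residue_name: str
    chain: str
    residue_seq: int
    ring_id: str
    member_atoms: list[AtomSite]
    centroid: np.ndarray
    normal: np.ndarray

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_seq, self.residue_name)

    @property
    def label(self) -> str:
        return f"{self.chain}/{self.residue_name}{self.residue_seq}/{self.ring_id}"

    @classmethod
    def from_atoms(cls, residue: Residue, ring_id: str,
                   member_atoms: list[AtomSite]) -> "AromaticRing":
        coords = np.array([a.position for a in member_atoms])
        if len(coords) not in (5, 6):
            raise GeometryError("aromatic ring must have 5 or 6 member atoms")
        centroid = coords.mean(axis=0)
        centered = coords - centroid
        # Least-squares plane via SVD; robust to slightly puckered rings.
        _, s, vt = np.linalg.svd(centered)
        if s[1] < 1e-9:
            raise GeometryError(
                f"degenerate (zero-area) ring plane for {residue.key}/{ring_id}")
        normal = vt[2]
        k = int(np.argmax(np.abs(normal)))
        if normal[k] < 0:
            normal = -normal
        normal = normal / np.linalg.norm(normal)
        return cls(residue.name, residue.chain, residue.seq, ring_id,
                   member_atoms, centroid, normal)


@dataclass
class SugarResidue:
    """A pyranose residue with its six carbons mapped by number (C1–C6)."""

    chain: str
    seq: int
    name: str
    carbon_positions: dict[int, np.ndarray]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seq, self.name)

    @property
    def label(self) -> str:
        return f"{self.chain}/{self.name}{self.seq}"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    raise ValueError(f"cannot infer structure format from suffix {suffix!r}")


_PDB_RWORK_RE = re.compile(r"REMARK   3   R VALUE\s*(?:\(WORKING SET\))?\s*:\s*([0-9.]+)")


def _read_r_factor_pdb(path: Path) -> float | None:
    with open(path) as fh:
        for line in fh:
            if line.startswith("ATOM") or line.startswith("HETATM"):
                break
            m = _PDB_RWORK_RE.match(line)
            if m:
                return float(m.group(1))
    return None


def _read_refine_mmcif(path: Path) -> tuple[float | None, float | None]:
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    res = block.find_value("_refine.ls_d_res_high")
    rw = (block.find_value("_refine.ls_R_factor_R_work")
          or block.find_value("_refine.ls_R_factor_obs"))

    def _num(v):
        if v is None or v in ("?", "."):
            return None
        return float(v)

    return _num(res), _num(rw)


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # Highest occupancy wins; ties broken by file order.
    best = atoms[0]
    for a in atoms[1:]:
        if a.occ > best.occ:
            best = a
    return best


def load_structure(path: str | Path, format: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    All ATOM/HETATM records are kept.  Alternate locations are collapsed to
    the highest-occupancy conformer (ties -> first).  Resolution and R-factor
    are captured from the header when present, else left as ``None``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format if format is not None else _infer_format(path)
    if fmt == "pdb":
        coor = gemmi.CoorFormat.Pdb
    elif fmt == "mmcif":
        coor = gemmi.CoorFormat.Mmcif
    else:
        raise ValueError(f"unknown format token {fmt!r} (expected 'pdb' or 'mmcif')")

    st = gemmi.read_structure(str(path), format=coor)
    resolution: float | None = st.resolution if st.resolution > 0 else None
    r_factor: float | None = None
    if fmt == "pdb":
        r_factor = _read_r_factor_pdb(path)
    else:
        cif_res, cif_rw = _read_refine_mmcif(path)
        resolution = resolution or cif_res
        r_factor = cif_rw

    model = StructureModel(resolution=resolution, r_factor=r_factor,
                           id=path.stem.upper())
    if len(st) == 0:
        return model
    first = st[0]  # first model only
    for chain in first:
        for res in chain:
            by_name: dict[str, list[gemmi.Atom]] = {}
            order: list[str] = []
            for atom in res:
                if atom.name not in by_name:
                    by_name[atom.name] = []
                    order.append(atom.name)
                by_name[atom.name].append(atom)
            for name in order:
                atom = _pick_altloc(by_name[name])
                element = atom.element.name if atom.element.name else atom.name[0]
                model.atoms.append(AtomSite(
                    atom_name=name,
                    element=element,
                    residue_name=res.name,
                    residue_seq=res.seqid.num,
                    chain=chain.name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                ))
    return model


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a model as a fixed-column PDB file (fixture writer).

    Resolution and R-factor, when set, are emitted as REMARK 2/3 records so
    that :func:`load_structure` round-trips them.
    """
    st = gemmi.Structure()
    st.name = model.id or "SYNTH"
    gm = gemmi.Model("1")
    # gemmi's add_residue/add_chain copy their argument, so residues and
    # chains must be fully populated before insertion.
    chains: dict[str, list] = {}
    for residue in model.residues():
        res = gemmi.Residue()
        res.name = residue.name
        res.seqid = gemmi.SeqId(residue.seq, " ")
        res.het_flag = "A" if residue.name in _STANDARD_AA else "H"
        for a in residue.atoms:
            at = gemmi.Atom()
            at.name = a.atom_name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.position)
            at.occ = 1.0
            at.b_iso = 20.0
            res.add_atom(at)
        chains.setdefault(residue.chain, []).append(res)
    for chain_name, residues in chains.items():
        ch = gemmi.Chain(chain_name)
        for res in residues:
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    body = st.make_pdb_string()
    header_lines = []
    if model.resolution is not None:
        header_lines.append(f"REMARK   2 RESOLUTION.    {model.resolution:.2f} ANGSTROMS.")
    if model.r_factor is not None:
        header_lines.append(
            f"REMARK   3   R VALUE            (WORKING SET) : {model.r_factor:.3f}")
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        fh.write(body)


# ---------------------------------------------------------------------------
# Residue selection
# ---------------------------------------------------------------------------

def select_sugar_residues(model: StructureModel,
                          codes: frozenset[str] | set[str] = frozenset({"GAL"}),
                          ) -> list[SugarResidue]:
    """Extract pyranose residues matching the given component codes.

    Each matching residue must carry all six carbons C1–C6; residues with a
    missing carbon are skipped with an :class:`IncompleteResidueWarning`.
    """
    if not codes:
        raise ValueError("codes must be non-empty")
    sugars: list[SugarResidue] = []
    for res in model.residues():
        if res.name not in codes:
            continue
        carbons: dict[int, np.ndarray] = {}
        missing: list[str] = []
        for n in range(1, 7):
            atom = res.atom(f"C{n}")
            if atom is None:
                missing.append(f"C{n}")
            else:
                carbons[n] = atom.position
        if missing:
            warnings.warn(
                f"sugar residue {res.key} missing atoms {missing}; skipped",
                IncompleteResidueWarning, stacklevel=2)
            continue
        sugars.append(SugarResidue(res.chain, res.seq, res.name, carbons))
    return sugars


def select_aromatic_rings(model: StructureModel,
                          include_his: bool = True) -> list[AromaticRing]:
    """Extract aromatic rings from PHE/TYR/TRP (and HIS when enabled).

    PHE and TYR yield one six-membered ring each; TRP yields two rings
    (pyrrole and benzene); HIS yields one five-membered ring.  Rings with
    missing member atoms are skipped with a warning.
    """
    rings: list[AromaticRing] = []
    for res in model.residues():
        defs = RING_DEFINITIONS.get(res.name)
        if defs is None:
            continue
        if res.name == "HIS" and not include_his:
            continue
        for ring_id, member_names in defs:
            members = [res.atom(name) for name in member_names]
            if any(a is None for a in members):
                missing = [n for n, a in zip(member_names, members) if a is None]
                warnings.warn(
                    f"ring {ring_id} of {res.key} missing atoms {missing}; skipped",
                    IncompleteResidueWarning, stacklevel=2)
                continue
            rings.append(AromaticRing.from_atoms(res, ring_id, members))  # type: ignore[arg-type]
    return rings
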