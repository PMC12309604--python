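"""CH−π contact geometry, stacking classification and orientation CVs.

Two per-carbon features describe the relation of a sugar carbon Cn to an
aromatic ring:

* ``d``: the distance from Cn to the ring centroid (Ctr), in Å.
* ``theta``: the off-axis angle at vertex Cn between the direction to its
  orthogonal projection onto the ring plane and the direction to Ctr, in
  degrees.  It is 0° for a carbon directly above the centroid and 90° for a
  carbon in the ring plane (limiting convention).

A carbon forms a CH−π interaction when ``d < d_max`` (default 4.6 Å) and
``theta < theta_max`` (default 50°), both strict inequalities.  A CH−π
*stacking* interaction is three or more such contacts between one sugar
residue and one aromatic side chain (both Trp rings pool together).

The two orientation collective variables are sums of centroid distances:
CV1 = d(C1) + d(C2) and CV2 = d(C4) + d(C6).  Low CV2 corresponds to
stacking through the 3,4,5,6 face of galactose; low CV1 to the 1,3,5 face.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure_model import (
    AromaticRing,
    GeometryError,
    StructureModel,
    SugarResidue,
    select_aromatic_rings,
    select_sugar_residues,
)

__all__ = [
    "GeometryCriteria",
    "CHPiContact",
    "StackingInteraction",
    "ScanReport",
    "chpi_features",
    "detect_contacts",
    "classify_stacking",
    "compute_cvs",
    "scan_structure",
]

_IN_PLANE_TOL = 1e-9  # Å; below this the carbon counts as lying in the plane


@dataclass(frozen=True)
class GeometryCriteria:
    """Cutoffs defining a CH−π contact and a stacking interaction."""

    d_max: float = 4.6        # Å
    theta_max: float = 50.0   # degrees
    min_contacts: int = 3

    def __post_init__(self) -> None:
        if not self.d_max > 0:
            raise ValueError("d_max must be positive")
        if not (0 < self.theta_max <= 90):
            raise ValueError("theta_max must be in (0, 90]")
        if self.min_contacts < 1:
            raise ValueError("min_contacts must be >= 1")


@dataclass
class CHPiContact:
    """One carbon's geometric relation to its nearest aromatic ring."""

    carbon: int                # n in 1..6
    ring: AromaticRing
    d: float                   # Å, carbon-to-centroid
    theta: float               # degrees, off-axis angle
    is_contact: bool
    sugar: SugarResidue | None = None
    carbon_position: np.ndarray | None = None


@dataclass
class StackingInteraction:
    """Aggregated CH−π contacts between one sugar and one aromatic residue."""

    sugar: SugarResidue
    residue_key: tuple[str, int, str]   # aromatic (chain, seq, name)
    anchor_ring: AromaticRing
    contacts: list[CHPiContact]
    face_label: str                     # sorted passing carbons, e.g. "3456"
    cv1: float                          # Å, d(C1)+d(C2) to the anchor ring
    cv2: float                          # Å, d(C4)+d(C6) to the anchor ring

    @property
    def n_contacts(self) -> int:
        return sum(1 for c in self.contacts if c.is_contact)


def chpi_features(carbon: np.ndarray, ring: AromaticRing) -> tuple[float, float]:
    """Return (d, theta) for one carbon against one ring.

    ``theta`` is the three-point angle at vertex Cn between (Proj − Cn) and
    (Ctr − Cn), where Proj is the orthogonal projection of Cn onto the ring
    plane.  Computed with atan2 for conditioning near 0° and 90°.
    """
    carbon = np.asarray(carbon, dtype=float)
    rel = carbon - ring.centroid
    d = float(np.linalg.norm(rel))
    if d < _IN_PLANE_TOL:
        raise GeometryError("carbon coincides with the ring centroid")
    height = float(rel @ ring.normal)
    proj = carbon - height * ring.normal
    u = proj - carbon               # = -height * normal
    v = ring.centroid - carbon
    if np.linalg.norm(u) < _IN_PLANE_TOL:
        return d, 90.0              # carbon lies in the plane
    cross = np.linalg.norm(np.cross(u, v))
    dot = float(u @ v)
    theta = float(np.degrees(np.arctan2(cross, dot)))
    return d, theta


def detect_contacts(sugar: SugarResidue,
                    rings: list[AromaticRing],
                    criteria: GeometryCriteria | None = None) -> list[CHPiContact]:
    """Evaluate every carbon of a sugar against its nearest aromatic ring.

    Nearest means minimum centroid distance over all rings, assigned per
    carbon.  Returns one :class:`CHPiContact` per carbon (six in total).
    """
    if not rings:
        raise ValueError("rings must be non-empty")
    criteria = criteria or GeometryCriteria()
    contacts: list[CHPiContact] = []
    for n in sorted(sugar.carbon_positions):
        pos = sugar.carbon_positions[n]
        dists = [float(np.linalg.norm(pos - r.centroid)) for r in rings]
        best = int(np.argmin(dists))
        ring = rings[best]
        d, theta = chpi_features(pos, ring)
        is_contact = (d < criteria.d_max) and (theta < criteria.theta_max)
        contacts.append(CHPiContact(n, ring, d, theta, is_contact,
                                    sugar=sugar, carbon_position=pos))
    return contacts


def compute_cvs(sugar: SugarResidue, ring: AromaticRing) -> tuple[float, float]:
    """Orientation CVs against a single ring centroid.

    CV1 = d(C1)+d(C2); CV2 = d(C4)+d(C6), in Å.
    """
    d = {n: float(np.linalg.norm(sugar.carbon_positions[n] - ring.centroid))
         for n in (1, 2, 4, 6)}
    return d[1] + d[2], d[4] + d[6]


def classify_stacking(contacts: list[CHPiContact],
                      criteria: GeometryCriteria | None = None,
                      ) -> list[StackingInteraction]:
    """Group contacts per aromatic residue and keep groups with enough hits.

    Contacts must all reference the same sugar.  Both Trp rings pool into
    one group for the >= ``min_contacts`` threshold.  The anchor ring used
    for the CVs is the candidate ring with the smallest mean centroid
    distance over the passing carbons (ties -> first encountered).
    """
    criteria = criteria or GeometryCriteria()
    if not contacts:
        return []
    sugars = {id(c.sugar) for c in contacts}
    if len(sugars) != 1 or contacts[0].sugar is None:
        raise ValueError("contacts must all reference the same sugar")
    sugar = contacts[0].sugar

    groups: dict[tuple[str, int, str], list[CHPiContact]] = {}
    for c in contacts:
        groups.setdefault(c.ring.residue_key, []).append(c)

    interactions: list[StackingInteraction] = []
    for residue_key, group in groups.items():
        passing = [c for c in group if c.is_contact]
        if len(passing) < criteria.min_contacts:
            continue
        face_label = "".join(str(n) for n in sorted(c.carbon for c in passing))
        # Candidate anchors: the distinct rings the passing contacts reference.
        candidates: list[AromaticRing] = []
        for c in passing:
            if all(c.ring is not r for r in candidates):
                candidates.append(c.ring)
        mean_d = [
            float(np.mean([np.linalg.norm(c.carbon_position - ring.centroid)
                           for c in passing]))
            for ring in candidates
        ]
        anchor = candidates[int(np.argmin(mean_d))]
        cv1, cv2 = compute_cvs(sugar, anchor)
        interactions.append(StackingInteraction(
            sugar=sugar, residue_key=residue_key, anchor_ring=anchor,
            contacts=group, face_label=face_label, cv1=cv1, cv2=cv2))
    return interactions


#: Fixed column order of the per-stacking TSV report.
REPORT_COLUMNS = (
    ["pdb_id", "chain", "sugar_seq", "aa_name", "aa_seq", "ring_id",
     "n_contacts", "face_label", "cv1", "cv2"]
    + [f"d{n}" for n in range(1, 7)]
    + [f"theta{n}" for n in range(1, 7)]
)


@dataclass
class ScanReport:
    """Per-structure scan result: contacts, stackings and monomer counts."""

    model_id: str
    sugars: list[SugarResidue]
    contacts_by_sugar: dict[tuple[str, int, str], list[CHPiContact]]
    stackings: list[StackingInteraction]
    criteria: GeometryCriteria = field(default_factory=GeometryCriteria)

    @property
    def n_stacked_monomers(self) -> int:
        """Number of distinct sugar residues engaged in >= 1 stacking."""
        return len({s.sugar.key for s in self.stackings})

    @property
    def stacking_class(self) -> str:
        """'none', 'single' or 'multiple' per the stacked-monomer count."""
        n = self.n_stacked_monomers
        return "none" if n == 0 else ("single" if n == 1 else "multiple")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.stackings:
            per_carbon = {c.carbon: c for c in s.contacts}
            row = {
                "pdb_id": self.model_id,
                "chain": s.sugar.chain,
                "sugar_seq": s.sugar.seq,
                "aa_name": s.residue_key[2],
                "aa_seq": s.residue_key[1],
                "ring_id": s.anchor_ring.ring_id,
                "n_contacts": s.n_contacts,
                "face_label": s.face_label,
                "cv1": s.cv1,
                "cv2": s.cv2,
            }
            for n in range(1, 7):
                c = per_carbon.get(n)
                row[f"d{n}"] = c.d if c else np.nan
                row[f"theta{n}"] = c.theta if c else np.nan
            rows.append(row)
        return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def scan_structure(model: StructureModel,
                   criteria: GeometryCriteria | None = None,
                   include_his: bool = True,
                   sugar_codes: frozenset[str] | set[str] = frozenset({"GAL"}),
                   ) -> ScanReport:
    """Run the full contact/stacking pipeline on one structure.

    Warnings from residue selection propagate; a bad residue never aborts
    the scan.  A structure with no aromatic rings yields an empty report.
    """
    criteria = criteria or GeometryCriteria()
    sugars = select_sugar_residues(model, sugar_codes)
    rings = select_aromatic_rings(model, include_his=include_his)
    contacts_by_sugar: dict[tuple[str, int, str], list[CHPiContact]] = {}
    stackings: list[StackingInteraction] = []
    if rings:
        for sugar in sugars:
            contacts = detect_contacts(sugar, rings, criteria)
            contacts_by_sugar[sugar.key] = contacts
            stackings.extend(classify_stacking(contacts, criteria))
    return ScanReport(model.id, sugars, contacts_by_sugar, stackings, criteria)
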