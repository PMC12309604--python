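"""Synthetic fixtures with known ground truth.

Three generator families feed the rest of the package:

* idealized β-D-galactopyranose/aromatic-ring poses with per-carbon contact
  ground truth computed by a frame-rotation oracle that is deliberately
  independent of :mod:`sugarstack.chpi_geometry` (Newell polygon normal +
  cylindrical coordinates, rather than SVD plane + vector angles);
* HILLS files whose reconstructed free-energy surface is known by
  construction;
* mock dataset metadata tables whose class counts are realized exactly
  (rounded, not sampled), so statistical outputs are exact.

All generators are seed-deterministic and regenerate byte-identically.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .fes_analysis import FESGrid, HillsTable, write_hills
from .structure_model import AtomSite, StructureModel, write_pdb
from .toy_metad import KB_KCAL

__all__ = [
    "PoseSpec",
    "PoseContact",
    "MockDatasetSpec",
    "build_galactose_template",
    "build_ring_template",
    "make_pose",
    "make_pose_with_cvs",
    "make_multi_stack_model",
    "oracle_pose_contacts",
    "random_pose_specs",
    "synth_hills",
    "mock_dataset",
    "regenerate_fixtures",
]

RING_TYPES = ("PHE6", "TYR6", "TRP5", "TRP6", "HIS5")
FACES = ("axial-135", "axial-3456")

_CC_BOND = 1.52   # Å, idealized C–C bond length
_CHAIR_Z = 0.25   # Å, chair pucker amplitude


@dataclass(frozen=True)
class PoseSpec:
    """Placement of an idealized galactose over an aromatic ring.

    ``offset`` is the height of the stacking-face centroid above the ring
    plane (Å, along the ring normal), ``lateral`` an in-plane displacement,
    ``tilt``/``azimuth`` rotations in degrees, and ``face`` selects which
    carbon set points at the ring.
    """

    ring_type: str = "TRP6"
    offset: float = 3.6
    lateral: float = 0.0
    tilt: float = 0.0
    azimuth: float = 0.0
    face: str = "axial-3456"

    def __post_init__(self) -> None:
        if self.ring_type not in RING_TYPES:
            raise ValueError(f"ring_type must be one of {RING_TYPES}")
        if self.face not in FACES:
            raise ValueError(f"face must be one of {FACES}")
        if not self.offset > 0:
            raise ValueError("offset must be positive")


@dataclass(frozen=True)
class PoseContact:
    """Oracle ground truth for one carbon of a generated pose."""

    carbon: int
    ring_id: str
    d: float
    theta: float
    is_contact: bool


# ---------------------------------------------------------------------------
# Idealized residue templates
# ---------------------------------------------------------------------------

def build_galactose_template() -> dict[str, np.ndarray]:
    """Idealized ⁴C₁-chair galactopyranose skeleton (C1–C6 + ring O5).

    Ring atoms sit on a chair of uniform 1.52 Å sides; the exocyclic C6
    extends equatorially from C5.  Deterministic: identical across calls.
    """
    radius = np.sqrt(_CC_BOND ** 2 - (2 * _CHAIR_Z) ** 2)
    order = ["C1", "C2", "C3", "C4", "C5", "O5"]
    coords: dict[str, np.ndarray] = {}
    for i, name in enumerate(order):
        angle = np.deg2rad(60.0 * i)
        z = _CHAIR_Z if i % 2 == 0 else -_CHAIR_Z
        coords[name] = np.array([radius * np.cos(angle),
                                 radius * np.sin(angle), z])
    # Equatorial C6 off C5: outward direction away from both ring neighbours,
    # with the axial (z) component damped to keep the substituent equatorial.
    v = 2 * coords["C5"] - coords["C4"] - coords["O5"]
    v[2] *= 0.25
    coords["C6"] = coords["C5"] + _CC_BOND * v / np.linalg.norm(v)
    return coords


def _regular_ring(names: list[str], bond: float) -> dict[str, np.ndarray]:
    n = len(names)
    radius = bond / (2 * np.sin(np.pi / n))
    return {
        name: np.array([radius * np.cos(2 * np.pi * i / n),
                        radius * np.sin(2 * np.pi * i / n), 0.0])
        for i, name in enumerate(names)
    }


def _indole_coords() -> dict[str, np.ndarray]:
    """Planar idealized indole with a shared CD2–CE2 edge of 1.40 Å."""
    edge = 1.40
    coords: dict[str, np.ndarray] = {}
    # Six-ring (benzene) to the +x side of the shared edge.
    r6 = edge
    c6 = np.array([edge * np.cos(np.pi / 6), 0.0, 0.0])
    hex_names = ["CE2", "CZ2", "CH2", "CZ3", "CE3", "CD2"]
    for i, name in enumerate(hex_names):
        ang = np.deg2rad(150.0 - 60.0 * i)
        coords[name] = c6 + r6 * np.array([np.cos(ang), np.sin(ang), 0.0])
    # Five-ring (pyrrole) to the -x side.
    r5 = edge / (2 * np.sin(np.pi / 5))
    c5 = np.array([-r5 * np.cos(np.pi / 5), 0.0, 0.0])
    pent = {"CE2": 36.0, "NE1": 108.0, "CD1": 180.0, "CG": 252.0, "CD2": 324.0}
    for name, ang_deg in pent.items():
        ang = np.deg2rad(ang_deg)
        pos = c5 + r5 * np.array([np.cos(ang), np.sin(ang), 0.0])
        if name in ("CE2", "CD2"):
            # shared edge: keep the benzene coordinates
            continue
        coords[name] = pos
    return coords


#: ring_type -> (residue name, member atom names of the anchor ring)
RING_MEMBERS = {
    "PHE6": ("PHE", ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]),
    "TYR6": ("TYR", ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]),
    "TRP5": ("TRP", ["CG", "CD1", "NE1", "CE2", "CD2"]),
    "TRP6": ("TRP", ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]),
    "HIS5": ("HIS", ["CG", "ND1", "CE1", "NE2", "CD2"]),
}


def build_ring_template(ring_type: str) -> tuple[str, dict[str, np.ndarray]]:
    """Planar (z = 0) side-chain ring coordinates, anchor ring centered at 0.

    For TRP the full indole is returned (both rings); the requested ring's
    centroid is moved to the origin.
    """
    if ring_type not in RING_TYPES:
        raise ValueError(f"ring_type must be one of {RING_TYPES}")
    res_name, members = RING_MEMBERS[ring_type]
    if res_name == "TRP":
        coords = _indole_coords()
    elif res_name in ("PHE", "TYR"):
        coords = _regular_ring(["CG", "CD1", "CE1", "CZ", "CE2", "CD2"], 1.39)
    else:  # HIS
        coords = _regular_ring(["CG", "ND1", "CE1", "NE2", "CD2"], 1.37)
    centroid = np.mean([coords[m] for m in members], axis=0)
    return res_name, {k: v - centroid for k, v in coords.items()}


# ---------------------------------------------------------------------------
# Frame-rotation ground-truth oracle (independent of chpi_geometry)
# ---------------------------------------------------------------------------

def _newell_normal(coords: np.ndarray) -> np.ndarray:
    """Polygon normal by Newell's method (sum of edge cross products)."""
    n = np.zeros(3)
    for i in range(len(coords)):
        p, q = coords[i], coords[(i + 1) % len(coords)]
        n[0] += (p[1] - q[1]) * (p[2] + q[2])
        n[1] += (p[2] - q[2]) * (p[0] + q[0])
        n[2] += (p[0] - q[0]) * (p[1] + q[1])
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("degenerate polygon")
    return n / norm


def _oracle_features(carbon: np.ndarray, ring_coords: np.ndarray) -> tuple[float, float]:
    """(d, theta) in a frame rotated so the ring normal is +z.

    In that frame the carbon sits at cylindrical (ρ, z) relative to the
    centroid: d = hypot(ρ, z) and theta = atan2(ρ, |z|).
    """
    centroid = ring_coords.mean(axis=0)
    normal = _newell_normal(ring_coords)
    # Build an orthonormal frame (e1, e2, normal) and express the carbon in it.
    seed = np.array([1.0, 0.0, 0.0])
    if abs(normal @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - (seed @ normal) * normal
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    rel = carbon - centroid
    x, y, z = rel @ e1, rel @ e2, rel @ normal
    rho = np.hypot(x, y)
    d = float(np.hypot(rho, z))
    theta = float(np.degrees(np.arctan2(rho, abs(z))))
    return d, theta


def oracle_pose_contacts(carbons: dict[int, np.ndarray],
                         rings: dict[str, np.ndarray],
                         d_max: float = 4.6,
                         theta_max: float = 50.0) -> list[PoseContact]:
    """Per-carbon ground truth against the nearest ring (by centroid distance)."""
    out = []
    centroids = {rid: rc.mean(axis=0) for rid, rc in rings.items()}
    for n in sorted(carbons):
        pos = carbons[n]
        nearest = min(rings, key=lambda rid: float(np.linalg.norm(pos - centroids[rid])))
        d, theta = _oracle_features(pos, rings[nearest])
        out.append(PoseContact(n, nearest, d, theta,
                               bool(d < d_max and theta < theta_max)))
    return out


# ---------------------------------------------------------------------------
# Pose construction
# ---------------------------------------------------------------------------

_FACE_CARBONS = {"axial-135": (1, 3, 5), "axial-3456": (3, 4, 5, 6)}


def _face_frame(coords: dict[str, np.ndarray], face: str) -> tuple[np.ndarray, np.ndarray]:
    """Face centroid and outward face normal (pointing away from the rest)."""
    face_pts = np.array([coords[f"C{n}"] for n in _FACE_CARBONS[face]])
    centroid = face_pts.mean(axis=0)
    centered = face_pts - centroid
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]
    rest = np.mean([coords[f"C{n}"] for n in range(1, 7)
                    if n not in _FACE_CARBONS[face]], axis=0)
    if (rest - centroid) @ normal < 0:
        normal = -normal
    return centroid, normal  # normal points from the face into the sugar body


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a to unit vector b."""
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180° flip about any axis orthogonal to a
        axis = np.array([1.0, 0.0, 0.0])
        if abs(a @ axis) > 0.9:
            axis = np.array([0.0, 1.0, 0.0])
        axis = axis - (axis @ a) * a
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    return Rotation.from_rotvec(
        v / np.linalg.norm(v) * np.arccos(np.clip(c, -1, 1))).as_matrix()


def _place_sugar(spec: PoseSpec) -> dict[str, np.ndarray]:
    """Sugar atom coordinates for a pose over a ring centered at the origin."""
    coords = build_galactose_template()
    centroid, outward = _face_frame(coords, spec.face)
    R_face = _rotation_between(outward, np.array([0.0, 0.0, 1.0]))
    R_tilt = Rotation.from_euler("x", spec.tilt, degrees=True).as_matrix()
    R_az = Rotation.from_euler("z", spec.azimuth, degrees=True).as_matrix()
    R = R_az @ R_tilt @ R_face
    t = np.array([spec.lateral, 0.0, spec.offset])
    return {name: R @ (pos - centroid) + t for name, pos in coords.items()}


def _pose_atoms(res_name: str,
                ring_coords: dict[str, np.ndarray],
                sugar_coords: dict[str, np.ndarray],
                chain: str = "A",
                aa_seq: int = 1,
                sugar_seq: int = 2) -> list[AtomSite]:
    atoms = []
    for name, pos in ring_coords.items():
        atoms.append(AtomSite(name, name[0], res_name, aa_seq, chain, pos))
    for name in ["C1", "C2", "C3", "C4", "C5", "C6", "O5"]:
        atoms.append(AtomSite(name, name[0], "GAL", sugar_seq, chain,
                              sugar_coords[name]))
    return atoms


def _ring_systems(res_name: str,
                  ring_coords: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """All ring-member coordinate arrays a residue contributes."""
    systems = {}
    for rid, (rname, members) in RING_MEMBERS.items():
        if rname == res_name:
            systems[rid] = np.array([ring_coords[m] for m in members])
    return systems


def make_pose(spec: PoseSpec,
              d_max: float = 4.6,
              theta_max: float = 50.0) -> tuple[StructureModel, list[PoseContact]]:
    """Build a sugar-over-ring model plus oracle ground-truth contacts.

    The pose places the requested stacking face of an idealized galactose
    ``spec.offset`` Å above the ring plane.  Ground truth per carbon
    (d, theta, is_contact) is computed by the embedded frame-rotation
    oracle, not by :mod:`sugarstack.chpi_geometry`.
    """
    if spec.offset < 1.0:
        raise ValueError("offset < 1 Å would place the sugar inside the ring")
    res_name, ring_coords = build_ring_template(spec.ring_type)
    sugar_coords = _place_sugar(spec)
    model = StructureModel(_pose_atoms(res_name, ring_coords, sugar_coords),
                           id=f"POSE-{spec.ring_type}-{spec.face}")
    carbons = {n: sugar_coords[f"C{n}"] for n in range(1, 7)}
    truth = oracle_pose_contacts(carbons, _ring_systems(res_name, ring_coords),
                                 d_max=d_max, theta_max=theta_max)
    return model, truth


def random_pose_specs(n: int, seed: int = 0) -> list[PoseSpec]:
    """Seed-deterministic random pose specs spanning contact/no-contact space."""
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        specs.append(PoseSpec(
            ring_type=RING_TYPES[rng.integers(len(RING_TYPES))],
            offset=float(rng.uniform(2.2, 6.5)),
            lateral=float(rng.uniform(0.0, 3.0)),
            tilt=float(rng.uniform(-35.0, 35.0)),
            azimuth=float(rng.uniform(0.0, 360.0)),
            face=FACES[rng.integers(len(FACES))],
        ))
    return specs


def make_pose_with_cvs(cv1: float,
                       cv2: float,
                       ring_type: str = "TRP6",
                       min_height: float = 2.5) -> StructureModel:
    """Pose whose orientation CVs match the requested (CV1, CV2).

    A rigid placement of the galactose template over the ring (centered at
    the origin, plane z = 0) is optimized so that d(C1)+d(C2) = cv1 and
    d(C4)+d(C6) = cv2, with the sugar kept at least ``min_height`` Å above
    the plane.  Deterministic (fixed starting point).
    """
    res_name, ring_coords = build_ring_template(ring_type)
    template = build_galactose_template()
    names = sorted(template)
    base = np.array([template[k] for k in names])
    base -= base.mean(axis=0)
    idx = {k: i for i, k in enumerate(names)}

    def placed(p):
        R = Rotation.from_rotvec(p[3:]).as_matrix()
        return base @ R.T + p[:3]

    def objective(p):
        pts = placed(p)
        d = {n: np.linalg.norm(pts[idx[f"C{n}"]]) for n in (1, 2, 4, 6)}
        err = (d[1] + d[2] - cv1) ** 2 + (d[4] + d[6] - cv2) ** 2
        zmin = pts[:, 2].min()
        penalty = 100.0 * max(0.0, min_height - zmin) ** 2
        return err + penalty

    x0 = np.array([0.5, 0.0, 4.2, 0.0, 0.0, 0.0])
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"maxiter": 8000, "xatol": 1e-10, "fatol": 1e-14})
    pts = placed(res.x)
    d = {n: np.linalg.norm(pts[idx[f"C{n}"]]) for n in (1, 2, 4, 6)}
    achieved = (d[1] + d[2], d[4] + d[6])
    if abs(achieved[0] - cv1) > 1e-3 or abs(achieved[1] - cv2) > 1e-3:
        raise ValueError(
            f"could not realize CVs ({cv1}, {cv2}); best effort {achieved}")
    sugar_coords = {k: pts[idx[k]] for k in names}
    return StructureModel(_pose_atoms(res_name, ring_coords, sugar_coords),
                          id="POSE-CV")


def make_multi_stack_model(n_sites: int = 3,
                           spacing: float = 9.0,
                           spec: PoseSpec | None = None) -> StructureModel:
    """Trisaccharide-like fixture: one stacked galactose per Trp, in a row.

    Emulates a carbohydrate-binding module with ``n_sites`` contiguous
    tryptophans, each carrying a stacked sugar (rigid multi-residue
    placement; no glycosidic linkage geometry).
    """
    spec = spec or PoseSpec(ring_type="TRP6", face="axial-3456", offset=3.6)
    atoms: list[AtomSite] = []
    res_name, ring_coords = build_ring_template(spec.ring_type)
    sugar_coords = _place_sugar(spec)
    for site in range(n_sites):
        shift = np.array([site * spacing, 0.0, 0.0])
        for a in _pose_atoms(res_name,
                             {k: v + shift for k, v in ring_coords.items()},
                             {k: v + shift for k, v in sugar_coords.items()},
                             aa_seq=10 + site, sugar_seq=50 + site):
            atoms.append(a)
    return StructureModel(atoms, id="MULTISTACK")


# ---------------------------------------------------------------------------
# HILLS with known reconstruction
# ---------------------------------------------------------------------------

def synth_hills(target: FESGrid,
                gamma: float = 20.0,
                sigma: tuple[float, float] | None = None,
                n_hills: int | None = None,
                mode: str = "deterministic_grid",
                temperature: float = 300.0,
                w0: float = 0.1,
                seed: int = 0,
                path: str | Path | None = None) -> HillsTable:
    """Generate a HILLS table whose reconstructed FES is known.

    ``deterministic_grid`` deposits one hill per grid node with height
    proportional to (γ-1)/γ · (max F − F(node)) — the well-tempered bias
    that exactly complements the target — normalized by the discrete
    Gaussian mass so that summing the hills reproduces −(γ-1)/γ·(F − c) up
    to Gaussian-smoothing error.  ``sampled`` mimics a WT run: hill centers
    drawn from the biased Boltzmann weight on the grid, heights decaying
    with accumulated bias.
    """
    if not gamma > 1:
        raise ValueError("gamma must be > 1")
    ax1, ax2 = target.cv1_axis, target.cv2_axis
    dx1 = float(ax1[1] - ax1[0])
    dx2 = float(ax2[1] - ax2[0])
    if sigma is None:
        sigma = (2.0 * dx1, 2.0 * dx2)
    F = target.values - target.values.min()
    scale = (gamma - 1.0) / gamma
    n_nodes = F.size

    if mode == "deterministic_grid":
        if n_hills is not None and n_hills < n_nodes:
            raise ValueError(
                f"n_hills={n_hills} < {n_nodes} grid nodes in deterministic mode")
        m = np.arange(-30, 31)
        norm1 = float(np.exp(-(m * dx1) ** 2 / (2 * sigma[0] ** 2)).sum())
        norm2 = float(np.exp(-(m * dx2) ** 2 / (2 * sigma[1] ** 2)).sum())
        # Extend the deposition lattice beyond the grid (constant edge
        # padding of F) so the reconstruction inside the grid is free of
        # edge-truncation error and only carries Gaussian smoothing error.
        e1 = int(np.ceil(6 * sigma[0] / dx1))
        e2 = int(np.ceil(6 * sigma[1] / dx2))
        ext1 = np.concatenate([ax1[0] + dx1 * np.arange(-e1, 0), ax1,
                               ax1[-1] + dx1 * np.arange(1, e1 + 1)])
        ext2 = np.concatenate([ax2[0] + dx2 * np.arange(-e2, 0), ax2,
                               ax2[-1] + dx2 * np.arange(1, e2 + 1)])
        F_ext = np.pad(F, ((e1, e1), (e2, e2)), mode="edge")
        heights = (scale * (F.max() - F_ext) / (norm1 * norm2)).ravel()
        ii, jj = np.meshgrid(np.arange(len(ext1)), np.arange(len(ext2)),
                             indexing="ij")
        centers = np.column_stack([ext1[ii.ravel()], ext2[jj.ravel()]])
        table = HillsTable(
            time=np.arange(1.0, heights.size + 1),
            centers=centers,
            sigmas=np.tile(sigma, (heights.size, 1)),
            heights=heights,
            bias_factor=gamma,
            energy_unit="kcal/mol",
        )
    elif mode == "sampled":
        n_hills = n_hills or 2000
        rng = np.random.default_rng(seed)
        kbt = KB_KCAL * temperature
        delta_t = (gamma - 1.0) * temperature
        V = np.zeros_like(F)
        g1 = np.exp(-((ax1[:, None] - ax1[None, :]) ** 2) / (2 * sigma[0] ** 2))
        g2 = np.exp(-((ax2[:, None] - ax2[None, :]) ** 2) / (2 * sigma[1] ** 2))
        centers = np.empty((n_hills, 2))
        heights = np.empty(n_hills)
        for k in range(n_hills):
            logw = -(F + V) / kbt
            w = np.exp(logw - logw.max()).ravel()
            node = rng.choice(n_nodes, p=w / w.sum())
            i, j = np.unravel_index(node, F.shape)
            h = w0 * float(np.exp(-V[i, j] / (KB_KCAL * delta_t)))
            V += h * np.outer(g1[:, i], g2[:, j])
            centers[k] = (ax1[i], ax2[j])
            heights[k] = h
        table = HillsTable(
            time=np.arange(1.0, n_hills + 1),
            centers=centers,
            sigmas=np.tile(sigma, (n_hills, 1)),
            heights=heights,
            bias_factor=gamma,
            energy_unit="kcal/mol",
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if path is not None:
        write_hills(table, path)
    return table


# ---------------------------------------------------------------------------
# Mock dataset metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MockDatasetSpec:
    """Configured marginals for a mock structure-metadata table.

    Defaults mirror a published β-D-galactoside survey: 58 monosaccharide
    and 436 oligosaccharide structures, stacking prevalences of 93% and
    66%, 53 multi-stacking structures, 29% enzymes overall and 66% among
    multi-stacking records, and 240 unique proteins.
    """

    n_mono: int = 58
    n_oligo: int = 436
    stack_frac_mono: float = 0.93
    stack_frac_oligo: float = 0.66
    multi_frac_oligo: float = 53 / 436
    enzyme_frac: float = 0.29
    enzyme_frac_multi: float = 0.66
    n_unique: int | None = 240
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stack_frac_mono", "stack_frac_oligo", "multi_frac_oligo",
                     "enzyme_frac", "enzyme_frac_multi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def mock_dataset(spec: MockDatasetSpec | None = None) -> pd.DataFrame:
    """Mock metadata table whose realized counts equal round(frac × n).

    Counts are realized exactly (rounded half-up, not sampled); only the
    placement of the flags among rows, the resolutions/R-factors and the
    sequences use the seeded generator.  Identical seeds give identical
    tables.
    """
    spec = spec or MockDatasetSpec()
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_mono + spec.n_oligo
    n_stack_mono = _round_half_up(spec.stack_frac_mono * spec.n_mono)
    n_stack_oligo = _round_half_up(spec.stack_frac_oligo * spec.n_oligo)
    n_multi = min(_round_half_up(spec.multi_frac_oligo * spec.n_oligo),
                  n_stack_oligo)

    ligand = (["monosaccharide"] * spec.n_mono
              + ["oligosaccharide"] * spec.n_oligo)
    stacked = np.zeros(n_total, dtype=int)
    mono_idx = rng.permutation(spec.n_mono)[:n_stack_mono]
    stacked[mono_idx] = 1
    oligo_order = spec.n_mono + rng.permutation(spec.n_oligo)
    stacked[oligo_order[:n_multi]] = 2
    stacked[oligo_order[n_multi:n_stack_oligo]] = 1

    n_enzyme = _round_half_up(spec.enzyme_frac * n_total)
    multi_rows = np.where(stacked >= 2)[0]
    other_rows = np.where(stacked < 2)[0]
    n_enz_multi = min(_round_half_up(spec.enzyme_frac_multi * len(multi_rows)),
                      n_enzyme, len(multi_rows))
    enzyme = np.zeros(n_total, dtype=bool)
    enzyme[rng.permutation(multi_rows)[:n_enz_multi]] = True
    n_enz_rest = min(n_enzyme - n_enz_multi, len(other_rows))
    enzyme[rng.permutation(other_rows)[:n_enz_rest]] = True

    n_unique = spec.n_unique or n_total
    n_unique = min(n_unique, n_total)
    base_seqs = ["".join(rng.choice(_AA, size=60)) for _ in range(n_unique)]
    protein_of = np.concatenate([np.arange(n_unique),
                                 rng.integers(0, n_unique,
                                              size=n_total - n_unique)])
    protein_of = protein_of[rng.permutation(n_total)]

    return pd.DataFrame({
        "pdb_id": [f"SYN{i:04d}" for i in range(n_total)],
        "resolution": np.round(rng.uniform(1.0, 2.0, size=n_total), 2),
        "r_factor": np.round(rng.uniform(0.12, 0.20, size=n_total), 3),
        "ligand_class": ligand,
        "protein_class": np.where(enzyme, "enzyme", "other"),
        "sequence": [base_seqs[p] for p in protein_of],
        "n_stacked_monomers": stacked,
    })


# ---------------------------------------------------------------------------
# Fixture regeneration
# ---------------------------------------------------------------------------

def regenerate_fixtures(directory: str | Path, seed: int = 0) -> list[Path]:
    """Write the standard fixture set (pose PDBs, HILLS, metadata TSV)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    pose_model, _ = make_pose(PoseSpec(ring_type="TYR6", face="axial-3456"))
    pose_model.resolution, pose_model.r_factor = 1.50, 0.180
    p = directory / "pose_tyr_3456.pdb"
    write_pdb(pose_model, p)
    written.append(p)

    multi = make_multi_stack_model()
    p = directory / "multi_stack_trp.pdb"
    write_pdb(multi, p)
    written.append(p)

    ax = np.linspace(6.0, 14.0, 41)
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    target = FESGrid(ax, ax, 0.5 * ((xx - 9.0) ** 2 + (yy - 10.0) ** 2))
    p = directory / "HILLS.synthetic"
    synth_hills(target, path=p)
    written.append(p)

    table = mock_dataset(MockDatasetSpec(seed=seed))
    p = directory / "metadata.tsv"
    table.to_csv(p, sep="\t", index=False)
    written.append(p)
    return written
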