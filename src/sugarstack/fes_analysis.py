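"""Well-tempered metadynamics free-energy surface reconstruction and analysis.

A WT-MetaD run logs the Gaussian hills it deposits to a HILLS text file
(one row per hill: time, the two CV centers, the two widths, the height and
the bias factor γ).  Summing the hills gives the accumulated bias V(s); for
well-tempered runs the free energy follows as

    F(s) = -(γ/(γ-1)) · V(s)          ("deposited" height convention)
    F(s) = -V(s)                       ("rescaled": heights pre-scaled by (γ-1)/γ)

Surfaces live on a regular 2D grid over (CV1, CV2), are expressed in
kcal/mol (1 kcal = 4.184 kJ exactly) and are zero-referenced at their
minimum.  Analyses: replica averaging, contiguous low-energy basins, 1D
line profiles with forward/reverse barriers, minimax path barriers and a
simplified binding free-energy point estimate.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "KJ_PER_KCAL",
    "HillsTable",
    "FESGrid",
    "LineProfile",
    "BarrierResult",
    "HillsFormatError",
    "GridCoverageWarning",
    "read_hills",
    "write_hills",
    "bias_potential",
    "fes_from_bias",
    "average_replicas",
    "basin_region",
    "line_profile",
    "barrier_between",
    "minimax_path_barrier",
    "binding_free_energy",
    "kj_to_kcal",
    "kcal_to_kj",
]

KJ_PER_KCAL = 4.184  # exact thermochemical calorie

ENERGY_UNITS = ("kJ/mol", "kcal/mol")


class HillsFormatError(ValueError):
    """Malformed HILLS file (bad header, missing column, varying γ)."""


class GridCoverageWarning(UserWarning):
    """The analysis grid does not cover all hill centers ± 5σ."""


def kj_to_kcal(x):
    return np.asarray(x, dtype=float) / KJ_PER_KCAL


def kcal_to_kj(x):
    return np.asarray(x, dtype=float) * KJ_PER_KCAL


def _check_unit(unit: str) -> str:
    if unit not in ENERGY_UNITS:
        raise ValueError(f"unknown energy unit {unit!r}; expected one of {ENERGY_UNITS}")
    return unit


@dataclass
class HillsTable:
    """Time series of deposited Gaussians in a two-CV WT-MetaD run."""

    time: np.ndarray           # (n,)
    centers: np.ndarray        # (n, 2) in CV units (Å)
    sigmas: np.ndarray         # (n, 2) in CV units (Å)
    heights: np.ndarray        # (n,) in ``energy_unit``
    bias_factor: float         # γ, constant across rows
    cv_names: tuple[str, str] = ("cv1", "cv2")
    energy_unit: str = "kJ/mol"

    def __post_init__(self) -> None:
        self.time = np.atleast_1d(np.asarray(self.time, float))
        self.centers = np.asarray(self.centers, float).reshape(-1, 2)
        self.sigmas = np.asarray(self.sigmas, float).reshape(-1, 2)
        self.heights = np.atleast_1d(np.asarray(self.heights, float))
        _check_unit(self.energy_unit)
        n = len(self.time)
        if not (len(self.centers) == len(self.sigmas) == len(self.heights) == n):
            raise ValueError("inconsistent HILLS column lengths")
        if n and np.any(self.sigmas <= 0):
            raise ValueError("sigmas must be positive")
        if n and np.any(self.heights < 0):
            raise ValueError("heights must be non-negative")
        if not self.bias_factor > 1:
            raise ValueError("bias factor must be > 1")

    def __len__(self) -> int:
        return len(self.time)


def read_hills(path: str | Path, energy_unit: str = "kJ/mol") -> HillsTable:
    """Parse a HILLS file, mapping columns by FIELDS header name.

    The header must name ``time``, two CV columns with matching
    ``sigma_<cv>`` columns, ``height`` and ``biasf``.  The energy unit is
    not stored in the file and is taken from ``energy_unit``.
    """
    _check_unit(energy_unit)
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().split()
    if len(first) < 3 or first[0] != "#!" or first[1] != "FIELDS":
        raise HillsFormatError(f"{path}: missing '#! FIELDS' header")
    names = first[2:]
    col = {name: i for i, name in enumerate(names)}
    for required in ("time", "height", "biasf"):
        if required not in col:
            raise HillsFormatError(f"{path}: header missing column {required!r}")
    cvs = [n for n in names
           if n not in ("time", "height", "biasf")
           and not n.startswith("sigma_") and f"sigma_{n}" in col]
    if len(cvs) != 2:
        raise HillsFormatError(
            f"{path}: expected exactly two CV columns with sigma_* partners, "
            f"found {cvs!r}")
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.size == 0:
        data = np.empty((0, len(names)))
    if data.shape[1] != len(names):
        raise HillsFormatError(f"{path}: row width does not match header")
    biasf = data[:, col["biasf"]]
    if len(biasf) == 0:
        raise HillsFormatError(f"{path}: no hill rows")
    if not np.allclose(biasf, biasf[0], rtol=0, atol=1e-9):
        raise HillsFormatError(f"{path}: bias factor varies across rows")
    return HillsTable(
        time=data[:, col["time"]],
        centers=data[:, [col[cvs[0]], col[cvs[1]]]],
        sigmas=data[:, [col[f"sigma_{cvs[0]}"], col[f"sigma_{cvs[1]}"]]],
        heights=data[:, col["height"]],
        bias_factor=float(biasf[0]),
        cv_names=(cvs[0], cvs[1]),
        energy_unit=energy_unit,
    )


def write_hills(table: HillsTable, path: str | Path) -> None:
    """Write a HILLS file with a FIELDS header (round-trips read_hills)."""
    c1, c2 = table.cv_names
    with open(path, "w") as fh:
        fh.write(f"#! FIELDS time {c1} {c2} sigma_{c1} sigma_{c2} height biasf\n")
        for i in range(len(table)):
            fh.write("%.6f %.10g %.10g %.10g %.10g %.10g %.6f\n" % (
                table.time[i], table.centers[i, 0], table.centers[i, 1],
                table.sigmas[i, 0], table.sigmas[i, 1], table.heights[i],
                table.bias_factor))


@dataclass
class FESGrid:
    """Free energy on a regular (CV1, CV2) grid, kcal/mol, min-referenced.

    ``values[i, j]`` is the energy at (cv1_axis[i], cv2_axis[j]).
    """

    cv1_axis: np.ndarray
    cv2_axis: np.ndarray
    values: np.ndarray
    gamma: float | None = None
    replica_id: int | None = None

    def __post_init__(self) -> None:
        self.cv1_axis = np.asarray(self.cv1_axis, float)
        self.cv2_axis = np.asarray(self.cv2_axis, float)
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.cv1_axis), len(self.cv2_axis)):
            raise ValueError("values shape does not match axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("free energy must be finite on all cells")

    def zero_referenced(self) -> "FESGrid":
        return FESGrid(self.cv1_axis, self.cv2_axis,
                       self.values - self.values.min(),
                       gamma=self.gamma, replica_id=self.replica_id)

    def min_cell(self) -> tuple[int, int]:
        """Global minimum cell; ties broken by lowest (i, j) in row order."""
        flat = int(np.argmin(self.values))
        return np.unravel_index(flat, self.values.shape)  # type: ignore[return-value]

    def min_position(self) -> tuple[float, float]:
        i, j = self.min_cell()
        return float(self.cv1_axis[i]), float(self.cv2_axis[j])

    def same_grid(self, other: "FESGrid") -> bool:
        return (self.cv1_axis.shape == other.cv1_axis.shape
                and self.cv2_axis.shape == other.cv2_axis.shape
                and np.allclose(self.cv1_axis, other.cv1_axis)
                and np.allclose(self.cv2_axis, other.cv2_axis))

    def to_frame(self):
        import pandas as pd
        i, j = np.meshgrid(range(len(self.cv1_axis)), range(len(self.cv2_axis)),
                           indexing="ij")
        return pd.DataFrame({
            "cv1": self.cv1_axis[i.ravel()],
            "cv2": self.cv2_axis[j.ravel()],
            "free_energy": self.values.ravel(),
        })


def make_axis(lo: float, hi: float, step: float = 0.05) -> np.ndarray:
    """Uniform grid axis from lo to hi inclusive (default 0.05 Å spacing)."""
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def bias_potential(hills: HillsTable,
                   cv1_axis: np.ndarray,
                   cv2_axis: np.ndarray) -> np.ndarray:
    """Accumulated bias V(s) = Σ_k h_k exp(-Σ_i (s_i-c_ki)²/(2σ_ki²)).

    Returned in the hills' energy unit, shape (len(cv1_axis), len(cv2_axis)).
    Warns when the grid does not cover all centers ± 5σ.
    """
    cv1_axis = np.asarray(cv1_axis, float)
    cv2_axis = np.asarray(cv2_axis, float)
    V = np.zeros((len(cv1_axis), len(cv2_axis)))
    if len(hills) == 0:
        return V
    lo = hills.centers - 5 * hills.sigmas
    hi = hills.centers + 5 * hills.sigmas
    if (lo[:, 0].min() < cv1_axis[0] or hi[:, 0].max() > cv1_axis[-1]
            or lo[:, 1].min() < cv2_axis[0] or hi[:, 1].max() > cv2_axis[-1]):
        warnings.warn("grid does not cover all hill centers ± 5σ",
                      GridCoverageWarning, stacklevel=2)
    # Separable Gaussians: accumulate outer products axis-wise.
    for k in range(len(hills)):
        g1 = np.exp(-((cv1_axis - hills.centers[k, 0]) ** 2)
                    / (2 * hills.sigmas[k, 0] ** 2))
        g2 = np.exp(-((cv2_axis - hills.centers[k, 1]) ** 2)
                    / (2 * hills.sigmas[k, 1] ** 2))
        V += hills.heights[k] * np.outer(g1, g2)
    return V


def fes_from_bias(V: np.ndarray,
                  gamma: float,
                  cv1_axis: np.ndarray,
                  cv2_axis: np.ndarray,
                  convention: str = "deposited",
                  energy_unit: str = "kJ/mol",
                  replica_id: int | None = None) -> FESGrid:
    """Convert an accumulated bias into a zero-referenced FES in kcal/mol.

    ``deposited`` (default): the file stores as-deposited WT heights, so
    F = -(γ/(γ-1))·V.  ``rescaled``: heights were pre-scaled by (γ-1)/γ by
    the producing engine, so F = -V.
    """
    if not gamma > 1:
        raise ValueError("bias factor must be > 1")
    _check_unit(energy_unit)
    if convention == "deposited":
        F = -(gamma / (gamma - 1.0)) * np.asarray(V, float)
    elif convention == "rescaled":
        F = -np.asarray(V, float)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if energy_unit == "kJ/mol":
        F = kj_to_kcal(F)
    return FESGrid(cv1_axis, cv2_axis, F - F.min(),
                   gamma=gamma, replica_id=replica_id)


def average_replicas(fes_list: list[FESGrid]) -> FESGrid:
    """Arithmetic mean of zero-referenced replica surfaces, re-referenced."""
    if not fes_list:
        raise ValueError("need at least one replica surface")
    ref = fes_list[0]
    for f in fes_list[1:]:
        if not ref.same_grid(f):
            raise ValueError("replica grids do not match")
    mean = np.mean([f.values - f.values.min() for f in fes_list], axis=0)
    return FESGrid(ref.cv1_axis, ref.cv2_axis, mean - mean.min(),
                   gamma=ref.gamma)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    raise ValueError("connectivity must be 4 or 8")


def _wall_mask(fes: FESGrid, wall_bounds) -> np.ndarray:
    """True for cells allowed by the upper-wall bounds (None = everywhere)."""
    allowed = np.ones_like(fes.values, dtype=bool)
    if wall_bounds is None:
        return allowed
    b1, b2 = wall_bounds
    if b1 is not None:
        allowed &= (fes.cv1_axis <= b1)[:, None]
    if b2 is not None:
        allowed &= (fes.cv2_axis <= b2)[None, :]
    return allowed


def basin_region(fes: FESGrid,
                 cutoff: float = 1.5,
                 connectivity: int = 8,
                 wall_bounds: tuple[float | None, float | None] | None = None,
                 ) -> np.ndarray:
    """Boolean mask of the contiguous low-energy basin around the minimum.

    The basin is the connected component (8-connected by default) of cells
    with F <= cutoff (kcal/mol above the minimum) containing the global
    minimum cell.  Cells beyond an upper-wall bound are excluded when
    ``wall_bounds`` is given, since the bias there is restrained.
    """
    allowed = _wall_mask(fes, wall_bounds)
    values = np.where(allowed, fes.values, np.inf)
    flat = int(np.argmin(values))
    min_cell = np.unravel_index(flat, values.shape)
    low = (values - values[min_cell]) <= cutoff
    labels, _ = ndimage.label(low, structure=_connectivity_structure(connectivity))
    return labels == labels[min_cell]


@dataclass
class LineProfile:
    """1D free-energy profile along the line CV2 = a·CV1 + b.

    Sampled at a fixed CV2 step by bilinear interpolation and reported
    against CV2 (the plotting convention for translocation profiles).
    """

    a: float
    b: float
    cv2: np.ndarray
    values: np.ndarray

    @property
    def cv1(self) -> np.ndarray:
        return (self.cv2 - self.b) / self.a


def line_profile(fes: FESGrid,
                 a: float,
                 b: float,
                 cv2_range: tuple[float, float] | None = None,
                 step: float = 0.05) -> LineProfile:
    """Sample F along CV2 = a·CV1 + b, parametrized by CV2.

    The sampled range is clipped to the part of the line inside the grid;
    a line that misses the grid entirely raises ValueError.
    """
    if a == 0:
        raise ValueError("a horizontal line (a = 0) cannot be reported against CV2")
    lo2, hi2 = float(fes.cv2_axis[0]), float(fes.cv2_axis[-1])
    # CV2 values whose CV1 = (cv2-b)/a also falls inside the grid
    c1 = np.array([fes.cv1_axis[0], fes.cv1_axis[-1]])
    c2_from_c1 = a * c1 + b
    lo = max(lo2, c2_from_c1.min())
    hi = min(hi2, c2_from_c1.max())
    if cv2_range is not None:
        lo = max(lo, cv2_range[0])
        hi = min(hi, cv2_range[1])
    if hi < lo:
        raise ValueError("line does not intersect the grid over the requested range")
    n = int(np.floor((hi - lo) / step))
    cv2 = lo + step * np.arange(n + 1)
    cv1 = (cv2 - b) / a
    interp = RegularGridInterpolator((fes.cv1_axis, fes.cv2_axis), fes.values,
                                     bounds_error=True)
    values = interp(np.column_stack([cv1, cv2]))
    return LineProfile(a=a, b=b, cv2=cv2, values=values)


@dataclass
class BarrierResult:
    """Forward/reverse barriers between two basins along a profile."""

    basin_a: float        # kcal/mol, min F in window A
    basin_b: float        # kcal/mol, min F in window B
    transition: float     # kcal/mol, highest F crossed between the minima
    cv2_a: float
    cv2_b: float

    @property
    def forward(self) -> float:
        return self.transition - self.basin_a

    @property
    def reverse(self) -> float:
        return self.transition - self.basin_b


def barrier_between(profile: LineProfile,
                    window_a: tuple[float, float],
                    window_b: tuple[float, float]) -> BarrierResult:
    """Barriers between the minima found in two disjoint CV2 windows.

    The transition value is the maximum F on the profile segment between
    the two argmin positions (inclusive of the endpoints, so it is never
    below either basin value).
    """
    def window_min(window):
        lo, hi = window
        idx = np.where((profile.cv2 >= lo) & (profile.cv2 <= hi))[0]
        if idx.size == 0:
            raise ValueError(f"window {window} contains no profile samples")
        k = idx[int(np.argmin(profile.values[idx]))]
        return int(k)

    ia, ib = window_min(window_a), window_min(window_b)
    lo, hi = (ia, ib) if ia <= ib else (ib, ia)
    transition = float(profile.values[lo:hi + 1].max())
    return BarrierResult(
        basin_a=float(profile.values[ia]),
        basin_b=float(profile.values[ib]),
        transition=transition,
        cv2_a=float(profile.cv2[ia]),
        cv2_b=float(profile.cv2[ib]),
    )


def _neighbors(i: int, j: int, shape: tuple[int, int], connectivity: int):
    if connectivity == 8:
        steps = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
    else:
        steps = ((-1, 0), (1, 0), (0, -1), (0, 1))
    for di, dj in steps:
        ni, nj = i + di, j + dj
        if 0 <= ni < shape[0] and 0 <= nj < shape[1]:
            yield ni, nj


def minimax_path_barrier(fes: FESGrid,
                         cell_a: tuple[int, int],
                         cell_b: tuple[int, int],
                         connectivity: int = 8,
                         wall_bounds: tuple[float | None, float | None] | None = None,
                         ) -> float:
    """Minimal possible value of (max F along path) over grid paths A -> B.

    Widest-path variant of Dijkstra: the cost of a path is the highest cell
    energy it crosses, and the best path minimizes that.  Used as a 2D
    sanity check of 1D line barriers.
    """
    shape = fes.values.shape
    for cell in (cell_a, cell_b):
        if not (0 <= cell[0] < shape[0] and 0 <= cell[1] < shape[1]):
            raise ValueError(f"cell {cell} outside grid of shape {shape}")
    allowed = _wall_mask(fes, wall_bounds)
    if not (allowed[cell_a] and allowed[cell_b]):
        raise ValueError("endpoint cell excluded by wall bounds")
    F = fes.values
    best = np.full(shape, np.inf)
    start_cost = max(F[cell_a], F[cell_b])  # endpoints always on the path
    best[cell_a] = max(F[cell_a], F[cell_a])
    heap = [(float(F[cell_a]), cell_a)]
    while heap:
        cost, (i, j) = heapq.heappop(heap)
        if cost > best[i, j]:
            continue
        if (i, j) == cell_b:
            return float(max(cost, start_cost))
        for ni, nj in _neighbors(i, j, shape, connectivity):
            if not allowed[ni, nj]:
                continue
            ncost = max(cost, float(F[ni, nj]))
            if ncost < best[ni, nj]:
                best[ni, nj] = ncost
                heapq.heappush(heap, (ncost, (ni, nj)))
    raise ValueError("cells are disconnected under the wall bounds")


def binding_free_energy(fes: FESGrid,
                        bound_mask: np.ndarray,
                        unbound_mask: np.ndarray) -> float:
    """ΔG point estimate: min F over the bound region minus mean F over the
    unbound region (no standard-state/volume correction)."""
    bound_mask = np.asarray(bound_mask, bool)
    unbound_mask = np.asarray(unbound_mask, bool)
    if not bound_mask.any() or not unbound_mask.any():
        raise ValueError("masks must be non-empty")
    if np.any(bound_mask & unbound_mask):
        raise ValueError("masks must be disjoint")
    return float(fes.values[bound_mask].min() - fes.values[unbound_mask].mean())
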