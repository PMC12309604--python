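"""Desk-scale Langevin dynamics with well-tempered metadynamics biasing.

A single particle moves on an analytic 2D potential under overdamped
Euler–Maruyama dynamics while a WT-MetaD bias is grown underneath it:
every ``pace`` steps a Gaussian hill is deposited at the current position
with height w0·exp(-V(s)/(k_B·ΔT)), ΔT = (γ-1)·T.  Optional harmonic upper
walls restrain each coordinate.  The run writes a HILLS file readable by
:mod:`sugarstack.fes_analysis`, closing the loop for end-to-end validation
of the FES reconstruction against the analytic potential.

Internally all energies are kept in kcal/mol; ``energy_unit`` only rescales
inputs (w0) and outputs (HILLS heights), so a kJ/mol run is the same
trajectory expressed in different units.

Default integrator settings (dt = 0.01 ps, friction = 1 kcal·ps/mol/Ų)
were calibrated so a harmonic well equilibrates to the Boltzmann variance
within ~10⁵ steps; hill defaults (pace 250, w0 0.5 kcal/mol, σ 0.15) fill
a 5 kcal/mol double well within a 2×10⁵-step run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fes_analysis import FESGrid, HillsTable, KJ_PER_KCAL, write_hills

__all__ = [
    "KB_KCAL",
    "ToyPotential",
    "MetaDParams",
    "WallParams",
    "SimParams",
    "ToyRunResult",
    "potential_eval",
    "wall_bias",
    "deposit_hill_height",
    "langevin_step",
    "run_wtmetad",
    "run_replicas",
    "reference_fes_quadrature",
]

KB_KCAL = 0.0019872042586  # Boltzmann constant, kcal/mol/K


@dataclass
class ToyPotential:
    """Analytic 2D potential with value and gradient, in kcal/mol.

    ``double_well``: U = h·((x/x_w)² − 1)² + ½·k·y², minima at (±x_w, 0),
    saddle of height h at the origin.  ``harmonic``: U = ½·k·|s − s0|².
    ``custom``: user-supplied callables for value and gradient.
    """

    form: str
    h: float = 5.0          # kcal/mol, double-well barrier height
    x_w: float = 1.0        # Å, well separation (minima at ±x_w)
    k: float = 2.0          # kcal/mol/Ų, transverse / harmonic stiffness
    center: tuple[float, float] = (0.0, 0.0)
    value_fn: object = None
    grad_fn: object = None

    @classmethod
    def double_well(cls, h: float = 5.0, x_w: float = 1.0, k: float = 2.0):
        return cls(form="double_well", h=h, x_w=x_w, k=k)

    @classmethod
    def harmonic(cls, k: float = 2.0, center: tuple[float, float] = (0.0, 0.0)):
        return cls(form="harmonic", k=k, center=center)

    @classmethod
    def custom(cls, value_fn, grad_fn):
        return cls(form="custom", value_fn=value_fn, grad_fn=grad_fn)


def potential_eval(potential: ToyPotential, s: np.ndarray) -> tuple[float, np.ndarray]:
    """Analytic value and gradient of the potential at a point."""
    s = np.asarray(s, float)
    if potential.form == "double_well":
        x, y = s
        u = (x / potential.x_w) ** 2 - 1.0
        U = potential.h * u * u + 0.5 * potential.k * y * y
        gx = 4.0 * potential.h * u * x / potential.x_w ** 2
        gy = potential.k * y
        return float(U), np.array([gx, gy])
    if potential.form == "harmonic":
        rel = s - np.asarray(potential.center, float)
        return float(0.5 * potential.k * rel @ rel), potential.k * rel
    if potential.form == "custom":
        return float(potential.value_fn(s)), np.asarray(potential.grad_fn(s), float)
    raise ValueError(f"unknown potential form {potential.form!r}")


@dataclass
class MetaDParams:
    """WT-MetaD hill schedule.

    ``pace`` counts integrator steps between hills (protocol default 500);
    ``w0`` is the initial hill height in the run's energy unit; ``sigma``
    the per-CV Gaussian widths; ``gamma`` the bias factor (default 20);
    ``temperature`` in K (default 300).
    """

    pace: int = 500
    w0: float = 0.5
    sigma: tuple[float, float] = (0.15, 0.15)
    gamma: float = 20.0
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.pace < 1:
            raise ValueError("pace must be >= 1")
        if not self.w0 > 0:
            raise ValueError("w0 must be positive")
        if not self.gamma > 1:
            raise ValueError("gamma must be > 1")
        if min(self.sigma) <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class WallParams:
    """Harmonic upper walls: κ·(s_i − upper_i)^exponent above the bound.

    No ½ prefactor, matching the common biasing-engine convention for wall
    restraints.  ``kappa`` is in ``energy_unit`` (protocol default
    150 kJ/mol); ``upper`` entries may be None to disable a wall on one CV.
    """

    upper: tuple[float | None, float | None]
    kappa: float = 150.0
    exponent: int = 2
    energy_unit: str = "kJ/mol"

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")

    @property
    def kappa_kcal(self) -> float:
        return self.kappa / KJ_PER_KCAL if self.energy_unit == "kJ/mol" else self.kappa


@dataclass
class SimParams:
    """Overdamped Langevin integrator settings.

    dt in ps, friction in kcal·ps/mol/Ų; ``box`` aborts a diverged run.
    """

    dt: float = 0.01
    friction: float = 1.0
    n_steps: int = 200_000
    seed: int = 0
    save_every: int = 50
    box: float = 10.0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.friction > 0:
            raise ValueError("friction must be positive")


def wall_bias(s: np.ndarray, walls: WallParams | None) -> tuple[float, np.ndarray]:
    """Wall energy (in the wall's energy unit) and gradient at a point.

    Zero (with zero gradient) at and below the bound, κ·Δ^p above it; the
    gradient is continuous at the bound for p >= 2.
    """
    s = np.asarray(s, float)
    if walls is None:
        return 0.0, np.zeros_like(s)
    energy = 0.0
    grad = np.zeros_like(s)
    for i, bound in enumerate(walls.upper):
        if bound is None:
            continue
        delta = s[i] - bound
        if delta > 0:
            energy += walls.kappa * delta ** walls.exponent
            grad[i] = walls.kappa * walls.exponent * delta ** (walls.exponent - 1)
    return float(energy), grad


def deposit_hill_height(bias_at_s: float, metad: MetaDParams) -> float:
    """Well-tempered hill height w0·exp(−V(s)/(k_B·ΔT)), ΔT = (γ−1)·T.

    ``bias_at_s`` and the returned height are in kcal/mol.
    """
    delta_t = (metad.gamma - 1.0) * metad.temperature
    return metad.w0 * float(np.exp(-bias_at_s / (KB_KCAL * delta_t)))


def langevin_step(s: np.ndarray, total_force: np.ndarray, sim: SimParams,
                  temperature: float, rng: np.random.Generator) -> np.ndarray:
    """One overdamped Euler–Maruyama step.

    s' = s + (F/ζ)·dt + sqrt(2·k_B·T·dt/ζ)·ξ with ξ ~ N(0, 1) per component.
    """
    drift = total_force / sim.friction * sim.dt
    noise_scale = np.sqrt(2.0 * KB_KCAL * temperature * sim.dt / sim.friction)
    return s + drift + noise_scale * rng.standard_normal(2)


def _bias_and_grad(s: np.ndarray, centers: np.ndarray, heights: np.ndarray,
                   inv_two_sig2: np.ndarray, inv_sig2: np.ndarray,
                   n: int) -> tuple[float, np.ndarray]:
    """Accumulated hill bias and gradient at s over the first n hills (kcal/mol)."""
    if n == 0:
        return 0.0, np.zeros(2)
    diff = s - centers[:n]
    g = heights[:n] * np.exp(-(diff * diff) @ inv_two_sig2)
    V = float(g.sum())
    grad = -(g @ (diff * inv_sig2))
    return V, grad


@dataclass
class ToyRunResult:
    """Trajectory samples, deposited hills and the seed that produced them."""

    trajectory: np.ndarray        # (n_saved, 5): step, x, y, U, V_bias
    hills: HillsTable
    seed: int
    energy_unit: str


def run_wtmetad(potential: ToyPotential,
                metad: MetaDParams | None = None,
                walls: WallParams | None = None,
                sim: SimParams | None = None,
                hills_path: str | Path | None = None,
                energy_unit: str = "kcal/mol") -> ToyRunResult:
    """Run one WT-MetaD trajectory; optionally write its HILLS file.

    The run is bit-reproducible for a given ``sim.seed``.  ``energy_unit``
    fixes the unit in which ``metad.w0`` is given and in which hill heights
    are reported; the underlying dynamics are unit-invariant.
    """
    metad = metad or MetaDParams()
    sim = sim or SimParams()
    scale = KJ_PER_KCAL if energy_unit == "kJ/mol" else 1.0
    w0_kcal = metad.w0 / scale
    metad_internal = MetaDParams(pace=metad.pace, w0=w0_kcal, sigma=metad.sigma,
                                 gamma=metad.gamma, temperature=metad.temperature)

    rng = np.random.default_rng(sim.seed)
    s = np.zeros(2)
    # start in a potential minimum rather than on a saddle
    if potential.form == "double_well":
        s = np.array([-potential.x_w, 0.0])
    elif potential.form == "harmonic":
        s = np.asarray(potential.center, float).copy()

    max_hills = sim.n_steps // metad.pace
    centers = np.empty((max_hills, 2))
    heights_kcal = np.empty(max_hills)
    times = np.empty(max_hills)
    sig = np.asarray(metad.sigma, float)
    inv_two_sig2 = 1.0 / (2.0 * sig * sig)
    inv_sig2 = 1.0 / (sig * sig)
    n_hills = 0

    n_saved = sim.n_steps // sim.save_every + 1
    traj = np.empty((n_saved, 5))
    saved = 0

    for step in range(sim.n_steps + 1):
        U, gradU = potential_eval(potential, s)
        Vb, gradVb = _bias_and_grad(s, centers, heights_kcal,
                                    inv_two_sig2, inv_sig2, n_hills)
        Uw_unit, gradUw = wall_bias(s, walls)
        if walls is not None:
            wall_scale = (1.0 / KJ_PER_KCAL if walls.energy_unit == "kJ/mol" else 1.0)
        else:
            wall_scale = 1.0
        if step % sim.save_every == 0 and saved < n_saved:
            traj[saved] = (step, s[0], s[1], U, Vb)
            saved += 1
        if step > 0 and step % metad.pace == 0 and n_hills < max_hills:
            height = deposit_hill_height(Vb, metad_internal)
            centers[n_hills] = s
            heights_kcal[n_hills] = height
            times[n_hills] = step * sim.dt
            n_hills += 1
            # refresh bias gradient including the new hill
            Vb, gradVb = _bias_and_grad(s, centers, heights_kcal,
                                        inv_two_sig2, inv_sig2, n_hills)
        if step == sim.n_steps:
            break
        force = -(gradU + gradVb + wall_scale * gradUw)
        s = langevin_step(s, force, sim, metad.temperature, rng)
        if not np.all(np.isfinite(s)) or np.any(np.abs(s) > sim.box):
            raise RuntimeError(
                f"trajectory diverged at step {step}: s = {s}; check dt/friction")

    hills = HillsTable(
        time=times[:n_hills],
        centers=centers[:n_hills],
        sigmas=np.tile(sig, (n_hills, 1)),
        heights=heights_kcal[:n_hills] * scale,
        bias_factor=metad.gamma,
        energy_unit=energy_unit,
    ) if n_hills else HillsTable(
        time=np.empty(0), centers=np.empty((0, 2)), sigmas=np.empty((0, 2)),
        heights=np.empty(0), bias_factor=metad.gamma, energy_unit=energy_unit)

    if hills_path is not None:
        write_hills(hills, hills_path)
    return ToyRunResult(trajectory=traj[:saved], hills=hills, seed=sim.seed,
                        energy_unit=energy_unit)


def run_replicas(potential: ToyPotential,
                 metad: MetaDParams | None = None,
                 walls: WallParams | None = None,
                 sim: SimParams | None = None,
                 n_replicas: int = 3,
                 hills_dir: str | Path | None = None,
                 energy_unit: str = "kcal/mol") -> list[ToyRunResult]:
    """Independent replicas with per-replica seeds = root seed + index."""
    sim = sim or SimParams()
    results = []
    for r in range(n_replicas):
        rsim = SimParams(dt=sim.dt, friction=sim.friction, n_steps=sim.n_steps,
                         seed=sim.seed + r, save_every=sim.save_every, box=sim.box)
        path = None
        if hills_dir is not None:
            path = Path(hills_dir) / f"HILLS.{r}"
        results.append(run_wtmetad(potential, metad, walls, rsim,
                                   hills_path=path, energy_unit=energy_unit))
    return results


def reference_fes_quadrature(potential: ToyPotential,
                             temperature: float,
                             cv1_axis: np.ndarray,
                             cv2_axis: np.ndarray) -> FESGrid:
    """Deterministic reference free energy on a grid, kcal/mol.

    With the CVs equal to the simulated coordinates the marginal Boltzmann
    integral collapses and F(s) = U(s) − min U exactly; the grid evaluation
    below realizes that identity (temperature enters only through the
    general definition, not the result).
    """
    del temperature
    cv1_axis = np.asarray(cv1_axis, float)
    cv2_axis = np.asarray(cv2_axis, float)
    U = np.empty((len(cv1_axis), len(cv2_axis)))
    for i, x in enumerate(cv1_axis):
        for j, y in enumerate(cv2_axis):
            U[i, j], _ = potential_eval(potential, np.array([x, y]))
    return FESGrid(cv1_axis, cv2_axis, U - U.min())
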