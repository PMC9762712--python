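"""Synthetic fixtures with analytic ground truth for every pipeline stage.

Four generators:

* :func:`gnm_ensemble` — equilibrium Cα ensembles drawn from an anisotropic
  elastic-network (ANM) Gaussian whose covariance kBT·H⁺ is known in closed
  form, the oracle for the covariance/PCA/PRS chain;
* :func:`two_state_trajectory` — a minimal 4-atom system whose two atom-pair
  distances realize a prescribed mixture of switch states;
* :func:`smd_toy` — overdamped Langevin pulling of one particle on an analytic
  1-D potential by a constant-velocity spring, the oracle for the cumulant PMF;
* :func:`solvated_toy` — a point solute with waters placed just inside/outside
  a hydration cutoff.

These fixtures are statistical stand-ins: they reproduce the mathematical
structure the estimators assume, not RAS energetics or sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize_scalar

from .collective_motion import CovarianceMatrix
from .core_io import StructureModel, TrajectoryEnsemble
from .pmf import SMDTrace
from .thermo import ThermalParameters

__all__ = ["GNMSpec", "PullSpec", "Potential", "harmonic_potential",
           "double_well_potential", "well_minima", "pca_balanced_gnm_spec",
           "gnm_ensemble", "two_state_trajectory", "smd_toy", "solvated_toy"]


# ---------------------------------------------------------------------------
# elastic-network ensemble


@dataclass
class GNMSpec:
    """Specification of an elastic-network equilibrium ensemble."""

    n_residues: int = 20
    contact_cutoff: float = 10.0      # Å
    spring_k: float = 1.0             # kcal mol^-1 Å^-2
    temperature: float = 310.0        # K
    n_frames: int = 10_000
    seed: int = 0
    backbone_geometry: str = "random-walk"   # helix | extended | random-walk

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("need at least 4 residues")
        if self.backbone_geometry not in ("helix", "extended", "random-walk"):
            raise ValueError(f"unknown geometry {self.backbone_geometry!r}")


def _backbone(spec: GNMSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_residues
    if spec.backbone_geometry == "helix":
        # ideal alpha-helix: 2.3 Å radius, 1.5 Å rise, 100 deg per residue
        t = np.arange(n) * np.radians(100.0)
        return np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)])
    if spec.backbone_geometry == "extended":
        # near-linear strand with small off-axis ripple in y AND z; a perfectly
        # collinear chain would have zero transverse ANM stiffness
        i = np.arange(n)
        return np.column_stack([3.8 * i, 0.9 * np.sin(1.9 * i), 0.9 * np.cos(1.3 * i)])
    # compact random walk with 3.8 Å virtual bonds; weak persistence keeps the
    # chain globular enough that the contact network is generically connected
    coords = np.zeros((n, 3))
    d = np.array([1.0, 0.0, 0.0])
    for i in range(1, n):
        step = 0.4 * d + rng.normal(size=3)
        d = step / np.linalg.norm(step)
        coords[i] = coords[i - 1] + 3.8 * d
    return coords


def _anm_hessian(coords: np.ndarray, cutoff: float, k: float) -> np.ndarray:
    """Standard anisotropic-network Hessian: −(k/d²)·(d⊗d) blocks for contacts."""
    n = coords.shape[0]
    H = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(i + 1, n):
            dv = coords[j] - coords[i]
            d2 = dv @ dv
            if d2 <= cutoff * cutoff:
                blk = -(k / d2) * np.outer(dv, dv)
                H[3 * i:3 * i + 3, 3 * j:3 * j + 3] = blk
                H[3 * j:3 * j + 3, 3 * i:3 * i + 3] = blk
                H[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= blk
                H[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= blk
    return H


def _ca_topology(coords: np.ndarray) -> StructureModel:
    n = coords.shape[0]
    return StructureModel(
        atom_names=np.array(["CA"] * n),
        residue_numbers=np.arange(1, n + 1),
        residue_names=np.array(["ALA"] * n),
        chain_ids=np.array(["A"] * n),
        coordinates=coords,
        masses=np.full(n, 12.011),
    )


def pca_balanced_gnm_spec(n_frames: int = 10_000, seed: int = 0) -> GNMSpec:
    """A 20-residue helix network whose first five modes carry ~50% of the
    variance — the regime reported for the Cα PCA of the RAS trajectories,
    useful when a realistically balanced spectrum matters."""
    return GNMSpec(n_residues=20, contact_cutoff=15.0, spring_k=1.0,
                   backbone_geometry="helix", n_frames=n_frames, seed=seed)


def gnm_ensemble(spec: GNMSpec) -> tuple[TrajectoryEnsemble, CovarianceMatrix]:
    """Sample an elastic-network Gaussian ensemble with analytic covariance.

    The ANM Hessian of the backbone contact network is pseudo-inverted over its
    non-rigid modes (the six smallest are removed spectrally) and frames are
    drawn i.i.d. from N(mean, kBT·H⁺).  Returns the ensemble (marked aligned:
    the samples carry no rigid-body component by construction) and the analytic
    covariance.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    # a walk can produce a floppy network (low-degree node with near-collinear
    # contacts → a 7th soft mode); redraw until only the 6 rigid-body modes
    # are soft.  Deterministic geometries get a single attempt.
    attempts = 50 if spec.backbone_geometry == "random-walk" else 1
    n_zero = 3 * spec.n_residues
    for _ in range(attempts):
        coords = _backbone(spec, rng)
        H = _anm_hessian(coords, spec.contact_cutoff, spec.spring_k)
        vals, vecs = np.linalg.eigh(H)
        n_zero = int(np.sum(vals < 1e-8 * max(vals.max(), 1.0)))
        if n_zero <= 6:
            break
    else:
        raise ValueError(
            f"contact network is disconnected or floppy ({n_zero} soft modes); "
            "increase contact_cutoff"
        )
    kBT = ThermalParameters(spec.temperature).kBT
    inv = np.zeros_like(vals)
    inv[6:] = 1.0 / vals[6:]
    V = vecs[:, 6:]
    C = kBT * (V * inv[6:]) @ V.T
    C = 0.5 * (C + C.T)
    # sample: x = mean + V sqrt(kBT/λ) z
    L = V * np.sqrt(kBT * inv[6:])
    z = rng.standard_normal((spec.n_frames, V.shape[1]))
    X = coords.ravel() + z @ L.T
    ensemble = TrajectoryEnsemble(
        coordinates=X.reshape(spec.n_frames, spec.n_residues, 3),
        topology=_ca_topology(coords),
        frame_times=np.arange(spec.n_frames, dtype=float),
        replicate_ids=np.zeros(spec.n_frames, dtype=int),
        aligned=True,
    )
    analytic = CovarianceMatrix(C, coords.copy(), spec.n_frames)
    return ensemble, analytic


# ---------------------------------------------------------------------------
# two-state switch trajectory


def _two_state_topology() -> StructureModel:
    """Minimal 4-atom system realizing the two switch reaction coordinates.

    Atoms: Cα of residues 12 and 34 (pair 1), HN of residue 60 and Pγ of a GTP
    'residue' (pair 2), so the states module's default atom specs resolve.
    """
    return StructureModel(
        atom_names=np.array(["CA", "CA", "HN", "PG"]),
        residue_numbers=np.array([12, 34, 60, 200]),
        residue_names=np.array(["GLY", "PRO", "GLY", "GTP"]),
        chain_ids=np.array(["A"] * 4),
        coordinates=np.zeros((4, 3)),
        masses=np.array([12.011, 12.011, 1.008, 30.974]),
    )


def two_state_trajectory(
    weights: tuple[float, ...] = (0.7, 0.3),
    state_centers: tuple[tuple[float, float], ...] = ((7.0, 7.0), (26.0, 7.0)),
    noise_sd: float = 0.3,
    n_frames: int = 1000,
    seed: int = 0,
) -> TrajectoryEnsemble:
    """Frames drawn from a mixture of (d1, d2) switch-distance states.

    Each frame samples a state by ``weights``, then d1/d2 from Gaussians of
    width ``noise_sd`` about that state's centers; atoms are placed so the
    realized pair distances equal the drawn values exactly.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    centers = np.asarray(state_centers, dtype=float)
    if centers.shape[0] != weights.size:
        raise ValueError("one (d1, d2) center pair per weight required")
    rng = np.random.default_rng(seed)
    states = rng.choice(weights.size, size=n_frames, p=weights)
    d1 = np.maximum(centers[states, 0] + noise_sd * rng.standard_normal(n_frames), 0.1)
    d2 = np.maximum(centers[states, 1] + noise_sd * rng.standard_normal(n_frames), 0.1)
    coords = np.zeros((n_frames, 4, 3))
    coords[:, 1, 0] = d1                 # atom 34:CA at (d1, 0, 0)
    coords[:, 2, 1] = 50.0               # atom 60:HN at (0, 50, 0)
    coords[:, 3, 0] = d2                 # GTP:PG at (d2, 50, 0)
    coords[:, 3, 1] = 50.0
    return TrajectoryEnsemble(
        coordinates=coords,
        topology=_two_state_topology(),
        frame_times=np.arange(n_frames, dtype=float),
        replicate_ids=np.zeros(n_frames, dtype=int),
        aligned=True,
    )


# ---------------------------------------------------------------------------
# Langevin pulling


@dataclass
class Potential:
    """Analytic 1-D potential: energy u(x) and derivative du(x) in kcal/mol, Å."""

    name: str
    u: Callable[[np.ndarray], np.ndarray]
    du: Callable[[np.ndarray], np.ndarray]
    start: float                      # pulled particle's initial position

    def delta_f(self, a: float, b: float) -> float:
        """Potential difference u(b) − u(a) (the stiff-spring PMF ground truth)."""
        return float(self.u(np.asarray(b)) - self.u(np.asarray(a)))


def harmonic_potential(k: float = 2.0, center: float = 0.0) -> Potential:
    return Potential(
        name="harmonic",
        u=lambda x: 0.5 * k * (x - center) ** 2,
        du=lambda x: k * (x - center),
        start=center,
    )


def double_well_potential(
    barrier: float = 3.0,
    separation: float = 3.0,
    tilt: float = -0.5,
) -> Potential:
    """Quartic double well u = h·((x²−a²)/a²)² + tilt·x with minima near ±a.

    ``barrier`` (kcal/mol) is the untilted barrier height at x=0, ``separation``
    the distance 2a between the untilted minima, ``tilt`` (kcal/mol/Å) skews
    the wells so the inter-minimum free-energy difference is non-trivial.
    The exact minima of the tilted potential are located numerically by
    :func:`well_minima`.
    """
    a = separation / 2.0
    return Potential(
        name="double-well",
        u=lambda x: barrier * ((x ** 2 - a ** 2) / a ** 2) ** 2 + tilt * x,
        du=lambda x: barrier * 4.0 * x * (x ** 2 - a ** 2) / a ** 4 + tilt,
        start=-a,
    )


def well_minima(potential: Potential, span: float = 6.0) -> tuple[float, float]:
    """(left, right) local minima of the potential around its start point."""
    s = potential.start
    left = minimize_scalar(lambda x: float(potential.u(np.asarray(x))),
                           bounds=(s - span / 2, s + span / 4), method="bounded").x
    right = minimize_scalar(lambda x: float(potential.u(np.asarray(x))),
                            bounds=(s + span / 4, s + span), method="bounded").x
    return float(left), float(right)


@dataclass
class PullSpec:
    """Constant-velocity Langevin pulling protocol on an analytic potential.

    ``friction`` is the overdamped drag coefficient γ in kcal mol⁻¹ ps Å⁻²;
    the particle obeys γ ẋ = −u'(x) + k(x_anchor − x) + √(2γkBT) ξ(t).
    Defaults mirror the reference pulling protocol (0.03 Å/ps, 90 kcal/mol/Å²,
    samples every 24 fs, 2 fs integration step).
    """

    potential: Potential = field(default_factory=double_well_potential)
    friction: float = 10.0            # kcal mol^-1 ps Å^-2
    velocity: float = 0.03            # Å/ps
    spring_constant: float = 90.0     # kcal mol^-1 Å^-2
    temperature: float = 310.0        # K
    pull_distance: float = 3.5        # Å of anchor travel; default spans the
                                      # double well's minima plus a 0.5 Å margin
    timestep: float = 0.002           # ps
    sample_interval: float = 0.024    # ps
    n_runs: int = 70
    seed: int = 0

    def __post_init__(self) -> None:
        if self.friction <= 0 or self.velocity <= 0 or self.spring_constant <= 0:
            raise ValueError("friction, velocity and spring_constant must be positive")
        # explicit Euler-Maruyama stability: dt * k_max / gamma must stay small
        k_eff = self.spring_constant + 10.0  # headroom for potential curvature
        if self.timestep * k_eff / self.friction > 0.5:
            raise ValueError(
                "timestep unstable for this spring/friction; reduce timestep "
                "or increase friction"
            )


def smd_toy(spec: PullSpec) -> tuple[list[SMDTrace], Potential]:
    """Simulate constant-velocity pulling runs; returns traces + ground truth.

    All runs share the anchor schedule and are integrated in parallel with
    independent noise (Euler–Maruyama).  Recorded at ``sample_interval``:
    time, particle displacement from start, and spring force projected on the
    pulling direction.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    # temperature 0 is allowed here: deterministic (noise-free) pulling
    kBT = ThermalParameters(spec.temperature).kBT if spec.temperature > 0 else 0.0
    dt = spec.timestep
    gamma = spec.friction
    n_steps = int(np.ceil(spec.pull_distance / (spec.velocity * dt)))
    record_every = max(1, int(round(spec.sample_interval / dt)))
    x0 = spec.potential.start
    x = np.full(spec.n_runs, x0)
    noise_scale = np.sqrt(2.0 * gamma * kBT * dt) / gamma
    times, positions, forces = [0.0], [x.copy()], []
    anchor = x0
    forces.append(spec.spring_constant * (anchor - x))
    for step in range(1, n_steps + 1):
        anchor = x0 + spec.velocity * step * dt
        f_spring = spec.spring_constant * (anchor - x)
        f_total = -spec.potential.du(x) + f_spring
        x = x + (f_total / gamma) * dt + noise_scale * rng.standard_normal(spec.n_runs)
        if step % record_every == 0 or step == n_steps:
            f_rec = spec.spring_constant * (anchor - x)
            times.append(step * dt)
            positions.append(x.copy())
            forces.append(f_rec)
    t = np.asarray(times)
    P = np.asarray(positions)        # (T, n_runs)
    F = np.asarray(forces)
    traces = [
        SMDTrace(
            time=t,
            projected_position=P[:, r] - P[0, r],
            projected_force=F[:, r],
            run_id=r,
            velocity=spec.velocity,
            spring_constant=spec.spring_constant,
        )
        for r in range(spec.n_runs)
    ]
    return traces, spec.potential


# ---------------------------------------------------------------------------
# hydration toy


def solvated_toy(n_inside: int, n_outside: int, cutoff: float = 5.0,
                 seed: int = 0) -> StructureModel:
    """One-atom solute at the origin plus waters at radii cutoff ∓ 0.1 Å.

    Exactly ``n_inside`` water oxygens sit strictly within the cutoff and
    ``n_outside`` strictly beyond it, in random directions.
    """
    if n_inside < 0 or n_outside < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    n_wat = n_inside + n_outside
    dirs = rng.standard_normal((max(n_wat, 1), 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = np.concatenate([
        np.full(n_inside, cutoff - 0.1),
        np.full(n_outside, cutoff + 0.1),
    ])
    coords = np.vstack([np.zeros(3), dirs[:n_wat] * radii[:, None]])
    return StructureModel(
        atom_names=np.array(["C1"] + ["O"] * n_wat),
        residue_numbers=np.arange(1, n_wat + 2),
        residue_names=np.array(["LIG"] + ["HOH"] * n_wat),
        chain_ids=np.array(["A"] + ["W"] * n_wat),
        coordinates=coords,
        masses=np.array([12.011] + [15.999] * n_wat),
    )
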