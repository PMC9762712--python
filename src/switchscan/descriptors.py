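"""Per-residue and per-atom-pair trajectory descriptors.

RMSF and its between-system deltas, atom-pair distance and dihedral series,
normalized probability-density histograms (1 Å distance bins, 20° angle bins
by convention) and hydration-shell water counts.

Error conventions: quantities averaged over replicates (RMSF, histogram
densities) carry the standard error across replicates; time-averaged scalars
within one pooled trajectory (hydration, distance means) carry a block-averaged
standard error of the mean (5 contiguous blocks) to respect autocorrelation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    from MDAnalysis.lib.distances import calc_dihedrals

from .core_io import (
    AtomSelection,
    SelectionError,
    StructureModel,
    TrajectoryEnsemble,
    resolve_atom,
)

__all__ = [
    "FluctuationProfile",
    "AtomPairSeries",
    "DensityHistogram",
    "HydrationSeries",
    "rmsf",
    "rmsf_delta",
    "atom_pair_distance",
    "dihedral_series",
    "density_histogram",
    "hydration_count",
    "block_se",
]


def block_se(values: np.ndarray, n_blocks: int = 5) -> float:
    """Standard error of the mean from contiguous block averages.

    Correlated time series underestimate their SE when treated as i.i.d.;
    averaging within ``n_blocks`` contiguous blocks and taking the SE of the
    block means is the standard remedy.
    """
    values = np.asarray(values, dtype=float)
    if values.size < n_blocks or n_blocks < 2:
        return 0.0
    blocks = np.array_split(values, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / np.sqrt(n_blocks))


@dataclass
class FluctuationProfile:
    """Per-residue RMSF, per replicate and aggregated across replicates."""

    residue_numbers: np.ndarray       # (R,)
    rmsf_per_replicate: np.ndarray    # (n_rep, R) Å
    mean_rmsf: np.ndarray             # (R,) Å
    se_rmsf: np.ndarray               # (R,) Å, 0 when a single replicate

    def value(self, residue_number: int) -> tuple[float, float]:
        """(mean, se) for one residue."""
        i = np.flatnonzero(self.residue_numbers == residue_number)
        if i.size != 1:
            raise KeyError(f"residue {residue_number} not in profile")
        return float(self.mean_rmsf[i[0]]), float(self.se_rmsf[i[0]])


@dataclass
class AtomPairSeries:
    frame_times: np.ndarray
    distance: np.ndarray              # (F,) Å
    atom_a: str
    atom_b: str
    replicate_ids: np.ndarray | None = None

    @property
    def mean(self) -> float:
        return float(self.distance.mean())

    @property
    def se(self) -> float:
        return block_se(self.distance)


@dataclass
class DensityHistogram:
    """Probability density per bin, normalized so Σ density·width = 1."""

    bin_edges: np.ndarray             # (B+1,)
    density: np.ndarray               # (B,) per unit
    se_density: np.ndarray            # (B,)
    bin_width: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def integral(self) -> float:
        return float(self.density.sum() * self.bin_width)


@dataclass
class HydrationSeries:
    counts: np.ndarray                # (F,) int
    mean_count: float
    se_count: float
    cutoff: float


# ---------------------------------------------------------------------------


def rmsf(ensemble: TrajectoryEnsemble, selection: AtomSelection) -> FluctuationProfile:
    """Per-residue backbone RMSF, averaged over replicates.

    Within each replicate, each selected atom's mean-square fluctuation about
    its time-mean position is computed; a residue's RMSF is the root of the
    mean MSF over its selected atoms.  The profile reports the across-replicate
    mean and standard error.
    """
    if not ensemble.aligned:
        raise ValueError("ensemble must be superposed before RMSF (rigid-body "
                         "motion would otherwise dominate)")
    selection.require_nonempty()
    idx = selection.resolved_indices
    resnums = ensemble.topology.residue_numbers[idx]
    residues = ensemble.topology.unique_residues
    residues = residues[np.isin(residues, resnums)]
    if ensemble.n_frames == 1:
        warnings.warn("single-frame ensemble: RMSF is identically zero")
    reps = ensemble.replicates
    per_rep = np.zeros((reps.size, residues.size))
    for r, rep in enumerate(reps):
        block = ensemble.frames_of(rep)[:, idx, :]          # (f, s, 3)
        dev = block - block.mean(axis=0, keepdims=True)
        msf = (dev ** 2).sum(axis=2).mean(axis=0)           # (s,) per-atom MSF
        for j, res in enumerate(residues):
            per_rep[r, j] = np.sqrt(msf[resnums == res].mean())
    mean = per_rep.mean(axis=0)
    if reps.size > 1:
        se = per_rep.std(axis=0, ddof=1) / np.sqrt(reps.size)
    else:
        se = np.zeros_like(mean)
    return FluctuationProfile(residues, per_rep, mean, se)


def rmsf_delta(
    profile_a: FluctuationProfile,
    profile_b: FluctuationProfile,
    region: np.ndarray | list[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-residue difference a − b of mean RMSF, plus a region aggregate.

    Returns ``(residue_numbers, delta, region_mean)``; ``region`` is a list of
    residue numbers (defaults to all shared residues).
    """
    if (profile_a.residue_numbers.shape != profile_b.residue_numbers.shape
            or np.any(profile_a.residue_numbers != profile_b.residue_numbers)):
        only_a = set(profile_a.residue_numbers) - set(profile_b.residue_numbers)
        only_b = set(profile_b.residue_numbers) - set(profile_a.residue_numbers)
        raise ValueError(
            f"residue sets differ: only in a={sorted(only_a)}, only in b={sorted(only_b)}"
        )
    delta = profile_a.mean_rmsf - profile_b.mean_rmsf
    if region is None:
        mask = np.ones(delta.size, dtype=bool)
    else:
        mask = np.isin(profile_a.residue_numbers, np.asarray(region, dtype=int))
        if not mask.any():
            raise ValueError("region contains no profiled residues")
    return profile_a.residue_numbers.copy(), delta, float(delta[mask].mean())


def atom_pair_distance(
    ensemble: TrajectoryEnsemble,
    a: str,
    b: str,
    allow_identical: bool = False,
) -> AtomPairSeries:
    """Euclidean distance between two atoms per frame.

    Atoms are addressed as ``"12:CA"`` (residue number) or ``"GTP:PG"``
    (residue name).  Computed on raw coordinates, so the series is invariant
    under superposition.
    """
    ia = resolve_atom(ensemble.topology, a)
    ib = resolve_atom(ensemble.topology, b)
    if ia == ib and not allow_identical:
        raise SelectionError(f"atoms {a!r} and {b!r} are the same atom")
    d = np.linalg.norm(ensemble.coordinates[:, ia, :] - ensemble.coordinates[:, ib, :], axis=1)
    return AtomPairSeries(ensemble.frame_times.copy(), d, a, b, ensemble.replicate_ids.copy())


def dihedral_series(ensemble: TrajectoryEnsemble, atoms: tuple[str, str, str, str]) -> np.ndarray:
    """Signed dihedral (IUPAC convention) in degrees, range (−180, 180].

    ``atoms`` are four atom specs; for a Tyr χ₂ use CA–CB–CG–CD1.
    Raises on a collinear triple (undefined angle), naming the frame.
    """
    if len(set(atoms)) != 4:
        raise SelectionError("dihedral needs 4 distinct atoms")
    ijkl = [resolve_atom(ensemble.topology, s) for s in atoms]
    p = [ensemble.coordinates[:, i, :] for i in ijkl]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    for which, (u, v) in enumerate([(b1, b2), (b2, b3)]):
        cross = np.cross(u, v)
        bad = np.linalg.norm(cross, axis=1) < 1e-10
        if bad.any():
            raise ValueError(
                f"collinear atom triple ({'first' if which == 0 else 'last'} three) "
                f"at frame {int(np.flatnonzero(bad)[0])}: dihedral undefined"
            )
    ang = np.degrees(calc_dihedrals(p[0], p[1], p[2], p[3]))
    # map -180 -> +180 for the (−180, 180] convention
    ang[np.isclose(ang, -180.0)] = 180.0
    return ang


def density_histogram(
    values: np.ndarray,
    bin_width: float,
    value_range: tuple[float, float] | None = None,
    replicate_ids: np.ndarray | None = None,
    angular: bool = False,
) -> DensityHistogram:
    """Normalized probability-density histogram.

    Distance bins are anchored at 0 (edges at integer multiples of
    ``bin_width``); angular histograms wrap on (−180, 180] with edges anchored
    at −180.  When ``replicate_ids`` are given, the per-bin SE across replicate
    densities is reported.
    """
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)] if values.size else values
    if values.size == 0:
        raise ValueError("empty input")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if angular:
        lo, hi = -180.0, 180.0
        values = ((values - 180.0) % 360.0) - 180.0   # wrap into [-180, 180)
        n_bins = int(np.ceil((hi - lo) / bin_width))
        edges = lo + bin_width * np.arange(n_bins + 1)
    else:
        if value_range is not None:
            lo, hi = value_range
        else:
            lo = np.floor(values.min() / bin_width) * bin_width
            hi = np.ceil(values.max() / bin_width) * bin_width
            if hi <= lo:
                hi = lo + bin_width
        n_bins = int(round((hi - lo) / bin_width))
        edges = lo + bin_width * np.arange(n_bins + 1)
        values = np.clip(values, lo, np.nextafter(edges[-1], -np.inf))
    dens, _ = np.histogram(values, bins=edges, density=True)
    if replicate_ids is not None and np.unique(replicate_ids).size > 1:
        reps = np.unique(replicate_ids)
        per = np.stack([
            np.histogram(values[replicate_ids == r], bins=edges, density=True)[0]
            for r in reps
        ])
        se = per.std(axis=0, ddof=1) / np.sqrt(reps.size)
    else:
        se = np.zeros_like(dens)
    return DensityHistogram(edges, dens, se, float(bin_width))


def hydration_count(
    ensemble: TrajectoryEnsemble,
    solute: AtomSelection,
    waters: AtomSelection,
    cutoff: float = 5.0,
) -> HydrationSeries:
    """Number of water molecules within ``cutoff`` of the solute, per frame.

    A water molecule counts once if any of its selected atoms lies strictly
    within the cutoff of any solute atom; the boundary distance itself is
    excluded.  The mean carries a block-averaged SE of the mean.
    """
    solute.require_nonempty()
    waters.require_nonempty()
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    w_idx = waters.resolved_indices
    s_idx = solute.resolved_indices
    water_res = ensemble.topology.residue_numbers[w_idx]
    counts = np.zeros(ensemble.n_frames, dtype=int)
    for f in range(ensemble.n_frames):
        tree = cKDTree(ensemble.coordinates[f, s_idx, :])
        d, _ = tree.query(ensemble.coordinates[f, w_idx, :], k=1)
        counts[f] = np.unique(water_res[d < cutoff]).size
    return HydrationSeries(counts, float(counts.mean()), block_se(counts), float(cutoff))
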