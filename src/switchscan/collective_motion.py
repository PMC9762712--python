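"""Essential dynamics: Cα covariance, eigendecomposition, projections, eigen-RMSF.

The 3N×3N displacement covariance C = ⟨Δr Δrᵀ⟩ (deviations from the time-mean
structure, population normalisation 1/T, unit weighting by default) is shared
with the linear-response scan; its eigenvectors are the principal modes and
per-mode projections/reconstructions give the eigen-RMSF over a chosen band of
modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import linalg

from .core_io import AtomSelection, TrajectoryEnsemble
from .descriptors import FluctuationProfile

__all__ = ["CovarianceMatrix", "EigenDecomposition", "covariance",
           "eigendecompose", "eigen_rmsf", "project"]


@dataclass
class CovarianceMatrix:
    matrix: np.ndarray          # (3N, 3N) Å²
    mean_structure: np.ndarray  # (N, 3) Å
    n_frames_used: int
    selection: AtomSelection | None = None

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1] or M.shape[0] % 3:
            raise ValueError("covariance must be square with 3N rows")
        if not np.allclose(M, M.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        self.matrix = 0.5 * (M + M.T)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0] // 3

    @property
    def trace(self) -> float:
        return float(np.trace(self.matrix))

    def block(self, node: int) -> np.ndarray:
        """The 3N×3 column block coupling every coordinate to node ``node``."""
        return self.matrix[:, 3 * node:3 * node + 3]


@dataclass
class EigenDecomposition:
    eigenvalues: np.ndarray      # (k,) Å², descending
    eigenvectors: np.ndarray     # (3N, k), orthonormal columns
    total_variance: float        # trace of the full covariance

    @property
    def variance_fraction(self) -> np.ndarray:
        return self.eigenvalues / self.total_variance

    @property
    def cumulative_variance_fraction(self) -> np.ndarray:
        return np.cumsum(self.variance_fraction)

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size


def covariance(
    ensemble: TrajectoryEnsemble,
    selection: AtomSelection,
    mass_weighted: bool = False,
) -> CovarianceMatrix:
    """Displacement covariance of the selected atoms over all frames.

    Deviations are taken from the time-mean structure of the pooled frames;
    normalisation is 1/T.  ``mass_weighted`` multiplies each coordinate by
    √mass before the outer product (off by default).
    """
    if not ensemble.aligned:
        raise ValueError("superpose the ensemble on this selection first")
    selection.require_nonempty()
    if ensemble.n_frames < 2:
        raise ValueError("need at least 2 frames for a covariance")
    idx = selection.resolved_indices
    X = ensemble.coordinates[:, idx, :].reshape(ensemble.n_frames, -1)
    mean = X.mean(axis=0)
    D = X - mean
    if mass_weighted:
        w = np.sqrt(np.repeat(ensemble.topology.masses[idx], 3))
        D = D * w
    C = (D.T @ D) / ensemble.n_frames
    return CovarianceMatrix(C, mean.reshape(-1, 3), ensemble.n_frames, selection)


def eigendecompose(C: CovarianceMatrix, k: int | None = None) -> EigenDecomposition:
    """Top-``k`` principal modes of the covariance (all modes by default).

    Eigenvalues are sorted descending; each eigenvector's sign is fixed so its
    largest-magnitude component is positive, making results reproducible up to
    genuine degeneracy.
    """
    dim = C.matrix.shape[0]
    if k is None:
        k = dim
    if not 1 <= k <= dim:
        raise ValueError(f"k must be in [1, {dim}]")
    vals, vecs = linalg.eigh(C.matrix)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order][:k], vecs[:, order][:, :k]
    lead = np.abs(vecs).argmax(axis=0)
    signs = np.sign(vecs[lead, np.arange(k)])
    signs[signs == 0] = 1.0
    vecs = vecs * signs
    return EigenDecomposition(vals, vecs, C.trace)


def project(
    ensemble: TrajectoryEnsemble,
    selection: AtomSelection,
    decomposition: EigenDecomposition,
    mode: int,
    mean_structure: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame projection (Å) of the centered trajectory on one mode (0-based)."""
    if not 0 <= mode < decomposition.n_modes:
        raise ValueError(f"mode {mode} outside computed range [0, {decomposition.n_modes})")
    X = ensemble.coordinates[:, selection.resolved_indices, :].reshape(ensemble.n_frames, -1)
    if X.shape[1] != decomposition.eigenvectors.shape[0]:
        raise ValueError("selection does not match the decomposition's dimension")
    mu = X.mean(axis=0) if mean_structure is None else np.asarray(mean_structure).ravel()
    return (X - mu) @ decomposition.eigenvectors[:, mode]


def eigen_rmsf(
    ensemble: TrajectoryEnsemble,
    selection: AtomSelection,
    decomposition: EigenDecomposition,
    modes: Iterable[int],
) -> FluctuationProfile:
    """Per-residue RMSF of the trajectory reconstructed in a mode subspace.

    The centered trajectory is projected onto the chosen modes (0-based
    indices) and reconstructed there; with all 3N modes this equals the plain
    RMSF of the selection, with no modes it is zero.
    """
    modes = np.asarray(sorted(set(int(m) for m in modes)), dtype=int)
    if modes.size and (modes.min() < 0 or modes.max() >= decomposition.n_modes):
        raise ValueError("requested modes outside the computed range")
    idx = selection.resolved_indices
    resnums = ensemble.topology.residue_numbers[idx]
    residues = ensemble.topology.unique_residues
    residues = residues[np.isin(residues, resnums)]
    X = ensemble.coordinates[:, idx, :].reshape(ensemble.n_frames, -1)
    D = X - X.mean(axis=0)
    if modes.size:
        V = decomposition.eigenvectors[:, modes]
        recon = (D @ V) @ V.T
    else:
        recon = np.zeros_like(D)
    msf = (recon.reshape(ensemble.n_frames, -1, 3) ** 2).sum(axis=2).mean(axis=0)
    per_res = np.array([np.sqrt(msf[resnums == r].mean()) for r in residues])
    return FluctuationProfile(residues, per_res[None, :], per_res, np.zeros_like(per_res))
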