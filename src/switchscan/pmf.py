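"""Potential of mean force from constant-velocity pulling work traces.

Repeated steered-MD pullings record the spring force on the pulled atom; the
accumulated work per run, binned along the reaction coordinate (displacement
of the pulled atom projected on the pulling direction, 0.4 Å bins), enters the
second-order cumulant expansion of Jarzynski's equality

    F(z) − F(0) = ⟨W(z)⟩ − (⟨W(z)²⟩ − ⟨W(z)⟩²) / (2 kBT),

which is exact when the work distribution is Gaussian.  Runs that diverge
from the intended path are excluded before averaging; per-bin errors come from
block averaging over runs or bootstrap resampling of runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .thermo import ThermalParameters

__all__ = ["SMDTrace", "WorkSeries", "PMFProfile", "FilterReport",
           "read_smd_trace", "write_smd_trace", "work_accumulate",
           "filter_divergent", "pmf_cumulant", "pmf_error", "pmf_jarzynski"]


@dataclass
class SMDTrace:
    """One pulling run, projected on the pulling direction.

    ``projected_position`` is the pulled-atom displacement from its initial
    position (Å); ``projected_force`` is the spring force component along the
    pulling direction (kcal mol⁻¹ Å⁻¹).
    """

    time: np.ndarray                 # (T,) ps, strictly increasing
    projected_position: np.ndarray   # (T,) Å, starts at 0
    projected_force: np.ndarray      # (T,) kcal/mol/Å
    run_id: int = 0
    velocity: float = 0.03           # Å/ps
    spring_constant: float = 90.0    # kcal/mol/Å^2

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.projected_position = np.asarray(self.projected_position, dtype=float)
        self.projected_force = np.asarray(self.projected_force, dtype=float)
        if not (self.time.shape == self.projected_position.shape == self.projected_force.shape):
            raise ValueError("time/position/force must have equal length")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError(f"run {self.run_id}: time not strictly increasing")
        if self.velocity <= 0 or self.spring_constant <= 0:
            raise ValueError("velocity and spring_constant must be positive")

    @property
    def scheduled_position(self) -> np.ndarray:
        """Spring-anchor displacement v·(t − t0) (Å)."""
        return self.velocity * (self.time - self.time[0])

    @property
    def final_displacement(self) -> float:
        return float(self.projected_position[-1])


@dataclass
class WorkSeries:
    coordinate: np.ndarray    # (T,) Å — pulled-atom displacement
    work: np.ndarray          # (T,) kcal/mol cumulative, work[0] = 0
    run_id: int = 0


@dataclass
class PMFProfile:
    bin_centers: np.ndarray   # Å
    free_energy: np.ndarray   # kcal/mol, 0 at the first bin
    error: np.ndarray         # kcal/mol per bin
    n_runs_used: int
    n_runs_excluded: int = 0
    mean_work: np.ndarray | None = None


@dataclass
class FilterReport:
    retained: list[SMDTrace]
    excluded: list[SMDTrace]
    log: list[tuple[int, str]]   # (run_id, rule fired / 'retained')


# ---------------------------------------------------------------------------
# I/O

DEFAULT_COLUMNS = {"time": 0, "position": 1, "force": 2}


def read_smd_trace(
    path: str | Path,
    velocity: float = 0.03,
    spring_constant: float = 90.0,
    direction: np.ndarray | None = None,
    columns: dict[str, int | list[int]] | None = None,
    run_id: int = 0,
    time_unit: float = 1.0,
) -> SMDTrace:
    """Read a whitespace-delimited pulling log (NAMD-style).

    ``columns`` maps ``time``/``position``/``force`` to column indices; the
    position and force entries may be lists of three indices, in which case
    the 3-vectors are projected on ``direction``.  ``time_unit`` converts the
    file's time column to ps.  Positions are re-zeroed to the first sample.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS, **(columns or {}))
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                rows.append([float(x) for x in parts])
            except ValueError as exc:
                if not rows and ln == 1:
                    continue           # single leading header line
                raise ValueError(f"{path}:{ln}: non-numeric field: {exc}") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    width = min(len(r) for r in rows)

    def _col(key) -> np.ndarray:
        spec = cols[key]
        idx = [spec] if isinstance(spec, int) else list(spec)
        if max(idx) >= width:
            raise ValueError(f"{path}: column {max(idx)} for {key!r} missing "
                             f"(rows have {width} fields)")
        vals = np.array([[r[i] for i in idx] for r in rows], dtype=float)
        if len(idx) == 1:
            return vals[:, 0]
        if direction is None:
            raise ValueError(f"{key!r} given as 3-vector but no pulling direction supplied")
        u = np.asarray(direction, dtype=float)
        u = u / np.linalg.norm(u)
        return vals @ u

    t = _col("time") * time_unit
    pos = _col("position")
    force = _col("force")
    return SMDTrace(
        time=t,
        projected_position=pos - pos[0],
        projected_force=force,
        run_id=run_id,
        velocity=velocity,
        spring_constant=spring_constant,
    )


def write_smd_trace(trace: SMDTrace, path: str | Path) -> None:
    """Write the package's own TSV trace format (time_ps, pos_A, force_kcal_mol_A)."""
    arr = np.column_stack([trace.time, trace.projected_position, trace.projected_force])
    header = "time_ps\tpos_A\tforce_kcal_mol_A"
    np.savetxt(path, arr, delimiter="\t", header=header, comments="", fmt="%.10g")


# ---------------------------------------------------------------------------
# work and PMF


def work_accumulate(trace: SMDTrace) -> WorkSeries:
    """Cumulative work: trapezoidal integral of force against the schedule.

    The integration coordinate is the spring-anchor schedule v·t (the exact
    coordinate the external force acts along in constant-velocity pulling);
    the resulting work series is indexed by the pulled-atom displacement for
    binning.
    """
    if trace.time.size < 2:
        raise ValueError("need at least 2 samples to accumulate work")
    W = cumulative_trapezoid(trace.projected_force, trace.scheduled_position, initial=0.0)
    return WorkSeries(trace.projected_position.copy(), W, trace.run_id)


def _work_at_bins(traces: list[SMDTrace], centers: np.ndarray) -> np.ndarray:
    """(n_runs, n_bins) work of each run evaluated at the bin centers.

    The pulled atom fluctuates around the advancing anchor, so its displacement
    visits each bin many times; a run's work at a bin is the mean of its work
    samples recorded while the displacement lay in that bin.  (Taking the work
    at first passage instead would be systematically low by roughly
    force × fluctuation width, since first passage rides a favorable thermal
    kick.)  Bins a run never sampled are filled by linear interpolation from
    its sampled bins.
    """
    if centers.size == 0:
        raise ValueError("no bins")
    width = centers[1] - centers[0] if centers.size > 1 else 2 * centers[0]
    out = np.empty((len(traces), centers.size))
    for i, tr in enumerate(traces):
        ws = work_accumulate(tr)
        idx = np.floor(ws.coordinate / width).astype(int)
        in_range = (idx >= 0) & (idx < centers.size)
        sums = np.bincount(idx[in_range], weights=ws.work[in_range], minlength=centers.size)
        counts = np.bincount(idx[in_range], minlength=centers.size)
        filled = counts > 0
        if not filled.any():
            raise ValueError(f"run {tr.run_id} never sampled the binned range")
        vals = np.empty(centers.size)
        vals[filled] = sums[filled] / counts[filled]
        vals[~filled] = np.interp(centers[~filled], centers[filled], vals[filled])
        out[i] = vals
    return out


def filter_divergent(
    traces: list[SMDTrace],
    completion_fraction: float = 0.9,
    mad_k: float = 5.0,
    manual_exclude: set[int] | None = None,
) -> FilterReport:
    """Drop pulling runs that left the intended path.

    A run is excluded if (a) its final displacement is below
    ``completion_fraction`` of the largest scheduled pulling distance, or
    (b) its work at the last coordinate covered by all completing runs deviates
    from the ensemble median by more than ``mad_k``·MAD (with a small absolute
    floor so identical traces are never flagged).  Runs in ``manual_exclude``
    are dropped first.  Every decision is logged per run.
    """
    if len(traces) < 3:
        raise ValueError("need at least 3 traces for robust filtering")
    manual_exclude = manual_exclude or set()
    log: list[tuple[int, str]] = []
    retained: list[SMDTrace] = []
    excluded: list[SMDTrace] = []
    max_sched = max(tr.scheduled_position[-1] for tr in traces)
    stage: list[SMDTrace] = []
    for tr in traces:
        if tr.run_id in manual_exclude:
            excluded.append(tr)
            log.append((tr.run_id, "manual"))
        elif tr.final_displacement < completion_fraction * max_sched:
            excluded.append(tr)
            log.append((tr.run_id, "incomplete"))
        else:
            stage.append(tr)
    if len(stage) >= 3:
        last_common = min(tr.final_displacement for tr in stage)
        w_end = np.empty(len(stage))
        for i, tr in enumerate(stage):
            ws = work_accumulate(tr)
            near = ws.coordinate >= last_common - 0.4
            w_end[i] = ws.work[near].mean() if near.any() else ws.work[-1]
        med = np.median(w_end)
        mad = np.median(np.abs(w_end - med))
        floor = 1e-9 * max(1.0, abs(med))
        thresh = max(mad_k * mad, floor)
        for tr, w in zip(stage, w_end):
            if abs(w - med) > thresh:
                excluded.append(tr)
                log.append((tr.run_id, "work_outlier"))
            else:
                retained.append(tr)
                log.append((tr.run_id, "retained"))
    else:
        for tr in stage:
            retained.append(tr)
            log.append((tr.run_id, "retained"))
    if not retained:
        raise ValueError("all traces excluded; inspect the divergence criteria")
    return FilterReport(retained, excluded, log)


def _bins_for(traces: list[SMDTrace], bin_width: float) -> np.ndarray:
    """Bin centers on a grid anchored at 0 covering the common support."""
    support = min(tr.final_displacement for tr in traces)
    n_bins = int(np.floor(support / bin_width))
    if n_bins < 1:
        raise ValueError("no overlapping coordinate support at this bin width")
    return (np.arange(n_bins) + 0.5) * bin_width


def pmf_cumulant(
    traces: list[SMDTrace],
    bin_width: float = 0.4,
    thermal: ThermalParameters = ThermalParameters(),
    bin_centers: np.ndarray | None = None,
) -> PMFProfile:
    """Second-order cumulant PMF over the retained runs.

    Per bin (centers on a ``bin_width`` grid anchored at 0, spanning the
    coordinate range covered by every run), each run's cumulative work is
    linearly interpolated at the center; the estimate is
    ⟨W⟩ − Var(W)/(2 kBT) with population moments, referenced to zero at the
    first bin.
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 retained traces")
    centers = _bins_for(traces, bin_width) if bin_centers is None else np.asarray(bin_centers)
    W = _work_at_bins(traces, centers)        # (runs, bins)
    meanW = W.mean(axis=0)
    varW = W.var(axis=0)
    F = meanW - varW / (2.0 * thermal.kBT)
    F = F - F[0]
    return PMFProfile(
        bin_centers=centers,
        free_energy=F,
        error=np.zeros_like(F),
        n_runs_used=len(traces),
        mean_work=meanW - meanW[0],
    )


def pmf_jarzynski(
    traces: list[SMDTrace],
    bin_width: float = 0.4,
    thermal: ThermalParameters = ThermalParameters(),
    bin_centers: np.ndarray | None = None,
) -> PMFProfile:
    """Full exponential-average Jarzynski estimator (internal cross-check).

    F = −kBT ln⟨exp(−W/kBT)⟩ per bin; agrees with the cumulant when the work
    distribution is Gaussian, but is strongly biased at small run counts.
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 retained traces")
    centers = _bins_for(traces, bin_width) if bin_centers is None else np.asarray(bin_centers)
    W = _work_at_bins(traces, centers)
    beta = 1.0 / thermal.kBT
    # log-sum-exp for numerical stability
    a = (-beta * W).max(axis=0)
    F = -(a + np.log(np.exp(-beta * W - a).mean(axis=0))) / beta
    F = F - F[0]
    return PMFProfile(centers, F, np.zeros_like(F), len(traces))


def pmf_error(
    traces: list[SMDTrace],
    bin_width: float = 0.4,
    method: str = "bootstrap",
    n_boot: int = 1000,
    n_blocks: int = 5,
    seed: int | np.random.Generator = 0,
    thermal: ThermalParameters = ThermalParameters(),
) -> np.ndarray:
    """Per-bin error (kcal/mol) of the cumulant PMF across runs.

    ``block``: runs are partitioned into ``n_blocks`` groups, the PMF computed
    per group, and the standard error of the group estimates reported.
    ``bootstrap``: runs resampled with replacement ``n_boot`` times; the SD of
    the per-bin estimates is reported.  Deterministic for a fixed seed.
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 traces")
    centers = _bins_for(traces, bin_width)
    W = _work_at_bins(traces, centers)
    kBT = thermal.kBT

    def _estimate(block: np.ndarray) -> np.ndarray:
        F = block.mean(axis=0) - block.var(axis=0) / (2 * kBT)
        return F - F[0]

    if method == "block":
        if n_blocks > len(traces):
            raise ValueError(f"n_blocks={n_blocks} exceeds n_traces={len(traces)}")
        groups = np.array_split(np.arange(len(traces)), n_blocks)
        est = np.stack([_estimate(W[g]) for g in groups])
        return est.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    if method == "bootstrap":
        if n_boot < 2:
            warnings.warn("bootstrap with n_boot < 2 gives a degenerate zero SD")
            return np.zeros(centers.size)
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        idx = rng.integers(0, len(traces), size=(n_boot, len(traces)))
        est = np.stack([_estimate(W[i]) for i in idx])
        return est.std(axis=0, ddof=1)
    raise ValueError(f"unknown error method {method!r}")
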