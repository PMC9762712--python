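"""Switch I/II conformational-state classification from atom-pair distances.

Switch I (residues 30–38) is scored by the Cα(G/D12)–Cα(P34) distance:
closed below 8 Å, open above 16 Å, partially open between (boundaries
inclusive to partially open).  Switch II (59–76) is scored by the
HN(G60)–Pγ(GTP) distance: open strictly above 11 Å, closed otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core_io import TrajectoryEnsemble
from .descriptors import atom_pair_distance

__all__ = ["Switch1State", "Switch2State", "StateThresholds", "SwitchStateLabel",
           "classify_switch1", "classify_switch2", "classify_ensemble",
           "most_probable_conformation", "CLUSTER_STATE_PRESET"]


class Switch1State(str, Enum):
    CLOSED = "closed"
    PARTIALLY_OPEN = "partially_open"
    OPEN = "open"


class Switch2State(str, Enum):
    CLOSED = "closed"
    OPEN = "open"


@dataclass(frozen=True)
class StateThresholds:
    """Distance thresholds (Å) for the switch-state rules."""

    switch1_closed_max: float = 8.0
    switch1_open_min: float = 16.0
    switch2_open_min: float = 11.0

    def __post_init__(self) -> None:
        if not (0 < self.switch1_closed_max < self.switch1_open_min):
            raise ValueError("need 0 < switch1_closed_max < switch1_open_min")
        if self.switch2_open_min <= 0:
            raise ValueError("switch2_open_min must be positive")


@dataclass(frozen=True)
class SwitchStateLabel:
    switch1: Switch1State
    switch2: Switch2State

    def __str__(self) -> str:
        return f"({self.switch1.value}, {self.switch2.value})"


#: Distance ranges (Å) of the three clustered sub-states of the
#: T35(Oγ)–GTP(Pγ) and G60(HN)–GTP(Pγ) coordinates.  Descriptive preset used
#: for picking target conformations; not part of the classification rules.
CLUSTER_STATE_PRESET = {
    "T35_OG1-GTP_PG": {"state1": (3.0, 5.0), "state2": (6.0, 9.0), "state3": (12.0, 16.0)},
    "G60_HN-GTP_PG": {"state1": (5.0, 7.0), "state2": (2.0, 4.0), "state3": (8.0, 9.0)},
}


def _check_distance(d: float) -> float:
    d = float(d)
    if not np.isfinite(d) or d <= 0:
        raise ValueError(f"distance must be positive and finite, got {d}")
    return d


def classify_switch1(d: float, thresholds: StateThresholds = StateThresholds()) -> Switch1State:
    """Label Switch I from the Cα(12)–Cα(34) distance in Å."""
    d = _check_distance(d)
    if d < thresholds.switch1_closed_max:
        return Switch1State.CLOSED
    if d > thresholds.switch1_open_min:
        return Switch1State.OPEN
    return Switch1State.PARTIALLY_OPEN


def classify_switch2(d: float, thresholds: StateThresholds = StateThresholds()) -> Switch2State:
    """Label Switch II from the HN(60)–Pγ(GTP) distance in Å (11 Å is closed)."""
    d = _check_distance(d)
    return Switch2State.OPEN if d > thresholds.switch2_open_min else Switch2State.CLOSED


def classify_ensemble(
    ensemble: TrajectoryEnsemble,
    pair1: tuple[str, str] = ("12:CA", "34:CA"),
    pair2: tuple[str, str] = ("60:HN", "GTP:PG"),
    thresholds: StateThresholds = StateThresholds(),
) -> tuple[list[SwitchStateLabel], dict[SwitchStateLabel, float]]:
    """Per-frame joint labels plus joint-state occupancy fractions.

    Occupancies sum to 1 over the observed joint states.
    """
    d1 = atom_pair_distance(ensemble, *pair1).distance
    d2 = atom_pair_distance(ensemble, *pair2).distance
    labels = [
        SwitchStateLabel(classify_switch1(a, thresholds), classify_switch2(b, thresholds))
        for a, b in zip(d1, d2)
    ]
    occupancy: dict[SwitchStateLabel, float] = {}
    for lab in labels:
        occupancy[lab] = occupancy.get(lab, 0.0) + 1.0
    for lab in occupancy:
        occupancy[lab] /= len(labels)
    return labels, occupancy


def most_probable_conformation(
    ensemble: TrajectoryEnsemble,
    coord_a: tuple[str, str] = ("T35:OG1", "GTP:PG"),
    coord_b: tuple[str, str] = ("60:HN", "GTP:PG"),
    bin_width: float = 1.0,
) -> tuple[int, tuple[float, float]]:
    """Locate the modal conformation on a 2-D distance histogram.

    Bins the two atom-pair distance series on a grid of ``bin_width`` anchored
    at 0, finds the most populated 2-D bin (ties broken by lexicographically
    smallest bin index) and returns ``(frame_index, (center_a, center_b))``
    where the frame is the one closest to the modal bin's center in the
    two-distance plane (ties → lowest frame index).
    """
    if ensemble.n_frames == 0:
        raise ValueError("empty ensemble")
    da = atom_pair_distance(ensemble, *coord_a).distance
    db = atom_pair_distance(ensemble, *coord_b).distance
    ia = np.floor(da / bin_width).astype(int)
    ib = np.floor(db / bin_width).astype(int)
    pairs, counts = np.unique(np.stack([ia, ib], axis=1), axis=0, return_counts=True)
    best = pairs[counts == counts.max()]
    modal = best[np.lexsort((best[:, 1], best[:, 0]))][0]
    center = ((modal[0] + 0.5) * bin_width, (modal[1] + 0.5) * bin_width)
    dist2 = (da - center[0]) ** 2 + (db - center[1]) ** 2
    return int(np.argmin(dist2)), center
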