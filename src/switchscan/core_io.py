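"""Structure/trajectory I/O, atom selection and rigid-body superposition.

Containers are thin NumPy-backed records; parsing and writing of the standard
formats (PDB, DCD, XTC, multi-model PDB) is delegated to MDAnalysis.  Residue
numbering is always taken verbatim from the input file (1-based PDB numbering),
so residues of interest (12, 32, 34, 35, 60, 61 in the 5P21 numbering of HRAS)
are addressed by their printed residue number, never by sequence index.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda
    from MDAnalysis.analysis.align import rotation_matrix

__all__ = [
    "StructureModel",
    "TrajectoryEnsemble",
    "AtomSelection",
    "FormatError",
    "SelectionError",
    "AlignmentError",
    "TopologyError",
    "load_structure",
    "load_trajectory",
    "superpose",
    "select",
    "resolve_atom",
    "write_structure",
    "write_trajectory",
]

# water residue names across common force-field dialects
WATER_RESNAMES = {"HOH", "TIP3", "TIP3P", "SOL", "WAT", "SPC", "T3P"}
BACKBONE_NAMES = {"N", "CA", "C", "O"}

# atom-name dialect mapping: canonical name -> accepted synonyms
ATOM_NAME_SYNONYMS: dict[str, tuple[str, ...]] = {
    "OH": ("OH",),          # Tyr side-chain oxygen
    "HN": ("HN", "H"),      # backbone amide proton
    "PG": ("PG", "P3"),     # GTP gamma-phosphate
    "OG1": ("OG1", "OG"),   # Thr side-chain oxygen
    "OE1": ("OE1",),        # Gln side-chain oxygen
}


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in its declared format."""


class SelectionError(ValueError):
    """Raised when a selection expression or atom spec resolves to nothing."""


class AlignmentError(ValueError):
    """Raised when superposition preconditions are not met."""


class TopologyError(ValueError):
    """Raised on atom-count mismatch between trajectory and topology."""


@dataclass
class StructureModel:
    """A molecular structure as parallel per-atom arrays.

    Atom indices are 0-based and contiguous; ``residue_numbers`` keep the
    numbering printed in the source PDB.
    """

    atom_names: np.ndarray          # (n,) str
    residue_numbers: np.ndarray     # (n,) int, 1-based as printed
    residue_names: np.ndarray       # (n,) str
    chain_ids: np.ndarray           # (n,) str
    coordinates: np.ndarray         # (n, 3) float, Å
    masses: np.ndarray | None = None  # (n,) float, amu

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        n = self.n_atoms
        for name in ("atom_names", "residue_numbers", "residue_names", "chain_ids"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != n_atoms {n}")
            setattr(self, name, arr)
        if self.masses is None:
            self.masses = np.ones(n, dtype=float)
        else:
            self.masses = np.asarray(self.masses, dtype=float)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    @property
    def unique_residues(self) -> np.ndarray:
        """Residue numbers in order of first appearance."""
        _, idx = np.unique(self.residue_numbers, return_index=True)
        return self.residue_numbers[np.sort(idx)]

    def select(self, expression: str) -> "AtomSelection":
        return select(self, expression)


@dataclass
class TrajectoryEnsemble:
    """Frames × atoms × 3 coordinates with per-frame replicate provenance."""

    coordinates: np.ndarray         # (F, n, 3) Å
    topology: StructureModel
    frame_times: np.ndarray         # (F,) ps, strictly increasing per replicate
    replicate_ids: np.ndarray       # (F,) int
    aligned: bool = False

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must be (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"frames have {self.coordinates.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}"
            )
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.replicate_ids = np.asarray(self.replicate_ids, dtype=int)
        if self.frame_times.shape[0] != self.n_frames:
            raise ValueError("frame_times length mismatch")
        if self.replicate_ids.shape[0] != self.n_frames:
            raise ValueError("replicate_ids length mismatch")
        for rep in np.unique(self.replicate_ids):
            t = self.frame_times[self.replicate_ids == rep]
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"frame_times not strictly increasing in replicate {rep}")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def replicates(self) -> np.ndarray:
        return np.unique(self.replicate_ids)

    def frames_of(self, replicate_id: int) -> np.ndarray:
        """Coordinate block (f, n, 3) of one replicate."""
        return self.coordinates[self.replicate_ids == replicate_id]


@dataclass
class AtomSelection:
    """A resolved selection: the expression plus the 0-based atom indices."""

    expression: str
    resolved_indices: np.ndarray

    def __post_init__(self) -> None:
        self.resolved_indices = np.asarray(self.resolved_indices, dtype=int)

    def __len__(self) -> int:
        return self.resolved_indices.size

    def require_nonempty(self) -> None:
        if len(self) == 0:
            raise SelectionError(f"selection {self.expression!r} resolved to no atoms")


# ---------------------------------------------------------------------------
# selection mini-language


def _parse_int_list(tokens: Sequence[str]) -> np.ndarray:
    out: list[int] = []
    for tok in tokens:
        m = re.fullmatch(r"(-?\d+)[-:](-?\d+)", tok)
        if m:
            lo, hi = int(m.group(1)), int(m.group(2))
            out.extend(range(lo, hi + 1))
        else:
            out.append(int(tok))
    return np.array(out, dtype=int)


def select(structure: StructureModel, expression: str) -> AtomSelection:
    """Resolve a selection expression against a structure.

    The language is a conjunction of terms joined by ``and``; each term is one
    of ``all``, ``backbone``, ``water``, ``protein``, ``not <term>``, or a
    keyword with arguments: ``name CA OH``, ``resid 30-38 60``,
    ``resname GTP``, ``chain A``.
    """
    n = structure.n_atoms
    mask = np.ones(n, dtype=bool)
    clauses = [c.strip() for c in re.split(r"\band\b", expression) if c.strip()]
    if not clauses:
        raise SelectionError(f"empty selection expression {expression!r}")
    for clause in clauses:
        negate = False
        toks = clause.split()
        if toks[0] == "not":
            negate = True
            toks = toks[1:]
            if not toks:
                raise SelectionError(f"dangling 'not' in {expression!r}")
        key, args = toks[0], toks[1:]
        if key == "all":
            m = np.ones(n, dtype=bool)
        elif key == "backbone":
            m = np.isin(structure.atom_names, sorted(BACKBONE_NAMES))
        elif key == "water":
            m = np.isin(structure.residue_names, sorted(WATER_RESNAMES))
        elif key == "protein":
            m = ~np.isin(structure.residue_names, sorted(WATER_RESNAMES | {"GTP", "GNP", "MG", "NA", "CL", "LIG"}))
        elif key == "name":
            accepted: set[str] = set()
            for a in args:
                accepted.update(ATOM_NAME_SYNONYMS.get(a, (a,)))
            m = np.isin(structure.atom_names, sorted(accepted))
        elif key == "resid":
            m = np.isin(structure.residue_numbers, _parse_int_list(args))
        elif key == "resname":
            m = np.isin(structure.residue_names, args)
        elif key == "chain":
            m = np.isin(structure.chain_ids, args)
        else:
            raise SelectionError(f"unknown selection keyword {key!r} in {expression!r}")
        mask &= ~m if negate else m
    return AtomSelection(expression=expression, resolved_indices=np.flatnonzero(mask))


ATOM_SPEC_RE = re.compile(r"^([A-Za-z0-9]+):([A-Za-z0-9']+)$")


def resolve_atom(structure: StructureModel, spec: str) -> int:
    """Resolve an atom spec like ``12:CA`` (resid:name) or ``GTP:PG`` (resname:name).

    Returns the 0-based atom index; raises :class:`SelectionError` if the spec
    matches no atom or more than one.
    """
    m = ATOM_SPEC_RE.match(spec.strip())
    if not m:
        raise SelectionError(f"bad atom spec {spec!r}; expected 'resid:NAME' or 'RESNAME:NAME'")
    res, name = m.groups()
    names = ATOM_NAME_SYNONYMS.get(name.upper(), (name,))
    name_mask = np.isin(structure.atom_names, names)
    if res.lstrip("-").isdigit():
        res_mask = structure.residue_numbers == int(res)
    else:
        res_mask = structure.residue_names == res
    hits = np.flatnonzero(name_mask & res_mask)
    if hits.size == 0:
        raise SelectionError(f"atom {spec!r} not found")
    if hits.size > 1:
        raise SelectionError(f"atom {spec!r} is ambiguous ({hits.size} matches); add a chain-unique residue")
    return int(hits[0])


# ---------------------------------------------------------------------------
# file I/O


def _structure_from_universe(u: "mda.Universe") -> StructureModel:
    ag = u.atoms
    if len(ag) == 0:
        raise FormatError("structure contains zero atoms")

    def _attr(name, default):
        try:
            return np.asarray(getattr(ag, name)).astype(str)
        except (AttributeError, mda.exceptions.NoDataError):
            return np.full(len(ag), default, dtype=object).astype(str)

    try:
        masses = np.asarray(ag.masses, dtype=float)
    except (AttributeError, mda.exceptions.NoDataError):
        masses = np.ones(len(ag), dtype=float)
    chains = _attr("chainIDs", "A")
    chains[chains == ""] = "A"
    return StructureModel(
        atom_names=np.asarray(ag.names).astype(str),
        residue_numbers=np.asarray(ag.resids, dtype=int),
        residue_names=np.asarray(ag.resnames).astype(str),
        chain_ids=chains,
        coordinates=np.asarray(ag.positions, dtype=float),
        masses=masses,
    )


def load_structure(path: str | Path) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Every ATOM/HETATM record becomes one atom, re-indexed 0..n-1 regardless of
    the serial numbers printed in the file; residue numbering is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # MDAnalysis raises a zoo of types here
        raise FormatError(f"cannot parse {path} as PDB: {exc}") from exc
    return _structure_from_universe(u)


def _read_frames(path: Path, n_atoms: int) -> tuple[np.ndarray, np.ndarray]:
    """Read one coordinate file; returns (coords (f,n,3), times ps)."""
    u = mda.Universe.empty(n_atoms, trajectory=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.load_new(str(path))
            coords, times = [], []
            for ts in u.trajectory:
                coords.append(ts.positions.astype(float).copy())
                times.append(float(ts.time))
    except ValueError as exc:
        if "atoms" in str(exc):
            raise TopologyError(f"{path}: {exc}") from exc
        raise
    except (EOFError, OSError) as exc:
        raise IOError(f"truncated or unreadable trajectory {path}: {exc}") from exc
    arr = np.asarray(coords)
    t = np.asarray(times, dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        # format carried no usable time header; fall back to a uniform stride
        t = np.arange(arr.shape[0], dtype=float)
    return arr, t


def load_trajectory(
    paths: str | Path | Sequence[str | Path],
    topology: StructureModel,
) -> TrajectoryEnsemble:
    """Load one or more coordinate files (DCD/XTC/multi-model PDB).

    Each file becomes one replicate; replicate_ids follow the order given.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    coords, times, reps = [], [], []
    for rep, p in enumerate(paths):
        c, t = _read_frames(Path(p), topology.n_atoms)
        if c.shape[1] != topology.n_atoms:
            raise TopologyError(
                f"{p}: {c.shape[1]} atoms per frame, topology has {topology.n_atoms}"
            )
        coords.append(c)
        times.append(t)
        reps.append(np.full(c.shape[0], rep, dtype=int))
    return TrajectoryEnsemble(
        coordinates=np.concatenate(coords, axis=0),
        topology=topology,
        frame_times=np.concatenate(times),
        replicate_ids=np.concatenate(reps),
        aligned=False,
    )


def _universe_from_structure(structure: StructureModel) -> "mda.Universe":
    resnums = structure.residue_numbers
    # map consecutive (resid, resname) runs to residue indices
    boundaries = np.flatnonzero(np.diff(resnums) != 0)
    starts = np.concatenate([[0], boundaries + 1])
    resindex = np.zeros(structure.n_atoms, dtype=int)
    for i, s in enumerate(starts):
        e = starts[i + 1] if i + 1 < len(starts) else structure.n_atoms
        resindex[s:e] = i
    u = mda.Universe.empty(
        structure.n_atoms,
        n_residues=len(starts),
        atom_resindex=resindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", list(structure.atom_names))
    u.add_TopologyAttr("resids", [int(resnums[s]) for s in starts])
    u.add_TopologyAttr("resnames", [str(structure.residue_names[s]) for s in starts])
    u.add_TopologyAttr("chainIDs", list(structure.chain_ids))
    u.atoms.positions = structure.coordinates
    return u


def write_structure(structure: StructureModel, path: str | Path) -> None:
    """Write a structure to a single-model PDB file."""
    u = _universe_from_structure(structure)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path)) as w:
            w.write(u.atoms)


def write_trajectory(ensemble: TrajectoryEnsemble, path: str | Path) -> None:
    """Write all frames of an ensemble to DCD/XTC/multi-model PDB (by suffix)."""
    u = _universe_from_structure(ensemble.topology)
    u.load_new(ensemble.coordinates.astype(np.float32), order="fac")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), ensemble.n_atoms, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# superposition


def superpose(
    ensemble: TrajectoryEnsemble,
    selection: AtomSelection,
    reference: StructureModel | None = None,
) -> TrajectoryEnsemble:
    """Least-squares rigid-body fit of every frame onto a fixed reference.

    The fit (Kabsch) minimises the RMSD of ``selection`` atoms to the
    reference; the resulting rotation+translation is applied to all atoms of
    the frame.  The default reference is the first frame of the ensemble.
    """
    selection.require_nonempty()
    idx = selection.resolved_indices
    if idx.size < 3:
        raise AlignmentError("superposition needs at least 3 selected atoms")
    ref_coords = (reference.coordinates if reference is not None
                  else ensemble.coordinates[0])[idx]
    # collinearity check: rank of centered reference must be >= 2
    centered = ref_coords - ref_coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise AlignmentError("selection atoms are collinear; fit is degenerate")
    ref_com = ref_coords.mean(axis=0)
    out = np.empty_like(ensemble.coordinates)
    for f in range(ensemble.n_frames):
        frame = ensemble.coordinates[f]
        mob = frame[idx]
        mob_com = mob.mean(axis=0)
        R, _ = rotation_matrix(mob - mob_com, ref_coords - ref_com)
        out[f] = (frame - mob_com) @ R.T + ref_com
    return replace(ensemble, coordinates=out, aligned=True)
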