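"""RMSF, distances, dihedrals, density histograms and hydration counts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from switchscan.core_io import SelectionError, StructureModel, TrajectoryEnsemble, select
from switchscan.descriptors import (
    atom_pair_distance,
    density_histogram,
    dihedral_series,
    hydration_count,
    rmsf,
    rmsf_delta,
)


def _structure(names, resids, resnames=None, coords=None):
    n = len(names)
    return StructureModel(
        atom_names=np.array(names),
        residue_numbers=np.array(resids),
        residue_names=np.array(resnames if resnames else ["ALA"] * n),
        chain_ids=np.array(["A"] * n),
        coordinates=np.zeros((n, 3)) if coords is None else np.asarray(coords, float),
    )


def _ensemble(coords, top, aligned=True, replicate_ids=None):
    coords = np.asarray(coords, dtype=float)
    reps = (np.zeros(len(coords), dtype=int) if replicate_ids is None
            else np.asarray(replicate_ids))
    times = np.empty(len(coords))
    for r in np.unique(reps):
        times[reps == r] = np.arange((reps == r).sum(), dtype=float)
    return TrajectoryEnsemble(coords, top, times, reps, aligned=aligned)


class TestRmsf:
    def test_constant_trajectory_is_zero(self):
        top = _structure(["CA", "CA"], [1, 2])
        ens = _ensemble(np.zeros((5, 2, 3)), top)
        prof = rmsf(ens, select(top, "all"))
        np.testing.assert_array_equal(prof.mean_rmsf, 0.0)

    def test_two_frame_hand_value(self):
        # one atom at x = 0 and x = 2 Å: deviations ±1 Å, RMSF = 1 Å
        top = _structure(["CA"], [1])
        coords = np.zeros((2, 1, 3))
        coords[1, 0, 0] = 2.0
        prof = rmsf(_ensemble(coords, top), select(top, "all"))
        assert prof.value(1) == (1.0, 0.0)

    def test_unaligned_rejected(self):
        top = _structure(["CA"], [1])
        ens = _ensemble(np.zeros((3, 1, 3)), top, aligned=False)
        with pytest.raises(ValueError, match="superposed"):
            rmsf(ens, select(top, "all"))

    def test_matches_prescribed_variance_of_gaussian_ensemble(self, rng):
        # isotropic Gaussian displacements of known per-residue sigma:
        # E[RMSF] = sigma * sqrt(3)
        sigmas = np.array([0.5, 1.0, 2.0])
        top = _structure(["CA"] * 3, [1, 2, 3])
        n_rep, n_frames = 4, 2000
        coords = rng.normal(size=(n_rep * n_frames, 3, 3)) * sigmas[None, :, None]
        reps = np.repeat(np.arange(n_rep), n_frames)
        prof = rmsf(_ensemble(coords, top, replicate_ids=reps), select(top, "all"))
        expected = sigmas * np.sqrt(3)
        assert np.all(np.abs(prof.mean_rmsf - expected) < 3 * np.maximum(prof.se_rmsf, 1e-3))

    def test_delta_self_and_arithmetic(self):
        top = _structure(["CA"], [1])
        coords = np.zeros((2, 1, 3))
        coords[1, 0, 0] = 2.0
        prof = rmsf(_ensemble(coords, top), select(top, "all"))
        _, d, agg = rmsf_delta(prof, prof)
        assert d[0] == 0.0 and agg == 0.0

    def test_delta_residue_mismatch_reports_difference(self):
        top1 = _structure(["CA"], [1])
        top2 = _structure(["CA"], [2])
        e1 = _ensemble(np.zeros((2, 1, 3)), top1)
        e2 = _ensemble(np.zeros((2, 1, 3)), top2)
        p1, p2 = rmsf(e1, select(top1, "all")), rmsf(e2, select(top2, "all"))
        with pytest.raises(ValueError, match="differ"):
            rmsf_delta(p1, p2)


class TestDistances:
    def test_three_four_five(self):
        top = _structure(["CA", "CA"], [1, 2])
        coords = np.zeros((3, 2, 3))
        coords[:, 1] = [3.0, 4.0, 0.0]
        series = atom_pair_distance(_ensemble(coords, top), "1:CA", "2:CA")
        np.testing.assert_allclose(series.distance, 5.0)

    def test_identical_atom_guard(self):
        top = _structure(["CA"], [1])
        ens = _ensemble(np.zeros((2, 1, 3)), top)
        with pytest.raises(SelectionError):
            atom_pair_distance(ens, "1:CA", "1:CA")
        series = atom_pair_distance(ens, "1:CA", "1:CA", allow_identical=True)
        np.testing.assert_array_equal(series.distance, 0.0)

    def test_gaussian_pair_mean_recovered(self, rng):
        top = _structure(["CA", "CA"], [1, 2])
        d = rng.normal(10.0, 1.0, size=100)
        coords = np.zeros((100, 2, 3))
        coords[:, 1, 0] = d
        series = atom_pair_distance(_ensemble(coords, top), "1:CA", "2:CA")
        assert abs(series.mean - 10.0) < 0.4


class TestDihedrals:
    @staticmethod
    def _frame(angle_deg):
        """Four atoms with the given dihedral about the central z-axis bond."""
        a = np.radians(angle_deg)
        return np.array([
            [1.0, 0.0, 0.0],
            [0.0, 0.0, 0.0],
            [0.0, 0.0, 1.5],
            [np.cos(a), np.sin(a), 1.5],
        ])

    @pytest.mark.parametrize("angle", [0.0, 73.0, 180.0, -120.0])
    def test_constructed_angles(self, angle):
        top = _structure(["N", "CA", "CB", "CG"], [1] * 4)
        ens = _ensemble(self._frame(angle)[None], top)
        out = dihedral_series(ens, ("1:N", "1:CA", "1:CB", "1:CG"))
        assert abs(out[0] - (180.0 if angle == -180.0 else angle)) < 1e-6

    def test_range_convention_excludes_minus_180(self):
        top = _structure(["N", "CA", "CB", "CG"], [1] * 4)
        ens = _ensemble(self._frame(180.0)[None], top)
        assert dihedral_series(ens, ("1:N", "1:CA", "1:CB", "1:CG"))[0] == 180.0

    def test_collinear_triple_names_frame(self):
        top = _structure(["N", "CA", "CB", "CG"], [1] * 4)
        frame = self._frame(30.0)
        frame[0] = [0.0, 0.0, -1.0]   # N-CA-CB collinear along z
        ens = _ensemble(frame[None], top)
        with pytest.raises(ValueError, match="frame 0"):
            dihedral_series(ens, ("1:N", "1:CA", "1:CB", "1:CG"))


class TestDensityHistogram:
    def test_identical_values_single_bin(self):
        h = density_histogram(np.full(50, 4.2), bin_width=1.0)
        assert h.integral == pytest.approx(1.0, abs=1e-12)
        assert h.density.max() == pytest.approx(1.0)

    def test_uniform_samples(self, rng):
        h = density_histogram(rng.uniform(0, 10, size=1000), bin_width=1.0,
                              value_range=(0.0, 10.0))
        assert np.all(np.abs(h.density - 0.1) < 0.03)

    def test_angular_wrap_and_anchoring(self):
        h = density_histogram(np.array([-179.0, 179.0, 90.0]), bin_width=20.0,
                              angular=True)
        assert h.bin_edges[0] == -180.0 and h.bin_edges[-1] == 180.0
        assert h.bin_edges.size == 19
        assert h.integral == pytest.approx(1.0, abs=1e-9)

    def test_empty_and_bad_width_rejected(self):
        with pytest.raises(ValueError):
            density_histogram(np.array([]), 1.0)
        with pytest.raises(ValueError):
            density_histogram(np.array([1.0]), 0.0)

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=200),
           st.floats(0.1, 5.0))
    @settings(max_examples=60, deadline=None)
    def test_normalization_property(self, values, width):
        h = density_histogram(np.array(values), bin_width=width)
        assert abs(h.integral - 1.0) < 1e-9
        assert np.all(h.density >= 0)


class TestHydration:
    @staticmethod
    def _system(radii):
        n = len(radii)
        names = ["C1"] + ["O"] * n
        resids = list(range(1, n + 2))
        resnames = ["LIG"] + ["HOH"] * n
        coords = np.zeros((n + 1, 3))
        for i, r in enumerate(radii):
            coords[i + 1] = [r, 0.0, 0.0]
        top = _structure(names, resids, resnames, coords)
        return top, _ensemble(coords[None], top)

    def test_threshold_construction(self):
        top, ens = self._system([4.9, 4.9, 4.9, 5.1, 5.1])
        out = hydration_count(ens, select(top, "resname LIG"),
                              select(top, "water"), cutoff=5.0)
        assert out.counts[0] == 3

    def test_boundary_exactly_at_cutoff_excluded(self):
        top, ens = self._system([5.0])
        out = hydration_count(ens, select(top, "resname LIG"),
                              select(top, "water"), cutoff=5.0)
        assert out.counts[0] == 0

    def test_no_waters_in_range(self):
        top, ens = self._system([8.0, 9.0])
        out = hydration_count(ens, select(top, "resname LIG"),
                              select(top, "water"), cutoff=5.0)
        assert out.mean_count == 0.0 and out.se_count == 0.0

    def test_monotone_in_cutoff(self, rng):
        radii = rng.uniform(2.0, 12.0, size=30)
        top, ens = self._system(list(radii))
        counts = [
            hydration_count(ens, select(top, "resname LIG"),
                            select(top, "water"), cutoff=c).counts[0]
            for c in (3.0, 5.0, 7.0, 9.0, 13.0)
        ]
        assert counts == sorted(counts)
        assert counts[-1] == 30

    def test_molecules_not_atoms(self):
        # two atoms of the same water inside the cutoff count once
        top = _structure(["C1", "O", "H1"], [1, 2, 2], ["LIG", "HOH", "HOH"],
                         [[0, 0, 0], [3, 0, 0], [3.5, 0, 0]])
        ens = _ensemble(top.coordinates[None], top)
        out = hydration_count(ens, select(top, "resname LIG"),
                              select(top, "water"), cutoff=5.0)
        assert out.counts[0] == 1
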