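"""Work accumulation, divergent-run filtering and the cumulant PMF."""

import numpy as np
import pytest

from switchscan.pmf import (
    SMDTrace,
    _work_at_bins,
    filter_divergent,
    pmf_cumulant,
    pmf_error,
    pmf_jarzynski,
    read_smd_trace,
    work_accumulate,
    write_smd_trace,
)
from switchscan.thermo import ThermalParameters


def _trace(force_fn, run_id=0, v=0.03, k=90.0, t_end=100.0, dt=0.024,
           lag=0.0):
    """Deterministic trace: atom tracks the schedule with optional lag."""
    t = np.arange(0.0, t_end + dt / 2, dt)
    sched = v * t
    pos = np.maximum(sched - lag, 0.0)
    force = force_fn(sched)
    return SMDTrace(t, pos, force, run_id=run_id, velocity=v, spring_constant=k)


def _linear_work_traces(slopes, **kw):
    """Work grows linearly with the coordinate: W_r(z) = slope_r * z."""
    return [_trace(lambda s, c=c: np.full_like(s, c), run_id=i, **kw)
            for i, c in enumerate(slopes)]


class TestReadWrite:
    def test_two_row_minimal_file(self, tmp_path):
        p = tmp_path / "r.txt"
        p.write_text("0.0 0.0 0.0\n0.024 0.001 5.0\n")
        tr = read_smd_trace(p)
        assert tr.time.size == 2
        assert tr.projected_position[0] == 0.0
        assert tr.projected_force[1] == 5.0

    def test_round_trip_identical(self, tmp_path):
        tr = _trace(lambda s: 2.0 + 0.1 * s, t_end=10.0)
        p = tmp_path / "t.tsv"
        write_smd_trace(tr, p)
        back = read_smd_trace(p)
        np.testing.assert_allclose(back.time, tr.time, atol=1e-9)
        np.testing.assert_allclose(back.projected_position, tr.projected_position, atol=1e-9)
        np.testing.assert_allclose(back.projected_force, tr.projected_force, atol=1e-9)

    def test_vector_force_projected_on_direction(self, tmp_path):
        p = tmp_path / "v.txt"
        p.write_text("0.0 0.0 1.0 2.0 3.0\n1.0 0.5 4.0 5.0 6.0\n")
        tr = read_smd_trace(p, direction=np.array([0.0, 0.0, 1.0]),
                            columns={"time": 0, "position": 1, "force": [2, 3, 4]})
        np.testing.assert_allclose(tr.projected_force, [3.0, 6.0])

    def test_non_monotone_time_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0.0 0 0\n2.0 0 0\n1.0 0 0\n")
        with pytest.raises(ValueError, match="increasing"):
            read_smd_trace(p)

    def test_missing_column_reports_location(self, tmp_path):
        p = tmp_path / "short.txt"
        p.write_text("0.0 0.0\n1.0 0.5\n")
        with pytest.raises(ValueError, match="force"):
            read_smd_trace(p)


class TestWorkAccumulate:
    def test_zero_force_zero_work(self):
        ws = work_accumulate(_trace(lambda s: np.zeros_like(s)))
        np.testing.assert_array_equal(ws.work, 0.0)
        assert ws.work[0] == 0.0

    def test_constant_force_rectangle(self):
        # F = 2 kcal/mol/Å over 10 Å of scheduled pulling -> W_end = 20
        tr = _trace(lambda s: np.full_like(s, 2.0), v=0.1, t_end=100.0)
        ws = work_accumulate(tr)
        D = tr.scheduled_position[-1]      # ~10 Å of scheduled pulling
        assert D == pytest.approx(10.0, abs=0.01)
        assert ws.work[-1] == pytest.approx(2.0 * D, rel=1e-10)

    def test_linear_ramp_closed_form(self):
        # F = c * s: trapezoid is exact for linear integrands
        c = 0.7
        tr = _trace(lambda s: c * s, v=0.05, t_end=200.0)
        ws = work_accumulate(tr)
        D = tr.scheduled_position[-1]
        assert ws.work[-1] == pytest.approx(c * D ** 2 / 2, rel=1e-10)

    def test_single_sample_rejected(self):
        tr = SMDTrace(np.array([0.0]), np.array([0.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            work_accumulate(tr)


class TestFilterDivergent:
    def test_identical_traces_none_excluded(self):
        traces = _linear_work_traces([2.0] * 10)
        rep = filter_divergent(traces)
        assert len(rep.retained) == 10 and not rep.excluded

    def test_inflated_work_outlier_excluded(self, rng):
        slopes = list(2.0 + 0.05 * rng.standard_normal(9)) + [20.0]
        rep = filter_divergent(_linear_work_traces(slopes))
        assert [tr.run_id for tr in rep.excluded] == [9]
        assert ("work_outlier" in dict(rep.log)[9])

    def test_truncated_run_excluded(self):
        traces = _linear_work_traces([2.0] * 9)
        traces.append(_trace(lambda s: np.full_like(s, 2.0), run_id=9, t_end=50.0))
        rep = filter_divergent(traces)
        assert [tr.run_id for tr in rep.excluded] == [9]
        assert dict(rep.log)[9] == "incomplete"

    def test_manual_exclusion_honored(self):
        rep = filter_divergent(_linear_work_traces([2.0] * 5), manual_exclude={2})
        assert [tr.run_id for tr in rep.excluded] == [2]

    def test_all_excluded_raises(self):
        traces = _linear_work_traces([2.0] * 3)
        with pytest.raises(ValueError):
            filter_divergent(traces, manual_exclude={0, 1, 2})

    def test_too_few_traces_rejected(self):
        with pytest.raises(ValueError):
            filter_divergent(_linear_work_traces([2.0, 2.0]))


class TestPmfCumulant:
    def test_identical_traces_equal_binned_work(self):
        traces = _linear_work_traces([2.0] * 5)
        prof = pmf_cumulant(traces)
        # zero dissipation: F is exactly the binned mean work
        np.testing.assert_allclose(prof.free_energy, prof.mean_work, atol=1e-12)
        assert prof.free_energy[0] == 0.0
        w = _work_at_bins(traces, prof.bin_centers)[0]
        np.testing.assert_allclose(prof.free_energy, w - w[0], atol=1e-10)

    def test_gaussian_work_closed_form(self, rng):
        # W_r(z) = c_r z with c_r ~ N(mu, sd^2): at coordinate z the work is
        # Gaussian with mean mu*z, sd sd*z, so F(z) = mu z - (sd z)^2 / 2kBT
        mu, sd, n = 2.0, 0.25, 70
        slopes = mu + sd * rng.standard_normal(n)
        traces = _linear_work_traces(list(slopes))
        thermal = ThermalParameters()
        prof = pmf_cumulant(traces, thermal=thermal)
        boot = pmf_error(traces, method="bootstrap", n_boot=500, seed=4,
                         thermal=thermal)
        z = prof.bin_centers
        expected = (mu * z - (sd * z) ** 2 / (2 * thermal.kBT))
        expected -= expected[0]
        assert np.all(np.abs(prof.free_energy - expected) <= 3 * np.maximum(boot, 1e-6))

    def test_jarzynski_agrees_on_gaussian_fixture(self, rng):
        slopes = 2.0 + 0.15 * rng.standard_normal(70)
        traces = _linear_work_traces(list(slopes))
        cum = pmf_cumulant(traces)
        jar = pmf_jarzynski(traces)
        boot = pmf_error(traces, method="bootstrap", n_boot=300, seed=1)
        assert np.all(np.abs(cum.free_energy - jar.free_energy)
                      <= 3 * np.maximum(boot, 0.05))

    def test_bounded_above_by_mean_work(self, rng):
        slopes = 2.0 + 0.3 * rng.standard_normal(40)
        traces = _linear_work_traces(list(slopes))
        prof = pmf_cumulant(traces)
        W = _work_at_bins(traces, prof.bin_centers)
        # unreferenced estimate vs unreferenced mean work, bin by bin
        F_raw = W.mean(axis=0) - W.var(axis=0) / (2 * ThermalParameters().kBT)
        assert np.all(F_raw <= W.mean(axis=0) + 1e-12)

    def test_fewer_than_two_traces_rejected(self):
        with pytest.raises(ValueError):
            pmf_cumulant(_linear_work_traces([2.0]))


class TestPmfError:
    def test_identical_traces_zero_error_both_methods(self):
        traces = _linear_work_traces([2.0] * 10)
        assert np.all(pmf_error(traces, method="block") <= 1e-12)
        assert np.all(pmf_error(traces, method="bootstrap", n_boot=50, seed=0) <= 1e-12)

    def test_single_bootstrap_degenerate_with_warning(self):
        traces = _linear_work_traces([2.0, 2.5, 3.0])
        with pytest.warns(UserWarning):
            err = pmf_error(traces, method="bootstrap", n_boot=1)
        np.testing.assert_array_equal(err, 0.0)

    def test_bootstrap_matches_standard_error_scaling(self, rng):
        mu, sd, n = 2.0, 0.2, 60
        slopes = mu + sd * rng.standard_normal(n)
        traces = _linear_work_traces(list(slopes))
        err = pmf_error(traces, method="bootstrap", n_boot=800, seed=3)
        prof = pmf_cumulant(traces)
        z = prof.bin_centers
        # dominant term: SE of <W(z)> - <W(z0)> = sd_hat * (z - z0) / sqrt(n)
        sd_hat = np.std(slopes)
        expected = sd_hat * (z - z[0]) / np.sqrt(n)
        sel = expected > 0.01
        assert np.all(np.abs(err[sel] - expected[sel]) / expected[sel] < 0.3)

    def test_block_partition_count_validated(self):
        traces = _linear_work_traces([2.0, 2.1, 2.2])
        with pytest.raises(ValueError):
            pmf_error(traces, method="block", n_blocks=4)
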