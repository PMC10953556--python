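"""Generators: waveforms, time courses, populations, image stacks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from yapflow import synthetic as syn
from yapflow.brillouin import fit_timecourse
from yapflow.metrics import chromatin_cv


class TestFlowWaveform:
    def test_steady_is_constant(self):
        wf = syn.make_flow_waveform("steady", 12.0, duration=100.0, dt=1.0)
        assert np.all(wf.tau == 12.0)
        assert wf.tau_at(37.2) == 12.0

    def test_oscillatory_quarter_period_and_zero_mean(self):
        wf = syn.make_flow_waveform("oscillatory", 12.0, duration=10.0,
                                    dt=0.005, frequency=1.0)
        assert wf.tau_at(0.25) == pytest.approx(12.0)
        one_period = wf.tau[(wf.times >= 0) & (wf.times < 1.0)]
        assert abs(one_period.mean()) < 1e-10

    def test_condensed_schedule_duration(self):
        wf = syn.make_flow_waveform("oscillatory", 12.0, duration=86400.0,
                                    dt=0.005, frequency=1.0, compression=1.0e4)
        assert wf.schedule_duration == pytest.approx(8.64, abs=0)
        assert wf.times[-1] == pytest.approx(8.64)

    @pytest.mark.parametrize("kwargs", [
        dict(kind="steady", magnitude=1.0, duration=-1.0, dt=1.0),
        dict(kind="steady", magnitude=1.0, duration=10.0, dt=0.0),
        dict(kind="oscillatory", magnitude=1.0, duration=10.0, dt=1.0),
        dict(kind="steady", magnitude=1.0, duration=10.0, dt=1.0, compression=0.5),
        dict(kind="ramp", magnitude=1.0, duration=10.0, dt=1.0),
    ])
    def test_invalid_inputs_raise(self, kwargs):
        with pytest.raises(ValueError):
            syn.make_flow_waveform(**kwargs)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(freq=st.floats(0.2, 5.0), mag=st.floats(0.1, 50.0),
           periods=st.integers(1, 5))
    def test_zero_mean_over_whole_periods(self, freq, mag, periods):
        dt = 1.0 / (1000.0 * freq)
        wf = syn.make_flow_waveform("oscillatory", mag, duration=periods / freq,
                                    dt=dt, frequency=freq)
        mean = np.mean([wf.tau_at(t) for t in np.arange(0, periods / freq, dt)])
        assert abs(mean) < 1e-3 * mag


class TestCapTimecourse:
    def test_origin_and_saturation(self):
        tc = syn.make_cap_timecourse("USS12", duration=10 * 14400.0)
        assert tc.values[0] == 0.0
        assert tc.values[-1] == pytest.approx(0.30, rel=1e-3)

    def test_uss_plateau_exceeds_oss(self):
        assert (syn.CAP_PRESETS["USS12"]["plateau"]
                > syn.CAP_PRESETS["OSS"]["plateau"])

    def test_values_bounded_with_noise(self):
        tc = syn.make_cap_timecourse("USS12", noise_sd=0.3, seed=7)
        assert np.all(tc.values >= 0.0) and np.all(tc.values <= 1.0)

    def test_plateau_out_of_range_raises(self):
        with pytest.raises(ValueError):
            syn.make_cap_timecourse(plateau=1.2)

    def test_noisy_recovery_within_10pct(self):
        tc = syn.make_cap_timecourse("USS12", noise_sd=0.02, seed=11,
                                     duration=86400.0, n_points=50)
        fit = fit_timecourse(tc.times, tc.values)
        assert fit.plateau == pytest.approx(0.30, rel=0.10)

    def test_noise_free_roundtrip_exact(self):
        tc = syn.make_cap_timecourse("USS12")
        fit = fit_timecourse(tc.times, tc.values)
        assert fit.residual < 1e-8
        assert fit.plateau == pytest.approx(0.30, rel=1e-6)
        assert fit.time_constant == pytest.approx(14400.0, rel=1e-6)


class TestStiffnessTimecourse:
    def test_starts_at_baseline(self):
        tc = syn.make_stiffness_timecourse("USS12")
        assert tc.values[0] == pytest.approx(1.0)

    def test_uss_stiffens_monotonically(self):
        tc = syn.make_stiffness_timecourse("USS12")
        assert np.all(np.diff(tc.values) >= 0)
        assert tc.values[-1] > tc.values[0]

    def test_oss_softens_monotonically(self):
        tc = syn.make_stiffness_timecourse("OSS")
        assert np.all(np.diff(tc.values) <= 0)
        assert tc.values[-1] < tc.values[0]

    def test_nonpositive_modulus_raises(self):
        with pytest.raises(ValueError):
            syn.make_stiffness_timecourse(baseline=-1.0)


class TestCellPopulation:
    def test_zero_noise_is_exact_line(self):
        pop = syn.make_cell_population(n=40, intercept=1.2, slope=-0.35,
                                       noise_sd=0.0, seed=2)
        assert np.allclose(pop.yr, 1.2 - 0.35 * pop.cap_intensity)

    def test_default_preset_negative_ols_slope(self):
        pop = syn.make_cell_population(n=80, seed=5)
        slope = np.polyfit(pop.cap_intensity, pop.yr, 1)[0]
        assert slope < 0

    def test_single_cell_raises(self):
        with pytest.raises(ValueError):
            syn.make_cell_population(n=1)

    def test_seed_determinism(self):
        a = syn.make_cell_population(n=30, seed=9)
        b = syn.make_cell_population(n=30, seed=9)
        assert np.array_equal(a.cap_intensity, b.cap_intensity)
        assert np.array_equal(a.yr, b.yr)

    def test_all_yr_positive(self):
        pop = syn.make_cell_population(n=200, noise_sd=0.3, seed=1)
        assert np.all(pop.yr > 0)


class TestNucleusStack:
    def test_zero_compaction_gives_zero_cv(self):
        stack = syn.make_nucleus_stack(compaction=0.0, seed=0)
        assert chromatin_cv(stack.voxels, stack.nucleus_mask).cv == 0.0

    def test_cv_increases_with_compaction(self):
        cvs = [chromatin_cv(s.voxels, s.nucleus_mask).cv
               for s in (syn.make_nucleus_stack(compaction=c, seed=4)
                         for c in (0.0, 0.2, 0.5))]
        assert cvs[0] < cvs[1] < cvs[2]

    def test_mask_volume_matches_ellipsoid(self):
        axes = (8.0, 6.0, 5.0)
        stack = syn.make_nucleus_stack(semi_axes=axes, voxel_size=0.25)
        measured = stack.nucleus_mask.sum() * stack.voxel_size**3
        analytic = 4.0 / 3.0 * np.pi * axes[0] * axes[1] * axes[2]
        assert measured == pytest.approx(analytic, rel=0.05)

    def test_shapes_and_nonnegativity(self):
        stack = syn.make_nucleus_stack(compaction=0.5, seed=3)
        assert stack.voxels.shape == stack.nucleus_mask.shape
        assert np.all(stack.voxels >= 0)
        assert stack.apical_range[0] > np.max(
            np.nonzero(stack.nucleus_mask.any(axis=(1, 2)))[0])

    def test_nonpositive_axes_raise(self):
        with pytest.raises(ValueError):
            syn.make_nucleus_stack(semi_axes=(0.0, 5.0, 5.0))


def test_csv_roundtrips(tmp_path):
    tc = syn.make_cap_timecourse("OSS")
    tc.to_csv(tmp_path / "tc.csv")
    back = syn.TimeCourse.from_csv(tmp_path / "tc.csv")
    assert np.allclose(back.values, tc.values)
    pop = syn.make_cell_population(n=25, seed=8)
    pop.to_csv(tmp_path / "pop.csv")
    back = syn.CellPopulationSample.from_csv(tmp_path / "pop.csv")
    assert np.allclose(back.yr, pop.yr)
    stack = syn.make_nucleus_stack(seed=2)
    stack.to_tiff(tmp_path / "s.tif", tmp_path / "m.tif")
    import tifffile
    assert np.allclose(tifffile.imread(tmp_path / "s.tif"),
                       stack.voxels.astype(np.float32))
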