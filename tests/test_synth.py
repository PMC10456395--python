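"""Synthetic-data generators: determinism, duality with theory, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microfilt.blocking import ModelParams, volume
from microfilt.sizing import percentile_d, recovery
from microfilt.synth import (
    PHFSchedule,
    SoftPassageParams,
    apply_filter_rigid,
    apply_filter_soft,
    gen_bead_mixture,
    gen_cell_population,
    gen_filtration_curve,
    gen_phf_curve,
    render_image,
)


class TestCurveGenerator:
    def test_noiseless_matches_closed_form(self, well_posed):
        params, duration, dt = well_posed["cake"]
        curve = gen_filtration_curve("cake", params, duration, dt)
        np.testing.assert_allclose(curve.v, volume("cake", params, curve.times),
                                   rtol=1e-12)

    def test_seed_determinism(self, well_posed):
        params, duration, dt = well_posed["complete"]
        a = gen_filtration_curve("complete", params, duration, dt, 1e-4, seed=42)
        b = gen_filtration_curve("complete", params, duration, dt, 1e-4, seed=42)
        np.testing.assert_array_equal(a.v, b.v)
        c = gen_filtration_curve("complete", params, duration, dt, 1e-4, seed=43)
        assert np.any(a.v != c.v)

    def test_noisy_curve_satisfies_curve_contract(self, well_posed):
        params, duration, dt = well_posed["intermediate"]
        curve = gen_filtration_curve("intermediate", params, duration, dt,
                                     noise_sd=5e-4, seed=0)
        assert curve.v[0] == 0.0
        assert np.all(np.diff(curve.v) >= 0)

    def test_invalid_dt_rejected(self, well_posed):
        params, _, _ = well_posed["cake"]
        with pytest.raises(ValueError, match="dt_s"):
            gen_filtration_curve("cake", params, 10.0, 0.0)


class TestPHF:
    PARAMS = ModelParams(5.28e-4, 42.0)

    def test_full_restore_gives_equal_cycle_increments(self):
        curve = gen_phf_curve("intermediate", self.PARAMS, PHFSchedule(total_s=300.0))
        at_cycle_ends = curve.v[::100]  # dt 0.1, cycle 10 s
        increments = np.diff(at_cycle_ends[1:])
        assert np.ptp(increments) <= 1e-12 * increments.mean()

    def test_full_restore_envelope_is_linear(self):
        curve = gen_phf_curve("intermediate", self.PARAMS, PHFSchedule(total_s=300.0))
        cycle_idx = np.arange(1, 31)
        cycle_end_v = curve.v[::100][1:]
        coeffs = np.polyfit(cycle_idx, cycle_end_v, 1)
        resid = cycle_end_v - np.polyval(coeffs, cycle_idx)
        assert np.max(np.abs(resid)) / cycle_end_v[-1] < 1e-6

    def test_no_restore_matches_plain_law_on_filtering_time(self):
        schedule = PHFSchedule(restore_fraction=0.0, total_s=100.0)
        curve = gen_phf_curve("intermediate", self.PARAMS, schedule)
        cycle = 10.0
        c = np.minimum((curve.times // cycle).astype(int), 9)
        filtering_time = c * 5.0 + np.minimum(curve.times - c * cycle, 5.0)
        expected = volume("intermediate", self.PARAMS, filtering_time)
        np.testing.assert_allclose(curve.v, expected, rtol=1e-12, atol=1e-18)

    def test_volume_holds_during_backflush(self):
        curve = gen_phf_curve("intermediate", self.PARAMS, PHFSchedule(total_s=60.0))
        in_backflush = (curve.times % 10.0) > 5.0
        dv = np.diff(curve.v)
        assert np.all(dv[in_backflush[:-1]] == 0.0)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError, match="restore_fraction"):
            PHFSchedule(restore_fraction=1.2)


class TestPopulations:
    def test_bead_mixture_mean_and_determinism(self):
        beads = gen_bead_mixture(4000, seed=1)
        assert float(np.mean(beads.diameters)) == pytest.approx(7.8525, abs=0.05)
        again = gen_bead_mixture(4000, seed=1)
        np.testing.assert_array_equal(beads.diameters, again.diameters)

    def test_bead_counts(self):
        assert len(gen_bead_mixture(250, seed=2)) == 1000
        with pytest.raises(ValueError, match="n_per_component"):
            gen_bead_mixture(0)

    def test_cell_population_percentile_calibration(self):
        cells = gen_cell_population(100_000, seed=3)
        assert percentile_d(cells, 10) == pytest.approx(13.4, abs=0.2)
        assert percentile_d(cells, 50) == pytest.approx(15.7, abs=0.2)
        assert percentile_d(cells, 90) == pytest.approx(18.6, abs=0.2)
        # distribution mean is reported, not enforced: ~15.9 um
        assert float(np.mean(cells.diameters)) == pytest.approx(15.9, abs=0.3)

    def test_cell_population_right_skewed(self):
        cells = gen_cell_population(50_000, seed=4)
        d10, d50, d99 = (percentile_d(cells, q) for q in (10, 50, 99))
        assert d99 - d50 > d50 - d10

    def test_empty_population_request_rejected(self):
        with pytest.raises(ValueError, match="n must be"):
            gen_cell_population(0)


class TestFilters:
    def test_rigid_partition_and_full_recovery(self):
        beads = gen_bead_mixture(500, seed=5)
        filtrate, retentate = apply_filter_rigid(beads, 6.0)
        assert np.all(filtrate.diameters < 6.0)
        assert np.all(retentate.diameters >= 6.0)
        merged = np.sort(np.concatenate([filtrate.diameters, retentate.diameters]))
        np.testing.assert_array_equal(merged, np.sort(beads.diameters))
        report = recovery(len(filtrate), len(retentate), len(beads))
        assert report.rate_total_pct == 100.0

    def test_rigid_cutoff_bounds_filtrate_d99(self):
        beads = gen_bead_mixture(1000, seed=6)
        filtrate, _ = apply_filter_rigid(beads, 6.0)
        assert percentile_d(filtrate, 99) <= 6.0
        # essentially only the 5.12-um component passes a 6-um pore
        assert float(np.mean(filtrate.diameters)) == pytest.approx(5.12, abs=0.1)

    @pytest.mark.parametrize("d_pore,expect_pass", [(100.0, True), (0.0, False)])
    def test_rigid_extremes(self, d_pore, expect_pass):
        beads = gen_bead_mixture(100, seed=7)
        filtrate, retentate = apply_filter_rigid(beads, d_pore)
        assert (len(filtrate) == len(beads)) is expect_pass
        assert (len(retentate) == 0) is expect_pass

    def test_soft_reduces_to_rigid_in_sharp_limit(self):
        cells = gen_cell_population(2000, seed=8)
        soft = SoftPassageParams(r50=1.0, beta=500.0)
        soft_f, _ = apply_filter_soft(cells, 14.0, soft, seed=9)
        rigid_f, _ = apply_filter_rigid(cells, 14.0)
        # beta -> inf: passage indistinguishable from the hard cut
        assert abs(len(soft_f) - len(rigid_f)) <= 0.01 * len(cells)

    def test_soft_midpoint_passage_probability(self):
        soft = SoftPassageParams(r50=2.0, beta=8.0)
        at_mid = np.full(20_000, 10.0)  # d = r50 * d_pore for d_pore = 5
        from microfilt.sizing import ParticlePopulation
        filtrate, _ = apply_filter_soft(ParticlePopulation(at_mid), 5.0, soft, seed=10)
        assert len(filtrate) / 20_000 == pytest.approx(0.5, abs=0.01)

    def test_soft_conserves_multiset(self):
        cells = gen_cell_population(3000, seed=11)
        filtrate, retentate = apply_filter_soft(cells, 7.0, SoftPassageParams(), seed=12)
        merged = np.sort(np.concatenate([filtrate.diameters, retentate.diameters]))
        np.testing.assert_array_equal(merged, np.sort(cells.diameters))

    def test_smaller_pores_shift_filtrate_median_down(self):
        cells = gen_cell_population(50_000, seed=13)
        f5, _ = apply_filter_soft(cells, 5.0, SoftPassageParams(), seed=14)
        f9, _ = apply_filter_soft(cells, 9.0, SoftPassageParams(), seed=14)
        assert percentile_d(f5, 50) < percentile_d(f9, 50)
        assert percentile_d(f9, 50) <= percentile_d(cells, 50)


class TestRenderer:
    def test_zero_particles_gives_background_only(self):
        from microfilt.sizing import ParticlePopulation
        image, truth = render_image(ParticlePopulation(np.array([])), 50.0, 0.5, seed=0)
        assert truth == []
        np.testing.assert_allclose(image.pixels, 0.25)

    def test_disk_foreground_area_matches_geometry(self):
        from microfilt.sizing import ParticlePopulation
        image, _ = render_image(ParticlePopulation(np.array([15.0])), 100.0, 0.5, seed=1)
        area_px = float((image.pixels > 0.55).sum())
        assert area_px == pytest.approx(np.pi * 15.0**2 / 4.0 / 0.25, rel=0.02)

    def test_seed_determinism_bitwise(self):
        cells = gen_cell_population(10, seed=2)
        a, _ = render_image(cells, 150.0, 0.5, noise_sd=0.02, seed=3)
        b, _ = render_image(cells, 150.0, 0.5, noise_sd=0.02, seed=3)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_overcrowded_field_rejected(self):
        cells = gen_cell_population(500, seed=4)
        with pytest.raises(ValueError, match="place all particles"):
            render_image(cells, 60.0, 0.5, seed=5)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_truth_count_matches_population(self, seed):
        cells = gen_cell_population(12, seed=seed)
        _, truth = render_image(cells, 200.0, 0.5, dead_fraction=0.25,
                                aggregate_rate=0.3, seed=seed)
        assert len(truth) == 12
        assert sorted(p.diameter_um for p in truth) == sorted(cells.diameters.tolist())
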