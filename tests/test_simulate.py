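"""Brownian-dynamics binding simulator: conservation, equilibrium, reproducibility."""

import numpy as np
import pytest

from dsbkinetics import fcs, frap, imaging
from dsbkinetics.simulate import (
    BleachEvent,
    CameraDetection,
    Disk,
    GaussianDetection,
    GroundTruth,
    Rect,
    SimulationConfig,
    config_from_json,
    config_to_json,
    fcs_study_config,
    frap_study_config,
    simulate_fcs_trace,
    simulate_frap_record,
    simulate_particles,
    simulate_track_stack,
    track_study_config,
)


def small_config(**kw):
    base = dict(
        seed=42,
        nucleus_radius=4.0,
        n_particles=400,
        diffusion_coefficient=5.0,
        damage_region=Rect(0.0, 0.0, 1.5, 1.0),
        k_on=0.3,
        binding_site_density=1.0,
        k_off=0.1,
        dt=0.02,
        duration=10.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestGeometry:
    def test_disk_and_rect_contains_and_area(self):
        d = Disk(1.0, 0.0, 2.0)
        assert d.area == pytest.approx(np.pi * 4.0)
        assert bool(d.contains(np.array([2.9, 0.0])))
        assert not bool(d.contains(np.array([3.1, 0.0])))
        r = Rect(0.0, 0.0, 1.0, 0.5)
        assert r.area == pytest.approx(2.0)
        assert bool(r.contains(np.array([0.9, -0.4])))
        assert not bool(r.contains(np.array([0.9, 0.6])))


class TestSimulateParticles:
    def test_particle_count_conserved_and_inside_nucleus(self):
        cfg = small_config()
        traj = simulate_particles(cfg, record_every=25)
        assert traj.positions.shape[1] == cfg.n_particles
        r = np.hypot(traj.positions[..., 0], traj.positions[..., 1])
        assert np.all(r <= cfg.nucleus_radius + 1e-9)

    def test_no_binding_without_on_rate(self):
        cfg = small_config(k_on=0.0)
        traj = simulate_particles(cfg, record_every=50)
        assert traj.bound.sum() == 0

    def test_same_seed_is_bit_identical(self):
        t1 = simulate_particles(small_config(), record_every=100)
        t2 = simulate_particles(small_config(), record_every=100)
        np.testing.assert_array_equal(t1.positions, t2.positions)
        np.testing.assert_array_equal(t1.bound, t2.bound)

    def test_different_seed_changes_noise_not_truth(self):
        c1, c2 = small_config(seed=1), small_config(seed=2)
        t1 = simulate_particles(c1, record_every=100)
        t2 = simulate_particles(c2, record_every=100)
        assert not np.array_equal(t1.positions, t2.positions)
        assert GroundTruth.from_config(c1) == GroundTruth.from_config(c2)

    @pytest.mark.parametrize("k_on, k_off", [(0.3, 0.1), (0.1, 0.1), (0.5, 0.25)])
    def test_equilibrium_bound_fraction(self, k_on, k_off):
        cfg = small_config(
            seed=7, k_on=k_on, k_off=k_off, n_particles=2000, duration=40.0
        )
        traj = simulate_particles(cfg, record_every=10)
        # discard the first quarter as burn-in; average in-region bound fraction
        keep = traj.times > cfg.duration / 4
        fracs = []
        for pos, bound in zip(traj.positions[keep], traj.bound[keep]):
            in_region = cfg.damage_region.contains(pos)
            if in_region.sum():
                fracs.append(bound[in_region].mean())
        mean_frac = np.mean(fracs)
        expected = k_on / (k_on + k_off)
        # 3 standard errors of the (correlated) per-snapshot fraction
        n_eff = max(len(fracs) * cfg.dt * 10 * k_off, 4)
        se = np.std(fracs, ddof=1) / np.sqrt(n_eff)
        assert abs(mean_frac - expected) < max(3 * se, 0.03)

    def test_rate_resolution_guard(self):
        with pytest.raises(ValueError, match="dt"):
            small_config(k_on=100.0, dt=0.02)


class TestSimulateFrapRecord:
    def test_no_bleach_event_rejected(self):
        with pytest.raises(ValueError, match="bleach"):
            simulate_frap_record(small_config())

    def test_fluorescence_drops_at_bleach(self):
        cfg = frap_study_config(seed=3, bleach_area=1.0, n_particles=3000)
        rec, truth = simulate_frap_record(cfg)
        assert truth.bleach_area == pytest.approx(1.0)
        b = rec.bleach_index
        pre = rec.roi_trace[:b].mean()
        assert rec.roi_trace[b] < 0.35 * pre
        assert rec.protocol_tag == "damage-region-correction"

    def test_normalized_curve_has_unit_prebleach_and_recovers(self):
        cfg = frap_study_config(seed=4, bleach_area=1.0, n_particles=4000)
        rec, truth = simulate_frap_record(cfg)
        curve = frap.normalize_frap(rec)
        late = curve.value[curve.time_post_bleach > 40].mean()
        assert 0.75 < late < 1.2
        assert curve.value[0] < 0.3

    def test_reaction_dominant_regime_recovers_koff(self):
        # bound-occupancy noise is correlated over 1/k_off, so single records
        # scatter; a 4 µm² bleach spot samples 4x more molecules, and the
        # average of 12 seeded replicates (standard replicate pooling)
        # recovers k_off within 15% of the configured rate
        curves = []
        for seed in range(12):
            cfg = frap_study_config(seed=20 + seed, bleach_area=4.0, n_particles=8000)
            rec, truth = simulate_frap_record(cfg)
            c = frap.normalize_frap(rec)
            curves.append(c.value)
        mean_curve = frap.NormalizedFrapCurve(c.time_post_bleach, np.mean(curves, axis=0))
        fit = frap.fit_frap(mean_curve, "reaction")
        assert abs(fit.params.k_off - truth.k_off) / truth.k_off < 0.15

    def test_diffusion_only_tau_scales_with_bleach_area(self):
        # no binding, slow diffusion so the recovery spans many frames:
        # tau_D grows ~4x when the bleach area quadruples
        taus = {}
        for area in (0.5, 2.0):
            vals = []
            for seed in range(5):
                cfg = frap_study_config(
                    seed=50 + seed,
                    bleach_area=area,
                    n_particles=20000,
                    binding_enabled=False,
                    diffusion_coefficient=0.1,
                    dt=0.02,
                    frame_interval=0.1,
                    duration=32.0,
                    bleach=BleachEvent(roi=Disk(0.0, 0.0, np.sqrt(area / np.pi)), time=2.0),
                )
                rec, _ = simulate_frap_record(cfg)
                fit = frap.fit_frap(
                    frap.normalize_frap(rec), "diffusion", fit_window_start=0.0
                )
                vals.append(fit.params.tau_D)
            taus[area] = np.median(vals)
        ratio = taus[2.0] / taus[0.5]
        assert 2.0 < ratio < 8.0  # ideal 4.0; generous band for stochastic runs

    def test_acquisition_bleaching_cancelled_by_normalization(self):
        cfg = frap_study_config(
            seed=9, bleach_area=1.0, n_particles=6000, acquisition_bleach_rate=0.004
        )
        rec, _ = simulate_frap_record(cfg)
        curve = frap.normalize_frap(rec)
        late = curve.value[curve.time_post_bleach > 45].mean()
        assert late > 0.8  # reference division removed the global decay


class TestSimulateFcsTrace:
    def test_zero_particles_zero_background_degenerate(self):
        cfg = fcs_study_config(seed=1, n_particles=0)
        cfg = fcs_study_config(
            seed=1, n_particles=0, detection=GaussianDetection(background_rate=0.0)
        )
        with pytest.raises(ValueError, match="degenerate"):
            simulate_fcs_trace(cfg)

    def test_mean_count_rate_matches_analytic_expectation(self):
        cfg = fcs_study_config(seed=5)
        trace, truth = simulate_fcs_trace(cfg)
        det = cfg.detection
        box_xy = cfg.nucleus_radius * np.sqrt(np.pi)
        box_z = 3.2 * det.omega * det.waist
        # mean Gaussian weight integral over the periodic box
        w_int = (np.pi * det.waist**2 / 2.0) * np.sqrt(np.pi / 2.0) * det.omega * det.waist
        expected_rate = det.brightness * cfg.n_particles * w_int / (box_xy**2 * box_z)
        expected = (expected_rate + det.background_rate) * det.sample_interval
        assert trace.counts.mean() == pytest.approx(expected, rel=0.05)

    def test_ground_truth_residence_time(self):
        cfg = fcs_study_config(seed=6)
        _, truth = simulate_fcs_trace(cfg)
        det = cfg.detection
        assert truth.fcs_residence_time == pytest.approx(
            det.waist**2 / (4 * cfg.diffusion_coefficient)
        )

    def test_fitted_tau_consistent_with_w2_over_4d(self):
        errs = []
        for seed in range(4):
            trace, truth = simulate_fcs_trace(fcs_study_config(seed=60 + seed))
            curve = fcs.autocorrelate(trace)
            fit = fcs.fit_fcs(curve, 1, acquisition_window_s=trace.duration)
            errs.append(abs(fit.params.tau - truth.fcs_residence_time) / truth.fcs_residence_time)
        assert np.median(errs) < 0.25

    def test_reproducible_from_seed(self):
        t1, _ = simulate_fcs_trace(fcs_study_config(seed=8))
        t2, _ = simulate_fcs_trace(fcs_study_config(seed=8))
        np.testing.assert_array_equal(t1.counts, t2.counts)


class TestSimulateTrackStack:
    def test_unit_enrichment_gives_flat_series(self):
        cfg = track_study_config(seed=11, enrichment=1.0, duration=100.0)
        stack, masks, truth = simulate_track_stack(cfg)
        series = imaging.accumulation_series(stack, masks)
        assert abs(series.plateau() - 1.0) < 0.03

    def test_enrichment_two_recovered_via_pipeline(self):
        cfg = track_study_config(seed=12, enrichment=2.0)
        stack, masks, truth = simulate_track_stack(cfg)
        series = imaging.accumulation_series(stack, masks)
        assert series.plateau() == pytest.approx(2.0, rel=0.05)

    def test_segmentation_overlaps_truth(self):
        stack, masks, _ = simulate_track_stack(track_study_config(seed=13, enrichment=2.0))
        seg = imaging.segment_damage_region(stack)
        inter = (seg & masks.damage).sum()
        union = (seg | masks.damage).sum()
        assert inter / union >= 0.9

    def test_same_seed_identical_pixels(self):
        s1, _, _ = simulate_track_stack(track_study_config(seed=14))
        s2, _, _ = simulate_track_stack(track_study_config(seed=14))
        np.testing.assert_array_equal(s1.channels["protein"], s2.channels["protein"])
        np.testing.assert_array_equal(s1.channels["marker"], s2.channels["marker"])

    def test_negative_enrichment_rejected(self):
        with pytest.raises(ValueError, match="enrichment"):
            track_study_config(seed=1, enrichment=-0.5)


class TestConfigJson:
    def test_round_trip(self):
        for cfg in (
            frap_study_config(seed=1, bleach_area=2.0),
            fcs_study_config(seed=2, two_species=True),
            track_study_config(seed=3, enrichment=1.5),
        ):
            assert config_from_json(config_to_json(cfg)) == cfg

    def test_unknown_keys_rejected(self):
        obj = config_to_json(frap_study_config(seed=1))
        obj["mystery_knob"] = 3
        with pytest.raises(ValueError, match="unknown config keys"):
            config_from_json(obj)

    def test_seed_is_mandatory(self):
        with pytest.raises(TypeError):
            SimulationConfig()  # no seed
        with pytest.raises(ValueError, match="seed"):
            SimulationConfig(seed=None)
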