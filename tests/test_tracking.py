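"""RVT localisation, ridge segmentation, linking, contrast-to-height."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import iscatlab as il
from iscatlab.phantoms import ParticleTrack, Phantom, Tubule
from iscatlab.tracking import CalibrationViolation


def _particle_frame(cfg, ipsf, xy_px, z=500.0, focus=500.0, budget=None,
                    shape=(64, 64), seed=0, s_over_r=0.1):
    r = cfg.reference_reflectivity
    parts = [ParticleTrack(positions=np.array([[x * 30.0, y * 30.0, z]]),
                           amplitude=s_over_r * r) for x, y in xy_px]
    stack = il.render_acquisition(
        Phantom(shape=shape, particles=parts),
        il.AcquisitionPlan(focus_positions=[focus], photon_budget=budget),
        cfg, ipsf, seed=seed)
    return (stack.data - r**2) / r**2


class TestHessianRidgeSegment:
    def test_flat_image_empty(self):
        assert not il.hessian_ridge_segment(np.zeros((64, 64)), 2.0, 0.01).any()

    def test_straight_tubule_centerline_recovered(self, cfg, ipsf):
        tub = Tubule(polyline=np.array([[300.0, 960.0], [3500.0, 960.0]]),
                     radius=37.5, amplitude=0.12, z=200.0)
        ph = Phantom(shape=(64, 128), tubules=[tub])
        stack = il.render_acquisition(
            ph, il.AcquisitionPlan(focus_positions=[200.0], photon_budget=None),
            cfg, ipsf, seed=0)
        r2 = cfg.reference_reflectivity**2
        c = (stack.data - r2) / r2
        mask = il.hessian_ridge_segment(c, scale_px=2.0, threshold=0.01)
        centerline = mask[32, 10:117]
        assert centerline.mean() >= 0.95
        off_axis = mask & (np.abs(np.arange(64)[:, None] - 32) > 5)
        assert off_axis.mean() <= 0.02

    def test_crossing_tubules_both_segmented(self, cfg, ipsf):
        tubs = [Tubule(polyline=np.array([[200.0, 200.0], [3600.0, 3600.0]]),
                       radius=37.5, amplitude=0.12, z=200.0),
                Tubule(polyline=np.array([[200.0, 3600.0], [3600.0, 200.0]]),
                       radius=37.5, amplitude=0.12, z=200.0)]
        ph = Phantom(shape=(128, 128), tubules=tubs)
        stack = il.render_acquisition(
            ph, il.AcquisitionPlan(focus_positions=[200.0], photon_budget=None),
            cfg, ipsf, seed=0)
        r2 = cfg.reference_reflectivity**2
        mask = il.hessian_ridge_segment((stack.data - r2) / r2, 2.0, 0.01)
        # both diagonal arms present away from the crossing
        for px in (30, 98):
            assert mask[px, px]
            assert mask[px, 128 - 1 - px]


class TestRadialVarianceTransform:
    def test_constant_image_zero(self):
        score = il.radial_variance_transform(np.full((64, 64), 0.3), 0, 8)
        assert np.allclose(score, 0.0, atol=1e-12)

    def test_peak_at_ring_center_and_sign_blind(self, cfg, ipsf):
        # a defocused particle has a ringed iPSF; the RVT maximum sits at
        # its centre, and an inverted copy scores identically
        c = _particle_frame(cfg, ipsf, [(32, 32)], z=800.0, focus=500.0)
        score = il.radial_variance_transform(c, 0, 8)
        iy, ix = np.unravel_index(np.argmax(score), score.shape)
        assert (iy, ix) == (32, 32)
        score_inv = il.radial_variance_transform(-c, 0, 8)
        np.testing.assert_allclose(score_inv, score, atol=1e-12)

    def test_affine_intensity_invariance(self, cfg, ipsf):
        # a I + b scales scores by a^2 (exact in exact arithmetic; the FFT
        # convolution leaves ~1e-5 relative residue) and keeps the argmax
        c = _particle_frame(cfg, ipsf, [(20, 40)])
        s1 = il.radial_variance_transform(c, 1, 6)
        s2 = il.radial_variance_transform(2.5 * c + 0.7, 1, 6)
        np.testing.assert_allclose(s2, 2.5**2 * s1, rtol=1e-4, atol=1e-10)
        assert np.argmax(s2) == np.argmax(s1)

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError):
            il.radial_variance_transform(np.zeros((16, 16)), 0, 20)


class TestLocalizeParticles:
    def test_empty_scene_empty_list(self):
        dets = il.localize_particles(np.zeros((32, 32)), np.zeros((32, 32)),
                                     threshold=0.1)
        assert dets == []

    def test_two_particles_resolved_noiseless(self, cfg, ipsf):
        c = _particle_frame(cfg, ipsf, [(20.0, 32.0), (53.4, 32.0)],
                            shape=(64, 80))
        score = il.radial_variance_transform(c, 0, 6)
        dets = il.localize_particles(score, c, threshold=score.max() * 0.2,
                                     min_separation_px=5, pixel_size=30.0)
        assert len(dets) == 2
        got = sorted(d.x / 30.0 for d in dets)
        assert got[0] == pytest.approx(20.0, abs=0.2)
        assert got[1] == pytest.approx(53.4, abs=0.2)

    def test_subpixel_bias_below_tenth_pixel(self, cfg, ipsf):
        rng = np.random.default_rng(5)
        errs = []
        for _ in range(15):
            x = 32 + rng.uniform(-0.5, 0.5)
            y = 32 + rng.uniform(-0.5, 0.5)
            c = _particle_frame(cfg, ipsf, [(x, y)])
            score = il.radial_variance_transform(c, 0, 6)
            d = il.localize_particles(score, c, threshold=score.max() * 0.5,
                                      min_separation_px=5, pixel_size=30.0)[0]
            errs.append([d.x / 30.0 - x, d.y / 30.0 - y])
        bias = np.abs(np.mean(errs, axis=0))
        assert np.all(bias < 0.1)

    def test_localization_precision_under_shot_noise(self, cfg, ipsf):
        # |C| = 0.2 at photon budget 1e4: std < 0.5 px over realizations
        pos = []
        for i in range(100):
            c = _particle_frame(cfg, ipsf, [(32.3, 31.7)], budget=1e4,
                                seed=1000 + i)
            score = il.radial_variance_transform(c, 0, 6)
            dets = il.localize_particles(score, c,
                                         threshold=score.max() * 0.5,
                                         min_separation_px=5, pixel_size=30.0)
            d = max(dets, key=lambda q: q.score)
            pos.append([d.x, d.y])
        std_px = np.std(pos, axis=0) / 30.0
        assert np.all(std_px < 0.5)


class TestLinkTrajectories:
    def test_single_mover_single_track(self):
        dets = [il.Detection(t=t, x=1000.0 + 20.0 * t, y=500.0)
                for t in range(100)]
        trajs = il.link_trajectories(dets, max_disp_nm=100.0, min_length=25)
        assert len(trajs) == 1 and len(trajs[0]) == 100

    def test_short_tracks_filtered(self):
        dets = [il.Detection(t=t, x=100.0, y=100.0) for t in range(24)]
        dets += [il.Detection(t=t, x=5000.0, y=5000.0) for t in range(30)]
        trajs = il.link_trajectories(dets, max_disp_nm=100.0, min_length=25)
        assert len(trajs) == 1 and len(trajs[0]) == 30

    def test_detections_partitioned(self):
        rng = np.random.default_rng(9)
        dets = []
        for t in range(40):
            for k in range(5):
                dets.append(il.Detection(
                    t=t, x=2000.0 * k + rng.normal(0, 20),
                    y=1000.0 + rng.normal(0, 20)))
        trajs = il.link_trajectories(dets, max_disp_nm=300.0, min_length=25)
        seen = set()
        for tr in trajs:
            for d in tr.detections:
                assert id(d) not in seen
                seen.add(id(d))

    def test_identity_preservation_sparse_brownian(self):
        # step << spacing: >= 95 % of links match ground-truth identities
        ph = il.make_particle_ensemble(n=10, diffusion=1.0e3, duration=20.0,
                                       dt=0.1, shape=(512, 512), seed=10)
        dets, truth = [], {}
        for pid, p in enumerate(ph.particles):
            for t, (x, y, _) in enumerate(p.positions):
                d = il.Detection(t=t, x=x, y=y)
                truth[id(d)] = pid
                dets.append(d)
        trajs = il.link_trajectories(dets, max_disp_nm=400.0, min_length=25)
        good = total = 0
        for tr in trajs:
            ids = [truth[id(d)] for d in tr.detections]
            good += sum(a == b for a, b in zip(ids[:-1], ids[1:]))
            total += len(ids) - 1
        assert total > 0 and good / total >= 0.95


class TestContrastToDz:
    def test_constant_contrast_no_motion(self):
        cal = il.Calibration(c_max=0.2)
        z = il.contrast_to_dz(np.full(30, 0.1), cal)
        np.testing.assert_allclose(z, 0.0, atol=1e-9)

    def test_full_swing_equals_inversion_distance(self):
        cal = il.Calibration(c_max=0.2)
        c = 0.2 * np.cos(np.linspace(0, np.pi, 50))
        z = il.contrast_to_dz(c, cal)
        assert abs(z[-1]) == pytest.approx(cal.full_inversion_nm, rel=1e-6)
        assert round(cal.full_inversion_nm, -1) == 110.0

    def test_round_trip_on_rendered_descent(self, cfg, ipsf):
        # particle descending 40 nm in 1 nm steps, noiseless: RMSE < 5 nm
        r = cfg.reference_reflectivity
        focus, x = 450.0, 32 * 30.0
        zs = 515.0 - np.arange(41.0)
        cs = []
        for z in zs:
            p = ParticleTrack(positions=np.array([[x, x, z]]),
                              amplitude=0.1 * r)
            stack = il.render_acquisition(
                Phantom(shape=(64, 64), particles=[p]),
                il.AcquisitionPlan(focus_positions=[focus],
                                   photon_budget=None), cfg, ipsf, seed=0)
            cs.append((stack.data[32, 32] - r**2) / r**2)
        cs = np.array(cs)
        mid_dz = zs.mean() - focus
        env = ipsf.envelope(mid_dz)
        slope = (ipsf.axial_wavevector
                 + (1 / ipsf.gouy_range) / (1 + (mid_dz / ipsf.gouy_range) ** 2))
        cal = il.Calibration(c_max=2 * 0.1 * env,
                             full_inversion_nm=np.pi / slope)
        offset = (0.1 * env) ** 2  # s^2 term of the interference law
        z_rel = il.contrast_to_dz(np.clip(cs - offset, -cal.c_max, cal.c_max),
                                  cal, initial_phase=ipsf.phase(zs[0] - focus))
        rmse = np.sqrt(np.mean((z_rel - (zs - zs[0])) ** 2))
        assert rmse < 5.0

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_left_inverse_of_forward_model(self, seed):
        # random walk with per-step |dz| < d/4 whose phase stays on the
        # principal branch (0, pi): at a branch edge (contrast extremum)
        # |C| alone cannot distinguish crossing from reflection
        cal = il.Calibration(c_max=0.2)
        d = cal.full_inversion_nm
        rng = np.random.default_rng(seed)
        phi = np.pi / 2
        phases = [phi]
        for _ in range(60):
            step = rng.uniform(-np.pi / 4, np.pi / 4)
            lo, hi = 0.05 * np.pi, 0.95 * np.pi
            phi = lo + abs((phi + step - lo) % (2 * (hi - lo)))
            if phi > hi:
                phi = 2 * hi - phi
            phases.append(phi)
        phases = np.array(phases)
        z_true = (phases - phases[0]) * d / np.pi
        c = cal.c_max * np.cos(phases)
        z_rec = il.contrast_to_dz(c, cal, initial_phase=phases[0])
        np.testing.assert_allclose(z_rec, z_true, atol=1e-6)

    def test_inward_only_prior_monotone(self):
        cal = il.Calibration(c_max=0.2, direction_prior="inward_only")
        rng = np.random.default_rng(3)
        c = 0.19 * np.cos(np.cumsum(rng.uniform(0, 0.3, 80)))
        z = il.contrast_to_dz(np.clip(c, -0.2, 0.2), cal)
        assert np.all(np.diff(z) >= -1e-9)

    def test_calibration_violation(self):
        cal = il.Calibration(c_max=0.1)
        with pytest.raises(CalibrationViolation):
            il.contrast_to_dz(np.array([0.05, 0.2]), cal)


class TestTrajectoryStats:
    def test_static_trajectory(self):
        dets = [il.Detection(t=t, x=100.0, y=200.0, contrast=0.1)
                for t in range(30)]
        s = il.trajectory_stats(il.Trajectory(detections=dets))
        assert s["rmsd_nm"] == 0.0 and s["contrast_swing"] == 0.0

    def test_brownian_ensemble_lag1_msd(self):
        D, dt = 2.0e4, 0.05
        ph = il.make_particle_ensemble(n=100, diffusion=D, duration=25.0,
                                       dt=dt, shape=(1024, 1024), seed=11)
        trajs = []
        for pid, p in enumerate(ph.particles):
            dets = [il.Detection(t=t, x=x, y=y)
                    for t, (x, y, _) in enumerate(p.positions)]
            trajs.append(il.Trajectory(detections=dets, trajectory_id=pid))
        _, msd = il.ensemble_msd(trajs, max_lag=1, frame_interval=dt)
        assert msd[0] == pytest.approx(4 * D * dt, rel=0.10)

    def test_constant_velocity_speed(self):
        v, dt = 2000.0, 0.01  # nm/s over 10 ms frames
        dets = [il.Detection(t=t, x=v * dt * t, y=0.0) for t in range(200)]
        s = il.trajectory_stats(il.Trajectory(detections=dets),
                                frame_interval=dt)
        assert s["mean_speed_nm_s"] == pytest.approx(v, rel=0.05)


class TestColocalization:
    def test_all_inside(self):
        mask = np.ones((32, 32), dtype=bool)
        dets = [il.Detection(t=0, x=300.0, y=300.0)]
        assert il.colocalization_fraction(dets, mask, 0.0) == 1.0

    def test_none_inside(self):
        mask = np.zeros((32, 32), dtype=bool)
        dets = [il.Detection(t=0, x=300.0, y=300.0)]
        assert il.colocalization_fraction(dets, mask, 0.0) == 0.0

    def test_uniform_detections_match_area_fraction(self):
        rng = np.random.default_rng(12)
        mask = np.zeros((100, 100), dtype=bool)
        mask[:, :35] = True  # area fraction 0.35
        dets = [il.Detection(t=0, x=rng.uniform(0, 99) * 30.0,
                             y=rng.uniform(0, 99) * 30.0)
                for _ in range(1000)]
        frac = il.colocalization_fraction(dets, mask, 0.0)
        p = 0.35
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / 1000)

    def test_empty_detections_rejected(self):
        with pytest.raises(ValueError):
            il.colocalization_fraction([], np.ones((4, 4), dtype=bool))
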