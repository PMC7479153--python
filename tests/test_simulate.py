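"""Brownian-dynamics generator: trajectories, renderers, detector model."""

import numpy as np
import pytest

from fluctra import (
    BleachingModel,
    DetectorModel,
    ParticleSpecies,
    ScanProtocol,
    SimulationBox,
    Trajectories,
    apply_detector,
    render_fcs_trace,
    render_raster_stack,
    simulate_fcs_trace,
    simulate_paths,
    simulate_raster_stack,
)
from fluctra.errors import BoxSizeError, EmptyFieldWarning
from fluctra.psf import GAMMA_1P

from conftest import make_box, monomer


class TestPaths:
    def test_zero_diffusion_is_static(self, psf):
        box = make_box(psf, duration=1e-2, timestep=1e-4, seed=3)
        traj = simulate_paths([monomer(0.0, density=0.5)], box, psf)
        assert traj.n_particles > 0
        assert np.all(traj.positions == traj.positions[0])

    def test_msd_matches_6_d_dt(self, psf):
        # 100 particles x 100 steps = 1e4 particle-steps
        d = 5.0
        dt = 1e-4
        box = make_box(psf, duration=100 * dt, timestep=dt, seed=7)
        dens = 100 / box.volume
        traj = simulate_paths([monomer(d, density=dens)], box, psf)
        assert traj.n_particles * traj.n_steps >= 10_000
        msd = traj.msd(lag_steps=1)
        assert msd == pytest.approx(6.0 * d * dt, rel=0.05)

    def test_fixed_seed_reproducible(self, psf):
        box = make_box(psf, duration=1e-3, timestep=1e-5, seed=42)
        a = simulate_paths([monomer(10.0, density=1.0)], box, psf)
        b = simulate_paths([monomer(10.0, density=1.0)], box, psf)
        assert np.array_equal(a.positions, b.positions)

    def test_particle_count_constant_and_box_validated(self, psf):
        small = SimulationBox(box_dimensions=(1.0, 1.0, 1.0), timestep=1e-5, duration=1e-4)
        with pytest.raises(BoxSizeError):
            simulate_paths([monomer(1.0)], small, psf)


class TestDetector:
    def test_ideal_identity(self):
        out = apply_detector([0, 3, 1], DetectorModel.ideal())
        assert np.array_equal(out, [0.0, 3.0, 1.0])

    def test_affine_gain(self):
        det = DetectorModel.analog(conversion_factor=7.0, offset=10.0)
        assert apply_detector([2], det)[0] == pytest.approx(24.0)

    def test_dark_noise_statistics(self, rng):
        det = DetectorModel.analog(7.0, offset=10.0, readout_variance=4.0)
        out = apply_detector(np.zeros(100_000), det, rng)
        assert out.mean() == pytest.approx(10.0, abs=0.1)
        assert out.var() == pytest.approx(4.0, rel=0.05)

    def test_ideal_mode_rejects_gain(self):
        with pytest.raises(ValueError):
            DetectorModel(mode="ideal_counting", conversion_factor=7.0)


def _static_trajectories(psf, n_dwells, brightness, positions, seed=5):
    """Hand-built immobile particles (positions: (n_particles, 3))."""
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    box = make_box(psf, duration=n_dwells * 1e-5, timestep=1e-5, seed=seed)
    return Trajectories(
        positions=np.broadcast_to(positions, (n_dwells + 1, n, 3)).copy(),
        brightness=np.asarray(brightness, dtype=float),
        diffusion=np.zeros(n),
        species_index=np.zeros(n, dtype=np.intp),
        box=box,
    )


class TestFCSTrace:
    def test_zero_particles_gives_background(self, psf):
        box = make_box(psf, duration=0.02, timestep=1e-5, seed=1)
        det = DetectorModel.analog(1.0, offset=5.0)
        with pytest.warns(EmptyFieldWarning):
            tr = render_fcs_trace(
                simulate_paths([monomer(1.0, density=1e-9)], box, psf), psf, 1e-5, det
            )
        assert np.all(tr.values == 5.0)

    def test_immobile_center_particle_poisson_mean(self, psf):
        q, eps = 3, 0.8
        n_dwells = 20_000
        traj = _static_trajectories(psf, n_dwells, [q * eps], [[0.0, 0.0, 0.0]])
        tr = render_fcs_trace(traj, psf, 1e-5)
        lam = q * eps
        assert tr.values.mean() == pytest.approx(lam, abs=3 * np.sqrt(lam / n_dwells))

    def test_immobile_uniform_emitters_are_pure_poisson(self, psf, rng):
        # variance/mean of shot noise about a static configuration is 1
        pos = rng.uniform(-1.0, 1.0, size=(30, 3))
        traj = _static_trajectories(psf, 50_000, np.full(30, 2.0), pos)
        tr = render_fcs_trace(traj, psf, 1e-5)
        assert tr.values.var() / tr.values.mean() == pytest.approx(1.0, rel=0.02)

    def test_streaming_trace_reproducible(self, psf):
        sp = [monomer(50.0, density=0.5)]
        a = simulate_fcs_trace(sp, psf, 1e-5, 4096, seed=9)
        b = simulate_fcs_trace(sp, psf, 1e-5, 4096, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_half_decay_near_diffusion_time(self, psf):
        # tau_D = omega_r^2 / (4 D) = 3.6e-5 s for the fast calibration dye
        d = 435.0
        tau_d = psf.omega_r**2 / (4.0 * d)
        assert tau_d == pytest.approx(3.59e-5, rel=0.01)
        from fluctra import temporal_acf

        box = make_box(psf, 500_000 * 1e-5, 1e-5, seed=21)
        sp = [monomer(d, density=50 / box.volume)]  # ~50 particles
        tr = simulate_fcs_trace(sp, psf, 1e-5, 500_000, box=box)
        acf = temporal_acf(tr, "multi_tau")
        g0 = acf.g[:2].mean()
        half_lag = acf.lags[np.nonzero(acf.g < g0 / 2)[0][0]]
        assert 0.5 * tau_d < half_lag < 2.0 * tau_d

    @pytest.mark.parametrize("q", [1, 4])
    def test_trace_moments_match_oligomer_theory(self, psf, q):
        # mean = density q eps V_3DG ; var = mean + density (q eps)^2 gamma V_3DG
        eps = 0.6
        subunit_density = 2.0
        sp = [
            ParticleSpecies(
                diffusion_coefficient=98.0,
                brightness_per_subunit=eps,
                subunit_count=q,
                number_density=subunit_density / q,
            )
        ]
        box = make_box(psf, 1_000_000 * 1e-5, 1e-5, seed=30 + q)
        tr = simulate_fcs_trace(sp, psf, 1e-5, 1_000_000, box=box)
        v3 = psf.volume_3dg
        mean_th = (subunit_density / q) * q * eps * v3
        var_th = mean_th + (subunit_density / q) * (q * eps) ** 2 * GAMMA_1P * v3
        assert tr.values.mean() == pytest.approx(mean_th, rel=0.05)
        assert tr.values.var() == pytest.approx(var_th, rel=0.07)


class TestRasterStack:
    def test_zero_particles_all_zero(self, psf, small_scan):
        with pytest.warns(EmptyFieldWarning):
            st = simulate_raster_stack(
                [monomer(1.0, density=1e-9)], psf, small_scan, seed=2
            )
        assert np.all(st.data == 0)

    def test_immobile_particle_fixed_punctum(self, psf):
        scan = ScanProtocol(shape=(16, 16), n_frames=5)
        n_dwells = int(np.ceil(scan.total_duration / scan.pixel_dwell)) + 1
        # bright static particle at the centre of pixel (row 8, col 8);
        # bright enough that shot noise cannot flip the per-frame argmax
        x = (8 + 0.5 - 8.0) * scan.pixel_size
        traj = _static_trajectories(psf, n_dwells, [5000.0], [[x, x, 0.0]])
        traj.box = SimulationBox(
            box_dimensions=traj.box.box_dimensions,
            timestep=scan.pixel_dwell,
            duration=scan.total_duration + scan.pixel_dwell,
            rng_seed=5,
        )
        traj.positions = np.broadcast_to(
            traj.positions[0], (traj.box.n_steps + 1, 1, 3)
        ).copy()
        st = render_raster_stack(traj, psf, scan)
        for f in range(st.n_frames):
            peak = np.unravel_index(np.argmax(st.data[f]), st.data[f].shape)
            assert peak == (8, 8)

    def test_variance_over_mean_is_one_plus_molecular_brightness(self, psf):
        # per-pixel temporal variance/mean -> 1 + gamma * eps_centre
        eps = 1.2
        scan = ScanProtocol(shape=(64, 64), n_frames=80)
        st = simulate_raster_stack(
            [monomer(20.0, eps=eps, density=3.0)], psf, scan, seed=8
        )
        ratio = st.data.var(axis=0) / st.data.mean(axis=0)
        assert np.median(ratio) == pytest.approx(1.0 + GAMMA_1P * eps, rel=0.10)

    def test_streaming_stack_reproducible(self, psf, small_scan):
        sp = [monomer(5.0, density=1.0)]
        a = simulate_raster_stack(sp, psf, small_scan, seed=4)
        b = simulate_raster_stack(sp, psf, small_scan, seed=4)
        assert np.array_equal(a.data, b.data)

    def test_scan_window_must_fit_box(self, psf):
        scan = ScanProtocol(shape=(64, 64), n_frames=40)
        box = SimulationBox(
            box_dimensions=(3.0, 3.0, 12.5),
            timestep=scan.pixel_dwell,
            duration=scan.total_duration,
        )
        with pytest.raises(BoxSizeError):
            simulate_raster_stack([monomer(5.0)], psf, scan, box=box)

    def test_bleaching_dims_late_frames(self, psf):
        scan = ScanProtocol(shape=(32, 32), n_frames=40)
        sp = [monomer(5.0, eps=2.0, density=3.0)]
        rate = 0.5 / scan.total_duration  # ~40% decay over the stack
        st = simulate_raster_stack(
            sp, psf, scan, bleach=BleachingModel("exponential", rate), seed=6
        )
        first = st.data[:5].mean()
        last = st.data[-5:].mean()
        assert last < 0.8 * first


class TestStationaryOccupancy:
    def test_trace_mean_matches_occupancy_theory(self, psf):
        # time-averaged intensity = sum_species q eps density V_3DG
        eps, dens = 0.7, 1.5
        sp = [monomer(98.0, eps=eps, density=dens)]
        box = make_box(psf, 1_000_000 * 1e-5, 1e-5, seed=12)
        tr = simulate_fcs_trace(sp, psf, 1e-5, 1_000_000, box=box)
        assert tr.values.mean() == pytest.approx(
            dens * eps * psf.volume_3dg, rel=0.05
        )
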