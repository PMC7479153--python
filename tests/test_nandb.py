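"""Number & brightness moment analysis and brightness normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluctra import (
    BrightnessMaps,
    DetectorCalibration,
    ImageStack,
    ScanProtocol,
    apply_detector,
    calibrate_s_factor,
    compute_nandb_maps,
    fit_b_histogram,
    normalize_brightness,
    select_pixels_by_box,
    simulate_raster_stack,
)
from fluctra.errors import (
    EmptyResultError,
    EmptySelectionError,
    NormalizationError,
)
from fluctra.psf import GAMMA_1P
from fluctra.simulate import DetectorModel, ParticleSpecies

from conftest import monomer

EPS1 = 0.16 / GAMMA_1P  # per-subunit centre brightness giving monomer B = 1.16


def _maps_from_values(b_values, intensity=None):
    b = np.asarray(b_values, dtype=float).reshape(1, -1)
    mean = np.ones_like(b) if intensity is None else np.asarray(intensity).reshape(1, -1)
    return BrightnessMaps(
        b=b, n=np.ones_like(b), mean=mean, variance=np.ones_like(b),
        masks={},
    )


@pytest.fixture(scope="module")
def nb_scan():
    return ScanProtocol(shape=(128, 128), n_frames=100)


@pytest.fixture(scope="module")
def monomer_stack(psf, nb_scan):
    """Monomeric emitters at the brightness that maps to B = 1.16."""
    return simulate_raster_stack(
        [monomer(20.0, eps=EPS1, density=10 * 0.602214076)], psf, nb_scan, seed=201
    )


class TestMaps:
    def test_constant_stack_fully_masked(self):
        scan = ScanProtocol(shape=(8, 8), n_frames=30)
        st_ = ImageStack(np.full((30, 8, 8), 5.0), scan=scan)
        with pytest.raises(EmptyResultError):
            compute_nandb_maps(st_, detrend_window=None)

    def test_fluctuation_free_pixels_are_zero_and_masked(self, rng):
        scan = ScanProtocol(shape=(8, 8), n_frames=40)
        data = rng.poisson(10.0, (40, 8, 8)).astype(float)
        data[:, :, :4] = 7.0  # half the frame static
        maps = compute_nandb_maps(ImageStack(data, scan=scan), detrend_window=None)
        assert np.all(maps.masks["fluctuation_free"][:, :4])
        assert np.all(maps.b[:, :4] == 0.0)
        assert np.all(np.isfinite(maps.b[maps.valid]))

    def test_monomer_modal_brightness(self, monomer_stack):
        maps = compute_nandb_maps(monomer_stack, detrend_window=10)
        hist = fit_b_histogram(maps)
        assert hist.center == pytest.approx(1.16, abs=0.06)

    def test_detector_correction_recovers_photon_scale(self, monomer_stack, rng):
        # push the same photon stack through an analog detector and undo it
        det = DetectorModel.analog(7.0, offset=10.0, readout_variance=4.0)
        analog = ImageStack(
            apply_detector(monomer_stack.data, det, rng), scan=monomer_stack.scan
        )
        cal = DetectorCalibration(s_factor=7.0, offset=10.0, readout_variance=4.0)
        b_analog = fit_b_histogram(compute_nandb_maps(analog, cal)).center
        b_ideal = fit_b_histogram(compute_nandb_maps(monomer_stack)).center
        assert b_analog == pytest.approx(b_ideal, rel=0.05)

    def test_number_map_consistency(self, monomer_stack, psf):
        # n = N (eps + 1) / eps recovers the occupancy of V_eff; eps from
        # pooled variance/mean (the modal estimate is a few % low, which
        # the 1/eps factor would amplify)
        maps = compute_nandb_maps(monomer_stack, detrend_window=10)
        v = maps.valid
        eps = maps.variance[v].sum() / maps.mean[v].sum() - 1.0
        n_app = np.median(maps.n[v])
        n_true = 10 * 0.602214076 * psf.volume_eff
        assert n_app * (eps + 1) / eps == pytest.approx(n_true, rel=0.20)

    def test_detrending_corrects_bleached_brightness(self, rng):
        # bright Poisson pixels (B = 1) with a 10% multiplicative decay:
        # the drift inflates raw B by (0.1 I)^2/12 / I; detrending must
        # remove >= 5x more of that excess than it costs
        lam = 50.0
        n = 100
        scan = ScanProtocol(shape=(64, 64), n_frames=n)
        env = np.exp(-0.105 * np.arange(n) / (n - 1))  # 10% total decay
        clean = ImageStack(rng.poisson(lam, (n, 64, 64)).astype(float), scan=scan)
        bleached = ImageStack(
            rng.poisson(lam * env[:, None, None], (n, 64, 64)).astype(float),
            scan=scan,
        )
        b_ref = fit_b_histogram(compute_nandb_maps(clean, detrend_window=10)).center
        b_raw = fit_b_histogram(
            compute_nandb_maps(bleached, detrend_window=None)
        ).center
        b_det = fit_b_histogram(compute_nandb_maps(bleached, detrend_window=10)).center
        assert b_raw - b_ref > 0.02  # the drift visibly inflates raw B
        assert abs(b_det - b_ref) < abs(b_raw - b_ref) / 5.0


# the mode of a per-pixel variance estimate sits ~2/n_frames below the
# truth, and 1/eps amplifies that in B - 1; 400 frames keep the residual
# bias of the *ratio* well inside the 10% band
LIN_SCAN = ScanProtocol(shape=(96, 96), n_frames=400)


@pytest.fixture(scope="module")
def b_monomer_400(psf):
    st = simulate_raster_stack(
        [ParticleSpecies(20.0, EPS1, 1, 10 * 0.602214076)], psf, LIN_SCAN, seed=209
    )
    return fit_b_histogram(compute_nandb_maps(st)).center


class TestOligomerLinearity:
    @pytest.mark.parametrize("q", [2, 4])
    def test_brightness_additive_in_subunits(self, psf, b_monomer_400, q):
        # q-mer: modal B - 1 = q * (monomer modal B - 1) within 10%
        qmer = simulate_raster_stack(
            [ParticleSpecies(20.0 / q, EPS1, q, 10 * 0.602214076 / q)],
            psf, LIN_SCAN, seed=210 + q,
        )
        bq = fit_b_histogram(compute_nandb_maps(qmer)).center
        assert (bq - 1.0) == pytest.approx(q * (b_monomer_400 - 1.0), rel=0.10)


class TestSCalibration:
    def test_dark_stack_statistics(self, rng):
        scan = ScanProtocol(shape=(32, 32), n_frames=60)
        dark = ImageStack(rng.normal(10.0, 2.0, (60, 32, 32)), scan=scan)
        cal = calibrate_s_factor(dark)
        assert cal.offset == pytest.approx(10.0, rel=0.01)
        assert cal.readout_variance == pytest.approx(4.0, rel=0.05)

    def test_gain_from_graded_illumination(self, rng):
        s_true = 7.0
        scan = ScanProtocol(shape=(32, 32), n_frames=60)
        det = DetectorModel.analog(s_true, offset=10.0, readout_variance=4.0)
        dark = ImageStack(apply_detector(np.zeros((60, 32, 32)), det, rng), scan=scan)
        graded = [
            ImageStack(
                apply_detector(rng.poisson(lam, (60, 32, 32)), det, rng), scan=scan
            )
            for lam in (1.0, 3.0, 6.0)
        ]
        cal = calibrate_s_factor(dark, graded)
        assert cal.s_factor == pytest.approx(s_true, rel=0.05)
        assert 6.8 <= round(cal.s_factor, 1) <= 7.3  # instrument plausibility band

    def test_ideal_counting_dark_stack(self):
        scan = ScanProtocol(shape=(8, 8), n_frames=30)
        cal = calibrate_s_factor(ImageStack(np.zeros((30, 8, 8)), scan=scan))
        assert cal.offset == 0.0
        assert cal.readout_variance == 0.0
        assert cal.s_factor == 1.0


class TestHistogram:
    def test_recovers_gaussian_population(self, rng):
        maps = _maps_from_values(rng.normal(1.65, 0.25, 65536))
        hist = fit_b_histogram(maps)
        assert hist.center == pytest.approx(1.65, abs=0.02)
        assert hist.width == pytest.approx(0.25, rel=0.10)

    def test_delta_distribution_is_bin_limited(self):
        maps = _maps_from_values(np.full(2000, 1.5))
        hist = fit_b_histogram(maps, bin_width=0.01)
        assert hist.center == pytest.approx(1.5, abs=0.01)
        assert hist.width <= 0.05

    def test_mode_centring_tracks_majority_population(self, rng):
        values = np.concatenate(
            [rng.normal(1.2, 0.1, 40000), rng.normal(2.0, 0.3, 10000)]
        )
        maps = _maps_from_values(values)
        mode_fit = fit_b_histogram(maps)
        # free-centre single Gaussian gets pulled towards the bright tail
        from scipy.optimize import curve_fit

        counts, edges = np.histogram(values, bins=200)
        centers = 0.5 * (edges[:-1] + edges[1:])
        popt, _ = curve_fit(
            lambda x, a, c, s: a * np.exp(-0.5 * ((x - c) / s) ** 2),
            centers, counts, p0=[counts.max(), values.mean(), values.std()],
        )
        assert abs(mode_fit.center - 1.2) < abs(popt[1] - 1.2)

    def test_requires_enough_pixels(self):
        with pytest.raises(ValueError):
            fit_b_histogram(_maps_from_values(np.ones(10) + 0.1))


class TestSelection:
    def test_full_range_captures_everything(self, rng):
        b = rng.normal(1.3, 0.1, 5000)
        i = rng.uniform(1, 2, 5000)
        maps = _maps_from_values(b, i)
        mask, summary = select_pixels_by_box(maps, (-10, 10), (0, 10))
        assert summary["fraction"] == pytest.approx(1.0)
        assert summary["mean_b"] == pytest.approx(b.mean(), rel=1e-9)

    def test_empty_selection_raises(self, rng):
        maps = _maps_from_values(rng.normal(1.3, 0.1, 5000))
        with pytest.raises(EmptySelectionError):
            select_pixels_by_box(maps, (5.0, 6.0), (0.0, 10.0))

    def test_box_around_monomer_mode_captures_that_population(self, rng):
        n_mono, n_tet = 8000, 2000
        b = np.concatenate(
            [rng.normal(1.16, 0.05, n_mono), rng.normal(1.64, 0.08, n_tet)]
        )
        maps = _maps_from_values(b)
        _, summary = select_pixels_by_box(maps, (1.0, 1.35), (0.0, 2.0))
        assert summary["fraction"] >= n_mono / (n_mono + n_tet) * 0.95


class TestNormalization:
    def test_reported_tetramer_worked_example(self):
        # the printed B-histogram maxima give a subunit count of ~4
        norm = normalize_brightness(1.65, 1.16)
        assert norm.value == pytest.approx(4.06, abs=0.01)

    def test_monomer_identity_and_dimer_doubling(self):
        assert normalize_brightness(1.3, 1.3).value == pytest.approx(1.0)
        assert normalize_brightness(2 * 1.3 - 1, 1.3).value == pytest.approx(2.0)

    def test_reference_below_one_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_brightness(1.5, 0.99)

    @given(q=st.integers(1, 12), eps=st.floats(0.05, 1.0))
    @settings(max_examples=40, deadline=None)
    def test_linearity_in_subunit_count(self, q, eps):
        b_ref = 1.0 + eps
        b_q = 1.0 + q * eps
        assert normalize_brightness(b_q, b_ref).value == pytest.approx(float(q), rel=1e-9)
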