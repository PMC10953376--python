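"""Estimators and the closed-loop controller."""

import numpy as np
import pytest
from scipy.interpolate import PchipInterpolator

import duofocus as df
from duofocus.estimation import AmbiguityError, OutOfRangeError


def brute_force_single_shot(metric_pair, calib, step=0.001):
    """Independent oracle: exhaustive scan of the weighted residual on a
    very fine defocus grid built directly from the calibration arrays."""
    lo, hi = calib.singleshot_range
    z = np.arange(lo, hi + step / 2, step)
    cf = PchipInterpolator(calib.z_grid, calib.curve_fast)(z)
    cs = PchipInterpolator(calib.z_grid, calib.curve_slow)(z)
    r = ((metric_pair.m_fast - cf) / calib.noise_scale_fast) ** 2 + \
        ((metric_pair.m_slow - cs) / calib.noise_scale_slow) ** 2
    return float(z[np.argmin(r)])


def brute_force_slow_inversion(m_slow, calib, step=0.001):
    """Both slow-curve preimages of a metric value, by exhaustive scan."""
    lo, hi = calib.twostep_range
    z = np.arange(lo, hi + step / 2, step)
    cs = PchipInterpolator(calib.z_grid, calib.curve_slow)(z)
    ipk = int(np.argmax(cs))
    left = z[:ipk][np.argmin(np.abs(cs[:ipk] - m_slow))]
    right = z[ipk:][np.argmin(np.abs(cs[ipk:] - m_slow))]
    return float(left), float(right)


class TestSingleShot:
    @pytest.mark.parametrize("z", [10.0, -10.0, 25.0, -25.0])
    def test_noiseless_matches_brute_force_oracle(self, mini_setup,
                                                  mini_calib, z):
        f = df.render_frame(z, mini_setup["beam"], mini_setup["camera"],
                            mini_setup["background"], noise=False)
        m = df.compute_metrics(f, mini_calib.background)
        est = df.estimate_single_shot(f, mini_calib)
        assert est.valid and est.mode == "single_shot"
        assert est.z_hat == pytest.approx(brute_force_single_shot(m, mini_calib),
                                          abs=0.05)
        assert est.z_hat == pytest.approx(z, abs=0.05)
        assert np.sign(est.z_hat) == np.sign(z)

    def test_sign_flips_with_defocus_sign(self, mini_setup, mini_calib):
        ests = {}
        for z in (12.0, -12.0):
            f = df.render_frame(z, mini_setup["beam"], mini_setup["camera"],
                                mini_setup["background"], noise=False)
            ests[z] = df.estimate_single_shot(f, mini_calib).z_hat
        assert ests[12.0] == pytest.approx(-ests[-12.0], abs=0.1)

    def test_beyond_region_invalid(self, mini_setup, mini_calib):
        f = df.render_frame(45.0, mini_setup["beam"], mini_setup["camera"],
                            mini_setup["background"], noise=False)
        est = df.estimate_single_shot(f, mini_calib)
        assert not est.valid
        assert not est.in_singleshot_region
        assert np.isnan(est.z_hat)

    def test_noiseless_sign_always_correct_across_region(self, mini_setup,
                                                         mini_calib):
        zs = np.arange(0.5, 30.0, 1.5)
        for z in np.concatenate([zs, -zs]):
            f = df.render_frame(z, mini_setup["beam"], mini_setup["camera"],
                                mini_setup["background"], noise=False)
            est = df.estimate_single_shot(f, mini_calib)
            assert est.valid
            assert np.sign(est.z_hat) == np.sign(z), f"sign wrong at z={z}"

    def test_error_spread_grows_with_defocus(self, mini_setup, mini_calib):
        rng = np.random.default_rng(0)
        spreads = {}
        for z in (2.0, 30.0):
            errs = []
            for _ in range(25):
                f = df.render_frame(z, mini_setup["beam"],
                                    mini_setup["camera"],
                                    mini_setup["background"], noise=True,
                                    seed=rng)
                errs.append(df.estimate_single_shot(f, mini_calib).z_hat - z)
            spreads[z] = np.std(errs)
        assert spreads[30.0] > spreads[2.0]


class TestTwoStep:
    @pytest.mark.parametrize("z", [34.0, -33.0])
    def test_noiseless_matches_slow_curve_inversion(self, mini_setup,
                                                    mini_calib, z):
        f1 = df.render_frame(z, mini_setup["beam"], mini_setup["camera"],
                             mini_setup["background"], noise=False)
        f2 = df.render_frame(z + 3.0, mini_setup["beam"], mini_setup["camera"],
                             mini_setup["background"], noise=False)
        est = df.estimate_two_step(f1, f2, 3.0, mini_calib)
        assert est.mode == "two_step" and est.valid
        m1 = df.compute_metrics(f1, mini_calib.background)
        cands = brute_force_slow_inversion(m1.m_slow, mini_calib)
        assert min(abs(est.z_hat - c) for c in cands) < 0.05
        assert est.z_hat == pytest.approx(z, abs=0.5)

    def test_beyond_two_step_range_raises(self, mini_setup, mini_calib):
        f1 = df.render_frame(50.0, mini_setup["beam"], mini_setup["camera"],
                             mini_setup["background"], noise=False)
        f2 = df.render_frame(53.0, mini_setup["beam"], mini_setup["camera"],
                             mini_setup["background"], noise=False)
        with pytest.raises(OutOfRangeError):
            df.estimate_two_step(f1, f2, 3.0, mini_calib)

    def test_tiny_delta_ambiguous(self, mini_setup, mini_calib):
        f1 = df.render_frame(20.0, mini_setup["beam"], mini_setup["camera"],
                             mini_setup["background"], noise=False)
        f2 = df.render_frame(20.001, mini_setup["beam"], mini_setup["camera"],
                             mini_setup["background"], noise=False)
        with pytest.raises(AmbiguityError):
            df.estimate_two_step(f1, f2, 0.001, mini_calib)

    def test_zero_delta_rejected(self, mini_setup, mini_calib):
        f = df.render_frame(20.0, mini_setup["beam"], mini_setup["camera"],
                            mini_setup["background"], noise=False)
        with pytest.raises(ValueError):
            df.estimate_two_step(f, f, 0.0, mini_calib)


class TestAutofocusPolicy:
    def test_in_region_resolved_in_one_acquisition(self, mini_setup,
                                                   mini_calib):
        scope = df.SimulatedMicroscope(5.0, mini_setup["beam"],
                                       mini_setup["camera"],
                                       mini_setup["background"], seed=1)
        est = df.autofocus(scope, mini_calib)
        assert scope.acquisitions == 1
        assert est.mode == "single_shot"
        assert abs(scope.defocus) < 0.2

    def test_far_defocus_recovered_via_two_step(self, mini_setup, mini_calib):
        scope = df.SimulatedMicroscope(38.0, mini_setup["beam"],
                                       mini_setup["camera"],
                                       mini_setup["background"], seed=2)
        est = df.autofocus(scope, mini_calib)
        assert scope.acquisitions == 3
        assert est.mode == "single_shot"
        assert abs(scope.defocus) < 0.5

    def test_beyond_all_ranges_unrecoverable(self, mini_setup, mini_calib):
        scope = df.SimulatedMicroscope(50.0, mini_setup["beam"],
                                       mini_setup["camera"],
                                       mini_setup["background"], noise=False)
        with pytest.raises(df.UnrecoverableDefocusError):
            df.autofocus(scope, mini_calib)

    def test_idempotent_within_noise_floor(self, mini_setup, mini_calib):
        scope = df.SimulatedMicroscope(15.0, mini_setup["beam"],
                                       mini_setup["camera"],
                                       mini_setup["background"], seed=3)
        df.autofocus(scope, mini_calib)
        first_residual = scope.defocus
        df.autofocus(scope, mini_calib)
        assert abs(scope.defocus) <= abs(first_residual) + 0.1


class TestControllerConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            df.ControllerConfig(update_interval=0.0)
        with pytest.raises(ValueError):
            df.ControllerConfig(gain=0.0)
        with pytest.raises(ValueError):
            df.ControllerConfig(gain=1.5)
        with pytest.raises(ValueError):
            df.ControllerConfig(z_limits=(5.0, -5.0))


class TestFocusLock:
    def test_fixed_point_without_drift_or_noise(self, mini_setup, mini_calib):
        log = df.run_focus_lock(mini_calib, df.ControllerConfig(), 5.0,
                                beam=mini_setup["beam"],
                                camera=mini_setup["camera"],
                                background=mini_setup["background"],
                                drift_model="linear",
                                drift_params={"rate": 0.0}, noise=False,
                                seed=0)
        assert not log.lock_lost
        # after the first (bias-removing) update, corrections vanish
        assert np.all(np.abs(log.correction[1:]) < 1e-3)
        assert np.all(np.abs(log.residual) < 0.01)

    def test_deterministic_given_seed(self, mini_setup, mini_calib):
        kw = dict(beam=mini_setup["beam"], camera=mini_setup["camera"],
                  background=mini_setup["background"],
                  drift_model="sinusoidal",
                  drift_params={"amplitude": 1.0, "period": 60.0},
                  noise=True, seed=11)
        a = df.run_focus_lock(mini_calib, df.ControllerConfig(), 5.0, **kw)
        b = df.run_focus_lock(mini_calib, df.ControllerConfig(), 5.0, **kw)
        assert np.array_equal(a.residual, b.residual)
        assert np.array_equal(a.z_hat, b.z_hat)

    def test_linear_drift_tracked_to_small_residual(self, mini_setup,
                                                    mini_calib):
        # 1 um/min drift: residual bounded by per-update drift + estimator
        log = df.run_focus_lock(mini_calib, df.ControllerConfig(), 20.0,
                                beam=mini_setup["beam"],
                                camera=mini_setup["camera"],
                                background=mini_setup["background"],
                                drift_model="linear",
                                drift_params={"rate": 1.0 / 60.0},
                                noise=False, seed=0)
        assert not log.lock_lost
        assert np.max(np.abs(log.residual[2:])) < 0.05

    def test_drift_beyond_limits_loses_lock(self, mini_setup, mini_calib):
        log = df.run_focus_lock(
            mini_calib, df.ControllerConfig(z_limits=(-5.0, 5.0)), 60.0,
            beam=mini_setup["beam"], camera=mini_setup["camera"],
            background=mini_setup["background"], drift_model="linear",
            drift_params={"rate": 1.0}, noise=False, seed=0)
        assert log.lock_lost
        assert log.timestamp.size < 60.0 / 0.25

    def test_log_csv_roundtrip(self, tmp_path, mini_setup, mini_calib):
        log = df.run_focus_lock(mini_calib, df.ControllerConfig(), 3.0,
                                beam=mini_setup["beam"],
                                camera=mini_setup["camera"],
                                background=mini_setup["background"],
                                drift_model="linear",
                                drift_params={"rate": 0.0}, noise=True,
                                seed=5)
        path = tmp_path / "log.csv"
        log.to_csv(path)
        back = df.FocusLog.from_csv(path)
        assert np.allclose(back.residual, log.residual)
        assert np.allclose(back.timestamp, log.timestamp)
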