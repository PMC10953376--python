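"""Shared fixtures.

Two simulator scales are used: ``mini`` (256x256 sensor, small spot) keeps
unit tests fast and exercises the same code paths; ``default`` is the
shipped configuration whose frozen thresholds reproduce the reference
instrument's operating ranges, used by the acceptance-level tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import duofocus as df

MINI_FRACTIONS = (0.25, 0.55)
MINI_NOISE_SCALES = (0.011, 0.0033)


@pytest.fixture(scope="session")
def mini_setup():
    beam = df.BeamModel(w0_fast=4.0, w0_slow=12.0)
    camera = df.CameraModel(width=256, height=256, read_noise=2.0)
    background = df.BackgroundField(np.full((256, 256), 5.0))
    return {"beam": beam, "camera": camera, "background": background}


@pytest.fixture(scope="session")
def mini_calib(mini_setup):
    zg = np.arange(-55.0, 55.001, 0.5)
    frames = df.render_zstack(zg, mini_setup["beam"], mini_setup["camera"],
                              mini_setup["background"], noise=False)
    return df.build_calibration(
        frames, mini_setup["background"],
        fraction_fast=MINI_FRACTIONS[0], fraction_slow=MINI_FRACTIONS[1],
        noise_scales=MINI_NOISE_SCALES)


@pytest.fixture(scope="session")
def default_setup():
    beam = df.default_beam()
    camera = df.default_camera()
    background = df.default_background(camera)
    return {"beam": beam, "camera": camera, "background": background}


@pytest.fixture(scope="session")
def default_calib(default_setup):
    zg = np.arange(-80.0, 80.001, 0.5)
    frames = df.render_zstack(zg, default_setup["beam"],
                              default_setup["camera"],
                              default_setup["background"], noise=False)
    return df.build_calibration(frames, default_setup["background"])


@pytest.fixture()
def mini_config_json(tmp_path, mini_setup):
    """RunConfig JSON for CLI tests on the mini scale."""
    cfg = df.RunConfig(
        beam=mini_setup["beam"], camera=mini_setup["camera"],
        background_pedestal=5.0, background_blob_amplitude=0.0,
        calibration_z_min=-55.0, calibration_z_max=55.0,
        calibration_fraction_fast=MINI_FRACTIONS[0],
        calibration_fraction_slow=MINI_FRACTIONS[1],
        metric_noise_fast=MINI_NOISE_SCALES[0],
        metric_noise_slow=MINI_NOISE_SCALES[1])
    path = tmp_path / "mini_config.json"
    cfg.to_json(path)
    return path
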