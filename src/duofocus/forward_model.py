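"""Synthetic autofocus-camera frames of a dual-confocal-parameter laser spot.

The autofocus beam is shaped by two crossed cylindrical lenses so that its two
orthogonal axes focus with different confocal parameters, and one axis is
deliberately offset ~2 um axially from the other.  The camera therefore sees
an elliptical spot whose two widths depend differently on coverslip defocus
``z``; this asymmetry is what later allows sign-and-magnitude defocus readout
from a single frame.

Model: each axis follows the Gaussian-beam width law
``sigma(z) = w0 * sqrt(1 + (dz / zr)**2)`` with its own waist ``w0`` and
effective axial half-range ``zr`` (sample coordinates), the slow axis being
offset by ``focus_offset``.  The expectation image is a separable elliptical
Gaussian whose integrated photon count is independent of ``z`` (the spot only
spreads and dims, it does not lose energy), plus a fixed additive background
standing in for spurious reflections.  Noise is Poisson photon noise followed
by Gaussian read noise and integer quantisation.

Axial sign convention (shared by every module): ``z > 0`` means the
objective-coverslip separation is larger than at the fast-axis focus, which
defines ``z = 0``.  Pixel indexing is 0-based row-major; the "fast" axis is
the image column coordinate, so the fast-axis profile is obtained by
collapsing rows.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "BeamModel",
    "CameraModel",
    "BackgroundField",
    "Frame",
    "TruncationError",
    "spot_widths",
    "expectation_image",
    "render_frame",
    "render_zstack",
    "drift_trajectory",
    "default_beam",
    "default_camera",
    "default_background",
    "write_stack",
    "read_stack",
]

# Expectation level (photons) above which the Poisson draw is replaced by its
# normal approximation; below it the draw is exact.
_POISSON_NORMAL_THRESHOLD = 32.0
# Spot contribution (photons) below which a pixel is treated as pure
# background by the renderer's cropping fast path.
_SPOT_CROP_LEVEL = 1e-3


@dataclass(frozen=True)
class BeamModel:
    """Optical parameters of the dual-confocal-parameter autofocus beam.

    Waists are expressed in camera-plane pixels (the reported spot
    coordinates; the camera-plane scale is ``CameraModel.um_per_px``), axial
    quantities in micrometres of sample-side defocus.  ``zr_fast < zr_slow``:
    the fast axis defocuses faster and carries the high-precision,
    short-range information; the slow axis covers the long range.
    ``focus_offset`` is the axial separation between the two best-focus
    planes (slow-axis focus at ``z = focus_offset``), the symmetry-breaking
    ingredient that encodes the sign of defocus.
    """

    w0_fast: float = 12.0
    w0_slow: float = 48.0
    zr_fast: float = 8.0
    zr_slow: float = 25.0
    focus_offset: float = 2.0
    peak_photons: float = 1.0e4
    wavelength_nm: float = 930.0

    def __post_init__(self) -> None:
        if not (self.w0_fast > 0 and self.w0_slow > 0):
            raise ValueError("beam waists must be positive")
        if not (0 < self.zr_fast < self.zr_slow):
            raise ValueError("need 0 < zr_fast < zr_slow")
        if not np.isfinite(self.focus_offset):
            raise ValueError("focus_offset must be finite")
        if self.peak_photons <= 0:
            raise ValueError("peak_photons must be positive")


@dataclass(frozen=True)
class CameraModel:
    """Autofocus camera: geometry, digitisation and read noise."""

    width: int = 1024
    height: int = 1536
    pixel_value_max: int = 65535
    read_noise: float = 2.0
    gain: float = 1.0
    bit_depth: int = 16
    um_per_px: float = 1.0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError("sensor must be at least 64x64")
        if self.read_noise < 0:
            raise ValueError("read_noise must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be positive")


@dataclass(frozen=True)
class BackgroundField:
    """Fixed, z-independent background from spurious reflections.

    The low-coherence source makes stray back-reflections add incoherently,
    so they contribute a static intensity pattern rather than moving fringes;
    the default is a broad dim blob on a constant pedestal.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("background must be a 2-D image")
        if np.any(px < 0):
            raise ValueError("background values must be >= 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class Frame:
    """One autofocus camera image with acquisition metadata.

    ``z_true`` is the actual coverslip defocus used to synthesise the frame
    (``nan`` when unknown, as for hardware frames); ``z_commanded`` the
    axial-drive position.
    """

    pixels: np.ndarray
    z_true: float = float("nan")
    z_commanded: float = float("nan")
    timestamp: float = 0.0
    exposure_s: float = 0.01

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


class TruncationError(ValueError):
    """The spot significantly overfills the sensor (out-of-model defocus)."""


def default_beam() -> BeamModel:
    return BeamModel()


def default_camera() -> CameraModel:
    return CameraModel()


def default_background(camera: CameraModel | None = None) -> BackgroundField:
    """Shipped default background: constant pedestal plus an off-centre blob."""
    cam = camera or default_camera()
    y = np.arange(cam.height)[:, None] - (cam.height - 1) / 2.0 - 120.0
    x = np.arange(cam.width)[None, :] - (cam.width - 1) / 2.0 + 90.0
    blob = 15.0 * np.exp(-(x * x + y * y) / (2.0 * 180.0**2))
    return BackgroundField(20.0 + blob)


def spot_widths(z: float, beam: BeamModel) -> tuple[float, float]:
    """Per-axis Gaussian spot standard deviations (camera px) at defocus ``z``.

    Each axis is minimal exactly at its own focus: the fast axis at ``z = 0``,
    the slow axis at ``z = focus_offset``.
    """
    sigma_fast = beam.w0_fast * np.sqrt(1.0 + (z / beam.zr_fast) ** 2)
    sigma_slow = beam.w0_slow * np.sqrt(
        1.0 + ((z - beam.focus_offset) / beam.zr_slow) ** 2
    )
    return float(sigma_fast), float(sigma_slow)


def total_photons(beam: BeamModel) -> float:
    """Integrated spot photons per frame (independent of defocus)."""
    # peak_photons is the brightest pixel of the in-focus fast axis, i.e. at
    # z = 0 where sigma_fast = w0_fast and sigma_slow is slightly inflated
    # by the 2 um focus offset.
    sf0, ss0 = spot_widths(0.0, beam)
    return beam.peak_photons * 2.0 * np.pi * sf0 * ss0


def expectation_image(
    z: float, beam: BeamModel, camera: CameraModel
) -> np.ndarray:
    """Noise-free expected spot image (photons), background excluded.

    Separable elliptical Gaussian centred on the sensor; the integrated
    photon count equals :func:`total_photons` for every ``z`` (energy
    conservation - only the peak dims as the spot spreads).

    Raises
    ------
    TruncationError
        If either spot width exceeds a quarter of the corresponding sensor
        dimension, signalling out-of-model defocus.
    """
    sf, ss = spot_widths(z, beam)
    if sf > camera.width / 4.0 or ss > camera.height / 4.0:
        raise TruncationError(
            f"spot ({sf:.0f} x {ss:.0f} px) overfills sensor "
            f"{camera.width} x {camera.height} at z = {z:+.1f} um"
        )
    photons = total_photons(beam)
    x = np.arange(camera.width) - (camera.width - 1) / 2.0
    y = np.arange(camera.height) - (camera.height - 1) / 2.0
    gx = np.exp(-(x * x) / (2.0 * sf * sf)) / (np.sqrt(2.0 * np.pi) * sf)
    gy = np.exp(-(y * y) / (2.0 * ss * ss)) / (np.sqrt(2.0 * np.pi) * ss)
    return photons * np.outer(gy, gx)


def _quantize(img: np.ndarray, camera: CameraModel) -> np.ndarray:
    return np.clip(np.round(img), 0, camera.pixel_value_max)


def render_frame(
    z: float,
    beam: BeamModel,
    camera: CameraModel,
    background: BackgroundField | None = None,
    noise: bool = True,
    seed: int | np.random.Generator | None = None,
    timestamp: float = 0.0,
    z_commanded: float | None = None,
) -> Frame:
    """Render one autofocus camera frame at coverslip defocus ``z`` (um).

    With ``noise=True`` the pixel values are
    ``quantize(gain * Poisson(spot + background) + N(0, read_noise))`` clipped
    to the camera range; two calls with the same seed produce identical
    frames.  With ``noise=False`` the quantised expectation image is
    returned.  For speed, pixels far from the spot (pure background) are
    drawn from the matching normal approximation, as are pixels whose
    expectation exceeds ~32 photons; low-count pixels use exact Poisson
    draws.
    """
    if background is not None and background.shape != (camera.height, camera.width):
        raise ValueError("background dimensions do not match the camera")
    mu_spot = expectation_image(z, beam, camera)
    bg = background.pixels if background is not None else 0.0
    if not noise:
        pixels = _quantize(camera.gain * (mu_spot + bg), camera)
        return Frame(pixels, z_true=z, timestamp=timestamp,
                     z_commanded=z if z_commanded is None else z_commanded)

    rng = np.random.default_rng(seed)
    rn = camera.read_noise / camera.gain  # read noise in photon-equivalents
    if background is not None:
        # Far from the spot the expectation is just the background field;
        # draw those pixels in one vectorised pass (normal approximation is
        # exact in effect there since the metrics average >1e3 pixels).
        rows = np.flatnonzero(mu_spot.max(axis=1) > _SPOT_CROP_LEVEL)
        cols = np.flatnonzero(mu_spot.max(axis=0) > _SPOT_CROP_LEVEL)
        img = rng.normal(bg, np.sqrt(bg + rn * rn))
        if rows.size and cols.size:
            r0, r1 = int(rows[0]), int(rows[-1]) + 1
            c0, c1 = int(cols[0]), int(cols[-1]) + 1
            sub = mu_spot[r0:r1, c0:c1] + (
                bg[r0:r1, c0:c1] if isinstance(bg, np.ndarray) else bg
            )
            img[r0:r1, c0:c1] = _draw_counts(sub, rn, rng)
    else:
        img = _draw_counts(mu_spot, rn, rng)
    pixels = _quantize(camera.gain * img, camera)
    return Frame(pixels, z_true=z, timestamp=timestamp,
                 z_commanded=z if z_commanded is None else z_commanded)


def _draw_counts(mu: np.ndarray, read_noise: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson(+normal approx) photon draw plus Gaussian read noise."""
    out = np.empty_like(mu)
    big = mu >= _POISSON_NORMAL_THRESHOLD
    out[big] = rng.normal(mu[big], np.sqrt(mu[big]))
    out[~big] = rng.poisson(mu[~big])
    if read_noise > 0:
        out += rng.normal(0.0, read_noise, mu.shape)
    return out


def render_zstack(
    z_values: Sequence[float],
    beam: BeamModel,
    camera: CameraModel,
    background: BackgroundField | None = None,
    noise: bool = True,
    seed: int | None = None,
    dt: float = 0.0,
) -> list[Frame]:
    """Render one frame per ``z`` with independent noise draws.

    ``z_values`` must be strictly monotone (it emulates a continuous axial
    translation of the coverslip through focus).
    """
    zs = np.asarray(list(z_values), dtype=float)
    if zs.size == 0:
        return []
    if zs.size > 1:
        d = np.diff(zs)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("z_values must be strictly monotone")
    rng = np.random.default_rng(seed)
    return [
        render_frame(float(z), beam, camera, background, noise=noise,
                     seed=rng, timestamp=i * dt)
        for i, z in enumerate(zs)
    ]


def drift_trajectory(
    model: str,
    params: dict,
    duration: float,
    dt: float,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Axial drift time series emulating slow thermal/mechanical focus drift.

    Returns ``(t, z)`` with ``t = 0, dt, ..., <= duration``.  Models:

    - ``linear``: ``rate * t`` with ``rate`` in um/s;
    - ``sinusoidal``: ``amplitude * sin(2*pi*t / period)``;
    - ``random_walk``: cumulative Gaussian steps of ``step_std`` um each.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must be at least dt")
    t = np.arange(0.0, duration + dt / 2.0, dt)
    if model == "linear":
        z = params.get("rate", 0.0) * t
    elif model == "sinusoidal":
        amp = params.get("amplitude", 1.0)
        period = params.get("period", 600.0)
        z = amp * np.sin(2.0 * np.pi * t / period)
    elif model == "random_walk":
        rng = np.random.default_rng(seed)
        steps = rng.normal(0.0, params.get("step_std", 0.01), t.size)
        steps[0] = 0.0
        z = np.cumsum(steps)
    else:
        raise ValueError(f"unknown drift model {model!r}")
    return t, np.asarray(z, dtype=float)


# ---------------------------------------------------------------------------
# Frame I/O: multi-page 16-bit grayscale TIFF plus a sidecar CSV of metadata.
# ---------------------------------------------------------------------------

def write_stack(frames: Sequence[Frame], tiff_path: str | Path,
                csv_path: str | Path | None = None) -> None:
    """Write frames as a multi-page 16-bit TIFF with a z-metadata CSV."""
    tiff_path = Path(tiff_path)
    data = np.stack([f.pixels.astype(np.uint16) for f in frames])
    tifffile.imwrite(tiff_path, data, photometric="minisblack")
    csv_path = Path(csv_path) if csv_path else tiff_path.with_suffix(".csv")
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "z_true_um", "z_commanded_um", "timestamp_s"])
        for i, f in enumerate(frames):
            w.writerow([i, f.z_true, f.z_commanded, f.timestamp])


def read_stack(tiff_path: str | Path,
               csv_path: str | Path | None = None) -> list[Frame]:
    """Read a frame stack written by :func:`write_stack`."""
    tiff_path = Path(tiff_path)
    data = tifffile.imread(tiff_path)
    if data.ndim == 2:
        data = data[None]
    csv_path = Path(csv_path) if csv_path else tiff_path.with_suffix(".csv")
    meta: dict[int, tuple[float, float, float]] = {}
    if csv_path.exists():
        with open(csv_path, newline="") as fh:
            for row in csv.DictReader(fh):
                meta[int(row["index"])] = (
                    float(row["z_true_um"]),
                    float(row["z_commanded_um"]),
                    float(row["timestamp_s"]),
                )
    frames = []
    for i, px in enumerate(data):
        zt, zc, ts = meta.get(i, (float("nan"), float("nan"), 0.0))
        frames.append(Frame(px.astype(float), z_true=zt, z_commanded=zc,
                            timestamp=ts))
    return frames
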