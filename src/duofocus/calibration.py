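"""Calibration: background acquisition and the metric-vs-defocus look-up table.

A single z-stack of autofocus camera frames, recorded while the coverslip is
translated through focus, yields one metric curve per axis.  The fast-axis
curve peaks at ``z = 0``, the slow-axis curve at ``z = focus_offset``; both
fall off monotonically away from their peaks, so together they form an
invertible map from metric space back to defocus.  Thresholds on the metric
values delimit the operating regions: the single-shot region (fast curve
above threshold, closed-loop capable) and the wider two-step region (slow
curve above threshold).

Threshold rules
---------------
``fraction`` (default): thresholds are fixed fractions of each curve's peak,
frozen in the shipped configuration so that the default simulator yields the
operating ranges of the reference instrument (single-shot ~ +-37.5 um,
two-step reaching -68/+72 um around the slow peak).  ``background``:
thresholds from the metric statistics of pure-background frames
(mean + 5 std); with the spectral-FWHM metric this distribution is broad and
heavy-tailed (a noise spectrum has no defined width), so the rule is offered
for experimentation rather than as the default.  An intensity floor derived
from background frames (or a frozen default) guards validity decisions
against pure-noise frames regardless of rule.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .forward_model import BackgroundField, Frame
from .metrics import compute_metrics

__all__ = [
    "CalibrationTable",
    "CalibrationError",
    "SchemaError",
    "acquire_background",
    "build_calibration",
    "save_calibration",
    "load_calibration",
    "DEFAULT_FRACTION_FAST",
    "DEFAULT_FRACTION_SLOW",
    "DEFAULT_NOISE_SCALES",
]

SCHEMA_VERSION = 1

# Fraction-of-peak thresholds, frozen once for the shipped default simulator
# configuration; they place the single-shot edges at ~ +-37.75 um and the
# two-step edges at -68.5/+72.5 um (the slow-axis focus sits at +2 um, so
# its region is symmetric about +2, not 0).
DEFAULT_FRACTION_FAST = 0.2073
DEFAULT_FRACTION_SLOW = 0.3343

# Per-axis metric noise std (frequency bins) of the shipped default
# configuration under its default noise model, measured once from repeated
# frames; used to scale metric residuals when a calibration stack has no
# replicate frames to estimate them from.
DEFAULT_NOISE_SCALES = (0.0074, 0.0028)

# Default intensity floor: mean background-subtracted counts required before
# a frame can be considered to contain the autofocus spot at all.
DEFAULT_INTENSITY_FLOOR = 1.0

# Minimum noise-scaled metric-space separation demanded between calibration
# grid points inside the single-shot region (injectivity guard).
_INJECTIVITY_FLOOR = 2.0


class CalibrationError(RuntimeError):
    """Calibration could not be built (bad grid, no above-threshold region,
    or non-injective metric map)."""


class SchemaError(RuntimeError):
    """Calibration file is missing, truncated, or of an unknown schema."""


@dataclass
class CalibrationTable:
    """Look-up table mapping the metric pair to defocus.

    ``z_grid`` is strictly increasing (um); the three curves are sampled on
    it.  ``singleshot_range``/``twostep_range`` are the maximal contiguous
    intervals around each curve's peak where it exceeds its threshold;
    the single-shot interval is always contained in the two-step one.
    ``noise_scale_fast``/``noise_scale_slow`` are the per-axis metric noise
    std used to weight residuals during inversion.
    """

    z_grid: np.ndarray
    curve_fast: np.ndarray
    curve_slow: np.ndarray
    curve_intensity: np.ndarray
    background: BackgroundField
    threshold_fast: float
    threshold_slow: float
    threshold_intensity: float
    noise_scale_fast: float
    noise_scale_slow: float
    singleshot_range: tuple[float, float]
    twostep_range: tuple[float, float]
    created_at: str = ""
    config_hash: str = ""
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        for name in ("curve_fast", "curve_slow", "curve_intensity"):
            cur = np.asarray(getattr(self, name), dtype=float)
            if cur.shape != self.z_grid.shape:
                raise CalibrationError(f"{name} length != z_grid length")
            setattr(self, name, cur)
        if np.any(np.diff(self.z_grid) <= 0):
            raise CalibrationError("z_grid must be strictly increasing")
        if not (self.threshold_fast > 0 and self.threshold_slow > 0):
            raise CalibrationError("thresholds must be positive")
        lo, hi = self.singleshot_range
        lo2, hi2 = self.twostep_range
        if not (lo2 <= lo < hi <= hi2):
            raise CalibrationError("single-shot range must lie inside two-step range")


def config_hash(*configs) -> str:
    """Stable short hash of beam/camera configuration dataclasses."""
    payload = json.dumps([vars(c) if not isinstance(c, dict) else c
                          for c in configs], sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def acquire_background(frame_above: Frame, frame_below: Frame,
                       min_defocus: float = 100.0) -> BackgroundField:
    """Average two far-defocus frames into the stored background field.

    The two frames are recorded far above and far below focus, where the
    autofocus spot is spread so thin that the frames contain essentially only
    the fixed spurious-reflection background.
    """
    if frame_above.shape != frame_below.shape:
        raise ValueError("background frames differ in shape")
    for f in (frame_above, frame_below):
        if np.isfinite(f.z_true) and abs(f.z_true) < min_defocus:
            warnings.warn(
                f"background frame at |z| = {abs(f.z_true):.0f} um is closer "
                f"than {min_defocus:.0f} um to focus; residual spot light may "
                "contaminate the background", stacklevel=2)
    return BackgroundField((frame_above.pixels + frame_below.pixels) / 2.0)


def _contiguous_region(z: np.ndarray, curve: np.ndarray,
                       threshold: float) -> tuple[float, float]:
    """Maximal contiguous z-interval around the curve peak above threshold."""
    ipk = int(np.argmax(curve))
    if curve[ipk] < threshold:
        raise CalibrationError("curve has no above-threshold region")
    lo = ipk
    while lo > 0 and curve[lo - 1] >= threshold:
        lo -= 1
    hi = ipk
    while hi < curve.size - 1 and curve[hi + 1] >= threshold:
        hi += 1
    return float(z[lo]), float(z[hi])


def _estimate_noise_scales(z: np.ndarray, mf: np.ndarray,
                           ms: np.ndarray) -> tuple[float, float] | None:
    """Metric noise std from replicate frames at identical z, if present."""
    uniq, inv, counts = np.unique(z, return_inverse=True, return_counts=True)
    if counts.max() < 3:
        return None
    sf, ss = [], []
    for k in np.flatnonzero(counts >= 3):
        idx = inv == k
        sf.append(np.std(mf[idx], ddof=1))
        ss.append(np.std(ms[idx], ddof=1))
    return float(np.median(sf)), float(np.median(ss))


def build_calibration(
    frames: Sequence[Frame],
    background: BackgroundField,
    z_values: Sequence[float] | None = None,
    threshold_rule: str = "fraction",
    fraction_fast: float = DEFAULT_FRACTION_FAST,
    fraction_slow: float = DEFAULT_FRACTION_SLOW,
    background_frames: Sequence[Frame] | None = None,
    noise_scales: tuple[float, float] | None = None,
    median_filter: bool = False,
    config_hash_value: str = "",
) -> CalibrationTable:
    """Build the look-up table from a calibration z-stack.

    ``frames`` must span beyond both operating ranges with sub-micron steps
    near focus.  With ``threshold_rule='background'``, ``background_frames``
    (pure-background exposures) supply the metric statistics; thresholds are
    then ``mean + 5 std`` per axis.  ``median_filter`` applies an optional
    3-point median to the curves (for noisy hardware stacks; the default
    leaves them raw).
    """
    if z_values is None:
        z_values = [f.z_true for f in frames]
    z = np.asarray(list(z_values), dtype=float)
    if z.size != len(frames):
        raise CalibrationError("z_values length != number of frames")
    if z.size < 8:
        raise CalibrationError("calibration stack too small")
    order = np.argsort(z, kind="stable")
    z = z[order]
    frames = [frames[i] for i in order]

    mf = np.empty(z.size)
    ms = np.empty(z.size)
    mi = np.empty(z.size)
    for i, f in enumerate(frames):
        pair = compute_metrics(f, background)
        mf[i], ms[i], mi[i] = pair.m_fast, pair.m_slow, pair.mean_intensity

    if noise_scales is None:
        noise_scales = _estimate_noise_scales(z, mf, ms) or DEFAULT_NOISE_SCALES
    scale_f, scale_s = noise_scales

    # collapse replicate z entries to their mean
    uniq, inv = np.unique(z, return_inverse=True)
    if uniq.size != z.size:
        mf = np.bincount(inv, mf) / np.bincount(inv)
        ms = np.bincount(inv, ms) / np.bincount(inv)
        mi = np.bincount(inv, mi) / np.bincount(inv)
        z = uniq
    if np.any(np.diff(z) <= 0):
        raise CalibrationError("z grid not strictly monotone")

    if median_filter:
        from scipy.ndimage import median_filter as medf
        mf = medf(mf, size=3, mode="nearest")
        ms = medf(ms, size=3, mode="nearest")

    if threshold_rule == "fraction":
        thr_f = fraction_fast * mf.max()
        thr_s = fraction_slow * ms.max()
        thr_i = DEFAULT_INTENSITY_FLOOR
    elif threshold_rule == "background":
        if not background_frames:
            raise CalibrationError("background rule requires background_frames")
        bf = np.array([
            [compute_metrics(f, background).m_fast,
             compute_metrics(f, background).m_slow,
             compute_metrics(f, background).mean_intensity]
            for f in background_frames
        ])
        thr_f = bf[:, 0].mean() + 5.0 * bf[:, 0].std()
        thr_s = bf[:, 1].mean() + 5.0 * bf[:, 1].std()
        thr_i = bf[:, 2].mean() + 5.0 * bf[:, 2].std()
    else:
        raise ValueError(f"unknown threshold_rule {threshold_rule!r}")

    ss_range = _contiguous_region(z, mf, thr_f)
    ts_range = _contiguous_region(z, ms, thr_s)
    # the single-shot region must sit inside the two-step region
    ss_range = (max(ss_range[0], ts_range[0]), min(ss_range[1], ts_range[1]))

    _check_injectivity(z, mf, ms, scale_f, scale_s, ss_range)

    return CalibrationTable(
        z_grid=z, curve_fast=mf, curve_slow=ms, curve_intensity=mi,
        background=background,
        threshold_fast=float(thr_f), threshold_slow=float(thr_s),
        threshold_intensity=float(thr_i),
        noise_scale_fast=float(scale_f), noise_scale_slow=float(scale_s),
        singleshot_range=ss_range, twostep_range=ts_range,
        created_at=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        config_hash=config_hash_value,
    )


def _check_injectivity(z, mf, ms, scale_f, scale_s, ss_range) -> None:
    """Abort if two single-shot grid points are closer in metric space than
    the noise floor: the inversion would then be ambiguous by construction."""
    mask = (z >= ss_range[0]) & (z <= ss_range[1])
    f = mf[mask] / scale_f
    s = ms[mask] / scale_s
    zz = z[mask]
    n = zz.size
    for i in range(n):
        d2 = (f[i + 1:] - f[i]) ** 2 + (s[i + 1:] - s[i]) ** 2
        bad = np.flatnonzero(d2 < _INJECTIVITY_FLOOR**2)
        if bad.size:
            j = i + 1 + int(bad[0])
            raise CalibrationError(
                f"metric map not injective inside single-shot region: "
                f"z = {zz[i]:+.2f} and z = {zz[j]:+.2f} um are separated by "
                f"less than the metric noise floor")


# ---------------------------------------------------------------------------
# Persistence: JSON (grids, curves, thresholds) + TIFF background image.
# ---------------------------------------------------------------------------

def save_calibration(table: CalibrationTable, path: str | Path) -> None:
    """Write the table as ``<path>`` (JSON) plus ``<path stem>_background.tif``."""
    path = Path(path)
    bg_path = path.with_name(path.stem + "_background.tif")
    tifffile.imwrite(bg_path, table.background.pixels.astype(np.float32))
    doc = {
        "schema_version": table.schema_version,
        "created_at": table.created_at,
        "config_hash": table.config_hash,
        "z_grid": table.z_grid.tolist(),
        "curve_fast": table.curve_fast.tolist(),
        "curve_slow": table.curve_slow.tolist(),
        "curve_intensity": table.curve_intensity.tolist(),
        "threshold_fast": table.threshold_fast,
        "threshold_slow": table.threshold_slow,
        "threshold_intensity": table.threshold_intensity,
        "noise_scale_fast": table.noise_scale_fast,
        "noise_scale_slow": table.noise_scale_slow,
        "singleshot_range": list(table.singleshot_range),
        "twostep_range": list(table.twostep_range),
        "background_file": bg_path.name,
    }
    path.write_text(json.dumps(doc, indent=1))


_REQUIRED_KEYS = {
    "schema_version", "z_grid", "curve_fast", "curve_slow", "curve_intensity",
    "threshold_fast", "threshold_slow", "singleshot_range", "twostep_range",
    "background_file",
}


def load_calibration(path: str | Path,
                     expected_config_hash: str | None = None) -> CalibrationTable:
    """Load a table saved by :func:`save_calibration`.

    A config-hash mismatch (calibration built for different beam/camera
    settings) emits a warning rather than an error: the table may still be
    usable if only innocuous settings changed.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no calibration file at {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"calibration file {path} is corrupt: {exc}") from exc
    if not isinstance(doc, dict) or not _REQUIRED_KEYS <= doc.keys():
        raise SchemaError(f"calibration file {path} is missing required keys")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise SchemaError(
            f"calibration schema {doc['schema_version']} != {SCHEMA_VERSION}")
    bg_path = path.with_name(doc["background_file"])
    if not bg_path.exists():
        raise SchemaError(f"background image {bg_path} missing")
    background = BackgroundField(np.asarray(tifffile.imread(bg_path), float))
    if expected_config_hash and doc.get("config_hash") and \
            doc["config_hash"] != expected_config_hash:
        warnings.warn(
            f"calibration was built for config {doc['config_hash']}, current "
            f"config is {expected_config_hash}; re-calibration recommended",
            stacklevel=2)
    return CalibrationTable(
        z_grid=np.asarray(doc["z_grid"]),
        curve_fast=np.asarray(doc["curve_fast"]),
        curve_slow=np.asarray(doc["curve_slow"]),
        curve_intensity=np.asarray(doc["curve_intensity"]),
        background=background,
        threshold_fast=doc["threshold_fast"],
        threshold_slow=doc["threshold_slow"],
        threshold_intensity=doc.get("threshold_intensity", DEFAULT_INTENSITY_FLOOR),
        noise_scale_fast=doc.get("noise_scale_fast", DEFAULT_NOISE_SCALES[0]),
        noise_scale_slow=doc.get("noise_scale_slow", DEFAULT_NOISE_SCALES[1]),
        singleshot_range=tuple(doc["singleshot_range"]),
        twostep_range=tuple(doc["twostep_range"]),
        created_at=doc.get("created_at", ""),
        config_hash=doc.get("config_hash", ""),
    )
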