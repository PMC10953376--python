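"""Defocus estimation and closed-loop focus lock.

Single-shot estimation inverts the calibration look-up table jointly over
both metric curves: the measured metric pair is compared against the
(monotone-cubic-interpolated) curves on a dense defocus grid and the defocus
minimising the noise-weighted squared residual

    r(z) = ((m_fast - curve_fast(z)) / scale_fast)^2
         + ((m_slow - curve_slow(z)) / scale_slow)^2

is returned.  Because the slow-axis focus is offset axially from the
fast-axis focus, the two defocus values with identical fast-axis metric
(+|z| and -|z|) have different slow-axis metrics - the slow term is what
resolves the sign from a single frame.

Outside the single-shot region the two-step mode acquires a second frame a
few microns away: the defocus magnitude comes from inverting the slow-axis
curve (two symmetric candidates about the slow peak) and the sign from which
candidate is consistent with the observed change of the slow metric between
the two frames (metric increased <=> moved toward the slow-axis focus).

The focus-lock controller is a plain proportional (deadbeat at gain 1)
corrector running at a fixed cadence, with a per-update step clamp and
absolute drive limits as safety rails; estimates are used raw, with no
temporal filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .calibration import CalibrationTable
from .forward_model import (BackgroundField, BeamModel, CameraModel, Frame,
                            drift_trajectory, render_frame)
from .metrics import InvalidMetricError, compute_metrics

__all__ = [
    "DefocusEstimate",
    "ControllerConfig",
    "FocusLog",
    "OutOfRangeError",
    "AmbiguityError",
    "UnrecoverableDefocusError",
    "SimulatedMicroscope",
    "estimate_single_shot",
    "estimate_two_step",
    "autofocus",
    "run_focus_lock",
]

_INVERSION_GRID_UM = 0.05
# Two weighted squared residual terms of unit-variance noise: a second local
# minimum within this chi-square-like margin of the best is indistinguishable.
_AMBIGUITY_FLOOR = 4.0
# Minimum separation (um) for two residual minima to count as rival
# solutions rather than one noisy basin.
_AMBIGUITY_SEPARATION_UM = 1.0


class OutOfRangeError(RuntimeError):
    """Defocus beyond every calibrated operating range."""


class AmbiguityError(RuntimeError):
    """The metric residual does not single out one defocus solution."""


class UnrecoverableDefocusError(RuntimeError):
    """The full single-shot + two-step policy could not recover focus."""


@dataclass(frozen=True)
class DefocusEstimate:
    """Estimated defocus with provenance.

    ``residual`` is the noise-scaled metric-space mismatch at the solution;
    ``valid`` is False when the frame is outside the mode's operating region
    (``z_hat`` is then ``nan``).
    """

    z_hat: float
    mode: str  # "single_shot" | "two_step"
    residual: float
    valid: bool
    in_singleshot_region: bool


@dataclass(frozen=True)
class ControllerConfig:
    """Closed-loop focus-lock settings.

    ``setpoint`` is the desired defocus (um) relative to the fast-axis focus
    (user-offsettable to place the in-focus plane relative to the
    coverslip); ``gain`` is the fraction of the estimated error corrected
    per update (1 = deadbeat); ``max_step`` clamps a single correction,
    guarding against outlier estimates; ``z_limits`` bound the accumulated
    drive excursion.
    """

    setpoint: float = 0.0
    update_interval: float = 0.25
    z_limits: tuple[float, float] = (-100.0, 100.0)
    gain: float = 1.0
    max_step: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "z_limits", tuple(self.z_limits))
        if self.update_interval <= 0:
            raise ValueError("update_interval must be positive")
        if not self.z_limits[0] < self.z_limits[1]:
            raise ValueError("z_limits must be ordered")
        if not 0 < self.gain <= 1:
            raise ValueError("gain must be in (0, 1]")
        if self.max_step <= 0:
            raise ValueError("max_step must be positive")


@dataclass
class FocusLog:
    """Closed-loop time series: estimates, corrections, true residuals."""

    timestamp: np.ndarray
    z_hat: np.ndarray
    correction: np.ndarray
    residual: np.ndarray
    valid: np.ndarray
    lock_lost: bool = False

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "timestamp_s": self.timestamp,
            "z_hat_um": self.z_hat,
            "correction_um": self.correction,
            "residual_um": self.residual,
            "mode": "single_shot",
            "valid": self.valid.astype(bool),
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FocusLog":
        df = pd.read_csv(path)
        return cls(df["timestamp_s"].to_numpy(), df["z_hat_um"].to_numpy(),
                   df["correction_um"].to_numpy(), df["residual_um"].to_numpy(),
                   df["valid"].to_numpy())


# ---------------------------------------------------------------------------
# Look-up-table inversion
# ---------------------------------------------------------------------------

class _Inverter:
    """Dense interpolated curves for one calibration table (cached)."""

    def __init__(self, table: CalibrationTable) -> None:
        self.table = table
        self.fast = PchipInterpolator(table.z_grid, table.curve_fast)
        self.slow = PchipInterpolator(table.z_grid, table.curve_slow)
        lo, hi = table.singleshot_range
        self.z_ss = np.arange(lo, hi + 1e-9, _INVERSION_GRID_UM)
        self.cf_ss = self.fast(self.z_ss)
        self.cs_ss = self.slow(self.z_ss)
        lo2, hi2 = table.twostep_range
        self.z_ts = np.arange(lo2, hi2 + 1e-9, _INVERSION_GRID_UM)
        self.cs_ts = self.slow(self.z_ts)


def _inverter(table: CalibrationTable) -> _Inverter:
    inv = getattr(table, "_inverter_cache", None)
    if inv is None or inv.table is not table:
        inv = _Inverter(table)
        table.__dict__["_inverter_cache"] = inv
    return inv


def _local_minima(r: np.ndarray) -> np.ndarray:
    """Indices of strict-or-plateau local minima, endpoints included."""
    idx = []
    n = r.size
    for i in range(n):
        left = r[i - 1] if i > 0 else np.inf
        right = r[i + 1] if i < n - 1 else np.inf
        if r[i] <= left and r[i] <= right:
            idx.append(i)
    return np.asarray(idx, dtype=int)


def _refine(z: np.ndarray, r: np.ndarray, i: int) -> tuple[float, float]:
    """Parabolic sub-grid refinement of a residual minimum."""
    if 0 < i < z.size - 1:
        d1 = (r[i + 1] - r[i - 1]) / 2.0
        d2 = r[i + 1] - 2.0 * r[i] + r[i - 1]
        if d2 > 0:
            shift = float(np.clip(-d1 / d2, -1.0, 1.0))
            return float(z[i] + shift * (z[1] - z[0])), float(r[i] - 0.5 * d1 * shift)
    return float(z[i]), float(r[i])


def estimate_single_shot(frame: Frame, calib: CalibrationTable) -> DefocusEstimate:
    """Sign-and-magnitude defocus from one frame via joint curve inversion.

    Returns an invalid estimate when the fast-axis metric (or the mean
    intensity) is below its calibration threshold, i.e. when the frame lies
    outside the single-shot region.  Raises :class:`AmbiguityError` when two
    rival residual minima cannot be separated above the noise floor (the
    caller should fall back to the two-step mode).
    """
    m = compute_metrics(frame, calib.background)
    if m.mean_intensity < calib.threshold_intensity or \
            m.m_fast < calib.threshold_fast:
        return DefocusEstimate(float("nan"), "single_shot", float("inf"),
                               valid=False, in_singleshot_region=False)
    inv = _inverter(calib)
    r = ((m.m_fast - inv.cf_ss) / calib.noise_scale_fast) ** 2 + \
        ((m.m_slow - inv.cs_ss) / calib.noise_scale_slow) ** 2
    minima = _local_minima(r)
    order = minima[np.argsort(r[minima])]
    z_best, r_best = _refine(inv.z_ss, r, int(order[0]))
    for j in order[1:]:
        z_j, r_j = _refine(inv.z_ss, r, int(j))
        if abs(z_j - z_best) > _AMBIGUITY_SEPARATION_UM and \
                r_j - r_best < _AMBIGUITY_FLOOR:
            raise AmbiguityError(
                f"rival defocus solutions {z_best:+.2f} and {z_j:+.2f} um "
                "within the metric noise floor")
    return DefocusEstimate(z_best, "single_shot", r_best, valid=True,
                           in_singleshot_region=True)


def estimate_two_step(frame1: Frame, frame2: Frame, delta: float,
                      calib: CalibrationTable) -> DefocusEstimate:
    """Long-range defocus from two frames separated by ``delta`` um.

    ``frame2`` is acquired after moving the relative sample-objective
    position by ``delta``; the estimate is referenced to ``frame1``'s
    position.  Magnitude from the slow-axis curve, sign from the direction
    of change of the slow metric.
    """
    if delta == 0:
        raise ValueError("delta must be nonzero")
    m1 = compute_metrics(frame1, calib.background)
    m2 = compute_metrics(frame2, calib.background)
    ok1 = m1.m_slow >= calib.threshold_slow and \
        m1.mean_intensity >= calib.threshold_intensity
    ok2 = m2.m_slow >= calib.threshold_slow and \
        m2.mean_intensity >= calib.threshold_intensity
    if not (ok1 or ok2):
        raise OutOfRangeError(
            "slow-axis metric below threshold in both frames: defocus beyond "
            "the two-step operating range")
    if abs(m2.m_slow - m1.m_slow) < 3.0 * calib.noise_scale_slow:
        raise AmbiguityError(
            "slow metric changed by less than the noise floor between the two "
            "frames; increase the displacement delta")
    inv = _inverter(calib)
    # invert whichever frame is inside the region (prefer frame1)
    ref_m, ref_shift = (m1, 0.0) if ok1 else (m2, delta)
    rr = (ref_m.m_slow - inv.cs_ts) ** 2
    minima = _local_minima(rr)
    order = minima[np.argsort(rr[minima])][:2]
    candidates = [_refine(inv.z_ts, rr, int(i)) for i in order]
    # pick the candidate whose predicted companion metric matches the other
    # frame; the companion sits delta further along z than the reference
    other_m = m2 if ref_shift == 0.0 else m1
    other_off = delta if ref_shift == 0.0 else -delta
    lo, hi = calib.twostep_range
    best = None
    for zc, rc in candidates:
        z_other = np.clip(zc + other_off, lo, hi)
        mismatch = abs(float(inv.slow(z_other)) - other_m.m_slow)
        if best is None or mismatch < best[0]:
            best = (mismatch, zc, rc)
    assert best is not None
    _, zc, rc = best
    z_hat = zc - ref_shift
    residual = float(np.sqrt(rc)) / calib.noise_scale_slow
    in_ss = calib.singleshot_range[0] <= z_hat <= calib.singleshot_range[1]
    return DefocusEstimate(float(z_hat), "two_step", residual, valid=True,
                           in_singleshot_region=in_ss)


# ---------------------------------------------------------------------------
# Simulated microscope and the recovery policy
# ---------------------------------------------------------------------------

class SimulatedMicroscope:
    """Minimal camera + z-drive stand-in backed by the forward model.

    ``defocus`` is the current true coverslip defocus; ``move_z`` translates
    the objective so that the defocus changes by ``-step`` (moving the drive
    by a positive step brings a positive defocus toward zero).
    """

    def __init__(self, defocus: float, beam: BeamModel, camera: CameraModel,
                 background: BackgroundField | None = None,
                 noise: bool = True, seed: int | None = None) -> None:
        self.defocus = float(defocus)
        self.beam = beam
        self.camera = camera
        self.background = background
        self.noise = noise
        self.rng = np.random.default_rng(seed)
        self.acquisitions = 0
        self.drive = 0.0

    def acquire(self) -> Frame:
        self.acquisitions += 1
        return render_frame(self.defocus, self.beam, self.camera,
                            self.background, noise=self.noise, seed=self.rng,
                            z_commanded=self.drive)

    def move_z(self, step: float) -> None:
        self.drive += step
        self.defocus -= step


def autofocus(scope: SimulatedMicroscope, calib: CalibrationTable,
              delta: float = 3.0) -> DefocusEstimate:
    """Recover focus: single-shot first, two-step fallback, then re-shoot.

    Policy: try single-shot on one frame; if it is invalid or ambiguous,
    acquire a second frame ``delta`` um away, apply the coarse two-step
    correction, and finish with one more single-shot.  Uses at most three
    camera acquisitions.  The applied corrections move ``scope``; the
    returned estimate is the final one.
    """
    frame1 = scope.acquire()
    try:
        est = estimate_single_shot(frame1, calib)
        if est.valid:
            scope.move_z(est.z_hat)
            return est
    except AmbiguityError:
        pass
    scope.move_z(-delta)  # defocus increases by delta
    frame2 = scope.acquire()
    try:
        coarse = estimate_two_step(frame1, frame2, delta, calib)
    except (OutOfRangeError, AmbiguityError, InvalidMetricError) as exc:
        raise UnrecoverableDefocusError(
            f"two-step fallback failed: {exc}") from exc
    scope.move_z(coarse.z_hat + delta)  # undo the probe move, apply coarse
    frame3 = scope.acquire()
    final = estimate_single_shot(frame3, calib)
    if not final.valid:
        raise UnrecoverableDefocusError(
            "two-step correction did not land inside the single-shot region")
    scope.move_z(final.z_hat)
    return final


# ---------------------------------------------------------------------------
# Closed-loop focus lock
# ---------------------------------------------------------------------------

def run_focus_lock(
    calib: CalibrationTable,
    config: ControllerConfig,
    duration: float,
    beam: BeamModel | None = None,
    camera: CameraModel | None = None,
    background: BackgroundField | None = None,
    drift_model: str = "linear",
    drift_params: dict | None = None,
    noise: bool = True,
    seed: int | None = None,
) -> FocusLog:
    """Simulate continuous closed-loop focus correction under drift.

    Every ``config.update_interval`` seconds a frame is rendered at the true
    defocus (drift minus accumulated correction, relative to the setpoint),
    single-shot estimated, and a proportional correction applied, clamped to
    ``max_step`` per update and to the absolute ``z_limits``.  Three
    consecutive invalid estimates (or hard saturation at a drive limit)
    abandon the lock: the controller halts at the last safe position and the
    returned log carries ``lock_lost=True``.  Deterministic for a given
    seed.
    """
    from .forward_model import default_beam, default_camera, default_background
    beam = beam or default_beam()
    camera = camera or default_camera()
    if background is None:
        background = default_background(camera)
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    s_drift, s_frames = ss.spawn(2)
    dt = config.update_interval
    _, drift = drift_trajectory(drift_model, drift_params or {}, duration, dt,
                                seed=s_drift)
    rng = np.random.default_rng(s_frames)
    lo, hi = config.z_limits

    times, zhats, corrections, residuals, valids = [], [], [], [], []
    drive = 0.0
    misses = 0       # consecutive invalid estimates
    saturated = 0    # consecutive updates pinned at a drive limit
    lock_lost = False
    for k, d in enumerate(drift):
        t = k * dt
        z_true = d - drive + config.setpoint
        frame = render_frame(z_true, beam, camera, background, noise=noise,
                             seed=rng, timestamp=t, z_commanded=drive)
        try:
            est = estimate_single_shot(frame, calib)
        except (AmbiguityError, InvalidMetricError):
            est = DefocusEstimate(float("nan"), "single_shot", float("inf"),
                                  False, False)
        if est.valid:
            misses = 0
            step = float(np.clip(config.gain * (est.z_hat - config.setpoint),
                                 -config.max_step, config.max_step))
        else:
            misses += 1
            step = 0.0
        new_drive = drive + step
        clamped = float(np.clip(new_drive, lo, hi))
        saturated = saturated + 1 if clamped != new_drive else 0
        drive = clamped
        times.append(t)
        zhats.append(est.z_hat)
        corrections.append(step)
        residuals.append(d - drive)
        valids.append(est.valid)
        if misses >= 3 or saturated >= 3:
            lock_lost = True
            break
    return FocusLog(np.asarray(times), np.asarray(zhats),
                    np.asarray(corrections), np.asarray(residuals),
                    np.asarray(valids, dtype=bool), lock_lost=lock_lost)
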