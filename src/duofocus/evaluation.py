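"""In-silico evaluation protocols for the autofocus.

Mirrors how the hardware instrument was characterised: repeated refocusing
from preset defocus offsets (error boxplots), a 96-well bead-plate scan with
per-bead best-focus auditing of the residual defocus, true-focus
determination from an autofocus z-stack, and long-duration closed-loop
stability under drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .calibration import CalibrationTable
from .estimation import (AmbiguityError, ControllerConfig, FocusLog,
                         OutOfRangeError, estimate_single_shot,
                         estimate_two_step, run_focus_lock)
from .forward_model import (BackgroundField, BeamModel, CameraModel, Frame,
                            default_background, default_beam, default_camera,
                            render_frame)
from .metrics import InvalidMetricError, compute_metrics

__all__ = [
    "RepeatabilityReport",
    "PlateReport",
    "BeadFocusResult",
    "run_repeatability",
    "true_focus_from_stack",
    "simulate_bead_stack",
    "per_bead_focus",
    "simulate_plate",
    "run_stability",
]

#: Depth of field (um) of the 100x/1.4 NA objective at ~680 nm emission;
#: doubles as the axial intensity FWHM of a simulated bead.
DEPTH_OF_FIELD_UM = 0.65

#: Default axial offset of bead centres from the coverslip surface (um):
#: 100 nm beads attached to the glass sit at least ~50 nm above it.
BEAD_SURFACE_OFFSET_UM = 0.05


@dataclass
class RepeatabilityReport:
    """Signed refocusing errors per preset defocus offset."""

    offsets: np.ndarray
    errors: dict[float, np.ndarray]
    flagged: list[float]
    mode: str

    def mean_error(self, offset: float) -> float:
        return float(np.mean(self.errors[offset]))

    def std_error(self, offset: float) -> float:
        return float(np.std(self.errors[offset]))

    def iqr(self, offset: float) -> float:
        q1, q3 = np.percentile(self.errors[offset], [25, 75])
        return float(q3 - q1)

    @property
    def grand_mean_abs_error(self) -> float:
        """Mean |error| pooled over every tested offset and repeat."""
        pooled = np.concatenate([self.errors[o] for o in self.errors])
        return float(np.mean(np.abs(pooled)))


@dataclass
class PlateReport:
    """Residual-defocus statistics of a simulated multiwell-plate scan."""

    well_mean: np.ndarray      # (rows, cols) mean residual defocus, um
    well_std: np.ndarray       # (rows, cols) per-well std over beads, um
    well_offset: np.ndarray    # (rows, cols) true well-plane offsets, um

    @property
    def shape(self) -> tuple[int, int]:
        return self.well_mean.shape  # type: ignore[return-value]

    @property
    def std_of_means(self) -> float:
        """Plate-wide std of the per-well mean residual defocus (um)."""
        return float(np.std(self.well_mean))

    @property
    def mean_abs_error(self) -> float:
        return float(np.mean(np.abs(self.well_mean)))


@dataclass
class BeadFocusResult:
    """Per-bead best-focus planes from a bead z-stack."""

    z_focus: np.ndarray
    positions: np.ndarray      # (n, 2) row/col of accepted beads
    n_flagged: int             # beads dropped for overlapping a neighbour


def run_repeatability(
    offsets: Sequence[float],
    repeats: int,
    calib: CalibrationTable,
    mode: str = "short",
    beam: BeamModel | None = None,
    camera: CameraModel | None = None,
    background: BackgroundField | None = None,
    noise: bool = True,
    seed: int | None = None,
    delta: float = 3.0,
) -> RepeatabilityReport:
    """Refocus ``repeats`` times from each preset offset and record errors.

    ``mode='short'`` exercises the single-shot estimator (offsets within the
    single-shot region); ``mode='long'`` the two-step estimator.  Offsets
    outside the mode's operating range are flagged rather than fatal.
    """
    if repeats < 2:
        raise ValueError("repeats must be >= 2")
    if mode not in ("short", "long"):
        raise ValueError("mode must be 'short' or 'long'")
    beam = beam or default_beam()
    camera = camera or default_camera()
    if background is None:
        background = default_background(camera)
    rng = np.random.default_rng(seed)
    errors: dict[float, np.ndarray] = {}
    flagged: list[float] = []
    for z0 in offsets:
        errs = []
        for _ in range(repeats):
            try:
                if mode == "short":
                    frame = render_frame(z0, beam, camera, background,
                                         noise=noise, seed=rng)
                    est = estimate_single_shot(frame, calib)
                    if not est.valid:
                        raise OutOfRangeError("outside single-shot region")
                else:
                    f1 = render_frame(z0, beam, camera, background,
                                      noise=noise, seed=rng)
                    f2 = render_frame(z0 + delta, beam, camera, background,
                                      noise=noise, seed=rng)
                    est = estimate_two_step(f1, f2, delta, calib)
                errs.append(est.z_hat - z0)
            except (OutOfRangeError, AmbiguityError, InvalidMetricError):
                if z0 not in flagged:
                    flagged.append(z0)
        if errs:
            errors[float(z0)] = np.asarray(errs)
    return RepeatabilityReport(np.asarray(list(errors), dtype=float),
                               errors, flagged, mode)


def true_focus_from_stack(frames: Sequence[Frame],
                          background: BackgroundField | None = None,
                          z_values: Sequence[float] | None = None) -> float:
    """True in-focus position from an autofocus z-stack.

    Evaluates the fast-axis metric per frame and fits a parabola through the
    three grid points bracketing its maximum; the vertex is the plane where
    the focused beam is narrowest in the fast direction.
    """
    if z_values is None:
        z_values = [f.z_true for f in frames]
    z = np.asarray(list(z_values), dtype=float)
    curve = np.array([compute_metrics(f, background).m_fast for f in frames])
    i = int(np.argmax(curve))
    if i == 0 or i == curve.size - 1:
        raise ValueError("metric maximum at stack edge; extend the z range")
    z3, c3 = z[i - 1:i + 2], curve[i - 1:i + 2]
    a, b, _ = np.polyfit(z3, c3, 2)
    if a >= 0:
        raise ValueError("no parabolic maximum at stack centre")
    return float(-b / (2.0 * a))


# ---------------------------------------------------------------------------
# Bead z-stacks and per-bead best-focus (fluorescence-side audit)
# ---------------------------------------------------------------------------

def simulate_bead_stack(
    z_values: Sequence[float],
    n_beads: int = 50,
    focus_z: float = 0.0,
    size: int = 128,
    lateral_sigma_px: float = 1.5,
    axial_fwhm_um: float = DEPTH_OF_FIELD_UM,
    peak_photons: float = 500.0,
    background_photons: float = 10.0,
    positions: np.ndarray | None = None,
    noise: bool = True,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a fluorescence z-stack of sub-resolution beads.

    Each bead is a lateral Gaussian spot whose intensity follows a Gaussian
    axial profile of FWHM ``axial_fwhm_um`` (the microscope depth of field)
    centred on ``focus_z``; Poisson noise throughout.  Returns
    ``(stack, positions)`` with stack shape ``(n_z, size, size)``.
    """
    rng = np.random.default_rng(seed)
    z = np.asarray(list(z_values), dtype=float)
    if positions is None:
        margin = 6.0 * lateral_sigma_px
        positions = rng.uniform(margin, size - margin, size=(n_beads, 2))
    positions = np.asarray(positions, dtype=float)
    sig_z = axial_fwhm_um / 2.355
    yy, xx = np.mgrid[0:size, 0:size]
    spots = np.zeros((size, size))
    for r, c in positions:
        spots += np.exp(-((yy - r) ** 2 + (xx - c) ** 2)
                        / (2.0 * lateral_sigma_px**2))
    axial = peak_photons * np.exp(-(z - focus_z) ** 2 / (2.0 * sig_z**2))
    stack = np.empty((z.size, size, size))
    for k, amp in enumerate(axial):
        expect = amp * spots + background_photons
        stack[k] = rng.poisson(expect) if noise else expect
    return stack, positions


def per_bead_focus(
    bead_stack: np.ndarray,
    z_values: Sequence[float],
    lateral_sigma_px: float = 1.5,
    min_peak_photons: float = 50.0,
) -> BeadFocusResult:
    """Per-bead best-focus plane, PSFj style.

    Beads are detected as local maxima of the stack's maximum-intensity
    projection; any pair closer than three lateral sigmas is dropped as
    overlapping (flagged).  Each accepted bead's axial intensity trace is
    fitted with a parabola on log intensity around its brightest plane - for
    a Gaussian axial profile the log is exactly quadratic, so the vertex is
    the unbiased best-focus estimate.
    """
    stack = np.asarray(bead_stack, dtype=float)
    z = np.asarray(list(z_values), dtype=float)
    if stack.shape[0] != z.size:
        raise ValueError("stack depth != number of z values")
    mip = stack.max(axis=0)
    bg = float(np.median(mip))
    footprint = ndimage.maximum_filter(mip, size=5)
    peaks = np.argwhere((mip == footprint) & (mip > bg + min_peak_photons))
    # merge detections within 2 px (plateaus), then flag 3-sigma overlaps
    keep: list[np.ndarray] = []
    for p in peaks:
        if all(np.hypot(*(p - q)) > 2.0 for q in keep):
            keep.append(p)
    pts = np.asarray(keep, dtype=float)
    n_flagged = 0
    accepted = []
    limit = 3.0 * lateral_sigma_px
    for i, p in enumerate(pts):
        d = np.hypot(*(pts[np.arange(len(pts)) != i] - p).T) if len(pts) > 1 \
            else np.array([np.inf])
        if d.size and d.min() < limit:
            n_flagged += 1
        else:
            accepted.append(p)
    focus = []
    good_pos = []
    for r, c in accepted:
        ri, ci = int(round(r)), int(round(c))
        trace = stack[:, max(ri - 1, 0):ri + 2, max(ci - 1, 0):ci + 2].sum(axis=(1, 2))
        trace = np.clip(trace - 9.0 * bg, 1e-3, None)
        k = int(np.argmax(trace))
        if k == 0 or k == z.size - 1:
            continue
        # fit on planes within the central lobe (log-quadratic there)
        w = max(2, int(round(0.5 * DEPTH_OF_FIELD_UM / max(np.diff(z).mean(), 1e-6))))
        lo, hi = max(0, k - w), min(z.size, k + w + 1)
        a, b, _ = np.polyfit(z[lo:hi], np.log(trace[lo:hi]), 2)
        if a < 0:
            focus.append(-b / (2.0 * a))
            good_pos.append((r, c))
    return BeadFocusResult(np.asarray(focus), np.asarray(good_pos), n_flagged)


# ---------------------------------------------------------------------------
# Multiwell-plate protocol
# ---------------------------------------------------------------------------

def _well_offsets(rows: int, cols: int, tilt_x: float, tilt_y: float,
                  roughness_std: float, max_neighbor_step: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Smooth plate tilt plus clipped roughness; neighbouring wells never
    differ by more than ``max_neighbor_step`` um."""
    r = np.arange(rows)[:, None] - (rows - 1) / 2.0
    c = np.arange(cols)[None, :] - (cols - 1) / 2.0
    tilt = tilt_y * r + tilt_x * c
    cap = max(0.0, (max_neighbor_step - max(abs(tilt_x), abs(tilt_y))) / 2.0)
    rough = np.clip(rng.normal(0.0, roughness_std, (rows, cols)), -cap, cap)
    return tilt + rough


def simulate_plate(
    rows: int,
    cols: int,
    calib: CalibrationTable,
    tilt_x: float = 1.2,
    tilt_y: float = 2.0,
    roughness_std: float = 2.0,
    max_neighbor_step: float = 20.0,
    beam: BeamModel | None = None,
    camera: CameraModel | None = None,
    background: BackgroundField | None = None,
    n_beads: int = 50,
    bead_stack_halfrange: float = 4.0,
    bead_stack_step: float = 0.1,
    bead_bias: float = BEAD_SURFACE_OFFSET_UM,
    noise: bool = True,
    seed: int | None = None,
) -> PlateReport:
    """Scan a simulated bead plate: autofocus each well, audit with beads.

    Each well's coverslip plane is offset by a smooth plate tilt plus
    roughness (neighbouring wells differ by < ``max_neighbor_step``).  Per
    well, a single-shot autofocus correction is applied and the residual
    defocus is then *measured* the way the hardware evaluation did: a
    fluorescence bead z-stack about the corrected position is simulated and
    the mean per-bead best-focus plane is taken as the well's residual.
    ``bead_bias`` shifts the true bead planes off the coverslip (bead
    centres sit slightly above the glass).
    """
    beam = beam or default_beam()
    camera = camera or default_camera()
    if background is None:
        background = default_background(camera)
    rng = np.random.default_rng(seed)
    offsets = _well_offsets(rows, cols, tilt_x, tilt_y, roughness_std,
                            max_neighbor_step, rng)
    zs = np.arange(-bead_stack_halfrange, bead_stack_halfrange + 1e-9,
                   bead_stack_step)
    well_mean = np.full((rows, cols), np.nan)
    well_std = np.full((rows, cols), np.nan)
    for i in range(rows):
        for j in range(cols):
            z0 = float(offsets[i, j])
            frame = render_frame(z0, beam, camera, background, noise=noise,
                                 seed=rng)
            est = estimate_single_shot(frame, calib)
            residual = z0 - est.z_hat if est.valid else z0
            stack, _ = simulate_bead_stack(
                zs, n_beads=n_beads, focus_z=residual + bead_bias,
                noise=noise, seed=int(rng.integers(2**31)))
            res = per_bead_focus(stack, zs)
            if res.z_focus.size:
                well_mean[i, j] = res.z_focus.mean()
                well_std[i, j] = res.z_focus.std()
    return PlateReport(well_mean, well_std, offsets)


def run_stability(
    duration: float,
    calib: CalibrationTable,
    drift_model: str = "sinusoidal",
    drift_params: dict | None = None,
    config: ControllerConfig | None = None,
    settle_updates: int = 10,
    noise: bool = True,
    seed: int | None = None,
    **lock_kwargs,
) -> tuple[FocusLog, float]:
    """Closed-loop stability run: focus lock under drift, residual std.

    Returns the focus log and the standard deviation of the true residual
    defocus excluding the first ``settle_updates`` updates (controller
    settling).
    """
    config = config or ControllerConfig()
    log = run_focus_lock(calib, config, duration, drift_model=drift_model,
                         drift_params=drift_params, noise=noise, seed=seed,
                         **lock_kwargs)
    resid = log.residual[settle_updates:]
    return log, float(np.std(resid)) if resid.size else 0.0
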