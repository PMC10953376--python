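"""Configuration, logging and the command-line interface.

The CLI mirrors what an operator does at the instrument: simulate frames,
run the calibration procedure, read defocus off a frame, engage the
closed-loop focus lock, and run the evaluation protocols.  Every run is
reproducible: one top-level seed deterministically derives all per-module
seeds, and each command writes its resolved configuration next to its
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import click
import numpy as np

from . import __version__
from .calibration import (SCHEMA_VERSION, build_calibration, config_hash,
                          load_calibration, save_calibration)
from .estimation import ControllerConfig, estimate_single_shot, estimate_two_step
from .forward_model import (BackgroundField, BeamModel, CameraModel,
                            read_stack, render_frame, render_zstack,
                            write_stack)
from .metrics import compute_metrics, project, subtract_background

__all__ = [
    "RunConfig",
    "nyquist_limit_nm",
    "validate_pixel_size",
    "setup_logging",
    "main",
    "cli",
]

log = logging.getLogger("duofocus")


def nyquist_limit_nm(emission_nm: float = 670.0, na: float = 1.4) -> float:
    """Nyquist-limited sample-plane pixel size, lambda / (4 NA), in nm.

    The lateral diffraction cutoff of an incoherent widefield image is
    2 NA / lambda, so faithful sampling requires pixels no larger than
    lambda / (4 NA): ~119 nm for 670 nm emission through a 1.4 NA objective.
    """
    if emission_nm <= 0 or na <= 0:
        raise ValueError("emission wavelength and NA must be positive")
    return emission_nm / (4.0 * na)


def validate_pixel_size(pixel_nm: float, emission_nm: float = 670.0,
                        na: float = 1.4) -> bool:
    """True if a sample-plane pixel size satisfies the Nyquist criterion."""
    return pixel_nm <= nyquist_limit_nm(emission_nm, na)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    The background is parameterised (pedestal + one dim Gaussian blob)
    rather than stored as pixels so configs stay small and diffable.
    """

    beam: BeamModel = field(default_factory=BeamModel)
    camera: CameraModel = field(default_factory=CameraModel)
    background_pedestal: float = 20.0
    background_blob_amplitude: float = 15.0
    background_blob_sigma_px: float = 180.0
    background_blob_offset_px: tuple[float, float] = (120.0, -90.0)
    noise: bool = True
    calibration_z_min: float = -80.0
    calibration_z_max: float = 80.0
    calibration_z_step: float = 0.5
    calibration_fraction_fast: float = 0.2073
    calibration_fraction_slow: float = 0.3343
    metric_noise_fast: float = 0.0074
    metric_noise_slow: float = 0.0028
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    drift_model: str = "sinusoidal"
    drift_params: dict = field(default_factory=lambda: {"amplitude": 2.0,
                                                        "period": 600.0})
    seed: int = 0

    def background(self) -> BackgroundField:
        cam = self.camera
        dy, dx = self.background_blob_offset_px
        y = np.arange(cam.height)[:, None] - (cam.height - 1) / 2.0 - dy
        x = np.arange(cam.width)[None, :] - (cam.width - 1) / 2.0 - (-dx)
        s2 = 2.0 * self.background_blob_sigma_px**2
        blob = self.background_blob_amplitude * np.exp(-(x * x + y * y) / s2)
        return BackgroundField(self.background_pedestal + blob)

    def subseed(self, stream: int) -> np.random.SeedSequence:
        """Deterministic per-module seed stream derived from the run seed."""
        return np.random.SeedSequence([self.seed, stream])

    def hash(self) -> str:
        return config_hash(self.beam, self.camera)

    def to_json(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["beam"] = asdict(self.beam)
        doc["camera"] = asdict(self.camera)
        doc["controller"] = asdict(self.controller)
        doc["version"] = __version__
        doc["calibration_schema"] = SCHEMA_VERSION
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        doc.pop("version", None)
        doc.pop("calibration_schema", None)
        doc["beam"] = BeamModel(**doc.get("beam", {}))
        doc["camera"] = CameraModel(**doc.get("camera", {}))
        doc["controller"] = ControllerConfig(**doc.get("controller", {}))
        doc["background_blob_offset_px"] = tuple(
            doc.get("background_blob_offset_px", (120.0, -90.0)))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def setup_logging(verbose: bool = False, logfile: str | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers, force=True)


def _load_config(path: str | None) -> RunConfig:
    return RunConfig.from_json(path) if path else RunConfig()


def _write_resolved(cfg: RunConfig, out: Path) -> None:
    cfg.to_json(out.with_suffix(out.suffix + ".config.json"))


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
@click.version_option(__version__, message=f"duofocus %(version)s (calibration schema {SCHEMA_VERSION})")
@click.option("--verbose", is_flag=True, help="Debug-level logging.")
@click.option("--logfile", type=click.Path(dir_okay=False), default=None,
              help="Also write logs to this file.")
def cli(verbose: bool, logfile: str | None) -> None:
    """Dual-axis cylindrical-lens optical autofocus toolbox."""
    setup_logging(verbose, logfile)


@cli.command()
@click.option("--z", type=float, default=None, help="Single defocus (um).")
@click.option("--z-start", type=float, default=None)
@click.option("--z-stop", type=float, default=None)
@click.option("--z-step", type=float, default=0.5)
@click.option("--out", type=click.Path(dir_okay=False), required=True)
@click.option("--seed", type=int, default=0)
@click.option("--no-noise", is_flag=True)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
def simulate(z, z_start, z_stop, z_step, out, seed, no_noise, config_path):
    """Render one frame or a z-stack to a 16-bit TIFF (+ metadata CSV)."""
    cfg = _load_config(config_path)
    cfg.seed = seed
    bg = cfg.background()
    noise = cfg.noise and not no_noise
    if z is not None:
        frames = [render_frame(z, cfg.beam, cfg.camera, bg, noise=noise,
                               seed=int(cfg.subseed(1).generate_state(1)[0] % 2**31))]
    elif z_start is not None and z_stop is not None:
        zs = np.arange(z_start, z_stop + z_step / 2, z_step)
        frames = render_zstack(zs, cfg.beam, cfg.camera, bg, noise=noise,
                               seed=int(cfg.subseed(1).generate_state(1)[0] % 2**31))
    else:
        raise click.UsageError("give either --z or --z-start/--z-stop")
    write_stack(frames, out)
    _write_resolved(cfg, Path(out))
    log.info("wrote %d frame(s) to %s", len(frames), out)


@cli.command()
@click.option("--stack", type=click.Path(exists=True), default=None,
              help="Calibration z-stack TIFF (z metadata in sidecar CSV).")
@click.option("--zs", type=click.Path(exists=True), default=None,
              help="Optional metadata CSV if not the TIFF sidecar.")
@click.option("--background", "bg_path", type=click.Path(exists=True),
              default=None, help="Background TIFF; omit for simulated runs.")
@click.option("--simulate", "from_sim", is_flag=True,
              help="Build the calibration fully in silico (noiseless stack).")
@click.option("--out", type=click.Path(dir_okay=False), required=True)
@click.option("--seed", type=int, default=0)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
def calibrate(stack, zs, bg_path, from_sim, out, seed, config_path):
    """Build and save the metric-vs-defocus look-up table."""
    cfg = _load_config(config_path)
    cfg.seed = seed
    if from_sim:
        bg = cfg.background()
        zgrid = np.arange(cfg.calibration_z_min,
                          cfg.calibration_z_max + cfg.calibration_z_step / 2,
                          cfg.calibration_z_step)
        frames = render_zstack(zgrid, cfg.beam, cfg.camera, bg, noise=False)
    elif stack:
        frames = read_stack(stack, zs)
        if bg_path:
            import tifffile
            bg = BackgroundField(np.asarray(tifffile.imread(bg_path), float))
        else:
            bg = BackgroundField(np.zeros((cfg.camera.height, cfg.camera.width)))
    else:
        raise click.UsageError("give --stack or --simulate")
    table = build_calibration(
        frames, bg,
        fraction_fast=cfg.calibration_fraction_fast,
        fraction_slow=cfg.calibration_fraction_slow,
        noise_scales=(cfg.metric_noise_fast, cfg.metric_noise_slow),
        config_hash_value=cfg.hash())
    save_calibration(table, out)
    _write_resolved(cfg, Path(out))
    log.info("calibration: single-shot %s um, two-step %s um",
             table.singleshot_range, table.twostep_range)


@cli.command()
@click.option("--frame", "frame_path", type=click.Path(exists=True), required=True)
@click.option("--calib", "calib_path", type=click.Path(exists=True), required=True)
@click.option("--frame2", type=click.Path(exists=True), default=None,
              help="Second frame for two-step estimation.")
@click.option("--delta", type=float, default=3.0)
def estimate(frame_path, calib_path, frame2, delta):
    """Estimate defocus from a frame (two frames for two-step mode)."""
    table = load_calibration(calib_path)
    frames = read_stack(frame_path)
    if frame2:
        est = estimate_two_step(frames[0], read_stack(frame2)[0], delta, table)
    else:
        est = estimate_single_shot(frames[0], table)
    click.echo(json.dumps({
        "z_hat_um": None if not est.valid else round(est.z_hat, 4),
        "mode": est.mode, "valid": est.valid,
        "in_singleshot_region": est.in_singleshot_region,
        "residual": None if not np.isfinite(est.residual) else round(est.residual, 4),
    }))
    if not est.valid:
        sys.exit(3)


@cli.command()
@click.option("--calib", "calib_path", type=click.Path(exists=True), required=True)
@click.option("--duration", type=float, default=60.0)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(dir_okay=False), required=True)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
def lock(calib_path, duration, seed, out, config_path):
    """Run the closed-loop focus lock simulation, log to CSV."""
    from .estimation import run_focus_lock
    cfg = _load_config(config_path)
    cfg.seed = seed
    table = load_calibration(calib_path, expected_config_hash=cfg.hash())
    flog = run_focus_lock(table, cfg.controller, duration, beam=cfg.beam,
                          camera=cfg.camera, background=cfg.background(),
                          drift_model=cfg.drift_model,
                          drift_params=cfg.drift_params, noise=cfg.noise,
                          seed=seed)
    flog.to_csv(out)
    _write_resolved(cfg, Path(out))
    resid = flog.residual[10:]
    log.info("focus lock: %d updates, residual std %.1f nm%s",
             flog.timestamp.size, 1e3 * float(np.std(resid)) if resid.size else 0.0,
             " (LOCK LOST)" if flog.lock_lost else "")
    if flog.lock_lost:
        sys.exit(4)


@cli.command()
@click.option("--frame", "frame_path", type=click.Path(exists=True), required=True)
@click.option("--calib", "calib_path", type=click.Path(exists=True), default=None)
@click.option("--out", type=click.Path(dir_okay=False), required=True)
def inspect(frame_path, calib_path, out):
    """Debug dump: projections and power spectra of a frame to CSV."""
    import pandas as pd
    frames = read_stack(frame_path)
    bg = load_calibration(calib_path).background if calib_path else None
    corrected = subtract_background(frames[0], bg)
    pair = project(corrected)
    sf = np.abs(np.fft.rfft(pair.proj_fast - pair.proj_fast.mean())) ** 2
    ss = np.abs(np.fft.rfft(pair.proj_slow - pair.proj_slow.mean())) ** 2
    n = max(pair.proj_fast.size, pair.proj_slow.size, sf.size, ss.size)
    def pad(a):
        return np.pad(a.astype(float), (0, n - a.size), constant_values=np.nan)
    pd.DataFrame({
        "proj_fast": pad(pair.proj_fast), "proj_slow": pad(pair.proj_slow),
        "power_fast": pad(sf), "power_slow": pad(ss),
    }).to_csv(out, index_label="index")
    m = compute_metrics(frames[0], bg)
    log.info("m_fast %.3f  m_slow %.3f  mean intensity %.2f",
             m.m_fast, m.m_slow, m.mean_intensity)


@cli.group()
def evaluate() -> None:
    """Evaluation protocols (repeatability | plate | stability)."""


@evaluate.command()
@click.option("--calib", "calib_path", type=click.Path(exists=True), required=True)
@click.option("--mode", type=click.Choice(["short", "long"]), default="short")
@click.option("--max-offset", type=float, default=20.0)
@click.option("--step", type=float, default=2.0)
@click.option("--repeats", type=int, default=10)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(dir_okay=False), required=True)
@click.option("--plot", type=click.Path(dir_okay=False), default=None)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
def repeatability(calib_path, mode, max_offset, step, repeats, seed, out, plot,
                  config_path):
    """Repeat-from-offset accuracy protocol."""
    import pandas as pd
    from .evaluation import run_repeatability
    cfg = _load_config(config_path)
    table = load_calibration(calib_path)
    offsets = np.arange(-max_offset, max_offset + step / 2, step)
    rep = run_repeatability(offsets, repeats, table, mode=mode, beam=cfg.beam,
                            camera=cfg.camera, background=cfg.background(),
                            noise=cfg.noise, seed=seed)
    rows = [{"offset_um": o, "error_um": e}
            for o in rep.errors for e in rep.errors[o]]
    pd.DataFrame(rows).to_csv(out, index=False)
    summary = {
        "mode": mode, "repeats": repeats,
        "grand_mean_abs_error_um": rep.grand_mean_abs_error,
        "flagged_offsets": rep.flagged,
    }
    Path(out).with_suffix(".summary.json").write_text(json.dumps(summary, indent=1))
    log.info("repeatability (%s): grand mean |error| %.1f nm", mode,
             1e3 * rep.grand_mean_abs_error)
    if plot:
        _boxplot(rep, plot)


@evaluate.command()
@click.option("--calib", "calib_path", type=click.Path(exists=True), required=True)
@click.option("--rows", type=int, default=8)
@click.option("--cols", type=int, default=12)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(dir_okay=False), required=True)
@click.option("--plot", type=click.Path(dir_okay=False), default=None)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
def plate(calib_path, rows, cols, seed, out, plot, config_path):
    """Multiwell-plate residual-defocus protocol."""
    import pandas as pd
    from .evaluation import simulate_plate
    cfg = _load_config(config_path)
    table = load_calibration(calib_path)
    rep = simulate_plate(rows, cols, table, beam=cfg.beam, camera=cfg.camera,
                         background=cfg.background(), noise=cfg.noise,
                         seed=seed)
    pd.DataFrame(rep.well_mean).to_csv(out, index_label="row")
    summary = {"std_of_means_um": rep.std_of_means,
               "mean_abs_error_um": rep.mean_abs_error,
               "shape": list(rep.shape)}
    Path(out).with_suffix(".summary.json").write_text(json.dumps(summary, indent=1))
    log.info("plate: std of well means %.1f nm, mean |error| %.1f nm",
             1e3 * rep.std_of_means, 1e3 * rep.mean_abs_error)
    if plot:
        _heatmap(rep, plot)


@evaluate.command()
@click.option("--calib", "calib_path", type=click.Path(exists=True), required=True)
@click.option("--duration", type=float, default=600.0)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(dir_okay=False), required=True)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
def stability(calib_path, duration, seed, out, config_path):
    """Closed-loop stability protocol under drift."""
    from .evaluation import run_stability
    cfg = _load_config(config_path)
    table = load_calibration(calib_path)
    flog, std = run_stability(duration, table, drift_model=cfg.drift_model,
                              drift_params=cfg.drift_params,
                              config=cfg.controller, beam=cfg.beam,
                              camera=cfg.camera, background=cfg.background(),
                              noise=cfg.noise, seed=seed)
    flog.to_csv(out)
    Path(out).with_suffix(".summary.json").write_text(json.dumps(
        {"residual_std_um": std, "updates": int(flog.timestamp.size),
         "lock_lost": bool(flog.lock_lost)}, indent=1))
    log.info("stability: residual std %.1f nm over %d updates", 1e3 * std,
             flog.timestamp.size)


def _boxplot(rep, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    offsets = sorted(rep.errors)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.boxplot([1e3 * rep.errors[o] for o in offsets],
               positions=offsets, widths=0.6 * np.diff(offsets).mean())
    ax.axhspan(-1e3 * 0.325, 1e3 * 0.325, alpha=0.15, color="red",
               label="depth of field")
    ax.set_xlabel("initial defocus (um)")
    ax.set_ylabel("refocusing error (nm)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _heatmap(rep, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    im = ax1.imshow(rep.well_mean, cmap="coolwarm", vmin=-1, vmax=1)
    fig.colorbar(im, ax=ax1, label="mean residual defocus (um)")
    ax1.set_title("per-well mean residual")
    ax2.hist(1e3 * rep.well_mean.ravel(), bins=20)
    ax2.set_xlabel("well mean residual (nm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def main() -> None:
    try:
        cli(standalone_mode=True)
    except Exception:  # pragma: no cover - click handles usage errors
        log.exception("command failed")
        sys.exit(1)


if __name__ == "__main__":
    main()
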