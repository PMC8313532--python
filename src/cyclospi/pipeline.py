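"""End-to-end driver: generate-code -> make-mask -> simulate -> reconstruct
-> evaluate, with JSON configuration, provenance logging and a hashed
artifact manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from . import codes as codes_mod
from .codes import CyclicCode, validate_code
from .mask_layout import Layout2D, MaskGeometry, fold_crt
from .phantoms import Phantom, load_user_image, resolution_target, worm_like_sequence
from .recon import ImageEstimate, fuse, image_metrics
from .sim import AcquisitionConfig, acquire, acquire_video, noise_from_dict

__all__ = ["RunConfig", "run_pipeline", "video_pipeline", "DEFAULT_CONFIG"]

log = logging.getLogger("cyclospi")

#: Reference end-to-end experiment: rectangular 101 x 103 twin-prime mask,
#: five-fold oversampling, noiseless resolution target.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "code": {"method": "twin_prime", "p": 101, "q": 103},
    "layout": {"p": 101, "q": 103},
    "geometry": {"cell_width_um": 1.5, "pattern_radius_mm": 55.0, "rotation_speed_rpm": 600.0},
    "acquisition": {"oversampling": 5, "noise": {"kind": "none"}},
    "phantom": {"kind": "resolution_target", "bar_widths": [2, 3, 5, 8]},
    "reconstruction": {"deblend": True},
}


class ConfigError(ValueError):
    """Raised when a run configuration fails schema validation."""


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration (see :data:`DEFAULT_CONFIG`)."""

    seed: int
    code: dict
    layout: dict
    geometry: MaskGeometry
    acquisition: dict
    phantom: dict
    reconstruction: dict = field(default_factory=dict)
    n_frames: int | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        d = dict(DEFAULT_CONFIG)
        d.update(raw)
        for key in ("code", "layout", "acquisition", "phantom"):
            if not isinstance(d.get(key), dict):
                raise ConfigError(f"config section {key!r} missing or not an object")
        method = d["code"].get("method")
        if method not in ("quadratic_residue", "twin_prime", "m_sequence"):
            raise ConfigError(f"unknown code method {method!r}")
        p, q = int(d["layout"]["p"]), int(d["layout"]["q"])
        order = _code_order(d["code"])
        if order != p * q:
            raise ConfigError(
                f"code order {order} does not match layout {p}x{q} = {p * q}"
            )
        acq = d["acquisition"]
        if int(acq.get("oversampling", 1)) < 1:
            raise ConfigError("acquisition.oversampling must be >= 1")
        noise_from_dict(acq.get("noise"))  # raises on malformed noise spec
        kind = d["phantom"].get("kind")
        if kind not in ("resolution_target", "worm_like", "user_image"):
            raise ConfigError(f"unknown phantom kind {kind!r}")
        geometry = MaskGeometry(**d["geometry"]) if d.get("geometry") else MaskGeometry()
        n_frames = d.get("n_frames")
        return cls(
            seed=int(d.get("seed", 0)),
            code=d["code"],
            layout={"p": p, "q": q},
            geometry=geometry,
            acquisition=acq,
            phantom=d["phantom"],
            reconstruction=d.get("reconstruction", {}),
            n_frames=int(n_frames) if n_frames is not None else None,
        )

    def resolved(self) -> dict:
        return {
            "seed": self.seed,
            "code": self.code,
            "layout": self.layout,
            "geometry": self.geometry.to_dict(),
            "acquisition": self.acquisition,
            "phantom": self.phantom,
            "reconstruction": self.reconstruction,
            "n_frames": self.n_frames,
        }


def _code_order(spec: dict) -> int:
    method = spec["method"]
    if method == "quadratic_residue":
        return int(spec["p"])
    if method == "twin_prime":
        return int(spec["p"]) * int(spec["q"])
    return (1 << int(spec["m"])) - 1


def build_code(spec: dict) -> CyclicCode:
    method = spec["method"]
    if method == "quadratic_residue":
        return codes_mod.qr_code(int(spec["p"]))
    if method == "twin_prime":
        return codes_mod.twin_prime_code(int(spec["p"]), int(spec["q"]))
    if method == "m_sequence":
        taps = spec.get("taps")
        return codes_mod.m_sequence_code(int(spec["m"]), taps)
    raise ConfigError(f"unknown code method {method!r}")


def build_phantoms(cfg: RunConfig) -> list[Phantom]:
    p, q = cfg.layout["p"], cfg.layout["q"]
    spec = cfg.phantom
    kind = spec["kind"]
    if kind == "resolution_target":
        return [resolution_target(p, q, spec.get("bar_widths", [2, 3, 5]))]
    if kind == "worm_like":
        return worm_like_sequence(
            p,
            q,
            n_frames=cfg.n_frames or int(spec.get("n_frames", 1)),
            seed=cfg.seed,
            n_worms=int(spec.get("n_worms", 1)),
            speed=float(spec.get("speed", 1.5)),
        )
    return [load_user_image(spec["path"], p, q)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_estimate(est: ImageEstimate, out: Path, stem: str) -> list[Path]:
    tif = out / f"{stem}.tif"
    tifffile.imwrite(tif, est.image.astype(np.float32))
    png = out / f"{stem}.png"
    lo, hi = float(est.image.min()), float(est.image.max())
    scale = (est.image - lo) / (hi - lo) if hi > lo else np.zeros_like(est.image)
    iio.imwrite(png, (scale * 255).astype(np.uint8))
    return [tif, png]


def run_pipeline(config: dict | RunConfig, out_dir: str | Path) -> dict:
    """Run the full synthetic experiment; returns the manifest dict.

    Writes code text/JSON, layout JSON, phantom TIFF(s), trace CSV(s),
    reconstruction TIFF/PNG(s), metrics JSON, the resolved config and a
    manifest with SHA-256 content hashes.  Deterministic for a fixed seed.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    artifacts: list[Path] = []
    metrics_all = []
    try:
        stage = "config"
        (out / "config.json").write_text(json.dumps(cfg.resolved(), indent=2) + "\n")
        artifacts.append(out / "config.json")

        stage = "generate-code"
        log.info("stage %s: %s", stage, cfg.code)
        code = build_code(cfg.code)
        report = validate_code(code)
        if not report.ok:
            raise RuntimeError(f"generated code failed validation: {report}")
        code.save_txt(out / "code.txt")
        code.save_json(out / "code.json")
        artifacts += [out / "code.txt", out / "code.json"]

        stage = "make-layout"
        log.info("stage %s: %s", stage, cfg.layout)
        layout = fold_crt(code, cfg.layout["p"], cfg.layout["q"])
        layout.to_json(out / "layout.json")
        artifacts.append(out / "layout.json")

        stage = "phantom"
        phantoms = build_phantoms(cfg)
        log.info("stage %s: %d frame(s)", stage, len(phantoms))
        for i, ph in enumerate(phantoms):
            path = out / f"phantom_{i:03d}.tif"
            ph.save(path)
            artifacts += [path, path.with_suffix(".json")]

        stage = "simulate"
        acq = AcquisitionConfig(
            oversampling=int(cfg.acquisition.get("oversampling", 1)),
            noise=noise_from_dict(cfg.acquisition.get("noise")),
            seed=cfg.seed,
            geometry=cfg.geometry,
            phase_offset=float(cfg.acquisition.get("phase_offset", 0.0)),
        )
        log.info("stage %s: M=%d noise=%s", stage, acq.oversampling, acq.noise)
        xs = [layout.unfold(ph.image) for ph in phantoms]
        traces = acquire_video(code, xs, acq)
        for tr in traces:
            path = out / f"trace_{tr.frame_index:03d}.csv"
            tr.save_csv(path)
            artifacts += [path, path.with_suffix(".json")]

        stage = "reconstruct"
        deblend = bool(cfg.reconstruction.get("deblend", False))
        log.info("stage %s: deblend=%s", stage, deblend)
        estimates = [fuse(tr, code, layout, deblend=deblend) for tr in traces]
        for i, est in enumerate(estimates):
            artifacts += _write_estimate(est, out, f"recon_{i:03d}")

        stage = "evaluate"
        for ph, est in zip(phantoms, estimates):
            m = image_metrics(est, ph)
            metrics_all.append(
                {"rmse": m.rmse, "psnr": m.psnr, "bar_contrast": m.bar_contrast}
            )
        (out / "metrics.json").write_text(json.dumps(metrics_all, indent=2) + "\n")
        artifacts.append(out / "metrics.json")

        if len(phantoms) > 1:
            stage = "video"
            gif = out / "recon.gif"
            frames8 = [
                (np.clip(e.image, 0, 1) * 255).astype(np.uint8) for e in estimates
            ]
            iio.imwrite(gif, frames8, extension=".gif", duration=100, loop=0)
            artifacts.append(gif)
    except Exception as exc:
        log.error("pipeline failed in stage %r: %s", stage, exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    manifest = {
        "n_frames": len(metrics_all),
        "metrics": metrics_all,
        "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def video_pipeline(config: dict | RunConfig, out_dir: str | Path) -> dict:
    """Multi-frame variant of :func:`run_pipeline` (requires n_frames >= 2)."""
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_dict(config)
    if (cfg.n_frames or 1) < 2:
        raise ConfigError("video_pipeline requires n_frames >= 2")
    if cfg.phantom.get("kind") != "worm_like":
        raise ConfigError("video_pipeline expects a worm_like phantom sequence")
    return run_pipeline(cfg, out_dir)
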