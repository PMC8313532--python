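"""Forward model of the spinning-mask acquisition.

One frame consists of N pattern transitions; during each transition the
mask slides continuously by one cell, so the detector signal blends the
projections of two neighbouring basis functions.  M samples are taken
per transition (oversampling), sample m at sub-cell displacement
delta = m/M (plus an optional phase offset).  Detector noise can be
additive Gaussian or Poisson shot noise.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .codes import CyclicCode, _correlate_bits
from .mask_layout import MaskGeometry, transition_time

__all__ = [
    "GaussianNoise",
    "ShotNoise",
    "AcquisitionConfig",
    "SignalTrace",
    "project",
    "blended_measurement",
    "acquire",
    "acquire_video",
]

# Above this order the dense circulant product is replaced by an FFT
# correlation (identical result, O(N log N)).
_DENSE_LIMIT = 1024


@dataclass(frozen=True)
class GaussianNoise:
    """Additive N(0, sigma^2) detector noise."""

    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def apply(self, v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return v + rng.normal(0.0, self.sigma, size=v.shape)

    def to_dict(self) -> dict:
        return {"kind": "gaussian", "sigma": self.sigma}


@dataclass(frozen=True)
class ShotNoise:
    """Poisson photon-counting noise: v -> Poisson(v * k) / k."""

    photons_per_unit: float

    def __post_init__(self) -> None:
        if not self.photons_per_unit > 0:
            raise ValueError("photons_per_unit must be positive")

    def apply(self, v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        lam = np.maximum(v, 0.0) * self.photons_per_unit
        return rng.poisson(lam).astype(np.float64) / self.photons_per_unit

    def to_dict(self) -> dict:
        return {"kind": "shot", "photons_per_unit": self.photons_per_unit}


NoiseModel = GaussianNoise | ShotNoise | None


def noise_from_dict(d: dict | None) -> NoiseModel:
    if d is None or d.get("kind", "none") == "none":
        return None
    if d["kind"] == "gaussian":
        return GaussianNoise(sigma=float(d["sigma"]))
    if d["kind"] == "shot":
        return ShotNoise(photons_per_unit=float(d["photons_per_unit"]))
    raise ValueError(f"unknown noise model {d!r}")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Sampling parameters for one frame.

    oversampling:
        M, samples per pattern transition.
    noise:
        None, :class:`GaussianNoise` or :class:`ShotNoise`.
    seed:
        Seed for the noise generator; acquisitions are bit-reproducible.
    geometry:
        Optional mask geometry; when given, traces carry a physical
        time axis with sample spacing T/M.
    phase_offset:
        delta_0 in [0, 1/M): sub-cell displacement of the first sample
        of each transition (real systems have an unknown phase).
    """

    oversampling: int = 5
    noise: NoiseModel = None
    seed: int = 0
    geometry: MaskGeometry | None = None
    phase_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.oversampling < 1:
            raise ValueError("oversampling must be >= 1")
        if not 0 <= self.phase_offset < 1.0 / self.oversampling:
            raise ValueError("phase_offset must lie in [0, 1/M)")

    def to_dict(self) -> dict:
        return {
            "oversampling": self.oversampling,
            "noise": self.noise.to_dict() if self.noise else {"kind": "none"},
            "seed": self.seed,
            "geometry": self.geometry.to_dict() if self.geometry else None,
            "phase_offset": self.phase_offset,
        }


@dataclass(frozen=True, eq=False)
class SignalTrace:
    """The M*N detector samples of one frame."""

    samples: np.ndarray
    order: int
    oversampling: int
    time_step: float = 1.0
    frame_index: int = 0
    phase_offset: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.shape != (self.order * self.oversampling,):
            raise ValueError(
                f"trace must have length M*N = {self.order * self.oversampling}, "
                f"got {samples.shape}"
            )
        object.__setattr__(self, "samples", samples)

    def save_csv(self, path: str | Path) -> None:
        """Two-column ``time,value`` CSV plus a JSON metadata sidecar."""
        path = Path(path)
        t = np.arange(self.samples.size) * self.time_step
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time", "value"])
            for ti, vi in zip(t, self.samples):
                w.writerow([repr(float(ti)), repr(float(vi))])
        path.with_suffix(".json").write_text(
            json.dumps(
                {
                    "order": self.order,
                    "oversampling": self.oversampling,
                    "time_step": self.time_step,
                    "frame_index": self.frame_index,
                    "phase_offset": self.phase_offset,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def load_csv(cls, path: str | Path) -> "SignalTrace":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        values = []
        with path.open() as fh:
            reader = csv.reader(fh)
            header = next(reader)
            if header[:2] != ["time", "value"]:
                raise ValueError(f"malformed trace CSV {path}")
            for row in reader:
                values.append(float(row[1]))
        return cls(
            samples=np.asarray(values),
            order=int(meta["order"]),
            oversampling=int(meta["oversampling"]),
            time_step=float(meta["time_step"]),
            frame_index=int(meta.get("frame_index", 0)),
            phase_offset=float(meta.get("phase_offset", 0.0)),
        )


def project(code: CyclicCode, x: np.ndarray) -> np.ndarray:
    """All N noiseless pattern measurements: y[k] = sum_i bits[(i+k) % N] x[i].

    Uses the dense circulant product for small N and an FFT cyclic
    correlation beyond; both agree to floating-point tolerance.
    """
    x = np.asarray(x, dtype=np.float64)
    n = code.order
    if x.shape != (n,):
        raise ValueError(f"x must have shape ({n},), got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    if n <= _DENSE_LIMIT:
        return code.matrix().astype(np.float64) @ x
    return _correlate_bits(code, x)


def blended_measurement(code: CyclicCode, x: np.ndarray, k: int, delta: float) -> float:
    """Detector value at sub-cell displacement delta within transition k.

    A uniformly translating binary mask mixes the two neighbouring
    projections linearly: (1 - delta) * y[k] + delta * y[k+1].
    """
    if not 0 <= delta < 1:
        raise ValueError("delta must lie in [0, 1)")
    if not 0 <= k < code.order:
        raise ValueError(f"k={k} out of range [0, {code.order})")
    y = project(code, x)
    return float((1.0 - delta) * y[k] + delta * y[(k + 1) % code.order])


def _blend_samples(y: np.ndarray, m_over: int, phase_offset: float) -> np.ndarray:
    """Noiseless M*N sample vector from the N projections."""
    n = y.size
    deltas = np.arange(m_over) / m_over + phase_offset  # (M,)
    y_next = np.roll(y, -1)
    samples = (1.0 - deltas)[None, :] * y[:, None] + deltas[None, :] * y_next[:, None]
    return samples.reshape(n * m_over)


def acquire(code: CyclicCode, x: np.ndarray, cfg: AcquisitionConfig) -> SignalTrace:
    """Simulate one frame: samples[k*M + m] at displacement m/M + delta_0."""
    y = project(code, x)
    samples = _blend_samples(y, cfg.oversampling, cfg.phase_offset)
    if cfg.noise is not None:
        rng = np.random.default_rng(cfg.seed)
        samples = cfg.noise.apply(samples, rng)
    dt = (
        transition_time(cfg.geometry) / cfg.oversampling
        if cfg.geometry is not None
        else 1.0 / cfg.oversampling
    )
    return SignalTrace(
        samples=samples,
        order=code.order,
        oversampling=cfg.oversampling,
        time_step=dt,
        phase_offset=cfg.phase_offset,
    )


def acquire_video(
    code: CyclicCode, xs: Sequence[np.ndarray], cfg: AcquisitionConfig
) -> list[SignalTrace]:
    """One trace per frame; frame f uses a noise seed derived from
    (cfg.seed, f) so realizations differ but remain reproducible.
    The object is assumed static within each frame."""
    if len(xs) == 0:
        raise ValueError("need at least one frame")
    shapes = {np.asarray(x).shape for x in xs}
    if len(shapes) != 1:
        raise ValueError("all frames must have the same shape")
    traces = []
    for f, x in enumerate(xs):
        frame_cfg = AcquisitionConfig(
            oversampling=cfg.oversampling,
            noise=cfg.noise,
            seed=_frame_seed(cfg.seed, f),
            geometry=cfg.geometry,
            phase_offset=cfg.phase_offset,
        )
        tr = acquire(code, x, frame_cfg)
        traces.append(
            SignalTrace(
                samples=tr.samples,
                order=tr.order,
                oversampling=tr.oversampling,
                time_step=tr.time_step,
                frame_index=f,
                phase_offset=tr.phase_offset,
            )
        )
    return traces


def _frame_seed(seed: int, frame: int) -> int:
    """Deterministic per-frame seed derived from (seed, frame)."""
    return int(np.random.SeedSequence([seed, frame]).generate_state(1)[0])
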