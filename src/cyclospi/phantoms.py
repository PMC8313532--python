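"""Synthetic imaged objects with known ground truth.

Phantom values are transmittance in [0, 1]: 1 means the cell passes all
light toward the detector, 0 blocks it.  Absorbing and scattering
structures are treated identically (both just reduce the detected
light).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from scipy.interpolate import CubicSpline

__all__ = [
    "Phantom",
    "resolution_target",
    "worm_like_sequence",
    "load_user_image",
]

_KINDS = ("resolution_target", "grayscale", "worm_like", "user_image")


@dataclass(frozen=True, eq=False)
class Phantom:
    """A p x q transmittance map plus ground-truth metadata."""

    image: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=np.float64)
        if img.ndim != 2:
            raise ValueError("phantom image must be 2D")
        if img.min() < 0 or img.max() > 1:
            raise ValueError("phantom values must lie in [0, 1]")
        if self.kind not in _KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        object.__setattr__(self, "image", img)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape

    def save(self, path: str | Path) -> None:
        """16-bit TIFF plus a JSON ground-truth sidecar."""
        path = Path(path)
        u16 = np.round(self.image * 65535).astype(np.uint16)
        tifffile.imwrite(path, u16)
        meta = {"kind": self.kind, "shape": list(self.shape)}
        meta.update(_jsonable(self.meta))
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Phantom":
        path = Path(path)
        u16 = tifffile.imread(path)
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        kind = meta.pop("kind", "grayscale")
        meta.pop("shape", None)
        return cls(image=u16.astype(np.float64) / 65535.0, kind=kind, meta=meta)


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            out[k] = v.tolist()
        elif isinstance(v, (np.integer, np.floating)):
            out[k] = v.item()
        else:
            out[k] = v
    return out


def resolution_target(p: int, q: int, bar_widths: list[int]) -> Phantom:
    """Binary bar-triplet target: for each width a group of three vertical
    bars of that width, value 1 inside the bars, 0 elsewhere.

    The groups are laid out left to right with a gap of one bar width
    between bars and two cells between groups.  Raises if the groups do
    not fit in the p x q frame.
    """
    img = np.zeros((p, q), dtype=np.float64)
    bar_mask = np.zeros((p, q), dtype=bool)
    margin = min(2, max(0, p // 10))
    top, bottom = margin, p - margin
    if bottom <= top:
        top, bottom = 0, p
    x = 2
    for w in bar_widths:
        w = int(w)
        if w <= 0:
            raise ValueError("bar widths must be positive")
        group_w = 5 * w  # three bars + two gaps
        if x + group_w > q - 2 or bottom - top < w:
            raise ValueError(
                f"bar group of width {w} does not fit in a {p}x{q} frame at x={x}"
            )
        for b in range(3):
            x0 = x + b * 2 * w
            img[top:bottom, x0 : x0 + w] = 1.0
            bar_mask[top:bottom, x0 : x0 + w] = True
        x += group_w + 2
    return Phantom(
        image=img,
        kind="resolution_target",
        meta={"bar_widths": list(map(int, bar_widths)), "bar_mask": bar_mask},
    )


def worm_like_sequence(
    p: int,
    q: int,
    n_frames: int,
    seed: int,
    *,
    n_worms: int = 1,
    speed: float = 1.5,
    width: float = 2.0,
    dip_range: tuple[float, float] = (0.3, 0.7),
) -> list[Phantom]:
    """Moving grayscale curve phantoms on a transparent background.

    Each worm is a random cubic-spline backbone rendered with a Gaussian
    cross-section of the given width; its transmittance dip is drawn from
    ``dip_range``.  Between frames each worm translates by at most
    ``speed`` pixels (plus a mild shape wiggle), so the backbone centroid
    displacement per frame is bounded by the configured speed.
    Deterministic for a fixed seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    worms = []
    for _ in range(n_worms):
        n_ctrl = 5
        ctrl = np.column_stack(
            [
                rng.uniform(0.25 * p, 0.75 * p, n_ctrl),
                rng.uniform(0.25 * q, 0.75 * q, n_ctrl),
            ]
        )
        dip = rng.uniform(*dip_range)
        heading = rng.uniform(0, 2 * np.pi)
        worms.append({"ctrl": ctrl, "dip": dip, "heading": heading})

    frames: list[Phantom] = []
    for f in range(n_frames):
        img = np.ones((p, q), dtype=np.float64)
        centroids = []
        for w in worms:
            centroids.append(w["ctrl"].mean(axis=0).copy())
            _stamp_worm(img, w["ctrl"], w["dip"], width)
            # advance for the next frame: bounded translation + heading drift
            w["heading"] += rng.normal(0, 0.3)
            step = speed * rng.uniform(0.5, 1.0)
            v = step * np.array([np.cos(w["heading"]), np.sin(w["heading"])])
            w["ctrl"] = w["ctrl"] + v
            # steer back toward the frame centre near the borders (heading
            # only, so the per-frame displacement stays bounded by `speed`)
            c = w["ctrl"].mean(axis=0)
            if not (0.1 * p < c[0] < 0.9 * p):
                w["heading"] = np.pi - w["heading"]
            if not (0.1 * q < c[1] < 0.9 * q):
                w["heading"] = -w["heading"]
        frames.append(
            Phantom(
                image=np.clip(img, 0.0, 1.0),
                kind="worm_like",
                meta={
                    "frame": f,
                    "speed": speed,
                    "centroids": np.asarray(centroids),
                    "seed": seed,
                },
            )
        )
    return frames


def _stamp_worm(img: np.ndarray, ctrl: np.ndarray, dip: float, width: float) -> None:
    """Multiply a Gaussian-profile dark curve into a transmittance image."""
    t = np.linspace(0, 1, len(ctrl))
    spline = CubicSpline(t, ctrl, axis=0)
    pts = spline(np.linspace(0, 1, 60 * len(ctrl)))
    p, q = img.shape
    att = np.ones_like(img)
    r = int(np.ceil(3 * width))
    for y, x in pts:
        yi, xi = int(round(y)), int(round(x))
        y0, y1 = max(0, yi - r), min(p, yi + r + 1)
        x0, x1 = max(0, xi - r), min(q, xi + r + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (yy - y) ** 2 + (xx - x) ** 2
        profile = 1.0 - dip * np.exp(-d2 / (2.0 * width**2))
        np.minimum(att[y0:y1, x0:x1], profile, out=att[y0:y1, x0:x1])
    img *= att


def load_user_image(path: str | Path, p: int, q: int) -> Phantom:
    """Load a grayscale image, resample it to p x q and rescale to [0, 1]."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = im.convert("F") if im.mode in ("I", "I;16", "F") else im.convert("L")
            arr = np.asarray(im.resize((q, p), Image.BILINEAR), dtype=np.float64)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    hi = arr.max()
    if hi > 0:
        arr = arr / (255.0 if hi <= 255 else 65535.0)
    arr = np.clip(arr, 0.0, 1.0)
    return Phantom(image=arr, kind="user_image", meta={"source": str(path)})
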