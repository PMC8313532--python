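"""1D-to-2D mask folding and physical timing of the spinning mask.

A length-N cyclic code printed along an arc of a spinning disk produces
one basis pattern per single-cell advance.  For rectangular imaging the
1D code is folded onto a p x q grid with gcd(p, q) = 1 through the
Chinese-remainder index map i -> (i mod p, i mod q); a +1 cyclic shift of
the code then corresponds to a (+1 mod p, +1 mod q) displacement of the
2D pattern.

Timing quantities are derived from the mask geometry: the transition
time T between neighbouring basis functions is the time the arc takes to
advance by one cell width at the pattern radius.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .codes import CyclicCode

__all__ = [
    "MaskGeometry",
    "Layout2D",
    "FrameRate",
    "fold_crt",
    "transition_time",
    "modulation_rate",
    "frame_rate",
    "cell_size_variation",
    "DEFAULT_GEOMETRY",
]


@dataclass(frozen=True)
class MaskGeometry:
    """Physical mask parameters determining pattern timing.

    cell_width_um:      tangential cell width in micrometres
    pattern_radius_mm:  distance of the pattern from the rotation centre, mm
    rotation_speed_rpm: disk speed in revolutions per minute
    """

    cell_width_um: float = 1.5
    pattern_radius_mm: float = 55.0
    rotation_speed_rpm: float = 600.0

    def __post_init__(self) -> None:
        for name in ("cell_width_um", "pattern_radius_mm", "rotation_speed_rpm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.cell_width_um * 1e-3 >= 2 * math.pi * self.pattern_radius_mm:
            raise ValueError("cell width must be much smaller than the track circumference")

    def to_dict(self) -> dict:
        return {
            "cell_width_um": self.cell_width_um,
            "pattern_radius_mm": self.pattern_radius_mm,
            "rotation_speed_rpm": self.rotation_speed_rpm,
        }


#: Geometry of the reference configuration (1.5 um cells on a 55 mm track
#: at 600 rpm), which yields T of about 0.43 us.
DEFAULT_GEOMETRY = MaskGeometry()


def transition_time(geom: MaskGeometry) -> float:
    """Time in seconds for the mask to advance one cell at the pattern radius.

    T = cell_width / (2 pi radius * revolutions_per_second)
    """
    cell_m = geom.cell_width_um * 1e-6
    radius_m = geom.pattern_radius_mm * 1e-3
    rev_per_s = geom.rotation_speed_rpm / 60.0
    return cell_m / (2.0 * math.pi * radius_m * rev_per_s)


def modulation_rate(geom: MaskGeometry) -> float:
    """Patterns per second: the reciprocal of the transition time."""
    return 1.0 / transition_time(geom)


class FrameRate(NamedTuple):
    exact: float
    nearest: int


def frame_rate(recording_rate: float, n_pixels: int) -> FrameRate:
    """Frames per second from a total pixel recording rate.

    Returns both the exact ratio and its nearest integer.
    """
    if recording_rate < 0:
        raise ValueError("recording_rate must be non-negative")
    if n_pixels <= 0:
        raise ValueError("n_pixels must be positive")
    exact = recording_rate / n_pixels
    return FrameRate(exact=exact, nearest=int(round(exact)))


def cell_size_variation(geom: MaskGeometry, pattern_height_mm: float) -> float:
    """Fractional spread of tangential cell width across the pattern's
    radial extent: (r_outer - r_inner) / r_center."""
    if pattern_height_mm < 0:
        raise ValueError("pattern_height_mm must be non-negative")
    if pattern_height_mm >= 2 * geom.pattern_radius_mm:
        raise ValueError("pattern height exceeds the mask diameter")
    return pattern_height_mm / geom.pattern_radius_mm


@dataclass(frozen=True, eq=False)
class Layout2D:
    """Bijective map from 1D code index to 2D pixel coordinates.

    ``row_of[i], col_of[i]`` give the pixel of code element i.  For the
    CRT layout these are (i mod p, i mod q).  ``scan_axis`` records the
    2D displacement of a +1 cyclic code shift (purely informational; all
    sub-pixel arithmetic happens in the 1D code domain).
    """

    rows: int
    cols: int
    row_of: np.ndarray
    col_of: np.ndarray
    method: str = "crt"
    scan_axis: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        n = self.size
        row_of = np.asarray(self.row_of, dtype=np.intp)
        col_of = np.asarray(self.col_of, dtype=np.intp)
        if row_of.shape != (n,) or col_of.shape != (n,):
            raise ValueError("index arrays must have length rows*cols")
        flat = row_of * self.cols + col_of
        if np.unique(flat).size != n:
            raise ValueError("index map is not a bijection")
        object.__setattr__(self, "row_of", row_of)
        object.__setattr__(self, "col_of", col_of)

    @property
    def size(self) -> int:
        return self.rows * self.cols

    def fold(self, x: np.ndarray) -> np.ndarray:
        """Arrange a length-N vector into the p x q image."""
        x = np.asarray(x)
        if x.shape != (self.size,):
            raise ValueError(f"expected vector of length {self.size}, got {x.shape}")
        img = np.empty((self.rows, self.cols), dtype=x.dtype)
        img[self.row_of, self.col_of] = x
        return img

    def unfold(self, image2d: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`fold`: read the image back into code order."""
        image2d = np.asarray(image2d)
        if image2d.shape != (self.rows, self.cols):
            raise ValueError(
                f"expected image of shape ({self.rows}, {self.cols}), got {image2d.shape}"
            )
        return image2d[self.row_of, self.col_of]

    def pattern_image(self, code: CyclicCode, shift: int = 0) -> np.ndarray:
        """8-bit rendering of the folded pattern at a given cyclic shift
        (0 = opaque, 255 = transparent)."""
        from .codes import smatrix_row

        return (self.fold(smatrix_row(code, shift)) * 255).astype(np.uint8)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"p": self.rows, "q": self.cols, "method": self.method}, indent=2)
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Layout2D":
        d = json.loads(Path(path).read_text())
        if d.get("method", "crt") != "crt":
            raise ValueError(f"unsupported layout method {d.get('method')!r}")
        return crt_layout(int(d["p"]), int(d["q"]))


def crt_layout(p: int, q: int) -> Layout2D:
    """Chinese-remainder layout for a p x q grid with gcd(p, q) = 1."""
    if p <= 0 or q <= 0:
        raise ValueError("grid dimensions must be positive")
    if math.gcd(p, q) != 1:
        raise ValueError(f"gcd({p}, {q}) != 1: CRT folding needs coprime dimensions")
    i = np.arange(p * q)
    return Layout2D(rows=p, cols=q, row_of=i % p, col_of=i % q, method="crt")


def fold_crt(code: CyclicCode, p: int, q: int) -> Layout2D:
    """CRT layout matched to a code of order p*q."""
    if p * q != code.order:
        raise ValueError(f"p*q = {p * q} does not match code order {code.order}")
    return crt_layout(p, q)
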