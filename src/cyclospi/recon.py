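"""Image reconstruction from single-pixel traces.

The circulant structure of the measurement operator is exploited
throughout: inversion is a pointwise division in the Fourier domain
(O(N log N), no regularization needed because the basis is
well-conditioned), the M oversampled datasets are demultiplexed, each is
reconstructed independently, aligned by a fractional cyclic shift in the
1D code domain, and averaged.  An optional compressed-sensing path
solves a TV-regularized least-squares problem from a subset of the
measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codes import CyclicCode, validate_code
from .mask_layout import Layout2D
from .phantoms import Phantom
from .sim import SignalTrace, project

__all__ = [
    "ImageEstimate",
    "Metrics",
    "fft_reconstruct",
    "demux",
    "subpixel_align",
    "fuse",
    "cs_reconstruct",
    "image_metrics",
]


@dataclass(frozen=True, eq=False)
class ImageEstimate:
    """Reconstructed transmittance image plus metadata."""

    image: np.ndarray
    x_code_domain: np.ndarray
    n_datasets_used: int
    residual_norm: float
    method: str = "fft"
    converged: bool = True


@dataclass(frozen=True)
class Metrics:
    rmse: float
    psnr: float
    bar_contrast: float | None = None


def _eigenvalues(code: CyclicCode) -> np.ndarray:
    """Fourier multipliers of y = project(code, x): Y = B * conj(X) with
    B = DFT(bits), i.e. x = ifft(conj(fft(y) / B))."""
    return code.dft()


def fft_reconstruct(code: CyclicCode, y: np.ndarray) -> np.ndarray:
    """Invert y = S x by Fourier-domain division in O(N log N).

    Raises if the code's DFT has a (near-)zero coefficient, i.e. the
    circulant operator is singular.
    """
    y = np.asarray(y, dtype=np.float64)
    n = code.order
    if y.shape != (n,):
        raise ValueError(f"y must have shape ({n},), got {y.shape}")
    lam = _eigenvalues(code)
    if np.min(np.abs(lam)) <= 1e-12 * n:
        raise ValueError("singular circulant operator: code has a zero DFT coefficient")
    return np.fft.ifft(np.conj(np.fft.fft(y) / lam)).real


def demux(trace: SignalTrace) -> np.ndarray:
    """Split the interleaved trace into its M datasets of N points each.

    Returns an (M, N) array; dataset m holds samples {k*M + m}.
    """
    m, n = trace.oversampling, trace.order
    return trace.samples.reshape(n, m).T.copy()


def remux(datasets: np.ndarray) -> np.ndarray:
    """Inverse of :func:`demux`: interleave M datasets back into a trace."""
    return datasets.T.reshape(-1).copy()


def subpixel_align(x_m: np.ndarray, delta: float) -> np.ndarray:
    """Apply a fractional cyclic shift of -delta code-index units.

    Implemented as a Fourier-domain phase ramp, exact for band-limited
    content; delta = 0 is the identity.  Odd N is assumed throughout the
    package (every S-matrix order is odd), so there is no ambiguous
    Nyquist bin.
    """
    x_m = np.asarray(x_m, dtype=np.float64)
    if delta == 0:
        return x_m.copy()
    n = x_m.size
    freqs = np.fft.fftfreq(n, d=1.0 / n)
    ramp = np.exp(2j * np.pi * freqs * delta / n)
    return np.fft.ifft(np.fft.fft(x_m) * ramp).real


def _blend_response(n: int, m_over: int, phase_offset: float) -> np.ndarray:
    """Fourier multiplier of align-then-average over the M blended datasets."""
    freqs = np.fft.fftfreq(n, d=1.0 / n)
    h = np.zeros(n, dtype=complex)
    for m in range(m_over):
        d = m / m_over + phase_offset
        blend = (1.0 - d) + d * np.exp(-2j * np.pi * freqs / n)
        h += np.exp(2j * np.pi * freqs * d / n) * blend
    return h / m_over


def fuse(
    trace: SignalTrace,
    code: CyclicCode,
    layout: Layout2D,
    *,
    deblend: bool = False,
    deblend_eps: float = 1e-3,
) -> ImageEstimate:
    """Full reconstruction: demux -> FFT-invert each dataset -> sub-pixel
    align dataset m by delta = m/M -> average -> fold to 2D.

    With M = 1 and no noise the phantom is recovered exactly.  For M > 1
    the continuous mask translation acts as a mild (1-d, d) low-pass;
    ``deblend=True`` divides it out in the Fourier domain with a Tikhonov
    guard ``deblend_eps``.
    """
    n, m_over = trace.order, trace.oversampling
    if code.order != n or layout.size != n:
        raise ValueError("trace, code and layout must share the same order N")
    datasets = demux(trace)
    aligned = np.zeros(n)
    for m in range(m_over):
        x_m = fft_reconstruct(code, datasets[m])
        aligned += subpixel_align(x_m, m / m_over + trace.phase_offset)
    x = aligned / m_over
    if deblend and (m_over > 1 or trace.phase_offset != 0):
        h = _blend_response(n, m_over, trace.phase_offset)
        spec = np.fft.fft(x) * np.conj(h) / (np.abs(h) ** 2 + deblend_eps)
        x = np.fft.ifft(spec).real
    residual = float(np.linalg.norm(project(code, x) - datasets[0]))
    return ImageEstimate(
        image=layout.fold(x),
        x_code_domain=x,
        n_datasets_used=m_over,
        residual_norm=residual,
        method="fft",
    )


# ---------------------------------------------------------------------------
# compressed sensing (optional path)
# ---------------------------------------------------------------------------


def _tv_prox(z: np.ndarray, weight: float, n_iter: int = 30) -> np.ndarray:
    """Prox of anisotropic total variation on a 2D array (dual projection)."""
    if weight <= 0:
        return z
    p = np.zeros((z.shape[0] - 1, z.shape[1]))
    q = np.zeros((z.shape[0], z.shape[1] - 1))
    t = 1.0
    p_prev, q_prev = p, q
    step = 1.0 / 8.0
    for _ in range(n_iter):
        div = np.zeros_like(z)
        div[:-1, :] += p
        div[1:, :] -= p
        div[:, :-1] += q
        div[:, 1:] -= q
        u = z - weight * div
        gp = u[:-1, :] - u[1:, :]
        gq = u[:, :-1] - u[:, 1:]
        p_new = np.clip(p + step * gp / weight, -1.0, 1.0)
        q_new = np.clip(q + step * gq / weight, -1.0, 1.0)
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        p, q = (
            p_new + (t - 1) / t_new * (p_new - p_prev),
            q_new + (t - 1) / t_new * (q_new - q_prev),
        )
        p_prev, q_prev = p_new, q_new
        t = t_new
        p = np.clip(p, -1.0, 1.0)
        q = np.clip(q, -1.0, 1.0)
    div = np.zeros_like(z)
    div[:-1, :] += p_prev
    div[1:, :] -= p_prev
    div[:, :-1] += q_prev
    div[:, 1:] -= q_prev
    return z - weight * div


def tv_value(img: np.ndarray) -> float:
    """Anisotropic total variation of a 2D array."""
    return float(
        np.abs(np.diff(img, axis=0)).sum() + np.abs(np.diff(img, axis=1)).sum()
    )


def cs_reconstruct(
    code: CyclicCode,
    y_subset: np.ndarray,
    indices: np.ndarray,
    sparsity_weight: float,
    layout: Layout2D | None = None,
    *,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> ImageEstimate:
    """Reconstruct from a subset of measurements by FISTA on

        min_x 0.5 ||S_sub x - y||^2 + w * TV(fold(x))

    where S_sub keeps the given rows of the circulant operator.  With all
    indices and weight 0 this matches :func:`fft_reconstruct` to solver
    tolerance.  Non-convergence is flagged on the result, not raised.
    """
    n = code.order
    indices = np.asarray(indices, dtype=np.intp)
    y_subset = np.asarray(y_subset, dtype=np.float64)
    if indices.size == 0:
        raise ValueError("empty measurement set")
    if indices.size != y_subset.size:
        raise ValueError("indices and y_subset must have the same length")
    if indices.min() < 0 or indices.max() >= n:
        raise ValueError("indices out of range")
    if sparsity_weight < 0:
        raise ValueError("sparsity_weight must be non-negative")
    if sparsity_weight > 0 and layout is None:
        raise ValueError("a layout is required for the TV penalty")

    lam = np.abs(code.dft())
    lip = float(lam.max() ** 2)  # ||S_sub^T S_sub|| <= sigma_max(S)^2
    step = 1.0 / lip

    def grad(x: np.ndarray) -> np.ndarray:
        r_full = np.zeros(n)
        r_full[indices] = project(code, x)[indices] - y_subset
        # S^T r with S symmetric
        if n <= 1024:
            return code.matrix().astype(np.float64) @ r_full
        from .codes import _correlate_bits

        return _correlate_bits(code, r_full)

    def prox(z: np.ndarray) -> np.ndarray:
        if sparsity_weight == 0:
            return z
        img = _tv_prox(layout.fold(z), step * sparsity_weight)
        return layout.unfold(img)

    x = np.zeros(n)
    z = x.copy()
    t = 1.0
    converged = False
    for _ in range(max_iter):
        x_new = prox(z - step * grad(z))
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        z = x_new + (t - 1) / t_new * (x_new - x)
        denom = max(np.linalg.norm(x_new), 1e-12)
        if np.linalg.norm(x_new - x) / denom < tol:
            x = x_new
            converged = True
            break
        x, t = x_new, t_new
    residual = float(np.linalg.norm(project(code, x)[indices] - y_subset))
    if layout is not None:
        image = layout.fold(x)
    else:
        image = x.reshape(1, -1)
    return ImageEstimate(
        image=image,
        x_code_domain=x,
        n_datasets_used=1,
        residual_norm=residual,
        method="cs",
        converged=converged,
    )


def image_metrics(estimate: ImageEstimate | np.ndarray, truth: Phantom) -> Metrics:
    """RMSE, PSNR and (for bar phantoms) Michelson-style bar contrast."""
    img = estimate.image if isinstance(estimate, ImageEstimate) else np.asarray(estimate)
    if img.shape != truth.image.shape:
        raise ValueError(f"shape mismatch: {img.shape} vs {truth.image.shape}")
    err = img - truth.image
    rmse = float(np.sqrt(np.mean(err**2)))
    # dynamic range of the phantom class is [0, 1]
    psnr = float("inf") if rmse == 0 else float(20.0 * np.log10(1.0 / rmse))
    contrast = None
    bar_mask = truth.meta.get("bar_mask")
    if bar_mask is not None:
        bar_mask = np.asarray(bar_mask, dtype=bool)
        fg = float(img[bar_mask].mean()) if bar_mask.any() else 0.0
        bg = float(img[~bar_mask].mean()) if (~bar_mask).any() else 0.0
        denom = fg + bg
        contrast = 0.0 if denom == 0 else (fg - bg) / denom
    return Metrics(rmse=rmse, psnr=psnr, bar_contrast=contrast)
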