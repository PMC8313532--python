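# cyclospi

Single-pixel imaging (SPI) with cyclic Hadamard (S-matrix) masks, end to
end and fully synthetic: code construction, 1D-to-2D mask folding,
spinning-mask acquisition simulation with sub-pixel oversampling, and
FFT-based O(N log N) reconstruction with sub-pixel alignment and fusion.

In this SPI scheme a single binary code printed along an arc of a
spinning disk generates all N basis patterns by single-cell shifts.  The
detector is sampled M times during each one-cell transition; the M
interleaved datasets are reconstructed independently by circulant FFT
inversion, aligned by fractional cyclic shifts, and averaged.

## Modules

| module | contents |
| --- | --- |
| `cyclospi.codes` | `qr_code`, `twin_prime_code`, `m_sequence_code`, `validate_code`, `smatrix_row`, `analytic_inverse_apply` |
| `cyclospi.mask_layout` | `MaskGeometry`, `Layout2D`, `fold_crt`, `transition_time`, `modulation_rate`, `frame_rate`, `cell_size_variation` |
| `cyclospi.phantoms` | `resolution_target`, `worm_like_sequence`, `load_user_image` |
| `cyclospi.sim` | `AcquisitionConfig`, `SignalTrace`, `project`, `blended_measurement`, `acquire`, `acquire_video` |
| `cyclospi.recon` | `fft_reconstruct`, `demux`, `subpixel_align`, `fuse`, `cs_reconstruct`, `image_metrics` |
| `cyclospi.pipeline` / `cyclospi.cli` | `run_pipeline`, `video_pipeline`, JSON config, the `cyclospi` command |

## Quick start (Python)

```python
import numpy as np
from cyclospi import (twin_prime_code, fold_crt, resolution_target,
                      AcquisitionConfig, acquire, fuse, image_metrics)

code = twin_prime_code(101, 103)          # order N = 10,403 cyclic S-matrix
layout = fold_crt(code, 101, 103)         # CRT folding onto a 101 x 103 grid
phantom = resolution_target(101, 103, [2, 3, 5, 8])
x = layout.unfold(phantom.image)

trace = acquire(code, x, AcquisitionConfig(oversampling=5))
estimate = fuse(trace, code, layout, deblend=True)
print(image_metrics(estimate, phantom))
```

## Command line

```sh
cyclospi generate-code --method twin_prime -p 101 -q 103 --out code.txt
cyclospi make-layout --code code.txt -p 101 -q 103 --out layout.json
cyclospi phantom --kind resolution_target -p 101 -q 103 --bar-widths 2,3,5 --out ph.tif
cyclospi simulate --code code.txt --layout layout.json --phantom ph.tif -M 5 --out trace.csv
cyclospi reconstruct --trace trace.csv --code code.txt --layout layout.json --deblend --out rec.tif
cyclospi evaluate --image rec.tif --truth ph.tif
cyclospi timing                 # transition time / modulation rate / frame rate
cyclospi demo --out demo_run/   # default end-to-end experiment
```

`cyclospi demo --video --config cfg.json` runs the multi-frame pipeline
(moving worm-like phantoms, per-frame reconstruction, animated GIF).

## Conventions

* Code bits: 1 = transparent cell, 0 = opaque; `bits[0] = 1`, weight
  (N+1)/2, off-peak cyclic autocorrelation (N+1)/4.
* Circulant convention (global): `S[k, i] = bits[(i + k) mod N]`; this
  matrix is symmetric.
* Phantom values are transmittance in [0, 1].
* Fusion averages (rather than sums) the aligned reconstructions so the
  image scale is independent of M; `deblend=True` optionally inverts the
  (1-d, d) transition low-pass with a Tikhonov guard.
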