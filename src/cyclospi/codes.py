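"""Cyclic binary codes whose circulant matrices are S-matrices.

An S-matrix of order N is the {0,1} matrix obtained from a normalized
Hadamard matrix of order N+1 by deleting the first row and column and
mapping -1 -> 1, +1 -> 0.  A *cyclic* S-matrix is one whose rows are all
single-cell cyclic shifts of one binary sequence; that sequence is the
indicator of a cyclic difference set with parameters
(N, (N+1)/2, (N+1)/4).  Three classic families are provided:

* quadratic-residue codes, order N = p for a prime p = 3 (mod 4);
* twin-prime codes, order N = p*(p+2) for twin primes;
* m-sequences, order N = 2**m - 1 from a primitive LFSR polynomial.

The circulant convention used throughout the package is

    S[k, i] = bits[(i + k) mod N]

(measurement k correlates the scene with the code advanced by k cells).
Note this matrix is symmetric, so S == S^T.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sympy import isprime

__all__ = [
    "CyclicCode",
    "CodeValidationReport",
    "qr_code",
    "twin_prime_code",
    "m_sequence_code",
    "validate_code",
    "smatrix_row",
    "analytic_inverse_apply",
    "DEFAULT_LFSR_TAPS",
]

_METHODS = ("quadratic_residue", "twin_prime", "m_sequence", "custom")

# Dense fallback limit for analytic_inverse_apply; above this the O(N^2)
# matrix would be slow/large and an FFT correlation is used instead.
_DENSE_LIMIT = 4096


@dataclass(frozen=True, eq=False)
class CyclicCode:
    """A length-N binary sequence generating a cyclic S-matrix.

    Attributes
    ----------
    order:
        The sequence length N (and matrix order).
    bits:
        uint8 array of N values in {0, 1}; 1 marks a transparent cell.
    method:
        Which construction produced the code.
    """

    order: int
    bits: np.ndarray
    method: str

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 1 or bits.shape[0] != self.order:
            raise ValueError(
                f"bits must be a length-{self.order} vector, got shape {bits.shape}"
            )
        if not np.all((bits == 0) | (bits == 1)):
            raise ValueError("bits must contain only 0 and 1")
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        object.__setattr__(self, "bits", bits)
        object.__setattr__(self, "bits_f", bits.astype(np.float64))
        # cache, computed lazily
        object.__setattr__(self, "_dft", None)

    @property
    def weight(self) -> int:
        return int(self.bits.sum())

    def dft(self) -> np.ndarray:
        """DFT of the bit sequence (cached)."""
        if self._dft is None:
            object.__setattr__(self, "_dft", np.fft.fft(self.bits_f))
        return self._dft

    def matrix(self) -> np.ndarray:
        """Dense S with S[k, i] = bits[(i + k) mod N].  Small N only."""
        n = self.order
        if n > _DENSE_LIMIT:
            raise ValueError(f"dense matrix refused for N={n} (> {_DENSE_LIMIT})")
        idx = (np.arange(n)[:, None] + np.arange(n)[None, :]) % n
        return self.bits[idx].astype(np.int64)

    # ---- serialization -------------------------------------------------

    def bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    def save_txt(self, path: str | Path) -> None:
        """Two-line text format: header ``<order> <method>`` then the bits."""
        path = Path(path)
        path.write_text(f"{self.order} {self.method}\n{self.bitstring()}\n")

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "order": self.order,
                    "method": self.method,
                    "bits": self.bitstring(),
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_bitstring(cls, order: int, method: str, s: str) -> "CyclicCode":
        if len(s) != order:
            raise ValueError(f"bit string length {len(s)} != order {order}")
        bits = np.frombuffer(s.encode("ascii"), dtype=np.uint8) - ord("0")
        return cls(order=order, bits=bits, method=method)

    @classmethod
    def load(cls, path: str | Path) -> "CyclicCode":
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".json":
            d = json.loads(text)
            return cls.from_bitstring(int(d["order"]), d["method"], d["bits"])
        lines = text.splitlines()
        if len(lines) < 2:
            raise ValueError(f"malformed code file {path}")
        order_s, method = lines[0].split()
        return cls.from_bitstring(int(order_s), method, lines[1].strip())


@dataclass(frozen=True)
class CodeValidationReport:
    """Numerical health check of a candidate cyclic S-matrix code."""

    order: int
    weight_ok: bool
    autocorrelation_ok: bool
    min_abs_dft: float
    condition_number: float

    @property
    def ok(self) -> bool:
        return self.weight_ok and self.autocorrelation_ok and self.min_abs_dft > 0


# ---------------------------------------------------------------------------
# constructions
# ---------------------------------------------------------------------------


def _require_prime(p: int, name: str = "p") -> None:
    if not isprime(p):
        raise ValueError(f"{name}={p} is not prime")


def qr_code(p: int) -> CyclicCode:
    """Quadratic-residue code of prime order p with p = 3 (mod 4).

    bits[i] = 1 iff i == 0 or i is a nonzero quadratic residue mod p.
    """
    p = int(p)
    _require_prime(p)
    if p % 4 != 3:
        raise ValueError(
            f"p={p} = 1 (mod 4): the residue indicator is not an S-matrix code"
        )
    bits = np.zeros(p, dtype=np.uint8)
    bits[0] = 1
    i = np.arange(1, p, dtype=np.int64)
    bits[np.unique(i * i % p)] = 1
    return CyclicCode(order=p, bits=bits, method="quadratic_residue")


def _qr_set(p: int) -> np.ndarray:
    """Boolean table t[r] = r is a nonzero quadratic residue mod p."""
    t = np.zeros(p, dtype=bool)
    i = np.arange(1, p, dtype=np.int64)
    t[np.unique(i * i % p)] = True
    return t


def twin_prime_code(p: int, q: int) -> CyclicCode:
    """Twin-prime code of order N = p*q, q = p + 2, both prime.

    The support is the complement of the Stanton-Sprott difference set
    (multiples of q together with units whose two Legendre symbols agree),
    cyclically rotated so that bits[0] = 1.  It is a (N, (N+1)/2, (N+1)/4)
    difference set, hence a cyclic S-matrix generator.
    """
    p, q = int(p), int(q)
    _require_prime(p, "p")
    _require_prime(q, "q")
    if q != p + 2:
        raise ValueError(f"(p, q)=({p}, {q}) are not twin primes (need q == p + 2)")
    n = p * q
    i = np.arange(n, dtype=np.int64)
    ip, iq = i % p, i % q
    qr_p, qr_q = _qr_set(p), _qr_set(q)
    chi_agree = qr_p[ip] == qr_q[iq]  # both residues or both non-residues
    unit = (ip != 0) & (iq != 0)
    # Stanton-Sprott set D = {q | i} u {units with matching characters}
    in_d = (iq == 0) | (unit & chi_agree)
    bits = (~in_d).astype(np.uint8)
    shift = int(np.flatnonzero(bits)[0])
    bits = np.roll(bits, -shift)  # normalize so bits[0] = 1
    return CyclicCode(order=n, bits=bits, method="twin_prime")


#: Known-good feedback polynomial exponents (x^m + ... + 1) per register size.
DEFAULT_LFSR_TAPS: dict[int, tuple[int, ...]] = {
    2: (2, 1),
    3: (3, 1),
    4: (4, 1),
    5: (5, 2),
    6: (6, 1),
    7: (7, 1),
    8: (8, 4, 3, 2),
    9: (9, 4),
    10: (10, 3),
    11: (11, 2),
    12: (12, 6, 4, 1),
    13: (13, 4, 3, 1),
    14: (14, 5, 3, 1),
    15: (15, 1),
    16: (16, 5, 3, 2),
    17: (17, 3),
    18: (18, 7),
    19: (19, 5, 2, 1),
    20: (20, 3),
    21: (21, 2),
    22: (22, 1),
    23: (23, 5),
    24: (24, 4, 3, 1),
}


def m_sequence_code(m: int, taps: Sequence[int] | None = None) -> CyclicCode:
    """Maximal-length LFSR code of order N = 2**m - 1.

    Parameters
    ----------
    m:
        Register size, 2 <= m <= 24.
    taps:
        Exponents of the feedback polynomial's nonzero terms
        (x**m and the constant term may be included or omitted), e.g.
        ``(4, 1)`` for x^4 + x + 1.  Defaults to a known primitive
        polynomial for the given m.

    A non-primitive polynomial is detected by its short period and
    rejected.
    """
    m = int(m)
    if not 2 <= m <= 24:
        raise ValueError(f"m={m} out of range [2, 24]")
    if taps is None:
        taps = DEFAULT_LFSR_TAPS[m]
    exps = sorted({int(t) for t in taps} - {0, m}, reverse=True)
    if any(e < 0 or e > m for e in (int(t) for t in taps)):
        raise ValueError(f"tap exponents {taps} outside [0, {m}]")
    n = (1 << m) - 1
    # Fibonacci form: a[t] = a[t-m] xor (xor of a[t-(m-e)] for middle taps e)
    offsets = [m] + [m - e for e in exps]
    a = [1] + [0] * (m - 1)
    seed = tuple(a)
    period = None
    for t in range(m, n + m):
        bit = 0
        for off in offsets:
            bit ^= a[t - off]
        a.append(bit)
        if period is None and tuple(a[t - m + 1 : t + 1]) == seed:
            period = t - m + 1
    if period is None:
        period = n
    if period != n:
        raise ValueError(
            f"polynomial with taps {tuple(taps)} is not primitive: "
            f"sequence period {period} != {n}"
        )
    bits = np.asarray(a[:n], dtype=np.uint8)
    shift = int(np.flatnonzero(bits)[0])
    bits = np.roll(bits, -shift)
    return CyclicCode(order=n, bits=bits, method="m_sequence")


# ---------------------------------------------------------------------------
# validation and linear algebra
# ---------------------------------------------------------------------------


def validate_code(code: CyclicCode, rtol: float = 1e-6) -> CodeValidationReport:
    """Check the S-matrix invariants via the length-N DFT (O(N log N)).

    For a valid code the DFT has DC coefficient (N+1)/2 and every other
    coefficient has squared magnitude (N+1)/4; equivalently the cyclic
    autocorrelation is (N+1)/4 at every nonzero lag.  Never raises: an
    invalid code simply yields a failing report.
    """
    n = code.order
    f = code.dft()
    mag = np.abs(f)
    min_abs = float(mag.min())
    cond = float(mag.max() / min_abs) if min_abs > 0 else float("inf")
    weight_ok = n % 4 == 3 and code.weight * 2 == n + 1
    # cyclic autocorrelation by Wiener-Khinchin
    acf = np.fft.ifft(mag**2).real
    target = (n + 1) / 4
    autocorrelation_ok = bool(
        n % 4 == 3 and np.allclose(acf[1:], target, rtol=rtol, atol=rtol * n)
    )
    return CodeValidationReport(
        order=n,
        weight_ok=bool(weight_ok),
        autocorrelation_ok=autocorrelation_ok,
        min_abs_dft=min_abs,
        condition_number=cond,
    )


def smatrix_row(code: CyclicCode, k: int) -> np.ndarray:
    """Row k of the S-matrix: bits cyclically advanced by k cells."""
    if not 0 <= k < code.order:
        raise ValueError(f"shift index k={k} out of range [0, {code.order})")
    return np.roll(code.bits, -k)


def _correlate_bits(code: CyclicCode, v: np.ndarray) -> np.ndarray:
    """(S v)[k] = sum_i bits[(i+k) mod N] v[i], via FFT."""
    return np.fft.ifft(code.dft() * np.conj(np.fft.fft(v))).real


def analytic_inverse_apply(code: CyclicCode, y: np.ndarray) -> np.ndarray:
    """Apply the closed-form S-matrix inverse x = (2/(N+1)) (2 S^T y - (sum y) 1).

    Serves as the independent oracle for the FFT reconstruction path.  S is
    symmetric under the package convention, so S^T y is computed as a dense
    product for small N and as an FFT correlation for large N.
    """
    y = np.asarray(y, dtype=np.float64)
    n = code.order
    if y.shape != (n,):
        raise ValueError(f"y must have shape ({n},), got {y.shape}")
    if n <= _DENSE_LIMIT:
        sty = code.matrix().astype(np.float64) @ y
    else:
        sty = _correlate_bits(code, y)
    return (2.0 / (n + 1)) * (2.0 * sty - y.sum())
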