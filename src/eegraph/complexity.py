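"""Multiscale signal complexity: coarse-graining, sample entropy, permutation entropy."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


__all__ = [
    "MultiscaleCurve",
    "coarse_grain",
    "sample_entropy",
    "permutation_entropy",
    "multiscale_curve",
]


@dataclass
class MultiscaleCurve:
    """Entropy as a function of coarse-graining scale for one signal."""

    estimator: str  # "sample" or "permutation"
    scales: tuple[int, ...]
    values: np.ndarray  # nats for sample entropy, bits for permutation entropy
    channel: str = ""
    subject_id: str = ""
    params: dict = field(default_factory=dict)


def coarse_grain(x: Sequence[float] | np.ndarray, tau: int) -> np.ndarray:
    """Average ``x`` over non-overlapping windows of length ``tau``.

    Output element j is the mean of ``x[(j-1)*tau+1 .. j*tau]`` (1-based);
    trailing samples that do not fill a window are dropped, so the output
    has ``floor(len(x)/tau)`` elements.
    """
    if tau < 1:
        raise ValueError("scale factor tau must be >= 1")
    x = np.asarray(x, dtype=float)
    n = x.size // tau
    if n < 1:
        raise ValueError(f"sequence of length {x.size} too short for tau={tau}")
    if tau == 1:
        return x.copy()
    return x[: n * tau].reshape(n, tau).mean(axis=1)


@njit(cache=False)
def _sampen_counts(y: np.ndarray, m: int, r: float):  # pragma: no cover - jitted
    """Pairs of templates matching at length m (B) and m+1 (A), Chebyshev <= r."""
    n_templates = y.shape[0] - m
    a = 0
    b = 0
    for i in range(n_templates - 1):
        for j in range(i + 1, n_templates):
            d = 0.0
            for k in range(m):
                diff = abs(y[i + k] - y[j + k])
                if diff > d:
                    d = diff
            if d <= r:
                b += 1
                if abs(y[i + m] - y[j + m]) <= r:
                    a += 1
    return a, b


def sample_entropy(
    y: Sequence[float] | np.ndarray,
    m: int = 1,
    r: float = 0.25,
    r_absolute: float | None = None,
) -> float:
    """Sample entropy ``-ln(A/B)`` with self-matches excluded.

    ``B`` counts template pairs of length ``m`` within Chebyshev distance
    ``r * SD(y)`` (population SD of the input series); ``A`` counts the pairs
    still matching when extended by one sample.  Pass ``r_absolute`` to use a
    fixed tolerance instead of the SD-relative convention.  Returns ``nan``
    (undefined) when no extended pair matches.
    """
    y = np.asarray(y, dtype=float)
    if y.size <= m + 1:
        raise ValueError(f"sequence of length {y.size} too short for m={m}")
    if r_absolute is not None:
        tol = float(r_absolute)
    else:
        if r <= 0:
            raise ValueError("tolerance fraction r must be positive")
        tol = r * float(np.std(y))
    a, b = _sampen_counts(y, m, tol)
    if b == 0 or a == 0:
        if a == b:  # fully regular (e.g. constant) series: C_{m+1} = C_m
            return 0.0 if b > 0 else float("nan")
        return float("nan")
    return float(-np.log(a / b))


def permutation_entropy(y: Sequence[float] | np.ndarray, m: int = 3) -> float:
    """Shannon entropy (bits) of ordinal patterns of length ``m``.

    Relative frequencies are taken over the ``N - m + 1`` sliding windows;
    ties within a window are broken by order of appearance (stable argsort).
    The result lies in ``[0, log2(m!)]``.
    """
    y = np.asarray(y, dtype=float)
    if m < 2:
        raise ValueError("motif length m must be >= 2")
    if y.size < m:
        raise ValueError(f"sequence of length {y.size} shorter than m={m}")
    windows = np.lib.stride_tricks.sliding_window_view(y, m)
    ranks = np.argsort(windows, axis=1, kind="stable")
    codes = ranks @ (m ** np.arange(m))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / codes.size
    return float(-(p * np.log2(p)).sum())


def multiscale_curve(
    x: Sequence[float] | np.ndarray,
    estimator: str = "sample",
    scales: Sequence[int] = tuple(range(1, 31)),
    m: int | None = None,
    r: float = 0.25,
    channel: str = "",
    subject_id: str = "",
) -> MultiscaleCurve:
    """Entropy of ``coarse_grain(x, tau)`` for each scale ``tau``.

    Defaults follow the analysis conventions: sample entropy with m=1,
    r=0.25 x SD (tolerance recomputed per scale from the coarse-grained
    series); permutation entropy with motif length m=3.
    """
    x = np.asarray(x, dtype=float)
    scales = tuple(int(s) for s in scales)
    if estimator == "sample":
        m_eff = 1 if m is None else m
        min_len = m_eff + 2
    elif estimator == "permutation":
        m_eff = 3 if m is None else m
        min_len = m_eff
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if x.size // max(scales) < min_len:
        raise ValueError(
            f"sequence of length {x.size} too short for scale {max(scales)}"
        )
    values = np.empty(len(scales))
    for i, tau in enumerate(scales):
        y = coarse_grain(x, tau)
        if estimator == "sample":
            values[i] = sample_entropy(y, m=m_eff, r=r)
        else:
            values[i] = permutation_entropy(y, m=m_eff)
    params = {"m": m_eff}
    if estimator == "sample":
        params["r"] = r
    return MultiscaleCurve(estimator, scales, values, channel, subject_id, params)
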