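"""Minimal orthogonal wavelet transform for threshold denoising.

Self-contained Daubechies machinery: the scaling filter is computed at
import time by spectral factorization of the Daubechies moment polynomial
(roots inside the unit circle are kept), so no wavelet library is needed.
The decomposition uses periodized circular convolution, which keeps the
transform orthonormal on even-length signals — Parseval's identity then
guarantees that soft thresholding can only remove energy, never add it.

Odd lengths encountered during the cascade are padded by repeating the
last sample; the pad is dropped on reconstruction (one boundary sample is
then only approximately reconstructed).
"""

from __future__ import annotations

import numpy as np
from scipy.special import comb

__all__ = [
    "daubechies_filter",
    "qmf",
    "wavedec",
    "waverec",
    "denoise",
]


def daubechies_filter(p: int) -> np.ndarray:
    """Daubechies scaling (low-pass) filter with ``p`` vanishing moments.

    Length-2p orthonormal filter (sums to sqrt(2)); db2 and db3 reproduce
    the published coefficient tables to ~1e-10.
    """
    if p < 1:
        raise ValueError("need p >= 1")
    if p == 1:  # Haar
        return np.array([1.0, 1.0]) / np.sqrt(2.0)
    # moment polynomial P(y) = sum_k C(p-1+k, k) y^k, y = (2 - z - 1/z)/4
    # build z^{p-1} * P(y(z)) as an ordinary polynomial in z
    y_num = np.array([-0.25, 0.5, -0.25])  # y(z) * z
    acc = np.zeros(2 * p - 1)
    for k in range(p):
        c = comb(p - 1 + k, k, exact=True)
        term = np.array([1.0])
        for _ in range(k):
            term = np.convolve(term, y_num)
        # term has degree 2k and is symmetric; shift by z^{p-1-k}
        acc[(p - 1 - k):(p - 1 - k) + len(term)] += term * c
    # acc: coefficients of z^{2(p-1)} ... z^0 (descending powers)
    roots = np.roots(acc)
    inside = roots[np.abs(roots) < 1.0]
    # spectral factor from the roots inside the unit circle
    q = np.array([1.0])
    for r in inside:
        q = np.convolve(q, np.array([1.0, -r]))
    q = np.real(q)
    # multiply by ((1+z^{-1})/2)^p and normalize to sum sqrt(2)
    h = np.array([1.0])
    for _ in range(p):
        h = np.convolve(h, np.array([0.5, 0.5]))
    h = np.convolve(h, q)
    h = h * (np.sqrt(2.0) / h.sum())
    return h


def qmf(h: np.ndarray) -> np.ndarray:
    """Quadrature-mirror (high-pass) filter of an orthonormal scaling
    filter."""
    g = h[::-1].copy()
    g[1::2] *= -1.0
    return g


def _analysis_step(x: np.ndarray, h: np.ndarray, g: np.ndarray):
    n = len(x)
    padded = False
    if n % 2:
        x = np.append(x, x[-1])
        n += 1
        padded = True
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(len(h))[None, :]) % n
    xw = x[idx]
    return xw @ h, xw @ g, padded


def _synthesis_step(a: np.ndarray, d: np.ndarray, h: np.ndarray,
                    g: np.ndarray, padded: bool) -> np.ndarray:
    n = 2 * len(a)
    x = np.zeros(n)
    pos = (2 * np.arange(len(a))[:, None] + np.arange(len(h))[None, :]) % n
    np.add.at(x, pos.ravel(), (a[:, None] * h[None, :]).ravel())
    np.add.at(x, pos.ravel(), (d[:, None] * g[None, :]).ravel())
    return x[:-1] if padded else x


def wavedec(x: np.ndarray, h: np.ndarray, levels: int):
    """Periodized multilevel DWT: returns (approx, [detail_coarse ...
    detail_fine], pad_flags)."""
    if levels < 1:
        raise ValueError("need at least one level")
    if len(x) < 2 ** levels:
        raise ValueError("signal too short for the requested depth")
    g = qmf(h)
    a = np.asarray(x, dtype=float)
    details, pads = [], []
    for _ in range(levels):
        if len(a) < 2:
            break
        a, d, padded = _analysis_step(a, h, g)
        details.append(d)
        pads.append(padded)
    return a, details[::-1], pads[::-1]


def waverec(a: np.ndarray, details: list[np.ndarray], pads: list[bool],
            h: np.ndarray) -> np.ndarray:
    """Inverse of :func:`wavedec`."""
    g = qmf(h)
    for d, padded in zip(details, pads):
        a = _synthesis_step(a, d, h, g, padded)
    return a


def denoise(x: np.ndarray, p: int = 6, levels: int = 5) -> np.ndarray:
    """Wavelet-threshold denoising: universal threshold, soft rule.

    The noise scale is the median absolute deviation of the finest-level
    detail coefficients divided by 0.6745 (the Gaussian consistency
    factor); every detail level is soft-thresholded at sigma*sqrt(2 ln N).
    """
    x = np.asarray(x, dtype=float)
    h = daubechies_filter(p)
    a, details, pads = wavedec(x, h, levels)
    finest = details[-1]
    sigma = np.median(np.abs(finest)) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(max(len(x), 2)))
    details = [np.sign(d) * np.maximum(np.abs(d) - thr, 0.0) for d in details]
    return waverec(a, details, pads, h)
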