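"""Eight-feature description of a valve-closure vibration burst.

Per burst window the features are

=========  =================================================  =========
name       definition                                          units
=========  =================================================  =========
Amp        maximum absolute amplitude                          a.u.
Ener       sum of squared samples                              a.u.²
MS         time from the servo falling edge to the amplitude   ms
           maximum
Time       window duration                                     ms
f          frequency of the power-spectrum main peak (Burg     Hz
           autoregressive estimate)
Pow        height of that main peak                            a.u.²/Hz
SampEn     sample entropy (m = 2, r = 0.2·SD)                  nats
FuzzyEn    fuzzy entropy (m = 2, r = 0.2·SD, step n = 2)       nats
=========  =================================================  =========

Suffixes ``_t`` and ``_p`` denote the tricuspid and pulmonary valve.
Both entropies use the Chebyshev template distance; fuzzy entropy
mean-centres each template and replaces the hard tolerance with the
exponential membership exp(−(d/r)^n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.regression.linear_model import burg as _burg

from pulmovib.sigproc import CycleSegment, SoundWindow

__all__ = [
    "EntropyParams",
    "FEATURE_NAMES",
    "time_domain_features",
    "burg_psd",
    "burg_psd_peak",
    "sample_entropy",
    "fuzzy_entropy",
    "feature_table",
]

logger = logging.getLogger(__name__)

#: base feature names; the full table carries each with _t and _p suffixes
FEATURE_NAMES = ("Amp", "Ener", "MS", "Time", "f", "Pow", "SampEn", "FuzzyEn")


@dataclass
class EntropyParams:
    """Template parameters shared by both entropy features."""

    m: int = 2          # embedding dimension
    r_coeff: float = 0.2  # tolerance = r_coeff * SD(x)
    n_step: int = 2     # fuzzy membership exponent

    def __post_init__(self) -> None:
        if self.m < 1 or self.r_coeff <= 0 or self.n_step < 1:
            raise ValueError("need m >= 1, r_coeff > 0, n_step >= 1")


def time_domain_features(
    win: SoundWindow, fall_edge_t: float
) -> tuple[float, float, float, float]:
    """(Amp, Ener, MS, Time) of one burst window.

    MS is measured from the servo falling edge to the amplitude maximum
    (the single timing convention used for both valves), in ms.
    """
    if len(win.samples) == 0:
        raise ValueError("empty sound window")
    if fall_edge_t > win.center_t:
        raise ValueError("falling edge must precede the burst maximum")
    amp = float(np.max(np.abs(win.samples)))
    ener = float(np.sum(win.samples ** 2))
    ms = (win.center_t - fall_edge_t) * 1000.0
    dur = (win.end_t - win.start_t) * 1000.0
    return amp, ener, ms, dur


def burg_psd(
    x: np.ndarray, fs: float, order: int = 12, nfreq: int = 4096
) -> tuple[np.ndarray, np.ndarray]:
    """Autoregressive power spectral density by the Burg method.

    The AR coefficients come from the Burg forward-backward recursion;
    the PSD is sigma² / (fs·|A(e^{j2πf/fs})|²) evaluated on ``nfreq``
    points over [0, fs/2].
    """
    x = np.asarray(x, dtype=float)
    if len(x) <= order:
        raise ValueError("window must be longer than the AR order")
    ar, sigma2 = _burg(x - x.mean(), order=order)
    a = np.concatenate([[1.0], -ar])
    w = np.fft.rfft(a, 2 * (nfreq - 1))
    freqs = np.linspace(0.0, fs / 2.0, nfreq)
    psd = sigma2 / (fs * np.abs(w) ** 2)
    return freqs, psd


def burg_psd_peak(
    win: SoundWindow | np.ndarray, fs: float | None = None,
    order: int = 12, nfreq: int = 4096,
) -> tuple[float, float]:
    """(f, Pow): location and height of the PSD main peak in (0, fs/2)."""
    if isinstance(win, SoundWindow):
        x, fs = win.samples, win.fs
    else:
        if fs is None:
            raise ValueError("fs required for a bare sample array")
        x = win
    freqs, psd = burg_psd(x, fs, order=order, nfreq=nfreq)
    interior = slice(1, nfreq - 1)  # exclude DC and Nyquist
    i = int(np.argmax(psd[interior])) + 1
    return float(freqs[i]), float(psd[i])


def _templates(x: np.ndarray, m: int) -> np.ndarray:
    """All N−m+1 length-m windows of x, as rows."""
    return np.lib.stride_tricks.sliding_window_view(x, m)


def _chebyshev_pairs(T: np.ndarray) -> np.ndarray:
    """Condensed upper-triangle Chebyshev distances between rows of T."""
    n = len(T)
    iu, ju = np.triu_indices(n, k=1)
    return np.max(np.abs(T[iu] - T[ju]), axis=-1)


def sample_entropy(x: np.ndarray, params: EntropyParams | None = None) -> float:
    """Sample entropy −ln(A/B).

    B counts template pairs of length m within Chebyshev tolerance
    r = r_coeff·SD(x); A counts the same index pairs at length m+1.
    Self-matches are excluded; the m-templates are restricted to the
    first N−m start indices so A and B compare like with like.  Returns
    NaN (the "undefined" flag) when either count is zero.
    """
    p = params or EntropyParams()
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < p.m + 2:
        raise ValueError("series too short for the embedding dimension")
    r = p.r_coeff * float(np.std(x))
    Tm = _templates(x, p.m)[: n - p.m]
    Tm1 = _templates(x, p.m + 1)
    B = int(np.count_nonzero(_chebyshev_pairs(Tm) <= r))
    A = int(np.count_nonzero(_chebyshev_pairs(Tm1) <= r))
    if A == 0 or B == 0:
        return float("nan")
    return float(-np.log(A / B))


def fuzzy_entropy(x: np.ndarray, params: EntropyParams | None = None) -> float:
    """Fuzzy entropy ln(φ_m) − ln(φ_{m+1}).

    Templates are centred by their own mean; the hard tolerance is
    replaced by the exponential membership μ(d) = exp(−(d/r)^n_step) of
    the Chebyshev distance d, and φ_m averages μ over all distinct
    template pairs.  A zero-variance series returns 0 by convention.
    """
    p = params or EntropyParams()
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < p.m + 2:
        raise ValueError("series too short for the embedding dimension")
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    r = p.r_coeff * sd

    def phi(m: int) -> float:
        T = _templates(x, m)[: n - p.m]  # same start-index range for m, m+1
        T = T - T.mean(axis=1, keepdims=True)
        d = _chebyshev_pairs(T)
        return float(np.mean(np.exp(-((d / r) ** p.n_step))))

    return float(np.log(phi(p.m)) - np.log(phi(p.m + 1)))


def feature_table(
    segments: list[CycleSegment],
    windows_t: list[SoundWindow],
    windows_p: list[SoundWindow],
    entropy_params: EntropyParams | None = None,
    burg_order: int = 12,
) -> pd.DataFrame:
    """Per-cycle table of the 16 burst features plus pressure parameters.

    One row per cycle with columns ``Amp_t`` … ``FuzzyEn_p`` (8 features
    × 2 valves), the cycle index and PASP / MRR / MFR.  The tricuspid MS
    is referenced to the *previous* cycle's falling edge (the burst sits
    at systole onset, after that edge); the first cycle therefore has no
    reference and bursts flagged missing yield NaN rows, both logged.
    """
    if not (len(segments) == len(windows_t) == len(windows_p)):
        raise ValueError("segments and window lists must be aligned by cycle")
    ep = entropy_params or EntropyParams()
    rows = []
    for k, (seg, wt, wp) in enumerate(zip(segments, windows_t, windows_p)):
        row: dict[str, float] = {
            "cycle": k,
            "PASP": seg.pasp,
            "MRR": seg.mrr,
            "MFR": seg.mfr,
        }
        prev_fall = segments[k - 1].fall_t if k > 0 else None
        for suffix, win, fall_ref in (
            ("t", wt, prev_fall),
            ("p", wp, seg.fall_t),
        ):
            if win.missing or len(win.samples) <= burg_order or fall_ref is None:
                if win.missing:
                    logger.warning("cycle %d: missing %s burst", k, suffix)
                for name in FEATURE_NAMES:
                    row[f"{name}_{suffix}"] = np.nan
                continue
            amp, ener, ms, dur = time_domain_features(win, fall_ref)
            f, pw = burg_psd_peak(win, order=burg_order)
            row[f"Amp_{suffix}"] = amp
            row[f"Ener_{suffix}"] = ener
            row[f"MS_{suffix}"] = ms
            row[f"Time_{suffix}"] = dur
            row[f"f_{suffix}"] = f
            row[f"Pow_{suffix}"] = pw
            row[f"SampEn_{suffix}"] = sample_entropy(win.samples, ep)
            row[f"FuzzyEn_{suffix}"] = fuzzy_entropy(win.samples, ep)
        rows.append(row)
    cols = ["cycle", "PASP", "MRR", "MFR"] + [
        f"{name}_{s}" for s in ("t", "p") for name in FEATURE_NAMES
    ]
    return pd.DataFrame(rows, columns=cols)
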