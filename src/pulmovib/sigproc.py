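"""Signal conditioning, servo-based cycle segmentation and valve-sound
window extraction.

The servo motor pulse is the timing reference (it plays the role an ECG
would play in clinical phonocardiogram segmentation): high = systole,
low = diastole.  Each cardiac cycle runs from one rising edge to the
next.  Per cycle, the pressure parameters are

* PASP — maximum pulmonary-artery pressure during the servo-high span,
* MRR  — maximum rising rate of the pressure waveform (mmHg/ms),
* MFR  — maximum (most negative) falling rate (mmHg/ms),

and the valve-closure bursts are located inside edge-anchored search
windows: the tricuspid burst just after the rising edge, the pulmonary
burst just after the falling edge.  A burst window is grown symmetrically
outward from the absolute-amplitude maximum until it holds 98% of the
search-window energy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from pulmovib import wavelet

__all__ = [
    "CycleSegment",
    "SoundWindow",
    "lowpass_pressure",
    "denoise_vibration",
    "detect_edges",
    "per_cycle_pressure_params",
    "extract_valve_sound",
    "tricuspid_search_window",
    "pulmonary_search_window",
]

logger = logging.getLogger(__name__)

#: fraction of systole / diastole scanned for the burst, from the edge
SEARCH_FRACTION = 0.4
#: minimum spacing between detected edges of the same polarity
DEBOUNCE_S = 0.1


@dataclass
class CycleSegment:
    """One cardiac cycle delimited by servo rising edges, with its
    pressure parameters."""

    rise_t: float
    fall_t: float
    next_rise_t: float
    pasp: float
    mrr: float  # mmHg/ms, > 0
    mfr: float  # mmHg/ms, < 0

    def __post_init__(self) -> None:
        if not self.rise_t < self.fall_t < self.next_rise_t:
            raise ValueError("need rise_t < fall_t < next_rise_t")


@dataclass
class SoundWindow:
    """A valve-closure burst: the 98%-energy region around the amplitude
    maximum inside an edge-anchored search window."""

    valve: str
    start_t: float
    end_t: float
    center_t: float
    samples: np.ndarray
    fs: float
    energy_fraction: float = 1.0
    missing: bool = False
    clipped: bool = False


def lowpass_pressure(
    x: np.ndarray, fs: float, cutoff: float = 20.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth low-pass for pressure channels (DC gain 1).

    Applied forward-backward (filtfilt), so slow pulses keep their peak
    times; the default 20 Hz cutoff is far above the < 10 Hz pressure
    bandwidth.
    """
    if cutoff >= fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def denoise_vibration(x: np.ndarray, p: int = 6, levels: int = 5) -> np.ndarray:
    """Wavelet-threshold denoising of a vibration-sound channel
    (Daubechies-6, 5 levels, universal soft threshold)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2 ** levels:
        raise ValueError("signal shorter than the wavelet cascade depth")
    return wavelet.denoise(x, p=p, levels=levels)


def detect_edges(
    servo: np.ndarray, fs: float, debounce_s: float = DEBOUNCE_S
) -> tuple[np.ndarray, np.ndarray]:
    """Rising and falling edge times [s] of the servo pulse.

    Edges are half-amplitude threshold crossings; crossings closer than
    ``debounce_s`` to the previous same-polarity edge are chatter and are
    dropped.
    """
    servo = np.asarray(servo, dtype=float)
    lo, hi = servo.min(), servo.max()
    if hi - lo <= 1e-12:
        raise ValueError("servo signal is constant: no edges")
    level = (hi + lo) / 2.0
    binary = (servo > level).astype(int)
    d = np.diff(binary)
    rising = np.flatnonzero(d == 1) + 1
    falling = np.flatnonzero(d == -1) + 1
    if len(rising) == 0 and len(falling) == 0:
        raise ValueError("no edges found in servo signal")

    def debounce(idx: np.ndarray) -> np.ndarray:
        if len(idx) == 0:
            return idx
        keep = [idx[0]]
        gap = int(debounce_s * fs)
        for i in idx[1:]:
            if i - keep[-1] >= gap:
                keep.append(i)
        return np.array(keep)

    return debounce(rising) / fs, debounce(falling) / fs


def _smoothed_derivative(
    p: np.ndarray, fs: float, window_s: float = 0.05, polyorder: int = 3
) -> np.ndarray:
    """Smoothed first difference of a pressure trace, in mmHg/ms.

    Savitzky-Golay local-polynomial derivative: a raw first difference
    amplifies measurement noise far beyond the rate-feature scale, while
    a 50 ms cubic fit keeps the peak-slope bias of the (>150 ms) pressure
    upstroke negligible.
    """
    win = int(window_s * fs) // 2 * 2 + 1
    return signal.savgol_filter(
        p, win, polyorder, deriv=1, delta=1.0 / fs
    ) / 1000.0


def per_cycle_pressure_params(
    p_pa: np.ndarray,
    edges: tuple[np.ndarray, np.ndarray],
    fs: float,
) -> list[CycleSegment]:
    """Per-cycle pressure parameters from an (already low-passed)
    pulmonary-artery trace.

    PASP is the maximum over the servo-high span; MRR and MFR are the
    extrema of the smoothed derivative over the full cycle.  Cycles whose
    edge pattern is inconsistent are skipped with a log entry.
    """
    rise_t, fall_t = edges
    if len(rise_t) < 2:
        raise ValueError("need at least one complete cycle")
    deriv = _smoothed_derivative(np.asarray(p_pa, dtype=float), fs)
    segments: list[CycleSegment] = []
    for k in range(len(rise_t) - 1):
        r0, r1 = rise_t[k], rise_t[k + 1]
        falls = fall_t[(fall_t > r0) & (fall_t < r1)]
        if len(falls) != 1:
            logger.warning("cycle at %.3f s skipped: %d falling edges",
                           r0, len(falls))
            continue
        f0 = falls[0]
        i0, i1 = int(round(r0 * fs)), int(round(r1 * fs))
        if0 = int(round(f0 * fs))
        if if0 <= i0 or i1 > len(p_pa):
            logger.warning("cycle at %.3f s skipped: out of range", r0)
            continue
        pasp = float(np.max(p_pa[i0:if0]))
        mrr = float(np.max(deriv[i0:i1]))
        mfr = float(np.min(deriv[i0:i1]))
        segments.append(
            CycleSegment(rise_t=r0, fall_t=f0, next_rise_t=r1,
                         pasp=pasp, mrr=mrr, mfr=mfr)
        )
    return segments


def tricuspid_search_window(
    seg: CycleSegment, fraction: float = SEARCH_FRACTION
) -> tuple[float, float]:
    """Search span for the tricuspid burst: the first ``fraction`` of
    systole, from the rising edge."""
    return seg.rise_t, seg.rise_t + fraction * (seg.fall_t - seg.rise_t)


def pulmonary_search_window(
    seg: CycleSegment, fraction: float = SEARCH_FRACTION
) -> tuple[float, float]:
    """Search span for the pulmonary burst: the first ``fraction`` of
    diastole, from the falling edge."""
    return seg.fall_t, seg.fall_t + fraction * (seg.next_rise_t - seg.fall_t)


def extract_valve_sound(
    snd: np.ndarray,
    search_window: tuple[float, float],
    fs: float,
    valve: str = "",
    energy_frac: float = 0.98,
    energy_floor: float = 1e-12,
    clip_at: tuple[float, float] | None = None,
) -> SoundWindow:
    """Extract the burst window holding ``energy_frac`` of the
    search-window energy.

    The window starts at the absolute-amplitude maximum and grows one
    sample at a time, always taking the side (left/right) offering the
    larger incremental energy — ties extend left — until the cumulative
    energy reaches the target.  Growth never leaves the search window,
    nor — when ``clip_at`` gives the enclosing servo-edge times — the
    edge-bounded span around the maximum: a window stopped by those
    bounds before reaching its energy target is flagged ``clipped`` (the
    guard against a mis-specified search window that spans two cycles).
    A search window with essentially no energy returns a ``missing``
    flag.
    """
    t0, t1 = search_window
    i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
    if i0 < 0 or i1 > len(snd) or i1 <= i0:
        raise ValueError("search window outside the recording")
    seg = np.asarray(snd[i0:i1], dtype=float)
    e = seg ** 2
    total = float(e.sum())
    if total <= energy_floor:
        return SoundWindow(valve=valve, start_t=t0, end_t=t0, center_t=t0,
                           samples=np.empty(0), fs=fs, energy_fraction=0.0,
                           missing=True)
    c = int(np.argmax(np.abs(seg)))
    target = energy_frac * total
    lo, hi = 0, len(seg) - 1
    if clip_at is not None:
        lo = max(lo, int(round(clip_at[0] * fs)) - i0)
        hi = min(hi, int(round(clip_at[1] * fs)) - 1 - i0)
        if not lo <= c <= hi:
            raise ValueError("amplitude maximum outside the clip bounds")
    left = right = c
    cum = e[c]
    clipped = False
    while cum < target:
        can_l = left > lo
        can_r = right < hi
        if not can_l and not can_r:
            clipped = True
            break
        el = e[left - 1] if can_l else -1.0
        er = e[right + 1] if can_r else -1.0
        if el >= er:  # tie extends left
            left -= 1
            cum += e[left]
        else:
            right += 1
            cum += e[right]
    return SoundWindow(
        valve=valve,
        start_t=(i0 + left) / fs,
        end_t=(i0 + right + 1) / fs,  # half-open [start, end)
        center_t=(i0 + c) / fs,
        samples=seg[left:right + 1].copy(),
        fs=fs,
        energy_fraction=cum / total,
        clipped=clipped,
    )
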