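"""Behavioral statistics for persistent licking.

Initiation / termination bias
-----------------------------
A lick bout is summarised by 25 simple moving averages (SMA) of lick counts
in 200 ms bins after the anchoring event (liquid delivery onset, DO, for
initiation; quinine DO or delivery end for termination).  The k-th SMA is
the mean lick count over ``n`` consecutive bins starting at bin k, so the
series covers the 5 s evaluation epoch and the first SMA looks at the first
second after the anchor.  The initiation bias is ``1/idx`` where ``idx`` is
the index of the first SMA above 1.2 licks/bin (6 Hz), counted from just
after the last zero-valued SMA preceding that crossing; a bout that reaches
6 Hz immediately scores 1, a bout that never reaches it scores 0.  The
termination bias is ``1/idx`` for the first SMA below 1.0 licks/bin (5 Hz)
after the terminating anchor, 0 if licking never drops below 5 Hz.

Facial / locomotor activity
---------------------------
Facial activity at frame t is ``1 - r`` where ``r`` is the Pearson
correlation of the histogram-of-oriented-gradients (HOG) descriptors of
frames t and t+1 (8 orientations, 32 px cells, 1 cell per block).  Wheel
speed per encoder pulse is ``circumference / (CPR * dt)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.feature import hog

from .core_io import FacialTrace

# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass
class SMAConfig:
    dt: float = 0.2          # s per bin
    n: int = 5               # bins per moving average
    n_sma: int = 25          # number of SMA values (spans the 5 s epoch)
    init_threshold: float = 1.2   # licks/bin == 6 Hz
    term_threshold: float = 1.0   # licks/bin == 5 Hz
    zero_rule: str = "restart"    # "restart" (count from last zero) or "skip"


@dataclass
class FacialConfig:
    orientations: int = 8
    pixels_per_cell: int = 32
    cells_per_block: int = 1
    crop_height: int = 296
    crop_width: int = 364
    crop_offset: tuple[int, int] = (0, 0)  # (row, col); the "ear" crop is manual


@dataclass
class WheelConfig:
    circumf: float = 50.0  # wheel circumference, cm
    cpr: int = 360         # encoder cycles per revolution

    def __post_init__(self) -> None:
        if self.circumf <= 0 or self.cpr <= 0:
            raise ValueError("circumf and CPR must be positive")


# ---------------------------------------------------------------------------
# SMA-based bias
# ---------------------------------------------------------------------------


def _bin_counts(lick_times: np.ndarray, anchor: float, cfg: SMAConfig) -> np.ndarray:
    """Lick counts in half-open 200 ms bins [anchor + (k-1)dt, anchor + k dt)."""
    lick_times = np.asarray(lick_times, dtype=float)
    n_bins = cfg.n_sma + cfg.n - 1
    edges = anchor + cfg.dt * np.arange(n_bins + 1)
    counts, _ = np.histogram(lick_times, bins=edges)
    return counts.astype(float)


def sma_series(lick_times: Sequence[float], anchor: float, cfg: SMAConfig = SMAConfig()) -> np.ndarray:
    """The ``n_sma`` moving averages of lick counts after ``anchor``.

    Value k (0-based here, 1-based in the bias formulas) is the mean count
    over bins k..k+n-1.
    """
    counts = _bin_counts(np.asarray(lick_times, float), anchor, cfg)
    # sum integer counts first so SMA values are exact rationals (k / n)
    sums = np.convolve(counts, np.ones(cfg.n), mode="valid")[: cfg.n_sma]
    return sums / cfg.n


def initiation_bias(
    lick_times: Sequence[float], do: float, cfg: SMAConfig = SMAConfig()
) -> float:
    """1/idx for the first SMA above the 6 Hz threshold; 0 if never reached.

    ``idx`` is counted from just after the last zero-valued SMA preceding
    the crossing, so it measures the latency of the final sustained bout
    onset rather than of any earlier abortive licks.
    """
    sma = sma_series(lick_times, do, cfg)
    if np.all(sma == 0):
        return 0.0
    above = np.nonzero(sma > cfg.init_threshold)[0]
    if above.size == 0:
        return 0.0
    j = int(above[0])  # 0-based crossing position
    if cfg.zero_rule == "restart":
        zeros = np.nonzero(sma[:j] == 0)[0]
        origin = int(zeros[-1]) + 1 if zeros.size else 0
        idx = j - origin + 1
    elif cfg.zero_rule == "skip":
        idx = int(np.count_nonzero(sma[: j + 1] != 0))
    else:  # pragma: no cover - config error
        raise ValueError(f"unknown zero_rule {cfg.zero_rule!r}")
    return 1.0 / idx


def termination_bias(
    lick_times: Sequence[float], anchor: float, cfg: SMAConfig = SMAConfig()
) -> float:
    """1/idx for the first SMA below the 5 Hz threshold after ``anchor``."""
    sma = sma_series(lick_times, anchor, cfg)
    below = np.nonzero(sma < cfg.term_threshold)[0]
    if below.size == 0:
        return 0.0
    return 1.0 / (int(below[0]) + 1)


# ---------------------------------------------------------------------------
# facial activity (HOG dissimilarity of adjacent frames)
# ---------------------------------------------------------------------------


def hog_vector(frame: np.ndarray, cfg: FacialConfig = FacialConfig()) -> np.ndarray:
    """HOG descriptor of the configured crop of one grayscale frame."""
    r0, c0 = cfg.crop_offset
    r1, c1 = r0 + cfg.crop_height, c0 + cfg.crop_width
    if r1 > frame.shape[0] or c1 > frame.shape[1]:
        raise ValueError("crop exceeds frame bounds")
    crop = np.asarray(frame, dtype=float)[r0:r1, c0:c1]
    return hog(
        crop,
        orientations=cfg.orientations,
        pixels_per_cell=(cfg.pixels_per_cell, cfg.pixels_per_cell),
        cells_per_block=(cfg.cells_per_block, cfg.cells_per_block),
        feature_vector=True,
    )


def facial_activity(
    frames: Sequence[np.ndarray], cfg: FacialConfig = FacialConfig()
) -> np.ndarray:
    """``1 - corr(HOG_t, HOG_{t+1})`` for each adjacent frame pair.

    Flat (zero-variance) descriptors have no defined correlation; such
    pairs are scored 0 (no motion) with a warning.
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    vecs = [hog_vector(f, cfg) for f in frames]
    out = np.empty(len(vecs) - 1)
    flagged = False
    for i in range(len(vecs) - 1):
        a, b = vecs[i], vecs[i + 1]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            out[i] = 0.0
            flagged = True
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        out[i] = 1.0 - r
    if flagged:
        warnings.warn("flat HOG descriptor: activity set to 0 for affected pairs")
    return out


# ---------------------------------------------------------------------------
# locomotion
# ---------------------------------------------------------------------------


def locomotor_speed(
    pulse_times: Sequence[float], cfg: WheelConfig = WheelConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pulse wheel speed in cm/s.

    Returns ``(times, speed)`` where ``speed[i] = circumf / (CPR * dt_i)``
    and ``dt_i`` is the interval from the previous pulse.
    """
    t = np.asarray(pulse_times, dtype=float)
    if t.size < 2:
        return t[1:], np.empty(0)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("duplicate or non-increasing pulse timestamps")
    return t[1:], cfg.circumf / (cfg.cpr * dt)


# ---------------------------------------------------------------------------
# event-aligned z-scoring
# ---------------------------------------------------------------------------


def aligned_zscore(
    trace: FacialTrace,
    event_times: Sequence[float],
    window: tuple[float, float],
    baseline_window: tuple[float, float],
) -> np.ndarray:
    """Per-event z-scored snippets of a regularly sampled trace.

    For each event the samples in ``[event + window[0], event + window[1])``
    are z-scored against the mean and SD of the samples in the event's
    baseline window.  Raises if a window leaves the trace or a baseline has
    zero variance.
    """
    t = np.asarray(trace.times, float)
    x = np.asarray(trace.activity, float)
    dt = float(np.median(np.diff(t)))
    n_win = int(round((window[1] - window[0]) / dt))
    rows = []
    for e in event_times:
        i0 = int(round((e + window[0] - t[0]) / dt))
        b0 = int(round((e + baseline_window[0] - t[0]) / dt))
        b1 = int(round((e + baseline_window[1] - t[0]) / dt))
        if i0 < 0 or i0 + n_win > x.size or b0 < 0 or b1 > x.size:
            raise ValueError("window extends beyond trace extent")
        base = x[b0:b1]
        sd = base.std()
        if sd == 0:
            raise ValueError("zero baseline standard deviation")
        rows.append((x[i0 : i0 + n_win] - base.mean()) / sd)
    return np.asarray(rows)
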