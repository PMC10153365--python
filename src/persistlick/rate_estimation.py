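"""Firing-rate estimation with the Bayesian adaptive kernel smoother (BAKS).

BAKS places a Gaussian kernel at every spike and lets the bandwidth adapt
to the local spike density through a gamma prior on the inverse bandwidth.
With shape ``alpha`` and scale parameter ``beta`` the closed-form adaptive
bandwidth at evaluation time t is

    h(t) = Γ(α) / Γ(α + 1/2) * Σ_i ((t - t_i)²/2 + 1/β)^(-α)
                               / Σ_i ((t - t_i)²/2 + 1/β)^(-α - 1/2)

and the rate is ``Σ_i N(t; t_i, h(t)²)``.  Defaults follow the convention
α = 4 and β = n_spikes^(4/5).  The estimator is evaluated on a uniform
grid whose spacing sets the temporal scale of the readout: 5 ms for the
small per-lick window, 200 ms for the large per-trial window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import gamma as _gamma
from typing import Optional, Sequence

import numpy as np

from .core_io import AnalysisWindow, EventKind, EventLog, Liquid, SpikeTrainSet


@dataclass
class BAKSConfig:
    alpha: float = 4.0
    beta_exponent: float = 0.8  # beta = n_spikes ** beta_exponent
    output_dt: float = 0.005    # s; 0.005 for S-window, 0.2 for L-window
    h_max: Optional[float] = None  # optional cap on the adaptive bandwidth, s

    def __post_init__(self) -> None:
        if self.alpha <= 0.5:
            raise ValueError("alpha must exceed 0.5")
        if self.output_dt <= 0:
            raise ValueError("output_dt must be positive")
        if self.h_max is not None and self.h_max <= 0:
            raise ValueError("h_max must be positive")


@dataclass
class RateTrace:
    times: np.ndarray
    rate: np.ndarray
    unit_id: str = ""
    window: Optional[AnalysisWindow] = None
    empty: bool = False  # no spikes were available; rate is identically 0


def baks_bandwidth(
    spike_times: np.ndarray, eval_grid: np.ndarray, cfg: BAKSConfig = BAKSConfig()
) -> np.ndarray:
    """The data-adaptive bandwidth h(t) on the evaluation grid."""
    st = np.asarray(spike_times, float)
    t = np.asarray(eval_grid, float)
    n = st.size
    if n == 0:
        raise ValueError("bandwidth undefined for an empty spike train")
    beta = float(n) ** cfg.beta_exponent
    base = (t[:, None] - st[None, :]) ** 2 / 2.0 + 1.0 / beta
    num = np.power(base, -cfg.alpha).sum(axis=1)
    den = np.power(base, -cfg.alpha - 0.5).sum(axis=1)
    h = _gamma(cfg.alpha) / _gamma(cfg.alpha + 0.5) * num / den
    if cfg.h_max is not None:
        h = np.minimum(h, cfg.h_max)
    return h


def baks_rate(
    spike_times: Sequence[float],
    eval_grid: np.ndarray,
    cfg: BAKSConfig = BAKSConfig(),
    unit_id: str = "",
    window: Optional[AnalysisWindow] = None,
) -> RateTrace:
    """BAKS rate estimate on ``eval_grid`` (Hz).

    An empty spike train yields a zero trace flagged ``empty=True`` so that
    population matrices keep a fixed shape.
    """
    st = np.asarray(spike_times, float)
    t = np.asarray(eval_grid, float)
    if st.size == 0:
        return RateTrace(t, np.zeros_like(t), unit_id, window, empty=True)
    h = baks_bandwidth(st, t, cfg)
    diff = t[:, None] - st[None, :]
    rate = (
        np.exp(-(diff**2) / (2.0 * h[:, None] ** 2))
        / (np.sqrt(2.0 * np.pi) * h[:, None])
    ).sum(axis=1)
    return RateTrace(t, rate, unit_id, window)


def baks_rate_long(
    spike_times: np.ndarray,
    eval_grid: np.ndarray,
    cfg: BAKSConfig = BAKSConfig(),
    truncate_s: float = 2.0,
    chunk_s: float = 10.0,
) -> np.ndarray:
    """BAKS on a long recording, evaluated chunk-wise with truncated kernel
    support (spikes further than ``truncate_s`` from a chunk contribute
    negligibly to both the bandwidth and the rate)."""
    st = np.asarray(spike_times, float)
    t = np.asarray(eval_grid, float)
    if st.size == 0:
        return np.zeros_like(t)
    beta = float(st.size) ** cfg.beta_exponent
    out = np.empty_like(t)
    gr = _gamma(cfg.alpha) / _gamma(cfg.alpha + 0.5)
    start = 0
    while start < t.size:
        stop = min(start + int(chunk_s / max(cfg.output_dt, 1e-9)), t.size)
        tc = t[start:stop]
        lo = np.searchsorted(st, tc[0] - truncate_s)
        hi = np.searchsorted(st, tc[-1] + truncate_s)
        sc = st[lo:hi]
        if sc.size == 0:
            out[start:stop] = 0.0
            start = stop
            continue
        base = (tc[:, None] - sc[None, :]) ** 2 / 2.0 + 1.0 / beta
        num = np.power(base, -cfg.alpha).sum(axis=1)
        den = np.power(base, -cfg.alpha - 0.5).sum(axis=1)
        h = gr * num / den
        if cfg.h_max is not None:
            h = np.minimum(h, cfg.h_max)
        diff = tc[:, None] - sc[None, :]
        out[start:stop] = (
            np.exp(-(diff**2) / (2.0 * h[:, None] ** 2))
            / (np.sqrt(2.0 * np.pi) * h[:, None])
        ).sum(axis=1)
        start = stop
    return out


def baks_rate_matrix(
    spike_lists: Sequence[np.ndarray],
    grid: np.ndarray,
    cfg: BAKSConfig = BAKSConfig(),
) -> np.ndarray:
    """Batched BAKS: one trace per anchor-relative spike array.

    Rows with no spikes yield zero traces.  Padding with +inf removes the
    pad entries from both bandwidth sums and the kernel sum.
    """
    n_rows = len(spike_lists)
    grid = np.asarray(grid, float)
    if n_rows == 0:
        return np.empty((0, grid.size))
    counts = np.array([len(s) for s in spike_lists])
    nmax = int(counts.max()) if counts.size else 0
    if nmax == 0:
        return np.zeros((n_rows, grid.size))
    st = np.full((n_rows, nmax), np.inf)
    for i, s in enumerate(spike_lists):
        st[i, : len(s)] = s
    beta = np.where(counts > 0, counts, 1).astype(float) ** cfg.beta_exponent
    with np.errstate(invalid="ignore"):
        base = (grid[None, :, None] - st[:, None, :]) ** 2 / 2.0
        base += (1.0 / beta)[:, None, None]
        num = np.power(base, -cfg.alpha).sum(axis=2)
        den = np.power(base, -cfg.alpha - 0.5).sum(axis=2)
    gr = _gamma(cfg.alpha) / _gamma(cfg.alpha + 0.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = gr * num / den
    h[~np.isfinite(h)] = 1.0  # empty rows: bandwidth irrelevant, rate is 0
    if cfg.h_max is not None:
        h = np.minimum(h, cfg.h_max)
    diff = grid[None, :, None] - st[:, None, :]
    with np.errstate(over="ignore"):
        rate = (
            np.exp(-(diff**2) / (2.0 * h[:, :, None] ** 2))
            / (np.sqrt(2.0 * np.pi) * h[:, :, None])
        ).sum(axis=2)
    rate[counts == 0] = 0.0
    return rate


def window_grid(window: AnalysisWindow, dt: float) -> np.ndarray:
    """Uniform offset grid spanning a window at spacing dt (half-open)."""
    n = int(round((window.end_offset - window.start_offset) / dt))
    return window.start_offset + dt * np.arange(n + 1)


def first_lick_anchors(
    events: EventLog, liquid: Liquid, max_latency: float = 5.0
) -> list[float]:
    """First lick onset after each delivery onset of the given liquid.

    Trials whose first lick arrives more than ``max_latency`` s after the
    delivery onset (or never) are dropped.
    """
    lo = events.times(EventKind.LO)
    anchors = []
    for do, end, _liq in events.delivery_epochs(liquid):
        licks = lo[(lo >= do) & (lo < do + max_latency)]
        if licks.size:
            anchors.append(float(licks[0]))
    return anchors


def lick_anchors(events: EventLog, liquid: Liquid) -> list[float]:
    """All lick onsets falling inside delivery epochs of the given liquid."""
    lo = events.times(EventKind.LO)
    out: list[float] = []
    for do, end, _liq in events.delivery_epochs(liquid):
        out.extend(lo[(lo >= do) & (lo < end)].tolist())
    return out


def windowed_rates(
    spikes: SpikeTrainSet,
    events: EventLog,
    window: AnalysisWindow,
    cfg: Optional[BAKSConfig] = None,
    liquid: Liquid = Liquid.WATER,
    max_trials: Optional[int] = None,
) -> dict[str, list[RateTrace]]:
    """Per-unit, per-trial BAKS traces in an event-anchored window.

    S-windows anchor on every lick onset within delivery epochs, L-windows
    on the first lick onset of each delivery trial.  Spikes up to 0.25 s
    outside the window contribute so edge kernels are fully supported.
    """
    if cfg is None:
        cfg = BAKSConfig(output_dt=0.005 if window.kind == "S" else 0.2)
    if window.anchor == "FIRST_LO":
        anchors = first_lick_anchors(events, liquid)
    else:
        anchors = lick_anchors(events, liquid)
    if max_trials is not None:
        anchors = anchors[:max_trials]
    grid = window_grid(window, cfg.output_dt)
    margin = max(3 * cfg.output_dt, 0.5)
    out: dict[str, list[RateTrace]] = {}
    for u in spikes.units:
        traces = []
        for a in anchors:
            lo, hi = a + window.start_offset - margin, a + window.end_offset + margin
            st = u.spike_times[(u.spike_times >= lo) & (u.spike_times < hi)] - a
            traces.append(baks_rate(st, grid, cfg, unit_id=u.unit_id, window=window))
        out[u.unit_id] = traces
    return out
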