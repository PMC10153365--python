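"""Directed excitatory functional connectivity via Total Spiking Probability
Edges (TSPE).

For a putative connection src -> dst the cross-correlogram of the two spike
trains (1 ms bins, +/-50 ms delays) is normalised by the number of source
spikes, giving the probability of a target spike at each delay.  An
edge-filter bank (centre-minus-flanks detectors at several widths) converts
the correlogram into a spiking-probability-edge curve; the connection
weight is the maximum of the summed filter responses over strictly
positive delays, so a reverse-causal (dst leads src) pair scores nothing.

Significance is assessed against surrogate weights from spike-time
shuffled target trains (uniform redraws within the crop, preserving spike
counts and, for recombined lick-window data, per-segment counts).  The
surrogate percentile depends on the number N of units in the compared
representations: N < 10 is not evaluated, 10 <= N < 15 uses the 80th,
15 <= N < 20 the 90th, 20 <= N <= 32 the 95th and N > 32 the 99th
percentile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class TSPEConfig:
    max_delay_ms: float = 50.0
    bin_ms: float = 1.0
    crop_duration_s: float = 3.0
    n_surrogates: int = 200
    edge_filter_widths: tuple[int, ...] = (1, 2, 3)  # bins
    pair_percentile: float = 95.0  # per-pair detection threshold
    min_spikes: int = 2

    @property
    def n_delay_bins(self) -> int:
        return int(round(self.max_delay_ms / self.bin_ms))


def percentile_for_n(n: int) -> Optional[float]:
    """Surrogate percentile mandated for a representation of ``n`` units."""
    if n < 10:
        return None
    if n < 15:
        return 80.0
    if n < 20:
        return 90.0
    if n <= 32:
        return 95.0
    return 99.0


@dataclass
class EdgeMatrix:
    weights: np.ndarray          # (n_src, n_dst), nan where undefined
    significant: np.ndarray      # boolean, per-pair surrogate test
    percentile: Optional[float]  # percentile used (None -> not evaluated)
    group_significant: Optional[bool]  # mean-weight network-level test
    evaluated: bool


# ---------------------------------------------------------------------------
# recombination of lick windows
# ---------------------------------------------------------------------------


def lick_window_recombine(
    spike_times: np.ndarray,
    lick_times: Sequence[float],
    window: tuple[float, float] = (-0.100, 0.080),
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate per-lick half-open windows into one recombined train.

    Returns ``(times, segment_ids)`` where times are measured on the
    recombined axis (segment k occupies ``[k*w, (k+1)*w)`` with
    ``w = window span``) and segment ids record the lick of origin so
    correlogram accumulation can be masked at segment joins.
    """
    spike_times = np.asarray(spike_times, float)
    span = window[1] - window[0]
    out_t, out_seg = [], []
    for k, lo in enumerate(lick_times):
        m = (spike_times >= lo + window[0]) & (spike_times < lo + window[1])
        seg = spike_times[m] - (lo + window[0]) + k * span
        out_t.append(seg)
        out_seg.append(np.full(seg.size, k))
    if not out_t:
        return np.empty(0), np.empty(0, dtype=int)
    return np.concatenate(out_t), np.concatenate(out_seg).astype(int)


# ---------------------------------------------------------------------------
# core weight computation
# ---------------------------------------------------------------------------


def _correlogram(
    src: np.ndarray,
    dst: np.ndarray,
    cfg: TSPEConfig,
    src_seg: Optional[np.ndarray] = None,
    dst_seg: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Delay histogram of dst-src spike-time differences, / n_src.

    With segment ids, only same-segment pairs are counted so recombined
    window joins cannot create artifactual delays.
    """
    d_bins = cfg.n_delay_bins
    bw = cfg.bin_ms / 1000.0
    edges = (np.arange(-d_bins, d_bins + 1) - 0.5) * bw
    diffs = dst[None, :] - src[:, None]
    if src_seg is not None and dst_seg is not None:
        mask = src_seg[:, None] == dst_seg[None, :]
        diffs = diffs[mask]
    counts, _ = np.histogram(diffs, bins=edges)
    return counts / src.size


def _spe_curve(ncc: np.ndarray, cfg: TSPEConfig) -> tuple[np.ndarray, np.ndarray]:
    """Edge-filtered correlogram summed over filter widths.

    Returns (delays in bins, curve) restricted to strictly positive delays
    where every filter fits.
    """
    d_bins = cfg.n_delay_bins
    wmax = max(cfg.edge_filter_widths)
    lo = d_bins + 1           # index of delay +1 bin
    hi = 2 * d_bins + 1 - 2 * wmax
    delays = np.arange(lo, hi) - d_bins
    total = np.zeros(hi - lo)
    c = np.concatenate([[0.0], np.cumsum(ncc)])

    def win_mean(start: np.ndarray, width: int) -> np.ndarray:
        return (c[start + width] - c[start]) / width

    idx = np.arange(lo, hi)
    for w in cfg.edge_filter_widths:
        centre = win_mean(idx, w)
        left = win_mean(idx - w, w)
        right = win_mean(idx + w, w)
        total += centre - 0.5 * (left + right)
    return delays, total


def tspe_weight(
    src: np.ndarray,
    dst: np.ndarray,
    cfg: TSPEConfig = TSPEConfig(),
    src_seg: Optional[np.ndarray] = None,
    dst_seg: Optional[np.ndarray] = None,
) -> float:
    """TSPE weight src -> dst: max edge-filtered correlogram amplitude at
    positive delays.  ``nan`` when either train is too sparse."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if src.size < cfg.min_spikes or dst.size < cfg.min_spikes:
        return float("nan")
    ncc = _correlogram(src, dst, cfg, src_seg, dst_seg)
    _, curve = _spe_curve(ncc, cfg)
    return float(curve.max())


def tspe_pair(
    src: np.ndarray,
    dst: np.ndarray,
    cfg: TSPEConfig = TSPEConfig(),
    seed: int | np.random.Generator = 0,
    src_seg: Optional[np.ndarray] = None,
    dst_seg: Optional[np.ndarray] = None,
    return_surrogates: bool = False,
):
    """Weight plus per-pair surrogate significance for one directed pair."""
    rng = np.random.default_rng(seed)
    w = tspe_weight(src, dst, cfg, src_seg, dst_seg)
    if np.isnan(w):
        return (w, False, np.empty(0)) if return_surrogates else (w, False)
    surr = np.empty(cfg.n_surrogates)
    for k in range(cfg.n_surrogates):
        fake = _shuffle_train(np.asarray(dst, float), dst_seg, cfg, rng)
        surr[k] = tspe_weight(np.asarray(src, float), fake[0], cfg, src_seg, fake[1])
    sig = bool(w > np.percentile(surr, cfg.pair_percentile))
    if return_surrogates:
        return w, sig, surr
    return w, sig


def _shuffle_train(
    times: np.ndarray,
    seg: Optional[np.ndarray],
    cfg: TSPEConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Surrogate: uniform redraw preserving counts (per segment if given)."""
    if seg is None:
        hi = max(float(times.max()) if times.size else 0.0, cfg.crop_duration_s)
        return np.sort(rng.uniform(0.0, hi, times.size)), None
    span = 0.18  # recombined segment length
    out_t = np.empty_like(times)
    for s in np.unique(seg):
        m = seg == s
        out_t[m] = np.sort(rng.uniform(s * span, (s + 1) * span, int(m.sum())))
    return out_t, seg


def tspe_network(
    group_a: Sequence[np.ndarray],
    group_b: Sequence[np.ndarray],
    cfg: TSPEConfig = TSPEConfig(),
    seed: int = 0,
    exclude_diagonal: bool = False,
) -> EdgeMatrix:
    """All A -> B weights with the N-dependent percentile significance rule.

    N is the smaller of the two representation sizes; groups below 10
    units are not evaluated (weights are still reported).
    """
    rng = np.random.default_rng(seed)
    n_a, n_b = len(group_a), len(group_b)
    n = min(n_a, n_b)
    pct = percentile_for_n(n)

    weights = np.full((n_a, n_b), np.nan)
    significant = np.zeros((n_a, n_b), dtype=bool)
    pair_surr_means = []
    for i, src in enumerate(group_a):
        for j, dst in enumerate(group_b):
            if exclude_diagonal and i == j:
                continue
            w = tspe_weight(np.asarray(src, float), np.asarray(dst, float), cfg)
            weights[i, j] = w
            if pct is None or np.isnan(w):
                continue
            surr = np.empty(cfg.n_surrogates)
            for k in range(cfg.n_surrogates):
                fake, _ = _shuffle_train(np.asarray(dst, float), None, cfg, rng)
                surr[k] = tspe_weight(np.asarray(src, float), fake, cfg)
            significant[i, j] = bool(w > np.percentile(surr, pct))
            pair_surr_means.append(surr)

    group_sig: Optional[bool] = None
    if pct is not None and pair_surr_means:
        real_mean = float(np.nanmean(weights))
        surr_means = np.mean(np.stack(pair_surr_means), axis=0)
        group_sig = bool(real_mean > np.percentile(surr_means, pct))
    return EdgeMatrix(weights, significant, pct, group_sig, pct is not None)
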