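"""Single-unit classification into valence and movement-phase classes.

Valence classes (small, per-lick window)
----------------------------------------
Firing is summarised, per lick and per 5 ms bin, by the Euclidean norm of
temporally adjacent rate estimates.  Water-lick, quinine-lick and
pseudo-trial norm distributions are compared with the effect-size statistic

    Z12 = (mu1 - mu2) / sqrt(sd1^2 + sd2^2),

significant when |Z12| > 1.29.  The rule table is:

========  ==========================================================
LICK      quinine > pseudo  &  water > pseudo  &  same firing peak
          between liquids  &  time bias in both water and quinine
PV        water > pseudo  &  water > quinine  &  quinine <= pseudo
NV        quinine > pseudo  &  quinine > water  &  water <= pseudo
MV        water > pseudo  &  quinine > pseudo  &  different firing
          peaks  &  time bias in both
UV        anything else
========  ==========================================================

"time bias" is a permutation test on the Frobenius norm of column-mean
deviations of the (licks x 10 ms bins) rate matrix; "trial bias" is the
analogous row-mean test on the matrix binned into groups of 8 lick trials.

Phase classes (large, per-trial window)
---------------------------------------
Firing rates at five time points across 2 s windows anchored on the first
water / quinine lick of a trial are compared against percentiles of a
pseudo distribution sampled at random times from the whole (>= 70 s) spike
train: a unit is an initial-phase representation when it exceeds the 65th
pseudo percentile around the first water lick and falls below the 35th
around the first quinine lick (pre- and post-lick variants), and a
terminal-phase representation in the mirrored case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    AnalysisWindow,
    EventKind,
    EventLog,
    Liquid,
    PhaseClass,
    SessionBundle,
    ValenceClass,
)
from .rate_estimation import (
    BAKSConfig,
    baks_rate,
    baks_rate_long,
    baks_rate_matrix,
    window_grid,
)

logger = logging.getLogger("persistlick")


@dataclass
class ClassificationConfig:
    z_threshold: float = 1.29
    peak_p_threshold: float = 0.05
    n_shuffles: int = 1000
    frobenius_percentile: float = 95.0
    pseudo_baseline_s: float = 10.0
    time_bin_coarse: float = 0.010
    trial_bin: int = 8
    phase_hi: float = 0.65
    phase_lo: float = 0.35
    phase_timepoints: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)
    phase_agg: str = "majority"   # "majority" (>=3/5) or "all"
    n_phase_pseudo: int = 1000
    peak_h_max: float = 0.010     # bandwidth cap for the peak-time estimate
    n_valence_trials: int = 4     # real delivery trials entering the analysis
    licks_per_trial: int = 30     # per-trial cap on lick windows
    waveform_r_threshold: float = 0.85
    salt_windows: tuple[tuple[float, float], tuple[float, float]] = (
        (0.0, 0.005),
        (0.006, 0.010),
    )

    def __post_init__(self) -> None:
        if not 0 < self.phase_lo < self.phase_hi < 1:
            raise ValueError("need 0 < phase_lo < phase_hi < 1")


@dataclass
class UnitLabel:
    unit_id: str
    valence_class: ValenceClass
    phase_class: PhaseClass
    trial_bias: bool
    time_bias: bool
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def make_pseudo_trials(
    spike_times: np.ndarray,
    lick_times: np.ndarray,
    baseline_window: tuple[float, float],
    window: AnalysisWindow,
    baks_cfg: BAKSConfig,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Mean bin-shuffled pseudo-trial rate matrix from the baseline epoch.

    Pseudo lick anchors replicate the inter-lick intervals of the real
    licks, placed inside the lick-free baseline.  The per-anchor rate
    matrix is flattened, permuted, reshaped ``n_shuffles`` times and
    averaged, which preserves the marginal rate distribution while erasing
    temporal structure.
    """
    t0, t1 = baseline_window
    if t1 - t0 < 10.0:
        raise ValueError("baseline window must span at least 10 s")
    rng = np.random.default_rng(seed)
    lick_times = np.asarray(lick_times, float)
    if lick_times.size == 0:
        raise ValueError("need real licks to replicate their interval structure")
    ilis = np.diff(lick_times)
    margin = -window.start_offset + 0.1
    anchors = [t0 + margin]
    for ili in ilis:
        nxt = anchors[-1] + ili
        if nxt + window.end_offset + 0.1 > t1:
            break
        anchors.append(nxt)
    mat = _rate_matrix(spike_times, np.array(anchors), window, baks_cfg)
    flat = mat.ravel()
    tiled = np.tile(flat, (n_shuffles, 1))
    shuffled = rng.permuted(tiled, axis=1)
    return shuffled.mean(axis=0).reshape(mat.shape)


def _rate_matrix(
    spike_times: np.ndarray,
    anchors: np.ndarray,
    window: AnalysisWindow,
    cfg: BAKSConfig,
) -> np.ndarray:
    grid = window_grid(window, cfg.output_dt)
    # generous kernel support beyond the window so adaptive bandwidths are
    # fed by neighbouring spikes and the estimate has no edge dip
    margin = max(3 * cfg.output_dt, 0.5)
    spike_lists = []
    for a in anchors:
        lo, hi = a + window.start_offset - margin, a + window.end_offset + margin
        i0, i1 = np.searchsorted(spike_times, (lo, hi))
        spike_lists.append(spike_times[i0:i1] - a)
    return baks_rate_matrix(spike_lists, grid, cfg)


def adjacent_norm_series(trace: np.ndarray) -> np.ndarray:
    """Euclidean norms of temporally adjacent rate pairs.

    For a constant trace c this is c*sqrt(2) everywhere.
    """
    r = np.asarray(trace, float)
    if r.shape[-1] < 2:
        raise ValueError("need at least two samples")
    return np.sqrt(r[..., :-1] ** 2 + r[..., 1:] ** 2)


def z_compare(dist_a: np.ndarray, dist_b: np.ndarray) -> float:
    """Signed effect-size z between two distributions.

    ``(mu_a - mu_b) / sqrt(sd_a^2 + sd_b^2)``; 0 when both are constant and
    equal, +/-inf when both are constant but different (flagged upstream).
    """
    a, b = np.asarray(dist_a, float).ravel(), np.asarray(dist_b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("distributions must be non-empty")
    denom = np.sqrt(a.std() ** 2 + b.std() ** 2)
    diff = a.mean() - b.mean()
    if denom == 0:
        return 0.0 if diff == 0 else float(np.sign(diff)) * np.inf
    return float(diff / denom)


def _frobenius_mean_dev(means: np.ndarray) -> float:
    return float(np.sqrt(((means - means.mean()) ** 2).sum()))


def time_bias_test(
    rate_matrix: np.ndarray,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
    percentile: float = 95.0,
) -> tuple[float, bool]:
    """Permutation test for temporal structure across the window.

    Statistic: Frobenius norm of column-mean deviations from the grand
    mean; null: bins permuted independently within each trial.
    """
    m = np.asarray(rate_matrix, float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a trials x bins matrix with >= 2 bins")
    rng = np.random.default_rng(seed)
    real = _frobenius_mean_dev(m.mean(axis=0))
    tiled = np.broadcast_to(m, (n_shuffles,) + m.shape)
    shuffled = rng.permuted(tiled, axis=2)
    col_means = shuffled.mean(axis=1)
    norms = np.sqrt(
        ((col_means - col_means.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    )
    return real, bool(real > np.percentile(norms, percentile))


def trial_bias_test(
    rate_matrix: np.ndarray,
    trial_bin: int = 8,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
    percentile: float = 95.0,
) -> tuple[float, bool]:
    """Permutation test for drift across lick trials.

    Trials are binned into groups of ``trial_bin``; the statistic is the
    Frobenius norm of group-mean deviations; null: trial labels permuted.
    """
    m = np.asarray(rate_matrix, float)
    n_groups = m.shape[0] // trial_bin
    if n_groups < 2:
        raise ValueError("need at least two trial bins")
    n_used = n_groups * trial_bin
    rng = np.random.default_rng(seed)

    def stat(mat: np.ndarray) -> float:
        groups = mat[:n_used].reshape(n_groups, trial_bin, -1).mean(axis=(1, 2))
        return _frobenius_mean_dev(groups)

    real = stat(m)
    row_means = m[:n_used].mean(axis=1)
    perm = np.argsort(rng.random((n_shuffles, n_used)), axis=1)
    grouped = row_means[perm].reshape(n_shuffles, n_groups, trial_bin).mean(axis=2)
    norms = np.sqrt(((grouped - grouped.mean(axis=1, keepdims=True)) ** 2).sum(axis=1))
    return real, bool(real > np.percentile(norms, percentile))


# ---------------------------------------------------------------------------
# valence classification
# ---------------------------------------------------------------------------


def _peak_times(rate_matrix: np.ndarray, dt: float) -> np.ndarray:
    # per-trial time of maximum rate; ties -> earliest bin
    return np.argmax(rate_matrix, axis=1) * dt


def _coarsen(rate_matrix: np.ndarray, dt_fine: float, dt_coarse: float) -> np.ndarray:
    k = max(1, int(round(dt_coarse / dt_fine)))
    n = (rate_matrix.shape[1] // k) * k
    return rate_matrix[:, :n].reshape(rate_matrix.shape[0], -1, k).mean(axis=2)


def classify_valence(
    water: np.ndarray,
    quinine: np.ndarray,
    pseudo: np.ndarray,
    cfg: ClassificationConfig = ClassificationConfig(),
    seed: int | np.random.Generator = 0,
    dt: float = 0.005,
    water_peak: Optional[np.ndarray] = None,
    quinine_peak: Optional[np.ndarray] = None,
) -> tuple[ValenceClass, dict]:
    """Apply the valence rule table to water/quinine/pseudo rate matrices.

    ``water_peak``/``quinine_peak`` optionally supply narrow-bandwidth rate
    matrices for the firing-peak comparison (phasic latency structure is
    invisible at the adaptive bandwidth of the z statistics).
    """
    rng = np.random.default_rng(seed)
    zt = cfg.z_threshold
    nw = adjacent_norm_series(water)
    nq = adjacent_norm_series(quinine)
    np_ = adjacent_norm_series(pseudo)
    z_wp = z_compare(nw, np_)
    z_qp = z_compare(nq, np_)
    z_wq = z_compare(nw, nq)

    pw = _peak_times(water_peak if water_peak is not None else water, dt)
    pq = _peak_times(quinine_peak if quinine_peak is not None else quinine, dt)
    if pw.size > 1 and pq.size > 1 and (pw.std() > 0 or pq.std() > 0):
        peak_p = float(stats.ttest_ind(pw, pq, equal_var=False).pvalue)
    else:
        peak_p = 1.0
    peak_diff = peak_p < cfg.peak_p_threshold

    # bias tests run on the narrow-bandwidth estimate when available: the
    # adaptive bandwidth smooths fine structure below detectability, and a
    # dome-free fine-scale estimate keeps the permutation null calibrated
    tb_water = water_peak if water_peak is not None else water
    tb_quinine = quinine_peak if quinine_peak is not None else quinine
    cw = _coarsen(tb_water, dt, cfg.time_bin_coarse)
    cq = _coarsen(tb_quinine, dt, cfg.time_bin_coarse)
    _, tb_w = time_bias_test(cw, cfg.n_shuffles, rng, cfg.frobenius_percentile)
    _, tb_q = time_bias_test(cq, cfg.n_shuffles, rng, cfg.frobenius_percentile)

    diag = {
        "z_water_pseudo": z_wp,
        "z_quinine_pseudo": z_qp,
        "z_water_quinine": z_wq,
        "peak_p": peak_p,
        "time_bias_water": tb_w,
        "time_bias_quinine": tb_q,
    }
    if z_qp > zt and z_wp > zt and not peak_diff and tb_w and tb_q:
        cls = ValenceClass.LICK
    elif z_wp > zt and z_wq > zt and z_qp <= zt:
        cls = ValenceClass.PV
    elif z_qp > zt and -z_wq > zt and z_wp <= zt:
        cls = ValenceClass.NV
    elif z_wp > zt and z_qp > zt and peak_diff and tb_w and tb_q:
        cls = ValenceClass.MV
    else:
        cls = ValenceClass.UV
    return cls, diag


# ---------------------------------------------------------------------------
# phase classification
# ---------------------------------------------------------------------------


def classify_phase(
    spike_times: np.ndarray,
    first_water_lo: Optional[float],
    first_quinine_lo: Optional[float],
    cfg: ClassificationConfig = ClassificationConfig(),
    seed: int | np.random.Generator = 0,
    session_duration: Optional[float] = None,
    rate_trace: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> tuple[PhaseClass, dict]:
    """Movement-phase classification from large-window firing rates.

    ``rate_trace`` may supply a precomputed (times, rate) full-session
    trace at 200 ms sampling to avoid recomputation across units.
    """
    rng = np.random.default_rng(seed)
    if first_water_lo is None or first_quinine_lo is None:
        return PhaseClass.UNRELATED, {"flag": "missing anchor"}
    spike_times = np.asarray(spike_times, float)
    if session_duration is None:
        session_duration = float(spike_times[-1]) if spike_times.size else 0.0
    if session_duration < 70.0:
        raise ValueError("need >= 70 s of data for pseudo sampling")

    if rate_trace is None:
        grid = np.arange(0.0, session_duration, 0.2)
        trace = baks_rate_long(spike_times, grid, BAKSConfig(output_dt=0.2))
    else:
        grid, trace = rate_trace

    def rate_at(times: np.ndarray) -> np.ndarray:
        # snap to the nearest rate sample so pseudo and real evaluations
        # draw from the same marginal distribution
        idx = np.clip(
            np.round((np.asarray(times) - grid[0]) / (grid[1] - grid[0])).astype(int),
            0, grid.size - 1,
        )
        return trace[idx]

    draws = rng.uniform(2.0, session_duration - 2.0, size=cfg.n_phase_pseudo)
    pseudo = rate_at(draws)
    hi_th = np.percentile(pseudo, 100 * cfg.phase_hi)
    lo_th = np.percentile(pseudo, 100 * cfg.phase_lo)

    def window_vals(window: tuple[float, float]) -> np.ndarray:
        pts = np.linspace(window[0], window[1], len(cfg.phase_timepoints))
        return rate_at(pts)

    def cond(window: tuple[float, float], kind: str) -> bool:
        vals = window_vals(window)
        hits = (vals > hi_th) if kind == "hi" else (vals < lo_th)
        need = len(vals) if cfg.phase_agg == "all" else (len(vals) // 2 + 1)
        return int(hits.sum()) >= need

    w, q = first_water_lo, first_quinine_lo
    pre_hi = cond((w - 2.0, w), "hi")
    post_hi = cond((w, w + 2.0), "hi")
    q_hi = cond((q, q + 2.0), "hi")
    q_lo = cond((q, q + 2.0), "lo")
    w_lo4 = cond((w - 2.0, w + 2.0), "lo")  # 4 s anti-window of the terminal rule

    diag = {
        "pre_hi": pre_hi, "post_hi": post_hi, "q_hi": q_hi,
        "q_lo": q_lo, "w_lo4": w_lo4,
        "hi_threshold": float(hi_th), "lo_threshold": float(lo_th),
    }
    if pre_hi and post_hi and q_lo:
        # both initial windows qualify (smoothing leakage): pick the one
        # with the larger mean rate
        pre_mean = float(window_vals((w - 2.0, w)).mean())
        post_mean = float(window_vals((w, w + 2.0)).mean())
        cls = PhaseClass.INITIAL_PRE if pre_mean >= post_mean else PhaseClass.INITIAL_POST
        return cls, diag
    if pre_hi and q_lo:
        return PhaseClass.INITIAL_PRE, diag
    if post_hi and q_lo:
        return PhaseClass.INITIAL_POST, diag
    if q_hi and w_lo4:
        return PhaseClass.TERMINAL, diag
    return PhaseClass.UNRELATED, diag


# ---------------------------------------------------------------------------
# optogenetic identification
# ---------------------------------------------------------------------------


def identify_optotagged(
    spike_times: np.ndarray,
    laser_onsets: np.ndarray,
    waveform_evoked: np.ndarray,
    waveform_baseline: np.ndarray,
    cfg: ClassificationConfig = ClassificationConfig(),
    seed: int | np.random.Generator = 0,
    n_surrogates: int = 200,
) -> str:
    """SALT-style tagging: ``laser_evoked``, ``network_evoked`` or ``untagged``.

    The response probability in the 0-5 ms (laser) or 6-10 ms (network)
    post-pulse window is compared against surrogate pulse trains shifted
    uniformly into the pre-laser baseline; tagging additionally requires a
    mean-waveform correlation above 0.85.
    """
    spike_times = np.asarray(spike_times, float)
    laser_onsets = np.asarray(laser_onsets, float)
    if laser_onsets.size < 20:
        raise ValueError("need at least 20 laser pulses")
    rng = np.random.default_rng(seed)

    wf_r = float(np.corrcoef(waveform_evoked, waveform_baseline)[0, 1])
    if not wf_r > cfg.waveform_r_threshold:
        return "untagged"

    def resp_prob(onsets: np.ndarray, win: tuple[float, float]) -> float:
        lo = np.searchsorted(spike_times, onsets + win[0])
        hi = np.searchsorted(spike_times, onsets + win[1])
        return float(np.mean(hi > lo))

    t0 = laser_onsets[0]
    max_shift = max(t0 - laser_onsets[-1] - 0.02, -t0 + 0.02)
    base_lo = 0.02
    base_hi = max(t0 - 0.02, 0.04)
    labels = ("laser_evoked", "network_evoked")
    for win, label in zip(cfg.salt_windows, labels):
        obs = resp_prob(laser_onsets, win)
        if obs == 0:
            continue
        surr = np.empty(n_surrogates)
        shifts = rng.uniform(base_lo, base_hi, n_surrogates)
        for k, s in enumerate(shifts):
            surr[k] = resp_prob(laser_onsets - s, win)
        p = (1.0 + np.sum(surr >= obs)) / (n_surrogates + 1.0)
        if p < 0.05:
            return label
    return "untagged"


# ---------------------------------------------------------------------------
# association test
# ---------------------------------------------------------------------------


def association_test(labels: Sequence[UnitLabel]) -> tuple[float, float]:
    """Chi-square association between valence- and phase-preference."""
    val_pref = np.array([l.valence_class != ValenceClass.UV for l in labels])
    ph_pref = np.array([l.phase_class != PhaseClass.UNRELATED for l in labels])
    table = np.array(
        [
            [np.sum(val_pref & ph_pref), np.sum(val_pref & ~ph_pref)],
            [np.sum(~val_pref & ph_pref), np.sum(~val_pref & ~ph_pref)],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table (zero expected counts)")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# session driver
# ---------------------------------------------------------------------------


def classify_session(
    bundle: SessionBundle,
    cfg: ClassificationConfig = ClassificationConfig(),
    seed: int = 0,
) -> list[UnitLabel]:
    """Classify every unit of a session on both taxonomies."""
    rng = np.random.default_rng(seed)
    events = bundle.events
    s_win = AnalysisWindow.small()
    s_cfg = BAKSConfig(output_dt=0.005)
    peak_cfg = BAKSConfig(output_dt=0.005, h_max=cfg.peak_h_max)
    duration = bundle.spikes.session_duration

    def lick_anchors(liquid: Liquid) -> np.ndarray:
        lo = events.times(EventKind.LO)
        out = []
        epochs = events.delivery_epochs(liquid)[: cfg.n_valence_trials]
        for do, end, _l in epochs:
            trial = lo[(lo >= do) & (lo < end)][: cfg.licks_per_trial]
            out.extend(trial.tolist())
        return np.asarray(out)

    water_anchors = lick_anchors(Liquid.WATER)
    quinine_anchors = lick_anchors(Liquid.QUININE)

    def first_lo(liquid: Liquid) -> Optional[float]:
        lo = events.times(EventKind.LO)
        eps = events.delivery_epochs(liquid)
        for do, end, _l in eps:
            licks = lo[(lo >= do) & (lo < end)]
            if licks.size:
                return float(licks[0])
        return None

    w_first, q_first = first_lo(Liquid.WATER), first_lo(Liquid.QUININE)
    baseline = (0.0, max(cfg.pseudo_baseline_s, 10.0))

    labels: list[UnitLabel] = []
    grid_full = np.arange(0.0, duration, 0.2)
    for u in bundle.spikes.units:
        water = _rate_matrix(u.spike_times, water_anchors, s_win, s_cfg)
        quinine = _rate_matrix(u.spike_times, quinine_anchors, s_win, s_cfg)
        pseudo = make_pseudo_trials(
            u.spike_times, water_anchors, baseline, s_win, s_cfg,
            cfg.n_shuffles, rng,
        )
        wp = np.empty((0, water.shape[1] if water.size else 0))
        if min(water.shape[0], quinine.shape[0], pseudo.shape[0]) == 0:
            vclass, vdiag = ValenceClass.UV, {"flag": "no licks"}
        else:
            wp = _rate_matrix(u.spike_times, water_anchors, s_win, peak_cfg)
            qp = _rate_matrix(u.spike_times, quinine_anchors, s_win, peak_cfg)
            vclass, vdiag = classify_valence(
                water, quinine, pseudo, cfg, rng,
                water_peak=wp, quinine_peak=qp,
            )

        trace = baks_rate_long(u.spike_times, grid_full, BAKSConfig(output_dt=0.2))
        pclass, pdiag = classify_phase(
            u.spike_times, w_first, q_first, cfg, rng,
            session_duration=duration, rate_trace=(grid_full, trace),
        )

        # alternating licks only: consecutive 180 ms windows overlap by
        # ~37 ms at a 7 Hz lick rate, which would correlate the rows and
        # break the exchangeability null of the trial-bias test
        cw = _coarsen(wp[::2], 0.005, cfg.time_bin_coarse) if wp.size else wp
        try:
            _, trial_biased = trial_bias_test(
                cw, cfg.trial_bin, cfg.n_shuffles, rng, cfg.frobenius_percentile
            )
        except ValueError:
            trial_biased = False
        time_biased = bool(vdiag.get("time_bias_water", False))
        labels.append(
            UnitLabel(u.unit_id, vclass, pclass, trial_biased, time_biased,
                      {**vdiag, **pdiag})
        )
    return labels


def labels_frame(labels: Sequence[UnitLabel]) -> pd.DataFrame:
    rows = []
    for l in labels:
        row = {
            "unit_id": l.unit_id,
            "valence_class": l.valence_class.value,
            "phase_class": l.phase_class.value,
            "trial_bias": l.trial_bias,
            "time_bias": l.time_bias,
        }
        for k, v in l.diagnostics.items():
            if isinstance(v, (int, float, bool, str)):
                row[k] = v
        rows.append(row)
    return pd.DataFrame(rows)
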