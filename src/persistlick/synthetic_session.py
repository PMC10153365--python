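"""Synthetic session generator with known ground truth.

Emulates the structure of a head-fixed persistent-licking session: a
lick-free baseline, alternating liquid-delivery trials (water sustains a
6-8 Hz lick bout until delivery ends; quinine terminates the bout within a
couple of seconds), single units tuned to valence, movement phase, licks,
or nothing, optional planted directed connections between units, and a
facial-activity trace that rises after delivery onset.

Tuning model
------------
Each unit is an inhomogeneous Poisson (or gamma-renewal) process whose
rate is the baseline multiplied by a class-specific profile:

* ``PV`` / ``NV`` — constant gain during water / quinine delivery epochs.
* ``LICK`` — Gaussian rate bumps locked to every lick, same latency for
  both liquids.
* ``MV`` — lick-locked bumps with *different* latencies for water and
  quinine, so the firing peak shifts between liquids.
* ``INITIAL_PRE`` / ``INITIAL_POST`` — gain in the 2 s before / after the
  first water lick of each water trial, and suppression in the 2 s after
  the first quinine lick (phase classes are defined by elevation in the
  preferred window *and* low activity in the opposing one).
* ``TERMINAL`` — gain after the first quinine lick, suppression around the
  first water lick.
* untuned — flat baseline (``UV`` valence, ``UNRELATED`` phase).

Planted edges are realised by spike transfer: each source spike is copied
into the target train at a fixed lag with the edge's transfer probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .core_io import (
    EventKind,
    EventLog,
    FacialTrace,
    GeneratorTruth,
    Liquid,
    PhaseClass,
    Region,
    SessionBundle,
    SpikeTrainSet,
    Unit,
    ValenceClass,
)

REFRACTORY_S = 0.002  # spikes closer than this are merged when combining trains


class RecipeError(ValueError):
    """The recipe implies an unrealisable session."""


@dataclass
class SessionRecipe:
    """Study conditions for one synthetic session.

    Defaults follow the task structure the analyses assume: four water and
    four quinine delivery trials of 10 s each, sustained ~7 Hz lick bouts,
    and a mixed population of valence-, phase-, lick-tuned and untuned
    units.
    """

    # population composition
    n_pv: int = 6
    n_nv: int = 6
    n_mv: int = 5
    n_lick: int = 5
    n_initial_pre: int = 5
    n_initial_post: int = 5
    n_terminal: int = 5
    n_untuned: int = 8
    # rates
    baseline_rate_hz: float = 8.0
    gain: float = 3.0             # tuned-class rate multiplier
    suppression: float = 0.3      # anti-window multiplier for phase classes
    burst_gain: float = 10.0      # extra multiplier at lick-locked bursts
    burst_sd_s: float = 0.012     # width of lick-locked bursts (LICK/MV)
    lick_offset_s: float = 0.01   # burst latency of LICK units (both liquids)
    mv_offset_water_s: float = -0.02   # MV burst latency, water licks
    mv_offset_quinine_s: float = 0.02  # MV burst latency, quinine licks
    # licking
    lick_rate_hz: float = 7.0     # sustained in-bout rate
    lick_jitter_sd: float = 0.005
    water_latency: float = 0.5    # first lick after water DO (s)
    quinine_latency: float = 0.4
    quinine_bout_duration: float = 2.5
    # schedule
    n_water_trials: int = 4
    n_quinine_trials: int = 4
    delivery_duration: float = 10.0
    iti: float = 20.0
    baseline_duration: float = 12.0
    # spiking model
    isi_model: str = "poisson"    # or "gamma"
    gamma_shape: float = 2.0
    # facial
    facial_fps: float = 20.0
    facial_noise_sd: float = 0.05
    # connectivity ground truth: (src index, dst index, lag s, transfer prob)
    planted_edges: list[tuple[int, int, float, float]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if not (5.0 <= self.lick_rate_hz <= 9.0):
            raise RecipeError("in-bout lick rate must lie in [5, 9] Hz")
        if self.baseline_rate_hz * (self.gain + self.burst_gain) > 1.0 / REFRACTORY_S:
            raise RecipeError("peak rate implies >1 spike per refractory period")
        if self.isi_model not in ("poisson", "gamma"):
            raise RecipeError(f"unknown ISI model {self.isi_model!r}")

    @property
    def session_duration(self) -> float:
        n_trials = self.n_water_trials + self.n_quinine_trials
        return self.baseline_duration + n_trials * (self.delivery_duration + self.iti)


# ---------------------------------------------------------------------------
# elementary generators
# ---------------------------------------------------------------------------


def simulate_lick_bout(
    start: float,
    duration: float,
    rate: float,
    jitter_sd: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Approximately periodic lick times in ``[start, start + duration)``."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if duration <= 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    base = start + np.arange(int(np.floor(duration * rate))) / rate
    if jitter_sd > 0:
        base = base + rng.normal(0.0, jitter_sd, size=base.size)
    base = np.sort(base)
    base = base[(base >= start) & (base < start + duration)]
    return np.unique(base)


def _inhomogeneous_poisson(
    rate_fn: Callable[[np.ndarray], np.ndarray],
    rate_max: float,
    duration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Thinning sampler for an inhomogeneous Poisson process on [0, duration)."""
    n_cand = rng.poisson(rate_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, n_cand))
    keep = rng.uniform(0.0, rate_max, n_cand) < rate_fn(cand)
    return cand[keep]


def _gamma_renewal(
    rate_fn: Callable[[np.ndarray], np.ndarray],
    shape: float,
    duration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gamma-ISI renewal process via time rescaling of the cumulative rate."""
    grid = np.arange(0.0, duration, 0.01)
    lam = rate_fn(grid)
    cum = np.concatenate([[0.0], np.cumsum(lam[:-1] * np.diff(grid))])
    total = cum[-1]
    # unit-rate gamma renewal in rescaled time (mean ISI 1)
    n_est = int(total * 1.5) + 20
    isis = rng.gamma(shape, 1.0 / shape, size=n_est)
    arr = np.cumsum(isis)
    arr = arr[arr < total]
    return np.interp(arr, cum, grid)


def _dedupe(times: np.ndarray) -> np.ndarray:
    """Sort and enforce a minimal inter-spike separation."""
    times = np.sort(times)
    if times.size < 2:
        return times
    keep = np.concatenate([[True], np.diff(times) >= REFRACTORY_S / 2])
    return times[keep]


# ---------------------------------------------------------------------------
# facial frames
# ---------------------------------------------------------------------------


def simulate_facial_frames(
    activity_trace: Sequence[float],
    image_size: tuple[int, int],
    seed: int,
    grating_period_px: float = 24.0,
) -> np.ndarray:
    """Frames whose adjacent-frame HOG dissimilarity tracks the commanded
    activity.

    Each frame is a fixed random texture plus an oriented grating; the
    grating orientation advances between frames by an angle proportional to
    the activity level, so orientation-energy turnover — what the HOG
    metric measures — is monotone in activity.  Zero activity yields
    identical frames.
    """
    act = np.asarray(activity_trace, float)
    if act.size and (act.min() < 0 or act.max() > 1):
        raise ValueError("activity trace must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    texture = rng.normal(0.0, 0.15, size=(h, w))
    freq = 2.0 * np.pi / grating_period_px
    theta = rng.uniform(0.0, np.pi)
    frames = np.empty((act.size + 1, h, w))
    for i in range(act.size + 1):
        if i > 0:
            theta += 0.5 * act[i - 1]  # radians per frame at full drive
        grating = np.sin(freq * (xx * np.cos(theta) + yy * np.sin(theta)))
        frames[i] = 0.5 + 0.25 * grating + texture
    return frames


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------


def _schedule(recipe: SessionRecipe) -> list[tuple[float, float, Liquid]]:
    """Delivery epochs: all water trials first, then quinine trials."""
    out = []
    t = recipe.baseline_duration
    for _ in range(recipe.n_water_trials):
        out.append((t, t + recipe.delivery_duration, Liquid.WATER))
        t += recipe.delivery_duration + recipe.iti
    for _ in range(recipe.n_quinine_trials):
        out.append((t, t + recipe.delivery_duration, Liquid.QUININE))
        t += recipe.delivery_duration + recipe.iti
    return out


def _interval_multiplier(
    intervals: list[tuple[float, float]], factor: float
) -> Callable[[np.ndarray], np.ndarray]:
    starts = np.array([s for s, _ in intervals])
    ends = np.array([e for _, e in intervals])

    def fn(t: np.ndarray) -> np.ndarray:
        inside = (
            (t[:, None] >= starts[None, :]) & (t[:, None] < ends[None, :])
        ).any(axis=1)
        return np.where(inside, factor, 1.0)

    return fn


def _bump_multiplier(
    centers: np.ndarray, amplitude: float, sd: float
) -> Callable[[np.ndarray], np.ndarray]:
    def fn(t: np.ndarray) -> np.ndarray:
        out = np.ones_like(t)
        if centers.size:
            d = t[:, None] - centers[None, :]
            near = np.abs(d) < 4 * sd
            out = out + amplitude * np.where(near, np.exp(-(d**2) / (2 * sd**2)), 0.0).sum(
                axis=1
            )
        return out

    return fn


def simulate_session(recipe: SessionRecipe) -> SessionBundle:
    """Generate a full labeled session from a recipe."""
    recipe.validate()
    rng = np.random.default_rng(recipe.seed)
    epochs = _schedule(recipe)
    duration = recipe.session_duration

    # --- behavior: lick bouts -------------------------------------------
    lick_times: list[np.ndarray] = []
    first_lo: dict[Liquid, list[float]] = {Liquid.WATER: [], Liquid.QUININE: []}
    for do, end, liq in epochs:
        if liq == Liquid.WATER:
            latency = recipe.water_latency + abs(rng.normal(0.0, 0.15))
            bout_dur = end - do - latency
        else:
            latency = recipe.quinine_latency + abs(rng.normal(0.0, 0.1))
            bout_dur = min(recipe.quinine_bout_duration, end - do - latency)
        bout = simulate_lick_bout(
            do + latency, bout_dur, recipe.lick_rate_hz, recipe.lick_jitter_sd, rng
        )
        if bout.size:
            first_lo[liq].append(float(bout[0]))
            lick_times.append(bout)
    licks = np.sort(np.concatenate(lick_times)) if lick_times else np.empty(0)

    water_epochs = [(s, e) for s, e, l in epochs if l == Liquid.WATER]
    quinine_epochs = [(s, e) for s, e, l in epochs if l == Liquid.QUININE]
    water_licks = np.concatenate(
        [licks[(licks >= s) & (licks < e)] for s, e in water_epochs]
    ) if water_epochs else np.empty(0)
    quinine_licks = np.concatenate(
        [licks[(licks >= s) & (licks < e)] for s, e in quinine_epochs]
    ) if quinine_epochs else np.empty(0)

    # --- units -----------------------------------------------------------
    b = recipe.baseline_rate_hz
    g = recipe.gain
    sup = recipe.suppression
    specs: list[tuple[ValenceClass, PhaseClass, Callable[[np.ndarray], np.ndarray], float]] = []

    def add(n: int, val: ValenceClass, ph: PhaseClass,
            fn: Callable[[np.ndarray], np.ndarray], peak: float) -> None:
        for _ in range(n):
            specs.append((val, ph, fn, peak))

    ones = lambda t: np.ones_like(t)
    bg, bsd = recipe.burst_gain, recipe.burst_sd_s
    both_epochs = water_epochs + quinine_epochs
    add(recipe.n_pv, ValenceClass.PV, PhaseClass.UNRELATED,
        _interval_multiplier(water_epochs, g), b * g)
    add(recipe.n_nv, ValenceClass.NV, PhaseClass.UNRELATED,
        _interval_multiplier(quinine_epochs, g), b * g)

    # lick- and mixed-valence units: sustained elevation in delivery epochs
    # plus a sharp burst locked to each lick (latency distinguishes MV)
    def lick_fn(t: np.ndarray) -> np.ndarray:
        broad = _interval_multiplier(both_epochs, g)(t)
        burst = _bump_multiplier(licks + recipe.lick_offset_s, bg, bsd)(t)
        return broad + burst - 1.0

    add(recipe.n_lick, ValenceClass.LICK, PhaseClass.UNRELATED,
        lick_fn, b * (g + bg))

    def mv_fn(t: np.ndarray) -> np.ndarray:
        broad = _interval_multiplier(both_epochs, g)(t)
        bw = _bump_multiplier(water_licks + recipe.mv_offset_water_s, bg, bsd)(t)
        bq = _bump_multiplier(quinine_licks + recipe.mv_offset_quinine_s, bg, bsd)(t)
        return broad + bw + bq - 2.0

    add(recipe.n_mv, ValenceClass.MV, PhaseClass.UNRELATED, mv_fn, b * (g + bg))

    w_firsts = np.array(first_lo[Liquid.WATER])
    q_firsts = np.array(first_lo[Liquid.QUININE])
    pre_wins = [(f - 2.0, f) for f in w_firsts]
    post_wins = [(f, f + 2.0) for f in w_firsts]
    q_wins = [(f, f + 2.0) for f in q_firsts]
    w_around = [(f - 2.0, f + 2.0) for f in w_firsts]

    def phase_fn(pref: list[tuple[float, float]], anti: list[tuple[float, float]]):
        fp = _interval_multiplier(pref, g)
        fa = _interval_multiplier(anti, sup)
        return lambda t: fp(t) * fa(t)

    add(recipe.n_initial_pre, ValenceClass.UV, PhaseClass.INITIAL_PRE,
        phase_fn(pre_wins, q_wins), b * g)
    add(recipe.n_initial_post, ValenceClass.UV, PhaseClass.INITIAL_POST,
        phase_fn(post_wins, q_wins), b * g)
    add(recipe.n_terminal, ValenceClass.UV, PhaseClass.TERMINAL,
        phase_fn(q_wins, w_around), b * g)
    add(recipe.n_untuned, ValenceClass.UV, PhaseClass.UNRELATED, ones, b)

    regions = [Region.IC, Region.M1, Region.mPFC]
    units: list[Unit] = []
    valence_truth: dict[str, ValenceClass] = {}
    phase_truth: dict[str, PhaseClass] = {}
    spike_arrays: list[np.ndarray] = []
    for i, (val, ph, fn, peak) in enumerate(specs):
        rate_fn = lambda t, fn=fn: b * fn(t)
        if recipe.isi_model == "poisson":
            st = _inhomogeneous_poisson(rate_fn, max(peak, b) * 1.05, duration, rng)
        else:
            st = _gamma_renewal(rate_fn, recipe.gamma_shape, duration, rng)
        spike_arrays.append(st)
        uid = f"u{i:03d}"
        valence_truth[uid] = val
        phase_truth[uid] = ph

    # --- planted edges ---------------------------------------------------
    edges: list[tuple[str, str, float, float]] = []
    for src, dst, lag, strength in recipe.planted_edges:
        transferred = spike_arrays[src] + lag
        keep = rng.uniform(size=transferred.size) < strength
        merged = np.concatenate([spike_arrays[dst], transferred[keep]])
        spike_arrays[dst] = _dedupe(merged[(merged >= 0) & (merged < duration)])
        edges.append((f"u{src:03d}", f"u{dst:03d}", float(lag), float(strength)))

    for i, st in enumerate(spike_arrays):
        units.append(Unit(f"u{i:03d}", regions[i % 3], _dedupe(st)))

    # --- events ----------------------------------------------------------
    records: list[tuple[float, str, str]] = []
    for do, end, liq in epochs:
        records.append((do, EventKind.DO.value, liq.value))
        records.append((end, EventKind.DELIVERY_OFF.value, liq.value))
    for t in licks:
        records.append((float(t), EventKind.LO.value, Liquid.NONE.value))
    records.sort(key=lambda r: r[0])
    events = EventLog.from_records(records)

    # --- facial trace ----------------------------------------------------
    fps = recipe.facial_fps
    ft = np.arange(0.0, duration, 1.0 / fps)
    drive = np.zeros_like(ft)
    for do, end, _liq in epochs:
        rise = 1.0 - np.exp(-np.clip(ft - do, 0.0, None) / 0.5)
        decay = np.where(ft >= end, np.exp(-(ft - end) / 1.0), 1.0)
        drive = np.maximum(drive, np.where(ft >= do, rise * decay, 0.0))
    truth_trace = np.clip(0.1 + 0.6 * drive, 0.0, 1.0)
    observed = np.clip(
        truth_trace + rng.normal(0.0, recipe.facial_noise_sd, ft.size), 0.0, 1.0
    )

    truth = GeneratorTruth(valence_truth, phase_truth, edges, truth_trace)
    bundle = SessionBundle(
        spikes=SpikeTrainSet(units, duration),
        events=events,
        facial=FacialTrace(ft, observed),
        ground_truth=truth,
    )
    bundle.validate()
    return bundle
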