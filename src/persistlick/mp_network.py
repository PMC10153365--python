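"""Spiking-network model of prefrontal motor-projecting (MP) neurons and
the decision algorithm converting its output into lick rasters.

Network
-------
1000 excitatory and 800 inhibitory conductance-based Hodgkin-Huxley
neurons, sparsely connected (excitatory connection probability 0.05,
inhibitory 0.2).  The membrane equation is

    Cm dV/dt = gl(El - V) - gNa m^3 h (V - ENa) - gK n^4 (V - EK)
               + ge(Ee - V) + gi(Ei - V) + Iex(t)

with exponentially decaying synaptic conductances (tau_e = 5 ms,
tau_i = 10 ms).  Gating kinetics use the standard cortical
(Traub-Miles-type) rate functions; the remaining maximal conductances are
calibrated so that isolated neurons driven with 50-200 pA fire in the slow
(< ~10 Hz) regime expected of layer-5 MP neurons.  Synapses carry
short-term plasticity through the release-resource pair (u, x):
du/dt = -omega_f u, dx/dt = omega_d (1 - x), with a jump
u <- u + U(1 - u), release u x, x <- x - u x at each presynaptic spike
(facilitation rate 3.33 /s, depression recovery 2 /s, rest release
probability 0.6).

Integration is semi-implicit Euler for the membrane with
exponential-Euler gating updates from precomputed lookup tables,
dt = 0.05 ms by default.

Decision algorithm
------------------
One lick cycle is assumed to be carried by a rotational population
dynamic divided into nine phase groups.  With phi_g(t) the spike count of
group g in a 10 ms bin, the lick-triggering probability at time t is

    P(t) = 1  iff  prod_g phi_g(t - 280 ms) > 0
               and SD_g phi_g(t - 280 ms) < sd_threshold

and 0 otherwise.  A lick is emitted whenever P(t) = 1 and at least one
minimal inter-lick interval (125 ms, the ~8 Hz ceiling of observed
licking) has elapsed since the previous lick.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


class IntegrationError(RuntimeError):
    """The membrane integration diverged (names the offending step)."""


@dataclass
class NetworkConfig:
    n_exc: int = 1000
    n_inh: int = 800
    p_exc_connect: float = 0.05
    p_inh_connect: float = 0.2
    # membrane (mV, nS, pF, ms); leak/Na/K values are the package's
    # slow-spiking calibration, see docs/methods.md
    Cm: float = 200.0
    gl: float = 20.0
    El: float = -70.0
    gNa: float = 20000.0
    ENa: float = 50.0
    gK: float = 6000.0
    EK: float = -90.0
    VT: float = -63.0          # rate-function threshold shift
    Ee: float = 0.0
    Ei: float = -80.0
    tau_e: float = 5.0         # ms
    tau_i: float = 10.0        # ms
    w_exc: float = 8.0         # nS conductance increment per release unit
    w_inh: float = 10.0
    # initial conditions
    v_init: tuple[float, float] = (-65.0, -63.0)
    ge_init: tuple[float, float] = (0.0, 0.06)
    gi_init: tuple[float, float] = (0.0, 1.5)
    # short-term plasticity
    omega_f: float = 3.33      # /s facilitation decay
    omega_d: float = 2.0       # /s depression recovery
    u_rest: float = 0.6        # rest release probability
    # quenched heterogeneity of the input drive (uniform 1 +/- spread),
    # breaking the lockstep synchrony of identical neurons
    input_gain_spread: float = 0.5
    # inhibitory neurons receive the sensory drive at this fraction of the
    # excitatory amplitude, so feedback inhibition does not collapse when
    # the excitatory population is reduced
    input_inh_gain: float = 0.0
    # Ornstein-Uhlenbeck membrane noise current (pA), modelling background
    # synaptic bombardment; keeps the network in an asynchronous
    # fluctuation-driven regime instead of lockstep volleys
    noise_sigma_pA: float = 60.0
    noise_tau_ms: float = 5.0
    noise_dt_ms: float = 0.1   # OU update interval (>= dt; coarser is cheaper)
    dt_ms: float = 0.05
    spike_threshold: float = -20.0

    def __post_init__(self) -> None:
        for name in ("gl", "gNa", "gK", "w_exc", "w_inh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for p in (self.p_exc_connect, self.p_inh_connect, self.u_rest):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.dt_ms > 0.1:
            raise ValueError("dt must resolve HH dynamics (<= 0.1 ms)")

    @property
    def n_total(self) -> int:
        return self.n_exc + self.n_inh

    def digest(self) -> str:
        return hashlib.sha1(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class InputProgram:
    """Square-pulse current drive to the excitatory population."""

    amplitude_pA: float = 125.0
    delay: str = "fixed"              # "fixed" (50 ms) or "flexible" (1-200 ms)
    fixed_delay_s: float = 0.050
    duration_s: float = 6.0
    interruptions: tuple[float, ...] = ()   # starts, s after input onset
    interruption_duration_s: float = 0.2

    def __post_init__(self) -> None:
        if not 0 <= self.amplitude_pA <= 1000:
            raise ValueError("amplitude out of range")
        starts = sorted(self.interruptions)
        for a, b in zip(starts, starts[1:]):
            if b < a + self.interruption_duration_s:
                raise ValueError("interruption windows overlap")
        for s in starts:
            if s < 0 or s + self.interruption_duration_s > self.duration_s:
                raise ValueError("interruption outside the stimulation epoch")

    def delay_s(self, rng: np.random.Generator) -> float:
        if self.delay == "fixed":
            return self.fixed_delay_s
        return float(rng.uniform(0.001, 0.200))


# interruption start offsets (s after input onset) used by the published
# interruption experiments: both windows precede the nominal bout onset
INTERRUPTION_STARTS: dict[int, tuple[float, ...]] = {
    0: (),
    1: (1.0,),
    2: (1.0, 2.2),
}


@dataclass
class DecisionConfig:
    n_phases: int = 9
    lag_ms: float = 280.0
    sd_threshold: float = 30.0     # the printed rule is ambiguous (30 vs 300)
    bin_ms: float = 10.0
    min_ili_ms: float = 125.0      # 8 Hz lick ceiling
    assignment: str = "random"     # or "latency" (sorted first-spike latency)
    count_mode: str = "counts"     # or "binary"
    trigger: str = "refractory"    # or "transition" (lick only on 0->1)


@dataclass
class LickRaster:
    lick_times: np.ndarray
    seed: int
    config_digest: str = ""
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# gating-rate lookup tables (Traub-Miles-type kinetics)
# ---------------------------------------------------------------------------

_V_MIN, _V_MAX, _DV = -120.0, 60.0, 0.01


def _safe_exprel(x: np.ndarray) -> np.ndarray:
    # x / (exp(x) - 1), continuous at 0
    out = np.empty_like(x)
    small = np.abs(x) < 1e-9
    out[small] = 1.0
    out[~small] = x[~small] / np.expm1(x[~small])
    return out


def _rate_tables(cfg: NetworkConfig) -> tuple[np.ndarray, np.ndarray]:
    """(xinf, efac) tables for m, h, n on a uniform V grid.

    xinf = a/(a+b); efac = 1 - exp(-dt (a+b)) so that the exponential-Euler
    update is x += (xinf - x) * efac.
    """
    v = np.arange(_V_MIN, _V_MAX + _DV, _DV)
    vt = cfg.VT
    am = 0.32 * 4.0 * _safe_exprel((13.0 - v + vt) / 4.0)
    bm = 0.28 * 5.0 * _safe_exprel((v - vt - 40.0) / 5.0)
    ah = 0.128 * np.exp((17.0 - v + vt) / 18.0)
    bh = 4.0 / (1.0 + np.exp((40.0 - v + vt) / 5.0))
    an = 0.032 * 5.0 * _safe_exprel((15.0 - v + vt) / 5.0)
    bn = 0.5 * np.exp((10.0 - v + vt) / 40.0)
    xinf = np.empty((3, v.size))
    efac = np.empty((3, v.size))
    for i, (a, b) in enumerate(((am, bm), (ah, bh), (an, bn))):
        tot = a + b
        xinf[i] = a / tot
        efac[i] = 1.0 - np.exp(-cfg.dt_ms * tot)
    return xinf, efac


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _run_kernel(
    n_steps,
    dt,
    n_exc,
    V, m, h, n, ge, gi, u, x,
    xinf, efac,
    Cm, gl, El, gNa, ENa, gK, EK, Ee, Ei,
    efac_e, efac_i, ufac, xfac, u_rest,
    w_exc, w_inh,
    indptr, indices,
    iex_steps, input_gain,
    v_thresh,
    noise_sigma, noise_decay, noise_drive, noise_every,
    rng_seed,
    out_steps, out_ids, max_spikes,
):
    N = V.size
    dv_inv = 1.0 / _DV
    n_spk = 0
    np.random.seed(rng_seed)
    inoise = np.zeros(N)
    spiked = np.empty(N, dtype=np.int64)
    for step in range(n_steps):
        iex = iex_steps[step]
        n_now = 0
        update_noise = noise_sigma > 0.0 and step % noise_every == 0
        for i in range(N):
            v = V[i]
            if update_noise:
                inoise[i] = inoise[i] * noise_decay + noise_drive * np.random.normal()
            k = int((v - _V_MIN) * dv_inv)
            if k < 0:
                k = 0
            elif k >= xinf.shape[1]:
                k = xinf.shape[1] - 1
            m[i] += (xinf[0, k] - m[i]) * efac[0, k]
            h[i] += (xinf[1, k] - h[i]) * efac[1, k]
            n[i] += (xinf[2, k] - n[i]) * efac[2, k]
            gna = gNa * m[i] * m[i] * m[i] * h[i]
            gk = gK * n[i] * n[i] * n[i] * n[i]
            drive = iex * input_gain[i] + inoise[i]
            num = gl * El + gna * ENa + gk * EK + ge[i] * Ee + gi[i] * Ei + drive
            den = gl + gna + gk + ge[i] + gi[i]
            vnew = (v + dt / Cm * num) / (1.0 + dt / Cm * den)
            if vnew > 200.0 or vnew < -200.0 or vnew != vnew:
                return -(step + 1), n_spk
            if v < v_thresh and vnew >= v_thresh:
                spiked[n_now] = i
                n_now += 1
            V[i] = vnew
            ge[i] *= efac_e
            gi[i] *= efac_i
            u[i] *= ufac
            x[i] = 1.0 + (x[i] - 1.0) * xfac
        for s in range(n_now):
            j = spiked[s]
            if n_spk < max_spikes:
                out_steps[n_spk] = step
                out_ids[n_spk] = j
                n_spk += 1
            uj = u[j] + u_rest * (1.0 - u[j])
            rel = uj * x[j]
            x[j] -= rel
            u[j] = uj
            if j < n_exc:
                inc = w_exc * rel
                for t in range(indptr[j], indptr[j + 1]):
                    ge[indices[t]] += inc
            else:
                inc = w_inh * rel
                for t in range(indptr[j], indptr[j + 1]):
                    gi[indices[t]] += inc
    return n_spk, n_spk


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------


def build_connectivity(
    cfg: NetworkConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """CSR adjacency (indptr, indices): targets of each presynaptic neuron."""
    N = cfg.n_total
    indptr = np.zeros(N + 1, dtype=np.int64)
    chunks = []
    for j in range(N):
        p = cfg.p_exc_connect if j < cfg.n_exc else cfg.p_inh_connect
        mask = rng.random(N) < p
        mask[j] = False
        tgt = np.flatnonzero(mask)
        chunks.append(tgt)
        indptr[j + 1] = indptr[j] + tgt.size
    indices = (
        np.concatenate(chunks).astype(np.int64) if chunks else np.empty(0, np.int64)
    )
    return indptr, indices


def input_current_steps(
    inp: InputProgram,
    do_time_s: float,
    total_s: float,
    dt_ms: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Per-step drive (pA) and the realised input-onset time."""
    n_steps = int(round(total_s * 1000.0 / dt_ms))
    t = np.arange(n_steps) * dt_ms / 1000.0
    onset = do_time_s + inp.delay_s(rng)
    drive = np.where((t >= onset) & (t < onset + inp.duration_s),
                     inp.amplitude_pA, 0.0)
    for s in inp.interruptions:
        a, b = onset + s, onset + s + inp.interruption_duration_s
        drive[(t >= a) & (t < b)] = 0.0
    return drive, onset


@dataclass
class SimulationResult:
    spike_times: np.ndarray   # s
    neuron_ids: np.ndarray
    n_exc: int
    duration_s: float
    input_onset_s: float
    do_time_s: float
    seed: int


def simulate_network(
    cfg: NetworkConfig,
    inp: InputProgram,
    seed: int,
    do_time_s: float = 0.2,
    total_s: Optional[float] = None,
) -> SimulationResult:
    """Simulate the full network for one seed.

    Connectivity, initial conditions and (for flexible delays) the input
    onset are all drawn from ``seed``, so repeat runs are identical.
    """
    rng = np.random.default_rng(seed)
    if total_s is None:
        total_s = do_time_s + inp.fixed_delay_s + inp.duration_s + 0.1
    N = cfg.n_total
    indptr, indices = build_connectivity(cfg, rng)
    V = rng.uniform(*cfg.v_init, N)
    ge = rng.uniform(*cfg.ge_init, N)
    gi = rng.uniform(*cfg.gi_init, N)
    xinf, efac = _rate_tables(cfg)
    k0 = np.clip(((V - _V_MIN) / _DV).astype(int), 0, xinf.shape[1] - 1)
    m = xinf[0, k0].copy()
    h = xinf[1, k0].copy()
    n_gate = xinf[2, k0].copy()
    u = np.zeros(N)
    x = np.ones(N)
    drive, onset = input_current_steps(inp, do_time_s, total_s, cfg.dt_ms, rng)
    input_gain = np.empty(N)
    input_gain[: cfg.n_exc] = rng.uniform(
        1.0 - cfg.input_gain_spread, 1.0 + cfg.input_gain_spread, cfg.n_exc
    )
    input_gain[cfg.n_exc :] = cfg.input_inh_gain * rng.uniform(
        1.0 - cfg.input_gain_spread, 1.0 + cfg.input_gain_spread, cfg.n_inh
    )
    n_steps = drive.size
    max_spikes = int(N * total_s * 100) + 1000  # 100 Hz ceiling
    out_steps = np.empty(max_spikes, dtype=np.int64)
    out_ids = np.empty(max_spikes, dtype=np.int64)
    status, n_spk = _run_kernel(
        n_steps, cfg.dt_ms, cfg.n_exc,
        V, m, h, n_gate, ge, gi, u, x,
        xinf, efac,
        cfg.Cm, cfg.gl, cfg.El, cfg.gNa, cfg.ENa, cfg.gK, cfg.EK, cfg.Ee, cfg.Ei,
        float(np.exp(-cfg.dt_ms / cfg.tau_e)),
        float(np.exp(-cfg.dt_ms / cfg.tau_i)),
        float(np.exp(-cfg.dt_ms * cfg.omega_f / 1000.0)),
        float(np.exp(-cfg.dt_ms * cfg.omega_d / 1000.0)),
        cfg.u_rest, cfg.w_exc, cfg.w_inh,
        indptr, indices,
        drive, input_gain,
        cfg.spike_threshold,
        cfg.noise_sigma_pA,
        float(np.exp(-cfg.noise_dt_ms / cfg.noise_tau_ms)),
        float(cfg.noise_sigma_pA
              * np.sqrt(1.0 - np.exp(-2.0 * cfg.noise_dt_ms / cfg.noise_tau_ms))),
        max(1, int(round(cfg.noise_dt_ms / cfg.dt_ms))),
        int(rng.integers(2**31)),
        out_steps, out_ids, max_spikes,
    )
    if status < 0:
        raise IntegrationError(
            f"membrane potential diverged at step {-status - 1} "
            f"(t = {(-status - 1) * cfg.dt_ms:.3f} ms)"
        )
    times = out_steps[:n_spk] * cfg.dt_ms / 1000.0
    return SimulationResult(
        times, out_ids[:n_spk].copy(), cfg.n_exc, total_s, onset, do_time_s, seed
    )


# ---------------------------------------------------------------------------
# decision algorithm
# ---------------------------------------------------------------------------


def assign_phase_groups(
    sim: SimulationResult, cfg: DecisionConfig, seed: int
) -> np.ndarray:
    """Phase-group index (0..n_phases-1) for each excitatory neuron."""
    rng = np.random.default_rng(seed)
    n = sim.n_exc
    if cfg.assignment == "random":
        groups = np.arange(n) % cfg.n_phases
        rng.shuffle(groups)
        return groups
    if cfg.assignment == "latency":
        first = np.full(n, np.inf)
        exc = sim.neuron_ids < n
        for t, i in zip(sim.spike_times[exc], sim.neuron_ids[exc]):
            if t < first[i]:
                first[i] = t
        order = np.argsort(first, kind="stable")
        groups = np.empty(n, dtype=int)
        groups[order] = np.arange(n) * cfg.n_phases // n
        return groups
    raise ValueError(f"unknown assignment {cfg.assignment!r}")


def phase_counts(
    sim: SimulationResult, groups: np.ndarray, cfg: DecisionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """(bin_times, counts[n_bins, n_phases]) for the excitatory readout."""
    bin_s = cfg.bin_ms / 1000.0
    n_bins = int(np.ceil(sim.duration_s / bin_s))
    counts = np.zeros((n_bins, cfg.n_phases))
    exc = sim.neuron_ids < sim.n_exc
    b = np.minimum((sim.spike_times[exc] / bin_s).astype(int), n_bins - 1)
    g = groups[sim.neuron_ids[exc]]
    np.add.at(counts, (b, g), 1.0)
    if cfg.count_mode == "binary":
        counts = (counts > 0).astype(float)
    times = (np.arange(n_bins) + 1) * bin_s
    return times, counts


def decision_algorithm(
    sim: SimulationResult,
    cfg: DecisionConfig = DecisionConfig(),
    seed: int = 0,
    groups: Optional[np.ndarray] = None,
) -> LickRaster:
    """Convert network spikes into a lick raster via the nine-phase rule."""
    if groups is None:
        groups = assign_phase_groups(sim, cfg, seed)
    counts_per_group = np.bincount(groups, minlength=cfg.n_phases)
    if (counts_per_group == 0).any():
        raise ValueError("empty phase group: the product rule is trivially 0")
    times, counts = phase_counts(sim, groups, cfg)
    lag_bins = int(round(cfg.lag_ms / cfg.bin_ms))
    prod_pos = (counts > 0).all(axis=1)
    sd = counts.std(axis=1)
    p_now = prod_pos & (sd < cfg.sd_threshold)
    # P(t) consults the counts one lag earlier
    p = np.zeros(times.size, dtype=bool)
    p[lag_bins:] = p_now[: times.size - lag_bins]

    min_ili = cfg.min_ili_ms / 1000.0
    licks = []
    last = -np.inf
    prev = False
    for t, active in zip(times, p):
        fire = active and (not prev) if cfg.trigger == "transition" else active
        if fire and t - last >= min_ili:
            licks.append(t)
            last = t
        prev = active
    return LickRaster(np.asarray(licks), sim.seed, meta={"lag_bins": lag_bins})


def rotation_index(
    sim: SimulationResult,
    cfg: DecisionConfig = DecisionConfig(),
    groups: Optional[np.ndarray] = None,
    seed: int = 0,
    max_lag_ms: float = 100.0,
) -> float:
    """Sequential-activation index of the nine phase groups.

    Cross-correlates successive groups' mean-subtracted rate traces and
    averages the signed peak lag (normalised by the search half-width):
    positive means groups activate in phase order, negative in reverse.
    NaN (flagged) for a silent network.
    """
    if groups is None:
        groups = assign_phase_groups(sim, cfg, seed)
    if sim.duration_s < 1.0:
        raise ValueError("need at least 1 s of activity")
    _, counts = phase_counts(sim, groups, cfg)
    if counts.sum() == 0:
        return float("nan")
    max_lag = int(round(max_lag_ms / cfg.bin_ms))
    lags = []
    for g in range(cfg.n_phases):
        a = counts[:, g] - counts[:, g].mean()
        b = counts[:, (g + 1) % cfg.n_phases]
        b = b - b.mean()
        if a.std() == 0 or b.std() == 0:
            continue
        cc = np.correlate(b, a, mode="full")
        centre = b.size - 1
        window = cc[centre - max_lag : centre + max_lag + 1]
        lags.append((int(np.argmax(window)) - max_lag) / max_lag)
    return float(np.mean(lags)) if lags else float("nan")


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


def run_single(
    cfg: NetworkConfig,
    inp: InputProgram,
    dec: DecisionConfig,
    seed: int,
    do_time_s: float = 0.2,
) -> tuple[LickRaster, float]:
    """Simulate one seed and compute its initiation bias (stimulation onset
    treated as the delivery onset)."""
    from .behavior_metrics import SMAConfig, initiation_bias

    sim = simulate_network(cfg, inp, seed, do_time_s=do_time_s)
    raster = decision_algorithm(sim, dec, seed=seed)
    ib = initiation_bias(raster.lick_times, do_time_s, SMAConfig())
    raster.config_digest = cfg.digest()
    raster.meta["ibias"] = ib
    return raster, ib


def run_experiment(
    cfg: NetworkConfig,
    inp: InputProgram,
    dec: DecisionConfig,
    n_seeds: int,
    base_seed: int = 0,
    do_time_s: float = 0.2,
) -> dict:
    """Per-seed lick rasters and the initiation-bias distribution (in %)."""
    rasters, ibias = [], []
    for k in range(n_seeds):
        raster, ib = run_single(cfg, inp, dec, base_seed + k, do_time_s)
        rasters.append(raster)
        ibias.append(100.0 * ib)
    arr = np.asarray(ibias)
    return {
        "rasters": rasters,
        "ibias_percent": arr,
        "mean": float(arr.mean()),
        "sd": float(arr.std()),
        "sem": float(arr.std(ddof=1) / np.sqrt(max(len(arr) - 0, 1)))
        if len(arr) > 1
        else 0.0,
    }


def scaled_config(
    cfg: NetworkConfig, fraction: float, exc_only: bool = True
) -> NetworkConfig:
    """Network with neuron counts scaled by ``fraction`` (silencing model).

    By default only the excitatory population is reduced: the silenced
    motor-projecting neurons are the CaMKIIa-positive excitatory cells,
    while the local inhibitory pool is untouched.
    """
    d = asdict(cfg)
    d["n_exc"] = max(1, int(round(cfg.n_exc * fraction)))
    if not exc_only:
        d["n_inh"] = max(1, int(round(cfg.n_inh * fraction)))
    return NetworkConfig(**d)
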