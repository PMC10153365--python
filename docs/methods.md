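# Methods

`persistlick` re-implements, as a tested pipeline on synthetic data, the
computational stack used to study persistent licking: behavioral
persistence statistics, firing-rate estimation, single-unit
classification, spike-train connectivity, population decoding, and a
spiking-network model of prefrontal motor-projecting (MP) neurons whose
output is converted to lick rasters by a nine-phase decision rule.  This
note records the models, the conventions chosen where the procedures were
underdetermined, and what the synthetic studies do and do not establish.

## Behavioral persistence statistics

A persistent lick bout is summarised by 25 simple moving averages (SMA)
of lick counts in 200 ms bins after an anchoring event.  The k-th SMA is
the mean count over the five bins *starting* at bin k (forward-looking
windows).  The alternative trailing-window convention was rejected
because it makes an immediately-at-threshold bout unattainable (a bout at
7 Hz from the anchor would never reach `ibias = 1`) and breaks the stated
terminal-rule limits; with forward windows a bout that reaches 6 Hz in its
first second scores exactly 1.  SMA values are computed as integer bin
counts divided by the window length, so threshold comparisons are exact
(licking at exactly 6.0 Hz does *not* exceed the 1.2 licks/bin initiation
threshold).

* initiation bias: `1/idx`, `idx` the 1-based index of the first SMA
  above 1.2 licks/bin (6 Hz), counted from just after the last zero-valued
  SMA before that crossing — the "restart" reading of the zero-skip rule,
  which makes the statistic measure the latency of the final sustained
  bout onset.  The alternative "ignore zeros entirely" reading is
  config-selectable (`SMAConfig.zero_rule`).
* termination bias: `1/idx` for the first SMA below 1.0 licks/bin (5 Hz)
  after the terminating anchor; 0 if licking never drops below 5 Hz.

Facial activity is `1 − r` with `r` the Pearson correlation between HOG
descriptors (8 orientations, 32 px cells, one cell per block) of
temporally adjacent frames of a fixed crop.  Flat descriptors (identical
blank frames) have no defined correlation and are scored 0 with a
warning, since identical frames mean no motion.  Wheel speed per encoder
pulse is `circumference / (CPR · Δt)` with CPR = 360.

## Firing-rate estimation (BAKS)

Rates are estimated with the Bayesian adaptive kernel smoother: Gaussian
kernels at each spike whose bandwidth h(t) follows the closed-form
gamma-prior expression with shape α = 4 and β = n_spikes^(4/5).  The
"bandwidth of 5 ms / 200 ms" attached to the small and large analysis
windows is interpreted as the *output sampling interval* of the rate
grid; an optional hard cap on h(t) (`BAKSConfig.h_max`) implements the
alternative reading and is used by the classifier's firing-peak test
(below).  Numerical notes:

* Windowed estimates include spikes well beyond the window (0.5 s of
  margin, comparable to the bandwidths that arise on sparse windows) so
  the estimate has no systematic dip at the window borders; with narrower
  support the dip fakes temporal structure and the time-bias test fires
  on every unit.
* The estimator conserves mass (`∫rate ≈ n`) up to an O(1) positive edge
  excess (~1.7 spikes independent of n) plus slowly decaying tails where
  h(t) grows away from the data.  The 2 % integral check therefore holds
  for trains of ≳250 spikes over a modest (±0.2 s) integration margin and
  degrades for sparser trains.
* Empty trains yield zero traces flagged `empty` rather than errors so
  population matrices keep fixed shape.

## Single-unit classification

Valence (small window, −100…+80 ms around each lick onset): per-lick rate
matrices at 5 ms sampling are reduced to Euclidean norms of adjacent
samples, pooled over licks and bins, and compared with the effect-size
statistic `Z12 = (μ1−μ2)/√(σ1²+σ2²)`, significant at |Z| > 1.29.
Pseudo-trials replicate the real inter-lick intervals inside the lick-free
baseline; their rate matrix is flattened, permuted and averaged over 1000
shuffles.  The rule table (LICK / PV / NV / MV, fallback UV) follows the
class definitions: "quinine ≤ pseudo" is read as *not significantly
greater* (z ≤ 1.29), consistent with the significance convention.  The
firing-peak comparison (two-sample t-test on per-lick argmax times,
p < 0.05, ties to the earliest bin) uses a narrow-bandwidth estimate
(h capped at 10 ms): phasic latency structure is invisible at the
adaptive bandwidth, which on 180 ms windows smooths to several hundred
milliseconds.  Time bias (temporal structure across the window) and trial
bias (drift across 8-trial groups) are permutation tests on the Frobenius
norm of column-/row-mean deviations, 1000 shuffles, 95th percentile; both
run on the narrow-bandwidth (capped) estimate, where fine structure is
resolvable and the permutation null is calibrated, and the trial-bias
rows use alternating licks only, because consecutive 180 ms windows
overlap by ~40 ms at a 7 Hz lick rate and overlapping rows would break
the exchangeability null.

Phase (large window): full-session rates at 200 ms sampling are evaluated
at five equally spaced time points across 2 s windows anchored on the
session's first water and first quinine lick, against the 65th/35th
percentiles of a pseudo distribution sampled at 1000 random times from
the ≥70 s recording.  A percentile condition holds when a majority (≥3/5)
of time points satisfies it; the strict "all five" variant is
config-selectable but brittle at 200 ms sampling.  The terminal rule's
4 s anti-window around the first water lick is implemented as stated even
though it is wider than the other windows.  Pseudo draws are snapped to
the rate grid so real and pseudo evaluations share one marginal
distribution.  When both initial windows qualify (smoothing leakage), the
window with the larger mean rate wins.

Opto-tagging is a SALT-style occupancy test, not SALT-exact: the response
probability in the 0–5 ms (laser) or 6–10 ms (network) post-pulse window
is compared against ≥200 surrogate pulse trains shifted uniformly into
the pre-laser baseline (empirical p < 0.05), combined with a
mean-waveform correlation > 0.85.

Nominal false-positive rates used by the null-calibration tests: 5 % for
each permutation test, ~10 % for the one-sided z > 1.29 convention, and
~15 % for the compound phase rule (binomial majority-of-five with 35 %
per-point probability, two initial variants sharing the quinine
condition plus the terminal rule).

## Connectivity (TSPE)

The src→dst weight is the maximum, over strictly positive delays up to
50 ms, of an edge-filtered spiking-probability correlogram: 1 ms bins,
normalised by source spike count, passed through a centre-minus-flanks
filter bank at widths 1–3 bins and summed.  Restricting to positive
delays makes detection directional — a reverse-causal pair scores
nothing.  Significance compares the weight against 200 surrogates with
the target's spike times redrawn uniformly within the 3 s crop
(per-segment for recombined lick windows); the percentile is set by the
representation size N (<10 not evaluated; 10–14: 80th; 15–19: 90th;
20–32: 95th; >32: 99th).  Lick-window recombination concatenates the
per-lick 180 ms windows with segment ids, and correlogram accumulation is
masked to same-segment pairs so joins cannot create artifactual edges.
The 70th percentile listed in the original rule is never selected by the
N-ranges and is not reachable by default.

## Population decoding and facial prediction

Decoding: per-unit max normalisation over the pooled water+quinine
windows, PCA fitted on the training split only (avoiding leakage),
keeping the leading components that explain ≥85 % of variance, then a
linear-kernel SVM — wrapped in error-correcting output codes for ≥3
classes, a single binary SVM for two (where ECOC degenerates).  Accuracy
is averaged over 10 stratified 50/50 splits; the chance band is the
2.5–97.5 percentile range over 50 pseudo datasets built from randomly
drawn anchor times (or label permutations when only rate tensors are
available).  Trajectory separation embeds per-condition trial-mean
population trajectories in a common PCA space and reports the mean
point-by-point Euclidean distance plus per-PC variance shares.

The facial-activity predictor is a Hammerstein model: a static
polynomial input nonlinearity (degree 2–5) feeding a rational linear
transfer function with nb−1 ∈ {0,1,2} zeros and nf ∈ {1,2,3} poles
(nf ≥ nb for realizability), fitted by linear least squares in ARX form
on trials 1–2 and evaluated by free-run simulation on trials 3–4.
Accuracy is the normalised-RMSE fit percentage
`100·(1 − ‖y−ŷ‖/‖y−ȳ‖)` — the standard system-identification fit metric;
a unit is counted predictive above 30 %.  Unstable fitted poles reject a
grid candidate; among candidates tying within 0.1 fit-points on the
training free-run, the least complex (degree, poles, zeros) wins, which
is what makes noise-free degree recovery well-posed despite nesting.

## Synthetic sessions

The generator emulates the head-fixed task: a 12 s lick-free baseline,
four 10 s water deliveries then four 10 s quinine deliveries (20 s
inter-trial intervals), sustained ~7 Hz lick bouts starting ≤3 s after
water onset and terminating ~2.5 s into quinine delivery, and a facial
trace that rises after delivery onset.  Units are inhomogeneous Poisson
(or gamma-renewal) processes at 8 Hz baseline with class-specific
multiplicative profiles:

* PV / NV — ×3 during water / quinine delivery epochs;
* LICK — ×3 during all delivery epochs plus a sharp burst (×10, σ = 12 ms)
  at +10 ms after every lick;
* MV — the same two components with burst latencies −20 ms (water) and
  +20 ms (quinine), so only the firing peak distinguishes MV from LICK;
  the ±20 ms offsets avoid aliasing of a burst through the neighbouring
  lick (inter-lick interval ≈143 ms) into the analysis-window edges;
* phase classes — ×3 in their preferred 2 s window (before/after the
  first water lick, or after the first quinine lick) and ×0.3 in the
  opposing window, because the phase rules test a contrast, not mere
  elevation;
* untuned — flat baseline.

Planted connectivity is realised by spike transfer at a fixed lag with
the edge's transfer probability.  Facial frames are synthetic textures
whose grating orientation advances in proportion to the commanded
activity, so HOG turnover is monotone in activity without any video
data.  What passing recovery tests show is that the generator/classifier
pair is self-consistent at these effect sizes; they do not show that the
thresholds are optimal for real recordings, where waveform
non-stationarity, bursting, correlated noise and behavioral variability
are all absent from the generator.

## MP network model

Conductance-based Hodgkin-Huxley network, 1000 excitatory and 800
inhibitory neurons, connection probabilities 0.05 (E) and 0.2 (I),
synaptic reversal/decay Ee = 0 mV, Ei = −80 mV, τe = 5 ms, τi = 10 ms,
release governed by the facilitation/depression pair (u, x) with
du/dt = −ω_f·u, dx/dt = ω_d(1−x), ω_f = 3.33 /s, ω_d = 2 /s, rest release
probability 0.6, and the event rules u ← u + U(1−u), release u·x,
x ← x − u·x at each presynaptic spike.  Membrane potentials start in
[−65, −63] mV, conductances in [0, 0.06] nS (e) and [0, 1.5] nS (i).
Gating kinetics are the standard cortical Traub-Miles-type rate functions
with VT = −63 mV; the remaining parameters are the package's calibration
of the unstated constants: Cm = 200 pF, gNa = 20 µS, gK = 6 µS, and leak
(gl, El) set so that the median single-neuron rate under a mid-range
(125 pA) drive stays in the slow (≤10 Hz) regime of layer-5 MP neurons.
Two forms of biological variability keep the network out of the lockstep
synchrony that identical deterministic neurons fall into: a quenched
per-neuron input gain (uniform ±50 %) and a seeded Ornstein-Uhlenbeck
background current (σ = 60 pA, τ = 5 ms, updated every 0.1 ms)
representing synaptic bombardment from outside the modelled circuit.

Integration is semi-implicit Euler for the membrane with
exponential-Euler gating updates from lookup tables at 0.01 mV
resolution, dt = 0.05 ms; refining dt tenfold changes an isolated
neuron's 5 s spike count by ≤1.  Divergence (|V| > 200 mV) raises an
error naming the step.

The decision algorithm divides the lick cycle into nine phase groups
(excitatory neurons partitioned uniformly at random by default; a
first-spike-latency assignment is selectable).  With φ_g the group spike
count in a 10 ms bin, P(t) = 1 iff all nine lagged (280 ms) counts are
positive and their standard deviation is below 30 — the stricter of the
two inconsistently printed bounds (30 vs 300); both are reachable through
`DecisionConfig.sd_threshold`.  A lick is emitted whenever P(t) = 1 and
at least 125 ms (the ~8 Hz lick ceiling) has elapsed since the previous
lick; a transition-only trigger variant is selectable.  Counts (not
binary indicators) are used for φ, with the binary variant as a toggle.

Model experiments treat the stimulation onset as the delivery onset for
the SMA procedure.  The input is a square 125 pA pulse (mid-range of the
50–200 pA band) with a fixed 50 ms delay and 6 s duration; interruption
experiments zero the drive for 200 ms starting 1.0 s (single) or 1.0 s
and 2.2 s (double) after input onset — both windows precede the nominal
bias crossing, which is what lets a later interruption compound the
delay.  The silencing sweep reduces the excitatory population only
(silenced motor-projecting cells are the CaMKIIa-positive excitatory
neurons) at sizes 100 %, 40 % and 30 %; because the nine-group product
requires every group to stay active, the lick drive degrades as the
per-group count (∝ N_exc) approaches 1 per bin.

Problem sizes for the shipped studies: 20 seeds per condition, 6 s of
stimulation per run, full default network; recovery and calibration
studies use 50 synthetic sessions with the default recipe.

## Known limitations

* The behavioral statistics depend on the forward-window SMA convention;
  the trailing reading would shift absolute ibias values.
* BAKS mass conservation is O(1)-biased at data edges (see above).
* The peak-time test requires the capped-bandwidth estimate; with the
  uncapped adaptive bandwidth MV and LICK units are indistinguishable.
* The network model's absolute bias percentages depend on the calibrated
  leak/weight constants; only orderings and relative changes are robust
  model predictions.
* The generator's effect sizes are stylised; recovery rates quantify
  pipeline self-consistency, not expected performance on recordings.
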