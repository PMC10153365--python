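"""MP network model: input programs, decision algorithm on constructed
spike data, rotation index, and single-cell/integration properties."""

import numpy as np
import pytest

from persistlick.mp_network import (
    DecisionConfig,
    InputProgram,
    IntegrationError,
    NetworkConfig,
    SimulationResult,
    assign_phase_groups,
    decision_algorithm,
    input_current_steps,
    rotation_index,
    scaled_config,
    simulate_network,
)


def make_sim(times, ids, n_exc=90, duration=3.0):
    return SimulationResult(
        np.asarray(times, float), np.asarray(ids, int), n_exc, duration, 0.25, 0.2, 0
    )


def tiled_groups(n_exc, n_phases=9):
    # neuron i belongs to group i % 9
    return np.arange(n_exc) % n_phases


class TestInputProgram:
    def test_square_pulse_and_delay(self):
        inp = InputProgram(amplitude_pA=100.0, duration_s=1.0)
        rng = np.random.default_rng(0)
        drive, onset = input_current_steps(inp, 0.2, 1.5, 0.1, rng)
        t = np.arange(drive.size) * 1e-4
        assert onset == pytest.approx(0.25)
        assert drive[t < 0.25].max() == 0.0
        assert drive[(t >= 0.26) & (t < 1.2)].min() == 100.0
        assert drive[t >= 1.26].max() == 0.0

    def test_interruptions_zero_the_drive(self):
        inp = InputProgram(amplitude_pA=100.0, duration_s=2.0,
                           interruptions=(0.5, 1.2))
        rng = np.random.default_rng(0)
        drive, onset = input_current_steps(inp, 0.0, 2.2, 0.1, rng)
        t = np.arange(drive.size) * 1e-4
        for s in (0.5, 1.2):
            win = (t >= onset + s) & (t < onset + s + 0.2)
            assert drive[win].max() == 0.0

    def test_overlapping_interruptions_rejected(self):
        with pytest.raises(ValueError):
            InputProgram(interruptions=(0.5, 0.6))

    def test_interruption_outside_epoch_rejected(self):
        with pytest.raises(ValueError):
            InputProgram(duration_s=1.0, interruptions=(0.95,))

    def test_flexible_delay_range(self):
        inp = InputProgram(delay="flexible")
        rng = np.random.default_rng(5)
        delays = [inp.delay_s(rng) for _ in range(50)]
        assert min(delays) >= 0.001 and max(delays) <= 0.2
        assert np.std(delays) > 0


class TestDecisionAlgorithm:
    CFG = DecisionConfig()

    def _uniform_spikes(self, rate_per_group, duration=3.0, n_exc=90, seed=0):
        """Each of 9 groups spikes `rate_per_group` times per 10 ms bin."""
        rng = np.random.default_rng(seed)
        times, ids = [], []
        for b in range(int(duration / 0.01)):
            for g in range(9):
                for k in range(rate_per_group):
                    times.append(b * 0.01 + rng.uniform(0, 0.01))
                    ids.append(g)  # neuron g is in group g under tiled assignment
        order = np.argsort(times)
        return np.array(times)[order], np.array(ids)[order]

    def test_all_groups_active_produces_licks_at_ili_floor(self):
        times, ids = self._uniform_spikes(2)
        sim = make_sim(times, ids)
        raster = decision_algorithm(sim, self.CFG, groups=tiled_groups(90))
        assert raster.lick_times.size > 0
        ili = np.diff(raster.lick_times)
        assert np.all(ili >= 0.125 - 1e-9)
        assert np.median(ili) == pytest.approx(0.13, abs=0.01)

    def test_silent_group_blocks_licks(self):
        times, ids = self._uniform_spikes(2)
        keep = ids != 4  # silence group 4 entirely
        sim = make_sim(times[keep], ids[keep])
        raster = decision_algorithm(sim, self.CFG, groups=tiled_groups(90))
        assert raster.lick_times.size == 0

    def test_high_count_dispersion_blocks_licks(self):
        times, ids = self._uniform_spikes(2)
        # inflate group 0 counts so the across-group SD exceeds threshold
        extra_t = np.repeat(np.arange(0, 3.0, 0.01), 120) + 0.005
        extra_i = np.zeros(extra_t.size, dtype=int)
        t = np.concatenate([times, extra_t])
        i = np.concatenate([ids, extra_i])
        order = np.argsort(t)
        sim = make_sim(t[order], i[order])
        raster = decision_algorithm(sim, self.CFG, groups=tiled_groups(90))
        assert raster.lick_times.size == 0

    def test_empty_phase_group_is_an_error(self):
        times, ids = self._uniform_spikes(1)
        sim = make_sim(times, ids)
        bad_groups = np.zeros(90, dtype=int)  # everyone in group 0
        with pytest.raises(ValueError):
            decision_algorithm(sim, self.CFG, groups=bad_groups)

    def test_lag_shifts_first_lick(self):
        times, ids = self._uniform_spikes(2)
        start = times + 1.0
        sim = make_sim(start, ids, duration=4.5)
        raster = decision_algorithm(sim, self.CFG, groups=tiled_groups(90))
        # spikes begin at 1.0; counts are consulted 280 ms later
        assert raster.lick_times[0] == pytest.approx(1.0 + 0.28, abs=0.02)

    def test_transition_trigger_fires_once_per_episode(self):
        times, ids = self._uniform_spikes(2)
        sim = make_sim(times, ids)
        cfg = DecisionConfig(trigger="transition")
        raster = decision_algorithm(sim, cfg, groups=tiled_groups(90))
        assert raster.lick_times.size <= 2  # single sustained P=1 episode


class TestRotationIndex:
    def _sequential(self, order, n_cycles=20, cycle=0.45):
        times, ids = [], []
        for c in range(n_cycles):
            for slot, g in enumerate(order):
                burst = c * cycle + slot * 0.05 + np.linspace(0, 0.01, 5)
                times.extend(burst)
                ids.extend([g] * 5)
        idx = np.argsort(times)
        return make_sim(np.array(times)[idx], np.array(ids)[idx], n_exc=9,
                        duration=n_cycles * cycle)

    GROUPS = np.arange(9)

    def test_sequential_bursts_positive(self):
        sim = self._sequential(list(range(9)))
        assert rotation_index(sim, DecisionConfig(), groups=self.GROUPS) > 0.1

    def test_reversed_sequence_negative(self):
        sim = self._sequential(list(range(9))[::-1])
        assert rotation_index(sim, DecisionConfig(), groups=self.GROUPS) < -0.1

    def test_shuffled_near_zero(self, rng):
        vals = []
        for k in range(8):
            order = rng.permutation(9)
            sim = self._sequential(list(order))
            vals.append(rotation_index(sim, DecisionConfig(), groups=self.GROUPS))
        assert abs(np.mean(vals)) < 0.2

    def test_silent_network_nan(self):
        sim = make_sim([], [], n_exc=9, duration=3.0)
        assert np.isnan(rotation_index(sim, DecisionConfig(), groups=self.GROUPS))

    def test_short_recording_rejected(self):
        sim = make_sim([0.1], [0], n_exc=9, duration=0.5)
        with pytest.raises(ValueError):
            rotation_index(sim, DecisionConfig(), groups=self.GROUPS)


class TestPhaseAssignment:
    def test_random_partition_is_balanced(self):
        sim = make_sim([], [], n_exc=900)
        groups = assign_phase_groups(sim, DecisionConfig(), seed=0)
        counts = np.bincount(groups, minlength=9)
        assert counts.min() == counts.max() == 100

    def test_latency_assignment_orders_by_first_spike(self):
        times = np.array([0.5, 0.1, 0.9])
        ids = np.array([0, 1, 2])
        sim = make_sim(times, ids, n_exc=3)
        cfg = DecisionConfig(n_phases=3, assignment="latency")
        groups = assign_phase_groups(sim, cfg, seed=0)
        assert groups[1] <= groups[0] <= groups[2]


class TestSingleNeuron:
    def _iso(self, **kw):
        return NetworkConfig(n_exc=1, n_inh=0, p_exc_connect=0.0,
                             p_inh_connect=0.0, ge_init=(0.0, 0.0),
                             gi_init=(0.0, 0.0), input_gain_spread=0.0,
                             noise_sigma_pA=0.0, **kw)

    def test_zero_input_silence(self):
        sim = simulate_network(self._iso(), InputProgram(amplitude_pA=0.0),
                               seed=0, total_s=1.0)
        assert np.sum(sim.spike_times > 0.2) == 0

    def test_suprathreshold_regular_spiking(self):
        sim = simulate_network(self._iso(), InputProgram(amplitude_pA=400.0,
                                                         duration_s=4.0),
                               seed=0, total_s=4.3)
        isi = np.diff(sim.spike_times[sim.spike_times > 1.0])
        assert isi.size > 5
        assert isi.std() / isi.mean() < 0.02  # regular after the transient

    def test_dt_refinement_changes_count_by_at_most_one(self):
        counts = []
        for dt in (0.05, 0.005):
            sim = simulate_network(self._iso(dt_ms=dt),
                                   InputProgram(amplitude_pA=400.0,
                                                duration_s=5.0),
                                   seed=1, total_s=5.3)
            counts.append(sim.spike_times.size)
        assert abs(counts[0] - counts[1]) <= 1

    def test_divergence_raises_named_step(self):
        # a pathological Na reversal drives the upstroke past the guard
        cfg = self._iso(ENa=500.0)
        with pytest.raises(IntegrationError, match="step"):
            simulate_network(cfg, InputProgram(amplitude_pA=1000.0),
                             seed=0, total_s=0.5)


class TestScaledConfig:
    def test_exc_only_default(self):
        cfg = NetworkConfig()
        small = scaled_config(cfg, 0.5)
        assert small.n_exc == 500 and small.n_inh == cfg.n_inh

    def test_both_populations_option(self):
        small = scaled_config(NetworkConfig(), 0.5, exc_only=False)
        assert small.n_exc == 500 and small.n_inh == 400
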