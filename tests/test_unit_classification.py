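"""Unit classification: z statistic, bias permutation tests, rule tables,
opto-tagging, association test."""

import numpy as np
import pytest

import persistlick as pl
from persistlick.core_io import AnalysisWindow, PhaseClass, ValenceClass
from persistlick.rate_estimation import BAKSConfig
from persistlick.unit_classification import (
    ClassificationConfig,
    UnitLabel,
    association_test,
    adjacent_norm_series,
    classify_phase,
    classify_valence,
    identify_optotagged,
    make_pseudo_trials,
    time_bias_test,
    trial_bias_test,
    z_compare,
)


class TestAdjacentNorms:
    def test_constant_trace(self):
        out = adjacent_norm_series(np.full(10, 3.0))
        assert np.allclose(out, 3.0 * np.sqrt(2))

    def test_zero_trace(self):
        assert np.all(adjacent_norm_series(np.zeros(5)) == 0)

    def test_ramp_hand_computed(self):
        out = adjacent_norm_series(np.array([0.0, 1.0, 2.0]))
        assert np.allclose(out, [1.0, np.sqrt(5.0)])

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            adjacent_norm_series(np.array([1.0]))


class TestZCompare:
    def test_identical_distributions_zero(self, rng):
        a = rng.normal(size=500)
        assert z_compare(a, a.copy()) == 0.0

    def test_direct_formula(self, rng):
        a = rng.normal(2.0, 1.0, 200_000)
        b = rng.normal(0.0, 1.0, 200_000)
        assert z_compare(a, b) == pytest.approx(2.0 / np.sqrt(2.0), abs=0.02)

    def test_sign_flips_on_swap(self, rng):
        a, b = rng.normal(1, 1, 100), rng.normal(0, 1, 100)
        assert z_compare(a, b) == pytest.approx(-z_compare(b, a))

    def test_degenerate_flagged(self):
        assert z_compare([1.0, 1.0], [1.0, 1.0]) == 0.0
        assert z_compare([2.0, 2.0], [1.0, 1.0]) == np.inf


class TestBiasTests:
    def test_column_constant_matrix_not_biased(self, rng):
        m = np.tile(rng.normal(size=(20, 1)), (1, 10))  # rows vary, columns flat
        norm, biased = time_bias_test(np.ascontiguousarray(m.T).T * 0 + 5.0, 200, 1)
        assert norm == pytest.approx(0.0)
        assert not biased

    def test_single_hot_column_biased(self, rng):
        m = rng.normal(0, 0.1, size=(30, 12))
        m[:, 4] += 5.0
        _, biased = time_bias_test(m, 200, 0)
        assert biased

    def test_iid_noise_calibrated(self, rng):
        hits = 0
        for k in range(200):
            m = rng.normal(size=(12, 10))
            _, b = time_bias_test(m, 200, k)
            hits += b
        assert hits / 200 < 0.12  # ~5% nominal, 2x slack

    def test_single_bin_matrix_errors(self):
        with pytest.raises(ValueError):
            time_bias_test(np.ones((5, 1)))

    def test_trial_drift_biased(self, rng):
        m = rng.normal(size=(32, 10)) + np.linspace(0, 3, 32)[:, None]
        _, biased = trial_bias_test(m, 8, 200, 0)
        assert biased

    def test_trial_exchangeable_calibrated(self, rng):
        hits = sum(
            trial_bias_test(rng.normal(size=(32, 10)), 8, 200, k)[1]
            for k in range(200)
        )
        assert hits / 200 < 0.12

    def test_constant_matrix_norm_zero(self):
        norm, biased = trial_bias_test(np.full((16, 5), 2.0), 8, 100, 0)
        assert norm == 0.0 and not biased

    def test_too_few_trials_error(self):
        with pytest.raises(ValueError):
            trial_bias_test(np.ones((10, 5)), 8, 100, 0)


class TestPseudoTrials:
    WIN = AnalysisWindow.small()
    CFG = BAKSConfig(output_dt=0.005)

    def test_no_spikes_zero_matrix(self):
        licks = np.arange(20.0, 25.0, 1 / 7)
        m = make_pseudo_trials(np.empty(0), licks, (0.0, 12.0), self.WIN,
                               self.CFG, 100, 0)
        assert np.all(m == 0)

    def test_homogeneous_baseline_flat_near_rate(self, rng):
        st = np.sort(rng.uniform(0, 12, 120))  # 10 Hz baseline
        licks = np.arange(20.0, 30.0, 1 / 7)
        m = make_pseudo_trials(st, licks, (0.0, 12.0), self.WIN, self.CFG, 500, 1)
        assert m.std() < 0.1 * m.mean()  # near-constant after shuffle-averaging
        assert m.mean() == pytest.approx(10.0, rel=0.35)

    def test_seed_sensitivity_and_convergence(self, rng):
        st = np.sort(rng.uniform(0, 12, 120))
        licks = np.arange(20.0, 28.0, 1 / 7)
        m1 = make_pseudo_trials(st, licks, (0.0, 12.0), self.WIN, self.CFG, 50, 1)
        m2 = make_pseudo_trials(st, licks, (0.0, 12.0), self.WIN, self.CFG, 50, 2)
        assert not np.allclose(m1, m2)
        assert abs(m1.mean() - m2.mean()) < 0.05 * m1.mean() + 1e-9

    def test_short_baseline_rejected(self):
        with pytest.raises(ValueError):
            make_pseudo_trials(np.arange(5), np.arange(3.0), (0.0, 5.0),
                               self.WIN, self.CFG)


def _mat(mean, shape, rng, structure=None):
    m = rng.normal(mean, mean * 0.15, size=shape).clip(min=0.0)
    if structure is not None:
        m += structure
    return m


class TestValenceRules:
    CFG = ClassificationConfig(n_shuffles=200)

    def test_pv_rule(self, rng):
        water = _mat(30.0, (40, 37), rng)
        quinine = _mat(10.0, (40, 37), rng)
        pseudo = np.full((40, 37), 10.0)
        cls, diag = classify_valence(water, quinine, pseudo, self.CFG, 0)
        assert cls == ValenceClass.PV

    def test_nv_rule(self, rng):
        water = _mat(10.0, (40, 37), rng)
        quinine = _mat(30.0, (40, 37), rng)
        pseudo = np.full((40, 37), 10.0)
        cls, _ = classify_valence(water, quinine, pseudo, self.CFG, 0)
        assert cls == ValenceClass.NV

    def test_all_equal_uv(self, rng):
        water = _mat(10.0, (40, 37), rng)
        quinine = _mat(10.0, (40, 37), rng)
        pseudo = np.full((40, 37), 10.0)
        cls, _ = classify_valence(water, quinine, pseudo, self.CFG, 0)
        assert cls == ValenceClass.UV

    def test_mv_rule_peaked_and_biased(self, rng):
        bins = np.arange(37)
        bump_w = 25 * np.exp(-((bins - 10) ** 2) / 18.0)
        bump_q = 25 * np.exp(-((bins - 28) ** 2) / 18.0)
        water = _mat(12.0, (40, 37), rng, bump_w)
        quinine = _mat(12.0, (40, 37), rng, bump_q)
        pseudo = np.full((40, 37), 6.0)
        cls, diag = classify_valence(water, quinine, pseudo, self.CFG, 0)
        assert cls == ValenceClass.MV

    def test_lick_rule_same_peak(self, rng):
        bins = np.arange(37)
        bump = 25 * np.exp(-((bins - 18) ** 2) / 18.0)
        water = _mat(12.0, (40, 37), rng, bump)
        quinine = _mat(12.0, (40, 37), rng, bump)
        pseudo = np.full((40, 37), 6.0)
        cls, _ = classify_valence(water, quinine, pseudo, self.CFG, 0)
        assert cls == ValenceClass.LICK

    def test_exhaustiveness_fuzz(self, rng):
        # arbitrary garbage still yields exactly one label
        for k in range(25):
            shape = (int(rng.integers(8, 30)), 37)
            water = rng.gamma(2.0, 5.0, size=shape)
            quinine = rng.gamma(2.0, 5.0, size=(shape[0] // 2 + 2, 37))
            pseudo = rng.gamma(2.0, 5.0, size=shape)
            cls, _ = classify_valence(water, quinine, pseudo, self.CFG, k)
            assert isinstance(cls, ValenceClass)


class TestPhaseRules:
    def _trace(self, duration=200.0):
        grid = np.arange(0.0, duration, 0.2)
        return grid

    def test_silent_unit_unrelated(self):
        cls, _ = classify_phase(np.empty(0), 50.0, 150.0,
                                session_duration=200.0,
                                rate_trace=(self._trace(), np.zeros(1000)))
        assert cls == PhaseClass.UNRELATED

    def test_missing_anchor_flagged_unrelated(self):
        cls, diag = classify_phase(np.arange(100.0), None, 150.0,
                                   session_duration=200.0)
        assert cls == PhaseClass.UNRELATED
        assert "flag" in diag

    def test_initial_pre_construction(self):
        grid = self._trace()
        rate = np.full(1000, 8.0)
        w, q = 50.0, 150.0
        rate[(grid >= w - 2) & (grid < w)] = 25.0     # pre-window elevated
        rate[(grid >= q) & (grid < q + 2)] = 1.0      # quinine suppressed
        cls, _ = classify_phase(np.arange(100.0), w, q,
                                session_duration=200.0, rate_trace=(grid, rate))
        assert cls == PhaseClass.INITIAL_PRE

    def test_terminal_construction(self):
        grid = self._trace()
        rate = np.full(1000, 8.0)
        w, q = 50.0, 150.0
        rate[(grid >= q) & (grid < q + 2)] = 25.0
        rate[(grid >= w - 2) & (grid < w + 2)] = 1.0
        cls, _ = classify_phase(np.arange(100.0), w, q,
                                session_duration=200.0, rate_trace=(grid, rate))
        assert cls == PhaseClass.TERMINAL

    def test_flat_unit_mostly_unrelated(self, rng):
        grid = self._trace()
        hits = 0
        n = 60
        for k in range(n):
            rate = rng.normal(8.0, 1.0, 1000)
            cls, _ = classify_phase(np.arange(100.0), 50.0, 150.0, seed=k,
                                    session_duration=200.0,
                                    rate_trace=(grid, rate))
            hits += cls != PhaseClass.UNRELATED
        # compound nominal rate ~15%; allow 2x
        assert hits / n < 0.30


class TestOptotagging:
    CFG = ClassificationConfig()

    def _waveform(self, rng, flip=False):
        w = np.exp(-((np.arange(30) - 10) ** 2) / 8.0)
        return -w if flip else w

    def test_fixed_2ms_responder_laser_evoked(self, rng):
        pulses = 20.0 + np.arange(60) * 0.05
        spont = np.sort(rng.uniform(0, 19, 40))
        st = np.sort(np.concatenate([spont, pulses + 0.002]))
        wf = self._waveform(rng)
        out = identify_optotagged(st, pulses, wf, wf + rng.normal(0, 0.01, 30),
                                  self.CFG, 0)
        assert out == "laser_evoked"

    def test_fixed_8ms_responder_network_evoked(self, rng):
        pulses = 20.0 + np.arange(60) * 0.05
        spont = np.sort(rng.uniform(0, 19, 40))
        st = np.sort(np.concatenate([spont, pulses + 0.008]))
        wf = self._waveform(rng)
        out = identify_optotagged(st, pulses, wf, wf, self.CFG, 0)
        assert out == "network_evoked"

    def test_poor_waveform_correlation_untagged(self, rng):
        pulses = 20.0 + np.arange(60) * 0.05
        st = np.sort(np.concatenate([rng.uniform(0, 19, 40), pulses + 0.002]))
        out = identify_optotagged(st, pulses, self._waveform(rng),
                                  self._waveform(rng, flip=True), self.CFG, 0)
        assert out == "untagged"

    def test_poisson_unit_calibrated(self, rng):
        pulses = 20.0 + np.arange(40) * 0.05
        wf = self._waveform(rng)
        hits = 0
        n = 60
        for k in range(n):
            st = np.sort(rng.uniform(0, 25, 250))
            hits += identify_optotagged(st, pulses, wf, wf, self.CFG, k) != "untagged"
        assert hits / n < 0.20  # two windows at ~5% each, 2x slack

    def test_too_few_pulses_error(self):
        with pytest.raises(ValueError):
            identify_optotagged(np.arange(10.0), np.arange(5.0),
                                np.ones(5), np.ones(5), self.CFG, 0)


class TestAssociation:
    def _labels(self, pairs):
        out = []
        for i, (v, p) in enumerate(pairs):
            out.append(UnitLabel(f"u{i}", ValenceClass(v), PhaseClass(p),
                                 False, False))
        return out

    def test_balanced_table_statistic_zero(self):
        pairs = (
            [("PV", "INITIAL_PRE")] * 10 + [("PV", "UNRELATED")] * 10
            + [("UV", "INITIAL_PRE")] * 10 + [("UV", "UNRELATED")] * 10
        )
        stat, p = association_test(self._labels(pairs))
        assert stat == pytest.approx(0.0)

    def test_nested_labels_tiny_p(self):
        pairs = (
            [("PV", "INITIAL_PRE")] * 20 + [("UV", "UNRELATED")] * 20
            + [("PV", "UNRELATED")] * 1 + [("UV", "INITIAL_PRE")] * 1
        )
        _, p = association_test(self._labels(pairs))
        assert p < 1e-6

    def test_degenerate_table_errors(self):
        pairs = [("PV", "INITIAL_PRE")] * 5
        with pytest.raises(ValueError):
            association_test(self._labels(pairs))

    def test_independent_labels_p_roughly_uniform(self, rng):
        ps = []
        for k in range(120):
            pairs = [
                (rng.choice(["PV", "UV"]), rng.choice(["INITIAL_PRE", "UNRELATED"]))
                for _ in range(60)
            ]
            try:
                ps.append(association_test(self._labels(pairs))[1])
            except ValueError:
                continue
        ps = np.array(ps)
        assert 0.25 < np.mean(ps < 0.5) < 0.75
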