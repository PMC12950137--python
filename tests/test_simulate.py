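"""Generator tests: config validation, determinism, refractory structure,
rate fidelity against a brute-force oracle, and trace rendering."""

import numpy as np
import pytest

import caldyn
from caldyn.simulate import REFRACTORY_S, _renewal_times


def single_state_config(**kw):
    base = dict(
        n_neurons=50,
        n_mice=1,
        phase_schedule=(("awake", 100.0),),
        initial_class_fractions=(0.0, 0.0, 1.0),
        class_transitions=(),
        class_rates={"low": 0.0, "moderate": 0.1, "high": 1.0},
        sync={"awake": 0.0},
        burst_rates={"awake": 0.0},
        background_gain=0.0,
        noise_sd=0.0,
        baseline_f=None,
    )
    base.update(kw)
    return caldyn.SimulationConfig(**base)


class TestConfigValidation:
    def test_rate_above_refractory_bound_rejected(self):
        with pytest.raises(ValueError, match="refractory"):
            single_state_config(class_rates={"low": 0, "moderate": 0.1, "high": 1.3})

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            caldyn.SimulationConfig(initial_class_fractions=(0.5, 0.2, 0.2))

    def test_transition_rows_must_be_stochastic(self):
        bad = tuple(
            np.eye(3).tolist() if i else [[0.5, 0.5, 0.5]] * 3 for i in range(4)
        )
        with pytest.raises(ValueError):
            caldyn.SimulationConfig(class_transitions=bad)

    def test_kernel_time_constants_ordered(self):
        with pytest.raises(ValueError):
            caldyn.SimulationConfig(kernel_rise_s=0.5, kernel_decay_s=0.1)

    def test_marginal_fractions_follow_the_chain(self):
        cfg = caldyn.SimulationConfig()
        fr = cfg.class_fractions
        p = np.asarray(cfg.initial_class_fractions)
        assert np.allclose(fr[cfg.states[0]], p)
        for state, T in zip(cfg.states[1:], cfg.class_transitions):
            p = p @ np.asarray(T)
            assert np.allclose(fr[state], p)


class TestEvents:
    def test_deterministic_per_seed(self):
        cfg = caldyn.SimulationConfig(n_neurons=20, seed=7)
        t1 = caldyn.simulate_events(cfg)
        t2 = caldyn.simulate_events(caldyn.SimulationConfig(n_neurons=20, seed=7))
        for a, b in zip(t1.event_times, t2.event_times):
            assert np.array_equal(a, b)
        assert np.array_equal(t1.class_by_state, t2.class_by_state)

    def test_zero_rate_state_has_no_events(self):
        identity = tuple(tuple(map(tuple, np.eye(3))) for _ in range(4))
        cfg = caldyn.SimulationConfig(
            n_neurons=30,
            seed=0,
            initial_class_fractions=(1.0, 0.0, 0.0),
            class_transitions=identity,
            class_rates={
                "low": {s: 0.0 if s == "maintenance" else 0.05
                        for s in ("awake", "induction", "maintenance",
                                  "early_recovery", "late_recovery")},
                "moderate": 0.1,
                "high": 0.5,
            },
        )
        truth = caldyn.simulate_events(cfg)
        lo, hi = 200.0, 700.0  # maintenance span
        for ev in truth.event_times:
            assert not np.any((ev >= lo) & (ev < hi))

    def test_refractory_gap_everywhere(self):
        cfg = caldyn.SimulationConfig(n_neurons=100, seed=3)
        truth = caldyn.simulate_events(cfg)
        for ev in truth.event_times:
            if len(ev) > 1:
                assert np.diff(ev).min() >= REFRACTORY_S - 1e-9

    def test_count_matches_brute_force_renewal_oracle(self):
        # pure refractory renewal (sync off) at 1.0 events/s for 100 s;
        # oracle re-simulates the stated generative definition 10,000 times
        rng = np.random.default_rng(12345)
        reps = 10_000
        counts = np.empty(reps)
        mean_exp = 1.0 / 1.0 - REFRACTORY_S
        for r in range(reps):
            t, c = rng.exponential(mean_exp), 0
            while t < 100.0:
                c += 1
                t += REFRACTORY_S + rng.exponential(mean_exp)
            counts[r] = c
        mc_mean, mc_sd = counts.mean(), counts.std()

        cfg = single_state_config(n_neurons=200, seed=11)
        truth = caldyn.simulate_events(cfg)
        obs = np.asarray([len(ev) for ev in truth.event_times], float)
        assert abs(obs.mean() - mc_mean) < 4 * mc_sd / np.sqrt(len(obs))
        # every individual neuron's count within 3 MC SDs plus slack for the
        # discreteness of a single draw
        assert np.all(np.abs(obs - mc_mean) < 3 * mc_sd + 1)

    def test_sampler_rate_with_refractory(self):
        rng = np.random.default_rng(0)
        ev = _renewal_times(rng, 0.5, 0.0, 2000.0, -np.inf)
        assert abs(len(ev) / 2000.0 - 0.5) < 0.05

    def test_burst_locked_fraction_matches_sync(self):
        cfg = caldyn.SimulationConfig(n_neurons=200, seed=4)
        truth = caldyn.simulate_events(cfg)
        s_idx = list(truth.states).index("maintenance")
        bursts = truth.burst_times["maintenance"]
        near = total = 0
        for i, ev in enumerate(truth.event_times):
            if truth.class_by_state[i, s_idx] != "high":
                continue
            sub = ev[(ev >= 200.0) & (ev < 700.0)]
            total += len(sub)
            if len(sub):
                d = np.min(np.abs(sub[:, None] - bursts[None, :]), axis=1)
                near += int((d < 0.2).sum())
        assert total > 0
        assert near / total > 0.8 * cfg.sync_of("maintenance")

    def test_class_separability_in_awake_window(self):
        """Firing-count supports of the three planted classes barely overlap."""
        cfg = caldyn.SimulationConfig(n_neurons=900, seed=21)
        truth = caldyn.simulate_events(cfg)
        cls = truth.class_by_state[:, 0]
        counts = {c: [] for c in caldyn.CLASSES}
        for i, ev in enumerate(truth.event_times):
            counts[cls[i]].append(int(((ev >= 0) & (ev < 100)).sum()))
        lo = np.asarray(counts["low"])
        mid = np.asarray(counts["moderate"])
        hi = np.asarray(counts["high"])
        b1 = (lo.max() + mid.min()) / 2
        b2 = (mid.max() + hi.min()) / 2
        err = ((lo >= b1).sum() + ((mid < b1) | (mid >= b2)).sum()
               + (hi < b2).sum())
        assert err / 900 < 0.01


class TestRenderTraces:
    def test_zero_events_zero_noise_gives_zero_trace(self):
        cfg = single_state_config(class_rates={"low": 0.0, "moderate": 0.0, "high": 0.0})
        truth = caldyn.simulate_events(cfg)
        tr = caldyn.render_traces(truth, cfg)
        assert tr.is_dff
        assert np.all(tr.values == 0.0)

    def test_single_event_peak_equals_amplitude(self):
        cfg = single_state_config(n_neurons=1, amplitude_cv=0.0, amplitude_mean=2.0)
        truth = caldyn.simulate_events(cfg)
        truth.event_times[0] = np.asarray([50.33])
        tr = caldyn.render_traces(truth, cfg)
        assert tr.values.max() == pytest.approx(2.0)
        peak_frame = int(tr.values[0].argmax())
        kernel_peak_s = 50.33 + 0.17  # analytic double-exponential peak lag
        assert abs(peak_frame / 10.0 - kernel_peak_s) <= 0.2

    def test_neuron_count_mismatch_rejected(self):
        cfg = single_state_config(n_neurons=5)
        truth = caldyn.simulate_events(cfg)
        with pytest.raises(ValueError, match="neurons"):
            caldyn.render_traces(truth, single_state_config(n_neurons=6))

    def test_traces_deterministic(self):
        cfg = caldyn.SimulationConfig(n_neurons=10, seed=5)
        a, _ = caldyn.simulate(cfg)
        b, _ = caldyn.simulate(caldyn.SimulationConfig(n_neurons=10, seed=5))
        assert np.array_equal(a.values, b.values)

    def test_raw_fluorescence_is_positive(self):
        tr, _ = caldyn.simulate(caldyn.SimulationConfig(n_neurons=30, seed=9))
        assert not tr.is_dff
        assert tr.values.min() > 0


class TestGroundTruthIO:
    def test_json_round_trip(self, tmp_path):
        cfg = caldyn.SimulationConfig(n_neurons=8, seed=2)
        truth = caldyn.simulate_events(cfg)
        truth.to_json(tmp_path / "t.json")
        back = caldyn.GroundTruth.from_json(tmp_path / "t.json")
        for a, b in zip(truth.event_times, back.event_times):
            assert np.allclose(a, b)
        assert np.array_equal(truth.class_by_state, back.class_by_state)
        assert back.window_states(10.0) == truth.window_states(10.0)
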