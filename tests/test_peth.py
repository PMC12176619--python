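import json

import numpy as np
import pytest

from cfaphys.core import (
    BinnedSpikes,
    Epoch,
    InvalidInputError,
    NormStats,
    bin_spikes,
    causal_half_gaussian_smooth,
    epoch_stats,
    zscore_with_stats,
)
from cfaphys.peth import (
    PETHMatrix,
    delay_event_trace,
    delay_stats,
    reward_peth,
    scalar_response,
    stim_bout_peth,
    whole_experiment_trace,
)


class TestRewardPeth:
    def test_constant_z_gives_constant_peth(self, consumption_session):
        ev = consumption_session["events"]
        binned = bin_spikes([[]], t_range=(0.0, ev.epochs["consumption"].end))
        z = np.full((1, binned.n_bins), 2.5, dtype=np.float32)
        p = reward_peth(z, binned, ev, "flavour")
        assert np.allclose(p.values, 2.5)
        assert p.values.shape[1] == 1500

    def test_single_event_equals_aligned_slice(self, rng):
        counts = rng.poisson(1.0, (2, 4000))
        binned = BinnedSpikes(counts, 0.010, 0.0, np.arange(2))
        z = counts.astype(float)
        from cfaphys.core import EventLog

        ev = EventLog(
            cue_times=[19.0],
            cue_ports=["flavour"],
            reward_times=[20.0],
            reward_ports=["flavour"],
            entry_times=[20.0],
            entry_ports=["flavour"],
            stim_bouts=np.empty((0, 2)),
            epochs={"consumption": Epoch("consumption", 0.0, 35.0),
                    "delay": Epoch("delay", 35.0, 40.0)},
        )
        p = reward_peth(z, binned, ev, "flavour")
        assert np.array_equal(p.values, z[:, 1500:3000])
        assert p.n_events == 1

    def test_peak_latency_matches_noiseless_oracle(self, consumption_session):
        # alignment check: a noise-free alpha response placed at every flavour
        # delivery must come back with its peak within one bin of the kernel
        # mode after the identical smoothing
        from cfaphys.simulate import alpha_kernel

        ev = consumption_session["events"]
        cons = ev.epochs["consumption"]
        binned = bin_spikes([[]], t_range=(0.0, cons.end))
        t_bins = binned.t0 + (np.arange(binned.n_bins) + 0.5) * binned.bin_width
        z = np.zeros((1, binned.n_bins))
        for r in ev.rewards_for_port("flavour"):
            z[0] += alpha_kernel(t_bins - r, 2.0)
        p = reward_peth(z, binned, ev, "flavour", smooth=True)
        peak_bin = int(np.argmax(p.values[0]))
        kernel = alpha_kernel(p.lags + 0.005, 2.0)
        expected_bin = int(np.argmax(causal_half_gaussian_smooth(kernel, 0.100, 0.010)))
        assert abs(peak_bin - expected_bin) <= 1

    def test_stochastic_peak_latency_is_near_kernel_mode(self, consumption_session):
        # with Poisson noise the class-average peak sits on the kernel's flat
        # top; at quarter-second resolution it must match the mode's bin
        ev = consumption_session["events"]
        truth = consumption_session["truth"]
        cons = ev.epochs["consumption"]
        binned = bin_spikes(consumption_session["spikes"], t_range=(0.0, cons.end))
        stats = epoch_stats(binned, cons)
        z = zscore_with_stats(binned, stats)
        p = reward_peth(z, binned, ev, "flavour", smooth=True)
        class_mean = p.values[truth.labels == "flavour"].mean(axis=0)
        coarse = class_mean[500:].reshape(-1, 25).mean(axis=1)  # 0.25-s bins, post only
        peak_s = (np.argmax(coarse) + 0.5) * 0.25
        # the expected profile is within 1% of its maximum over ~1.5-3 s, so
        # the stochastic argmax can land anywhere on that flat top
        assert 1.0 <= peak_s <= 3.5

    def test_missing_port_errors(self, consumption_session):
        ev = consumption_session["events"]
        binned = bin_spikes([[]], t_range=(0.0, ev.epochs["consumption"].end))
        z = np.zeros((1, binned.n_bins))
        ev2 = type(ev)(
            cue_times=ev.cue_times, cue_ports=ev.cue_ports, reward_times=ev.reward_times,
            reward_ports=np.array(["water"] * 60, dtype=object), entry_times=ev.entry_times,
            entry_ports=ev.entry_ports, stim_bouts=ev.stim_bouts, epochs=ev.epochs,
        )
        with pytest.raises(InvalidInputError):
            reward_peth(z, binned, ev2, "flavour")


class TestStimBoutPeth:
    def test_constant_z_is_zero_after_baseline_subtraction(self):
        binned = BinnedSpikes(np.zeros((2, 6000), dtype=int), 0.010, 0.0, np.arange(2))
        z = np.full((2, 6000), 3.0)
        bouts = np.array([[10.0, 13.0], [20.0, 23.0], [30.0, 33.0]])
        p = stim_bout_peth(z, binned, bouts)
        assert np.allclose(p.values, 0.0, atol=1e-12)

    def test_baseline_window_mean_is_exactly_zero(self, planted_session):
        ev = planted_session["events"]
        stim = ev.epochs["stimulation"]
        binned = bin_spikes(planted_session["spikes"], t_range=(stim.start - 2.0, stim.end))
        cons_stats = NormStats(
            mean=np.zeros(binned.n_neurons), sd=np.ones(binned.n_neurons),
            provenance={"epoch": "consumption"},
        )
        z = binned.counts.astype(float)
        p = stim_bout_peth(z, binned, ev.stim_bouts)
        base = p.values[:, p.lag_slice(-1.0, 0.0)]
        assert np.allclose(base.mean(axis=1), 0.0, atol=1e-10)

    def test_flavour_class_responds_to_bouts(self, planted_session):
        ev = planted_session["events"]
        truth = planted_session["truth"]
        stim = ev.epochs["stimulation"]
        cons = ev.epochs["consumption"]
        binned_cons = bin_spikes(planted_session["spikes"], t_range=(0.0, cons.end))
        stats = epoch_stats(binned_cons, cons)
        binned_stim = bin_spikes(planted_session["spikes"], t_range=(stim.start - 2.0, stim.end))
        z = zscore_with_stats(binned_stim, stats)
        p = stim_bout_peth(z, binned_stim, ev.stim_bouts)
        sl = p.lag_slice(0.0, 3.0)
        flav = p.values[truth.labels == "flavour"][:, sl].mean()
        wat = p.values[truth.labels == "water"][:, sl].mean()
        assert flav > wat

    def test_shuffled_bout_times_collapse_class_difference(self, planted_session, rng):
        ev = planted_session["events"]
        truth = planted_session["truth"]
        stim = ev.epochs["stimulation"]
        cons = ev.epochs["consumption"]
        binned_cons = bin_spikes(planted_session["spikes"], t_range=(0.0, cons.end))
        stats = epoch_stats(binned_cons, cons)
        binned_stim = bin_spikes(planted_session["spikes"], t_range=(stim.start - 2.0, stim.end))
        z = zscore_with_stats(binned_stim, stats)
        diffs = []
        for _ in range(5):
            onsets = np.sort(rng.uniform(stim.start, stim.end - 4.0, len(ev.stim_bouts)))
            fake = np.column_stack([onsets, onsets + 3.0])
            p = stim_bout_peth(z, binned_stim, fake)
            sl = p.lag_slice(0.0, 3.0)
            diffs.append(
                p.values[truth.labels == "flavour"][:, sl].mean()
                - p.values[truth.labels == "water"][:, sl].mean()
            )
        # random alignment samples bouts and gaps alike; the class contrast
        # shrinks to a small fraction of the aligned one
        p_true = stim_bout_peth(z, binned_stim, ev.stim_bouts)
        sl = p_true.lag_slice(0.0, 3.0)
        aligned = (
            p_true.values[truth.labels == "flavour"][:, sl].mean()
            - p_true.values[truth.labels == "water"][:, sl].mean()
        )
        assert abs(np.mean(diffs)) < 0.5 * aligned


class TestWholeExperimentTrace:
    def test_length_and_delay_self_normalization(self, planted_session):
        ev = planted_session["events"]
        binned = bin_spikes(planted_session["spikes"], t_range=(0.0, ev.session_end))
        stats = delay_stats(binned, ev)
        trace = whole_experiment_trace(binned, ev, stats)
        assert trace.shape[1] == 90
        delay_seg = trace[:, 15:45]
        assert abs(delay_seg.mean()) < 0.2

    def test_downsampled_minutes_match_direct_recomputation(self, planted_session):
        ev = planted_session["events"]
        binned = bin_spikes(planted_session["spikes"], t_range=(0.0, ev.session_end))
        stats = delay_stats(binned, ev)
        trace = whole_experiment_trace(binned, ev, stats)
        # recompute a minute inside the delay segment directly: trace sample 20
        # is delay minute 5
        delay = ev.epochs["delay"]
        k0 = binned.bin_slice(delay.start, delay.end).start + 5 * 6000
        block = binned.counts[:, k0 : k0 + 6000].astype(float)
        direct = ((block - stats.mean[:, None]) / stats.sd[:, None]).mean(axis=1)
        assert np.allclose(trace[:, 20], direct, atol=1e-6)


class TestDelayEventTrace:
    def _session(self, rng, n=30, r_pre=20.0, r_post=None, step_units=None):
        # Poisson counts with an optional planted rate step at the event
        pre, post = 1800.0, 2700.0
        t_event = pre
        n_bins = int((pre + post) / 0.010)
        rates = np.full((n, n_bins), r_pre * 0.010)
        if step_units:
            for u, mult in step_units.items():
                rates[u, int(pre / 0.010):] *= mult
        counts = rng.poisson(rates)
        binned = BinnedSpikes(counts, 0.010, 0.0, np.arange(n))
        from cfaphys.core import EventLog

        ev = EventLog(
            cue_times=[], cue_ports=[], reward_times=[], reward_ports=[],
            entry_times=[], entry_ports=[], stim_bouts=np.empty((0, 2)),
            epochs={"consumption": Epoch("consumption", -100.0, 0.0),
                    "delay": Epoch("delay", 0.0, pre),
                    "malaise": Epoch("malaise", pre, pre + post)},
        )
        return binned, ev, t_event

    def test_output_length_and_pre_event_mean(self, rng):
        binned, ev, t_event = self._session(rng)
        stats = delay_stats(binned, ev)
        trace = delay_event_trace(binned, ev, t_event, stats)
        assert trace.shape[1] == 75
        assert abs(trace[:, :30].mean()) < 0.15

    def test_planted_step_subclass_recovered(self, rng):
        step = {u: 4.0 for u in range(10)}
        binned, ev, t_event = self._session(rng, step_units=step)
        stats = delay_stats(binned, ev)
        trace = delay_event_trace(binned, ev, t_event, stats)
        assert trace[:10, 30:].mean() > 1.0
        assert abs(trace[10:, 30:].mean()) < 0.3

    def test_insufficient_pre_data_errors(self, rng):
        binned, ev, t_event = self._session(rng)
        stats = delay_stats(binned, ev)
        with pytest.raises(InvalidInputError):
            delay_event_trace(binned, ev, 100.0, stats)


class TestScalarResponse:
    def test_constant_trace(self):
        trace = np.ones((3, 75))
        assert np.allclose(scalar_response(trace, "cgrp_45min"), 1.0)

    def test_linear_ramp_midpoint(self):
        minutes = np.arange(75) - 30.0  # value = minutes relative to event
        trace = np.tile(minutes, (2, 1))
        # mean over +5..+15 min of a ramp equals its midpoint
        assert np.allclose(scalar_response(trace, "licl_5_15min"), 9.5)

    def test_cgrp_scalar_monotone_in_bout_gain(self):
        from cfaphys.acceptance import cgrp_scalar_from_spikes
        from cfaphys.simulate import SimConfig, simulate_population, simulate_task_events

        means = []
        for g in (0.0, 0.5, 1.0, 2.0):
            cfg = SimConfig(seed=21, n_neurons=40, frac_flavour=1.0, frac_water=0.0,
                            bout_gain_mean=g, bout_gain_shape=50.0)
            ev = simulate_task_events(cfg)
            spikes, truth = simulate_population(cfg, ev)
            means.append(cgrp_scalar_from_spikes(spikes, ev).mean())
        assert np.all(np.diff(means) > 0)

    def test_unknown_rule_errors(self):
        with pytest.raises(InvalidInputError):
            scalar_response(np.ones((1, 80)), "bogus")


class TestPethProvenance:
    def test_translation_invariance(self, rng):
        counts = rng.poisson(1.0, (3, 5000))
        z = counts.astype(float)
        from cfaphys.core import EventLog

        def make_ev(shift):
            return EventLog(
                cue_times=[14.0 + shift], cue_ports=["flavour"],
                reward_times=[15.0 + shift], reward_ports=["flavour"],
                entry_times=[15.0 + shift], entry_ports=["flavour"],
                stim_bouts=np.empty((0, 2)),
                epochs={"consumption": Epoch("consumption", shift, 40.0 + shift),
                        "delay": Epoch("delay", 40.0 + shift, 50.0 + shift)},
            )

        b0 = BinnedSpikes(counts, 0.010, 0.0, np.arange(3))
        b1 = BinnedSpikes(counts, 0.010, 7.0, np.arange(3))  # same data, shifted clock
        p0 = reward_peth(z, b0, make_ev(0.0), "flavour")
        p1 = reward_peth(z, b1, make_ev(7.0), "flavour")
        assert np.array_equal(p0.values, p1.values)

    def test_provenance_roundtrips_through_json(self):
        p = PETHMatrix(
            values=np.zeros((2, 1500)), window=(5.0, 10.0), bin_width=0.010,
            baseline_rule="none", normalization={"stats": "consumption", "day": 1},
            smoothed=True, n_events=30, n_dropped=2,
        )
        doc = json.dumps({
            "window": p.window, "bin_width": p.bin_width, "baseline_rule": p.baseline_rule,
            "normalization": p.normalization, "smoothed": p.smoothed,
            "n_events": p.n_events, "n_dropped": p.n_dropped,
        })
        back = json.loads(doc)
        assert tuple(back["window"]) == p.window
        assert back["normalization"] == p.normalization
        assert back["n_events"] == p.n_events

    def test_lag_bin_count_invariant_enforced(self):
        with pytest.raises(InvalidInputError):
            PETHMatrix(values=np.zeros((2, 100)), window=(5.0, 10.0), bin_width=0.010,
                       baseline_rule="none", normalization={"stats": "x"})
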