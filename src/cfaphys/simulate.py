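"""Synthetic session generator with ground truth.

Emulates the two-reward conditioning paradigm: a 5-min acclimation, a cued
consumption period in which 60 rewards (20 ul each, 1.2 ml total) are
delivered with every consecutive block of ten rewards split 5/5 between the
flavour and water ports, a 30-min delay in a second context, and then either
a 45-min malaise-signal stimulation period composed of 3-s optogenetic bouts
separated by truncated-exponential gaps, or a single LiCl-style injection
event.

Spiking is inhomogeneous Poisson, generated by thinning.  Each neuron's rate
is

    rate(t) = baseline * suppression(t) * (1 + sum of event kernels)

where the event kernels are alpha functions ``(dt/tau) * exp(1 - dt/tau)``
(peak equal to the neuron's response gain at lag ``tau``) following rewards
at the neuron's preferred port, plus a bout-locked boxcar gain during each
stimulation bout for flavour-preferring neurons.  ``suppression(t)`` is 1
until the end of consumption and a constant factor (< 1) afterwards,
emulating the drop in activity after consumption ends.

Cross-day plasticity is expressed on the measured-response scale: the
retrieval-day change in a flavour-preferring neuron's normalized flavour
response is ``beta`` times its normalized stimulation-period response plus
noise.  The generator converts this target into a day-2 kernel gain using
closed-form expectations of the analysis quantities (see
``expected_response_per_gain`` and ``expected_cgrp_response``), so that the
downstream regression of response change on stimulation response estimates
``beta`` directly, mirroring how the plasticity relationship is quantified
from data.  The familiarization variant instead multiplies flavour-response
gains by a decay factor and leaves water responses unchanged.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np

from .core import Epoch, EventLog, InvalidInputError, UnitMeta

KERNEL_SUPPORT_SDS = 8.0  # alpha kernels are truncated at 8*tau


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random substream derived from one master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


@dataclass
class SimConfig:
    """Parameters of a simulated experiment (defaults are the study conditions)."""

    n_neurons: int = 300
    frac_flavour: float = 0.30
    frac_water: float = 0.10
    baseline_rate_median: float = 2.0  # sp/s, lognormal across neurons
    baseline_rate_sigma: float = 0.5
    reward_gain_median: float = 2.0  # alpha-kernel peak, lognormal across neurons
    reward_gain_sigma: float = 0.25
    kernel_tau: float = 2.0  # s, alpha-function timescale
    delay_suppression: float = 0.6  # multiplicative rate factor after consumption
    bout_gain_shape: float = 2.0  # gamma shape of flavour-class reactivation gains
    bout_gain_mean: float = 1.0  # gamma mean; 0 disables reactivation
    beta: float = 0.5  # plasticity slope (measured-response scale)
    plasticity_noise_sd: float = 0.2  # s.d. of plasticity noise, kernel-gain scale
    familiar_decay: float = 0.3  # day-2 flavour-gain multiplier on familiarization
    # task structure
    acclimation_s: float = 300.0
    iti_range_s: tuple[int, int] = (10, 20)  # integer seconds, inclusive
    entry_latency_range_s: tuple[float, float] = (0.5, 2.0)
    n_rewards: int = 60
    block_size: int = 10
    reward_volume_ul: float = 20.0
    consumption_pad_s: float = 10.0  # epoch extends this far past the final reward
    delay_duration_s: float = 1800.0
    malaise_mode: str = "stim"  # 'stim', 'licl' or 'none'
    malaise_duration_s: float = 2700.0
    bout_duration_s: float = 3.0
    bout_gap_min_s: float = 1.0
    bout_gap_mean_s: float = 3.0
    bout_gap_max_s: float = 7.8
    rate_ceiling: float = 500.0  # sp/s; exceeding this raises an error
    seed: int = 0

    def validate(self) -> None:
        if self.frac_flavour < 0 or self.frac_water < 0 or self.frac_flavour + self.frac_water > 1:
            raise InvalidInputError("class fractions must be non-negative and sum to <= 1")
        if self.n_neurons < 1:
            raise InvalidInputError("n_neurons must be >= 1")
        if self.n_rewards % self.block_size:
            raise InvalidInputError("n_rewards must be a multiple of block_size")
        if self.block_size % 2:
            raise InvalidInputError("block_size must be even to split 5/5 per port")
        for name in (
            "baseline_rate_median",
            "reward_gain_median",
            "kernel_tau",
            "delay_suppression",
            "bout_gain_mean",
            "familiar_decay",
        ):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        if self.malaise_mode not in ("stim", "licl", "none"):
            raise InvalidInputError("malaise_mode must be 'stim', 'licl' or 'none'")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})
        cfg.validate()
        return cfg


@dataclass
class GroundTruth:
    """Per-neuron generative parameters of a simulated population."""

    labels: np.ndarray  # 'flavour' | 'water' | 'nonselective'
    baseline_rate: np.ndarray
    reward_gain: np.ndarray  # day-1 alpha-kernel peak at the preferred port
    bout_gain: np.ndarray  # reactivation gain during stimulation bouts
    beta: float | None = None
    familiar_decay: float | None = None
    day2_reward_gain: np.ndarray | None = None
    expected_cgrp_response: np.ndarray | None = None  # normalized-scale
    expected_delta_response: np.ndarray | None = None  # normalized-scale target


# --- events -----------------------------------------------------------------


def sample_bout_gap(rng: np.random.Generator, config: SimConfig) -> float:
    """Shifted-exponential bout gap (min 1 s, mean 3 s) rejected above 7.8 s."""
    scale = config.bout_gap_mean_s - config.bout_gap_min_s
    while True:
        g = config.bout_gap_min_s + rng.exponential(scale)
        if g <= config.bout_gap_max_s:
            return g


def simulate_task_events(config: SimConfig, seed: int | None = None) -> EventLog:
    """Generate one session's event log.

    The consumption period delivers exactly ``n_rewards`` rewards; each
    consecutive block of ``block_size`` rewards is evenly split between the
    two ports, inter-trial intervals are integer seconds drawn uniformly
    from ``iti_range_s``, and every cued trial is rewarded after a short
    port-entry latency.
    """
    config.validate()
    rng = substream(config.seed if seed is None else seed, "events")
    half = config.block_size // 2
    ports: list[str] = []
    for _ in range(config.n_rewards // config.block_size):
        block = ["flavour"] * half + ["water"] * half
        rng.shuffle(block)
        ports.extend(block)

    cue_times, reward_times, entry_times = [], [], []
    t = config.acclimation_s
    lat_lo, lat_hi = config.entry_latency_range_s
    for port in ports:
        t += rng.integers(config.iti_range_s[0], config.iti_range_s[1] + 1)
        cue_times.append(t)
        t += rng.uniform(lat_lo, lat_hi)
        reward_times.append(t)
        entry_times.append(t)

    cons_end = reward_times[-1] + config.consumption_pad_s
    epochs = {
        "acclimation": Epoch("acclimation", 0.0, config.acclimation_s),
        "consumption": Epoch("consumption", config.acclimation_s, cons_end),
        "delay": Epoch("delay", cons_end, cons_end + config.delay_duration_s),
    }
    delay_end = epochs["delay"].end
    bouts: list[tuple[float, float]] = []
    injection = None
    if config.malaise_mode == "stim":
        stim_end = delay_end + config.malaise_duration_s
        epochs["stimulation"] = Epoch("stimulation", delay_end, stim_end)
        tb = delay_end
        while tb + config.bout_duration_s <= stim_end:
            bouts.append((tb, tb + config.bout_duration_s))
            tb += config.bout_duration_s + sample_bout_gap(rng, config)
    elif config.malaise_mode == "licl":
        injection = delay_end
        epochs["malaise"] = Epoch("malaise", delay_end, delay_end + config.malaise_duration_s)

    ports_arr = np.array(ports, dtype=object)
    log = EventLog(
        cue_times=np.array(cue_times),
        cue_ports=ports_arr.copy(),
        reward_times=np.array(reward_times),
        reward_ports=ports_arr.copy(),
        entry_times=np.array(entry_times),
        entry_ports=ports_arr.copy(),
        stim_bouts=np.array(bouts, dtype=float).reshape(-1, 2),
        epochs=epochs,
        injection_time=injection,
    )
    log.validate()
    return log


# --- spiking ----------------------------------------------------------------


def alpha_kernel(dt: np.ndarray, tau: float) -> np.ndarray:
    """Unit-peak alpha function, truncated at ``KERNEL_SUPPORT_SDS * tau``."""
    dt = np.asarray(dt, dtype=float)
    out = np.where(
        (dt > 0) & (dt < KERNEL_SUPPORT_SDS * tau),
        (dt / tau) * np.exp(1.0 - dt / tau),
        0.0,
    )
    return out


def alpha_kernel_mass(x: np.ndarray | float, tau: float) -> np.ndarray:
    """Integral of the unit-peak alpha kernel from 0 to ``x`` (closed form)."""
    x = np.clip(np.asarray(x, dtype=float), 0.0, KERNEL_SUPPORT_SDS * tau)
    return np.e * tau * (1.0 - np.exp(-x / tau) * (1.0 + x / tau))


@dataclass
class _NeuronParams:
    baseline: float
    reward_gain: float
    bout_gain: float
    preferred: str | None  # port driving the alpha kernel, or None


def _draw_population(config: SimConfig, rng: np.random.Generator) -> GroundTruth:
    n = config.n_neurons
    n_f = int(round(config.frac_flavour * n))
    n_w = int(round(config.frac_water * n))
    labels = np.array(
        ["flavour"] * n_f + ["water"] * n_w + ["nonselective"] * (n - n_f - n_w), dtype=object
    )
    baseline = rng.lognormal(np.log(config.baseline_rate_median), config.baseline_rate_sigma, n)
    gain = rng.lognormal(np.log(config.reward_gain_median), config.reward_gain_sigma, n)
    gain[labels == "nonselective"] = 0.0
    bout = np.zeros(n)
    if config.bout_gain_mean > 0:
        scale = config.bout_gain_mean / config.bout_gain_shape
        draws = rng.gamma(config.bout_gain_shape, scale, n)
        bout[labels == "flavour"] = draws[labels == "flavour"]
    else:
        rng.gamma(config.bout_gain_shape, 1.0, n)  # keep the stream aligned
    return GroundTruth(
        labels=labels, baseline_rate=baseline, reward_gain=gain, bout_gain=bout,
        familiar_decay=config.familiar_decay,
    )


def _rate_at(
    t: np.ndarray,
    p: _NeuronParams,
    events: EventLog,
    config: SimConfig,
    cons_end: float,
) -> np.ndarray:
    """Evaluate one neuron's firing rate at arbitrary times (vectorized)."""
    rate = np.full(t.shape, p.baseline)
    rate[t >= cons_end] *= config.delay_suppression
    mod = np.zeros(t.shape)
    if p.preferred is not None and p.reward_gain > 0:
        rewards = events.rewards_for_port(p.preferred)
        if rewards.size:
            idx = np.searchsorted(rewards, t)
            # at most two kernels can overlap given ITI >= 10 s and 8*tau support
            for back in (1, 2):
                j = idx - back
                ok = j >= 0
                dt = np.where(ok, t - rewards[np.clip(j, 0, None)], -1.0)
                mod += p.reward_gain * alpha_kernel(dt, config.kernel_tau)
    if p.bout_gain > 0 and events.stim_bouts.size:
        onsets = events.stim_bouts[:, 0]
        offsets = events.stim_bouts[:, 1]
        j = np.searchsorted(onsets, t, side="right") - 1
        in_bout = (j >= 0) & (t < offsets[np.clip(j, 0, None)])
        mod += p.bout_gain * in_bout
    return rate * (1.0 + mod)


def _thin_neuron(
    p: _NeuronParams,
    events: EventLog,
    config: SimConfig,
    rng: np.random.Generator,
    t_stop: float,
) -> np.ndarray:
    """Inhomogeneous-Poisson spikes for one neuron via thinning.

    Candidates are drawn homogeneously within segments whose ceilings bound
    the true rate (tight piecewise bounds keep the rejection rate low), then
    accepted with probability rate/ceiling.
    """
    cons_end = events.epochs["consumption"].end
    tau = config.kernel_tau
    sup = config.delay_suppression
    # overlap of two alpha tails is at most ~5% above a single peak
    peak = 1.05 * p.reward_gain
    tail_end = min(cons_end + KERNEL_SUPPORT_SDS * tau, t_stop)
    segments = [
        (0.0, min(cons_end, t_stop), p.baseline * (1.0 + peak)),
        (min(cons_end, t_stop), tail_end, p.baseline * sup * (1.0 + peak) + 1e-12),
        (tail_end, t_stop, p.baseline * max(sup, 1e-12) * (1.0 + p.bout_gain)),
    ]
    spikes = []
    for a, b, ceiling in segments:
        if b <= a or ceiling <= 0:
            continue
        if ceiling > config.rate_ceiling:
            raise InvalidInputError(
                f"rate ceiling {ceiling:.1f} sp/s exceeds configured maximum "
                f"{config.rate_ceiling} sp/s"
            )
        n_cand = rng.poisson(ceiling * (b - a))
        if n_cand == 0:
            continue
        cand = np.sort(rng.uniform(a, b, n_cand))
        accept = rng.uniform(0.0, ceiling, n_cand) < _rate_at(cand, p, events, config, cons_end)
        spikes.append(cand[accept])
    return np.concatenate(spikes) if spikes else np.empty(0)


def simulate_population(
    config: SimConfig,
    events: EventLog,
    seed: int | None = None,
    truth: GroundTruth | None = None,
    t_stop: float | None = None,
    stream: str = "spikes",
) -> tuple[list[np.ndarray], GroundTruth]:
    """Simulate spiking for a whole population over one session.

    ``t_stop`` limits simulation to ``[0, t_stop)`` (e.g. the consumption
    period only) for analyses that do not need the full session.  ``truth``
    allows re-using (possibly modified) generative parameters, as in the
    multiday simulations.
    """
    config.validate()
    master = config.seed if seed is None else seed
    if truth is None:
        truth = _draw_population(config, substream(master, "population"))
    if t_stop is None:
        t_stop = events.session_end
    rng = substream(master, stream)
    preferred = {"flavour": "flavour", "water": "water", "nonselective": None}
    spikes = []
    for u in range(truth.labels.size):
        p = _NeuronParams(
            baseline=float(truth.baseline_rate[u]),
            reward_gain=float(truth.reward_gain[u]),
            bout_gain=float(truth.bout_gain[u]),
            preferred=preferred[truth.labels[u]],
        )
        spikes.append(_thin_neuron(p, events, config, rng, float(t_stop)))
    return spikes, truth


def default_unit_meta(truth: GroundTruth) -> list[UnitMeta]:
    """Unit metadata for simulated neurons (all pass the quality filter)."""
    return [
        UnitMeta(
            unit_id=u,
            median_amplitude=60.0,
            fp_rate=0.01,
            firing_rate=float(truth.baseline_rate[u]),
            curation_label="good",
        )
        for u in range(truth.labels.size)
    ]


# --- calibration of measured-scale expectations ----------------------------


def _window_kernel_mean(rewards: np.ndarray, a: float, b: float, tau: float) -> float:
    """Mean unit-peak kernel value over absolute window [a, b], all rewards."""
    mass = alpha_kernel_mass(b - rewards, tau) - alpha_kernel_mass(a - rewards, tau)
    return float(mass.sum() / (b - a))


def expected_response_per_gain(
    events: EventLog,
    baseline: np.ndarray,
    reward_gain: np.ndarray,
    config: SimConfig,
    window: float = 10.0,
    baseline_window: tuple[float, float] = (-10.0, -5.0),
) -> np.ndarray:
    """Expected normalized flavour response per unit of kernel gain.

    The measured response is the mean consumption-z-scored activity in the
    10 s after each flavour delivery minus the mean over the per-trial
    baseline window, averaged over flavour trials.  Its expectation is
    linear in the neuron's kernel gain with the slope returned here, which
    accounts for kernel spill-over from neighbouring flavour rewards into
    both windows and for the reward-driven inflation of the consumption-
    period count s.d.
    """
    tau = config.kernel_tau
    cons = events.epochs["consumption"]
    flav = events.rewards_for_port("flavour")
    w_bar = np.mean(
        [
            _window_kernel_mean(flav, r, r + window, tau)
            - _window_kernel_mean(flav, r + baseline_window[0], r + baseline_window[1], tau)
            for r in flav
        ]
    )
    # mean kernel level over the consumption epoch (per unit gain)
    k_bar = float(alpha_kernel_mass(cons.end - flav, tau).sum() / cons.duration)
    bw = 0.010
    mean_rate = baseline * (1.0 + reward_gain * k_bar)
    sd_counts = np.sqrt(bw * mean_rate)  # Poisson approximation, 10-ms bins
    return baseline * bw * w_bar / sd_counts


def expected_cgrp_response(
    events: EventLog, baseline: np.ndarray, bout_gain: np.ndarray, config: SimConfig
) -> np.ndarray:
    """Expected stimulation-period response on the delay-normalized z scale."""
    stim = events.epochs.get("stimulation")
    if stim is None or events.stim_bouts.size == 0:
        return np.zeros_like(baseline)
    bout_frac = float(np.diff(events.stim_bouts, axis=1).sum() / stim.duration)
    bw = 0.010
    sup = config.delay_suppression
    sd_delay = np.sqrt(bw * baseline * sup)
    return baseline * sup * bout_frac * bout_gain * bw / sd_delay


# --- multiday ---------------------------------------------------------------


@dataclass
class MultidaySim:
    """Paired conditioning/retrieval (or novel/familiar) sessions."""

    events_day1: EventLog
    spikes_day1: list[np.ndarray]
    events_day2: EventLog
    spikes_day2: list[np.ndarray]
    truth: GroundTruth


def simulate_multiday(
    config: SimConfig,
    seed: int | None = None,
    mode: str = "conditioning",
    day2_t_stop: float | None = None,
) -> MultidaySim:
    """Simulate a paired two-day experiment with ground-truth plasticity.

    ``mode='conditioning'``: day 1 includes the stimulation period; each
    flavour-preferring neuron's day-2 gain is set so that the expected change
    in its normalized flavour response equals ``beta`` times its expected
    normalized stimulation response, plus Gaussian noise (s.d.
    ``plasticity_noise_sd`` on the kernel-gain scale).

    ``mode='familiarization'``: no malaise signal on either day; day-2
    flavour gains are ``familiar_decay`` times the day-1 gains and water
    responses are unchanged.

    ``day2_t_stop`` optionally truncates day-2 simulation (the cross-day
    analyses only need day-2 consumption).
    """
    if mode not in ("conditioning", "familiarization"):
        raise InvalidInputError("mode must be 'conditioning' or 'familiarization'")
    master = config.seed if seed is None else seed
    day1_cfg = replace(config, malaise_mode="stim" if mode == "conditioning" else "none")
    events1 = simulate_task_events(day1_cfg, substream(master, "events-day1").integers(2**31))
    truth = _draw_population(config, substream(master, "population"))
    spikes1, _ = simulate_population(day1_cfg, events1, master, truth=truth, stream="spikes-day1")

    day2_cfg = replace(config, malaise_mode="none")
    events2 = simulate_task_events(day2_cfg, substream(master, "events-day2").integers(2**31))

    flavour = truth.labels == "flavour"
    day2_gain = truth.reward_gain.copy()
    expected_delta = np.zeros(config.n_neurons)
    cgrp = expected_cgrp_response(events1, truth.baseline_rate, truth.bout_gain, day1_cfg)
    if mode == "conditioning":
        # Expected measured response is slope_d * gain on day d; both days are
        # normalized with day-1 statistics, so the s.d. term is shared.  Using
        # each day's realized event statistics removes the session-level
        # response-scale factor from the plasticity relation.
        slope1 = expected_response_per_gain(
            events1, truth.baseline_rate, truth.reward_gain, config
        )
        slope2 = expected_response_per_gain(
            events2, truth.baseline_rate, truth.reward_gain, config
        )
        noise = substream(master, "plasticity").normal(0.0, config.plasticity_noise_sd,
                                                       config.n_neurons)
        target = config.beta * cgrp + slope1 * noise
        g2 = (target + slope1 * truth.reward_gain) / slope2
        day2_gain = np.where(flavour, np.clip(g2, 0.0, None), truth.reward_gain)
        expected_delta = np.where(flavour, day2_gain * slope2 - truth.reward_gain * slope1, 0.0)
        truth.beta = config.beta
    else:
        day2_gain[flavour] = config.familiar_decay * truth.reward_gain[flavour]
    truth.day2_reward_gain = day2_gain
    truth.expected_cgrp_response = cgrp
    truth.expected_delta_response = expected_delta
    truth2 = GroundTruth(
        labels=truth.labels,
        baseline_rate=truth.baseline_rate,
        reward_gain=day2_gain,
        bout_gain=np.zeros(config.n_neurons),
    )
    spikes2, _ = simulate_population(
        day2_cfg, events2, master, truth=truth2, t_stop=day2_t_stop, stream="spikes-day2"
    )
    return MultidaySim(events1, spikes1, events2, spikes2, truth)


# --- photometry -------------------------------------------------------------


@dataclass
class PhotometryTrace:
    """Uniformly sampled two-channel photometry recording."""

    time: np.ndarray
    iso405: np.ndarray
    act488: np.ndarray
    fs: float

    def validate(self) -> None:
        if not (self.time.size == self.iso405.size == self.act488.size):
            raise InvalidInputError("photometry channels must have equal length")
        if self.time.size > 1 and np.any(np.diff(self.time) <= 0):
            raise InvalidInputError("time must be strictly increasing")
        if self.fs <= 0:
            raise InvalidInputError("sampling rate must be positive")


def simulate_photometry(
    duration: float,
    seed: int = 0,
    fs: float = 200.0,
    transient_times: Sequence[float] = (),
    transient_amp: float = 1.0,
    transient_tau: float = 10.0,
    bleach_tau: float = 1200.0,
    bleach_amp: float = 0.5,
    noise_sd: float = 0.01,
    baseline_405: float = 1.0,
    baseline_488: float = 2.0,
) -> PhotometryTrace:
    """Two-channel photometry with shared slow bleaching.

    Both channels decay with the same slow exponential bleach (scaled to
    their baselines); activity transients -- alpha-shaped with timescale
    ``transient_tau`` -- are added to the 488-nm channel only, and i.i.d.
    Gaussian sensor noise is added to both channels.
    """
    rng = substream(seed, "photometry")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    bleach = 1.0 - bleach_amp * (1.0 - np.exp(-t / bleach_tau))
    iso = baseline_405 * bleach
    act = baseline_488 * bleach
    for t0 in transient_times:
        dt = t - t0
        act = act + transient_amp * alpha_kernel(dt, transient_tau)
    iso = iso + rng.normal(0.0, noise_sd, n)
    act = act + rng.normal(0.0, noise_sd, n)
    trace = PhotometryTrace(time=t, iso405=iso, act488=act, fs=fs)
    trace.validate()
    return trace
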