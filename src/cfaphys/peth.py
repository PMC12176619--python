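"""Peri-event time histograms and scalar response summaries.

All PETHs operate on 10-ms binned, z-scored activity.  Reward PETHs span
-5 s to +10 s around delivery; stimulation-bout PETHs span -1 s to +4 s
(chronic experiments) or -1 s to +2 s (acute response typing) and are
baseline-subtracted over (-1, 0) s.  Events whose window extends past the
available data are dropped from the average (never zero-padded) and the
number of averaged events is recorded.  Minute-resolution traces are
normalized with delay-period statistics, by default from the final 20 min
of the delay, and downsampled with non-overlapping minute means aligned to
the segment start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    BinnedSpikes,
    Epoch,
    EventLog,
    InvalidInputError,
    NormStats,
    causal_half_gaussian_smooth,
    downsample_mean,
    epoch_stats,
    zscore_with_stats,
)

SMOOTH_SD = 0.100  # s; causal half-Gaussian for display PETHs


@dataclass
class PETHMatrix:
    """Neurons x lag-bins event-aligned average with provenance."""

    values: np.ndarray
    window: tuple[float, float]  # (pre, post), seconds; lags span [-pre, +post)
    bin_width: float
    baseline_rule: str
    normalization: dict
    smoothed: bool = False
    n_events: int = 0
    n_dropped: int = 0

    def __post_init__(self) -> None:
        expect = int(round((self.window[0] + self.window[1]) / self.bin_width))
        if self.values.shape[1] != expect:
            raise InvalidInputError(
                f"lag-bin count {self.values.shape[1]} != (pre+post)/bin_width = {expect}"
            )
        if not self.baseline_rule or not self.normalization:
            raise InvalidInputError("provenance fields must be non-empty")

    @property
    def lags(self) -> np.ndarray:
        """Left edges of the lag bins, seconds relative to the event."""
        return -self.window[0] + np.arange(self.values.shape[1]) * self.bin_width

    def lag_slice(self, a: float, b: float) -> slice:
        k0 = int(np.ceil((a + self.window[0]) / self.bin_width - 1e-9))
        k1 = int(np.floor((b + self.window[0]) / self.bin_width + 1e-9))
        return slice(max(k0, 0), min(k1, self.values.shape[1]))


def _event_aligned_average(
    z: np.ndarray,
    binned: BinnedSpikes,
    event_times: np.ndarray,
    window: tuple[float, float],
) -> tuple[np.ndarray, int, int]:
    pre, post = window
    n_lags = int(round((pre + post) / binned.bin_width))
    pre_bins = int(round(pre / binned.bin_width))
    acc = np.zeros((z.shape[0], n_lags))
    used = dropped = 0
    for t in event_times:
        k = int(np.floor((t - binned.t0) / binned.bin_width + 1e-9))
        a, b = k - pre_bins, k - pre_bins + n_lags
        if a < 0 or b > binned.n_bins:
            dropped += 1
            continue
        acc += z[:, a:b]
        used += 1
    if used == 0:
        raise InvalidInputError("no event window fits inside the recording")
    return acc / used, used, dropped


def reward_peth(
    z: np.ndarray,
    binned: BinnedSpikes,
    events: EventLog,
    port: str,
    window: tuple[float, float] = (5.0, 10.0),
    smooth: bool = False,
    normalization: dict | None = None,
) -> PETHMatrix:
    """Average z-scored activity around reward deliveries at one port.

    ``z`` must be normalized with consumption-period statistics; for the
    second day of a multiday recording the caller passes day-1 statistics
    (recorded in ``normalization``) so units are comparable across days.
    """
    deliveries = events.rewards_for_port(port)
    if deliveries.size == 0:
        raise InvalidInputError(f"no reward deliveries for port {port!r}")
    values, used, dropped = _event_aligned_average(z, binned, deliveries, window)
    if smooth:
        values = causal_half_gaussian_smooth(values, SMOOTH_SD, binned.bin_width)
    return PETHMatrix(
        values=values,
        window=window,
        bin_width=binned.bin_width,
        baseline_rule="none",
        normalization=normalization or {"stats": "consumption"},
        smoothed=smooth,
        n_events=used,
        n_dropped=dropped,
    )


def stim_bout_peth(
    z: np.ndarray,
    binned: BinnedSpikes,
    bouts: np.ndarray,
    window: tuple[float, float] = (1.0, 4.0),
    normalization: dict | None = None,
) -> PETHMatrix:
    """Bout-aligned average minus each neuron's own (-1, 0) s baseline mean."""
    bouts = np.asarray(bouts, dtype=float).reshape(-1, 2)
    if bouts.size == 0:
        raise InvalidInputError("no stimulation bouts")
    values, used, dropped = _event_aligned_average(z, binned, bouts[:, 0], window)
    peth = PETHMatrix(
        values=values,
        window=window,
        bin_width=binned.bin_width,
        baseline_rule="mean(-1,0)s subtracted",
        normalization=normalization or {"stats": "consumption"},
        n_events=used,
        n_dropped=dropped,
    )
    base = peth.values[:, peth.lag_slice(-1.0, 0.0)].mean(axis=1, keepdims=True)
    peth.values = peth.values - base
    return peth


def delay_stats(
    binned: BinnedSpikes, events: EventLog, final_minutes: float | None = 20.0
) -> NormStats:
    """Normalization statistics from the delay period.

    By default only the final ``final_minutes`` of the delay are used (the
    segment immediately preceding the malaise signal); pass ``None`` for the
    full delay.
    """
    delay = events.epochs["delay"]
    start = delay.start if final_minutes is None else max(delay.start, delay.end - 60.0 * final_minutes)
    stats = epoch_stats(binned, Epoch("delay-final", start, delay.end))
    stats.provenance["epoch"] = (
        "delay" if final_minutes is None else f"delay-final-{final_minutes:g}min"
    )
    return stats


def whole_experiment_trace(
    binned: BinnedSpikes,
    events: EventLog,
    stats: NormStats,
    spans_min: tuple[float, float, float] = (15.0, 30.0, 45.0),
) -> np.ndarray:
    """Minute-resolution whole-experiment trace.

    Concatenates the final ``spans_min[0]`` minutes of consumption, the first
    ``spans_min[1]`` minutes of delay and the first ``spans_min[2]`` minutes
    of the stimulation/malaise period of 10-ms binned spiking, z-scores the
    concatenated counts with ``stats`` (delay-derived), and downsamples to
    one sample per minute.
    """
    cons = events.epochs["consumption"]
    delay = events.epochs["delay"]
    mal = events.epochs.get("stimulation") or events.epochs.get("malaise")
    if mal is None:
        raise InvalidInputError("session has no stimulation/malaise epoch")
    segs = []
    for ep, want_min, anchor in (
        (cons, spans_min[0], "end"),
        (delay, spans_min[1], "start"),
        (mal, spans_min[2], "start"),
    ):
        want = 60.0 * want_min
        if ep.duration < want - 1e-9:
            warnings.warn(
                f"epoch {ep.label!r} shorter than requested {want_min:g} min; truncating",
                RuntimeWarning,
                stacklevel=2,
            )
            want = ep.duration
        n_want = int(round(want / binned.bin_width))
        sl = binned.bin_slice(ep.start, ep.end)
        if anchor == "end":
            k0, k1 = sl.stop - n_want, sl.stop
        else:
            k0, k1 = sl.start, sl.start + n_want
        segs.append(binned.counts[:, max(k0, 0) : k1])
    counts = np.concatenate(segs, axis=1)
    sub = BinnedSpikes(counts=counts, bin_width=binned.bin_width, t0=0.0, unit_ids=binned.unit_ids)
    z = zscore_with_stats(sub, stats)
    return downsample_mean(z, int(round(60.0 / binned.bin_width)))


def delay_event_trace(
    binned: BinnedSpikes,
    events: EventLog,
    t_event: float,
    stats: NormStats,
    window_min: tuple[float, float] = (30.0, 45.0),
) -> np.ndarray:
    """Minute-resolution trace around a malaise-signal onset.

    Spans ``window_min[0]`` minutes before to ``window_min[1]`` minutes after
    ``t_event``, z-scored with delay statistics (final 20 min by default via
    :func:`delay_stats`).
    """
    pre, post = 60.0 * window_min[0], 60.0 * window_min[1]
    if t_event - pre < binned.t0 - 1e-9 or events.epochs["delay"].duration < 1200.0 - 1e-9:
        raise InvalidInputError("insufficient pre-event data for the delay-event trace")
    sl = binned.bin_slice(t_event - pre, min(t_event + post, binned.t_end))
    sub = BinnedSpikes(
        counts=binned.counts[:, sl], bin_width=binned.bin_width, t0=0.0, unit_ids=binned.unit_ids
    )
    z = zscore_with_stats(sub, stats)
    return downsample_mean(z, int(round(60.0 / binned.bin_width)))


def scalar_response(trace: np.ndarray, rule: str, event_sample: int | None = None) -> np.ndarray:
    """Scalar per-neuron response under a named rule.

    ``trace`` is a minute-resolution matrix as produced by
    :func:`delay_event_trace` (``event_sample`` marks the event minute;
    defaults to the sample at the boundary of the standard 30-min pre
    window).

    Rules: ``cgrp_45min`` -- mean over minutes 0-45 after the event;
    ``licl_5_15min`` -- mean over minutes +5 to +15 after the event.
    """
    trace = np.atleast_2d(np.asarray(trace, dtype=float))
    if event_sample is None:
        event_sample = 30
    if rule == "cgrp_45min":
        a, b = event_sample, event_sample + 45
    elif rule == "licl_5_15min":
        a, b = event_sample + 5, event_sample + 15
    else:
        raise InvalidInputError(f"unknown scalar-response rule {rule!r}")
    if b > trace.shape[1]:
        raise InvalidInputError(f"trace too short for rule {rule!r}")
    return trace[:, a:b].mean(axis=1)


def reward_scalar_response(
    responses_post: np.ndarray, responses_baseline: np.ndarray | None = None
) -> np.ndarray:
    """Mean 10-s post-reward response, optionally per-trial baseline subtracted.

    ``responses_post`` holds per-trial mean z over (0, +10] s; the optional
    ``responses_baseline`` holds per-trial means over (-10, -5) s.
    """
    post = np.asarray(responses_post, dtype=float)
    if responses_baseline is not None:
        post = post - np.asarray(responses_baseline, dtype=float)
    return post.mean(axis=1)
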