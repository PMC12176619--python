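"""Classification of neurons as flavour-preferring, water-preferring or nonselective.

Per neuron, the mean normalized activity in the 10 s following each reward
delivery is compared between flavour and water trials with a Wilcoxon
rank-sum test; the resulting p-values are corrected across all pooled
neurons with the two-stage Benjamini-Krieger-Yekutieli step-up procedure at
a 5% false-discovery rate, and rejected neurons are labelled by the sign of
(mean flavour response - mean water response).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import BinnedSpikes, EventLog, InvalidInputError, NormStats


@dataclass
class TrialResponses:
    """Per-neuron, per-trial mean responses grouped by port."""

    flavour: np.ndarray  # neurons x flavour trials
    water: np.ndarray  # neurons x water trials
    window: float = 10.0


@dataclass
class SelectivityLabels:
    labels: np.ndarray  # 'flavour' | 'water' | 'nonselective'
    statistic: np.ndarray  # centered rank-sum statistic (U - n1*n2/2)
    pvalue: np.ndarray
    mean_flavour: np.ndarray
    mean_water: np.ndarray
    rejected: np.ndarray  # FDR-rejected mask
    unclassifiable: np.ndarray | None = None

    def fraction(self, label: str) -> float:
        return float(np.mean(self.labels == label))


def _aligned_window(t0: float, bin_width: float, n_bins: int, a: float, b: float) -> tuple[int, int]:
    """Bin-index span of bins wholly inside (a, b]; clipped to the matrix."""
    k0 = int(np.ceil((a - t0) / bin_width - 1e-9))
    k1 = int(np.floor((b - t0) / bin_width + 1e-9))
    return max(k0, 0), min(k1, n_bins)


def trial_response_matrix(
    z: np.ndarray,
    binned: BinnedSpikes,
    events: EventLog,
    window: float = 10.0,
) -> TrialResponses:
    """Mean z-scored activity over ``(delivery, delivery + window]`` per trial.

    ``z`` must be the matrix produced by normalizing ``binned`` over the
    consumption period.  Windows extending past the end of the matrix are
    truncated with a warning.
    """
    out = {}
    for port in ("flavour", "water"):
        deliveries = events.rewards_for_port(port)
        if deliveries.size == 0:
            raise InvalidInputError(f"no reward deliveries for port {port!r}")
        resp = np.empty((z.shape[0], deliveries.size))
        for i, t in enumerate(deliveries):
            k0, k1 = _aligned_window(binned.t0, binned.bin_width, binned.n_bins, t, t + window)
            if t + window > binned.t_end + 1e-9:
                warnings.warn(
                    "response window truncated by the end of the recording",
                    RuntimeWarning,
                    stacklevel=2,
                )
            resp[:, i] = z[:, k0:k1].mean(axis=1)
        out[port] = resp
    return TrialResponses(flavour=out["flavour"], water=out["water"], window=window)


def spike_count_stats(
    spike_times: list[np.ndarray], start: float, end: float, bin_width: float = 0.010
) -> NormStats:
    """Mean/population-s.d. of binned counts without materializing the matrix.

    Equivalent to ``epoch_stats(bin_spikes(...), epoch)`` but computed from
    the sparse spike times; used for large null simulations.
    """
    n_bins = int(np.floor((end - start) / bin_width + 1e-9))
    means = np.empty(len(spike_times))
    sds = np.empty(len(spike_times))
    for u, t in enumerate(spike_times):
        t = t[(t >= start) & (t < start + n_bins * bin_width)]
        if t.size:
            idx = ((t - start) / bin_width).astype(np.int64)
            _, counts = np.unique(idx, return_counts=True)
            s1 = counts.sum()
            s2 = float((counts.astype(float) ** 2).sum())
        else:
            s1, s2 = 0, 0.0
        mu = s1 / n_bins
        means[u] = mu
        sds[u] = np.sqrt(max(s2 / n_bins - mu * mu, 0.0))
    return NormStats(
        mean=means,
        sd=sds,
        provenance={"epoch": "consumption", "bin_width": bin_width, "sd_convention": "population",
                    "epoch_start": start, "epoch_end": end},
    )


def trial_responses_from_spikes(
    spike_times: list[np.ndarray],
    events: EventLog,
    stats: NormStats,
    window: float = 10.0,
    t0: float = 0.0,
    bin_width: float = 0.010,
    baseline_window: tuple[float, float] | None = None,
) -> TrialResponses:
    """Spike-domain equivalent of :func:`trial_response_matrix`.

    The mean z over a bin-aligned window equals ``(count / n_bins - mean) / sd``,
    so responses can be computed directly from spike counts.  With
    ``baseline_window`` set (seconds relative to delivery), each trial's mean
    z over that window is subtracted (per-trial baseline subtraction).
    """
    sd = np.where(stats.sd > 0, stats.sd, 1.0)
    zero = stats.sd == 0

    def window_mean_z(deliveries: np.ndarray, a_off: float, b_off: float) -> np.ndarray:
        k0 = np.ceil((deliveries + a_off - t0) / bin_width - 1e-9).astype(np.int64)
        k1 = np.floor((deliveries + b_off - t0) / bin_width + 1e-9).astype(np.int64)
        starts = t0 + k0 * bin_width
        ends = t0 + k1 * bin_width
        n_bins = np.maximum(k1 - k0, 1)
        resp = np.empty((len(spike_times), deliveries.size))
        for u, t in enumerate(spike_times):
            c = np.searchsorted(t, ends) - np.searchsorted(t, starts)
            resp[u] = (c / n_bins - stats.mean[u]) / sd[u]
        resp[zero] = 0.0
        return resp

    out = {}
    for port in ("flavour", "water"):
        deliveries = events.rewards_for_port(port)
        if deliveries.size == 0:
            raise InvalidInputError(f"no reward deliveries for port {port!r}")
        resp = window_mean_z(deliveries, 0.0, window)
        if baseline_window is not None:
            resp = resp - window_mean_z(deliveries, baseline_window[0], baseline_window[1])
        out[port] = resp
    return TrialResponses(flavour=out["flavour"], water=out["water"], window=window)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum test (midranks for ties).

    Returns the centered statistic ``U1 - n1*n2/2`` and the two-sided p-value
    from the tie-corrected normal approximation with continuity correction.
    If all values in both samples are identical, p is 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise InvalidInputError("both samples must be non-empty")
    centered_offset = x.size * y.size / 2.0
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return float(res.statistic - centered_offset), float(res.pvalue)


def bky_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Two-stage Benjamini-Krieger-Yekutieli adaptive step-up procedure.

    Stage 1 runs a linear (Benjamini-Hochberg) step-up at ``q' = q/(1+q)``
    to estimate the number of true nulls; stage 2 re-runs the step-up at
    the adjusted level ``q' * m / m0_hat``.  Returns a boolean rejection
    mask.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidInputError("p-values must lie in [0, 1]")
    m = p.size
    q1 = q / (1.0 + q)
    r1 = _bh_step_up(p, q1)
    if r1.sum() == 0:
        return r1
    if r1.sum() == m:
        return r1
    m0_hat = m - int(r1.sum())
    return _bh_step_up(p, q1 * m / m0_hat)


def _bh_step_up(p: np.ndarray, level: float) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = level * np.arange(1, m + 1) / m
    below = p[order] <= thresh
    mask = np.zeros(m, dtype=bool)
    if np.any(below):
        k = int(np.max(np.nonzero(below)[0]))
        mask[order[: k + 1]] = True
    return mask


def classify_selectivity(
    responses: TrialResponses, q: float = 0.05, min_trials: int = 2
) -> SelectivityLabels:
    """Label neurons from their per-trial responses under FDR control.

    Neurons with fewer than ``min_trials`` trials in either port are flagged
    unclassifiable (labelled nonselective and excluded from the FDR pool).
    Rejected neurons whose mean flavour response strictly exceeds the mean
    water response are flavour-preferring; exact ties fall to water.
    """
    n = responses.flavour.shape[0]
    stat = np.zeros(n)
    p = np.ones(n)
    unclassifiable = np.zeros(n, dtype=bool)
    mean_f = np.zeros(n)
    mean_w = np.zeros(n)
    for u in range(n):
        xf = responses.flavour[u][~np.isnan(responses.flavour[u])]
        xw = responses.water[u][~np.isnan(responses.water[u])]
        if xf.size < min_trials or xw.size < min_trials:
            unclassifiable[u] = True
            continue
        stat[u], p[u] = rank_sum_test(xf, xw)
        mean_f[u] = xf.mean()
        mean_w[u] = xw.mean()
    rejected = np.zeros(n, dtype=bool)
    pool = ~unclassifiable
    if pool.any():
        rejected[pool] = bky_fdr(p[pool], q)
    labels = np.where(
        rejected & (mean_f > mean_w), "flavour", np.where(rejected, "water", "nonselective")
    ).astype(object)
    return SelectivityLabels(
        labels=labels,
        statistic=stat,
        pvalue=p,
        mean_flavour=mean_f,
        mean_water=mean_w,
        rejected=rejected,
        unclassifiable=unclassifiable,
    )
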