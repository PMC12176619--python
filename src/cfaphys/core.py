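"""Shared time-series data model and primitives.

All times are session-clock seconds (double precision) with the origin at
the start of the acclimation period.  Spiking is represented either as
per-unit spike-time arrays or as a :class:`BinnedSpikes` count matrix with
10-ms bins (the resolution used throughout the downstream analyses).  Bins
are left-closed / right-open, so a spike exactly at the right edge of the
binned range is dropped; this makes spike-count conservation unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DEFAULT_BIN_WIDTH = 0.010
#: Grid-snapping tolerance when mapping continuous times onto bin indices.
_EDGE_EPS = 1e-9


class InvalidInputError(ValueError):
    """Raised when an operation receives arguments outside its contract."""


@dataclass(frozen=True)
class Epoch:
    """A named, half-open interval ``[start, end)`` of the session."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise InvalidInputError(
                f"epoch {self.label!r}: start ({self.start}) must precede end ({self.end})"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class EventLog:
    """Typed timeline of task events for one session.

    ``cue_onsets``, ``reward_deliveries`` and ``port_entries`` are pairs of
    parallel arrays (times in seconds, port labels).  ``stim_bouts`` is an
    ``(n, 2)`` array of bout ``(onset, offset)`` pairs.  ``epochs`` maps
    labels (``consumption``, ``delay`` and ``stimulation`` or ``malaise``)
    to :class:`Epoch` objects.
    """

    cue_times: np.ndarray
    cue_ports: np.ndarray
    reward_times: np.ndarray
    reward_ports: np.ndarray
    entry_times: np.ndarray
    entry_ports: np.ndarray
    stim_bouts: np.ndarray  # shape (n, 2)
    epochs: dict[str, Epoch]
    injection_time: float | None = None

    PORTS = ("flavour", "water")

    def __post_init__(self) -> None:
        self.cue_times = np.asarray(self.cue_times, dtype=float)
        self.reward_times = np.asarray(self.reward_times, dtype=float)
        self.entry_times = np.asarray(self.entry_times, dtype=float)
        self.cue_ports = np.asarray(self.cue_ports, dtype=object)
        self.reward_ports = np.asarray(self.reward_ports, dtype=object)
        self.entry_ports = np.asarray(self.entry_ports, dtype=object)
        self.stim_bouts = np.asarray(self.stim_bouts, dtype=float).reshape(-1, 2)

    def validate(self) -> None:
        """Check the event-log invariants; raise ``InvalidInputError`` on failure."""
        for name in ("cue_times", "reward_times", "entry_times"):
            t = getattr(self, name)
            if t.size and np.any(np.diff(t) < 0):
                raise InvalidInputError(f"{name} must be non-decreasing")
        for port in np.concatenate([self.cue_ports, self.reward_ports]):
            if port not in self.PORTS:
                raise InvalidInputError(f"unknown port label {port!r}")
        required = ["consumption", "delay"]
        malaise_label = "stimulation" if "stimulation" in self.epochs else "malaise"
        if malaise_label in self.epochs:
            required.append(malaise_label)
        prev_end = -np.inf
        for label in required:
            if label not in self.epochs:
                raise InvalidInputError(f"missing epoch {label!r}")
            ep = self.epochs[label]
            if ep.start < prev_end:
                raise InvalidInputError(f"epoch {label!r} overlaps its predecessor")
            prev_end = ep.end
        cons = self.epochs["consumption"]
        if self.reward_times.size and not (
            np.all(self.reward_times >= cons.start) and np.all(self.reward_times < cons.end)
        ):
            raise InvalidInputError("reward deliveries must lie inside the consumption epoch")
        if self.stim_bouts.size:
            stim = self.epochs.get("stimulation")
            if stim is None:
                raise InvalidInputError("stim bouts present but no stimulation epoch")
            if np.any(self.stim_bouts[:, 0] < stim.start) or np.any(
                self.stim_bouts[:, 1] > stim.end
            ):
                raise InvalidInputError("stim bouts must lie inside the stimulation epoch")
            if np.any(self.stim_bouts[:, 1] <= self.stim_bouts[:, 0]):
                raise InvalidInputError("stim bout offsets must follow onsets")

    @property
    def session_end(self) -> float:
        ends = [ep.end for ep in self.epochs.values()]
        if self.injection_time is not None:
            ends.append(self.injection_time)
        return max(ends)

    def rewards_for_port(self, port: str) -> np.ndarray:
        return self.reward_times[self.reward_ports == port]


@dataclass
class UnitMeta:
    """Per-unit curation metrics from the spike-sorting pipeline."""

    unit_id: int
    median_amplitude: float  # template-scaling amplitude, uV
    fp_rate: float  # refractory-violation false-positive estimate (fraction)
    firing_rate: float  # spikes / s
    curation_label: str = "good"  # 'good' or 'mua'
    region_label: str = "CEA"


@dataclass
class NormStats:
    """Per-neuron normalization statistics with provenance.

    ``sd`` is the population (divide-by-N) standard deviation of the counts
    used to derive the statistics; the granularity (bin width) and source
    epoch are recorded so that downstream stages can verify they reuse the
    correct normalization (for example day-1 statistics on day-2 data).
    """

    mean: np.ndarray
    sd: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape:
            raise InvalidInputError("mean and sd must have equal length")
        if np.any(self.sd < 0):
            raise InvalidInputError("sd must be non-negative")

    @property
    def n_neurons(self) -> int:
        return self.mean.size


@dataclass
class BinnedSpikes:
    """Neurons x bins spike-count matrix.

    Bin ``k`` covers ``[t0 + k*bin_width, t0 + (k+1)*bin_width)``.
    """

    counts: np.ndarray
    bin_width: float
    t0: float
    unit_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.unit_ids = np.asarray(self.unit_ids)
        if self.counts.ndim != 2:
            raise InvalidInputError("counts must be a 2-D neurons x bins matrix")
        if np.any(self.counts < 0):
            raise InvalidInputError("counts must be non-negative")
        if self.unit_ids.size != self.counts.shape[0]:
            raise InvalidInputError("unit_ids length must match neuron count")

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def t_end(self) -> float:
        return self.t0 + self.n_bins * self.bin_width

    def bin_times(self) -> np.ndarray:
        """Left edges of every bin."""
        return self.t0 + np.arange(self.n_bins) * self.bin_width

    def bin_slice(self, start: float, end: float) -> slice:
        """Indices of bins lying wholly inside ``[start, end)``."""
        k0 = int(np.ceil((start - self.t0) / self.bin_width - _EDGE_EPS))
        k1 = int(np.floor((end - self.t0) / self.bin_width + _EDGE_EPS))
        return slice(max(k0, 0), min(k1, self.n_bins))


def bin_spikes(
    spike_times: Sequence[np.ndarray],
    bin_width: float = DEFAULT_BIN_WIDTH,
    t_range: tuple[float, float] = (0.0, None),
    unit_ids: Sequence | None = None,
    dtype=np.int16,
) -> BinnedSpikes:
    """Bin per-unit spike times into a counts matrix over ``[start, end)``.

    Spikes outside ``t_range`` are dropped; the total of the count matrix
    equals the number of in-range spikes.
    """
    if bin_width <= 0:
        raise InvalidInputError("bin_width must be positive")
    if len(spike_times) == 0:
        raise InvalidInputError("at least one unit is required")
    start, end = t_range
    if end is None:
        end = max((float(t[-1]) if len(t) else 0.0) for t in spike_times) + bin_width
    if not (start < end):
        raise InvalidInputError("t_range start must precede end")
    n_bins = int(np.ceil((end - start) / bin_width - _EDGE_EPS))
    edges = start + np.arange(n_bins + 1) * bin_width
    # keep the covered range within [start, end): the final bin may be partial
    # only when (end-start) is not a multiple of bin_width, in which case it
    # still only collects spikes below `end`.
    counts = np.zeros((len(spike_times), n_bins), dtype=dtype)
    for u, t in enumerate(spike_times):
        t = np.asarray(t, dtype=float)
        if not np.all(np.isfinite(t)):
            raise InvalidInputError(f"unit {u}: spike times must be finite")
        t = t[(t >= start) & (t < end)]
        if t.size:
            idx = np.minimum(((t - start) / bin_width).astype(np.int64), n_bins - 1)
            counts[u] = np.bincount(idx, minlength=n_bins).astype(dtype)
    ids = np.arange(len(spike_times)) if unit_ids is None else np.asarray(unit_ids)
    return BinnedSpikes(counts=counts, bin_width=bin_width, t0=float(start), unit_ids=ids)


def epoch_stats(binned: BinnedSpikes, epoch: Epoch) -> NormStats:
    """Per-neuron mean and population s.d. of counts in bins wholly inside ``epoch``."""
    sl = binned.bin_slice(epoch.start, epoch.end)
    n = sl.stop - sl.start
    if n < 2:
        raise InvalidInputError(
            f"epoch {epoch.label!r} overlaps the binned range by {n} bins (< 2)"
        )
    block = binned.counts[:, sl].astype(float)
    mean = block.mean(axis=1)
    sd = block.std(axis=1)  # population (divide-by-N) convention
    flagged = np.flatnonzero(sd == 0)
    if flagged.size:
        warnings.warn(
            f"{flagged.size} neuron(s) have zero-variance counts in epoch {epoch.label!r}",
            RuntimeWarning,
            stacklevel=2,
        )
    return NormStats(
        mean=mean,
        sd=sd,
        provenance={
            "epoch": epoch.label,
            "epoch_start": epoch.start,
            "epoch_end": epoch.end,
            "bin_width": binned.bin_width,
            "sd_convention": "population",
            "zero_sd_units": flagged.tolist(),
        },
    )


def zscore_with_stats(binned: BinnedSpikes, stats: NormStats, dtype=np.float32) -> np.ndarray:
    """Z-score counts per neuron with precomputed stats.

    Neurons with ``sd == 0`` produce all-zero rows (with a warning) rather
    than propagating infinities.
    """
    if stats.n_neurons != binned.n_neurons:
        raise InvalidInputError(
            f"stats cover {stats.n_neurons} neurons but counts have {binned.n_neurons}"
        )
    sd = stats.sd.copy()
    zero = sd == 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} neuron(s) have sd=0; their z-scored rows are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        sd[zero] = 1.0
    z = (binned.counts.astype(dtype) - stats.mean[:, None].astype(dtype)) / sd[:, None].astype(
        dtype
    )
    z[zero] = 0.0
    return z


def half_gaussian_kernel(sd: float, bin_width: float) -> np.ndarray:
    """Right half (lag >= 0) of a Gaussian, truncated at 4*sd, unit sum."""
    if sd <= 0:
        raise InvalidInputError("sd must be positive")
    n_lags = int(np.floor(4.0 * sd / bin_width + _EDGE_EPS))
    lags = np.arange(n_lags + 1) * bin_width
    k = np.exp(-0.5 * (lags / sd) ** 2)
    return k / k.sum()


def causal_half_gaussian_smooth(
    trace: np.ndarray, sd: float, bin_width: float = DEFAULT_BIN_WIDTH
) -> np.ndarray:
    """Causal smoothing with a half-Gaussian kernel (current and past samples).

    Output sample ``n`` is a weighted mean of samples ``n-m .. n``; near the
    start of the trace the kernel is renormalized over the available samples
    so that constant inputs are preserved exactly.  Works on 1-D traces or
    row-wise on 2-D arrays.
    """
    trace = np.asarray(trace, dtype=float)
    k = half_gaussian_kernel(sd, bin_width)
    if trace.ndim == 1:
        return _causal_convolve(trace[None, :], k)[0]
    return _causal_convolve(trace, k)


def _causal_convolve(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    n = x.shape[1]
    m = kernel.size
    full = np.apply_along_axis(lambda r: np.convolve(r, kernel), 1, x)[:, :n]
    # renormalize the first m-1 samples by the cumulative kernel mass so the
    # smoother is mass-preserving right from the first sample
    norm = np.ones(n)
    edge = min(m - 1, n)
    if edge > 0:
        norm[:edge] = np.cumsum(kernel)[:edge]
    return full / norm


def downsample_mean(trace: np.ndarray, factor: int) -> np.ndarray:
    """Non-overlapping block means; a trailing partial block is averaged over
    its actual length.  Works on 1-D traces or row-wise on 2-D arrays."""
    if factor < 1 or int(factor) != factor:
        raise InvalidInputError("factor must be an integer >= 1")
    factor = int(factor)
    trace = np.asarray(trace, dtype=float)
    one_d = trace.ndim == 1
    x = trace[None, :] if one_d else trace
    n = x.shape[1]
    n_full = n // factor
    out_parts = []
    if n_full:
        out_parts.append(x[:, : n_full * factor].reshape(x.shape[0], n_full, factor).mean(axis=2))
    if n % factor:
        out_parts.append(x[:, n_full * factor :].mean(axis=1, keepdims=True))
    out = np.concatenate(out_parts, axis=1) if out_parts else np.empty((x.shape[0], 0))
    return out[0] if one_d else out


# --- unit quality -----------------------------------------------------------

AMPLITUDE_FLOOR_UV = 20.0
FP_RATE_CEILING = 1.0
FIRING_RATE_FLOOR = 0.05
SINGLE_UNIT_FP_MAX = 0.10


def unit_quality_filter(meta: Sequence[UnitMeta]) -> tuple[np.ndarray, np.ndarray]:
    """Apply the standard unit-inclusion criteria.

    Units are excluded as noise when the median template-scaling amplitude is
    below 20 uV, the estimated refractory false-positive rate exceeds 100%,
    or the firing rate is below 0.05 sp/s.  Among included units, those
    curated as 'good' with a false-positive rate below 10% count as single
    units; the rest are multiunits.  Returns ``(included, single_unit)``
    boolean masks (``single_unit`` implies ``included``).
    """
    amp = np.array([m.median_amplitude for m in meta], dtype=float)
    fp = np.array([m.fp_rate for m in meta], dtype=float)
    rate = np.array([m.firing_rate for m in meta], dtype=float)
    good = np.array([m.curation_label == "good" for m in meta])
    if np.any(amp < 0) or np.any(fp < 0) or np.any(rate < 0):
        raise InvalidInputError("unit metrics must be non-negative")
    included = (amp >= AMPLITUDE_FLOOR_UV) & (fp <= FP_RATE_CEILING) & (rate >= FIRING_RATE_FLOOR)
    single = included & good & (fp < SINGLE_UNIT_FP_MAX)
    return included, single


def refractory_fp_rate(
    spike_times: np.ndarray,
    duration: float,
    refractory_s: float = 0.002,
    censored_s: float = 0.0,
) -> float:
    """Reference false-positive (contamination) estimate from refractory violations.

    Uses the standard violation-rate estimator: assuming contaminating spikes
    occur independently of the true train, the expected number of inter-spike
    intervals shorter than the refractory period is
    ``2 * (t_ref - t_cens) * n^2 * fp / T``, which is solved linearly for
    ``fp``.  The estimate may exceed 1 for heavily contaminated clusters;
    callers treat values above 1 as noise.
    """
    t = np.sort(np.asarray(spike_times, dtype=float))
    n = t.size
    if n < 2 or duration <= 0:
        return 0.0
    isi = np.diff(t)
    n_viol = int(np.sum(isi < refractory_s))
    window = 2.0 * (refractory_s - censored_s) * n * n
    if window <= 0:
        return 0.0
    return n_viol * duration / window


def two_bottle_preference(flavour_g: float, water_g: float) -> float:
    """Two-bottle flavour preference: flavour / (flavour + water)."""
    if flavour_g < 0 or water_g < 0:
        raise InvalidInputError("consumed weights must be non-negative")
    total = flavour_g + water_g
    if total == 0:
        raise InvalidInputError("preference undefined: nothing was consumed")
    return flavour_g / total
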