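"""Population decoder for flavour reactivation detection.

A three-class (flavour / water / baseline) multinomial logistic regression
is trained on consumption-period population vectors: 1-s spike counts after
each reward delivery (labelled by port) and 1-s counts before each cue
onset (baseline), normalized per neuron by subtracting the mean pre-cue
count and dividing by the s.d. of 1-s counts tiled over the consumption
period.  Training minimizes the total multinomial negative log-likelihood
plus ``lambda * sum(|weights|)`` (intercepts unpenalized) with a monotone
proximal-gradient (FISTA-style) solver, so the objective trace is
non-increasing and the fit is deterministic.

The trained decoder is then evaluated over the whole session in 1-s sliding
windows stepped by 150 ms, with spike counts z-scored per neuron by their
delay-period 1-s-count statistics.  Strict local maxima of a class
posterior exceeding 0.5 are reactivation events, counted in 1-min windows
stepped by 30 s to give a reactivation rate in events per minute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import BinnedSpikes, EventLog, InvalidInputError, NormStats

CLASSES = ("flavour", "water", "baseline")


@dataclass
class DecoderModel:
    classes: tuple[str, ...]
    weights: np.ndarray  # classes x neurons
    intercepts: np.ndarray  # classes
    lam: float
    training_stats: NormStats
    evaluation_stats: NormStats | None = None
    n_iter: int = 0
    converged: bool = True
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def posteriors(self, features: np.ndarray) -> np.ndarray:
        """Softmax class posteriors for feature rows; rows sum to 1."""
        logits = features @ self.weights.T + self.intercepts
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)


@dataclass
class PosteriorSeries:
    times: np.ndarray  # window centers, seconds
    posteriors: np.ndarray  # windows x classes
    classes: tuple[str, ...]
    window: float = 1.0
    step: float = 0.15

    def class_series(self, cls: str) -> np.ndarray:
        return self.posteriors[:, self.classes.index(cls)]


# --- training set -----------------------------------------------------------


def _window_counts_binned(
    binned: BinnedSpikes, starts: np.ndarray, width: float
) -> np.ndarray:
    """Spike counts per neuron in bin-aligned windows ``[start, start+width)``."""
    nb = int(round(width / binned.bin_width))
    k0 = np.floor((np.asarray(starts) - binned.t0) / binned.bin_width + 1e-9).astype(np.int64)
    out = np.empty((len(k0), binned.n_neurons))
    for i, k in enumerate(k0):
        if k < 0 or k + nb > binned.n_bins:
            raise InvalidInputError("count window outside the binned range")
        out[i] = binned.counts[:, k : k + nb].sum(axis=1)
    return out


def _window_counts_spikes(
    spike_times: list[np.ndarray], starts: np.ndarray, width: float
) -> np.ndarray:
    starts = np.asarray(starts, dtype=float)
    out = np.empty((starts.size, len(spike_times)))
    for u, t in enumerate(spike_times):
        out[:, u] = np.searchsorted(t, starts + width) - np.searchsorted(t, starts)
    return out


def one_second_count_stats(
    spike_times: list[np.ndarray], start: float, end: float, width: float = 1.0
) -> NormStats:
    """Mean/s.d. of counts in non-overlapping windows tiling ``[start, end)``."""
    n_win = int(np.floor((end - start) / width + 1e-9))
    if n_win < 2:
        raise InvalidInputError("need at least two tiling windows for count statistics")
    starts = start + width * np.arange(n_win)
    counts = _window_counts_spikes(spike_times, starts, width)
    return NormStats(
        mean=counts.mean(axis=0),
        sd=counts.std(axis=0),
        provenance={"window": width, "start": start, "end": end, "granularity": "tiled"},
    )


def build_training_set(
    spike_times: list[np.ndarray],
    events: EventLog,
    min_population: int = 75,
    window: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, NormStats]:
    """Assemble decoder training features from the consumption period.

    One feature vector per event: per-neuron spike counts within 1 s after
    each reward delivery (labelled flavour/water) and within 1 s before each
    cue onset (baseline), baseline-subtracted by the neuron's mean pre-cue
    count and divided by the s.d. of its 1-s counts tiled over the
    consumption period.  ``min_population`` optionally enforces the
    simultaneously-recorded population-size gate used for decoding.
    """
    n = len(spike_times)
    if min_population and n <= min_population:
        raise InvalidInputError(
            f"population of {n} neurons does not exceed the gate of {min_population}"
        )
    cons = events.epochs["consumption"]
    for port in ("flavour", "water"):
        if events.rewards_for_port(port).size == 0:
            raise InvalidInputError(f"no {port} deliveries in the consumption period")
    pre_cue = _window_counts_spikes(spike_times, events.cue_times - window, window)
    stats = one_second_count_stats(spike_times, cons.start, cons.end, window)
    sd = stats.sd.copy()
    zero = sd == 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} neuron(s) have zero 1-s count variance; features set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        sd[zero] = 1.0
    mean_pre = pre_cue.mean(axis=0)

    blocks, labels = [], []
    for cls, starts in (
        ("flavour", events.rewards_for_port("flavour")),
        ("water", events.rewards_for_port("water")),
        ("baseline", events.cue_times - window),
    ):
        counts = _window_counts_spikes(spike_times, starts, window)
        feats = (counts - mean_pre) / sd
        feats[:, zero] = 0.0
        blocks.append(feats)
        labels.extend([cls] * len(starts))
    train_stats = NormStats(
        mean=mean_pre,
        sd=stats.sd,
        provenance={
            "center": "mean pre-cue 1-s count",
            "scale": "s.d. of 1-s counts tiled over consumption",
            "window": window,
        },
    )
    return np.vstack(blocks), np.array(labels, dtype=object), train_stats


# --- L1 multinomial fit -----------------------------------------------------


def _nll_and_grad(
    W: np.ndarray, b: np.ndarray, X: np.ndarray, Y: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Total multinomial negative log-likelihood and its gradients."""
    logits = X @ W.T + b
    logits -= logits.max(axis=1, keepdims=True)
    logZ = np.log(np.exp(logits).sum(axis=1, keepdims=True))
    logp = logits - logZ
    nll = -float((Y * logp).sum())
    P = np.exp(logp)
    diff = P - Y
    return nll, diff.T @ X, diff.sum(axis=0)


def fit_multinomial_l1(
    features: np.ndarray,
    labels: np.ndarray,
    lam: float = 1.0,
    classes: tuple[str, ...] = CLASSES,
    max_iter: int = 5000,
    tol: float = 1e-6,
    training_stats: NormStats | None = None,
) -> DecoderModel:
    """Lasso-regularized multinomial logistic regression.

    Minimizes ``sum_i NLL_i + lam * sum|W|`` (intercepts unpenalized) with a
    monotone accelerated proximal-gradient method.  The recorded objective
    trace is non-increasing; non-convergence within ``max_iter`` returns the
    partial model flagged ``converged=False``.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=object)
    present = [c for c in classes if np.any(labels == c)]
    if len(present) < 2:
        raise InvalidInputError("at least two classes must be present")
    if lam < 0:
        raise InvalidInputError("lambda must be non-negative")
    K, d = len(classes), X.shape[1]
    Y = np.zeros((X.shape[0], K))
    for k, c in enumerate(classes):
        Y[labels == c, k] = 1.0
    if not np.all(Y.sum(axis=1) == 1.0):
        raise InvalidInputError("labels contain classes outside the class set")

    # Lipschitz bound for the multinomial NLL gradient: 0.5 * smax(X~)^2
    # with the intercept column appended.
    Xa = np.hstack([X, np.ones((X.shape[0], 1))])
    L = 0.5 * np.linalg.norm(Xa, 2) ** 2
    step = 1.0 / max(L, 1e-12)

    def objective(W, b):
        nll, _, _ = _nll_and_grad(W, b, X, Y)
        return nll + lam * np.abs(W).sum()

    W = np.zeros((K, d))
    b = np.zeros(K)
    Wm, bm = W.copy(), b.copy()  # momentum point
    t_acc = 1.0
    trace = [objective(W, b)]
    converged = False
    for it in range(max_iter):
        _, gW, gb = _nll_and_grad(Wm, bm, X, Y)
        W_new = Wm - step * gW
        W_new = np.sign(W_new) * np.maximum(np.abs(W_new) - step * lam, 0.0)
        b_new = bm - step * gb
        f_new = objective(W_new, b_new)
        if f_new > trace[-1]:
            # monotone safeguard: restart momentum from the best iterate
            _, gW, gb = _nll_and_grad(W, b, X, Y)
            W_new = W - step * gW
            W_new = np.sign(W_new) * np.maximum(np.abs(W_new) - step * lam, 0.0)
            b_new = b - step * gb
            f_new = objective(W_new, b_new)
            t_acc = 1.0
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc * t_acc))
        Wm = W_new + ((t_acc - 1.0) / t_next) * (W_new - W)
        bm = b_new + ((t_acc - 1.0) / t_next) * (b_new - b)
        t_acc = t_next
        rel = abs(trace[-1] - f_new) / max(1.0, abs(f_new))
        W, b = W_new, b_new
        trace.append(min(f_new, trace[-1]))
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"decoder fit did not converge within {max_iter} iterations", RuntimeWarning,
            stacklevel=2,
        )
    return DecoderModel(
        classes=tuple(classes),
        weights=W,
        intercepts=b,
        lam=lam,
        training_stats=training_stats
        or NormStats(mean=np.zeros(d), sd=np.ones(d), provenance={"source": "unspecified"}),
        n_iter=len(trace) - 1,
        converged=converged,
        objective_trace=np.array(trace),
    )


def lambda_grid(n: int = 9, lo: float = 1e-4, hi: float = 1e4) -> np.ndarray:
    """Logarithmically spaced penalty grid (default 1e-4 .. 1e4, nine values)."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


def cross_validate_lambda(
    features: np.ndarray,
    labels: np.ndarray,
    folds: int = 10,
    grid: np.ndarray | None = None,
    seed: int = 0,
    classes: tuple[str, ...] = CLASSES,
    max_iter: int = 2000,
) -> dict:
    """Stratified K-fold cross-validation over the penalty grid.

    Returns per-lambda mean held-out log-likelihood (per sample) and
    misclassification rate.  Fold assignment is stratified by class from an
    explicit seed, recorded in the output.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=object)
    if grid is None:
        grid = lambda_grid()
    present = [c for c in classes if np.any(y == c)]
    if len(present) < 2:
        raise InvalidInputError("cross-validation requires at least two classes")
    min_count = min(int(np.sum(y == c)) for c in present)
    if min_count < folds:
        warnings.warn(
            f"reducing folds from {folds} to {min_count} (smallest class size)",
            RuntimeWarning,
            stacklevel=2,
        )
        folds = min_count
    rng = np.random.default_rng(seed)
    fold_of = np.empty(y.size, dtype=int)
    for c in present:
        idx = rng.permutation(np.flatnonzero(y == c))
        fold_of[idx] = np.arange(idx.size) % folds
    ll = np.zeros((len(grid), folds))
    err = np.zeros((len(grid), folds))
    for gi, lam in enumerate(grid):
        for f in range(folds):
            tr, te = fold_of != f, fold_of == f
            model = fit_multinomial_l1(X[tr], y[tr], lam, classes=classes, max_iter=max_iter)
            P = model.posteriors(X[te])
            yi = np.array([model.classes.index(c) for c in y[te]])
            p_true = np.clip(P[np.arange(yi.size), yi], 1e-300, None)
            ll[gi, f] = float(np.mean(np.log(p_true)))
            err[gi, f] = float(np.mean(P.argmax(axis=1) != yi))
    return {
        "grid": np.asarray(grid),
        "mean_loglik": ll.mean(axis=1),
        "mean_misclassification": err.mean(axis=1),
        "folds": folds,
        "seed": seed,
    }


# --- session-wide evaluation ------------------------------------------------


def sliding_window_starts(t0: float, t_end: float, window: float = 1.0, step: float = 0.15
                          ) -> np.ndarray:
    """Window start times covering ``[t0, t_end)``; the number of windows is
    ``floor((T - window)/step) + 1`` for session length ``T``."""
    T = t_end - t0
    if T < window:
        raise InvalidInputError("window larger than the session")
    n = int(np.floor((T - window) / step + 1e-9)) + 1
    return t0 + step * np.arange(n)


def sliding_posteriors(
    model: DecoderModel,
    spike_times: list[np.ndarray] | BinnedSpikes,
    eval_stats: NormStats,
    t_range: tuple[float, float] | None = None,
    window: float = 1.0,
    step: float = 0.15,
) -> PosteriorSeries:
    """Evaluate the decoder in sliding windows across the session.

    Counts in each window are z-scored per neuron with the delay-period
    1-s-count statistics (``eval_stats``), then scored by the model.  Accepts
    either spike-time arrays or a :class:`BinnedSpikes` matrix (the window
    and step must then be multiples of the bin width).
    """
    if isinstance(spike_times, BinnedSpikes):
        t0 = spike_times.t0 if t_range is None else t_range[0]
        t_end = spike_times.t_end if t_range is None else t_range[1]
        starts = sliding_window_starts(t0, t_end, window, step)
        counts = _window_counts_binned(spike_times, starts, window)
    else:
        if t_range is None:
            raise InvalidInputError("t_range is required with spike-time input")
        starts = sliding_window_starts(t_range[0], t_range[1], window, step)
        counts = _window_counts_spikes(spike_times, starts, window)
    sd = np.where(eval_stats.sd > 0, eval_stats.sd, 1.0)
    feats = (counts - eval_stats.mean) / sd
    feats[:, eval_stats.sd == 0] = 0.0
    return PosteriorSeries(
        times=starts + window / 2.0,
        posteriors=model.posteriors(feats),
        classes=model.classes,
        window=window,
        step=step,
    )


def detect_reactivations(
    series: PosteriorSeries, cls: str, threshold: float = 0.5
) -> np.ndarray:
    """Times of strict local maxima of a class posterior above ``threshold``.

    A plateau contributes its first index; endpoints are eligible when they
    exceed their single neighbour.
    """
    p = series.class_series(cls)
    idx = peak_indices(p, threshold)
    return series.times[idx]


def peak_indices(values: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Indices of strict local maxima above ``threshold`` (plateau -> first index)."""
    v = np.asarray(values, dtype=float)
    n = v.size
    out = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left_ok = i == 0 or v[i - 1] < v[i]
        right_ok = j == n - 1 or v[j + 1] < v[i]
        if left_ok and right_ok and v[i] > threshold and not (i == 0 and j == n - 1):
            out.append(i)
        i = j + 1
    return np.array(out, dtype=int)


def reactivation_rate(
    event_times: np.ndarray,
    span: tuple[float, float],
    window: float = 60.0,
    step: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Events per minute in sliding 1-min windows stepped by 30 s.

    Returns ``(window_centers, rate)``; the rate is the event count per
    window scaled to events/min.
    """
    t = np.sort(np.asarray(event_times, dtype=float))
    starts = np.arange(span[0], span[1] - window + 1e-9, step)
    if starts.size == 0:
        raise InvalidInputError("span shorter than one rate window")
    counts = np.searchsorted(t, starts + window) - np.searchsorted(t, starts)
    return starts + window / 2.0, counts * (60.0 / window)
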