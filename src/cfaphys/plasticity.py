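"""Cross-day plasticity analyses and stimulation-response typing.

Tracked neurons are classified on day 1 only; per-day flavour responses are
per-trial baseline-subtracted (mean over -10 to -5 s before delivery) so
that a change in baseline firing rate across days does not masquerade as
plasticity.  The change in flavour response (day 2 - day 1) is regressed on
each neuron's stimulation-period response, separately per selectivity
class.  Stimulation-bout response shapes are typed with a four-component
diagonal-covariance Gaussian mixture fitted by EM with random-responsibility
restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import InvalidInputError
from .peth import PETHMatrix
from .selectivity import TrialResponses
from .simulate import substream

RESPONSE_TYPES = ("strongly activated", "weakly activated", "inhibited", "unmodulated")


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r: float
    pvalue: float
    slope_ci: tuple[float, float]  # 95% CI for the slope
    n: int


@dataclass
class PairedDayResult:
    delta_response: np.ndarray  # day2 - day1 flavour response per neuron
    delta_selectivity: np.ndarray  # day2 - day1 (flavour - water) response
    day1_response: np.ndarray
    day2_response: np.ndarray
    n_excluded: int = 0


@dataclass
class ResponseTypeModel:
    means: np.ndarray  # components x features
    variances: np.ndarray  # components x features (diagonal)
    weights: np.ndarray  # mixing weights, sum to 1
    assignments: np.ndarray  # hard component index per neuron
    type_of_component: np.ndarray  # semantic label per component
    log_likelihood: float
    ll_traces: list[np.ndarray]  # per-restart EM log-likelihood traces

    def labels(self) -> np.ndarray:
        return self.type_of_component[self.assignments]


def paired_day_responses(
    day1: TrialResponses,
    day1_baseline: TrialResponses,
    day2: TrialResponses,
    day2_baseline: TrialResponses,
    matched: np.ndarray | None = None,
) -> PairedDayResult:
    """Per-neuron change in flavour response and selectivity across days.

    ``dayN`` hold per-trial mean z over (0, +10] s post delivery and
    ``dayN_baseline`` the matching per-trial means over (-10, -5) s; the
    difference is averaged per day and differenced across days.  ``matched``
    optionally masks units tracked across both days; unmatched units are
    excluded and counted.
    """
    n = day1.flavour.shape[0]
    if day2.flavour.shape[0] != n:
        raise InvalidInputError("day matrices must cover the same unit set")
    keep = np.ones(n, dtype=bool) if matched is None else np.asarray(matched, bool)

    f1 = (day1.flavour - day1_baseline.flavour).mean(axis=1)
    w1 = (day1.water - day1_baseline.water).mean(axis=1)
    f2 = (day2.flavour - day2_baseline.flavour).mean(axis=1)
    w2 = (day2.water - day2_baseline.water).mean(axis=1)
    nan = np.full(n, np.nan)
    return PairedDayResult(
        delta_response=np.where(keep, f2 - f1, nan),
        delta_selectivity=np.where(keep, (f2 - w2) - (f1 - w1), nan),
        day1_response=np.where(keep, f1, nan),
        day2_response=np.where(keep, f2, nan),
        n_excluded=int((~keep).sum()),
    )


def delta_vs_cgrp_regression(
    delta: np.ndarray, cgrp_response: np.ndarray, mask: np.ndarray
) -> RegressionSummary:
    """OLS of response change on stimulation response within one class.

    Reports the slope with its t-based 95% confidence interval, the Pearson
    correlation and its two-sided p-value.
    """
    mask = np.asarray(mask, bool) & np.isfinite(delta) & np.isfinite(cgrp_response)
    x = np.asarray(cgrp_response, float)[mask]
    y = np.asarray(delta, float)[mask]
    if x.size < 3:
        raise InvalidInputError("need at least 3 neurons for the regression")
    if np.ptp(x) == 0:
        raise InvalidInputError("zero-variance predictor")
    res = sps.linregress(x, y)
    tcrit = sps.t.ppf(0.975, x.size - 2)
    return RegressionSummary(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        pvalue=float(res.pvalue),
        slope_ci=(float(res.slope - tcrit * res.stderr), float(res.slope + tcrit * res.stderr)),
        n=int(x.size),
    )


def selectivity_proportions_by_day(labels_day1, labels_day2) -> dict:
    """Per-day class fractions (classification run independently per day)."""
    out = {}
    for cls in ("flavour", "water", "nonselective"):
        f1 = float(np.mean(labels_day1.labels == cls))
        f2 = float(np.mean(labels_day2.labels == cls))
        out[cls] = {"day1": f1, "day2": f2, "paired_difference": f2 - f1}
    return out


# --- GMM response typing ----------------------------------------------------


def _em_fit(
    X: np.ndarray,
    resp0: np.ndarray,
    var_floor: float,
    max_iter: int = 200,
    tol: float = 1e-7,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One EM run from initial responsibilities; returns (ll, mu, var, w, trace)."""
    n, d = X.shape
    R = resp0
    trace = []
    ll_prev = -np.inf
    for _ in range(max_iter):
        nk = R.sum(axis=0) + 1e-12
        w = nk / n
        mu = (R.T @ X) / nk[:, None]
        var = (R.T @ (X**2)) / nk[:, None] - mu**2
        var = np.maximum(var, var_floor)
        # E step
        log_det = np.log(var).sum(axis=1)
        quad = (
            ((X**2) @ (1.0 / var).T)
            - 2.0 * (X @ (mu / var).T)
            + (mu**2 / var).sum(axis=1)
        )
        log_p = np.log(w) - 0.5 * (d * np.log(2 * np.pi) + log_det + quad)
        m = log_p.max(axis=1, keepdims=True)
        log_norm = m + np.log(np.exp(log_p - m).sum(axis=1, keepdims=True))
        ll = float(log_norm.sum())
        R = np.exp(log_p - log_norm)
        trace.append(ll)
        if ll - ll_prev < tol * max(1.0, abs(ll)) and len(trace) > 1:
            break
        ll_prev = ll
    return ll, mu, var, w, np.array(trace)


def gmm_response_types(
    stim_peths: PETHMatrix,
    n_components: int = 4,
    var_floor: float = 1e-5,
    replicates: int = 100,
    seed: int = 0,
    feature_window: tuple[float, float] = (0.0, 1.0),
) -> ResponseTypeModel:
    """Type stimulation responses with a diagonal-covariance Gaussian mixture.

    Features are the baseline-subtracted PETH bins in ``feature_window``
    (0 to +1 s during stimulation).  EM is restarted ``replicates`` times
    from random responsibilities, keeping the highest log-likelihood fit;
    the per-restart log-likelihood traces are recorded (each is
    non-decreasing by the EM guarantee).  Components are labelled
    semantically from their mean response: the most negative is inhibited,
    the one nearest zero among the rest is unmodulated, and the remaining
    two are strongly/weakly activated in magnitude order.  A warning is
    raised when the fitted structure does not match this expected pattern.
    """
    X = stim_peths.values[:, stim_peths.lag_slice(*feature_window)].astype(float)
    n = X.shape[0]
    if n < 4 * n_components:
        raise InvalidInputError("need at least 4x more neurons than mixture components")
    rng = substream(seed, "gmm")
    best = None
    traces = []
    for _ in range(replicates):
        R0 = rng.uniform(size=(n, n_components))
        R0 /= R0.sum(axis=1, keepdims=True)
        ll, mu, var, w, trace = _em_fit(X, R0, var_floor)
        traces.append(trace)
        if not np.isfinite(ll):
            continue
        if best is None or ll > best[0]:
            best = (ll, mu, var, w)
    if best is None:
        raise InvalidInputError("all EM restarts degenerated")
    ll, mu, var, w = best
    # hard assignments under the best model
    log_det = np.log(var).sum(axis=1)
    quad = ((X**2) @ (1.0 / var).T) - 2.0 * (X @ (mu / var).T) + (mu**2 / var).sum(axis=1)
    log_p = np.log(w) - 0.5 * (X.shape[1] * np.log(2 * np.pi) + log_det + quad)
    assignments = log_p.argmax(axis=1)

    comp_mean = mu.mean(axis=1)  # mean response over the stimulation window
    order = np.argsort(comp_mean)  # ascending
    type_of = np.empty(n_components, dtype=object)
    inhibited = order[0]
    type_of[inhibited] = "inhibited"
    rest = [k for k in range(n_components) if k != inhibited]
    unmod = rest[int(np.argmin(np.abs(comp_mean[rest])))]
    type_of[unmod] = "unmodulated"
    activated = sorted(
        (k for k in rest if k != unmod), key=lambda k: abs(comp_mean[k]), reverse=True
    )
    type_of[activated[0]] = "strongly activated"
    for k in activated[1:]:
        type_of[k] = "weakly activated"
    if comp_mean[inhibited] >= 0 or any(comp_mean[k] <= 0 for k in activated):
        warnings.warn(
            "fitted mixture does not show the expected two-activated/one-inhibited/"
            "one-unmodulated structure; labels assigned by rule anyway",
            RuntimeWarning,
            stacklevel=2,
        )
    return ResponseTypeModel(
        means=mu,
        variances=var,
        weights=w,
        assignments=assignments,
        type_of_component=type_of,
        log_likelihood=ll,
        ll_traces=traces,
    )
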