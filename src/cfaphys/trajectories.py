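"""Population-trajectory analysis of reward responses.

Trial-averaged, smoothed PETHs of the reward-selective neurons are baseline
subtracted (mean over -5 to -4 s before delivery, averaged across both
reward types), peak-normalized per neuron by the maximum absolute value
across both reward types, and the 0-5 s segments of the flavour and water
PETHs are concatenated into a neurons x 1000-bin matrix.  Every column
(time bin) is centred across neurons before extracting principal directions
in neuron space, so each component is a per-neuron loading vector and
population vectors at any time bin can be projected onto the component
axes.  The same frozen loadings and normalization constants are reused to
project a second day's activity or the stimulation-period PETH, making
trajectories comparable across conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import InvalidInputError
from .peth import PETHMatrix


@dataclass
class PCAResult:
    loadings: np.ndarray  # components x neurons, orthonormal rows
    variance_fraction: np.ndarray  # per component, non-increasing
    baseline_mean: np.ndarray  # per neuron, from the PCA input construction
    peak_value: np.ndarray  # per neuron, max |value| across both reward PETHs
    kept: np.ndarray  # mask of neurons retained (nonzero peak)
    sign_convention: str = "flavour-peak-positive"
    n_input_columns: int = 0

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def build_pca_input(
    flavour_peth: PETHMatrix,
    water_peth: PETHMatrix,
    selective_mask: np.ndarray,
    segment: tuple[float, float] = (0.0, 5.0),
    baseline_window: tuple[float, float] = (-5.0, -4.0),
) -> tuple[np.ndarray, dict]:
    """Concatenate normalized flavour and water PETH segments for PCA.

    Per selective neuron: subtract the baseline-window mean averaged across
    both reward types, divide by the maximum absolute value across both
    reward types, then concatenate the ``segment`` spans of the two PETHs.
    Neurons whose peak value is zero are dropped with a warning.
    """
    if flavour_peth.values.shape != water_peth.values.shape:
        raise InvalidInputError("flavour and water PETHs must have matching shapes")
    mask = np.asarray(selective_mask, dtype=bool)
    F = flavour_peth.values[mask]
    W = water_peth.values[mask]
    base_sl = flavour_peth.lag_slice(*baseline_window)
    baseline = 0.5 * (F[:, base_sl].mean(axis=1) + W[:, base_sl].mean(axis=1))
    Fb = F - baseline[:, None]
    Wb = W - baseline[:, None]
    peak = np.maximum(np.abs(Fb).max(axis=1), np.abs(Wb).max(axis=1))
    kept = peak > 0
    if not np.all(kept):
        warnings.warn(
            f"dropping {int((~kept).sum())} neuron(s) with zero peak value",
            RuntimeWarning,
            stacklevel=2,
        )
    seg_sl = flavour_peth.lag_slice(*segment)
    mat = np.concatenate(
        [Fb[kept][:, seg_sl] / peak[kept, None], Wb[kept][:, seg_sl] / peak[kept, None]], axis=1
    )
    record = {
        "baseline_mean": baseline,
        "peak_value": peak,
        "kept": kept,
        "baseline_window": baseline_window,
        "segment": segment,
        "n_flavour_columns": seg_sl.stop - seg_sl.start,
    }
    return mat, record


def fit_pca(
    matrix: np.ndarray,
    record: dict | None = None,
    n_components: int | None = None,
) -> PCAResult:
    """Principal directions in neuron space of the column-centred input.

    Time bins act as observations and neurons as variables: each column is
    centred across neurons and the singular directions of the centred matrix
    give per-neuron loading vectors with variance-explained fractions.  The
    sign of each component is fixed so that the flavour-segment projection's
    largest-magnitude value is positive (PCA signs are otherwise arbitrary).
    """
    X = np.asarray(matrix, dtype=float)
    n_neurons, n_cols = X.shape
    if n_neurons < 3:
        raise InvalidInputError("PCA requires at least 3 neurons")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    k_max = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    k = k_max if n_components is None else min(n_components, k_max)
    loadings = U[:, :k].T.copy()
    var_frac = (s[:k] ** 2) / (s**2).sum()
    # sign convention: the flavour trajectory's extreme projection is positive
    n_flav = record.get("n_flavour_columns", n_cols // 2) if record else n_cols // 2
    proj_f = loadings @ Xc[:, :n_flav]
    for j in range(k):
        extreme = proj_f[j, np.argmax(np.abs(proj_f[j]))]
        if extreme < 0:
            loadings[j] *= -1.0
    return PCAResult(
        loadings=loadings,
        variance_fraction=var_frac,
        baseline_mean=record["baseline_mean"] if record else np.zeros(n_neurons),
        peak_value=record["peak_value"] if record else np.ones(n_neurons),
        kept=record["kept"] if record else np.ones(n_neurons, dtype=bool),
        n_input_columns=n_cols,
    )


def _project_columns(pca: PCAResult, columns: np.ndarray) -> np.ndarray:
    """Centre population vectors across neurons and project onto the loadings."""
    centred = columns - columns.mean(axis=0, keepdims=True)
    return pca.loadings @ centred


def project_trajectory(
    peth: PETHMatrix,
    pca: PCAResult,
    selective_mask: np.ndarray | None = None,
    pre_normalized: bool = False,
) -> np.ndarray:
    """Project a population reward PETH into PC space.

    Unless ``pre_normalized``, the PETH is normalized with the SAME
    constants recorded in the PCA result (baseline means and peak values,
    e.g. day-1 constants for day-2 data).  Returns a components x lags
    trajectory.
    """
    vals = peth.values if selective_mask is None else peth.values[np.asarray(selective_mask, bool)]
    if not pre_normalized:
        if vals.shape[0] != pca.baseline_mean.size:
            raise InvalidInputError("neuron set does not match the PCA normalization record")
        vals = vals[pca.kept]
        vals = (vals - pca.baseline_mean[pca.kept, None]) / pca.peak_value[pca.kept, None]
    if vals.shape[0] != pca.loadings.shape[1]:
        raise InvalidInputError("neuron set does not match the PCA loadings")
    return _project_columns(pca, vals)


def project_stim_trajectory(
    stim_peth: PETHMatrix,
    pca: PCAResult,
    selective_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Project the stimulation-bout PETH into the consumption PC space.

    The stimulation PETH is baseline-subtracted over (-1, 0) s and
    peak-normalized by its OWN maximum absolute value per neuron (the
    stimulation response scale differs from the reward scale), then
    projected with the frozen consumption loadings.
    """
    vals = (
        stim_peth.values
        if selective_mask is None
        else stim_peth.values[np.asarray(selective_mask, bool)]
    )
    if vals.shape[0] != pca.kept.size:
        raise InvalidInputError("neuron set does not match the PCA normalization record")
    vals = vals[pca.kept]
    base = vals[:, stim_peth.lag_slice(-1.0, 0.0)].mean(axis=1, keepdims=True)
    vals = vals - base
    peak = np.abs(vals).max(axis=1, keepdims=True)
    peak[peak == 0] = 1.0
    return _project_columns(pca, vals / peak)


def trajectory_cosine(traj_a: np.ndarray, traj_b: np.ndarray) -> float:
    """Cosine similarity between the time-averaged PC vectors of two trajectories.

    Each trajectory is a components x lags array (typically restricted to
    post-event lags); averaging over lags gives one direction per trajectory
    in PC space, and the cosine of the angle between those directions
    summarizes how similar the evoked population states are.
    """
    a = np.asarray(traj_a, dtype=float).mean(axis=1)
    b = np.asarray(traj_b, dtype=float).mean(axis=1)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))
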