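"""End-to-end report runner: simulate -> classify -> PETH -> decode -> project.

``run_pipeline`` executes the stage chain on a simulated session, writes the
CSV/JSON artifacts of every stage and a run manifest (config hash, seeds and
file checksums) that makes the outputs reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .core import InvalidInputError, bin_spikes, epoch_stats, zscore_with_stats
from .decoder import (
    build_training_set,
    detect_reactivations,
    fit_multinomial_l1,
    one_second_count_stats,
    reactivation_rate,
    sliding_posteriors,
)
from .peth import reward_peth, stim_bout_peth
from .selectivity import classify_selectivity, trial_response_matrix
from .simulate import SimConfig, default_unit_meta, simulate_population, simulate_task_events
from .trajectories import build_pca_input, fit_pca, project_stim_trajectory, project_trajectory


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    files: dict[str, str]  # relative path -> sha256

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path) -> dict:
    text = Path(path).read_text()
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise InvalidInputError("config must be a mapping")
    unknown = set(cfg) - {"sim", "analysis"}
    if unknown:
        raise InvalidInputError(f"unknown top-level config keys: {sorted(unknown)}")
    if "sim" not in cfg:
        raise InvalidInputError("config is missing the required 'sim' section")
    return cfg


def run_pipeline(config: dict | str | Path, outdir, seed: int | None = None) -> RunManifest:
    """Run the full synthetic-session analysis chain and write all artifacts."""
    if not isinstance(config, dict):
        config = load_config(config)
    sim_cfg = SimConfig.from_dict(config.get("sim", {}))
    analysis = config.get("analysis", {})
    lam = float(analysis.get("lambda", 1.0))
    q = float(analysis.get("fdr_q", 0.05))
    if seed is not None:
        sim_cfg.seed = seed
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate ---
    events = simulate_task_events(sim_cfg)
    spikes, truth = simulate_population(sim_cfg, events)
    io.write_events(out / "events.csv", out / "epochs.json", events)
    io.write_spikes_csv(out / "spikes.csv", spikes)
    io.write_unit_meta_csv(out / "unit_meta.csv", default_unit_meta(truth))
    pd.DataFrame(
        {
            "unit_id": np.arange(sim_cfg.n_neurons),
            "label": truth.labels,
            "baseline_rate": truth.baseline_rate,
            "reward_gain": truth.reward_gain,
            "bout_gain": truth.bout_gain,
        }
    ).to_csv(out / "ground_truth.csv", index=False, float_format="%.8g")

    # --- classify ---
    cons = events.epochs["consumption"]
    binned = bin_spikes(spikes, t_range=(0.0, events.session_end))
    cons_stats = epoch_stats(binned, cons)
    z = zscore_with_stats(binned, cons_stats)
    responses = trial_response_matrix(z, binned, events)
    labels = classify_selectivity(responses, q=q)
    io.write_labels_csv(out / "selectivity.csv", labels)

    # --- PETHs + trajectories ---
    pf = reward_peth(z, binned, events, "flavour", smooth=True)
    pw = reward_peth(z, binned, events, "water", smooth=True)
    selective = labels.rejected
    artifacts = {}
    if selective.sum() >= 3:
        mat, record = build_pca_input(pf, pw, selective)
        pca = fit_pca(mat, record)
        traj_f = project_trajectory(pf, pca, selective)
        traj_w = project_trajectory(pw, pca, selective)
        artifacts["pca_variance_fraction"] = pca.variance_fraction[:5].tolist()
        pd.DataFrame(pca.loadings.T, columns=[f"pc{i+1}" for i in range(pca.n_components)]).to_csv(
            out / "pc_loadings.csv", index=False, float_format="%.8g"
        )
        pd.DataFrame(
            {
                "lag_s": pf.lags,
                "flavour_pc1": traj_f[0],
                "flavour_pc2": traj_f[1] if traj_f.shape[0] > 1 else 0.0,
                "water_pc1": traj_w[0],
                "water_pc2": traj_w[1] if traj_w.shape[0] > 1 else 0.0,
            }
        ).to_csv(out / "trajectories.csv", index=False, float_format="%.8g")
        if events.stim_bouts.size:
            sp = stim_bout_peth(z, binned, events.stim_bouts)
            traj_s = project_stim_trajectory(sp, pca, selective)
            pd.DataFrame(
                {
                    "lag_s": sp.lags,
                    "stim_pc1": traj_s[0],
                    "stim_pc2": traj_s[1] if traj_s.shape[0] > 1 else 0.0,
                }
            ).to_csv(out / "stim_trajectory.csv", index=False, float_format="%.8g")

    # --- decode ---
    features, train_labels, train_stats = build_training_set(spikes, events)
    model = fit_multinomial_l1(features, train_labels, lam, training_stats=train_stats)
    eval_stats = one_second_count_stats(
        spikes, events.epochs["delay"].start, events.epochs["delay"].end
    )
    series = sliding_posteriors(model, spikes, eval_stats, t_range=(0.0, events.session_end))
    pd.DataFrame(
        {
            "time_s": series.times,
            **{c: series.posteriors[:, i] for i, c in enumerate(series.classes)},
        }
    ).to_csv(out / "posteriors.csv", index=False, float_format="%.6g")
    model_doc = {
        "classes": list(model.classes),
        "lambda": model.lam,
        "weights": np.round(model.weights, 10).tolist(),
        "intercepts": np.round(model.intercepts, 10).tolist(),
        "converged": bool(model.converged),
        "n_iter": int(model.n_iter),
    }
    (out / "decoder.json").write_text(json.dumps(model_doc, indent=1, sort_keys=True))
    rates = {}
    for cls in ("flavour", "water"):
        ev = detect_reactivations(series, cls)
        mal = events.epochs.get("stimulation") or events.epochs.get("malaise")
        if mal is not None:
            ev_in = ev[(ev >= mal.start) & (ev < mal.end)]
            centers, rate = reactivation_rate(ev_in, (mal.start, mal.end))
            rates[cls] = {"n_events": int(ev_in.size), "mean_rate_per_min": float(rate.mean())}
    artifacts["reactivation"] = rates
    (out / "summary.json").write_text(json.dumps(artifacts, indent=1, sort_keys=True))

    # --- manifest ---
    canonical = json.dumps(
        {"sim": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(sim_cfg).items()},
         "analysis": analysis},
        sort_keys=True,
    )
    files = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config_hash=hashlib.sha256(canonical.encode()).hexdigest(),
        seed=sim_cfg.seed,
        version=__version__,
        files=files,
    )
    manifest.write(out / "manifest.json")
    return manifest
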