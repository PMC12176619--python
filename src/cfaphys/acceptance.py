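"""End-to-end property evaluations of the full analysis chain.

Each function runs one complete study on freshly simulated data -- task
structure, false-discovery control on null populations, classifier
recovery, decoder reactivation specificity, trajectory similarity,
plasticity-slope coverage, response-type clustering and photometry
recovery -- and returns the measured quantities.  The problem sizes
(numbers of seeds, neurons and sessions) are fixed study designs chosen so
each evaluation completes in minutes; they are documented in the methods
note.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score, balanced_accuracy_score

from .core import bin_spikes, epoch_stats, zscore_with_stats
from .decoder import (
    build_training_set,
    detect_reactivations,
    fit_multinomial_l1,
    one_second_count_stats,
    sliding_posteriors,
)
from .peth import PETHMatrix, reward_peth, stim_bout_peth
from .photometry import preprocess_akar2, preprocess_gcamp, reward_peth_pka
from .plasticity import delta_vs_cgrp_regression, gmm_response_types
from .selectivity import (
    classify_selectivity,
    spike_count_stats,
    trial_response_matrix,
    trial_responses_from_spikes,
)
from .simulate import (
    SimConfig,
    simulate_multiday,
    simulate_photometry,
    simulate_population,
    simulate_task_events,
    substream,
)
from .trajectories import (
    build_pca_input,
    fit_pca,
    project_stim_trajectory,
    project_trajectory,
    trajectory_cosine,
)


def _seeds(seed: int, name: str, n: int) -> np.ndarray:
    return substream(seed, name).integers(0, 2**31 - 1, size=n)


# --- task structure ---------------------------------------------------------


def task_structure(seed: int = 0, n_seeds: int = 100) -> dict:
    """Reward count and per-block port balance over many simulated sessions."""
    cfg = SimConfig()
    ok_count = ok_blocks = 0
    for s in _seeds(seed, "task", n_seeds):
        ev = simulate_task_events(cfg, int(s))
        ok_count += ev.reward_times.size == 60
        ports = ev.reward_ports
        balanced = all(
            np.sum(ports[b : b + 10] == "flavour") == 5 for b in range(0, ports.size, 10)
        )
        ok_blocks += balanced
    return {
        "reward_count_fraction_correct": ok_count / n_seeds,
        "block_balance_fraction_correct": ok_blocks / n_seeds,
        "n": n_seeds,
    }


# --- FDR control ------------------------------------------------------------


def null_fdr(seed: int = 0, n_seeds: int = 100, n_neurons: int = 1000) -> dict:
    """Fraction of neurons labelled selective when no neuron codes anything."""
    fractions = []
    for s in _seeds(seed, "nullfdr", n_seeds):
        cfg = SimConfig(
            n_neurons=n_neurons,
            frac_flavour=0.0,
            frac_water=0.0,
            bout_gain_mean=0.0,
            malaise_mode="none",
            seed=int(s),
        )
        ev = simulate_task_events(cfg)
        cons = ev.epochs["consumption"]
        spikes, _ = simulate_population(cfg, ev, t_stop=cons.end)
        stats = spike_count_stats(spikes, cons.start, cons.end)
        resp = trial_responses_from_spikes(spikes, ev, stats)
        labels = classify_selectivity(resp)
        fractions.append(1.0 - labels.fraction("nonselective"))
    return {"mean_selective_fraction": float(np.mean(fractions)), "n": n_seeds}


# --- classifier recovery ----------------------------------------------------


def classifier_recovery(seed: int = 0) -> dict:
    """Balanced accuracy of selectivity labels against ground truth."""
    cfg = SimConfig(seed=int(_seeds(seed, "recovery", 1)[0]))
    ev = simulate_task_events(cfg)
    cons = ev.epochs["consumption"]
    spikes, truth = simulate_population(cfg, ev, t_stop=cons.end)
    binned = bin_spikes(spikes, t_range=(cons.start - 15.0, cons.end))
    stats = epoch_stats(binned, cons)
    z = zscore_with_stats(binned, stats)
    labels = classify_selectivity(trial_response_matrix(z, binned, ev))
    acc = balanced_accuracy_score(truth.labels.astype(str), labels.labels.astype(str))
    return {"balanced_accuracy": float(acc), "n": cfg.n_neurons}


# --- decoder specificity ----------------------------------------------------


def _session_reactivation_counts(cfg: SimConfig) -> dict:
    ev = simulate_task_events(cfg)
    spikes, _ = simulate_population(cfg, ev)
    feats, labels, _ = build_training_set(spikes, ev)
    model = fit_multinomial_l1(feats, labels, lam=1.0)
    delay = ev.epochs["delay"]
    eval_stats = one_second_count_stats(spikes, delay.start, delay.end)
    series = sliding_posteriors(model, spikes, eval_stats, t_range=(0.0, ev.session_end))
    stim = ev.epochs["stimulation"]
    out = {}
    for cls in ("flavour", "water"):
        t = detect_reactivations(series, cls)
        out[cls] = int(np.sum((t >= stim.start) & (t < stim.end)))
    out["minutes"] = stim.duration / 60.0
    return out


def decoder_specificity(seed: int = 0, n_seeds: int = 10) -> dict:
    """Flavour vs water reactivation rates with and without planted gain.

    Event counts are pooled across seeds; the null-condition ratio uses
    add-one smoothing so it remains defined when both counts are near zero.
    """
    res = {}
    for cond, bout_mean in (("planted", None), ("null", 0.0)):
        nf = nw = 0
        minutes = 0.0
        for s in _seeds(seed, f"decoder-{cond}", n_seeds):
            cfg = SimConfig(seed=int(s))
            if bout_mean is not None:
                cfg.bout_gain_mean = bout_mean
            counts = _session_reactivation_counts(cfg)
            nf += counts["flavour"]
            nw += counts["water"]
            minutes += counts["minutes"]
        res[cond] = {
            "flavour_rate_per_min": nf / minutes,
            "water_rate_per_min": nw / minutes,
            "rate_ratio": (nf + 1) / (nw + 1),
        }
    planted = res["planted"]
    null = res["null"]
    null_r = null["rate_ratio"]
    return {
        "planted_flavour_over_water": planted["flavour_rate_per_min"]
        / max(planted["water_rate_per_min"], 1e-12),
        "null_rate_ratio_max_over_min": max(null_r, 1 / null_r),
        "planted": planted,
        "null": null,
        "n": n_seeds,
    }


# --- trajectory similarity --------------------------------------------------


def trajectory_similarity(seed: int = 0) -> dict:
    """Cosine similarity of the stimulation trajectory to the consumption ones."""
    cfg = SimConfig(seed=int(_seeds(seed, "traj", 1)[0]))
    ev = simulate_task_events(cfg)
    spikes, truth = simulate_population(cfg, ev)
    cons = ev.epochs["consumption"]
    stim = ev.epochs["stimulation"]

    binned_cons = bin_spikes(spikes, t_range=(cons.start - 10.0, cons.end + 11.0))
    stats = epoch_stats(binned_cons, cons)
    z_cons = zscore_with_stats(binned_cons, stats)
    resp = trial_response_matrix(z_cons, binned_cons, ev)
    labels = classify_selectivity(resp)
    selective = labels.rejected

    pf = reward_peth(z_cons, binned_cons, ev, "flavour", smooth=True)
    pw = reward_peth(z_cons, binned_cons, ev, "water", smooth=True)
    mat, record = build_pca_input(pf, pw, selective)
    pca = fit_pca(mat, record)
    traj_f = project_trajectory(pf, pca, selective)
    traj_w = project_trajectory(pw, pca, selective)

    binned_stim = bin_spikes(spikes, t_range=(stim.start - 2.0, stim.end))
    z_stim = zscore_with_stats(binned_stim, stats)
    sp = stim_bout_peth(z_stim, binned_stim, ev.stim_bouts)
    traj_s = project_stim_trajectory(sp, pca, selective)

    post_f = traj_f[:2, pf.lag_slice(0.0, 5.0)]
    post_w = traj_w[:2, pw.lag_slice(0.0, 5.0)]
    post_s = traj_s[:2, sp.lag_slice(0.0, 3.0)]
    return {
        "stim_vs_flavour_cosine": trajectory_cosine(post_s, post_f),
        "stim_vs_water_cosine": trajectory_cosine(post_s, post_w),
        "pc12_variance_fraction": float(pca.variance_fraction[:2].sum()),
        "n": int(selective.sum()),
    }


# --- plasticity slope coverage ----------------------------------------------


def plasticity_coverage(
    seed: int = 0,
    betas: tuple[float, ...] = (0.2, 0.5, 1.0),
    n_seeds: int = 100,
    n_neurons: int = 150,
) -> dict:
    """Fraction of seeds whose slope CI covers the generator's beta."""
    out = {}
    for beta in betas:
        hits = 0
        for s in _seeds(seed, f"plasticity-{beta}", n_seeds):
            cfg = SimConfig(seed=int(s), n_neurons=n_neurons, beta=beta)
            md = simulate_multiday(cfg)
            reg = _plasticity_regression(md)
            hits += reg.slope_ci[0] <= beta <= reg.slope_ci[1]
        out[f"coverage_beta_{beta:g}"] = hits / n_seeds
    out["n"] = n_seeds
    return out


def _plasticity_regression(md):
    ev1, ev2 = md.events_day1, md.events_day2
    cons1 = ev1.epochs["consumption"]
    st1 = spike_count_stats(md.spikes_day1, cons1.start, cons1.end)
    r1 = trial_responses_from_spikes(md.spikes_day1, ev1, st1, baseline_window=(-10, -5))
    r2 = trial_responses_from_spikes(md.spikes_day2, ev2, st1, baseline_window=(-10, -5))
    delta = r2.flavour.mean(axis=1) - r1.flavour.mean(axis=1)
    cgrp = cgrp_scalar_from_spikes(md.spikes_day1, ev1)
    return delta_vs_cgrp_regression(delta, cgrp, md.truth.labels == "flavour")


def cgrp_scalar_from_spikes(spike_times, events) -> np.ndarray:
    """Stimulation-period response on the final-20-min delay z scale."""
    delay = events.epochs["delay"]
    stim = events.epochs.get("stimulation") or events.epochs.get("malaise")
    stats = spike_count_stats(spike_times, delay.end - 1200.0, delay.end)
    bins = (stim.end - stim.start) / 0.010
    out = np.empty(len(spike_times))
    for u, t in enumerate(spike_times):
        c = np.sum((t >= stim.start) & (t < stim.end))
        sd = stats.sd[u] if stats.sd[u] > 0 else 1.0
        out[u] = (c / bins - stats.mean[u]) / sd
    return out


# --- GMM response-type recovery ---------------------------------------------


def planted_response_types(
    seed: int = 0, per_type: int = 60, noise_sd: float = 0.3
) -> tuple[PETHMatrix, np.ndarray]:
    """Synthetic baseline-subtracted stimulation PETHs with four planted types."""
    rng = substream(seed, "gmm-plant")
    lags = np.arange(-1.0, 2.0, 0.010)
    bump = np.clip(np.sin(np.clip(lags, 0, 1) * np.pi), 0, None)
    templates = {
        "strongly activated": 2.0 * bump,
        "weakly activated": 0.8 * bump,
        "inhibited": -1.0 * bump,
        "unmodulated": 0.0 * bump,
    }
    rows, truth = [], []
    for name, tpl in templates.items():
        rows.append(tpl + rng.normal(0.0, noise_sd, (per_type, lags.size)))
        truth.extend([name] * per_type)
    peth = PETHMatrix(
        values=np.vstack(rows),
        window=(1.0, 2.0),
        bin_width=0.010,
        baseline_rule="mean(-1,0)s subtracted",
        normalization={"stats": "synthetic-plant"},
        n_events=1,
    )
    return peth, np.array(truth, dtype=object)


def gmm_recovery(seed: int = 0) -> dict:
    """Adjusted Rand index of recovered response types and EM monotonicity."""
    peth, truth = planted_response_types(seed)
    model = gmm_response_types(peth, seed=int(_seeds(seed, "gmm-fit", 1)[0]))
    ari = adjusted_rand_score(truth.astype(str), model.labels().astype(str))
    monotone = all(np.all(np.diff(tr) >= -1e-8) for tr in model.ll_traces)
    return {
        "adjusted_rand_index": float(ari),
        "fraction_monotone_restarts": float(
            np.mean([bool(np.all(np.diff(tr) >= -1e-8)) for tr in model.ll_traces])
        ),
        "all_restarts_monotone": bool(monotone),
        "n": truth.size,
    }


# --- photometry -------------------------------------------------------------


def photometry_recovery(seed: int = 0, n_seeds: int = 100) -> dict:
    """Debleaching exactness and AKAR2 port discrimination."""
    # perfect linear bleach: output must vanish
    trace = simulate_photometry(duration=300.0, seed=int(_seeds(seed, "ph0", 1)[0]),
                                noise_sd=0.0)
    trace.act488 = 1.7 * trace.iso405 + 0.3
    out = preprocess_gcamp(trace)
    max_abs = float(np.max(np.abs(out.value)))

    wins = 0
    for s in _seeds(seed, "akar2", n_seeds):
        rng = substream(int(s), "events")
        times_a = 40.0 + np.cumsum(rng.uniform(25.0, 35.0, 4))
        times_b = times_a + rng.uniform(12.0, 16.0, 4)
        tr = simulate_photometry(
            duration=float(times_b[-1] + 40.0),
            seed=int(s),
            transient_times=times_a,
            transient_amp=0.15,
            transient_tau=8.0,
            noise_sd=0.02,
        )
        sig = preprocess_akar2(tr)
        res = reward_peth_pka(sig, {"A": times_a, "B": times_b})
        wins += res["A"]["scalar"] > res["B"]["scalar"]
    return {
        "linear_bleach_max_abs_output": max_abs,
        "port_a_gt_b_fraction": wins / n_seeds,
        "n": n_seeds,
    }
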