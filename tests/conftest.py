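import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_session():
    """One full conditioning session with bout-locked reactivation planted."""
    from cfaphys.simulate import SimConfig, simulate_population, simulate_task_events

    cfg = SimConfig(seed=11)
    events = simulate_task_events(cfg)
    spikes, truth = simulate_population(cfg, events)
    return {"config": cfg, "events": events, "spikes": spikes, "truth": truth}


@pytest.fixture(scope="session")
def consumption_session():
    """A consumption-only session (no malaise period) at default gains."""
    from cfaphys.simulate import SimConfig, simulate_population, simulate_task_events

    cfg = SimConfig(seed=7, malaise_mode="none")
    events = simulate_task_events(cfg)
    cons = events.epochs["consumption"]
    spikes, truth = simulate_population(cfg, events, t_stop=cons.end)
    return {"config": cfg, "events": events, "spikes": spikes, "truth": truth}


@pytest.fixture(scope="session")
def consumption_analysis(consumption_session):
    """Binned, z-scored consumption data with trial responses and labels."""
    from cfaphys.core import bin_spikes, epoch_stats, zscore_with_stats
    from cfaphys.selectivity import classify_selectivity, trial_response_matrix

    ev = consumption_session["events"]
    cons = ev.epochs["consumption"]
    binned = bin_spikes(consumption_session["spikes"], t_range=(cons.start - 15.0, cons.end))
    stats = epoch_stats(binned, cons)
    z = zscore_with_stats(binned, stats)
    responses = trial_response_matrix(z, binned, ev)
    labels = classify_selectivity(responses)
    return {
        "binned": binned,
        "stats": stats,
        "z": z,
        "responses": responses,
        "labels": labels,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
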