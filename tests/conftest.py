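import numpy as np
import pytest
from scipy import stats

import offsetgain as og


def discretise_to_chips(cdf_fn, theta_min, theta_max):
    """Turn a CDF into a valid 10-bin / 100-chip roulette allocation."""
    edges = np.linspace(theta_min, theta_max, 11)
    mass = np.diff(cdf_fn(edges))
    return tuple(int(c) for c in og.largest_remainder_chips(mass))


@pytest.fixture
def normal_record():
    """Histogram discretised from Normal(20, 4) on (8, 32), richness family."""
    chips = discretise_to_chips(
        lambda x: stats.norm.cdf(x, 20, 4), 8.0, 32.0)
    return og.RouletteElicitation(
        expert_id="e1", scenario_id="s1", attribute="forb_richness",
        state="reference", theta_min=8.0, theta_max=32.0, chips=chips)


@pytest.fixture
def beta_record():
    """Symmetric Beta(3, 3) histogram on a (0, 100) cover interval."""
    chips = discretise_to_chips(
        lambda x: stats.beta.cdf(np.asarray(x) / 100.0, 3, 3), 0.0, 100.0)
    return og.RouletteElicitation(
        expert_id="e1", scenario_id="s1", attribute="grass_cover",
        state="reference", theta_min=0.0, theta_max=100.0, chips=chips)


@pytest.fixture(scope="session")
def moderate_scenario():
    return og.make_default_scenarios()["moderate"]


@pytest.fixture(scope="session")
def small_panel(moderate_scenario):
    """A 6-expert roulette panel on the moderate scenario with its truth."""
    cfg = og.GeneratorConfig(n_experts_roulette=6, seed=42)
    records, truth = og.simulate_roulette_elicitations(
        moderate_scenario, cfg, np.random.default_rng(42))
    return cfg, records, truth


@pytest.fixture(scope="session")
def small_point_panel():
    """A small site pool with expert point scores and ground truth."""
    cfg = og.GeneratorConfig(n_sites=40, n_experts_points=12, n_experts_bau=8,
                             sites_per_expert=12, n_common=4, seed=7)
    rng = np.random.default_rng(7)
    sites, site_truth = og.simulate_site_pool(cfg, rng)
    scores, expert_truth = og.simulate_point_scores(sites, cfg, rng)
    return cfg, sites, site_truth, scores, expert_truth
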