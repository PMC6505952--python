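"""Synthetic site pools, expert panels, point scores and roulette elicitations
with known ground truth.

The study data this generator emulates were never deposited, so every stage
of the pipeline is exercised against simulated panels whose generating
parameters are known exactly.  Sites sit on a latent condition gradient
u ~ Uniform(0, 1); each vegetation attribute rises monotonically with u
toward its reference scale while alien plant cover falls.  Experts carry a
score intercept (some score everything high or low), an optimism term shared
between their BAU and offset judgements (producing the negative averted-loss
versus management-gain association seen across real panels), and an
overconfidence factor shrinking their subjective spread.  The true
management-gain function is linear in unrealised condition,
MG*(BC_start) = a (1 - BC_start) + b, and the true averted loss grows with
standing condition, AL*(BC_start) = c BC_start: degraded sites have more to
gain, good sites more to lose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    N_BINS,
    N_CHIPS,
    RouletteElicitation,
    Scenario,
    SiteDescription,
    WSGW_ATTRIBUTES,
    bin_edges,
)

#: Reference-state scale of each attribute (the benchmark mean R_a an expert
#: in good remnant woodland would report): percent covers, per-plot richness
#: counts, large-tree counts and log lengths on their natural units.
REFERENCE_MEANS: dict[str, float] = {
    "tree_cover": 30.0, "shrub_cover": 20.0, "grass_cover": 60.0,
    "forb_cover": 25.0, "fern_cover": 3.0,
    "tree_richness": 4.0, "shrub_richness": 8.0, "grass_richness": 15.0,
    "forb_richness": 25.0, "fern_richness": 1.5,
    "large_trees": 12.0, "litter_cover": 70.0, "log_length": 80.0,
}


@dataclass
class GeneratorConfig:
    """Study-design constants and noise/bias levels of the synthetic panel.

    Panel sizes mirror the emulated study: 64 sites, 29 point-scoring experts
    seeing 15 sites each (5 common to all, 16 experts also scoring a BAU
    future), and 25 roulette experts.  ``true_MG_function`` holds (a, b) of
    MG* = a (1 - BC_start) + b on the 0-1 condition scale; ``true_AL_slope``
    is c of AL* = c BC_start.  ``expert_intercept_sd`` and
    ``expert_score_noise_sd`` are points on the 0-100 score scale;
    ``bias_sd`` is the SD of the shared per-expert optimism term in condition
    units; ``overconfidence_factor`` multiplies the subjective SD
    (1 = calibrated, <1 = overconfident); ``relative_sd`` is the true
    uncertainty of an attribute as a fraction of its reference scale.
    """

    n_sites: int = 64
    n_experts_points: int = 29
    n_experts_bau: int = 16
    n_experts_roulette: int = 25
    sites_per_expert: int = 15
    n_common: int = 5
    true_condition_weights: dict[str, float] = field(default_factory=dict)
    expert_intercept_sd: float = 5.0
    expert_score_noise_sd: float = 5.0
    true_MG_function: tuple[float, float] = (0.15, 0.0)
    true_AL_slope: float = 0.10
    bias_sd: float = 0.05
    overconfidence_factor: float = 1.0
    relative_sd: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_common > self.sites_per_expert:
            raise ValueError("n_common cannot exceed sites_per_expert")
        if not (0 < self.overconfidence_factor <= 1):
            raise ValueError("overconfidence_factor must be in (0, 1]")
        if min(self.n_sites, self.n_experts_points, self.n_experts_roulette,
               self.sites_per_expert) < 1:
            raise ValueError("panel counts must be positive")

    def mg_star(self, bc_start):
        a, b = self.true_MG_function
        return a * (1.0 - np.asarray(bc_start, dtype=float)) + b

    def al_star(self, bc_start):
        return self.true_AL_slope * np.asarray(bc_start, dtype=float)

    def weights(self) -> dict[str, float]:
        if self.true_condition_weights:
            return dict(self.true_condition_weights)
        w = {name: 1.0 for name in WSGW_ATTRIBUTES}
        w["invasive_alien_cover"] = 1.0
        return w


def true_condition(site: SiteDescription, config: GeneratorConfig) -> float:
    """Ground-truth aggregate condition of a site on 0-100: a weighted mean
    of reference-capped attribute ratios and (1 - invasive alien cover)."""
    w = config.weights()
    num = den = 0.0
    for name, weight in w.items():
        if name == "invasive_alien_cover":
            x = 1.0 - site.invasive_alien_cover_pct / 100.0
        else:
            x = min(site.attribute_values[name] / REFERENCE_MEANS[name], 1.0)
        num += weight * x
        den += weight
    return 100.0 * num / den


def simulate_site_pool(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[list[SiteDescription], pd.DataFrame]:
    """Draw a pool of sites along a latent condition gradient.

    Returns the site descriptions and a ground-truth table (site_id, u,
    true_score).  Native attributes increase monotonically with u toward
    their reference scale; alien plant cover decreases with u.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    u = rng.uniform(0, 1, size=config.n_sites)
    sites = []
    for i, ui in enumerate(u):
        values = {}
        for name, ref in REFERENCE_MEANS.items():
            attr = WSGW_ATTRIBUTES[name]
            v = ref * (0.05 + 0.95 * ui) + rng.normal(0, 0.10 * ref)
            values[name] = float(attr.clip(v))
        invasive = float(np.clip(60 * (1 - ui) + rng.normal(0, 5), 0, 100))
        total = float(np.clip(invasive + 15 * (1 - ui) + rng.normal(0, 5),
                              invasive, 100))
        landscape = float(np.clip(rng.uniform(30, 90), 0, 100))
        sites.append(SiteDescription(
            site_id=f"S{i:03d}", attribute_values=values,
            landscape_native_cover_pct=landscape,
            invasive_alien_cover_pct=invasive,
            total_alien_cover_pct=total,
        ))
    truth = pd.DataFrame({
        "site_id": [s.site_id for s in sites],
        "u": u,
        "true_score": [true_condition(s, config) for s in sites],
    })
    return sites, truth


def _assign_sites(
    sites: list[SiteDescription], config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[list[str], dict[str, list[str]]]:
    """Common sites spread across the gradient plus a random draw per expert."""
    ids = [s.site_id for s in sites]
    order = np.argsort([true_condition(s, config) for s in sites])
    common_pos = np.linspace(0, len(ids) - 1, config.n_common).round().astype(int)
    common = [ids[order[p]] for p in common_pos]
    rest = [sid for sid in ids if sid not in common]
    n_extra = config.sites_per_expert - config.n_common
    assignment = {}
    for e in range(config.n_experts_points):
        extra = rng.choice(rest, size=min(n_extra, len(rest)), replace=False)
        assignment[f"E{e:02d}"] = common + sorted(extra.tolist())
    return common, assignment


def simulate_point_scores(
    sites: list[SiteDescription],
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate expert point scores with known ground truth.

    Each expert's current score is the site's true score plus their intercept
    and observation noise, clipped to [0, 100].  The offset future adds
    100 MG*(BC_start) and the BAU future (first ``n_experts_bau`` experts
    only) subtracts 100 AL*(BC_start), each with fresh noise.  Returns the
    ``point_scores`` table and an expert ground-truth table (intercepts).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    site_by_id = {s.site_id: s for s in sites}
    _, assignment = _assign_sites(sites, config, rng)
    intercepts = {
        e: rng.normal(0, config.expert_intercept_sd) for e in assignment
    }
    rows = []
    for k, (expert, site_ids) in enumerate(assignment.items()):
        has_bau = k < config.n_experts_bau
        for sid in site_ids:
            true = true_condition(site_by_id[sid], config)
            bc = true / 100.0
            current = np.clip(true + intercepts[expert]
                              + rng.normal(0, config.expert_score_noise_sd),
                              0, 100)
            offset = np.clip(current + 100 * config.mg_star(bc)
                             + rng.normal(0, config.expert_score_noise_sd),
                             0, 100)
            bau = (np.clip(current - 100 * config.al_star(bc)
                           + rng.normal(0, config.expert_score_noise_sd),
                           0, 100) if has_bau else np.nan)
            rows.append((expert, sid, float(current), float(offset),
                         float(bau) if has_bau else np.nan))
    scores = pd.DataFrame(
        rows, columns=["expert_id", "site_id", "current", "future_offset",
                       "future_bau"])
    expert_truth = pd.DataFrame({
        "expert_id": list(assignment),
        "intercept": [intercepts[e] for e in assignment],
        "has_bau": [k < config.n_experts_bau for k in range(len(assignment))],
    })
    return scores, expert_truth


def largest_remainder_chips(probs: np.ndarray, total: int = N_CHIPS) -> np.ndarray:
    """Round probabilities to integer chip counts summing exactly to total.

    Floors total*p and hands the remaining chips to the bins with the largest
    fractional parts (ties broken by bin index), so no bin is systematically
    favoured and the chip budget is always exact.
    """
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    raw = probs * total
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    frac = raw - base
    order = np.lexsort((np.arange(len(probs)), -frac))
    base[order[:short]] += 1
    return base


def _true_state_means(
    scenario: Scenario, config: GeneratorConfig
) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for name, ref in REFERENCE_MEANS.items():
        start = scenario.start_values.get(name)
        if start is None:
            continue
        bc = min(start / ref, 1.0)
        out[name] = {
            "reference": ref,
            "future_offset": ref * (bc + float(config.mg_star(bc))),
            "future_bau": max(ref * (bc - float(config.al_star(bc))), 0.0),
        }
    return out


def _subjective_histogram(
    mean: float, sd: float, attr, rng: np.random.Generator
) -> tuple[float, float, np.ndarray]:
    """Bin a subjective normal (beta analogue for covers) into 100 chips."""
    lo, hi = attr.support
    theta_min = max(mean - 3 * sd, lo)
    theta_max = min(mean + 3 * sd, hi) if np.isfinite(hi) else mean + 3 * sd
    if theta_max - theta_min < 1e-6:
        theta_max = theta_min + 1e-3
    edges = bin_edges(theta_min, theta_max)
    if attr.is_percent:
        m, v = mean / 100.0, (sd / 100.0) ** 2
        m = float(np.clip(m, 1e-4, 1 - 1e-4))
        v = min(v, m * (1 - m) * 0.98)
        nu = m * (1 - m) / v - 1.0
        cdf = stats.beta.cdf(np.clip(edges / 100.0, 0, 1), m * nu, (1 - m) * nu)
    else:
        cdf = stats.norm.cdf(edges, loc=mean, scale=sd)
    mass = np.diff(cdf)
    if mass.sum() <= 0:
        mass = np.ones(N_BINS)
    chips = largest_remainder_chips(mass)
    return float(theta_min), float(theta_max), chips


def simulate_roulette_elicitations(
    scenario: Scenario,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[RouletteElicitation], pd.DataFrame]:
    """Generate a panel of roulette histograms for one scenario.

    Each expert's subjective distribution for an attribute/state is centred
    on the true state mean plus the expert's bias — an optimism term (one
    draw per expert, in condition units, scaled by the reference) added to
    both future states and subtracted nowhere else, so optimists report high
    futures under BAU and offset alike — with SD equal to the true relative
    uncertainty shrunk by the overconfidence factor.  Bounds are the
    subjective mean +/- 3 subjective SDs clipped to the support; chips are
    the bin masses rounded by largest remainder.  Returns the records and a
    ground-truth table of generating parameters.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state_means = _true_state_means(scenario, config)
    records, truth_rows = [], []
    for e in range(config.n_experts_roulette):
        expert = f"R{e:02d}"
        optimism = rng.normal(0, config.bias_sd)
        for name, means in state_means.items():
            attr = WSGW_ATTRIBUTES[name]
            ref = REFERENCE_MEANS[name]
            for state in scenario.states_elicited:
                true_mean = means[state]
                bias = optimism * ref if state.startswith("future") else 0.0
                subj_mean = max(true_mean + bias
                                + rng.normal(0, 0.02 * ref), 1e-6)
                subj_sd = (config.relative_sd * ref
                           * config.overconfidence_factor)
                tmin, tmax, chips = _subjective_histogram(
                    subj_mean, subj_sd, attr, rng)
                records.append(RouletteElicitation(
                    expert_id=expert, scenario_id=scenario.id,
                    attribute=name, state=state, theta_min=tmin,
                    theta_max=tmax, chips=tuple(int(c) for c in chips)))
                truth_rows.append({
                    "expert_id": expert, "scenario_id": scenario.id,
                    "attribute": name, "state": state,
                    "true_mean": true_mean, "subj_mean": subj_mean,
                    "subj_sd": subj_sd, "optimism": optimism,
                })
    return records, pd.DataFrame(truth_rows)


def pooled_median_mg_interval(
    scenario: Scenario,
    config: GeneratorConfig,
    draws_per_expert: int = 84,
    n_rep: int = 200,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Monte-Carlo 95% interval of the pooled-median-MG statistic per attribute.

    Replicates the generative process directly from ground truth — fresh
    expert biases and subjective draws each replicate, no binning or fitting —
    computes the pooled median MG exactly as the benefit engine would, and
    returns the 2.5% / 97.5% envelope across replicates.  This is the
    independent yardstick for end-to-end parameter recovery.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state_means = _true_state_means(scenario, config)
    attrs = list(state_means)
    medians = {a: [] for a in attrs}
    n_e = config.n_experts_roulette
    for _ in range(n_rep):
        optimism = rng.normal(0, config.bias_sd, size=n_e)
        for name in attrs:
            attr = WSGW_ATTRIBUTES[name]
            ref = REFERENCE_MEANS[name]
            start = scenario.start_values[name]
            sd = config.relative_sd * ref * config.overconfidence_factor
            mg_all = []
            for e in range(n_e):
                mu_ref = state_means[name]["reference"] + rng.normal(0, 0.02 * ref)
                mu_off = (state_means[name]["future_offset"]
                          + optimism[e] * ref + rng.normal(0, 0.02 * ref))
                R = attr.clip(rng.normal(mu_ref, sd, size=draws_per_expert))
                R = np.maximum(R, 0.01 * max(mu_ref, 1e-6))
                V = attr.clip(rng.normal(mu_off, sd, size=draws_per_expert))
                bc_start = np.minimum(start / R, 1.0)
                bc_off = np.minimum(V / R, 1.0)
                mg_all.append(bc_off - bc_start)
            medians[name].append(float(np.median(np.concatenate(mg_all))))
    rows = []
    a_mg, b_mg = config.true_MG_function
    for name in attrs:
        med = np.asarray(medians[name])
        bc = min(scenario.start_values[name] / REFERENCE_MEANS[name], 1.0)
        rows.append({
            "attribute": name,
            "true_MG": a_mg * (1 - bc) + b_mg,
            "lo": float(np.quantile(med, 0.025)),
            "hi": float(np.quantile(med, 0.975)),
            "mc_median": float(np.median(med)),
        })
    return pd.DataFrame(rows)


def make_default_scenarios() -> dict[str, Scenario]:
    """Good / moderate / poor grassy-woodland scenarios.

    Start values are the reference scale of each attribute multiplied by a
    condition fraction (0.95 / 0.60 / 0.35); invasive alien cover rises as
    condition falls.  The moderate scenario elicits all three states so
    averted loss and total benefit are computable; the other two elicit the
    offset future only.
    """
    def starts(frac):
        return {name: ref * frac for name, ref in REFERENCE_MEANS.items()}

    return {
        "good": Scenario(
            id="good", vegetation_class="WSGW", start_values=starts(0.95),
            invasive_alien_cover_pct=2.0, total_alien_cover_pct=5.0,
            states_elicited=("reference", "future_offset")),
        "moderate": Scenario(
            id="moderate", vegetation_class="WSGW", start_values=starts(0.60),
            invasive_alien_cover_pct=15.0, total_alien_cover_pct=30.0,
            states_elicited=("reference", "future_bau", "future_offset")),
        "poor": Scenario(
            id="poor", vegetation_class="WSGW", start_values=starts(0.35),
            invasive_alien_cover_pct=40.0, total_alien_cover_pct=60.0,
            states_elicited=("reference", "future_offset")),
    }
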