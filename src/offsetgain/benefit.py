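"""Averted-loss / management-gain / total-benefit accounting.

The benefit of securing and managing a site as a biodiversity offset is split
into two components, both measured against a counterfactual business-as-usual
(BAU) trajectory over a fixed horizon:

* management gain, MG = BC_offset - BC_start — the improvement above the
  current state delivered by offset management;
* averted loss, AL = BC_start - BC_bau — the decline under BAU that the
  offset prevents;
* total benefit, TB = AL + MG.

On the attribute pathway all quantities are first standardised against a
reference (benchmark) state: BC = V / R, capped at 1 when V >= R, so benefits
are expressed on a common 0-1 condition scale.  Per-expert subjective
distributions are propagated by Monte-Carlo: a fixed number of draws per
expert, pooled across the panel, so the pooled distribution reflects both
within- and among-expert variation.  On the aggregate pathway the same
arithmetic applies directly to 0-100 point scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_EXCLUDED_ATTRIBUTES,
    PointScoreRecord,
    RouletteElicitation,
    WSGW_ATTRIBUTES,
)
from .fitting import FittedDistribution, fit_distribution, sample

DRAWS_PER_EXPERT = 84  # 25 experts x 84 draws = 2100 pooled samples
REFERENCE_FLOOR_FRACTION = 0.01

SAMPLE_COLUMNS = ["expert_id", "scenario_id", "attribute", "draw",
                  "AL", "MG", "TB", "BC_start", "BC_bau", "BC_offset"]


def condition_score(value, reference):
    """Reference-standardised condition score min(value / reference, 1).

    ``value`` is the current or future attribute value V and ``reference`` the
    benchmark value R; the score is capped at 1 when V >= R, so exceeding the
    benchmark is not counted as additional condition.  Works elementwise on
    arrays.
    """
    value = np.asarray(value, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if np.any(value < 0) or np.any(reference < 0):
        raise ValueError("condition_score requires non-negative inputs")
    if np.any(reference <= 0):
        raise ValueError("reference must be positive")
    out = np.minimum(value / reference, 1.0)
    return float(out) if out.ndim == 0 else out


def fit_panel(
    elicitations: list[RouletteElicitation],
) -> dict[tuple[str, str, str], FittedDistribution]:
    """Fit every (expert, attribute, state) histogram of one scenario."""
    fitted = {}
    for rec in elicitations:
        fitted[(rec.expert_id, rec.attribute, rec.state)] = fit_distribution(rec)
    return fitted


def pooled_benefit(
    elicitations: list[RouletteElicitation],
    start_values: dict[str, float],
    draws_per_expert: int = DRAWS_PER_EXPERT,
    rng: np.random.Generator | None = None,
    excluded_attributes: tuple[str, ...] = DEFAULT_EXCLUDED_ATTRIBUTES,
    fitted: dict[tuple[str, str, str], FittedDistribution] | None = None,
) -> pd.DataFrame:
    """Monte-Carlo pooled benefit samples for one scenario.

    For every expert and draw index, one reference draw R, one offset-future
    draw V_off and (where elicited) one BAU-future draw V_bau are taken from
    that expert's fitted distributions.  The reference draw is shared within
    the draw, standardising the start value and both futures coherently:
    BC_start = min(start/R, 1), BC_offset = min(V_off/R, 1), and with BAU
    BC_bau = min(V_bau/R, 1), giving MG, AL and TB = AL + MG per draw.
    Samples are pooled across experts, so each attribute contributes exactly
    n_experts * draws_per_expert rows.

    Reference draws below ``REFERENCE_FLOOR_FRACTION`` of the fitted reference
    mean are floored there to avoid ratio blow-ups; the number of floored
    draws is recorded in ``df.attrs["n_reference_floored"]``.

    Raises if an expert contributes a future state without a reference
    distribution — silently excluding them would bias the pool.
    """
    if rng is None:
        rng = np.random.default_rng()
    if fitted is None:
        fitted = fit_panel(elicitations)

    by_attr: dict[str, dict[str, dict[str, FittedDistribution]]] = {}
    scenario_ids = set()
    for (expert, attribute, state), dist in fitted.items():
        if attribute in excluded_attributes:
            continue
        by_attr.setdefault(attribute, {}).setdefault(expert, {})[state] = dist
        if dist.source is not None:
            scenario_ids.add(dist.source.scenario_id)
    scenario_id = scenario_ids.pop() if len(scenario_ids) == 1 else ""

    rows = []
    n_floored = 0
    for attribute in sorted(by_attr):
        attr = WSGW_ATTRIBUTES[attribute]
        if attribute not in start_values:
            raise ValueError(f"no start value for attribute {attribute!r}")
        start = start_values[attribute]
        for expert in sorted(by_attr[attribute]):
            dists = by_attr[attribute][expert]
            if "future_offset" not in dists:
                continue
            if "reference" not in dists:
                raise ValueError(
                    f"expert {expert!r} elicited a future for {attribute!r} "
                    "but no reference distribution"
                )
            R = sample(dists["reference"], draws_per_expert, attr, rng)
            v_off = sample(dists["future_offset"], draws_per_expert, attr, rng)
            v_bau = (
                sample(dists["future_bau"], draws_per_expert, attr, rng)
                if "future_bau" in dists else None
            )
            floor = REFERENCE_FLOOR_FRACTION * dists["reference"].mean()
            floor = max(floor, np.finfo(float).tiny)
            n_floored += int(np.count_nonzero(R < floor))
            R = np.maximum(R, floor)

            bc_start = condition_score(np.full(draws_per_expert, start), R)
            bc_off = condition_score(v_off, R)
            mg = bc_off - bc_start
            if v_bau is not None:
                bc_bau = condition_score(v_bau, R)
                al = bc_start - bc_bau
                tb = al + mg
            else:
                bc_bau = np.full(draws_per_expert, np.nan)
                al = np.full(draws_per_expert, np.nan)
                tb = np.full(draws_per_expert, np.nan)
            for d in range(draws_per_expert):
                rows.append((expert, scenario_id, attribute, d, al[d], mg[d],
                             tb[d], bc_start[d], bc_bau[d], bc_off[d]))
    df = pd.DataFrame(rows, columns=SAMPLE_COLUMNS)
    df.attrs["n_reference_floored"] = n_floored
    return df


def aggregate_point_benefit(record: PointScoreRecord) -> dict[str, float | None]:
    """Benefit arithmetic on 0-100 aggregate condition scores.

    MG = future-with-offset - current; where a BAU future was elicited,
    AL = current - future-BAU and TB = AL + MG.  Negative values are
    legitimate (an expert may expect decline even with an offset).
    """
    mg = record.future_offset_score - record.current_score
    if record.future_bau_score is None:
        return {"MG": mg, "AL": None, "TB": None}
    al = record.current_score - record.future_bau_score
    return {"MG": mg, "AL": al, "TB": al + mg}


def summarize(
    samples: pd.DataFrame, zero_tolerance: float = 1e-9
) -> pd.DataFrame:
    """Per-attribute quartile summary of the pooled benefit samples.

    Quantiles use linear interpolation between order statistics.  The TB
    sign fractions count TB < -tolerance as negative and |TB| <= tolerance as
    zero; zeros arise naturally from the condition-score cap.
    """
    if samples.empty:
        raise ValueError("empty sample set")
    out = []
    for attribute, g in samples.groupby("attribute", sort=True):
        row: dict[str, float | str] = {"attribute": attribute,
                                       "n_samples": len(g)}
        for comp in ("AL", "MG", "TB"):
            vals = g[comp].dropna().to_numpy()
            if vals.size:
                q25, med, q75 = np.quantile(vals, [0.25, 0.5, 0.75])
            else:
                q25 = med = q75 = np.nan
            row[f"{comp}_q25"] = q25
            row[f"{comp}_median"] = med
            row[f"{comp}_q75"] = q75
        tb = g["TB"].dropna().to_numpy()
        if tb.size:
            row["fraction_negative_TB"] = np.mean(tb < -zero_tolerance)
            row["fraction_zero_TB"] = np.mean(np.abs(tb) <= zero_tolerance)
        else:
            row["fraction_negative_TB"] = np.nan
            row["fraction_zero_TB"] = np.nan
        out.append(row)
    return pd.DataFrame(out)


def mg_vs_start(samples: pd.DataFrame) -> pd.DataFrame:
    """Pair each attribute's starting-condition summary with its MG summary.

    Accepts pooled samples from one or several scenarios (grouped on the
    ``scenario_id`` column); the output supports the management-gain versus
    starting-condition scatter, where a negative association indicates larger
    expected gains at more degraded sites.
    """
    if samples.empty:
        raise ValueError("empty sample set")
    out = []
    for (scenario_id, attribute), g in samples.groupby(
        ["scenario_id", "attribute"], sort=True
    ):
        bc = g["BC_start"].to_numpy()
        mg = g["MG"].to_numpy()
        out.append({
            "scenario_id": scenario_id,
            "attribute": attribute,
            "BC_start_q25": np.quantile(bc, 0.25),
            "BC_start_median": np.quantile(bc, 0.5),
            "BC_start_q75": np.quantile(bc, 0.75),
            "MG_q25": np.quantile(mg, 0.25),
            "MG_median": np.quantile(mg, 0.5),
            "MG_q75": np.quantile(mg, 0.75),
            "n_samples": len(g),
        })
    return pd.DataFrame(out)
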