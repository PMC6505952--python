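"""Per-expert bias diagnostics on the pooled benefit samples.

Plotting each expert's mean averted loss against their mean management gain
separates optimists (expect little decline under BAU and improvement with an
offset) from pessimists (expect decline regardless of management) and from
experts whose optimism is conditional on the offset.  A negative AL-MG
association across experts indicates a shared optimism/pessimism axis rather
than independent judgements of the two components.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

QUADRANT_TOLERANCE = 0.01  # on the 0-1 condition scale

QUADRANTS = ("optimistic_both", "pessimistic_both", "offset_believer",
             "offset_sceptic", "neutral")


def expert_means(samples: pd.DataFrame) -> pd.DataFrame:
    """Mean AL and MG per expert x attribute.

    Attributes without any BAU-derived AL draws are excluded (AL undefined);
    the excluded attribute names are recorded in
    ``df.attrs["attributes_without_AL"]``.
    """
    no_al = sorted(
        a for a, g in samples.groupby("attribute") if g["AL"].isna().all()
    )
    kept = samples[~samples["attribute"].isin(no_al)]
    out = (
        kept.groupby(["expert_id", "attribute"], sort=True)
        .agg(mean_AL=("AL", "mean"), mean_MG=("MG", "mean"),
             n_draws=("MG", "size"))
        .reset_index()
    )
    out.attrs["attributes_without_AL"] = no_al
    return out


def classify_quadrant(
    mean_AL: float, mean_MG: float, tolerance: float = QUADRANT_TOLERANCE
) -> str:
    """Classify one expert-attribute mean into an opinion quadrant.

    Within ``tolerance`` of both axes is neutral.  Otherwise the quadrant is
    decided by whether AL and MG exceed the tolerance: high MG with low AL is
    optimism under both scenarios; high AL with low MG is pessimism under
    both; high AL and high MG means decline expected under BAU but recovery
    with an offset (an offset believer); low on both axes is an offset
    sceptic.  The classification is exhaustive and mutually exclusive for any
    finite pair.
    """
    if not (np.isfinite(mean_AL) and np.isfinite(mean_MG)):
        raise ValueError("means must be finite")
    if abs(mean_AL) <= tolerance and abs(mean_MG) <= tolerance:
        return "neutral"
    al_high = mean_AL > tolerance
    mg_high = mean_MG > tolerance
    if al_high and mg_high:
        return "offset_believer"
    if al_high:
        return "pessimistic_both"
    if mg_high:
        return "optimistic_both"
    return "offset_sceptic"


def al_mg_fit(means: pd.DataFrame, attribute: str) -> dict[str, float]:
    """OLS fit of mean MG on mean AL across experts, plus Pearson correlation.

    Requires at least three experts for the attribute.
    """
    g = means[means["attribute"] == attribute].sort_values("expert_id")
    if len(g) < 3:
        raise ValueError(
            f"need >= 3 experts for attribute {attribute!r}, got {len(g)}"
        )
    x = g["mean_AL"].to_numpy()
    y = g["mean_MG"].to_numpy()
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "correlation": float(res.rvalue), "n_experts": len(g)}


def systematic_bias(
    means: pd.DataFrame,
    share_threshold: float = 0.8,
    min_attributes: int = 5,
) -> pd.DataFrame:
    """Flag experts whose mean MG has a consistent sign across attributes.

    An expert is an optimist (pessimist) if mean MG is positive (negative)
    for at least ``share_threshold`` of their attributes; otherwise unbiased.
    Experts with fewer than ``min_attributes`` attributes are not assessed.
    """
    rows = []
    for expert, g in means.groupby("expert_id", sort=True):
        n = len(g)
        if n < min_attributes:
            continue
        pos = int((g["mean_MG"] > 0).sum())
        neg = int((g["mean_MG"] < 0).sum())
        if pos / n >= share_threshold:
            flag = "optimist"
        elif neg / n >= share_threshold:
            flag = "pessimist"
        else:
            flag = "unbiased"
        rows.append({"expert_id": expert, "n_attributes": n,
                     "n_positive_MG": pos, "n_negative_MG": neg, "flag": flag})
    return pd.DataFrame(rows)


def diagnostics_table(
    samples: pd.DataFrame, tolerance: float = QUADRANT_TOLERANCE
) -> pd.DataFrame:
    """Expert means with quadrant labels, ready for the diagnostics CSV."""
    means = expert_means(samples)
    means["quadrant"] = [
        classify_quadrant(al, mg, tolerance)
        for al, mg in zip(means["mean_AL"], means["mean_MG"])
    ]
    return means
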