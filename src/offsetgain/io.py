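"""CSV readers and writers for the elicitation pipeline.

All tables are plain CSV.  Readers validate every record against the data
model and report schema problems with row numbers; unknown attributes or
states are hard errors (a silently dropped record would bias downstream
pooling).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    N_BINS,
    PointScoreRecord,
    RouletteElicitation,
    SiteDescription,
    ValidationError,
    WSGW_ATTRIBUTES,
    validate_elicitation,
)

CHIP_COLUMNS = [f"chip_{i:02d}" for i in range(1, N_BINS + 1)]
ELICITATION_COLUMNS = ["expert_id", "scenario_id", "attribute", "state",
                       "theta_min", "theta_max"] + CHIP_COLUMNS
POINT_SCORE_COLUMNS = ["expert_id", "site_id", "current", "future_offset",
                       "future_bau"]
SITE_COLUMNS = (["site_id"] + list(WSGW_ATTRIBUTES)
                + ["landscape_cover", "invasive_alien_cover",
                   "total_alien_cover"])


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required columns {missing}", ["schema"]
        )


def write_elicitations(records: list[RouletteElicitation], path) -> None:
    rows = []
    for r in records:
        row = {"expert_id": r.expert_id, "scenario_id": r.scenario_id,
               "attribute": r.attribute, "state": r.state,
               "theta_min": r.theta_min, "theta_max": r.theta_max}
        row.update({c: chip for c, chip in zip(CHIP_COLUMNS, r.chips)})
        rows.append(row)
    pd.DataFrame(rows, columns=ELICITATION_COLUMNS).to_csv(path, index=False)


def read_elicitations(path) -> list[RouletteElicitation]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ELICITATION_COLUMNS, path)
    records = []
    for i, row in df.iterrows():
        rec = RouletteElicitation(
            expert_id=str(row["expert_id"]), scenario_id=str(row["scenario_id"]),
            attribute=str(row["attribute"]), state=str(row["state"]),
            theta_min=float(row["theta_min"]), theta_max=float(row["theta_max"]),
            chips=tuple(int(row[c]) for c in CHIP_COLUMNS),
        )
        try:
            validate_elicitation(rec)
        except ValidationError as err:
            raise ValidationError(f"{path}: row {i + 2}: {err}",
                                  err.violations) from err
        records.append(rec)
    return records


def write_point_scores(scores: pd.DataFrame, path) -> None:
    scores[POINT_SCORE_COLUMNS].to_csv(path, index=False)


def read_point_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, POINT_SCORE_COLUMNS, path)
    for i, row in df.iterrows():
        try:
            PointScoreRecord(
                expert_id=str(row["expert_id"]), site_id=str(row["site_id"]),
                current_score=float(row["current"]),
                future_offset_score=float(row["future_offset"]),
                future_bau_score=(None if pd.isna(row["future_bau"])
                                  else float(row["future_bau"])),
            )
        except ValidationError as err:
            raise ValidationError(f"{path}: row {i + 2}: {err}",
                                  err.violations) from err
    df["expert_id"] = df["expert_id"].astype(str)
    df["site_id"] = df["site_id"].astype(str)
    return df


def sites_to_frame(sites: list[SiteDescription]) -> pd.DataFrame:
    rows = []
    for s in sites:
        row = {"site_id": s.site_id}
        row.update({name: s.attribute_values[name] for name in WSGW_ATTRIBUTES})
        row["landscape_cover"] = s.landscape_native_cover_pct
        row["invasive_alien_cover"] = s.invasive_alien_cover_pct
        row["total_alien_cover"] = s.total_alien_cover_pct
        rows.append(row)
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def frame_to_sites(df: pd.DataFrame) -> list[SiteDescription]:
    sites = []
    for _, row in df.iterrows():
        sites.append(SiteDescription(
            site_id=str(row["site_id"]),
            attribute_values={name: float(row[name]) for name in WSGW_ATTRIBUTES},
            landscape_native_cover_pct=float(row["landscape_cover"]),
            invasive_alien_cover_pct=float(row["invasive_alien_cover"]),
            total_alien_cover_pct=float(row["total_alien_cover"]),
        ))
    return sites


def write_sites(sites: list[SiteDescription], path) -> None:
    sites_to_frame(sites).to_csv(path, index=False)


def read_sites(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SITE_COLUMNS, path)
    frame_to_sites(df)  # validation
    df["site_id"] = df["site_id"].astype(str)
    return df


def write_fitted(fitted: dict, path) -> None:
    """Write a fit_panel result: one row per (expert, attribute, state)."""
    rows = []
    for (expert, attribute, state), dist in sorted(fitted.items()):
        src = dist.source
        rows.append({
            "expert_id": expert,
            "scenario_id": src.scenario_id if src else "",
            "attribute": attribute, "state": state,
            "family": dist.family,
            "param1": dist.params[0], "param2": dist.params[1],
            "fit_sse": dist.fit_sse,
            "multimodal_flag": dist.multimodal,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
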