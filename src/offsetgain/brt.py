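"""Boosted regression trees on aggregate point scores: relative influence,
partial dependence and ensemble condition predictions.

A stagewise squared-error gradient boosting model (shallow trees, small
learning rate, per-tree row subsampling) is fitted to expert point scores,
with 75% of rows used for training and the held-out 25% monitoring deviance
as trees are added in fixed-size steps; growth stops when the held-out
deviance stops improving.  Covariate importance is the standard boosting
relative influence — squared-error improvement summed over each covariate's
splits, averaged over trees — normalised to sum to 100 (NRI).  Expert
identity enters as a categorical covariate via one-hot columns whose
influences are summed back into a single "expert_id" score, so among-expert
level differences are directly comparable with ecological covariates.

Tree growth itself is delegated to scikit-learn's GradientBoostingRegressor;
tree complexity (the number of splits per tree) maps to max_leaf_nodes =
complexity + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor

from .core import SiteDescription, WSGW_ATTRIBUTES

SITE_COVARIATES = list(WSGW_ATTRIBUTES) + [
    "landscape_cover", "invasive_alien_cover", "total_alien_cover"
]

RESPONSES = ("current", "MG", "AL", "TB")


@dataclass(frozen=True)
class BRTConfig:
    """Boosting hyperparameters.

    ``tree_complexity`` is the number of splits per tree (interaction depth),
    ``learning_rate`` the per-tree shrinkage, ``bag_fraction`` the per-tree
    row-subsampling fraction, and the tree count is selected forward in steps
    of ``tree_step`` trees against the 25% holdout, up to ``max_trees``.
    """

    tree_complexity: int = 5
    learning_rate: float = 0.005
    bag_fraction: float = 0.75
    cv_folds: int = 10
    tree_step: int = 50
    max_trees: int = 10000
    train_fraction: float = 0.75
    patience_steps: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.tree_complexity < 1 or self.learning_rate <= 0:
            raise ValueError("tree_complexity and learning_rate must be positive")
        if not (0 < self.bag_fraction <= 1):
            raise ValueError("bag_fraction must be in (0, 1]")
        if min(self.tree_step, self.max_trees, self.cv_folds) < 1:
            raise ValueError("tree counts and folds must be positive")


@dataclass
class BRTModel:
    """A fitted boosting ensemble plus the metadata needed to interpret it."""

    response: str
    config: BRTConfig
    feature_names: list[str]          # design-matrix columns (one-hot experts)
    covariate_names: list[str]        # user-facing covariates (single expert_id)
    expert_levels: list[str]
    train_mean: float
    n_trees_selected: int
    cv_deviance_profile: list[tuple[int, float]]
    estimator: GradientBoostingRegressor | None
    train_design: pd.DataFrame = field(repr=False, default=None)

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        if "expert_id" in design.columns:
            design, _ = _encode(design, self.expert_levels)
        X = design[self.feature_names].to_numpy(dtype=float)
        if self.estimator is None or self.n_trees_selected == 0:
            return np.full(len(design), self.train_mean)
        return self.estimator.predict(X)


def build_design(
    point_scores: pd.DataFrame,
    sites: pd.DataFrame,
    response: str,
) -> tuple[pd.DataFrame, pd.Series]:
    """Join point scores to site descriptions into a model table.

    One row per expert x site.  Covariates are the 13 vegetation attributes,
    landscape cover, invasive and total alien cover, and expert identity; for
    the benefit responses (MG, AL, TB) the expert's own current score is an
    additional covariate.  Rows whose response cannot be computed (no BAU
    score for AL/TB) are dropped; a score record referencing an unknown site
    is an error.
    """
    if response not in RESPONSES:
        raise ValueError(f"unknown response {response!r}")
    missing = set(point_scores["site_id"]) - set(sites["site_id"])
    if missing:
        raise ValueError(f"score records reference unknown sites: {sorted(missing)}")
    df = point_scores.merge(sites, on="site_id", how="left", validate="m:1")

    if response == "current":
        y = df["current"]
    elif response == "MG":
        y = df["future_offset"] - df["current"]
    elif response == "AL":
        y = df["current"] - df["future_bau"]
    else:  # TB
        y = (df["current"] - df["future_bau"]) + (df["future_offset"] - df["current"])

    keep = y.notna()
    df, y = df.loc[keep].copy(), y.loc[keep]
    covars = list(SITE_COVARIATES)
    X = df[["expert_id", "site_id"] + covars].copy()
    if response != "current":
        X["current_score"] = df["current"]
    y = pd.Series(y.to_numpy(dtype=float), index=X.index, name=response)
    return X, y


def _encode(design: pd.DataFrame, expert_levels: list[str]) -> tuple[pd.DataFrame, list[str]]:
    """One-hot the expert column against a fixed level set."""
    X = design.drop(columns=[c for c in ("site_id",) if c in design]).copy()
    for lev in expert_levels:
        X[f"expert={lev}"] = (design["expert_id"] == lev).astype(float)
    X = X.drop(columns=["expert_id"])
    return X, list(X.columns)


def fit_brt(design: pd.DataFrame, y: pd.Series, config: BRTConfig) -> BRTModel:
    """Fit a BRT with forward holdout-monitored selection of the tree count.

    The table is first put into a canonical (expert_id, site_id) order so the
    fit is invariant to input row order; the 75/25 train/holdout split is
    stratified by expert so every expert level is estimable in training.
    Trees are added ``tree_step`` at a time until the holdout squared-error
    deviance has not improved for ``patience_steps`` steps or ``max_trees``
    is reached; the model is then refitted at the best tree count.  If no
    tree count beats the intercept-only deviance the ensemble has zero
    effective trees and predicts the training mean.
    """
    if len(design) < 50:
        raise ValueError("need at least 50 rows to fit a BRT")
    order = np.lexsort((design["site_id"].to_numpy()
                        if "site_id" in design else np.arange(len(design)),
                        design["expert_id"].to_numpy()))
    design = design.iloc[order].reset_index(drop=True)
    y = y.iloc[order].reset_index(drop=True)

    expert_levels = sorted(design["expert_id"].unique())
    X, feature_names = _encode(design, expert_levels)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 covariates")
    covariate_names = [c for c in X.columns if not c.startswith("expert=")]
    covariate_names.append("expert_id")

    rng = np.random.default_rng(config.seed)
    train_mask = np.zeros(len(design), dtype=bool)
    for lev in expert_levels:
        idx = np.flatnonzero(design["expert_id"].to_numpy() == lev)
        rng.shuffle(idx)
        n_train = max(1, int(round(config.train_fraction * len(idx))))
        train_mask[idx[:n_train]] = True

    Xa = X.to_numpy(dtype=float)
    ya = y.to_numpy(dtype=float)
    X_tr, y_tr = Xa[train_mask], ya[train_mask]
    X_va, y_va = Xa[~train_mask], ya[~train_mask]
    train_mean = float(np.mean(y_tr))

    def make_gbr(n_estimators, warm=False):
        return GradientBoostingRegressor(
            loss="squared_error",
            learning_rate=config.learning_rate,
            n_estimators=n_estimators,
            subsample=config.bag_fraction,
            max_leaf_nodes=config.tree_complexity + 1,
            max_depth=None,
            random_state=config.seed,
            warm_start=warm,
        )

    baseline = float(np.mean((y_va - train_mean) ** 2)) if len(y_va) else np.inf
    profile: list[tuple[int, float]] = [(0, baseline)]
    best_n, best_dev = 0, baseline

    if np.ptp(y_tr) > 0 and len(y_va):
        gbr = make_gbr(config.tree_step, warm=True)
        n = 0
        since_best = 0
        while n < config.max_trees:
            n = min(n + config.tree_step, config.max_trees)
            gbr.set_params(n_estimators=n)
            gbr.fit(X_tr, y_tr)
            dev = float(np.mean((y_va - gbr.predict(X_va)) ** 2))
            profile.append((n, dev))
            if dev < best_dev - 1e-12:
                best_n, best_dev = n, dev
                since_best = 0
            else:
                since_best += 1
                if since_best >= config.patience_steps:
                    break

    if best_n == 0:
        estimator = None
    else:
        estimator = make_gbr(best_n)
        estimator.fit(X_tr, y_tr)

    return BRTModel(
        response=str(y.name), config=config, feature_names=feature_names,
        covariate_names=covariate_names, expert_levels=expert_levels,
        train_mean=train_mean, n_trees_selected=best_n,
        cv_deviance_profile=profile, estimator=estimator,
        train_design=design,
    )


def relative_influence(model: BRTModel) -> pd.Series:
    """Normalised relative influence (NRI) per covariate, summing to 100.

    Influence is the squared-error improvement attributed to each covariate's
    splits, averaged over all trees; one-hot expert columns are summed into a
    single ``expert_id`` entry before normalising.  Raises on an ensemble
    with no trees.
    """
    if model.estimator is None or model.n_trees_selected == 0:
        raise ValueError("cannot compute relative influence of an empty ensemble")
    imp = pd.Series(model.estimator.feature_importances_,
                    index=model.feature_names)
    expert_cols = [c for c in imp.index if c.startswith("expert=")]
    out = imp.drop(expert_cols)
    out["expert_id"] = imp[expert_cols].sum()
    total = out.sum()
    if total <= 0:
        raise ValueError("ensemble contains no informative splits")
    nri = (100.0 * out / total).sort_values(ascending=False)
    nri.name = "NRI"
    return nri


def fitted_function(
    model: BRTModel, covariate: str, grid: np.ndarray
) -> np.ndarray:
    """Partial dependence: mean prediction over the training rows with one
    covariate fixed at each grid value."""
    if covariate not in model.covariate_names or covariate == "expert_id":
        raise ValueError(f"unknown or non-numeric covariate {covariate!r}")
    base = model.train_design.copy()
    out = np.empty(len(grid))
    for i, v in enumerate(np.asarray(grid, dtype=float)):
        base[covariate] = v
        enc, _ = _encode(base, model.expert_levels)
        out[i] = float(np.mean(model.predict(enc)))
    return out


def _site_row(site: SiteDescription) -> dict[str, float]:
    row = dict(site.attribute_values)
    row["landscape_cover"] = site.landscape_native_cover_pct
    row["invasive_alien_cover"] = site.invasive_alien_cover_pct
    row["total_alien_cover"] = site.total_alien_cover_pct
    return row


def predict_condition(
    models: list[BRTModel], site: SiteDescription
) -> tuple[float, float]:
    """Ensemble prediction of a site's aggregate condition score.

    Each member model predicts the site once per expert level (expert
    identity is a covariate) and averages across levels; the ensemble value
    is the mean of member predictions clipped to [0, 100], the spread their
    standard deviation.  Raises if the site lacks a covariate any member
    needs.
    """
    if not models:
        raise ValueError("need at least one fitted model")
    row = _site_row(site)
    member_preds = []
    for m in models:
        needed = [c for c in m.covariate_names if c != "expert_id"]
        missing = [c for c in needed if c not in row]
        if missing:
            raise ValueError(f"site {site.site_id!r} missing covariates {missing}")
        frame = pd.DataFrame(
            [{**{c: row[c] for c in needed}, "expert_id": lev, "site_id": site.site_id}
             for lev in m.expert_levels]
        )
        enc, _ = _encode(frame, m.expert_levels)
        member_preds.append(float(np.mean(m.predict(enc))))
    preds = np.clip(member_preds, 0.0, 100.0)
    return float(np.mean(preds)), float(np.std(preds))


def fit_brt_ensemble(
    design: pd.DataFrame, y: pd.Series, config: BRTConfig, n_members: int = 5
) -> list[BRTModel]:
    """Fit an ensemble of BRTs differing only in split/subsample seed."""
    from dataclasses import replace

    return [
        fit_brt(design, y, replace(config, seed=config.seed + k))
        for k in range(n_members)
    ]
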