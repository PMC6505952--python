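"""Elicitation data model: attributes, scenarios, roulette histograms, point scores.

The trial-roulette ("histogram") method asks an expert to state a plausible
interval [theta_min, theta_max] for a quantity and then distribute 100 chips
among 10 equal-width bins spanning that interval; the chip proportions encode
the expert's subjective probability histogram.  This module defines those
records, the site/scenario descriptions they refer to, and strict validation:
unknown attributes or malformed records are hard errors, never silent drops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_BINS = 10
N_CHIPS = 100

STATES = ("reference", "future_bau", "future_offset")

#: Attribute categories. Percent covers live on [0, 100]; counts and lengths
#: are non-negative and unbounded above.
PERCENT_CATEGORIES = frozenset({"foliage_cover_pct", "litter_cover_pct"})
CATEGORIES = frozenset(
    {"foliage_cover_pct", "richness_count", "large_tree_count",
     "litter_cover_pct", "log_length_m"}
)


class ValidationError(ValueError):
    """Raised when a record violates the elicitation data model.

    ``violations`` is a machine-readable list of short codes, e.g.
    ``["chip_sum", "support"]``.
    """

    def __init__(self, message: str, violations: list[str] | None = None):
        super().__init__(message)
        self.violations = violations or []


@dataclass(frozen=True)
class AttributeDefinition:
    """One vegetation condition attribute (e.g. grass foliage cover).

    ``plot_area`` is the sampling plot in m^2: 400 for growth-form cover and
    richness, 1000 for habitat-structure attributes.  ``support`` is the
    closed numeric interval of admissible values.
    """

    name: str
    category: str
    plot_area: float
    support: tuple[float, float]

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"unknown attribute category {self.category!r}", ["category"]
            )
        lo, hi = self.support
        if self.is_percent:
            if lo < 0 or hi > 100:
                raise ValidationError(
                    f"percent attribute {self.name!r} support must lie in [0, 100]",
                    ["support"],
                )
        elif lo != 0:
            raise ValidationError(
                f"count/length attribute {self.name!r} must have lower support 0",
                ["support"],
            )

    @property
    def is_percent(self) -> bool:
        return self.category in PERCENT_CATEGORIES

    def contains(self, value: float) -> bool:
        lo, hi = self.support
        return lo <= value <= hi

    def clip(self, values):
        lo, hi = self.support
        return np.clip(values, lo, hi)


def _cover(name):
    return AttributeDefinition(name, "foliage_cover_pct", 400.0, (0.0, 100.0))


def _richness(name):
    return AttributeDefinition(name, "richness_count", 400.0, (0.0, np.inf))


#: The 13 grassy-woodland attributes: foliage cover and native species richness
#: of five growth forms, plus three habitat-structure attributes.
WSGW_ATTRIBUTES: dict[str, AttributeDefinition] = {
    a.name: a
    for a in [
        _cover("tree_cover"),
        _cover("shrub_cover"),
        _cover("grass_cover"),
        _cover("forb_cover"),
        _cover("fern_cover"),
        _richness("tree_richness"),
        _richness("shrub_richness"),
        _richness("grass_richness"),
        _richness("forb_richness"),
        _richness("fern_richness"),
        AttributeDefinition("large_trees", "large_tree_count", 1000.0, (0.0, np.inf)),
        AttributeDefinition("litter_cover", "litter_cover_pct", 1000.0, (0.0, 100.0)),
        AttributeDefinition("log_length", "log_length_m", 1000.0, (0.0, np.inf)),
    ]
}

#: Fern attributes are excluded from benefit summaries by default: they are
#: frequently absent from reference states so their standardised scores are
#: uninformative.
DEFAULT_EXCLUDED_ATTRIBUTES = ("fern_cover", "fern_richness")


@dataclass
class Scenario:
    """A hypothetical site whose future is elicited under one or more states.

    ``start_values`` are the current attribute values handed to experts;
    ``states_elicited`` is the subset of states for which roulette histograms
    exist (averted loss needs ``future_bau``).  ``horizon`` is years.
    """

    id: str
    vegetation_class: str
    start_values: dict[str, float]
    landscape_native_cover_pct: float = 70.0
    invasive_alien_cover_pct: float = 0.0
    total_alien_cover_pct: float = 0.0
    states_elicited: tuple[str, ...] = ("reference", "future_bau", "future_offset")
    horizon: int = 20

    def __post_init__(self):
        for s in self.states_elicited:
            if s not in STATES:
                raise ValidationError(f"unknown state {s!r}", ["state"])
        for name, v in self.start_values.items():
            attr = WSGW_ATTRIBUTES.get(name)
            if attr is None:
                raise ValidationError(f"unknown attribute {name!r}", ["attribute"])
            if not attr.contains(v):
                raise ValidationError(
                    f"start value {v} outside support of {name!r}", ["support"]
                )


@dataclass(frozen=True)
class RouletteElicitation:
    """One expert's binned subjective distribution for one attribute/state."""

    expert_id: str
    scenario_id: str
    attribute: str
    state: str
    theta_min: float
    theta_max: float
    chips: tuple[int, ...]


@dataclass(frozen=True)
class PointScoreRecord:
    """One expert's aggregate 0-100 condition scores for one site."""

    expert_id: str
    site_id: str
    current_score: float
    future_offset_score: float
    future_bau_score: float | None = None

    def __post_init__(self):
        scores = [self.current_score, self.future_offset_score]
        if self.future_bau_score is not None:
            scores.append(self.future_bau_score)
        for s in scores:
            if not (0.0 <= s <= 100.0):
                raise ValidationError(
                    f"point score {s} outside [0, 100] for expert "
                    f"{self.expert_id!r} site {self.site_id!r}",
                    ["score_range"],
                )


@dataclass
class SiteDescription:
    """A synthetic 2-ha vegetation patch handed to experts for scoring."""

    site_id: str
    attribute_values: dict[str, float]
    landscape_native_cover_pct: float
    invasive_alien_cover_pct: float
    total_alien_cover_pct: float
    dominant_species: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, v in self.attribute_values.items():
            attr = WSGW_ATTRIBUTES.get(name)
            if attr is None:
                raise ValidationError(f"unknown attribute {name!r}", ["attribute"])
            if not attr.contains(v):
                raise ValidationError(
                    f"value {v} outside support of {name!r} at site "
                    f"{self.site_id!r}",
                    ["support"],
                )
        for pct in (self.landscape_native_cover_pct,
                    self.invasive_alien_cover_pct, self.total_alien_cover_pct):
            if not (0.0 <= pct <= 100.0):
                raise ValidationError(
                    f"cover percentage {pct} outside [0, 100] at site "
                    f"{self.site_id!r}",
                    ["support"],
                )


def make_bins(theta_min: float, theta_max: float) -> list[tuple[float, float]]:
    """Partition [theta_min, theta_max] into 10 contiguous equal-width bins.

    Bins are half-open [lo, hi) except the last, which is closed, so no value
    in the interval is double-counted.

    Raises
    ------
    ValidationError
        If the interval is degenerate (theta_min >= theta_max) or not finite.
    """
    if not (np.isfinite(theta_min) and np.isfinite(theta_max)):
        raise ValidationError("interval bounds must be finite", ["interval"])
    if theta_min >= theta_max:
        raise ValidationError(
            f"degenerate interval [{theta_min}, {theta_max}]", ["interval"]
        )
    edges = np.linspace(theta_min, theta_max, N_BINS + 1)
    return [(float(edges[i]), float(edges[i + 1])) for i in range(N_BINS)]


def bin_edges(theta_min: float, theta_max: float) -> np.ndarray:
    """The 11 bin edges of :func:`make_bins` as an array."""
    make_bins(theta_min, theta_max)  # validation
    return np.linspace(theta_min, theta_max, N_BINS + 1)


def chips_to_probabilities(chips) -> np.ndarray:
    """Convert a 10-chip allocation to bin probabilities (chips / 100)."""
    chips = np.asarray(chips)
    if chips.shape != (N_BINS,):
        raise ValidationError(
            f"expected {N_BINS} chip counts, got shape {chips.shape}", ["chip_count"]
        )
    if np.any(chips < 0):
        raise ValidationError("chip counts must be non-negative", ["chip_sign"])
    if chips.sum() != N_CHIPS:
        raise ValidationError(
            f"chips sum to {int(chips.sum())}, expected {N_CHIPS}", ["chip_sum"]
        )
    return chips / N_CHIPS


def validate_elicitation(
    record: RouletteElicitation,
    attr: AttributeDefinition | None = None,
) -> RouletteElicitation:
    """Validate a roulette record against the data model and attribute support.

    Returns the record unchanged if valid; otherwise raises
    :class:`ValidationError` carrying the full list of violation codes.
    """
    violations: list[str] = []
    if attr is None:
        attr = WSGW_ATTRIBUTES.get(record.attribute)
        if attr is None:
            raise ValidationError(
                f"unknown attribute {record.attribute!r}", ["attribute"]
            )
    if record.state not in STATES:
        violations.append("state")
    chips = np.asarray(record.chips)
    if chips.shape != (N_BINS,):
        violations.append("chip_count")
    else:
        if np.any(chips < 0):
            violations.append("chip_sign")
        if chips.sum() != N_CHIPS:
            violations.append("chip_sum")
    if not (np.isfinite(record.theta_min) and np.isfinite(record.theta_max)) or (
        record.theta_min >= record.theta_max
    ):
        violations.append("interval")
    elif not (attr.contains(record.theta_min) and attr.contains(record.theta_max)):
        violations.append("support")
    if violations:
        raise ValidationError(
            f"invalid elicitation (expert={record.expert_id!r}, "
            f"attribute={record.attribute!r}, state={record.state!r}): "
            f"{violations}",
            violations,
        )
    return record
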