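"""Fit parametric subjective distributions to roulette histograms and sample them.

An elicited histogram gives cumulative probabilities at the nine interior bin
edges.  A parametric family — a beta rescaled to (0, 100) for percent-cover
attributes, a normal for everything else — is fitted by least squares on those
cumulative probabilities, the convention of standard elicitation-fitting
toolkits.  Fitted distributions can then be sampled, with draws clipped to the
attribute's support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core import (
    AttributeDefinition,
    RouletteElicitation,
    WSGW_ATTRIBUTES,
    bin_edges,
    chips_to_probabilities,
    validate_elicitation,
)

BETA_RESCALE = 100.0
#: interior rescaled edges equal to 0 or 1 are nudged inward before beta CDF
#: evaluation to keep the objective finite
_EDGE_NUDGE = 1e-9
_OBJ_TOL = 1e-8


class FittingError(RuntimeError):
    pass


@dataclass(frozen=True)
class FittedDistribution:
    """Parametric representation of one elicited histogram.

    ``params`` is (mu, sigma) for the normal family and (alpha, beta) for the
    rescaled beta, whose support is fixed to (0, 100).  ``fit_sse`` is the sum
    of squared CDF-matching residuals at the interior bin edges.
    """

    family: str  # "normal" | "beta_rescaled"
    params: tuple[float, float]
    fit_sse: float
    source: RouletteElicitation | None = None
    multimodal: bool = False

    def __post_init__(self):
        a, b = self.params
        if self.family == "normal":
            if b <= 0:
                raise ValueError("sigma must be positive")
        elif self.family == "beta_rescaled":
            if a <= 0 or b <= 0:
                raise ValueError("alpha and beta must be positive")
        else:
            raise ValueError(f"unknown family {self.family!r}")
        if self.fit_sse < 0:
            raise ValueError("fit_sse must be non-negative")

    def cdf(self, x):
        a, b = self.params
        if self.family == "normal":
            return stats.norm.cdf(x, loc=a, scale=b)
        return stats.beta.cdf(np.asarray(x) / BETA_RESCALE, a, b)

    def mean(self) -> float:
        a, b = self.params
        if self.family == "normal":
            return a
        return BETA_RESCALE * a / (a + b)


def choose_family(attr: AttributeDefinition) -> str:
    """Percent-cover attributes get a rescaled beta; all others a normal."""
    return "beta_rescaled" if attr.is_percent else "normal"


def detect_multimodality(record: RouletteElicitation) -> tuple[bool, list[int]]:
    """Flag histograms with two or more separated strict local maxima.

    A bin is a strict local maximum if it holds strictly more chips than both
    neighbours (one neighbour at the ends); plateaus are not maxima, so a
    uniform allocation is unimodal by convention.  Returns the flag and the
    0-based indices of the modal bins.
    """
    chips = np.asarray(record.chips)
    modes = []
    n = len(chips)
    for i in range(n):
        left = chips[i - 1] if i > 0 else -np.inf
        right = chips[i + 1] if i < n - 1 else -np.inf
        if chips[i] > left and chips[i] > right:
            modes.append(i)
    return len(modes) >= 2, modes


def _histogram_moments(edges: np.ndarray, probs: np.ndarray) -> tuple[float, float]:
    """Mean and sd of the histogram, including the within-bin variance."""
    mids = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    mean = float(np.sum(probs * mids))
    var = float(np.sum(probs * (mids - mean) ** 2) + width**2 / 12.0)
    return mean, np.sqrt(var)


def _normal_sse(mu, sigma, interior, cum):
    return float(np.sum((stats.norm.cdf(interior, loc=mu, scale=sigma) - cum) ** 2))


def _beta_sse(alpha, beta, interior01, cum):
    return float(np.sum((stats.beta.cdf(interior01, alpha, beta) - cum) ** 2))


def fit_distribution(
    record: RouletteElicitation,
    attr: AttributeDefinition | None = None,
) -> FittedDistribution:
    """Least-squares CDF fit of the chosen family to an elicited histogram.

    The objective is the sum of squared differences between the parametric CDF
    and the elicited cumulative probabilities at the nine interior bin edges
    (for the beta family, edges first mapped to (0,1) by dividing by 100).
    Optimisation is Nelder-Mead from moment-matched starting values with a
    coarse grid fallback.

    A single-bin histogram carries no spread information; it is fitted with
    its centre at the bin midpoint and a minimum spread of (bin width)/4, so
    the expert's stated bounds remain an effective support.
    """
    if attr is None:
        attr = WSGW_ATTRIBUTES[record.attribute]
    validate_elicitation(record, attr)
    multimodal, _ = detect_multimodality(record)

    edges = bin_edges(record.theta_min, record.theta_max)
    probs = chips_to_probabilities(record.chips)
    interior = edges[1:-1]
    cum = np.cumsum(probs)[:-1]
    family = choose_family(attr)

    mean0, sd0 = _histogram_moments(edges, probs)
    width = edges[1] - edges[0]
    single_bin = int(np.count_nonzero(probs)) == 1
    min_sigma = width / 4.0
    if single_bin:
        mean0 = float(0.5 * (edges[:-1] + edges[1:])[np.argmax(probs)])
        sd0 = min_sigma

    if family == "normal":
        def obj(p):
            mu, log_sigma = p
            return _normal_sse(mu, max(np.exp(log_sigma), min_sigma), interior, cum)

        x0 = np.array([mean0, np.log(max(sd0, min_sigma))])
        res = optimize.minimize(obj, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": _OBJ_TOL,
                                         "maxiter": 2000})
        mu, sigma = res.x[0], max(float(np.exp(res.x[1])), min_sigma)
        sse = _normal_sse(mu, sigma, interior, cum)
        if not np.isfinite(sse):
            mu, sigma, sse = _grid_normal(interior, cum, edges, min_sigma)
        return FittedDistribution("normal", (float(mu), float(sigma)), sse,
                                  record, multimodal)

    # rescaled beta
    interior01 = np.clip(interior / BETA_RESCALE, _EDGE_NUDGE, 1.0 - _EDGE_NUDGE)
    m01 = np.clip(mean0 / BETA_RESCALE, 1e-6, 1 - 1e-6)
    v01 = max((sd0 / BETA_RESCALE) ** 2, 1e-8)
    v01 = min(v01, m01 * (1 - m01) * 0.99)
    nu = m01 * (1 - m01) / v01 - 1.0
    a0, b0 = max(m01 * nu, 1e-3), max((1 - m01) * nu, 1e-3)

    def obj(p):
        return _beta_sse(np.exp(p[0]), np.exp(p[1]), interior01, cum)

    res = optimize.minimize(obj, np.log([a0, b0]), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": _OBJ_TOL,
                                     "maxiter": 2000})
    alpha, beta = np.exp(res.x)
    sse = _beta_sse(alpha, beta, interior01, cum)
    if not np.isfinite(sse) or sse > 1e-3:
        # local search stuck: restart from the best point of a coarse grid
        grid = _grid_beta(interior01, cum)
        res = optimize.minimize(obj, np.log(grid[:2]), method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": _OBJ_TOL,
                                         "maxiter": 2000})
        a2, b2 = np.exp(res.x)
        sse2 = _beta_sse(a2, b2, interior01, cum)
        if np.isfinite(sse2) and (not np.isfinite(sse) or sse2 < sse):
            alpha, beta, sse = a2, b2, sse2
        if not np.isfinite(sse):
            raise FittingError(
                f"beta fit failed for expert {record.expert_id!r}, "
                f"attribute {record.attribute!r}, state {record.state!r}"
            )
    return FittedDistribution("beta_rescaled", (float(alpha), float(beta)),
                              sse, record, multimodal)


def _grid_normal(interior, cum, edges, min_sigma):
    span = edges[-1] - edges[0]
    mus = np.linspace(edges[0], edges[-1], 41)
    sigmas = np.geomspace(max(min_sigma, span / 200), span, 41)
    best = (mus[0], sigmas[0], np.inf)
    for mu in mus:
        for s in sigmas:
            sse = _normal_sse(mu, s, interior, cum)
            if sse < best[2]:
                best = (mu, s, sse)
    return best


def _grid_beta(interior01, cum):
    grid = np.geomspace(0.05, 200, 35)
    best = (grid[0], grid[0], np.inf)
    for a in grid:
        for b in grid:
            sse = _beta_sse(a, b, interior01, cum)
            if sse < best[2]:
                best = (a, b, sse)
    return best


def sample(
    dist: FittedDistribution,
    n: int,
    attr: AttributeDefinition | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` values from a fitted distribution, clipped to the support.

    Count and length attributes are floored at 0; percent covers clipped to
    [0, 100].  Draws are reproducible given the generator state.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    a, b = dist.params
    if dist.family == "normal":
        draws = rng.normal(a, b, size=n)
    else:
        draws = BETA_RESCALE * rng.beta(a, b, size=n)
    if attr is None and dist.source is not None:
        attr = WSGW_ATTRIBUTES.get(dist.source.attribute)
    if attr is not None:
        draws = attr.clip(draws)
    return draws


def clipped_fraction(
    dist: FittedDistribution, attr: AttributeDefinition
) -> float:
    """Probability mass outside the attribute support (the mass clipping moves)."""
    lo, hi = attr.support
    below = float(dist.cdf(lo)) if np.isfinite(lo) else 0.0
    above = 1.0 - float(dist.cdf(hi)) if np.isfinite(hi) else 0.0
    return below + above
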