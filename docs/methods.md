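# Methods note

This note records the model, the numerical choices and the assumptions baked
into `offsetgain`, in enough detail to re-derive any number the package
produces.

## 1. Condition accounting

For an attribute with value `V` and reference (benchmark) value `R > 0`, the
benchmark-standardised condition is

```
BC = min(V / R, 1),        V ≥ 0.
```

The cap encodes the convention that exceeding the benchmark confers no extra
condition credit. Over a fixed management horizon, with start, business-as-
usual (BAU) and offset-future states,

```
AL = BC_start − BC_bau,   MG = BC_offset − BC_start,   TB = AL + MG.
```

`TB` is computed as the literal sum `AL + MG`, so the identity holds to the
last floating-point bit. When a BAU elicitation is absent for an attribute,
`AL` and `TB` are reported as NaN rather than imputed.

## 2. Trial-roulette elicitation and fitting

An elicitation is an interval `[θ_min, θ_max]` (θ_max > θ_min) with 100
chips over 10 equal-width bins; bins are half-open `[lo, hi)` except the
last, which is closed. Validation collects all violations (chip count, chip
sum, negative chips, interval ordering, support bounds, unknown state or
attribute) rather than stopping at the first.

**Family choice.** Percent-cover attributes get a beta rescaled to
(0, 100); counts and lengths get a normal. Sampling clips to the attribute
support (counts floored at 0; percent covers already live in (0, 100)).

**Objective.** With elicited cumulative probabilities `P_i` at the 9
interior bin edges `x_i`, minimise `Σ_i (F(x_i; φ) − P_i)²` over the family
parameters φ — a least-squares quantile/CDF match on the histogram, not a
likelihood. Optimisation is Nelder–Mead on `(μ, log σ)` or
`(log α, log β)` from a moment-matched start (bin-variance corrected by
width²/12), `xatol = fatol = 1e-8`, max 2000 iterations. A coarse
log-spaced grid search is used as a fallback only when the simplex result
is non-finite or has SSE > 1e-3. σ is floored at bin_width/4 so
degenerate histograms never collapse to a point mass; a histogram with all
100 chips in one bin falls back to a normal at the bin midpoint with that
floor σ. Multimodality is flagged when the chip sequence has ≥ 2 strict
local maxima (plateaus do not count); modes are reported as 0-based bin
indices.

## 3. Monte-Carlo pooling

Per expert and per draw, one reference value `R` is drawn and used to
standardise the start value and *both* futures, so within-draw comparisons
cancel reference uncertainty. Reference draws are floored at 1% of the
fitted reference mean to keep the ratio finite; the number of floored draws
is recorded on the output frame (`attrs["n_reference_floored"]`). Defaults —
84 draws per expert, 25 experts, hence 2100 pooled samples per attribute —
are the package's chosen panel size; both are parameters. Fern attributes
are excluded from benefit summaries by default because near-zero benchmarks
make their condition ratios unstable; they remain available as covariates
elsewhere. Summaries use `numpy.quantile` with linear interpolation;
`fraction_zero_TB` counts |TB| ≤ 1e-9.

## 4. Expert diagnostics

Per-expert means of AL and MG (attributes with no AL excluded and recorded)
are classified with tolerance 0.01: `neutral` if both |means| ≤ tolerance;
otherwise `offset_believer` (both positive), `pessimistic_both` (AL
positive), `optimistic_both` (MG positive), else `offset_sceptic`. The
panel AL–MG relation is an ordinary least-squares fit over per-expert means
(≥ 3 experts; rows sorted by expert id internally so results are invariant
to input order). An expert is flagged a systematic optimist/pessimist when
≥ 80% of their ≥ 5 attribute-level mean MGs share a sign.

## 5. Relative influence of point-score covariates

Aggregate point scores (site scored out of 100) are modelled with gradient-
boosted regression trees: tree complexity 5 (trees with at most 6 leaves,
i.e. exactly 5 splits), learning rate 0.005, bag fraction 0.75. Expert
identity enters as one-hot columns whose importances are summed back into a
single `expert_id` term. Rows are canonically sorted by (expert, site)
before splitting so results are invariant to row order; the 75/25
train/holdout split is stratified by expert. The tree count is chosen by
forward stepping (50 trees per step, up to 10 000) monitored on the 25%
holdout with a patience of 2 steps, then the model is refitted fresh at the
selected count — a holdout-based stand-in for stepwise cross-validated
selection. Normalised relative influence is impurity-based importance
scaled to sum to 100. Fitted functions are partial-dependence curves over
the training rows; condition predictions average over expert levels and are
clipped to [0, 100]. If the response is constant the selected ensemble has
zero trees and influence is undefined (an error), not silently zero.

## 6. Synthetic panel generator

The generator emulates a field elicitation exercise with known truth, not
any particular real data set. Sites sit on a latent gradient `u ~ U(0,1)`;
attribute values are `ref · (0.05 + 0.95u)` plus noise, with invasive cover
declining in `u`. True condition is a weighted mean of capped attribute
ratios. Ground-truth dynamics are linear in start condition:
`MG* = a(1 − BC_start) + b` (defaults a = 0.15, b = 0 — more headroom,
more gain) and `AL* = c · BC_start` (c = 0.10 — more to lose, more
averted). Each roulette expert carries a shared optimism term
(SD 0.05 condition units) added to *both* future states, inducing the
negative among-expert AL–MG correlation seen in real panels; subjective
spread is `relative_sd` (0.15) times the state mean, shrunk by an
`overconfidence_factor`. Histograms are formed over a ±3 SD interval with
largest-remainder rounding to exactly 100 chips. Point-score experts have
scoring intercepts (SD 5) and noise (SD 5); 29 experts score 15 of 64
sites each, 5 in common, spread across the gradient. Default panel sizes
(64 sites, 29 point experts, 16 BAU, 25 roulette) are the package's chosen
defaults for a realistic exercise. `pooled_median_mg_interval` gives a
direct Monte-Carlo 95% interval for the pooled median MG straight from the
generative process (no elicitation or fitting), used as the oracle for
end-to-end recovery checks.

What the generator does **not** emulate: motivational bias tied to stakes,
expert learning or anchoring between questions, spatial correlation among
sites, or non-linear condition dynamics.

## 7. Limitations

* The least-squares CDF fit ignores within-bin chip placement and treats
  chips as exact probabilities; very ragged histograms are summarised by a
  unimodal family even when flagged multimodal.
* The condition cap makes benefits insensitive to improvements above the
  benchmark.
* Holdout-based tree selection is noisier than full cross-validation at
  small panel sizes; ensembles over seeds (`fit_brt_ensemble`) are the
  intended mitigation.
* Impurity-based influence shares the known bias toward high-cardinality
  covariates; expert identity (many one-hot levels, importances summed)
  should be compared against permutation checks when stakes are high.
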