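# Methods

## Common categorical scheme

All three sources are mapped onto one ordered scheme of categorical
characteristics. The Spanish default is age block (`<35`, `35–49`, `≥50`;
under-20s fold into the first block, over-64s into the third), sex (F/M),
autonomous community (17 communities plus Ceuta and Melilla merged into one
label), and a 10-block activity classification defined by CNAE-2009 division
ranges. Mapping helpers are idempotent — a value that is already a valid
category label passes through — so harmonizing a harmonized table is the
identity. CNAE divisions outside the block definition (34, 40, 44, 48, 54,
57, 67, 76, 83, 89, 98 and other codes with no active content) raise an
unmapped-code error by default rather than falling into an "other" bucket;
a lenient mode drops and counts them instead. The province → community
lookup ships as a data file so other administrative schemes can be swapped
in.

Record filters: survey rows are kept only for respondents who worked in the
reference week and report a province inside the country; rows missing age,
sex or activity are dropped and counted (the sources do not prescribe a
treatment for these, so the count is always reported). Register rows coded
as relapses (type-of-accident 2) or commuting accidents (place-of-accident
3, "in itinere") are removed per the official reporting convention. Every
filter's drop count is reported and `rows_in = retained + Σ dropped` always
holds.

## Calibration weighting

Given the K×S stacked one-hot matrix `Y` and target shares `p` (each
feature's shares a distribution), the weights solve

    max −Σ wₛ ln wₛ   s.t.  Yw = p,  w ≥ 0,  1ᵀw = 1.

The strict-equality form makes the regularization weight immaterial; it is
kept in `SolverSettings` only for interface stability. The optimum has the
product (raking) form `wₛ ∝ exp(yₛᵀλ)`, so the solver minimizes the smooth
convex dual `g(λ) = log Σₛ exp(yₛᵀλ) − pᵀλ` with L-BFGS; the dual gradient
is exactly the marginal residual `Yw(λ) − p`, and a solve is accepted only
if the residual meets the configured tolerances (defaults
`eps_rel = eps_abs = 1e-6`, iteration cap 100,000). Per-feature constraint
redundancy (both sides sum to one) only creates flat directions in the
dual. Categories with an exactly-zero target but nonzero sample membership
are handled by pinning their instances to weight zero before the solve (the
entropy optimum reaches them only in the limit λ → −∞); a positive target
with no sample instance is reported as infeasible before solving.

Properties asserted in the tests: agreement with an independent IPF
implementation (uniform start, run to 1e-12) within 1e-6 per weight on
random feasible instances; equal weights for identical category vectors;
entropy bounded by ln S; entropy no lower than random feasible
perturbations projected back onto the constraint set. Entropy is reported
positive on the natural-log scale. The full-scale study's printed entropy
pair (12.204 vs 12.357) requires the restricted national microdata; the
package reports the analogous diagnostics for whatever sample it is given
and asserts the bound.

## Synthetic population

Cell masses `N · Σ_{s∈l} wₛ` are integerized by largest-remainder
apportionment (floors first, leftover units to the largest fractional
remainders, ties to the earlier cell in the lexicographic enumeration),
which conserves `Σ m_l = N` exactly and keeps every count within one worker
of its exact share. Masses are normalized before apportionment, so weight
vectors rounded for publication (summing to slightly less than one) still
allocate the full population; this is what makes the published worked
example reproduce exactly on its self-consistent cells. Cells with no
survey instance are emitted with `m_l = 0` so the enumeration is stable;
raw (non-integer) masses are retained alongside and can be used for the
ratio denominators instead (`use_raw_masses`).

## Ratios

`r_l = 100000 · A_l / W_l` per stratum and year; exact values are kept and
the display value is truncated toward zero, the convention most consistent
with the published result tables (8 of 10 printed rows match exactly; the
two that differ by ≤2 units trace to rounded worker counts in print).
Cells with `W_l = 0` are flagged invalid, excluded from model training, and
never imputed. Aggregation always sums accidents and workers over the
marginalized categories and re-divides — never averages cell ratios — which
makes it order-independent and conservative of both totals.

## Baselines

The baseline of a stratum is the ratio a gradient-boosted ensemble predicts
for it from its characteristics alone. Model: XGBoost regression trees on
the one-hot characteristics, `count:poisson` objective applied directly to
the ratio (the configuration of the original full-scale study); a
statistically more orthodox alternative — accident counts with a
log-exposure offset of `workers/100000` — is available as
`objective_mode="counts_offset"` and recovers simulated true rates somewhat
better, but the literal form remains the default for fidelity.

Leave-group-out protocol: the training set for stratum `l` is every valid
stratum except those from the same autonomous community with the same
activity — the stratum's own community–activity group, i.e. itself and its
most similar strata. The stricter variant that also removes every
same-community and every same-activity stratum is available as
`exclusion_mode="either"`; it forces the model to extrapolate both group
effects and is structurally unable to learn either, which makes it
uncompetitive with even a linear fit whenever those effects matter, so the
group rule is the default. Exclusion integrity is asserted programmatically
on every fit. Predictions from `n_runs = 10` refits with distinct derived
seeds are averaged (their spread is reported per cell) and clipped at zero.

Hyperparameters: the shipped preset is the set selected by the full-scale
study's grid search (`max_depth 2, learning_rate 0.2, n_estimators 150,
colsample_bytree 0.7`) on top of the fixed settings (`subsample 0.8`,
`colsample_bylevel 0.3`, Poisson objective). The source material is
internally inconsistent here — it lists a fixed shrinkage of 0.1, a tested
learning-rate axis of [0.05, 0.1, 0.3, 0.5], and a selected learning rate
of 0.2 that appears in neither; the preset is shipped verbatim as printed
and the search machinery treats shrinkage as one parameter. The search
itself scores every grid point on shared random train/test splits (33 %
held out), ranks candidates by their minimum test coefficient of
determination across splits, and among the best (pool of 100 by default)
prefers the smallest train–test gap, then shallower trees, then fewer
estimators — all anti-overfitting criteria. Degenerate (constant-ratio)
responses are rejected.

Comparison models: an in-sample OLS on the one-hot design (one reference
category dropped per feature), and the same OLS run under the identical
leave-group-out protocol. The forecast-vs-forecast comparison is the
meaningful one: an in-sample R² is inflated by fitting observation noise,
which at simulation scale (tens of survey instances and accidents per cell)
is a substantial share of the variance.

## Simulator

The simulator generates the three sources with known truth. Worker
population: multinomial over cells with log-linear attractiveness
(per-feature effects, log-sd 0.5) plus cell-level noise (0.15), so the
joint is deliberately not product-form. Survey: inclusion probability
proportional to cell count times a product of per-feature response
propensities (defaults: older workers and women over-represented, activity
blocks on a mild ramp) — the regime in which entropy calibration is
consistent, because the truth differs from the biased sampling distribution
by exactly a product factor and is therefore the I-projection the solver
finds; a non-product tilt (`misspecified_bias_sd`) exists to demonstrate
the failure mode of under-represented groups. Rates: log-linear with
per-feature spreads chosen to mirror stratum-level incidence structure
(activity 0.5 — the construction-versus-office magnitude, sex 0.45, age
0.35, community 0.15), an age×sex interaction (0.30) that a tree ensemble
can learn but an additive model cannot, a small community×activity
interaction (0.06, the "low-interaction" default), and an intercept of
3,000 per 100,000 workers·year, the national order of magnitude. Register:
per-cell Poisson counts at `count·rate/100000`, with relapse rows (4 % of
the genuine total) and commuting rows (10 %) injected on top so the filters
must remove exactly those counts. Default sizes are desk-scale — 8
communities (480 cells), 200,000 workers, 5,000 respondents — large enough
for the boosted model, small enough for a minutes-scale test run.

What the simulator does not emulate: real Spanish demography and the actual
joint distribution of the labour force, temporal dynamics, non-categorical
covariates, and reporting artifacts other than relapses and commuting
records. Passing recovery tests therefore demonstrates the pipeline's
statistical machinery under a correctly- (or deliberately mis-)specified
bias model, not the accuracy of any particular national estimate; the
full-scale study's printed R² values require the restricted microdata and
are not reproduced, only the qualitative ensemble-versus-linear ordering
is.

## Numerical choices and degenerate inputs

Floor rounding for displayed ratios; exact rationals internally. Largest
remainder ties break to the earlier cell. Dual solves start at λ = 0 and
are deterministic; all stochastic stages (simulation, splits, refits)
derive their seeds from one master seed via a seed sequence, recorded in
the run manifest. Zero-weight instances contribute 0·ln 0 = 0 to entropy.
Aggregating away every feature is allowed and yields the single national
cell. Empty survey after filtering, infeasible targets, degenerate
responses and too-small training sets all raise typed errors that the CLI
maps to distinct exit codes (2 config / 3 data / 4 solver).

## Problem sizes used in the checks

The recovery checks run the full pipeline at the default scenario over 10
seeds (baseline recovery and model ordering), at survey sizes 1,000 / 5,000
/ 20,000 over 10 seeds (cell-count convergence), and the solver oracle
check uses 100 random instances of up to 4 features and 50 instances.
These sizes keep the whole suite at minutes scale while leaving every
claimed property measurable.
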