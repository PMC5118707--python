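# Methods

## The process and the data

A continuous bead mill grinds an *E. coli* slurry between agitated glass
beads; the response is the concentration of released cholesterol oxidase
(COD, g/L) in the outflow. Four factors drive the process: slurry feed rate
*A* (mL/h), bead load *B* (% v/v of the 600-mL grinding chamber), cell load
*C* (OD₆₀₀) and run time *D* (min). The packaged dataset is a 30-run central
composite design (CCD) — 16 factorial, 8 axial, 6 center runs — with factor
coding centers (400, 70, 60, 25) and steps (100, 10, 10, 5).

The axial distance is α = 1.4142: although such designs are often described
with levels −2…+2, the tabulated axial levels (e.g. 400 ± 141.42 mL/h) are
√2 coded units from the center, and the builder follows the tabulated
values. α is a parameter; the rotatable value 2^(k/4) is available.

Responses are stored at the supplied two-decimal precision; the
three-decimal extremes (0.794, 3.282 g/L) reported alongside the table are
kept as fixture metadata because derived quantities (the max/min ratio
4.133) depend on them.

## Response-surface methodology

Models are polynomials over coded factors fitted by ordinary least squares.
All diagnostics follow the standard DoE conventions:

- **Type III partial SS.** For a single-df term,
  SS_j = β̂_j²/(XᵀX)⁻¹_jj, which equals the increase in residual SS when the
  term alone is removed; the test suite verifies this identity against
  brute-force refits for every term.
- **Lack of fit / pure error.** Pure error is the within-replicate-group
  scatter (5 df from the 6 center replicates in the packaged design); lack
  of fit is the residual remainder (9 df for the 15-term model,
  n − p = 30 − 16 = 14 total).
- **PRESS** uses the hat-matrix shortcut Σ(eᵢ/(1−hᵢᵢ))², verified against
  explicit leave-one-out refits; predicted R² = 1 − PRESS/SS_total.
- **Adequate precision** is (max ŷ − min ŷ)/√(p·σ̂²/n) with p counting the
  intercept; values above 4 indicate a usable signal.

**Model reduction.** Linear terms are kept at p < 0.05; interactions *and*
quadratics at the relaxed p < 0.10. The relaxed class for quadratics is
deliberate: it is the screening that reproduces the reduced term set used
for this dataset (D² enters at p = 0.053, B² at p = 0.043). With hierarchy
on, a factor appearing in any kept higher-order term retains its linear
term — this is why B (p = 0.32) stays in the reduced model.

**Two canonical term sets.** `FIFTEEN_TERMS` is the full reduced-cubic
ANOVA set (4 linear + 6 interactions + 4 quadratics + ABC); `ELEVEN_TERMS`
is the term set of the published reduced coded equation
(A, B, C, D, AB, AC, BD, CD, A², B², D²). The two do not describe the same
reduction — the equation retains AB and CD although they fail the screen —
so both are provided rather than guessing intent. `REFERENCE_EQUATION`
carries the published coefficients; note that its displayed intercept
(2.22) is rounded — the same model's center-point prediction is printed
elsewhere as 2.24, and refitting the two-decimal responses gives 2.256.
Refits of the 2-dp data reproduce all reference coefficients within ±0.03
except B² (−0.157 vs −0.094), a discrepancy attributable to the original
fit using unrounded responses.

**Optimum search.** `rsm_optimum` scans a dense grid over the coded box
(21 points per axis by default) and polishes the best node with L-BFGS-B;
the test suite checks the result against an independent 41⁴ grid oracle.
Degenerate inputs: a constant response column yields R² = 0 (not NaN);
zero residual df reports F as undefined rather than raising.

## Neural surrogate

Architecture: 4 inputs → one tanh hidden layer (10 units by default,
configurable) → linear output, on inputs and targets min–max normalized to
[−1, 1]. Only COD recovery is modeled.

Training is batch Levenberg–Marquardt: solve (JᵀJ + μI)δ = Jᵀe on the
training split, with μ (damping, initial 1e-3) divided by 10 on accepted
steps and multiplied by 10 on rejections. The Jacobian is computed by
reverse accumulation and verified against finite differences. The 30 runs
are split 20/5/5 into train/validation/test by a seeded permutation.
Stopping: validation failures ≥ patience (6), training-MSE goal, gradient
below 1e-7 (the customary LM floor), μ overflow, or 300 epochs; the
returned parameters are those of the minimum-validation-MSE epoch.

With 61 parameters fitted to 20 points, LM reaches a stationary point in
about six epochs and single runs vary strongly with the initialization.
Two design choices address this: Nguyen–Widrow initialization (hidden-unit
active regions tile the input range) and seeded multi-restart training
(default 10 restarts; the restart with the lowest best-validation MSE is
returned). All randomness — split, every restart's weights — derives from
the single user seed, so training is exactly reproducible. The "gradient
descent with momentum" learning function sometimes quoted alongside LM
toolchains is vestigial under batch LM and is not implemented.

Even so, surrogate quality on 30 noisy runs is seed-dependent: the
replicate noise (σ = 0.21 g/L ≈ 0.17 on the normalized scale) alone puts a
floor of ~0.03 on the achievable all-run normalized MSE, and individual
seeds land between ~0.04 and ~0.09. Optimum *locations* along weak factors
are correspondingly unstable (bead load has partial F ≈ 1 in this data set,
so surrogates do not consistently place the optimum at high bead load),
while optimum *values* are stable to ~±10 %.

## Genetic algorithm

Real-coded, generational: linear rank selection (ties broken by evaluation
order via stable sort), intermediate blend crossover with probability 0.8,
otherwise a Gaussian mutation with σ = 0.1 of each variable's range,
clipped to bounds; 2 elites; population 50; 100 generations. Maximization
is posed by negating the objective. The published option set for this
process is not available; these defaults are ordinary textbook values and
every one is overridable. Default bounds are each factor's axial range.
For a fixed seed runs are bit-reproducible, and with elitism the
best-so-far trace is monotone.

## Synthetic-data generators

**Polynomial truth** draws responses as the reference equation at each
coded point plus N(0, σ²) with σ = 0.21 g/L — the square root of the
pure-error mean square (0.045) of the packaged data — i.e. homoscedastic
replicate noise, the only variance structure the data support.

**Mechanistic truth** extends batch first-order lysis,
ln(1/(1−Rp)) = k·t, to continuous operation by treating the chamber as a
stirred vessel: residence time τ = 60·V·(1−b/100)/Q minutes, steady-state
fractional release Rp = kτ/(1+kτ), damped by a startup factor
(1 − e^(−t/τ)) while the chamber content turns over. The rate constant
k = k0·(b/100)^p/(1+γ·c) rises with bead load and falls with slurry
viscosity (proxied by cell load). Response (g/L) =
Rm · f · c · Rp · 10⁻³ with Rm = 5.89 µg/mL/OD₆₀₀ (the dilute-assay
maximum release) and a slurry concentration factor f = 10: the dilute-assay
figure alone cannot produce the observed multi-g/L recoveries, so the
effective maximum is calibrated — once, frozen — together with
(k0 = 2.5 min⁻¹, p = 5, γ = 0.015/OD, V = 600 mL) so that the packaged
design yields responses inside the observed 0.8–3.3 g/L window with the
expected qualitative behavior: non-decreasing in bead load, cell load and
run time, unimodal-or-decreasing in feed rate. This continuous-flow
extension is a documented modeling device for generating plausible test
data, not a fitted process model.

A caveat for recovery studies: the mechanistic surface is flat (< 1 %) in
feed rate over the upper third of its range, so the feed coordinate of its
argmax is not statistically identifiable from 30 runs; recovery checks use
the identifiable coordinates and the optimum *value*.

**What passing tests do and do not show.** The generators emulate the
design geometry, the replicate noise level and the qualitative factor
effects of the real process. They do not emulate heteroscedasticity, drift,
batch effects, heat generation or bead wear; parameter-recovery results
therefore demonstrate correctness of the estimation machinery, not
robustness to real-world artifacts.

## Numerical choices

- p-values from scipy's F survival function; no two-sided conventions arise.
- Coefficient comparisons against published values use ±0.03 absolute and
  summary statistics ±1–2 % relative, reflecting the two-decimal rounding of
  the stored responses (the original fit used unrounded data).
- Rank deficiency raises an error naming the dependent columns (greedy
  rank-revealing sweep); leverage-one runs make PRESS undefined and raise.
- Monte-Carlo recovery checks hold the headline feed-rate coefficient to
  2 MC standard errors and the full 16-coefficient vector to a
  multiplicity-adjusted 3.5-SE joint bound.
- Problem sizes used in validation: 41⁴ grids for optimum oracles, 200
  simulated designs for coefficient recovery, 5 fixed seeds (1–5) for every
  stochastic agreement band, 10 LM restarts per training call.

## Known limitations

- The ANN path's optimum location along statistically weak factors is
  seed-dependent (see above); report optima with the per-seed spread, not a
  single run.
- The GA is a plain generational scheme; no constraint handling beyond box
  clipping, no hybrid local polish.
- The economic comparison is a single productivity fold-change
  (24.33/6.56 ≈ 3.7); no cost model is included.
- Designs other than full CCDs (fractional factorials, Box–Behnken,
  D-optimal) are out of scope, as are multi-response desirability methods
  and Box–Cox transforms.
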