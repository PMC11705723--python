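# Methods

## Scope and model

`aafscreen` re-implements, as a tested pipeline over synthetic data with
known ground truth, the drug-sensitivity and combination-synergy analysis
applied to ovarian-cancer cell lines cultured with patient-derived
acellular ascites fluid (AAF): plate quality control and normalisation,
four-parameter log-logistic (4PL/LL4) concentration-response fitting, drug
sensitivity scores (DSS), combination ratios (CR), ZIP synergy, 100−VUS
surface scores, treatment ranking, and the downstream statistics on DSS and
phospho-marker tables.  The raw patient screen is not publicly deposited,
so every stage is validated by recovery against the synthetic generator and
against independent numeric oracles rather than against archived tables.

### Concentration-response model

The response is parameterised on the inhibition scale.  For dose `x`
(molar),

    I(x) = c + (d − c) / (1 + (e/x)^b),        V(x) = 100 − I(x)

with Hill slope `b > 0`, baseline inhibition `c` (fixed at 0 by default —
the "lower boundary at zero" convention of the normalised screens), maximal
inhibition `d` ∈ [0, 100] (the top asymptote; `100 − d` is the residual
viability floor of a partial-efficacy drug), and midpoint `e` where
inhibition reaches `(c + d)/2`.  This is the parameterisation under which
the DSS method is defined and under which chemoresistance has two natural
knobs: a rightward midpoint shift (potency loss) and a reduction of `d`
(efficacy loss, i.e. a rising viability floor).  Fitting is nonlinear least
squares (`scipy.optimize.least_squares`, trf, box constraints
`b ∈ [0.05, 25]`, `d ∈ [0, 100]`, log-parameterised midpoint).  Starts:
`d₀` = strongest observed inhibition, `e₀` = dose nearest half of `d₀`,
`b₀ = 1`; the multi-start accepts an essentially exact fit or two
concordant successful starts, and sweeps up to five additional jittered
starts before declaring non-convergence (reported as a flag, never an
exception).  ICp uses the closed-form inversion
`x = e ((p − c)/(d − p))^(1/b)` in the absolute convention (IC50 = dose at
50% inhibition on the normalised scale); a relative-to-span mode is
available behind a flag.  Outlier screening is a single pass: points with
absolute studentized residual > 3 against the initial fit are dropped (at
most 20% of points), followed by one refit.

### DSS

The raw activity is the area of the fitted inhibition curve above a
threshold `t` (default 10%) over the tested window `[x_min, x_max]` in
log10 molar, computed from the closed-form antiderivative of the logistic
(`∫ s du = ln(1 + 10^{b(u−u_e)}) / (b ln 10)`, evaluated with `logaddexp`
for stability).  Variants:

* **DSS1** `= 100·A / ((100 − t)(x_max − x_min))` — area normalised to the
  full-window box.
* **DSS2** `= DSS1 · log10(d)/2` — penalises partial maximal inhibition
  (identity at `d = 100`); the package default.
* **DSS3** `= DSS2 · (x_max − x_on)/(x_max − x_min)` — additionally scales
  by the fraction of the window in which the curve is active (`x_on` = the
  threshold crossing).

The cited DSS method's exact variant normalisations are not restated in
the source study, so variants 2 and 3 above are this package's documented
conventions; all three are implemented and selectable.  Scores are clamped
to [0, 100] and are 0 whenever `d ≤ t`.

### Combination scoring

* **CR** `= (DSS_combo + 100)/(DSS_mono + 100)`: the +100 augmentation
  keeps the ratio defined (and equal to 1) when either score is 0; CR > 1
  means the combination improves on the comparator, which is the priming
  standard-of-care drug's monotherapy DSS in the same condition.
* **ZIP**: the zero-interaction reference at each positive dose pair is the
  Bliss expectation `y₁ + y₂ − y₁y₂` from the fitted monotherapy marginals
  (inhibition fractions).  The observed surface is smoothed by directional
  logistic refits — one fit per fixed partner dose, averaged over the two
  directions for factorial grids, single direction for anchored grids
  (where the priming marginal comes from the monotherapy fit).  Design
  choice: the directional refit initialises its baseline at the partner's
  fitted single-agent effect but leaves both asymptotes free within
  generous bounds (baseline ±0.5, top ≤ 1.25).  A refit with a pinned
  baseline cannot represent a uniformly shifted Bliss surface and recovers
  only ~80% of an injected interaction; the free-asymptote smoother
  reproduces noiseless Bliss-independent and uniformly shifted surfaces
  exactly.  `delta = (observed − expected)·100`; the summary is the mean
  delta over positive-dose cells.
* **100−VUS**: iterated trapezoid integration of the viability surface over
  (log10 dose × log10 dose) on the positive-dose cells, normalised by the
  enclosing box (100% viability over the two axis spans); reported as
  `100 − VUS` so high = effective.  Zero-dose levels anchor the marginals
  but do not enter the integration bounds (log of zero); anchored grids are
  scored with the 1-D normalised-AUC analogue along the titrated drug.
* **Synergy calls**: per priming-drug population, the threshold is the
  empirical 95th percentile of ZIP summaries using linear interpolation
  between order statistics (type 7 — recorded because the threshold depends
  on the convention); entries strictly above are synergistic.  CR < 0.75
  (strict) flags non-improvement.  Populations under 20 are marked
  percentile-unstable.
* **Ranking**: descending on CR (or DSS) with deterministic tie-breaks —
  higher DSS, fewer drugs, lexicographic label.

### Plate QC and normalisation

Z′ `= 1 − 3(σ_pos + σ_neg)/|μ_pos − μ_neg|` with sample SDs; pass cutoff
0.5 (standard HTS practice; the source study reports QC without stating its
cutoff).  Control normalisation maps the per-plate negative-control mean to
100% and positive-control mean to 0% and is exactly invariant to per-plate
gain.  Vehicle normalisation (for concentration-response experiments)
divides by the per-plate vehicle reference; the reference is the mean of
the high-DMSO and low-DMSO well means (the alternative grand-mean-of-all-
vehicle-wells reading is selectable — the prose this rule derives from
admits both).  Water-solvent drugs without a vehicle gradient fall back to
the untreated controls (reference ratio identically 1).  Viability is not
clipped; out-of-range values carry information for fitting.

### Downstream statistics

Marker tables are normalised as log2 ratio to the same-sample IgG control
(an `arcsinh(x/cofactor)` alternative is provided; the exact heatmap
transformation in the source is unstated, so both are exposed).  Per-marker
inference is a two-sided one-sample t against the unstimulated control (or
paired t with a matched table), Holm-corrected across the panel
(statsmodels `multipletests`; the test suite checks it against a
brute-force step-down).  Correlation matrices use Pearson r with the
t-transform p, Holm-corrected over unique pairs, significance mask at
adjusted p < 0.05.  The two-way ANOVA on DSS uses the additive model (cell
line + AAF condition) with type-II sums of squares — the screens often
yield one DSS per condition per run, leaving no replication for an
interaction term; a full-interaction option exists.  Tukey HSD among AAF
levels uses the additive model's residual mean square and the
studentized-range distribution (Tukey–Kramer standard errors for unbalanced
counts; marginal means, which equal adjusted means in balanced designs).
Clustering is scipy's Ward linkage on Euclidean distances (the Ward-d2
criterion), exported as merge heights, leaf order and Newick (via
scikit-bio).

## Synthetic generator

The generator emulates the study design: 5 cell lines × (media + 5 AAF
conditions) = 30 conditions, 11 drugs (2 standard-of-care + 9 repurposed),
8-point half-log (√10) titrations — micromolar-to-millimolar for the
repurposed drugs, nanomolar for paclitaxel — 3 technical × 2 biological
replicates, on one 384-well plate per (cell line, condition, biological
replicate) with untreated negative controls, full-kill positive controls
and high/low vehicle wells.  Signals follow
`RFU = gain · viability_fraction · exp(N(0, σ))` with
`σ = sqrt(ln(1 + CV²))` (multiplicative log-normal; plate-reader
luminescence noise is scale-dependent) and per-plate gain uniform in
[0.8, 1.2] × nominal to exercise per-plate normalisation.  Noise CV
defaults to 5%.  Biological replicates perturb the true midpoint by a 5%-CV
log-normal (passage effects); technical replicates share the truth.

Chemoresistance is phenomenological at the curve level: each (cell line,
AAF) carries a `resistance_shift` multiplying every midpoint and an
`efficacy_loss` subtracted from maximal inhibition (floored at 0).  The
magnitudes of real AAF-induced shifts are not published, so they are free
parameters; the defaults place mild effects on ordinary AAFs (shift 1–3.2×,
loss 0–20 points) and a strong phenotype (10×, 50 points) on one condition,
"A19" — the carcinosarcoma-ascites analogue that resists every drug.
Combination grids carry a constant Bliss-deviation `epsilon` over the
positive-dose region (`y = y₁ + y₂ − y₁y₂ + ε`, clipped to [0, 1]); a
dose-dependent interaction is out of scope.  Anchored grids fix the priming
drug at its true ICp (default IC20).  Marker tables draw log2 fold-changes
from a multivariate normal whose correlation matrix embeds the target pairs
(feasibility checked by eigenvalue before sampling); fluorescence is
`IgG_base · 2^fold`, so IgG normalisation recovers the true fold-changes
exactly at zero noise.

What the generator does **not** emulate: growth kinetics, spheroids,
cytokine concentrations, edge/spatial plate effects, dose-dependent
interactions, and non-log-normal error (e.g. dispensing failures).  Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated error model, not robustness to every artefact of real plates.

## Validation experiments and problem sizes

`aafscreen.recovery` packages the standard experiments, at the sizes the
package's own validation runs use: closed-form DSS vs a 10⁴-point trapezoid
oracle over 1000 random curves; midpoint recovery over 200 seeds of the
8-dose, 3×2-replicate, 5%-CV design; ZIP null over 500 noiseless
Bliss-independent grids with random marginals and sign recovery over 200
noisy seeds at ε = ±0.10; ANOVA type-I calibration over 500 null
simulations and Tukey power over 200 seeds at a 3-residual-SD shift; and
the end-to-end ranking over 50 full screens.  The ε-recovery scenario uses
partial-efficacy marginals (maximal inhibition 70%) on a mid-range grid so
the whole Bliss surface stays inside [0.12, 0.90]: the generator clips
expected inhibition to [0, 1], and a ±0.10 shift is only representable —
hence only recoverable — where it is not truncated.

## Numerical choices and degenerate inputs

Closed-form DSS uses `logaddexp` to avoid overflow at extreme slopes;
curves with `d ≤ t` score exactly 0; saturated curves score exactly 100
after clamping.  (When validating the closed form against a dense
trapezoid oracle, note the oracle carries O(h²) absolute error at the
threshold-crossing kink, so relative agreement is only meaningful for
non-vanishing scores.)  Free-baseline fits are parameterised as
(baseline, span) so the asymptotes cannot invert on flat data.  Flat titrations fit with `d ≈ 0`, are flagged
non-responders and score 0 rather than erroring.  ICp outside `(c, d)`
raises (the target is never reached within the model range).  Z′ requires
two wells per control group and distinct means.  Correlation of constant
columns is masked NaN, never silently 0.  Zero-variance t-tests report the
limit case (p = 0 for a nonzero shift, p = 1 otherwise) with a flag.
Percentile thresholds from populations under 20 are flagged unstable.
Clustering refuses missing values and directs to complete-case extraction;
ties in merge order are resolved by scipy's deterministic ordering, so
identical inputs always give identical trees.

## Known limitations

DSS variant 2/3 normalisations are this package's documented conventions
for the method's under-specified variants.  The ZIP summary is the mean
delta; a maximum-over-matrix convention would give larger values on the
same data, and printed population thresholds from the real screen are not
comparable to synthetic ones.  The Tukey post-hoc uses marginal rather than
covariate-adjusted means and is exact only for balanced designs.  The
vehicle-reference rule has two defensible readings; both are implemented,
neither asserted as the original intent.
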