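# Methods

`facenorms` implements the standard Italian neuropsychological norming
pipeline (the "equivalent scores" tradition) for a 36-item facial
complex-mental-state recognition test, together with the clinical statistics
used around it. This note records the models, the defaults and why, and the
design decisions taken where the methodology leaves room.

## Regression-based norms

Raw scores $y \in [0, 36]$ are regressed on demographic predictors. For
each of age and education the search considers the identity, quadratic,
logarithmic ($\ln x$), inverse ($1/x$) and square-root transforms, plus
exclusion of the variable — a $6 \times 6$ grid of 36 candidate OLS fits.
Predictors enter centered at the sample mean of the transformed values, so
the intercept is the sample mean score and the adjustment at the centering
demographics is exactly zero.

**Selection.** "Most effective in reducing the residual variance" is
operationalized as maximizing adjusted $R^2$ (equivalently, minimizing the
residual variance with a degrees-of-freedom penalty). A combination is
admissible only if every included coefficient has $p <$ `entry_alpha`
(default 0.05; set to 1 to disable the gate — whether the original norming
gated entry on significance or on residual variance alone is not
documented, so both are supported). Ties break toward fewer parameters,
then toward the transform order identity, quadratic, logarithmic, inverse,
square root.

**Identifiability caveat.** Over realistic demographic ranges the five
candidate transforms are monotone and nearly collinear, so at $n \approx
229$ with residual noise calibrated to an adjusted $R^2$ near 0.31 the
*specific transform* is only weakly identified: simulation shows the
adjusted-$R^2$ margin between the generating pair (age: identity,
education: $\sqrt{\cdot}$) and the winning pair is typically below 0.01, and
exact-pair recovery is on the order of 10–20%, rising toward 100% only as
the noise shrinks (≈85% at noise SD 0.5). The *adjustment* produced by
competing transform pairs is nonetheless almost identical, which is why the
practice is harmless for norming even though transform recovery is poor.

**Adjusted scores.** With fitted slopes $\beta_v$ and centers $c_v$,

$$\text{adjusted} = \text{raw} - \sum_v \beta_v\,(t_v(x_v) - c_v).$$

For the published FACE constants this is
`raw + 0.0723 (age − 53.275) − 1.6493 (√edu − 3.595)`. Adjusted scores are
deliberately **not** clamped to $[0, 36]$: the top equivalent-score interval
is open-ended and clamping would distort it. Corrections are reported at 2
decimals (grid), thresholds at 3; all comparisons are made at full
precision. Reported rounding is half-away-from-zero everywhere (banker's
rounding would change some printed cells and the 27.5% → 28% prevalence
example).

**Heteroscedasticity.** The Breusch–Pagan LM test (squared residuals
regressed on the design; statistic $nR^2$, $\chi^2_k$ reference) is computed
via statsmodels and stored with the fit, for reporting.

## Tolerance limits and equivalent scores

With $x_{(1)} \le \dots \le x_{(n)}$ the sorted adjusted scores:

* **Outer limit** (ES0 boundary): $x_{(r)}$ with $r$ the *largest* rank such
  that $P(\mathrm{Bin}(n, p) \ge r) \ge \gamma$, defaults $p = 0.05$,
  $\gamma = 0.95$. At $n = 229$ this gives $r = 6$. With 95% confidence at
  most 5% of the healthy population scores at or below it.
* **Inner limit**: the smallest rank with
  $P(\mathrm{Bin}(n,p) \le r-1) \ge \gamma$ ($r = 18$ at $n = 229$). Its
  defining rank is not documented in the norming tradition's tables; this
  complement criterion is the standard reading and is flagged as inferred.
  Scores in (outer, inner] are clinically *borderline*.
* **ES1/ES2/ES3 boundaries**: the z-interval $[\Phi^{-1}(p),\, 0]$ is split
  into three equal segments; the interior cut points $z = -1.0966, -0.5483$
  map to ranks $\lceil n\,\Phi(z)\rceil$ (32 and 67 at $n = 229$). This is
  the standard operationalization of the quasi-interval ES scale; it sits
  behind its own function so an alternative rule can be swapped in.
* **ES4**: strictly above the empirical median (mean of the central pair for
  even $n$); ES0 is inclusive of the outer limit, matching the published
  interval table.

Binomial tails are computed exactly (scipy), never via the normal
approximation — cheap at these $n$ and free of platform drift. If no rank
satisfies the outer criterion the error reports the minimal usable $n$
($\lceil \log(1-\gamma)/\log(1-p) \rceil = 59$ at the defaults).
Tie handling at threshold values in the original norming is unknowable from
the published tables; this implementation compares at full precision.

## Published norms fixture

The constants that depend on the original participant-level data — the
fitted coefficients (0.0723, 1.6493), centers, the ES interval boundaries,
and the outer/inner limits — cannot be recomputed here and ship verbatim in
`src/facenorms/data/face_published.json`. Scoring against them reproduces
all 44 printed correction-grid cells to 2 decimals. Demographics outside
the printed lattice (age outside 20–85, education outside 5–17, or the
young/low-education corner where the grid has no cells) trigger a warning,
not an error, mirroring clinical practice.

The 18-item short forms convert to the 36-point scale through a pluggable
monotone table. The published equipercentile table lives in supplementary
material not reproduced here, so the default is linear doubling — monotone
and endpoint-exact, but explicitly a stand-in; supply the real table via
`ShortFormConversion` when fidelity matters.

## Synthetic cohorts

The normative generator reproduces the published stratification exactly
(4 education bands × 7 age decades × sex; 229 subjects, 137 female / 92
male). Within a band, ages and education years are drawn uniformly over the
integer band — the within-band distributions are unpublished, so uniform is
an assumption. The "≤5 years" education band is encoded as exactly 5 (the
study enrolled only participants with ≥5 years of education); open-ended
bands cap at 89 years of age and 21 years of education.

Raw scores follow `round(28.5 − 0.0723 (age − 53.275) + 1.6493 (√edu −
3.595) + ε)`, ε ~ N(0, 2.6²), clipped to [0, 36] (the latent mean lives in
roughly [23, 33], so clipping is essentially inactive). The slopes mirror
the published correction formula with signs flipped; noise SD 2.6 puts the
fitted adjusted $R^2$ near the published ≈0.31 (simulated mean ≈0.38 after
integer rounding and the band-induced age–education correlation). Sex has
no effect, matching the null published sex comparison. Rounding is
half-away-from-zero then clip, so golden tests reproduce across platforms.
One integer seed drives a single `numpy` Generator; no global state.

The clinical generator emulates a Parkinson's-type sample: n = 40, ages
N(70.4, 5.3²) rounded and floored at 60, education N(11.4, 4.0²) rounded
and floored at 0, and `round(n × 0.35) = 14` randomly chosen patients whose
latent score is shifted by −6 points before rounding (a shift large enough
to put most impaired patients below the inner limit, giving a flagged
prevalence in the high-20s percent range).

What the generator does *not* emulate: item-level responses, practice and
fatigue effects, the empirical (non-Gaussian, ceiling-skewed) raw-score
distribution, and any sex or cohort effects. Passing tests therefore
demonstrate the correctness of the *procedures* under a known generative
model, not the field validity of the published constants.

## Inferential toolkit

* **Spearman** via scipy (mid-ranks, t-approximation $p$ with $n-2$ df).
* **Partial Spearman** (one covariate): the first-order formula on
  rank-transformed data, $p$ via $t$ with $n-3$ df; verified to 1e-10
  against the residual-of-ranks formulation and against pingouin. A
  constant covariate degrades gracefully to plain Spearman.
* **Mann-Whitney U**: $U_1 = \#\{x_i > y_j\} + \tfrac12\#\{x_i = y_j\}$.
  Exact tie-aware permutation $p$ (rank-sum dynamic program over doubled
  mid-ranks, two-sided by symmetry about $n_1 n_2 / 2$) when
  $n_1 n_2 \le 400$; otherwise scipy's normal approximation with tie
  correction.
* **ICC**: two-way random effects, absolute agreement, single measures —
  ICC(2,1) from the ANOVA mean squares. The published report does not say
  which ICC variant was used; this default is configurable in the sense
  that the mean squares are the standard ones and other forms are linear in
  them. Matches pingouin's ICC(A,1) to 1e-10.
* **Paired TOST** with default bounds ±0.5 score points and α = 0.05;
  equivalent iff both one-sided $p <$ α. A zero-variance difference
  strictly inside the bounds counts as equivalent by convention (logged).
  Matches `statsmodels.stats.weightstats.ttost_paired`.
* **Bonferroni**: α/k at full precision (reported at 3 decimals:
  0.05/16 → 0.003).
* **ROC**: AUC by the rank/U identity; candidate cutoffs at midpoints
  between adjacent distinct scores, positive call = score ≤ cutoff under
  the lower-is-positive orientation; the cutoff maximizes Youden's
  $J$ (ties → higher sensitivity). How the published cutoff was chosen is
  not documented; Youden is the conventional default and the criterion is
  isolated in one function. `confusion_from_rates` reconstructs confusion
  counts from reported sensitivity/specificity and group sizes
  (half-away-from-zero rounding), which reproduces the published 79.84% and
  80% accuracies.

## Problem sizes used in tests and the acceptance script

The simulation studies run at the study's own scale: 200 synthetic
normative cohorts of n = 229 for the selection/recovery study, 2000
replicates for the outer-limit coverage study, 5000 replicates for the TOST
type-I check, 500 instances for the AUC/U identity, and 1000 replicates for
the Breusch–Pagan type-I rate. These sizes give Monte-Carlo standard errors
comfortably below the asserted tolerances.

## Known limitations

* Transform recovery is weakly identified at the default noise (see above);
  consumers should read the *selected transform* as one member of an
  equivalence class, and the adjustment itself as the stable quantity.
* The short-form conversion default (doubling) is a placeholder for the
  unavailable equipercentile table.
* No confidence intervals for AUC or ICC (point estimates only), and no
  interaction terms, splines, or more than two demographic predictors.
* The clinical generator's impairment model (a constant latent shift) is
  the simplest possible; real socio-cognitive impairment is heterogeneous.
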