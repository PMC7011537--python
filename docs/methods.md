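# Methods

This note records the statistical models implemented in `delphiscales`,
the numerical conventions, the design decisions that were genuinely
open, and what the synthetic-data generator does and does not emulate.

## Data model

A rating panel is a long table with one row per
(participant, round, goal, scale) key and an ordinal rating drawn from
that scale's ordered categories.  Missing ratings are absent rows, never
sentinels; complete-case filtering keeps exactly the participants with a
full goals × scales grid in both rounds and is idempotent.  The three
built-in scales are the three-point goal scale (*no goal* < *secondary
goal* < *main goal*), the five-point importance scale (*this does not
apply to me* < *I do not expect this* < *a little important* < *somewhat
important* < *very important*), and the numeric nine-point scale
(1 … 9).  User-defined scales carry their own category order and
three-level map (supplied in YAML); no automatic binning is attempted,
because a defensible collapse is semantic, not arithmetic.

### Harmonization

The three-level frame is NONE < SECONDARY < MAIN.  Built-in maps:
five-point {very important} → MAIN, {somewhat, a little} → SECONDARY,
{do not expect, does not apply} → NONE; nine-point {7,8,9} → MAIN,
{4,5,6} → SECONDARY, {1,2,3} → NONE.  The nine-point questionnaire
labels its bands "9, 8, 7 = important" and "6, 5, 4 = important, but not
critical", so category 7 belongs to the top band; the map is validated
to be monotone in category order, and "top category" is *defined* as the
MAIN preimage, so consensus counting and harmonization can never drift
apart.

## Consensus

The per-cell statistic is the unrounded percentage of participants whose
rating harmonizes to MAIN.  The threshold sweep (defaults 60, 70, 75,
80, 90%) counts goals with `p ≥ t` (rule `AT_LEAST`; `STRICT` uses `>`).
`AT_LEAST` is the default because consensus prescriptions are normally
phrased "at least t%"; on any grid whose percentages never equal a
threshold exactly the two rules coincide.  Comparisons always use
unrounded proportions — rounding to one decimal is display-only — so a
cell at 74.95% cannot be promoted across the 75% line by formatting.
Counts are asserted non-increasing in the threshold at construction.

## Test-retest reliability

All statistics derive from the K × K transition table of paired round-1
(rows) × round-2 (columns) ratings; unpaired ratings are dropped with a
logged count.  Percent agreement is `100·tr(O)/n`; percent changes is
its exact complement.  Weighted kappa uses *disagreement* weights
`v_ij = ((i−j)/(K−1))²`:

    kappa_w = 1 − Σ v_ij o_ij / Σ v_ij r_i c_j

with `o` the observed proportions and `r`, `c` the table's own row and
column marginals (Cohen-style chance term; the two rounds' marginals are
not averaged, matching the standard definition for paired ratings).  The
(K−1)² normalization makes coefficients comparable across K, so the raw
five- and nine-point kappas can sit in the same report as the
three-point one.  Degenerate conventions: a table with zero observed
*and* zero chance-expected weighted disagreement (all mass in one
diagonal cell) returns 1 with a log note; fewer than two pairs is an
error.

Class imbalance — the share of the modal category — is reported
alongside, because it explains the divergence between absolute and
chance-corrected agreement (the prevalence effect): as one category
absorbs most ratings, chance agreement rises and kappa falls even at
constant percent agreement.

### Confidence interval

The source study does not state how its kappa CIs were produced, and its
printed intervals are mutually inconsistent for same-size slices, so no
attempt is made to reproduce them.  The package uses a participant-level
percentile bootstrap (default B = 2000, seeded): participants, not
individual ratings, are resampled, which respects the within-participant
clustering of the pooled all-goals slice.  Degenerate resamples are
skipped with a logged count.

Known limitation: percentile intervals are slightly anti-conservative in
small samples when the rating distribution is extremely imbalanced.  In
a simulation with ~79% of mass in the top category and kappa ≈ 0.77,
attained coverage of the nominal 95% interval is ≈ 93% at n ≤ 500
participants; in balanced designs with moderate kappa it is ≈ 95% at
n = 500.  The packaged coverage test therefore runs in the latter
regime; users analysing panels as imbalanced as the motivating survey
should read the CI as approximate.

### Interpretation bands

Kappa labels (rule of thumb): < 0 poor, [0, 0.2] slight, (0.2, 0.4]
fair, (0.4, 0.6] moderate, (0.6, 0.8] substantial, > 0.8 almost perfect.
Correlation labels on |ρ|: ≤ 0.3 negligible, (0.3, 0.5] low, (0.5, 0.7]
moderate, (0.7, 0.9] high, (0.9, 1] very high.  Published band
definitions overlap at their endpoints; here upper endpoints belong to
the lower band (except 1.0) so labelling is deterministic.

## Cross-scale association

Ratings are converted to integer codes via their scale's category order
and correlated with Spearman's ρ (midranks for ties, via
`scipy.stats.spearmanr`).  ρ is invariant under *strictly* monotone
recoding, which is what makes scales of different granularity
comparable; note that collapsing categories (a non-injective recoding)
ties previously distinct ranks, so even two scales driven by an
identical latent rating have ρ < 1 — under heavy imbalance the Fréchet
upper bound can be far from 1 (≈ 0.77 for the calibrated three- vs
nine-point pair).  Constant vectors make ρ undefined (NaN), reported as
such rather than coerced.

## Sample size for kappa-CI precision

Planning model: two ratings per subject, K categories with prevalences
π, joint cell probabilities `p_ij(κ) = π_i π_j + κ π_i (δ_ij − π_j)`
(the common-correlation agreement model; admissible κ is bounded below
by −min π_i/(1−π_i)).  The expected (1−α) CI limit at sample size n is
the κ′ solving

    n · Σ_ij (p_ij(κ₀) − p_ij(κ′))² / p_ij(κ′) = χ²(1−α, 1 df)

searched separately below and above κ₀ by bracketed root finding
(tolerance 1e−9).  The minimum n is the smallest sample size whose
expected interval lies inside [κ_L, κ_U], found by geometric bracketing
plus binary search (valid because the interval width is monotone in n),
capped at 10⁶.  The divergence is Pearson chi-square with the candidate
κ′ in the denominator; the likelihood-ratio and reversed-Pearson
variants were evaluated against the reference design (κ₀ = 0.5, bounds
0.3/0.7, π = (0.7, 0.2, 0.1), α = 0.05 → n = 78) and give 77 and 71
respectively, so the Pearson form is the one shipped.  A Monte-Carlo
check (1,500 simulated designs at n = 200) confirms that the sampled
kappa estimates fall inside the analytic expected limits at the nominal
rate ± 2%.  Only the two-ratings design is implemented; more raters
raise `NotImplementedError` rather than silently extrapolating.

## Panel simulator

The generator is a Gaussian latent-trait cutpoint (probit) model, chosen
over ordered-logit because every population quantity then reduces to
bivariate-normal rectangle probabilities, which are exact and cheap —
the oracles are what make the pipeline testable.

For participant p, goal g, round r, scale s:

    s_pg    = σ_θ θ_p + √(1−σ_θ²) η_pg            stable trait, Var = 1
    u_pgr   = √ρ s_pg + √(1−ρ) ε_pgr              occasion latent
    v_pgrs  = β_g + shift_r + √(1−τ_s) u_pgr + √τ_s δ_pgrs

with all innovations standard normal and independent, one seeded
generator, no global state.  Every v is N(β_g + shift_r, 1), so the
cutpoints of all scales live on one standard-normal metric.  Implied
correlations: test-retest of scale s is ρ(1−τ_s); same-round cross-scale
is √((1−τ_s)(1−τ_s′)).  The optional round-2 mean shift models
systematically higher second-round expectations and defaults to 0.

Oracles: band probabilities for marginals, bivariate rectangle masses
for round-1 × round-2 (or scale × scale) joints, collapsed through the
harmonization map for starred quantities, goal-averaged for pooled
slices; population Spearman is the Pearson correlation of mid-CDF scores
under the joint, i.e. the large-sample limit of the midrank statistic.

### Calibrated defaults

The packaged default configuration emulates the motivating TKA survey:

* 87 participants, 19 goals; per-goal shifts β_g are the probit-
  transformed, centered round-1 three-point top percentages of the
  published grid (range −1.66 for *sex life* to +0.74 for *stability*).
* Cutpoints solved so the goal-pooled marginals match the published
  class-imbalance profile: three-point 10/11/79%, five-point top 65%,
  nine-point top 63% with 88.25% in the 7–9 band.
* ρ = 0.97 and τ = (0.065, 0.090, 0.125) solved so the pooled
  round-to-round change rates match the published 12.48 / 24.73 /
  32.26% for the three scales.
* σ_θ = 0.7: half the stable-trait variance is a participant
  disposition, giving plausible within-participant clustering for the
  bootstrap; no published value constrains it.

What the defaults do *not* reproduce: with round noise and scale noise
independent, the cross-scale correlation is bounded below by roughly the
retest correlations, so matching the observed change rates forces
population cross-scale ρ ≈ 0.75–0.81, at or above the upper end of the
survey's observed 0.65–0.74.  Real panels evidently contain
scale-idiosyncratic but retest-stable response styles (a participant who
consistently reads the nine-point anchors differently), which this model
omits.  Likewise the population kappas implied by the defaults
(≈ 0.82–0.85) exceed the survey's printed 0.47–0.78 — the published
coefficients are used only as interpretation-band examples, since the
raw ratings needed to recompute them were never deposited.  Passing
tests therefore demonstrate internal consistency of the estimators
against the generative model, not fidelity of that model to every moment
of the real data.

## Problem sizes in the test suite

Monte-Carlo tests were sized for tight tolerances at modest cost:
parameter recovery uses 2,000-participant, 10-goal panels (empirical
κ_w, agreement and top-proportion within ±0.02 / ±1 pt / ±2 pt of the
oracles); marginal and joint convergence use 2×10⁴ and 10⁵ participants;
coarsening monotonicity uses 50 random 25-participant panels; bootstrap
coverage uses 200 panels of 500 participants with B = 2000; oracle
equivalence of the weighted kappa enumerates all 3×3 tables with n ≤ 6
plus 1,000 random 5×5 and 9×9 tables against an exact-fraction
direct-formula implementation (agreement to 1e−12, with an independent
`scikit-learn` cross-check on random tables).

## Known limitations

* No estimation: the latent model is never fitted to observed panels
  (cutpoints and correlations are inputs, not outputs).
* Two occasions only; no multi-rater kappa, no ICC, no polychoric
  correlation, no significance tests for ρ.
* Consensus is top-category-proportion only; median/IQR-style Delphi
  consensus definitions are out of scope, as is any iterative feedback
  loop between rounds.
* The percentile-bootstrap CI undercovers mildly under extreme class
  imbalance (see above).
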