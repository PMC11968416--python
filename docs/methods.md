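# Methods

This note documents the models, conventions and design choices behind the
pipeline, in the order the stages run.

## Transect reduction

Raw LA-ICPMS transects are tables of (distance, Sr, Mg, Ca counts) sampled
every 5 μm (25 μm beam at 5 μm/s and 10 Hz is recorded as fixture
metadata; the reduction only uses the distance axis). The transect starts
100 μm before the otolith core, so the core sits at distance 100 μm and
the **core window is the closed interval [75, 125] μm**; the **edge window
is the final 50 μm**. Points at window boundaries are included.

Reduction order is blank subtraction → drift correction → quantification →
molar ratios. The order of the first two steps is a convention (both are
per-channel linear maps; on zero-blank fixtures they commute to < 1e-9,
asserted in tests):

* **Blank**: per-channel argon-blank means are subtracted and counts
  floored at zero.
* **Drift**: per channel, counts are divided by the relative sensitivity
  at the transect's position in the acquisition sequence, interpolated
  linearly in standard-block index between bracketing CaCO₃ standard
  blocks (constant extrapolation outside). Linear interpolation in block
  index is used because blocks bracket every 10–20 samples, making the
  index a monotone proxy for time. A multiplicative drift that is linear
  in block position is inverted exactly by this scheme.
* **Quantification**: Ca is the pseudo-internal standard with an assumed
  otolith Ca content of 38.8 wt% (aragonite convention; configurable).
  conc_e = (counts_e/counts_Ca) / R_std(e:Ca) × (cert_e/cert_Ca) ×
  assumed Ca, where R_std is the reference standard block's net count
  ratio. Points with non-positive Ca counts are flagged invalid and
  excluded from summaries rather than raising.
* **Ratios**: Sr:Ca = (Sr/87.62)/(Ca/40.078) × 10⁶ μmol:mol (Mg
  analogous with 24.305). The whole chain is invariant to rescaling all
  raw channels by any c > 0.
* **Limit of detection**: 3×SD of the gas blank divided by sensitivity;
  points below LOD are retained but flagged (faithful fixtures never
  trigger the flag).

**Vaterite QC**: a core is vateritic iff core Sr:Ca < 150 μmol:mol AND
core Mg:Ca > 1000 μmol:mol (strict inequalities, both required). Vateritic
fish are excluded from calibration and classification and their count is
reported.

## Calibration

Per family, otolith edge Sr:Ca is modelled as
y_ij = α + β x_j + u_j + ε_ij with u_j ~ N(0, τ²) a random intercept per
sampling location and ε_ij ~ N(0, σ²/w_ij). Weights: w_ij ∝ 1/n_j
(inverse of the location's sample share, normalised to mean one), so every
location contributes equally and heavily sampled locations cannot dominate
— the weighting scheme is configurable (`equal_location` | `none`). The
fit is REML: fixed effects are profiled out by GLS and the two variance
components are optimised numerically, with Woodbury-form per-location
covariance inverses. This fitter is implemented in-package because
per-location variance weights are not expressible in the standard
mixed-model APIs; the unweighted case is cross-checked against an
established REML implementation in the test suite, and the zero-τ case
against weighted least squares.

Reported per model: slope, intercept, √τ², √σ², Nakagawa marginal and
conditional R², the Wald F for the water effect with denominator df =
n_locations − 2, and `domain_water` = the observed range of per-location
mean water Sr:Ca.

Families with too narrow a sampled water range are calibrated by
**partition coefficients**: k_body = mean otolith edge Sr:Ca / mean water
Sr:Ca per capture body, summarised by (k_lo, k_hi) = (min, max) over
bodies. Previously published family relations are supplied as
configuration records (slope, intercept, water domain) and are not refit.

Calibration observations come from the `reference` source — fish of known
life-long residence (the closed-water-body collection pattern) — so the
edge-vs-water pairing is unambiguous; if no reference fish exist, all fish
are used.

## Origin windows

Water percentiles use linear interpolation between closest order
statistics (type-7, the numpy default; configurable). Windows:

* linear: [β·p5 + α, β·p95 + α];
* partition: [k_lo·p5, k_hi·p95] — lowest coefficient times lower
  percentile, highest times upper.

**Model limits** are the calibration evaluated at its water-domain
endpoints (partition: [k_lo·min water, k_hi·max water]). Windows are
intersected with the limits; a proper intersection sets `truncated`, an
empty one sets `dropped`. Truncation (rather than discarding the body) is
the implemented reading of "predict only within model bounds"; a
drop-instead switch is provided.

## Classification

Windows are closed intervals; ties at shared boundaries match both bodies,
which feeds multi-match refinement instead of arbitrary tie-breaking.
Coarse rules, in order: core below/above model limits →
unclassifiable_below/above; any match including the mainstem → potential
resident; matches excluding the mainstem → tributary; no match but below
all windows → low Sr:Ca, above all → high Sr:Ca. **Interior gaps** (inside
the limits, between windows) are not specified by the source protocol;
they are labelled relative to the mainstem window (below its lower bound →
low Sr:Ca, else high) and carry a distinct audit flag. Mainstem-only
matches are counted as potential residents with refined label "UMR" (the
category definition nominally requires a tributary as well, but chemistry
can isolate the mainstem window).

Refinement: single body → its label; tributary-only matches containing the
Wisconsin River plus one or two others → "small tributary or Wisconsin
River" (this rule precedes the next); three or more tributaries whose
confluences span multiple reaches → "TRIB"; potential residents with ≥3
tributaries → "TRIB or UMR", with 1–2 tributaries → "UMR or <names>".
Unrecognised combinations get a canonical alphabetical "or"-joined label
rather than a guessed category name. "Spanning multiple reaches" is read
from water-body metadata (`confluence_reach`, with "multiple" explicit).

## Assemblage comparisons

r×c Fisher exact test: the two-sided p sums multivariate-hypergeometric
probabilities of all margin-fixed tables with P(T) ≤ P(obs)·(1+1e-7)
(relative guard against floating-point ties). Enumeration runs when the
margin-constrained table count fits the enumeration limit (default 10⁵);
otherwise a Monte-Carlo estimator permutes column labels against row
membership — an exact sampler of the fixed-margins null — and reports
(1 + hits)/(reps + 1) with default 10⁵ reps and a required seed. The two
estimators are contract-tested against each other and the 2×2 case
against the classical closed form.

Comparison suite: predator species pairwise within each reach; each
predator species across reaches; prey families pairwise within each reach;
each prey family across reaches; collection years within each reach; and
consumed vs. independently sampled prey per taxon pairing (the pairing is
a configuration mapping; external labels are harmonised, including the
"Upper Iowa or Wisconsin" → "small tributary or Wisconsin River" relabel,
and out-of-limits records are removed with counts reported). Groups with
fewer than five individuals per reach are removed. The Bonferroni divisor
is the number of tests actually executed; skipped comparisons appear as
skip records.

## Synthetic data generator

The generator emulates the study design: one high-Sr:Ca large tributary,
several low-Sr:Ca tributaries with partially overlapping chemistry, an
intermediate mainstem sampled over three reaches and two years, plus two
closed "pond" anchor sites that host only calibration reference fish and
extend the calibration domain past every origin window (mirroring the use
of closed water bodies to characterise water-otolith relations).

* Water Sr:Ca per body is log-normal, parameterised by median and CV, so
  the percentile window has a closed form for tests.
* A fish's core/edge integrates weeks-to-months of exposure, so the
  chemistry it records is drawn uniformly from the central 80% of its
  body's water profile rather than from single grab samples; reference
  fish, resident for life, record the body mean. Fish whose experienced
  chemistry fell outside their body's 5th–95th window would be
  definitionally unassignable to it — a property of the percentile-window
  method, not of the implementation — and the generator deliberately does
  not produce them.
* Otolith noise: a per-(family, body) site intercept ~ N(0, site_sd) and
  a per-fish residual ~ N(0, residual_sd). In the reference noisy
  scenario both SDs are 10% of the family's mainstem window width
  (21/12/16/13 μmol:mol for the four families).
* Vateritic cores are drawn uniformly on Sr:Ca [50, 140] and Mg:Ca
  [1100, 3000] μmol:mol so the QC filter is unambiguous; the reference
  vaterite fraction is 4%.
* Counts are ablation-yield × concentration × sensitivity × drift plus
  the argon blank; drift is multiplicative, linear in standard-block
  index and slightly different per channel (so per-channel correction is
  actually exercised); standard blocks (3 replicates) are emitted per
  acquisition interval of 15 transects. Default measurement noise is a
  0.2% count CV and a 2% drift slope per block.
* Published-family coefficients in the scenarios (e.g. the centrarchid
  relation) are generator truths standing in for prior-study values that
  are not printed anywhere reproducible.

What passing synthetic tests do **not** show about real data: real water
chemistry is seasonally structured rather than i.i.d. log-normal; real
otolith profiles have ontogenetic drift and annuli rather than a clean
core→edge ramp; early-life movement can decouple the core from the natal
body; and real calibration sets are unbalanced in ways the weight scheme
can only partially absorb.

## Reference scenarios and problem sizes

The noise-free scenario uses 4–5% water CVs with medians spaced so all
linear-family windows are disjoint and no partition-family tributary
window touches the mainstem window (the k range [96.9, 178] forces median
ratios > 2.1); all otolith-side noise is zero, and the pipeline must
recover every latent coarse category exactly. The noisy reference
scenario keeps overlapping low-tributary chemistry; its recovery metric
compares each fish's classification with the classification of the same
fish's noise-free core through the same fitted windows, isolating
otolith noise (truth-role recovery is not attainable there by design:
partition-family windows overlap the mainstem window, which is exactly
the ambiguity the "potential resident" category encodes).

Validation problem sizes (chosen as comfortable desk-scale defaults):
round trips use 90–150 study fish per seed with five seeds pooled;
calibration recovery uses 200 replicates of a 20-location design;
exact-test oracles use 1000 random 2×2 tables and ten 3×4 tables at
3×10⁴ Monte-Carlo reps; null calibration uses 2000 two-group multinomial
draws of 25 fish per group.

## Numerical choices

REML optimisation is Nelder-Mead on (log σ², log τ²) with bounds clipped
at e^±40; the exact-fit limit (zero residuals) drives σ² to the boundary
while the GLS fixed effects remain exact. Percentile and interpolation
conventions are stated above. Fisher p-values are clipped to (0, 1] and
never report exactly zero. All randomness flows from a single root seed
split per stage (SHA-256 of "seed:stage"), giving one-number
reproducibility; fixture files are written with a fixed float format so
identical seeds give byte-identical files.

## Known limitations

* The interior-gap and mainstem-only rules are conventions where the
  source protocol is silent; both are flagged/audited in the output.
* The weighted REML fitter supports only random intercepts (no random
  slopes) — sufficient for the calibration model here.
* The F statistic uses a Wald form with denominator df = locations − 2;
  small-sample Satterthwaite corrections are not implemented, and
  recovery validation targets the slope, not F.
* Enumeration cost grows quickly with table size; large tables fall back
  to Monte Carlo automatically (the method and rep count are reported).
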