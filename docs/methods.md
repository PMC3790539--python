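# Methods

`camsecr` implements a complete sociodemographic population assessment
for individually identifiable, camera-trapped wildlife: spatially
explicit capture–recapture (SECR) density estimation, non-spatial
abundance for comparison, social-group inference from co-detections,
residency classification, approximate home ranges, and interobserver
reliability statistics. This note records the models, their
assumptions, the defaults, and the design decisions taken where the
design was genuinely open.

## The SECR model

Each individual `i` has a latent activity centre `s_i`; activity
centres form a homogeneous Poisson process of intensity `D`
(individuals/km²) over the plane. A camera at distance `d` from a
centre detects the animal following a half-normal curve

    g(d) = g0 · exp(−d² / (2σ²)),

with `g0` the detection probability (Bernoulli encounter model, one
binary outcome per detector × 30-day occasion) or the expected
encounter rate `λ0` (Poisson count model), and `σ` the spatial scale in
metres. Fractional camera effort `e_ks ∈ [0, 1]` (days filming /
occasion length) enters the Bernoulli model as an exponent,
`p = 1 − (1 − g)^e`, and the count model as a rate multiplier.

The plane is discretised into a habitat mask: a square lattice covering
the camera bounding box plus a buffer, with non-habitat cells removed.
Writing `p·(m)` for the probability that an animal centred in cell `m`
is detected at least once, the full (Poisson-process) log-likelihood of
the observed histories `ω_1 … ω_n` is

    logL = −Λ + Σ_i log( a · Σ_m Σ_c w_ic · D_c π_c · Pr(ω_i | m, θ_c) ),
    Λ    = a · Σ_m Σ_c D_c π_c · p·_c(m),

where `a` is the cell area, `c` runs over detection classes, `w_ic`
restricts known class membership (an individual of known sex
contributes only through its own sex's classes; unknown-sex individuals
sum over all), and `π_c` are latent-mixture proportions. The number of
detected individuals is Poisson by default; a binomial n-distribution
(fixed super-population `N = D·A` on the mask) is available as a
variant and changes only the n-term.

### Model ladder

| variant  | parameters | structure |
|----------|-----------|-----------|
| null     | 3  | one class: `D, g0, σ` |
| sex      | 6  | female/male classes, each with own `D, g0, σ` |
| sexhet   | 9  | sex classes + 2-class latent mixture on `(g0, σ)` |
| group    | 6  | group-living vs solitary classes |
| grouphet | 9  | group classes + the latent mixture |

The latent mixture adds one link-scale offset for `g0`, one for `log σ`
(shared across known classes) and one mixing proportion, landing on 9
parameters. With the mixing proportion fixed at 1 the mixture reduces
exactly to the corresponding non-mixture model. The `solitary`
covariate for the group variants is produced by the pipeline itself
(singleton components of the co-detection graph), not taken from truth.

Models are compared by AICc (`n` = number of individuals) with Akaike
weights `∝ exp(−ΔAICc/2)`; derived quantities are density (summed over
known classes), expected abundance `D × region area`, and the circular
95% home-range radius `r95 = σ·√(χ²₀.₉₅(2)) ≈ 2.4477 σ` with area
`π r95²`. The precision of an estimate is the full width of its 95% CI
divided by the estimate, reported as a rounded percentage.

### Estimation and numerics

Parameters live on link scales (log for densities, rates and scales,
logit for probabilities and mixing proportions). The likelihood is
maximised with L-BFGS-B inside generous box bounds; the default start
uses the naive density `n/A`, `g0 = 0.1` (or `λ0 = 0.3`) and `σ` from
RPSV. Three jittered restarts guard against local optima, and mixture
variants always additionally try a well-separated start (a low-rate
minority class), because finite mixtures are multimodal. The relative
function tolerance is 1e-11 (≈1e-8 absolute on a log-likelihood of
O(10³)). Two numerical points deserve note:

* per-individual numerators are evaluated with a log-sum-exp shift over
  the classes the individual may belong to; shifted terms that still
  underflow are floored at 1e-300 so the objective stays finite (and
  steeply unfavourable) everywhere inside the bounds — bounded
  quasi-Newton implementations must be able to evaluate the corner of
  the feasible box, and a hard `inf` there stalls them;
* `−∞` log-likelihood is reserved for the genuinely impossible case
  (no detection possible anywhere yet a nonempty history).

Standard errors come from the inverse of a central-difference Hessian
at the optimum; Wald CIs are back-transformed from the link scale, and
the density CI uses the log-normal form
`(D̂/C, D̂·C)`, `C = exp(1.96·√(ln(1 + CV²)))`.

RPSV — the root pooled spatial variance of detection locations about
individual centroids, with the combined x+y sum of squares divided by
**twice** the pooled degrees of freedom — estimates the per-axis scale
σ directly, so the default buffer is the conventional `4 × RPSV ≈ 4σ`.
The default mask spacing is `buffer/30`; the validation studies use
`buffer/8`, which changes log-likelihoods by far less than reporting
precision (the likelihood is invariant under cell refinement to <1e-6
once the buffer reaches ~6σ).

## Non-spatial comparison: the two-innate-rates model

TIRM posits a proportion `q` of "easy" individuals captured at rate
`α·λ` against `λ` for the rest, and maximises the likelihood of the
per-individual capture counts with `N − n` unobserved zero-count
animals (Poissonised multinomial; the overall rate is profiled out).
The MLE is a profile search over integer `N ∈ [n, max_N]` (default
`max_N = 20n`), with a vectorised EM across the whole grid. The default
95% CI inverts the profile likelihood-ratio test (log-likelihood drop
≤ 1.92); a seeded parametric-bootstrap percentile CI (200 reps) is
available but measurably narrower — resampling conditions on the
estimated mixture parameters, so it under-covers relative to the
profile interval (which covers the truth in 86% of the seeded
validation runs at N = 100, q = 0.3, α = 5). Degenerate inputs are flagged rather than
estimated: all-singleton counts leave `N` unidentifiable (estimate
pinned at `max_N`), and identical counts collapse to the single-rate
(equal-catchability) model. Naive density is abundance divided by the
raw sampled area (the camera-polygon MCP), the traditional non-spatial
comparison.

## Social structure and residency

Individuals recorded on the same camera within 15 minutes (inclusive)
of each other are linked; social units are the transitive closure
(connected components) of that relation. For one-male-group species,
minimum group size anchors on identified adult males: companions in
each clip are tallied by age–sex class, per-class maxima are taken over
clips, and the anchor is added — identification of the companions is
not required.

Residency splits the data into biweekly periods (26 by default) and
scores each individual by the mean waiting time in biweeks between
successive presence periods: ≤5 resident, ≥15 nonresident, in between
intermediate; individuals with fewer than two presence periods are
unclassifiable rather than forced into a class.

## Home ranges and sex effects

The approximate home range (AHR) of an individual or group is the
minimum convex polygon around the cameras where it was detected
(computed with shapely; note camera locations, not movement paths).
Sex effects on log AHR are tested with the number of observations
(log-transformed, then z-scored with the sample n−1 standard deviation)
and its interaction with sex as covariates: an OLS model with a
full-vs-null F-test (df 2, n−4) for a single community, and a
random-intercept (group identity) mixed model fitted by ML with a
full-vs-null likelihood-ratio test on χ²(2) for group-living species.
The mixed-model fit falls back across optimisers and, at the
zero-variance boundary, to the OLS limit, with the boundary flagged.

## Interobserver reliability

Agreement between a participant's same/different judgments and the
expert gold standard is summarised by Cohen's κ = (p_o − p_e)/(1 − p_e)
with chance agreement from the marginals. Participant categories are
compared with exact Wilcoxon signed-ranks tests: zero differences are
dropped (reported as ties), tied magnitudes get mid-ranks, and for
n ≤ 25 the two-sided p doubles the smaller exact tail of the
signed-rank distribution, computed by the generating-polynomial
convolution that is numerically identical to enumerating all 2ⁿ sign
assignments (doubled mid-ranks keep everything in integers). Species
differences use the tie-corrected Friedman test referred to χ²(k−1).

## The synthetic study generator

No real dataset of this kind is public, so validation runs on a
generator that mirrors the field design: a systematic grid of 1-km²
cells with one camera per cell at a seeded within-cell offset, 20
occasions of 30 days, camera outage blocks written to an activity log,
per-visit identification failure emitted as anonymous (`UNID`) rows,
and three social systems — fission–fusion communities (members' centres
scattered around a community centre), stable one-male groups (members
share one centre; solitary males range independently), and female core
groups with solitary males plus a resident/transient split.

Choices that matter, and why:

* **Species presets.** Densities (1.72/1.2/1.37 weaned ind./km²), sex
  ratios (1:2.1, 1:3.2, 1:2), identification rates (42/22/43%), camera
  counts (45/45/24) and the occasion structure follow the original
  field study; σ values are set so circular-r95 home ranges land in the
  reported 40–60 km² range, and detection intercepts were calibrated
  once so simulated sample sizes (identified individuals, visit totals)
  land near the reported ones (~130 identified chimpanzees from ~900
  visits, ~70 gorillas, ~120 elephants from ~1700 visits).
* **Territorial unit placement.** Social-unit centres sit on a jittered
  lattice rather than a Poisson scatter: territorial mosaics are how
  chimpanzee communities and gorilla group ranges actually tile a
  landscape, and a Poisson scatter of 30-animal communities adds
  cluster-level density variance that no closed-population estimator
  could be expected to absorb.
* **Population region.** Individuals are simulated over the camera
  bounding box plus 6σ, comfortably beyond any buffer a fit will use;
  with a smaller world the likelihood integrates over empty area and
  density is diluted by several percent.
* **Co-travel.** A detected animal's group-mates co-trigger the same
  camera within U(0, 15) minutes with probability
  `co_trigger_prob × exp(−d_mate²/(2σ_mate²))` — the mate joins only
  where its own range makes that plausible. Ungated co-triggering
  records mates at arbitrary distances from their centres, flattens the
  observed distance decay and biased fitted density by ~25% in pilot
  runs; the gate keeps the marginal detection process approximately
  half-normal while still producing the co-detection edges that group
  inference needs.
* **Transients.** Nonresident elephants are present in each biweek
  independently, with an individual presence probability drawn from
  U(0.05, 0.3). Random temporary emigration leaves the super-population
  density estimable and produces the long between-capture waiting times
  that define nonresidents; a single contiguous presence window does
  neither (it violates closure non-randomly, and while present the
  animal looks resident).
* **Dependent juveniles** travel with their group and appear only via
  co-triggering; they exercise the weaned-only filter and the anchored
  composition tallies without entering density truth.

What the generator does **not** emulate: movement autocorrelation
(animals are detected independently across cameras and occasions given
their centre), behavioural responses to cameras, diurnal activity
patterns, landscape covariates on density, and identification errors
other than failure (no false matches). Passing validation therefore
shows the estimators are correct under their own assumptions plus
moderate, realistically structured violations (social clustering,
co-travel, intermittent presence) — not that they are robust to every
pathology of real camera-trap data.

## Validation configuration

End-to-end density recovery fits the variant matching each preset's
generating structure — `sex` for the chimpanzee-like preset, `group`
for the gorilla-like one, and `sexhet` for the elephant-like one, where
the resident/transient split is persistent individual rate
heterogeneity, exactly the finite-mixture case (and the best-supported
model for elephants in the original study). Problem sizes used by the
test suite and the acceptance script: buffer `4×RPSV` from the data,
mask spacing buffer/8 (a few hundred to ~1500 cells), 50 replicates per
preset in the suite and 20 in the acceptance script. The coverage
target is realistic rather than nominal (≥85% at a 95% level):
residual co-travel heterogeneity and the strict closure assumption cost
a few points, the same frictions the original study discusses.

## Known limitations

* Independence of activity centres is assumed by the likelihood but
  deliberately violated by the generator's social structure; for
  strongly clustered populations the point estimate can carry a
  double-digit relative error that only the (appropriately wide)
  interval absorbs — the stable-group preset shows this pattern.
* The anchored composition method reports *minimum* group sizes.
* MCP home ranges from camera locations undershoot true ranges at low
  detection counts; degenerate hulls (<3 distinct non-collinear
  cameras) are flagged, not filtered.
* The TIRM profile CI is asymptotic in the LRT sense; at very small n
  it should be read qualitatively.
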