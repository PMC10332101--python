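# Methods

## Scope and model

`vnokit` implements the quantitative pipeline for *en face* Ca²⁺ imaging of
vomeronasal sensory neuron (VSN) dendritic knobs, together with the
behavioral preference statistic and the activity-count (pS6 / c-Fos)
statistics used around it. The imaging unit is one knob; the analyzed
object is its ratio trace F_x/F_0, where F_0 is the mean raw fluorescence
over the baseline window (the first 50 frames at 1.5 s/frame by default).
Stimuli are applied for 30 s, at least twice each, with ≥ 4 min between
onsets.

A knob *responds* to one stimulus application when the ratio trace shows a
stimulus-dependent deviation above `mean_b + k·sd_b`, with `mean_b` and
`sd_b` the mean and sample SD over the baseline window and `k = 2`, and the
deviation starts no later than 60 s after application onset. A knob is a
*responder* to a stimulus only if it responds on every application of that
stimulus (the repeatability criterion). Responders to two paired stimuli
partition into four selectivity classes (A-only, B-only, both, none); class
sizes are reported as densities — percent of the *estimated total knob
number*, i.e. a mean knob density times the recorded area — and as Venn
shares of all responsive knobs.

## The sustained-deviation rule

"Deviation above threshold" cannot mean a single super-threshold frame in
an automated pipeline: on independent Gaussian frame noise, the probability
that *some* frame in a 41-frame search window exceeds a 2-SD threshold is
≈ 0.6, i.e. a ≈ 41 % null responder rate even with the repeatability
criterion — manual analysis avoids this implicitly because a human scorer
does not call an isolated one-frame spike a response. `detect_response`
therefore requires the trace to stay above threshold for
`min_frames_above` consecutive frames, default 3 (4.5 s — short relative
to the tens-of-seconds Ca²⁺ transients being detected). A direct
Monte-Carlo of the rule on pure noise gives null responder rates of ≈ 0.41
(1 frame), 2.7×10⁻³ (2 frames) and ≈ 1×10⁻⁵ (3 frames); three frames makes
the false-positive contribution negligible against the smallest class of
interest (0.1 % of knobs) while leaving planted transients at ≥ 5× noise SD
detected essentially always. Setting `min_frames_above=1` recovers the bare
first-crossing rule.

Two further readings were fixed where the verbal criteria are ambiguous:

* the baseline SD is computed on the **normalized** trace over the single
  global baseline window (a standard error would make the threshold depend
  on window length; a per-application pre-window is available as an
  option);
* "within 1 min of application" anchors to application **onset** (the only
  unambiguous time point; the 30-s application lies inside the window), and
  constrains the **start** of the deviation — its confirmation frames may
  extend past the 60-s mark. A crossing at exactly 60 s counts.

Frames are 0-based, windows half-open `[start, end)` except the inclusive
latency bound. Bleaching is not corrected by default; a linear detrend
exists for stress tests. Monotonicity holds by construction: raising the
threshold multiplier or adding applications never adds responders.

## Density normalization and summaries

Knob density is estimated from counts in 40 × 40 µm sampling squares
(count/16 per 100 µm²; mean ± SEM across squares, SEM undefined for one
square). The pooled constant 8.32 knobs/100 µm² — the unweighted mean of
the two genotype means 8.42 and 8.21 — is the default normalizer;
per-site or per-group densities are options. Total knobs =
round(density × area / 100), so a 40,000 µm² site carries ≈ 3,328 knobs.

Group summaries report class densities as mean ± SEM across recording
sites, and Venn shares both from pooled responder counts and from mean site
densities: the two conventions differ (e.g. 72 % vs 73 % for the dominant
class) and the JSON report labels each. Headline shares and folds are
rounded half away from zero at printed precision; the rounding goes through
the shortest decimal repr because binary floats under-round exact halves
(8.315 must print 8.32). Fold change is reference/comparison, flagged
infinite when the comparison is 0; a share over an all-zero class vector is
a data error.

## Knob detection

The paper's pipeline counts knobs manually; `detect_knobs` replaces this
with multiscale Laplacian-of-Gaussian blob detection (scikit-image) plus
greedy non-maximum suppression at a 2 µm minimum spacing (knobs are
physical structures ≈ 1–2 µm across and cannot overlap). Its only pipeline
role is density estimation, so it is validated against the generator's
ground truth (recall and precision ≥ 0.95 at a 1 µm match radius on fields
at study density), not against any published number.

## Behavior

Investigation bouts (subject, side label, start, stop) are summed per side;
the preference score is log₂ IT_A − log₂ IT_B (the log-difference form
makes antisymmetry under label swap exact in floating point). The group
statistic is the **mean of per-animal scores** — not the score of the
group-mean times, which differs in general — with a two-sided one-sample
t-test against zero. Zero investigation times are a hard error by default;
an epsilon policy (add 0.5 s to both sides, flagged in the output) is
available. A converter from point start/stop event rows to bouts is
included for ethogram-tool exports.

## Counts

pS6 is quantified as percent of DAPI nuclei, c-Fos as positive cells per
µm². Per-subject values are unweighted means over that subject's
regions/sections (area-weighted means are an option). Percent reduction is
100·(control − test)/control at printed precision.

## Statistics policy

Two-group comparisons gate on normality: Shapiro-Wilk at α = 0.05 on each
group; both pass → unpaired two-sided t-test, otherwise two-sided
Mann-Whitney U (exact for small tie-free samples, tie-corrected normal
approximation otherwise). A constant sample fails the gate by definition.
Three or more groups: Kruskal-Wallis omnibus, then pairwise Mann-Whitney
with Holm-Šídák step-down adjustment (statsmodels), which is monotone in
the raw p-values and bounded by 1. All tests are two-sided at α = 0.05.
Under a Normal null at n = 10 the gate's empirical type-I error sits within
0.05 ± 0.01 (the Mann-Whitney branch is slightly conservative at small n).

## Synthetic data

The generator emulates the structure of the recordings, not their optics:

* **Knob fields.** Jittered hexagonal lattice whose pitch matches the
  target density (default 8.32/100 µm²) with jitter bounded so spacing
  stays ≥ 2 µm. A lattice rather than a Poisson process because knobs
  cannot overlap; counts are deterministic up to edge effects.
* **Traces.** Raw trace = F0_true·(1 − bleach·t) + iid Gaussian noise of SD
  `noise_sd`·F0_true (default 0.02, zero bleach). Classes are drawn
  multinomially from the configured fractions (defaults: both 1.6 %,
  A-only 0.5 %, B-only 0.1 % — the selectivity pattern of the urine
  recordings); on each application of its stimulus a responder fires with
  probability `respond_prob` (default 1, so planted responders satisfy the
  repeatability criterion by construction; lowering it stresses that
  criterion). A firing adds a unit-peak double-exponential transient
  (τ_rise 3 s, τ_decay 15 s — typical somatic kinetics for a Rhod-2-class
  indicator; the source recordings show but do not parameterize transients)
  with amplitude uniform in `amp_range` (default 5–8× the noise SD) on the
  dF/F0 scale and onset latency uniform in 1.5–9 s. The kernel is truncated
  below 10⁻⁴ of peak so a transient cannot bleed an infinitesimal tail into
  the next stimulus window (which would otherwise defeat the noiseless
  limit, where sd_b = 0 makes the threshold exact).
* **Stacks.** Each knob a Gaussian spot (σ 0.6 µm default) scaled by its
  trace value, for exercising the detector.
* **Behavior.** Per mouse and side, Poisson bout counts (rate 12) and
  Gamma durations (shape 2, mean 2.5 s; side A scaled by 2^planted_mu), so
  expected totals ≈ 30 s and ≈ 52 s at the planted effect 0.81 — matching
  the scale of the observed investigation times — and the expected log₂
  ratio equals the planted value (the log-of-sums bias cancels between
  sides). Bouts are placed without overlap using Dirichlet gaps; a
  Poisson-zero side (probability ≈ 6×10⁻⁶) is redrawn to keep times
  positive under the strict zero policy.
* **Counts.** DAPI ~ Poisson(rate·area), positives ~ Binomial(DAPI, p) with
  p defaulting to the observed 2.19 % / 0.98 %.

All randomness flows from one seed; outputs are bit-reproducible for a
fixed seed and library version.

What the generator does **not** emulate: temporally correlated noise, focal
drift and motion, bleaching nonlinearity, overlapping ROIs, scorer
ambiguity in bout boundaries, and spatial heterogeneity of cell density.
Passing tests therefore demonstrate that the pipeline implements its
criteria correctly and recovers planted structure under the stated noise
model — not that the criteria are optimal for any particular real
recording.

## Validation design and problem sizes

The null calibration compares the full pipeline (generator → normalization
→ detection → repeatability) on ~10⁵ pure-noise knobs against an
independent vectorized Monte-Carlo of the same rule (2×10⁵ replicates;
the threshold's scale invariance lets the oracle work on unit-normal
frames), requiring agreement within 3 binomial SE and strict subsetting of
repeatable responders within single-application responders. Parameter
recovery plants the default class fractions in a ~20,000-knob field —
matching the ~20,239-knob scale of the imaging data — and requires each
recovered fraction within 3 binomial SE of truth with ≤ 2 % class
confusion. The behavioral power check runs 500 cohorts of 11 mice at a
planted effect of 0.8 and requires the one-sample-test rejection rate to
fall in a band pre-registered from a closed-form noncentral-t oracle
(delta-method score SD √(2(k+1)/(kλ))/ln 2 ≈ 0.72, giving power ≈ 0.88,
± 0.07 model slack). These sizes keep the default suite under a minute
while leaving Monte-Carlo error well inside the asserted bounds.

## Known limitations

* The detector is 2-D and single-frame; no tracking across frames, no
  registration (inputs are assumed aligned).
* The repeatability criterion generalizes "both applications" to *all*
  applications when a stimulus is delivered more than twice; other
  readings (e.g. ≥ 2 of n) are not implemented.
* The exact normality test behind the published gate is unnamed;
  Shapiro-Wilk is this package's choice, and borderline samples may route
  differently than in the original analysis.
* Venn shares from pooled counts cannot be reproduced exactly from printed
  class-density means (the underlying per-class counts are unpublished);
  both conventions are emitted and labelled instead.
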