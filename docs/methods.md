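# Methods

## Setting and data model

The package analyzes reader studies in which n raters annotate the same N
cases with labels from a hierarchical diagnostic scheme, in one or two
blinded rounds. All statistics operate on *case-level presence*: however
many bounding boxes a rater drew, on whichever projections, a (case, rater,
category, round) cell is a single binary indicator. Absence of a record is a
negative, not missing data; the case/rater universe should therefore be
declared explicitly so silent raters contribute zeros. Bounding boxes are
retained in the record model but ignored by every statistic — spatial
agreement is a different analysis and out of scope here.

Reportable categories are derived from the scheme with union semantics:

- each raw label;
- for each non-leaf label, a congregate "`<label> incl. sub-categories`"
  whose member set is the label plus its transitive descendants;
- each declared composite (e.g. costophrenic angle blunting merged with
  pleural effusion). The merged ("AND") category is a union, not an
  intersection: it is positive when any member is. This is the reading
  consistent with its positive agreement exceeding either member's, which
  merging produces and intersecting cannot.

On the packaged 20-label lung-tissue scheme this yields 25 categories in a
fixed pre-order: a congregate row immediately precedes its label; a
composite follows the last of its members. `Normal` is an ordinary raw
label (raters mark it explicitly); it is never inferred from the absence of
findings when ingesting real data, and the simulator emits it exactly when
a simulated rater reports nothing else.

## Agreement battery

Per category, with s_i positive and d_i = n − s_i negative ratings on case i:

- **Observed agreement** P̄o = (1/N) Σ_i [s_i(s_i−1) + d_i(d_i−1)]/(n(n−1)),
  the mean fraction of concordant rater pairs; verified in the tests against
  a brute-force enumeration of all n(n−1)/2 pairs.
- **Free-marginal multi-rater kappa** κ_free = (P̄o − 1/q)/(1 − 1/q). Each
  label is analyzed as its own binary (q = 2) variable, matching a design
  where raters may attach any number of labels to a case, so label
  prevalences are free rather than fixed. The q-general count form is also
  implemented. Free-marginal correction is deliberate: fixed-marginal
  (Fleiss-type) kappa is not provided.
- **PABAK** = 2·Po − 1 for two raters, including a rater against their own
  second round (intra-rater agreement).
- **Specific agreement**: two-rater PPA = 2a/(2a+b+c), PNA = 2d/(2d+b+c);
  multi-rater PPA = Σ s_i(s_i−1)/Σ s_i(n−1), PNA = Σ d_i(d_i−1)/Σ d_i(n−1).
  At n = 2 the multi-rater forms reduce exactly to the two-rater ones
  (asserted in the tests).

Kappa-family values carry the Landis–Koch verbal band (<0 poor, ≤0.20
slight, ≤0.40 fair, ≤0.60 moderate, ≤0.80 substantial, ≤1 almost perfect;
exactly 0 falls in "slight" so the partition is closed).

### Numerical choices

- **Undefined statistics.** A zero denominator (e.g. PPA when no rater ever
  used a label) yields NaN, rendered as a blank table cell — never 0. A PPA
  of 0 is meaningful (positives exist but are never shared) and distinct
  from undefined.
- **Confidence intervals.** Nonparametric case-resampling percentile
  bootstrap, default B = 2000, explicit seed, 2.5/97.5 percentiles. The CI
  method used for the published reference table is not stated, so bootstrap
  intervals are reported but never compared against printed intervals.
  NaN replicates (a resample can lose all positives) are dropped; the
  reported interval is widened if needed to bracket the point estimate.
- **Rounding.** Report tables round half-up to 2 decimals, the convention
  of the reference tables (banker's rounding would differ on exact halves).
- **Determinism.** Same inputs and seeds produce byte-identical output
  tables; all randomness flows through explicitly seeded numpy generators.

## Marginal reconstruction

For a label with reported PPA = 0, no case was positively labeled by ≥2
raters. Under that *zero co-positivity* constraint the per-rater positive
counts force the annotation configuration up to a permutation of cases, and
every statistic here is permutation-invariant — so κ_free and PNA are exactly
recomputable from a frequency table alone. The reconstruction assigns
positives deterministically to the lowest-index free cases (feasible iff
Σ counts ≤ N); the determinism is purely for reproducibility and provably
cannot affect any statistic. Labels with PPA > 0 are not reconstructed:
marginals plus PPA underdetermine the configuration, and no attempt is made
to invert it.

Four rows of the packaged reference agreement table are forced this way
(Tuberculosis, Abscess, Chronic Lung Changes, Increased Translucency); the
acceptance script and regression tests recompute them from the packaged
counts at 2-decimal parity.

## Synthetic rater model

The generator emulates a six-reader, 100-case, two-round study. A latent
truth assigns each case a set of true leaf findings via independent
per-finding prevalences; `Normal` is true iff the set is empty. Each rater
has five dials:

| parameter | meaning | default range (by experience) |
|---|---|---|
| sensitivity | P(detect a true finding) | 0.65–0.85, rising with experience |
| specificity | per-finding true-negative probability | 0.995–0.997 |
| granularity | P(report a detected finding at leaf level) | 0.30 (novice) to 0.95 (experienced) |
| over_annotation_rate | Poisson mean of spurious labels per case | peaks at intermediate level (0.8–1.0) |
| rescore_flip | P(a used/not-used decision flips in round 2) | 0.04–0.06 |

Non-leaf reporting substitutes an ancestor chosen uniformly along the path
to the subtree root — this reproduces, structurally, the documented
behavior of less experienced readers labeling an infection as an infiltrate
or as decreased translucency. Spurious labels are drawn over all annotatable
labels with prevalence-smoothed weights (additive smoothing 0.005; parents
weighted by their subtree's mean leaf prevalence), since no distribution for
over-annotation is documented. Round 2 applies independent symmetric flips
to every non-Normal label decision, giving the closed form
E[PABAK] = 1 − 2p used in the tests. Prevalences default to values placing
expected per-rater counts in the reference frequency table's order of
magnitude (pleural effusion in the tens, tuberculosis ≤ 2 per 100 cases).

The per-level sensitivity/specificity/granularity values are illustrative:
they are not estimable from published summary tables, and are chosen once
to produce a plausible study, not tuned to reproduce any reported
agreement value. The generator omits several features of real reader data —
correlated errors between raters viewing the same image, case-difficulty
heterogeneity, memory effects across rounds surviving the wash-out,
projection-specific visibility, and any spatial structure (bounding boxes
are dummies). Passing tests therefore validate the pipeline's statistical
machinery and behavioral directionality (granularity contrasts,
flip monotonicity), not fidelity to any particular reader population.

## Problem sizes

The test suite exercises the closed forms against brute-force oracles at
n ≤ 6, N ≤ 50 over hundreds of random instances; null calibration of
κ_free uses 200 replicates of 6×200 uniform raters; simulator parameter
recovery uses one rater at N = 5000 (≈3 SE tolerance); bootstrap coverage
uses 120 simulations with B = 300. End-to-end CLI checks run 30–100 cases
with B ≤ 500. These sizes keep the whole suite in seconds while leaving
Monte-Carlo tolerances comfortably non-degenerate.

## Known limitations

- The two packaged schemes cover lung-tissue findings only; the revised
  (descriptive-label) scheme fixture is a clearly marked synthetic
  stand-in, as the published revision is figure-only.
- Intra-rater summaries are produced both per rater and pooled (mean over
  raters); published per-reader figures are not asserted against, since
  their pooling convention is not recoverable.
- No significance tests against κ = 0, no Cohen/Fleiss/weighted kappa, no
  sample-size machinery: scope is deliberately the free-marginal battery.
- Whether `Atelectasis` should split into linear/segmental variants is left
  to the scheme author; the packaged scheme keeps it as a single leaf, as
  the reference frequency table does.
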