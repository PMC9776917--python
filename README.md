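# cxragree

Inter- and intra-rater agreement analysis for **hierarchical multi-label
image annotation**, built around the setting of reader studies on chest
X-rays: several radiologists annotate the same cases with labels drawn from
a hierarchical diagnostic scheme (a broad finding like *Decreased
Translucency* subdivides into *Infiltrate*, which subdivides into
*Infection*, *Abscess*, *Tuberculosis*), in one or two blinded rounds.

The package is for anyone who needs to quantify how consistently a labeling
scheme is used — typically as quality control before the annotations feed a
machine-learning model — and ships:

- **ontology**: label-scheme loading/validation and derivation of the
  reportable categories — each raw label, each non-leaf label's
  "incl. sub-categories" congregate (label ∪ descendants, union semantics),
  and declared composites;
- **annotation store**: collapse of per-projection, per-bounding-box records
  to case-level binary matrices (a label either *was or was not used* on a
  case by a rater in a round);
- **agreement statistics**: observed agreement, Randolph's free-marginal
  multi-rater kappa, PABAK, two- and multi-rater specific agreement
  (PPA/PNA), case-resampling bootstrap CIs, Landis–Koch bands;
- **marginal reconstruction**: exact rebuilding of single-label matrices
  from per-rater positive counts under zero co-positivity;
- **synthetic raters**: a behavioral simulator (sensitivity, specificity,
  label granularity, over-annotation, test–retest flips) generating
  full two-round studies;
- a **CLI** (`cxragree`) orchestrating the study-level tables.

## The statistics

For one category, the data are an N×n binary matrix (N cases, n raters).
With s_i positive and d_i = n − s_i negative ratings on case i:

- observed agreement  P̄o = (1/N) Σᵢ [sᵢ(sᵢ−1) + dᵢ(dᵢ−1)] / (n(n−1)) —
  the mean fraction of concordant rater pairs per case;
- **Randolph's free-marginal kappa**  κ_free = (P̄o − 1/q)/(1 − 1/q) with
  q = 2 categories (used / not used). Free-marginal chance correction is the
  appropriate choice when raters are not constrained to fixed label
  prevalences;
- **PABAK** (two raters) = 2·Po − 1, with Po the raw proportion of
  concordant cases; also used rater-against-self across rounds
  (intra-rater agreement);
- **specific agreement**: PPA = 2a/(2a+b+c), PNA = 2d/(2d+b+c) for two
  raters, and the multi-rater forms
  PPA = Σ sᵢ(sᵢ−1) / Σ sᵢ(n−1), PNA = Σ dᵢ(dᵢ−1) / Σ dᵢ(n−1).
  Zero-denominator cases are reported as *undefined* (blank), never as 0.

A useful identity: for n = 2 and q = 2, κ_free ≡ PABAK exactly.

## Worked example

A label used once by one of six raters over 100 cases (per-rater counts
0,0,1,0,0,0, and no case labeled by two raters) has its agreement fully
determined by those marginals:

```text
$ cxragree reconstruct --label Tuberculosis --counts 0,0,1,0,0,0
Tuberculosis: n_raters=6 N=100
  free-marginal kappa = 0.99 (almost perfect)
  PPA = 0.00
  PNA = 1.00
```

Reading: 99 cases have all six raters concordant-negative and one case has
a 5-vs-1 split, so P̄o = (99 + 20/30)/100 ≈ 0.9967 and
κ_free = 2·P̄o − 1 = 0.99. The single positive is shared by no one
(PPA = 0) while negative use is essentially unanimous (PNA = 1.00).

A full synthetic study — six raters, two per experience level, 100 cases,
two rounds — and its all-reader agreement table:

```text
$ cxragree scheme validate
scheme 'fig1_lung': 20 labels, 25 reportable categories (4 congregate, 1 composite)
$ cxragree simulate --n-cases 100 --seed 7 --out ann.csv --universe-out universe.yaml
wrote 4784 records to ann.csv
$ cxragree analyze all --annotations ann.csv --universe universe.yaml \
    --seed 7 --bootstrap-reps 500 --out out
$ head -5 out/all_readers.csv
category,kappa,ci_low,ci_high,ppa,pna,interpretation
Normal,0.54,0.44,0.63,0.47,0.85,moderate
Increased Translucency incl. sub-categories,0.64,0.57,0.73,0.53,0.89,substantial
Increased Translucency,0.83,0.76,0.89,0.15,0.95,almost perfect
Pneumothorax,0.76,0.68,0.84,0.36,0.93,substantial
```

Each row is one reportable category: chance-corrected all-reader agreement
(κ_free with a 95% bootstrap CI), the shared-positive and shared-negative
proportions, and the Landis–Koch verbal band. `cxragree analyze pairs`
and `cxragree analyze intra` produce the two-reader (same experience
level) and round-1-vs-round-2 tables in the same style.

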