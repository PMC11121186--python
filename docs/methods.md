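# Methods

## The model

`dreamocracy` scores drug-repurposing candidates by aggregating two kinds of
prior evidence for a disease: drug lists published by computational drug
repurposing studies (CDRS) and drug lists extracted from clinical trial
registry exports (CTS). It is a voting scheme over *annotations*, not over
drugs: each drug in a study list contributes its mechanisms of action
(MoAs), its initial indications (Inds) and its targeted pathways (Paths),
and the votes accumulate per feature.

For a disease *d*, a collection method *c* and a modality, every feature
*i* observed across the study lists gets

    DC_i = W_F · NormFreq_i + W_LC · NormListCount_i

* `Freq_i` — distinct drugs in the union of lists annotated with *i*. A
  drug repeated across lists counts once; the repetition is already what
  `ListCount` measures, and counting it twice would double-weight the same
  information.
* `ListCount_i` — number of study lists containing at least one drug
  annotated with *i*.
* Both are divided by their maximum over the modality's unfiltered table,
  so every observed feature keeps a nonzero score and a feature maximal in
  both metrics scores exactly 1. Divide-by-max (not min–max) is deliberate:
  min–max would zero out the weakest observed feature, which is still
  evidence.
* Defaults `W_F = 0.4`, `W_LC = 0.6`: a signature recurring across
  independent studies is worth more than a high within-study frequency.
  Weights are user options; non-normalised weights are rescaled to sum 1
  with a warning, negative weights are rejected.

**Enrichment filter.** Sampling *n* collection drugs from a library of *M*
drugs of which *K* carry feature *i*, the number of carriers is
hypergeometric. Features with upper-tail probability P(X ≥ k) ≥ 0.05 are
flagged as not kept (the cutoff is strict: p = 0.05 exactly is excluded).
The tail is computed with exact integer arithmetic (a sum of
binomial-coefficient products), so the only numerical error is one float
rounding; dropped features remain in the table with `kept = False` for
audit. The choice of the annotation library as the background population is
a design decision — it is the only sampling frame the method carries — and
normalisation maxima are taken before filtering, since scores exist before
the filter runs.

**Drug scoring.** A drug's per-modality score is the **maximum** DC score
over its kept features in that modality (configurable to the mean). Max is
a deliberate choice where the aggregation rule was genuinely open: it
rewards one strong match and is insensitive to annotation cardinality — a
drug with forty pathways is not diluted relative to a drug with two. This
choice changes every real score and is therefore surfaced as an explicit
`aggregator` parameter everywhere. A drug with no kept features in a
modality scores 0 there rather than being dropped, so the composite is
defined for every library drug:

    Composite = W1·ScoreOfPaths + W2·ScoreOfMoAs + W3·ScoreOfInds
    Total Composite = (1/N) Σ Composite_method

Defaults `W1 = W2 = 0.4`, `W3 = 0.2` (pathways and mechanisms describe the
drug's action; the initial indication only its first use). N adapts to the
methods present for a disease; rows record `n_methods` so a single-method
total is visible as such.

## Ingestion rules

* Drug names are matched after canonicalisation: lowercase, trimmed,
  internal whitespace collapsed, unicode en/em dashes folded to the ASCII
  hyphen. An optional alias table supplements this; there is no fuzzy
  matching, since a silent membership change is worse than an unmatched
  report. Unmatched drugs are removed and reported — scoring requires
  annotations.
* Trial exports keep statuses Completed / Recruiting / Actively Recruiting /
  Not yet recruiting / Active (,) not recruiting (case- and
  comma-insensitive); Suspended, Withdrawn and Terminated are dropped. Only
  `Drug:` interventions are used. Each drug is kept once at its highest
  phase (Early Phase 1 < Phase 1 < Phase 1/2 < Phase 2 < Phase 2/3 <
  Phase 3 < Phase 4, NA and unknown lowest; ties keep the first trial in
  export order).
* The retained trial is the CTS study unit: study lists group the deduped
  drugs by the trial that carried them. The grouping rule is ours (the
  unit of "an initial study" for CTS is not otherwise pinned down), and it
  follows from the dedupe rule, which assigns each drug to exactly one
  trial.
* Combination interventions ("Drug: A + B") are kept as one name and show
  up in the unmatched report if the library does not know them.
* Fewer than three lists for a disease triggers a reliability warning, not
  an error: the scores remain well defined, they just rest on little
  evidence.

## Synthetic data

The generator emulates all four inputs (hub-dialect annotation TSV, GMT
gene sets, CDRS list files, registry-style trial CSVs) with a known ground
truth. Drugs receive uniformly sampled MoAs, indications and targets;
pathways are derived by the same target-membership rule as real data.
Planted signal works through sampling weights: carriers of a disease's
planted features are drawn into its study lists with weight *m* ≥ 1
(*m* = 1 is the null). Acting on drug sampling — rather than injecting
features post hoc — makes `Freq` and `ListCount` respond jointly, which is
exactly the coupling the DC score assumes. Synthetic trial CSVs include
deliberately discardable `Terminated` decoys and a lower-phase duplicate
trial so the ingestion rules are exercised end to end.

Default conditions (chosen once as the reference simulation): 300 drugs,
30 MoAs, 25 indications, 20 pathways over 200 genes, 2 MoAs / 2 indications
/ 3 targets per drug, 6 lists of 40 drugs, 5 planted MoAs, m = 10. Under
these conditions the top-5 DC-ranked MoAs recover ≥ 80 % of the planted set
in well over 90 % of seeds, and under m = 1 the planted ranks are uniform
(checked with a Kolmogorov–Smirnov test on a randomised integral transform
of the discrete ranks; the mild negative dependence between the five ranks
within one seed makes that test conservative).

What the generator does **not** emulate: real MoA/pathway co-occurrence
structure, correlated annotations, real name variation beyond dash/case
noise, or list-size heterogeneity. Passing recovery tests therefore shows
the machinery is sound and sensitive under clean planted signal — not that
real evidence piles are this well behaved.

## Statistics

* Hypergeometric tails (enrichment filter and signature-overlap tests) are
  exact integer computations; tests cross-check them against brute-force
  enumeration of all draws and against an independent summed-PMF oracle.
* Signature overlap between CDRS and CTS uses the library's modality
  universe as the background and compares kept (post-filter) features only.
* Paired group comparisons use the Wilcoxon signed-rank test. Zero
  differences are dropped; for n ≤ 25 the two-sided p comes from the exact
  conditional distribution over all 2^n sign assignments (computed by
  dynamic programming, midranks for tied magnitudes, p = min(1, 2·min
  tail)); above that, the normal approximation with continuity correction.
  The exact branch is implemented in-package because the conditional
  sign-flip definition with ties must match the enumeration definition of
  the test. Independent groups use the rank-sum test, exact for
  min(n) ≤ 10 without ties, asymptotic with continuity correction
  otherwise.
* Frequency concordance between methods is an ordinary least-squares fit of
  one method's normalised frequencies on the other's over common features
  (≥ 3 required, constant predictors rejected).

## Numerical and determinism choices

* All ranked outputs break ties deterministically: DC score descending,
  then feature label ascending; rankings by score then drug name. Top-k
  selections resolve boundary ties by name so exactly k rows are taken.
* All simulation randomness flows through one seeded numpy `Generator`
  threaded explicitly; identical seeds give byte-identical fixture files
  and pipeline outputs (the manifest's stage timings are the only
  run-varying output, and they live only in `manifest.json`).
* Weighted sums use plain float arithmetic; the equation-exactness tests
  bound the error against fraction arithmetic at 1e-12, far below any
  decision threshold the scores feed.
* Degenerate inputs fail loudly and specifically: empty libraries or lists,
  all-unmatched collections, all-zero paired differences, too-few
  regression points and inconsistent hypergeometric parameters each raise a
  dedicated error rather than returning a silent default.

## Known limitations

* Scores depend on the annotation library's coverage; a drug the library
  does not annotate cannot be scored and is reported as unmatched.
* Pathway membership is plain union over gene sets (any shared target
  gene); no enrichment gating or ortholog/alias expansion of gene symbols.
* The per-drug max aggregator makes scores insensitive to how *many* strong
  features a drug has; use `aggregator="mean"` to probe that sensitivity.
* `Freq` counts distinct drugs, which is one of two defensible readings of
  a frequency over lists; anyone reconciling against other implementations
  should check this convention first, along with the choice of
  hypergeometric background.
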