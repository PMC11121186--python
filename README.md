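# dreamocracy

Aggregate prior drug-discovery evidence into disease-specific scores for
drug repurposing candidates.

Two kinds of studies leave long drug lists behind: computational drug
repurposing studies (CDRS) publish tables of candidate drugs, and clinical
trial registries (CTS) record which drugs were actually tested against a
disease. `dreamocracy` turns a pile of such lists, together with an
annotated drug library (mechanisms of action, initial indications, protein
targets and the pathways those targets sit in), into:

1. **DC-matrices** — per disease and per collection method, a table scoring
   every annotation feature by weight-modulated majority voting:

   ```
   DC_i = W_F · NormFreq_i + W_LC · NormListCount_i        (W_F = 0.4, W_LC = 0.6)
   ```

   where `Freq` counts the distinct drugs carrying feature *i* across the
   study lists, `ListCount` counts the lists containing at least one such
   drug, and both are normalised by their per-modality maximum. Features
   that could plausibly arise from random draws of library drugs are pruned
   by an exact hypergeometric test (strictly p < 0.05 against the library
   background).

2. **Composite Scores** — any drug is scored against a disease by
   aggregating (max by default) the DC scores of its kept features per
   modality, then combining:

   ```
   Composite = W1 · ScoreOfPaths + W2 · ScoreOfMoAs + W3 · ScoreOfInds
                                             (W1 = 0.4, W2 = 0.4, W3 = 0.2)
   Total Composite = mean over collection methods (N = 2 for CDRS + CTS)
   ```

   Scoring a whole library against several diseases yields the
   **super-reference table**, which can then be queried for any candidate.

3. **Comparative reports** — CDRS-vs-CTS signature overlap with exact
   hypergeometric p-values, disease–disease commonality networks, top-k
   ranking overlaps, frequency concordance regressions and Wilcoxon
   comparisons of drug-group score distributions.

The method is intentionally *not* a predictive model: it quantifies where
prior evidence already points, with user-controlled weights.

## Worked example

Everything below runs offline from generated fixtures; `simulate` plants
five enriched MoAs for a synthetic disease so there is a known signal to
recover.

```sh
dreamocracy simulate --seed 1 --out fixtures/
dreamocracy ingest --disease disease-a --method cdrs \
    --input fixtures/disease-a-cdrs-01.txt --input fixtures/disease-a-cdrs-02.txt \
    --input fixtures/disease-a-cdrs-03.txt --input fixtures/disease-a-cdrs-04.txt \
    --input fixtures/disease-a-cdrs-05.txt --input fixtures/disease-a-cdrs-06.txt \
    --library fixtures/library.tsv --out collection.tsv
dreamocracy build-matrix --collection collection.tsv --library fixtures/library.tsv \
    --gene-sets fixtures/gene_sets.gmt --out dcmatrix_disease-a_CDRS.tsv
```

which prints

```
wrote collection.tsv (6 lists, 131 drugs, 0 unmatched)
wrote dcmatrix_disease-a_CDRS.tsv (75 features, 6 kept at p<0.05)
```

i.e. 6 study lists covering 131 distinct library drugs produced 75 observed
features (MoAs + indications + pathways), of which 6 survive the enrichment
filter. The top MoA rows of the matrix (score descending):

```
modality  feature  freq  list_count  norm_freq  norm_listcount  dc_score  p_value   kept
MoA       moa-012  23    6           1.000      1.0             1.000     1.61e-09  True
MoA       moa-003  22    6           0.957      1.0             0.983     4.43e-07  True
```

`moa-012` appears in every list and in more distinct drugs than any other
MoA, so both normalised metrics are 1 and its DC score is exactly 1.0; the
tiny p-value says that 23 carriers among 131 sampled drugs is far more than
the library background would give by chance. Both top MoAs are planted
features of the simulation (`fixtures/truth.json`), recovered from the
lists alone.

The same steps run in Python (see `dreamocracy.simulate`,
`build_dc_matrix`, `build_super_reference`, `score_query`), and
`dreamocracy run --config pipeline.json` chains ingest → matrices → super
table → comparisons with a provenance manifest.

## Layout

| module | role |
| --- | --- |
| `dreamocracy.annotations` | drug library loading, name canonicalisation, GMT gene sets, target→pathway mapping |
| `dreamocracy.ingestion` | CDRS list files, ClinicalTrials-style CSV exports, status/phase rules, library resolution |
| `dreamocracy.dcmatrix` | feature counting, normalisation, DC scores, exact hypergeometric filter |
| `dreamocracy.scoring` | per-drug modality scores, Composite / Total Composite, super-reference table, queries |
| `dreamocracy.comparison` | signature overlap, disease networks, top-k overlap, concordance, Wilcoxon tests |
| `dreamocracy.synthetic` | seeded fixture generator with planted enrichment and recovery metrics |
| `dreamocracy.pipeline` / `cli` | config validation, orchestration, manifest, `dreamocracy` command |

See `docs/methods.md` for the model, its assumptions and the design
decisions.
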