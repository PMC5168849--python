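# debench

Benchmarking the **sensitivity, specificity and reproducibility of RNA-seq
differential-expression (DE) calls** on multi-site reference-mixture designs,
with synthetic data of known ground truth.

## The problem

Multi-site benchmark studies sequence well-characterized reference RNA
samples — A (a universal reference), B (a brain reference) and their known
titration mixtures — at several laboratory sites with technical replicates.
Two design properties make this layout a measuring instrument for DE
pipelines:

1. **Bounded up-regulation.** Sample C is 3 parts A and 1 part B, so for a
   gene with pure-sample abundances $a_g$, $b_g$ the true fold change of
   A over C is $a_g / (0.75\,a_g + 0.25\,b_g) \le 4/3$: no gene can be
   up-regulated in A past 4/3-fold, while down-regulation is unbounded.
2. **Same–same comparisons.** Comparing nominally identical samples across
   sites (A-vs-A, C-vs-C) can only yield false positives, giving an
   *empirical* false discovery rate for a site pair $(1,2)$:

   $$\mathrm{eFDR} = \frac{X_{A_1\text{-vs-}A_2} + X_{C_1\text{-vs-}C_2}}
                          {X_{A_1\text{-vs-}C_2} + X_{A_2\text{-vs-}C_1}}$$

   where $X$ counts filtered DE calls in each cross-site comparison.

`debench` reproduces this evaluation end-to-end on simulated data: a
negative-binomial count generator with the mixture design, site-level latent
confounders (library-preparation-like batch effects), TMM + log-CPM
normalization, surrogate-variable removal by residual SVD, two built-in DE
callers (moderated-t and NB-Wald), the q < 5% / |log2FC| > 1 /
average-expression filter cascade with a sensitivity-equalizing calibration
(3,000 calls at a median site), and the evaluation statistics: staged call
counts, per-pair eFDR, direction-aware intersection-over-union agreement,
top-N ranked-list concordance, truth-based FDR/sensitivity, and a two-way
sensitivity ANOVA. External callers' outputs can be imported through a
uniform DE-table contract and scored by the same machinery.

For whom: method developers who want a controlled testbed for DE pipelines,
and analysts who want to see — on data where the truth is known — why
factor-analysis correction plus effect-size and abundance filters are needed
before DE lists reproduce across laboratories.

## Worked example

The default benchmark simulates 20,000 genes at 6 sites × {A, C} × 4
technical replicates with two site-level confounders, then runs both callers
through all stages:

```bash
$ debench run --seed 1 --outdir results/demo
moderated_t: median intra-site calls 3004, median eFDR sva 0.03%, sva_fc_ae 0.00%
nb_wald: median intra-site calls 2998, median eFDR sva 2.55%, sva_fc_ae 0.69%
report written to results/demo
```

The report bundle (`comparisons.tsv`, `intra_counts.tsv`, `agreement.tsv`,
`topn.tsv`, `calibration.tsv`, `truth_metrics.tsv`, `anova.tsv`,
`run_summary.json`) stages everything as *raw* → *sva* (after
surrogate-variable removal) → *sva_fc* (+ fold-change filter) → *sva_fc_ae*
(+ calibrated average-expression filter). For seed 1 the median-over-pairs
summaries read:

| caller       | stage      | eFDR (%) | inter-site agreement |
|--------------|-----------|---------:|---------------------:|
| moderated_t  | raw       |    35.66 | 0.69 |
| moderated_t  | sva       |     0.03 | 0.68 |
| moderated_t  | sva_fc_ae |     0.00 | 0.81 |
| nb_wald      | raw       |    40.01 | 0.70 |
| nb_wald      | sva       |     2.55 | 0.71 |
| nb_wald      | sva_fc_ae |     0.69 | 0.84 |

Reading it: with hidden site confounders left in, roughly a third of
cross-site calls are false (eFDR 36–40%). Removing latent factors estimated
from design residuals crushes the false positives without touching
intra-site sensitivity; the fold-change and calibrated abundance filters
then lift inter-site list agreement from ~0.70 to ~0.81–0.84 and top-1000
ranked-list concordance above 0.91 (`topn.tsv`). The calibration report
shows the percentile of weakly expressed genes excluded per caller (27.7 and
34.9 here) so that a median site makes 3,000 calls — the common operating
point that makes callers comparable.

Other entry points: `debench simulate` (counts + metadata + truth TSVs),
`debench call` (one comparison on an imported count matrix),
`debench calibrate`, `debench evaluate --plots`, `debench check-config`.
All accept a JSON configuration (`debench check-config` echoes the fully
defaulted form); everything is deterministic given `--seed`.

## Layout

- `src/debench/simulate.py` — mixture-design count generator + ground truth
- `src/debench/data_model.py` — count container, TSV I/O, TMM, log-CPM, M/A
- `src/debench/confounders.py` — residual-SVD surrogate variables
- `src/debench/de_callers.py` — BH, moderated-t, NB-Wald, import contract
- `src/debench/filters.py` — q/FC/AE cascade and AE calibration
- `src/debench/evaluation.py` — eFDR, agreement, top-N, truth metrics, ANOVA
- `src/debench/orchestration.py`, `cli.py` — config, runner, CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
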