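# stoolmark

Biomarker discovery from stool microbiome profiles in case/control cohorts
with a continuous symptom score — the setting of interstitial
cystitis/bladder pain syndrome (IC/BPS), where candidate diagnostic species
are *depleted* in patients and co-vary as a community.

The package implements the full analysis chain as a tested, reusable
pipeline:

1. **Extended Random Forest (ERF) relevance ranking.** The OTU table is
   extended with *shadow features* (per-feature permutations that preserve
   each marginal but destroy any association with the response). A random
   forest (defaults Ntree = 25,000, Mtry = 200) is fit repeatedly over
   independent shadow draws, recording a permutation-based variable
   importance measure (VIM) per feature and run. Each feature's per-run
   VIMs are compared with those of the best-performing shadow by a one-sided
   Welch t-test; its **likelihood of relevance** is 1 − p. The best shadow
   sits at 50% by construction, and features above 70% are called relevant.
2. **ΔΔCT quantitation.** Duplicate qPCR wells per sample and species are
   collapsed, expressed relative to a calibrator (positive-control) sample,
   and converted to fold changes 2^(−ΔΔCT); groups are compared by
   Mann–Whitney (or Welch) with significance at P < 0.05.
3. **ROC biomarkers.** Classic univariate AUC (identical to the normalized
   Mann–Whitney U statistic, ties at half credit) for metabolites, and
   stratified 5-fold cross-validated AUC of a linear threshold model for
   species fold changes; markers with AUC > 0.70 are called significant.
4. **MIC co-variation networks.** The Maximal Information Coefficient
   (alpha = 0.6) between feature pairs, with edges above a configurable
   threshold (default 0.5), identifies taxa that co-vary as a community.
5. **Synthetic cohorts.** Because such study cohorts are small and rarely
   deposited, a generator produces 16S-style multinomial count tables
   (defaults: 16 controls + 18 cases, 300 taxa, 50,000 reads/sample) with
   planted case-depleted, latent-factor-correlated taxa that drive a
   GUPI-like symptom score (group means 1 and 26 on the 0–45 scale),
   matched qPCR Ct wells and a metabolite table — with ground truth, so
   every stage's recovery behaviour is testable end to end.

## Worked example

```python
from stoolmark import (SimSpec, simulate_cohort, to_relative_abundance,
                       ErfConfig, erf_rank)

otu, meta, truth = simulate_cohort(SimSpec(seed=9))
rel = to_relative_abundance(otu)
res = erf_rank(rel.data, meta.symptom_score,
               ErfConfig(seed=9).scaled())       # 500-tree desk profile
print(res.table.head(6)[["mean_vim", "likelihood", "rank", "relevant"]])
print("planted:", truth.planted_feature_ids)
```

prints

```
             mean_vim  likelihood  rank  relevant
feature_id
OTU_0085    32.010264    1.000000     1      True
OTU_0286    29.126132    1.000000     2      True
OTU_0034     6.125938    1.000000     3      True
OTU_0124     2.303470    0.991974     4      True
OTU_0298     0.920660    0.688986     5     False
OTU_0157     0.883051    0.667098     6     False
planted: ('OTU_0034', 'OTU_0085', 'OTU_0124', 'OTU_0258', 'OTU_0286')
```

Four of the five planted case-depleted taxa rank 1–4 with likelihood of
relevance near 1 (their importance beats the best shadow in essentially
every stability run) and are flagged `relevant` at the 70% threshold; the
fifth planted taxon (OTU_0258) lands just below the cutoff in this seed —
the typical behaviour for a 4-fold depletion in a 34-sample cohort.

The same analysis runs from the shell:

```bash
stoolmark run-all --seed 9 --scaled --out-dir results/
```

writing the simulated inputs, the ERF ranking, ΔΔCT fold changes and group
comparisons, per-marker ROC results, the MIC edge list and a JSON manifest.

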