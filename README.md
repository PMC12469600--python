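# prspredict

Sex-stratified allelic polygenic risk scores (PRS) for case–control genotype
data, with model-free percentile classification, leave-one-out
cross-validation, smoothed ROC/AUC, and a Monte-Carlo overlap-replication
test between two strata's top-k variant lists.

The pipeline:

1. **Variant QC** — sequential filters: missing call rate (> 0.10 removed),
   monomorphic variants, Hardy–Weinberg exact test in controls
   (alpha 1e-3), minor allele frequency (< 0.01 removed), and windowed
   VIF-based LD pruning (window 50, step 5, VIF > 2 removed).
2. **Sex split** — males and females become two independent datasets over
   the same variant list.
3. **Scoring** — per-variant allelic odds ratios (Haldane–Anscombe corrected
   when a cell is empty); variants ranked by OR descending (or |log OR|);
   PRS_j = Σ log(OR_i)·g_ij / (2·N_j) over the top-N variants, where g is
   minor-allele dosage and N_j skips an individual's missing calls.
4. **Prediction** — an individual is called a case when their score strictly
   exceeds the 95th percentile of control scores; the resulting 2×2 decision
   table yields PPV, NPV, table OR, and accuracy (a+d)/total.
5. **Evaluation** — sweep over a grid of variant counts N; the ragged
   (FPR, TPR) series is smoothed by repeated overlapping 3-point moving
   averages until it is a proper ROC curve, then integrated (trapezoid) for
   AUC. Leave-one-out cross-validation refits counts, ranking, selection and
   threshold without each individual before predicting them.
6. **Replication** — the overlap between the male and female top-k variant
   lists is tested against the null of two uniform random subsets
   (Monte-Carlo subset resampling, with the exact hypergeometric tail as an
   analytic oracle).

A synthetic-data module generates reproducible case–control cohorts with
sex-specific planted effects (HWE genotypes, logistic liability, intercept
solved for a target prevalence) so every stage is testable offline.

## CLI

```sh
prspredict simulate --config sim.yaml --out cohort          # PLINK bed/bim/fam
prspredict qc       --bfile cohort --mind-geno 0.10 --maf 0.01 \
                    --hwe 1e-3 --indep 50 5 2 --out qc/
prspredict score    --bfile qc/filtered --n-variants 5000 --out scores/
prspredict sweep    --bfile qc/filtered --grid 5,10,100,1000 --by-sex --out sweep/
prspredict loocv    --bfile qc/filtered --n-variants 5000 --out loo/
prspredict replic2  --universe 179082 --k1 5000 --k2 5000 \
                    --observed 544 --reps 100000 --seed 1
prspredict pipeline --bfile cohort --n-variants 50 --seed 1 --out run/
```

Genotype input is PLINK 1 binary (`--bfile PREFIX`) or a tab-separated text
dialect (`--text FILE`, gzip accepted): header
`sample_id  sex  phenotype  <variant ids…>`, one row per individual, dosages
0/1/2 or `NA`. Dosages always count the minor allele, recomputed from the
data. Outputs are TSV/JSON plus a `manifest.json` recording config and
seeds; every stochastic command requires `--seed`.

## Notes

- Accuracy is the proportion of correct predictions, (a+d)/(a+b+c+d).
- ROC smoothing holds the curve's endpoints fixed; if the endpoints
  themselves sit below the diagonal the conditions are unreachable and a
  convergence error is raised rather than a non-conforming curve returned.
- Bit-exact parity with PLINK's `--indep` pruning is a non-goal; the
  documented windowed-VIF contract is what is tested.
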