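# fdeam — CpG-deamination fraction as a negative predictor of HRD

Homologous recombination deficiency (HRD) makes tumors sensitive to PARP
inhibitors and platinum chemotherapy, so calling HRD from sequencing data is
a core task of precision oncology. The established genomic-instability
readout is the scar score **HRDsum = LOH + LST + TAI**, computed from
allele-specific copy-number segments — but it degrades badly in samples of
low tumor purity, which are common in clinical practice.

This package implements an alternative readout computed directly from
somatic single-base substitutions (SBS). Classifying each SBS into the
standard 96 trinucleotide channels, define

```
f_deam = 100% × ( #N[C>T]G mutations ) / TMB
```

— the percentage of C>T transitions at CpG sites (channels `A[C>T]G`,
`C[C>T]G`, `G[C>T]G`, `T[C>T]G`) among all SBS, where TMB is the total SBS
count. These mutations arise from the clock-like spontaneous deamination of
5-methylcytosine (signature SBS1). HR-deficient tumors accumulate mutations
across many other channels, which *dilutes* the clock-like fraction: **low
f_deam predicts HRD**. Because every detected variant contributes equally
to the ratio, f_deam is nearly invariant under loss of tumor purity, while
HRDsum collapses once allelic imbalances become indistinguishable from the
balanced normal background.

The package provides, as importable modules and a CLI:

| module             | contents |
|--------------------|----------|
| `catalog96`        | MAF/VCF parsing, pyrimidine-strand 96-channel catalogs, TMB, f_deam (NA below a TMB floor of 10) |
| `hr_class`         | cause-of-HRD classes H1a/H1b/H2a/H2b/H3 from gene alterations, BRCA1 promoter methylation, and the H1a\* vs H3 benchmark labels |
| `scar_scores`      | LOH (>15 Mb, sub-chromosomal), LST (3 Mb smoothing, ≥10 Mb flanks), TAI (telomeric, centromere-sparing), HRDsum |
| `purity_sim`       | variant-level read-mixing dilution (expected VAF scales by p/q), binomial detection model, copy-number attenuation, the purity experiment |
| `biomarker_eval`   | ROC/AUC with score direction, paired DeLong test, balanced-accuracy cutpoints, Spearman, Cohen's kappa, 96-channel Wilcoxon + BH-FDR differential analysis, signature CG>TG content |
| `synthetic_cohort` | labeled cohort generator with known class spectra, planted scar events, VAFs, purities |
| `pipeline`         | end-to-end orchestration with reproducible TSV/JSON outputs |

## Worked example

```python
from fdeam import GeneratorConfig, generate_cohort, roc_auc, optimize_cutpoint, spearman

cohort = generate_cohort(GeneratorConfig(seed=7))   # 20 HR-deficient + 20 HR-proficient
summ = cohort.summary()
print(summ.groupby("label")[["tmb", "f_deam", "hrdsum"]].mean().round(1))

auc_f = roc_auc(summ["f_deam"], summ["label"], "lower_predicts_positive").auc
auc_h = roc_auc(summ["hrdsum"], summ["label"], "higher_predicts_positive").auc
r, p = spearman(summ["f_deam"], summ["hrdsum"])
cut = optimize_cutpoint(summ["f_deam"], summ["label"], "lower_predicts_positive")
print(f"AUC f_deam = {auc_f:.2f}, AUC HRDsum = {auc_h:.2f}")
print(f"Spearman R(f_deam, HRDsum) = {r:.2f}")
print(f"optimal f_deam cutpoint = {cut.threshold:.1f}% "
      f"(sens {cut.sensitivity:.2f}, spec {cut.specificity:.2f})")
```

prints

```
           tmb  f_deam  hrdsum
label
negative  71.4    26.3    18.8
positive  55.6     7.3    53.8
AUC f_deam = 0.99, AUC HRDsum = 0.97
Spearman R(f_deam, HRDsum) = -0.72
optimal f_deam cutpoint = 18.9% (sens 1.00, spec 0.90)
```

HR-deficient ("positive", H1a\*) samples sit low on f_deam and high on
HRDsum; the two biomarkers are negatively correlated; the balanced-accuracy
optimal cutpoint falls between the class means. The same analysis runs from
the shell:

```sh
fdeam simulate --seed 7 --out cohort/
fdeam run-all --input-dir cohort/ --output-dir results/ --seed 7
```

which writes `classification.tsv`, `biomarkers.tsv`, `evaluation.json`,
`differential_channels.tsv` and `purity_experiment.tsv`. The purity table
shows the characteristic asymmetry: diluting the same cohort to 10% tumor
purity leaves f_deam's balanced accuracy essentially unchanged while
HRDsum's falls to chance.

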