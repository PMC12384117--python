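# riskprofiler

Multilocus genetic risk profiling for cardiovascular SNP panels.

`riskprofiler` implements the population-genetics workflow used to compare
genetic risk between small populations typed on a fixed SNP panel — here, a
19-SNP panel for atherosclerosis (AT: *SORT1*, *ADAMTS7*, *PCSK9*, *APOE*,
*LDLR*, 9p21) and venous thromboembolism (VTE: *F5*, *F2*, *MTHFR*), modeled
on a comparison of Azorean and mainland Portuguese blood-donor cohorts.
It is aimed at population geneticists and medical-genetics labs who have
unphased genotypes (CSV or VCF) and published reference frequencies, and
want frequency comparisons, haplotype structure and per-individual risk
classification from one toolkit.

## What it computes

* **Allele/genotype frequencies** by direct count, with Hardy–Weinberg
  tests (χ² against expected p², 2pq, q² counts, df = 1).
* **Population comparisons.** Two cohorts: Pearson χ² on the 2×2
  risk-allele table (no continuity correction) or the two-sided Fisher
  exact test when an expected cell is below 5; odds ratio with the Woolf
  95% CI, exp(ln OR ± 1.96·√(Σ 1/cellᵢ)). One cohort vs a reference that
  publishes only frequencies: one-sample χ², χ² = n(p̂ − p₀)²⁄(p₀(1 − p₀)).
  Bonferroni thresholds α/m per comparison family.
* **Haplotype frequencies** per gene by maximum likelihood from unphased
  genotypes (EM over the 2^(h−1) compatible phasings per individual, with
  random restarts; monotone likelihood asserted at every iteration).
* **Multilocus genetic profiles (MGPs).** Each individual's combined
  genotype string over a disease sub-panel defines a profile class with
  risk-allele count (RV), protective-allele count (PV), risk-homozygous
  SNP count (HoR), and a weighted genetic risk score,
  GRS = Σⱼ cⱼ·ORⱼ (or Σⱼ cⱼ·ln ORⱼ), cⱼ ∈ {0, 1, 2}. Individuals in the
  top/bottom decile of the score distribution are classified high/low
  risk, with stratified frequency tables by population, Azorean
  geographic group and sex, and an AT×VTE cross-risk overlap test.
* **Synthetic cohorts** with the study's structure (HWE per SNP, or
  gene-level haplotype sampling) and Monte-Carlo power for the χ² test at
  a given Cohen's w (cross-checked against the noncentral-χ² closed form,
  λ = n·w²).

## Worked example

```python
import riskprofiler as rp

# Azorean-style cohort: n=170, groups 70/70/30, 85M/85F, published freqs
cohort = rp.simulate_hwe_cohort(rp.azores_like_scenario(seed=42))

counts = rp.allele_counts(cohort, "rs10757274")
print("risk-allele (G) frequency:", round(counts.freq("G"), 3))
# risk-allele (G) frequency: 0.482

res = rp.gof_vs_reference(counts, rp.allele_frequencies("EUR")["rs10757274"])
print(f"vs EUR: chi2 = {res.statistic:.2f}, p = {res.p_value:.3f}")
# vs EUR: chi2 = 0.25, p = 0.615          (no frequency shift at this SNP)

# EM haplotype estimation on a cohort with real 9p21 haplotype structure
hap_cohort = rp.simulate_haplotype_cohort(
    {"9p21": rp.AZORES_HAPLOTYPES["9p21"]}, n=170, seed=42)
print(rp.em_estimate(hap_cohort, gene="9p21", seed=0).summary()
        [["label", "haplotype", "frequency"]].round(3))
#  H1 AG 0.520 / H2 GC 0.432 / H3 GG 0.044 / H4 AC 0.003
#  (generating frequencies were 0.502 / 0.434 / 0.045 / 0.019)

vte = rp.RiskProfileModel(cohort, "VTE", rp.VTE_WEIGHTS).fit()
print(vte.n_distinct_profiles, vte.classification.counts())
# 16 {'high': 9, 'intermediate': 0, 'low': 161}
print(vte.summary().head(3))
# VTE-MGP1  A/G G/G C/T A/A  RV=2 PV=0 HoR=0  GRS=4.38  (one carrier) ...
```

The VTE score uses the weights `{rs6025 (F5): 4.38, rs1799963 (F2): 1.80}`;
the *MTHFR* SNPs carry no odds-ratio weight and contribute 0 to the GRS
while still counting toward RV/HoR. A GRS of 4.38 is an *F5* Leiden
heterozygote; 6.18 adds a prothrombin G20210A heterozygote.

The same pipeline is available from the shell:

```sh
riskprofiler simulate --scenario azores --seed 5 --out cohort.csv
riskprofiler report --in cohort.csv --out-dir out/   # freqs, HWE, EM, MGPs, cross-risk
riskprofiler power --n 170 --w 0.3 --reps 2000 --seed 1
```

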