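# Methods

## Data model

A panel is an ordered list of biallelic SNPs; order is fixed by the config
file and defines the layout of multilocus profile strings, so identical
configs always yield identical profile strings. Each SNP carries its two
alleles, an optional risk allele, an optional protective allele and an
optional odds-ratio (OR) weight. Genotypes are unphased, unordered allele
pairs; cells are canonicalized alphabetically ("G/A" ≡ "A/G"). The built-in
19-SNP panel designates risk alleles for 15 of the AT SNPs and all 4 VTE
SNPs, and protective alleles at four AT SNPs (rs11591147-T, rs7412-C,
rs2228671-T, rs1433099-T). Orientation always comes from the config table,
never from comparing frequency columns: several PCSK9/APOE/LDLR rows of the
published frequency table are reported on opposite allele orientations in
the Portuguese and gnomAD columns, so frequency-based inference would
silently flip them.

Missing data: a sample missing any genotype inside a sub-panel is excluded
from that sub-panel's profile analysis (and from a gene's EM when a
genotype of that gene is missing) but is retained for per-SNP allele
counts. Exclusion counts are reported, never silently applied.

## Frequency statistics

* Allele frequencies are direct counts: each called genotype contributes
  two alleles.
* HWE: χ² goodness of fit with df = 1 of the observed (hom, het, hom)
  counts against (p², 2pq, q²)·n at the observed allele frequency.
  Monomorphic SNPs are flagged, not tested. The χ² approximation is used
  rather than the exact test; at the cohort sizes targeted here
  (n ≈ 100–200, MAF > 0.1) its null rejection rate is within Monte-Carlo
  error of the nominal level (checked in the test suite at n = 170).
* Two-population comparison: 2×2 table of risk vs non-risk allele counts;
  Pearson χ² without continuity correction when all expected cells ≥ 5
  (the classic rule), otherwise the two-sided Fisher exact test (sum of
  table probabilities ≤ the observed one). OR = ad/bc with the Woolf CI
  exp(ln OR ± z₀.₉₇₅·√(1/a + 1/b + 1/c + 1/d)); OR/CI are omitted when a
  cell is empty. This combination (no Yates, Woolf, z = 1.96) exactly
  reproduces the published 9p21 rs10757274 interval (1.023–2.047,
  p = 0.036) from counts reconstructed off the printed frequencies, which
  is the validation anchor for the implementation.
* Reference comparison: public frequency databases often publish
  frequencies without allele numbers, so the default is the one-sample
  χ² = n(p̂ − p₀)²/(p₀(1 − p₀)), df = 1. When reference counts are
  available the two-sample path can be used instead; the two agree as the
  reference size grows (tested at 2×10⁶ reference alleles).
* Multiple testing: Bonferroni α/m with the family size m configurable
  per comparison family (15 for the AT-panel-vs-reference family, 4 for
  the VTE family).
* `freq_to_count` reconstructs integer allele counts from frequencies
  printed at 3 decimals (round half to even) and warns when no integer
  count rounds back to the printed value.

## Cohort simulation

The generator defines the study conditions used throughout the tests:

* `azores_like_scenario()`: n = 170; geographic groups Eastern/Central/
  Western of 70/70/30; 85 males and 85 females interleaved so each group
  is sex-balanced; per-SNP effect-allele frequencies set to the published
  Azorean column.
* `mainland_like_scenario()`: n = 108 with 101 males and 7 females, at
  the published mainland frequencies.

Under `simulate_hwe_cohort` each individual draws two alleles per SNP
independently (HWE within SNP, linkage equilibrium between SNPs). Group
and sex labels are independent of genotype unless a scenario supplies
group-specific frequency overrides, which is how the group-comparison
machinery is exercised under an alternative. `simulate_haplotype_cohort`
draws two i.i.d. haplotypes per gene from a supplied frequency vector and
then discards phase; the bundled presets are the published gene-level
haplotype tables (the APOE block of that table is internally inconsistent
and is not bundled). What the generator deliberately does not emulate:
between-gene linkage, genotyping error, missingness patterns, and
population substructure beyond the group-frequency overrides — so passing
tests certify the statistical machinery under the stated sampling model,
not robustness to those real-data features.

One integer seed drives every run; all randomness flows through
`numpy.random.default_rng` streams derived from it, and identical
seeds give byte-identical outputs.

Power: the study's sample-size justification is re-derived by direct
Monte-Carlo — multinomial draws under the alternative implied by Cohen's
w (null uniform over df + 1 cells; probability w/√(2k) shifted between
the first two cells), χ² test at level α, rejection fraction over 2000
replicates — cross-checked against the noncentral-χ² closed form with
λ = n·w². Both df = 1 and df = 2 variants are exposed since allelic and
genotypic tests are both plausible readings.

## EM haplotype estimation

For one gene's m SNPs, an individual with h heterozygous sites is
compatible with 2^(h−1) unordered haplotype pairs. The observed-data
likelihood is Π over individuals of Σ over compatible pairs of
f(h₁)f(h₂)(2 − [h₁ = h₂]). Standard EM: posterior pair weights in the
E-step, weighted haplotype counts over 2n in the M-step. Defaults:
tolerance 1e-7 on the log-likelihood change, max 1000 iterations, 10
starts (first from the product of single-SNP allele frequencies, the rest
Dirichlet(1) draws), haplotypes below 1e-6 pruned and the vector
renormalized (the reported log-likelihood is recomputed on the pruned
vector). Monotonicity of the log-likelihood is asserted at every
iteration. The product-of-margins start is exactly the stationary saddle
on all-double-heterozygote data; the random restarts escape it, and this
case is covered by a dedicated test rather than hidden. Known fixed-point
property used as a test oracle: the per-SNP allele frequencies implied by
the estimate equal the direct-count frequencies. Labels H₁, H₂, … are
assigned by descending frequency, ties broken lexicographically. No
per-individual phasing output and no standard errors are produced.

## Profiles, GRS and classification

RV/PV/HoR are counted from the panel orientation; PV counts only alleles
explicitly designated protective (at risk-only SNPs the alternate allele
is neutral), which is the only reading consistent with the published VTE
profile table showing PV = 0 throughout. GRS in `or` mode is Σ cⱼ·ORⱼ and
in `log_or` mode Σ cⱼ·ln ORⱼ; SNPs without a weight contribute 0 in both
modes (but still count toward RV/PV/HoR) — again forced by the published
tables, where MTHFR-only profiles score 0.00 despite carrying risk
alleles. Weights are config, never hard-coded; `weights_from_table`
recovers weights from (profile, GRS) pairs by least squares, which is how
the bundled VTE weights {F5: 4.38, F2: 1.80} were reconstructed. These
reconstructed values reproduce every printed VTE GRS; they are
illustrative config, not authoritative epidemiological ORs.

Classification uses empirical quantiles (linear interpolation) of the
individual-level score at 0.10/0.90 by default. Tie handling is declared
and configurable: with the default `expand` rule, scores equal to a
boundary quantile join the extreme group; when a single score value spans
both deciles (the VTE distribution has ~90% of individuals at GRS = 0)
the tied atom joins the low group only, since it sits at the bottom of
the distribution — expanding the same value into both groups would be
contradictory. `strict` keeps boundary ties intermediate. Because scores
are discrete, realized high-risk fractions fluctuate around 10% (ties
inflate, discreteness deflates); the observed range on simulated Azorean
cohorts stays within roughly 6–20%. Both sample-level and profile-level
memberships are reported. Profile-level deciles (quantiles over distinct
profiles rather than individuals) are intentionally not the default.

Stratified output mirrors the published table layout: per population,
per geographic group, per sex; strata with no classified samples are
reported absent, not as zero. High-risk counts are compared across
geographic groups (2×k χ²) and between sexes (χ²/Fisher by the expected-
cell rule). The AT×VTE cross-risk analysis tabulates (AT-high vs not) ×
(VTE-high vs not) over the common samples with a Fisher test, and reports
mean AT-GRS inside and outside the VTE-high stratum.

## Numerical and design notes

* Quantiles: `numpy.quantile` default linear interpolation; documented
  because the high/low group sizes depend on it at small n.
* χ²/Fisher/noncentral-χ² tail probabilities come from scipy;
  `statsmodels` is used in the tests as an independent check of the Woolf
  interval, never as the implementation.
* Degenerate inputs: monomorphic SNPs (HWE), empty strata, all-equal
  score distributions, zero table cells and reference frequencies at the
  {0,1} boundary are all explicit code paths with flags, warnings or
  validation errors — not silent NaNs.
* VCF ingestion is keyed on rsID, biallelic records only, no liftover or
  strand heuristics; REF/ALT must match the panel alleles as a set.
* Problem sizes in the test suite: EM parameter recovery uses cohorts of
  10⁴ individuals (sampling SE of the largest haplotype ≈ 0.0034, so the
  ±0.01 recovery check is a ~3σ bound); calibration checks use 1000
  Monte-Carlo replicates at the study allele numbers; the grid-search
  oracle for 2-SNP EM refines from step 0.01 to 10⁻⁴ over the haplotype
  simplex.

## Known limitations

* No covariate adjustment, logistic association, FDR control, LD
  statistics, imputation or multi-allelic support.
* The EM excludes individuals with missing genotypes in the gene rather
  than integrating over them.
* The percentile rule cannot reproduce every fraction in the published
  profile tables; those tables are not fully internally consistent (their
  profile frequencies do not sum to 1), so the rule here is declared and
  reported in output rather than reverse-engineered.
* Reconstructed VTE weights are a two-parameter fit to printed scores;
  AT weights must be supplied by the user.
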