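"""Synthetic cohort generation.

Cohorts are drawn either SNP-by-SNP under Hardy-Weinberg equilibrium at
specified allele frequencies, or gene-by-gene from haplotype frequency
vectors (two haplotypes per individual, i.i.d., phase then discarded).
Preset scenarios reproduce the structure of the two Portuguese study
cohorts: an Azorean cohort of n=170 (geographic groups Eastern/Central/
Western of 70/70/30, 85 males and 85 females) and a mainland cohort of
n=108 (101 males, 7 females), at the published allele frequencies.

Metadata labels (group, sex) are assigned independently of genotype unless
a scenario supplies group-specific frequencies, so the group-comparison
machinery can be exercised under both the null and an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import zip_longest

import numpy as np
import pandas as pd

from . import datasets
from .panel import (GenotypeTable, MISSING, Panel, SampleRecord,
                    ValidationError)

AZORES_GROUP_SIZES = {"Eastern": 70, "Central": 70, "Western": 30}


@dataclass
class SimulationScenario:
    """Parameters of one synthetic cohort.

    ``allele_freqs`` maps rsid -> frequency of that SNP's *effect allele*
    (named in ``effect_alleles``); the other allele gets the complement.
    ``group_freqs`` optionally overrides frequencies per geographic group
    to simulate between-group differences.
    """

    panel: Panel
    allele_freqs: dict[str, float]
    effect_alleles: dict[str, str]
    n: int
    population: str = "other"
    group_sizes: dict[str, int] = field(default_factory=dict)
    sex_counts: dict[str, int] = field(default_factory=dict)
    group_freqs: dict[str, dict[str, float]] | None = None
    seed: int = 0
    name: str = "scenario"

    def __post_init__(self) -> None:
        for rsid, f in self.allele_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"{rsid}: frequency {f} outside [0, 1]")
            if rsid not in self.panel:
                raise ValidationError(f"{rsid}: not in panel")
        if self.group_sizes and sum(self.group_sizes.values()) != self.n:
            raise ValidationError("group sizes must sum to cohort n")
        if self.sex_counts and sum(self.sex_counts.values()) != self.n:
            raise ValidationError("sex counts must sum to cohort n")


def _sample_records(scenario: SimulationScenario) -> list[SampleRecord]:
    groups: list[str] = []
    if scenario.group_sizes:
        for name, size in scenario.group_sizes.items():
            groups.extend([name] * size)
    else:
        groups = ["none"] * scenario.n
    if scenario.sex_counts:
        # interleave sexes across the cohort so each geographic group is
        # sex-balanced where counts allow (the study sampled half/half
        # per island)
        per_sex = [[name] * size for name, size in scenario.sex_counts.items()]
        sexes = [s for tup in zip_longest(*per_sex) for s in tup if s is not None]
    else:
        sexes = ["unknown"] * scenario.n
    width = len(str(scenario.n))
    return [
        SampleRecord(
            sample_id=f"{scenario.name}_{i + 1:0{width}d}",
            population=scenario.population,
            geographic_group=groups[i],
            sex=sexes[i],
        )
        for i in range(scenario.n)
    ]


def simulate_hwe_cohort(scenario: SimulationScenario,
                        seed: int | None = None) -> GenotypeTable:
    """Draw a cohort SNP-by-SNP under HWE.

    Each individual receives two alleles drawn independently with the
    scenario's effect-allele frequency (Hardy-Weinberg genotype
    proportions p^2 : 2pq : q^2). Deterministic given the seed.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    samples = _sample_records(scenario)
    sample_groups = np.array([s.geographic_group for s in samples])
    data: dict[str, list[str]] = {}
    for snp in scenario.panel:
        if snp.rsid not in scenario.allele_freqs:
            data[snp.rsid] = [MISSING] * scenario.n
            continue
        eff = scenario.effect_alleles.get(snp.rsid, snp.allele_a)
        other = snp.allele_b if eff == snp.allele_a else snp.allele_a
        freq = np.full(scenario.n, scenario.allele_freqs[snp.rsid])
        if scenario.group_freqs:
            for gname, override in scenario.group_freqs.items():
                if snp.rsid in override:
                    freq[sample_groups == gname] = override[snp.rsid]
        draws = rng.random((scenario.n, 2)) < freq[:, None]
        cells = []
        for has_eff in draws:
            pair = sorted(eff if hit else other for hit in has_eff)
            cells.append("/".join(pair))
        data[snp.rsid] = cells
    ids = pd.Index([s.sample_id for s in samples])
    gts = pd.DataFrame(data, index=ids, columns=list(scenario.panel.rsids))
    return GenotypeTable(scenario.panel, samples, gts)


def simulate_haplotype_cohort(gene_haps: dict[str, dict[str, float]],
                              n: int, seed: int,
                              panel: Panel | None = None,
                              population: str = "other") -> GenotypeTable:
    """Draw a cohort gene-by-gene from haplotype frequency vectors.

    ``gene_haps`` maps gene -> {haplotype string: frequency}; haplotype
    strings run over the gene's SNPs in panel order. Each individual gets
    two i.i.d. haplotypes per gene; only the unordered genotypes are
    exposed (phase is discarded, as in real unphased assay data).
    """
    if panel is None:
        panel = datasets.default_panel()
    rng = np.random.default_rng(seed)
    width = len(str(n))
    samples = [SampleRecord(sample_id=f"hap_{i + 1:0{width}d}", population=population)
               for i in range(n)]
    data: dict[str, list[str]] = {
        rsid: [MISSING] * n for rsid in panel.rsids
    }
    for gene, hap_freqs in gene_haps.items():
        snps = panel.gene_snps(gene)
        haps = list(hap_freqs)
        freqs = np.array([hap_freqs[h] for h in haps], dtype=float)
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"{gene}: haplotype frequencies sum to {freqs.sum():.6f}, not 1"
            )
        for h in haps:
            if len(h) != len(snps):
                raise ValidationError(
                    f"{gene}: haplotype {h!r} has {len(h)} alleles for "
                    f"{len(snps)} SNPs"
                )
            for al, snp in zip(h, snps):
                if al not in snp.alleles:
                    raise ValidationError(
                        f"{gene}: haplotype {h!r} allele {al!r} invalid at "
                        f"{snp.rsid}"
                    )
        picks = rng.choice(len(haps), size=(n, 2), p=freqs)
        for i in range(n):
            h1, h2 = haps[picks[i, 0]], haps[picks[i, 1]]
            for j, snp in enumerate(snps):
                pair = sorted((h1[j], h2[j]))
                data[snp.rsid][i] = "/".join(pair)
    ids = pd.Index([s.sample_id for s in samples])
    gts = pd.DataFrame(data, index=ids, columns=list(panel.rsids))
    return GenotypeTable(panel, samples, gts)


def azores_like_scenario(seed: int = 0) -> SimulationScenario:
    """Preset: Azorean-style cohort, n=170 (groups 70/70/30, 85M/85F),
    per-SNP published Azorean frequencies, HWE within SNP."""
    panel = datasets.default_panel()
    return SimulationScenario(
        panel=panel,
        allele_freqs=datasets.allele_frequencies("azores"),
        effect_alleles=datasets.effect_alleles(),
        n=170,
        population="azores",
        group_sizes=dict(AZORES_GROUP_SIZES),
        sex_counts={"M": 85, "F": 85},
        seed=seed,
        name="azores",
    )


def mainland_like_scenario(seed: int = 0) -> SimulationScenario:
    """Preset: mainland-style cohort, n=108 (101 males, 7 females), at the
    published mainland frequencies."""
    panel = datasets.default_panel()
    return SimulationScenario(
        panel=panel,
        allele_freqs=datasets.allele_frequencies("mainland"),
        effect_alleles=datasets.effect_alleles(),
        n=108,
        population="mainland",
        sex_counts={"M": 101, "F": 7},
        seed=seed,
        name="mainland",
    )
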