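"""Population-genetics statistics: direct-count frequencies, HWE, 2x2
comparisons with Woolf odds-ratio intervals, reference goodness-of-fit,
Bonferroni thresholds, and Monte-Carlo power for chi-square tests.

Conventions match the classic contingency-table toolkit: Pearson chi-square
without continuity correction when every expected cell is at least 5,
otherwise a two-sided Fisher exact test; odds-ratio confidence intervals by
Woolf's log-OR normal approximation, exp(ln OR +/- z * sqrt(sum 1/cell)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .panel import GenotypeTable, MISSING, ValidationError

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class AlleleCounts:
    """Biallelic allele counts at one SNP, oriented by the panel alleles."""

    rsid: str
    allele_a: str
    allele_b: str
    count_a: int
    count_b: int
    risk_allele: str | None = None

    @property
    def n_alleles(self) -> int:
        return self.count_a + self.count_b

    @property
    def freq_a(self) -> float:
        return self.count_a / self.n_alleles

    @property
    def freq_b(self) -> float:
        return self.count_b / self.n_alleles

    @property
    def maf(self) -> float:
        return min(self.freq_a, self.freq_b)

    @property
    def count_risk(self) -> int:
        if self.risk_allele is None:
            raise ValidationError(f"{self.rsid}: no risk allele designated")
        return self.count_a if self.risk_allele == self.allele_a else self.count_b

    @property
    def count_nonrisk(self) -> int:
        return self.n_alleles - self.count_risk

    def freq(self, allele: str) -> float:
        if allele == self.allele_a:
            return self.freq_a
        if allele == self.allele_b:
            return self.freq_b
        raise KeyError(allele)


@dataclass(frozen=True)
class AssociationResult:
    """Outcome of a frequency comparison (chi-square or Fisher)."""

    method: str  # chi2_2x2 | fisher_2x2 | chi2_gof
    statistic: float
    df: int
    p_value: float
    or_point: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    alpha: float = 0.05
    table: tuple | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class HweResult:
    """Chi-square goodness-of-fit of genotype counts to HWE proportions."""

    observed: tuple[int, int, int]  # (hom_a, het, hom_b)
    expected: tuple[float, float, float]
    chi2: float
    p_value: float
    monomorphic: bool = False


@dataclass(frozen=True)
class PowerResult:
    """Monte-Carlo power estimate with its noncentral chi-square analogue."""

    power: float
    analytic_power: float
    n: int
    w: float
    df: int
    alpha: float
    reps: int

    @property
    def mc_se(self) -> float:
        return float(np.sqrt(self.power * (1.0 - self.power) / self.reps))


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def allele_counts(gt: GenotypeTable, rsid: str) -> AlleleCounts:
    """Direct-count allele tally at one SNP (2 alleles per called genotype)."""
    snp = gt.panel[rsid]
    count_a = count_b = 0
    for cell in gt.genotypes[rsid]:
        if cell == MISSING:
            continue
        for al in cell.split("/"):
            if al == snp.allele_a:
                count_a += 1
            else:
                count_b += 1
    if count_a + count_b == 0:
        raise ValidationError(f"{rsid}: all genotypes missing, no allele denominator")
    return AlleleCounts(rsid, snp.allele_a, snp.allele_b, count_a, count_b,
                        risk_allele=snp.risk_allele)


def freq_to_count(freq: float, n_alleles: int) -> int:
    """Reconstruct an integer allele count from a rounded frequency.

    Uses round-half-to-even. Warns when the reconstructed count does not
    round back to the input frequency at 3 decimals (i.e. the printed
    frequency cannot have come from this denominator).
    """
    if not 0.0 <= freq <= 1.0:
        raise ValidationError(f"frequency {freq} outside [0, 1]")
    if n_alleles <= 0:
        raise ValidationError("n_alleles must be positive")
    count = int(round(freq * n_alleles))
    if round(count / n_alleles, 3) != round(freq, 3):
        warnings.warn(
            f"count {count}/{n_alleles} does not round back to {freq:.3f}",
            stacklevel=2,
        )
    return count


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def hwe_test(counts: tuple[int, int, int]) -> HweResult:
    """HWE chi-square (df=1) from observed (hom_a, het, hom_b) counts.

    Expected counts are (p^2, 2pq, q^2) * n at the observed allele
    frequencies. Monomorphic input cannot depart from HWE and is returned
    flagged with chi2=0, p=1.
    """
    hom_a, het, hom_b = counts
    n = hom_a + het + hom_b
    if n < 1:
        raise ValidationError("empty genotype counts")
    p = (2 * hom_a + het) / (2 * n)
    q = 1.0 - p
    expected = (p * p * n, 2 * p * q * n, q * q * n)
    if p == 0.0 or q == 0.0:
        return HweResult((hom_a, het, hom_b), expected, 0.0, 1.0, monomorphic=True)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(counts, expected))
    p_value = float(sps.chi2.sf(chi2, df=1))
    return HweResult((hom_a, het, hom_b), expected, float(chi2), p_value)


def _woolf_ci(table: np.ndarray, z: float = Z_95) -> tuple[float, float, float]:
    a, b = table[0]
    c, d = table[1]
    or_point = (a * d) / (b * c)
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    log_or = float(np.log(or_point))
    return float(or_point), float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def compare_allele_counts(a: AlleleCounts, b: AlleleCounts,
                          alpha: float = 0.05) -> AssociationResult:
    """Two-population allele-frequency comparison on the 2x2 risk table.

    Rows are populations, columns risk/non-risk allele counts (panel
    orientation; falls back to allele_a when no risk allele is set).
    Pearson chi-square (df=1, no continuity correction) when all expected
    cells are >= 5, otherwise the two-sided Fisher exact test. The odds
    ratio is (a_risk * b_nonrisk) / (a_nonrisk * b_risk), with the Woolf
    95% CI; OR/CI are absent when the table has an empty cell.
    """
    if a is b:
        raise ValidationError("the two populations are the same object")
    if a.risk_allele is not None:
        table = np.array([[a.count_risk, a.count_nonrisk],
                          [b.count_risk, b.count_nonrisk]], dtype=float)
    else:
        table = np.array([[a.count_a, a.count_b],
                          [b.count_a, b.count_b]], dtype=float)
    if table.sum() == 0 or (table.sum(axis=1) == 0).any():
        raise ValidationError("degenerate comparison: a population has no alleles")

    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    expected = np.outer(row, col) / n

    if (col == 0).any():
        # one allele absent everywhere: no association is testable
        method, stat, p_value = "fisher_2x2", float("nan"), 1.0
    elif (expected >= 5).all():
        method = "chi2_2x2"
        stat, p_value, _, _ = sps.chi2_contingency(table, correction=False)
        stat, p_value = float(stat), float(p_value)
    else:
        method = "fisher_2x2"
        stat, p_value = sps.fisher_exact(table.astype(int), alternative="two-sided")
        stat, p_value = float(stat), float(p_value)

    if (table > 0).all():
        or_point, ci_low, ci_high = _woolf_ci(table)
    else:
        or_point = ci_low = ci_high = None
    return AssociationResult(method, stat, 1, p_value, or_point, ci_low,
                             ci_high, alpha, tuple(map(tuple, table.astype(int))))


def gof_vs_reference(a: AlleleCounts, p0: float,
                     alpha: float = 0.05) -> AssociationResult:
    """One-sample chi-square of observed allele frequency against a
    reference frequency p0 (df=1): chi2 = n * (p_hat - p0)^2 / (p0 (1-p0)).

    Used when the reference (e.g. a public frequency database) publishes
    frequencies without allele numbers; p_hat is the risk-allele frequency
    when the panel designates one, otherwise freq_a.
    """
    if not 0.0 < p0 < 1.0:
        raise ValidationError(f"reference frequency must be in (0,1), got {p0}")
    n = a.n_alleles
    p_hat = (a.count_risk / n) if a.risk_allele is not None else a.freq_a
    chi2 = n * (p_hat - p0) ** 2 / (p0 * (1.0 - p0))
    p_value = float(sps.chi2.sf(chi2, df=1))
    return AssociationResult("chi2_gof", float(chi2), 1, p_value, alpha=alpha)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if m < 1:
        raise ValidationError("number of comparisons m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# Power
# ---------------------------------------------------------------------------

def _alternative_cells(w: float, df: int) -> tuple[np.ndarray, np.ndarray]:
    """Null and alternative cell probabilities realizing Cohen's w.

    The null is uniform over k = df + 1 cells; the alternative shifts
    probability delta from the second cell to the first, with delta chosen
    so that sqrt(sum (p1-p0)^2 / p0) = w.
    """
    k = df + 1
    p0 = np.full(k, 1.0 / k)
    delta = w / np.sqrt(2.0 * k)
    if delta >= 1.0 / k:
        raise ValidationError(f"effect size w={w} too large for df={df}")
    p1 = p0.copy()
    p1[0] += delta
    p1[1] -= delta
    return p0, p1


def power_simulation(n: int, w: float, df: int = 1, alpha: float = 0.05,
                     reps: int = 2000, seed: int = 0) -> PowerResult:
    """Monte-Carlo power of the chi-square goodness-of-fit test.

    Draws ``reps`` multinomial samples of size ``n`` under an alternative
    with Cohen's effect size ``w`` (noncentrality lambda = n * w^2), tests
    each against the uniform null at level ``alpha``, and returns the
    rejection fraction together with the closed-form noncentral chi-square
    power for cross-checking.
    """
    if w < 0:
        raise ValidationError("Cohen's w must be non-negative")
    if reps < 100:
        raise ValidationError("reps must be at least 100")
    rng = np.random.default_rng(seed)
    p0, p1 = _alternative_cells(w, df)
    counts = rng.multinomial(n, p1, size=reps)
    expected = n * p0
    chi2 = ((counts - expected) ** 2 / expected).sum(axis=1)
    crit = sps.chi2.ppf(1.0 - alpha, df)
    power = float((chi2 > crit).mean())
    analytic = float(sps.ncx2.sf(crit, df, n * w * w))
    return PowerResult(power, analytic, n, w, df, alpha, reps)
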