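"""Maximum-likelihood haplotype frequency estimation from unphased
genotypes (EM algorithm).

For a gene with m biallelic SNPs, an individual's unphased genotype is
compatible with 2^(h-1) unordered haplotype pairs, where h is the number
of heterozygous sites. Under random mating, the probability of genotype g
given haplotype frequencies f is

    P(g | f) = sum over compatible pairs {h1, h2} of f(h1) f(h2) (2 - [h1 = h2])

The EM algorithm iterates between assigning each individual posterior
weights over its compatible pairs (E-step) and re-estimating frequencies
as weighted haplotype counts over 2n (M-step). The observed-data
log-likelihood is non-decreasing at every step; this is asserted, not
assumed. The all-double-heterozygote saddle (where the product-of-margins
start is a stationary point) is handled with random Dirichlet restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypeTable, MISSING, ValidationError

PRUNE_TOL = 1e-6


def enumerate_phasings(genotype_vector) -> list[tuple[str, str]]:
    """All unordered haplotype pairs compatible with one unphased genotype.

    ``genotype_vector`` is a sequence of per-SNP allele pairs (2-tuples or
    "A/G" strings, unordered). Returns 2^(h-1) distinct pairs (1 when the
    number of heterozygous sites h is 0 or 1), each as a sorted tuple of
    two haplotype strings.
    """
    pairs = []
    for cell in genotype_vector:
        if isinstance(cell, str):
            if cell == MISSING:
                raise ValidationError("missing genotype in phasing enumeration")
            a1, a2 = cell.split("/")
        else:
            a1, a2 = cell
        pairs.append((a1, a2))
    het_idx = [i for i, (a1, a2) in enumerate(pairs) if a1 != a2]
    base = [a1 for a1, _ in pairs]
    if not het_idx:
        hap = "".join(base)
        return [(hap, hap)]
    # fix the first heterozygous site on haplotype 1 to avoid generating
    # each unordered pair twice
    out: list[tuple[str, str]] = []
    free = het_idx[1:]
    for mask in range(1 << len(free)):
        h1 = list(base)
        h2 = [a2 for _, a2 in pairs]
        h1[het_idx[0]] = pairs[het_idx[0]][0]
        h2[het_idx[0]] = pairs[het_idx[0]][1]
        for bit, i in enumerate(free):
            if (mask >> bit) & 1:
                h1[i], h2[i] = pairs[i][1], pairs[i][0]
            else:
                h1[i], h2[i] = pairs[i][0], pairs[i][1]
        s1, s2 = "".join(h1), "".join(h2)
        out.append((s1, s2) if s1 <= s2 else (s2, s1))
    return out


def log_likelihood(frequencies: dict[str, float], genotype_vectors) -> float:
    """Observed-data log-likelihood of haplotype frequencies.

    ``genotype_vectors`` is an iterable of per-individual genotype vectors
    (as accepted by :func:`enumerate_phasings`). Individuals whose every
    compatible pair has zero probability contribute -inf.
    """
    total = 0.0
    for vec in genotype_vectors:
        prob = 0.0
        for h1, h2 in enumerate_phasings(vec):
            f1 = frequencies.get(h1, 0.0)
            f2 = frequencies.get(h2, 0.0)
            prob += f1 * f2 * (1.0 if h1 == h2 else 2.0)
        if prob <= 0.0:
            return float("-inf")
        total += np.log(prob)
    return float(total)


@dataclass
class HaplotypeEMResults:
    """Fitted haplotype frequency distribution for one gene.

    Haplotype labels H1, H2, ... are assigned by descending frequency
    (ties broken lexicographically), matching the usual presentation of
    population haplotype tables.
    """

    gene: str
    snp_rsids: tuple[str, ...]
    haplotypes: tuple[str, ...]
    frequencies: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    n_restarts_used: int
    n_individuals: int
    n_excluded: int

    def frequency(self, haplotype: str) -> float:
        try:
            return float(self.frequencies[self.haplotypes.index(haplotype)])
        except ValueError:
            return 0.0

    def as_dict(self) -> dict[str, float]:
        return {h: float(f) for h, f in zip(self.haplotypes, self.frequencies)}

    def implied_allele_frequencies(self) -> dict[str, dict[str, float]]:
        """Per-SNP allele frequencies implied by the haplotype vector."""
        out: dict[str, dict[str, float]] = {}
        for j, rsid in enumerate(self.snp_rsids):
            freqs: dict[str, float] = {}
            for hap, f in zip(self.haplotypes, self.frequencies):
                freqs[hap[j]] = freqs.get(hap[j], 0.0) + float(f)
            out[rsid] = freqs
        return out

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "label": [f"H{i + 1}" for i in range(len(self.haplotypes))],
            "haplotype": list(self.haplotypes),
            "frequency": self.frequencies,
            "gene": self.gene,
            "loglik": self.log_likelihood,
            "converged": self.converged,
        })


class HaplotypeEM:
    """EM model for haplotype frequencies of one gene's SNPs.

    Parameters
    ----------
    genotype_table
        Unphased genotype data; only the gene's SNP columns are used.
    gene
        Gene label to select SNPs by; alternatively pass explicit
        ``rsids``. Individuals missing any of the selected genotypes are
        excluded from the fit (their count is reported on the results).
    """

    def __init__(self, genotype_table: GenotypeTable, gene: str | None = None,
                 rsids: tuple[str, ...] | None = None):
        panel = genotype_table.panel
        if rsids is None:
            if gene is None:
                raise ValidationError("specify a gene or explicit rsids")
            snps = panel.gene_snps(gene)
            rsids = tuple(s.rsid for s in snps)
        self.gene = gene or "+".join(rsids)
        self.rsids = tuple(rsids)
        sub = genotype_table.genotypes[list(self.rsids)]
        complete = sub[(sub != MISSING).all(axis=1)]
        self.n_excluded = len(sub) - len(complete)
        if complete.empty:
            raise ValidationError(
                f"{self.gene}: no samples with complete genotypes"
            )
        self._vectors = [tuple(row) for row in complete.itertuples(index=False)]
        self._snps = tuple(panel[r] for r in self.rsids)

    # -- internal machinery -------------------------------------------------

    def _compile(self):
        """Group identical genotype vectors and index their phasings."""
        classes: dict[tuple, int] = {}
        for vec in self._vectors:
            classes[vec] = classes.get(vec, 0) + 1
        hap_index: dict[str, int] = {}
        compiled = []  # (count, [(i, j, multiplicity)])
        for vec, count in classes.items():
            entries = []
            for h1, h2 in enumerate_phasings(vec):
                for h in (h1, h2):
                    if h not in hap_index:
                        hap_index[h] = len(hap_index)
                mult = 1.0 if h1 == h2 else 2.0
                entries.append((hap_index[h1], hap_index[h2], mult))
            compiled.append((count, entries))
        haps = [None] * len(hap_index)
        for h, i in hap_index.items():
            haps[i] = h
        return haps, compiled

    def _initial_freq(self, haps, restart: int, rng) -> np.ndarray:
        if restart == 0:
            # product of direct-count allele frequencies
            allele_freq = []
            for j in range(len(self.rsids)):
                counts: dict[str, int] = {}
                for vec in self._vectors:
                    a1, a2 = vec[j].split("/")
                    counts[a1] = counts.get(a1, 0) + 1
                    counts[a2] = counts.get(a2, 0) + 1
                total = sum(counts.values())
                allele_freq.append({a: c / total for a, c in counts.items()})
            f = np.array([
                np.prod([allele_freq[j].get(h[j], 0.0) for j in range(len(h))])
                for h in haps
            ])
            if f.sum() <= 0:
                f = np.full(len(haps), 1.0 / len(haps))
            return f / f.sum()
        return rng.dirichlet(np.ones(len(haps)))

    @staticmethod
    def _loglik(freq, compiled) -> float:
        total = 0.0
        for count, entries in compiled:
            prob = sum(freq[i] * freq[j] * m for i, j, m in entries)
            if prob <= 0.0:
                return float("-inf")
            total += count * np.log(prob)
        return float(total)

    def fit(self, tol: float = 1e-7, max_iter: int = 1000,
            restarts: int = 10, seed: int = 0) -> HaplotypeEMResults:
        """Run EM with multiple starts and return the best solution.

        The first start uses product-of-allele-frequency initialization;
        the remaining ``restarts - 1`` starts draw Dirichlet(1) frequency
        vectors. Convergence: |change in log-likelihood| < ``tol``.
        """
        haps, compiled = self._compile()
        n = sum(count for count, _ in compiled)
        rng = np.random.default_rng(seed)
        best = None
        for restart in range(max(1, restarts)):
            freq = self._initial_freq(haps, restart, rng)
            ll = self._loglik(freq, compiled)
            converged = False
            it = 0
            for it in range(1, max_iter + 1):
                expected = np.zeros(len(haps))
                for count, entries in compiled:
                    weights = np.array([freq[i] * freq[j] * m
                                        for i, j, m in entries])
                    total = weights.sum()
                    if total <= 0.0:
                        continue
                    weights *= count / total
                    for (i, j, _m), w in zip(entries, weights):
                        expected[i] += w
                        expected[j] += w
                freq = expected / (2.0 * n)
                new_ll = self._loglik(freq, compiled)
                if np.isfinite(ll) and new_ll < ll - 1e-9:
                    raise AssertionError(
                        f"EM log-likelihood decreased: {ll} -> {new_ll}"
                    )
                if np.isfinite(ll) and abs(new_ll - ll) < tol:
                    ll = new_ll
                    converged = True
                    break
                ll = new_ll
            if best is None or ll > best[0] + 1e-12:
                best = (ll, freq, it, converged, restart + 1)
        ll, freq, iters, converged, used = best
        keep = freq >= PRUNE_TOL
        haps_kept = [h for h, k in zip(haps, keep) if k]
        freq_kept = freq[keep]
        freq_kept = freq_kept / freq_kept.sum()
        # report the likelihood of the pruned, renormalized vector so the
        # results object is internally consistent
        full = np.zeros(len(haps))
        full[keep] = freq_kept
        ll = self._loglik(full, compiled)
        order = sorted(range(len(haps_kept)),
                       key=lambda i: (-freq_kept[i], haps_kept[i]))
        return HaplotypeEMResults(
            gene=self.gene,
            snp_rsids=self.rsids,
            haplotypes=tuple(haps_kept[i] for i in order),
            frequencies=np.array([freq_kept[i] for i in order]),
            log_likelihood=float(ll),
            n_iterations=iters,
            converged=converged,
            n_restarts_used=used,
            n_individuals=n,
            n_excluded=self.n_excluded,
        )


def em_estimate(gts: GenotypeTable, gene: str | None = None,
                rsids: tuple[str, ...] | None = None, tol: float = 1e-7,
                max_iter: int = 1000, restarts: int = 10,
                seed: int = 0) -> HaplotypeEMResults:
    """Convenience wrapper: ``HaplotypeEM(gts, gene).fit(...)``."""
    return HaplotypeEM(gts, gene=gene, rsids=rsids).fit(
        tol=tol, max_iter=max_iter, restarts=restarts, seed=seed
    )
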