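"""Built-in panel definition and published frequency presets.

The default panel covers 19 cardiovascular SNPs: a 15-SNP atherosclerosis
(AT) group (SORT1, ADAMTS7, PCSK9, APOE, LDLR and the 9p21 region) and a
4-SNP venous thromboembolism (VTE) group (F5, F2, MTHFR x2). For every SNP
the table records the published effect-allele frequency in the mainland
Portuguese and Azorean cohorts and in four gnomAD reference populations
(frequencies are config values here; nothing is downloaded).

Risk/protective orientation comes from this table, never from comparing
frequencies between columns: a few PCSK9/APOE/LDLR rows are reported on
opposite allele orientations in the Portuguese versus gnomAD columns, so
frequency-based inference would silently flip them.
"""

from __future__ import annotations

from .panel import Panel, SnpDefinition

# rsid, gene, group, allele_a, allele_b, effect allele, risk, protective,
# then effect-allele frequencies: mainland, azores, EUR, AFR, AMR, SAS
_PANEL_ROWS = [
    ("rs6025",     "F5",      "VTE", "A", "G", "A", "A", None, 0.028, 0.021, 0.022, 0.004, 0.008, 0.014),
    ("rs1799963",  "F2",      "VTE", "A", "G", "A", "A", None, 0.019, 0.024, 0.013, 0.002, 0.011, 0.002),
    ("rs1801133",  "MTHFR",   "VTE", "C", "T", "T", "T", None, 0.375, 0.326, 0.337, 0.109, 0.478, 0.149),
    ("rs1801131",  "MTHFR",   "VTE", "A", "C", "C", "C", None, 0.309, 0.279, 0.313, 0.163, 0.177, 0.411),
    ("rs12740374", "SORT1",   "AT",  "G", "T", "T", "T", None, 0.208, 0.185, 0.221, 0.249, 0.210, 0.244),
    ("rs3825807",  "ADAMTS7", "AT",  "C", "T", "T", "T", None, 0.574, 0.541, 0.446, 0.152, 0.246, 0.348),
    ("rs11206510", "PCSK9",   "AT",  "C", "T", "T", "T", None, 0.782, 0.821, 0.182, 0.137, 0.110, 0.049),
    ("rs11591147", "PCSK9",   "AT",  "G", "T", "T", None, "T", 0.009, 0.009, 0.017, 0.002, 0.007, 0.001),
    ("rs562556",   "PCSK9",   "AT",  "A", "G", "A", "A", None, 0.880, 0.821, 0.824, 0.790, 0.904, 0.874),
    ("rs505151",   "PCSK9",   "AT",  "A", "G", "G", "G", None, 0.037, 0.035, 0.966, 0.736, 0.967, 0.977),
    ("rs405509",   "APOE",    "AT",  "G", "T", "T", "T", None, 0.644, 0.412, 0.523, 0.747, 0.502, 0.444),
    ("rs429358",   "APOE",    "AT",  "C", "T", "C", "C", None, 0.088, 0.094, 0.151, 0.221, 0.107, 0.101),
    ("rs7412",     "APOE",    "AT",  "C", "T", "C", None, "C", 0.894, 0.915, 0.078, 0.106, 0.035, 0.042),
    ("rs439401",   "APOE",    "AT",  "C", "T", "T", "T", None, 0.264, 0.274, 0.630, 0.853, 0.502, 0.442),
    ("rs2228671",  "LDLR",    "AT",  "C", "T", "T", None, "T", 0.139, 0.097, 0.123, 0.038, 0.072, 0.071),
    ("rs688",      "LDLR",    "AT",  "C", "T", "T", "T", None, 0.157, 0.218, 0.446, 0.102, 0.421, 0.393),
    ("rs1433099",  "LDLR",    "AT",  "C", "T", "T", None, "T", 0.301, 0.291, 0.731, 0.461, 0.788, 0.673),
    ("rs10757274", "9p21",    "AT",  "A", "G", "G", "G", None, 0.389, 0.479, 0.496, 0.217, 0.457, 0.523),
    ("rs1333049",  "9p21",    "AT",  "C", "G", "C", "C", None, 0.421, 0.453, 0.488, 0.239, 0.483, 0.515),
]

_FREQ_COLUMNS = {"mainland": 8, "azores": 9, "EUR": 10, "AFR": 11, "AMR": 12, "SAS": 13}


def default_panel() -> Panel:
    """The built-in 19-SNP AT+VTE panel (fixed order; AT=15, VTE=4 SNPs)."""
    snps = []
    for row in _PANEL_ROWS:
        rsid, gene, group, a, b, _eff, risk, prot = row[:8]
        snps.append(SnpDefinition(
            rsid=rsid, gene=gene, disease_group=group,
            allele_a=a, allele_b=b, risk_allele=risk, protective_allele=prot,
        ))
    return Panel(tuple(snps))


def effect_alleles() -> dict[str, str]:
    """Effect allele per rsid: the allele whose frequency the presets give."""
    return {row[0]: row[5] for row in _PANEL_ROWS}


def allele_frequencies(population: str) -> dict[str, float]:
    """Published effect-allele frequencies for one population.

    ``population`` is one of ``mainland``, ``azores``, ``EUR``, ``AFR``,
    ``AMR``, ``SAS``.
    """
    try:
        col = _FREQ_COLUMNS[population]
    except KeyError:
        raise KeyError(
            f"unknown population {population!r}; choose from {sorted(_FREQ_COLUMNS)}"
        ) from None
    return {row[0]: row[col] for row in _PANEL_ROWS}


# Reconstructed VTE odds-ratio weights. The published per-SNP OR table is
# not reproduced in the article body; these two values are recovered by
# solving the printed VTE profile scores (F5-het + F2-het + MTHFR-het
# profiles score 6.18, F5-only profiles 4.38, MTHFR-only profiles 0.00).
# MTHFR SNPs carry no weight and contribute 0 to the score.
VTE_WEIGHTS: dict[str, float] = {"rs6025": 4.38, "rs1799963": 1.80}


# Gene-level haplotype frequency presets (Azorean cohort totals). Each gene
# maps haplotype strings in panel SNP order to frequencies summing to 1;
# "<0.001" entries are carried as 0.001 / 0 so the vectors close exactly.
AZORES_HAPLOTYPES: dict[str, dict[str, float]] = {
    # (rs1801133, rs1801131)
    "MTHFR": {"CA": 0.765, "CC": 0.094, "TA": 0.141},
    # (rs11206510, rs11591147, rs562556, rs505151)
    "PCSK9": {
        "TGAA": 0.657, "CGAA": 0.134, "TGGA": 0.128, "CGGA": 0.036,
        "TGAG": 0.026, "CTGA": 0.006, "TGGG": 0.006, "CGGG": 0.003,
        "TTAA": 0.003, "CGAG": 0.001,
    },
    # (rs2228671, rs688, rs1433099)
    "LDLR": {
        "CCC": 0.427, "CCT": 0.282, "CTC": 0.187, "TCC": 0.074,
        "TTC": 0.021, "CTT": 0.007, "TTT": 0.002,
    },
    # (rs10757274, rs1333049)
    "9p21": {"AG": 0.502, "GC": 0.434, "GG": 0.045, "AC": 0.019},
}

MAINLAND_HAPLOTYPES: dict[str, dict[str, float]] = {
    "MTHFR": {"CA": 0.787, "CC": 0.102, "TA": 0.111},
    "PCSK9": {
        "TGAA": 0.655, "CGAA": 0.190, "TGGA": 0.091, "TGAG": 0.028,
        "CGGA": 0.018, "TGGG": 0.008, "CTAA": 0.005, "CTGA": 0.004,
        "CGAG": 0.001,
    },
    "LDLR": {
        "CCC": 0.461, "CCT": 0.261, "CTC": 0.119, "TCC": 0.100,
        "CTT": 0.020, "TCT": 0.020, "TTC": 0.019,
    },
    "9p21": {"AG": 0.559, "GC": 0.369, "AC": 0.052, "GG": 0.020},
}
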