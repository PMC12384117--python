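"""Multilocus genetic profiles (MGPs) and weighted genetic risk scores.

An MGP is the combined genotype string of an individual across a fixed
disease sub-panel (AT or VTE), in panel order, one space-separated
canonical genotype per SNP, e.g. ``"GA GG CT AA"``. Distinct strings
define profile classes; for each class we report

* RV  - number of risk alleles over the sub-panel,
* PV  - number of protective alleles (only at SNPs that designate one),
* HoR - number of SNPs homozygous for the risk allele,
* GRS - genetic risk score: sum over SNPs of the risk-allele count times
  the SNP's odds-ratio weight (``or`` mode) or its natural logarithm
  (``log_or`` mode). SNPs without a weight contribute 0 to the GRS but
  still count toward RV/PV/HoR.

Individuals are then classified by empirical percentiles of their score:
the top decile is the high-risk group and the bottom decile the low-risk
group, with ties at a quantile boundary expanded into the extreme group
(configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import (GenotypeTable, MISSING, Panel, SampleRecord,
                    ValidationError)
from .stats import AssociationResult


@dataclass(frozen=True)
class MgProfile:
    """One distinct multilocus genotype string and its risk summary."""

    profile_string: str
    disease_group: str
    rv: int
    pv: int
    hor: int
    grs: float
    carriers: tuple[str, ...]
    relative_frequency: float


@dataclass
class RiskClassification:
    """Percentile-based high/low/intermediate risk labels.

    ``scores`` and ``categories`` are indexed by sample_id; only samples
    with complete sub-panel genotypes are present.
    """

    disease_group: str
    scores: pd.Series
    q_low: float
    q_high: float
    categories: pd.Series
    n_distinct_profiles: int
    ties: str = "expand"
    profile_categories: dict[str, str] = field(default_factory=dict)

    @property
    def n_classified(self) -> int:
        return len(self.scores)

    def counts(self) -> dict[str, int]:
        vc = self.categories.value_counts()
        return {cat: int(vc.get(cat, 0)) for cat in ("high", "intermediate", "low")}


def resolve_weights(snps, weights: dict[str, float] | None) -> dict[str, float]:
    """Effective OR weight per rsid: explicit ``weights`` override the
    panel's ``or_weight``; SNPs with neither are absent from the result."""
    out: dict[str, float] = {}
    for snp in snps:
        if weights is not None and snp.rsid in weights:
            out[snp.rsid] = float(weights[snp.rsid])
        elif snp.or_weight is not None:
            out[snp.rsid] = float(snp.or_weight)
    for w in out.values():
        if not w > 0:
            raise ValidationError("OR weights must be positive")
    return out


def grs(genotype_vector, snps, weights: dict[str, float] | None = None,
        weights_mode: str = "or") -> float:
    """Genetic risk score of one genotype vector over a sub-panel.

    ``genotype_vector`` aligns with ``snps`` (canonical cells). ``or``
    mode: sum of risk-allele count x OR; ``log_or`` mode: sum of
    risk-allele count x ln(OR). Unweighted SNPs contribute 0.
    """
    if weights_mode not in ("or", "log_or"):
        raise ValidationError(f"unknown weights mode {weights_mode!r}")
    eff = resolve_weights(snps, weights)
    total = 0.0
    for snp, cell in zip(snps, genotype_vector):
        w = eff.get(snp.rsid)
        if w is None:
            continue
        c = snp.risk_allele_count(cell)
        total += c * (np.log(w) if weights_mode == "log_or" else w)
    return float(total)


def build_profiles(gt: GenotypeTable, sub_panel: str,
                   weights: dict[str, float] | None = None,
                   weights_mode: str = "or") -> list[MgProfile]:
    """Enumerate distinct multilocus profiles of one disease sub-panel.

    Samples missing any genotype within the sub-panel are excluded from
    profile analysis (they remain usable for per-SNP counts). Profiles
    are returned sorted by descending GRS, then by profile string.
    """
    snps = tuple(gt.panel.sub_panel(sub_panel))
    if not snps:
        raise ValidationError(f"sub-panel {sub_panel!r} is empty")
    rsids = [s.rsid for s in snps]
    sub = gt.genotypes[rsids]
    complete = sub[(sub != MISSING).all(axis=1)]
    if complete.empty:
        raise ValidationError(
            f"no samples with complete {sub_panel} genotypes"
        )
    groups: dict[str, list[str]] = {}
    vectors: dict[str, tuple[str, ...]] = {}
    for sample_id, row in complete.iterrows():
        vec = tuple(row)
        key = " ".join(vec)
        groups.setdefault(key, []).append(sample_id)
        vectors[key] = vec
    n_classified = len(complete)
    profiles = []
    for key, carriers in groups.items():
        vec = vectors[key]
        rv = sum(s.risk_allele_count(c) for s, c in zip(snps, vec))
        pv = sum(s.protective_allele_count(c) for s, c in zip(snps, vec))
        hor = sum(1 for s, c in zip(snps, vec) if s.risk_allele_count(c) == 2)
        profiles.append(MgProfile(
            profile_string=key,
            disease_group=sub_panel,
            rv=rv, pv=pv, hor=hor,
            grs=grs(vec, snps, weights, weights_mode),
            carriers=tuple(carriers),
            relative_frequency=len(carriers) / n_classified,
        ))
    profiles.sort(key=lambda p: (-p.grs, p.profile_string))
    return profiles


def classify(profiles: list[MgProfile], low_q: float = 0.10,
             high_q: float = 0.90, ties: str = "expand") -> RiskClassification:
    """Split classified samples into high/low/intermediate risk by the
    empirical quantiles of their GRS.

    Quantiles use linear interpolation. With ``ties="expand"`` (default)
    scores exactly equal to a boundary quantile join the extreme group;
    ``ties="strict"`` keeps them intermediate. When every score is
    identical no percentile split exists: everyone is intermediate and a
    warning is emitted.
    """
    if ties not in ("expand", "strict"):
        raise ValidationError(f"unknown tie rule {ties!r}")
    if not profiles:
        raise ValidationError("no profiles to classify")
    disease_group = profiles[0].disease_group
    records = {}
    for p in profiles:
        for sid in p.carriers:
            records[sid] = (p.grs, p.profile_string)
    scores = pd.Series({sid: v[0] for sid, v in records.items()}, dtype=float)
    if len(scores) < 10:
        raise ValidationError(
            f"percentile classification needs >= 10 samples, got {len(scores)}"
        )
    q_low = float(np.quantile(scores.to_numpy(), low_q))
    q_high = float(np.quantile(scores.to_numpy(), high_q))
    categories = pd.Series("intermediate", index=scores.index, dtype=object)
    if scores.nunique() == 1:
        warnings.warn("degenerate score distribution: all samples intermediate",
                      stacklevel=2)
    else:
        high = scores > q_high
        low = scores < q_low
        if ties == "expand":
            # when one score value spans both deciles (e.g. a large atom at
            # zero) the tied samples sit at the bottom of the distribution:
            # they join the low group only
            if q_low == q_high:
                low |= scores == q_low
            else:
                high |= scores == q_high
                low |= scores == q_low
        categories[high] = "high"
        categories[low] = "low"
    profile_categories = {}
    for p in profiles:
        cat = categories[p.carriers[0]] if p.carriers else "intermediate"
        profile_categories[p.profile_string] = cat
    return RiskClassification(
        disease_group=disease_group,
        scores=scores,
        q_low=q_low,
        q_high=q_high,
        categories=categories,
        n_distinct_profiles=len(profiles),
        ties=ties,
        profile_categories=profile_categories,
    )


# ---------------------------------------------------------------------------
# Stratified tables
# ---------------------------------------------------------------------------

def _strata(samples: list[SampleRecord]):
    meta = pd.DataFrame({
        "sample_id": [s.sample_id for s in samples],
        "population": [s.population for s in samples],
        "group": [s.geographic_group for s in samples],
        "sex": [s.sex for s in samples],
    }).set_index("sample_id")
    strata = [("total", "Total", meta.index)]
    for pop in meta["population"].unique():
        strata.append(("population", pop, meta.index[meta["population"] == pop]))
    for grp in ("Eastern", "Central", "Western"):
        idx = meta.index[meta["group"] == grp]
        if len(idx):
            strata.append(("geographic_group", grp, idx))
    for sex in ("M", "F"):
        idx = meta.index[meta["sex"] == sex]
        if len(idx):
            strata.append(("sex", sex, idx))
    return meta, strata


def _count_test(table: np.ndarray, alpha: float = 0.05) -> AssociationResult:
    """2 x k comparison of high-risk counts across strata."""
    table = np.asarray(table, dtype=float)
    k = table.shape[1]
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    if k == 2 and not (expected >= 5).all():
        stat, p = sps.fisher_exact(table.astype(int))
        method = "fisher_2x2"
        df = 1
    else:
        stat, p, df, _ = sps.chi2_contingency(table, correction=False)
        method = "chi2_2x2" if k == 2 else "chi2_2xk"
    or_point = ci_low = ci_high = None
    if k == 2 and (table > 0).all():
        a, b = table[:, 0]
        c, d = table[:, 1]
        or_point = float((a * d) / (b * c))
        se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
        ci_low = float(np.exp(np.log(or_point) - 1.959963984540054 * se))
        ci_high = float(np.exp(np.log(or_point) + 1.959963984540054 * se))
    return AssociationResult(method, float(stat), int(df), float(p),
                             or_point, ci_low, ci_high, alpha)


@dataclass
class GroupFrequencyTable:
    """Stratified high/low/intermediate frequencies plus count tests."""

    disease_group: str
    table: pd.DataFrame
    tests: dict[str, AssociationResult]


def group_frequency_table(cls: RiskClassification,
                          samples: list[SampleRecord],
                          alpha: float = 0.05) -> GroupFrequencyTable:
    """Relative frequency of each risk category per stratum.

    Strata: cohort total, each population, each Azorean geographic group,
    each sex. Strata with zero classified samples are reported as absent
    (NaN), never as frequency 0. Also runs a 2 x k test of high-risk
    counts across geographic groups and a 2 x 2 test between sexes when
    those strata exist.
    """
    meta, strata = _strata(samples)
    classified = set(cls.categories.index)
    rows = []
    for kind, name, idx in strata:
        ids = [i for i in idx if i in classified]
        n = len(ids)
        row = {"stratum_type": kind, "stratum": name, "n": n}
        for cat in ("high", "low", "intermediate"):
            if n == 0:
                row[cat] = np.nan
                row[f"n_{cat}"] = 0
            else:
                count = int((cls.categories[ids] == cat).sum())
                row[cat] = count / n
                row[f"n_{cat}"] = count
        rows.append(row)
    table = pd.DataFrame(rows).set_index(["stratum_type", "stratum"])

    tests: dict[str, AssociationResult] = {}
    geo = table.loc[table.index.get_level_values(0) == "geographic_group"]
    if len(geo) >= 2 and geo["n"].gt(0).all():
        counts = np.vstack([
            geo["n_high"].to_numpy(),
            (geo["n"] - geo["n_high"]).to_numpy(),
        ])
        if counts.sum(axis=1).all():
            tests["geographic_group"] = _count_test(counts, alpha)
    sex = table.loc[table.index.get_level_values(0) == "sex"]
    if len(sex) == 2 and sex["n"].gt(0).all():
        counts = np.array([
            [sex["n_high"].iloc[0], sex["n"].iloc[0] - sex["n_high"].iloc[0]],
            [sex["n_high"].iloc[1], sex["n"].iloc[1] - sex["n_high"].iloc[1]],
        ])
        if counts.sum(axis=0).all():
            tests["sex"] = _count_test(counts, alpha)
    return GroupFrequencyTable(cls.disease_group, table, tests)


@dataclass
class CrossRiskResult:
    """Overlap of AT-high and VTE-high classifications on one cohort."""

    table: pd.DataFrame  # 2x2 counts: (AT high vs not) x (VTE high vs not)
    association: AssociationResult
    mean_at_grs_vte_high: float
    mean_at_grs_vte_other: float


def cross_risk_table(at: RiskClassification,
                     vte: RiskClassification,
                     alpha: float = 0.05) -> CrossRiskResult:
    """Test whether AT-high and VTE-high status co-occur.

    Builds the 2x2 table over samples classified in both analyses and
    runs the Fisher exact test (with Woolf OR/CI when estimable); also
    reports the mean AT score inside and outside the VTE-high stratum.
    """
    common = at.categories.index.intersection(vte.categories.index)
    if len(common) == 0:
        raise ValidationError("AT and VTE classifications share no samples")
    at_high = at.categories[common] == "high"
    vte_high = vte.categories[common] == "high"
    counts = np.array([
        [int((at_high & vte_high).sum()), int((at_high & ~vte_high).sum())],
        [int((~at_high & vte_high).sum()), int((~at_high & ~vte_high).sum())],
    ])
    stat, p = sps.fisher_exact(counts)
    or_point = ci_low = ci_high = None
    if (counts > 0).all():
        a, b = counts[0]
        c, d = counts[1]
        or_point = float(a * d / (b * c))
        se = float(np.sqrt((1.0 / counts).sum()))
        ci_low = float(np.exp(np.log(or_point) - 1.959963984540054 * se))
        ci_high = float(np.exp(np.log(or_point) + 1.959963984540054 * se))
    assoc = AssociationResult("fisher_2x2", float(stat), 1, float(p),
                              or_point, ci_low, ci_high, alpha,
                              tuple(map(tuple, counts)))
    table = pd.DataFrame(counts,
                         index=pd.Index(["AT_high", "AT_other"]),
                         columns=pd.Index(["VTE_high", "VTE_other"]))
    at_scores = at.scores[common]
    high_scores = at_scores[vte_high.to_numpy()]
    other_scores = at_scores[~vte_high.to_numpy()]
    return CrossRiskResult(
        table=table,
        association=assoc,
        mean_at_grs_vte_high=float(high_scores.mean()) if len(high_scores) else float("nan"),
        mean_at_grs_vte_other=float(other_scores.mean()) if len(other_scores) else float("nan"),
    )


def weights_from_table(pairs: list[tuple[str, float]], snps,
                       min_count: int = 1) -> dict[str, float]:
    """Recover per-SNP OR weights from (profile string, GRS) pairs.

    Solves the least-squares system  sum_j c_ij * w_j = GRS_i  where c_ij
    is the risk-allele count of profile i at SNP j. SNPs whose risk-allele
    count is zero in every supplied profile are indeterminate and omitted;
    fitted weights indistinguishable from zero are treated as absent.
    """
    snps = tuple(snps)
    design = []
    target = []
    for profile_string, score in pairs:
        cells = profile_string.split()
        if len(cells) != len(snps):
            raise ValidationError(
                f"profile {profile_string!r} has {len(cells)} genotypes for "
                f"{len(snps)} SNPs"
            )
        design.append([s.risk_allele_count("/".join(sorted(c)))
                       for s, c in zip(snps, cells)])
        target.append(score)
    design = np.array(design, dtype=float)
    target = np.array(target, dtype=float)
    informative = (design != 0).sum(axis=0) >= min_count
    if not informative.any():
        raise ValidationError("no SNP has risk alleles in the supplied profiles")
    coef, *_ = np.linalg.lstsq(design[:, informative], target, rcond=None)
    out: dict[str, float] = {}
    for snp, w in zip((s for s, keep in zip(snps, informative) if keep), coef):
        if abs(w) > 1e-9:
            out[snp.rsid] = float(w)
    return out


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

class RiskProfileModel:
    """Multilocus risk-profile analysis of one disease sub-panel.

    Statsmodels-style facade: construct from a genotype table, call
    :meth:`fit` to enumerate profiles and classify individuals, inspect
    the returned :class:`RiskProfileResults`.
    """

    def __init__(self, genotype_table: GenotypeTable, disease_group: str,
                 weights: dict[str, float] | None = None,
                 weights_mode: str = "or"):
        self.data = genotype_table
        self.disease_group = disease_group
        self.weights = weights
        self.weights_mode = weights_mode

    @classmethod
    def from_csv(cls, path, panel: Panel, disease_group: str,
                 weights: dict[str, float] | None = None,
                 weights_mode: str = "or") -> "RiskProfileModel":
        from .panel import read_genotype_table
        return cls(read_genotype_table(path, panel), disease_group,
                   weights, weights_mode)

    def fit(self, low_q: float = 0.10, high_q: float = 0.90,
            ties: str = "expand") -> "RiskProfileResults":
        profiles = build_profiles(self.data, self.disease_group,
                                  self.weights, self.weights_mode)
        classification = classify(profiles, low_q, high_q, ties)
        return RiskProfileResults(self, profiles, classification)


class RiskProfileResults:
    """Fitted profile enumeration + risk classification."""

    def __init__(self, model: RiskProfileModel, profiles: list[MgProfile],
                 classification: RiskClassification):
        self.model = model
        self.profiles = profiles
        self.classification = classification

    @property
    def n_distinct_profiles(self) -> int:
        return len(self.profiles)

    def group_frequency_table(self, alpha: float = 0.05) -> GroupFrequencyTable:
        return group_frequency_table(self.classification,
                                     self.model.data.samples, alpha)

    def summary(self) -> pd.DataFrame:
        """Profile table in the style of published MGP tables."""
        rows = []
        for i, p in enumerate(self.profiles, start=1):
            rows.append({
                "profile_id": f"{p.disease_group}-MGP{i}",
                "profile_string": p.profile_string,
                "RV": p.rv, "PV": p.pv, "HoR": p.hor,
                "GRS": p.grs,
                "n_carriers": len(p.carriers),
                "relative_frequency": p.relative_frequency,
                "category": self.classification.profile_categories[p.profile_string],
            })
        return pd.DataFrame(rows)
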