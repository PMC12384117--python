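"""SNP panel and genotype data model.

A :class:`Panel` is an ordered list of biallelic SNPs, each carrying its
risk/protective allele orientation and an optional odds-ratio weight. The
panel is partitioned into disease sub-panels (atherosclerosis ``AT`` and
venous thromboembolism ``VTE``); the panel order is fixed and defines the
order of multilocus profile strings downstream.

Genotypes are unphased, unordered allele pairs ("A/G"); cells are
canonicalized alphabetically so "G/A" and "A/G" are the same genotype.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = "./."

VALID_BASES = frozenset("ACGT")
POPULATIONS = ("mainland", "azores", "other")
GEO_GROUPS = ("Eastern", "Central", "Western", "none")
SEXES = ("M", "F", "unknown")
DISEASE_GROUPS = ("AT", "VTE")

METADATA_COLUMNS = ("sample_id", "population", "group", "sex")


class ValidationError(ValueError):
    """Raised when a panel, genotype table, or config fails validation."""


def canonical_genotype(cell: str) -> str:
    """Return the alphabetically canonical form of a genotype cell.

    ``"G/A"`` and ``"A/G"`` denote the same unordered genotype; the
    canonical form is ``"A/G"``. The missing token ``"./."`` is preserved.
    """
    if cell == MISSING:
        return MISSING
    parts = cell.split("/")
    if len(parts) != 2:
        raise ValidationError(f"malformed genotype cell {cell!r}")
    return "/".join(sorted(parts))


@dataclass(frozen=True)
class SnpDefinition:
    """One panel SNP: alleles, risk orientation, optional OR weight."""

    rsid: str
    gene: str
    disease_group: str
    allele_a: str
    allele_b: str
    risk_allele: str | None = None
    protective_allele: str | None = None
    or_weight: float | None = None
    panel_index: int = 0

    def __post_init__(self) -> None:
        if self.disease_group not in DISEASE_GROUPS:
            raise ValidationError(
                f"{self.rsid}: disease group must be one of {DISEASE_GROUPS}, "
                f"got {self.disease_group!r}"
            )
        for al in (self.allele_a, self.allele_b):
            if al not in VALID_BASES:
                raise ValidationError(f"{self.rsid}: invalid allele symbol {al!r}")
        if self.allele_a == self.allele_b:
            raise ValidationError(f"{self.rsid}: alleles must differ")
        alleles = {self.allele_a, self.allele_b}
        for name, al in (("risk_allele", self.risk_allele),
                         ("protective_allele", self.protective_allele)):
            if al is not None and al not in alleles:
                raise ValidationError(
                    f"{self.rsid}: {name} {al!r} not in alleles {sorted(alleles)}"
                )
        if (self.risk_allele is not None and self.protective_allele is not None
                and self.risk_allele == self.protective_allele):
            raise ValidationError(
                f"{self.rsid}: risk and protective allele cannot both be "
                f"{self.risk_allele!r}"
            )
        if self.or_weight is not None and not self.or_weight > 0:
            raise ValidationError(f"{self.rsid}: or_weight must be > 0")

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.allele_a, self.allele_b))

    def risk_allele_count(self, genotype: str) -> int:
        """Number of risk alleles (0, 1 or 2) in a canonical genotype cell."""
        if self.risk_allele is None or genotype == MISSING:
            return 0
        return genotype.split("/").count(self.risk_allele)

    def protective_allele_count(self, genotype: str) -> int:
        if self.protective_allele is None or genotype == MISSING:
            return 0
        return genotype.split("/").count(self.protective_allele)


@dataclass(frozen=True)
class Panel:
    """Ordered SNP panel with AT/VTE sub-panels.

    Order equals the config file row order and is what fixes the layout of
    multilocus profile strings, so it must be stable across runs.
    """

    snps: tuple[SnpDefinition, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for snp in self.snps:
            if snp.rsid in seen:
                raise ValidationError(f"duplicate rsid in panel: {snp.rsid}")
            seen.add(snp.rsid)
        # freeze positional indices to row order
        object.__setattr__(
            self, "snps",
            tuple(replace(s, panel_index=i) for i, s in enumerate(self.snps)),
        )

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)

    def __contains__(self, rsid: str) -> bool:
        return any(s.rsid == rsid for s in self.snps)

    def __getitem__(self, rsid: str) -> SnpDefinition:
        for snp in self.snps:
            if snp.rsid == rsid:
                return snp
        raise KeyError(rsid)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(s.rsid for s in self.snps)

    def sub_panel(self, disease_group: str) -> "Panel":
        """Sub-panel (same relative order) for one disease group."""
        if disease_group not in DISEASE_GROUPS:
            raise ValidationError(f"unknown disease group {disease_group!r}")
        return Panel(tuple(s for s in self.snps if s.disease_group == disease_group))

    def genes(self) -> tuple[str, ...]:
        out: list[str] = []
        for s in self.snps:
            if s.gene not in out:
                out.append(s.gene)
        return tuple(out)

    def gene_snps(self, gene: str) -> tuple[SnpDefinition, ...]:
        snps = tuple(s for s in self.snps if s.gene == gene)
        if not snps:
            raise KeyError(gene)
        return snps


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata: population, Azorean geographic group, sex."""

    sample_id: str
    population: str = "other"
    geographic_group: str = "none"
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValidationError(
                f"{self.sample_id}: population must be one of {POPULATIONS}"
            )
        if self.geographic_group not in GEO_GROUPS:
            raise ValidationError(
                f"{self.sample_id}: geographic group must be one of {GEO_GROUPS}"
            )
        if self.geographic_group != "none" and self.population != "azores":
            raise ValidationError(
                f"{self.sample_id}: geographic group is only defined for the "
                "Azorean population"
            )
        if self.sex not in SEXES:
            raise ValidationError(f"{self.sample_id}: sex must be one of {SEXES}")


@dataclass
class GenotypeTable:
    """Samples x panel matrix of unordered genotype calls plus metadata.

    ``genotypes`` is indexed by sample_id with one column per panel rsid;
    cells hold canonical genotype strings ("A/G") or the missing token.
    """

    panel: Panel
    samples: list[SampleRecord]
    genotypes: pd.DataFrame

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample_id in genotype table")
        if list(self.genotypes.index) != ids:
            raise ValidationError("genotype matrix rows do not match sample list")
        if list(self.genotypes.columns) != list(self.panel.rsids):
            raise ValidationError("genotype matrix columns do not match panel")
        for snp in self.panel:
            col = self.genotypes[snp.rsid]
            for sample_id, cell in col.items():
                if cell == MISSING:
                    continue
                canon = canonical_genotype(cell)
                if canon != cell:
                    self.genotypes.loc[sample_id, snp.rsid] = canon
                    cell = canon
                if not set(cell.split("/")) <= snp.alleles:
                    raise ValidationError(
                        f"sample {sample_id}, {snp.rsid}: genotype {cell!r} uses "
                        f"alleles outside {{{snp.allele_a},{snp.allele_b}}}"
                    )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "population": [s.population for s in self.samples],
                "group": [s.geographic_group for s in self.samples],
                "sex": [s.sex for s in self.samples],
            }
        ).set_index("sample_id")

    def genotype(self, sample_id: str, rsid: str) -> str:
        return self.genotypes.at[sample_id, rsid]

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeTable":
        keep = set(sample_ids)
        samples = [s for s in self.samples if s.sample_id in keep]
        gts = self.genotypes.loc[[s.sample_id for s in samples]]
        return GenotypeTable(self.panel, samples, gts.copy())

    def to_frame(self) -> pd.DataFrame:
        """Flat frame (metadata columns + one column per rsid) for CSV I/O."""
        meta = self.metadata().reset_index()
        gts = self.genotypes.reset_index(drop=True)
        return pd.concat([meta, gts], axis=1)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_PANEL_COLUMNS = ("rsid", "gene", "group", "allele_a", "allele_b",
                  "risk_allele", "protective_allele", "or_weight")


def _snp_from_record(rec: Mapping[str, object]) -> SnpDefinition:
    def opt(key: str) -> str | None:
        val = rec.get(key)
        if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
            return None
        return str(val)

    weight = rec.get("or_weight")
    if weight is None or weight == "" or (isinstance(weight, float) and np.isnan(weight)):
        or_weight = None
    else:
        or_weight = float(weight)
    return SnpDefinition(
        rsid=str(rec["rsid"]),
        gene=str(rec["gene"]),
        disease_group=str(rec["group"]),
        allele_a=str(rec["allele_a"]),
        allele_b=str(rec["allele_b"]),
        risk_allele=opt("risk_allele"),
        protective_allele=opt("protective_allele"),
        or_weight=or_weight,
    )


def load_panel(path: str | Path) -> Panel:
    """Read a panel config (TSV with header, or JSON list of records).

    Required columns: rsid, gene, group, allele_a, allele_b; optional:
    risk_allele, protective_allele, or_weight (empty cell = absent). Row
    order is preserved and becomes the panel order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"panel config not found: {path}")
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise ValidationError(f"{path}: JSON panel must be a list of records")
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        missing = {"rsid", "gene", "group", "allele_a", "allele_b"} - set(df.columns)
        if missing:
            raise ValidationError(f"{path}: missing panel columns {sorted(missing)}")
        records = df.to_dict(orient="records")
    return Panel(tuple(_snp_from_record(rec) for rec in records))


def write_panel(panel: Panel, path: str | Path) -> None:
    rows = []
    for s in panel:
        rows.append({
            "rsid": s.rsid, "gene": s.gene, "group": s.disease_group,
            "allele_a": s.allele_a, "allele_b": s.allele_b,
            "risk_allele": s.risk_allele or "",
            "protective_allele": s.protective_allele or "",
            "or_weight": "" if s.or_weight is None else s.or_weight,
        })
    pd.DataFrame(rows, columns=list(_PANEL_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_genotype_table(path: str | Path, panel: Panel) -> GenotypeTable:
    """Read a genotype CSV (metadata columns then one column per rsid)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"genotype table not found: {path}")
    df = pd.read_csv(path, dtype=str, comment="#")
    missing_meta = set(METADATA_COLUMNS) - set(df.columns)
    if missing_meta:
        raise ValidationError(f"{path}: missing metadata columns {sorted(missing_meta)}")
    missing_rsids = set(panel.rsids) - set(df.columns)
    if missing_rsids:
        raise ValidationError(f"{path}: missing rsid columns {sorted(missing_rsids)}")
    samples = [
        SampleRecord(
            sample_id=str(row["sample_id"]),
            population=str(row["population"]),
            geographic_group=str(row["group"]),
            sex=str(row["sex"]),
        )
        for _, row in df.iterrows()
    ]
    gts = df[list(panel.rsids)].copy()
    gts.index = pd.Index([s.sample_id for s in samples])
    gts = gts.fillna(MISSING)
    return GenotypeTable(panel, samples, gts)


def write_genotype_table(gt: GenotypeTable, path: str | Path,
                         header_comment: str | None = None) -> None:
    """Write a genotype CSV readable by :func:`read_genotype_table`."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        gt.to_frame().to_csv(fh, index=False)


def read_vcf(path: str | Path, panel: Panel) -> GenotypeTable:
    """Build a GenotypeTable from a VCF, keyed on rsID.

    Records whose ID is not in the panel are ignored; panel SNPs absent
    from the VCF are missing for all samples. REF/ALT must match the panel
    alleles (as a set) at each matched record.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    data: dict[str, list[str]] = {
        rsid: [MISSING] * len(sample_ids) for rsid in panel.rsids
    }
    for variant in vcf:
        rsid = variant.ID
        if rsid is None or rsid not in panel:
            continue
        snp = panel[rsid]
        alts = [a for a in variant.ALT if a != "."]
        if len(alts) > 1:
            raise ValidationError(f"{rsid}: multi-allelic records are not supported")
        symbols = [variant.REF] + alts
        if not set(symbols) <= snp.alleles:
            raise ValidationError(
                f"{rsid}: VCF REF/ALT {symbols} incompatible with panel alleles "
                f"{{{snp.allele_a},{snp.allele_b}}}"
            )
        for i, call in enumerate(variant.genotypes):
            a1, a2 = call[0], call[1]
            if a1 < 0 or a2 < 0:
                continue
            pair = sorted((symbols[a1], symbols[a2]))
            data[rsid][i] = "/".join(pair)
    vcf.close()
    samples = [SampleRecord(sample_id=sid) for sid in sample_ids]
    gts = pd.DataFrame(data, index=pd.Index(sample_ids), columns=list(panel.rsids))
    return GenotypeTable(panel, samples, gts)
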