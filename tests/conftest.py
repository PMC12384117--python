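import pandas as pd
import pytest

from riskprofiler import (GenotypeTable, Panel, SampleRecord, default_panel)
from riskprofiler.panel import MISSING


@pytest.fixture(scope="session")
def panel() -> Panel:
    return default_panel()


def build_table(panel: Panel, genotypes: dict[str, dict[str, str]],
                meta: dict[str, dict] | None = None) -> GenotypeTable:
    """Assemble a GenotypeTable from {sample_id: {rsid: 'A/G', ...}}.

    SNPs not mentioned for a sample are missing. ``meta`` optionally maps
    sample_id -> SampleRecord keyword overrides.
    """
    meta = meta or {}
    samples = [SampleRecord(sample_id=sid, **meta.get(sid, {}))
               for sid in genotypes]
    data = {
        rsid: [genotypes[sid].get(rsid, MISSING) for sid in genotypes]
        for rsid in panel.rsids
    }
    gts = pd.DataFrame(data, index=pd.Index(list(genotypes)),
                       columns=list(panel.rsids))
    return GenotypeTable(panel, samples, gts)


@pytest.fixture(scope="session")
def vte_snps(panel):
    return tuple(panel.sub_panel("VTE"))
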