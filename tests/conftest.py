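import pytest

from maldiplex import MassTable, default_panel
from maldiplex.panel import Assay


@pytest.fixture(scope="session")
def mass_table() -> MassTable:
    return MassTable.default()


@pytest.fixture(scope="session")
def panel():
    return default_panel()


def make_assay(assay_id: str, primer: str, wt: str = "A", muts=None, **kw) -> Assay:
    """Minimal valid assay for mass/pooling tests."""
    return Assay(
        assay_id=assay_id,
        gene=kw.pop("gene", "GENE"),
        aa_label=kw.pop("aa_label", "X1"),
        primer_seq=primer,
        wt_base=wt,
        mut_alleles=muts or {"T": "X1Y"},
        **kw,
    )
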