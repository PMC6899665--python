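import pandas as pd
import pytest

from dietmerge import (
    Detection,
    ESVTable,
    Lineage,
    TaxonLabel,
    parse_lineage,
)


def lin(text: str) -> Lineage:
    return parse_lineage(text)


def det(sample: str, marker: str, lineage: str, motu=None) -> Detection:
    return Detection(
        sample=sample, marker=marker,
        taxon=TaxonLabel(lineage=lin(lineage), motu=motu),
    )


@pytest.fixture
def coleoptera():
    return lin("Animalia;Arthropoda;Insecta;Coleoptera")


@pytest.fixture
def carabidae():
    return lin("Animalia;Arthropoda;Insecta;Coleoptera;Carabidae")


@pytest.fixture
def chrysomelidae():
    return lin("Animalia;Arthropoda;Insecta;Coleoptera;Chrysomelidae")


@pytest.fixture
def chrysomelid_species():
    return lin(
        "Animalia;Arthropoda;Insecta;Coleoptera;Chrysomelidae;"
        "Chrysomela;Chrysomela populi"
    )


def make_table(marker: str, seqs: dict, counts: dict) -> ESVTable:
    """counts: esv -> {pcr: reads}; missing cells are zero."""
    pcrs = sorted({p for row in counts.values() for p in row})
    frame = pd.DataFrame(0, index=list(seqs), columns=pcrs, dtype=int)
    for esv, row in counts.items():
        for p, n in row.items():
            frame.loc[esv, p] = n
    return ESVTable(marker=marker, sequences=seqs, counts=frame)
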