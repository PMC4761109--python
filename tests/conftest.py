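import pytest

from unicity import (
    DigestSpec,
    Feature,
    FeatureKind,
    ProteinEntry,
    Proteome,
)


@pytest.fixture
def two_entry_proteome() -> Proteome:
    """Two entries on different genes sharing the tryptic peptide CCR."""
    return Proteome(
        entries=[
            ProteinEntry(accession="P1", canonical_seq="AAKCCR", gene_symbol="G1"),
            ProteinEntry(accession="P2", canonical_seq="DDKCCR", gene_symbol="G2"),
        ]
    )


@pytest.fixture
def loose_spec() -> DigestSpec:
    """Digestion spec without a meaningful length filter."""
    return DigestSpec(enzyme="trypsin", max_missed=0, min_len=1, max_len=45)


@pytest.fixture
def mkaar_entry() -> ProteinEntry:
    """Canonical MKAAR with a chain and a variant, for form enumeration."""
    return ProteinEntry(
        accession="P00001",
        canonical_seq="MKAAR",
        features=[
            Feature(FeatureKind.CHAIN, "canonical", 3, 5),
            Feature(FeatureKind.VARIANT, "canonical", 4, 4, "A>V"),
        ],
    )
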