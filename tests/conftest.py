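import pytest

from mitocodon.genome_io import GeneFeature, MitogenomeRecord
from mitocodon.synthetic import SyntheticSpec, build_synthetic_mitogenome


@pytest.fixture(scope="session")
def default_record():
    """One deterministic synthetic mitogenome with canonical gene order."""
    return build_synthetic_mitogenome(SyntheticSpec(seed=7), accession="SYNFIX01")


@pytest.fixture(scope="session")
def rearranged_record():
    """Synthetic genome carrying the extra OH_1 origin between trnE and cob."""
    return build_synthetic_mitogenome(
        SyntheticSpec(seed=8, extra_oh=True), accession="SYNFIX02"
    )


def make_record(sequence, features, accession="TOY"):
    return MitogenomeRecord(
        accession=accession, organism="toy", sequence=sequence,
        features=[GeneFeature(*f) if isinstance(f, tuple) else f for f in features],
    )


@pytest.fixture
def toy_record():
    """Tiny hand-built record for coordinate-level assertions."""
    return make_record(
        "ATGCCCGGGTTT",
        [
            GeneFeature("geneA", "PCG", "H", [(0, 6)]),
            GeneFeature("geneB", "tRNA", "L", [(6, 12)]),
        ],
    )
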