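import numpy as np
import pytest

from mutacc.genome_model import CodingInterval, GenomeModel
from mutacc.synthetic_data import ToyGenomeSpec, make_toy_genome


@pytest.fixture(scope="session")
def uniform_model() -> GenomeModel:
    """1 kb genome of 'ACGT' repeats: equal composition, symmetric replichores,
    two macrodomains, one forward gene and one reverse gene."""
    return GenomeModel(
        sequence="ACGT" * 250,
        ori_position=1,
        ter_position=501,
        macrodomains=[("MD1", 1, 501), ("MD2", 501, 1001)],
        coding_intervals=[
            CodingInterval(101, 201, 1, "geneF"),   # 100 bp, fwd (not codon-aligned on purpose elsewhere)
            CodingInterval(301, 400, -1, "geneR"),  # 99 bp, rev
        ],
    )


@pytest.fixture(scope="session")
def toy_bundle(tmp_path_factory):
    """A 10 kb generated genome bundle (FASTA + GFF3 + geometry) round-tripped
    through the file readers."""
    out = tmp_path_factory.mktemp("toy_genome")
    model, paths = make_toy_genome(
        ToyGenomeSpec(length=10_000, coding_fraction=0.5), seed=11, out_dir=out
    )
    return model, paths


@pytest.fixture(scope="session")
def midsize_model() -> GenomeModel:
    """200 kb random genome with asymmetric replichores (0.45/0.55) and four
    macrodomains; fast enough for simulation-heavy tests."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=200_000))
    return GenomeModel(
        sequence=seq,
        ori_position=1,
        ter_position=90_001,
        macrodomains=[
            ("Ori", 1, 50_001),
            ("Right", 50_001, 100_001),
            ("Ter", 100_001, 150_001),
            ("Left", 150_001, 200_001),
        ],
    )
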