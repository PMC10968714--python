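import numpy as np
import pytest

from tsrnakit.reference import TRNAGeneRecord, build_reference
from tsrnakit.simulate import SimulationConfig, make_reference, make_signatures

# the 35-nt 5' half fragment of tRNA-His-GTG reported in colorectal tissue
HIS_5P_HALF = "GCCGTGATCGTATAGTGGTTAGTACTCTGCGTTGT"


def _dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def his_bundle():
    """Two His-GTG isodecoders whose mature forms both contain the 35-nt
    5' half at positions 2-36 and share their last 20 genomic bases, plus
    one unrelated Gly gene.  His gene bodies are 72 nt, so the matures
    are 76 nt (1 for G-1 + 72 + 3 for CCA)."""
    rng = np.random.default_rng(20240901)
    tail = _dna(rng, 20)
    mid_a = _dna(rng, 17)
    mid_b = _dna(rng, 17)
    while mid_b == mid_a:
        mid_b = _dna(rng, 17)
    his_a = HIS_5P_HALF + mid_a + tail  # 35 + 17 + 20 = 72 nt
    his_b = HIS_5P_HALF + mid_b + tail
    gly = _dna(rng, 73)

    genes = [
        TRNAGeneRecord(
            gene_id="His-GTG-1-1", isotype="His", anticodon="GTG", family_index=1,
            chromosome="chr1", strand="+", genomic_start=1000, genomic_end=1071,
            gene_sequence=his_a,
            leader_seq=_dna(rng, 50), trailer_seq=_dna(rng, 35),
        ),
        TRNAGeneRecord(
            gene_id="His-GTG-1-2", isotype="His", anticodon="GTG", family_index=1,
            chromosome="chr1", strand="+", genomic_start=5000, genomic_end=5071,
            gene_sequence=his_b,
            leader_seq=_dna(rng, 50), trailer_seq=_dna(rng, 35),
        ),
        TRNAGeneRecord(
            gene_id="Gly-GCC-1-3", isotype="Gly", anticodon="GCC", family_index=1,
            chromosome="chr16", strand="+", genomic_start=9000, genomic_end=9072,
            gene_sequence=gly,
            leader_seq=_dna(rng, 50), trailer_seq=_dna(rng, 35),
        ),
    ]
    return build_reference(genes)


@pytest.fixture(scope="session")
def sim_setup():
    """A seeded synthetic reference plus engineered signature catalog."""
    config = SimulationConfig(seed=11)
    genes, bundle = make_reference(config)
    catalog = make_signatures(config, bundle)
    return config, bundle, catalog
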