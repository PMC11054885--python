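import numpy as np
import pytest

from miredit.io import FastqRead, MatureAnnotation
from miredit.reference import HairpinReference
from miredit.simulate import SimConfig, generate_reference


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(n_hairpins=12, reads_per_mature=120.0, rng_seed=11)


@pytest.fixture(scope="session")
def ref(sim_config):
    return generate_reference(sim_config)


@pytest.fixture
def tiny_ref():
    """Two hand-built hairpins with one mature arm each."""
    seqs = {
        "hpA": "GGCATTCAGGACTTACGGTCAAGCTGATCCGTACGATGCAGTCCTGAATGCCAAGTGGTC",
        "hpB": "TTGACCGTAAGTCCTGAATGCACGTAGGCTCAATCGGATCAGCTTGACCATAGCTTAACG",
    }
    anns = [
        MatureAnnotation("hpA", "mirA-5p", 3, 24),
        MatureAnnotation("hpB", "mirB-3p", 30, 51),
    ]
    return HairpinReference(seqs, anns)


def make_read(rid, seq, q=40):
    quals = [q] * len(seq) if isinstance(q, int) else list(q)
    return FastqRead(rid, seq, quals)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
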