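import numpy as np
import pytest

from mirtail.refs import MiRNARef, MotifConfig, build_motif
from mirtail.simulate import preset_params, simulate_library, simulate_references

LET7A = "UGAGGUAGUAGGUUGUAUAGUU"  # 22 nt


def make_ref(mirna_id="let-7a-5p", mature=LET7A, flank3="GGACAGCU",
             config=MotifConfig()):
    motif, offset = build_motif(mature, config)
    return MiRNARef(mirna_id=mirna_id, arm="5p", mature_seq=mature,
                    flank3=flank3, motif=motif, motif_offset=offset)


@pytest.fixture
def toy_ref():
    return make_ref()


@pytest.fixture(scope="session")
def sim_refs():
    return simulate_references(8, seed=11)


@pytest.fixture(scope="session")
def small_library(sim_refs):
    """A 5000-read wild-type-like library with its ground truth."""
    params = preset_params("WT", n_reads=5000, seed=7)
    records, truth = simulate_library(sim_refs, params, "WT")
    return params, records, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
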