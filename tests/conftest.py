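import numpy as np
import pytest

from countseg import synthetic as syn
from countseg.io_binning import BinnedGenome
from countseg.segmentation import path_to_segments


@pytest.fixture(scope="session")
def nb_model():
    return syn.default_model(K=3, D=2, family="negbinom")


@pytest.fixture(scope="session")
def small_genome():
    return BinnedGenome(("chr1", "chr2"), (1500 * 200, 1000 * 200), 200)


@pytest.fixture(scope="session")
def simulated(nb_model, small_genome):
    """A medium simulation shared by segmentation/evaluation/enrichment tests."""
    mats, truth = syn.simulate_hmm_counts(nb_model, small_genome, seed=7)
    annotation = path_to_segments(truth.path, small_genome)
    return {"counts": mats["cell0"], "truth": truth, "annotation": annotation}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
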