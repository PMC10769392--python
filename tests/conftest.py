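import numpy as np
import pytest

from seqens import simulate
from seqens.types import GenomicWindow, PWMMotif


@pytest.fixture(scope="session")
def small_model():
    """A compact ground truth: 2 tracks, 4 motifs, 1 kb windows."""
    return simulate.make_ground_truth(
        n_tracks=2, n_motifs=4, motif_length=6, seed=7,
        receptive_field=512, decay_scale=150.0, bin_width=128)


@pytest.fixture(scope="session")
def small_ensemble(small_model):
    return simulate.make_replicate_ensemble(
        small_model, m=5, sigma=0.5, seeds=[101, 102, 103, 104, 105],
        n_spurious=1, n_shared_spurious=1)


@pytest.fixture(scope="session")
def small_windows(small_model):
    windows, sites = simulate.simulate_regulatory_genome(
        n_windows=6, length=1024, gc=0.41, motif_density=1.5, seed=11,
        motif_library=small_model.motifs, bin_width=128)
    return windows, sites


@pytest.fixture
def toy_window():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), size=512))
    return GenomicWindow(chrom="toy", start=0, sequence=seq, anchor=256)


class ConstantPredictor:
    """Mock predictor: the same rates for every input."""

    def __init__(self, values):
        self.values = np.asarray(values, dtype=float)

    def predict(self, window, track=None):
        return self.values.copy()


@pytest.fixture
def one_hot_motif():
    mat = np.zeros((4, 4))
    for i, base in enumerate("ACGT"):
        mat[i, "ACGT".index(base)] = 1.0
    return PWMMotif(motif_id="onehot_ACGT", matrix=mat)
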