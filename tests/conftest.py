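import numpy as np
import pytest

from idpchar import parse_sequence
from idpchar.ensembles import BasinMixture, fjc_ensemble, sample_ensemble

#: The 33-residue disordered N-terminal region of the bacterial magnesium
#: transporter MgtA, the package's reference peptide.
KEIF = "MFKEIFTRLIRHLPSRLVHRDPLPGAQQTVNTV"


@pytest.fixture(scope="session")
def keif():
    return parse_sequence(KEIF, name="KEIF")


@pytest.fixture(scope="session")
def small_ensemble(keif):
    """A 60-frame disordered ensemble shared across read-only tests."""
    return sample_ensemble(keif, n_frames=60, seed=11)


@pytest.fixture(scope="session")
def helix_ppii_ensemble(keif):
    """300 frames of an equal helix/PPII mixture."""
    mixture = BasinMixture(weights={"helix": 0.5, "ppii": 0.5})
    return sample_ensemble(keif, mixture, n_frames=300, seed=21)


@pytest.fixture(scope="session")
def fjc_toy():
    return fjc_ensemble(10, n_frames=8, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
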