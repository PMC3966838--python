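import numpy as np
import pytest

from qsfr.network import build_network, detect_hbonds
from qsfr.synthetic import PeptideEnsembleSpec, make_peptide_ensemble


@pytest.fixture(scope="session")
def helix12():
    """Single unperturbed 12-residue ideal helix frame (with bonds)."""
    ens = make_peptide_ensemble(PeptideEnsembleSpec(12, "helix", 1))
    frame = ens.frame(0)
    frame.bonds = ens.frames.bonds
    return frame, ens


@pytest.fixture(scope="session")
def helix12_network(helix12):
    frame, _ = helix12
    hbonds = detect_hbonds(frame)
    return build_network(frame, hbonds), hbonds


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240326)
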