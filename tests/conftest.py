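import numpy as np
import pytest

from rotordyn.hop_analysis import analyze_ensemble
from rotordyn.synthetic_data import generate, get_preset


@pytest.fixture(scope="session")
def small_rh_ensemble():
    """A 40-trajectory fast-rotor ensemble shared across read-only tests."""
    ensemble, ledger = generate(get_preset("rh_like", n_traj=40, seed=11))
    return ensemble, ledger


@pytest.fixture(scope="session")
def small_rh_records(small_rh_ensemble):
    ensemble, ledger = small_rh_ensemble
    records, undecayed = analyze_ensemble(ensemble)
    return records, undecayed, ledger


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
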