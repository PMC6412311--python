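import numpy as np
import pytest

from rpistack import SaeConfig, SimConfig, simulate
from rpistack.io_formats import RawPssm
from rpistack.protein_features import Pssm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_row_stochastic(rng, r):
    """Random r x 20 row-stochastic matrix (Dirichlet rows)."""
    return rng.dirichlet(np.ones(20), size=r)


def random_raw_pssm(rng, r, protein_id="p"):
    """Random integer PSSM whose percentage rows sum to <= 100."""
    probs = rng.dirichlet(np.ones(20), size=r)
    percentages = np.floor(100 * probs).astype(np.int64)
    log_odds = rng.integers(-8, 12, size=(r, 20))
    residues = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=r))
    return RawPssm(
        protein_id=protein_id,
        log_odds=log_odds,
        percentages=percentages,
        residue_column=residues,
    )


@pytest.fixture
def pssm_factory(rng):
    def make(r, protein_id="p"):
        return Pssm(protein_id=protein_id, P=random_row_stochastic(rng, r))

    return make


@pytest.fixture
def raw_pssm_factory(rng):
    def make(r, protein_id="p"):
        return random_raw_pssm(rng, r, protein_id)

    return make


@pytest.fixture
def fast_sae_config():
    """Small auto-encoder for mechanics tests (not the study conditions)."""
    return SaeConfig(
        layer_sizes=(16, 8), epochs=8, batch_size=64, dropout_rate=0.5, seed=7
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Session-shared small planted-signal dataset for pipeline tests."""
    cfg = SimConfig(n_proteins=12, n_rnas=40, n_pairs=120, seed=11)
    return simulate(cfg)
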