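import numpy as np
import pytest

from amyloidvs import BindingParams, SynthSpec, synth_ligand_db, synth_titration
from amyloidvs.synthetic_data import default_truth_params


@pytest.fixture(scope="session")
def truth_params() -> BindingParams:
    return default_truth_params()


@pytest.fixture(scope="session")
def noiseless_titration(truth_params):
    return synth_titration(truth_params, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def fbh_table(tmp_path_factory):
    """388-ligand all-FBH affinity table with 27 limiting entries, as CSV."""
    spec = SynthSpec(seed=11, n_ligands=388, limiting_fraction=27 / 388,
                     competition_fraction=1.0, reference_competitor_fraction=1.0)
    path = tmp_path_factory.mktemp("fixtures") / "fbh.csv"
    synth_ligand_db(spec, path)
    return path


@pytest.fixture(scope="session")
def small_ligand_table(tmp_path_factory):
    """Small mixed-assay table exercising units, limits and competitors."""
    spec = SynthSpec(seed=5, n_ligands=40, limiting_fraction=0.1,
                     duplicate_fraction=0.1, competition_fraction=0.6,
                     reference_competitor_fraction=0.8)
    path = tmp_path_factory.mktemp("fixtures") / "small.csv"
    synth_ligand_db(spec, path)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
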