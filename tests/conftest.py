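import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("ci")

from maldiderep.pipeline import RunConfig, build_features
from maldiderep.synthetic import SynthConfig, generate_collection


@pytest.fixture(scope="session")
def small_collection():
    """5 cultures x 4 bio x 3 tech at default (low-noise) settings."""
    cfg = SynthConfig(n_cultures=5, seed=11)
    spectra, records, truth = generate_collection(cfg)
    return spectra, records, truth


@pytest.fixture(scope="session")
def small_features(small_collection):
    """QC-filtered feature matrix of the 5-culture collection."""
    spectra, records, truth = small_collection
    matrix, report = build_features(spectra, records, RunConfig())
    return matrix, records, truth


def make_pair_table(n_intra, n_inter, intra_lo, intra_hi, inter_lo, inter_hi, seed):
    """Pair table with intra CS uniform in [intra_lo, intra_hi] and inter
    CS uniform in [inter_lo, inter_hi]."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_intra):
        rows.append(
            {"sample_a": f"i{i}", "sample_b": f"j{i}",
             "cs": rng.uniform(intra_lo, intra_hi), "relation": "intra"}
        )
    for i in range(n_inter):
        rows.append(
            {"sample_a": f"p{i}", "sample_b": f"q{i}",
             "cs": rng.uniform(inter_lo, inter_hi), "relation": "inter"}
        )
    return pd.DataFrame(rows)
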