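import warnings

import numpy as np
import pytest

import serptools as st


@pytest.fixture(scope="session")
def small_config():
    return st.SimulationConfig(
        seed=7, n_target_genes=6, n_background_genes=14, n_transposon_genes=1,
        gene_length_range=(150, 250),
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return st.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_analysis(small_config, small_dataset):
    ds = small_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return st.analyze_experiment(
            ds.annotation, ds.tracks, small_config.bait,
            truth_ids=ds.truth_set, negative_ids=ds.negative_set,
        )


@pytest.fixture(scope="session")
def disk_experiment(tmp_path_factory, small_config):
    outdir = tmp_path_factory.mktemp("synthetic") / "dataset"
    st.simulate_experiment(small_config, outdir)
    return outdir


def make_profile(values, exon_mask=None, **kwargs):
    values = np.asarray(values, dtype=float)
    if exon_mask is None:
        exon_mask = np.ones(values.size, dtype=bool)
    defaults = dict(gene_id="g", condition="ip", bait="bait", replicate=1)
    defaults.update(kwargs)
    return st.GeneProfile(values=values, exon_mask=np.asarray(exon_mask, bool),
                          **defaults)


@pytest.fixture
def profile_factory():
    return make_profile
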