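import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from ptmnet.mlp import TrainConfig
from ptmnet.model import PTMSiteModel
from ptmnet.scales import FeatureEncoder
from ptmnet.synthetic import default_kinase_motif, generate_dataset
from ptmnet.training import SplitSpec


@pytest.fixture(scope="session")
def encoder():
    """The canonical 90-dimensional encoder (ten bundled scales, min-max)."""
    return FeatureEncoder()


@pytest.fixture(scope="session")
def strong_dataset():
    """A cleanly separable motif dataset (pure consensus positives)."""
    return generate_dataset(default_kinase_motif(1.0), n_pos=40, neg_per_pos=5, seed=7)


@pytest.fixture(scope="session")
def trained_model_dir(tmp_path_factory, encoder):
    """A small but genuinely trained model directory for predictor tests.

    Returns (directory, ptm_type).
    """
    ds = generate_dataset(
        default_kinase_motif(1.0), n_pos=30, neg_per_pos=5, seed=5, ptm_type="demo/kinase"
    )
    model = PTMSiteModel(ds, encoder=encoder, split_spec=SplitSpec(n_splits=1, seed=5))
    results = model.fit(config=TrainConfig(epochs=15, seed=5), h_values=[2])
    d = tmp_path_factory.mktemp("models")
    results.save(d)
    return d, ds.ptm_type
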