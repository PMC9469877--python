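import numpy as np
import pytest

from semnet import dbn, evaluation, preprocessing, semantics, synthetic
from semnet.rbm import RBMParams


def random_tiny_rbm(rng, n_visible=4, n_hidden=3, scale=1.0, visible_type="binary"):
    """A small random RBM for enumeration-based oracles."""
    return RBMParams(
        weights=rng.normal(0.0, scale, size=(n_hidden, n_visible)),
        visible_bias=rng.normal(0.0, scale, size=n_visible),
        hidden_bias=rng.normal(0.0, scale, size=n_hidden),
        visible_type=visible_type,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def benchmark_config(seed: int) -> dbn.TrainConfig:
    """Desk-scale stack used by the synthetic benchmark tests."""
    return dbn.TrainConfig(layer_sizes=(64, 32), epochs=30, seed=seed)


@pytest.fixture(scope="session")
def loso_benchmark():
    """LOSO accuracies of the statistical baseline vs. the combined feature
    set (statistical + DBN readout) on the default synthetic benchmark, over
    five generator seeds.  Computed once per session; shared by the protocol
    and acceptance tests."""
    results = []
    for seed in range(1, 6):
        spec = synthetic.SyntheticSpec(seed=seed)
        windows, _ = synthetic.generate_dataset(spec, np.random.default_rng(seed))
        stat = evaluation.loso_evaluate(
            windows, evaluation.statistical_feature_fn(), feature_set="statistical"
        )
        combined = evaluation.loso_evaluate(
            windows,
            evaluation.combined_feature_fn(benchmark_config(seed)),
            feature_set="statistical+dbn",
        )
        results.append((seed, stat, combined))
    return results


@pytest.fixture(scope="session")
def semantic_recovery():
    """Best-match |r| per ground-truth attribute for a small trained stack on
    the default synthetic benchmark, over five generator seeds."""
    per_seed = []
    for seed in range(1, 6):
        spec = synthetic.SyntheticSpec(seed=seed)
        windows, truth = synthetic.generate_dataset(spec, np.random.default_rng(seed))
        std, _ = preprocessing.standardize(windows)
        X = preprocessing.flatten_windows(std)
        config = benchmark_config(seed)
        model = dbn.init_model(config, X.shape[1])
        dbn.train_layerwise(model, X, config)
        features = dbn.extract_features(model, X)
        report = semantics.correlation_matrix(features, truth.attributes)
        per_seed.append((seed, np.abs(report.best_r)))
    return per_seed
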