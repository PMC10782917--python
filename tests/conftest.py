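import numpy as np
import pytest

from sgae.preprocess import preprocess
from sgae.synth import SynthConfig, generate_layered_dataset
from sgae.train import TrainConfig, extract_embeddings, fit


@pytest.fixture(scope="session")
def small_synth():
    """400-spot, 4-band synthetic tissue used across the suite."""
    cfg = SynthConfig(n_spots=400, n_domains=4, n_genes=60, n_marker_genes=5, seed=7)
    expr, coords, truth = generate_layered_dataset(cfg)
    return cfg, expr, coords, truth


@pytest.fixture(scope="session")
def trained_small(small_synth):
    """Preprocessed + trained state on the small synthetic tissue."""
    _, expr, coords, truth = small_synth
    pcs, coords = preprocess(expr, coords, n_pcs=20, seed=7)
    cfg = TrainConfig(batch_size=200, epochs=15, seed=7)
    params, history = fit(pcs, coords, cfg)
    emb = extract_embeddings(pcs, coords, params, cfg)
    return pcs, coords, cfg, params, history, emb, truth
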