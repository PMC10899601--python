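import numpy as np
import pytest

from wsimil import pipeline, synthetic


def quick_params(**kw) -> synthetic.SynthesisParams:
    """Small, fast slides for unit tests (128 px slide, 64 px tiles)."""
    base = dict(slide_px=128, tile_px=64, seed=0)
    base.update(kw)
    return synthetic.SynthesisParams(**base)


DESK_CFG_OVERRIDES = dict(
    n_slides=60, seed=1,
    pretrain_epochs=6, head_epochs=100, patience=20, head_lr=1e-3,
)


@pytest.fixture(scope="session")
def desk_run(tmp_path_factory):
    """One full desk-scale experiment shared across tests: a seeded 60-slide
    cohort (8x8 tile grid per slide), contrastive pretraining, diagnosis +
    protein training, predictions and the metrics report."""
    out = tmp_path_factory.mktemp("desk_run")
    cfg = pipeline.parse_config(overrides={})
    cfg.update(DESK_CFG_OVERRIDES)
    cfg["out_dir"] = str(out)
    report = pipeline.run("all", cfg)
    return cfg, report


@pytest.fixture(scope="session")
def desk_models(desk_run):
    from wsimil import heads

    cfg, _ = desk_run
    root = cfg["out_dir"]
    return {
        "diagnosis": heads.load_task_model(f"{root}/models/diagnosis.npz"),
        "protein": heads.load_task_model(f"{root}/models/protein.npz"),
    }


@pytest.fixture(scope="session")
def desk_features(desk_run):
    cfg, _ = desk_run
    bags = pipeline.load_bags(cfg)
    return bags, pipeline.compute_features(cfg, bags=bags)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
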