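"""Task heads: softmax/MSE oracles, weak-supervision training on bag
features, label isolation, and the HER2-proxy response path."""

import numpy as np
import pandas as pd
import pytest

from wsimil import heads, stats
from wsimil.heads import HeadConfig, ProteinPanel, classify_head, mse_loss


# ----------------------------------------------------------- unit oracles
def test_classify_head_symmetric_logits():
    probs = classify_head(np.ones(4), np.zeros((2, 4)), np.zeros(2))
    assert probs == pytest.approx([0.5, 0.5])


def test_classify_head_softmax_arithmetic():
    # logits (l, l + log 3) -> probabilities (0.25, 0.75)
    probs = classify_head(np.array([1.0]), np.array([[2.0], [2.0]]),
                          np.array([0.0, np.log(3.0)]))
    assert probs == pytest.approx([0.25, 0.75], abs=1e-12)


def test_classify_head_normalizes_random_params(rng):
    for _ in range(20):
        probs = classify_head(rng.standard_normal(6),
                              rng.standard_normal((2, 6)),
                              rng.standard_normal(2))
        assert probs.sum() == pytest.approx(1.0, abs=1e-7)


def test_mse_loss_cases(rng):
    assert mse_loss([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert mse_loss([0.0, 0.0], [1.0, 3.0]) == 5.0
    y, yh = rng.standard_normal(223), rng.standard_normal(223)
    naive = sum((a - b) ** 2 for a, b in zip(y, yh)) / 223
    assert mse_loss(y, yh) == pytest.approx(naive, abs=1e-10)
    with pytest.raises(ValueError):
        mse_loss([1.0], [1.0, 2.0])


def test_protein_panel_validation():
    with pytest.raises(ValueError):
        ProteinPanel(names=["a"], values=[1.0, 2.0])
    with pytest.raises(ValueError):
        ProteinPanel(names=["a"], values=[np.nan])
    cfg = HeadConfig(task="protein")
    assert cfg.loss == "mse"
    with pytest.raises(ValueError):
        HeadConfig(task="segmentation")


# ----------------------------------------------------------- toy cohort
def toy_features_manifest(n=36, d=8, tiles=12, seed=0):
    """Bag features with planted structure: tumor bags contain a shifted
    tile subpopulation whose prevalence drives the 'protein' levels."""
    rng = np.random.default_rng(seed)
    rows, features = [], {}
    split = (["train"] * (n - 12) + ["val"] * 6 + ["test"] * 6)
    for i in range(n):
        tumor = i % 2 == 0
        frac = rng.uniform(0.3, 0.8) if tumor else 0.0
        H = rng.standard_normal((tiles, d)) * 0.3
        k = int(round(frac * tiles))
        H[:k, :3] += 2.0
        sid = f"S{i:03d}"
        features[sid] = H
        rows.append({
            "slide_id": sid, "patient_id": f"P{i:03d}", "split": split[i],
            "tumor_flag": tumor, "tumor_fraction": frac,
            "protein_1": frac + rng.normal(0, 0.05),
            "protein_2": 1.3 * frac + rng.normal(0, 0.05),
            "protein_3": rng.normal(0, 1.0),
            "surv_time": 1.0, "surv_event": 1,
            "responder": bool(rng.uniform() < 0.5),
        })
    return pd.DataFrame(rows), features


@pytest.fixture(scope="module")
def toy_cohort():
    return toy_features_manifest()


def head_cfg(task, **kw):
    base = dict(task=task, attention_dim=16, lr=1e-2, epochs=40, patience=10,
                seed=0)
    base.update(kw)
    return HeadConfig(**base)


def test_diagnosis_training_separates_classes(toy_cohort):
    manifest, features = toy_cohort
    model = heads.train_task(manifest, None, head_cfg("diagnosis"), features)
    preds = heads.predict(model, manifest, features)
    test = preds.merge(manifest[["patient_id", "tumor_flag"]], on="patient_id")
    test = test[test["split"] == "test"]
    _, acc = stats.confusion_and_accuracy((test["class_1"] > 0.5).astype(int),
                                          test["tumor_flag"].astype(int))
    assert acc >= 0.9


def test_protein_training_recovers_signal(toy_cohort):
    manifest, features = toy_cohort
    model = heads.train_task(manifest, None,
                             head_cfg("protein", hidden_dims=(16,)), features)
    assert model.output_names == ["protein_1", "protein_2", "protein_3"]
    preds = heads.predict(model, manifest, features)
    merged = preds.merge(manifest, on="patient_id", suffixes=("_hat", ""))
    held = merged[merged["split"] == "val"]
    for name in ("protein_1", "protein_2"):
        r, _ = stats.pearson(held[name], held[name + "_hat"])
        assert r > 0.5


def test_all_one_class_labels_rejected(toy_cohort):
    manifest, features = toy_cohort
    bad = manifest.copy()
    bad["tumor_flag"] = True
    with pytest.raises(ValueError):
        heads.train_task(bad, None, head_cfg("diagnosis"), features)


def test_response_labels_never_influence_protein_training(toy_cohort):
    """Poisoning the responder column leaves the protein model bit-identical
    (label isolation of the HER2-proxy protocol)."""
    manifest, features = toy_cohort
    cfg = head_cfg("protein", epochs=5)
    m1 = heads.train_task(manifest, None, cfg, features)
    poisoned = manifest.copy()
    poisoned["responder"] = ~poisoned["responder"]
    m2 = heads.train_task(poisoned, None, cfg, features)
    assert m1.state_bytes() == m2.state_bytes()
    assert m1.audit["responder_labels_read"] == 0


def test_multi_task_outputs_differ_only_via_final_rows(toy_cohort):
    """Weight surgery: editing one output row changes only that protein."""
    manifest, features = toy_cohort
    model = heads.train_task(manifest, None,
                             head_cfg("protein", epochs=3), features)
    H = features[manifest["slide_id"].iloc[0]]
    before, _ = model.forward(H)
    model.head.out.w.data[1] += 1.0
    model.head.out.b.data[1] += 0.5
    after, _ = model.forward(H)
    assert after[0] == pytest.approx(before[0])
    assert after[2] == pytest.approx(before[2])
    assert after[1] != pytest.approx(before[1])


def test_her2_proxy_scoring_and_errors(toy_cohort):
    manifest, features = toy_cohort
    model = heads.train_task(manifest, None,
                             head_cfg("protein", hidden_dims=(16,)), features)
    scores = heads.predict_response_via_her2(manifest, model, "protein_1",
                                             features)
    assert set(scores.columns) == {"patient_id", "split", "response_score"}
    assert len(scores) == manifest["patient_id"].nunique()
    with pytest.raises(ValueError):
        heads.predict_response_via_her2(manifest, model, "HER2-missing",
                                        features)


def test_per_patient_prediction_averages_slides(toy_cohort):
    manifest, features = toy_cohort
    model = heads.train_task(manifest, None, head_cfg("diagnosis", epochs=2),
                             features)
    doubled = pd.concat([manifest, manifest.assign(
        slide_id=manifest["slide_id"] + "b")], ignore_index=True)
    feats2 = dict(features)
    feats2.update({sid + "b": H for sid, H in features.items()})
    per_patient = heads.predict(model, doubled, feats2, per_patient=True)
    assert len(per_patient) == manifest["patient_id"].nunique()
    per_slide = heads.predict(model, doubled, feats2, per_patient=False)
    p0 = manifest["patient_id"].iloc[0]
    mean0 = per_slide.loc[per_slide["patient_id"] == p0, "class_1"].mean()
    assert per_patient.loc[per_patient["patient_id"] == p0, "class_1"
                           ].iloc[0] == pytest.approx(mean0)


def test_task_model_roundtrip(tmp_path, toy_cohort):
    manifest, features = toy_cohort
    model = heads.train_task(manifest, None, head_cfg("diagnosis", epochs=2),
                             features)
    heads.save_task_model(model, tmp_path / "m.npz")
    loaded = heads.load_task_model(tmp_path / "m.npz")
    H = features[manifest["slide_id"].iloc[0]]
    out1, a1 = model.forward(H)
    out2, a2 = loaded.forward(H)
    assert np.allclose(out1, out2) and np.allclose(a1, a2)


def test_fine_tuning_updates_encoder_weights():
    """With fine_tune_encoder the backbone parameters move during training."""
    from wsimil import contrastive, prep, synthetic
    from conftest import quick_params

    params = quick_params(slide_px=256, seed=5)
    bags, rows = {}, []
    for i in range(6):
        s = synthetic.make_slide(params, i)
        slide = prep.SlideRaster(pixels=s.raster, slide_id=s.slide_id)
        mask = prep.segment_tissue(slide, downsample=4)
        bags[s.slide_id] = prep.tessellate(slide, mask, tile_px=64,
                                           min_tissue_frac=0.25)
        rows.append({"slide_id": s.slide_id, "patient_id": f"P{i}",
                     "split": "train" if i < 4 else "val",
                     "tumor_flag": s.labels["tumor_flag"],
                     "protein_1": s.labels["proteins"].values[0],
                     "responder": False})
    manifest = pd.DataFrame(rows)
    state = contrastive.pretrain(bags.values(),
                                 contrastive.PretrainConfig(epochs=1,
                                                            queue_size=32))
    before = [p.data.copy() for p in state.backbone.parameters()]
    features = {sid: contrastive.embed(b, state) for sid, b in bags.items()}
    cfg = HeadConfig(task="protein", attention_dim=8, lr=1e-3, epochs=2,
                     patience=5, fine_tune_encoder=True, seed=0)
    heads.train_task(manifest, state, cfg, features, bags=bags)
    moved = any(not np.allclose(b, p.data)
                for b, p in zip(before, state.backbone.parameters()))
    assert moved
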