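"""Orchestration of the four-stage flow: preprocess -> contrastive pretrain
-> weakly supervised fine-tune -> attentive aggregation and downstream tasks,
with a flat key=value run config, structured JSONL logging and seeded,
reproducible stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import contrastive, heads, stats, survival, synthetic
from .heatmap import deconvolve, export_overlay
from .mil import SlideFeature
from .prep import TileBag, TissueMask, read_slide, normalize_color, segment_tissue, tessellate

STAGES = ("synthesize", "tile", "pretrain", "train", "predict", "heatmap",
          "evaluate", "all")

DEFAULTS: dict = {
    "out_dir": "wsimil_run",
    "seed": 0,
    # cohort
    "n_slides": 20,
    "slide_px": 512,
    "tile_px": 64,
    "n_proteins": 32,
    "n_signal_proteins": 8,
    "noise_sd": 0.1,
    "censoring_rate": 0.3,
    "texture_strength": 1.0,
    # preprocessing
    "downsample": 4,
    "min_tissue_frac": 0.5,
    "magnification": 40,
    "color_normalize": False,
    # contrastive pretraining
    "pretrain_epochs": 4,
    "batch_size": 64,
    "tau": 0.07,
    "queue_size": 256,
    "ema": 0.999,
    "pretrain_lr": 0.03,
    "embed_dim": 32,
    "in_px": 32,
    "sample_fraction": 1.0,
    "max_slides": 0,            # 0 = no cap
    # heads
    "attention_dim": 64,
    "head_lr": 1e-3,
    "head_epochs": 60,
    "patience": 15,
    "protein_hidden": 32,
    # evaluation
    "alpha": 0.05,
    "cv_k": 5,
    "her2": synthetic.HER2_PROTEIN,
    "heatmap_downsample": 8,
    "heatmap_alpha": 0.5,
}


def parse_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Resolve DEFAULTS <- config file (key = value lines) <- overrides."""
    cfg = dict(DEFAULTS)
    if path is not None:
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            cfg[key.strip()] = _coerce(key.strip(), val.strip())
    for k, v in (overrides or {}).items():
        cfg[k] = _coerce(k, v) if isinstance(v, str) else v
    return cfg


def _coerce(key: str, val: str):
    ref = DEFAULTS.get(key)
    if isinstance(ref, bool):
        return val.lower() in ("1", "true", "yes")
    if isinstance(ref, int):
        return int(val)
    if isinstance(ref, float):
        return float(val)
    return val


def _freeze_config(cfg: dict, root: Path):
    lines = [f"{k} = {cfg[k]}" for k in sorted(cfg)]
    (root / "config.frozen.cfg").write_text("\n".join(lines) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(root: Path, stage: str, seed: int, artifacts: list[Path]):
    entry = {"stage": stage, "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
             "seed": seed,
             "artifacts": {str(p.relative_to(root)): _sha256(p)
                           for p in artifacts if p.is_file()}}
    with open(root / "run_log.jsonl", "a") as fh:
        fh.write(json.dumps(entry) + "\n")
    return entry


def _require(path: Path, producing_stage: str):
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path}; run the '{producing_stage}' "
            f"stage first")
    return path


def _root(cfg) -> Path:
    root = Path(cfg["out_dir"])
    root.mkdir(parents=True, exist_ok=True)
    return root


def synthesis_params(cfg: dict) -> synthetic.SynthesisParams:
    return synthetic.SynthesisParams(
        slide_px=cfg["slide_px"], tile_px=cfg["tile_px"],
        n_proteins=cfg["n_proteins"], n_signal_proteins=cfg["n_signal_proteins"],
        noise_sd=cfg["noise_sd"], censoring_rate=cfg["censoring_rate"],
        texture_strength=cfg["texture_strength"], seed=cfg["seed"])


def stage_synthesize(cfg: dict):
    root = _root(cfg)
    _freeze_config(cfg, root)
    manifest = synthetic.make_cohort(synthesis_params(cfg), cfg["n_slides"],
                                     root / "cohort")
    arts = [manifest.manifest_path, *sorted((root / "cohort" / "slides").iterdir())]
    _log(root, "synthesize", cfg["seed"], arts)
    return manifest


def _load_manifest(cfg) -> pd.DataFrame:
    root = _root(cfg)
    path = _require(root / "cohort" / "manifest.csv", "synthesize")
    return pd.read_csv(path)


def stage_tile(cfg: dict):
    root = _root(cfg)
    manifest = _load_manifest(cfg)
    tiles_dir = root / "tiles"
    tiles_dir.mkdir(exist_ok=True)
    index_rows = []
    for _, row in manifest.iterrows():
        slide = read_slide(row["path"], magnification=cfg["magnification"])
        mask = segment_tissue(slide, downsample=cfg["downsample"])
        bag = tessellate(slide, mask, tile_px=cfg["tile_px"],
                         min_tissue_frac=cfg["min_tissue_frac"])
        if cfg["color_normalize"]:
            bag = normalize_color(bag)
        np.savez(tiles_dir / f"{row['slide_id']}.npz", pixels=bag.pixels,
                 coords=bag.coords, fracs=bag.tissue_fraction_per_tile,
                 tile_px=np.array(bag.tile_px),
                 magnification=np.array(bag.magnification))
        for (x0, y0), fr in zip(bag.coords, bag.tissue_fraction_per_tile):
            index_rows.append((row["slide_id"], int(x0), int(y0),
                               bag.magnification, float(fr)))
    index = pd.DataFrame(index_rows, columns=["slide_id", "x0", "y0",
                                              "magnification", "tissue_frac"])
    index.to_csv(tiles_dir / "index.csv", index=False)
    _log(root, "tile", cfg["seed"], [tiles_dir / "index.csv"])
    return index


def load_bags(cfg: dict) -> dict[str, TileBag]:
    root = _root(cfg)
    tiles_dir = _require(root / "tiles", "tile")
    _require(tiles_dir / "index.csv", "tile")
    bags = {}
    for path in sorted(tiles_dir.glob("*.npz")):
        with np.load(path) as npz:
            bags[path.stem] = TileBag(
                slide_id=path.stem, coords=npz["coords"], pixels=npz["pixels"],
                tile_px=int(npz["tile_px"]),
                magnification=int(npz["magnification"]),
                tissue_fraction_per_tile=npz["fracs"])
    return bags


def stage_pretrain(cfg: dict):
    root = _root(cfg)
    bags = load_bags(cfg)
    pconf = contrastive.PretrainConfig(
        epochs=cfg["pretrain_epochs"], batch_size=cfg["batch_size"],
        lr=cfg["pretrain_lr"], tau=cfg["tau"], queue_size=cfg["queue_size"],
        ema=cfg["ema"], in_px=cfg["in_px"], embed_dim=cfg["embed_dim"],
        sample_fraction=cfg["sample_fraction"],
        max_slides=cfg["max_slides"] or None, seed=cfg["seed"])
    (root / "checkpoints").mkdir(exist_ok=True)
    state = contrastive.pretrain(bags.values(), pconf,
                                 log_path=root / "checkpoints" / "pretrain_log.csv")
    contrastive.save_checkpoint(state, root / "checkpoints" / "encoder.npz")
    _log(root, "pretrain", cfg["seed"],
         [root / "checkpoints" / "pretrain_log.csv"])
    return state


def compute_features(cfg: dict, state=None, bags=None) -> dict[str, np.ndarray]:
    root = _root(cfg)
    if state is None:
        ckpt = _require(root / "checkpoints" / "encoder.npz", "pretrain")
        state = contrastive.load_checkpoint(ckpt)
    bags = bags or load_bags(cfg)
    return {sid: contrastive.embed(bag, state) for sid, bag in bags.items()}


def stage_train(cfg: dict, task: str):
    root = _root(cfg)
    manifest = _load_manifest(cfg)
    features = compute_features(cfg)
    if task == "protein":
        config = heads.HeadConfig(task="protein",
                                  hidden_dims=(cfg["protein_hidden"],),
                                  attention_dim=cfg["attention_dim"],
                                  lr=cfg["head_lr"], epochs=cfg["head_epochs"],
                                  patience=cfg["patience"], seed=cfg["seed"])
    else:
        config = heads.HeadConfig(task=task, attention_dim=cfg["attention_dim"],
                                  lr=cfg["head_lr"], epochs=cfg["head_epochs"],
                                  patience=cfg["patience"], seed=cfg["seed"])
    model = heads.train_task(manifest, None, config, features)
    (root / "models").mkdir(exist_ok=True)
    heads.save_task_model(model, root / "models" / f"{task}.npz")
    log = pd.DataFrame(model.train_log)
    log.to_csv(root / "models" / f"{task}_log.csv", index=False)
    _log(root, f"train[{task}]", cfg["seed"], [root / "models" / f"{task}_log.csv"])
    return model


def stage_predict(cfg: dict):
    root = _root(cfg)
    manifest = _load_manifest(cfg)
    features = compute_features(cfg)
    (root / "predictions").mkdir(exist_ok=True)
    outputs = {}
    for task in ("diagnosis", "protein"):
        path = _require(root / "models" / f"{task}.npz", "train")
        model = heads.load_task_model(path)
        preds = heads.predict(model, manifest, features)
        preds.to_csv(root / "predictions" / f"{task}.csv", index=False)
        outputs[task] = preds
    protein_model = heads.load_task_model(root / "models" / "protein.npz")
    resp = heads.predict_response_via_her2(manifest, protein_model,
                                           cfg["her2"], features)
    resp.to_csv(root / "predictions" / "response.csv", index=False)
    outputs["response"] = resp
    _log(root, "predict", cfg["seed"],
         sorted((root / "predictions").glob("*.csv")))
    return outputs


def attention_features(cfg: dict, model, bags=None,
                       features=None) -> dict[str, SlideFeature]:
    """Per-slide attention vectors + pooled features under a trained model."""
    bags = bags or load_bags(cfg)
    features = features or compute_features(cfg, bags=bags)
    out = {}
    for sid, H in features.items():
        _, a = model.forward(H)
        out[sid] = SlideFeature(S=a @ H, attention=a, coords=bags[sid].coords,
                                slide_id=sid)
    return out


def attention_localization_auc(cfg: dict, model=None, split: str | None = "test",
                               tumor_tile_frac: float = 0.5) -> float:
    """Mean per-slide AUC of tile attention against the planted tumor mask.

    A tile counts as tumor when at least ``tumor_tile_frac`` of its area lies
    inside the true tumor mask; slides without both tile classes are skipped.
    ``split=None`` evaluates every slide.
    """
    import imageio.v3 as iio

    root = _root(cfg)
    manifest = _load_manifest(cfg)
    if model is None:
        model = heads.load_task_model(
            _require(root / "models" / "diagnosis.npz", "train"))
    bags = load_bags(cfg)
    features = compute_features(cfg, bags=bags)
    sfs = attention_features(cfg, model, bags, features)
    tp = cfg["tile_px"]
    rows = manifest if split is None else manifest[manifest["split"] == split]
    aucs = []
    for _, row in rows.iterrows():
        if not row["tumor_flag"]:
            continue
        tumor = iio.imread(row["tumor_mask_path"]) > 127
        sid = row["slide_id"]
        labels = np.array([int(tumor[y0:y0 + tp, x0:x0 + tp].mean()
                               >= tumor_tile_frac)
                           for x0, y0 in bags[sid].coords])
        if labels.min() == labels.max():
            continue
        aucs.append(stats.roc_auc(sfs[sid].attention, labels))
    if not aucs:
        raise ValueError(f"no evaluable tumor slides in split {split!r}")
    return float(np.mean(aucs))


def stage_heatmap(cfg: dict, max_slides: int = 4):
    root = _root(cfg)
    manifest = _load_manifest(cfg)
    model_path = _require(root / "models" / "diagnosis.npz", "train")
    model = heads.load_task_model(model_path)
    bags = load_bags(cfg)
    features = compute_features(cfg, bags=bags)
    sfs = attention_features(cfg, model, bags, features)
    (root / "heatmaps").mkdir(exist_ok=True)
    test_ids = manifest.loc[manifest["split"] == "test", "slide_id"]
    score_rows = []
    for sid in list(test_ids)[:max_slides]:
        row = manifest[manifest["slide_id"] == sid].iloc[0]
        slide = read_slide(row["path"])
        hm = deconvolve(sfs[sid], (slide.height_px, slide.width_px),
                        tile_px=cfg["tile_px"],
                        downsample=cfg["heatmap_downsample"])
        export_overlay(hm, slide.pixels, cfg["heatmap_alpha"],
                       root / "heatmaps" / f"{sid}_overlay.png",
                       tiff_path=root / "heatmaps" / f"{sid}_heat.tiff")
        for (x0, y0), a in zip(sfs[sid].coords, sfs[sid].attention):
            score_rows.append((sid, int(x0), int(y0), float(a)))
    pd.DataFrame(score_rows, columns=["slide_id", "x0", "y0", "attention"]
                 ).to_csv(root / "heatmaps" / "attention_scores.csv", index=False)
    _log(root, "heatmap", cfg["seed"],
         sorted((root / "heatmaps").glob("*.png")))


def stage_evaluate(cfg: dict) -> dict:
    root = _root(cfg)
    manifest = _load_manifest(cfg)
    for task in ("diagnosis", "protein"):
        _require(root / "predictions" / f"{task}.csv", "predict")
    report: dict = {}
    alpha = cfg["alpha"]
    test = manifest[manifest["split"] == "test"]

    diag = pd.read_csv(root / "predictions" / "diagnosis.csv")
    diag = diag.merge(manifest[["patient_id", "tumor_flag"]].drop_duplicates(),
                      on="patient_id")
    dtest = diag[diag["split"] == "test"]
    if dtest["tumor_flag"].nunique() == 2:
        cm, acc = stats.confusion_and_accuracy(
            (dtest["class_1"] > 0.5).astype(int), dtest["tumor_flag"].astype(int))
        report["diagnosis"] = {
            "accuracy": acc, "confusion": cm.tolist(),
            "auc": stats.roc_auc(dtest["class_1"], dtest["tumor_flag"].astype(int))}

    prot = pd.read_csv(root / "predictions" / "protein.csv")
    protein_cols = [c for c in manifest.columns if c.startswith("protein_")]
    merged = prot[prot["split"] == "test"].merge(
        manifest[["patient_id"] + protein_cols].drop_duplicates("patient_id"),
        on="patient_id", suffixes=("_pred", "_true"))
    if len(merged) >= 3:
        results = stats.correlation_panel(
            merged[[c + "_true" for c in protein_cols]].rename(
                columns=lambda c: c[:-5]),
            merged[[c + "_pred" for c in protein_cols]].rename(
                columns=lambda c: c[:-5]), alpha=alpha)
        report["protein"] = {
            "mean_r": float(np.mean([c.r for c in results])),
            "n_significant": int(sum(c.significant for c in results)),
            "per_protein": [{"protein": c.protein, "r": c.r, "p": c.p,
                             "p_adj": c.p_adj, "significant": c.significant}
                            for c in results]}

    resp = pd.read_csv(root / "predictions" / "response.csv")
    rtest = resp[resp["split"] == "test"].merge(
        manifest[["patient_id", "responder"]].drop_duplicates(), on="patient_id")
    if rtest["responder"].nunique() == 2:
        # responders carry LOW HER2-like levels, so the responder score is
        # the negated predicted level
        report["response"] = {"auc": stats.roc_auc(
            -rtest["response_score"], rtest["responder"].astype(int))}

    # prognosis: univariate Cox on the predicted tumor probability
    risk_col = diag.set_index("patient_id")["class_1"]
    records = [
        survival.SurvivalRecord(patient_id=r["patient_id"], time=r["surv_time"],
                                event=int(r["surv_event"]),
                                covariates=[risk_col[r["patient_id"]]])
        for _, r in manifest.iterrows()
    ]
    train_recs = [rec for rec, (_, r) in zip(records, manifest.iterrows())
                  if r["split"] == "train"]
    if sum(r.event for r in train_recs) >= 2:
        try:
            model = survival.fit_cox(train_recs)
            scores = np.array([survival.risk_score(model, r.covariates)
                               for r in records])
            times = np.array([r.time for r in records])
            events = np.array([r.event for r in records])
            hr, ci = survival.univariate_hr(train_recs)
            report["prognosis"] = {
                "c_index": stats.c_index(scores, times, events),
                "hazard_ratio": hr, "hr_ci": list(ci),
                "theta": model.theta.tolist()}
        except ValueError:
            pass

    (root / "metrics").mkdir(exist_ok=True)
    (root / "metrics" / "report.json").write_text(json.dumps(report, indent=2))
    _log(root, "evaluate", cfg["seed"], [root / "metrics" / "report.json"])
    return report


def run(stage: str, cfg: dict):
    """Execute one pipeline stage (or `all`); see STAGES."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    if stage in ("synthesize", "all"):
        stage_synthesize(cfg)
    if stage in ("tile", "all"):
        stage_tile(cfg)
    if stage in ("pretrain", "all"):
        stage_pretrain(cfg)
    if stage in ("train", "all"):
        for task in ("diagnosis", "protein"):
            stage_train(cfg, task)
    if stage in ("predict", "all"):
        stage_predict(cfg)
    if stage in ("heatmap", "all"):
        stage_heatmap(cfg)
    if stage in ("evaluate", "all"):
        return stage_evaluate(cfg)
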