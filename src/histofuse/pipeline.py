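"""End-to-end orchestration: simulate -> split -> extract -> train -> evaluate.

Two bundled systems mirror the two arms of the workflow:

* ``system1`` — backbone-only classification: the dual-branch transformer is
  trained on the training split and classifies the test split through its
  averaged branch-head logits.
* ``system2`` (default) — hybrid classification: per-branch CLS features are
  fused with the 818-dim handcrafted vector and a feed-forward ANN is
  trained on the fused vectors (jointly on the combined vector by default,
  or per branch with averaged probabilities via ``branch_mode: separate``).

Every stochastic stage derives its seed from the single run seed (documented
offsets), every intermediate artifact is persisted in the run directory, and
a JSON-lines event log records stages, seeds and timings.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import backbone as bb
from . import evaluation, fusion, imaging, synthetic
from .features import feature_names, handcrafted_vector

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "extract_features",
           "reevaluate", "load_config"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "system": "system2",
    "branch_mode": "joint",
    "preset": "easy",
    "n_per_class": 100,
    "image_size": 64,
    "backbone": {"preset": "tiny"},
    "split": {"ratios": (0.70, 0.15, 0.15), "stratify": True},
    "augment": {"enabled": False, "copies": 1, "max_rotation_deg": 15.0,
                "hflip_prob": 0.5, "vflip_prob": 0.5, "brightness_delta": 0.1,
                "contrast_delta": 0.1, "saturation_delta": 0.1},
    "backbone_train": {"epochs": 0, "lr": 1e-3, "batch_size": 16},
    "ann": {"hidden_units": 128, "max_epochs": 100, "learning_rate": 1e-3,
            "batch_size": 32, "early_stop_patience": 20, "standardize": True},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge the defaults with a YAML document and explicit overrides."""
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        import yaml
        doc = yaml.safe_load(Path(path).read_text()) or {}
        config = _merge(config, doc)
    if overrides:
        config = _merge(config, overrides)
    return config


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def event(self, stage: str, **fields) -> None:
        rec = {"time": time.time(), "stage": stage, **fields}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")


def extract_features(dataset: synthetic.LabeledDataset, config: bb.BackboneConfig,
                     params, batch_size: int = 32) -> pd.DataFrame:
    """Per-image deep CLS + handcrafted features as one table.

    Columns: label, tag, ds_* (small CLS), dl_* (large CLS), then the
    handcrafted columns (fch_/lbp_/glcm_).  Extraction is deterministic.
    """
    deep_small, deep_large, hand = [], [], []
    images = dataset.images
    for start in range(0, len(images), batch_size):
        batch = np.stack(images[start:start + batch_size])
        feats = bb.forward_features(batch, config, params)
        deep_small.append(feats.z_cls_small)
        deep_large.append(feats.z_cls_large)
    for img in images:
        hand.append(handcrafted_vector(img))
    ds = np.concatenate(deep_small) if deep_small else np.empty((0, config.dim_small))
    dl = np.concatenate(deep_large) if deep_large else np.empty((0, config.dim_large))
    hd = np.stack(hand) if hand else np.empty((0, len(feature_names())))
    cols = {}
    cols["label"] = dataset.labels
    cols["tag"] = dataset.tags
    for i in range(ds.shape[1]):
        cols[f"ds_{i:03d}"] = ds[:, i]
    for i in range(dl.shape[1]):
        cols[f"dl_{i:03d}"] = dl[:, i]
    for i, name in enumerate(feature_names()):
        cols[name] = hd[:, i]
    return pd.DataFrame(cols)


def _fused_matrix(frame: pd.DataFrame, mode: str) -> np.ndarray:
    ds_cols = [c for c in frame.columns if c.startswith("ds_")]
    dl_cols = [c for c in frame.columns if c.startswith("dl_")]
    hand_cols = feature_names()
    small = frame[ds_cols + hand_cols].to_numpy(dtype=np.float64)
    large = frame[dl_cols + hand_cols].to_numpy(dtype=np.float64)
    if mode == "small":
        return small
    if mode == "large":
        return large
    return np.concatenate([small, large], axis=1)


def _train_system2(frames, cfg, ann_cfg, log):
    tr, va, te = frames
    mode = cfg["branch_mode"]
    if mode == "separate":
        models, histories = {}, {}
        probs_te = []
        for branch in ("small", "large"):
            model, hist = fusion.train_ann(
                _fused_matrix(tr, branch), tr["label"].to_numpy(),
                _fused_matrix(va, branch), va["label"].to_numpy(), ann_cfg)
            models[branch] = model
            histories[branch] = hist
            _, p2 = fusion.predict(model, _fused_matrix(te, branch))
            probs_te.append(p2)
        scores = np.mean(probs_te, axis=0)
        labels = np.where(scores > 0.5, 2, 1)
        history = histories["large"]
        model = models
    else:
        model, history = fusion.train_ann(
            _fused_matrix(tr, "joint"), tr["label"].to_numpy(),
            _fused_matrix(va, "joint"), va["label"].to_numpy(), ann_cfg)
        labels, scores = fusion.predict(model, _fused_matrix(te, "joint"))
    log.event("train_ann", best_epoch=history.best_epoch,
              best_val_loss=history.best_val_loss)
    return model, history, labels, scores


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the full run; returns a summary dict with artifact paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "log.jsonl")
    seed = int(config["seed"])
    (out / "config.json").write_text(json.dumps(config, indent=2, default=str))

    # --- simulate ----------------------------------------------------------
    size = (config["image_size"], config["image_size"])
    dataset = synthetic.generate_preset_dataset(
        config["preset"], config["n_per_class"], size, seed)
    manifest = synthetic.save_dataset(dataset, out / "data")
    log.event("simulate", seed=seed, n=len(dataset), preset=config["preset"])

    # --- split -------------------------------------------------------------
    split_spec = imaging.SplitSpec(ratios=tuple(config["split"]["ratios"]),
                                   stratify=bool(config["split"]["stratify"]),
                                   seed=seed + 1)
    train, val, test = imaging.partition(dataset, split_spec)
    (out / "split.json").write_text(json.dumps(
        {"train": len(train), "val": len(val), "test": len(test),
         "ratios": list(split_spec.ratios), "seed": split_spec.seed}))
    log.event("split", seed=seed + 1, sizes=[len(train), len(val), len(test)])

    # --- augment (train split only, optional) ------------------------------
    aug = config["augment"]
    if aug.get("enabled"):
        extra_images, extra_labels, extra_tags = [], [], []
        for copy in range(int(aug.get("copies", 1))):
            for i, img in enumerate(train.images):
                spec = imaging.AugmentSpec(
                    hflip_prob=aug["hflip_prob"], vflip_prob=aug["vflip_prob"],
                    max_rotation_deg=aug["max_rotation_deg"],
                    brightness_delta=aug["brightness_delta"],
                    contrast_delta=aug["contrast_delta"],
                    saturation_delta=aug["saturation_delta"],
                    seed=seed + 5 + copy * len(train) + i)
                extra_images.append(imaging.augment(img, spec))
                extra_labels.append(train.labels[i])
                extra_tags.append(train.tags[i] + "+aug")
        train = synthetic.LabeledDataset(
            images=train.images + extra_images,
            labels=np.concatenate([train.labels, extra_labels]),
            tags=train.tags + extra_tags)
        log.event("augment", seed=seed + 5, n_extra=len(extra_images))

    # --- backbone ----------------------------------------------------------
    bb_config = bb.config_from_dict(config["backbone"])
    params = bb.init_params(bb_config, seed + 2)
    bt = config["backbone_train"]
    system = config["system"]
    epochs = int(bt.get("epochs", 0)) or (3 if system == "system1" else 0)
    if epochs:
        losses = bb.train_backbone(
            np.stack(train.images), train.labels, bb_config, params,
            epochs=epochs, batch_size=int(bt["batch_size"]),
            lr=float(bt["lr"]), seed=seed + 3)
        log.event("train_backbone", seed=seed + 3, epochs=epochs,
                  final_loss=losses[-1])
    bb.save_params(params, out / "backbone.npz")

    # --- evaluate / system paths -------------------------------------------
    history = None
    if system == "system1":
        logits = bb.forward_logits(np.stack(test.images), bb_config, params)
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        scores = p[:, 1]
        labels = np.where(scores > 0.5, 2, 1)
        log.event("classify_backbone", n=len(test))
    else:
        frames = []
        for name, subset in (("train", train), ("val", val), ("test", test)):
            frame = extract_features(subset, bb_config, params)
            frame.to_csv(out / f"features_{name}.csv", index=False)
            frames.append(frame)
        log.event("extract", n=sum(len(f) for f in frames))
        ann_cfg = fusion.TrainConfig(seed=seed + 4, **config["ann"])
        model, history, labels, scores = _train_system2(
            frames, config, ann_cfg, log)
        if isinstance(model, dict):
            for branch, m in model.items():
                fusion.save_model(m, out / f"ann_{branch}.npz")
        else:
            fusion.save_model(model, out / "ann.npz")
        (out / "history.json").write_text(json.dumps({
            "train_loss": history.train_loss, "val_loss": history.val_loss,
            "best_epoch": history.best_epoch,
            "best_val_loss": history.best_val_loss}, indent=2))

    counts, report = evaluation.evaluate(test.labels, labels, scores)
    report.to_json(out / "report.json")
    (out / "report.txt").write_text(evaluation.report_table(counts, report))
    log.event("evaluate", **{k: v for k, v in report.to_dict().items()
                             if k != "warnings"})
    return {"out_dir": str(out), "manifest": str(manifest),
            "report": report, "counts": counts, "history": history,
            "test_labels": test.labels, "pred_labels": labels,
            "scores": scores}


def reevaluate(run_dir) -> evaluation.MetricsReport:
    """Recompute the metrics report from persisted features and ANN model.

    A run directory is self-contained: this reproduces ``report.json``
    exactly for a joint-mode system2 run.
    """
    run_dir = Path(run_dir)
    frame = pd.read_csv(run_dir / "features_test.csv")
    model = fusion.load_model(run_dir / "ann.npz")
    labels, scores = fusion.predict(model, _fused_matrix(frame, "joint"))
    _, report = evaluation.evaluate(frame["label"].to_numpy(), labels, scores)
    return report
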