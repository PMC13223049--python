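"""End-to-end experiment runner: simulate -> preprocess -> split -> balance ->
baseline -> CNN -> evaluate -> interpret, with provenance and stage caching.

The run directory receives a verbatim copy of the configuration before any
stage executes, a JSON-lines log with per-stage seeds and durations, and one
sub-directory per stage. Completed stages are skipped on re-run when their
section of the configuration is unchanged. The held-out test split is kept
behind a guard object that raises if anything touches it before the
evaluation stage.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import os
import time
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import baseline as bl
from . import cnn as cnn_mod
from . import evaluate as ev
from . import interpret as itp
from . import partition as pt
from . import preprocess as pp
from . import synthdata as sd
from ._seeds import child_seed
from .augment import AugmentParams, offline_augment, train_time_augment
from .config import ExperimentConfig


class HeldOutGuardError(RuntimeError):
    pass


class HeldOutGuard:
    """Holds the test-split manifest; access before release is an error."""

    def __init__(self, manifest: pd.DataFrame):
        self._manifest = manifest
        self._released = False

    def release(self) -> None:
        self._released = True

    @property
    def manifest(self) -> pd.DataFrame:
        if not self._released:
            raise HeldOutGuardError("test split accessed before the evaluation stage")
        return self._manifest


def _section_hash(cfg: ExperimentConfig, *sections: str) -> str:
    payload = {"seed": cfg.seed}
    for s in sections:
        payload[s] = getattr(cfg, s).model_dump(mode="json")
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage_done(stage_dir: Path, digest: str) -> bool:
    marker = stage_dir / "stage.json"
    if not marker.exists():
        return False
    try:
        return json.loads(marker.read_text()).get("config_hash") == digest
    except json.JSONDecodeError:
        return False


def _mark_done(stage_dir: Path, digest: str, **extra) -> None:
    (stage_dir / "stage.json").write_text(json.dumps({"config_hash": digest, **extra}, indent=2))


def _load_images(root: Path, manifest: pd.DataFrame) -> list[np.ndarray]:
    return [np.asarray(Image.open(root / p).convert("L")) for p in manifest["path"]]


def _resize_square(img: np.ndarray, size: int) -> np.ndarray:
    return np.asarray(Image.fromarray(img).resize((size, size), Image.BILINEAR))


def run_experiment(config: ExperimentConfig, out_dir: str | os.PathLike) -> Path:
    """Execute every enabled stage; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log_path = out / "log.jsonl"

    def log(stage, **kv):
        with open(log_path, "a") as fh:
            fh.write(json.dumps({"stage": stage, "time": datetime.datetime.now().isoformat(), **kv}) + "\n")

    def run_stage(name, sections, fn):
        stage_dir = out / name
        stage_dir.mkdir(exist_ok=True)
        digest = _section_hash(config, *sections)
        if _stage_done(stage_dir, digest):
            log(name, skipped=True)
            return stage_dir, True
        t0 = time.time()
        fn(stage_dir)
        _mark_done(stage_dir, digest)
        log(name, seconds=round(time.time() - t0, 3), seed=config.seed)
        return stage_dir, False

    # ---- simulate --------------------------------------------------------
    ds = config.dataset
    dcfg = sd.DatasetConfig(
        n_per_sex=ds.n_per_sex,
        size_classes=tuple(ds.size_classes),
        frames_min=ds.frames_min,
        frames_max=ds.frames_max,
        canvas=tuple(ds.canvas),
        locations=tuple(ds.locations),
        start_date=ds.start_date,
        ghost_rate=ds.ghost_rate,
        suppress_rate=ds.suppress_rate,
        truncate_rate=ds.truncate_rate,
        overlay_border_px=ds.overlay_border_px,
        overlay_text_px=ds.overlay_text_px,
        population=sd.PopulationParams(effect_size=ds.effect_size),
    )

    def do_simulate(stage_dir):
        sd.generate_dataset(dcfg, stage_dir, seed=child_seed(config.seed, "simulate"))

    sim_dir, _ = run_stage("data", ["dataset"], do_simulate)
    manifest = pd.read_csv(sim_dir / "manifest.csv")

    # ---- preprocess ------------------------------------------------------
    pc = config.preprocess

    def do_preprocess(stage_dir):
        border = pc.border if pc.border == "auto" else tuple(int(x) for x in pc.border.split(","))
        stripped = {}
        for p in manifest["path"]:
            img = np.asarray(Image.open(sim_dir / p).convert("L"))
            stripped[p] = pp.strip_overlay(img, border, pc.text_band)
        if pc.qc:
            kept, excluded = pp.filter_quality(manifest, loader=stripped.__getitem__)
        else:
            kept, excluded = manifest.copy(), manifest.iloc[0:0].copy()
        crops, kept_rows = [], []
        for _, row in kept.iterrows():
            try:
                _, crop = pp.extract_roi(stripped[row["path"]], pc.threshold)
            except pp.EmptySpecimenError:
                continue
            crops.append(crop)
            kept_rows.append(row)
        kept = pd.DataFrame(kept_rows).reset_index(drop=True)
        if pc.pad == "auto":
            target = (max(c.shape[0] for c in crops), max(c.shape[1] for c in crops))
        else:
            target = tuple(int(x) for x in pc.pad.lower().split("x"))
        for crop, p in zip(crops, kept["path"]):
            Image.fromarray(pp.zero_pad(crop, *target), mode="L").save(stage_dir / p)
        kept.to_csv(stage_dir / "manifest.csv", index=False)
        excluded.to_csv(stage_dir / "excluded.csv", index=False)

    prep_dir, _ = run_stage("prep", ["dataset", "preprocess"], do_preprocess)
    kept = pd.read_csv(prep_dir / "manifest.csv")

    # ---- split -----------------------------------------------------------
    sp = config.split

    def do_split(stage_dir):
        assignment = pt.assign_splits(
            kept, sp.n_val_per_sex, sp.n_test_per_sex, seed=child_seed(config.seed, "split")
        )
        report = pt.check_leakage(assignment, kept)
        if not report.is_clean:
            raise RuntimeError(f"leaked individuals: {report.leaked_individuals}")
        assignment.to_csv(stage_dir / "splits.csv")
        (stage_dir / "audit.json").write_text(
            json.dumps({"n_leaked": report.n_leaked, "per_split": report.per_split}, indent=2)
        )

    split_dir, _ = run_stage("split", ["dataset", "preprocess", "split"], do_split)
    assignment = pt.SplitAssignment.from_csv(split_dir / "splits.csv")
    frame_split = assignment.frame_split(kept)
    train_manifest = kept.loc[frame_split == "train"].reset_index(drop=True)
    val_manifest = kept.loc[frame_split == "val"].reset_index(drop=True)
    guard = HeldOutGuard(kept.loc[frame_split == "test"].reset_index(drop=True))

    # ---- balance (train split only) --------------------------------------
    bal = config.balance

    def do_balance(stage_dir):
        if not bal.enabled:
            bal_manifest = train_manifest.assign(synthetic=False)
        else:
            params = AugmentParams()
            bal_manifest = pt.balance_training_set(
                train_manifest,
                augmenter=lambda img, seed: offline_augment(img, params, seed),
                target=bal.target if bal.target == "auto" else int(bal.target),
                cap=bal.cap,
                seed=child_seed(config.seed, "balance"),
                loader=lambda p: np.asarray(Image.open(prep_dir / p).convert("L")),
                writer=lambda p, img: Image.fromarray(img, mode="L").save(stage_dir / p),
            )
        bal_manifest.to_csv(stage_dir / "train_manifest.csv", index=False)

    bal_dir, _ = run_stage("balance", ["dataset", "preprocess", "split", "balance"], do_balance)
    train_aug = pd.read_csv(bal_dir / "train_manifest.csv")

    def load_train(aug: bool) -> tuple[list[np.ndarray], pd.DataFrame]:
        man = train_aug if aug else train_manifest
        imgs = []
        for _, row in man.iterrows():
            root = bal_dir if bool(row.get("synthetic", False)) else prep_dir
            imgs.append(np.asarray(Image.open(root / row["path"]).convert("L")))
        return imgs, man

    # ---- baseline --------------------------------------------------------
    bs = config.baseline

    def do_baseline(stage_dir):
        if not bs.enabled:
            return
        imgs_tr, man_tr = load_train(bs.use_augmented)
        X_tr = bl.flatten_features(imgs_tr)
        X_va = bl.flatten_features(_load_images(prep_dir, val_manifest))
        grid = bl.GridSpec(tuple(bs.C_values), tuple(bs.penalties), tuple(bs.solvers), tuple(bs.pca_components))
        model = bl.grid_search_baseline(
            X_tr, man_tr["sex"].to_numpy(), X_va, val_manifest["sex"].to_numpy(),
            grid, seed=child_seed(config.seed, "baseline"),
        )
        (stage_dir / "model.json").write_text(
            json.dumps(
                {
                    "hyperparameters": model.hyperparameters,
                    "val_balanced_accuracy": model.val_balanced_accuracy,
                    "n_evaluated": model.n_evaluated,
                    "n_skipped": model.n_skipped,
                    "cumulative_variance": model.pca.cumulative_variance.tolist(),
                },
                indent=2,
            )
        )
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        ax.plot(np.arange(1, model.pca.k + 1), model.pca.cumulative_variance, marker="o")
        ax.set_xlabel("components")
        ax.set_ylabel("cumulative explained variance")
        fig.savefig(stage_dir / "cumulative_variance.png", dpi=120)
        plt.close(fig)
        np.savez(
            stage_dir / "baseline.npz",
            scaler_mean=model.scaler.mean_,
            scaler_scale=model.scaler.scale_,
            components=model.pca.components,
            pca_mean=model.pca.pca.mean_,
            coef=model.classifier.coef_,
            intercept=model.classifier.intercept_,
        )

    base_dir, _ = run_stage("baseline", ["dataset", "preprocess", "split", "balance", "baseline"], do_baseline)

    # ---- cnn -------------------------------------------------------------
    cn = config.cnn
    cnn_cfg = cnn_mod.CNNConfig(
        family=cn.family,
        size_variant=cn.size_variant,
        schedule=tuple(cn.schedule) if cn.schedule else None,
        convs_per_block=cn.convs_per_block,
        input_size=cn.input_size,
        dropout_rate=cn.dropout_rate,
        dense_head=tuple(cn.dense_head),
    )

    def do_train(stage_dir):
        if not cn.enabled:
            return
        imgs_tr, man_tr = load_train(True)
        X_tr = np.stack([_resize_square(i, cn.input_size) for i in imgs_tr])
        X_va = np.stack(
            [_resize_square(i, cn.input_size) for i in _load_images(prep_dir, val_manifest)]
        )
        warm = None
        if cn.warm_start:
            with np.load(cn.warm_start, allow_pickle=False) as z:
                warm = {int(k.split("_")[0]): {} for k in z.files}
                for k in z.files:
                    i, name = k.split("_", 1)
                    warm[int(i)][name] = z[k]
        tcfg = cnn_mod.TrainConfig(
            batch_size=cn.batch_size,
            optimizer=cn.optimizer,
            learning_rate=cn.learning_rate,
            max_epochs=cn.max_epochs,
            monitor_start_epoch=cn.monitor_start_epoch,
            patience=cn.patience,
            checkpoint_gate=cn.checkpoint_gate,
            seed=child_seed(config.seed, "cnn"),
            warm_start=warm,
        )
        model = cnn_mod.build_cnn(cnn_cfg, seed=child_seed(config.seed, "cnn-init"))
        aug = (lambda img, seed: train_time_augment(img, seed=seed)) if cn.train_time_augment else None
        history, best = cnn_mod.train_model(
            model, X_tr, man_tr["sex"].to_numpy(), X_va, val_manifest["sex"].to_numpy(), tcfg, augment=aug
        )
        history.table.to_csv(stage_dir / "history.csv", index=False)
        state = best if best is not None else model.state_dict()
        np.savez(stage_dir / "checkpoint.npz", **{f"{i}_{k}": v for i, d in state.items() for k, v in d.items()})
        (stage_dir / "checkpoint_meta.json").write_text(
            json.dumps(
                {
                    "config": json.loads(json.dumps(cnn_cfg.__dict__, default=str)),
                    "seed": tcfg.seed,
                    "best_epoch": history.best_epoch,
                    "stopped_epoch": history.stopped_epoch,
                },
                indent=2,
            )
        )

    train_dir, _ = run_stage("train", ["dataset", "preprocess", "split", "balance", "cnn"], do_train)

    # ---- evaluate (the only stage that opens the test split) -------------
    def do_evaluate(stage_dir):
        guard.release()
        test_manifest = guard.manifest
        reports = {}
        if cn.enabled and (train_dir / "checkpoint.npz").exists():
            model = cnn_mod.build_cnn(cnn_cfg, seed=child_seed(config.seed, "cnn-init"))
            with np.load(train_dir / "checkpoint.npz") as z:
                state: dict = {}
                for k in z.files:
                    i, name = k.split("_", 1)
                    state.setdefault(int(i), {})[name] = z[k]
            model.load_state_dict(state)
            for split, man in (("val", val_manifest), ("test", test_manifest)):
                X = np.stack([_resize_square(i, cn.input_size) for i in _load_images(prep_dir, man)])
                labels, _ = cnn_mod.predict(model, X)
                rep = ev.evaluate_predictions(man["sex"].to_numpy(), labels, split)
                reports[f"cnn_{split}"] = rep.to_dict()
                ev.plot_confusion(rep.matrix, stage_dir / f"cnn_{split}_confusion.png", f"cnn {split}")
        (stage_dir / "reports.json").write_text(json.dumps(reports, indent=2))

    eval_dir, _ = run_stage("evaluate", ["dataset", "preprocess", "split", "balance", "cnn"], do_evaluate)

    # ---- interpret -------------------------------------------------------
    it = config.interpret

    def do_interpret(stage_dir):
        if not it.enabled or not cn.enabled or not (train_dir / "checkpoint.npz").exists():
            return
        model = cnn_mod.build_cnn(cnn_cfg, seed=child_seed(config.seed, "cnn-init"))
        with np.load(train_dir / "checkpoint.npz") as z:
            state: dict = {}
            for k in z.files:
                i, name = k.split("_", 1)
                state.setdefault(int(i), {})[name] = z[k]
        model.load_state_dict(state)
        imgs = _load_images(prep_dir, train_manifest)
        X = np.stack([_resize_square(i, cn.input_size) for i in imgs])
        feats = itp.extract_feature_matrix(model, X, it.layer_index)
        from sklearn.decomposition import PCA

        Z = PCA(n_components=min(it.n_pca_components, feats.shape[1], feats.shape[0]),
                random_state=config.seed).fit_transform(feats)
        sel = itp.select_k(Z, range(it.k_min, it.k_max + 1), seed=child_seed(config.seed, "kmeans"))
        result = {
            "k_values": sel.k_values,
            "wcss": sel.wcss,
            "silhouette": sel.silhouette,
            "elbow_k": sel.elbow_k,
            "selected_k": sel.selected_k,
            "label_silhouette": itp.silhouette_score(feats, train_manifest["sex"].to_numpy()),
        }
        (stage_dir / "clusters.json").write_text(json.dumps(result, indent=2))
        if len(X) > 3 * it.perplexity:
            emb = itp.tsne_embed(feats, seed=child_seed(config.seed, "tsne"), perplexity=it.perplexity)
            pd.DataFrame(
                {"path": train_manifest["path"], "sex": train_manifest["sex"], "x": emb[:, 0], "y": emb[:, 1]}
            ).to_csv(stage_dir / "tsne.csv", index=False)
        _, overlay = itp.extract_activations(model, X[0], layer_index=0)
        Image.fromarray(overlay).save(stage_dir / "activation_overlay.png")

    run_stage("interpret", ["dataset", "preprocess", "split", "balance", "cnn", "interpret"], do_interpret)
    return out
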