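"""End-to-end orchestration: phantom cohort -> segmentation -> features ->
benchmark -> report bundle.

One global seed deterministically derives every stage seed, so two runs
with the same configuration produce identical result tables.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .cnn import CNNSpec, preprocess_for_cnn, train_eval_cnn
from .core import FeatureTable, OutcomeLabels
from .deep_features import (
    AutoencoderSpec,
    build_autoencoder,
    deep_feature_table,
    filter_by_std,
    train_autoencoder,
)
from .hmls import HMLSConfig, build_combos, run_grid
from .io import write_feature_table
from .phantom import CohortSpec, PhantomSpec, generate_cohort, generate_labeled_phantoms
from .radiomics import DiscretizationConfig, extract_all, prune_features
from .segmentation import SegmentationConfig, segment_striatum


@dataclass
class RunConfig:
    n_subjects: int = 60
    seed: int = 0
    out_dir: str = "striatome_run"
    #: uptake contrast for (normal, abnormal) subjects: abnormal = reduced uptake;
    #: the jitter makes the imaging signal informative but weaker than the
    #: clinical one, as in real DAT-SPECT outcome prediction
    contrast_by_label: tuple[float, float] = (3.4, 2.8)
    contrast_jitter: float = 0.15
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    discretization: DiscretizationConfig = field(default_factory=DiscretizationConfig)
    autoencoder: AutoencoderSpec = field(
        default_factory=lambda: AutoencoderSpec(epochs=8)
    )
    df_std_threshold: float = 0.25
    cnn: CNNSpec = field(default_factory=lambda: CNNSpec(epochs=6))
    hmls: HMLSConfig = field(
        default_factory=lambda: HMLSConfig(k_grid=(10, 20), tuner_method="none")
    )
    run_cnn: bool = True
    verbosity: int = 1

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        names = ["cohort", "phantom", "autoencoder", "hmls", "cnn"]
        return {
            n: int(child.generate_state(1)[0] % (2**31))
            for n, child in zip(names, ss.spawn(len(names)))
        }


@dataclass
class RunBundle:
    out_dir: Path
    results_table: pd.DataFrame | None = None
    best_per_combo: pd.DataFrame | None = None
    cnn_result: dict | None = None
    failures: list[dict] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def _log(config: RunConfig, msg: str) -> None:
    if config.verbosity > 0:
        print(f"[striatome] {msg}")


def pipeline_run(config: RunConfig) -> RunBundle:
    """Execute every stage on synthetic data and write the report bundle.

    Stage failures are recorded (subject and stage named) and the bundle is
    emitted with whatever completed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    bundle = RunBundle(out_dir=out)
    manifest: dict = {
        "version": __version__,
        "global_seed": config.seed,
        "stage_seeds": seeds,
        "n_subjects": config.n_subjects,
        "warnings": [],
    }

    # ---- clinical cohort -------------------------------------------------
    cohort_spec = CohortSpec(n_subjects=config.n_subjects, seed=seeds["cohort"])
    cf_table, labels, moca = generate_cohort(cohort_spec)
    _log(config, f"cohort: {config.n_subjects} subjects, "
                 f"prevalence(abnormal)={labels.prevalence:.2f}")

    # ---- phantoms with outcome-linked uptake -----------------------------
    phantoms = generate_labeled_phantoms(
        labels.values(), config.phantom, config.contrast_by_label,
        contrast_jitter=config.contrast_jitter, seed=seeds["phantom"],
    )
    subjects = labels.subjects

    # ---- segmentation + radiomics ----------------------------------------
    rf_rows: dict[str, dict[str, float]] = {}
    crops: dict[str, np.ndarray] = {}
    for sid, (vol, gt_left, gt_right) in zip(subjects, phantoms):
        try:
            seg = segment_striatum(vol, config.segmentation)
            feats: dict[str, float] = {}
            for side, mask in (("L", seg.left), ("R", seg.right)):
                roi = mask if not mask.is_empty() else (gt_left if side == "L" else gt_right)
                side_feats = extract_all(vol, roi, config.discretization)
                feats.update({f"{side}.{k}": v for k, v in side_feats.items()})
            rf_rows[sid] = feats
            crops[sid] = preprocess_for_cnn(vol, config.cnn.input_shape)
        except Exception as exc:
            bundle.failures.append({
                "stage": "segmentation/radiomics", "subject": sid, "error": str(exc),
                "trace": traceback.format_exc(limit=3),
            })
    _log(config, f"radiomics: {len(rf_rows)} subjects x {2 * 215} features")
    if not rf_rows:
        _finalize(bundle, manifest, out)
        return bundle
    ok_subjects = list(rf_rows)
    rf_df = pd.DataFrame.from_dict(rf_rows, orient="index")
    rf_df.index.name = "subject_id"
    rf_df = rf_df.replace([np.inf, -np.inf], np.nan).fillna(0.0)
    rf_table = FeatureTable(rf_df, "RF")
    rf_table, drop_log = prune_features(rf_table)
    manifest["rf_features_after_pruning"] = rf_table.shape[1]
    manifest["rf_features_dropped"] = len(drop_log)

    # ---- deep features ---------------------------------------------------
    ae_spec = AutoencoderSpec(
        input_shape=config.cnn.input_shape,
        epochs=config.autoencoder.epochs,
        channels=config.autoencoder.channels,
        learning_rate=config.autoencoder.learning_rate,
        batch_size=config.autoencoder.batch_size,
        seed=seeds["autoencoder"],
    )
    model = build_autoencoder(ae_spec)
    model, loss_history = train_autoencoder(model, [crops[s] for s in ok_subjects])
    df_table = deep_feature_table(model, {s: crops[s] for s in ok_subjects})
    df_table, dropped = filter_by_std(df_table, config.df_std_threshold)
    manifest["autoencoder_loss_history"] = loss_history
    manifest["df_features_after_std_filter"] = df_table.shape[1]
    if df_table.shape[1] < 2:
        # phantom bottlenecks can be flatter than clinical data; keep the most
        # variable features so image-only combos remain exercisable
        full = deep_feature_table(model, {s: crops[s] for s in ok_subjects})
        stds = full.values().std(axis=0)
        top = [full.columns[i] for i in np.argsort(-stds)[:50]]
        df_table = full.select(top)
        manifest["warnings"].append(
            "std filter left <2 deep features; kept the 50 most variable instead"
        )
    _log(config, f"deep features: {df_table.shape[1]} kept "
                 f"(std > {config.df_std_threshold}), {len(dropped)} dropped")

    # ---- benchmark grid --------------------------------------------------
    cf_ok = FeatureTable(cf_table.df.loc[ok_subjects], "CF")
    y_ok = OutcomeLabels(labels.labels.loc[ok_subjects])
    combos = build_combos(cf_ok, rf_table, df_table)
    hmls_cfg = HMLSConfig(
        k_grid=config.hmls.k_grid,
        classifiers=config.hmls.classifiers,
        holdout_fraction=config.hmls.holdout_fraction,
        cv_folds=config.hmls.cv_folds,
        tuner_method=config.hmls.tuner_method,
        tuner_budget=config.hmls.tuner_budget,
        seed=seeds["hmls"],
    )
    grid = run_grid(combos, y_ok, hmls_cfg)
    bundle.results_table = grid.table
    bundle.best_per_combo = grid.best_per_combo
    grid.table.to_csv(out / "results.csv", index=False)
    grid.best_per_combo.to_csv(out / "best_per_combo.csv", index=False)
    for k in hmls_cfg.k_grid:
        hm = grid.heatmap_table(k)
        hm.to_csv(out / f"heatmap_cv_k{k}.csv")
        _plot_heatmap(hm, out / f"heatmap_cv_k{k}.png",
                      f"mean CV accuracy, top-{k} features")
    sel = {
        f"{r.combo}|{r.classifier}|k={r.k}": r.selected_features
        for r in grid.results if not r.error
    }
    (out / "selected_features.json").write_text(json.dumps(sel, indent=1))
    _log(config, "benchmark grid written to results.csv")

    # ---- CNN baseline ----------------------------------------------------
    if config.run_cnn:
        try:
            cnn_spec = CNNSpec(
                input_shape=config.cnn.input_shape,
                filters=config.cnn.filters,
                epochs=config.cnn.epochs,
                learning_rate=config.cnn.learning_rate,
                batch_size=config.cnn.batch_size,
                conventional_order=config.cnn.conventional_order,
                seed=seeds["cnn"],
            )
            res = train_eval_cnn(
                [crops[s] for s in ok_subjects], y_ok.values(), cnn_spec,
                holdout_fraction=config.hmls.holdout_fraction,
                cv_folds=config.hmls.cv_folds, seed=seeds["cnn"],
            )
            bundle.cnn_result = res.as_row()
            pd.DataFrame([res.as_row()]).to_csv(out / "cnn_results.csv", index=False)
        except Exception as exc:
            bundle.failures.append({"stage": "cnn", "subject": "", "error": str(exc)})

    write_feature_table(cf_ok, out / "features_cf.csv")
    write_feature_table(rf_table, out / "features_rf.csv")
    write_feature_table(df_table, out / "features_df.csv")
    labels.labels.loc[ok_subjects].rename("abnormal").to_csv(out / "labels.csv")
    moca.loc[ok_subjects].to_csv(out / "moca_year4.csv")
    _finalize(bundle, manifest, out)
    return bundle


def _finalize(bundle: RunBundle, manifest: dict, out: Path) -> None:
    manifest["failures"] = bundle.failures
    bundle.manifest = manifest
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    if bundle.failures:
        (out / "failure_report.json").write_text(
            json.dumps(bundle.failures, indent=1, default=str)
        )


def _plot_heatmap(hm: pd.DataFrame, path: Path, title: str) -> None:
    fig, ax = plt.subplots(figsize=(1.2 * len(hm.columns) + 2, 0.6 * len(hm) + 2))
    im = ax.imshow(hm.to_numpy(), cmap="viridis", vmin=0.4, vmax=1.0)
    ax.set_xticks(range(len(hm.columns)), hm.columns, rotation=45)
    ax.set_yticks(range(len(hm.index)), hm.index)
    for i in range(len(hm.index)):
        for j in range(len(hm.columns)):
            v = hm.iloc[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=8,
                        color="white" if v < 0.75 else "black")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
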