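"""End-to-end orchestration: extract -> select -> cross-validate -> report.

Each stage writes its artifact as CSV into the run directory so later
stages (and separate CLI invocations) can resume from a saved feature
table without the images present.  A manifest records the full config,
seeds, package versions and stage timings; rerunning the same config over
the same inputs with the stub backbone reproduces every CSV byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .backbones import FeatureExtractor, pretrained_backbone_adapter, stub_backbone
from .classify import CvResult, cross_validate
from .config import PipelineConfig, save_config
from .features import FeatureTable, build_feature_table, load_table_csv, save_table_csv
from .metrics import MetricsReport, confusion, metrics
from .nca import nca_fit, select_top_k

__all__ = ["make_backbone", "run_pipeline", "save_selection", "load_selection"]

log = logging.getLogger(__name__)


def make_backbone(config: PipelineConfig) -> FeatureExtractor:
    if config.backbone == "stub":
        return stub_backbone(config.backbone_seed, config.backbone_dim)
    return pretrained_backbone_adapter(config.backbone, config.backbone_layer)


def save_selection(indices: np.ndarray, weights: np.ndarray, path: Path) -> None:
    pd.DataFrame(
        {"feature_index": np.asarray(indices, dtype=np.int64),
         "weight": np.asarray(weights, dtype=np.float64)}
    ).to_csv(path, index=False, float_format="%.17g")


def load_selection(path: Path) -> np.ndarray:
    return pd.read_csv(path)["feature_index"].to_numpy(dtype=np.intp)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full pipeline; returns the run directory.

    Artifacts: ``features.csv`` (N x D table), ``nca_weights.csv`` (global
    fit, written for inspection regardless of selection mode),
    ``selection.csv``, ``predictions.csv`` (out-of-fold), a
    ``confusion.csv`` count matrix, ``metrics.csv`` + ``metrics.txt``, and
    ``manifest.yaml`` + ``timings.json``.
    """
    if config.dataset_dir is None:
        raise ValueError("dataset_dir is not set")
    dataset = Path(config.dataset_dir)
    if not dataset.is_dir():
        raise FileNotFoundError(f"dataset directory not found: {dataset}")

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_run_logging(out)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    backbone = make_backbone(config)
    table = build_feature_table(dataset, backbone, config.pyramid)
    save_table_csv(table, out / "features.csv")
    timings["extract_s"] = time.perf_counter() - t0
    log.info("extracted %d x %d features", table.n_samples, table.n_features)

    t0 = time.perf_counter()
    k = min(config.k_select, table.n_features)
    weights = nca_fit(table, config.nca)
    sel = select_top_k(weights, k)
    pd.DataFrame(
        {"feature_index": np.arange(table.n_features), "weight": weights.w}
    ).to_csv(out / "nca_weights.csv", index=False, float_format="%.17g")
    save_selection(sel.indices, sel.weights_at_selection, out / "selection.csv")
    timings["select_s"] = time.perf_counter() - t0
    log.info("NCA selected %d / %d columns", k, table.n_features)

    t0 = time.perf_counter()
    result = cross_validate(table, config.cv, config.svm, config.nca, k)
    class_order = tuple(np.unique(table.labels))
    cm = confusion(table.labels, result.predictions, class_order)
    report = metrics(cm)
    _write_cv_outputs(out, table, result, cm, report)
    timings["cv_s"] = time.perf_counter() - t0
    log.info("out-of-fold accuracy %.2f%%", report.overall_accuracy)

    save_config(config, out / "manifest.yaml")
    with open(out / "timings.json", "w") as fh:
        json.dump(timings, fh, indent=2)
    return out


def _write_cv_outputs(
    out: Path, table: FeatureTable, result: CvResult, cm, report: MetricsReport
) -> None:
    pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "true_label": table.labels,
            "predicted_label": result.predictions,
            "fold": result.fold_of_sample,
        }
    ).to_csv(out / "predictions.csv", index=False)
    pd.DataFrame(
        cm.counts, index=list(cm.class_order), columns=list(cm.class_order)
    ).to_csv(out / "confusion.csv")
    df = report.per_class.copy()
    df.insert(0, "class", df.index)
    df.to_csv(out / "metrics.csv", index=False, float_format="%.6f")
    (out / "metrics.txt").write_text(report.to_text() + "\n")


def _setup_run_logging(out: Path) -> None:
    """Mirror pipeline logs to stderr and a run-local file."""
    root = logging.getLogger("pyrafex")
    root.setLevel(logging.INFO)
    have_file = any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == (out / "run.log").resolve()
        for h in root.handlers
    )
    if not have_file:
        fh = logging.FileHandler(out / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        root.addHandler(fh)
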