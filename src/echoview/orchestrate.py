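"""End-to-end experiment drivers.

Two studies are orchestrated from a single YAML-able config dict:

* the **view study** — simulate (or ingest) a training cohort, normalize
  every clip, train the 5-fold ensemble under one or both input
  strategies, classify an independent test cohort, and evaluate
  (confusion table, accuracy, weighted kappa, misclassification report);
* the **noise study** — build the LVEF-regression dataset, corrupt its
  training half at the configured mislabeling rates, and measure the
  degradation of the estimated-vs-reference LVEF correlation.

Every run writes a ``manifest.json`` (config snapshot, master seed,
package version, SHA-256 digest of each output file, timestamps); a run
repeated from its manifest reproduces the prediction CSVs bit for bit.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import STUDY_STRATA, CohortSpec, EchoStudy, FrameSet, VIEW_ORDER, ViewLabel
from .evaluate import accuracy, confusion, misclassification_report, weighted_kappa
from .labelnoise import EFDataset, EFModelConfig, robustness_curve
from .preprocess import preprocess_clip
from .synthetic import iter_cohort
from .viewnet import ModelConfig, Sample, ensemble_proba_many, make_folds, train_crossval

__all__ = [
    "default_config", "scaled_strata", "prepare_framesets",
    "run_view_study", "run_noise_study", "rerun",
]

log = logging.getLogger(__name__)


def default_config() -> dict:
    """Study-protocol defaults: full stratified cohort, 120 px / 18.07 cm
    field, 10 frames per cycle, 5 folds, 50 epochs, noise rates
    0/0.5/1.5/1.9%."""
    return {
        "seed": 0,
        "cohort": {
            "n_train": None,          # None -> the full 340-patient design
            "n_test": 189,
            "image_size": 160,
            "speckle_sigma": 0.35,
        },
        "preprocess": {
            "size_px": 120,
            "fov_cm": 18.07,
            "k": 10,
            "register": False,
            "window": [0.0, 255.0],
        },
        "model": {
            "n_conv_layers": 5,
            "channels": [64, 80, 96, 112, 128],
            "epochs": 50,
            "batch_size": 32,
            "lr": 1e-3,
            "dense_units": 64,
            "modes": ["averaged", "per_frame"],
        },
        "folds": 5,
        "kappa_weighting": "linear",
        "noise": {
            "rates": [0.0, 0.005, 0.015, 0.019],
            "view": "AP4",
            "test_fraction": 0.33,
            "ef_model": {"channels": [16, 24, 32], "epochs": 50,
                         "batch_size": 16, "lr": 2e-3, "dense_units": 32},
        },
    }


def scaled_strata(n: int) -> tuple[tuple[float, float, int], ...]:
    """Shrink the 340-patient stratified design to ``n`` patients,
    keeping the strata proportions (largest-remainder rounding)."""
    total = sum(s[2] for s in STUDY_STRATA)
    raw = [s[2] * n / total for s in STUDY_STRATA]
    counts = [int(np.floor(x)) for x in raw]
    rem = n - sum(counts)
    order = np.argsort([c - x for c, x in zip(counts, raw)])
    for i in order[:rem]:
        counts[i] += 1
    return tuple((lo, hi, c) for (lo, hi, _), c in zip(STUDY_STRATA, counts))


def _cohort_spec(cfg: dict, n: int | None, seed: int) -> CohortSpec:
    strata = STUDY_STRATA if n is None else scaled_strata(n)
    return CohortSpec(strata=strata, seed=seed)


def prepare_framesets(studies, pp_cfg: dict,
                      ) -> tuple[dict[str, dict[ViewLabel, FrameSet]], dict[str, float]]:
    """Normalize every clip of every study into FrameSets.

    Returns ``(framesets[patient][view], lvef[patient])``; studies may be
    an iterator, so raw clips are released as soon as they are processed.
    """
    framesets: dict[str, dict[ViewLabel, FrameSet]] = {}
    lvef: dict[str, float] = {}
    for study in studies:
        per_view = {}
        for view in VIEW_ORDER:
            fs = preprocess_clip(
                study.clips[view],
                fov_cm=pp_cfg["fov_cm"], size_px=pp_cfg["size_px"],
                k=pp_cfg["k"], register=pp_cfg["register"],
                window=tuple(pp_cfg["window"]),
            )
            fs.patient_id = study.patient_id
            fs.clip_id = f"{study.patient_id}_{view.value}"
            per_view[view] = fs
        framesets[study.patient_id] = per_view
        lvef[study.patient_id] = study.lvef
        study.clips.clear()
    return framesets, lvef


def _samples(framesets: dict[str, dict[ViewLabel, FrameSet]]) -> list[Sample]:
    return [Sample(pid, fs, view)
            for pid, per_view in framesets.items()
            for view, fs in per_view.items()]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out: Path, config: dict, stages: list[str]) -> None:
    manifest = {
        "package": "echoview",
        "version": __version__,
        "seed": config["seed"],
        "config": config,
        "stages": stages,
        "outputs": {p.name: _digest(p) for p in sorted(out.iterdir())
                    if p.is_file() and p.name != "manifest.json"},
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _prediction_frame(framesets, probs: np.ndarray) -> pd.DataFrame:
    rows = []
    flat = [(pid, view, fs) for pid, per_view in framesets.items()
            for view, fs in per_view.items()]
    for (pid, view, fs), p in zip(flat, probs, strict=True):
        row = {"clip_id": fs.clip_id, "patient_id": pid, "true_view": view.value}
        for v, pv in zip(VIEW_ORDER, p):
            row[f"p_{v.value}"] = round(float(pv), 8)
        row["predicted_view"] = VIEW_ORDER[int(np.argmax(p))].value
        rows.append(row)
    return pd.DataFrame(rows)


def run_view_study(config: dict, out_dir: str | Path) -> Path:
    """Full view-classification experiment; returns the results directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = copy.deepcopy(config)
    seed = config["seed"]
    cc, pp, mc = config["cohort"], config["preprocess"], config["model"]
    stages = []

    t0 = time.time()
    train_spec = _cohort_spec(cc, cc["n_train"], seed)
    test_spec = _cohort_spec(cc, cc["n_test"], seed + 7919)
    train_fs, _ = prepare_framesets(
        iter_cohort(train_spec, image_size=cc["image_size"],
                    speckle_sigma=cc["speckle_sigma"]), pp)
    test_fs, _ = prepare_framesets(
        iter_cohort(test_spec, image_size=cc["image_size"],
                    speckle_sigma=cc["speckle_sigma"]), pp)
    stages.append(f"simulate+preprocess: {len(train_fs)}+{len(test_fs)} studies "
                  f"in {time.time() - t0:.1f}s")

    folds = make_folds(sorted(train_fs), k=config["folds"], seed=seed + 13)
    pd.Series(folds, name="fold").rename_axis("patient_id").to_csv(out / "folds.csv")
    samples = _samples(train_fs)
    test_list = [fs for per_view in test_fs.values() for fs in per_view.values()]

    summary = {}
    for mode in mc["modes"]:
        t1 = time.time()
        epochs = mc["epochs"][mode] if isinstance(mc["epochs"], dict) else mc["epochs"]
        cfg = ModelConfig(
            n_conv_layers=mc["n_conv_layers"], channels=tuple(mc["channels"]),
            input_mode=mode, epochs=epochs, batch_size=mc["batch_size"],
            lr=mc["lr"], dense_units=mc["dense_units"], input_size=pp["size_px"],
            seed=seed + 101,
        )
        weight_sets = train_crossval(samples, folds, cfg, k=config["folds"])
        probs = ensemble_proba_many(weight_sets, test_list, mode=mode)
        preds = _prediction_frame(test_fs, probs)
        preds.to_csv(out / f"predictions_{mode}.csv", index=False)
        table = confusion(preds)
        table.to_frame().to_csv(out / f"confusion_{mode}.csv")
        kap = weighted_kappa(table, weighting=config["kappa_weighting"])
        acc = accuracy(table)
        summary[mode] = {
            "accuracy": acc, "kappa": kap.kappa, "kappa_se": kap.se,
            "kappa_ci95": list(kap.ci95), "kappa_weighting": kap.weighting,
            "val_losses": [w.val_loss for w in weight_sets],
        }
        fs_by_id = {fs.clip_id: fs for fs in test_list}
        misclassification_report(preds, fs_by_id, out / f"misclassified_{mode}")
        stages.append(f"train+evaluate[{mode}]: acc={acc:.3f} "
                      f"kappa={kap.kappa:.3f} in {time.time() - t1:.1f}s")
        log.info(stages[-1])

    (out / "kappa.json").write_text(json.dumps(summary, indent=1))
    _write_manifest(out, config, stages)
    return out


def run_noise_study(config: dict, out_dir: str | Path) -> Path:
    """Label-noise robustness experiment; returns the results directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = copy.deepcopy(config)
    seed = config["seed"]
    cc, pp, nz = config["cohort"], config["preprocess"], config["noise"]
    rates = [float(r) for r in nz["rates"]]
    if 0.0 not in rates:
        raise ValueError("noise rates must include the 0 baseline")

    spec = _cohort_spec(cc, cc["n_train"], seed)
    framesets, lvef = prepare_framesets(
        iter_cohort(spec, image_size=cc["image_size"],
                    speckle_sigma=cc["speckle_sigma"]), pp)

    pids = sorted(framesets)
    rng = np.random.default_rng(seed + 31)
    order = rng.permutation(len(pids))
    n_test = max(4, int(round(nz["test_fraction"] * len(pids))))
    test_ids = {pids[i] for i in order[:n_test]}
    view = ViewLabel(nz["view"])
    log.warning("EF input view = %s (convention; configurable)", view.value)
    train_ds = EFDataset.from_framesets(
        {p: framesets[p] for p in pids if p not in test_ids}, lvef, view)
    test_ds = EFDataset.from_framesets(
        {p: framesets[p] for p in test_ids}, lvef, view)

    ef_cfg = EFModelConfig(**{**nz["ef_model"], "input_size": pp["size_px"],
                              "seed": seed + 57})
    curve = robustness_curve(train_ds, test_ds, framesets, rates,
                             config=ef_cfg, seed=seed + 71)
    curve.table.to_csv(out / "robustness.csv", index=False)
    (out / "robustness.json").write_text(
        curve.table.to_json(orient="records", indent=1))
    (out / "corrupted_ids.json").write_text(
        json.dumps({str(k): v for k, v in curve.corrupted_ids.items()}, indent=1))
    _write_manifest(out, config, [f"noise study over rates {rates}"])
    return out


def rerun(manifest_path: str | Path, out_dir: str | Path, study: str = "view") -> Path:
    """Repeat a run from its manifest's config snapshot."""
    manifest = json.loads(Path(manifest_path).read_text())
    driver = run_view_study if study == "view" else run_noise_study
    return driver(manifest["config"], out_dir)
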