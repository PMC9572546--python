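"""End-to-end orchestration: curate → descriptors → select → train →
evaluate → predict → filter → consensus → (optional) ic50.

Configuration is a nested mapping (YAML on disk) whose defaults encode the
screening protocol's standard settings: 1 µM activity threshold, 4:1
stratified split, 0.8 correlation-pruning threshold, 0.8 dual-confidence
threshold, −10.6 kcal/mol reference affinity and 0.8 total-score cut. Each
stage writes its artifact before the next begins and a run manifest records
the seed, the echoed config and a content hash.
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
import yaml

from . import __version__
from .bioassay import fit_plate
from .chem_io import curate_dataset, read_compounds, split_dataset, to_frame
from .descriptors import (DescriptorMatrix, Standardizer, compute_descriptors,
                          fit_chemspace)
from .evaluation import confusion_and_metrics, crossval_report, roc_auc
from .feature_selection import ThreeStageDescriptorSelector
from .qsar import EnsembleQSARClassifier, tune_hyperparameters, HyperparameterSpace
from .screening import (activity_filter, druglikeness_filter, rank_candidates,
                        read_library, score_library, write_library)
from .synthetic_data import (SynthSpec, synth_dose_response,
                             synth_qsar_dataset, synth_screening_library)

logger = logging.getLogger("jnkscreen.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and partial-output location."""

    def __init__(self, stage: str, outdir: Path, cause: Exception):
        super().__init__(f"stage {stage!r} failed ({cause}); "
                         f"partial outputs in {outdir}")
        self.stage = stage


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthetic": {
        "qsar": {"n_active": 1138, "n_inactive": 285, "n_features": 208,
                 "n_constant": 12, "n_duplicated": 20, "n_independent": 30,
                 "effect_size": 1.0},
        "library": {"n": 4112, "fraction_dual_high": 343 / 4112,
                    "admet_pass_fraction": 22 / 343,
                    "energy_range_kcal": [-9.5, -6.0]},
        "dose_response": {"ic50_um": [15.0, 60.0, 80.0], "hill": 1.0,
                          "ratio_noise_sd": 0.02},
    },
    "inputs": {"compounds": None, "descriptors": None, "library": None},
    "curation": {"threshold_um": 1.0},
    "split": {"ratio": [4, 1], "stratify": True},
    "selection": {"variance_epsilon": 0.0, "mi_epsilon": "auto",
                  "correlation_threshold": 0.8},
    "qsar": {"tune": False, "budget": 50, "folds": 10, "meta_folds": 5},
    "evaluation": {"folds": 10, "threshold": 0.5},
    "screening": {"confidence_threshold": 0.8, "total_score_threshold": 0.8,
                  "reference_energy_kcal": -10.6},
    "stages": {"curate": True, "descriptors": True, "select": True,
               "train": True, "evaluate": True, "predict": True,
               "filter_activity": True, "filter_druglikeness": True,
               "consensus": True, "ic50": False},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            config = _deep_merge(config, yaml.safe_load(fh) or {})
    if overrides:
        config = _deep_merge(config, overrides)
    return config


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: dict | None = None, outdir: str | Path = "run_output") -> dict:
    """Run the enabled stages in order; returns artifact paths and key results."""
    config = _deep_merge(DEFAULT_CONFIG, config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stages = config["stages"]
    results: dict = {"outdir": str(outdir)}
    t_start = time.time()

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)

    current = "setup"
    try:
        # ---- inputs (synthetic unless files are supplied) ----------------
        current = "curate"
        synth = None
        if config["inputs"]["compounds"]:
            records, rejects = read_compounds(config["inputs"]["compounds"])
        else:
            synth = synth_qsar_dataset(SynthSpec(seed=seed,
                                                 **config["synthetic"]["qsar"]))
            records = synth.records
        if stages["curate"]:
            curated, report = curate_dataset(
                records, threshold_um=config["curation"]["threshold_um"])
            to_frame(curated).to_csv(outdir / "curated.csv", index=False)
            results["curation"] = {"n_kept": report.n_kept,
                                   "n_active": report.n_active,
                                   "n_inactive": report.n_inactive}
            logger.info("curate: kept %d (%d active / %d inactive)",
                        report.n_kept, report.n_active, report.n_inactive)
        else:
            curated = list(records)

        current = "descriptors"
        if stages["descriptors"]:
            if synth is not None:
                matrix = synth.matrix
            elif config["inputs"]["descriptors"]:
                matrix = DescriptorMatrix.read_csv(config["inputs"]["descriptors"])
            else:
                matrix, _ = compute_descriptors(curated)
            keep = [cid for cid in matrix.compound_ids
                    if cid in {r.compound_id for r in curated}]
            frame = matrix.to_frame().loc[keep]
            matrix = DescriptorMatrix.from_frame(frame)
            matrix.write_csv(outdir / "descriptors.csv")
            labels = np.array(
                [1 if r.label == "active" else 0 for r in curated
                 if r.compound_id in set(matrix.compound_ids)])
        else:
            raise PipelineError("descriptors", outdir,
                                ValueError("descriptor stage cannot be disabled"))

        current = "split"
        split = split_dataset(curated, ratio=tuple(config["split"]["ratio"]),
                              seed=seed, stratify=config["split"]["stratify"])
        pd.DataFrame({
            "compound_id": split.train_ids + split.test_ids,
            "subset": ["train"] * len(split.train_ids) + ["test"] * len(split.test_ids),
        }).to_csv(outdir / "split.csv", index=False)
        id_to_row = {cid: i for i, cid in enumerate(matrix.compound_ids)}
        train_rows = [id_to_row[c] for c in split.train_ids]
        test_rows = [id_to_row[c] for c in split.test_ids]
        frame = matrix.to_frame()
        X_train_raw = DescriptorMatrix.from_frame(frame.iloc[train_rows])
        X_test_raw = DescriptorMatrix.from_frame(frame.iloc[test_rows])
        y_train = labels[train_rows]
        y_test = labels[test_rows]

        current = "select"
        standardizer = Standardizer().fit(X_train_raw)
        X_train_std = standardizer.transform(X_train_raw)
        X_test_std = standardizer.transform(X_test_raw)
        if stages["select"]:
            sel_cfg = config["selection"]
            selector = ThreeStageDescriptorSelector(
                variance_epsilon=sel_cfg["variance_epsilon"],
                mi_epsilon=sel_cfg["mi_epsilon"],
                correlation_threshold=sel_cfg["correlation_threshold"],
                random_state=seed).fit(X_train_std, y_train)
            selector.report_.write_csv(outdir / "selection_report.csv")
            X_train = selector.transform(X_train_std)
            X_test = selector.transform(X_test_std)
            results["selection"] = {"n_kept": len(selector.report_.kept)}
            logger.info("select: %d -> %d descriptors",
                        matrix.shape[1], len(selector.report_.kept))
        else:
            X_train, X_test = X_train_std, X_test_std

        chemspace = fit_chemspace(X_train, n_components=2)
        coords = chemspace.transform(X_train)
        flags, _ = chemspace.applicability_domain(X_train)
        coords["in_domain"] = flags
        coords.to_csv(outdir / "chemspace_train.csv")

        current = "train"
        hyperparameters = None
        if stages["train"]:
            if config["qsar"]["tune"]:
                space = HyperparameterSpace(budget=config["qsar"]["budget"],
                                            seed=seed)
                tuned = tune_hyperparameters(X_train, y_train, space,
                                             folds=config["qsar"]["folds"])
                hyperparameters = {m: tuned[m]["params"] for m in tuned}
                with open(outdir / "hyperparameters.yaml", "w") as fh:
                    yaml.safe_dump(hyperparameters, fh)
            model = EnsembleQSARClassifier(
                hyperparameters=hyperparameters,
                meta_folds=config["qsar"]["meta_folds"],
                random_state=seed).fit(X_train, y_train)
        else:
            model = None

        current = "evaluate"
        if stages["evaluate"] and model is not None:
            rows = []
            for fusion in ("voting", "stacking"):
                cv = crossval_report(
                    EnsembleQSARClassifier(hyperparameters=hyperparameters,
                                           fusion=fusion,
                                           meta_folds=config["qsar"]["meta_folds"],
                                           random_state=seed),
                    X_train, y_train, folds=config["evaluation"]["folds"],
                    seed=seed, threshold=config["evaluation"]["threshold"])
                mean_row = cv[cv["fold"] == "mean"].iloc[0]
                conf = (model.voting_confidence(X_test) if fusion == "voting"
                        else model.stacking_confidence(X_test))
                test_metrics = confusion_and_metrics(
                    y_test, conf, threshold=config["evaluation"]["threshold"])
                test_auc, _ = roc_auc(y_test, conf)
                rows.append({"model": fusion, "context": "train_cv",
                             **{k: mean_row[k] for k in
                                ("accuracy", "precision", "recall", "f1", "auc")}})
                rows.append({"model": fusion, "context": "test",
                             **test_metrics.to_dict() | {"auc": test_auc}})
            metrics = pd.DataFrame(rows)
            metrics.to_csv(outdir / "metrics.csv", index=False)
            results["metrics"] = metrics
            logger.info("evaluate: voting test AUC %.3f",
                        metrics[(metrics["model"] == "voting")
                                & (metrics["context"] == "test")]["auc"].iloc[0])

        current = "predict"
        if stages["predict"] and model is not None:
            predictions = model.predict_confidence(X_test)
            predictions.to_csv(outdir / "predictions.csv")
            results["predictions"] = predictions

        # ---- screening funnel -------------------------------------------
        current = "filter_activity"
        if config["inputs"]["library"]:
            library = read_library(config["inputs"]["library"])
        else:
            library, lib_manifest = synth_screening_library(
                seed=seed, **config["synthetic"]["library"])
            with open(outdir / "library_manifest.yaml", "w") as fh:
                yaml.safe_dump({k: v for k, v in lib_manifest.items()
                                if k != "admet_violations"}, fh)
        write_library(library, outdir / "library.csv")
        funnel = {"library": len(library)}
        survivors = library
        if stages["filter_activity"]:
            survivors, counts = activity_filter(
                survivors, threshold=config["screening"]["confidence_threshold"])
            funnel["activity_filter"] = counts["passed"]
        current = "filter_druglikeness"
        if stages["filter_druglikeness"]:
            survivors, tally = druglikeness_filter(survivors)
            funnel["druglikeness_filter"] = tally["passed"]
        results["funnel"] = funnel
        logger.info("screening funnel: %s", funnel)

        current = "consensus"
        if stages["consensus"]:
            score_library(survivors,
                          reference_energy_kcal=config["screening"]["reference_energy_kcal"])
            ranked, selected = rank_candidates(
                survivors,
                select_threshold=config["screening"]["total_score_threshold"])
            ranked.to_csv(outdir / "ranked.csv", index=False)
            results["ranked"] = ranked
            results["n_selected"] = len(selected)
            funnel["selected"] = len(selected)

        current = "ic50"
        if stages["ic50"]:
            dr_cfg = config["synthetic"]["dose_response"]
            rows = []
            for i, planted in enumerate(dr_cfg["ic50_um"]):
                readings = synth_dose_response(
                    ic50_um=planted, hill=dr_cfg["hill"],
                    ratio_noise_sd=dr_cfg["ratio_noise_sd"], seed=seed + i)
                curve = fit_plate(readings)
                rows.append({"compound": f"candidate_{i + 1}",
                             "planted_ic50_um": planted,
                             "ic50_um": curve.ic50_um,
                             "censored": curve.censored,
                             "censor_bound_um": curve.censor_bound_um,
                             "hill": curve.hill_slope, "top": curve.top,
                             "bottom": curve.bottom,
                             "converged": curve.converged})
            ic50_frame = pd.DataFrame(rows)
            ic50_frame.to_csv(outdir / "ic50.csv", index=False)
            results["ic50"] = ic50_frame
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 — surfaced with stage context
        raise PipelineError(current, outdir, exc) from exc

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "elapsed_s": round(time.time() - t_start, 2),
        "funnel": results.get("funnel"),
    }
    with open(outdir / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    results["manifest"] = manifest
    return results
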