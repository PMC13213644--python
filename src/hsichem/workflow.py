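"""End-to-end pipeline orchestration with a reproducibility manifest.

``run_pipeline`` executes the requested stages in order on synthetic data —
simulate, calibrate, classify, quantify, screen, map — writing the standard
report tables (chain x model classification accuracies; constituent x model x
selector calibration/prediction results), trained model archives, rendered
maps and a JSON manifest that records the configuration hash, seeds and
library versions.  A stage failure aborts with the stage name and cause;
outputs of completed stages are retained.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .evaluation import (
    SplitPlan,
    classification_report_grid,
    quantification_report,
    regression_metrics,
    stratified_split,
)
from .hsi_io import calibrate_reflectance, threshold_mask, write_envi
from .mapping import predict_pixel_map, render_map
from .metabolomics import anova_fc_screen, filter_features, plsda_fit
from .models import (
    ClassifierSpec,
    ELMConfig,
    LSSVMConfig,
    elm_train,
    lssvm_train,
    save_model,
)
from .preprocess import chain_from_name
from .selection import (
    CARSConfig,
    FrogConfig,
    SPAConfig,
    cars_select,
    random_frog_select,
    spa_select,
    variable_reduction,
)
from .synthetic import (
    SimulationConfig,
    simulate_feature_table,
    simulate_hypercube,
    simulate_spectrum_set,
)

__all__ = ["RunConfig", "StageError", "run_pipeline"]

ALL_STAGES = ("simulate", "calibrate", "classify", "quantify", "screen", "map")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Serialized config + seed fully determine all outputs."""

    output_dir: str = "runs/demo"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    simulation: SimulationConfig | None = None
    chains: tuple[str, ...] = ("Raw", "SNV", "2ndD-SG")
    classifiers: tuple[str, ...] = ("LR", "SVM")
    analytes: tuple[str, ...] = ("norisoboldine",)
    selectors: tuple[str, ...] = ("CARS",)
    quant_chain: str = "SNV"
    frog_iterations: int = 300         # scaled-down demo default
    cube_shape: tuple[int, int] = (24, 24)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _select(name, X, y, seed, frog_iterations):
    if name == "CARS":
        return cars_select(X, y, CARSConfig(seed=seed))
    if name == "SPA":
        return spa_select(X, y, SPAConfig(m_max=min(50, X.shape[0] // 2)))
    if name == "RF":
        return random_frog_select(
            X, y, FrogConfig(n_iterations=frog_iterations, seed=seed)
        )
    raise ValueError(f"unknown selector {name!r}")


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages; returns the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
        "outputs": [],
    }
    sim = config.simulation
    spectra_set = None
    best_models: dict[str, object] = {}

    def _record(stage, t0, files):
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        manifest["outputs"].extend(str(f) for f in files)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    try:
        if "simulate" in config.stages:
            t0 = time.time()
            spectra_set = simulate_spectrum_set(sim)
            spectra_set.to_csv(out / "spectra.csv")
            _record("simulate", t0, [out / "spectra.csv"])

        if "calibrate" in config.stages:
            t0 = time.time()
            rows, cols = config.cube_shape
            layout = np.full((rows, cols), "", dtype=object)
            third = cols // 3
            layout[2:-2, 1:third] = "tuberous"
            layout[2:-2, third + 1 : 2 * third] = "taproot"
            layout[2:-2, 2 * third + 1 : cols - 1] = "old"
            raw, refs, truth = simulate_hypercube(sim, layout)
            cube = calibrate_reflectance(raw, refs)
            hdr = write_envi(out / "cube_reflectance", cube)
            np.savez(out / "cube_truth.npz", **{
                "labels": truth["labels"],
                "concentrations": truth["concentrations"],
            })
            manifest["stages"].setdefault("calibrate", {})
            _record("calibrate", t0, [hdr, out / "cube_truth.npz"])
            run_cube, run_truth = cube, truth
        else:
            run_cube = run_truth = None

        if "classify" in config.stages:
            t0 = time.time()
            if spectra_set is None:
                spectra_set = simulate_spectrum_set(sim)
            chains = [chain_from_name(c) for c in config.chains]
            specs = [ClassifierSpec(kind=k, seed=config.seed)
                     for k in config.classifiers]
            grid = classification_report_grid(
                spectra_set.spectra, spectra_set.labels, chains, specs,
                SplitPlan(seed=config.seed), seed=config.seed,
            )
            grid.to_csv(out / "classification_accuracy.csv")
            _record("classify", t0, [out / "classification_accuracy.csv"])

        if "quantify" in config.stages:
            t0 = time.time()
            if spectra_set is None:
                spectra_set = simulate_spectrum_set(sim)
            chain = chain_from_name(config.quant_chain)
            X = chain(spectra_set.spectra)
            results = []
            sel_rows = []
            for analyte in config.analytes:
                y = spectra_set.concentrations[analyte].to_numpy()
                cal_idx, pred_idx = _two_to_one_split(
                    spectra_set.labels, config.seed
                )
                for sel_name in config.selectors:
                    subset = _select(sel_name, X[cal_idx], y[cal_idx],
                                     config.seed, config.frog_iterations)
                    sel_rows.append({
                        "constituent": analyte, "selection": sel_name,
                        "n_ews": len(subset),
                        "reduction_pct": variable_reduction(X.shape[1], subset),
                    })
                    for model_name, trainer in (
                        ("LSSVM", lambda a, b: lssvm_train(a, b, LSSVMConfig())),
                        ("ELM", lambda a, b: elm_train(
                            a, b, ELMConfig(seed=config.seed))),
                    ):
                        model = trainer(X[cal_idx][:, subset.indices], y[cal_idx])
                        cal_pred = model.predict(X[cal_idx][:, subset.indices])
                        tst_pred = model.predict(X[pred_idx][:, subset.indices])
                        results.append({
                            "constituent": analyte, "model": model_name,
                            "selection": sel_name, "n_ews": len(subset),
                            "calibration": regression_metrics(y[cal_idx], cal_pred),
                            "prediction": regression_metrics(y[pred_idx], tst_pred),
                        })
                        if analyte not in best_models:
                            best_models[analyte] = (model, subset, chain)
            import pandas as pd

            quantification_report(results).to_csv(
                out / "quantification_results.csv", index=False
            )
            pd.DataFrame(sel_rows).to_csv(out / "selected_wavelengths.csv",
                                          index=False)
            files = [out / "quantification_results.csv",
                     out / "selected_wavelengths.csv"]
            for analyte, (model, subset, chain_) in best_models.items():
                model.chain = chain_
                model.subset = subset
                model.wavelengths = spectra_set.wavelengths
                files.append(save_model(model, out / f"model_{analyte}.pkl"))
            _record("quantify", t0, files)

        if "screen" in config.stages:
            t0 = time.time()
            table = simulate_feature_table(seed=config.seed)
            filtered = filter_features(table)
            diff = anova_fc_screen(filtered)
            diff.table.to_csv(out / "differential_features.csv")
            plsda = plsda_fit(filtered, seed=config.seed)
            (out / "plsda_summary.json").write_text(json.dumps({
                "n_components": plsda.n_components, "R2X": plsda.r2x,
                "R2Y": plsda.r2y, "Q2": plsda.q2,
            }, indent=2))
            _record("screen", t0,
                    [out / "differential_features.csv", out / "plsda_summary.json"])

        if "map" in config.stages:
            t0 = time.time()
            if run_cube is None:
                raise ValueError("map stage requires the calibrate stage")
            if not best_models:
                raise ValueError("map stage requires the quantify stage")
            analyte, (model, subset, chain) = next(iter(best_models.items()))
            mask = threshold_mask(run_cube, 800.0)
            cmap = predict_pixel_map(run_cube, model, mask, analyte=analyte)
            cmap.to_csv(out / f"map_{analyte}.csv")
            render_map(cmap, out / f"map_{analyte}.png")
            _record("map", t0,
                    [out / f"map_{analyte}.csv", out / f"map_{analyte}.png"])
    except StageError:
        raise
    except Exception as exc:
        stage = next((s for s in config.stages if s not in manifest["stages"]),
                     "unknown")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        raise StageError(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _two_to_one_split(labels, seed: int):
    """Stratified 2:1 calibration/prediction split (the quantitative scheme)."""
    cal, pred = stratified_split(labels, SplitPlan(fractions=(2 / 3, 1 / 3),
                                                   seed=seed))
    return cal, pred
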