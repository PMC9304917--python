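"""Configuration-driven orchestration of the full screening pipeline.

Stages run in the fixed order synth -> preprocess -> split -> latent ->
twodcos -> rescnn -> oplsvip -> quant -> netfilter; any stage can be toggled
off, and a stage failure aborts with the stage name attached. The report
mirrors the tables a part-discrimination study prints: a PLS-DA diagnostics
block, per-class classification metrics, OPLS-DA R2X/R2Y/Q2 with the VIP
table, CNN training curves and external confusion matrix, quantification
tables, and network-pharmacology summaries.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import poriascreen
from poriascreen import latent, netfilter, oplsvip, preprocess, quant, rescnn, split
from poriascreen import twodcos as tdc
from poriascreen._seeds import stream
from poriascreen.spectra import PORIA
from poriascreen.synth import (
    CalibrationConfig,
    PeakTableConfig,
    SynthConfig,
    generate_calibration_set,
    generate_peak_table,
    generate_spectra,
)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str | None = None
    stages: dict = field(
        default_factory=lambda: {
            "latent": True,
            "twodcos": True,
            "rescnn": True,
            "oplsvip": True,
            "quant": True,
            "netfilter": True,
        }
    )
    synth: SynthConfig = field(default_factory=SynthConfig)
    peaks: PeakTableConfig = field(default_factory=PeakTableConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    net: rescnn.NetConfig = field(default_factory=rescnn.NetConfig)
    train_fraction: float = 2 / 3
    n_lv: int = 4
    n_permutations: int = 200
    cv_folds: int = 7
    n_ortho: int = 1
    external_fraction: float = 0.10
    map_grid: int = 64

    def __post_init__(self) -> None:
        # propagate the pipeline seed into sub-configs left at their default
        for sub in (self.synth, self.peaks, self.calibration, self.net):
            if sub.seed == 0:
                sub.seed = self.seed

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        seed = d.get("seed", 0)
        kwargs: dict = {"seed": seed}
        for key, sub in (
            ("synth", SynthConfig),
            ("peaks", PeakTableConfig),
            ("calibration", CalibrationConfig),
            ("net", rescnn.NetConfig),
        ):
            params = dict(d.get(key, {}))
            params.setdefault("seed", seed)
            kwargs[key] = sub(**params)
        for key in (
            "outdir", "stages", "train_fraction", "n_lv", "n_permutations",
            "cv_folds", "n_ortho", "external_fraction", "map_grid",
        ):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return [_jsonable(v) for v in sorted(obj, key=str)]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages and return the (JSON-serializable) report."""
    report: dict = {
        "version": poriascreen.__version__,
        "seed": cfg.seed,
        "config": {
            "synth": dataclasses.asdict(cfg.synth),
            "n_lv": cfg.n_lv,
            "n_permutations": cfg.n_permutations,
            "train_fraction": cfg.train_fraction,
        },
    }
    stage = "synth"
    try:
        spectra = generate_spectra(cfg.synth)
        peak_table = generate_peak_table(cfg.peaks, cfg.synth.n_per_part)
        calib = generate_calibration_set(cfg.calibration)
        report["synth"] = {
            "n_records": spectra.n_records,
            "n_grid_points": spectra.n_points,
            "n_samples": len(spectra.unique_samples()),
        }

        stage = "preprocess"
        averaged = preprocess.average_replicates(spectra)
        report["preprocess"] = {"n_averaged": averaged.n_records}

        stage = "split"
        ks = split.kennard_stone_split(averaged.absorbance, cfg.train_fraction)
        report["split"] = {
            "method": ks.method,
            "n_train": len(ks.train_ids),
            "n_test": len(ks.test_ids),
        }

        if cfg.stages.get("latent", True):
            stage = "latent"
            report["latent"] = _latent_block(averaged, ks, cfg)

        maps = None
        if cfg.stages.get("twodcos", True) or cfg.stages.get("rescnn", True):
            stage = "twodcos"
            maps = tdc.per_sample_maps(spectra, max_grid=cfg.map_grid)
            report["twodcos"] = {
                "n_samples": len(maps),
                "n_maps": 3 * len(maps),
                "grid_points": int(maps[0].sync.shape[0]),
            }

        if cfg.stages.get("rescnn", True):
            stage = "rescnn"
            report["rescnn"] = _rescnn_block(averaged, maps, cfg)

        if cfg.stages.get("oplsvip", True):
            stage = "oplsvip"
            report["oplsvip"] = _oplsvip_block(peak_table, cfg)

        if cfg.stages.get("quant", True):
            stage = "quant"
            report["quant"] = _quant_block(calib, cfg)

        if cfg.stages.get("netfilter", True):
            stage = "netfilter"
            report["netfilter"] = _netfilter_block()
    except Exception as err:  # noqa: BLE001 - re-tag with stage context
        if cfg.outdir:
            _write_report(report, cfg.outdir)  # keep partial outputs
        raise StageError(stage, err) from err

    report = _jsonable(report)
    if cfg.outdir:
        _write_report(report, cfg.outdir)
    return report


def _write_report(report: dict, outdir: str) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=1))


def _latent_block(averaged, ks, cfg: PipelineConfig) -> dict:
    X = averaged.absorbance
    y = averaged.y01()
    pca = latent.fit_pca(X, 2)
    Xtr, ytr = X[ks.train_ids], y[ks.train_ids]
    Xte, yte = X[ks.test_ids], y[ks.test_ids]
    model = latent.fit_plsda(Xtr, ytr, cfg.n_lv)
    metrics = latent.evaluate_metrics(model, Xtr, ytr, cfg.cv_folds)
    cm_tr = latent.ConfusionMatrix.from_predictions(ytr, model.predict_class(Xtr))
    cm_te = latent.ConfusionMatrix.from_predictions(yte, model.predict_class(Xte))
    perm = latent.permutation_test(
        Xtr, ytr, cfg.n_lv, cfg.n_permutations, cfg.seed, cfg.cv_folds
    )
    return {
        "pca_explained_percent": (100 * pca.explained_variance_fraction).tolist(),
        "n_lv": cfg.n_lv,
        "R2Y": metrics.R2Y,
        "Q2": metrics.Q2,
        "RMSEE": metrics.RMSEE,
        "RMSECV": metrics.RMSECV,
        "AUC": metrics.AUC,
        "train_accuracy": latent.class_metrics(cm_tr).accuracy,
        "test_accuracy": latent.class_metrics(cm_te).accuracy,
        "train_confusion": dataclasses.asdict(cm_tr),
        "test_confusion": dataclasses.asdict(cm_te),
        "permutation": {
            "n": perm.n_permutations,
            "Q2_intercept": perm.Q2_intercept,
            "R2_intercept": perm.R2_intercept,
            "valid": perm.valid,
        },
    }


def _rescnn_block(averaged, maps, cfg: PipelineConfig) -> dict:
    images = np.stack(
        [
            tdc.render_map(m.sync, cfg.net.image_size, kind="sync").pixels[:, :, 0]
            for m in maps
        ]
    )
    sid_to_part = dict(zip(averaged.sample_id.astype(str), averaged.part_label))
    labels = np.array(
        [1 if sid_to_part[m.sample_id] == PORIA else 0 for m in maps]
    )
    outer = split.random_holdout(len(maps), cfg.external_fraction, cfg.seed)
    inner_pool = np.asarray(outer.train_ids)
    flat = images[inner_pool].reshape(len(inner_pool), -1)
    inner = split.kennard_stone_split(flat, 0.8)
    inner_split = split.SplitResult(
        train_ids=[int(inner_pool[i]) for i in inner.train_ids],
        test_ids=[int(inner_pool[i]) for i in inner.test_ids],
        fraction=0.8,
        method="kennard_stone",
    )
    model, record = rescnn.train(images, labels, inner_split, cfg.net)
    ext_idx = np.asarray(outer.test_ids)
    cm, ext_acc = rescnn.external_validate(model, images[ext_idx], labels[ext_idx])
    return {
        "map_kind": "sync",
        "weighted_layers": model.weighted_layer_count,
        "n_parameters": model.n_parameters,
        "epochs_run": record.epochs_run,
        "final_train_loss": record.epoch_loss[-1],
        "final_train_accuracy": record.epoch_accuracy[-1],
        "test_accuracy": record.test_accuracy,
        "external_accuracy": ext_acc,
        "external_confusion": dataclasses.asdict(cm),
        "loss_curve": record.epoch_loss,
        "accuracy_curve": record.epoch_accuracy,
    }


def _oplsvip_block(peak_table, cfg: PipelineConfig) -> dict:
    model = oplsvip.fit_oplsda(
        peak_table, peak_table.y01(), cfg.n_ortho, folds=cfg.cv_folds
    )
    vip = oplsvip.vip_scores(model)
    return {
        "R2X": model.R2X,
        "R2Y": model.R2Y,
        "Q2": model.Q2,
        "n_ortho": model.n_ortho,
        "vip": dict(zip(map(str, vip.labels), vip.vip.tolist())),
        "selected_peaks": oplsvip.screen_biomarkers(vip),
    }


def _quant_block(calib, cfg: PipelineConfig) -> dict:
    curves = {}
    curve_rows = {}
    for a in calib.analytes:
        curve = quant.fit_calibration(a["concentration"], a["area"], a["name"])
        sd = cfg.calibration.noise_sd * (
            a["true_slope"] * a["concentration"][-1] + a["true_intercept"]
        )
        curve.lod, curve.loq = quant.lod_loq(sd, curve.slope)
        curves[a["name"]] = curve
        curve_rows[a["name"]] = {
            "slope": curve.slope,
            "intercept": curve.intercept,
            "r_squared": curve.r_squared,
            "linearity_ok": curve.linearity_ok,
            "lod": curve.lod,
            "loq": curve.loq,
        }

    # planted two-part content study for the three headline triterpenoids:
    # every analyte's true content is higher in Poria
    markers = ["poricoic acid A", "pachymic acid", "dehydrotrametenolic acid"]
    rng = stream(cfg.seed, "quant-contents")
    n = 30
    parts = np.array([PORIA] * n + ["PoriaeCutis"] * n, dtype=object)
    areas = {}
    for name in markers:
        a = calib.analyte(name)
        lo, hi = a["concentration"][0], a["concentration"][-1]
        base = np.sqrt(lo * hi)
        true = np.where(parts == PORIA, 1.4 * base, base)
        conc = true * np.exp(0.15 * rng.standard_normal(2 * n))
        areas[name] = a["true_slope"] * conc + a["true_intercept"]
    comparison = quant.quantify_and_compare(curves, pd.DataFrame(areas), parts)
    return {
        "curves": curve_rows,
        "comparison": comparison.to_dict(orient="records"),
        "poria_higher_all": bool(
            all(r.startswith(PORIA) for r in comparison["direction"])
        ),
    }


def _netfilter_block() -> dict:
    comp, edges = netfilter.load_toy_tables()
    kept = netfilter.filter_components(comp)
    g = netfilter.build_ppi(edges)
    topo = netfilter.core_targets(g)
    ranking = netfilter.degree_ranking(edges)
    return {
        "components_in": len(comp),
        "components_kept": kept["component"].tolist(),
        "ppi_nodes": g.number_of_nodes(),
        "ppi_edges": g.number_of_edges(),
        "core_targets": sorted(topo.core_targets),
        "top_degree": ranking[:5],
    }
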