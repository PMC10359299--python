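"""End-to-end orchestration of the synthetic why/how analysis.

Stages (in dependency order): ``simulate`` -> ``qc`` -> ``glm`` ->
``decode_searchlight`` -> ``discover_rois`` -> ``decode_roi`` ->
``predict`` -> ``infer`` -> ``report``.  Each stage reads the bundle
produced by its predecessors and adds its own artifacts; requesting a
stage whose inputs are missing raises :class:`DependencyError` naming
the stage to run first.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import decoding, inference, prediction, qc, synthetic
from .design import make_block_design
from .glm import build_design_matrix, contrast_image, fit_glm, social_contrast_weights
from .io import (StudyConfig, make_run_record, save_nifti,
                 write_ground_truth_json, write_json)

STAGES = ("simulate", "qc", "glm", "decode_searchlight", "discover_rois",
          "decode_roi", "predict", "infer", "report")

_REQUIRES = {
    "simulate": (),
    "qc": ("subjects",),
    "glm": ("subjects", "qc_reports"),
    "decode_searchlight": ("betas",),
    "discover_rois": ("accuracy_maps",),
    "decode_roi": ("betas", "rois"),
    "predict": ("contrasts", "rois"),
    "infer": ("roi_accuracies", "predictions"),
    "report": ("inference",),
}
_PROVIDES = {
    "simulate": "subjects", "qc": "qc_reports", "glm": "betas",
    "decode_searchlight": "accuracy_maps", "discover_rois": "rois",
    "decode_roi": "roi_accuracies", "predict": "predictions",
    "infer": "inference", "report": "report",
}


class DependencyError(RuntimeError):
    pass


def _stage_simulate(cfg: StudyConfig, state: dict) -> None:
    design = make_block_design(cfg.n_blocks_per_condition, cfg.stimuli_per_block,
                               tr=cfg.tr, targets=cfg.targets, seed=cfg.seed)
    truth = synthetic.default_ground_truth(
        grid=cfg.grid, voxel_size_mm=cfg.voxel_size_mm,
        condition_effect_gain=cfg.condition_effect_gain,
        score_encoding_gain=cfg.score_encoding_gain,
        shared_fraction=cfg.shared_fraction, noise_sd=cfg.noise_sd, seed=cfg.seed)
    state["design"] = design
    state["truth"] = truth
    state["behavior"] = synthetic.sample_behavior(cfg.n_subjects, seed=cfg.seed)
    state["subjects"] = synthetic.simulate_study(
        design, truth, cfg.n_subjects, seed=cfg.seed, behavior=state["behavior"])
    state["mask"] = np.ones(cfg.grid, dtype=bool)


def _stage_qc(cfg: StudyConfig, state: dict) -> None:
    reports = []
    for subj in state["subjects"]:
        reports.append(qc.motion_qc(subj.motion, sampling_hz=1.0 / cfg.tr,
                                    series2d=subj.series2d, mask=state["mask"],
                                    lowpass_hz=cfg.butterworth_cutoff_hz,
                                    order=cfg.butterworth_order))
    p50 = np.array([r.fd_p50 for r in reports])
    p95 = np.array([r.fd_p95 for r in reports])
    flags = (qc.flag_outlier_participants(p50, p95) if len(reports) >= 5
             else np.zeros(len(reports), dtype=bool))
    for r, f in zip(reports, flags):
        r.outlier = bool(f)
    state["qc_reports"] = reports


def _stage_glm(cfg: StudyConfig, state: dict) -> None:
    betas, contrasts = [], []
    for subj, rep in zip(state["subjects"], state["qc_reports"]):
        X = build_design_matrix(subj.design, highpass_cutoff=cfg.highpass_cutoff_s,
                                motion=subj.motion, spike_frames=rep.spikes)
        res = fit_glm(subj.series2d, X, robust=cfg.robust_wls)
        betas.append(res)
        contrasts.append(contrast_image(res, social_contrast_weights(res.names)))
    state["betas"] = betas
    state["contrasts"] = np.asarray(contrasts)


def _stage_decode_searchlight(cfg: StudyConfig, state: dict) -> None:
    maps: dict[str, list[np.ndarray]] = {t: [] for t in cfg.targets}
    for res in state["betas"]:
        pset = decoding.BetaPatternSet.from_betas(res)
        for tgt in cfg.targets:
            sub = pset.select_target(tgt)
            b4 = sub.patterns.T.reshape(*cfg.grid, -1)
            maps[tgt].append(decoding.searchlight_decode(
                b4, sub.inference, state["mask"], radius=cfg.searchlight_radius,
                cost=cfg.svm_cost))
    state["accuracy_maps"] = {t: np.asarray(m) for t, m in maps.items()}


def _stage_discover_rois(cfg: StudyConfig, state: dict) -> None:
    state["rois"] = decoding.group_roi_discovery(
        state["accuracy_maps"], state["mask"], alpha=cfg.alpha,
        cluster_k=cfg.cluster_k, seed=cfg.seed)


def _stage_decode_roi(cfg: StudyConfig, state: dict) -> None:
    out = {}
    pattern_sets = {}
    for name, mask in state["rois"].masks.items():
        flat = np.flatnonzero(mask.ravel())
        psets = [decoding.BetaPatternSet.from_betas(res, voxel_index=flat)
                 for res in state["betas"]]
        pattern_sets[name] = psets
        out[name] = np.array([decoding.roi_decode(p, cost=cfg.svm_cost) for p in psets])
    state["roi_accuracies"] = out
    state["roi_pattern_sets"] = pattern_sets


def _stage_predict(cfg: StudyConfig, state: dict) -> None:
    scores = state["behavior"]["sni_size"].to_numpy(dtype=float)
    z = prediction.zscore(scores)
    preds = {}
    for name, mask in state["rois"].masks.items():
        feats = state["contrasts"][:, mask.ravel()]
        preds[name] = prediction.lopo_svr(feats, z, nu=cfg.svr_nu, cost=cfg.svr_cost)
    state["predictions"] = preds
    state["prediction_labels"] = z


def _stage_infer(cfg: StudyConfig, state: dict) -> None:
    results = {}
    z = state["prediction_labels"]
    for name, res in state["predictions"].items():
        feats = state["contrasts"][:, state["rois"].masks[name].ravel()]
        null = inference.null_svr(feats, z, n_perm=cfg.n_perm, seed=cfg.seed,
                                  nu=cfg.svr_nu, cost=cfg.svr_cost)
        p, sig = inference.perm_pvalue(res.r, null, cfg.significance_percentile)
        res.p = p
        res.null_q5 = null.percentile(5)
        res.null_q95 = null.percentile(95)
        results[name] = {"r": res.r, "r2": res.r2, "p": p, "significant": sig,
                         "null_q5": res.null_q5, "null_q95": res.null_q95}
    if results:
        reject, p_adj = inference.fdr_correct([v["p"] for v in results.values()],
                                              q=cfg.fdr_q)
        for (name, v), rej, pa in zip(results.items(), reject, p_adj):
            v["fdr_significant"] = bool(rej)
            v["p_adjusted"] = float(pa)
    state["inference"] = results


def _stage_report(cfg: StudyConfig, state: dict) -> None:
    roi_rows = [{"roi": name,
                 "mean_accuracy_pct": float(np.mean(acc)),
                 "n_voxels": int(state["rois"].masks[name].sum())}
                for name, acc in state["roi_accuracies"].items()]
    pred_rows = [{"roi": name, **{k: v for k, v in stats_.items()}}
                 for name, stats_ in state["inference"].items()]
    state["report"] = {"config_digest": cfg.digest(), "seed": cfg.seed,
                       "n_subjects": cfg.n_subjects,
                       "roi_decoding": roi_rows, "roi_prediction": pred_rows,
                       "qc_outliers": [bool(r.outlier) for r in state["qc_reports"]]}


_RUNNERS = {
    "simulate": _stage_simulate, "qc": _stage_qc, "glm": _stage_glm,
    "decode_searchlight": _stage_decode_searchlight,
    "discover_rois": _stage_discover_rois, "decode_roi": _stage_decode_roi,
    "predict": _stage_predict, "infer": _stage_infer, "report": _stage_report,
}


def run_pipeline(config: StudyConfig, stages=None, outdir=None,
                 state: dict | None = None) -> dict:
    """Execute the requested stages in dependency order.

    ``state`` carries artifacts between calls; omitting it runs from a
    clean bundle.  When ``outdir`` is given, key artifacts (ROI masks,
    accuracy maps, report) are written there with provenance records.
    """
    state = {} if state is None else state
    todo = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = (set(stages) - set(STAGES)) if stages is not None else set()
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for stage in todo:
        missing = [k for k in _REQUIRES[stage] if k not in state]
        if missing:
            producers = sorted({s for s, p in _PROVIDES.items()
                                for k in missing if p == k})
            raise DependencyError(
                f"stage {stage!r} needs {missing}; run {producers} first")
        _RUNNERS[stage](config, state)
    if outdir is not None:
        _write_artifacts(config, state, Path(outdir))
    return state


def _write_artifacts(cfg: StudyConfig, state: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    vs = cfg.voxel_size_mm
    if "accuracy_maps" in state:
        for tgt, stack in state["accuracy_maps"].items():
            path = outdir / f"accuracy_{tgt}.nii.gz"
            save_nifti(path, np.moveaxis(stack, 0, -1), voxel_size=vs)
            written.append(path)
    if "rois" in state:
        for name, mask in state["rois"].masks.items():
            path = outdir / f"roi_{name}.nii.gz"
            save_nifti(path, mask.astype(np.uint8), voxel_size=vs)
            written.append(path)
    if "contrasts" in state:
        path = outdir / "social_contrast.nii.gz"
        stack = state["contrasts"].T.reshape(*cfg.grid, -1)
        save_nifti(path, stack, voxel_size=vs)
        written.append(path)
    if "truth" in state:
        path = outdir / "ground_truth.json"
        write_ground_truth_json(path, state["truth"])
        written.append(path)
    if "predictions" in state:
        import pandas as pd

        for name, res in state["predictions"].items():
            path = outdir / f"prediction_{name}.tsv"
            pd.DataFrame({"observed": res.observed,
                          "predicted": res.predicted}).to_csv(path, sep="\t",
                                                              index=False)
            written.append(path)
    if "report" in state:
        path = outdir / "report.json"
        write_json(path, state["report"])
        written.append(path)
    if written:
        record = make_run_record(cfg, stage="pipeline", output_paths=written)
        write_json(outdir / "run_record.json", record.to_dict())
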