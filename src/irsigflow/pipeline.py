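"""Stage orchestration: simulate -> gate -> signatures -> citrus -> betaperm
-> pls -> plsda -> report, with stable on-disk artifacts and a JSON run report.

Each stage reads only the artifacts of earlier stages from the output
directory, so stages can be re-run independently; a missing upstream artifact
raises an error naming the stage to run first. All tabular artifacts are TSV,
reports are JSON, and every file layout is deterministic under a fixed seed.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .betareg import apply_thresholds, fit_all_subsets, minp_thresholds
from .citrus import cluster_features, pamr_fit_cv, pool_and_cluster, sam_select
from .config import RunConfig
from .events import EventMatrix, default_channel_roles, downsample
from .gating import build_signature_table, combo_columns
from .pls import fit_pls, orthogonal_rotate, permutation_significance, vip_scores
from .synthetic import generate_cohort, generate_supernatant

logger = logging.getLogger(__name__)

STAGES = ("simulate", "gate", "signatures", "citrus", "betaperm", "pls", "plsda", "report")


class PipelineError(RuntimeError):
    pass


def _require(path: Path, stage_needed: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing artifact {path.name}; run the {stage_needed!r} stage first"
        )
    return path


def _write_json(path: Path, payload: dict) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=default))


def _load_events(out: Path) -> tuple[list[EventMatrix], list[EventMatrix]]:
    meta = json.loads(_require(out / "events_meta.json", "simulate").read_text())
    roles = default_channel_roles()
    events, fm5 = [], []
    for sid in meta["subjects"]:
        values = pd.read_csv(out / "events" / f"{sid}.csv")
        events.append(EventMatrix(sid, values, roles, meta["transform_state"], meta["cofactor"]))
    for bid in meta["fm5"]:
        values = pd.read_csv(out / "fm5" / f"{bid}.csv")
        fm5.append(EventMatrix(bid, values, roles, meta["transform_state"], meta["cofactor"]))
    return events, fm5


def _load_design(out: Path) -> pd.DataFrame:
    return pd.read_csv(_require(out / "design.tsv", "simulate"), sep="\t")


def stage_simulate(cfg: RunConfig, out: Path) -> dict:
    syn = dataclasses.replace(cfg.synthetic, seed=cfg.stage_seed("simulate"),
                              cofactor=cfg.cofactor)
    design, events, fm5, plasma = generate_cohort(syn)
    (out / "events").mkdir(parents=True, exist_ok=True)
    (out / "fm5").mkdir(parents=True, exist_ok=True)
    design.to_csv(out / "design.tsv", sep="\t", index=False)
    for m in events:
        m.values.to_csv(out / "events" / f"{m.sample_id}.csv", index=False)
    for m in fm5:
        m.values.to_csv(out / "fm5" / f"{m.sample_id}.csv", index=False)
    plasma.values.to_csv(out / "plasma.tsv", sep="\t")
    _write_json(out / "events_meta.json", {
        "subjects": [m.sample_id for m in events],
        "fm5": [m.sample_id for m in fm5],
        "transform_state": "arcsinh",
        "cofactor": syn.cofactor,
    })
    return {"n_subjects": len(design), "n_batches": len(fm5),
            "events_per_subject": syn.events_per_subject}


def stage_gate(cfg: RunConfig, out: Path) -> dict:
    from .gating import derive_gates_per_batch

    _, fm5 = _load_events(out)
    gates = derive_gates_per_batch(fm5, quantile=cfg.gate_quantile)
    rows = [
        {"batch": b, "marker": g.marker, "threshold": g.threshold, "quantile": g.quantile}
        for b, by_marker in gates.items() for g in by_marker.values()
    ]
    pd.DataFrame(rows).to_csv(out / "gates.tsv", sep="\t", index=False)
    return {"n_batches": len(gates), "quantile": cfg.gate_quantile}


def stage_signatures(cfg: RunConfig, out: Path) -> dict:
    _require(out / "gates.tsv", "gate")
    design = _load_design(out)
    events, fm5 = _load_events(out)
    rng = np.random.default_rng(cfg.stage_seed("signatures"))
    events = [downsample(m, cfg.downsample_n, rng) for m in events]
    table3 = build_signature_table(events, design, fm5, quantile=cfg.gate_quantile)
    table4 = build_signature_table(events, design, fm5, quantile=cfg.gate_quantile,
                                   combo_set=("PD-1", "TIGIT", "CD160", "TIM-3"))
    table3.to_csv(out / "signatures.tsv", sep="\t")
    table4.to_csv(out / "signatures4.tsv", sep="\t")
    syn = dataclasses.replace(cfg.synthetic, seed=cfg.stage_seed("simulate"))
    supernatant = generate_supernatant(
        design, table3["pos_TIGIT"], syn, seed=cfg.stage_seed("supernatant"))
    supernatant.values.to_csv(out / "supernatant.tsv", sep="\t")
    supernatant.cells_per_well.rename("cells_per_well").to_csv(
        out / "cells_per_well.tsv", sep="\t")
    return {"n_subjects": len(table3), "n_combo_columns": len(combo_columns(table3))}


def stage_citrus(cfg: RunConfig, out: Path) -> dict:
    design = _load_design(out)
    events, _ = _load_events(out)
    rng = np.random.default_rng(cfg.stage_seed("citrus"))
    events = [downsample(m, cfg.downsample_n, rng) for m in events]
    tree = pool_and_cluster(
        events,
        min_cluster_frac=cfg.citrus.min_cluster_frac,
        max_pooled_events=cfg.citrus.max_pooled_events,
        seed=cfg.stage_seed("citrus_pool"),
    )
    feats = cluster_features(tree)
    feats.values.to_csv(out / "cluster_features.tsv", sep="\t")
    labels = design.set_index("subject_id").loc[feats.values.index, "hiv"].to_numpy()
    pamr = pamr_fit_cv(feats, labels, n_folds=cfg.citrus.n_folds,
                       seed=cfg.stage_seed("citrus_pamr"))
    sam = sam_select(feats, labels, fdr_target=cfg.citrus.fdr_target,
                     n_perm=cfg.citrus.n_perm, seed=cfg.stage_seed("citrus_sam"))
    payload = {
        "qualifying_nodes": tree.qualifying,
        "pamr": {
            "selected_delta": pamr.selected_delta,
            "cv_accuracy": pamr.cv_accuracy,
            "selected_features": pamr.selected_features,
            "delta_grid": pamr.delta_grid,
            "cv_error": pamr.cv_error,
        },
        "sam": {
            "fdr_target": sam.fdr_target,
            "selected_features": sam.selected_features,
            "n_perm": sam.n_perm,
        },
    }
    _write_json(out / "citrus.json", payload)
    return {"n_qualifying": len(tree.qualifying),
            "pamr_cv_accuracy": pamr.cv_accuracy,
            "pamr_selected": pamr.selected_features,
            "sam_selected": sam.selected_features}


def stage_betaperm(cfg: RunConfig, out: Path) -> dict:
    design = _load_design(out)
    signatures = pd.read_csv(_require(out / "signatures.tsv", "signatures"),
                             sep="\t", index_col="subject_id")
    combos = signatures[combo_columns(signatures)].dropna()
    design_fit = design[design["subject_id"].isin(combos.index)].reset_index(drop=True)
    combos = combos.loc[design_fit["subject_id"]]
    fits = fit_all_subsets(combos, design_fit)
    thresholds = minp_thresholds(combos, design_fit, n_perm=cfg.betaperm.n_perm,
                                 seed=cfg.stage_seed("betaperm"))
    significant = apply_thresholds(fits, thresholds)
    coef_rows = []
    for subset, fit in fits.items():
        for term in ("intercept", "hiv", "age"):
            coef_rows.append({
                "subset": subset, "term": term, "estimate": fit.params[term],
                "se": fit.se[term], "z": fit.z[term], "p": fit.p[term],
                "phi": fit.phi,
            })
    pd.DataFrame(coef_rows).to_csv(out / "betareg.tsv", sep="\t", index=False)
    _write_json(out / "betaperm.json", {
        "thresholds": {t: thr.threshold for t, thr in thresholds.items()},
        "minp_distribution": {t: thr.minp_distribution for t, thr in thresholds.items()},
        "n_perm": cfg.betaperm.n_perm,
        "seed": cfg.stage_seed("betaperm"),
        "significant": significant,
    })
    return {"thresholds": {t: thr.threshold for t, thr in thresholds.items()},
            "significant": significant}


def _drop_constant(X: pd.DataFrame) -> pd.DataFrame:
    """Z-scoring needs spread; silently-absent subsets carry no signal."""
    sd = X.std(axis=0, ddof=1)
    dropped = sd[sd == 0].index.tolist()
    if dropped:
        logger.info("dropping %d zero-variance feature columns: %s", len(dropped), dropped)
    return X.loc[:, sd > 0]


def _plsr_stratum(cfg: RunConfig, X: pd.DataFrame, y: pd.Series, seed: int) -> dict:
    X = _drop_constant(X)
    a_grid = [a for a in cfg.pls.a_grid if a <= min(len(X) - 2, X.shape[1])]
    p, detail = permutation_significance(
        X, y.to_frame(), a_grid, n_perm=cfg.pls.n_perm, seed=seed,
        mode="regression", n_folds=cfg.pls.n_folds,
    )
    model = fit_pls(X, y.to_frame(), detail["a_star"], mode="regression")
    vip = vip_scores(model)
    return {
        "a_star": detail["a_star"],
        "cv_curve": {str(k): v for k, v in detail["cv_curve"].items()},
        "permutation_p": p,
        "vip": vip.to_dict(),
        "vip_gt1": vip[vip > 1].index.tolist(),
        "explained_y_fraction": model.explained_y_fraction(),
    }


def stage_pls(cfg: RunConfig, out: Path) -> dict:
    design = _load_design(out)
    signatures = pd.read_csv(_require(out / "signatures.tsv", "signatures"),
                             sep="\t", index_col="subject_id")
    plasma = pd.read_csv(_require(out / "plasma.tsv", "simulate"), sep="\t", index_col=0)
    seed = cfg.stage_seed("pls")
    result = {}
    for stratum, hiv_flag in (("uninfected", 0), ("hiv", 1)):
        subj = design.loc[design["hiv"] == hiv_flag, "subject_id"]
        subj = [s for s in subj if s in signatures.index and s in plasma.index]
        X = plasma.loc[subj]
        y = signatures.loc[subj, "pos_TIGIT"]
        result[stratum] = _plsr_stratum(cfg, X, y, seed)
    _write_json(out / "pls.json", result)
    return {s: {"permutation_p": r["permutation_p"], "a_star": r["a_star"]}
            for s, r in result.items()}


def stage_plsda(cfg: RunConfig, out: Path) -> dict:
    design = _load_design(out)
    sig4 = pd.read_csv(_require(out / "signatures4.tsv", "signatures"),
                       sep="\t", index_col="subject_id")
    plasma = pd.read_csv(_require(out / "plasma.tsv", "simulate"), sep="\t", index_col=0)
    combos = sig4[combo_columns(sig4)]
    X = _drop_constant(combos.join(plasma, how="inner").dropna())
    dd = design.set_index("subject_id").loc[X.index]
    labels = (dd["hiv"].map({0: "uninfected", 1: "hiv"}) + "_" + dd["age_group"]).to_numpy()
    seed = cfg.stage_seed("plsda")
    a_grid = [a for a in cfg.pls.a_grid if a <= min(len(X) - 2, X.shape[1])]
    p, detail = permutation_significance(
        X, labels, a_grid, n_perm=cfg.pls.n_perm, seed=seed,
        mode="discriminant", n_folds=cfg.pls.n_folds,
    )
    a_star = max(detail["a_star"], 2)
    model = fit_pls(X, labels, a_star, mode="discriminant")
    if cfg.pls.rotation_criterion != "none" and a_star >= 2:
        model = orthogonal_rotate(model, cfg.pls.rotation_criterion)
    vip = vip_scores(model)
    scores = pd.DataFrame(model.T[:, :2], index=X.index, columns=["LV1", "LV2"])
    scores.to_csv(out / "plsda_scores.tsv", sep="\t")
    payload = {
        "a_star": detail["a_star"],
        "permutation_p": p,
        "cv_curve": {str(k): v for k, v in detail["cv_curve"].items()},
        "vip": vip.to_dict(),
        "vip_gt1": vip[vip > 1].index.tolist(),
        "explained_y_fraction": model.explained_y_fraction(),
        "rotation": model.rotation,
    }
    _write_json(out / "plsda.json", payload)
    return {"permutation_p": p, "a_star": detail["a_star"],
            "n_vip_gt1": len(payload["vip_gt1"])}


def stage_report(cfg: RunConfig, out: Path) -> dict:
    report: dict = {"gaps": []}
    for name in ("citrus", "betaperm", "pls", "plsda"):
        path = out / f"{name}.json"
        if path.exists():
            report[name] = json.loads(path.read_text())
        else:
            report["gaps"].append(name)
    _write_json(out / "report.json", report)
    return {"gaps": report["gaps"]}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "gate": stage_gate,
    "signatures": stage_signatures,
    "citrus": stage_citrus,
    "betaperm": stage_betaperm,
    "pls": stage_pls,
    "plsda": stage_plsda,
    "report": stage_report,
}


def run(subcommand: str, cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run one stage or ``all``; returns the run report dict."""
    cfg.validate()
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(STAGES) if subcommand == "all" else [subcommand]
    if any(s not in _STAGE_FUNCS for s in stages):
        raise PipelineError(f"unknown subcommand {subcommand!r}")
    report = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }
    for stage in stages:
        logger.info("running stage %s (sub-seed %d)", stage, cfg.stage_seed(stage))
        report["stages"][stage] = _STAGE_FUNCS[stage](cfg, out)
    _write_json(out / "run_report.json", report)
    return report
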