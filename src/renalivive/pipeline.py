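"""End-to-end orchestration: raw tables in, fit reports and predictions out.

The pipeline runs the stages in their natural order — binding, uptake
kinetics, facilitated-dissociation fits, the empirical log-log regression,
REF/RAF-scaled prediction of renal clearance, and accuracy metrics — and
serialises every stage's result to the output directory (CSV tables and a
JSON report).  Inputs default to the packaged study tables; raw
replicate-level data can be supplied as delimited text instead.

Raw-input schemas (CSV):

* binding: substrate, albumin_g_per_dl, replicate_id, fu
* time courses: substrate, line, condition, replicate, time_min,
  amount_pmol_per_mg, unbound_um
* observed clinical references: substrate, observed_clr_ml_min[, fu_b]
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets
from .binding import BindingMeasurement, fit_kd
from .domain import (AlbuminCondition, PhysiologyConstants, OAT1, OAT3,
                     CONDITION_PROBENECID)
from .fdmodel import fit_fd_full, fit_fd_reduced
from .ivive import ScalerSet, predict_renal_clearance
from .metrics import summarize_accuracy
from .regression import ess_f_test, loglog_fit
from .uptake import (UptakeTimecourse, albumin_ratio, clint_u,
                     decompose_active, fit_uptake_slope)

__all__ = ["RunConfig", "PipelineError", "run_pipeline",
           "read_binding_csv", "read_timecourse_csv",
           "process_timecourses", "fit_binding_panel",
           "predict_panel", "evaluate_against_observed"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    binding_csv: str | None = None      # raw replicate binding data
    timecourse_csv: str | None = None   # raw uptake time courses
    observed_csv: str | None = None     # clinical references for evaluation
    scaler_mode: str = "REF"            # REF or RAF
    hsa_level: str = "hsa_4pct"         # condition used for IVIVE
    kd_weighting: str = "relative"
    fd_residual_scale: str = "log"
    physiology: PhysiologyConstants = field(default_factory=PhysiologyConstants)
    outdir: str | None = None
    seed: int = 0


# ---------------------------------------------------------------------------
# raw-input readers

def read_binding_csv(path) -> list[BindingMeasurement]:
    df = pd.read_csv(path)
    out = []
    for (sub, pct), grp in df.groupby(["substrate", "albumin_g_per_dl"]):
        cond = (AlbuminCondition.control() if pct == 0
                else AlbuminCondition.hsa(float(pct)))
        out.append(BindingMeasurement(sub, cond, grp["fu"].tolist()))
    return out


def read_timecourse_csv(path) -> list[UptakeTimecourse]:
    df = pd.read_csv(path)
    out = []
    keys = ["substrate", "line", "condition", "replicate"]
    for (sub, line, cond, rep), grp in df.groupby(keys):
        grp = grp.sort_values("time_min")
        out.append(UptakeTimecourse(
            substrate=sub, transporter_line=line, condition=cond,
            replicate_id=int(rep),
            points=list(zip(grp["time_min"], grp["amount_pmol_per_mg"])),
            unbound_conc=float(grp["unbound_um"].iloc[0]),
        ))
    return out


# ---------------------------------------------------------------------------
# stages

def fit_binding_panel(measurements: list[BindingMeasurement],
                      weighting: str = "relative") -> dict:
    """Per-substrate K_d fits; returns substrate -> KdFit."""
    by_sub: dict[str, list] = {}
    for m in measurements:
        by_sub.setdefault(m.substrate, []).append(m)
    fits = {}
    for sub, ms in sorted(by_sub.items()):
        try:
            fits[sub] = fit_kd(ms, weighting=weighting)
        except ValueError as exc:
            raise PipelineError("binding", f"{sub}: {exc}") from exc
    return fits


def process_timecourses(
    timecourses: list[UptakeTimecourse],
    include_intercept: bool = True,
) -> tuple[dict, dict]:
    """Slopes -> clearances -> active decomposition -> albumin ratios.

    Returns ``(clearance_sets, ratio_results)`` keyed by
    ``(substrate, line)``; ratio_results values map HSA condition ->
    RatioResult.
    """
    groups: dict[tuple, dict[str, dict[int, float]]] = {}
    for tc in timecourses:
        slope = fit_uptake_slope(tc, include_intercept=include_intercept)
        cl = clint_u(slope.slope, tc.unbound_conc)
        key = (tc.substrate, tc.transporter_line)
        groups.setdefault(key, {}).setdefault(tc.condition, {})[tc.replicate_id] = cl

    clearance_sets, ratios = {}, {}
    for key, conds in groups.items():
        sub, line = key
        if CONDITION_PROBENECID not in conds:
            raise PipelineError(
                "uptake", f"{sub}/{line}: no probenecid condition — the "
                "passive-clearance input is missing")
        passive = [v for _, v in sorted(conds[CONDITION_PROBENECID].items())]
        total = {c: [v for _, v in sorted(reps.items())]
                 for c, reps in conds.items() if c != CONDITION_PROBENECID}
        cs = decompose_active(total, passive, substrate=sub,
                              transporter_line=line)
        clearance_sets[key] = cs
        ratios[key] = {}
        control = cs.clint_u_active.get("control")
        if control is None or np.any(control <= 0):
            continue
        for cond, active in cs.clint_u_active.items():
            if cond == "control":
                continue
            ratios[key][cond] = albumin_ratio(
                active, control, substrate=sub, transporter_line=line,
                hsa_level=cond, paired=len(active) == len(control))
    return clearance_sets, ratios


def table_fd_fits(residual_scale: str = "log") -> dict:
    """Facilitated-dissociation fits on the packaged study tables."""
    oat3_r = datasets.ratio_series_from_tables(OAT3)
    oat1_subs = ("olmesartan", "bumetanide", "4-pyridoxic acid")
    oat1_r = datasets.ratio_series_from_tables(OAT1, substrates=oat1_subs)
    reduced_oat3 = fit_fd_reduced(oat3_r, residual_scale=residual_scale)
    reduced_oat1 = fit_fd_reduced(oat1_r, kdm_fixed=reduced_oat3.kdm,
                                  residual_scale=residual_scale)
    full_oat3 = fit_fd_full(datasets.fd_series_from_tables(OAT3),
                            residual_scale=residual_scale)
    full_oat1 = fit_fd_full(
        datasets.fd_series_from_tables(OAT1, substrates=oat1_subs),
        kdm_fixed=full_oat3.kdm, residual_scale=residual_scale)
    return {"reduced_oat3": reduced_oat3, "reduced_oat1": reduced_oat1,
            "full_oat3": full_oat3, "full_oat1": full_oat1}


def table_regressions() -> dict:
    """Log-log fits of R on f_u,inc from the packaged tables, plus the
    between-transporter F-test."""
    binding = datasets.load_binding_table().set_index("substrate")
    cl = datasets.load_clearance_table()
    data = {}
    for transporter in (OAT1, OAT3):
        sub_tbl = cl[cl["transporter"] == transporter]
        fu, r = [], []
        for _, row in sub_tbl.iterrows():
            b = binding.loc[row["substrate"]]
            fu += [b["fu_1pct_mean"], b["fu_4pct_mean"]]
            r += [row["r_1pct_mean"], row["r_4pct_mean"]]
        data[transporter] = (fu, r)
    fits = {t: loglog_fit(fu, r, transporter=t) for t, (fu, r) in data.items()}
    ftest = ess_f_test(*data[OAT1], *data[OAT3])
    return {"fits": fits, "f_test": ftest}


def load_scalers() -> dict:
    tbl = datasets.load_scaler_table()
    out = {}
    for _, row in tbl.iterrows():
        out[row["transporter"]] = ScalerSet(
            transporter=row["transporter"],
            abundance_invivo=row["abundance_invivo_mean"],
            abundance_invitro=row["abundance_invitro_mean"],
            clint_invivo_ref=row["clint_invivo_ref"],
            clint_invitro_ref=row["clint_invitro_ref_mean"],
            reference_probe=row["reference_probe"],
        )
    return out


_COND_COLUMN = {"control": "clint_control_mean", "hsa_1pct": "clint_1pct_mean",
                "hsa_4pct": "clint_4pct_mean"}


def predict_panel(
    mode: str = "REF",
    hsa_level: str = "hsa_4pct",
    phys: PhysiologyConstants | None = None,
    observed: dict | None = None,
    fu_b: dict | None = None,
) -> dict:
    """Bottom-up renal-clearance predictions for the packaged panel.

    For substrates without a reported plasma fraction unbound, the
    incubation value at 4% HSA stands in (the two agree within ~1.5-fold
    for this panel).  In RAF mode the probe substrates are excluded — their
    clinical data define the scaler.
    """
    phys = phys or PhysiologyConstants()
    scalers = load_scalers()
    panel = datasets.load_substrate_panel()
    binding = datasets.load_binding_table().set_index("substrate")
    cl = datasets.load_clearance_table()
    col = _COND_COLUMN[hsa_level]

    predictions = {}
    for sub, record in panel.items():
        if mode == "RAF" and record.reference_probe_for:
            continue
        rows = cl[cl["substrate"] == sub]
        clint_by_t = {}
        for _, row in rows.iterrows():
            if row["transporter"] in record.transporters:
                clint_by_t[row["transporter"]] = float(row[col])
        if not clint_by_t:
            continue
        fu_p = record.fu_p or float(binding.loc[sub, "fu_4pct_mean"])
        predictions[sub] = predict_renal_clearance(
            sub, clint_by_t, scalers, min(fu_p, 1.0), phys, mode=mode,
            hsa_level=hsa_level,
            fu_b=(fu_b or {}).get(sub),
            observed_clr=(observed or {}).get(sub))
    return predictions


def evaluate_against_observed(predictions: dict, observed: dict,
                              rmse_scale: str = "linear"):
    """Accuracy summary of predicted vs observed renal clearance (mL/min)."""
    pred = {s: p.cl_r for s, p in predictions.items()}
    return summarize_accuracy(pred, observed, rmse_scale=rmse_scale)


# ---------------------------------------------------------------------------

def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return (and optionally write) the report."""
    report: dict = {"config": {"scaler_mode": config.scaler_mode,
                               "hsa_level": config.hsa_level,
                               "seed": config.seed}}

    # stage 1: albumin binding
    if config.binding_csv:
        measurements = read_binding_csv(config.binding_csv)
    else:
        measurements = []
        for _, row in datasets.binding_measurement_frame().iterrows():
            measurements.append(BindingMeasurement(
                row["substrate"],
                AlbuminCondition.hsa(row["albumin_g_per_dl"]),
                [row["fu_mean"]]))
    kd_fits = fit_binding_panel(measurements, weighting=config.kd_weighting)
    report["binding"] = {s: f for s, f in kd_fits.items()}

    # stage 2: uptake kinetics (raw data only; the packaged tables already
    # hold condition-mean clearances and ratios)
    if config.timecourse_csv:
        tcs = read_timecourse_csv(config.timecourse_csv)
        clearances, ratios = process_timecourses(tcs)
        report["uptake"] = {
            f"{sub}/{line}": {
                "non_substrate": cs.non_substrate_flag,
                "active_means": {c: cs.mean_sd(c)[0]
                                 for c in cs.clint_u_active},
            } for (sub, line), cs in clearances.items()}
        report["ratios"] = {
            f"{sub}/{line}": {c: rr.r_mean for c, rr in conds.items()}
            for (sub, line), conds in ratios.items()}

    # stage 3: facilitated-dissociation fits
    try:
        report["fd"] = table_fd_fits(residual_scale=config.fd_residual_scale)
    except ValueError as exc:
        raise PipelineError("fd_model", str(exc)) from exc

    # stage 4: empirical regression
    report["regression"] = table_regressions()

    # stage 5: IVIVE
    observed = None
    fu_b = None
    if config.observed_csv:
        obs_df = pd.read_csv(config.observed_csv)
        observed = dict(zip(obs_df["substrate"],
                            obs_df["observed_clr_ml_min"]))
        if "fu_b" in obs_df.columns:
            fu_b = dict(zip(obs_df["substrate"], obs_df["fu_b"]))
    predictions = predict_panel(mode=config.scaler_mode,
                                hsa_level=config.hsa_level,
                                phys=config.physiology,
                                observed=observed, fu_b=fu_b)
    report["predictions"] = predictions
    report["scalers"] = load_scalers()

    # stage 6: accuracy, when clinical references exist
    if observed:
        report["accuracy"] = evaluate_against_observed(predictions, observed)

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(_to_jsonable(report), fh, indent=2)
        rows = [{
            "substrate": s, "scaling_mode": p.scaling_mode,
            "hsa_level": p.hsa_level, "clint_sec_ml_min": p.clint_sec,
            "cl_sec_ml_min": p.cl_sec, "cl_r_ml_min": p.cl_r,
            "fold_error": p.fold_error,
        } for s, p in predictions.items()]
        pd.DataFrame(rows).to_csv(outdir / "predictions.csv", index=False)
    return report
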