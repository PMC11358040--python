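"""Full-screen orchestration: reduce -> metrics -> similarity -> cluster ->
kinetics -> triage merge, with machine-readable reports.

``run_screen`` executes every stage on a simulated (or on-disk) plate and
returns a :class:`ScreenReport`; per-sample failures are recorded as
exclusion reasons rather than aborting the plate.  Reports are exported
as CSV tables plus one ``report.json`` whose structure is checked by
``validate_report_dict``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, TrsaxsError
from .io import FrameSeries, SampleSheet, load_manifest
from .kinetics import fit_exponential_decay, rank_and_cluster_kvr
from .metrics import aggregation_check, guinier_fit, z_factor
from .reduction import subtract_time_matched
from .similarity import (
    VR_NBINS,
    VR_WINDOW,
    benchmark_envelope,
    classify_transition,
    similarity_matrix,
    vr_trace,
)
from .cluster import kl_select_k, kmeans_cluster, single_linkage_cluster
from .reduction import average_curves
from .synth import (
    FragmentEffect,
    SimConfig,
    TriageConfig,
    default_library,
    simulate_screen_plate,
    simulate_triage_assays,
)
from .triage import fit_boltzmann_tm, mst_amplitude, qc_melt_curve, threshold_call

__all__ = ["ScreenConfig", "ScreenReport", "run_screen", "export_report",
           "validate_report_dict"]


@dataclass(frozen=True)
class ScreenConfig:
    """Everything a screen run needs; identical config + seed => identical report."""

    seed: int
    manifest_path: str | None = None     # load a plate from disk instead of simulating
    q_window: tuple[float, float] = VR_WINDOW
    nbins: int = VR_NBINS
    qmax_rg_limit: float = 1.3
    cluster_kmax: int = 8
    forced_k: int = 4
    kmeans_restarts: int = 50
    late_time: float = 2.1               # s; clustered alongside the earliest frame
    library: tuple[FragmentEffect, ...] = field(
        default_factory=lambda: tuple(default_library())
    )
    sim: SimConfig | None = None
    triage: TriageConfig | None = None
    run_triage: bool = True

    def resolved_sim(self) -> SimConfig:
        return self.sim if self.sim is not None else SimConfig(seed=self.seed)

    def resolved_triage(self) -> TriageConfig:
        return self.triage if self.triage is not None else TriageConfig(seed=self.seed)

    def hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, (tuple, list)):
                return [enc(v) for v in o]
            if isinstance(o, np.ndarray):
                return o.tolist()
            return o
        payload = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ScreenReport:
    config_hash: str
    seed: int
    metrics: pd.DataFrame          # well, label, time_s, rg, rg_err, i0, i0_err, ...
    z_factors: dict[str, dict]
    vr_traces: dict[str, dict]     # label -> {times, values}
    envelopes: dict[str, dict]
    classifications: pd.DataFrame  # label, first_significant, first_dimer_entered
    ssm: dict[str, dict]           # time-point key -> {labels, values, clusters}
    kinetics: pd.DataFrame
    triage: pd.DataFrame | None
    exclusions: pd.DataFrame       # label, stage, reason
    meta: dict[str, Any]

    def to_dict(self) -> dict:
        def df(d: pd.DataFrame):
            return json.loads(d.to_json(orient="table", index=False))["data"]
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.meta.get("version", ""),
            "q_window": list(self.meta["q_window"]),
            "nbins": self.meta["nbins"],
            "z_factors": self.z_factors,
            "metrics": df(self.metrics),
            "vr_traces": self.vr_traces,
            "envelopes": self.envelopes,
            "classifications": df(self.classifications),
            "ssm": self.ssm,
            "kinetics": df(self.kinetics.astype(object).where(self.kinetics.notna(), -1)),
            "triage": df(self.triage) if self.triage is not None else None,
            "exclusions": df(self.exclusions),
        }


def _collect_plate(config: ScreenConfig):
    if config.manifest_path is not None:
        sheet, series, _report = load_manifest(config.manifest_path)
        truth = None
    else:
        plate = simulate_screen_plate(list(config.library), config.resolved_sim())
        sheet, series, truth = plate.sheet, plate.series, plate.truth
    if not len(sheet.table):
        raise ConfigError("empty manifest")
    return sheet, series, truth


def _frame_index_near(series: FrameSeries, t: float) -> int:
    return int(np.argmin(np.abs(series.times - t)))


def run_screen(config: ScreenConfig) -> ScreenReport:
    """Execute the full screen; deterministic for a fixed config + seed."""
    sheet, raw, truth = _collect_plate(config)
    buffers = [raw[w] for w in sheet.wells("buffer")]
    if not buffers:
        raise ConfigError("manifest has no buffer wells")
    exclusions: list[dict] = []

    # --- reduction: time-matched buffer subtraction for every non-buffer well
    reduced: dict[str, FrameSeries] = {}
    for well in sheet.wells():
        role = sheet.table.set_index("well").loc[well, "role"]
        if role == "buffer":
            continue
        try:
            reduced[well] = subtract_time_matched(raw[well], buffers)
        except TrsaxsError as e:
            exclusions.append({"label": raw[well].label, "stage": "reduction", "reason": str(e)})

    # --- per-frame Guinier metrics
    rows = []
    for well, ser in reduced.items():
        for frame in ser:
            rec = {"well": well, "label": ser.label, "time_s": frame.meta.frame_time}
            try:
                fit = guinier_fit(frame, qmax_rg_limit=config.qmax_rg_limit)
                agg = aggregation_check(frame, fit)
                rec.update(rg=fit.rg, rg_err=fit.rg_err, i0=fit.i0, i0_err=fit.i0_err,
                           qmin=fit.qmin, qmax=fit.qmax, r2=fit.r2,
                           aggregation_flag=agg.flagged)
            except TrsaxsError as e:
                rec.update(rg=np.nan, rg_err=np.nan, i0=np.nan, i0_err=np.nan,
                           qmin=np.nan, qmax=np.nan, r2=np.nan, aggregation_flag=False)
                exclusions.append({"label": ser.label, "stage": "guinier",
                                   "reason": f"t={frame.meta.frame_time}: {e}"})
            rows.append(rec)
    metrics = pd.DataFrame(rows)

    # --- Z-factors from control replicates (dimer = max-signal state)
    mono_wells = sheet.wells("monomer-control")
    dim_wells = sheet.wells("dimer-control")
    z_factors = {}
    for col in ("rg", "i0"):
        pos = metrics[metrics["well"].isin(dim_wells)][col].dropna()
        neg = metrics[metrics["well"].isin(mono_wells)][col].dropna()
        if len(pos) >= 2 and len(neg) >= 2:
            q = z_factor(pos, neg, metric=col)
            z_factors[col] = dataclasses.asdict(q)

    # --- V_R traces vs the time-matched averaged dimer benchmark
    if not dim_wells or not mono_wells:
        raise ConfigError("benchmark envelopes need monomer and dimer control replicates")
    dimer_series = [reduced[w] for w in dim_wells]
    mono_series = [reduced[w] for w in mono_wells]
    dimer_ref = FrameSeries(
        "dimer-benchmark",
        tuple(average_curves([s.frames[k] for s in dimer_series])
              .with_meta(label="dimer-benchmark", frame_time=float(dimer_series[0].times[k]))
              for k in range(len(dimer_series[0]))),
    )
    win, nb = config.q_window, config.nbins
    traces = {}
    sample_wells = sheet.wells("sample")
    for well in sample_wells:
        if well not in reduced:
            continue
        ser = reduced[well]
        try:
            traces[ser.label] = vr_trace(ser, dimer_ref, win, nb)
        except TrsaxsError as e:
            exclusions.append({"label": ser.label, "stage": "similarity", "reason": str(e)})

    # --- benchmark envelopes: monomer-vs-dimer and dimer self-similarity
    mono_traces = [vr_trace(s, dimer_ref, win, nb) for s in mono_series]
    mono_env = benchmark_envelope(mono_traces, k=3.0, sense="lower", label="monomer")
    dim_pair_traces = []
    for i in range(len(dimer_series)):
        for j in range(i + 1, len(dimer_series)):
            dim_pair_traces.append(vr_trace(dimer_series[i], dimer_series[j], win, nb))
    dim_env = benchmark_envelope(dim_pair_traces, k=3.0, sense="upper", label="dimer")

    class_rows = []
    for label, tr in traces.items():
        labels_t, summary = classify_transition(tr, mono_env, dim_env)
        class_rows.append({"label": label, "first_significant": summary["first_significant"],
                           "first_dimer_entered": summary["first_dimer_entered"],
                           "final_state": labels_t[-1]})
    classifications = pd.DataFrame(class_rows)

    # --- SSM + chemotype clustering at the earliest and ~late_time frames
    any_series = next(iter(reduced.values()))
    time_points = {
        "early": 0,
        "late": _frame_index_near(any_series, config.late_time),
    }
    ssm_out = {}
    cluster_wells = sample_wells + mono_wells + dim_wells
    for key, fi in time_points.items():
        curves = [(reduced[w].label, reduced[w].frames[fi]) for w in cluster_wells
                  if w in reduced]
        ssm = similarity_matrix(curves, win, nb)
        ahc, _ = single_linkage_cluster(ssm.values, k=config.forced_k, labels=ssm.labels)
        scan = None
        kl_k = None
        try:
            scan = kl_select_k(ssm.values, kmax=min(config.cluster_kmax, len(curves) - 1),
                               restarts=config.kmeans_restarts, seed=config.seed)
            kl_k = scan.chosen_k
        except TrsaxsError:
            pass
        km_sel = kmeans_cluster(ssm.values, kl_k or config.forced_k,
                                restarts=config.kmeans_restarts, seed=config.seed,
                                labels=ssm.labels)
        km_forced = kmeans_cluster(ssm.values, config.forced_k,
                                   restarts=config.kmeans_restarts, seed=config.seed,
                                   labels=ssm.labels)
        ssm_out[key] = {
            "frame_index": fi,
            "time_s": float(any_series.times[fi]),
            "labels": list(ssm.labels),
            "values": ssm.values.tolist(),
            "ahc_clusters": ahc.assignment,
            "kmeans_selected_k": kl_k,
            "kmeans_clusters_selected": km_sel.assignment,
            "kmeans_clusters_forced": km_forced.assignment,
            "kl_low_confidence": bool(scan.low_confidence) if scan else True,
        }

    # --- kinetics: k_VR from each sample trace
    fits = []
    for label, tr in traces.items():
        try:
            fits.append(fit_exponential_decay(tr))
        except TrsaxsError as e:
            exclusions.append({"label": label, "stage": "kinetics", "reason": str(e)})
    kin_table, _kin_assign = rank_and_cluster_kvr(
        fits, kmax=min(6, max(2, len(fits) - 1)), restarts=config.kmeans_restarts,
        seed=config.seed,
    )

    # --- DSF/MST triage
    triage_table = None
    if config.run_triage:
        assays = simulate_triage_assays(list(config.library), config.resolved_triage())
        ref_tms = []
        for mc in assays.reference_melts:
            f = fit_boltzmann_tm(mc)
            if f.determinate:
                ref_tms.append(f.tm)
        comp_rows = []
        for frag in config.library:
            mc = assays.melts[frag.compound_id]
            tmfit = fit_boltzmann_tm(mc)
            ok, reason = qc_melt_curve(mc, tmfit)
            amp = mst_amplitude(assays.mst[frag.compound_id])
            comp_rows.append({"compound_id": frag.compound_id, "qc_pass": ok,
                              "qc_reason": reason,
                              "tm": tmfit.tm if ok else np.nan, "mst_amplitude": amp})
        tri = pd.DataFrame(comp_rows)
        passing = tri[tri["qc_pass"]]
        dsf_calls, dsf_summary = threshold_call(
            passing["tm"].to_numpy(), ref_tms, k=3.0, sense="two-sided",
            labels=list(passing["compound_id"]),
        )
        ref_amps = [mst_amplitude(scans) for scans in assays.reference_mst]
        mst_calls, mst_summary = threshold_call(
            tri["mst_amplitude"].to_numpy(), ref_amps, k=3.0, sense="less",
            labels=list(tri["compound_id"]),
        )
        tri = tri.merge(
            dsf_calls.rename(columns={"label": "compound_id", "value": "tm_fit",
                                      "delta": "delta_tm", "hit": "dsf_hit",
                                      "direction": "dsf_direction"}),
            on="compound_id", how="left",
        ).merge(
            mst_calls.rename(columns={"label": "compound_id", "value": "mst_amp",
                                      "delta": "mst_delta", "hit": "mst_hit",
                                      "direction": "mst_direction"}),
            on="compound_id", how="left",
        )
        tri["dsf_hit"] = tri["dsf_hit"].map(lambda v: bool(v) if pd.notna(v) else False)
        tri["verified"] = tri["dsf_hit"] | tri["mst_hit"]
        tri["dual_verified"] = tri["dsf_hit"] & tri["mst_hit"]
        tri.attrs["dsf_summary"] = dsf_summary
        tri.attrs["mst_summary"] = mst_summary
        triage_table = tri

    def env_dict(env):
        return {"times": env.times.tolist(), "mean": env.mean.tolist(),
                "sd": env.sd.tolist(), "sigma_bar": env.sigma_bar,
                "threshold": env.threshold.tolist(), "sense": env.sense,
                "n_replicates": env.n_replicates}

    report = ScreenReport(
        config_hash=config.hash(),
        seed=config.seed,
        metrics=metrics,
        z_factors=z_factors,
        vr_traces={lbl: {"times": tr.times.tolist(), "values": tr.values.tolist()}
                   for lbl, tr in traces.items()},
        envelopes={"monomer": env_dict(mono_env), "dimer": env_dict(dim_env)},
        classifications=classifications,
        ssm=ssm_out,
        kinetics=kin_table,
        triage=triage_table,
        exclusions=pd.DataFrame(exclusions, columns=["label", "stage", "reason"]),
        meta={"version": __version__, "q_window": config.q_window, "nbins": config.nbins,
              "truth": truth},
    )
    return report


def export_report(report: ScreenReport, out_dir: str | Path,
                  formats: tuple[str, ...] = ("csv", "json")) -> list[Path]:
    """Write compounds.csv, ssm_<t>.csv, kinetics.csv, triage.csv, report.json."""
    supported = {"csv", "json"}
    unknown = set(formats) - supported
    if unknown:
        raise ConfigError(f"unknown format(s) {sorted(unknown)}; supported: {sorted(supported)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if "csv" in formats:
        p = out / "compounds.csv"
        report.metrics.to_csv(p, index=False)
        written.append(p)
        for key, entry in report.ssm.items():
            p = out / f"ssm_{key}.csv"
            pd.DataFrame(entry["values"], index=entry["labels"],
                         columns=entry["labels"]).to_csv(p)
            written.append(p)
        p = out / "kinetics.csv"
        report.kinetics.to_csv(p, index=False)
        written.append(p)
        if report.triage is not None:
            p = out / "triage.csv"
            report.triage.to_csv(p, index=False)
            written.append(p)
        p = out / "classifications.csv"
        report.classifications.to_csv(p, index=False)
        written.append(p)
    if "json" in formats:
        p = out / "report.json"
        p.write_text(json.dumps(report.to_dict(), sort_keys=True, indent=1))
        written.append(p)
    return written


_REPORT_REQUIRED: dict[str, type | tuple] = {
    "config_hash": str, "seed": int, "version": str, "q_window": list, "nbins": int,
    "z_factors": dict, "metrics": list, "vr_traces": dict, "envelopes": dict,
    "classifications": list, "ssm": dict, "kinetics": list, "exclusions": list,
}


def validate_report_dict(d: dict) -> list[str]:
    """Structural check of a report dict; returns a list of problems (empty = valid)."""
    problems = []
    for key, typ in _REPORT_REQUIRED.items():
        if key not in d:
            problems.append(f"missing key {key!r}")
        elif not isinstance(d[key], typ):
            problems.append(f"key {key!r} has type {type(d[key]).__name__}, wanted {typ}")
    for side in ("monomer", "dimer"):
        env = d.get("envelopes", {}).get(side)
        if not isinstance(env, dict):
            problems.append(f"missing envelope {side!r}")
            continue
        for k in ("times", "mean", "sd", "sigma_bar", "threshold", "sense"):
            if k not in env:
                problems.append(f"envelope {side!r} missing {k!r}")
    for key, entry in d.get("ssm", {}).items():
        labels = entry.get("labels")
        values = entry.get("values")
        if not (isinstance(labels, list) and isinstance(values, list)
                and len(values) == len(labels)
                and all(len(row) == len(labels) for row in values)):
            problems.append(f"ssm[{key!r}] is not square over its labels")
    return problems
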