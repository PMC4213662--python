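"""End-to-end analysis: detection -> calibration -> QC -> kinetics.

This is the sidecar-blind analysis chain: it consumes only rendered
traces and produces the tables every downstream statistic is computed
from.  The simulator's ground truth is never read here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationMap, assign_positions, build_calibration, qc_filter
from .constructs import MRNAConstruct, default_construct
from .detection import (
    DetectionConfig,
    detect_binding_events,
    detect_bleach,
    detect_joining,
    detect_pulses,
    events_to_frame,
    pulses_to_frame,
)
from .trace_io import Dataset
from . import kinetics as kin


@dataclass
class AnalysisResult:
    """All per-trace and per-event outputs of the analysis chain."""

    events: pd.DataFrame                 # one row per binding event
    pulses: pd.DataFrame                 # one row per tRNA pulse
    joins: dict[str, float]              # rnc_id -> joining time
    bleaches: dict[str, float]           # rnc_id -> bleach / trace-end time
    calibrations: dict[str, CalibrationMap]
    qc_retained: set[str]                # traces passing the pulse-count QC
    qc_log: dict[str, str]
    skipped: dict[str, str] = field(default_factory=dict)

    @property
    def rnc_ids(self) -> list[str]:
        return list(self.joins)


def analyze_dataset(
    ds: Dataset,
    detection: DetectionConfig | None = None,
    construct: MRNAConstruct | None = None,
    required_pulses: int | None = None,
) -> AnalysisResult:
    """Run detection, calibration and QC over every trace of a dataset.

    Traces without a detectable joining step are skipped (logged).  The
    pulse-count QC requirement defaults to the construct's number of
    landmark runs (4 for cWT); pass ``required_pulses=0`` for constructs
    without landmarks.
    """
    cfg = detection or DetectionConfig()
    if construct is None:
        name = ds.manifest.get("config", {}).get("construct", {}).get("name")
        construct = default_construct(name) if name else None

    all_events = []
    all_pulses = []
    joins: dict[str, float] = {}
    bleaches: dict[str, float] = {}
    cals: dict[str, CalibrationMap] = {}
    skipped: dict[str, str] = {}
    pulse_counts: dict[str, int] = {}

    for tr in ds.traces:
        join = detect_joining(tr, cfg)
        if join is None:
            skipped[tr.rnc_id] = "no joining step detected"
            continue
        bleach = detect_bleach(tr, cfg, join)
        events = detect_binding_events(tr, cfg, join=join, bleach=bleach)
        pulses = [
            p for p in detect_pulses(tr, cfg) if join <= p.t_start < bleach
        ]
        joins[tr.rnc_id] = join
        bleaches[tr.rnc_id] = bleach
        pulse_counts[tr.rnc_id] = len(pulses)
        if construct is not None and construct.landmark_runs and pulses:
            try:
                cal = build_calibration(join, pulses, construct, rnc_id=tr.rnc_id)
            except ValueError as exc:
                skipped[tr.rnc_id] = f"calibration failed: {exc}"
                cal = None
            if cal is not None:
                cals[tr.rnc_id] = cal
                assign_positions(events, cal)
        all_events.extend(events)
        all_pulses.extend(pulses)

    n_runs = len(construct.landmark_runs) if construct is not None else 0
    req = n_runs if required_pulses is None else required_pulses
    retained, log = qc_filter(pulse_counts, req)
    retained &= set(cals)  # length-resolved analyses also need a calibration

    return AnalysisResult(
        events=events_to_frame(all_events),
        pulses=pulses_to_frame(all_pulses),
        joins=joins,
        bleaches=bleaches,
        calibrations=cals,
        qc_retained=retained,
        qc_log=log,
        skipped=skipped,
    )


def headline_statistics(
    result: AnalysisResult,
    srp_conc: float = 100e-9,
    ramp_end_aa: float = 55.0,
) -> dict:
    """Every headline statistic of the assay, from one analyzed dataset.

    Returns a flat dict: arrival half-times (s), per-bin residence
    lifetimes (s), tRNA pulse lifetimes (s), the first-arrival position
    distribution (%), the post-exposure association rate (M-1 s-1), the
    chain-length occupancy profile, and the per-RNC event-count summary.

    Length-resolved quantities and per-index pulse lifetimes use only
    traces passing the full-pulse-count QC (their pulse indices are
    guaranteed to align with the landmark runs); arrival statistics use
    every analyzable trace.
    """
    out: dict = {}
    stats = kin.arrival_times(result.events, result.joins)
    out["half_time_first_s"] = stats.half_time_first
    out["half_time_subsequent_s"] = stats.half_time_subsequent
    out["arrival_ratio"] = stats.half_time_first / stats.half_time_subsequent
    out["plateau_first"] = stats.plateau_first
    out["n_first_arrivals"] = int(stats.first_arrivals.size)
    out["n_subsequent_gaps"] = int(stats.subsequent_gaps.size)
    _, frac_gt2 = kin.events_per_rnc(result.events, result.rnc_ids)
    out["fraction_gt2_events"] = frac_gt2

    qc_ev = result.events[
        result.events["rnc_id"].isin(result.qc_retained)
    ].dropna(subset=["aa_at_start"])
    rb = kin.residence_by_bin(qc_ev)
    out["residence_by_bin"] = rb
    by_lo = rb.set_index("aa_lo")
    out["lifetime_40_50_s"] = float(by_lo.loc[40.0, "mean_lifetime"])
    out["lifetime_50_60_s"] = float(by_lo.loc[50.0, "mean_lifetime"])
    out["n_events_40_50"] = int(by_lo.loc[40.0, "n_events"])
    out["n_events_50_60"] = int(by_lo.loc[50.0, "n_events"])

    firsts = qc_ev[qc_ev["ordinal"] == 1]
    aa = firsts["aa_at_start"].to_numpy(dtype=float)
    out["n_first_positions"] = int(aa.size)
    out["pct_first_before_40aa"] = 100.0 * float(np.mean(aa < 40.0)) if aa.size else float("nan")
    out["pct_first_40_55aa"] = (
        100.0 * float(np.mean((aa >= 40.0) & (aa <= 55.0))) if aa.size else float("nan")
    )

    # per-index pulse lifetimes on QC traces (indices align with runs there)
    qc_pulses = result.pulses[result.pulses["rnc_id"].isin(result.qc_retained)]
    for key, idx in (("pulse_first", [1]), ("pulse_cluster", [2, 3, 4])):
        sel = qc_pulses[qc_pulses["pulse_index"].isin(idx)]
        cens = np.array(
            [
                p.t_end >= result.bleaches.get(p.rnc_id, np.inf) - 0.2
                for p in sel.itertuples()
            ]
        )
        if len(sel):
            fit = kin.fit_exponential(sel["duration"].to_numpy(), cens)
            out[f"{key}_lifetime_s"] = fit.mean_lifetime
            out[f"n_{key}_pulses"] = int(len(sel))
        else:
            out[f"{key}_lifetime_s"] = float("nan")
            out[f"n_{key}_pulses"] = 0

    # association rate from post-exposure unbound gaps
    gaps = []
    for rid in result.qc_retained:
        cal = result.calibrations.get(rid)
        if cal is None:
            continue
        sub = result.events[result.events["rnc_id"] == rid].sort_values("ordinal").head(10)
        starts = sub["t_start"].to_numpy()
        ends = sub["t_end"].to_numpy()
        from .calibration import time_to_aa

        for s, e in zip(starts[1:], ends[:-1]):
            if time_to_aa(cal, e) >= ramp_end_aa:
                gaps.append(max(s - e, 0.0))
    out["n_post_exposure_gaps"] = len(gaps)
    out["kon_post_hat"] = (
        kin.association_rate(gaps, srp_conc) if gaps else float("nan")
    )

    occ = kin.occupancy_by_aa(
        qc_ev,
        {r: result.calibrations[r] for r in result.qc_retained if r in result.calibrations},
        observed_end=result.bleaches,
    )
    out["occupancy"] = occ
    return out
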