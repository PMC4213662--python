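"""Mapping trace time to amino acids translated.

The 50S-joining step anchors codon 0 and each detected labeled-tRNA
pulse anchors the first codon of the corresponding landmark run (cWT:
codons 5, 25, 55, 85 — pulse onset marks accommodation of the first
labeled tRNA of the run).  Chain position between anchors is interpolated
linearly; beyond the last anchor it is extrapolated at the last segment's
rate and capped at the construct length (run-off stall on the
3'-truncated mRNA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constructs import MRNAConstruct
from .detection import BindingEvent, PulseEvent


@dataclass
class CalibrationMap:
    """Piecewise-linear time -> codon position map for one RNC."""

    rnc_id: str
    anchors: tuple[tuple[float, float], ...]  # (time s, codon index)
    terminal_rate: float                      # codons/s past the last anchor
    length_aa: int

    def __post_init__(self) -> None:
        ts = [a[0] for a in self.anchors]
        cs = [a[1] for a in self.anchors]
        if len(self.anchors) < 2:
            raise ValueError("calibration needs at least 2 anchors")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("anchor times must be strictly increasing")
        if any(b <= a for a, b in zip(cs, cs[1:])):
            raise ValueError("anchor codon indices must be strictly increasing")


def build_calibration(
    join: float,
    pulses: list[PulseEvent],
    construct: MRNAConstruct,
    rnc_id: str = "",
) -> CalibrationMap:
    """Anchor the position map on joining plus detected tRNA pulse starts.

    Pulses are matched to landmark runs in order; detecting more pulses
    than the construct has landmark runs is an error (spurious pulses).
    """
    runs = construct.landmark_runs
    if len(pulses) > len(runs):
        raise ValueError(
            f"{rnc_id or 'trace'}: {len(pulses)} pulses detected but construct "
            f"{construct.name!r} has only {len(runs)} landmark runs"
        )
    times = [p.t_start for p in pulses]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError(f"{rnc_id or 'trace'}: non-monotonic pulse times")
    anchors = [(float(join), 0.0)]
    for p, (first, _last) in zip(pulses, runs):
        anchors.append((float(p.t_start), float(first)))
    if len(anchors) < 2:
        raise ValueError(f"{rnc_id or 'trace'}: no pulses; cannot calibrate")
    (t0, c0), (t1, c1) = anchors[-2], anchors[-1]
    return CalibrationMap(
        rnc_id=rnc_id or (pulses[0].rnc_id if pulses else ""),
        anchors=tuple(anchors),
        terminal_rate=(c1 - c0) / (t1 - t0),
        length_aa=construct.length_aa,
    )


def time_to_aa(cal: CalibrationMap, t: float | np.ndarray):
    """Fractional chain length (aa) at time t.

    Piecewise-linear between anchors; linear extrapolation at the terminal
    rate past the last anchor, capped at the construct length.  Times
    before the first anchor (pre-joining) are an error.
    """
    ts = np.array([a[0] for a in cal.anchors])
    cs = np.array([a[1] for a in cal.anchors])
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < ts[0] - 1e-9):
        raise ValueError("time precedes the joining anchor")
    aa = np.interp(t_arr, ts, cs)
    beyond = t_arr > ts[-1]
    if np.any(beyond):
        aa = np.where(beyond, cs[-1] + (t_arr - ts[-1]) * cal.terminal_rate, aa)
    aa = np.minimum(aa, float(cal.length_aa))
    return float(aa) if np.isscalar(t) or t_arr.ndim == 0 else aa


def assign_positions(
    events: list[BindingEvent], cal: CalibrationMap
) -> list[BindingEvent]:
    """Fill ``aa_at_start`` for each event from its start time."""
    for ev in events:
        ev.aa_at_start = time_to_aa(cal, max(ev.t_start, cal.anchors[0][0]))
    return events


def qc_filter(
    pulse_counts: dict[str, int], required_pulses: int
) -> tuple[set[str], dict[str, str]]:
    """Trace-inclusion rule for length-resolved analyses.

    Only traces in which exactly ``required_pulses`` tRNA pulses were
    detected enter the chain-length-resolved analyses (residence vs
    length, occupancy); arrival-time analyses are not pulse-filtered.
    Returns the retained rnc_ids and a per-trace decision log.
    """
    keep: set[str] = set()
    log: dict[str, str] = {}
    for rid, n in pulse_counts.items():
        if n == required_pulses:
            keep.add(rid)
            log[rid] = f"retained ({n} pulses)"
        else:
            log[rid] = f"excluded ({n} pulses, require {required_pulses})"
    return keep, log
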