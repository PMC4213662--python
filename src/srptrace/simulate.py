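"""Stochastic simulation of co-translational SRP binding trajectories.

A trajectory is generated in three layers:

1. *Translation*: the 50S subunit joins at an exponential time after
   delivery; each codon dwell is an independent exponential whose mean is
   larger at labeled-Phe codons (the labeled ternary complex is dilute).
   The ribosome stalls at run-off (3'-truncated mRNA), after which the
   chain length stays at ``length_aa``.
2. *SRP binding*: a two-state (unbound/bound) continuous-time process.
   The association hazard is ``kon_at(chain_aa(t)) * [SRP]``, piecewise
   constant between codon completions (chain length only changes at codon
   boundaries, so this is exact Gillespie within each codon interval).
   The dissociation rate of an event is set by the chain length at which
   the event starts (the binding mode is locked in at engagement) and the
   bound dwell is exponential at that rate.
3. *Observation*: the donor bleaches at an exponential time; bound
   intervals are clipped to [join, min(bleach, duration)].

In ``stalled_mode`` the chain length is pinned at ``length_aa`` for the
whole trace and each RNC's kon and koff are scaled by independent
lognormal factors (log-sd ``rnc_heterogeneity_sd``), reproducing the
broad molecule-to-molecule dispersion seen for stalled complexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constructs import FullConfig, KineticConfig, MRNAConstruct, OpticsConfig, kon_at
from .trace_io import Dataset, Trace


@dataclass
class StateTrajectory:
    """Ground truth for one simulated RNC."""

    rnc_id: str
    seed: int
    join_time: float
    bleach_time: float                 # donor bleach (may exceed duration)
    codon_completion_times: np.ndarray  # shape (n_codons_completed,)
    srp_intervals: list[tuple[float, float, float]]  # (start, end, efret)
    trna_intervals: list[tuple[float, float, int]]   # (start, end, run index)
    duration: float

    @property
    def observed_end(self) -> float:
        """End of the observable window: bleach or end of record."""
        return min(self.bleach_time, self.duration)

    def chain_aa(self, t: float) -> float:
        """Number of completed codons at time t (ground truth)."""
        return float(np.searchsorted(self.codon_completion_times, t, side="right"))


def _draw_efret(optics: OpticsConfig, rng: np.random.Generator) -> float:
    k = rng.choice(len(optics.efret_weights), p=np.asarray(optics.efret_weights))
    e = rng.normal(optics.efret_means[k], optics.efret_sds[k])
    return float(np.clip(e, 1e-3, 1 - 1e-3))


def simulate_trajectory(
    construct: MRNAConstruct,
    kinetics: KineticConfig,
    seed: int | np.random.Generator,
    optics: OpticsConfig | None = None,
    rnc_id: str = "rnc-0",
) -> StateTrajectory:
    """Simulate one ground-truth trajectory.

    ``optics`` is only used to draw the per-event FRET efficiency level
    (stored on the trajectory so rendering is deterministic given it);
    defaults to the standard optical model.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    optics = optics or OpticsConfig()
    L = construct.length_aa
    duration = kinetics.duration

    join = float(rng.exponential(kinetics.join_mean))
    bleach = join + float(rng.exponential(kinetics.bleach_mean_donor))

    # per-RNC heterogeneity multipliers (stalled mode)
    if kinetics.stalled_mode and kinetics.rnc_heterogeneity_sd > 0:
        sd = kinetics.rnc_heterogeneity_sd
        mult_on = float(rng.lognormal(0.0, sd))
        mult_off = float(rng.lognormal(0.0, sd))
    else:
        mult_on = mult_off = 1.0

    # --- translation ------------------------------------------------------
    if kinetics.stalled_mode:
        completions = np.empty(0)
        trna_intervals: list[tuple[float, float, int]] = []

        def chain_at(_t: float) -> int:
            return L
    else:
        means = np.full(L, kinetics.dwell_mean_nonphe)
        phe_idx = np.asarray(construct.phe_positions, dtype=int) - 1
        if phe_idx.size:
            means[phe_idx] = kinetics.dwell_mean_phe
        if kinetics.deterministic_dwells:
            dwells = means
        else:
            dwells = rng.exponential(means)
        completions = join + np.cumsum(dwells)

        trna_intervals = []
        for i, (first, last) in enumerate(construct.landmark_runs):
            start = join if first == 1 else completions[first - 2]
            end = completions[last - 1]
            if start < min(bleach, duration):
                trna_intervals.append((start, min(end, duration), i))

        def chain_at(t: float) -> int:
            return int(np.searchsorted(completions, t, side="right"))

    # --- SRP binding ------------------------------------------------------
    # piecewise-constant association hazard between codon completions
    boundaries = completions[completions < duration]
    srp_intervals: list[tuple[float, float, float]] = []
    conc = kinetics.srp_conc
    t = join
    end = duration  # the process is simulated to end of record; clipping below
    while t < end:
        # sample next association time from the inhomogeneous (piecewise
        # constant) hazard by inverting the cumulative hazard
        target = rng.exponential(1.0)
        acc = 0.0
        tb = None
        seg_start = t
        while seg_start < end:
            chain = chain_at(seg_start)
            nxt_i = int(np.searchsorted(boundaries, seg_start, side="right"))
            seg_end = boundaries[nxt_i] if nxt_i < boundaries.size else end
            seg_end = min(seg_end, end)
            haz = kon_at(construct, kinetics, chain) * conc * mult_on
            if acc + haz * (seg_end - seg_start) >= target:
                tb = seg_start + (target - acc) / haz
                break
            acc += haz * (seg_end - seg_start)
            seg_start = seg_end
        if tb is None:
            break
        koff = kinetics.koff_at(chain_at(tb)) * mult_off
        dur = rng.exponential(1.0 / koff)
        efret = _draw_efret(optics, rng)
        srp_intervals.append((tb, min(tb + dur, end), efret))
        t = tb + dur

    # clip bound intervals to the observable window
    obs_end = min(bleach, duration)
    srp_intervals = [
        (a, min(b, obs_end), e) for a, b, e in srp_intervals if a < obs_end
    ]
    trna_intervals = [
        (a, min(b, obs_end), i) for a, b, i in trna_intervals if a < obs_end
    ]

    seed_val = seed if isinstance(seed, (int, np.integer)) else -1
    return StateTrajectory(
        rnc_id=rnc_id,
        seed=int(seed_val),
        join_time=join,
        bleach_time=bleach,
        codon_completion_times=completions,
        srp_intervals=srp_intervals,
        trna_intervals=trna_intervals,
        duration=duration,
    )


def _rasterize(
    intervals: list[tuple[float, float]],
    weights: list[float],
    n_frames: int,
    dt: float,
) -> np.ndarray:
    """Per-frame weighted coverage of a set of intervals (pro-rated)."""
    out = np.zeros(n_frames)
    for (a, b), w in zip(intervals, weights):
        if b <= a:
            continue
        i0 = max(int(np.floor(a / dt)), 0)
        i1 = min(int(np.ceil(b / dt)), n_frames)
        if i1 <= i0:
            continue
        idx = np.arange(i0, i1)
        lo = idx * dt
        hi = lo + dt
        out[i0:i1] += w * (np.minimum(b, hi) - np.maximum(a, lo)) / dt
    return out


def render_trace(
    traj: StateTrajectory,
    optics: OpticsConfig,
    seed: int | np.random.Generator,
    frame_interval: float,
) -> Trace:
    """Render a trajectory into a noisy three-channel fluorescence trace.

    Energy partition: during a bound interval with efficiency E the donor
    emits ``donor_amp * (1 - E)`` and the acceptor ``zmw_quench *
    donor_amp * E``.  Outside [join, bleach) both FRET channels are at
    baseline 0.  The tRNA channel is ``trna_amp`` during landmark
    occupancy.  Partial-frame overlap is pro-rated; independent Gaussian
    noise is added per channel and frame.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = frame_interval
    n = int(round(traj.duration / dt))
    times = (np.arange(n) + 0.5) * dt

    obs_end = traj.observed_end
    active = _rasterize([(traj.join_time, obs_end)], [1.0], n, dt)
    bound_iv = [(a, b) for a, b, _ in traj.srp_intervals]
    e_levels = [e for _, _, e in traj.srp_intervals]
    e_cov = _rasterize(bound_iv, e_levels, n, dt)  # sum of E * coverage

    donor = optics.donor_amp * (active - e_cov)
    acceptor = optics.zmw_quench * optics.donor_amp * e_cov
    acceptor = acceptor + optics.crosstalk * donor
    trna_cov = _rasterize(
        [(a, b) for a, b, _ in traj.trna_intervals],
        [1.0] * len(traj.trna_intervals),
        n,
        dt,
    )
    trna = optics.trna_amp * np.clip(trna_cov, 0.0, 1.0)

    if optics.noise_sd > 0:
        noise = rng.normal(0.0, optics.noise_sd, size=(3, n))
        donor = donor + noise[0]
        acceptor = acceptor + noise[1]
        trna = trna + noise[2]

    return Trace(
        rnc_id=traj.rnc_id,
        times=times,
        donor=donor,
        acceptor=acceptor,
        trna=trna,
        meta={"frame_interval": dt, "seed": traj.seed, "rnc_id": traj.rnc_id},
    )


def simulate_dataset(
    config: FullConfig,
    n_traces: int,
    seed: int | None = None,
) -> tuple[Dataset, list[StateTrajectory]]:
    """Simulate an independent dataset of rendered traces + ground truth.

    Per-trace generators are spawned from a single master ``SeedSequence``
    (counter-based), so the dataset is bit-reproducible for a given
    (config, seed) regardless of execution order.  Returns the dataset and
    the ground-truth sidecar (one trajectory per trace, same order).
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    children = ss.spawn(2 * n_traces)
    traces = []
    trajs = []
    for i in range(n_traces):
        rid = f"rnc-{i:04d}"
        traj = simulate_trajectory(
            config.construct,
            config.kinetics,
            np.random.default_rng(children[2 * i]),
            optics=config.optics,
            rnc_id=rid,
        )
        traj.seed = int(children[2 * i].generate_state(1)[0] % (2**31))
        trace = render_trace(
            traj,
            config.optics,
            np.random.default_rng(children[2 * i + 1]),
            config.kinetics.frame_interval,
        )
        trace.meta.update(
            {
                "construct": config.construct.name,
                "srp_conc": config.kinetics.srp_conc,
                "mode": "ZMW",
                "master_seed": int(master),
            }
        )
        traces.append(trace)
        trajs.append(traj)
    manifest = {
        "schema": "srptrace-dataset/1",
        "n_traces": n_traces,
        "master_seed": int(master),
        "config": config.to_dict(),
    }
    return Dataset(traces=traces, manifest=manifest), trajs
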