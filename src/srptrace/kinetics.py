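"""Kinetic summary statistics for SRP-RNC binding.

Conventions used throughout:

* *First arrival* of an RNC = first binding-event start minus the joining
  time.  *Subsequent arrivals* (2nd-10th) are unbound waiting times,
  measured end-of-previous-event to start-of-next (start-to-start would
  conflate residence with association).  Events beyond the 10th are
  excluded from arrival statistics but retained everywhere else.
* *Half-time* = smallest t at which an empirical cumulative distribution
  reaches 50% of its plateau F_inf, where F_inf is the fraction of
  molecules exhibiting the event within the record (not forced to 1).
  The underlying curves are multi-step and are deliberately not fitted
  to exponentials.
* Dwell/residence lifetimes use the right-censored exponential MLE
  tau = (sum of all durations) / (number of uncensored durations);
  events truncated by donor bleach are never dropped.
* Chain-length bins are 10 aa wide and left-closed, [a, a+10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture


# ---------------------------------------------------------------------------
# arrival statistics

@dataclass
class ArrivalStats:
    first_arrivals: np.ndarray        # per-RNC, s
    subsequent_gaps: np.ndarray       # pooled 2nd-10th unbound waits, s
    n_rnc: int                        # all RNCs (CDF plateau normalization)
    plateau_first: float              # F_inf of the first-arrival CDF
    half_time_first: float
    half_time_subsequent: float


def half_time(samples, plateau: float = 1.0) -> float:
    """Smallest t with empirical CDF(t) >= 0.5 * plateau.

    ``samples`` are the observed event times; the CDF is normalized so
    that it plateaus at ``plateau`` (the fraction of molecules showing
    the event within the record).
    """
    x = np.sort(np.asarray(samples, dtype=float))
    if x.size == 0 or plateau <= 0:
        raise ValueError("half_time needs samples and a positive plateau")
    # CDF(x[k]) = plateau * (k+1)/n ; find first k with CDF >= plateau/2
    k = int(np.ceil(x.size / 2.0)) - 1
    return float(x[k])


def arrival_times(
    events_df: pd.DataFrame, joins: dict[str, float], max_ordinal: int = 10
) -> ArrivalStats:
    """First and subsequent (2nd-10th) arrival statistics.

    ``events_df`` is the detected-events table (one row per binding
    event); ``joins`` maps every analyzed rnc_id — with or without
    events — to its joining time.  RNCs without events contribute no
    first arrival but count toward the CDF plateau normalization.
    """
    firsts = []
    gaps = []
    for rid, join in joins.items():
        sub = events_df[events_df["rnc_id"] == rid].sort_values("ordinal")
        if sub.empty:
            continue
        if float(sub["t_start"].iloc[0]) < join - 1e-9:
            raise ValueError(f"{rid}: event precedes the joining time")
        firsts.append(float(sub["t_start"].iloc[0]) - join)
        sub = sub.head(max_ordinal)
        starts = sub["t_start"].to_numpy()
        ends = sub["t_end"].to_numpy()
        gaps.extend(np.maximum(starts[1:] - ends[:-1], 0.0))
    n_rnc = len(joins)
    firsts_arr = np.asarray(firsts)
    gaps_arr = np.asarray(gaps)
    plateau = len(firsts) / n_rnc if n_rnc else 0.0
    return ArrivalStats(
        first_arrivals=firsts_arr,
        subsequent_gaps=gaps_arr,
        n_rnc=n_rnc,
        plateau_first=plateau,
        half_time_first=half_time(firsts_arr, plateau) if len(firsts) else float("nan"),
        half_time_subsequent=half_time(gaps_arr) if len(gaps) else float("nan"),
    )


# ---------------------------------------------------------------------------
# dwell-time fits

@dataclass
class DwellFit:
    mean_lifetime: float
    ci95: tuple[float, float]
    n_uncensored: int
    n_censored: int
    low_n: bool = False


def fit_exponential(durations, censored=None) -> DwellFit:
    """Single-exponential MLE with right censoring.

    tau_hat = (sum of all durations) / (number of uncensored durations);
    the 95% CI comes from the likelihood-ratio bound (chi-square with
    1 degree of freedom) on the exponential log-likelihood.
    """
    d = np.asarray(durations, dtype=float)
    c = (
        np.zeros(d.size, dtype=bool)
        if censored is None
        else np.asarray(censored, dtype=bool)
    )
    if d.size == 0:
        raise ValueError("no dwells to fit")
    n_unc = int((~c).sum())
    if n_unc == 0:
        raise ValueError("no uncensored dwells; lifetime unidentifiable")
    total = float(d.sum())
    tau = total / n_unc

    # profile likelihood: l(tau) = -n_unc*log(tau) - total/tau
    def nll(t):
        return n_unc * np.log(t) + total / t

    crit = stats.chi2.ppf(0.95, df=1) / 2.0
    lo, hi = tau, tau
    target = nll(tau) + crit
    step = tau / 2
    while nll(max(lo - step, 1e-12)) < target and lo - step > 1e-12:
        lo -= step
    lo = _bisect(nll, max(lo - step, 1e-12), tau, target)
    while nll(hi + step) < target:
        hi += step
    hi = _bisect(nll, tau, hi + step, target)
    return DwellFit(
        mean_lifetime=tau, ci95=(lo, hi), n_uncensored=n_unc, n_censored=int(c.sum())
    )


def _bisect(f, a, b, target, tol=1e-9, iters=200):
    fa, fb = f(a) - target, f(b) - target
    if fa * fb > 0:
        return a if abs(fa) < abs(fb) else b
    for _ in range(iters):
        m = 0.5 * (a + b)
        fm = f(m) - target
        if abs(fm) < tol:
            return m
        if fa * fm <= 0:
            b, fb = m, fm
        else:
            a, fa = m, fm
    return 0.5 * (a + b)


def residence_by_bin(
    events_df: pd.DataFrame,
    bins: np.ndarray | None = None,
    min_uncensored: int = 5,
) -> pd.DataFrame:
    """Censored-MLE residence lifetime per chain-length bin.

    Events are grouped by the calibrated chain length at event *start*
    into left-closed 10-aa bins; censored events participate through the
    censored MLE; bins with fewer than ``min_uncensored`` uncensored
    events are flagged low-n.
    """
    if bins is None:
        bins = np.arange(0.0, 110.0, 10.0)
    rows = []
    aa = events_df["aa_at_start"].to_numpy(dtype=float)
    for lo, hi in zip(bins[:-1], bins[1:]):
        mask = (aa >= lo) & (aa < hi)
        sub = events_df[mask]
        row = {"aa_lo": lo, "aa_hi": hi, "n_events": int(mask.sum())}
        n_unc = int((~sub["censored"].astype(bool)).sum()) if len(sub) else 0
        if n_unc >= 1:
            fit = fit_exponential(
                sub["duration"].to_numpy(), sub["censored"].to_numpy(dtype=bool)
            )
            row.update(
                mean_lifetime=fit.mean_lifetime,
                ci_lo=fit.ci95[0],
                ci_hi=fit.ci95[1],
                n_uncensored=fit.n_uncensored,
                n_censored=fit.n_censored,
                low_n=fit.n_uncensored < min_uncensored,
            )
        else:
            row.update(
                mean_lifetime=np.nan,
                ci_lo=np.nan,
                ci_hi=np.nan,
                n_uncensored=0,
                n_censored=int(len(sub)),
                low_n=True,
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# occupancy and event-count summaries

@dataclass
class OccupancyProfile:
    aa_bins: np.ndarray
    bound_counts: np.ndarray
    totals: np.ndarray
    fraction: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "aa_lo": self.aa_bins[:-1],
                "aa_hi": self.aa_bins[1:],
                "bound": self.bound_counts,
                "total": self.totals,
                "fraction": self.fraction,
            }
        )


def occupancy_by_aa(
    events_df: pd.DataFrame,
    cal_maps: dict[str, "CalibrationMap"],
    bins: np.ndarray | None = None,
    observed_end: dict[str, float] | None = None,
) -> OccupancyProfile:
    """Fraction of RNCs bound by SRP while traversing each chain-length bin.

    For each bin an RNC counts as occupied if any of its bound intervals
    overlaps the time window during which its calibrated position lies in
    the bin; the denominator counts RNCs that traverse (enter) the bin
    within their observed window.  The window is the *transit* through the
    bin's aa range: for the bin containing the construct's final codon it
    ends when translation completes, so the indefinite run-off stall does
    not count as "translating" that bin.
    """
    from .calibration import CalibrationMap, time_to_aa  # noqa: F401

    if bins is None:
        bins = np.arange(0.0, 110.0, 10.0)
    nb = len(bins) - 1
    bound = np.zeros(nb, dtype=int)
    totals = np.zeros(nb, dtype=int)
    for rid, cal in cal_maps.items():
        sub = events_df[events_df["rnc_id"] == rid]
        iv = list(zip(sub["t_start"].to_numpy(), sub["t_end"].to_numpy()))
        t_end = observed_end.get(rid) if observed_end else None
        for k in range(nb):
            lo, hi = bins[k], bins[k + 1]
            if lo >= cal.length_aa:
                continue
            t_lo = _time_at_aa(cal, lo)
            t_hi = _time_at_aa(cal, min(hi, float(cal.length_aa)))
            if t_lo is None:
                continue
            if t_end is not None and t_lo > t_end:
                continue  # bleached before reaching the bin
            totals[k] += 1
            w_hi = t_hi if t_hi is not None else (t_end if t_end is not None else np.inf)
            if t_end is not None:
                w_hi = min(w_hi, t_end)
            if any(a < w_hi and b > t_lo for a, b in iv):
                bound[k] += 1
    frac = np.divide(
        bound, totals, out=np.zeros(nb, dtype=float), where=totals > 0
    )
    return OccupancyProfile(
        aa_bins=np.asarray(bins), bound_counts=bound, totals=totals, fraction=frac
    )


def _time_at_aa(cal, aa: float) -> float | None:
    """Inverse of the calibration map (first time position reaches aa)."""
    ts = np.array([a[0] for a in cal.anchors])
    cs = np.array([a[1] for a in cal.anchors])
    if aa <= cs[0]:
        return float(ts[0])
    if aa <= cs[-1]:
        return float(np.interp(aa, cs, ts))
    if cal.terminal_rate <= 0 or aa > cal.length_aa:
        return None
    return float(ts[-1] + (aa - cs[-1]) / cal.terminal_rate)


def events_per_rnc(
    events_df: pd.DataFrame, rnc_ids: list[str], threshold: int = 2
) -> tuple[pd.Series, float]:
    """Per-RNC binding-event counts and the fraction with > threshold events."""
    counts = events_df.groupby("rnc_id").size()
    counts = counts.reindex(rnc_ids, fill_value=0)
    frac = float((counts > threshold).mean()) if len(counts) else 0.0
    return counts, frac


def per_rnc_dispersion(
    events_df: pd.DataFrame, joins: dict[str, float], min_events: int = 5
) -> pd.DataFrame:
    """Per-RNC medians and variances of arrival gaps and residences.

    Restricted to RNCs with more than ``min_events`` events; the output
    is ordered by decreasing variance of the arrival gaps, with a pooled
    'total' row appended (mean and variance over all events).
    """
    rows = []
    all_gaps, all_res = [], []
    for rid, join in joins.items():
        sub = events_df[events_df["rnc_id"] == rid].sort_values("t_start")
        if len(sub) <= min_events:
            continue
        starts = sub["t_start"].to_numpy()
        ends = sub["t_end"].to_numpy()
        gaps = np.concatenate([[starts[0] - join], np.maximum(starts[1:] - ends[:-1], 0)])
        res = sub["duration"].to_numpy()
        all_gaps.extend(gaps)
        all_res.extend(res)
        rows.append(
            {
                "rnc_id": rid,
                "n_events": len(sub),
                "median_arrival": float(np.median(gaps)),
                "var_arrival": float(np.var(gaps)),
                "median_residence": float(np.median(res)),
                "var_residence": float(np.var(res)),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "rnc_id",
            "n_events",
            "median_arrival",
            "var_arrival",
            "median_residence",
            "var_residence",
        ],
    )
    df = df.sort_values("var_arrival", ascending=False).reset_index(drop=True)
    if all_gaps:
        total = pd.DataFrame(
            [
                {
                    "rnc_id": "total",
                    "n_events": len(all_res),
                    "median_arrival": float(np.mean(all_gaps)),
                    "var_arrival": float(np.var(all_gaps)),
                    "median_residence": float(np.mean(all_res)),
                    "var_residence": float(np.var(all_res)),
                }
            ]
        )
        df = pd.concat([df, total], ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# association rate and Forster conversions

def association_rate(waiting_times, conc: float, censored=None) -> float:
    """Bimolecular association rate k_on = 1 / (mean waiting time x [SRP]).

    The mean waiting time is the censoring-aware exponential MLE.
    """
    if conc <= 0:
        raise ValueError("concentration must be positive")
    fit = fit_exponential(waiting_times, censored)
    return 1.0 / (fit.mean_lifetime * conc)


def fret_efficiency(r: float, r0: float) -> float:
    """Forster relation E = 1 / (1 + (r/R0)^6)."""
    if r <= 0 or r0 <= 0:
        raise ValueError("distances must be positive")
    return 1.0 / (1.0 + (r / r0) ** 6)


def distance_from_efret(e: float, r0: float) -> float:
    """Unique positive inverse of the Forster relation."""
    if not 0 < e < 1:
        raise ValueError("E must lie in (0, 1)")
    if r0 <= 0:
        raise ValueError("R0 must be positive")
    return r0 * ((1.0 - e) / e) ** (1.0 / 6.0)


# ---------------------------------------------------------------------------
# E_FRET mixture

@dataclass
class MixtureFit:
    component_means: tuple[float, float]
    component_sds: tuple[float, float]
    component_weights: tuple[float, float]
    assignment_fractions: tuple[float, float]
    single_component: bool = False


def fit_efret_mixture(values, min_n: int = 10) -> MixtureFit:
    """Two-component Gaussian mixture of event-mean FRET efficiencies.

    EM with a deterministic quantile initialization (means at the 25th
    and 75th percentiles), so repeated fits are identical.  Degenerate
    input (all values identical) is rejected; if EM collapses onto one
    component the fit is flagged ``single_component``.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} values, got {x.size}")
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate input: all efficiencies identical")
    init_means = np.percentile(x, [25, 75]).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=2,
        covariance_type="spherical",
        means_init=init_means,
        weights_init=[0.5, 0.5],
        precisions_init=1.0 / np.full(2, max(np.var(x), 1e-6)),
        max_iter=500,
        tol=1e-8,
        reg_covar=1e-8,
    )
    labels = gm.fit_predict(x)
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_.ravel()[order]
    assign = np.array(
        [(labels == order[0]).mean(), (labels == order[1]).mean()]
    )
    single = bool(weights.min() < 0.02 or abs(means[1] - means[0]) < 1e-3)
    return MixtureFit(
        component_means=(float(means[0]), float(means[1])),
        component_sds=(float(sds[0]), float(sds[1])),
        component_weights=(float(weights[0]), float(weights[1])),
        assignment_fractions=(float(assign[0]), float(assign[1])),
        single_component=single,
    )


# ---------------------------------------------------------------------------
# events around tRNA pulses

def events_relative_to_pulses(
    events_df: pd.DataFrame, pulses_df: pd.DataFrame, window: float = 60.0
) -> pd.DataFrame:
    """Signed offsets of binding-event starts around each tRNA pulse start.

    One row per (pulse_index, event) pair with |offset| <= window.
    """
    rows = []
    for _, p in pulses_df.iterrows():
        sub = events_df[events_df["rnc_id"] == p["rnc_id"]]
        off = sub["t_start"].to_numpy() - p["t_start"]
        for o in off[np.abs(off) <= window]:
            rows.append({"pulse_index": int(p["pulse_index"]), "offset": float(o)})
    return pd.DataFrame(rows, columns=["pulse_index", "offset"])
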