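"""Kinetic estimators: oracle values, parameter recovery, invariants."""

import numpy as np
import pandas as pd
import pytest

import srptrace as st
from srptrace.calibration import CalibrationMap
from srptrace.kinetics import (
    _time_at_aa,
    arrival_times,
    association_rate,
    distance_from_efret,
    events_per_rnc,
    events_relative_to_pulses,
    fit_efret_mixture,
    fit_exponential,
    fret_efficiency,
    half_time,
    occupancy_by_aa,
    per_rnc_dispersion,
    residence_by_bin,
)


def events_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "rnc_id", "ordinal", "t_start", "t_end", "duration",
            "mean_efret", "censored", "aa_at_start",
        ],
    )


def ev(rid, k, t0, t1, aa=np.nan, censored=False):
    return dict(
        rnc_id=rid, ordinal=k, t_start=t0, t_end=t1, duration=t1 - t0,
        mean_efret=0.3, censored=censored, aa_at_start=aa,
    )


class TestArrivals:
    def test_first_and_gap_are_simple_differences(self):
        df = events_frame([ev("a", 1, 60, 70), ev("a", 2, 80, 95)])
        stats = arrival_times(df, {"a": 10.0})
        assert stats.first_arrivals.tolist() == [50.0]
        assert stats.subsequent_gaps.tolist() == [10.0]

    def test_only_second_to_tenth_gaps_counted(self):
        rows = [ev("a", k, 100 * k, 100 * k + 10) for k in range(1, 13)]
        stats = arrival_times(events_frame(rows), {"a": 0.0})
        assert stats.subsequent_gaps.size == 9

    def test_eventless_rncs_lower_plateau(self):
        df = events_frame([ev("a", 1, 60, 70)])
        stats = arrival_times(df, {"a": 10.0, "b": 5.0})
        assert stats.plateau_first == 0.5
        assert stats.n_rnc == 2

    def test_event_before_join_rejected(self):
        df = events_frame([ev("a", 1, 3, 9)])
        with pytest.raises(ValueError):
            arrival_times(df, {"a": 10.0})

    def test_first_much_slower_than_subsequent(self, run750):
        stats = run750["stats"]
        assert stats["half_time_first_s"] > 10 * stats["half_time_subsequent_s"]


class TestHalfTime:
    def test_small_sample(self):
        assert half_time([1, 2, 3, 4]) == 2

    def test_exponential_limit(self, rng):
        m = 20.0
        x = rng.exponential(m, 200_000)
        assert half_time(x) == pytest.approx(np.log(2) * m, rel=0.05)

    def test_empty_or_zero_plateau_rejected(self):
        with pytest.raises(ValueError):
            half_time([])
        with pytest.raises(ValueError):
            half_time([1.0, 2.0], plateau=0.0)


class TestExponentialFit:
    def test_uncensored_mle_is_mean(self):
        fit = fit_exponential([10, 20, 30])
        assert fit.mean_lifetime == pytest.approx(20.0)
        assert fit.ci95[0] < 20.0 < fit.ci95[1]

    def test_censored_mle(self):
        # total time / number of uncensored = (10+20+30)/2
        fit = fit_exponential([10, 20, 30], [False, False, True])
        assert fit.mean_lifetime == pytest.approx(30.0)
        assert fit.n_censored == 1

    def test_empty_and_all_censored_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential([])
        with pytest.raises(ValueError):
            fit_exponential([5.0, 6.0], [True, True])

    @pytest.mark.parametrize("tau", [5.0, 35.0, 75.0])
    def test_parameter_recovery_with_censoring(self, tau):
        rng = np.random.default_rng(int(tau))
        x = rng.exponential(tau, 400)
        cens = x > 1.8 * tau          # right-censor the long tail
        x = np.minimum(x, 1.8 * tau)
        n_unc = int((~cens).sum())
        assert n_unc >= 300
        fit = fit_exponential(x, cens)
        assert fit.mean_lifetime == pytest.approx(tau, rel=0.10)


class TestResidenceByBin:
    def test_single_bin_fit(self):
        df = events_frame([
            ev("a", 1, 0, 10, aa=52.0),
            ev("a", 2, 20, 40, aa=55.0),
            ev("a", 3, 50, 80, aa=58.0),
        ])
        out = residence_by_bin(df).set_index("aa_lo")
        assert out.loc[50.0, "mean_lifetime"] == pytest.approx(20.0)
        assert out.loc[50.0, "low_n"]         # fewer than 5 uncensored
        assert np.isnan(out.loc[20.0, "mean_lifetime"])

    def test_left_closed_boundary(self):
        df = events_frame([ev("a", 1, 0, 10, aa=50.0)])
        out = residence_by_bin(df).set_index("aa_lo")
        assert out.loc[50.0, "n_events"] == 1
        assert out.loc[40.0, "n_events"] == 0


class TestOccupancy:
    def _cal(self):
        # constant 0.2 aa/s: aa 50 at t=250, aa 60 at t=300
        return CalibrationMap("a", ((0.0, 0.0), (250.0, 50.0)), 0.2, 95)

    def test_bound_during_transit_counts_once(self):
        df = events_frame([ev("a", 1, 260, 290, aa=52.0)])
        occ = occupancy_by_aa(df, {"a": self._cal()})
        frame = occ.to_frame().set_index("aa_lo")
        assert frame.loc[50.0, "fraction"] == 1.0
        assert frame.loc[30.0, "fraction"] == 0.0
        assert frame.loc[70.0, "fraction"] == 0.0

    def test_no_traces_all_zero(self):
        occ = occupancy_by_aa(events_frame([]), {})
        assert occ.fraction.sum() == 0.0
        assert occ.totals.sum() == 0

    def test_fractions_bounded(self, run750):
        occ = run750["stats"]["occupancy"]
        assert np.all((occ.fraction >= 0) & (occ.fraction <= 1))

    def test_inverse_of_calibration(self):
        cal = self._cal()
        assert _time_at_aa(cal, 50.0) == pytest.approx(250.0)
        assert _time_at_aa(cal, 60.0) == pytest.approx(300.0)


class TestEventsPerRnc:
    def test_fraction_above_two(self):
        df = events_frame(
            [ev("b", 1, 0, 1)]
            + [ev("c", k, 10 * k, 10 * k + 1) for k in range(1, 4)]
            + [ev("d", k, 10 * k, 10 * k + 1) for k in range(1, 6)]
        )
        counts, frac = events_per_rnc(df, ["a", "b", "c", "d"])
        assert counts["a"] == 0 and counts["d"] == 5
        assert frac == 0.5

    def test_all_zero(self):
        _, frac = events_per_rnc(events_frame([]), ["a", "b"])
        assert frac == 0.0


class TestDispersion:
    def test_median_of_gaps(self):
        rows = [ev("a", 1, 2, 3), ev("a", 2, 7, 8), ev("a", 3, 12, 13),
                ev("a", 4, 17, 18), ev("a", 5, 22, 23), ev("a", 6, 123, 124)]
        df = events_frame(rows)
        out = per_rnc_dispersion(df, {"a": 0.0}, min_events=5)
        row = out[out.rnc_id == "a"].iloc[0]
        assert row["median_arrival"] == pytest.approx(4.0)

    def test_homogeneous_population_has_no_excess_dispersion(self):
        # stalled RNCs with no molecule-to-molecule heterogeneity: the
        # between-RNC spread of median gaps is explained by sampling alone
        kin = st.KineticConfig(stalled_mode=True, duration=2000.0,
                               bleach_mean_donor=1e7)
        con = st.default_construct("cWT")
        gaps_by_rnc = []
        for s in range(80):
            g = st.simulate_trajectory(con, kin, seed=s)
            edges = [g.join_time] + [b for _, b, _ in g.srp_intervals[:-1]]
            gaps = [a - e for e, (a, _, _) in zip(edges, g.srp_intervals)]
            if len(gaps) > 5:
                gaps_by_rnc.append(np.asarray(gaps))
        obs = np.var([np.median(g) for g in gaps_by_rnc])
        pooled = np.concatenate(gaps_by_rnc)
        sizes = [len(g) for g in gaps_by_rnc]
        rng = np.random.default_rng(0)
        null = []
        for _ in range(500):
            perm = rng.permutation(pooled)
            meds, i = [], 0
            for n in sizes:
                meds.append(np.median(perm[i : i + n]))
                i += n
            null.append(np.var(meds))
        p = np.mean(np.asarray(null) >= obs)
        assert p > 0.01

    def test_heterogeneous_stalled_rncs_span_orders_of_magnitude(self):
        kin = st.KineticConfig(stalled_mode=True, rnc_heterogeneity_sd=1.0,
                               duration=1200.0)
        con = st.MRNAConstruct(name="lepB55", length_aa=55,
                               exposure_aa=40, ramp_end_aa=55)
        cfg = st.FullConfig(construct=con, kinetics=kin)
        ds, _ = st.simulate_dataset(cfg, 120, seed=6)
        res = st.analyze_dataset(ds, construct=con, required_pulses=0)
        disp = per_rnc_dispersion(res.events, res.joins, min_events=5)
        med = disp[disp.rnc_id != "total"]["median_arrival"]
        assert len(med) >= 20
        assert med.max() / max(med.min(), 1e-9) >= 10.0


class TestAssociationRate:
    def test_point_estimate(self):
        assert association_rate([5.56], 1e-7) == pytest.approx(1.8e6, rel=0.01)

    def test_halved_waits_double_rate(self):
        w = np.array([3.0, 5.0, 9.0])
        assert association_rate(w / 2, 1e-7) == pytest.approx(
            2 * association_rate(w, 1e-7)
        )

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            association_rate([5.0], 0.0)
        with pytest.raises(ValueError):
            association_rate([], 1e-7)


class TestForster:
    def test_known_distance(self):
        assert fret_efficiency(95, 65) == pytest.approx(
            1.0 / (1.0 + (95 / 65) ** 6), rel=1e-12
        )
        assert fret_efficiency(95, 65) == pytest.approx(0.093, abs=0.001)

    def test_forster_radius_is_half_point(self):
        assert fret_efficiency(65, 65) == pytest.approx(0.5, rel=1e-12)

    def test_round_trip(self):
        for r in np.linspace(20, 150, 14):
            e = fret_efficiency(r, 65)
            assert abs(distance_from_efret(e, 65) - r) < 1e-9

    def test_inverse_domain(self):
        for bad in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(ValueError):
                distance_from_efret(bad, 65)


class TestMixture:
    def test_recovers_two_components(self, rng):
        x = np.concatenate([
            rng.normal(0.26, 0.05, 250), rng.normal(0.42, 0.05, 250)
        ])
        fit = fit_efret_mixture(x)
        assert fit.component_means[0] == pytest.approx(0.26, abs=0.03)
        assert fit.component_means[1] == pytest.approx(0.42, abs=0.03)
        assert not fit.single_component

    def test_fit_is_deterministic(self, rng):
        x = rng.normal(0.3, 0.06, 300)
        f1 = fit_efret_mixture(x)
        f2 = fit_efret_mixture(x)
        assert f1.component_means == f2.component_means

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_efret_mixture(np.full(100, 0.3))
        with pytest.raises(ValueError):
            fit_efret_mixture([0.2, 0.3])

    def test_single_component_flagged(self, rng):
        x = rng.normal(0.30, 0.01, 500)
        fit = fit_efret_mixture(x)
        # either one weight collapses or the two means coincide
        close = abs(fit.component_means[1] - fit.component_means[0]) < 0.02
        assert fit.single_component or close


class TestEventsAroundPulses:
    def test_window_rule(self):
        events = events_frame([ev("a", 1, 110, 115), ev("a", 2, 175, 180)])
        pulses = pd.DataFrame(
            [{"rnc_id": "a", "pulse_index": 2, "t_start": 100.0,
              "t_end": 130.0, "duration": 30.0}]
        )
        out = events_relative_to_pulses(events, pulses, window=60.0)
        assert out["offset"].tolist() == [10.0]

    def test_binding_concentrates_at_exposure_landmark(self, run750):
        # arrivals cluster around the codon-55 pulse, not the codon-5 pulse
        res = run750["res"]
        qc = res.pulses[res.pulses["rnc_id"].isin(res.qc_retained)]
        out = events_relative_to_pulses(res.events, qc, window=60.0)
        n3 = (out["pulse_index"] == 3).sum()
        n1 = (out["pulse_index"] == 1).sum()
        assert n3 > 2 * n1
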