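"""Density, concordance, KM estimation, time-dependent ROC, log-rank."""

import numpy as np
import pandas as pd
import pytest

from nucquant import fixtures
from nucquant.cohort import (
    concordance,
    density,
    km_curve,
    logrank,
    stratify_cohort,
    td_roc_cutoff,
)


class TestDensity:
    def test_empty_map_gives_zero_density(self):
        n, area, d = density(np.zeros((100, 100), int), 0.25)
        assert n == 0 and d == 0.0

    def test_full_core_closed_form(self):
        """100 cells over a 1 mm-diameter circular core: density =
        100 / (pi * 0.5^2) = 127.324 cells/mm^2."""
        mpp = 0.25
        # build a label map whose analysed mask is exactly the core area
        radius_px = int(round(500 / mpp))  # 0.5 mm in pixels
        n_px_target = np.pi * 0.5**2 / (mpp / 1000) ** 2
        side = 2 * radius_px + 1
        rr, cc = np.mgrid[0:side, 0:side]
        core = (rr - radius_px) ** 2 + (cc - radius_px) ** 2 <= radius_px**2
        labels = np.zeros((side, side), int)
        labels.flat[np.flatnonzero(core)[:100]] = np.arange(1, 101)
        n, area, d = density(labels, mpp, analysed_mask=core)
        assert n == 100
        # rasterized circle area approximates pi r^2 to ~0.1%
        assert area == pytest.approx(np.pi * 0.5**2, rel=2e-3)
        assert d == pytest.approx(100 / (np.pi * 0.5**2), rel=2e-3)

    def test_density_scales_inverse_square_of_mpp(self):
        labels = np.zeros((64, 64), int)
        labels[2:6, 2:6] = 1
        _, _, d1 = density(labels, 0.25)
        _, _, d2 = density(labels, 0.5)
        assert d2 == pytest.approx(d1 / 4)

    def test_invalid_mpp_rejected(self):
        with pytest.raises(ValueError):
            density(np.zeros((4, 4), int), 0.0)


class TestConcordance:
    def test_perfect_and_anti_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert concordance(x, x) == pytest.approx(1.0)
        assert concordance(x, -2 * x) == pytest.approx(-1.0)

    def test_hand_computed_product_moment(self):
        assert concordance([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            concordance([1, 1, 1], [1, 2, 3])


class TestKMCurve:
    def test_all_censored_flat_at_one(self):
        curve = km_curve([1.0, 2.0, 3.0], [0, 0, 0])
        assert (curve["survival"] == 1.0).all()

    def test_three_events_product_limit(self):
        curve = km_curve([1.0, 2.0, 3.0], [1, 1, 1])
        surv = dict(zip(curve["time"], curve["survival"]))
        assert surv[1.0] == pytest.approx(2 / 3)
        assert surv[2.0] == pytest.approx(1 / 3)
        assert surv[3.0] == pytest.approx(0.0)

    def test_single_event_drop_factor(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        events = [0, 0, 1, 0, 0]
        curve = km_curve(times, events)
        surv = dict(zip(curve["time"], curve["survival"]))
        assert surv[3.0] == pytest.approx(2 / 3)  # 3 at risk, drop (n-1)/n

    def test_matches_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(2.0, size=50)
        curve = km_curve(t, np.ones(50, int))
        for q in (0.5, 1.0, 2.0):
            empirical = (t > q).mean()
            km_at = curve.loc[curve["time"] <= q, "survival"].iloc[-1]
            assert km_at == pytest.approx(empirical, abs=1e-12)

    def test_starts_at_one_and_non_increasing(self):
        rng = np.random.default_rng(1)
        curve = km_curve(rng.exponential(3, 30),
                         (rng.random(30) < 0.6).astype(int))
        s = curve["survival"].to_numpy()
        assert curve["survival"].iloc[0] == 1.0
        assert (np.diff(s) <= 1e-12).all()


def _hand_logrank(t1, e1, t2, e2):
    """Observed-minus-expected log-rank statistic computed longhand."""
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2])
    group = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    o_minus_e = 0.0
    var = 0.0
    for u in np.unique(times[events == 1]):
        at_risk = times >= u
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = ((times == u) & (events == 1)).sum()
        d1 = ((times == u) & (events == 1) & (group == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_chi2_zero(self):
        g = pd.DataFrame({"time_years": [1, 2, 3, 4],
                          "event": [1, 0, 1, 0]})
        chi2, p = logrank(g, g.copy(), horizon=5.0)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_statistic(self):
        t1 = np.array([0.5, 1.2, 2.0, 2.8, 3.5, 4.4])
        e1 = np.array([1, 1, 0, 1, 1, 0])
        t2 = np.array([0.9, 1.7, 2.4, 3.1, 3.9, 4.8])
        e2 = np.array([1, 0, 1, 1, 0, 1])
        chi2, _ = logrank(pd.DataFrame({"time_years": t1, "event": e1}),
                          pd.DataFrame({"time_years": t2, "event": e2}),
                          horizon=None)
        assert chi2 == pytest.approx(_hand_logrank(t1, e1, t2, e2), rel=1e-9)

    def test_horizon_censors_late_events(self):
        # identical within 5 years; divergent only afterwards
        g1 = pd.DataFrame({"time_years": [1.0, 6.0, 7.0],
                           "event": [1, 1, 1]})
        g2 = pd.DataFrame({"time_years": [1.0, 9.0, 10.0],
                           "event": [1, 1, 1]})
        chi2, p = logrank(g1, g2, horizon=5.0)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_empty_group_rejected(self):
        g = pd.DataFrame({"time_years": [1.0], "event": [1]})
        with pytest.raises(ValueError):
            logrank(g, g.iloc[:0])

    def test_power_against_separated_groups(self):
        """n=100 per arm with hazard ratio e: the test rejects."""
        rng = np.random.default_rng(0)
        t1 = rng.exponential(1.0, 100)
        t2 = rng.exponential(np.e, 100)
        chi2, p = logrank(
            pd.DataFrame({"time_years": t1, "event": np.ones(100, int)}),
            pd.DataFrame({"time_years": t2, "event": np.ones(100, int)}),
            horizon=5.0)
        assert p < 0.001


class TestTdRocCutoff:
    def _cohort(self, densities, times, events):
        return pd.DataFrame({"density": densities, "time_years": times,
                             "event": events})

    def test_separable_marker_gives_auc_one_and_exact_split(self):
        # everyone above 100 dies before year 5, everyone below survives
        dens = np.array([150, 160, 170, 180, 50, 60, 70, 80], float)
        times = np.array([1, 2, 3, 4, 8, 9, 9, 10], float)
        events = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        roc, cutoff, auc = td_roc_cutoff(self._cohort(dens, times, events))
        assert auc == pytest.approx(1.0)
        assert 80 < cutoff <= 150
        j = roc.loc[roc["cutoff"] == cutoff, "youden_j"].iloc[0]
        assert j == pytest.approx(1.0)

    def test_uninformative_marker_auc_near_half(self):
        aucs = []
        for seed in range(8):
            c = fixtures.generate_cohort(fixtures.SynthCohortConfig(
                n_patients=500, log_hazard_ratio_per_unit_density=0.0,
                seed=seed))
            _, _, auc = td_roc_cutoff(c)
            aucs.append(auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            td_roc_cutoff(self._cohort([1.0, 2.0, 3.0], [9, 9, 9], [0, 0, 0]))

    def test_strong_effect_orders_group_event_rates(self):
        c = fixtures.generate_cohort(fixtures.SynthCohortConfig(
            n_patients=300, log_hazard_ratio_per_unit_density=1.5, seed=3))
        summary = stratify_cohort(c)
        hi = c["density"] >= summary.cutoff
        ev_hi = c.loc[hi, "event"].mean()
        ev_lo = c.loc[~hi, "event"].mean()
        assert ev_hi > ev_lo

    def test_naive_variant_close_to_km_without_censoring(self):
        c = fixtures.generate_cohort(fixtures.SynthCohortConfig(
            n_patients=400, log_hazard_ratio_per_unit_density=1.0,
            censoring_rate=0.0, follow_up_cap=np.inf, seed=5))
        _, _, auc_km = td_roc_cutoff(c, adjust="km")
        _, _, auc_naive = td_roc_cutoff(c, adjust="none")
        assert auc_km == pytest.approx(auc_naive, abs=0.02)


class TestStratifyCohort:
    def test_dichotomization_is_a_partition(self):
        c = fixtures.generate_cohort(fixtures.SynthCohortConfig(
            n_patients=150, log_hazard_ratio_per_unit_density=1.0, seed=1))
        s = stratify_cohort(c)
        assert s.group_sizes[1] + s.group_sizes[2] == len(c)
        assert s.group_sizes[1] > 0 and s.group_sizes[2] > 0

    def test_km_curves_start_at_one(self):
        c = fixtures.generate_cohort(fixtures.SynthCohortConfig(
            n_patients=150, log_hazard_ratio_per_unit_density=1.0, seed=2))
        s = stratify_cohort(c)
        for curve in s.km_curves.values():
            assert curve["survival"].iloc[0] == 1.0
            assert (np.diff(curve["survival"]) <= 1e-12).all()
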