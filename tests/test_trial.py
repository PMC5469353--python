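"""Trial design and statistics: minimization assignment, balance enumeration,
power/sample size, cohort summaries, slope regression, missing-data policy,
mixed-design ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rehabsim.trial import (
    assign_minimization,
    balance_percentile,
    cohort_summary,
    imbalance_score,
    impute_and_filter,
    mixed_anova,
    power_one_sample,
    sample_size_two_sample,
    session_slope,
)


def _table(rows):
    return pd.DataFrame(rows)


class TestMinimization:
    def test_empty_groups_random_but_seeded(self):
        empty = _table([]).reindex(columns=["subject", "group", "baseline_arat", "age"])
        new = {"baseline_arat": 30, "age": 50}
        g1 = assign_minimization(empty, new, seed=1)
        assert g1 in ("AAN", "ST")
        assert assign_minimization(empty, new, seed=1) == g1

    def test_assigns_to_group_reducing_gap(self):
        table = _table(
            [{"group": "AAN", "baseline_arat": a, "age": 50} for a in (38, 40, 42)]
            + [{"group": "ST", "baseline_arat": a, "age": 50} for a in (18, 20, 22)]
        )
        new = {"baseline_arat": 20, "age": 50}
        assert assign_minimization(table, new, seed=0) == "AAN"

    def test_missing_covariate_rejected(self):
        with pytest.raises(ValueError):
            assign_minimization(_table([]), {"age": 50}, seed=0)

    def test_minimization_beats_median_random_assignment(self):
        # Monte-Carlo: sequential minimization vs random labelings
        rng = np.random.default_rng(0)
        wins = 0
        n_cohorts = 60
        for c in range(n_cohorts):
            arat = rng.uniform(0, 57, 12)
            age = rng.uniform(20, 75, 12)
            table = _table([]).reindex(columns=["group", "baseline_arat", "age"])
            for i in range(12):
                new = {"baseline_arat": arat[i], "age": age[i]}
                g = assign_minimization(table, new, seed=int(rng.integers(2**31)))
                table = pd.concat(
                    [table, pd.DataFrame([{**new, "group": g}])], ignore_index=True
                )
            final = imbalance_score(table)
            rand_scores = []
            for _ in range(60):
                perm = table.copy()
                perm["group"] = rng.permutation(
                    ["AAN"] * 6 + ["ST"] * 6
                )
                rand_scores.append(imbalance_score(perm))
            wins += final <= np.median(rand_scores)
        assert wins >= 0.95 * n_cohorts


class TestBalancePercentile:
    def test_identical_covariates_all_tie(self):
        table = _table(
            [{"group": g, "baseline_arat": 20, "age": 50}
             for g in ("AAN", "AAN", "ST", "ST")]
        )
        assert balance_percentile(table) == 0.0

    def test_four_subject_enumeration(self):
        # values {0,0,10,10}, realized split {0,10}/{0,10}: only the two
        # {0,0}-vs-{10,10} labelings are strictly worse
        table = _table(
            [
                {"group": "AAN", "baseline_arat": 0, "age": 50},
                {"group": "ST", "baseline_arat": 0, "age": 50},
                {"group": "AAN", "baseline_arat": 10, "age": 50},
                {"group": "ST", "baseline_arat": 10, "age": 50},
            ]
        )
        frac = balance_percentile(table)
        # independent enumeration oracle
        covs = np.array([0.0, 0.0, 10.0, 10.0])
        sd = covs.std(ddof=1)
        realized = 0.0
        worse = total = 0
        for combo in itertools.combinations(range(4), 2):
            mask = np.zeros(4, bool)
            mask[list(combo)] = True
            total += 1
            worse += abs(covs[mask].mean() - covs[~mask].mean()) / sd > realized + 1e-12
        assert frac == pytest.approx(worse / total)
        assert frac == pytest.approx(2 / 6)

    def test_worst_realized_assignment_gives_zero(self):
        table = _table(
            [
                {"group": "AAN", "baseline_arat": 0, "age": 50},
                {"group": "AAN", "baseline_arat": 0, "age": 50},
                {"group": "ST", "baseline_arat": 10, "age": 50},
                {"group": "ST", "baseline_arat": 10, "age": 50},
            ]
        )
        assert balance_percentile(table) == 0.0

    def test_packaged_cohort_enumerable(self, cohort):
        sub = cohort.dropna(subset=["baseline_arat"])
        frac = balance_percentile(sub)
        assert 0.0 <= frac <= 1.0


class TestPowerAndSampleSize:
    def test_reproduces_trial_design_numbers(self):
        n_group, n_enrolled = sample_size_two_sample(3, 2, 0.90, 0.05, 0.20)
        assert (n_group, n_enrolled) == (10, 24)

    def test_doubling_delta_quarters_preceiling_n(self):
        z = stats.norm.ppf(0.975) + stats.norm.ppf(0.9)
        raw1 = 2 * (z * 2 / 3) ** 2
        raw2 = 2 * (z * 2 / 6) ** 2
        assert raw2 == pytest.approx(raw1 / 4)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        delta=st.floats(0.5, 10),
        sd=st.floats(0.5, 10),
        power=st.floats(0.5, 0.99),
    )
    def test_monotonicity(self, delta, sd, power):
        n, _ = sample_size_two_sample(delta, sd, power)
        n_bigger_delta, _ = sample_size_two_sample(delta * 1.5, sd, power)
        n_bigger_sd, _ = sample_size_two_sample(delta, sd * 1.5, power)
        n_more_power, _ = sample_size_two_sample(delta, sd, min(power + 0.005, 0.995))
        assert n_bigger_delta <= n
        assert n_bigger_sd >= n
        assert n_more_power >= n

    def test_power_at_zero_effect_equals_alpha(self):
        p = power_one_sample(20, 0.0, 2.0, 0.05)
        assert p["normal"] == pytest.approx(0.05, abs=1e-6)

    def test_power_approaches_one_for_large_n(self):
        assert power_one_sample(10_000, 0.5, 2.0)["exact"] > 0.999

    def test_trial_one_sample_power_closed_form(self):
        p = power_one_sample(20, 1.5, 2.0, 0.05)
        expected = stats.norm.cdf(1.5 * np.sqrt(20) / 2 - stats.norm.ppf(0.975))
        assert p["normal"] == pytest.approx(expected, abs=1e-4)
        assert 0.85 < p["exact"] < 0.95  # the design's ~90% power


class TestCohortSummary:
    def test_completer_means_match_study_report(self, cohort):
        s = cohort_summary(cohort, completers_only=True, n_screened=37)
        assert s["mean_time_since_injury"] == 16
        assert s["mean_baseline_arat"] == 25
        assert s["dropout_pct"] == 18
        assert s["enrollment_pct"] == 46
        assert s["n"] == 14

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary(pd.DataFrame())


class TestSessionSlope:
    def test_exact_line_zero_width_ci(self):
        r = session_slope(0.5 * np.arange(1, 11))
        assert r.slope == pytest.approx(0.5)
        assert r.zero_residual
        assert r.ci_low == r.ci_high == pytest.approx(0.5)

    def test_constant_deltas_zero_slope(self):
        r = session_slope(np.full(10, 3.3))
        assert r.slope == pytest.approx(0.0, abs=1e-12)
        assert not r.significant

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            session_slope([1.0, 2.0])

    def test_ci_coverage_on_noisy_line(self):
        cov = 0
        for rep in range(100):
            rng = np.random.default_rng(2000 + rep)
            y = 0.5 * np.arange(1, 11) + rng.normal(0, 0.1, 10)
            r = session_slope(y)
            cov += r.ci_low <= 0.5 <= r.ci_high
        assert cov >= 93


class TestImputeAndFilter:
    def _matrix(self, missing_sessions, n_sessions=10):
        rows = []
        for s in ("S01", "S02"):
            for k in range(1, n_sessions + 1):
                v = float(k)
                if s == "S01" and k in missing_sessions:
                    v = np.nan
                rows.append({"subject": s, "group": "AAN", "session": k, "value": v})
        return pd.DataFrame(rows)

    def test_three_missing_sessions_excludes_subject(self):
        out, report = impute_and_filter(self._matrix({1, 2, 3}))
        assert "S01" in report["excluded"]
        assert set(out["subject"]) == {"S02"}

    def test_single_missing_cell_imputed_with_subject_mean(self):
        out, report = impute_and_filter(self._matrix({4}))
        s01 = out[out["subject"] == "S01"].set_index("session")["value"]
        observed_mean = np.mean([k for k in range(1, 11) if k != 4])
        assert s01[4] == pytest.approx(observed_mean)
        assert report["n_replaced"] == 1

    def test_complete_matrix_unchanged(self):
        m = self._matrix(set())
        out, report = impute_and_filter(m)
        assert report["n_replaced"] == 0
        assert len(out) == len(m)


class TestMixedAnova:
    def _long(self, values, groups=("AAN", "ST")):
        """values[group][subject][session]"""
        rows = []
        for g, subs in zip(groups, values):
            for i, sess_vals in enumerate(subs):
                for k, v in enumerate(sess_vals, start=1):
                    rows.append(
                        {"subject": f"{g}{i}", "group": g, "session": k, "value": v}
                    )
        return pd.DataFrame(rows)

    def test_two_level_within_factor_has_unit_epsilon(self):
        rng = np.random.default_rng(0)
        df = self._long([rng.normal(size=(4, 2)), rng.normal(size=(4, 2))])
        res = mixed_anova(df)
        assert res["epsilon"] == 1.0
        assert res["sphericity"]

    def test_matches_hand_rolled_sums_of_squares(self):
        # balanced 2 groups x 3 sessions x 3 subjects toy dataset
        vals = [
            [[1.0, 2.0, 3.0], [2.0, 2.5, 3.5], [0.5, 1.5, 2.0]],
            [[3.0, 3.0, 4.0], [4.0, 5.0, 5.5], [3.5, 4.0, 6.0]],
        ]
        df = self._long(vals)
        res = mixed_anova(df)
        eff = res["effects"].set_index("effect")

        # independent oracle: classical split-plot sums of squares
        y = np.array(vals)  # (group, subject, session)
        g, s, k = y.shape
        grand = y.mean()
        ss_group = s * k * np.sum((y.mean(axis=(1, 2)) - grand) ** 2)
        subj_means = y.mean(axis=2)
        group_means = y.mean(axis=(1, 2))
        ss_subj_within = k * np.sum((subj_means - group_means[:, None]) ** 2)
        ss_session = g * s * np.sum((y.mean(axis=(0, 1)) - grand) ** 2)
        cell = y.mean(axis=1)  # group x session
        ss_inter = s * np.sum(
            (cell - y.mean(axis=(1, 2))[:, None] - y.mean(axis=(0, 1))[None, :] + grand) ** 2
        )
        ss_err = np.sum((y - cell[:, None, :] - subj_means[..., None]
                         + y.mean(axis=(1, 2))[:, None, None]) ** 2)
        f_group = (ss_group / (g - 1)) / (ss_subj_within / (g * (s - 1)))
        f_sess = (ss_session / (k - 1)) / (ss_err / (g * (s - 1) * (k - 1)))
        f_inter = (ss_inter / ((g - 1) * (k - 1))) / (ss_err / (g * (s - 1) * (k - 1)))
        assert eff.loc["group", "F"] == pytest.approx(f_group, abs=1e-10)
        assert eff.loc["session", "F"] == pytest.approx(f_sess, abs=1e-10)
        assert eff.loc["interaction", "F"] == pytest.approx(f_inter, abs=1e-10)

    def test_strong_interaction_triggers_simple_main_effects(self):
        rng = np.random.default_rng(1)
        aan = [[k * 1.0 + rng.normal(0, 0.2) for k in range(5)] for _ in range(5)]
        st_ = [[rng.normal(0, 0.2) for _ in range(5)] for _ in range(5)]
        res = mixed_anova(self._long([aan, st_]))
        assert res["simple_main_effects"] is not None
        assert set(res["simple_main_effects"]) == {"AAN", "ST"}

    def test_tiny_group_rejected(self):
        df = self._long([[[1.0, 2.0]], [[1.0, 2.0], [2.0, 3.0]]])
        with pytest.raises(ValueError):
            mixed_anova(df)
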