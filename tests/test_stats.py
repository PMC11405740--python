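"""Group-comparison machinery: effect-size oracles, test routing, reports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pupilclust.schedule import build_schedule
from pupilclust.stats import (
    compare_groups, cohens_d, rank_effects, chi_square_2x2,
    report_levels, report_blocks, peak_reactions,
)


def rank_effects_oracle(x0, x1):
    """Normative pairwise enumeration of CLES (ties count half)."""
    wins = sum((b > a) + 0.5 * (b == a) for a in x0 for b in x1)
    cles = wins / (len(x0) * len(x1))
    return cles, 2 * cles - 1


class TestRankEffects:
    def test_single_tie(self):
        u, rbc, cles = rank_effects([1.0], [1.0])
        assert cles == pytest.approx(0.5) and rbc == pytest.approx(0.0)

    def test_complete_separation(self):
        u, rbc, cles = rank_effects([1, 2], [3, 4])
        assert cles == 1.0 and rbc == 1.0 and u == 4.0

    def test_matches_enumeration_on_random_instances(self, rng):
        for _ in range(1000):
            n0, n1 = rng.integers(1, 12, 2)
            # integer draws force plenty of ties
            x0 = rng.integers(0, 6, n0).astype(float)
            x1 = rng.integers(0, 6, n1).astype(float)
            u, rbc, cles = rank_effects(x0, x1)
            cles_o, rbc_o = rank_effects_oracle(x0, x1)
            assert cles == pytest.approx(cles_o, abs=1e-12)
            assert rbc == pytest.approx(rbc_o, abs=1e-12)
            assert rbc == pytest.approx(2 * cles - 1, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 5), min_size=1, max_size=10),
           st.lists(st.integers(0, 5), min_size=1, max_size=10))
    def test_rbc_cles_identity_property(self, a, b):
        _, rbc, cles = rank_effects(np.array(a, float), np.array(b, float))
        assert rbc == pytest.approx(2 * cles - 1, abs=1e-12)


class TestCohensD:
    def test_one_pooled_sd_difference(self):
        x0 = np.array([0.0, 1, 2, 3, 4])
        d, _ = cohens_d(x0, x0 + x0.std(ddof=1))
        assert d == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        x0, x1 = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        d_a, (lo_a, hi_a) = cohens_d(x0, x1)
        d_b, (lo_b, hi_b) = cohens_d(x1, x0)
        assert d_a == pytest.approx(-d_b)
        assert lo_a == pytest.approx(-hi_b) and hi_a == pytest.approx(-lo_b)

    def test_recovery_simulation(self, rng):
        """Mean estimate within 0.05 of a true standardized difference 0.5."""
        ds = [cohens_d(rng.normal(0, 1, 50), rng.normal(0.5, 1, 50))[0]
              for _ in range(2000)]
        assert np.mean(ds) == pytest.approx(0.5, abs=0.05)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled SD"):
            cohens_d([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])

    def test_noncentral_ci_brackets_estimate(self, rng):
        x0, x1 = rng.normal(0, 1, 40), rng.normal(0.8, 1, 40)
        d, (lo, hi) = cohens_d(x0, x1, noncentral=True)
        assert lo < d < hi


class TestCompareGroups:
    def test_identical_large_normal_samples(self, rng):
        x = rng.normal(size=200)
        res = compare_groups(x, x)
        assert res.p_value > 0.99
        assert abs(res.d) < 1e-12
        assert res.cles == pytest.approx(0.5)

    def test_complete_separation_effects(self):
        res = compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.cles == 1.0 and res.rbc == 1.0

    def test_normal_groups_use_student_t(self, rng):
        res = compare_groups(rng.normal(0, 1, 40), rng.normal(1, 1, 40))
        assert res.test == "student_t"
        assert np.isfinite(res.r) and -1 <= res.r <= 1

    def test_skewed_groups_use_mann_whitney(self, rng):
        res = compare_groups(rng.exponential(1, 60) ** 3,
                             rng.exponential(1.5, 60) ** 3)
        assert res.test == "mann_whitney"

    def test_constant_group_forces_nonparametric(self):
        res = compare_groups([2.0] * 10, [1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.test == "mann_whitney"

    def test_type_i_error_calibration(self):
        """Null rejection rate of the gated procedure stays near nominal."""
        rng = np.random.default_rng(2024)
        n_rep = 10_000
        rej = sum(compare_groups(rng.normal(size=33), rng.normal(size=37)).p_value < 0.05
                  for _ in range(n_rep))
        assert 0.045 <= rej / n_rep <= 0.055

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestChiSquare:
    def test_uniform_table_null(self):
        chi2, p = chi_square_2x2([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_closed_form_value(self):
        # N(ad-bc)^2 / (r1 r2 c1 c2) = 60*(10*10-20*20)^2/(30*30*30*30)
        chi2, _ = chi_square_2x2([[10, 20], [20, 10]])
        assert chi2 == pytest.approx(60 * (100 - 400) ** 2 / 30**4, abs=1e-9)
        assert chi2 == pytest.approx(6.667, abs=1e-3)

    def test_doubling_cells_doubles_statistic(self, rng):
        tab = rng.integers(5, 30, (2, 2))
        chi2_a, _ = chi_square_2x2(tab)
        chi2_b, _ = chi_square_2x2(2 * tab)
        assert chi2_b == pytest.approx(2 * chi2_a)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [5, 5]])


def make_metrics(rng, n0=15, n1=15, gap=2.0, n_blocks=2, n_levels=3):
    """Long-format metric table with a known group gap on 'mu'."""
    rows = []
    pids, clusters = [], []
    for i in range(n0 + n1):
        pid = f"p{i:02d}"
        cluster = 0 if i < n0 else 1
        pids.append(pid)
        clusters.append(cluster)
        for b in range(1, n_blocks + 1):
            for l in range(1, n_levels + 1):
                rows.append({"participant": pid, "block": b, "level": l,
                             "metric": "mu",
                             "value": gap * (cluster == 0) + rng.normal()})
    labels = pd.DataFrame({"participant": pids, "cluster": clusters})
    return pd.DataFrame(rows), labels


class TestReports:
    def test_separated_metric_significant_everywhere(self, rng):
        metrics, labels = make_metrics(rng, gap=3.0)
        rep = report_levels(metrics, labels)
        assert len(rep) == 6
        assert (rep["p_value"] < 0.05).all()
        assert (rep["mean0"] > rep["mean1"]).all()

    def test_null_calibration_of_level_rows(self, rng):
        metrics, labels = make_metrics(rng, n0=20, n1=20, gap=0.0,
                                       n_blocks=3, n_levels=6)
        perm = labels.copy()
        perm["cluster"] = rng.permutation(perm["cluster"].to_numpy())
        rep = report_levels(metrics, perm)
        assert (rep["p_value"] < 0.05).mean() < 0.25

    def test_missing_metric_rows_skipped(self, rng):
        metrics, labels = make_metrics(rng)
        metrics.loc[metrics["metric"] == "mu", "value"] = np.nan
        rep = report_levels(metrics, labels)
        assert len(rep) == 0

    def test_bh_column_appended_not_substituted(self, rng):
        metrics, labels = make_metrics(rng, gap=0.5)
        rep = report_levels(metrics, labels)
        assert "p_bh" in rep.columns
        assert (rep["p_bh"] >= rep["p_value"] - 1e-12).all()

    def test_block_value_is_mean_of_levels(self, rng):
        metrics, labels = make_metrics(rng, gap=1.0)
        rep = report_blocks(metrics, labels)
        manual = (metrics.merge(labels, on="participant")
                  .groupby(["participant", "block", "cluster"])["value"].mean()
                  .reset_index())
        b1 = manual[(manual.block == 1) & (manual.cluster == 0)]["value"].mean()
        row = rep[rep["segment"].apply(lambda s: s == (1,))].iloc[0]
        assert row["mean0"] == pytest.approx(b1)

    def test_constant_metric_block_value(self, rng):
        metrics, labels = make_metrics(rng, gap=0.0)
        metrics["value"] = 7.0
        rep = report_blocks(metrics, labels)
        assert (rep["mean0"] == 7.0).all() and (rep["mean1"] == 7.0).all()


class TestPeakReactions:
    def test_deception_peak_flagged(self, rng):
        sched = build_schedule()
        rows = []
        pids, clusters = [], []
        for i in range(8):
            pid = f"p{i}"
            pids.append(pid)
            clusters.append(i % 2)
            for b in range(1, 4):
                for l in range(1, 7):
                    val = rng.normal(scale=0.01)
                    if i % 2 == 1 and (b, l) == (2, 3):
                        val += 5.0
                    rows.append({"participant": pid, "block": b, "level": l,
                                 "metric": "pupil", "value": val})
        labels = pd.DataFrame({"participant": pids, "cluster": clusters})
        peaks = peak_reactions(pd.DataFrame(rows), labels, sched)
        row = peaks[(peaks.cluster == 1) & (peaks.metric == "pupil") & (peaks.kind == "max")].iloc[0]
        assert (row.block, row.level) == (2, 3)
        assert row.deceptive

    def test_constant_metric_tie_earliest(self, rng):
        sched = build_schedule()
        rows = [{"participant": f"p{i}", "block": b, "level": l,
                 "metric": "flat", "value": 1.0}
                for i in range(6) for b in range(1, 4) for l in range(1, 7)]
        labels = pd.DataFrame({"participant": [f"p{i}" for i in range(6)],
                               "cluster": [0, 0, 0, 1, 1, 1]})
        peaks = peak_reactions(pd.DataFrame(rows), labels, sched)
        row = peaks[(peaks.cluster == 0) & (peaks.kind == "max")].iloc[0]
        assert (row.block, row.level) == (1, 1)
        assert row.tie

    def test_monotone_metric_max_at_end(self, rng):
        sched = build_schedule()
        rows = [{"participant": f"p{i}", "block": b, "level": l,
                 "metric": "rising", "value": (b - 1) * 6 + l}
                for i in range(6) for b in range(1, 4) for l in range(1, 7)]
        labels = pd.DataFrame({"participant": [f"p{i}" for i in range(6)],
                               "cluster": [0, 0, 0, 1, 1, 1]})
        peaks = peak_reactions(pd.DataFrame(rows), labels, sched)
        row = peaks[(peaks.cluster == 0) & (peaks.kind == "max")].iloc[0]
        assert (row.block, row.level) == (3, 6)
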