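import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dfcmeta import stats


def long_table(values: np.ndarray, n_subj: int, n_runs: int) -> pd.DataFrame:
    """values shaped (2 * n_subj, n_runs): controls first, then cases."""
    rows = []
    i = 0
    for g in ("control", "case"):
        for s in range(n_subj):
            for r in range(n_runs):
                rows.append((f"{g}{s}", g, r + 1, values[i, r]))
            i += 1
    return pd.DataFrame(rows, columns=["subject", "group", "run", "value"])


class TestICC:
    def test_perfect_agreement(self):
        x = np.tile(np.arange(10.0)[:, None], (1, 4))
        icc, band = stats.icc_1_1(x)
        assert icc == pytest.approx(1.0)
        assert band == "almost perfect"

    def test_no_subject_variance(self):
        rng = np.random.default_rng(0)
        icc, _ = stats.icc_1_1(rng.standard_normal((200, 4)))
        assert abs(icc) < 0.1

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((6, 3)) + rng.standard_normal((6, 1))
        icc, _ = stats.icc_1_1(x)
        # explicit one-way ANOVA sums of squares
        n, k = x.shape
        grand = x.mean()
        bss = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
        wss = sum((x[i, j] - x[i].mean()) ** 2 for i in range(n) for j in range(k))
        bms, wms = bss / (n - 1), wss / (n * (k - 1))
        expected = (bms - wms) / (bms + (k - 1) * wms)
        assert icc == pytest.approx(expected, abs=1e-10)

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((8, 3)) + 2 * rng.standard_normal((8, 1))
        a, _ = stats.icc_1_1(x)
        b, _ = stats.icc_1_1(3.5 * x + 100.0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_missing_cells_rejected(self):
        x = np.ones((4, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            stats.icc_1_1(x)


class TestARTAnova:
    def test_pure_group_shift(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((40, 1)) * 0.01  # tiny subject wobble
        vals = np.tile(base, (1, 4))
        vals[20:] += 10.0  # case group shifted
        res = stats.art_anova(long_table(vals, 20, 4))
        assert res["group"]["p"] < 0.001
        assert res["run"]["p"] > 0.9
        assert res["group:run"]["p"] > 0.9

    def test_pure_run_effect(self):
        rng = np.random.default_rng(4)
        vals = rng.standard_normal((40, 4)) * 0.05 + np.array([0, 1, 2, 3.0])
        res = stats.art_anova(long_table(vals, 20, 4))
        assert res["run"]["p"] < 0.001
        assert res["group"]["p"] > 0.05

    def test_planted_interaction(self):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal((40, 4)) * 0.1
        vals[20:, 2:] += 3.0  # cases differ only in later runs
        res = stats.art_anova(long_table(vals, 20, 4))
        assert res["group:run"]["p"] < 0.001

    def test_alignment_diagnostic_zero(self):
        rng = np.random.default_rng(6)
        vals = rng.standard_normal((16, 4))
        res = stats.art_anova(long_table(vals, 8, 4))
        for effect in res.values():
            assert effect["align_max_dev"] < 1e-9

    def test_degrees_of_freedom(self):
        rng = np.random.default_rng(7)
        res = stats.art_anova(long_table(rng.standard_normal((20, 4)), 10, 4))
        assert (res["group"]["df1"], res["group"]["df2"]) == (1, 18)
        assert (res["run"]["df1"], res["run"]["df2"]) == (3, 54)
        assert (res["group:run"]["df1"], res["group:run"]["df2"]) == (3, 54)

    def test_missing_run_rejected(self):
        df = long_table(np.random.default_rng(8).standard_normal((8, 3)), 4, 3)
        df = df.drop(index=0)
        with pytest.raises(ValueError, match="missing runs"):
            stats.art_anova(df)

    def test_type_one_error_calibrated(self):
        # light version of the calibration suite (full run in acceptance)
        rng = np.random.default_rng(9)
        hits = {"group": 0, "run": 0, "group:run": 0}
        n_sim = 200
        for _ in range(n_sim):
            res = stats.art_anova(long_table(rng.standard_normal((30, 4)), 15, 4))
            for e in hits:
                hits[e] += res[e]["p"] < 0.05
        for e, h in hits.items():
            assert 0.02 <= h / n_sim <= 0.09, (e, h / n_sim)


class TestFriedmanWilcoxon:
    def test_friedman_identical_columns(self):
        chi2, p = stats.friedman(np.tile(np.arange(8.0)[:, None], (1, 4)))
        assert chi2 == 0.0
        assert p == 1.0

    def test_friedman_strong_run_effect(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((15, 4)) * 0.1 + np.array([0, 1, 2, 3.0])
        chi2, p = stats.friedman(x)
        assert p < 0.001

    def test_wilcoxon_paired_identical(self):
        x = np.arange(10.0)
        res = stats.wilcoxon_paired(x, x)
        assert res["z"] == 0.0
        assert res["p"] == 1.0
        assert res["r"] == 0.0

    def test_wilcoxon_independent_fully_separated(self):
        x = np.arange(20.0)
        y = np.arange(100.0, 120.0)
        res = stats.wilcoxon_independent(x, y)
        # brute-force oracle for the maximal rank-sum Z at n1 = n2 = 20
        u_max = 20 * 20
        sd_u = np.sqrt(20 * 20 * 41 / 12.0)
        z_expected = (u_max - 200 - 0.5) / sd_u
        assert abs(res["z"]) == pytest.approx(z_expected, abs=1e-10)
        assert res["r"] == pytest.approx(z_expected / np.sqrt(40), abs=1e-10)
        assert 0.85 < res["r"] < 0.87
        assert res["p"] < 1e-6

    def test_wilcoxon_paired_shift_detected(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(30)
        res = stats.wilcoxon_paired(x, x + 1.0)
        assert res["p"] < 0.001
        assert res["r"] > 0.5


class TestPermWelch:
    def test_disjoint_support_floor(self):
        x = np.linspace(0, 1, 15)
        y = np.linspace(10, 11, 15)
        _, p = stats.perm_welch_t(x, y, n_perm=9999, seed=0)
        assert p == pytest.approx(1 / 10000)

    def test_identical_multisets(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        _, p = stats.perm_welch_t(x, x.copy(), n_perm=999, seed=1)
        assert p == 1.0

    def test_determinism(self):
        rng = np.random.default_rng(12)
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        assert stats.perm_welch_t(x, y, seed=5) == stats.perm_welch_t(x, y, seed=5)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(13)
        ps = []
        for _ in range(300):
            x, y = rng.standard_normal(15), rng.standard_normal(15)
            _, p = stats.perm_welch_t(x, y, n_perm=199, seed=rng.integers(1 << 31))
            ps.append(p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestAssumptionChecks:
    def test_equal_samples_zero_d(self):
        x = np.arange(10.0)
        res = stats.assumption_checks(x, x.copy())
        assert res["cohens_d"] == 0.0

    def test_unit_shift_d_near_one(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal(5000)
        y = rng.standard_normal(5000) + 1.0
        res = stats.assumption_checks(x, y)
        assert abs(res["cohens_d"] + 1.0) < 0.05  # x below y -> d approx -1

    def test_skewed_sample_fails_shapiro(self):
        rng = np.random.default_rng(15)
        x = rng.exponential(size=100) ** 2
        y = rng.standard_normal(100)
        res = stats.assumption_checks(x, y)
        assert res["shapiro_p_x"] < 0.05


class TestBonferroni:
    def test_basic(self):
        assert stats.bonferroni([0.01], m=8)[0] == pytest.approx(0.08)

    def test_capped(self):
        assert stats.bonferroni([0.5], m=8)[0] == 1.0

    def test_identity(self):
        assert stats.bonferroni([0.3], m=1)[0] == pytest.approx(0.3)


class TestFlowchart:
    def test_planted_interaction_runs_steps_2_3_6(self):
        rng = np.random.default_rng(16)
        vals = rng.standard_normal((60, 4)) * 0.3
        vals[30:, 2:] += 3.0
        report = stats.flowchart(long_table(vals, 30, 4))
        steps = {t["step"] for t in report.trace}
        assert {1, 2, 3, 6} <= steps
        assert any(c["type"] == "run" for c in report.contrasts)
        assert any(c["type"] == "group" for c in report.contrasts)

    def test_null_data_stops_after_step_1(self):
        stops = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            report = stats.flowchart(long_table(rng.standard_normal((20, 4)), 10, 4))
            if max(t["step"] for t in report.trace) == 1:
                stops += 1
        assert stops / n_seeds >= 0.9

    def test_group_shift_without_interaction(self):
        rng = np.random.default_rng(17)
        vals = rng.standard_normal((40, 4))
        vals[20:] += 2.0
        report = stats.flowchart(long_table(vals, 20, 4))
        assert report.effects["group"]["significant"]
        grp = [c for c in report.contrasts if c["type"] == "group"]
        assert grp and grp[0]["retained"]

    def test_retention_rule(self):
        # run effect size dwarfs the group effect -> contrast not retained
        rng = np.random.default_rng(18)
        vals = rng.standard_normal((40, 4)) * 0.5 + np.array([0, 4, 8, 12.0])
        vals[20:, :] += np.array([0.0, 0.5, 1.0, 1.5])  # mild interaction-ish
        report = stats.flowchart(long_table(vals, 20, 4))
        grp = [c for c in report.contrasts if c["type"] == "group"]
        run = [c for c in report.contrasts if c["type"] == "run" and c["significant"]]
        if grp and run:
            max_run_r = max(c["r"] for c in run)
            for c in grp:
                assert c["retained"] == (c["significant"] and c["r"] > max_run_r)

    def test_single_run_degrades_to_independent_test(self):
        rng = np.random.default_rng(19)
        vals = np.concatenate([rng.standard_normal(15), rng.standard_normal(15) + 3])
        rows = [
            (f"s{i}", "control" if i < 15 else "case", 1, vals[i]) for i in range(30)
        ]
        table = pd.DataFrame(rows, columns=["subject", "group", "run", "value"])
        report = stats.flowchart(table)
        assert report.contrasts[0]["type"] == "group"
        assert report.contrasts[0]["significant"]

    def test_report_serializes(self):
        rng = np.random.default_rng(20)
        report = stats.flowchart(long_table(rng.standard_normal((12, 4)), 6, 4))
        payload = report.to_json()
        assert '"trace"' in payload


def test_p_values_within_unit_interval():
    rng = np.random.default_rng(21)
    for _ in range(20):
        x, y = rng.standard_normal(12), rng.standard_normal(12)
        res = stats.wilcoxon_independent(x, y)
        assert 0 <= res["p"] <= 1
        _, p = stats.perm_welch_t(x, y, n_perm=99, seed=0)
        assert 0 < p <= 1
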