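"""Statistics stage: descriptives, Shapiro-Wilk decisions, Mann-Whitney
U against a brute-force enumeration oracle and scipy's asymptotic test,
correlation against a rank-then-correlate oracle, ROC cutoff search,
and the full cohort analysis report."""

import itertools
import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import carpalcone as cc
from carpalcone.cohort_stats import EXACT_ENUMERATION_BOUND

from conftest import REFERENCE_SWEEP


def enumerate_mw_oracle(a, b):
    """Brute-force two-sided permutation p for the Mann-Whitney U,
    computing U by direct pair counting (no rank-sum identity) for
    every assignment of the pooled values to groups."""
    pooled = np.concatenate([a, b])
    n1, n = len(a), len(pooled)
    # G[i, j] = score of observation i against j (1 win, 0.5 tie).
    G = (pooled[:, None] > pooled[None, :]) + 0.5 * (
        pooled[:, None] == pooled[None, :]
    )
    np.fill_diagonal(G, 0.0)
    mu = n1 * (n - n1) / 2.0
    u_obs = G[:n1, n1:].sum()
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        u = G[np.ix_(mask, ~mask)].sum()
        hits += abs(u - mu) >= dev - 1e-12
        total += 1
    return u_obs, hits / total


class TestDescriptives:
    @pytest.mark.parametrize(
        "values, mean, sd, median",
        [([5, 5, 5], 5.0, 0.0, 5.0), ([1, 2, 3, 4], 2.5, None, 2.5)],
    )
    def test_small_samples(self, values, mean, sd, median):
        s = cc.descriptive_summary(values)
        assert s.mean == pytest.approx(mean)
        assert s.median == pytest.approx(median)
        if sd is not None:
            assert s.sd == pytest.approx(sd)
        assert s.min <= s.median <= s.max

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cc.descriptive_summary([])

    def test_generator_sample_matches_oracle(self):
        """1e4 noiseless draws summarize to the configured truncated-normal
        moments (mean within 0.5 deg of 122.55, SD within 0.5 of oracle)."""
        cohort = cc.generate_cohort(
            cc.CohortConfig(n=10_000, measurement_sd=0.0, seed=9)
        )
        s = cc.descriptive_summary([x.angle_mean for x in cohort])
        cfg = cc.CohortConfig()
        a = (cfg.angle_min - cfg.angle_mean) / cfg.angle_sd
        b = (cfg.angle_max - cfg.angle_mean) / cfg.angle_sd
        dist = sps.truncnorm(a, b, loc=cfg.angle_mean, scale=cfg.angle_sd)
        assert abs(s.mean - 122.55) < 0.5
        assert abs(s.sd - dist.std()) < 0.5


class TestNormalityCheck:
    def test_constant_sample_degenerate(self):
        with pytest.raises(ValueError):
            cc.normality_check([4.0] * 10)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            cc.normality_check([1.0, 2.0])

    def test_uniform_rejected_at_large_n(self, rng):
        res = cc.normality_check(rng.uniform(size=5000))
        assert res.method == "shapiro-wilk"
        assert res.extras["reject_normality"] is True

    def test_type_i_error_calibration(self):
        """Over 200 seeded normal samples (n=5000) the rejection rate at
        alpha 0.05 stays within [0.02, 0.09]."""
        rej = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            rej += cc.normality_check(r.normal(size=5000)).extras["reject_normality"]
        assert 0.02 <= rej / 200 <= 0.09


class TestMannWhitney:
    def test_identical_groups(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = cc.mann_whitney_u(x, x, mode="exact")
        assert res.statistic == pytest.approx(len(x) ** 2 / 2)
        assert res.p_value == 1.0
        res_approx = cc.mann_whitney_u(x, x, mode="approximate")
        assert res_approx.p_value == 1.0

    def test_tiny_exact_case(self):
        # All 6 assignments of {1,2,3,4} into two pairs; the observed
        # split is one of the 2 most extreme -> p = 2/6.
        res = cc.mann_whitney_u([1.0, 2.0], [3.0, 4.0], mode="exact")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cc.mann_whitney_u([], [1.0])

    def test_exact_matches_enumeration_oracle(self, rng):
        """Exact-mode p equals brute-force pair-counting enumeration to
        machine precision on 50 random 8-vs-8 samples without ties."""
        for _ in range(50):
            a = rng.normal(size=8)
            b = rng.normal(loc=rng.uniform(-1, 1), size=8)
            u_ref, p_ref = enumerate_mw_oracle(a, b)
            res = cc.mann_whitney_u(a, b, mode="exact")
            assert res.statistic == pytest.approx(u_ref, abs=1e-9)
            assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_exact_matches_enumeration_with_ties(self, rng):
        """The permutation null needs no tie correction: exact mode agrees
        with the oracle on small tied integer samples (<= 12 observations)."""
        for _ in range(25):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 13 - n1))
            a = rng.integers(0, 4, size=n1).astype(float)
            b = rng.integers(0, 4, size=n2).astype(float)
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            u_ref, p_ref = enumerate_mw_oracle(a, b)
            res = cc.mann_whitney_u(a, b, mode="exact")
            assert res.statistic == pytest.approx(u_ref, abs=1e-9)
            assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_auto_mode_selection(self, rng):
        small = cc.mann_whitney_u(rng.normal(size=5), rng.normal(size=5))
        assert small.extras["mode"] == "exact"
        big = cc.mann_whitney_u(rng.normal(size=40), rng.normal(size=51))
        assert big.extras["mode"] == "approximate"
        assert math.comb(91, 40) > EXACT_ENUMERATION_BOUND

    def test_approximate_agrees_with_scipy(self, rng):
        """The tie/continuity-corrected normal approximation matches
        scipy's asymptotic Mann-Whitney on moderate samples with ties."""
        for _ in range(20):
            a = np.round(rng.normal(0, 2, size=30), 1)
            b = np.round(rng.normal(0.5, 2, size=25), 1)
            res = cc.mann_whitney_u(a, b, mode="approximate")
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            assert res.statistic == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)


class TestCorrelation:
    def test_self_correlation(self):
        x = [1.0, 4.0, 2.0, 7.0, 5.0]
        assert cc.correlation(x, x, "pearson").statistic == pytest.approx(1.0)

    def test_reference_sweep_spearman_is_one(self):
        alphas = sorted(REFERENCE_SWEEP)
        vols = [REFERENCE_SWEEP[a][3] for a in alphas]
        res = cc.correlation(alphas, vols, "spearman")
        assert res.statistic == 1.0

    def test_spearman_equals_rank_pearson_oracle(self, rng):
        """Spearman == Pearson applied to midranks (independent oracle)."""
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            r_oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
            assert cc.correlation(x, y, "spearman").statistic == pytest.approx(
                r_oracle, abs=1e-12
            )

    @given(
        scale=st.floats(min_value=0.1, max_value=50.0),
        shift=st.floats(min_value=-100.0, max_value=100.0),
        cube=st.booleans(),
    )
    @settings(deadline=None, max_examples=25)
    def test_spearman_monotone_invariance(self, scale, shift, cube):
        """Spearman is unchanged by strictly monotone transforms."""
        r = np.random.default_rng(99)
        x, y = r.normal(size=20), r.normal(size=20)
        base = cc.correlation(x, y, "spearman").statistic
        tx = scale * x + shift
        if cube:
            tx = tx**3
        assert cc.correlation(tx, y, "spearman").statistic == pytest.approx(
            base, abs=1e-12
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cc.correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFindCutoff:
    def test_perfect_separation(self):
        values = [float(v) for v in range(1, 11)] + [float(v) for v in range(20, 30)]
        labels = [0] * 10 + [1] * 10
        rep = cc.find_cutoff(values, labels)
        assert rep.youden_j == pytest.approx(1.0)
        assert rep.auc == pytest.approx(1.0)
        assert rep.cutoff_found and rep.verdict == "cutoff found"
        assert 10.0 < rep.threshold < 20.0

    def test_random_labels_no_cutoff(self, rng):
        values = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        rep = cc.find_cutoff(values, labels)
        assert not rep.cutoff_found
        assert rep.verdict == "no suitable cutoff"
        assert abs(rep.auc - 0.5) < 0.05

    def test_auc_equals_normalized_u(self, rng):
        """AUC identity: the empirical AUC equals U/(n1*n2) from the
        rank-sum test on the same data, ties included (50 instances)."""
        for _ in range(50):
            n1 = int(rng.integers(5, 40))
            n0 = int(rng.integers(5, 40))
            values = np.round(rng.normal(size=n1 + n0), 1)
            labels = np.concatenate([np.ones(n1, int), np.zeros(n0, int)])
            rep = cc.find_cutoff(values, labels)
            u = cc.mann_whitney_u(values[labels == 1], values[labels == 0]).statistic
            assert rep.auc == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cc.find_cutoff([1.0, 2.0], [1, 1])


class TestAnalyzeCohort:
    def test_single_subject_skips_comparisons(self):
        cohort = cc.generate_cohort(cc.CohortConfig(n=1, seed=0))
        report = cc.analyze_cohort(cohort)
        assert report["n"] == 1
        assert "skipped" in report["tests"]["sex_vs_angle"]
        assert "skipped" in report["cutoff"]
        assert report["descriptives"]["overall"]["angle_deg"]["n"] == 1

    def test_default_cohort_report_complete(self, default_cohort):
        report = cc.analyze_cohort(default_cohort)
        assert report["n"] == 91
        assert report["calibration"]["B"] == pytest.approx(241.34)
        for key in ("sex_vs_angle", "sex_vs_age", "angle_volume_pearson",
                    "angle_volume_spearman", "normality_angle_deg"):
            assert "p_value" in report["tests"][key]
        json.dumps(report)  # report must be JSON-serializable

    def test_angle_volume_spearman_near_one(self, default_cohort):
        """Volume is a noiseless strictly increasing function of the mean
        angle, so the rank correlation is (numerically) one."""
        report = cc.analyze_cohort(default_cohort)
        assert report["tests"]["angle_volume_spearman"]["statistic"] >= 0.99

    def test_single_sex_cohort_skips_sex_tests(self):
        cohort = cc.generate_cohort(cc.CohortConfig(n=10, male_fraction=1.0, seed=1))
        report = cc.analyze_cohort(cohort)
        assert report["tests"]["sex_vs_angle"] == {"skipped": "single class"}
        assert report["cutoff"] == {"skipped": "single class"}

    def test_sex_angle_null_p_uniform(self):
        """The generator draws angle independently of sex, so the sex-vs-
        angle rank-sum p-value is ~Uniform(0,1) across seeded replicates
        (Kolmogorov distance < 0.1 over 500 cohorts)."""
        ps = []
        for seed in range(500):
            cohort = cc.generate_cohort(cc.CohortConfig(seed=seed))
            angles = np.array([s.angle_mean for s in cohort])
            sexes = np.array([s.sex for s in cohort])
            m, f = angles[sexes == "male"], angles[sexes == "female"]
            if m.size == 0 or f.size == 0:
                continue
            ps.append(cc.mann_whitney_u(m, f, mode="approximate").p_value)
        dist = sps.kstest(ps, "uniform").statistic
        assert dist < 0.1
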