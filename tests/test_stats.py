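"""Within-subject ANOVA, G-G epsilon, eta_G^2 and paired t-tests.

The ANOVA is checked two ways: against a brute-force sums-of-squares
computation written out by explicit summation in this file, and against
pingouin (an independent implementation) for one-way and two-way designs.
Epsilon checks use data matrices constructed to have an *exact* sample
covariance, so sphericity properties hold to machine precision rather
than within simulation noise.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import linalg
from scipy import stats as sps

from toolgaze.stats import (gg_epsilon, generalized_eta_squared, paired_t,
                            pairwise_t, rm_anova)


def long_from_matrix(Y, factor="cond"):
    n, k = Y.shape
    rows = [(s, f"c{j}", Y[s, j]) for s in range(n) for j in range(k)]
    return pd.DataFrame(rows, columns=["subject", factor, "dv"])


def brute_force_oneway(Y):
    """One-way within-subject ANOVA by explicit summation (oracle)."""
    n, k = Y.shape
    grand = Y.mean()
    cond_means = Y.mean(axis=0)
    subj_means = Y.mean(axis=1)
    ss_cond = n * sum((m - grand) ** 2 for m in cond_means)
    ss_subj = k * sum((m - grand) ** 2 for m in subj_means)
    ss_err = sum((Y[s, j] - cond_means[j] - subj_means[s] + grand) ** 2
                 for s in range(n) for j in range(k))
    ss_total = sum((Y[s, j] - grand) ** 2
                   for s in range(n) for j in range(k))
    F = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    return dict(ss_cond=ss_cond, ss_subj=ss_subj, ss_err=ss_err,
                ss_total=ss_total, F=F)


def matrix_with_exact_cov(n, sigma, rng):
    """n x k data whose *sample* covariance equals sigma exactly."""
    k = sigma.shape[0]
    X = rng.normal(size=(n, k + 1))
    X -= X.mean(axis=0)
    Q, _ = np.linalg.qr(X)
    Z = Q[:, :k] * np.sqrt(n - 1)  # centred, sample cov exactly I
    L = np.linalg.cholesky(sigma + 1e-15 * np.eye(k))
    return Z @ L.T


class TestRmAnovaOracle:
    def test_four_subject_toy_matches_brute_force(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(100, 10, size=(4, 3))
        want = brute_force_oneway(Y)
        eff = rm_anova(long_from_matrix(Y), within=["cond"])[0]
        assert eff.F == pytest.approx(want["F"], abs=1e-10)
        assert eff.ss_effect == pytest.approx(want["ss_cond"], abs=1e-8)
        assert eff.ss_error == pytest.approx(want["ss_err"], abs=1e-8)
        # eta_G^2 denominator: effect + subject + error strata
        want_eta = want["ss_cond"] / (want["ss_cond"] + want["ss_subj"]
                                      + want["ss_err"])
        assert eff.eta_g2 == pytest.approx(want_eta, abs=1e-10)

    def test_uncorrected_dfs_26_subjects_3_levels(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(400, 20, size=(26, 3))
        eff = rm_anova(long_from_matrix(Y), within=["cond"])[0]
        assert (eff.df1_unc, eff.df2_unc) == (2, 50)
        assert eff.df1_corr == pytest.approx(eff.epsilon_gg * 2)
        assert eff.df2_corr == pytest.approx(eff.epsilon_gg * 50)

    def test_ss_conservation_two_way(self):
        from toolgaze.stats import _subset_ss
        rng = np.random.default_rng(5)
        data = rng.normal(size=(6, 3, 4))
        ss = _subset_ss(data)
        total = float(np.sum((data - data.mean()) ** 2))
        assert sum(ss.values()) == pytest.approx(total, rel=1e-10)

    def test_matches_pingouin_two_way(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        rows = []
        for s in range(10):
            off = rng.normal(0, 5)
            for a in range(3):
                for b in range(4):
                    rows.append((s, f"a{a}", f"b{b}",
                                 100 + 3 * a + 2 * b + off
                                 + rng.normal(0, 4)))
        df = pd.DataFrame(rows, columns=["subject", "A", "B", "dv"])
        mine = {e.effect: e for e in rm_anova(df, within=["A", "B"])}
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov = pg.rm_anova(data=df, dv="dv", within=["A", "B"],
                              subject="subject", detailed=True,
                              effsize="ng2").set_index("Source")
        for name, key in [("A", "A"), ("B", "B"), ("A x B", "A * B")]:
            assert mine[name].F == pytest.approx(aov.loc[key, "F"],
                                                 rel=1e-9)
            assert mine[name].eta_g2 == pytest.approx(aov.loc[key, "ng2"],
                                                      rel=1e-9)
        # main-effect epsilons agree (pingouin's interaction epsilon uses a
        # different, self-admittedly unreliable definition -- not compared)
        assert mine["A"].epsilon_gg == pytest.approx(aov.loc["A", "eps"],
                                                     rel=1e-6)
        assert mine["B"].epsilon_gg == pytest.approx(aov.loc["B", "eps"],
                                                     rel=1e-6)

    def test_three_way_decomposition_runs_and_conserves(self):
        rng = np.random.default_rng(2)
        rows = [(s, a, b, c, rng.normal())
                for s in range(8) for a in range(2) for b in range(4)
                for c in range(2)]
        df = pd.DataFrame(rows, columns=["subject", "A", "B", "C", "dv"])
        effects = rm_anova(df, within=["A", "B", "C"])
        assert len(effects) == 7  # 3 mains + 3 two-way + 1 three-way
        for e in effects:
            assert e.F >= 0 and 0 <= e.eta_g2 <= 1
            assert 1.0 / e.df1_unc - 1e-12 <= e.epsilon_gg <= 1.0 + 1e-12

    def test_unbalanced_table_names_missing_cells(self):
        df = long_from_matrix(np.zeros((4, 3)))
        df = df[~((df.subject == 2) & (df.cond == "c1"))]
        with pytest.raises(ValueError, match="missing cells"):
            rm_anova(df, within=["cond"])

    def test_noiseless_single_source_eta_is_one(self):
        # dv depends on condition only: no subject variance at all
        Y = np.tile([1.0, 2.0, 3.0], (6, 1))
        eff = rm_anova(long_from_matrix(Y), within=["cond"])[0]
        assert eff.eta_g2 == pytest.approx(1.0)
        assert np.isinf(eff.F) and eff.p_gg == 0.0


class TestEpsilon:
    def test_lower_bound_k3(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            Y = rng.normal(size=(8, 3))
            assert 0.5 - 1e-12 <= gg_epsilon(Y) <= 1.0 + 1e-12

    def test_exact_compound_symmetry_gives_one(self):
        rng = np.random.default_rng(3)
        sigma = 2.0 * np.eye(4) + 1.5 * np.ones((4, 4))
        Y = matrix_with_exact_cov(12, sigma, rng)
        assert gg_epsilon(Y) == pytest.approx(1.0, abs=1e-9)

    def test_rank_one_contrast_covariance_hits_lower_bound(self):
        rng = np.random.default_rng(4)
        w = np.array([1.0, -1.0, 0.0])  # rank-1, not proportional to 1
        sigma = np.outer(w, w)
        Y = matrix_with_exact_cov(10, sigma, rng)
        assert gg_epsilon(Y) == pytest.approx(0.5, abs=1e-9)

    def test_constructed_epsilon_point_eight(self):
        # contrast-space eigenvalues (1, 3): eps = (1+3)^2/(2*(1+9)) = 0.8
        rng = np.random.default_rng(5)
        C = linalg.helmert(3).T
        sigma = C @ np.diag([1.0, 3.0]) @ C.T + np.ones((3, 3))
        Y = matrix_with_exact_cov(26, sigma, rng)
        assert gg_epsilon(Y) == pytest.approx(0.8, abs=1e-9)

    def test_p_gg_increases_as_epsilon_decreases(self):
        F, df1, df2 = 4.0, 2, 50
        ps = [sps.f.sf(F, e * df1, e * df2) for e in (1.0, 0.8, 0.6)]
        assert ps[0] < ps[1] < ps[2]


class TestPairedT:
    def _table(self, a, b):
        rows = [(s, "A", a[s]) for s in range(len(a))]
        rows += [(s, "B", b[s]) for s in range(len(b))]
        return pd.DataFrame(rows, columns=["subject", "tool_end", "dv"])

    def test_identical_levels(self):
        x = np.arange(10.0)
        r = paired_t(self._table(x, x), "A", "B")
        assert (r.t, r.mean_diff, r.p_raw) == (0.0, 0.0, 1.0)

    def test_constant_difference_capped_not_infinite(self):
        x = np.arange(10.0)
        r = paired_t(self._table(x + 5, x), "A", "B")
        assert r.degenerate and np.isfinite(r.t)
        assert r.mean_diff == pytest.approx(5.0)
        assert r.p_raw == 0.0

    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(0)
        r = paired_t(self._table(rng.normal(size=26), rng.normal(size=26)),
                     "A", "B")
        assert r.df == 25

    def test_matches_scipy_and_sign_convention(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(5, 1, 20), rng.normal(4, 1, 20)
        r = paired_t(self._table(a, b), "A", "B")
        t, p = sps.ttest_rel(a, b)
        assert r.t == pytest.approx(t) and r.p_raw == pytest.approx(p)
        assert np.sign(r.t) == np.sign(r.mean_diff)

    def test_holm_adjustment_ordering(self):
        rng = np.random.default_rng(2)
        rows = []
        for s in range(15):
            for lv, mu in (("a", 0.0), ("b", 1.5), ("c", 0.1)):
                rows.append((s, lv, mu + rng.normal()))
        df = pd.DataFrame(rows, columns=["subject", "tool_end", "dv"])
        res = pairwise_t(df)
        assert len(res) == 3
        for r in res:
            assert r.p_adjusted >= r.p_raw - 1e-15


class TestEtaG2:
    def test_zero_effect(self):
        assert generalized_eta_squared(0.0, 38.0) == 0.0

    def test_toy_ratio(self):
        assert generalized_eta_squared(2.0, 38.0) == pytest.approx(0.05)
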