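"""Statistical battery against independent oracles: textbook mean-based
ANOVA decomposition, closed forms, dense quadrature, and pingouin."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy import stats as sps

from rivalrykit.stats import (bonferroni_adjust, fit_ip_logistic, gg_epsilon,
                              jzs_bf10_paired, paired_t, pearson_cor, rm_anova)


# ---------------------------------------------------------------------------
# oracles

def oneway_anova_oracle(Y):
    """SS/F for a one-way within design by explicit design-matrix least squares."""
    n, k = Y.shape
    y = Y.reshape(-1)
    subj = np.repeat(np.arange(n), k)
    cond = np.tile(np.arange(k), n)

    def rss(cols):
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(np.sum((y - X @ beta) ** 2))

    subj_d = [(subj == i).astype(float) for i in range(n)]
    cond_d = [(cond == j).astype(float) for j in range(k)]
    rss_reduced = rss(subj_d)
    rss_full = rss(subj_d + cond_d[1:])
    ss_a = rss_reduced - rss_full
    ss_err = rss_full
    F = (ss_a / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    return ss_a, ss_err, F


def twoway_anova_oracle(Y, a, b):
    """Textbook marginal-mean decomposition of a two-way within design."""
    n = Y.shape[0]
    Yab = Y.reshape(n, a, b)
    m = Yab.mean()
    mA = Yab.mean(axis=(0, 2))
    mB = Yab.mean(axis=(0, 1))
    mS = Yab.mean(axis=(1, 2))
    mAB = Yab.mean(axis=0)
    mAS = Yab.mean(axis=2)
    mBS = Yab.mean(axis=1)
    out = {}
    ss_a = n * b * np.sum((mA - m) ** 2) / 1
    ss_as = b * np.sum((mAS - mA[None, :] - mS[:, None] + m) ** 2)
    out["A"] = (ss_a, ss_as, (ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1))))
    ss_b = n * a * np.sum((mB - m) ** 2)
    ss_bs = a * np.sum((mBS - mB[None, :] - mS[:, None] + m) ** 2)
    out["B"] = (ss_b, ss_bs, (ss_b / (b - 1)) / (ss_bs / ((b - 1) * (n - 1))))
    ss_ab = n * np.sum((mAB - mA[:, None] - mB[None, :] + m) ** 2)
    resid = (Yab - mAB[None] - mAS[:, :, None] - mBS[:, None, :]
             + mA[None, :, None] + mB[None, None, :] + mS[:, None, None] - m)
    ss_abs = np.sum(resid ** 2)
    df_ab = (a - 1) * (b - 1)
    out["A:B"] = (ss_ab, ss_abs, (ss_ab / df_ab) / (ss_abs / (df_ab * (n - 1))))
    return out


def _long_table(Y, factors):
    n = Y.shape[0]
    rows = []
    from itertools import product
    cells = list(product(*[range(k) for k in factors.values()]))
    names = list(factors)
    for i in range(n):
        for j, cell in enumerate(cells):
            row = {"subject": f"s{i}", "y": Y[i, j]}
            for name, lev in zip(names, cell):
                row[name] = f"{name}{lev}"
            rows.append(row)
    return pd.DataFrame(rows)


def bf_delta_space_oracle(t, n, rscale, nodes=200_001, span=60.0):
    """BF10 by dense Simpson integration over the effect size itself."""
    nu = n - 1
    delta = np.linspace(-span, span, nodes)
    num = sps.nct.pdf(t, nu, delta * math.sqrt(n)) * sps.cauchy.pdf(delta, 0, rscale)
    return integrate.simpson(num, x=delta) / sps.t.pdf(t, nu)


# ---------------------------------------------------------------------------
# rm-ANOVA

class TestRmAnova:
    def test_two_level_factor_equals_squared_paired_t(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            Y = rng.normal(size=(9, 2))
            table = _long_table(Y, {"a": 2})
            res = rm_anova(table, dv="y", within=["a"])["a"]
            tt = paired_t(Y[:, 0], Y[:, 1])
            assert abs(res.F - tt.t ** 2) < 1e-8
            assert res.p == pytest.approx(tt.p, abs=1e-10)

    def test_oneway_matches_design_matrix_oracle(self):
        rng = np.random.default_rng(4)
        for n, k in [(6, 3), (8, 3), (5, 2)]:
            Y = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            ss_a, ss_err, F = oneway_anova_oracle(Y)
            res = rm_anova(_long_table(Y, {"a": k}), dv="y", within=["a"])["a"]
            assert res.ss == pytest.approx(ss_a, abs=1e-8)
            assert res.ss_error == pytest.approx(ss_err, abs=1e-8)
            assert res.F == pytest.approx(F, abs=1e-8)

    def test_twoway_matches_textbook_decomposition(self):
        rng = np.random.default_rng(5)
        for n, a, b in [(6, 2, 3), (8, 2, 2), (7, 3, 2)]:
            Y = rng.normal(size=(n, a * b)) + rng.normal(size=(n, 1))
            oracle = twoway_anova_oracle(Y, a, b)
            res = rm_anova(_long_table(Y, {"a": a, "b": b}), dv="y", within=["a", "b"])
            for key, name in [("A", "a"), ("B", "b"), ("A:B", "a:b")]:
                ss, ss_err, F = oracle[key]
                assert res[name].ss == pytest.approx(ss, abs=1e-8)
                assert res[name].ss_error == pytest.approx(ss_err, abs=1e-8)
                assert res[name].F == pytest.approx(F, abs=1e-8)

    def test_agrees_with_pingouin_including_gg(self):
        import pingouin as pg

        rng = np.random.default_rng(6)
        Y = rng.normal(size=(12, 3)) + np.array([0.0, 0.4, 0.9])
        table = _long_table(Y, {"a": 3})
        res = rm_anova(table, dv="y", within=["a"])["a"]
        ref = pg.rm_anova(data=table, dv="y", within="a", subject="subject",
                          correction=True, detailed=True)
        assert res.F == pytest.approx(float(ref.loc[0, "F"]), rel=1e-9)
        assert res.gg_epsilon == pytest.approx(float(ref.loc[0, "eps"]), rel=1e-6)
        assert res.p_gg == pytest.approx(float(ref.loc[0, "p_GG_corr"]), rel=1e-6)

    def test_fractional_corrected_dfs_reported_for_three_levels(self):
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(10, 6)) * np.array([1, 1, 1, 1, 2, 3.0])
        res = rm_anova(_long_table(Y, {"m": 2, "c": 3}), dv="y", within=["m", "c"])
        eff = res["c"]
        assert eff.gg_epsilon is not None and eff.df_num_gg == pytest.approx(
            eff.gg_epsilon * 2)
        assert 1 / 2 <= eff.gg_epsilon <= 1
        assert res["m"].gg_epsilon is None  # two-level factor needs no correction
        assert res["m:c"].gg_epsilon is not None

    def test_missing_cell_raises_naming_subject(self):
        rng = np.random.default_rng(8)
        table = _long_table(rng.normal(size=(5, 3)), {"a": 3})
        table = table[~((table["subject"] == "s2") & (table["a"] == "a1"))]
        with pytest.raises(ValueError, match="s2"):
            rm_anova(table, dv="y", within=["a"])


class TestGGEpsilon:
    def test_compound_symmetry_gives_one(self):
        S = 0.3 * np.ones((4, 4)) + 0.7 * np.eye(4)
        assert gg_epsilon(S) == pytest.approx(1.0)

    def test_closed_form_on_diagonal_covariance(self):
        S = np.diag([1.0, 1.0, 10.0])
        # independent elementwise double-centering arithmetic
        row = S.mean(axis=1)
        St = S - row[:, None] - row[None, :] + S.mean()
        expected = np.trace(St) ** 2 / (2 * np.sum(St * St))
        assert gg_epsilon(S) == pytest.approx(expected, abs=1e-12)

    def test_lower_bound_for_three_levels(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            A = rng.normal(size=(3, 6))
            eps = gg_epsilon(A @ A.T)
            assert 0.5 - 1e-12 <= eps <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# paired t, Bonferroni

class TestPairedT:
    def test_identical_samples_error_on_zero_variance(self):
        with pytest.raises(ValueError):
            paired_t([1, 2, 3], [1, 2, 3])

    def test_zero_mean_difference(self):
        res = paired_t([1.0, 2.0, 3.0, 4.0], [1.5, 1.5, 3.5, 3.5])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_arithmetic_example(self):
        # diffs (1,2,3,4): mean 2.5, sd 1.2910, SE 0.6455
        res = paired_t([1.0, 2.0, 3.0, 4.0], [0.0, 0.0, 0.0, 0.0])
        assert res.t == pytest.approx(2.5 / (np.std([1, 2, 3, 4], ddof=1) / 2), abs=1e-12)
        assert res.t == pytest.approx(3.87298, abs=1e-4)
        assert res.df == 3
        assert res.d_z == pytest.approx(2.5 / np.std([1, 2, 3, 4], ddof=1))

    def test_sign_flip_symmetry(self):
        x = np.array([1.0, 2.0, 3.5, 0.5, 2.2])
        y = np.zeros(5)
        a = paired_t(x, y)
        b = paired_t(y, x)
        assert b.t == pytest.approx(-a.t)
        assert b.p == pytest.approx(a.p)

    def test_one_sided(self):
        x = np.array([1.0, 2.0, 3.5, 0.5, 2.2])
        y = np.zeros(5)
        assert paired_t(x, y, "greater").p == pytest.approx(paired_t(x, y).p / 2)


class TestBonferroni:
    def test_examples(self):
        assert bonferroni_adjust([0.01, 0.04], m=2) == [0.02, 0.08]
        assert bonferroni_adjust([0.9], m=3) == [1.0]

    def test_order_preserving(self):
        rng = np.random.default_rng(10)
        p = sorted(rng.uniform(size=8))
        assert bonferroni_adjust(p, m=10) == sorted(bonferroni_adjust(p, m=10))

    def test_family_smaller_than_input_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2, 0.3], m=2)


# ---------------------------------------------------------------------------
# JZS Bayes factor

class TestJZSBayesFactor:
    def test_null_t_favors_null(self):
        assert jzs_bf10_paired(0.0, 30).bf10 < 1

    def test_monotone_in_t(self):
        bfs = [jzs_bf10_paired(t, 28).bf10 for t in (0.0, 1.0, 2.0, 3.0, 4.0)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_symmetric_in_t_sign(self):
        assert jzs_bf10_paired(2.3, 20).bf10 == pytest.approx(
            jzs_bf10_paired(-2.3, 20).bf10, rel=1e-9)

    def test_matches_delta_space_oracle(self):
        r = math.sqrt(2) / 2
        for t, n in [(2.5, 28), (0.5, 10), (4.0, 100)]:
            mine = jzs_bf10_paired(t, n, r)
            assert mine.error_bound <= 1e-6
            assert mine.bf10 == pytest.approx(bf_delta_space_oracle(t, n, r), rel=1e-6)

    def test_bf10_bf01_reciprocal(self):
        res = jzs_bf10_paired(1.7, 25)
        assert res.bf10 * res.bf01 == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# random-intercept logistic

def _records(counts):
    rows = []
    for subj, (kf, nf, kb, nb) in counts.items():
        for mim, k, n in [("free", kf, nf), ("blocked", kb, nb)]:
            rows += [{"subject": subj, "mimicry": mim,
                      "ip": "happy" if j < k else "neutral"} for j in range(n)]
    return pd.DataFrame(rows)


class TestIPLogistic:
    def test_zero_variance_matches_2x2_log_odds(self):
        # pooled frequencies: blocked 304 happy / 128 neutral, free 317 / 113,
        # split over two subjects; the constrained slope is the 2x2 log odds
        # ratio ln[(304/128)/(317/113)] ~ -0.1665 (OR ~ 0.8466)
        df = _records({"s1": (158, 215, 152, 216), "s2": (159, 215, 152, 216)})
        fit = fit_ip_logistic(df, constrain_zero_variance=True)
        expected = math.log((304 / 128) / (317 / 113))
        assert fit.beta == pytest.approx(expected, abs=1e-6)
        assert fit.odds_ratio == pytest.approx(0.8466, abs=1e-4)

    def test_balanced_counts_give_zero_slope(self):
        df = _records({f"s{i}": (8, 16, 8, 16) for i in range(6)})
        fit = fit_ip_logistic(df)
        assert abs(fit.beta) < 1e-4
        assert fit.odds_ratio == pytest.approx(1.0, abs=1e-3)

    def test_single_subject_refused(self):
        with pytest.raises(ValueError, match="two subjects"):
            fit_ip_logistic(_records({"s1": (5, 10, 3, 10)}))

    def test_separation_detected(self):
        df = _records({"s1": (10, 10, 0, 10), "s2": (10, 10, 0, 10)})
        with pytest.raises(ValueError, match="separation"):
            fit_ip_logistic(df)

    def test_reduces_to_plain_logistic_when_variance_vanishes(self):
        rng = np.random.default_rng(11)
        # homogeneous subjects: AGHQ estimate approaches the pooled fit
        df = _records({f"s{i}": (int(rng.binomial(20, 0.7)), 20,
                                 int(rng.binomial(20, 0.6)), 20) for i in range(20)})
        full = fit_ip_logistic(df)
        pooled = fit_ip_logistic(df, constrain_zero_variance=True)
        assert full.beta == pytest.approx(pooled.beta, abs=0.05)

    def test_recovery_on_simulated_subjects(self):
        rng = np.random.default_rng(12)
        hits = 0
        n_reps = 30
        for _ in range(n_reps):
            counts = {}
            for i in range(28):
                u = rng.normal(0, 0.5)
                pf = 1 / (1 + math.exp(-(0.8 + u)))
                pb = 1 / (1 + math.exp(-(0.8 - 0.2 + u)))
                counts[f"s{i}"] = (rng.binomial(16, pf), 16, rng.binomial(16, pb), 16)
            fit = fit_ip_logistic(_records(counts))
            if abs(fit.beta - (-0.2)) <= 2 * fit.se:
                hits += 1
        assert hits / n_reps >= 0.8


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        assert pearson_cor(x, x).r == pytest.approx(1.0)
        assert pearson_cor(x, -x).r == pytest.approx(-1.0)

    def test_df_convention(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(size=28), rng.normal(size=28)
        res = pearson_cor(x, y)
        assert res.df == 26 and res.n == 28
        r, p = sps.pearsonr(x, y)
        assert res.p == pytest.approx(p)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_cor([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
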