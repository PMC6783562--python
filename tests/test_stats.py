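"""Correlation banding, PCA and repeated-measures ANOVA against oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from melstat.encoding import IntervalPattern
from melstat.markov import PieceByPatternMatrix
from melstat.stats import (
    band_correlations,
    bonferroni_posthoc,
    correlate_pieces,
    count_correlations_at,
    pca_pieces,
    related_keys,
    rm_anova,
)


def make_matrix(values, order=1):
    values = np.asarray(values, dtype=float)
    vocab = [IntervalPattern((0, j + 1)) for j in range(values.shape[1])]
    ids = [f"p{i}" for i in range(values.shape[0])]
    return PieceByPatternMatrix(order=order, piece_ids=ids, vocabulary=vocab, values=values)


def hand_pearson(x, y):
    """Textbook formula, written out without numpy vector helpers."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


class TestCorrelation:
    def test_identical_rows_r_one(self):
        report = correlate_pieces(make_matrix([[0.1, 0.5, 0.4], [0.1, 0.5, 0.4]]))
        assert report.r[0, 1] == pytest.approx(1.0)

    def test_opposite_rows_r_minus_one(self):
        x = [0.3, -1.2, 0.9, 0.1]
        report = correlate_pieces(make_matrix([x, [-v for v in x]]))
        assert report.r[0, 1] == pytest.approx(-1.0)

    def test_matches_hand_pearson(self):
        rows = [[0.5, 0.2, 0.1, 0.2], [0.4, 0.4, 0.1, 0.1], [0.1, 0.2, 0.3, 0.4]]
        report = correlate_pieces(make_matrix(rows))
        for i, j in itertools.combinations(range(3), 2):
            assert report.r[i, j] == pytest.approx(hand_pearson(rows[i], rows[j]), abs=1e-12)
            assert report.r[i, j] == report.r[j, i]

    def test_p_values_match_scipy(self):
        rng = np.random.default_rng(11)
        rows = rng.random((4, 20))
        report = correlate_pieces(make_matrix(rows))
        for i, j in itertools.combinations(range(4), 2):
            r, p = sps.pearsonr(rows[i], rows[j])
            assert report.r[i, j] == pytest.approx(r, abs=1e-12)
            assert report.p[i, j] == pytest.approx(p, abs=1e-12)

    def test_zero_variance_row_flagged(self):
        report = correlate_pieces(make_matrix([[0.2, 0.2, 0.2], [0.1, 0.5, 0.4]]))
        assert report.undefined[0, 1]
        assert report.band[0, 1] == "none"

    def test_spearman_is_rank_pearson(self):
        rng = np.random.default_rng(5)
        rows = rng.random((3, 12))
        report = correlate_pieces(make_matrix(rows), method="spearman")
        expect = sps.spearmanr(rows[0], rows[1]).statistic
        assert report.r[0, 1] == pytest.approx(expect, abs=1e-12)

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(3)
        report = correlate_pieces(make_matrix(rng.random((8, 30))))
        assert np.linalg.eigvalsh(report.r).min() >= -1e-10


class TestBanding:
    def test_band_boundaries(self):
        # banding is a pure function of (|r|, p)
        from melstat.stats import _band_of

        assert _band_of(0.75, 0.001) == "strong"
        assert _band_of(-0.7, 0.001) == "strong"
        assert _band_of(0.5, 0.001) == "moderate"
        assert _band_of(0.25, 0.001) == "weak"
        assert _band_of(0.15, 0.001) == "none"
        assert _band_of(0.9, 0.05) == "none"  # not significant at 0.01

    def test_identical_rows_all_strong(self):
        report = correlate_pieces(
            make_matrix([[0.1, 0.5, 0.4, 0.2]] * 3 + [[0.1, 0.5, 0.41, 0.2]])
        )
        bands = band_correlations(report)
        assert bands.set_index("band").loc["strong", "pairs"] == 6

    def test_permuting_pieces_preserves_band_counts(self):
        rng = np.random.default_rng(9)
        rows = rng.random((6, 25))
        before = band_correlations(correlate_pieces(make_matrix(rows)))
        after = band_correlations(correlate_pieces(make_matrix(rows[::-1])))
        assert before["pairs"].tolist() == after["pairs"].tolist()

    def test_count_correlations_threshold(self):
        report = correlate_pieces(
            make_matrix([[0.1, 0.5, 0.4], [0.1, 0.5, 0.4], [0.4, 0.5, 0.1]])
        )
        assert count_correlations_at(report, 0.3) >= 1


class TestPCA:
    def test_rank_one_two_pieces(self):
        x = np.array([0.1, 0.4, 0.2, 0.8, 0.3])
        m = make_matrix(np.vstack([x, 2 * x]))
        res = pca_pieces(m)
        assert res.n_retained == 1
        assert res.variance_pct[0] == pytest.approx(100.0)
        assert res.loadings["component_1"].values == pytest.approx([1.0, 1.0])

    def test_trace_conservation(self):
        rng = np.random.default_rng(21)
        m = make_matrix(rng.random((5, 100)))
        res = pca_pieces(m)
        assert res.eigenvalues.sum() == pytest.approx(5.0)
        assert (res.eigenvalues / 5 * 100).sum() == pytest.approx(100.0)

    def test_matches_svd_oracle(self):
        """Loadings agree (up to sign) with an independent SVD of the
        standardized data matrix."""
        rng = np.random.default_rng(17)
        X = rng.random((40, 6))  # observations x pieces
        m = make_matrix(X.T)
        res = pca_pieces(m)
        Z = (X - X.mean(0)) / X.std(0)
        _, s, vt = np.linalg.svd(Z, full_matrices=False)
        eig = s**2 / X.shape[0]
        assert res.eigenvalues[: len(eig)] == pytest.approx(eig, abs=1e-10)
        for k in range(res.n_retained):
            oracle = vt[k] * np.sqrt(eig[k])
            got = res.loadings.values[:, k]
            assert np.allclose(got, oracle, atol=1e-10) or np.allclose(
                got, -oracle, atol=1e-10
            )

    def test_variance_shares_non_increasing(self):
        rng = np.random.default_rng(2)
        res = pca_pieces(make_matrix(rng.random((6, 50))))
        v = res.variance_pct
        assert all(a >= b for a, b in zip(v, v[1:]))
        assert res.cumulative_pct == pytest.approx(np.cumsum(v))

    def test_constant_piece_named_in_error(self):
        m = make_matrix([[0.2, 0.2, 0.2, 0.2], [0.1, 0.5, 0.4, 0.2]])
        with pytest.raises(ValueError, match="p0"):
            pca_pieces(m)

    def test_few_observations_warns(self):
        rng = np.random.default_rng(4)
        with pytest.warns(UserWarning, match="observations"):
            pca_pieces(make_matrix(rng.random((5, 4))))


def rm_anova_oracle_2x2(Y):
    """Textbook sums-of-squares oracle for a 2-factor within design.

    Y has shape (subjects, levels_A, levels_B); returns F for the A main
    effect computed from marginal means, the long way.
    """
    S, a, b = Y.shape
    grand = Y.mean()
    m_sA = Y.mean(axis=2)  # subject x A
    m_A = Y.mean(axis=(0, 2))
    m_s = Y.mean(axis=(1, 2))
    ss_A = S * b * ((m_A - grand) ** 2).sum()
    ss_As = b * ((m_sA - m_s[:, None] - m_A[None, :] + grand) ** 2).sum()
    df_A, df_err = a - 1, (a - 1) * (S - 1)
    return (ss_A / df_A) / (ss_As / df_err)


class TestRmAnova:
    def _long(self, Y, factors):
        names = list(factors)
        rows = []
        for s in range(Y.shape[0]):
            for idx in itertools.product(*[range(len(v)) for v in factors.values()]):
                rows.append(
                    {
                        "subject": s,
                        **{n: factors[n][i] for n, i in zip(names, idx)},
                        "y": Y[(s, *idx)],
                    }
                )
        return pd.DataFrame(rows)

    def test_constant_data_gives_zero_f(self):
        Y = np.full((6, 2, 3), 2.5)
        df = self._long(Y, {"A": ["a1", "a2"], "B": ["b1", "b2", "b3"]})
        res = rm_anova(df, "y", "subject", ["A", "B"])
        assert (res.table["F"] == 0).all()
        assert (res.table["p"] == 1).all()

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(123)
        Y = rng.normal(size=(12, 2, 4))
        Y[:, 1, :] += 0.7  # planted main effect
        df = self._long(Y, {"A": ["a1", "a2"], "B": list("wxyz")})
        res = rm_anova(df, "y", "subject", ["A", "B"], gg_policy="never")
        assert res.effect("A")["F"] == pytest.approx(rm_anova_oracle_2x2(Y), abs=1e-8)

    def test_matches_pingouin_two_way(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        Y = rng.normal(size=(10, 2, 4))
        df = self._long(Y, {"A": ["a1", "a2"], "B": list("wxyz")})
        res = rm_anova(df, "y", "subject", ["A", "B"], gg_policy="never")
        ref = pg.rm_anova(df, dv="y", within=["A", "B"], subject="subject", detailed=True)
        for src, eff in [("A", "A"), ("B", "B"), ("A * B", "A * B")]:
            row = ref[ref["Source"] == src].iloc[0]
            got = res.effect(eff)
            assert got["F"] == pytest.approx(row["F"], abs=1e-8)
            assert got["p_uncorrected"] == pytest.approx(row["p_unc"], abs=1e-8)
            assert (got["df1_uncorrected"], got["df2_uncorrected"]) == (
                row["ddof1"], row["ddof2"],
            )

    def test_gg_epsilon_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        cov = np.array([[1, 0.8, 0.2, 0.1], [0.8, 1, 0.2, 0.1],
                        [0.2, 0.2, 1, 0.1], [0.1, 0.1, 0.1, 1]])
        Y = rng.multivariate_normal(np.arange(4) * 0.3, cov, size=12)
        df = self._long(Y, {"B": ["b1", "b2", "b3", "b4"]})
        res = rm_anova(df, "y", "subject", ["B"], gg_policy="always")
        ref = pg.rm_anova(df, dv="y", within="B", subject="subject",
                          correction=True).iloc[0]
        got = res.effect("B")
        assert got["gg_epsilon"] == pytest.approx(ref["eps"], abs=1e-8)
        assert got["p"] == pytest.approx(ref["p_GG_corr"], abs=1e-8)
        sph = pg.sphericity(df, dv="y", within="B", subject="subject")
        assert got["mauchly_W"] == pytest.approx(sph.W, abs=1e-8)

    def test_corrected_dfs_never_exceed_uncorrected(self):
        rng = np.random.default_rng(31)
        Y = rng.normal(size=(8, 2, 4)) * np.array([0.2, 1, 3, 0.5])
        df = self._long(Y, {"A": ["a1", "a2"], "B": list("wxyz")})
        res = rm_anova(df, "y", "subject", ["A", "B"], gg_policy="always")
        assert (res.table["df1"] <= res.table["df1_uncorrected"] + 1e-12).all()
        assert (res.table["df2"] <= res.table["df2_uncorrected"] + 1e-12).all()
        assert res.table["partial_eta_sq"].between(0, 1).all()

    def test_incomplete_design_lists_missing_cells(self):
        Y = np.zeros((4, 2, 2))
        df = self._long(Y, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        df = df[~((df.subject == 0) & (df.A == "a1") & (df.B == "b2"))]
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova(df, "y", "subject", ["A", "B"])

    def test_four_way_effect_count(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(4, 2, 2, 2, 3))
        df = self._long(
            Y,
            {"A": ["a1", "a2"], "B": ["b1", "b2"], "C": ["c1", "c2"], "D": list("pqr")},
        )
        res = rm_anova(df, "y", "subject", ["A", "B", "C", "D"])
        assert len(res.table) == 15  # all main effects and interactions


class TestBonferroni:
    def _df(self, Y, levels):
        rows = [
            {"subject": s, "g": levels[j], "y": Y[s, j]}
            for s in range(Y.shape[0])
            for j in range(Y.shape[1])
        ]
        return pd.DataFrame(rows)

    def test_two_levels_single_comparison(self):
        rng = np.random.default_rng(0)
        df = self._df(rng.normal(size=(8, 2)), ["a", "b"])
        out = bonferroni_posthoc(df, "y", "subject", "g")
        assert len(out) == 1
        assert out["n_comparisons"].iloc[0] == 1
        assert out["p_bonferroni"].iloc[0] == pytest.approx(out["p_uncorrected"].iloc[0])

    def test_four_levels_six_comparisons(self):
        rng = np.random.default_rng(0)
        df = self._df(rng.normal(size=(8, 4)), list("abcd"))
        out = bonferroni_posthoc(df, "y", "subject", "g")
        assert len(out) == 6
        assert (out["n_comparisons"] == 6).all()
        assert (out["p_bonferroni"] <= 1).all()

    def test_deviant_level_found_and_matches_ttest_oracle(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(12, 4), scale=0.3)
        Y[:, 2] += 2.0  # one deviant level
        df = self._df(Y, list("abcd"))
        out = bonferroni_posthoc(df, "y", "subject", "g")
        sig = out[out["p_bonferroni"] < 0.05]
        assert set(map(tuple, sig[["level_a", "level_b"]].values)) == {
            ("a", "c"), ("b", "c"), ("c", "d"),
        }
        row = out[(out.level_a == "a") & (out.level_b == "c")].iloc[0]
        t, p = sps.ttest_rel(Y[:, 0], Y[:, 2])
        assert row["t"] == pytest.approx(t, abs=1e-12)
        assert row["p_bonferroni"] == pytest.approx(min(p * 6, 1.0), abs=1e-12)

    def test_unknown_column_rejected(self):
        df = self._df(np.zeros((3, 2)), ["a", "b"])
        with pytest.raises(ValueError, match="nope"):
            bonferroni_posthoc(df, "y", "subject", "nope")


class TestRelatedKeys:
    def test_c_major_row(self):
        rk = related_keys("C", "major")
        assert rk.relative == "Am"
        assert rk.fifth_related == {"F", "G", "Dm", "Em"}
        assert rk.parallel == "Cm"

    def test_f_major_row(self):
        rk = related_keys("F", "major")
        assert rk.relative == "Dm"
        assert rk.fifth_related == {"Bb", "C", "Gm", "Am"}
        assert rk.parallel == "Fm"

    def test_eb_major_row(self):
        rk = related_keys("Eb", "major")
        assert rk.relative == "Cm"
        assert rk.fifth_related == {"Ab", "Bb", "Fm", "Gm"}

    def test_minor_side(self):
        rk = related_keys("A", "minor")
        assert rk.relative == "C"
        assert rk.parallel == "A"
        assert rk.fifth_related == {"Dm", "Em", "F", "G"}

    def test_relation_is_symmetric_over_all_keys(self):
        from melstat.keys import MAJOR_ROOTS, MINOR_ROOTS

        table = {}
        for mode, roots in (("major", MAJOR_ROOTS), ("minor", MINOR_ROOTS)):
            for root in roots:
                rk = related_keys(root, mode)
                table[rk.key] = rk.all
        for key, rel in table.items():
            for other in rel:
                assert key in table[other], f"{other} does not list {key}"

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            related_keys("H", "major")
        with pytest.raises(ValueError):
            related_keys("C", "dorian")
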