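"""Clustering, adequacy tests, factor extraction/rotation, quality scores."""

import numpy as np
import pandas as pd
import pytest

from herbqc.chemometrics import (
    adequacy,
    bartlett,
    composite_score,
    extract_factors,
    factor_analysis,
    factor_scores,
    hca,
    kmo,
    rank_samples,
    score_coefficients,
    varimax,
)
from herbqc.fixtures import load_fixture
from herbqc.synthetic_data import default_design, sample_contents


def planted_three_factor_data(n=15, noise=0.2, seed=11):
    """Six features driven pairwise by three exactly-orthogonal latent
    factors (QR-orthonormalized so the plant is orthogonal even at small n)."""
    rng = np.random.default_rng(seed)
    f = rng.normal(size=(n, 3))
    q, _ = np.linalg.qr(f - f.mean(axis=0))
    f = q * np.sqrt(n)
    x = np.zeros((n, 6))
    for j in range(6):
        x[:, j] = f[:, j // 2] + noise * rng.normal(size=n)
    return pd.DataFrame(x, columns=[f"v{j}" for j in range(6)])


class TestHCA:
    def test_duplicated_row_merges_at_zero(self):
        data = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]], index=list("abc"))
        tree = hca(data, mode="squared-euclidean")
        assert tree.merges[0, 2] == 0.0

    def test_hand_traced_average_linkage(self):
        """Points 0, 1, 10 on a line: first merge {0,1} at d=1, then the
        pair joins {10} at mean(81, 100) = 90.5 squared-Euclidean."""
        tree = hca(pd.DataFrame({"x": [0.0, 1.0, 10.0]}), mode="squared-euclidean")
        assert tree.merges[0, 2] == pytest.approx(1.0)
        assert tree.merges[1, 2] == pytest.approx(90.5)

    def test_cut_recovers_planted_content_profiles(self):
        design = default_design(1)
        contents = sample_contents(design, 15, 3, groups=3)
        cut = hca(contents, mode="squared-euclidean").cut(3)
        planted = pd.Series(contents.attrs["groups"], index=contents.index)
        # exact recovery up to label permutation
        table = pd.crosstab(cut, planted)
        assert (table.gt(0).sum(axis=0) == 1).all()
        assert (table.gt(0).sum(axis=1) == 1).all()

    def test_heatmap_mode_rejects_constant_row(self):
        data = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 4.0], [2.0, 1.0, 5.0]])
        with pytest.raises(ValueError, match="constant rows"):
            hca(data, mode="similarity-heatmap")

    def test_heatmap_mode_merges_correlated_profiles_first(self):
        data = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0], "b": [2.0, 4.1, 6.0], "c": [3.0, -1.0, 0.5]},
            index=["p", "q", "r"],
        ).T
        tree = hca(data, mode="similarity-heatmap")
        assert sorted(tree.merges[0, :2]) == [0, 1]  # a and b are near-proportional

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            hca(pd.DataFrame(np.eye(3)), mode="ward")


class TestKMO:
    def test_two_variables_always_half(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(30, 2))
        assert kmo(data) == pytest.approx(0.5, abs=1e-12)

    def test_matches_partial_correlation_oracle(self):
        """Brute-force oracle: partial correlations via residual regression."""
        rng = np.random.default_rng(5)
        f = rng.normal(size=(60, 2))
        x = np.column_stack(
            [
                f[:, 0] + 0.3 * rng.normal(size=60),
                f[:, 0] + 0.3 * rng.normal(size=60),
                f[:, 1] + 0.3 * rng.normal(size=60),
                f[:, 1] + 0.3 * rng.normal(size=60),
            ]
        )
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        p = z.shape[1]
        r = np.corrcoef(z, rowvar=False)

        def partial(i, j):
            others = [k for k in range(p) if k not in (i, j)]
            a = np.column_stack([z[:, others], np.ones(len(z))])
            ri = z[:, i] - a @ np.linalg.lstsq(a, z[:, i], rcond=None)[0]
            rj = z[:, j] - a @ np.linalg.lstsq(a, z[:, j], rcond=None)[0]
            return np.corrcoef(ri, rj)[0, 1]

        r2 = sum(r[i, j] ** 2 for i in range(p) for j in range(p) if i != j)
        q2 = sum(partial(i, j) ** 2 for i in range(p) for j in range(p) if i != j)
        assert kmo(x) == pytest.approx(r2 / (r2 + q2), abs=1e-10)

    def test_near_singular_raises(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(20, 1))
        x = np.column_stack([base, base + 1e-13 * rng.normal(size=(20, 1)), rng.normal(size=(20, 1))])
        with pytest.raises(ValueError, match="singular"):
            kmo(x)


class TestBartlett:
    def test_orthogonal_columns_give_zero_chi2(self):
        # exactly uncorrelated columns: orthogonal polynomial contrasts
        t = np.arange(8.0)
        x = np.column_stack([t - t.mean(), (t - t.mean()) ** 2 - ((t - t.mean()) ** 2).mean()])
        x[:, 1] -= x[:, 0] * (x[:, 0] @ x[:, 1]) / (x[:, 0] @ x[:, 0])
        res = bartlett(x)
        assert res.bartlett_chi2 == pytest.approx(0.0, abs=1e-8)

    def test_degrees_of_freedom(self):
        rng = np.random.default_rng(2)
        res = bartlett(rng.normal(size=(15, 6)))
        assert res.bartlett_df == 15

    def test_matches_direct_determinant_formula(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(25, 4))
        x[:, 1] += 0.8 * x[:, 0]
        res = bartlett(x)
        r = np.corrcoef((x - x.mean(0)) / x.std(0, ddof=1), rowvar=False)
        expected = -(25 - 1 - (2 * 4 + 5) / 6) * np.log(np.linalg.det(r))
        assert res.bartlett_chi2 == pytest.approx(expected, rel=1e-10)

    def test_needs_more_rows_than_columns(self):
        with pytest.raises(ValueError, match="observations"):
            bartlett(np.random.default_rng(0).normal(size=(4, 6)))


class TestExtraction:
    def test_reference_eigenvalues_cumulative_and_retention(self):
        """The published eigenvalue set: three factors clear the 0.8 bar and
        explain 89.283% of the variance."""
        ev = load_fixture("table7_variance")["eigenvalue"].to_numpy()
        assert ev.sum() == pytest.approx(6.0, abs=0.001)  # printed to 3 dp
        cum3 = 100 * ev[:3].sum() / ev.sum()
        assert round(cum3, 3) == 89.283
        assert (ev > 0.8).sum() == 3

    def test_eigenvalue_conservation(self):
        rng = np.random.default_rng(4)
        vals, _ = extract_factors(rng.normal(size=(40, 6)), retain_threshold=0.0)
        assert vals.sum() == pytest.approx(6.0, abs=1e-8)

    def test_isotropic_data_has_flat_spectrum(self):
        rng = np.random.default_rng(6)
        vals, _ = extract_factors(rng.normal(size=(4000, 6)), retain_threshold=0.0)
        assert np.all((vals > 0.9) & (vals < 1.1))

    def test_no_factor_retained_raises(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError, match="threshold"):
            extract_factors(rng.normal(size=(40, 4)), retain_threshold=10.0)


class TestVarimax:
    def test_simple_structure_is_a_fixed_point(self):
        load = pd.DataFrame([[0.9, 0.0], [0.8, 0.0], [0.0, 0.9], [0.0, 0.7]])
        rotated, _ = varimax(load)
        assert np.allclose(rotated.to_numpy(), load.to_numpy(), atol=1e-6)

    def test_recovers_structure_after_random_orthogonal_mixing(self):
        rng = np.random.default_rng(8)
        load = np.array([[0.9, 0.0, 0.0], [0.85, 0.1, 0.0], [0.0, 0.8, 0.1],
                         [0.1, 0.75, 0.0], [0.0, 0.0, 0.9], [0.0, 0.1, 0.8]])
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated, _ = varimax(pd.DataFrame(load @ q))
        # compare up to column order/sign via absolute congruence
        got = rotated.to_numpy()
        for j in range(3):
            cong = np.abs(load[:, j] @ got) / (np.linalg.norm(load[:, j]) * np.linalg.norm(got, axis=0))
            assert cong.max() > 0.99

    def test_communalities_preserved(self):
        data = planted_three_factor_data()
        _, load = extract_factors(data)
        rotated, _ = varimax(load)
        before = (load**2).sum(axis=1)
        after = (rotated**2).sum(axis=1)
        assert float((before - after).abs().max()) < 1e-8

    def test_matches_r_stats_varimax(self):
        """Frozen oracle from R stats::varimax (Kaiser-normalized, eps 1e-10)
        on a fixed 6 x 3 loading matrix; equality up to column order/sign."""
        x = np.array(
            [[0.83, 0.28, -0.11], [0.78, 0.33, 0.05], [0.15, 0.90, 0.21],
             [0.05, 0.84, -0.26], [-0.22, 0.12, 0.88], [0.31, -0.08, 0.79]]
        )
        expected = np.array(
            [[0.8629082495, 0.1726472192, -0.0705853428],
             [0.8133100272, 0.2245372444, 0.0889371999],
             [0.2559455121, 0.8671436892, 0.2432153720],
             [0.1682051025, 0.8328756196, -0.2317870700],
             [-0.2382430615, 0.1246196704, 0.8745914368],
             [0.2648183167, -0.1400824989, 0.7980276641]]
        )
        rotated, _ = varimax(pd.DataFrame(x))
        got = rotated.to_numpy()
        for j in range(3):
            dots = expected[:, j] @ got
            k = int(np.argmax(np.abs(dots)))
            sign = np.sign(dots[k])
            assert np.allclose(expected[:, j], sign * got[:, k], atol=1e-4)

    def test_single_factor_is_noop(self):
        load = pd.DataFrame({"F1": [0.9, 0.8, 0.7]})
        rotated, iters = varimax(load)
        pd.testing.assert_frame_equal(rotated, load)
        assert iters == 0


class TestScoresAndComposite:
    def test_one_hot_coefficients_return_standardized_feature(self):
        data = planted_three_factor_data()
        coef = pd.DataFrame(0.0, index=data.columns, columns=["F1"])
        coef.loc["v0", "F1"] = 1.0
        scores = factor_scores(data, coef)
        z = (data["v0"] - data["v0"].mean()) / data["v0"].std(ddof=1)
        assert np.allclose(scores["F1"], z)

    def test_row_at_the_mean_scores_zero(self):
        # rows v, -v, 0: the zero row sits exactly at every column mean
        v = np.array([1.0, -2.0, 0.5, 3.0, -1.0, 2.0])
        data = pd.DataFrame([v, -v, 0 * v], index=list("abc"))
        coef = pd.DataFrame(
            np.arange(12.0).reshape(6, 2), index=data.columns, columns=["F1", "F2"]
        )
        scores = factor_scores(data, coef)
        assert np.allclose(scores.loc["c"], 0.0)

    def test_model_scores_have_unit_variance(self):
        fm = factor_analysis(planted_three_factor_data())
        assert np.allclose(fm.scores.var(ddof=1), 1.0, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        data = planted_three_factor_data()
        coef = pd.DataFrame(0.0, index=[f"w{j}" for j in range(6)], columns=["F1"])
        with pytest.raises(ValueError, match="conform"):
            factor_scores(data, coef)

    def test_composite_zero_scores(self):
        assert composite_score(pd.DataFrame({"F1": [0.0], "F2": [0.0], "F3": [0.0]}),
                               [38.006, 27.720, 23.556]).iloc[0] == 0.0

    def test_composite_reference_weights(self):
        f = composite_score(pd.DataFrame({"F1": [1.0], "F2": [0.0], "F3": [0.0]}),
                            [38.006, 27.720, 23.556])
        assert f.iloc[0] == pytest.approx(38.006 / 89.282, abs=5e-5)

    def test_equal_weights_give_arithmetic_mean(self):
        f = composite_score(pd.DataFrame({"F1": [1.0], "F2": [2.0], "F3": [6.0]}), [1, 1, 1])
        assert f.iloc[0] == pytest.approx(3.0)

    def test_ranking_reference_scores(self):
        t1 = load_fixture("table1_batches").set_index("batch")
        ranks = rank_samples(t1["score"])
        assert ranks["S14"] == 1
        pd.testing.assert_series_equal(
            ranks, t1["ranking"].rename("ranking"), check_dtype=False
        )

    def test_ranking_tie_rules(self):
        assert rank_samples(pd.Series([5.0, 5.0, 1.0])).tolist() == [1, 1, 3]
        assert rank_samples(pd.Series([2.0, 2.0, 2.0])).tolist() == [1, 1, 1]

    def test_ranking_invariant_to_weight_rescaling(self):
        fm = factor_analysis(planted_three_factor_data())
        f2 = composite_score(fm.scores, 7.5 * fm.contributions)
        pd.testing.assert_series_equal(rank_samples(f2), fm.ranking, check_names=False)


class TestFullPipeline:
    def test_planted_factor_recovery(self):
        """15 batches with 3 planted orthogonal factors: extraction retains
        3 and the rotated loadings align with the plant (congruence > 0.95)."""
        data = planted_three_factor_data()
        fm = factor_analysis(data, retain_threshold=0.8)
        assert fm.rotated_loadings.shape[1] == 3
        got = fm.rotated_loadings.to_numpy()
        for k in range(3):
            ind = np.zeros(6)
            ind[2 * k] = ind[2 * k + 1] = 1.0
            cong = np.abs(ind @ got) / (np.linalg.norm(ind) * np.linalg.norm(got, axis=0))
            assert cong.max() > 0.95

    def test_adequacy_on_study_contents(self):
        design = default_design(1)
        contents = sample_contents(design, 15, 1)
        stats = adequacy(contents)
        assert 0.0 <= stats.kmo <= 1.0
        assert stats.bartlett_df == 15
        assert 0.0 <= stats.bartlett_p <= 1.0
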