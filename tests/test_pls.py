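"""Cross-block decomposition, permutation and bootstrap inference."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mindpls import pls
from tests.conftest import make_standardized_blocks


def exact_corr_blocks(diag, n=400, seed=0):
    """Blocks whose cross-correlation matrix is exactly diag(diag).

    Built from an orthonormal basis so X'Y/(n-1) has no sampling noise.
    """
    rng = np.random.default_rng(seed)
    k = len(diag)
    basis, _ = np.linalg.qr(rng.standard_normal((n, 2 * k + 1)))
    # drop any component along the constant vector, then re-orthonormalize
    ones = np.ones((n, 1)) / np.sqrt(n)
    basis = basis - ones @ (ones.T @ basis)
    basis, _ = np.linalg.qr(basis)
    scale = np.sqrt(n - 1)
    x = basis[:, :k] * scale
    y = np.empty_like(x)
    for j, r in enumerate(diag):
        w = basis[:, k + j]
        y[:, j] = (r * basis[:, j] + np.sqrt(1 - r**2) * w) * scale
    return x, y


class TestDecompose:
    def test_self_correlation_single_column(self, rng):
        x = pls.standardize_columns(rng.standard_normal((50, 1)))
        d = pls.crossblock_decompose(x, x)
        assert d.singular_values[0] == pytest.approx(1.0, abs=1e-10)
        assert d.pct_crossblock[0] == pytest.approx(100.0)

    def test_planted_diagonal_correlations(self):
        x, y = exact_corr_blocks([0.6, 0.3])
        d = pls.crossblock_decompose(x, y)
        assert np.allclose(d.singular_values, [0.6, 0.3], atol=1e-10)
        assert np.allclose(d.pct_crossblock, [80.0, 20.0], atol=1e-8)

    def test_independent_blocks_have_small_top_singular_value(self):
        rng = np.random.default_rng(5)
        x, y = make_standardized_blocks(rng, n=10000, p=2, q=2)
        d = pls.crossblock_decompose(x, y)
        assert d.singular_values[0] < 0.2

    def test_nonstandardized_block_rejected(self, rng):
        x, y = make_standardized_blocks(rng)
        with pytest.raises(pls.StandardizationError):
            pls.crossblock_decompose(x * 2.0, y)
        with pytest.raises(pls.StandardizationError):
            pls.crossblock_decompose(x + 0.5, y)

    def test_salience_columns_orthonormal(self, rng):
        x, y = make_standardized_blocks(rng, n=80, p=4, q=6)
        d = pls.crossblock_decompose(x, y)
        assert np.allclose(d.behavior_saliences.T @ d.behavior_saliences, np.eye(4), atol=1e-8)
        assert np.allclose(d.outcome_saliences.T @ d.outcome_saliences, np.eye(4), atol=1e-8)
        assert d.pct_crossblock.sum() == pytest.approx(100.0, abs=1e-6)

    def test_sign_convention_largest_behavior_weight_positive(self, rng):
        x, y = make_standardized_blocks(rng, n=80, p=4, q=6)
        d = pls.crossblock_decompose(x, y)
        for i in range(d.n_lv):
            j = np.argmax(np.abs(d.behavior_saliences[:, i]))
            assert d.behavior_saliences[j, i] > 0

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_energy_conservation(self, seed):
        rng = np.random.default_rng(seed)
        x, y = make_standardized_blocks(rng, n=40, p=3, q=5)
        d = pls.crossblock_decompose(x, y)
        r = x.T @ y / (len(x) - 1)
        assert np.sum(d.singular_values**2) == pytest.approx(
            np.linalg.norm(r, "fro") ** 2, abs=1e-10
        )


class TestPermutation:
    def test_perfect_association_minimum_pvalue(self, rng):
        x = pls.standardize_columns(rng.standard_normal((30, 2)))
        res = pls.permutation_test(x, x, n_perm=99, seed=1)
        assert res.pvalues[0] == pytest.approx(1 / 100)

    def test_same_seed_reproducible(self, rng):
        x, y = make_standardized_blocks(rng)
        a = pls.permutation_test(x, y, n_perm=50, seed=9)
        b = pls.permutation_test(x, y, n_perm=50, seed=9)
        assert np.array_equal(a.pvalues, b.pvalues)
        assert np.array_equal(a.null_singular_values, b.null_singular_values)

    def test_invariant_to_outcome_column_order(self, rng):
        x, y = make_standardized_blocks(rng, n=50, p=3, q=4)
        a = pls.permutation_test(x, y, n_perm=80, seed=3)
        b = pls.permutation_test(x, y[:, ::-1], n_perm=80, seed=3)
        assert np.allclose(a.pvalues, b.pvalues)

    def test_pvalues_use_add_one_rule(self, rng):
        x, y = make_standardized_blocks(rng, n=40)
        res = pls.permutation_test(x, y, n_perm=49, seed=2)
        exceed = (res.null_singular_values >= pls.crossblock_decompose(x, y).singular_values).sum(axis=0)
        assert np.allclose(res.pvalues, (1 + exceed) / 50)
        assert ((res.pvalues > 0) & (res.pvalues <= 1)).all()


class TestBootstrap:
    def test_identity_resampling_gives_zero_se(self, rng):
        x, y = make_standardized_blocks(rng, n=40)
        res = pls.bootstrap_stability(
            x, y, n_boot=10, seed=0, index_sampler=lambda r, n: np.arange(n)
        )
        assert np.allclose(res.behavior_se, 0, atol=1e-12)
        assert np.allclose(res.outcome_se, 0, atol=1e-12)

    def test_procrustes_restores_sign_flip(self, rng):
        x, y = make_standardized_blocks(rng, n=60, p=3, q=4)
        d = pls.crossblock_decompose(x, y)
        q_rot = pls._procrustes_rotation(-d.behavior_saliences, d.behavior_saliences)
        assert np.allclose(-d.behavior_saliences @ q_rot, d.behavior_saliences, atol=1e-10)

    def test_planted_support_columns_get_large_bootstrap_ratios(self):
        # rank-one planted structure: supported outcome columns should be
        # stable (|BR| > 1.96) in nearly all replicate datasets
        a = np.array([0.5, 0.5, 0.5, 0.5, 0.0])
        b = np.array([0.6, 0.6, 0.4, 0.0, 0.0, 0.35])
        b = b / np.linalg.norm(b)
        hits, total = 0, 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            f = rng.standard_normal(250)
            cx = np.sqrt(0.4 * 5) * a
            cy = np.sqrt(0.4 * 6) * b
            x = f[:, None] * cx + rng.standard_normal((250, 5)) * np.sqrt(1 - cx**2)
            y = f[:, None] * cy + rng.standard_normal((250, 6)) * np.sqrt(1 - cy**2)
            res = pls.bootstrap_stability(
                pls.standardize_columns(x), pls.standardize_columns(y),
                n_boot=200, seed=rep,
            )
            support = np.abs(b) > 0.3
            hits += res.outcome_significant[support, 0].sum()
            total += support.sum()
        assert hits / total >= 0.9

    def test_bootstrap_se_shrinks_with_n(self):
        ses = {}
        for n in (100, 800):
            rng = np.random.default_rng(n)
            f = rng.standard_normal(n)
            c = np.sqrt(0.3)
            x = f[:, None] * c + rng.standard_normal((n, 4)) * np.sqrt(1 - c**2)
            y = f[:, None] * c + rng.standard_normal((n, 5)) * np.sqrt(1 - c**2)
            res = pls.bootstrap_stability(
                pls.standardize_columns(x), pls.standardize_columns(y),
                n_boot=300, seed=1,
            )
            ses[n] = np.median(res.behavior_se[:, 0])
        assert ses[800] < ses[100]

    def test_degenerate_resample_redrawn(self, rng):
        x, y = make_standardized_blocks(rng, n=20)
        calls = {"k": 0}

        def sampler(r, n):
            calls["k"] += 1
            if calls["k"] == 1:
                return np.zeros(n, dtype=int)  # zero-variance resample
            return r.integers(0, n, n)

        res = pls.bootstrap_stability(x, y, n_boot=5, seed=0, index_sampler=sampler)
        assert res.n_redrawn == 1


class TestLatentScores:
    def test_single_behavior_column_scores_equal_block(self, rng):
        x = pls.standardize_columns(rng.standard_normal((40, 1)))
        y = pls.standardize_columns(rng.standard_normal((40, 3)))
        d = pls.crossblock_decompose(x, y)
        s = pls.latent_scores(x, y, d)
        assert np.allclose(np.abs(s.behavior_scores[:, 0]), np.abs(x[:, 0]))

    def test_reported_correlation_matches_direct_pearson(self, rng):
        x, y = make_standardized_blocks(rng, n=70, p=4, q=5)
        d = pls.crossblock_decompose(x, y)
        s = pls.latent_scores(x, y, d)
        for i in range(d.n_lv):
            direct = np.corrcoef(x @ d.behavior_saliences[:, i], y @ d.outcome_saliences[:, i])[0, 1]
            assert s.correlations[i] == pytest.approx(direct, abs=1e-12)

    def test_first_lv_correlation_nonnegative(self, rng):
        for seed in range(5):
            r2 = np.random.default_rng(seed)
            x, y = make_standardized_blocks(r2, n=50)
            d = pls.crossblock_decompose(x, y)
            s = pls.latent_scores(x, y, d)
            assert s.correlations[0] >= 0

    def test_lv_permutation_permutes_score_columns(self, rng):
        x, y = make_standardized_blocks(rng, n=50, p=3, q=3)
        d = pls.crossblock_decompose(x, y)
        perm = [2, 0, 1]
        d2 = pls.CrossBlockDecomposition(
            singular_values=d.singular_values[perm],
            behavior_saliences=d.behavior_saliences[:, perm],
            outcome_saliences=d.outcome_saliences[:, perm],
            pct_crossblock=d.pct_crossblock[perm],
        )
        s1 = pls.latent_scores(x, y, d)
        s2 = pls.latent_scores(x, y, d2)
        assert np.allclose(s2.behavior_scores, s1.behavior_scores[:, perm])
        assert np.allclose(s2.outcome_scores, s1.outcome_scores[:, perm])


class TestModelAPI:
    def test_fit_summary_and_tables(self, rng):
        x, y = exact_corr_blocks([0.5, 0.2], n=120, seed=3)
        xdf = pd.DataFrame(x, columns=["a", "b"], index=[f"s{i}" for i in range(120)])
        ydf = pd.DataFrame(y, columns=["u", "v"], index=xdf.index)
        res = pls.BehavioralPLS.from_dataframes(xdf, ydf).fit(n_perm=99, n_boot=50, seed=4)
        assert res.pvalues[0] < 0.05
        text = res.summary()
        assert "Behavioral PLS" in text and "singular_value" in text
        assert list(res.behavior_table(0).index) == ["a", "b"]
        assert list(res.outcome_table(0).index) == ["u", "v"]

    def test_fit_is_seed_deterministic(self, rng):
        x, y = make_standardized_blocks(rng, n=50)
        m = pls.BehavioralPLS(x, y)
        r1 = m.fit(n_perm=50, n_boot=20, seed=11)
        r2 = m.fit(n_perm=50, n_boot=20, seed=11)
        assert np.array_equal(r1.pvalues, r2.pvalues)
        assert np.array_equal(r1.bootstrap.behavior_se, r2.bootstrap.behavior_se)

    def test_from_dataframes_aligns_by_subject(self, rng):
        x, y = make_standardized_blocks(rng, n=30)
        idx = [f"s{i}" for i in range(30)]
        xdf = pd.DataFrame(x, index=idx)
        ydf = pd.DataFrame(y, index=idx[::-1])  # shuffled row order
        m = pls.BehavioralPLS.from_dataframes(xdf, ydf)
        assert len(m.x) == 30
        d_direct = pls.crossblock_decompose(
            pls.standardize_columns(xdf.sort_index()),
            pls.standardize_columns(ydf.sort_index()),
        )
        assert np.allclose(m.fit(n_perm=1, n_boot=2, seed=0).singular_values,
                           d_direct.singular_values)
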