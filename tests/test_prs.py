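"""PRS-PCA aggregation and dichotomisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gxescreen.prs import PrsPca, dichotomize_prs, prs_pca, read_prsice_all_score


def random_scores(seed: int, n: int = 200, k: int = 10) -> np.ndarray:
    rng = np.random.default_rng(seed)
    shared = rng.standard_normal((n, 1))
    x = 0.7 * shared + 0.5 * rng.standard_normal((n, k))
    return x * 10.0 ** rng.uniform(-3, 0, size=k) + rng.normal(0, 1, size=k)


class TestPrsPca:
    def test_identical_columns_rank_one(self):
        rng = np.random.default_rng(1)
        col = rng.standard_normal(100)
        X = np.tile(col[:, None], (1, 10))
        res = prs_pca(X)
        assert res.pc1_variance_fraction == pytest.approx(1.0, abs=1e-12)
        z = (col - col.mean()) / col.std(ddof=1)
        assert np.allclose(res.score, z, atol=1e-8)

    def test_matches_brute_force_eigendecomposition(self):
        X = random_scores(seed=2)
        est = PrsPca().fit(X)
        # independent oracle: correlation matrix + full eigendecomposition
        R = np.corrcoef(X, rowvar=False)
        eigvals, eigvecs = np.linalg.eig(R)
        order = np.argsort(eigvals.real)[::-1]
        eigvals = eigvals.real[order]
        lead = eigvecs.real[:, order[0]]
        assert est.pc1_variance_fraction_ == pytest.approx(
            eigvals[0] / eigvals.sum(), abs=1e-10
        )
        assert np.allclose(np.abs(est.loadings_), np.abs(lead), atol=1e-8)

    def test_sign_alignment_is_deterministic_and_equivariant(self):
        """The alignment convention pins the otherwise-arbitrary PC1 sign.

        Negating every input column reverses what "high" means, so the
        aggregated score flips sign exactly (equivariance); refitting the
        same data always reproduces the same orientation.
        """
        X = random_scores(seed=3)
        a = PrsPca().fit(X).transform(X)
        b = PrsPca().fit(-X).transform(-X)
        assert np.allclose(a, -b, atol=1e-8)
        again = PrsPca().fit(X).transform(X)
        assert np.allclose(a, again, atol=1e-12)
        # the aligned component tracks the mean standardised score positively
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        assert np.corrcoef(a, Z.mean(axis=1))[0, 1] > 0

    @given(scale=st.floats(0.1, 50), shift=st.floats(-100, 100))
    def test_affine_invariance(self, scale, shift):
        X = random_scores(seed=4)
        a = PrsPca().fit(X).transform(X)
        b = PrsPca().fit(scale * X + shift).transform(scale * X + shift)
        assert np.allclose(a, b, atol=1e-8)

    def test_score_standardised(self):
        score = PrsPca().fit_result(random_scores(seed=5)).score
        assert abs(score.mean()) < 1e-8
        assert abs(score.std(ddof=1) - 1.0) < 1e-8

    def test_zero_variance_column_named(self):
        X = random_scores(seed=6)
        X[:, 3] = 2.5
        frame = pd.DataFrame(X, columns=[f"t{i}" for i in range(1, 11)])
        with pytest.raises(ValueError, match="t4"):
            PrsPca().fit(frame)

    def test_missing_values_rejected(self):
        X = random_scores(seed=7)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            PrsPca().fit(X)

    def test_more_columns_than_rows_rejected(self):
        with pytest.raises(ValueError, match="more rows"):
            PrsPca().fit(np.random.default_rng(0).standard_normal((5, 10)))

    def test_sklearn_get_set_params(self):
        est = PrsPca(high_quantile=0.9)
        assert est.get_params() == {"high_quantile": 0.9}
        est.set_params(high_quantile=0.75)
        assert est.high_quantile == 0.75


class TestDichotomize:
    def test_distinct_values_exact_quarter(self):
        high = dichotomize_prs(np.arange(1, 101))
        assert high.sum() == 25

    def test_constant_vector_has_no_high_group(self):
        assert dichotomize_prs(np.ones(50)).sum() == 0

    def test_gaussian_sample_quarter_high(self):
        score = np.random.default_rng(11).standard_normal(10_000)
        frac = dichotomize_prs(score).mean()
        assert abs(frac - 0.25) < 0.02

    def test_high_fraction_matches_strict_threshold(self):
        score = np.random.default_rng(12).standard_normal(999)
        high = dichotomize_prs(score)
        threshold = np.quantile(score, 0.75)
        assert high.sum() == (score > threshold).sum()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_prs(np.array([]))


def test_read_prsice_all_score(tmp_path):
    rng = np.random.default_rng(13)
    table = pd.DataFrame(
        {
            "FID": [f"f{i}" for i in range(20)],
            "IID": [f"i{i}" for i in range(20)],
            **{f"Pt_{t}": rng.standard_normal(20) for t in ("5e-08", "0.001", "1")},
        }
    )
    path = tmp_path / "all.score"
    table.to_csv(path, sep=" ", index=False)
    ids, scores, labels = read_prsice_all_score(str(path))
    assert labels == ["5e-08", "0.001", "1"]
    assert list(ids) == [f"i{i}" for i in range(20)]
    assert scores.shape == (20, 3)
    assert np.allclose(scores["Pt_1"], table["Pt_1"])
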