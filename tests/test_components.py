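import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA as SkPCA

from chdi import (FitError, ScoringConfig, catpca_fit, pca_fit, read_model,
                  score_new_units, subset_search, write_model)
from chdi.diagnostics import kmo


def sklearn_pca_oracle(x):
    """Independent eigendecomposition route: SVD-based PCA on standardised
    data (scikit-learn), returning eigenvalues, eigenvectors and scores."""
    x = np.asarray(x, dtype=float)
    z = (x - x.mean(0)) / x.std(0, ddof=1)
    sk = SkPCA(n_components=min(z.shape), svd_solver="full").fit(z)
    return sk.explained_variance_, sk.components_.T, sk.transform(z)


def assert_equal_up_to_sign(a, b, atol):
    for j in range(a.shape[1]):
        direct = np.abs(a[:, j] - b[:, j]).max()
        flipped = np.abs(a[:, j] + b[:, j]).max()
        assert min(direct, flipped) < atol


class TestPCA:
    def test_matches_independent_oracle(self):
        """Loadings, variance shares and scores agree with an SVD-based PCA
        up to component sign on 200 random 20x5 matrices."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            x = rng.standard_normal((20, 5))
            x[:, :3] += rng.standard_normal((20, 1))
            model = pca_fit(x, n_components=5)
            ev, vecs, scores = sklearn_pca_oracle(x)
            np.testing.assert_allclose(model.eigenvalues, ev, atol=1e-8)
            np.testing.assert_allclose(model.variance_shares * 5,
                                       ev, atol=1e-8)
            assert_equal_up_to_sign(model.components, vecs, atol=1e-8)
            assert_equal_up_to_sign(model.scores, scores, atol=1e-8)

    def test_variance_shares_sum_to_one(self, rng):
        x = rng.standard_normal((30, 6))
        model = pca_fit(x, n_components=6)
        assert model.eigenvalues.sum() / 6 == pytest.approx(1.0, abs=1e-10)
        assert model.cumulative_variance == pytest.approx(1.0, abs=1e-10)

    def test_collinear_rank_one_limit(self, rng):
        base = rng.standard_normal(40)
        x = np.column_stack([base + 1e-9 * rng.standard_normal(40)
                             for _ in range(3)])
        model = pca_fit(x, retention_rule="cumulative_variance",
                        min_cumulative_variance=0.8)
        assert model.n_components == 1
        assert model.variance_shares[0] == pytest.approx(1.0, abs=1e-6)

    def test_scores_centred_and_shares_nonincreasing(self, rng):
        x = rng.standard_normal((50, 5))
        model = pca_fit(x, n_components=3)
        np.testing.assert_allclose(model.scores.mean(axis=0), 0, atol=1e-12)
        assert np.all(np.diff(model.variance_shares) <= 1e-12)

    def test_deterministic_sign_convention(self, rng):
        x = rng.standard_normal((50, 5))
        model = pca_fit(x, n_components=3)
        for j in range(3):
            idx = np.argmax(np.abs(model.loadings[:, j]))
            assert model.loadings[idx, j] > 0

    def test_errors(self, rng):
        with pytest.raises(FitError, match="constant"):
            pca_fit(np.column_stack([np.ones(10),
                                     rng.standard_normal(10)]))
        with pytest.raises(FitError, match="units"):
            pca_fit(rng.standard_normal((2, 4)))
        with pytest.raises(FitError, match="retention"):
            pca_fit(rng.standard_normal((10, 3)), n_components=5)


def _ordinal_frame(rng, n=150, levels=5):
    """Two-factor ordinal data: quantile-discretised noisy loadings."""
    f = rng.standard_normal((n, 2))
    cols = {}
    scales = {}
    for j in range(5):
        load = (0.9, 0.1) if j < 3 else (0.3, 0.85)
        latent = load[0] * f[:, 0] + load[1] * f[:, 1] \
            + 0.3 * rng.standard_normal(n)
        edges = np.quantile(latent, np.linspace(0, 1, levels + 1)[1:-1])
        cols[f"v{j}"] = np.searchsorted(edges, latent).astype(float)
        scales[f"v{j}"] = "ordinal"
    return pd.DataFrame(cols), scales


class TestCATPCA:
    def test_linear_limit_equals_pca(self, rng):
        """Ordinal columns that are exact affine transforms of equally
        spaced codes span a rank-2 space, where optimal scaling cannot
        improve on the numeric coding."""
        c1 = rng.integers(0, 5, size=120).astype(float)
        c2 = rng.integers(0, 4, size=120).astype(float)
        frame = pd.DataFrame({
            "a": c1, "b": 2 * c1, "c": 3 * c1,
            "d": c2, "e": 5 * c2,
        })
        scales = {k: "ordinal" for k in frame}
        cat = catpca_fit(frame, scales, n_components=2, seed=0)
        num = pca_fit(frame.to_numpy(), n_components=2)
        assert cat.cumulative_variance == pytest.approx(
            num.cumulative_variance, abs=1e-6)

    def test_vaf_nondecreasing_and_monotone_quantifications(self, rng):
        frame, scales = _ordinal_frame(rng)
        model = catpca_fit(frame, scales, n_components=2, seed=3)
        vaf = np.asarray(model.vaf_history)
        assert np.all(np.diff(vaf) >= -1e-10)
        for qmap in model.quantifications.values():
            codes = sorted(qmap)
            vals = [qmap[c] for c in codes]
            assert np.all(np.diff(vals) >= -1e-12)

    def test_vaf_at_least_pca_on_integer_coding(self, rng):
        frame, scales = _ordinal_frame(rng)
        cat = catpca_fit(frame, scales, n_components=2, seed=0)
        num = pca_fit(frame.to_numpy(), n_components=2)
        assert cat.cumulative_variance >= num.cumulative_variance - 1e-9

    def test_nominal_quantification_unconstrained(self, rng):
        frame, scales = _ordinal_frame(rng)
        scales["v4"] = "nominal"
        model = catpca_fit(frame, scales, n_components=2, seed=11)
        assert model.converged
        assert "v4" in model.quantifications

    def test_requires_categorical_column(self, rng):
        frame = pd.DataFrame(rng.standard_normal((30, 3)),
                             columns=["a", "b", "c"])
        with pytest.raises(FitError, match="ordinal/nominal"):
            catpca_fit(frame, {"a": "numeric", "b": "numeric",
                               "c": "numeric"})

    def test_single_level_column_rejected(self, rng):
        frame, scales = _ordinal_frame(rng)
        frame["v0"] = 1.0
        with pytest.raises(FitError, match="levels|constant"):
            catpca_fit(frame, scales)


class TestParameterRecovery:
    def test_two_factor_loading_recovery(self):
        """PCA on a 2-factor design (loadings 0.8/0.6, noise sd 0.5, n=300)
        recovers loading vectors correlated > 0.9 with the truth."""
        rng = np.random.default_rng(2024)
        n = 300
        f = rng.standard_normal((n, 2))
        true = np.zeros((6, 2))
        true[:3, 0] = 0.8
        true[3:, 1] = 0.6
        x = f @ true.T + 0.5 * rng.standard_normal((n, 6))
        model = pca_fit(x, n_components=2)
        for t in range(2):
            best = max(
                abs(np.corrcoef(true[:, t], model.loadings[:, j])[0, 1])
                for j in range(2)
            )
            assert best > 0.9


class TestScoreNewUnits:
    def test_training_matrix_self_consistency(self, rng):
        x = rng.standard_normal((40, 5))
        model = pca_fit(x, n_components=2)
        np.testing.assert_allclose(score_new_units(model, x), model.scores,
                                   atol=1e-12)

    def test_column_means_give_zero_scores(self, rng):
        x = rng.standard_normal((40, 5))
        model = pca_fit(x, n_components=2)
        scores = score_new_units(model, x.mean(axis=0))
        np.testing.assert_allclose(scores, 0, atol=1e-12)

    def test_increasing_positive_loading_increases_score(self, rng):
        x = rng.standard_normal((60, 4)) + rng.standard_normal((60, 1))
        model = pca_fit(x, n_components=1)
        j = int(np.argmax(model.loadings[:, 0]))
        assert model.loadings[j, 0] > 0
        unit = x[0].copy()
        bumped = unit.copy()
        bumped[j] += 1.0
        assert (score_new_units(model, bumped)[0, 0]
                > score_new_units(model, unit)[0, 0])

    def test_column_mismatch_error(self, rng):
        x = rng.standard_normal((40, 5))
        model = pca_fit(x, n_components=2)
        with pytest.raises(FitError, match="columns"):
            score_new_units(model, x[:, :4])

    def test_catpca_projection_consistency(self, rng):
        frame, scales = _ordinal_frame(rng)
        model = catpca_fit(frame, scales, n_components=2, seed=0)
        np.testing.assert_allclose(score_new_units(model, frame),
                                   model.scores, atol=1e-10)


class TestModelSerialization:
    def test_round_trip(self, tmp_path, rng):
        frame, scales = _ordinal_frame(rng)
        model = catpca_fit(frame, scales, n_components=2, seed=5)
        path = tmp_path / "model.txt"
        write_model(model, path)
        back = read_model(path)
        np.testing.assert_allclose(back.loadings, model.loadings)
        np.testing.assert_allclose(back.scores, model.scores)
        assert back.quantifications == model.quantifications
        np.testing.assert_allclose(
            score_new_units(back, frame), model.scores, atol=1e-12)


def subset_search_oracle(frame, config):
    """Independent exhaustive enumeration using the SVD-based PCA route."""
    names = list(frame.columns)
    best = None
    for r in range(2, len(names) + 1):
        for subset in itertools.combinations(names, r):
            arr = frame[list(subset)].to_numpy(dtype=float)
            try:
                diag = kmo(arr)
            except Exception:
                continue
            ev, _, _ = sklearn_pca_oracle(arr)
            cumvar = ev[:config.n_components].sum() / len(subset)
            if diag > config.kmo_threshold and \
                    cumvar >= config.min_cumulative_variance:
                key = (r, cumvar)
                if best is None or key > best[0]:
                    best = (key, subset)
    return best[1] if best else None


class TestSubsetSearch:
    def test_noise_indicator_excluded(self):
        """5 structural indicators on 2 factors plus one pure-noise column:
        the noise column is dropped, in agreement with an independent
        exhaustive enumeration."""
        rng = np.random.default_rng(7)
        n = 200
        f = rng.standard_normal((n, 2))
        cols = {}
        for j in range(5):
            load = (0.95, 0.1) if j < 3 else (0.4, 0.85)
            cols[f"s{j}"] = (load[0] * f[:, 0] + load[1] * f[:, 1]
                             + 0.25 * rng.standard_normal(n))
        cols["noise"] = rng.standard_normal(n)
        frame = pd.DataFrame(cols)
        config = ScoringConfig(min_cumulative_variance=0.85)
        result = subset_search(frame, {c: "numeric" for c in frame},
                               "pca", config)
        assert result.acceptable
        assert "noise" not in result.chosen
        assert set(result.chosen) == {"s0", "s1", "s2", "s3", "s4"}
        assert tuple(sorted(result.chosen)) == tuple(
            sorted(subset_search_oracle(frame, config)))

    def test_all_acceptable_prefers_largest(self):
        rng = np.random.default_rng(8)
        n = 150
        f = rng.standard_normal(n)
        frame = pd.DataFrame({
            f"c{j}": f + 0.45 * rng.standard_normal(n) for j in range(3)
        })
        config = ScoringConfig(min_cumulative_variance=0.8)
        result = subset_search(frame, {c: "numeric" for c in frame},
                               "pca", config)
        assert result.acceptable
        assert len(result.chosen) == 3

    def test_nothing_acceptable_returns_flagged_full_set(self, rng):
        frame = pd.DataFrame(rng.standard_normal((100, 4)),
                             columns=list("abcd"))
        result = subset_search(frame, {c: "numeric" for c in frame},
                               "pca", ScoringConfig())
        assert not result.acceptable
        assert result.chosen == ("a", "b", "c", "d")

    def test_enumeration_bound(self, rng):
        frame = pd.DataFrame(rng.standard_normal((30, 17)))
        frame.columns = [f"c{j}" for j in range(17)]
        with pytest.raises(FitError, match="16"):
            subset_search(frame, {c: "numeric" for c in frame}, "pca",
                          ScoringConfig())
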