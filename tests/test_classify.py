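import numpy as np
import pytest

from scibet import (
    ExpressionMatrix,
    GroupMeans,
    MatrixState,
    ValidationError,
    align_genes,
    apply_unassignment,
    build_null_model,
    confidence_score,
    predict,
    score_loglik,
    train_from_means,
)
from scibet.classify import PredictionResult


def _model_from_probs(probs, types=None, genes=None):
    probs = np.asarray(probs, float)
    types = types or [f"t{j}" for j in range(probs.shape[0])]
    genes = genes or [f"g{i}" for i in range(probs.shape[1])]
    from scibet import SciBetModel

    return SciBetModel(types, genes, np.log(probs))


def _query(values, genes=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = [f"c{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(genes, cells, values, MatrixState.NORMALIZED_LOG)


def _random_instance(rng, n_genes=12, n_types=4):
    probs = rng.dirichlet(np.ones(n_genes), size=n_types)
    model = _model_from_probs(probs)
    y = rng.gamma(1.0, 2.0, size=(n_genes, 1))
    return model, _query(y)


class TestScoreLoglik:
    def test_hand_values_two_types(self):
        model = _model_from_probs([[0.9, 0.1], [0.1, 0.9]], types=["A", "B"])
        L = score_loglik(model, _query([[10.0], [0.0]]))
        assert L[0, 0] == pytest.approx(10 * np.log(0.9), rel=1e-12)
        assert L[0, 1] == pytest.approx(10 * np.log(0.1), rel=1e-12)

    def test_all_zero_cell_scores_zero_everywhere(self):
        model = _model_from_probs([[0.5, 0.5], [0.2, 0.8]])
        L = score_loglik(model, _query([[0.0], [0.0]]))
        np.testing.assert_array_equal(L, 0.0)

    def test_doubling_expression_doubles_loglik(self):
        rng = np.random.default_rng(0)
        model, query = _random_instance(rng)
        doubled = _query(query.values * 2)
        np.testing.assert_allclose(
            score_loglik(model, doubled), 2 * score_loglik(model, query), rtol=1e-12
        )

    def test_misaligned_query_rejected(self):
        model = _model_from_probs([[0.5, 0.5]])
        bad = _query(np.ones((2, 1)), genes=["other1", "other2"])
        with pytest.raises(ValidationError, match="align"):
            score_loglik(model, bad)

    def test_normalization_mismatch_warns(self):
        model = _model_from_probs([[0.5, 0.5], [0.2, 0.8]])
        model.metadata["normalization"] = "umi"
        with pytest.warns(UserWarning, match="normalization"):
            score_loglik(model, _query([[1.0], [1.0]]), query_normalization="tpm")

    def test_invariant_under_model_gene_permutation(self):
        rng = np.random.default_rng(1)
        model, query = _random_instance(rng)
        perm = rng.permutation(len(model.gene_names))
        from scibet import SciBetModel

        shuffled = SciBetModel(
            model.type_names,
            [model.gene_names[i] for i in perm],
            model.log_prob[:, perm],
        )
        aligned = align_genes(shuffled.gene_names, query).matrix
        np.testing.assert_allclose(
            score_loglik(shuffled, aligned), score_loglik(model, query), rtol=1e-12
        )


class TestPredict:
    def test_hand_example_assigns_likelier_type(self):
        model = _model_from_probs([[0.9, 0.1], [0.1, 0.9]], types=["A", "B"])
        result = predict(model, _query([[10.0], [0.0]]))
        assert result.assigned_type == ["A"]

    def test_all_zero_cell_gets_first_type_and_degenerate_flag(self):
        model = _model_from_probs([[0.5, 0.5], [0.2, 0.8]], types=["first", "second"])
        result = predict(model, _query([[0.0, 1.0], [0.0, 0.0]]))
        assert result.assigned_type[0] == "first"
        assert result.degenerate.tolist() == [True, False]

    def test_mle_equals_min_kl_on_random_instances(self):
        """argmax_j Σ y ln p_j must match an independent argmin_j KL(q‖p_j)."""
        rng = np.random.default_rng(7)
        agree = 0
        for _ in range(1000):
            model, query = _random_instance(rng)
            mle = predict(model, query).assigned_type[0]
            y = query.values[:, 0]
            q = y / y.sum()
            with np.errstate(divide="ignore", invalid="ignore"):
                contrib = np.where(q > 0, q * (np.log(q) - model.log_prob), 0.0)
            kl = contrib.sum(axis=1)
            agree += mle == model.type_names[int(np.argmin(kl))]
        assert agree == 1000


class TestNullModelAndConfidence:
    def test_null_model_is_pooled_pseudo_type(self, tiny_norm):
        m, _ = tiny_norm
        null = build_null_model(m)
        pooled = m.values.mean(axis=1)
        expected = np.log((pooled + 1) / (pooled + 1).sum())
        np.testing.assert_allclose(null.log_prob[0], expected, rtol=1e-12)
        assert null.type_names == ["null"]

    def test_empty_background_rejected(self):
        empty = ExpressionMatrix(["g1"], [], np.zeros((1, 0)), MatrixState.NORMALIZED_LOG)
        with pytest.raises(ValidationError, match="empty"):
            build_null_model(empty)

    def test_identical_reference_and_null_score_zero(self, tiny_norm):
        m, _ = tiny_norm
        logC = confidence_score(m, m, m, k=3)
        np.testing.assert_allclose(logC, 0.0, atol=1e-12)

    def test_logc_matches_independent_likelihood_ratio(self):
        """Dual route: pipeline log C vs a from-scratch Eq.-style computation."""
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(20)]
        ref = ExpressionMatrix(
            genes, [f"r{i}" for i in range(15)],
            rng.gamma(2.0, 1.0, (20, 15)), MatrixState.NORMALIZED_LOG,
        )
        null = ExpressionMatrix(
            genes, [f"n{i}" for i in range(25)],
            rng.gamma(1.0, 1.0, (20, 25)), MatrixState.NORMALIZED_LOG,
        )
        query = ExpressionMatrix(
            genes, [f"q{i}" for i in range(5)],
            rng.gamma(2.0, 1.0, (20, 5)), MatrixState.NORMALIZED_LOG,
        )
        k = 8
        logC = confidence_score(ref, null, query, k=k)
        # oracle: pooled means, two-group ΔS ranking, smoothed ratio
        xr, xn = ref.values.mean(axis=1), null.values.mean(axis=1)
        M = np.vstack([xr, xn]) + 1.0
        ds = 2 * (np.log(M.mean(axis=0)) - np.log(M).mean(axis=0))
        order = np.lexsort((genes, -ds))[:k]
        pr = (xr[order] + 1) / (xr[order] + 1).sum()
        pn = (xn[order] + 1) / (xn[order] + 1).sum()
        expected = query.values[order].T @ (np.log(pr) - np.log(pn))
        np.testing.assert_allclose(logC, expected, rtol=1e-10)

    def test_logc_monotone_in_reference_favored_gene(self, tiny_norm):
        m, _ = tiny_norm
        rng = np.random.default_rng(2)
        null = ExpressionMatrix(
            m.gene_names, ["n1", "n2"], rng.gamma(1.0, 1.0, (3, 2)),
            MatrixState.NORMALIZED_LOG,
        )
        base = confidence_score(m, null, m, k=3)
        boosted_vals = m.values.copy()
        # find a gene favoring the reference and boost one query cell on it
        xr, xn = m.values.mean(axis=1), null.values.mean(axis=1)
        fav = int(np.argmax(np.log(xr + 1) - np.log(xn + 1)))
        boosted_vals[fav, 0] += 2.0
        boosted = ExpressionMatrix(
            m.gene_names, m.cell_names, boosted_vals, MatrixState.NORMALIZED_LOG
        )
        out = confidence_score(m, null, boosted, k=3)
        assert out[0] > base[0]

    def test_k_clamped_with_warning(self, tiny_norm):
        m, _ = tiny_norm
        with pytest.warns(UserWarning, match="clamp"):
            logC = confidence_score(m, m, m, k=500)
        assert logC.shape == (4,)


class TestApplyUnassignment:
    def _result(self, logC, cells=None):
        n = len(logC)
        cells = cells or [f"c{i}" for i in range(n)]
        return PredictionResult(
            cells, ["A"], np.zeros((n, 1)), ["A"] * n,
            np.zeros(n, bool), confidence_logC=np.asarray(logC, float),
        )

    def test_exact_count_at_quantile_cutoff(self):
        logC = [5.0, -3.0, 2.0, -7.0, 1.0, 0.5, 4.0, 3.0, 2.5, 6.0]
        out = apply_unassignment(self._result(logC), 0.2)
        assert out.unassigned.sum() == 2
        assert out.unassigned[1] and out.unassigned[3]
        assert out.labels[3] == "unassigned" and out.labels[0] == "A"

    def test_vanishing_cutoff_unassigns_nobody(self):
        out = apply_unassignment(self._result([1.0, 2.0, 3.0]), 0.01)
        assert out.unassigned.sum() == 0

    def test_equal_scores_resolved_by_cell_name(self):
        out = apply_unassignment(self._result([1.0] * 10), 0.5)
        assert out.unassigned.sum() == 5
        assert [c for c, u in zip(out.cell_names, out.unassigned) if u] == [
            "c0", "c1", "c2", "c3", "c4",
        ]

    def test_absolute_mode_thresholds_on_C(self):
        out = apply_unassignment(self._result([np.log(0.01), np.log(0.9)]), 0.05, mode="absolute")
        assert out.unassigned.tolist() == [True, False]

    def test_invalid_cutoffs_rejected(self):
        res = self._result([1.0, 2.0])
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValidationError):
                apply_unassignment(res, bad)
        with pytest.raises(ValidationError, match="confidence"):
            apply_unassignment(
                PredictionResult(["c"], ["A"], np.zeros((1, 1)), ["A"], np.zeros(1, bool)),
                0.1,
            )
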