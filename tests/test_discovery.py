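import numpy as np
import pytest

from surrogene.discovery import (
    StratumCorrelation,
    _bulk_pearson,
    correlate_gene_pathways,
    pearson_r_p,
    rank_surrogates,
)
from surrogene.io_formats import ExpressionMatrix
from surrogene.ssgsea import ScoreMatrix, SsgseaParams, score_matrix


class TestPearson:
    def test_perfect_positive(self):
        r, p = pearson_r_p(np.array([1.0, 2, 3]), np.array([2.0, 4, 6]))
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_sign_flip(self):
        r, _ = pearson_r_p(np.array([1.0, 2, 3]), np.array([3.0, 2, 1]))
        assert r == pytest.approx(-1.0)

    def test_zero_variance_sentinel(self, caplog):
        with caplog.at_level("WARNING"):
            r, p = pearson_r_p(np.array([1.0, 1, 1]), np.array([1.0, 2, 3]))
        assert np.isnan(r) and np.isnan(p)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r_p(np.array([1.0, 2]), np.array([1.0, 2]))

    def test_bulk_matches_scalar(self):
        """The vectorized many-genes path must agree with scipy per gene."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 15))
        y = rng.normal(size=15)
        r, p = _bulk_pearson(X, y)
        for i in range(20):
            ri, pi = pearson_r_p(X[i], y)
            assert r[i] == pytest.approx(ri, abs=1e-12)
            assert p[i] == pytest.approx(pi, rel=1e-9)


def _scores_from(values_by_sample, names=("pw",)):
    samples = list(values_by_sample)
    arr = np.array([values_by_sample[s] for s in samples], float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return ScoreMatrix(sample_ids=samples, set_names=list(names), scores=arr)


class TestCorrelateGenePathways:
    def test_gene_equal_to_score_has_r_one(self):
        samples = [f"s{i}" for i in range(6)]
        score_vals = {s: float(i) for i, s in enumerate(samples)}
        expr = ExpressionMatrix(
            ["g_copy", "g_noise"],
            samples,
            np.vstack([np.arange(6.0), np.array([3.0, 1, 4, 1, 5, 9])]),
            value_space="log",
        )
        out = correlate_gene_pathways(
            expr, _scores_from(score_vals), {s: "T" for s in samples}, log_transform=False
        )
        copy = next(c for c in out if c.gene_id == "g_copy")
        assert copy.r == pytest.approx(1.0)
        assert copy.p == pytest.approx(0.0, abs=1e-12)

    def test_small_stratum_skipped_with_warning(self, caplog):
        samples = ["a", "b", "c", "d", "e"]
        expr = ExpressionMatrix(
            ["g"], samples, np.arange(5.0)[None, :], value_space="log"
        )
        scores = _scores_from({s: float(i) for i, s in enumerate(samples)})
        strata = {"a": "big", "b": "big", "c": "big", "d": "small", "e": "small"}
        with caplog.at_level("WARNING"):
            out = correlate_gene_pathways(expr, scores, strata, log_transform=False)
        assert {c.stratum_id for c in out} == {"big"}
        assert any("skipped" in r.message for r in caplog.records)

    def test_no_usable_stratum_is_error(self):
        expr = ExpressionMatrix(["g"], ["a", "b"], np.array([[1.0, 2.0]]), value_space="log")
        scores = _scores_from({"a": 0.0, "b": 1.0})
        with pytest.raises(ValueError, match="no stratum"):
            correlate_gene_pathways(expr, scores, {"a": "x", "b": "x"}, log_transform=False)

    def test_planted_surrogate_positive_in_all_strata(self, default_study):
        """The generator's planted gene must correlate strongly (r > 0.5)
        with every pathway score in every tumor type."""
        expr, sets, clinical, truth = default_study
        sm = score_matrix(expr, sets, SsgseaParams())
        out = correlate_gene_pathways(expr, sm, clinical.strata())
        surrogate = [c for c in out if c.gene_id == truth.surrogate_gene_id]
        assert len(surrogate) == 6 * 3
        assert all(c.r > 0.5 for c in surrogate)


def _corr(gene, stratum, pathway, r, p, n=10):
    return StratumCorrelation(gene, stratum, pathway, n, r, p)


class TestRankSurrogates:
    PATHWAYS = ("pw1", "pw2", "pw3")

    def test_saturated_single_gene(self):
        corrs = [
            _corr("g", f"t{i}", pw, 1.0, 0.0)
            for i in range(5)
            for pw in self.PATHWAYS
        ]
        (res,) = rank_surrogates(corrs)
        assert res.aggregate_count == 15
        assert res.per_pathway_counts == {pw: 5 for pw in self.PATHWAYS}
        assert res.rank == 1

    def test_count_monotonicity_orders_genes(self):
        corrs = []
        for stratum in range(3):
            for pw in self.PATHWAYS:
                corrs.append(_corr("A", f"t{stratum}", pw, 0.8, 0.01))
                corrs.append(_corr("B", f"t{stratum}", pw, 0.9, 0.01 if stratum < 2 else 0.5))
        res = {r.gene_id: r for r in rank_surrogates(corrs)}
        assert res["A"].aggregate_count == 9
        assert res["B"].aggregate_count == 6
        assert res["A"].rank < res["B"].rank

    def test_threshold_extremes_count_all_strata(self):
        corrs = [
            _corr(g, f"t{i}", pw, r, 0.9)
            for g in ("A", "B")
            for i in range(4)
            for pw, r in zip(self.PATHWAYS, (-0.5, 0.1, 0.3))
        ]
        res = rank_surrogates(corrs, r_threshold=-1.0, p_threshold=1.0)
        assert all(r.aggregate_count == 4 * 3 for r in res)

    def test_ties_broken_by_mean_r_then_gene_id(self):
        corrs = []
        for pw in self.PATHWAYS:
            corrs.append(_corr("B", "t0", pw, 0.9, 0.01))
            corrs.append(_corr("A", "t0", pw, 0.7, 0.01))
            corrs.append(_corr("C", "t0", pw, 0.7, 0.01))
        ranked = [r.gene_id for r in rank_surrogates(corrs)]
        assert ranked == ["B", "A", "C"]  # count tie -> mean r; then gene id

    def test_require_all_pathways_counts_strata_once(self):
        corrs = []
        for pw in self.PATHWAYS:
            corrs.append(_corr("g", "t0", pw, 0.8, 0.01))  # all three significant
            corrs.append(_corr("g", "t1", pw, 0.8, 0.01 if pw != "pw3" else 0.9))
        (res,) = rank_surrogates(corrs, require_all_pathways=True)
        assert res.aggregate_count == 1

    def test_nan_correlations_never_count(self):
        corrs = [_corr("g", "t0", "pw1", float("nan"), float("nan")),
                 _corr("g", "t1", "pw1", 0.9, 0.01)]
        (res,) = rank_surrogates(corrs)
        assert res.aggregate_count == 1

    def test_adding_stratum_never_decreases_counts(self):
        base = [
            _corr(g, f"t{i}", pw, r, 0.01)
            for g in ("A", "B")
            for i in range(3)
            for pw, r in zip(self.PATHWAYS, (0.5, -0.2, 0.8))
        ]
        extra = [_corr(g, "t_new", pw, 0.6, 0.01) for g in ("A", "B") for pw in self.PATHWAYS]
        before = {r.gene_id: r.aggregate_count for r in rank_surrogates(base)}
        after = {r.gene_id: r.aggregate_count for r in rank_surrogates(base + extra)}
        assert all(after[g] >= before[g] for g in before)

    def test_ranks_are_dense_and_deterministic(self):
        rng = np.random.default_rng(2)
        corrs = [
            _corr(f"g{k}", f"t{i}", pw, float(rng.uniform(-1, 1)), float(rng.uniform()))
            for k in range(10)
            for i in range(4)
            for pw in self.PATHWAYS
        ]
        res1 = rank_surrogates(corrs)
        res2 = rank_surrogates(list(reversed(corrs)))
        assert [r.rank for r in res1] == list(range(1, 11))
        assert [(r.gene_id, r.rank) for r in res1] == [(r.gene_id, r.rank) for r in res2]

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            rank_surrogates([])
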