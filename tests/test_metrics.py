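"""Communication cost, well-formedness and partition-similarity measures."""

import numpy as np
import pytest

import colorgame as cg
from colorgame.metrics import (
    NamingModel,
    adjusted_rand_index,
    aggregate_expected_surprise,
    bayes_decoder,
    exemplar_decoder,
    expected_surprise,
    kl_loss_from_partition,
    mean_pairwise_ari,
    wellformedness,
)
from colorgame.partitioning import Partition, random_partition
from conftest import make_chips


def det_model(labels):
    return NamingModel({c: {lab: 1.0} for c, lab in enumerate(labels)})


class TestBayesDecoder:
    def test_two_terms_covering_two_chips_each(self):
        """4 chips, 2 deterministic terms, uniform prior -> p(c|w) = 1/2."""
        decoder = bayes_decoder(det_model(["a", "a", "b", "b"]))
        assert decoder["a"] == {0: pytest.approx(0.5), 1: pytest.approx(0.5)}
        assert decoder["b"] == {2: pytest.approx(0.5), 3: pytest.approx(0.5)}

    def test_single_term_returns_prior(self):
        prior = {0: 0.5, 1: 0.3, 2: 0.2}
        decoder = bayes_decoder(det_model(["w", "w", "w"]), prior)
        assert decoder["w"] == pytest.approx(prior)

    def test_normalization_on_random_models(self, rng):
        for _ in range(10):
            model = NamingModel(
                {c: dict(zip("abc", rng.dirichlet(np.ones(3)))) for c in range(6)}
            )
            for dist in bayes_decoder(model).values():
                assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            NamingModel({})


class TestExpectedSurprise:
    def test_half_mass_posterior_costs_one_bit(self):
        model = det_model(["a", "a", "b", "b"])
        decoder = bayes_decoder(model)
        assert expected_surprise(model, decoder, 0) == pytest.approx(1.0)

    def test_single_term_costs_log2_n(self):
        n = 8
        model = det_model(["w"] * n)
        assert aggregate_expected_surprise(model) == pytest.approx(np.log2(n))

    def test_perfect_system_costs_zero(self):
        model = det_model(["a", "b", "c"])
        assert aggregate_expected_surprise(model) == pytest.approx(0.0)

    def test_zero_posterior_yields_infinity_with_warning(self):
        model = NamingModel({0: {"a": 1.0}, 1: {"a": 0.5, "b": 0.5}})
        decoder = {"a": {0: 1.0}, "b": {1: 1.0}}  # term a never decodes chip 1
        with pytest.warns(RuntimeWarning):
            assert expected_surprise(model, decoder, 1) == np.inf


class TestKlLoss:
    def test_two_identical_chips_one_category_is_one_bit(self):
        chart = cg.ChipChart(chips=make_chips((0, 0, 0), (0, 0, 0)), name="c2")
        part = Partition(labels={0: "w", 1: "w"}, chart_ref="c2")
        assert kl_loss_from_partition(part, chart) == pytest.approx(1.0)

    def test_exemplar_decoder_normalizes_per_word(self, chart_small, rng):
        part = random_partition(chart_small, 4, rng)
        decoder = exemplar_decoder(part, chart_small)
        assert len(decoder) == part.term_count
        for dist in decoder.values():
            assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_matches_expected_surprise_for_deterministic_naming(self, chart_small, rng):
        """With a deterministic naming model and the exemplar listener, the
        per-chip expected surprise collapses to -log2 p(c|w) = the KL form."""
        part = random_partition(chart_small, 3, rng)
        model = NamingModel.from_partition(part)
        decoder = exemplar_decoder(part, chart_small)
        per_chip = [
            expected_surprise(model, decoder, c) for c in range(len(chart_small))
        ]
        assert np.mean(per_chip) == pytest.approx(
            kl_loss_from_partition(part, chart_small), rel=1e-12
        )

    def test_finer_coherent_partitions_cost_less(self, chart330):
        from colorgame.corr_clustering import build_similarity_graph, solve

        graph = build_similarity_graph(chart330)
        rng = np.random.default_rng(0)
        kl = {}
        for k in (3, 8):
            part, _ = solve(graph, restarts=3, rng=rng, max_clusters=k,
                            chart_ref=chart330.name)
            kl[k] = kl_loss_from_partition(part, chart330)
        assert kl[8] < kl[3]

    def test_per_category_variant_is_cheaper(self, chart_small, rng):
        part = random_partition(chart_small, 3, rng)
        assert kl_loss_from_partition(part, chart_small, per_category_norm=True) <= (
            kl_loss_from_partition(part, chart_small)
        )


class TestWellformedness:
    def test_singletons_score_zero(self, chart_small):
        part = Partition.from_array(np.arange(len(chart_small)), chart_ref=chart_small.name)
        assert wellformedness(part, chart_small) == 0.0

    def test_two_chip_category_scores_sim_minus_half(self):
        d = np.sqrt(-np.log(0.9) / 0.001)  # distance at which sim = 0.9
        chart = cg.ChipChart(chips=make_chips((0, 0, 0), (d, 0, 0)), name="c2")
        part = Partition(labels={0: "w", 1: "w"}, chart_ref="c2")
        assert wellformedness(part, chart) == pytest.approx(0.4)

    def test_never_exceeds_solver_optimum(self, chart_small, rng):
        from colorgame.corr_clustering import build_similarity_graph, solve

        graph = build_similarity_graph(chart_small)
        _, best = solve(graph, restarts=10, rng=rng)
        for k in (2, 5, len(chart_small)):
            part = random_partition(chart_small, k, rng)
            assert wellformedness(part, chart_small) <= best + 1e-9


class TestAdjustedRandIndex:
    def make(self, labels, ref="c"):
        return Partition.from_array(labels, chart_ref=ref)

    def test_identical_partitions_score_one(self):
        p = self.make([1, 1, 2, 2, 3])
        assert adjusted_rand_index(p, p) == pytest.approx(1.0)

    def test_hand_computed_negative_case(self):
        """Crossing 2x2 design: contingency arithmetic gives exactly -0.5."""
        a = self.make([1, 1, 2, 2])
        b = self.make([1, 2, 1, 2])
        assert adjusted_rand_index(a, b) == pytest.approx(-0.5)

    def test_label_permutation_invariance(self):
        a = self.make(["x", "x", "y", "z"])
        b = self.make([5, 5, 9, 1])
        assert adjusted_rand_index(a, b) == pytest.approx(1.0)

    def test_different_charts_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index(self.make([1, 2], "a"), self.make([1, 2], "b"))

    def test_independent_random_partitions_score_near_zero(self):
        rng = np.random.default_rng(0)
        scores = []
        for _ in range(1000):
            a = self.make(rng.integers(0, 5, 330))
            b = self.make(rng.integers(0, 5, 330))
            scores.append(adjusted_rand_index(a, b))
        assert abs(np.mean(scores)) < 0.01


class TestMeanPairwiseAri:
    def test_identical_members_give_mean_one_ci_zero(self):
        p = Partition.from_array([1, 1, 2, 2])
        s = mean_pairwise_ari([p, p, p])
        assert s.mean == pytest.approx(1.0) and s.ci_halfwidth == 0.0

    def test_single_pair_has_flagged_undefined_ci(self):
        a = Partition.from_array([1, 1, 2, 2])
        b = Partition.from_array([1, 2, 1, 2])
        s = mean_pairwise_ari([a, b])
        assert s.n_pairs == 1 and s.ci_halfwidth == 0.0 and not s.ci_defined

    def test_cross_group_counts_all_pairs(self):
        a = Partition.from_array([1, 1, 2, 2])
        b = Partition.from_array([1, 2, 1, 2])
        s = mean_pairwise_ari([a, a], [b, b, b])
        assert s.n_pairs == 6

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mean_pairwise_ari([])
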