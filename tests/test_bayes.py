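import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kinbayes import (
    ActivityAnnotation,
    KinaseVector,
    activity_likelihood,
    bayes_update,
    cmbf,
    colocalization_likelihood,
    estimate_poisson_pivot,
    expression_likelihood,
    floor_likelihood,
    information_content,
    interpolate_missing,
    motif_match_likelihood,
    run_pipeline,
    sty_preference_likelihood,
)
from kinbayes.bayes import ConfigurationError, selected_positions_for

from conftest import make_site, small_registry, uniform_bundle


def series(values, registry):
    return pd.Series(values, index=list(registry.kinases), dtype=float)


class TestCmbf:
    def test_exact_values(self):
        assert cmbf(0.0) == 0.0
        assert cmbf(1.0) == pytest.approx(1 - np.exp(-0.5), abs=1e-15)
        assert cmbf(2.0) == pytest.approx(1 - np.exp(-2.0), abs=1e-15)

    def test_sign_symmetric(self):
        for z in (0.3, 1.7, 4.0):
            assert cmbf(z) == cmbf(-z)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            cmbf(np.inf)


class TestFloor:
    def test_examples(self):
        np.testing.assert_allclose(
            floor_likelihood(np.array([0.0, 0.3, 0.9])), [0.5, 0.5, 0.9]
        )

    def test_identity_above_floor(self):
        v = np.array([0.5, 0.7, 1.0])
        np.testing.assert_allclose(floor_likelihood(v), v)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, values):
        once = floor_likelihood(np.array(values))
        np.testing.assert_allclose(floor_likelihood(once), once)


class TestBayesUpdate:
    def test_uniform_invariance(self):
        reg = small_registry(4)
        prior = KinaseVector.uniform_prior(reg)
        lik = KinaseVector.likelihood(series(0.7, reg))
        post = bayes_update(prior, lik)
        np.testing.assert_allclose(post.values, 0.25)

    def test_hand_normalization(self):
        reg = small_registry(2)
        prior = KinaseVector(series([0.5, 0.5], reg), "prior")
        lik = KinaseVector.likelihood(series([0.9, 0.1], reg))
        post = bayes_update(prior, lik)
        np.testing.assert_allclose(post.values, [0.9, 0.1])

    def test_sequential_equals_product(self):
        reg = small_registry(3)
        prior = KinaseVector.uniform_prior(reg)
        l1 = series([0.9, 0.5, 0.5], reg)
        l2 = series([0.5, 0.9, 0.5], reg)
        step = bayes_update(bayes_update(prior, KinaseVector.likelihood(l1)),
                            KinaseVector.likelihood(l2))
        combined = bayes_update(prior, KinaseVector.likelihood(l1 * l2))
        np.testing.assert_allclose(step.values, combined.values, atol=1e-15)
        np.testing.assert_allclose(step.values, [0.3913, 0.3913, 0.2174],
                                   atol=5e-5)

    def test_all_zero_products_error(self):
        reg = small_registry(2)
        prior = KinaseVector.uniform_prior(reg)
        with pytest.raises(ZeroDivisionError):
            bayes_update(prior, KinaseVector.likelihood(series(0.0, reg)))

    def test_posterior_sums_to_one_property(self):
        rng = np.random.default_rng(2)
        reg = small_registry(5)
        post = KinaseVector.uniform_prior(reg)
        for _ in range(7):
            lik = series(rng.uniform(0.1, 1.0, 5), reg)
            post = bayes_update(post, KinaseVector.likelihood(lik))
            assert post.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        reg = small_registry(5)
        liks = [series(rng.uniform(0.1, 1.0, 5), reg) for _ in range(7)]
        prior = KinaseVector.uniform_prior(reg)

        def run(order):
            post = prior
            for i in order:
                post = bayes_update(post, KinaseVector.likelihood(liks[i]))
            return post.values

        base = run(range(7))
        shuffled = run(rng.permutation(7))
        np.testing.assert_allclose(base, shuffled, atol=1e-12)


class TestExpression:
    def test_zero_floors(self):
        reg = small_registry(2)
        lik = expression_likelihood(series([0.0, 5.0], reg), pivot=1.0,
                                    registry=reg)
        assert lik["K1"] == 0.5

    def test_three_pivots(self):
        reg = small_registry(1)
        lik = expression_likelihood(series([3.0], reg), pivot=1.0, registry=reg)
        assert lik["K1"] == pytest.approx(1 - np.exp(-4.5), abs=1e-12)

    def test_missing_kinase_never_beats_expressed(self):
        reg = small_registry(3)
        values = pd.Series({"K1": 10.0})  # K2, K3 unmeasured
        lik = expression_likelihood(values, pivot=1.0, registry=reg)
        assert lik["K1"] > lik["K2"] == lik["K3"] == 0.5


class TestStyPreference:
    def test_pure_serine_alignment(self):
        reg = small_registry(1)
        table = pd.DataFrame({"f_S": [1.0], "f_T": [0.0], "f_Y": [0.0]},
                             index=["K1"])
        lik = sty_preference_likelihood(table, np.array([1.0, 0, 0]), reg)
        assert lik["K1"] == pytest.approx(1 - np.exp(-81 / 2), abs=1e-12)

    def test_tyrosine_kinase_floored(self):
        reg = small_registry(1)
        table = pd.DataFrame({"f_S": [0.0], "f_T": [0.0], "f_Y": [1.0]},
                             index=["K1"])
        lik = sty_preference_likelihood(table, np.array([0.7, 0.3, 0.0]), reg)
        assert lik["K1"] == 0.5

    def test_half_overlap(self):
        reg = small_registry(1)
        table = pd.DataFrame({"f_S": [0.5], "f_T": [0.5], "f_Y": [0.0]},
                             index=["K1"])
        lik = sty_preference_likelihood(table, np.array([0.6, 0.4, 0.0]), reg)
        # dot = 0.5, z* = 4.5
        assert lik["K1"] == pytest.approx(1 - np.exp(-4.5**2 / 2), abs=1e-12)


class TestColocalization:
    def test_orthogonal_floors(self):
        reg = small_registry(2)
        profiles = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["K1", "K2"],
                                columns=["a", "b"])
        cluster = pd.Series([0.0, 1.0], index=["a", "b"])
        lik, _ = colocalization_likelihood(profiles, cluster, reg, pivot=0.4)
        assert lik["K1"] == 0.5  # zero overlap floors to the coin flip
        assert lik["K2"] > 0.5

    def test_scores_match_nested_loop_oracle(self):
        rng = np.random.default_rng(8)
        reg = small_registry(5)
        profiles = pd.DataFrame(rng.uniform(0, 1, (5, 4)),
                                index=list(reg.kinases),
                                columns=list("abcd"))
        cluster = pd.Series(rng.uniform(0, 1, 4), index=list("abcd"))
        oracle = {
            k: sum(profiles.loc[k, f] * cluster[f] for f in "abcd")
            for k in reg.kinases
        }
        scores = profiles.to_numpy() @ cluster.to_numpy()
        for k, s in zip(reg.kinases, scores):
            assert s == pytest.approx(oracle[k], abs=1e-12)

    def test_mismatched_fractions_error(self):
        reg = small_registry(1)
        profiles = pd.DataFrame([[1.0, 0.0]], index=["K1"], columns=["a", "b"])
        cluster = pd.Series([1.0], index=["c"])
        with pytest.raises(ValueError):
            colocalization_likelihood(profiles, cluster, reg, pivot=1.0)


class TestActivity:
    @pytest.mark.parametrize(
        "label, direction, expected",
        [
            ("increase", "increased", 0.9),
            ("decrease", "increased", 0.1),
            ("regulated_unknown", "increased", 0.7),
            ("regulated_unknown", "decreased", 0.7),
            ("none", "decreased", 0.5),
        ],
    )
    def test_discrete_mapping(self, label, direction, expected):
        reg = small_registry(1)
        ann = ActivityAnnotation({} if label == "none" else {"K1": label})
        lik = activity_likelihood(ann, direction, reg)
        assert lik["K1"] == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            ActivityAnnotation({"K1": "sideways"})


class TestInformationContent:
    def test_matching_background_is_zero(self):
        freqs = pd.DataFrame({"A": [0.25], "C": [0.75]}, index=[0])
        bg = pd.Series({"A": 0.25, "C": 0.75})
        assert (information_content(freqs, bg).to_numpy() == 0).all()

    def test_two_bits(self):
        freqs = pd.DataFrame({"A": [1.0]}, index=[0])
        bg = pd.Series({"A": 0.25})
        assert information_content(freqs, bg).loc[0, "A"] == pytest.approx(
            2.0, abs=1e-12
        )

    def test_half_frequency(self):
        freqs = pd.DataFrame({"A": [0.5]}, index=[0])
        bg = pd.Series({"A": 0.05})
        assert information_content(freqs, bg).loc[0, "A"] == pytest.approx(
            0.5 * np.log2(10), abs=1e-12
        )

    def test_zero_background_with_mass_errors(self):
        freqs = pd.DataFrame({"A": [0.5], "C": [0.5]}, index=[0])
        bg = pd.Series({"A": 0.0, "C": 1.0})
        with pytest.raises(ValueError, match="A"):
            information_content(freqs, bg)


class TestMotifMatch:
    def _ic(self, data, positions):
        return pd.DataFrame(data, index=positions)

    def test_identical_ic_is_maximal(self):
        reg = small_registry(3)
        positions = list(range(-6, 7))
        cluster = pd.DataFrame(0.0, index=positions, columns=["A", "R"])
        cluster.loc[1, "A"] = 1.5
        kinase_ic = {
            "K1": cluster.copy(),
            "K2": cluster * 0.3,
            "K3": cluster * 0.0,
        }
        lik, _ = motif_match_likelihood(kinase_ic, cluster, (1,), reg, pivot=1.0)
        assert lik["K1"] == lik.max()

    def test_zero_cluster_ic_floors_everything(self):
        reg = small_registry(2)
        positions = list(range(-6, 7))
        cluster = pd.DataFrame(0.0, index=positions, columns=["A", "R"])
        kinase_ic = {k: cluster + 1.0 for k in reg.kinases}
        lik, _ = motif_match_likelihood(kinase_ic, cluster, (1, 2), reg, pivot=1.0)
        assert (lik == 0.5).all()

    def test_toy_against_nested_loop_oracle(self):
        rng = np.random.default_rng(12)
        reg = small_registry(3)
        positions = [-3, -2]
        cols = ["A", "R", "S"]
        cluster = pd.DataFrame(rng.normal(0, 1, (2, 3)), index=positions,
                               columns=cols)
        full_idx = list(range(-6, 7))
        cluster = cluster.reindex(full_idx, fill_value=0.0)
        kinase_ic = {
            k: pd.DataFrame(rng.normal(0, 1, (13, 3)), index=full_idx,
                            columns=cols)
            for k in reg.kinases
        }
        oracle = {}
        for k in reg.kinases:
            total = 0.0
            for pos in positions:
                for aa in cols:
                    prod = kinase_ic[k].loc[pos, aa] * cluster.loc[pos, aa]
                    total += max(prod, 0.0)
            oracle[k] = total
        lik, _ = motif_match_likelihood(kinase_ic, cluster, tuple(positions),
                                        reg, pivot=1.0)
        for k in reg.kinases:
            expected = max(0.5, cmbf(oracle[k]))
            assert lik[k] == pytest.approx(expected, abs=1e-12)

    def test_empty_selection_errors(self):
        reg = small_registry(1)
        with pytest.raises(ValueError):
            motif_match_likelihood({}, pd.DataFrame(index=range(-6, 7)), (),
                                   reg, pivot=1.0)


class TestInterpolation:
    def test_neighbor_fill(self):
        reg = small_registry(3)  # K1 -> K2 -> K3 -> K1
        out = interpolate_missing({"K1": 0.8}, {"K3": "K1", "K2": "K3"}, reg)
        assert out["K3"] == 0.8

    def test_identity_when_complete(self):
        reg = small_registry(2)
        out = interpolate_missing({"K1": 0.1, "K2": 0.9}, reg.neighbor_map, reg)
        assert out["K1"] == 0.1 and out["K2"] == 0.9

    def test_chain_walk(self):
        reg = small_registry(3)
        out = interpolate_missing({"K1": 0.6}, {"K3": "K2", "K2": "K1"}, reg)
        assert out["K3"] == 0.6

    def test_unscored_cycle_falls_to_zero(self):
        reg = small_registry(3)
        out = interpolate_missing({"K1": 0.6}, {"K3": "K2", "K2": "K3"}, reg)
        assert out["K3"] == 0.0


class TestPoissonPivot:
    def test_mean(self):
        assert estimate_poisson_pivot([1, 2, 3]).value == pytest.approx(2.0)

    def test_constant(self):
        assert estimate_poisson_pivot([4.0] * 10).value == pytest.approx(4.0)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            estimate_poisson_pivot([0.0, 0.0])

    def test_sampling_consistency(self):
        rng = np.random.default_rng(6)
        draws = rng.poisson(4.0, 1000)
        est = estimate_poisson_pivot(draws)
        assert abs(est.value - 4.0) < 3 * np.sqrt(4.0 / 1000)


class TestPipeline:
    def _cluster_sites(self):
        return [
            make_site("s1", "AAAAAASPAAAAA", [0.1, 0.2, 0.3, 0.4], gene="G_s1"),
            make_site("s2", "AAAAAASPAAAAA", [0.1, 0.2, 0.3, 0.4], gene="G_s1"),
        ]

    def test_constant_evidence_gives_unit_ratios(self, toy_registry):
        bundle = uniform_bundle(toy_registry)
        result = run_pipeline(self._cluster_sites(), "I", bundle, toy_registry)
        np.testing.assert_allclose(result["probability_ratio"], 1.0, atol=1e-9)

    def test_missing_step_named(self, toy_registry):
        bundle = uniform_bundle(toy_registry)
        bundle.sty = None
        with pytest.raises(ConfigurationError, match="sty"):
            run_pipeline(self._cluster_sites(), "I", bundle, toy_registry)

    def test_posterior_sums_to_one(self, toy_registry):
        bundle = uniform_bundle(toy_registry)
        result = run_pipeline(self._cluster_sites(), "I", bundle, toy_registry)
        assert result["posterior"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_dominant_kinase_ranks_first(self, default_experiment):
        """A kinase favored by every evidence layer tops its own cluster."""
        from kinbayes import assign_sites, regulation_report
        from kinbayes.bayes import rank_all_clusters

        sites, bundle, truth, registry = default_experiment
        report = regulation_report(sites)
        regulated = [s for s in sites if s.site_id in set(report.regulated_ids)]
        rankings = rank_all_clusters(regulated, assign_sites(regulated), bundle,
                                     registry)
        hits = 0
        pairs = truth.drop_duplicates("kinase")[["kinase", "expected_leaf"]]
        for kinase, leaf in pairs.itertuples(index=False):
            if leaf in rankings and kinase in set(rankings[leaf].head(5)["kinase"]):
                hits += 1
        assert hits >= 4  # at least 4 of the 5 planted kinases in one run

    def test_floor_keeps_zero_evidence_kinase_alive(self, toy_registry):
        bundle = uniform_bundle(toy_registry)
        bundle.transcript = pd.Series({"K1": 50.0, "K2": 50.0})  # K3 unmeasured
        result = run_pipeline(self._cluster_sites(), "I", bundle, toy_registry)
        assert (result["posterior"] > 0).all()

    def test_tie_break_alphabetical(self, toy_registry):
        bundle = uniform_bundle(toy_registry)
        result = run_pipeline(self._cluster_sites(), "I", bundle, toy_registry)
        assert list(result["kinase"]) == sorted(result["kinase"])

    def test_selected_positions_longest_prefix(self):
        assert selected_positions_for("I.A.2.a") == (1,)
        assert selected_positions_for("II.A.1.b") == (-3, -2)
        assert selected_positions_for("II.B.1.a") == (-3,)
        assert selected_positions_for("IV.B") == (-2, -1)


class TestOracleEquivalence:
    def test_sequential_equals_single_pass_product(self):
        """For small registries, 7 sequential updates equal the product form."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(2, 6))
            reg = small_registry(n)
            liks = [
                floor_likelihood(rng.uniform(0, 1, n)) for _ in range(7)
            ]
            post = KinaseVector.uniform_prior(reg)
            for lik in liks:
                post = bayes_update(
                    post, KinaseVector.likelihood(series(lik, reg))
                )
            product = np.prod(liks, axis=0) / n
            oracle = product / product.sum()
            np.testing.assert_allclose(post.values.to_numpy(), oracle,
                                       atol=1e-12)
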