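"""R/S construction, the W = R.X and Y = S.W products, and their bounds."""

import numpy as np
import pandas as pd
import pytest

from metnet import (
    MetabolicActivityScorer,
    SchemaError,
    build_abundance_matrix,
    build_reaction_matrix,
    build_subsystem_matrix,
    compute_reaction_scores,
    compute_subsystem_scores,
    generate_features,
    match_taxa,
)

from conftest import make_bundle


def random_scoring_fixture(seed):
    """Random bundle + abundances, plus the matrices the pipeline builds."""
    rng = np.random.default_rng(seed)
    bundle = make_bundle(
        n_taxa=int(rng.integers(2, 6)),
        strains_per_taxon=int(rng.integers(1, 5)),
        n_reactions=int(rng.integers(4, 15)),
        n_subsystems=int(rng.integers(1, 5)),
        density=float(rng.uniform(0.2, 0.9)),
        seed=seed,
    )
    taxa = sorted({s.species_key for s in bundle.strains})
    matches, _ = match_taxa(bundle, taxa, "species")
    n_samples = int(rng.integers(2, 7))
    X = pd.DataFrame(
        rng.dirichlet(np.ones(len(matches)), size=n_samples).T,
        index=[m.taxon_name for m in matches],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    R = build_reaction_matrix(bundle, matches)
    W = compute_reaction_scores(R, X)
    return bundle, matches, X, R, W


class TestReactionMatrix:
    def test_three_of_four_strains_gives_075(self):
        bundle = make_bundle(n_taxa=1, strains_per_taxon=4, n_reactions=2,
                             density=1.0, seed=0)
        bundle.presence.loc["t0_s3", "r00"] = 0  # 3 of 4 strains carry r00
        matches, _ = match_taxa(bundle, ["Genus0 epithet0"], "species")
        R = build_reaction_matrix(bundle, matches, weight_mode="ratio")
        assert R.at["r00", "Genus0 epithet0"] == 0.75

    def test_full_mode_gives_all_or_nothing(self):
        bundle = make_bundle(n_taxa=1, strains_per_taxon=4, n_reactions=2,
                             density=1.0, seed=0)
        bundle.presence.loc["t0_s3", "r00"] = 0
        matches, _ = match_taxa(bundle, ["Genus0 epithet0"], "species")
        R = build_reaction_matrix(bundle, matches, weight_mode="full")
        assert R.at["r00", "Genus0 epithet0"] == 1.0

    def test_full_dominates_ratio_elementwise(self):
        for seed in range(5):
            bundle, matches, X, R, W = random_scoring_fixture(seed)
            Rf = build_reaction_matrix(bundle, matches, weight_mode="full")
            assert (Rf.to_numpy() >= R.to_numpy() - 1e-15).all()
            Wf = compute_reaction_scores(Rf, X)
            assert (Wf.to_numpy() >= W.to_numpy() - 1e-12).all()

    def test_empty_matches_rejected(self, small_bundle):
        with pytest.raises(SchemaError):
            build_reaction_matrix(small_bundle, [])


class TestReactionScores:
    def test_identity_abundance_reproduces_r_column(self, small_bundle):
        matches, _ = match_taxa(
            small_bundle, ["Genus0 epithet0", "Genus1 epithet1"], "species"
        )
        R = build_reaction_matrix(small_bundle, matches)
        X = pd.DataFrame({"s1": [1.0, 0.0]}, index=R.columns)
        W = compute_reaction_scores(R, X)
        np.testing.assert_allclose(W["s1"], R["Genus0 epithet0"])

    def test_zero_abundance_gives_zero_scores(self, small_bundle):
        matches, _ = match_taxa(small_bundle, ["Genus0 epithet0"], "species")
        R = build_reaction_matrix(small_bundle, matches)
        X = pd.DataFrame({"s1": [0.0]}, index=R.columns)
        assert (compute_reaction_scores(R, X).to_numpy() == 0).all()

    def test_taxon_order_mismatch_rejected(self, small_bundle):
        matches, _ = match_taxa(
            small_bundle, ["Genus0 epithet0", "Genus1 epithet1"], "species"
        )
        R = build_reaction_matrix(small_bundle, matches)
        X = pd.DataFrame({"s1": [0.5, 0.5]}, index=list(R.columns)[::-1])
        with pytest.raises(SchemaError, match="order"):
            compute_reaction_scores(R, X)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_loop_oracle(self, seed):
        """W and Y agree with naive double/triple-loop summation."""
        bundle, matches, X, R, W = random_scoring_fixture(seed)
        W_loop = np.zeros(W.shape)
        for k in range(R.shape[0]):
            for j in range(X.shape[1]):
                for i in range(R.shape[1]):
                    W_loop[k, j] += R.iat[k, i] * X.iat[i, j]
        np.testing.assert_allclose(W.to_numpy(), W_loop, atol=1e-12, rtol=0)

        S = build_subsystem_matrix(bundle, list(W.index))
        Y = compute_subsystem_scores(S, W)
        Y_loop = np.zeros(Y.shape)
        for z in range(S.matrix.shape[0]):
            for j in range(W.shape[1]):
                for k in range(W.shape[0]):
                    Y_loop[z, j] += S.matrix.iat[z, k] * W.iat[k, j]
        np.testing.assert_allclose(Y.to_numpy(), Y_loop, atol=1e-12, rtol=0)


class TestSubsystemMatrix:
    def test_global_weight_is_one_over_member_count(self):
        bundle = make_bundle(n_taxa=2, n_reactions=10, n_subsystems=1,
                             density=0.6, seed=4)
        S = build_subsystem_matrix(bundle, bundle.reaction_ids)
        row = S.matrix.loc["sub0"]
        np.testing.assert_allclose(row[row > 0], 1 / 10)
        assert row.sum() == pytest.approx(1.0)

    def test_contextualized_uses_present_member_count(self):
        bundle = make_bundle(n_taxa=2, n_reactions=10, n_subsystems=1,
                             density=0.6, seed=4)
        rids = bundle.reaction_ids
        w = np.zeros(10)
        w[:6] = 0.4  # 6 of 10 member reactions present
        W = pd.DataFrame({"s1": w}, index=rids)
        S = build_subsystem_matrix(bundle, rids, mode="contextualized", W=W)
        row = S.per_sample["s1"].loc["sub0"]
        np.testing.assert_allclose(row[rids[:6]], 1 / 6)
        assert (row[rids[6:]] == 0).all()
        Y = compute_subsystem_scores(S, W)
        assert Y.at["sub0", "s1"] == pytest.approx(0.4)

    def test_contextualized_vs_global_scale_factor(self):
        """With 6 of 10 members sharing one value, ratios differ by 10/6."""
        bundle = make_bundle(n_taxa=2, n_reactions=10, n_subsystems=1,
                             density=0.6, seed=4)
        rids = bundle.reaction_ids
        w = np.zeros(10)
        w[:6] = 0.3
        W = pd.DataFrame({"s1": w}, index=rids)
        Yg = compute_subsystem_scores(
            build_subsystem_matrix(bundle, rids), W)
        Yc = compute_subsystem_scores(
            build_subsystem_matrix(bundle, rids, mode="contextualized", W=W),
            W)
        assert Yc.at["sub0", "s1"] == pytest.approx(
            Yg.at["sub0", "s1"] * 10 / 6)

    def test_zero_present_members_yield_zero_activity(self):
        bundle = make_bundle(n_taxa=2, n_reactions=6, n_subsystems=2, seed=5)
        rids = bundle.reaction_ids
        W = pd.DataFrame({"s1": np.zeros(len(rids))}, index=rids)
        S = build_subsystem_matrix(bundle, rids, mode="contextualized", W=W)
        Y = compute_subsystem_scores(S, W)
        assert (Y.to_numpy() == 0).all()

    def test_constant_member_scores_pass_through_globally(self):
        bundle = make_bundle(n_taxa=2, n_reactions=8, n_subsystems=2, seed=6)
        rids = bundle.reaction_ids
        W = pd.DataFrame({"s1": np.full(len(rids), 0.42)}, index=rids)
        S = build_subsystem_matrix(bundle, rids)
        Y = compute_subsystem_scores(S, W)
        np.testing.assert_allclose(Y["s1"], 0.42)


class TestBoundsAndMonotonicity:
    @pytest.mark.parametrize("seed", range(10))
    def test_scores_in_unit_interval(self, seed):
        bundle, matches, X, R, W = random_scoring_fixture(seed)
        S = build_subsystem_matrix(bundle, list(W.index))
        Y = compute_subsystem_scores(S, W)
        for M in (R, W, Y):
            v = M.to_numpy()
            assert (v >= -1e-12).all() and (v <= 1 + 1e-12).all()
        # global-mode Y is bounded by the max member activity
        members = bundle.subsystem_members()
        for z in S.subsystem_names:
            cap = W.loc[[r for r in members[z] if r in W.index]].max(axis=0)
            assert (Y.loc[z] <= cap + 1e-12).all()

    def test_monotone_in_taxon_abundance(self):
        bundle, matches, X, R, W = random_scoring_fixture(11)
        X2 = X.copy()
        X2.iloc[0, 0] += 0.1  # raise taxon 0 in sample 0, others fixed
        W2 = compute_reaction_scores(R, X2)
        carried = R.iloc[:, 0] > 0
        assert (W2.iloc[:, 0][carried] >= W.iloc[:, 0][carried] - 1e-15).all()
        np.testing.assert_allclose(W2.iloc[:, 1:], W.iloc[:, 1:])


class TestGenerateFeatures:
    def test_toy_end_to_end_shapes_and_bounds(self, toy):
        res = generate_features(toy.feature_table, toy.taxonomy, toy.bundle)
        assert res.reaction_scores.shape == (6, 6)
        assert res.subsystem_scores.shape == (2, 6)
        for M in (res.reaction_scores, res.subsystem_scores):
            v = M.to_numpy()
            assert (v >= 0).all() and (v <= 1).all()

    def test_defaults_match_method_defaults(self):
        est = MetabolicActivityScorer()
        p = est.get_params(deep=False)
        assert (p["level"], p["weight_mode"], p["subsystem_mode"],
                p["renormalize_after_match"]) == (
            "species", "ratio", "global", False)

    def test_sklearn_transform_agrees_with_pipeline(self, toy):
        est = MetabolicActivityScorer(bundle=toy.bundle,
                                      taxonomy=toy.taxonomy)
        scores = est.fit_transform(toy.feature_table.T)
        pd.testing.assert_frame_equal(scores, est.reaction_scores_.T)
        assert list(est.get_feature_names_out()) == list(
            est.reaction_scores_.index)
        # clone-ability via get_params/set_params round trip
        from sklearn.base import clone

        est2 = clone(est)
        pd.testing.assert_frame_equal(
            est2.fit_transform(toy.feature_table.T), scores)

    def test_subsystem_target(self, toy):
        est = MetabolicActivityScorer(bundle=toy.bundle,
                                      taxonomy=toy.taxonomy,
                                      target="subsystem")
        scores = est.fit(toy.feature_table.T).transform(toy.feature_table.T)
        pd.testing.assert_frame_equal(scores, est.subsystem_scores_.T)
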