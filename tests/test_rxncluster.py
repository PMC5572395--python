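"""Reaction co-expression projection, clustering, and differential scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from conet import (
    ReactionEnzymeMap,
    build_network,
    cluster_reactions,
    cluster_tf_enrichment,
    combine_deregulation_flags,
    differential_cluster_scores,
    fisher_z,
    reaction_coexpression_matrix,
    select_highly_regulated_clusters,
    subsystem_enrichment,
)
from conet.coreg import PhysicalNetwork
from conet.rxncluster import ReactionCoexpressionMatrix
from conftest import make_corr


def corr_from_pairs(genes, pair_rs):
    m = np.eye(len(genes))
    idx = {g: i for i, g in enumerate(genes)}
    for (a, b), r in pair_rs.items():
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = r
    return make_corr(genes, m)


class TestReactionCoexpressionMatrix:
    def test_shared_identical_enzyme(self):
        rmap = ReactionEnzymeMap(
            enzymes={"R1": ("e1",), "R2": ("e1",)},
            subsystem={"R1": "S", "R2": "S"},
        )
        table = corr_from_pairs(["e1", "e2"], {("e1", "e2"): 0.1})
        mat = reaction_coexpression_matrix(rmap, table)
        assert mat.r_max("R1", "R2") == pytest.approx(1.0)

    def test_max_over_enumerated_pairs(self):
        rmap = ReactionEnzymeMap(
            enzymes={"R1": ("a", "b"), "R2": ("c",)},
            subsystem={"R1": "S", "R2": "S"},
        )
        table = corr_from_pairs(
            ["a", "b", "c"], {("a", "c"): 0.2, ("b", "c"): 0.7, ("a", "b"): 0.0}
        )
        mat = reaction_coexpression_matrix(rmap, table)
        assert mat.r_max("R1", "R2") == pytest.approx(0.7)

    def test_unexpressed_reaction_excluded(self):
        rmap = ReactionEnzymeMap(
            enzymes={"R1": ("a",), "R2": ("b",), "R3": ("zz",)},
            subsystem={"R1": "S", "R2": "S", "R3": "S"},
        )
        table = corr_from_pairs(["a", "b"], {("a", "b"): 0.4})
        mat = reaction_coexpression_matrix(rmap, table)
        assert mat.excluded == ["R3"]
        assert "R3" not in mat.reactions

    def test_diagonal_is_one(self, study, corr_ref):
        mat = reaction_coexpression_matrix(study.reaction_map, corr_ref)
        assert np.allclose(np.diag(mat.matrix), 1.0)

    def test_dominance_over_individual_pairs(self, rng):
        """r_max >= every enzyme-pair correlation, against brute force."""
        genes = [f"e{i}" for i in range(10)]
        m = np.clip(rng.uniform(-1, 1, size=(10, 10)), -1, 1)
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        table = make_corr(genes, m)
        enzymes = {}
        for k in range(6):
            size = int(rng.integers(1, 4))
            enzymes[f"R{k}"] = tuple(
                sorted(rng.choice(genes, size=size, replace=False))
            )
        rmap = ReactionEnzymeMap(
            enzymes=enzymes, subsystem={r: "S" for r in enzymes}
        )
        mat = reaction_coexpression_matrix(rmap, table)
        idx = {g: i for i, g in enumerate(genes)}
        for ra, rb in itertools.combinations(sorted(enzymes), 2):
            pairs = [
                m[idx[x], idx[y]]
                for x in enzymes[ra]
                for y in enzymes[rb]
            ]
            assert mat.r_max(ra, rb) == pytest.approx(max(pairs))
            assert all(mat.r_max(ra, rb) >= p for p in pairs)


class TestFisherZ:
    def test_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half(self):
        assert fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)

    def test_odd_symmetry(self):
        assert fisher_z(-0.5) == pytest.approx(-fisher_z(0.5))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)

    def test_roundtrip_within_clamp(self, rng):
        r = rng.uniform(-0.99, 0.99, size=50)
        assert np.allclose(np.tanh(fisher_z(r)), r, atol=1e-12)

    def test_strictly_increasing(self):
        r = np.linspace(-0.999, 0.999, 201)
        assert (np.diff(fisher_z(r)) > 0).all()


class TestClusterReactions:
    def test_hand_built_dendrogram(self):
        """A/B merge first (d=0.1), C/D next (0.2), E stays apart at k=3."""
        reactions = list("ABCDE")
        r = np.full((5, 5), -0.5)
        np.fill_diagonal(r, 1.0)
        pairs = {("A", "B"): 0.9, ("C", "D"): 0.8}
        idx = {x: i for i, x in enumerate(reactions)}
        for (a, b), v in pairs.items():
            r[idx[a], idx[b]] = r[idx[b], idx[a]] = v
        mat = ReactionCoexpressionMatrix(
            reactions=reactions, matrix=r, condition="t"
        )
        cl = cluster_reactions(mat, k=3)
        assert cl.assignment["A"] == cl.assignment["B"]
        assert cl.assignment["C"] == cl.assignment["D"]
        assert cl.assignment["A"] != cl.assignment["C"]
        assert cl.assignment["E"] not in (cl.assignment["A"], cl.assignment["C"])

    def test_two_blocks_recovered(self, rng):
        n = 20
        reactions = [f"R{i:02d}" for i in range(n)]
        r = np.full((n, n), 0.0)
        r[:10, :10] = 0.9
        r[10:, 10:] = 0.9
        r += rng.normal(0, 0.01, size=(n, n))
        r = np.clip((r + r.T) / 2, -1, 1)
        np.fill_diagonal(r, 1.0)
        mat = ReactionCoexpressionMatrix(reactions=reactions, matrix=r, condition="t")
        cl = cluster_reactions(mat, k=2)
        first = {cl.assignment[x] for x in reactions[:10]}
        second = {cl.assignment[x] for x in reactions[10:]}
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_k_equals_n_gives_singletons(self):
        reactions = list("ABCD")
        r = np.eye(4) * 0.5 + 0.5
        mat = ReactionCoexpressionMatrix(reactions=reactions, matrix=r, condition="t")
        cl = cluster_reactions(mat, k=4)
        assert cl.k == 4
        assert sorted(cl.assignment.values()) == [1, 2, 3, 4]

    def test_invalid_k_rejected(self):
        mat = ReactionCoexpressionMatrix(
            reactions=["A", "B"], matrix=np.eye(2), condition="t"
        )
        for k in (0, 3):
            with pytest.raises(ValueError):
                cluster_reactions(mat, k=k)

    def test_input_order_invariance(self, study, corr_ref):
        rmap = study.reaction_map
        shuffled = ReactionEnzymeMap(
            enzymes=dict(reversed(list(rmap.enzymes.items()))),
            subsystem=rmap.subsystem,
        )
        m1 = reaction_coexpression_matrix(rmap, corr_ref)
        m2 = reaction_coexpression_matrix(shuffled, corr_ref)
        c1 = cluster_reactions(m1, k=15)
        c2 = cluster_reactions(m2, k=15)
        assert c1.assignment == c2.assignment


class TestDifferentialClusters:
    def test_identical_conditions_give_zero_delta(self, study, corr_ref):
        mat = reaction_coexpression_matrix(study.reaction_map, corr_ref)
        cl = cluster_reactions(mat, k=10)
        diff = differential_cluster_scores(cl, mat, mat)
        defined = diff["delta"].dropna()
        assert np.allclose(defined, 0.0)

    def test_ceil_flag_rule(self, study, corr_ref, corr_disease):
        mat_ref = reaction_coexpression_matrix(study.reaction_map, corr_ref)
        mat_dis = reaction_coexpression_matrix(study.reaction_map, corr_disease)
        cl = cluster_reactions(mat_ref, k=20)
        for q, expected in ((0.01, 1), (0.1, 2), (0.25, 5)):
            diff = differential_cluster_scores(cl, mat_ref, mat_dis, q=q)
            assert diff["flagged"].sum() == expected

    def test_planted_deregulated_cluster_has_max_delta(
        self, study, corr_ref, corr_disease
    ):
        truth = study.truth
        rmap = study.reaction_map
        mat_ref = reaction_coexpression_matrix(rmap, corr_ref)
        mat_dis = reaction_coexpression_matrix(rmap, corr_disease)
        cl = cluster_reactions(mat_ref, k=20)
        diff = differential_cluster_scores(cl, mat_ref, mat_dis, q=0.01)
        flagged = set(diff.loc[diff["flagged"], "cluster"])
        planted = [
            r for r, s in rmap.subsystem.items()
            if s == truth.planted_subsystem and r in cl.assignment
        ]
        in_flagged = sum(1 for r in planted if cl.assignment[r] in flagged)
        assert in_flagged / len(planted) > 0.5

    def test_combined_flags(self):
        t1 = pd.DataFrame({"cluster": [1, 2, 3], "flagged": [True, False, False]})
        t2 = pd.DataFrame({"cluster": [1, 2, 3], "flagged": [False, True, False]})
        dis = pd.DataFrame({"cluster": [1, 2, 3], "flagged": [True, True, False]})
        combined = combine_deregulation_flags({"a": t1, "b": t2}, dis)
        both = set(combined.loc[combined["both"], "cluster"])
        assert both == {1, 2}


class TestClusterTfEnrichment:
    def _toy(self):
        rmap = ReactionEnzymeMap(
            enzymes={
                "R1": ("a", "b"),
                "R2": ("b", "c"),
                "R3": ("d", "e"),
                "R4": ("e", "f"),
            },
            subsystem={r: "S" for r in ("R1", "R2", "R3", "R4")},
        )
        from conet.rxncluster import ReactionClustering

        cl = ReactionClustering(
            assignment={"R1": 1, "R2": 1, "R3": 2, "R4": 2}, k=2
        )
        return rmap, cl

    def test_saturated_tf_never_significant(self):
        rmap, cl = self._toy()
        rn = PhysicalNetwork(
            kind="regulatory", edges=[("TF1", g) for g in "abcdef"]
        )
        res = cluster_tf_enrichment(cl, rmap, rn)
        assert np.allclose(res["p"], 1.0)

    def test_cluster_specific_tf_matches_oracle(self):
        rmap, cl = self._toy()
        rn = PhysicalNetwork(
            kind="regulatory", edges=[("TF1", "a"), ("TF1", "b"), ("TF1", "c")]
        )
        res = cluster_tf_enrichment(cl, rmap, rn).set_index("cluster")
        # universe 6 genes, term 3, query (cluster 1) = {a,b,c}, overlap 3:
        # p = C(3,3)*C(3,0)/C(6,3) = 1/20
        assert res.loc[1, "p"] == pytest.approx(1 / 20, abs=1e-12)

    def test_no_tfs_yields_empty(self):
        rmap, cl = self._toy()
        rn = PhysicalNetwork(kind="regulatory", edges=[("TF1", "zz")])
        res = cluster_tf_enrichment(cl, rmap, rn)
        assert res.empty or not res["significant"].any()


class TestHighlyRegulatedClusters:
    def test_top_scoring_enrichment_selected(self):
        """Cluster enriched in the #1 and #2 TFs of 100 clears the KS gate."""
        importance = pd.DataFrame(
            {
                "tf": [f"TF{i:03d}" for i in range(100)],
                "score": np.linspace(1.0, 0.0, 100),
            }
        )
        enrichment = pd.DataFrame(
            {
                "cluster": [1, 1],
                "tf": ["TF000", "TF001"],
                "significant": [True, True],
            }
        )
        res = select_highly_regulated_clusters(enrichment, importance, alpha=0.25)
        assert bool(res.loc[res["cluster"] == 1, "selected"].iloc[0])
        expected = ks_2samp(
            np.array([1.0, 1.0 - 1 / 99]),
            importance["score"].to_numpy(),
            alternative="less",
        ).pvalue
        assert res.loc[res["cluster"] == 1, "ks_p"].iloc[0] == pytest.approx(expected)

    def test_uniform_enrichment_selection_calibrated(self, rng):
        """Enriched TFs drawn uniformly: selection rate tracks alpha = 0.25."""
        importance = pd.DataFrame(
            {
                "tf": [f"TF{i:03d}" for i in range(60)],
                "score": rng.normal(size=60),
            }
        )
        hits = 0
        n_rep = 400
        for rep in range(n_rep):
            chosen = rng.choice(importance["tf"], size=5, replace=False)
            enrichment = pd.DataFrame(
                {"cluster": 1, "tf": chosen, "significant": True}
            )
            res = select_highly_regulated_clusters(
                enrichment, importance, alpha=0.25
            )
            hits += int(res["selected"].iloc[0])
        rate = hits / n_rep
        assert 0.10 <= rate <= 0.40  # generous binomial band around 0.25

    def test_no_enriched_tfs_not_selected(self):
        importance = pd.DataFrame({"tf": ["TF1", "TF2"], "score": [1.0, 0.5]})
        enrichment = pd.DataFrame(
            {"cluster": [1], "tf": ["TF1"], "significant": [False]}
        )
        res = select_highly_regulated_clusters(enrichment, importance)
        assert not res["selected"].any()

    def test_regulated_subsystem_cluster_selected_end_to_end(
        self, study, corr_ref
    ):
        from conet import build_feature_matrix, fit_importance

        rmap = study.reaction_map
        mat_ref = reaction_coexpression_matrix(rmap, corr_ref)
        cl = cluster_reactions(mat_ref, k=20)
        enr = cluster_tf_enrichment(cl, rmap, study.regulatory)
        net = build_network(corr_ref, q=0.01)
        imp = fit_importance(
            build_feature_matrix(net, study.regulatory), n_trees=200, seed=0
        )
        res = select_highly_regulated_clusters(enr, imp)
        selected = set(res.loc[res["selected"], "cluster"])
        regulated = {
            cl.assignment[r]
            for r, s in rmap.subsystem.items()
            if s == study.truth.regulated_subsystem and r in cl.assignment
        }
        assert selected & regulated


class TestSubsystemEnrichment:
    def test_single_subsystem_p_one(self, study, corr_ref):
        rmap = ReactionEnzymeMap(
            enzymes={f"R{i}": (f"e{i}",) for i in range(6)},
            subsystem={f"R{i}": "only" for i in range(6)},
        )
        genes = [f"e{i}" for i in range(6)]
        table = corr_from_pairs(genes, {})
        mat = reaction_coexpression_matrix(rmap, table)
        cl = cluster_reactions(mat, k=2)
        res = subsystem_enrichment(cl, rmap)
        assert np.allclose(res["p"], 1.0)

    def test_planted_subsystem_concentrates_in_one_cluster(self, study, corr_ref):
        rmap = study.reaction_map
        mat = reaction_coexpression_matrix(rmap, corr_ref)
        cl = cluster_reactions(mat, k=20)
        res = subsystem_enrichment(cl, rmap)
        planted = res[res["subsystem"] == study.truth.planted_subsystem]
        best = planted.nsmallest(1, "p").iloc[0]
        assert best["p"] < 1e-6
        # and the best cluster for the planted subsystem holds most of it
        members = cl.members(best["cluster"])
        frac = np.mean(
            [rmap.subsystem[r] == study.truth.planted_subsystem for r in members]
        )
        assert best["overlap"] / best["term_size"] > 0.5 or frac > 0.5
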