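"""Chronograms, preset hypothesis trees, BM ancestral states, Kmult."""

import numpy as np
import pytest
from scipy.optimize import minimize

from paleoshape import (
    Chronogram,
    BrownianAncestralReconstruction,
    bm_ancestral_states,
    build_hypothesis,
    kmult,
    phylo_covariance,
    read_newick,
    write_newick,
)
from paleoshape.phylo import TreeError

TREE5 = "(((A:1,B:2):1,C:3):1,(D:2,E:1):2);"
TREE5_VALUES = np.array([1.0, 3.0, -2.0, 0.5, 2.5])
# independent R oracle (phytools): fastAnc point estimates and REML 95% CIs,
# and phylosig's univariate K, for TREE5 with TREE5_VALUES
PHYTOOLS_ANC = {
    "n0": (1.002513, (-1.591020, 3.596046)),
    "n1": (0.690955, (-1.496252, 2.878161)),
    "n2": (1.276382, (-0.476694, 3.029458)),
    "n6": (1.625628, (-0.192398, 3.443655)),
}
PHYTOOLS_K = 0.8479593


class TestChronogram:
    def test_three_tip_parse_and_ages(self):
        t = Chronogram.from_newick("((A:1,B:1):1,C:2);")
        assert t.n_tips == 3
        assert t.root_age == 2.0
        assert t.tip_ages() == {"A": 0.0, "B": 0.0, "C": 0.0}
        c = t.covariance(["A", "B", "C"])
        assert np.allclose(c, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_newick_roundtrip(self, tmp_path):
        t = build_hypothesis("h1")
        p = tmp_path / "t.nwk"
        write_newick(t, p)
        t2 = read_newick(p)
        assert t2.tip_labels == t.tip_labels
        assert np.allclose(t2.covariance(t.tip_labels), t.covariance(), atol=1e-9)

    def test_polytomies_rejected_by_default(self):
        with pytest.raises(TreeError):
            Chronogram.from_newick("(A:1,B:1,C:1);")

    def test_missing_branch_lengths_rejected(self):
        with pytest.raises(TreeError):
            Chronogram.from_newick("((A:1,B),C:2);")

    def test_star_tree_unit_branches_gives_identity_covariance(self):
        star = Chronogram.star(["A", "B", "C", "D"])
        assert np.allclose(star.covariance(), np.eye(4))

    def test_drop_tips_collapses_and_keeps_depths(self):
        t = Chronogram.from_newick("(((A:1,B:1):1,C:2):1,D:3);")
        pruned = t.drop_tips(["B"])
        assert sorted(pruned.tip_labels) == ["A", "C", "D"]
        # A's root-to-tip depth is preserved through the collapsed node
        c = pruned.covariance(["A", "C", "D"])
        assert c[0, 0] == pytest.approx(3.0)
        assert c[0, 1] == pytest.approx(1.0)  # MRCA(A, C) depth unchanged


class TestPresets:
    @pytest.mark.parametrize("name,n", [("h1", 29), ("h2", 29), ("h1b", 25), ("h2b", 25)])
    def test_tip_counts(self, name, n):
        assert build_hypothesis(name).n_tips == n

    def test_anchor_node_ages(self):
        h1 = build_hypothesis("h1")
        assert h1.node_age(h1.mrca("EarlyHsapiens", "Neandertal_WestEurope")) == 600.0
        assert h1.node_age(h1.mrca("EarlyHsapiens", "San")) == 305.0
        assert h1.node_age(h1.mrca("Neandertal_Early", "Neandertal_WestEurope")) == 300.0
        assert h1.node_age(h1.mrca("Australia", "NorthAfrica")) == 90.0
        h2 = build_hypothesis("h2")
        assert h2.node_age(h2.mrca("SouthAsia", "NorthAfrica")) == 75.0
        assert h2.node_age(h2.mrca("Australia", "NorthAfrica")) == 75.0

    def test_fossil_tips_use_chronology_midpoints(self):
        ages = build_hypothesis("h1").tip_ages()
        assert ages["EarlyHsapiens"] == 100.0
        assert ages["Neandertal_Early"] == 195.0
        assert ages["Hhabilis"] == 1800.0
        assert all(ages[p] == 0.0 for p in ("San", "NorthAmerica", "EastAsiaJapan"))

    @pytest.mark.parametrize("name", ["h1", "h2", "h1b", "h2b"])
    def test_covariances_positive_definite(self, name):
        np.linalg.cholesky(build_hypothesis(name).covariance())  # must not raise

    def test_b_variants_drop_khoisan_and_pygmies(self):
        labels = build_hypothesis("h1b").tip_labels
        for gone in ("San", "Khoikhoi", "Bayaka", "Mbuti"):
            assert gone not in labels

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="h1"):
            build_hypothesis("h99")


class TestBrownianAncestralStates:
    def test_star_tree_root_is_tip_mean(self):
        star = Chronogram.star(["A", "B", "C"])
        est = bm_ancestral_states(star, np.array([1.0, 2.0, 3.0]))
        assert est["n0"].values[0] == pytest.approx(2.0, abs=1e-12)

    def test_two_tip_gls_closed_form(self):
        t = Chronogram.from_newick("(A:1,B:3);")
        est = bm_ancestral_states(t, np.array([0.0, 4.0]))
        assert est["n0"].values[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_joint_likelihood_maximization(self):
        """Re-rooted GLS equals the joint ML over all internal node states."""
        tree = Chronogram.from_newick(TREE5)
        est = bm_ancestral_states(tree, TREE5_VALUES)
        edges = tree.edges()
        tips = dict(zip(tree.tip_labels, TREE5_VALUES))
        internal = tree.internal_node_ids

        def neg_loglik_profile(x):  # sigma profiles out; minimize the quadratic form
            vals = {**dict(zip(internal, x)), **tips}
            return sum((vals[c] - vals[p]) ** 2 / bl for p, c, bl in edges)

        res = minimize(neg_loglik_profile, np.zeros(len(internal)), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 50000})
        for nid, x in zip(internal, res.x):
            assert est[nid].values[0] == pytest.approx(x, abs=1e-4)

    def test_matches_phytools_fastanc_estimates_and_reml_ci(self):
        tree = Chronogram.from_newick(TREE5)
        est = bm_ancestral_states(tree, TREE5_VALUES, method="REML")
        for nid, (val, (lo, hi)) in PHYTOOLS_ANC.items():
            assert est[nid].values[0] == pytest.approx(val, abs=1e-6)
            assert est[nid].ci95[0][0] == pytest.approx(lo, abs=1e-5)
            assert est[nid].ci95[0][1] == pytest.approx(hi, abs=1e-5)

    def test_estimates_invariant_under_branch_rescaling(self):
        tree = Chronogram.from_newick(TREE5)
        scaled = Chronogram.from_newick(
            TREE5.replace(":1", ":10").replace(":2", ":20").replace(":3", ":30")
        )
        e1 = bm_ancestral_states(tree, TREE5_VALUES)
        e2 = bm_ancestral_states(scaled, TREE5_VALUES)
        for nid in e1:
            assert e1[nid].values[0] == pytest.approx(e2[nid].values[0], abs=1e-10)
            # rate per unit branch length scales inversely; the node variance
            # (their product with the structural factor) is invariant
            assert e1[nid].sigma2[0] == pytest.approx(10 * e2[nid].sigma2[0], rel=1e-10)
            assert e1[nid].variances[0] == pytest.approx(e2[nid].variances[0], rel=1e-10)

    def test_root_estimate_within_tip_convex_hull(self, rng):
        tree = build_hypothesis("h1")
        y = rng.normal(size=(29, 4))
        est = bm_ancestral_states(tree, y)
        root = est[tree.root_id].values
        assert np.all(root >= y.min(axis=0) - 1e-12)
        assert np.all(root <= y.max(axis=0) + 1e-12)

    def test_estimator_interface(self):
        tree = Chronogram.from_newick(TREE5)
        model = BrownianAncestralReconstruction(tree).fit(TREE5_VALUES[:, None])
        assert model.root_.values[0] == pytest.approx(1.002513, abs=1e-6)
        assert model.sigma2_.shape == (1,)
        assert model.get_params()["method"] == "ML"

    def test_input_validation(self):
        tree = Chronogram.from_newick(TREE5)
        with pytest.raises(ValueError):
            bm_ancestral_states(tree, np.zeros((4, 1)))  # wrong tip count
        with pytest.raises(ValueError):
            bm_ancestral_states(tree, np.zeros((5, 0)))  # no traits


class TestKmult:
    def test_star_tree_unit_branches_gives_k_of_one(self, rng):
        star = Chronogram.star([f"t{i}" for i in range(8)])
        y = rng.normal(size=(8, 3))
        r = kmult(star, y, n_perm=19, seed=0)
        assert r.K == pytest.approx(1.0, abs=1e-12)

    def test_matches_phytools_phylosig(self):
        tree = Chronogram.from_newick(TREE5)
        r = kmult(tree, TREE5_VALUES, n_perm=9, seed=1)
        assert r.K == pytest.approx(PHYTOOLS_K, abs=1e-6)

    def test_deterministic_given_seed(self, rng):
        tree = build_hypothesis("h1")
        y = rng.normal(size=(29, 2))
        r1 = kmult(tree, y, n_perm=99, seed=77)
        r2 = kmult(tree, y, n_perm=99, seed=77)
        assert (r1.K, r1.p_value) == (r2.K, r2.p_value)

    def test_seed_mandatory_and_degenerate_data_rejected(self):
        tree = Chronogram.from_newick(TREE5)
        with pytest.raises(ValueError):
            kmult(tree, TREE5_VALUES)
        with pytest.raises(ValueError):
            kmult(tree, np.ones((5, 2)), seed=1)


def test_phylo_covariance_wrapper_matches_method():
    t = Chronogram.from_newick(TREE5)
    assert np.array_equal(phylo_covariance(t), t.covariance())
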