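"""GLS ancestral reconstruction under Brownian motion: closed-form and
matrix oracles, rate estimation, and along-branch envelope interpolation."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import paleoniche as pn
from paleoniche.phylo import (BeyondBranchError, MissingTraitError,
                              NicheReconstruction, _tip_covariance)
from paleoniche.synthetic import simulate_yule_tree


def brownian_covariance_oracle(ptree):
    """Shared-path-length covariance via explicit per-pair MRCA search."""
    tips = ptree.tips
    n = len(tips)

    def ancestors(nd):
        out = []
        while nd is not None:
            out.append(nd)
            nd = nd.parent_node
        return out

    C = np.zeros((n, n))
    for i in range(n):
        ai = ancestors(tips[i])
        for j in range(i, n):
            aj = set(ancestors(tips[j]))
            mrca = next(a for a in ai if a in aj)
            C[i, j] = C[j, i] = ptree.root_age - ptree.ages[mrca]
    return C


def gls_node_oracle(ptree, trait):
    """Conditional-mean oracle: anc = mu + C_at Ctt^-1 (x - mu)."""
    x = np.array([trait[l] for l in ptree.tip_labels])
    Ctt = brownian_covariance_oracle(ptree)
    Cinv = np.linalg.inv(Ctt)
    one = np.ones_like(x)
    mu = (one @ Cinv @ x) / (one @ Cinv @ one)

    def ancestors(nd):
        out = []
        while nd is not None:
            out.append(nd)
            nd = nd.parent_node
        return out

    est = {}
    for nd in ptree.internal:
        a_anc = ancestors(nd)
        cov = np.zeros(len(ptree.tips))
        for j, t in enumerate(ptree.tips):
            tj = set(ancestors(t))
            mrca = next(a for a in a_anc if a in tj)
            cov[j] = ptree.root_age - ptree.ages[mrca]
        est[ptree.node_label(nd)] = mu + cov @ Cinv @ (x - mu)
    return est, mu


class TestAncestralEstimate:
    def test_two_tip_symmetry(self):
        tree = pn.PhyloTree.from_newick("(a:1.0,b:1.0);")
        est = pn.ancestral_estimate(tree, {"a": 0.0, "b": 10.0})
        assert est["estimate"].iloc[0] == pytest.approx(5.0)

    def test_star_tree_inverse_length_weighted_mean(self):
        tree = pn.PhyloTree.from_newick("(a:1.0,b:2.0,c:4.0);")
        vals = {"a": 1.0, "b": 5.0, "c": 9.0}
        est = pn.ancestral_estimate(tree, vals)
        w = np.array([1.0, 0.5, 0.25])
        expect = (w * [1.0, 5.0, 9.0]).sum() / w.sum()
        assert est["estimate"].iloc[0] == pytest.approx(expect)

    def test_missing_tip_rejected(self):
        tree = pn.PhyloTree.from_newick("(a:1.0,b:1.0);")
        with pytest.raises(MissingTraitError):
            pn.ancestral_estimate(tree, {"a": 0.0})

    def test_matches_covariance_matrix_oracle(self):
        """100 random 4-6 tip trees: node estimates equal the explicit
        Brownian-covariance conditional means within 1e-8."""
        rng = np.random.default_rng(7)
        for k in range(100):
            n = int(rng.integers(4, 7))
            tree = simulate_yule_tree(n, 1.0, rng, min_terminal_my=0.0)
            trait = {l: float(v) for l, v in
                     zip(tree.tip_labels, rng.normal(scale=3.0, size=n))}
            est = pn.ancestral_estimate(tree, trait, with_se=False)
            oracle, mu = gls_node_oracle(tree, trait)
            root_lbl = tree.node_label(tree.nodes[0])
            assert est.at[root_lbl, "estimate"] == pytest.approx(mu,
                                                                 abs=1e-8)
            for lbl, v in oracle.items():
                assert est.at[lbl, "estimate"] == pytest.approx(v, abs=1e-8)

    def test_invariant_to_tip_ordering(self):
        a = pn.PhyloTree.from_newick("((a:1,b:1):1,c:2);")
        b = pn.PhyloTree.from_newick("(c:2,(b:1,a:1):1);")
        trait = {"a": 1.0, "b": 4.0, "c": -2.0}
        ea = pn.ancestral_estimate(a, trait)["estimate"]
        eb = pn.ancestral_estimate(b, trait)["estimate"]
        np.testing.assert_allclose(np.sort(ea), np.sort(eb))

    def test_matches_r_phytools_fastanc(self, tmp_path):
        """Independent cross-check against the GLS re-rooting ancestral
        state estimator in R (phytools::fastAnc)."""
        newick = "((a:1.0,b:1.5):0.7,(c:0.9,d:2.0):1.1);"
        trait = {"a": 0.3, "b": 2.7, "c": -1.2, "d": 4.4}
        script = textwrap.dedent(f"""
            suppressMessages(library(phytools))
            tree <- ape::read.tree(text="{newick}")
            x <- c(a=0.3, b=2.7, c=-1.2, d=4.4)
            a <- fastAnc(tree, x)
            cat(sprintf("%.10f\\n", as.numeric(a)))
        """)
        r = subprocess.run(["Rscript", "-e", script], capture_output=True,
                           text=True, timeout=300)
        assert r.returncode == 0, r.stderr
        r_vals = np.array([float(v) for v in r.stdout.split()])
        tree = pn.PhyloTree.from_newick(newick)
        est = pn.ancestral_estimate(tree, trait, with_se=False)
        # fastAnc reports nodes in cladewise order: root, then each clade
        np.testing.assert_allclose(np.sort(est["estimate"]),
                                   np.sort(r_vals), atol=1e-6)


class TestBrownianRate:
    def test_constant_trait_rate_zero(self):
        tree = pn.PhyloTree.from_newick("(a:1,(b:0.5,c:0.5):0.5);")
        with pytest.warns(UserWarning):
            assert pn.bm_rate_ml(tree, {"a": 2.0, "b": 2.0, "c": 2.0}) == 0.0

    def test_doubling_branch_lengths_halves_rate(self):
        t1 = pn.PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = pn.PhyloTree.from_newick("((a:2,b:2):2,(c:2,d:2):2);")
        trait = {"a": 0.0, "b": 3.0, "c": -1.0, "d": 2.0}
        assert pn.bm_rate_ml(t2, trait) == pytest.approx(
            pn.bm_rate_ml(t1, trait) / 2)

    def test_rate_and_root_recovery_on_simulated_data(self):
        """200 replicates on a 50-tip tree: the mean ML rate and root
        estimates recover the simulation truth within 3 MC standard
        errors (allowing the known ML downward bias factor (n-1)/n)."""
        from paleoniche.synthetic import _simulate_bm_on_tree
        rng = np.random.default_rng(17)
        tree = simulate_yule_tree(50, 1.0, rng)
        rates, roots = [], []
        for _ in range(200):
            trait = _simulate_bm_on_tree(tree, 5.0, 1.0, rng)
            rates.append(pn.bm_rate_ml(tree, trait))
            est = pn.ancestral_estimate(tree, trait, with_se=False)
            roots.append(est["estimate"].iloc[0])
        rates, roots = np.array(rates), np.array(roots)
        expect_rate = 1.0 * (50 - 1) / 50
        assert abs(rates.mean() - expect_rate) \
            < 3 * rates.std(ddof=1) / np.sqrt(200)
        assert abs(roots.mean() - 5.0) < 3 * roots.std(ddof=1) / np.sqrt(200)


class TestEnvelopeAtTime:
    @pytest.fixture(scope="class")
    def recon(self):
        tree = pn.PhyloTree.from_newick("((a:1.0,b:1.0):1.0,c:2.0);")
        envs = {
            "a": pn.NicheEnvelope(("BIO1",), [0.0], [10.0]),
            "b": pn.NicheEnvelope(("BIO1",), [4.0], [20.0]),
            "c": pn.NicheEnvelope(("BIO1",), [-5.0], [5.0]),
        }
        return NicheReconstruction(tree, pn.envelopes_to_traits(envs))

    def test_t0_returns_tip_envelope(self, recon):
        env = recon.envelope_at_time("a", 0.0)
        assert env.bound("BIO1") == (0.0, 10.0)

    def test_parent_age_returns_node_estimate(self, recon):
        env = recon.envelope_at_time("a", 1000.0)   # parent at 1 My
        node = recon.ptree.node_label(recon.ptree.tip("a").parent_node)
        assert env.bound("BIO1")[0] == pytest.approx(
            recon.node_estimates.at[node, "BIO1_lower"])
        assert env.bound("BIO1")[1] == pytest.approx(
            recon.node_estimates.at[node, "BIO1_upper"])

    def test_half_branch_is_midpoint(self, recon):
        e0 = recon.envelope_at_time("a", 0.0)
        e1 = recon.envelope_at_time("a", 1000.0)
        eh = recon.envelope_at_time("a", 500.0)
        np.testing.assert_allclose(eh.lower, 0.5 * (e0.lower + e1.lower))
        np.testing.assert_allclose(eh.upper, 0.5 * (e0.upper + e1.upper))

    def test_provenance_records_time(self, recon):
        assert recon.envelope_at_time("a", 8.0).provenance \
            == "time-adjusted at 8 ka"

    def test_beyond_branch_rejected(self, recon):
        with pytest.raises(BeyondBranchError):
            recon.envelope_at_time("a", 1500.0)

    def test_bound_crossing_collapses_to_midpoint(self):
        """GLS node estimates average valid envelopes columnwise, so
        crossings cannot arise from the reconstruction itself; the repair
        path is exercised by overriding a node estimate directly (as a
        corrupted reconstruction report would)."""
        tree = pn.PhyloTree.from_newick("(a:1.0,b:1.0);")
        traits = pd.DataFrame(
            {"BIO1_lower": [0.0, 30.0], "BIO1_upper": [1.0, 40.0]},
            index=["a", "b"])
        recon = NicheReconstruction(tree, traits)
        node = recon.ptree.node_label(recon.ptree.tip("a").parent_node)
        recon.node_estimates.at[node, "BIO1_lower"] = 50.0
        recon.node_estimates.at[node, "BIO1_upper"] = -50.0
        with pytest.warns(UserWarning, match="bound crossing"):
            env = recon.envelope_at_time("a", 900.0)
        assert env.lower[0] == env.upper[0]

    def test_zero_rate_world_envelopes_time_constant(self, small_results):
        """With no niche evolution the time-adjusted envelope equals the
        tip envelope at every slice."""
        recon = small_results.reconstruction
        sp = next(iter(small_results.envelopes))
        tip = small_results.envelopes[sp]
        for t in (0.0, 40.0, 76.0):
            env = recon.envelope_at_time(sp, t)
            np.testing.assert_allclose(env.lower, tip.lower, atol=1e-9)
            np.testing.assert_allclose(env.upper, tip.upper, atol=1e-9)


def test_tip_covariance_matches_oracle():
    rng = np.random.default_rng(3)
    for _ in range(20):
        tree = simulate_yule_tree(int(rng.integers(3, 8)), 1.0, rng,
                                  min_terminal_my=0.0)
        np.testing.assert_allclose(_tip_covariance(tree),
                                   brownian_covariance_oracle(tree),
                                   atol=1e-10)
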