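"""Codon site models: rate matrices, pruning, M1a/M2a fits, posteriors."""

import math

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chi2

from mkconcord.counting import CodonAlignment
from mkconcord.sitemodel import (
    CodonModel,
    PhyloTree,
    _structure,
    build_rate_matrix,
    f1x4_frequencies,
    fit_site_models,
    lrt_pvalue,
    pruning_loglik,
    site_posteriors,
    transition_probability,
    uniform_frequencies,
)

CODONS, INDEX, DIFF, TS, SYNM = _structure(1)
PI = uniform_frequencies()


class TestRateMatrix:
    def test_rows_sum_to_zero_and_mean_rate_is_one(self):
        q = build_rate_matrix(CodonModel(2.0, 0.5, PI))
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        assert -(PI * np.diag(q)).sum() == pytest.approx(1.0)

    def test_omega_zero_silences_nonsynonymous_entries(self):
        q = build_rate_matrix(CodonModel(2.0, 0.0, PI), scale=False)
        assert np.all(q[DIFF & ~SYNM] == 0.0)
        assert np.all(q[DIFF & SYNM] > 0.0)

    def test_multi_nucleotide_changes_forbidden(self):
        q = build_rate_matrix(CodonModel(1.0, 1.0, PI))
        off_diag = ~np.eye(len(PI), dtype=bool)
        assert np.all(q[off_diag & ~DIFF] == 0.0)

    def test_detailed_balance(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(len(PI)))
        q = build_rate_matrix(CodonModel(3.0, 0.4, pi))
        flux = pi[:, None] * q
        assert np.allclose(flux, flux.T, atol=1e-12)

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0])
    def test_transition_matrix_is_stochastic_and_matches_expm(self, t):
        model = CodonModel(2.5, 1.7, PI)
        p = transition_probability(model, t)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(p, expm(build_rate_matrix(model) * t), atol=1e-10)

    def test_nonpositive_frequencies_rejected(self):
        bad = PI.copy()
        bad[0] = 0.0
        with pytest.raises(ValueError):
            CodonModel(2.0, 1.0, bad)


def _enumeration_loglik_star(tree_lengths, aln, model):
    """Brute-force lnL for a star tree: sum over the single internal state."""
    q = build_rate_matrix(model)
    mats = [expm(q * t) for t in tree_lengths]
    pi = model.pi
    lnl = 0.0
    for site in range(aln.n_codons):
        obs = [INDEX[s[3 * site : 3 * site + 3]] for s in aln.sequences]
        lik = sum(
            pi[r] * np.prod([m[r, o] for m, o in zip(mats, obs)])
            for r in range(len(pi))
        )
        lnl += math.log(lik)
    return lnl


class TestPruning:
    def test_star_tree_matches_enumeration(self):
        aln = CodonAlignment(
            names=["a", "b", "c"],
            sequences=["ATGTTTAAA", "ATGTTCAAG", "ATATTTAAA"],
        )
        model = CodonModel(2.0, 0.6, PI)
        tree = PhyloTree.from_newick("(a:0.1,b:0.2,c:0.15);")
        lnl = pruning_loglik(tree, aln, [(1.0, model)])
        oracle = _enumeration_loglik_star([0.1, 0.2, 0.15], aln, model)
        assert lnl == pytest.approx(oracle, rel=1e-10)

    def test_four_taxon_matches_enumeration(self):
        aln = CodonAlignment(
            names=["a", "b", "c", "d"],
            sequences=["ATGTTTAAA", "ATGTTCAAG", "ATATTTAAA", "ATGCTTAAA"],
        )
        model = CodonModel(2.0, 0.5, PI)
        tree = PhyloTree.from_newick(
            "((a:0.1,b:0.2):0.05,(c:0.15,d:0.1):0.07);", deroot=False
        )
        lnl = pruning_loglik(tree, aln, [(1.0, model)])
        q = build_rate_matrix(model)
        p = {k: expm(q * t) for k, t in
             [("a", 0.1), ("b", 0.2), ("n1", 0.05), ("c", 0.15), ("d", 0.1), ("n2", 0.07)]}
        oracle = 0.0
        for site in range(3):
            obs = {n: INDEX[aln[n][3 * site : 3 * site + 3]] for n in "abcd"}
            # contract over the two internal states and the root explicitly
            inner1 = p["a"][:, obs["a"]] * p["b"][:, obs["b"]]  # (61,)
            inner2 = p["c"][:, obs["c"]] * p["d"][:, obs["d"]]
            lik = PI @ ((p["n1"] @ inner1) * (p["n2"] @ inner2))
            oracle += math.log(lik)
        assert lnl == pytest.approx(oracle, rel=1e-10)

    def test_zero_length_star_identical_sequences_closed_form(self):
        aln = CodonAlignment(names=["a", "b", "c"], sequences=["ATGTTT"] * 3)
        model = CodonModel(2.0, 1.0, PI)
        tree = PhyloTree.from_newick("(a:0.0,b:0.0,c:0.0);")
        lnl = pruning_loglik(tree, aln, [(1.0, model)])
        expected = sum(math.log(PI[INDEX[c]]) for c in ("ATG", "TTT"))
        assert lnl == pytest.approx(expected, rel=1e-10)

    def test_duplicated_class_is_degenerate_mixture(self):
        aln = CodonAlignment(
            names=["a", "b", "c"], sequences=["ATGTTTAAA", "ATGTTCAAG", "ATATTTAAA"]
        )
        model = CodonModel(2.0, 0.6, PI)
        tree = PhyloTree.from_newick("(a:0.1,b:0.2,c:0.15);")
        single = pruning_loglik(tree, aln, [(1.0, model)])
        double = pruning_loglik(tree, aln, [(0.5, model), (0.5, model)])
        assert single == pytest.approx(double, rel=1e-12)

    def test_leaf_order_irrelevant(self):
        aln = CodonAlignment(
            names=["c", "a", "b"],
            sequences=["ATATTTAAA", "ATGTTTAAA", "ATGTTCAAG"],
        )
        model = CodonModel(2.0, 0.6, PI)
        tree = PhyloTree.from_newick("(a:0.1,b:0.2,c:0.15);")
        aln2 = aln.subset(["a", "b", "c"])
        assert pruning_loglik(tree, aln, [(1.0, model)]) == pytest.approx(
            pruning_loglik(tree, aln2, [(1.0, model)]), rel=1e-12
        )

    def test_leaf_name_mismatch_rejected(self):
        aln = CodonAlignment(names=["a", "b"], sequences=["ATG", "ATG"])
        tree = PhyloTree.from_newick("(a:0.1,x:0.2);")
        with pytest.raises(ValueError):
            pruning_loglik(tree, aln, [(1.0, CodonModel(2.0, 1.0, PI))])


class TestLRT:
    def test_zero_statistic_gives_p_one(self):
        assert lrt_pvalue(-100.0, -100.0) == 1.0

    @pytest.mark.parametrize("stat,p", [(5.991, 0.05), (9.21, 0.01)])
    def test_chi_square_quantiles(self, stat, p):
        assert lrt_pvalue(0.0, stat / 2.0) == pytest.approx(p, abs=5e-4)
        assert lrt_pvalue(0.0, stat / 2.0) == pytest.approx(chi2.sf(stat, 2), rel=1e-12)

    def test_worse_alternative_signals_optimizer_bug(self):
        with pytest.raises(ValueError):
            lrt_pvalue(-100.0, -101.0)


@pytest.fixture(scope="module")
def m2a_true_fit():
    """Fit on data simulated with a genuine positively selected class."""
    from mkconcord.simulate import SimulationConfig, simulate_divergence

    cfg = SimulationConfig(
        tree="((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1);",
        n_genes=1, n_codons=500, adaptive_fraction=1.0,
        adaptive_site_fraction=0.1, q=0.4, s1=0.0025, focal="a",
    )
    gene = simulate_divergence(cfg, np.random.default_rng(42))[0]
    tree = PhyloTree.from_newick(cfg.tree)
    fit = fit_site_models(tree, gene.alignment, seed=0, n_restarts=1)
    return cfg, gene, tree, fit


class TestFit:
    def test_selected_class_recovered(self, m2a_true_fit):
        cfg, gene, tree, fit = m2a_true_fit
        true_a2 = (gene.site_classes == 2).sum()
        assert fit.p_value < 0.01
        assert fit.m2a["omega2"] > 1.5
        assert fit.a2 == pytest.approx(true_a2, rel=0.5)

    def test_m2a_never_below_m1a(self, m2a_true_fit):
        *_, fit = m2a_true_fit
        assert fit.lnl_m2a >= fit.lnl_m1a - 1e-6

    def test_m2a_constrained_to_boundary_reproduces_m1a(self, m2a_true_fit):
        cfg, gene, tree, fit = m2a_true_fit
        pi = f1x4_frequencies(gene.alignment)
        kappa = fit.m1a["kappa"]
        tree_fit = tree.with_branch_lengths(fit.m1a["branch_lengths"])
        classes = [
            (fit.m1a["p0"], CodonModel(kappa, fit.m1a["omega0"], pi)),
            (fit.m1a["p1"] - 1e-9, CodonModel(kappa, 1.0, pi)),
            (1e-9, CodonModel(kappa, 2.0, pi)),
        ]
        lnl = pruning_loglik(tree_fit, gene.alignment, classes)
        assert lnl == pytest.approx(fit.lnl_m1a, abs=1e-3)

    def test_posteriors_flag_truly_selected_sites(self, m2a_true_fit):
        cfg, gene, tree, fit = m2a_true_fit
        post = site_posteriors(fit, tree, gene.alignment)
        assert post.shape == (gene.alignment.n_codons,)
        assert np.all((post >= 0) & (post <= 1))
        selected = post[gene.site_classes == 2]
        background = post[gene.site_classes != 2]
        assert selected.mean() > background.mean() + 0.2
        assert selected.max() > 0.9
        assert fit.a2prime <= gene.alignment.n_codons

    def test_null_data_keeps_selected_class_empty(self):
        from mkconcord.simulate import SimulationConfig, simulate_divergence

        cfg = SimulationConfig(
            tree="(a:0.2,b:0.2,c:0.2);", n_genes=1, n_codons=200,
            adaptive_fraction=0.0, q=0.3, focal="a",
        )
        gene = simulate_divergence(cfg, np.random.default_rng(7))[0]
        tree = PhyloTree.from_newick(cfg.tree)
        fit = fit_site_models(tree, gene.alignment, seed=0, n_restarts=0)
        assert fit.p_value > 0.05
        assert fit.a2 < 0.1 * gene.alignment.n_codons

    def test_too_few_sequences_rejected(self):
        aln = CodonAlignment(names=["a", "b"], sequences=["ATG", "ATG"])
        tree = PhyloTree.from_newick("(a:0.1,b:0.1);")
        with pytest.raises(ValueError, match="at least 3"):
            fit_site_models(tree, aln)
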