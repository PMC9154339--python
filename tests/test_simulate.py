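"""Synthetic-data generator: SFS sampling, divergence classes, scenarios."""

import math

import numpy as np
import pytest
from scipy import stats

from mkconcord.counting import ka_ks
from mkconcord.mk import mk_fisher
from mkconcord.polymorphism import SYN, pa_ps
from mkconcord.simulate import (
    VARIABLE_SELECTION_COMPOSITION,
    SFSSampler,
    SimulationConfig,
    fluctuating_q_experiment,
    scenario_concordance_experiment,
    simulate_divergence,
    simulate_polymorphism,
)


def wright_fisher_snapshots(
    N, s, influx, generations, burn, spacing, rng
):
    """Forward haploid Wright-Fisher oracle: recurrent mutation, selection s.

    Returns pooled mutant frequencies from snapshots taken every ``spacing``
    generations after ``burn``.
    """
    counts = np.zeros(0, dtype=int)
    pooled = []
    for gen in range(generations):
        x = counts / N
        x_sel = x * (1 + s) / (1 + x * s)
        counts = rng.binomial(N, x_sel)
        counts = counts[(counts > 0) & (counts < N)]
        n_new = rng.poisson(influx)
        counts = np.concatenate([counts, np.ones(n_new, dtype=int)])
        if gen >= burn and (gen - burn) % spacing == 0:
            pooled.append(counts.copy())
    return np.concatenate(pooled) / N


class TestSFSSampler:
    def test_neutral_sample_spectrum_is_one_over_k(self):
        # closed-form oracle: E[xi_k] proportional to 1/k for the neutral SFS
        sampler = SFSSampler(0.0, 20)
        rng = np.random.default_rng(0)
        k = sampler.sample(rng, 20_000)
        obs = np.bincount(k, minlength=20)[1:20]
        expected = 1.0 / np.arange(1, 20)
        expected = expected / expected.sum() * obs.sum()
        chi2 = ((obs - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=18)
        assert p > 0.01

    def test_selected_spectrum_skews_to_low_frequency(self):
        neutral, selected = SFSSampler(0.0, 20), SFSSampler(-20.0, 20)
        rng = np.random.default_rng(1)
        assert selected.sample(rng, 5000).mean() < neutral.sample(rng, 5000).mean()

    def test_cutoff_removes_more_deleterious_than_neutral(self):
        neutral, selected = SFSSampler(0.0, 20), SFSSampler(-20.0, 20)
        # surviving fraction above the 0.2 cutoff
        assert (selected.mass_above(0.2) / selected.mass) < (
            neutral.mass_above(0.2) / neutral.mass
        )

    @pytest.mark.parametrize("gamma,s", [(0.0, 0.0), (-5.0, -0.025)])
    def test_matches_wright_fisher_forward_oracle(self, gamma, s):
        # N=100 haploid WF with recurrent mutation vs the PRF sampler
        # snapshots 2N generations apart so the pooled frequencies are
        # effectively independent draws from the stationary distribution;
        # ~1200 sites keeps the test sensitive to shape errors while O(1/N)
        # discreteness of the forward model stays below detection
        N, n = 100, 20
        rng = np.random.default_rng(0)
        freqs = wright_fisher_snapshots(
            N, s, influx=5.0, generations=13_000, burn=1000, spacing=200, rng=rng
        )
        wf_counts = rng.binomial(n, freqs)
        wf_counts = wf_counts[(wf_counts > 0) & (wf_counts < n)][:1200]
        sampler = SFSSampler(gamma, n)
        prf_counts = sampler.sample(rng, len(wf_counts))
        _, p = stats.ks_2samp(wf_counts, prf_counts)
        assert p > 0.01

    def test_sample_size_bounds(self):
        with pytest.raises(ValueError):
            SFSSampler(0.0, 1)


class TestDivergenceSimulation:
    def test_bit_reproducible_given_seed(self):
        cfg = SimulationConfig(n_genes=3, n_codons=50)
        g1 = simulate_divergence(cfg, np.random.default_rng(7))
        g2 = simulate_divergence(cfg, np.random.default_rng(7))
        for a, b in zip(g1, g2):
            assert a.alignment.sequences == b.alignment.sequences
            assert np.array_equal(a.site_classes, b.site_classes)

    def test_class_ratios_converge_to_theory(self):
        # each pure class at 10^5 codons and 4% divergence; the counting
        # estimator is accurate in this regime for omega up to a few
        kwargs = dict(tree="(a:0.02,b:0.02);", n_genes=1, n_codons=100_000, focal="a")
        cases = [
            (dict(adaptive_fraction=0.0, q=0.0), 1.0),  # neutral
            (dict(adaptive_fraction=1.0, adaptive_site_fraction=1.0, q=0.0,
                  s1=0.001), None),  # advantageous, 2Ns ~ 2.3
        ]
        for overrides, expected in cases:
            cfg = SimulationConfig(**kwargs, **overrides)
            gene = simulate_divergence(cfg, np.random.default_rng(13))[0]
            truth = expected if expected is not None else gene.expected_kaks["a"]
            est = ka_ks(gene.alignment, kappa=cfg.kappa).ratio
            assert est == pytest.approx(truth, rel=0.05)

    def test_deleterious_class_shows_no_divergence(self):
        cfg = SimulationConfig(tree="(a:0.05,b:0.05);", n_genes=1, n_codons=20_000,
                               adaptive_fraction=0.0, q=1.0, focal="a")
        gene = simulate_divergence(cfg, np.random.default_rng(14))[0]
        est = ka_ks(gene.alignment, kappa=cfg.kappa)
        assert est.ka / est.ks < 0.01

    def test_elevated_ratio_in_adaptive_genes(self):
        cfg = SimulationConfig(tree="(a:0.02,b:0.02);", n_genes=2, n_codons=30_000,
                               adaptive_fraction=0.5, adaptive_site_fraction=0.05,
                               q=0.8, s1=0.001, focal="a")
        genes = simulate_divergence(cfg, np.random.default_rng(15))
        adaptive = ka_ks(genes[0].alignment, kappa=cfg.kappa).ratio
        background = ka_ks(genes[1].alignment, kappa=cfg.kappa).ratio
        assert adaptive == pytest.approx(genes[0].expected_kaks["a"], rel=0.1)
        assert adaptive > background


class TestPolymorphismSimulation:
    def test_high_frequency_ratio_approaches_one_minus_q(self):
        cfg = SimulationConfig(n_genes=8, n_codons=2000, adaptive_fraction=0.0,
                               q=0.8, theta=0.02)
        rng = np.random.default_rng(17)
        genes = simulate_divergence(cfg, rng)
        samplers = {}
        pn = ps = ln = ls = 0
        for g in genes:
            pset = simulate_polymorphism(cfg, g, rng, samplers=samplers)
            kept = pset.filtered(min_freq=0.2)
            pn += sum(1 for s in kept if s.cls != SYN)
            ps += sum(1 for s in kept if s.cls == SYN)
            ln += pset.ln
            ls += pset.ls
        ratio = (pn / ln) / (ps / ls)
        se = ratio * math.sqrt(1 / pn + 1 / ps)
        assert abs(ratio - 0.2) < 3 * se + 0.02

    def test_low_frequency_bin_enriched_for_deleterious(self):
        cfg = SimulationConfig(n_genes=4, n_codons=2000, adaptive_fraction=0.0,
                               q=0.8, theta=0.03)
        rng = np.random.default_rng(18)
        genes = simulate_divergence(cfg, rng)
        low = high = 0.0
        lowc = highc = 0
        for g in genes:
            pset = simulate_polymorphism(cfg, g, rng)
            low_sites = [s for s in pset.sites if s.freq < 0.2]
            high_sites = [s for s in pset.sites if s.freq >= 0.2]
            lowc += sum(1 for s in low_sites if s.cls != SYN)
            low += max(len(low_sites), 1)
            highc += sum(1 for s in high_sites if s.cls != SYN)
            high += max(len(high_sites), 1)
        assert lowc / low > highc / high

    def test_advantageous_sites_contribute_no_polymorphism(self):
        cfg = SimulationConfig(n_genes=1, n_codons=5000, adaptive_fraction=1.0,
                               adaptive_site_fraction=0.5, q=0.0, theta=0.02)
        rng = np.random.default_rng(19)
        gene = simulate_divergence(cfg, rng)[0]
        pset = simulate_polymorphism(cfg, gene, rng)
        ratio = pa_ps(pset, min_freq=0.0)
        # nonsyn polymorphism comes only from the neutral half of sites
        assert ratio.value < 0.75


class TestScenarios:
    def test_supergene_composition_arithmetic(self):
        groups = sum(c for c, _ in VARIABLE_SELECTION_COMPOSITION)
        adaptive = sum(c * k for c, k in VARIABLE_SELECTION_COMPOSITION)
        assert groups == 300
        assert adaptive == 1000

    def test_scaled_scenario_preserves_proportions(self):
        cfg = SimulationConfig(n_codons=30)
        scen = scenario_concordance_experiment(cfg, seed=0, scale=0.1, with_polymorphism=False)
        assert len(scen.genes) == 300
        assert len(scen.adaptive_genes) == 100
        assert len(scen.supergenes_random) == 30
        assert len(scen.supergenes_composed) == 30
        # composed groups have exactly the prescribed adaptive counts
        sizes = sorted(
            sum(g in scen.adaptive_genes for g in grp)
            for grp in scen.supergenes_composed
        )
        expected = sorted(
            k for c, k in VARIABLE_SELECTION_COMPOSITION for _ in range(int(c * 0.1))
        )
        assert sizes == expected
        # every gene appears exactly once in each scheme
        for scheme in (scen.supergenes_random, scen.supergenes_composed):
            flat = [g for grp in scheme for g in grp]
            assert sorted(flat) == sorted(g.gene for g in scen.genes)

    def test_non_integral_scale_rejected(self):
        with pytest.raises(ValueError, match="integral"):
            scenario_concordance_experiment(SimulationConfig(), scale=0.07)

    def test_fluctuating_q_flips_the_mk_conclusion(self):
        res = fluctuating_q_experiment(n_reps=100, seed=5)
        assert res["flip_rate"] > 0.8

    def test_constant_q_control_stays_concordant(self):
        res = fluctuating_q_experiment(n_reps=100, seed=5, q_b=0.848)
        assert res["flip_rate"] < 0.2
        assert res["reject_rate_a"] == pytest.approx(res["reject_rate_b"], abs=0.1)
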