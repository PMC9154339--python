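"""Codon counting: site fractions, pathway differences, Ka/Ks estimation."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mkconcord.counting import (
    AllPathsBlockedError,
    CodonAlignment,
    StopCodonError,
    count_differences,
    count_sites,
    estimate_kappa,
    jukes_cantor,
    ka_ks,
    lineage_kaks,
    read_codon_alignment,
)
from mkconcord.genetics import NUCS, is_stop, is_transition, sense_codons, translate_codon

SENSE = sense_codons(1)


# --- independent brute-force oracles -------------------------------------


def oracle_sites(codon, kappa):
    """Direct neighbor enumeration with kappa weights, nonsense excluded."""
    syn = 0.0
    for pos in range(3):
        weights = []
        for b in NUCS:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if is_stop(mut):
                continue
            w = kappa if is_transition(codon[pos], b) else 1.0
            weights.append((w, translate_codon(mut) == translate_codon(codon)))
        tot = sum(w for w, _ in weights)
        if tot:
            syn += sum(w for w, is_syn in weights if is_syn) / tot
    return syn, 3.0 - syn


def oracle_differences(a, b):
    """Average step classification over stop-free orderings of the changes."""
    positions = [i for i in range(3) if a[i] != b[i]]
    outcomes = []
    for order in itertools.permutations(positions):
        cur, syn, blocked = a, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if is_stop(nxt):
                blocked = True
                break
            syn += translate_codon(cur) == translate_codon(nxt)
            cur = nxt
        if not blocked:
            outcomes.append(syn)
    if not outcomes:
        return None
    mean_syn = sum(outcomes) / len(outcomes)
    return mean_syn, len(positions) - mean_syn


# --- count_sites ----------------------------------------------------------


class TestCountSites:
    def test_phenylalanine_has_one_third_synonymous_site(self):
        assert count_sites("TTT", kappa=1.0) == pytest.approx((1 / 3, 8 / 3))

    def test_methionine_fully_nonsynonymous(self):
        for kappa in (1.0, 2.0, 5.0):
            assert count_sites("ATG", kappa) == pytest.approx((0.0, 3.0))

    @pytest.mark.parametrize("kappa", [1.0, 2.0, 4.5])
    def test_agrees_with_enumeration_oracle_on_all_codons(self, kappa):
        for codon in SENSE:
            assert count_sites(codon, kappa) == pytest.approx(
                oracle_sites(codon, kappa), abs=1e-12
            )

    def test_sites_sum_to_three(self):
        for codon in SENSE:
            s, n = count_sites(codon, kappa=2.7)
            assert s + n == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(StopCodonError):
            count_sites("TAA")


# --- count_differences ----------------------------------------------------


class TestCountDifferences:
    def test_single_synonymous_difference(self):
        assert count_differences("TTT", "TTC") == (1.0, 0.0)

    def test_single_nonsynonymous_difference(self):
        assert count_differences("TGT", "TGG") == (0.0, 1.0)

    def test_identical_codons(self):
        assert count_differences("ATG", "ATG") == (0.0, 0.0)

    def test_two_step_pathway_average(self):
        expected = oracle_differences("TTT", "GTA")
        assert count_differences("TTT", "GTA") == pytest.approx(expected)

    def test_agrees_with_path_oracle_on_all_sense_pairs(self):
        for a in SENSE:
            for b in SENSE:
                expected = oracle_differences(a, b)
                if expected is None:
                    with pytest.raises(AllPathsBlockedError):
                        count_differences(a, b)
                else:
                    got = count_differences(a, b)
                    assert got == pytest.approx(expected, abs=1e-12)
                    assert got[0] + got[1] == pytest.approx(
                        sum(x != y for x, y in zip(a, b))
                    )

    def test_symmetric_in_codon_order(self):
        for a, b in [("TTT", "GTA"), ("AAA", "ACC"), ("CTC", "CAG")]:
            assert count_differences(a, b) == pytest.approx(count_differences(b, a))


# --- pairwise Ka/Ks -------------------------------------------------------


class TestKaKs:
    def test_identical_sequences_undefined_ratio(self):
        aln = CodonAlignment(names=["a", "b"], sequences=["ATGTTT", "ATGTTT"])
        r = ka_ks(aln)
        assert r.ka == 0.0 and r.ks == 0.0 and r.undefined

    def test_one_synonymous_difference_hand_computed(self, pair_alignment):
        aln = pair_alignment(n_codons=100)
        r = ka_ks(aln, kappa=1.0)
        # site totals from the counting oracle: averaging TTT and TTC columns
        ls = sum(oracle_sites(c, 1.0)[0] for c in ["TTT"] * 99) + (
            oracle_sites("TTT", 1.0)[0] + oracle_sites("TTC", 1.0)[0]
        ) / 2
        assert r.ka == 0.0
        assert r.ks == pytest.approx(jukes_cantor(1.0 / ls))
        assert r.nd == 0.0 and r.sd == 1.0

    def test_sequence_order_irrelevant(self, pair_alignment):
        aln = pair_alignment()
        swapped = CodonAlignment(names=["b", "a"], sequences=aln.sequences[::-1])
        r1, r2 = ka_ks(aln, kappa=2.0), ka_ks(swapped, kappa=2.0)
        assert (r1.ka, r1.ks, r1.ln, r1.ls) == (r2.ka, r2.ks, r2.ln, r2.ls)

    def test_site_totals_sum_to_sequence_length(self, pair_alignment):
        aln = pair_alignment()
        r = ka_ks(aln)
        assert r.ln + r.ls == pytest.approx(3 * r.n_codons)

    def test_gapped_codons_dropped_pairwise(self):
        aln = CodonAlignment(names=["a", "b"], sequences=["ATG---TTT", "ATGAAATTC"])
        r = ka_ks(aln)
        assert r.n_codons == 2 and r.skipped_codons == 1

    def test_neutral_simulation_estimates_unity(self):
        # omega = 1 data at 10^4 codons: estimate within +-0.05 of 1
        import numpy as np

        from mkconcord.simulate import SimulationConfig, simulate_divergence

        cfg = SimulationConfig(
            tree="(a:0.05,b:0.05);", n_genes=1, n_codons=10_000,
            adaptive_fraction=0.0, q=0.0, focal="a",
        )
        gene = simulate_divergence(cfg, np.random.default_rng(11))[0]
        r = ka_ks(gene.alignment, kappa=cfg.kappa)
        assert r.ratio == pytest.approx(1.0, abs=0.05)


# --- lineage-specific Ka/Ks ----------------------------------------------


def _triplet(focal, sister, outgroup):
    return CodonAlignment(names=["f", "s", "o"], sequences=[focal, sister, outgroup])


class TestLineageKaKs:
    def test_focal_specific_synonymous_change(self):
        # focal TTC vs sister/outgroup TTT: one syn change on the focal branch
        aln = _triplet("ATGTTC", "ATGTTT", "ATGTTT")
        res = lineage_kaks(aln, "f", "s", "o")
        assert res["focal"].sd == 1.0 and res["focal"].nd == 0.0
        assert res["sister"].sd == 0.0 and res["sister"].nd == 0.0

    def test_hand_parsimony_on_five_codon_toy(self):
        # codons 1-3, 5 identical across taxa; codon 4 differs in all three
        # taxa at position 3 (outgroup matches neither) -> unresolvable
        focal = "ATG" + "CTT" + "GGG" + "AAA" + "TTT"
        sister = "ATG" + "CTT" + "GGG" + "AAG" + "TTT"
        outgr = "ATG" + "CTT" + "GGG" + "AAC" + "TTT"
        res = lineage_kaks(_triplet(focal, sister, outgr), "f", "s", "o")
        assert res["ambiguous_codons"] == 1
        assert res["focal"].sd + res["focal"].nd == 0.0
        assert res["sister"].sd + res["sister"].nd == 0.0

    def test_focal_change_polarized_by_outgroup(self):
        aln = _triplet("CTTAAA", "CTCAAA", "CTCAAA")
        res = lineage_kaks(aln, "f", "s", "o")
        assert res["focal"].sd == 1.0  # CTC -> CTT, synonymous, focal branch

    def test_symmetric_divergence_gives_matching_ratios(self):
        import numpy as np

        from mkconcord.simulate import SimulationConfig, simulate_divergence

        cfg = SimulationConfig(n_genes=1, n_codons=20_000, adaptive_fraction=0.0, q=0.5)
        gene = simulate_divergence(cfg, np.random.default_rng(5))[0]
        res = lineage_kaks(gene.alignment, "focal", "sister", "out1", kappa=cfg.kappa)
        assert res["focal"].ratio == pytest.approx(res["sister"].ratio, rel=0.15)


class TestKappaEstimation:
    def test_transition_rich_fourfold_sites(self):
        # 12 fourfold codons: 8 transition diffs, 2 transversion diffs
        a = "GGT" * 10 + "GGT" * 2
        b = "GGC" * 8 + "GGT" * 2 + "GGA" * 2
        kappa = estimate_kappa(a, b)
        assert kappa == pytest.approx(2.0 * 8 / 2)

    def test_uninformative_data_falls_back(self):
        with pytest.warns(UserWarning):
            assert estimate_kappa("ATGATG", "ATGATG") == 2.0


class TestAlignmentIO:
    def test_fasta_round_trip_with_terminal_stop(self, tmp_path):
        p = tmp_path / "toy.fa"
        p.write_text(">x\nATGTTTTAA\n>y\nATGTTCTAA\n")
        aln = read_codon_alignment(p)
        assert aln.n_codons == 2  # stop trimmed
        assert aln["x"] == "ATGTTT"

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            CodonAlignment(names=["a"], sequences=["ATGTAAATG"])

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            CodonAlignment(names=["a"], sequences=["ATGT"])
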