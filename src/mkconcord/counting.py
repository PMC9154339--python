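"""Ka/Ks estimation by kappa-weighted Nei-Gojobori codon counting.

The counting method classifies the mutational opportunity of every codon
position into synonymous and nonsynonymous fractions, weighting transitions
by ``kappa`` relative to transversions, counts observed differences between
codons by averaging over all minimal stop-free mutational paths, and corrects
the resulting proportions for multiple hits with the Jukes-Cantor formula
``d = -(3/4) ln(1 - (4/3) p)``.  Lineage-specific ratios are obtained by
assigning substitutions to the focal or sister branch with an outgroup, by
codon-level parsimony.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

from Bio import SeqIO

from .genetics import NUCS, is_sense, is_stop, is_transition, sense_codons, translate_codon

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "count_sites",
    "count_differences",
    "ka_ks",
    "lineage_kaks",
    "estimate_kappa",
    "read_codon_alignment",
]


class StopCodonError(ValueError):
    """A stop codon was supplied where a sense codon is required."""


class AllPathsBlockedError(ValueError):
    """Every mutational path between two codons passes through a stop codon."""


@dataclass
class CodonAlignment:
    """An in-frame codon alignment: equal-length DNA strings, length % 3 == 0."""

    names: list[str]
    sequences: list[str]
    table_id: int = 1

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences differ in length")
        if not self.sequences:
            raise ValueError("empty alignment")
        self.sequences = [s.upper() for s in self.sequences]
        length = len(self.sequences[0])
        if any(len(s) != length for s in self.sequences):
            raise ValueError("sequences are not aligned (unequal lengths)")
        if length % 3 != 0:
            raise ValueError("alignment length is not a multiple of 3")
        for name, seq in zip(self.names, self.sequences):
            for i in range(0, length, 3):
                codon = seq[i : i + 3]
                if set(codon) <= set(NUCS) and is_stop(codon, self.table_id):
                    raise ValueError(
                        f"internal stop codon {codon} at codon {i // 3} in {name!r}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3

    def codons(self, index: int) -> list[str]:
        """Column of codons at codon position ``index`` (0-based)."""
        return [s[3 * index : 3 * index + 3] for s in self.sequences]

    def __getitem__(self, name: str) -> str:
        return self.sequences[self.names.index(name)]

    def subset(self, names: list[str]) -> "CodonAlignment":
        return CodonAlignment(
            names=list(names), sequences=[self[n] for n in names], table_id=self.table_id
        )


@dataclass
class KaKsResult:
    """Per-site substitution rates and the raw counts behind them.

    ``ln``/``ls`` are the (fractional) nonsynonymous and synonymous site
    totals, ``nd``/``sd`` the (fractional) difference counts.  ``ratio`` is
    ``nan`` with ``undefined=True`` when Ks is zero or a Jukes-Cantor
    correction is out of range.
    """

    ka: float
    ks: float
    ratio: float
    ln: float
    ls: float
    nd: float
    sd: float
    n_codons: int = 0
    skipped_codons: int = 0
    undefined: bool = False
    notes: list[str] = field(default_factory=list)


def _clean_codon(codon: str) -> bool:
    return set(codon) <= set(NUCS)


@lru_cache(maxsize=None)
def _count_sites_cached(codon: str, kappa: float, table_id: int) -> tuple[float, float]:
    aa = translate_codon(codon, table_id)
    syn = 0.0
    for pos in range(3):
        w_syn = 0.0
        w_tot = 0.0
        for base in NUCS:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            # Nonsense changes are not a viable mutational opportunity (they
            # are removed instantly by selection) and are excluded from the
            # per-position normalization.
            if is_stop(mutant, table_id):
                continue
            w = kappa if is_transition(codon[pos], base) else 1.0
            w_tot += w
            if translate_codon(mutant, table_id) == aa:
                w_syn += w
        if w_tot > 0:
            syn += w_syn / w_tot
    return syn, 3.0 - syn


def count_sites(codon: str, kappa: float = 1.0, table_id: int = 1) -> tuple[float, float]:
    """Synonymous and nonsynonymous site fractions of one sense codon.

    Each of the three positions contributes its kappa-weighted fraction of
    synonymous changes among the viable (non-nonsense) single-base changes
    (transitions weighted ``kappa``, transversions 1).  The two fractions
    always sum to exactly 3.
    """
    codon = codon.upper()
    if not is_sense(codon, table_id):
        raise StopCodonError(f"{codon} is not a sense codon")
    return _count_sites_cached(codon, float(kappa), table_id)


@lru_cache(maxsize=None)
def _count_diffs_cached(a: str, b: str, table_id: int) -> tuple[float, float]:
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    syn_paths = []
    for order in itertools.permutations(positions):
        current = a
        syn = 0.0
        blocked = False
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if is_stop(nxt, table_id):
                blocked = True
                break
            if translate_codon(current, table_id) == translate_codon(nxt, table_id):
                syn += 1.0
            current = nxt
        if not blocked:
            syn_paths.append(syn)
    if not syn_paths:
        raise AllPathsBlockedError(f"all mutational paths {a} -> {b} pass through stops")
    syn = sum(syn_paths) / len(syn_paths)
    return syn, len(positions) - syn


def count_differences(codon_a: str, codon_b: str, table_id: int = 1) -> tuple[float, float]:
    """Synonymous and nonsynonymous difference counts between two codons.

    Averages the step classification over all orderings of the differing
    positions whose intermediate codons are not stops; the two counts sum
    to the number of differing positions.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if not is_sense(c, table_id):
            raise StopCodonError(f"{c} is not a sense codon")
    return _count_diffs_cached(codon_a, codon_b, table_id)


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction of a raw difference proportion."""
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def estimate_kappa(seq_a: str, seq_b: str, table_id: int = 1) -> float:
    """Transition/transversion rate ratio from fourfold-degenerate sites.

    At a fourfold-degenerate third position there is one transition target
    and two transversion targets, so the rate ratio is twice the observed
    ts/tv count ratio.  Falls back to 2.0 (with a warning) when the data are
    uninformative.
    """
    ts = tv = 0
    for i in range(0, min(len(seq_a), len(seq_b)) - 2, 3):
        ca, cb = seq_a[i : i + 3].upper(), seq_b[i : i + 3].upper()
        if not (_clean_codon(ca) and _clean_codon(cb)):
            continue
        if ca[:2] != cb[:2] or not (is_sense(ca, table_id) and is_sense(cb, table_id)):
            continue
        fam = ca[:2]
        aas = {translate_codon(fam + n, table_id) for n in NUCS}
        if len(aas) != 1 or "*" in aas:
            continue
        if ca[2] != cb[2]:
            if is_transition(ca[2], cb[2]):
                ts += 1
            else:
                tv += 1
    if tv == 0:
        warnings.warn("no transversions at fourfold sites; falling back to kappa = 2")
        return 2.0
    return 2.0 * ts / tv


def _resolve_kappa(kappa, seq_a: str, seq_b: str, table_id: int) -> float:
    if kappa == "auto":
        return estimate_kappa(seq_a, seq_b, table_id)
    return float(kappa)


def ka_ks(
    aln: CodonAlignment,
    kappa: float | str = 1.0,
    correction: bool = True,
) -> KaKsResult:
    """Pairwise Ka/Ks by kappa-weighted NG counting with JC correction.

    ``aln`` must hold exactly two sequences.  Gapped or ambiguous codons are
    dropped pairwise; codon pairs whose every mutational path crosses a stop
    are skipped with a warning.  ``kappa="auto"`` estimates kappa from
    fourfold-degenerate sites first.
    """
    if len(aln.sequences) != 2:
        raise ValueError("ka_ks needs an alignment of exactly 2 sequences")
    seq_a, seq_b = aln.sequences
    k = _resolve_kappa(kappa, seq_a, seq_b, aln.table_id)
    ln = ls = nd = sd = 0.0
    used = skipped = 0
    notes: list[str] = []
    for i in range(aln.n_codons):
        ca, cb = aln.codons(i)
        if not (_clean_codon(ca) and _clean_codon(cb)):
            skipped += 1
            continue
        if not (is_sense(ca, aln.table_id) and is_sense(cb, aln.table_id)):
            skipped += 1
            continue
        try:
            s_diff, n_diff = count_differences(ca, cb, aln.table_id)
        except AllPathsBlockedError:
            warnings.warn(f"codon pair {ca}/{cb} at {i}: all paths cross stops; skipped")
            skipped += 1
            continue
        sa, na = count_sites(ca, k, aln.table_id)
        sb, nb = count_sites(cb, k, aln.table_id)
        ls += (sa + sb) / 2.0
        ln += (na + nb) / 2.0
        sd += s_diff
        nd += n_diff
        used += 1
    if used == 0:
        raise ValueError("no analyzable codons after filtering")
    p_n = nd / ln if ln > 0 else 0.0
    p_s = sd / ls if ls > 0 else 0.0
    if correction:
        ka_v, ks_v = jukes_cantor(p_n), jukes_cantor(p_s)
    else:
        ka_v, ks_v = p_n, p_s
    undefined = False
    if math.isnan(ka_v) or math.isnan(ks_v):
        notes.append("difference proportion >= 3/4; JC correction undefined")
        undefined = True
        ratio = math.nan
    elif ks_v == 0.0:
        notes.append("Ks = 0; ratio undefined")
        undefined = True
        ratio = math.nan
    else:
        ratio = ka_v / ks_v
    return KaKsResult(
        ka=ka_v, ks=ks_v, ratio=ratio, ln=ln, ls=ls, nd=nd, sd=sd,
        n_codons=used, skipped_codons=skipped, undefined=undefined, notes=notes,
    )


def lineage_kaks(
    aln: CodonAlignment,
    focal: str,
    sister: str,
    outgroup: str,
    kappa: float | str = 1.0,
    correction: bool = True,
) -> dict:
    """Lineage-specific Ka/Ks for the focal and sister branches.

    Unweighted parsimony per alignment position: where the two ingroup bases
    differ and the outgroup matches exactly one of them, the matched state is
    ancestral and the change is assigned to the other lineage's branch.
    Codons containing a position the outgroup resolves for neither state are
    discarded from the difference counts and tallied as ambiguous.  Site
    totals are averaged over the two ingroup sequences and shared by both
    lineages.

    Returns ``{"focal": KaKsResult, "sister": KaKsResult,
    "ambiguous_codons": int}``.
    """
    sub = aln.subset([focal, sister, outgroup])
    seq_f, seq_s, seq_o = sub.sequences
    k = _resolve_kappa(kappa, seq_f, seq_s, aln.table_id)
    ln = ls = 0.0
    diffs = {focal: [0.0, 0.0], sister: [0.0, 0.0]}  # [syn, nonsyn]
    used = skipped = ambiguous = 0
    for i in range(sub.n_codons):
        cf, cs, co = sub.codons(i)
        if not all(_clean_codon(c) and is_sense(c, aln.table_id) for c in (cf, cs, co)):
            skipped += 1
            continue
        sa, na = count_sites(cf, k, aln.table_id)
        sb, nb = count_sites(cs, k, aln.table_id)
        ls += (sa + sb) / 2.0
        ln += (na + nb) / 2.0
        used += 1
        if cf == cs:
            continue
        # Per-position parsimony: the ancestral base at each differing
        # position is the ingroup state matched by the outgroup.  The codon
        # is discarded (and tallied) when any differing position cannot be
        # resolved, or when the inferred ancestral codon is a stop.
        anc = []
        resolvable = True
        for pos in range(3):
            if cf[pos] == cs[pos]:
                anc.append(cf[pos])
            elif co[pos] == cs[pos]:
                anc.append(cs[pos])
            elif co[pos] == cf[pos]:
                anc.append(cf[pos])
            else:
                resolvable = False
                break
        if not resolvable:
            ambiguous += 1
            continue
        anc = "".join(anc)
        if not is_sense(anc, aln.table_id):
            ambiguous += 1
            continue
        try:
            assigned = {
                branch: count_differences(anc, der, aln.table_id)
                for branch, der in ((focal, cf), (sister, cs))
                if anc != der
            }
        except AllPathsBlockedError:
            ambiguous += 1
            continue
        for branch, (s_diff, n_diff) in assigned.items():
            diffs[branch][0] += s_diff
            diffs[branch][1] += n_diff
    if used == 0:
        raise ValueError("no analyzable codons after filtering")
    results = {}
    for key, name in (("focal", focal), ("sister", sister)):
        sd, nd = diffs[name]
        p_n = nd / ln if ln > 0 else 0.0
        p_s = sd / ls if ls > 0 else 0.0
        if correction:
            ka_v, ks_v = jukes_cantor(p_n), jukes_cantor(p_s)
        else:
            ka_v, ks_v = p_n, p_s
        undefined = math.isnan(ka_v) or math.isnan(ks_v) or ks_v == 0.0
        ratio = math.nan if undefined else ka_v / ks_v
        results[key] = KaKsResult(
            ka=ka_v, ks=ks_v, ratio=ratio, ln=ln, ls=ls, nd=nd, sd=sd,
            n_codons=used, skipped_codons=skipped, undefined=undefined,
        )
    results["ambiguous_codons"] = ambiguous
    return results


def read_codon_alignment(path, table_id: int = 1, trim_terminal_stop: bool = True) -> CodonAlignment:
    """Read an in-frame FASTA alignment; optionally trim a shared final stop."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    names = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    if trim_terminal_stop and len(seqs[0]) % 3 == 0 and len(seqs[0]) >= 3:
        tails = [s[-3:] for s in seqs]
        if any(set(t) <= set(NUCS) and is_stop(t, table_id) for t in tails):
            seqs = [s[:-3] for s in seqs]
    return CodonAlignment(names=names, sequences=seqs, table_id=table_id)
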