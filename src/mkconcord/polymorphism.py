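"""Within-species polymorphism: site classification and Pa/Ps estimation.

Pa/Ps is the polymorphism analogue of Ka/Ks: the number of segregating
nonsynonymous sites per nonsynonymous site over the number of segregating
synonymous sites per synonymous site.  Because deleterious variants segregate
mostly at low frequency, Pa/Ps is computed after polarizing alleles against
an outgroup and discarding variants below a derived-frequency cutoff
(default 0.2), which leaves the ratio approximating ``1 - q`` with ``q`` the
deleterious fraction.  Singleton and CpG filters, frequency-bin profiles and
a heterozygous mode for single diploid genomes are provided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genetics import NUCS, is_sense, is_stop, translate_codon
from .theory import RateRatio

__all__ = [
    "PolymorphicSite",
    "PolymorphismSet",
    "classify_variant",
    "polarize",
    "pa_ps",
    "frequency_profile",
    "heterozygous_pa_ps",
    "cpg_flag",
    "read_site_table",
    "write_site_table",
]

SYN = "synonymous"
NONSYN = "nonsynonymous"
NONSENSE = "nonsense"


@dataclass
class PolymorphicSite:
    """One segregating coding site, polarized against an outgroup."""

    gene: str
    codon_index: int
    codon_pos: int
    anc: str
    der: str
    der_count: int
    n: int
    cls: str
    singleton: bool = False
    cpg: bool = False
    unpolarized: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.der_count < self.n:
            raise ValueError("a segregating site needs 0 < derived count < sample size")
        self.singleton = self.der_count == 1

    @property
    def freq(self) -> float:
        return self.der_count / self.n


@dataclass
class PolymorphismSet:
    """Segregating sites for one gene (or pooled gene set) plus site totals.

    ``ln``/``ls`` are the nonsynonymous and synonymous site totals of the
    underlying coding sequence (from the codon-counting module), the
    denominators of Pa and Ps.
    """

    sites: list[PolymorphicSite]
    ln: float
    ls: float
    gene: str = "pooled"

    def filtered(
        self,
        min_freq: float = 0.0,
        drop_singletons: bool = False,
        drop_cpg: bool = False,
        include_nonsense: bool = False,
    ) -> list[PolymorphicSite]:
        """Sites passing the derived-frequency cutoff and flag filters."""
        out = []
        for s in self.sites:
            if s.unpolarized or s.freq <= min_freq:
                continue
            if drop_singletons and s.singleton:
                continue
            if drop_cpg and s.cpg:
                continue
            if s.cls == NONSENSE and not include_nonsense:
                continue
            out.append(s)
        return out


def classify_variant(codon: str, position: int, derived: str, table_id: int = 1) -> str:
    """Classify a coding change as synonymous, nonsynonymous or nonsense."""
    codon, derived = codon.upper(), derived.upper()
    if derived not in NUCS:
        raise ValueError(f"invalid base {derived!r}")
    if not is_sense(codon, table_id):
        raise ValueError(f"{codon} is not a sense codon")
    if derived == codon[position]:
        raise ValueError("derived base equals the ancestral base")
    mutant = codon[:position] + derived + codon[position + 1 :]
    if is_stop(mutant, table_id):
        return NONSENSE
    if translate_codon(mutant, table_id) == translate_codon(codon, table_id):
        return SYN
    return NONSYN


def polarize(counts: dict[str, int], outgroup: str) -> tuple[str, float] | None:
    """Orient a biallelic site with a single outgroup allele.

    ``counts`` maps the two segregating alleles to their haplotype counts.
    If the outgroup carries one of them, the other is derived and its sample
    frequency is returned as ``(derived_allele, frequency)``.  Returns
    ``None`` (unpolarized) when the outgroup matches neither allele, and
    raises on non-biallelic input (triallelic sites are excluded upstream).
    """
    alleles = [a for a, c in counts.items() if c > 0]
    if len(alleles) != 2:
        raise ValueError("polarize expects a biallelic site")
    outgroup = outgroup.upper()
    total = sum(counts.values())
    if outgroup == alleles[0]:
        derived = alleles[1]
    elif outgroup == alleles[1]:
        derived = alleles[0]
    else:
        return None
    return derived, counts[derived] / total


def _ratio(pn: int, ps: int, ln: float, ls: float) -> RateRatio:
    if ls <= 0 or ln <= 0:
        raise ValueError("site totals Ln, Ls must be positive")
    if ps == 0:
        return RateRatio(math.nan, kind="Pa/Ps", undefined=True)
    return RateRatio((pn / ln) / (ps / ls), kind="Pa/Ps")


def pa_ps(
    pset: PolymorphismSet,
    min_freq: float = 0.2,
    drop_singletons: bool = False,
    drop_cpg: bool = False,
    include_nonsense: bool = False,
) -> RateRatio:
    """Per-site Pa/Ps over variants passing the frequency cutoff and filters.

    The cutoff is strict (derived frequency must exceed ``min_freq``); with
    ``min_freq=0`` and no filters the unfiltered ratio is returned.  The
    ratio is flagged undefined when no synonymous variant survives.
    """
    kept = pset.filtered(min_freq, drop_singletons, drop_cpg, include_nonsense)
    pn = sum(1 for s in kept if s.cls != SYN)
    ps = sum(1 for s in kept if s.cls == SYN)
    return _ratio(pn, ps, pset.ln, pset.ls)


def frequency_profile(
    pset: PolymorphismSet,
    bin_width: float = 0.1,
    drop_singletons: bool = False,
    drop_cpg: bool = False,
) -> pd.DataFrame:
    """Pa/Ps per derived-frequency bin, plus the Low (<0.2) / High summary.

    Returns a DataFrame with columns ``bin``, ``lo``, ``hi``, ``pn``, ``ps``,
    ``pa_ps`` (NaN where the bin has no synonymous variant).  The final two
    rows are the two-bin summary used throughout: variants below 0.20 in the
    Low-Freq bin, the rest in High-Freq.
    """
    kept = pset.filtered(0.0, drop_singletons, drop_cpg)
    edges = []
    lo = 0.0
    while lo < 1.0 - 1e-9:
        edges.append((lo, min(lo + bin_width, 1.0)))
        lo += bin_width
    rows = []
    for lo, hi in edges:
        in_bin = [s for s in kept if lo < s.freq <= hi or (lo == 0.0 and s.freq == 0.0)]
        rows.append((f"({lo:.2f},{hi:.2f}]", lo, hi, in_bin))
    rows.append(("Low-Freq", 0.0, 0.2, [s for s in kept if s.freq < 0.2]))
    rows.append(("High-Freq", 0.2, 1.0, [s for s in kept if s.freq >= 0.2]))
    records = []
    for label, lo, hi, sites in rows:
        pn = sum(1 for s in sites if s.cls != SYN)
        ps = sum(1 for s in sites if s.cls == SYN)
        if ps == 0:
            value = math.nan
        else:
            value = (pn / pset.ln) / (ps / pset.ls)
        records.append({"bin": label, "lo": lo, "hi": hi, "pn": pn, "ps": ps, "pa_ps": value})
    return pd.DataFrame.from_records(records)


def heterozygous_pa_ps(het_classes: list[str], ln: float, ls: float) -> RateRatio:
    """Pa/Ps over the heterozygous coding sites of one diploid individual.

    ``het_classes`` lists the synonymous/nonsynonymous classification of each
    heterozygous site (sample size 2, so no frequency cutoff applies).
    Undefined when there is no heterozygous synonymous site.
    """
    pn = sum(1 for c in het_classes if c == NONSYN)
    ps = sum(1 for c in het_classes if c == SYN)
    return _ratio(pn, ps, ln, ls)


def cpg_flag(context: str) -> bool:
    """True when the central base of a 3-base ancestral context sits in a CpG.

    ``context`` is ``left + site + right``.  A site is CpG-prone when it is a
    C followed by G or a G preceded by C (the same dinucleotide read from the
    other strand).  Missing context (short string or non-ACGT characters)
    leaves the site unflagged with a warning.
    """
    context = context.upper()
    if len(context) != 3 or not set(context) <= set(NUCS):
        warnings.warn("incomplete or ambiguous context; CpG status unknown, site unflagged")
        return False
    left, base, right = context
    return (base == "C" and right == "G") or (base == "G" and left == "C")


SITE_TABLE_COLUMNS = ["gene", "codon_index", "codon_pos", "anc", "der", "der_count", "n"]


def read_site_table(path, ln: float, ls: float, table_id: int = 1, gene: str | None = None) -> PolymorphismSet:
    """Read the plain TSV site-table dialect into a PolymorphismSet.

    Columns: gene, codon_index, codon_pos, anc, der, der_count, n — where
    ``anc`` is the full ancestral codon and ``der`` the derived base.
    Classification is done from the codon context on load.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SITE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    sites = []
    for row in df.itertuples(index=False):
        cls = classify_variant(row.anc, int(row.codon_pos), row.der, table_id)
        sites.append(
            PolymorphicSite(
                gene=row.gene,
                codon_index=int(row.codon_index),
                codon_pos=int(row.codon_pos),
                anc=row.anc,
                der=row.der,
                der_count=int(row.der_count),
                n=int(row.n),
                cls=cls,
            )
        )
    return PolymorphismSet(sites=sites, ln=ln, ls=ls, gene=gene or "pooled")


def write_site_table(pset: PolymorphismSet, path) -> None:
    rows = [
        {
            "gene": s.gene,
            "codon_index": s.codon_index,
            "codon_pos": s.codon_pos,
            "anc": s.anc,
            "der": s.der,
            "der_count": s.der_count,
            "n": s.n,
        }
        for s in pset.sites
    ]
    pd.DataFrame(rows, columns=SITE_TABLE_COLUMNS).to_csv(Path(path), sep="\t", index=False)
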