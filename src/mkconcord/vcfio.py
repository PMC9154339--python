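"""Load polymorphic coding sites from VCF + BED + coding FASTA.

The reader handles the common minimal setup: biallelic SNPs with an ``AA``
(ancestral allele) INFO tag, a BED file giving each gene's coding intervals
(0-based half-open, plus strand assumed, intervals in transcription order),
and the per-gene coding sequence used to recover codon context.  Allele
counts come from ``AC``/``AN`` INFO fields or, failing that, from genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from cyvcf2 import VCF

from .counting import count_sites
from .genetics import NUCS, is_stop
from .polymorphism import PolymorphicSite, PolymorphismSet, classify_variant

__all__ = ["read_bed_genes", "read_vcf_polymorphism"]


def read_bed_genes(path) -> pd.DataFrame:
    """BED (chrom, start, end, name) -> one row per coding interval."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "gene"], usecols=[0, 1, 2, 3],
        dtype={"chrom": str, "gene": str},
    )
    if (df.end <= df.start).any():
        raise ValueError("BED intervals must satisfy start < end")
    return df


def _cds_offset(intervals: pd.DataFrame, chrom: str, pos0: int) -> int | None:
    """Offset of genomic position ``pos0`` (0-based) within the spliced CDS."""
    offset = 0
    for row in intervals.itertuples():
        if row.chrom == chrom and row.start <= pos0 < row.end:
            return offset + (pos0 - row.start)
        offset += row.end - row.start
    return None


def read_vcf_polymorphism(
    vcf_path,
    bed: pd.DataFrame,
    coding_seqs: dict[str, str],
    gene: str,
    table_id: int = 1,
    kappa: float = 1.0,
) -> PolymorphismSet:
    """Extract one gene's classified, polarized segregating sites from a VCF.

    Sites are skipped (with a warning tally) when they are not biallelic
    SNPs, lack a usable ``AA`` tag, or the ancestral allele matches neither
    observed allele (unpolarized).  Sample size is per-site (``AN`` or
    called genotypes), accommodating missing data.
    """
    intervals = bed[bed.gene == gene].sort_values("start")
    if intervals.empty:
        raise ValueError(f"gene {gene!r} not in BED")
    seq = coding_seqs[gene].upper()
    ln = ls = 0.0
    for i in range(len(seq) // 3):
        codon = seq[3 * i : 3 * i + 3]
        if set(codon) <= set(NUCS) and not is_stop(codon, table_id):
            s, n = count_sites(codon, kappa, table_id)
            ls += s
            ln += n
    sites: list[PolymorphicSite] = []
    skipped = {"non_snp": 0, "no_aa": 0, "unpolarized": 0, "outside": 0, "monomorphic": 0}
    vcf = VCF(str(vcf_path))
    chroms = set(intervals.chrom)
    for rec in vcf:
        if rec.CHROM not in chroms:
            continue
        if len(rec.ALT) != 1 or not rec.is_snp:
            skipped["non_snp"] += 1
            continue
        offset = _cds_offset(intervals, rec.CHROM, rec.POS - 1)
        if offset is None or offset >= 3 * (len(seq) // 3):
            skipped["outside"] += 1
            continue
        aa = rec.INFO.get("AA")
        if not aa or aa.upper() not in NUCS:
            skipped["no_aa"] += 1
            continue
        aa = aa.upper()
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if aa == ref:
            derived = alt
        elif aa == alt:
            derived = ref
        else:
            skipped["unpolarized"] += 1
            continue
        an = rec.INFO.get("AN")
        ac = rec.INFO.get("AC")
        if an is None or ac is None:
            gts = rec.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            called = gts != 2
            an = int(2 * called.sum())
            ac = int((gts[called] == 1).sum() + 2 * (gts[called] == 3).sum())
        an, ac = int(an), int(ac)
        der_count = ac if derived == alt else an - ac
        if not 0 < der_count < an:
            skipped["monomorphic"] += 1
            continue
        codon_index, codon_pos = divmod(offset, 3)
        codon = seq[3 * codon_index : 3 * codon_index + 3]
        anc_codon = codon[:codon_pos] + aa + codon[codon_pos + 1 :]
        if not set(anc_codon) <= set(NUCS) or is_stop(anc_codon, table_id):
            skipped["outside"] += 1
            continue
        cls = classify_variant(anc_codon, codon_pos, derived, table_id)
        sites.append(
            PolymorphicSite(
                gene=gene, codon_index=codon_index, codon_pos=codon_pos,
                anc=anc_codon, der=derived, der_count=der_count, n=an, cls=cls,
            )
        )
    if any(skipped.values()):
        warnings.warn(f"{gene}: skipped variants {skipped}")
    return PolymorphismSet(sites=sites, ln=ln, ls=ls, gene=gene)
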