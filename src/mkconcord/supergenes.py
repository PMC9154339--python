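"""Supergene construction: merging genes to boost test power.

A supergene is an artificial concatenation of 20-30 genes (by physical
neighborhood or by shared functional label).  Merging multiplies the number
of informative substitutions per testing unit, trading resolution for power;
the component-gene breakdown maps supergene-level calls back onto the
individual genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .counting import CodonAlignment
from .mk import MKTable

__all__ = [
    "Supergene",
    "group_by_location",
    "group_by_label",
    "merge_for_mk",
    "merge_alignments",
    "component_breakdown",
]


@dataclass
class Supergene:
    """An ordered concatenation of member genes with merged test inputs."""

    id: str
    members: list[str]
    table: MKTable | None = None
    alignment: CodonAlignment | None = None

    @property
    def size(self) -> int:
        return len(self.members)


def group_by_location(
    genes: pd.DataFrame,
    n_groups: int | None = None,
    size_range: tuple[int, int] = (20, 30),
) -> list[list[str]]:
    """Group neighboring genes into runs of ``size_range`` members.

    ``genes`` needs columns ``gene``, ``chrom``, ``start`` (BED-style
    coordinates).  Genes are sorted by (chrom, start) and cut into
    consecutive runs; the per-chromosome remainder is folded into that
    chromosome's last group.  When ``n_groups`` is given, the target group
    size is ``round(total / n_groups)`` clipped into ``size_range``.

    Returns ordered member-id lists (feed them to :func:`merge_for_mk` /
    :func:`merge_alignments`).
    """
    lo, hi = size_range
    if not 0 < lo <= hi:
        raise ValueError("invalid size range")
    total = len(genes)
    if n_groups:
        target = min(max(round(total / n_groups), lo), hi)
    else:
        target = round((lo + hi) / 2)
    ordered = genes.sort_values(["chrom", "start"], kind="mergesort")
    groups: list[list[str]] = []
    for _, chrom_df in ordered.groupby("chrom", sort=True):
        ids = chrom_df["gene"].tolist()
        chrom_groups = [ids[i : i + target] for i in range(0, len(ids), target)]
        if len(chrom_groups) >= 2 and len(chrom_groups[-1]) < lo:
            tail = chrom_groups.pop()
            chrom_groups[-1].extend(tail)
        if len(chrom_groups) == 1 and len(chrom_groups[0]) < lo:
            warnings.warn(
                f"chromosome with {len(chrom_groups[0])} genes: single undersized group"
            )
        groups.extend(chrom_groups)
    return groups


def group_by_label(
    labels: pd.DataFrame,
    size_range: tuple[int, int] = (20, 30),
) -> tuple[list[tuple[str, list[str]]], list[str]]:
    """One candidate supergene per shared label (gene function, ontology...).

    ``labels`` needs columns ``gene`` and ``label``; genes may carry several
    labels and then appear in several groups.  Labels outside ``size_range``
    are skipped and returned separately.
    """
    lo, hi = size_range
    kept: list[tuple[str, list[str]]] = []
    skipped: list[str] = []
    for label, sub in labels.groupby("label", sort=True):
        members = sub["gene"].drop_duplicates().tolist()
        if lo <= len(members) <= hi:
            kept.append((str(label), members))
        else:
            skipped.append(str(label))
    return kept, skipped


def merge_for_mk(members: list[MKTable], gene: str = "supergene") -> MKTable:
    """Element-wise sum of member MK tables (counts and site totals)."""
    if not members:
        raise ValueError("cannot merge an empty member list")
    lineages = {t.lineage for t in members}
    if len(lineages) > 1:
        raise ValueError(f"mixed lineages in merge: {sorted(lineages)}")
    return MKTable(
        dn=sum(t.dn for t in members),
        ds=sum(t.ds for t in members),
        pn=sum(t.pn for t in members),
        ps=sum(t.ps for t in members),
        ln=sum(t.ln for t in members),
        ls=sum(t.ls for t in members),
        gene=gene,
        lineage=members[0].lineage,
    )


def merge_alignments(members: list[CodonAlignment], names: list[str] | None = None) -> CodonAlignment:
    """Concatenate member codon alignments over a shared taxon set."""
    if not members:
        raise ValueError("cannot merge an empty member list")
    if names is None:
        names = members[0].names
    seqs = ["".join(m[n] for m in members) for n in names]
    return CodonAlignment(names=list(names), sequences=seqs, table_id=members[0].table_id)


def component_breakdown(
    supergene_members: dict[str, list[str]],
    significant_supergenes_a: set[str],
    significant_supergenes_b: set[str],
    gene_p_a: dict[str, float],
    gene_p_b: dict[str, float],
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-test component-gene tally inside significant supergenes.

    For each test (a = MK, b = the site model), collects the member genes of
    that test's significant supergenes, counts how many are individually
    significant, and reports the overlap universe (genes present in both
    collections, deduplicated) with its joint-significance count.
    """
    rows = []
    comp_a = {g for sg in significant_supergenes_a for g in supergene_members.get(sg, [])}
    comp_b = {g for sg in significant_supergenes_b for g in supergene_members.get(sg, [])}
    sig_a = {g for g in comp_a if gene_p_a.get(g, 1.0) < threshold}
    sig_b = {g for g in comp_b if gene_p_b.get(g, 1.0) < threshold}
    common = comp_a & comp_b
    both = {g for g in common if g in sig_a and g in sig_b}
    rows.append(
        {
            "components_mk": len(comp_a),
            "components_sitemodel": len(comp_b),
            "significant_mk": len(sig_a),
            "significant_sitemodel": len(sig_b),
            "common_components": len(common),
            "significant_both": len(both),
        }
    )
    return pd.DataFrame(rows)
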