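"""The McDonald-Kreitman test: 2x2 tables, Fisher's exact test, alpha and A1.

The test contrasts fixed differences on a focal lineage (Dn nonsynonymous,
Ds synonymous) with segregating variation in the extant species (Pn, Ps,
after the derived-frequency cutoff).  Under neutrality the two ratios match;
an excess of Dn/Ds over Pn/Ps indicates adaptive fixation.  The proportion of
adaptive nonsynonymous substitutions is

    alpha = 1 - (Ds * Pn) / (Dn * Ps)

and A1 = max(alpha, 0) * Dn is the implied number of adaptive sites per gene.
For merged (super)genes two pooled estimators are provided; the
divergence-weighted one damps the bias that arises when polymorphism level
and nonsynonymous divergence are negatively correlated across loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

from .counting import KaKsResult
from .polymorphism import SYN, PolymorphismSet

__all__ = [
    "MKTable",
    "MKResult",
    "build_table",
    "mk_fisher",
    "alpha_single",
    "alpha_pooled",
    "adaptive_sites_A1",
    "mk_test",
]


@dataclass
class MKTable:
    """Divergence/polymorphism counts for one gene (or supergene) and lineage."""

    dn: int
    ds: int
    pn: int
    ps: int
    ln: float = 0.0
    ls: float = 0.0
    gene: str = ""
    lineage: str = ""

    def __post_init__(self) -> None:
        for name in ("dn", "ds", "pn", "ps"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")
            setattr(self, name, int(v))


@dataclass
class MKResult:
    table: MKTable
    p_value: float
    alpha: float  # may be negative (excess constrained polymorphism) or nan
    a1: float  # adaptive substitutions, floored at 0
    direction: str  # "adaptive" | "constrained" | "none"
    degenerate: bool = False
    sided: str = "one"


def build_table(
    divergence: KaKsResult,
    pset: PolymorphismSet,
    min_freq: float = 0.2,
    gene: str = "",
    lineage: str = "",
    drop_singletons: bool = False,
    drop_cpg: bool = False,
) -> MKTable:
    """Assemble the 2x2 MK table from lineage divergence counts and polymorphism.

    Dn/Ds are the raw (rounded) assigned difference counts of the focal
    lineage; Pn/Ps count polymorphic sites with derived frequency above
    ``min_freq``.
    """
    if gene and pset.gene not in ("pooled", gene):
        raise ValueError(f"gene mismatch: divergence {gene!r} vs polymorphism {pset.gene!r}")
    kept = pset.filtered(min_freq, drop_singletons, drop_cpg)
    pn = sum(1 for s in kept if s.cls != SYN)
    ps = sum(1 for s in kept if s.cls == SYN)
    return MKTable(
        dn=round(divergence.nd),
        ds=round(divergence.sd),
        pn=pn,
        ps=ps,
        ln=divergence.ln,
        ls=divergence.ls,
        gene=gene or pset.gene,
        lineage=lineage,
    )


def mk_fisher(table: MKTable, sided: str = "one") -> tuple[float, bool]:
    """Fisher's exact test on the MK 2x2 table.

    One-sided (default) tests for an excess of Dn/Ds over Pn/Ps, the
    adaptive direction; ``sided="two"`` gives the two-sided test.  Returns
    ``(p_value, degenerate)`` where degenerate margins (an empty row or
    column) force p = 1.
    """
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    d_row = table.dn + table.ds
    p_row = table.pn + table.ps
    n_col = table.dn + table.pn
    s_col = table.ds + table.ps
    if d_row == 0 or p_row == 0 or n_col == 0 or s_col == 0:
        return 1.0, True
    contingency = [[table.dn, table.ds], [table.pn, table.ps]]
    alternative = "greater" if sided == "one" else "two-sided"
    _, p = stats.fisher_exact(contingency, alternative=alternative)
    return float(min(p, 1.0)), False


def alpha_single(table: MKTable) -> float:
    """alpha = 1 - (Ds*Pn)/(Dn*Ps); nan when Dn or Ps is zero."""
    if table.dn == 0 or table.ps == 0:
        return math.nan
    return 1.0 - (table.ds * table.pn) / (table.dn * table.ps)


def alpha_pooled(tables: list[MKTable], method: str = "weighted") -> float:
    """Pooled alpha over several genes.

    ``method="pooled-counts"`` sums Dn, Ds, Pn, Ps and applies the single-gene
    formula to the sums (exactly the alpha of the merged table).
    ``method="weighted"`` (the default used for supergenes) averages the
    per-gene neutral ratios ``Ds_i*Pn_i/(Dn_i*Ps_i)`` with weights
    proportional to ``Dn_i``, damping the covariance between polymorphism
    level and nonsynonymous divergence across loci.  Genes whose term is
    undefined (Dn or Ps zero) are excluded from the weighted average.
    """
    if len(tables) < 2:
        raise ValueError("alpha_pooled needs at least two tables")
    if method == "pooled-counts":
        merged = MKTable(
            dn=sum(t.dn for t in tables),
            ds=sum(t.ds for t in tables),
            pn=sum(t.pn for t in tables),
            ps=sum(t.ps for t in tables),
        )
        return alpha_single(merged)
    if method == "weighted":
        num = den = 0.0
        for t in tables:
            if t.dn == 0 or t.ps == 0:
                continue
            num += t.dn * (t.ds * t.pn) / (t.dn * t.ps)
            den += t.dn
        if den == 0:
            return math.nan
        return 1.0 - num / den
    raise ValueError(f"unknown method {method!r}")


def adaptive_sites_A1(alpha: float, table: MKTable) -> float:
    """A1 = max(alpha, 0) * Dn: the expected adaptive substitutions of a gene."""
    if math.isnan(alpha):
        return 0.0
    return max(alpha, 0.0) * table.dn


def mk_test(table: MKTable, sided: str = "one") -> MKResult:
    """Run the full single-table MK analysis (p-value, alpha, A1, direction)."""
    p, degenerate = mk_fisher(table, sided)
    a = alpha_single(table)
    a1 = adaptive_sites_A1(a, table)
    if math.isnan(a) or degenerate:
        direction = "none"
    elif a > 0:
        direction = "adaptive"
    elif a < 0:
        direction = "constrained"
    else:
        direction = "none"
    return MKResult(table=table, p_value=p, alpha=a, a1=a1, direction=direction,
                    degenerate=degenerate, sided=sided)
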