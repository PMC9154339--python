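"""Shared genetic-code utilities (built on Biopython's code tables)."""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

NUCS = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True when the substitution a->b is a purine<->purine or pyr<->pyr change."""
    return (a in PURINES) == (b in PURINES) and a != b


@lru_cache(maxsize=None)
def code_tables(table_id: int = 1):
    """Return (codon -> amino acid dict, frozenset of stop codons)."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(table.forward_table), frozenset(table.stop_codons)


@lru_cache(maxsize=None)
def sense_codons(table_id: int = 1) -> tuple[str, ...]:
    """Sense (non-stop) codons in lexicographic order; 61 for the universal code."""
    fwd, stops = code_tables(table_id)
    return tuple(
        c
        for c in (a + b + d for a in NUCS for b in NUCS for d in NUCS)
        if c not in stops
    )


def translate_codon(codon: str, table_id: int = 1) -> str:
    """One-letter amino acid, or '*' for a stop codon."""
    fwd, stops = code_tables(table_id)
    if codon in stops:
        return "*"
    return fwd[codon]


def is_stop(codon: str, table_id: int = 1) -> bool:
    return codon in code_tables(table_id)[1]


def is_sense(codon: str, table_id: int = 1) -> bool:
    return codon in code_tables(table_id)[0]
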