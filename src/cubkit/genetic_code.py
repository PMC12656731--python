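"""Standard genetic-code tables used throughout the package.

Everything is derived from Biopython's standard codon table (NCBI table 1)
so the 59-codon scored set, synonymous family structure and degeneracy
classes stay consistent with the canonical code.

Conventions:

* DNA alphabet internally (``T`` not ``U``); :func:`to_rna` is a
  presentation-layer helper for outputs that mirror RNA spelling.
* The *scored* codon set excludes the three stop codons plus the
  single-codon amino acids ATG (Met) and TGG (Trp), leaving 59 codons in
  18 synonymous families: nine two-fold, one three-fold (Ile), five
  four-fold and three six-fold (Leu, Ser, Arg).
"""

from __future__ import annotations

from itertools import product

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

BASES = ("A", "C", "G", "T")

#: all 64 codons in lexicographic order
ALL_CODONS: tuple[str, ...] = tuple("".join(p) for p in product(BASES, repeat=3))

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: codon -> one-letter amino acid for the 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

#: amino acids encoded by exactly one codon (Met, Trp) — excluded from bias scoring
SINGLE_CODON_AAS: frozenset[str] = frozenset(
    aa
    for aa in set(CODON_TO_AA.values())
    if sum(1 for c in SENSE_CODONS if CODON_TO_AA[c] == aa) == 1
)

#: the 59 codons retained for bias statistics
SCORED_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if CODON_TO_AA[c] not in SINGLE_CODON_AAS
)

#: amino acid -> tuple of synonymous codons (18 scored families)
SYN_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SCORED_CODONS:
    SYN_FAMILIES.setdefault(CODON_TO_AA[_codon], ())
for _codon in SCORED_CODONS:
    _aa = CODON_TO_AA[_codon]
    SYN_FAMILIES[_aa] = SYN_FAMILIES[_aa] + (_codon,)

#: family degeneracy class (2, 3, 4 or 6) per scored amino acid
FAMILY_SIZE: dict[str, int] = {aa: len(cods) for aa, cods in SYN_FAMILIES.items()}

#: the eight codon boxes whose third position is fully degenerate
#: (includes the four-fold sub-boxes of the six-fold families Leu/Ser/Arg)
FOURFOLD_BOXES: tuple[str, ...] = tuple(
    sorted(
        p
        for p in ("".join(x) for x in product(BASES, repeat=2))
        if len({CODON_TO_AA.get(p + b) for b in BASES}) == 1
        and (p + "A") in CODON_TO_AA
    )
)


def to_rna(codon: str) -> str:
    """Spell a DNA codon in RNA (T -> U) for presentation."""
    return codon.replace("T", "U")


def to_dna(codon: str) -> str:
    """Normalize an RNA-spelled codon to the internal DNA alphabet."""
    return codon.upper().replace("U", "T")
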