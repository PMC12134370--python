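"""Small sequence utilities shared across modules."""

from __future__ import annotations

from Bio.Seq import Seq

#: IUPAC nucleotide codes -> the set of concrete bases each matches
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


def revcomp(seq: str) -> str:
    """Reverse complement (DNA, IUPAC-aware)."""
    return str(Seq(seq).reverse_complement())


def complement(seq: str) -> str:
    return str(Seq(seq).complement())


def to_rna(seq: str) -> str:
    """DNA -> RNA (T->U), same orientation."""
    return seq.replace("T", "U").replace("t", "u")


def to_dna(seq: str) -> str:
    """RNA -> DNA (U->T), same orientation."""
    return seq.replace("U", "T").replace("u", "t")


def gc_percent(seq: str) -> float:
    """(G+C)/length * 100; ambiguity codes not counted as G/C."""
    if not seq:
        return 0.0
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)
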