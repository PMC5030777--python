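"""Shared nucleotide-sequence helpers.

All internal comparisons run in DNA space (U mapped to T, uppercase);
writers preserve the alphabet of whatever reference they were given.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

IUPAC_DNA_RNA = set("ACGTUNRYSWKMBDHV")


def to_dna(seq: str) -> str:
    """Uppercase and map U->T for comparison."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_iupac(seq: str) -> bool:
    return bool(seq) and set(seq.upper()) <= IUPAC_DNA_RNA


# Watson-Crick partners in DNA space.
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
# miRNA:target wobble pairs (G:U and U:G), DNA space.
_WOBBLE = {("G", "T"), ("T", "G")}


def pairs_wc(a: str, b: str) -> bool:
    return (to_dna(a), to_dna(b)) in _WC


def pairs_wobble(a: str, b: str) -> bool:
    return (to_dna(a), to_dna(b)) in _WOBBLE
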