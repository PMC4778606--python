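"""Small sequence utilities shared across the pipeline.

All coordinates in this package are 1-based inclusive on the forward genome
strand; sequences reported for minus-strand features are reverse complements
of the forward-strand slice.
"""

from __future__ import annotations

_DNA_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_RNA_COMP = str.maketrans("ACGUNacgun", "UGCANugcan")


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def to_rna(seq: str) -> str:
    """DNA -> RNA (T->U), uppercased."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    """RNA -> DNA (U->T), uppercased."""
    return seq.upper().replace("U", "T")


def gc_percent(seq: str) -> float:
    """GC content in percent of sequence length."""
    if not seq:
        return 0.0
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def extract(chrom_seq: str, start: int, end: int, strand: str = "+") -> str:
    """Extract a 1-based inclusive DNA slice; minus strand is reverse complemented."""
    sub = chrom_seq[start - 1 : end]
    if strand == "-":
        sub = revcomp_dna(sub)
    return sub
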