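"""Ungapped short-read alignment against a genome with a mismatch budget.

Replicates bowtie-style end-to-end alignment with 0-2 mismatches and no
gaps.  Search uses pigeonhole seeding: a read is partitioned into
``budget + 1`` disjoint seed windows, of which at least one must match the
genome exactly for any placement with at most ``budget`` mismatches, so
exact k-mer lookup of every window enumerates all candidate placements.
This makes the search exact for ungapped alignment.

Coordinates are 1-based inclusive on the forward strand; a minus-strand hit
means the reverse complement of the read matches the forward genome there.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from ._seq import revcomp_dna
from .preprocess import CollapsedRead

DEFAULT_SEED_LEN = 5


@dataclass(frozen=True)
class AlignmentHit:
    """An ungapped full-length placement of a read on the genome."""

    read_id: str
    seq: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    mismatches: int
    count: int = 1

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.seq):
            raise ValueError("hit span must equal read length")


class GenomeIndex:
    """Exact k-mer lookup table over the forward strand of every chromosome."""

    def __init__(self, genome: Mapping[str, str], seed_len: int = DEFAULT_SEED_LEN):
        self.seed_len = seed_len
        self.genome = {c: s.upper() for c, s in genome.items()}
        self._table: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom in sorted(self.genome):
            seq = self.genome[chrom]
            for i in range(len(seq) - seed_len + 1):
                self._table[seq[i : i + seed_len]].append((chrom, i))

    @classmethod
    def from_fasta(cls, path: str, seed_len: int = DEFAULT_SEED_LEN) -> "GenomeIndex":
        genome = {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
        return cls(genome, seed_len)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """All (chrom, 1-based position) occurrences of a seed_len-mer on +."""
        if len(kmer) != self.seed_len:
            raise ValueError(f"query must be exactly {self.seed_len} nt")
        return [(c, p + 1) for c, p in self._table.get(kmer.upper(), ())]


def _hamming_within(a: str, b: str, budget: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > budget:
                return -1
    return mm


def align_read(read: CollapsedRead | str, index: GenomeIndex, budget: int = 2,
               read_id: str = "read") -> list[AlignmentHit]:
    """All best-stratum ungapped hits of a read, at most ``budget`` mismatches.

    Every placement achieving the minimum mismatch count (within budget) is
    returned, ordered by (mismatches, chrom, start, strand).
    """
    if isinstance(read, CollapsedRead):
        seq, count = read.seq.upper(), read.count
    else:
        seq, count = read.upper(), 1
    k = index.seed_len
    n = len(seq)
    if n < k * (budget + 1):
        raise ValueError(
            f"read of {n} nt too short for {budget}-mismatch pigeonhole "
            f"seeding with seed_len={k}")
    if budget not in (0, 1, 2):
        raise ValueError("mismatch budget must be 0, 1 or 2")

    seen: set[tuple[str, int, str]] = set()
    hits: list[AlignmentHit] = []
    offsets = [i * n // (budget + 1) for i in range(budget + 1)]
    for strand, query in (("+", seq), ("-", revcomp_dna(seq))):
        for off in offsets:
            for chrom, pos in index.lookup(query[off : off + k]):
                start0 = pos - 1 - off
                if start0 < 0 or start0 + n > len(index.genome[chrom]):
                    continue
                key = (chrom, start0, strand)
                if key in seen:
                    continue
                seen.add(key)
                mm = _hamming_within(index.genome[chrom][start0 : start0 + n],
                                     query, budget)
                if mm >= 0:
                    hits.append(AlignmentHit(read_id, seq, chrom, start0 + 1,
                                             start0 + n, strand, mm, count))
    if not hits:
        return []
    best = min(h.mismatches for h in hits)
    hits = [h for h in hits if h.mismatches == best]
    hits.sort(key=lambda h: (h.mismatches, h.chrom, h.start, h.strand))
    return hits


def align_library(reads: Sequence[CollapsedRead], index: GenomeIndex,
                  budget: int = 2) -> dict[str, list[AlignmentHit]]:
    """Align every collapsed read; returns read_id -> best-stratum hits.

    Read ids are ``seq<i>`` in input order (matching the collapsed FASTA
    header convention); unaligned reads map to an empty list.
    """
    return {f"seq{i}": align_read(r, index, budget, read_id=f"seq{i}")
            for i, r in enumerate(reads, 1)}


def alignment_rate(hits_by_read: Mapping[str, Sequence[AlignmentHit]]
                   ) -> tuple[float, int, int]:
    """Fraction of distinct reads with >= 1 hit, plus numerator/denominator."""
    if not hits_by_read:
        raise ValueError("alignment rate undefined for an empty library")
    aligned = sum(1 for h in hits_by_read.values() if h)
    return aligned / len(hits_by_read), aligned, len(hits_by_read)


def write_hits_tsv(hits: Iterable[AlignmentHit], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstart\tend\tstrand\tmismatches\tcount\n")
        for h in hits:
            fh.write(f"{h.read_id}\t{h.chrom}\t{h.start}\t{h.end}\t"
                     f"{h.strand}\t{h.mismatches}\t{h.count}\n")


def write_sam(hits: Iterable[AlignmentHit], index: GenomeIndex, path: str) -> None:
    """Minimal SAM export (flag 16 for minus strand, 1-based POS)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom in sorted(index.genome):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{len(index.genome[chrom])}\n")
        for h in hits:
            flag = 16 if h.strand == "-" else 0
            seq = revcomp_dna(h.seq) if h.strand == "-" else h.seq
            fh.write(f"{h.read_id}\t{flag}\t{h.chrom}\t{h.start}\t255\t"
                     f"{len(h.seq)}M\t*\t0\t0\t{seq}\t*\tNM:i:{h.mismatches}\n")
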