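"""Small RNA-seq read preprocessing: adapter/quality trimming, length
filtering, collapsing identical reads, and library statistics.

The stage mirrors standard small-RNA QC: 3' adapter removal (the insert is
shorter than the read, so the sequencer runs into the adapter), removal of
low-quality 3' tails, rejection of ambiguous reads, a 16-30 nt length
window, and collapsing of identical sequences into one record with an
occurrence count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO

from Bio import SeqIO

MIN_LEN = 16
MAX_LEN = 30

#: widely used Illumina TruSeq small-RNA 3' adapter, overridable everywhere
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass(frozen=True)
class CollapsedRead:
    """A unique read sequence with its occurrence count in one library."""

    seq: str
    count: int

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("collapsed read count must be >= 1")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class LibraryStats:
    total_sequences: int = 0
    distinct_sequences: int = 0
    total_after_length_filter: int = 0
    distinct_after_length_filter: int = 0
    #: read length -> number of distinct sequences of that length (after filtering)
    length_histogram: dict[int, int] = field(default_factory=dict)


def trim_adapter(seq: str, qual: Optional[Sequence[int]], adapter: str,
                 min_overlap: int = 5, max_mismatch_frac: float = 0.1
                 ) -> tuple[str, Optional[Sequence[int]]]:
    """Remove the 3' adapter starting at the leftmost adapter-prefix match.

    A match at read position ``p`` aligns ``adapter[:n]`` with the read
    suffix (``n`` limited by read end, i.e. partial adapters at the 3' end
    count), requires ``n >= min_overlap`` and at most
    ``max_mismatch_frac * n`` mismatches.  Reads without a match are
    returned unchanged.
    """
    if min_overlap < 5:
        raise ValueError("min_overlap must be >= 5")
    n_read = len(seq)
    su, au = seq.upper(), adapter.upper()
    for p in range(0, n_read - min_overlap + 1):
        n = min(len(au), n_read - p)
        allowed = int(max_mismatch_frac * n)
        mm = 0
        for a, b in zip(su[p : p + n], au[:n]):
            if a != b:
                mm += 1
                if mm > allowed:
                    break
        else:
            return seq[:p], (qual[:p] if qual is not None else None)
    return seq, qual


def quality_filter(seq: str, qual: Sequence[int], min_mean_q: float = 20.0,
                   trim_tail_below: int = 20
                   ) -> Optional[tuple[str, Sequence[int]]]:
    """Trim low-quality 3' tail bases; reject low-mean-quality or N reads."""
    end = len(seq)
    while end > 0 and qual[end - 1] < trim_tail_below:
        end -= 1
    seq, qual = seq[:end], qual[:end]
    if not seq:
        return None
    if "N" in seq.upper():
        return None
    if sum(qual) / len(qual) < min_mean_q:
        return None
    return seq, qual


def length_filter(seqs: Iterable[str], min_len: int = MIN_LEN,
                  max_len: int = MAX_LEN) -> list[str]:
    """Keep reads with min_len <= length <= max_len (both bounds inclusive)."""
    return [s for s in seqs if min_len <= len(s) <= max_len]


def collapse(seqs: Iterable[str]) -> list[CollapsedRead]:
    """Collapse identical sequences; order by count desc, then lexicographic."""
    counts = Counter(s.upper() for s in seqs)
    return [CollapsedRead(seq, n)
            for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]


def summarize(before: Sequence[str], after: Sequence[str]) -> LibraryStats:
    """Library statistics before/after filtering plus the distinct-sequence
    length histogram of the filtered library."""
    hist = Counter(len(s) for s in {s.upper() for s in after})
    return LibraryStats(
        total_sequences=len(before),
        distinct_sequences=len({s.upper() for s in before}),
        total_after_length_filter=len(after),
        distinct_after_length_filter=len({s.upper() for s in after}),
        length_histogram=dict(sorted(hist.items())),
    )


def preprocess_library(fastq: str | TextIO, adapter: str = DEFAULT_ADAPTER,
                       min_overlap: int = 5, max_mismatch_frac: float = 0.1,
                       min_mean_q: float = 20.0, trim_tail_below: int = 20,
                       min_len: int = MIN_LEN, max_len: int = MAX_LEN,
                       ) -> tuple[list[CollapsedRead], LibraryStats]:
    """Full preprocessing chain for one FASTQ library.

    Returns the collapsed, length-filtered reads and Table-1-style
    statistics (raw totals vs post-filter totals, length histogram).
    """
    raw: list[str] = []
    kept: list[str] = []
    for rec in SeqIO.parse(fastq, "fastq"):
        seq = str(rec.seq)
        qual = rec.letter_annotations["phred_quality"]
        raw.append(seq)
        trimmed = quality_filter(seq, qual, min_mean_q, trim_tail_below)
        if trimmed is None:
            continue
        seq, qual = trim_adapter(*trimmed, adapter, min_overlap, max_mismatch_frac)
        if min_len <= len(seq) <= max_len:
            kept.append(seq.upper())
    return collapse(kept), summarize(raw, kept)


def write_collapsed_fasta(reads: Sequence[CollapsedRead], path: str) -> None:
    """Write collapsed reads as FASTA with ``seq<id>_x<count>`` headers."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads, 1):
            fh.write(f">seq{i}_x{r.count}\n{r.seq}\n")


def read_collapsed_fasta(path: str) -> list[CollapsedRead]:
    reads = []
    for rec in SeqIO.parse(path, "fasta"):
        count = int(rec.id.rsplit("_x", 1)[1])
        reads.append(CollapsedRead(str(rec.seq).upper(), count))
    return reads


def write_stats_tsv(stats: LibraryStats, path: str) -> None:
    rows = [
        ("total_sequences", stats.total_sequences),
        ("distinct_sequences", stats.distinct_sequences),
        ("total_sequences_after_length_filter", stats.total_after_length_filter),
        ("distinct_sequences_after_length_filter", stats.distinct_after_length_filter),
    ]
    with open(path, "w") as fh:
        fh.write("statistic\tvalue\n")
        for k, v in rows:
            fh.write(f"{k}\t{v}\n")


def write_length_histogram_tsv(stats: LibraryStats, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("length\tdistinct_sequences\n")
        for length, n in stats.length_histogram.items():
            fh.write(f"{length}\t{n}\n")
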