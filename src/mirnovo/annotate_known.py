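"""Known-miRNA and ncRNA annotation of genome-aligned reads.

Builds the deduplicated multi-species mature-miRNA database (identical
sequences collapse to one entry keeping every species/name provenance),
then annotates each aligned read by Hamming-distance matching with a small
end-overhang tolerance, applying the precedence

    target-species miRNA > other-species miRNA > ncRNA families > mRNA
    > unannotated

so that a read is assigned to the ncRNA or mRNA tiers only when it fails
the miRNA tier, mirroring a pipeline that screens miRBase first and Rfam /
RefSeq afterwards.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

from ._seq import to_rna
from .preprocess import CollapsedRead


@dataclass
class UniqueMirnaDB:
    """Mature sequence -> provenance set; deduplicated across species."""

    records: dict[str, set[tuple[str, str]]]  # RNA seq -> {(species, name)}
    n_input: int
    n_unique: int


@dataclass(frozen=True)
class AnnotatedRead:
    read: CollapsedRead
    category: str  # target_species_miRNA | other_species_miRNA | ncRNA:<fam> | mRNA | unannotated
    matched_name: Optional[str] = None
    matched_mismatches: Optional[int] = None
    all_names: tuple[str, ...] = field(default_factory=tuple)


def parse_mirbase_header(header: str) -> tuple[str, str]:
    """``dre-miR-182-5p ...`` -> (species ``dre``, name ``dre-miR-182-5p``)."""
    name = header.split()[0]
    return name.split("-", 1)[0].lower(), name


def build_unique_db(records: Iterable[tuple[str, str]] | str) -> UniqueMirnaDB:
    """Deduplicate a multi-species mature-miRNA FASTA (path or pairs).

    Identical sequences (after T->U) merge into one entry whose provenance
    preserves every (species, name) it appeared under.
    """
    if isinstance(records, str):
        records = [(rec.description, str(rec.seq)) for rec in SeqIO.parse(records, "fasta")]
    table: dict[str, set[tuple[str, str]]] = defaultdict(set)
    n_input = 0
    for header, seq in records:
        n_input += 1
        table[to_rna(seq)].add(parse_mirbase_header(header))
    return UniqueMirnaDB(dict(table), n_input, len(table))


def _best_overhang_match(read_rna: str, ref_rna: str, max_mismatch: int,
                         max_overhang: int = 2) -> Optional[int]:
    """Min Hamming distance matching the shorter sequence inside the longer,
    allowing a total length difference (end overhang) of <= max_overhang."""
    short, long_ = sorted((read_rna, ref_rna), key=len)
    over = len(long_) - len(short)
    if over > max_overhang:
        return None
    best: Optional[int] = None
    for off in range(over + 1):
        mm = sum(1 for a, b in zip(short, long_[off : off + len(short)]) if a != b)
        if mm <= max_mismatch and (best is None or mm < best):
            best = mm
    return best


def annotate(reads: Sequence[CollapsedRead], db: UniqueMirnaDB,
             target_species: str = "dre",
             decoys: Sequence[tuple[str, str]] = (),
             mrna: Sequence[str] = (),
             max_mismatch: int = 2) -> list[AnnotatedRead]:
    """Annotate aligned reads with the tiered best-hit rule.

    ``decoys`` are (family, sequence) pairs (e.g. ``("tRNA", ...)``);
    ``mrna`` is a plain sequence list.  Within the miRNA tier the best hit
    has fewest mismatches; ties prefer the target species, then the
    lexicographically first name (all tied names are retained).
    """
    out: list[AnnotatedRead] = []
    decoys_rna = [(fam, to_rna(s)) for fam, s in decoys]
    mrna_rna = [to_rna(s) for s in mrna]
    for read in reads:
        rna = to_rna(read.seq)
        # miRNA tier
        best_mm: Optional[int] = None
        matches: list[tuple[str, str, int]] = []  # (species, name, mm)
        for ref, provenance in db.records.items():
            mm = _best_overhang_match(rna, ref, max_mismatch)
            if mm is None:
                continue
            for species, name in provenance:
                matches.append((species, name, mm))
            if best_mm is None or mm < best_mm:
                best_mm = mm
        if best_mm is not None:
            tied = sorted({(sp, nm) for sp, nm, mm in matches if mm == best_mm},
                          key=lambda t: (t[0] != target_species, t[1]))
            names = tuple(nm for _, nm in tied)
            category = ("target_species_miRNA" if tied[0][0] == target_species
                        else "other_species_miRNA")
            out.append(AnnotatedRead(read, category, names[0], best_mm, names))
            continue
        # ncRNA tier: read is a fragment of a longer decoy -> substring match
        fam_hit = None
        for fam, ref in decoys_rna:
            if _fragment_matches(rna, ref, max_mismatch):
                fam_hit = fam
                break
        if fam_hit is not None:
            out.append(AnnotatedRead(read, f"ncRNA:{fam_hit}", fam_hit, None))
            continue
        if any(_fragment_matches(rna, ref, max_mismatch) for ref in mrna_rna):
            out.append(AnnotatedRead(read, "mRNA"))
            continue
        out.append(AnnotatedRead(read, "unannotated"))
    return out


def _fragment_matches(read: str, ref: str, max_mismatch: int) -> bool:
    """Read occurs within ref (any offset) with <= max_mismatch mismatches."""
    if len(read) > len(ref):
        return _best_overhang_match(read, ref, max_mismatch) is not None
    for off in range(len(ref) - len(read) + 1):
        if sum(1 for a, b in zip(read, ref[off:]) if a != b) <= max_mismatch:
            return True
    return False


def chromosome_distribution(mirna_chrom_pairs: Iterable[tuple[str, str]]
                            ) -> dict[str, int]:
    """chrom -> number of distinct miRNA names with a hit there.

    A miRNA hit on two chromosomes counts once per chromosome.
    """
    per_chrom: dict[str, set[str]] = defaultdict(set)
    for chrom, name in mirna_chrom_pairs:
        per_chrom[chrom].add(name)
    return {c: len(s) for c, s in sorted(per_chrom.items())}


def compare_libraries(sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Disjoint Venn-region counts for the given libraries (7 regions for 3).

    Keys are sorted tuples of library names whose *exclusive* intersection
    the count refers to; regions are disjoint and sum to the union size.
    """
    names = sorted(sets)
    regions: dict[tuple[str, ...], int] = {}
    for r in range(len(names), 0, -1):
        for combo in combinations(names, r):
            inter = set.intersection(*(sets[n] for n in combo))
            for other in names:
                if other not in combo:
                    inter = inter - sets[other]
            regions[combo] = len(inter)
    return regions


def category_summary(annotated: Sequence[AnnotatedRead]) -> dict[str, int]:
    """Distinct-read counts per annotation category."""
    counts: dict[str, int] = defaultdict(int)
    for a in annotated:
        counts[a.category] += 1
    return dict(sorted(counts.items()))


def load_family_fasta(path: str) -> list[tuple[str, str]]:
    """Decoy FASTA with ``family=<fam>`` tags in descriptions."""
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        fam = "unknown"
        for tok in rec.description.split():
            if tok.startswith("family="):
                fam = tok.split("=", 1)[1]
        out.append((fam, str(rec.seq)))
    return out
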