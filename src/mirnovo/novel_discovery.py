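"""Novel miRNA discovery from unannotated aligned reads.

Mireap-style procedure: unannotated reads (mapped with zero mismatches)
are clustered into genomic loci; around each locus representative two
precursor windows are excised (the mature may sit on either arm); each
window is folded and evaluated against the hairpin criteria — single
stem-loop, mature on one arm, a star arm with bounded loop spacing,
enough mature base pairs, bounded bulges, bounded duplex asymmetry,
bounded mature/star mismatches and a precursor free energy at or below
-18 kcal/mol.  Surviving precursors are ranked by the minimal folding
free energy index

    MFEI = MFE / precursor_length * 100 / GC%

and only candidates whose |MFEI| exceeds 0.85 (strict) are reported, in a
table mirroring the standard per-tissue novel-miRNA report.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import pandas as pd

from ._seq import gc_percent, revcomp_dna, to_rna
from .genome_align import AlignmentHit
from .rna_fold import FoldResult, fold, is_single_hairpin


@dataclass(frozen=True)
class CriteriaConfig:
    """Hairpin-candidate acceptance parameters (Mireap-style defaults)."""

    min_mature_len: int = 18
    max_mature_len: int = 26
    min_ref_len: int = 20       # star ("reference") length bounds
    max_ref_len: int = 24
    uniqueness: int = 20        # reads mapping to more loci are repeats
    max_precursor_energy: float = -18.0  # kcal/mol
    min_space: int = 5          # mature..star spacing (loop side)
    max_space: int = 35
    min_mature_pairs: int = 14
    max_mature_bulge: int = 4
    max_duplex_asymmetry: int = 5
    flank: int = 100
    max_mature_star_mismatches: int = 6
    mfei_threshold: float = 0.85
    min_read_count: int = 100
    merge_gap: int = 30


@dataclass
class ReadCluster:
    chrom: str
    strand: str
    start: int
    end: int
    hits: list[AlignmentHit]

    @property
    def total_count(self) -> int:
        return sum(h.count for h in self.hits)

    @property
    def representative(self) -> AlignmentHit:
        return max(self.hits,
                   key=lambda h: (h.count, len(h.seq), _revlex(h.seq)))


def _revlex(s: str):
    # max() with this key picks the lexicographically *smallest* on ties
    return tuple(-ord(c) for c in s)


@dataclass
class HairpinCandidate:
    name: str
    chrom: str
    precursor_start: int  # 1-based inclusive, forward strand
    precursor_end: int
    strand: str
    precursor_seq: str  # RNA, transcript sense
    mature_seq: str
    star_seq: str
    read_count: int
    gc_percent: float
    mfe: float
    mfei: float
    structure: str = ""
    diagnostics: dict[str, bool] = field(default_factory=dict)

    @property
    def precursor_len(self) -> int:
        return len(self.precursor_seq)

    @property
    def mature_len(self) -> int:
        return len(self.mature_seq)


@dataclass
class Rejection:
    chrom: str
    strand: str
    window_start: int
    window_end: int
    failed_criteria: tuple[str, ...]


def cluster_loci(hits: Sequence[AlignmentHit],
                 merge_gap: int = 30) -> list[ReadCluster]:
    """Merge hits on the same chrom+strand within ``merge_gap`` nt."""
    by_key: dict[tuple[str, str], list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        by_key[(h.chrom, h.strand)].append(h)
    clusters: list[ReadCluster] = []
    for (chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda h: (h.start, h.end))
        current: list[AlignmentHit] = []
        for h in group:
            if current and h.start > max(x.end for x in current) + merge_gap:
                clusters.append(ReadCluster(chrom, strand,
                                            min(x.start for x in current),
                                            max(x.end for x in current), current))
                current = []
            current.append(h)
        if current:
            clusters.append(ReadCluster(chrom, strand,
                                        min(x.start for x in current),
                                        max(x.end for x in current), current))
    clusters.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return clusters


def filter_repeats(hits: Sequence[AlignmentHit],
                   uniqueness: int = 20) -> list[AlignmentHit]:
    """Drop reads placed at more than ``uniqueness`` genomic loci."""
    n_loci: dict[str, int] = defaultdict(int)
    for h in hits:
        n_loci[h.read_id] += 1
    return [h for h in hits if n_loci[h.read_id] <= uniqueness]


def excise_windows(cluster: ReadCluster, genome: Mapping[str, str],
                   flank: int = 100, anchor_pad: int = 15
                   ) -> list[tuple[str, int, int, int]]:
    """Candidate precursor windows around the cluster representative.

    The examined genomic span is mature +- ``flank`` (clipped to the
    chromosome); two windows are returned, one extending mostly downstream
    (mature on the 5' arm) and one mostly upstream (3' arm).  Each entry is
    ``(window_rna, mature_offset0, genomic_start, genomic_end)`` with the
    window in transcript orientation (minus-strand windows reverse
    complemented) and the mature offset 0-based within it.
    """
    rep = cluster.representative
    chrom_seq = genome[cluster.chrom]
    n = len(chrom_seq)
    windows = []
    for gs, ge in ((rep.start - anchor_pad, rep.end + flank),
                   (rep.start - flank, rep.end + anchor_pad)):
        gs, ge = max(1, gs), min(n, ge)
        sub = chrom_seq[gs - 1 : ge]
        if cluster.strand == "-":
            sub = revcomp_dna(sub)
            off = ge - rep.end
        else:
            off = rep.start - gs
        windows.append((to_rna(sub), off, gs, ge))
    return windows


def compute_mfei(mfe: float, precursor_len: int, gc_pct: float) -> float:
    """MFEI = MFE / precursor_length * 100 / GC%; sign follows the MFE."""
    if gc_pct <= 0:
        raise ValueError("GC percent must be positive")
    if precursor_len <= 0:
        raise ValueError("precursor length must be positive")
    return mfe / precursor_len * 100.0 / gc_pct


def _longest_unpaired_run(partner: Sequence[int], lo: int, hi: int) -> int:
    run = best = 0
    for k in range(lo, hi + 1):
        run = run + 1 if partner[k] < 0 else 0
        best = max(best, run)
    return best


def _star_cluster(partners: Sequence[int], max_gap: int = 8
                  ) -> tuple[list[int], int, int]:
    """Largest contiguous cluster of mature pairing partners.

    Stray mature bases occasionally pair into an unrelated helix; the star
    arm is taken as the biggest run of partners with inter-partner gaps of
    at most ``max_gap`` nt, and the strays are treated as unpaired.
    """
    ordered = sorted(partners)
    best: list[int] = []
    current: list[int] = []
    for p in ordered:
        if current and p - current[-1] > max_gap:
            if len(current) > len(best):
                best = current
            current = []
        current.append(p)
    if len(current) > len(best):
        best = current
    return best, best[0], best[-1]


def evaluate(window_rna: str, mature_offset: int, mature_len: int,
             config: CriteriaConfig = CriteriaConfig(),
             ) -> tuple[Optional[dict], list[str]]:
    """Apply the full criterion set to one excised window.

    Returns ``(result, failed)``: ``result`` holds the trimmed precursor
    (0-based slice within the window), its fold, star span and diagnostics
    when every criterion passes, else ``None`` with the failed criteria.
    """
    diagnostics: dict[str, bool] = {}
    failed: list[str] = []

    def check(name: str, ok: bool) -> bool:
        diagnostics[name] = ok
        if not ok:
            failed.append(name)
        return ok

    m0, m1 = mature_offset, mature_offset + mature_len - 1
    if not check("mature_length",
                 config.min_mature_len <= mature_len <= config.max_mature_len):
        return None, failed
    if len(window_rna) < 2 * mature_len + config.min_space or m1 >= len(window_rna):
        check("window_length", False)
        return None, failed
    diagnostics["window_length"] = True

    wfold = fold(window_rna)
    partners = wfold.partner
    mature_partners = [partners[k] for k in range(m0, m1 + 1) if partners[k] >= 0]
    if not check("min_mature_pairs",
                 len(mature_partners) >= config.min_mature_pairs):
        return None, failed
    cluster, star_lo, star_hi = _star_cluster(mature_partners)
    if not check("min_mature_pairs", len(cluster) >= config.min_mature_pairs):
        return None, failed
    if not check("mature_star_disjoint", star_lo > m1 or star_hi < m0):
        return None, failed

    # trim to the minimal hairpin-containing subwindow and refold
    p0, p1 = min(m0, star_lo), max(m1, star_hi)
    pre_rna = window_rna[p0 : p1 + 1]
    pfold = fold(pre_rna)
    single, loop_span = is_single_hairpin(pfold)
    if not check("single_hairpin", single):
        return None, failed
    nm0, nm1 = m0 - p0 + 1, m1 - p0 + 1  # 1-based in precursor

    pp = pfold.partner
    mp = [pp[k] for k in range(nm0 - 1, nm1) if pp[k] >= 0]
    if not check("min_mature_pairs_precursor",
                 len(mp) >= config.min_mature_pairs):
        return None, failed
    duplex, s_lo, s_hi = _star_cluster(mp)
    if not check("min_mature_pairs_precursor",
                 len(duplex) >= config.min_mature_pairs):
        return None, failed
    # mature sits in one arm iff its paired bases all reach across the
    # loop to one side; an unpaired mature tail inside the terminal loop
    # is tolerated (common at wobbled stem ends)
    if s_lo > nm1 - 1:
        arm = "5p"
    elif s_hi < nm0 - 1:
        arm = "3p"
    else:
        arm = "spanning"
    if not check("mature_one_arm", arm in ("5p", "3p")):
        return None, failed
    star_len = s_hi - s_lo + 1
    check("star_length", config.min_ref_len <= star_len <= config.max_ref_len)
    # space between mature and star across the loop
    space = (s_lo - (nm1 - 1) - 1) if arm == "5p" else ((nm0 - 1) - s_hi - 1)
    check("mature_star_space", config.min_space <= space <= config.max_space)
    check("max_mature_bulge",
          _longest_unpaired_run(pp, nm0 - 1, nm1 - 1) <= config.max_mature_bulge)
    unpaired_mature = mature_len - len(duplex)
    unpaired_star = star_len - len(duplex)
    check("max_duplex_asymmetry",
          abs(unpaired_mature - unpaired_star) <= config.max_duplex_asymmetry)
    check("max_mature_star_mismatches",
          unpaired_mature <= config.max_mature_star_mismatches)
    # "no break": every paired mature base must pair into the star segment
    check("no_break", all(s_lo <= q <= s_hi for q in mp))
    check("precursor_energy", pfold.mfe <= config.max_precursor_energy)

    if failed:
        return None, failed
    star_rna = pre_rna[s_lo : s_hi + 1]
    if arm == "3p":
        # keep star in transcript orientation (it precedes the mature)
        pass
    return ({"precursor_slice": (p0, p1), "fold": pfold,
             "mature_span": (nm0, nm1), "star_span": (s_lo + 1, s_hi + 1),
             "star_rna": star_rna, "diagnostics": diagnostics}, [])


def discover(hits: Sequence[AlignmentHit], genome: Mapping[str, str],
             config: CriteriaConfig = CriteriaConfig(),
             ) -> tuple[list[HairpinCandidate], list[Rejection]]:
    """Run clustering, excision and evaluation over unannotated hits.

    Only zero-mismatch hits are used (strict re-mapping for the discovery
    stage); clusters below ``min_read_count`` total reads are skipped.
    For each locus the best-energy window that passes all criteria yields
    one candidate.
    """
    strict = [h for h in hits if h.mismatches == 0]
    strict = filter_repeats(strict, config.uniqueness)
    candidates: list[HairpinCandidate] = []
    rejections: list[Rejection] = []
    for cluster in cluster_loci(strict, config.merge_gap):
        if cluster.total_count < config.min_read_count:
            continue
        rep = cluster.representative
        best: Optional[HairpinCandidate] = None
        window_failures: list[str] = []
        for window_rna, off, gs, ge in excise_windows(cluster, genome,
                                                      config.flank):
            result, failed = evaluate(window_rna, off, len(rep.seq), config)
            if result is None:
                window_failures.extend(failed)
                continue
            p0, p1 = result["precursor_slice"]
            pfold: FoldResult = result["fold"]
            # map the trimmed precursor back to forward-strand coordinates
            if cluster.strand == "+":
                pre_start, pre_end = gs + p0, gs + p1
            else:
                pre_start, pre_end = ge - p1, ge - p0
            gc = gc_percent(pfold.seq)
            mfei = compute_mfei(pfold.mfe, len(pfold.seq), gc)
            cand = HairpinCandidate(
                name="", chrom=cluster.chrom, precursor_start=pre_start,
                precursor_end=pre_end, strand=cluster.strand,
                precursor_seq=pfold.seq, mature_seq=to_rna(rep.seq),
                star_seq=result["star_rna"], read_count=cluster.total_count,
                gc_percent=gc, mfe=pfold.mfe,
                mfei=mfei, structure=pfold.structure,
                diagnostics=result["diagnostics"])
            if best is None or cand.mfe < best.mfe:
                best = cand
        if best is not None:
            candidates.append(best)
        else:
            rejections.append(Rejection(
                cluster.chrom, cluster.strand, cluster.start, cluster.end,
                tuple(dict.fromkeys(window_failures)) or ("window_length",)))
    return _dedupe_overlapping(candidates), rejections


def _dedupe_overlapping(candidates: list[HairpinCandidate]
                        ) -> list[HairpinCandidate]:
    """Collapse candidates with overlapping precursor spans on one chrom.

    A perfect inverted repeat maps its mature read onto both strands of the
    same locus (the minus-strand placement is the star arm), producing two
    mirror candidates; keep the lower-energy one (ties: plus strand).
    """
    kept: list[HairpinCandidate] = []
    for cand in sorted(candidates, key=lambda c: (c.mfe, c.strand != "+")):
        clash = any(k.chrom == cand.chrom
                    and not (cand.precursor_end < k.precursor_start
                             or cand.precursor_start > k.precursor_end)
                    for k in kept)
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda c: (c.chrom, c.precursor_start, c.strand))
    return kept


def filter_mfei(candidates: Sequence[HairpinCandidate],
                threshold: float = 0.85) -> list[HairpinCandidate]:
    """Keep candidates with |MFEI| strictly greater than the threshold."""
    return [c for c in candidates if abs(c.mfei) > threshold]


def name_and_report(candidates_per_tissue: Mapping[str, Sequence[HairpinCandidate]],
                    prefix: str = "Dre-mir-nov") -> pd.DataFrame:
    """Deterministically numbered per-tissue report table.

    Ordering: tissue (input order), then descending read count, then
    coordinates; names are ``<prefix><N>`` with N running over the whole
    report.
    """
    rows = []
    counter = 0
    for tissue, cands in candidates_per_tissue.items():
        ordered = sorted(cands, key=lambda c: (-c.read_count, c.chrom,
                                               c.precursor_start, c.strand))
        for c in ordered:
            counter += 1
            named = replace(c, name=f"{prefix}{counter}")
            rows.append({
                "tissue": tissue, "chromosome": named.chrom,
                "name": named.name, "sequence": named.mature_seq,
                "mirna_length": named.mature_len,
                "read_count": named.read_count,
                "precursor_start": named.precursor_start,
                "precursor_end": named.precursor_end,
                "strand": named.strand,
                "precursor_length": named.precursor_len,
                "gc_percent": round(named.gc_percent, 2),
                "mfei": round(named.mfei, 2),
            })
    return pd.DataFrame(rows, columns=[
        "tissue", "chromosome", "name", "sequence", "mirna_length",
        "read_count", "precursor_start", "precursor_end", "strand",
        "precursor_length", "gc_percent", "mfei"])


def write_rejections_tsv(rejections: Sequence[Rejection], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstrand\twindow_start\twindow_end\tfailed_criteria\n")
        for r in rejections:
            fh.write(f"{r.chrom}\t{r.strand}\t{r.window_start}\t"
                     f"{r.window_end}\t{','.join(r.failed_criteria)}\n")
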