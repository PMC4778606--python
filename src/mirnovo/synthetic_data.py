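"""Self-contained synthetic small RNA-seq datasets with planted truth.

Generates every input the pipeline consumes — a toy genome with planted
miRNA hairpin loci and decoy ncRNA loci, adaptered FASTQ reads per tissue
with Poisson abundances, a redundant multi-species mature-miRNA database,
and 3'-UTRs with planted antisense target sites — together with truth
tables for evaluating recovery.

Design of the planted loci: a hairpin locus is ``pad + mature + loop +
star + pad`` where the star is the reverse complement of the mature with a
configurable fraction of positions converted to G:U wobbles (or mismatches
where the base cannot wobble, capped at 6).  Loop and pad bases are drawn
from {A, C} so they cannot pair with each other, making the planted
stem-loop the unambiguous minimum-energy structure under any reasonable
nearest-neighbour model.  Decoy loci are tRNA-like cloverleafs (three
short stem-loops), rRNA-like GC-rich random sequences, and plain random
sequences; all are expressed (reads are simulated from a central fragment)
but must fail the hairpin criteria.

All randomness flows through ``numpy.random.default_rng(seed)``; with a
fixed seed every output is byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from ._seq import revcomp_dna, revcomp_rna, to_dna, to_rna
from .energy import PAIR_ID, BASE_CODE
from .preprocess import DEFAULT_ADAPTER

DEFAULT_TISSUES = ("brain", "pineal_dark", "pineal_light")

_RNA = "ACGU"


@dataclass
class HairpinSpec:
    """A constructed precursor with 1-based arm coordinates."""

    precursor: str  # RNA
    mature_start: int
    mature_end: int
    star_start: int
    star_end: int
    n_mismatches: int


@dataclass
class PlantedLocus:
    name: str
    chrom: str
    start: int  # 1-based inclusive, forward strand
    end: int
    strand: str
    kind: str  # known_mirna | novel_mirna | trna_decoy | rrna_decoy | random
    mature_seq: str  # RNA, transcript sense
    star_seq: str  # RNA ("" for decoys)
    loop_len: int
    per_tissue_abundance: dict[str, float]

    def __post_init__(self):
        if any(v < 0 for v in self.per_tissue_abundance.values()):
            raise ValueError("abundance must be >= 0")


@dataclass
class TruthTable:
    loci: list[PlantedLocus]
    adapter_seq: str
    tissue_names: list[str]
    planted_log2fc: dict[str, float] = field(default_factory=dict)

    def log2fc(self, tissue_a: str, tissue_b: str) -> dict[str, float]:
        """Planted log2 abundance ratio A over B per locus (inf for exclusives)."""
        out = {}
        for loc in self.loci:
            a = loc.per_tissue_abundance.get(tissue_a, 0.0)
            b = loc.per_tissue_abundance.get(tissue_b, 0.0)
            if a > 0 and b > 0:
                out[loc.name] = math.log2(a / b)
            elif a > 0:
                out[loc.name] = math.inf
            elif b > 0:
                out[loc.name] = -math.inf
        return out


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_rna(rng, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G U
    return "".join(rng.choice(list(_RNA), size=n, p=p))


def _unpaired_filler(rng, n: int) -> str:
    """Bases from {A, C}: cannot pair among themselves (A:C is no pair)."""
    return "".join(rng.choice(["A", "C"], size=n, p=[0.7, 0.3]))


def make_hairpin_locus(mature: str, loop_len: int, wobble_rate: float,
                       rng_seed, precursor_len: Optional[int] = None,
                       max_mismatches: int = 6) -> HairpinSpec:
    """Build a precursor hairpin around a mature sequence (5' arm).

    The star is the reverse complement of the mature; ``wobble_rate`` of
    its positions are converted to G:U wobbles where the opposing mature
    base allows it (G or U) and to mismatches elsewhere, with at most
    ``max_mismatches`` mismatches ever introduced.  Flanking pads bring the
    precursor to 60-100 nt.
    """
    rng = _rng(rng_seed)
    mat = to_rna(mature)
    if not 18 <= len(mat) <= 26:
        raise ValueError("mature must be 18-26 nt")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    star = list(revcomp_rna(mat))
    n_wob = int(round(wobble_rate * len(star)))
    n_mismatch = 0
    for t in sorted(rng.choice(len(star), size=n_wob, replace=False)):
        opposite = mat[len(mat) - 1 - t]
        if opposite == "G":
            star[t] = "U"  # G:U
        elif opposite == "U":
            star[t] = "G"  # U:G
        elif n_mismatch < max_mismatches:
            bad = [b for b in _RNA
                   if PAIR_ID[BASE_CODE[opposite], BASE_CODE[b]] < 0]
            star[t] = str(rng.choice(bad))
            n_mismatch += 1
    star_seq = "".join(star)
    loop = _unpaired_filler(rng, loop_len)
    core = len(mat) * 2 + loop_len
    if precursor_len is None:
        lo = max(60, core + 6)
        precursor_len = int(rng.integers(lo, 101))
    if not core + 2 <= precursor_len <= 100 + 20:
        raise ValueError("precursor length incompatible with mature/loop")
    pad_total = precursor_len - core
    pad5 = pad_total // 2
    precursor = (_unpaired_filler(rng, pad5) + mat + loop + star_seq
                 + _unpaired_filler(rng, pad_total - pad5))
    m0 = pad5 + 1
    return HairpinSpec(precursor, m0, m0 + len(mat) - 1,
                       m0 + len(mat) + loop_len,
                       m0 + len(mat) + loop_len + len(star_seq) - 1,
                       n_mismatch)


def make_trna_decoy(rng) -> str:
    """tRNA-like cloverleaf: acceptor stem enclosing three stem-loops."""
    def stemloop(stem_n, loop_n):
        stem = random_rna(rng, stem_n, gc=0.6)
        return stem + _unpaired_filler(rng, loop_n) + revcomp_rna(stem)
    acceptor = random_rna(rng, 7, gc=0.6)
    body = (stemloop(4, 8) + _unpaired_filler(rng, 2) + stemloop(5, 7)
            + _unpaired_filler(rng, 2) + stemloop(5, 7))
    return acceptor + body + revcomp_rna(acceptor)


def make_genome(n_chrom: int, chrom_len: int, loci_spec: Sequence[dict],
                rng_seed, tissue_names: Sequence[str] = DEFAULT_TISSUES,
                adapter: str = DEFAULT_ADAPTER,
                ) -> tuple[dict[str, str], TruthTable]:
    """Random genome with planted loci; returns (chrom -> DNA seq, truth).

    Each locus spec is a dict with keys ``kind`` (known_mirna, novel_mirna,
    trna_decoy, rrna_decoy, random), optional ``name``, ``mature`` (RNA;
    generated if absent for hairpin kinds), ``loop_len``, ``wobble_rate``,
    ``gc``, ``strand``, ``chrom``, ``start`` (random placement if absent)
    and ``abundance`` (map tissue -> expected read count).  Background is
    i.i.d. uniform ACGT; overlapping placements raise.
    """
    rng = _rng(rng_seed)
    chroms = [f"chr{i + 1}" for i in range(n_chrom)]
    genome = {c: list("".join(rng.choice(list("ACGT"), size=chrom_len)))
              for c in chroms}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    loci: list[PlantedLocus] = []

    for i, spec in enumerate(loci_spec):
        kind = spec["kind"]
        name = spec.get("name", f"{kind}_{i + 1}")
        loop_len = spec.get("loop_len", int(rng.integers(6, 13)))
        if kind in ("known_mirna", "novel_mirna"):
            mature = spec.get("mature")
            if mature is None:
                mlen = int(rng.choice([21, 22, 23], p=[0.2, 0.5, 0.3]))
                mature = random_rna(rng, mlen, gc=spec.get("gc", 0.5))
            hp = make_hairpin_locus(mature, loop_len,
                                    spec.get("wobble_rate", 0.05), rng)
            insert_rna = hp.precursor
            mature_seq, star_seq = to_rna(mature), hp.precursor[
                hp.star_start - 1 : hp.star_end]
        else:
            if kind == "trna_decoy":
                insert_rna = make_trna_decoy(rng)
            elif kind == "rrna_decoy":
                insert_rna = random_rna(rng, int(rng.integers(100, 130)), gc=0.62)
            elif kind == "random":
                insert_rna = random_rna(rng, int(rng.integers(70, 100)), gc=0.5)
            else:
                raise ValueError(f"unknown locus kind {kind!r}")
            mlen = 22
            off = (len(insert_rna) - mlen) // 2
            mature_seq, star_seq = insert_rna[off : off + mlen], ""
        n = len(insert_rna)
        strand = spec.get("strand", str(rng.choice(["+", "-"])))
        chrom = spec.get("chrom", str(rng.choice(chroms)))
        start = spec.get("start")
        if start is None:
            for _ in range(200):
                cand = int(rng.integers(200, chrom_len - n - 200))
                if all(cand + n - 1 < s or cand > e for s, e in occupied[chrom]):
                    start = cand
                    break
            else:
                raise ValueError("could not place locus without overlap")
        end = start + n - 1
        if start < 1 or end > chrom_len:
            raise ValueError(f"locus {name} outside chromosome bounds")
        if any(not (end < s or start > e) for s, e in occupied[chrom]):
            raise ValueError(f"locus {name} overlaps a previous locus")
        occupied[chrom].append((start, end))
        dna = to_dna(insert_rna)
        if strand == "-":
            dna = revcomp_dna(dna)
        genome[chrom][start - 1 : end] = list(dna)
        loci.append(PlantedLocus(
            name, chrom, start, end, strand, kind, mature_seq, star_seq,
            loop_len, dict(spec.get("abundance", {t: 0.0 for t in tissue_names}))))

    truth = TruthTable([l for l in loci], adapter, list(tissue_names))
    if len(tissue_names) >= 2:
        truth.planted_log2fc = truth.log2fc(tissue_names[0], tissue_names[1])
    return {c: "".join(s) for c, s in genome.items()}, truth


def simulate_reads(truth: TruthTable, tissue: str,
                   adapter: Optional[str] = None, error_rate: float = 0.0,
                   rng_seed=0, read_len: int = 36, end_trim_prob: float = 0.15,
                   quality: int = 38) -> list[tuple[str, str, list[int]]]:
    """Simulate adaptered FASTQ records (id, sequence, phred list) for one
    tissue: Poisson counts around each locus abundance, reads = mature
    (3' trimmed by <= 2 nt with ``end_trim_prob``) + adapter prefix, with
    i.i.d. substitution errors at ``error_rate``."""
    if tissue not in truth.tissue_names:
        raise ValueError(f"unknown tissue {tissue!r}")
    if not 0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be within [0, 0.05]")
    adapter = to_dna(adapter if adapter is not None else truth.adapter_seq)
    if not adapter:
        raise ValueError("adapter must be non-empty")
    rng = _rng(rng_seed)
    reads = []
    for loc in truth.loci:
        lam = loc.per_tissue_abundance.get(tissue, 0.0)
        n = int(rng.poisson(lam)) if lam > 0 else 0
        core_full = to_dna(loc.mature_seq)
        for k in range(n):
            core = core_full
            if rng.random() < end_trim_prob:
                core = core[: len(core) - int(rng.integers(1, 3))]
            seq = (core + adapter)[:read_len]
            if error_rate > 0:
                bases = list(seq)
                for p in np.flatnonzero(rng.random(len(bases)) < error_rate):
                    bases[p] = str(rng.choice([b for b in "ACGT" if b != bases[p]]))
                seq = "".join(bases)
            reads.append((f"{loc.name}:{tissue}:{k + 1}", seq, [quality] * len(seq)))
    return reads


def make_known_db(species_labels: Sequence[str], shared_fraction: float,
                  rng_seed, mature_seqs: Optional[Sequence[str]] = None,
                  n_mirnas: int = 10) -> list[tuple[str, str]]:
    """Redundant multi-species mature-miRNA records (miRBase-style headers).

    The first ``shared_fraction`` of sequences appear under *every* species
    label (identical sequence, distinct headers); the rest only under the
    first (target) species.  Headers follow ``<species>-miR-<id>``.
    """
    rng = _rng(rng_seed)
    if mature_seqs is None:
        mature_seqs = [random_rna(rng, int(rng.choice([21, 22, 23])))
                       for _ in range(n_mirnas)]
    n_shared = int(round(shared_fraction * len(mature_seqs)))
    records = []
    for i, seq in enumerate(mature_seqs):
        labels = species_labels if i < n_shared else species_labels[:1]
        for sp in labels:
            records.append((f"{sp}-miR-{i + 1}", to_rna(seq)))
    return records


def make_utr_targets(mirnas: Mapping[str, str], n_utrs: int,
                     sites_per_utr: int | Sequence[int], rng_seed,
                     utr_len: int = 300, n_wobbles: int = 0,
                     ) -> tuple[dict[str, str], list[tuple[str, str, int]]]:
    """Random UTRs (DNA) with planted antisense miRNA sites.

    A planted site is the reverse complement of a miRNA (with up to
    ``n_wobbles`` G:U-compatible substitutions), embedded at a random
    position.  Returns (utr_id -> sequence, truth [(utr, mirna, 1-based
    position)]).
    """
    rng = _rng(rng_seed)
    if isinstance(sites_per_utr, int):
        sites_per_utr = [sites_per_utr] * n_utrs
    names = sorted(mirnas)
    utrs: dict[str, str] = {}
    truth: list[tuple[str, str, int]] = []
    for u in range(n_utrs):
        utr_id = f"utr{u + 1}"
        seq = list("".join(rng.choice(list("ACGT"), size=utr_len)))
        placed: list[tuple[int, int]] = []
        for _ in range(sites_per_utr[u]):
            m_name = names[int(rng.integers(len(names)))]
            site = list(revcomp_dna(to_dna(mirnas[m_name])))
            for t in sorted(rng.choice(len(site), size=n_wobbles, replace=False)):
                # C->T opposite a G, A->G opposite a T: becomes a G:U pair
                if site[t] == "C":
                    site[t] = "T"
                elif site[t] == "A":
                    site[t] = "G"
            for _try in range(100):
                pos = int(rng.integers(0, utr_len - len(site)))
                if all(pos + len(site) <= s or pos >= e for s, e in placed):
                    break
            else:
                continue
            placed.append((pos, pos + len(site)))
            seq[pos : pos + len(site)] = site
            truth.append((utr_id, m_name, pos + 1))
        utrs[utr_id] = "".join(seq)
    return utrs, truth


def write_fasta(records: Mapping[str, str] | Sequence[tuple[str, str]],
                path: str) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for header, seq in items:
            fh.write(f">{header}\n{seq}\n")


def write_fastq(reads: Sequence[tuple[str, str, list[int]]], path: str) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            q = "".join(chr(33 + v) for v in qual)
            fh.write(f"@{rid}\n{seq}\n+\n{q}\n")


def write_truth_tsv(truth: TruthTable, path: str) -> None:
    with open(path, "w") as fh:
        cols = ["name", "chrom", "start", "end", "strand", "kind", "mature_seq"]
        fh.write("\t".join(cols + list(truth.tissue_names)) + "\n")
        for loc in truth.loci:
            vals = [loc.name, loc.chrom, str(loc.start), str(loc.end),
                    loc.strand, loc.kind, loc.mature_seq]
            vals += [str(loc.per_tissue_abundance.get(t, 0))
                     for t in truth.tissue_names]
            fh.write("\t".join(vals) + "\n")


def _hamming_min(seq: str, others: Sequence[str]) -> int:
    best = 10**9
    for o in others:
        if abs(len(o) - len(seq)) > 2:
            continue
        short, long_ = sorted((seq, o), key=len)
        for off in range(len(long_) - len(short) + 1):
            d = sum(1 for a, b in zip(short, long_[off:]) if a != b)
            best = min(best, d + (len(long_) - len(short)))
    return best


def generate_dataset(outdir: str, rng_seed: int,
                     n_known: int = 12, n_novel: int = 20,
                     n_trna: int = 8, n_rrna: int = 6, n_random: int = 6,
                     n_chrom: int = 3, chrom_len: int = 40_000,
                     n_utrs: int = 15, error_rate: float = 0.0005,
                     tissues: Sequence[str] = DEFAULT_TISSUES,
                     adapter: str = DEFAULT_ADAPTER) -> dict:
    """Generate a complete synthetic study into ``outdir``.

    Conditions: three tissue libraries; known-miRNA loci planted with
    log2 fold changes in {-3, 0, +3} between the first two tissues (plus a
    couple of library-exclusive miRNAs); strongly expressed novel hairpin
    loci (>= 100 expected reads); tRNA/rRNA decoy loci carried in the decoy
    database and plain random expressed loci that are not; UTRs with
    planted antisense sites for the novel matures.  Returns paths, the
    truth table and ancillary truth lists.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    rng = _rng(rng_seed)

    # --- known loci with planted DE between tissues[0] and tissues[1]
    known_matures: list[str] = []
    specs: list[dict] = []
    classes = ["up", "down", "neutral"]
    for i in range(n_known):
        mlen = int(rng.choice([21, 22, 23], p=[0.2, 0.5, 0.3]))
        mature = random_rna(rng, mlen, gc=float(rng.uniform(0.45, 0.6)))
        known_matures.append(mature)
        base = float(rng.uniform(250, 1000))
        cls = classes[i % 3] if i < n_known - 2 else "exclusive"
        if cls == "up":
            ab = {tissues[0]: base * 8, tissues[1]: base}
        elif cls == "down":
            ab = {tissues[0]: base, tissues[1]: base * 8}
        elif cls == "neutral":
            ab = {tissues[0]: base, tissues[1]: base}
        else:  # exclusive to one of the two tissues
            ab = ({tissues[0]: base, tissues[1]: 0.0} if i % 2 == 0
                  else {tissues[0]: 0.0, tissues[1]: base})
        if len(tissues) > 2:
            ab[tissues[2]] = base * float(rng.uniform(0.5, 2.0))
        specs.append({"kind": "known_mirna", "name": f"known{i + 1}",
                      "mature": mature, "wobble_rate": 0.05,
                      "abundance": ab})

    # --- novel hairpin loci: strong stems, distinct from the known set
    novel_matures: list[str] = []
    for i in range(n_novel):
        while True:
            mlen = int(rng.choice([21, 22, 23, 24], p=[0.2, 0.4, 0.3, 0.1]))
            mature = random_rna(rng, mlen, gc=float(rng.uniform(0.45, 0.62)))
            if (_hamming_min(mature, known_matures) > 4
                    and _hamming_min(mature, novel_matures) > 4):
                break
        novel_matures.append(mature)
        ab = {t: float(rng.uniform(150, 1200)) for t in tissues}
        specs.append({"kind": "novel_mirna", "name": f"novel{i + 1}",
                      "mature": mature,
                      "wobble_rate": float(rng.uniform(0.0, 0.1)),
                      "abundance": ab})

    # --- decoys: tRNA/rRNA (in the decoy database) and random (not)
    for kind, n in (("trna_decoy", n_trna), ("rrna_decoy", n_rrna),
                    ("random", n_random)):
        for i in range(n):
            ab = {t: float(rng.uniform(150, 600)) for t in tissues}
            specs.append({"kind": kind, "name": f"{kind}{i + 1}",
                          "abundance": ab})

    genome, truth = make_genome(n_chrom, chrom_len, specs,
                                rng, tissues, adapter)

    # --- known-miRNA database: planted matures under the target species,
    #     a fraction shared with other species, plus unplanted extras
    db_records = make_known_db(["dre", "ola", "ipu"], 0.4, rng,
                               mature_seqs=known_matures)
    for j in range(6):
        db_records.append((f"ola-miR-9{j + 1:02d}", random_rna(rng, 22)))

    decoy_records = [(f"{loc.name} family={'tRNA' if loc.kind == 'trna_decoy' else 'rRNA_SSU'}",
                      to_dna(_locus_insert(genome, loc)))
                     for loc in truth.loci
                     if loc.kind in ("trna_decoy", "rrna_decoy")]

    # --- UTRs carrying antisense sites for the first half of the novels
    target_mirnas = {f"novel{i + 1}": m
                     for i, m in enumerate(novel_matures[: max(1, n_novel // 2)])}
    site_counts = [int(rng.integers(0, 3)) for _ in range(n_utrs)]
    utrs, utr_truth = make_utr_targets(target_mirnas, n_utrs, site_counts,
                                       rng, utr_len=400)

    paths = {
        "genome": f"{outdir}/genome.fa",
        "known_db": f"{outdir}/known_mirnas.fa",
        "decoys": f"{outdir}/decoys.fa",
        "utrs": f"{outdir}/utrs.fa",
        "truth": f"{outdir}/truth.tsv",
        "utr_truth": f"{outdir}/utr_sites.tsv",
        "reads": {},
    }
    write_fasta(genome, paths["genome"])
    write_fasta(db_records, paths["known_db"])
    write_fasta(decoy_records, paths["decoys"])
    write_fasta(utrs, paths["utrs"])
    write_truth_tsv(truth, paths["truth"])
    with open(paths["utr_truth"], "w") as fh:
        fh.write("utr\tmirna\tposition\n")
        for u, m, p in utr_truth:
            fh.write(f"{u}\t{m}\t{p}\n")
    for t in tissues:
        reads = simulate_reads(truth, t, adapter, error_rate,
                               rng_seed=int(rng.integers(2**31)))
        paths["reads"][t] = f"{outdir}/reads_{t}.fastq"
        write_fastq(reads, paths["reads"][t])

    return {"paths": paths, "truth": truth, "utr_truth": utr_truth,
            "novel_matures": dict(zip([f"novel{i+1}" for i in range(n_novel)],
                                      novel_matures)),
            "known_matures": dict(zip([f"known{i+1}" for i in range(n_known)],
                                      known_matures))}


def _locus_insert(genome: Mapping[str, str], loc: PlantedLocus) -> str:
    """Transcript-sense DNA of a planted locus."""
    sub = genome[loc.chrom][loc.start - 1 : loc.end]
    return revcomp_dna(sub) if loc.strand == "-" else sub
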