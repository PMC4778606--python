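"""End-to-end pipeline orchestration, config handling, fixture access and
report generation.

Stage order: preprocess -> genome alignment -> known-miRNA/ncRNA
annotation -> differential expression -> novel-hairpin discovery ->
3'-UTR target prediction.  Every stage writes plain TSV/FASTA outputs
into the run directory and the run finishes with a provenance manifest
(package version, config hash, per-stage output checksums).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from importlib import resources
import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from . import annotate_known as ann
from . import diff_expression as de
from . import genome_align as ga
from . import novel_discovery as nd
from . import preprocess as pp
from . import target_predict as tp

log = logging.getLogger("mirnovo")


@dataclass
class PipelineConfig:
    """All stage inputs and thresholds; defaults are the pipeline's
    standard operating point (length 16-30, 2/0 mismatches, MFE <= -18,
    |MFEI| > 0.85, log2FC +-1, score > 150, energy < -20, flank 100)."""

    genome: str = ""
    reads: dict[str, str] = field(default_factory=dict)  # tissue -> FASTQ
    known_db: str = ""
    decoys: str = ""
    utrs: str = ""
    outdir: str = "mirnovo_out"
    adapter: str = pp.DEFAULT_ADAPTER
    target_species: str = "dre"
    min_len: int = 16
    max_len: int = 30
    min_mean_q: float = 20.0
    trim_tail_below: int = 20
    align_mismatches: int = 2
    novel_align_mismatches: int = 0
    seed_len: int = ga.DEFAULT_SEED_LEN
    annotate_mismatches: int = 2
    pseudocount: float = 1.0
    log2fc_threshold: float = 1.0
    criteria: nd.CriteriaConfig = field(default_factory=nd.CriteriaConfig)
    target_min_score: float = 150.0
    target_max_energy: float = -20.0
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        crit = raw.pop("criteria", None)
        cfg = cls(**raw)
        if crit:
            cfg.criteria = nd.CriteriaConfig(**crit)
        return cfg

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def load_table2_fixture() -> pd.DataFrame:
    """The packaged 53-row novel-miRNA characteristics fixture.

    Columns: tissue, chromosome, name, sequence, mirna_length, read_count,
    precursor_start, precursor_end, strand, precursor_length, gc_percent,
    mfei (signed, negative).
    """
    with resources.files("mirnovo.fixtures").joinpath(
            "table2_novel_mirnas.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns a result dict and writes outputs + manifest."""
    for name, path in [("genome", config.genome), ("known_db", config.known_db),
                       *[(f"reads[{t}]", p) for t, p in config.reads.items()]]:
        if not path or not os.path.exists(path):
            raise FileNotFoundError(f"missing input for stage setup: {name} ({path!r})")
    os.makedirs(config.outdir, exist_ok=True)
    results: dict = {"outputs": []}

    def emit(path):
        results["outputs"].append(path)
        return path

    # --- preprocess
    collapsed: dict[str, list[pp.CollapsedRead]] = {}
    stats: dict[str, pp.LibraryStats] = {}
    for tissue, fastq in config.reads.items():
        reads, st = pp.preprocess_library(
            fastq, config.adapter, min_mean_q=config.min_mean_q,
            trim_tail_below=config.trim_tail_below,
            min_len=config.min_len, max_len=config.max_len)
        collapsed[tissue], stats[tissue] = reads, st
        pp.write_collapsed_fasta(reads, emit(f"{config.outdir}/collapsed_{tissue}.fa"))
        pp.write_stats_tsv(st, emit(f"{config.outdir}/stats_{tissue}.tsv"))
        pp.write_length_histogram_tsv(
            st, emit(f"{config.outdir}/length_histogram_{tissue}.tsv"))
        log.info("preprocess %s: %d reads -> %d distinct", tissue,
                 st.total_sequences, st.distinct_after_length_filter)

    # --- alignment
    index = ga.GenomeIndex.from_fasta(config.genome, config.seed_len)
    hits_by_lib: dict[str, dict[str, list[ga.AlignmentHit]]] = {}
    rates: dict[str, float] = {}
    for tissue, reads in collapsed.items():
        hits = ga.align_library(reads, index, config.align_mismatches)
        hits_by_lib[tissue] = hits
        rate, n_aligned, n_total = ga.alignment_rate(hits)
        rates[tissue] = rate
        ga.write_hits_tsv((h for hs in hits.values() for h in hs),
                          emit(f"{config.outdir}/hits_{tissue}.tsv"))
        log.info("align %s: %.2f%% (%d/%d)", tissue, 100 * rate,
                 n_aligned, n_total)
    results["alignment_rates"] = rates

    # --- annotation
    db = ann.build_unique_db(config.known_db)
    decoys = ann.load_family_fasta(config.decoys) if config.decoys else []
    annotated: dict[str, list[ann.AnnotatedRead]] = {}
    mirna_sets: dict[str, set] = {}
    chrom_pairs = []
    for tissue, reads in collapsed.items():
        aligned = [r for i, r in enumerate(reads, 1)
                   if hits_by_lib[tissue].get(f"seq{i}")]
        annotated[tissue] = ann.annotate(aligned, db, config.target_species,
                                         decoys, max_mismatch=config.annotate_mismatches)
        mirna_sets[tissue] = {a.matched_name for a in annotated[tissue]
                              if a.category.endswith("miRNA")}
        by_seq = {a.read.seq: a for a in annotated[tissue]}
        for i, r in enumerate(reads, 1):
            a = by_seq.get(r.seq)
            if a is not None and a.category.endswith("miRNA"):
                for h in hits_by_lib[tissue][f"seq{i}"]:
                    chrom_pairs.append((h.chrom, a.matched_name))
        summary = ann.category_summary(annotated[tissue])
        pd.Series(summary).rename("distinct_reads").to_csv(
            emit(f"{config.outdir}/annotation_summary_{tissue}.tsv"), sep="\t")
    results["db"] = {"n_input": db.n_input, "n_unique": db.n_unique}
    results["venn"] = ann.compare_libraries(mirna_sets)
    results["chrom_distribution"] = ann.chromosome_distribution(chrom_pairs)
    pd.Series(results["chrom_distribution"]).rename("n_mirnas").to_csv(
        emit(f"{config.outdir}/chromosome_distribution.tsv"), sep="\t")
    with open(emit(f"{config.outdir}/venn.tsv"), "w") as fh:
        fh.write("libraries\tcount\n")
        for combo, n in results["venn"].items():
            fh.write("+".join(combo) + f"\t{n}\n")

    # --- differential expression (first two libraries)
    counts = de.build_count_table(annotated)
    counts.to_csv(emit(f"{config.outdir}/count_table.tsv"), sep="\t")
    tissues = list(config.reads)
    if len(tissues) >= 2 and (counts.to_numpy() > 0).all(axis=1).any():
        records = de.classify_table(counts, tissues[0], tissues[1],
                                    config.pseudocount)
        de.records_to_frame(records).to_csv(
            emit(f"{config.outdir}/diff_expression.tsv"), sep="\t", index=False)
        de.heatmap_matrix(records, config.pseudocount).to_csv(
            emit(f"{config.outdir}/heatmap_matrix.tsv"), sep="\t")
        results["de_classes"] = pd.Series(
            [r.reg_class for r in records]).value_counts().to_dict()
        results["de_records"] = records

    # --- novel discovery (unannotated reads, strict mapping)
    genome = {rec.id: str(rec.seq).upper()
              for rec in SeqIO.parse(config.genome, "fasta")}
    novel_per_tissue: dict[str, list[nd.HairpinCandidate]] = {}
    all_rejections = []
    for tissue, reads in collapsed.items():
        unannotated = {a.read.seq for a in annotated[tissue]
                       if a.category == "unannotated"}
        strict_hits = []
        for i, r in enumerate(reads, 1):
            if r.seq in unannotated:
                try:
                    strict_hits.extend(ga.align_read(
                        r, index, config.novel_align_mismatches,
                        read_id=f"{tissue}:seq{i}"))
                except ValueError:
                    continue
        cands, rejections = nd.discover(strict_hits, genome, config.criteria)
        novel_per_tissue[tissue] = nd.filter_mfei(cands,
                                                  config.criteria.mfei_threshold)
        all_rejections.extend(rejections)
        log.info("novel %s: %d candidates (%d rejected loci)", tissue,
                 len(novel_per_tissue[tissue]), len(rejections))
    report = nd.name_and_report(novel_per_tissue)
    report.to_csv(emit(f"{config.outdir}/novel_mirnas.tsv"), sep="\t", index=False)
    nd.write_rejections_tsv(all_rejections,
                            emit(f"{config.outdir}/novel_rejections.tsv"))
    results["novel_report"] = report
    results["novel_per_tissue"] = novel_per_tissue

    # --- target prediction for novel matures
    if config.utrs:
        utrs = {rec.id: str(rec.seq) for rec in SeqIO.parse(config.utrs, "fasta")}
        mirnas = {row["name"]: row["sequence"]
                  for _, row in report.iterrows()
                  if 18 <= len(row["sequence"]) <= 26}
        hits = tp.scan_all(mirnas, utrs)
        kept, summary = tp.filter_and_summarize(hits, config.target_min_score,
                                                config.target_max_energy)
        tp.write_hits_tsv(kept, emit(f"{config.outdir}/target_hits.tsv"))
        summary.to_csv(emit(f"{config.outdir}/target_summary.tsv"),
                       sep="\t", index=False)
        results["target_hits"] = kept
        results["target_summary"] = summary

    # --- provenance manifest
    manifest = {
        "mirnovo_version": __version__,
        "config_hash": config.digest(),
        "outputs": {os.path.basename(p): _sha256(p)
                    for p in results["outputs"]},
    }
    with open(f"{config.outdir}/manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
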