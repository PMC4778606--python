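# Methods

`mirnovo` re-implements, as a tested library with a CLI, the classic
in-silico small-RNA discovery workflow: read preprocessing and collapsing,
ungapped genome alignment, tiered annotation against a deduplicated
mature-miRNA database and ncRNA decoys, fold-change classification of
known miRNAs, Mireap-style novel hairpin calling with the minimal folding
free energy index (MFEI) as the second-stage filter, and miRanda-style
antisense target scanning in 3'-UTRs.  This note records the models,
parameter choices and their rationale, what the synthetic data does and
does not emulate, and known limitations.

## Preprocessing

Reads are quality-trimmed (3' bases below Q20 removed; mean quality < 20
or any `N` rejects the read), 3'-adapter-trimmed (leftmost adapter-prefix
match with ≥ 5 nt overlap and ≤ 10% mismatches; partial adapters at the
read end count), filtered to 16–30 nt inclusive, and collapsed to unique
sequences with occurrence counts.  The Q20 thresholds are conventional
small-RNA QC values and are configurable; rejection of `N`-containing
reads is required because collapsing and annotation are exact-sequence
operations.  Collapse output is ordered by descending count then
lexicographically so output files are reproducible.  The default 3'
adapter is the standard Illumina small-RNA adapter
`TGGAATTCTCGGGTGCCAAGG`; it is a plausible default, not a claim about any
particular dataset, and every entry point accepts another.

## Alignment

Ungapped, full-length alignment with a mismatch budget of 0–2, replicating
bowtie's `-v` mode semantics.  Search is pigeonhole-seeded: the read is
partitioned into `budget + 1` disjoint seed windows, so any placement
within budget must match one window exactly; exact k-mer lookup (default
k = 5) of each window therefore enumerates every candidate placement, and
the search is exact — the test suite proves equivalence against a
brute-force sliding-window Hamming scan for every budget.  All hits at the
minimum achievable mismatch count are kept (best stratum).  Coordinates
are 1-based inclusive on the forward strand throughout; a minus-strand
hit means the read's reverse complement matches the forward genome there.
Alignment rates are reported over distinct (collapsed) reads.

## Annotation

The multi-species mature-miRNA database is deduplicated by exact sequence,
preserving every (species, name) provenance.  Aligned reads are matched by
Hamming distance (≤ 2 mismatches, ≤ 2 nt end overhang) — a deterministic
stand-in for heuristic local search that is consistent with the ungapped
alignment budget.  Categories are assigned with strict precedence:
target-species miRNA > other-species miRNA > ncRNA family (tRNA, rRNA, …)
> mRNA > unannotated, so a read reaches the decoy tier only if the miRNA
tier fails.  Equally good matches to several database entries keep all
names; the primary is the target species first, then lexicographic.

## Differential expression

Libraries are normalized with DESeq-style median-of-ratios size factors:
factor_j = median over genes expressed in every library of
count_gj / geometric-mean_g, with the median taken on the linear ratio
scale.  Size factors fix normalized counts only up to a common constant,
so cross-library ratios (and log2 fold changes) are the scale-free
quantities; the property tests assert that form of invariance.  Each
miRNA's log2FC = log2((a + 1)/(b + 1)) on normalized counts (pseudocount
1.0, needed because exclusively expressed miRNAs have a zero side) and the
classes are strict: up if log2FC > 1, down if < −1, neutral otherwise;
nonzero raw counts in exactly one condition give `exclusive_A`/`_B`
regardless of fold change.  No dispersion estimation or testing is
performed — the classes depend only on thresholds and the zero pattern.

## RNA folding

An in-repo simplified Turner-style nearest-neighbour model: helix stack
energies for the 36 canonical pair combinations (WC plus G:U wobble),
tabulated hairpin/bulge/internal loop initiation energies with
Jacobson–Stockmayer log extrapolation (1.75·RT·ln(n/base), RT = 0.6163
kcal/mol at 37 °C), capped internal-loop asymmetry (0.5/nt, max 3.0), an
affine multiloop penalty (close 3.4, per branch 0.4, unpaired free) and a
0.5 kcal/mol AU/GU hairpin-closing penalty.  No dangles, coaxial stacking
or tetraloop bonuses.  The parameter tables ship as plain TSVs under
`mirnovo/data/`.  The dynamic program is the standard Zuker recursion with
loop size bounded at 30 nt, JIT-compiled with numba when available (pure
Python otherwise), with a deterministic traceback.  Correctness is
anchored two ways: exhaustive enumeration of all structures for short
sequences scored by an independent loop-decomposition function, and a
qualitative cross-check against ViennaRNA's RNAfold on strong hairpins.
Lonely pairs are legal; they earn no stacking and pay the surrounding loop
penalties, which suppresses them in practice without a dedicated term.
Reverse-complementing a sequence mirrors its hairpin; MFE agrees within
the stacking-table asymmetry (≤ 10% on strong hairpins — tested).
Absolute MFE values are model-dependent and are never compared against
external engines to decimals; the hairpin criteria below are designed to
be robust to any reasonable parameter set.

## Novel hairpin discovery

Unannotated reads are re-mapped with zero mismatches, reads placed at more
than 20 loci are discarded as repeats, and hits within 30 nt on one
chromosome strand merge into a locus (the representative is the
highest-count read; ties prefer the longer, then lexicographically first
sequence).  Loci with fewer than 100 total reads are skipped — every
strongly supported candidate in practice clears this, and the value is
configurable.  Around the representative two windows are excised (mature
± 100 nt flank, upstream- and downstream-anchored, strand-aware), folded,
and evaluated:

- ≥ 14 mature bases paired, all into one contiguous partner run (the star);
  stray single pairs into unrelated helices are treated as unpaired,
- mature and star disjoint, star on one side of the loop (mature on one
  arm; an unpaired mature tail inside the terminal loop is tolerated —
  common when the stem end carries wobbles),
- the precursor is trimmed to the minimal mature+star span and refolded;
  the refold must be a single stem-loop (exactly one terminal loop),
- star length 20–24, mature–star loop spacing 5–35 nt, longest mature
  bulge ≤ 4, duplex asymmetry ≤ 5, ≤ 6 mature–star mismatches, no break
  (every paired mature base pairs into the star segment),
- precursor MFE ≤ −18 kcal/mol.

MFEI = MFE / precursor length × 100 / GC%; candidates survive only if
|MFEI| > 0.85 (strict).  The reported MFEI is signed (negative, following
the MFE); the filter applies to the magnitude.  Perfect inverted repeats
place the mature read on both strands of the same locus (the minus-strand
placement is the star arm), so candidates with overlapping precursor spans
are collapsed to the lower-energy one.  Every rejected locus is logged
with at least one named failed criterion.  Reports are deterministic:
candidates are numbered `Dre-mir-nov<N>` by tissue, then descending read
count, then coordinates.

## Target prediction

Local alignment of the miRNA 3'→5' against the UTR 5'→3' where a "match"
is complementarity: Watson–Crick +5, G:U wobble +1, mismatch −3, affine
gaps −9/−4.  Positions 2–8 from the miRNA 5' end (the seed) have their
match/mismatch contribution multiplied by the seed scale.  The default
scale is 3.0, chosen from the score geometry: a perfect 22-nt duplex then
scores 5·15 + 15·7 = 180, comfortably above the 150 reporting threshold,
while the null distribution (best score of a 22-mer against random 250-nt
UTRs) has its 99th percentile near 117 — a scale of 2 pushes perfect
22-mers below 150 (filtering them out wholesale), a scale of 4 lets a few
percent of random UTRs over it.  Non-overlapping sites are extracted
greedily by descending score.  Duplex free energy reuses the folding
module's stack/loop tables over the aligned pairs; reported targets must
clear score > 150 and energy < −20 kcal/mol, both strict.  The −20
threshold is therefore relative to this energy model (as any such
threshold is to its engine's).

## Synthetic data

The generator emulates the statistical structure the pipeline assumes: a
uniform-background genome with planted, non-overlapping loci; hairpin loci
built as pad + mature + loop + star where the star is the mature's reverse
complement with a configurable wobble/mismatch rate (≤ 6 mismatches), and
loop/pad bases drawn from {A, C} so they cannot pair among themselves —
the planted stem is the unambiguous optimum under any reasonable
nearest-neighbour model; per-locus GC varied (0.45–0.62) to exercise the
MFEI GC term.  Expression is Poisson per tissue around planted abundances;
reads are mature (3'-trimmed ≤ 2 nt with prob. 0.15) + adapter, truncated
to 36 nt, with i.i.d. substitution errors (default 5×10⁻⁴) and flat Q38
qualities.  The known-miRNA database carries the planted known matures
under the target species with a configurable fraction duplicated under
other species labels (exercising deduplication) plus unplanted extras.
Decoys are tRNA-like cloverleafs and rRNA-like GC-rich sequences (present
in the decoy database, so their reads annotate as ncRNA) and plain random
expressed loci (absent from every database, so their reads reach the
discovery stage and must fail the hairpin criteria).  UTRs are random DNA
with planted perfect antisense sites.

The default study has 3 tissues, 3 × 40 kb chromosomes, 12 known loci
with planted log2FC ∈ {−3, 0, +3} (ratios 8×) plus two library-exclusive
ones, 20 novel hairpin loci and 20 decoys, and 15 UTRs — sized so the
whole pipeline runs in well under a minute while every recovery statistic
rests on ≥ 20 planted instances.

What it does not emulate: realistic error/quality profiles, indels,
ligation bias, isomiR 5' heterogeneity, repeat structure or GC
heterogeneity of real genomes, transcript-level expression correlation,
overdispersion.  Passing recovery tests therefore demonstrate the
*pipeline logic* — coordinates, strand handling, thresholds, filter
arithmetic, determinism — not performance on real tissue libraries.

## Numerical and procedural choices

- All coordinates 1-based inclusive; minus-strand sequences are reverse
  complements of the forward slice (report arithmetic
  `end − start + 1 = length` holds for every emitted row and is tested).
- DP tracebacks compare energies with a 1e-6 absolute tolerance against
  re-derived branch values; ties resolve toward the first branch in a
  fixed order, making structures deterministic.
- MFEI is stored at full precision (recomputation from the reported MFE,
  length and GC% matches to 1e-9); report tables round to 2 decimals.
- The strict boundary conventions: log2FC exactly ±1 → neutral; |MFEI|
  exactly 0.85 → dropped; score exactly 150 or energy exactly −20 →
  dropped.
- With a fixed seed every output is byte-identical across runs; the run
  manifest records the package version, a config hash and per-output
  SHA-256 checksums.

## Limitations

- The folding model is deliberately small: absolute MFE values differ
  from full Turner-2004 engines by a few kcal/mol (structures of strong
  hairpins agree).  An external engine can be plugged into `fold()`
  (a ready RNAfold adapter is included).
- Annotation matching is Hamming-based; diverged paralogs that would be
  found by local alignment with indels are out of reach (consistent with
  the ungapped alignment stage).
- miRNA* read support, conservation filtering and expression significance
  testing are out of scope for candidate calling; the discovery criteria
  are structural and energetic only.
- The target scanner models seed emphasis with one scale factor; it does
  not implement 3'-supplementary pairing bonuses or conservation.
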