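"""miRNA count tables, median-of-ratios normalization and fold-change
classification.

Normalization is the DESeq-style size factor: for each library the median,
over genes expressed in every library, of the ratio between the gene's
count and its across-library geometric mean.  Classification uses the
log2 fold change of pseudocounted normalized counts with strict +-1
thresholds (up / down / neutral), and flags library-exclusive miRNAs
(nonzero raw count in exactly one of the two conditions) separately.
No dispersion estimation or significance testing is performed — the class
labels depend only on the fold-change thresholds and the zero pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate_known import AnnotatedRead


@dataclass(frozen=True)
class ExpressionRecord:
    mirna_name: str
    raw_counts: dict[str, int]
    size_factors: dict[str, float]
    norm_counts: dict[str, float]
    log2fc: float
    reg_class: str  # up | down | neutral | exclusive_A | exclusive_B


def build_count_table(annotated: Mapping[str, Sequence[AnnotatedRead]],
                      categories: tuple[str, ...] = ("target_species_miRNA",
                                                     "other_species_miRNA"),
                      ) -> pd.DataFrame:
    """miRNA x library matrix of summed collapsed-read counts (missing = 0)."""
    cells: dict[str, dict[str, int]] = {}
    for lib, reads in annotated.items():
        for a in reads:
            if a.category in categories and a.matched_name:
                cells.setdefault(a.matched_name, {}).setdefault(lib, 0)
                cells[a.matched_name][lib] += a.read.count
    df = pd.DataFrame.from_dict(cells, orient="index", columns=list(annotated))
    df = df.astype(float).fillna(0.0).astype(int)
    return df.sort_index()


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per library (column).

    Only genes with nonzero counts in every library enter the median;
    raises if no such gene exists (advising a pseudocount on the counts).
    """
    mat = counts.to_numpy(dtype=float)
    everywhere = (mat > 0).all(axis=1)
    if not everywhere.any():
        raise ValueError(
            "no gene has nonzero counts in all libraries; add a pseudocount "
            "to the count table before computing size factors")
    sub = mat[everywhere]
    geomean = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / geomean[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame,
              factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def classify(norm_a: float, norm_b: float, raw_a: int, raw_b: int,
             pseudocount: float = 1.0) -> tuple[float, str]:
    """log2 fold change (A over B) and regulation class for one miRNA.

    Strict thresholds: up iff log2fc > 1, down iff log2fc < -1, else
    neutral.  A miRNA with raw counts only in A (resp. B) is exclusive_A
    (exclusive_B) regardless of the fold change.
    """
    log2fc = float(np.log2((norm_a + pseudocount) / (norm_b + pseudocount)))
    if raw_a > 0 and raw_b == 0:
        cls = "exclusive_A"
    elif raw_b > 0 and raw_a == 0:
        cls = "exclusive_B"
    elif log2fc > 1:
        cls = "up"
    elif log2fc < -1:
        cls = "down"
    else:
        cls = "neutral"
    return log2fc, cls


def classify_table(counts: pd.DataFrame, lib_a: str, lib_b: str,
                   pseudocount: float = 1.0) -> list[ExpressionRecord]:
    """Classify every miRNA for the condition pair A over B."""
    factors = size_factors(counts)
    norm = normalize(counts, factors)
    records = []
    for name in counts.index:
        log2fc, cls = classify(norm.at[name, lib_a], norm.at[name, lib_b],
                               int(counts.at[name, lib_a]),
                               int(counts.at[name, lib_b]), pseudocount)
        records.append(ExpressionRecord(
            name,
            raw_counts={lib: int(counts.at[name, lib]) for lib in counts.columns},
            size_factors=dict(factors),
            norm_counts={lib: float(norm.at[name, lib]) for lib in counts.columns},
            log2fc=log2fc, reg_class=cls))
    return records


def heatmap_matrix(records: Sequence[ExpressionRecord],
                   pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(normalized + pseudocount) matrix, rows ordered by log2fc desc."""
    ordered = sorted(records, key=lambda r: (-r.log2fc, r.mirna_name))
    data = {r.mirna_name: {lib: float(np.log2(v + pseudocount))
                           for lib, v in r.norm_counts.items()}
            for r in ordered}
    return pd.DataFrame.from_dict(data, orient="index").loc[
        [r.mirna_name for r in ordered]]


def records_to_frame(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict = {"mirna": r.mirna_name}
        row.update({f"raw_{k}": v for k, v in r.raw_counts.items()})
        row.update({f"norm_{k}": round(v, 4) for k, v in r.norm_counts.items()})
        row["log2fc"] = round(r.log2fc, 4)
        row["reg_class"] = r.reg_class
        rows.append(row)
    return pd.DataFrame(rows)
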