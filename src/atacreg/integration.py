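"""ATAC-RNA integration: peak-gene pairing and fold-change congruence.

Two pairing rules mirror standard practice: promoter pairing (a peak
overlapping the +/-1 kb window around a TSS is paired with that gene; one
peak may pair with several genes) and GREAT-style single-nearest-gene
assignment (proximal basal window 5 kb upstream / 1 kb downstream, distal
up to 1,000 kb).  Congruence between accessibility and expression changes
is the Pearson correlation of peak and gene log2 fold changes with the
linear-model slope t test p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .peaks import GenomicInterval


@dataclass(frozen=True)
class PeakGenePair:
    peak_id: str
    gene_id: str
    rule: str  # promoter_1kb | proximal | distal
    distance: int  # signed, TSS-relative, strand-aware


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def _require_tss_columns(tss_table: pd.DataFrame) -> None:
    missing = {"chrom", "tss", "gene_id"} - set(tss_table.columns)
    if missing:
        raise ValueError(f"tss_table missing columns: {sorted(missing)}")
    if tss_table.empty:
        raise ValueError("tss_table must be non-empty")


def _signed_distance(start: int, end: int, tss: int, strand: str) -> int:
    """Distance from TSS to the nearest peak edge, negative upstream of the TSS
    in transcript orientation; 0 when the peak covers the TSS."""
    if start <= tss < end:
        d = 0
    elif end <= tss:
        d = end - tss  # peak entirely before the TSS (negative)
    else:
        d = start - tss
    return -d if strand == "-" else d


def pair_promoter_genes(
    peaks: Sequence[GenomicInterval],
    tss_table: pd.DataFrame,
    flank: int = 1000,
) -> list[PeakGenePair]:
    """Pair every peak with every gene whose +/-``flank`` bp TSS window it overlaps.

    All pairs are retained when one promoter peak overlaps several genes'
    windows.  Overlap is >= 1 bp against the half-open window
    [tss - flank, tss + flank).
    """
    _require_tss_columns(tss_table)
    trees: dict[str, IntervalTree] = {}
    for _, row in tss_table.iterrows():
        tss = int(row["tss"])
        strand = row.get("strand", "+") if isinstance(row, pd.Series) else "+"
        trees.setdefault(row["chrom"], IntervalTree()).addi(
            max(0, tss - flank), tss + flank, (row["gene_id"], tss, strand or "+")
        )
    pairs: list[PeakGenePair] = []
    for peak in peaks:
        tree = trees.get(peak.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(peak.start, peak.end), key=lambda h: h.data[1]):
            gene_id, tss, strand = hit.data
            pairs.append(
                PeakGenePair(
                    peak_id=peak.name,
                    gene_id=gene_id,
                    rule="promoter_1kb",
                    distance=_signed_distance(peak.start, peak.end, tss, strand),
                )
            )
    return pairs


def assign_nearest_gene(
    peak: GenomicInterval,
    tss_table: pd.DataFrame,
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_dist: int = 1_000_000,
) -> PeakGenePair | None:
    """Single-nearest-gene assignment for one peak (GREAT-style).

    The gene whose TSS is nearest the peak midpoint is chosen; the pair is
    ``proximal`` when the midpoint lies in the gene's strand-aware basal
    window (``basal_up`` upstream, ``basal_down`` downstream of the TSS) and
    ``distal`` otherwise, up to ``max_dist``; beyond that, None.
    """
    _require_tss_columns(tss_table)
    sub = tss_table[tss_table["chrom"] == peak.chrom]
    if sub.empty:
        return None
    mid = peak.midpoint
    tss = sub["tss"].to_numpy(dtype=np.int64)
    dist = np.abs(tss - mid)
    i = int(np.argmin(dist))
    if dist[i] > max_dist:
        return None
    row = sub.iloc[i]
    strand = row.get("strand", "+") or "+"
    t = int(row["tss"])
    if strand == "-":
        in_basal = t - basal_down <= mid <= t + basal_up
    else:
        in_basal = t - basal_up <= mid <= t + basal_down
    signed = mid - t if strand != "-" else t - mid
    return PeakGenePair(
        peak_id=peak.name,
        gene_id=row["gene_id"],
        rule="proximal" if in_basal else "distal",
        distance=int(signed),
    )


def assign_nearest_genes(
    peaks: Sequence[GenomicInterval],
    tss_table: pd.DataFrame,
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_dist: int = 1_000_000,
) -> list[PeakGenePair]:
    """Vectorized nearest-gene assignment over many peaks (drops unassigned)."""
    _require_tss_columns(tss_table)
    out: list[PeakGenePair] = []
    by_chrom = {c: g.sort_values("tss") for c, g in tss_table.groupby("chrom")}
    for peak in peaks:
        sub = by_chrom.get(peak.chrom)
        if sub is None:
            continue
        pair = assign_nearest_gene(peak, sub, basal_up, basal_down, max_dist)
        if pair is not None:
            out.append(pair)
    return out


def correlate_lfc(
    pairs: Sequence[PeakGenePair] | pd.DataFrame,
    atac_results: pd.DataFrame,
    rna_results: pd.DataFrame,
    collapse_nearest: bool = False,
) -> CorrelationResult:
    """Pearson correlation between peak and gene log2 fold changes over pairs.

    Duplicate (peak, gene) pairs are deduplicated.  With
    ``collapse_nearest`` each gene keeps only its nearest pair.  The p-value
    is from the regression slope t test (identical to the Pearson test).
    With fewer than 3 complete pairs r is still reported (when defined) and
    p is NA.
    """
    if isinstance(pairs, pd.DataFrame):
        df = pairs.copy()
    else:
        df = pd.DataFrame(
            [
                {"peak_id": p.peak_id, "gene_id": p.gene_id, "distance": p.distance}
                for p in pairs
            ],
            columns=["peak_id", "gene_id", "distance"],
        )
    if df.empty:
        return CorrelationResult(r=float("nan"), p=float("nan"), n=0)
    if collapse_nearest and "distance" in df.columns:
        df["absd"] = df["distance"].abs()
        df = df.sort_values("absd").drop_duplicates("gene_id")
    df = df.drop_duplicates(["peak_id", "gene_id"])
    atac = atac_results.set_index("feature_id")["log2fc"]
    rna = rna_results.set_index("feature_id")["log2fc"]
    x = df["peak_id"].map(atac)
    y = df["gene_id"].map(rna)
    ok = x.notna() & y.notna()
    x, y = x[ok].to_numpy(float), y[ok].to_numpy(float)
    n = len(x)
    if n < 2 or np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(r=float("nan"), p=float("nan"), n=n)
    r, p = stats.pearsonr(x, y)
    if n < 3:
        p = float("nan")
    return CorrelationResult(r=float(r), p=float(p), n=n)
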