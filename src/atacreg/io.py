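"""Readers and writers for the plain-text formats the pipeline consumes.

BED-family files are 0-based half-open.  broadPeak is BED6+3 with the
q-value as -log10 in column 9; segmentation BED4 carries the chromatin state
name in column 4.  Count matrices and sample sheets are TSV; motifs are
JASPAR-style count matrices parsed with Bio.motifs.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .peaks import CountsMatrix, GenomicInterval, ScoredPeak

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED4/BED6 into intervals (extra columns ignored)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else None
            score = float(f[4]) if len(f) > 4 and f[4] != "." else None
            strand = f[5] if len(f) > 5 else None
            out.append(
                GenomicInterval(f[0], int(f[1]), int(f[2]), name, score, strand)
            )
    return out


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand is not None:
                fields.append("0" if iv.score is None else f"{iv.score:g}")
            if iv.strand is not None:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


def read_broadpeak(path) -> list[ScoredPeak]:
    """Read broadPeak (BED6+3; col 9 = -log10 q) or narrowPeak (BED6+4, col 10 = summit)."""
    out: list[ScoredPeak] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            iv = GenomicInterval(
                f[0], int(f[1]), int(f[2]),
                name=f[3] if len(f) > 3 and f[3] != "." else None,
                strand=f[5] if len(f) > 5 and f[5] in "+-." else None,
            )
            neglog_q = float(f[8]) if len(f) > 8 else 0.0
            q = 10.0 ** (-neglog_q) if neglog_q > 0 else 1.0
            summit = None
            if len(f) > 9:
                s = int(f[9])
                summit = s if s >= 0 else None
            out.append(ScoredPeak(iv, q=q, summit_offset=summit))
    return out


def write_broadpeak(peaks: Sequence[ScoredPeak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            neglog_q = -math.log10(p.q) if p.q > 0 else 999.0
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        iv.name or ".",
                        "0",
                        iv.strand or ".",
                        "0",
                        "-1",
                        f"{neglog_q:.5g}",
                    ]
                )
                + "\n"
            )


def read_state_bed(path) -> list[tuple[GenomicInterval, str]]:
    """Read a BED4 chromatin-state segmentation (state name in column 4)."""
    out = []
    for iv in read_bed(path):
        if iv.name is None:
            raise ValueError(f"{path}: segmentation BED requires a state name column")
        out.append((GenomicInterval(iv.chrom, iv.start, iv.end), iv.name))
    return out


def write_state_bed(segments: Sequence[tuple[GenomicInterval, str]], path) -> None:
    with open(path, "w") as fh:
        for iv, state in segments:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{state}\n")


def read_counts_tsv(path, lib_sizes=None) -> CountsMatrix:
    """Read a feature x sample integer TSV (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountsMatrix.from_frame(df, lib_sizes)


def write_counts_tsv(counts: CountsMatrix, path) -> None:
    counts.to_frame().rename_axis("feature_id").to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the sample sheet TSV (sample_id, group, sex)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    bad_group = set(df["group"]) - {"control", "centenarian"}
    if bad_group:
        raise ValueError(f"unknown group labels: {sorted(bad_group)}")
    bad_sex = set(df["sex"]) - {"F", "M"}
    if bad_sex:
        raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
    return df


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_pfms(path) -> list:
    """Read JASPAR-style PFM file(s); returns a list of motifs.MotifModel."""
    from .motifs import MotifModel

    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
        out = []
        for m in records:
            pfm = np.array(
                [m.counts[b] for b in "ACGT"], dtype=float
            )
            out.append(MotifModel(name=m.name or m.matrix_id, pfm=pfm))
    return out


def write_pfms(motif_models: Sequence, path) -> None:
    """Write motifs in JASPAR count-matrix format."""
    with open(path, "w") as fh:
        for m in motif_models:
            fh.write(f">{m.name}\t{m.name}\n")
            for b, row in zip("ACGT", m.pfm):
                vals = " ".join(f"{v:10.2f}" for v in row)
                fh.write(f"{b}  [{vals} ]\n")
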