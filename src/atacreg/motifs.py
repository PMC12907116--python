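"""PWM scanning, motif enrichment and transcription-factor nomination.

Position frequency matrices are converted to log-odds PWMs and scanned on
both strands of peak sequences.  Differential-peak motif enrichment uses a
one-sided hypergeometric test on summit +/-200 bp windows with the non-DA
consensus peaks as the matched-universe background.  A TF is nominated as
longevity-associated when its motif is enriched in opening (closing) peaks
AND its own gene is up- (down-) regulated, per stratum (all / female /
male); targets of a nominated TF are the nearest genes of the DA peaks
carrying its motif.  A simplified aggregate footprint (mean insertion
profile around motif hits, flank-minus-core depth) stands in for
model-based footprinting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import adjust_bh
from .integration import assign_nearest_genes
from .peaks import GenomicInterval

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class MotifModel:
    """A TF binding motif as a 4 x w count matrix (rows A, C, G, T)."""

    name: str
    pfm: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.25

    def __post_init__(self) -> None:
        self.pfm = np.asarray(self.pfm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pfm.ndim != 2 or self.pfm.shape[0] != 4:
            raise ValueError("pfm must be a 4 x w matrix (rows A, C, G, T)")
        if self.width < 4:
            raise ValueError("motif width must be >= 4")
        if np.any(self.pfm < 0):
            raise ValueError("pfm counts must be non-negative")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")

    @property
    def width(self) -> int:
        return self.pfm.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pfm.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    peak_id: str
    offset: int  # bp from scanned-window start (forward-strand coordinates)
    strand: str
    score: float


@dataclass(frozen=True)
class MotifEnrichmentResult:
    tf: str
    fg_with_motif: int
    fg_total: int
    bg_with_motif: int
    bg_total: int
    p: float
    fold: float
    padj: float = float("nan")


def pfm_to_pwm(motif: MotifModel) -> np.ndarray:
    """Log-odds PWM: log2 of pseudocounted column frequency over background."""
    counts = motif.pfm + motif.pseudocount
    colsums = counts.sum(axis=0)
    if np.any(colsums <= 0):
        raise ValueError("pfm column sums must be positive after pseudocount")
    freqs = counts / colsums
    return np.log2(freqs / motif.background[:, None])


def max_score(pwm: np.ndarray) -> float:
    return float(pwm.max(axis=0).sum())


def default_min_score(pwm: np.ndarray, fraction: float = 0.8) -> float:
    """Default scan threshold: a fraction (80%) of the PWM's maximum score."""
    return fraction * max_score(pwm)


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to base indices; non-ACGT becomes -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def scan_sequence(
    seq: str, pwm: np.ndarray, min_score: float | None = None
) -> list[tuple[int, str, float]]:
    """Scan both strands; return (offset, strand, score) for windows >= min_score.

    Offsets are forward-strand window starts for both strands.  Windows
    containing a non-ACGT base are skipped.
    """
    if min_score is None:
        min_score = default_min_score(pwm)
    w = pwm.shape[1]
    if len(seq) < w:
        return []
    enc = _encode(seq)
    n_win = len(enc) - w + 1
    idx = np.lib.stride_tricks.sliding_window_view(enc, w)  # (n_win, w)
    valid = np.all(idx >= 0, axis=1)
    pos = np.arange(w)
    safe = np.where(idx >= 0, idx, 0)
    fwd = pwm[safe, pos].sum(axis=1)
    # reverse strand: score of the window's reverse complement under pwm
    pwm_rc = pwm[::-1, ::-1]
    rev = pwm_rc[safe, pos].sum(axis=1)
    hits: list[tuple[int, str, float]] = []
    for off in np.nonzero(valid)[0]:
        if fwd[off] >= min_score:
            hits.append((int(off), "+", float(fwd[off])))
        if rev[off] >= min_score:
            hits.append((int(off), "-", float(rev[off])))
    return hits


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


def scan_peaks(
    sequences: Mapping[str, str],
    motif: MotifModel,
    min_score: float | None = None,
) -> pd.DataFrame:
    """Scan every peak sequence; returns a hits frame (peak_id, offset, strand, score)."""
    pwm = pfm_to_pwm(motif)
    if min_score is None:
        min_score = default_min_score(pwm)
    rows = []
    for peak_id, seq in sequences.items():
        for off, strand, score in scan_sequence(seq, pwm, min_score):
            rows.append(
                {"peak_id": peak_id, "offset": off, "strand": strand, "score": score}
            )
    return pd.DataFrame(rows, columns=["peak_id", "offset", "strand", "score"])


def _has_motif_in_window(
    seq: str, summit: int, pwm: np.ndarray, min_score: float, window: int
) -> bool:
    lo = max(0, summit - window)
    hi = min(len(seq), summit + window)
    return len(scan_sequence(seq[lo:hi], pwm, min_score)) > 0


def motif_indicator(
    peak_ids: Sequence[str],
    sequences: Mapping[str, str],
    motif: MotifModel,
    summits: Mapping[str, int] | None = None,
    window: int = 200,
    min_score: float | None = None,
) -> dict[str, bool]:
    """Whether each peak "has" the motif: >= 1 hit in its summit +/-window bp.

    The summit defaults to the sequence midpoint.  Computing this once per
    motif lets several strata share one scan.
    """
    pwm = pfm_to_pwm(motif)
    if min_score is None:
        min_score = default_min_score(pwm)
    out: dict[str, bool] = {}
    for peak_id in peak_ids:
        seq = sequences[peak_id]
        summit = summits[peak_id] if summits and peak_id in summits else len(seq) // 2
        out[peak_id] = _has_motif_in_window(seq, summit, pwm, min_score, window)
    return out


def enrichment_from_indicator(
    tf: str,
    fg_peaks: Sequence[str],
    bg_peaks: Sequence[str],
    has_motif: Mapping[str, bool],
) -> MotifEnrichmentResult:
    """Hypergeometric enrichment from a precomputed per-peak motif indicator."""
    fg = list(fg_peaks)
    bg = list(bg_peaks)
    if not fg:
        raise ValueError("foreground peak set must be non-empty")
    if set(fg) & set(bg):
        raise ValueError("foreground and background peak sets must be disjoint")
    fg_with = sum(bool(has_motif[p]) for p in fg)
    bg_with = sum(bool(has_motif[p]) for p in bg)
    N = len(fg) + len(bg)
    K = fg_with + bg_with
    p = float(stats.hypergeom.sf(fg_with - 1, N, K, len(fg))) if K > 0 else 1.0
    fg_rate = fg_with / len(fg)
    bg_rate = bg_with / len(bg) if bg else 0.0
    if K == 0:
        fold = 0.0
    elif bg_rate == 0.0:
        fold = float("inf")
    else:
        fold = fg_rate / bg_rate
    return MotifEnrichmentResult(
        tf=tf,
        fg_with_motif=int(fg_with),
        fg_total=len(fg),
        bg_with_motif=int(bg_with),
        bg_total=len(bg),
        p=min(1.0, p),
        fold=fold,
    )


def motif_enrichment(
    fg_peaks: Sequence[str],
    bg_peaks: Sequence[str],
    sequences: Mapping[str, str],
    motif: MotifModel,
    summits: Mapping[str, int] | None = None,
    window: int = 200,
    min_score: float | None = None,
) -> MotifEnrichmentResult:
    """One-sided hypergeometric enrichment of a motif in foreground peaks.

    A peak "has" the motif when >= 1 hit falls in its summit +/-``window``
    bp sequence window (summit defaults to the sequence midpoint).  The
    p-value is the upper hypergeometric tail P(X >= fg_with_motif) drawing
    ``fg_total`` peaks from the pooled fg+bg universe.
    """
    fg = list(fg_peaks)
    bg = list(bg_peaks)
    has = motif_indicator(fg + bg, sequences, motif, summits, window, min_score)
    return enrichment_from_indicator(motif.name, fg, bg, has)


def enrich_motifs(
    motif_models: Sequence[MotifModel],
    fg_peaks: Sequence[str],
    bg_peaks: Sequence[str],
    sequences: Mapping[str, str],
    summits: Mapping[str, int] | None = None,
    window: int = 200,
    min_score: float | None = None,
) -> pd.DataFrame:
    """Enrichment of several motifs with BH adjustment across motifs."""
    results = [
        motif_enrichment(fg_peaks, bg_peaks, sequences, m, summits, window, min_score)
        for m in motif_models
    ]
    df = pd.DataFrame([r.__dict__ for r in results])
    df["padj"] = adjust_bh(df["p"])
    return df


def occurrence_profile(
    hits: pd.DataFrame,
    summits: Mapping[str, int],
    motif_width: int,
    n_peaks: int | None = None,
    span: int = 500,
    bin_size: int = 10,
) -> pd.DataFrame:
    """Per-bin fraction of peaks with >= 1 hit centered in the bin.

    Coordinates are summit-relative over [-span, +span); a hit's position is
    its motif center.  Returns a frame (bin_start, occurrence) with
    2 * span / bin_size rows, values in [0, 1].
    """
    if n_peaks is None:
        n_peaks = len(summits)
    edges = np.arange(-span, span + bin_size, bin_size)
    n_bins = len(edges) - 1
    seen: list[set] = [set() for _ in range(n_bins)]
    if not hits.empty:
        for _, h in hits.iterrows():
            pid = h["peak_id"]
            if pid not in summits:
                continue
            center = h["offset"] + motif_width / 2.0 - summits[pid]
            b = int(np.floor((center + span) / bin_size))
            if 0 <= b < n_bins:
                seen[b].add(pid)
    occ = np.array([len(s) for s in seen], dtype=float) / max(n_peaks, 1)
    return pd.DataFrame({"bin_start": edges[:-1], "occurrence": occ})


def footprint_profile(
    insertion_counts: Mapping[str, np.ndarray],
    hits: pd.DataFrame,
    core: int,
    flank: int = 50,
) -> tuple[np.ndarray, float]:
    """Aggregate Tn5 insertion profile around motif hits and footprint depth.

    Per-bp insertion vectors are aligned on each hit's motif center and
    averaged; depth = mean(flank) - mean(core), positive depth indicating
    protection (a footprint).  Hits too close to the peak edge are skipped.
    Returns (profile, depth); with no usable hits the profile is empty and
    depth is NaN.
    """
    half = core // 2
    width = 2 * (half + flank)
    windows = []
    for _, h in hits.iterrows():
        vec = insertion_counts.get(h["peak_id"])
        if vec is None:
            continue
        center = int(h["offset"] + core // 2)
        lo = center - half - flank
        hi = lo + width
        if lo < 0 or hi > len(vec):
            continue
        windows.append(np.asarray(vec[lo:hi], dtype=float))
    if not windows:
        return np.array([]), float("nan")
    profile = np.mean(windows, axis=0)
    core_region = profile[flank : flank + 2 * half]
    flank_region = np.concatenate([profile[:flank], profile[flank + 2 * half :]])
    depth = float(flank_region.mean() - core_region.mean())
    return profile, depth


def nominate_tfs(
    enrichment: Mapping[str, Mapping[str, pd.DataFrame]],
    de_results: Mapping[str, pd.DataFrame],
    tf_gene_map: Mapping[str, str],
    padj_max: float = 0.05,
) -> pd.DataFrame:
    """Intersect motif enrichment with the TF's own differential expression.

    ``enrichment[stratum]["opening"|"closing"]`` are enrich_motifs frames and
    ``de_results[stratum]`` differential tables with a ``call`` column (up /
    down / ns).  Per stratum a TF is nominated ``opening+up`` when its motif
    is enriched (padj < ``padj_max``) in opening peaks and its gene is
    called up; symmetrically ``closing+down``.  Returns one row per (tf,
    direction) with the set of supporting strata.
    """
    support: dict[tuple[str, str], set[str]] = {}
    for stratum, tables in enrichment.items():
        de = de_results[stratum].set_index("feature_id")
        for direction, de_call in (("opening+up", "up"), ("closing+down", "down")):
            enr = tables.get(direction.split("+")[0])
            if enr is None or enr.empty:
                continue
            enriched = enr[enr["padj"] < padj_max]
            for tf in enriched["tf"]:
                gene = tf_gene_map.get(tf)
                if gene is None or gene not in de.index:
                    warnings.warn(
                        f"TF {tf!r} has no gene in the expression table; skipped",
                        stacklevel=2,
                    )
                    continue
                if de.loc[gene, "call"] == de_call:
                    support.setdefault((tf, direction), set()).add(stratum)
    rows = [
        {
            "tf": tf,
            "direction": direction,
            "stratum_support": ",".join(sorted(strata)),
            "n_strata": len(strata),
        }
        for (tf, direction), strata in sorted(support.items())
    ]
    return pd.DataFrame(rows, columns=["tf", "direction", "stratum_support", "n_strata"])


def assign_tf_targets(
    da_peaks: Sequence[GenomicInterval],
    hits: pd.DataFrame,
    tss_table: pd.DataFrame,
    de_results: pd.DataFrame,
) -> pd.DataFrame:
    """Nearest genes of DA peaks carrying the motif, joined with their DE call.

    Returns one row per (gene, peak) link; genes reachable from >= 1
    motif-bearing DA peak are the TF's potential targets.
    """
    with_motif = set(hits["peak_id"]) if not hits.empty else set()
    carrying = [p for p in da_peaks if p.name in with_motif]
    pairs = assign_nearest_genes(carrying, tss_table)
    de = de_results.set_index("feature_id")
    rows = []
    for pair in pairs:
        call = de.loc[pair.gene_id, "call"] if pair.gene_id in de.index else None
        rows.append(
            {
                "gene_id": pair.gene_id,
                "peak_id": pair.peak_id,
                "rule": pair.rule,
                "distance": pair.distance,
                "de_call": call,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "peak_id", "rule", "distance", "de_call"]
    )
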