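"""Chromatin-state annotation of consensus peaks.

Each peak is intersected with per-cell-type chromHMM-style segmentations;
when several states overlap one peak the conflict is resolved by a fixed
priority order so every peak gets exactly one state per cell type.  States
are then pooled into 6 meta-states for interpretation, and peaks whose
resolved state is an active promoter/enhancer in exactly one cell
population are labeled cell-specific.  A separate positional annotator
classifies peaks as promoter / genic / intergenic relative to TSSs and gene
bodies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .peaks import GenomicInterval

#: Conflict-resolution priority, highest first.
DEFAULT_STATE_PRIORITY = [
    "Active Enhancer",
    "Genic Enhancer",
    "Bivalent TSS",
    "Weak Enhancer",
    "Bivalent Enhancer",
    "PolyComb repressed",
    "TSS Flanking",
    "Transcription",
    "ZNF Genes and repeats",
    "Heterochromatin",
    "Quiescent/Low signal",
]

META_STATES = ["TSS", "Enhancer", "Repressed PolyComb", "Transcription", "Quiescent", "Other"]

#: Pooling of the 11 states into 6 meta-states.  Genic Enhancer joins the
#: Enhancer pool and TSS Flanking the TSS pool (Roadmap naming conventions);
#: both are overridable through StateVocabulary.
DEFAULT_META_MAP = {
    "Active Enhancer": "Enhancer",
    "Genic Enhancer": "Enhancer",
    "Bivalent TSS": "TSS",
    "Weak Enhancer": "Enhancer",
    "Bivalent Enhancer": "Enhancer",
    "PolyComb repressed": "Repressed PolyComb",
    "TSS Flanking": "TSS",
    "Transcription": "Transcription",
    "ZNF Genes and repeats": "Other",
    "Heterochromatin": "Other",
    "Quiescent/Low signal": "Quiescent",
}

#: States counting as "active promoter or active enhancer" for cell-specific
#: labeling.  "Active TSS" is honoured when a custom vocabulary includes it.
DEFAULT_ACTIVE_STATES = frozenset(
    {"Active Enhancer", "Genic Enhancer", "TSS Flanking", "Active TSS"}
)

NO_OVERLAP_STATE = "Quiescent/Low signal"


@dataclass
class StateVocabulary:
    """The chromatin-state vocabulary: priority order and meta-state pooling."""

    priority: list[str] = field(default_factory=lambda: list(DEFAULT_STATE_PRIORITY))
    meta_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_META_MAP))

    def __post_init__(self) -> None:
        if len(set(self.priority)) != len(self.priority):
            raise ValueError("priority list contains duplicates")
        missing = [s for s in self.priority if s not in self.meta_map]
        if missing:
            raise ValueError(f"meta_map is not total over states: missing {missing}")
        self._rank = {s: i for i, s in enumerate(self.priority)}

    @property
    def states(self) -> list[str]:
        return list(self.priority)

    def rank(self, state: str) -> int:
        try:
            return self._rank[state]
        except KeyError:
            raise ValueError(f"unknown chromatin state: {state!r}")


def resolve_state(overlapping_states: Iterable[str], vocab: StateVocabulary | None = None) -> str:
    """Resolve multiple overlapping states to the single highest-priority one."""
    vocab = vocab or StateVocabulary()
    states = list(overlapping_states)
    if not states:
        raise ValueError("resolve_state requires a non-empty state set")
    unknown = sorted({s for s in states if s not in vocab._rank})
    if unknown:
        raise ValueError(f"unknown chromatin states: {unknown}")
    return min(states, key=vocab.rank)


def pool_meta(state: str, vocab: StateVocabulary | None = None) -> str:
    """Map a state to its meta-state (total over the vocabulary)."""
    vocab = vocab or StateVocabulary()
    vocab.rank(state)  # validates membership
    return vocab.meta_map[state]


def _segmentation_tree(
    segments: Sequence[tuple[GenomicInterval, str]], cell_type: str
) -> dict[str, IntervalTree]:
    by_chrom: dict[str, list[tuple[GenomicInterval, str]]] = {}
    for iv, state in segments:
        by_chrom.setdefault(iv.chrom, []).append((iv, state))
    trees: dict[str, IntervalTree] = {}
    for chrom, items in by_chrom.items():
        items.sort(key=lambda x: x[0].start)
        prev_end = -1
        tree = IntervalTree()
        for iv, state in items:
            if iv.start < prev_end:
                raise ValueError(
                    f"segmentation for {cell_type!r} has overlapping intervals "
                    f"on {chrom} near {iv.start}"
                )
            prev_end = iv.end
            tree.addi(iv.start, iv.end, state)
        trees[chrom] = tree
    return trees


def annotate_states(
    peaks: Sequence[GenomicInterval],
    state_maps: Mapping[str, Sequence[tuple[GenomicInterval, str]]],
    vocab: StateVocabulary | None = None,
) -> pd.DataFrame:
    """Assign one resolved state and meta-state per (peak, cell type).

    States overlapping the peak by >= 1 bp are collected and resolved by
    priority; peaks with no overlap (including whole chromosomes absent from
    a segmentation) default to "Quiescent/Low signal".
    """
    vocab = vocab or StateVocabulary()
    rows = []
    for cell_type, segments in state_maps.items():
        trees = _segmentation_tree(segments, cell_type)
        for peak in peaks:
            tree = trees.get(peak.chrom)
            hits = tree.overlap(peak.start, peak.end) if tree is not None else ()
            states = [h.data for h in hits]
            state = resolve_state(states, vocab) if states else NO_OVERLAP_STATE
            rows.append(
                {
                    "peak_id": peak.name,
                    "cell_type": cell_type,
                    "state": state,
                    "meta": pool_meta(state, vocab),
                }
            )
    return pd.DataFrame(rows, columns=["peak_id", "cell_type", "state", "meta"])


def label_cell_specific(
    annotations: pd.DataFrame,
    active_states: frozenset[str] | set[str] = DEFAULT_ACTIVE_STATES,
) -> pd.DataFrame:
    """Label peaks whose resolved state is active in exactly one cell type.

    Returns one row per peak with ``cell_type`` set to the single population
    in which the peak is active, or None when the peak is active in zero or
    in multiple populations.
    """
    if annotations.empty:
        return pd.DataFrame(columns=["peak_id", "cell_type"])
    active = annotations[annotations["state"].isin(active_states)]
    counts = active.groupby("peak_id")["cell_type"].agg(list)
    label_map = {
        pid: cts[0] for pid, cts in counts.items() if len(cts) == 1
    }
    peak_ids = annotations["peak_id"].drop_duplicates()
    return pd.DataFrame(
        {"peak_id": peak_ids, "cell_type": [label_map.get(p) for p in peak_ids]}
    )


def positional_annotate(
    peaks: Sequence[GenomicInterval],
    tss_table: pd.DataFrame,
    gene_bodies: Sequence[GenomicInterval] = (),
    promoter_flank: int = 2000,
    summits: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Classify peaks as promoter / genic / intergenic.

    A peak is a promoter when its summit (midpoint when no summit is known)
    lies within ``promoter_flank`` bp of any TSS; otherwise genic when the
    peak overlaps a gene body; otherwise intergenic.  ``tss_table`` needs
    columns chrom, tss, gene_id (strand optional).
    """
    if tss_table.empty:
        raise ValueError("tss_table must be non-empty")
    tss_by_chrom: dict[str, list[int]] = {}
    for _, row in tss_table.iterrows():
        tss_by_chrom.setdefault(row["chrom"], []).append(int(row["tss"]))
    import numpy as np

    tss_sorted = {c: np.sort(v) for c, v in tss_by_chrom.items()}
    body_trees: dict[str, IntervalTree] = {}
    for iv in gene_bodies:
        body_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    rows = []
    for peak in peaks:
        if summits is not None and peak.name in summits:
            point = peak.start + summits[peak.name]
        else:
            point = peak.midpoint
        category = "intergenic"
        positions = tss_sorted.get(peak.chrom)
        if positions is not None and len(positions):
            i = np.searchsorted(positions, point)
            best = min(
                abs(point - positions[j])
                for j in (max(i - 1, 0), min(i, len(positions) - 1))
            )
            if best <= promoter_flank:
                category = "promoter"
        if category != "promoter":
            tree = body_trees.get(peak.chrom)
            if tree is not None and tree.overlap(peak.start, peak.end):
                category = "genic"
        rows.append({"peak_id": peak.name, "positional": category})
    return pd.DataFrame(rows)
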