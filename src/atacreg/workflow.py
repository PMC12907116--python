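"""Pipeline orchestration: the three contrasts (all / female / male) end to end.

Stages run in dependency order on a cohort directory of plain-text inputs:
consensus building -> consensus filtering -> NB differential (ATAC and RNA,
per stratum) -> chromatin-state and positional annotation -> ATAC-RNA
integration -> motif enrichment -> TF nomination and target assignment.
Sex-stratified contrasts rerun the differential engine on the subset sample
sheets with a group-only design; the "all" contrast includes the sex
covariate.  Outputs are TSVs plus a summary JSON; everything is a pure
function of the inputs, so a rerun reproduces the run byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as areg_io
from .annotation import (
    StateVocabulary,
    annotate_states,
    label_cell_specific,
    positional_annotate,
)
from .differential import adjust_bh, run_differential
from .integration import correlate_lfc, pair_promoter_genes
from .motifs import (
    assign_tf_targets,
    enrichment_from_indicator,
    motif_indicator,
    scan_peaks,
    nominate_tfs,
)
from .peaks import (
    DEFAULT_AUTOSOMES,
    CountsMatrix,
    GenomicInterval,
    build_consensus,
    filter_consensus,
)

logger = logging.getLogger("atacreg")

STRATA = ("all", "female", "male")


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run."""

    input_dir: str
    output_dir: str
    q_max: float = 0.01
    min_reads: int = 20
    max_cpm: float = 500.0
    padj_max: float = 0.05
    fc_min: float = 1.5
    promoter_flank: int = 2000  # positional annotation window around TSS
    pairing_flank: int = 1000  # promoter peak-gene pairing window
    enrich_window: int = 200  # motif enrichment window around summits
    scan_threshold_fraction: float = 0.8
    strata: tuple[str, ...] = STRATA
    autosomes: tuple[str, ...] = tuple(sorted(DEFAULT_AUTOSOMES))

    def __post_init__(self) -> None:
        bad = set(self.strata) - set(STRATA)
        if bad:
            raise ValueError(f"unknown strata: {sorted(bad)}")
        for name, lo, hi in (
            ("q_max", 0, 1),
            ("padj_max", 0, 1),
            ("scan_threshold_fraction", 0, 1),
        ):
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ValueError(f"{name} must be in ({lo}, {hi}], got {v}")
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "strata" in data:
            data["strata"] = tuple(data["strata"])
        if "autosomes" in data:
            data["autosomes"] = tuple(data["autosomes"])
        return cls(**data)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _read_tss(path) -> pd.DataFrame:
    rows = [
        {"chrom": iv.chrom, "tss": iv.start, "gene_id": iv.name, "strand": iv.strand or "+"}
        for iv in areg_io.read_bed(path)
    ]
    return pd.DataFrame(rows)


def map_consensus_to_reference(
    consensus: list[GenomicInterval], reference: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Name consensus intervals after the reference feature they overlap most.

    Count matrices are keyed by reference feature ids (read counting from
    alignments is outside this pipeline), so consensus intervals inherit the
    id of their best-overlapping reference peak; intervals overlapping no
    reference feature are dropped.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for iv in reference:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.name)
    named = []
    used = set()
    for iv in consensus:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        hits = tree.overlap(iv.start, iv.end)
        if not hits:
            continue
        best = max(hits, key=lambda h: min(h.end, iv.end) - max(h.begin, iv.start))
        if best.data in used:
            continue
        used.add(best.data)
        named.append(GenomicInterval(iv.chrom, iv.start, iv.end, name=best.data))
    return named


def _stratum_sheet(sheet: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "all":
        return sheet
    sex = "F" if stratum == "female" else "M"
    return sheet[sheet["sex"] == sex].reset_index(drop=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the summary dict (also written as JSON)."""
    t0 = time.time()
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    summary: dict = {"config": asdict(config), "stages": {}}

    def stage(name):
        def deco(fn):
            start = time.time()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(name, str(exc)) from exc
            logger.info("stage %-12s done in %.2fs", name, time.time() - start)
            summary["stages"][name] = round(time.time() - start, 3)
            return result

        return deco

    @stage("inputs")
    def _inputs():
        sheet = areg_io.read_sample_sheet(indir / "sample_sheet.tsv")
        peak_sets = {
            s: areg_io.read_broadpeak(indir / f"peaks_{s}.broadPeak")
            for s in sheet["sample_id"]
        }
        reference = areg_io.read_bed(indir / "peaks.bed")
        atac_lib = (
            sheet["atac_lib_size"].astype(float).to_numpy()
            if "atac_lib_size" in sheet.columns
            else None
        )
        rna_lib = (
            sheet["rna_lib_size"].astype(float).to_numpy()
            if "rna_lib_size" in sheet.columns
            else None
        )
        atac = areg_io.read_counts_tsv(indir / "atac_counts.tsv", atac_lib)
        rna = areg_io.read_counts_tsv(indir / "rna_counts.tsv", rna_lib)
        blacklist = areg_io.read_bed(indir / "blacklist.bed")
        tss = _read_tss(indir / "tss.bed")
        bodies = areg_io.read_bed(indir / "genes.bed")
        return sheet, peak_sets, reference, atac, rna, blacklist, tss, bodies

    sheet, peak_sets, reference, atac, rna, blacklist, tss, bodies = _inputs

    @stage("consensus")
    def _consensus():
        merged = build_consensus(list(peak_sets.values()), q_max=config.q_max)
        named = map_consensus_to_reference(merged, reference)
        areg_io.write_bed(named, outdir / "consensus.bed")
        filtered = filter_consensus(
            named,
            atac,
            blacklist,
            min_reads=config.min_reads,
            max_cpm=config.max_cpm,
            autosomes=set(config.autosomes),
        )
        areg_io.write_bed(filtered, outdir / "consensus_filtered.bed")
        return named, filtered

    consensus, filtered = _consensus
    filtered_ids = [p.name for p in filtered]
    atac_f = atac.subset_features(filtered_ids)

    @stage("differential")
    def _differential():
        atac_res, rna_res = {}, {}
        for stratum in config.strata:
            sub = _stratum_sheet(sheet, stratum)
            ids = list(sub["sample_id"])
            atac_res[stratum] = run_differential(
                atac_f.subset_samples(ids), sub,
                include_sex=(stratum == "all"),
                padj_max=config.padj_max, fc_min=config.fc_min,
                up_label="opening", down_label="closing",
            )
            rna_res[stratum] = run_differential(
                rna.subset_samples(ids), sub,
                include_sex=(stratum == "all"),
                padj_max=config.padj_max, fc_min=config.fc_min,
                up_label="up", down_label="down",
            )
            atac_res[stratum].to_csv(
                outdir / f"differential_atac_{stratum}.tsv", sep="\t", index=False
            )
            rna_res[stratum].to_csv(
                outdir / f"differential_rna_{stratum}.tsv", sep="\t", index=False
            )
        return atac_res, rna_res

    atac_res, rna_res = _differential

    @stage("annotation")
    def _annotation():
        state_files = sorted(indir.glob("states_*.bed"))
        state_maps = {
            f.stem.removeprefix("states_"): areg_io.read_state_bed(f)
            for f in state_files
        }
        vocab = StateVocabulary()
        ann = annotate_states(filtered, state_maps, vocab)
        specific = label_cell_specific(ann)
        positional = positional_annotate(
            filtered, tss, bodies, promoter_flank=config.promoter_flank
        )
        merged = ann.merge(
            specific.rename(columns={"cell_type": "specific_to"}), on="peak_id"
        ).merge(positional, on="peak_id")
        merged.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        return merged

    annotation = _annotation

    @stage("integration")
    def _integration():
        pairs = pair_promoter_genes(filtered, tss, flank=config.pairing_flank)
        pairs_df = pd.DataFrame(
            [
                {"peak_id": p.peak_id, "gene_id": p.gene_id, "rule": p.rule,
                 "distance": p.distance}
                for p in pairs
            ],
            columns=["peak_id", "gene_id", "rule", "distance"],
        )
        pairs_df.to_csv(outdir / "peak_gene_pairs.tsv", sep="\t", index=False)
        corr = correlate_lfc(pairs_df, atac_res["all"], rna_res["all"])
        pd.DataFrame([corr.__dict__]).to_csv(
            outdir / "correlation.tsv", sep="\t", index=False
        )
        return pairs_df, corr

    pairs_df, corr = _integration

    @stage("motifs")
    def _motifs():
        motif_models = areg_io.read_pfms(indir / "motif.pfm")
        sequences = areg_io.read_fasta(indir / "peaks.fa")
        # each motif is scanned once; strata share the per-peak indicator
        indicators = {
            m.name: motif_indicator(
                filtered_ids, sequences, m, window=config.enrich_window
            )
            for m in motif_models
        }
        enrichment: dict[str, dict[str, pd.DataFrame]] = {}
        for stratum in config.strata:
            res = atac_res[stratum].set_index("feature_id")
            calls = res.loc[filtered_ids, "call"]
            bg = list(calls[calls == "ns"].index)
            enrichment[stratum] = {}
            for direction in ("opening", "closing"):
                fg = list(calls[calls == direction].index)
                if not fg:
                    enrichment[stratum][direction] = pd.DataFrame(
                        columns=["tf", "fg_with_motif", "fg_total", "bg_with_motif",
                                 "bg_total", "p", "fold", "padj"]
                    )
                    continue
                rows = [
                    enrichment_from_indicator(m.name, fg, bg, indicators[m.name])
                    for m in motif_models
                ]
                df = pd.DataFrame([r.__dict__ for r in rows])
                df["padj"] = adjust_bh(df["p"])
                enrichment[stratum][direction] = df
                df.to_csv(
                    outdir / f"motif_enrichment_{stratum}_{direction}.tsv",
                    sep="\t", index=False,
                )
        return motif_models, sequences, enrichment

    motif_models, sequences, enrichment = _motifs

    @stage("nomination")
    def _nomination():
        tf_map_df = pd.read_csv(indir / "tf_gene_map.tsv", sep="\t")
        tf_gene_map = dict(zip(tf_map_df["tf"], tf_map_df["gene_id"]))
        noms = nominate_tfs(enrichment, rna_res, tf_gene_map, padj_max=config.padj_max)
        noms.to_csv(outdir / "nominations.tsv", sep="\t", index=False)
        targets = {}
        res_all = atac_res["all"].set_index("feature_id")
        da_ids = set(res_all.index[res_all["call"] != "ns"]) & set(filtered_ids)
        da_peaks = [p for p in filtered if p.name in da_ids]
        da_seqs = {p.name: sequences[p.name] for p in da_peaks}
        for tf in noms["tf"].unique() if not noms.empty else []:
            model = next(m for m in motif_models if m.name == tf)
            hits = scan_peaks(da_seqs, model)
            tgt = assign_tf_targets(da_peaks, hits, tss, rna_res["all"])
            tgt.to_csv(outdir / f"targets_{tf}.tsv", sep="\t", index=False)
            targets[tf] = tgt
        return noms, targets

    nominations, targets = _nomination

    meta_counts = (
        annotation.groupby("meta")["peak_id"].nunique().to_dict() if not annotation.empty else {}
    )
    summary.update(
        {
            "n_consensus": len(consensus),
            "n_filtered": len(filtered),
            "da_peaks": {
                s: atac_res[s]["call"].value_counts().to_dict() for s in config.strata
            },
            "de_genes": {
                s: rna_res[s]["call"].value_counts().to_dict() for s in config.strata
            },
            "meta_state_peaks": meta_counts,
            "correlation": {"r": corr.r, "p": corr.p, "n": corr.n},
            "nominated_tfs": nominations.to_dict("records"),
            "n_target_genes": {tf: int(t["gene_id"].nunique()) for tf, t in targets.items()},
            "runtime_s": round(time.time() - t0, 2),
        }
    )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return summary


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _setup_logging(outdir: Path) -> None:
    if logger.handlers:
        for h in list(logger.handlers):
            if isinstance(h, logging.FileHandler):
                logger.removeHandler(h)
                h.close()
    else:
        stream = logging.StreamHandler()
        stream.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
        logger.addHandler(stream)
        logger.setLevel(logging.INFO)
    fh = logging.FileHandler(outdir / "pipeline.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
    logger.addHandler(fh)
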