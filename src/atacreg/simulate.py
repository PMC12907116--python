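"""Synthetic PBMC multi-omics cohort generator with known ground truth.

Emulates the statistical structure of a two-group (control vs centenarian),
two-sex ATAC + RNA cohort: negative-binomial counts with planted
opening/closing peaks and up/down genes, a group-by-sex interaction for
sex-specific effects (female-dominant), cell-type-specific active chromatin
states, per-sample jittered peak calls with q-scores, peak sequences with a
planted "longevity TF" motif enriched near the summits of opening peaks,
and a decoy motif present only at background rates.  Every planted effect
is recorded in a machine-readable truth table so recovery can be scored
exactly.

All randomness flows from a single cohort seed; per-stage generators are
derived by stable hashing of the stage name, so outputs are byte-identical
for a fixed seed regardless of module call order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as areg_io
from .motifs import MotifModel
from .peaks import CountsMatrix, GenomicInterval, ScoredPeak

ACTIVE_STATES = ["Active Enhancer", "Genic Enhancer", "TSS Flanking"]
OTHER_STATES = [
    "Bivalent TSS",
    "Weak Enhancer",
    "Bivalent Enhancer",
    "PolyComb repressed",
    "Transcription",
    "ZNF Genes and repeats",
    "Heterochromatin",
]
QUIESCENT = "Quiescent/Low signal"

DEFAULT_CELL_TYPES = ["plasma_cell", "naive_B_cell", "monocyte"]


def _default_chrom_sizes() -> dict[str, int]:
    sizes = {f"chr{i}": 3_000_000 for i in range(1, 6)}
    sizes["chrX"] = 1_000_000  # decoy to exercise the autosome filter
    return sizes


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults mirror the study's structure at desk scale: 15 vs 15 samples,
    roughly two-thirds women, 5,000 peaks with 10% opening and 5% closing at
    a log2 fold change of 1.5, NB dispersion 0.2, and a fifth of planted
    effects restricted to women (group-by-sex interaction).
    """

    n_control: int = 15
    n_centenarian: int = 15
    sex_ratio: float = 0.65  # fraction female
    n_peaks: int = 5000
    n_genes: int = 2000
    frac_opening: float = 0.10
    frac_closing: float = 0.05
    frac_sex_specific: float = 0.20
    lfc_mean: float = 1.5
    dispersion: float = 0.2
    lib_size_range: tuple[float, float] = (1.5e7, 3.0e7)
    motif_plant_prob_fg: float = 0.4
    motif_plant_prob_bg: float = 0.05
    chrom_sizes: dict[str, int] = field(default_factory=_default_chrom_sizes)
    n_cell_types: int = 3
    seed: int = 0
    # secondary knobs
    peak_width_range: tuple[int, int] = (300, 700)
    baseline_log_mean: float = float(np.log(50.0))
    baseline_log_sd: float = 0.7
    rna_baseline_log_mean: float = float(np.log(100.0))
    rna_baseline_log_sd: float = 1.0
    gene_lfc_sd: float = 0.3
    tf_name: str = "ERG"
    tf_gene_lfc: float = 2.5  # near-absent -> strongly induced regulator
    jitter_sd: float = 10.0
    frac_q_pass: float = 0.95
    frac_blacklist: float = 0.01

    def __post_init__(self) -> None:
        for name in ("n_control", "n_centenarian", "n_peaks", "n_genes", "n_cell_types"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "sex_ratio",
            "frac_opening",
            "frac_closing",
            "frac_sex_specific",
            "motif_plant_prob_fg",
            "motif_plant_prob_bg",
            "frac_q_pass",
            "frac_blacklist",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        if self.frac_opening + self.frac_closing > 1.0:
            raise ValueError("frac_opening + frac_closing must be <= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion (NB alpha) must be > 0")
        lo, hi = self.lib_size_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError("lib_size_range must be a positive (low, high) pair")


@dataclass
class SyntheticTruth:
    """Planted-effect tables driving all recovery tests."""

    peak_effects: pd.DataFrame  # peak_id, effect, lfc, sex_specificity
    gene_effects: pd.DataFrame  # gene_id, effect, lfc, sex_specificity
    state_assignments: pd.DataFrame  # cell_type, peak_id, state
    tf_name: str = ""
    tf_gene_id: str = ""
    target_peak_ids: list[str] = field(default_factory=list)
    target_gene_ids: list[str] = field(default_factory=list)
    motif_plants: pd.DataFrame | None = None  # peak_id, position, motif


@dataclass
class SyntheticCohort:
    config: SimConfig
    sample_sheet: pd.DataFrame  # sample_id, group, sex (+ lib sizes)
    peaks: list[GenomicInterval]  # true peak intervals, named
    summits: dict[str, int]  # peak_id -> summit offset from start
    atac_counts: CountsMatrix
    rna_counts: CountsMatrix
    tss_table: pd.DataFrame  # chrom, tss, gene_id, strand
    gene_bodies: list[GenomicInterval]
    blacklist: list[GenomicInterval]
    state_maps: dict[str, list[tuple[GenomicInterval, str]]]
    truth: SyntheticTruth
    tf_gene_map: dict[str, str]
    peak_calls: dict[str, list[ScoredPeak]] | None = None
    sequences: dict[str, str] | None = None
    motif_models: list[MotifModel] | None = None


def _rng(seed: int, stage: str) -> np.random.Generator:
    """Stage generator derived from the cohort seed by stable name hashing."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    )


def default_planted_motif(name: str = "ERG") -> MotifModel:
    """An ETS-family-like 10-bp motif (consensus ACAGGAAGTG) as the planted TF."""
    consensus = "ACAGGAAGTG"
    return _consensus_pfm(name, consensus)


def default_decoy_motif(name: str = "ZNFDECOY") -> MotifModel:
    """A decoy motif never planted above background (consensus GCGCATGCGC)."""
    return _consensus_pfm(name, "GCGCATGCGC")


def _consensus_pfm(name: str, consensus: str, major: float = 85.0) -> MotifModel:
    pfm = np.full((4, len(consensus)), (100.0 - major) / 3.0)
    for i, b in enumerate(consensus):
        pfm["ACGT".index(b), i] = major
    return MotifModel(name=name, pfm=pfm)


def _place_peaks(config: SimConfig, rng: np.random.Generator):
    """Non-overlapping peak placement, allocated across chromosomes by size."""
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    counts = np.floor(config.n_peaks * sizes / sizes.sum()).astype(int)
    while counts.sum() < config.n_peaks:
        counts[int(np.argmax(sizes / (counts + 1)))] += 1
    w_lo, w_hi = config.peak_width_range
    intervals: list[tuple[str, int, int]] = []
    for chrom, k in zip(chroms, counts):
        if k == 0:
            continue
        slot = config.chrom_sizes[chrom] // k
        if slot <= w_hi + 1:
            raise ValueError(
                f"{chrom} too small for {k} peaks of width up to {w_hi}"
            )
        widths = rng.integers(w_lo, w_hi + 1, size=k)
        offsets = rng.integers(0, slot - w_hi, size=k)
        for i in range(k):
            start = i * slot + int(offsets[i])
            intervals.append((chrom, start, start + int(widths[i])))
    intervals.sort()
    peaks = [
        GenomicInterval(c, s, e, name=f"peak_{i + 1:06d}")
        for i, (c, s, e) in enumerate(intervals)
    ]
    summits = {p.name: p.length // 2 for p in peaks}
    return peaks, summits


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson draw: NB with Var = mu + alpha * mu^2."""
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    return rng.poisson(lam)


def _sample_sheet(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    idx = 1
    for group, n in (("control", config.n_control), ("centenarian", config.n_centenarian)):
        n_f = int(round(n * config.sex_ratio))
        sexes = ["F"] * n_f + ["M"] * (n - n_f)
        for sex in sexes:
            rows.append({"sample_id": f"S{idx:03d}", "group": group, "sex": sex})
            idx += 1
    return pd.DataFrame(rows)


def _effect_table(
    ids: list[str],
    eligible: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    up_label: str,
    down_label: str,
) -> pd.DataFrame:
    """Plant up/down effects of magnitude lfc_mean on eligible features."""
    n = len(ids)
    effect = np.array(["none"] * n, dtype=object)
    lfc = np.zeros(n)
    sex_spec = np.array(["all"] * n, dtype=object)
    n_up = int(round(config.frac_opening * n))
    n_down = int(round(config.frac_closing * n))
    pool = np.flatnonzero(eligible)
    chosen = rng.choice(pool, size=min(n_up + n_down, len(pool)), replace=False)
    up_idx, down_idx = chosen[:n_up], chosen[n_up:]
    effect[up_idx] = up_label
    lfc[up_idx] = config.lfc_mean
    effect[down_idx] = down_label
    lfc[down_idx] = -config.lfc_mean
    planted = np.concatenate([up_idx, down_idx])
    if len(planted):
        sexed = rng.random(len(planted)) < config.frac_sex_specific
        sex_spec[planted[sexed]] = "F"  # female-dominant remodeling in miniature
    return pd.DataFrame(
        {"feature_id": ids, "effect": effect, "lfc": lfc, "sex_specificity": sex_spec}
    )


def _count_matrix(
    feature_effects: pd.DataFrame,
    sheet: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    baseline_log_mean: float,
    baseline_log_sd: float,
    baseline_override: Mapping[str, float] | None = None,
) -> tuple[CountsMatrix, np.ndarray]:
    n_feat = len(feature_effects)
    n_samp = len(sheet)
    lo, hi = config.lib_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samp))
    sf = lib / np.exp(np.mean(np.log(lib)))
    baseline = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, size=n_feat))
    if baseline_override:
        ids = list(feature_effects["feature_id"])
        for fid, value in baseline_override.items():
            baseline[ids.index(fid)] = value
    is_cent = (sheet["group"] == "centenarian").to_numpy()
    is_f = (sheet["sex"] == "F").to_numpy()
    lfc = feature_effects["lfc"].to_numpy()
    female_only = (feature_effects["sex_specificity"] == "F").to_numpy()
    # effect applies to centenarians; female-only effects to centenarian women
    applies = np.where(
        female_only[:, None], is_cent[None, :] & is_f[None, :], is_cent[None, :]
    )
    mean = baseline[:, None] * sf[None, :] * np.power(2.0, lfc[:, None] * applies)
    values = _nb_draw(rng, mean, config.dispersion)
    cm = CountsMatrix(
        list(feature_effects["feature_id"]), list(sheet["sample_id"]), values, lib
    )
    return cm, lib


def simulate_cohort(config: SimConfig | None = None) -> SyntheticCohort:
    """Generate the full synthetic cohort (counts, annotations, truth)."""
    config = config or SimConfig()
    sheet = _sample_sheet(config, _rng(config.seed, "samples"))
    peaks, summits = _place_peaks(config, _rng(config.seed, "peaks"))
    peak_ids = [p.name for p in peaks]
    autosomal = np.array([p.chrom != "chrX" for p in peaks])

    eff_rng = _rng(config.seed, "effects")
    peak_effects = _effect_table(
        peak_ids, autosomal, config, eff_rng, "opening", "closing"
    ).rename(columns={"feature_id": "peak_id"})

    # genes piggyback on a subset of autosomal peaks: TSS at the peak summit,
    # expression effect inherited from the peak (plus noise) so accessibility
    # and expression changes are congruent by construction
    gene_rng = _rng(config.seed, "genes")
    auto_idx = np.flatnonzero(autosomal)
    if config.n_genes > len(auto_idx):
        raise ValueError("n_genes exceeds the number of autosomal peaks")
    gene_peak_idx = np.sort(gene_rng.choice(auto_idx, size=config.n_genes, replace=False))
    gene_ids = [f"gene_{i + 1:05d}" for i in range(config.n_genes)]
    strands = np.where(gene_rng.random(config.n_genes) < 0.5, "+", "-")
    tss_rows = []
    gene_bodies = []
    for gid, pi, strand in zip(gene_ids, gene_peak_idx, strands):
        p = peaks[pi]
        tss = p.start + summits[p.name]
        length = int(gene_rng.integers(5_000, 20_000))
        if strand == "+":
            b_start, b_end = tss, min(tss + length, config.chrom_sizes[p.chrom])
        else:
            b_start, b_end = max(0, tss - length), tss + 1
        tss_rows.append({"chrom": p.chrom, "tss": tss, "gene_id": gid, "strand": strand})
        gene_bodies.append(GenomicInterval(p.chrom, b_start, b_end, name=gid, strand=strand))
    tss_table = pd.DataFrame(tss_rows)

    pe = peak_effects.set_index("peak_id")
    g_eff, g_lfc, g_sex = [], [], []
    for pi in gene_peak_idx:
        row = pe.loc[peaks[pi].name]
        if row["effect"] == "opening":
            g_eff.append("up")
            g_lfc.append(row["lfc"] + gene_rng.normal(0, config.gene_lfc_sd))
        elif row["effect"] == "closing":
            g_eff.append("down")
            g_lfc.append(row["lfc"] + gene_rng.normal(0, config.gene_lfc_sd))
        else:
            g_eff.append("none")
            g_lfc.append(0.0)
        g_sex.append(row["sex_specificity"])
    gene_effects = pd.DataFrame(
        {"gene_id": gene_ids, "effect": g_eff, "lfc": g_lfc, "sex_specificity": g_sex}
    )

    # the planted longevity TF: its own gene is unconditionally upregulated
    none_genes = np.flatnonzero((gene_effects["effect"] == "none").to_numpy())
    tf_gene_pos, decoy_gene_pos = gene_rng.choice(none_genes, size=2, replace=False)
    tf_gene_id = gene_ids[int(tf_gene_pos)]
    decoy_gene_id = gene_ids[int(decoy_gene_pos)]
    gene_effects.loc[int(tf_gene_pos), ["effect", "lfc", "sex_specificity"]] = [
        "up", config.tf_gene_lfc, "all",
    ]

    counts_rng = _rng(config.seed, "atac_counts")
    atac_counts, _ = _count_matrix(
        peak_effects.rename(columns={"peak_id": "feature_id"}),
        sheet, config, counts_rng,
        config.baseline_log_mean, config.baseline_log_sd,
    )
    rna_rng = _rng(config.seed, "rna_counts")
    # the planted TF's gene is a well-expressed transcript (+1 sd baseline):
    # the emulated regulator is consistently detectable, not a borderline gene
    tf_baseline = float(
        np.exp(config.rna_baseline_log_mean + config.rna_baseline_log_sd)
    )
    rna_counts, _ = _count_matrix(
        gene_effects.rename(columns={"gene_id": "feature_id"}),
        sheet, config, rna_rng,
        config.rna_baseline_log_mean, config.rna_baseline_log_sd,
        baseline_override={tf_gene_id: tf_baseline},
    )
    sheet = sheet.copy()
    sheet["atac_lib_size"] = atac_counts.lib_sizes
    sheet["rna_lib_size"] = rna_counts.lib_sizes

    # blacklist covers a few effect-free autosomal peaks
    bl_rng = _rng(config.seed, "blacklist")
    none_auto = np.flatnonzero(
        (peak_effects["effect"] == "none").to_numpy() & autosomal
    )
    n_black = int(round(config.frac_blacklist * config.n_peaks))
    black_idx = np.sort(bl_rng.choice(none_auto, size=min(n_black, len(none_auto)), replace=False))
    blacklist = [
        GenomicInterval(peaks[i].chrom, max(0, peaks[i].start - 100), peaks[i].end + 100)
        for i in black_idx
    ]

    state_maps, state_assignments = _simulate_states(
        config, peaks, _rng(config.seed, "states")
    )

    truth = SyntheticTruth(
        peak_effects=peak_effects,
        gene_effects=gene_effects,
        state_assignments=state_assignments,
        tf_name=config.tf_name,
        tf_gene_id=tf_gene_id,
    )
    return SyntheticCohort(
        config=config,
        sample_sheet=sheet,
        peaks=peaks,
        summits=summits,
        atac_counts=atac_counts,
        rna_counts=rna_counts,
        tss_table=tss_table,
        gene_bodies=gene_bodies,
        blacklist=blacklist,
        state_maps=state_maps,
        truth=truth,
        tf_gene_map={config.tf_name: tf_gene_id, "ZNFDECOY": decoy_gene_id},
    )


def _simulate_states(config, peaks, rng):
    """Per-cell-type segmentations tiling each chromosome.

    Around each peak one of four patterns is drawn: cell-specific active
    (one cell type active), shared active, non-active regulatory, or
    quiescent everywhere; everything between peaks is quiescent.
    """
    cell_types = (
        DEFAULT_CELL_TYPES[: config.n_cell_types]
        if config.n_cell_types <= len(DEFAULT_CELL_TYPES)
        else [f"cell_type_{i + 1}" for i in range(config.n_cell_types)]
    )
    n = len(peaks)
    pattern = rng.choice(
        ["specific", "shared", "nonactive", "quiescent"],
        size=n,
        p=[0.10, 0.10, 0.15, 0.65],
    )
    peak_states: dict[str, list[str]] = {ct: [] for ct in cell_types}
    for i in range(n):
        if pattern[i] == "specific":
            ct = cell_types[int(rng.integers(len(cell_types)))]
            state = ACTIVE_STATES[int(rng.integers(len(ACTIVE_STATES)))]
            for c in cell_types:
                peak_states[c].append(state if c == ct else QUIESCENT)
        elif pattern[i] == "shared":
            state = ACTIVE_STATES[int(rng.integers(len(ACTIVE_STATES)))]
            for c in cell_types:
                peak_states[c].append(state)
        elif pattern[i] == "nonactive":
            for c in cell_types:
                peak_states[c].append(
                    OTHER_STATES[int(rng.integers(len(OTHER_STATES)))]
                )
        else:
            for c in cell_types:
                peak_states[c].append(QUIESCENT)

    state_maps: dict[str, list[tuple[GenomicInterval, str]]] = {}
    rows = []
    by_chrom: dict[str, list[int]] = {}
    for i, p in enumerate(peaks):
        by_chrom.setdefault(p.chrom, []).append(i)
    for ct in cell_types:
        segments: list[tuple[GenomicInterval, str]] = []
        for chrom, size in config.chrom_sizes.items():
            cursor = 0
            for i in by_chrom.get(chrom, []):
                p = peaks[i]
                if p.start > cursor:
                    segments.append((GenomicInterval(chrom, cursor, p.start), QUIESCENT))
                segments.append((GenomicInterval(chrom, p.start, p.end), peak_states[ct][i]))
                cursor = p.end
            if cursor < size:
                segments.append((GenomicInterval(chrom, cursor, size), QUIESCENT))
        state_maps[ct] = segments
        rows.extend(
            {"cell_type": ct, "peak_id": peaks[i].name, "state": peak_states[ct][i]}
            for i in range(n)
        )
    return state_maps, pd.DataFrame(rows)


def simulate_peak_calls(
    cohort: SyntheticCohort,
    jitter_sd: float | None = None,
    frac_q_pass: float | None = None,
) -> dict[str, list[ScoredPeak]]:
    """Per-sample scored peak calls: jittered true boundaries with q-scores.

    Boundaries are jittered by rounded Gaussian noise (``jitter_sd`` = 0
    reproduces the true intervals exactly); q-scores pass the 1% cutoff with
    probability ``frac_q_pass`` independently per (peak, sample).
    """
    config = cohort.config
    jitter_sd = config.jitter_sd if jitter_sd is None else jitter_sd
    frac_q_pass = config.frac_q_pass if frac_q_pass is None else frac_q_pass
    rng = _rng(config.seed, "peak_calls")
    calls: dict[str, list[ScoredPeak]] = {}
    for sample_id in cohort.sample_sheet["sample_id"]:
        sample_peaks: list[ScoredPeak] = []
        for p in cohort.peaks:
            if jitter_sd > 0:
                ds, de = np.round(rng.normal(0, jitter_sd, size=2)).astype(int)
            else:
                ds = de = 0
            start = max(0, p.start + int(ds))
            end = max(start + 1, p.end + int(de))
            if rng.random() < frac_q_pass:
                q = 10.0 ** (-rng.uniform(2.0, 8.0))
            else:
                q = float(rng.uniform(0.011, 1.0))
            summit = min(max(0, p.start + cohort.summits[p.name] - start), end - start - 1)
            sample_peaks.append(
                ScoredPeak(
                    GenomicInterval(p.chrom, start, end, name=p.name),
                    q=q,
                    summit_offset=summit,
                )
            )
        calls[sample_id] = sample_peaks
    cohort.peak_calls = calls
    return calls


def simulate_sequences(
    cohort: SyntheticCohort,
    motif: MotifModel | None = None,
    plant_prob_fg: float | None = None,
    plant_prob_bg: float | None = None,
) -> dict[str, str]:
    """Peak sequences: i.i.d. uniform background with motif plants near summits.

    The planted TF's consensus is inserted near the summit of opening peaks
    with probability ``plant_prob_fg`` and anywhere in other peaks with
    probability ``plant_prob_bg``.  Plant positions, the TF's target peaks
    and the implied target genes are recorded in the truth table.
    """
    config = cohort.config
    motif = motif or default_planted_motif(config.tf_name)
    fg_p = config.motif_plant_prob_fg if plant_prob_fg is None else plant_prob_fg
    bg_p = config.motif_plant_prob_bg if plant_prob_bg is None else plant_prob_bg
    w = len(motif.consensus)
    min_len = min(p.length for p in cohort.peaks)
    if w > min_len:
        raise ValueError(f"motif width {w} exceeds the shortest peak ({min_len} bp)")
    rng = _rng(config.seed, "sequences")
    consensus = motif.consensus
    effects = cohort.truth.peak_effects.set_index("peak_id")["effect"]
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    consensus_bytes = consensus.encode()
    sequences: dict[str, str] = {}
    plant_rows = []
    for p in cohort.peaks:
        seq = bytearray(lut[rng.integers(0, 4, size=p.length)].tobytes())
        opening = effects.loc[p.name] == "opening"
        prob = fg_p if opening else bg_p
        if rng.random() < prob:
            if opening:
                pos = int(
                    np.clip(
                        cohort.summits[p.name] - w // 2 + round(rng.normal(0, 20)),
                        0,
                        p.length - w,
                    )
                )
            else:
                pos = int(rng.integers(0, p.length - w + 1))
            seq[pos : pos + w] = consensus_bytes
            plant_rows.append({"peak_id": p.name, "position": pos, "motif": motif.name})
        sequences[p.name] = seq.decode()
    cohort.sequences = sequences
    cohort.motif_models = [motif, default_decoy_motif()]
    plants = pd.DataFrame(plant_rows, columns=["peak_id", "position", "motif"])
    cohort.truth.motif_plants = plants
    planted_set = set(plants["peak_id"])
    cohort.truth.target_peak_ids = [
        pid for pid in effects.index if pid in planted_set and effects.loc[pid] == "opening"
    ]
    peak_of_gene = dict(
        zip(
            cohort.tss_table["gene_id"],
            (
                cohort.peaks[i].name
                for i in _gene_peak_indices(cohort)
            ),
        )
    )
    target_peaks = set(cohort.truth.target_peak_ids)
    cohort.truth.target_gene_ids = [
        g for g, pk in peak_of_gene.items() if pk in target_peaks
    ]
    return sequences


def _gene_peak_indices(cohort: SyntheticCohort) -> list[int]:
    """Indices of the peaks whose summits host each gene's TSS (in gene order)."""
    summit_to_idx = {
        (p.chrom, p.start + cohort.summits[p.name]): i
        for i, p in enumerate(cohort.peaks)
    }
    return [
        summit_to_idx[(row["chrom"], row["tss"])]
        for _, row in cohort.tss_table.iterrows()
    ]


def truth_frame(truth: SyntheticTruth) -> pd.DataFrame:
    """Single machine-readable truth table over peaks and genes."""
    target_peaks = set(truth.target_peak_ids)
    target_genes = set(truth.target_gene_ids)
    pk = truth.peak_effects.rename(columns={"peak_id": "feature_id"}).copy()
    pk.insert(0, "kind", "peak")
    pk["tf_target"] = pk["feature_id"].isin(target_peaks).astype(int)
    gn = truth.gene_effects.rename(columns={"gene_id": "feature_id"}).copy()
    gn.insert(0, "kind", "gene")
    gn["tf_target"] = gn["feature_id"].isin(target_genes).astype(int)
    return pd.concat([pk, gn], ignore_index=True)


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Emit the cohort as the pipeline's plain-text input files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.sample_sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    areg_io.write_counts_tsv(cohort.atac_counts, outdir / "atac_counts.tsv")
    areg_io.write_counts_tsv(cohort.rna_counts, outdir / "rna_counts.tsv")
    areg_io.write_bed(cohort.peaks, outdir / "peaks.bed")
    areg_io.write_bed(cohort.blacklist, outdir / "blacklist.bed")
    tss_intervals = [
        GenomicInterval(r["chrom"], r["tss"], r["tss"] + 1, r["gene_id"], 0.0, r["strand"])
        for _, r in cohort.tss_table.iterrows()
    ]
    areg_io.write_bed(tss_intervals, outdir / "tss.bed")
    areg_io.write_bed(cohort.gene_bodies, outdir / "genes.bed")
    for ct, segments in cohort.state_maps.items():
        areg_io.write_state_bed(segments, outdir / f"states_{ct}.bed")
    if cohort.peak_calls is None:
        simulate_peak_calls(cohort)
    for sample_id, calls in cohort.peak_calls.items():
        areg_io.write_broadpeak(calls, outdir / f"peaks_{sample_id}.broadPeak")
    if cohort.sequences is None:
        simulate_sequences(cohort)
    areg_io.write_fasta(cohort.sequences, outdir / "peaks.fa")
    areg_io.write_pfms(cohort.motif_models, outdir / "motif.pfm")
    pd.DataFrame(
        [
            {"tf": tf, "gene_id": g, "planted": int(tf == cohort.truth.tf_name)}
            for tf, g in cohort.tf_gene_map.items()
        ]
    ).to_csv(outdir / "tf_gene_map.tsv", sep="\t", index=False)
    truth_frame(cohort.truth).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return outdir
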