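"""PWM construction and scanning, motif enrichment, profiles, nomination."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from atacreg.motifs import (
    MotifModel,
    assign_tf_targets,
    default_min_score,
    footprint_profile,
    max_score,
    motif_enrichment,
    nominate_tfs,
    occurrence_profile,
    pfm_to_pwm,
    reverse_complement,
    scan_peaks,
    scan_sequence,
)
from atacreg.peaks import GenomicInterval


def motif_from_consensus(consensus, name="TF", major=97.0):
    pfm = np.full((4, len(consensus)), (100 - major) / 3)
    for i, b in enumerate(consensus):
        pfm["ACGT".index(b), i] = major
    return MotifModel(name=name, pfm=pfm)


class TestPfmToPwm:
    def test_uniform_column_gives_zeros(self):
        m = MotifModel("u", np.full((4, 4), 10.0), pseudocount=0.0)
        np.testing.assert_allclose(pfm_to_pwm(m), 0.0, atol=1e-12)

    def test_single_count_column_arithmetic(self):
        pfm = np.zeros((4, 4))
        pfm[0, :] = 1.0  # A-only columns
        m = MotifModel("a", pfm, pseudocount=0.25)
        pwm = pfm_to_pwm(m)
        assert pwm[0, 0] == pytest.approx(math.log2((1.25 / 2) / 0.25))

    def test_shape(self):
        m = motif_from_consensus("ACGTAC")
        assert pfm_to_pwm(m).shape == (4, 6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            MotifModel("bad", -np.ones((4, 4)))

    def test_short_motif_rejected(self):
        with pytest.raises(ValueError):
            MotifModel("short", np.ones((4, 3)))


class TestScan:
    def test_planted_consensus_found_at_max_score(self):
        m = motif_from_consensus("ACGGAAGT")
        pwm = pfm_to_pwm(m)
        seq = "T" * 20 + m.consensus + "T" * 20
        hits = scan_sequence(seq, pwm)
        plus = [h for h in hits if h[1] == "+"]
        assert any(h[0] == 20 for h in plus)
        best = max(h[2] for h in plus)
        assert best == pytest.approx(max_score(pwm))

    def test_threshold_above_max_is_empty(self):
        m = motif_from_consensus("ACGGAAGT")
        pwm = pfm_to_pwm(m)
        assert scan_sequence("ACGGAAGT" * 4, pwm, min_score=max_score(pwm) + 1) == []

    def test_non_acgt_window_skipped(self):
        m = motif_from_consensus("ACGT")
        pwm = pfm_to_pwm(m)
        hits = scan_sequence("ACNTACGT", pwm, min_score=0.0)
        assert all(h[0] >= 3 for h in hits)  # windows covering the N are dropped

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_reverse_complement_symmetry(self, data):
        """Scanning revcomp(seq) mirrors the hit set: offsets reflect, strands flip."""
        rng_seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(rng_seed)
        w = int(rng.integers(4, 9))
        L = int(rng.integers(w, 40))
        pwm = rng.normal(0, 1, size=(4, w))
        seq = "".join(rng.choice(list("ACGT"), L))
        fwd = scan_sequence(seq, pwm, min_score=-1e9)
        rev = scan_sequence(reverse_complement(seq), pwm, min_score=-1e9)
        flip = {"+": "-", "-": "+"}
        mirrored = sorted(
            (L - w - off, flip[strand], round(score, 6)) for off, strand, score in rev
        )
        assert sorted((o, s, round(sc, 6)) for o, s, sc in fwd) == mirrored

    def test_matches_biopython_pssm_scores(self):
        """Forward log-odds scores agree with Biopython's PSSM calculation."""
        from Bio.Seq import Seq
        from Bio.motifs import Motif
        from Bio.motifs.matrix import FrequencyPositionMatrix

        rng = np.random.default_rng(11)
        counts = rng.integers(1, 50, size=(4, 6)).astype(float)
        m = MotifModel("x", counts, pseudocount=0.5)
        pwm = pfm_to_pwm(m)
        bio_counts = FrequencyPositionMatrix(
            "ACGT", {b: list(counts["ACGT".index(b)]) for b in "ACGT"}
        )
        bio_pwm = bio_counts.normalize(pseudocounts=0.5)
        bio_pssm = bio_pwm.log_odds()
        seq = "".join(rng.choice(list("ACGT"), 30))
        ours = {
            off: score for off, strand, score in scan_sequence(seq, pwm, -1e9) if strand == "+"
        }
        theirs = bio_pssm.calculate(Seq(seq))
        for off, score in ours.items():
            assert score == pytest.approx(float(theirs[off]), abs=1e-4)


class TestEnrichment:
    def _seqs(self, with_motif, without, consensus="ACGGAAGT"):
        seqs = {}
        for pid in with_motif:
            seqs[pid] = "T" * 50 + consensus + "T" * 50
        for pid in without:
            seqs[pid] = "T" * (100 + len(consensus))
        return seqs

    def test_exact_hypergeometric_tail(self):
        """fg = exactly the 5 motif-bearing peaks of 10 -> p = 1 / C(10, 5)."""
        m = motif_from_consensus("ACGGAAGT")
        with_m = [f"w{i}" for i in range(5)]
        without = [f"o{i}" for i in range(5)]
        res = motif_enrichment(with_m, without, self._seqs(with_m, without), m)
        assert res.p == pytest.approx(1 / math.comb(10, 5), rel=1e-9)
        assert res.fg_with_motif == 5 and res.bg_with_motif == 0

    def test_equal_rates_not_enriched(self):
        m = motif_from_consensus("ACGGAAGT")
        fg_w, fg_o = ["a1", "a2"], ["a3", "a4"]
        bg_w, bg_o = ["b1", "b2", "b3"], ["b4", "b5", "b6"]
        seqs = self._seqs(fg_w + bg_w, fg_o + bg_o)
        res = motif_enrichment(fg_w + fg_o, bg_w + bg_o, seqs, m)
        assert res.p > 0.5

    def test_absent_motif_trivial(self):
        m = motif_from_consensus("ACGGAAGT")
        fg, bg = ["a"], ["b"]
        res = motif_enrichment(fg, bg, self._seqs([], fg + bg), m)
        assert res.p == 1.0 and res.fold == 0.0

    def test_overlapping_sets_rejected(self):
        m = motif_from_consensus("ACGGAAGT")
        seqs = self._seqs(["a"], ["b"])
        with pytest.raises(ValueError, match="disjoint"):
            motif_enrichment(["a"], ["a", "b"], seqs, m)

    def test_empty_foreground_rejected(self):
        m = motif_from_consensus("ACGGAAGT")
        with pytest.raises(ValueError, match="non-empty"):
            motif_enrichment([], ["b"], self._seqs([], ["b"]), m)

    def test_hit_outside_summit_window_ignored(self):
        m = motif_from_consensus("ACGGAAGT")
        # motif planted 400 bp from the summit of a 1 kb peak; window is 200
        seqs = {"far": "T" * 900 + m.consensus + "T" * 92, "none": "T" * 1000}
        res = motif_enrichment(["far"], ["none"], seqs, m, window=200)
        assert res.fg_with_motif == 0


class TestProfiles:
    def test_plants_at_summit_fill_central_bin(self):
        w = 8
        hits = pd.DataFrame(
            {"peak_id": [f"p{i}" for i in range(40)],
             "offset": [200 - w // 2] * 40,
             "strand": ["+"] * 40,
             "score": [10.0] * 40}
        )
        summits = {f"p{i}": 200 for i in range(100)}
        prof = occurrence_profile(hits, summits, motif_width=w)
        assert len(prof) == 100
        central = prof[(prof["bin_start"] <= 0) & (prof["bin_start"] > -10)]
        assert central["occurrence"].iloc[0] == pytest.approx(0.4)
        assert prof["occurrence"].sum() == pytest.approx(0.4)

    def test_no_hits_zero_profile(self):
        prof = occurrence_profile(
            pd.DataFrame(columns=["peak_id", "offset", "strand", "score"]),
            {"p": 100},
            motif_width=8,
        )
        assert len(prof) == 100 and prof["occurrence"].sum() == 0.0

    def test_footprint_detects_core_protection(self):
        rng = np.random.default_rng(12)
        core, flank = 10, 50
        vecs, rows = {}, []
        for i in range(30):
            v = rng.poisson(10.0, 400).astype(float)
            v[195:205] = rng.poisson(2.0, 10)  # core suppressed to 20%
            vecs[f"p{i}"] = v
            rows.append({"peak_id": f"p{i}", "offset": 195, "strand": "+", "score": 5.0})
        profile, depth = footprint_profile(vecs, pd.DataFrame(rows), core=core, flank=flank)
        assert depth > 0
        assert len(profile) == 2 * (core // 2 + flank)

    def test_uniform_insertions_no_footprint(self):
        vecs = {"p": np.full(400, 7.0)}
        hits = pd.DataFrame([{"peak_id": "p", "offset": 195, "strand": "+", "score": 5.0}])
        _, depth = footprint_profile(vecs, hits, core=10)
        assert depth == pytest.approx(0.0, abs=1e-9)

    def test_no_hits_gives_nan_depth(self):
        profile, depth = footprint_profile(
            {}, pd.DataFrame(columns=["peak_id", "offset", "strand", "score"]), core=10
        )
        assert profile.size == 0 and np.isnan(depth)

    def test_edge_hits_skipped(self):
        vecs = {"p": np.full(60, 5.0)}
        hits = pd.DataFrame([{"peak_id": "p", "offset": 2, "strand": "+", "score": 5.0}])
        profile, depth = footprint_profile(vecs, hits, core=10, flank=50)
        assert profile.size == 0 and np.isnan(depth)


def _enr(tf, padj):
    return pd.DataFrame(
        [{"tf": tf, "fg_with_motif": 5, "fg_total": 10, "bg_with_motif": 1,
          "bg_total": 50, "p": padj / 2, "fold": 10.0, "padj": padj}]
    )


def _de(gene, call):
    return pd.DataFrame([{"feature_id": gene, "log2fc": 1.0, "call": call}])


class TestNomination:
    def test_full_stratum_support(self):
        enrichment = {
            s: {"opening": _enr("ERG", 0.001), "closing": _enr("ERG", 0.9)}
            for s in ("all", "female", "male")
        }
        de = {s: _de("gene_erg", "up") for s in ("all", "female", "male")}
        noms = nominate_tfs(enrichment, de, {"ERG": "gene_erg"})
        assert len(noms) == 1
        row = noms.iloc[0]
        assert row["tf"] == "ERG" and row["direction"] == "opening+up"
        assert row["stratum_support"] == "all,female,male"

    def test_enriched_but_gene_ns_not_nominated(self):
        enrichment = {"all": {"opening": _enr("ERG", 0.001), "closing": _enr("ERG", 1.0)}}
        noms = nominate_tfs(enrichment, {"all": _de("gene_erg", "ns")}, {"ERG": "gene_erg"})
        assert noms.empty

    def test_gene_up_but_motif_flat_not_nominated(self):
        enrichment = {"all": {"opening": _enr("ERG", 0.8), "closing": _enr("ERG", 1.0)}}
        noms = nominate_tfs(enrichment, {"all": _de("gene_erg", "up")}, {"ERG": "gene_erg"})
        assert noms.empty

    def test_missing_gene_warns_and_skips(self):
        enrichment = {"all": {"opening": _enr("ERG", 0.001), "closing": _enr("ERG", 1.0)}}
        with pytest.warns(UserWarning, match="no gene"):
            noms = nominate_tfs(enrichment, {"all": _de("other", "up")}, {"ERG": "missing"})
        assert noms.empty


class TestTargets:
    def test_join_semantics_two_peaks_one_gene(self):
        peaks = [
            GenomicInterval("chr1", 1000, 1400, name="pk1"),
            GenomicInterval("chr1", 3000, 3400, name="pk2"),
            GenomicInterval("chr1", 5000, 5400, name="pk_nomotif"),
        ]
        hits = pd.DataFrame(
            [{"peak_id": "pk1", "offset": 10, "strand": "+", "score": 9.0},
             {"peak_id": "pk2", "offset": 20, "strand": "-", "score": 8.0}]
        )
        tss = pd.DataFrame(
            [{"chrom": "chr1", "tss": 2000, "gene_id": "target", "strand": "+"}]
        )
        de = pd.DataFrame([{"feature_id": "target", "log2fc": 2.0, "call": "up"}])
        tgt = assign_tf_targets(peaks, hits, tss, de)
        assert len(tgt) == 2  # one row per motif-bearing peak
        assert set(tgt["gene_id"]) == {"target"}
        assert set(tgt["de_call"]) == {"up"}
        assert "pk_nomotif" not in set(tgt["peak_id"])

    def test_planted_truth_targets_recovered(self, small_cohort):
        """Targets of the planted TF resolve to genes marked up/down in truth."""
        from atacreg.simulate import simulate_sequences

        cohort = small_cohort
        if cohort.sequences is None:
            simulate_sequences(cohort)
        truth_targets = set(cohort.truth.target_gene_ids)
        planted_peaks = [p for p in cohort.peaks if p.name in set(cohort.truth.target_peak_ids)]
        hits = pd.DataFrame(
            [{"peak_id": p.name, "offset": 0, "strand": "+", "score": 1.0} for p in planted_peaks]
        )
        de = cohort.truth.gene_effects.rename(
            columns={"gene_id": "feature_id", "effect": "call"}
        )
        tgt = assign_tf_targets(planted_peaks, hits, cohort.tss_table, de)
        # every truth target gene is reachable from its own promoter peak
        assert truth_targets <= set(tgt["gene_id"])
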