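import numpy as np
import pandas as pd
import pytest

import vmerv
from vmerv.assembly import ErvElement
from vmerv.context import (
    TranscriptHit,
    biased_screen,
    compute_transcript_hits,
    consistent_transcript_overlap,
    distance_to_nearest_peak,
    nearest_gene,
    scaled_profile,
)


def element(start, end, strand="+", chrom="chr1", eid="e1"):
    return ErvElement(id=eid, chrom=chrom, start=start, end=end, strand=strand, family="IAP")


def genes_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "strand"])


class TestNearestGene:
    def test_element_inside_gene_distance_zero(self):
        genes = genes_df([("chr1", 1000, 50000, "gA", "+")])
        assert nearest_gene(element(2000, 9000), genes) == ("gA", 0)

    def test_upstream_gene_has_negative_signed_distance(self):
        genes = genes_df(
            [("chr1", 100, 1900, "gLeft", "+"), ("chr1", 9500, 12000, "gRight", "+")]
        )
        gene, dist = nearest_gene(element(2000, 9000), genes)
        assert (gene, dist) == ("gLeft", -100)

    def test_equidistant_tie_goes_to_lower_coordinate_gene(self, caplog):
        genes = genes_df(
            [("chr1", 100, 1900, "gLeft", "+"), ("chr1", 9100, 12000, "gRight", "+")]
        )
        with caplog.at_level("INFO"):
            gene, dist = nearest_gene(element(2000, 9000), genes)
        assert gene == "gLeft"
        assert dist == -100

    def test_no_gene_on_chromosome(self):
        genes = genes_df([("chr2", 100, 1900, "gA", "+")])
        assert nearest_gene(element(2000, 9000), genes) == (None, None)


class TestBiasedScreen:
    def test_element_inside_de_gene_retained(self):
        genes = genes_df([("chr1", 1000, 50000, "gA", "+")])
        kept = biased_screen([element(2000, 9000)], {"gA"}, genes)
        assert [e.id for e in kept] == ["e1"]

    def test_nearest_non_de_gene_drops_element(self):
        genes = genes_df(
            [("chr1", 1000, 1900, "gNear", "+"), ("chr1", 90000, 95000, "gDE", "+")]
        )
        assert biased_screen([element(2000, 9000)], {"gDE"}, genes) == []

    def test_window_controls_retention(self):
        genes = genes_df([("chr1", 11000, 20000, "gDE", "+")])
        el = element(2000, 9000)  # 2 kb from the DE gene
        assert biased_screen([el], {"gDE"}, genes, window=10_000) == [el]
        assert biased_screen([el], {"gDE"}, genes, window=1_000) == []

    def test_empty_de_list_warns_and_returns_nothing(self, caplog):
        genes = genes_df([("chr1", 1000, 50000, "gA", "+")])
        with caplog.at_level("WARNING"):
            out = biased_screen([element(2000, 9000)], set(), genes)
        assert out == []
        assert "empty DE" in caplog.text


def constant_signal(chrom="chr1", lo=0, hi=1_000_000, value=1.0):
    return pd.DataFrame({"chrom": [chrom], "start": [lo], "end": [hi], "value": [value]})


class TestScaledProfile:
    def test_flat_field_gives_flat_profile(self):
        els = [element(50_000, 57_000), element(200_000, 202_000, strand="-")]
        prof = scaled_profile(constant_signal(), els, flank=5000, body_bins=20, flank_bins=50)
        assert np.allclose(prof.values, 1.0)
        assert np.allclose(prof.coverage, 1.0)
        assert prof.n_bins == 120

    def test_signal_restricted_to_bodies_leaves_flanks_empty(self):
        els = [element(50_000, 57_000)]
        signal = pd.DataFrame(
            {"chrom": ["chr1"], "start": [50_000], "end": [57_000], "value": [2.0]}
        )
        prof = scaled_profile(signal, els, flank=5000)
        assert np.allclose(prof.values[:50], 0.0)
        assert np.allclose(prof.values[50:70], 2.0)
        assert np.allclose(prof.values[70:], 0.0)

    def test_flank_bins_average_across_elements(self):
        rows = []
        for start, end, v in [(50_000, 57_000, 2.0), (200_000, 205_000, 4.0)]:
            rows.append(("chr1", start - 5000, start, v))
            rows.append(("chr1", end, end + 5000, v))
        signal = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        els = [element(50_000, 57_000), element(200_000, 205_000, eid="e2")]
        prof = scaled_profile(signal, els, flank=5000)
        assert np.allclose(prof.values[:50], 3.0)
        assert np.allclose(prof.values[70:], 3.0)
        assert np.allclose(prof.values[50:70], 0.0)

    def test_mirror_symmetry_under_reflection(self):
        # reflect the whole setting around the chromosome midpoint: the
        # meta-profile must be the left-right flip of the original, and
        # additionally flipping the strand labels restores the original
        # (orientation-aware binning undoes the reflection)
        rng = np.random.default_rng(5)
        length = 1_000_000
        rows = []
        pos = 0
        while pos < length:
            w = int(rng.integers(500, 5_000))
            rows.append(("chr1", pos, min(pos + w, length), float(rng.uniform(0, 3))))
            pos += w
        signal = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        els = [
            element(100_000, 106_000, strand="+"),
            element(300_000, 302_000, strand="-", eid="e2"),
            element(700_000, 709_000, strand="+", eid="e3"),
        ]
        mirrored_signal = pd.DataFrame(
            {
                "chrom": signal["chrom"],
                "start": length - signal["end"],
                "end": length - signal["start"],
                "value": signal["value"],
            }
        ).sort_values("start")
        mirrored_els = [
            ErvElement(
                id=e.id, chrom=e.chrom, start=length - e.end, end=length - e.start,
                strand=e.strand, family=e.family,
            )
            for e in els
        ]
        flipped_strand_els = [
            ErvElement(
                id=e.id, chrom=e.chrom, start=e.start, end=e.end,
                strand="-" if e.strand == "+" else "+", family=e.family,
            )
            for e in mirrored_els
        ]
        prof = scaled_profile(signal, els, flank=5000, body_bins=20, flank_bins=50)
        mirror = scaled_profile(mirrored_signal, mirrored_els, flank=5000, body_bins=20, flank_bins=50)
        np.testing.assert_allclose(mirror.values, prof.values[::-1], atol=1e-9)
        restored = scaled_profile(
            mirrored_signal, flipped_strand_els, flank=5000, body_bins=20, flank_bins=50
        )
        np.testing.assert_allclose(restored.values, prof.values, atol=1e-9)

    def test_element_exceeding_bounds_skipped_with_log(self, caplog):
        els = [element(2_000, 4_000), element(50_000, 57_000, eid="e2")]
        with caplog.at_level("WARNING"):
            prof = scaled_profile(
                constant_signal(), els, flank=5000, chrom_lengths={"chr1": 1_000_000}
            )
        assert prof.n_elements == 1
        assert "skipping" in caplog.text

    def test_requires_elements_and_positive_flank(self):
        with pytest.raises(ValueError):
            scaled_profile(constant_signal(), [], flank=5000)
        with pytest.raises(ValueError):
            scaled_profile(constant_signal(), [element(10_000, 12_000)], flank=0)


class TestPeakDistance:
    def peaks(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def test_overlapping_peak_distance_zero(self):
        assert distance_to_nearest_peak(element(2000, 9000), self.peaks([("chr1", 8900, 9100)])) == 0

    def test_left_gap_distance(self):
        assert distance_to_nearest_peak(element(2000, 9000), self.peaks([("chr1", 1500, 1900)])) == 100

    def test_no_peak_on_chromosome_returns_none(self):
        assert distance_to_nearest_peak(element(2000, 9000), self.peaks([("chr2", 1500, 1900)])) is None

    def test_agrees_with_brute_force_on_random_peaks(self):
        rng = np.random.default_rng(11)
        starts = np.sort(rng.integers(0, 10**6, size=1000))
        peaks = self.peaks([("chr1", int(s), int(s + rng.integers(50, 400))) for s in starts])
        for _ in range(50):
            a = int(rng.integers(0, 10**6 - 5000))
            el = element(a, a + int(rng.integers(200, 5000)))
            brute = min(
                max(p.start - el.end, el.start - p.end, 0)
                for p in peaks.itertuples(index=False)
            )
            assert distance_to_nearest_peak(el, peaks) == brute

    def test_planted_peaks_closer_than_background(self):
        cfg = vmerv.SimulationConfig(
            seed=6,
            element_counts={
                ("IAP", "full_length", "variable"): 25,
                ("IAP", "full_length", "hypermethylated"): 25,
            },
        )
        _f, _g, truth = vmerv.generate_annotation(cfg)
        ctx = vmerv.generate_context(truth, cfg)
        els = {e.id: e for e in vmerv.truth_to_elements(truth)}
        flagged = truth.elements[truth.elements["peak_distance"] >= 0]["id"]
        background = truth.elements[truth.elements["peak_distance"] < 0]["id"]
        d_flag = [distance_to_nearest_peak(els[i], ctx.peaks) for i in flagged]
        d_bg = [distance_to_nearest_peak(els[i], ctx.peaks) for i in background]
        from scipy.stats import mannwhitneyu

        stat = mannwhitneyu(d_flag, d_bg, alternative="less")
        assert np.median(d_flag) < np.median(d_bg)
        assert stat.pvalue < 0.01


def hit(eid, rid, cell, sex, relation="overlapping"):
    return TranscriptHit(
        element_id=eid, replicate_id=rid, cell_type=cell, sex=sex,
        t_start=0, t_end=100, t_strand="+", relation=relation,
    )


class TestTranscriptConsistency:
    def test_three_replicates_same_group_qualify(self):
        hits = [hit("e1", f"RNA_B_F_{k}", "B", "F") for k in (1, 2, 3)]
        out = consistent_transcript_overlap(hits)
        assert out["element_id"].tolist() == ["e1"]
        assert out.iloc[0]["n_replicates"] == 3

    def test_two_plus_two_across_cell_types_do_not_qualify(self):
        hits = [hit("e1", f"RNA_B_F_{k}", "B", "F") for k in (1, 2)] + [
            hit("e1", f"RNA_T_F_{k}", "T", "F") for k in (1, 2)
        ]
        assert len(consistent_transcript_overlap(hits)) == 0

    def test_three_replicates_spanning_sexes_do_not_qualify(self):
        hits = [
            hit("e1", "RNA_B_F_1", "B", "F"),
            hit("e1", "RNA_B_F_2", "B", "F"),
            hit("e1", "RNA_B_M_1", "B", "M"),
        ]
        assert len(consistent_transcript_overlap(hits)) == 0

    def test_duplicate_hits_in_one_replicate_count_once(self):
        hits = [hit("e1", "RNA_B_F_1", "B", "F")] * 3 + [hit("e1", "RNA_B_F_2", "B", "F")]
        assert len(consistent_transcript_overlap(hits)) == 0

    def test_initiating_relation_reported_when_any_hit_initiates(self):
        hits = [hit("e1", f"RNA_B_F_{k}", "B", "F") for k in (1, 2)] + [
            hit("e1", "RNA_B_F_3", "B", "F", relation="initiating")
        ]
        out = consistent_transcript_overlap(hits)
        assert out.iloc[0]["relation"] == "initiating"

    def test_hit_relations_are_strand_aware(self):
        el = element(10_000, 16_000, strand="+")
        tx = pd.DataFrame(
            [
                ("chr1", 12_000, 25_000, "t1", 0, "+"),  # starts inside -> initiating
                ("chr1", 1_000, 13_000, "t2", 0, "+"),  # ends inside -> terminating
                ("chr1", 12_000, 25_000, "t3", 0, "-"),  # 5' end at genomic end -> terminating
            ],
            columns=["chrom", "start", "end", "name", "score", "strand"],
        )
        hits = compute_transcript_hits([el], {"r1": tx}, {"r1": ("B", "F")})
        assert [h.relation for h in hits] == ["initiating", "terminating", "terminating"]

    def test_planted_transcript_groups_recovered_end_to_end(self):
        cfg = vmerv.SimulationConfig(
            seed=7,
            element_counts={("IAP", "full_length", "variable"): 10},
            n_transcript_elements=4,
        )
        _f, _g, truth = vmerv.generate_annotation(cfg)
        ctx = vmerv.generate_context(truth, cfg)
        els = vmerv.truth_to_elements(truth)
        hits = compute_transcript_hits(els, ctx.transcripts, ctx.transcript_meta)
        out = consistent_transcript_overlap(hits)
        planted = truth.elements[truth.elements["transcript_cell"] != ""]
        assert set(planted["id"]).issubset(set(out["element_id"]))
        sub = out.set_index("element_id")
        for row in planted.itertuples(index=False):
            got = sub.loc[row.id]
            got = got.iloc[0] if isinstance(got, pd.DataFrame) else got
            assert got["relation"] == "initiating"
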