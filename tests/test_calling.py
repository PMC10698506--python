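"""HD/LOH segment identification and gene-level deletion calling."""
import numpy as np
import pandas as pd
import pytest

from paradel import calling
from paradel.annotation import GenomeLayout, read_gene_models


def seg(sample, chrom, start, end, major, minor):
    return dict(sample=sample, chrom=str(chrom), start=start, end=end,
                n_major=major, n_minor=minor)


def seg_frame(rows):
    return pd.DataFrame(rows)


class TestReadSegments:
    def test_ascat_dialect_accepted_and_extras_ignored(self):
        df = pd.DataFrame({"sample": ["s"], "chr": ["chr5"], "startpos": [10],
                           "endpos": [20], "nMajor": [2], "nMinor": [1],
                           "extra": ["x"]})
        out = calling.read_segments(df)
        assert list(out.columns) == calling.SEGMENT_COLUMNS
        assert out.loc[0, "chrom"] == "5"

    def test_minor_above_major_rejected(self):
        with pytest.raises(calling.SegmentError):
            calling.read_segments(seg_frame([seg("s", 1, 1, 10, 1, 2)]))

    def test_sex_chromosomes_filtered(self):
        out = calling.read_segments(seg_frame([seg("s", "X", 1, 10, 1, 1),
                                               seg("s", 2, 1, 10, 1, 1)]))
        assert list(out["chrom"]) == ["2"]


class TestIdentifyHD:
    def test_only_double_zero_segments_are_hd(self):
        segs = seg_frame([seg("s", 1, 100, 200, 0, 0), seg("s", 1, 300, 400, 1, 0)])
        hd = calling.identify_hd_segments(segs)
        assert len(hd) == 1 and hd.loc[0, "length"] == 101

    def test_bookended_records_merge_gap_does_not(self):
        segs = seg_frame([seg("s", 1, 100, 200, 0, 0), seg("s", 1, 201, 300, 0, 0),
                          seg("s", 1, 302, 400, 0, 0)])
        hd = calling.identify_hd_segments(segs, merge_bookended=True)
        assert [(r.start, r.end, r.n_merged) for r in hd.itertuples()] == \
            [(100, 300, 2), (302, 400, 1)]
        unmerged = calling.identify_hd_segments(segs, merge_bookended=False)
        assert len(unmerged) == 3

    def test_overlapping_hd_records_rejected_with_locus(self):
        segs = seg_frame([seg("s", 1, 100, 250, 0, 0), seg("s", 1, 200, 300, 0, 0)])
        with pytest.raises(calling.SegmentError, match=r"sample s at 1:200"):
            calling.identify_hd_segments(segs)


class TestGeneCalls:
    GENES = read_gene_models(pd.DataFrame({
        "gene_id": ["G"], "chrom": ["1"], "start": [100], "end": [200]}))

    @pytest.mark.parametrize("hd_span,expected", [
        ((50, 300), "full"),      # coding span fully inside the HD segment
        ((150, 300), "partial"),  # overlap without containment
        ((300, 400), None),       # disjoint
    ])
    def test_containment_rule(self, hd_span, expected):
        hd = calling.identify_hd_segments(
            seg_frame([seg("s", 1, hd_span[0], hd_span[1], 0, 0)]))
        pairs = calling.call_gene_hds(self.GENES, hd)
        if expected is None:
            assert pairs.empty
        else:
            assert pairs.loc[0, "call"] == expected

    def test_agrees_with_per_base_oracle_on_random_genomes(self):
        """A gene is fully deleted iff every coding base lies in an HD segment."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            n_genes, n_segs = 25, 12
            gs = rng.integers(1, 3_000, n_genes)
            genes = read_gene_models(pd.DataFrame({
                "gene_id": [f"G{i}" for i in range(n_genes)],
                "chrom": rng.choice(["1", "2"], n_genes),
                "start": gs, "end": gs + rng.integers(0, 400, n_genes)}))
            rows = []
            pos = 1
            for _ in range(n_segs):  # non-overlapping random HD segments
                a = pos + int(rng.integers(2, 400))
                b = a + int(rng.integers(0, 300))
                pos = b + 1
                rows.append(seg("s", rng.choice(["1", "2"]), a, b, 0, 0))
            segs = seg_frame(rows)
            hd = calling.identify_hd_segments(segs)
            pairs = calling.call_gene_hds(genes, hd)
            called_full = set(pairs.loc[pairs["call"] == "full", "gene_id"])
            # brute force: per-base coverage per chromosome
            for g in genes.itertuples():
                cov = np.zeros(5_000, dtype=bool)
                for h in hd[hd["chrom"] == g.chrom].itertuples():
                    cov[h.start:h.end + 1] = True
                expect_full = bool(cov[g.start:g.end + 1].all())
                assert (g.gene_id in called_full) == expect_full

    def test_full_calls_invariant_to_bookended_resplitting(self):
        """Splitting an HD segment into gap-free pieces and re-merging leaves
        the gene calls unchanged, however the pieces are chosen."""
        rng = np.random.default_rng(3)
        genes = read_gene_models(pd.DataFrame({
            "gene_id": [f"G{i}" for i in range(40)], "chrom": "1",
            "start": np.arange(40) * 250 + 1, "end": np.arange(40) * 250 + 180}))
        base = seg_frame([seg("s", 1, k * 1_000 + 1, k * 1_000 + int(rng.integers(100, 700)), 0, 0)
                          for k in range(10)])
        reference = calling.call_gene_hds(genes, calling.identify_hd_segments(base))
        for trial in range(5):
            rows = []
            for r in base.itertuples():
                cuts = np.sort(rng.choice(np.arange(r.start, r.end), size=2, replace=False))
                bounds = [r.start, *cuts.tolist(), r.end]
                pieces = [(bounds[i] + (1 if i else 0), bounds[i + 1])
                          for i in range(3)]
                rows += [seg("s", 1, a, b, 0, 0) for a, b in pieces if a <= b]
            resplit = calling.call_gene_hds(
                genes, calling.identify_hd_segments(seg_frame(rows)))
            pd.testing.assert_frame_equal(
                resplit.sort_values(["sample", "gene_id"]).reset_index(drop=True),
                reference.sort_values(["sample", "gene_id"]).reset_index(drop=True))


class TestSampleQC:
    def test_hyper_deleted_threshold_is_strict(self):
        counts = pd.Series({"a": 100, "b": 101, "c": 0})
        retained, dropped = calling.filter_hyper_deleted(counts, threshold=100)
        assert set(retained) == {"a", "c"} and dropped == ["b"]


class TestLOH:
    def test_subtypes_by_total_copy_number(self, toy_layout):
        segs = seg_frame([seg("s", 1, 1, 10_000, 1, 0),
                          seg("s", 1, 20_000, 30_000, 2, 0),
                          seg("s", 1, 40_000, 50_000, 3, 0),
                          seg("s", 1, 60_000, 70_000, 2, 1)])
        loh = calling.identify_loh_segments(segs, toy_layout)
        assert list(loh["subtype"]) == ["copy_loss", "copy_neutral", "other"]

    def test_focal_is_strictly_under_half_arm(self, toy_layout):
        # chromosome 1 p-arm is ~100 Mb: 49 Mb focal, 51 Mb not
        segs = seg_frame([seg("s", 1, 1_000_000, 50_000_000 - 1, 1, 0),
                          seg("s", 1, 1_000_000, 52_000_000 - 1, 1, 0)])
        loh = calling.identify_loh_segments(segs, toy_layout)
        assert list(loh["focal"]) == [True, False]

    def test_centromere_spanning_flagged(self, toy_layout):
        segs = seg_frame([seg("s", 1, 90_000_000, 110_000_000, 1, 0)])
        loh = calling.identify_loh_segments(segs, toy_layout)
        assert bool(loh.loc[0, "spans_centromere"])


class TestBoundSegments:
    def test_flags_follow_observed_boundaries(self, toy_layout):
        cohort = seg_frame([
            seg("s1", 1, 1_000, 98_000_000, 1, 1),
            seg("s1", 1, 102_000_000, 199_000_000, 1, 1),
            seg("s2", 1, 1_000, 5_000, 0, 0),
            seg("s2", 1, 97_000_000, 98_000_000, 0, 0),
            seg("s2", 1, 102_000_000, 103_000_000, 0, 0),
            seg("s2", 1, 50_000_000, 60_000_000, 0, 0),
        ])
        layout = toy_layout.with_observed_bounds(cohort)
        hd = calling.identify_hd_segments(cohort)
        hd = calling.detect_bound_segments(hd, layout)
        by_start = hd.set_index("start")
        assert bool(by_start.loc[1_000, "telomere_bound"])
        assert bool(by_start.loc[97_000_000, "centromere_bound"])
        assert bool(by_start.loc[102_000_000, "centromere_bound"])
        interior = by_start.loc[50_000_000]
        assert not interior["telomere_bound"] and not interior["centromere_bound"]

    def test_requires_observed_bounds(self, toy_layout):
        hd = pd.DataFrame({"sample": ["s"], "chrom": ["1"], "start": [1],
                           "end": [10], "length": [10], "n_merged": [1]})
        with pytest.raises(ValueError, match="observed bounds"):
            calling.detect_bound_segments(hd, toy_layout)


class TestSegmentStats:
    def test_median_over_gene_deleting_segments_only(self):
        genes = read_gene_models(pd.DataFrame({
            "gene_id": [f"G{i}" for i in range(9)], "chrom": "1",
            "start": np.arange(9) * 100 + 10, "end": np.arange(9) * 100 + 50}))
        # segments deleting 3, 1 and 5 genes plus one intragenic
        segs = seg_frame([seg("s", 1, 1, 260, 0, 0),       # G0-G2
                          seg("s", 1, 300, 360, 0, 0),     # G3
                          seg("s", 1, 400, 899, 0, 0),     # G4-G8
                          seg("s", 1, 920, 930, 0, 0)])    # inside G9? -> overlaps none
        hd = calling.identify_hd_segments(segs)
        stats = calling.genes_per_segment_stats(hd, genes)
        assert stats["median_genes_per_deleting_segment"] == 3
        assert stats["n_gene_deleting_segments"] == 3
        seglen = hd.loc[0, "length"]
        assert seglen == 260


class TestCohortInvariants:
    def test_count_consistency(self, small_analysis):
        tbl = small_analysis.cohorts["sim"].gene_table
        assert (tbl["n_full_hd"] <= tbl["n_partial_hd"]).all()
        assert ((tbl["n_full_hd"] >= 3) <= (tbl["n_full_hd"] >= 1)).all()

    def test_loh_universal_while_hd_rare(self, small_analysis):
        """Neutral hemizygous events cover every passenger at least once while
        most passengers have no HD."""
        tbl = small_analysis.cohorts["sim"].gene_table
        psg = tbl[tbl["gene_id"].isin(small_analysis.passenger_table["gene_id"])]
        assert (psg["loh_all"] >= 1).all()
        assert (psg["n_full_hd"] == 0).mean() > 0.5
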