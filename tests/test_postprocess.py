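import numpy as np

from condsig.genome_io import BedGraphTrack
from condsig.postprocess import (
    PeakClassification,
    classify_peaks,
    high_confidence_sites,
    peaks_to_domains,
    refine_classification,
)


def track_from_records(records):
    """records: list of (chrom, start, end, value)."""
    by_chrom = {}
    for chrom, s, e, v in records:
        by_chrom.setdefault(chrom, []).append((s, e, v))
    out = {}
    for chrom, recs in by_chrom.items():
        recs.sort()
        arr = np.array(recs, dtype=float)
        out[chrom] = (arr[:, 0].astype(int), arr[:, 1].astype(int), arr[:, 2])
    return BedGraphTrack(out)


class TestClassify:
    def test_one_bp_overlap_is_positive(self):
        cls = classify_peaks("A", [("chr1", 999, 1500)], [("chr1", 0, 1000)])
        assert cls.positive_peaks == [("chr1", 999, 1500)]

    def test_no_overlap_is_negative(self):
        cls = classify_peaks("A", [("chr1", 1000, 1500)], [("chr1", 0, 1000)])
        assert cls.negative_peaks == [("chr1", 1000, 1500)]

    def test_no_sites_all_negative_with_warning(self, caplog):
        cls = classify_peaks("A", [("chr1", 0, 100)], [])
        assert cls.positive_peaks == [] and len(cls.negative_peaks) == 1
        assert any("not a component" in r.message for r in caplog.records)


class TestRefine:
    def test_atac_mode_removes_from_both_classes(self):
        cls = PeakClassification(
            "A", [("chr1", 0, 100), ("chr1", 5000, 5100)], [("chr1", 9000, 9100)]
        )
        refined = refine_classification(cls, atac_peaks=[("chr1", 0, 50)])
        assert refined.positive_peaks == [("chr1", 0, 100)]
        assert refined.negative_peaks == []

    def test_cap_count_mode_strict_comparison(self, make_occ):
        O = np.zeros((3, 12), dtype=np.uint8)
        O[0, :11] = 1  # 11 occupied CAPs > 10 -> retained
        O[1, :10] = 1  # exactly 10 -> removed
        occ = make_occ(O)
        cls = PeakClassification("A", [("chr1", 0, 500), ("chr1", 1000, 1500)], [])
        refined = refine_classification(cls, occ=occ, min_caps=10)
        assert refined.positive_peaks == [("chr1", 0, 500)]

    def test_refinement_never_moves_between_classes(self):
        cls = PeakClassification("A", [("chr1", 0, 100)], [("chr1", 200, 300)])
        refined = refine_classification(
            cls, atac_peaks=[("chr1", 0, 400)]
        )
        assert refined.positive_peaks == cls.positive_peaks
        assert refined.negative_peaks == cls.negative_peaks


class TestDomains:
    def test_gap_merge_arithmetic(self):
        cls = PeakClassification("A", [("chr1", 0, 1000)], [("chr1", 3000, 4000)])
        out = peaks_to_domains(cls, gap_kb=5)
        assert out.positive_domains == [("chr1", 0, 4000)]  # gap 2000 <= 5000
        assert out.negative_domains == []

    def test_gap_beyond_threshold_stays_split(self):
        cls = PeakClassification("A", [("chr1", 0, 1000)], [("chr1", 7000, 8000)])
        out = peaks_to_domains(cls, gap_kb=5)
        assert out.positive_domains == [("chr1", 0, 1000)]
        assert out.negative_domains == [("chr1", 7000, 8000)]

    def test_mixed_domain_is_positive(self):
        cls = PeakClassification("A", [("chr1", 0, 1000)], [("chr1", 2000, 3000)])
        out = peaks_to_domains(cls, gap_kb=5)
        assert out.positive_domains == [("chr1", 0, 3000)]

    def test_domain_counts_partition(self):
        rng = np.random.default_rng(8)
        starts = np.sort(rng.choice(np.arange(0, 200_000, 1500), 40, replace=False))
        peaks = [("chr1", int(s), int(s + 800)) for s in starts]
        pos = peaks[::3]
        neg = [p for p in peaks if p not in pos]
        out = peaks_to_domains(PeakClassification("A", pos, neg), gap_kb=2)
        n_domains = len(out.positive_domains) + len(out.negative_domains)
        for d in out.positive_domains + out.negative_domains:
            assert d[2] - d[1] >= 800
        assert n_domains <= len(peaks)


class TestHighConfidence:
    def _setup(self, make_occ, site_value, baseline_value):
        from condsig.signatures import CondSig, Signature

        O = np.ones((4, 4), dtype=np.uint8)
        occ = make_occ(O, caps=list("ABCD"))
        sig = Signature(
            id="s", focus_cap="A", context="promoter", member_caps=list("ABCD"),
            components=["A", "B"], component_z={}, component_prob={"A": 0.5, "B": 0.4},
            pos_rows=np.array([0, 1]), positive_bins=np.array([0, 1]),
            neg_rows=np.array([2]),
        )
        cs = CondSig(sig, {"F_LLPS": 0.9}, 0.9, ["F_LLPS"], True)
        tracks = {
            c: track_from_records(
                [("chr1", 0, 2000, site_value), ("chr1", 8000, 9000, baseline_value)]
            )
            for c in "AB"
        }
        negs = {c: [("chr1", 8000, 9000)] for c in "AB"}
        return occ, [cs], tracks, negs

    def test_two_fold_enrichment_kept(self, make_occ):
        occ, condsigs, tracks, negs = self._setup(make_occ, 2.0, 1.0)
        sites = high_confidence_sites(condsigs, occ, tracks, negs, fold=1.5)
        assert sites == [("chr1", 0, 2000)]

    def test_exact_threshold_dropped(self, make_occ):
        occ, condsigs, tracks, negs = self._setup(make_occ, 1.5, 1.0)
        assert high_confidence_sites(condsigs, occ, tracks, negs, fold=1.5) == []

    def test_missing_baseline_skips_site(self, make_occ, caplog):
        occ, condsigs, tracks, _ = self._setup(make_occ, 2.0, 1.0)
        sites = high_confidence_sites(condsigs, occ, tracks, {"A": [], "B": []})
        assert sites == []
        assert any("baseline" in r.message for r in caplog.records)

    def test_sites_subset_of_merged_positive(self, make_occ):
        from condsig.signatures import merged_positive_sites

        occ, condsigs, tracks, negs = self._setup(make_occ, 2.0, 1.0)
        merged = merged_positive_sites(condsigs, occ)
        kept = high_confidence_sites(condsigs, occ, tracks, negs)
        assert set(kept) <= set(merged)
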