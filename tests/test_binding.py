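"""Peak annotation, IUPAC motif scanning, HSE detection, DGT overlap."""

import re

import numpy as np
import pandas as pd
import pytest

from pachydyn import (
    HEPTAMER_PATTERN,
    OCTAMER_PATTERN,
    MotifPattern,
    annotate_peak,
    annotate_peaks,
    category_fractions,
    detect_hse,
    overlap_driver_targets,
    peaks_to_genes,
    scan_motif,
)
from pachydyn.simulate import IUPAC, revcomp


@pytest.fixture(scope="module")
def toy_annotation():
    """One gene on each strand with TSS, exons and an intron."""
    tss = pd.DataFrame(
        {
            "gene_id": ["gA", "gB"],
            "contig": ["chr1", "chr1"],
            "position": [10_000, 40_000],
            "strand": ["+", "-"],
        }
    )
    models = pd.DataFrame(
        [
            ("gA", "chr1", 10_000, 10_500, "+", "exon"),
            ("gA", "chr1", 12_000, 12_500, "+", "exon"),
            ("gB", "chr1", 39_500, 40_000, "-", "exon"),
            ("gB", "chr1", 37_000, 37_500, "-", "exon"),
        ],
        columns=["gene_id", "contig", "start", "end", "strand", "feature"],
    )
    return models, tss


class TestAnnotatePeak:
    def test_proximal_promoter_by_midpoint(self, toy_annotation):
        models, tss = toy_annotation
        ann = annotate_peak(("chr1", 9_800, 10_100), models, tss)
        assert ann.category == "proximal_promoter" and ann.gene_id == "gA"

    def test_exon_when_far_from_tss(self, toy_annotation):
        models, tss = toy_annotation
        ann = annotate_peak(("chr1", 12_100, 12_400), models, tss)
        assert ann.category == "exon" and ann.gene_id == "gA"

    def test_one_peak_per_category(self, toy_annotation):
        models, tss = toy_annotation
        peaks = pd.DataFrame(
            {
                "contig": ["chr1"] * 5,
                "start": [9_900, 8_200, 12_100, 11_000, 25_000],
                "end": [10_100, 8_600, 12_400, 11_500, 25_400],
                "score": 1.0,
            }
        )
        # midpoints: 10_000 (proximal), 8_400 (promoter), 12_250 (exon),
        # 11_250 (intron), 25_200 (intergenic)
        cats = [a.category for a in annotate_peaks(peaks, models, tss)]
        assert sorted(cats) == sorted(
            ["proximal_promoter", "promoter", "exon", "intron", "intergenic"]
        )

    def test_minus_strand_promoter_is_downstream_in_genome(self, toy_annotation):
        models, tss = toy_annotation
        # gB TSS at 40_000 on '-': upstream 2 kb is genomic (40_500, 42_000]
        ann = annotate_peak(("chr1", 41_000, 41_200), models, tss)
        assert ann.category == "promoter" and ann.gene_id == "gB"

    def test_unknown_contig_named_in_error(self, toy_annotation):
        models, tss = toy_annotation
        with pytest.raises(ValueError, match="chrZ"):
            annotate_peak(("chrZ", 0, 100), models, tss)


class TestCategoryFractions:
    def test_all_proximal(self, toy_annotation):
        models, tss = toy_annotation
        peaks = pd.DataFrame(
            {"contig": ["chr1"] * 3, "start": [9_900] * 3, "end": [10_100] * 3,
             "score": 1.0}
        )
        frac = category_fractions(annotate_peaks(peaks, models, tss))
        assert frac["proximal_promoter"] == 1.0
        assert frac.drop("proximal_promoter").sum() == 0.0

    def test_fractions_echo_reported_percentages(self):
        """522 peaks split (384, 14, 45, 52, 27) across categories."""
        from pachydyn.binding import CATEGORIES, PeakAnnotation

        counts = dict(zip(CATEGORIES, (384, 14, 45, 52, 27)))
        anns = [
            PeakAnnotation("c", 0, 1, cat, "g", 0)
            for cat, k in counts.items()
            for _ in range(k)
        ]
        frac = category_fractions(anns)
        assert frac.sum() == pytest.approx(1.0, abs=1e-9)
        assert frac["proximal_promoter"] == pytest.approx(0.7356, abs=5e-5)
        assert frac["promoter"] == pytest.approx(0.0268, abs=5e-5)
        assert frac["exon"] == pytest.approx(0.0862, abs=5e-5)
        assert frac["intron"] == pytest.approx(0.0996, abs=5e-5)
        assert frac["intergenic"] == pytest.approx(0.0517, abs=5e-5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            category_fractions([])


def iupac_regex(pattern: str) -> re.Pattern:
    return re.compile("".join(f"[{IUPAC[c]}]" for c in pattern))


class TestScanMotif:
    def test_single_forward_hit(self):
        hits = scan_motif("TTAGAACGTT", HEPTAMER_PATTERN)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1
        assert fwd[0].position == 1 and fwd[0].matched == "TAGAACG"

    def test_no_hits_in_homopolymer(self):
        assert scan_motif("C" * 20, HEPTAMER_PATTERN) == []

    def test_strand_symmetry(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        fwd = {(h.position, h.strand) for h in scan_motif(seq, HEPTAMER_PATTERN)}
        rc = scan_motif(revcomp(seq), HEPTAMER_PATTERN)
        k = len(HEPTAMER_PATTERN.pattern)
        mirrored = {
            (len(seq) - h.position - k, "+" if h.strand == "-" else "-") for h in rc
        }
        assert fwd == mirrored

    @pytest.mark.parametrize("pattern", [HEPTAMER_PATTERN, OCTAMER_PATTERN])
    def test_agrees_with_regex_oracle(self, pattern):
        """Oracle: a '-' hit sits wherever the window's reverse complement
        matches the forward pattern."""
        rng = np.random.default_rng(13)
        fwd_re = iupac_regex(pattern.pattern)
        k = len(pattern.pattern)
        for _ in range(1000):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            hits = scan_motif(seq, pattern)
            expected = set()
            for i in range(len(seq) - k + 1):
                window = seq[i : i + k]
                if fwd_re.fullmatch(window):
                    expected.add((i, "+"))
                if fwd_re.fullmatch(revcomp(window)):
                    expected.add((i, "-"))
            assert {(h.position, h.strand) for h in hits} == expected

    def test_n_never_matches(self):
        assert scan_motif("TAGNACG", HEPTAMER_PATTERN) == []

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            MotifPattern("bad", "AXG")
        with pytest.raises(ValueError):
            MotifPattern("bad", "")


class TestDetectHSE:
    def test_three_alternating_units(self):
        hits = detect_hse("AGAACGTTCTAGAAC")
        assert len(hits) == 1
        assert hits[0].start == 0 and hits[0].n_units == 3

    def test_same_orientation_units_rejected(self):
        assert detect_hse("AGAACAGAAC" + "AGAAC") == []

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            fwd = {(h.start, h.end) for h in detect_hse(seq)}
            rc = detect_hse(revcomp(seq))
            mirrored = {(len(seq) - h.end, len(seq) - h.start) for h in rc}
            assert fwd == mirrored

    def test_degenerate_unit_allowed_with_budget(self):
        # middle unit core GTC is one mismatch from TTC
        seq = "AGAACGGTCTAGAAC"
        assert detect_hse(seq, max_mismatch_units=0) == []
        hits = detect_hse(seq, max_mismatch_units=1)
        assert len(hits) == 1 and hits[0].n_mismatch_units == 1

    def test_min_units_validated(self):
        with pytest.raises(ValueError):
            detect_hse("AGAAC", min_units=1)


class TestPeaksToGenes:
    def test_single_promoter_peak(self, toy_annotation):
        models, tss = toy_annotation
        peaks = pd.DataFrame(
            {"contig": ["chr1"], "start": [9_900], "end": [10_100], "score": [1.0]}
        )
        bound = peaks_to_genes(peaks, models, tss)
        assert list(bound["gene_id"]) == ["gA"]

    def test_multiplicity_recorded(self, toy_annotation):
        models, tss = toy_annotation
        peaks = pd.DataFrame(
            {
                "contig": ["chr1"] * 3,
                "start": [9_900, 10_100, 40_100],
                "end": [10_100, 10_300, 40_300],
                "score": 1.0,
            }
        )
        bound = peaks_to_genes(peaks, models, tss).set_index("gene_id")
        assert bound.loc["gA", "n_peaks"] == 2
        assert bound.loc["gB", "n_peaks"] == 1

    def test_recovers_planted_ledger_exactly(self, toy_genome):
        bound = peaks_to_genes(
            toy_genome.peaks, toy_genome.gene_models, toy_genome.tss_records
        )
        assert set(bound["gene_id"]) == set(toy_genome.peak_genes["gene_id"])


class TestOverlapDriverTargets:
    def test_disjoint(self):
        res = overlap_driver_targets({"a", "b"}, {"c"})
        assert res["n_overlap"] == 0

    def test_identical(self):
        res = overlap_driver_targets({"a", "b", "c"}, {"a", "b", "c"})
        assert res["n_overlap"] == 3 == res["n_bound"] == res["n_driver"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            overlap_driver_targets(set(), {"a"})
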