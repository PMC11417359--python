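"""Peak annotation, degenerate-motif scanning and driver-target overlap.

Binding intervals (peaks) from a chromatin-profiling assay are assigned
to genomic categories by their midpoint relative to gene annotation —
proximal promoter (TSS-500..TSS+500, transcription-strand oriented),
promoter (the configurable upstream extension), exon, intron, intergenic
— with that precedence, so every peak lands in exactly one category.
Promoter sequences are scanned on both strands for IUPAC-degenerate
motifs — the heptamer HRGAAYV and octamer GAMSCKYC enriched under bound
peaks — and for heat-shock elements (HSE): tandem arrays of at least
three oppositely oriented nGAAn pentamer units.  Genes bound at their
promoter are intersected with trajectory driver genes to form driver
gene targets (DGTs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import IUPAC, revcomp

__all__ = [
    "MotifPattern",
    "MotifHit",
    "PeakAnnotation",
    "HEPTAMER_PATTERN",
    "OCTAMER_PATTERN",
    "annotate_peak",
    "annotate_peaks",
    "category_fractions",
    "scan_motif",
    "detect_hse",
    "peaks_to_genes",
    "overlap_driver_targets",
]

CATEGORIES = ("proximal_promoter", "promoter", "exon", "intron", "intergenic")

PROXIMAL_UP = 500
PROXIMAL_DOWN = 500
PROMOTER_UP = 2000


@dataclass(frozen=True)
class MotifPattern:
    """IUPAC-degenerate motif; ``strand_mode`` 'both' or 'forward'."""

    motif_id: str
    pattern: str
    strand_mode: str = "both"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = [c for c in self.pattern.upper() if c not in IUPAC]
        if bad:
            raise ValueError(f"invalid IUPAC letters in pattern: {bad}")
        if self.strand_mode not in ("both", "forward"):
            raise ValueError(f"unknown strand_mode {self.strand_mode!r}")


HEPTAMER_PATTERN = MotifPattern("heptamer", "HRGAAYV")
OCTAMER_PATTERN = MotifPattern("octamer", "GAMSCKYC")

_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp_pattern(pattern: str) -> str:
    """Reverse complement of an IUPAC-degenerate pattern."""
    return pattern.upper().translate(_IUPAC_COMP)[::-1]


@dataclass(frozen=True)
class MotifHit:
    contig: str
    position: int  # forward-strand coordinate of the window start
    strand: str
    matched: str  # window on the reported strand
    motif_id: str


@dataclass
class PeakAnnotation:
    contig: str
    start: int
    end: int
    category: str
    gene_id: str
    distance_to_tss: int


def _window(tss: int, strand: str, up: int, down: int) -> tuple[int, int]:
    """Half-open genomic interval [TSS-up, TSS+down) in strand orientation."""
    if strand == "+":
        return tss - up, tss + down
    return tss - down + 1, tss + up + 1


def annotate_peak(
    peak, gene_models: pd.DataFrame, tss_records: pd.DataFrame,
    promoter_upstream: int = PROMOTER_UP,
    contig_lengths: dict[str, int] | None = None,
) -> PeakAnnotation:
    """Assign one peak a genomic category and a gene by its midpoint.

    Precedence: proximal_promoter > promoter > exon > intron >
    intergenic.  Intron = inside a gene span (first to last exon) but
    not in an exon.  Intergenic peaks are assigned the nearest TSS.
    """
    contig, start, end = str(peak[0]), int(peak[1]), int(peak[2])
    if start >= end:
        raise ValueError(f"degenerate peak interval [{start}, {end})")
    if contig_lengths is not None and contig not in contig_lengths:
        raise ValueError(f"peak on unknown contig {contig!r}")
    tss_c = tss_records[tss_records["contig"] == contig]
    if tss_c.empty and (contig_lengths is None):
        raise ValueError(f"peak on unknown contig {contig!r}: no annotation")
    mid = (start + end) // 2

    # proximal promoter, then promoter extension
    for category, up, down in (
        ("proximal_promoter", PROXIMAL_UP, PROXIMAL_DOWN),
        ("promoter", promoter_upstream, -PROXIMAL_UP),
    ):
        for row in tss_c.itertuples():
            lo, hi = _window(int(row.position), row.strand, up, down)
            if lo <= mid < hi:
                return PeakAnnotation(
                    contig, start, end, category, row.gene_id,
                    mid - int(row.position),
                )

    models_c = gene_models[gene_models["contig"] == contig]
    exons = models_c[models_c["feature"] == "exon"]
    for row in exons.itertuples():
        if row.start <= mid < row.end:
            return PeakAnnotation(contig, start, end, "exon", row.gene_id, _tss_dist(mid, tss_c, row.gene_id))
    for gene_id, grp in exons.groupby("gene_id"):
        if grp["start"].min() <= mid < grp["end"].max():
            return PeakAnnotation(contig, start, end, "intron", gene_id, _tss_dist(mid, tss_c, gene_id))

    if tss_c.empty:
        return PeakAnnotation(contig, start, end, "intergenic", "", 0)
    d = (tss_c["position"] - mid).abs()
    nearest = tss_c.loc[d.idxmin()]
    return PeakAnnotation(
        contig, start, end, "intergenic", nearest["gene_id"],
        mid - int(nearest["position"]),
    )


def _tss_dist(mid: int, tss_c: pd.DataFrame, gene_id: str) -> int:
    row = tss_c[tss_c["gene_id"] == gene_id]
    if row.empty:
        return 0
    return mid - int(row.iloc[0]["position"])


def annotate_peaks(
    peaks: pd.DataFrame, gene_models: pd.DataFrame, tss_records: pd.DataFrame,
    promoter_upstream: int = PROMOTER_UP,
) -> list[PeakAnnotation]:
    return [
        annotate_peak(
            (row["contig"], row["start"], row["end"]),
            gene_models, tss_records, promoter_upstream,
        )
        for _, row in peaks.iterrows()
    ]


def category_fractions(annotations: list[PeakAnnotation]) -> pd.Series:
    """Fraction of peaks per genomic category (sums to 1)."""
    if not annotations:
        raise ValueError("no annotated peaks")
    counts = pd.Series(0, index=list(CATEGORIES), dtype=float)
    for a in annotations:
        counts[a.category] += 1
    return counts / counts.sum()


def _matches(window: str, pattern: str) -> bool:
    return all(b in IUPAC[p] for b, p in zip(window, pattern))


def scan_motif(sequence: str, pattern: MotifPattern, contig: str = "") -> list[MotifHit]:
    """All motif matches on both strands of ``sequence``.

    Case-insensitive; N in the sequence never matches.  Reverse-strand
    hits are reported at the forward coordinate of the window start with
    the matched sequence given on the reverse strand.
    """
    seq = sequence.upper()
    pat = pattern.pattern.upper()
    rc_pat = revcomp_pattern(pat) if pattern.strand_mode == "both" else None
    k = len(pat)
    hits = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if "N" in window:
            continue
        if _matches(window, pat):
            hits.append(MotifHit(contig, i, "+", window, pattern.motif_id))
        if rc_pat is not None and _matches(window, rc_pat):
            hits.append(MotifHit(contig, i, "-", revcomp(window), pattern.motif_id))
    return hits


@dataclass(frozen=True)
class HSEHit:
    contig: str
    start: int
    end: int
    n_units: int
    n_mismatch_units: int


def detect_hse(
    sequence: str,
    min_units: int = 3,
    max_mismatch_units: int = 0,
    contig: str = "",
) -> list[HSEHit]:
    """Maximal tandem arrays of oppositely oriented nGAAn units (HSEs).

    An HSE is a run of >= ``min_units`` adjacent 5-mers at period 5 whose
    middle triplet alternates between GAA and its reverse complement TTC.
    Degenerate mode tolerates up to ``max_mismatch_units`` units whose
    core deviates from the expected triplet by one base.  Runs are
    reported maximally (never contained in a longer reported run at the
    same phase).
    """
    if min_units < 2:
        raise ValueError("min_units must be >= 2")
    seq = sequence.upper()
    n = len(seq)

    def core_state(pos: int) -> tuple[int, int] | None:
        """(orientation, mismatches) of the unit at pos, or None."""
        if pos + 5 > n:
            return None
        core = seq[pos + 1 : pos + 4]
        best = None
        for orient, target in ((0, "GAA"), (1, "TTC")):
            mm = sum(a != b for a, b in zip(core, target))
            if mm <= 1 and (best is None or mm < best[1]):
                best = (orient, mm)
        return best

    hits: list[HSEHit] = []
    for phase_start in range(n):
        # only start runs at positions not continuing a previous run
        state = core_state(phase_start)
        if state is None:
            continue
        orient, mm0 = state
        if mm0 > (1 if max_mismatch_units > 0 else 0):
            continue
        # check this is a run start (previous period-5 unit doesn't extend it)
        prev = phase_start - 5
        if prev >= 0:
            ps = core_state(prev)
            if ps is not None and ps[0] == 1 - orient and _unit_ok(ps[1], max_mismatch_units):
                continue
        units = []
        pos = phase_start
        expect = orient
        while True:
            st = core_state(pos)
            if st is None or st[0] != expect or not _unit_ok(st[1], max_mismatch_units):
                break
            units.append(st[1])
            pos += 5
            expect = 1 - expect
        n_mm = sum(1 for m in units if m > 0)
        # enforce the mismatch-unit budget over the run greedily
        while len(units) >= min_units and n_mm > max_mismatch_units:
            dropped = units.pop()
            if dropped > 0:
                n_mm -= 1
        if len(units) >= min_units:
            hits.append(
                HSEHit(contig, phase_start, phase_start + 5 * len(units), len(units), n_mm)
            )
    return hits


def _unit_ok(mm: int, max_mismatch_units: int) -> bool:
    return mm == 0 or (mm == 1 and max_mismatch_units > 0)


def peaks_to_genes(
    peaks: pd.DataFrame,
    gene_models: pd.DataFrame,
    tss_records: pd.DataFrame,
    promoter_upstream: int = PROMOTER_UP,
    categories: tuple[str, ...] = ("proximal_promoter", "promoter"),
) -> pd.DataFrame:
    """Bound genes from peak annotation (promoter-class peaks by default).

    Returns one row per bound gene with the number of supporting peaks.
    """
    annotations = annotate_peaks(peaks, gene_models, tss_records, promoter_upstream)
    hits: dict[str, int] = {}
    for a in annotations:
        if a.category in categories and a.gene_id:
            hits[a.gene_id] = hits.get(a.gene_id, 0) + 1
    return pd.DataFrame(
        sorted(hits.items()), columns=["gene_id", "n_peaks"]
    )


def overlap_driver_targets(bound_genes, driver_genes) -> dict:
    """Intersect promoter-bound genes with trajectory drivers (DGTs)."""
    bound = set(bound_genes)
    drivers = set(driver_genes)
    if not bound or not drivers:
        raise ValueError("bound and driver gene sets must both be nonempty")
    overlap = sorted(bound & drivers)
    return {
        "dgt_genes": overlap,
        "n_bound": len(bound),
        "n_driver": len(drivers),
        "n_overlap": len(overlap),
    }
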