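"""Gene annotation, intergenic spacers, and peak-to-feature assignment.

Intergenic spacers are classified by the transcription direction of their
flanking genes: type A lies between divergently transcribed genes (a
promoter-bearing A spacer can drive transcription in both directions, so it
counts twice in the upper promoter bound), type B between codirectional
genes (one promoter), and type C between convergent genes (downstream of
both, so it contributes no promoter).
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from fractions import Fraction

from ._util import round_half_up

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Gene:
    id: str
    start: int
    end: int
    strand: str
    operon: str | None = None
    essential: bool = False

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene {self.id}: start must precede end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: invalid strand {self.strand!r}")


@dataclass
class Spacer:
    left_gene: Gene
    right_gene: Gene
    start: int
    end: int
    type_code: str
    peaks: list = field(default_factory=list)
    has_hns: bool = False

    @property
    def internal(self) -> bool:
        """True when both flanking genes belong to the same operon, i.e. any
        promoter here is internal to one transcription unit."""
        return flag_internal(self)


@dataclass(frozen=True)
class PeakAssignment:
    peak: object
    category: str  # "spacer" | "orf" | "nearest"
    container: object


def classify_spacer(left_strand: str, right_strand: str) -> str:
    """Orientation class from the flanking strands alone:
    (-,+) -> A divergent; (+,+)/(-,-) -> B codirectional; (+,-) -> C convergent."""
    for s in (left_strand, right_strand):
        if s not in ("+", "-"):
            raise ValueError(f"invalid strand symbol: {s!r}")
    if left_strand == "-" and right_strand == "+":
        return "A"
    if left_strand == right_strand:
        return "B"
    return "C"


def extract_spacers(genes: list[Gene]) -> list[Spacer]:
    """One spacer per adjacent gene pair with a positive gap.

    Genes must be sorted by start; pairs that touch or overlap produce no
    spacer."""
    if any(b.start < a.start for a, b in zip(genes, genes[1:])):
        raise ValueError("genes must be sorted by start position")
    spacers = []
    for left, right in zip(genes, genes[1:]):
        if right.start > left.end:
            spacers.append(
                Spacer(
                    left_gene=left,
                    right_gene=right,
                    start=left.end,
                    end=right.start,
                    type_code=classify_spacer(left.strand, right.strand),
                )
            )
    return spacers


def flag_internal(spacer: Spacer) -> bool:
    """A spacer is internal when both flanking genes carry the same operon
    identifier; missing identifiers are conservatively non-internal."""
    a, b = spacer.left_gene.operon, spacer.right_gene.operon
    return a is not None and a == b


def assign_peaks(
    peaks: list, spacers: list[Spacer], genes: list[Gene]
) -> list[PeakAssignment]:
    """Assign each peak to the feature containing its summit.

    A summit inside a spacer interval is a spacer assignment (the peak is
    also attached to that spacer); inside a gene body, an ORF assignment.
    Summits falling in neither (gaps left by overlapping genes) go to the
    nearest feature and are logged.
    """
    features: list[tuple[int, int, str, object]] = [
        (s.start, s.end, "spacer", s) for s in spacers
    ] + [(g.start, g.end, "orf", g) for g in genes]
    features.sort(key=lambda f: (f[0], f[1]))
    starts = [f[0] for f in features]
    max_span = _max_feature_span(features)
    assignments = []
    for peak in peaks:
        summit = peak.summit
        container = None
        # scan candidates whose start <= summit, nearest-start first
        for j in range(bisect_right(starts, summit) - 1, -1, -1):
            lo, hi, cat, obj = features[j]
            if lo <= summit < hi:
                container = (cat, obj)
                break
            if summit - lo > max_span:
                break
        if container is None:
            cat, obj = _nearest_feature(features, summit)
            logger.info("peak summit %d outside all features; assigned to nearest", summit)
            assignments.append(PeakAssignment(peak, "nearest", obj))
        else:
            cat, obj = container
            if cat == "spacer":
                obj.peaks.append(peak)
            assignments.append(PeakAssignment(peak, cat, obj))
    return assignments


def _max_feature_span(features) -> int:
    return max((hi - lo) for lo, hi, _, _ in features) if features else 0


def _nearest_feature(features, summit: int):
    def dist(f):
        lo, hi, _, _ = f
        return max(lo - summit, summit - (hi - 1), 0)

    lo, hi, cat, obj = min(features, key=dist)
    return cat, obj


def assignment_summary(assignments: list[PeakAssignment]) -> dict:
    """Counts of spacer/ORF-assigned peaks and mean peaks per occupied
    feature, means rounded half-up to 2 decimals."""
    spacer_peaks = [a for a in assignments if a.category == "spacer"]
    orf_peaks = [a for a in assignments if a.category == "orf"]
    n_spacers = len({id(a.container) for a in spacer_peaks})
    n_genes = len({id(a.container) for a in orf_peaks})
    summary = {
        "n_peaks": len(assignments),
        "spacer_peaks": len(spacer_peaks),
        "orf_peaks": len(orf_peaks),
        "nearest_peaks": sum(1 for a in assignments if a.category == "nearest"),
        "occupied_spacers": n_spacers,
        "occupied_genes": n_genes,
    }
    if n_spacers:
        summary["peaks_per_spacer"] = round_half_up(
            Fraction(len(spacer_peaks), n_spacers), 2
        )
    if n_genes:
        summary["peaks_per_gene"] = round_half_up(Fraction(len(orf_peaks), n_genes), 2)
    return summary


def count_constitutive_bounds(spacers: list[Spacer]) -> tuple[int, int]:
    """Promoter-count bounds from peak-bearing spacers.

    Each peak-bearing type-B spacer holds one promoter; a type-A spacer
    holds at least one and at most two (one per direction); type C holds
    none.  min = nA + nB, max = 2 nA + nB.
    """
    with_peaks = [s for s in spacers if s.peaks]
    n_a = sum(1 for s in with_peaks if s.type_code == "A")
    n_b = sum(1 for s in with_peaks if s.type_code == "B")
    return n_a + n_b, 2 * n_a + n_b


def genes_per_promoter(controlled_gene_counts: list[int]) -> float:
    """Mean number of genes under the control of one promoter, given the
    per-promoter controlled-gene counts; rounded half-up to 2 decimals."""
    if not controlled_gene_counts:
        raise ValueError("no promoters supplied")
    total = sum(controlled_gene_counts)
    return round_half_up(Fraction(total, len(controlled_gene_counts)), 2)
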