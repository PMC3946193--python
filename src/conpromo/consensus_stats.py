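"""Summary statistics over promoter hits: conservation cross-tabulation,
sequence-logo information content, H-NS silencing arithmetic, and
essential-gene coverage.

Percentages are computed with exact rational arithmetic and rounded
half-up, matching the convention used for printed summary figures.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from ._util import percent, round_half_up

_BIN_LABELS = ["6", "5", "4", "<=3"]


def _bin(count: int) -> str:
    return str(count) if count >= 4 else "<=3"


@dataclass
class ConservationTable:
    """Cross-tab of -35 vs -10 match-count bins {6, 5, 4, <=3} plus the
    aggregate fraction of promoters with at least 4/6 in both boxes."""

    counts: pd.DataFrame  # rows: m35 bin, columns: m10 bin
    n: int
    n_qualifying: int  # both boxes >= 4/6

    @property
    def aggregate_percent(self) -> float:
        return percent(self.n_qualifying, self.n)


def conservation_crosstab(hits) -> ConservationTable:
    """Bin promoter hits by per-box conservation level.

    ``hits`` is any iterable of objects with integer ``m35``/``m10``
    attributes (or a DataFrame with those columns).
    """
    if isinstance(hits, pd.DataFrame):
        pairs = list(zip(hits["m35"], hits["m10"]))
    else:
        pairs = [(h.m35, h.m10) for h in hits]
    if not pairs:
        raise ValueError("empty promoter set")
    counts = pd.DataFrame(0, index=_BIN_LABELS, columns=_BIN_LABELS, dtype=int)
    qualifying = 0
    for m35, m10 in pairs:
        counts.loc[_bin(m35), _bin(m10)] += 1
        if m35 >= 4 and m10 >= 4:
            qualifying += 1
    return ConservationTable(counts=counts, n=len(pairs), n_qualifying=qualifying)


def pooled_fraction(part_counts: list[int], whole_counts: list[int]) -> float:
    """Pooled percentage: sum(parts) / sum(wholes), rounded half-up."""
    if len(part_counts) != len(whole_counts):
        raise ValueError("part and whole lists must be parallel")
    return percent(sum(part_counts), sum(whole_counts))


@dataclass
class LogoMatrix:
    """Per-position base frequencies and Shannon information content for an
    aligned set of hexamers: R(i) = 2 - H(i) bits, H over {A,C,G,T} with N
    excluded position-wise (uniform background, no small-sample correction)."""

    frequencies: pd.DataFrame  # index A,C,G,T; columns positions 1..6
    information: np.ndarray  # bits, length 6

    def letter_heights(self) -> pd.DataFrame:
        """Frequency x information, the conventional logo letter heights."""
        return self.frequencies * self.information


def position_information(aligned_hexamers: list[str]) -> LogoMatrix:
    """Base frequencies and information content per column of a gap-free
    hexamer alignment."""
    if not aligned_hexamers:
        raise ValueError("empty alignment")
    if any(len(s) != 6 for s in aligned_hexamers):
        raise ValueError("all sequences must be length-6 hexamers")
    bases = "ACGT"
    freq = np.zeros((4, 6))
    for pos in range(6):
        column = [s[pos].upper() for s in aligned_hexamers]
        counts = np.array([column.count(b) for b in bases], dtype=float)
        total = counts.sum()
        if total == 0:
            raise ValueError(f"position {pos + 1} contains only N bases")
        freq[:, pos] = counts / total
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    entropy = -plogp.sum(axis=0)
    info = 2.0 - entropy
    frequencies = pd.DataFrame(freq, index=list(bases), columns=range(1, 7))
    return LogoMatrix(frequencies=frequencies, information=info)


def has_hns_overlap(spacer, hns_sites: list[tuple[int, int]]) -> bool:
    """True when any H-NS interval overlaps the spacer by >= 1 bp (half-open
    intervals: an abutting site does not overlap)."""
    return any(site_start < spacer.end and site_end > spacer.start
               for site_start, site_end in hns_sites)


def annotate_hns(spacers, hns_sites: list[tuple[int, int]]) -> None:
    """Set ``has_hns`` on each spacer in place."""
    for s in spacers:
        s.has_hns = has_hns_overlap(s, hns_sites)


def hns_silencing_count(spacers, max_count: int | None = None) -> tuple[int, float]:
    """Promoters potentially silenced by H-NS.

    H-NS spreads cooperatively along a bound spacer, so one bound type-A
    spacer silences both of its divergent promoters (counted twice) and a
    bound type-B spacer silences its single promoter.  Returns the count and
    its fraction of the maximum constitutive-promoter bound (computed from
    the same spacers' peak-bearing A/B counts unless ``max_count`` is given).
    """
    spacers = list(spacers)
    n_a_hns = sum(1 for s in spacers if s.type_code == "A" and s.has_hns)
    n_b_hns = sum(1 for s in spacers if s.type_code == "B" and s.has_hns)
    count = 2 * n_a_hns + n_b_hns
    if max_count is None:
        n_a = sum(1 for s in spacers if s.type_code == "A" and s.peaks)
        n_b = sum(1 for s in spacers if s.type_code == "B" and s.peaks)
        max_count = 2 * n_a + n_b
    if max_count == 0:
        raise ZeroDivisionError("no constitutive promoters to take a fraction of")
    return count, round_half_up(Fraction(count, max_count), 3)


def essential_coverage(
    controlled_genes: set[str], essential_list: set[str]
) -> tuple[int, float]:
    """How many essential genes fall under constitutive-promoter control:
    intersection size and its percentage of the essential list."""
    essential = set(essential_list)
    if not essential:
        raise ValueError("empty essential-gene list")
    covered = len(essential & set(controlled_genes))
    return covered, percent(covered, len(essential))
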