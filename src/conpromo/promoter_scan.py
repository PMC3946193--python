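"""Consensus-hexamer promoter scanning.

Scores candidate sigma-70 promoters by counting matches of two hexamer
windows against the canonical -35 (TTGACA) and -10 (TATAAT) boxes, plus a
bonus for spacer lengths near the optimal 17 bp (+3 at 17, +2 at 16/18,
+1 at 15/19, 0 otherwise).  A perfect promoter, TTGACA-17bp-TATAAT, scores
6 + 6 + 3 = 15.

Scanning slides both windows over every position of the sequence (1-bp
steps), enumerates every spacer length from 15 to 19, and retains candidate
hits whose per-box and summed match counts pass configurable thresholds
(default: at least 4/6 in each box and at least 8/12 summed).  The minus
strand is handled by scanning the reverse complement and mapping hits back
to forward coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from ._util import check_alphabet, reverse_complement

CONSENSUS_35 = "TTGACA"
CONSENSUS_10 = "TATAAT"

SPACER_SCORES = {17: 3, 16: 2, 18: 2, 15: 1, 19: 1}

_MIN_FOOTPRINT = 6 + min(SPACER_SCORES) + 6  # 27 bp: smallest scannable region


@dataclass(frozen=True)
class ScoringScheme:
    """Match-count thresholds and spacer bonus table for promoter scoring.

    ``strict`` switches the retention predicate from >= to > on both the
    per-box and the summed thresholds.
    """

    consensus35: str = CONSENSUS_35
    consensus10: str = CONSENSUS_10
    spacer_scores: dict = field(default_factory=lambda: dict(SPACER_SCORES))
    min_box_match: int = 4
    min_box_sum: int = 8
    strict: bool = False

    def __post_init__(self):
        if not (0 <= self.min_box_match <= 6):
            raise ValueError("min_box_match must be in [0, 6]")
        if not (0 <= self.min_box_sum <= 12):
            raise ValueError("min_box_sum must be in [0, 12]")

    def retain(self, m35: int, m10: int) -> bool:
        if self.strict:
            return (
                m35 > self.min_box_match
                and m10 > self.min_box_match
                and m35 + m10 > self.min_box_sum
            )
        return (
            m35 >= self.min_box_match
            and m10 >= self.min_box_match
            and m35 + m10 >= self.min_box_sum
        )


@dataclass(frozen=True)
class PromoterHit:
    """One scored (-35, spacer, -10) candidate.

    ``pos35`` is the 0-based forward-genome start of the 6-mer that reads as
    the -35 box on the promoter strand; for minus-strand hits that is the
    leftmost coordinate of the segment whose reverse complement is the box.
    ``seq35``/``seq10`` are given as read on the promoter strand.
    """

    strand: str
    pos35: int
    seq35: str
    seq10: str
    spacer_len: int
    m35: int
    m10: int
    spacer_score: int

    @property
    def total(self) -> int:
        return self.m35 + self.m10 + self.spacer_score


def hexamer_match(seq6: str, consensus: str) -> int:
    """Number of identical positions between two hexamers.

    One point per matching base, zero per mismatch, no gaps; ``N`` never
    matches.
    """
    if len(seq6) != 6 or len(consensus) != 6:
        raise ValueError("hexamer_match requires two length-6 sequences")
    s, c = seq6.upper(), consensus.upper()
    return sum(1 for a, b in zip(s, c) if a == b and a != "N")


def spacer_length_score(length: int) -> int:
    """Bonus for spacer length: 3 at 17 bp, 2 at 16/18, 1 at 15/19, else 0."""
    if length < 0:
        raise ValueError("spacer length must be non-negative")
    return SPACER_SCORES.get(length, 0)


def _match_profile(arr: np.ndarray, consensus: str) -> np.ndarray:
    """Match counts of every 6-mer window of ``arr`` against ``consensus``.

    ``arr`` is a uint8 view of the upper-cased sequence; returns an int array
    of length ``len(arr) - 5`` (empty when the sequence is shorter than 6).
    """
    n = arr.size
    if n < 6:
        return np.zeros(0, dtype=np.int64)
    out = np.zeros(n - 5, dtype=np.int64)
    for k, base in enumerate(consensus.encode("ascii")):
        out += arr[k : n - 5 + k] == base
    return out


def _scan_one_strand(seq: str, scheme: ScoringScheme, strand: str) -> list[PromoterHit]:
    n = len(seq)
    if n < _MIN_FOOTPRINT:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    m35 = _match_profile(arr, scheme.consensus35)
    m10 = _match_profile(arr, scheme.consensus10)
    hits: list[PromoterHit] = []
    for spacer, bonus in sorted(scheme.spacer_scores.items()):
        # -10 window starts 6 + spacer after the -35 window
        offset = 6 + spacer
        n_pos = n - (12 + spacer) + 1
        if n_pos <= 0:
            continue
        a35 = m35[:n_pos]
        a10 = m10[offset : offset + n_pos]
        if scheme.strict:
            keep = (
                (a35 > scheme.min_box_match)
                & (a10 > scheme.min_box_match)
                & (a35 + a10 > scheme.min_box_sum)
            )
        else:
            keep = (
                (a35 >= scheme.min_box_match)
                & (a10 >= scheme.min_box_match)
                & (a35 + a10 >= scheme.min_box_sum)
            )
        for i in np.flatnonzero(keep):
            i = int(i)
            hits.append(
                PromoterHit(
                    strand=strand,
                    pos35=i,
                    seq35=seq[i : i + 6],
                    seq10=seq[i + offset : i + offset + 6],
                    spacer_len=spacer,
                    m35=int(a35[i]),
                    m10=int(a10[i]),
                    spacer_score=bonus,
                )
            )
    return hits


def scan_sequence(
    seq: str,
    scheme: ScoringScheme | None = None,
    strand_mode: str = "both",
    offset: int = 0,
) -> list[PromoterHit]:
    """Scan a sequence for promoter candidates on one or both strands.

    Minus-strand hits are found on the reverse complement and reported in
    forward coordinates (``pos35`` = leftmost forward coordinate of the -35
    box segment).  ``offset`` shifts all reported coordinates, for scanning
    an excised region of a larger genome.  Hits are returned sorted by
    (pos35, strand, spacer_len).
    """
    if strand_mode not in ("both", "forward"):
        raise ValueError(f"unknown strand_mode: {strand_mode!r}")
    scheme = scheme or ScoringScheme()
    seq = seq.upper()
    check_alphabet(seq)
    hits = _scan_one_strand(seq, scheme, "+")
    if strand_mode == "both":
        n = len(seq)
        rc = reverse_complement(seq)
        for h in _scan_one_strand(rc, scheme, "-"):
            # position p on the reverse complement maps to forward n - p - 6
            hits.append(replace(h, pos35=n - h.pos35 - 6))
    if offset:
        hits = [replace(h, pos35=h.pos35 + offset) for h in hits]
    hits.sort(key=lambda h: (h.pos35, h.strand, h.spacer_len))
    return hits


def best_hit(hits: list[PromoterHit]) -> PromoterHit | None:
    """Single best hit of a region: highest total score; ties broken by
    spacer length closest to 17, then larger -10 match count, then smaller
    position.  Returns None for an empty list."""
    if not hits:
        return None
    return min(
        hits,
        key=lambda h: (-h.total, abs(h.spacer_len - 17), -h.m10, h.pos35),
    )


_COMPACT_RE = re.compile(r"^([ACGTNacgtn]{6})-(\d+)-([ACGTNacgtn]{6})$")


def score_promoter_string(compact: str) -> int:
    """Score a promoter written in compact ``HEXAMER-N-HEXAMER`` notation,
    e.g. ``"TTGACA-17-TATAAT"`` -> 15."""
    m = _COMPACT_RE.match(compact.strip())
    if m is None:
        raise ValueError(f"malformed promoter string: {compact!r}")
    box35, spacer, box10 = m.group(1), int(m.group(2)), m.group(3)
    return (
        hexamer_match(box35, CONSENSUS_35)
        + hexamer_match(box10, CONSENSUS_10)
        + spacer_length_score(spacer)
    )
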