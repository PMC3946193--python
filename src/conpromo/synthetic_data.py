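"""Synthetic genomes, annotations, planted promoters, array signal, and
kinetic time courses with recorded ground truth.

Every downstream stage of the pipeline (peak calling, spacer classification,
promoter scanning, kinetic fitting) is exercised against data produced here,
so each generator records exactly what it planted and all randomness flows
through an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import check_alphabet, reverse_complement
from .genome_annotation import Gene
from .promoter_scan import CONSENSUS_10, CONSENSUS_35, hexamer_match

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence over {A,C,G,T,N}, optionally circular."""

    name: str
    seq: str
    circular: bool = False

    def __post_init__(self):
        if len(self.seq) < 1:
            raise ValueError("genome must contain at least one base")
        check_alphabet(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def subseq(self, start: int, end: int, strand: str = "+") -> str:
        """Strand-aware subsequence on 0-based half-open coordinates;
        wraps around the origin when the genome is circular."""
        n = len(self.seq)
        if self.circular:
            idx = [(i % n) for i in range(start, end)]
            s = "".join(self.seq[i] for i in idx)
        else:
            if start < 0 or end > n or start > end:
                raise IndexError(f"[{start}, {end}) outside genome of length {n}")
            s = self.seq[start:end]
        return s if strand == "+" else reverse_complement(s)


@dataclass(frozen=True)
class PlantedPromoter:
    """Ground truth for one planted promoter: ``pos35`` is the 0-based
    forward-genome start of the -35 box segment (leftmost coordinate on
    either strand), matching the scanner's coordinate convention."""

    pos35: int
    strand: str
    m35: int
    m10: int
    spacer_len: int


@dataclass
class PlantedTruth:
    promoters: list[PlantedPromoter] = field(default_factory=list)
    peaks: list[tuple[int, float]] = field(default_factory=list)
    hns_sites: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class AnnotationSet:
    """Planted gene models plus the ground-truth spacer layout
    (start, end, type_code) requested for each adjacent planted pair."""

    genes: list[Gene]
    planted_spacers: list[tuple[int, int, str]]


@dataclass(frozen=True)
class SyntheticConfig:
    genome_length: int = 100_000
    gc_fraction: float = 0.5
    probe_interval: int = 105
    probe_length: int = 60
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.probe_interval < 1:
            raise ValueError("probe_interval must be >= 1")
        if not (0 < self.gc_fraction < 1):
            raise ValueError("gc_fraction must lie strictly between 0 and 1")


def generate_genome(length: int, gc_fraction: float, seed: int) -> GenomeSequence:
    """I.i.d. random genome with P(G) = P(C) = gc_fraction / 2."""
    if length < 100:
        raise ValueError("genome length must be >= 100")
    if not (0.0 <= gc_fraction <= 1.0):
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    probs = [p_at, p_gc, p_gc, p_at]  # A C G T
    seq = "".join(rng.choice(BASES, size=length, p=probs))
    return GenomeSequence(name=f"synthetic_{seed}", seq=seq)


# strand pairs realizing each spacer orientation class:
# A = divergent (genes point away), B = codirectional, C = convergent
_LAYOUT_STRANDS = {"A": ("-", "+"), "B": ("+", "+"), "C": ("+", "-")}


def plant_gene_layout(
    genome: GenomeSequence,
    layout: list[tuple[str, int]],
    seed: int = 0,
    gene_length: int = 300,
    pair_gap: int = 60,
) -> AnnotationSet:
    """Emit gene pairs whose strands realize the requested spacer classes.

    Each layout entry ``(type_code, spacer_len)`` produces two genes of
    ``gene_length`` bp separated by exactly ``spacer_len`` bp; consecutive
    pairs are separated by ``pair_gap`` bp.  The gene coordinates partition
    the genome deterministically (the seed is accepted for interface
    symmetry but the placement is sequential).
    """
    genes: list[Gene] = []
    planted: list[tuple[int, int, str]] = []
    cursor = 0
    for idx, (type_code, spacer_len) in enumerate(layout):
        if type_code not in _LAYOUT_STRANDS:
            raise ValueError(f"unknown spacer type code: {type_code!r}")
        if spacer_len < 0:
            raise ValueError("spacer length must be non-negative")
        left_strand, right_strand = _LAYOUT_STRANDS[type_code]
        left = Gene(
            id=f"g{2 * idx}", start=cursor, end=cursor + gene_length, strand=left_strand
        )
        sp_start = left.end
        sp_end = sp_start + spacer_len
        right = Gene(
            id=f"g{2 * idx + 1}",
            start=sp_end,
            end=sp_end + gene_length,
            strand=right_strand,
        )
        if right.end > len(genome):
            raise ValueError(
                f"layout requires {right.end} bp but genome has {len(genome)}"
            )
        genes.extend([left, right])
        planted.append((sp_start, sp_end, type_code))
        cursor = right.end + pair_gap
    return AnnotationSet(genes=genes, planted_spacers=planted)


def _degrade_box(consensus: str, matches: int, rng: np.random.Generator) -> str:
    """A hexamer with exactly ``matches`` positions equal to the consensus;
    mismatch positions are chosen uniformly and receive a uniformly chosen
    non-consensus base."""
    if not (0 <= matches <= 6):
        raise ValueError("match count must be in [0, 6]")
    box = list(consensus)
    for pos in rng.choice(6, size=6 - matches, replace=False):
        alternatives = [b for b in "ACGT" if b != consensus[pos]]
        box[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(box)


def plant_promoter(
    genome: GenomeSequence,
    position: int,
    strand: str,
    m35: int,
    m10: int,
    spacer_len: int,
    seed: int,
) -> tuple[GenomeSequence, PlantedPromoter]:
    """Write a promoter with controlled consensus degradation into the genome.

    The planted cassette is (-35 box, ``spacer_len`` random bases, -10 box);
    on the minus strand its reverse complement is written so that the
    promoter reads correctly on that strand.  Returns the modified genome and
    a truth record whose match counts are guaranteed to recount correctly.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"invalid strand: {strand!r}")
    footprint = 6 + spacer_len + 6
    if position < 0 or position + footprint > len(genome):
        raise ValueError("promoter footprint does not fit at requested position")
    rng = np.random.default_rng(seed)
    box35 = _degrade_box(CONSENSUS_35, m35, rng)
    box10 = _degrade_box(CONSENSUS_10, m10, rng)
    spacer = "".join(rng.choice(BASES, size=spacer_len))
    cassette = box35 + spacer + box10
    assert hexamer_match(box35, CONSENSUS_35) == m35
    assert hexamer_match(box10, CONSENSUS_10) == m10
    if strand == "-":
        cassette = reverse_complement(cassette)
        pos35 = position + spacer_len + 6  # leftmost coordinate of the -35 segment
    else:
        pos35 = position
    seq = genome.seq[:position] + cassette + genome.seq[position + footprint :]
    truth = PlantedPromoter(
        pos35=pos35, strand=strand, m35=m35, m10=m10, spacer_len=spacer_len
    )
    return GenomeSequence(genome.name, seq, genome.circular), truth


PEAK_KERNEL_HALF_WIDTH = 150  # bp; reflects the ~300-bp selected fragment size


def simulate_array_signal(
    genome_length: int,
    cfg: SyntheticConfig,
    peaks: list[tuple[int, float]],
    baseline: float = 1000.0,
) -> pd.DataFrame:
    """Tiling-array probe signal with triangular enrichment peaks.

    Probes start at 0, ``probe_interval``, 2x``probe_interval``, ...  Cy3 is
    the (noisy) library baseline; Cy5 = Cy3 x (1 + sum of peak kernels) x
    multiplicative lognormal noise.  A peak of amplitude ``a`` contributes
    ``a * max(0, 1 - |x - center| / 150)``, wide enough that at least two
    adjacent probes (105 bp apart) are elevated.
    """
    for center, _amp in peaks:
        if not (0 <= center < genome_length):
            raise ValueError(f"peak center {center} outside genome")
    rng = np.random.default_rng(cfg.seed)
    pos = np.arange(0, genome_length, cfg.probe_interval, dtype=np.int64)
    enrich = np.ones(pos.size)
    for center, amp in peaks:
        enrich += amp * np.clip(1.0 - np.abs(pos - center) / PEAK_KERNEL_HALF_WIDTH, 0, None)
    if cfg.noise_sd > 0:
        cy3 = baseline * rng.lognormal(0.0, cfg.noise_sd, size=pos.size)
        noise = rng.lognormal(0.0, cfg.noise_sd, size=pos.size)
    else:
        cy3 = np.full(pos.size, baseline)
        noise = np.ones(pos.size)
    cy5 = cy3 * enrich * noise
    return pd.DataFrame({"probe_start": pos, "cy5": cy5, "cy3": cy3})


def simulate_time_course(
    amplitude: float,
    rate_k: float,
    times: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Saturating-exponential transcription time course
    y(t) = A (1 - exp(-k t)) with multiplicative lognormal noise."""
    if amplitude <= 0 or rate_k <= 0:
        raise ValueError("amplitude and rate must be positive")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    y = amplitude * (1.0 - np.exp(-rate_k * t))
    if noise_sd > 0:
        y = y * rng.lognormal(0.0, noise_sd, size=t.size)
    return pd.DataFrame({"time_min": t, "signal": y})
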