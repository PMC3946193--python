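"""Tiling-array peak calling for holoenzyme-binding signal.

Two criteria define a binding peak: the probe ratio must reach a cutoff
expressed relative to the genome-wide maximum (default 2%), and the run of
above-cutoff probes must span at least two consecutive probes — a ~300 bp
bound fragment necessarily covers more than one probe at 105-bp probe
spacing, so single-probe spikes are treated as noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import round_half_up


@dataclass
class ProbeTrack:
    """Normalized probe signal: positions (0-based, strictly increasing),
    raw intensities and the Cy5/Cy3 enrichment ratio."""

    probe_start: np.ndarray
    cy5: np.ndarray
    cy3: np.ndarray
    ratio: np.ndarray
    probe_length: int = 60
    circular: bool = False

    def __len__(self) -> int:
        return len(self.probe_start)


@dataclass(frozen=True)
class BindingPeak:
    """A maximal run of above-cutoff probes.

    The interval spans from the first probe start to the last probe start
    plus one probe length (half-open); the summit is the position of the
    highest-ratio probe, first occurrence winning ties.
    """

    start: int
    end: int
    summit: int
    height: float
    rel_height: float
    n_probes: int


def normalize_ratio(
    track: pd.DataFrame, floor_frac: float = 1e-6, probe_length: int = 60,
    circular: bool = False,
) -> ProbeTrack:
    """Compute per-probe Cy5/Cy3 ratios from a raw probe table.

    Cy3 values are floored at ``floor_frac`` x median(cy3) so zero-intensity
    reference probes yield large finite ratios instead of dividing by zero.
    """
    if len(track) == 0:
        raise ValueError("empty probe track")
    pos = np.asarray(track["probe_start"], dtype=np.int64)
    if np.any(np.diff(pos) <= 0):
        raise ValueError("probe positions must be strictly increasing")
    cy5 = np.asarray(track["cy5"], dtype=float)
    cy3 = np.asarray(track["cy3"], dtype=float)
    med = np.median(cy3)
    floor = floor_frac * med if med > 0 else floor_frac
    ratio = cy5 / np.maximum(cy3, floor)
    return ProbeTrack(pos, cy5, cy3, ratio, probe_length=probe_length, circular=circular)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges of maximal True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, ends)]


def call_peaks(
    track: ProbeTrack, cutoff_frac: float = 0.02, min_probes: int = 2
) -> list[BindingPeak]:
    """Call binding peaks as runs of >= ``min_probes`` consecutive probes
    whose ratio reaches ``cutoff_frac`` of the genome-wide maximum ratio.

    On circular tracks a run touching both ends of the probe array is
    stitched across the origin before the length filter is applied.
    """
    ratio = track.ratio
    global_max = float(ratio.max())
    if global_max <= 0:
        warnings.warn("all-zero probe track: no peaks definable", stacklevel=2)
        return []
    threshold = cutoff_frac * global_max
    runs = _runs(ratio >= threshold)
    wrapped_tail: tuple[int, int] | None = None
    if (
        track.circular
        and len(runs) >= 2
        and runs[0][0] == 0
        and runs[-1][1] == len(track)
    ):
        wrapped_tail = runs.pop()  # joined onto the first run across the origin
    peaks = []
    for lo, hi in runs:
        members = list(range(lo, hi))
        if wrapped_tail is not None and lo == 0:
            members = list(range(*wrapped_tail)) + members
            wrapped_tail = None
        if len(members) < min_probes:
            continue
        sub = ratio[members]
        top = int(np.argmax(sub))  # first occurrence wins ties
        peaks.append(
            BindingPeak(
                start=int(track.probe_start[members[0]]),
                end=int(track.probe_start[members[-1]]) + track.probe_length,
                summit=int(track.probe_start[members[top]]),
                height=float(sub[top]),
                rel_height=float(sub[top] / global_max),
                n_probes=len(members),
            )
        )
    peaks.sort(key=lambda p: p.start)
    return peaks


def rank_peaks(peaks: list[BindingPeak]) -> list[BindingPeak]:
    """Peaks sorted by relative height, descending; equal heights keep
    genome order (stable sort)."""
    if not peaks:
        raise ValueError("rank_peaks requires a non-empty peak list")
    in_order = sorted(peaks, key=lambda p: p.start)
    return sorted(in_order, key=lambda p: -p.rel_height)


def peaks_to_frame(peaks: list[BindingPeak]) -> pd.DataFrame:
    """Tabular view of called peaks, ranked by relative height."""
    ranked = rank_peaks(peaks) if peaks else []
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(ranked) + 1),
            "start": [p.start for p in ranked],
            "end": [p.end for p in ranked],
            "summit": [p.summit for p in ranked],
            "height": [p.height for p in ranked],
            "rel_height": [p.rel_height for p in ranked],
            "n_probes": [p.n_probes for p in ranked],
            "score": [int(round_half_up(1000 * p.rel_height)) for p in ranked],
        }
    )
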