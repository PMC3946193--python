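"""Readers and writers for the pipeline's file formats.

Genomes travel as FASTA, gene models as GFF3 (feature type ``gene``,
attributes ``ID`` and optional ``operon``), intervals (peaks, H-NS sites)
as BED, and tabular data (probe signal, promoter hits, spacers, kinetic
fits) as TSV.  Internal coordinates are 0-based half-open; GFF3 is written
1-based closed per its standard, BED stays 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .array_peaks import BindingPeak, peaks_to_frame, rank_peaks
from .genome_annotation import Gene, Spacer
from .promoter_scan import PromoterHit
from .synthetic_data import GenomeSequence


# ---------------------------------------------------------------- FASTA

def write_fasta(genome: GenomeSequence, path: str | Path) -> None:
    record = SeqRecord(Seq(genome.seq), id=genome.name, description="")
    SeqIO.write([record], str(path), "fasta")


def read_fasta(path: str | Path, circular: bool = False) -> GenomeSequence:
    record = next(SeqIO.parse(str(path), "fasta"))
    return GenomeSequence(name=record.id, seq=str(record.seq).upper(), circular=circular)


# ----------------------------------------------------------------- GFF3

def write_gff3(genes: list[Gene], path: str | Path, seqid: str = "genome") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.id}"
            if g.operon is not None:
                attrs += f";operon={g.operon}"
            if g.essential:
                attrs += ";essential=true"
            fh.write(
                "\t".join(
                    [
                        seqid,
                        "conpromo",
                        "gene",
                        str(g.start + 1),  # GFF3 is 1-based closed
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[Gene]:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            genes.append(
                Gene(
                    id=attrs.get("ID", f"gene_{fields[3]}"),
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    strand=fields[6],
                    operon=attrs.get("operon"),
                    essential=attrs.get("essential", "").lower() == "true",
                )
            )
    genes.sort(key=lambda g: g.start)
    return genes


# ------------------------------------------------------------------ BED

def read_bed_intervals(path: str | Path) -> list[tuple[int, int]]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            intervals.append((int(fields[1]), int(fields[2])))
    return intervals


def write_bed_intervals(
    intervals: list[tuple[int, int]], path: str | Path, chrom: str = "genome"
) -> None:
    with open(path, "w") as fh:
        for start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_peaks_bed(
    peaks: list[BindingPeak], path: str | Path, chrom: str = "genome"
) -> None:
    """BED6 of called peaks: name = height rank (1 = highest), score =
    1000 x relative height rounded."""
    ranked = rank_peaks(peaks)
    with open(path, "w") as fh:
        for rank, p in enumerate(ranked, start=1):
            score = int(round(1000 * p.rel_height))
            fh.write(f"{chrom}\t{p.start}\t{p.end}\tpeak_{rank}\t{score}\t.\n")


def read_peaks_bed(path: str | Path) -> list[BindingPeak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            start, end = int(fields[1]), int(fields[2])
            rel = int(fields[4]) / 1000 if len(fields) > 4 else 1.0
            peaks.append(
                BindingPeak(
                    start=start,
                    end=end,
                    summit=(start + end) // 2,
                    height=rel,
                    rel_height=rel,
                    n_probes=2,
                )
            )
    return peaks


# ------------------------------------------------------------------ TSV

def write_probe_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_probe_tsv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"probe_start", "cy5", "cy3"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    return table


def write_peaks_tsv(peaks: list[BindingPeak], path: str | Path) -> None:
    peaks_to_frame(peaks).to_csv(path, sep="\t", index=False)


def hits_to_frame(hits: list[PromoterHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strand": [h.strand for h in hits],
            "pos35": [h.pos35 for h in hits],
            "seq35": [h.seq35 for h in hits],
            "spacer_len": [h.spacer_len for h in hits],
            "seq10": [h.seq10 for h in hits],
            "m35": [h.m35 for h in hits],
            "m10": [h.m10 for h in hits],
            "total": [h.total for h in hits],
        }
    )


def write_hits_tsv(hits: list[PromoterHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def spacers_to_frame(spacers: list[Spacer]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start": [s.start for s in spacers],
            "end": [s.end for s in spacers],
            "type": [s.type_code for s in spacers],
            "n_peaks": [len(s.peaks) for s in spacers],
            "internal": [s.internal for s in spacers],
            "has_hns": [s.has_hns for s in spacers],
        }
    )


def write_spacers_tsv(spacers: list[Spacer], path: str | Path) -> None:
    spacers_to_frame(spacers).to_csv(path, sep="\t", index=False)


def read_spacers_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_essential_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_timecourse_tsv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"template_id", "time_min", "intensity"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"time-course table missing columns: {sorted(missing)}")
    return table


def read_transcripts_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
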