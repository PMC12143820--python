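"""Readers and writers for the plain-text genomics formats the pipeline touches.

Supported: ENCODE narrowPeak / BED5 peaks, bedGraph signal tracks, GTF gene
models (gene and exon features only) and TSV tables.  All readers validate
every line and report the offending line number instead of silently skipping
malformed records; all writers emit 0-based half-open coordinates.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_model import GeneModel, GenomeAnnotation, GenomicInterval, Peak

__all__ = [
    "FormatError",
    "SignalTrack",
    "read_narrowpeak",
    "read_gtf_genes",
    "read_bedgraph",
    "signal_over",
    "write_bed",
    "write_gtf",
    "write_table",
    "read_table",
]

MISSING = "."  # BED-family missing-value marker


class FormatError(ValueError):
    """A malformed record in an input file; the message names the line."""


@dataclass
class SignalTrack:
    """Per-chromosome piecewise-constant coverage, bedGraph-style.

    ``data`` maps chromosome -> (starts, ends, values) as parallel lists,
    sorted by start and non-overlapping within each chromosome.
    """

    data: Mapping[str, tuple[list[int], list[int], list[float]]]

    def chroms(self) -> tuple[str, ...]:
        return tuple(sorted(self.data))


def _split_fields(line: str, path: str, lineno: int, minimum: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < minimum:
        raise FormatError(
            f"{path}:{lineno}: expected >= {minimum} tab-separated fields, "
            f"got {len(fields)}"
        )
    return fields


def _parse_int(value: str, what: str, path: str, lineno: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: {what} is not an integer: {value!r}")


def _parse_float(value: str, what: str, path: str, lineno: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: {what} is not a number: {value!r}")


def read_narrowpeak(path: str | Path) -> list[Peak]:
    """Read peaks from a narrowPeak (BED6+4) or 5-column BED file.

    With 10 fields the signal is narrowPeak signalValue (column 7; the BED
    score column is display-clamped to 1000 and not used) and the summit
    offset is column 10 when >= 0.  With fewer fields the signal falls back
    to column 5.
    """
    path = Path(path)
    peaks: list[Peak] = []
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_fields(line, str(path), lineno, 5)
            chrom = fields[0]
            start = _parse_int(fields[1], "start", str(path), lineno)
            end = _parse_int(fields[2], "end", str(path), lineno)
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3]
            summit: int | None = None
            if len(fields) >= 10:
                signal = _parse_float(fields[6], "signalValue", str(path), lineno)
                raw_summit = _parse_int(fields[9], "summit", str(path), lineno)
                if raw_summit >= 0:
                    summit = raw_summit
            else:
                signal = _parse_float(fields[4], "score", str(path), lineno)
            try:
                peaks.append(
                    Peak(GenomicInterval(chrom, start, end), name, signal, summit)
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return peaks


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _merge_intervals(
    chrom: str, intervals: Iterable[tuple[int, int]]
) -> tuple[GenomicInterval, ...]:
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple(GenomicInterval(chrom, s, e) for s, e in merged)


def read_gtf_genes(path: str | Path) -> GenomeAnnotation:
    """Build a :class:`GenomeAnnotation` from GTF gene/exon features.

    GTF coordinates (1-based closed) are converted to 0-based half-open.  A
    gene's span is the union extent of all its features; overlapping exons
    are merged.  Features other than ``gene``/``exon`` are ignored.
    """
    path = Path(path)
    spans: dict[str, tuple[str, str, int, int]] = {}  # gene -> chrom, strand, lo, hi
    exons: dict[str, list[tuple[int, int]]] = {}
    symbols: dict[str, str] = {}
    order: list[str] = []
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_fields(line, str(path), lineno, 9)
            feature = fields[2]
            if feature not in ("gene", "exon"):
                continue
            chrom = fields[0]
            start = _parse_int(fields[3], "start", str(path), lineno) - 1
            end = _parse_int(fields[4], "end", str(path), lineno)
            strand = fields[6]
            if strand not in ("+", "-"):
                raise FormatError(
                    f"{path}:{lineno}: unknown strand {strand!r}"
                )
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            if "gene_name" in attrs:
                symbols[gene_id] = attrs["gene_name"]
            if gene_id not in spans:
                spans[gene_id] = (chrom, strand, start, end)
                order.append(gene_id)
            else:
                pchrom, pstrand, lo, hi = spans[gene_id]
                if pchrom != chrom or pstrand != strand:
                    raise FormatError(
                        f"{path}:{lineno}: gene {gene_id!r} features disagree "
                        "on chromosome or strand"
                    )
                spans[gene_id] = (chrom, strand, min(lo, start), max(hi, end))
            if feature == "exon":
                exons.setdefault(gene_id, []).append((start, end))
    genes = []
    for gene_id in order:
        chrom, strand, lo, hi = spans[gene_id]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                span=GenomicInterval(chrom, lo, hi),
                exons=_merge_intervals(chrom, exons.get(gene_id, [])),
                symbol=symbols.get(gene_id),
            )
        )
    return GenomeAnnotation(genes)


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Overlapping records are an error: the track would be ambiguous.
    """
    path = Path(path)
    raw: dict[str, list[tuple[int, int, float]]] = {}
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_fields(line, str(path), lineno, 4)
            chrom = fields[0]
            start = _parse_int(fields[1], "start", str(path), lineno)
            end = _parse_int(fields[2], "end", str(path), lineno)
            value = _parse_float(fields[3], "value", str(path), lineno)
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative value {value}")
            raw.setdefault(chrom, []).append((start, end, value))
    data: dict[str, tuple[list[int], list[int], list[float]]] = {}
    for chrom, records in raw.items():
        records.sort()
        starts, ends, values = [], [], []
        for start, end, value in records:
            if ends and start < ends[-1]:
                raise FormatError(
                    f"{path}: overlapping bedGraph records on {chrom} at {start}"
                )
            starts.append(start)
            ends.append(end)
            values.append(value)
        data[chrom] = (starts, ends, values)
    return SignalTrack(data)


def signal_over(track: SignalTrack, region: GenomicInterval) -> float:
    """Area under the track within ``region``: sum of value x overlap length."""
    if region.chrom not in track.data:
        return 0.0
    starts, ends, values = track.data[region.chrom]
    # first record whose end is past region.start
    i = bisect.bisect_right(ends, region.start)
    total = 0.0
    while i < len(starts) and starts[i] < region.end:
        overlap = min(ends[i], region.end) - max(starts[i], region.start)
        if overlap > 0:
            total += values[i] * overlap
        i += 1
    return total


def write_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks as BED5 (chrom, start, end, name, signal), sorted by
    (chrom, start); round-trips through :func:`read_narrowpeak`."""
    path = Path(path)
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.interval.start, p.interval.end))
    with path.open("w") as handle:
        for peak in ordered:
            handle.write(
                f"{peak.chrom}\t{peak.interval.start}\t{peak.interval.end}\t"
                f"{peak.name}\t{peak.signal:g}\n"
            )


def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write gene and exon features (converting back to 1-based closed)."""
    path = Path(path)
    with path.open("w") as handle:
        for gene in annotation:
            attrs = f'gene_id "{gene.gene_id}";'
            if gene.symbol:
                attrs += f' gene_name "{gene.symbol}";'
            handle.write(
                f"{gene.chrom}\tsepipe\tgene\t{gene.span.start + 1}\t"
                f"{gene.span.end}\t.\t{gene.strand}\t.\t{attrs}\n"
            )
            for exon in gene.exons:
                handle.write(
                    f"{gene.chrom}\tsepipe\texon\t{exon.start + 1}\t{exon.end}\t"
                    f".\t{gene.strand}\t.\t{attrs}\n"
                )


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV with a header line; missing values as '.'."""
    frame.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` ('.' read back as missing)."""
    return pd.read_csv(path, sep="\t", na_values=MISSING)
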