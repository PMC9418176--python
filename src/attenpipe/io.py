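"""Readers and writers for the tab-delimited formats the pipeline touches.

BED, bedGraph, count-matrix TSV, sample-sheet TSV and TSS-table TSV.
Everything is 0-based half-open; ``#`` comment lines and blank lines are
ignored on input. bedGraph is the reference signal dialect (testable
bit-exactly); bigWig is out of scope.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import pandas as pd

from .core import (
    CountMatrix,
    GenomicInterval,
    Peak,
    PeakSet,
    SampleSheet,
    SignalTrack,
    TSSTable,
    ValidationError,
)

__all__ = [
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_tss_table",
    "write_tss_table",
]


class ParseError(ValueError):
    """Malformed input line; the message names the file and line number."""


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("track"):
                continue
            yield lineno, line.split("\t")


def read_bed(path: str | Path, name: str | None = None) -> PeakSet:
    """Read a BED3/BED6(+fdr column 7) file into a sorted :class:`PeakSet`.

    Column 5 (score) and column 7 (per-peak FDR) are optional; missing
    names are synthesized as ``peak_<lineno>``.
    """
    peaks = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
        try:
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        pname = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else f"peak_{lineno}"
        try:
            score = float(fields[4]) if len(fields) > 4 and fields[4] not in ("", ".") else 0.0
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
        fdr = None
        if len(fields) > 6 and fields[6] not in ("", "."):
            try:
                fdr = float(fields[6])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric fdr") from exc
        try:
            interval = GenomicInterval(chrom, start, end, strand)
            peaks.append(Peak(interval, pname, score, fdr))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(name or Path(path).stem, peaks)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fields = [iv.chrom, str(iv.start), str(iv.end), p.name, repr(p.score), iv.strand]
            if p.fdr is not None:
                fields.append(repr(p.fdr))
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Steps may arrive unsorted but must not overlap; overlap raises
    :class:`~attenpipe.core.ValidationError`.
    """
    steps: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 tab-separated fields")
        try:
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            value = float(fields[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed bedGraph fields") from exc
        steps.setdefault(chrom, []).append((start, end, value))
    return SignalTrack(steps)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_steps():
            fh.write(f"{chrom}\t{start}\t{end}\t{value!r}\n")


def read_counts(path: str | Path, sheet: SampleSheet | None = None) -> CountMatrix:
    """Read a TSV count matrix (first column gene id, header sample ids).

    When a sample sheet is given, the matrix is validated against it:
    every matrix sample must appear in the sheet.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"{path}: duplicate gene rows: {dups[:5]}")
    try:
        cm = CountMatrix(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    if sheet is not None:
        sheet.validate_against(cm)
    return cm


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    counts.data.to_csv(path, sep="\t", index_label="gene")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"sample": str, "genotype": str, "treatment": str}
    )
    df["replicate"] = df["replicate"].astype(int)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_NONE)


def read_tss_table(path: str | Path) -> TSSTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str, "chrom": str, "strand": str})
    df["tss"] = df["tss"].astype(int)
    return TSSTable(df)


def write_tss_table(table: TSSTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)
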