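"""Domain types shared across the pipeline.

Coordinate convention: every interval in this package is 0-based,
half-open ``[start, end)`` — BED native — for peaks, signal-track steps
and TSS positions alike. Chromosome names are compared by exact string
match (no ``chr`` aliasing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "DAXX_KO", "ATRX_KO")
TREATMENTS = ("DMSO", "etoposide")

__all__ = [
    "GENOTYPES",
    "TREATMENTS",
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "SignalTrack",
    "CountMatrix",
    "SampleSheet",
    "TSSTable",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``strand`` is one of ``{"+", "-", "."}``; peaks are treated as
    unstranded throughout the pipeline, strand is retained only for TSS
    bookkeeping.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def distance_to(self, pos: int) -> int:
        """Distance from the interval (as the continuum [start, end]) to a point.

        Zero when the point falls inside the interval.
        """
        return max(self.start - pos, pos - self.end, 0)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    name: str
    score: float = 0.0
    fdr: float | None = None

    def __post_init__(self) -> None:
        if self.score < 0 or not math.isfinite(self.score):
            raise ValidationError(f"peak {self.name}: score must be finite and >= 0")
        if self.fdr is not None and not (0.0 <= self.fdr <= 1.0):
            raise ValidationError(f"peak {self.name}: fdr must lie in [0, 1]")


class PeakSet:
    """An ordered collection of peaks, sorted by (chrom, start, end).

    Peak names are unique within a set; the set is the universe for all
    overlap statistics downstream.
    """

    def __init__(self, name: str, peaks: Iterable[Peak]):
        self.name = name
        self.peaks = sorted(
            peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
        )
        names = [p.name for p in self.peaks]
        if len(set(names)) != len(names):
            raise ValidationError(f"peak set {name!r}: duplicate peak names")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, PeakSet)
            and self.name == other.name
            and self.peaks == other.peaks
        )

    def chroms(self) -> list[str]:
        return sorted({p.interval.chrom for p in self.peaks})

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.interval.chrom, []).append(p)
        return out


class SignalTrack:
    """Stepwise-constant per-base signal with bedGraph semantics.

    Steps are stored per chromosome as parallel (start, end, value)
    arrays, sorted and non-overlapping; bases not covered by a step have
    value 0 implicitly.
    """

    def __init__(self, steps: Mapping[str, Iterable[tuple[int, int, float]]]):
        self._steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, chunk in steps.items():
            rows = sorted(chunk)
            if not rows:
                continue
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=np.float64)
            if np.any(starts < 0) or np.any(ends <= starts):
                raise ValidationError(f"{chrom}: steps must satisfy 0 <= start < end")
            if not np.all(np.isfinite(values)):
                raise ValidationError(f"{chrom}: step values must be finite")
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"{chrom}: overlapping steps")
            self._steps[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._steps)

    def steps(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, values) arrays for one chromosome (empty if absent)."""
        if chrom not in self._steps:
            empty = np.array([], dtype=np.int64)
            return empty, empty, np.array([], dtype=np.float64)
        return self._steps[chrom]

    def iter_steps(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in self.chroms:
            starts, ends, values = self._steps[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def total_signal(self) -> float:
        """Sum of value * span over all steps."""
        tot = 0.0
        for chrom in self.chroms:
            starts, ends, values = self._steps[chrom]
            tot += float(np.sum((ends - starts) * values))
        return tot

    def covered_span(self) -> int:
        return sum(
            int(np.sum(e - s)) for s, e, _ in (self._steps[c] for c in self.chroms)
        )

    def scaled(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            {
                c: list(zip(s.tolist(), e.tolist(), (v * factor).tolist()))
                for c, (s, e, v) in self._steps.items()
            }
        )

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base values over [start, end); uncovered bases are 0.

        Intended for small windows and for test oracles, not bulk use.
        """
        out = np.zeros(end - start, dtype=np.float64)
        starts, ends, values = self.steps(chrom)
        for s, e, v in zip(starts, ends, values):
            lo, hi = max(int(s), start), min(int(e), end)
            if lo < hi:
                out[lo - start : hi - start] = v
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if self.chroms != other.chroms:
            return False
        for c in self.chroms:
            for a, b in zip(self._steps[c], other._steps[c]):
                if not np.array_equal(a, b):
                    return False
        return True


@dataclass
class CountMatrix:
    """Gene x sample matrix of nonnegative integer counts."""

    data: pd.DataFrame = field()

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            raise ValidationError("duplicate gene ids in count matrix")
        if df.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in count matrix")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("counts must be integers")
            df = df.astype(np.int64)
            self.data = df
            arr = df.to_numpy()
        if (arr < 0).any():
            raise ValidationError("counts must be nonnegative")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountMatrix) and self.data.equals(other.data)


@dataclass
class SampleSheet:
    """Per-sample genotype / treatment / replicate metadata.

    Columns: ``sample``, ``genotype`` in {WT, DAXX_KO, ATRX_KO},
    ``treatment`` in {DMSO, etoposide}, ``replicate`` >= 1.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = {"sample", "genotype", "treatment", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        if df["sample"].duplicated().any():
            raise ValidationError("duplicate sample ids in sample sheet")
        bad_g = set(df["genotype"]) - set(GENOTYPES)
        if bad_g:
            raise ValidationError(f"unknown genotypes: {sorted(bad_g)}")
        bad_t = set(df["treatment"]) - set(TREATMENTS)
        if bad_t:
            raise ValidationError(f"unknown treatments: {sorted(bad_t)}")
        if (df["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate indices must be >= 1")

    def samples_for(self, genotype: str, treatment: str) -> list[str]:
        df = self.data
        sel = df[(df["genotype"] == genotype) & (df["treatment"] == treatment)]
        return list(sel.sort_values("replicate")["sample"])

    def replicates_for(self, genotype: str, treatment: str) -> list[int]:
        df = self.data
        sel = df[(df["genotype"] == genotype) & (df["treatment"] == treatment)]
        return sorted(int(r) for r in sel["replicate"])

    def validate_against(self, counts: CountMatrix) -> None:
        sheet_samples = set(self.data["sample"])
        matrix_samples = set(counts.samples)
        if matrix_samples - sheet_samples:
            raise ValidationError(
                f"samples absent from sheet: {sorted(matrix_samples - sheet_samples)}"
            )
        # every (genotype, treatment) cell present in the sheet needs >= 2 reps
        for (g, t), grp in self.data.groupby(["genotype", "treatment"]):
            if len(grp) < 2:
                raise ValidationError(f"cell ({g}, {t}) has < 2 replicates")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleSheet) and self.data.equals(other.data)


@dataclass
class TSSTable:
    """Transcript start sites: one row per (gene, TSS); a gene may have several."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "chrom", "tss", "strand"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"TSS table missing columns: {sorted(missing)}")
        if (self.data["tss"].astype(int) < 0).any():
            raise ValidationError("TSS positions must be >= 0")

    def by_chrom(self) -> dict[str, pd.DataFrame]:
        return {str(c): g for c, g in self.data.groupby("chrom")}
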