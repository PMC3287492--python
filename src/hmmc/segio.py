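"""Segmented copy-number I/O and breakpoint-union summarization.

Per-sample segment tables (as produced by CBS or any segmentation tool)
rarely share breakpoints across samples.  To compare samples segment by
segment, the breakpoints of all samples are unioned per chromosome and every
sample's profile is summarized onto the resulting common grid, giving a
samples x segments matrix of mean copy numbers.  All downstream modelling
operates on that matrix.

Coordinates are 1-based and inclusive at both ends (SEG convention):
adjacent segments satisfy ``next.start == previous.end + 1``.  Copy numbers
are stored on the linear scale (~2 for diploid); log2-ratio input is
converted on read.  Sex chromosomes are dropped at read time to avoid
gender-driven clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_AUTOSOMES = {str(i) for i in range(1, 23)}
_SEX_CHROMS = {"X", "Y", "XY", "23", "24", "M", "MT", "25"}

REQUIRED_COLUMNS = ("sample", "chromosome", "start", "end", "mean")


class FormatError(ValueError):
    """Raised for malformed segment tables or matrix files."""


def _normalize_chrom(chrom: str) -> str:
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper() if c.upper() in _SEX_CHROMS else c


@dataclass(frozen=True)
class SegmentRecord:
    """One constant-copy-number interval of one sample."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    mean_cn: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"segment start {self.start} > end {self.end} "
                f"({self.sample_id} chr{self.chromosome})"
            )
        if not np.isfinite(self.mean_cn) or self.mean_cn <= 0:
            raise ValueError(f"mean copy number must be positive, got {self.mean_cn}")
        if self.chromosome not in _AUTOSOMES:
            raise ValueError(f"chromosome {self.chromosome!r} is not an autosome label")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True, eq=False)
class SegmentGrid:
    """Common segment grid: ordered (chromosome, start, end) intervals.

    Within a chromosome the intervals tile contiguously between the union
    breakpoints; chromosomes are ordered numerically.
    """

    chromosomes: tuple
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        if len(self.chromosomes) == 0:
            raise ValueError("grid must contain at least one segment")
        object.__setattr__(self, "starts", np.asarray(self.starts, dtype=np.int64))
        object.__setattr__(self, "ends", np.asarray(self.ends, dtype=np.int64))
        if not (len(self.chromosomes) == len(self.starts) == len(self.ends)):
            raise ValueError("grid field lengths differ")

    @property
    def T(self) -> int:
        return len(self.chromosomes)

    @property
    def chain_starts(self) -> np.ndarray:
        """Indices where a new chromosome (hence a new HMM chain) begins."""
        ch = np.asarray(self.chromosomes, dtype=object)
        breaks = np.flatnonzero(ch[1:] != ch[:-1]) + 1
        return np.concatenate(([0], breaks)).astype(np.int64)

    def labels(self) -> list[str]:
        return [
            f"{c}:{s}-{e}"
            for c, s, e in zip(self.chromosomes, self.starts, self.ends)
        ]

    def __eq__(self, other) -> bool:
        if not isinstance(other, SegmentGrid):
            return NotImplemented
        return (
            self.chromosomes == other.chromosomes
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )

    def __hash__(self) -> int:
        return hash((self.chromosomes, self.starts.tobytes(), self.ends.tobytes()))


@dataclass(eq=False)
class CopyNumberMatrix:
    """Samples x segments matrix of mean linear copy numbers."""

    sample_ids: list
    grid: SegmentGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if self.values.shape != (len(self.sample_ids), self.grid.T):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.grid.T} segments"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("all copy numbers must be finite and positive")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def T(self) -> int:
        return self.grid.T

    def subset(self, rows: Sequence[int]) -> "CopyNumberMatrix":
        rows = list(rows)
        return CopyNumberMatrix(
            sample_ids=[self.sample_ids[i] for i in rows],
            grid=self.grid,
            values=self.values[rows],
        )


def read_seg_table(path, dialect: str = "linear") -> list[SegmentRecord]:
    """Parse a tab-delimited segment table into records.

    Expected header columns: sample, chromosome, start, end, mean.
    ``dialect`` declares the scale of the mean column: ``linear`` copy
    number or ``log2`` ratio (converted as ``2 * 2**value``).  Rows on sex
    chromosomes are dropped (count logged); non-positive linear copy
    numbers are rejected with a warning.
    """
    if dialect not in ("linear", "log2"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chromosome": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty segment table: {path}") from exc
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"segment table is missing required column {col!r}")

    records: list[SegmentRecord] = []
    n_sex = 0
    n_bad = 0
    for row in df.itertuples(index=False):
        chrom = _normalize_chrom(row.chromosome)
        if chrom in _SEX_CHROMS:
            n_sex += 1
            continue
        mean = float(row.mean)
        if dialect == "log2":
            mean = 2.0 * 2.0 ** mean
        if mean <= 0 or not np.isfinite(mean):
            n_bad += 1
            log.warning(
                "rejecting segment with non-positive copy number %s "
                "(sample %s, chr%s:%s-%s)",
                mean, row.sample, chrom, row.start, row.end,
            )
            continue
        records.append(
            SegmentRecord(
                sample_id=str(row.sample),
                chromosome=chrom,
                start=int(row.start),
                end=int(row.end),
                mean_cn=mean,
            )
        )
    if n_sex:
        log.info("dropped %d sex-chromosome segments", n_sex)
    if n_bad:
        log.warning("rejected %d segments with non-positive copy number", n_bad)
    return records


def _chrom_sort_key(chrom: str):
    return int(chrom)


def build_union_grid(records: Iterable[SegmentRecord]) -> SegmentGrid:
    """Union all samples' breakpoints into a common segment grid.

    Per chromosome, every distinct start and (end + 1) across all samples
    becomes a cut position; grid segments are the intervals between
    consecutive cuts.
    """
    records = list(records)
    if not records:
        raise ValueError("no segment records supplied")
    cuts_by_chrom: dict[str, set] = {}
    for r in records:
        cuts = cuts_by_chrom.setdefault(r.chromosome, set())
        cuts.add(r.start)
        cuts.add(r.end + 1)

    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for chrom in sorted(cuts_by_chrom, key=_chrom_sort_key):
        cuts = sorted(cuts_by_chrom[chrom])
        for a, b in zip(cuts[:-1], cuts[1:]):
            chroms.append(chrom)
            starts.append(a)
            ends.append(b - 1)
    return SegmentGrid(chromosomes=tuple(chroms), starts=starts, ends=ends)


def summarize_to_matrix(
    records: Iterable[SegmentRecord], grid: SegmentGrid
) -> CopyNumberMatrix:
    """Summarize per-sample segments onto the common grid.

    Each cell is the length-weighted mean of the sample's source segments
    over the grid interval; when a source segment coincides with a grid
    interval the value is copied exactly.  Every sample must cover every
    grid interval completely.
    """
    records = list(records)
    if not records:
        raise ValueError("no segment records supplied")
    sample_ids: list[str] = []
    seen = set()
    for r in records:
        if r.sample_id not in seen:
            seen.add(r.sample_id)
            sample_ids.append(r.sample_id)

    by_sample_chrom: dict[tuple, list[SegmentRecord]] = {}
    for r in records:
        by_sample_chrom.setdefault((r.sample_id, r.chromosome), []).append(r)
    for segs in by_sample_chrom.values():
        segs.sort(key=lambda r: r.start)

    values = np.empty((len(sample_ids), grid.T), dtype=np.float64)
    for j, sid in enumerate(sample_ids):
        for t in range(grid.T):
            chrom = grid.chromosomes[t]
            gs, ge = int(grid.starts[t]), int(grid.ends[t])
            glen = ge - gs + 1
            wsum = 0.0
            vsum = 0.0
            for r in by_sample_chrom.get((sid, chrom), ()):
                ov = min(r.end, ge) - max(r.start, gs) + 1
                if ov > 0:
                    wsum += ov
                    vsum += ov * r.mean_cn
            if wsum < glen:
                raise ValueError(
                    f"sample {sid!r} does not cover grid interval "
                    f"{chrom}:{gs}-{ge}"
                )
            values[j, t] = vsum / wsum
    return CopyNumberMatrix(sample_ids=sample_ids, grid=grid, values=values)


def write_matrix(m: CopyNumberMatrix, path) -> None:
    """Write the matrix as TSV: first column sample_id, header chrom:start-end."""
    df = pd.DataFrame(m.values, index=m.sample_ids, columns=m.grid.labels())
    df.to_csv(path, sep="\t", index_label="sample_id", float_format="%.6g")


def read_matrix(path) -> CopyNumberMatrix:
    """Read a matrix TSV written by :func:`write_matrix`."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty matrix file: {path}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"matrix file has no data: {path}")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for col in df.columns:
        try:
            chrom, span = str(col).split(":")
            s, e = span.split("-")
            chroms.append(chrom)
            starts.append(int(s))
            ends.append(int(e))
        except ValueError as exc:
            raise FormatError(f"malformed segment header {col!r}") from exc
    grid = SegmentGrid(chromosomes=tuple(chroms), starts=starts, ends=ends)
    vals = df.to_numpy(dtype=np.float64)
    if vals.shape != (len(df.index), grid.T):
        raise FormatError("matrix shape does not match header")
    return CopyNumberMatrix(
        sample_ids=[str(s) for s in df.index], grid=grid, values=vals
    )
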