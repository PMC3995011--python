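"""Genomic intervals and BED I/O.

All in-memory and TSV coordinates in this package are GRCh37, 1-based,
fully inclusive. BED files on disk keep their native 0-based half-open
convention; the conversion happens here and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd


class AssemblyMismatchError(ValueError):
    """BED header declares a different assembly than the one expected."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval [start, end], 1-based, on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_position(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def read_bed(path: str | Path, expected_assembly: str | None = None) -> pd.DataFrame:
    """Read a BED (3+name) file into a 1-based inclusive DataFrame.

    Header lines starting with '#' are scanned for an ``#assembly=<tag>``
    declaration; if ``expected_assembly`` is given and the file declares a
    different one, :class:`AssemblyMismatchError` is raised.

    Returns a DataFrame with columns chrom, start, end, name (start/end
    1-based inclusive) and a ``df.attrs['assembly']`` entry.
    """
    path = Path(path)
    assembly = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if stripped.lower().startswith("assembly="):
                    assembly = stripped.split("=", 1)[1].strip()
                continue
            if line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed BED line in {path}: {line!r}")
            name = fields[3] if len(fields) > 3 else ""
            # BED is 0-based half-open; convert to 1-based inclusive.
            rows.append((fields[0], int(fields[1]) + 1, int(fields[2]), name))
    if expected_assembly is not None and assembly is not None:
        if assembly != expected_assembly:
            raise AssemblyMismatchError(
                f"{path} declares assembly {assembly!r}, expected {expected_assembly!r}"
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    df.attrs["assembly"] = assembly
    return df


def write_bed(
    intervals: Iterable[tuple[str, GenomicInterval]],
    path: str | Path,
    assembly: str | None = None,
) -> None:
    """Write (name, interval) pairs as BED, converting back to 0-based half-open."""
    path = Path(path)
    with open(path, "w") as fh:
        if assembly:
            fh.write(f"#assembly={assembly}\n")
        for name, iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\n")


def bed_to_intervals(df: pd.DataFrame) -> list[tuple[str, GenomicInterval]]:
    """Turn a read_bed DataFrame into (name, GenomicInterval) pairs."""
    return [
        (str(name), GenomicInterval(chrom, int(start), int(end)))
        for chrom, start, end, name in df[["chrom", "start", "end", "name"]].itertuples(
            index=False
        )
    ]
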