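"""PC / AS / IR isoform quantification from junction counts and coverage.

The locus model mirrors the worm SAM-synthetase *sams-3* situation: a
canonical intron whose 3' splice site can be methylated, an alternative
intron using an upstream cryptic acceptor (sharing the donor), and an
intron-retained variant.  Abundances are estimated as

* PC  — spliced reads whose junction equals the canonical intron,
* AS  — spliced reads whose junction equals the alternative intron,
* IR  — mean per-base coverage over the canonical intron trimmed by
  ``trim`` nucleotides on both sides (default 10), which avoids edge
  artifacts at the splice junctions,

all normalized to reads per million (rpm) with an explicitly supplied
library size (junction tables undercount the library, so the library
size is never inferred from them).

Junction coordinates are 1-based inclusive, matching the spliced-aligner
junction-table dialect; bedGraph coverage input is 0-based half-open and
converted at this module's boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .genome import one_based_to_bed


class JunctionTableError(ValueError):
    """Malformed junction table line."""


@dataclass(frozen=True)
class JunctionRecord:
    """One splice junction: intron interval (1-based inclusive) + unique count."""

    contig: str
    intron_start: int
    intron_end: int
    strand_code: int  # 0 undefined, 1 '+', 2 '-'
    count: float

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise JunctionTableError(
                f"junction {self.contig}:{self.intron_start}-{self.intron_end} inverted"
            )
        if self.count < 0:
            raise JunctionTableError("negative junction count")


def read_junction_table(path: str | Path) -> list[JunctionRecord]:
    """Parse a spliced-aligner junction table (>= 7 tab-separated columns:
    contig, start, end, strand code, motif code, annotated flag, unique
    count).  Columns beyond 7 are ignored.  Coordinate or count fields
    that are not integers raise :class:`JunctionTableError` naming the line.
    """
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise JunctionTableError(
                    f"{path}:{lineno}: expected >= 7 columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                strand_code = int(fields[3])
                count = int(fields[6])
            except ValueError as exc:
                raise JunctionTableError(f"{path}:{lineno}: {exc}") from exc
            records.append(
                JunctionRecord(
                    contig=fields[0],
                    intron_start=start,
                    intron_end=end,
                    strand_code=strand_code,
                    count=count,
                )
            )
    return records


@dataclass
class CoverageTrack:
    """Per-base read depth as a per-contig step function.

    Stored internally as parallel numpy arrays of 0-based half-open
    intervals with non-negative depth, sorted and non-overlapping.
    """

    intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )  # contig -> (starts0, ends0, depths)

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "CoverageTrack":
        per_contig: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                fields = line.split()
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
                contig, start, end, depth = (
                    fields[0], int(fields[1]), int(fields[2]), float(fields[3]),
                )
                if depth < 0:
                    raise ValueError(f"{path}:{lineno}: negative depth")
                per_contig.setdefault(contig, []).append((start, end, depth))
        track = cls()
        for contig, rows in per_contig.items():
            rows.sort()
            for (s1, e1, _), (s2, _, _) in zip(rows, rows[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping bedGraph intervals on {contig}")
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            depths = np.array([r[2] for r in rows], dtype=float)
            track.intervals[contig] = (starts, ends, depths)
        return track

    def depth_array(self, contig: str, start: int, end: int) -> np.ndarray:
        """Per-base depth over the 1-based inclusive interval [start, end]."""
        if start > end:
            raise ValueError("empty interval")
        length = end - start + 1
        out = np.zeros(length, dtype=float)
        if contig not in self.intervals:
            return out
        starts0, ends0, depths = self.intervals[contig]
        q_start0, q_end0 = one_based_to_bed(start, end)
        lo = np.clip(starts0, q_start0, q_end0)
        hi = np.clip(ends0, q_start0, q_end0)
        for s, e, d in zip(lo, hi, depths):
            if e > s:
                out[s - q_start0 : e - q_start0] = d
        return out

    def mean_depth(self, contig: str, start: int, end: int) -> float:
        return float(self.depth_array(contig, start, end).mean())

    def to_bedgraph(self) -> str:
        lines = []
        for contig in sorted(self.intervals):
            starts0, ends0, depths = self.intervals[contig]
            for s, e, d in zip(starts0, ends0, depths):
                val = int(d) if float(d).is_integer() else d
                lines.append(f"{contig}\t{s}\t{e}\t{val}")
        return "\n".join(lines) + ("\n" if lines else "")


@dataclass(frozen=True)
class LocusDefinition:
    """A splicing locus with canonical and alternative introns.

    The alternative intron shares the donor with (or is nested within)
    the canonical intron; ``trim`` nucleotides are removed from each end
    of the canonical intron before averaging coverage for the IR
    estimate; ``pc_amplicon_len`` optionally records the fully spliced
    RT-PCR product length for amplicon arithmetic.
    """

    locus_id: str
    contig: str
    canonical_intron: tuple[int, int]
    alternative_intron: tuple[int, int]
    trim: int = 10
    pc_amplicon_len: int | None = None

    def __post_init__(self) -> None:
        cs, ce = self.canonical_intron
        als, ale = self.alternative_intron
        if not (cs <= als and ale <= ce):
            raise ValueError(
                "alternative intron must be nested within (or share the donor "
                "of) the canonical intron"
            )
        if 2 * self.trim >= ce - cs + 1:
            raise ValueError("trim*2 must be smaller than the canonical intron")


@dataclass(frozen=True)
class IsoformQuant:
    """rpm-normalized isoform abundances for one locus in one sample."""

    pc_rpm: float
    as_rpm: float
    ir_rpm: float
    library_size: int
    near_miss_counts: float = 0.0  # junctions within +-1 of either intron end

    def __post_init__(self) -> None:
        if min(self.pc_rpm, self.as_rpm, self.ir_rpm) < 0:
            raise ValueError("rpm values must be non-negative")


def intron_length(start: int, end: int) -> int:
    """Length of a 1-based inclusive interval: ``end - start + 1``."""
    if start > end:
        raise ValueError("start must be <= end")
    return end - start + 1


def rpm(count: float, library_size: float) -> float:
    """Reads per million: ``count * 1e6 / library_size``."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return count * 1e6 / library_size


def amplicon_length(base_product_len: int, retained_len: int) -> int:
    """RT-PCR product length when ``retained_len`` intronic nucleotides stay
    in the transcript: base (fully spliced) product plus retained length.
    """
    if base_product_len < 0 or retained_len < 0:
        raise ValueError("lengths must be non-negative")
    return base_product_len + retained_len


def quantify_isoforms(
    junctions: Iterable[JunctionRecord],
    coverage: CoverageTrack,
    locus: LocusDefinition,
    library_size: int,
) -> IsoformQuant:
    """Quantify PC/AS/IR abundances (rpm) for one locus in one sample.

    Junction matching requires exact equality of both intron ends;
    junctions matching either intron within +-1 nt (but not exactly) are
    tallied into ``near_miss_counts`` as a QC signal for coordinate-
    dialect problems.  An absent junction yields 0.
    """
    pc_count = 0.0
    as_count = 0.0
    near_miss = 0.0
    for rec in junctions:
        if rec.contig != locus.contig:
            continue
        key = (rec.intron_start, rec.intron_end)
        if key == locus.canonical_intron:
            pc_count += rec.count
        elif key == locus.alternative_intron:
            as_count += rec.count
        else:
            for target in (locus.canonical_intron, locus.alternative_intron):
                if (
                    abs(rec.intron_start - target[0]) <= 1
                    and abs(rec.intron_end - target[1]) <= 1
                ):
                    near_miss += rec.count
                    break
    cs, ce = locus.canonical_intron
    trim_start, trim_end = cs + locus.trim, ce - locus.trim
    if trim_start > trim_end:
        raise ValueError("trimmed IR interval is empty")
    ir_mean_depth = coverage.mean_depth(locus.contig, trim_start, trim_end)
    return IsoformQuant(
        pc_rpm=rpm(pc_count, library_size),
        as_rpm=rpm(as_count, library_size),
        ir_rpm=rpm(ir_mean_depth, library_size),
        library_size=library_size,
        near_miss_counts=near_miss,
    )
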