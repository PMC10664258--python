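"""Genomic containers and readers/writers for the formats the toolkit touches.

Coordinates are 0-based half-open (BED convention) everywhere internally;
1-based coordinates appear only in log messages. A *fragment* is the full
template span of one properly paired read template (both mates), counted
once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .errors import LayoutMismatchError, ParseError, ValidationError

logger = logging.getLogger(__name__)

#: chromosome names treated as mitochondrial and excluded at ingestion
MITO_NAMES = frozenset({"chrM", "MT", "chrMT", "M"})

#: SAM flag bits excluded when reading alignments (unmapped, secondary,
#: QC-fail, duplicate, supplementary) -- the standard samtools
#: ``-F 4 -F 256 -F 512 -F 1024 -F 2048`` filter set.
EXCLUDE_FLAGS = 0x4 | 0x100 | 0x200 | 0x400 | 0x800

DEFAULT_MIN_MAPQ = 30


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered reference coordinate system for all genome-wide vectors."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise ValidationError("genome layout has no chromosomes")
        if len(self.names) != len(set(self.names)):
            raise ValidationError("duplicate chromosome names in layout")
        if len(self.names) != len(self.lengths):
            raise ValidationError("names and lengths differ in length")
        for name, length in zip(self.names, self.lengths):
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def n_chromosomes(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"chromosome {name!r} not in layout") from None

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def length_of(self, name: str) -> int:
        return self.lengths[self.index(name)]


@dataclass(frozen=True)
class Fragment:
    """One sequenced template: the span from leftmost to rightmost mate end."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"invalid fragment interval {self.chrom}:{self.start}-{self.end}"
            )


class FragmentSet:
    """A sample's filtered fragments, stored as parallel numpy arrays.

    ``chrom_idx`` indexes into ``layout.names``; ``start``/``end`` are
    0-based half-open base-pair coordinates.
    """

    def __init__(
        self,
        layout: GenomeLayout,
        chrom_idx: np.ndarray,
        start: np.ndarray,
        end: np.ndarray,
        *,
        validate: bool = True,
    ) -> None:
        self.layout = layout
        self.chrom_idx = np.asarray(chrom_idx, dtype=np.int32)
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        if not (len(self.chrom_idx) == len(self.start) == len(self.end)):
            raise ValidationError("fragment arrays differ in length")
        if validate and len(self.start) > 0:
            if np.any(self.start < 0) or np.any(self.start >= self.end):
                raise ValidationError("fragment with start < 0 or start >= end")
            lengths = np.asarray(layout.lengths, dtype=np.int64)
            if np.any(self.chrom_idx < 0) or np.any(self.chrom_idx >= layout.n_chromosomes):
                raise ValidationError("fragment chromosome index out of range")
            if np.any(self.end > lengths[self.chrom_idx]):
                raise ValidationError("fragment extends past chromosome end")

    @property
    def library_size(self) -> int:
        return len(self.start)

    def __len__(self) -> int:
        return len(self.start)

    @classmethod
    def from_fragments(cls, layout: GenomeLayout, fragments: Iterable[Fragment]) -> "FragmentSet":
        frags = list(fragments)
        chrom_idx = np.fromiter((layout.index(f.chrom) for f in frags), dtype=np.int32, count=len(frags))
        start = np.fromiter((f.start for f in frags), dtype=np.int64, count=len(frags))
        end = np.fromiter((f.end for f in frags), dtype=np.int64, count=len(frags))
        return cls(layout, chrom_idx, start, end)

    def iter_fragments(self) -> Iterator[Fragment]:
        names = self.layout.names
        for c, s, e in zip(self.chrom_idx, self.start, self.end):
            yield Fragment(names[c], int(s), int(e))

    def sorted(self) -> "FragmentSet":
        order = np.lexsort((self.end, self.start, self.chrom_idx))
        return FragmentSet(
            self.layout, self.chrom_idx[order], self.start[order], self.end[order], validate=False
        )

    def subset(self, mask_or_index: np.ndarray) -> "FragmentSet":
        return FragmentSet(
            self.layout,
            self.chrom_idx[mask_or_index],
            self.start[mask_or_index],
            self.end[mask_or_index],
            validate=False,
        )


@dataclass(frozen=True)
class Peak:
    """A significant-enrichment interval, as called upstream (e.g. MACS2)."""

    chrom: str
    start: int
    end: int
    score: float | None = None
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"peak {self.chrom}:{self.start}-{self.end} has start >= end")


class PeakSet:
    """Peaks sorted by (chromosome order, start), stored as arrays."""

    def __init__(
        self,
        layout: GenomeLayout,
        chrom_idx: np.ndarray,
        start: np.ndarray,
        end: np.ndarray,
        score: np.ndarray | None = None,
        summit_offset: np.ndarray | None = None,
    ) -> None:
        self.layout = layout
        chrom_idx = np.asarray(chrom_idx, dtype=np.int32)
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        if len(start) and (np.any(start >= end) or np.any(start < 0)):
            raise ValidationError("peak with start >= end or negative start")
        if len(start):
            lengths = np.asarray(layout.lengths, dtype=np.int64)
            if np.any(end > lengths[chrom_idx]):
                raise ValidationError("peak extends past chromosome end")
        order = np.lexsort((start, chrom_idx))
        self.chrom_idx = chrom_idx[order]
        self.start = start[order]
        self.end = end[order]
        self.score = None if score is None else np.asarray(score, dtype=float)[order]
        self.summit_offset = (
            None if summit_offset is None else np.asarray(summit_offset, dtype=np.int64)[order]
        )

    def __len__(self) -> int:
        return len(self.start)

    def __getitem__(self, i: int) -> Peak:
        return Peak(
            self.layout.names[self.chrom_idx[i]],
            int(self.start[i]),
            int(self.end[i]),
            None if self.score is None else float(self.score[i]),
            None if self.summit_offset is None else int(self.summit_offset[i]),
        )

    def __iter__(self) -> Iterator[Peak]:
        return (self[i] for i in range(len(self)))

    @classmethod
    def from_peaks(cls, layout: GenomeLayout, peaks: Sequence[Peak]) -> "PeakSet":
        chrom_idx = np.array([layout.index(p.chrom) for p in peaks], dtype=np.int32)
        start = np.array([p.start for p in peaks], dtype=np.int64)
        end = np.array([p.end for p in peaks], dtype=np.int64)
        score = None
        if any(p.score is not None for p in peaks):
            score = np.array([np.nan if p.score is None else p.score for p in peaks])
        summit = None
        if any(p.summit_offset is not None for p in peaks):
            summit = np.array(
                [-1 if p.summit_offset is None else p.summit_offset for p in peaks],
                dtype=np.int64,
            )
        return cls(layout, chrom_idx, start, end, score, summit)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Parse a two-column ``name<TAB>length`` chromosome-sizes file.

    File order is preserved and becomes the canonical genome order.
    """
    names: list[str] = []
    lengths: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected two columns, got {line!r}")
            try:
                length = int(parts[1])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: length {parts[1]!r} is not an integer"
                ) from None
            if parts[0] in names:
                raise ValidationError(f"{path}: line {lineno}: duplicate chromosome {parts[0]!r}")
            names.append(parts[0])
            lengths.append(length)
    if not names:
        raise ParseError(f"{path}: no chromosomes found")
    return GenomeLayout(tuple(names), tuple(lengths))


def read_fragments_bed(path: str | Path, layout: GenomeLayout, *, strict: bool = True) -> FragmentSet:
    """Read fragments from BED3 (or the first three columns of BEDPE-like rows).

    In lenient mode records on chromosomes outside the layout are dropped
    and counted in the log; in strict mode they raise.
    """
    chrom_idx: list[int] = []
    starts: list[int] = []
    ends: list[int] = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom, s, e = parts[0], int(parts[1]), int(parts[2])
            if s >= e or s < 0:
                raise ParseError(f"{path}: line {lineno}: invalid interval {s}-{e}")
            if chrom not in layout:
                if strict:
                    raise ValidationError(
                        f"{path}: line {lineno}: chromosome {chrom!r} not in layout"
                    )
                n_dropped += 1
                continue
            ci = layout.index(chrom)
            if e > layout.lengths[ci]:
                if strict:
                    raise ValidationError(
                        f"{path}: line {lineno}: fragment past end of {chrom}"
                    )
                n_dropped += 1
                continue
            chrom_idx.append(ci)
            starts.append(s)
            ends.append(e)
    if n_dropped:
        logger.info("read_fragments_bed: dropped %d record(s) outside layout", n_dropped)
    return FragmentSet(
        layout,
        np.array(chrom_idx, dtype=np.int32),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
    )


def read_fragments_alignment(
    path: str | Path,
    layout: GenomeLayout,
    *,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    exclude_flags: int = EXCLUDE_FLAGS,
    exclude_chroms: frozenset[str] | set[str] = MITO_NAMES,
) -> tuple[FragmentSet, dict[str, int]]:
    """Read one fragment per properly paired template from SAM/BAM.

    A pair survives only if *both* mates pass the flag, mapping-quality and
    chromosome filters; the fragment is the template span from the leftmost
    mate start to the rightmost mate end. Returns the fragment set and a
    dict counting excluded records by reason (each excluded alignment is
    attributed to exactly one reason, checked in flag-bit order).
    """
    reasons = {
        "unmapped": 0,
        "secondary": 0,
        "qc_fail": 0,
        "duplicate": 0,
        "supplementary": 0,
        "low_mapq": 0,
        "excluded_chrom": 0,
        "not_in_layout": 0,
        "unpaired": 0,
        "orphan": 0,
    }
    # first mate seen per template, keyed by query name
    pending: dict[str, tuple[str, int, int]] = {}
    chrom_idx: list[int] = []
    starts: list[int] = []
    ends: list[int] = []

    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            for read in af.fetch(until_eof=True):
                flag = read.flag
                if flag & exclude_flags:
                    if flag & 0x4:
                        reasons["unmapped"] += 1
                    elif flag & 0x100:
                        reasons["secondary"] += 1
                    elif flag & 0x200:
                        reasons["qc_fail"] += 1
                    elif flag & 0x400:
                        reasons["duplicate"] += 1
                    else:
                        reasons["supplementary"] += 1
                    continue
                if not read.is_paired:
                    reasons["unpaired"] += 1
                    continue
                if read.mapping_quality < min_mapq:
                    reasons["low_mapq"] += 1
                    pending.pop(read.query_name, None)
                    continue
                chrom = read.reference_name
                if chrom in exclude_chroms:
                    reasons["excluded_chrom"] += 1
                    continue
                if chrom not in layout:
                    reasons["not_in_layout"] += 1
                    continue
                mate = pending.pop(read.query_name, None)
                if mate is None:
                    pending[read.query_name] = (
                        chrom,
                        read.reference_start,
                        read.reference_end,
                    )
                    continue
                mchrom, mstart, mend = mate
                if mchrom != chrom:
                    reasons["orphan"] += 2
                    continue
                ci = layout.index(chrom)
                s = min(mstart, read.reference_start)
                e = min(max(mend, read.reference_end), layout.lengths[ci])
                chrom_idx.append(ci)
                starts.append(s)
                ends.append(e)
    finally:
        pysam.set_verbosity(save)

    reasons["orphan"] += len(pending)
    excluded = {k: v for k, v in reasons.items() if v}
    if excluded:
        logger.info("read_fragments_alignment: excluded %s", excluded)
    frags = FragmentSet(
        layout,
        np.array(chrom_idx, dtype=np.int32),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
    )
    return frags, reasons


def read_peaks_narrowpeak(path: str | Path, layout: GenomeLayout, *, strict: bool = True) -> PeakSet:
    """Read ENCODE narrowPeak (BED6+4) or plain BED peaks; output is sorted.

    The summit offset is taken from column 10 when present (and >= 0);
    plain BED3 yields peaks without scores or summits.
    """
    chrom_idx: list[int] = []
    starts: list[int] = []
    ends: list[int] = []
    scores: list[float] = []
    summits: list[int] = []
    have_score = have_summit = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom, s, e = parts[0], int(parts[1]), int(parts[2])
            if s >= e:
                raise ParseError(f"{path}: line {lineno}: start >= end")
            if chrom not in layout:
                if strict:
                    raise ValidationError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
                continue
            ci = layout.index(chrom)
            if e > layout.lengths[ci]:
                if strict:
                    raise ValidationError(f"{path}: line {lineno}: peak past end of {chrom}")
                continue
            chrom_idx.append(ci)
            starts.append(s)
            ends.append(e)
            if len(parts) >= 5:
                have_score = True
                scores.append(float(parts[4]))
            else:
                scores.append(np.nan)
            if len(parts) >= 10 and int(parts[9]) >= 0:
                have_summit = True
                summits.append(int(parts[9]))
            else:
                summits.append(-1)
    return PeakSet(
        layout,
        np.array(chrom_idx, dtype=np.int32),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        np.array(scores) if have_score else None,
        np.array(summits, dtype=np.int64) if have_summit else None,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_fragments_bed(frags: FragmentSet, path: str | Path) -> None:
    """Write sorted BED3; round-trips losslessly through read_fragments_bed."""
    s = frags.sorted()
    names = frags.layout.names
    with open(path, "w") as fh:
        for c, a, b in zip(s.chrom_idx, s.start, s.end):
            fh.write(f"{names[c]}\t{a}\t{b}\n")


def write_signal_bedgraph(track, path: str | Path) -> None:
    """Write one bedGraph record per bin with the integer WFpkm value."""
    grid = track.grid
    names = grid.layout.names
    with open(path, "w") as fh:
        for c, s, e, v in zip(grid.bin_chrom_idx, grid.bin_start, grid.bin_end, track.wfpkm):
            fh.write(f"{names[c]}\t{s}\t{e}\t{v}\n")


def read_signal_bedgraph(path: str | Path, grid) -> np.ndarray:
    """Read back a bedGraph written by :func:`write_signal_bedgraph`.

    Records must match the grid's bins one-to-one, in order.
    """
    values = np.zeros(grid.n_bins, dtype=np.int64)
    names = grid.layout.names
    with open(path) as fh:
        i = 0
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            chrom, s, e, v = line.split()
            if i >= grid.n_bins:
                raise ParseError(f"{path}: line {lineno}: more records than grid bins")
            if (
                chrom != names[grid.bin_chrom_idx[i]]
                or int(s) != grid.bin_start[i]
                or int(e) != grid.bin_end[i]
            ):
                raise ParseError(f"{path}: line {lineno}: record does not match grid bin {i}")
            values[i] = int(float(v))
            i += 1
    if i != grid.n_bins:
        raise ParseError(f"{path}: expected {grid.n_bins} records, found {i}")
    return values


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(layout.names, layout.lengths):
            fh.write(f"{name}\t{length}\n")


def write_peaks_narrowpeak(peaks: PeakSet, path: str | Path) -> None:
    """Write peaks as narrowPeak (BED6+4); missing scores/summits become -1/0."""
    names = peaks.layout.names
    with open(path, "w") as fh:
        for i in range(len(peaks)):
            chrom = names[peaks.chrom_idx[i]]
            s, e = peaks.start[i], peaks.end[i]
            score = 0.0
            if peaks.score is not None and not np.isnan(peaks.score[i]):
                score = peaks.score[i]
            summit = -1
            if peaks.summit_offset is not None:
                summit = int(peaks.summit_offset[i])
            fh.write(
                f"{chrom}\t{s}\t{e}\tpeak_{i}\t{int(score)}\t.\t{score:.4f}\t-1\t-1\t{summit}\n"
            )
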