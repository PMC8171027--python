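"""Readers and writers for the genomic file formats the pipeline touches.

Coordinate convention: 0-based, half-open ``[start, end)`` everywhere, which
is the native convention of BED and bedGraph; nothing is shifted on input.
Strand is ignored throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical mark order: the ten histone modifications followed by DNase I
#: sensitivity.  Every per-mark feature block uses this order.
MARKS = (
    "H3K4me1", "H3K4me2", "H3K4me3", "H3K9ac", "H3K9me3",
    "H4K20me1", "H3K27ac", "H3K27me3", "H3K36me3", "H3K79me2",
    "DNase",
)

_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


@dataclass
class Genome:
    """A reference genome as a map chromosome name -> uppercase A/C/G/T/N string."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name in self.sequences:
            if not name:
                raise FormatError("empty chromosome name")

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])


@dataclass(frozen=True)
class GenomicLocus:
    """One variant position.

    ``label`` is 1 (positive: the locus affects gene regulation), 0 (negative)
    or ``None`` (unlabeled).  ``pos`` is the 0-based index of the variant base.
    """

    chrom: str
    pos: int
    label: Optional[int]
    cell_line: str = ""

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos} on {self.chrom}")
        if self.label not in (0, 1, None):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")

    @property
    def label_token(self) -> str:
        return "." if self.label is None else str(self.label)


@dataclass
class EpigeneticTrack:
    """A named epigenetic mark as non-overlapping scored intervals per chromosome.

    ``intervals[chrom]`` is a tuple of numpy arrays ``(starts, ends, scores)``
    sorted by start, pairwise disjoint, with ``scores >= 0``.  Overlaps in the
    source file are resolved at load time by taking the per-base maximum.
    """

    mark_name: str
    intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    def chroms(self) -> Iterable[str]:
        return self.intervals.keys()

    def n_intervals(self) -> int:
        return sum(len(s) for s, _, _ in self.intervals.values())

    def profile(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base signal over ``[start, end)``; zero outside every interval."""
        out = np.zeros(end - start, dtype=float)
        if chrom not in self.intervals:
            return out
        starts, ends, scores = self.intervals[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], scores[lo:hi]):
            out[max(s, start) - start: min(e, end) - start] = v
        return out

    def covers(self, chrom: str, pos: int) -> bool:
        """True iff ``pos`` lies inside some interval (half-open)."""
        if chrom not in self.intervals:
            return False
        starts, ends, _ = self.intervals[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        return i >= 0 and pos < ends[i]


def merge_intervals(
    raw: Iterable[tuple[int, int, float]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve overlapping scored intervals into a disjoint per-base-maximum set.

    Sweep over the union of interval boundaries; each elementary segment takes
    the maximum score of the intervals covering it, then equal-score adjacent
    segments are coalesced.  Equivalent to a dense per-base max (the test-suite
    oracle) but independent of coordinate magnitude.
    """
    items = sorted(raw)
    if not items:
        empty = np.empty(0)
        return empty.astype(np.int64), empty.astype(np.int64), empty.astype(float)
    bounds = np.unique([b for s, e, _ in items for b in (s, e)])
    seg_max = np.full(len(bounds) - 1, -np.inf)
    for s, e, v in items:
        i, j = np.searchsorted(bounds, (s, e))
        seg_max[i:j] = np.maximum(seg_max[i:j], v)
    starts, ends, scores = [], [], []
    for i, v in enumerate(seg_max):
        if v == -np.inf:
            continue
        if scores and scores[-1] == v and ends[-1] == bounds[i]:
            ends[-1] = bounds[i + 1]  # coalesce equal-score neighbours
        else:
            starts.append(bounds[i])
            ends.append(bounds[i + 1])
            scores.append(v)
    return (
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
        np.asarray(scores, dtype=float),
    )


def read_genome(path: str | Path) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Sequences are uppercased; characters outside A/C/G/T/N are mapped to N
    with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            logger.warning(
                "chromosome %s: %d characters outside {A,C,G,T,N} mapped to N",
                record.id, sum(seq.count(c) for c in bad),
            )
            seq = "".join(c if c in _VALID_BASES else "N" for c in seq)
        if record.id in sequences:
            raise FormatError(f"duplicate chromosome name {record.id!r}")
        sequences[record.id] = seq
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    return Genome(sequences)


def write_genome(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_track(path: str | Path, mark_name: str) -> EpigeneticTrack:
    """Read a BED (>=3 columns, score optional, default 1.0) or bedGraph file.

    BED detection is positional: a 4th column that parses as a float is taken
    as the score (this covers bedGraph; BED name columns that are numeric are
    indistinguishable and treated as scores).  Overlapping intervals are merged
    keeping the per-base maximum score.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            score = 1.0
            if len(cols) >= 4:
                try:
                    score = float(cols[3])
                except ValueError:
                    score = 1.0  # BED name column; keep default score
            if score < 0:
                raise FormatError(f"{path}:{lineno}: negative score {score}")
            per_chrom.setdefault(chrom, []).append((start, end, score))
    track = EpigeneticTrack(mark_name=mark_name)
    for chrom, items in per_chrom.items():
        track.intervals[chrom] = merge_intervals(items)
    return track


def read_bigwig(path: str | Path, mark_name: str) -> EpigeneticTrack:
    """Adapter reading a bigWig file into the same :class:`EpigeneticTrack` contract."""
    import pyBigWig  # optional dependency, imported lazily

    bw = pyBigWig.open(str(path))
    track = EpigeneticTrack(mark_name=mark_name)
    try:
        for chrom in bw.chroms():
            ivals = bw.intervals(chrom)
            if ivals:
                track.intervals[chrom] = merge_intervals(
                    (s, e, max(v, 0.0)) for s, e, v in ivals
                )
    finally:
        bw.close()
    return track


def write_track(track: EpigeneticTrack, path: str | Path) -> None:
    """Write a track as 4-column bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(track.intervals):
            starts, ends, scores = track.intervals[chrom]
            for s, e, v in zip(starts, ends, scores):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


_LOCI_COLUMNS = ("chrom", "pos", "label", "cell_line")


def read_loci(path: str | Path, one_based: bool = False) -> list[GenomicLocus]:
    """Read a variant-locus TSV with columns chrom, pos, label, cell_line.

    The label column takes values ``1``, ``0`` or ``.`` (unlabeled).  With
    ``one_based=True`` positions are shifted down by one on input, for tables
    that follow the 1-based convention of VCF-style coordinates.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _LOCI_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    loci: list[GenomicLocus] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        token = str(row.label)
        if token == ".":
            label: Optional[int] = None
        elif token in ("0", "1"):
            label = int(token)
        else:
            raise FormatError(f"{path}: line {i}: unknown label token {token!r}")
        try:
            pos = int(row.pos)
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: non-integer pos {row.pos!r}") from exc
        loci.append(GenomicLocus(row.chrom, pos - one_based, label, row.cell_line))
    counts = (
        pd.DataFrame(
            [(l.cell_line, l.label_token) for l in loci],
            columns=["cell_line", "label"],
        )
        .value_counts()
        .sort_index()
    )
    for (cell, label), n in counts.items():
        logger.info("loci %s: cell_line=%s label=%s n=%d", path, cell, label, n)
    return loci


def write_loci(loci: Iterable[GenomicLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_LOCI_COLUMNS) + "\n")
        for l in loci:
            fh.write(f"{l.chrom}\t{l.pos}\t{l.label_token}\t{l.cell_line}\n")
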