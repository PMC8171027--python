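"""Feature construction: the model input for one locus.

Each locus contributes a 150 x 4 one-hot sequence map (window centred on the
variant) plus a 43-long tabular vector: Peak/Max/Sum window summaries for the
ten histone marks and DNase (33 values, in canonical mark order) followed by
ten nucleotide-composition features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from sslvar.genomic_io import Genome, GenomicLocus, EpigeneticTrack, MARKS

logger = logging.getLogger(__name__)

WINDOW = 150
#: Column order of the one-hot matrix.
BASE_ORDER = "ATCG"
_BASE_ROW = {b: i for i, b in enumerate(BASE_ORDER)}

COMPOSITION_NAMES = (
    "a_count", "t_count", "g_count", "c_count",
    "gc_dinuc_count", "gt_dinuc_count", "ga_dinuc_count",
    "at_skew", "gc_skew", "skew_ratio",
)

#: The 43 tabular column names: [peak, max, sum] per mark, then composition.
TABULAR_COLUMNS: tuple[str, ...] = tuple(
    f"{mark}_{score}" for mark in MARKS for score in ("peak", "max", "sum")
) + COMPOSITION_NAMES

#: Max and Sum columns get a log1p transform before standardization.
LOG_COLUMNS = frozenset(c for c in TABULAR_COLUMNS if c.endswith(("_max", "_sum")))


class BoundaryError(ValueError):
    """Window does not fit inside its chromosome."""


@dataclass(frozen=True)
class SequenceWindow:
    """A 150-bp window around a locus: ``[pos - 75, pos + 75)``, variant at row 75."""

    locus: GenomicLocus
    start: int
    end: int
    seq: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.seq):
            raise ValueError("window coordinates inconsistent with sequence length")

    @property
    def onehot(self) -> np.ndarray:
        return one_hot(self.seq)


def extract_window(genome: Genome, locus: GenomicLocus, width: int = WINDOW) -> SequenceWindow:
    """Extract the ``width``-bp sequence window centred on the locus.

    With even ``width`` the window is ``[pos - width//2, pos + width//2)``, so
    the variant base sits at offset ``width//2`` (row 75 for the default).
    """
    if locus.chrom not in genome:
        raise KeyError(f"chromosome {locus.chrom!r} not in genome")
    half = width // 2
    start, end = locus.pos - half, locus.pos + (width - half)
    chrom_len = genome.length(locus.chrom)
    if start < 0 or end > chrom_len:
        raise BoundaryError(
            f"window [{start},{end}) for locus {locus.chrom}:{locus.pos} "
            f"exceeds chromosome bounds [0,{chrom_len})"
        )
    return SequenceWindow(locus, start, end, genome[locus.chrom][start:end])


def one_hot(seq: str) -> np.ndarray:
    """One-hot encode a nucleotide string, rows in A,T,C,G column order.

    A -> [1,0,0,0], T -> [0,1,0,0], C -> [0,0,1,0], G -> [0,0,0,1];
    N -> all-zero row.  Any other character is an error.
    """
    out = np.zeros((len(seq), 4), dtype=np.float64)
    for i, base in enumerate(seq):
        if base == "N":
            continue
        try:
            out[i, _BASE_ROW[base]] = 1.0
        except KeyError:
            raise ValueError(f"cannot encode base {base!r} at position {i}") from None
    return out


def peak_score(track: EpigeneticTrack, locus: GenomicLocus) -> int:
    """1 iff the variant base itself lies inside a peak interval of the mark."""
    return int(track.covers(locus.chrom, locus.pos))


def max_score(track: EpigeneticTrack, window: SequenceWindow) -> float:
    """Maximum per-base enrichment over the window; 0 with no overlap."""
    prof = track.profile(window.locus.chrom, window.start, window.end)
    return float(prof.max(initial=0.0))


def sum_score(track: EpigeneticTrack, window: SequenceWindow) -> float:
    """Summed per-base enrichment over the window (non-covered bases add 0)."""
    prof = track.profile(window.locus.chrom, window.start, window.end)
    return float(prof.sum())


def composition(seq: str) -> dict[str, float]:
    """The ten nucleotide-composition features of a window.

    Mononucleotide counts of A/T/G/C (N excluded); overlapping-adjacent-pair
    counts of the dinucleotides GC, GT and GA; AT skew (A-T)/(A+T) and GC skew
    (G-C)/(G+C) where the denominators are mononucleotide totals; and the skew
    ratio gc_skew/at_skew.  Any division with a zero denominator yields 0.0
    (kept finite by convention; logged at debug level).
    """
    if len(seq) < 2:
        raise ValueError("composition needs a sequence of length >= 2")
    a, t, g, c = (seq.count(b) for b in "ATGC")
    gc_d = gt_d = ga_d = 0
    for i in range(len(seq) - 1):
        if seq[i] == "G":
            nxt = seq[i + 1]
            gc_d += nxt == "C"
            gt_d += nxt == "T"
            ga_d += nxt == "A"

    def _ratio(num: float, den: float) -> float:
        if den == 0:
            logger.debug("zero denominator in skew; returning 0.0")
            return 0.0
        return num / den

    at_skew = _ratio(a - t, a + t)
    gc_skew = _ratio(g - c, g + c)
    return {
        "a_count": float(a), "t_count": float(t),
        "g_count": float(g), "c_count": float(c),
        "gc_dinuc_count": float(gc_d), "gt_dinuc_count": float(gt_d),
        "ga_dinuc_count": float(ga_d),
        "at_skew": at_skew, "gc_skew": gc_skew,
        "skew_ratio": _ratio(gc_skew, at_skew),
    }


def build_feature_map(
    genome: Genome,
    tracks: dict[str, EpigeneticTrack],
    locus: GenomicLocus,
    allow_missing: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """One locus's model input: (150x4 one-hot, 43-vector in TABULAR_COLUMNS order).

    ``tracks`` maps mark name -> track and must contain all 11 canonical marks
    unless ``allow_missing`` is set, in which case absent marks contribute
    zeros for their Peak/Max/Sum columns.
    """
    missing = [m for m in MARKS if m not in tracks]
    if missing and not allow_missing:
        raise KeyError(f"missing tracks for marks {missing}; pass allow_missing=True to zero-fill")
    window = extract_window(genome, locus)
    values: list[float] = []
    for mark in MARKS:
        track = tracks.get(mark)
        if track is None:
            values += [0.0, 0.0, 0.0]
        else:
            values += [
                float(peak_score(track, locus)),
                max_score(track, window),
                sum_score(track, window),
            ]
    comp = composition(window.seq)
    values += [comp[name] for name in COMPOSITION_NAMES]
    return window.onehot, np.asarray(values, dtype=np.float64)


@dataclass
class FeatureTable:
    """A collection of feature maps: the in-memory dataset for training/evaluation.

    Attributes
    ----------
    onehot : (n, 150, 4) float array of one-hot sequence maps.
    tabular : (n, 43) float array, columns in :data:`TABULAR_COLUMNS` order.
    labels : (n,) int array with 1/0 for labeled loci and -1 for unlabeled.
    loci : the source loci, for provenance and audit.
    """

    onehot: np.ndarray
    tabular: np.ndarray
    labels: np.ndarray
    loci: list[GenomicLocus] = field(default_factory=list)
    columns: tuple[str, ...] = TABULAR_COLUMNS

    def __post_init__(self) -> None:
        n = len(self.tabular)
        if len(self.onehot) != n or len(self.labels) != n:
            raise ValueError("onehot/tabular/labels length mismatch")
        if self.tabular.shape[1] != len(self.columns):
            raise ValueError(
                f"tabular width {self.tabular.shape[1]} != {len(self.columns)} columns"
            )

    def __len__(self) -> int:
        return len(self.tabular)

    def subset(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            self.onehot[idx],
            self.tabular[idx],
            self.labels[idx],
            [self.loci[i] for i in np.atleast_1d(idx)] if self.loci else [],
            self.columns,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular features as a DataFrame (locus id, label, 43 named columns)."""
        ids = (
            [f"{l.chrom}:{l.pos}" for l in self.loci]
            if self.loci
            else [str(i) for i in range(len(self))]
        )
        df = pd.DataFrame(self.tabular, columns=list(self.columns))
        df.insert(0, "locus", ids)
        df.insert(1, "label", [{-1: "."}.get(v, str(v)) for v in self.labels])
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_feature_table(
    genome: Genome,
    tracks: dict[str, EpigeneticTrack],
    loci: Sequence[GenomicLocus],
    allow_missing: bool = False,
) -> FeatureTable:
    """Vectorise :func:`build_feature_map` over many loci into a :class:`FeatureTable`."""
    onehots = np.empty((len(loci), WINDOW, 4))
    tabular = np.empty((len(loci), len(TABULAR_COLUMNS)))
    labels = np.empty(len(loci), dtype=np.int64)
    for i, locus in enumerate(loci):
        onehots[i], tabular[i] = build_feature_map(genome, tracks, locus, allow_missing)
        labels[i] = -1 if locus.label is None else locus.label
    return FeatureTable(onehots, tabular, labels, list(loci))


class Preprocessor:
    """log1p on Max/Sum columns then per-column standardization.

    Statistics are fitted on a training partition only and reapplied unchanged
    to validation/test data; zero-variance columns get scale 1 with a warning
    so constant features come out exactly zero.
    """

    def __init__(self) -> None:
        self.mean_: Optional[np.ndarray] = None
        self.scale_: Optional[np.ndarray] = None
        self.columns: tuple[str, ...] = TABULAR_COLUMNS
        self._log_mask = np.array([c in LOG_COLUMNS for c in self.columns])

    def fit(self, tabular: np.ndarray) -> "Preprocessor":
        x = self._log(tabular)
        self.mean_ = x.mean(axis=0)
        std = x.std(axis=0)
        # near-zero std means a constant column up to float rounding
        degenerate = std < 1e-9 * np.maximum(1.0, np.abs(self.mean_))
        if np.any(degenerate):
            flat = [self.columns[i] for i in np.flatnonzero(degenerate)]
            logger.warning("zero-variance columns scaled by 1: %s", flat)
            std = np.where(degenerate, 1.0, std)
        self.scale_ = std
        return self

    def transform(self, tabular: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Preprocessor.transform called before fit")
        return (self._log(tabular) - self.mean_) / self.scale_

    def fit_transform(self, tabular: np.ndarray) -> np.ndarray:
        return self.fit(tabular).transform(tabular)

    def _log(self, tabular: np.ndarray) -> np.ndarray:
        x = np.array(tabular, dtype=np.float64, copy=True)
        x[:, self._log_mask] = np.log1p(x[:, self._log_mask])
        return x

    def to_dict(self) -> dict:
        return {
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "columns": list(self.columns),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Preprocessor":
        p = cls()
        p.mean_ = np.asarray(d["mean"], dtype=np.float64)
        p.scale_ = np.asarray(d["scale"], dtype=np.float64)
        p.columns = tuple(d["columns"])
        return p
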