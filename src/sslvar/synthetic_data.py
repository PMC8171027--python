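"""Fully synthetic benchmark: genome, epigenetic tracks and labeled loci.

The generator emulates the statistical structure the method assumes: a random
genome; per-mark peak tracks with log-normal enrichment, DNase peaks
co-locating with enhancer (H3K27ac) peaks; and variant loci whose probability
of being functional follows a logistic model on standardized per-mark window
scores with a cell-line-specific effect vector.  Labels are flipped with a
small noise rate so classifiers cannot saturate, and the labeled/unlabeled
pool shapes mirror the scarcity and imbalance of real variant catalogues.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from sslvar.genomic_io import (
    EpigeneticTrack,
    Genome,
    GenomicLocus,
    MARKS,
    merge_intervals,
    write_genome,
    write_loci,
    write_track,
)

_WINDOW_MARGIN = 75  # half of the 150-bp feature window


def _default_effects() -> dict[str, dict[str, float]]:
    # two cell lines with orthogonal drivers: A is accessibility/enhancer
    # driven, B promoter driven
    return {
        "cellA": {"DNase": 1.5, "H3K27ac": 1.0, "H3K4me1": 0.8},
        "cellB": {"H3K4me2": 1.0, "H3K4me3": 1.2, "H3K9ac": 0.8},
    }


def _default_peak_geometry() -> dict[str, tuple[int, int, int]]:
    # per mark: (mean gap between peaks, min length, max length)
    geom = {mark: (4000, 400, 1200) for mark in MARKS}
    geom["DNase"] = (3000, 150, 400)  # narrower, denser accessibility peaks
    return geom


@dataclass
class ScenarioConfig:
    """Everything the generator needs to emit one benchmark scenario.

    ``effect_vectors`` maps cell line -> mark -> log-odds weight per standard
    deviation of that mark's window Max score; marks absent from the map have
    zero effect.  ``label_noise`` is the probability a drawn label is flipped
    (default 0.15, keeping attainable AUCs in a realistic 0.7-0.9 band
    instead of saturating).  ``dnase_cooccurrence`` is the probability a DNase
    peak is placed inside an H3K27ac peak, emulating open-chromatin coupling.
    """

    n_chromosomes: int = 2
    chrom_length: int = 200_000
    n_positive: int = 400
    n_negative: int = 1600
    peak_geometry: dict[str, tuple[int, int, int]] = field(
        default_factory=_default_peak_geometry
    )
    signal_mu: float = 1.0      # log-normal log-mean of peak enrichment
    signal_sigma: float = 0.5   # log-normal log-sd
    dnase_cooccurrence: float = 0.7
    effect_vectors: dict[str, dict[str, float]] = field(default_factory=_default_effects)
    intercept: float = -1.6     # base log-odds of being functional
    label_noise: float = 0.15
    sequence_effect: Optional[str] = None  # motif planted in positive windows
    oversample: int = 4         # candidate loci drawn per requested locus

    def __post_init__(self) -> None:
        if self.chrom_length < 1000:
            raise ValueError("chromosomes must be at least 1 kb")
        if not (0 <= self.label_noise <= 1 and 0 <= self.dnase_cooccurrence <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        for cell, vec in self.effect_vectors.items():
            for mark, w in vec.items():
                if mark not in MARKS:
                    raise ValueError(f"unknown mark {mark!r} in effects for {cell}")
                if not np.isfinite(w):
                    raise ValueError(f"non-finite effect for {cell}/{mark}")


def generate_genome(config: ScenarioConfig, seed: int = 0) -> Genome:
    """I.i.d. uniform A/C/G/T chromosomes named chr1..chrN, seeded."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences = {
        f"chr{i + 1}": bases[rng.integers(0, 4, size=config.chrom_length)]
        .tobytes()
        .decode()
        for i in range(config.n_chromosomes)
    }
    return Genome(sequences)


def generate_tracks(
    genome: Genome, config: ScenarioConfig, cell_line: str, seed: int = 0
) -> dict[str, EpigeneticTrack]:
    """Seeded per-mark peak tracks with log-normal enrichment scores.

    Peaks within a mark are drawn by a renewal process (exponential gaps) and
    never overlap; DNase peaks are re-seated inside H3K27ac peaks at the
    configured co-occurrence rate.
    """
    rng = np.random.default_rng(seed)
    tracks: dict[str, EpigeneticTrack] = {}
    for mark in MARKS:  # H3K27ac precedes DNase in canonical order
        gap, len_lo, len_hi = config.peak_geometry[mark]
        track = EpigeneticTrack(mark_name=mark)
        for chrom, seq in genome.sequences.items():
            raw: list[tuple[int, int, float]] = []
            if gap <= 0:  # zero peak density: the mark is emitted but empty
                track.intervals[chrom] = merge_intervals(raw)
                continue
            pos = 0
            while True:
                start = pos + int(rng.exponential(gap))
                length = int(rng.integers(len_lo, len_hi + 1))
                if start + length >= len(seq):
                    break
                score = float(rng.lognormal(config.signal_mu, config.signal_sigma))
                raw.append((start, start + length, score))
                pos = start + length
            if mark == "DNase" and "H3K27ac" in tracks:
                anchors = tracks["H3K27ac"].intervals.get(chrom)
                if anchors is not None and len(anchors[0]):
                    a_starts, a_ends, _ = anchors
                    reseated = []
                    for s, e, v in raw:
                        if rng.random() < config.dnase_cooccurrence:
                            j = int(rng.integers(len(a_starts)))
                            width = min(e - s, int(a_ends[j] - a_starts[j]))
                            lo = int(a_starts[j])
                            hi = int(a_ends[j]) - width
                            s = lo if hi <= lo else int(rng.integers(lo, hi + 1))
                            e = s + width
                        reseated.append((s, e, v))
                    raw = reseated
            track.intervals[chrom] = merge_intervals(raw)
        tracks[mark] = track
    return tracks


def _window_max_scores(
    tracks: dict[str, EpigeneticTrack], chroms: np.ndarray, positions: np.ndarray
) -> np.ndarray:
    """Per-candidate, per-mark maximum signal over the 150-bp window."""
    out = np.zeros((len(positions), len(MARKS)))
    for j, mark in enumerate(MARKS):
        track = tracks[mark]
        for i, (chrom, pos) in enumerate(zip(chroms, positions)):
            prof = track.profile(chrom, pos - _WINDOW_MARGIN, pos + _WINDOW_MARGIN)
            out[i, j] = prof.max(initial=0.0)
    return out


def generate_loci(
    genome: Genome,
    tracks: dict[str, EpigeneticTrack],
    config: ScenarioConfig,
    cell_line: str,
    seed: int = 0,
) -> tuple[list[GenomicLocus], pd.DataFrame]:
    """Draw labeled loci under the logistic planted-effect model.

    Candidate positions are uniform over the genome (margin 75 bp); each gets
    ``P(functional) = logistic(intercept + sum_m w_m * z_m)`` where ``z_m`` is
    the candidate-standardized window Max score of mark m and ``w`` is the
    cell line's effect vector.  Labels are Bernoulli draws flipped with the
    noise rate, then trimmed to the requested class counts.  The manifest
    records the latent probability and pre-noise label of every kept locus.
    """
    rng = np.random.default_rng(seed)
    effects = config.effect_vectors.get(cell_line, {})
    n_cand = config.oversample * (config.n_positive + config.n_negative)
    chrom_names = list(genome.sequences)
    lengths = np.array([genome.length(c) for c in chrom_names], dtype=float)
    chrom_idx = rng.choice(len(chrom_names), size=n_cand, p=lengths / lengths.sum())
    chroms = np.array(chrom_names, dtype=object)[chrom_idx]
    positions = np.array([
        rng.integers(_WINDOW_MARGIN, lengths[i] - _WINDOW_MARGIN)
        for i in chrom_idx
    ])

    raw_scores = _window_max_scores(tracks, chroms, positions)
    std = raw_scores.std(axis=0)
    z = (raw_scores - raw_scores.mean(axis=0)) / np.where(std == 0, 1.0, std)
    weights = np.array([effects.get(m, 0.0) for m in MARKS])
    logit = config.intercept + z @ weights
    prob = 1.0 / (1.0 + np.exp(-logit))
    label_pre = (rng.random(n_cand) < prob).astype(int)
    flip = rng.random(n_cand) < config.label_noise
    label = np.where(flip, 1 - label_pre, label_pre)

    keep_pos = np.flatnonzero(label == 1)[: config.n_positive]
    keep_neg = np.flatnonzero(label == 0)[: config.n_negative]
    if len(keep_pos) < config.n_positive or len(keep_neg) < config.n_negative:
        raise RuntimeError(
            f"generated only {len(keep_pos)} positives / {len(keep_neg)} negatives; "
            "increase oversample or adjust intercept/effects"
        )
    keep = np.sort(np.concatenate([keep_pos, keep_neg]))

    if config.sequence_effect:
        _plant_motif(genome, config.sequence_effect,
                     chroms[keep], positions[keep], label[keep], rng)

    loci = [
        GenomicLocus(chroms[i], int(positions[i]), int(label[i]), cell_line)
        for i in keep
    ]
    manifest = pd.DataFrame({
        "chrom": chroms[keep],
        "pos": positions[keep],
        "latent_p": prob[keep],
        "label_pre_noise": label_pre[keep],
        "label": label[keep],
    })
    return loci, manifest


def _plant_motif(genome, motif, chroms, positions, labels, rng):
    """Write the motif into positive windows at a random in-window offset."""
    for chrom, pos, lab in zip(chroms, positions, labels):
        if lab != 1:
            continue
        off = int(rng.integers(-_WINDOW_MARGIN, _WINDOW_MARGIN - len(motif)))
        seq = genome.sequences[chrom]
        start = pos + off
        genome.sequences[chrom] = seq[:start] + motif + seq[start + len(motif):]


#: Split sizes for the default benchmark, proportional to a 20%-positive
#: catalogue of 2000 loci: balanced labeled 320 (160/160), balanced validation
#: 160 (80/80), everything else (1520, imbalanced) unlabeled.
BENCHMARK_SPLIT_SIZES: tuple[int, Optional[int], int] = (320, None, 160)


@dataclass
class SyntheticBundle:
    """One generated scenario: genome, per-cell tracks, loci and manifests."""

    config: ScenarioConfig
    seed: int
    genome: Genome
    tracks: dict[str, dict[str, EpigeneticTrack]]
    loci: dict[str, list[GenomicLocus]]
    manifests: dict[str, pd.DataFrame]

    @property
    def cell_lines(self) -> list[str]:
        return list(self.loci)

    def feature_tables(self):
        """Per-cell :class:`FeatureTable` built through the standard pipeline."""
        from sslvar.features import build_feature_table

        return {
            cell: build_feature_table(self.genome, self.tracks[cell], self.loci[cell])
            for cell in self.cell_lines
        }

    def write(self, out_dir: str | Path) -> dict:
        """Write FASTA + bedGraph + loci TSV + manifest TSV; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict = {"genome": str(out / "genome.fa"), "cells": {}}
        write_genome(self.genome, out / "genome.fa")
        for cell in self.cell_lines:
            cdir = out / cell
            cdir.mkdir(exist_ok=True)
            track_paths = {}
            for mark, track in self.tracks[cell].items():
                p = cdir / f"{mark}.bedgraph"
                write_track(track, p)
                track_paths[mark] = str(p)
            write_loci(self.loci[cell], cdir / "loci.tsv")
            self.manifests[cell].to_csv(cdir / "manifest.tsv", sep="\t", index=False)
            paths["cells"][cell] = {
                "tracks": track_paths,
                "loci": str(cdir / "loci.tsv"),
                "manifest": str(cdir / "manifest.tsv"),
            }
        with open(out / "scenario.json", "w") as fh:
            json.dump(
                {"seed": self.seed, "config": _config_json(self.config)},
                fh, indent=2, default=str,
            )
        return paths


def _config_json(config: ScenarioConfig) -> dict:
    d = dataclasses.asdict(config)
    d["peak_geometry"] = {k: list(v) for k, v in d["peak_geometry"].items()}
    return d


def generate_bundle(config: ScenarioConfig, seed: int = 0) -> SyntheticBundle:
    """Generate a full scenario; one root seed fans out per stage and cell."""
    ss = np.random.SeedSequence(seed)
    genome_seed, *cell_seeds = ss.spawn(1 + len(config.effect_vectors))
    genome = generate_genome(config, genome_seed.generate_state(1)[0] % (2**31))
    tracks, loci, manifests = {}, {}, {}
    for cell, cs in zip(config.effect_vectors, cell_seeds):
        t_seed, l_seed = (s.generate_state(1)[0] % (2**31) for s in cs.spawn(2))
        tracks[cell] = generate_tracks(genome, config, cell, t_seed)
        loci[cell], manifests[cell] = generate_loci(
            genome, tracks[cell], config, cell, l_seed
        )
    return SyntheticBundle(config, seed, genome, tracks, loci, manifests)


def default_benchmark(seed: int = 0, config: Optional[ScenarioConfig] = None) -> SyntheticBundle:
    """THE two-cell-line benchmark scenario used throughout the test suite.

    Cell line A is driven by accessibility/enhancer marks (DNase, H3K27ac,
    H3K4me1), cell line B by promoter marks (H3K4me2/3, H3K9ac) — orthogonal
    effect vectors, ~2000 loci each at a 20% positive rate, to be split with
    :data:`BENCHMARK_SPLIT_SIZES`.
    """
    return generate_bundle(config or ScenarioConfig(), seed)
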