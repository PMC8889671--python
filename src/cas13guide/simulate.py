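"""Synthetic study-condition generator.

Emulates the data the efficacy model is trained on without any downloads:
a small multi-transcript transcriptome, protein-occupancy peaks in
transcript coordinates (emitted in both BED and macs2-xls dialects), and a
3-replicate guide/expression table with a plantable sequence -> efficacy
signal and controllable replicate noise.

The planted rules are compositional — a sequence term (nucleotide identity
at one spacer position), a position term (guides in the mid-transcript
30-70% band knock down better, matching the positional preference observed
in real training data), and an occupancy term (protein-occluded windows
knock down worse) — so each feature family can be validated in isolation.

Defaults mirror the source study's scale: 555 guides, 3 replicates,
normalized expression in [0,1]. Replicate noise is additive Gaussian on the
expected expression (sd 0.08 by default); alternatively a target
replicate-pair quartile-disagreement rate can be requested and the noise sd
is calibrated to it by bisection. Everything is deterministic under a fixed
seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .guide_space import GuideCandidate, enumerate_guides
from .features import occupancy_overlap_feature, relative_position_feature
from .model import KnockdownObservation, assign_class
from .seq_io import OccupancyPeak, TranscriptRecord

logger = logging.getLogger(__name__)

BASES = "ACGT"
N_REPLICATES = 3


@dataclass(frozen=True)
class PlantedRule:
    """Deterministic map from (spacer, relative position, occupancy overlap)
    to expected normalized expression.

    ``kind='nucleotide_at'``: expression is read straight from
    ``base_levels`` by the spacer nucleotide at ``position`` — a noiseless
    single-position signal for recovery tests.

    ``kind='compositional'``: additive around ``baseline``; the spacer
    nucleotide at ``position`` shifts by ``seq_effects[base]``, mid-
    transcript guides (relpos in ``efficient_band``) get ``-position_effect``
    (others ``+position_effect``), and occupancy adds
    ``occupancy_effect * overlap/100``. Clipped to [0,1].
    """

    kind: Literal["nucleotide_at", "compositional"] = "compositional"
    position: int = 8
    base_levels: tuple[float, float, float, float] = (0.10, 0.35, 0.60, 0.85)
    baseline: float = 0.45
    seq_effects: tuple[float, float, float, float] = (-0.22, -0.08, 0.08, 0.22)
    efficient_band: tuple[float, float] = (0.3, 0.7)
    position_effect: float = 0.10
    occupancy_effect: float = 0.20

    def expected_expression(
        self, spacer: str, relpos: float, occupancy_pct: float
    ) -> float:
        base_idx = BASES.index(spacer[self.position])
        if self.kind == "nucleotide_at":
            return self.base_levels[base_idx]
        value = self.baseline + self.seq_effects[base_idx]
        lo, hi = self.efficient_band
        value += -self.position_effect if lo <= relpos <= hi else self.position_effect
        value += self.occupancy_effect * occupancy_pct / 100.0
        return float(np.clip(value, 0.0, 1.0))


@dataclass
class FixtureConfig:
    """Study-condition knobs. Defaults are the conditions the pipeline is
    validated under: 555 guides x 3 replicates over a dozen transcripts."""

    n_transcripts: int = 12
    length_range: tuple[int, int] = (300, 1200)
    gc_content: float = 0.5
    n_guides_per_transcript: int | str = "all"
    n_total_guides: int | None = 555
    planted_rule: PlantedRule = field(default_factory=PlantedRule)
    replicate_noise_sd: float = 0.08
    replicate_disagreement_rate: float | None = None
    peaks_per_transcript: int = 3
    peak_length_range: tuple[int, int] = (20, 80)
    open_band: tuple[float, float] | None = None  # keep peaks out of this relpos band
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts <= 0 or self.peaks_per_transcript < 0:
            raise ValueError("counts must be positive")
        if self.length_range[0] < 28:
            raise ValueError("minimum transcript length must be >= 28")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0,1)")
        if self.replicate_noise_sd < 0:
            raise ValueError("replicate_noise_sd must be non-negative")


def make_transcriptome(
    config: FixtureConfig, fasta_path: str | Path | None = None
) -> list[TranscriptRecord]:
    """Random transcripts at the configured GC content; reproducible given
    seed. Optionally also written as FASTA."""
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    records = []
    for i in range(config.n_transcripts):
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = "".join(rng.choice(list(BASES), size=length, p=probs))
        records.append(
            TranscriptRecord(
                transcript_id=f"SYNT{i:04d}",
                sequence=seq,
                gene_id=f"SYNG{i:04d}",
                gene_symbol=f"GENE{i}",
            )
        )
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for rec in records:
                fh.write(f">{rec.transcript_id}\n")
                for off in range(0, rec.length, 60):
                    fh.write(rec.sequence[off : off + 60] + "\n")
    return records


def make_peaks(
    config: FixtureConfig,
    transcriptome: Sequence[TranscriptRecord],
    bed_path: str | Path | None = None,
    xls_path: str | Path | None = None,
) -> list[OccupancyPeak]:
    """Random occupancy peaks within transcript bounds; identical intervals
    are written to both requested dialect files. ``config.open_band``
    (relative coordinates) is kept peak-free so low-occupancy efficiency can
    be planted."""
    rng = np.random.default_rng(config.seed + 1)
    peaks: list[OccupancyPeak] = []
    for rec in transcriptome:
        placed = 0
        attempts = 0
        while placed < config.peaks_per_transcript and attempts < 200:
            attempts += 1
            plen = int(rng.integers(*config.peak_length_range))
            if plen >= rec.length:
                continue
            start = int(rng.integers(0, rec.length - plen))
            end = start + plen
            if config.open_band is not None:
                lo = config.open_band[0] * rec.length
                hi = config.open_band[1] * rec.length
                if start < hi and end > lo:
                    continue
            peaks.append(
                OccupancyPeak(rec.transcript_id, start, end, float(rng.integers(5, 50)))
            )
            placed += 1
    if bed_path is not None:
        write_peaks_bed(peaks, bed_path)
    if xls_path is not None:
        write_peaks_macs2_xls(peaks, xls_path)
    return peaks


def write_peaks_bed(peaks: Sequence[OccupancyPeak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(
            sorted(peaks, key=lambda p: (p.reference_id, p.start))
        ):
            fh.write(f"{p.reference_id}\t{p.start}\t{p.end}\tpeak_{i}\t{p.score:g}\n")


def write_peaks_macs2_xls(peaks: Sequence[OccupancyPeak], path: str | Path) -> None:
    """macs2 .xls dialect: '#' comments, header row, 1-based inclusive start."""
    with open(path, "w") as fh:
        fh.write("# This file is a synthetic peak table in the macs2 .xls dialect\n")
        fh.write("#\n")
        fh.write(
            "chr\tstart\tend\tlength\tabs_summit\tpileup\t-log10(pvalue)\t"
            "fold_enrichment\t-log10(qvalue)\tname\n"
        )
        for i, p in enumerate(
            sorted(peaks, key=lambda p: (p.reference_id, p.start))
        ):
            mid = (p.start + 1 + p.end) // 2
            fh.write(
                f"{p.reference_id}\t{p.start + 1}\t{p.end}\t{p.end - p.start}\t{mid}\t"
                f"{p.score:g}\t5.0\t3.0\t2.5\tpeak_{i}\n"
            )


def sample_guides(
    config: FixtureConfig, transcriptome: Sequence[TranscriptRecord]
) -> list[GuideCandidate]:
    """Enumerate guides and subsample per config: ``n_guides_per_transcript``
    first, then a uniform draw down to ``n_total_guides`` (order preserved)."""
    rng = np.random.default_rng(config.seed + 2)
    guides: list[GuideCandidate] = []
    for rec in transcriptome:
        g = enumerate_guides(rec)
        if config.n_guides_per_transcript != "all":
            k = min(int(config.n_guides_per_transcript), len(g))
            idx = sorted(rng.choice(len(g), size=k, replace=False))
            g = [g[i] for i in idx]
        guides.extend(g)
    if config.n_total_guides is not None and len(guides) > config.n_total_guides:
        idx = sorted(rng.choice(len(guides), size=config.n_total_guides, replace=False))
        guides = [guides[i] for i in idx]
    return guides


def expected_expressions(
    config: FixtureConfig,
    guides: Sequence[GuideCandidate],
    transcriptome: Sequence[TranscriptRecord],
    peaks: Sequence[OccupancyPeak],
) -> np.ndarray:
    by_tid = {t.transcript_id: t for t in transcriptome}
    peaks_by_tid: dict[str, list[OccupancyPeak]] = {}
    for p in peaks:
        peaks_by_tid.setdefault(p.reference_id, []).append(p)
    out = np.empty(len(guides))
    for i, g in enumerate(guides):
        rec = by_tid[g.source_transcript]
        relpos = relative_position_feature(g, rec.length)
        occ = occupancy_overlap_feature(g, peaks_by_tid.get(g.source_transcript, ()))
        out[i] = config.planted_rule.expected_expression(g.spacer, relpos, occ)
    return out


def _simulate_disagreement(expected: np.ndarray, sd: float, rng: np.random.Generator) -> float:
    """Fraction of replicate pairs whose quartile labels conflict at noise sd."""
    reps = np.clip(
        expected[:, None] + rng.normal(0.0, sd, size=(len(expected), N_REPLICATES)),
        0.0, 1.0,
    )
    classes = np.minimum((reps * 4).astype(int), 3)
    total = 0
    conflicting = 0
    for row in classes:
        for a in range(N_REPLICATES):
            for b in range(a + 1, N_REPLICATES):
                total += 1
                conflicting += int(row[a] != row[b])
    return conflicting / total


def calibrate_noise_sd(
    expected: np.ndarray, target_rate: float, seed: int, tol: float = 0.005
) -> float:
    """Bisection for the noise sd whose replicate-pair quartile disagreement
    matches ``target_rate`` on these expected expressions."""
    rng = np.random.default_rng(seed)
    lo, hi = 0.0, 0.6
    # disagreement is monotone in sd for fixed expected values
    for _ in range(40):
        mid = (lo + hi) / 2
        rate = _simulate_disagreement(expected, mid, np.random.default_rng(seed + 7))
        if abs(rate - target_rate) < tol:
            return mid
        if rate < target_rate:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def make_knockdown_table(
    config: FixtureConfig,
    guides: Sequence[GuideCandidate],
    transcriptome: Sequence[TranscriptRecord],
    peaks: Sequence[OccupancyPeak],
) -> list[KnockdownObservation]:
    """Three replicate observations per guide: expected expression from the
    planted rule plus clipped Gaussian replicate noise."""
    rng = np.random.default_rng(config.seed + 3)
    expected = expected_expressions(config, guides, transcriptome, peaks)
    sd = config.replicate_noise_sd
    if config.replicate_disagreement_rate is not None:
        sd = calibrate_noise_sd(expected, config.replicate_disagreement_rate, config.seed)
        logger.info("calibrated replicate noise sd = %.4f", sd)
    observations: list[KnockdownObservation] = []
    for g, mu in zip(guides, expected):
        for rep in range(1, N_REPLICATES + 1):
            value = float(np.clip(mu + rng.normal(0.0, sd), 0.0, 1.0))
            observations.append(KnockdownObservation(g.guide_id, rep, value))
    return observations


def write_knockdown_table(
    observations: Sequence[KnockdownObservation], path: str | Path
) -> None:
    """Training-table text layout: guide, replicate, expression, class."""
    with open(path, "w") as fh:
        fh.write("guide_id\treplicate_id\texpression\tclass\n")
        for o in observations:
            fh.write(
                f"{o.guide_id}\t{o.replicate_id}\t{o.expression:.6f}\t"
                f"{assign_class(o.expression).code}\n"
            )


def write_gene_list(
    transcriptome: Sequence[TranscriptRecord], path: str | Path
) -> None:
    symbols = []
    for rec in transcriptome:
        if rec.gene_symbol and rec.gene_symbol not in symbols:
            symbols.append(rec.gene_symbol)
    Path(path).write_text(",".join(symbols) + "\n")


def write_annotation_table(
    transcriptome: Sequence[TranscriptRecord], path: str | Path
) -> None:
    from .seq_io import ANNOTATION_COLUMNS

    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for rec in transcriptome:
            fh.write(
                f"{rec.gene_id}\t{rec.transcript_id}\t{rec.gene_symbol}\t1\t0\t"
                f"{rec.length}\t{rec.strand}\t{rec.length}\t{rec.sequence}\n"
            )
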