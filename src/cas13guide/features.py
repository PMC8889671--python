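"""Guide feature extraction.

Each guide becomes a named feature vector drawn from three sources:

* positional k-mer one-hot indicators (k in {1,2,3} at every spacer offset;
  28*4 + 27*16 + 26*64 = 2208 binary columns),
* spacer nucleotide composition percentages and the guide's relative
  position along its target transcript (midpoint / transcript length),
* target availability: percent of the spacer covered by protein-occupancy
  peaks, and the number of complementary windows found in the transcriptome
  (the multi-target count).

Positions in feature names are 0-based from the 5' end of the spacer;
report-facing renderers add 1. Extraction is a pure function of
(spacer, position, peaks, hits): identical inputs give identical vectors.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .guide_space import SPACER_LEN, AlignmentHit, GuideCandidate
from .seq_io import OccupancyPeak, TranscriptRecord

logger = logging.getLogger(__name__)

BASES = "ACGT"


@dataclass(frozen=True)
class FeatureDescriptor:
    """A named feature column.

    kinds: positional_kmer (one-hot indicator for ``kmer`` at ``position``),
    composition (percent of one base in the spacer), position (relative
    target position in [0,1]), occupancy (percent spacer overlap with
    peaks), multiplicity (transcriptome hit count).
    """

    name: str
    kind: str
    k: int | None = None
    kmer: str | None = None
    position: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "positional_kmer":
            assert self.k is not None and self.kmer is not None and self.position is not None
            if self.position + self.k > SPACER_LEN:
                raise ValueError(f"{self.name}: position+k exceeds spacer length")


def kmer_descriptor(k: int, kmer: str, position: int) -> FeatureDescriptor:
    return FeatureDescriptor(
        name=f"kmer|{k}|{kmer}|{position}", kind="positional_kmer", k=k, kmer=kmer, position=position
    )


def default_feature_space(k_values: Sequence[int] = (1, 2, 3)) -> list[FeatureDescriptor]:
    """The full pre-selection feature space: positional k-mers, composition,
    relative position, occupancy overlap, hit count (2215 columns for the
    default k set)."""
    descriptors: list[FeatureDescriptor] = []
    for k in sorted(k_values):
        for position in range(SPACER_LEN - k + 1):
            for kmer_tuple in itertools.product(BASES, repeat=k):
                descriptors.append(kmer_descriptor(k, "".join(kmer_tuple), position))
    for base in BASES:
        descriptors.append(FeatureDescriptor(name=f"comp|{base}", kind="composition"))
    descriptors.append(FeatureDescriptor(name="relpos", kind="position"))
    descriptors.append(FeatureDescriptor(name="occ_overlap", kind="occupancy"))
    descriptors.append(FeatureDescriptor(name="n_hits", kind="multiplicity"))
    names = [d.name for d in descriptors]
    assert len(names) == len(set(names))
    return descriptors


def positional_kmer_features(
    spacer: str, k_values: Sequence[int] = (1, 2, 3)
) -> dict[str, int]:
    """One-hot indicators: for each (k, position) the k-mer present is 1 and
    its 4^k - 1 siblings are 0."""
    _check_spacer(spacer)
    out: dict[str, int] = {}
    for k in sorted(k_values):
        for position in range(SPACER_LEN - k + 1):
            present = spacer[position : position + k]
            for kmer_tuple in itertools.product(BASES, repeat=k):
                kmer = "".join(kmer_tuple)
                out[f"kmer|{k}|{kmer}|{position}"] = int(kmer == present)
    return out


def composition_features(spacer: str) -> dict[str, float]:
    """Percent composition of each base; the four values sum to 100."""
    _check_spacer(spacer)
    return {f"comp|{b}": 100.0 * spacer.count(b) / SPACER_LEN for b in BASES}


def relative_position_feature(guide: GuideCandidate, transcript_length: int) -> float:
    """Midpoint of the complementary region normalized by transcript length
    (0 at the 5' end, 1 at the 3' end)."""
    if transcript_length <= 0:
        raise ValueError("transcript_length must be positive")
    if guide.target_end > transcript_length:
        raise ValueError(
            f"guide {guide.guide_id}: window end {guide.target_end} exceeds "
            f"transcript length {transcript_length}"
        )
    return (guide.target_start + SPACER_LEN / 2) / transcript_length


def occupancy_overlap_feature(
    guide: GuideCandidate, peaks: Iterable[OccupancyPeak]
) -> float:
    """Percent of the spacer window covered by the union of peak intervals.

    Overlapping peaks are unioned before measuring, so the value never
    exceeds 100 and is invariant to peak ordering and to splitting a peak
    into abutting pieces.
    """
    lo, hi = guide.target_start, guide.target_end
    clipped = sorted(
        (max(p.start, lo), min(p.end, hi)) for p in peaks if p.start < hi and p.end > lo
    )
    covered = 0
    cur_start: int | None = None
    cur_end = 0
    for s, e in clipped:
        if cur_start is None:
            cur_start, cur_end = s, e
        elif s <= cur_end:
            cur_end = max(cur_end, e)
        else:
            covered += cur_end - cur_start
            cur_start, cur_end = s, e
    if cur_start is not None:
        covered += cur_end - cur_start
    return 100.0 * covered / SPACER_LEN


@dataclass
class FeatureMatrix:
    """Guides (or guide x replicate rows) by named features."""

    row_ids: list[str]
    descriptors: list[FeatureDescriptor]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.descriptors)):
            raise ValueError(
                f"matrix shape {self.values.shape} != "
                f"({len(self.row_ids)}, {len(self.descriptors)})"
            )
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def subset(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = [self.names.index(n) for n in names]
        return FeatureMatrix(
            list(self.row_ids), [self.descriptors[i] for i in idx], self.values[:, idx]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.names)

    def to_tsv(self, path: str | Path, extra: Mapping[str, Sequence] | None = None) -> None:
        """Tab-delimited export: header of descriptor names, one row per
        row_id; ``extra`` appends trailing columns (e.g. label, expression)."""
        df = self.to_dataframe()
        if extra:
            for col, vals in extra.items():
                df[col] = list(vals)
        df.to_csv(path, sep="\t", index_label="row_id")

    @classmethod
    def from_tsv(cls, path: str | Path, feature_space: Sequence[FeatureDescriptor] | None = None
                 ) -> tuple["FeatureMatrix", pd.DataFrame]:
        """Read a matrix written by :meth:`to_tsv`. Returns the matrix over
        the recognized feature columns plus a DataFrame of any trailing
        non-feature columns (labels, expression, replicate)."""
        df = pd.read_csv(path, sep="\t", index_col="row_id", comment="#")
        space = list(feature_space) if feature_space is not None else None
        if space is None:
            space = [_descriptor_from_name(c) for c in df.columns]
            space = [d for d in space if d is not None]
        names = [d.name for d in space]
        missing = [n for n in names if n not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing feature columns {missing[:5]}...")
        extra_cols = [c for c in df.columns if c not in set(names)]
        matrix = cls(
            row_ids=[str(i) for i in df.index],
            descriptors=space,
            values=df[names].to_numpy(dtype=float),
        )
        return matrix, df[extra_cols]


def _descriptor_from_name(name: str) -> FeatureDescriptor | None:
    parts = name.split("|")
    if parts[0] == "kmer" and len(parts) == 4:
        return kmer_descriptor(int(parts[1]), parts[2], int(parts[3]))
    if parts[0] == "comp" and len(parts) == 2:
        return FeatureDescriptor(name=name, kind="composition")
    if name == "relpos":
        return FeatureDescriptor(name=name, kind="position")
    if name == "occ_overlap":
        return FeatureDescriptor(name=name, kind="occupancy")
    if name == "n_hits":
        return FeatureDescriptor(name=name, kind="multiplicity")
    return None


def build_feature_matrix(
    guides: Sequence[GuideCandidate],
    hits: Mapping[str, Sequence[AlignmentHit]],
    peaks: Mapping[str, Sequence[OccupancyPeak]],
    transcripts: Mapping[str, TranscriptRecord] | Sequence[TranscriptRecord],
    feature_space: Sequence[FeatureDescriptor] | None = None,
) -> FeatureMatrix:
    """Assemble the guides x features matrix in guide input order.

    ``peaks`` maps transcript ID to its peak list; transcripts with no
    occupancy data contribute overlap 0 (warned once per transcript).
    """
    if feature_space is None:
        feature_space = default_feature_space()
    if not isinstance(transcripts, Mapping):
        transcripts = {t.transcript_id: t for t in transcripts}

    names = [d.name for d in feature_space]
    col_of = {n: i for i, n in enumerate(names)}
    values = np.zeros((len(guides), len(feature_space)), dtype=float)
    warned: set[str] = set()

    for i, guide in enumerate(guides):
        tid = guide.source_transcript
        if tid not in transcripts:
            raise KeyError(f"guide {guide.guide_id}: unknown transcript {tid!r}")
        transcript = transcripts[tid]
        if tid not in peaks and tid not in warned:
            logger.warning("transcript %s: no occupancy data, overlap set to 0", tid)
            warned.add(tid)
        row = values[i]
        spacer = guide.spacer
        for k in (1, 2, 3):
            for position in range(SPACER_LEN - k + 1):
                name = f"kmer|{k}|{spacer[position:position + k]}|{position}"
                col = col_of.get(name)
                if col is not None:
                    row[col] = 1.0
        for name, val in composition_features(spacer).items():
            col = col_of.get(name)
            if col is not None:
                row[col] = val
        if "relpos" in col_of:
            row[col_of["relpos"]] = relative_position_feature(guide, transcript.length)
        if "occ_overlap" in col_of:
            row[col_of["occ_overlap"]] = occupancy_overlap_feature(
                guide, peaks.get(tid, ())
            )
        if "n_hits" in col_of:
            row[col_of["n_hits"]] = len(hits.get(guide.guide_id, ()))
    return FeatureMatrix([g.guide_id for g in guides], list(feature_space), values)


def _check_spacer(spacer: str) -> None:
    if len(spacer) != SPACER_LEN:
        raise ValueError(f"spacer length {len(spacer)} != {SPACER_LEN}")
    bad = set(spacer) - set(BASES)
    if bad:
        raise ValueError(f"spacer contains non-ACGT characters {sorted(bad)}")
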