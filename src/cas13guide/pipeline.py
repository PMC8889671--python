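"""End-to-end plumbing: assemble training datasets and study bundles.

A training row is one (guide, replicate) observation: replicates of the
same guide share the guide's feature vector and differ only in label. The
non-k-mer features (composition, relative position, occupancy overlap, hit
count) are appended to every selected k-mer list when a model feature list
is finalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .features import (
    FeatureDescriptor,
    FeatureMatrix,
    build_feature_matrix,
    default_feature_space,
)
from .guide_space import GuideCandidate, search_transcriptome
from .model import KnockdownObservation
from .seq_io import OccupancyPeak, TranscriptRecord, peaks_by_reference
from .select import SelectionResult
from .simulate import (
    FixtureConfig,
    make_knockdown_table,
    make_peaks,
    make_transcriptome,
    sample_guides,
)

NON_KMER_FEATURES = ["comp|A", "comp|C", "comp|G", "comp|T", "relpos", "occ_overlap", "n_hits"]


def final_feature_names(selection: SelectionResult | Sequence[str]) -> list[str]:
    """A model feature list: the selected k-mer indicators plus the seven
    non-k-mer features (deduplicated, selection order preserved)."""
    names = list(selection.names) if isinstance(selection, SelectionResult) else list(selection)
    for extra in NON_KMER_FEATURES:
        if extra not in names:
            names.append(extra)
    return names


def expand_to_replicates(
    guide_matrix: FeatureMatrix,
    observations: Sequence[KnockdownObservation],
) -> tuple[FeatureMatrix, np.ndarray, np.ndarray, list[str]]:
    """Repeat each guide's feature row once per replicate observation.

    Returns (row-per-observation matrix, class labels, replicate ids,
    guide ids); observation order is preserved.
    """
    row_of = {rid: i for i, rid in enumerate(guide_matrix.row_ids)}
    idx = []
    labels = []
    replicate_ids = []
    guide_ids = []
    for o in observations:
        if o.guide_id not in row_of:
            raise KeyError(f"observation for unknown guide {o.guide_id!r}")
        idx.append(row_of[o.guide_id])
        labels.append(o.efficacy_class.code)
        replicate_ids.append(o.replicate_id)
        guide_ids.append(o.guide_id)
    matrix = FeatureMatrix(
        row_ids=[f"{o.guide_id}|rep{o.replicate_id}" for o in observations],
        descriptors=list(guide_matrix.descriptors),
        values=guide_matrix.values[idx],
    )
    return matrix, np.asarray(labels), np.asarray(replicate_ids), guide_ids


@dataclass
class StudyBundle:
    """Everything one synthetic study run produces, ready for selection,
    training and evaluation."""

    config: FixtureConfig
    transcriptome: list[TranscriptRecord]
    guides: list[GuideCandidate]
    peaks: list[OccupancyPeak]
    hits: dict
    observations: list[KnockdownObservation]
    guide_matrix: FeatureMatrix  # one row per guide, full feature space
    matrix: FeatureMatrix  # one row per (guide, replicate)
    labels: np.ndarray
    replicate_ids: np.ndarray
    guide_ids: list[str]
    expressions: np.ndarray  # per training row


def assemble_study(
    config: FixtureConfig,
    feature_space: Sequence[FeatureDescriptor] | None = None,
    max_mismatches: int = 3,
) -> StudyBundle:
    """Generate a full synthetic study: transcriptome, peaks, guides,
    transcriptome search, replicate knockdown table, and feature matrices."""
    transcriptome = make_transcriptome(config)
    peaks = make_peaks(config, transcriptome)
    guides = sample_guides(config, transcriptome)
    hits = search_transcriptome(guides, transcriptome, max_mismatches=max_mismatches)
    observations = make_knockdown_table(config, guides, transcriptome, peaks)
    guide_matrix = build_feature_matrix(
        guides, hits, peaks_by_reference(peaks), transcriptome,
        feature_space or default_feature_space(),
    )
    matrix, labels, replicate_ids, guide_ids = expand_to_replicates(
        guide_matrix, observations
    )
    expressions = np.array([o.expression for o in observations])
    return StudyBundle(
        config=config,
        transcriptome=transcriptome,
        guides=guides,
        peaks=peaks,
        hits=hits,
        observations=observations,
        guide_matrix=guide_matrix,
        matrix=matrix,
        labels=labels,
        replicate_ids=replicate_ids,
        guide_ids=guide_ids,
        expressions=expressions,
    )
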