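"""Candidate spacer enumeration and mismatch-tolerant transcriptome search.

A guide's 28-nt spacer is stored as the reverse complement of the transcript
window it targets (the guide hybridizes to the transcript). Searching is
done on the target side: a hit is any 28-nt transcript window within the
allowed Hamming distance of the guide's complementary target sequence. Only
the sense strand is searched — transcripts are single-stranded RNA, so
antisense windows are not Cas13 targets. Mismatch tolerance is capped at 3,
the maximum the Cas13 system tolerates.

The search uses pigeonhole seeding: a 28-mer with at most m mismatches must
contain at least one of m+1 disjoint exact seed blocks, so candidate
positions come from an exact k-mer index and are verified by a full Hamming
check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .seq_io import TranscriptRecord

logger = logging.getLogger(__name__)

SPACER_LEN = 28
MAX_MISMATCHES = 3

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GuideCandidate:
    """A 28-nt spacer and the transcript window it targets (0-based half-open)."""

    guide_id: str
    spacer: str
    source_transcript: str
    target_start: int

    def __post_init__(self) -> None:
        if len(self.spacer) != SPACER_LEN:
            raise ValueError(f"spacer length {len(self.spacer)} != {SPACER_LEN}")

    @property
    def target_end(self) -> int:
        return self.target_start + SPACER_LEN

    @property
    def target_sequence(self) -> str:
        """The transcript window the spacer base-pairs with."""
        return reverse_complement(self.spacer)


@dataclass(frozen=True)
class AlignmentHit:
    """One complementary window found in the transcriptome."""

    guide_id: str
    reference_id: str
    position: int
    mismatches: int


def enumerate_guides(transcript: TranscriptRecord) -> list[GuideCandidate]:
    """All 28-nt windows of a transcript as guide candidates.

    Windows containing 'N' are excluded (an undefined base cannot
    parameterize sequence features). Candidates are ordered by target_start.
    """
    seq = transcript.sequence
    n = len(seq)
    if n < SPACER_LEN:
        logger.warning(
            "transcript %s length %d < %d: no guides", transcript.transcript_id, n, SPACER_LEN
        )
        return []
    guides = []
    for start in range(n - SPACER_LEN + 1):
        window = seq[start : start + SPACER_LEN]
        if "N" in window:
            continue
        guides.append(
            GuideCandidate(
                guide_id=f"{transcript.transcript_id}|{start}",
                spacer=reverse_complement(window),
                source_transcript=transcript.transcript_id,
                target_start=start,
            )
        )
    return guides


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))


def _build_seed_index(
    transcriptome: Sequence[TranscriptRecord], seed_len: int
) -> dict[str, list[tuple[int, int]]]:
    """Exact k-mer index: seed -> [(transcript index, offset), ...]."""
    index: dict[str, list[tuple[int, int]]] = {}
    for t_idx, rec in enumerate(transcriptome):
        seq = rec.sequence
        for off in range(len(seq) - seed_len + 1):
            kmer = seq[off : off + seed_len]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((t_idx, off))
    return index


def search_transcriptome(
    guides: Iterable[GuideCandidate],
    transcriptome: Sequence[TranscriptRecord],
    max_mismatches: int = MAX_MISMATCHES,
) -> dict[str, list[AlignmentHit]]:
    """Find every transcript window within ``max_mismatches`` of each guide's
    target sequence.

    Pigeonhole seeding: the 28-mer is split into ``max_mismatches + 1``
    blocks; any window within the mismatch budget matches at least one block
    exactly, so the block lookups enumerate a superset of true hits which a
    full Hamming check then filters. Each window is reported exactly once.
    """
    if not 0 <= max_mismatches <= MAX_MISMATCHES:
        raise ValueError(f"max_mismatches must be in [0,{MAX_MISMATCHES}]")
    if not transcriptome:
        raise ValueError("transcriptome is empty")

    n_blocks = max_mismatches + 1
    seed_len = SPACER_LEN // n_blocks
    # block offsets cover the spacer; the remainder tail is absorbed by the
    # last block's verification step, not by seeding
    block_offsets = [i * seed_len for i in range(n_blocks)]
    index = _build_seed_index(transcriptome, seed_len)

    results: dict[str, list[AlignmentHit]] = {}
    for guide in guides:
        if len(guide.spacer) != SPACER_LEN:
            raise ValueError(f"guide {guide.guide_id}: bad spacer length")
        target = guide.target_sequence
        seen: set[tuple[int, int]] = set()
        hits: list[AlignmentHit] = []
        for off in block_offsets:
            block = target[off : off + seed_len]
            for t_idx, pos in index.get(block, ()):
                start = pos - off
                if start < 0:
                    continue
                ref = transcriptome[t_idx]
                if start + SPACER_LEN > len(ref.sequence):
                    continue
                if (t_idx, start) in seen:
                    continue
                seen.add((t_idx, start))
                window = ref.sequence[start : start + SPACER_LEN]
                mm = hamming(target, window)
                if mm <= max_mismatches:
                    hits.append(
                        AlignmentHit(guide.guide_id, ref.transcript_id, start, mm)
                    )
        hits.sort(key=lambda h: (h.reference_id, h.position))
        results[guide.guide_id] = hits
    return results


def brute_force_search(
    guides: Iterable[GuideCandidate],
    transcriptome: Sequence[TranscriptRecord],
    max_mismatches: int = MAX_MISMATCHES,
) -> dict[str, list[AlignmentHit]]:
    """Naive all-windows Hamming scan. Reference oracle for the seeded search."""
    results: dict[str, list[AlignmentHit]] = {}
    for guide in guides:
        target = guide.target_sequence
        hits = []
        for rec in transcriptome:
            seq = rec.sequence
            for start in range(len(seq) - SPACER_LEN + 1):
                mm = hamming(target, seq[start : start + SPACER_LEN])
                if mm <= max_mismatches:
                    hits.append(AlignmentHit(guide.guide_id, rec.transcript_id, start, mm))
        hits.sort(key=lambda h: (h.reference_id, h.position))
        results[guide.guide_id] = hits
    return results


def hits_to_bed(hits: Mapping[str, Sequence[AlignmentHit]], path: str | Path) -> None:
    """Export hits as BED6: reference, start, end, guide_id, mismatches, '+'.

    Sorted by reference then position for stable downstream diffing.
    """
    rows = [h for hit_list in hits.values() for h in hit_list]
    rows.sort(key=lambda h: (h.reference_id, h.position, h.guide_id))
    with open(path, "w") as fh:
        for h in rows:
            fh.write(
                f"{h.reference_id}\t{h.position}\t{h.position + SPACER_LEN}\t"
                f"{h.guide_id}\t{h.mismatches}\t+\n"
            )
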