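"""I/O for every external format the pipeline touches.

All coordinates are normalized to 0-based half-open intervals on the
transcript (never the genome). Two peak dialects are accepted: plain BED
(already 0-based half-open) and the tab-separated ``.xls`` table emitted by
macs2, whose ``start`` column is 1-based inclusive and is decremented on
read. Transcript sequences are uppercased and U is mapped to T so that all
downstream sequence handling works on a single DNA-style alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")

#: Column layout of the transcript annotation table (delimited text).
ANNOTATION_COLUMNS = [
    "gene_id",
    "transcript_id",
    "gene_symbol",
    "chromosome",
    "gene_start",
    "gene_end",
    "strand",
    "length",
    "sequence",
]


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One reference transcript with its gene linkage.

    ``sequence`` is uppercase over {A,C,G,T,N}; ``length`` always equals
    ``len(sequence)``.
    """

    transcript_id: str
    sequence: str
    gene_id: str = ""
    gene_symbol: str = ""
    strand: str = "+"

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ParseError(
                f"transcript {self.transcript_id!r}: invalid characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OccupancyPeak:
    """A protein-occupancy interval on a transcript, 0-based half-open.

    ``score`` records the caller's enrichment/pileup value; the overlap
    feature never consults it.
    """

    reference_id: str
    start: int
    end: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ParseError(f"peak on {self.reference_id}: negative start {self.start}")
        if self.start >= self.end:
            raise ParseError(
                f"peak on {self.reference_id}: empty interval [{self.start},{self.end})"
            )


@dataclass
class GeneList:
    """Ordered, deduplicated gene symbols (first occurrence kept)."""

    symbols: list[str] = field(default_factory=list)

    @classmethod
    def from_iterable(cls, symbols: Iterable[str]) -> "GeneList":
        seen: set[str] = set()
        out: list[str] = []
        for s in symbols:
            s = s.strip()
            if s and s not in seen:
                seen.add(s)
                out.append(s)
        return cls(out)


def _normalize_sequence(raw: str, record_name: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - VALID_BASES
    if bad:
        raise ParseError(
            f"record {record_name!r}: sequence characters outside ACGTNU: {sorted(bad)}"
        )
    return seq


def read_transcriptome(path: str | Path, format: str = "fasta") -> list[TranscriptRecord]:
    """Read transcripts from FASTA or from the annotation-table layout.

    FASTA headers carry the transcript ID as the first whitespace-delimited
    token. The annotation table is delimited text with the columns of
    :data:`ANNOTATION_COLUMNS`; its declared ``length`` must match the
    sequence. Records with an empty sequence are dropped with a warning.
    """
    path = Path(path)
    if format == "fasta":
        return _read_fasta(path)
    if format == "annotation-table":
        return _read_annotation_table(path)
    raise ValueError(f"unknown transcriptome format {format!r}")


def _read_fasta(path: Path) -> list[TranscriptRecord]:
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        tid = rec.id
        if not tid:
            raise ParseError(f"{path}: FASTA header with no ID token")
        if len(rec.seq) == 0:
            logger.warning("dropping transcript %s: empty sequence", tid)
            continue
        if tid in seen:
            raise ParseError(f"{path}: duplicate transcript ID {tid!r}")
        seen.add(tid)
        records.append(TranscriptRecord(tid, _normalize_sequence(str(rec.seq), tid)))
    return records


def _read_annotation_table(path: Path) -> list[TranscriptRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: annotation table missing columns {missing}")
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        tid = row["transcript_id"]
        seq = row["sequence"]
        if not isinstance(seq, str) or not seq:
            logger.warning("dropping transcript %s: empty sequence", tid)
            continue
        seq = _normalize_sequence(seq, tid)
        declared = int(row["length"])
        if declared != len(seq):
            raise ParseError(
                f"{path} row {i}: declared length {declared} != sequence length {len(seq)}"
            )
        if tid in seen:
            raise ParseError(f"{path}: duplicate transcript ID {tid!r}")
        seen.add(tid)
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                sequence=seq,
                gene_id=row["gene_id"],
                gene_symbol=row["gene_symbol"],
                strand=row["strand"] if row["strand"] in {"+", "-"} else "+",
            )
        )
    return records


def read_peaks(path: str | Path, dialect: str = "bed") -> list[OccupancyPeak]:
    """Read occupancy peaks, normalizing both dialects to 0-based half-open.

    ``bed``: >=3 tab-separated columns, already 0-based half-open; column 5
    (if present) is kept as the score. ``macs2-xls``: '#' comment lines and
    one header row, 1-based inclusive start (decremented by 1 on read), with
    a ``pileup`` column used as the score when present.
    """
    path = Path(path)
    if dialect == "bed":
        return _read_bed(path)
    if dialect == "macs2-xls":
        return _read_macs2_xls(path)
    raise ValueError(f"unknown peak dialect {dialect!r}")


def _read_bed(path: Path) -> list[OccupancyPeak]:
    peaks: list[OccupancyPeak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED line with <3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            score = 0.0
            if len(fields) >= 5:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = 0.0
            try:
                peaks.append(OccupancyPeak(fields[0], start, end, score))
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not peaks:
        logger.warning("%s: no peaks parsed", path)
    return peaks


def _read_macs2_xls(path: Path) -> list[OccupancyPeak]:
    peaks: list[OccupancyPeak] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                continue
            row = dict(zip(header, fields))
            try:
                # macs2 .xls start is 1-based inclusive
                start = int(row["start"]) - 1
                end = int(row["end"])
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: bad macs2-xls row") from exc
            score = float(row.get("pileup", 0.0) or 0.0)
            try:
                peaks.append(OccupancyPeak(row["chr"], start, end, score))
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not peaks:
        logger.warning("%s: no peaks parsed", path)
    return peaks


def peaks_by_reference(peaks: Iterable[OccupancyPeak]) -> dict[str, list[OccupancyPeak]]:
    """Group peaks by transcript; peaks for unknown transcripts stay grouped
    under their reference and are simply never consulted downstream."""
    grouped: dict[str, list[OccupancyPeak]] = {}
    for p in peaks:
        grouped.setdefault(p.reference_id, []).append(p)
    return grouped


def read_gene_list(path: str | Path) -> GeneList:
    """Gene list: plain text or comma-separated, one symbol per field."""
    text = Path(path).read_text()
    tokens: list[str] = []
    for line in text.splitlines():
        tokens.extend(line.split(","))
    return GeneList.from_iterable(tokens)


def write_guide_fasta(guides: Sequence, path: str | Path) -> None:
    """Write spacers as FASTA, header ``>transcript_id|start`` (0-based).

    Output order is deterministic: source transcript, then target offset.
    """
    for g in guides:
        if len(g.spacer) != 28:
            raise ValueError(f"guide {g.guide_id}: spacer length {len(g.spacer)} != 28")
    ordered = sorted(guides, key=lambda g: (g.source_transcript, g.target_start))
    if not ordered:
        logger.warning("write_guide_fasta: empty guide collection -> empty file")
    records = [
        SeqRecord(Seq(g.spacer), id=f"{g.source_transcript}|{g.target_start}", description="")
        for g in ordered
    ]
    SeqIO.write(records, str(path), "fasta")


def read_guide_fasta(path: str | Path) -> list[tuple[str, int, str]]:
    """Read a guide FASTA back into (source_transcript, target_start, spacer)."""
    out: list[tuple[str, int, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            tid, start = rec.id.rsplit("|", 1)
            out.append((tid, int(start), str(rec.seq).upper()))
        except ValueError as exc:
            raise ParseError(f"{path}: malformed guide header {rec.id!r}") from exc
    return out
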