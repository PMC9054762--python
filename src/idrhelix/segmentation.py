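"""IDR segmentation: turning a per-residue disorder track into segments.

An IDR here is a maximal run of residues whose disorder score is at or above
a cutoff, kept only if the run is strictly longer than a minimum length
(default 40 residues, so segments of length 41 and up qualify).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .io import ProteinRecord, ResidueTrack


@dataclass(frozen=True)
class SegmentationConfig:
    """Disorder binarization cutoff and the exclusive minimum segment length."""

    disorder_cutoff: float = 0.5
    min_length: int = 40  # exclusive: segments must be strictly longer

    def __post_init__(self) -> None:
        if not 0.0 <= self.disorder_cutoff <= 1.0:
            raise ValueError("disorder_cutoff must lie in [0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass(frozen=True)
class IDRSegment:
    """A maximal disordered stretch of one protein (1-based inclusive)."""

    accession: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad segment bounds {self.start}..{self.end}")
        if len(self.sequence) != self.length:
            raise ValueError(
                f"{self.accession}: sequence length {len(self.sequence)} != "
                f"span {self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def binarize(track: ResidueTrack, cutoff: float = 0.5) -> np.ndarray:
    """Boolean disorder calls: position i is disordered iff value >= cutoff.

    The boundary is inclusive so pre-binarized 0/1 tracks pass through
    unchanged at the default cutoff.
    """
    if track.kind != "disorder":
        raise ValueError(f"expected a disorder track, got kind={track.kind!r}")
    return track.values >= cutoff


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """0-based half-open (start, stop) spans of maximal True runs."""
    padded = np.concatenate(([False], np.asarray(mask, dtype=bool), [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def segment_idrs(
    record: ProteinRecord,
    track: ResidueTrack,
    config: SegmentationConfig = SegmentationConfig(),
) -> list[IDRSegment]:
    """Maximal disordered runs of ``record`` longer than ``config.min_length``.

    Returned segments are sorted by start, non-overlapping, and never span
    proteins. Raises if the track length differs from the sequence length.
    """
    if len(track) != len(record):
        raise ValueError(
            f"{record.accession}: track length {len(track)} != "
            f"sequence length {len(record)}"
        )
    mask = binarize(track, config.disorder_cutoff)
    segments = []
    for lo, hi in _true_runs(mask):
        if hi - lo > config.min_length:
            segments.append(
                IDRSegment(record.accession, lo + 1, hi, record.sequence[lo:hi])
            )
    return segments


def write_segments_tsv(segments: Iterable[IDRSegment], path: str | Path) -> None:
    """Write segments as TSV; both coordinate columns 1-based inclusive."""
    lines = ["# coordinates: 1-based, inclusive on both ends",
             "accession\tstart\tend\tlength\tsequence"]
    for s in segments:
        lines.append(f"{s.accession}\t{s.start}\t{s.end}\t{s.length}\t{s.sequence}")
    Path(path).write_text("\n".join(lines) + "\n")
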