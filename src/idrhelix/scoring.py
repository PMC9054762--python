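"""Polyalanine/helix-propensity stretch scoring of IDR segments.

The scoring model: each amino acid carries a non-negative propensity score
(alanine the largest; other helix-promoting residues such as methionine,
leucine and glutamine smaller positive values; everything else zero). A
"stretch" is a maximal run of consecutive residues whose score is positive;
its score is the sum of the residues' scores, so a contiguous eight-alanine
tract scores twice what the same tract split in half by a zero-scored
residue does. The per-IDR scalar used for prevalence statistics is the
maximum stretch score in the segment.

A separate criterion flags IDRs containing an alpha-helical element: a run
of at least ``min_run`` residues (default 5) whose predicted helix
propensity is strictly above a cutoff (default 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .io import CANONICAL_AA, ProteinRecord, ResidueTrack
from .segmentation import IDRSegment


@dataclass
class ScoreTable:
    """Per-amino-acid propensity scores; a versioned configuration artifact."""

    name: str
    scores: dict[str, float]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        table = {aa: 0.0 for aa in CANONICAL_AA}
        for aa, s in self.scores.items():
            aa = aa.upper()
            if len(aa) != 1:
                raise ValueError(f"score table {self.name}: bad key {aa!r}")
            if s < 0:
                raise ValueError(f"score table {self.name}: negative score for {aa}")
            table[aa] = float(s)
        extra = set(table) - set(CANONICAL_AA)
        if extra - {"B", "Z", "X", "U"}:
            raise ValueError(f"score table {self.name}: unknown letters {sorted(extra)}")
        if not any(v > 0 for v in table.values()):
            raise ValueError(f"score table {self.name}: all scores are zero")
        self.scores = table

    def __getitem__(self, aa: str) -> float:
        # non-canonical residues (X, B, Z, U) score 0 and act as breakers
        return self.scores.get(aa.upper(), 0.0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoreTable":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(doc.get("name", Path(path).stem), doc["scores"],
                   version=str(doc.get("version", "unversioned")))

    def to_yaml(self, path: str | Path) -> None:
        doc = {"name": self.name, "version": self.version,
               "scores": {aa: s for aa, s in self.scores.items() if s > 0}}
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def default_score_table() -> ScoreTable:
    """The packaged default propensity table (see data/polyala_scores.yaml)."""
    from importlib.resources import files

    return ScoreTable.from_yaml(files("idrhelix.data") / "polyala_scores.yaml")


@dataclass(frozen=True)
class StretchHit:
    """One maximal positively-scored run inside a segment (parent coords)."""

    segment: IDRSegment
    start: int
    end: int
    score: float


@dataclass(frozen=True)
class HelixElementConfig:
    """Helix-element criterion: >= min_run residues strictly above cutoff."""

    min_run: int = 5
    cutoff: float = 0.8  # exclusive

    def __post_init__(self) -> None:
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError("cutoff must lie in [0, 1]")


def stretches(segment: IDRSegment, table: ScoreTable) -> list[StretchHit]:
    """Maximal runs of positively scored residues, with summed scores.

    Coordinates of the hits are in parent-protein numbering.
    """
    hits: list[StretchHit] = []
    run_start: int | None = None
    run_sum = 0.0
    for i, aa in enumerate(segment.sequence):
        s = table[aa]
        if s > 0:
            if run_start is None:
                run_start = i
                run_sum = 0.0
            run_sum += s
        elif run_start is not None:
            hits.append(StretchHit(segment, segment.start + run_start,
                                   segment.start + i - 1, run_sum))
            run_start = None
    if run_start is not None:
        hits.append(StretchHit(segment, segment.start + run_start,
                               segment.end, run_sum))
    return hits


def max_polyala_score(segment: IDRSegment, table: ScoreTable) -> float:
    """The per-IDR scalar: maximum stretch score, 0.0 if no stretch."""
    hits = stretches(segment, table)
    return max((h.score for h in hits), default=0.0)


def longest_homorepeat(seq: IDRSegment | str, letter: str) -> int:
    """Length of the longest contiguous run of ``letter``; 0 if absent."""
    s = seq.sequence if isinstance(seq, IDRSegment) else seq
    if not s:
        raise ValueError("empty sequence")
    letter = letter.upper()
    best = run = 0
    for aa in s.upper():
        run = run + 1 if aa == letter else 0
        best = max(best, run)
    return best


def has_helix_element(
    track: ResidueTrack,
    segment: IDRSegment,
    config: HelixElementConfig = HelixElementConfig(),
) -> bool:
    """True iff the segment contains >= min_run consecutive residues whose
    helix propensity is strictly above the cutoff."""
    if track.kind != "helix":
        raise ValueError(f"expected a helix track, got kind={track.kind!r}")
    if segment.end > len(track):
        raise ValueError(
            f"{segment.accession}: helix track length {len(track)} does not "
            f"cover segment end {segment.end}"
        )
    window = track.values[segment.start - 1 : segment.end]
    run = 0
    for v in window:
        run = run + 1 if v > config.cutoff else 0
        if run >= config.min_run:
            return True
    return False


def score_segments(
    segments: Iterable[IDRSegment],
    table: ScoreTable,
    helix_tracks: Mapping[str, ResidueTrack] | None = None,
    helix_config: HelixElementConfig = HelixElementConfig(),
) -> pd.DataFrame:
    """Per-IDR result table: one row per segment.

    Columns: accession, start, end, length, max_score, longest_A_run, and
    has_helix_element (pandas NA where no helix track is available).
    """
    rows = []
    for seg in segments:
        helix: bool | None = None
        if helix_tracks is not None and seg.accession in helix_tracks:
            helix = has_helix_element(helix_tracks[seg.accession], seg, helix_config)
        rows.append(
            {
                "accession": seg.accession,
                "start": seg.start,
                "end": seg.end,
                "length": seg.length,
                "max_score": max_polyala_score(seg, table),
                "longest_A_run": longest_homorepeat(seg, "A"),
                "has_helix_element": helix,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["accession", "start", "end", "length", "max_score",
                 "longest_A_run", "has_helix_element"],
    )
    df["has_helix_element"] = df["has_helix_element"].astype("boolean")
    return df
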