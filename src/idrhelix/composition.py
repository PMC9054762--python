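"""Amino-acid composition profiles and set differences in prion order.

Used to compare paralog IDR sets: per-letter fractions are pooled over all
sequences in a set, differences between two sets are reported with the
letters sorted from most to least prion-promoting, and letters too rare to
be informative (fewer than ``low_count_min`` occurrences in either set) are
masked but still reported.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .io import CANONICAL_AA


@dataclass(frozen=True)
class CompositionProfile:
    """Pooled residue counts and fractions over the 20 canonical letters.

    Non-canonical letters (X, B, Z, U) are pooled under ``other_count`` and
    excluded from the fraction denominator.
    """

    set_label: str
    counts: dict[str, int]
    fractions: dict[str, float]
    total_residues: int
    other_count: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1 over canonical letters")
        if sum(self.counts.values()) != self.total_residues:
            raise ValueError("counts must sum to total_residues")


@dataclass(frozen=True)
class PrionOrder:
    """The 20 canonical letters ordered most prion-promoting first."""

    order: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if sorted(self.order) != sorted(CANONICAL_AA):
            raise ValueError("order must be a permutation of the 20 canonical letters")


def default_prion_order() -> PrionOrder:
    from importlib.resources import files

    doc = yaml.safe_load((files("idrhelix.data") / "prion_order.yaml").read_text())
    return PrionOrder(tuple(doc["order"]), source=str(doc.get("source", "")))


def composition(seqs: Iterable[str], set_label: str = "") -> CompositionProfile:
    """Pooled composition of a collection of sequences (order-insensitive)."""
    counter: Counter[str] = Counter()
    n_seqs = 0
    for s in seqs:
        n_seqs += 1
        counter.update(s.upper())
    if n_seqs == 0:
        raise ValueError("empty sequence collection")
    counts = {aa: counter.get(aa, 0) for aa in CANONICAL_AA}
    other = sum(n for aa, n in counter.items() if aa not in CANONICAL_AA)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no canonical residues in collection")
    fractions = {aa: n / total for aa, n in counts.items()}
    return CompositionProfile(set_label, counts, fractions, total, other)


@dataclass(frozen=True)
class CompositionDifference:
    """Per-letter fraction differences between two sets, in prion order.

    ``masked`` flags letters occurring fewer than the low-count minimum
    times in either set; their differences are still reported.
    """

    label_a: str
    label_b: str
    ordering: PrionOrder
    differences: dict[str, float]
    masked: dict[str, bool]
    low_count_min: int

    def __post_init__(self) -> None:
        if abs(sum(self.differences.values())) > 1e-9:
            raise ValueError("fraction differences must sum to zero")

    def to_frame(self, a: CompositionProfile | None = None,
                 b: CompositionProfile | None = None) -> pd.DataFrame:
        rows = []
        for aa in self.ordering.order:
            row = {"letter": aa, "diff": self.differences[aa],
                   "masked": self.masked[aa]}
            if a is not None and b is not None:
                row = {
                    "letter": aa,
                    "count_a": a.counts[aa], "count_b": b.counts[aa],
                    "frac_a": a.fractions[aa], "frac_b": b.fractions[aa],
                    "diff": self.differences[aa], "masked": self.masked[aa],
                }
            rows.append(row)
        return pd.DataFrame(rows)


def composition_difference(
    a: CompositionProfile,
    b: CompositionProfile,
    order: PrionOrder | None = None,
    low_count_min: int = 10,
) -> CompositionDifference:
    """fraction(a) - fraction(b) per letter, emitted in prion order.

    A letter is masked when its raw count is below ``low_count_min`` in
    either set (conservative: rare in one set is enough).
    """
    order = order or default_prion_order()
    diffs = {aa: a.fractions[aa] - b.fractions[aa] for aa in CANONICAL_AA}
    masked = {
        aa: (a.counts[aa] < low_count_min or b.counts[aa] < low_count_min)
        for aa in CANONICAL_AA
    }
    return CompositionDifference(a.set_label, b.set_label, order, diffs, masked,
                                 low_count_min)


def write_difference_tsv(
    diff: CompositionDifference,
    a: CompositionProfile,
    b: CompositionProfile,
    path: str | Path,
) -> None:
    diff.to_frame(a, b).to_csv(path, sep="\t", index=False)
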