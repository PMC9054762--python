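"""Secondary chemical shifts and referencing-robust helicity analysis.

Secondary chemical shifts are the deviations of measured backbone shifts
from random-coil reference values, Δδ = δ_obs − δ_rc. In a residual
α-helix, ΔδCα and ΔδC′ are positive and ΔδCβ negative; the per-residue
index ΔδCα − ΔδCβ (written ``dCAB`` in the tables here) cancels any
constant carbon referencing offset, making it robust to calibration error.
Variant-minus-wildtype differences of this index, Δ(ΔδCα − ΔδCβ), localize
helicity changes caused by deletions; amide differences (ΔδH, ΔδN) are
reported alongside. Missing assignments propagate as missing (NaN), never
as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CANONICAL_AA, SHIFT_ATOMS, ShiftTable

logger = logging.getLogger(__name__)

#: Canonical full-helix secondary-shift amplitudes (ppm): the expected Δδ
#: for a 100%-populated α-helix, used to convert a mean index into a
#: fractional helix population. Configurable wherever used.
FULL_HELIX_OFFSETS = {"CA": 2.8, "CB": -0.5, "C": 1.8, "H": -0.25, "N": -1.5}

_DELTA_COLS = ["dCA", "dCB", "dC", "dH", "dN", "dCAB"]
_ATOM_TO_COL = {"CA": "dCA", "CB": "dCB", "C": "dC", "H": "dH", "N": "dN"}


class RandomCoilTable:
    """Random-coil reference shifts per (residue, atom), a versioned table.

    Glycine has no CB entry and proline no amide H; lookups for those return
    None. Nearest-neighbor/temperature correction schemes can be supplied by
    loading a different table (the lookup interface is the hook).
    """

    def __init__(self, shifts: Mapping[tuple[str, str], float],
                 metadata: Mapping[str, str] | None = None) -> None:
        self._shifts = {(aa.upper(), atom.upper()): float(v)
                        for (aa, atom), v in shifts.items()}
        self.metadata = dict(metadata or {})
        for aa in CANONICAL_AA:
            for atom in SHIFT_ATOMS:
                if aa == "G" and atom == "CB":
                    continue
                if aa == "P" and atom == "H":
                    continue
                if (aa, atom) not in self._shifts:
                    raise ValueError(f"random-coil table incomplete: missing {aa}/{atom}")

    def get(self, residue_type: str, atom: str) -> float | None:
        return self._shifts.get((residue_type.upper(), atom.upper()))

    @classmethod
    def from_tsv(cls, path: str | Path, **metadata: str) -> "RandomCoilTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        shifts = {
            (str(r.residue), str(r.atom)): float(r.shift_ppm) for r in df.itertuples()
        }
        return cls(shifts, metadata)


def default_random_coil_table() -> RandomCoilTable:
    from importlib.resources import files

    return RandomCoilTable.from_tsv(
        files("idrhelix.data") / "random_coil_shifts.tsv",
        source="packaged default (disordered reference peptides)",
    )


@dataclass
class SecondaryShiftProfile:
    """Per-residue Δδ values for one construct.

    ``data`` is indexed by residue number with columns dCA, dCB, dC, dH,
    dN and dCAB (= dCA − dCB); NaN marks missing assignments.
    """

    construct_id: str
    data: pd.DataFrame
    sequence: str = ""

    def mean_helicity_index(self, window: tuple[int, int] | None = None) -> float:
        """Mean ΔδCα − ΔδCβ over ``window`` (1-based inclusive), NaN-aware."""
        d = self.data["dCAB"]
        if window is not None:
            d = d.loc[(d.index >= window[0]) & (d.index <= window[1])]
        return float(d.mean())


def secondary_shifts(
    observed: ShiftTable, sequence: str, rc: RandomCoilTable,
    first_residue: int = 1,
) -> SecondaryShiftProfile:
    """Δδ = observed − random-coil per residue and atom.

    ``sequence`` is the construct sequence with residue ``first_residue``
    at its first position (constructs are often numbered in parent-protein
    coordinates). Residue types in the shift table must match the sequence;
    a mismatch is an error naming the residue. ΔδCαβ is present only where
    both ΔδCα and ΔδCβ are (absent at glycines).
    """
    sequence = sequence.upper()
    rows = {}
    for idx in observed.residues():
        offset = idx - first_residue
        if not 0 <= offset < len(sequence):
            raise ValueError(
                f"{observed.construct_id}: residue {idx} outside the sequence "
                f"({first_residue}..{first_residue + len(sequence) - 1})"
            )
        rtype = observed.residue_types[idx]
        if sequence[offset] != rtype:
            raise ValueError(
                f"{observed.construct_id}: residue {idx} typed {rtype!r} in the "
                f"shift table but {sequence[offset]!r} in the sequence"
            )
        row = {col: np.nan for col in _DELTA_COLS}
        for atom, col in _ATOM_TO_COL.items():
            obs = observed.get(idx, atom)
            ref = rc.get(rtype, atom)
            if obs is not None and ref is not None:
                row[col] = obs - ref
        if not np.isnan(row["dCA"]) and not np.isnan(row["dCB"]):
            row["dCAB"] = row["dCA"] - row["dCB"]
        rows[idx] = row
    data = pd.DataFrame.from_dict(rows, orient="index", columns=_DELTA_COLS)
    data.index.name = "residue"
    return SecondaryShiftProfile(observed.construct_id, data.sort_index(), sequence)


# ---------------------------------------------------------------------------
# Variant vs wildtype


@dataclass
class VariantMap:
    """Residue correspondence between a deletion construct and wildtype.

    Built from the construct design (declared deleted wildtype ranges),
    not from sequence alignment: deletions are known exactly.
    """

    construct_id: str
    pairs: list[tuple[int, int]]  # (variant residue, wildtype residue)
    deleted_ranges: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = [p[0] for p in self.pairs]
        w = [p[1] for p in self.pairs]
        if sorted(v) != v or sorted(w) != w or len(set(v)) != len(v) or len(set(w)) != len(w):
            raise ValueError("mapping must be strictly increasing on both sides")
        deleted = set()
        for lo, hi in self.deleted_ranges:
            deleted.update(range(lo, hi + 1))
        if deleted & set(w):
            raise ValueError("deleted ranges overlap mapped wildtype residues")

    @classmethod
    def identity(cls, construct_id: str, start: int, end: int) -> "VariantMap":
        return cls(construct_id, [(i, i) for i in range(start, end + 1)])

    @classmethod
    def from_deletions(
        cls, construct_id: str, wt_start: int, wt_end: int,
        deletions: Sequence[tuple[int, int]],
        renumber: bool = False,
    ) -> "VariantMap":
        """Map built by deleting ``deletions`` (wildtype coords) from wildtype.

        With ``renumber=False`` the variant keeps wildtype numbering for the
        preserved residues (the usual convention for deletion constructs);
        with ``renumber=True`` variant residues are renumbered 1..n.
        """
        deleted = set()
        for lo, hi in deletions:
            deleted.update(range(lo, hi + 1))
        kept = [w for w in range(wt_start, wt_end + 1) if w not in deleted]
        pairs = [(w if not renumber else i + 1, w) for i, w in enumerate(kept)]
        return cls(construct_id, pairs, [tuple(d) for d in deletions])

    def wildtype_index(self, variant_residue: int) -> int | None:
        for v, w in self.pairs:
            if v == variant_residue:
                return w
        return None

    def adjacent_to_deletion(self, wt_residue: int) -> bool:
        return any(wt_residue == lo - 1 or wt_residue == hi + 1
                   for lo, hi in self.deleted_ranges)


@dataclass
class DeltaDeltaProfile:
    """Variant-minus-wildtype differences on mapped residues.

    ``data`` is indexed by wildtype residue number with columns ddCAB
    (Δ(ΔδCα − ΔδCβ)), ddH, ddN, and ``near_deletion`` flagging residues
    immediately flanking a deleted range (truncation-site effects are
    discounted in interpretation).
    """

    variant_id: str
    wildtype_id: str
    data: pd.DataFrame


def delta_delta(
    variant: SecondaryShiftProfile,
    wildtype: SecondaryShiftProfile,
    vmap: VariantMap,
) -> DeltaDeltaProfile:
    """Δ(ΔδCαβ) and amide ΔδH/ΔδN differences on mapped residues only.

    A residue contributes a difference only where both constructs carry the
    underlying value; variant residues with data but no mapping are excluded
    with a warning.
    """
    mapped_v = {v for v, _ in vmap.pairs}
    unmapped = [i for i in variant.data.index if i not in mapped_v]
    if unmapped:
        logger.warning(
            "%s: %d assigned residues not covered by the variant map (excluded)",
            variant.construct_id, len(unmapped),
        )
    rows = {}
    for v, w in vmap.pairs:
        if v not in variant.data.index or w not in wildtype.data.index:
            continue
        vr, wr = variant.data.loc[v], wildtype.data.loc[w]
        row = {
            "ddCAB": vr["dCAB"] - wr["dCAB"],
            "ddH": vr["dH"] - wr["dH"],
            "ddN": vr["dN"] - wr["dN"],
            "near_deletion": vmap.adjacent_to_deletion(w),
        }
        if all(np.isnan(x) for x in (row["ddCAB"], row["ddH"], row["ddN"])):
            continue
        rows[w] = row
    data = pd.DataFrame.from_dict(
        rows, orient="index", columns=["ddCAB", "ddH", "ddN", "near_deletion"]
    )
    data.index.name = "wt_residue"
    return DeltaDeltaProfile(variant.construct_id, wildtype.construct_id,
                             data.sort_index())


# ---------------------------------------------------------------------------
# Helicity ranking and population estimation


@dataclass(frozen=True)
class HelicityRanking:
    """Constructs ordered by mean helicity index over a window.

    ``groups`` lists tiers from most to least helical; constructs within a
    tier differ by less than the tolerance and are reported equivalent.
    """

    window: tuple[int, int]
    means: dict[str, float]
    groups: tuple[tuple[str, ...], ...]
    unranked: tuple[str, ...]
    tolerance: float

    @property
    def order(self) -> tuple[str, ...]:
        return tuple(c for g in self.groups for c in g)


def helicity_ranking(
    profiles: Mapping[str, SecondaryShiftProfile],
    window: tuple[int, int],
    maps: Mapping[str, VariantMap] | None = None,
    tolerance: float = 0.05,
) -> HelicityRanking:
    """Rank constructs by mean ΔδCα − ΔδCβ over a wildtype-coordinate window.

    Deletion constructs are projected through their :class:`VariantMap` so
    the window always refers to wildtype numbering. Constructs with no data
    in the window are flagged unranked. Means within ``tolerance`` (ppm) of
    the previous construct join its equivalence tier.
    """
    means: dict[str, float] = {}
    unranked: list[str] = []
    for cid, prof in profiles.items():
        if maps is not None and cid in maps:
            vmap = maps[cid]
            vals = [
                prof.data.loc[v, "dCAB"]
                for v, w in vmap.pairs
                if window[0] <= w <= window[1] and v in prof.data.index
            ]
            mean = float(np.nanmean(vals)) if vals else float("nan")
        else:
            mean = prof.mean_helicity_index(window)
        if np.isnan(mean):
            unranked.append(cid)
        else:
            means[cid] = mean
    ordered = sorted(means, key=lambda c: means[c], reverse=True)
    groups: list[list[str]] = []
    for cid in ordered:
        if groups and means[groups[-1][-1]] - means[cid] < tolerance:
            groups[-1].append(cid)
        else:
            groups.append([cid])
    return HelicityRanking(
        window=tuple(window),
        means=means,
        groups=tuple(tuple(g) for g in groups),
        unranked=tuple(unranked),
        tolerance=tolerance,
    )


def estimate_helix_population(
    profile: SecondaryShiftProfile,
    window: tuple[int, int] | None = None,
    full_helix_index: float | None = None,
) -> float:
    """Fractional helix population from the mean helicity index.

    p̂ = mean(ΔδCαβ) / (full-helix ΔδCα − ΔδCβ); the denominator defaults
    to the packaged full-helix amplitudes (2.8 − (−0.5) = 3.3 ppm).
    """
    if full_helix_index is None:
        full_helix_index = FULL_HELIX_OFFSETS["CA"] - FULL_HELIX_OFFSETS["CB"]
    return profile.mean_helicity_index(window) / full_helix_index


def combined_amide_csp(ddH: float, ddN: float, n_weight: float = 0.2) -> float:
    """Optional convenience: combined amide chemical-shift perturbation.

    sqrt(ΔδH² + (w·ΔδN)²) with the conventional nitrogen weight 0.2. The
    primary outputs keep ΔδH and ΔδN separate; this norm is provided only
    as a summary helper.
    """
    return float(np.sqrt(ddH**2 + (n_weight * ddN) ** 2))


def write_profile_tsv(profile: SecondaryShiftProfile, path: str | Path) -> None:
    profile.data.to_csv(path, sep="\t", na_rep="NA")
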