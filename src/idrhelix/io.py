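"""Sequence, track, set-list and chemical-shift I/O.

Coordinate convention: residue positions are 1-based and inclusive at every
interface of this package (matching the "residues 237-362" style of numbering
used for protein constructs). Internal 0-based slicing never leaks into
outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, one-letter codes.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Accepted sequence alphabet: canonical residues plus ambiguity codes
#: (B, Z, X) and selenocysteine (U), all of which occur in real proteome FASTA.
ALLOWED_AA = CANONICAL_AA + "BZXU"

#: Backbone atoms used in secondary chemical-shift analysis. "C" is the
#: carbonyl carbon (C'); aliases accepted on input are mapped onto these.
SHIFT_ATOMS = ("H", "N", "CA", "CB", "C")

_ATOM_ALIASES = {
    "H": "H", "HN": "H",
    "N": "N",
    "CA": "CA",
    "CB": "CB",
    "C": "C", "CO": "C", "C'": "C", "CPRIME": "C",
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class SequenceFormatError(ValueError):
    """Raised when an input file violates the format contracts."""


@dataclass
class ProteinRecord:
    """One protein sequence with its accession and set membership labels.

    ``set_labels`` records which analysis sets the protein belongs to
    (e.g. ``"proteome"``, ``"RBP"``, ``"mRBP"``).
    """

    accession: str
    sequence: str
    description: str = ""
    set_labels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise SequenceFormatError(f"record {self.accession!r}: empty sequence")
        for i, ch in enumerate(self.sequence, start=1):
            if ch not in ALLOWED_AA:
                raise SequenceFormatError(
                    f"record {self.accession!r}: illegal character {ch!r} "
                    f"at position {i}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ResidueTrack:
    """A per-residue score track (disorder or helix propensity) in [0, 1]."""

    accession: str
    kind: str  # "disorder" | "helix"
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("disorder", "helix"):
            raise ValueError(f"unknown track kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError(f"track {self.accession}: values must be a non-empty 1-D array")
        bad = np.flatnonzero((self.values < 0.0) | (self.values > 1.0))
        if bad.size:
            raise SequenceFormatError(
                f"track {self.accession}: value {self.values[bad[0]]!r} at "
                f"position {bad[0] + 1} outside [0, 1]"
            )

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class ShiftTable:
    """Assigned backbone chemical shifts for one construct.

    At most one value per (residue index, atom); the residue type at a given
    index must be consistent across atoms.
    """

    construct_id: str
    shifts: dict[tuple[int, str], float] = field(default_factory=dict)
    residue_types: dict[int, str] = field(default_factory=dict)

    def add(self, residue_index: int, residue_type: str, atom: str, shift: float) -> None:
        residue_type = residue_type.upper()
        atom = _ATOM_ALIASES.get(atom.upper())
        if atom is None:
            raise ValueError(f"atom not in {SHIFT_ATOMS}")
        known = self.residue_types.get(residue_index)
        if known is not None and known != residue_type:
            raise SequenceFormatError(
                f"{self.construct_id}: residue {residue_index} typed both "
                f"{known!r} and {residue_type!r}"
            )
        key = (residue_index, atom)
        if key in self.shifts and not np.isclose(self.shifts[key], shift):
            raise SequenceFormatError(
                f"{self.construct_id}: conflicting values for residue "
                f"{residue_index} atom {atom}: {self.shifts[key]} vs {shift}"
            )
        self.residue_types[residue_index] = residue_type
        self.shifts[key] = float(shift)

    def get(self, residue_index: int, atom: str) -> float | None:
        return self.shifts.get((residue_index, atom))

    def residues(self) -> list[int]:
        return sorted(self.residue_types)

    def __len__(self) -> int:
        return len(self.shifts)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "construct_id": self.construct_id,
                "residue_index": idx,
                "residue_type": self.residue_types[idx],
                "atom": atom,
                "shift_ppm": val,
            }
            for (idx, atom), val in sorted(self.shifts.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["construct_id", "residue_index", "residue_type", "atom", "shift_ppm"],
        )


# ---------------------------------------------------------------------------
# FASTA


def _accession_from_header(header_id: str) -> str:
    # UniProt-style "db|ACC|NAME" headers; otherwise the first token is the id.
    parts = header_id.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return header_id.split()[0]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Accessions are taken from UniProt-style ``db|ACC|NAME`` headers when
    present, otherwise from the first whitespace-delimited header token.
    Duplicate accessions and illegal sequence characters are errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = _accession_from_header(rec.id)
        records.append(ProteinRecord(acc, str(rec.seq), description=rec.description))
        seen[acc] = seen.get(acc, 0) + 1
    if not records:
        raise SequenceFormatError(f"{path}: no FASTA records found")
    dups = sorted(a for a, n in seen.items() if n > 1)
    if dups:
        raise SequenceFormatError(f"{path}: duplicate accessions: {', '.join(dups)}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description or "")
        for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Per-residue tracks


def read_track(path: str | Path, kind: str) -> dict[str, ResidueTrack]:
    """Read a 3-column TSV (accession, position, value) into tracks.

    Positions must be contiguous from 1 within each accession; values must
    lie in [0, 1]. Returns a dict keyed by accession.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"accession", "position", "value"}
    if not required.issubset(df.columns):
        raise SequenceFormatError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    tracks: dict[str, ResidueTrack] = {}
    for acc, sub in df.groupby("accession", sort=False):
        pos = sub["position"].to_numpy(dtype=int)
        order = np.argsort(pos)
        pos = pos[order]
        expected = np.arange(1, pos.size + 1)
        if not np.array_equal(pos, expected):
            missing = sorted(set(expected) - set(pos))
            where = missing[0] if missing else int(pos[0])
            raise SequenceFormatError(
                f"{path}: track {acc}: positions not contiguous from 1 "
                f"(first problem at position {where})"
            )
        values = sub["value"].to_numpy(dtype=float)[order]
        tracks[str(acc)] = ResidueTrack(str(acc), kind, values)
    if not tracks:
        raise SequenceFormatError(f"{path}: no track rows found")
    return tracks


def write_track(tracks: Iterable[ResidueTrack], path: str | Path) -> None:
    frames = []
    for t in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "accession": t.accession,
                    "position": np.arange(1, len(t) + 1),
                    "value": t.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Set-membership lists


def read_set_list(
    path: str | Path, label: str, records: Sequence[ProteinRecord]
) -> tuple[int, list[str]]:
    """Label records listed (one accession per line) in ``path``.

    Returns ``(n_matched, unmatched)``; unmatched accessions are reported,
    never silently dropped. Blank lines and ``#`` comments are ignored.
    """
    by_acc = {r.accession: r for r in records}
    matched = 0
    unmatched: list[str] = []
    for line in Path(path).read_text().splitlines():
        acc = line.strip()
        if not acc or acc.startswith("#"):
            continue
        rec = by_acc.get(acc)
        if rec is None:
            unmatched.append(acc)
        else:
            rec.set_labels.add(label)
            matched += 1
    return matched, unmatched


# ---------------------------------------------------------------------------
# Chemical-shift tables


def read_shift_table(
    path: str | Path, dialect: str = "tsv", construct_id: str | None = None
) -> ShiftTable:
    """Read an assigned chemical-shift table.

    ``dialect="tsv"``: columns construct_id, residue_index, residue_type,
    atom, shift_ppm. ``dialect="nmrstar_like"``: a minimal NMR-STAR-style
    ``_Atom_chem_shift`` loop as exported from BMRB entries. Atoms outside
    the backbone set (H, N, CA, CB, C') are skipped with a logged warning.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_shift_tsv(path, construct_id)
    if dialect == "nmrstar_like":
        return _read_shift_star(path, construct_id)
    raise ValueError(f"unknown shift-table dialect {dialect!r}")


def _coerce_rows(
    rows: Iterable[tuple[int, str, str, float]], construct_id: str
) -> ShiftTable:
    table = ShiftTable(construct_id)
    for idx, rtype, atom, shift in rows:
        if _ATOM_ALIASES.get(atom.upper()) is None:
            logger.warning(
                "%s: skipping atom %r at residue %d (not a backbone shift atom)",
                construct_id, atom, idx,
            )
            continue
        table.add(idx, rtype, atom, shift)
    return table


def _read_shift_tsv(path: Path, construct_id: str | None) -> ShiftTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"construct_id", "residue_index", "residue_type", "atom", "shift_ppm"}
    if not required.issubset(df.columns):
        raise SequenceFormatError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    ids = df["construct_id"].unique().tolist()
    if construct_id is None:
        if len(ids) != 1:
            raise SequenceFormatError(
                f"{path}: multiple construct_ids {ids}; pass construct_id explicitly"
            )
        construct_id = str(ids[0])
    else:
        df = df[df["construct_id"] == construct_id]
        if df.empty:
            raise SequenceFormatError(f"{path}: no rows for construct {construct_id!r}")
    rows = (
        (int(r.residue_index), str(r.residue_type), str(r.atom), float(r.shift_ppm))
        for r in df.itertuples()
    )
    return _coerce_rows(rows, construct_id)


def _read_shift_star(path: Path, construct_id: str | None) -> ShiftTable:
    """Parse a minimal NMR-STAR-like ``_Atom_chem_shift`` loop.

    Recognizes the Seq_ID / Comp_ID / Atom_ID / Val tags in any order; other
    tags in the loop are ignored. Comp_ID may be one- or three-letter.
    """
    tags: list[str] = []
    rows: list[tuple[int, str, str, float]] = []
    in_loop = False
    reading_rows = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "loop_":
            in_loop, reading_rows, tags = True, False, []
            continue
        if line in ("stop_", "save_"):
            in_loop = reading_rows = False
            continue
        if in_loop and line.startswith("_"):
            tags.append(line.split(".")[-1])
            continue
        if in_loop and tags:
            reading_rows = True
        if reading_rows and {"Seq_ID", "Comp_ID", "Atom_ID", "Val"}.issubset(tags):
            fields = line.split()
            if len(fields) < len(tags):
                continue
            row = dict(zip(tags, fields))
            comp = row["Comp_ID"].upper()
            rtype = _THREE_TO_ONE.get(comp, comp if len(comp) == 1 else None)
            if rtype is None:
                raise SequenceFormatError(f"{path}: unknown residue type {comp!r}")
            rows.append((int(row["Seq_ID"]), rtype, row["Atom_ID"], float(row["Val"])))
    if not rows:
        raise SequenceFormatError(f"{path}: no _Atom_chem_shift rows found")
    return _coerce_rows(rows, construct_id or path.stem)


def write_shift_table(table: ShiftTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)
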