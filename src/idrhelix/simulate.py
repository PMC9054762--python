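"""Synthetic proteomes and chemical-shift sets with known ground truth.

The proteome generator emulates the statistical structure the scoring
pipeline is meant to detect: proteins with one long disordered region each,
a controlled fraction of which carry a planted polyalanine stretch
(optionally interrupted by a single breaker residue, mirroring the
continuous-vs-interrupted tract contrast between paralogs), with disorder
and helix-propensity tracks matched to the plants. The shift generator
implements the linear model observed = random-coil + p·(full-helix offset)
+ Gaussian noise inside a helical span.

All generators are pure functions of (spec, seed); truth tables suffice to
compute every downstream expected statistic by direct counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CANONICAL_AA, ProteinRecord, ResidueTrack, ShiftTable, write_fasta, write_track
from .nmr import FULL_HELIX_OFFSETS, RandomCoilTable

_LETTERS = np.array(list(CANONICAL_AA))


@dataclass(frozen=True)
class ProteomeSpec:
    """Parameters of a synthetic proteome.

    ``idr_fraction`` is the fraction of proteins bearing an IDR;
    ``planted_stretch_rate`` the fraction of IDR-bearing proteins given a
    polyalanine stretch, so the protein-level planted prevalence is their
    product. Background composition is uniform over the 20 canonical
    letters, which keeps planted-signal arithmetic exact; disorder values
    sit in well-separated bands around the 0.5 cutoff (disordered
    U(0.6, 1.0), ordered U(0.0, 0.4)) unless ``adversarial`` asks for
    values straddling the cutoff.
    """

    n_proteins: int = 10_000
    min_length: int = 120
    max_length: int = 300
    idr_fraction: float = 1.0
    idr_min_len: int = 45
    idr_max_len: int = 90
    planted_stretch_rate: float = 0.3
    stretch_min_len: int = 8
    stretch_max_len: int = 8
    interruption_rate: float = 0.0
    breaker: str = "V"
    adversarial: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("idr_fraction", "planted_stretch_rate", "interruption_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.stretch_min_len < 1 or self.stretch_max_len < self.stretch_min_len:
            raise ValueError("bad stretch length bounds")
        if self.idr_min_len < 1 or self.idr_max_len < self.idr_min_len:
            raise ValueError("bad IDR length bounds")
        if self.stretch_max_len > self.idr_min_len:
            raise ValueError("infeasible spec: stretch may exceed the IDR that holds it")
        if self.idr_max_len > self.min_length:
            raise ValueError("infeasible spec: IDR may exceed protein length")


@dataclass
class SyntheticProteome:
    """Generated records, matched tracks, and the plant truth table."""

    records: list[ProteinRecord]
    disorder_tracks: dict[str, ResidueTrack]
    helix_tracks: dict[str, ResidueTrack]
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, outdir / "proteome.fasta")
        write_track(self.disorder_tracks.values(), outdir / "disorder.tsv")
        write_track(self.helix_tracks.values(), outdir / "helix.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def gen_proteome(spec: ProteomeSpec) -> SyntheticProteome:
    """Generate a proteome with planted polyalanine stretches inside IDRs.

    Truth-table columns: accession, length, idr_start/idr_end (1-based
    inclusive, 0/0 when the protein has no IDR), plant_start, plant_len
    (0 when nothing planted) and interrupted.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    disorder: dict[str, ResidueTrack] = {}
    helix: dict[str, ResidueTrack] = {}
    truth_rows = []
    lo_band = (0.45, 0.4999) if spec.adversarial else (0.0, 0.4)
    hi_band = (0.5, 0.55) if spec.adversarial else (0.6, 1.0)
    for i in range(spec.n_proteins):
        acc = f"SYN{i:05d}"
        length = int(rng.integers(spec.min_length, spec.max_length + 1))
        seq = _LETTERS[rng.integers(0, 20, size=length)]
        dvals = rng.uniform(*lo_band, size=length)
        hvals = rng.uniform(0.0, 0.4, size=length)
        idr_start = idr_end = plant_start = plant_len = 0
        interrupted = False
        if rng.random() < spec.idr_fraction:
            idr_len = int(rng.integers(spec.idr_min_len, spec.idr_max_len + 1))
            s0 = int(rng.integers(0, length - idr_len + 1))  # 0-based
            dvals[s0 : s0 + idr_len] = rng.uniform(*hi_band, size=idr_len)
            # keep the IDR maximal: flanking residues stay in the ordered band
            if s0 > 0:
                dvals[s0 - 1] = lo_band[0]
            if s0 + idr_len < length:
                dvals[s0 + idr_len] = lo_band[0]
            idr_start, idr_end = s0 + 1, s0 + idr_len
            if rng.random() < spec.planted_stretch_rate:
                plant_len = int(rng.integers(spec.stretch_min_len, spec.stretch_max_len + 1))
                p0 = s0 + int(rng.integers(0, idr_len - plant_len + 1))
                seq[p0 : p0 + plant_len] = "A"
                hvals[p0 : p0 + plant_len] = rng.uniform(0.85, 1.0, size=plant_len)
                plant_start = p0 + 1
                if rng.random() < spec.interruption_rate:
                    seq[p0 + plant_len // 2] = spec.breaker
                    interrupted = True
        records.append(ProteinRecord(acc, "".join(seq.tolist())))
        disorder[acc] = ResidueTrack(acc, "disorder", dvals)
        helix[acc] = ResidueTrack(acc, "helix", hvals)
        truth_rows.append(
            {
                "accession": acc, "length": length,
                "idr_start": idr_start, "idr_end": idr_end,
                "plant_start": plant_start, "plant_len": plant_len,
                "interrupted": interrupted,
            }
        )
    return SyntheticProteome(records, disorder, helix, pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# Synthetic chemical-shift sets


@dataclass(frozen=True)
class ShiftSimSpec:
    """Linear secondary-shift model: rc + p·offset inside the span + noise."""

    construct_id: str
    sequence: str
    helix_span: tuple[int, int]  # 1-based inclusive, in construct numbering
    helix_population: float = 0.4
    offsets: dict[str, float] = field(default_factory=lambda: dict(FULL_HELIX_OFFSETS))
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"CA": 0.05, "CB": 0.05, "C": 0.05, "H": 0.01, "N": 0.05}
    )
    missing_rate: float = 0.0
    first_residue: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.helix_population <= 1.0:
            raise ValueError("helix_population must lie in [0, 1]")
        lo, hi = self.helix_span
        last = self.first_residue + len(self.sequence) - 1
        if not self.first_residue <= lo <= hi <= last:
            raise ValueError("helix_span must lie within the sequence")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


def gen_shift_set(spec: ShiftSimSpec, rc: RandomCoilTable) -> ShiftTable:
    """Simulate an assigned shift table under the linear helix model.

    Inside ``helix_span`` each atom's shift is rc + p·offset + noise;
    outside, rc + noise. A ``missing_rate`` fraction of assignments is
    dropped at random to emulate missing peaks.
    """
    rng = np.random.default_rng(spec.seed)
    table = ShiftTable(spec.construct_id)
    lo, hi = spec.helix_span
    for offset_i, aa in enumerate(spec.sequence.upper()):
        idx = spec.first_residue + offset_i
        for atom in ("H", "N", "CA", "CB", "C"):
            ref = rc.get(aa, atom)
            if ref is None:
                continue
            value = ref + rng.normal(0.0, spec.noise_sd.get(atom, 0.0))
            if lo <= idx <= hi:
                value += spec.helix_population * spec.offsets.get(atom, 0.0)
            if spec.missing_rate and rng.random() < spec.missing_rate:
                continue
            table.add(idx, aa, atom, value)
    return table
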