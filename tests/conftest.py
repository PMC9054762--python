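import numpy as np
import pytest

from idrhelix import (
    IDRSegment,
    ProteinRecord,
    ResidueTrack,
    ScoreTable,
    default_random_coil_table,
)


@pytest.fixture(scope="session")
def rc_table():
    return default_random_coil_table()


@pytest.fixture
def ala_table():
    """Score table where only alanine is positive (A = 0.5)."""
    return ScoreTable("ala-only", {"A": 0.5}, version="test")


@pytest.fixture
def helix_table():
    """Alanine plus smaller weights for M/L/Q, as in the shipped default."""
    return ScoreTable("helix", {"A": 0.5, "M": 0.3, "L": 0.3, "Q": 0.2}, version="test")


def make_segment(sequence: str, accession: str = "P1", start: int = 1) -> IDRSegment:
    return IDRSegment(accession, start, start + len(sequence) - 1, sequence)


@pytest.fixture
def segment_factory():
    return make_segment


@pytest.fixture
def two_protein_fasta(tmp_path):
    path = tmp_path / "two.fasta"
    path.write_text(">sp|P1|X first protein\nMAPAG\n>sp|P2|Y second\nGGAAG\n")
    return path


def write_track_tsv(tmp_path, rows, name="track.tsv"):
    path = tmp_path / name
    lines = ["accession\tposition\tvalue"]
    lines += [f"{a}\t{p}\t{v}" for a, p, v in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def track_writer(tmp_path):
    return lambda rows, name="track.tsv": write_track_tsv(tmp_path, rows, name)


def random_disorder_track(rng: np.random.Generator, accession: str, length: int) -> ResidueTrack:
    return ResidueTrack(accession, "disorder", rng.random(length))


@pytest.fixture
def random_record():
    from idrhelix.io import CANONICAL_AA

    def make(rng: np.random.Generator, length: int, accession: str = "R1") -> ProteinRecord:
        letters = np.array(list(CANONICAL_AA))
        return ProteinRecord(accession, "".join(letters[rng.integers(0, 20, length)]))

    return make
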