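"""Sequence input/output, one-hot encoding and scanning windows.

DNA sequences are normalized to the five-letter alphabet {A, C, G, T, N}:
lowercase is upper-cased and every IUPAC ambiguity code other than A/C/G/T
collapses to N.  One-hot matrices are 4 x L with fixed row order (A, C, G, T);
an N column is all zeros, so ambiguous positions contribute nothing to any
convolution.  Long sequences are cut into fixed-length windows (default
1024 bp, shifted by 500 bp) before being fed to the feature-extraction CNN.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

ALPHABET = "ACGT"
WINDOW_LENGTH = 1024
WINDOW_STRIDE = 500

# residue byte -> row index; N and every other IUPAC code -> -1 (zero column)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _BASE_INDEX[ord(_b)] = _i

_NORMALIZE = bytes(
    ord(chr(i).upper()) if chr(i).upper() in "ACGTN" else ord("N") for i in range(256)
)


def normalize_residues(raw: str) -> str:
    """Uppercase and map non-ACGT symbols (IUPAC ambiguity codes etc.) to N."""
    return raw.encode("ascii", errors="replace").translate(_NORMALIZE).decode("ascii")


@dataclass(frozen=True)
class DnaSequence:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - set("ACGTN")
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains unnormalized symbols {sorted(bad)}; "
                "use DnaSequence.from_raw or read_fasta"
            )

    @classmethod
    def from_raw(cls, id: str, raw: str) -> "DnaSequence":
        return cls(id=id, residues=normalize_residues(raw))

    @property
    def length(self) -> int:
        return len(self.residues)

    def gc_fraction(self) -> float:
        s = self.residues
        return (s.count("G") + s.count("C")) / len(s)


@dataclass
class WindowSet:
    """Fixed-length scanning windows of one sequence, one-hot encoded.

    ``matrices`` has shape (n_windows, 4, window_length).  For a sequence
    shorter than ``window_length`` there is exactly one window, right-padded
    with all-zero columns.
    """

    source_id: str
    matrices: np.ndarray
    starts: list[int] = field(default_factory=list)
    window_length: int = WINDOW_LENGTH
    stride: int = WINDOW_STRIDE

    def __len__(self) -> int:
        return self.matrices.shape[0]


def one_hot_encode(seq: DnaSequence | str) -> np.ndarray:
    """Encode a sequence as a 4 x L {0,1} matrix, row order (A, C, G, T)."""
    residues = seq.residues if isinstance(seq, DnaSequence) else seq
    if not residues:
        raise ValueError("cannot one-hot encode an empty sequence")
    idx = _BASE_INDEX[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    mat = np.zeros((4, len(residues)), dtype=np.float32)
    cols = np.nonzero(idx >= 0)[0]
    mat[idx[cols], cols] = 1.0
    return mat


def decode_one_hot(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; all-zero columns decode to N."""
    letters = np.array(list(ALPHABET + "N"))
    idx = np.where(mat.sum(axis=0) == 0, 4, mat.argmax(axis=0))
    return "".join(letters[idx])


def make_windows(
    seq: DnaSequence,
    window_length: int = WINDOW_LENGTH,
    stride: int = WINDOW_STRIDE,
) -> WindowSet:
    """Cut ``seq`` into one-hot windows: starts 0, stride, 2*stride, ...

    A trailing remainder shorter than ``window_length`` is discarded; a
    sequence shorter than ``window_length`` yields a single zero-padded
    window at start 0.
    """
    if window_length < 1 or stride < 1:
        raise ValueError("window_length and stride must be >= 1")
    full = one_hot_encode(seq)
    length = seq.length
    if length < window_length:
        mat = np.zeros((1, 4, window_length), dtype=np.float32)
        mat[0, :, :length] = full
        return WindowSet(seq.id, mat, [0], window_length, stride)
    starts = list(range(0, length - window_length + 1, stride))
    mats = np.stack([full[:, s : s + window_length] for s in starts])
    return WindowSet(seq.id, mats, starts, window_length, stride)


def _open_text(path: Path) -> Iterator[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:  # type: ignore[operator]
        yield from fh


def read_fasta(path: str | Path) -> list[DnaSequence]:
    """Read a (possibly gzipped) FASTA file into normalized sequences.

    Ids are taken from the header up to the first whitespace.  An empty
    record is a validation error naming the offending id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[DnaSequence] = []
    current_id: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if current_id is None:
            return
        if not chunks or not "".join(chunks):
            raise ValueError(f"FASTA record {current_id!r} has an empty sequence")
        records.append(DnaSequence.from_raw(current_id, "".join(chunks)))

    for line in _open_text(path):
        line = line.rstrip()
        if not line:
            continue
        if line.startswith(">"):
            _flush()
            current_id = line[1:].split()[0] if line[1:].split() else ""
            if not current_id:
                raise ValueError("FASTA header with empty id")
            chunks = []
        else:
            if current_id is None:
                raise ValueError(f"{path}: sequence data before first header")
            chunks.append(line)
    _flush()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, sequences: list[DnaSequence], width: int = 80) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, seq.length, width):
                fh.write(seq.residues[i : i + width] + "\n")
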