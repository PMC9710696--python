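"""k-mer frequency profiles — the conventional composition baseline.

Counts every length-k substring at offsets 0..L-k (shift-by-one scanning)
on the given strand only, skips windows containing N, and normalizes by the
number of counted windows.  Profiles are indexed in lexicographic order
over (A, C, G, T), so e.g. AAA is index 0 for k = 3.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .seqio import ALPHABET, DnaSequence, _BASE_INDEX


@dataclass
class KmerProfile:
    """Normalized k-mer frequencies of one sequence.

    ``all_invalid`` flags the degenerate case where every window contained
    an N; the profile is then all zeros instead of summing to 1.
    """

    k: int
    values: np.ndarray  # length 4**k
    source_id: str
    all_invalid: bool = False


def kmer_names(k: int) -> list[str]:
    """The 4**k k-mers in lexicographic (A, C, G, T) order."""
    return ["".join(p) for p in itertools.product(ALPHABET, repeat=k)]


def kmer_profile(seq: DnaSequence, k: int) -> KmerProfile:
    """Frequency of each k-mer among the N-free windows of ``seq``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if seq.length < k:
        raise ValueError(
            f"sequence {seq.id!r} of length {seq.length} is shorter than k={k}"
        )
    codes = _BASE_INDEX[np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)]
    codes = codes.astype(np.int64)
    windows = sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return KmerProfile(k, np.zeros(4**k), seq.id, all_invalid=True)
    powers = 4 ** np.arange(k - 1, -1, -1)
    indices = windows[valid] @ powers
    counts = np.bincount(indices, minlength=4**k).astype(float)
    return KmerProfile(k, counts / counts.sum(), seq.id)


def kmer_table(sequences: list[DnaSequence], k: int) -> tuple[list[str], np.ndarray]:
    """Stack per-sequence profiles into (ids, matrix) for the binning step."""
    ids, rows = [], []
    for seq in sequences:
        prof = kmer_profile(seq, k)
        ids.append(prof.source_id)
        rows.append(prof.values)
    return ids, np.vstack(rows)
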