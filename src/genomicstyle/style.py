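"""Genomic style: Gram matrices of CNN feature maps as sequence features.

For a layer-``l`` feature-map matrix F with N_l maps of M_l positions, the
style matrix is the Gram matrix G[i, j] = sum_k F[i, k] * F[j, k] — the
inner product between the i-th and j-th feature maps.  G discards where
along the window a filter fired and keeps only how strongly filters co-fire,
which is the formal sense in which "style" (composition, texture) is
separated from "content" (positional arrangement).

A sequence longer than one window is scanned (1024 bp windows, 500 bp
shift); the per-window Gram matrices are averaged elementwise, and the rows
of the averaged matrix are listed in order to form the style vector used
for clustering.  Coverage, when available, is appended as one extra
dimension after a dataset-level scale adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .feature_cnn import FeatureCnn
from .seqio import WINDOW_LENGTH, WINDOW_STRIDE, DnaSequence, make_windows


@dataclass
class StyleVector:
    """Row-listed, window-averaged style matrix of one sequence."""

    layer: int
    values: np.ndarray  # flat, length N_l**2
    source_id: str
    n_windows_averaged: int


@dataclass
class CoverageScaleStats:
    """Dataset-level calibration for the coverage dimension.

    ``style_sd`` is the mean per-dimension standard deviation of the
    dataset's style vectors; the appended coverage entry is the coverage
    z-score times this scale, so one unit of coverage spread is worth about
    one unit of style spread.
    """

    mean_cov: float
    sd_cov: float
    style_sd: float


def gram(feature_map_matrix: np.ndarray) -> np.ndarray:
    """Style (Gram) matrix of an N_l x M_l feature-map matrix.

    No normalization by the map size: windows at one layer share one M_l, so
    averaging across windows stays well-defined.  Accumulates in float64.
    """
    F = np.asarray(feature_map_matrix, dtype=np.float64)
    if F.ndim != 2 or F.shape[0] < 1 or F.shape[1] < 1:
        raise ValueError("feature_map_matrix must be a nonempty 2-D array")
    return F @ F.T


def normalized_gram(feature_map_matrix: np.ndarray) -> np.ndarray:
    """Gram matrix divided by N_l * M_l (optional experimentation variant)."""
    F = np.asarray(feature_map_matrix, dtype=np.float64)
    return gram(F) / (F.shape[0] * F.shape[1])


def _layer_maps_for_windows(
    model: FeatureCnn, seq: DnaSequence, layer: int,
    window_length: int, stride: int, batch_size: int = 64,
) -> np.ndarray:
    """(n_windows, N_l, M_l) post-ReLU feature maps of module ``layer``."""
    n_layers = len(model.convs)
    if not 1 <= layer <= n_layers:
        raise ValueError(f"layer must be in 1..{n_layers}, got {layer}")
    ws = make_windows(seq, window_length=window_length, stride=stride)
    chunks = []
    for start in range(0, len(ws), batch_size):
        _, maps = model.forward(
            ws.matrices[start : start + batch_size], train=False, upto_layer=layer
        )
        chunks.append(maps[layer - 1])
    return np.concatenate(chunks, axis=0)


def style_of_sequence(
    model: FeatureCnn,
    seq: DnaSequence,
    layer: int,
    window_length: int = WINDOW_LENGTH,
    stride: int = WINDOW_STRIDE,
) -> StyleVector:
    """Window-averaged layer-``layer`` style vector of one sequence.

    Each 1024 bp window yields one Gram matrix; their elementwise mean is
    the sequence's style matrix, vectorized by listing rows in order.
    """
    maps = _layer_maps_for_windows(model, seq, layer, window_length, stride)
    maps64 = np.ascontiguousarray(maps, dtype=np.float64)
    grams = maps64 @ maps64.transpose(0, 2, 1)  # per-window Gram matrices
    mean_gram = grams.mean(axis=0)
    return StyleVector(
        layer=layer,
        values=mean_gram.reshape(-1),
        source_id=seq.id,
        n_windows_averaged=maps.shape[0],
    )


def feature_map_vector(
    model: FeatureCnn,
    seq: DnaSequence,
    layer: int,
    window_length: int = WINDOW_LENGTH,
    stride: int = WINDOW_STRIDE,
) -> StyleVector:
    """Window-averaged *flattened feature maps* (no Gram) — the contrast
    feature: position-resolved activations used directly as a clustering
    feature, which the style construction is designed to improve on."""
    maps = _layer_maps_for_windows(model, seq, layer, window_length, stride)
    flat = maps.reshape(maps.shape[0], -1).astype(np.float64)
    return StyleVector(
        layer=layer,
        values=flat.mean(axis=0),
        source_id=seq.id,
        n_windows_averaged=maps.shape[0],
    )


def style_table(
    model: FeatureCnn,
    sequences: list[DnaSequence],
    layer: int,
    feature: str = "style",
    window_length: int = WINDOW_LENGTH,
    stride: int = WINDOW_STRIDE,
) -> tuple[list[str], np.ndarray]:
    """Stack per-sequence vectors into (ids, matrix) for the binning step.

    ``feature`` selects "style" (Gram) or "feature_map" (flattened maps).
    """
    maker = {"style": style_of_sequence, "feature_map": feature_map_vector}[feature]
    ids, rows = [], []
    for seq in sequences:
        vec = maker(model, seq, layer, window_length=window_length, stride=stride)
        ids.append(vec.source_id)
        rows.append(vec.values)
    return ids, np.vstack(rows)


def coverage_scale_stats(style_matrix: np.ndarray, coverages: np.ndarray) -> CoverageScaleStats:
    """Calibrate the coverage dimension over the full dataset being binned.

    Uses population (ddof=0) statistics of the coverage values and the mean
    per-dimension standard deviation of the style vectors.
    """
    coverages = np.asarray(coverages, dtype=float)
    if (coverages < 0).any():
        raise ValueError("coverage values must be nonnegative")
    return CoverageScaleStats(
        mean_cov=float(coverages.mean()),
        sd_cov=float(coverages.std()),
        style_sd=float(np.asarray(style_matrix, dtype=float).std(axis=0).mean()),
    )


def augment_with_coverage(
    vec: StyleVector | np.ndarray,
    coverage: float,
    stats: CoverageScaleStats,
) -> np.ndarray:
    """Append the scaled coverage as one extra feature dimension.

    The appended entry is ((coverage - mean) / sd) * style_sd; when the
    dataset's coverages are constant (sd = 0) the entry is 0, so coverage
    contributes nothing.
    """
    if coverage < 0:
        raise ValueError("coverage must be nonnegative")
    values = vec.values if isinstance(vec, StyleVector) else np.asarray(vec, dtype=float)
    if stats.sd_cov == 0:
        extra = 0.0
    else:
        extra = (coverage - stats.mean_cov) / stats.sd_cov * stats.style_sd
    return np.concatenate([values, [extra]])


def augment_table_with_coverage(
    matrix: np.ndarray, coverages: np.ndarray
) -> np.ndarray:
    """Coverage-augment every row of a style table with shared calibration."""
    stats = coverage_scale_stats(matrix, coverages)
    extras = np.array(
        [augment_with_coverage(row, cov, stats)[-1] for row, cov in zip(matrix, coverages)]
    )
    return np.column_stack([matrix, extras])
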