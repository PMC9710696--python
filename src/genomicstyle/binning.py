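"""Binning: Ward agglomerative clustering of per-sequence feature vectors.

The clustering is feature-agnostic — style vectors, coverage-augmented
style vectors and k-mer profiles all arrive as rows of a FeatureTable.
Merging starts from singletons and repeatedly joins the two clusters whose
Ward (minimum variance) distance is smallest, until the requested number of
bins remains.  The true bin count is an input, as in reference-free binning
evaluations where the species count is given.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage


@dataclass
class FeatureTable:
    """One feature vector per sequence id, constant width."""

    ids: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be 2-D (one row per id)")
        if len(self.ids) != self.vectors.shape[0]:
            raise ValueError("ids and vectors must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in feature table")
        if not np.isfinite(self.vectors).all():
            raise ValueError("feature table contains non-finite entries")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class BinAssignment:
    """Cluster label in {0..n_bins-1} per sequence id."""

    ids: list[str]
    labels: np.ndarray
    n_bins: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.ids) != self.labels.shape[0]:
            raise ValueError("ids and labels must have equal length")
        if self.labels.size and not (
            (self.labels >= 0).all() and (self.labels < self.n_bins).all()
        ):
            raise ValueError("labels must lie in {0..n_bins-1}")


def agglomerative_bin(table: FeatureTable, n_bins: int) -> BinAssignment:
    """Euclidean/Ward agglomerative clustering cut at ``n_bins`` clusters.

    Labels are renumbered by order of first appearance so the assignment is
    deterministic; bin indices carry no meaning beyond identity.
    """
    n = len(table)
    if not 1 <= n_bins <= n:
        raise ValueError(f"n_bins must be in 1..{n}, got {n_bins}")
    if n_bins == n:
        labels = np.arange(n)
    elif n_bins == 1:
        labels = np.zeros(n, dtype=int)
    else:
        Z = linkage(table.vectors, method="ward")
        raw = fcluster(Z, t=n_bins, criterion="maxclust")
        _, labels = np.unique(raw, return_inverse=True)
        # renumber by first appearance for a stable, input-order labeling
        order = {}
        for lab in labels:
            if lab not in order:
                order[lab] = len(order)
        labels = np.array([order[lab] for lab in labels])
    return BinAssignment(ids=list(table.ids), labels=labels, n_bins=n_bins)


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read the tab-separated feature matrix written by the CLI extract step."""
    df = pd.read_csv(path, sep="\t")
    if "sequence_id" not in df.columns:
        raise ValueError(f"{path}: missing 'sequence_id' column")
    ids = df["sequence_id"].astype(str).tolist()
    return FeatureTable(ids=ids, vectors=df.drop(columns="sequence_id").to_numpy(float))


def write_feature_table(path: str | Path, ids: list[str], matrix: np.ndarray) -> None:
    matrix = np.asarray(matrix)
    cols = [f"v{i}" for i in range(matrix.shape[1])]
    df = pd.DataFrame(matrix, columns=cols)
    df.insert(0, "sequence_id", ids)
    df.to_csv(path, sep="\t", index=False)


def write_assignment(path: str | Path, assignment: BinAssignment) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\tbin_index\n")
        for sid, lab in zip(assignment.ids, assignment.labels):
            fh.write(f"{sid}\t{int(lab)}\n")


def read_assignment(path: str | Path) -> BinAssignment:
    df = pd.read_csv(path, sep="\t")
    labels = df["bin_index"].to_numpy(int)
    n_bins = int(labels.max()) + 1 if labels.size else 0
    return BinAssignment(
        ids=df["sequence_id"].astype(str).tolist(), labels=labels, n_bins=n_bins
    )
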