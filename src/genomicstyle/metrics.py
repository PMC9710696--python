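"""Clustering evaluation: pair counts, RI/ARI, homogeneity, completeness, F.

Pair-based scores treat every unordered pair of sequences as a binary
decision: TP = same species, same bin; TN = different species, different
bins; FP = different species, same bin; FN = same species, different bins.
RI is the fraction of correctly decided pairs and the pair F-measure is the
harmonic mean of pairwise recall TP/(TP+FN) and precision TP/(TP+FP).  The
ARI is the Hubert–Arabie chance-corrected form, (RI - E[RI])/(max RI -
E[RI]) under the hypergeometric permutation null, computed via the standard
contingency-table closed form.  Homogeneity and completeness are the
entropy-based scores of Rosenberg & Hirschberg: 1 - H(true|pred)/H(true)
and 1 - H(pred|true)/H(pred), with the convention that a zero unconditional
entropy yields a score of 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from sklearn.metrics import (
    adjusted_rand_score,
    homogeneity_completeness_v_measure,
)
from sklearn.metrics.cluster import contingency_matrix


@dataclass(frozen=True)
class PairCounts:
    """Unordered-pair confusion counts for a predicted vs. true labeling."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class ClusteringScores:
    rand_index: float
    ari: float
    homogeneity: float
    completeness: float
    f_measure: float


def _check_labels(true_labels, pred_labels) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if t.shape != p.shape or t.ndim != 1 or t.size == 0:
        raise ValueError("label lists must be 1-D, nonempty and of equal length")
    return t, p


def pair_counts(true_labels, pred_labels) -> PairCounts:
    """Exact TP/TN/FP/FN over all n(n-1)/2 unordered pairs.

    Computed from the contingency table: pairs co-clustered in both
    labelings are sum of C(n_ij, 2), etc., so the cost is O(#distinct label
    combinations), not O(n^2).
    """
    t, p = _check_labels(true_labels, pred_labels)
    n = t.size
    cont = contingency_matrix(t, p, sparse=True)
    nij = cont.data.astype(np.int64)
    ai = np.asarray(cont.sum(axis=1)).ravel().astype(np.int64)  # per true class
    bj = np.asarray(cont.sum(axis=0)).ravel().astype(np.int64)  # per predicted bin
    same_both = int(sum(comb(int(x), 2) for x in nij))
    same_true = int(sum(comb(int(x), 2) for x in ai))
    same_pred = int(sum(comb(int(x), 2) for x in bj))
    total = comb(n, 2)
    TP = same_both
    FN = same_true - same_both
    FP = same_pred - same_both
    TN = total - TP - FN - FP
    return PairCounts(TP=TP, TN=TN, FP=FP, FN=FN)


def rand_index(true_labels, pred_labels) -> float:
    """RI = (TP + TN) / (all pairs); 1.0 for a single-element input."""
    c = pair_counts(true_labels, pred_labels)
    return (c.TP + c.TN) / c.total if c.total else 1.0


def adjusted_rand_index(true_labels, pred_labels) -> float:
    """Hubert–Arabie ARI (contingency closed form; chance level is 0)."""
    t, p = _check_labels(true_labels, pred_labels)
    return float(adjusted_rand_score(t, p))


def homogeneity_completeness(true_labels, pred_labels) -> tuple[float, float]:
    """Entropy-based homogeneity and completeness (natural-log entropies)."""
    t, p = _check_labels(true_labels, pred_labels)
    h, c, _ = homogeneity_completeness_v_measure(t, p)
    return float(h), float(c)


def pair_f_measure(counts: PairCounts) -> float:
    """Harmonic mean of pairwise recall and precision; 0 when TP = 0."""
    if counts.TP == 0:
        return 0.0
    rec = counts.TP / (counts.TP + counts.FN)
    pre = counts.TP / (counts.TP + counts.FP)
    return 2 * rec * pre / (rec + pre)


def score_clustering(true_labels, pred_labels) -> ClusteringScores:
    """All five indices for one predicted vs. true labeling."""
    counts = pair_counts(true_labels, pred_labels)
    h, c = homogeneity_completeness(true_labels, pred_labels)
    return ClusteringScores(
        rand_index=(counts.TP + counts.TN) / counts.total if counts.total else 1.0,
        ari=adjusted_rand_index(true_labels, pred_labels),
        homogeneity=h,
        completeness=c,
        f_measure=pair_f_measure(counts),
    )
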