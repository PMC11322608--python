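"""Protein-sequence features used to characterize signature components.

Charged amino-acid blocks are a multivalency proxy: runs of sequence where
the net charge per residue (NCPR) in a 10-residue sliding window is extreme.
PS-Self / PS-Part ranking scores (self-assembly vs partner-dependent phase
separation potential, both in [0, 1]) are clustered into four canonical
groups with k-means started from fixed centroids so the labels are
meaningful: Both, Self-only, Part-only, None.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

POSITIVE_RESIDUES = frozenset("RKH")
NEGATIVE_RESIDUES = frozenset("DE")

KMEANS_CENTROIDS = np.array([[0.8, 0.8], [0.8, 0.4], [0.4, 0.8], [0.4, 0.4]])
KMEANS_LABELS = ("Both", "Self", "Part", "None")


@dataclass(frozen=True)
class ChargedBlock:
    """Maximal merged run of extreme-NCPR windows (residue coordinates)."""

    start: int
    end: int  # half-open
    sign: str  # '+' or '-'
    window_ncpr: tuple[float, ...]

    @property
    def length(self) -> int:
        return self.end - self.start


def ncpr_windows(sequence: str, window: int = 10) -> np.ndarray:
    """NCPR of every sliding window (step 1). Non-standard residues are neutral."""
    seq = sequence.upper()
    n = len(seq)
    if n < window:
        return np.empty(0)
    charge = np.zeros(n)
    for i, aa in enumerate(seq):
        if aa in POSITIVE_RESIDUES:
            charge[i] = 1.0
        elif aa in NEGATIVE_RESIDUES:
            charge[i] = -1.0
    csum = np.concatenate([[0.0], np.cumsum(charge)])
    return (csum[window:] - csum[:-window]) / window


def charged_blocks(
    sequence: str, window: int = 10, threshold: float = 0.5
) -> tuple[list[ChargedBlock], float]:
    """Charged blocks and the fraction of residues they cover.

    Windows with NCPR > threshold (positive) or < -threshold (negative) are
    block seeds; overlapping windows of the same sign merge into one block.
    Blocks of opposite sign may overlap. The returned fraction is the share
    of residues covered by the union of all blocks.
    """
    ncpr = ncpr_windows(sequence, window)
    n = len(sequence)
    if ncpr.size == 0:
        return [], 0.0
    blocks: list[ChargedBlock] = []
    for sign, mask in (("+", ncpr > threshold), ("-", ncpr < -threshold)):
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            continue
        run_start = idx[0]
        prev = idx[0]
        runs = []
        for i in idx[1:]:
            if i - prev < window:  # windows overlap -> same block
                prev = i
            else:
                runs.append((run_start, prev))
                run_start = prev = i
        runs.append((run_start, prev))
        for ws, we in runs:
            blocks.append(
                ChargedBlock(
                    start=int(ws),
                    end=int(we + window),
                    sign=sign,
                    window_ncpr=tuple(float(v) for v in ncpr[ws : we + 1]),
                )
            )
    blocks.sort(key=lambda b: (b.start, b.end, b.sign))
    covered = np.zeros(n, dtype=bool)
    for b in blocks:
        covered[b.start : b.end] = True
    return blocks, float(covered.sum() / n)


def charged_fraction(sequence: str, window: int = 10, threshold: float = 0.5) -> float:
    """Fraction of residues inside charged blocks."""
    return charged_blocks(sequence, window, threshold)[1]


# ---------------------------------------------------------------------------
# PS-Self / PS-Part clustering


def ps_kmeans(
    ps_scores: Mapping[str, tuple[float, float]] | Sequence[tuple[float, float]],
    max_iter: int = 300,
) -> dict:
    """Four-way Lloyd k-means of (PS-Self, PS-Part) scores with fixed init.

    Initial centroids (0.8,0.8), (0.8,0.4), (0.4,0.8), (0.4,0.4) correspond
    to the labels Both / Self / Part / None, which the assignment keeps.
    Iterates to an assignment fixpoint (or ``max_iter``); with fewer than 4
    points no iteration is performed and points take their nearest initial
    centroid. A cluster that empties is reseeded to its initial centroid.

    Returns {'labels': per-point label, 'assignments': per-point cluster
    index, 'centroids': final 4x2 array}; labels keyed like the input.
    """
    if isinstance(ps_scores, Mapping):
        keys = list(ps_scores)
        pts = np.array([ps_scores[k] for k in keys], dtype=np.float64)
    else:
        keys = list(range(len(ps_scores)))
        pts = np.asarray(ps_scores, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("scores must be (self, part) pairs")
    if ((pts < 0) | (pts > 1)).any():
        raise ValueError("PS scores must lie in [0, 1]")

    def assign(centroids: np.ndarray) -> np.ndarray:
        d2 = ((pts[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    centroids = KMEANS_CENTROIDS.copy()
    labels_idx = assign(centroids)
    if len(pts) >= 4:
        for _ in range(max_iter):
            new_centroids = centroids.copy()
            for c in range(4):
                members = pts[labels_idx == c]
                if len(members):
                    new_centroids[c] = members.mean(axis=0)
                else:
                    new_centroids[c] = KMEANS_CENTROIDS[c]
            new_idx = assign(new_centroids)
            centroids = new_centroids
            if (new_idx == labels_idx).all():
                labels_idx = new_idx
                break
            labels_idx = new_idx
    return {
        "labels": {k: KMEANS_LABELS[i] for k, i in zip(keys, labels_idx)},
        "assignments": labels_idx,
        "centroids": centroids,
    }
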