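"""Focus-CAP segmentation of the occupancy matrix.

For each focus CAP the co-occupancy level of every other CAP is scored with
an F1 statistic (the other CAP's occupancy vector treated as a predictor of
the focus CAP's). The top-q co-occupied CAPs form the segment members; their
z-scored F1 values weight a per-bin occupancy score whose positive bins form
the segment. Segments are then split into promoter and non-promoter contexts
because co-occupancy frequencies differ strongly between the two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .occupancy import OccupancyMatrix

logger = logging.getLogger(__name__)


@dataclass
class Segment:
    """Focus-CAP-specific sub-matrix description.

    ``member_caps`` lists the top-q co-occupied CAPs (by F1, descending) with
    the focus CAP appended last so that it participates in the downstream
    vocabulary. ``beta``/``gamma`` align with the first ``len(member_caps)-1``
    entries (the ranked members; the focus CAP carries no beta).
    ``bins`` holds row indices into the filtered occupancy matrix.
    """

    focus_cap: str
    member_caps: list[str]
    beta: np.ndarray
    gamma: np.ndarray
    bins: np.ndarray
    delta: np.ndarray
    context: str = "unsplit"

    @property
    def n_bins(self) -> int:
        return len(self.bins)


def _check_binary(vec: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(vec)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return arr.astype(np.float64)


def co_occupancy_f1(focus_col: np.ndarray, other_col: np.ndarray) -> float:
    """F1 of ``other_col`` predicting ``focus_col`` (positive class = occupied).

    Returns 0 when precision + recall is 0 (disjoint supports or empty
    predictor).
    """
    f = _check_binary(focus_col, "focus_col")
    o = _check_binary(other_col, "other_col")
    if f.shape != o.shape:
        raise ValueError("vectors must have equal length")
    tp = float(f @ o)
    n_o = float(o.sum())
    n_f = float(f.sum())
    if tp == 0.0:
        return 0.0
    precision = tp / n_o
    recall = tp / n_f
    return 2 * precision * recall / (precision + recall)


def _f1_all(O: np.ndarray, focus_idx: int) -> np.ndarray:
    """Vectorized F1 of every column as predictor of the focus column."""
    Of = O.astype(np.float64)
    f = Of[:, focus_idx]
    tp = f @ Of
    n_other = Of.sum(axis=0)
    n_f = f.sum()
    denom = n_other + n_f  # 2*TP/(TP+FP+TP+FN) form of F1
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(denom > 0, 2 * tp / denom, 0.0)
    f1[tp == 0] = 0.0
    return f1


def build_segment(
    occ: OccupancyMatrix,
    focus_cap: str,
    q: int = 50,
    population_z: bool = True,
) -> Segment:
    """Segment the matrix around ``focus_cap``.

    The focus CAP is excluded from the F1 ranking but appended to the member
    list so its word can appear in downstream documents. Ties at the q-th
    rank break lexicographically by CAP name. ``gamma`` is the z-score of the
    kept members' F1 values (population SD by default); the per-bin occupancy
    score is delta_i = sum_j gamma_j * O[i, j] over kept members and bins
    with delta > 0 are retained.
    """
    if focus_cap not in occ.caps:
        raise KeyError(f"unknown focus CAP {focus_cap!r}")
    f_idx = occ.caps.index(focus_cap)
    if occ.n_caps < 3:
        raise ValueError("need at least 2 candidate CAPs besides the focus")
    f1 = _f1_all(occ.O, f_idx)
    candidates = [j for j in range(occ.n_caps) if j != f_idx]
    order = sorted(candidates, key=lambda j: (-f1[j], occ.caps[j]))
    kept = order[: min(q, len(order))]
    beta = f1[kept]
    sd = beta.std(ddof=0 if population_z else 1)
    if sd == 0:
        gamma = np.zeros_like(beta)
    else:
        gamma = (beta - beta.mean()) / sd
    delta = occ.O[:, kept].astype(np.float64) @ gamma
    bins = np.nonzero(delta > 0)[0]
    if bins.size == 0:
        logger.info("segment for %s is empty (degenerate co-occupancy ranking)", focus_cap)
    members = [occ.caps[j] for j in kept] + [focus_cap]
    return Segment(focus_cap, members, beta, gamma, bins, delta[bins])


def split_context(
    segment: Segment, promoter_flags_rows: np.ndarray
) -> list[Segment]:
    """Partition segment bins into promoter and non-promoter contexts.

    ``promoter_flags_rows`` is the per-row promoter flag aligned to the
    filtered occupancy matrix. Empty contexts are dropped with a log message;
    member CAPs, beta and gamma are shared unchanged.
    """
    flags = promoter_flags_rows[segment.bins]
    out: list[Segment] = []
    for context, mask in (("promoter", flags), ("non-promoter", ~flags)):
        if not mask.any():
            logger.info("segment %s: %s context empty, dropped", segment.focus_cap, context)
            continue
        out.append(
            replace(
                segment,
                bins=segment.bins[mask],
                delta=segment.delta[mask],
                context=context,
            )
        )
    return out
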