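"""Signature calling and condensation-potential filtration.

Topics are interpreted as co-occupancy signatures: component CAPs are the
words whose occurrence probability stands out (z-score above a threshold)
within the topic, and signature-positive bins are those co-occupied by most
components. Each signature is then contrasted against comparably-occupied
negative bins via ROC analysis of six condensation-related features; only
signatures whose features are enriched (AUROC) survive as CondSigs, and
near-duplicate CondSigs are removed greedily.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .genome_io import CapAnnotations
from .occupancy import OccupancyMatrix
from .segmentation import Segment
from .topic_model import Corpus, TopicModel

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("F_LLPS", "F_MLO", "F_IDR", "F_PPI", "F_RBP", "S_RBS")


def _ceil_frac(frac: float, n: int) -> int:
    """ceil(frac * n) robust to binary float representation of frac."""
    return int(math.ceil(frac * n - 1e-9))


@dataclass
class Signature:
    """A called co-occupancy signature (pre-filtration)."""

    id: str
    focus_cap: str
    context: str
    member_caps: list[str]
    components: list[str]
    component_z: dict[str, float]
    component_prob: dict[str, float]
    pos_rows: np.ndarray  # row indices into the filtered occupancy matrix
    positive_bins: np.ndarray  # global bin indices
    neg_rows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def n_positive(self) -> int:
        return len(self.pos_rows)


@dataclass
class CondSig:
    """A signature with its per-feature AUROCs and the final pass flag."""

    signature: Signature
    aurocs: dict[str, float]
    mean_top3_auroc: float
    passing_features: list[str]
    is_condsig: bool

    @property
    def id(self) -> str:
        return self.signature.id

    def top_components(self, n: int = 5) -> frozenset:
        """Top-n components by topic occurrence probability (ties by name)."""
        ranked = sorted(
            self.signature.components,
            key=lambda c: (-self.signature.component_prob[c], c),
        )
        return frozenset(ranked[:n])


# ---------------------------------------------------------------------------
# signature calling


def call_signatures(
    model: TopicModel,
    corpus: Corpus,
    segment: Segment,
    occ: OccupancyMatrix,
    lambda_z: float = 1.3,
    pos_frac: float = 0.8,
    min_components: int = 3,
    min_positive: int = 200,
) -> list[Signature]:
    """Extract signatures from a fitted topic model.

    Per topic, components are words whose z-scored occurrence probability
    (within the topic's phi row, population SD) exceeds ``lambda_z``;
    positive bins are segment bins occupied by at least
    ceil(pos_frac * n_components) of the components. Signatures with fewer
    than ``min_components`` components or ``min_positive`` positive bins are
    discarded.
    """
    vocab = corpus.vocab
    cols = [occ.caps.index(c) for c in vocab]
    sub = occ.O[np.ix_(segment.bins, cols)]
    signatures = []
    for t in range(model.k):
        row = model.phi[t]
        sd = row.std(ddof=0)
        if sd == 0:
            continue
        z = (row - row.mean()) / sd
        comp_idx = np.nonzero(z > lambda_z)[0]
        if comp_idx.size < min_components:
            continue
        threshold = _ceil_frac(pos_frac, comp_idx.size)
        counts = sub[:, comp_idx].sum(axis=1)
        pos_mask = counts >= threshold
        if pos_mask.sum() < min_positive:
            continue
        pos_rows = segment.bins[pos_mask]
        components = [vocab[i] for i in comp_idx]
        signatures.append(
            Signature(
                id=f"{segment.focus_cap}|{segment.context}|topic{t}",
                focus_cap=segment.focus_cap,
                context=segment.context,
                member_caps=list(segment.member_caps),
                components=components,
                component_z={vocab[i]: float(z[i]) for i in comp_idx},
                component_prob={vocab[i]: float(row[i]) for i in comp_idx},
                pos_rows=pos_rows,
                positive_bins=occ.bin_index[pos_rows],
            )
        )
    return signatures


def define_negative_bins(
    signature: Signature,
    occ: OccupancyMatrix,
    promoter_flags_rows: np.ndarray,
    neg_frac: float = 0.8,
    max_components_occupied: int = 1,
) -> np.ndarray:
    """Context-matched bins comparable to, but lacking, the signature.

    Negative bins are occupied by at least h = ceil(neg_frac * n_components)
    of the segment member CAPs while at most ``max_components_occupied``
    components are present; positive bins are excluded. Row indices into the
    filtered matrix are stored on the signature and returned.
    """
    member_cols = [occ.caps.index(c) for c in signature.member_caps]
    comp_cols = [occ.caps.index(c) for c in signature.components]
    h = _ceil_frac(neg_frac, len(signature.components))
    member_counts = occ.O[:, member_cols].sum(axis=1)
    comp_counts = occ.O[:, comp_cols].sum(axis=1)
    want_promoter = signature.context == "promoter"
    mask = (
        (member_counts >= h)
        & (comp_counts <= max_components_occupied)
        & (promoter_flags_rows == want_promoter)
    )
    mask[signature.pos_rows] = False
    neg = np.nonzero(mask)[0]
    if neg.size == 0:
        logger.warning("signature %s has no negative bins; scored as non-CondSig", signature.id)
    signature.neg_rows = neg
    return neg


# ---------------------------------------------------------------------------
# condensation features


def compute_features(
    rows: np.ndarray,
    occ: OccupancyMatrix,
    member_caps: list[str],
    annotations: CapAnnotations,
    rbs: np.ndarray | None = None,
    mlo_mode: str = "max",
) -> dict[str, np.ndarray]:
    """Per-bin condensation features from the occupied member CAPs.

    Fractions are over the member CAPs occupying each bin. F_MLO defaults to
    the best single membrane-less organelle (max over MLOs of the occupied
    fraction belonging to it); ``mlo_mode='shared'`` instead scores the
    fraction of occupied CAPs sharing >= 1 MLO with another occupied CAP.
    F_PPI is the fraction of occupied pairs with a known interaction, 0 when
    fewer than two CAPs are occupied. Bins with zero occupied members are
    excluded (see the returned 'valid' mask). ``rbs`` is a per-row signal
    aligned to the filtered matrix.
    """
    cols = [occ.caps.index(c) for c in member_caps]
    sub = occ.O[np.ix_(rows, cols)].astype(np.float64)
    counts = sub.sum(axis=1)
    valid = counts > 0
    ann = annotations.arrays_for(member_caps)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_llps = np.where(valid, sub @ ann["llps"] / counts, np.nan)
        f_idr = np.where(valid, sub @ ann["idr"] / counts, np.nan)
        f_rbp = np.where(valid, sub @ ann["rbp"] / counts, np.nan)
        if ann["mlo"].shape[1]:
            per_mlo = sub @ ann["mlo"]  # bins x MLOs
            if mlo_mode == "max":
                f_mlo = np.where(valid, per_mlo.max(axis=1) / counts, np.nan)
            elif mlo_mode == "shared":
                shared = np.zeros(len(rows))
                mlo_m = ann["mlo"].astype(np.float64)
                for i in range(len(rows)):
                    occ_idx = np.nonzero(sub[i])[0]
                    if occ_idx.size == 0:
                        continue
                    tot = per_mlo[i]
                    n_shared = sum(
                        1 for j in occ_idx if ((mlo_m[j] > 0) & (tot - mlo_m[j] > 0)).any()
                    )
                    shared[i] = n_shared
                f_mlo = np.where(valid, shared / counts, np.nan)
            else:
                raise ValueError(f"unknown mlo_mode {mlo_mode!r}")
        else:
            f_mlo = np.where(valid, 0.0, np.nan)
        edge_counts = ((sub @ ann["ppi"]) * sub).sum(axis=1) / 2.0
        n_pairs = counts * (counts - 1) / 2.0
        f_ppi = np.where(n_pairs > 0, edge_counts / np.maximum(n_pairs, 1), 0.0)
        f_ppi = np.where(valid, f_ppi, np.nan)
    out = {
        "F_LLPS": f_llps,
        "F_MLO": f_mlo,
        "F_IDR": f_idr,
        "F_PPI": f_ppi,
        "F_RBP": f_rbp,
        "n_occupied": counts,
        "valid": valid,
    }
    if rbs is not None:
        out["S_RBS"] = np.where(valid, rbs[rows], np.nan)
    return out


def auroc(positive_values: np.ndarray, negative_values: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUROC with midranks for ties.

    Equals P(pos > neg) + 0.5 * P(pos == neg) over random pos/neg pairs.
    """
    pos = np.asarray(positive_values, dtype=np.float64)
    neg = np.asarray(negative_values, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both value sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def score_signature(
    signature: Signature,
    occ: OccupancyMatrix,
    annotations: CapAnnotations,
    rbs: np.ndarray | None = None,
    mlo_mode: str = "max",
) -> dict[str, float]:
    """Per-feature AUROC of positive vs negative bins for one signature."""
    if signature.neg_rows.size == 0:
        return {}
    names = list(FEATURE_NAMES if rbs is not None else FEATURE_NAMES[:5])
    fpos = compute_features(signature.pos_rows, occ, signature.member_caps,
                            annotations, rbs, mlo_mode)
    fneg = compute_features(signature.neg_rows, occ, signature.member_caps,
                            annotations, rbs, mlo_mode)
    aurocs = {}
    for name in names:
        pv = fpos[name][fpos["valid"]]
        nv = fneg[name][fneg["valid"]]
        if pv.size == 0 or nv.size == 0:
            continue
        aurocs[name] = auroc(pv, nv)
    return aurocs


def filter_condsigs(
    signatures: list[Signature],
    occ: OccupancyMatrix,
    annotations: CapAnnotations,
    rbs: np.ndarray | None = None,
    auroc_min: float = 0.6,
    mean_top3_min: float = 0.65,
    min_passing: int = 3,
    mlo_mode: str = "max",
) -> list[CondSig]:
    """Score every signature and flag those passing the condensation filter.

    A signature passes iff at least ``min_passing`` features have
    AUROC > ``auroc_min`` and the mean of its top three AUROCs exceeds
    ``mean_top3_min``.
    """
    out = []
    for sig in signatures:
        aurocs = score_signature(sig, occ, annotations, rbs, mlo_mode)
        if aurocs:
            vals = sorted(aurocs.values(), reverse=True)
            mean_top3 = float(np.mean(vals[:3]))
            passing = sorted(n for n, a in aurocs.items() if a > auroc_min)
            ok = len(passing) >= min_passing and mean_top3 > mean_top3_min
        else:
            mean_top3 = float("nan")
            passing = []
            ok = False
        out.append(CondSig(sig, aurocs, mean_top3, passing, ok))
    return out


def deduplicate(condsigs: list[CondSig], max_jaccard: float = 0.25) -> list[CondSig]:
    """Greedy redundancy removal on top-5 component overlap.

    CondSigs are visited in decreasing mean top-3 AUROC (ties by id for
    determinism); one is kept iff the Jaccard index of its top-5 components
    with every already-kept CondSig is <= ``max_jaccard``.
    """
    ranked = sorted(condsigs, key=lambda c: (-c.mean_top3_auroc, c.id))
    kept: list[CondSig] = []
    kept_tops: list[frozenset] = []
    for cs in ranked:
        top = cs.top_components(5)
        redundant = False
        for other in kept_tops:
            inter = len(top & other)
            union = len(top | other)
            if union and inter / union > max_jaccard:
                redundant = True
                break
        if not redundant:
            kept.append(cs)
            kept_tops.append(top)
    return kept


def merged_positive_sites(condsigs: list[CondSig], occ: OccupancyMatrix) -> list:
    """Union of positive bins over CondSigs, book-ended bins merged."""
    from .genome_io import merge_intervals

    bins = sorted({int(b) for cs in condsigs for b in cs.signature.positive_bins})
    intervals = [occ.binning.bin_interval(b) for b in bins]
    if not intervals:
        return []
    return merge_intervals(intervals, gap=0)
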