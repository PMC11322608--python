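"""Classify CAP peaks and domains by CondSig membership; extract
high-confidence condensate-related sites.

A CAP's peak is CondSig-positive when it overlaps a site where that CAP was
called as a component. Domains are single-linkage merges of nearby peaks
(gap measured between nearest edges, inclusive); a domain is positive iff it
contains a positive peak. The high-confidence filter keeps a merged positive
site only when every component CAP assigned to it shows more than a
fold-change of signal there relative to its own CondSig-negative peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genome_io import BedGraphTrack, Interval, intervals_overlap, merge_intervals
from .occupancy import OccupancyMatrix
from .signatures import CondSig

logger = logging.getLogger(__name__)


@dataclass
class PeakClassification:
    cap: str
    positive_peaks: list[Interval]
    negative_peaks: list[Interval]
    positive_domains: list[Interval] = field(default_factory=list)
    negative_domains: list[Interval] = field(default_factory=list)
    refinement: str = "none"


def positive_sites_for_cap(
    cap: str, condsigs: Sequence[CondSig], occ: OccupancyMatrix
) -> list[Interval]:
    """Merged positive sites of the CondSigs in which ``cap`` is a component."""
    bins = sorted(
        {
            int(b)
            for cs in condsigs
            if cap in cs.signature.components
            for b in cs.signature.positive_bins
        }
    )
    if not bins:
        return []
    return merge_intervals([occ.binning.bin_interval(b) for b in bins], gap=0)


def classify_peaks(
    cap: str, peaks: Sequence[Interval], positive_sites: Sequence[Interval]
) -> PeakClassification:
    """Split peaks by >= 1 bp overlap with the CAP's own positive sites."""
    if not positive_sites:
        logger.warning("CAP %s is not a component of any CondSig; all peaks negative", cap)
        return PeakClassification(cap, [], sorted(peaks))
    hit = intervals_overlap(list(peaks), list(positive_sites))
    pos = [p for p, h in zip(peaks, hit) if h]
    neg = [p for p, h in zip(peaks, hit) if not h]
    return PeakClassification(cap, sorted(pos), sorted(neg))


def refine_classification(
    classification: PeakClassification,
    atac_peaks: Sequence[Interval] | None = None,
    occ: OccupancyMatrix | None = None,
    min_caps: int = 10,
) -> PeakClassification:
    """Drop peaks (from both classes) failing the accessibility matching rule.

    With ``atac_peaks``, a peak must overlap an ATAC peak; with ``occ``, it
    must overlap a bin occupied by more than ``min_caps`` CAPs (strict >).
    Refinement never moves peaks between classes.
    """
    if (atac_peaks is None) == (occ is None):
        raise ValueError("provide exactly one of atac_peaks or occ")
    if atac_peaks is not None:
        mode = "atac"

        def keep(peaks):
            if not peaks:
                return []
            hit = intervals_overlap(list(peaks), list(atac_peaks))
            return [p for p, h in zip(peaks, hit) if h]

    else:
        mode = "cap-count"
        counts = occ.O.sum(axis=1)
        busy_bins = occ.bin_index[counts > min_caps]
        busy = [occ.binning.bin_interval(int(b)) for b in busy_bins]

        def keep(peaks):
            if not peaks:
                return []
            hit = intervals_overlap(list(peaks), busy)
            return [p for p, h in zip(peaks, hit) if h]

    return PeakClassification(
        classification.cap,
        keep(classification.positive_peaks),
        keep(classification.negative_peaks),
        refinement=mode,
    )


def peaks_to_domains(
    classification: PeakClassification, gap_kb: float
) -> PeakClassification:
    """Merge peaks whose edge gap is <= gap_kb * 1000 bp into domains.

    A domain is positive iff it contains at least one positive peak. Typical
    gaps: 5 kb for narrow-peak CAPs, 10 kb for broad-peak CAPs.
    """
    gap = int(gap_kb * 1000)
    all_peaks = classification.positive_peaks + classification.negative_peaks
    if not all_peaks:
        return classification
    domains = merge_intervals(all_peaks, gap=gap)
    if classification.positive_peaks:
        has_pos = intervals_overlap(domains, classification.positive_peaks)
    else:
        has_pos = np.zeros(len(domains), dtype=bool)
    pos_d = [d for d, h in zip(domains, has_pos) if h]
    neg_d = [d for d, h in zip(domains, has_pos) if not h]
    return PeakClassification(
        classification.cap,
        classification.positive_peaks,
        classification.negative_peaks,
        pos_d,
        neg_d,
        classification.refinement,
    )


def _mean_signal_over(track: BedGraphTrack, intervals: Sequence[Interval]) -> float:
    """Length-weighted mean signal across a set of intervals."""
    total = 0.0
    length = 0
    for chrom, s, e in intervals:
        total += track.interval_mean(chrom, s, e) * (e - s)
        length += e - s
    return total / length if length else float("nan")


def high_confidence_sites(
    condsigs: Sequence[CondSig],
    occ: OccupancyMatrix,
    signal_tracks: Mapping[str, BedGraphTrack],
    negative_peaks: Mapping[str, Sequence[Interval]],
    fold: float = 1.5,
) -> list[Interval]:
    """Merged positive sites where every assigned component CAP is enriched.

    A site is kept iff for every component CAP of every CondSig whose
    positive bins built the site, the mean signal at the site exceeds
    ``fold`` times that CAP's mean signal over its CondSig-negative peaks
    (strict >). Sites lacking a required track or whose CAP has no negative
    peaks (undefined baseline) are skipped with a warning.
    """
    from .signatures import merged_positive_sites

    final = [cs for cs in condsigs if cs.is_condsig]
    sites = merged_positive_sites(final, occ)
    # map each site to the components of every CondSig contributing bins to it
    site_caps: list[set] = [set() for _ in sites]
    for cs in final:
        ivs = [occ.binning.bin_interval(int(b)) for b in cs.signature.positive_bins]
        hit = intervals_overlap(sites, ivs)
        for i, h in enumerate(hit):
            if h:
                site_caps[i].update(cs.signature.components)

    baselines: dict[str, float] = {}
    kept: list[Interval] = []
    for site, caps in zip(sites, site_caps):
        ok = True
        for cap in sorted(caps):
            track = signal_tracks.get(cap)
            if track is None:
                logger.warning("no signal track for %s; site %s skipped", cap, site)
                ok = False
                break
            if cap not in baselines:
                negs = list(negative_peaks.get(cap, []))
                if not negs:
                    baselines[cap] = float("nan")
                else:
                    baselines[cap] = _mean_signal_over(track, negs)
            base = baselines[cap]
            if not np.isfinite(base):
                logger.warning("CAP %s has no negative-peak baseline; site %s skipped", cap, site)
                ok = False
                break
            site_mean = track.interval_mean(*site)
            if not site_mean > fold * base:
                ok = False
                break
        if ok and caps:
            kept.append(site)
    return kept
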