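"""Genome-wide binary CAP occupancy matrix and its quality filters.

The matrix O (bins x CAPs) has O[i, j] = 1 iff CAP j has at least 1 bp of
peak overlap with bin i. Filtering removes low-coverage CAPs (too few
occupancy events to trust the underlying ChIP-seq data), hyper-occupied bins
(likely sequencing artefacts) and blacklisted regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome_io import GenomeBinning, Interval, PeakSet

logger = logging.getLogger(__name__)


@dataclass
class OccupancyMatrix:
    """Binary occupancy of CAPs over retained genomic bins.

    ``O`` is n_kept x m with values in {0, 1}; ``bin_index`` maps each row to
    its global bin index in ``binning``.
    """

    binning: GenomeBinning
    caps: list[str]
    O: np.ndarray
    bin_index: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.O.shape[0]

    @property
    def n_caps(self) -> int:
        return self.O.shape[1]

    def column(self, cap: str) -> np.ndarray:
        return self.O[:, self.caps.index(cap)]

    def to_triplets(self):
        """Sparse (row, cap, 1) triplets for debugging/export."""
        rows, cols = np.nonzero(self.O)
        return [(int(self.bin_index[r]), self.caps[c], 1) for r, c in zip(rows, cols)]


def build_occupancy_matrix(
    binning: GenomeBinning, peaksets: Sequence[PeakSet]
) -> OccupancyMatrix:
    """Mark O[i, j] = 1 iff CAP j has >= 1 bp peak overlap with bin i."""
    if not peaksets:
        raise ValueError("at least one PeakSet required")
    names = [ps.cap_name for ps in peaksets]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate CAP names: {dupes}")
    O = np.zeros((binning.n_bins, len(peaksets)), dtype=np.uint8)
    for j, ps in enumerate(peaksets):
        for chrom, start, end in ps.intervals:
            if chrom not in binning.chrom_order:
                logger.warning("peak of %s on unknown chromosome %s skipped", ps.cap_name, chrom)
                continue
            r = binning.overlapping_bins(chrom, start, end)
            O[r.start : r.stop, j] = 1
    return OccupancyMatrix(binning, names, O, np.arange(binning.n_bins))


def filter_matrix(
    occ: OccupancyMatrix,
    blacklist: Iterable[Interval] | None = None,
    min_events: int = 500,
    max_frac: float = 0.9,
) -> OccupancyMatrix:
    """Drop low-event CAPs, hyper-occupied bins and blacklisted bins.

    One pass drops CAPs with fewer than ``min_events`` occupancy events
    (strict <), then bins occupied by more than ``max_frac`` of the retained
    CAPs (strict >) and bins overlapping the blacklist. Because removing bins
    can push a CAP back under ``min_events``, the pass is repeated until
    nothing changes, so the result is a fixpoint and filtering is idempotent.
    """
    blacklist_rows = None
    if blacklist is not None:
        flags = occ.binning.flag_intervals(blacklist)
        blacklist_rows = flags[occ.bin_index]

    O = occ.O
    caps = list(occ.caps)
    bin_index = occ.bin_index
    bl = blacklist_rows
    while True:
        col_sums = O.sum(axis=0)
        keep_cols = col_sums >= min_events
        if not keep_cols.any():
            raise ValueError("no qualifying CAPs after event-count filter")
        changed = not keep_cols.all()
        O = O[:, keep_cols]
        caps = [c for c, k in zip(caps, keep_cols) if k]

        frac = O.sum(axis=1) / O.shape[1]
        keep_rows = frac <= max_frac
        if bl is not None:
            keep_rows &= ~bl
        if not keep_rows.all():
            changed = True
        O = O[keep_rows]
        bin_index = bin_index[keep_rows]
        if bl is not None:
            bl = bl[keep_rows]
        if not changed:
            break
    logger.info(
        "occupancy filter retained %d/%d CAPs and %d/%d bins",
        len(caps), occ.n_caps, O.shape[0], occ.n_bins,
    )
    return OccupancyMatrix(occ.binning, caps, O, bin_index)
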