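"""Genomic coordinate model and readers/writers for the standard input formats.

All coordinates are 0-based half-open (BED convention). The genome is tiled
with fixed-width bins; trailing partial bins at chromosome ends are dropped so
every bin has exactly ``bin_width`` bp, which keeps per-bin features
comparable. Overlap rules are minimal: a bin counts as occupied / promoter /
covered if it overlaps the relevant interval by at least 1 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Interval = tuple[str, int, int]


class FormatError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# binning


@dataclass(frozen=True)
class GenomeBinning:
    """Fixed-width tiling of a genome.

    Bins are ordered by ``chrom_order`` then start coordinate, and indexed
    globally (0..n_bins-1). A chromosome of length L contributes
    floor(L / bin_width) bins; the trailing partial bin is dropped.
    """

    chrom_order: tuple[str, ...]
    chrom_sizes: Mapping[str, int]
    bin_width: int = 1000
    _n_per_chrom: tuple[int, ...] = field(init=False, repr=False)
    _offsets: Mapping[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        n_per = []
        offsets = {}
        total = 0
        for chrom in self.chrom_order:
            size = self.chrom_sizes[chrom]
            n = size // self.bin_width
            offsets[chrom] = total
            n_per.append(n)
            total += n
        object.__setattr__(self, "_n_per_chrom", tuple(n_per))
        object.__setattr__(self, "_offsets", offsets)

    @classmethod
    def from_chrom_sizes(cls, chrom_sizes: Mapping[str, int], bin_width: int = 1000) -> "GenomeBinning":
        return cls(tuple(chrom_sizes), dict(chrom_sizes), bin_width)

    @property
    def n_bins(self) -> int:
        return sum(self._n_per_chrom)

    def n_bins_chrom(self, chrom: str) -> int:
        return self._n_per_chrom[self.chrom_order.index(chrom)]

    def bin_interval(self, i: int) -> Interval:
        """Genomic interval of global bin ``i``."""
        if i < 0 or i >= self.n_bins:
            raise IndexError(f"bin index {i} out of range")
        for chrom, n in zip(self.chrom_order, self._n_per_chrom):
            if i < n:
                start = i * self.bin_width
                return chrom, start, start + self.bin_width
            i -= n
        raise IndexError("unreachable")  # pragma: no cover

    def overlapping_bins(self, chrom: str, start: int, end: int) -> range:
        """Global indices of bins overlapping [start, end) by >= 1 bp."""
        if chrom not in self._offsets:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if end <= start:
            return range(0)
        off = self._offsets[chrom]
        n = self._n_per_chrom[self.chrom_order.index(chrom)]
        first = max(start // self.bin_width, 0)
        last = min((end - 1) // self.bin_width, n - 1)
        if first > last:
            return range(0)
        return range(off + first, off + last + 1)

    def flag_intervals(self, intervals: Iterable[Interval]) -> np.ndarray:
        """Boolean per-bin flag: True iff the bin overlaps >= 1 interval by >= 1 bp."""
        flags = np.zeros(self.n_bins, dtype=bool)
        for chrom, start, end in intervals:
            if chrom not in self._offsets:
                logger.warning("interval on unknown chromosome %s skipped", chrom)
                continue
            r = self.overlapping_bins(chrom, start, end)
            flags[r.start : r.stop] = True
        return flags

    def bin_frame(self, indices: Sequence[int] | None = None) -> pd.DataFrame:
        """BED-like frame (chrom, start, end) for all bins or a subset."""
        rows = []
        idx = range(self.n_bins) if indices is None else indices
        for i in idx:
            rows.append(self.bin_interval(i))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# peak sets


@dataclass
class PeakSet:
    """A named set of genomic intervals (one CAP's peaks)."""

    cap_name: str
    intervals: list[Interval]

    def __len__(self) -> int:
        return len(self.intervals)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Parse a two-column chrom.sizes file, preserving order of appearance."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        lines = [ln for ln in fh]
    if not any(ln.strip() for ln in lines):
        raise FormatError(f"{path}: empty chrom.sizes file")
    for lineno, line in enumerate(lines, 1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        chrom, size_s = fields
        try:
            size = int(size_s)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: size {size_s!r} is not an integer") from None
        if size <= 0:
            raise FormatError(f"{path}:{lineno}: non-positive size {size}")
        if chrom in sizes:
            raise FormatError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
        sizes[chrom] = size
    return sizes


def read_bed(
    path: str | Path,
    cap_name: str | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
) -> PeakSet:
    """Read a BED3+ file into a sorted PeakSet.

    Records with start >= end raise; when ``chrom_sizes`` is given, records on
    unknown chromosomes are skipped with a warning.
    """
    name = cap_name if cap_name is not None else Path(path).stem
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start {start}")
            if chrom_sizes is not None and chrom not in chrom_sizes:
                logger.warning("%s:%d: unknown chromosome %s, record skipped", path, lineno, chrom)
                continue
            intervals.append((chrom, start, end))
    intervals.sort()
    return PeakSet(name, intervals)


def write_bed(path: str | Path, intervals: Iterable[Interval]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# promoters


def promoters_from_genes(
    genes: Iterable[tuple[str, int, int, str]],
    binning: GenomeBinning,
    flank: int = 3000,
) -> np.ndarray:
    """Per-bin promoter flag from gene annotations.

    Each gene is (chrom, start, end, strand). The TSS is ``start`` for +
    strand genes and ``end - 1`` for - strand genes; the promoter is
    [TSS - flank, TSS + flank) clipped to the chromosome. A bin is a
    promoter bin iff it overlaps >= 1 promoter by >= 1 bp.
    """
    promoter_intervals: list[Interval] = []
    for chrom, start, end, strand in genes:
        if strand == "+":
            tss = start
        elif strand == "-":
            tss = end - 1
        else:
            raise FormatError(f"gene on {chrom}:{start}-{end} has invalid strand {strand!r}")
        size = binning.chrom_sizes.get(chrom)
        if size is None:
            logger.warning("gene on unknown chromosome %s skipped", chrom)
            continue
        lo = max(tss - flank, 0)
        hi = min(tss + flank, size)
        if hi > lo:
            promoter_intervals.append((chrom, lo, hi))
    return binning.flag_intervals(promoter_intervals)


def read_genes_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a BED6 gene annotation (chrom, start, end, name, score, strand)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: gene BED needs >= 6 fields (strand required)")
            genes.append((fields[0], int(fields[1]), int(fields[2]), fields[5]))
    return genes


# ---------------------------------------------------------------------------
# signal tracks


@dataclass
class BedGraphTrack:
    """Raw bedGraph records, per chromosome, for arbitrary-interval queries."""

    records: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]  # starts, ends, values

    def interval_mean(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean over [start, end); uncovered bp contribute 0."""
        if end <= start:
            raise ValueError("empty interval")
        if chrom not in self.records:
            return 0.0
        starts, ends, values = self.records[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        ov = np.clip(ov, 0, None)
        return float((values[lo:hi] * ov).sum() / (end - start))


def read_bedgraph(path: str | Path) -> BedGraphTrack:
    """Load a 4-column bedGraph. Negative values are rejected."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
        dtype={"chrom": str},
    )
    if (df["value"] < 0).any():
        bad = df.index[df["value"] < 0][0] + 1
        raise FormatError(f"{path}:{bad}: negative signal value")
    if not np.isfinite(df["value"]).all():
        raise FormatError(f"{path}: non-finite signal value")
    records = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        records[str(chrom)] = (
            grp["start"].to_numpy(np.int64),
            grp["end"].to_numpy(np.int64),
            grp["value"].to_numpy(np.float64),
        )
    return BedGraphTrack(records)


def read_signal_bedgraph(path: str | Path, binning: GenomeBinning) -> np.ndarray:
    """Per-bin signal: length-weighted mean of overlapping records, uncovered -> 0."""
    track = read_bedgraph(path)
    return bin_signal(track, binning)


def bin_signal(track: BedGraphTrack, binning: GenomeBinning) -> np.ndarray:
    values = np.zeros(binning.n_bins, dtype=np.float64)
    bw = binning.bin_width
    for chrom, (starts, ends, vals) in track.records.items():
        if chrom not in binning.chrom_order:
            logger.warning("bedGraph records on unknown chromosome %s ignored", chrom)
            continue
        n = binning.n_bins_chrom(chrom)
        if n == 0:
            continue
        off = binning._offsets[chrom]
        for s, e, v in zip(starts, ends, vals):
            first = s // bw
            last = min((e - 1) // bw, n - 1)
            for b in range(first, last + 1):
                if b >= n:
                    break
                ov = min(e, (b + 1) * bw) - max(s, b * bw)
                if ov > 0:
                    values[off + b] += v * ov / bw
    return values


# ---------------------------------------------------------------------------
# CAP annotations


@dataclass
class CapAnnotations:
    """Condensation-related annotations for CAPs.

    ``records`` maps CAP name to a dict with keys is_llps, has_idr, is_rbp
    (bool), mlos (frozenset of MLO names), ps_self, ps_part (float or NaN).
    ``ppi_edges`` holds unordered CAP-name pairs (stored as frozensets).
    ``sequences`` optionally maps CAP name to an amino-acid string.
    """

    records: dict[str, dict]
    ppi_edges: set[frozenset]
    sequences: dict[str, str] = field(default_factory=dict)

    _DEFAULT = {
        "is_llps": False,
        "has_idr": False,
        "is_rbp": False,
        "mlos": frozenset(),
        "ps_self": float("nan"),
        "ps_part": float("nan"),
    }

    def record(self, cap: str) -> dict:
        rec = self.records.get(cap)
        if rec is None:
            logger.warning("CAP %s absent from annotation tables; defaults used", cap)
            return dict(self._DEFAULT)
        return rec

    def arrays_for(self, caps: Sequence[str]) -> dict:
        """Vectorized annotation views aligned to ``caps``.

        Returns llps/idr/rbp boolean arrays, an MLO membership matrix
        (caps x MLOs), and a symmetric PPI adjacency matrix.
        """
        m = len(caps)
        recs = [self.record(c) for c in caps]
        llps = np.array([r["is_llps"] for r in recs], dtype=bool)
        idr = np.array([r["has_idr"] for r in recs], dtype=bool)
        rbp = np.array([r["is_rbp"] for r in recs], dtype=bool)
        mlo_names = sorted({mlo for r in recs for mlo in r["mlos"]})
        mlo = np.zeros((m, len(mlo_names)), dtype=bool)
        for i, r in enumerate(recs):
            for name in r["mlos"]:
                mlo[i, mlo_names.index(name)] = True
        adj = np.zeros((m, m), dtype=bool)
        index = {c: i for i, c in enumerate(caps)}
        for edge in self.ppi_edges:
            pair = [index[c] for c in edge if c in index]
            if len(pair) == 2:
                adj[pair[0], pair[1]] = adj[pair[1], pair[0]] = True
        return {"llps": llps, "idr": idr, "rbp": rbp, "mlo": mlo, "ppi": adj}

    def permuted(self, seed: int, caps: Sequence[str] | None = None) -> "CapAnnotations":
        """Annotations with CAP identities permuted (marginals preserved).

        CAP ``c`` receives the record of ``sigma(c)``; a PPI edge exists
        between (c, d) iff one existed between (sigma(c), sigma(d)).
        """
        names = list(caps) if caps is not None else sorted(self.records)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(names))
        sigma = {names[i]: names[perm[i]] for i in range(len(names))}
        inv = {v: k for k, v in sigma.items()}
        records = {c: dict(self.record(sigma[c])) for c in names}
        edges = set()
        for edge in self.ppi_edges:
            mapped = frozenset(inv.get(c, c) for c in edge)
            if len(mapped) == 2:
                edges.add(mapped)
        return CapAnnotations(records, edges, dict(self.sequences))


_TRUTHY = {"1", "true", "yes", "t"}


def _as_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float)):
        return bool(value)
    return str(value).strip().lower() in _TRUTHY


def read_cap_annotations(
    path: str | Path,
    ppi_path: str | Path | None = None,
    known_caps: Sequence[str] | None = None,
) -> CapAnnotations:
    """Read the per-CAP annotation TSV (and optionally a PPI edge TSV).

    Expected columns: cap, llps, mlos (comma-separated, may be empty), idr,
    rbp and optional ps_self, ps_part. Unknown CAPs (not in ``known_caps``)
    are ignored with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"cap", "llps", "mlos", "idr", "rbp"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records: dict[str, dict] = {}
    known = set(known_caps) if known_caps is not None else None
    for _, row in df.iterrows():
        cap = row["cap"]
        if known is not None and cap not in known:
            logger.warning("annotation row for unknown CAP %s ignored", cap)
            continue
        mlos = frozenset(m for m in row["mlos"].split(",") if m)
        records[cap] = {
            "is_llps": _as_bool(row["llps"]),
            "has_idr": _as_bool(row["idr"]),
            "is_rbp": _as_bool(row["rbp"]),
            "mlos": mlos,
            "ps_self": float(row["ps_self"]) if row.get("ps_self", "") != "" else float("nan"),
            "ps_part": float(row["ps_part"]) if row.get("ps_part", "") != "" else float("nan"),
        }
    edges: set[frozenset] = set()
    if ppi_path is not None:
        ppi = pd.read_csv(ppi_path, sep="\t", dtype=str)
        if not {"cap1", "cap2"} <= set(ppi.columns):
            raise FormatError(f"{ppi_path}: expected columns cap1, cap2")
        for _, row in ppi.iterrows():
            a, b = row["cap1"], row["cap2"]
            if a == b:
                continue
            if known is not None and (a not in known or b not in known):
                logger.warning("PPI edge %s-%s with unknown CAP ignored", a, b)
                continue
            edges.add(frozenset((a, b)))
    return CapAnnotations(records, edges)


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# interval utilities (shared by postprocess / site output)


def merge_intervals(intervals: Iterable[Interval], gap: int = 0) -> list[Interval]:
    """Single-linkage merge of intervals whose edge gap is <= ``gap`` bp."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    merged: list[Interval] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s - cur_e <= gap:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return merged


def intervals_overlap(
    query: Sequence[Interval], subject: Sequence[Interval]
) -> np.ndarray:
    """Boolean per-query flag: overlaps >= 1 bp with any subject interval."""
    subj_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in subject:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, spans in by_chrom.items():
        spans.sort()
        arr = np.array(spans)
        subj_by_chrom[chrom] = (arr[:, 0], arr[:, 1])
    out = np.zeros(len(query), dtype=bool)
    for i, (chrom, s, e) in enumerate(query):
        if chrom not in subj_by_chrom:
            continue
        starts, ends = subj_by_chrom[chrom]
        lo = np.searchsorted(ends, s, side="right")
        hi = np.searchsorted(starts, e, side="left")
        out[i] = hi > lo
    return out
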