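"""End-to-end detection pipeline and its run configuration.

Composes: occupancy matrix construction and filtering -> per-focus-CAP
segmentation -> promoter/non-promoter context split -> biterm topic model
with automatic topic-number selection -> signature calling -> negative-bin
definition -> condensation-feature AUROC filtration -> redundancy removal.
A single global seed fans out deterministically to per-(focus, context, k)
sampler seeds, so results do not depend on execution order.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genome_io
from .genome_io import CapAnnotations, GenomeBinning, write_bed
from .occupancy import OccupancyMatrix, build_occupancy_matrix, filter_matrix
from .segmentation import build_segment, split_context
from .signatures import (
    CondSig,
    Signature,
    call_signatures,
    deduplicate,
    define_negative_bins,
    filter_condsigs,
    merged_positive_sites,
)
from .topic_model import corpus_from_segment, derive_seed, select_topic_number

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline tunables with their default thresholds."""

    bin_width: int = 1000
    min_events: int = 500
    max_frac: float = 0.9
    q: int = 50
    promoter_flank: int = 3000
    k_min: int = 2
    k_max: int = 10
    alpha_topic: float | None = None  # None -> 50/k
    beta_word: float = 0.01
    n_iter: int = 500
    lambda_z: float = 1.3
    pos_frac: float = 0.8
    min_components: int = 3
    min_positive: int = 200
    auroc_min: float = 0.6
    mean_top3_min: float = 0.65
    min_passing: int = 3
    dedup_jaccard: float = 0.25
    mlo_mode: str = "max"
    context: str = "both"  # promoter | non-promoter | both
    seed: int = 0

    @property
    def k_range(self) -> range:
        return range(self.k_min, self.k_max + 1)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class DetectionResult:
    condsigs: list[CondSig]  # final, deduplicated CondSigs
    all_scored: list[CondSig]  # every scored signature with its AUROCs
    signatures: list[Signature]  # every called signature (pre-filtration)
    selection_reports: list[dict]  # focus, context and the per-k score table
    occ: OccupancyMatrix
    promoter_rows: np.ndarray


def detect_signatures(
    occ: OccupancyMatrix,
    promoter_rows: np.ndarray,
    config: RunConfig,
) -> tuple[list[Signature], list[dict]]:
    """Run segmentation + topic modelling and call signatures (no filtration).

    Annotation-independent: the returned signatures already carry their
    positive and negative bins, so different annotation sets can be scored
    against the same calls.
    """
    signatures: list[Signature] = []
    reports: list[dict] = []
    wanted = (
        ("promoter", "non-promoter") if config.context == "both" else (config.context,)
    )
    for focus in occ.caps:
        try:
            segment = build_segment(occ, focus, q=config.q)
        except ValueError as exc:
            logger.warning("segmentation for %s failed: %s", focus, exc)
            continue
        if segment.n_bins == 0:
            continue
        for ctx_seg in split_context(segment, promoter_rows):
            if ctx_seg.context not in wanted:
                continue
            corpus = corpus_from_segment(ctx_seg, occ)
            if corpus.n_biterms == 0:
                logger.info("corpus for %s/%s has no biterms; skipped", focus, ctx_seg.context)
                continue
            seeds = [
                derive_seed(config.seed, focus, ctx_seg.context, k)
                for k in config.k_range
            ]
            model, report = select_topic_number(
                corpus,
                k_range=list(config.k_range),
                seeds=seeds,
                alpha_topic=config.alpha_topic,
                beta_word=config.beta_word,
                n_iter=config.n_iter,
            )
            reports.append(
                {"focus": focus, "context": ctx_seg.context,
                 "chosen_k": report.chosen_k, "table": report.table}
            )
            sigs = call_signatures(
                model, corpus, ctx_seg, occ,
                lambda_z=config.lambda_z,
                pos_frac=config.pos_frac,
                min_components=config.min_components,
                min_positive=config.min_positive,
            )
            for sig in sigs:
                define_negative_bins(sig, occ, promoter_rows, neg_frac=config.pos_frac)
            signatures.extend(sigs)
    return signatures, reports


def score_and_filter(
    signatures: list[Signature],
    occ: OccupancyMatrix,
    annotations: CapAnnotations,
    rbs_rows: np.ndarray | None,
    config: RunConfig,
) -> tuple[list[CondSig], list[CondSig]]:
    """Condensation-feature AUROC filtration + dedup. Returns (final, all scored)."""
    scored = filter_condsigs(
        signatures, occ, annotations, rbs_rows,
        auroc_min=config.auroc_min,
        mean_top3_min=config.mean_top3_min,
        min_passing=config.min_passing,
        mlo_mode=config.mlo_mode,
    )
    final = deduplicate([c for c in scored if c.is_condsig], config.dedup_jaccard)
    return final, scored


def detect(
    occ: OccupancyMatrix,
    promoter_flags: np.ndarray,
    annotations: CapAnnotations,
    config: RunConfig,
    rbs: np.ndarray | None = None,
) -> DetectionResult:
    """Full detection on a filtered occupancy matrix.

    ``promoter_flags`` and ``rbs`` are per *global* bin (aligned to
    ``occ.binning``); they are re-indexed to the retained rows here.
    """
    promoter_rows = np.asarray(promoter_flags)[occ.bin_index]
    rbs_rows = None if rbs is None else np.asarray(rbs)[occ.bin_index]
    if rbs is None:
        logger.info("no RNA-binding-strength track: scoring 5 features")
    signatures, reports = detect_signatures(occ, promoter_rows, config)
    final, scored = score_and_filter(signatures, occ, annotations, rbs_rows, config)
    return DetectionResult(final, scored, signatures, reports, occ, promoter_rows)


# ---------------------------------------------------------------------------
# file-level entry points and output writing


def load_inputs(
    peaks_dir: str | Path,
    chrom_sizes_path: str | Path,
    genes_path: str | Path,
    annotations_path: str | Path,
    ppi_path: str | Path | None = None,
    blacklist_path: str | Path | None = None,
    rbs_path: str | Path | None = None,
    config: RunConfig | None = None,
):
    """Read all detect inputs from disk into pipeline-ready objects."""
    config = config or RunConfig()
    sizes = genome_io.read_chrom_sizes(chrom_sizes_path)
    binning = GenomeBinning.from_chrom_sizes(sizes, config.bin_width)
    bed_files = sorted(Path(peaks_dir).glob("*.bed"))
    if not bed_files:
        raise FileNotFoundError(f"no .bed files in {peaks_dir}")
    peaksets = [genome_io.read_bed(p, chrom_sizes=sizes) for p in bed_files]
    genes = genome_io.read_genes_bed(genes_path)
    promoter_flags = genome_io.promoters_from_genes(genes, binning, config.promoter_flank)
    caps = [ps.cap_name for ps in peaksets]
    annotations = genome_io.read_cap_annotations(annotations_path, ppi_path, known_caps=caps)
    blacklist = (
        genome_io.read_bed(blacklist_path, chrom_sizes=sizes).intervals
        if blacklist_path
        else None
    )
    rbs = genome_io.read_signal_bedgraph(rbs_path, binning) if rbs_path else None
    occ = build_occupancy_matrix(binning, peaksets)
    occ = filter_matrix(occ, blacklist, config.min_events, config.max_frac)
    return occ, promoter_flags, annotations, rbs


def condsigs_table(result: DetectionResult) -> pd.DataFrame:
    """Tabular summary of the final CondSigs."""
    rows = []
    for cs in result.condsigs:
        sig = cs.signature
        row = {
            "condsig_id": sig.id,
            "context": sig.context,
            "focus_cap": sig.focus_cap,
            "components": ",".join(sig.components),
            "top5_components": ",".join(sorted(cs.top_components(5))),
            "component_zscores": ",".join(
                f"{sig.component_z[c]:.4f}" for c in sig.components
            ),
            "n_positive_bins": sig.n_positive,
            "n_negative_bins": int(sig.neg_rows.size),
            "mean_top3_auroc": round(cs.mean_top3_auroc, 6),
            "passing_features": ",".join(cs.passing_features),
        }
        for name, val in sorted(cs.aurocs.items()):
            row[f"auroc_{name}"] = round(val, 6)
        rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(result: DetectionResult, out_dir: str | Path, config: RunConfig) -> None:
    """Write condsigs.tsv, positive-site BEDs, selection reports and config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    condsigs_table(result).to_csv(out / "condsigs.tsv", sep="\t", index=False)
    sites = merged_positive_sites(result.condsigs, result.occ)
    write_bed(out / "positive_sites.bed", sites)
    per_sig_dir = out / "condsig_bins"
    per_sig_dir.mkdir(exist_ok=True)
    for cs in result.condsigs:
        name = cs.id.replace("|", "_").replace("/", "_")
        intervals = [
            result.occ.binning.bin_interval(int(b)) for b in cs.signature.positive_bins
        ]
        write_bed(per_sig_dir / f"{name}.bed", intervals)
    tables = []
    for rep in result.selection_reports:
        t = rep["table"].copy()
        t.insert(0, "focus", rep["focus"])
        t.insert(1, "context", rep["context"])
        t["chosen"] = t["k"] == rep["chosen_k"]
        tables.append(t)
    if tables:
        pd.concat(tables, ignore_index=True).to_csv(
            out / "selection_report.tsv", sep="\t", index=False, float_format="%.6f"
        )
    config.to_yaml(out / "config_echo.yaml")
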