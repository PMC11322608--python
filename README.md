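# condsig

Detection of condensate-like chromatin-associated protein (CAP) co-occupancy
signatures — **CondSigs** — from peak data.

Many chromatin regulators concentrate in biomolecular condensates, and their
genomic binding profiles carry a footprint of that behaviour: specific sets of
CAPs co-occupy the same loci far more often than chance, and those sets are
enriched for phase-separation capacity, shared membrane-less organelle (MLO)
membership, intrinsically disordered regions (IDRs), dense protein–protein
interactions and RNA binding. `condsig` turns a collection of per-CAP peak
files into a ranked list of such signatures, for genomics groups who have
dozens-to-hundreds of ChIP-seq peak sets for one cell type and want candidate
condensate components and the loci where they act.

## Method

1. **Occupancy matrix.** The genome is tiled into 1 kb bins
   B = {b_1..b_n}; for CAPs C = {c_1..c_m} a binary matrix O has
   O_ij = 1 iff CAP j has ≥1 bp of peak overlap with bin i. CAPs with
   <500 occupancy events, bins occupied by >90 % of CAPs and blacklisted bins
   are removed.
2. **Segmentation.** For each focus CAP c_f, every other CAP's occupancy
   vector is scored as a predictor of the focus CAP's with an F1 statistic
   β_j; the top q = 50 CAPs form the segment members. With γ = z-scored β,
   each bin gets an occupancy score δ_i = Σ_j γ_j O_ij and bins with
   δ_i > 0 form the segment, split into promoter (TSS ± 3 kb) and
   non-promoter contexts.
3. **Biterm topic model.** Each segment bin is a document whose words are the
   occupied member CAPs. A biterm topic model — collapsed Gibbs sampling over
   unordered word pairs, the right regime for such short documents — yields
   Φ (word | topic) and Θ (topic | document). The topic number k ∈ 2..10 is
   selected automatically by combining a specificity score
   SS_k = log(k⁻¹ Σ_j σ_j/μ_j²) over Θ columns with a purity score
   PS_k = log(p⁻¹ Σ_i σ_i) over Θ rows, via CS_k = αSS_k + (1−α)PS_k with
   α = PS_k/(SS_k+PS_k).
4. **Signature calling.** Per topic, component CAPs are words with
   z(Φ_tj) > 1.3; signature-positive bins are those occupied by ≥80 % of the
   components (≥3 components and ≥200 positive bins required).
5. **Condensation filtration.** Against context-matched, comparably occupied
   negative bins, six per-bin features — F_LLPS, F_MLO, F_IDR, F_PPI, F_RBP
   (fractions of occupied CAPs with each property) and S_RBS (RNA-binding
   strength) — are compared by rank-based AUROC. A signature is a CondSig if
   ≥3 features have AUROC > 0.6 and the top-3 mean exceeds 0.65. Redundant
   CondSigs (top-5 component Jaccard > 0.25) are removed greedily by mean
   AUROC.

Protein-level utilities annotate charged amino-acid blocks (10-residue NCPR
windows beyond ±0.5, merged) and cluster PS-Self/PS-Part scores into
Both / Self / Part / None with fixed-centroid k-means. Post-processing
classifies each CAP's peaks and merged-peak domains into CondSig-positive and
-negative sets, optionally refined by chromatin accessibility, and extracts
high-confidence sites with >1.5-fold signal over the CAP's negative peaks.

## Worked example

`examples/01_simulate_and_detect.py` simulates a 3 Mb genome with 20 CAPs and
two planted 5-component signatures, then runs the full pipeline:

```
occupancy matrix: 3000 bins x 20 CAPs after filtering
               condsig_id      context                    components  mean_top3_auroc  n_positive_bins
CAP12|non-promoter|topic1 non-promoter CAP02,CAP00,CAP01,CAP03,CAP04         0.945057              271
    CAP19|promoter|topic2     promoter CAP06,CAP09,CAP08,CAP07,CAP05         0.918987              210

match against the planted ground truth:
  planted ['CAP00', 'CAP01', 'CAP02', 'CAP03', 'CAP04'] (non-promoter): component Jaccard 1.00, bin recall 0.86
  planted ['CAP05', 'CAP06', 'CAP07', 'CAP08', 'CAP09'] (promoter): component Jaccard 1.00, bin recall 0.69
```

Both planted signatures are recovered exactly (component Jaccard 1.0) with
strong mean condensation-feature AUROCs; bin recall is the fraction of planted
bins called signature-positive. The other examples demonstrate topic-number
selection (`02`), protein annotation (`03`) and peak/domain classification
(`04`).

## Command line

```bash
condsig simulate --out sim --seed 4
condsig detect --peaks-dir sim/peaks --chrom-sizes sim/chrom.sizes \
    --genes sim/genes.bed --annotations sim/annotations.tsv \
    --ppi sim/ppi.tsv --rbs sim/rbs.bedgraph --seed 11 --out run
condsig postprocess --peaks sim/peaks/CAP00.bed --cap CAP00 \
    --sites run/positive_sites.bed --out pp
condsig annotate-proteins --fasta sim/sequences.fasta --out prot
```

`detect` writes `condsigs.tsv`, per-CondSig and merged positive-site BEDs, a
topic-number selection report and a config echo sufficient to reproduce the
run byte-identically.

Input formats: peaks/blacklist/ATAC as BED3+, `chrom.sizes` (two columns),
genes as BED6 (strand required), signal as 4-column bedGraph, annotations as a
TSV with columns `cap  llps  mlos  idr  rbp  ps_self  ps_part` (MLOs
comma-separated), PPI edges as a TSV with `cap1  cap2`, protein sequences as
FASTA.

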