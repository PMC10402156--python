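# stripehic

Predict 10kb-resolution, Z-score-normalized 3D chromatin contact maps from
single-cell ATAC-seq alone. From a 10x-style fragments file the package
builds three inputs — a 50bp pseudobulk accessibility track, a 50bp CTCF
motif/ChIP score track, and 500bp metacell Jaccard co-accessibility — and
trains a two-feature-extractor convolutional network that predicts one-sided
"V-stripes" (the contacts between one 10kb bin and all bins within 2Mb).
Stripes are assembled into chromosome-wide maps, and a one-epoch fine-tune
plus per-cluster inference deconvolves bulk Hi-C into cluster-specific maps.

The network and its training loop are implemented on a small numpy
reverse-mode autodiff engine (`stripehic.nn`), so the package runs on a
plain scientific-Python stack with no deep-learning framework and no GPU.
A fully parameterized window geometry lets the identical code run at a
miniature scale (0.41Mb windows) for desk-size experiments and tests.

## Layout

| module | contents |
| --- | --- |
| `io_formats` | fragments/BED/bedGraph/contact-triplet/chrom.sizes readers and writers (0-based half-open everywhere) |
| `tracks` | cell QC, pseudobulk accessibility, PWM scanning, CTCF motif/ChIP tracks, window extraction |
| `coaccess` | LSI embedding, Cicero-style overlapping kNN metacells, Jaccard co-accessibility slices |
| `hic` | contact-map container, distance-stratified Z-score stand-in, clipping, low-signal masks, V-stripe targets, top-decile labels |
| `nn`, `model`, `geometry` | autodiff engine; feature extractors, outer-concatenation, shared-weight left/right stripe prediction |
| `dataset`, `training` | window-example assembly; two-stage training with cell/metacell subsampling, ±50bp shifts, masked MSE, early stopping, 1-epoch fine-tuning |
| `inference` | chromosome-wide V-stripe assembly; per-cluster deconvolution |
| `evaluation` | distance-stratified Pearson, bin/peak-level AUROC/AUPRC, insulation score, paired t-test |
| `synthetic` | paired scATAC + contact-map simulator with planted, cluster-specific loops and accessibility-matched decoys |
| `cli` | `stripehic` command with all subcommands |

## CLI walkthrough

```bash
stripehic simulate --seed 7 --out data/            # fragments, CTCF, Hi-C, peaks
stripehic preprocess --fragments data/fragments.tsv \
    --chrom-sizes data/chrom.sizes --out prep/      # QC + pseudobulk bedGraph
stripehic coaccess  --fragments data/fragments.tsv \
    --chrom-sizes data/chrom.sizes --out coa/       # metacell assignment
stripehic train     --data data/ --out model.npz    # stage 1 + stage 2
stripehic predict   --data data/ --checkpoint model.npz \
    --chrom chr3 --out pred_chr3.tsv
stripehic evaluate  --pred pred_chr3.tsv --truth data/contacts_bulk.tsv \
    --chrom-sizes data/chrom.sizes --max-distance 200000 --out metrics.csv
stripehic finetune  --data data/ --checkpoint model.npz --out tuned.npz
stripehic deconvolve --data data/ --checkpoint tuned.npz \
    --chrom chr3 --out-dir deconv/
stripehic compare   --metrics-a a.csv --metrics-b b.csv
```

Real-data use follows the same paths: fragments TSV(.gz) plus a contact
table holding either raw counts (normalized internally by the
distance-stratified Z stand-in) or precomputed normalized Z-scores, and a
CTCF bedGraph (motif scores or ChIP signal).

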