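# proxifilter

Reference-anchored quality assessment and contaminant removal for
proximity-labeling (spatially resolved) proteomics.

Given a protein quantification table whose columns are labeled-to-control
ratios (e.g. TMT channel pairs) and two plain-text reference lists —
curated residents of the target compartment (true positives) and known
contaminants (false positives) — proxifilter:

1. **checks replicate consistency** by pairwise correlation of the ratio
   columns (Pearson on log2 ratios, or Spearman);
2. **ranks** each column descending and scans it against the references,
   producing per-rank TPR/FPR/(TPR−FPR) curves, the ROC curve and its AUC
   (tie-blocked trapezoidal, equal to the Mann–Whitney statistic);
3. **cuts off** each ranking at the rank where TPR−FPR peaks, retaining
   everything above it — unannotated proteins included;
4. **intersects** the per-column retained sets into the final proteome;
5. optionally runs **over-representation analysis** (hypergeometric test,
   Benjamini–Hochberg FDR) of the final proteome against user-supplied
   annotation term sets;
6. renders the matching **plots** (correlation grid, rank curves, ROC with
   cutoff marker, ORA bars) and writes all result tables plus a YAML
   manifest and run summary.

A synthetic-data module (`proxifilter.synth`) generates ratio tables with a
two-component log-normal structure — including a "failed enrichment" mode
whose ratios are independent of the labels — so the whole pipeline is
testable without any downloads.

## CLI

```sh
# full pipeline: QC -> curves/cutoff -> intersection -> top-N -> ORA -> plots
proxifilter run --input ratios.csv --tp surface.txt --fp intracellular.txt \
    --outdir out/ [--columns 129C:127N,129C:127C] [--annotations terms.tsv]

# individual stages
proxifilter qc --input ratios.csv --out corr.tsv
proxifilter cutoff --input ratios.csv --tp tp.txt --fp fp.txt --outdir out/
proxifilter ora --study study.txt --background bg.txt --annotations terms.gmt --out ora.tsv
proxifilter synth --outdir sim/ --n-tp 1000 --n-fp 1000 --failed --seed 1
proxifilter subsample-ref --tp tp.txt --fp fp.txt --fraction-tp 0.1 --outdir sub/
proxifilter plot --input ratios.csv --tp tp.txt --fp fp.txt --column R1 --kind roc --out roc.png
```

Input conventions: CSV/TSV with a header row, first column UniProt
accessions (isoform suffixes and FASTA-header tokens are normalized away by
default); reference lists are one accession per line with `#` comments.
Ratios must be positive; non-positive or unparseable cells are treated as
missing for the affected column only. An AUC below 0.7 across all columns
triggers a warning that enrichment may have failed (an AUC near 0.5
indicates random capture); it never aborts the run.

## Library

```python
import proxifilter as pf

table = pf.read_ratio_table("ratios.csv")
ref = pf.read_reference("surface.txt", "intracellular.txt")
curves, result, tops = pf.analyze_table(table, ref)
curves[0].auc, curves[0].cutoff_rank, len(result.final_proteome)
```

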