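# haircut

Processing and evaluation toolkit for single-cell DNA-repair hairpin
("Haircut") assays.

In a Haircut experiment, synthetic polyadenylated DNA hairpins carrying
defined lesions (a uracil paired with A or G, an embedded ribonucleotide,
an abasic site, or no lesion) are spiked into a droplet single-cell 3'
gene-expression run. Inside each droplet, repair enzymes from the lysed
cell incise the hairpin strand; reverse transcription from the polyA tail
then captures the incised strand, so the 5' alignment position of the
substrate-derived read reports *where* the strand was cut — e.g. uracil
excision by UNG followed by abasic-site cleavage produces reads starting
one base downstream of the lesion, while RNASEH2 incision 5' of a
ribonucleotide produces reads starting at the lesion itself. Counting
unique molecules per cell barcode, substrate and position turns a
sequencing run into thousands of parallel single-cell biochemistry
measurements.

This package implements the computational half of that assay, for people
building or analyzing such experiments:

- **read processing** — cell barcode (16 nt) + UMI (10 nt) extraction from
  R1 with whitelist Hamming-1 correction; template-switch-oligo and polyA
  trimming of R2;
- **alignment** — exhaustive ungapped forward-strand placement of trimmed
  reads on the ~50-100 nt hairpin references (the 5' start position is the
  incision readout; indels and reverse-complement hits are excluded by
  construction);
- **UMI deduplication** — per-(cell, substrate, position) directional
  grouping: a UMI `b` is absorbed into a Hamming-1 neighbor `a` when
  `count(a) >= 2*count(b) - 1`;
- **matrices** — sparse cells x `substrate:position` count matrices with
  10x-style MatrixMarket I/O, plus empty-droplet ambient background
  profiles;
- **activity scores** — per-cell repair activity
  `ln(1 + count_site / total_cell * 1e4)` at each scored incision site, and
  pairwise two-sided Wilcoxon rank-sum comparisons between cell groups
  with Bonferroni (or BH) correction;
- **genotype calling** — knockout mixing experiments: a cell whose uracil-
  site count exceeds 5% of the per-activity maximum while its
  ribonucleotide-site count does not is `RNASEH2C_KO` (and vice versa);
  both high is a doublet, both low is unclassified;
- **evaluation** — one-vs-rest confusion/TPR/FPR, label-permutation
  baselines, nearest-centroid classification, and read-level downsampling
  sensitivity curves;
- **droplet chemistry** — expected hairpin molecules per droplet,
  `(C/2) * 270 pl * 6.02e23`, and per-droplet recovery fractions;
- **simulator** — a seeded generator of complete synthetic experiments
  (FASTQ pairs plus per-read and per-cell ground truth) covering
  genotype-specific incision distributions, intact substrates, empty-drop
  background, UMI duplication and sequencing error.

## Worked example

Simulate a knockout cell-mixing experiment (30 UNG-null + 30
RNASEH2C-null cells plus doublets and empty droplets), process it, and
call genotypes:

```sh
haircut simulate --n-per-genotype 30 --seed 5 --out simdir
awk -F'\t' 'NR>1 && $2!="empty" {print $1}' simdir/truth_cells.tsv > cells.txt
haircut count --r1 simdir/r1.fastq.gz --r2 simdir/r2.fastq.gz \
    --whitelist simdir/whitelist.txt --substrate-table simdir/substrates.tsv \
    --cells cells.txt --out countdir
haircut classify --matrix-dir countdir/matrix --out calls.tsv
```

The `count` step prints its QC accounting — every input read pair lands
in exactly one category:

```
QC: {"ambiguous": 0, "counted": 13064, "discarded_short_r2": 0,
     "excluded_short_r1": 0, "umi_contains_n": 0, "unaligned": 11,
     "unmatched_barcode": 3}
```

and `calls.tsv` holds one genotype call per cell with the site counts the
decision used:

```
cell_barcode      label   uracil_site_count  ribo_site_count  uracil_fraction_of_max  ribo_fraction_of_max
AAATGTGACCGGCATT  UNG_KO  0                  29               0.0000                  0.9062
AAGGGAACTAACCAGA  UNG_KO  0                  25               0.0000                  0.7812
```

A cell with 29 deduplicated molecules at the ribonucleotide incision site
(`riboG:44`) and none at the uracil site (`uracilA:45`) has ribonucleotide
repair but no uracil repair, hence carries the UNG knockout.

Droplet loading estimates, at one significant figure:

```
$ haircut chem --conc 0.5 --conc 2.5 --conc 5 --conc 10 --conc 25
conc_nM  molecules_per_drop  rounded_1_sig_fig
0.5      40635               40000
2.5      203175              200000
5        406350              400000
10       812700              800000
25       2.03175e+06         2e+06
```

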