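# Methods

## The measurement model

A Haircut substrate is a single-stranded view of a polyadenylated DNA
hairpin with one synthetic lesion at a known 1-based position. Strand
incision by a cellular repair enzyme creates a new 5' end; reverse
transcription primed on the polyA tail copies the strand up to that end,
so the substrate-derived read, aligned to the hairpin reference in the
forward orientation, starts exactly at the incision position. An
unincised hairpin yields a read starting at position 1 (reverse
transcription of the intact strand runs to the reference 5' end; the
physical oligo's terminal spacers are never sequenced). The package
therefore treats the pair (substrate, 5' start position) as the unit of
biochemical signal and counts unique molecules per cell at each such
pair.

Coordinates are 1-based and inclusive everywhere. The example panel puts
every lesion at position 44 and scores uracil incision at 45 (the glycosylase
leaves an abasic site whose cleavage product starts one base downstream),
ribonucleotide incision at 44 (RNASEH2 cuts 5' of the ribonucleotide and
the reverse transcriptase copies through it), and abasic short-/long-patch
processing at 45/46.

### Example substrate length

The example substrates are 70-mers. The printed coordinate layout
(lesion 44, scored sites 44-46) is kept, but the reference must extend
far enough 3' of the lesion that an incised read — which spans from the
incision position to the reference end — clears the 20 nt post-trim
minimum length; at 70 nt an incision read at position 45 is 26 nt. The
five fixed sequences were chosen once so that any read of >= 20 nt placed
at any wrong (substrate, offset) pair carries at least 7 mismatches
(alignment with a 2-mismatch budget can never be ambiguous between them),
and so that the final six bases contain no A (polyA trimming cannot bite
into the reference).

## Read processing

R1 is a positional slice: barcode = bases 1-16, UMI = bases 17-26 (10x 3'
v2 layout); shorter reads are tallied and dropped, trailing bases ignored.
Barcode correction follows the droplet-sequencing convention: exact
whitelist hit, else a unique Hamming-1 neighbor; zero or multiple
neighbors leave the read unmatched. No quality weighting is used — with a
known whitelist the unique-neighbor rule recovers essentially all
correctable errors at these error rates. UMIs containing N are dropped
and tallied; UMIs are otherwise not quality-filtered.

R2 trimming removes a 5' template-switch remnant when the read's
full-length prefix matches the TSO with at most one mismatch. The default
TSO is the 3'-most 13 nt of the canonical 10x template-switch oligo
(`CAGAGTACATGGG`) — the portion template switching appends to the cDNA —
and is overridable. The polyA tail is the longest 3' suffix that (a) is at
least 6 bases, (b) is at least 90% A, and (c) itself begins with an A.
Condition (c) matters: without it the 10% tolerance absorbs trailing
non-A read bases ahead of the tail (a body ending `...CGT` followed by
20 A's is 95% A over 21 bases), shaving reference bases off every read.
Products shorter than 20 nt after trimming are discarded (tallied):
below that, unique placement on ~50-100 nt references is unreliable.

## Alignment

Hairpin references are short synthetic sequences, so alignment is an
exhaustive, deterministic scan rather than a heuristic mapper: the read
is placed at every forward-strand offset of every reference at which it
is fully contained, mismatches are counted (vectorized over offsets), and
the placement with the fewest mismatches wins if it is unique and within
the budget (default 2). Ties are never broken — ambiguous reads are
tallied and excluded, because a guessed start position would corrupt the
positional signal. Indels are not modeled for the same reason. Reads
longer than a reference cannot align to it (a 3' overhang implies
untrimmed tail, handled upstream). Equivalence to a brute-force
all-offsets oracle is asserted over random instances in the test suite.
Aligned reads can be exported as SAM with `XT` (= `substrate:position`),
`CB` (corrected barcode) and `UB` (UMI) tags.

## UMI deduplication

Within each (cell, substrate, position) stratum, UMIs are grouped
directionally: a directed edge a -> b exists when Hamming(a, b) = 1 and
count(a) >= 2*count(b) - 1; clusters are the sets reachable from
unvisited roots, processing roots in descending count order with
lexicographic tie-break. The tie-break makes the result independent of
input order. The molecule count of a stratum is its number of clusters.
Grouping is deliberately per-position: merging UMIs across adjacent
positions would blur distinct incision products. A `unique` method (one
cluster per distinct UMI) is available for comparison. Equivalence to an
exhaustive pairwise adjacency-graph oracle is asserted in the suite.

## Matrices and background

The count matrix is sparse cells x `substrate:position`, restricted to a
supplied cell-barcode list (in a real experiment, the mRNA pipeline's
filtered barcodes); listed cells without signal keep zero rows, and
features are the observed keys sorted by substrate then position. A
rank-based fallback cell caller (top N barcodes by total molecules) is
provided for purely synthetic runs; it is plumbing, not a statistical
cell caller (no knee-point or ambient-model calling is attempted).
Serialization is the 10x-style triplet (MatrixMarket + barcodes.tsv +
features.tsv).

Empty-droplet background: barcodes outside the cell list are ranked by
total molecule count (descending, ties lexicographic) and the top N
retained, N defaulting to the number of cell-associated barcodes — this
ranking implicitly discards the long tail of single-UMI barcodes. The
profile is the mean count per position across retained drops, counting
absent entries as zero.

## Activity scores and comparisons

Counts are normalized per cell: `ln(1 + count / total * 1e4)`, where the
total is the cell's summed repair counts. The `log1p` form keeps zeros at
zero. The denominator pools repair features only — the repair matrix is
normalized standalone, without mRNA counts; in an experiment that also
captures mRNA, pooling both fractions in the denominator would shift
every score, so absolute score scales depend on this choice even when
relative patterns agree.
A cell's activity at a scored site is the normalized value of the raw
count there (summed over positions for multi-site activities such as a
combined long-patch window).

Group comparisons use the two-sided Mann-Whitney U test for every
activity and every group pair: exact p-values for small untied samples,
otherwise the normal approximation with tie correction
(`scipy.stats.mannwhitneyu(method="auto")`). The log fold change is the
difference of group mean scores (already log-scale). Multiple-testing
correction is applied across all reported tests, Bonferroni by default
with Benjamini-Hochberg as an option. Groups with fewer than two cells
are skipped.

## Genotype calling and evaluation

The mixing-experiment caller uses raw counts at the uracil incision site
and the ribonucleotide incision site. With `max_u`, `max_r` the
per-activity maxima over all cells, a count is "high" when strictly
greater than 5% of its maximum and "low" otherwise; exact equality falls
to the low side (the strict inequalities of the rule leave equality
unassigned; assigning it low is the conservative choice). High/low
combinations map to: uracil-only -> `RNASEH2C_KO`, ribo-only ->
`UNG_KO`, both high -> doublet, both low -> unclassified. Because the
threshold is relative to the maxima, scaling both count vectors leaves
every label unchanged. A zero maximum for either activity is rejected as
a degenerate experiment.

Evaluation: one-vs-rest confusion per true class (doublet/unclassified
predictions count as negatives for every class), TPR/FPR with 0/0
reported as undefined, a seeded label-permutation baseline whose expected
per-class TPR equals the class frequency, and a nearest-centroid
classifier (Euclidean, lexicographic tie-break) as a simple stand-in for
reference-based label transfer. Downsampling sensitivity operates at read
level *before* deduplication — per cell, reads are sampled without
replacement to each target depth, molecules are re-deduplicated, and
cells reclassified; a target at or above the deepest cell reproduces the
full-depth result exactly.

## Droplet chemistry

Molecules per droplet = `(C / 2) * V * N_A` with C the master-mix molar
concentration (halved because droplet formation doubles the mix volume),
V = 270 pl and `N_A = 6.02e23`. The stated 270 pl is used directly rather
than recomputed from the 80 um droplet diameter (a sphere of that
diameter is ~268 pl); the diameter is kept as metadata. Estimates are
reported at one significant figure, the precision at which per-drop
loading is meaningfully quoted; recovery fractions divide a droplet's
aligned read count by the estimate.

## Simulator

The generator emulates, per droplet: Poisson molecule capture per
substrate (mean = profile depth), incision positions drawn from the
profile's categorical distribution (intact mass at position 1), one
uniform random UMI per molecule, geometric read multiplicity (mean 2),
optional TSO prefix per read (probability 0.5), the substrate suffix from
the incision position plus a 30 nt polyA tail, and independent per-base
substitution errors (default 1e-3) on both mates. Doublets merge two
profiles' draws under one barcode. Empty drops draw Poisson background
molecules (default mean 1 per substrate) with an intact-heavy position
distribution (90% at position 1, the rest on the scored sites). All draws
come from one seeded generator in a fixed order, and gzip headers are
normalized, so output is byte-identical per (config, seed).

The mixing configuration models the two-knockout experiment: each
genotype's active substrate puts probability 0.6 at the scored incision
site, 0.15 and 0.05 at the next two positions (downstream processing) and
0.2 intact; the other substrate is fully intact. Default depth is 40
captured molecules per cell per substrate with a 5% doublet rate, 500
empty drops and a 4000-barcode whitelist — sizes chosen to give clearly
resolvable per-cell signal at desk-scale runtimes (a 500+500-cell
experiment is ~180k read pairs and processes in seconds).

What the simulator does **not** model: the mRNA fraction and its
cross-talk, substrate dose-response over incubation time, droplet size
variation, barcode-sharing artifacts, PCR chimeras, indel sequencing
errors, and real cell-type incision efficiencies (profile probabilities
are declared parameters, not estimates). Passing end-to-end tests
therefore demonstrates correctness of the processing chain under the
stated generative model, not biological fidelity on real libraries.

## Numerical and degenerate-input choices

- All tie-breaks are explicit and deterministic (lexicographic after
  count ordering); permuting input order never changes any output.
- Equality at the 5% genotype threshold falls low; equality of centroid
  distances falls to the lexicographically first class.
- Zero-total cells normalize to zero rows; scored sites absent from the
  feature space count as zero rather than erroring.
- QC accounting is total: `counted + excluded_short_r1 + umi_contains_n +
  unmatched_barcode + discarded_short_r2 + unaligned + ambiguous` equals
  the number of input read pairs, asserted in tests.

## Known limitations

- The per-cell normalization denominator excludes mRNA counts (see
  above).
- The aligner's exhaustive scan is quadratic in reference length and is
  intended for hairpin-sized references, not genomes.
- The empty-drop ranking reproduces the descending-UMI filtering
  procedure; it is not a statistical ambient-RNA model.
- Genotype calling assumes exactly two complementary activities; more
  complex mixtures need the centroid or external classifiers.
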