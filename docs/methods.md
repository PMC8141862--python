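# Methods

## Problem and scope

`vquad` asks, for immunoglobulin heavy-chain V (IGHV) gene segments, whether
G-quadruplex (G4) structures are likely to form, on which strand, and how they
interact with the sequence preferences of activation-induced deaminase (AID)
during somatic hypermutation (SHM).  The package implements the complete
analysis chain — strand-resolved G4 scoring, attribution, in-silico saturation
mutagenesis, percent-mismatch track analysis, and repertoire mutability
statistics — together with seeded generators that emulate each external input
(germline allele sets, G4-seq-style mismatch tracks, mutated repertoires), so
that every stage is testable end to end without downloads.

## G4 potential scoring

A G4 scorer is any pure function mapping a DNA string to a potential in
[0, 1].  Learned scorers (convolutional networks over fixed-width one-hot
input) plug in through the `G4Scorer` contract; their weights are external and
are not shipped.  The built-in `ReferenceG4Scorer` is a deterministic
surrogate driven by the canonical quadruplex consensus

    G{3,} N(1,7) G{3,} N(1,7) G{3,} N(1,7) G{3,}

— four guanine runs of at least `min_run` (default 3) separated by loops of
1–7 nt.  Matches are found over maximal G-runs, scanning left to right; from
the earliest run that can anchor a complete chain the lexicographically
smallest valid chain is taken (earliest compatible next run, with
backtracking), and scanning resumes past the emitted match.  Pure greedy
next-run choice without backtracking can dead-end and miss a real match, so
the backtracking rule is the one both the implementation and the brute-force
test oracle pin down.

The surrogate score is `1 − 2^(−q)` with `q = Σ (min-run-length − 2)` over
non-overlapping matches: 0 with no match, 0.5 for a single minimal motif, and
approaching 1 as motifs accumulate or runs lengthen.  The constants are fixed
design choices that make strand logic and motif bookkeeping exact and
bit-reproducible; the numbers are *not* comparable to a trained model's
outputs, and analyses that need a learned scorer should supply one through
the contract.

Bottom-strand potential is always the score of the reverse complement;
every coordinate reported anywhere in the package is a top-strand coordinate.

## One-hot convention and attribution

Learned scorers consume a fixed-width (default 297 nt) flat one-hot vector of
length 4×width in base order A, C, G, T.  Shorter sequences are zero-padded at
the 3' end; longer ones keep their 5'-most `width` nt, the choice consistent
with 3'-end padding.  Attribution uses integrated gradients from an all-zeros
baseline: the straight-line path integral of the scorer's gradient,
approximated by a right-endpoint Riemann sum at `n_steps` (default 128).  The
completeness gap |Σ attributions − (f(x) − f(0))| is reported alongside; it is
zero for linear scorers and shrinks as 1/n_steps for smooth ones, which the
tests verify against the analytic integral of a quadratic scorer.

## In-silico mutagenesis and AID context

Saturation mutagenesis runs two sweeps over a germline: every non-G base is
substituted by G (one record per site), and every G is replaced by each of
A/C/T with the three mutant potentials averaged into one record.  Both strands
are rescored from scratch for every mutant — a substitution changes both
strand contexts, so no antisymmetry is assumed.  C sites are classified from
the two bases 5' of the C on the strand where the C lives: WRC (W=A/T, R=A/G)
hotspot, SYC (S=C/G, Y=C/T) coldspot, otherwise neutral; sites with fewer
than two 5' context bases are neutral by convention.  Bottom-strand C sites
are the top-strand G positions, classified off the reverse complement and kept
in top-strand coordinates.

Strand-effect summaries place each classified mutant's delta on each strand
into a (site class × strand mutated × strand affected) grid, with pairwise
two-sided Mann–Whitney U tests between classes; per-trinucleotide tables
report mean ± sd delta with an optional one-sample Wilcoxon test against 0.
The "no difference" band is ±0.01 on the score scale by default — the
same/opposite/no-effect distinction needs a numeric cut and 1% of the score
range is well below any effect the surrogate scorer can produce by
motif gain or loss (its minimum step is 0.25 for a single minimal motif at
unit q).  P-values are raw throughout; a Benjamini–Hochberg switch exists but
is off by default to match how such analyses are conventionally reported.

## Mismatch tracks and observed G4s

G4-seq-style assays report percent read mismatches per interval, strand by
strand (two bedGraph files; strand is out of band).  An observed G4 is a
maximal run of intervals at or above the calling threshold (default 25%),
merged at zero gap with no minimum length.  Region statistics use the maximum
and the width-weighted mean over covered positions only — uncovered positions
are excluded rather than imputed as zero, since the assay reports mismatches
only where reads align; a region with no coverage reports missing values, not
zeros.  Motif densities count possibly-overlapping occurrences per nt
(AGCTAGCT contains two AGCT).  Potential-vs-activity concordance uses
Spearman correlation per strand on per-gene maximum mismatch, plus a
two-sided Mann–Whitney U comparison of the strands; a constant vector yields
an undefined (not zero) correlation.

## Repertoire mutability

Repertoires must arrive pre-aligned to their germline, substitutions only,
with N marking uncovered positions (indel handling is upstream alignment
work, out of scope).  The unit of analysis is the per-site mutation frequency
(mutated reads / covering reads), averaged over the occurrences of each
WRC/SYC motif per strand; a tabular per-site count format is accepted for
privacy-reduced data.  The top−bottom difference in hotspot mutability is
correlated (Pearson) against each strand's G4 potential across genes,
requiring at least three genes; per-gene potential defaults to the mean over
alleles.  The CCC-coldspot split takes top-strand CCC sites, divides them by
the predicted bottom-strand delta of their in-silico C>G mutant
(negative change: delta < −ε; no difference: |delta| ≤ ε; sites raising the
potential beyond +ε are excluded), and compares the two groups' mutation
frequencies with a two-sided Mann–Whitney U test.

## Synthetic data: what it emulates and what it does not

The germline generator produces ~300 nt V-like alleles across families
IGHV1–IGHV7 with a proportional FW1…CDR3-part region layout, IMGT-style `.`
gap placeholders inside CDR1/CDR2, planted canonical G4 cassettes on a chosen
strand, and planted AID motifs.  Backgrounds are sampled with every G- and
C-run capped below the canonical minimum run length and features are kept
more than one loop-length apart with A/T flanks, so the planted cassettes are
exactly the canonical matches a scanner finds, on either strand — ground
truth is exact by construction.  Defaults follow the study design the package
emulates: 40 genes (the number of functional IGHV genes locatable in the
reference genome), with cassettes in half of them so carriers and
non-carriers can be contrasted.

The SHM generator mutates each site of each read independently at a base rate
of 1e-3 per nt (the physiological per-division order of magnitude), scaled by
hotspot/coldspot multipliers at WRC/SYC targeted-C sites and by an optional
G4 strand-coupling factor that multiplies (a) motif sites on the strand
carrying a planted cassette and (b) CCC coldspots opposite a cassette
footprint — the two couplings the mutability analyses are designed to detect.
Coupling products are capped at 1 with a log notice; a base rate × multiplier
already above 1 is rejected as a configuration error.

The track generator tiles each gene with fixed-width intervals of
truncated-normal background (mean 5%, sd 2%) and elevates intervals over
cassette footprints to ~60% on the cassette's strand, then emits matching BED
regions.  The fixtures do not model read-level sequencing error, coverage
gradients, polymerase-stalling biophysics, clonal structure, or selection —
so passing recovery tests demonstrates the *statistical machinery* is correct
at realistic effect sizes, not that real G4-seq or repertoire data will be as
clean.

## Numerical and design choices

- Coordinates: 1-based inclusive for IMGT/gapped positions; 0-based
  half-open for all BED/bedGraph intervals.
- One-hot base order fixed at A,C,G,T; adapters for scorers with other
  orderings permute on their side.
- N bases are rejected in scoring paths (scorers are defined over ACGT) and
  permitted in track/interval and alignment paths.
- Standard deviation of a single observation is reported as 0 so grouped
  summary tables have no missing cells; groups of n>1 use the sample (ddof=1)
  estimator.
- Reads containing N are scored after imputing the germline base at the
  uncovered positions.
- Problem sizes in the test suite and the reproduction script (40 simulated
  genes, 2000 reads for recovery checks, 200 replicates for null
  calibration, 500–1000 random instances for oracle-equivalence sweeps) were
  chosen so each recovery target has comfortable statistical resolution at
  desk scale; the null-calibration replicates use an elevated base rate
  (0.02 at 500 reads) so the rank statistic is effectively tie-free.

## Known limitations

- The built-in scorer is structural, not thermodynamic or learned: it sees
  only canonical G3+ motifs with loops ≤ 7 and scores in coarse steps, so
  subtle effects a trained model would register (long loops, bulged runs,
  two-tetrad G4s) are invisible to it.
- The published study-scale figures (per-family potentials of the real IMGT
  germline set, correlations against genome-wide G4-seq tracks, repertoire
  hotspot correlations) require those external datasets and a trained
  scorer's weights; this package reproduces the *methods* and validates them
  on synthetic analogues.
- Multi-site mutants and indels are out of scope, as are consensus building
  from reads, VDJ junction reconstruction, and S-region boundary detection
  (region definitions are user-supplied BED).
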