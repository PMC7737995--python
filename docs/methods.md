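# Methods

`haplokit` re-implements, as one tested Python package, a single-input
mitochondrial-DNA workflow: from an aligned multi-FASTA of cytochrome
*b* sequences to haplotype tables, population frequency matrices,
Hamming and K80 distance matrices, neighbor-joining trees with
bootstrap support, minimum-spanning haplotype networks, and the
associated figures. This note records the models, the defaults and why
they were chosen, the numerical conventions, and the known limitations.

## Input model

The single input is an aligned (equal-length) DNA multi-FASTA. Labels
are the full header line minus `>`, because the sampling convention
tags individuals as `<Population><sep><number>` with an underscore *or
a space* as separator (`Kumluca_6`, `Bayatbadem 24`); a
`--label-from first-token` switch restores the usual first-token
behaviour. Sequences are uppercased and U is mapped to T at read time
so every later stage sees a single DNA alphabet. The population of a
sample is obtained by stripping one trailing digit run together with
the single separator immediately before it; this generalises the
two-token convention safely to population names that themselves contain
separators (`Geyik_bayir_3` → `Geyik_bayir`). The rule is idempotent on
well-formed labels; a pathological population name that itself ends in
`<sep><digits>` cannot be represented unambiguously under this
convention at all, which is a property of the labelling scheme, not of
the parser. Multiple sequence alignment itself is out of scope: the
package requires pre-aligned input and offers only end trimming
(leading/trailing columns whose gap/N fraction exceeds a threshold;
interior columns are never touched, and the left offset is recorded).

## Haplotype extraction

Haplotype identity is exact string equality. Gaps and IUPAC ambiguity
codes are literal fifth/sixth states, never wildcards, so the partition
of samples into haplotypes is well defined without any phasing or
imputation. Ids H1..Hk follow first appearance in input order — the
ordering is presentation-only, so golden tests against the reference
dataset compare partitions, counts and distances, never id assignment.
Percentages use round-half-up to two decimals (55/120 → 45.83%), the
convention of the published table. A variable (polymorphic) site is any
column with two or more distinct states among the haplotype sequences;
`acgt_only` restricts this to definite-base differences. The reference
data are gapless, so either convention reproduces its 41-site table.
The dot-notation rendering (reference row verbatim, `.` where another
row agrees) is invertible given the reference row, and the package
round-trips it.

## Distances

* **Hamming**: literal count of differing positions over equal-length
  strings, all characters compared literally. This reproduces the
  published 20×20 haplotype matrix cell for cell, and is the weight
  function of the network. Because invariant columns contribute zero,
  Hamming over the variable-site strings equals Hamming over the full
  sequences; this cross-module identity is property-tested.
* **K80** (Kimura two-parameter): d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)
  with P and Q the observed transition (A↔G, C↔T) and transversion
  proportions over usable sites. Non-ACGT characters are excluded:
  by default under *global deletion* (any column containing a
  non-definite base in any sequence is dropped before all
  comparisons), mirroring the default of the distance routine the
  original workflow calls; *pairwise deletion* is available. Where a
  logarithm's argument is non-positive (saturated divergence) the
  package raises an explicit undefined-distance error rather than
  emitting NaN. No gamma rate correction is applied. The reference
  analysis prints no K80 value, so K80 is verified against the closed
  form and by property (q = 0 reduces to −½ ln(1 − 2p); the correction
  never shrinks the raw proportion), not against published numbers.

## Neighbor joining and bootstrap

NJ follows Saitou–Nei: join the pair minimising
Q(i,j) = (k−2)·d(i,j) − R_i − R_j, branch lengths
v_i = d(i,j)/2 + (R_i − R_j)/(2(k−2)), reduction
d(u,m) = (d(i,m)+d(j,m)−d(i,j))/2. Ties in Q are broken by the lowest
(i,j) index pair in the current matrix so results are identical across
platforms; the reference library leaves this to the implementation.
Negative branch lengths are retained by default (mirroring the
behaviour of the classical `nj()` and keeping the additivity oracle
exact — on tree-realisable matrices the output path lengths reproduce
the input to 1e−9); `clamp_negative` zeroes them for display.

Bootstrap support resamples alignment columns with replacement (seeded
NumPy generator), rebuilds the tree per replicate, and scores each
internal edge of the reference tree with the percentage of replicates
containing the same unrooted tip bipartition (Felsenstein semantics:
branch lengths ignored, trees treated as unrooted), rounded to the
nearest integer. A replicate whose distance matrix is undefined under
K80 is re-drawn, at most ten times, with a log record; this situation
cannot arise under Hamming. Supports are binned into the four
confidence categories black/red/pink/white. Two conventions exist for
the interval edges: the `cut()`-style left-open right-closed bins
(0,50] poor, (50,70] weak, (70,85] moderate, (85,100] strong — the
behaviour of the original plotting code — and the verbal rule under
which 85 itself is strong. The code convention is the default; the
verbal one sits behind `convention="text"`.

## Haplotype network

The backbone is a minimum spanning tree over the integer haplotype
Hamming matrix, computed by Kruskal's algorithm with deterministic
tie-breaking (weight, then lexicographic endpoint pair). On top of the
k−1 tree links, *alternative links* record equally parsimonious
connections: every non-tree pair whose weight equals the weight of the
edge that first connected its two components during construction. The
published network for the reference dataset reports 71 links in total;
that count depends on internals of the rendering library that are not
recorded anywhere, and is deliberately **not** reproduced or claimed.
Instead the rule above is documented exactly, and an explicit
`alt_threshold` lets users add all non-tree pairs up to a chosen
weight without pretending the original specified it. Link weights are
drawn as one tick per mutational step; no median/inferred intermediate
nodes are ever created (this is a minimum-spanning network, not a
median-joining one). Node pies are tabulated at the individual,
population, or group level and always reconcile with the frequency
matrix margins.

## Figures

All figures are pure functions of their inputs on a fixed backend:
the network layout is force-directed with a fixed seed, tree layouts
are deterministic. Node size scales with *area* ∝ frequency by default
(radius mode available): with a modal haplotype at 55 of 120, radius
scaling would visually exaggerate it. Default palettes follow the
reference figures where recorded (nucleotides
rosybrown/sienna/light-goldenrod/light-sky-blue; support
black/red/pink/white; groups blue/red/green); everything is
overridable via `PlotSpec`. The heatmap orders rows and columns by
complete-linkage hierarchical clustering of the given distances — the
original figure does not state its linkage, so complete linkage was
chosen and is recorded here; dark red marks small distances.
Pixel-level replication of the published figures is a non-goal.

## Bundled reference data and the synthetic reconstruction

The package ships the published tables for the 120-bee *B. terrestris
dalmatinus* cyt *b* survey (373 bp, eight populations of 15): the 20
haplotypes at 41 variable sites with frequencies, the 20×20 Hamming
matrix, and the haplotype-by-population counts. Two reconciliations
were needed:

* The population-count table as originally printed is internally
  inconsistent: the Geyikbayir column's entries make four row sums
  disagree with the published haplotype frequencies. Reassigning that
  column's two minor-row entries one row down (to H9 and H11) is the
  unique correction consistent with both margins; the bundled copy
  carries the corrected matrix and its docstring says so.
* The original per-individual FASTA is not redistributed. For
  end-to-end census tests a *synthetic reconstruction* is generated:
  the 41 variable sites embedded at deterministic seeded positions in
  a 373-bp monomorphic background, 120 individuals labelled and
  assigned per the count matrix. It is exact wherever the published
  tables constrain it (haplotype strings, frequencies, population
  counts, polymorphic-site count) and synthetic in the background
  composition and site coordinates — so tests on it validate the
  census, distance, tree and network machinery, but say nothing about
  base composition or site distribution of the real gene.

## Synthetic data generator

`generate_dataset` emulates the input structure with known ground
truth: a random ancestor; k haplotypes derived from it by distinct
substitution sets (no indels — the reference data are gapless);
individuals assigned per population by a seeded multinomial whose
weights put an expected `mixing` share on one dominant shared haplotype
and the rest on a small population-private subset, mimicking the
dominant-plus-private structure of the reference counts. Defaults are
the study design: k = 20 haplotypes, 373 bp, eight populations of 15,
1–25 substitutions per haplotype, mixing 0.45 (the observed modal share
is 45.8%). Every planted haplotype is guaranteed at least one carrier,
so the collapse stage must recover exactly k classes with the recorded
counts. The generator makes no claim of coalescent realism: mutation
placement is uniform, homoplasy is possible only by collision, and
population structure enters only through the assignment weights —
passing parameter-recovery tests therefore validates bookkeeping and
determinism, not evolutionary inference on real data.

## Numerical and degenerate-input conventions

* Site positions are 1-based in the post-trim coordinate system; the
  trim offset is recorded on the alignment.
* A 2-taxon NJ "tree" is the single edge split evenly; k = 1 haplotype
  yields an empty variable-site table and a single-node network with
  no links; fewer than four taxa admit no nontrivial bipartitions, so
  bootstrap supports are undefined there and the support figure is
  skipped with a log message.
* Distance matrices validate symmetry and a zero diagonal on
  construction; asymmetric input is rejected, not averaged.
* All randomness (bootstrap, generator, network layout) flows through
  seeded NumPy generators; a fixed seed reproduces every output
  byte-for-byte (images on a pinned matplotlib).

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on the bundled
tables (20 haplotypes), the 120 × 373 reconstruction, and generated
datasets up to the study design size; bootstrap uses B = 100
replicates, the published setting. NJ additivity is exercised on 4–8
taxon random trees and the spanning-tree oracle on exhaustive ≤ 6-node
batteries, sizes at which independent brute-force oracles are exact.

## Known limitations

* Haplotype id numbering is first-appearance, which need not match the
  published H-numbers when record order differs; all comparisons are
  therefore order-free.
* The 71-link figure of the published network is not reproducible from
  any stated rule (see above) and is not claimed.
* The "0.6% genetic variation" scale-bar annotation of the published
  tree figures is presentation-only and untested.
* K80 has no published numeric anchor in the reference tables, so its
  validation is analytic/property-based.
* Figures are checked structurally (existence, row counts, legend
  contents), not pixel-wise.
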