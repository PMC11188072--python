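# Methods

This note documents the models, parameter choices and numerical conventions
behind the `ismorf` toolkit, and what the synthetic benchmarks do and do not
demonstrate.

## Coordinate model and input handling

All coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
is converted at the I/O boundary and BED output is emitted natively.
Nucleotide sequences are normalized on read (uppercase, U→T, any other
IUPAC code → N with a logged count). Codons containing N or gaps are
excluded from all rate computations (pairwise deletion) rather than
triggering whole-column removal: microprotein alignments are short, and
complete deletion would discard most of the usable signal in gappy
families. Translation uses the bacterial code (table 11) with the
initiator rendered as M for ATG/GTG/TTG starts, matching RefSeq
convention. Whether `gene` or `CDS` features bound the intergenic space is
configurable (`feature_types`); the default is `gene`.

## Intergenic regions and ismORFs

Intergenic regions (IGs) are maximal intervals not covered by the
strand-agnostic union of gene features; 33–1500 nt intervals are retained.
Intervals at linear contig ends are kept (exclusion would silently drop
sequence and is recoverable by filtering); on circular contigs the
wrap-around gap is joined into a single region. ORF scanning reports, per
stop codon, the longest start→stop span by default (an `all_starts` option
emits nested starts); the stored span includes the stop codon, and the
45-nt minimum applies to the coding length excluding the stop, which makes
the nucleotide threshold and the 15-aa protein minimum consistent. An ORF
becomes an ismORF when ≥ 80% of its span lies within a single IG (the IG
of maximal overlap; an ORF matching several IGs is reported once) and its
protein is 15–70 aa. Overlapping ismORFs within an IG are all kept.
ismORFs with strong translated-search hits to annotated proteins
(E < 1e−5 **and** identity > 50% **and** alignment > 50% of the protein
length) can be removed via an externally produced hit table.

## Clustering and alignment

Family clustering is a behavioural emulation of greedy incremental
clustering at the documented thresholds, not a bit-compatible CD-HIT
clone: no k-word prefilter is used and a full pairwise alignment is always
computed, which is affordable at the corpus sizes this toolkit targets.
Sequences are processed longest-first (ties by identifier); each joins the
best-identity existing cluster whose representative satisfies identity
≥ 0.5 (identical residues / shorter length), aligned-core coverage ≥ 0.95
of the longer sequence, and length ratio ≥ 0.95; otherwise it founds a new
cluster. Families with fewer than 3 members are discarded, and sequences
shorter than 6 aa rejected. Pairwise alignment uses BLOSUM62 with gap
open 10 / extend 1 and free terminal gaps.

The built-in multiple aligner is a center-star progressive alignment
seeded on the representative ("once a gap, always a gap"). It is adequate
for the high-identity families the clustering admits but is **not**
equivalent to a modern MSA program; externally computed alignments can be
ingested and are validated member-by-member. Codon alignments are produced
by expanding each residue to its source codon and each gap to `---`, after
verifying that the CDS (trailing stop stripped) translates exactly to the
aligned protein.

## Evolutionary rates

For each unordered member pair of a family's codon alignment:

* **K2P** — transitions *P* and transversions *Q* per compared site;
  `k2p = -½·ln[(1−2P−Q)·√(1−2Q)]`, flagged non-finite when a logarithm
  argument is non-positive (saturation).
* **NG86** — synonymous site fractions enumerate the three single-nucleotide
  changes at each codon position, counting changes that create stop codons
  as nonsynonymous; *S* is the mean of the two rows' totals and
  *N* = 3·codons − *S*. Differences between codons differing at *d*
  positions are averaged over all *d*! substitution pathways, excluding
  pathways through stop codons (if every pathway passes through a stop,
  the *d* changes are counted as nonsynonymous). `dS`/`dN` apply the
  Jukes–Cantor correction `-¾·ln(1 − 4/3·p)`, non-finite at p ≥ 3/4.
  NG86 with Jukes–Cantor correction was chosen as the fully specifiable
  canonical codon-counting method so results are exactly reproducible.

Family-level `dN`, `dS`, `Kd` are arithmetic means of the finite pairwise
values (non-finite pairs are excluded with counts reported — saturated
shuffled pairs would otherwise poison the means); `dN/dS` is the **ratio
of means**, which is robust to individual dS = 0 pairs, with 0/0 defined
as 0 and x/0 (x > 0) flagged non-finite. `Kd` is bound to the
K2P-corrected distance by default; a `kd_metric` switch substitutes the
raw p-distance, since the two are often conflated in informal usage.
A family in which every pair is undefined is scored as missing.

## Null model, calibration, classification

The shuffled null preserves local composition exactly: each member CDS is
shuffled preserving all trinucleotide counts via Euler-path sampling on
the dinucleotide multigraph — a uniformly random arborescence rooted at
the terminal dinucleotide fixes each vertex's last exit, remaining edges
are randomly ordered, and the Eulerian walk spells the shuffle (uniform
over the valid shuffle set; first/last dinucleotides preserved). By
default the shuffled rows are laid into the original codon-MSA gap
pattern, which preserves pairability without re-invoking the aligner; an
option re-aligns instead. Calibration reports bootstrap (B = 1000,
linear-interpolation quantiles) 1%/99% quantiles of `dN`, `dS`, `Kd` for
positive and shuffled score sets; the operational thresholds are the fixed
constants `dN < 0.2, dS < 0.7, Kd < 0.2, dN/dS < 0.5`, all strict, with
any non-finite statistic classified noncoding. The calibration machinery
is exposed (q99 of positives, q01 of shuffled per statistic) so users can
adopt data-derived cutoffs.

The random forest (500 trees, recorded seed, 70/30 stratified split) uses
features `[dN, dS, Kd, dN/dS]`; whether the ratio is included is
configurable since it is derived from the first two. Non-finite values are
encoded as the documented sentinel 100 — forests need finite inputs and
the sentinel is far outside the biological range.

## Synteny and genomic context

Locally-collinear blocks are consumed as a tabular input (block, genome,
contig, span, strand); computing them is out of scope. A Syn-IGS groups
IGs that intersect the same block by ≥ 50% of the IG length, represent
≥ 2 species, and include ≥ 1 coding-classified ismORF. "Intact" for
turnover means an ismORF of the same family fully contained in the member
IG; `fraction_intact` is intact genomes over member genomes, and the
summary reports the share of blocks at 1.0.

Orientation classes follow the reading direction of the ismORF: the
downstream flank is collinear or convergent, the upstream flank collinear
or divergent ("head-to-head"); distances are strand-aware gaps (negative =
overlap), with flags for stop-to-start gaps ≤ 10 nt and 1–4 nt overlaps.
Because the correct chance model for orientation is debatable, enrichment
reports three quantities side by side: an exact binomial p against a ½
co-direction probability, a Fisher exact p on the observed-vs-expected
2×2 (reported for completeness — comparing one random margin against a
fixed expectation roughly halves the variance the test assumes, so this p
is conservative), and a strand-permutation p, which is the calibrated
default (empirical size ≈ 0.047 at α = 0.05). Hydrophobicity comparisons
use the Kyte–Doolittle GRAVY (the field-default scale, swappable), with
two-sided Mann–Whitney tests (exact when both groups ≤ 20 without ties).

## Simulator

The generator emulates the statistical structure the analysis assumes —
AT-rich IGs (default GC 0.30, reflecting the elevated AT content of
enterobacterial intergenic sequence), conserved coding ismORFs under
purifying selection, neutral decoys of matched composition — with exact
truth tables. Families evolve on a star tree by acceptance-rejection:
proposals are uniform single-nucleotide changes at Poisson rate
`mutable_nt × branch_scale` per lineage, synonymous proposals always
accepted, nonsynonymous accepted with probability ω, stop-creating
rejected, start and stop codons immutable. This gives a directly
controlled realized dN/dS target (ω > 1 is rejected; positive selection is
not representable in this scheme). Ancestral codons are drawn from the
iid-nucleotide distribution at the configured GC restricted to sense
codons. Decoys are trinucleotide-shuffled copies of planted ancestors,
with shuffle-created internal stops replaced by random sense codons so the
decoy remains a findable, clusterable ORF, then evolved neutrally (ω = 1).

Genomes interleave filler genes (300 nt) with IGs embedding each family
member at homologous coordinates behind a short all-frame stop guard
(`TAAATAAATAA`, containing no start codon) that prevents upstream starts
from extending the planted ORF; the LCB truth table spans the homologous
IGs. Defaults (6 species, 30 planted families, 30 decoys, ω = 0.1,
branch scale 0.1 expected synonymous divergence per lineage, 60 kb
genomes, seed 7) define the demonstration corpus used throughout the
benchmarks. The simulator omits indels, rearrangements, recombination and
horizontal transfer; passing benchmarks therefore demonstrate correctness
of the statistical machinery under the stated model, not performance on
real genomes, where alignment error and annotation noise add variance the
simulation does not represent.

## Reproducibility and problem sizes

Every stochastic step takes an explicit seed and the pipeline is a pure
function of (inputs, config, seeds); two runs with the same configuration
produce byte-identical tables (verified by hash comparison in the test
suite). The benchmark sizes — 200 + 200 clusters for the classifier
comparison, six 60-kb genomes for the end-to-end run, 1000 replicates for
the type-I-error check — were chosen as the smallest designs at which the
measured quantities are stable to within a few percent across seeds.

## Known limitations

* The built-in aligner is a center-star heuristic; for divergent families
  an external MSA should be ingested.
* Cluster-level rates assume star-like relatedness; no tree-aware or
  maximum-likelihood rate estimation is attempted.
* The trailing 3 nt of a shuffled CDS are dropped when mapping into the
  codon frame, so the null's stop-codon position is not composition-exact.
* RNAcode-style coding calls are supported only by ingesting an external
  result table (P < 0.05 plus an identity < 90% diversity filter); the
  tool itself is not re-implemented.
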