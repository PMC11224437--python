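# Methods

This note documents the models, algorithms, parameter choices and known
limitations of tephrimark, in the order data flows through the pipeline.

## Synthetic-data generator

The generator (`tephrimark.simulate`) is first-class, tested code: it
defines the study conditions under which every downstream stage is
validated.

**Species tree.** Either a Yule tree (pure-birth, exponential waiting
times via dendropy's birth–death simulator with death rate 0; because the
process stops at the n-th speciation, one further exponential waiting time
is added to every tip edge so the final cherry is not zero-length) or a
balanced tree (recursive halving of the remaining time). Both are
ultrametric and rescaled so the root-to-tip depth equals `tree_depth`.

**Sequence evolution.** Loci evolve on the tree under Jukes–Cantor with
substitutions only (no indels): on a branch of length b, a site with rate
r substitutes with probability p = ¾(1 − e^(−4br/3)), moving to one of
the three other bases uniformly. Rates are a per-locus Gamma multiplier
(shape 6, mean 1) times a per-site Gamma multiplier (shape 0.5, mean 1).
Because there are no indels, the true per-locus alignments are
column-exact, which is what lets the capture stage replace multiple
sequence alignment with probe-anchored columnization and lets tests
compare captured alignments to truth column-for-column.

**Genome assembly.** Each retained (locus, taxon) copy is embedded —
forward or reverse-complemented with probability ½ — at recorded
coordinates in i.i.d. uniform background sequence (one contig per taxon;
`background_length` bp of background split into gaps of ≥ 50 bp).
Dropout removes a (locus, taxon) copy from the genome and the truth
alignment with probability `dropout_prob`, creating the occupancy
structure the supermatrix stage filters on. Unique regions are i.i.d.
uniform DNA planted once in exactly one taxon: non-homologous to
everything else by construction, they are the ground truth of the
diagnostic screen. An optional decoy mode copies a unique region into a
neighbouring taxon with a configurable per-site mutation rate to create
near-miss negatives, and a duplication mode plants a second copy of the
first loci in taxon 1 to exercise duplicate removal.

**Default conditions and why.** 8 taxa, 50 loci of ~600 ± 100 bp, 10%
dropout, one 1-kb unique region per taxon, root-to-tip depth 0.02
substitutions/site. The depth and the locus-rate shape deserve comment:
the harvesting matcher (identity ≥ 0.85) and the diagnostic cross-match
(identity ≥ 0.90 over ≥ 90% of a 200-bp window) define identity radii,
and "conserved single-copy marker" only means something if conserved loci
fall inside them for every pair in the panel. At depth 0.02 with locus
rates of shape 6 (sd ≈ 0.41), the most divergent pair's expected window
identity stays ≥ 0.95, about three window-level standard deviations above
the 0.90 cut, so conserved-locus windows are reliably rejected by the
specificity filter while planted unique regions are reliably kept. At
depth 0.05 the expected extreme-pair identity is ≈ 0.906 — straddling the
cut — and window fluctuations make genuinely conserved loci appear
species-specific. Deeper divergences are therefore exercised explicitly
where wanted (capture recovery is validated at depth 0.05; rate recovery
at 0.3) rather than built into the defaults. Dropout has no empirical
model here; `dropout_prob` is a free, documented knob.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: indels and alignment error (real flanks need
MAFFT-style alignment and trimming does real work there), GC and
compositional heterogeneity, paralogy beyond the simple duplication mode,
incomplete lineage sorting and introgression (gene-tree discordance here
comes only from finite-locus sampling noise), and assembly
fragmentation/error. One consequence worth flagging: captured flanks are
background sequence, non-homologous across taxa, so flank columns in
captured alignments behave like saturated sites and inflate PIS and
distance estimates relative to real flanking DNA, which is variable but
homologous.

## Locus capture

Matching is exact k-mer seeding (default k = 15, every query offset, both
strands) followed by ungapped extension over the full probe span, clipped
at contig ends. A hit needs identity ≥ 0.85 over a span covering ≥ 0.8 of
the probe; N never matches anything, conservatively. Overlapping hits of
one probe on one contig keep the best-identity representative. There is
no gapped extension: the generator is indel-free, and gapped capture is
out of scope. A mismatch every ≥ k+1 bases still guarantees a surviving
seed; a brute-force sliding-window Hamming scan serves as the oracle in
tests. Defaults (identity 0.85, coverage 0.8, join distance 100 bp) are
ordinary harvesting practice and are config-exposed; only the 400-bp
flank is a fixed convention of this workflow.

Duplicate policy is per taxon: a locus whose probes hit two distinct
regions (after merging same-locus hits within 100 bp) is dropped for that
taxon only (`DUPLICATE_LOCUS`), and a region claimed by two loci drops
both (`SHARED_REGION`). Surviving loci are extracted with 400-bp flanks
truncated at contig ends, reverse-complemented into probe orientation for
minus-strand hits.

`anchor_align` columnizes the captured copies of a locus by probe-match
offset, gap-filling columns outside each taxon's attainable flanks. This
is exact under the no-indel model and replaces the aligner entirely; it
is *not* a general-purpose aligner.

## Supermatrices

Trimming removes columns whose gap+missing fraction (over rows present)
exceeds `max_gap_frac` (default 0.5; the single-rule replacement for an
external trimmer, with a column-provenance map retained). Occupancy uses
⌈τ·N⌉ so "at least τ" is literal. Concatenation pads absent taxa with
`?` and emits 1-based inclusive partitions in input order; slicing the
matrix by partition reproduces the inputs exactly. A column is
parsimony-informative iff ≥ 2 distinct non-missing states each occur in
≥ 2 rows; gaps, `?` and ambiguity codes (including N) are not states.
Missing data counts both `-` and `?` cells over the full taxa × sites
grid — whether real-world reports count gaps as missing varies, so the
choice is documented here and tested. PIS/missing logic is
alphabet-agnostic (NT or AA); nucleotide loci are not translated.

## Gene trees and tree-space concordance

Distances are Jukes–Cantor, d = −¾ ln(1 − 4p/3), over pairwise-complete
columns only; a saturated pair (p ≥ ¾) gets a flagged ceiling of 5.0
substitutions/site, and a pair with no comparable columns is an error
naming the pair. Neighbor joining is the standard Q-criterion
agglomeration with negative branch lengths clamped to zero, ties broken
deterministically by first minimum; it recovers any additive matrix
exactly (tested to 1e-9 on path lengths). NJ + column bootstrap is an
explicit stand-in for maximum-likelihood gene-tree estimation — the
object of interest is the concordance analysis downstream, and external
Newick trees are accepted wherever trees are consumed.

Bootstrap supports are the percentage of replicates containing each
internal bipartition of the point-estimate tree. Inside replicates,
internal branches shorter than 1e-12 are collapsed to polytomies before
bipartitions are read off; without this, tie-breaking would manufacture
100% support from zero-signal data. The point-estimate tree itself is not
collapsed.

Robinson–Foulds is unnormalized (|B₁ △ B₂| over non-trivial
bipartitions, trees unrooted, polytomies allowed), matching the common
multi-tree convention; a normalized variant RF/(2(n−3)) exists but is off
by default. `rf_matrix` prunes all trees to their common leaf set (with a
log entry) before comparison — the conventional choice where the
alternative would be to error on any missing taxon — and refuses panels
whose common set has fewer than four leaves. Classical MDS is Torgerson
double-centering with eigenvalues clamped at zero and a deterministic
sign convention (first nonzero coordinate of each axis positive), exact
to 1e-9 on distances that are Euclidean, as planted 2-D configurations
are.

## Phylogenetic informativeness

Per-site rates are Fitch parsimony step counts on an ultrametric
reference tree divided by total tree length; missing leaf states enter
Fitch as unconstrained sets. This deterministic, dependency-free
estimator replaces likelihood rate estimation and is validated by
simulation recovery: Spearman ρ ≥ 0.7 against the generating rates at
depth 0.3 with 2,500 sites on a 16-taxon panel. Sixteen taxa, not eight,
because step counts on an 8-leaf tree take too few distinct values to
rank 2,500 sites finely (measured ρ ≈ 0.68 at n = 8 vs ≈ 0.76 at n = 16);
larger panels, as in real studies, resolve the ranking. Rates are
reported raw per locus; `normalize_site_rates` rescales a locus
collection to grand mean 1 and flags it, since a single locus cannot know
the dataset mean.

The profile is the four-state symmetric-model informativeness
φ(t; λ) = 16 λ² t e^(−4λt), the form used by the informativeness
literature; it is isolated behind one function should a different model
ever be wanted. φ peaks at t = 1/(4λ) for fixed λ and at λ = 1/(2t) for
fixed t. Note the units: φ is a density in time, so rescaling time by c
and rates by 1/c rescales φ by 1/c (φ dt is the invariant); tests assert
this form. Per-locus PI(t) sums φ over sites, total PI sums loci, and the
"per-locus" display view is the mean across loci. The default time grid
is 100 points spanning 1.5× the reference-tree root depth.

## Diagnostic screen

Windows are w = 200 bp at step s = 50 (count ⌊(L−w)/s⌋ + 1 for L ≥ w);
fragments containing N are skipped with a log entry. Cross-matching
reuses the capture matcher at identity ≥ 0.9 over ≥ 0.9 coverage — the
specificity-defining knobs, config-exposed. A fragment is
species-specific iff it hits the target genome and no other; survivors
are merged into maximal regions by stitching overlapping windows.

Primer design is exhaustive within a region (regions are at most a few
kb): lengths 18–27 nt, GC 40–60%, Wallace Tm = 2(A+T) + 4(G+C) in
[53, 60] °C, pair ΔTm ≤ 3, no mononucleotide run > 4, products 100–200
bp, optional 3'-G/C clamp; ranked by |pair mean Tm − 57| then product
centrality, with per-filter rejection counts logged when nothing passes.
The Wallace rule is exact and integer-valued, hence directly testable; a
nearest-neighbor model could sit behind the same interface.

In-silico PCR finds binding sites with ≤ 2 mismatches and an exact
3'-terminal 3 bases, both strands (vectorized window comparison; N in
the template never matches). Amplicons are convergent site pairs with
product size in [50, 2000] bp, in both (fwd, rev) and (rev, fwd)
orientations. Verdicts use band semantics: UNIQUE = exactly one target
amplicon and none elsewhere; SIZE_DISCRIMINABLE = one target amplicon and
every off-target amplicon differing in size by ≥ 10 bp (identifiable by
band size despite off-target amplification); NON_SPECIFIC otherwise;
FAILED = no target band. `screen_panel` verifies the top 3 ranked pairs
per specific region and reports at most 10, UNIQUE first; everything is
deterministic for fixed inputs.

## Numerical and degenerate-input choices

- All internal coordinates are 0-based half-open on the forward strand;
  1-based inclusive appears only in partition files and reports.
- Supports record their scale (0–100 bootstrap vs 0–1 posterior);
  averaging requires a uniform scale.
- Zero-variation alignments: JC distance 0, NJ resolves arbitrarily but
  bootstrap support is 0 throughout (see collapsing rule above).
- Empty partition lists write an empty file with a warning; all-gap
  columns trim to an empty alignment with a warning; an empty diagnostic
  panel (target only) makes every fragment trivially specific, warned.
- One global seed drives a run; per-stage seeds are derived from it so
  stages can be rerun in isolation. Reruns are byte-identical.

## Problem sizes used in validation

Tests and the acceptance script run entirely on seeded simulations sized
for a desk machine: panels of 2–16 taxa, 1–50 loci of 0.1–12 kb, genomes
of 10–100 kb, 10–100 bootstrap replicates, 100–1,000 random instances per
oracle comparison (PIS classifier, RF vs graph-connectivity splits, NJ on
additive matrices, MDS on planted configurations). These sizes are the
package's validation conditions, chosen to make every oracle exhaustive
or near-exhaustive at its scale; nothing in the implementation depends on
them.

## Known limitations

- The matcher is ungapped end to end; real probe sets over indel-rich
  divergences need gapped alignment and would under-capture here.
- `anchor_align` is only correct without indels (see generator note).
- NJ/JC gene trees are a stand-in; absolute support values and RF spreads
  are not comparable to likelihood-based analyses.
- Wallace Tm is a rough model outside primer lengths ~18–27 nt and
  ignores salt and concentration corrections.
- The informativeness profile treats sites independently and
  symmetrically; it ranks marker sets, it does not predict resolution
  probabilities for specific internodes.
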