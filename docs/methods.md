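# Methods

This note documents the models, estimators and numerical conventions behind
`polyploidkit`, what the synthetic-data generator does and does not emulate,
and the design choices made where the problem left the design open.

## The inference problem

A tetraploid and a higher polyploid relative can share their extra genome
copies for two very different reasons.  Under **nested autopolyploid WGDs**,
one lineage duplicated its genome, speciated, and duplicated again: the four
subgenome copies of the octoploid are then two *recent sister pairs*, each
pair sister to one tetraploid copy.  Under **reticulate
allopolyploidization**, diverged diploid progenitors hybridized (here A×C
and B×D into two allotetraploids, then AC×BD into an allooctoploid): each
tetraploid copy is then sister to the octoploid copy descending from the
*same* progenitor, and the remaining octoploid copies attach deeper in the
tree.  The package tests these hypotheses with four mutually reinforcing
instruments: a gene-tree topology census over syntenic anchor genes, k-mer
subgenome phasing with homoeologous-exchange calling, read-composition
profiling, and two molecular clocks (LTR insertion ages and Ks ratios).

## The simulator

`simulate.ScenarioSpec` parameterizes a rooted diploid lineage tree over
{outgroup, A, B, C, D} with node ages in MY, a list of hybridization events
(parents, child nucleus, time), and the genomes sampled today (outgroup,
tetraploid = AC, octoploid = ACBD).  From these the genealogy of all seven
present-day subgenome copies is derived: two copies of the same progenitor
split when one of them entered a nucleus the other did not (e.g. the
tetraploid's A copy and the octoploid's A copy split at the
octoploidization, 0.44 MY by default); copies of different progenitors split
at the progenitors' divergence.  Default ages follow the study system the
package targets: progenitor radiation between 5 and 7.3 MY, tetraploids at
0.91 (BD) and 0.5 (AC) MY, octoploid at 0.44 MY.

Sequences evolve by **Jukes–Cantor with a strict clock**: each site differs
from its ancestor with probability ¾(1 − e^(−4d/3)) after d = rate·t
expected substitutions, uniformly over the three alternatives.  The default
rate is 0.005 substitutions/site/MY, giving ~7 % divergence across the root
— diverged enough to resolve deep branches on 300 bp genes, young enough to
stay far from saturation.  Gene families are planted as stop-free random
CDSs at collinear positions (uniform slotting without overlap, "+" strand),
at an exact 1:2:4 copy ratio; optional single-copy families are annotated
once per genome.  Mutations may create in-frame stops (the nucleotide
process is unconstrained); translation maps them to `X`, and pairwise Ks
masks them (below).

**Repeats and LTR retrotransposons.**  Each progenitor subgenome owns one
repeat motif (400 bp) and one LTR-RT family template (300 bp LTR + 600 bp
internal + identical 300 bp LTR).  Insertions occur only during that
subgenome's *activity window* (young, old), uniform in time, Poisson in
number (default 25 repeats and 10 LTR elements per chromosome per MY of
window).  An insertion of age t is shared by every copy of the subgenome
whose split is younger than t (so A-window insertions predate the AC split
and appear in both tetraploid and octoploid A copies — which is what makes
tetraploid reads classifiable against octoploid k-mer sets).  Each inserted
copy then accumulates JC mutations for its age, so the two terminal repeats
of an element diverge by 2·rate·t in expectation.  The default windows are
A, C: (0.5, 5.0) MY and B, D: (0.7, 7.3) MY.  These are *planted burst
windows*, deliberately an explicit parameter rather than a quantity derived
from the lineage tree: empirically measured LTR windows reflect
lineage-specific transposition activity and need not coincide with sister
splits (A and B are sisters yet have different windows).  This is a
simulator idealization and the basis of the window-ordering benchmark.

**Homoeologous exchanges** replace a recipient interval (backbone
coordinates) with the homologous donor segment — including the donor's
repeats and LTR elements, which is precisely what makes exchanges detectable
by k-mer enrichment — plus independent JC drift for the exchange age.  Truth
tables record final coordinates, donors, carried-over genes and elements.

Everything derives from `numpy` `SeedSequence` streams keyed by
(seed, purpose, chromosome): identical specs give byte-identical FASTA,
GFF3, FASTQ and truth TSVs.

**What the generator does not emulate** — and hence what passing benchmarks
do and do not show: no indels (alignments of simulated homologs are trivial;
the MAFFT stage is exercised but never stressed), no rate variation among
sites or lineages (clock-based dating is exact in expectation; real data
violate this), no gene loss/fractionation by default (the 1:2:4 ratio is
clean; real anchor extraction loses most genes), a single repeat family per
subgenome rather than nested TE superfamilies, uniform GC, strand "+" only,
and no chromosome rearrangements beyond the planted exchanges.  Recovery on
these benchmarks validates the *logic and implementation* of each stage, not
its robustness to every property of real genomes.

## Orthology and synteny

Proteins are compared by local BLOSUM62 alignment (affine gaps −11/−1,
`Bio.Align.PairwiseAligner`) after a shared-5-peptide prefilter; a
cross-genome pair passes at ≥ 50 % identity over aligned columns and ≥ 50 %
coverage of the shorter sequence.  **Orthogroups are connected components of
the passing-hit graph** (single linkage).  A reciprocal-*best*-hit rule was
rejected deliberately: in a polyploid the B/D copies lose the best-hit slot
to the closer A/C copies and fragment their families, destroying exactly the
1:2:4 unit the analysis needs.

Collinear blocks chain homologous gene pairs by dynamic programming over
gene-order ranks: `score(i) = match + max_j (score(j) − gap·(rank gaps))`
over predecessors monotone on both sides with per-side gaps ≤ 25, both
orientations, blocks extracted best-first without pair reuse, minimum 5
genes, ties to the lexicographically smallest block.  Defaults
(match 50, gap 1) behave like standard collinearity tools at desk scale; an
exhaustive chain-enumeration oracle pins the scores on ≤ 12-pair instances.
Tandem duplicates (same orthogroup, rank distance ≤ 2) collapse to one
representative before chaining.  Anchor groups are connected components of
block gene pairs with *exactly* the requested per-genome copy counts; any
missing or surplus copy excludes the family.

## Trees and the census

Anchor proteins are aligned with MAFFT (`--auto`), trimmed by an explicit
maximum-gap-fraction rule (default 0.2; codon alignments in whole-codon
units), back-translated, and distances computed by JC over shared ungapped
sites (saturated pairs, p ≥ 0.75, capped at distance 5.0 with a warning).
Trees are **neighbor joining** with a documented tie-break (lowest-index
pair joins first) and negative branch estimates clamped to zero; NJ is
consistent on additive matrices, which the property suite verifies on 50
random 6-taxon trees and cross-checks against scikit-bio.  NJ replaces
maximum likelihood deliberately: it is deterministic, dependency-free and
sufficient for topology classification on clock-like synthetic data, and the
module boundary lets an ML engine drop in for real data.  Bootstrap supports
resample columns (codons for codon alignments) and report the percentage of
replicates containing each full-data split.

For the census each tree is rooted on the outgroup tip and canonicalized
(children ordered by their smallest contained role label), giving a string
invariant under sibling order; multifurcations simply never match a model
class and fall into "other".  The census is computed over concrete subgenome
labels — the two tetraploid and four octoploid copies are distinguishable by
their phased subgenome — so the model classes are explicit label sets: 6
topologies for nested WGD, 48 for the reticulate shape; the sets are
disjoint by construction and checked.  No support filter is applied by
default.  Macro-synteny groups collect anchors sharing their full
homoeologous chromosome tuple; their concatenated alignments yield
macro-synteny trees, and an exhaustive quartet-score search (all unrooted
topologies, ≤ 8 taxa) provides the coalescence-summary species tree.

## Phasing and exchanges

K-mers are counted canonically (strand minimum; odd k required — even k has
no unique canonical form; ambiguous bases break windows) with k = 15 by
default; a `min_total` threshold (10) restricts the matrix to repetitive
k-mers.  **Differential** k-mers have max-chromosome per-bp count ≥ 2× their
mean over chromosomes; chromosomes are clustered by k-means (scikit-learn,
best of 10 restarts, labels renamed canonically by cluster size) on per-bp
normalized, column-standardized vectors.  **Subgenome-specific** sets then
require a subgenome's per-bp count ≥ 2× every other subgenome's.

Window enrichment uses the exact hypergeometric upper tail — drawing the
window's specific-k-mer occurrences from the genome-wide pool — with
Benjamini–Hochberg FDR across all window×subgenome tests at α = 0.05; the
genome-scale defaults are 1 Mb windows with exchanges shorter than 5 Mb
discarded, and the synthetic scale keeps that 5:1 ratio (20–25 kb windows,
5-window minimum).  An exchange call is a maximal run of windows enriched
for a non-host subgenome, bridging at most one uncalled window, donor = the
run's modal label; runs within one window of the length threshold are
flagged `borderline` for human review (the explicit stand-in for manual
curation).  After the first pass the specific sets are recomputed once with
called exchange segments masked, and windows/exchanges are re-called — so
exchanged repeats do not contaminate the sets (one iteration, no fixpoint
loop).  Intervals are assigned to the exchange donor if their midpoint lies
in a called segment, else to the host chromosome's subgenome.  Reads are
classified to the subgenome whose specific k-mers they match most (ties and
zero matches unassigned) and placed at their first matching k-mer's genome
position for per-window depth.

## Dating

**LTR clock**: for each annotated element the two terminal repeats are
compared (equal lengths directly, otherwise global alignment), p-distance is
JC-corrected to K, and T = K/(2μ) with μ in substitutions/site/year — μ has
no universal value and must be supplied (the pipeline defaults to the
simulation's own clock, rate/10⁶).  Elements inside called exchange segments
are excluded, as are elements whose k-mer content does not single out their
host subgenome's specific set.  Saturated pairs (p ≥ 0.75) are excluded with
a warning.  The divergence–hybridization window per subgenome is the
symmetric 95 % percentile interval (2.5th–97.5th, linear interpolation) of
its insertion ages, requiring ≥ 20 datable elements.  Individual LTR ages
are noisy (a 300 bp LTR at 7 MY carries a ±≈1.5 MY binomial standard error),
so the CI *bounds* overshoot the planted windows outward; the *ordering* of
windows between subgenomes is the robust signal and is what the benchmark
scores.

**Ks clock**: NG86 — per-codon synonymous site fractions averaged over both
sequences (mutations to stops count as nonsynonymous), differences averaged
over all substitution orders excluding paths through stops (all paths used
only if every path is blocked), ps and pn JC-corrected.  An in-frame stop
raises with its codon index; for batch medians, stop-carrying codons are
gap-masked pairwise first — dropping whole pairs would preferentially
discard the most diverged genes and bias Ks down (observed: ~10 % at the
default scale).  NG86 replaces the heavier YN-style estimator deliberately:
the inference consumes only *median Ks ratios*, which NG86 preserves under
the simulator's uniform-rate model.  Dating is linear calibration,
T = Ks_query/Ks_calibration × T_calibration, with 7.7 MY as the conventional
default calibration age (the pipeline calibrates on the outgroup–tetraploid
split, whose true age the scenario fixes).  Medians (not means) summarize
each lineage pair.  At 300 bp genes the clock's floor is one synonymous
difference (~Ks 0.013), so splits younger than ~1 MY read as 0 — the deep
progenitor divergences are the quantities this estimator is for.  Ks
histograms report local maxima above 10 % prominence; no peak below the
speciation peak means no detectable recent WGD.

## Benchmarks and problem sizes

`polyploidkit.benchmarks` fixes the study conditions used by the validation
suite and the reproduction script: census discrimination on 10-seed sweeps
with 200 anchor families per scenario (repeat/LTR insertion disabled there —
the census consumes genes only); phasing accuracy on 12-chromosome
octoploids (3 per subgenome, 150 kb) clean and with 10 % of repeat
insertions drawn from a foreign library; exchange calling on 8-chromosome
octoploids (250 kb backbone) with two planted exchanges per genome at 20 kb
windows and a 5-window minimum, scored by overlap + donor identity with
boundaries within one window (planted segments below the minimum call
length are excluded from the recall denominator, matching the caller's
contract); LTR window ordering on 10 seeds; Ks dating of the four deep
divergences at 200 families, accepted within 15 % relative error.
Chromosome sizes of 0.1–0.3 Mb with 20 kb windows preserve the ratios of
the genome-scale defaults (≈0.25 Gb chromosomes, 1 Mb windows, 5 Mb
exchange cut-off) at desk scale.

## Known limitations

Exchange boundaries are window-quantized; a gene straddling an exchange
breakpoint is classified by its midpoint.  The exchange model applies
exchanges to the octoploid only (shared tetraploid/octoploid exchanges, as
arise in a common AC ancestor, are not simulated).  The quartet species-tree
search is exhaustive and hence capped at 8 taxa.  k-means phasing assumes
each chromosome is mostly one subgenome; a chromosome dominated by exchanged
content will cluster with its donor (by design — the window track, not the
chromosome label, carries the signal there).  The NG86/JC stack assumes no
transition/transversion bias and equal codon frequencies; on real data a
YN-style estimator and an ML tree engine should replace those modules, which
the module boundaries anticipate.
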