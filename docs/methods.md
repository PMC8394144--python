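# Methods

This note documents the models, rules and numerical choices behind
`magcatkit`, and what the synthetic-data tests do and do not demonstrate.

## Genome quality

Completeness and contamination are CheckM-style estimates supplied as bin
metadata on the percent scale; the package never re-estimates them from
sequence. Three derived quantities drive all downstream decisions:

- **Quality score** `QS = completeness − 5·contamination` (percentage
  points; may be negative).
- **QC filter**: a bin is retained iff completeness ≥ 50, contamination ≤ 5
  and QS ≥ 50. All three bounds are inclusive; we read "minimum" and
  "maximum" thresholds as attainable. Note the filter is *not* implied by
  tier membership: any bin with completeness < 50 + 5·contamination is
  tiered (MQ/NC) yet filtered out — the three thresholds are independent.
- **Intactness score** `S = QS + 0.5·log10(N50)` with N50 in bp, no
  pseudocount (N50 ≥ 1 is guaranteed by non-empty contigs). S ranks
  conspecific genomes to pick cluster representatives; the 0.5·log10 term
  breaks near-ties between bins of equal CheckM quality in favor of less
  fragmented assemblies.
- **Tiers**: HQ requires 5S+16S+23S rRNA, ≥ 18 tRNAs, completeness ≥ 90 and
  contamination < 5; NC drops the RNA requirements; MQ covers
  completeness [50, 90) at contamination < 5. Tiering uses strict `< 5`
  contamination as printed for the tiers, while the upstream filter is
  inclusive at 5; the MQ tier keeps the contamination bound even though it
  is usually stated only for HQ/NC, because tiered bins have passed the 5%
  filter anyway.

## MinHash sketches and Mash-style distance

Bottom-s MinHash over distinct canonical k-mers (lexicographic minimum of
the 2-bit-encoded k-mer and its reverse complement), defaults k = 21 and
s = 10,000 — the parameters used for all-vs-all genome comparison at
catalog scale; k = 21 is the conventional sketching default. Tests use
smaller s (typically 500–1000) for speed; the Jaccard estimator's sampling
error scales as sqrt(j(1−j)/s), which the fidelity tests bound explicitly.

The hash is a seeded splitmix64 finalizer applied to the 2-bit k-mer code.
It is well mixed, non-cryptographic and bit-exact for a given seed; results
are reproducible for a fixed `hash_seed` but not across different hash
functions. k-mers containing non-ACGT characters are skipped.

Distance: `d = −(1/k)·ln(2j/(1+j))`, clamped to [0, 1]; the Jaccard
estimate comes from the bottom-s values of the merged sketch (the fraction
of them present in both sketches). `j = 0` maps to `d = 1` (the log
diverges). Sorting pairs by d is equivalent to sorting by −j.

## Fragment-mapping ANI with coverage gating

ANI between two bins is estimated by fragment mapping, self-contained and
deterministic:

1. Each query contig (≥ 500 bp) is tiled by near-equal windows of about
   1,000 bp covering the contig fully — no terminal slack is dropped, which
   would otherwise bias coverage downward on fragmented bins.
2. Each window is located in the reference by exact 16-mer seeds: window
   16-mers vote for alignment diagonals (32-bp buckets, both strands), and
   the window is aligned by banded edit distance (edlib, band 55% of the
   window) against the reference segment around each of the top three
   diagonals. A window with no exact seed is unmapped; at the 70% identity
   floor a ≥ 250 bp piece retains an intact 16-mer with high probability,
   so the sensitivity loss is negligible and confined to windows whose
   weight is smallest.
3. A window at identity ≥ 0.97 is accepted whole. Below that, the
   alignment path is trimmed to its well-matching runs (maximal-scoring
   segments under match = +0.4 / other = −0.6, i.e. kept runs exceed 60%
   identity). This distinguishes a uniformly divergent window (kept whole
   at its true identity) from a window that overlaps a region absent from
   the reference or spans a reference contig junction, whose mismatch/indel
   run is trimmed away instead of deflating ANI. Runs found against
   different candidate segments (e.g. the two contigs flanking a junction)
   are combined greedily over non-overlapping query spans. Kept runs
   shorter than 100 bp or below the 70% identity floor are discarded.
4. ANI = length-weighted mean identity of the query's mapped material;
   aligned fractions are computed in both directions (query onto reference
   and vice versa) and **coverage = min** of the two. A pair passes iff
   coverage ≥ `min(0.8, comp_A·comp_B)` with completeness as fractions —
   the product form is the expected overlap of two random subsets of a
   genome, capped at 0.8. Pairs failing coverage are "regarded as different
   genomes" and enter clustering at distance 1 (rather than being removed,
   so average linkage stays well defined).

On synthetic genomes this recovers a planted substitution rate of 0.03 on
200-kb genomes as ANI 0.970 ± 0.001, and realized coverage tracks the
completeness of the less complete bin to within a few percent.

## Two-step iterative species clustering

Step 1: all-vs-all Mash distances, average-linkage hierarchical clustering
cut at 0.2 (scipy's implementation; flat clusters contain exactly the
merges at linkage distance ≤ cutoff). Step 2: within each preliminary
cluster, pairwise fragment ANI; distance = 1 − ANI, or 1 on coverage
failure; average linkage cut at 0.05 (the 95% species boundary). Each
cluster's representative is its argmax-S member, ties broken by
lexicographically smallest bin id so results are order-independent.

"Iterate until the clusters cease to change" is implemented at the
representative level: each round re-clusters the current representatives
and merges clusters whose representatives co-cluster, until the partition
of the original bins is stable (max 25 rounds, non-convergence is an
error). Re-feeding representatives rather than all genomes is the design
choice here: it is the variant that makes the procedure a fixpoint of its
own output and scales as the catalog grows. Singletons represent
themselves; any multi-member cluster selects argmax S.

Catalog merging reruns the same clustering on the union of base
representatives and new bins and labels each resulting cluster `novel`
(no base member), `replaced` (base member present but a new genome won the
representative) or `inherited`.

**Non-redundant counting**: genomes within Mash distance 0.001 (≈ 99.9%
ANI) are redundant. For tractability the 0.001 average-linkage clustering
runs only inside connected components of the ≤ 0.1 graph; genomes sharing
(sample, species cluster) are additionally collapsed. The collapse is
applied as a union with the 0.001-clusters (equivalently: after them); the
count is the number of resulting equivalence classes.

**Depth pairing**: bins assembled from the same sample at two sequencing
depths are paired by Mash average linkage at 0.1 (≈ 90% identity); only
clusters with exactly one bin per depth condition yield a pair, and
completeness, contamination, N50 and genome size are compared across pairs
with a two-sided Mann-Whitney U test.

## SNV density and chimerism screen

Conspecific alignment uses unique-anchor chaining: 31-mers that occur
exactly once in both genomes become anchors, contiguous same-diagonal
anchors merge into exact runs, the best collinear chain is selected
(weighted longest increasing subsequence), and inter-run gaps of ≤ 5 kb on
both genomes are closed by global edit-distance alignment. The output is a
set of gapless blocks, one-to-one on the representative — the analogue of
a best-bidirectional-alignment filter. At the ≥ 95% identity this module
targets, anchors tile essentially the whole genome; unrelated genomes
share no unique 31-mers and produce an empty alignment (not an error).

SNVs are substitution columns inside blocks, 1-based on the representative;
indels are not SNVs. Per species cluster G with representative r:

    SNV per kb = [ Σ_{g ∈ G−{r}} #SNV_{r,g} / (aligned_length_{r,g}/1000) ] / (n(G) − 1)

Pairs with zero aligned length contribute 0 and are flagged. SNVs are
computed for clusters with ≥ 3 genomes; density analyses restrict to ≥ 10
genomes to limit sampling bias (both configurable).

Chimerism screen: the aligned blocks are laid end-to-end and partitioned
into consecutive chunks — 50 kb when the species density exceeds 5 SNVs/kb,
100 kb otherwise — with the trailing partial chunk dropped. Chunking the
concatenated aligned region (not raw representative coordinates) keeps
chunk exposure constant. Pairs with ≥ 5 chunks are tested by one-sample
Kolmogorov-Smirnov against a normal with the sample mean and SD;
Benjamini-Hochberg q-values are computed across pairs and a pair is called
normal iff q > 0.05. Estimating the normal's parameters from the sample
makes the KS test conservative (the Lilliefors issue); this is accepted
and means the screen under-flags mild deviations while still catching the
10×-hot-chunk pattern reliably.

Speciation association: patristic distances on a supplied newick tree
(dendropy); per species the mean distance to its five nearest leaves;
Spearman correlation against SNV density plus a two-sided Mann-Whitney U
comparing the closest decile (floor(0.1·n) species, distance ties broken
by species id) against the rest.

## Epitope cross-reactivity

Epitope filtering drops peptides shorter than 5 residues, rows requiring
post-translational modification, rows with non-amino-acid characters
(warned) and duplicate peptides. Alignment is exact Smith-Waterman
(Biopython PairwiseAligner, BLOSUM62, gap open 11 / extend 1); an exact
aligner dominates any heuristic search's hit set, so no E-values are
involved. The score

    AS = (match length − gap length) / epitope length

takes "match length" as *identical aligned residues*, the stricter of the
two readings; under it AS = 1 holds exactly when the epitope occurs in the
protein verbatim, full-length and gap-free. ECG counting therefore uses an
exact substring scan, with the equivalence to the alignment route
property-tested. A gene counts once however many epitopes hit it; ECG
density = ECGs / proteome size.

Clade enrichment compares a clade's ECG densities against the entire
species set (clade included) with fold change of medians and a two-sided
Mann-Whitney p. High cross-reactivity taxa are clades with p < 1e−05 *and*
fold change > 1, plus all their descendant taxa; requiring enrichment
(not just significance) keeps significantly *depleted* clades out of the
high set. Disease associations are computed only for diseases with more
than 40 annotated taxa: OR_assoc from the 2×2 high/low × annotated/not
table over the full taxon universe, OR_direction from high/low ×
increase/decrease among annotated taxa, both with two-sided Fisher's exact
tests; a zero cell gets the Haldane +0.5 correction for the point estimate
only. Duplicate-protein detection groups byte-identical sequences by exact
hashing; the redundant count is Σ(group size − 1).

## Depth-stratified profiling

Profiles are taken as classified read counts per taxon; read classification
itself is out of scope. Lower depths are subsampled from a reference count
table either without replacement (multivariate hypergeometric — true
rarefaction) or multinomially. Taxa are stratified by their mean relative
abundance in the deepest profile into eight ten-fold bins with
upper-inclusive bounds 1e−07 … 1; means at or below 1e−08 (below the lowest
printed level, whose lower edge is undefined) fall into the lowest stratum.
Per stratum, Pearson and Spearman correlations between relative-abundance
vectors are computed against the deepest profile; strata with fewer than 3
taxa, or with a constant vector, are reported undefined. Correlations are
computed on relative abundances (counts would conflate depth with
composition).

## Synthetic data: what it emulates and what it does not

The generator plants every ground truth the pipeline estimates: ancestor
identity (species label), per-genome substitution rate and positions,
realized completeness/contamination, epitope occurrences, 2×2 disease
contingency structure and community composition. Design choices:

- Substitutions are i.i.d. uniform over the 3 alternative bases, no
  transition/transversion bias — sufficient for testing identity-based
  clustering and SNV counting.
- Contamination fragments come from a designated foreign ancestor, so
  contamination is detectable by k-mer content.
- `degrade_to_bin` cuts at jittered-even random breakpoints (contig lengths
  ≈ L/n ± 20%, no sub-500 bp slivers) and trims the last retained contig so
  realized completeness matches the target exactly; stored metadata is the
  realized truth.
- In the standard catalog scenario, `max_sub_rate` (default 0.03) caps the
  *pairwise* substitution divergence within a species; per-genome branch
  rates are drawn in (0.002, max_sub_rate/2]. This keeps every conspecific
  pair on the ≥ 95% identity side of the species boundary, so "exact
  recovery of the planted clusters" is a well-posed expectation.
  Completeness is drawn in [0.80, 0.93] — a realistic MAG range; since the
  generator's stored completeness is the exact retained fraction, a bin at
  ~100% would make the min(0.8, c_A·c_B) coverage rule a knife edge where
  expected coverage equals the cutoff exactly.
- All randomness flows from explicit integer seeds via
  `numpy.random.default_rng`; identical arguments and seeds give
  byte-identical output.

Not emulated: sequencing error and read-level artifacts, assembly/binning
biases, rearrangements, codon usage, horizontal transfer, and strain
mixtures. Passing tests therefore demonstrate the *statistical machinery*
(clustering rules, estimators, tests, thresholds) on data satisfying the
models' assumptions — not robustness to real-data violations of them.

## Problem sizes and tolerances

The test suite runs the clustering recovery at 30 bins × 100 kb (6 species
× 5 MAGs), ANI recovery at 200 kb, sketch fidelity over 50 pairs at
s = 1000, SNV recovery on 10-genome clusters of 100-kb genomes with the
normality screen on 100 simulated pairs over 1-Mb aligned regions, and the
depth property on a 1000-taxon community at depths 1e5–1e7 over 20 seeds —
sizes chosen so the full suite completes in about a minute while keeping
every estimator's sampling error well inside the asserted tolerances
(binomial 3σ bounds for rates and counts, ±0.005 for ANI, 5% relative for
SNV density).

## Known limitations

- Fragment ANI is tuned for the ≥ 70% identity regime; it is not a general
  homology search and does not model rearrangements (windows map
  independently, so translocations cost nothing — by design for MAGs).
- The KS normality screen is conservative with estimated parameters;
  Lilliefors-corrected critical values are deliberately not used.
- The Mann-Whitney implementation switches from exact enumeration (both
  sides ≤ 8, no ties) to the tie-corrected normal approximation; p-values
  near the switch point change method, not meaning.
- Average-linkage clustering and the exact tests are delegated to
  scipy/statsmodels; the package pins behavior by contract tests against
  enumeration oracles rather than by reimplementation.
- Target scale is hundreds of bins, not 10^5; distance matrices are dense.
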