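# Methods

## Overview

`strainpath` estimates per-strain abundances in a shotgun metagenome from
two inputs: per-species variation graphs (GFA; one embedded path per
strain genome) and read-to-graph alignments (GAF) against the merged
super-graph. The method proceeds in the order the modules are laid out:
graph model → alignment model → species binning → strain-level
path-abundance optimization (PAO) → final profile. A synthetic-data module
generates all of these inputs with known truth so the whole pipeline is
testable offline.

## Graph model and assumptions

A variation graph's nodes are genomic segments, edges are adjacencies
observed in at least one strain, and each strain genome is a path. The
model assumes one graph per species and one path per strain; paths may
revisit nodes (multiplicities are tracked), and triples of consecutive
steps are compared under reverse-complement canonicalization, since the
same genomic context can be walked in either direction. Graphs read from
external GFA (P- or W-line dialects) are renumbered to integer node ids
1..N (original names kept in a sidecar map) because integer ids make the
super-graph offsetting trivial. The invariant that every edge is traversed
by a path is enforced strictly on internally built graphs but relaxed to a
warning for external files, whose builders may emit extra edges. Species
represented by a single genome are fragmented into 1024 bp chain nodes so
that downstream statistics (triplets, breadth) remain meaningful.

Merging shifts each graph's node ids by the cumulative maximum id of its
predecessors. No inter-species edges are ever introduced, so the species
of any alignment is recoverable from its first node id.

## Species binning

Each mapped read keeps exactly one optimal alignment. The selection key is
(higher alignment score from the AS tag, falling back to residue matches;
then higher MAPQ with the 255 "missing" sentinel demoted to 0; then
smaller species taxid; then lexicographically smaller path string). The
last two components are a documented convention to make cross-species ties
deterministic and order-independent. Species are then filtered by read
support: at least `min_reads` = 10 assigned reads and at least
`min_highconf_frac` = 25% of them at MAPQ ≥ 30. These three thresholds are
defaults of this implementation (exposed on the CLI); they encode the
intuition that a genuinely present species accrues uniquely placeable
reads, whereas a false-positive species attracts only ambiguous,
shared-region alignments. Normalized read coverage divides aligned read
bases (query-span, which is robust to error-rate differences between
technologies) by the arithmetic mean strain-genome length of the species'
graph.

## The PAO linear program

For candidate strain paths P over node set V (the union of the candidate
paths' nodes), PAO minimizes the length-weighted L1 residual between
observed node depths and path-implied depths, subject to non-negativity.
The absolute values linearize exactly with one auxiliary variable per
node, giving an LP solved with HiGHS (via `scipy.optimize.linprog`, sparse
constraints, feasibility tolerances 1e−6). L1 was chosen over L2 because
it is robust to localized coverage artifacts and keeps the problem an LP;
with noise-free uniform coverage the optimum is exact (zero residual), a
property the tests assert to 1e−6. The weighted-L1 optimum behaves like a
length-weighted median of node depths per path, so with a single candidate
and uniform depth c the estimate is exactly c.

## Filter cascade

* **Stage 1** (before PAO #1): f_strain ≥ 0.3 for short reads, ≥ 0.5 for
  long reads (inclusive). f_strain is the covered fraction of the strain's
  specific triplets. "Covered" defaults to *traversal*: some single
  alignment walks the oriented triple consecutively. A weaker "nodes" mode
  (all three member nodes have nonzero depth) is available for regimes
  where reads are shorter than the typical triple span. A strain with no
  specific triplets has f_strain = 0 by definition.
* **PAO #1** over stage-1 survivors yields a_p.
* **a_p,triplet** is the length-weighted mean depth over the distinct
  nodes of the strain's specific triplets **that no other path of the
  species traverses**. The restriction to strain-exclusive nodes is
  essential: shared backbone nodes carry the summed depth of every
  co-occurring strain, and including them would bias the estimate toward
  the species total. If a strain's specific triplets contain no exclusive
  node (shared nodes in a novel order), all triplet nodes are used as a
  fallback.
* **Stage 2**: d_strain = |a_p − a_p,triplet| / max(a_p, a_p,triplet)
  (defined 0 at 0/0) must be ≤ 0.46; strains at 0.46 < d ≤ 0.6 are rescued
  iff r_strain = b_strain × f_strain ≥ 0.85, where b_strain is the
  fraction of path bases on covered nodes. Breadth was chosen for b_strain
  so that r = b × f is guaranteed to live in [0, 1], which the 0.85 cutoff
  presupposes.
* **PAO #2** re-solves over the final survivors, rescued strains included
  — they are retained candidates and excluding them would misattribute
  their coverage. Rescued strains report min(a_p, a_p,triplet) (the more
  conservative of the two estimates); others report the PAO #2 a_p.
* **Species consistency**: d_species = |A_i − S_i| / max(A_i, S_i) between
  the species depth estimate A_i = c_i and the strain sum S_i; species
  with d_species > 0.2 are removed with all their strains. If S_i > A_i
  for a retained species, strains are scaled by A_i / S_i so the sum
  matches exactly. A species whose every candidate strain was eliminated
  stays in the species profile (with a warning) but contributes nothing to
  the strain profile.

All thresholds sit in one `StrainConfig` dataclass; lowering any of them
never removes a previously passing strain (asserted as a property test).

## Database construction

Dereplication runs single-linkage clustering (connected components of the
≥-threshold ANI graph) in two sequential passes, 95% then 99.9%, keeping
per cluster the genome with the highest mean ANI to its cluster mates
(ties: longer genome, then smaller accession) and capping a species at its
10 largest clusters. ANI values are accepted as a TSV matrix (directed
entries symmetrized by max); computing ANI itself is out of scope. The
fast-mode pre-filter sketches genome k-mers (FracMinHash: canonical k-mers
whose 64-bit hash clears 1/scale of the hash space; k = 21, scale = 1000
by default) and estimates ANI = 100 · C^(1/k) from the containment C of
the genome sketch in the read k-mer set — a k-mer survives divergence p
with probability ≈ (1−p)^k. Genomes below the 99% threshold are dropped
before graph construction.

## Synthetic data: what it does and does not emulate

The generator emulates: strain genomes derived from a common ancestor by
independent per-base substitutions (presets 0.001 and 0.01, the typical
within-species divergence regime), per-strain depths in the 1–20×
low-complexity range (or explicit per-strain depths), short reads (150 bp,
0.1% error) and long reads (10 kb, 2% error), uniform read placement on
both strands, ground-truth GAF placement with a 60/3/0 MAPQ model driven
by placement multiplicity within the species, and optional lower-scoring
decoy alignments.

It does **not** emulate: indels or structural variants (substitutions keep
graph construction exact — every strain path provably spells its genome),
platform-specific error profiles (homopolymer errors, quality strings),
GC- or position-biased coverage, conserved inter-species homology (decoys
are placed uniformly at random), or chimeric reads. Passing tests
therefore demonstrate correctness of the algorithmic cascade under its own
model assumptions, not robustness to real-data artifacts such as
misassembly, contamination or reference bias.

## Problem sizes and read regimes in the checks

The bundled end-to-end checks use 50–100 kb genomes — large enough for
thousands of variant sites and stable coverage statistics, small enough to
re-run routinely. The multi-strain recovery and divergence-versus-ratio
scenarios use the long-read regime (1–10 kb reads): under the default
traversal definition of triplet coverage, a specific triple
(backbone–allele–backbone) spans more bases than a 150 bp read at 0.1–1%
divergence, so short-read scenes would measure the "nodes" fallback rather
than the stricter traversal semantics. The divergence-versus-ratio grid
fixes total depth at 20× over pairwise identities {97, 98, 99, 99.8}% and
ratios {1:1, 1:3, 1:5, 1:10}, placing the minor strain at ≈1.8–10×.

## Numerical choices and degenerate inputs

LP feasibility tolerances are 1e−6; estimates are clipped at 0 to remove
solver-level negative round-off. d_strain and d_species are defined as 0
when both operands are 0. An empty retained species set yields an empty
profile with a logged warning rather than an error; an empty strain
profile is legal. Evaluation metrics: L1/L2/Bray–Curtis over the union of
truth and predicted taxa; AFE is the mean absolute frequency error; RFE is
the mean of |p−t| / max(p, t), a bounded, symmetric relative error chosen
because the conventional |p−t|/t is undefined for false-positive taxa
(t = 0) that profilers must be penalized for.

## Known limitations

Strains absent from the reference graphs cannot be detected (no novel
strain discovery); unmapped reads are discarded rather than interpreted.
Tie-breaking for equal-scoring cross-species alignments is a convention of
this implementation. The per-species LP assumes coverage within a species
is attributable to its candidate paths alone; systematic cross-species
misalignment is only handled by the MAPQ species filter and the d_species
consistency check.
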