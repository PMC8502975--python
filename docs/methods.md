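# Methods

This note documents the models, the simulator, the numerical choices and
the known limitations of the package. It states how each quantity is
defined and computed; every number quoted in the README is printed by the
code itself.

## The synthetic strain panel

The simulator is the package's instrument for validation: it produces
panels whose gene-family structure, phylogeny, nucleotide identity and
transfer events are known exactly, so each analysis stage can be scored
against truth.

**Tree.** By default a random rooted binary topology is drawn by uniform
pair-merging over the strains (a coalescent-style shape without waiting
times); every branch carries the same per-branch substitution probability
`per_branch_divergence` (default 0.02/site/branch). A user tree can be
supplied as Newick, in which case branch lengths are read as per-branch
substitution probabilities — this is how structured panels (e.g. three
clades with small within- and large between-clade divergence) are built.

**Families.** Three classes:

* *core*: `n_core` single-copy families present in every strain, born at
  the root;
* *dispensable*: gains drawn per branch as Poisson(`dispensable_rate`),
  each a new family born on that branch and inherited by all descendant
  tips (gain-only; no loss);
* *unique*: Poisson(`unique_per_strain`) fresh families per tip.

**Sequences.** Gene lengths are uniform in `gene_len_range` (default
300–600 bp, rounded to codons); root genes are sampled i.i.d. with
P(G) = P(C) = GC/2 at `background_gc` (default 0.415, a *Bacillus*-like
value), resampling any stop codon. Evolution is independent per-site
substitution (probability d per branch, uniform over the three other
bases), with no indels in genes, so the expected identity between two tips
separated by branches d₁…d_k is Π(1 − dᵢ) (plus a 1/3 coincidence
correction applied for the two-branch case); this closed form is what
`GroundTruth.true_ani` records. Proteins are translations under the
bacterial genetic code (table 11); a substitution that creates an internal
stop is translated as `X`, which the aligner scores 0 against everything.

**Genomes.** Each genome is the core genes in fixed family order separated
by intergenic spacers, followed by the strain's accessory genes each with
its own spacer. Spacers are born with their family (backbone spacers at
the root) and evolve along the tree by the same substitution process, so
genome-wide identity matches gene identity; a spacer-only indel rate
exists but defaults to 0 so that true ANI stays analytically exact.

**Planted transfer.** When configured, `n_genes` donor genes are generated
at `background_gc + gc_shift` (defaults 3 genes, +0.08), lightly diverged
copies (2 % per site) are inserted as one contiguous block with
like-composition spacers at a random core-backbone boundary of the first
strain, and the coordinates, gene ids and donor-lineage relatives (two
independently diverged copies of each donor gene, labeled with the donor
name) are recorded in the ground truth. The planted genes appear in the
proteome and gene table but not in the family table — they are the
known-true positives for the HGT screen.

What the generator does *not* emulate: recombination, gene loss,
rearrangement, realistic codon usage or length variation between
orthologs, contig fragmentation, and annotation error. Passing tests
therefore demonstrate correctness of the algorithms under the stated
model, not robustness to the full messiness of real assemblies.

## Alignment and similarity

One dynamic-programming core (Smith–Waterman / Needleman–Wunsch with
affine gaps) serves proteins and nucleotide fragments. Protein scoring is
BLOSUM62 with gap open 11, extend 1 — the conventional defaults of the
pan-genome pipelines this package mirrors — with `X` rescored to 0
against all residues. Identity is identical columns over *all* alignment
columns (gap columns count in the denominator — the stricter reading);
coverage is the aligned span on the *longer* sequence over that sequence's
length. Raw scores become bits via the standard gapped Karlin–Altschul
constants for BLOSUM62(11,1) (λ = 0.267, K = 0.041) and
E = m·n·2^(−bits) over the per-pair search space, without edge
corrections. Because co-optimal tracebacks need not be symmetric, each
unordered pair is aligned in a canonical order so that identity and
coverage are exactly symmetric. Pass thresholds: identity ≥ 0.5, coverage
≥ 0.5, E ≤ 10⁻⁵ (configurable).

Nucleotide fragment scoring is +1/−1 with gap open 4, extend 1.

## Clustering

Families are connected components of the undirected pass graph
(single-linkage transitivity); genes without passing edges are singleton
families, and family ids are the lexicographically smallest member id, so
the output is independent of hit order. A Markov-clustering option
(expansion 2, inflation 1.5, self-loops weighted like the heaviest
incident edge to suppress period-2 oscillation) is available for
sensitivity analysis; components remain the default because they are
deterministic and auditable.

## Pan-genome curves and fits

Accumulation curves use random strain orderings (default up to 1,000,
seeded; all n! orderings are enumerated when that is fewer, making small
cases exact). Fits are performed on the per-depth medians, matching the
median-curve convention of pan-genome plotting tools.

Both three-parameter fits (Heaps `A·x^B + C`, exponential
`A·e^{B·x} + C`) use the same estimator: the exponent/rate B is profiled
on a grid — for fixed B the model is linear in (A, C), solved by least
squares — refined by bounded scalar minimization, then polished by
Levenberg–Marquardt from the profile solution and from the conventional
multi-starts (A₀ = range of y, B₀ ∈ {0.1, 0.5, 0.9} or
{−0.1, −0.5, −1}, C₀ = min y). The profile path guarantees a converged
answer even where free optimization diverges (e.g. a step-then-flat core
curve that pushes B → −∞; the estimate then sits at the profile-grid
boundary, B = −12, and the covariance is reported as NaN). Exactly flat
curves short-circuit to the degenerate solution A = 0, C = mean.

Openness is "open" iff 0 < B_pan < 1 *strictly*; estimates within 10⁻⁹ of
the boundary are treated as on it, so an exactly linear curve (B = 1 up
to floating-point jitter) reads closed. The expected new-gene yield of an
additional genome is the first difference pan(n+1) − pan(n) of the fitted
Heaps curve; a separate new-gene power law is deliberately not fitted,
since the accumulation data underdetermine the choice between the two
conventions.

## ANI and species groups

Directional ANI cuts the query genome into consecutive non-overlapping
1,020-bp fragments (a trailing partial fragment is dropped) and aligns
each locally to the whole subject genome; fragments are retained at
≥ 30 % identity and ≥ 70 % alignable span — the published ANIb defaults.
ANI is the mean identity of retained fragments × 100; a pair where every
fragment is filtered has *undefined* ANI (NaN), never 0. The reported
per-pair value is the mean of the two directions. Species groups are
connected components of the ANI > 95 % graph; undefined pairs never link.
Raising the threshold can only refine the grouping.

## Phylogeny

Single-copy core families (copy count exactly 1 in every strain) are
globally aligned per strain pair with free end gaps; differing/total
non-gap columns are pooled across families and the p-distance is their
ratio. Neighbor joining follows Saitou–Nei with the Q-criterion,
deterministic tie-breaking toward the lexicographically smallest pair of
cluster representatives, negative branch lengths clamped to 0, and the
final three clusters joined by the three-point formulas (unrooted
result; optional rooting on a named outgroup leaf). Bootstrap resamples
*families* with replacement — the natural unit for concatenated
distances, and cheap because per-family column counts are computed once —
and reports the percentage of replicates containing each original
bipartition.

## HGT screen

*Composition*: the candidate cluster's GC (ambiguous bases excluded) is
compared with the distribution of same-length sliding windows (default
step: window/10) over the host genome; windows overlapping the cluster
are excluded from the background (leave-one-out), and |z| ≥ 2 flags the
cluster. Both cluster-vs-window and cluster-vs-whole-genome GC are
reported, since the two contrasts answer slightly different questions.
*Placement*: a neighbor-joining tree over the query protein plus a
labeled reference panel (p-distances from global alignments); the
placement taxon is the lineage label of the query's nearest leaf by
patristic distance, flagged when it differs from the self lineage, with
exact ties broken to the lexicographically first label and marked.

## Problem sizes used in validation

Validation runs use desk-scale panels chosen to keep every quantity
statistically decidable: 6-strain panels (15 core families, 300–600-bp
genes, ~10–14-kb genomes) for clustering and end-to-end runs; 12-strain
family-table-only panels (30 core, dispensable rate 2, unique rate 3) over
100 seeds for openness classification; two-strain panels with 25 core
families (~12 retained fragments, binomial SE ≈ 0.09 points) for ANI
calibration at substitution rates 0.01–0.05; 8-strain panels for tree
recovery; and 100/50 seeds for the GC/placement transfer screens. The
17-strain partition and Heaps-law identities are computed at the published
counts themselves.

## Known limitations

* Exhaustive all-vs-all alignment scales quadratically in total gene
  count; the package targets simulated or small real panels, not
  thousand-genome collections.
* Connected-component clustering can chain distinct families through a
  promiscuous domain; the MCL option mitigates but paralog resolution is
  out of scope.
* The ANI implementation replaces NUCmer with exact local DP: equivalent
  at these scales but far slower on full-size genomes.
* The gain-only accessory model makes the dispensable/specific split of
  simulated panels cleaner than in real data, where loss and transfer
  blur the classes.
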