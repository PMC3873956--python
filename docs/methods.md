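# Methods

This note documents the models and procedures implemented in
`complexweaver`, the parameter choices that matter, what the synthetic
data generator does and does not emulate, and the numerical decisions
taken where the design was genuinely open.

## Evidence features

**GO information content.** For a namespace with T annotation events
(protein→term pairs), a term's probability is
p(t) = (Σ_{u ∈ D_t} A(u)) / T, where D_t is t plus its descendants and
A(u) the direct annotation count of u. p is 1 at the namespace root and
non-decreasing from child to parent. Terms with zero closure count get
the Laplace-style p = 1/(T+1) so their information content −ln p stays
finite. Term similarity is the Resnik/Lord form: the maximum IC over
the common ancestor set, normalized to [0, 1] by −ln(1/T) (the IC of a
singleton-annotation term); values from smoothed terms are clipped at 1.
Normalization makes the pair-filtering threshold (below) interpretable
across corpora of different sizes. Gene-level similarity is the maximum
over all annotation term pairs; a protein with no annotation in a
namespace yields an *absent* feature, not 0. GO Slim overlap uses
map2slim semantics (each direct annotation maps to every slim ancestor,
itself included when it is in the slim set) with namespace roots
removed before intersecting.

**Neighbor overlap.** The Czekanowski–Dice family measures how many
interaction partners two proteins share. We use the self-inclusive
similarity 2|N*(X) ∩ N*(Y)| / (|N*(X)| + |N*(Y)|) with
N*(V) = N(V) ∪ {V}, so adjacent proteins with identical partner sets
score 1 and higher means "more likely to interact"; the corresponding
distance is 1 minus this value. Self-inclusion keeps adjacent pairs
from being penalized for not being their own neighbors.

**Absence semantics.** "No domain data for either protein" and "domain
data present, DDI sum 0" are different evidence states; likewise a pair
missing from a score table vs scored 0. Features are therefore
NaN-able until discretization, which emits an explicit absent-indicator
bin per feature, making absence a learnable signal.

**Pair filtering.** Pairs whose only evidence is weak GO + expression
signal are removed before learning: a pair is dropped iff (i) DDI,
passthrough scores and neighbor overlap are all absent, (ii) BP and CC
Type I features are 0 (or absent) and BP and CC Type II similarities
fall below 0.002 (or are absent), and (iii) Pearson r < 0.5 (or
absent). MF is not inspected by (ii): the heuristic targets the
process/location coherence expected of co-complex proteins. Treating
an absent GO feature as satisfying the removal condition follows the
heuristic's intent — absence of evidence is not evidence.

**Discretization.** Equal-frequency bins (default 5 per feature) are
fit on finite values only, with quantile ties collapsed to unique
boundaries; a constant feature degrades to a single bin with a warning.
The expanded binary length is data- and configuration-dependent, not a
contract.

## PU ensemble

Training pairs are the curated positives; pseudo-negatives are sampled
uniformly without replacement from the unlabeled pool (sorted before
sampling, so draw order never depends on set iteration order). Group
mode trains one member per (repeat, ratio) over the ladder
{1, 2, 4, …, 2ⁿ}; fixed mode repeats a single ratio. Per-member RNG
streams are spawned from the spec seed in repeat-major order, so adding
members never perturbs earlier draws.

Member scores are min–max normalized over the scored set before
summation (default). A raw-sum switch exists: summing raw margins is
the literal historical behaviour, but it makes the aggregate depend on
each member's arbitrary score scale, which is undefined for arbitrary
base learners. Ties in the aggregate are broken lexicographically by
canonical pair for reproducibility. The default base learner is a
linear max-margin classifier (LinearSVC); any object with
`fit(pos, neg)` / `score(rows)` where larger means more positive-like
satisfies the contract.

Cross-validation partitions the positives into five folds; each test
fold is hidden inside the unlabeled pool, the ensemble is retrained on
the remainder, and Lift at each k is computed with the held-out
positives as truth. Group mode sums member scores within a fold before
ranking; fixed mode averages one Lift per repeat. Both the group ladder
and the fixed-ratio list ({1, 2, 4, 6, 8} in the comparison layout) are
configuration, since the two conventions in circulation differ.

## Reconstruction and MCL

The reconstructed network is reliable ∪ top-n predicted edges, each
edge tagged with its provenance; predicted edges are unweighted unless
a flag copies aggregate scores as weights (detectors in the original
setting may or may not have seen weights — both are supported).
Overlap between predictions and the reliable set is treated as an
upstream pool-construction bug and raises.

MCL adds self-loops of weight 1 before column normalization (standard
regularization; guarantees aperiodicity), then iterates expansion
(matrix power e=2), inflation (entrywise power r with column
renormalization) and pruning of entries < 1e−5, until the maximum
entrywise change drops below 1e−6 or 100 iterations pass
(non-convergence returns the current interpretation with a warning
flag). Clusters are read off the converged matrix: rows with diagonal
mass are attractors; attractors with overlapping supports form one
attractor system; every node joins the system holding its largest
column mass, with lexicographic tie-breaking, yielding a deterministic
partition. Defaults r=2.0, minimum cluster size 3 (matching the
benchmark's size filter); work is done per connected component, which
provably changes nothing since flow never crosses components.

## Evaluation

Matching uses NA(p, b) = |V_p ∩ V_b|²/(|V_p||V_b|) at ω = 0.25
(0.20 is the common alternative); best matches are reported by maximum
NA, but precision/recall/F depend only on the ≥ ω predicate, so tie
handling cannot affect them. Enrichment significance is the raw
one-sided hypergeometric tail P(X ≥ k), minimized over the terms
annotating a cluster (per namespace when requested); no
multiple-testing correction is applied by default because the
downstream metric thresholds raw p < 0.01 — a Bonferroni switch
exists. Pair relevance counts edges whose metric is *strictly* above
the threshold among edges where the metric is defined, reporting the
number excluded.

## Synthetic data

The generator emulates the shapes of a real study at desk scale:
500 proteins, 20 disjoint planted complexes of 4–8 members (disjoint to
keep NA-based evaluation clean; an overlap stress mode is a possible
extension), within-complex interaction probability 0.9, background pair
probability 5e−4 (real interactomes have well under 1% of random pairs
interacting), and a 50/50 split of true interactions into labeled
positives and hidden positives left in the unlabeled pool.

Evidence noise defaults: 20 expression samples with complex-latent
profiles plus N(0, 0.5²) member noise (within-complex r ≈ 0.8);
complex-coherent BP/CC leaf annotation with probability 0.85 (random
background annotation 0.7, MF random); domain coverage 0.8 with an
interacting domain pair injected for half the true PPIs; score columns
(one STRING-like, three AP-MS-like) covering 80% of true pairs at mean
0.8 vs false entries at mean 0.2, sd 0.25; an observed network with
20% false negatives and 15% spurious edges. These were chosen once as
a moderately noisy but learnable regime comparable to curated yeast
resources.

What passing tests on this universe do **not** show: robustness to
overlapping complexes, to scale-free degree structure, to systematic
(non-independent) noise across evidence sources, or to the extreme
class imbalance of a full 24-million-pair universe. The generator's
independence assumptions (noise independent across sources and pairs)
are the main idealization.

Known scale effect: with ~170 hidden positives, ranking metrics at
k ≫ #positives saturate — every reasonable ranking places all hidden
positives inside the top 1000 of ~124,600 pairs, so Lift@1000 hits its
ceiling and cannot separate sampling modes that differ only within the
top ranks; smaller k (or larger universes) restore discrimination.

## Pipeline and seeds

One master seed fans out to per-stage seeds (truth, evidence, pool,
learning) via spawned seed sequences, all recorded in the run manifest
together with config snapshot, package version, stage timings and
output file digests. Re-running an identical config reproduces
byte-identical rankings and cluster files.

## Limitations

- External detectors are adapters over their output files only.
- Ontology I/O is the package's TSV dialect; OBO/GAF conversion is out
  of core scope.
- The hypergeometric enrichment treats annotations as direct hits (no
  ancestor propagation before testing).
- MCL's overlapping-attractor interpretation resolves ambiguity to a
  hard partition; genuinely overlapping complexes require an external
  detector.
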