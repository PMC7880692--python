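# Methods

This note documents the models and procedures implemented in `tcrdyn`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer should
know about.

## Clone identity and depth matching

All analyses operate on amino-acid-level clonotypes identified by the
tuple `(chain, v_gene, j_gene, cdr3_aa)`; nucleotide-level variants of
the same amino-acid junction are deliberately merged, because clustering
and classification act on amino-acid CDR3s and mixing identity levels
across stages invites double counting. Duplicate rows in an input table
are merged by summing abundance, with a warning.

Samples from different sequencing runs are made comparable by subsampling
to a common molecule depth (the cohort minimum, by convention). The
subsample is a multivariate hypergeometric draw over clone counts —
molecules are drawn without replacement, as in re-sequencing a finite
library — so expected output frequencies equal input frequencies exactly
and the count variance of a clone follows the hypergeometric formula
(both property-tested at 3σ).

CDR3 validation uses `^C[A-Z]+[FW]$` (conserved cysteine to conserved
phenylalanine or tryptophan). The default policy is warn-and-keep:
genuine junctions occasionally end in W or carry rare residues, and the
downstream statistics do not require canonical anchors. Strict exclusion
is available for pipelines that want it.

## Expansion detection and the Poisson sampling null

Between a depth-matched reference and target sample, the expanded set is
`{clone : count_ref = 0 and count_tgt ≥ k}`, reported per threshold
k ∈ {4, 8, 16, 32} with k = 8 the default. The headline percentage uses
the number of unique clones in the target subsample as the denominator
(configurable; the choice only rescales, it does not reorder subjects).
The same statistic computed with reference and target swapped is an
internal control: under sampling noise alone the two directions are
exchangeable.

The sampling null is made quantitative by modeling a clone's counts in
two equal-depth samples as i.i.d. Poisson(λ): the probability of a
0 → ≥k transition is f(λ) = e^−λ · P(Pois(λ) ≥ k), and since λ (the
clone's expected count) is unknown, we bound over all rates:
sup_λ f(λ), located by dense grid search over λ ∈ (0, 30] (30 000
points; f vanishes beyond the grid because e^−λ dominates, and the
maximizer for k = 8 sits near λ ≈ 2.4). For k = 8 the bound is
9.65×10⁻⁴ < 0.05: per-clone false transitions are rare, so even a
modest count of expanded clones is overwhelming evidence against pure
sampling. This sup-over-rate reading is deliberately conservative — any
particular clone's rate gives a smaller probability.

Correlation between per-subject expansion counts and ordinal clinical
scores (patch-test grades encoded − = 0 … +++ = 3) uses Spearman rank
correlation with average ranks for ties; a constant input raises an
error rather than propagating NaN.

## Bootstrap V/J skew test

For each gene segment, the observed proportion among the unique expanded
clones is ranked within 1000 proportions computed on equal-sized sets of
unique clones drawn without replacement from the pre-sensitization
background (equal-sized *sets* of clones, not molecules, because the
expanded set is itself a set of unique clonotypes; a with-replacement
variant is available). A gene whose observed proportion is among the 50
largest of the 1001 values is over-represented; among the 50 smallest,
under-represented — a per-side level of 50/1001 ≈ 0.05, with no
correction across genes.

Ties between the observed and bootstrap values are broken by placing the
observed value last among its equals on the side being tested, which
biases calls toward non-significance; the calibration test therefore
checks the empirical type-I rate from above (≤ nominal + 3σ) and only
loosely from below. Under-represented calls for genes the expanded set
is too small to resolve (background frequency below 1/|expanded set|)
carry a `low_confidence` flag.

## Triplet spectrum-kernel clustering

The similarity of two CDR3s is the k = 3 spectrum kernel — the inner
product of their 3-mer count vectors — normalized by the geometric mean
of the self-kernels, giving K̂ ∈ [0, 1] with K̂(x, x) = 1. Sequences with
K̂ strictly above 0.75 are connected; connected components with ≥ 2
members are clusters, and components with > 3 members are reported as
"large". The implementation computes the Gram matrix as a sparse 3-mer
count-matrix product and is verified against a brute-force
substring-comparison oracle for exact equality.

Nodes are unique CDR3 strings (multiplicity does not create extra
nodes). Sequences shorter than 3 residues carry no triplet and are
excluded with a warning. In place of an external multiple-sequence
alignment, a cluster is summarized by a left-anchored position-frequency
matrix over its members (20 amino acids + a gap state for positions past
a shorter member's end, rows summing to 1); left anchoring is a fair
approximation because kernel clusters share their N-terminal anchor, but
it will smear motifs in clusters with length heterogeneity concentrated
at the N-terminus.

## The positional DBN classifier

**Encoding.** CDR3s are left-aligned at the conserved cysteine and
padded to 22 positions with a dummy symbol (alphabet: 20 amino acids =
codes 0–19, 20 = non-canonical residue, 21 = dummy). Sequences longer
than 22 are rejected — the cap keeps the unrolled network tractable —
and triplets that span the CDR3/dummy boundary use the dummy symbol
literally (padding precedes triplet extraction).

**Score tables.** From a training split, every feature is scored 1
(more frequent in the expanded class) or 2 (more frequent in the
control class), with exact ties decided by a fair coin: V genes, J
genes, each amino acid at each position, and per-position prefixes —
the singleton at position 1, the ordered pair at position 2, the
triplet ending at each later position. One table set is built per
training split and shared by both class models, since every score is by
construction a comparison *between* the classes. The coin is a
deterministic hash of (seed, feature), so tie outcomes are reproducible
and independent of evaluation order, including for keys first seen at
test time (unknown genes and unseen triplets fall back to the same
coin).

**Class scores.** The class score at position i is a majority vote over
the sequence's V score, J score, all per-position amino-acid scores,
and the triplet scores of positions before i, ties again by the seeded
coin. For training sequences the final position's class score is
overwritten with the true class code — this is the supervised signal;
test sequences get only table-derived scores.

**Model.** One network per class, unrolled over 22 slices with hidden
binary `Class` nodes chained across slices, `AA_{i−1} → AA_i` edges,
and `Class_i` as parent of the slice's amino acid, triplet score, class
score, V and J nodes. All CPTs are position-specific. Because only the
class chain is hidden, exact inference reduces to forward-backward
message passing on a non-homogeneous two-state chain (what the junction
tree algorithm becomes on this structure); the implementation is
cross-checked to 1e-8 against brute-force enumeration of all 2^L hidden
paths on small networks.

**Training.** EM (Baum–Welch) with CPTs initialized from Dirichlet
draws and an M-step that adds `prior_strength` (default 1.0)
pseudocounts to every CPT cell — the MAP update under a
Dirichlet(1 + prior_strength) prior. The quantity EM provably increases
is the penalized objective log P(data|θ) + log P(θ); both it and the
raw log-likelihood are recorded, and the monotonicity test asserts the
penalized objective. At most 10 iterations, stopping early below a 1e-6
gain. Classification compares the two models' exact log-likelihoods,
summing over members for sets; exact ties are broken by the seeded coin.

**Cross-validation.** Repeated stratified k-fold (default 10×10) on
balanced class sets, rebuilding score tables from each training split
only (a leakage guard verifies train/test disjointness). Reported
tiers: each whole test half classified as one set; disjoint sets of 10;
every sequence; and the top 5%/10% of sequences by log-likelihood-ratio
confidence. On well-separated synthetic classes the tiers order as
expected (full set ≥ sets of 10 ≥ confident fractions ≥ all sequences),
and permuting class labels before training drops per-sequence accuracy
to 50% ± Monte-Carlo error — the chance-level control recomputed by
`scripts/acceptance.py`.

A reporting utility exposes the ratio of neighboring-residue
conditionals between the classes (P(Y at j+1 | X at j) in one class
over the other, add-one smoothed), whose largest deviations localize
implanted or learned motifs.

## Synthetic data: what it does and does not emulate

The generator draws, per subject, a pool of background clonotypes
(default 30 000) with Zipf weights (rank^−α, default α = 1.0) and
resamples counts at each time point as an independent multinomial draw
at fixed depth (default 21 838 molecules) — pure sampling noise, no real
background dynamics. Expanded clones are excluded from the baseline
draw, appear at the second time point with abundance uniform in
(8, 200) by default, and decay by binomial thinning with survival
probability `persistence` (default 0.3) per subsequent time point.
Their CDR3s carry an implanted length-3 motif with probability
`motif_prob` and draw V/J from a concentrated bias distribution;
control subjects implant nothing. Patch scores are a noisy monotone
function of the number of implanted clones, so rank correlation is
recoverable but not deterministic.

Default scales follow the study design the package targets: depth
21 838 (a cohort-minimum subsampling depth), ~90 implanted clones per
patient (about the per-patient share of a ~2000-clone expanded set over
22 patients), four patient time points and three control visits. The
Zipf exponent 1.0 was chosen so a baseline sample at that depth shows a
heavy-tailed but diverse repertoire (thousands of unique clones, Gini
≈ 0.7, top clone < 10% of molecules); larger exponents collapse the
repertoire onto a handful of clones, which is unrealistic for blood.

Not emulated: V(D)J generation probabilities and nucleotide-level
recombination, selection against particular junctions, shared/public
clones between subjects, library-preparation artifacts, or real
inter-time-point drift of the background. Passing tests on this
generator therefore demonstrate the *statistical machinery* (detection,
calibration, recovery, classification) under the assumed structure, not
performance on any particular real cohort; classifier accuracy on
synthetic motif classes in particular is set by construction (motif
probability and V/J bias), and only its calibration controls (chance
level under label permutation, exchangeable classes at 50%) transfer to
real data unconditionally.

Tests and the acceptance script run the generator at reduced scale
(thousands of clones and molecules, hundreds of classifier sequences) —
sizes chosen so the whole suite completes in well under a minute while
keeping every Monte-Carlo band at 3σ or wider.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; tie-breaks use a hash-based coin so outcomes are order-independent.
- Shannon entropy uses natural log (base configurable); Gini is computed
  over unique-clone abundances via the sorted-rank identity.
- The "frequency ≥ 1/1000" abundant-clone rule is inclusive at the
  boundary.
- Graph edges require similarity strictly greater than the threshold.
- Forward-backward works on per-position-rescaled emissions with
  per-step normalization, so likelihoods of length-22 sequences with
  ~40-state emission alphabets stay well-conditioned; emission terms are
  floored at 1e-300 before taking logs.
- The expansion percentage denominator, kernel threshold, cluster size
  cutoffs, bootstrap draw mode, Shannon base, and the DBN's slice count,
  prior strength and EM budget are all parameters, with defaults as
  above.

## Known limitations

- The left-anchored PFM is a crude stand-in for a real multiple
  alignment of a CDR3 cluster.
- The DBN's intra-slice edge set is fixed to the structure described
  above; no structure learning is attempted.
- Under-representation calls in the V/J skew test are intrinsically weak
  for small expanded sets, flag or no flag.
- The Poisson transition bound treats the two samples as exactly
  depth-matched; unequal depths would need a two-rate version.
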