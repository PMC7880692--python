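# tcrdyn

Longitudinal T-cell receptor (TCR) repertoire analysis for
sensitization-style study designs: a subject is sampled before exposure to
an antigen (a contact-sensitizing hapten, a vaccine, an infection) and
again at later time points, and the question is which clonotypes expanded
in response, and whether the expanded set carries the sequence signatures
of an antigen-driven response.

`tcrdyn` implements the full analysis chain on amino-acid-level clone
tables (one row per unique `chain / V gene / J gene / CDR3` with a
UMI-derived molecule count):

- **Expansion detection** between depth-matched time points: a clone is
  *expanded* when it has count 0 in the reference subsample and count ≥ k
  (default k = 8) in the target subsample. The reverse-direction
  percentage is an internal sampling control, and a Poisson model of
  sequencing sampling bounds the per-clone probability of a spurious
  0 → ≥8 transition at sup over λ of e^−λ · P(Pois(λ) ≥ 8) ≈ 9.6×10⁻⁴,
  far below 0.05.
- **Repertoire summaries**: Shannon diversity H = −Σ pᵢ ln pᵢ, the Gini
  inequality coefficient of clone abundances, and the count of clones at
  frequency ≥ 1/1000, all on subsamples drawn to a common depth.
- **V/J usage skew**: a bootstrap rank test — the observed proportion of
  each V/J gene among expanded clones is ranked within 1000 proportions
  from equal-sized random sets of background clones; genes in the top /
  bottom 50 of the 1001 ranks are called over-/under-represented
  (0.05 per side).
- **CDR3 clustering** with the k = 3 spectrum string kernel
  K̂(a,b) = ⟨c_a,c_b⟩ / √(⟨c_a,c_a⟩⟨c_b,c_b⟩) over triplet count vectors;
  pairs with K̂ > 0.75 are connected and connected components form
  clusters, compared against size-matched random background draws.
- **A positional dynamic Bayesian network (DBN) classifier** separating
  antigen-expanded from background CDR3s: the network is unrolled over 22
  CDR3 positions with a hidden binary class chain
  (Class_{i−1} → Class_i), neighboring-residue edges (AA_{i−1} → AA_i),
  and per-slice observations (amino acid, V, J, triplet score, class
  score). Exact inference is forward-backward message passing; training
  is EM with Dirichlet smoothing; classification compares per-class model
  log-likelihoods, summed over members for sets of sequences. A repeated
  stratified 10-fold cross-validation harness reports accuracy for whole
  test sets, sets of 10, single sequences, and the most confident
  fractions of sequences.
- **A synthetic-data generator** that emulates the study structure —
  Zipf-tailed background repertoires resampled per time point, implanted
  transient expansions sharing triplet motifs and biased V/J usage,
  motif-free control subjects — with ground truth attached, so every
  stage is testable end to end.

## Worked example

```python
from tcrdyn import (SimConfig, simulate_cohort, detect_expanded,
                    poisson_transition_bound, shannon_index,
                    gini_coefficient, bootstrap_skew)
from tcrdyn.io import TcrClone

cfg = SimConfig(seed=42, n_clones=5000, depth=10000, n_vgenes=12,
                n_jgenes=6, n_expanded=60,
                expansion_abundance_range=(16, 150))
study = simulate_cohort(cfg, n_patients=2, n_controls=1)
subj = study.patients[0]
ps, pt1 = subj.samples["PS"], subj.samples["PT1"]
print(f"PS:  {ps.n_unique} unique clones, depth {ps.total_depth}, "
      f"Shannon {shannon_index(ps):.3f}, Gini {gini_coefficient(ps):.3f}")
res = detect_expanded(ps, pt1, threshold=8, seed=0)
print(f"PT1 expanded: {len(res.expanded)} clones "
      f"({res.pct_expanded:.2f}% of {res.n_unique_target} target clones); "
      f"reverse: {len(res.reverse_expanded)} ({res.reverse_pct:.2f}%)")
```

prints

```
PS:  2214 unique clones, depth 10000, Shannon 5.935, Gini 0.700
PT1 expanded: 35 clones (1.77% of 1974 target clones); reverse: 0 (0.00%)
```

All 35 detected clones are the implanted ground-truth expansions
(`subj.truth_expanded["PT1"]`), and the reverse direction is empty, as
expected when the only structured change between time points is the
implanted response. The bootstrap skew test on the expanded set
(`bootstrap_skew(...)`) flags exactly the V/J genes the generator biased
(`TRBV1, TRBV3, TRBJ1, TRBJ2` here), and
`poisson_transition_bound(8)` returns `9.65e-04`: a clone's chance of a
0 → ≥8 transition by sampling alone, even at the least favorable clone
frequency, is about 1 in 1000.

A command-line interface mirrors the library (`tcr io validate`,
`tcr summary`, `tcr expand`, `tcr vjskew`, `tcr cluster`, `tcr dbn-cv`,
`tcr run --config study.yaml` for the whole pipeline with a checksummed
manifest).

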