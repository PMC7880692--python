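"""Positional dynamic Bayesian network classifier for CDR3 sequences.

The classifier separates antigen-expanded from background CDR3s using a
Bayesian network unrolled over CDR3 positions (one "slice" per position,
22 by default).  Each slice i carries observed nodes — the amino acid
AA_i, the V and J gene, a triplet score T_i and a class score CS_i, both
binary summaries of how class-discriminative the local sequence context
looked in the training data — and one hidden binary Class_i node.  The
edge set is:

    Class_{i-1} -> Class_i          (hidden chain)
    AA_{i-1}   -> AA_i              (neighboring-residue dependence)
    Class_i    -> AA_i, T_i, CS_i, V_i, J_i

With every node except the Class chain observed, the model is a
non-homogeneous two-state hidden chain with position-specific conditional
probability tables, so exact inference is forward-backward message
passing (the junction-tree algorithm specializes to exactly this on a
chain).  Parameters are fitted by expectation-maximization with Dirichlet
smoothing, at most 10 iterations by default.  One model is trained per
class on that class's sequences; a sequence (or a set, by summing) is
labeled by the model with the higher log-likelihood.

Sequences are left-aligned at the conserved cysteine and padded to the
slice count with a dummy symbol; CDR3s longer than the slice count are
rejected.  Score tables are always built from training data only, and the
cross-validation harness guards against train/test leakage.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["EncodedSequence", "ScoreTables", "DbnModel",
           "ClassificationResult", "encode", "build_score_tables",
           "assign_class_scores", "train", "loglik", "loglik_enumerate",
           "classify", "classify_set", "cross_validate", "shuffle_labels",
           "bigram_ratio_heatmap", "N_POSITIONS"]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN_CODE = 20        # non-canonical residue
DUMMY_CODE = 21          # pad symbol past the end of the CDR3
N_SYMBOLS = 22
N_POSITIONS = 22         # default slice count (CDR3 length cap)

_AA_CODE = {a: i for i, a in enumerate(AA20)}

DPC, CTRL = "DPC", "CTRL"
_CLASS_CODE = {DPC: 1, CTRL: 2}


def _coin(seed: int, *key) -> int:
    """Deterministic fair coin in {1, 2}, keyed by (seed, *key).

    Used for every '1 or 2 uniformly at random' tie-break, so the outcome
    is reproducible and independent of evaluation order.
    """
    h = zlib.crc32(repr((seed,) + key).encode())
    return 1 + (h & 1)


@dataclass
class EncodedSequence:
    """A CDR3 with gene context, integer-encoded and padded to the slice
    count; score vectors are attached by :func:`assign_class_scores`."""

    v_gene: str
    j_gene: str
    cdr3_aa: str
    symbols: np.ndarray                      # (n_positions,) ints 0..21
    true_class: str = "unknown"              # DPC, CTRL or unknown
    triplet_scores: np.ndarray | None = None  # (n_positions,) in {1,2}
    class_scores: np.ndarray | None = None    # (n_positions,) in {1,2}
    v_code: int | None = None
    j_code: int | None = None


def encode(v_gene: str, j_gene: str, cdr3_aa: str,
           true_class: str = "unknown",
           n_positions: int = N_POSITIONS) -> EncodedSequence:
    """Integer-encode a CDR3: amino acids 0-19 (alphabetical), 20 for a
    non-canonical residue, 21 for the dummy pad filling positions past the
    CDR3's end.  CDR3s longer than ``n_positions`` exceed the length cap
    and are rejected; shorter than 3 residues cannot carry a triplet."""
    cdr3_aa = cdr3_aa.strip().upper()
    if len(cdr3_aa) > n_positions:
        raise ValueError(f"CDR3 {cdr3_aa!r} exceeds length cap {n_positions}")
    if len(cdr3_aa) < 3:
        raise ValueError(f"CDR3 {cdr3_aa!r} shorter than 3 residues")
    symbols = np.full(n_positions, DUMMY_CODE, dtype=np.int64)
    for i, a in enumerate(cdr3_aa):
        symbols[i] = _AA_CODE.get(a, UNKNOWN_CODE)
    return EncodedSequence(v_gene=v_gene, j_gene=j_gene, cdr3_aa=cdr3_aa,
                           symbols=symbols, true_class=true_class)


@dataclass
class ScoreTables:
    """Class-discrimination score tables learned from a training split.

    Every score is 1 ("looked more like the expanded class in training")
    or 2 ("more like the control class"); exact frequency ties, and keys
    never seen in training, fall back to the deterministic seeded coin.
    Position 1 is scored on the single residue, position 2 on the ordered
    pair, and positions >= 3 on the triplet ending at that position
    (dummy-padded triplets are looked up literally).
    """

    n_positions: int
    seed: int
    v_scores: dict[str, int]
    j_scores: dict[str, int]
    aa_scores: np.ndarray                       # (n_positions, 22) in {1,2}
    prefix_scores: list[dict[tuple, int]]       # per position, key -> score
    v_vocab: dict[str, int]                     # gene -> code (UNK = last)
    j_vocab: dict[str, int]

    @property
    def n_v(self) -> int:
        return len(self.v_vocab) + 1            # +1 for unseen genes

    @property
    def n_j(self) -> int:
        return len(self.j_vocab) + 1

    def v_code(self, gene: str) -> int:
        return self.v_vocab.get(gene, len(self.v_vocab))

    def j_code(self, gene: str) -> int:
        return self.j_vocab.get(gene, len(self.j_vocab))

    def v_score(self, gene: str) -> int:
        s = self.v_scores.get(gene)
        return s if s is not None else _coin(self.seed, "V?", gene)

    def j_score(self, gene: str) -> int:
        s = self.j_scores.get(gene)
        return s if s is not None else _coin(self.seed, "J?", gene)

    def triplet_score(self, pos: int, key: tuple) -> int:
        s = self.prefix_scores[pos].get(key)
        return s if s is not None else _coin(self.seed, "T?", pos, key)


def _score_counts(dpc_n: int, ctrl_n: int, seed: int, *key) -> int:
    if dpc_n > ctrl_n:
        return 1
    if ctrl_n > dpc_n:
        return 2
    return _coin(seed, *key)


def _prefix_key(symbols: np.ndarray, pos: int) -> tuple:
    """Scoring key at 0-based position: singleton, ordered pair, then the
    triplet of the two previous residues plus the current one."""
    lo = max(0, pos - 2)
    return tuple(int(s) for s in symbols[lo:pos + 1])


def build_score_tables(train_dpc: Sequence[EncodedSequence],
                       train_ctrl: Sequence[EncodedSequence],
                       seed: int = 0) -> ScoreTables:
    """Build V/J, per-position amino-acid, and per-position prefix
    (singleton/pair/triplet) score tables from the two training sets."""
    if not train_dpc or not train_ctrl:
        raise ValueError("both training sets must be nonempty")
    L = len(train_dpc[0].symbols)

    def gene_counts(seqs, attr):
        out: dict[str, int] = {}
        for s in seqs:
            g = getattr(s, attr)
            out[g] = out.get(g, 0) + 1
        return out

    v_dpc, v_ctrl = gene_counts(train_dpc, "v_gene"), gene_counts(train_ctrl, "v_gene")
    j_dpc, j_ctrl = gene_counts(train_dpc, "j_gene"), gene_counts(train_ctrl, "j_gene")
    v_scores = {g: _score_counts(v_dpc.get(g, 0), v_ctrl.get(g, 0), seed, "V", g)
                for g in sorted(set(v_dpc) | set(v_ctrl))}
    j_scores = {g: _score_counts(j_dpc.get(g, 0), j_ctrl.get(g, 0), seed, "J", g)
                for g in sorted(set(j_dpc) | set(j_ctrl))}

    sym_dpc = np.stack([s.symbols for s in train_dpc])
    sym_ctrl = np.stack([s.symbols for s in train_ctrl])
    aa_scores = np.zeros((L, N_SYMBOLS), dtype=np.int64)
    for p in range(L):
        cd = np.bincount(sym_dpc[:, p], minlength=N_SYMBOLS)
        cc = np.bincount(sym_ctrl[:, p], minlength=N_SYMBOLS)
        for a in range(N_SYMBOLS):
            aa_scores[p, a] = _score_counts(int(cd[a]), int(cc[a]), seed, "AA", p, a)

    prefix_scores: list[dict[tuple, int]] = []
    for p in range(L):
        cd: dict[tuple, int] = {}
        cc: dict[tuple, int] = {}
        for s in train_dpc:
            k = _prefix_key(s.symbols, p)
            cd[k] = cd.get(k, 0) + 1
        for s in train_ctrl:
            k = _prefix_key(s.symbols, p)
            cc[k] = cc.get(k, 0) + 1
        prefix_scores.append(
            {k: _score_counts(cd.get(k, 0), cc.get(k, 0), seed, "T", p, k)
             for k in sorted(set(cd) | set(cc))})

    v_vocab = {g: i for i, g in enumerate(sorted(set(v_dpc) | set(v_ctrl)))}
    j_vocab = {g: i for i, g in enumerate(sorted(set(j_dpc) | set(j_ctrl)))}
    return ScoreTables(n_positions=L, seed=seed, v_scores=v_scores,
                       j_scores=j_scores, aa_scores=aa_scores,
                       prefix_scores=prefix_scores,
                       v_vocab=v_vocab, j_vocab=j_vocab)


def assign_class_scores(seq: EncodedSequence, tables: ScoreTables,
                        training: bool = False) -> EncodedSequence:
    """Attach triplet scores and cumulative class scores to a sequence.

    The class score at position i is a majority vote over the sequence's
    V score, J score, all per-position amino-acid scores, and the triplet
    scores of positions before i; exact ties fall to the seeded coin.  For
    training sequences the final position's class score is overridden with
    the sequence's true class code, which is how class identity enters the
    model during training.
    """
    L = tables.n_positions
    if len(seq.symbols) != L:
        raise ValueError("sequence and tables disagree on slice count")
    trip = np.array([tables.triplet_score(p, _prefix_key(seq.symbols, p))
                     for p in range(L)], dtype=np.int64)
    base_votes = [tables.v_score(seq.v_gene), tables.j_score(seq.j_gene)]
    base_votes += [int(tables.aa_scores[p, seq.symbols[p]]) for p in range(L)]
    n1_base = sum(1 for v in base_votes if v == 1)
    n2_base = len(base_votes) - n1_base

    cs = np.zeros(L, dtype=np.int64)
    n1_trip = n2_trip = 0
    for i in range(L):
        # triplet scores from positions strictly before i contribute
        if i > 0:
            if trip[i - 1] == 1:
                n1_trip += 1
            else:
                n2_trip += 1
        n1, n2 = n1_base + n1_trip, n2_base + n2_trip
        if n1 > n2:
            cs[i] = 1
        elif n2 > n1:
            cs[i] = 2
        else:
            cs[i] = _coin(tables.seed, "CS", bytes(seq.symbols), seq.v_gene,
                          seq.j_gene, i)
    if training:
        if seq.true_class not in _CLASS_CODE:
            raise ValueError("training sequence needs a known true class")
        cs[L - 1] = _CLASS_CODE[seq.true_class]
    seq.triplet_scores = trip
    seq.class_scores = cs
    seq.v_code = tables.v_code(seq.v_gene)
    seq.j_code = tables.j_code(seq.j_gene)
    return seq


# --------------------------------------------------------------------------
# model and inference


@dataclass
class DbnModel:
    """Position-specific CPTs of the unrolled network (all probabilities,
    rows normalized).  ``n_v``/``n_j`` include one code for unseen genes."""

    n_positions: int
    n_v: int
    n_j: int
    pi_class: np.ndarray        # (2,)
    trans: np.ndarray           # (L-1, 2, 2): P(Class_i | Class_{i-1})
    aa_first: np.ndarray        # (2, S): P(AA_1 | Class_1)
    aa: np.ndarray              # (L-1, 2, S, S): P(AA_i | Class_i, AA_{i-1})
    trip: np.ndarray            # (L, 2, 2): P(T_i | Class_i)
    cs: np.ndarray              # (L, 2, 2): P(CS_i | Class_i)
    v: np.ndarray               # (L, 2, n_v): P(V_i | Class_i)
    j: np.ndarray               # (L, 2, n_j): P(J_i | Class_i)
    prior_strength: float = 1.0
    loglik_history: list[float] = field(default_factory=list)
    objective_history: list[float] = field(default_factory=list)
    seed: int = 0

    def to_json(self, path) -> None:
        payload = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "DbnModel":
        with open(path) as fh:
            payload = json.load(fh)
        arrays = {"pi_class", "trans", "aa_first", "aa", "trip", "cs", "v", "j"}
        return cls(**{k: (np.array(v) if k in arrays else v)
                      for k, v in payload.items()})


def _pack(seqs: Sequence[EncodedSequence]):
    sym = np.stack([s.symbols for s in seqs])
    trip = np.stack([s.triplet_scores for s in seqs]) - 1
    cs = np.stack([s.class_scores for s in seqs]) - 1
    v = np.array([s.v_code for s in seqs], dtype=np.int64)
    j = np.array([s.j_code for s in seqs], dtype=np.int64)
    if np.any(trip < 0) or np.any(cs < 0):
        raise ValueError("sequences must be scored before training/inference")
    return sym, trip, cs, v, j


def _log_emissions(model: DbnModel, sym, trip, cs, v, j) -> np.ndarray:
    """log P(observed slice i | Class_i = c) for every sequence: (N, L, 2)."""
    N, L = sym.shape
    logb = np.zeros((N, L, 2))
    tiny = 1e-300
    pos = np.arange(L)[None, :]                     # broadcasts to (N, L)
    pos1 = np.arange(L - 1)[None, :]
    for c in (0, 1):
        logb[:, 0, c] = np.log(model.aa_first[c, sym[:, 0]] + tiny)
        logb[:, 1:, c] = np.log(model.aa[pos1, c, sym[:, :-1], sym[:, 1:]] + tiny)
        logb[:, :, c] += np.log(model.trip[pos, c, trip] + tiny)
        logb[:, :, c] += np.log(model.cs[pos, c, cs] + tiny)
        logb[:, :, c] += np.log(model.v[pos, c, v[:, None]] + tiny)
        logb[:, :, c] += np.log(model.j[pos, c, j[:, None]] + tiny)
    return logb


def _forward_backward(model: DbnModel, logb: np.ndarray):
    """Scaled forward-backward over the binary class chain.

    Returns (loglik per sequence, gamma (N,L,2), xi (N,L-1,2,2)).
    """
    N, L, _ = logb.shape
    b = np.exp(logb - logb.max(axis=2, keepdims=True))
    logoff = logb.max(axis=2)                      # (N, L)
    alpha = np.zeros((N, L, 2))
    scale = np.zeros((N, L))
    a = model.pi_class[None, :] * b[:, 0, :]
    scale[:, 0] = a.sum(axis=1)
    alpha[:, 0, :] = a / scale[:, 0:1]
    for i in range(1, L):
        a = (alpha[:, i - 1, :] @ model.trans[i - 1]) * b[:, i, :]
        scale[:, i] = a.sum(axis=1)
        alpha[:, i, :] = a / scale[:, i:i + 1]
    ll = np.log(scale).sum(axis=1) + logoff.sum(axis=1)

    beta = np.zeros((N, L, 2))
    beta[:, L - 1, :] = 1.0
    for i in range(L - 2, -1, -1):
        beta[:, i, :] = (beta[:, i + 1, :] * b[:, i + 1, :]) @ model.trans[i].T
        beta[:, i, :] /= scale[:, i + 1:i + 2]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    xi = (alpha[:, :-1, :, None] * model.trans[None, :, :, :] *
          (b * beta)[:, 1:, None, :]) / scale[:, 1:, None, None]
    return ll, gamma, xi


def _normalize(counts: np.ndarray) -> np.ndarray:
    return counts / counts.sum(axis=-1, keepdims=True)


def _log_prior(model: DbnModel) -> float:
    """Log Dirichlet(1 + prior_strength) prior over all CPT rows (up to an
    additive constant): prior_strength * sum log theta."""
    a = model.prior_strength
    if a == 0:
        return 0.0
    tiny = 1e-300
    total = 0.0
    for arr in (model.pi_class, model.trans, model.aa_first, model.aa,
                model.trip, model.cs, model.v, model.j):
        total += float(np.log(arr + tiny).sum())
    return a * total


def train(sequences: Sequence[EncodedSequence], tables: ScoreTables,
          prior_strength: float = 1.0, em_max_iters: int = 10,
          tol: float = 1e-6, seed: int = 0) -> DbnModel:
    """Fit one class model by EM on scored sequences.

    The Class chain is hidden; all other nodes are observed.  CPTs are
    initialized from Dirichlet draws, and each M-step adds
    ``prior_strength`` pseudocounts to every CPT cell (the MAP update for
    a Dirichlet(1 + prior_strength) prior), so EM monotonically increases
    the penalized objective log P(data | theta) + log P(theta), recorded
    in ``objective_history`` (raw log-likelihood in ``loglik_history``).
    Stops early when the objective gain falls below ``tol``.
    """
    if not sequences:
        raise ValueError("empty training set")
    L = tables.n_positions
    n_v, n_j = tables.n_v, tables.n_j
    sym, trip, cs, v, j = _pack(sequences)
    N = sym.shape[0]
    rng = np.random.default_rng(seed)

    def dirich(shape):
        g = rng.gamma(1.0, size=shape)
        return g / g.sum(axis=-1, keepdims=True)

    model = DbnModel(
        n_positions=L, n_v=n_v, n_j=n_j,
        pi_class=dirich((2,)), trans=dirich((L - 1, 2, 2)),
        aa_first=dirich((2, N_SYMBOLS)), aa=dirich((L - 1, 2, N_SYMBOLS, N_SYMBOLS)),
        trip=dirich((L, 2, 2)), cs=dirich((L, 2, 2)),
        v=dirich((L, 2, n_v)), j=dirich((L, 2, n_j)),
        prior_strength=prior_strength, seed=seed)

    prev_obj = -np.inf
    for _ in range(em_max_iters):
        logb = _log_emissions(model, sym, trip, cs, v, j)
        ll, gamma, xi = _forward_backward(model, logb)
        total_ll = float(ll.sum())
        obj = total_ll + _log_prior(model)
        if not np.isfinite(total_ll):
            raise FloatingPointError(
                f"non-finite log-likelihood during EM (ll={total_ll}); "
                f"N={N}, L={L}, prior_strength={prior_strength}")
        model.loglik_history.append(total_ll)
        model.objective_history.append(obj)

        a = prior_strength
        model.pi_class = _normalize(gamma[:, 0, :].sum(axis=0) + a)
        model.trans = _normalize(xi.sum(axis=0) + a)
        cnt = np.zeros((2, N_SYMBOLS))
        for c in (0, 1):
            np.add.at(cnt[c], sym[:, 0], gamma[:, 0, c])
        model.aa_first = _normalize(cnt + a)
        cnt = np.zeros((L - 1, 2, N_SYMBOLS, N_SYMBOLS))
        for i in range(1, L):
            for c in (0, 1):
                np.add.at(cnt[i - 1, c], (sym[:, i - 1], sym[:, i]), gamma[:, i, c])
        model.aa = _normalize(cnt + a)
        for name, obs, size in (("trip", trip, 2), ("cs", cs, 2),
                                ("v", v, None), ("j", j, None)):
            if name in ("trip", "cs"):
                cnt = np.zeros((L, 2, size))
                for i in range(L):
                    for c in (0, 1):
                        np.add.at(cnt[i, c], obs[:, i], gamma[:, i, c])
            else:
                width = n_v if name == "v" else n_j
                cnt = np.zeros((L, 2, width))
                for i in range(L):
                    for c in (0, 1):
                        np.add.at(cnt[i, c], obs, gamma[:, i, c])
            setattr(model, name, _normalize(cnt + a))

        if obj - prev_obj < tol and np.isfinite(prev_obj):
            break
        prev_obj = obj
    return model


def loglik(model: DbnModel, sequences: Sequence[EncodedSequence]) -> np.ndarray:
    """Exact per-sequence log-likelihood via the forward pass."""
    sym, trip, cs, v, j = _pack(sequences)
    logb = _log_emissions(model, sym, trip, cs, v, j)
    ll, _, _ = _forward_backward(model, logb)
    return ll


def loglik_enumerate(model: DbnModel, seq: EncodedSequence) -> float:
    """Brute-force log-likelihood by summing over all 2^L hidden class
    paths — an independent exact-inference route for small slice counts,
    used to cross-check the forward-backward recursion."""
    L = model.n_positions
    if L > 16:
        raise ValueError("enumeration is only feasible for small slice counts")
    sym, trip, cs, v, j = _pack([seq])
    logb = _log_emissions(model, sym, trip, cs, v, j)[0]   # (L, 2)
    total = -np.inf
    for mask in range(2 ** L):
        path = [(mask >> i) & 1 for i in range(L)]
        lp = np.log(model.pi_class[path[0]]) + logb[0, path[0]]
        for i in range(1, L):
            lp += np.log(model.trans[i - 1, path[i - 1], path[i]]) + logb[i, path[i]]
        total = np.logaddexp(total, lp)
    return float(total)


@dataclass(frozen=True)
class ClassificationResult:
    loglik_dpc: float
    loglik_ctrl: float
    label: str
    confidence: float           # |loglik difference|


def _label(diff: float, seed: int, key) -> str:
    if diff > 0:
        return DPC
    if diff < 0:
        return CTRL
    return DPC if _coin(seed, "tie", key) == 1 else CTRL


def classify(sequences: Sequence[EncodedSequence], model_dpc: DbnModel,
             model_ctrl: DbnModel, seed: int = 0) -> list[ClassificationResult]:
    """Label each sequence by the higher-likelihood model; exact ties are
    broken by the seeded coin."""
    ld = loglik(model_dpc, sequences)
    lc = loglik(model_ctrl, sequences)
    return [ClassificationResult(float(d), float(c), _label(d - c, seed, i),
                                 abs(float(d - c)))
            for i, (d, c) in enumerate(zip(ld, lc))]


def classify_set(sequences: Sequence[EncodedSequence], model_dpc: DbnModel,
                 model_ctrl: DbnModel, seed: int = 0) -> ClassificationResult:
    """Classify a set of sequences jointly by summed log-likelihoods."""
    ld = float(loglik(model_dpc, sequences).sum())
    lc = float(loglik(model_ctrl, sequences).sum())
    return ClassificationResult(ld, lc, _label(ld - lc, seed, "set"),
                                abs(ld - lc))


# --------------------------------------------------------------------------
# cross-validation harness


def shuffle_labels(dpc_set: Sequence[tuple], ctrl_set: Sequence[tuple],
                   seed: int = 0) -> tuple[list[tuple], list[tuple]]:
    """Randomly permute class labels over the pooled corpus, preserving
    balance — the chance-level control for the classifier."""
    pool = list(dpc_set) + list(ctrl_set)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    half = len(dpc_set)
    return [pool[i] for i in order[:half]], [pool[i] for i in order[half:]]


def _prepare(raw: Iterable[tuple], true_class: str,
             n_positions: int) -> list[EncodedSequence]:
    return [encode(v, j, cdr3, true_class=true_class, n_positions=n_positions)
            for (v, j, cdr3) in raw]


def cross_validate(dpc_set: Sequence[tuple], ctrl_set: Sequence[tuple],
                   n_folds: int = 10, n_repeats: int = 10, set_size: int = 10,
                   confidence_fracs: Sequence[float] = (0.05, 0.10),
                   seed: int = 0, prior_strength: float = 1.0,
                   em_max_iters: int = 10,
                   n_positions: int = N_POSITIONS) -> pd.DataFrame:
    """Repeated stratified k-fold cross-validation of the two-model
    classifier on balanced (v_gene, j_gene, cdr3_aa) sets.

    Per fold, score tables are rebuilt from the training split only, one
    model is trained per class, and the held-out sequences are scored at
    four granularities: the whole test half of each class as one set
    ("full_set"), disjoint subsets of ``set_size`` ("set_of_N"), every
    sequence individually ("per_sequence"), and the top fractions of
    sequences ranked by log-likelihood-difference confidence
    ("top_Xpct").  Returns a tidy frame (repeat, fold, tier, accuracy, n);
    means per tier are the headline numbers.
    """
    if len(dpc_set) != len(ctrl_set):
        raise ValueError("class sets must be balanced (equal sizes)")
    n = len(dpc_set)
    if n < n_folds:
        raise ValueError("fewer sequences than folds")
    rows = []
    for rep in range(n_repeats):
        rng = np.random.default_rng(seed + 7919 * rep)
        perm_d = rng.permutation(n)
        perm_c = rng.permutation(n)
        fold_of = np.arange(n) % n_folds
        for fold in range(n_folds):
            test_d_idx = perm_d[fold_of == fold]
            test_c_idx = perm_c[fold_of == fold]
            train_d_idx = perm_d[fold_of != fold]
            train_c_idx = perm_c[fold_of != fold]
            if set(test_d_idx) & set(train_d_idx) or set(test_c_idx) & set(train_c_idx):
                raise RuntimeError("train/test leakage in fold assignment")

            fold_seed = seed + 104729 * rep + 13 * fold
            tr_d = _prepare([dpc_set[i] for i in train_d_idx], DPC, n_positions)
            tr_c = _prepare([ctrl_set[i] for i in train_c_idx], CTRL, n_positions)
            te_d = _prepare([dpc_set[i] for i in test_d_idx], DPC, n_positions)
            te_c = _prepare([ctrl_set[i] for i in test_c_idx], CTRL, n_positions)

            tables = build_score_tables(tr_d, tr_c, seed=fold_seed)
            for s in tr_d + tr_c:
                assign_class_scores(s, tables, training=True)
            for s in te_d + te_c:
                assign_class_scores(s, tables, training=False)

            model_dpc = train(tr_d, tables, prior_strength=prior_strength,
                              em_max_iters=em_max_iters, seed=fold_seed)
            model_ctrl = train(tr_c, tables, prior_strength=prior_strength,
                               em_max_iters=em_max_iters, seed=fold_seed + 1)

            ld_d = loglik(model_dpc, te_d) - loglik(model_ctrl, te_d)
            ld_c = loglik(model_dpc, te_c) - loglik(model_ctrl, te_c)

            # (a) whole test half of each class as one set
            full_acc = (float(ld_d.sum() > 0) + float(ld_c.sum() < 0)) / 2.0
            rows.append((rep, fold, "full_set", full_acc, 2))
            # (b) disjoint subsets of set_size
            set_hits, set_n = 0, 0
            for arr, want_pos in ((ld_d, True), (ld_c, False)):
                for k in range(len(arr) // set_size):
                    s = arr[k * set_size:(k + 1) * set_size].sum()
                    set_hits += int((s > 0) == want_pos)
                    set_n += 1
            if set_n:
                rows.append((rep, fold, f"set_of_{set_size}",
                             set_hits / set_n, set_n))
            # (c) per-sequence
            diffs = np.concatenate([ld_d, ld_c])
            correct = np.concatenate([ld_d > 0, ld_c < 0])
            rows.append((rep, fold, "per_sequence",
                         float(correct.mean()), diffs.size))
            # (d) most-confident fractions
            order = np.argsort(-np.abs(diffs))
            for frac in confidence_fracs:
                k = max(1, int(round(frac * diffs.size)))
                rows.append((rep, fold, f"top_{int(round(frac * 100))}pct",
                             float(correct[order[:k]].mean()), k))
    return pd.DataFrame(rows, columns=["repeat", "fold", "tier", "accuracy", "n"])


def cv_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy per tier across repeats and folds."""
    return (report.groupby("tier", as_index=False)
            .agg(mean_accuracy=("accuracy", "mean"),
                 sd=("accuracy", "std"), n_cells=("accuracy", "size")))


def bigram_ratio_heatmap(dpc_seqs: Sequence[EncodedSequence],
                         ctrl_seqs: Sequence[EncodedSequence],
                         pseudo: float = 1.0) -> np.ndarray:
    """Ratio of neighboring-residue conditionals between the classes.

    Entry [r, p] with r encoding the ordered pair (X, Y) (r = 22*X + Y) is
    P(Y at p+1 | X at p, expanded class) / P(same | control class), with
    add-``pseudo`` smoothing.  Large deviations from 1 localize the
    positions where the classes differ — e.g. at an implanted motif.
    """
    L = len(dpc_seqs[0].symbols)

    def cond(seqs):
        sym = np.stack([s.symbols for s in seqs])
        cnt = np.full((L - 1, N_SYMBOLS, N_SYMBOLS), pseudo)
        for i in range(L - 1):
            np.add.at(cnt[i], (sym[:, i], sym[:, i + 1]), 1.0)
        return cnt / cnt.sum(axis=2, keepdims=True)

    pd_, pc = cond(dpc_seqs), cond(ctrl_seqs)
    ratio = pd_ / pc
    return ratio.transpose(1, 2, 0).reshape(N_SYMBOLS * N_SYMBOLS, L - 1)
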