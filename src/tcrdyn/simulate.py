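"""Synthetic longitudinal repertoires with implanted transient expansions.

The generator emulates the statistical structure the analysis pipeline
assumes in real hapten-sensitization data:

* heavy-tailed background clone abundances (discrete power law over clone
  ranks, resampled multinomially at fixed sequencing depth per time point);
* per-subject samples at four time points (PS, PT1, PT2, PT3), with a small
  set of clones implanted that are absent at PS, appear at PT1 with a
  configurable abundance, and decay geometrically afterwards;
* implanted (antigen-driven–like) clones share CDR3 amino-acid triplet
  motifs and draw V/J genes from a biased distribution, while background
  clones use the background V/J frequencies;
* control subjects carry no implanted clones at any time point.

Ground truth (which clones were implanted, and when) is carried alongside
the samples so detection operations can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import RepertoireSample, TcrClone

__all__ = ["SimConfig", "SimSubject", "SimStudy", "simulate_subject",
           "simulate_cohort", "simulate_dbn_sets"]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Mildly non-uniform residue usage for CDR3 interiors; serine/glycine-rich
# as in beta-chain junctions.
_BG_AA_WEIGHTS = np.array([
    6.0, 1.5, 4.0, 5.0, 3.5, 8.0, 2.0, 3.0, 2.5, 5.5,
    1.5, 4.5, 3.5, 4.5, 4.5, 9.0, 5.5, 4.0, 1.5, 4.5,
])
_BG_AA_PROBS = _BG_AA_WEIGHTS / _BG_AA_WEIGHTS.sum()

PATIENT_TPS = ("PS", "PT1", "PT2", "PT3")


def _decreasing_probs(n: int, decay: float = 0.92) -> np.ndarray:
    w = decay ** np.arange(n)
    return w / w.sum()


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the scale of the sensitization cohort: sequencing depth
    equal to the cohort-minimum subsampling depth (21 838 beta TCRs),
    tens of thousands of background clonotypes with a Zipf tail, and on the
    order of ninety implanted transiently-expanded clones per subject.
    """

    n_clones: int = 30_000
    depth: int = 21_838
    abundance_exponent: float = 1.0
    cdr3_length_range: tuple[int, int] = (8, 22)
    n_vgenes: int = 40
    n_jgenes: int = 13
    vj_background_freqs: tuple[np.ndarray, np.ndarray] | None = None
    n_expanded: int = 90
    expansion_abundance_range: tuple[int, int] = (8, 200)
    motif_set: tuple[str, ...] = ("ASS", "SQG", "YEQ")
    motif_prob: float = 0.5
    expanded_vj_bias: tuple[np.ndarray, np.ndarray] | None = None
    persistence: float = 0.3
    chain: str = "beta"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_expanded > self.n_clones:
            raise ValueError("n_expanded exceeds n_clones")
        if not 0.0 <= self.motif_prob <= 1.0:
            raise ValueError("motif_prob must be in [0, 1]")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must be in [0, 1]")
        lo, hi = self.cdr3_length_range
        if lo < 5 or hi > 22 or lo > hi:
            raise ValueError("cdr3_length_range must lie within [5, 22]")
        for m in self.motif_set:
            if not (m.isalpha() and m.isupper() and len(m) == 3):
                raise ValueError(f"motif {m!r} must be a length-3 uppercase triplet")
        if self.vj_background_freqs is None:
            self.vj_background_freqs = (_decreasing_probs(self.n_vgenes),
                                        _decreasing_probs(self.n_jgenes))
        if self.expanded_vj_bias is None:
            # concentrate ~80% of mass on the first three V and two J genes
            v = np.full(self.n_vgenes, 0.2 / max(self.n_vgenes - 3, 1))
            v[:3] = 0.8 / 3
            j = np.full(self.n_jgenes, 0.2 / max(self.n_jgenes - 2, 1))
            j[:2] = 0.8 / 2
            self.expanded_vj_bias = (v / v.sum(), j / j.sum())
        for vec in (*self.vj_background_freqs, *self.expanded_vj_bias):
            if abs(float(np.sum(vec)) - 1.0) > 1e-9:
                raise ValueError("probability vectors must sum to 1")


@dataclass
class SimSubject:
    """One simulated subject: samples per time point plus ground truth."""

    subject_id: str
    samples: dict[str, RepertoireSample]
    truth_expanded: dict[str, set]          # time point -> clone identities implanted
    patch_score: str | None = None
    n_expanded_true: int = 0


@dataclass
class SimStudy:
    """A simulated cohort of patients and motif-free controls."""

    subjects: list[SimSubject] = field(default_factory=list)
    seed: int = 0

    @property
    def patients(self) -> list[SimSubject]:
        return [s for s in self.subjects if s.n_expanded_true > 0 or
                s.subject_id.startswith("P")]

    @property
    def controls(self) -> list[SimSubject]:
        return [s for s in self.subjects if s.subject_id.startswith("HV")]


def _random_cdr3(rng: np.random.Generator, length: int,
                 motif: str | None = None) -> str:
    """CDR3 of the given total length: C + interior + F, optionally with a
    triplet motif implanted at a random interior position."""
    interior = rng.choice(list(AA20), size=length - 2, p=_BG_AA_PROBS)
    if motif is not None and length - 2 >= len(motif):
        start = int(rng.integers(0, length - 2 - len(motif) + 1))
        interior[start:start + len(motif)] = list(motif)
    return "C" + "".join(interior) + "F"


def _background_pool(cfg: SimConfig, rng: np.random.Generator):
    """Draw the subject's background clonotypes and their Zipf weights."""
    lo, hi = cfg.cdr3_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_clones)
    vfreq, jfreq = cfg.vj_background_freqs
    v_idx = rng.choice(cfg.n_vgenes, size=cfg.n_clones, p=vfreq)
    j_idx = rng.choice(cfg.n_jgenes, size=cfg.n_clones, p=jfreq)
    seen: set[tuple] = set()
    clones: list[tuple] = []
    for i in range(cfg.n_clones):
        while True:
            cdr3 = _random_cdr3(rng, int(lengths[i]))
            ident = (cfg.chain, f"TRBV{v_idx[i] + 1}", f"TRBJ{j_idx[i] + 1}", cdr3)
            if ident not in seen:
                seen.add(ident)
                clones.append(ident)
                break
    ranks = rng.permutation(cfg.n_clones) + 1
    weights = ranks.astype(float) ** (-cfg.abundance_exponent)
    return clones, weights / weights.sum(), seen


def _expanded_clones(cfg: SimConfig, rng: np.random.Generator,
                     n_expanded: int, taken: set) -> list[tuple]:
    lo, hi = cfg.cdr3_length_range
    vbias, jbias = cfg.expanded_vj_bias
    out: list[tuple] = []
    while len(out) < n_expanded:
        length = int(rng.integers(max(lo, 6), hi + 1))
        motif = None
        if cfg.motif_set and rng.random() < cfg.motif_prob:
            motif = cfg.motif_set[int(rng.integers(len(cfg.motif_set)))]
        cdr3 = _random_cdr3(rng, length, motif)
        v = f"TRBV{int(rng.choice(cfg.n_vgenes, p=vbias)) + 1}"
        j = f"TRBJ{int(rng.choice(cfg.n_jgenes, p=jbias)) + 1}"
        ident = (cfg.chain, v, j, cdr3)
        if ident not in taken:
            taken.add(ident)
            out.append(ident)
    return out


def simulate_subject(config: SimConfig, subject_id: str = "P01",
                     n_expanded: int | None = None,
                     time_points: Sequence[str] = PATIENT_TPS,
                     rng: np.random.Generator | None = None) -> SimSubject:
    """Simulate one subject's longitudinal samples.

    Background clonotypes are drawn once per subject; their counts at each
    time point are an independent multinomial draw of ``config.depth``
    molecules over the subject's Zipf weights (pure sampling noise, no real
    dynamics).  Implanted clones are excluded from the first time point,
    appear at the second with abundance uniform in
    ``expansion_abundance_range``, and decay as a binomial thinning with
    survival probability ``persistence`` at later time points.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n_expanded is None:
        n_expanded = config.n_expanded
    if n_expanded > config.n_clones:
        raise ValueError("n_expanded exceeds n_clones")

    bg_clones, bg_probs, taken = _background_pool(config, rng)
    exp_clones = _expanded_clones(config, rng, n_expanded, taken)

    lo_a, hi_a = config.expansion_abundance_range
    exp_counts = {tp: np.zeros(len(exp_clones), dtype=np.int64) for tp in time_points}
    if exp_clones and len(time_points) > 1:
        peak_tp = time_points[1]
        cur = rng.integers(lo_a, hi_a + 1, size=len(exp_clones))
        exp_counts[peak_tp] = cur.copy()
        for tp in time_points[2:]:
            cur = rng.binomial(cur, config.persistence)
            exp_counts[tp] = cur.copy()

    samples: dict[str, RepertoireSample] = {}
    truth: dict[str, set] = {tp: set() for tp in time_points}
    for tp in time_points:
        bg_counts = rng.multinomial(config.depth, bg_probs)
        clones = [TcrClone(*ident, abundance=int(k))
                  for ident, k in zip(bg_clones, bg_counts) if k > 0]
        for ident, k in zip(exp_clones, exp_counts[tp]):
            if k > 0:
                clones.append(TcrClone(*ident, abundance=int(k)))
                truth[tp].add(ident)
        samples[tp] = RepertoireSample.from_clones(
            clones, subject_id=subject_id, time_point=tp, chain=config.chain)
    return SimSubject(subject_id=subject_id, samples=samples,
                      truth_expanded=truth, n_expanded_true=n_expanded)


def _patch_score_from_expansion(n_expanded: int, rng: np.random.Generator,
                                scale: float) -> str:
    """Noisy monotone mapping from implanted-clone count to an ordinal
    patch-test score, so a positive rank correlation is recoverable but not
    deterministic."""
    z = n_expanded / max(scale, 1.0) + rng.normal(0, 0.25)
    if z < 0.4:
        return "-"
    if z < 0.8:
        return "+"
    if z < 1.3:
        return "++"
    return "+++"


def simulate_cohort(config: SimConfig, n_patients: int = 8,
                    n_controls: int = 4) -> SimStudy:
    """Simulate a cohort: patients at PS/PT1/PT2/PT3 with implanted
    expansions, and healthy-volunteer controls (day 0, 2 and 6 weeks) with
    none.  Each patient's implanted-clone count is drawn around
    ``config.n_expanded`` and the patch score increases (noisily) with it.
    """
    rng = np.random.default_rng(config.seed)
    study = SimStudy(seed=config.seed)
    base = config.n_expanded
    for p in range(n_patients):
        n_exp = int(rng.integers(max(base // 2, 0), max(int(base * 1.5), 1) + 1)) \
            if base > 0 else 0
        subj = simulate_subject(config, subject_id=f"P{p + 1:02d}",
                                n_expanded=n_exp, rng=rng)
        subj.patch_score = _patch_score_from_expansion(n_exp, rng, scale=base or 1)
        for s in subj.samples.values():
            s.patch_score = subj.patch_score
        study.subjects.append(subj)
    for h in range(n_controls):
        subj = simulate_subject(config, subject_id=f"HV{h + 1:02d}",
                                n_expanded=0,
                                time_points=("HV0", "HV2", "HV6"), rng=rng)
        study.subjects.append(subj)
    return study


def simulate_dbn_sets(config: SimConfig, n_per_class: int,
                      seed: int | None = None
                      ) -> tuple[list[tuple], list[tuple]]:
    """Generate balanced (antigen-like, control) sequence sets for
    classifier benchmarking.

    Returns two lists of ``(v_gene, j_gene, cdr3_aa)`` tuples.  The
    antigen-like class carries implanted triplet motifs (probability
    ``motif_prob`` per sequence) and biased V/J usage; the control class is
    drawn from the background model.  All CDR3s are at most 22 residues.
    """
    if not config.motif_set:
        raise ValueError("motif_set must be nonempty for the antigen-like class")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.cdr3_length_range
    vfreq, jfreq = config.vj_background_freqs
    vbias, jbias = config.expanded_vj_bias

    def draw(n: int, motif_prob: float, vp, jp) -> list[tuple]:
        out = []
        for _ in range(n):
            length = int(rng.integers(max(lo, 6), hi + 1))
            motif = None
            if motif_prob > 0 and rng.random() < motif_prob:
                motif = config.motif_set[int(rng.integers(len(config.motif_set)))]
            cdr3 = _random_cdr3(rng, length, motif)
            out.append((f"TRBV{int(rng.choice(config.n_vgenes, p=vp)) + 1}",
                        f"TRBJ{int(rng.choice(config.n_jgenes, p=jp)) + 1}",
                        cdr3))
        return out

    dpc_like = draw(n_per_class, config.motif_prob, vbias, jbias)
    control = draw(n_per_class, 0.0, vfreq, jfreq)
    return dpc_like, control
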