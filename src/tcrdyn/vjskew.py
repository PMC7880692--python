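"""Bootstrap rank test for V/J gene usage skew in an expanded clone set.

The observed proportion of each V (or J) gene among the unique expanded
clones is ranked within 1000 proportions computed on equal-sized sets of
unique clones drawn at random from the pre-sensitization background.  A
gene whose observed proportion falls among the 50 largest of the 1001
values is called over-represented, among the 50 smallest under-represented
(a two-sided 0.05-per-side rank criterion); everything else is not
significant.  Ties between the observed value and bootstrap values are
broken conservatively, pushing the observed value away from the extreme.

Under-represented calls on small expanded sets are statistically fragile —
a gene can land in the bottom ranks just because the expanded set is too
small to contain it — so results carry a ``low_confidence`` flag when the
expanded set cannot resolve the gene's background frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io import RepertoireSample, TcrClone, merge_samples

__all__ = ["GeneSkewResult", "gene_proportions", "bootstrap_skew",
           "skew_to_frame"]


@dataclass(frozen=True)
class GeneSkewResult:
    gene: str
    segment: str                 # "V" or "J"
    chain: str
    observed_prop: float
    rank: int                    # ascending rank of observed among the 1001
    status: str                  # "over", "under", or "ns"
    n_boot: int = 1000
    alpha_ranks: int = 50
    combined: bool = False
    low_confidence: bool = False


def _genes_of(clones: Iterable[TcrClone], segment: str) -> list[str]:
    if segment == "V":
        return [c.v_gene for c in clones]
    if segment == "J":
        return [c.j_gene for c in clones]
    raise ValueError("segment must be 'V' or 'J'")


def gene_proportions(clones, segment: str) -> dict[str, float]:
    """Proportion of each gene among unique clones; proportions sum to 1."""
    clones = list(clones)
    if not clones:
        raise ValueError("empty clone set")
    genes = _genes_of(clones, segment)
    n = len(genes)
    out: dict[str, float] = {}
    for g in genes:
        out[g] = out.get(g, 0.0) + 1.0 / n
    return out


def _draw_indices(rng: np.random.Generator, n_boot: int, n_pool: int,
                  m: int, with_replacement: bool) -> np.ndarray:
    """(n_boot, m) index matrix of bootstrap draws from the pool."""
    if with_replacement:
        return rng.integers(0, n_pool, size=(n_boot, m))
    # vectorized without-replacement sampling: take the m smallest of a row
    # of uniform keys (equivalent to a uniform m-subset)
    keys = rng.random((n_boot, n_pool))
    return np.argpartition(keys, m - 1, axis=1)[:, :m]


def bootstrap_skew(expanded, background, n_boot: int = 1000,
                   alpha_ranks: int = 50, seed: int = 0,
                   with_replacement: bool = False,
                   segments: tuple[str, ...] = ("V", "J"),
                   combined: bool = False) -> list[GeneSkewResult]:
    """Rank each gene's observed proportion in the expanded set against
    1000 equal-sized draws of unique clones from the background.

    Parameters
    ----------
    expanded:
        The expanded clone set (iterable of :class:`TcrClone`); treated as
        unique clones.
    background:
        A :class:`RepertoireSample`, or a list of them (pooled with
        :func:`merge_samples` when ``combined`` draws should come from all
        subjects' pre-sensitization repertoires).
    with_replacement:
        Default False — draws are equal-sized *sets* of distinct background
        clones; set True for a classical multinomial bootstrap.
    """
    expanded = list(expanded)
    if not expanded:
        raise ValueError("expanded set is empty")
    if isinstance(background, (list, tuple)):
        background = merge_samples(background)
        combined = True
    bg_clones = list(background)
    m = len(expanded)
    if not with_replacement and len(bg_clones) < m:
        raise ValueError(f"background pool ({len(bg_clones)} unique clones) "
                         f"smaller than expanded set ({m})")
    chain = expanded[0].chain
    rng = np.random.default_rng(seed)
    results: list[GeneSkewResult] = []
    for segment in segments:
        obs = gene_proportions(expanded, segment)
        bg_genes = _genes_of(bg_clones, segment)
        genes = sorted(set(bg_genes) | set(obs))
        code = {g: i for i, g in enumerate(genes)}
        bg_codes = np.array([code[g] for g in bg_genes], dtype=np.int64)

        idx = _draw_indices(rng, n_boot, len(bg_clones), m, with_replacement)
        drawn = bg_codes[idx]                              # (n_boot, m)
        offsets = (np.arange(n_boot)[:, None] * len(genes) + drawn).ravel()
        counts = np.bincount(offsets, minlength=n_boot * len(genes))
        boot_props = counts.reshape(n_boot, len(genes)) / m  # (n_boot, n_genes)

        for g in genes:
            o = obs.get(g, 0.0)
            col = boot_props[:, code[g]]
            n_less = int(np.sum(col < o - 1e-12))
            n_greater = int(np.sum(col > o + 1e-12))
            n_equal = n_boot - n_less - n_greater
            # conservative tie handling: observed placed last among equals
            # on whichever side is being tested
            rank_from_top = n_greater + n_equal + 1    # descending rank
            rank_from_bottom = n_less + n_equal + 1    # ascending rank
            if rank_from_top <= alpha_ranks:
                status = "over"
            elif rank_from_bottom <= alpha_ranks:
                status = "under"
            else:
                status = "ns"
            # a gene rarer than 1/m in the background cannot be resolved by
            # an expanded set of size m; under-calls there are fragile
            bg_freq = float(np.sum(bg_codes == code[g])) / len(bg_codes)
            low_conf = status == "under" and bg_freq < 1.0 / m
            results.append(GeneSkewResult(
                gene=g, segment=segment, chain=chain, observed_prop=o,
                rank=rank_from_bottom, status=status, n_boot=n_boot,
                alpha_ranks=alpha_ranks, combined=combined,
                low_confidence=low_conf))
    return results


def skew_to_frame(results: list[GeneSkewResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
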