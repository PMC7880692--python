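"""Repertoire summary statistics: Shannon diversity, Gini inequality,
abundant-clone counts, with depth-matched subsampling across a cohort."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import RepertoireSample, subsample

__all__ = ["RepertoireSummary", "shannon_index", "gini_coefficient",
           "count_abundant", "summarize_samples"]


@dataclass(frozen=True)
class RepertoireSummary:
    subject_id: str
    time_point: str
    shannon: float
    gini: float
    n_abundant: int
    n_unique: int
    depth_used: int
    threshold_freq: float = 1e-3


def shannon_index(sample: RepertoireSample, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over clone frequencies.

    Natural log by default; pass ``base`` (e.g. 2) for another unit.
    """
    x = sample.abundances()
    if x.size == 0:
        raise ValueError("empty sample")
    p = x / x.sum()
    h = float(-np.sum(p * np.log(p)))
    if base is not None:
        h /= np.log(base)
    return h


def gini_coefficient(sample: RepertoireSample) -> float:
    """Gini inequality of unique-clone abundances.

    G = sum_ij |x_i - x_j| / (2 n sum x); 0 when all clones are equally
    abundant, approaching 1 when one clone dominates.  Computed via the
    sorted-rank identity, O(n log n).
    """
    x = np.sort(sample.abundances())
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    total = x.sum()
    ranks = np.arange(1, n + 1)
    return float((2.0 * np.sum(ranks * x)) / (n * total) - (n + 1) / n)


def count_abundant(sample: RepertoireSample, threshold_freq: float = 1e-3) -> int:
    """Number of clones at frequency >= ``threshold_freq`` (inclusive) of
    the sample's total depth — the 'abundant' clones at the conventional
    1/1000 cut."""
    x = sample.abundances()
    if x.size == 0:
        raise ValueError("empty sample")
    return int(np.sum(x / x.sum() >= threshold_freq))


def summarize_samples(samples: list[RepertoireSample], depth: int | None = None,
                      seed: int = 0,
                      threshold_freq: float = 1e-3) -> pd.DataFrame:
    """Depth-match all samples (to ``depth`` or the cohort minimum) and
    tabulate the three summary statistics per sample."""
    if not samples:
        raise ValueError("no samples")
    if depth is None:
        depth = min(s.total_depth for s in samples)
    rows = []
    for i, s in enumerate(samples):
        sub = subsample(s, depth, seed + i) if s.total_depth > depth else s
        rows.append(RepertoireSummary(
            subject_id=s.subject_id, time_point=s.time_point,
            shannon=shannon_index(sub), gini=gini_coefficient(sub),
            n_abundant=count_abundant(sub, threshold_freq),
            n_unique=sub.n_unique, depth_used=depth,
            threshold_freq=threshold_freq))
    return pd.DataFrame([r.__dict__ for r in rows])
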