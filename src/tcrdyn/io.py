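"""Clone tables: reading, validation, writing, and depth-matched subsampling.

A repertoire sample is a multiset of T-cell receptor clones.  A clone is
identified by the tuple ``(chain, v_gene, j_gene, cdr3_aa)`` — the
amino-acid level clonotype that every downstream analysis (expansion
detection, clustering, classification) operates on — and carries a
UMI-derived molecule count (``abundance``).

Tables are plain TSV with a header.  Canonical column names are
``v_gene``, ``j_gene``, ``cdr3_aa``, ``abundance``; common aliases
(AIRR-style ``v_call``/``junction_aa``/``duplicate_count``, Decombinator
``vgene``/``cdr3``/``count`` …) are accepted, and an explicit mapping can
be supplied for anything else.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TcrClone",
    "RepertoireSample",
    "CloneTableError",
    "read_clone_table",
    "write_clone_table",
    "subsample",
    "merge_samples",
]

#: Time points used in the sensitization study design: pre-sensitization
#: (PS, week 0), post-sensitization at ~2, ~6 and ~24 weeks (PT1-PT3), and
#: healthy-volunteer visits at day 0, 2 weeks and 6 weeks (HV0, HV2, HV6).
TIME_POINTS = ("PS", "PT1", "PT2", "PT3", "HV0", "HV2", "HV6")

#: Ordinal patch-test scores: no reaction, weak, strong, extreme.
PATCH_SCORES = ("-", "+", "++", "+++")

CDR3_PATTERN = re.compile(r"^C[A-Z]+[FW]$")

CANONICAL_COLUMNS = ("v_gene", "j_gene", "cdr3_aa", "abundance")

#: Default header aliases, lower-cased.  First match wins.
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "v_gene": ("v_gene", "v", "vgene", "v_call", "v gene"),
    "j_gene": ("j_gene", "j", "jgene", "j_call", "j gene"),
    "cdr3_aa": ("cdr3_aa", "cdr3", "junction_aa", "cdr3aa", "aaseq"),
    "abundance": ("abundance", "count", "counts", "duplicate_count",
                  "umi_count", "frequency_count", "n"),
}


class CloneTableError(ValueError):
    """Malformed clone table (missing columns, empty, bad values)."""


@dataclass(frozen=True, order=True)
class TcrClone:
    """One unique clonotype; identity excludes abundance.

    Equality and hashing use ``(chain, v_gene, j_gene, cdr3_aa)`` only, so
    the same clone observed at two depths compares equal.
    """

    chain: str
    v_gene: str
    j_gene: str
    cdr3_aa: str
    abundance: int = field(default=1, compare=False)

    def __post_init__(self) -> None:
        if self.chain not in ("alpha", "beta"):
            raise ValueError(f"chain must be 'alpha' or 'beta', got {self.chain!r}")
        if self.abundance < 1:
            raise ValueError(f"abundance must be >= 1, got {self.abundance}")

    @property
    def identity(self) -> tuple[str, str, str, str]:
        return (self.chain, self.v_gene, self.j_gene, self.cdr3_aa)

    def cdr3_is_canonical(self) -> bool:
        """True if the CDR3 runs from the conserved Cys to a terminal F/W."""
        return bool(CDR3_PATTERN.match(self.cdr3_aa))


@dataclass
class RepertoireSample:
    """A clone table plus subject/time-point metadata.

    ``clones`` maps clone identity to :class:`TcrClone`; duplicates are
    merged by summing abundance at construction time.
    """

    subject_id: str
    time_point: str
    clones: dict[tuple, TcrClone]
    chain: str = "beta"
    patch_score: str | None = None
    sensitization_score: float | None = None

    @classmethod
    def from_clones(cls, clones: Iterable[TcrClone], subject_id: str = "NA",
                    time_point: str = "PS", **meta) -> "RepertoireSample":
        merged: dict[tuple, TcrClone] = {}
        n_dup = 0
        for c in clones:
            key = c.identity
            if key in merged:
                prev = merged[key]
                merged[key] = replace(prev, abundance=prev.abundance + c.abundance)
                n_dup += 1
            else:
                merged[key] = c
        if n_dup:
            logger.warning("merged %d duplicate clone rows by summing abundance", n_dup)
        return cls(subject_id=subject_id, time_point=time_point, clones=merged, **meta)

    def __post_init__(self) -> None:
        if self.time_point not in TIME_POINTS:
            raise ValueError(f"unknown time point {self.time_point!r}")
        if self.patch_score is not None and self.patch_score not in PATCH_SCORES:
            raise ValueError(f"unknown patch score {self.patch_score!r}")

    def __len__(self) -> int:
        return len(self.clones)

    def __iter__(self):
        return iter(self.clones.values())

    def __contains__(self, clone: TcrClone) -> bool:
        return clone.identity in self.clones

    @property
    def total_depth(self) -> int:
        """Total number of sequenced molecules (sum of UMI counts)."""
        return sum(c.abundance for c in self.clones.values())

    @property
    def n_unique(self) -> int:
        return len(self.clones)

    def abundance_of(self, clone: TcrClone) -> int:
        c = self.clones.get(clone.identity)
        return 0 if c is None else c.abundance

    def abundances(self) -> np.ndarray:
        """Clone abundances in the sample's deterministic sort order."""
        return np.array([c.abundance for c in self.sorted_clones()], dtype=np.int64)

    def sorted_clones(self) -> list[TcrClone]:
        """Descending abundance, then lexicographic (cdr3, v, j)."""
        return sorted(self.clones.values(),
                      key=lambda c: (-c.abundance, c.cdr3_aa, c.v_gene, c.j_gene))

    def to_frame(self) -> pd.DataFrame:
        rows = [(c.v_gene, c.j_gene, c.cdr3_aa, c.abundance)
                for c in self.sorted_clones()]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def _resolve_columns(columns: Sequence[str],
                     column_map: Mapping[str, str] | None) -> dict[str, str]:
    """Map canonical names to actual header names; raise if any is missing."""
    lower = {c.lower(): c for c in columns}
    resolved: dict[str, str] = {}
    for canon in CANONICAL_COLUMNS:
        if column_map and canon in column_map:
            if column_map[canon] not in columns:
                raise CloneTableError(
                    f"mapped column {column_map[canon]!r} for {canon!r} not in header")
            resolved[canon] = column_map[canon]
            continue
        for alias in DEFAULT_ALIASES[canon]:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
        else:
            raise CloneTableError(
                f"no column for {canon!r} in header {list(columns)}")
    return resolved


def read_clone_table(path: str | Path, chain: str = "beta",
                     subject_id: str = "NA", time_point: str = "PS",
                     patch_score: str | None = None,
                     sensitization_score: float | None = None,
                     column_map: Mapping[str, str] | None = None,
                     validate_cdr3: str = "warn") -> RepertoireSample:
    """Read a TSV clone table into a validated :class:`RepertoireSample`.

    Parameters
    ----------
    validate_cdr3:
        ``"warn"`` (default) logs non-canonical CDR3s (not matching
        ``^C[A-Z]+[FW]$``) and keeps them; ``"strict"`` excludes them,
        counting exclusions in a logged report; ``"off"`` skips the check.

    Rows with non-positive abundance are always rejected; duplicate clone
    identities are merged by summing abundance with a logged warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise CloneTableError(f"{path}: empty file") from None
    if df.empty:
        raise CloneTableError(f"{path}: table has no rows")
    cols = _resolve_columns(df.columns, column_map)

    clones: list[TcrClone] = []
    n_bad_abund = n_bad_cdr3 = 0
    for _, row in df.iterrows():
        try:
            abund = int(row[cols["abundance"]])
        except (TypeError, ValueError):
            n_bad_abund += 1
            continue
        if abund < 1:
            n_bad_abund += 1
            continue
        cdr3 = str(row[cols["cdr3_aa"]]).strip().upper()
        if validate_cdr3 != "off" and not CDR3_PATTERN.match(cdr3):
            if validate_cdr3 == "strict":
                n_bad_cdr3 += 1
                continue
            logger.warning("%s: non-canonical CDR3 %r kept", path.name, cdr3)
        clones.append(TcrClone(chain=chain, v_gene=str(row[cols["v_gene"]]).strip(),
                               j_gene=str(row[cols["j_gene"]]).strip(),
                               cdr3_aa=cdr3, abundance=abund))
    if n_bad_abund or n_bad_cdr3:
        logger.warning("%s: excluded %d rows with non-positive abundance, "
                       "%d with malformed CDR3", path.name, n_bad_abund, n_bad_cdr3)
    if not clones:
        raise CloneTableError(f"{path}: no valid clone rows")
    return RepertoireSample.from_clones(
        clones, subject_id=subject_id, time_point=time_point, chain=chain,
        patch_score=patch_score, sensitization_score=sensitization_score)


def write_clone_table(sample: RepertoireSample, path: str | Path) -> None:
    """Write a TSV with stable column order and deterministic row order
    (descending abundance, lexicographic CDR3/V/J tiebreak)."""
    sample.to_frame().to_csv(Path(path), sep="\t", index=False)


def subsample(sample: RepertoireSample, depth: int, seed: int) -> RepertoireSample:
    """Draw exactly ``depth`` molecules uniformly without replacement.

    Sampling is at the molecule (UMI) level — a multivariate hypergeometric
    draw over clone counts — which models re-sequencing a finite library at
    lower depth.  Deterministic given ``seed``; clones drawn zero times are
    dropped.
    """
    total = sample.total_depth
    if depth > total:
        raise ValueError(f"requested depth {depth} exceeds sample depth {total}; "
                         "use the cohort minimum depth")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    order = sample.sorted_clones()
    counts = np.array([c.abundance for c in order], dtype=np.int64)
    rng = np.random.default_rng(seed)
    new_counts = rng.multivariate_hypergeometric(counts, depth)
    kept = [replace(c, abundance=int(k))
            for c, k in zip(order, new_counts) if k > 0]
    return RepertoireSample(subject_id=sample.subject_id,
                            time_point=sample.time_point,
                            clones={c.identity: c for c in kept},
                            chain=sample.chain,
                            patch_score=sample.patch_score,
                            sensitization_score=sample.sensitization_score)


def merge_samples(samples: Iterable[RepertoireSample], subject_id: str = "combined",
                  time_point: str = "PS") -> RepertoireSample:
    """Pool clone tables, merging shared identities by summing abundance."""
    samples = list(samples)
    if not samples:
        raise ValueError("no samples to merge")
    chain = samples[0].chain
    all_clones = [c for s in samples for c in s]
    return RepertoireSample.from_clones(all_clones, subject_id=subject_id,
                                        time_point=time_point, chain=chain)
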