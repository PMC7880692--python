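"""End-to-end study orchestration: simulate or ingest a cohort, then run
summaries, expansion detection, V/J skew, CDR3 clustering, and classifier
cross-validation, writing per-stage TSVs plus a checksummed manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, dbn, diversity, expansion, simulate, vjskew
from .io import write_clone_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """One flat config for a whole study run.

    Defaults match the analysis conventions throughout the package:
    expansion threshold 8 (with the 4/16/32 sensitivity ladder available),
    kernel cutoff 0.75, 1000 bootstrap draws, 10-fold x 10-repeat CV with
    at most 10 EM iterations.
    """

    mode: str = "simulate"                 # "simulate" | "tables"
    out_dir: str = "study_out"
    seed: int = 0
    # simulate mode
    n_patients: int = 4
    n_controls: int = 2
    sim: dict = field(default_factory=dict)     # SimConfig overrides
    # tables mode
    dpc_table: str | None = None
    ctrl_table: str | None = None
    # analysis parameters
    expansion_threshold: int = 8
    depth: int | None = None               # None -> cohort minimum
    cluster_threshold: float = 0.75
    n_boot: int = 1000
    cv_folds: int = 10
    cv_repeats: int = 10
    em_max_iters: int = 10
    stages: tuple[str, ...] = ("summary", "expansion", "vjskew",
                               "cluster", "dbn")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages; returns the output directory.

    Every output file lands under ``out_dir`` with the config echoed back
    (``config.yaml``) and a ``manifest.json`` listing per-stage outputs,
    checksums, seeds and wall times.  A stage failure is recorded in the
    manifest before the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}

    def record(stage: str, files: list[Path], t0: float, ok: bool = True):
        manifest["stages"][stage] = {
            "ok": ok, "wall_s": round(time.time() - t0, 3),
            "outputs": [str(f.relative_to(out)) for f in files]}
        for f in files:
            manifest["files"][str(f.relative_to(out))] = _sha256(f)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    study = None
    dpc_seqs = ctrl_seqs = None
    if config.mode == "simulate":
        t0 = time.time()
        sim_cfg = simulate.SimConfig(seed=config.seed, **config.sim)
        study = simulate.simulate_cohort(sim_cfg, config.n_patients,
                                         config.n_controls)
        files = []
        for subj in study.subjects:
            for tp, sample in subj.samples.items():
                p = out / "tables" / f"{subj.subject_id}_{tp}.tsv"
                p.parent.mkdir(exist_ok=True)
                write_clone_table(sample, p)
                files.append(p)
        truth_rows = [(s.subject_id, tp, v, j, cdr3)
                      for s in study.subjects
                      for tp, idents in s.truth_expanded.items()
                      for (_c, v, j, cdr3) in sorted(idents)]
        p = out / "tables" / "ground_truth.tsv"
        pd.DataFrame(truth_rows, columns=["subject_id", "time_point", "v_gene",
                                          "j_gene", "cdr3_aa"]).to_csv(
            p, sep="\t", index=False)
        files.append(p)
        meta = pd.DataFrame(
            [(s.subject_id, s.patch_score or "", s.n_expanded_true)
             for s in study.subjects],
            columns=["subject_id", "patch_score", "n_true_expanded"])
        p = out / "tables" / "metadata.tsv"
        meta.to_csv(p, sep="\t", index=False)
        files.append(p)
        record("simulate", files, t0)
    elif config.mode == "tables":
        if "dbn" in config.stages or "cluster" in config.stages:
            if not (config.dpc_table and config.ctrl_table):
                raise ValueError("tables mode needs dpc_table and ctrl_table")
            dpc_seqs = _read_seq_table(config.dpc_table)
            ctrl_seqs = _read_seq_table(config.ctrl_table)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    patients = study.patients if study else []
    all_samples = [s.samples[tp] for s in (study.subjects if study else [])
                   for tp in s.samples]
    depth = config.depth
    if depth is None and all_samples:
        depth = min(s.total_depth for s in all_samples)

    expanded_by_subject: dict[str, list] = {}
    if study and "summary" in config.stages:
        t0 = time.time()
        df = diversity.summarize_samples(all_samples, depth=depth,
                                         seed=config.seed)
        p = out / "summary.tsv"
        df.to_csv(p, sep="\t", index=False)
        record("summary", [p], t0)

    if study and "expansion" in config.stages:
        t0 = time.time()
        rows, files = [], []
        for subj in patients:
            tps = list(subj.samples)
            ref = subj.samples[tps[0]]
            tgt = subj.samples[tps[1]]
            res = expansion.detect_expanded(ref, tgt,
                                            threshold=config.expansion_threshold,
                                            depth=depth, seed=config.seed)
            expanded_by_subject[subj.subject_id] = [
                k for k in res.expanded]
            rows.append((subj.subject_id, res.reference_tp, res.target_tp,
                         res.threshold, len(res.expanded), res.pct_expanded,
                         len(res.reverse_expanded), res.reverse_pct,
                         subj.patch_score or ""))
            p = out / "expansion" / f"{subj.subject_id}.tsv"
            p.parent.mkdir(exist_ok=True)
            res.to_frame().to_csv(p, sep="\t", index=False)
            files.append(p)
        p = out / "expansion_summary.tsv"
        pd.DataFrame(rows, columns=["subject_id", "ref", "tgt", "threshold",
                                    "n_expanded", "pct_expanded", "n_reverse",
                                    "reverse_pct", "patch_score"]).to_csv(
            p, sep="\t", index=False)
        files.append(p)
        record("expansion", files, t0)

    if study and "vjskew" in config.stages and expanded_by_subject:
        t0 = time.time()
        from .io import TcrClone, merge_samples
        combined = [TcrClone(*ident)
                    for idents in expanded_by_subject.values()
                    for ident in idents]
        combined = list({c.identity: c for c in combined}.values())
        if combined:
            bg = merge_samples([s.samples[list(s.samples)[0]] for s in patients])
            res = vjskew.bootstrap_skew(combined, bg, n_boot=config.n_boot,
                                        seed=config.seed, combined=True)
            p = out / "vjskew.tsv"
            vjskew.skew_to_frame(res).to_csv(p, sep="\t", index=False)
            record("vjskew", [p], t0)

    if "cluster" in config.stages:
        t0 = time.time()
        if study:
            cdr3s = {ident[3] for idents in expanded_by_subject.values()
                     for ident in idents}
        else:
            cdr3s = {c for (_v, _j, c) in dpc_seqs}
        if len(cdr3s) >= 2:
            sg = clustering.build_graph(cdr3s, threshold=config.cluster_threshold)
            st = clustering.cluster_stats(sg)
            files = []
            p = out / "cluster_stats.tsv"
            pd.DataFrame([{
                "n_nodes": st.n_nodes, "n_clusters": st.n_clusters,
                "pct_in_clusters": st.pct_in_clusters,
                "largest_cluster_size": len(st.largest_cluster),
            }]).to_csv(p, sep="\t", index=False)
            files.append(p)
            p = out / "cluster_members.tsv"
            pd.DataFrame(
                [(i, m) for i, cl in enumerate(sg.clusters) for m in sorted(cl)],
                columns=["cluster", "cdr3_aa"]).to_csv(p, sep="\t", index=False)
            files.append(p)
            if st.largest_cluster:
                p = out / "largest_cluster_pfm.tsv"
                clustering.cluster_pfm(st.largest_cluster).to_csv(p, sep="\t")
                files.append(p)
            record("cluster", files, t0)

    if "dbn" in config.stages:
        t0 = time.time()
        if dpc_seqs is None:
            sim_cfg = simulate.SimConfig(seed=config.seed, **config.sim)
            dpc_seqs, ctrl_seqs = simulate.simulate_dbn_sets(
                sim_cfg, n_per_class=200, seed=config.seed + 1)
        report = dbn.cross_validate(dpc_seqs, ctrl_seqs,
                                    n_folds=config.cv_folds,
                                    n_repeats=config.cv_repeats,
                                    em_max_iters=config.em_max_iters,
                                    seed=config.seed)
        p1 = out / "dbn_cv.tsv"
        report.to_csv(p1, sep="\t", index=False)
        p2 = out / "dbn_cv_summary.tsv"
        dbn.cv_summary(report).to_csv(p2, sep="\t", index=False)
        record("dbn", [p1, p2], t0)

    return out


def _read_seq_table(path) -> list[tuple]:
    """Read a (v_gene, j_gene, cdr3_aa) sequence table (the classifier
    benchmark schema), tolerating common column aliases."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}

    def pick(*names):
        for n in names:
            if n in cols:
                return cols[n]
        raise ValueError(f"no column among {names} in {path}")

    v = pick("v_gene", "v", "vgene", "v_call")
    j = pick("j_gene", "j", "jgene", "j_call")
    c = pick("cdr3_aa", "cdr3", "junction_aa", "cdr3aa")
    return list(df[[v, j, c]].itertuples(index=False, name=None))
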