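import numpy as np
import pytest

from tcrdyn.diversity import gini_coefficient
from tcrdyn.expansion import detect_expanded, score_correlation
from tcrdyn.simulate import (SimConfig, simulate_cohort, simulate_dbn_sets,
                             simulate_subject)

# scaled-down study conditions so a subject simulates in well under a second
SMALL = dict(n_clones=2000, depth=4000, n_vgenes=10, n_jgenes=5)


class TestConfig:
    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_clones=10, n_expanded=11)

    def test_bad_motif_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(motif_set=("ASSL",))

    def test_default_probability_vectors_normalized(self):
        cfg = SimConfig()
        for vec in (*cfg.vj_background_freqs, *cfg.expanded_vj_bias):
            assert np.sum(vec) == pytest.approx(1.0, abs=1e-9)


class TestSimulateSubject:
    def test_no_expansions_means_empty_truth(self):
        cfg = SimConfig(seed=1, n_expanded=0, **SMALL)
        subj = simulate_subject(cfg)
        assert all(not s for s in subj.truth_expanded.values())

    def test_truth_clones_absent_at_baseline_and_above_minimum(self):
        cfg = SimConfig(seed=2, n_expanded=30,
                        expansion_abundance_range=(8, 50), **SMALL)
        subj = simulate_subject(cfg)
        ps = subj.samples["PS"]
        pt1 = subj.samples["PT1"]
        assert subj.truth_expanded["PT1"]
        for ident in subj.truth_expanded["PT1"]:
            assert ident not in ps.clones
            assert pt1.clones[ident].abundance >= 8

    def test_forced_motif_in_every_expanded_cdr3(self):
        cfg = SimConfig(seed=3, n_expanded=25, motif_prob=1.0,
                        motif_set=("ASS",), **SMALL)
        subj = simulate_subject(cfg)
        for (_c, _v, _j, cdr3) in subj.truth_expanded["PT1"]:
            assert "ASS" in cdr3

    def test_gini_in_unit_interval_and_seed_stable(self):
        vals = [gini_coefficient(
            simulate_subject(SimConfig(seed=s, n_expanded=0,
                                       abundance_exponent=2.0,
                                       **SMALL)).samples["PS"])
            for s in range(5)]
        assert all(0.0 < g < 1.0 for g in vals)
        assert np.std(vals) < 0.05  # stable across seeds

    def test_reproducible_given_seed(self):
        cfg = SimConfig(seed=9, n_expanded=10, **SMALL)
        a = simulate_subject(cfg)
        b = simulate_subject(cfg)
        for tp in a.samples:
            assert {c.identity: c.abundance for c in a.samples[tp]} == \
                {c.identity: c.abundance for c in b.samples[tp]}

    def test_persistence_zero_clears_late_time_points(self):
        cfg = SimConfig(seed=4, n_expanded=20, persistence=0.0, **SMALL)
        subj = simulate_subject(cfg)
        assert not subj.truth_expanded["PT2"]
        assert not subj.truth_expanded["PT3"]

    def test_vj_marginals_match_background_freqs(self):
        """Marginal V frequencies of a large background sample stay within
        3-sigma multinomial error of the configured frequencies."""
        cfg = SimConfig(seed=6, n_expanded=0, n_clones=6000, depth=6000,
                        n_vgenes=8, n_jgenes=4)
        subj = simulate_subject(cfg)
        clones = list(subj.samples["PS"])
        n = len(clones)
        vfreq = cfg.vj_background_freqs[0]
        for k in range(cfg.n_vgenes):
            obs = sum(1 for c in clones if c.v_gene == f"TRBV{k + 1}") / n
            se = np.sqrt(vfreq[k] * (1 - vfreq[k]) / n)
            assert abs(obs - vfreq[k]) < 4 * se + 1e-3, k


class TestNullCalibration:
    def test_zero_to_eight_transitions_rare_without_implants(self):
        """With no implanted clones, the per-clone rate of spurious
        0 -> >=8 transitions between equal-depth draws stays consistent
        with the Poisson sampling bound (rate < 1e-3)."""
        n_hits = n_clones_tested = 0
        for seed in range(6):
            cfg = SimConfig(seed=seed, n_expanded=0, **SMALL)
            subj = simulate_subject(cfg)
            res = detect_expanded(subj.samples["PS"], subj.samples["PT1"],
                                  threshold=8, seed=seed)
            n_hits += len(res.expanded)
            n_clones_tested += cfg.n_clones   # every clone is one trial
        assert n_hits / n_clones_tested < 1e-3


class TestSimulateCohort:
    def test_controls_have_no_implants(self):
        cfg = SimConfig(seed=7, n_expanded=20, **SMALL)
        study = simulate_cohort(cfg, n_patients=0, n_controls=3)
        assert len(study.controls) == 3
        for s in study.controls:
            assert all(not t for t in s.truth_expanded.values())
            assert set(s.samples) == {"HV0", "HV2", "HV6"}

    def test_patch_score_correlates_with_implant_count(self):
        from tcrdyn.expansion import PATCH_SCORE_CODES
        cfg = SimConfig(seed=8, n_expanded=60, n_clones=800, depth=1500,
                        n_vgenes=8, n_jgenes=4)
        study = simulate_cohort(cfg, n_patients=22, n_controls=0)
        x = [s.n_expanded_true for s in study.patients]
        y = [PATCH_SCORE_CODES[s.patch_score] for s in study.patients]
        rho, _ = score_correlation(x, y)
        assert rho > 0

    def test_detector_recovers_implanted_clones(self):
        """Expansion detection at threshold 8 recovers >= 90% of clones
        implanted with abundance >= 16 across a small cohort."""
        cfg = SimConfig(seed=12, n_expanded=15,
                        expansion_abundance_range=(16, 120), **SMALL)
        study = simulate_cohort(cfg, n_patients=5, n_controls=0)
        found = total = 0
        for subj in study.patients:
            res = detect_expanded(subj.samples["PS"], subj.samples["PT1"],
                                  threshold=8, seed=0)
            truth = subj.truth_expanded["PT1"]
            total += len(truth)
            found += len(truth & set(res.expanded))
        assert total > 0
        assert found / total >= 0.90


class TestSimulateDbnSets:
    def test_length_cap_respected(self):
        cfg = SimConfig(seed=10, cdr3_length_range=(8, 22), **SMALL)
        dpc, ctrl = simulate_dbn_sets(cfg, 100)
        assert all(len(c) <= 22 for (_v, _j, c) in dpc + ctrl)
        assert len(dpc) == len(ctrl) == 100

    def test_forced_motifs_present(self):
        cfg = SimConfig(seed=11, motif_prob=1.0, motif_set=("QQQ",), **SMALL)
        dpc, _ = simulate_dbn_sets(cfg, 50)
        assert all("QQQ" in c for (_v, _j, c) in dpc)

    def test_empty_motif_set_rejected(self):
        cfg = SimConfig(seed=1, **SMALL)
        cfg.motif_set = ()
        with pytest.raises(ValueError):
            simulate_dbn_sets(cfg, 10)
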