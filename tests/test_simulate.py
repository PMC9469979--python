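"""Synthetic study generator: determinism, planted structure, NB moments."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from sarcoseq import (
    MarkerConfig,
    SimulationConfig,
    simulate_counts,
    simulate_reference_panels,
)
from sarcoseq.simulate import ConfigurationError, _nb_draw


class TestConfigValidation:
    def test_too_many_planted_genes(self):
        with pytest.raises(ConfigurationError, match="exceeds"):
            SimulationConfig(n_genes=100, n_degs_per_group=40,
                             group_sizes=(3, 3, 3))

    def test_bad_range(self):
        with pytest.raises(ConfigurationError, match="low <= high"):
            SimulationConfig(baseline_mean_log_range=(9.0, 3.0))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dispersion": 0.0},
            {"group_sizes": (1, 1)},
            {"library_size_range": (0.0, 1.0)},
            {"n_mislabeled": 99},
        ],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)


class TestSimulateCounts:
    def test_deterministic_under_seed(self, small_config):
        cm1, t1 = simulate_counts(small_config)
        cm2, t2 = simulate_counts(small_config)
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)
        pd.testing.assert_frame_equal(cm1.metadata, cm2.metadata)
        assert t1.planted_deg_ids == t2.planted_deg_ids

    def test_seed_changes_output(self, small_config):
        import dataclasses

        cm1, _ = simulate_counts(small_config)
        cm2, _ = simulate_counts(
            dataclasses.replace(small_config, seed=small_config.seed + 1)
        )
        assert not cm1.counts.equals(cm2.counts)

    def test_null_configuration_has_no_group_structure(self):
        cfg = SimulationConfig(
            n_genes=500, group_sizes=(8, 8, 8), n_degs_per_group=0,
            deg_log2fc=0.0, marker_config=MarkerConfig(0, 0), seed=5,
        )
        cm, truth = simulate_counts(cfg)
        assert all(not v for v in truth.planted_deg_ids.values())
        sf = cm.counts.sum(axis=0)
        norm = cm.counts / (sf / sf.mean())
        means = {
            st: norm.loc[:, (cm.subtypes == st).to_numpy()].mean(axis=1)
            for st in ("FS", "PNST", "PWT")
        }
        ratios = np.log2((means["FS"] + 1) / (means["PNST"] + 1))
        # group-mean log2 ratios concentrate near 0
        assert abs(float(np.median(ratios))) < 0.1
        assert float(np.mean(np.abs(ratios) > 1.0)) < 0.01

    def test_planted_genes_disjoint_across_subtypes(self, small_study):
        _, truth = small_study
        sets = [set(v) for v in truth.planted_deg_ids.values()]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not sets[i] & sets[j]

    def test_markers_are_planted_degs_of_their_subtype(self, small_study):
        _, truth = small_study
        for st, mk in truth.planted_marker_ids.items():
            planted = set(truth.planted_deg_ids[st])
            assert set(mk["single"]) <= planted
            for a, b in mk["pairs"]:
                assert {a, b} <= planted

    def test_mislabeled_samples_carry_wrong_label(self):
        cfg = SimulationConfig(seed=2, n_mislabeled=2,
                               marker_config=MarkerConfig(0, 0))
        cm, truth = simulate_counts(cfg)
        assert len(truth.mislabeled_sample_ids) == 2
        assert set(truth.mislabeled_sample_ids) <= set(cm.sample_ids)
        for s in truth.mislabeled_sample_ids:
            assert cm.subtypes[s] != truth.true_labels[s]
        others = set(cm.sample_ids) - set(truth.mislabeled_sample_ids)
        for s in others:
            assert cm.subtypes[s] == truth.true_labels[s]

    def test_planted_deg_counts_match_nb_moments(self):
        """Pooled standardized residuals of planted-DEG counts match the
        NB mean/variance law (method-of-moments check)."""
        cfg = SimulationConfig(
            n_genes=2000, group_sizes=(6, 5, 5), n_degs_per_group=100,
            deg_log2fc=2.0, marker_config=MarkerConfig(0, 0), seed=1,
        )
        cm, truth = simulate_counts(cfg)
        # reconstruct per-cell means from the recorded generator state
        lib = np.exp(
            np.random.default_rng([cfg.seed, 4]).uniform(
                np.log(cfg.library_size_range[0]),
                np.log(cfg.library_size_range[1]),
                size=sum(cfg.group_sizes),
            )
        )
        true_idx = cm.sample_ids.map(
            lambda s: list(cfg.subtypes).index(truth.true_labels[s])
        ).to_numpy()
        eff = truth.effects_log2.to_numpy()[:, true_idx]
        mu = (
            np.exp2(truth.baseline_log2_mean.to_numpy())[:, None]
            * np.exp2(eff) * lib[None, :]
        )
        planted = sorted(set().union(*truth.planted_deg_ids.values()))
        rows = cm.gene_ids.get_indexer(planted)
        k = cm.counts.to_numpy()[rows].astype(float)
        m = mu[rows]
        z = (k - m) / np.sqrt(m + cfg.dispersion * m**2)
        assert abs(z.mean()) < 0.05
        assert abs((z**2).mean() - 1.0) < 0.1

    def test_nb_draw_moments_at_scale(self):
        rng = np.random.default_rng(9)
        mu, alpha = 120.0, 0.1
        x = _nb_draw(rng, np.full(10_000, mu), np.full(10_000, alpha))
        assert x.mean() == pytest.approx(mu, rel=0.02)
        assert x.var() == pytest.approx(mu + alpha * mu**2, rel=0.06)


class TestReferencePanels:
    def test_correct_panel_shares_baseline(self, small_config, small_study):
        cm, truth = small_study
        refs = simulate_reference_panels(small_config, truth)
        base_log = truth.baseline_log2_mean.to_numpy()
        obs = np.log2(
            refs.normal_panels[refs.correct_panel].counts.mean(axis=1) + 0.5
        )
        assert np.corrcoef(base_log, obs)[0, 1] > 0.98
        # up to a global library-size scale, panel means track the baseline
        resid = obs - base_log
        assert (resid - np.median(resid)).std() < 0.5
        # a gene-permuted decoy panel does not
        decoy = np.log2(
            refs.normal_panels["normal_decoy_1"].counts.mean(axis=1) + 0.5
        )
        assert np.corrcoef(base_log, decoy)[0, 1] < 0.3

    def test_matched_human_column_correlates(self, small_config, small_study):
        _, truth = small_study
        refs = simulate_reference_panels(small_config, truth)
        for st, hcol in refs.matched_human.items():
            degs = sorted(truth.planted_deg_ids[st])
            profile = (
                truth.baseline_log2_mean.loc[degs]
                + truth.effects_log2.loc[degs, st]
            )
            cors = {
                c: np.corrcoef(profile, refs.human_panel.loc[degs, c])[0, 1]
                for c in refs.human_panel.columns
            }
            assert max(cors, key=cors.get) == hcol

    def test_sarcoma_set_enriched_in_planted_up_degs(
        self, small_config, small_study
    ):
        """The phenotype set is maximally enriched for planted up-DEGs by
        exact hypergeometric evaluation."""
        _, truth = small_study
        refs = simulate_reference_panels(small_config, truth)
        universe = set(truth.baseline_log2_mean.index)
        up = set().union(*(truth.up_degs(st) for st in truth.planted_deg_ids))
        s = refs.sarcoma_set
        k = len(s & up)
        p = hypergeom.sf(k - 1, len(universe), len(s), len(up))
        assert p < 1e-10

    def test_deterministic(self, small_config, small_study):
        _, truth = small_study
        r1 = simulate_reference_panels(small_config, truth)
        r2 = simulate_reference_panels(small_config, truth)
        pd.testing.assert_frame_equal(r1.human_panel, r2.human_panel)
        for name in r1.normal_panels:
            pd.testing.assert_frame_equal(
                r1.normal_panels[name].counts, r2.normal_panels[name].counts
            )

    def test_null_config_gives_exchangeable_human_columns(self):
        cfg = SimulationConfig(
            n_genes=500, group_sizes=(5, 5, 5), n_degs_per_group=0,
            deg_log2fc=0.0, marker_config=MarkerConfig(0, 0), seed=3,
        )
        cm, truth = simulate_counts(cfg)
        refs = simulate_reference_panels(cfg, truth)
        # with no planted effects every matched column is just noisy
        # baseline; correlations with the baseline are statistically
        # indistinguishable across columns
        base = truth.baseline_log2_mean
        cors = np.array([
            np.corrcoef(base, refs.human_panel[c])[0, 1]
            for c in refs.human_panel.columns[:3]
        ])
        assert cors.max() - cors.min() < 0.05
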