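"""NB Wald differential expression: null behavior, symmetry, BH, recovery."""

import numpy as np
import pandas as pd
import pytest

from sarcoseq import (
    MarkerConfig,
    SimulationConfig,
    common_and_specific,
    nb_wald_test,
    one_vs_rest_degs,
    simulate_counts,
    tumor_vs_normal_degs,
)
from sarcoseq.de import DesignError
from sarcoseq.readwrite import CountMatrix

from conftest import make_cm


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Brute-force Benjamini-Hochberg step-up."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBH:
    def test_worked_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.9])
        np.testing.assert_allclose(bh_oracle(p), [0.04, 0.04, 0.04, 0.9])
        from statsmodels.stats.multitest import multipletests

        np.testing.assert_allclose(
            multipletests(p, method="fdr_bh")[1], [0.04, 0.04, 0.04, 0.9]
        )

    def test_adjustment_matches_oracle_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 60))
            np.testing.assert_allclose(
                multipletests(p, method="fdr_bh")[1], bh_oracle(p),
                rtol=1e-12,
            )

    def test_padj_monotone_and_at_least_p(self, small_study):
        cm, _ = small_study
        tab = one_vs_rest_degs(cm)["FS"]
        tested = tab[tab["base_mean"] >= 1.0].sort_values("p")
        assert (tested["padj"].to_numpy() >= tested["p"].to_numpy() - 1e-15).all()
        assert (np.diff(tested["padj"].to_numpy()) >= -1e-15).all()


class TestNBWald:
    def test_identical_groups_yield_nothing(self):
        rng = np.random.default_rng(0)
        block = rng.negative_binomial(10, 0.2, size=(100, 3))
        cm = make_cm(np.hstack([block, block]), ["A"] * 3 + ["B"] * 3)
        tab = nb_wald_test(cm, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert np.allclose(tab["log2fc"], 0.0)
        assert not tab["is_deg"].any()
        assert np.allclose(tab["p"], 1.0)

    def test_label_swap_negates_lfc_preserves_p(self, small_study):
        cm, _ = small_study
        labels = cm.subtypes
        a = list(labels.index[labels == "FS"])
        b = list(labels.index[labels != "FS"])
        t1 = nb_wald_test(cm, a, b)
        t2 = nb_wald_test(cm, b, a)
        np.testing.assert_allclose(t1["log2fc"], -t2["log2fc"], rtol=1e-12)
        np.testing.assert_allclose(t1["p"], t2["p"], rtol=1e-12)

    def test_direction_is_sign_of_lfc(self, small_study):
        cm, _ = small_study
        tab = one_vs_rest_degs(cm)["PWT"]
        up = tab["direction"] == "up"
        assert (tab.loc[up, "log2fc"] >= 0).all()
        assert (tab.loc[~up, "log2fc"] < 0).all()

    def test_deg_definition(self, small_study):
        cm, _ = small_study
        tab = one_vs_rest_degs(cm)["FS"]
        expect = (tab["padj"] < 0.05) & (tab["log2fc"].abs() > 1.0)
        assert (tab["is_deg"] == expect).all()

    def test_small_group_rejected(self, tiny_cm):
        with pytest.raises(DesignError, match=">= 2 samples"):
            nb_wald_test(tiny_cm, ["s0"], ["s1", "s2", "s3"])

    def test_overlapping_groups_rejected(self, tiny_cm):
        with pytest.raises(DesignError, match="disjoint"):
            nb_wald_test(tiny_cm, ["s0", "s1"], ["s1", "s2"])

    def test_planted_two_group_recovery(self):
        """log2FC = 3 planted at n = 6 vs 10: >= 90% sensitivity with
        empirical FDR <= 10% over seeds."""
        tp = fp = fn = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n_genes = 1000
            base = np.exp2(rng.uniform(3, 9, n_genes))
            eff = np.zeros(n_genes)
            planted = rng.choice(n_genes, 60, replace=False)
            eff[planted] = np.where(np.arange(60) % 2 == 0, 3.0, -3.0)
            mu = np.tile(base[:, None], (1, 16)).astype(float)
            mu[:, :6] *= np.exp2(eff)[:, None]
            r = 1 / 0.1
            counts = rng.negative_binomial(r, r / (r + mu))
            cm = make_cm(counts, ["A"] * 6 + ["B"] * 10)
            tab = nb_wald_test(
                cm, [f"s{j}" for j in range(6)],
                [f"s{j}" for j in range(6, 16)],
            )
            called = set(tab.index[tab["is_deg"]])
            pl = {f"g{i}" for i in planted}
            tp += len(called & pl)
            fp += len(called - pl)
            fn += len(pl - called)
        assert tp / (tp + fn) >= 0.9
        assert fp / max(tp + fp, 1) <= 0.1

    def test_near_nominal_null_calibration(self):
        """Under the global null the raw p-values are close to calibrated
        at the 0.05 level (the Wald approximation is mildly liberal at
        n = 16)."""
        fracs = []
        for seed in range(15):
            cfg = SimulationConfig(
                n_degs_per_group=0, deg_log2fc=0.0,
                marker_config=MarkerConfig(0, 0), seed=100 + seed,
            )
            cm, _ = simulate_counts(cfg)
            labels = cm.subtypes
            tab = nb_wald_test(
                cm,
                list(labels.index[labels == "FS"]),
                list(labels.index[labels != "FS"]),
            )
            fracs.append(float((tab["p"] < 0.05).mean()))
        assert 0.035 <= np.mean(fracs) <= 0.07

    def test_agrees_with_independent_glm_engine(self):
        """Cross-check against an independent NB GLM implementation
        (pydeseq2) on a small planted dataset: strongly correlated log2FC
        and consistent top calls."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(3)
        n_genes = 300
        base = np.exp2(rng.uniform(4, 9, n_genes))
        eff = np.zeros(n_genes)
        planted = rng.choice(n_genes, 30, replace=False)
        eff[planted] = np.where(np.arange(30) % 2 == 0, 2.5, -2.5)
        mu = np.tile(base[:, None], (1, 12)).astype(float)
        mu[:, :6] *= np.exp2(eff)[:, None]
        r = 1 / 0.1
        counts = rng.negative_binomial(r, r / (r + mu))
        cm = make_cm(counts, ["A"] * 6 + ["B"] * 6)
        ours = nb_wald_test(
            cm, [f"s{j}" for j in range(6)], [f"s{j}" for j in range(6, 12)]
        )

        md = pd.DataFrame({"condition": ["A"] * 6 + ["B"] * 6},
                          index=cm.sample_ids)
        dds = DeseqDataSet(
            counts=cm.counts.T, metadata=md, design="~condition", quiet=True
        )
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "A", "B"], quiet=True)
        ds.summary()
        ref = ds.results_df["log2FoldChange"]
        rho = np.corrcoef(ours["log2fc"], ref.loc[ours.index])[0, 1]
        assert rho > 0.95
        ref_deg = set(ref.index[(ds.results_df["padj"] < 0.05)
                                & (ref.abs() > 1)])
        our_deg = set(ours.index[ours["is_deg"]])
        jacc = len(ref_deg & our_deg) / max(len(ref_deg | our_deg), 1)
        assert jacc > 0.6


class TestTumorVsNormal:
    def test_same_matrix_relabeled_yields_zero_degs(self, small_study):
        cm, _ = small_study
        twin = CountMatrix(
            cm.counts.rename(columns=lambda s: f"n_{s}"),
            cm.metadata.rename(index=lambda s: f"n_{s}"),
        )
        tab = tumor_vs_normal_degs(cm, twin)
        assert not tab["is_deg"].any()

    def test_gene_universe_intersection(self, small_study):
        cm, _ = small_study
        normal = CountMatrix(
            cm.counts.iloc[:200].rename(columns=lambda s: f"n_{s}"),
            cm.metadata.rename(index=lambda s: f"n_{s}"),
        )
        tab = tumor_vs_normal_degs(cm, normal)
        assert len(tab) == 200

    def test_disjoint_universes_error(self, tiny_cm):
        other = make_cm(np.array([[1, 2], [3, 4]]), ["A", "B"],
                        genes=["x0", "x1"], samples=["t0", "t1"])
        with pytest.raises(ValueError, match="share no gene"):
            tumor_vs_normal_degs(tiny_cm, other)


class TestCommonAndSpecific:
    @staticmethod
    def _table(up: set[str], down: set[str], universe: list[str]):
        df = pd.DataFrame(
            {
                "log2fc": 0.0,
                "p": 1.0,
                "padj": 1.0,
                "direction": "up",
                "is_deg": False,
            },
            index=pd.Index(universe),
        )
        df.loc[sorted(up), ["is_deg", "direction"]] = [True, "up"]
        df.loc[sorted(down), ["is_deg", "direction"]] = [True, "down"]
        return df

    def test_disjoint_sets_share_nothing(self):
        uni = [f"g{i}" for i in range(20)]
        tabs = {
            "A": self._table({"g0"}, {"g1"}, uni),
            "B": self._table({"g2"}, {"g3"}, uni),
        }
        sets = common_and_specific(tabs)
        assert not sets.shared_up and not sets.shared_down
        assert sets.specific_up["A"] == {"g0"}

    def test_identical_sets_have_no_specific(self):
        uni = [f"g{i}" for i in range(20)]
        t = self._table({"g0", "g1"}, {"g2"}, uni)
        sets = common_and_specific({"A": t, "B": t.copy()})
        assert sets.shared_up == {"g0", "g1"}
        assert sets.shared_down == {"g2"}
        assert all(not s for s in sets.specific_up.values())

    def test_matches_bruteforce_on_random_sets(self):
        rng = np.random.default_rng(7)
        uni = [f"g{i}" for i in range(50)]
        tabs = {}
        raw = {}
        for st in "ABC":
            up = set(rng.choice(uni, 15, replace=False))
            down = set(rng.choice(sorted(set(uni) - up), 10, replace=False))
            raw[st] = (up, down)
            tabs[st] = self._table(up, down, uni)
        sets = common_and_specific(tabs)
        exp_shared_up = raw["A"][0] & raw["B"][0] & raw["C"][0]
        exp_shared_down = raw["A"][1] & raw["B"][1] & raw["C"][1]
        assert sets.shared_up == exp_shared_up
        assert sets.shared_down == exp_shared_down
        for st in "ABC":
            assert sets.specific_up[st] == raw[st][0] - exp_shared_up
            assert sets.specific_down[st] == raw[st][1] - exp_shared_down
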