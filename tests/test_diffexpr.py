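"""Differential-expression engines and the high-confidence consensus rule."""

import numpy as np
import pandas as pd
import pytest

import scresilience as sr
from scresilience.diffexpr import (
    Contrast,
    DEResult,
    bootstrap_support_decision,
    consensus_high_confidence,
    intersect_conditions,
    median_of_ratios,
)


class TestContrast:
    def test_named_contrasts_fix_their_groups(self):
        early = Contrast("early")
        late = Contrast("late")
        assert (early.baseline, early.comparison) == ("low", "intermediate")
        assert (late.baseline, late.comparison) == ("intermediate", "high")

    def test_conflicting_definition_rejected(self):
        with pytest.raises(ValueError):
            Contrast("early", baseline="high", comparison="low")


class TestHurdleMixed:
    def test_planted_genes_recovered_with_correct_directions(self, de_cohort):
        ds, nm, truth = de_cohort
        res = sr.fit_hurdle_mixed(nm, ds.cell_meta, ds.donor_meta, Contrast("early"))
        planted = truth.de_genes["T0"]
        sig = set(res.significant_genes)
        hits = sig & set(planted)
        assert len(hits) / len(planted) >= 0.7
        for g in hits:
            assert (planted[g] > 0) == (res.table.loc[g, "direction"] == "up")

    def test_published_filters_gate_significance(self, de_cohort):
        ds, nm, truth = de_cohort
        res = sr.fit_hurdle_mixed(nm, ds.cell_meta, ds.donor_meta, Contrast("early"))
        t = res.table[res.table["significant"]]
        assert ((t["pct_base"] > 0.2) | (t["pct_comp"] > 0.2)).all()
        assert (t["logFC"].abs() > 0.1).all()
        assert (t["padj"] < 0.05).all()

    def test_null_cohorts_are_calibrated(self):
        fracs = []
        for seed in range(3):
            cfg = sr.CohortConfig(n_donors_per_group=14, n_celltypes=1,
                                  n_cells_per_donor=22, n_genes=2000,
                                  n_de_genes=0, n_marker_genes_per_type=0,
                                  seed=700 + seed)
            ds, _ = sr.simulate_cohort(cfg)
            nm = sr.normalize_log(ds)
            res = sr.fit_hurdle_mixed(nm, ds.cell_meta, ds.donor_meta, Contrast("early"))
            fracs.append(res.table["significant"].mean())
        assert np.mean(fracs) <= 0.05

    def test_too_few_donors_raises(self, de_cohort):
        ds, nm, _ = de_cohort
        keep = ds.cell_meta["donor_id"].isin(["Dlow00", "Dint00", "Dint01"])
        with pytest.raises(ValueError, match="donors"):
            sr.fit_hurdle_mixed(nm, ds.cell_meta[keep], ds.donor_meta, Contrast("early"))


class TestBootstrap:
    def test_support_boundary_nineteen_vs_twenty(self):
        up = np.array([19, 20, 100, 25])
        down = np.array([0, 0, 0, 3])
        support, direction, passed = bootstrap_support_decision(up, down, 20)
        assert list(passed) == [False, True, True, False]  # 25-up/3-down conflicted
        assert list(direction[:3]) == ["up", "up", "up"]
        assert list(support) == [19, 20, 100, 25]

    def test_raising_min_support_never_grows_the_set(self):
        rng = np.random.default_rng(0)
        up = rng.integers(0, 100, 200)
        down = rng.integers(0, 5, 200)
        prev = None
        for min_support in (10, 20, 40, 80):
            _, _, passed = bootstrap_support_decision(up, down, min_support)
            if prev is not None:
                assert not np.any(passed & ~prev)
            prev = passed

    def test_seeded_runs_are_bit_reproducible_and_order_invariant(self, de_cohort):
        ds, nm, _ = de_cohort
        kwargs = dict(contrast=Contrast("early"), n_iter=5, seed=3)
        a = sr.bootstrap_de(nm, ds.cell_meta, ds.donor_meta, **kwargs)
        b = sr.bootstrap_de(nm, ds.cell_meta, ds.donor_meta, **kwargs)
        pd.testing.assert_frame_equal(a.table, b.table)
        shuffled = ds.cell_meta.sample(frac=1.0, random_state=1)
        c = sr.bootstrap_de(nm, shuffled, ds.donor_meta, **kwargs)
        pd.testing.assert_frame_equal(a.table, c.table)

    def test_strong_planted_genes_accumulate_support(self, de_cohort):
        ds, nm, truth = de_cohort
        boot = sr.bootstrap_de(nm, ds.cell_meta, ds.donor_meta, Contrast("early"),
                               n_iter=20, seed=5)
        planted = sorted(truth.de_genes["T0"])
        assert boot.table.loc[planted, "support"].median() >= 10


class TestPseudobulk:
    def _null_pb(self, n_genes=300, mean=50.0, seed=0):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(mean, size=(20, n_genes))
        pb = pd.DataFrame(counts, index=[f"D{i}" for i in range(20)],
                          columns=[f"g{j}" for j in range(n_genes)])
        groups = pd.Series(["low"] * 10 + ["intermediate"] * 10, index=pb.index)
        nexp = pd.Series(100, index=pb.columns)
        return pb, groups, nexp

    def test_genes_under_twenty_nuclei_are_absent(self):
        pb, groups, nexp = self._null_pb(50)
        nexp.iloc[0] = 19
        nexp.iloc[1] = 20
        res = sr.pseudobulk_de(pb, nexp, groups, Contrast("early"))
        assert "g0" not in res.table.index
        assert "g1" in res.table.index

    def test_planted_fold_change_detected(self):
        pb, groups, nexp = self._null_pb(300)
        rng = np.random.default_rng(1)
        pb.iloc[10:, :30] = rng.poisson(200.0, size=(10, 30))
        res = sr.pseudobulk_de(pb, nexp, groups, Contrast("early"))
        de = res.table.iloc[:30]
        assert (de["padj"] < 0.05).mean() >= 0.9
        assert (de["direction"] == "up").all()

    def test_median_of_ratios_normalizes_library_scale(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(100.0, size=(6, 200)).astype(float)
        scaled = base * np.array([1, 2, 4, 1, 0.5, 1])[:, None]
        sf = median_of_ratios(pd.DataFrame(scaled))
        ratio = sf / sf[0]
        assert ratio == pytest.approx([1, 2, 4, 1, 0.5, 1], rel=0.05)

    def test_matches_pydeseq2_on_shared_genes(self):
        """Independent oracle: pyDESeq2 Wald on the same pseudobulk counts."""
        pb, groups, nexp = self._null_pb(60, seed=3)
        rng = np.random.default_rng(4)
        pb.iloc[10:, :10] = rng.poisson(250.0, size=(10, 10))
        res = sr.pseudobulk_de(pb, nexp, groups, Contrast("early"))

        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats
        meta = pd.DataFrame({"condition": groups.to_numpy()}, index=pb.index)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(counts=pb, metadata=meta, design="~condition", quiet=True)
            dds.deseq2()
            ds_res = DeseqStats(dds, contrast=["condition", "intermediate", "low"],
                                quiet=True)
            ds_res.summary()
        oracle = ds_res.results_df
        ours_sig = res.table["padj"] < 0.05
        oracle_sig = oracle.loc[res.table.index, "padj"] < 0.05
        agree = (ours_sig.to_numpy() == oracle_sig.to_numpy()).mean()
        assert agree >= 0.95
        # effect sizes agree on the planted genes (ours natural log, theirs log2)
        ours_lfc = res.table["logFC"].iloc[:10] / np.log(2)
        theirs = oracle.loc[res.table.index[:10], "log2FoldChange"]
        assert np.allclose(ours_lfc, theirs, atol=0.25)


class TestConsensus:
    def _de(self, genes, directions, method, sig=True, contrast=None):
        table = pd.DataFrame(
            {"logFC": [1.0 if d == "up" else -1.0 for d in directions],
             "direction": directions,
             "significant": sig if isinstance(sig, list) else [sig] * len(genes)},
            index=pd.Index(genes, name="gene_id"),
        )
        return DEResult(table=table, method=method, contrast=contrast or Contrast("early"))

    def test_mixed_only_gene_is_excluded(self):
        mixed = self._de(["g1"], ["up"], "mixed")
        boot = self._de(["g1"], ["up"], "bootstrap", sig=False)
        hc = consensus_high_confidence(mixed, bootstrap=boot)
        assert hc.genes == set()

    def test_mixed_plus_bootstrap_is_included(self):
        mixed = self._de(["g1"], ["up"], "mixed")
        boot = self._de(["g1"], ["up"], "bootstrap")
        hc = consensus_high_confidence(mixed, bootstrap=boot)
        assert hc.genes == {"g1"}
        assert bool(hc.table.loc["g1", "bootstrap"])

    def test_bootstrap_plus_pseudobulk_without_mixed_is_excluded(self):
        mixed = self._de(["g1"], ["up"], "mixed", sig=False)
        boot = self._de(["g1"], ["up"], "bootstrap")
        pb = self._de(["g1"], ["up"], "pseudobulk")
        hc = consensus_high_confidence(mixed, bootstrap=boot, pseudobulk=pb)
        assert hc.genes == set()

    def test_hub_membership_corroborates(self):
        mixed = self._de(["g1"], ["down"], "mixed")
        hc = consensus_high_confidence(mixed, hub_genes={"g1"})
        assert hc.genes == {"g1"}
        assert bool(hc.table.loc["g1", "coexpr_hub"])

    def test_direction_conflict_excludes_and_logs(self):
        mixed = self._de(["g1"], ["up"], "mixed")
        pb = self._de(["g1"], ["down"], "pseudobulk")
        hc = consensus_high_confidence(mixed, pseudobulk=pb, hub_genes={"g1"})
        assert hc.genes == set()
        assert hc.direction_conflicts == ["g1"]

    def test_consensus_is_subset_of_mixed(self, de_cohort):
        ds, nm, truth = de_cohort
        mixed = sr.fit_hurdle_mixed(nm, ds.cell_meta, ds.donor_meta, Contrast("early"))
        hubs = set(list(truth.de_genes["T0"])[:5])
        hc = consensus_high_confidence(mixed, hub_genes=hubs)
        assert hc.genes <= set(mixed.significant_genes)

    def test_mismatched_contrasts_rejected(self):
        mixed = self._de(["g1"], ["up"], "mixed", contrast=Contrast("early"))
        pb = self._de(["g1"], ["up"], "pseudobulk", contrast=Contrast("late"))
        with pytest.raises(ValueError):
            consensus_high_confidence(mixed, pseudobulk=pb)


class TestIntersections:
    def test_identical_and_disjoint_sets(self):
        sets = {f"s{i}": {"a", "b", "c"} for i in range(4)}
        membership, shared, pairwise = intersect_conditions(sets)
        assert len(shared) == 3
        assert (pairwise.to_numpy() == 3).all()
        disjoint = {"x": {"a"}, "y": {"b"}, "z": {"c"}}
        _, shared_d, pairwise_d = intersect_conditions(disjoint)
        assert shared_d == []
        off_diag = pairwise_d.to_numpy()[~np.eye(3, dtype=bool)]
        assert (off_diag == 0).all()

    def test_membership_matrix_matches_brute_force(self):
        rng = np.random.default_rng(7)
        universe = [f"g{i}" for i in range(50)]
        sets = {name: {g for g in universe if rng.random() < 0.4}
                for name in ("BA9-early", "BA9-late", "BA17-early", "BA17-late")}
        membership, shared, pairwise = intersect_conditions(sets)
        for name, s in sets.items():
            for g in membership.index:
                assert membership.loc[g, name] == (g in s)
        assert set(shared) == set.intersection(*sets.values())
        for a in sets:
            for b in sets:
                assert pairwise.loc[a, b] == len(sets[a] & sets[b])
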