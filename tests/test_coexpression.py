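"""Metacells, soft power, TOM, module detection, kME and stability."""

import warnings

import numpy as np
import pandas as pd
import pytest

import scresilience as sr
from scresilience.coexpression import MetacellMatrix, _adjacency, topological_overlap
from scresilience.data import NormalizedMatrix


def _nm(values: np.ndarray) -> NormalizedMatrix:
    return NormalizedMatrix(
        values=np.asarray(values, float),
        size_factors=np.ones(values.shape[1]),
        gene_ids=pd.Index([f"g{i:03d}" for i in range(values.shape[0])]),
        cell_ids=pd.Index([f"c{i}" for i in range(values.shape[1])]),
    )


def _factor_metacells(n_genes=120, n_meta=150, n_modules=2, size=30, seed=0,
                      noise_sd=0.3):
    """Metacell matrix with known latent factors; gene 0 of each module has
    loading 1.0 (the hub), later members taper off."""
    rng = np.random.default_rng(seed)
    values = rng.normal(0, noise_sd, size=(n_genes, n_meta))
    truth = {}
    for m in range(n_modules):
        f = rng.normal(size=n_meta)
        idx = np.arange(m * size, (m + 1) * size)
        loadings = np.concatenate([[1.0], np.linspace(0.7, 0.4, size - 1)])
        values[idx] += loadings[:, None] * f[None, :]
        for i in idx:
            truth[f"g{i:03d}"] = m
    return MetacellMatrix(values=values, gene_ids=pd.Index([f"g{i:03d}" for i in range(n_genes)]),
                          members=[np.arange(25)] * n_meta, groups=["T0"] * n_meta, k=25), truth


class TestMetacells:
    def test_group_below_min_cells_is_skipped(self, module_cohort):
        nm, _, _ = module_cohort
        groups = np.array(["small"] * 49 + ["big"] * (nm.values.shape[1] - 49))
        with pytest.warns(UserWarning, match="skipped"):
            mc = sr.build_metacells(nm, groups, k=25, min_cells=50, seed=0)
        assert set(mc.groups) == {"big"}

    def test_every_metacell_has_k_members_from_one_group(self, module_cohort):
        _, mc, _ = module_cohort
        assert mc.n_metacells > 0
        for mem in mc.members:
            assert len(mem) == 25

    def test_identical_cells_give_the_common_profile(self):
        profile = np.arange(20.0)
        values = np.tile(profile[:, None], (1, 60))
        mc = sr.build_metacells(_nm(values), ["T0"] * 60, k=10, min_cells=50, seed=0)
        for j in range(mc.n_metacells):
            assert np.allclose(mc.values[:, j], profile)

    def test_separated_subpopulations_are_never_mixed(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.5, size=(30, 60))
        b = rng.normal(20, 0.5, size=(30, 60))
        values = np.concatenate([a, b], axis=1)
        mc = sr.build_metacells(_nm(values), ["T0"] * 120, k=10, min_cells=50, seed=0)
        for mem in mc.members:
            side = mem < 60
            assert side.all() or (~side).all()


class TestNetwork:
    def test_power_one_adjacency_is_absolute_correlation(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(40, 80))
        adj = _adjacency(values, 1.0)
        assert np.allclose(adj, np.abs(np.corrcoef(values)))
        adj6 = _adjacency(values, 6.0)
        assert adj6.min() >= 0.0 and adj6.max() <= 1.0

    def test_tom_is_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(3)
        adj = _adjacency(rng.normal(size=(50, 60)), 4.0)
        tom = topological_overlap(adj)
        assert np.allclose(tom, tom.T)
        assert np.allclose(np.diag(tom), 1.0)
        assert tom.min() >= 0.0 and tom.max() <= 1.0

    def test_soft_power_scan_reports_all_candidates(self, module_cohort):
        _, mc, _ = module_cohort
        power, scan = sr.choose_soft_power(mc, powers=range(1, 13))
        assert list(scan["power"]) == list(range(1, 13))
        assert 1 <= power <= 12
        assert (scan["mean_connectivity"].diff().dropna() < 0).all()


class TestModules:
    def test_planted_modules_recovered(self, module_cohort):
        nm, mc, truth = module_cohort
        power, _ = sr.choose_soft_power(mc)
        ms = sr.detect_modules(mc, power)
        assert len(ms.module_ids) == 2
        from sklearn.metrics import adjusted_rand_score
        true_lab = [truth.module_membership.get(str(g), -1) + 1
                    if str(g) in truth.module_membership else 0
                    for g in nm.gene_ids]
        ari = adjusted_rand_score(true_lab, ms.assignments.to_numpy())
        assert ari >= 0.9

    def test_all_noise_matrix_stays_grey(self):
        rng = np.random.default_rng(4)
        mc = MetacellMatrix(values=rng.normal(size=(200, 120)),
                            gene_ids=pd.Index([f"g{i}" for i in range(200)]),
                            members=[np.arange(25)] * 120, groups=["T0"] * 120, k=25)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ms = sr.detect_modules(mc, 6)
        assert ms.module_ids == []


class TestKme:
    def test_gene_identical_to_eigengene_has_kme_one(self):
        mc, truth = _factor_metacells(seed=5)
        ms = sr.detect_modules(mc, 4)
        assert len(ms.module_ids) >= 1
        m = ms.module_ids[0]
        eig = ms.eigengenes[m].to_numpy()
        mc2 = MetacellMatrix(
            values=np.vstack([mc.values, eig[None, :]]),
            gene_ids=mc.gene_ids.append(pd.Index(["geig"])),
            members=mc.members, groups=mc.groups, k=mc.k,
        )
        ms2 = sr.ModuleSet(
            assignments=pd.Series(
                np.concatenate([ms.assignments.to_numpy(), [m]]), index=mc2.gene_ids
            ),
            eigengenes=ms.eigengenes,
        )
        sr.compute_kme(mc2, ms2)
        assert abs(ms2.kme.loc["geig", m]) == pytest.approx(1.0, abs=1e-9)

    def test_planted_hub_is_top_ranked(self):
        mc, truth = _factor_metacells(seed=6)
        ms = sr.detect_modules(mc, 4)
        hubs = {f"g{m * 30:03d}" for m in range(2)}
        top1 = {ms.top10[m][0] for m in ms.module_ids}
        assert top1 == hubs

    def test_independent_gene_has_small_kme(self):
        mc, _ = _factor_metacells(n_meta=150, seed=7)
        ms = sr.detect_modules(mc, 4)
        noise_genes = [g for g in ms.kme.index if ms.assignments[g] == 0]
        assert len(noise_genes) > 10
        assert ms.kme.loc[noise_genes].abs().to_numpy().max() < 0.5
        assert ms.kme.loc[noise_genes].abs().median().max() < 0.3

    def test_hub_lists_are_nested_in_members(self):
        mc, _ = _factor_metacells(seed=8)
        ms = sr.detect_modules(mc, 4)
        for m in ms.module_ids:
            members = set(ms.members(m))
            assert set(ms.top10[m]) <= set(ms.top50[m]) <= members
            assert ms.kme.to_numpy().max() <= 1.0 + 1e-12


class TestStability:
    def test_planted_modules_are_stable(self):
        # near-noiseless factors: module membership should survive resampling
        mc, _ = _factor_metacells(seed=9, noise_sd=0.15)
        ms = sr.detect_modules(mc, 6)
        stab = sr.module_stability(mc, ms, n_boot=15, seed=1)
        assert (stab >= 0.9).all()

    def test_grey_only_reference_gives_empty_output(self):
        rng = np.random.default_rng(10)
        mc = MetacellMatrix(values=rng.normal(size=(100, 80)),
                            gene_ids=pd.Index([f"g{i}" for i in range(100)]),
                            members=[np.arange(25)] * 80, groups=["T0"] * 80, k=25)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ms = sr.detect_modules(mc, 6)
        stab = sr.module_stability(mc, ms, n_boot=5, seed=0)
        assert stab.empty


class TestModuleDeSummary:
    def _moduleset(self):
        mc, _ = _factor_metacells(seed=11)
        return sr.detect_modules(mc, 4)

    def test_constant_logfc_averages_exactly(self):
        ms = self._moduleset()
        m = ms.module_ids[0]
        genes = ms.members(m)
        table = pd.DataFrame({"logFC": 0.5, "significant": False},
                             index=pd.Index(genes))
        out = sr.module_de_summary(ms, {"early": table})
        row = out[(out["module"] == m) & (out["contrast"] == "early")].iloc[0]
        assert row["mean_logFC"] == pytest.approx(0.5)
        assert row["n_de_members"] == 0

    def test_matches_brute_force_group_average(self):
        ms = self._moduleset()
        rng = np.random.default_rng(12)
        all_genes = list(ms.assignments.index)
        table = pd.DataFrame(
            {"logFC": rng.normal(size=len(all_genes)),
             "significant": rng.random(len(all_genes)) < 0.3},
            index=pd.Index(all_genes),
        )
        out = sr.module_de_summary(ms, {"c": table})
        for m in ms.module_ids:
            genes = ms.members(m)
            row = out[(out["module"] == m)].iloc[0]
            assert row["mean_logFC"] == pytest.approx(table.loc[genes, "logFC"].mean())
            assert row["n_de_members"] == int(table.loc[genes, "significant"].sum())
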