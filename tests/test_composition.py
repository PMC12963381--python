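"""Compositional model: reference choice, DM likelihood, posterior behavior,
beta regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

import scresilience as sr
from scresilience._dm_mcmc import _loglik_logits
from scresilience.composition import CompositionPosterior

FAST_MCMC = {"chains": 2, "warmup": 300, "samples": 300, "seed": 1}


def _table(counts: np.ndarray, groups=None) -> sr.CompositionTable:
    counts = np.asarray(counts)
    d, k = counts.shape
    idx = pd.Index([f"D{i}" for i in range(d)], name="donor_id")
    if groups is None:
        groups = ["low"] * (d // 2) + ["high"] * (d - d // 2)
    rng = np.random.default_rng(0)
    design = pd.DataFrame(
        {"pathology_group": groups,
         "sex": rng.choice(["F", "M"], d),
         "age": rng.normal(75, 5, d),
         "APOE": rng.choice(["E3/E3", "E3/E4"], d),
         "assay": rng.choice(["10xv2", "10xv3"], d)},
        index=idx,
    )
    return sr.CompositionTable(
        pd.DataFrame(counts, index=idx, columns=[f"T{j}" for j in range(k)]),
        design,
    )


class TestSelectReference:
    def test_constant_proportion_type_is_selected(self):
        counts = np.array([[10, 25, 65], [20, 50, 90], [30, 75, 400]])
        # T0 is exactly 10% of each donor's total? craft: totals 100, 160, 505
        counts = np.array([[10, 25, 65], [16, 50, 94], [50, 75, 375]])
        ct = _table(counts)  # T0 proportions: .1, .1, .1
        assert sr.select_reference(ct, presence_min=0.5) == "T0"

    def test_type_absent_in_half_the_donors_is_ineligible(self):
        counts = np.array([[0, 50, 50], [60, 40, 0], [0, 30, 70], [55, 45, 0]])
        ref = sr.select_reference(ct := _table(counts), presence_min=0.9)
        assert ref == "T1"  # only broadly present type

    def test_known_dispersions_argmin(self):
        rng = np.random.default_rng(2)
        d = 40
        t0 = rng.poisson(100, d) + 1          # low dispersion
        t1 = (rng.gamma(2.0, 50, d)).astype(int) + 1  # high dispersion
        t2 = rng.poisson(100, d) + rng.integers(0, 300, d)  # noisy
        ct = _table(np.column_stack([t0, t1, t2]))
        props = ct.counts.div(ct.counts.sum(axis=1), axis=0)
        disp = props.var(axis=0, ddof=1) / props.mean(axis=0)
        assert sr.select_reference(ct, presence_min=0.5) == disp.idxmin()


class TestDMLikelihood:
    def test_matches_scipy_dirichlet_multinomial_on_toys(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            counts = rng.integers(1, 40, size=(6, 3)).astype(float)
            n_d = counts.sum(axis=1)
            logits = rng.normal(0, 1, size=(6, 3))
            lphi = float(np.log(rng.uniform(20, 200)))
            phi = np.exp(lphi)
            p = np.exp(logits - logits.max(axis=1, keepdims=True))
            p /= p.sum(axis=1, keepdims=True)
            want = 0.0
            for d in range(6):
                want += stats.dirichlet_multinomial.logpmf(counts[d], phi * p[d], n_d[d])
                want -= special.gammaln(n_d[d] + 1) - special.gammaln(counts[d] + 1).sum()
            got = _loglik_logits(counts, n_d, logits, lphi)
            assert got == pytest.approx(want, rel=1e-10)

    def test_compositional_closure_constant_logit_shift_is_invariant(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 50, size=(8, 4)).astype(float)
        n_d = counts.sum(axis=1)
        logits = rng.normal(0, 1, size=(8, 4))
        base = _loglik_logits(counts, n_d, logits, np.log(80.0))
        shifted = _loglik_logits(counts, n_d, logits + 3.7, np.log(80.0))
        assert shifted == pytest.approx(base, rel=1e-12)

    def test_relabeling_non_reference_types_permutes_likelihood(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 50, size=(6, 4)).astype(float)
        n_d = counts.sum(axis=1)
        logits = rng.normal(0, 1, size=(6, 4))
        perm = [0, 2, 3, 1]
        a = _loglik_logits(counts, n_d, logits, np.log(60.0))
        b = _loglik_logits(counts[:, perm], n_d, logits[:, perm], np.log(60.0))
        assert a == pytest.approx(b, rel=1e-12)


class TestDMPosterior:
    def test_mcmc_is_deterministic_under_fixed_seed(self):
        cfg = sr.CohortConfig(n_donors_per_group=5, n_celltypes=4,
                              n_cells_per_donor=500, n_genes=50, seed=6)
        counts, meta = sr.simulate_composition(cfg)
        ct = sr.CompositionTable(counts, meta)
        a = sr.fit_dirichlet_multinomial(ct, reference="T0", mcmc=FAST_MCMC)
        b = sr.fit_dirichlet_multinomial(ct, reference="T0", mcmc=FAST_MCMC)
        assert np.array_equal(a.beta_draws, b.beta_draws)

    def test_reference_type_is_zero_in_every_draw(self):
        cfg = sr.CohortConfig(n_donors_per_group=4, n_celltypes=3,
                              n_cells_per_donor=400, n_genes=50, seed=7)
        counts, meta = sr.simulate_composition(cfg)
        post = sr.fit_dirichlet_multinomial(
            sr.CompositionTable(counts, meta), reference="T1", mcmc=FAST_MCMC
        )
        ref_col = post.celltypes.index("T1")
        assert np.all(post.beta_draws[:, :, :, ref_col] == 0.0)

    def test_constrained_mode_has_no_positive_draws(self):
        cfg = sr.CohortConfig(n_donors_per_group=4, n_celltypes=4,
                              n_cells_per_donor=400, n_genes=50, seed=8)
        counts, meta = sr.simulate_composition(cfg)
        post = sr.fit_dirichlet_multinomial(
            sr.CompositionTable(counts, meta), reference="T0",
            constrain_nonpositive=True, mcmc=FAST_MCMC,
        )
        nonref = [k for k, c in enumerate(post.celltypes) if c != "T0"]
        assert post.beta_draws[:, :, :, nonref].max() <= 0.0


class TestCredibleEffects:
    def _posterior(self, pip, lfc):
        levels = ["high"]
        cols = ["T0", "T1"]
        return CompositionPosterior(
            celltypes=cols, group_levels=levels, reference="T0",
            constrained=False,
            beta_draws=np.zeros((1, 1, 1, 2)),
            pip=pd.DataFrame([[0.0, pip]], index=levels, columns=cols),
            log2fc=pd.DataFrame([[0.0, lfc]], index=levels, columns=cols),
            credible=pd.DataFrame([[False, pip > 0.95]], index=levels, columns=cols),
            credible_method="posterior inclusion probability",
        )

    def test_magnitude_rule_excludes_small_effects(self):
        out = sr.credible_effects(self._posterior(0.96, 0.05))
        assert out.empty

    def test_pip_rule_excludes_uncertain_effects(self):
        out = sr.credible_effects(self._posterior(0.90, 1.75))
        assert out.empty

    def test_joint_rule_includes_qualifying_effects(self):
        out = sr.credible_effects(self._posterior(0.96, -0.46))
        assert list(out["celltype"]) == ["T1"]


class TestBetaRegression:
    def test_constant_proportions_give_zero_coefficient(self):
        counts = np.tile([25, 75], (12, 1))
        groups = ["low"] * 4 + ["intermediate"] * 4 + ["high"] * 4
        ct = _table(counts, groups=groups)
        out = sr.fit_beta_regression(ct, contrast="high")
        assert out.loc["T0", "coef"] == pytest.approx(0.0, abs=1e-6)
        assert out.loc["T0", "p"] == pytest.approx(1.0)

    def test_rare_type_excluded_by_min_donors(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(20, 60, size=(12, 3))
        counts[:, 2] = 0
        counts[0, 2] = 5
        counts[1, 2] = 3
        groups = ["low"] * 6 + ["high"] * 6
        out = sr.fit_beta_regression(_table(counts, groups=groups), contrast="high")
        assert bool(out.loc["T2", "excluded"])
        assert np.isnan(out.loc["T2", "coef"])

    def test_planted_logit_shift_recovered(self):
        """Coefficient within +-0.3 of the planted 1.0 logit shift in >= 80%
        of 20 replicates (total high-vs-low log-abundance shift 1.0 nat)."""
        lfc = np.zeros(8)
        lfc[0] = 1.0 / np.log(2.0)  # 1.0 on the natural-log scale
        hits = 0
        for seed in range(20):
            cfg = sr.CohortConfig(n_donors_per_group=20, n_celltypes=8,
                                  n_cells_per_donor=2000, comp_log2fc=lfc,
                                  n_genes=50, seed=600 + seed)
            counts, meta = sr.simulate_composition(cfg)
            out = sr.fit_beta_regression(
                sr.CompositionTable(counts, meta), contrast="high"
            )
            if abs(out.loc["T0", "coef"] - 1.0) <= 0.3:
                hits += 1
        assert hits >= 16
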