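"""Compositional analysis of cell-type abundance across pathology groups.

Donor-level cell-type counts are modeled with a Dirichlet-multinomial
regression in the style of scCODA: counts_d ~ DM(n_d, phi * softmax(a + x_d
B)), with one cell type held out as a reference (B[:, ref] = 0), adjusting
for sex, APOE genotype, assay and standardized age.  Disease-group effects
carry a spike-and-slab prior whose posterior inclusion probability (PIP)
gates credibility; a "loss-only" stress-test variant constrains every group
coefficient to be non-positive via a HalfNormal magnitude prior.  A
fixed-effects beta regression on donor-level proportions provides an
independent frequentist check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.othermod.betareg import BetaModel
from statsmodels.stats.multitest import multipletests

from ._dm_mcmc import run_chain

LN2 = float(np.log(2.0))


@dataclass
class CompositionTable:
    """Donor x cell-type counts with aligned donor covariates."""

    counts: pd.DataFrame  # donors x cell types, non-negative integers
    design: pd.DataFrame  # donor covariates incl. pathology_group

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.design.index):
            self.design = self.design.loc[self.counts.index]
        if (self.counts.sum(axis=1) <= 0).any():
            raise ValueError("every donor must have at least one cell")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative cell-type counts")

    @property
    def celltypes(self) -> list[str]:
        return list(self.counts.columns)

    @classmethod
    def from_cohort(cls, ds, region: str | None = None) -> "CompositionTable":
        """Tabulate donor x cluster cell counts from a cohort dataset."""
        meta = ds.cell_meta
        if region is not None:
            meta = meta[meta["region"] == region]
        counts = (
            meta.groupby(["donor_id", "cluster"]).size().unstack(fill_value=0)
        )
        counts = counts.loc[counts.sum(axis=1) > 0]
        return cls(counts=counts, design=ds.donor_meta.loc[counts.index])


def select_reference(ct: CompositionTable, presence_min: float = 0.9) -> str:
    """Automatic reference: the most dispersion-stable, broadly present type.

    Among cell types observed (nonzero) in at least ``presence_min`` of
    donors, pick the one minimizing the dispersion of its relative abundance
    (variance of proportion / mean proportion); ties break lexicographically.
    If no type is present broadly enough, fall back to the most prevalent
    type with a warning.
    """
    if ct.counts.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    props = ct.counts.div(ct.counts.sum(axis=1), axis=0)
    presence = (ct.counts > 0).mean(axis=0)
    eligible = presence[presence >= presence_min].index
    if len(eligible) == 0:
        warnings.warn(
            "no cell type present in enough donors; falling back to the most "
            "prevalent type",
            stacklevel=2,
        )
        return str(props.mean(axis=0).idxmax())
    disp = props[eligible].var(axis=0, ddof=1) / props[eligible].mean(axis=0)
    best = disp.min()
    candidates = sorted(str(c) for c in disp.index[disp == best])
    return candidates[0]


def _design_matrices(design: pd.DataFrame) -> tuple[np.ndarray, list[str], np.ndarray, list[str]]:
    """Split covariates into group dummies (vs 'low') and nuisance columns."""
    group = pd.Categorical(
        design["pathology_group"], categories=["low", "intermediate", "high"]
    )
    Xg = pd.get_dummies(pd.Series(group, index=design.index), drop_first=True)
    Xg.columns = [str(c) for c in Xg.columns]
    nuis = []
    for col in ("sex", "APOE", "assay"):
        if col in design.columns and design[col].nunique() > 1:
            d = pd.get_dummies(design[col].astype(str), prefix=col, drop_first=True)
            nuis.append(d)
    if "age" in design.columns:
        age = design["age"].astype(float)
        sd = age.std(ddof=0)
        nuis.append(((age - age.mean()) / (sd if sd > 0 else 1.0)).rename("age_std"))
    Xn = pd.concat(nuis, axis=1) if nuis else pd.DataFrame(index=design.index)
    return (
        Xg.to_numpy(dtype=np.float64),
        list(Xg.columns),
        Xn.to_numpy(dtype=np.float64) if Xn.shape[1] else np.zeros((len(design), 0)),
        list(Xn.columns),
    )


@dataclass
class CompositionPosterior:
    """Posterior summaries of the Dirichlet-multinomial regression.

    ``beta_draws`` has shape (chains, samples, group levels, cell types) with
    the reference column identically zero.  In unconstrained mode ``pip``
    holds posterior inclusion probabilities; in constrained mode credibility
    is assessed by the 95% credible interval instead (``credible_method``
    records which rule applies).
    """

    celltypes: list[str]
    group_levels: list[str]
    reference: str
    constrained: bool
    beta_draws: np.ndarray
    pip: pd.DataFrame  # group levels x cell types
    log2fc: pd.DataFrame  # posterior-mean beta / ln 2
    credible: pd.DataFrame  # boolean, before the magnitude filter
    credible_method: str
    diagnostics: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("max_rhat", np.inf) <= 1.05)


def _split_rhat(draws: np.ndarray) -> float:
    """Split-R-hat over (chains, samples) draws of one scalar parameter."""
    c, s = draws.shape
    half = s // 2
    if half < 2:
        return np.nan
    chains = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    m, n = chains.shape
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 1e-300:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _ess(draws: np.ndarray) -> float:
    """Crude bulk effective sample size via pooled autocorrelation."""
    c, s = draws.shape
    x = draws - draws.mean(axis=1, keepdims=True)
    total = c * s
    if np.allclose(x, 0):
        return float(total)
    acf = np.zeros(min(s - 1, 200))
    denom = (x * x).sum()
    if denom <= 0:
        return float(total)
    for lag in range(1, len(acf) + 1):
        acf[lag - 1] = (x[:, :-lag] * x[:, lag:]).sum() / denom
    rho_sum = 0.0
    for r in acf:
        if r < 0.05:
            break
        rho_sum += r
    return float(total / (1.0 + 2.0 * rho_sum))


def fit_dirichlet_multinomial(
    ct: CompositionTable,
    reference: str | None = None,
    constrain_nonpositive: bool = False,
    mcmc: dict | None = None,
    prior: dict | None = None,
) -> CompositionPosterior:
    """Sample the DM compositional regression posterior.

    ``mcmc`` keys: chains (4), warmup (1000), samples (1000), seed (0),
    n_leapfrog (8).  ``prior`` keys: slab_sd (1.0), inclusion_prob (0.2),
    halfnormal_scale (1.0), intercept_sd (5.0), nuisance_sd (1.0),
    logphi_mu (log 100), logphi_sd (1.5).  Non-convergence (split R-hat >
    1.05 on any group coefficient) flags the result via ``diagnostics`` and a
    warning; it is never silent.
    """
    mcmc = {**{"chains": 4, "warmup": 1000, "samples": 1000, "seed": 0, "n_leapfrog": 8},
            **(mcmc or {})}
    prior = {**{"slab_sd": 1.0, "inclusion_prob": 0.2, "halfnormal_scale": 1.0,
                "intercept_sd": 5.0, "nuisance_sd": 1.0,
                "logphi_mu": float(np.log(100.0)), "logphi_sd": 1.5},
             **(prior or {})}
    if reference is None:
        reference = select_reference(ct)
    if reference not in ct.celltypes:
        raise ValueError(f"reference {reference!r} not among cell types")
    ref = ct.celltypes.index(reference)

    counts = ct.counts.to_numpy(dtype=np.float64)
    n_d = counts.sum(axis=1)
    Xg, group_levels, Xn, _ = _design_matrices(ct.design)
    D, K = counts.shape
    Jg = Xg.shape[1]

    chains = []
    z_chains = []
    accept, divergences = [], 0
    for c in range(mcmc["chains"]):
        theta, z, acc, div = run_chain(
            counts, n_d, Xg, Xn, ref, constrain_nonpositive,
            mcmc["warmup"], mcmc["samples"],
            int(mcmc["seed"]) * 1000 + c + 1,
            mcmc["n_leapfrog"],
            prior["intercept_sd"], prior["slab_sd"], prior["nuisance_sd"],
            prior["halfnormal_scale"], prior["logphi_mu"], prior["logphi_sd"],
            prior["inclusion_prob"],
        )
        chains.append(theta)
        z_chains.append(z)
        accept.append(acc)
        divergences += div

    theta_draws = np.stack(chains)  # chains x samples x n_free
    z_draws = np.stack(z_chains)  # chains x samples x Jg*(K-1)
    S = mcmc["samples"]
    nonref = [k for k in range(K) if k != ref]

    # assemble beta draws on the full (levels x types) grid, reference = 0
    beta = np.zeros((mcmc["chains"], S, Jg, K))
    for j in range(Jg):
        for c_i, k in enumerate(nonref):
            raw = theta_draws[:, :, K + j * (K - 1) + c_i]
            if constrain_nonpositive:
                beta[:, :, j, k] = -np.abs(raw)
            else:
                beta[:, :, j, k] = raw * z_draws[:, :, j * (K - 1) + c_i]

    pip = np.zeros((Jg, K))
    if not constrain_nonpositive:
        for j in range(Jg):
            for c_i, k in enumerate(nonref):
                pip[j, k] = z_draws[:, :, j * (K - 1) + c_i].mean()
    log2fc = beta.mean(axis=(0, 1)) / LN2

    if constrain_nonpositive:
        lo = np.quantile(beta, 0.025, axis=(0, 1))
        hi = np.quantile(beta, 0.975, axis=(0, 1))
        credible = (hi < 0) & (lo < 0)
        credible[:, ref] = False
        method = "95% credible interval excluding 0 (loss-only support)"
    else:
        credible = pip > 0.95
        method = "posterior inclusion probability"

    rhats = []
    for j in range(Jg):
        for k in nonref:
            rhats.append(_split_rhat(beta[:, :, j, k]))
    max_rhat = float(np.nanmax(rhats)) if rhats else 1.0
    ess = float(np.median([_ess(beta[:, :, j, k]) for j in range(Jg) for k in nonref]))
    if max_rhat > 1.05:
        warnings.warn(
            f"DM sampler may not have converged (max split R-hat {max_rhat:.3f})",
            stacklevel=2,
        )

    cols = ct.celltypes
    levels = group_levels
    return CompositionPosterior(
        celltypes=cols,
        group_levels=levels,
        reference=reference,
        constrained=constrain_nonpositive,
        beta_draws=beta,
        pip=pd.DataFrame(pip, index=levels, columns=cols),
        log2fc=pd.DataFrame(log2fc, index=levels, columns=cols),
        credible=pd.DataFrame(credible, index=levels, columns=cols),
        credible_method=method,
        diagnostics={
            "max_rhat": max_rhat,
            "median_ess": ess,
            "accept_rate": float(np.mean(accept)),
            "divergences": int(divergences),
        },
    )


def credible_effects(
    post: CompositionPosterior,
    pip_min: float = 0.95,
    min_abs_log2fc: float = 0.1,
) -> pd.DataFrame:
    """Table of credible (cell type, contrast, log2FC) effects.

    An effect qualifies with PIP > ``pip_min`` (or, in constrained mode, a
    95% credible interval excluding 0) AND |posterior-mean log2FC| >
    ``min_abs_log2fc``.  The reference type is never returned.
    """
    rows = []
    for level in post.group_levels:
        for ctype in post.celltypes:
            if ctype == post.reference:
                continue
            lfc = float(post.log2fc.loc[level, ctype])
            if post.constrained:
                gate = bool(post.credible.loc[level, ctype])
            else:
                gate = float(post.pip.loc[level, ctype]) > pip_min
            if gate and abs(lfc) > min_abs_log2fc:
                rows.append(
                    {
                        "celltype": ctype,
                        "contrast": level,
                        "log2fc": lfc,
                        "pip": float(post.pip.loc[level, ctype]) if not post.constrained else np.nan,
                    }
                )
    return pd.DataFrame(rows, columns=["celltype", "contrast", "log2fc", "pip"])


def fit_beta_regression(
    ct: CompositionTable,
    contrast: str = "high",
    min_donors: int = 3,
) -> pd.DataFrame:
    """Per-type beta regression of donor proportions on pathology group.

    Proportions are shrunk away from {0, 1} by (y (n-1) + 0.5) / n before the
    logit-link Beta fit; the reported row is the ``contrast`` group dummy
    (vs the 'low' reference).  Types observed in fewer than ``min_donors``
    donors are reported with ``excluded=True``; per-type non-convergence
    yields an NA row with ``converged=False``.  BH correction runs across the
    types actually tested.
    """
    props = ct.counts.div(ct.counts.sum(axis=1), axis=0)
    n = len(props)
    shrunk = (props * (n - 1) + 0.5) / n
    Xg, levels, Xn, nuis_names = _design_matrices(ct.design)
    if contrast not in levels:
        raise ValueError(f"contrast {contrast!r} not among group levels {levels}")
    exog = pd.DataFrame(
        np.column_stack([np.ones(n), Xg, Xn]),
        columns=["const"] + levels + nuis_names,
        index=props.index,
    )
    rows = []
    for ctype in ct.celltypes:
        observed_in = int((ct.counts[ctype] > 0).sum())
        if observed_in < min_donors:
            rows.append({"celltype": ctype, "coef": np.nan, "se": np.nan,
                         "z": np.nan, "p": np.nan, "excluded": True,
                         "converged": False, "n_donors_observed": observed_in})
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = BetaModel(shrunk[ctype].to_numpy(), exog.to_numpy())
                res = model.fit(disp=False)
            idx = list(exog.columns).index(contrast)
            coef = float(res.params[idx])
            se = float(res.bse[idx])
            z = coef / se if se > 0 else np.nan
            p = float(res.pvalues[idx])
            if not np.isfinite(p) and abs(coef) < 1e-5:
                p = 1.0  # degenerate (constant proportions): no group effect
            ok = np.isfinite(coef) and np.isfinite(p)
            rows.append({"celltype": ctype, "coef": coef, "se": se, "z": z,
                         "p": p, "excluded": False, "converged": ok,
                         "n_donors_observed": observed_in})
        except Exception:
            rows.append({"celltype": ctype, "coef": np.nan, "se": np.nan,
                         "z": np.nan, "p": np.nan, "excluded": False,
                         "converged": False, "n_donors_observed": observed_in})
    out = pd.DataFrame(rows).set_index("celltype")
    tested = out.index[(~out["excluded"]) & out["converged"]]
    out["fdr"] = np.nan
    if len(tested):
        out.loc[tested, "fdr"] = multipletests(
            out.loc[tested, "p"].to_numpy(), method="fdr_bh"
        )[1]
    return out
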