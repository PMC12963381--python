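"""Numba kernels for the two-part (hurdle) mixed differential-expression test.

Per gene the model has a detection part (penalized logistic regression of
expressed 0/1 on the design) and an expression part (penalized linear model
of log values among expressing cells).  The donor random intercept is fitted
by penalized quasi-likelihood: donor indicator columns enter with a ridge
penalty lambda = 1/sigma_u^2, with sigma_u^2 re-estimated from the fitted
donor effects over a few outer iterations.  Because donor indicators are
one-hot, the donor block of the working normal equations is diagonal and the
system is solved through its p x p Schur complement, keeping the per-gene
cost linear in cells.

The gene-level p-value is a chi-square test on the sum of the two parts'
penalized likelihood-ratio statistics for dropping the condition column
(2 df when both parts are estimable, 1 df otherwise).
"""

import math

import numpy as np
from numba import njit

MAX_ABS_COEF = 15.0  # logistic separation guard


@njit(cache=True)
def _solve_blocked(Sxx, Sxz, Du, rx, ru, beta, u):
    """Solve the [[Sxx, Sxz^T], [Sxz, diag(Du)]] system via Schur complement."""
    p = Sxx.shape[0]
    q = Du.shape[0]
    M = np.empty((p, p))
    r = np.empty(p)
    for a in range(p):
        r[a] = rx[a]
        for b in range(p):
            M[a, b] = Sxx[a, b]
    for d in range(q):
        inv = 1.0 / Du[d]
        for a in range(p):
            r[a] -= Sxz[d, a] * ru[d] * inv
            for b in range(p):
                M[a, b] -= Sxz[d, a] * Sxz[d, b] * inv
    sol = np.linalg.solve(M, r)
    for a in range(p):
        beta[a] = sol[a]
    for d in range(q):
        acc = ru[d]
        for a in range(p):
            acc -= Sxz[d, a] * beta[a]
        u[d] = acc / Du[d]


@njit(cache=True)
def _logistic_pql(y, X, donor, q, lam_init, use_donor, n_outer, beta, u):
    """Penalized-quasi-likelihood logistic fit; returns (pen_dev, lam, sep).

    ``lam_init <= 0`` means estimate lambda (= 1/sigma_u^2) by PQL outer
    iterations; a positive value holds it fixed (used for the reduced model).
    """
    n, p = X.shape
    if lam_init <= 0.0:  # cold start; fixed-lambda refits keep the warm start
        for a in range(p):
            beta[a] = 0.0
        for d in range(q):
            u[d] = 0.0
    lam = lam_init if lam_init > 0.0 else 2.0
    Sxx = np.empty((p, p))
    Sxz = np.empty((q, p))
    Du = np.empty(q)
    Dw = np.empty(q)
    rx = np.empty(p)
    ru = np.empty(q)
    outer = n_outer if (use_donor and lam_init <= 0.0) else 1
    pen_dev = 0.0
    for it_out in range(outer):
        for it in range(10):
            for a in range(p):
                rx[a] = 0.0
                for b in range(p):
                    Sxx[a, b] = 0.0
            for d in range(q):
                Du[d] = lam if use_donor else 1e10
                Dw[d] = 0.0
                ru[d] = 0.0
                for a in range(p):
                    Sxz[d, a] = 0.0
            for i in range(n):
                eta = 0.0
                for a in range(p):
                    eta += X[i, a] * beta[a]
                if use_donor:
                    eta += u[donor[i]]
                if eta > 25.0:
                    eta = 25.0
                elif eta < -25.0:
                    eta = -25.0
                mu = 1.0 / (1.0 + math.exp(-eta))
                w = mu * (1.0 - mu) + 1e-9
                zi = eta + (y[i] - mu) / w
                wz = w * zi
                d_i = donor[i]
                Dw[d_i] += w
                Du[d_i] += w
                ru[d_i] += wz
                for a in range(p):
                    xa = X[i, a]
                    rx[a] += wz * xa
                    Sxz[d_i, a] += w * xa
                    for b in range(a, p):
                        Sxx[a, b] += w * xa * X[i, b]
            for a in range(p):
                Sxx[a, a] += 1e-6
                for b in range(a):
                    Sxx[a, b] = Sxx[b, a]
            beta_old0 = beta[0]
            beta_old1 = beta[1] if p > 1 else 0.0
            _solve_blocked(Sxx, Sxz, Du, rx, ru, beta, u)
            if not use_donor:
                for d in range(q):
                    u[d] = 0.0
            delta = abs(beta[0] - beta_old0)
            if p > 1:
                d1 = abs(beta[1] - beta_old1)
                if d1 > delta:
                    delta = d1
            if delta < 1e-5:
                break
        if use_donor and lam_init <= 0.0:
            uu = 0.0
            q_eff = 0.0
            for d in range(q):
                uu += u[d] * u[d]
                q_eff += Dw[d] / (Dw[d] + lam)
            if q_eff < 1.0:
                q_eff = 1.0
            sigma2 = uu / q_eff
            if sigma2 < 1e-3:
                sigma2 = 1e-3
            if sigma2 > 25.0:
                sigma2 = 25.0
            lam = 1.0 / sigma2
    # penalized deviance
    pen_dev = 0.0
    for i in range(n):
        eta = 0.0
        for a in range(p):
            eta += X[i, a] * beta[a]
        if use_donor:
            eta += u[donor[i]]
        if eta > 25.0:
            eta = 25.0
        elif eta < -25.0:
            eta = -25.0
        mu = 1.0 / (1.0 + math.exp(-eta))
        if mu < 1e-12:
            mu = 1e-12
        if mu > 1.0 - 1e-12:
            mu = 1.0 - 1e-12
        pen_dev += -2.0 * (y[i] * math.log(mu) + (1.0 - y[i]) * math.log(1.0 - mu))
    if use_donor:
        for d in range(q):
            pen_dev += lam * u[d] * u[d]
    sep = 0.0
    for a in range(p):
        if abs(beta[a]) > MAX_ABS_COEF:
            sep = 1.0
    return pen_dev, lam, sep


@njit(cache=True)
def _linear_pql(y, X, donor, q, lam_init, use_donor, n_outer, beta, u):
    """Penalized linear fit among expressing cells; returns (PRSS, lam)."""
    n, p = X.shape
    lam = lam_init if lam_init > 0.0 else 2.0
    Sxx = np.empty((p, p))
    Sxz = np.empty((q, p))
    Du = np.empty(q)
    Dw = np.empty(q)
    rx = np.empty(p)
    ru = np.empty(q)
    outer = n_outer if (use_donor and lam_init <= 0.0) else 1
    for it_out in range(outer):
        for a in range(p):
            rx[a] = 0.0
            for b in range(p):
                Sxx[a, b] = 0.0
        for d in range(q):
            Du[d] = lam if use_donor else 1e10
            Dw[d] = 0.0
            ru[d] = 0.0
            for a in range(p):
                Sxz[d, a] = 0.0
        for i in range(n):
            d_i = donor[i]
            Dw[d_i] += 1.0
            Du[d_i] += 1.0
            ru[d_i] += y[i]
            for a in range(p):
                xa = X[i, a]
                rx[a] += y[i] * xa
                Sxz[d_i, a] += xa
                for b in range(a, p):
                    Sxx[a, b] += xa * X[i, b]
        for a in range(p):
            Sxx[a, a] += 1e-8
            for b in range(a):
                Sxx[a, b] = Sxx[b, a]
        _solve_blocked(Sxx, Sxz, Du, rx, ru, beta, u)
        if not use_donor:
            for d in range(q):
                u[d] = 0.0
        if use_donor and lam_init <= 0.0:
            rss = 0.0
            for i in range(n):
                pred = 0.0
                for a in range(p):
                    pred += X[i, a] * beta[a]
                pred += u[donor[i]]
                rss += (y[i] - pred) ** 2
            dof = n - p
            if dof < 1:
                dof = 1
            sigma_e2 = rss / dof
            if sigma_e2 < 1e-8:
                sigma_e2 = 1e-8
            uu = 0.0
            q_eff = 0.0
            for d in range(q):
                uu += u[d] * u[d]
                q_eff += Dw[d] / (Dw[d] + lam)
            if q_eff < 1.0:
                q_eff = 1.0
            sigma_u2 = uu / q_eff
            if sigma_u2 < 1e-4 * sigma_e2:
                sigma_u2 = 1e-4 * sigma_e2
            lam = sigma_e2 / sigma_u2
            if lam > 1e6:
                lam = 1e6
    prss = 0.0
    for i in range(n):
        pred = 0.0
        for a in range(p):
            pred += X[i, a] * beta[a]
        if use_donor:
            pred += u[donor[i]]
        prss += (y[i] - pred) ** 2
    if use_donor:
        for d in range(q):
            prss += lam * u[d] * u[d]
    return prss, lam


@njit(cache=True)
def hurdle_test_all(Y, E, X_full, X_red, cond_col, donor, q, use_donor):
    """Hurdle LRT for every gene.

    Y, E: genes x cells (log values; expressed 0/1).  X_full includes the
    condition column at ``cond_col``; X_red is the same design without it.
    Returns (logfc, pvals, df_used, flags) with flags 1 = logistic
    separation (p set to NaN), 2 = insufficient expressing cells for the
    continuous part.
    """
    G, n = Y.shape
    p = X_full.shape[1]
    pr = X_red.shape[1]
    logfc = np.full(G, np.nan)
    stat = np.full(G, np.nan)
    dfs = np.zeros(G)
    flags = np.zeros(G)

    beta_f = np.empty(p)
    beta_r = np.empty(pr)
    u_f = np.empty(q)
    u_r = np.empty(q)

    for g in range(G):
        lr_total = 0.0
        df = 0.0
        sep = 0.0
        # ---------- detection part
        n_pos = 0
        for i in range(n):
            if E[g, i] > 0.5:
                n_pos += 1
        if 0 < n_pos < n:
            dev_f, lam, sep = _logistic_pql(E[g], X_full, donor, q, -1.0,
                                            use_donor, 2, beta_f, u_f)
            if sep == 0.0:
                j = 0
                for a in range(p):
                    if a != cond_col:
                        beta_r[j] = beta_f[a]
                        j += 1
                for d in range(q):
                    u_r[d] = u_f[d]
                dev_r, _, _ = _logistic_pql(E[g], X_red, donor, q, lam,
                                            use_donor, 1, beta_r, u_r)
                lr = dev_r - dev_f
                if lr < 0.0:
                    lr = 0.0
                lr_total += lr
                df += 1.0
        # ---------- expression part (expressing cells only)
        if sep == 0.0 and n_pos >= p + 2:
            ysub = np.empty(n_pos)
            Xsub = np.empty((n_pos, p))
            Xsub_r = np.empty((n_pos, pr))
            dsub = np.empty(n_pos, dtype=np.int64)
            j = 0
            for i in range(n):
                if E[g, i] > 0.5:
                    ysub[j] = Y[g, i]
                    for a in range(p):
                        Xsub[j, a] = X_full[i, a]
                    for a in range(pr):
                        Xsub_r[j, a] = X_red[i, a]
                    dsub[j] = donor[i]
                    j += 1
            prss_f, lam_c = _linear_pql(ysub, Xsub, dsub, q, -1.0, use_donor, 2,
                                        beta_f, u_f)
            prss_r, _ = _linear_pql(ysub, Xsub_r, dsub, q, lam_c, use_donor, 1,
                                    beta_r, u_r)
            if prss_f < 1e-12:
                prss_f = 1e-12
            if prss_r < prss_f:
                prss_r = prss_f
            lr_total += n_pos * math.log(prss_r / prss_f)
            df += 1.0
            logfc[g] = beta_f[cond_col]
        else:
            flags[g] += 2.0
        if sep > 0.0:
            flags[g] += 1.0
            stat[g] = np.nan
            dfs[g] = 0.0
        elif df > 0.0:
            stat[g] = lr_total
            dfs[g] = df
    return logfc, stat, dfs, flags
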