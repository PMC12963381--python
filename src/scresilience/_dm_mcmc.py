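"""Numba kernels for the Dirichlet-multinomial compositional sampler.

Model (one donor d, K cell types, total n_d):

    counts_d ~ DirichletMultinomial(n_d, alpha_d)
    alpha_d  = phi * softmax(a + x_d B),   B[:, reference] = 0

so phi is the total concentration (donor-level overdispersion) and the
softmax makes the likelihood exactly invariant to adding a constant to all
type logits (compositional closure).  Group-effect coefficients carry a
spike-and-slab prior (point mass at zero + Normal slab) whose inclusion
indicators are Gibbs-sampled; nuisance covariates (sex, APOE, assay, age)
carry plain Normal priors.  Continuous parameters are sampled by Hamiltonian
Monte Carlo with dual-averaging step-size adaptation during warmup.

In the constrained ("loss-only") variant the group coefficients are
reparameterized as beta = -|b| with b Gaussian (a folded-normal magnitude,
i.e. HalfNormal prior on |beta|), so every posterior draw satisfies
beta <= 0 exactly while HMC moves on an unconstrained, well-mixing scale.
"""

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------- likelihood


@njit(cache=True)
def _loglik_logits(counts, n_d, logits, lphi):
    """DM log-likelihood given precomputed type logits (D x K)."""
    D, K = counts.shape
    phi = math.exp(lphi)
    if phi < 1e-8 or not np.isfinite(phi):  # off-support excursion; step rejected
        return -1e300
    total = 0.0
    for d in range(D):
        m = logits[d, 0]
        for k in range(1, K):
            if logits[d, k] > m:
                m = logits[d, k]
        s = 0.0
        for k in range(K):
            s += math.exp(logits[d, k] - m)
        total += math.lgamma(phi) - math.lgamma(n_d[d] + phi)
        for k in range(K):
            alpha = phi * math.exp(logits[d, k] - m) / s
            if alpha < 1e-12:  # underflow guard; the step is rejected anyway
                alpha = 1e-12
            total += math.lgamma(counts[d, k] + alpha) - math.lgamma(alpha)
    return total


@njit(cache=True)
def _grad_logits(counts, n_d, logits, lphi, grad_logits, out_glphi):
    """Gradient of the DM log-likelihood wrt logits and log phi.

    Writes the logit gradient into ``grad_logits`` and returns the log-phi
    gradient.  Uses d/dalpha = digamma(x + alpha) - digamma(alpha).
    """
    D, K = counts.shape
    phi = math.exp(lphi)
    if phi < 1e-8 or not np.isfinite(phi):
        for d in range(counts.shape[0]):
            for k in range(counts.shape[1]):
                grad_logits[d, k] = 0.0
        out_glphi[0] = 0.0
        return 0.0
    glphi = 0.0
    for d in range(D):
        m = logits[d, 0]
        for k in range(1, K):
            if logits[d, k] > m:
                m = logits[d, k]
        s = 0.0
        for k in range(K):
            s += math.exp(logits[d, k] - m)
        dot = 0.0
        for k in range(K):
            p = math.exp(logits[d, k] - m) / s
            alpha = phi * p
            if alpha < 1e-12:
                alpha = 1e-12
            g = _digamma(counts[d, k] + alpha) - _digamma(alpha)
            grad_logits[d, k] = g * p  # temp store g*p
            dot += g * p
        for k in range(K):
            p = math.exp(logits[d, k] - m) / s
            g_p = grad_logits[d, k]
            grad_logits[d, k] = phi * (g_p - p * dot)
        glphi += phi * (dot + _digamma(phi) - _digamma(n_d[d] + phi))
    out_glphi[0] = glphi
    return glphi


@njit(cache=True)
def _digamma(x):
    """Digamma via upward recurrence + asymptotic series (x > 0)."""
    result = 0.0
    while x < 6.0:
        result -= 1.0 / x
        x += 1.0
    inv = 1.0 / x
    inv2 = inv * inv
    result += (
        math.log(x)
        - 0.5 * inv
        - inv2 * (1.0 / 12.0 - inv2 * (1.0 / 120.0 - inv2 / 252.0))
    )
    return result


# ------------------------------------------------------------------ sampler
#
# Parameter vector layout (n_free = K + Jg*(K-1) + Jn*(K-1) + 1):
#   theta[0:K]                     intercepts a
#   theta[K : K+Jg*(K-1)]          group coefficients (slab values b, or gamma
#                                  in constrained mode), reference type absent
#   theta[... : ...+Jn*(K-1)]      nuisance coefficients
#   theta[-1]                      log phi


@njit(cache=True)
def _nonref_col(k, ref):
    """Column index of type k among non-reference types."""
    if k < ref:
        return k
    return k - 1


@njit(cache=True)
def _logits_from_theta(theta, z, Xg, Xn, K, ref, constrained, logits):
    D = Xg.shape[0]
    Jg = Xg.shape[1]
    Jn = Xn.shape[1]
    for d in range(D):
        for k in range(K):
            eta = theta[k]
            if k != ref:
                c = _nonref_col(k, ref)
                for j in range(Jg):
                    b = theta[K + j * (K - 1) + c]
                    if constrained:
                        b = -abs(b)
                    else:
                        b = b * z[j * (K - 1) + c]
                    eta += Xg[d, j] * b
                base = K + Jg * (K - 1)
                for j in range(Jn):
                    eta += Xn[d, j] * theta[base + j * (K - 1) + c]
            logits[d, k] = eta


@njit(cache=True)
def _log_prior(theta, z, K, Jg, Jn, constrained, intercept_sd, slab_sd, nuisance_sd,
               hn_scale, lphi_mu, lphi_sd):
    lp = 0.0
    for k in range(K):
        lp += -0.5 * (theta[k] / intercept_sd) ** 2
    for i in range(Jg * (K - 1)):
        t = theta[K + i]
        if constrained:
            # beta = -|b| with b ~ Normal(0, hn_scale^2): |b| is HalfNormal
            lp += -0.5 * (t / hn_scale) ** 2
        else:
            lp += -0.5 * (t / slab_sd) ** 2
    base = K + Jg * (K - 1)
    for i in range(Jn * (K - 1)):
        lp += -0.5 * (theta[base + i] / nuisance_sd) ** 2
    lp += -0.5 * ((theta[-1] - lphi_mu) / lphi_sd) ** 2
    return lp


@njit(cache=True)
def _grad_posterior(theta, z, counts, n_d, Xg, Xn, K, ref, constrained,
                    intercept_sd, slab_sd, nuisance_sd, hn_scale,
                    lphi_mu, lphi_sd, logits, glogits, grad):
    """Gradient of log posterior wrt theta; returns log posterior value."""
    D = Xg.shape[0]
    Jg = Xg.shape[1]
    Jn = Xn.shape[1]
    _logits_from_theta(theta, z, Xg, Xn, K, ref, constrained, logits)
    ll = _loglik_logits(counts, n_d, logits, theta[-1])
    tmp = np.zeros(1)
    _grad_logits(counts, n_d, logits, theta[-1], glogits, tmp)
    for i in range(grad.shape[0]):
        grad[i] = 0.0
    # intercepts
    for k in range(K):
        s = 0.0
        for d in range(D):
            s += glogits[d, k]
        grad[k] = s - theta[k] / intercept_sd**2
    # group coefficients
    for j in range(Jg):
        for k in range(K):
            if k == ref:
                continue
            c = _nonref_col(k, ref)
            i = K + j * (K - 1) + c
            s = 0.0
            for d in range(D):
                s += Xg[d, j] * glogits[d, k]
            if constrained:
                # beta = -|b|; d beta / d b = -sign(b)
                sign = 1.0 if theta[i] >= 0.0 else -1.0
                grad[i] = s * (-sign) - theta[i] / hn_scale**2
            else:
                grad[i] = s * z[j * (K - 1) + c] - theta[i] / slab_sd**2
    # nuisance coefficients
    base = K + Jg * (K - 1)
    for j in range(Jn):
        for k in range(K):
            if k == ref:
                continue
            c = _nonref_col(k, ref)
            i = base + j * (K - 1) + c
            s = 0.0
            for d in range(D):
                s += Xn[d, j] * glogits[d, k]
            grad[i] = s - theta[i] / nuisance_sd**2
    # log phi
    grad[grad.shape[0] - 1] = tmp[0] - (theta[-1] - lphi_mu) / lphi_sd**2
    lp = ll + _log_prior(theta, z, K, Jg, Jn, constrained, intercept_sd, slab_sd,
                         nuisance_sd, hn_scale, lphi_mu, lphi_sd)
    return lp


@njit(cache=True)
def run_chain(counts, n_d, Xg, Xn, ref, constrained, warmup, samples, seed,
              n_leapfrog, intercept_sd, slab_sd, nuisance_sd, hn_scale,
              lphi_mu, lphi_sd, inclusion_prob):
    """One MCMC chain; returns (theta_draws, z_draws, accept_rate, divergences)."""
    np.random.seed(seed)
    D, K = counts.shape
    Jg = Xg.shape[1]
    Jn = Xn.shape[1]
    n_free = K + (Jg + Jn) * (K - 1) + 1
    nz = Jg * (K - 1)

    theta = np.zeros(n_free)
    theta[-1] = lphi_mu
    if constrained:
        for i in range(nz):
            theta[K + i] = 0.1  # small initial loss magnitudes
    z = np.ones(nz)
    if not constrained:
        for i in range(nz):
            z[i] = 1.0 if np.random.random() < inclusion_prob else 0.0

    logits = np.zeros((D, K))
    glogits = np.zeros((D, K))
    grad = np.zeros(n_free)
    grad_new = np.zeros(n_free)

    # dual averaging (Nesterov) targeting 0.8 acceptance
    eps = 0.02
    log_eps_bar = math.log(eps)
    h_bar = 0.0
    mu_da = math.log(10.0 * eps)
    gamma_da = 0.05
    t0 = 10.0
    kappa = 0.75
    target = 0.8

    theta_draws = np.zeros((samples, n_free))
    z_draws = np.zeros((samples, nz))
    n_accept = 0
    n_total = 0
    divergences = 0

    lp = _grad_posterior(theta, z, counts, n_d, Xg, Xn, K, ref, constrained,
                         intercept_sd, slab_sd, nuisance_sd, hn_scale,
                         lphi_mu, lphi_sd, logits, glogits, grad)

    for it in range(warmup + samples):
        # ---- HMC update of continuous parameters
        p = np.empty(n_free)
        for i in range(n_free):
            p[i] = np.random.normal()
        ham0 = -lp
        for i in range(n_free):
            ham0 += 0.5 * p[i] * p[i]
        theta_new = theta.copy()
        for i in range(n_free):
            grad_new[i] = grad[i]
        lp_new = lp
        diverged = False
        for step in range(n_leapfrog):
            for i in range(n_free):
                p[i] += 0.5 * eps * grad_new[i]
                theta_new[i] += eps * p[i]
            lp_new = _grad_posterior(theta_new, z, counts, n_d, Xg, Xn, K, ref,
                                     constrained, intercept_sd, slab_sd,
                                     nuisance_sd, hn_scale, lphi_mu, lphi_sd,
                                     logits, glogits, grad_new)
            for i in range(n_free):
                p[i] += 0.5 * eps * grad_new[i]
            if not np.isfinite(lp_new):
                diverged = True
                break
        if diverged:
            accept_prob = 0.0
            divergences += 1
        else:
            ham1 = -lp_new
            for i in range(n_free):
                ham1 += 0.5 * p[i] * p[i]
            d_ham = ham0 - ham1
            if d_ham > 0.0:
                accept_prob = 1.0
            else:
                accept_prob = math.exp(d_ham)
            if d_ham < -1000.0:
                divergences += 1
        if np.random.random() < accept_prob:
            for i in range(n_free):
                theta[i] = theta_new[i]
                grad[i] = grad_new[i]
            lp = lp_new
            if it >= warmup:
                n_accept += 1
        if it >= warmup:
            n_total += 1
        # step-size adaptation during warmup
        if it < warmup:
            m = it + 1
            h_bar = (1.0 - 1.0 / (m + t0)) * h_bar + (target - accept_prob) / (m + t0)
            log_eps = mu_da - math.sqrt(m) / gamma_da * h_bar
            w = m ** (-kappa)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = math.exp(log_eps)
            if it == warmup - 1:
                eps = math.exp(log_eps_bar)

        # ---- Gibbs update of inclusion indicators (unconstrained only)
        if not constrained:
            _logits_from_theta(theta, z, Xg, Xn, K, ref, constrained, logits)
            ll_cur = _loglik_logits(counts, n_d, logits, theta[-1])
            for i in range(nz):
                z_old = z[i]
                z[i] = 1.0 - z_old
                _logits_from_theta(theta, z, Xg, Xn, K, ref, constrained, logits)
                ll_flip = _loglik_logits(counts, n_d, logits, theta[-1])
                if z_old == 1.0:
                    ll1, ll0 = ll_cur, ll_flip
                else:
                    ll1, ll0 = ll_flip, ll_cur
                log_odds = (
                    math.log(inclusion_prob) - math.log(1.0 - inclusion_prob) + ll1 - ll0
                )
                p1 = 1.0 / (1.0 + math.exp(-log_odds))
                z_new = 1.0 if np.random.random() < p1 else 0.0
                if z_new == z_old:
                    z[i] = z_old
                    # ll_cur unchanged
                else:
                    z[i] = z_new
                    ll_cur = ll_flip
            # inactive slab values have the prior as full conditional; refresh
            for i in range(nz):
                if z[i] == 0.0:
                    theta[K + i] = slab_sd * np.random.normal()
            # refresh cached posterior gradient for the (possibly) new z
            lp = _grad_posterior(theta, z, counts, n_d, Xg, Xn, K, ref, constrained,
                                 intercept_sd, slab_sd, nuisance_sd, hn_scale,
                                 lphi_mu, lphi_sd, logits, glogits, grad)

        if it >= warmup:
            s = it - warmup
            for i in range(n_free):
                theta_draws[s, i] = theta[i]
            for i in range(nz):
                z_draws[s, i] = z[i]

    accept_rate = n_accept / max(n_total, 1)
    return theta_draws, z_draws, accept_rate, divergences
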