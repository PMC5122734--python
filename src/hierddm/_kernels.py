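"""Numba kernels: Wiener first-passage density, trial simulation, MCMC sweep.

Everything in this module works on plain float/ndarray state so it can be
jit-compiled; the public API wraps these in validated, documented functions.
All times are in seconds and the diffusion coefficient is fixed at s = 1.
"""

import math

import numpy as np
from numba import njit

# default absolute truncation error for the density series
DENSITY_TOL = 1e-7


@njit(cache=False)
def fpt_density_std(t, w, eps):
    """First-passage density at the lower bound of a unit, driftless process.

    Boundaries at 0 and 1, start at w, evaluated at normalized time t.  Uses
    the small-time or large-time series expansion, whichever needs fewer
    terms for truncation error eps (both series are exact in the limit).
    """
    if t <= 0.0:
        return 0.0
    # terms required by the small-time expansion
    if 2.0 * math.sqrt(2.0 * math.pi * t) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * t * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * t)))
        if ks < math.sqrt(t) + 1.0:
            ks = math.sqrt(t) + 1.0
    else:
        ks = 2.0
    # terms required by the large-time expansion
    if math.pi * t * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * t * eps) / (math.pi * math.pi * t))
        if kl < 1.0 / (math.pi * math.sqrt(t)):
            kl = 1.0 / (math.pi * math.sqrt(t))
    else:
        kl = 1.0 / (math.pi * math.sqrt(t))

    if ks < kl:  # small-time branch
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) - (K - 1) // 2
        acc = 0.0
        for k in range(lo, hi + 1):
            x = w + 2.0 * k
            acc += x * math.exp(-x * x / (2.0 * t))
        acc /= math.sqrt(2.0 * math.pi * t * t * t)
    else:  # large-time branch
        K = int(math.ceil(kl))
        acc = 0.0
        for k in range(1, K + 1):
            acc += k * math.exp(-k * k * math.pi * math.pi * t / 2.0) * math.sin(k * math.pi * w)
        acc *= math.pi
    if acc < 0.0:  # series tails can leave a tiny negative residue
        acc = 0.0
    return acc


@njit(cache=False)
def wfpt_logpdf(rt, upper, t_nd, a, v, w, tol):
    """Log of the defective FPT density at one boundary of the full process.

    Drift v, boundaries [0, a], start w*a, diffusion 1, non-decision time
    t_nd.  ``upper`` selects the boundary; the upper-boundary density is the
    lower-boundary density of the reflected process (w -> 1-w, v -> -v).
    Returns -inf for rt <= t_nd (a response cannot precede the non-decision
    time) and for out-of-domain parameters.
    """
    u = rt - t_nd
    if u <= 0.0 or a <= 0.0 or w <= 0.0 or w >= 1.0 or t_nd < 0.0:
        return -np.inf
    if upper:
        vv = -v
        ww = 1.0 - w
    else:
        vv = v
        ww = w
    # scale factor between the normalized density and the full one
    log_scale = -2.0 * math.log(a) - vv * a * ww - vv * vv * u / 2.0
    # truncation error of the normalized series is inflated by exp(log_scale),
    # so request eps that keeps the *full* density error below tol
    eps = tol * math.exp(min(-log_scale, 30.0))
    if eps > 1e-3:
        eps = 1e-3
    p = fpt_density_std(u / (a * a), ww, eps)
    if p <= 0.0:
        return -np.inf
    return math.log(p) + log_scale


@njit(cache=False)
def loglik_subject(rts, uppers, t_nd, a, v, tol):
    """Summed trial log-likelihood for one subject (z fixed at 0.5)."""
    total = 0.0
    for i in range(rts.shape[0]):
        lp = wfpt_logpdf(rts[i], uppers[i] == 1, t_nd, a, v, 0.5, tol)
        if lp == -np.inf:
            return -np.inf
        total += lp
    return total


@njit(cache=False)
def simulate_euler(n, t_nd, a, v, w, dt, deadline, seed):
    """Euler–Maruyama simulation of n trials.

    Returns (rt, boundary) with boundary 1 = upper, 0 = lower, -1 = deadline
    hit (rt is NaN for those).  deadline <= 0 means no deadline.
    """
    np.random.seed(seed)
    rts = np.empty(n)
    boundary = np.empty(n, dtype=np.int8)
    sq = math.sqrt(dt)
    # drawing normals in blocks is several times faster than one at a time
    buf = np.random.standard_normal(8192)
    pos = 0
    for i in range(n):
        x = w * a
        tcur = 0.0
        while True:
            if pos == 8192:
                buf = np.random.standard_normal(8192)
                pos = 0
            x += v * dt + sq * buf[pos]
            pos += 1
            tcur += dt
            if x >= a:
                rts[i] = t_nd + tcur
                boundary[i] = 1
                break
            if x <= 0.0:
                rts[i] = t_nd + tcur
                boundary[i] = 0
                break
            if deadline > 0.0 and t_nd + tcur > deadline:
                rts[i] = np.nan
                boundary[i] = -1
                break
    return rts, boundary


# ---------------------------------------------------------------------------
# hierarchical-model log densities (shared by the posterior and the sampler)
# ---------------------------------------------------------------------------

LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@njit(cache=False)
def norm_logpdf(x, loc, scale):
    z = (x - loc) / scale
    return -0.5 * z * z - math.log(scale) - LOG_SQRT_2PI


@njit(cache=False)
def std_norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@njit(cache=False)
def truncnorm_logpdf(x, loc, scale, lower):
    """Normal(loc, scale) truncated to [lower, inf); lower=-inf => plain normal."""
    if x < lower:
        return -np.inf
    lp = norm_logpdf(x, loc, scale)
    if lower == -np.inf:
        return lp
    z = 1.0 - std_norm_cdf((lower - loc) / scale)
    if z <= 0.0:
        return -np.inf
    return lp - math.log(z)


@njit(cache=False)
def halfnorm_logpdf(x, scale):
    if x <= 0.0:
        return -np.inf
    return norm_logpdf(x, 0.0, scale) + math.log(2.0)


@njit(cache=False)
def log_posterior_task(rts, uppers, subj_start, subj_end, subj_group,
                       theta, mu, sigma,
                       mu_prior_loc, mu_prior_scale, mu_lower,
                       sigma_prior_scale, param_lower, tol):
    """Joint log posterior of one task's hierarchy.

    theta: (S, 3) per-subject (t, a, v); mu, sigma: (G, 3) group locations
    and spreads; param_lower: domain lower bound per parameter (0, 0, -inf);
    mu_lower: prior truncation per parameter.  Returns -inf off-domain.
    """
    G, P = mu.shape
    total = 0.0
    for g in range(G):
        for p in range(P):
            if sigma[g, p] <= 0.0:
                return -np.inf
            total += truncnorm_logpdf(mu[g, p], mu_prior_loc[p], mu_prior_scale[p], mu_lower[p])
            total += halfnorm_logpdf(sigma[g, p], sigma_prior_scale[p])
    if total == -np.inf:
        return -np.inf
    S = theta.shape[0]
    for i in range(S):
        g = subj_group[i]
        for p in range(P):
            lp = truncnorm_logpdf(theta[i, p], mu[g, p], sigma[g, p], param_lower[p])
            if lp == -np.inf:
                return -np.inf
            total += lp
        ll = loglik_subject(rts[subj_start[i]:subj_end[i]],
                            uppers[subj_start[i]:subj_end[i]],
                            theta[i, 0], theta[i, 1], theta[i, 2], tol)
        if ll == -np.inf:
            return -np.inf
        total += ll
    return total


@njit(cache=False)
def run_mcmc_task(rts, uppers, subj_start, subj_end, subj_group, n_groups,
                  theta0, mu0, sigma0,
                  mu_prior_loc, mu_prior_scale, mu_lower,
                  sigma_prior_scale, param_lower,
                  n_iter, adapt_until, target_acc, seed, tol):
    """Adaptive Metropolis-within-Gibbs over one task's hierarchy.

    Scalar random-walk updates for every subject-level parameter and every
    group location; log-scale random-walk for group spreads.  Proposal scales
    adapt toward target_acc only while iteration < adapt_until, so the
    post-adaptation chain is a valid Markov chain.  Draws are stored for
    every iteration in the layout [mu (G*3), sigma (G*3), theta (S*3)].
    """
    np.random.seed(seed)
    S = theta0.shape[0]
    G = n_groups
    P = 3
    theta = theta0.copy()
    mu = mu0.copy()
    sigma = sigma0.copy()

    n_par = G * P * 2 + S * P
    draws = np.empty((n_iter, n_par))

    # cached per-subject trial log-likelihood
    cur_ll = np.empty(S)
    for i in range(S):
        cur_ll[i] = loglik_subject(rts[subj_start[i]:subj_end[i]],
                                   uppers[subj_start[i]:subj_end[i]],
                                   theta[i, 0], theta[i, 1], theta[i, 2], tol)

    # proposal scales and acceptance bookkeeping per scalar block
    th_scale = np.full((S, P), 0.08)
    mu_scale = np.full((G, P), 0.05)
    sg_scale = np.full((G, P), 0.15)  # on log sigma
    tr_scale = np.full((G, P), 0.05)  # group translation moves
    av_scale = np.full(S, 0.10)       # joint (a, v) scale moves
    gv_scale = np.full(G, 0.05)       # group-level joint (a, v) scale moves
    fn_scale = np.full((G, P), 0.20)  # funnel (spread + deviations) moves
    th_acc = np.zeros((S, P))
    mu_acc = np.zeros((G, P))
    sg_acc = np.zeros((G, P))
    tr_acc = np.zeros((G, P))
    av_acc = np.zeros(S)
    gv_acc = np.zeros(G)
    fn_acc = np.zeros((G, P))
    th_tot = np.zeros((S, P))
    mu_tot = np.zeros((G, P))
    sg_tot = np.zeros((G, P))
    tr_tot = np.zeros((G, P))
    av_tot = np.zeros(S)
    gv_tot = np.zeros(G)
    fn_tot = np.zeros((G, P))
    window = 25

    for it in range(n_iter):
        # --- subject-level parameters -----------------------------------
        for i in range(S):
            g = subj_group[i]
            for p in range(P):
                old = theta[i, p]
                prop = old + th_scale[i, p] * np.random.standard_normal()
                th_tot[i, p] += 1.0
                if prop < param_lower[p]:
                    continue
                # truncation normalizer is shared between old and prop
                dprior = (norm_logpdf(prop, mu[g, p], sigma[g, p])
                          - norm_logpdf(old, mu[g, p], sigma[g, p]))
                theta[i, p] = prop
                new_ll = loglik_subject(rts[subj_start[i]:subj_end[i]],
                                        uppers[subj_start[i]:subj_end[i]],
                                        theta[i, 0], theta[i, 1], theta[i, 2], tol)
                if new_ll == -np.inf:
                    theta[i, p] = old
                    continue
                logr = new_ll - cur_ll[i] + dprior
                if logr >= 0.0 or math.log(np.random.random()) < logr:
                    cur_ll[i] = new_ll
                    th_acc[i, p] += 1.0
                else:
                    theta[i, p] = old
            # joint (a, v) scale move: multiplies both by exp(eps), walking
            # along the weakly identified ridge at near-ceiling accuracy
            eps = av_scale[i] * np.random.standard_normal()
            av_tot[i] += 1.0
            c = math.exp(eps)
            a_new = theta[i, 1] * c
            v_new = theta[i, 2] * c
            new_ll = loglik_subject(rts[subj_start[i]:subj_end[i]],
                                    uppers[subj_start[i]:subj_end[i]],
                                    theta[i, 0], a_new, v_new, tol)
            if new_ll > -np.inf:
                logr = new_ll - cur_ll[i] + 2.0 * eps  # Jacobian of the scaling
                logr += (truncnorm_logpdf(a_new, mu[g, 1], sigma[g, 1], param_lower[1])
                         - truncnorm_logpdf(theta[i, 1], mu[g, 1], sigma[g, 1], param_lower[1])
                         + norm_logpdf(v_new, mu[g, 2], sigma[g, 2])
                         - norm_logpdf(theta[i, 2], mu[g, 2], sigma[g, 2]))
                if logr >= 0.0 or math.log(np.random.random()) < logr:
                    theta[i, 1] = a_new
                    theta[i, 2] = v_new
                    cur_ll[i] = new_ll
                    av_acc[i] += 1.0

        # --- group locations and spreads --------------------------------
        for g in range(G):
            for p in range(P):
                # location
                old = mu[g, p]
                prop = old + mu_scale[g, p] * np.random.standard_normal()
                mu_tot[g, p] += 1.0
                lp_new = truncnorm_logpdf(prop, mu_prior_loc[p], mu_prior_scale[p], mu_lower[p])
                if lp_new > -np.inf:
                    lp_old = truncnorm_logpdf(old, mu_prior_loc[p], mu_prior_scale[p], mu_lower[p])
                    logr = lp_new - lp_old
                    for i in range(S):
                        if subj_group[i] == g:
                            logr += (truncnorm_logpdf(theta[i, p], prop, sigma[g, p], param_lower[p])
                                     - truncnorm_logpdf(theta[i, p], old, sigma[g, p], param_lower[p]))
                    if logr >= 0.0 or math.log(np.random.random()) < logr:
                        mu[g, p] = prop
                        mu_acc[g, p] += 1.0
                # spread (random walk on log sigma, Jacobian included)
                old_s = sigma[g, p]
                prop_s = old_s * math.exp(sg_scale[g, p] * np.random.standard_normal())
                sg_tot[g, p] += 1.0
                logr = (halfnorm_logpdf(prop_s, sigma_prior_scale[p])
                        - halfnorm_logpdf(old_s, sigma_prior_scale[p])
                        + math.log(prop_s) - math.log(old_s))
                for i in range(S):
                    if subj_group[i] == g:
                        logr += (truncnorm_logpdf(theta[i, p], mu[g, p], prop_s, param_lower[p])
                                 - truncnorm_logpdf(theta[i, p], mu[g, p], old_s, param_lower[p]))
                if logr >= 0.0 or math.log(np.random.random()) < logr:
                    sigma[g, p] = prop_s
                    sg_acc[g, p] += 1.0
                # translation move: shift the location and every subject in
                # the group together, decoupling mu from its individuals
                delta = tr_scale[g, p] * np.random.standard_normal()
                tr_tot[g, p] += 1.0
                mu_new = mu[g, p] + delta
                lp_new = truncnorm_logpdf(mu_new, mu_prior_loc[p], mu_prior_scale[p], mu_lower[p])
                if lp_new > -np.inf:
                    logr = lp_new - truncnorm_logpdf(mu[g, p], mu_prior_loc[p],
                                                     mu_prior_scale[p], mu_lower[p])
                    new_lls = np.empty(S)
                    ok = True
                    for i in range(S):
                        if subj_group[i] != g:
                            continue
                        x_new = theta[i, p] + delta
                        dpr = (truncnorm_logpdf(x_new, mu_new, sigma[g, p], param_lower[p])
                               - truncnorm_logpdf(theta[i, p], mu[g, p], sigma[g, p], param_lower[p]))
                        if dpr == -np.inf:
                            ok = False
                            break
                        t_i = theta[i, 0] + delta if p == 0 else theta[i, 0]
                        a_i = theta[i, 1] + delta if p == 1 else theta[i, 1]
                        v_i = theta[i, 2] + delta if p == 2 else theta[i, 2]
                        ll = loglik_subject(rts[subj_start[i]:subj_end[i]],
                                            uppers[subj_start[i]:subj_end[i]],
                                            t_i, a_i, v_i, tol)
                        if ll == -np.inf:
                            ok = False
                            break
                        new_lls[i] = ll
                        logr += dpr + ll - cur_ll[i]
                    if ok and (logr >= 0.0 or math.log(np.random.random()) < logr):
                        mu[g, p] = mu_new
                        for i in range(S):
                            if subj_group[i] == g:
                                theta[i, p] += delta
                                cur_ll[i] = new_lls[i]
                        tr_acc[g, p] += 1.0

        # --- funnel moves: scale a spread and its subjects' deviations ---
        # sigma' = c sigma, theta_i' = mu + c (theta_i - mu); frees the
        # sampler from the funnel neck when individual values are weakly
        # identified (a and v only; t is data-dominated and needs none)
        for g in range(G):
            for p in range(1, 3):
                eps = fn_scale[g, p] * np.random.standard_normal()
                fn_tot[g, p] += 1.0
                c = math.exp(eps)
                sig_new = sigma[g, p] * c
                logr = (halfnorm_logpdf(sig_new, sigma_prior_scale[p])
                        - halfnorm_logpdf(sigma[g, p], sigma_prior_scale[p]))
                if logr == -np.inf:
                    continue
                n_g = 0
                ok = True
                new_lls = np.empty(S)
                new_vals = np.empty(S)
                for i in range(S):
                    if subj_group[i] != g:
                        continue
                    n_g += 1
                    x_new = mu[g, p] + c * (theta[i, p] - mu[g, p])
                    dpr = (truncnorm_logpdf(x_new, mu[g, p], sig_new, param_lower[p])
                           - truncnorm_logpdf(theta[i, p], mu[g, p], sigma[g, p], param_lower[p]))
                    if dpr == -np.inf:
                        ok = False
                        break
                    t_i = theta[i, 0]
                    a_i = x_new if p == 1 else theta[i, 1]
                    v_i = x_new if p == 2 else theta[i, 2]
                    ll = loglik_subject(rts[subj_start[i]:subj_end[i]],
                                        uppers[subj_start[i]:subj_end[i]],
                                        t_i, a_i, v_i, tol)
                    if ll == -np.inf:
                        ok = False
                        break
                    new_lls[i] = ll
                    new_vals[i] = x_new
                    logr += dpr + ll - cur_ll[i]
                if not ok or n_g == 0:
                    continue
                logr += (n_g + 1.0) * eps  # Jacobian of the joint scaling
                if logr >= 0.0 or math.log(np.random.random()) < logr:
                    sigma[g, p] = sig_new
                    for i in range(S):
                        if subj_group[i] == g:
                            theta[i, p] = new_vals[i]
                            cur_ll[i] = new_lls[i]
                    fn_acc[g, p] += 1.0

        # --- group-level joint (a, v) scaling ---------------------------
        # multiplies a whole group's locations, spreads and subject values
        # for a and v by exp(eps): the slowest collective mode when
        # accuracy is at ceiling and only the a/v ratio is well identified
        for g in range(G):
            eps = gv_scale[g] * np.random.standard_normal()
            gv_tot[g] += 1.0
            c = math.exp(eps)
            n_g = 0
            logr = 0.0
            ok = True
            new_lls = np.empty(S)
            for i in range(S):
                if subj_group[i] != g:
                    continue
                n_g += 1
                ll = loglik_subject(rts[subj_start[i]:subj_end[i]],
                                    uppers[subj_start[i]:subj_end[i]],
                                    theta[i, 0], theta[i, 1] * c, theta[i, 2] * c, tol)
                if ll == -np.inf:
                    ok = False
                    break
                new_lls[i] = ll
                logr += ll - cur_ll[i]
            if not ok or n_g == 0:
                continue
            # hyperprior ratios for the scaled group-level quantities
            for p in range(1, 3):
                lp_new = truncnorm_logpdf(mu[g, p] * c, mu_prior_loc[p],
                                          mu_prior_scale[p], mu_lower[p])
                if lp_new == -np.inf:
                    ok = False
                    break
                logr += lp_new - truncnorm_logpdf(mu[g, p], mu_prior_loc[p],
                                                  mu_prior_scale[p], mu_lower[p])
                logr += (halfnorm_logpdf(sigma[g, p] * c, sigma_prior_scale[p])
                         - halfnorm_logpdf(sigma[g, p], sigma_prior_scale[p]))
            if not ok:
                continue
            # individual densities: truncnorm(c x; c mu, c sigma) at a lower
            # bound of 0 rescales by 1/c per term, i.e. -2 n_g eps in total
            logr += -2.0 * n_g * eps
            # Jacobian of scaling 2 locations, 2 spreads and 2 n_g subject values
            logr += (4.0 + 2.0 * n_g) * eps
            if logr >= 0.0 or math.log(np.random.random()) < logr:
                mu[g, 1] *= c
                mu[g, 2] *= c
                sigma[g, 1] *= c
                sigma[g, 2] *= c
                for i in range(S):
                    if subj_group[i] == g:
                        theta[i, 1] *= c
                        theta[i, 2] *= c
                        cur_ll[i] = new_lls[i]
                gv_acc[g] += 1.0

        # --- adaptation (burn-in only) ----------------------------------
        if it < adapt_until and (it + 1) % window == 0:
            for i in range(S):
                for p in range(P):
                    rate = th_acc[i, p] / max(th_tot[i, p], 1.0)
                    th_scale[i, p] *= math.exp(0.8 * (rate - target_acc))
                    th_scale[i, p] = min(max(th_scale[i, p], 1e-5), 5.0)
                rate = av_acc[i] / max(av_tot[i], 1.0)
                av_scale[i] *= math.exp(0.8 * (rate - target_acc))
                av_scale[i] = min(max(av_scale[i], 1e-5), 5.0)
            for g in range(G):
                for p in range(P):
                    rate = mu_acc[g, p] / max(mu_tot[g, p], 1.0)
                    mu_scale[g, p] *= math.exp(0.8 * (rate - target_acc))
                    mu_scale[g, p] = min(max(mu_scale[g, p], 1e-5), 5.0)
                    rate = sg_acc[g, p] / max(sg_tot[g, p], 1.0)
                    sg_scale[g, p] *= math.exp(0.8 * (rate - target_acc))
                    sg_scale[g, p] = min(max(sg_scale[g, p], 1e-5), 5.0)
                    rate = tr_acc[g, p] / max(tr_tot[g, p], 1.0)
                    tr_scale[g, p] *= math.exp(0.8 * (rate - target_acc))
                    tr_scale[g, p] = min(max(tr_scale[g, p], 1e-5), 5.0)
                rate = gv_acc[g] / max(gv_tot[g], 1.0)
                gv_scale[g] *= math.exp(0.8 * (rate - target_acc))
                gv_scale[g] = min(max(gv_scale[g], 1e-5), 5.0)
                for p in range(1, 3):
                    rate = fn_acc[g, p] / max(fn_tot[g, p], 1.0)
                    fn_scale[g, p] *= math.exp(0.8 * (rate - target_acc))
                    fn_scale[g, p] = min(max(fn_scale[g, p], 1e-5), 5.0)
            th_acc[:] = 0.0
            th_tot[:] = 0.0
            mu_acc[:] = 0.0
            mu_tot[:] = 0.0
            sg_acc[:] = 0.0
            sg_tot[:] = 0.0
            tr_acc[:] = 0.0
            tr_tot[:] = 0.0
            av_acc[:] = 0.0
            av_tot[:] = 0.0
            gv_acc[:] = 0.0
            gv_tot[:] = 0.0
            fn_acc[:] = 0.0
            fn_tot[:] = 0.0

        # --- store -------------------------------------------------------
        k = 0
        for g in range(G):
            for p in range(P):
                draws[it, k] = mu[g, p]
                k += 1
        for g in range(G):
            for p in range(P):
                draws[it, k] = sigma[g, p]
                k += 1
        for i in range(S):
            for p in range(P):
                draws[it, k] = theta[i, p]
                k += 1

    # post-adaptation acceptance rates per block, same layout as draws
    rates = np.empty(n_par)
    k = 0
    for g in range(G):
        for p in range(P):
            rates[k] = mu_acc[g, p] / max(mu_tot[g, p], 1.0)
            k += 1
    for g in range(G):
        for p in range(P):
            rates[k] = sg_acc[g, p] / max(sg_tot[g, p], 1.0)
            k += 1
    for i in range(S):
        for p in range(P):
            rates[k] = th_acc[i, p] / max(th_tot[i, p], 1.0)
            k += 1
    return draws, rates
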