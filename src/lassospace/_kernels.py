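"""Numba-compiled Gibbs kernels for the Laplace (LASSO) and ridge hierarchies.

Each full-conditional update is a separate njit function so that it can be
exercised on frozen conditioning values by the unit tests; `run_chain`
composes them into one sweep per iteration.

The hierarchy sampled here (shrinkage prior on marker effects beta, overall
mean mu with a flat prior, noise variance sigma^2 with p(sigma^2) ~ 1/sigma^2):

* LASSO: beta_j | sigma^2, tau_j^2 ~ N(0, sigma^2 tau_j^2) with
  tau_j^2 ~ Exp(lambda^2 / 2), which marginally gives the conditional
  Laplace prior with rate lambda / sigma. The conjugate updates are
  normal (beta_j, mu), inverse-gamma (sigma^2), inverse-Gaussian
  (1 / tau_j^2) and, when the tuning parameter is random with
  p(lambda) ~ 1/lambda, gamma (lambda^2).
* Ridge: beta | sigma^2, lambda ~ N(0, sigma^2 / lambda I); the random
  tuning parameter with p(lambda) ~ 1/lambda has a gamma full conditional.

Marker effects are updated one coordinate at a time while maintaining the
residual vector, the same computational scheme used by standard Bayesian
whole-genome regression samplers for this model family.
"""
import numpy as np
from numba import njit

# |beta_j| is clamped at this floor before the inverse-Gaussian draw: the
# conditional mean lambda*sigma/|beta_j| diverges as beta_j -> 0.
BETA_FLOOR = 1e-10
# 1/tau_j^2 draws are clipped into [ITAU_MIN, ITAU_MAX]; under a permuted
# null with beta_j pinned at the floor, the inverse-Gaussian draw can
# overflow to inf, which would poison the precision of the next beta draw.
ITAU_MIN = 1e-15
ITAU_MAX = 1e15

# error codes returned by run_chain
ERR_NONE = 0
ERR_BETA = 1
ERR_SIGMA2 = 2


@njit(cache=True, fastmath=True)
def sweep_beta_lasso(Xt, s, r, beta, tau2, sigma2, rng):
    """One coordinate-wise sweep of beta_j | rest ~ N(c_j/p_j, sigma^2/p_j).

    ``Xt`` is the (m, n) transposed design, ``s`` the column sums of squares,
    ``r`` the current residual y - mu - X beta (updated in place), and
    p_j = s_j + 1/tau_j^2.
    """
    m, n = Xt.shape
    for j in range(m):
        xj = Xt[j]
        bj = beta[j]
        cj = s[j] * bj
        for i in range(n):
            cj += xj[i] * r[i]
        prec = s[j] + 1.0 / tau2[j]
        bnew = cj / prec + np.sqrt(sigma2 / prec) * rng.standard_normal()
        d = bj - bnew
        for i in range(n):
            r[i] += xj[i] * d
        beta[j] = bnew


@njit(cache=True, fastmath=True)
def sweep_beta_ridge(Xt, s, r, beta, lam, sigma2, rng):
    """Coordinate sweep under the ridge prior: precision p_j = s_j + lambda."""
    m, n = Xt.shape
    for j in range(m):
        xj = Xt[j]
        bj = beta[j]
        cj = s[j] * bj
        for i in range(n):
            cj += xj[i] * r[i]
        prec = s[j] + lam
        bnew = cj / prec + np.sqrt(sigma2 / prec) * rng.standard_normal()
        d = bj - bnew
        for i in range(n):
            r[i] += xj[i] * d
        beta[j] = bnew


@njit(cache=True, fastmath=True)
def draw_mu_shift(r, sigma2, rng):
    """Draw mu | rest ~ N(mean(r_partial), sigma^2/n) expressed as a shift.

    ``r`` holds y - mu_old - X beta; the returned value is mu_new - mu_old
    and ``r`` is updated in place to y - mu_new - X beta.
    """
    n = r.shape[0]
    rbar = 0.0
    for i in range(n):
        rbar += r[i]
    rbar /= n
    shift = rbar + np.sqrt(sigma2 / n) * rng.standard_normal()
    for i in range(n):
        r[i] -= shift
    return shift


@njit(cache=True, fastmath=True)
def draw_sigma2(r, pen, n, m, rng):
    """sigma^2 | rest ~ InvGamma((n+m)/2, (||r||^2 + pen)/2).

    ``pen`` is sum(beta_j^2/tau_j^2) for LASSO or lambda * ||beta||^2 for
    ridge.
    """
    sse = 0.0
    for i in range(r.shape[0]):
        sse += r[i] * r[i]
    a = 0.5 * (n + m)
    b = 0.5 * (sse + pen)
    return b / rng.gamma(a, 1.0)


@njit(cache=True, fastmath=True)
def draw_tau2(beta, tau2, lam2, sigma2, rng):
    """1/tau_j^2 | rest ~ InvGaussian(sqrt(lam2*sigma2)/|beta_j|, lam2)."""
    m = beta.shape[0]
    for j in range(m):
        b = abs(beta[j])
        if b < BETA_FLOOR:
            b = BETA_FLOOR
        mu_ig = np.sqrt(lam2 * sigma2) / b
        itau = rng.wald(mu_ig, lam2)
        if not np.isfinite(itau) or itau > ITAU_MAX:
            itau = ITAU_MAX
        elif itau < ITAU_MIN:
            itau = ITAU_MIN
        tau2[j] = 1.0 / itau


@njit(cache=True)
def draw_lambda2_lasso(tau2, a0, b0, rng):
    """lambda^2 | rest ~ Gamma(m + a0, rate b0 + sum(tau_j^2)/2).

    a0 = b0 = 0 corresponds to the improper prior p(lambda) ~ 1/lambda.
    """
    m = tau2.shape[0]
    t = 0.0
    for j in range(m):
        t += tau2[j]
    return rng.gamma(m + a0, 1.0) / (b0 + 0.5 * t)


@njit(cache=True)
def draw_lambda_ridge(beta, sigma2, a0, b0, rng):
    """lambda | rest ~ Gamma(m/2 + a0, rate b0 + ||beta||^2/(2 sigma^2))."""
    m = beta.shape[0]
    ss = 0.0
    for j in range(m):
        ss += beta[j] * beta[j]
    return rng.gamma(0.5 * m + a0, 1.0) / (b0 + 0.5 * ss / sigma2)


@njit(cache=True, fastmath=True)
def run_chain(
    Xt,
    y,
    ridge,
    lam_init,
    random_lam,
    sample_mu,
    burn_in,
    thin,
    n_draws,
    a0,
    b0,
    keep_tau2,
    rng,
):
    """Run one Gibbs chain and return retained draws.

    Returns ``(beta, mu, sigma2, tau2, lam, err_code, err_iter)``; on a
    numerical failure the error code identifies the offending parameter
    block and ``err_iter`` the iteration (1-based).
    """
    m, n = Xt.shape
    s = np.empty(m)
    for j in range(m):
        t = 0.0
        xj = Xt[j]
        for i in range(n):
            t += xj[i] * xj[i]
        s[j] = t

    beta = np.zeros(m)
    tau2 = np.ones(m)
    mu = 0.0
    if sample_mu:
        for i in range(n):
            mu += y[i]
        mu /= n
    r = np.empty(n)
    for i in range(n):
        r[i] = y[i] - mu
    sigma2 = 0.0
    for i in range(n):
        sigma2 += r[i] * r[i]
    sigma2 = sigma2 / n + 1e-12

    lam = lam_init
    lam2 = lam * lam

    beta_out = np.empty((n_draws, m))
    mu_out = np.empty(n_draws)
    sig_out = np.empty(n_draws)
    if keep_tau2:
        tau_out = np.empty((n_draws, m))
    else:
        tau_out = np.empty((0, m))
    lam_out = np.empty(n_draws)

    total = burn_in + thin * n_draws
    kept = 0
    for it in range(1, total + 1):
        if ridge:
            sweep_beta_ridge(Xt, s, r, beta, lam, sigma2, rng)
        else:
            sweep_beta_lasso(Xt, s, r, beta, tau2, sigma2, rng)
        bsum = 0.0
        for j in range(m):
            bsum += beta[j]
        if not np.isfinite(bsum):
            return beta_out, mu_out, sig_out, tau_out, lam_out, ERR_BETA, it
        if sample_mu:
            mu += draw_mu_shift(r, sigma2, rng)
        pen = 0.0
        if ridge:
            for j in range(m):
                pen += beta[j] * beta[j]
            pen *= lam
        else:
            for j in range(m):
                pen += beta[j] * beta[j] / tau2[j]
        sigma2 = draw_sigma2(r, pen, n, m, rng)
        if not np.isfinite(sigma2) or sigma2 <= 0.0:
            return beta_out, mu_out, sig_out, tau_out, lam_out, ERR_SIGMA2, it
        if ridge:
            if random_lam:
                lam = draw_lambda_ridge(beta, sigma2, a0, b0, rng)
        else:
            draw_tau2(beta, tau2, lam2, sigma2, rng)
            if random_lam:
                lam2 = draw_lambda2_lasso(tau2, a0, b0, rng)
                lam = np.sqrt(lam2)
        if it > burn_in and (it - burn_in) % thin == 0:
            for j in range(m):
                beta_out[kept, j] = beta[j]
            mu_out[kept] = mu
            sig_out[kept] = sigma2
            if keep_tau2:
                for j in range(m):
                    tau_out[kept, j] = tau2[j]
            lam_out[kept] = lam
            kept += 1
    return beta_out, mu_out, sig_out, tau_out, lam_out, ERR_NONE, 0
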