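"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route independent of the package
implementation it checks: dense-grid quadrature of the unnormalized
posterior for the samplers, exhaustive draw counting for HPW selection,
and naive double loops for pair enumeration.
"""
from __future__ import annotations

import numpy as np


def quad_posterior(X, y, lam, model="lasso", n_beta=121, n_s2=81, span=8.0):
    """Posterior mean and P(beta_j > 0) by dense-grid quadrature.

    Integrates the unnormalized posterior of (beta, sigma^2) for the
    centred model y = X beta + eps with p(sigma^2) ~ 1/sigma^2 and either
    the conditional Laplace prior (rate lam/sigma per coefficient, the
    local scales integrated out analytically) or the Gaussian ridge prior
    beta ~ N(0, sigma^2/lam I). Supports m in {1, 2}.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if m not in (1, 2):
        raise ValueError("quadrature oracle supports m in {1, 2} only")
    # centre beta grids on least squares, sigma^2 grid on residual variance
    bhat, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ bhat
    s2_hat = max(float(resid @ resid) / max(n - m, 1), 1e-3)
    se = np.sqrt(s2_hat / np.diag(X.T @ X))
    grids = [
        np.linspace(bhat[j] - span * se[j], bhat[j] + span * se[j], n_beta)
        for j in range(m)
    ]
    s2 = np.exp(np.linspace(np.log(s2_hat / 30), np.log(s2_hat * 30), n_s2))

    mesh = np.meshgrid(*grids, s2, indexing="ij")
    S2 = mesh[-1]
    B = np.stack(mesh[:-1], axis=0)                      # (m, ...)
    pred = np.tensordot(np.moveaxis(B, 0, -1), X.T, axes=1)  # (..., n)
    rss = ((y - pred) ** 2).sum(axis=-1)
    logpost = -0.5 * n * np.log(S2) - rss / (2 * S2) - np.log(S2)
    if model == "lasso":
        logpost += m * (np.log(lam) - 0.5 * np.log(S2))
        logpost -= lam * np.abs(B).sum(axis=0) / np.sqrt(S2)
    elif model == "ridge":
        logpost += 0.5 * m * (np.log(lam) - np.log(S2))
        logpost -= lam * (B ** 2).sum(axis=0) / (2 * S2)
    else:
        raise ValueError(model)
    w = np.exp(logpost - logpost.max())

    def integrate(f):
        g = f
        g = np.trapezoid(g, x=s2, axis=-1)
        for j in range(m - 1, -1, -1):
            g = np.trapezoid(g, x=grids[j], axis=j)
        return float(g)

    Z = integrate(w)
    means = np.array([integrate(w * B[j]) / Z for j in range(m)])
    p_pos = np.array(
        [integrate(w * (B[j] > 0)) / Z for j in range(m)]
    )
    return means, p_pos


def hpw_bruteforce(draws, n_single, pairs, alpha):
    """Greedy HPW selection with all probabilities found by naive counting.

    ``draws`` is the full (S, n_single + len(pairs)) effect matrix;
    ``pairs`` a list of (j, k, is_sum) tuples describing the combined
    columns. Returns the boolean selection vector.
    """
    S, E = draws.shape
    q = np.empty(E)
    sign = np.empty(E, dtype=int)
    for c in range(E):
        pos = sum(1 for s in range(S) if draws[s, c] > 0)
        neg = sum(1 for s in range(S) if draws[s, c] < 0)
        if pos >= neg:
            q[c], sign[c] = pos / S, 1
        else:
            q[c], sign[c] = neg / S, -1
    order = sorted(range(E), key=lambda c: (-q[c], 0 if c >= n_single else 1, c))
    chosen: list[int] = []
    selected = np.zeros(E, dtype=bool)
    for c in order:
        if c < n_single:
            blocked = any(
                p >= n_single and c in pairs[p - n_single][:2] for p in chosen
            )
        else:
            j, k, _ = pairs[c - n_single]
            members = {j, k}
            blocked = any(
                (p < n_single and p in members)
                or (p >= n_single and members & set(pairs[p - n_single][:2]))
                for p in chosen
            )
        if blocked:
            continue
        trial = chosen + [c]
        count = 0
        for s in range(S):
            if all(
                (draws[s, t] > 0 if sign[t] > 0 else draws[s, t] < 0)
                for t in trial
            ):
                count += 1
        if count / S > alpha:
            chosen.append(c)
            selected[c] = True
        else:
            break
    return selected


def pairs_bruteforce(V, rho):
    """All qualifying (j, k, kind) pairs by naive double loops.

    Agreement requires equal nonzero entries; a 0 disagrees with any
    nonzero entry and neither agrees nor disagrees with another 0.
    """
    n, m = V.shape
    out = set()
    for j in range(m):
        for k in range(j + 1, m):
            agree = sum(
                1 for l in range(n) if V[l, j] == V[l, k] and V[l, j] != 0
            )
            disagree = sum(1 for l in range(n) if V[l, j] != V[l, k])
            if agree / n > rho:
                out.add((j, k, "sum"))
            if disagree / n > rho:
                out.add((j, k, "difference"))
    return out
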