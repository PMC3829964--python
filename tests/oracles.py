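"""Independent reference implementations used to verify the package.

Everything here is deliberately naive (brute force, enumeration, direct
numerical integration) and shares no code with the implementation paths
it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import integrate
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm


def bh_step_up(pvals):
    """Literal evaluation of the BH step-up definition, O(m^2)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    adj = np.empty(m)
    for i in range(m):
        adj[i] = min(min(ps[j] * m / (j + 1) for j in range(i, m)), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def studentized_range_cdf(q: float, k: int, df: int,
                          n_z: int = 2001, n_u: int = 240) -> float:
    """P(Q <= q) for the studentized range by direct double integration.

    Inner integral: CDF of the range of k standard normals,
    P_range(r) = k * int phi(z) [Phi(z) - Phi(z - r)]^(k-1) dz.
    Outer: integrate P_range(q * s) against the distribution of
    s = sqrt(W / df), W ~ chi-square(df), via Gauss-Legendre nodes on the
    probability scale of W.
    """
    if q <= 0:
        return 0.0
    z = np.linspace(-9.0, 9.0, n_z)
    phi = norm.pdf(z)
    nodes, weights = np.polynomial.legendre.leggauss(n_u)
    u = 0.5 * (nodes + 1.0)          # map to (0, 1)
    w_quad = 0.5 * weights
    s = np.sqrt(chi2_dist.ppf(u, df) / df)
    r = q * s                        # shape (n_u,)
    inner = norm.cdf(z)[None, :] - norm.cdf(z[None, :] - r[:, None])
    integrand = k * phi[None, :] * inner ** (k - 1)
    p_range = integrate.simpson(integrand, x=z, axis=1)
    return float(np.sum(w_quad * p_range))


def pearson_chi2(observed) -> tuple[float, int]:
    """Sum (O - E)^2 / E with expectations from the margins."""
    obs = np.asarray(observed, dtype=float)
    expected = obs.sum(axis=1, keepdims=True) * obs.sum(axis=0, keepdims=True) \
        / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, df


def _f_statistic(groups) -> float:
    groups = [np.asarray(g, dtype=float) for g in groups]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    k = len(groups)
    n = len(allv)
    if ss_within == 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def anova_permutation_p(groups) -> float:
    """Exact permutation p-value of the F statistic (all relabelings)."""
    sizes = [len(g) for g in groups]
    pool = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    f_obs = _f_statistic(groups)
    count = total = 0
    for perm in set(itertools.permutations(range(len(pool)))):
        vals = pool[list(perm)]
        split = []
        start = 0
        for s in sizes:
            split.append(vals[start:start + s])
            start += s
        total += 1
        if _f_statistic(split) >= f_obs - 1e-12:
            count += 1
    return count / total


def ttest_permutation_p(a, b) -> float:
    """Exact two-sided permutation p-value via |mean difference|."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pool = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    idx = range(len(pool))
    count = total = 0
    for chosen in itertools.combinations(idx, len(a)):
        mask = np.zeros(len(pool), dtype=bool)
        mask[list(chosen)] = True
        diff = abs(pool[mask].mean() - pool[~mask].mean())
        total += 1
        if diff >= obs - 1e-12:
            count += 1
    return count / total
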