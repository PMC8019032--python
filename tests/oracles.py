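"""Independent brute-force oracles used to check the implementation.

Everything here is computed from first principles (definition formulas,
naive loops, tensor quadrature, rejection sampling) and never calls the
code paths it is used to verify.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln, logsumexp


def pearson_bruteforce(x, y):
    """Pearson r from raw sums of cross-products, plus the exact t-based
    two-sided p-value."""
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    r = (n * sxy - sx * sy) / math.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
    t = r * math.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, p


def interaction_f_extra_ss(log_reward, log_volume, source):
    """Sequential interaction F by the explicit extra-sum-of-squares route:
    (RSS_reduced − RSS_full)/df1 ÷ RSS_full/df2."""
    log_reward = np.asarray(log_reward, dtype=float)
    log_volume = np.asarray(log_volume, dtype=float)
    levels = sorted(set(source))
    n = log_reward.size
    dummies = np.column_stack(
        [(np.asarray(source) == lv).astype(float) for lv in levels[1:]]
    )
    X_red = np.column_stack([np.ones(n), log_volume, dummies])
    X_full = np.column_stack([X_red, dummies * log_volume[:, None]])

    def rss(X):
        coef, *_ = np.linalg.lstsq(X, log_reward, rcond=None)
        resid = log_reward - X @ coef
        return float(resid @ resid)

    rss_red, rss_full = rss(X_red), rss(X_full)
    df1 = len(levels) - 1
    df2 = n - X_full.shape[1]
    F = (rss_red - rss_full) / df1 / (rss_full / df2)
    return F, df1, df2


def zinb_logpmf_scalar(y, mu, theta, pi):
    """Term-by-term scalar ZINB pmf (log), from the mixture definition."""
    lognb = (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1)
        + theta * (math.log(theta) - math.log(theta + mu))
        + y * (math.log(mu) - math.log(theta + mu))
    )
    if y == 0:
        return math.log(pi + (1 - pi) * math.exp(lognb))
    return math.log(1 - pi) + lognb


def quadrature_marginal_loglik(
    data, beta, theta, pi, sigma2_site, sigma2_period, n_nodes=10, center=None
):
    """Brute-force marginal log-likelihood by tensor-product Gauss–Hermite
    over every (u_j, v_k) dimension jointly.

    With ``center=(m, s)`` the rule is adaptive: integration variables are
    shifted/scaled per coordinate (a pure change of variables — the
    integrand is still evaluated from the model definition).  Feasible for
    a handful of random-effect levels only.
    """
    from beescape.zinb import zinb_logpmf

    J, K = data.n_sites, data.n_periods
    D = J + K
    x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    if center is None:
        m = np.zeros(D)
        s = np.concatenate(
            [np.full(J, math.sqrt(sigma2_site)), np.full(K, math.sqrt(sigma2_period))]
        )
        # plain rule in the prior metric: log-weights absorb the prior pdf
        per_dim_logw = [np.log(w) - 0.5 * np.log(2 * np.pi) for _ in range(D)]
        prior_in_integrand = False
    else:
        m, s = center
        # adaptive: integrate f(z)dz with z_d = m_d + s_d x_d; the e^{-x²/2}
        # of the rule is divided back out and the prior stays in f
        per_dim_logw = [np.log(w) + 0.5 * x**2 + np.log(s[d]) for d in range(D)]
        prior_in_integrand = True

    lin = data.X @ beta + data.offset
    total = np.zeros([n_nodes] * D)
    for j in range(J):
        un = m[j] + s[j] * x
        for k in range(K):
            idx = (data.site_idx == j) & (data.period_idx == k)
            if not idx.any():
                continue
            vn = m[J + k] + s[J + k] * x
            eta = lin[idx][:, None, None] + un[None, :, None] + vn[None, None, :]
            M = zinb_logpmf(data.y[idx][:, None, None], np.exp(eta), theta, pi).sum(
                axis=0
            )
            sh = [1] * D
            sh[j] = n_nodes
            sh[J + k] = n_nodes
            total = total + M.reshape(sh)
    for d in range(D):
        sh = [1] * D
        sh[d] = n_nodes
        contrib = per_dim_logw[d].copy()
        if prior_in_integrand:
            zd = m[d] + s[d] * x
            s2 = sigma2_site if d < J else sigma2_period
            contrib = contrib - 0.5 * (np.log(2 * np.pi * s2) + zd**2 / s2)
        total = total + contrib.reshape(sh)
    return float(logsumexp(total))


def disc_area_montecarlo(patches, center, radius, n_points, rng):
    """Rejection-sampled polygon∩disc area per land type.

    Uniform points in the disc; each point is attributed to the patch that
    contains it via vectorised containment.  Returns (areas dict,
    binomial-SE dict) in m².
    """
    import shapely

    r = radius * np.sqrt(rng.random(n_points))
    phi = rng.random(n_points) * 2 * np.pi
    px = center[0] + r * np.cos(phi)
    py = center[1] + r * np.sin(phi)
    disc_area = np.pi * radius**2
    areas: dict[str, float] = {}
    ses: dict[str, float] = {}
    for p in patches:
        inside = shapely.contains_xy(p.polygon, px, py)
        frac = inside.mean()
        if frac > 0:
            areas[p.land_type] = areas.get(p.land_type, 0.0) + frac * disc_area
    # per-land-type SE from the pooled hit fraction
    for lt in areas:
        frac = areas[lt] / disc_area
        ses[lt] = disc_area * math.sqrt(frac * (1 - frac) / n_points)
    return areas, ses


def moran_i_definition(values, coords):
    """Moran's I straight from the definition with 1/d weights."""
    z = np.asarray(values, float)
    z = z - z.mean()
    xy = np.asarray(coords, float)
    n = len(z)
    num = 0.0
    S0 = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = math.dist(xy[i], xy[j])
            w = 1.0 / d
            num += w * z[i] * z[j]
            S0 += w
    return (n / S0) * num / float(z @ z)
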