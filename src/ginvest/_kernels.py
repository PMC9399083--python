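"""Compiled inner loops for the Gibbs sampler.

All randomness enters through pre-drawn uniform/normal arrays produced by a
numpy ``Generator`` in the driver, so draws are reproducible and independent
of the compilation backend.  The normal quantile function is Wichura's PPND16
rational approximation (double precision); the CDF goes through ``erfc``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)
_INF = np.inf


@njit(cache=True, fastmath=False)
def ndtr(x: float) -> float:
    """Standard normal CDF."""
    return 0.5 * math.erfc(-x / _SQRT2)


@njit(cache=True, fastmath=False)
def ndtri(p: float) -> float:
    """Standard normal quantile (PPND16); p clamped away from {0, 1}."""
    if p <= 1e-300:
        p = 1e-300
    if p >= 1.0 - 1e-16:
        p = 1.0 - 1e-16
    q = p - 0.5
    if abs(q) <= 0.425:
        r = 0.180625 - q * q
        num = (((((((2.5090809287301226727e3 * r + 3.3430575583588128105e4) * r
                    + 6.7265770927008700853e4) * r + 4.5921953931549871457e4) * r
                  + 1.3731693765509461125e4) * r + 1.9715909503065514427e3) * r
                + 1.3314166789178437745e2) * r + 3.3871328727963666080e0)
        den = (((((((5.2264952788528545610e3 * r + 2.8729085735721942674e4) * r
                    + 3.9307895800092710610e4) * r + 2.1213794301586595867e4) * r
                  + 5.3941960214247511077e3) * r + 6.8718700749205790830e2) * r
                + 4.2313330701600911252e1) * r + 1.0)
        return q * num / den
    if q < 0.0:
        r = p
    else:
        r = 1.0 - p
    r = math.sqrt(-math.log(r))
    if r <= 5.0:
        r = r - 1.6
        num = (((((((7.74545014278341407640e-4 * r + 2.27238449892691845833e-2) * r
                    + 2.41780725177450611770e-1) * r + 1.27045825245236838258e0) * r
                  + 3.64784832476320460504e0) * r + 5.76949722146069140550e0) * r
                + 4.63033784615654529590e0) * r + 1.42343711074968357734e0)
        den = (((((((1.05075007164441684324e-9 * r + 5.47593808499534494600e-4) * r
                    + 1.51986665636164571966e-2) * r + 1.48103976427480074590e-1) * r
                  + 6.89767334985100004550e-1) * r + 1.67638483018380384940e0) * r
                + 2.05319162663775882187e0) * r + 1.0)
    else:
        r = r - 5.0
        num = (((((((2.01033439929228813265e-7 * r + 2.71155556874348757815e-5) * r
                    + 1.24266094738807843860e-3) * r + 2.65321895265761230930e-2) * r
                  + 2.96560571828504891230e-1) * r + 1.78482653991729133580e0) * r
                + 5.46378491116411436990e0) * r + 6.65790464350110377720e0)
        den = (((((((2.04426310338993978564e-15 * r + 1.42151175831644588870e-7) * r
                    + 1.84631831751005468180e-5) * r + 7.86869131145613259100e-4) * r
                  + 1.48753612908506148525e-2) * r + 1.36929880922735805310e-1) * r
                + 5.99832206555887937690e-1) * r + 1.0)
    val = num / den
    return -val if q < 0.0 else val


@njit(cache=True, fastmath=False)
def truncnorm_draw(m: float, lo: float, hi: float, u: float) -> float:
    """One N(m, 1) draw truncated to (lo, hi) via inverse-CDF with tail care."""
    a = lo - m
    b = hi - m
    if a == -_INF:
        if b == _INF:
            return m + ndtri(u)
        return m + ndtri(u * ndtr(b))
    if b == _INF:
        # z in (a, inf): reflect through zero
        return m - ndtri(u * ndtr(-a))
    if a > 0.0:
        # both bounds in the upper tail: work on the reflected interval
        pa = ndtr(-b)
        pb = ndtr(-a)
        if pb - pa <= 0.0:
            return m + a  # numerically degenerate sliver: clamp to near bound
        return m - ndtri(pa + u * (pb - pa))
    pa = ndtr(a)
    pb = ndtr(b)
    if pb - pa <= 0.0:
        return m + b
    return m + ndtri(pa + u * (pb - pa))


@njit(cache=True, fastmath=False)
def update_ystar(ystar, codes, mask, lam, eta, item_factor, item_ncat,
                 tau_flat, tau_start, U):
    """Redraw the underlying continuous responses at every observed ordinal
    cell: truncated N(lambda_j * eta_ig, 1) on the category's threshold
    interval.  Continuous items (ncat == 0) and masked cells are untouched."""
    n, J = ystar.shape
    for j in range(J):
        K = item_ncat[j]
        if K == 0:
            continue
        f = item_factor[j]
        t0 = tau_start[j]
        for i in range(n):
            if not mask[i, j]:
                continue
            c = codes[i, j]
            lo = -_INF if c == 0 else tau_flat[t0 + c - 1]
            hi = _INF if c == K - 1 else tau_flat[t0 + c]
            m = lam[j] * eta[i, f]
            ystar[i, j] = truncnorm_draw(m, lo, hi, U[i, j])


@njit(cache=True, fastmath=False)
def update_eta(eta, ystar, mask, lam, item_factor, Psi_inv, mu, Z):
    """Draw each row's latent vector from its exact multivariate-normal full
    conditional given its observed y* cells, the loadings, the structural
    mean ``mu`` and the latent error covariance (``Psi_inv`` given).

    Precision = Psi_inv + diag(sum_j lam_j^2 over observed cells);
    rows with no observed cells reduce to N(mu_i, Psi)."""
    n, J = ystar.shape
    G = eta.shape[1]
    P = np.empty((G, G))
    L = np.empty((G, G))
    d = np.empty(G)
    s = np.empty(G)
    y = np.empty(G)
    w = np.empty(G)
    v = np.empty(G)
    for i in range(n):
        for g in range(G):
            d[g] = 0.0
            s[g] = 0.0
        for j in range(J):
            if mask[i, j]:
                f = item_factor[j]
                d[f] += lam[j] * lam[j]
                s[f] += lam[j] * ystar[i, j]
        for a in range(G):
            for b in range(G):
                P[a, b] = Psi_inv[a, b]
            P[a, a] += d[a]
        for a in range(G):
            acc = s[a]
            for b in range(G):
                acc += Psi_inv[a, b] * mu[i, b]
            y[a] = acc
        # Cholesky P = L L^T
        for a in range(G):
            for b in range(a + 1):
                acc = P[a, b]
                for k in range(b):
                    acc -= L[a, k] * L[b, k]
                if a == b:
                    L[a, a] = math.sqrt(acc)
                else:
                    L[a, b] = acc / L[b, b]
        # mean = P^{-1} y : forward then back substitution
        for a in range(G):
            acc = y[a]
            for k in range(a):
                acc -= L[a, k] * w[k]
            w[a] = acc / L[a, a]
        for a in range(G - 1, -1, -1):
            acc = w[a]
            for k in range(a + 1, G):
                acc -= L[k, a] * y[k]
            y[a] = acc / L[a, a]
        # noise with covariance P^{-1}: solve L^T v = z
        for a in range(G - 1, -1, -1):
            acc = Z[i, a]
            for k in range(a + 1, G):
                acc -= L[k, a] * v[k]
            v[a] = acc / L[a, a]
        for g in range(G):
            eta[i, g] = y[g] + v[g]


@njit(cache=True, fastmath=False)
def category_extrema(ystar, codes, mask, col_idx, K):
    """Pooled (max, min) of y* per category over the tied columns
    ``col_idx``; +-inf where a category is empty.  Returns (maxs, mins),
    each length K."""
    maxs = np.full(K, -_INF)
    mins = np.full(K, _INF)
    n = ystar.shape[0]
    for jj in range(col_idx.shape[0]):
        j = col_idx[jj]
        for i in range(n):
            if mask[i, j]:
                c = codes[i, j]
                y = ystar[i, j]
                if y > maxs[c]:
                    maxs[c] = y
                if y < mins[c]:
                    mins[c] = y
    return maxs, mins


@njit(cache=True, fastmath=False)
def run_chain_fused(rng,
                    codes, mask, item_factor, item_ncat, item_tau_start,
                    XallT, col_factor, Cfull,
                    lam_group, tg_start, tg_ncat, tg_cols, tg_ptr,
                    beta_prior_mean, beta_prior_var,
                    loading_mean, loading_var,
                    threshold_mean, threshold_var,
                    psi_df0, psi_scale, sample_psi,
                    ph_exposure, ph_outfac, ph_gamma,
                    ystar, eta, lam, lam_g, tau_flat, beta, Psi, Psi_inv,
                    phi, nu, sig2,
                    iterations, burnin, thin, out):
    """One full chain, all six updates fused per sweep (linear-auxiliary
    phantoms only).  State arrays are updated in place; retained draws go to
    ``out`` (beta | lam_g | tau | Psi upper triangle | phantom nu/sig2 per
    row).  Returns the number of recorded draws."""
    n, J = ystar.shape
    G = eta.shape[1]
    P = beta.size
    L = lam_g.size
    T = tau_flat.size
    K = nu.size
    n_tg = tg_ncat.size

    mu = np.empty((n, G))
    target = np.empty((n, G))
    Pm = np.empty((G, G))
    Lc = np.empty((G, G))
    dv = np.empty(G)
    sv = np.empty(G)
    yv = np.empty(G)
    wv = np.empty(G)
    vv = np.empty(G)
    shh = np.empty(max(L, 1))
    shy = np.empty(max(L, 1))
    maxs = np.empty(16)
    mins = np.empty(16)
    M = np.empty((P, P))
    rhs = np.empty(P)
    wp = np.empty(P)
    vp = np.empty(P)
    A = np.zeros((G, G))
    Fi = np.zeros((G, G))
    sd_tau = math.sqrt(threshold_var)

    keep = 0
    for itn in range(iterations):
        # ---- structural mean mu = X beta (+ phantom paths) ----
        for i in range(n):
            for g in range(G):
                mu[i, g] = 0.0
        for a in range(P):
            f = col_factor[a]
            ba = beta[a]
            for i in range(n):
                mu[i, f] += XallT[a, i] * ba
        for k in range(K):
            f = ph_outfac[k]
            c = ph_gamma[k]
            for i in range(n):
                mu[i, f] += c * phi[i, k]

        # ---- per-row y* then eta ----
        for i in range(n):
            for j in range(J):
                Kc = item_ncat[j]
                if Kc == 0 or not mask[i, j]:
                    continue
                cc = codes[i, j]
                t0 = item_tau_start[j]
                lo = -_INF if cc == 0 else tau_flat[t0 + cc - 1]
                hi = _INF if cc == Kc - 1 else tau_flat[t0 + cc]
                ystar[i, j] = truncnorm_draw(lam[j] * eta[i, item_factor[j]],
                                             lo, hi, rng.random())
            for g in range(G):
                dv[g] = 0.0
                sv[g] = 0.0
            for j in range(J):
                if mask[i, j]:
                    f = item_factor[j]
                    dv[f] += lam[j] * lam[j]
                    sv[f] += lam[j] * ystar[i, j]
            for a in range(G):
                for b in range(G):
                    Pm[a, b] = Psi_inv[a, b]
                Pm[a, a] += dv[a]
            for a in range(G):
                acc = sv[a]
                for b in range(G):
                    acc += Psi_inv[a, b] * mu[i, b]
                yv[a] = acc
            for a in range(G):
                for b in range(a + 1):
                    acc = Pm[a, b]
                    for k in range(b):
                        acc -= Lc[a, k] * Lc[b, k]
                    if a == b:
                        Lc[a, a] = math.sqrt(acc)
                    else:
                        Lc[a, b] = acc / Lc[b, b]
            for a in range(G):
                acc = yv[a]
                for k in range(a):
                    acc -= Lc[a, k] * wv[k]
                wv[a] = acc / Lc[a, a]
            for a in range(G - 1, -1, -1):
                acc = wv[a]
                for k in range(a + 1, G):
                    acc -= Lc[k, a] * yv[k]
                yv[a] = acc / Lc[a, a]
            for a in range(G - 1, -1, -1):
                acc = rng.standard_normal()
                for k in range(a + 1, G):
                    acc -= Lc[k, a] * vv[k]
                vv[a] = acc / Lc[a, a]
            for g in range(G):
                eta[i, g] = yv[g] + vv[g]

        # ---- loadings (pooled over tied cells) ----
        if L > 0:
            for l in range(L):
                shh[l] = 0.0
                shy[l] = 0.0
            for j in range(J):
                lg = lam_group[j]
                if lg < 0:
                    continue
                f = item_factor[j]
                a1 = 0.0
                a2 = 0.0
                for i in range(n):
                    if mask[i, j]:
                        e = eta[i, f]
                        a1 += e * e
                        a2 += e * ystar[i, j]
                shh[lg] += a1
                shy[lg] += a2
            for l in range(L):
                prec = 1.0 / loading_var + shh[l]
                mean = (loading_mean / loading_var + shy[l]) / prec
                lam_g[l] = mean + rng.standard_normal() / math.sqrt(prec)
            for j in range(J):
                if lam_group[j] >= 0:
                    lam[j] = lam_g[lam_group[j]]

        # ---- thresholds (truncated-prior full conditionals) ----
        for t in range(n_tg):
            Kc = tg_ncat[t]
            t0 = tg_start[t]
            for c in range(Kc):
                maxs[c] = -_INF
                mins[c] = _INF
            for pp in range(tg_ptr[t], tg_ptr[t + 1]):
                j = tg_cols[pp]
                for i in range(n):
                    if mask[i, j]:
                        cc = codes[i, j]
                        y = ystar[i, j]
                        if y > maxs[cc]:
                            maxs[cc] = y
                        if y < mins[cc]:
                            mins[cc] = y
            for m in range(Kc - 1):
                lo = maxs[m]
                hi = mins[m + 1]
                if m > 0 and tau_flat[t0 + m - 1] > lo:
                    lo = tau_flat[t0 + m - 1]
                if m < Kc - 2 and tau_flat[t0 + m + 1] < hi:
                    hi = tau_flat[t0 + m + 1]
                if lo >= hi:
                    raise FloatingPointError("inverted threshold bounds")
                a = (lo - threshold_mean) / sd_tau
                b = (hi - threshold_mean) / sd_tau
                tau_flat[t0 + m] = threshold_mean + sd_tau * truncnorm_draw(
                    0.0, a, b, rng.random())

        # ---- structural block (SUR conjugate MVN) ----
        for i in range(n):
            for g in range(G):
                target[i, g] = eta[i, g]
        for k in range(K):
            f = ph_outfac[k]
            c = ph_gamma[k]
            for i in range(n):
                target[i, f] -= c * phi[i, k]
        XtT = XallT @ target                      # (P, G)
        for a in range(P):
            fa = col_factor[a]
            racc = beta_prior_mean / beta_prior_var
            for h in range(G):
                racc += Psi_inv[fa, h] * XtT[a, h]
            rhs[a] = racc
            for b in range(P):
                M[a, b] = Psi_inv[fa, col_factor[b]] * Cfull[a, b]
            M[a, a] += 1.0 / beta_prior_var
        Lb = np.linalg.cholesky(M)
        for a in range(P):
            acc = rhs[a]
            for k in range(a):
                acc -= Lb[a, k] * wp[k]
            wp[a] = acc / Lb[a, a]
        for a in range(P - 1, -1, -1):
            acc = wp[a]
            for k in range(a + 1, P):
                acc -= Lb[k, a] * rhs[k]
            rhs[a] = acc / Lb[a, a]               # rhs now holds the mean
        for a in range(P - 1, -1, -1):
            acc = rng.standard_normal()
            for k in range(a + 1, P):
                acc -= Lb[k, a] * vp[k]
            vp[a] = acc / Lb[a, a]
        for a in range(P):
            beta[a] = rhs[a] + vp[a]

        # ---- latent error covariance (inverse Wishart) ----
        if sample_psi or K > 0:
            # refresh mu with the new beta (and current phantoms)
            for i in range(n):
                for g in range(G):
                    mu[i, g] = 0.0
            for a in range(P):
                f = col_factor[a]
                ba = beta[a]
                for i in range(n):
                    mu[i, f] += XallT[a, i] * ba
            for k in range(K):
                f = ph_outfac[k]
                c = ph_gamma[k]
                for i in range(n):
                    mu[i, f] += c * phi[i, k]
        if sample_psi:
            for a in range(G):
                for b in range(a, G):
                    acc = psi_scale[a, b]
                    for i in range(n):
                        acc += (eta[i, a] - mu[i, a]) * (eta[i, b] - mu[i, b])
                    Pm[a, b] = acc
                    Pm[b, a] = acc
            Sinv = np.linalg.inv(Pm)
            Ls = np.linalg.cholesky(Sinv)
            df = psi_df0 + n
            for a in range(G):
                A[a, a] = math.sqrt(rng.chisquare(df - a))
                for b in range(a):
                    A[a, b] = rng.standard_normal()
            F = Ls @ A                            # W = F F^T ~ Wishart(df, Sinv)
            # invert the lower-triangular F
            for a in range(G):
                Fi[a, a] = 1.0 / F[a, a]
                for b in range(a):
                    acc = 0.0
                    for k in range(b, a):
                        acc -= F[a, k] * Fi[k, b]
                    Fi[a, b] = acc / F[a, a]
            for a in range(G):
                for b in range(a, G):
                    acc = 0.0
                    for k in range(a, G):  # Fi is lower: Fi[k,a], k >= a
                        if k >= b:
                            acc += Fi[k, a] * Fi[k, b]
                    Psi[a, b] = acc
                    Psi[b, a] = acc
            Pinv = np.linalg.inv(Psi)
            for a in range(G):
                for b in range(G):
                    Psi_inv[a, b] = Pinv[a, b]

        # ---- phantom confounders (linear auxiliary) ----
        for k in range(K):
            c = ph_gamma[k]
            f = ph_outfac[k]
            s2 = sig2[k]
            prec = 1.0 + c * c / s2 + c * c * Psi_inv[f, f]
            sdk = 1.0 / math.sqrt(prec)
            for i in range(n):
                pracc = 0.0
                for g in range(G):
                    rg = eta[i, g] - mu[i, g]
                    if g == f:
                        rg += c * phi[i, k]
                    pracc += rg * Psi_inv[g, f]
                mean = (c * (ph_exposure[i, k] - nu[k]) / s2 + c * pracc) / prec
                newphi = mean + sdk * rng.standard_normal()
                mu[i, f] += c * (newphi - phi[i, k])
                phi[i, k] = newphi
            ssum = 0.0
            for i in range(n):
                ssum += ph_exposure[i, k] - c * phi[i, k]
            v = 1.0 / (n / s2 + 1.0 / beta_prior_var)
            nu[k] = v * ssum / s2 + math.sqrt(v) * rng.standard_normal()
            ssr = 0.0
            for i in range(n):
                d = ph_exposure[i, k] - c * phi[i, k] - nu[k]
                ssr += d * d
            sig2[k] = (0.001 + 0.5 * ssr) / rng.gamma(0.001 + 0.5 * n, 1.0)

        # ---- record ----
        if itn >= burnin and (itn - burnin) % thin == thin - 1:
            if keep < out.shape[0]:
                off = 0
                for a in range(P):
                    out[keep, off + a] = beta[a]
                off += P
                for l in range(L):
                    out[keep, off + l] = lam_g[l]
                off += L
                for t in range(T):
                    out[keep, off + t] = tau_flat[t]
                off += T
                for a in range(G):
                    for b in range(a, G):
                        out[keep, off] = Psi[a, b]
                        off += 1
                for k in range(K):
                    out[keep, off] = nu[k]
                    off += 1
                    out[keep, off] = sig2[k]
                    off += 1
                keep += 1
    return keep
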