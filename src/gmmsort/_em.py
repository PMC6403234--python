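"""Compiled expectation-maximization inner loop shared by all mixture fits.

A single kernel handles univariate and multivariate data (d >= 1), full
covariances, and the fixed-mean variant (``update_means=False``).  The kernel
returns the per-iteration log-likelihood trace so callers can verify EM
monotonicity.
"""

import numpy as np
from numba import njit

_LOG2PI = float(np.log(2.0 * np.pi))
_INV_SQRT_2PI = float(1.0 / np.sqrt(2.0 * np.pi))


@njit(cache=True, fastmath=True)
def em_run_1d(x, w, mu, var, floor, max_iter, rel_tol_pct, update_means, min_weight):
    """Univariate specialization of :func:`em_run` (scalar variances).

    Same contract as ``em_run``; the E-step and the M-step sufficient
    statistics (responsibility mass, first and second moments) are accumulated
    in one fused pass over the data.  Callers should center the data so the
    moment subtraction stays well-conditioned.  Points under total density
    underflow get a uniform responsibility row.
    """
    n = x.shape[0]
    k = w.shape[0]
    trace = np.empty(max_iter)
    a = np.empty(k)
    b = np.empty(k)
    p = np.empty(k)
    nk = np.empty(k)
    sx = np.empty(k)
    sxx = np.empty(k)
    prev = -np.inf
    converged = False
    n_iter = 0
    n_clamped = 0
    for it in range(max_iter):
        for j in range(k):
            a[j] = w[j] * _INV_SQRT_2PI / np.sqrt(var[j])
            b[j] = -0.5 / var[j]
            nk[j] = 0.0
            sx[j] = 0.0
            sxx[j] = 0.0
        ll = 0.0
        for i in range(n):
            xi = x[i]
            s = 0.0
            for j in range(k):
                z = xi - mu[j]
                q = b[j] * z * z
                pj = a[j] * np.exp(q) if q > -45.0 else 0.0
                p[j] = pj
                s += pj
            if s < 1e-300:
                ll += np.log(1e-300)
                inv = 1.0 / k
                for j in range(k):
                    nk[j] += inv
                    sx[j] += inv * xi
                    sxx[j] += inv * xi * xi
            else:
                ll += np.log(s)
                inv = 1.0 / s
                for j in range(k):
                    r = p[j] * inv
                    nk[j] += r
                    sx[j] += r * xi
                    sxx[j] += r * xi * xi
        trace[it] = ll
        n_iter = it + 1
        denom = abs(ll)
        if denom < 1e-300:
            denom = 1e-300
        if it > 0 and abs(ll - prev) / denom * 100.0 < rel_tol_pct:
            converged = True
            break
        prev = ll
        wsum = 0.0
        for j in range(k):
            if nk[j] < 1e-10:
                n_clamped += 1
                w[j] = min_weight
                var[j] = floor
                wsum += w[j]
                continue
            w[j] = nk[j] / n
            wsum += w[j]
            if update_means:
                mu[j] = sx[j] / nk[j]
            # sum_i r (x - mu)^2 = sxx - 2 mu sx + mu^2 nk
            v = (sxx[j] - 2.0 * mu[j] * sx[j] + mu[j] * mu[j] * nk[j]) / nk[j]
            if v < 0.0:
                v = 0.0
            var[j] = v + floor
        for j in range(k):
            w[j] /= wsum
    return trace[:n_iter].copy(), converged, n_iter, n_clamped


@njit(cache=True)
def em_run(x, w, mu, cov, floor, max_iter, rel_tol_pct, update_means, min_weight):
    """Run EM to convergence on pre-initialized parameters, in place.

    Parameters are modified in place. ``floor`` is a per-dimension ridge added
    to covariance diagonals each M-step.  Convergence: percentage change of
    log p(x) below ``rel_tol_pct``.

    Returns (trace, converged, n_iter, n_clamped): trace is the log-likelihood
    at the start of each iteration (monotone non-decreasing up to the ridge),
    n_clamped counts component-iterations where a component lost all posterior
    mass and was clamped to (min_weight, floor).
    """
    n, d = x.shape
    k = w.shape[0]
    resp = np.empty((n, k))
    trace = np.empty(max_iter)
    diff = np.empty(d)
    y = np.empty(d)
    prev = -np.inf
    converged = False
    n_iter = 0
    n_clamped = 0
    for it in range(max_iter):
        # E-step: log responsibilities via Cholesky of each covariance
        for j in range(k):
            L = np.linalg.cholesky(cov[j])
            logdet = 0.0
            for a in range(d):
                logdet += np.log(L[a, a])
            logdet *= 2.0
            lw = np.log(w[j]) if w[j] > 0.0 else -1e300
            c = lw - 0.5 * (d * _LOG2PI + logdet)
            for i in range(n):
                for a in range(d):
                    diff[a] = x[i, a] - mu[j, a]
                q = 0.0
                for a in range(d):
                    s = diff[a]
                    for b in range(a):
                        s -= L[a, b] * y[b]
                    y[a] = s / L[a, a]
                    q += y[a] * y[a]
                resp[i, j] = c - 0.5 * q
        ll = 0.0
        for i in range(n):
            m = resp[i, 0]
            for j in range(1, k):
                if resp[i, j] > m:
                    m = resp[i, j]
            s = 0.0
            for j in range(k):
                s += np.exp(resp[i, j] - m)
            ll += m + np.log(s)
            inv = 1.0 / s
            for j in range(k):
                resp[i, j] = np.exp(resp[i, j] - m) * inv
        trace[it] = ll
        n_iter = it + 1
        denom = abs(ll)
        if denom < 1e-300:
            denom = 1e-300
        if it > 0 and abs(ll - prev) / denom * 100.0 < rel_tol_pct:
            converged = True
            break
        prev = ll
        # M-step
        wsum = 0.0
        for j in range(k):
            nk = 0.0
            for i in range(n):
                nk += resp[i, j]
            if nk < 1e-10:
                # component captured no mass: clamp rather than delete so the
                # component count (and downstream cluster identity) is stable
                n_clamped += 1
                w[j] = min_weight
                for a in range(d):
                    for b in range(d):
                        cov[j, a, b] = floor[a] if a == b else 0.0
                wsum += w[j]
                continue
            w[j] = nk / n
            wsum += w[j]
            if update_means:
                for a in range(d):
                    s = 0.0
                    for i in range(n):
                        s += resp[i, j] * x[i, a]
                    mu[j, a] = s / nk
            for a in range(d):
                for b in range(a + 1):
                    s = 0.0
                    for i in range(n):
                        s += resp[i, j] * (x[i, a] - mu[j, a]) * (x[i, b] - mu[j, b])
                    v = s / nk
                    cov[j, a, b] = v
                    cov[j, b, a] = v
            for a in range(d):
                cov[j, a, a] += floor[a]
        for j in range(k):
            w[j] /= wsum
    return trace[:n_iter].copy(), converged, n_iter, n_clamped
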