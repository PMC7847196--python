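"""Compiled inner loops for the Laplace marginal likelihood.

Each animal's 2-d latent mode (log baseline radius, log growth rate) is
found by a damped Newton iteration with analytic gradient and Hessian;
the Laplace approximation of the marginal likelihood then needs only the
joint density and the 2x2 curvature at the mode.  Animals are independent,
so the loop nests animal-outer / timepoint-inner with scalar arithmetic.

A pure-numpy fallback lives in :mod:`xenopower.model`; these kernels are
numerically equivalent and exist for speed (the power engine runs
thousands of fits).
"""

from __future__ import annotations

import math

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


_LOG2PI = math.log(2.0 * math.pi)
_SPHERE = 4.0 * math.pi / 3.0


@njit(cache=True)
def _g_grad_hess_1(u1, u2, t, y, n, radius_scale, mu1, mu2a, s1, s2, s3):
    """Joint -log density of one animal's data and latent pair, with its
    gradient and Hessian in (u1, u2)."""
    a = math.exp(u1)
    b = math.exp(u2)
    inv3 = 1.0 / (s3 * s3)
    g = 0.0
    g1 = 0.0
    g2 = 0.0
    h11 = 0.0
    h22 = 0.0
    h12 = 0.0
    for j in range(n):
        s = a + b * t[j]
        s_1 = a
        s_2 = b * t[j]
        if radius_scale:
            m = s
            m1 = s_1
            m2 = s_2
            m11 = s_1
            m22 = s_2
            m12 = 0.0
        else:
            ss = s * s
            m = _SPHERE * ss * s
            k3 = 3.0 * _SPHERE * ss
            k6 = 6.0 * _SPHERE * s
            m1 = k3 * s_1
            m2 = k3 * s_2
            m11 = k6 * s_1 * s_1 + k3 * s_1
            m22 = k6 * s_2 * s_2 + k3 * s_2
            m12 = k6 * s_1 * s_2
        resid = y[j] - m
        r = resid / (s3 * m)
        g += math.log(m) + 0.5 * r * r
        phi = 1.0 / m - y[j] * resid * inv3 / (m * m * m)
        dphi = (
            -1.0 / (m * m)
            + inv3 * (y[j] / (m * m * m) + 3.0 * y[j] * resid / (m * m * m * m))
        )
        g1 += m1 * phi
        g2 += m2 * phi
        h11 += m11 * phi + m1 * m1 * dphi
        h22 += m22 * phi + m2 * m2 * dphi
        h12 += m12 * phi + m1 * m2 * dphi
    g += n * (0.5 * _LOG2PI + math.log(s3))
    z1 = (u1 - mu1) / s1
    z2 = (u2 - mu2a) / s2
    g += 0.5 * (z1 * z1 + z2 * z2) + math.log(s1) + math.log(s2) + _LOG2PI
    g1 += z1 / s1
    g2 += z2 / s2
    h11 += 1.0 / (s1 * s1)
    h22 += 1.0 / (s2 * s2)
    return g, g1, g2, h11, h22, h12


@njit(cache=True)
def _g_1(u1, u2, t, y, n, radius_scale, mu1, mu2a, s1, s2, s3):
    a = math.exp(u1)
    b = math.exp(u2)
    g = 0.0
    for j in range(n):
        s = a + b * t[j]
        m = s if radius_scale else _SPHERE * s * s * s
        r = (y[j] - m) / (s3 * m)
        g += math.log(m) + 0.5 * r * r
    g += n * (0.5 * _LOG2PI + math.log(s3))
    z1 = (u1 - mu1) / s1
    z2 = (u2 - mu2a) / s2
    g += 0.5 * (z1 * z1 + z2 * z2) + math.log(s1) + math.log(s2) + _LOG2PI
    return g


@njit(cache=True)
def _newton_1(u1, u2, t, y, n, radius_scale, mu1, mu2a, s1, s2, s3,
              tol, maxiter):
    """Damped Newton to the per-animal joint mode.  Returns the mode, the
    value and the Hessian there."""
    g, g1, g2, h11, h22, h12 = _g_grad_hess_1(
        u1, u2, t, y, n, radius_scale, mu1, mu2a, s1, s2, s3
    )
    for _ in range(maxiter):
        gn = abs(g1)
        if abs(g2) > gn:
            gn = abs(g2)
        if gn <= tol * (1.0 + abs(g)):
            break
        # positive-definite 2x2 solve (eigenvalue ridge)
        tr = h11 + h22
        disc = math.sqrt((h11 - h22) * (h11 - h22) + 4.0 * h12 * h12)
        lam_min = 0.5 * (tr - disc)
        ridge = 0.0
        if lam_min < 1e-8:
            ridge = 1e-8 - lam_min
        a11 = h11 + ridge
        a22 = h22 + ridge
        det = a11 * a22 - h12 * h12
        st1 = (a22 * g1 - h12 * g2) / det
        st2 = (a11 * g2 - h12 * g1) / det
        if st1 > 20.0:
            st1 = 20.0
        elif st1 < -20.0:
            st1 = -20.0
        if st2 > 20.0:
            st2 = 20.0
        elif st2 < -20.0:
            st2 = -20.0
        slope = g1 * st1 + g2 * st2
        if slope < 2e-13 * (1.0 + abs(g)):
            break  # achievable decrease is below float resolution
        alpha = 1.0
        accepted = False
        for _ in range(16):
            v1 = u1 - alpha * st1
            v2 = u2 - alpha * st2
            if v1 > 30.0:
                v1 = 30.0
            elif v1 < -30.0:
                v1 = -30.0
            if v2 > 30.0:
                v2 = 30.0
            elif v2 < -30.0:
                v2 = -30.0
            g_try = _g_1(v1, v2, t, y, n, radius_scale, mu1, mu2a, s1, s2, s3)
            if g_try <= g - 1e-4 * alpha * slope:
                u1 = v1
                u2 = v2
                g = g_try
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break  # float-level stall at the mode
        g, g1, g2, h11, h22, h12 = _g_grad_hess_1(
            u1, u2, t, y, n, radius_scale, mu1, mu2a, s1, s2, s3
        )
    return u1, u2, g, h11, h22, h12


@njit(cache=True)
def laplace_loglik(theta, t, y, nobs, treated, radius_scale, u_warm, u0):
    """Laplace marginal log-likelihood over all animals.

    ``theta`` = (mu1, mu2, sigma1, sigma2, sigma3, c); ``u_warm`` is
    updated in place with the modes; ``u0`` holds cold-start values used
    when a warm start strands the Newton iteration.
    """
    mu1, mu2, s1, s2, s3, c = theta
    n_animals = t.shape[0]
    total = 0.0
    for i in range(n_animals):
        mu2a = mu2 + c * treated[i]
        ti = t[i]
        yi = y[i]
        n = nobs[i]
        u1, u2, g, h11, h22, h12 = _newton_1(
            u_warm[i, 0], u_warm[i, 1], ti, yi, n, radius_scale,
            mu1, mu2a, s1, s2, s3, 1e-11, 60,
        )
        # cold restart if the warm path stalled far from a mode
        _, cg1, cg2, _, _, _ = _g_grad_hess_1(
            u1, u2, ti, yi, n, radius_scale, mu1, mu2a, s1, s2, s3
        )
        gn = abs(cg1) if abs(cg1) > abs(cg2) else abs(cg2)
        if gn > 1e-4 * (1.0 + abs(g)):
            v1, v2, g_c, h11c, h22c, h12c = _newton_1(
                u0[i, 0], u0[i, 1], ti, yi, n, radius_scale,
                mu1, mu2a, s1, s2, s3, 1e-11, 60,
            )
            if g_c < g:
                u1, u2, g, h11, h22, h12 = v1, v2, g_c, h11c, h22c, h12c
        u_warm[i, 0] = u1
        u_warm[i, 1] = u2
        # PD-ridged determinant for the Laplace factor
        tr = h11 + h22
        disc = math.sqrt((h11 - h22) * (h11 - h22) + 4.0 * h12 * h12)
        lam_min = 0.5 * (tr - disc)
        if lam_min < 1e-8:
            r = 1e-8 - lam_min
            h11 += r
            h22 += r
        det = h11 * h22 - h12 * h12
        if det < 1e-300:
            det = 1e-300
        total += -g + _LOG2PI - 0.5 * math.log(det)
    return total
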