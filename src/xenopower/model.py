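"""Maximum-likelihood fitting of the linear-radius growth model.

Two estimation approaches are provided behind one statsmodels-style API:

``TumorGrowthModel(study, approach="mixed")``
    Nonlinear mixed-effects model.  Per animal, the baseline radius ``a``
    and radial growth rate ``b`` are latent lognormal effects; the
    marginal likelihood integrates them out.  The 2-d per-animal integral
    is approximated by a Laplace approximation around the joint mode
    (Newton iterations with analytic gradient and Hessian, vectorized
    across animals), with an adaptive Gauss-Hermite cross-check mode.

``TumorGrowthModel(study, approach="pooled")``
    Naive pooled fit: one fixed ``(a, b)`` for all animals, proportional
    error, with the residual SD profiled out analytically.  Radius scale
    only.

The treatment effect ``c`` shifts the mean of ``log b`` in the treated
arm.  Nested fits (with / without ``c``) are compared with a likelihood
ratio test against the chi-square distribution with 1 df.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from . import _kernels
from .growth import StudyTable
from .params import GrowthParams

__all__ = [
    "TumorGrowthModel",
    "GrowthResults",
    "TestResult",
    "fit_mixed",
    "fit_pooled",
    "lrt",
]

_SPHERE = 4.0 * math.pi / 3.0
_LOG2PI = math.log(2.0 * math.pi)

_SIGMA_FLOOR = 1e-6  # residual-SD floor for degenerate (noise-free) pooled fits
_LOG_SIG_BOUNDS = (-7.0, 2.5)


@dataclass
class TestResult:
    """Outcome of a two-arm treatment-effect test.

    ``effect`` is the estimated log-scale growth effect (model methods) or
    the observed %TGI (empirical t-test).
    """

    method: str  # "lrt_mixed" | "lrt_pooled" | "t_test"
    statistic: float
    p_value: float
    effect: float
    horizon: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Data marshalling


class _StudyArrays:
    """Padded rectangular arrays for vectorized per-animal computation."""

    def __init__(self, study: StudyTable, scale: str):
        animals = sorted(study.animals, key=lambda a: (a.arm, a.animal_id))
        n = len(animals)
        jmax = max(a.n_obs for a in animals)
        self.t = np.zeros((n, jmax))
        self.y = np.ones((n, jmax))
        self.mask = np.zeros((n, jmax), dtype=bool)
        self.treated = np.array([a.arm == "treated" for a in animals], dtype=float)
        for i, a in enumerate(animals):
            j = a.n_obs
            self.t[i, :j] = a.times
            self.y[i, :j] = a.radii if scale == "radius" else a.volumes
            self.mask[i, :j] = True
        self.nobs_per_animal = self.mask.sum(axis=1)
        self.n_animals = n
        self.nobs = int(self.mask.sum())
        self.scale = scale
        # radius-scale observations, used for starting values on either scale
        self.r = np.ones((n, jmax))
        for i, a in enumerate(animals):
            self.r[i, : a.n_obs] = a.radii


def _per_animal_lines(arr: _StudyArrays):
    """Per-animal OLS intercept/slope of radius vs time (starting values)."""
    n = arr.n_animals
    a0 = np.empty(n)
    b0 = np.empty(n)
    for i in range(n):
        m = arr.mask[i]
        t, r = arr.t[i, m], arr.r[i, m]
        if len(t) >= 2 and np.ptp(t) > 0:
            b, a = np.polyfit(t, r, 1)
        else:
            a, b = r.mean(), 0.0
        a0[i] = max(a, 1e-3)
        b0[i] = max(b, 1e-4)
    return a0, b0


# ---------------------------------------------------------------------------
# Mixed model internals (Laplace / AGHQ)


class _MixedLik:
    """Marginal log-likelihood of the mixed model, Laplace-approximated.

    The per-animal latent vector is u = (log a, log b).  Newton iterations
    run simultaneously for all animals on (n, 2) arrays; the mode from the
    previous likelihood evaluation warm-starts the next one.
    """

    def __init__(self, arr: _StudyArrays, with_effect: bool):
        self.arr = arr
        self.with_effect = with_effect
        self.u_warm: np.ndarray | None = None

    # -- joint negative log density of (data_i, u_i), vectorized ------------

    def _predict(self, u1, u2):
        """Mean response and its u-derivatives.  Shapes broadcast to (n, j)."""
        t = self.arr.t
        a = np.exp(u1)
        b = np.exp(u2)
        s = a + b * t
        s1, s2 = np.broadcast_to(a, s.shape), b * t
        if self.arr.scale == "radius":
            return s, s1, s2, s1, s2, np.zeros_like(s)
        m = _SPHERE * s**3
        k3 = 3.0 * _SPHERE * s**2
        m1, m2 = k3 * s1, k3 * s2
        k6 = 6.0 * _SPHERE * s
        m11 = k6 * s1**2 + k3 * s1
        m22 = k6 * s2**2 + k3 * s2
        m12 = k6 * s1 * s2
        return m, m1, m2, m11, m22, m12

    def _g_grad_hess(self, u, theta):
        mu1, mu2, s1, s2, s3, c = theta
        arr = self.arr
        u1 = u[:, 0:1]
        u2 = u[:, 1:2]
        m, m1, m2, m11, m22, m12 = self._predict(u1, u2)
        y, mask = arr.y, arr.mask
        inv_s3sq = 1.0 / (s3 * s3)
        resid = y - m
        robs = resid / (s3 * m)
        f_obs = np.where(mask, np.log(m) + 0.5 * robs**2, 0.0)
        phi = 1.0 / m - y * resid * inv_s3sq / m**3
        # dphi/dm = -1/m^2 + y/(s3^2 m^3) + 3 y (y - m)/(s3^2 m^4)
        dphi = -1.0 / m**2 + inv_s3sq * (y / m**3 + 3.0 * y * resid / m**4)
        w = mask.astype(float)
        g1 = np.sum(w * m1 * phi, axis=1)
        g2 = np.sum(w * m2 * phi, axis=1)
        h11 = np.sum(w * (m11 * phi + m1 * m1 * dphi), axis=1)
        h22 = np.sum(w * (m22 * phi + m2 * m2 * dphi), axis=1)
        h12 = np.sum(w * (m12 * phi + m1 * m2 * dphi), axis=1)

        nobs = arr.nobs_per_animal
        g = np.sum(w * f_obs, axis=1) + nobs * (0.5 * _LOG2PI + math.log(s3))
        # priors on u
        mu2_arm = mu2 + c * arr.treated
        z1 = (u[:, 0] - mu1) / s1
        z2 = (u[:, 1] - mu2_arm) / s2
        g += 0.5 * (z1**2 + z2**2) + math.log(s1) + math.log(s2) + _LOG2PI
        g1 += z1 / s1
        g2 += z2 / s2
        h11 = h11 + 1.0 / (s1 * s1)
        h22 = h22 + 1.0 / (s2 * s2)
        return g, np.stack([g1, g2], axis=1), h11, h22, h12

    def _g_only(self, u1, u2, theta):
        """Joint neg log density for arbitrary point sets u1, u2 of shape (n, p)."""
        mu1, mu2, s1, s2, s3, c = theta
        arr = self.arr
        t = arr.t[:, None, :]
        y = arr.y[:, None, :]
        w = arr.mask[:, None, :].astype(float)
        a = np.exp(u1)[:, :, None]
        b = np.exp(u2)[:, :, None]
        s = a + b * t
        m = s if arr.scale == "radius" else _SPHERE * s**3
        robs = (y - m) / (s3 * m)
        g = np.sum(w * (np.log(m) + 0.5 * robs**2), axis=2)
        g += arr.nobs_per_animal[:, None] * (0.5 * _LOG2PI + math.log(s3))
        mu2_arm = (mu2 + c * arr.treated)[:, None]
        z1 = (u1 - mu1) / s1
        z2 = (u2 - mu2_arm) / s2
        g += 0.5 * (z1**2 + z2**2) + math.log(s1) + math.log(s2) + _LOG2PI
        return g

    # -- inner Newton --------------------------------------------------------

    def _u_init(self):
        if not hasattr(self, "_u0"):
            a0, b0 = _per_animal_lines(self.arr)
            self._u0 = np.stack([np.log(a0), np.log(b0)], axis=1)
        return self._u0.copy()

    def _newton(self, u, theta, tol, maxiter, max_backtrack=16):
        """Damped Newton on the joint density, vectorized over animals.

        Animals whose line search can no longer improve (float-level
        stalls near the mode) are frozen so the loop terminates promptly.
        """
        g, grad, h11, h22, h12 = self._g_grad_hess(u, theta)
        frozen = np.zeros(len(g), dtype=bool)
        for _ in range(maxiter):
            gnorm = np.abs(grad).max(axis=1)
            active = (gnorm > tol * (1.0 + np.abs(g))) & ~frozen
            if not active.any():
                break
            # make each 2x2 Hessian positive definite
            tr = h11 + h22
            disc = np.sqrt((h11 - h22) ** 2 + 4.0 * h12**2)
            lam_min = 0.5 * (tr - disc)
            ridge = np.where(lam_min < 1e-8, 1e-8 - lam_min, 0.0)
            a11 = h11 + ridge
            a22 = h22 + ridge
            det = a11 * a22 - h12**2
            step = np.empty_like(u)
            step[:, 0] = (a22 * grad[:, 0] - h12 * grad[:, 1]) / det
            step[:, 1] = (a11 * grad[:, 1] - h12 * grad[:, 0]) / det
            step = np.clip(step, -20.0, 20.0)
            # backtracking (Armijo) line search, vectorized over animals;
            # an animal that cannot achieve a decrease is frozen in place
            alpha = np.where(active, 1.0, 0.0)
            slope = np.sum(grad * step, axis=1)
            new_u = u.copy()
            new_g = g.copy()
            searching = active.copy()
            for _ in range(max_backtrack):
                if not searching.any():
                    break
                u_try = np.clip(u - alpha[:, None] * step, -30.0, 30.0)
                g_try = self._g_only(u_try[:, 0:1], u_try[:, 1:2], theta)[:, 0]
                ok = searching & (g_try <= g - 1e-4 * alpha * slope)
                new_u[ok] = u_try[ok]
                new_g[ok] = g_try[ok]
                searching &= ~ok
                alpha = np.where(searching, alpha * 0.5, alpha)
            moved = active & (new_g < g)
            frozen |= active & ~moved
            if not moved.any():
                break
            u, g = new_u, new_g
            g, grad, h11, h22, h12 = self._g_grad_hess(u, theta)
        gnorm = np.abs(grad).max(axis=1)
        return u, g, h11, h22, h12, gnorm

    def _find_modes(self, theta, tol=1e-6, maxiter=60):
        u0 = self.u_warm.copy() if self.u_warm is not None else self._u_init()
        u, g, h11, h22, h12, gnorm = self._newton(u0, theta, tol, maxiter)
        # short tight pass: quadratic convergence pushes the modes to
        # float-level accuracy, keeping the outer objective smooth for
        # finite-difference gradients
        u, g, h11, h22, h12, gnorm = self._newton(u, theta, 1e-11, 3, max_backtrack=3)
        bad = gnorm > 1e-4 * (1.0 + np.abs(g))
        if bad.any() and self.u_warm is not None:
            # stale warm starts can strand Newton; restart failures cold
            u_r = u.copy()
            u_r[bad] = self._u_init()[bad]
            u2, g2, h11b, h22b, h12b, gnorm2 = self._newton(u_r, theta, tol, maxiter)
            better = g2 < g
            u = np.where(better[:, None], u2, u)
            g = np.where(better, g2, g)
            h11 = np.where(better, h11b, h11)
            h22 = np.where(better, h22b, h22)
            h12 = np.where(better, h12b, h12)
        self.u_warm = u
        return u, g, h11, h22, h12

    # -- marginal log-likelihood --------------------------------------------

    def loglik(self, theta, method="laplace", gh_nodes=5):
        if method == "laplace" and _kernels.HAVE_NUMBA:
            if self.u_warm is None:
                self.u_warm = self._u_init()
            arr = self.arr
            return float(
                _kernels.laplace_loglik(
                    np.asarray(theta, dtype=float),
                    arr.t, arr.y,
                    arr.nobs_per_animal.astype(np.int64),
                    arr.treated,
                    arr.scale == "radius",
                    self.u_warm,
                    self._u_init(),
                )
            )
        u, g, h11, h22, h12 = self._find_modes(theta)
        # ridge any non-PD curvature (possible for animals stuck short of
        # the mode) so the Laplace determinant stays meaningful
        tr = h11 + h22
        disc = np.sqrt((h11 - h22) ** 2 + 4.0 * h12**2)
        lam_min = 0.5 * (tr - disc)
        ridge = np.where(lam_min < 1e-8, 1e-8 - lam_min, 0.0)
        h11 = h11 + ridge
        h22 = h22 + ridge
        det = h11 * h22 - h12**2
        det = np.maximum(det, 1e-300)
        if method == "laplace":
            return float(np.sum(-g + _LOG2PI - 0.5 * np.log(det)))
        if method != "aghq":
            raise ValueError("integration method must be 'laplace' or 'aghq'")
        # adaptive Gauss-Hermite centred at the mode, scaled by H^{-1/2}
        z, wgh = np.polynomial.hermite.hermgauss(gh_nodes)
        zz1, zz2 = np.meshgrid(z, z, indexing="ij")
        zz1, zz2 = zz1.ravel(), zz2.ravel()
        logw = np.log(np.outer(wgh, wgh)).ravel() + zz1**2 + zz2**2
        # Cholesky of H^{-1} per animal
        c11 = h22 / det
        c12 = -h12 / det
        c22 = h11 / det
        l11 = np.sqrt(c11)
        l21 = c12 / l11
        l22 = np.sqrt(np.maximum(c22 - l21**2, 1e-300))
        root2 = math.sqrt(2.0)
        u1p = u[:, 0:1] + root2 * l11[:, None] * zz1[None, :]
        u2p = u[:, 1:2] + root2 * (
            l21[:, None] * zz1[None, :] + l22[:, None] * zz2[None, :]
        )
        gp = self._g_only(u1p, u2p, theta)
        from scipy.special import logsumexp

        li = math.log(2.0) + np.log(l11 * l22) + logsumexp(logw[None, :] - gp, axis=1)
        return float(li.sum())


def _unpack_mixed(x, with_effect):
    mu1, mu2, ls1, ls2, ls3 = x[:5]
    c = x[5] if with_effect else 0.0
    return mu1, mu2, math.exp(ls1), math.exp(ls2), math.exp(ls3), c


# ---------------------------------------------------------------------------
# Public model / results classes


class TumorGrowthModel:
    """Linear-radius tumour growth model for one two-arm study.

    Parameters
    ----------
    study : StudyTable
        Two-arm measurement series.
    scale : {"radius", "volume"}
        Regress against radii (default; measurement error lives on the
        length scale) or raw volumes.
    approach : {"mixed", "pooled"}
        Mixed-effects (animal-level random baseline and growth rate) or
        naive pooled fixed-effects fit.  Pooled supports the radius scale
        only.
    treatment_effect : bool
        Include the treatment effect ``c`` on the treated arm's log
        growth rate.
    integration : {"laplace", "aghq"}
        Approximation of the per-animal marginal integral (mixed only).
    """

    def __init__(
        self,
        study: StudyTable,
        scale: str = "radius",
        approach: str = "mixed",
        treatment_effect: bool = True,
        integration: str = "laplace",
        gh_nodes: int = 5,
    ):
        if scale not in ("radius", "volume"):
            raise ValueError("scale must be 'radius' or 'volume'")
        if approach not in ("mixed", "pooled"):
            raise ValueError("approach must be 'mixed' or 'pooled'")
        if approach == "pooled" and scale != "radius":
            raise ValueError("the pooled approach supports the radius scale only")
        counts = [a.n_obs for a in study.animals]
        if len(counts) < 2 or min(counts) < 2:
            raise ValueError("need >= 2 animals with >= 2 timepoints each")
        self.study = study
        self.scale = scale
        self.approach = approach
        self.treatment_effect = bool(treatment_effect)
        self.integration = integration
        self.gh_nodes = gh_nodes
        self._arr = _StudyArrays(study, scale)

    @classmethod
    def from_dataframe(
        cls, df, horizon=None, study_id=None, **kwargs
    ) -> "TumorGrowthModel":
        """Build from a long-format table (study, arm, animal, day, volume_mm3)."""
        from .studydata import StudyDatabase

        db = StudyDatabase.from_dataframe(df)
        if horizon is not None:
            db = db.truncate(horizon)
        tables = db.to_study_tables()
        if study_id is None:
            if len(tables) != 1:
                raise ValueError(
                    "table holds several studies; pass study_id to select one"
                )
            table = tables[0]
        else:
            match = [s for s in tables if s.study_id == str(study_id)]
            if not match:
                raise KeyError(f"study {study_id!r} not found")
            table = match[0]
        return cls(table, **kwargs)

    # -- starting values -----------------------------------------------------

    def _start(self) -> np.ndarray:
        arr = self._arr
        a0, b0 = _per_animal_lines(arr)
        la, lb = np.log(a0), np.log(b0)
        treated = arr.treated.astype(bool)
        mu1 = float(la.mean())
        if self.treatment_effect and treated.any() and (~treated).any():
            mu2 = float(lb[~treated].mean())
            c0 = float(lb[treated].mean() - mu2)
        else:
            mu2 = float(lb.mean())
            c0 = 0.0
        s1 = float(np.clip(la.std(), 0.05, 2.0))
        s2 = float(np.clip(lb.std(), 0.05, 2.0))
        # proportional residual spread around per-animal lines (radius scale)
        pred = a0[:, None] + b0[:, None] * arr.t
        rel = (arr.r - pred) / np.maximum(pred, 1e-6)
        s3 = float(np.clip(rel[arr.mask].std(), 0.01, 1.0))
        if self.scale == "volume":
            s3 = min(3.0 * s3, 1.0)
        x = [mu1, mu2, math.log(s1), math.log(s2), math.log(s3)]
        if self.treatment_effect:
            x.append(np.clip(c0, -5.0, 5.0))
        return np.array(x)

    # -- fitting -------------------------------------------------------------

    def fit(self, start=None, maxiter: int = 300) -> "GrowthResults":
        """Maximize the (marginal) likelihood; returns a results object."""
        if self.approach == "mixed":
            return self._fit_mixed(start, maxiter)
        return self._fit_pooled(start, maxiter)

    def _fit_mixed(self, start, maxiter) -> "GrowthResults":
        lik = _MixedLik(self._arr, self.treatment_effect)
        method, nodes = self.integration, self.gh_nodes

        def nll(x):
            theta = _unpack_mixed(x, self.treatment_effect)
            try:
                return -lik.loglik(theta, method, nodes)
            except FloatingPointError:  # pragma: no cover
                return 1e12

        x0 = np.asarray(start, dtype=float) if start is not None else self._start()
        lo, hi = _LOG_SIG_BOUNDS
        bounds = [(-10, 10), (-12, 8), (lo, hi), (lo, hi), (lo, hi)]
        if self.treatment_effect:
            bounds.append((-25, 10))
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds, jac="3-point",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
        )
        converged = bool(res.success)
        if not converged:
            res2 = optimize.minimize(
                nll, res.x, method="Nelder-Mead",
                options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-9},
            )
            if res2.fun <= res.fun:
                res = res2
            converged = bool(res2.success)
        theta = _unpack_mixed(res.x, self.treatment_effect)
        boundary = any(
            abs(v - b) < 1e-9 for v in res.x[2:5] for b in _LOG_SIG_BOUNDS
        )
        params = GrowthParams(
            mu1=theta[0], mu2=theta[1], sigma1=theta[2], sigma2=theta[3],
            sigma3=theta[4], c=theta[5],
        )
        return GrowthResults(
            model=self, params=params, theta=res.x.copy(), loglik=-float(res.fun),
            converged=converged, boundary=boundary, nll=nll,
        )

    def _fit_pooled(self, start, maxiter) -> "GrowthResults":
        arr = self._arr
        t, y, w = arr.t, arr.y, arr.mask.astype(float)
        treated = arr.treated[:, None]
        nobs = arr.nobs

        def profile(x):
            mu1, mu2 = x[0], x[1]
            c = x[2] if self.treatment_effect else 0.0
            a = math.exp(mu1)
            b = np.exp(mu2 + c * treated)
            m = a + b * t
            rel = (y - m) / m
            s3sq = float(np.sum(w * rel**2) / nobs)
            s3 = max(math.sqrt(s3sq), _SIGMA_FLOOR)
            nllv = (
                nobs * math.log(s3)
                + float(np.sum(w * np.log(m)))
                + 0.5 * nobs * _LOG2PI
                + 0.5 * float(np.sum(w * rel**2)) / s3**2
            )
            return nllv, s3

        def nll(x):
            return profile(x)[0]

        if start is not None:
            x0 = np.asarray(start, dtype=float)
        else:
            s = self._start()
            x0 = np.array([s[0], s[1]] + ([s[5]] if self.treatment_effect else []))
        res = optimize.minimize(
            nll, x0, method="Nelder-Mead",
            options={"maxiter": 5000, "xatol": 1e-10, "fatol": 1e-12},
        )
        _, s3 = profile(res.x)
        c = float(res.x[2]) if self.treatment_effect else 0.0
        params = GrowthParams(
            mu1=float(res.x[0]), mu2=float(res.x[1]),
            sigma1=0.0, sigma2=0.0, sigma3=s3, c=c,
        )
        return GrowthResults(
            model=self, params=params, theta=res.x.copy(), loglik=-float(res.fun),
            converged=bool(res.success), boundary=s3 <= _SIGMA_FLOOR, nll=nll,
        )


class GrowthResults:
    """Fit results: estimates, uncertainty, diagnostics, LRT helper."""

    def __init__(self, model, params, theta, loglik, converged, boundary, nll):
        self.model = model
        self.params = params
        self.theta = theta
        self.loglik = loglik
        self.converged = converged
        self.boundary = boundary
        self._nll = nll
        self._cov = None

    # -- metadata ------------------------------------------------------------

    @property
    def n_animals(self) -> int:
        return self.model._arr.n_animals

    @property
    def nobs(self) -> int:
        return self.model._arr.nobs

    @property
    def scale(self) -> str:
        return self.model.scale

    @property
    def approach(self) -> str:
        return self.model.approach

    @property
    def param_names(self) -> list:
        if self.model.approach == "mixed":
            names = ["mu1", "mu2", "sigma1", "sigma2", "sigma3"]
        else:
            names = ["mu1", "mu2"]
        if self.model.treatment_effect:
            names.append("c")
        return names

    @property
    def estimates(self) -> dict:
        p = self.params
        vals = {"mu1": p.mu1, "mu2": p.mu2, "sigma1": p.sigma1,
                "sigma2": p.sigma2, "sigma3": p.sigma3, "c": p.c}
        return {k: vals[k] for k in self.param_names}

    # -- uncertainty ---------------------------------------------------------

    def _cov_theta(self):
        """Covariance of the internal parameter vector via the observed
        information (central finite differences of the negative loglik)."""
        if self._cov is not None:
            return self._cov
        x = np.asarray(self.theta, dtype=float)
        k = len(x)
        h = 1e-4 * (1.0 + np.abs(x))
        H = np.empty((k, k))
        f = self._nll
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * h[i] * h[j])
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        self._cov = cov
        return cov

    @property
    def bse(self) -> dict:
        """Standard errors on the natural parameter scale (delta method for
        the sigmas, which are optimized as logs)."""
        cov = self._cov_theta()
        var = np.diag(cov).copy()
        var[var < 0] = np.nan
        se = np.sqrt(var)
        names = self.param_names
        out = {}
        for i, name in enumerate(names):
            if name.startswith("sigma"):
                out[name] = float(se[i] * self.estimates[name])
            else:
                out[name] = float(se[i])
        return out

    # -- inference -----------------------------------------------------------

    def compare_lr_test(self, null_results: "GrowthResults") -> TestResult:
        """Likelihood-ratio test of this (treatment-effect) fit against a
        nested null fit on the same data."""
        return lrt(null_results, self)

    # -- presentation --------------------------------------------------------

    def summary(self) -> str:
        est = self.estimates
        try:
            ses = self.bse
        except Exception:  # pragma: no cover
            ses = {k: float("nan") for k in est}
        lines = [
            "Linear-radius tumour growth model",
            "=" * 46,
            f"approach:  {self.approach:<10} scale: {self.scale}",
            f"animals:   {self.n_animals:<10} observations: {self.nobs}",
            f"log-likelihood: {self.loglik:.4f}",
            f"converged: {self.converged}"
            + ("   (boundary estimate)" if self.boundary else ""),
            "-" * 46,
            f"{'param':<8}{'estimate':>12}{'std err':>12}",
        ]
        for k in est:
            lines.append(f"{k:<8}{est[k]:>12.5f}{ses.get(k, float('nan')):>12.5f}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "approach": self.approach,
            "scale": self.scale,
            "n_animals": self.n_animals,
            "nobs": self.nobs,
            "loglik": self.loglik,
            "converged": self.converged,
            "boundary": self.boundary,
            "estimates": self.estimates,
        }


# ---------------------------------------------------------------------------
# Functional wrappers


def fit_mixed(
    study: StudyTable,
    scale: str = "radius",
    with_treatment_effect: bool = True,
    **kwargs,
) -> GrowthResults:
    """Fit the mixed-effects growth model to a two-arm study."""
    return TumorGrowthModel(
        study, scale=scale, approach="mixed", treatment_effect=with_treatment_effect,
        **kwargs,
    ).fit()


def fit_pooled(study: StudyTable, with_treatment_effect: bool = True) -> GrowthResults:
    """Fit the naive pooled (fixed-effects) radius model."""
    return TumorGrowthModel(
        study, scale="radius", approach="pooled",
        treatment_effect=with_treatment_effect,
    ).fit()


def lrt(fit_null: GrowthResults, fit_alt: GrowthResults) -> TestResult:
    """Likelihood-ratio test for the treatment effect between nested fits.

    The statistic 2 * (loglik_alt - loglik_null) is referred to the
    chi-square distribution with 1 df (the effect is a single interior
    parameter); small negative values from optimizer tolerance are
    clipped to zero.
    """
    if fit_null.model.treatment_effect or not fit_alt.model.treatment_effect:
        raise ValueError(
            "expected a null fit (no treatment effect) and an alternative "
            "fit (with treatment effect)"
        )
    same = (
        fit_null.scale == fit_alt.scale
        and fit_null.approach == fit_alt.approach
        and fit_null.n_animals == fit_alt.n_animals
        and fit_null.nobs == fit_alt.nobs
    )
    if not same:
        raise ValueError("fits must share the data, scale and approach")
    stat = 2.0 * (fit_alt.loglik - fit_null.loglik)
    if stat < -1e-4:
        warnings.warn(
            f"LRT statistic {stat:.3g} is negative beyond optimizer tolerance; "
            "the alternative fit may not have converged",
            RuntimeWarning,
            stacklevel=2,
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df=1))
    return TestResult(
        method=f"lrt_{fit_alt.approach}",
        statistic=float(stat),
        p_value=p,
        effect=float(fit_alt.params.c),
        horizon=float(fit_alt.model.study.horizon),
    )


def lr_treatment_test(
    study: StudyTable,
    scale: str = "radius",
    approach: str = "mixed",
    **kwargs,
) -> TestResult:
    """Convenience: fit null and alternative models and run the LRT.

    The alternative fit is warm-started from the null optimum (with c = 0)
    and from its own data-driven start, keeping whichever attains the
    higher likelihood, which enforces nesting up to optimizer tolerance.
    """
    null_model = TumorGrowthModel(
        study, scale=scale, approach=approach, treatment_effect=False, **kwargs
    )
    fit0 = null_model.fit()
    alt_model = TumorGrowthModel(
        study, scale=scale, approach=approach, treatment_effect=True, **kwargs
    )
    warm = np.append(fit0.theta, 0.0)
    fit1 = alt_model.fit(start=warm)
    if fit1.loglik < fit0.loglik:  # warm start failed to move; retry cold
        fit1b = alt_model.fit()
        if fit1b.loglik > fit1.loglik:
            fit1 = fit1b
    return lrt(fit0, fit1)
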