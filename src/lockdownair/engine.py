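"""Bayesian inference engine for linear-Gaussian mixed models with Matérn
spatial random effects.

Given the Matérn hyperparameters and the residual standard deviation, every
coefficient block of the pollution model (fixed spline coefficients, spatial
city deviations, day-of-week effects, covariate slopes) is jointly Gaussian
with an analytically available posterior.  The engine therefore works on the
marginal likelihood of the hyperparameters:

1. the coefficient vector is integrated out in closed form,
2. the hyperparameter posterior (marginal likelihood x PC priors, on the log
   scale) is maximised and approximated by a Laplace Gaussian at the mode,
3. posterior draws of the coefficients are obtained exactly from their
   conditional Gaussian, mixed over Laplace draws of the hyperparameters.

This mirrors the nested-Laplace strategy used for latent Gaussian models:
with a few dozen sites the exact dense Matérn covariance replaces any mesh
or sparse approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize

from .spatial import PCPrior, inverse_with_logdet, matern_cov_from_dist, haversine_km

#: Variance of the near-flat Gaussian prior on unstructured coefficients.
FLAT_PRIOR_VARIANCE = 1e6


@dataclass
class FlatComponent:
    """Coefficient block with an essentially flat Normal(0, 1e6) prior."""

    name: str
    x: np.ndarray  # (n_obs, q)
    prior_var: float = FLAT_PRIOR_VARIANCE


@dataclass
class MaternComponent:
    """Coefficient block (one value per site) with a Matérn GP prior.

    Carries its own (range, sd) hyperparameters, estimated under a PC prior.
    """

    name: str
    x: np.ndarray  # (n_obs, n_sites)
    coords: np.ndarray  # (n_sites, 2) lon/lat degrees
    pc_prior: PCPrior = field(default_factory=PCPrior)
    nu: float = 1.0


@dataclass
class EngineSettings:
    """Inference settings: draw count, seed and optimizer controls."""

    n_draws: int = 1000
    seed: int | None = None
    maxiter: int = 200
    hessian_step: float = 0.05
    range_bounds: tuple[float, float] = (10.0, 20000.0)


@dataclass
class Posterior:
    """Posterior draws and summaries from the marginal-likelihood engine."""

    draws: np.ndarray  # (n_draws, p) coefficient draws
    slices: dict[str, slice]
    theta_map: np.ndarray  # mode of (log sigma, [log range, log sd]...)
    theta_cov: np.ndarray
    theta_draws: np.ndarray
    theta_names: list[str]
    diagnostics: dict

    def block(self, name: str) -> np.ndarray:
        return self.draws[:, self.slices[name]]

    @property
    def sigma_draws(self) -> np.ndarray:
        return np.exp(self.theta_draws[:, 0])

    def hyper_draws(self, component: str) -> dict[str, np.ndarray]:
        out = {}
        for i, nm in enumerate(self.theta_names):
            if nm.startswith(component + "."):
                out[nm.split(".", 1)[1]] = np.exp(self.theta_draws[:, i])
        return out


class LinearGaussianModel:
    """y = sum_c X_c u_c + eps with Gaussian priors per component block."""

    def __init__(self, y: np.ndarray, components: list[FlatComponent | MaternComponent]):
        self.y = np.asarray(y, dtype=float).ravel()
        if not np.isfinite(self.y).all():
            raise ValueError("response contains non-finite values")
        self.components = components
        self.n = self.y.size
        xs, self.slices, start = [], {}, 0
        for c in components:
            q = c.x.shape[1]
            if c.x.shape[0] != self.n:
                raise ValueError(f"component {c.name}: design rows != n_obs")
            self.slices[c.name] = slice(start, start + q)
            xs.append(np.asarray(c.x, dtype=float))
            start += q
        self.p = start
        a = np.concatenate(xs, axis=1)
        self.ata = a.T @ a
        self.aty = a.T @ self.y
        self.yty = float(self.y @ self.y)
        self._a = a
        self.matern = [c for c in components if isinstance(c, MaternComponent)]
        self._dists = {c.name: haversine_km(c.coords) for c in self.matern}
        scale = float(np.std(self.y))
        self.scale = scale if scale > 0 else 1.0
        self.theta_names = ["log_sigma"]
        for c in self.matern:
            self.theta_names += [f"{c.name}.range_km", f"{c.name}.sd"]

    # -- marginal likelihood ------------------------------------------------
    def _prior_precision(self, theta: np.ndarray) -> tuple[np.ndarray, float]:
        """Block-diagonal prior precision and its log-determinant."""
        q_mat = np.zeros((self.p, self.p))
        logdet = 0.0
        for c in self.components:
            sl = self.slices[c.name]
            if isinstance(c, FlatComponent):
                q = sl.stop - sl.start
                q_mat[sl, sl] = np.eye(q) / c.prior_var
                logdet += -q * np.log(c.prior_var)
        for j, c in enumerate(self.matern):
            sl = self.slices[c.name]
            rng_km = np.exp(theta[1 + 2 * j])
            sd = np.exp(theta[2 + 2 * j])
            cov = matern_cov_from_dist(self._dists[c.name], rng_km, sd, c.nu)
            inv, ld = inverse_with_logdet(cov)
            q_mat[sl, sl] = inv
            logdet += -ld
        return q_mat, logdet

    def log_marginal_likelihood(self, theta: np.ndarray) -> float:
        sigma2 = np.exp(2.0 * theta[0])
        q_mat, logdet_q = self._prior_precision(theta)
        prec = self.ata / sigma2 + q_mat
        try:
            c, low = cho_factor(prec, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf
        logdet_p = 2.0 * np.sum(np.log(np.diag(c)))
        b = self.aty / sigma2
        m = cho_solve((c, low), b)
        quad = self.yty / sigma2 - float(b @ m)
        return float(
            -0.5 * self.n * np.log(2.0 * np.pi * sigma2)
            + 0.5 * logdet_q
            - 0.5 * logdet_p
            - 0.5 * quad
        )

    def log_hyper_prior(self, theta: np.ndarray) -> float:
        """PC priors on each Matérn (range, sd) with log-scale Jacobians;
        flat prior on log sigma."""
        lp = 0.0
        for j, c in enumerate(self.matern):
            log_r, log_s = theta[1 + 2 * j], theta[2 + 2 * j]
            lp += c.pc_prior.logpdf(np.exp(log_r), np.exp(log_s)) + log_r + log_s
        return lp

    def neg_log_posterior(self, theta: np.ndarray) -> float:
        val = self.log_marginal_likelihood(theta) + self.log_hyper_prior(theta)
        return -val if np.isfinite(val) else 1e300

    # -- fitting ------------------------------------------------------------
    def _bounds(self, settings: EngineSettings) -> list[tuple[float, float]]:
        s = self.scale
        bounds = [(np.log(1e-5 * s), np.log(1e3 * s))]
        for _ in self.matern:
            bounds.append(tuple(np.log(settings.range_bounds)))
            bounds.append((np.log(1e-4 * s), np.log(1e2 * s)))
        return bounds

    def _initial(self) -> np.ndarray:
        theta0 = [np.log(0.5 * self.scale)]
        for c in self.matern:
            theta0 += [np.log(c.pc_prior.range0), np.log(0.3 * self.scale)]
        return np.array(theta0)

    def _hessian(self, theta: np.ndarray, step: float) -> np.ndarray:
        """Central-difference Hessian of the negative log posterior."""
        k = theta.size
        h = np.full(k, step)
        hess = np.zeros((k, k))
        f0 = self.neg_log_posterior(theta)
        for i in range(k):
            ei = np.zeros(k); ei[i] = h[i]
            fpp = self.neg_log_posterior(theta + ei)
            fmm = self.neg_log_posterior(theta - ei)
            hess[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
            for j in range(i + 1, k):
                ej = np.zeros(k); ej[j] = h[j]
                fp = self.neg_log_posterior(theta + ei + ej)
                fm = self.neg_log_posterior(theta - ei - ej)
                fpm = self.neg_log_posterior(theta + ei - ej)
                fmp = self.neg_log_posterior(theta - ei + ej)
                hess[i, j] = hess[j, i] = (fp + fm - fpm - fmp) / (4 * h[i] * h[j])
        return hess

    def _conditional(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
        """Posterior mean and Cholesky precision of coefficients given theta."""
        sigma2 = np.exp(2.0 * theta[0])
        q_mat, _ = self._prior_precision(theta)
        prec = self.ata / sigma2 + q_mat
        # the shared fixed block and the sum of per-site blocks are exactly
        # collinear in the design; when sigma is tiny the prior no longer
        # regularises numerically, so escalate a diagonal jitter if needed
        base = np.mean(np.diag(prec))
        for jitter in (0.0, 1e-12, 1e-9, 1e-6):
            try:
                c, low = cho_factor(prec + jitter * base * np.eye(self.p), lower=True)
                break
            except np.linalg.LinAlgError:
                continue
        else:  # pragma: no cover
            raise FloatingPointError("coefficient precision not positive definite")
        m = cho_solve((c, low), self.aty / sigma2)
        return m, c, low

    def fit(self, settings: EngineSettings | None = None) -> Posterior:
        settings = settings or EngineSettings()
        if settings.seed is None:
            raise ValueError("a seed is required for posterior draws")
        rng = np.random.default_rng(settings.seed)
        bounds = self._bounds(settings)
        opt = minimize(
            self.neg_log_posterior,
            self._initial(),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": settings.maxiter},
        )
        theta_map = opt.x
        hess = self._hessian(theta_map, settings.hessian_step)
        eigval, eigvec = np.linalg.eigh(hess)
        hessian_pd = bool(np.all(eigval > 0))
        # clip non-positive curvature (flat/unidentified directions get wide,
        # bound-limited uncertainty rather than a crash)
        floor = max(1e-6, 1e-8 * np.abs(eigval).max())
        eigval = np.clip(eigval, floor, None)
        theta_cov = (eigvec / eigval) @ eigvec.T
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        chol_t = np.linalg.cholesky(theta_cov)
        # antithetic coefficient draws: each hyperparameter draw contributes a
        # +/- pair around its conditional mean, so the empirical mean of the
        # draws equals the mixture of conditional means exactly (no
        # coefficient-level Monte-Carlo error in posterior means)
        n_half = (settings.n_draws + 1) // 2
        theta_half = theta_map[None, :] + rng.standard_normal(
            (n_half, theta_map.size)
        ) @ chol_t.T
        theta_half = np.clip(theta_half, lo[None, :], hi[None, :])
        theta_draws = np.repeat(theta_half, 2, axis=0)[: settings.n_draws]
        draws = np.empty((settings.n_draws, self.p))
        for s in range(n_half):
            m, c, low = self._conditional(theta_half[s])
            z = rng.standard_normal(self.p)
            # prec = L L' (lower); draw = m + L'^{-1} z has covariance prec^{-1}
            dev = solve_triangular(c, z, lower=low, trans=1)
            draws[2 * s] = m + dev
            if 2 * s + 1 < settings.n_draws:
                draws[2 * s + 1] = m - dev
        converged = bool(opt.success) and hessian_pd
        if not converged:
            warnings.warn(
                "hyperparameter optimisation did not fully converge "
                f"(success={opt.success}, hessian_pd={hessian_pd}); "
                "posterior summaries may be unreliable",
                RuntimeWarning,
                stacklevel=2,
            )
        diagnostics = {
            "converged": converged,
            "opt_success": bool(opt.success),
            "opt_message": str(opt.message),
            "neg_log_posterior": float(opt.fun),
            "n_function_evals": int(opt.nfev),
            "hessian_pd": hessian_pd,
            "n_draws": int(settings.n_draws),
            "seed": int(settings.seed),
        }
        return Posterior(
            draws=draws,
            slices=dict(self.slices),
            theta_map=theta_map,
            theta_cov=theta_cov,
            theta_draws=theta_draws,
            theta_names=list(self.theta_names),
            diagnostics=diagnostics,
        )

    def fitted_draws(self, posterior: Posterior) -> np.ndarray:
        """(n_draws, n_obs) posterior draws of the linear predictor."""
        return posterior.draws @ self._a.T


def sum_to_zero_contrast(n_levels: int = 7) -> np.ndarray:
    """(n_levels, n_levels-1) contrast whose image is the sum-to-zero subspace."""
    t = np.vstack([np.eye(n_levels - 1), -np.ones(n_levels - 1)])
    return t
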