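"""Spatial covariance machinery: great-circle distances, the Matérn family,
penalized-complexity (PC) priors for its hyperparameters, and exact Gaussian
field draws over a finite set of cities.

City-level random coefficients are modelled as draws from a zero-mean
Gaussian process with a Matérn covariance over great-circle distance.  With a
few dozen sites the dense covariance is tiny, so everything here works with
the exact covariance matrix rather than any sparse approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.special import gamma as gamma_fn
from scipy.special import kv

EARTH_RADIUS_KM = 6371.0088


def haversine_km(coords_a: np.ndarray, coords_b: np.ndarray | None = None) -> np.ndarray:
    """Great-circle distance matrix in km between (lon, lat) degree coordinates.

    Parameters
    ----------
    coords_a : (n, 2) array of (longitude, latitude) in degrees.
    coords_b : optional (m, 2) array; defaults to ``coords_a``.

    Returns
    -------
    (n, m) distance matrix in kilometres.
    """
    a = np.asarray(coords_a, dtype=float)
    b = a if coords_b is None else np.asarray(coords_b, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or b.ndim != 2 or b.shape[1] != 2:
        raise ValueError("coordinates must be (n, 2) arrays of (lon, lat)")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite coordinates")
    lon1, lat1 = np.radians(a[:, 0])[:, None], np.radians(a[:, 1])[:, None]
    lon2, lat2 = np.radians(b[:, 0])[None, :], np.radians(b[:, 1])[None, :]
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def matern_cov(
    coords: np.ndarray,
    range_km: float,
    marginal_sd: float,
    nu: float = 1.0,
    jitter: float = 1e-8,
) -> np.ndarray:
    """Matérn covariance matrix over great-circle distances.

    Uses the "range" parameterisation common in spatial statistics, where the
    correlation drops to about 0.13 at distance ``range_km``:

        C(d) = sd^2 * (kappa d)^nu * K_nu(kappa d) / (2^(nu-1) Gamma(nu)),
        kappa = sqrt(8 nu) / range_km.

    A diagonal jitter of ``jitter * sd^2`` keeps the matrix numerically
    positive definite.
    """
    if range_km <= 0:
        raise ValueError("range_km must be positive")
    if marginal_sd < 0:
        raise ValueError("marginal_sd must be non-negative")
    if nu <= 0:
        raise ValueError("nu must be positive")
    d = haversine_km(coords)
    return matern_cov_from_dist(d, range_km, marginal_sd, nu, jitter=jitter)


def matern_cov_from_dist(
    d: np.ndarray,
    range_km: float,
    marginal_sd: float,
    nu: float = 1.0,
    jitter: float = 1e-8,
) -> np.ndarray:
    """Matérn covariance from a precomputed distance matrix (see matern_cov)."""
    d = np.asarray(d, dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("non-finite distances")
    var = marginal_sd**2
    kappa = np.sqrt(8.0 * nu) / range_km
    scaled = kappa * d
    corr = np.ones_like(scaled)
    pos = scaled > 0
    s = scaled[pos]
    corr[pos] = (s**nu) * kv(nu, s) / (2.0 ** (nu - 1.0) * gamma_fn(nu))
    cov = var * corr
    if cov.ndim == 2 and cov.shape[0] == cov.shape[1]:
        cov[np.diag_indices_from(cov)] = var
        cov = cov + jitter * var * np.eye(cov.shape[0])
    return cov


@dataclass(frozen=True)
class PCPrior:
    """Penalized-complexity prior for a Matérn field's (range, sd).

    Defined by the tail probabilities
    ``P(range < range0) = alpha_range`` and ``P(sd > sd0) = alpha_sd``.
    In two spatial dimensions the implied densities are

        pi(range) = (d/2) lam_r range^(-d/2 - 1) exp(-lam_r range^(-d/2)),
        pi(sd)    = lam_s exp(-lam_s sd),

    with d = 2, lam_r = -log(alpha_range) * range0^(d/2) and
    lam_s = -log(alpha_sd) / sd0.
    """

    range0: float = 500.0
    alpha_range: float = 0.5
    sd0: float = 10.0
    alpha_sd: float = 0.05
    dim: int = 2

    def __post_init__(self) -> None:
        if self.range0 <= 0 or self.sd0 <= 0:
            raise ValueError("range0 and sd0 must be positive")
        for a in (self.alpha_range, self.alpha_sd):
            if not 0.0 < a < 1.0:
                raise ValueError("tail probabilities must lie in (0, 1)")

    @property
    def lam_range(self) -> float:
        return -np.log(self.alpha_range) * self.range0 ** (self.dim / 2.0)

    @property
    def lam_sd(self) -> float:
        return -np.log(self.alpha_sd) / self.sd0

    def logpdf_range(self, range_km: float | np.ndarray) -> float | np.ndarray:
        r = np.asarray(range_km, dtype=float)
        half_d = self.dim / 2.0
        lam = self.lam_range
        with np.errstate(divide="ignore"):
            out = np.where(
                r > 0,
                np.log(half_d) + np.log(lam) - (half_d + 1.0) * np.log(r) - lam * r**-half_d,
                -np.inf,
            )
        return out if out.ndim else float(out)

    def logpdf_sd(self, sd: float | np.ndarray) -> float | np.ndarray:
        s = np.asarray(sd, dtype=float)
        lam = self.lam_sd
        out = np.where(s >= 0, np.log(lam) - lam * s, -np.inf)
        return out if out.ndim else float(out)

    def logpdf(self, range_km: float, sd: float) -> float:
        """Joint log-density (range and sd independent a priori)."""
        return float(self.logpdf_range(range_km)) + float(self.logpdf_sd(sd))


def pc_prior_logdensity(range_km: float, marginal_sd: float, pc_prior: PCPrior) -> float:
    """Joint PC-prior log density at (range_km, marginal_sd)."""
    return pc_prior.logpdf(range_km, marginal_sd)


def sample_matern_fields(
    coords: np.ndarray,
    range_km: float,
    sd: float,
    nu: float = 1.0,
    n_fields: int = 1,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw independent zero-mean Matérn Gaussian fields at fixed sites.

    Returns an (n_sites, n_fields) matrix whose columns are i.i.d. draws from
    N(0, C) with C the Matérn covariance over great-circle distances.  With
    sd = 0 the result is exactly zero.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sites for a spatial field")
    if range_km <= 0:
        raise ValueError("range_km must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0.0:
        return np.zeros((n, n_fields))
    rng = np.random.default_rng(rng)
    cov = matern_cov(coords, range_km, sd, nu)
    try:
        chol = cholesky(cov, lower=True)
    except np.linalg.LinAlgError as err:  # pragma: no cover - jitter normally suffices
        raise FloatingPointError("Matérn covariance not positive definite after jitter") from err
    z = rng.standard_normal((n, n_fields))
    return chol @ z


def inverse_with_logdet(cov: np.ndarray) -> tuple[np.ndarray, float]:
    """Return (inverse, log-determinant) of an SPD matrix via Cholesky."""
    c, low = cho_factor(cov, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    inv = cho_solve((c, low), np.eye(cov.shape[0]))
    return inv, logdet
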