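"""Overdispersed count emission distributions and their weighted MLE.

Two families model per-bin read counts given a chromatin state:

* negative binomial — Poisson with a Gamma-distributed rate; parameterized
  by mean ``mu`` and size (inverse overdispersion) ``r``, variance
  ``mu + mu^2/r``;
* Poisson-lognormal — Poisson with a lognormally distributed rate
  ``log(lambda) ~ N(mu_log, sigma^2)``; no closed-form pmf, evaluated by
  mode-centered Gauss-Hermite quadrature.

Sequencing-depth differences across cell types enter as multiplicative
size factors on the mean: a count from cell type ``l`` is modeled with mean
``mu * s_{d,l}`` (NB) or log-mean ``mu_log + log(s_{d,l})`` (Poilog).

Weighted fitting groups observations by unique count value (and size factor)
first, so the likelihood is evaluated on the few hundred distinct counts a
track contains rather than on every genomic bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

# pmf floor inside EM: keeps log-likelihoods finite for outlier bins
LOG_PMF_FLOOR = np.log(1e-300)

SIGMA_MIN = 1e-2   # lower box bound for the poilog sd
SIGMA_MAX = 10.0
MU_FLOOR = 1e-3    # reads/bin at size factor 1, for degenerate all-zero fits

# Panelled Gauss-Legendre grid for the poilog integral, in units of the
# posterior-mode scale: panel edges grow geometrically away from the mode so
# the narrow likelihood core and the wide prior-dominated left tail are both
# resolved (the integrand is log-concave, so it dies within these edges for
# any x, sigma combination of practical interest).
_PANEL_EDGES = np.array([0, 0.5, 1, 1.5, 2, 2.5, 3, 4, 5, 6, 8, 10, 12, 16,
                         20, 24, 32, 40, 48, 64, 80, 96, 128, 160, 192, 256,
                         320, 384, 448, 512], dtype=float)
_GL_X, _GL_W = np.polynomial.legendre.leggauss(10)


def _build_quad_grid():
    """Relative node offsets and log-weights for both sides of the mode."""
    offs, logw = [], []
    for sign in (1.0, -1.0):
        for a, b in zip(_PANEL_EDGES[:-1], _PANEL_EDGES[1:]):
            mid, half = 0.5 * (a + b), 0.5 * (b - a)
            offs.append(sign * (mid + half * _GL_X))
            logw.append(np.log(half * _GL_W))
    return np.concatenate(offs), np.concatenate(logw)


_QUAD_OFFSETS, _QUAD_LOGW = _build_quad_grid()


@dataclass(frozen=True)
class NegBinomParams:
    """Negative binomial with mean ``mu`` and size ``r`` (variance mu + mu^2/r)."""
    mu: float
    size: float

    def __post_init__(self):
        if not (self.mu > 0 and self.size > 0):
            raise ValueError("mu and size must be positive")


@dataclass(frozen=True)
class PoilogParams:
    """Poisson-lognormal: rate lambda with log(lambda) ~ N(mu_log, sigma^2)."""
    mu_log: float
    sigma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")

    @property
    def mean(self) -> float:
        return float(np.exp(self.mu_log + self.sigma ** 2 / 2.0))


def _check_counts(x) -> np.ndarray:
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.integer):
        if not np.all(np.equal(np.mod(x, 1), 0)):
            raise ValueError("counts must be integers")
        x = x.astype(np.int64)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    return x


def nb_log_pmf(x, params: NegBinomParams, size_factor=1.0) -> np.ndarray:
    """Log pmf of NB with mean ``mu * s`` and size ``r``.

    pmf(x) = Gamma(r+x)/(x! Gamma(r)) * (m/(r+m))^x * (r/(r+m))^r, m = mu*s.
    """
    x = _check_counts(x)
    s = np.asarray(size_factor, dtype=float)
    if np.any(s <= 0):
        raise ValueError("size factor must be positive")
    m = params.mu * s
    r = params.size
    return stats.nbinom.logpmf(x, r, r / (r + m))


def _poilog_log_pmf_core(x: np.ndarray, m: np.ndarray, sigma: float) -> np.ndarray:
    """Log poilog pmf for integer x >= 0 with log-rate ~ N(m, sigma^2).

    Deterministic quadrature on z = log(lambda): the log-integrand
    h(z) = x z - e^z - (z-m)^2/(2 sigma^2) - log x! - log(sqrt(2 pi) sigma)
    is globally log-concave, so damped Newton finds its unique mode; panelled
    Gauss-Legendre nodes scaled by the local curvature then integrate it.
    """
    x = x.astype(float)
    inv_var = 1.0 / sigma ** 2
    # Newton for the mode of h; h'' = -e^z - 1/sigma^2 < 0 everywhere
    z = np.where(x > 0, np.log(np.maximum(x, 1e-12)), m - sigma ** 2)
    z = np.minimum(z, m + sigma ** 2 * np.maximum(x, 1.0))  # keep start sane
    for _ in range(200):
        ez = np.exp(z)
        grad = x - ez - (z - m) * inv_var
        hess = -ez - inv_var
        step = grad / hess
        # damp: |step| <= 2 keeps e^z from overflowing en route
        step = np.clip(step, -2.0, 2.0)
        z = z - step
        if np.max(np.abs(step)) < 1e-13:
            break
    scale = 1.0 / np.sqrt(np.exp(z) + inv_var)  # sqrt(-1/h'') at the mode
    nodes = z[..., None] + scale[..., None] * _QUAD_OFFSETS
    with np.errstate(over="ignore"):
        h = (x[..., None] * nodes - np.exp(nodes)
             - 0.5 * (nodes - m[..., None]) ** 2 * inv_var)
    h = np.nan_to_num(h, nan=-np.inf, neginf=-np.inf)
    h = h - special.gammaln(x + 1.0)[..., None] - 0.5 * np.log(2.0 * np.pi * sigma ** 2)
    return (special.logsumexp(_QUAD_LOGW + h, axis=-1) + np.log(scale))


def poilog_log_pmf(x, params: PoilogParams, size_factor=1.0) -> np.ndarray:
    """Log pmf of the Poisson-lognormal with log-mean ``mu_log + log(s)``."""
    x = _check_counts(x)
    s = np.asarray(size_factor, dtype=float)
    if np.any(s <= 0):
        raise ValueError("size factor must be positive")
    if params.sigma <= 0:
        raise ValueError("sigma must be positive")
    scalar = np.isscalar(x) or (np.ndim(x) == 0 and np.ndim(s) == 0)
    xb, sb = np.broadcast_arrays(np.atleast_1d(x), np.atleast_1d(s))
    m = params.mu_log + np.log(sb.astype(float))
    out = _poilog_log_pmf_core(xb.astype(np.int64), m, params.sigma)
    return float(out[0]) if scalar and out.size == 1 else out


@dataclass
class GroupedCounts:
    """Unique (count, size-factor) groups with pooled posterior weights f_c.

    ``sum(weights)`` equals the total posterior weight of the underlying
    bins; evaluating the emission log-likelihood on groups is exactly
    equivalent to the per-bin sum.
    """

    counts: np.ndarray        # unique count values c
    size_factors: np.ndarray  # size factor of each group
    weights: np.ndarray       # f_c = sum of per-bin weights in the group

    def __post_init__(self):
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")

    def total_weight(self) -> float:
        return float(self.weights.sum())

    def objective(self, family: str, params) -> float:
        """Weighted log-likelihood sum_c f_c log psi(c)."""
        logp = _family_log_pmf(family, self.counts, params, self.size_factors)
        return float(np.dot(self.weights, np.maximum(logp, LOG_PMF_FLOOR)))


def _family_log_pmf(family: str, x, params, s):
    if family == "negbinom":
        return nb_log_pmf(x, params, s)
    if family == "poilog":
        return poilog_log_pmf(x, params, s)
    raise ValueError(f"unknown emission family {family!r}")


def group_counts(track_column, weights, size_factor=1.0) -> GroupedCounts:
    """Group a count column by unique (count, size factor) with summed weights.

    ``size_factor`` may be a scalar (single cell type) or a per-bin array
    (concatenated cell types with differing depths).
    """
    c = _check_counts(track_column)
    w = np.asarray(weights, dtype=float)
    if w.shape != c.shape:
        raise ValueError("weights must have the same length as the count column")
    s = np.broadcast_to(np.asarray(size_factor, dtype=float), c.shape)
    keys = np.stack([c.astype(np.float64), s], axis=1)
    uniq, inv = np.unique(keys, axis=0, return_inverse=True)
    f = np.bincount(inv, weights=w, minlength=len(uniq))
    return GroupedCounts(counts=uniq[:, 0].astype(np.int64),
                         size_factors=uniq[:, 1], weights=f)


def _perturb(theta, rng, scale=0.3):
    return theta + rng.normal(0.0, scale, size=len(theta))


def fit_emission(grouped: GroupedCounts, family: str, init,
                 n_restarts: int = 3, seed: int = 0):
    """Maximize ``sum_c f_c log psi(c)`` over the family's parameters.

    Bounded quasi-Newton in log-parameters; the returned parameters never
    score worse than ``init`` (the init is kept if optimization fails to
    improve). Degenerate input with all weight on zero counts returns a
    floored-mean distribution instead of a zero mean.
    """
    if grouped.total_weight() <= 0:
        raise ValueError("total grouped weight must be positive")
    rng = np.random.default_rng(seed)
    f, c, s = grouped.weights, grouped.counts.astype(float), grouped.size_factors
    wmean_scaled = float(np.dot(f, c) / np.dot(f, s))  # MLE of mu for NB, fixed r

    if family == "negbinom":
        if wmean_scaled <= 0:  # all weight on zero counts
            return NegBinomParams(mu=MU_FLOOR, size=init.size)
        if np.allclose(s, s[0]):
            # single size factor: the mean MLE is the weighted sample mean / s
            # for any r, so only the size needs numerical optimization
            mu_hat = wmean_scaled

            def neg_obj_r(log_r):
                return -grouped.objective(
                    family, NegBinomParams(mu_hat, float(np.exp(log_r))))

            best = NegBinomParams(mu_hat, init.size)
            res = optimize.minimize_scalar(neg_obj_r,
                                           bounds=(np.log(1e-4), np.log(1e8)),
                                           method="bounded",
                                           options={"xatol": 1e-10})
            cand = NegBinomParams(mu_hat, float(np.exp(res.x)))
            if grouped.objective(family, cand) > grouped.objective(family, best):
                best = cand
        else:
            bounds = [(np.log(1e-6), np.log(1e9)), (np.log(1e-4), np.log(1e8))]

            def neg_obj(theta):
                p = NegBinomParams(float(np.exp(theta[0])), float(np.exp(theta[1])))
                return -grouped.objective(family, p)

            theta0 = np.array([np.log(init.mu), np.log(init.size)])
            starts = [theta0, np.array([np.log(wmean_scaled), np.log(init.size)])]
            starts += [_perturb(theta0, rng) for _ in range(n_restarts - 1)]
            best_theta, best_val = theta0, neg_obj(theta0)
            for st in starts:
                st = np.clip(st, [b[0] for b in bounds], [b[1] for b in bounds])
                res = optimize.minimize(neg_obj, st, method="L-BFGS-B", bounds=bounds)
                if np.isfinite(res.fun) and res.fun < best_val:
                    best_theta, best_val = res.x, res.fun
            best = NegBinomParams(float(np.exp(best_theta[0])),
                                  float(np.exp(best_theta[1])))
        if grouped.objective(family, best) < grouped.objective(family, init) - 1e-9:
            best = init
        return best

    if family == "poilog":
        theta0 = np.array([init.mu_log, np.log(init.sigma)])
        bounds = [(-30.0, 30.0), (np.log(SIGMA_MIN), np.log(SIGMA_MAX))]

        def neg_obj(theta):
            p = PoilogParams(float(theta[0]), float(np.exp(theta[1])))
            return -grouped.objective(family, p)

        starts = [theta0]
        if wmean_scaled > 0:  # moment-based warm start
            starts.append(np.array([np.log(wmean_scaled), np.log(0.5)]))
        starts += [_perturb(theta0, rng) for _ in range(n_restarts - 1)]
        best_theta, best_val = theta0, neg_obj(theta0)
        for st in starts:
            st = np.clip(st, [b[0] for b in bounds], [b[1] for b in bounds])
            try:
                res = optimize.minimize(neg_obj, st, method="L-BFGS-B", bounds=bounds)
            except Exception:
                continue
            if np.isfinite(res.fun) and res.fun < best_val:
                best_theta, best_val = res.x, res.fun
        return PoilogParams(float(best_theta[0]), float(np.exp(best_theta[1])))

    raise ValueError(f"unknown emission family {family!r}")


@dataclass
class EmissionGrid:
    """K x D grid of emission parameters, one family per model."""

    family: str  # 'negbinom' | 'poilog'
    params: list  # params[k][d]

    def __post_init__(self):
        if self.family not in ("negbinom", "poilog"):
            raise ValueError(f"unknown emission family {self.family!r}")
        widths = {len(row) for row in self.params}
        if len(widths) > 1:
            raise ValueError("ragged emission grid")

    @property
    def n_states(self) -> int:
        return len(self.params)

    @property
    def n_tracks(self) -> int:
        return len(self.params[0])

    def log_pmf(self, k: int, d: int, x, size_factor=1.0) -> np.ndarray:
        return _family_log_pmf(self.family, x, self.params[k][d], size_factor)

    def log_emission_matrix(self, counts: np.ndarray, size_factors: np.ndarray
                            ) -> np.ndarray:
        """(T, K) per-bin log emission, tracks independent given the state.

        Evaluated on the unique counts of each track (the count-grouping
        speed-up), then scattered back to bins; floored at LOG_PMF_FLOOR.
        """
        T, D = counts.shape
        K = self.n_states
        logb = np.zeros((T, K))
        for d in range(D):
            uniq, inv = np.unique(counts[:, d], return_inverse=True)
            s = float(size_factors[d])
            for k in range(K):
                lp = _family_log_pmf(self.family, uniq, self.params[k][d], s)
                logb[:, k] += np.maximum(lp, LOG_PMF_FLOOR)[inv]
        return logb

    def means(self, size_factors=None) -> np.ndarray:
        """(K, D) distribution means at the given (default unit) size factors."""
        K, D = self.n_states, self.n_tracks
        s = np.ones(D) if size_factors is None else np.asarray(size_factors, float)
        out = np.empty((K, D))
        for k in range(K):
            for d in range(D):
                p = self.params[k][d]
                base = p.mu if self.family == "negbinom" else p.mean
                out[k, d] = base * s[d]
        return out
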