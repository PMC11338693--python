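"""Bayesian GLMMs for population growth rate and abundance.

Two models share one machinery:

* Growth model — group-year growth rates R_gt ~ Normal(mu, sigma^2) with
  mu = beta0 + beta'z + u_g, group random intercepts u_g ~ N(0, sigma_g^2);
  covariates are the standardized rodent index, elevation, their
  interaction and snow depth.

* Abundance model — transect-year track counts y_it ~ NegBin(mu, theta)
  (variance mu + mu^2/theta) with
  log mu = log(length) + log(days) + delta0 + delta'z + v_t,
  year random intercepts v_t ~ N(0, sigma_y^2); covariates additionally
  include mature-spruce and agricultural kernel densities.  The two
  log-effort offsets are summed into a single offset term.

Priors are weakly informative: Normal(0, 2^2) on every intercept and slope,
half-Normal(0, 2) on the standard deviations and Exponential(1) on the
inverse NB dispersion 1/theta.  Positive parameters are sampled on the log
scale with the Jacobian included.

Sampling uses an affine-invariant ensemble (emcee) initialised in a tight
ball around the posterior mode; ``chains`` independent ensembles are run
and treated as MCMC chains, so the usual split-R-hat and effective sample
size diagnostics (via arviz) apply across genuinely independent runs.
Convergence failures (R-hat >= 1.01) are flagged explicitly on the result,
never silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln

import emcee

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az

RHAT_LIMIT = 1.01
_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)

GROWTH_COVARIATES = ("rodent_index", "elevation", "rodent_x_elevation", "snow")
ABUNDANCE_COVARIATES = (
    "rodent_index",
    "elevation",
    "rodent_x_elevation",
    "snow",
    "spruce_density",
    "agri_density",
)


@dataclass(frozen=True)
class GrowthModelSpec:
    """Normal GLMM for R_gt with a group random intercept."""

    covariates: tuple[str, ...] = GROWTH_COVARIATES
    response: str = "growth_rate"
    group_col: str | None = "group_id"
    known_sigma: float | None = None  # fix the residual SD (conjugate checks)
    prior_sd: float = 2.0
    sd_prior_scale: float = 2.0
    noncentered: bool | None = None   # None: decide from data per level
    family: str = field(default="normal", init=False)


@dataclass(frozen=True)
class AbundanceModelSpec:
    """Negative-binomial GLMM for track counts with effort offsets."""

    covariates: tuple[str, ...] = ABUNDANCE_COVARIATES
    response: str = "tracks"
    year_col: str | None = "year"
    offset_cols: tuple[str, ...] = ("length_km", "days_since_snow")
    prior_sd: float = 2.0
    sd_prior_scale: float = 2.0
    noncentered: bool | None = None   # None: decide from data per level
    family: str = field(default="negbin", init=False)


@dataclass
class PosteriorDraws:
    """MCMC output: draws, summaries, and convergence diagnostics."""

    names: list[str]
    draws: np.ndarray               # (chains, draws_per_chain, n_params)
    mean: pd.Series
    cri_lower: pd.Series            # 80% equal-tailed by default
    cri_upper: pd.Series
    cri_level: float
    rhat: pd.Series
    ess_bulk: pd.Series
    converged: bool
    seed: int
    settings: dict

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def summary(self) -> pd.DataFrame:
        lo, hi = self.cri_lower, self.cri_upper
        return pd.DataFrame(
            {
                "mean": self.mean,
                f"cri_{self.cri_level:.0%}_lower": lo,
                f"cri_{self.cri_level:.0%}_upper": hi,
                "excludes_zero": (lo > 0) | (hi < 0),
                "rhat": self.rhat,
                "ess_bulk": self.ess_bulk,
            }
        )


# ---------------------------------------------------------------------------
# design construction and parameter packing


class _Design:
    """Model-frame arrays plus the parameter layout for one spec."""

    def __init__(self, spec, data: pd.DataFrame, check_rank: bool = False):
        self.spec = spec
        df = data.reset_index(drop=True)
        cols = [spec.response, *spec.covariates]
        if spec.family == "negbin":
            cols += list(spec.offset_cols)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"data is missing columns: {missing}")
        if df[cols].isna().any().any():
            raise ValueError("model rows contain missing values")

        self.y = df[spec.response].to_numpy(dtype=float)
        self.X = np.column_stack(
            [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in spec.covariates]
        )
        if check_rank and np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")

        if spec.family == "negbin":
            if (self.y < 0).any() or not np.allclose(self.y, np.round(self.y)):
                raise ValueError("counts must be non-negative integers")
            off = np.zeros(len(df))
            for c in spec.offset_cols:
                vals = df[c].to_numpy(dtype=float)
                if (vals <= 0).any():
                    raise ValueError(f"offset column {c} must be strictly positive")
                off += np.log(vals)
            self.offset = off
            re_col = spec.year_col
        else:
            self.offset = None
            re_col = spec.group_col

        if re_col is not None and re_col in df.columns:
            levels, idx = np.unique(df[re_col].to_numpy(), return_inverse=True)
            self.re_levels = [str(l) for l in levels]
            self.re_idx = idx
        else:
            self.re_levels = []
            self.re_idx = None
        if self.re_levels and len(self.re_levels) < 2:
            raise ValueError("random effect needs >= 2 levels to identify its SD")

        # parameterization of the random effects: centered when each level
        # carries enough data to pin its effect down, non-centered (u_raw ~
        # N(0,1), effect = sigma * u_raw) when levels are weakly identified
        # and the centered joint density would be badly funnel-shaped
        if getattr(spec, "noncentered", None) is None:
            self.noncentered = bool(self.re_levels) and (
                len(df) / max(len(self.re_levels), 1) < 50
            )
        else:
            self.noncentered = bool(spec.noncentered)

        self.G = len(self.re_levels)
        # the normal model admits exact marginalization of the random
        # intercepts (per-group covariance sigma^2 I + sigma_g^2 J), so the
        # sampler only has to explore the fixed effects and the two scale
        # parameters; effects are re-drawn from their exact conditionals
        self.marginalize = spec.family == "normal" and self.G > 0
        if self.G:
            A = np.zeros((self.G, len(df)))
            A[self.re_idx, np.arange(len(df))] = 1.0
            self._A = A
            self._n_per_group = A.sum(axis=1)

        fe_prefix = "delta" if spec.family == "negbin" else "beta"
        self.names = [f"{fe_prefix}_intercept"] + [f"{fe_prefix}_{c}" for c in spec.covariates]
        self.k = len(self.names)
        self.G = len(self.re_levels)
        re_prefix = "v" if spec.family == "negbin" else "u"
        self.names += [f"{re_prefix}[{l}]" for l in self.re_levels]
        if spec.family == "negbin":
            self.names += ["log_sigma_year", "log_theta"]
        else:
            if self.G:
                self.names.append("log_sigma_group")
            if spec.known_sigma is None:
                self.names.append("log_sigma")
        self.ndim = len(self.names)

    # -- vectorized log posterior; params has shape (W, ndim) --------------
    def log_posterior(self, params: np.ndarray, prior_only: bool = False) -> np.ndarray:
        """Joint log density in the sampling parameterization.

        In the non-centered parameterization random effects enter as
        standardized values u_raw ~ N(0, 1) with the actual effect
        sigma_re * u_raw in the linear predictor, which keeps the joint
        density bounded and near-Gaussian when levels carry little data;
        in the centered one they are the effects themselves with a
        N(0, sigma_re^2) prior.
        """
        params = np.atleast_2d(np.asarray(params, dtype=float))
        spec = self.spec
        fe = params[:, : self.k]                              # (W, k)
        pos = self.k
        re = params[:, pos : pos + self.G]                    # (W, G)
        pos += self.G

        lp = -0.5 * (fe / spec.prior_sd) ** 2 - np.log(spec.prior_sd) - _HALF_LOG_2PI
        lp = lp.sum(axis=1)

        def half_normal_on_log(log_s):
            # half-Normal(scale) prior on s, sampled as log s (Jacobian +log s)
            s = np.exp(log_s)
            return (
                np.log(2.0)
                - _HALF_LOG_2PI
                - np.log(spec.sd_prior_scale)
                - 0.5 * (s / spec.sd_prior_scale) ** 2
                + log_s
            )

        if spec.family == "negbin":
            log_sigma_re = params[:, pos]
            log_theta = params[:, pos + 1]
            lp += half_normal_on_log(log_sigma_re)
            # Exponential(1) on 1/theta, sampled as log theta
            lp += -np.exp(-log_theta) - log_theta
            sigma_re = np.exp(log_sigma_re)
            theta = np.exp(log_theta)
        else:
            sigma_re = None
            if self.G:
                log_sigma_re = params[:, pos]
                lp += half_normal_on_log(log_sigma_re)
                sigma_re = np.exp(log_sigma_re)
                pos += 1
            if spec.known_sigma is None:
                log_sigma = params[:, pos]
                lp += half_normal_on_log(log_sigma)
                sigma = np.exp(log_sigma)
            else:
                sigma = np.full(params.shape[0], float(spec.known_sigma))

        if self.G:
            if self.noncentered:
                lp += (-0.5 * re**2 - _HALF_LOG_2PI).sum(axis=1)
            else:
                lp += (
                    -0.5 * (re / sigma_re[:, None]) ** 2
                    - np.log(sigma_re)[:, None]
                    - _HALF_LOG_2PI
                ).sum(axis=1)

        if prior_only:
            return lp

        eta = self.X @ fe.T                                   # (n, W)
        if self.G:
            effects = sigma_re[:, None] * re if self.noncentered else re
            eta = eta + effects.T[self.re_idx]
        if spec.family == "negbin":
            mu = np.exp(eta + self.offset[:, None])
            th = theta[None, :]
            y = self.y[:, None]
            ll = (
                gammaln(y + th)
                - gammaln(th)
                - gammaln(y + 1.0)
                + th * np.log(th / (th + mu))
                + y * np.log(mu / (th + mu))
            ).sum(axis=0)
        else:
            resid = self.y[:, None] - eta
            ll = (
                -0.5 * (resid / sigma[None, :]) ** 2
                - np.log(sigma)[None, :]
                - _HALF_LOG_2PI
            ).sum(axis=0)
        out = lp + ll
        out[~np.isfinite(out)] = -np.inf
        return out

    # -- marginal posterior for the normal model ---------------------------
    # layout: [fixed effects, log_sigma_group, log_sigma (unless known)]
    @property
    def ndim_marginal(self) -> int:
        return self.k + 1 + (0 if self.spec.known_sigma is not None else 1)

    def log_marginal_posterior(self, params: np.ndarray) -> np.ndarray:
        """Log posterior with the group intercepts integrated out.

        Per group the marginal covariance is sigma^2 I + sigma_g^2 J; the
        Woodbury identity reduces both the determinant and the quadratic
        form to the per-group residual sums, so the evaluation stays O(n)
        per walker.
        """
        spec = self.spec
        params = np.atleast_2d(np.asarray(params, dtype=float))
        fe = params[:, : self.k]
        log_sigma_g = params[:, self.k]
        if spec.known_sigma is None:
            log_sigma = params[:, self.k + 1]
            sigma = np.exp(log_sigma)
        else:
            sigma = np.full(params.shape[0], float(spec.known_sigma))

        lp = (-0.5 * (fe / spec.prior_sd) ** 2 - np.log(spec.prior_sd) - _HALF_LOG_2PI).sum(
            axis=1
        )
        s = np.exp(log_sigma_g)
        lp += (
            np.log(2.0)
            - _HALF_LOG_2PI
            - np.log(spec.sd_prior_scale)
            - 0.5 * (s / spec.sd_prior_scale) ** 2
            + log_sigma_g
        )
        if spec.known_sigma is None:
            sv = sigma
            lp += (
                np.log(2.0)
                - _HALF_LOG_2PI
                - np.log(spec.sd_prior_scale)
                - 0.5 * (sv / spec.sd_prior_scale) ** 2
                + log_sigma
            )

        r = self.y[:, None] - self.X @ fe.T                   # (n, W)
        s1 = self._A @ r                                      # (G, W): group sums
        s2 = self._A @ r**2                                   # (G, W): group sq sums
        n_g = self._n_per_group[:, None]
        sig2 = sigma[None, :] ** 2
        tau2 = s[None, :] ** 2
        denom = sig2 + n_g * tau2
        quad = (s2 - tau2 * s1**2 / denom) / sig2
        logdet = n_g * np.log(sig2) + np.log1p(n_g * tau2 / sig2)
        ll = -0.5 * (quad + logdet + n_g * 2.0 * _HALF_LOG_2PI).sum(axis=0)
        out = lp + ll
        out[~np.isfinite(out)] = -np.inf
        return out

    def conditional_random_effects(
        self, fe: np.ndarray, sigma_g: np.ndarray, sigma: np.ndarray,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Exact draws of u_g | fixed effects, scales, data — one per row of fe."""
        r = self.y[:, None] - self.X @ fe.T                   # (n, D)
        s1 = self._A @ r                                      # (G, D)
        n_g = self._n_per_group[:, None]
        prec = n_g / sigma[None, :] ** 2 + 1.0 / sigma_g[None, :] ** 2
        mean = (s1 / sigma[None, :] ** 2) / prec
        sd = 1.0 / np.sqrt(prec)
        return (mean + sd * rng.standard_normal(mean.shape)).T  # (D, G)


def log_posterior(model_spec, params, data: pd.DataFrame, prior_only: bool = False) -> float:
    """Log posterior density (likelihood + priors) at one parameter vector.

    The parameter order is the ``names`` layout of the fitted design:
    fixed effects, random-effect values, then log-scale SDs / dispersion.
    Random effects are given in the sampling parameterization the design
    resolves (``spec.noncentered``, or data-driven when that is None).
    Returns -inf outside the support.
    """
    design = _Design(model_spec, data)
    params = np.asarray(params, dtype=float)
    if params.shape != (design.ndim,):
        raise ValueError(f"expected {design.ndim} parameters {design.names}, got {params.shape}")
    return float(design.log_posterior(params[None, :], prior_only=prior_only)[0])


def parameter_names(model_spec, data: pd.DataFrame) -> list[str]:
    """Parameter layout used by :func:`log_posterior` and :func:`fit`."""
    return list(_Design(model_spec, data).names)


# ---------------------------------------------------------------------------
# fitting


def _map_estimate(logpost, x0: np.ndarray, rng: np.random.Generator,
                  bounds=None) -> np.ndarray:
    """Posterior mode of a vectorized log density by L-BFGS with restarts.

    ``bounds`` (scipy style) keep the optimizer away from the degenerate
    density spike of hierarchical models at sigma_re -> 0: the spike has
    vanishing mass, so an interior (or bound-constrained) point is the
    right centre for the sampler's proposal even when the unconstrained
    mode diverges.
    """

    def neg(p):
        v = logpost(p[None, :])[0]
        return -v if np.isfinite(v) else 1e12

    best = None
    for attempt in range(3):
        start = x0 + (0.0 if attempt == 0 else rng.normal(0, 0.1, len(x0)))
        res = optimize.minimize(neg, start, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 1000})
        if best is None or res.fun < best.fun:
            best = res
        if np.isfinite(res.fun) and res.fun < 1e11:
            break
    return best.x


def _laplace(logpost, center: np.ndarray):
    """Gaussian (Laplace) approximation at the posterior mode.

    The Hessian of the negative log posterior is computed by central finite
    differences, evaluated in vectorized batches; its inverse seeds the
    walker initialisation so ensemble moves start with posterior-shaped
    spread.  Falls back to a diagonal covariance if the Hessian is not
    positive definite (e.g. flat directions at a boundary mode).
    """
    d = len(center)
    h = 1e-4 * np.maximum(1.0, np.abs(center))
    E = np.diag(h)
    pts = [center[None, :]]
    for i in range(d):
        pts.append(center[None, :] + E[i])
        pts.append(center[None, :] - E[i])
    for i in range(d):
        for j in range(i + 1, d):
            pts.append(center[None, :] + E[i] + E[j])
            pts.append(center[None, :] - E[i] - E[j])
    vals = logpost(np.vstack(pts))
    f0 = vals[0]
    fp = vals[1 : 2 * d + 1 : 2]
    fm = vals[2 : 2 * d + 1 : 2]
    H = np.empty((d, d))
    for i in range(d):
        H[i, i] = -(fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    pos = 2 * d + 1
    for i in range(d):
        for j in range(i + 1, d):
            fpp, fmm = vals[pos], vals[pos + 1]
            pos += 2
            mixed = -(fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm) / (2 * h[i] * h[j])
            H[i, j] = H[j, i] = mixed
    try:
        # smallest eigenvalue guard before Cholesky
        w = np.linalg.eigvalsh(H)
        if w.min() <= 0 or not np.isfinite(H).all():
            raise np.linalg.LinAlgError
        cov = np.linalg.inv(H)
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        diag = np.clip(np.diag(H), 1e-6, None)
        cov = np.diag(1.0 / diag)
    return cov


class _LaplaceIndependenceMove(emcee.moves.MHMove):
    """Independence Metropolis-Hastings proposal from a heavy-tailed Laplace fit.

    Proposes multivariate-t draws centred on the posterior mode with the
    Laplace covariance (inflated, df small enough for heavy tails) —
    independent of the current state, so for the near-Gaussian GLMM
    posteriors the chain decorrelates in O(1/acceptance) steps and walkers
    are genuinely independent MH chains.
    """

    def __init__(self, center: np.ndarray, chol: np.ndarray, df: float = 8.0,
                 inflate: float = 1.3):
        self.center = center
        self.chol = chol * inflate
        self.df = float(df)
        self.ndim_ = len(center)
        super().__init__(self.get_proposal)

    def _log_q(self, x: np.ndarray) -> np.ndarray:
        from scipy.linalg import solve_triangular

        r = solve_triangular(self.chol, (x - self.center).T, lower=True)
        q2 = (r**2).sum(axis=0)
        return -0.5 * (self.df + self.ndim_) * np.log1p(q2 / self.df)

    def get_proposal(self, coords, random):
        nw, nd = coords.shape
        z = random.standard_normal((nw, nd))
        g = random.chisquare(self.df, nw) / self.df
        prop = self.center[None, :] + (z / np.sqrt(g)[:, None]) @ self.chol.T
        # Hastings factor log q(x | x') - log q(x' | x) = log q(x) - log q(x')
        factors = self._log_q(coords) - self._log_q(prop)
        return prop, factors


class _HierarchicalRescaleMove(emcee.moves.MHMove):
    """Joint funnel move: rescale the random effects with their SD.

    Proposes log sigma' = log sigma + eps and u' = u * e^eps, which walks
    along the ridge u ~ sigma of a hierarchical posterior; the Gaussian
    prior term is invariant under the map, so acceptance is governed only
    by the likelihood and hyperprior.  The volume change contributes the
    log-Jacobian G * eps to the Hastings factor.
    """

    def __init__(self, re_start: int, re_stop: int, sigma_idx: int, scale: float = 0.5):
        self.re_start = re_start
        self.re_stop = re_stop
        self.sigma_idx = sigma_idx
        self.scale = scale
        super().__init__(self.get_proposal)

    def get_proposal(self, coords, random):
        eps = self.scale * random.standard_normal(coords.shape[0])
        prop = coords.copy()
        prop[:, self.sigma_idx] += eps
        prop[:, self.re_start : self.re_stop] *= np.exp(eps)[:, None]
        factors = (self.re_stop - self.re_start) * eps
        return prop, factors


class _InterceptShiftMove(emcee.moves.MHMove):
    """Volume-preserving trade-off move between intercept and random effects.

    Proposes beta0' = beta0 + eps, u' = u - eps: the linear predictor is
    unchanged, so acceptance depends only on the priors.  This directly
    mixes the soft likelihood-flat direction that otherwise dominates the
    autocorrelation time of hierarchical intercept models.
    """

    def __init__(self, re_start: int, re_stop: int, scale: float = 0.3):
        self.re_start = re_start
        self.re_stop = re_stop
        self.scale = scale
        super().__init__(self.get_proposal)

    def get_proposal(self, coords, random):
        eps = self.scale * random.standard_normal(coords.shape[0])
        prop = coords.copy()
        prop[:, 0] += eps
        prop[:, self.re_start : self.re_stop] -= eps[:, None]
        return prop, np.zeros(coords.shape[0])


def fit(
    model_spec,
    data: pd.DataFrame,
    chains: int = 4,
    iterations: int = 6000,
    warmup: int = 3000,
    seed: int = 0,
    nwalkers: int | None = None,
    cri_level: float = 0.80,
    prior_only: bool = False,
    progress: bool = False,
) -> PosteriorDraws:
    """Sample the posterior of a growth or abundance GLMM.

    Runs ``chains`` independent walker ensembles for ``iterations`` steps
    each (the first ``warmup`` discarded); each ensemble contributes
    ``iterations - warmup`` posterior draws assembled from its post-warmup
    walkers.  Per-parameter posterior means, equal-tailed credible
    intervals (80% by default), R-hat across the independent ensembles and
    bulk effective sample sizes are attached to the result.  If any R-hat
    is >= 1.01 the result carries ``converged=False`` and a warning is
    emitted — never a silent failure.
    """
    if iterations <= warmup:
        raise ValueError("iterations must exceed warmup")
    design = _Design(model_spec, data, check_rank=True)
    ndim = design.ndim
    ndraws = iterations - warmup

    master = np.random.SeedSequence(seed)
    map_seq, recon_seq, *chain_seqs = master.spawn(chains + 2)
    map_rng = np.random.default_rng(map_seq)

    marginal = design.marginalize and not prior_only
    if marginal:
        logpost = design.log_marginal_posterior
        ndim_s = design.ndim_marginal
        x0 = np.zeros(ndim_s)
        x0[design.k :] = np.log(0.5)
        n_scales = ndim_s - design.k
    else:
        logpost = lambda p: design.log_posterior(p, prior_only=prior_only)  # noqa: E731
        ndim_s = ndim
        x0 = np.zeros(ndim_s)
        x0[design.k + design.G :] = np.log(0.5)
        n_scales = ndim_s - design.k - design.G
    if nwalkers is None:
        nwalkers = max(2 * ndim_s + 2, 32)
        nwalkers += nwalkers % 2

    # log-scale parameters are bounded during optimisation so the centre
    # never lands in the zero-variance density spike of the hierarchy
    bounds = [(None, None)] * (ndim_s - n_scales) + [(np.log(0.05), np.log(20.0))] * n_scales
    center = (
        np.zeros(ndim_s) if prior_only else _map_estimate(logpost, x0, map_rng, bounds)
    )
    cov = _laplace(logpost, center)
    # floor on the log-scale coordinates' proposal spread: a Hessian pinched
    # against an optimisation bound must not give a degenerate proposal
    if n_scales:
        d = np.diag(cov).copy()
        bump = np.zeros(ndim_s)
        bump[ndim_s - n_scales :] = np.maximum(0.15**2 - d[ndim_s - n_scales :], 0.0)
        if bump.any():
            cov = cov + np.diag(bump)
    chol = np.linalg.cholesky(cov)

    # independence proposals from the Laplace fit do the heavy lifting;
    # an occasional covariance-scaled random walk handles any locally
    # non-Gaussian pocket the independence proposal covers poorly
    rw_cov = cov * (2.38**2 / ndim_s)
    moves = [
        (_LaplaceIndependenceMove(center, chol), 0.8),
        (emcee.moves.GaussianMove(rw_cov), 0.2),
    ]
    if not marginal and not prior_only and design.G and not design.noncentered:
        # centered hierarchies mix slowly along two soft directions: the
        # (sigma_re, effects) funnel and the likelihood-flat intercept vs
        # mean-effect trade-off; dedicated joint moves walk both directly
        moves = [
            (_LaplaceIndependenceMove(center, chol), 0.55),
            (emcee.moves.GaussianMove(rw_cov), 0.15),
            (_HierarchicalRescaleMove(design.k, design.k + design.G, design.k + design.G), 0.15),
            (
                _InterceptShiftMove(
                    design.k,
                    design.k + design.G,
                    # shifts beyond ~sigma_re are prior-rejected, so match
                    # the proposal scale to the fitted random-effect SD
                    scale=float(np.clip(1.5 * np.exp(center[design.k + design.G]), 0.05, 1.0)),
                ),
                0.15,
            ),
        ]
    chain_draws = []
    for child in chain_seqs:
        rng = np.random.default_rng(child)
        # posterior-shaped initial cloud so difference-vector proposals are
        # well-scaled from the first step
        p0 = center[None, :] + rng.standard_normal((nwalkers, ndim_s)) @ chol.T
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim_s, logpost, vectorize=True, moves=moves
        )
        sampler._random = np.random.RandomState(int(rng.integers(2**31 - 1)))
        sampler.run_mcmc(p0, iterations, progress=progress)
        post = sampler.get_chain(discard=warmup)            # (steps, walkers, ndim)
        # assemble this ensemble's chain by thinning the step-major flattened
        # post-warmup draws across the whole window; a stride that is not a
        # multiple of the walker count makes consecutive thinned draws come
        # from different walkers, while the step-major ordering keeps
        # split-R-hat comparing early vs late sampling
        flat_sm = post.reshape(-1, ndim_s)
        total = len(flat_sm)
        stride = max(total // ndraws, 1)
        if stride >= nwalkers and stride % nwalkers == 0:
            stride -= 1
        idx = total - 1 - stride * np.arange(ndraws - 1, -1, -1)
        chain_draws.append(flat_sm[idx])
    draws = np.stack(chain_draws)                           # (chains, ndraws, ndim_s)

    if marginal:
        # reconstruct the group intercepts from their exact conditionals,
        # producing draws in the full reported layout
        recon_rng = np.random.default_rng(recon_seq)
        full = np.empty((chains, ndraws, ndim))
        for c in range(chains):
            fe = draws[c, :, : design.k]
            sigma_g = np.exp(draws[c, :, design.k])
            if model_spec.known_sigma is None:
                sigma = np.exp(draws[c, :, design.k + 1])
            else:
                sigma = np.full(ndraws, float(model_spec.known_sigma))
            u = design.conditional_random_effects(fe, sigma_g, sigma, recon_rng)
            full[c, :, : design.k] = fe
            full[c, :, design.k : design.k + design.G] = u
            full[c, :, design.k + design.G] = draws[c, :, design.k]
            if model_spec.known_sigma is None:
                full[c, :, design.k + design.G + 1] = draws[c, :, design.k + 1]
        draws = full
    elif design.G and design.noncentered:
        # map the non-centered (standardized) random effects back to the
        # reported scale: u = sigma_re * u_raw; log_sigma_re sits right
        # after the random-effect block in the layout
        sig = np.exp(draws[..., design.k + design.G])
        draws[..., design.k : design.k + design.G] *= sig[..., None]

    if chains >= 2:
        ds = az.convert_to_dataset(draws)
        rhat = np.asarray(az.rhat(ds)["x"])
        ess = np.asarray(az.ess(ds, method="bulk")["x"])
    else:
        rhat = np.full(ndim, np.nan)
        ess = np.full(ndim, np.nan)

    flat = draws.reshape(-1, ndim)
    alpha = (1.0 - cri_level) / 2.0
    lo = np.quantile(flat, alpha, axis=0)
    hi = np.quantile(flat, 1.0 - alpha, axis=0)
    converged = bool(np.all(rhat < RHAT_LIMIT)) if chains >= 2 else True
    if not converged:
        bad = [design.names[i] for i in np.flatnonzero(rhat >= RHAT_LIMIT)]
        warnings.warn(
            f"MCMC convergence not reached (R-hat >= {RHAT_LIMIT}) for: {bad}",
            stacklevel=2,
        )
    names = design.names
    return PosteriorDraws(
        names=names,
        draws=draws,
        mean=pd.Series(flat.mean(axis=0), index=names),
        cri_lower=pd.Series(lo, index=names),
        cri_upper=pd.Series(hi, index=names),
        cri_level=cri_level,
        rhat=pd.Series(rhat, index=names),
        ess_bulk=pd.Series(ess, index=names),
        converged=converged,
        seed=seed,
        settings={
            "chains": chains,
            "iterations": iterations,
            "warmup": warmup,
            "nwalkers": nwalkers,
            "sampler": "emcee affine-invariant ensemble",
            "prior_only": prior_only,
        },
    )


def credible_interval(draws, level: float = 0.80):
    """Equal-tailed credible interval(s) and excludes-zero flag(s).

    ``draws`` is a 1-d sample for one parameter or a (n, p) array; returns
    ``(lower, upper, excludes_zero)`` with matching shapes.  ``level=1.0``
    returns the sample range.
    """
    a = np.asarray(draws, dtype=float)
    n = a.shape[0]
    if n < 100:
        raise ValueError("need at least 100 draws for a credible interval")
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(a, alpha, axis=0)
    hi = np.quantile(a, 1.0 - alpha, axis=0)
    excludes = (lo > 0) | (hi < 0)
    return lo, hi, excludes


def posterior_predictive_check(
    model_spec,
    posterior: PosteriorDraws,
    data: pd.DataFrame,
    stats: tuple[str, ...] | None = None,
    n_rep: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare observed summary statistics to replicated datasets.

    For ``n_rep`` thinned posterior draws, a replicate response vector is
    simulated from the model at those parameter values (including the
    drawn random-effect values), the statistics are computed, and the
    observed statistic's quantile position within the replicate
    distribution is reported.  Positions near 0 or 1 signal misfit.
    """
    design = _Design(model_spec, data)
    if stats is None:
        stats = ("mean", "sd", "prop_zero") if model_spec.family == "negbin" else ("mean", "sd")
    rng = np.random.default_rng(seed)
    flat = posterior.flat
    idx = np.linspace(0, len(flat) - 1, num=min(n_rep, len(flat)), dtype=int)

    def compute(y):
        out = {}
        for s in stats:
            if s == "mean":
                out[s] = float(np.mean(y))
            elif s == "sd":
                out[s] = float(np.std(y, ddof=1))
            elif s == "prop_zero":
                out[s] = float(np.mean(y == 0))
            else:
                raise ValueError(f"unknown statistic {s!r}")
        return out

    reps = {s: [] for s in stats}
    for p in flat[idx]:
        fe = p[: design.k]
        re = p[design.k : design.k + design.G]
        eta = design.X @ fe
        if design.G:
            eta = eta + re[design.re_idx]
        if model_spec.family == "negbin":
            theta = np.exp(p[-1])
            mu = np.exp(eta + design.offset)
            y_rep = rng.negative_binomial(theta, theta / (theta + mu))
        else:
            # log_sigma is the last entry of the layout when not fixed
            sigma = (
                float(model_spec.known_sigma)
                if model_spec.known_sigma is not None
                else np.exp(p[-1])
            )
            y_rep = rng.normal(eta, sigma)
        for s, v in compute(y_rep).items():
            reps[s].append(v)

    observed = compute(design.y)
    rows = []
    for s in stats:
        rep = np.asarray(reps[s])
        rows.append(
            {
                "statistic": s,
                "observed": observed[s],
                "rep_mean": float(rep.mean()),
                "rep_lower_2.5": float(np.quantile(rep, 0.025)),
                "rep_upper_97.5": float(np.quantile(rep, 0.975)),
                "observed_quantile": float(np.mean(rep < observed[s]) + 0.5 * np.mean(rep == observed[s])),
            }
        )
    return pd.DataFrame(rows)
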