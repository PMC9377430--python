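"""Poisson-lognormal disease mapping with convolution (BYM-type) random effects.

The model for areal counts O_i with offsets E_i (expected counts from
indirect standardization) and region covariates X_1..X_p is

    O_i ~ Poisson(E_i * r_i)
    log r_i = beta0 + sum_k beta_k X_ki + u_i + s_i

with an exchangeable effect u_i ~ N(0, 1/tau_u) absorbing overdispersion
and an intrinsic-CAR (ICAR) effect s_i absorbing spatially structured
residual risk.  The ICAR prior penalizes squared differences between
contiguity neighbors,

    p(s | tau_s) ∝ tau_s^((n-c)/2) * exp(-(tau_s/2) * sum_{i~j} (s_i - s_j)^2)

(c = number of graph components), identified by a sum-to-zero constraint;
the intercept carries the level.  Priors: beta ~ N(0, sd^2) with a wide
default sd, and Gamma hyperpriors on the precisions tau_u, tau_s.

Inference is Metropolis-within-Gibbs: adaptive random-walk updates for the
betas, vectorized single-site updates for u, graph-colored single-site
updates for s (sites of one color are conditionally independent), and
conjugate Gamma draws for the precisions.  Two posterior functionals
summarize the random effects: the spatial fraction

    psi = SD(s) / (SD(s) + SD(u))        per retained draw,

which tends to 1 when residual risk variation is predominantly spatial,
and the per-region relative risk r_i = exp(beta0 + x_i'beta + u_i + s_i).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .geography import Geography

logger = logging.getLogger(__name__)

__all__ = [
    "BYMPoissonModel", "PosteriorSamples", "PosteriorSummary",
    "icar_quadratic", "log_unnormalized_posterior", "fit_bym",
    "compute_psi", "relative_risk", "summarize", "geweke_z",
]


class SamplerError(RuntimeError):
    """Raised when the chain reaches a non-finite posterior state."""


# ---------------------------------------------------------------------------
# adjacency helpers

def _edge_array(adjacency) -> np.ndarray:
    """Normalize an adjacency argument to an (n_edges, 2) array with i < j.

    Accepts a :class:`Geography`, a numpy (m, 2) edge array, or a
    per-region sequence of neighbor index sequences (Python lists/tuples).
    The numpy-vs-list distinction is deliberate: a 2-regular graph's
    neighbor lists and an edge list are both (n, 2)-shaped.
    """
    if isinstance(adjacency, Geography):
        return adjacency.edges
    if isinstance(adjacency, np.ndarray):
        e = adjacency.astype(np.intp).reshape(-1, 2)
        lo = np.minimum(e[:, 0], e[:, 1])
        hi = np.maximum(e[:, 0], e[:, 1])
        keep = lo != hi
        return np.unique(np.column_stack([lo[keep], hi[keep]]), axis=0)
    edges = [(i, j) for i, nbrs in enumerate(adjacency) for j in nbrs if i < j]
    return np.asarray(edges, dtype=np.intp).reshape(-1, 2)


def icar_quadratic(s, adjacency) -> float:
    """ICAR penalty: sum over unordered neighbor pairs of (s_i - s_j)^2."""
    s = np.asarray(s, dtype=float)
    e = _edge_array(adjacency)
    if len(e) == 0:
        return 0.0
    d = s[e[:, 0]] - s[e[:, 1]]
    return float(d @ d)


def _graph_coloring(n: int, edges: np.ndarray) -> list[np.ndarray]:
    """Greedy proper coloring; returns site-index arrays, one per color."""
    nbrs = [[] for _ in range(n)]
    for i, j in edges:
        nbrs[i].append(j)
        nbrs[j].append(i)
    color = np.full(n, -1)
    for i in range(n):
        used = {color[j] for j in nbrs[i] if color[j] >= 0}
        c = 0
        while c in used:
            c += 1
        color[i] = c
    return [np.flatnonzero(color == c) for c in range(color.max() + 1)]


# ---------------------------------------------------------------------------
# posterior density

def log_unnormalized_posterior(beta, u, s, tau_u, tau_s, *,
                               y, expected, X, adjacency,
                               beta_prior_sd: float = 100.0,
                               tau_shape: float = 0.5,
                               tau_rate: float = 0.0005) -> float:
    """Log unnormalized posterior of the full parameter state.

    ``X`` is the raw covariate matrix (n, p) without intercept; ``beta``
    is length p+1 with the intercept first.  The Poisson term drops the
    log(y!) constant; all prior terms keep their normalizing constants
    (the ICAR normalizer uses rank n - c).
    """
    beta = np.asarray(beta, dtype=float)
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    y = np.asarray(y, dtype=float)
    E = np.asarray(expected, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates contain non-finite values")
    n = y.size
    edges = _edge_array(adjacency)
    log_mu = np.log(E) + beta[0] + X @ beta[1:] + u + s
    ll = float(y @ log_mu - np.exp(log_mu).sum())

    lp = -0.5 * np.sum(beta**2) / beta_prior_sd**2 \
        - beta.size * (0.5 * np.log(2 * np.pi) + np.log(beta_prior_sd))
    lp += 0.5 * n * (np.log(tau_u) - np.log(2 * np.pi)) - 0.5 * tau_u * (u @ u)
    rank = n - _n_components(n, edges)
    lp += 0.5 * rank * (np.log(tau_s) - np.log(2 * np.pi)) \
        - 0.5 * tau_s * icar_quadratic(s, edges)
    for tau in (tau_u, tau_s):
        lp += (tau_shape * np.log(tau_rate) - gammaln(tau_shape)
               + (tau_shape - 1) * np.log(tau) - tau_rate * tau)
    return ll + lp


def _n_components(n: int, edges: np.ndarray) -> int:
    if len(edges) == 0:
        return n
    A = sp.coo_matrix((np.ones(len(edges)), (edges[:, 0], edges[:, 1])),
                      shape=(n, n))
    return int(connected_components(A, directed=False)[0])


# ---------------------------------------------------------------------------
# containers

@dataclass
class PosteriorSamples:
    """Retained MCMC draws.

    ``beta`` has shape (m, p+1) with the intercept in column 0; ``u`` and
    ``s`` have shape (m, n); precisions are length-m vectors.  Every
    retained ``s`` draw sums to zero (ICAR identifiability).
    """

    beta: np.ndarray
    u: np.ndarray
    s: np.ndarray
    tau_u: np.ndarray
    tau_s: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def n_regions(self) -> int:
        return self.u.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Flat draw-by-parameter table (for CSV persistence)."""
        p = self.beta.shape[1]
        cols = {f"beta{k}": self.beta[:, k] for k in range(p)}
        cols.update({f"u{i}": self.u[:, i] for i in range(self.n_regions)})
        cols.update({f"s{i}": self.s[:, i] for i in range(self.n_regions)})
        cols["tau_u"] = self.tau_u
        cols["tau_s"] = self.tau_s
        return pd.DataFrame(cols)


@dataclass
class PosteriorSummary:
    """Table-style posterior summary: coefficients, spatial fraction, risks."""

    coefficients: pd.DataFrame      # mean, q2.5, q97.5, significant per beta
    psi: tuple                      # (mean, lo, hi)
    relative_risk: pd.DataFrame     # per region: mean, q2.5, q97.5
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# posterior functionals

def compute_psi(samples: PosteriorSamples):
    """Spatial fraction psi = SD(s)/(SD(s)+SD(u)) per draw, summarized.

    SDs are the empirical (ddof=1) standard deviations of the s and u
    vectors within each draw.  Draws where both SDs are zero have no
    defined psi and are dropped with a log message.

    Returns ``(mean, lo, hi)`` with an equal-tailed 95% interval.
    """
    if samples.n_draws < 1:
        raise ValueError("need at least one retained draw")
    sd_s = samples.s.std(axis=1, ddof=1)
    sd_u = samples.u.std(axis=1, ddof=1)
    ok = (sd_s + sd_u) > 0
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("psi undefined (both SDs zero) in %d draw(s); excluded", n_bad)
    if not ok.any():
        raise ValueError("psi undefined in every draw")
    psi = sd_s[ok] / (sd_s[ok] + sd_u[ok])
    lo, hi = np.quantile(psi, [0.025, 0.975])
    return float(psi.mean()), float(lo), float(hi)


def relative_risk(samples: PosteriorSamples, X) -> pd.DataFrame:
    """Per-region relative risk r_i = exp(beta0 + x_i'beta + u_i + s_i).

    ``X`` is the covariate matrix on the scale the model was fitted on.
    Returns a DataFrame with posterior mean and equal-tailed 95% bounds.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != samples.n_regions:
        raise ValueError(
            f"covariates have {X.shape[0]} rows for {samples.n_regions} regions"
        )
    if X.shape[1] != samples.beta.shape[1] - 1:
        raise ValueError("covariate count does not match sampled coefficients")
    eta = samples.beta[:, :1] + samples.beta[:, 1:] @ X.T + samples.u + samples.s
    r = np.exp(eta)
    lo, hi = np.quantile(r, [0.025, 0.975], axis=0)
    return pd.DataFrame({"rr_mean": r.mean(axis=0), "rr_q025": lo, "rr_q975": hi},
                        index=pd.RangeIndex(samples.n_regions, name="region"))


def summarize(samples: PosteriorSamples, X) -> PosteriorSummary:
    """Posterior means, equal-tailed 95% intervals and significance flags.

    A coefficient is flagged significant when its 95% interval strictly
    excludes zero (an endpoint exactly at zero is not significant).
    Includes the psi summary and per-region relative risks.
    """
    if samples.n_draws < 100:
        logger.warning("only %d retained draws; summaries will be noisy",
                       samples.n_draws)
    lo, hi = np.quantile(samples.beta, [0.025, 0.975], axis=0)
    coef = pd.DataFrame({
        "mean": samples.beta.mean(axis=0),
        "q025": lo,
        "q975": hi,
    }, index=[f"beta{k}" for k in range(samples.beta.shape[1])])
    coef["significant"] = (coef["q025"] > 0) | (coef["q975"] < 0)
    return PosteriorSummary(
        coefficients=coef,
        psi=compute_psi(samples),
        relative_risk=relative_risk(samples, X),
        meta=dict(samples.meta),
    )


def geweke_z(chain, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence score: standardized difference between the mean of
    the first 10% and last 50% of a chain, with autocorrelation-adjusted
    standard errors (effective sample size via arviz)."""
    import arviz as az

    chain = np.asarray(chain, dtype=float)
    a = chain[: max(2, int(first * len(chain)))]
    b = chain[int((1 - last) * len(chain)):]
    var = 0.0
    for seg in (a, b):
        ess = float(az.ess(seg))
        if not np.isfinite(ess):
            ess = float(len(seg))
        var += seg.var(ddof=1) / max(ess, 2.0)
    if var == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(var))


# ---------------------------------------------------------------------------
# the estimator

class BYMPoissonModel(BaseEstimator):
    """Bayesian Poisson-lognormal areal model with BYM convolution effects.

    Scikit-learn-style estimator: configure in ``__init__``, call
    :meth:`fit` with the covariate matrix, observed counts, expected
    counts and the adjacency structure; fitted state lands in
    ``samples_`` (retained draws), ``summary_`` (coefficient table, psi,
    relative risks) and friends.

    Parameters
    ----------
    n_iterations, n_burnin, thin : int
        Chain length, discarded prefix, thinning stride.
    beta_prior_sd : float
        SD of the independent normal priors on the intercept and slopes.
    tau_shape, tau_rate : float
        Gamma hyperprior on both random-effect precisions (the classic
        diffuse Gamma(0.5, 0.0005) by default).
    target_accept : float
        Target acceptance rate for the elementwise random-walk updates.
    adapt_interval : int
        Step sizes adapt every this many iterations during burn-in only.
    standardize : bool
        Z-score the covariates before fitting; coefficients are then on
        the standardized scale (recorded in ``summary_.meta``).
    random_state : int or None
        Seed; identical seeds give bit-identical chains.
    """

    def __init__(self, n_iterations: int = 15000, n_burnin: int = 5000,
                 thin: int = 1, beta_prior_sd: float = 100.0,
                 tau_shape: float = 0.5, tau_rate: float = 0.0005,
                 target_accept: float = 0.44, adapt_interval: int = 50,
                 standardize: bool = False, random_state=None):
        self.n_iterations = n_iterations
        self.n_burnin = n_burnin
        self.thin = thin
        self.beta_prior_sd = beta_prior_sd
        self.tau_shape = tau_shape
        self.tau_rate = tau_rate
        self.target_accept = target_accept
        self.adapt_interval = adapt_interval
        self.standardize = standardize
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y, expected=None, adjacency=None):
        """Run the sampler.

        Parameters
        ----------
        X : array (n_regions, p)
            Region covariates (no intercept column).
        y : array (n_regions,)
            Observed counts.
        expected : array (n_regions,)
            Offsets E_i from indirect standardization; must be positive.
        adjacency : Geography, edge array, or neighbor lists
            Symmetric contiguity structure for the ICAR prior.
        """
        if expected is None or adjacency is None:
            raise ValueError("expected counts and adjacency are required")
        if not (self.n_iterations > self.n_burnin >= 0):
            raise ValueError("need n_iterations > n_burnin >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        E = np.asarray(expected, dtype=float).ravel()
        n, p = X.shape
        if y.size != n or E.size != n:
            raise ValueError("X, y and expected must align")
        if not np.all(np.isfinite(X)):
            raise ValueError("covariates contain non-finite values")
        if np.any(E <= 0):
            raise ValueError("all modeled regions need positive expected counts")

        if self.standardize:
            self._x_mean = X.mean(axis=0)
            scale = X.std(axis=0, ddof=0)
            self._x_scale = np.where(scale > 0, scale, 1.0)
            Xs = (X - self._x_mean) / self._x_scale
        else:
            self._x_mean = np.zeros(p)
            self._x_scale = np.ones(p)
            Xs = X

        # sample on centered covariates (decorrelates intercept and slopes;
        # draws are transformed back to the requested scale when stored)
        x_center = Xs.mean(axis=0)
        Xc = Xs - x_center

        edges = _edge_array(adjacency)
        ncomp = _n_components(n, edges)
        if ncomp > 1:
            logger.warning("adjacency graph has %d components; s is centered "
                           "per component", ncomp)
        colors = _graph_coloring(n, edges)
        # neighbor sums via sparse binary adjacency
        if len(edges):
            A = sp.csr_matrix(
                (np.ones(2 * len(edges)),
                 (np.r_[edges[:, 0], edges[:, 1]], np.r_[edges[:, 1], edges[:, 0]])),
                shape=(n, n))
        else:
            A = sp.csr_matrix((n, n))
        deg = np.asarray(A.sum(axis=1)).ravel()
        comp_labels = (connected_components(A, directed=False)[1]
                       if len(edges) else np.arange(n))

        rng = np.random.default_rng(self.random_state)
        log_E = np.log(E)

        # initial state: intercept at the crude log-SIR level
        beta = np.zeros(p + 1)
        beta[0] = np.log(max(y.sum(), 0.5) / E.sum())
        u = np.zeros(n)
        s = np.zeros(n)
        tau_u = tau_s = 10.0

        step_beta = np.full(p + 1, 0.1)
        step_u = np.full(n, 0.5)
        step_s = np.full(n, 0.5)
        step_ridge = np.full(p + 1, 0.1)
        acc_beta = np.zeros(p + 1)
        acc_u = np.zeros(n)
        acc_s = np.zeros(n)
        acc_ridge = np.zeros(p + 1)
        # ICAR quadratic of each centered covariate column and of constants,
        # used by the likelihood-invariant ridge moves below
        if len(edges):
            dX = Xc[edges[:, 0]] - Xc[edges[:, 1]]
            quad_x = np.einsum("ij,ij->j", dX, dX)
        else:
            dX = np.zeros((0, p))
            quad_x = np.zeros(p)

        n_keep = (self.n_iterations - self.n_burnin + self.thin - 1) // self.thin
        out_beta = np.empty((n_keep, p + 1))
        out_u = np.empty((n_keep, n))
        out_s = np.empty((n_keep, n))
        out_tau_u = np.empty(n_keep)
        out_tau_s = np.empty(n_keep)

        eta_x = Xc @ beta[1:]  # covariate part excl. intercept
        log_mu = log_E + beta[0] + eta_x + u + s
        mu = np.exp(log_mu)
        k = 0
        for it in range(self.n_iterations):
            # --- betas: per-coordinate random walk
            for j in range(p + 1):
                prop = step_beta[j] * rng.standard_normal()
                d_eta = prop if j == 0 else prop * Xc[:, j - 1]
                new_log_mu = log_mu + d_eta
                new_mu = np.exp(new_log_mu)
                d_post = (y @ (new_log_mu - log_mu) - (new_mu.sum() - mu.sum())
                          - ((beta[j] + prop) ** 2 - beta[j] ** 2)
                          / (2 * self.beta_prior_sd ** 2))
                if np.log(rng.random()) < d_post:
                    beta[j] += prop
                    log_mu, mu = new_log_mu, new_mu
                    acc_beta[j] += 1

            # --- u: all sites at once (conditionally independent)
            prop = step_u * rng.standard_normal(n)
            u_new = u + prop
            d = (y * prop - (np.exp(log_mu + prop) - mu)
                 - 0.5 * tau_u * (u_new ** 2 - u ** 2))
            acc = np.log(rng.random(n)) < d
            u = np.where(acc, u_new, u)
            log_mu = log_mu + np.where(acc, prop, 0.0)
            mu = np.exp(log_mu)
            acc_u += acc

            # --- s: colored single-site updates
            nbr_sum = A @ s
            for sites in colors:
                prop = step_s[sites] * rng.standard_normal(sites.size)
                s_new = s[sites] + prop
                d_pr = -0.5 * tau_s * (
                    deg[sites] * (s_new ** 2 - s[sites] ** 2)
                    - 2 * prop * nbr_sum[sites])
                d = (y[sites] * prop
                     - (np.exp(log_mu[sites] + prop) - mu[sites]) + d_pr)
                acc = np.log(rng.random(sites.size)) < d
                ds = np.where(acc, prop, 0.0)
                s[sites] += ds
                log_mu[sites] += ds
                mu[sites] = np.exp(log_mu[sites])
                acc_s[sites] += acc
                if np.any(ds):
                    nbr_sum = A @ s

            # --- ridge moves: translate along likelihood-invariant directions
            # (beta_k, s - d*x_k) and (beta0, u - d); the linear predictor is
            # unchanged, so only priors enter the acceptance ratio.  These
            # decorrelate the slopes from the smooth component of the spatial
            # field (spatial confounding) and the intercept from mean(u).
            d0 = step_ridge[0] * rng.standard_normal()
            d_post = (-((beta[0] + d0) ** 2 - beta[0] ** 2)
                      / (2 * self.beta_prior_sd ** 2)
                      - 0.5 * tau_u * (n * d0 ** 2 - 2 * d0 * u.sum()))
            if np.log(rng.random()) < d_post:
                beta[0] += d0
                u -= d0
                acc_ridge[0] += 1
            if len(edges):
                ds_edges = s[edges[:, 0]] - s[edges[:, 1]]
                for j in range(1, p + 1):
                    dj = step_ridge[j] * rng.standard_normal()
                    cross = float(ds_edges @ dX[:, j - 1])
                    d_post = (-((beta[j] + dj) ** 2 - beta[j] ** 2)
                              / (2 * self.beta_prior_sd ** 2)
                              - 0.5 * tau_s * (dj ** 2 * quad_x[j - 1]
                                               - 2 * dj * cross))
                    if np.log(rng.random()) < d_post:
                        beta[j] += dj
                        s -= dj * Xc[:, j - 1]
                        ds_edges -= dj * dX[:, j - 1]
                        acc_ridge[j] += 1

            # --- recenter s (sum-to-zero); fold the global level into beta0
            if ncomp == 1:
                shift = s.mean()
                s -= shift
                beta[0] += shift
            else:
                for c in range(ncomp):
                    mask = comp_labels == c
                    s[mask] -= s[mask].mean()
                eta_x = Xc @ beta[1:]
                log_mu = log_E + beta[0] + eta_x + u + s
                mu = np.exp(log_mu)

            # --- precisions: conjugate Gamma draws
            tau_u = rng.gamma(self.tau_shape + 0.5 * n,
                              1.0 / (self.tau_rate + 0.5 * (u @ u)))
            quad = icar_quadratic(s, edges)
            tau_s = rng.gamma(self.tau_shape + 0.5 * (n - ncomp),
                              1.0 / (self.tau_rate + 0.5 * quad))

            if not np.all(np.isfinite(log_mu)):
                raise SamplerError(
                    f"non-finite state at iteration {it}: "
                    f"beta={beta!r}, tau_u={tau_u}, tau_s={tau_s}")

            # --- step-size adaptation, burn-in only
            if it < self.n_burnin and (it + 1) % self.adapt_interval == 0:
                w = self.adapt_interval
                for stp, acc_ct in ((step_beta, acc_beta), (step_u, acc_u),
                                    (step_s, acc_s), (step_ridge, acc_ridge)):
                    rate = acc_ct / w
                    stp *= np.exp(np.clip(rate - self.target_accept, -0.5, 0.5))
                    np.clip(stp, 1e-4, 20.0, out=stp)
                    acc_ct[:] = 0.0

            if it >= self.n_burnin and (it - self.n_burnin) % self.thin == 0:
                out_beta[k] = beta
                out_beta[k, 0] -= x_center @ beta[1:]
                out_u[k] = u
                out_s[k] = s
                out_tau_u[k] = tau_u
                out_tau_s[k] = tau_s
                k += 1
            eta_x = Xc @ beta[1:]

        self.samples_ = PosteriorSamples(
            beta=out_beta[:k], u=out_u[:k], s=out_s[:k],
            tau_u=out_tau_u[:k], tau_s=out_tau_s[:k],
            meta={
                "seed": self.random_state,
                "n_iterations": self.n_iterations,
                "n_burnin": self.n_burnin,
                "thin": self.thin,
                "standardize": self.standardize,
                "beta_prior_sd": self.beta_prior_sd,
                "tau_shape": self.tau_shape,
                "tau_rate": self.tau_rate,
            },
        )
        self._X_fit = Xs
        self.n_regions_ = n
        self.expected_ = E
        self.summary_ = summarize(self.samples_, Xs)
        self.psi_, self.psi_ci_ = (self.summary_.psi[0], self.summary_.psi[1:])
        self.coef_ = self.samples_.beta.mean(axis=0)
        self.geweke_ = np.array(
            [geweke_z(self.samples_.beta[:, j]) for j in range(p + 1)])
        return self

    def predict(self, X=None):
        """Posterior-mean fitted counts E_i * r_i for the training regions."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "samples_")
        if X is not None:
            raise ValueError("prediction is for the fitted regions; pass no X")
        return self.expected_ * self.summary_.relative_risk["rr_mean"].to_numpy()


def fit_bym(X, y, expected, adjacency, **params) -> BYMPoissonModel:
    """Functional wrapper: configure, fit and return a :class:`BYMPoissonModel`."""
    return BYMPoissonModel(**params).fit(X, y, expected=expected,
                                         adjacency=adjacency)
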