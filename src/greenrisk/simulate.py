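"""Synthetic study generator: lattice geography, covariates, stratified
counts from the generative Poisson-lognormal model, and toy reflectance
rasters for the EVI stage.

Everything downstream of real data acquisition can be exercised against
data with known ground truth.  The default configuration emulates the
study setting: a 140-region lattice (10 x 14), eight strata (2 sexes x 4
age groups), a smooth vegetation covariate X1 in [0, 1], four unit-scale
deprivation-style covariates X2..X5, and counts that are overdispersed
relative to Poisson with spatially correlated residual risk:

    O_i ~ Poisson(E_i * exp(x_i'beta + u_i + s_i))
    u_i ~ iid N(0, sigma_u^2)
    s   ~ ICAR draw, sum-to-zero, rescaled to empirical SD sigma_s.

All outputs are deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geography import Geography
from .standardize import AGE_GROUPS, SEXES

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationTruth", "DEFAULT_BASELINE_RATES", "simulate_covariates",
    "simulate_populations", "draw_icar", "simulate_counts",
    "generate_band_rasters",
]


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth parameters of the generative model.

    ``beta`` holds (beta0, beta1..beta5); ``sigma_u`` is the SD of the
    exchangeable effect; ``sigma_s`` the empirical (marginal-scale) SD the
    ICAR draw is rescaled to.
    """

    beta: tuple = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    sigma_u: float = 0.0
    sigma_s: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma_u < 0 or self.sigma_s < 0:
            raise ValueError("effect SDs must be nonnegative")


#: baseline cases/person per (sex, age group), spread over a plausible
#: 0.05-0.25 band so each stratum has a distinct crude level
DEFAULT_BASELINE_RATES = {
    (sex, ag): rate
    for (sex, ag), rate in zip(
        [(s, a) for s in SEXES for a in AGE_GROUPS],
        np.linspace(0.05, 0.25, len(SEXES) * len(AGE_GROUPS)).round(4),
    )
}


def simulate_covariates(geog: Geography, seed: int) -> pd.DataFrame:
    """Region covariate table: X1 (EVI-like, smooth, in [0,1]) and X2..X5.

    X1 is a diagonal spatial gradient plus small noise, squashed to
    [0, 1], so it is spatially autocorrelated like a real vegetation
    surface.  X2..X5 are standard-normal deprivation-style scores.
    """
    rng = np.random.default_rng(seed)
    n = geog.n_regions
    if geog.coords is not None:
        rc = geog.coords.astype(float)
        t = (rc[:, 0] / max(rc[:, 0].max(), 1)
             + rc[:, 1] / max(rc[:, 1].max(), 1)) / 2
    else:
        t = np.linspace(0, 1, n)
    x1 = np.clip(0.15 + 0.6 * t + rng.normal(0, 0.05, n), 0.0, 1.0)
    cov = {"region_id": list(geog.region_ids), "X1": x1}
    for k in range(2, 6):
        cov[f"X{k}"] = rng.standard_normal(n)
    return pd.DataFrame(cov)


def simulate_populations(geog: Geography, seed: int,
                         low: int = 800, high: int = 4000) -> pd.DataFrame:
    """Per (region, sex, age group) populations, uniform integers in [low, high]."""
    rng = np.random.default_rng(seed)
    rows = []
    for rid in geog.region_ids:
        for sex in SEXES:
            for ag in AGE_GROUPS:
                rows.append((rid, sex, ag, int(rng.integers(low, high + 1))))
    return pd.DataFrame(rows, columns=["region_id", "sex", "age_group",
                                       "population"])


def draw_icar(geog: Geography, sigma_s: float, rng) -> np.ndarray:
    """One draw from the ICAR distribution on the sum-to-zero subspace,
    rescaled so its empirical (ddof=1) SD equals ``sigma_s``.

    Realized by eigendecomposition of the graph Laplacian: coordinates
    along eigenvectors with eigenvalue lam get variance 1/lam; the null
    space (constants per component) is excluded.
    """
    n = geog.n_regions
    if sigma_s == 0:
        return np.zeros(n)
    L = np.zeros((n, n))
    for i, j in geog.edges:
        L[i, i] += 1
        L[j, j] += 1
        L[i, j] -= 1
        L[j, i] -= 1
    lam, V = np.linalg.eigh(L)
    pos = lam > 1e-8 * max(lam.max(), 1.0)
    z = rng.standard_normal(int(pos.sum())) / np.sqrt(lam[pos])
    s = V[:, pos] @ z
    s -= s.mean()
    sd = s.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate ICAR draw (no non-null eigenmodes)")
    return s * (sigma_s / sd)


def simulate_counts(geog: Geography, covariates: pd.DataFrame,
                    populations: pd.DataFrame, truth: SimulationTruth,
                    baseline_rates: dict | None = None,
                    share_effects: bool = False) -> pd.DataFrame:
    """Stratified observed counts from the generative model.

    Expected counts come from configured per-stratum baseline rates,
    E = rate(sex, age) * population; each stratum then receives its own
    independent (u, s) realization (``share_effects=True`` reuses one
    realization across strata).  Counts are capped at the stratum
    population with a logged warning, preserving the observed <=
    population invariant.

    Returns a StratumTable with the realized ``expected`` and the latent
    ``u``/``s`` attached in ``DataFrame.attrs["truth_effects"]``.
    """
    if baseline_rates is None:
        baseline_rates = DEFAULT_BASELINE_RATES
    ids = list(geog.region_ids)
    cov = covariates.set_index("region_id")
    if set(cov.index) != set(ids):
        raise ValueError("covariate rows do not align with the geography")
    X = cov.loc[ids, ["X1", "X2", "X3", "X4", "X5"]].to_numpy(dtype=float)
    beta = np.asarray(truth.beta, dtype=float)
    eta_fixed = beta[0] + X @ beta[1:]

    rng = np.random.default_rng(truth.seed)
    pop = populations.set_index(["region_id", "sex", "age_group"])["population"]
    rows = []
    effects = {}
    shared = None
    for sex in SEXES:
        for ag in AGE_GROUPS:
            if shared is None or not share_effects:
                u = rng.normal(0.0, truth.sigma_u, geog.n_regions)
                s = draw_icar(geog, truth.sigma_s, rng)
                shared = (u, s)
            u, s = shared
            effects[(sex, ag)] = (u.copy(), s.copy())
            p = pop.loc[[(rid, sex, ag) for rid in ids]].to_numpy(dtype=float)
            E = baseline_rates[(sex, ag)] * p
            lam = E * np.exp(eta_fixed + u + s)
            O = rng.poisson(lam)
            over = O > p
            if over.any():
                logger.warning("stratum (%s, %s): %d count(s) capped at "
                               "population", sex, ag, int(over.sum()))
                O = np.minimum(O, p.astype(np.int64))
            for i, rid in enumerate(ids):
                rows.append((rid, sex, ag, int(p[i]), int(O[i]), float(E[i])))
    out = pd.DataFrame(rows, columns=["region_id", "sex", "age_group",
                                      "population", "observed", "expected"])
    out.attrs["truth_effects"] = effects
    return out


def generate_band_rasters(n_rows_px: int, n_cols_px: int, zone_map,
                          veg_fraction, seed: int):
    """Toy blue/red/NIR reflectance grids driven by per-region vegetation.

    Each pixel mixes a "vegetated" spectrum (high NIR, low red) and a
    "bare" spectrum (the reverse) according to its region's vegetation
    fraction, plus small noise; all reflectances are clamped to [0, 1].
    Emulates 30 m surface-reflectance imagery well enough to exercise the
    EVI stage end to end.

    Returns ``(blue, red, nir)`` float grids of shape
    (n_rows_px, n_cols_px); pixels with a negative zone index get NaN.
    """
    zone_map = np.asarray(zone_map)
    if zone_map.shape != (n_rows_px, n_cols_px):
        raise ValueError("zone map shape must match the pixel grid")
    veg_fraction = np.asarray(veg_fraction, dtype=float)
    valid = zone_map >= 0
    if valid.any() and zone_map[valid].max() >= veg_fraction.size:
        raise ValueError("zone map indexes a region without a veg_fraction")
    if np.any((veg_fraction < 0) | (veg_fraction > 1)):
        raise ValueError("veg_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    # endmember spectra: (blue, red, nir)
    veg = np.array([0.04, 0.05, 0.45])
    bare = np.array([0.12, 0.25, 0.28])
    f = np.where(valid, veg_fraction[np.clip(zone_map, 0, None)], 0.0)
    bands = []
    for b in range(3):
        base = f * veg[b] + (1 - f) * bare[b]
        noisy = base + rng.normal(0, 0.01, zone_map.shape)
        grid = np.clip(noisy, 0.0, 1.0)
        grid[~valid] = np.nan
        bands.append(grid)
    return tuple(bands)
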