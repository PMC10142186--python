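"""Bivariate phylogenetic regression with intraspecific (measurement) variance.

The model is the Ives-type measurement-error extension of phylogenetic GLS.
Species-level diet diversity x and venom diversity y evolve as correlated
Brownian motion on the phylogeny: with C the Brownian covariance matrix
(shared root-to-MRCA branch lengths) and 1 the vector of ones,

    [x]   ~ MVN( [a_x 1] ,  [ s2x*C + D_x   sxy*C       ] )
    [y]          [a_y 1]    [ sxy*C         s2y*C + D_y ] )

where (s2x, s2y, sxy) is the 2x2 Brownian rate matrix and D_x, D_y are
diagonal within-species sampling-variance matrices.  Observed values are
species means of replicate records; for venom diversity the sampling variance
is the pooled within-species variance divided by the number of records m_i.
The evolutionary regression of y on x has

    slope     b1 = sxy / s2x
    intercept b0 = a_y - b1 * a_x.

Fitting is by maximum likelihood (required for the likelihood-ratio test
against the sxy = 0, "intercept-only" null) over the unconstrained
parameterization (a_x, a_y, log s2x, log s2y, atanh(rho)) with
sxy = rho * sqrt(s2x * s2y), which keeps the rate matrix positive
semi-definite by construction.  Multi-start quasi-Newton optimization guards
against the sensitivity to starting conditions this model shows near
variance boundaries.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .errors import ValidationError
from .phylo import PhyloCovariance

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# species-level summaries
# ---------------------------------------------------------------------------

@dataclass
class SpeciesSummary:
    """Per-species means and sampling variances feeding the regression."""

    taxa: list[str]
    x_mean: np.ndarray
    y_mean: np.ndarray
    m: np.ndarray  # venomic records per species
    pooled_within_var_y: float
    sampling_var_y: np.ndarray
    sampling_var_x: np.ndarray

    def __post_init__(self) -> None:
        self.x_mean = np.asarray(self.x_mean, dtype=float)
        self.y_mean = np.asarray(self.y_mean, dtype=float)
        self.m = np.asarray(self.m, dtype=int)
        self.sampling_var_y = np.asarray(self.sampling_var_y, dtype=float)
        self.sampling_var_x = np.asarray(self.sampling_var_x, dtype=float)
        n = len(self.taxa)
        for name in ("x_mean", "y_mean", "m", "sampling_var_y", "sampling_var_x"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length does not match {n} taxa")
        if np.any(self.m < 1):
            raise ValidationError("every species needs at least one record")
        if self.pooled_within_var_y < 0 or np.any(self.sampling_var_y < 0) or np.any(
            self.sampling_var_x < 0
        ):
            raise ValidationError("sampling variances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.taxa)


def summarize_replicates(rows: pd.DataFrame | Sequence[tuple]) -> SpeciesSummary:
    """Collapse per-record (species, x, y) rows to species means.

    Each species must carry exactly one distinct x value (diet diversity is a
    species-level quantity); y values are venomic-record diversities averaged
    per species.  The within-species variance of y is pooled across species
    with >= 2 records,

        s2_w = sum_i sum_j (y_ij - ybar_i)^2 / sum_i (m_i - 1),

    and each species' sampling variance is s2_w / m_i.  Diet sampling variance
    defaults to zero (one pooled diet estimate per species).
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(rows, columns=["species", "x", "y"])
    if rows.empty:
        raise ValidationError("no rows to summarize")

    taxa, x_mean, y_mean, m = [], [], [], []
    ss, df = 0.0, 0
    for species, group in rows.groupby("species", sort=False):
        xs = group["x"].unique()
        if len(xs) > 1:
            raise ValidationError(
                f"species {species!r} has conflicting x values: {sorted(xs)}"
            )
        ys = group["y"].to_numpy(dtype=float)
        taxa.append(str(species))
        x_mean.append(float(xs[0]))
        y_mean.append(float(ys.mean()))
        m.append(len(ys))
        if len(ys) >= 2:
            ss += float(((ys - ys.mean()) ** 2).sum())
            df += len(ys) - 1

    if df > 0:
        pooled = ss / df
    else:
        pooled = 0.0
        logger.warning(
            "all species have a single record; pooled within-species variance set to 0"
        )
    m_arr = np.asarray(m, dtype=float)
    return SpeciesSummary(
        taxa=taxa,
        x_mean=np.asarray(x_mean),
        y_mean=np.asarray(y_mean),
        m=np.asarray(m, dtype=int),
        pooled_within_var_y=pooled,
        sampling_var_y=pooled / m_arr,
        sampling_var_x=np.zeros(len(taxa)),
    )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

@dataclass
class IvesParams:
    """ML parameters: phylogenetic means and the 2x2 Brownian rate matrix."""

    a_x: float
    a_y: float
    sigma2_x: float
    sigma2_y: float
    sigma_xy: float

    def __post_init__(self) -> None:
        if self.sigma2_x <= 0 or self.sigma2_y <= 0:
            raise ValidationError("Brownian rates must be positive")
        bound = math.sqrt(self.sigma2_x * self.sigma2_y)
        if abs(self.sigma_xy) > bound * (1 + 1e-12):
            raise ValidationError(
                f"|sigma_xy|={abs(self.sigma_xy):g} exceeds sqrt(s2x*s2y)={bound:g}"
            )


def _loglik_core(
    a_x: float,
    a_y: float,
    s2x: float,
    s2y: float,
    sxy: float,
    x: np.ndarray,
    y: np.ndarray,
    C: np.ndarray,
    dx: np.ndarray,
    dy: np.ndarray,
) -> float:
    """Gaussian log-likelihood of the stacked (x, y) system; -inf if V not PD."""
    n = len(x)
    V = np.empty((2 * n, 2 * n))
    V[:n, :n] = s2x * C
    V[:n, :n].flat[:: n + 1] += dx
    V[n:, n:] = s2y * C
    V[n:, n:].flat[:: n + 1] += dy
    V[:n, n:] = sxy * C
    V[n:, :n] = V[:n, n:].T
    r = np.concatenate([x - a_x, y - a_y])
    try:
        cho = scipy.linalg.cho_factor(V, lower=True, check_finite=False)
    except scipy.linalg.LinAlgError:
        return -math.inf
    logdet = 2.0 * np.log(np.diag(cho[0])).sum()
    if not np.isfinite(logdet):
        return -math.inf
    quad = float(r @ scipy.linalg.cho_solve(cho, r, check_finite=False))
    return -0.5 * (2 * n * _LOG_2PI + logdet + quad)


def ives_loglik(
    params: IvesParams, data: SpeciesSummary, C: PhyloCovariance
) -> float:
    """Log-likelihood of the bivariate Brownian measurement-error model.

    Returns ``-inf`` (not an exception) when the implied covariance is not
    positive definite, so optimizers can step back and recover.
    """
    if C.n != data.n:
        raise ValidationError(f"covariance has {C.n} taxa, data has {data.n}")
    Cm = C.reorder(data.taxa).matrix if C.taxa != data.taxa else C.matrix
    return _loglik_core(
        params.a_x,
        params.a_y,
        params.sigma2_x,
        params.sigma2_y,
        params.sigma_xy,
        data.x_mean,
        data.y_mean,
        Cm,
        data.sampling_var_x,
        data.sampling_var_y,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class IvesFit:
    """A maximum-likelihood fit with its derived regression line."""

    params: IvesParams
    loglik: float
    constrained: bool
    n_species: int
    converged: bool
    n_starts_used: int
    start_seed: int | None = None

    @property
    def slope(self) -> float:
        if self.constrained:
            return 0.0
        return self.params.sigma_xy / self.params.sigma2_x

    @property
    def intercept(self) -> float:
        return self.params.a_y - self.slope * self.params.a_x

    def to_dict(self) -> dict:
        return {
            "params": asdict(self.params),
            "slope": self.slope,
            "intercept": self.intercept,
            "loglik": self.loglik,
            "constrained": self.constrained,
            "n_species": self.n_species,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "start_seed": self.start_seed,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _gls_mean_and_rate(v: np.ndarray, Cinv_solve) -> tuple[float, float]:
    """Empirical GLS mean and Brownian rate of one trait, used to seed starts."""
    n = len(v)
    ones = np.ones(n)
    Ci1 = Cinv_solve(ones)
    a = float(ones @ Cinv_solve(v)) / float(ones @ Ci1)
    r = v - a
    rate = float(r @ Cinv_solve(r)) / n
    return a, max(rate, 1e-10)


def fit_ives(
    data: SpeciesSummary,
    C: PhyloCovariance,
    constrain_slope: bool = False,
    n_starts: int = 5,
    seed: int | np.random.Generator | None = None,
) -> IvesFit:
    """Multi-start ML fit of the measurement-error phylogenetic regression.

    Optimizes (a_x, a_y, log s2x, log s2y, atanh(rho)) by quasi-Newton search
    (L-BFGS-B, finite-difference gradients, objective tolerance 1e-8); the
    constrained variant fixes rho = 0 so the slope sxy/s2x is exactly zero.
    Starting values per restart: means drawn around the empirical GLS means
    (+- 1 trait SD), log-rates around the empirical GLS rates (+- 1), and
    atanh(rho) uniform on (-1, 1).  The unconstrained fit adds one
    deterministic start at an internal rho = 0 pre-fit so its optimum cannot
    fall below the nested slope-free model's, and the winning point is
    polished with a derivative-free pass.  Returns the best of all starts; a
    fit where every start failed is flagged non-converged with loglik -inf.
    """
    if data.n < 3:
        raise ValidationError(f"need at least 3 species, got {data.n}")
    Cm = C.reorder(data.taxa).matrix if C.taxa != data.taxa else C.matrix
    x, y = data.x_mean, data.y_mean
    dx, dy = data.sampling_var_x, data.sampling_var_y

    start_seed = None
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        start_seed = seed
        rng = np.random.default_rng(seed)

    # Empirical GLS seeds ignore the measurement terms; good enough to start.
    cho_C = scipy.linalg.cho_factor(
        Cm + 1e-12 * np.eye(data.n), lower=True, check_finite=False
    )
    solve_C = lambda v: scipy.linalg.cho_solve(cho_C, v, check_finite=False)
    ax0, rate_x0 = _gls_mean_and_rate(x, solve_C)
    ay0, rate_y0 = _gls_mean_and_rate(y, solve_C)
    sd_x = max(float(np.std(x)), 1e-6)
    sd_y = max(float(np.std(y)), 1e-6)

    def unpack(theta: np.ndarray) -> tuple[float, float, float, float, float]:
        a_x, a_y, ls2x, ls2y = theta[0], theta[1], theta[2], theta[3]
        # clip log-rates so exploratory optimizer steps cannot overflow exp
        s2x = math.exp(min(max(ls2x, -700.0), 700.0))
        s2y = math.exp(min(max(ls2y, -700.0), 700.0))
        rho = 0.0 if constrain_slope else math.tanh(theta[4])
        return a_x, a_y, s2x, s2y, rho * math.sqrt(s2x * s2y)

    def negll(theta: np.ndarray) -> float:
        ll = _loglik_core(*unpack(theta), x, y, Cm, dx, dy)
        return 1e12 if not np.isfinite(ll) else -ll

    starts = []
    for _ in range(n_starts):
        theta0 = [
            ax0 + rng.uniform(-1, 1) * sd_x,
            ay0 + rng.uniform(-1, 1) * sd_y,
            math.log(rate_x0) + rng.uniform(-1, 1),
            math.log(rate_y0) + rng.uniform(-1, 1),
        ]
        if not constrain_slope:
            theta0.append(rng.uniform(-1, 1))
        starts.append(theta0)
    if not constrain_slope:
        # the full model nests the slope-free one, so its optimum can never lie
        # below the constrained optimum: seed one start from an internal
        # constrained pre-fit (deterministic empirical start, rho = 0)
        def negll_rho0(th: np.ndarray) -> float:
            s2x = math.exp(min(max(th[2], -700.0), 700.0))
            s2y = math.exp(min(max(th[3], -700.0), 700.0))
            ll = _loglik_core(th[0], th[1], s2x, s2y, 0.0, x, y, Cm, dx, dy)
            return 1e12 if not np.isfinite(ll) else -ll

        pre = scipy.optimize.minimize(
            negll_rho0,
            np.asarray([ax0, ay0, math.log(rate_x0), math.log(rate_y0)]),
            method="L-BFGS-B",
            options={"ftol": 1e-10, "gtol": 1e-7, "maxiter": 500},
        )
        starts.append([pre.x[0], pre.x[1], pre.x[2], pre.x[3], 0.0])

    best_theta, best_ll, n_ok = None, -math.inf, 0
    for theta0 in starts:
        res = scipy.optimize.minimize(
            negll,
            np.asarray(theta0),
            method="L-BFGS-B",
            options={"ftol": 1e-10, "gtol": 1e-7, "maxiter": 500},
        )
        ll = -res.fun
        if np.isfinite(ll) and ll > -1e11:
            n_ok += 1
            if ll > best_ll:
                best_ll, best_theta = ll, res.x

    if best_theta is not None:
        # derivative-free polish: L-BFGS with finite differences occasionally
        # stalls short of the optimum near flat ridges of the profile surface
        polish = scipy.optimize.minimize(
            negll, best_theta, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000},
        )
        if np.isfinite(polish.fun) and -polish.fun > best_ll:
            best_ll, best_theta = -polish.fun, polish.x

    if best_theta is None:
        logger.warning("fit_ives: all %d starts diverged", n_starts)
        params = IvesParams(a_x=ax0, a_y=ay0, sigma2_x=rate_x0, sigma2_y=rate_y0, sigma_xy=0.0)
        return IvesFit(
            params=params,
            loglik=-math.inf,
            constrained=constrain_slope,
            n_species=data.n,
            converged=False,
            n_starts_used=n_starts,
            start_seed=start_seed,
        )

    a_x, a_y, s2x, s2y, sxy = unpack(best_theta)
    return IvesFit(
        params=IvesParams(a_x=a_x, a_y=a_y, sigma2_x=s2x, sigma2_y=s2y, sigma_xy=sxy),
        loglik=best_ll,
        constrained=constrain_slope,
        n_species=data.n,
        converged=True,
        n_starts_used=n_starts,
        start_seed=start_seed,
    )
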