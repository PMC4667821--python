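"""Generalized birth-death likelihood of ordered divergence times and ML fits.

The model
---------
A community of s species sampled from a speciation-extinction process with
speciation rate λ, extinction rate μ (per unit relative tree time) and
species sampling proportion ρ has ordered divergence times
t = (t_1, ..., t_{s-1}), t_1 > ... > t_{s-1} > 0.  Conditional on t_1 (the
community's own root age), the remaining s - 2 node ages are exchangeable and
i.i.d. with density

    f(t) = λ p1(t) / v_{t_1},      0 < t < t_1,

built from the classical reconstructed-process quantities

    P(0,t) = ρ(λ-μ) / (ρλ + (λ(1-ρ) - μ) e^{(μ-λ)t})
    p1(t)  = (1/ρ) P(0,t)^2 e^{(μ-λ)t}
    v_t    = 1 - (1/ρ) P(0,t) e^{(μ-λ)t}
           = ρλ (1 - e^{(μ-λ)t}) / (ρλ + (λ(1-ρ) - μ) e^{(μ-λ)t}),

so the log-likelihood is

    log L = log (s-2)! + Σ_{j=2}^{s-1} [ log λ + log p1(t_j) ] - (s-2) log v_{t_1}.

v_t is the CDF kernel of the node-age density: d v_t / d t = λ p1(t), which
makes f integrate to one on (0, t_1) and gives an analytic inverse CDF used
by the simulator.

The two-step procedure
----------------------
Step one fits (λ, μ) to the meta-community's divergence times with ρ fixed
(:class:`SpeciationExtinctionModel`).  Step two holds those estimates fixed
and fits the effective sampling proportion ρ_E of each local community from
its own induced-subtree ages (:class:`SamplingProportionModel`).  ρ_E larger
than the community's actual sampling fraction signals young, clade-clustered
divergences; the ratio is the phylogenetic skew computed in
:mod:`phyloskew.diversity`.

Both models follow the statsmodels convention: construct from data, call
``fit()``, receive a :class:`BirthDeathResults` carrying estimates, standard
errors (from the inverse numerical observed information), the log-likelihood
and convergence diagnostics, with a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln
from scipy.stats import qmc

__all__ = [
    "BirthDeathParams",
    "BirthDeathResults",
    "BirthDeathError",
    "InsufficientDataError",
    "prob_unsampled",
    "p1",
    "v",
    "log_likelihood",
    "SpeciationExtinctionModel",
    "SamplingProportionModel",
    "fit_speciation_extinction",
    "fit_sampling_proportion",
    "RHO_MIN",
]

#: lower bound of the sampling-proportion search domain
RHO_MIN = 1e-6

#: two starts "agree" when their log-likelihoods differ by less than this
AGREE_TOL = 1e-4

_BOUNDARY_FRAC = 1e-4  # transformed-fraction proximity that counts as a boundary hit


class BirthDeathError(ValueError):
    """Invalid parameters or divergence times for the birth-death model."""


class InsufficientDataError(BirthDeathError):
    """Too few divergence times for the requested fit."""


@dataclass(frozen=True)
class BirthDeathParams:
    """Speciation rate λ, extinction rate μ and sampling proportion ρ.

    Rates are per unit relative tree time; ρ is dimensionless.  The process
    must be supercritical (0 ≤ μ < λ) so that v_t stays positive.
    """

    lam: float
    mu: float = 0.0
    rho: float = 1.0

    def __post_init__(self) -> None:
        if not (self.lam > 0):
            raise BirthDeathError(f"speciation rate must be positive, got {self.lam!r}")
        if not (0 <= self.mu < self.lam):
            raise BirthDeathError(
                f"need 0 <= mu < lam (supercritical), got mu={self.mu!r}, lam={self.lam!r}"
            )
        if not (0 < self.rho <= 1):
            raise BirthDeathError(f"sampling proportion must be in (0, 1], got {self.rho!r}")

    @property
    def net_rate(self) -> float:
        """Net diversification rate λ - μ."""
        return self.lam - self.mu


def _validate_ages(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise BirthDeathError("ages must be nonnegative")
    return t


def prob_unsampled(t, params: BirthDeathParams):
    """P(0, t): probability a lineage alive at age t has sampled descendants today.

    The classical survival-and-sampling factor of the reconstructed
    birth-death process: it lies in (0, 1], equals ρ at t = 0 and tends to
    the survival probability (λ-μ)/λ for large t when ρ = 1.
    """
    t = _validate_ages(t)
    lam, mu, rho = params.lam, params.mu, params.rho
    a = lam * (1.0 - rho) - mu
    E = np.exp((mu - lam) * t)
    return rho * (lam - mu) / (rho * lam + a * E)


def p1(t, params: BirthDeathParams):
    """Density factor p1(t) = (1/ρ) P(0,t)² e^{(μ-λ)t}; p1(0) = ρ."""
    t = _validate_ages(t)
    lam, mu, rho = params.lam, params.mu, params.rho
    P = prob_unsampled(t, params)
    return (P * P / rho) * np.exp((mu - lam) * t)


def v(t, params: BirthDeathParams):
    """Cumulative weight v_t = 1 - (1/ρ) P(0,t) e^{(μ-λ)t}.

    v_0 = 0, v is strictly increasing with derivative λ p1(t), and
    v_t / v_{t1} is the CDF of a node age on (0, t1).
    """
    t = _validate_ages(t)
    lam, mu, rho = params.lam, params.mu, params.rho
    a = lam * (1.0 - rho) - mu
    E = np.exp((mu - lam) * t)
    # 1 - (1/rho) P E simplifies to rho*lam*(1-E) / (rho*lam + a*E); the
    # expm1 form is exact at t = 0 and stable for small t.
    return rho * lam * (-np.expm1((mu - lam) * t)) / (rho * lam + a * E)


def _log_p1(t, params: BirthDeathParams):
    lam, mu, rho = params.lam, params.mu, params.rho
    a = lam * (1.0 - rho) - mu
    mlt = (mu - lam) * t
    log_denom = np.log(rho * lam + a * np.exp(mlt))
    log_P = math.log(rho * (lam - mu)) - log_denom
    return -math.log(rho) + 2.0 * log_P + mlt


def _log_v(t, params: BirthDeathParams):
    lam, mu, rho = params.lam, params.mu, params.rho
    a = lam * (1.0 - rho) - mu
    mlt = (mu - lam) * t
    log_denom = np.log(rho * lam + a * np.exp(mlt))
    return math.log(rho * lam) + np.log(-np.expm1(mlt)) - log_denom


def log_likelihood(times: Sequence[float], params: BirthDeathParams) -> float:
    """Log-likelihood of ordered divergence times under the birth-death model.

    ``times[0]`` must be the community's oldest divergence t_1; it enters the
    likelihood only through the normalizing v_{t_1} (the density is
    conditional on t_1).  The remaining entries may appear in any order (the
    density is exchangeable given t_1).  The combinatorial log (s-2)! term is
    included so reported values are comparable across implementations; it
    does not move the maximizer.

    For s = 2 (a single divergence time) the product is empty and the value
    is exactly 0.
    """
    t = np.asarray(times, dtype=float).ravel()
    if t.size < 1:
        raise InsufficientDataError("need at least one divergence time (s >= 2)")
    if np.any(t <= 0):
        raise BirthDeathError("divergence times must be strictly positive")
    s = t.size + 1
    if s == 2:
        return 0.0
    t1 = t[0]
    rest = t[1:]
    if rest.max() >= t1:
        raise BirthDeathError(
            "ordering violated: the first time t_1 must strictly exceed all others"
        )
    ll = (
        gammaln(s - 1)
        + np.sum(math.log(params.lam) + _log_p1(rest, params))
        - (s - 2) * _log_v(t1, params)
    )
    return float(ll)


# -- results container -------------------------------------------------------


@dataclass
class BirthDeathResults:
    """ML fit of birth-death parameters to divergence times.

    Attributes
    ----------
    params
        Full parameter set at the optimum (fitted and fixed components).
    free
        Names of the parameters that were fitted.
    llf
        Maximized log-likelihood (includes the log (s-2)! constant).
    bse
        Standard errors of the free parameters from the inverse numerical
        observed information (NaN where the curvature is unusable, e.g. on a
        boundary).
    boundary
        Per-free-parameter boundary flag: ``"lower"``, ``"upper"`` or None.
    n_starts_agreeing
        Number of multi-start runs whose final log-likelihood is within
        ``AGREE_TOL`` of the best.
    """

    params: BirthDeathParams
    free: tuple[str, ...]
    llf: float
    bse: dict[str, float]
    boundary: dict[str, str | None]
    converged: bool
    n_starts_agreeing: int
    n_starts: int
    nobs: int
    model: object = field(repr=False, default=None)

    def to_dict(self) -> dict:
        out = {
            "lam": self.params.lam,
            "mu": self.params.mu,
            "rho": self.params.rho,
            "loglik": self.llf,
            "converged": self.converged,
            "n_starts_agreeing": self.n_starts_agreeing,
            "n_starts": self.n_starts,
            "n_times": self.nobs,
        }
        for name in self.free:
            out[f"{name}_se"] = self.bse.get(name, float("nan"))
            out[f"{name}_boundary"] = self.boundary.get(name) or "none"
        return out

    def write_flat(self, path) -> None:
        """Serialize as flat ``key = value`` text."""
        lines = [f"{k} = {v}" for k, v in self.to_dict().items()]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    def summary(self) -> str:
        rows = []
        for name in ("lam", "mu", "rho"):
            est = getattr(self.params, name)
            if name in self.free:
                se = self.bse.get(name, float("nan"))
                se_s = f"{se:12.4g}" if np.isfinite(se) else "         nan"
                bd = self.boundary.get(name) or "-"
            else:
                se_s = "       fixed"
                bd = "-"
            rows.append(f"{name:>6} {est:14.6g} {se_s}   {bd}")
        width = 46
        lines = [
            "Birth-death maximum likelihood fit".center(width),
            "=" * width,
            f"{'param':>6} {'estimate':>14} {'std err':>12}   boundary",
            "-" * width,
            *rows,
            "-" * width,
            f"log-likelihood {self.llf:14.6g}    n times {self.nobs}",
            f"converged {self.converged}    starts agreeing "
            f"{self.n_starts_agreeing}/{self.n_starts}",
            "=" * width,
        ]
        return "\n".join(lines)


# -- numerical curvature -----------------------------------------------------


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian with per-coordinate relative steps."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1e-8)
    H = np.full((n, n), np.nan)
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / (h[i] * h[i])
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _bse_from_hessian(f, x: np.ndarray, names: tuple[str, ...]) -> dict[str, float]:
    try:
        H = _numeric_hessian(f, x)
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        return {
            name: float(np.sqrt(d)) if np.isfinite(d) and d > 0 else float("nan")
            for name, d in zip(names, diag)
        }
    except (np.linalg.LinAlgError, BirthDeathError, FloatingPointError):
        return {name: float("nan") for name in names}


def _multistart(neg, starts, maxiter=2000):
    runs = []
    for x0 in starts:
        res = minimize(
            neg,
            np.asarray(x0, dtype=float),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": maxiter},
        )
        runs.append(res)
    best = min(runs, key=lambda r: r.fun)
    lls = np.array([-r.fun for r in runs])
    n_agree = int(np.sum(lls >= -best.fun - AGREE_TOL))
    return best, n_agree


# -- step one: (lambda, mu) with rho fixed -----------------------------------


class SpeciationExtinctionModel:
    """ML fit of (λ, μ) to ordered divergence times with ρ held fixed.

    This is step one of the two-step skew procedure: applied to the
    meta-community tree's divergence times with ρ = 1.  Optimization runs in
    the unconstrained parameterization (log λ, logit(μ/λ)), which enforces
    λ > μ ≥ 0 without a constrained solver, from a fixed-seed Latin-hypercube
    set of starts.
    """

    free = ("lam", "mu")

    def __init__(self, times: Sequence[float], rho: float = 1.0) -> None:
        t = np.asarray(times, dtype=float).ravel()
        if t.size < 3:
            raise InsufficientDataError(
                f"fitting (lam, mu) needs at least 3 divergence times (s >= 4), got {t.size}"
            )
        if not (0 < rho <= 1):
            raise BirthDeathError(f"rho must be in (0, 1], got {rho!r}")
        # validate ordering once up front
        log_likelihood(t, BirthDeathParams(1.0, 0.0, rho))
        self.times = t
        self.rho = float(rho)

    def loglike(self, lam: float, mu: float) -> float:
        return log_likelihood(self.times, BirthDeathParams(lam, mu, self.rho))

    def _unpack(self, x) -> tuple[float, float]:
        lam = math.exp(min(float(x[0]), 50.0))
        frac = expit(float(x[1]))
        return lam, lam * frac

    def fit(self, n_starts: int = 10, seed: int = 0) -> BirthDeathResults:
        def neg(x):
            lam, mu = self._unpack(x)
            try:
                return -log_likelihood(self.times, BirthDeathParams(lam, mu, self.rho))
            except (BirthDeathError, FloatingPointError, OverflowError):
                return 1e18

        # data-driven box for the Latin-hypercube starts: the mean non-root
        # age sets the natural rate scale
        scale = 1.0 / max(float(np.mean(self.times[1:])), 1e-12)
        lo, hi = math.log(scale / 30.0), math.log(scale * 30.0)
        u = qmc.LatinHypercube(d=2, seed=seed).random(n_starts)
        starts = np.column_stack([lo + u[:, 0] * (hi - lo), -6.0 + u[:, 1] * 9.0])

        best, n_agree = _multistart(neg, starts)
        lam, mu = self._unpack(best.x)
        frac = expit(float(best.x[1]))
        boundary = {
            "lam": None,
            "mu": "lower" if frac < _BOUNDARY_FRAC else (
                "upper" if frac > 1 - _BOUNDARY_FRAC else None
            ),
        }
        llf = -float(best.fun)
        converged = bool(best.success) and np.isfinite(llf)

        def neg_raw(theta):
            l, m = theta
            if not (l > 0 and 0 <= m < l):
                return float("nan")
            return -log_likelihood(self.times, BirthDeathParams(l, m, self.rho))

        bse = _bse_from_hessian(neg_raw, np.array([lam, mu]), self.free)
        return BirthDeathResults(
            params=BirthDeathParams(lam, mu, self.rho),
            free=self.free,
            llf=llf,
            bse=bse,
            boundary=boundary,
            converged=converged,
            n_starts_agreeing=n_agree,
            n_starts=n_starts,
            nobs=self.times.size,
            model=self,
        )


# -- step two: rho with (lambda, mu) fixed -----------------------------------


class SamplingProportionModel:
    """ML fit of the effective sampling proportion ρ_E with (λ, μ) fixed.

    Step two of the two-step procedure, applied per community to the
    divergence times of its induced subtree, conditioned on the community's
    own oldest divergence.  The search runs over a logit transform of
    [RHO_MIN, 1]; boundary solutions are flagged rather than hidden.
    """

    free = ("rho",)

    def __init__(self, times: Sequence[float], lam: float, mu: float) -> None:
        t = np.asarray(times, dtype=float).ravel()
        if t.size < 2:
            raise InsufficientDataError(
                f"fitting rho needs at least 2 divergence times (s >= 3), got {t.size}"
            )
        if not (lam > mu >= 0):
            raise BirthDeathError(f"need lam > mu >= 0, got lam={lam!r}, mu={mu!r}")
        log_likelihood(t, BirthDeathParams(lam, mu, 1.0))
        self.times = t
        self.lam = float(lam)
        self.mu = float(mu)

    def loglike(self, rho: float) -> float:
        return log_likelihood(self.times, BirthDeathParams(self.lam, self.mu, rho))

    def _to_rho(self, x: float, rho_min: float) -> float:
        return rho_min + (1.0 - rho_min) * expit(x)

    def fit(
        self, n_starts: int = 10, seed: int = 0, rho_min: float = RHO_MIN
    ) -> BirthDeathResults:
        def neg(x):
            rho = self._to_rho(float(x[0]), rho_min)
            try:
                return -self.loglike(rho)
            except (BirthDeathError, FloatingPointError, OverflowError):
                return 1e18

        u = qmc.LatinHypercube(d=1, seed=seed).random(n_starts)
        starts = (-12.0 + u[:, 0] * 20.0).reshape(-1, 1)
        best, n_agree = _multistart(neg, starts, maxiter=500)
        frac = expit(float(best.x[0]))
        rho_hat = self._to_rho(float(best.x[0]), rho_min)
        boundary = {
            "rho": "lower" if frac < _BOUNDARY_FRAC else (
                "upper" if frac > 1 - _BOUNDARY_FRAC else None
            )
        }
        llf = -float(best.fun)
        converged = bool(best.success) and np.isfinite(llf)

        if boundary["rho"] is None:
            def neg_raw(theta):
                r = theta[0]
                if not (0 < r <= 1):
                    return float("nan")
                return -self.loglike(r)

            bse = _bse_from_hessian(neg_raw, np.array([rho_hat]), self.free)
        else:
            bse = {"rho": float("nan")}
        return BirthDeathResults(
            params=BirthDeathParams(self.lam, self.mu, rho_hat),
            free=self.free,
            llf=llf,
            bse=bse,
            boundary=boundary,
            converged=converged,
            n_starts_agreeing=n_agree,
            n_starts=n_starts,
            nobs=self.times.size,
            model=self,
        )


# -- functional wrappers ------------------------------------------------------


def fit_speciation_extinction(
    times: Sequence[float],
    rho_fixed: float = 1.0,
    n_starts: int = 10,
    seed: int = 0,
) -> BirthDeathResults:
    """Step one: maximize the likelihood over (λ, μ) with ρ fixed."""
    return SpeciationExtinctionModel(times, rho=rho_fixed).fit(
        n_starts=n_starts, seed=seed
    )


def fit_sampling_proportion(
    times: Sequence[float],
    lam: float,
    mu: float,
    n_starts: int = 10,
    seed: int = 0,
) -> BirthDeathResults:
    """Step two: maximize the likelihood over ρ with (λ, μ) fixed."""
    return SamplingProportionModel(times, lam, mu).fit(n_starts=n_starts, seed=seed)
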