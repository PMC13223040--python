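"""Interfering-plant attenuation of the received quantity.

A neighbouring plant standing on the transmitter-receiver axis intercepts
part of the airborne tracer.  Its net, path-scale effect is modelled as a
multiplicative attenuation of the cumulative received quantity,

    I(alpha, beta) = lam * exp(-xi * alpha) * exp(-(beta - mu)^2 / sigma^2)

where ``alpha`` is the interferer-to-receiver radius ratio (size effect,
exponential) and ``beta`` its fractional position along the axis (position
effect, Gaussian with an interior optimum at ``mu``).  The four parameters
are estimated from simulated or measured uptake ratios by damped nonlinear
least squares (Levenberg-Marquardt), optionally under the physical bound
``lam < 1`` that keeps I a pure attenuation.

The fitting pipeline follows the Model/Results idiom: build an
:class:`AttenuationModel` from observations, call :meth:`~AttenuationModel.fit`,
and read estimates, standard errors and goodness of fit off the returned
:class:`AttenuationResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "InterferenceGeometry",
    "AttenuationParams",
    "GofMetrics",
    "attenuation_factor",
    "interfered_quantity",
    "gof_metrics",
    "AttenuationModel",
    "AttenuationResults",
    "fit_attenuation",
]


@dataclass(frozen=True)
class InterferenceGeometry:
    """Relative size (alpha) and axial position fraction (beta) of the
    interfering plant.  Working range is the unit square."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")


@dataclass(frozen=True)
class AttenuationParams:
    """Parameters of the attenuation response I(alpha, beta)."""

    lam: float = 0.5     # amplitude
    xi: float = 1.0      # size-decay rate
    mu: float = 0.5      # peak position in beta
    sigma: float = 0.3   # width in beta

    def __post_init__(self) -> None:
        for name in ("lam", "xi", "mu", "sigma"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"AttenuationParams.{name} must be finite")
        if self.sigma <= 0:
            raise ValueError("AttenuationParams.sigma must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.lam, self.xi, self.mu, self.sigma])

    def replace(self, **kw) -> "AttenuationParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class GofMetrics:
    """Goodness-of-fit triple: R², SSE and RMSE (= sqrt(SSE/n))."""

    r2: float
    sse: float
    rmse: float


def attenuation_factor(geom: InterferenceGeometry,
                       params: AttenuationParams) -> float:
    """Attenuation I(alpha, beta); peaks over beta at beta = mu and decreases
    in alpha for xi > 0."""
    return float(_attenuation(geom.alpha, geom.beta, params.as_array()))


def _attenuation(alpha, beta, p):
    lam, xi, mu, sigma = p
    return lam * np.exp(-xi * np.asarray(alpha)) * np.exp(
        -((np.asarray(beta) - mu) ** 2) / sigma**2)


def interfered_quantity(Q: float, geom: InterferenceGeometry,
                        params: AttenuationParams) -> float:
    """Received quantity behind the interferer: Q_I = I(alpha, beta) * Q."""
    if Q < 0:
        raise ValueError("Q must be non-negative")
    return attenuation_factor(geom, params) * Q


def gof_metrics(observed, predicted) -> GofMetrics:
    """R², SSE = sum((o-p)^2), RMSE = sqrt(SSE/n); R² = 1 - SSE/SStot."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError("observed and predicted must have equal length")
    if o.size < 2:
        raise ValueError("need at least 2 points for goodness of fit")
    sse = float(np.sum((o - p) ** 2))
    sstot = float(np.sum((o - o.mean()) ** 2))
    if sstot > 0:
        r2 = 1.0 - sse / sstot
    else:
        # constant observations carry no explainable variance
        r2 = 1.0 if sse == 0.0 else 0.0
    return GofMetrics(r2=r2, sse=sse, rmse=math.sqrt(sse / o.size))


class AttenuationModel:
    """LM fit of the attenuation response to observed uptake ratios.

    Parameters
    ----------
    observations : DataFrame or array-like
        Columns/fields (alpha, beta, ratio) where ratio = Q_I / Q_baseline,
        the uptake relative to the interferer-free run.  At least 5
        observations over distinct (alpha, beta) pairs.
    strict_bound : bool
        Constrain lam < 1 so that 0 < I < 1 (pure attenuation).
    """

    def __init__(self, observations, strict_bound: bool = False):
        if isinstance(observations, pd.DataFrame):
            df = observations[["alpha", "beta", "ratio"]]
            arr = df.to_numpy(dtype=float)
        else:
            arr = np.asarray(observations, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("observations must be (alpha, beta, ratio) triples")
        if arr.shape[0] < 5:
            raise ValueError("need at least 5 observations")
        pairs = {(round(a, 12), round(b, 12)) for a, b in arr[:, :2]}
        if len(pairs) < 2:
            raise ValueError("degenerate observations: all (alpha, beta) "
                             "identical, nothing to fit")
        self.alpha = arr[:, 0]
        self.beta = arr[:, 1]
        self.ratio = arr[:, 2]
        self.strict_bound = bool(strict_bound)

    def _residuals(self, p):
        return _attenuation(self.alpha, self.beta, p) - self.ratio

    def fit(self, init: AttenuationParams = AttenuationParams(),
            multistart: int = 10, seed: int = 0) -> "AttenuationResults":
        """Fit by Levenberg-Marquardt (trust-region reflective when the
        lam < 1 bound is active); multi-start from perturbed initial values
        guards against local minima."""
        lo = np.array([-np.inf, -np.inf, -np.inf, 1e-12])
        hi = np.array([np.inf, np.inf, np.inf, np.inf])
        if self.strict_bound:
            hi[0] = 1.0 - 1e-9
            lo[0] = 1e-12
        rng = np.random.default_rng(seed)
        p0s = [init.as_array()]
        for _ in range(max(multistart - 1, 0)):
            p0s.append(init.as_array() * rng.uniform(0.5, 2.0, size=4))
        best = None
        statuses = []
        for p0 in p0s:
            p0 = np.clip(p0, lo + 1e-9, np.where(np.isfinite(hi), hi - 1e-9, p0))
            p0 = np.where(np.isfinite(p0), p0, init.as_array())
            # pure LM when unbounded; trust-region reflective when lam < 1
            method = "trf" if self.strict_bound else "lm"
            if method == "lm":
                sol = least_squares(self._residuals, p0, method="lm",
                                    xtol=1e-14, ftol=1e-14)
            else:
                sol = least_squares(self._residuals, p0, method="trf",
                                    bounds=(lo, hi), xtol=1e-14, ftol=1e-14)
            statuses.append(sol.status)
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or best.status <= 0:
            raise RuntimeError(f"attenuation fit did not converge "
                               f"(statuses {statuses})")
        return AttenuationResults(self, best)


class AttenuationResults:
    """Estimates, uncertainties and diagnostics of an attenuation fit."""

    _names = ("lam", "xi", "mu", "sigma")

    def __init__(self, model: AttenuationModel, sol):
        self.model = model
        self._sol = sol
        p = sol.x
        self.params = AttenuationParams(lam=p[0], xi=p[1], mu=p[2],
                                        sigma=abs(p[3]))
        self.fittedvalues = _attenuation(model.alpha, model.beta, p)
        self.resid = self.fittedvalues - model.ratio
        self.gof = gof_metrics(model.ratio, self.fittedvalues)
        self.nobs = model.ratio.size
        self.converged = sol.status > 0
        self.bse = self._standard_errors()

    def _standard_errors(self):
        J = self._sol.jac
        dof = max(self.nobs - 4, 1)
        s2 = 2.0 * self._sol.cost / dof
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            return np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            return np.full(4, np.nan)

    @property
    def rsquared(self) -> float:
        return self.gof.r2

    def summary(self) -> str:
        p = self.params.as_array()
        lines = [
            "Attenuation response fit (Levenberg-Marquardt)",
            f"  nobs: {self.nobs}   strict lam<1 bound: {self.model.strict_bound}",
            f"  R2: {self.gof.r2:.6f}   SSE: {self.gof.sse:.4g}   "
            f"RMSE: {self.gof.rmse:.4g}",
            "  param     estimate      std err",
        ]
        for name, est, se in zip(self._names, p, self.bse):
            lines.append(f"  {name:<8} {est:>11.5f} {se:>12.4g}")
        return "\n".join(lines)


def fit_attenuation(observations, init: AttenuationParams = AttenuationParams(),
                    strict_bound: bool = False, multistart: int = 10,
                    seed: int = 0):
    """Convenience wrapper: fit and return (AttenuationParams, GofMetrics)."""
    res = AttenuationModel(observations, strict_bound=strict_bound).fit(
        init=init, multistart=multistart, seed=seed)
    return res.params, res.gof
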