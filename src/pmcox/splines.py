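"""Restricted cubic spline exposure-response curves.

A restricted cubic spline with knots k₁<…<k_m is a piecewise cubic that is
constrained to be *linear* beyond the boundary knots. With m knots it has
m−1 basis terms: the identity, plus m−2 restricted truncated-power terms

    b_{j+1}(x) = [ (x−k_j)₊³
                   − (x−k_{m−1})₊³ (k_m−k_j)/(k_m−k_{m−1})
                   + (x−k_m)₊³ (k_{m−1}−k_j)/(k_m−k_{m−1}) ] / (k_m−k₁)²

for j = 1..m−2. The division by (k_m−k₁)² gives every term the exposure's
units, so spline coefficients live on the same scale as the linear slope.
Below k₁ all nonlinear terms vanish, which makes evaluation at a 0 µg/m³
reference a well-defined linear-tail extrapolation even when 0 lies below
the observed exposure range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import CellData, CoxFit, EngineError, fit_cox

KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


class SplineError(ValueError):
    pass


@dataclass
class SplineBasis:
    """Restricted truncated-power cubic basis for a set of knots."""

    knots: np.ndarray

    def __post_init__(self):
        k = np.asarray(self.knots, float)
        if k.ndim != 1 or len(k) < 3 or np.any(np.diff(k) <= 0):
            raise SplineError(f"knots must be >=3 strictly increasing values, got {k}")
        self.knots = k

    @property
    def m(self) -> int:
        return len(self.knots)

    @property
    def n_terms(self) -> int:
        return self.m - 1

    def names(self, var: str) -> list[str]:
        return [var] + [f"{var}_rcs{j}" for j in range(2, self.m)]

    def __call__(self, x) -> np.ndarray:
        """Evaluate the basis; returns shape (..., m-1) with b₁ = x."""
        x = np.asarray(x, float)
        k = self.knots
        km, km1 = k[-1], k[-2]
        norm = (km - k[0]) ** 2
        cols = [x]
        for j in range(self.m - 2):
            kj = k[j]
            term = (
                np.maximum(x - kj, 0) ** 3
                - np.maximum(x - km1, 0) ** 3 * (km - kj) / (km - km1)
                + np.maximum(x - km, 0) ** 3 * (km1 - kj) / (km - km1)
            ) / norm
            cols.append(term)
        return np.stack(cols, axis=-1)


def rcs_basis(x, knots) -> np.ndarray:
    """Functional form of :class:`SplineBasis`: basis matrix for exposures x."""
    return SplineBasis(np.asarray(knots, float))(x)


def place_knots(exposure_values, m: int = 3, quantiles=None) -> np.ndarray:
    """Default quantile knot placement on the person-month exposure distribution."""
    if quantiles is None:
        if m not in KNOT_QUANTILES:
            raise SplineError(f"no default quantiles for m={m}; pass them explicitly")
        quantiles = KNOT_QUANTILES[m]
    x = np.asarray(exposure_values, float)
    x = x[np.isfinite(x)]
    if len(np.unique(x)) < m:
        raise SplineError(f"need >= {m} distinct exposure values to place {m} knots")
    knots = np.quantile(x, quantiles)
    if np.any(np.diff(knots) <= 0):
        raise SplineError(
            f"duplicate knots at quantiles {quantiles}; reduce the knot count"
        )
    return knots


@dataclass
class RRCurve:
    """Exposure-response curve relative to a reference exposure."""

    exposure: np.ndarray
    rr: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    x_ref: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "exposure": self.exposure,
                "rr": self.rr,
                "rr_lo95": self.lo95,
                "rr_hi95": self.hi95,
            }
        )


def rr_curve(
    fit: CoxFit,
    basis: SplineBasis,
    grid,
    x_ref: float = 0.0,
    terms: slice | None = None,
) -> RRCurve:
    """RR(x) = exp(βᵀ[b(x) − b(x_ref)]) with pointwise delta-method 95% CI.

    ``terms`` selects the spline coefficients inside ``fit.beta`` (defaults
    to the leading m−1 coefficients). The reference is 0 µg/m³ by default,
    reached through the basis's linear lower tail.
    """
    if not fit.converged:
        raise EngineError("refusing to build an RR curve from an unconverged fit")
    sl = terms if terms is not None else slice(0, basis.n_terms)
    beta = fit.beta[sl]
    cov = fit.cov[sl, sl] if np.ndim(fit.cov[sl, sl]) == 2 else np.atleast_2d(fit.cov[sl, sl])
    grid = np.asarray(grid, float)
    g = basis(grid) - basis(np.full_like(grid, x_ref))
    log_rr = g @ beta
    var = np.einsum("ij,jk,ik->i", g, cov, g)
    se = np.sqrt(np.maximum(var, 0))
    return RRCurve(
        exposure=grid,
        rr=np.exp(log_rr),
        lo95=np.exp(log_rr - 1.96 * se),
        hi95=np.exp(log_rr + 1.96 * se),
        x_ref=float(x_ref),
    )


def aic(fit: CoxFit) -> float:
    """AIC on the partial likelihood: 2k − 2·loglik."""
    return 2 * len(fit.beta) - 2 * fit.loglik


def compare_knot_counts(fit_fn, exposure_values, m_list=(3, 4, 5)) -> dict:
    """Fit spline models with each knot count and rank them by AIC.

    ``fit_fn(basis) -> CoxFit`` is supplied by the caller (it owns cell
    construction); non-convergent candidates are excluded with a warning
    entry. Ties in AIC resolve to fewer knots.
    """
    report = {"candidates": {}, "excluded": {}, "best_m": None}
    best = (np.inf, None)
    for m in sorted(m_list):
        basis = SplineBasis(place_knots(exposure_values, m))
        fit = fit_fn(basis)
        if not fit.converged:
            report["excluded"][m] = "did not converge"
            continue
        a = aic(fit)
        report["candidates"][m] = {
            "aic": a,
            "loglik": fit.loglik,
            "k": len(fit.beta),
            "knots": basis.knots.tolist(),
            "fit": fit,
        }
        if a < best[0] - 1e-12:  # strict improvement; ties keep fewer knots
            best = (a, m)
    report["best_m"] = best[1]
    return report
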