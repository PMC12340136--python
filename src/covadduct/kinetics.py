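"""Phosphatase activity-assay numerics.

Two fits: (i) the DiFMU product standard curve — an ordinary
least-squares line of fluorescence on concentration, inverted to
convert experimental fluorescence readings to product concentration;
(ii) the one-phase exponential decay of enzyme activity against
inhibitor concentration,

    Y(c) = plateau + (y0 - plateau) * exp(-k * c)

fit by bounded nonlinear least squares with multi-start initialisation
(k from a log-spaced grid, y0/plateau from the data extremes) so no
user tuning is needed to escape local minima.  r^2 for both fits uses
the 1 - SSres/SStot-about-the-mean convention of the common graphing
software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats


@dataclass(frozen=True)
class StandardCurve:
    """OLS line fluorescence = slope * concentration + intercept."""

    slope: float
    intercept: float
    r2: float
    conc_min: float = 0.0
    conc_max: float = math.inf


@dataclass(frozen=True)
class DecayFit:
    """One-phase exponential decay parameters and goodness of fit."""

    y0: float
    plateau: float
    k: float
    r2: float

    def predict(self, conc: "np.ndarray | float") -> "np.ndarray | float":
        return self.plateau + (self.y0 - self.plateau) * np.exp(-self.k * np.asarray(conc, dtype=float))


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def fit_standard_curve(standards: Sequence[tuple[float, float]]) -> StandardCurve:
    """Fit the line of best fit to (concentration, fluorescence) standards."""
    pts = np.asarray(standards, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two standards")
    conc, fluor = pts[:, 0], pts[:, 1]
    if np.unique(conc).size < 2:
        raise ValueError("standards need at least two distinct concentrations")
    res = stats.linregress(conc, fluor)
    yhat = res.slope * conc + res.intercept
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=_r2(fluor, yhat),
        conc_min=float(conc.min()),
        conc_max=float(conc.max()),
    )


def interpolate_product(
    fluorescence: float, curve: StandardCurve
) -> tuple[float, bool]:
    """Concentration for a fluorescence reading via the inverted line.

    Returns ``(concentration, extrapolated)`` where the flag marks
    values outside the fitted standard range.
    """
    if curve.slope == 0:
        raise ValueError("standard curve slope is zero; cannot invert")
    conc = (fluorescence - curve.intercept) / curve.slope
    extrapolated = not (curve.conc_min <= conc <= curve.conc_max)
    return conc, extrapolated


def _decay(c: np.ndarray, y0: float, plateau: float, k: float) -> np.ndarray:
    return plateau + (y0 - plateau) * np.exp(-k * c)


def fit_one_phase_decay(
    points: Sequence[tuple[float, float]],
    k_grid: Sequence[float] | None = None,
) -> DecayFit:
    """Fit Y(c) = plateau + (y0 - plateau) exp(-k c), k >= 0, plateau >= 0.

    Multi-start: k initialised over a log-spaced grid spanning the dose
    range, y0 from the low-dose activity and plateau from the high-dose
    activity; the best converged start by residual sum of squares wins.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 4:
        raise ValueError("need at least four (concentration, activity) points")
    conc, y = pts[:, 0], pts[:, 1]
    if np.unique(conc).size < 3:
        raise ValueError("need at least three distinct concentrations")

    order = np.argsort(conc)
    y0_init = float(y[order[0]])
    plateau_init = max(float(y[order[-1]]), 0.0)
    span = float(conc.max() - conc.min())
    if k_grid is None:
        # Decay scales from ~1/(100*range) to ~10/range of the dose axis.
        k_grid = np.geomspace(1e-2 / max(span, 1e-12), 10.0 / max(span, 1e-12), 7)

    lower = [-np.inf, 0.0, 0.0]
    upper = [np.inf, np.inf, np.inf]
    best: tuple[float, np.ndarray] | None = None
    for k0 in k_grid:
        p0 = [y0_init, plateau_init, float(k0)]
        try:
            popt, _ = optimize.curve_fit(
                _decay, conc, y, p0=p0, bounds=(lower, upper), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        ss = float(np.sum((y - _decay(conc, *popt)) ** 2))
        if best is None or ss < best[0]:
            best = (ss, popt)
    if best is None:
        raise RuntimeError("one-phase decay fit failed to converge from any start")
    _, (y0, plateau, k) = best
    fit = DecayFit(y0=float(y0), plateau=float(plateau), k=float(k), r2=0.0)
    r2 = _r2(y, np.asarray(fit.predict(conc), dtype=float))
    return DecayFit(y0=fit.y0, plateau=fit.plateau, k=fit.k, r2=r2)
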