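"""In-vitro ACE-inhibition assay mathematics.

The assay quantifies hippuric acid (HA) released from the substrate HHL.
A linear calibration maps chromatographic response to HA concentration;
inhibition is ``100 x (A - B) / A`` where ``A`` and ``B`` are the HA
concentrations without and with inhibitor.  The dose-response is a
two-parameter logistic in log concentration with the floor fixed at 0% and
the ceiling at 100% (the inhibition definition bounds the response)::

    inhibition(c) = 100 / (1 + (IC50 / c) ** h)

IC50 is fitted by least squares on ``log10 IC50`` (symmetric error
structure); ``pIC50 = -log10(IC50 [M])``.  Replicates are fitted as
individual points, never pre-averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import optimize, stats


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line: response = slope * concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def predict(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept

    def inverse(self, response: float) -> float:
        """Concentration that would produce ``response`` (inverse prediction)."""
        if self.slope == 0:
            raise ZeroDivisionError("calibration slope is zero")
        return (response - self.intercept) / self.slope


def fit_calibration(standards: Sequence[Tuple[float, float]]) -> CalibrationCurve:
    """Fit the HA calibration line from (concentration, response) standards."""
    if len(standards) < 3:
        raise ValueError("calibration requires at least 3 standards")
    conc = np.asarray([s[0] for s in standards], dtype=float)
    resp = np.asarray([s[1] for s in standards], dtype=float)
    if np.allclose(conc, conc[0]):
        raise ValueError("calibration requires distinct concentrations")
    fit = stats.linregress(conc, resp)
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=len(standards),
    )


def inhibition_percent(A: float, B: float) -> float:
    """ACE inhibition %, ``100 x (A - B) / A``.

    ``A``: HA concentration of the uninhibited reaction; ``B``: with
    peptide.  A value below 0 (B > A) is reported, not clamped.
    """
    if A <= 0:
        raise ValueError("uninhibited HA concentration A must be positive")
    if B < 0:
        raise ValueError("HA concentration B cannot be negative")
    return 100.0 * (A - B) / A


def pic50(ic50: float) -> float:
    """-log10 of the molar IC50."""
    if ic50 <= 0:
        raise ValueError("IC50 must be positive")
    return -math.log10(ic50)


def logistic_inhibition(conc, ic50: float, hill: float = 1.0):
    """Model curve: 100 / (1 + (IC50/c)^h)."""
    conc = np.asarray(conc, dtype=float)
    return 100.0 / (1.0 + (ic50 / conc) ** hill)


@dataclass(frozen=True)
class DoseResponseFit:
    ic50: float
    hill: float
    pic50: float
    rmse: float
    n_points: int
    converged: bool


def _initial_log_ic50(log_c: np.ndarray, inh: np.ndarray) -> float:
    """Log-linear interpolation of the 50% crossing, used as initializer."""
    order = np.argsort(log_c)
    lc, y = log_c[order], inh[order]
    below = np.where(y < 50.0)[0]
    above = np.where(y > 50.0)[0]
    exact = np.where(y == 50.0)[0]
    if exact.size:
        return float(lc[exact[0]])
    i = below[-1]
    j = above[above > i][0] if (above > i).any() else above[0]
    return float(lc[i] + (50.0 - y[i]) * (lc[j] - lc[i]) / (y[j] - y[i]))


def fit_ic50(points: Sequence[Tuple[float, float]]) -> DoseResponseFit:
    """Fit IC50 and Hill slope from (molar concentration, inhibition %) points.

    Requires at least 4 points with inhibition both below and above 50%
    (otherwise the 50% crossing is extrapolation and the fit is refused
    with advice to widen the concentration range).
    """
    if len(points) < 4:
        raise ValueError("IC50 fitting requires at least 4 dose-response points")
    conc = np.asarray([p[0] for p in points], dtype=float)
    inh = np.asarray([p[1] for p in points], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if not (np.any(inh < 50.0) and np.any(inh > 50.0)):
        raise ValueError(
            "dose-response points do not bracket 50% inhibition; extend the "
            "concentration range below and above the IC50"
        )
    log_c = np.log10(conc)
    x0 = np.array([_initial_log_ic50(log_c, inh), 1.0])

    def residuals(params):
        log_ic50, hill = params
        return 100.0 / (1.0 + 10.0 ** (hill * (log_ic50 - log_c))) - inh

    sol = optimize.least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    log_ic50, hill = sol.x
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    ic50 = float(10.0**log_ic50)
    return DoseResponseFit(
        ic50=ic50,
        hill=float(hill),
        pic50=pic50(ic50),
        rmse=rmse,
        n_points=len(points),
        converged=bool(sol.success),
    )
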