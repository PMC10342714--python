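"""Quantitation: peak areas, internal-standard PARs, calibration, validation.

Quantities follow standard LC-MS/MS practice.  The response is the peak
area ratio (PAR) of the analyte's quantitation ion to the internal
standard; an unweighted linear calibration maps PAR to concentration;
LOD and LOQ come from the standard-error-of-response-and-slope approach
(3.3 and 10 times the y-intercept SE over the slope).  The accuracy and
precision of the deconvolution itself are assessed with a validation
plot: estimated vs expected composition, where the slope measures
accuracy (1 = perfect), and the residual standard error of the fit
(SE-Lin, fraction scale) measures precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .msdata import ValidationError

logger = logging.getLogger("ledams")

LOD_MULTIPLIER = 3.3
LOQ_MULTIPLIER = 10.0


def integrate_peak(times: np.ndarray, intensities: np.ndarray,
                   bounds: tuple[float, float]) -> float:
    """Trapezoidal area of a trace over [start, end] (intensity * min)."""
    times = np.asarray(times, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    lo, hi = bounds
    mask = (times >= lo) & (times <= hi)
    if mask.sum() < 2:
        raise ValidationError("need at least 2 trace points inside the bounds")
    return float(np.trapezoid(intensities[mask], times[mask]))


def compute_par(analyte_area: float, is_area: float) -> float:
    """Peak area ratio analyte / internal standard."""
    if is_area <= 0:
        raise ValidationError("internal-standard area must be positive")
    return float(analyte_area) / float(is_area)


@dataclass
class CalibrationCurve:
    """Linear PAR-vs-concentration calibration with LOD/LOQ."""

    analyte: str
    quant_ion: float
    levels: np.ndarray        # nominal ng/mL
    pars: np.ndarray
    slope: float
    y_intercept: float
    r_squared: float
    y_se: float               # SE of the y-intercept (response SE)
    lod: float | None         # ng/mL; None when the slope is unusable
    loq: float | None

    def predict(self, concentration: float) -> float:
        return self.slope * concentration + self.y_intercept

    def summary(self) -> dict:
        return {"analyte": self.analyte, "quant_ion": self.quant_ion,
                "slope": self.slope, "y_intercept": self.y_intercept,
                "r_squared": self.r_squared, "y_se": self.y_se,
                "lod": self.lod, "loq": self.loq}


def fit_calibration(levels: Sequence[float], pars: Sequence[float],
                    analyte: str = "", quant_ion: float = 0.0) -> CalibrationCurve:
    """Unweighted OLS calibration; LOD/LOQ from the intercept SE and slope."""
    levels = np.asarray(levels, dtype=float)
    pars = np.asarray(pars, dtype=float)
    if np.unique(levels).size < 3:
        raise ValidationError("calibration needs at least 3 distinct levels")
    if np.ptp(levels) == 0:
        raise ValidationError("zero variance in calibration levels")
    fit = stats.linregress(levels, pars)
    y_se = float(fit.intercept_stderr)
    if fit.slope > 0:
        lod = LOD_MULTIPLIER * y_se / fit.slope
        loq = LOQ_MULTIPLIER * y_se / fit.slope
    else:
        logger.warning("non-positive calibration slope; LOD/LOQ unavailable")
        lod = loq = None
    return CalibrationCurve(analyte=analyte, quant_ion=quant_ion,
                            levels=levels, pars=pars,
                            slope=float(fit.slope), y_intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue) ** 2, y_se=y_se,
                            lod=lod, loq=loq)


def quantify(par: float, curve: CalibrationCurve) -> float:
    """Back-calculate a concentration (ng/mL) from a PAR.

    Values below zero (PAR under the intercept) are clipped to 0 with a
    logged warning.
    """
    if curve.slope == 0:
        raise ValidationError("calibration slope is zero")
    conc = (par - curve.y_intercept) / curve.slope
    if conc < 0:
        logger.warning("back-calculated concentration %.3g ng/mL clipped to 0", conc)
        return 0.0
    return float(conc)


@dataclass
class ValidationPlot:
    """Estimated-vs-expected composition regression (fraction scale)."""

    expected: np.ndarray
    estimated: np.ndarray
    slope: float
    y_intercept: float
    r_squared: float
    se_lin: float             # residual standard error sqrt(SSR/(n-2))

    def summary(self) -> dict:
        return {"slope": self.slope, "y_intercept": self.y_intercept,
                "r_squared": self.r_squared, "se_lin": self.se_lin,
                "n": int(self.expected.size)}


def build_validation_plot(expected: Sequence[float], estimated: Sequence[float]) -> ValidationPlot:
    """Regress deconvolution estimates on the known compositions."""
    expected = np.asarray(expected, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if expected.size < 3 or expected.size != estimated.size:
        raise ValidationError("validation plot needs >=3 paired points")
    fit = stats.linregress(expected, estimated)
    resid = estimated - (fit.slope * expected + fit.intercept)
    se_lin = float(np.sqrt(np.sum(resid ** 2) / (expected.size - 2)))
    return ValidationPlot(expected=expected, estimated=estimated,
                          slope=float(fit.slope), y_intercept=float(fit.intercept),
                          r_squared=float(fit.rvalue) ** 2, se_lin=se_lin)


def run_validation_study(table, compositions: Sequence[float] = (0.9, 0.75, 0.5, 0.25, 0.1),
                         n_replicates: int = 6, noise_sd: float = 0.01,
                         seed: int | None = None) -> dict[str, ValidationPlot]:
    """Simulate the mixture-panel validation of the deconvolution.

    Each of the five standard mixtures is measured ``n_replicates`` times
    with additive Gaussian ratio noise; each mixture's composition is
    estimated as the mean deconvolved fraction over its replicates, and
    the per-mixture estimates are regressed on the expected values.  One
    validation plot per isomer is returned.
    """
    from . import synthgen
    from .leda import solve_mixture

    rng = np.random.default_rng(seed)
    expected = {name: [] for name in table.isomers}
    estimated = {name: [] for name in table.isomers}
    for frac_a in compositions:
        fractions = np.array([frac_a, 1.0 - frac_a])
        reps = synthgen.gen_mixture_ratios(table, fractions, noise_sd=noise_sd,
                                           n_replicates=n_replicates,
                                           seed=int(rng.integers(2 ** 31)))
        per_rep = np.array([solve_mixture(table, v).fractions for v in reps])
        mean_f = per_rep.mean(axis=0)
        for x, name in enumerate(table.isomers):
            expected[name].append(float(fractions[x]))
            estimated[name].append(float(mean_f[x]))
    return {name: build_validation_plot(expected[name], estimated[name])
            for name in table.isomers}


def validation_table(plots: dict[str, ValidationPlot]) -> pd.DataFrame:
    """One-row-per-isomer summary of validation plots."""
    rows = [{"isomer": name, **plot.summary()} for name, plot in plots.items()]
    return pd.DataFrame(rows)
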