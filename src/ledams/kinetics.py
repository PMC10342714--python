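"""First-order plasma-stability kinetics.

When the substrate concentration is far below the Michaelis constant of
the plasma esterases, ester hydrolysis follows first-order kinetics:
ln C(t) is linear in the incubation time, its slope is the degradation
rate constant k (ln(uM)/min), and the half-life is t1/2 = ln(0.5)/k.
Rates smaller in magnitude than 0.006 ln(uM)/min cannot be resolved over
a 120-minute incubation, so such compounds — and any computed half-life
beyond the last sampling time — are reported as ">120" min.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .msdata import ValidationError

logger = logging.getLogger("ledams")

#: |k| below this (ln(uM)/min) is unresolvable over the 120-min incubation
STABLE_RATE_THRESHOLD = 0.006

#: longest incubation time (min); half-lives beyond it are censored
MAX_REPORTED_HALF_LIFE = 120.0

STABLE_LABEL = ">120"


@dataclass
class DegradationSeries:
    """Replicate concentrations of one compound over the incubation schedule."""

    compound: str
    times_min: np.ndarray
    replicates: np.ndarray
    concentrations_um: np.ndarray
    c0_nominal_um: float = 1.0

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.replicates = np.asarray(self.replicates)
        self.concentrations_um = np.asarray(self.concentrations_um, dtype=float)
        if not (self.times_min.shape == self.replicates.shape == self.concentrations_um.shape):
            raise ValidationError("times, replicates and concentrations must align")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"compound": self.compound, "time_min": self.times_min,
                      "replicate": self.replicates,
                      "conc_um": self.concentrations_um}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DegradationSeries":
        frame = pd.read_csv(path)
        return cls(compound=str(frame["compound"].iloc[0]),
                   times_min=frame["time_min"].to_numpy(dtype=float),
                   replicates=frame["replicate"].to_numpy(),
                   concentrations_um=frame["conc_um"].to_numpy(dtype=float))


@dataclass
class KineticsResult:
    """Fitted degradation rate and (possibly censored) half-life."""

    compound: str
    k: float                      # slope of ln C vs t, ln(uM)/min
    k_sd: float
    t_half: float | str           # minutes, or the literal ">120"
    t_half_sd: float | None       # delta-method SD when t_half is numeric
    r_squared: float
    n: int

    @property
    def is_stable(self) -> bool:
        return self.t_half == STABLE_LABEL

    def as_dict(self) -> dict:
        return {"compound": self.compound, "k": self.k, "k_sd": self.k_sd,
                "t_half": self.t_half, "t_half_sd": self.t_half_sd,
                "r_squared": self.r_squared, "n": self.n}


def half_life(k: float) -> float | str:
    """Half-life (min) from a first-order rate constant, with censoring.

    Rates with |k| below the resolvable threshold, and computed
    half-lives beyond the 120-min incubation window, report the bound
    ``">120"``.  A resolvable positive k (growth) has no half-life and
    returns NaN with a warning.
    """
    if math.isnan(k):
        raise ValidationError("rate constant is NaN")
    if abs(k) < STABLE_RATE_THRESHOLD:
        return STABLE_LABEL
    if k > 0:
        logger.warning("positive rate constant %.4g: growth, half-life undefined", k)
        return math.nan
    t = math.log(0.5) / k
    return STABLE_LABEL if t > MAX_REPORTED_HALF_LIFE else t


def fit_first_order(series: DegradationSeries) -> KineticsResult:
    """Pooled OLS of ln-concentration on incubation time.

    All replicates enter one regression with a free intercept (the
    half-life uses only the slope).  Non-positive concentrations cannot
    be log-transformed and are excluded with a warning.
    """
    mask = series.concentrations_um > 0
    if not mask.all():
        logger.warning("excluding %d non-positive concentration(s) of %s",
                       int((~mask).sum()), series.compound)
    t = series.times_min[mask]
    c = series.concentrations_um[mask]
    if np.unique(t).size < 3:
        raise ValidationError("need at least 3 distinct usable time points")
    fit = stats.linregress(t, np.log(c))
    k = float(fit.slope)
    k_sd = float(fit.stderr)
    t_half = half_life(k)
    if isinstance(t_half, float) and math.isfinite(t_half):
        t_half_sd = abs(math.log(0.5)) * k_sd / k ** 2
    else:
        t_half_sd = None
    return KineticsResult(compound=series.compound, k=k, k_sd=k_sd,
                          t_half=t_half, t_half_sd=t_half_sd,
                          r_squared=float(fit.rvalue) ** 2, n=int(t.size))


@dataclass
class StabilityPanelReport:
    """Per-compound kinetics plus the plasma-activity control check."""

    results: dict[str, KineticsResult]
    reference: KineticsResult | None
    reference_pass: bool | None

    def to_frame(self) -> pd.DataFrame:
        rows = [r.as_dict() for r in self.results.values()]
        if self.reference is not None:
            row = self.reference.as_dict()
            row["compound"] = f"{row['compound']} (reference)"
            rows.append(row)
        return pd.DataFrame(rows)


def analyze_stability_panel(batch: Mapping[str, DegradationSeries],
                            reference: DegradationSeries | None = None) -> StabilityPanelReport:
    """Fit every compound in a stability panel and check the plasma control.

    The reference compound (a known esterase substrate) validates the
    hydrolytic activity of the plasma pool: it must degrade with a
    half-life within the 120-min window, otherwise the whole batch is
    suspect and the check fails with a warning.
    """
    results = {name: fit_first_order(s) for name, s in batch.items()}
    ref_result = None
    ref_pass: bool | None = None
    if reference is None:
        logger.warning("no reference compound supplied; plasma activity unchecked")
    else:
        ref_result = fit_first_order(reference)
        ref_pass = (not ref_result.is_stable
                    and isinstance(ref_result.t_half, float)
                    and ref_result.t_half <= MAX_REPORTED_HALF_LIFE)
        if not ref_pass:
            logger.warning("plasma activity check FAILED: reference %s is stable",
                           reference.compound)
    return StabilityPanelReport(results=results, reference=ref_result,
                                reference_pass=ref_pass)
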