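"""Energy-resolved MS/MS (ERMS) breakdown-curve analysis.

In an ion trap the precursor is activated by applying an excitation
amplitude (ExA, a.u.) for a fixed excitation time (ExT, ms).  Ramping the
ExA and recording precursor and product-ion abundances yields three
curves that characterise the collision-induced dissociation (CID)
energetics:

* survival yield      SY  = 100 * prec / (prec + sum(products))
* product formation   PiF = 100 * sum(products) / (prec + sum(products))
* product yield       PiY = 100 * sum(products) / precursor_ion_max

``precursor_ion_max`` is the mean precursor abundance at low ExA, before
any fragmentation channel opens; unlike PiF, the PiY curve referenced to
it is sensitive to precursor ejection and low-mass cut-off losses and so
measures the true efficiency of the CID process.  Summary descriptors are
the 50%-survival amplitude (SY_ExA50) and the PiY maximum with its
amplitude (PiY_max, ExA_max).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msdata import ERMSDataset, ValidationError

logger = logging.getLogger("ledams")

#: a step counts as "pre-activation" while PiF is below this percentage
ACTIVATION_THRESHOLD_PCT = 1.0


def compute_sy(precursor_abundance: float, product_abundances) -> float:
    """Survival yield (%) of the precursor at one ramp step.

    Returns NaN when the total signal is zero (undefined point, dropped
    at curve level rather than raised).
    """
    prod = float(np.sum(product_abundances)) if np.ndim(product_abundances) else float(product_abundances)
    total = float(precursor_abundance) + prod
    if total <= 0:
        return float("nan")
    return 100.0 * float(precursor_abundance) / total


def compute_pif(precursor_abundance: float, product_abundances) -> float:
    """Product-ion formation (%) at one ramp step; complement of SY."""
    sy = compute_sy(precursor_abundance, product_abundances)
    return 100.0 - sy if np.isfinite(sy) else float("nan")


def estimate_precursor_max(dataset: ERMSDataset,
                           activation_threshold_pct: float = ACTIVATION_THRESHOLD_PCT) -> float:
    """Mean precursor abundance over the pre-activation steps.

    Steps qualify while their PiF is below ``activation_threshold_pct``;
    the average over them is the precursor signal available to the CID
    process (denominator of PiY).  If every step already fragments, the
    lowest-ExA step is used and a warning is logged.
    """
    if dataset.n_steps == 0:
        raise ValidationError("empty ERMS dataset")
    totals = dataset.product_total()
    pif = np.array([compute_pif(p, s) for p, s in zip(dataset.precursor, totals)])
    mask = np.isfinite(pif) & (pif < activation_threshold_pct)
    if not mask.any():
        logger.warning(
            "no pre-activation plateau below PiF %.3g%%; falling back to the "
            "lowest-ExA precursor abundance", activation_threshold_pct)
        return float(dataset.precursor[0])
    return float(dataset.precursor[mask].mean())


@dataclass(frozen=True)
class EnergyCurvePoint:
    exa: float
    sy_pct: float
    pif_pct: float
    piy_pct: float


@dataclass
class EnergyProfile:
    """SY/PiF/PiY curves of one ramp plus their summary descriptors."""

    ext_ms: float
    points: list[EnergyCurvePoint]
    precursor_ion_max: float
    sy_exa50: float | None
    piy_max_pct: float
    exa_max: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"exa": [p.exa for p in self.points],
             "sy_pct": [p.sy_pct for p in self.points],
             "pif_pct": [p.pif_pct for p in self.points],
             "piy_pct": [p.piy_pct for p in self.points]})

    def summary(self) -> dict:
        return {"ext_ms": self.ext_ms,
                "precursor_ion_max": self.precursor_ion_max,
                "sy_exa50": self.sy_exa50,
                "piy_max_pct": self.piy_max_pct,
                "exa_max": self.exa_max}


def interpolate_sy_crossing(exa: np.ndarray, sy: np.ndarray, level: float = 50.0) -> float | None:
    """ExA where the SY curve crosses ``level``, by linear interpolation.

    The first downward bracketing pair is used; ``None`` if the curve
    never crosses.
    """
    for i in range(len(exa) - 1):
        s0, s1 = sy[i], sy[i + 1]
        if not (np.isfinite(s0) and np.isfinite(s1)):
            continue
        if s0 >= level >= s1 and s0 != s1:
            frac = (s0 - level) / (s0 - s1)
            return float(exa[i] + frac * (exa[i + 1] - exa[i]))
        if s0 == level:
            return float(exa[i])
    return None


def build_energy_profile(dataset: ERMSDataset,
                         activation_threshold_pct: float = ACTIVATION_THRESHOLD_PCT) -> EnergyProfile:
    """Compute the full CID energetics profile of one ERMS ramp.

    Zero-total-signal steps are dropped from the curves.  SY_ExA50 is
    read off by linear interpolation between the bracketing grid points;
    ties in the PiY maximum resolve to the lowest ExA (minimal energy
    achieving maximal yield).
    """
    totals = dataset.product_total()
    pmax = estimate_precursor_max(dataset, activation_threshold_pct)
    points = []
    for exa, prec, tot in zip(dataset.exa, dataset.precursor, totals):
        sy = compute_sy(prec, tot)
        if not np.isfinite(sy):
            continue
        points.append(EnergyCurvePoint(exa=float(exa), sy_pct=sy, pif_pct=100.0 - sy,
                                       piy_pct=100.0 * tot / pmax))
    if not points:
        raise ValidationError("every ramp step has zero total signal")
    exa_arr = np.array([p.exa for p in points])
    sy_arr = np.array([p.sy_pct for p in points])
    piy_arr = np.array([p.piy_pct for p in points])
    sy_exa50 = interpolate_sy_crossing(exa_arr, sy_arr, 50.0)
    imax = int(np.argmax(piy_arr))  # argmax returns first = lowest ExA on ties
    return EnergyProfile(ext_ms=dataset.ext_ms, points=points, precursor_ion_max=pmax,
                         sy_exa50=sy_exa50, piy_max_pct=float(piy_arr[imax]),
                         exa_max=float(exa_arr[imax]))


@dataclass
class BreakdownCurveSet:
    """Per-ion yield curves, normalised to the pre-activation precursor."""

    exa: np.ndarray
    curves: dict[float, np.ndarray]  # ion m/z -> yield (%) on the shared grid
    precursor_ion_max: float

    def to_frame(self) -> pd.DataFrame:
        data = {"exa": self.exa}
        data.update({repr(mz): y for mz, y in self.curves.items()})
        return pd.DataFrame(data)


def build_breakdown_curves(dataset: ERMSDataset,
                           activation_threshold_pct: float = ACTIVATION_THRESHOLD_PCT) -> BreakdownCurveSet:
    """Yield-of-formation curve of each ion: abundance / precursor_ion_max * 100.

    The precursor's own decay curve is included under its m/z.
    """
    pmax = estimate_precursor_max(dataset, activation_threshold_pct)
    curves = {dataset.precursor_mz: 100.0 * dataset.precursor / pmax}
    for mz, arr in dataset.products.items():
        curves[mz] = 100.0 * arr / pmax
    return BreakdownCurveSet(exa=dataset.exa.copy(), curves=curves, precursor_ion_max=pmax)


def compare_sy_exa50_vs_ext(profiles: list[EnergyProfile]) -> pd.DataFrame:
    """Tabulate SY_ExA50 against excitation time across a profile family.

    As the excitation time grows the amplitude needed to fragment half of
    the precursor population drops along a roughly exponential trend; the
    successive differences quantify how quickly the curves converge.
    """
    if len(profiles) < 2:
        raise ValidationError("need at least two profiles at distinct ExT")
    exts = [p.ext_ms for p in profiles]
    if len(set(exts)) != len(exts):
        raise ValidationError("duplicate ExT values in profile family")
    order = np.argsort(exts)
    rows = [{"ext_ms": profiles[i].ext_ms, "sy_exa50": profiles[i].sy_exa50} for i in order]
    frame = pd.DataFrame(rows)
    frame["delta_sy_exa50"] = frame["sy_exa50"].diff()
    return frame
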