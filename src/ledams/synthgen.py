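"""Seeded synthetic-data generators for every workflow input.

Each generator is a pure function of its parameters and seed and emits
the ground truth it drew from alongside the data, so downstream modules
always have a recovery target.  Noise models: multiplicative lognormal
on raw abundances (detector noise), additive Gaussian on Pi/Ri ratios
(SD 0.01, the replicate SD observed on characteristic-ratio tables),
and lognormal with 5% CV on plasma concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .kinetics import DegradationSeries
from .leda import CharacteristicRatioTable, MeasuredRatioVector
from .msdata import (DEFAULT_SEGMENT_BOUNDS, ERMSDataset, EventChromatogram,
                     MSMSEventScan, ValidationError)


@dataclass
class ERMSSimParams:
    """Parameters of a synthetic excitation-amplitude ramp.

    The precursor survival follows a logistic decay in ExA centred at
    ``sy_midpoint`` with scale ``sy_width``; fragmentation channels open
    at ``sy_midpoint - 2 * sy_width``, below which the precursor sits at
    a flat plateau and no products form.  Of the precursor signal lost,
    ``ejection_loss_fraction`` vanishes undetected (precursor ejection /
    low-mass cut-off) and the rest is shared among the product channels
    by their branching fractions.
    """

    sy_midpoint: float = 30.0
    sy_width: float = 3.0
    ejection_loss_fraction: float = 0.0
    branching: dict[float, float] = field(default_factory=lambda: {
        221.0: 0.45, 366.0: 0.25, 279.0: 0.12, 384.0: 0.10, 392.0: 0.05, 253.0: 0.03})
    plateau_abundance: float = 1.0e6
    exa_grid: np.ndarray = field(default_factory=lambda: np.arange(0.0, 50.5, 1.0))
    ext_ms: float = 50.0
    precursor_mz: float = 604.0
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.exa_grid = np.asarray(self.exa_grid, dtype=float)
        if self.exa_grid.min() < 0 or self.exa_grid.max() > 50:
            raise ValidationError("exa grid must lie within the 0-50 a.u. ramp range")
        if any(b < 0 for b in self.branching.values()):
            raise ValidationError("branching fractions must be non-negative")
        if sum(self.branching.values()) > 1 + 1e-12:
            raise ValidationError("branching fractions must sum to at most 1")
        if not 0 <= self.ejection_loss_fraction < 1:
            raise ValidationError("ejection_loss_fraction must lie in [0, 1)")

    @property
    def onset_exa(self) -> float:
        return self.sy_midpoint - 2.0 * self.sy_width


def gen_erms(params: ERMSSimParams) -> tuple[ERMSDataset, dict]:
    """Simulate one ERMS ramp; returns (dataset, truth).

    Noise-free with no ejection loss, the survival yield equals the
    generating logistic over the active region and the interpolated
    SY_ExA50 recovers ``sy_midpoint``.
    """
    rng = np.random.default_rng(params.seed)
    exa = params.exa_grid
    survival = 1.0 / (1.0 + np.exp((exa - params.sy_midpoint) / params.sy_width))
    active = exa >= params.onset_exa
    precursor = np.where(active, params.plateau_abundance * survival, params.plateau_abundance)
    lost = np.where(active, params.plateau_abundance * (1.0 - survival), 0.0)
    detected = lost * (1.0 - params.ejection_loss_fraction)
    products = {mz: detected * frac for mz, frac in params.branching.items()}
    if params.noise_cv > 0:
        sigma = np.sqrt(np.log1p(params.noise_cv ** 2))
        def jitter(arr):
            return arr * np.exp(rng.normal(0.0, sigma, size=arr.shape) - sigma ** 2 / 2)
        precursor = jitter(precursor)
        products = {mz: jitter(arr) for mz, arr in products.items()}
    dataset = ERMSDataset(ext_ms=params.ext_ms, precursor_mz=params.precursor_mz,
                          exa=exa.copy(), precursor=precursor, products=products)
    truth = {"sy_midpoint": params.sy_midpoint, "sy_width": params.sy_width,
             "onset_exa": params.onset_exa, "plateau_abundance": params.plateau_abundance,
             "ejection_loss_fraction": params.ejection_loss_fraction,
             "branching": dict(params.branching)}
    return dataset, truth


def gen_erms_family(ext_values: Sequence[float] = (10.0, 25.0, 50.0, 100.0),
                    midpoint_a: float = 18.0, midpoint_b: float = 18.0,
                    midpoint_c: float = 0.03, seed: int = 0,
                    **overrides) -> list[tuple[ERMSDataset, dict]]:
    """A family of ramps at several excitation times.

    The half-survival amplitude decays exponentially with the excitation
    time, sy_exa50(ExT) = a + b * exp(-c * ExT): longer activation needs
    less amplitude, with diminishing differences at long ExT.
    """
    out = []
    for i, ext in enumerate(ext_values):
        mid = midpoint_a + midpoint_b * np.exp(-midpoint_c * ext)
        params = ERMSSimParams(sy_midpoint=float(mid), ext_ms=float(ext),
                               seed=seed + i, **overrides)
        out.append(gen_erms(params))
    return out


def gen_mixture_ratios(table: CharacteristicRatioTable, fractions: Sequence[float],
                       noise_sd: float = 0.01, n_replicates: int = 1,
                       seed: int | None = None,
                       ri_abundance: float = 1.0e5) -> list[MeasuredRatioVector]:
    """Noisy measured ratio vectors for a known mixture composition.

    Each replicate is M @ f plus independent Gaussian noise of SD
    ``noise_sd`` per ion, truncated at zero (abundance ratios cannot be
    negative).
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions < 0):
        raise ValidationError("mixture fractions must be non-negative")
    if fractions.size != table.n_isomers:
        raise ValidationError("fraction vector length must match the table")
    rng = np.random.default_rng(seed)
    clean = table.ratios @ fractions
    out = []
    for _ in range(n_replicates):
        noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean.copy()
        out.append(MeasuredRatioVector(pi_mz=table.pi_mz.copy(),
                                       ratios=np.clip(noisy, 0.0, None),
                                       ri_abundance=ri_abundance))
    return out


@dataclass
class ChromSimParams:
    """Parameters of a synthetic two-segment event chromatogram.

    Gaussian elution envelopes; the internal standard elutes in segment
    1, the isomers co-elute (identical retention time by default — the
    worst case for recognition) in segment 2, where Ri and Pis events
    alternate with one scan every ``event_period_min``.
    """

    table: CharacteristicRatioTable
    isomer_fractions: Sequence[float] = (0.5, 0.5)
    rt_is_min: float = 1.6
    rt_isomers_min: Sequence[float] | float = 4.6
    peak_sigma_min: float = 0.2
    is_mz: float = 455.0
    is_height: float = 5.0e5
    analyte_height: float = 1.0e6
    event_period_min: float = 0.005   # 0.3 s per event, 0.6 s per Ri/Pis pair
    segment_bounds: tuple = DEFAULT_SEGMENT_BOUNDS
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        (s1lo, s1hi), (s2lo, s2hi) = self.segment_bounds
        if not s1lo <= self.rt_is_min < s1hi:
            raise ValidationError("IS retention time must lie in segment 1")
        rts = np.atleast_1d(np.asarray(self.rt_isomers_min, dtype=float))
        if rts.size == 1:
            rts = np.repeat(rts, self.table.n_isomers)
        if rts.size != self.table.n_isomers:
            raise ValidationError("one retention time per isomer (or a shared scalar)")
        if np.any((rts < s2lo) | (rts >= s2hi)):
            raise ValidationError("isomer retention times must lie in segment 2")
        self.rt_isomers_min = rts
        self.isomer_fractions = np.asarray(self.isomer_fractions, dtype=float)
        if np.any(self.isomer_fractions < 0):
            raise ValidationError("isomer fractions must be non-negative")


def _gauss(t: np.ndarray, rt: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - rt) / sigma) ** 2)


def gen_chromatogram(params: ChromSimParams) -> tuple[EventChromatogram, dict]:
    """Simulate an alternating-event chromatogram; returns (chrom, truth).

    Segment-1 scans carry the IS envelope; in segment 2 the Ri event
    records the summed isomer envelopes of the precursor while the Pis
    event records each product ion as the fraction-weighted combination
    of the isomers' characteristic ratios times their envelopes.
    """
    rng = np.random.default_rng(params.seed)
    table = params.table
    (s1lo, s1hi), (s2lo, s2hi) = params.segment_bounds
    sigma_noise = np.sqrt(np.log1p(params.noise_cv ** 2)) if params.noise_cv > 0 else 0.0

    def jitter(x: float) -> float:
        if sigma_noise == 0:
            return x
        return float(x * np.exp(rng.normal(0.0, sigma_noise) - sigma_noise ** 2 / 2))

    scans: list[MSMSEventScan] = []
    t = s1lo
    while t < s1hi - 1e-12:
        ab = params.is_height * _gauss(np.array([t]), params.rt_is_min, params.peak_sigma_min)[0]
        scans.append(MSMSEventScan(time_min=round(t, 6), segment=1, event="IS",
                                   abundances={params.is_mz: jitter(ab)}))
        t += params.event_period_min

    events = ("Ri", "Pis")
    i = 0
    t = s2lo
    while t < s2hi - 1e-12:
        env = np.array([params.analyte_height * f *
                        _gauss(np.array([t]), rt, params.peak_sigma_min)[0]
                        for f, rt in zip(params.isomer_fractions, params.rt_isomers_min)])
        event = events[i % 2]
        if event == "Ri":
            ab = {table.ri_mz: jitter(float(env.sum()))}
        else:
            ab = {float(mz): jitter(float(table.ratios[j] @ env))
                  for j, mz in enumerate(table.pi_mz)}
        scans.append(MSMSEventScan(time_min=round(t, 6), segment=2, event=event,
                                   abundances=ab))
        i += 1
        t += params.event_period_min

    chrom = EventChromatogram(scans=scans, segment_bounds=params.segment_bounds)
    fr = params.isomer_fractions
    truth = {"isomer_fractions": dict(zip(table.isomers, map(float, fr))),
             "rt_is_min": params.rt_is_min,
             "rt_isomers_min": list(map(float, params.rt_isomers_min)),
             "peak_sigma_min": params.peak_sigma_min,
             "is_height": params.is_height,
             "analyte_height": params.analyte_height,
             "ri_peak_area": float(params.analyte_height * fr.sum()
                                   * params.peak_sigma_min * np.sqrt(2 * np.pi))}
    return chrom, truth


def gen_calibration_set(slope_true: float,
                        levels: Sequence[float] = (5.0, 10.0, 25.0, 50.0, 100.0),
                        noise_cv: float = 0.03, seed: int | None = None,
                        ) -> tuple[np.ndarray, np.ndarray, dict]:
    """(levels, PARs, truth) for a proportional calibration with CV noise."""
    if slope_true <= 0:
        raise ValidationError("true slope must be positive")
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValidationError("no calibration levels supplied")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_cv, size=levels.shape) if noise_cv > 0 else np.zeros_like(levels)
    pars = slope_true * levels * (1.0 + eps)
    return levels, pars, {"slope_true": slope_true, "noise_cv": noise_cv}


def gen_degradation_panel(k_true: Mapping[str, float], c0_um: float = 1.0,
                          times_min: Sequence[float] = (0.0, 30.0, 60.0, 120.0),
                          replicates: int = 3, cv: float = 0.05,
                          seed: int | None = None) -> dict[str, DegradationSeries]:
    """Triplicate first-order decay series per compound, lognormal CV noise.

    The noise multiplier has median 1 (exp of a zero-mean normal), so
    the ln-concentration regression is unbiased for the true rate.
    """
    if c0_um <= 0:
        raise ValidationError("initial concentration must be positive")
    rng = np.random.default_rng(seed)
    times_min = np.asarray(times_min, dtype=float)
    sigma = np.sqrt(np.log1p(cv ** 2))
    panel = {}
    for name, k in k_true.items():
        t = np.repeat(times_min, replicates)
        rep = np.tile(np.arange(1, replicates + 1), times_min.size)
        noise = np.exp(rng.normal(0.0, sigma, size=t.shape)) if cv > 0 else np.ones_like(t)
        conc = c0_um * np.exp(k * t) * noise
        panel[name] = DegradationSeries(compound=name, times_min=t, replicates=rep,
                                        concentrations_um=conc, c0_nominal_um=c0_um)
    return panel
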