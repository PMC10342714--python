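"""LEDA: linear-equation deconvolution of co-eluting isomer MS/MS signals.

Isomers that co-elute and share a precursor cannot be told apart
chromatographically, but their product-ion (Pi) spectra differ.  Each Pi
abundance, expressed relative to a reference ion (Ri) shared by the
isomers — here the unfragmented precursor acquired in a dedicated
low-energy MS/MS event — is a linear mixture of the isomers'
characteristic ratios:

    (Pi/Ri)_measured = sum_x (Pi/Ri)_x * f_x

with f_x the fractional abundance of isomer x.  Collecting one equation
per retained product ion gives an (n_ions x n_isomers) system that is
deliberately overdetermined (six equations for two isomers with the
default >=5% inclusion rule) and is solved by least squares.  The
fractions are *not* constrained to sum to one, so an unknown co-eluting
contributor shows up as a deficit rather than being silently absorbed.

The solver is applied either to peak-integrated areas (one composition
per peak) or scan-by-scan, which splits the unresolved Ri profile into
one reconstructed chromatogram per isomer.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .msdata import EventChromatogram, ValidationError, mz_match, MZ_TOLERANCE

logger = logging.getLogger("ledams")

INCLUSION_THRESHOLD_PCT = 5.0


class DegenerateSystemError(ValidationError):
    """The ratio matrix cannot distinguish the isomers (rank deficient)."""


@dataclass
class CharacteristicRatioTable:
    """Characteristic Pi/Ri ratios of pure isomers (the LEDA matrix).

    ``ratios[i, x]`` is the mean Pi/Ri ratio of product ion ``pi_mz[i]``
    for isomer ``isomers[x]``; ``sds`` holds the replicate SDs.  Rows are
    the linear equations of the deconvolution system, so there must be at
    least as many ions as isomers.
    """

    isomers: tuple[str, ...]
    pi_mz: np.ndarray
    ri_mz: float
    ratios: np.ndarray  # (n_ions, n_isomers)
    sds: np.ndarray     # same shape

    def __post_init__(self) -> None:
        self.pi_mz = np.asarray(self.pi_mz, dtype=float)
        self.ratios = np.atleast_2d(np.asarray(self.ratios, dtype=float))
        self.sds = np.atleast_2d(np.asarray(self.sds, dtype=float))
        n_ions, n_iso = self.ratios.shape
        if n_iso != len(self.isomers) or self.pi_mz.size != n_ions:
            raise ValidationError("ratio matrix shape does not match ion/isomer labels")
        if self.sds.shape != self.ratios.shape:
            raise ValidationError("SD matrix must match the ratio matrix shape")
        if n_ions < n_iso:
            raise ValidationError("need at least as many product ions as isomers")
        if np.any(self.ratios < 0) or np.any(self.sds < 0):
            raise ValidationError("ratios and SDs must be non-negative")

    @property
    def n_ions(self) -> int:
        return int(self.pi_mz.size)

    @property
    def n_isomers(self) -> int:
        return len(self.isomers)

    def column(self, isomer: str) -> np.ndarray:
        return self.ratios[:, self.isomers.index(isomer)].copy()

    def ion_labels(self) -> list[str]:
        return [f"{mz:g}/{self.ri_mz:g}" for mz in self.pi_mz]

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for i, mz in enumerate(self.pi_mz):
            for x, name in enumerate(self.isomers):
                rows.append({"isomer": name, "pi_mz": mz, "ri_mz": self.ri_mz,
                             "mean_ratio": self.ratios[i, x], "sd": self.sds[i, x]})
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CharacteristicRatioTable":
        frame = pd.read_csv(path)
        isomers = tuple(dict.fromkeys(frame["isomer"]))
        # preserve the file's row order for ions, not sorted order
        pi_mz = frame["pi_mz"].drop_duplicates().to_numpy(dtype=float)
        ri_mz = float(frame["ri_mz"].iloc[0])
        ratios = np.zeros((pi_mz.size, len(isomers)))
        sds = np.zeros_like(ratios)
        for x, name in enumerate(isomers):
            sub = frame[frame["isomer"] == name].set_index("pi_mz")
            ratios[:, x] = sub.loc[pi_mz, "mean_ratio"].to_numpy(dtype=float)
            sds[:, x] = sub.loc[pi_mz, "sd"].to_numpy(dtype=float)
        return cls(isomers=isomers, pi_mz=pi_mz, ri_mz=ri_mz, ratios=ratios, sds=sds)


@dataclass
class MeasuredRatioVector:
    """Measured Pi/Ri ratios of one sample (or one scan)."""

    pi_mz: np.ndarray
    ratios: np.ndarray
    ri_abundance: float

    def __post_init__(self) -> None:
        self.pi_mz = np.asarray(self.pi_mz, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.pi_mz.shape != self.ratios.shape:
            raise ValidationError("pi_mz and ratios must have the same length")
        if np.any(self.ratios < 0):
            raise ValidationError("measured ratios must be non-negative")


@dataclass
class DeconvolutionResult:
    """Per-isomer assigned fractions ("ratio purity") and fit diagnostics."""

    isomers: tuple[str, ...]
    fractions: np.ndarray
    residual_ss: float
    measured: np.ndarray
    fitted: np.ndarray
    solver: str

    @property
    def percent(self) -> np.ndarray:
        return 100.0 * self.fractions

    def fraction_of(self, isomer: str) -> float:
        return float(self.fractions[self.isomers.index(isomer)])

    def as_dict(self) -> dict:
        return {"fractions": dict(zip(self.isomers, map(float, self.fractions))),
                "percent": dict(zip(self.isomers, map(float, self.percent))),
                "residual_ss": self.residual_ss,
                "solver": self.solver}


def build_ratio_table(pure_runs: Mapping[str, Sequence[tuple[float, Mapping[float, float]]]],
                      ri_mz: float,
                      inclusion_threshold_pct: float = INCLUSION_THRESHOLD_PCT) -> CharacteristicRatioTable:
    """Assemble the LEDA matrix from replicate pure-isomer acquisitions.

    Parameters
    ----------
    pure_runs : per-isomer sequence of replicates, each a pair of the Ri
        abundance and a mapping of product-ion m/z to abundance.
    ri_mz : m/z of the reference ion (the re-isolated precursor).
    inclusion_threshold_pct : a product ion enters the matrix iff its
        relative abundance (percent of the most abundant Pi in that
        isomer's mean spectrum) reaches this threshold in at least one
        isomer.  Low-abundance channels carry noise, not information.
    """
    isomers = tuple(pure_runs)
    if not isomers:
        raise ValidationError("no pure-isomer runs supplied")
    all_mz: list[float] = []
    for reps in pure_runs.values():
        for ri, pis in reps:
            if ri <= 0:
                raise ValidationError("Ri abundance must be positive in every replicate")
            for mz in pis:
                if not any(mz_match(mz, m) for m in all_mz):
                    all_mz.append(float(mz))
    all_mz.sort()

    def mean_spectrum(reps):
        spec = np.zeros(len(all_mz))
        for ri, pis in reps:
            for mz, a in pis.items():
                idx = next(i for i, m in enumerate(all_mz) if mz_match(mz, m))
                spec[idx] += a / len(reps)
        return spec

    # relative abundance screen (percent of base peak, per isomer)
    keep = np.zeros(len(all_mz), dtype=bool)
    for reps in pure_runs.values():
        spec = mean_spectrum(reps)
        base = spec.max()
        if base > 0:
            keep |= (100.0 * spec / base) >= inclusion_threshold_pct
    if not keep.any():
        raise ValidationError(
            f"no product ion reaches {inclusion_threshold_pct}% relative abundance")
    kept_mz = [mz for mz, k in zip(all_mz, keep) if k]

    ratios = np.zeros((len(kept_mz), len(isomers)))
    sds = np.zeros_like(ratios)
    for x, name in enumerate(isomers):
        reps = pure_runs[name]
        per_rep = np.zeros((len(reps), len(kept_mz)))
        for r, (ri, pis) in enumerate(reps):
            for i, mz in enumerate(kept_mz):
                per_rep[r, i] = sum(a for m, a in pis.items() if mz_match(m, mz)) / ri
        ratios[:, x] = per_rep.mean(axis=0)
        sds[:, x] = per_rep.std(axis=0, ddof=1) if len(reps) > 1 else 0.0

    # canonical ion order: descending mean ratio of the first isomer, ties by m/z
    order = sorted(range(len(kept_mz)), key=lambda i: (-ratios[i, 0], kept_mz[i]))
    return CharacteristicRatioTable(
        isomers=isomers,
        pi_mz=np.array([kept_mz[i] for i in order]),
        ri_mz=float(ri_mz),
        ratios=ratios[order],
        sds=sds[order])


def measure_ratios(ri_abundance: float,
                   pi_abundances: Mapping[float, float]) -> MeasuredRatioVector | None:
    """Elementwise Pi/Ri ratios; ``None`` flags an undefined scan (Ri <= 0)."""
    if ri_abundance <= 0:
        return None
    mzs = np.array(sorted(pi_abundances), dtype=float)
    ratios = np.array([pi_abundances[m] / ri_abundance for m in sorted(pi_abundances)])
    return MeasuredRatioVector(pi_mz=mzs, ratios=ratios, ri_abundance=float(ri_abundance))


def align_to_table(table: CharacteristicRatioTable, measured: MeasuredRatioVector,
                   tol: float = MZ_TOLERANCE) -> np.ndarray:
    """Reindex a measured vector into the table's canonical ion order."""
    out = np.zeros(table.n_ions)
    for i, mz in enumerate(table.pi_mz):
        hits = [r for m, r in zip(measured.pi_mz, measured.ratios) if mz_match(m, mz, tol)]
        if not hits:
            raise ValidationError(f"measured vector lacks product ion {mz:g}")
        out[i] = sum(hits)
    return out


def _check_rank(table: CharacteristicRatioTable) -> None:
    if np.linalg.matrix_rank(table.ratios) < table.n_isomers:
        # name the offending columns for the error message
        pairs = []
        for a, b in itertools.combinations(range(table.n_isomers), 2):
            ca, cb = table.ratios[:, a], table.ratios[:, b]
            if np.linalg.matrix_rank(np.column_stack([ca, cb])) < 2:
                pairs.append(f"{table.isomers[a]}~{table.isomers[b]}")
        detail = ", ".join(pairs) if pairs else "columns are linearly dependent"
        raise DegenerateSystemError(f"indistinguishable isomers: {detail}")


def solve_mixture(table: CharacteristicRatioTable,
                  measured: MeasuredRatioVector | np.ndarray,
                  solver: str = "nonnegative") -> DeconvolutionResult:
    """Solve the overdetermined ratio system for the isomer fractions.

    ``solver="nonnegative"`` (default) uses non-negative least squares,
    which cannot report unphysical negative percentages;
    ``solver="unconstrained"`` gives plain linear-regression semantics.
    The fractions are not forced to sum to one — a shortfall or excess is
    diagnostic of an unaccounted co-eluting contributor.
    """
    _check_rank(table)
    if isinstance(measured, MeasuredRatioVector):
        r = align_to_table(table, measured)
    else:
        r = np.asarray(measured, dtype=float)
        if r.shape != (table.n_ions,):
            raise ValidationError("measured vector length does not match the table")
    M = table.ratios
    if solver == "nonnegative":
        f, _ = nnls(M, r)
    elif solver == "unconstrained":
        f, *_ = np.linalg.lstsq(M, r, rcond=None)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    fitted = M @ f
    rss = float(np.sum((fitted - r) ** 2))
    return DeconvolutionResult(isomers=table.isomers, fractions=f, residual_ss=rss,
                               measured=r, fitted=fitted, solver=solver)


def brute_force_mixture(table: CharacteristicRatioTable,
                        measured: MeasuredRatioVector | np.ndarray,
                        grid_step: float = 0.005,
                        max_fraction: float = 1.2) -> DeconvolutionResult:
    """Exhaustive grid-search reference solver (2-3 isomers only).

    Minimises the residual sum of squares over fraction tuples on a
    regular grid in [0, max_fraction]^n; intended as an independent check
    of :func:`solve_mixture`, not for production use.
    """
    n = table.n_isomers
    if n > 3:
        raise ValidationError("brute force supported for at most 3 isomers")
    if isinstance(measured, MeasuredRatioVector):
        r = align_to_table(table, measured)
    else:
        r = np.asarray(measured, dtype=float)
    M = table.ratios
    axis = np.arange(0.0, max_fraction + grid_step / 2, grid_step)
    grids = np.meshgrid(*([axis] * n), indexing="ij")
    F = np.stack([g.ravel() for g in grids])            # (n, n_grid)
    # ||Mf - r||^2 = f'M'Mf - 2 f'M'r + r'r, vectorised over the grid
    G = M.T @ M
    obj = np.einsum("ik,ij,jk->k", F, G, F) - 2.0 * (M.T @ r) @ F + r @ r
    best = int(np.argmin(obj))
    f = F[:, best]
    fitted = M @ f
    return DeconvolutionResult(isomers=table.isomers, fractions=f.copy(),
                               residual_ss=float(max(obj[best], 0.0)),
                               measured=r, fitted=fitted, solver="brute_force")


# ---------------------------------------------------------------------------
# Chromatogram-level deconvolution
# ---------------------------------------------------------------------------

@dataclass
class PeakDeconvolution:
    """Peak-integrated deconvolution: Ri area split between the isomers."""

    ri_area: float
    assigned_areas: dict[str, float]
    result: DeconvolutionResult


def deconvolve_peak(chrom: EventChromatogram, table: CharacteristicRatioTable,
                    peak_bounds: tuple[float, float],
                    solver: str = "nonnegative") -> PeakDeconvolution:
    """Deconvolve one chromatographic peak from integrated trace areas.

    Each Pi trace (from the Pis-event scans) and the Ri trace are
    integrated over ``peak_bounds`` by the trapezoid rule; the area
    ratios form one measured vector, and the Ri area is then distributed
    by the renormalised fractions so that the assigned areas conserve the
    Ri signal.
    """
    lo, hi = peak_bounds
    seg_lo, seg_hi = chrom.segment_bounds[1]
    if not (seg_lo <= lo < hi <= seg_hi):
        raise ValidationError("peak bounds must lie within time segment 2")

    def _integrate(event: str, mz: float) -> float:
        t, a = chrom.trace(event, mz)
        mask = (t >= lo) & (t <= hi)
        if mask.sum() < 2:
            raise ValidationError(f"fewer than 2 {event} scans inside the peak bounds")
        return float(np.trapezoid(a[mask], t[mask]))

    ri_area = _integrate("Ri", table.ri_mz)
    if ri_area <= 0:
        raise ValidationError("Ri area is not positive inside the peak bounds")
    pi_areas = {float(mz): _integrate("Pis", mz) for mz in table.pi_mz}
    measured = measure_ratios(ri_area, pi_areas)
    result = solve_mixture(table, measured, solver=solver)
    fsum = float(result.fractions.sum())
    if fsum <= 0:
        logger.warning("all fractions zero; no Ri area assigned")
        assigned = {name: 0.0 for name in table.isomers}
    else:
        assigned = {name: ri_area * float(f) / fsum
                    for name, f in zip(table.isomers, result.fractions)}
    return PeakDeconvolution(ri_area=ri_area, assigned_areas=assigned, result=result)


@dataclass
class ScanwiseProfiles:
    """Reconstructed per-isomer Ri chromatograms from scan-by-scan LEDA.

    ``profiles[name][j]`` is the share of the interpolated Ri abundance
    assigned to that isomer at ``times[j]``; undefined scans are NaN.
    """

    times: np.ndarray
    ri_interpolated: np.ndarray
    profiles: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        data = {"time_min": self.times, "ri_interpolated": self.ri_interpolated}
        data.update(self.profiles)
        return pd.DataFrame(data)


def deconvolve_scanwise(chrom: EventChromatogram, table: CharacteristicRatioTable,
                        solver: str = "nonnegative") -> ScanwiseProfiles:
    """Deconvolve every Pis scan, splitting the Ri profile isomer-by-isomer.

    The Ri abundance at each Pis scan time is taken by linear
    interpolation between the neighbouring Ri-event scans (the two events
    alternate and are never simultaneous).  Scans with non-positive
    interpolated Ri, or whose solved fractions all vanish, yield NaN gaps.
    """
    ri_t, ri_a = chrom.trace("Ri", table.ri_mz)
    if ri_t.size == 0:
        raise ValidationError("chromatogram contains no Ri scans")
    pis_scans = chrom.select(event="Pis")
    times = np.array([s.time_min for s in pis_scans])
    ri_interp = np.interp(times, ri_t, ri_a) if times.size else np.empty(0)
    profiles = {name: np.full(times.size, np.nan) for name in table.isomers}
    for j, scan in enumerate(pis_scans):
        pi_ab = {float(mz): scan.abundance_at(mz) for mz in table.pi_mz}
        measured = measure_ratios(ri_interp[j], pi_ab)
        if measured is None:
            continue
        result = solve_mixture(table, measured, solver=solver)
        fsum = float(result.fractions.sum())
        if fsum <= 0:
            continue
        for name, f in zip(table.isomers, result.fractions):
            profiles[name][j] = ri_interp[j] * float(f) / fsum
    return ScanwiseProfiles(times=times, ri_interpolated=ri_interp, profiles=profiles)
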