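"""Shared domain types and file formats for ion-trap MS/MS isomer workflows.

Containers for energy-resolved (ERMS) ramp data and event-structured
chromatograms, plus the CSV/JSON exchange formats used by every other
module.  All times are minutes, abundances are arbitrary detector counts,
and m/z values are matched with a unit-resolution tolerance (default
+/- 0.5 Th) appropriate for an ion trap.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ledams")

#: default m/z window (Th) when mapping file columns to configured ions
MZ_TOLERANCE = 0.5

#: MS/MS event labels: internal standard, reference ion, product-ion scan
EVENTS = ("IS", "Ri", "Pis")


class FormatError(ValueError):
    """Raised when a file does not conform to the expected layout."""


class ValidationError(ValueError):
    """Raised when parsed values violate a domain invariant."""


def mz_match(a: float, b: float, tol: float = MZ_TOLERANCE) -> bool:
    """True if two m/z values refer to the same nominal ion."""
    return abs(float(a) - float(b)) <= tol


@dataclass(frozen=True)
class IonSignal:
    """A single ion observation: m/z (Th) and abundance (counts)."""

    mz: float
    abundance: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValidationError(f"mz must be positive, got {self.mz}")
        if self.abundance < 0:
            raise ValidationError(f"abundance must be >= 0, got {self.abundance}")


@dataclass
class ERMSDataset:
    """One excitation-amplitude ramp acquired at a fixed excitation time.

    Parameters
    ----------
    ext_ms : excitation time (ms) applied at every step.
    precursor_mz : m/z of the mass-selected precursor ion.
    exa : strictly increasing excitation amplitudes (a.u., instrument
        scale 0-50).
    precursor : precursor-ion abundance at each step.
    products : mapping of product-ion m/z to its abundance at each step;
        insertion order is preserved and round-trips through CSV.
    """

    ext_ms: float
    precursor_mz: float
    exa: np.ndarray
    precursor: np.ndarray
    products: dict[float, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.exa = np.asarray(self.exa, dtype=float)
        self.precursor = np.asarray(self.precursor, dtype=float)
        self.products = {float(mz): np.asarray(a, dtype=float) for mz, a in self.products.items()}
        if self.ext_ms <= 0:
            raise ValidationError("ext_ms must be positive")
        if self.exa.size < 3:
            raise ValidationError("an ERMS ramp needs at least 3 steps")
        if np.any(np.diff(self.exa) <= 0):
            raise ValidationError("exa values must be strictly increasing")
        arrays = [self.precursor, *self.products.values()]
        for arr in arrays:
            if arr.shape != self.exa.shape:
                raise ValidationError("all abundance columns must match the exa grid")
            if np.any(arr < 0):
                raise ValidationError("abundances must be non-negative")

    @property
    def n_steps(self) -> int:
        return int(self.exa.size)

    def product_total(self) -> np.ndarray:
        """Summed product-ion abundance at each step."""
        if not self.products:
            return np.zeros_like(self.exa)
        return np.sum(list(self.products.values()), axis=0)


@dataclass
class MSMSEventScan:
    """A single time-stamped MS/MS acquisition event."""

    time_min: float
    segment: int
    event: str
    abundances: dict[float, float]

    def __post_init__(self) -> None:
        if self.event not in EVENTS:
            raise ValidationError(f"unknown event {self.event!r}; expected one of {EVENTS}")
        if self.segment not in (1, 2):
            raise ValidationError("segment must be 1 or 2")
        if self.event == "IS" and self.segment != 1:
            raise ValidationError("IS events belong to time segment 1")
        if self.event in ("Ri", "Pis") and self.segment != 2:
            raise ValidationError(f"{self.event} events belong to time segment 2")
        if any(a < 0 for a in self.abundances.values()):
            raise ValidationError("abundances must be non-negative")

    def abundance_at(self, mz: float, tol: float = MZ_TOLERANCE) -> float:
        """Summed abundance of ions within ``tol`` of ``mz`` (0 if none)."""
        return float(sum(a for m, a in self.abundances.items() if mz_match(m, mz, tol)))


# segment layout of the two-segment acquisition: the IS elutes in the first
# window, the unresolved isomer peak in the second.  Half-open intervals
# [start, end) avoid a gap or overlap at the printed 3.27/3.28 boundary.
DEFAULT_SEGMENT_BOUNDS: tuple[tuple[float, float], tuple[float, float]] = (
    (0.00, 3.28),
    (3.28, 10.00),
)


@dataclass
class EventChromatogram:
    """A time-ordered sequence of MS/MS event scans in two time segments.

    Segment 1 carries the internal-standard (IS) event; segment 2
    alternates the reference-ion (Ri) and product-ion-scan (Pis) events
    that feed the deconvolution.
    """

    scans: list[MSMSEventScan]
    segment_bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_SEGMENT_BOUNDS
    event_schedule: tuple[str, ...] = ("Ri", "Pis")

    def __post_init__(self) -> None:
        times = [s.time_min for s in self.scans]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("scans must be sorted by time")
        for s in self.scans:
            lo, hi = self.segment_bounds[s.segment - 1]
            if not (lo <= s.time_min < hi):
                raise ValidationError(
                    f"scan at {s.time_min} min labelled segment {s.segment} "
                    f"lies outside [{lo}, {hi})"
                )
        seg2 = [s.event for s in self.scans if s.segment == 2]
        for e1, e2 in zip(seg2, seg2[1:]):
            if e1 == e2:
                raise ValidationError("segment-2 events must strictly alternate Ri/Pis")

    def select(self, segment: int | None = None, event: str | None = None) -> list[MSMSEventScan]:
        out = self.scans
        if segment is not None:
            out = [s for s in out if s.segment == segment]
        if event is not None:
            out = [s for s in out if s.event == event]
        return out

    def trace(self, event: str, mz: float, tol: float = MZ_TOLERANCE) -> tuple[np.ndarray, np.ndarray]:
        """(times, abundances) of one ion across all scans of one event."""
        scans = self.select(event=event)
        t = np.array([s.time_min for s in scans])
        a = np.array([s.abundance_at(mz, tol) for s in scans])
        return t, a


@dataclass
class RunConfig:
    """Acquisition parameters of the two-segment HPLC-MS/MS method.

    Defaults mirror a unit-resolution ion-trap method for a 604 Th
    precursor: the Ri event re-isolates the precursor at low excitation
    amplitude (no fragmentation), the Pis event scans the product-ion
    range at the amplitude of maximal CID yield.
    """

    precursor_mz: float = 604.0
    is_mz: float = 455.0
    ri_window: tuple[float, float] = (580.0, 620.0)
    pis_window: tuple[float, float] = (165.0, 450.0)
    exa_ri: float = 20.0
    exa_pis: float = 35.0
    segment_bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_SEGMENT_BOUNDS
    inclusion_threshold_pct: float = 5.0
    mz_tol: float = MZ_TOLERANCE

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("ri_window", self.ri_window), ("pis_window", self.pis_window)):
            if not lo < hi:
                raise ValidationError(f"{name} must be a non-empty m/z range")
        for name, v in (("exa_ri", self.exa_ri), ("exa_pis", self.exa_pis)):
            if not 0 <= v <= 50:
                raise ValidationError(f"{name} must lie in the 0-50 a.u. ramp range")

    def to_json(self, path: str | Path) -> None:
        data = {
            "precursor_mz": self.precursor_mz,
            "is_mz": self.is_mz,
            "ri_window": list(self.ri_window),
            "pis_window": list(self.pis_window),
            "exa_ri": self.exa_ri,
            "exa_pis": self.exa_pis,
            "segment_bounds": [list(b) for b in self.segment_bounds],
            "inclusion_threshold_pct": self.inclusion_threshold_pct,
            "mz_tol": self.mz_tol,
        }
        Path(path).write_text(json.dumps(data, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        data["ri_window"] = tuple(data["ri_window"])
        data["pis_window"] = tuple(data["pis_window"])
        data["segment_bounds"] = tuple(tuple(b) for b in data["segment_bounds"])
        return cls(**data)


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def write_erms_csv(dataset: ERMSDataset, path: str | Path) -> None:
    """Write a ramp as CSV: a metadata comment line, then exa + ion columns."""
    path = Path(path)
    cols: dict[str, np.ndarray] = {"exa": dataset.exa, repr(dataset.precursor_mz): dataset.precursor}
    for mz, arr in dataset.products.items():
        cols[repr(mz)] = arr
    frame = pd.DataFrame(cols)
    with path.open("w", newline="") as fh:
        fh.write(f"# ext_ms={dataset.ext_ms!r} precursor_mz={dataset.precursor_mz!r}\n")
        frame.to_csv(fh, index=False)


def read_erms_csv(path: str | Path) -> ERMSDataset:
    """Parse an ERMS ramp CSV written by :func:`write_erms_csv`.

    The first line is a ``#`` metadata record carrying the excitation time
    and precursor m/z; the header row is ``exa`` plus one column per ion.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
        if not first.startswith("#"):
            raise FormatError(f"{path}: missing metadata line ('# ext_ms=... precursor_mz=...')")
        meta: dict[str, float] = {}
        for tok in first.lstrip("#").split():
            if "=" not in tok:
                raise FormatError(f"{path}: malformed metadata token {tok!r}")
            key, val = tok.split("=", 1)
            meta[key] = float(val)
        frame = pd.read_csv(fh)
    if "exa" not in frame.columns:
        raise FormatError(f"{path}: header must contain an 'exa' column")
    try:
        ext_ms = meta["ext_ms"]
        precursor_mz = meta["precursor_mz"]
    except KeyError as exc:
        raise FormatError(f"{path}: metadata missing {exc}") from None
    exa = frame["exa"].to_numpy(dtype=float)
    if np.any(np.diff(exa) <= 0):
        raise ValidationError(f"{path}: exa column must be strictly increasing")
    precursor = None
    products: dict[float, np.ndarray] = {}
    for col in frame.columns:
        if col == "exa":
            continue
        try:
            mz = float(col)
        except ValueError:
            raise FormatError(f"{path}: ion column {col!r} is not an m/z value") from None
        if precursor is None and mz_match(mz, precursor_mz):
            precursor = frame[col].to_numpy(dtype=float)
        else:
            products[mz] = frame[col].to_numpy(dtype=float)
    if precursor is None:
        raise FormatError(f"{path}: no column matches precursor m/z {precursor_mz}")
    return ERMSDataset(ext_ms=ext_ms, precursor_mz=precursor_mz, exa=exa,
                       precursor=precursor, products=products)


def write_chromatogram_csv(chrom: EventChromatogram, path: str | Path) -> None:
    """Wide CSV: time_min, segment, event, then one column per ion m/z.

    Ions not acquired in a given event are left empty (not zero), so a
    genuine zero abundance survives the round trip.
    """
    all_mz = sorted({mz for s in chrom.scans for mz in s.abundances})
    rows = []
    for s in chrom.scans:
        row: dict[str, object] = {"time_min": s.time_min, "segment": s.segment, "event": s.event}
        for mz in all_mz:
            row[repr(mz)] = s.abundances.get(mz, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_chromatogram_csv(path: str | Path, config: RunConfig | None = None) -> EventChromatogram:
    """Parse an event chromatogram CSV; validates segment/event labelling."""
    frame = pd.read_csv(path)
    required = {"time_min", "segment", "event"}
    if not required.issubset(frame.columns):
        raise FormatError(f"{path}: columns {sorted(required)} are required")
    ion_cols = [c for c in frame.columns if c not in required]
    try:
        mzs = {c: float(c) for c in ion_cols}
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric ion column: {exc}") from None
    scans = []
    for _, row in frame.iterrows():
        abund = {mzs[c]: float(row[c]) for c in ion_cols if pd.notna(row[c])}
        scans.append(MSMSEventScan(time_min=float(row["time_min"]),
                                   segment=int(row["segment"]),
                                   event=str(row["event"]),
                                   abundances=abund))
    bounds = config.segment_bounds if config is not None else DEFAULT_SEGMENT_BOUNDS
    return EventChromatogram(scans=scans, segment_bounds=bounds)


def read_chromatogram_mzml(path: str | Path, config: RunConfig) -> EventChromatogram:
    """Optional mzML adapter: map MS2 spectra onto IS/Ri/Pis events.

    Scans are classified by retention time (segment) and by the scan-window
    overlap with the configured Ri/Pis ranges.  Requires :mod:`pyteomics`.
    """
    from pyteomics import mzml  # deferred: optional dependency

    scans: list[MSMSEventScan] = []
    with mzml.read(str(path)) as reader:
        for spec in reader:
            if spec.get("ms level") != 2:
                continue
            t = float(spec["scanList"]["scan"][0]["scan start time"])
            seg = 1 if config.segment_bounds[0][0] <= t < config.segment_bounds[0][1] else 2
            lo = float(spec["scanList"]["scan"][0]["scanWindowList"]["scanWindow"][0]["scan window lower limit"])
            event = classify_event(seg, lo, config)
            abund = {float(m): float(i) for m, i in zip(spec["m/z array"], spec["intensity array"])}
            scans.append(MSMSEventScan(time_min=t, segment=seg, event=event, abundances=abund))
    scans.sort(key=lambda s: s.time_min)
    return EventChromatogram(scans=scans, segment_bounds=config.segment_bounds)


def classify_event(segment: int, window_lo: float, config: RunConfig) -> str:
    """Assign an event label from the time segment and scan-window start."""
    if segment == 1:
        return "IS"
    if abs(window_lo - config.ri_window[0]) <= abs(window_lo - config.pis_window[0]):
        return "Ri"
    return "Pis"
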