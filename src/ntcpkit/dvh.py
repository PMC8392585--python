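"""Dose-volume histogram containers, IO, algebra and point-dose metrics.

A DVH is stored on a shared ascending dose-edge grid ``e[0..k]`` (Gy):

* *cumulative* form carries one volume value per edge, ``c[i]`` being the
  absolute volume (cc) receiving at least ``e[i]``; ``c[0]`` equals the organ
  volume and the curve is non-increasing;
* *differential* form carries one volume value per bin ``(e[i], e[i+1]]``,
  the bin dose being the arithmetic bin centre.

All volumes are kept absolute (cc); relative inputs are converted on read.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "DoseVolumeHistogram",
    "DoseSummary",
    "DvhError",
    "Dialect",
    "read_dvh",
    "write_dvh",
    "to_differential",
    "to_cumulative",
    "combine_organs",
    "dose_at_volume",
    "summarize",
    "rebin",
]

CUMULATIVE = "cumulative"
DIFFERENTIAL = "differential"

_VOL_TOL = 1e-9


class DvhError(ValueError):
    """Raised for malformed DVH data or invalid DVH operations."""


@dataclass(frozen=True)
class DoseVolumeHistogram:
    """A binned dose-volume curve for one organ at risk."""

    organ_label: str
    form: str
    dose_edges: np.ndarray  # Gy, strictly increasing, >= 0
    volume: np.ndarray  # cc; per edge (cumulative) or per bin (differential)
    total_volume: float  # cc

    def __post_init__(self) -> None:
        edges = np.asarray(self.dose_edges, dtype=float)
        vol = np.asarray(self.volume, dtype=float)
        object.__setattr__(self, "dose_edges", edges)
        object.__setattr__(self, "volume", vol)
        if self.form not in (CUMULATIVE, DIFFERENTIAL):
            raise DvhError(f"unknown DVH form {self.form!r}")
        if edges.ndim != 1 or edges.size < 2:
            raise DvhError("need at least two dose edges")
        if edges[0] < 0 or np.any(np.diff(edges) <= 0):
            raise DvhError("dose edges must be non-negative and strictly increasing")
        if not np.isfinite(self.total_volume) or self.total_volume < 0:
            raise DvhError("total volume must be finite and non-negative")
        tol = _VOL_TOL * max(1.0, self.total_volume)
        if self.form == CUMULATIVE:
            if vol.size != edges.size:
                raise DvhError("cumulative DVH needs one volume per dose edge")
            rising = np.nonzero(np.diff(vol) > tol)[0]
            if rising.size:
                raise DvhError(
                    f"cumulative volume rises with dose at row {rising[0] + 1}"
                )
            if abs(vol[0] - self.total_volume) > tol:
                raise DvhError("first cumulative value must equal the total volume")
            if vol[-1] < -tol:
                raise DvhError("cumulative volumes must be non-negative")
        else:
            if vol.size != edges.size - 1:
                raise DvhError("differential DVH needs one volume per dose bin")
            if np.any(vol < -tol):
                raise DvhError("differential bin volumes must be non-negative")
            if abs(vol.sum() - self.total_volume) > 1e-9 * max(1.0, self.total_volume):
                raise DvhError("differential volumes must sum to the total volume")

    @property
    def bin_centers(self) -> np.ndarray:
        """Arithmetic centres of the dose bins (Gy)."""
        e = self.dose_edges
        return 0.5 * (e[:-1] + e[1:])

    def as_relative(self) -> np.ndarray:
        """Volumes as fractions of the organ volume."""
        if self.total_volume == 0:
            raise DvhError("cannot normalise a zero-volume organ")
        return self.volume / self.total_volume


@dataclass(frozen=True)
class DoseSummary:
    """Point dose metrics of one DVH (all in Gy; volume in cc)."""

    mean_dose: float
    max_dose: float
    d98: float
    volume: float

    def __post_init__(self) -> None:
        for name in ("mean_dose", "max_dose", "d98", "volume"):
            if getattr(self, name) < 0:
                raise DvhError(f"{name} must be non-negative")
        if self.d98 > self.max_dose + 1e-9:
            raise DvhError("D98% cannot exceed the maximum dose")


@dataclass(frozen=True)
class Dialect:
    """Column/unit mapping for tabular DVH exports.

    ``units_dose`` is ``Gy`` or ``cGy``; ``units_volume`` is ``cc`` or
    ``percent`` (percent requires ``total_volume_cc``); ``form`` is
    ``cumulative`` or ``differential``.
    """

    units_dose: str = "Gy"
    units_volume: str = "cc"
    form: str = CUMULATIVE
    total_volume_cc: float | None = None
    dose_column: str = "dose"
    volume_column: str = "volume"

    @classmethod
    def from_file(cls, path: str | Path) -> "Dialect":
        text = Path(path).read_text()
        data = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        return cls(**data)

    def __post_init__(self) -> None:
        if self.units_dose not in ("Gy", "cGy"):
            raise DvhError(f"unknown dose unit {self.units_dose!r}")
        if self.units_volume not in ("cc", "percent"):
            raise DvhError(f"unknown volume unit {self.units_volume!r}")
        if self.form not in (CUMULATIVE, DIFFERENTIAL):
            raise DvhError(f"unknown DVH form {self.form!r}")
        if self.units_volume == "percent" and self.total_volume_cc is None:
            raise DvhError("relative (percent) volumes require total_volume_cc")


def read_dvh(
    path: str | Path,
    dialect: Dialect | Mapping | None = None,
    organ_label: str = "",
) -> DoseVolumeHistogram:
    """Read a two-column dose/volume CSV and normalise it to Gy and cc."""
    if dialect is None:
        dialect = Dialect()
    elif isinstance(dialect, Mapping):
        dialect = Dialect(**dialect)
    path = Path(path)
    doses, volumes = [], []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise DvhError(f"{path}: empty file")
        dcol, vcol = dialect.dose_column, dialect.volume_column
        missing = {dcol, vcol} - set(reader.fieldnames)
        if missing:
            raise DvhError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=1):
            try:
                d, v = float(row[dcol]), float(row[vcol])
            except (TypeError, ValueError) as exc:
                raise DvhError(f"{path}: non-numeric value at row {i}") from exc
            if v < 0:
                raise DvhError(f"{path}: negative volume at row {i}")
            doses.append(d)
            volumes.append(v)
    dose = np.asarray(doses)
    vol = np.asarray(volumes)
    if dose.size < 2:
        raise DvhError(f"{path}: need at least two rows")
    if np.any(np.diff(dose) <= 0):
        row = int(np.nonzero(np.diff(dose) <= 0)[0][0]) + 2
        raise DvhError(f"{path}: dose column not strictly increasing at row {row}")
    if dialect.units_dose == "cGy":
        dose = dose / 100.0
    if dialect.units_volume == "percent":
        vol = vol / 100.0 * float(dialect.total_volume_cc)
    if dialect.form == CUMULATIVE:
        rising = np.nonzero(np.diff(vol) > _VOL_TOL * max(1.0, vol[0]))[0]
        if rising.size:
            raise DvhError(
                f"{path}: cumulative volume rises with dose at row {rising[0] + 2}"
            )
        total = float(vol[0])
        edges, values = dose, vol
        if vol[-1] > _VOL_TOL * max(1.0, total):
            # residual volume at/above the last listed dose: close the curve
            # one median bin-width further out
            width = float(np.median(np.diff(dose)))
            edges = np.append(dose, dose[-1] + width)
            values = np.append(vol, 0.0)
        return DoseVolumeHistogram(organ_label, CUMULATIVE, edges, values, total)
    # differential export: rows are (upper bin edge, bin volume); prepend a
    # lower edge so the first row keeps its listed width
    width = float(dose[1] - dose[0])
    lower = max(0.0, dose[0] - width)
    edges = np.concatenate([[lower], dose])
    total = float(vol.sum())
    return DoseVolumeHistogram(organ_label, DIFFERENTIAL, edges, vol, total)


def write_dvh(dvh: DoseVolumeHistogram, path: str | Path) -> None:
    """Write a DVH as a cumulative dose/volume CSV (Gy, cc)."""
    cum = to_cumulative(dvh) if dvh.form == DIFFERENTIAL else dvh
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["dose", "volume"])
        for d, v in zip(cum.dose_edges, cum.volume):
            writer.writerow([f"{d:.6g}", f"{v:.9g}"])


def to_differential(dvh: DoseVolumeHistogram) -> DoseVolumeHistogram:
    """Difference a cumulative DVH into per-bin volumes."""
    if dvh.form != CUMULATIVE:
        raise DvhError("to_differential expects a cumulative DVH")
    bins = -np.diff(dvh.volume)
    bins = np.clip(bins, 0.0, None)  # wash float negatives from flat segments
    total = float(bins.sum())
    return DoseVolumeHistogram(
        dvh.organ_label, DIFFERENTIAL, dvh.dose_edges, bins, total
    )


def to_cumulative(dvh: DoseVolumeHistogram) -> DoseVolumeHistogram:
    """Accumulate a differential DVH back onto its dose edges."""
    if dvh.form != DIFFERENTIAL:
        raise DvhError("to_cumulative expects a differential DVH")
    cum = np.concatenate([[dvh.total_volume], dvh.total_volume - np.cumsum(dvh.volume)])
    cum = np.clip(cum, 0.0, None)
    return DoseVolumeHistogram(
        dvh.organ_label, CUMULATIVE, dvh.dose_edges, cum, dvh.total_volume
    )


def rebin(dvh: DoseVolumeHistogram, new_edges: np.ndarray) -> DoseVolumeHistogram:
    """Mass-preserving re-binning of a differential DVH onto ``new_edges``.

    Each source bin's volume is allocated to target bins in proportion to
    interval overlap (volume treated as uniform within a bin).
    """
    if dvh.form != DIFFERENTIAL:
        raise DvhError("rebin expects a differential DVH")
    new_edges = np.asarray(new_edges, dtype=float)
    lo_s, hi_s = dvh.dose_edges[:-1], dvh.dose_edges[1:]
    if new_edges[0] > lo_s[0] or new_edges[-1] < hi_s[-1]:
        raise DvhError("new grid must cover the DVH dose range")
    out = np.zeros(new_edges.size - 1)
    lo_t, hi_t = new_edges[:-1], new_edges[1:]
    for a, b, v in zip(lo_s, hi_s, dvh.volume):
        if v == 0.0:
            continue
        overlap = np.minimum(hi_t, b) - np.maximum(lo_t, a)
        overlap = np.clip(overlap, 0.0, None)
        out += v * overlap / (b - a)
    # renormalise the tiny float drift so mass is conserved exactly
    s = out.sum()
    if s > 0:
        out *= dvh.total_volume / s
    return DoseVolumeHistogram(
        dvh.organ_label, DIFFERENTIAL, new_edges, out, dvh.total_volume
    )


def combine_organs(
    left: DoseVolumeHistogram,
    right: DoseVolumeHistogram,
    organ_label: str | None = None,
    grid_width: float = 0.1,
) -> DoseVolumeHistogram:
    """Sum two organs into one (e.g. both parotids into combined parotids).

    Both DVHs must be differential with absolute volumes; they are resampled
    onto a shared uniform grid (default 0.1 Gy) with mass-preserving
    allocation and the absolute volumes are added.
    """
    for d in (left, right):
        if d.form != DIFFERENTIAL:
            raise DvhError("combine_organs expects differential DVHs")
    if left.total_volume == 0:
        return replace(right, organ_label=organ_label or right.organ_label)
    if right.total_volume == 0:
        return replace(left, organ_label=organ_label or left.organ_label)
    top = max(left.dose_edges[-1], right.dose_edges[-1])
    n_bins = int(np.ceil(top / grid_width)) + 1
    edges = np.arange(n_bins + 1) * grid_width
    lv = rebin(left, edges).volume
    rv = rebin(right, edges).volume
    label = organ_label or f"{left.organ_label}+{right.organ_label}"
    return DoseVolumeHistogram(
        label, DIFFERENTIAL, edges, lv + rv, left.total_volume + right.total_volume
    )


def dose_at_volume(dvh: DoseVolumeHistogram, volume_fraction: float) -> float:
    """Dose D(x): largest dose received by at least ``volume_fraction`` of the
    organ, by linear interpolation on the cumulative curve (D98% = 0.98)."""
    if not 0.0 < volume_fraction <= 1.0:
        raise DvhError("volume_fraction must lie in (0, 1]")
    cum = to_cumulative(dvh) if dvh.form == DIFFERENTIAL else dvh
    if cum.total_volume == 0:
        raise DvhError("zero-volume organ has no dose metrics")
    target = volume_fraction * cum.total_volume
    c = cum.volume
    e = cum.dose_edges
    below = np.nonzero(c < target - _VOL_TOL * max(1.0, cum.total_volume))[0]
    if below.size == 0:
        return float(e[-1])
    i = int(below[0])
    if i == 0:
        return float(e[0])
    # interpolate on the falling segment [e[i-1], e[i]]
    c0, c1 = c[i - 1], c[i]
    if c0 == c1:  # flat segment cannot cross the target
        return float(e[i - 1])
    frac = (c0 - target) / (c0 - c1)
    return float(e[i - 1] + frac * (e[i] - e[i - 1]))


def summarize(dvh: DoseVolumeHistogram) -> DoseSummary:
    """Mean (volume-weighted bin-centre), maximum and near-minimum (D98%) dose."""
    if dvh.total_volume == 0:
        raise DvhError("zero-volume organ has no dose summary")
    diff = to_differential(dvh) if dvh.form == CUMULATIVE else dvh
    rel = diff.as_relative()
    mean = float(np.dot(rel, diff.bin_centers))
    nz = np.nonzero(diff.volume > _VOL_TOL * max(1.0, diff.total_volume))[0]
    max_dose = float(diff.dose_edges[nz[-1] + 1]) if nz.size else 0.0
    d98 = dose_at_volume(dvh, 0.98)
    return DoseSummary(mean, max_dose, d98, float(dvh.total_volume))
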