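"""Raw probe signals -> free and transferred Zn(II), and back.

Two probe chemistries are covered:

* a 2:1 chromogenic chelator (PAR): absorbance of the Zn(ligand)2 complex at
  492 nm gives the complex concentration via Beer-Lambert; the free metal
  follows from the overall Kd12 (M^2) with the bis-ligand free-ligand
  correction.
* a 1:1 fluorescent probe (ZnAF-2F): with per-sample Fmin (probe Zn-free,
  chelator-saturated) and Fmax (Zn-saturated) anchors, free Zn(II) is
  Kd * (F - Fmin) / (Fmax - F).  All conversions are ratio-based, so the
  fluorescence units are arbitrary.

Metal buffers (a 1:1 chelator partially saturated with Zn) pin free Zn at
Kd * f / (1 - f), where f is the fractional saturation of the chelator in
ligand excess.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .equilibria import OneToOneChelator, OneToOneProbe, TwoToOneProbe

__all__ = [
    "FluorescenceCalibration",
    "TransferObservation",
    "TitrationDataset",
    "SaturationError",
    "free_zinc_from_fluorescence",
    "fluorescence_from_free_zinc",
    "znpar2_from_absorbance",
    "free_zinc_from_par",
    "buffer_free_zinc",
    "read_signal_csv",
    "write_signal_csv",
]


class SaturationError(ValueError):
    """Signal at or beyond the saturated anchor; free metal is undefined."""


@dataclass(frozen=True)
class FluorescenceCalibration:
    """Per-sample fluorescence anchors of a 1:1 probe."""

    f_min: float
    f_max: float
    probe: OneToOneProbe

    def __post_init__(self) -> None:
        if not (self.f_max > self.f_min):
            raise ValueError("f_max must exceed f_min")


@dataclass(frozen=True)
class TransferObservation:
    """One equilibrium Zn(II) transfer measurement (competition endpoint).

    ``transferred_eq`` is mol Zn transferred to the competitor per mol
    protein; ``n_sites`` the protein's maximum Zn load.
    """

    transferred_eq: float
    protein_total: float
    competitor_total: float
    n_sites: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.transferred_eq <= self.n_sites):
            raise ValueError(
                f"transferred_eq must lie in [0, n_sites={self.n_sites}], "
                f"got {self.transferred_eq}"
            )
        if not (self.protein_total > 0 and self.competitor_total > 0):
            raise ValueError("totals must be > 0")


@dataclass
class TitrationDataset:
    """One experimental trace: x, y and free-form metadata."""

    x: np.ndarray
    y: np.ndarray
    kind: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same shape")


def free_zinc_from_fluorescence(f: float, cal: FluorescenceCalibration) -> float:
    """Free Zn(II) from a calibrated 1:1 probe fluorescence reading.

    [Zn]free = Kd * (F - Fmin) / (Fmax - F).  Readings at or above Fmax are a
    saturation error; readings below Fmin (baseline noise) clamp to zero with
    a warning.
    """
    if f >= cal.f_max:
        raise SaturationError(
            f"fluorescence {f} >= f_max {cal.f_max}: probe saturated, free Zn undefined"
        )
    if f < cal.f_min:
        warnings.warn(
            f"fluorescence {f} below f_min {cal.f_min}; clamping free Zn to 0",
            stacklevel=2,
        )
        return 0.0
    return cal.probe.kd * (f - cal.f_min) / (cal.f_max - f)


def fluorescence_from_free_zinc(free_zn: float, cal: FluorescenceCalibration) -> float:
    """Exact inverse of :func:`free_zinc_from_fluorescence`."""
    if free_zn < 0:
        raise ValueError("free_zn must be >= 0")
    sat = free_zn / (free_zn + cal.probe.kd)
    return cal.f_min + (cal.f_max - cal.f_min) * sat


def znpar2_from_absorbance(a_492: float, probe: TwoToOneProbe) -> float:
    """Beer-Lambert: concentration of the Zn(ligand)2 complex from A492."""
    if a_492 < 0:
        raise ValueError("absorbance must be >= 0 (baseline-corrected)")
    return a_492 / (probe.epsilon_492 * probe.path_length)


def free_zinc_from_par(znpar2: float, par_total: float, probe: TwoToOneProbe) -> float:
    """Free Zn(II) from the 2:1 probe equilibrium.

    [Zn]free = Kd12 * [ZnL2] / ([L]free)^2 with [L]free = total - 2 [ZnL2].
    """
    if znpar2 < 0:
        raise ValueError("znpar2 must be >= 0")
    if znpar2 == 0.0:
        return 0.0
    l_free = par_total - 2.0 * znpar2
    if l_free <= 0:
        raise ValueError(
            f"probe depleted: 2*[ZnL2]={2 * znpar2:.3e} >= total {par_total:.3e}"
        )
    return probe.kd12 * znpar2 / (l_free * l_free)


def buffer_free_zinc(chelator: OneToOneChelator, zn_fraction: float) -> float:
    """Free Zn(II) fixed by a 1:1 metal buffer at fractional saturation f.

    [Zn]free = Kd * f / (1 - f); valid for ligand excess over protein.
    """
    if not (0.0 < zn_fraction < 1.0):
        raise ValueError(f"zn_fraction must be in (0, 1), got {zn_fraction}")
    return chelator.kd * zn_fraction / (1.0 - zn_fraction)


# ---------------------------------------------------------------------------
# CSV dialect: two data columns, '#'-prefixed "key: value" metadata header


def read_signal_csv(path) -> TitrationDataset:
    path = Path(path)
    metadata: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                metadata[key.strip()] = value.strip()
    frame = pd.read_csv(path, comment="#")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns")
    x_col, y_col = frame.columns[:2]
    return TitrationDataset(
        x=frame[x_col].to_numpy(),
        y=frame[y_col].to_numpy(),
        kind=metadata.get("kind", ""),
        metadata=metadata,
    )


def write_signal_csv(path, dataset: TitrationDataset, columns: tuple[str, str] = ("x", "signal")):
    path = Path(path)
    with open(path, "w") as fh:
        if dataset.kind:
            fh.write(f"# kind: {dataset.kind}\n")
        for key, value in dataset.metadata.items():
            if key == "kind":
                continue
            fh.write(f"# {key}: {value}\n")
        pd.DataFrame({columns[0]: dataset.x, columns[1]: dataset.y}).to_csv(fh, index=False)
    return path
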