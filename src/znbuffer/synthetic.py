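"""Forward simulation of every experiment type the estimators consume.

Each simulator generates data from ground-truth binding parameters through
the same equilibrium formalism the fitters invert, plus Gaussian noise
applied in signal space with a standard deviation expressed as a fraction of
the trace's dynamic range (how instrument noise presents).  Under a fixed
seed every simulator is deterministic, and at zero noise each one is exactly
invertible by its paired estimator -- the module's central property.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .equilibria import (
    EquilibriumSystem,
    OneToOneChelator,
    OneToOneProbe,
    SteppedBindingModel,
    TwoToOneProbe,
    solve_free_zinc,
)
from .io import Registry, bundled_registry
from .kinetics import KineticTrace
from .probes import TitrationDataset, TransferObservation

__all__ = [
    "NoiseSpec",
    "make_fixture_models",
    "simulate_par_transfer",
    "simulate_znaf_transfer_isotherm",
    "simulate_apo_titration",
    "simulate_ph_titration",
    "simulate_buffer_cd",
    "simulate_kinetic_trace",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian signal-space noise; sigma is a fraction of dynamic range."""

    sigma: float = 0.0
    seed: int = 0
    kind: str = "gaussian"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.kind != "gaussian":
            raise ValueError(f"unsupported noise kind {self.kind!r}")

    def apply(self, clean: np.ndarray, dynamic_range: Optional[float] = None) -> np.ndarray:
        clean = np.asarray(clean, dtype=float)
        if self.sigma == 0.0:
            return clean.copy()
        if dynamic_range is None:
            dynamic_range = float(np.ptp(clean)) or 1.0
        rng = np.random.default_rng(self.seed)
        return clean + rng.normal(0.0, self.sigma * dynamic_range, size=clean.shape)


def make_fixture_models() -> Registry:
    """Registry of the ten reference metallothionein models, chelators and
    probes bundled with the package."""
    return bundled_registry()


def _monotone(grid: np.ndarray, name: str) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError(f"{name} grid is empty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError(f"{name} grid must be strictly increasing")
    return grid


def simulate_par_transfer(
    model: SteppedBindingModel,
    protein_total: float,
    par_total: float,
    probe: TwoToOneProbe,
    noise: Optional[NoiseSpec] = None,
) -> TransferObservation:
    """Equilibrium Zn transfer from the holo protein to the 2:1 probe."""
    if protein_total <= 0 or par_total < 0:
        raise ValueError("protein_total must be > 0 and par_total >= 0")
    if par_total == 0.0:
        t = 0.0
    else:
        system = EquilibriumSystem(
            zn_total=model.n_sites * protein_total,
            protein=(model, protein_total),
            probe_2to1=(probe, par_total),
        )
        state = solve_free_zinc(system)
        t = state.species[f"{probe.name}:ZnL2"] / protein_total
    if noise is not None:
        t = float(np.clip(noise.apply(np.array([t]), dynamic_range=model.n_sites)[0],
                          0.0, model.n_sites))
    return TransferObservation(
        transferred_eq=t,
        protein_total=protein_total,
        competitor_total=max(par_total, 1e-30),
        n_sites=model.n_sites,
    )


def simulate_znaf_transfer_isotherm(
    model: SteppedBindingModel,
    protein_total: float,
    probe_grid: Sequence[float],
    probe: OneToOneProbe,
    noise: Optional[NoiseSpec] = None,
) -> pd.DataFrame:
    """Zn transfer from the holo protein to increasing 1:1 probe totals.

    Returns a frame with columns (probe_total, transferred_eq, pzn); pzn is
    the equilibrium free Zn of each point, computed with the same solver the
    fitters use.
    """
    grid = _monotone(np.asarray(probe_grid), "probe_total")
    transferred = np.zeros(grid.size)
    pzn = np.zeros(grid.size)
    for k, p_tot in enumerate(grid):
        system = EquilibriumSystem(
            zn_total=model.n_sites * protein_total,
            protein=(model, protein_total),
            probe_1to1=(probe, float(p_tot)),
        )
        state = solve_free_zinc(system)
        transferred[k] = state.species[f"{probe.name}:Zn"] / protein_total
        pzn[k] = state.pzn
    if noise is not None:
        transferred = np.clip(noise.apply(transferred), 0.0, model.n_sites)
    return pd.DataFrame(
        {"probe_total": grid, "transferred_eq": transferred, "pzn": pzn}
    )


def simulate_apo_titration(
    model: SteppedBindingModel,
    protein_total: float,
    probe_total: float,
    ratio_grid: Sequence[float],
    probe: OneToOneProbe,
    noise: Optional[NoiseSpec] = None,
    f_min: float = 0.0,
    f_max: float = 1.0,
) -> pd.DataFrame:
    """Zn titration of the apo protein in the presence of the 1:1 probe.

    Returns (ratio, fluorescence, pzn); fluorescence is the probe's
    saturation mapped onto [f_min, f_max].
    """
    grid = _monotone(np.asarray(ratio_grid), "ratio")
    fluor = np.zeros(grid.size)
    pzn = np.zeros(grid.size)
    for k, r in enumerate(grid):
        system = EquilibriumSystem(
            zn_total=float(r) * protein_total,
            protein=(model, protein_total),
            probe_1to1=(probe, probe_total),
        )
        state = solve_free_zinc(system)
        sat = state.species[f"{probe.name}:Zn"] / probe_total if probe_total > 0 else 0.0
        fluor[k] = f_min + (f_max - f_min) * sat
        pzn[k] = state.pzn
    if noise is not None:
        fluor = noise.apply(fluor, dynamic_range=f_max - f_min)
    return pd.DataFrame({"ratio": grid, "fluorescence": fluor, "pzn": pzn})


def simulate_ph_titration(
    pka_prime: float,
    n: float,
    plateaus: tuple[float, float],
    ph_grid: Sequence[float],
    noise: Optional[NoiseSpec] = None,
) -> TitrationDataset:
    """Absorbance pH titration with a single Hill transition at pKa'."""
    grid = _monotone(np.asarray(ph_grid), "pH")
    a_lo, a_hi = plateaus
    clean = a_lo + (a_hi - a_lo) / (1.0 + 10.0 ** (n * (pka_prime - grid)))
    signal = noise.apply(clean, dynamic_range=abs(a_hi - a_lo)) if noise else clean
    return TitrationDataset(
        x=grid,
        y=signal,
        kind="ph_titration",
        metadata={"pka_prime_truth": pka_prime, "n_truth": n},
    )


def simulate_buffer_cd(
    model: SteppedBindingModel,
    buffers: Sequence[tuple[OneToOneChelator, float, float]],
    protein_total: float,
    noise: Optional[NoiseSpec] = None,
    theta_apo: float = 0.0,
    theta_sat: float = -30.0,
) -> pd.DataFrame:
    """Metal-buffer CD isotherm: ellipticity vs initial buffered pZn.

    ``buffers`` are (chelator, total ligand M, Zn fractional saturation).
    The initial pZn is what the buffer alone would fix; the ellipticity comes
    from the full equilibrium including protein withdrawal from the pool,
    taken proportional to the protein's fractional zinc saturation (the CD
    change tracks metal-coupled folding).
    """
    pzn_initial = np.zeros(len(buffers))
    theta = np.zeros(len(buffers))
    for k, (chel, l_tot, f) in enumerate(buffers):
        if not (0 < f < 1):
            raise ValueError(f"buffer {k}: fraction must be in (0,1)")
        pzn_initial[k] = -(math.log10(chel.kd) + math.log10(f / (1.0 - f)))
        system = EquilibriumSystem(
            zn_total=f * l_tot,
            protein=(model, protein_total),
            chelators=((chel, l_tot),),
        )
        state = solve_free_zinc(system)
        occupancy = sum(
            i * state.species[f"{model.name}:Zn{i}"] for i in range(model.n_sites + 1)
        ) / protein_total
        theta[k] = theta_apo + (theta_sat - theta_apo) * occupancy / model.n_sites
    if noise is not None:
        theta = noise.apply(theta, dynamic_range=abs(theta_sat - theta_apo))
    return pd.DataFrame({"pzn_initial": pzn_initial, "ellipticity": theta})


def simulate_kinetic_trace(
    k_obsd: float,
    amplitude: float,
    offset: float,
    t_grid: Sequence[float],
    noise: Optional[NoiseSpec] = None,
) -> KineticTrace:
    """Exponential TNB- appearance trace A(t) = offset + amplitude (1-e^-kt)."""
    if k_obsd <= 0:
        raise ValueError("k_obsd must be > 0")
    grid = _monotone(np.asarray(t_grid), "time")
    clean = offset + amplitude * (1.0 - np.exp(-k_obsd * grid))
    signal = noise.apply(clean, dynamic_range=abs(amplitude)) if noise else clean
    return KineticTrace(
        time=grid,
        signal=signal,
        metadata={"k_obsd_truth": k_obsd, "amplitude_truth": amplitude},
    )
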