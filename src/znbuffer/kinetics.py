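"""Thiol-reactivity kinetics: TNB- appearance fits and endpoint analysis.

Free Cys thiols of a metallothionein reduce DTNB quickly; thiolates engaged
in Zn(II) coordination react slowly.  The appearance of the TNB- chromophore
(A412) therefore follows pseudo-first-order kinetics whose observed rate
constant k_obsd reports how much of the protein's thiol inventory is exposed
at a given Zn load.  Plotting k_obsd against added Zn(II) equivalents shows
piecewise-linear drops whose breakpoints mark metalation-stage endpoints, and
plotting log10 k_obsd against the -logKd of a competing weak chelator is
linear.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np
from scipy.optimize import minimize
from scipy.stats import linregress

from .estimators import FitResult

__all__ = [
    "KineticTrace",
    "fit_pseudo_first_order",
    "titration_endpoints",
    "chelator_rate_regression",
]


@dataclass
class KineticTrace:
    """Absorbance-vs-time trace of TNB- appearance."""

    time: np.ndarray
    signal: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.size < 5:
            raise ValueError("trace needs >= 5 points")
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have the same shape")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")


def fit_pseudo_first_order(trace: KineticTrace) -> FitResult:
    """Fit A(t) = A0 + A_amp (1 - exp(-k t)); returns k_obsd (1/s).

    The baseline offset A0 is fitted, not forced to zero.  A flat trace (no
    resolvable amplitude) returns a non-converged result with a diagnostic
    flag rather than a spurious rate.
    """
    t, y = trace.time, trace.signal
    span = float(np.ptp(y))
    if span < 1e-12 or span < 1e-9 * max(abs(float(np.mean(y))), 1.0):
        return FitResult(
            parameters={},
            standard_errors={},
            residual_norm=0.0,
            converged=False,
            model_tag="pseudo-first-order",
            flags=("flat-trace",),
            message="signal has no resolvable amplitude",
        )
    # initial rate from the time to reach half of the observed amplitude
    y0, y_end = float(y[0]), float(y[-1])
    half = y0 + 0.5 * (y_end - y0)
    crossing = np.nonzero((y - half) * np.sign(y_end - y0) >= 0)[0]
    t_half = float(t[crossing[0]]) if crossing.size else float(t[-1] / 2)
    k0 = math.log(2.0) / max(t_half, float(t[1] - t[0]))

    params = lmfit.Parameters()
    params.add("k_obsd", value=k0, min=1e-12)
    params.add("amplitude", value=y_end - y0)
    params.add("offset", value=y0)

    def resid(p):
        return (
            p["offset"].value
            + p["amplitude"].value * (1.0 - np.exp(-p["k_obsd"].value * t))
            - y
        )

    out = lmfit.minimize(resid, params, method="leastsq")
    names = ["k_obsd", "amplitude", "offset"]
    ok = bool(out.success) and float(out.params["k_obsd"].value) > 0
    return FitResult(
        parameters={n: float(out.params[n].value) for n in names},
        standard_errors={
            n: float(out.params[n].stderr) if out.params[n].stderr is not None else float("nan")
            for n in names
        },
        residual_norm=float(np.linalg.norm(out.residual)),
        converged=ok,
        model_tag="pseudo-first-order",
        flags=() if ok else ("non-convergence",),
        message="" if ok else out.message,
    )


def _pw_design(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for k in knots:
        cols.append(np.maximum(x - k, 0.0))
    return np.stack(cols, axis=1)


def _pw_sse(x: np.ndarray, y: np.ndarray, knots: Sequence[float]) -> tuple[float, np.ndarray]:
    design = _pw_design(x, knots)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = design @ coef - y
    return float(resid @ resid), coef


def titration_endpoints(
    points: Sequence[tuple[float, float]], n_breaks: int = 1
) -> FitResult:
    """Continuous piecewise-linear fit with free knots; returns breakpoints.

    Knots are grid-initialized over the interior of the x-range and refined
    by Nelder-Mead; segment slopes come from the final linear solve.  If the
    piecewise model does not improve on a single line the knot positions are
    unidentifiable and flagged as such.
    """
    if n_breaks not in (1, 2):
        raise ValueError("n_breaks must be 1 or 2")
    data = np.asarray(points, dtype=float)
    if data.shape[0] < 2 * (n_breaks + 1):
        raise ValueError(f"need >= {2 * (n_breaks + 1)} points for {n_breaks} breakpoints")
    order = np.argsort(data[:, 0])
    x, y = data[order, 0], data[order, 1]

    interior = np.linspace(x[1], x[-2], 40)
    if n_breaks == 1:
        candidates = [(k,) for k in interior]
    else:
        candidates = [
            (a, b) for a, b in itertools.combinations(interior, 2) if b - a > 1e-9
        ]
    best_knots, best_sse = None, math.inf
    for ks in candidates:
        sse, _ = _pw_sse(x, y, ks)
        # ties toward smaller x
        if sse < best_sse - 1e-15:
            best_sse, best_knots = sse, ks
    assert best_knots is not None

    span = float(x[-1] - x[0])

    def objective(ks: np.ndarray) -> float:
        ks = np.sort(ks)
        if ks[0] <= x[0] or ks[-1] >= x[-1]:
            return best_sse + 1.0 + float(np.sum(np.abs(ks))) / max(span, 1.0)
        return _pw_sse(x, y, ks)[0]

    res = minimize(
        objective,
        np.asarray(best_knots, dtype=float),
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-18, "maxiter": 2000},
    )
    knots = tuple(float(v) for v in np.sort(res.x))
    sse, coef = _pw_sse(x, y, knots)
    slopes = np.cumsum(coef[1:])  # slope of segment j = base slope + hinge increments

    sse_line, _ = _pw_sse(x, y, ())
    unidentifiable = sse_line - sse <= 1e-12 * max(sse_line, 1e-30) + 1e-30
    params = {f"breakpoint_{i + 1}": k for i, k in enumerate(knots)}
    params.update({f"slope_{i + 1}": float(s) for i, s in enumerate(slopes)})
    params["intercept"] = float(coef[0])
    return FitResult(
        parameters=params,
        standard_errors={k: float("nan") for k in params},
        residual_norm=math.sqrt(sse),
        converged=True,
        model_tag=f"piecewise-linear-{n_breaks}",
        flags=("unidentifiable",) if unidentifiable else (),
    )


def chelator_rate_regression(points: Sequence[tuple[float, float]]) -> FitResult:
    """OLS of log10 k_obsd against chelator -logKd (linear in the field)."""
    data = np.asarray(points, dtype=float)
    if data.shape[0] < 3:
        raise ValueError("need >= 3 (chelator_pkd, log10_k_obsd) points")
    x, y = data[:, 0], data[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("rank-deficient design: all chelator pkd values identical")
    fit = linregress(x, y)
    return FitResult(
        parameters={
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "r_squared": float(fit.rvalue**2),
        },
        standard_errors={
            "slope": float(fit.stderr),
            "intercept": float(fit.intercept_stderr),
            "r_squared": float("nan"),
        },
        residual_norm=float(np.linalg.norm(y - (fit.slope * x + fit.intercept))),
        converged=True,
        model_tag="chelator-rate-ols",
    )
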