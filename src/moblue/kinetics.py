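"""Stopped-flow-style kinetic analysis of sigmoidal cluster formation.

Traces of cluster formation ({Mo36} at 350 nm, {PMo12} at 440 nm) are
sigmoidal: an induction (lag) period, autocatalytic acceleration, then
saturation.  The minimal rate law used here is the two-step autocatalytic
scheme (Finke-Watzky type)

    A -> B        (k1, slow uncatalyzed nucleation)
    A + B -> 2B   (k2, autocatalytic growth)

which is a surrogate for the two-pathway mechanism (uncatalyzed formation
until the product reaches a critical concentration, after which the
autocatalytic cycle dominates); it is not a fitted mechanistic claim about
any specific elementary steps.  With C = A0 + B0 conserved the product
concentration has the closed form

    B(t) = (u(t) - k1) / k2,   u(t) = r / (1 + (r/u0 - 1) exp(-r t))

where u0 = k1 + k2*B0 and r = k1 + k2*C (a logistic in u).  Precursor
concentration is counted in product units (e.g. [Mo]/36 for {Mo36}) so
that A + B is conserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "KineticTrace",
    "SigmoidFit",
    "two_step_solution",
    "simulate_sigmoid",
    "fit_sigmoid",
    "finite_difference_rate",
    "absorbance_to_concentration",
    "concentration_to_absorbance",
]


@dataclass
class KineticTrace:
    """A (time, signal) series with optional spectroscopic metadata."""

    times: np.ndarray
    signal: np.ndarray
    wavelength: float | None = None
    conditions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape or self.times.ndim != 1:
            raise ValueError("times and signal must be 1-D arrays of equal length")
        if len(self.times) >= 2 and (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if not np.isfinite(self.signal).all():
            raise ValueError("signal contains non-finite values")

    def to_csv(self, path, sidecar: bool = True) -> None:
        pd.DataFrame({"time_s": self.times, "signal": self.signal}).to_csv(
            path, index=False
        )
        if sidecar:
            meta = {"wavelength_nm": self.wavelength, "conditions": self.conditions}
            Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path) -> "KineticTrace":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (time, signal)")
        wavelength = None
        conditions: dict = {}
        sidecar = Path(str(path) + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            wavelength = meta.get("wavelength_nm")
            conditions = meta.get("conditions", {})
        return cls(
            df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), wavelength, conditions
        )


@dataclass
class SigmoidFit:
    """Result of fitting the two-step autocatalytic closed form."""

    k1: float
    k2: float
    A0: float
    B0: float
    covariance: np.ndarray | None
    residual_norm: float
    success: bool = True
    message: str = ""
    fixed: dict = field(default_factory=dict)

    def predict(self, times: np.ndarray) -> np.ndarray:
        return two_step_solution(np.asarray(times, float), self.k1, self.k2, self.A0, self.B0)


def two_step_solution(
    times: np.ndarray, k1: float, k2: float, A0: float, B0: float
) -> np.ndarray:
    """Closed-form product concentration B(t) of A->B, A+B->2B."""
    t = np.asarray(times, dtype=float)
    C = A0 + B0
    if k2 <= 0:
        # pure first-order approach to completion
        return C - (C - B0) * np.exp(-k1 * t)
    r = k1 + k2 * C
    u0 = k1 + k2 * B0
    if u0 <= 0:  # k1 = 0 and B0 = 0: nothing ever forms
        return np.full_like(t, B0, dtype=float)
    u = r / (1.0 + (r / u0 - 1.0) * np.exp(-r * t))
    return (u - k1) / k2


def simulate_sigmoid(
    k1: float,
    k2: float,
    A0: float,
    B0: float,
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    wavelength: float | None = None,
    conditions: Mapping | None = None,
) -> KineticTrace:
    """Synthetic concentration trace from the closed form plus Gaussian noise."""
    if min(k1, k2, A0, B0) < 0 or noise_sd < 0:
        raise ValueError("parameters must be non-negative")
    t = np.asarray(times, dtype=float)
    y = two_step_solution(t, k1, k2, A0, B0)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.shape)
    return KineticTrace(t, y, wavelength, dict(conditions or {}))


_PARAMS = ("k1", "k2", "A0", "B0")


def fit_sigmoid(
    trace: KineticTrace,
    p0: Mapping[str, float] | None = None,
    fixed: Mapping[str, float] | None = None,
    weights: np.ndarray | None = None,
    max_nfev: int = 20_000,
) -> SigmoidFit:
    """Weighted least-squares fit of the two-step closed form.

    ``fixed`` pins parameters to known values (e.g. ``B0`` to a seeded
    product concentration).  The trace must already be in concentration
    units; convert absorbance with :func:`absorbance_to_concentration`.
    Returns a :class:`SigmoidFit` with ``success=False`` (never raises) for
    flat traces or non-convergent optimizations.
    """
    fixed = dict(fixed or {})
    t, y = trace.times, trace.signal
    scale = float(np.max(np.abs(y))) if len(y) else 0.0
    span = float(np.ptp(y)) if len(y) else 0.0
    if len(t) < 4 or span <= max(1e-12, 1e-9 * scale):
        return SigmoidFit(
            np.nan, np.nan, np.nan, np.nan, None, np.nan,
            success=False, message="flat or degenerate trace", fixed=fixed,
        )
    yf = float(np.max(y))
    guess = {
        "k1": 1.0 / (t[-1] - t[0]),
        "k2": 4.0 / (max(yf, 1e-12) * (t[-1] - t[0])),
        "A0": max(yf - float(y[0]), 1e-12),
        "B0": max(float(y[0]), 0.0),
    }
    guess.update(p0 or {})
    guess.update(fixed)
    free = [p for p in _PARAMS if p not in fixed]
    if not free:
        raise ValueError("all parameters fixed; nothing to fit")
    sigma = None if weights is None else 1.0 / np.sqrt(np.asarray(weights, float))

    def model(tt, *theta):
        kw = dict(fixed)
        kw.update(zip(free, theta))
        return two_step_solution(tt, kw["k1"], kw["k2"], kw["A0"], kw["B0"])

    x0 = [max(guess[p], 0.0) for p in free]
    try:
        popt, pcov = curve_fit(
            model, t, y, p0=x0, sigma=sigma,
            bounds=(0.0, np.inf), max_nfev=max_nfev,
        )
    except (RuntimeError, ValueError) as exc:
        return SigmoidFit(
            np.nan, np.nan, np.nan, np.nan, None, np.nan,
            success=False, message=f"optimizer failed: {exc}", fixed=fixed,
        )
    kw = dict(fixed)
    kw.update(zip(free, popt))
    resid = y - model(t, *popt)
    return SigmoidFit(
        kw["k1"], kw["k2"], kw["A0"], kw["B0"],
        pcov, float(np.linalg.norm(resid)), True, "", fixed,
    )


def finite_difference_rate(trace: KineticTrace) -> KineticTrace:
    """d(signal)/dt on the trace's own grid.

    Central differences in the interior and one-sided differences at the
    ends (second-order on non-uniform grids), applied directly to the data.
    """
    if len(trace.times) < 3:
        raise ValueError("need at least 3 points for a rate curve")
    rate = np.gradient(trace.signal, trace.times)
    return KineticTrace(trace.times, rate, trace.wavelength, dict(trace.conditions))


def absorbance_to_concentration(
    absorbance, epsilon: float, path_cm: float = 1.0
):
    """Beer-Lambert conversion c = A / (epsilon * l)."""
    if epsilon <= 0 or path_cm <= 0:
        raise ValueError("epsilon and path length must be > 0")
    return np.asarray(absorbance, dtype=float) / (epsilon * path_cm)


def concentration_to_absorbance(
    concentration, epsilon: float, path_cm: float = 1.0
):
    """Inverse Beer-Lambert conversion A = epsilon * l * c."""
    if epsilon <= 0 or path_cm <= 0:
        raise ValueError("epsilon and path length must be > 0")
    return np.asarray(concentration, dtype=float) * epsilon * path_cm
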