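"""Foliar-uptake kinetics: the SOFU statistic and the penetration-rate fit.

The foliar-uptake assay statistic R(t) = -ln(1 - M_t/M0) is linear in time
with slope equal to the penetration rate A.  Assuming the uptaken amount is
proportional to the depth gained by the surfactant within the nanopore,
M_t = B (z(0) - z(t)), the depth itself follows the exponential-saturation
law

    z(t) = (M0/B) (1 - exp(-A t))

(with depth measured downward; in this package's sign convention depths are
negative and the law reads z(t) = -(M0/B)(1 - exp(-A t))).  M0 and B are
not separately identifiable from a depth trace, so the fit reports the
lumped prefactor M0/B only.

A is reported in 1/ns; experimental SOFU rates are usually quoted in 1/h
(1 ns^-1 = 3.6e12 h^-1) -- a conversion helper is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "PenetrationTrace",
    "UptakeFit",
    "DegenerateTraceError",
    "sofu_rate",
    "uptake_from_depth",
    "fit_penetration_rate",
    "per_ns_to_per_hour",
]

log = logging.getLogger("waxpore")

NS_PER_HOUR = 3.6e12


def per_ns_to_per_hour(a_per_ns: float) -> float:
    """Convert a rate from 1/ns to 1/h for comparison with uptake assays."""
    return a_per_ns * NS_PER_HOUR


class DegenerateTraceError(ValueError):
    """Raised when a depth trace carries no penetration signal to fit."""


@dataclass
class PenetrationTrace:
    """Depth-vs-time series of the deepest molecule of a species.

    times in ns (strictly increasing), depths z(t) in nm, and the surface
    anchor z0 (the position at t = 0).
    """

    times: np.ndarray
    depths: np.ndarray
    z0: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        if self.times.shape != self.depths.shape or self.times.ndim != 1:
            raise ValueError("times and depths must be matching 1-D arrays")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def excursion(self) -> np.ndarray:
        """Depth gained below the anchor, |z0 - z(t)| as fitted."""
        return self.z0 - self.depths

    def to_table(self) -> str:
        lines = ["# time_ns\tz_nm"]
        for t, z in zip(self.times, self.depths):
            lines.append(f"{t:.6g}\t{z:.9g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_table(cls, text: str, z0: float | None = None) -> "PenetrationTrace":
        rows = [ln.split() for ln in text.splitlines()
                if ln.strip() and not ln.lstrip().startswith(("#", "@"))]
        arr = np.asarray(rows, dtype=float)
        if arr.ndim != 2 or arr.shape[1] < 2:
            raise ValueError("trace table needs two columns: time_ns, z_nm")
        return cls(times=arr[:, 0], depths=arr[:, 1],
                   z0=float(arr[0, 1]) if z0 is None else z0)


@dataclass
class UptakeFit:
    """Result of the exponential-saturation fit.

    A : penetration rate (1/ns); prefactor : lumped depth scale M0/B (nm).
    Uncertainties are 1-sigma from the least-squares covariance.
    """

    A: float
    prefactor: float
    residual_rms: float
    A_stderr: float
    prefactor_stderr: float
    n_points: int

    def report(self) -> str:
        return (
            "penetration-rate fit\n"
            f"A            = {self.A:.6g} 1/ns (+- {self.A_stderr:.2g})\n"
            f"A            = {per_ns_to_per_hour(self.A):.6g} 1/h\n"
            f"prefactor    = {self.prefactor:.6g} nm (+- {self.prefactor_stderr:.2g})\n"
            f"residual RMS = {self.residual_rms:.3g} nm over {self.n_points} points\n"
        )


def sofu_rate(times: np.ndarray, uptaken_fraction: np.ndarray) -> np.ndarray:
    """Uptake-assay statistic R(t) = -ln(1 - M_t/M0), elementwise.

    For first-order uptake M_t/M0 = 1 - exp(-A t) this is exactly A*t.
    Fractions >= 1 (complete uptake) are flagged as errors, never clipped.
    """
    times = np.asarray(times, dtype=float)
    frac = np.asarray(uptaken_fraction, dtype=float)
    if times.shape != frac.shape:
        raise ValueError("times and fractions must have the same shape")
    if np.any(frac < 0):
        raise ValueError("uptaken fraction must be >= 0")
    if np.any(frac >= 1):
        raise ValueError("uptaken fraction >= 1 (complete uptake); "
                         "R(t) is undefined there")
    return -np.log1p(-frac)


def uptake_from_depth(trace: PenetrationTrace, B: float) -> np.ndarray:
    """Uptaken amount M_t = B (z0 - z(t)) from a depth trace.

    B is the amount of AI carried per nm of surfactant penetration.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    return B * trace.excursion


def _model(t: np.ndarray, prefactor: float, A: float) -> np.ndarray:
    return prefactor * (1.0 - np.exp(-A * t))


def fit_penetration_rate(trace: PenetrationTrace) -> UptakeFit:
    """Nonlinear least-squares fit of the depth excursion to the saturation law.

    Fits |z0 - z(t)| to prefactor * (1 - exp(-A t)) by ordinary least
    squares.  Initial guesses: prefactor from the maximum excursion, A from
    the time to reach half of it.  Raises DegenerateTraceError on a flat
    trace and RuntimeError (with diagnostics) on non-convergence.
    """
    if trace.times.size < 3 or np.unique(trace.times).size < 3:
        raise ValueError("need at least 3 distinct time points to fit")
    y = np.abs(trace.excursion)
    ymax = y.max()
    if ymax <= 1e-12 or np.ptp(y) <= 1e-12:
        raise DegenerateTraceError("degenerate trace: no depth excursion to fit")

    half_idx = int(np.argmax(y >= 0.5 * ymax))
    t_half = trace.times[half_idx] if trace.times[half_idx] > 0 else (
        trace.times[-1] / 2 or 1.0)
    p0 = (ymax, 1.0 / t_half)
    try:
        popt, pcov = curve_fit(
            _model, trace.times, y, p0=p0,
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"penetration-rate fit did not converge (p0={p0}, "
            f"n={trace.times.size}): {exc}") from exc
    prefactor, A = popt
    resid = y - _model(trace.times, *popt)
    perr = np.sqrt(np.diag(pcov))
    fit = UptakeFit(
        A=float(A), prefactor=float(prefactor),
        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
        A_stderr=float(perr[1]), prefactor_stderr=float(perr[0]),
        n_points=int(trace.times.size),
    )
    if not (fit.A > 0 and fit.prefactor > 0):
        log.warning("fit returned non-positive parameters: A=%g prefactor=%g",
                    fit.A, fit.prefactor)
    return fit
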