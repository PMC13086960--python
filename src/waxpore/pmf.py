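"""Free-energy-profile post-processing.

Operates on converged 1-D and 2-D potentials of mean force (PMFs), as
produced by adaptive-bias or umbrella-sampling calculations, expressed in
kT on a reaction-coordinate grid xi (nm, the molecule's centre-of-mass
height relative to the wax surface).

Provided operations: min-shifting (the convention under which profiles are
compared), free-energy differences between caller-specified anchors (e.g.
the adsorption free energy between a surface and a bulk anchor), pore
penetration barriers reported as magnitudes, the ideal non-interacting
two-molecule reference surface PMF(xi1) + PMF(xi2), and the convergence
statistics: grid RMSD against a reference profile and the symmetry RMSD of
a two-coordinate surface.

Converged profiles of this kind typically carry an uncertainty of order
+-1.5 kT; reports round accordingly and no smaller precision is implied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "PMFProfile",
    "PMFSurface",
    "read_profile",
    "read_surface",
    "write_surface",
    "shift_min_to_zero",
    "free_energy_difference",
    "penetration_barrier",
    "ideal_pair_surface",
    "rmsd_convergence",
    "symmetry_rmsd",
]


@dataclass(frozen=True)
class PMFProfile:
    """1-D free-energy profile PMF(xi) in kT on a strictly monotonic grid."""

    xi: np.ndarray
    values: np.ndarray
    species: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "xi", np.asarray(self.xi, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.xi.ndim != 1 or self.xi.shape != self.values.shape:
            raise ValueError("xi and values must be matching 1-D arrays")
        d = np.diff(self.xi)
        if self.xi.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("xi grid must be strictly monotonic")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("PMF values must be finite")

    def ascending(self) -> "PMFProfile":
        if self.xi.size > 1 and self.xi[1] < self.xi[0]:
            return replace(self, xi=self.xi[::-1].copy(),
                           values=self.values[::-1].copy())
        return self

    def interpolate(self, x: float) -> float:
        p = self.ascending()
        if not (p.xi[0] <= x <= p.xi[-1]):
            raise ValueError(f"anchor xi = {x} nm outside the profile grid "
                             f"[{p.xi[0]}, {p.xi[-1]}]")
        return float(np.interp(x, p.xi, p.values))


@dataclass(frozen=True)
class PMFSurface:
    """2-D free-energy surface PMF(xi1, xi2) in kT."""

    xi1: np.ndarray
    xi2: np.ndarray
    values: np.ndarray
    species: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "xi1", np.asarray(self.xi1, dtype=float))
        object.__setattr__(self, "xi2", np.asarray(self.xi2, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        for g in (self.xi1, self.xi2):
            d = np.diff(g)
            if g.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("surface grids must be strictly monotonic")
        if self.values.shape != (self.xi1.size, self.xi2.size):
            raise ValueError("values matrix does not match the grids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("PMF values must be finite")


# ---------------------------------------------------------------------------
# I/O: two-column tables and the xvg dialect
# ---------------------------------------------------------------------------

def read_profile(path: str, species: str = "") -> PMFProfile:
    """Read a 1-D profile from a two-column (xi, kT) table.

    Accepts the xvg dialect: lines starting with '#' or '@' are comments.
    """
    data = np.loadtxt(path, comments=("#", "@"))
    data = np.atleast_2d(data)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (xi, PMF)")
    return PMFProfile(xi=data[:, 0], values=data[:, 1], species=species)


def write_surface(surface: PMFSurface, path: str) -> None:
    """Dense matrix with grid headers (first row xi2, first column xi1)."""
    with open(path, "w") as fh:
        fh.write("# PMF surface (kT); row grid xi1, column grid xi2\n")
        fh.write("xi1\\xi2\t" + "\t".join(f"{v:.6g}" for v in surface.xi2) + "\n")
        for x1, row in zip(surface.xi1, surface.values):
            fh.write(f"{x1:.6g}\t" + "\t".join(f"{v:.9g}" for v in row) + "\n")


def read_surface(path: str, species: str = "") -> PMFSurface:
    with open(path) as fh:
        rows = [ln.rstrip("\n") for ln in fh
                if ln.strip() and not ln.startswith(("#", "@"))]
    header = rows[0].split("\t")
    xi2 = np.asarray(header[1:], dtype=float)
    body = [r.split("\t") for r in rows[1:]]
    xi1 = np.asarray([r[0] for r in body], dtype=float)
    values = np.asarray([r[1:] for r in body], dtype=float)
    return PMFSurface(xi1=xi1, xi2=xi2, values=values, species=species)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def shift_min_to_zero(obj: PMFProfile | PMFSurface):
    """Subtract the global minimum so min(PMF) = 0 kT.  Idempotent."""
    if isinstance(obj, PMFProfile):
        return replace(obj, values=obj.values - obj.values.min())
    if isinstance(obj, PMFSurface):
        return replace(obj, values=obj.values - obj.values.min())
    raise TypeError(f"cannot min-shift {type(obj).__name__}")


def free_energy_difference(profile: PMFProfile, xi_a: float, xi_b: float) -> float:
    """PMF(xi_a) - PMF(xi_b), linearly interpolated between grid points.

    With xi_a at the adsorbed-state anchor and xi_b in the bulk this is the
    adsorption free energy (negative for spontaneous adsorption); it is
    antisymmetric in its anchors.
    """
    return profile.interpolate(xi_a) - profile.interpolate(xi_b)


def penetration_barrier(profile: PMFProfile, xi_entrance: float,
                        xi_inside: float = -3.0) -> float:
    """Pore-penetration free-energy barrier, reported as a magnitude (kT).

    The barrier between the entrance minimum and the deep-pore anchor.
    Reported positive for uphill penetration; the anchors are fully
    caller-specified (the entrance minimum position is surfactant-specific,
    e.g. 0.7 nm vs 0.4 nm for flexible- vs rigid-headed surfactants).
    """
    return abs(free_energy_difference(profile, xi_entrance, xi_inside))


def ideal_pair_surface(profile: PMFProfile) -> PMFSurface:
    """Non-interacting two-molecule reference: PMF(xi1) + PMF(xi2), min-shifted.

    The outer sum over the profile's own grid; exactly symmetric by
    construction, so its symmetry RMSD is zero.
    """
    p = profile.ascending()
    vals = p.values[:, None] + p.values[None, :]
    return shift_min_to_zero(
        PMFSurface(xi1=p.xi.copy(), xi2=p.xi.copy(), values=vals,
                   species=p.species))


def _as_values(obj: PMFProfile | PMFSurface) -> np.ndarray:
    return obj.values


def rmsd_convergence(series: Sequence[PMFProfile | PMFSurface],
                     reference: PMFProfile | PMFSurface) -> np.ndarray:
    """Grid RMSD of each profile/surface against a reference.

    RMSD(t) = sqrt( sum_grid (PMF(xi, t) - PMF_ref(xi))^2 / N ) with N the
    number of grid points; every input is min-shifted before comparison, so
    a constant offset never registers as deviation.
    """
    ref = shift_min_to_zero(reference)
    ref_vals = _as_values(ref)
    out = np.empty(len(series))
    for k, obj in enumerate(series):
        shifted = shift_min_to_zero(obj)
        vals = _as_values(shifted)
        if vals.shape != ref_vals.shape:
            raise ValueError("grid mismatch between series member and reference")
        grids_match = (
            np.array_equal(getattr(shifted, "xi", None), getattr(ref, "xi", None))
            if isinstance(shifted, PMFProfile)
            else (np.array_equal(shifted.xi1, ref.xi1)
                  and np.array_equal(shifted.xi2, ref.xi2)))
        if not grids_match:
            raise ValueError("series and reference are not on the same grid")
        out[k] = np.sqrt(np.mean((vals - ref_vals) ** 2))
    return out


def symmetry_rmsd(surface: PMFSurface) -> float:
    """Symmetry convergence statistic of a two-coordinate surface.

    sqrt( sum_{xi1, xi2} (PMF(xi1, xi2) - PMF(xi2, xi1))^2 / N ) with N the
    total number of grid points; requires xi1 and xi2 to be the same grid.
    Zero iff the surface is exactly symmetric.
    """
    if surface.xi1.size != surface.xi2.size or not np.allclose(surface.xi1,
                                                               surface.xi2):
        raise ValueError("symmetry RMSD requires a square surface with "
                         "identical xi1 and xi2 grids")
    v = surface.values
    return float(np.sqrt(np.mean((v - v.T) ** 2)))
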