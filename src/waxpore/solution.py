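"""Aqueous solution composer.

Populates the region above the wax slab with oriented surfactant monolayers
at a target surface excess Gamma, hydrophilic active-ingredient (AI)
molecules at a stated AI:surfactant molar ratio, dissolved salts, water, and
neutralising counterions.

Concentrations follow the mol-per-litre-of-water convention (water taken as
55.5 mol/L), so an AI count n_ai and water count n_water give
c_AI = n_ai * 55.5 / n_water.  All realized quantities in the composition
report are recomputed from the integer molecule counts actually placed,
never echoed from the request.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .wax_builder import StructureModel, round_half_away

__all__ = [
    "AVOGADRO",
    "WATER_MOLARITY",
    "SALTS",
    "SolutionSpec",
    "CompositionReport",
    "surfactant_count_from_gamma",
    "realized_gamma",
    "ionic_strength",
    "compose_solution",
    "neutrality_check",
]

log = logging.getLogger("waxpore")

AVOGADRO = 6.02214076e23          # 1/mol
WATER_MOLARITY = 55.5             # mol of water per litre of water
BULK_WATER_DENSITY = 33.37        # molecules / nm^3 at ambient conditions

# Fully dissociated salt formulas: species -> list of (ion label, charge, stoichiometry)
SALTS: dict[str, list[tuple[str, int, int]]] = {
    "NaCl": [("Na", +1, 1), ("Cl", -1, 1)],
    "CaCl2": [("Ca", +2, 1), ("Cl", -1, 2)],
    "KCl": [("K", +1, 1), ("Cl", -1, 1)],
    "MgCl2": [("Mg", +2, 1), ("Cl", -1, 2)],
}

ION_CHARGES = {"Na": +1, "Ca": +2, "K": +1, "Mg": +2, "Cl": -1}

# Coarse bead counts for the surfactant models (tail beads, head beads).
SURFACTANT_BEADS = {
    "C12E6": (12, 6),
    "C12E8": (12, 8),
    "C12G1": (12, 6),
    "C12G2": (12, 11),
}


@dataclass(frozen=True)
class SolutionSpec:
    """What to place above the wax.

    gamma_per_interface is the surfactant surface excess (mol/m^2) applied
    at each requested interface; 3.5e-6 is the saturated C12E6 monolayer.
    ai_to_surfactant_ratio counts surfactants at ALL interfaces (8:3 for
    C12E6, 1:1 for C12G1, 5:2 for C12G2).  Salt concentrations are mol per
    litre of water.
    """

    surfactant: str = "C12E6"
    gamma_per_interface: float = 3.5e-6
    interfaces: Literal["top", "bottom", "both"] = "both"
    ai_species: str | None = "MG"
    ai_to_surfactant_ratio: tuple[int, int] = (8, 3)
    ai_concentration: float = 2.2            # target c_AI, mol / L water
    salts: tuple[tuple[str, float], ...] = ()  # (formula, mol / L water)
    counterion: str = "Ca"
    n_water_override: int | None = None
    solution_height: float | None = None     # nm; None -> from water volume
    min_insert_distance: float = 0.25        # nm, heavy-atom exclusion
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma_per_interface < 0:
            raise ValueError("gamma must be >= 0")
        if self.interfaces not in ("top", "bottom", "both"):
            raise ValueError(f"unknown interfaces {self.interfaces!r}")
        a, s = self.ai_to_surfactant_ratio
        if a < 0 or s <= 0:
            raise ValueError("ai_to_surfactant_ratio must be nonnegative:positive integers")
        for formula, conc in self.salts:
            if formula not in SALTS:
                raise ValueError(f"unknown salt {formula!r}")
            if conc < 0:
                raise ValueError("salt concentrations must be >= 0")
        if self.ai_concentration <= 0:
            raise ValueError("ai_concentration must be positive")


@dataclass
class CompositionReport:
    n_surfactant_per_interface: dict[str, int]
    n_ai: int
    n_water: int
    n_ions: dict[str, int]
    realized_gamma: float          # mol/m^2, from counts
    realized_ai_concentration: float  # mol / L water, from counts
    net_charge: int
    area_nm2: float

    def as_dict(self) -> dict:
        return {
            "n_surfactant_per_interface": dict(self.n_surfactant_per_interface),
            "n_ai": self.n_ai,
            "n_water": self.n_water,
            "n_ions": dict(self.n_ions),
            "realized_gamma_mol_per_m2": self.realized_gamma,
            "realized_cai_mol_per_L_water": self.realized_ai_concentration,
            "net_charge": self.net_charge,
            "area_nm2": self.area_nm2,
        }


def surfactant_count_from_gamma(gamma: float, area_nm2: float) -> int:
    """Molecule count realizing surface excess ``gamma`` (mol/m^2) on ``area_nm2``.

    count = round(gamma * area * N_A); e.g. 3.5e-6 mol/m^2 on 36 nm^2 -> 76.
    """
    if gamma < 0 or area_nm2 < 0:
        raise ValueError("gamma and area must be >= 0")
    return round_half_away(gamma * area_nm2 * 1e-18 * AVOGADRO)


def realized_gamma(count: int, area_nm2: float) -> float:
    """Inverse map: surface excess (mol/m^2) realized by an integer count."""
    return count / (area_nm2 * 1e-18 * AVOGADRO)


def ionic_strength(salts: list[tuple[str, float]]) -> float:
    """Ionic strength I = 1/2 sum_i c_i z_i^2 of fully dissociated salts.

    ``salts`` is a list of (formula, concentration) pairs; concentrations in
    mol/L.  CaCl2 at 1.1 mol/L gives 0.5*(1.1*4 + 2.2*1) = 3.3 mol/L.
    """
    total = 0.0
    for formula, conc in salts:
        if formula not in SALTS:
            raise ValueError(f"unknown salt {formula!r}")
        if conc < 0:
            raise ValueError("concentration must be >= 0")
        ions = SALTS[formula]
        if sum(z * nu for _, z, nu in ions) != 0:
            raise ValueError(f"salt {formula!r} is not charge-neutral")
        total += sum(conc * nu * z * z for _, z, nu in ions)
    return 0.5 * total


def neutrality_check(model: StructureModel) -> int:
    """Net formal charge of a structure; 0 for any composed system."""
    if model.n_atoms == 0:
        return 0
    return model.total_charge()


# ---------------------------------------------------------------------------
# Placement helpers
# ---------------------------------------------------------------------------

_WATER_OH = 0.09572   # nm
_WATER_HH_HALF_ANGLE = math.radians(104.52 / 2.0)


def _water_sites(origin: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Three-site geometry-only water: O at origin, two H at the TIP-like angle."""
    # random orientation
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    v = np.cross(u, rng.normal(size=3))
    v /= np.linalg.norm(v)
    h1 = origin + _WATER_OH * (math.cos(_WATER_HH_HALF_ANGLE) * u
                               + math.sin(_WATER_HH_HALF_ANGLE) * v)
    h2 = origin + _WATER_OH * (math.cos(_WATER_HH_HALF_ANGLE) * u
                               - math.sin(_WATER_HH_HALF_ANGLE) * v)
    return np.vstack([origin, h1, h2])


def _grid_sites(box_xy: np.ndarray, z_lo: float, z_hi: float, n_needed: int,
                spacing: float, rng: np.random.Generator) -> np.ndarray:
    """Jittered-lattice insertion sites with guaranteed minimum separation.

    Sites sit on a cubic lattice of pitch >= spacing/0.8 and are jittered by
    at most 10% of the pitch per axis, so no two sites approach closer than
    0.8 * pitch >= spacing.
    """
    pitch = spacing / 0.8
    nx = max(1, int(box_xy[0] // pitch))
    ny = max(1, int(box_xy[1] // pitch))
    nz = max(1, int(math.ceil(n_needed / (nx * ny))))
    if z_lo + nz * pitch > z_hi:
        raise ValueError(
            f"requested density geometrically unplaceable: need {n_needed} sites "
            f"in {box_xy[0]:.1f} x {box_xy[1]:.1f} x {z_hi - z_lo:.1f} nm")
    gx = (np.arange(nx) + 0.5) * (box_xy[0] / nx)
    gy = (np.arange(ny) + 0.5) * (box_xy[1] / ny)
    gz = z_lo + (np.arange(nz) + 0.5) * pitch
    sites = np.array(np.meshgrid(gx, gy, gz, indexing="ij")).reshape(3, -1).T
    sites += rng.uniform(-0.1 * pitch, 0.1 * pitch, size=sites.shape)
    rng.shuffle(sites)
    return sites[:n_needed]


_BEAD_PITCH = 0.13  # nm, along the extended surfactant backbone


def _monolayer_extent(species: str) -> float:
    n_tail, n_head = SURFACTANT_BEADS.get(species, (12, 6))
    return _BEAD_PITCH * (n_tail + n_head - 1)


def _surfactant_part(species: str, n: int, area_box: np.ndarray, z_anchor: float,
                     tails_up: bool, rng: np.random.Generator) -> StructureModel | None:
    """One oriented monolayer of coarse bead-chain surfactants.

    ``z_anchor`` is the z of the bead nearest the interface the monolayer
    dresses: for the bottom (wax/solution) layer the deepest tail bead, for
    the top (air/solution) layer the topmost tail bead.  Heads always face
    the water in between.
    """
    if n == 0:
        return None
    n_tail, n_head = SURFACTANT_BEADS.get(species, (12, 6))
    n_beads = n_tail + n_head
    side = int(math.ceil(math.sqrt(n)))
    xs = (np.arange(side) + 0.5) * (area_box[0] / side)
    ys = (np.arange(side) + 0.5) * (area_box[1] / side)
    lat = np.array(np.meshgrid(xs, ys, indexing="ij")).reshape(2, -1).T[:n]
    lat += rng.uniform(-0.02, 0.02, size=lat.shape)

    if tails_up:       # top monolayer: heads below, tails reaching up to z_anchor
        beads_z = z_anchor - _BEAD_PITCH * np.arange(n_beads)          # tail..head
        bead_elems = ["C"] * n_tail + ["O"] * n_head
    else:              # bottom monolayer: tails resting on the wax, heads above
        beads_z = z_anchor + _BEAD_PITCH * np.arange(n_beads)          # tail..head
        bead_elems = ["C"] * n_tail + ["O"] * n_head

    elements, labels, chain_ids, positions, charges = [], [], [], [], []
    for mol in range(n):
        pos = np.column_stack([
            np.full(n_beads, lat[mol, 0]),
            np.full(n_beads, lat[mol, 1]),
            beads_z,
        ])
        positions.append(pos)
        elements.extend(bead_elems)
        labels.extend(["surfactant-atom"] * n_beads)
        chain_ids.extend([-1] * n_beads)
        charges.extend([0] * n_beads)
    return StructureModel(elements, np.vstack(positions), np.asarray(chain_ids),
                          labels, np.asarray(charges), np.append(area_box, 0.0))


def compose_solution(slab: StructureModel, spec: SolutionSpec
                     ) -> tuple[StructureModel, CompositionReport]:
    """Place surfactants, AI, water, salts and counterions above the slab.

    Monolayers are oriented with heads toward the water; the bottom
    (wax/solution) monolayer points tails down, the top (air/solution) one
    tails up.  The AI count follows the molar ratio applied to the total
    surfactant count; the water count targets the requested c_AI in mol per
    litre of water; counterions are added so the composed system is exactly
    net-neutral.  Insertion positions are random but non-overlapping and
    fully reproducible under the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    area = float(slab.box[0] * slab.box[1])
    n_per_iface = surfactant_count_from_gamma(spec.gamma_per_interface, area)
    ifaces = ("top", "bottom") if spec.interfaces == "both" else (spec.interfaces,)
    n_surf_total = n_per_iface * len(ifaces)

    ra, rs = spec.ai_to_surfactant_ratio
    n_ai = round_half_away(n_surf_total * ra / rs) if spec.ai_species else 0

    if spec.n_water_override is not None:
        n_water = spec.n_water_override
    elif n_ai > 0:
        n_water = round_half_away(n_ai * WATER_MOLARITY / spec.ai_concentration)
    else:
        height = spec.solution_height or 5.0
        n_water = round_half_away(BULK_WATER_DENSITY * area * height)

    n_ions: dict[str, int] = {}
    for formula, conc in spec.salts:
        n_formula = round_half_away(conc * n_water / WATER_MOLARITY)
        for ion, _z, nu in SALTS[formula]:
            n_ions[ion] = n_ions.get(ion, 0) + nu * n_formula

    # neutralize wax (e.g. COO-) plus any salt imbalance with counterions
    out = slab.copy()
    charge = out.total_charge() + sum(ION_CHARGES[i] * n for i, n in n_ions.items())
    if charge != 0:
        z_ci = ION_CHARGES.get(spec.counterion)
        if z_ci is None:
            raise ValueError(f"no counterion species declared for {spec.counterion!r}")
        if charge * z_ci > 0:
            raise ValueError(
                f"counterion {spec.counterion} cannot neutralize charge {charge:+d}")
        n_ci, rem = divmod(-charge, z_ci) if z_ci > 0 else divmod(charge, -z_ci)
        if rem:
            # e.g. odd COO- count with divalent Ca2+: drop one COO- to COOH
            coo = [i for i, lab in enumerate(out.group_labels) if lab == "COO"]
            if not coo:
                raise ValueError("impossible neutralization: residual charge "
                                 f"{rem} with counterion valence {abs(z_ci)}")
            log.warning("odd COO- count %d not divisible by counterion valence %d; "
                        "protonating one COO- to COOH", -charge, z_ci)
            out.group_labels[coo[-1]] = "COOH"
            out.formal_charges[coo[-1]] = 0
        n_ions[spec.counterion] = n_ions.get(spec.counterion, 0) + n_ci

    # --- geometry -----------------------------------------------------------
    # Solution occupies z in (0, height).  The insertion grid for point
    # molecules must clear the monolayers, so size the box from the grid
    # capacity rather than the bulk water volume alone.
    n_ion_total = sum(n_ions.values())
    n_point = n_water + n_ai + n_ion_total
    mono_pad = {i: _monolayer_extent(spec.surfactant) + 0.35 if i in ifaces else 0.35
                for i in ("top", "bottom")}
    if spec.solution_height is not None:
        height = spec.solution_height
    else:
        pitch = spec.min_insert_distance / 0.8
        per_layer = max(1, int(slab.box[0] // pitch)) * max(1, int(slab.box[1] // pitch))
        depth_needed = math.ceil(n_point / per_layer) * pitch
        height = 1.05 * depth_needed + mono_pad["top"] + mono_pad["bottom"] + 0.5

    parts = [out]
    iface_z = {"bottom": 0.05, "top": height - 0.05}
    for iface in ifaces:
        mono = _surfactant_part(spec.surfactant, n_per_iface, slab.box[:2],
                                iface_z[iface], tails_up=(iface == "top"), rng=rng)
        if mono is not None:
            parts.append(mono)

    sites = _grid_sites(slab.box[:2], mono_pad["bottom"], height - mono_pad["top"],
                        n_point, spec.min_insert_distance, rng)
    cursor = 0

    if n_ai:
        ai_pos = sites[cursor:cursor + n_ai]
        cursor += n_ai
        parts.append(StructureModel(
            ["C"] * n_ai, ai_pos, np.full(n_ai, -1), ["AI-atom"] * n_ai,
            np.zeros(n_ai, dtype=int), slab.box))
    for ion, n in sorted(n_ions.items()):
        if n == 0:
            continue
        pos = sites[cursor:cursor + n]
        cursor += n
        parts.append(StructureModel(
            [ion] * n, pos, np.full(n, -1), ["ion"] * n,
            np.full(n, ION_CHARGES[ion], dtype=int), slab.box))
    if n_water:
        origins = sites[cursor:cursor + n_water]
        cursor += n_water
        wpos = np.vstack([_water_sites(o, rng) for o in origins])
        elements = ["O", "H", "H"] * n_water
        labels = ["water-O", "water-H", "water-H"] * n_water
        parts.append(StructureModel(
            elements, wpos, np.full(3 * n_water, -1), labels,
            np.zeros(3 * n_water, dtype=int), slab.box))

    box = np.array([slab.box[0], slab.box[1], slab.box[2] + height])
    composed = StructureModel.concatenate(
        parts, box=box,
        provenance={**dict(slab.provenance), "solution": spec})

    report = CompositionReport(
        n_surfactant_per_interface={i: n_per_iface for i in ifaces},
        n_ai=n_ai,
        n_water=n_water,
        n_ions=dict(n_ions),
        realized_gamma=realized_gamma(n_per_iface, area),
        realized_ai_concentration=(n_ai * WATER_MOLARITY / n_water) if n_water else 0.0,
        net_charge=composed.total_charge(),
        area_nm2=area,
    )
    log.info("composed solution: %s", report.as_dict())
    return composed, report
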