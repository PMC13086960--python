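"""Model epicuticular wax builder.

Constructs an orthorhombic crystalline slab of all-trans alkane chains with
terminal CH3 groups exposed on the (001) surface, optionally carves a
cylindrical nanopore through it, and optionally replaces terminal CH3 groups
by carboxyl(ate) groups to model the surface charge of real plant cuticles.

Conventions
-----------
* Units: nm throughout.
* The exposed methyl surface defines z = 0; wax occupies z < 0 and the
  aqueous phase sits at z > 0.  Penetration depths are therefore negative,
  with more negative meaning deeper.
* Chains are united-atom: one site per carbon, labelled CH3 at both chain
  ends and CH2 in between.  The wax is frozen in downstream simulations, so
  only geometry, labels and formal charges matter.
* The lateral subcell is the orthorhombic polyethylene-type cell
  (a = 0.742 nm, b = 0.496 nm) with two chains per subcell in a herringbone
  arrangement (setting angles +-45 degrees).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, NamedTuple, Sequence

import numpy as np

__all__ = [
    "LatticeSpec",
    "PoreSpec",
    "FunctionalizationSpec",
    "AtomRecord",
    "StructureModel",
    "round_half_away",
    "build_chain",
    "build_crystal_slab",
    "carve_pore",
    "functionalize_surface",
]

# Formal charges of the group labels the builder can emit.
GROUP_CHARGES = {
    "CH3": 0,
    "CH2": 0,
    "COO": -1,   # deprotonated carboxylate
    "COOH": 0,
}

ATOMIC_MASSES = {
    "C": 12.011,
    "O": 15.999,
    "H": 1.008,
    "Na": 22.990,
    "Cl": 35.453,
    "Ca": 40.078,
    "X": 1.0,
}


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero.

    Used for every fractional-count conversion in the package (Python's
    built-in ``round`` rounds halves to even, which is surprising in CLI
    output).
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of the orthorhombic crystalline alkane lattice.

    Parameters
    ----------
    subcell_a, subcell_b
        Lateral subcell constants (nm); the orthorhombic polyethylene-type
        values by default.
    carbons_per_chain
        Carbons in one all-trans chain (default 30, giving a layer close to
        4 nm thick).
    cc_bond, ccc_angle
        C-C bond length (nm) and C-C-C angle (degrees) of the all-trans
        backbone.
    layer_count
        Number of stacked chain layers: 1 for the flat adsorption slab,
        4 for the pore-bearing slab.
    layer_pitch
        Vertical repeat of one layer (nm).  Default 3.75 nm so that four
        layers span exactly the 15 nm pore depth while accommodating the
        3.74 nm backbone of a C30 chain.
    """

    subcell_a: float = 0.742
    subcell_b: float = 0.496
    chains_per_subcell: int = 2
    carbons_per_chain: int = 30
    cc_bond: float = 0.154
    ccc_angle: float = 114.0
    layer_count: int = 1
    layer_pitch: float = 3.75
    setting_angle: float = 45.0

    def __post_init__(self) -> None:
        for name in ("subcell_a", "subcell_b", "cc_bond", "layer_pitch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.carbons_per_chain < 1 or self.layer_count < 1:
            raise ValueError("carbons_per_chain and layer_count must be >= 1")
        if self.chains_per_subcell != 2:
            raise ValueError("orthorhombic herringbone packing requires 2 chains per subcell")
        if not 0.0 < self.ccc_angle < 180.0:
            raise ValueError("ccc_angle must lie strictly between 0 and 180 degrees")

    @property
    def axial_rise(self) -> float:
        """Per-carbon rise along the chain axis: cc_bond * sin(angle/2)."""
        return self.cc_bond * math.sin(math.radians(self.ccc_angle) / 2.0)

    @property
    def chain_extent(self) -> float:
        """End-to-end backbone length of one all-trans chain."""
        return (self.carbons_per_chain - 1) * self.axial_rise

    @property
    def chain_area_density(self) -> float:
        """Chains per nm^2 of surface."""
        return self.chains_per_subcell / (self.subcell_a * self.subcell_b)


@dataclass(frozen=True)
class PoreSpec:
    """Cylindrical nanopore carved by whole-chain removal.

    by_count mode removes exactly ``n_remove`` chains nearest the pore axis
    in every layer spanned by ``depth`` (the paper-style pore: ~14 chains,
    accessible radius 0.75-0.8 nm).  by_radius removes every chain whose
    axis lies within accessible_radius + methyl_radius of the pore axis.
    """

    mode: Literal["by_count", "by_radius"] = "by_count"
    n_remove: int = 14
    accessible_radius: float = 0.775
    methyl_radius: float = 0.20
    center: tuple[float, float] | None = None  # None -> lateral box center
    depth: float = 15.0

    def __post_init__(self) -> None:
        if self.mode not in ("by_count", "by_radius"):
            raise ValueError(f"unknown pore mode {self.mode!r}")
        if self.accessible_radius < 0:
            raise ValueError("accessible_radius must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_remove < 0:
            raise ValueError("n_remove must be >= 0")


@dataclass(frozen=True)
class FunctionalizationSpec:
    """Replacement of terminal CH3 groups by COO- or COOH.

    ``fraction`` is the fraction of ALL CH3/CH2 carbon groups in the slab
    (the convention under which "more than 2%" neutralises the measured
    bound-Ca density); replacements are realised only at terminal CH3 sites
    on the chosen face.
    """

    group: Literal["COO_minus", "COOH"] = "COO_minus"
    fraction: float = 0.015
    face: Literal["top", "bottom", "pore_wall"] = "top"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in ("COO_minus", "COOH"):
            raise ValueError(f"unknown functional group {self.group!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.face not in ("top", "bottom", "pore_wall"):
            raise ValueError(f"unknown face {self.face!r}")

    @property
    def group_label(self) -> str:
        return "COO" if self.group == "COO_minus" else "COOH"


# ---------------------------------------------------------------------------
# Structure container
# ---------------------------------------------------------------------------

class AtomRecord(NamedTuple):
    element: str
    position: tuple[float, float, float]
    chain_id: int
    group_label: str
    formal_charge: int


@dataclass
class StructureModel:
    """Column-oriented atom collection with a rectangular box.

    Attributes
    ----------
    elements : list of chemical symbols
    positions : (n, 3) float array, nm
    chain_ids : (n,) int array; -1 for non-chain (solution) atoms
    group_labels : list of str (CH3, CH2, COO, COOH, water-O, ...)
    formal_charges : (n,) int array
    box : (3,) float array, nm
    provenance : builder parameters used, for the manifest
    """

    elements: list[str]
    positions: np.ndarray
    chain_ids: np.ndarray
    group_labels: list[str]
    formal_charges: np.ndarray
    box: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.chain_ids = np.asarray(self.chain_ids, dtype=int)
        self.formal_charges = np.asarray(self.formal_charges, dtype=int)
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.elements)
        if not (self.positions.shape[0] == self.chain_ids.size ==
                len(self.group_labels) == self.formal_charges.size == n):
            raise ValueError("inconsistent column lengths in StructureModel")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def total_charge(self) -> int:
        return int(self.formal_charges.sum())

    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield AtomRecord(
                self.elements[i],
                tuple(self.positions[i]),
                int(self.chain_ids[i]),
                self.group_labels[i],
                int(self.formal_charges[i]),
            )

    def copy(self) -> "StructureModel":
        return StructureModel(
            list(self.elements),
            self.positions.copy(),
            self.chain_ids.copy(),
            list(self.group_labels),
            self.formal_charges.copy(),
            self.box.copy(),
            dict(self.provenance),
        )

    def select(self, mask: np.ndarray) -> "StructureModel":
        idx = np.flatnonzero(mask)
        return StructureModel(
            [self.elements[i] for i in idx],
            self.positions[idx],
            self.chain_ids[idx],
            [self.group_labels[i] for i in idx],
            self.formal_charges[idx],
            self.box.copy(),
            dict(self.provenance),
        )

    @staticmethod
    def concatenate(parts: Sequence["StructureModel"], box: np.ndarray | None = None,
                    provenance: dict | None = None) -> "StructureModel":
        if not parts:
            raise ValueError("nothing to concatenate")
        return StructureModel(
            sum((list(p.elements) for p in parts), []),
            np.vstack([p.positions for p in parts]),
            np.concatenate([p.chain_ids for p in parts]),
            sum((list(p.group_labels) for p in parts), []),
            np.concatenate([p.formal_charges for p in parts]),
            np.asarray(box if box is not None else parts[0].box, dtype=float),
            provenance if provenance is not None else dict(parts[0].provenance),
        )


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_chain(lattice: LatticeSpec, orientation: str = "z") -> np.ndarray:
    """Backbone positions of one all-trans alkane chain.

    The chain's long axis is the surface normal (z); the zig-zag lies in the
    xz plane before any herringbone rotation.  Carbon 0 sits at the origin
    (the exposed CH3), subsequent carbons descend by one axial rise each:

        rise = cc_bond * sin(ccc_angle / 2)

    Returns an (n_carbons, 3) array.
    """
    if orientation != "z":
        raise ValueError("only surface-normal (z) chains are supported")
    n = lattice.carbons_per_chain
    rise = lattice.axial_rise
    sway = lattice.cc_bond * math.cos(math.radians(lattice.ccc_angle) / 2.0)
    pos = np.zeros((n, 3))
    idx = np.arange(n)
    pos[:, 0] = (idx % 2) * sway       # alternating lateral zig-zag offset
    pos[:, 2] = -idx * rise            # descending into the wax
    return pos


def _chain_lateral_sites(lattice: LatticeSpec, nx: int, ny: int) -> tuple[np.ndarray, np.ndarray]:
    """Chain-axis (x, y) sites and per-chain setting angles for an nx x ny tiling."""
    a, b = lattice.subcell_a, lattice.subcell_b
    sites = []
    angles = []
    phi = math.radians(lattice.setting_angle)
    for ix in range(nx):
        for iy in range(ny):
            x0, y0 = ix * a, iy * b
            # herringbone pair: corner chain and centre chain, opposite setting
            sites.append((x0 + a * 0.25, y0 + b * 0.25))
            angles.append(phi)
            sites.append((x0 + a * 0.75, y0 + b * 0.75))
            angles.append(-phi)
    return np.asarray(sites), np.asarray(angles)


def build_crystal_slab(lateral_target: tuple[float, float],
                       lattice: LatticeSpec | None = None) -> StructureModel:
    """Tile the orthorhombic lattice to approximate a lateral target size.

    The tiling uses nx = round(target_x / a), ny = round(target_y / b)
    subcells with two chains each; the realized box is recorded.  Chains are
    perpendicular to the surface, the terminal CH3 layer defines z = 0 and
    wax occupies z < 0.  With layer_count > 1 whole layers are stacked
    downward at the lattice's layer pitch.
    """
    lattice = lattice or LatticeSpec()
    tx, ty = lateral_target
    if tx < lattice.subcell_a or ty < lattice.subcell_b:
        raise ValueError("lateral target smaller than one subcell")
    nx = round_half_away(tx / lattice.subcell_a)
    ny = round_half_away(ty / lattice.subcell_b)
    sites, angles = _chain_lateral_sites(lattice, nx, ny)
    template = build_chain(lattice)
    zig = template[:, 0]            # in-plane zig-zag amplitude per carbon
    zs = template[:, 2]
    n_carbons = lattice.carbons_per_chain

    elements: list[str] = []
    group_labels: list[str] = []
    positions = []
    chain_ids = []
    chain_id = 0
    labels = ["CH3"] + ["CH2"] * (n_carbons - 2) + ["CH3"] if n_carbons >= 2 else ["CH3"]
    for layer in range(lattice.layer_count):
        z_off = -layer * lattice.layer_pitch
        for (sx, sy), ang in zip(sites, angles):
            # rotate the zig-zag plane by the herringbone setting angle,
            # centred on the chain axis
            dx = (zig - zig.mean()) * math.cos(ang)
            dy = (zig - zig.mean()) * math.sin(ang)
            chain_pos = np.column_stack([sx + dx, sy + dy, zs + z_off])
            positions.append(chain_pos)
            elements.extend(["C"] * n_carbons)
            group_labels.extend(labels)
            chain_ids.extend([chain_id] * n_carbons)
            chain_id += 1

    box = np.array([
        nx * lattice.subcell_a,
        ny * lattice.subcell_b,
        lattice.layer_count * lattice.layer_pitch,
    ])
    n_total = chain_id * n_carbons
    model = StructureModel(
        elements,
        np.vstack(positions),
        np.asarray(chain_ids),
        group_labels,
        np.zeros(n_total, dtype=int),
        box,
        provenance={
            "lattice": lattice,
            "nx": nx,
            "ny": ny,
            "n_chains": chain_id,
            "chain_sites": np.tile(sites, (lattice.layer_count, 1)),
        },
    )
    return model


def _pore_center(model: StructureModel, spec: PoreSpec) -> np.ndarray:
    if spec.center is not None:
        return np.asarray(spec.center, dtype=float)
    return model.box[:2] / 2.0


def _chain_axes(model: StructureModel) -> tuple[np.ndarray, np.ndarray]:
    """Unique chain ids and their lateral axis positions (mean x, y)."""
    ids = np.unique(model.chain_ids[model.chain_ids >= 0])
    axes = np.empty((ids.size, 2))
    for k, cid in enumerate(ids):
        axes[k] = model.positions[model.chain_ids == cid, :2].mean(axis=0)
    return ids, axes


def _lateral_distance(points: np.ndarray, center: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image lateral distance to a centre under xy periodicity."""
    d = points - center
    d -= np.round(d / box[:2]) * box[:2]
    return np.hypot(d[:, 0], d[:, 1])


def carve_pore(slab: StructureModel, spec: PoreSpec | None = None
               ) -> tuple[StructureModel, int]:
    """Remove whole chains to carve a cylindrical pore.

    Returns the carved structure and the number of chains removed per layer.
    Carving is a pure deletion: no surviving atom moves.  In by_count mode
    exactly ``n_remove`` chains nearest the pore axis are removed in every
    layer spanned by ``depth`` (distance ties broken by ascending chain id);
    in by_radius mode every chain whose axis lies within
    accessible_radius + methyl_radius is removed.
    """
    spec = spec or PoreSpec()
    lattice: LatticeSpec = slab.provenance.get("lattice", LatticeSpec())
    pitch = lattice.layer_pitch
    n_span = round_half_away(spec.depth / pitch)
    if abs(spec.depth - n_span * pitch) > 0.05 * pitch:
        raise ValueError(
            f"pore depth {spec.depth} nm is not a multiple of the layer pitch {pitch} nm")
    if n_span < 1:
        raise ValueError("pore depth spans no layers")
    if n_span > lattice.layer_count:
        raise ValueError(
            f"pore depth {spec.depth} nm exceeds the slab thickness "
            f"({lattice.layer_count} layers of {pitch} nm)")

    center = _pore_center(slab, spec)
    ids, axes = _chain_axes(slab)
    # layer index of each chain from its topmost atom
    top_z = np.array([slab.positions[slab.chain_ids == cid, 2].max() for cid in ids])
    layer_of = np.rint(-top_z / pitch).astype(int)
    dist = _lateral_distance(axes, center, slab.box)

    remove_ids: set[int] = set()
    per_layer = 0
    for layer in range(n_span):
        in_layer = layer_of == layer
        layer_ids = ids[in_layer]
        layer_dist = dist[in_layer]
        if spec.mode == "by_count":
            if spec.n_remove > layer_ids.size:
                raise ValueError("n_remove exceeds chains in a layer")
            order = np.lexsort((layer_ids, layer_dist))
            chosen = layer_ids[order[: spec.n_remove]]
        else:
            cut = spec.accessible_radius + spec.methyl_radius
            chosen = layer_ids[layer_dist <= cut]
        if layer == 0:
            per_layer = chosen.size
        remove_ids.update(int(c) for c in chosen)

    keep = ~np.isin(slab.chain_ids, sorted(remove_ids))
    carved = slab.select(keep)
    carved.provenance = dict(slab.provenance)
    carved.provenance.update({
        "pore": spec,
        "pore_center": tuple(center),
        "pore_removed_per_layer": per_layer,
        "pore_layers_spanned": n_span,
    })
    return carved, per_layer


def functionalize_surface(slab: StructureModel, spec: FunctionalizationSpec
                          ) -> StructureModel:
    """Replace terminal CH3 groups on one face by COO- or COOH.

    The replacement count is round(fraction x total CH3/CH2 carbons of the
    slab), realized at uniformly random (seeded) terminal CH3 sites of the
    requested face.  COO- carries formal charge -1; COOH is neutral.  These
    are the only wax groups allowed to move in downstream simulations.
    """
    n_carbons_total = sum(lab in ("CH3", "CH2") for lab in slab.group_labels)
    n_replace = round_half_away(spec.fraction * n_carbons_total)
    out = slab.copy()
    if n_replace == 0:
        return out

    lattice: LatticeSpec = slab.provenance.get("lattice", LatticeSpec())
    labels = np.asarray(slab.group_labels)
    is_ch3 = labels == "CH3"
    z = slab.positions[:, 2]
    if spec.face == "top":
        face_mask = is_ch3 & (z > -0.5 * lattice.axial_rise)
    elif spec.face == "bottom":
        face_mask = is_ch3 & (z < z.min() + 0.5 * lattice.axial_rise)
    else:  # pore_wall: terminal CH3 sites of chains bordering the carved pore
        pore = slab.provenance.get("pore")
        if pore is None:
            raise ValueError("face='pore_wall' requires a carved slab")
        center = np.asarray(slab.provenance["pore_center"])
        ids, axes = _chain_axes(slab)
        dist = _lateral_distance(axes, center, slab.box)
        margin = math.hypot(lattice.subcell_a, lattice.subcell_b)
        wall_ids = ids[dist <= pore.accessible_radius + pore.methyl_radius + margin]
        face_mask = is_ch3 & np.isin(slab.chain_ids, wall_ids)

    sites = np.flatnonzero(face_mask)
    if n_replace > sites.size:
        raise ValueError(
            f"fraction {spec.fraction} demands {n_replace} replacements but the "
            f"{spec.face} face exposes only {sites.size} terminal CH3 sites")
    rng = np.random.default_rng(spec.seed)
    chosen = rng.choice(sites, size=n_replace, replace=False)
    charge = GROUP_CHARGES[spec.group_label]
    for i in chosen:
        out.group_labels[i] = spec.group_label
        out.formal_charges[i] = charge
    out.provenance = dict(out.provenance)
    out.provenance["functionalization"] = replace(spec)
    out.provenance["n_replaced"] = int(n_replace)
    return out
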