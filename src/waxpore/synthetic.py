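"""Synthetic trajectory generation with known ground truth.

The generator stands in for the MD engine: it produces labelled multi-frame
trajectories whose penetration kinetics, water-cluster structure and ion
balance are known by construction, so every analysis stage downstream can be
validated at desk scale.  Depth kinetics follow the exponential-saturation
law

    z(t) = -(M0/B) * (1 - exp(-A t))

directly (plus optional Gaussian noise); no force-field physics is
simulated.  Times are in ns, rates in 1/ns, lengths in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .wax_builder import ATOMIC_MASSES

__all__ = [
    "Trajectory",
    "KineticsGroundTruth",
    "PoreRegion",
    "ClusterLayoutSpec",
    "PoreLayoutSpec",
    "penetration_depth_law",
    "simulate_penetration",
    "simulate_pore_system",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-ordered frames of labelled molecule coordinates.

    The molecule roster (ids, species, formal charges, site structure) is
    constant across frames; only coordinates change.

    Attributes
    ----------
    times : (n_frames,) ns, strictly increasing
    coords : (n_frames, n_sites, 3) nm
    mol_ids : (n_mol,) molecule identifiers
    species : per-molecule species labels
    charges : (n_mol,) formal charges
    site_mol : (n_sites,) index into the molecule roster for every site
    site_elements : per-site chemical symbols (for mass-weighted COM)
    box : (3,) nm; lateral (x, y) directions are periodic, z is not
    """

    times: np.ndarray
    coords: np.ndarray
    mol_ids: np.ndarray
    species: list[str]
    charges: np.ndarray
    site_mol: np.ndarray
    site_elements: list[str]
    box: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.mol_ids = np.asarray(self.mol_ids, dtype=int)
        self.charges = np.asarray(self.charges, dtype=int)
        self.site_mol = np.asarray(self.site_mol, dtype=int)
        self.box = np.asarray(self.box, dtype=float)
        if self.times.ndim != 1 or self.coords.ndim != 3:
            raise ValueError("times must be 1-D and coords (n_frames, n_sites, 3)")
        if self.coords.shape[0] != self.times.size:
            raise ValueError("frame count mismatch between times and coords")
        if self.coords.shape[1] != self.site_mol.size:
            raise ValueError("site count mismatch between coords and site_mol")
        if len(self.species) != self.mol_ids.size or self.charges.size != self.mol_ids.size:
            raise ValueError("molecule roster columns disagree in length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("time stamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def n_molecules(self) -> int:
        return self.mol_ids.size

    @property
    def n_sites(self) -> int:
        return self.site_mol.size

    def site_masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES.get(e, 1.0) for e in self.site_elements])

    def com(self, frame: int) -> np.ndarray:
        """Mass-weighted centres of mass of every molecule in one frame."""
        m = self.site_masses()
        w = np.zeros(self.n_molecules)
        np.add.at(w, self.site_mol, m)
        out = np.zeros((self.n_molecules, 3))
        for ax in range(3):
            np.add.at(out[:, ax], self.site_mol, m * self.coords[frame, :, ax])
        return out / w[:, None]

    def species_indices(self, species: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.species) == species)

    def frame_index_at(self, time: float | None) -> int:
        """Index of the frame at ``time`` (None -> final frame)."""
        if time is None:
            return self.n_frames - 1
        if time < self.times[0] - 1e-9 or time > self.times[-1] + 1e-9:
            raise ValueError(f"time {time} ns outside trajectory range "
                             f"[{self.times[0]}, {self.times[-1]}]")
        return int(np.argmin(np.abs(self.times - time)))


@dataclass(frozen=True)
class PoreRegion:
    """Cylindrical pore region: lateral axis, radius and z extent."""

    axis: tuple[float, float]
    radius: float
    z_top: float = 0.0
    z_bottom: float = -15.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.z_bottom >= self.z_top:
            raise ValueError("z_bottom must lie below z_top")


@dataclass(frozen=True)
class KineticsGroundTruth:
    """True parameters of a generated penetration trace.

    ``prefactor_true`` is the lumped depth scale M0/B (nm); ``A_true`` the
    penetration rate (1/ns).
    """

    A_true: float = 0.02
    prefactor_true: float = 3.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.A_true <= 0 or self.prefactor_true <= 0:
            raise ValueError("A_true and prefactor_true must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class ClusterLayoutSpec:
    """One water cluster: size, centre, and whether it bridges to the bulk."""

    n_waters: int
    center: tuple[float, float, float]
    bulk_connected: bool = False

    def __post_init__(self) -> None:
        if self.n_waters < 1:
            raise ValueError("cluster needs at least one water")


@dataclass(frozen=True)
class PoreLayoutSpec:
    """Ground-truth layout for a synthetic pore system.

    Clusters are placed inside the pore with intra-cluster O-O spacing below
    the clustering cutoff; distinct clusters (and the bulk slab) are kept
    farther apart than the cutoff, so the ground-truth partition is the one
    constructed.  Ion counts are per region.
    """

    clusters: tuple[ClusterLayoutSpec, ...] = ()
    ions_in_pore: tuple[tuple[str, int], ...] = ()
    ions_above: tuple[tuple[str, int], ...] = ()
    n_bulk_waters: int = 64
    intra_spacing: float = 0.28     # nm, < default cluster cutoff 0.35
    min_separation: float = 0.60    # nm, > cutoff, between distinct clusters

    def __post_init__(self) -> None:
        for _, n in self.ions_in_pore + self.ions_above:
            if n < 0:
                raise ValueError("ion counts must be >= 0")
        if self.n_bulk_waters < 0:
            raise ValueError("n_bulk_waters must be >= 0")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def penetration_depth_law(t: np.ndarray, A: float, prefactor: float) -> np.ndarray:
    """Noise-free depth law z(t) = -prefactor * (1 - exp(-A t))."""
    return -prefactor * (1.0 - np.exp(-A * np.asarray(t, dtype=float)))


def simulate_penetration(truth: KineticsGroundTruth, schedule: np.ndarray,
                         region: PoreRegion | None = None,
                         species: str = "C12E6"):
    """Emit a tracer whose depth follows the exponential-saturation law.

    Returns (trajectory, trace) where ``trace`` is the noise-free
    PenetrationTrace ground truth and the trajectory carries the noisy
    depths.  Deterministic under ``truth.seed``.
    """
    from .kinetics import PenetrationTrace  # local import: avoid cycle

    schedule = np.asarray(schedule, dtype=float)
    if schedule.size == 0:
        raise ValueError("schedule must be non-empty")
    if schedule.size > 1 and not np.all(np.diff(schedule) > 0):
        raise ValueError("schedule must be strictly increasing")
    region = region or PoreRegion(axis=(3.0, 3.0), radius=0.775)

    z_clean = penetration_depth_law(schedule, truth.A_true, truth.prefactor_true)
    rng = np.random.default_rng(truth.seed)
    z_noisy = z_clean + rng.normal(0.0, truth.noise_sigma, size=schedule.size) \
        if truth.noise_sigma > 0 else z_clean.copy()

    coords = np.zeros((schedule.size, 1, 3))
    coords[:, 0, 0] = region.axis[0]
    coords[:, 0, 1] = region.axis[1]
    coords[:, 0, 2] = z_noisy
    traj = Trajectory(
        times=schedule,
        coords=coords,
        mol_ids=np.array([0]),
        species=[species],
        charges=np.array([0]),
        site_mol=np.array([0]),
        site_elements=["X"],
        box=np.array([2 * region.axis[0], 2 * region.axis[1],
                      region.z_top - region.z_bottom]),
        metadata={"truth": truth},
    )
    trace = PenetrationTrace(times=schedule, depths=z_clean, z0=0.0)
    return traj, trace


def _cluster_positions(spec: ClusterLayoutSpec, spacing: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Compact random walk: consecutive oxygens one ``spacing`` apart.

    Consecutive-neighbour contacts guarantee the cluster is one connected
    component at any cutoff above ``spacing``.
    """
    pts = [np.asarray(spec.center, dtype=float)]
    while len(pts) < spec.n_waters:
        step = rng.normal(size=3)
        step *= spacing / np.linalg.norm(step)
        cand = pts[-1] + step
        # reject steps that land on an existing member (keeps points distinct)
        if min(np.linalg.norm(cand - p) for p in pts) > 0.12:
            pts.append(cand)
    return np.asarray(pts)


def simulate_pore_system(layout: PoreLayoutSpec, pore: PoreRegion,
                         seed: int = 0, n_frames: int = 1,
                         box: np.ndarray | None = None) -> Trajectory:
    """Build a static pore system with known cluster/ion ground truth.

    Water oxygens are placed in the requested clusters (single-site waters:
    cluster analysis keys on oxygens), a bulk slab is laid above z_top, and
    ions are dropped inside/above the pore.  A ``bulk_connected`` cluster is
    bridged to the slab by a ladder of extra waters.  Raises if the layout
    cannot keep distinct clusters separated.
    """
    rng = np.random.default_rng(seed)
    if box is None:
        box = np.array([max(6.0, 4 * pore.radius + 2), max(6.0, 4 * pore.radius + 2),
                        pore.z_top - pore.z_bottom + 4.0])
    box = np.asarray(box, dtype=float)

    groups: list[np.ndarray] = []       # water oxygen positions per logical group
    for spec in layout.clusters:
        pts = _cluster_positions(spec, layout.intra_spacing, rng)
        if spec.bulk_connected:
            # ladder from the cluster top to just above the surface; it ends
            # within one spacing of z_top so it reaches the bulk region while
            # staying clear of the slab grid itself
            top = pts[np.argmax(pts[:, 2])]
            n_steps = int(np.ceil((pore.z_top + 0.02 - top[2])
                                  / layout.intra_spacing))
            if n_steps > 0:
                ladder = top + np.outer(np.arange(1, n_steps + 1),
                                        [0.0, 0.0, layout.intra_spacing])
                pts = np.vstack([pts, ladder])
        groups.append(pts)

    # distinct clusters must stay apart (ground-truth partition well defined)
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            d = np.linalg.norm(groups[i][:, None, :] - groups[j][None, :, :], axis=-1)
            if d.min() < layout.min_separation:
                raise ValueError(
                    f"cluster layouts {i} and {j} overlap (min O-O distance "
                    f"{d.min():.2f} nm < required {layout.min_separation} nm)")

    # bulk slab above the surface; gridded at the intra spacing so the slab
    # itself is one connected component
    bulk = np.empty((0, 3))
    if layout.n_bulk_waters:
        s = layout.intra_spacing
        nx = max(1, int(box[0] // s))
        ny = max(1, int(box[1] // s))
        z0 = pore.z_top + layout.min_separation + 0.1
        cols = []
        k = 0
        layer = 0
        while k < layout.n_bulk_waters:
            take = min(nx * ny, layout.n_bulk_waters - k)
            gx = (np.arange(nx) + 0.5) * (box[0] / nx)
            gy = (np.arange(ny) + 0.5) * (box[1] / ny)
            grid = np.array(np.meshgrid(gx, gy, indexing="ij")).reshape(2, -1).T[:take]
            cols.append(np.column_stack([grid, np.full(take, z0 + layer * s)]))
            k += take
            layer += 1
        bulk = np.vstack(cols)

    positions = []
    species: list[str] = []
    charges: list[int] = []
    elements: list[str] = []
    for pts in groups:
        positions.append(pts)
        species.extend(["water"] * len(pts))
        charges.extend([0] * len(pts))
        elements.extend(["O"] * len(pts))
    if len(bulk):
        positions.append(bulk)
        species.extend(["water"] * len(bulk))
        charges.extend([0] * len(bulk))
        elements.extend(["O"] * len(bulk))

    from .solution import ION_CHARGES  # local import: avoid cycle

    def _place_ions(spec_list, z_lo, z_hi):
        for ion, n in spec_list:
            if n == 0:
                continue
            r = pore.radius * np.sqrt(rng.uniform(0.3, 0.9, size=n))
            th = rng.uniform(0, 2 * np.pi, size=n)
            zz = rng.uniform(z_lo, z_hi, size=n)
            pts = np.column_stack([pore.axis[0] + r * np.cos(th),
                                   pore.axis[1] + r * np.sin(th), zz])
            positions.append(pts)
            species.extend([ion] * n)
            charges.extend([ION_CHARGES[ion]] * n)
            elements.extend([ion] * n)

    _place_ions(layout.ions_in_pore, pore.z_bottom + 0.5, pore.z_top - 0.5)
    _place_ions(layout.ions_above, pore.z_top + 0.5, pore.z_top + 2.0)

    all_pos = np.vstack(positions) if positions else np.empty((0, 3))
    n_mol = len(species)
    coords = np.repeat(all_pos[None, :, :], n_frames, axis=0)
    times = np.arange(n_frames, dtype=float)
    return Trajectory(
        times=times,
        coords=coords,
        mol_ids=np.arange(n_mol),
        species=species,
        charges=np.asarray(charges, dtype=int),
        site_mol=np.arange(n_mol),
        site_elements=elements,
        box=box,
        metadata={"layout": layout, "pore": pore, "seed": seed},
    )
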