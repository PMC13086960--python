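"""Trajectory-derived observables.

Implements the pore-centric metrics used to characterise surfactant-assisted
uptake: deepest-water penetration depth, per-species penetration traces and
pore occupancy, in-pore net charge, molecule-location density scans, and
discrete water-cluster detection.

Geometric conventions: the exposed wax surface is z = 0 with the pore below
it; "inside the pore" means the molecule's centre of mass lies within the
pore cylinder (lateral minimum-image distance to the axis <= radius).
Lateral (x, y) directions are treated as periodic; z is not, because the
wax slab breaks z periodicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .synthetic import PoreRegion, Trajectory

__all__ = [
    "PoreRegion",
    "DensityMap",
    "ClusterSet",
    "deepest_water_depth",
    "penetration_trace",
    "occupancy_counts",
    "net_charge_in_region",
    "density_scan",
    "water_clusters",
]

WATER_SPECIES = ("water", "SOL", "HOH", "WAT")


@dataclass
class DensityMap:
    """2-D occupancy histogram accumulated over frames, one grid per species."""

    plane: str                    # "top_view" (x, y) or "side_view" (x, z)
    bin_width: float
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: dict[str, np.ndarray]
    frame_count: int

    def per_frame(self, species: str) -> np.ndarray:
        return self.counts[species] / self.frame_count

    def to_table(self, species: str) -> str:
        """Delimited grid export: a header with the edges, then the matrix."""
        lines = [
            f"# plane {self.plane} bin_width {self.bin_width} frames {self.frame_count}",
            "# x_edges " + " ".join(f"{v:.6g}" for v in self.x_edges),
            "# y_edges " + " ".join(f"{v:.6g}" for v in self.y_edges),
        ]
        for row in self.counts[species]:
            lines.append("\t".join(f"{v:.6g}" for v in row))
        return "\n".join(lines) + "\n"

    def render(self, species: str, path: str) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.pcolormesh(self.x_edges, self.y_edges, self.counts[species].T, cmap="inferno")
        ax.set_xlabel("x (nm)")
        ax.set_ylabel("y (nm)" if self.plane == "top_view" else "z (nm)")
        ax.set_title(species)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


@dataclass
class ClusterSet:
    """Partition of the selected water oxygens into contact clusters."""

    cutoff: float
    clusters: list[frozenset[int]]           # member molecule ids
    bulk_connected: list[bool]
    frame_time: float = 0.0

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def discrete_clusters(self) -> list[frozenset[int]]:
        """Clusters not connected to the bulk aqueous phase."""
        return [c for c, b in zip(self.clusters, self.bulk_connected) if not b]


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _lateral_inside(com: np.ndarray, region: PoreRegion, box: np.ndarray) -> np.ndarray:
    d = com[:, :2] - np.asarray(region.axis)
    d -= np.round(d / box[:2]) * box[:2]
    return np.hypot(d[:, 0], d[:, 1]) <= region.radius


def _in_cylinder(com: np.ndarray, region: PoreRegion, box: np.ndarray) -> np.ndarray:
    return (_lateral_inside(com, region, box)
            & (com[:, 2] >= region.z_bottom) & (com[:, 2] <= region.z_top))


def _frame_range(traj: Trajectory, discard: float) -> range:
    if not 0.0 <= discard < 1.0:
        raise ValueError("discard fraction must lie in [0, 1)")
    start = int(np.floor(discard * traj.n_frames))
    return range(start, traj.n_frames)


def _water_mask(traj: Trajectory) -> np.ndarray:
    return np.isin(np.asarray(traj.species), WATER_SPECIES)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def deepest_water_depth(traj: Trajectory, region: PoreRegion,
                        discard: float = 0.0) -> float:
    """Trajectory-averaged depth of the most deeply penetrating water.

    Per frame, the minimum water centre-of-mass z among waters laterally
    inside the pore cylinder; the result is the average over the analysed
    frames.  Negative values mean inside the pore.
    """
    if traj.n_frames == 0:
        raise ValueError("trajectory has no frames")
    widx = np.flatnonzero(_water_mask(traj))
    if widx.size == 0:
        raise ValueError("trajectory contains no water molecules")
    minima = []
    for f in _frame_range(traj, discard):
        com = traj.com(f)[widx]
        inside = _lateral_inside(com, region, traj.box)
        if not inside.any():
            continue
        minima.append(com[inside, 2].min())
    if not minima:
        raise ValueError("no water inside the pore region in any analysed frame")
    return float(np.mean(minima))


def penetration_trace(traj: Trajectory, species: str, region: PoreRegion):
    """Depth-vs-time series z(t) for the deepest molecule of one species.

    z(t) is the minimum centre-of-mass z among molecules of the species
    laterally inside the pore in each frame; z(0), the value in the first
    frame, anchors the surface position z0.
    """
    from .kinetics import PenetrationTrace  # local import: avoid cycle

    sidx = traj.species_indices(species)
    if sidx.size == 0:
        raise ValueError(f"species {species!r} absent from trajectory")
    depths = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        com = traj.com(f)[sidx]
        inside = _lateral_inside(com, region, traj.box)
        sel = com[inside, 2] if inside.any() else com[:, 2]
        depths[f] = sel.min()
    return PenetrationTrace(times=traj.times.copy(), depths=depths,
                            z0=float(depths[0]))


def occupancy_counts(traj: Trajectory, region: PoreRegion,
                     species: list[str] | None = None,
                     time: float | None = None) -> dict[str, int]:
    """Molecules of each species inside the pore cylinder at one time.

    Default time is the final frame (the paper-style "uptaken in 200 ns"
    reading); counts key on centre-of-mass position.
    """
    f = traj.frame_index_at(time)
    com = traj.com(f)
    inside = _in_cylinder(com, region, traj.box)
    all_species = np.asarray(traj.species)
    if species is None:
        species = sorted(set(traj.species))
    return {s: int(np.count_nonzero(inside & (all_species == s))) for s in species}


def net_charge_in_region(traj: Trajectory, region: PoreRegion,
                         time: float | None = None) -> int:
    """Sum of formal charges of molecules inside the region at one time."""
    f = traj.frame_index_at(time)
    inside = _in_cylinder(traj.com(f), region, traj.box)
    return int(traj.charges[inside].sum())


def density_scan(traj: Trajectory, plane: str = "side_view",
                 bin_width: float = 0.1,
                 species: list[str] | None = None,
                 extent: tuple[tuple[float, float], tuple[float, float]] | None = None,
                 ) -> DensityMap:
    """Molecule-location scan: 2-D histogram of COM positions over frames.

    ``plane`` selects the projection: "top_view" bins (x, y), "side_view"
    bins (x, z).  The grid spans ``extent`` if given, else the data range,
    so every observation is in range and the counts conserve the total.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if plane not in ("top_view", "side_view"):
        raise ValueError(f"unknown plane {plane!r}")
    cols = (0, 1) if plane == "top_view" else (0, 2)
    if species is None:
        species = sorted(set(traj.species))

    coms = np.stack([traj.com(f) for f in range(traj.n_frames)])  # (F, M, 3)
    u = coms[:, :, cols[0]]
    v = coms[:, :, cols[1]]
    if extent is None:
        lo_u, hi_u = float(u.min()), float(u.max())
        lo_v, hi_v = float(v.min()), float(v.max())
    else:
        (lo_u, hi_u), (lo_v, hi_v) = extent
    if hi_u <= lo_u or hi_v <= lo_v:
        raise ValueError("degenerate scan extent")
    nx = max(1, int(np.ceil((hi_u - lo_u) / bin_width)))
    ny = max(1, int(np.ceil((hi_v - lo_v) / bin_width)))
    x_edges = lo_u + bin_width * np.arange(nx + 1)
    y_edges = lo_v + bin_width * np.arange(ny + 1)

    all_species = np.asarray(traj.species)
    counts = {}
    for s in species:
        m = all_species == s
        h, _, _ = np.histogram2d(u[:, m].ravel(), v[:, m].ravel(),
                                 bins=[x_edges, y_edges])
        counts[s] = h
    return DensityMap(plane=plane, bin_width=bin_width, x_edges=x_edges,
                      y_edges=y_edges, counts=counts, frame_count=traj.n_frames)


def water_clusters(traj: Trajectory, frame: int = -1, cutoff: float = 0.35,
                   bulk_z_top: float = 0.0) -> ClusterSet:
    """Discrete water clusters: connected components of the O-O contact graph.

    Two waters are in contact when their oxygen-oxygen distance (lateral
    minimum image) is below ``cutoff`` (default 0.35 nm, the first hydration
    shell).  A cluster is bulk-connected when any member lies in the bulk
    slab region (z > ``bulk_z_top``) or within ``cutoff`` of a member that
    does.  The partition is independent of molecule ordering.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if frame < 0:
        frame = traj.n_frames + frame
    widx = np.flatnonzero(_water_mask(traj))
    mol_ids = traj.mol_ids[widx]
    if widx.size == 0:
        return ClusterSet(cutoff=cutoff, clusters=[], bulk_connected=[],
                          frame_time=float(traj.times[frame]))

    # oxygen position of each water: first O site of the molecule
    elems = np.asarray(traj.site_elements)
    opos = np.empty((widx.size, 3))
    for k, mi in enumerate(widx):
        sites = np.flatnonzero(traj.site_mol == mi)
        osites = sites[elems[sites] == "O"]
        opos[k] = traj.coords[frame, osites[0] if osites.size else sites[0]]

    # contact graph under lateral periodicity: replicate via KD-tree on the
    # wrapped coordinates with boxsize in x, y only (z padded out of reach)
    box = traj.box
    wrapped = opos.copy()
    wrapped[:, 0] %= box[0]
    wrapped[:, 1] %= box[1]
    zspan = wrapped[:, 2].max() - wrapped[:, 2].min() + 10 * cutoff
    shifted = wrapped.copy()
    shifted[:, 2] -= wrapped[:, 2].min()
    tree = cKDTree(shifted, boxsize=[box[0], box[1], zspan + 1.0])
    pairs = tree.query_pairs(cutoff, output_type="ndarray")

    n = widx.size
    if len(pairs):
        data = np.ones(len(pairs))
        g = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        g = coo_matrix((n, n))
    n_comp, labels = connected_components(g, directed=False)

    in_bulk = opos[:, 2] > bulk_z_top
    clusters = []
    flags = []
    for c in range(n_comp):
        members = labels == c
        clusters.append(frozenset(int(m) for m in mol_ids[members]))
        # any member in the bulk region, or (transitively, via the contact
        # graph) within cutoff of one that is -- the component already closes
        # over contacts, so membership in the bulk region suffices
        flags.append(bool(in_bulk[members].any()))
    order = np.argsort([min(c) for c in clusters])
    return ClusterSet(cutoff=cutoff,
                      clusters=[clusters[i] for i in order],
                      bulk_connected=[flags[i] for i in order],
                      frame_time=float(traj.times[frame]))
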