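"""File formats, run configuration, and the pipeline driver.

Internal units are fixed (nm, ns, kT, mol/m^2, mol per litre of water);
conversions happen only at format boundaries (PDB is written in Angstrom).

Formats
-------
* GRO (fixed-column, nm) for structures and multi-frame trajectories; the
  fixed columns are authoritative, so write -> read -> write is
  byte-identical.
* XYZ with an extended comment line (``t= <ns> box= <bx> <by> <bz>``) and
  full floating-point precision, so trajectories round-trip bit-identically
  through write -> read.
* PDB (Angstrom, CRYST1 box) for structure export.
* A sidecar species map (TSV: molecule_id, species, formal charge, sites)
  carries the chemistry that coordinate formats cannot.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import numpy as np
import yaml

from .wax_builder import (GROUP_CHARGES, FunctionalizationSpec, LatticeSpec,
                          PoreSpec, StructureModel, build_crystal_slab,
                          carve_pore, functionalize_surface)
from .solution import ION_CHARGES, SolutionSpec, compose_solution
from .synthetic import (KineticsGroundTruth, PoreLayoutSpec, ClusterLayoutSpec,
                        PoreRegion, Trajectory, simulate_penetration,
                        simulate_pore_system)
from . import metrics as _metrics
from .kinetics import PenetrationTrace, fit_penetration_rate

__all__ = [
    "write_structure",
    "read_structure",
    "write_trajectory",
    "read_trajectory",
    "write_species_map",
    "read_species_map",
    "RunConfig",
    "derive_seed",
    "run_pipeline",
    "setup_logging",
]

log = logging.getLogger("waxpore")

# group label <-> GRO/PDB residue name
_LABEL_TO_RES = {
    "CH3": "CH3", "CH2": "CH2", "COO": "COO", "COOH": "COOH",
    "water-O": "SOL", "water-H": "SOL", "ion": "ION",
    "surfactant-atom": "SURF", "AI-atom": "AI",
}
_RES_TO_LABEL = {
    "CH3": "CH3", "CH2": "CH2", "COO": "COO", "COOH": "COOH",
    "ION": "ion", "SURF": "surfactant-atom", "AI": "AI-atom",
}


def setup_logging(level: str = "INFO", json_lines: bool = False) -> None:
    """Logging to stderr; optionally machine-readable JSON lines."""
    handler = logging.StreamHandler(sys.stderr)
    if json_lines:
        class _JsonFormatter(logging.Formatter):
            def format(self, record: logging.LogRecord) -> str:
                return json.dumps({"level": record.levelname,
                                   "name": record.name,
                                   "msg": record.getMessage()})
        handler.setFormatter(_JsonFormatter())
    else:
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("waxpore")
    root.handlers[:] = [handler]
    root.setLevel(level.upper())


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def _charge_for(label: str, element: str) -> int:
    if label in GROUP_CHARGES:
        return GROUP_CHARGES[label]
    if label == "ion":
        return ION_CHARGES.get(element, 0)
    return 0


def write_structure(model: StructureModel, path: str | Path) -> None:
    path = Path(path)
    fmt = path.suffix.lower().lstrip(".")
    if fmt == "gro":
        _write_gro_structure(model, path)
    elif fmt == "pdb":
        _write_pdb_structure(model, path)
    else:
        raise ValueError(f"unknown structure format {fmt!r}")


def read_structure(path: str | Path) -> StructureModel:
    path = Path(path)
    fmt = path.suffix.lower().lstrip(".")
    if fmt == "gro":
        return _read_gro_structure(path)
    if fmt == "pdb":
        return _read_pdb_structure(path)
    raise ValueError(f"unknown structure format {fmt!r}")


def _gro_atom_line(serial: int, resid: int, resname: str, name: str,
                   pos: np.ndarray) -> str:
    return (f"{resid % 100000:5d}{resname:<5.5s}{name:>5.5s}{serial % 100000:5d}"
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}\n")


def _write_gro_structure(model: StructureModel, path: Path, title: str = "waxpore structure") -> None:
    with open(path, "w") as fh:
        fh.write(title + "\n")
        fh.write(f"{model.n_atoms:5d}\n")
        for i in range(model.n_atoms):
            resid = int(model.chain_ids[i]) + 1 if model.chain_ids[i] >= 0 else 0
            resname = _LABEL_TO_RES.get(model.group_labels[i], "UNK")
            fh.write(_gro_atom_line(i + 1, resid, resname, model.elements[i],
                                    model.positions[i]))
        fh.write(f"{model.box[0]:10.5f}{model.box[1]:10.5f}{model.box[2]:10.5f}\n")


def _parse_gro_atom(line: str, lineno: int) -> tuple[int, str, str, np.ndarray]:
    try:
        resid = int(line[0:5])
        resname = line[5:10].strip()
        name = line[10:15].strip()
        pos = np.array([float(line[20:28]), float(line[28:36]), float(line[36:44])])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed GRO atom record at line {lineno}: {line!r}") from exc
    return resid, resname, name, pos


def _label_from(resname: str, name: str) -> str:
    if resname == "SOL":
        return "water-O" if name.startswith("O") else "water-H"
    return _RES_TO_LABEL.get(resname, resname)


def _read_gro_structure(path: Path) -> StructureModel:
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ValueError(f"{path}: truncated GRO file (line 2: atom count missing)")
    try:
        n = int(lines[1].strip())
    except ValueError as exc:
        raise ValueError(f"{path}: malformed atom count at line 2") from exc
    if len(lines) < n + 3:
        raise ValueError(f"{path}: truncated GRO file at line {len(lines) + 1} "
                         f"(expected {n} atoms plus a box line)")
    elements, labels, chain_ids, positions, charges = [], [], [], [], []
    for k in range(n):
        resid, resname, name, pos = _parse_gro_atom(lines[2 + k], 3 + k)
        label = _label_from(resname, name)
        element = "".join(c for c in name if not c.isdigit()) or "X"
        elements.append(element)
        labels.append(label)
        chain_ids.append(resid - 1 if label in GROUP_CHARGES else -1)
        positions.append(pos)
        charges.append(_charge_for(label, element))
    box_fields = lines[2 + n].split()
    if len(box_fields) < 3:
        raise ValueError(f"{path}: missing box line at line {3 + n}")
    box = np.array(box_fields[:3], dtype=float)
    return StructureModel(elements, np.array(positions), np.array(chain_ids),
                          labels, np.array(charges), box)


def _write_pdb_structure(model: StructureModel, path: Path) -> None:
    with open(path, "w") as fh:
        a, b, c = model.box * 10.0  # nm -> Angstrom
        fh.write(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
        for i in range(model.n_atoms):
            x, y, z = model.positions[i] * 10.0
            resname = _LABEL_TO_RES.get(model.group_labels[i], "UNK")
            resid = int(model.chain_ids[i]) + 1 if model.chain_ids[i] >= 0 else 0
            fh.write(
                f"ATOM  {(i + 1) % 100000:5d} {model.elements[i]:<4.4s} {resname:<4.4s} "
                f"{resid % 10000:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {model.elements[i]:>2.2s}\n")
        fh.write("END\n")


def _read_pdb_structure(path: Path) -> StructureModel:
    elements, labels, chain_ids, positions, charges = [], [], [], [], []
    box = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if line.startswith("CRYST1"):
            try:
                box = np.array([float(line[6:15]), float(line[15:24]),
                                float(line[24:33])]) / 10.0
            except ValueError as exc:
                raise ValueError(f"{path}: malformed CRYST1 at line {lineno}") from exc
        elif line.startswith(("ATOM  ", "HETATM")):
            try:
                name = line[12:16].strip()
                resname = line[17:21].strip()
                resid = int(line[22:26])
                pos = np.array([float(line[30:38]), float(line[38:46]),
                                float(line[46:54])]) / 10.0
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed ATOM record at line {lineno}") from exc
            label = _label_from(resname, name)
            element = line[76:78].strip() or name
            elements.append(element)
            labels.append(label)
            chain_ids.append(resid - 1 if label in GROUP_CHARGES else -1)
            positions.append(pos)
            charges.append(_charge_for(label, element))
    if box is None:
        raise ValueError(f"{path}: no CRYST1 record; a box is required")
    return StructureModel(elements, np.array(positions), np.array(chain_ids),
                          labels, np.array(charges), box)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def write_species_map(traj: Trajectory, path: str | Path) -> None:
    """Sidecar TSV: molecule_id, species, formal charge, site count, site elements."""
    with open(path, "w") as fh:
        fh.write("# molecule_id\tspecies\tcharge\tn_sites\tsite_elements\n")
        for k, mid in enumerate(traj.mol_ids):
            sites = np.flatnonzero(traj.site_mol == k)
            elems = ",".join(traj.site_elements[s] for s in sites)
            fh.write(f"{int(mid)}\t{traj.species[k]}\t{int(traj.charges[k])}\t"
                     f"{sites.size}\t{elems}\n")


def read_species_map(path: str | Path):
    mol_ids, species, charges, n_sites, site_elements = [], [], [], [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        mid, sp, q, ns, elems = line.split("\t")
        mol_ids.append(int(mid))
        species.append(sp)
        charges.append(int(q))
        n_sites.append(int(ns))
        site_elements.extend(elems.split(","))
    return (np.asarray(mol_ids), species, np.asarray(charges),
            np.asarray(n_sites), site_elements)


def write_trajectory(traj: Trajectory, path: str | Path,
                     species_map: str | Path | None = None) -> None:
    path = Path(path)
    fmt = path.suffix.lower().lstrip(".")
    if fmt == "gro":
        _write_gro_trajectory(traj, path)
    elif fmt == "xyz":
        _write_xyz_trajectory(traj, path)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")
    if species_map is not None:
        write_species_map(traj, species_map)


def read_trajectory(path: str | Path,
                    species_map: str | Path | None = None) -> Trajectory:
    path = Path(path)
    fmt = path.suffix.lower().lstrip(".")
    if fmt == "gro":
        traj = _read_gro_trajectory(path)
    elif fmt == "xyz":
        traj = _read_xyz_trajectory(path)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")
    if species_map is not None:
        mol_ids, species, charges, n_sites, site_elements = read_species_map(species_map)
        if mol_ids.size != traj.n_molecules and int(n_sites.sum()) == traj.n_sites:
            # coordinate formats may not delimit molecules; rebuild the roster
            site_mol = np.repeat(np.arange(mol_ids.size), n_sites)
            traj = Trajectory(traj.times, traj.coords, mol_ids, species,
                              charges, site_mol, site_elements, traj.box,
                              traj.metadata)
        else:
            if int(n_sites.sum()) != traj.n_sites:
                raise ValueError("species map does not match trajectory site count")
            traj.mol_ids = mol_ids
            traj.species = species
            traj.charges = charges
            traj.site_mol = np.repeat(np.arange(mol_ids.size), n_sites)
            traj.site_elements = site_elements
    return traj


def _write_gro_trajectory(traj: Trajectory, path: Path) -> None:
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"frame t= {traj.times[f]:.6f}\n")
            fh.write(f"{traj.n_sites:5d}\n")
            for s in range(traj.n_sites):
                mol = traj.site_mol[s]
                fh.write(_gro_atom_line(s + 1, int(traj.mol_ids[mol]) + 1,
                                        traj.species[mol][:5],
                                        traj.site_elements[s],
                                        traj.coords[f, s]))
            fh.write(f"{traj.box[0]:10.5f}{traj.box[1]:10.5f}{traj.box[2]:10.5f}\n")


def _read_gro_trajectory(path: Path) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    frames, times = [], []
    roster: list[tuple[int, str, str]] | None = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        t = 0.0
        if "t=" in title:
            t = float(title.split("t=")[1].split()[0])
        try:
            n = int(lines[i + 1].strip())
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}: malformed frame header at line {i + 2}") from exc
        if i + 2 + n >= len(lines) + 1 and len(lines) < i + 3 + n:
            raise ValueError(f"{path}: truncated frame at line {len(lines)}")
        this_roster = []
        pos = np.empty((n, 3))
        for k in range(n):
            resid, resname, name, p = _parse_gro_atom(lines[i + 2 + k], i + 3 + k)
            this_roster.append((resid, resname, name))
            pos[k] = p
        box = np.array(lines[i + 2 + n].split()[:3], dtype=float)
        if roster is None:
            roster = this_roster
        elif this_roster != roster:
            raise ValueError(f"{path}: molecule roster changes at frame {len(frames)}")
        frames.append(pos)
        times.append(t)
        i += n + 3

    if roster is None:
        raise ValueError(f"{path}: empty trajectory")
    resids = [r for r, _, _ in roster]
    uniq = sorted(set(resids), key=resids.index)
    mol_of_res = {r: k for k, r in enumerate(uniq)}
    site_mol = np.array([mol_of_res[r] for r in resids])
    species = [""] * len(uniq)
    for (r, resname, _), m in zip(roster, site_mol):
        species[m] = resname
    site_elements = ["".join(c for c in name if not c.isdigit()) or "X"
                     for _, _, name in roster]
    charges = np.array([ION_CHARGES.get(sp, 0) for sp in species])
    return Trajectory(np.asarray(times), np.stack(frames),
                      np.asarray(uniq) - 1, species, charges, site_mol,
                      site_elements, box)


def _write_xyz_trajectory(traj: Trajectory, path: Path) -> None:
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_sites}\n")
            fh.write(f"t= {float(traj.times[f])!r} box= {float(traj.box[0])!r} "
                     f"{float(traj.box[1])!r} {float(traj.box[2])!r}\n")
            for s in range(traj.n_sites):
                x, y, z = (float(v) for v in traj.coords[f, s])
                fh.write(f"{traj.site_elements[s]} {x!r} {y!r} {z!r}\n")


def _read_xyz_trajectory(path: Path) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    frames, times = [], []
    box = np.array([0.0, 0.0, 0.0])
    elements: list[str] | None = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        comment = lines[i + 1]
        t = float(comment.split("t=")[1].split()[0]) if "t=" in comment else 0.0
        if "box=" in comment:
            box = np.array(comment.split("box=")[1].split()[:3], dtype=float)
        this_elements = []
        pos = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 2 + k].split()
            this_elements.append(parts[0])
            pos[k] = [float(v) for v in parts[1:4]]
        if elements is None:
            elements = this_elements
        elif this_elements != elements:
            raise ValueError(f"{path}: site roster changes at frame {len(frames)}")
        frames.append(pos)
        times.append(t)
        i += n + 2
    if elements is None:
        raise ValueError(f"{path}: empty trajectory")
    n_sites = len(elements)
    return Trajectory(np.asarray(times), np.stack(frames),
                      np.arange(n_sites), list(elements),
                      np.zeros(n_sites, dtype=int), np.arange(n_sites),
                      elements, box)


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------

def derive_seed(global_seed: int, tag: str) -> int:
    """Stable per-stage seed below 2**31, derived from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _spec_from_dict(cls, data: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = dict(data)
    for f in fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            coerced[f.name] = tuple(
                tuple(v) if isinstance(v, list) else v for v in coerced[f.name])
    return cls(**coerced)


@dataclass
class RunConfig:
    """Declarative description of a full pipeline run.

    Every stochastic stage receives a seed derived from ``seed``; the config
    round-trips losslessly through YAML.
    """

    stages: tuple[str, ...] = ("build", "compose", "synth", "metrics", "kinetics")
    lateral: tuple[float, float] = (6.0, 6.0)
    lattice: dict = field(default_factory=dict)
    pore: dict | None = field(default_factory=dict)
    functionalization: dict | None = None
    solution: dict | None = field(default_factory=dict)
    kinetics_truth: dict = field(default_factory=dict)
    schedule: dict = field(default_factory=lambda: {"t_end": 200.0, "n": 401})
    region: dict = field(default_factory=dict)
    pmf_profile: str | None = None
    pmf_anchors: dict = field(default_factory=lambda: {
        "xi_surface": 3.0, "xi_bulk": 0.25, "xi_entrance": 0.7, "xi_inside": -3.0})
    seed: int = 0
    outdir: str = "waxpore_out"
    log_level: str = "INFO"

    _KNOWN_STAGES = ("build", "compose", "synth", "metrics", "kinetics", "pmf")

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        self.lateral = tuple(self.lateral)
        for s in self.stages:
            if s not in self._KNOWN_STAGES:
                raise ValueError(f"unknown stage {s!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        allowed = {f.name for f in fields(cls) if not f.name.startswith("_")}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            if f.name.startswith("_"):
                continue
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = list(v)
            out[f.name] = v
        return out

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        d = {k: v for k, v in self.to_dict().items()
             if k not in ("outdir", "log_level")}
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages and emit a manifest.

    Stage order: build -> compose -> synth -> metrics -> kinetics -> pmf.
    The manifest lists every output with the config hash and the per-stage
    seeds; any stage failure aborts with the stage name attached.
    """
    setup_logging(config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {},
        "outputs": {},
        "results": {},
    }
    state: dict = {}
    stage = "?"
    try:
        for stage in config.stages:
            _STAGE_RUNNERS[stage](config, state, manifest, outdir)
    except Exception as exc:
        manifest["failed_stage"] = stage
        (outdir / "manifest.partial.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    manifest["outputs"]["manifest"] = str(outdir / "manifest.json")
    return manifest


def _default_region(config: RunConfig, state: dict) -> PoreRegion:
    reg = dict(config.region)
    slab = state.get("slab")
    axis = tuple(reg.pop("axis", ())) or (
        tuple(np.asarray(slab.box[:2]) / 2) if slab is not None else (3.0, 3.0))
    region = PoreRegion(axis=axis, radius=reg.pop("radius", 0.975),
                        z_top=reg.pop("z_top", 0.0),
                        z_bottom=reg.pop("z_bottom", -15.0))
    if reg:
        raise ValueError(f"unknown region keys: {sorted(reg)}")
    return region


def _stage_build(config, state, manifest, outdir):
    ldata = dict(config.lattice)
    if config.pore is not None and "layer_count" not in ldata:
        ldata["layer_count"] = 4  # the pore-bearing slab spans four layers
    lattice = _spec_from_dict(LatticeSpec, ldata)
    slab = build_crystal_slab(config.lateral, lattice)
    if config.pore is not None:
        pore = _spec_from_dict(PoreSpec, config.pore)
        slab, per_layer = carve_pore(slab, pore)
        manifest["results"]["chains_removed_per_layer"] = per_layer
    if config.functionalization is not None:
        fdata = dict(config.functionalization)
        fdata.setdefault("seed", derive_seed(config.seed, "functionalize"))
        fspec = _spec_from_dict(FunctionalizationSpec, fdata)
        manifest["stage_seeds"]["functionalize"] = fdata["seed"]
        slab = functionalize_surface(slab, fspec)
        manifest["results"]["n_replaced"] = slab.provenance["n_replaced"]
    out = outdir / "slab.gro"
    write_structure(slab, out)
    manifest["outputs"]["slab"] = str(out)
    state["slab"] = slab


def _stage_compose(config, state, manifest, outdir):
    if "slab" not in state:
        raise ValueError("compose stage requires the build stage")
    sdata = dict(config.solution or {})
    sdata.setdefault("seed", derive_seed(config.seed, "compose"))
    spec = _spec_from_dict(SolutionSpec, sdata)
    manifest["stage_seeds"]["compose"] = sdata["seed"]
    composed, report = compose_solution(state["slab"], spec)
    out = outdir / "system.gro"
    write_structure(composed, out)
    rep = outdir / "composition.txt"
    rep.write_text("".join(f"{k} = {v}\n" for k, v in report.as_dict().items()))
    manifest["outputs"]["system"] = str(out)
    manifest["outputs"]["composition"] = str(rep)
    manifest["results"]["composition"] = report.as_dict()
    state["composed"] = composed
    state["report"] = report


def _stage_synth(config, state, manifest, outdir):
    tdata = dict(config.kinetics_truth)
    tdata.setdefault("seed", derive_seed(config.seed, "synth"))
    truth = _spec_from_dict(KineticsGroundTruth, tdata)
    manifest["stage_seeds"]["synth"] = tdata["seed"]
    sched = np.linspace(0.0, config.schedule.get("t_end", 200.0),
                        int(config.schedule.get("n", 401)))
    region = _default_region(config, state)
    traj, trace = simulate_penetration(truth, sched, region)
    tout = outdir / "penetration.xyz"
    write_trajectory(traj, tout, species_map=outdir / "penetration.species.tsv")
    (outdir / "penetration.truth.txt").write_text(
        f"A_true = {truth.A_true}\nprefactor_true = {truth.prefactor_true}\n"
        f"noise_sigma = {truth.noise_sigma}\nseed = {truth.seed}\n")
    manifest["outputs"]["penetration_traj"] = str(tout)

    pore_seed = derive_seed(config.seed, "pore_system")
    manifest["stage_seeds"]["pore_system"] = pore_seed
    layout = PoreLayoutSpec(
        clusters=(ClusterLayoutSpec(6, (region.axis[0], region.axis[1], -2.0)),
                  ClusterLayoutSpec(4, (region.axis[0], region.axis[1], -6.0))),
        ions_in_pore=(("Na", 3), ("Cl", 3)),
        n_bulk_waters=49)
    psys = simulate_pore_system(layout, region, seed=pore_seed)
    pout = outdir / "pore_system.xyz"
    write_trajectory(psys, pout, species_map=outdir / "pore_system.species.tsv")
    manifest["outputs"]["pore_system"] = str(pout)
    state.update(traj=traj, trace=trace, truth=truth, pore_system=psys,
                 region=region)


def _stage_metrics(config, state, manifest, outdir):
    if "pore_system" not in state:
        raise ValueError("metrics stage requires the synth stage")
    region = state["region"]
    psys = state["pore_system"]
    depth = _metrics.deepest_water_depth(psys, region)
    occ = _metrics.occupancy_counts(psys, region)
    q = _metrics.net_charge_in_region(psys, region)
    clusters = _metrics.water_clusters(psys, bulk_z_top=region.z_top)
    scan = _metrics.density_scan(psys, plane="side_view", bin_width=0.2)
    scan_path = outdir / "scan_water.tsv"
    scan_path.write_text(scan.to_table("water"))
    manifest["outputs"]["density_scan"] = str(scan_path)
    manifest["results"]["metrics"] = {
        "deepest_water_depth_nm": depth,
        "occupancy": occ,
        "net_charge_in_pore": q,
        "n_clusters": len(clusters.clusters),
        "n_discrete_clusters": len(clusters.discrete_clusters()),
    }


def _stage_kinetics(config, state, manifest, outdir):
    if "traj" not in state:
        raise ValueError("kinetics stage requires the synth stage")
    region = state["region"]
    trace = _metrics.penetration_trace(state["traj"], "C12E6", region)
    fit = fit_penetration_rate(trace)
    (outdir / "trace.tsv").write_text(trace.to_table())
    (outdir / "fit.txt").write_text(fit.report())
    manifest["outputs"]["trace"] = str(outdir / "trace.tsv")
    manifest["outputs"]["fit"] = str(outdir / "fit.txt")
    manifest["results"]["kinetics"] = {
        "A_per_ns": fit.A, "prefactor_nm": fit.prefactor,
        "residual_rms_nm": fit.residual_rms,
        "A_true": state["truth"].A_true,
    }


def _stage_pmf(config, state, manifest, outdir):
    from . import pmf as _pmf
    if config.pmf_profile is None:
        raise ValueError("pmf stage requires a pmf_profile path")
    prof = _pmf.read_profile(config.pmf_profile)
    anchors = config.pmf_anchors
    dg = _pmf.free_energy_difference(prof, anchors["xi_surface"], anchors["xi_bulk"])
    barrier = _pmf.penetration_barrier(prof, anchors["xi_entrance"],
                                       anchors["xi_inside"])
    surf = _pmf.ideal_pair_surface(prof)
    spath = outdir / "ideal_pair_surface.tsv"
    _pmf.write_surface(surf, spath)
    manifest["outputs"]["ideal_pair_surface"] = str(spath)
    manifest["results"]["pmf"] = {
        "dG_ads_kT": dg,
        "penetration_barrier_kT": barrier,
        "symmetry_rmsd_kT": _pmf.symmetry_rmsd(surf),
    }


_STAGE_RUNNERS = {
    "build": _stage_build,
    "compose": _stage_compose,
    "synth": _stage_synth,
    "metrics": _stage_metrics,
    "kinetics": _stage_kinetics,
    "pmf": _stage_pmf,
}
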