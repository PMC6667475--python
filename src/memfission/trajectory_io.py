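"""Trajectory and annotation I/O, leaflet assignment, and periodic unwrapping.

All coordinates are stored in Å and times in ps. GRO/PDB/XTC files are read
through MDAnalysis (which reports Å natively); the package's own plain-text
columnar format ("internal") is always available and needs no binary readers.

Only orthorhombic boxes are supported: the systems this package targets are
rectangular membrane slabs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BEAD_ROLES = ("phosphate", "headgroup", "glycerol", "tail", "solvent", "ion")

#: Leaflet label codes.
UPPER, LOWER, UNASSIGNED = 1, -1, 0

#: Lipids whose reference bead lies within this distance (Å) of the local
#: mid-plane are left unassigned.
LEAFLET_EPSILON = 2.0


class TrajectoryFormatError(ValueError):
    """Malformed or unsupported trajectory content."""


class AnnotationError(ValueError):
    """Missing or inconsistent particle annotations."""


@dataclass
class ParticleTable:
    """Per-particle annotations: which lipid each bead belongs to and its role.

    ``lipid_id`` is -1 for non-lipid particles (solvent, ions). Each lipid has
    at most one phosphate bead; particle ids are contiguous from 0.
    """

    particle_id: np.ndarray
    lipid_id: np.ndarray
    species: np.ndarray
    bead_role: np.ndarray

    def __post_init__(self) -> None:
        self.particle_id = np.asarray(self.particle_id, dtype=np.int64)
        self.lipid_id = np.asarray(self.lipid_id, dtype=np.int64)
        self.species = np.asarray(self.species, dtype=object)
        self.bead_role = np.asarray(self.bead_role, dtype=object)
        self.validate()

    def validate(self) -> None:
        n = len(self.particle_id)
        if not (len(self.lipid_id) == len(self.species) == len(self.bead_role) == n):
            raise AnnotationError("particle table columns have unequal lengths")
        if not np.array_equal(self.particle_id, np.arange(n)):
            raise AnnotationError("particle_ids must be unique and contiguous from 0")
        bad = set(self.bead_role) - set(BEAD_ROLES)
        if bad:
            raise AnnotationError(f"unknown bead roles: {sorted(bad)}")
        lipids = self.lipid_id[self.lipid_id >= 0]
        if lipids.size:
            phos = self.lipid_id[(self.lipid_id >= 0)
                                 & (self.bead_role == "phosphate")]
            uniq, counts = np.unique(phos, return_counts=True)
            if np.any(counts > 1):
                raise AnnotationError(
                    f"lipids with >1 phosphate bead: {uniq[counts > 1].tolist()}")

    def __len__(self) -> int:
        return len(self.particle_id)

    @property
    def n_lipids(self) -> int:
        return int(np.unique(self.lipid_id[self.lipid_id >= 0]).size)

    @property
    def lipid_ids(self) -> np.ndarray:
        """Sorted unique lipid ids (≥ 0)."""
        return np.unique(self.lipid_id[self.lipid_id >= 0])

    def lipid_species(self) -> np.ndarray:
        """Species tag per lipid, aligned with :attr:`lipid_ids`."""
        ids = self.lipid_ids
        first = np.zeros(ids.size, dtype=np.int64)
        for k, lid in enumerate(ids):
            first[k] = np.nonzero(self.lipid_id == lid)[0][0]
        return self.species[first]


@dataclass
class Frame:
    """A single snapshot: time (ps), N×3 coordinates (Å), orthorhombic box (Å)."""

    time: float
    coords: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise TrajectoryFormatError("coords must be N×3")
        if self.box.shape != (3,):
            raise TrajectoryFormatError("box must be 3 orthorhombic edge lengths")
        if not np.all(self.box > 0):
            raise TrajectoryFormatError("box edge lengths must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryFormatError("non-finite coordinates")


class FrameSeries:
    """Time-ordered coordinates with box vectors and a constant particle table.

    Internally stores a (T, N, 3) coordinate array; :meth:`frames` yields
    :class:`Frame` views for single-frame operations.
    """

    def __init__(self, times: Sequence[float], coords: np.ndarray,
                 boxes: np.ndarray, particles: ParticleTable,
                 provenance: Optional[dict] = None):
        self.times = np.asarray(times, dtype=np.float64)
        self.coords = np.asarray(coords, dtype=np.float64)
        self.boxes = np.asarray(boxes, dtype=np.float64)
        self.particles = particles
        self.provenance = provenance or {}
        self.validate()

    @classmethod
    def from_frames(cls, frames: Iterable[Frame], particles: ParticleTable,
                    provenance: Optional[dict] = None) -> "FrameSeries":
        frames = list(frames)
        if not frames:
            raise TrajectoryFormatError("empty frame list")
        return cls(times=[f.time for f in frames],
                   coords=np.stack([f.coords for f in frames]),
                   boxes=np.stack([f.box for f in frames]),
                   particles=particles, provenance=provenance)

    def validate(self) -> None:
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryFormatError("coords must be T×N×3")
        t, n, _ = self.coords.shape
        if self.times.shape != (t,) or self.boxes.shape != (t, 3):
            raise TrajectoryFormatError("times/boxes inconsistent with coords")
        if n != len(self.particles):
            raise TrajectoryFormatError(
                f"coordinate count {n} does not match particle table "
                f"({len(self.particles)})")
        if t > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryFormatError("times must be strictly increasing")
        if not np.all(self.boxes > 0):
            raise TrajectoryFormatError("box edge lengths must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryFormatError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(time=float(self.times[i]), coords=self.coords[i],
                     box=self.boxes[i])

    def frames(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class LeafletLabels:
    """Per-frame, per-lipid leaflet labels: +1 upper, -1 lower, 0 unassigned."""

    lipid_ids: np.ndarray
    labels: np.ndarray  # (n_frames, n_lipids) int8

    def __post_init__(self) -> None:
        self.lipid_ids = np.asarray(self.lipid_ids, dtype=np.int64)
        self.labels = np.atleast_2d(np.asarray(self.labels, dtype=np.int8))
        if self.labels.shape[1] != self.lipid_ids.size:
            raise ValueError("labels second axis must match lipid_ids")

    def counts(self, frame: int = 0) -> dict:
        lab = self.labels[frame]
        return {"upper": int(np.sum(lab == UPPER)),
                "lower": int(np.sum(lab == LOWER)),
                "unassigned": int(np.sum(lab == UNASSIGNED))}


# ---------------------------------------------------------------------------
# reference beads

def reference_bead_indices(particles: ParticleTable) -> tuple[np.ndarray, np.ndarray]:
    """One reference bead per lipid: the phosphate, else headgroup, else glycerol.

    Returns (lipid_ids, particle index of the reference bead per lipid).
    Lipids lacking any of the three roles raise :class:`AnnotationError`.
    """
    ids = particles.lipid_ids
    if ids.size == 0:
        raise AnnotationError("no headgroup reference beads: table has no lipids")
    ref = np.full(ids.size, -1, dtype=np.int64)
    fallback_used = False
    pos = {lid: np.nonzero(particles.lipid_id == lid)[0] for lid in ids}
    for k, lid in enumerate(ids):
        idx = pos[lid]
        roles = particles.bead_role[idx]
        for role in ("phosphate", "headgroup", "glycerol"):
            hit = idx[roles == role]
            if hit.size:
                ref[k] = hit[0]
                if role != "phosphate":
                    fallback_used = True
                break
        else:
            raise AnnotationError(
                f"lipid {lid} has no phosphate/headgroup/glycerol reference bead")
    if fallback_used:
        logger.info("phosphate bead absent for some lipids; using "
                    "headgroup/glycerol fallback as surface reference")
    return ids, ref


# ---------------------------------------------------------------------------
# leaflet assignment

def assign_leaflets(frame: Frame, particles: ParticleTable,
                    method: str = "planar_z",
                    epsilon: float = LEAFLET_EPSILON,
                    grid_m: Optional[int] = None) -> LeafletLabels:
    """Label each lipid upper/lower by its reference bead's position.

    ``planar_z`` compares the bead z to the global mean reference z —
    appropriate for near-planar membranes and invariant under rigid
    translation. ``local_midplane`` compares to a gridded local mid-plane
    estimate and handles corrugated membranes. Lipids within ``epsilon`` Å of
    the surface are left unassigned.
    """
    ids, ref = reference_bead_indices(particles)
    if ids.size < 2:
        raise AnnotationError("need at least 2 lipids with reference beads")
    z = frame.coords[ref, 2]
    if method == "planar_z":
        dz = z - z.mean()
    elif method == "local_midplane":
        mid = _local_midplane(frame, ref, grid_m=grid_m)
        dz = z - mid
    else:
        raise ValueError(f"unknown leaflet method {method!r}")
    labels = np.zeros(ids.size, dtype=np.int8)
    labels[dz > epsilon] = UPPER
    labels[dz < -epsilon] = LOWER
    return LeafletLabels(lipid_ids=ids, labels=labels[None, :])


def _local_midplane(frame: Frame, ref_idx: np.ndarray,
                    grid_m: Optional[int] = None) -> np.ndarray:
    """Per-lipid local mid-plane z from a coarse in-plane grid.

    Per cell the mid-plane is (z_max + z_min)/2, valid only where the cell
    spans both leaflets (z-span comparable to the membrane thickness); cells
    sampling a single leaflet are filled from periodic neighbours.
    """
    xy = frame.coords[ref_idx, :2]
    z = frame.coords[ref_idx, 2]
    if grid_m is None:
        # aim for ~8 beads per cell so both leaflets are usually sampled
        grid_m = max(2, int(np.sqrt(ref_idx.size / 8.0)))
    lx, ly = frame.box[0], frame.box[1]
    ix = np.floor(np.mod(xy[:, 0], lx) / lx * grid_m).astype(int) % grid_m
    iy = np.floor(np.mod(xy[:, 1], ly) / ly * grid_m).astype(int) % grid_m
    cell = ix * grid_m + iy
    n_cells = grid_m * grid_m
    zmax = np.full(n_cells, -np.inf)
    zmin = np.full(n_cells, np.inf)
    np.maximum.at(zmax, cell, z)
    np.minimum.at(zmin, cell, z)
    counts = np.bincount(cell, minlength=n_cells)
    span = zmax - zmin
    with np.errstate(invalid="ignore"):
        multi = counts >= 2
        med_span = np.median(span[multi]) if np.any(multi) else 0.0
        valid = multi & (span >= 0.5 * med_span)
    mid = np.full(n_cells, np.nan)
    mid[valid] = 0.5 * (zmax[valid] + zmin[valid])
    mid = _fill_periodic_nearest(mid.reshape(grid_m, grid_m)).ravel()
    return mid[cell]


def _fill_periodic_nearest(grid: np.ndarray) -> np.ndarray:
    """Fill NaN cells from periodic nearest neighbours by iterative dilation."""
    g = grid.copy()
    while np.any(np.isnan(g)):
        nan = np.isnan(g)
        acc = np.zeros_like(g)
        cnt = np.zeros_like(g)
        for axis in (0, 1):
            for shift in (1, -1):
                rolled = np.roll(g, shift, axis=axis)
                ok = ~np.isnan(rolled)
                acc[ok] += rolled[ok]
                cnt[ok] += 1
        fill = nan & (cnt > 0)
        if not np.any(fill):
            raise ValueError("cannot fill grid: all cells empty")
        g[fill] = acc[fill] / cnt[fill]
    return g


def assign_leaflets_series(series: FrameSeries, method: str = "planar_z",
                           **kwargs) -> LeafletLabels:
    """Apply :func:`assign_leaflets` to every frame of a series."""
    per_frame = [assign_leaflets(f, series.particles, method=method, **kwargs)
                 for f in series.frames()]
    return LeafletLabels(lipid_ids=per_frame[0].lipid_ids,
                         labels=np.vstack([p.labels for p in per_frame]))


# ---------------------------------------------------------------------------
# periodic unwrapping

def unwrap_coordinates(series: FrameSeries,
                       axes: Sequence[str] = ("x", "y", "z")) -> FrameSeries:
    """Remove periodic jumps so per-particle displacement series are continuous.

    Applies the minimum-image convention cumulatively along the requested
    axes; the first frame is unchanged. Requires frame-to-frame motion smaller
    than half the box edge (an exactly half-box step is ambiguous and raises).
    """
    axis_idx = sorted({"xyz".index(a) for a in axes})
    out = series.coords.copy()
    for t in range(1, series.n_frames):
        box = series.boxes[t]
        for ax in axis_idx:
            d = series.coords[t, :, ax] - series.coords[t - 1, :, ax]
            shift = np.round(d / box[ax])
            corrected = d - shift * box[ax]
            bad = np.abs(np.abs(corrected) - box[ax] / 2) < 1e-9
            if np.any(bad):
                pid = int(np.nonzero(bad)[0][0])
                raise ValueError(
                    f"ambiguous unwrap: particle {pid} moved half a box edge "
                    f"on axis {ax} between frames {t - 1} and {t}")
            out[t, :, ax] = out[t - 1, :, ax] + corrected
    return FrameSeries(series.times, out, series.boxes, series.particles,
                       provenance={**series.provenance, "unwrapped_axes":
                                   [("x", "y", "z")[i] for i in axis_idx]})


def wrap_coordinates(series: FrameSeries) -> FrameSeries:
    """Wrap all coordinates back into [0, box) on every axis."""
    coords = np.mod(series.coords, series.boxes[:, None, :])
    return FrameSeries(series.times, coords, series.boxes, series.particles,
                       provenance=dict(series.provenance))


# ---------------------------------------------------------------------------
# annotation tables

def read_annotations(path) -> pd.DataFrame:
    """Read a residue→species/bead-role map.

    CSV columns: resname, species, bead_atom_names (';'-separated), bead_role.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"resname", "species", "bead_atom_names", "bead_role"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"annotation file missing columns: {sorted(missing)}")
    bad = set(df["bead_role"]) - set(BEAD_ROLES)
    if bad:
        raise AnnotationError(f"annotation file has unknown bead roles: {sorted(bad)}")
    return df


def _annotate_universe(universe, annotations: Optional[pd.DataFrame]):
    """Build a ParticleTable from an MDAnalysis Universe plus annotation map."""
    atoms = universe.atoms
    n = len(atoms)
    species = np.empty(n, dtype=object)
    role = np.empty(n, dtype=object)
    lipid_id = np.full(n, -1, dtype=np.int64)

    lookup: dict[tuple[str, str], tuple[str, str]] = {}
    resname_known: set[str] = set()
    if annotations is not None:
        for _, row in annotations.iterrows():
            resname_known.add(row["resname"])
            for atom_name in str(row["bead_atom_names"]).split(";"):
                atom_name = atom_name.strip()
                if atom_name:
                    lookup[(row["resname"], atom_name)] = (row["species"],
                                                           row["bead_role"])

    unknown_res: set[str] = set()
    next_lipid = 0
    resid_to_lipid: dict[int, int] = {}
    resnames = atoms.resnames
    names = atoms.names
    resindices = atoms.resindices
    for i in range(n):
        key = (str(resnames[i]), str(names[i]))
        if key in lookup:
            sp, rl = lookup[key]
        elif str(resnames[i]) in resname_known:
            raise AnnotationError(
                f"no annotation for atom {names[i]!r} of residue {resnames[i]!r}")
        else:
            unknown_res.add(str(resnames[i]))
            sp, rl = str(resnames[i]), "solvent"
        species[i] = sp
        role[i] = rl
        if rl not in ("solvent", "ion"):
            ridx = int(resindices[i])
            if ridx not in resid_to_lipid:
                resid_to_lipid[ridx] = next_lipid
                next_lipid += 1
            lipid_id[i] = resid_to_lipid[ridx]
    if unknown_res:
        logger.warning("unannotated residues mapped to solvent: %s",
                       sorted(unknown_res))
    return ParticleTable(particle_id=np.arange(n), lipid_id=lipid_id,
                         species=species, bead_role=role)


# ---------------------------------------------------------------------------
# readers / writers

INTERNAL_MAGIC = "# memfission trajectory v1"


def read_trajectory(path, format: str, annotations=None) -> FrameSeries:
    """Read a trajectory into a :class:`FrameSeries` (coordinates in Å, times ps).

    Formats: ``internal`` (this package's columnar text, self-annotating),
    ``gro``/``pdb`` (single- or multi-frame coordinate files; ``annotations``
    CSV maps residues to species/bead roles), ``xtc_pair`` (path is the XTC,
    ``annotations`` must be ``(topology_path, annotation_csv)``).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read trajectory: {path} does not exist")
    if format == "internal":
        return _read_internal(path)
    if format in ("gro", "pdb"):
        return _read_mdanalysis(path, annotations)
    if format == "xtc_pair":
        if not (isinstance(annotations, (tuple, list)) and len(annotations) == 2):
            raise ValueError("xtc_pair requires annotations=(topology, annotation_csv)")
        return _read_mdanalysis(path, annotations[1], topology=annotations[0])
    raise ValueError(f"unknown trajectory format {format!r}")


def _read_mdanalysis(path, annotations, topology=None) -> FrameSeries:
    import MDAnalysis as mda

    if isinstance(annotations, pd.DataFrame):
        ann = annotations
    elif annotations is not None:
        ann = read_annotations(annotations)
    else:
        ann = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # mda guesses masses noisily
        if topology is not None:
            u = mda.Universe(str(topology), str(path))
        else:
            u = mda.Universe(str(path))
    particles = _annotate_universe(u, ann)
    fallback_dims = None
    if str(path).lower().endswith(".pdb"):
        fallback_dims = _pdb_cryst1(path)  # multi-MODEL readers may drop it
    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # readers without dt warn per frame
        timesteps = [(ts.frame, ts.time, ts.positions.astype(np.float64),
                      ts.dimensions) for ts in u.trajectory]
    for frame_no, time_ps, positions, dims in timesteps:
        if dims is None and fallback_dims is not None:
            dims = fallback_dims
        if dims is None or np.any(dims[:3] <= 0):
            raise TrajectoryFormatError(f"frame {frame_no}: missing box")
        if not np.allclose(dims[3:6], 90.0, atol=1e-3):
            raise TrajectoryFormatError(
                "triclinic boxes are unsupported (orthorhombic slabs only)")
        frames.append(Frame(time=float(time_ps), coords=positions,
                            box=np.asarray(dims[:3], dtype=np.float64)))
    # some single-frame readers report time 0 for every model
    times = np.array([f.time for f in frames])
    if len(frames) > 1 and not np.all(np.diff(times) > 0):
        for i, f in enumerate(frames):
            f.time = float(i)
    return FrameSeries.from_frames(frames, particles,
                                   provenance={"source": str(path)})


def _pdb_cryst1(path) -> Optional[np.ndarray]:
    """First CRYST1 record of a PDB as [a, b, c, α, β, γ], or None."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                vals = [float(line[6:15]), float(line[15:24]),
                        float(line[24:33]), float(line[33:40]),
                        float(line[40:47]), float(line[47:54])]
                return np.array(vals)
    return None


def _read_internal(path: Path) -> FrameSeries:
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != INTERNAL_MAGIC:
        raise TrajectoryFormatError(f"{path}: not an internal-format trajectory")
    i = 1
    # header: particle table
    while i < len(lines) and not lines[i].startswith("# particles"):
        i += 1
    if i == len(lines):
        raise TrajectoryFormatError(f"{path}: missing '# particles' header")
    n = int(lines[i].split()[-1])
    i += 2  # skip the column-name comment line
    pid, lid, spec, role = [], [], [], []
    for row in lines[i:i + n]:
        parts = row.split()
        if len(parts) != 4:
            raise TrajectoryFormatError(f"{path}: bad particle row {row!r}")
        pid.append(int(parts[0]))
        lid.append(int(parts[1]))
        spec.append(parts[2])
        role.append(parts[3])
    particles = ParticleTable(np.array(pid), np.array(lid),
                              np.array(spec, dtype=object),
                              np.array(role, dtype=object))
    i += n
    frames = []
    while i < len(lines):
        line = lines[i].strip()
        if not line or line.startswith("#"):
            i += 1
            continue
        if not line.startswith("t "):
            raise TrajectoryFormatError(f"{path}: expected 't <ps>' at line {i + 1}")
        time = float(line.split()[1])
        box = np.array([float(v) for v in lines[i + 1].split()[1:4]])
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise TrajectoryFormatError(
                f"{path}: frame {len(frames)} truncated "
                f"({len(block)} of {n} particles)")
        coords = np.empty((n, 3))
        for row in block:
            parts = row.split()
            coords[int(parts[0])] = [float(parts[1]), float(parts[2]),
                                     float(parts[3])]
        frames.append(Frame(time=time, coords=coords, box=box))
        i += 2 + n
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames")
    return FrameSeries.from_frames(frames, particles,
                                   provenance={"source": str(path)})


def write_trajectory(series: FrameSeries, path, format: str) -> None:
    """Write a FrameSeries; supported formats: internal, gro, pdb."""
    path = Path(path)
    if format == "internal":
        _write_internal(series, path)
    elif format in ("gro", "pdb"):
        _write_mdanalysis(series, path, format)
    else:
        raise ValueError(f"unsupported write format {format!r}")


def _write_internal(series: FrameSeries, path: Path) -> None:
    p = series.particles
    out = [INTERNAL_MAGIC, f"# particles {len(p)}",
           "# particle_id lipid_id species bead_role"]
    for i in range(len(p)):
        out.append(f"{p.particle_id[i]} {p.lipid_id[i]} {p.species[i]} "
                   f"{p.bead_role[i]}")
    for f in series.frames():
        out.append(f"t {f.time:.6f}")
        out.append(f"box {f.box[0]:.6f} {f.box[1]:.6f} {f.box[2]:.6f}")
        for i in range(len(p)):
            x, y, z = f.coords[i]
            out.append(f"{i} {x:.6f} {y:.6f} {z:.6f}")
    try:
        path.write_text("\n".join(out) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write trajectory to {path}: {exc}") from exc


def annotation_table(particles: ParticleTable) -> pd.DataFrame:
    """Annotation map matching the residue/atom names this package writes.

    Lets a GRO/PDB file written by :func:`write_trajectory` be read back with
    its species and bead roles intact.
    """
    rows = {}
    for i in range(len(particles)):
        sp = str(particles.species[i])
        role = str(particles.bead_role[i])
        key = (sp[:4] or "UNK", sp, role)
        rows.setdefault(key, set()).add(_ROLE_TO_NAME.get(role, "X"))
    return pd.DataFrame(
        [{"resname": k[0], "species": k[1],
          "bead_atom_names": ";".join(sorted(v)), "bead_role": k[2]}
         for k, v in sorted(rows.items())])


def _write_mdanalysis(series: FrameSeries, path: Path, format: str) -> None:
    import MDAnalysis as mda

    if format == "gro" and series.n_frames > 1:
        raise ValueError("gro holds a single frame; use pdb or internal "
                         "for multi-frame series")
    p = series.particles
    n = len(p)
    n_res = int(np.max(p.lipid_id)) + 1 if np.any(p.lipid_id >= 0) else 0
    resindex = np.where(p.lipid_id >= 0, p.lipid_id, -1)
    # give each non-lipid particle its own residue after the lipids
    n_extra = int(np.sum(resindex < 0))
    extra = np.arange(n_res, n_res + n_extra)
    resindex = resindex.copy()
    resindex[resindex < 0] = extra
    n_res_total = n_res + n_extra
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, n_residues=max(n_res_total, 1),
                               atom_resindex=np.maximum(resindex, 0),
                               trajectory=True)
        u.add_TopologyAttr("names", _bead_names(p))
        resnames = np.empty(max(n_res_total, 1), dtype=object)
        resnames[:] = "UNK"
        for i in range(n):
            resnames[resindex[i]] = str(p.species[i])[:4] or "UNK"
        u.add_TopologyAttr("resnames", resnames)
        u.add_TopologyAttr("resids", np.arange(1, max(n_res_total, 1) + 1))
        try:
            with mda.Writer(str(path), n_atoms=n, multiframe=series.n_frames > 1) as w:
                for f in series.frames():
                    u.atoms.positions = f.coords
                    u.dimensions = [f.box[0], f.box[1], f.box[2], 90, 90, 90]
                    w.write(u.atoms)
        except OSError as exc:
            raise IOError(f"cannot write trajectory to {path}: {exc}") from exc


_ROLE_TO_NAME = {"phosphate": "PO4", "headgroup": "NC3", "glycerol": "GL1",
                 "tail": "C1A", "solvent": "W", "ion": "ION"}


def _bead_names(p: ParticleTable) -> np.ndarray:
    return np.array([_ROLE_TO_NAME.get(str(r), "X") for r in p.bead_role],
                    dtype=object)
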