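"""Trajectory post-processing: ion binding and density fields.

An :class:`IonTrajectory` holds per-frame coordinates of mobile particles
(ions or lipid beads) and of named site atoms (e.g. the Asp carboxyl
oxygens of the binding site) in an orthorhombic periodic box.  Binding is a
distance criterion: an ion is bound while its minimum-image distance to any
site atom is at or below a threshold (default 3 Å, the convention for Na⁺
to Asp carboxyl oxygens).  Densities are voxelized counts averaged over
frames and converted to molar concentration,

    c[mol/L] = ⟨count⟩ / (V_voxel[ų] · 1e-27 L/ų · N_A),

so a bulk region of a well-mixed system reads back the nominal salt
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptySelectionError, ValidationError

AVOGADRO = 6.02214076e23
LITRE_PER_A3 = 1e-27


@dataclass
class IonTrajectory:
    """T frames of mobile-particle and site-atom coordinates.

    ``box`` is the orthorhombic cell (3-vector, Å) shared by all frames or
    per-frame (T x 3).  Triclinic cells are rejected.
    """

    ion_coords: np.ndarray  # T x n_ions x 3
    site_coords: np.ndarray  # T x n_site x 3 (n_site may be 0)
    box: np.ndarray  # 3 or T x 3
    ion_ids: list[str] = field(default_factory=list)
    site_labels: list[str] = field(default_factory=list)
    dt_ps: float | None = None

    def __post_init__(self) -> None:
        self.ion_coords = np.asarray(self.ion_coords, dtype=float)
        self.site_coords = np.asarray(self.site_coords, dtype=float)
        box = np.asarray(self.box, dtype=float)
        if box.ndim == 1:
            if box.shape[0] == 6:
                if not np.allclose(box[3:], 90.0):
                    raise ValidationError(
                        "triclinic boxes are not supported (angles must be 90°)"
                    )
                box = box[:3]
            if box.shape[0] != 3:
                raise ValidationError("box must be a 3-vector (or 6 with 90° angles)")
        elif box.ndim == 2 and box.shape[1] == 3:
            pass
        else:
            raise ValidationError("box must be a 3-vector or T x 3 array")
        if np.any(box <= 0):
            raise ValidationError("box lengths must be positive")
        self.box = box
        if self.ion_coords.ndim != 3 or self.ion_coords.shape[2] != 3:
            raise ValidationError("ion coordinates must be T x n_ions x 3")
        if self.site_coords.size and (
            self.site_coords.ndim != 3 or self.site_coords.shape[2] != 3
        ):
            raise ValidationError("site coordinates must be T x n_site x 3")
        if not self.ion_ids:
            self.ion_ids = [f"ion{i}" for i in range(self.n_ions)]

    @property
    def n_frames(self) -> int:
        return self.ion_coords.shape[0]

    @property
    def n_ions(self) -> int:
        return self.ion_coords.shape[1]

    @property
    def n_site_atoms(self) -> int:
        return 0 if self.site_coords.size == 0 else self.site_coords.shape[1]

    def box_of(self, frame: int) -> np.ndarray:
        return self.box if self.box.ndim == 1 else self.box[frame]


def read_trajectory_csv(path: str | Path, box) -> IonTrajectory:
    """Load the documented CSV frame table: columns
    ``frame,role,id,x,y,z`` with role ∈ {ion, site}."""
    df = pd.read_csv(path)
    needed = {"frame", "role", "id", "x", "y", "z"}
    if not needed <= set(df.columns):
        raise ValidationError(
            f"trajectory CSV needs columns {sorted(needed)}; got {list(df.columns)}"
        )
    frames = sorted(df["frame"].unique())
    ions = df[df["role"] == "ion"]
    sites = df[df["role"] == "site"]
    ion_ids = list(dict.fromkeys(ions["id"]))
    site_ids = list(dict.fromkeys(sites["id"]))
    T = len(frames)
    ion_xyz = np.full((T, len(ion_ids), 3), np.nan)
    site_xyz = np.full((T, len(site_ids), 3), np.nan)
    f_index = {f: t for t, f in enumerate(frames)}
    i_index = {i: k for k, i in enumerate(ion_ids)}
    s_index = {i: k for k, i in enumerate(site_ids)}
    for _, row in ions.iterrows():
        ion_xyz[f_index[row["frame"]], i_index[row["id"]]] = (row["x"], row["y"], row["z"])
    for _, row in sites.iterrows():
        site_xyz[f_index[row["frame"]], s_index[row["id"]]] = (row["x"], row["y"], row["z"])
    if np.any(~np.isfinite(ion_xyz)):
        raise ValidationError("trajectory CSV: particle identity not constant across frames")
    return IonTrajectory(
        ion_coords=ion_xyz,
        site_coords=site_xyz if site_ids else np.zeros((T, 0, 3)),
        box=box,
        ion_ids=[str(i) for i in ion_ids],
        site_labels=[str(i) for i in site_ids],
    )


def write_trajectory_csv(path: str | Path, traj: IonTrajectory) -> None:
    rows = []
    for t in range(traj.n_frames):
        for k, iid in enumerate(traj.ion_ids):
            x, y, z = traj.ion_coords[t, k]
            rows.append((t, "ion", iid, x, y, z))
        for k in range(traj.n_site_atoms):
            label = traj.site_labels[k] if traj.site_labels else f"site{k}"
            x, y, z = traj.site_coords[t, k]
            rows.append((t, "site", label, x, y, z))
    pd.DataFrame(rows, columns=["frame", "role", "id", "x", "y", "z"]).to_csv(
        path, index=False
    )


def minimum_image_distances(
    points_a: np.ndarray, points_b: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """All-pairs minimum-image distances (n_a x n_b) in an orthorhombic box."""
    a = np.asarray(points_a, dtype=float)[:, None, :]
    b = np.asarray(points_b, dtype=float)[None, :, :]
    box = np.asarray(box, dtype=float)
    d = a - b
    d -= box * np.round(d / box)
    return np.sqrt(np.sum(d**2, axis=-1))


def min_distance_series(traj: IonTrajectory) -> np.ndarray:
    """Per frame, per ion: minimum-image distance to the nearest site atom
    (T x n_ions)."""
    if traj.n_ions == 0:
        raise EmptySelectionError("trajectory has no ions")
    if traj.n_site_atoms == 0:
        raise EmptySelectionError("trajectory has no site atoms")
    out = np.empty((traj.n_frames, traj.n_ions))
    for t in range(traj.n_frames):
        d = minimum_image_distances(
            traj.ion_coords[t], traj.site_coords[t], traj.box_of(t)
        )
        out[t] = d.min(axis=1)
    return out


@dataclass
class BindingEvent:
    ion: str
    start_frame: int
    end_frame: int  # inclusive

    @property
    def length(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class BindingSeries:
    """Bound/unbound classification of every ion in every frame."""

    distances: np.ndarray  # T x n_ions
    bound: np.ndarray  # T x n_ions bool
    threshold: float
    ion_ids: list[str]

    @property
    def occupancy(self) -> float:
        """Fraction of frames with at least one bound ion."""
        return float(np.mean(self.bound.any(axis=1)))

    @property
    def per_ion_bound_fraction(self) -> np.ndarray:
        return self.bound.mean(axis=0)

    @property
    def events(self) -> list[BindingEvent]:
        """Contiguous bound segments (entry/exit frames) per ion."""
        out: list[BindingEvent] = []
        for k, iid in enumerate(self.ion_ids):
            col = self.bound[:, k]
            t = 0
            while t < len(col):
                if col[t]:
                    start = t
                    while t + 1 < len(col) and col[t + 1]:
                        t += 1
                    out.append(BindingEvent(ion=iid, start_frame=start, end_frame=t))
                t += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        T, n = self.distances.shape
        rows = []
        for t in range(T):
            for k in range(n):
                rows.append(
                    (t, self.ion_ids[k], self.distances[t, k], bool(self.bound[t, k]))
                )
        return pd.DataFrame(rows, columns=["frame", "ion", "min_distance", "bound"])


def bound_mask(
    distances: np.ndarray, threshold: float = 3.0, ion_ids: list[str] | None = None
) -> BindingSeries:
    """Apply the distance criterion: bound ⇔ min distance ≤ threshold (Å)."""
    distances = np.asarray(distances, dtype=float)
    if distances.ndim != 2:
        raise ValidationError("distances must be a T x n_ions array")
    ids = ion_ids or [f"ion{i}" for i in range(distances.shape[1])]
    return BindingSeries(
        distances=distances,
        bound=distances <= threshold,
        threshold=float(threshold),
        ion_ids=list(ids),
    )


def binding_series(traj: IonTrajectory, threshold: float = 3.0) -> BindingSeries:
    """Distance series + distance criterion in one call."""
    return bound_mask(min_distance_series(traj), threshold, traj.ion_ids)


@dataclass
class DensityGrid:
    """Voxelized average counts and molar concentration."""

    origin: np.ndarray  # 3
    spacing: np.ndarray  # 3
    counts: np.ndarray  # nx x ny x nz, per-frame average
    n_frames: int

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def concentration(self) -> np.ndarray:
        """mol/L per voxel."""
        return self.counts / (self.voxel_volume * LITRE_PER_A3 * AVOGADRO)

    @property
    def total_average_count(self) -> float:
        """Mean number of particles inside the grid (conserved under
        re-binning)."""
        return float(self.counts.sum())

    def write_dx(self, path: str | Path) -> None:
        """Export the concentration field in OpenDX grid format."""
        nx, ny, nz = self.counts.shape
        lines = [
            f"object 1 class gridpositions counts {nx} {ny} {nz}",
            "origin {:.6f} {:.6f} {:.6f}".format(*(self.origin + self.spacing / 2.0)),
            f"delta {self.spacing[0]:.6f} 0.000000 0.000000",
            f"delta 0.000000 {self.spacing[1]:.6f} 0.000000",
            f"delta 0.000000 0.000000 {self.spacing[2]:.6f}",
            f"object 2 class gridconnections counts {nx} {ny} {nz}",
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
        ]
        flat = self.concentration.ravel(order="C")
        for i in range(0, len(flat), 3):
            lines.append(" ".join(f"{v:.6e}" for v in flat[i : i + 3]))
        lines.append('attribute "dep" string "positions"')
        lines.append('object "density [mol/L]" class field')
        Path(path).write_text("\n".join(lines) + "\n")


def density_grid(
    traj: IonTrajectory,
    spacing: float | tuple[float, float, float] = 1.0,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> DensityGrid:
    """Histogram the ion coordinates on a regular grid, averaged over frames.

    ``bounds`` defaults to [0, box); coordinates are wrapped into the
    primary cell first, and a coordinate exactly on a voxel boundary
    belongs to the higher-index voxel (half-open voxels).
    """
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if np.any(spacing <= 0):
        raise ValidationError("voxel spacing must be positive")
    box0 = traj.box_of(0)
    if bounds is None:
        lo = np.zeros(3)
        hi = box0.astype(float).copy()
        wrap = True
    else:
        lo = np.asarray(bounds[0], dtype=float)
        hi = np.asarray(bounds[1], dtype=float)
        wrap = False
    if np.any(hi <= lo):
        raise ValidationError("grid bounds have zero or negative volume")
    nbins = np.maximum(1, np.round((hi - lo) / spacing).astype(int))
    edges = [np.linspace(lo[i], hi[i], nbins[i] + 1) for i in range(3)]
    pts = traj.ion_coords.reshape(-1, 3).copy()
    if wrap:
        pts = pts - box0 * np.floor(pts / box0)
    counts, _ = np.histogramdd(pts, bins=edges)
    return DensityGrid(
        origin=lo,
        spacing=(hi - lo) / nbins,
        counts=counts / traj.n_frames,
        n_frames=traj.n_frames,
    )


def bulk_density(
    grid: DensityGrid, region: np.ndarray | dict | None = None
) -> tuple[float, float]:
    """Mean concentration (mol/L) over the bulk voxels, with its s.e.m.

    ``region`` is a boolean voxel mask, a slab ``{"axis": 2, "min": z0,
    "max": z1}`` in Å, or None for the whole grid.
    """
    conc = grid.concentration
    if region is None:
        mask = np.ones(conc.shape, dtype=bool)
    elif isinstance(region, dict):
        ax = int(region["axis"])
        centers = (
            grid.origin[ax]
            + (np.arange(conc.shape[ax]) + 0.5) * grid.spacing[ax]
        )
        sel = (centers >= region["min"]) & (centers <= region["max"])
        mask = np.zeros(conc.shape, dtype=bool)
        index = [slice(None)] * 3
        index[ax] = sel
        mask[tuple(index)] = True
    else:
        mask = np.asarray(region, dtype=bool)
        if mask.shape != conc.shape:
            raise ValidationError("region mask shape must match the grid")
    vals = conc[mask]
    if vals.size == 0:
        raise EmptySelectionError("bulk region selects no voxels")
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return float(vals.mean()), sem
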