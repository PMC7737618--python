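"""Synthetic inputs with known ground truth for every analysis stage.

The generators emulate the data classes the pipeline consumes without any
downloads: two-state elevator Cα architectures (a static scaffold plus a
core domain rigidly translated along the membrane normal), noisy structural
ensembles of such states, ideal-gas ion trajectories at a stated bulk
concentration with a programmable bound fraction at a binding site,
Michaelis–Menten dose–response replicates, and sigmoidal melting curves.

All generators are pure functions of (parameters, seed): identical seeds
give bitwise-identical outputs, and no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binding import AVOGADRO, LITRE_PER_A3, IonTrajectory
from .errors import ValidationError
from .structures import CalphaModel, CorrespondenceTable, DomainDefinition, identity_correspondence

# ideal alpha-helix Calpha geometry
HELIX_RISE = 1.5  # Å per residue
HELIX_RADIUS = 2.3  # Å
HELIX_TURN_DEG = 100.0  # ~3.6 residues per turn


@dataclass
class ToyElevatorSpec:
    """Geometry of the two-state toy elevator.

    The scaffold (dimerization-domain stand-in) and core (transport-domain
    stand-in) are each built from ideal membrane-spanning helices parallel
    to the membrane normal (+z).  State B moves the core as a rigid body:
    ``shift`` Å along the normal and ``rotation_deg`` about it.
    """

    scaffold_residues: int = 60
    core_residues: int = 60
    shift: float = 5.0
    rotation_deg: float = 0.0
    binding_site_size: int = 2
    helices_per_domain: int = 2
    scaffold_helices: int | None = None  # overrides helices_per_domain
    core_helices: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shift < 0:
            raise ValidationError("elevator shift must be >= 0")
        if self.scaffold_residues < 10 or self.core_residues < 10:
            raise ValidationError("each domain needs >= 10 residues")
        if self.binding_site_size < 1:
            raise ValidationError("binding site needs >= 1 residue")


def _helix(n: int, origin: np.ndarray, phase: float = 0.0) -> np.ndarray:
    """Ideal Cα helix along +z starting at ``origin`` (successive Cα–Cα
    distances ≈ 3.8 Å)."""
    i = np.arange(n)
    ang = np.deg2rad(HELIX_TURN_DEG) * i + phase
    return np.column_stack(
        [
            origin[0] + HELIX_RADIUS * np.cos(ang),
            origin[1] + HELIX_RADIUS * np.sin(ang),
            origin[2] + HELIX_RISE * i,
        ]
    )


def _domain_chains(
    n_residues: int, n_helices: int, x_center: float, chain_ids: str
) -> list[tuple[str, np.ndarray]]:
    """Bundle of parallel membrane-spanning helices centred at x_center.

    Each helix is its own chain (8 Å apart in y), so successive Cα–Cα
    distances within every chain are the ideal ≈3.8 Å helical spacing.
    """
    per = [n_residues // n_helices] * n_helices
    per[-1] += n_residues - sum(per)
    out = []
    for h, n in enumerate(per):
        if n_helices <= 2:
            origin = np.array([x_center, (h - (n_helices - 1) / 2.0) * 8.0, 0.0])
        else:
            # two-column grid: a mutually braced bundle
            col, row = h % 2, h // 2
            rows = (n_helices + 1) // 2
            origin = np.array(
                [x_center + (col - 0.5) * 6.0, (row - (rows - 1) / 2.0) * 8.0, 0.0]
            )
        out.append((chain_ids[h], _helix(n, origin, phase=h * 1.0)))
    return out


def make_toy_elevator(
    spec: ToyElevatorSpec | None = None,
) -> tuple[CalphaModel, CalphaModel, DomainDefinition]:
    """Two-state toy elevator plus its domain definition.

    State A: scaffold helices (chains A, B, …) at x ≈ −8 Å and core helices
    (chains M, N, …) at x ≈ +8 Å, all spanning the membrane along +z.
    State B: the core rigidly moved by (shift Å along the normal, rotation
    about it through the core centroid); the scaffold is bitwise identical.
    The binding site is the central residues of the first core helix, near
    mid-membrane as a real ion site would be.
    """
    spec = spec or ToyElevatorSpec()
    n_scaffold = spec.scaffold_helices or spec.helices_per_domain
    n_core = spec.core_helices or spec.helices_per_domain
    scaffold = _domain_chains(spec.scaffold_residues, n_scaffold, -6.0, "ABCDEFGH")
    core = _domain_chains(spec.core_residues, n_core, +6.0, "MNOPQRST")

    residues = []
    coords = []
    for chain, xyz in scaffold + core:
        residues.extend((chain, i + 1, "", "ALA") for i in range(len(xyz)))
        coords.append(xyz)
    coords_a = np.vstack(coords)
    state_a = CalphaModel(residues=residues, coords=coords_a)

    core_xyz = np.vstack([xyz for _, xyz in core])
    if spec.rotation_deg != 0.0:
        theta = np.deg2rad(spec.rotation_deg)
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        centroid = core_xyz.mean(axis=0)
        core_b = (core_xyz - centroid) @ rot.T + centroid
    else:
        core_b = core_xyz.copy()
    core_b = core_b + np.array([0.0, 0.0, spec.shift])
    coords_b = np.vstack([np.vstack([xyz for _, xyz in scaffold]), core_b])
    state_b = CalphaModel(residues=residues, coords=coords_b)

    first_core_chain, first_core_xyz = core[0]
    mid = len(first_core_xyz) // 2
    lo = mid - spec.binding_site_size // 2
    site = set(range(lo + 1, lo + 1 + spec.binding_site_size))
    domains = DomainDefinition(
        domains={
            "dimer_domain": {
                chain: set(range(1, len(xyz) + 1)) for chain, xyz in scaffold
            },
            "core_domain": {
                chain: set(range(1, len(xyz) + 1)) for chain, xyz in core
            },
            "binding_site": {first_core_chain: site},
        }
    )
    return state_a, state_b, domains


def make_ensemble(
    states: list[CalphaModel],
    n_per_state: int,
    noise_sigma: float,
    seed: int = 0,
    id_prefix: str = "synth",
) -> tuple[dict[str, CalphaModel], CorrespondenceTable]:
    """Noisy copies of each state with an identity correspondence.

    Each member adds isotropic Gaussian noise (``noise_sigma`` Å per
    coordinate) to its parent state; all members share the parent residue
    numbering, so the correspondence maps every structure to itself.
    """
    if noise_sigma < 0:
        raise ValidationError("noise sigma must be >= 0")
    if not states:
        raise ValidationError("need at least one state")
    rng = np.random.default_rng(seed)
    models: dict[str, CalphaModel] = {}
    for si, state in enumerate(states):
        for k in range(n_per_state):
            sid = f"{id_prefix}_s{si}_{k}"
            noise = rng.normal(0.0, noise_sigma, size=state.coords.shape) if noise_sigma else 0.0
            models[sid] = state.with_coords(state.coords + noise)
    table = identity_correspondence(list(models), states[0])
    return models, table


def ion_count(concentration_mM: float, box: np.ndarray) -> int:
    """Number of ions for a concentration in an orthorhombic box:
    round(c · N_A · V)."""
    v_litre = float(np.prod(box)) * LITRE_PER_A3
    return int(round(concentration_mM * 1e-3 * AVOGADRO * v_litre))


def make_ion_traj(
    concentration_mM: float,
    box=(100.0, 100.0, 100.0),
    n_frames: int = 500,
    site_position: np.ndarray | None = None,
    bound_fraction: float = 0.0,
    seed: int = 0,
    binding_threshold: float = 3.0,
) -> IonTrajectory:
    """Ideal-gas ion trajectory at a stated bulk concentration.

    Unbound ions are uniform in the box each frame.  If a site is given,
    four static site atoms (a carboxyl-oxygen stand-in) surround
    ``site_position`` and ion 0 is placed within the binding threshold of a
    site atom for a ``bound_fraction`` of frames, in one contiguous block,
    so event segmentation sees entry and exit.  Bulk ions are kept out of
    the site zone so the programmed bound fraction is the exact ground
    truth.
    """
    if concentration_mM <= 0:
        raise ValidationError("concentration must be positive")
    if not 0.0 <= bound_fraction <= 1.0:
        raise ValidationError("bound fraction must be in [0, 1]")
    box = np.asarray(box, dtype=float)
    n_ions = ion_count(concentration_mM, box)
    if n_ions == 0:
        raise ValidationError(
            "zero ions at this concentration; use a larger box or concentration"
        )
    rng = np.random.default_rng(seed)
    ions = rng.uniform(0.0, 1.0, size=(n_frames, n_ions, 3)) * box

    if site_position is None:
        site = np.zeros((n_frames, 0, 3))
        return IonTrajectory(ion_coords=ions, site_coords=site, box=box)

    site_position = np.asarray(site_position, dtype=float)
    # four site atoms, a small tetrahedron around the nominal site position
    offsets = np.array(
        [[1.2, 0, 0], [-1.2, 0, 0], [0, 1.2, 0], [0, -1.2, 0]]
    ) * 0.8
    site_atoms = site_position + offsets
    site = np.broadcast_to(site_atoms, (n_frames, 4, 3)).copy()

    exclusion = binding_threshold + 0.5
    # keep bulk ions (and the tagged ion when unbound) out of the site zone
    for t in range(n_frames):
        for k in range(n_ions):
            guard = 0
            while (
                np.min(np.linalg.norm(ions[t, k] - site_atoms, axis=1)) < exclusion
                and guard < 100
            ):
                ions[t, k] = rng.uniform(0.0, 1.0, size=3) * box
                guard += 1

    n_bound = int(round(bound_fraction * n_frames))
    if n_bound > 0:
        start = 0 if n_bound >= n_frames else int(rng.integers(0, n_frames - n_bound + 1))
        for t in range(start, start + n_bound):
            atom = site_atoms[int(rng.integers(0, len(site_atoms)))]
            # uniform in a ball comfortably inside the threshold
            while True:
                p = rng.uniform(-1.0, 1.0, size=3)
                if np.linalg.norm(p) <= 1.0:
                    break
            ions[t, 0] = atom + p * (binding_threshold - 0.5)
    labels = [f"siteO{i + 1}" for i in range(4)]
    return IonTrajectory(
        ion_coords=ions,
        site_coords=site,
        box=box,
        site_labels=labels,
    )


def make_kinetics(
    km: float,
    vmax: float,
    concentrations,
    noise_fraction: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Michaelis–Menten responses with multiplicative Gaussian noise
    (n_conc x replicates)."""
    if km <= 0 or vmax <= 0:
        raise ValidationError("K_M and V_max must be positive")
    s = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    v = vmax * s / (km + s)
    noise = rng.normal(0.0, noise_fraction, size=(len(s), replicates)) if noise_fraction else 0.0
    return np.clip(v[:, None] * (1.0 + noise), 0.0, None)


def make_melt(
    tm: float,
    slope: float = 15.0,
    plateaus: tuple[float, float] = (1.0, 0.0),
    temperatures=None,
    noise_fraction: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sigmoidal melting curve (temperatures °C, signal).

    Gaussian noise is scaled by the transition span (``noise_fraction`` of
    |plateau difference|) so the two plateaus are equally noisy;
    ``plateaus`` is (low-T value, high-T value).
    """
    if tm <= 0:
        raise ValidationError("T_m must be positive (°C)")
    t = (
        np.arange(20.0, 80.1, 2.5)
        if temperatures is None
        else np.asarray(temperatures, dtype=float)
    )
    a, d = plateaus
    y = d + (a - d) / (1.0 + (t / tm) ** slope)
    if noise_fraction:
        rng = np.random.default_rng(seed)
        span = abs(a - d)
        y = y + rng.normal(0.0, noise_fraction * span, size=t.shape)
    return t, y
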