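"""Elastic network models and normal-mode analysis on Cα traces.

The protein is reduced to its Cα atoms joined by harmonic springs.  Two
parameterizations are available:

* ``cutoff-ANM`` -- uniform spring constant k0 for every pair within a
  distance cutoff R_c (the classic anisotropic network model);
* ``ED-ENM`` -- sequence-local springs C_seq/s^e for residues within a
  small sequence separation s, plus distance-decaying nonlocal springs
  (C_cart/r)^p inside the cutoff, a parameterization fitted to reproduce
  MD flexibility.

Diagonalizing the 3M x 3M Hessian of the harmonic energy yields 3M-6
non-rigid normal modes (ascending eigenvalue = stiffness); low- and
mid-frequency modes describe the collective motions, and their overlap with
a transition difference vector measures how much of a conformational change
the intrinsic dynamics already encodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.spatial import cKDTree

from .errors import ConnectivityError, DegenerateGeometryError, ValidationError
from .structures import CalphaModel


@dataclass
class ENMParams:
    """Spring parameterization of the elastic network.

    ``cutoff`` (R_c, Å) bounds nonlocal springs in both variants.  For
    ED-ENM, residues within ``seq_span`` positions on the same chain are
    joined with k = C_seq/s**seq_exponent regardless of distance, and
    nonlocal pairs inside the cutoff get k = (C_cart/r)**cart_power.
    Defaults follow the common ED-ENM parameterization (60/s² sequential,
    (6/r)⁶ Cartesian); unit tests exercise the fully specified cutoff-ANM.
    """

    variant: str = "cutoff-ANM"  # or "ED-ENM"
    cutoff: float = 12.0
    k0: float = 1.0
    c_seq: float = 60.0
    seq_exponent: float = 2.0
    c_cart: float = 6.0
    cart_power: float = 6.0
    seq_span: int = 3

    def __post_init__(self) -> None:
        if self.variant not in ("cutoff-ANM", "ED-ENM"):
            raise ValidationError(f"unknown ENM variant {self.variant!r}")
        if self.cutoff <= 0:
            raise ValidationError("cutoff must be positive")
        for name in ("k0", "c_seq", "c_cart"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.seq_span < 1:
            raise ValidationError("seq_span must be >= 1")


@dataclass
class ElasticNetwork:
    """Nodes plus springs (i < j, spring constant, equilibrium distance)."""

    coords: np.ndarray  # M x 3
    edges: np.ndarray  # E x 2 int
    spring_constants: np.ndarray  # E
    eq_distances: np.ndarray  # E

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int)
        self.spring_constants = np.asarray(self.spring_constants, dtype=float)
        self.eq_distances = np.asarray(self.eq_distances, dtype=float)
        if np.any(self.spring_constants <= 0):
            raise ValidationError("spring constants must be positive")

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def energy(self, coords: np.ndarray) -> float:
        """Harmonic energy E = ½ Σ k_ij (r_ij - r_ij⁰)² at given coordinates."""
        coords = np.asarray(coords, dtype=float).reshape(self.n_nodes, 3)
        d = coords[self.edges[:, 0]] - coords[self.edges[:, 1]]
        r = np.linalg.norm(d, axis=1)
        return float(0.5 * np.sum(self.spring_constants * (r - self.eq_distances) ** 2))


def build_network(model: CalphaModel, params: ENMParams | None = None) -> ElasticNetwork:
    """Connect the Cα nodes with springs per the chosen parameterization.

    Isolated nodes trigger a warning-grade :class:`ConnectivityError` only
    when the whole graph is disconnected; a single isolated node is logged
    by :func:`compute_modes` when extra zero modes show up.
    """
    params = params or ENMParams()
    coords = model.coords
    M = len(model)
    if M < 2:
        raise ValidationError("an elastic network needs at least 2 nodes")
    tree = cKDTree(coords)
    pairs = sorted(tree.query_pairs(params.cutoff))
    edge_k: dict[tuple[int, int], float] = {}
    if params.variant == "cutoff-ANM":
        for i, j in pairs:
            edge_k[(i, j)] = params.k0
    else:
        # nonlocal distance-decaying springs inside the cutoff
        for i, j in pairs:
            r = float(np.linalg.norm(coords[i] - coords[j]))
            edge_k[(i, j)] = (params.c_cart / r) ** params.cart_power
        # sequence-local springs override, irrespective of distance
        for start, stop in model.chain_slices():
            for i in range(start, stop):
                for j in range(i + 1, min(i + params.seq_span + 1, stop)):
                    s = j - i
                    edge_k[(i, j)] = params.c_seq / s**params.seq_exponent
    if not edge_k:
        raise ConnectivityError("no springs: every node pair is beyond the cutoff")
    edges = np.array(sorted(edge_k), dtype=int)
    k = np.array([edge_k[tuple(e)] for e in edges])
    r0 = np.linalg.norm(coords[edges[:, 0]] - coords[edges[:, 1]], axis=1)
    return ElasticNetwork(coords=coords, edges=edges, spring_constants=k, eq_distances=r0)


def hessian(network: ElasticNetwork) -> np.ndarray:
    """Assemble the 3M x 3M Hessian of the harmonic energy at equilibrium.

    Off-diagonal super-element for a spring (i, j):
    H_ij = -(k_ij/r⁰²) (d ⊗ d) with d the equilibrium bond vector; diagonal
    blocks make each row block sum to zero, which encodes translation
    invariance exactly.
    """
    M = network.n_nodes
    H = np.zeros((3 * M, 3 * M))
    for (i, j), k, r0 in zip(
        network.edges, network.spring_constants, network.eq_distances
    ):
        d = network.coords[i] - network.coords[j]
        block = (k / r0**2) * np.outer(d, d)
        H[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] -= block
        H[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] -= block
        H[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += block
        H[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] += block
    return H


def rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6 x 3M, or 5 x 3M for collinear nodes) of uniform
    translations and infinitesimal rotations about the centroid."""
    coords = np.asarray(coords, dtype=float)
    M = coords.shape[0]
    c = coords - coords.mean(axis=0)
    vecs = []
    for ax in range(3):
        t = np.zeros((M, 3))
        t[:, ax] = 1.0
        vecs.append(t.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        vecs.append(np.cross(np.broadcast_to(e, (M, 3)), c).ravel())
    B = np.array(vecs)
    # orthonormalize; drop numerically null rotations (collinear geometries)
    Q, R = np.linalg.qr(B.T)
    keep = np.abs(np.diag(R)) > 1e-10 * max(np.abs(np.diag(R)).max(), 1e-300)
    return Q.T[keep]


@dataclass
class ModeSet:
    """Non-rigid normal modes: ascending eigenvalues (stiffness, energy/Ų)
    and unit eigenvectors (rows, length 3M)."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # n_modes x 3M
    n_discarded: int
    n_nodes: int

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def mode_matrix(self, m: int) -> np.ndarray:
        """Mode m (1-based) reshaped to per-node M x 3 displacements."""
        if not 1 <= m <= self.n_modes:
            raise ValidationError(f"mode {m} out of range")
        return self.eigenvectors[m - 1].reshape(self.n_nodes, 3)


def compute_modes(network: ElasticNetwork, n_modes: int | None = None) -> ModeSet:
    """Diagonalize the Hessian and strip the rigid-body spectrum.

    A connected 3D network has exactly 6 near-zero modes (5 if the nodes are
    collinear); more indicates a disconnected graph and raises
    :class:`ConnectivityError` naming the components.  The remaining modes
    are returned in ascending eigenvalue order.
    """
    H = hessian(network)
    vals, vecs = scipy.linalg.eigh(H)
    rigid = rigid_body_basis(network.coords)
    n_rigid = rigid.shape[0]
    scale = max(vals[-1], 1e-300)
    near_zero = int(np.sum(vals < 1e-9 * scale))
    if near_zero > n_rigid:
        comps = _connected_components(network)
        raise ConnectivityError(
            f"{near_zero} near-zero modes for {n_rigid} rigid-body degrees of "
            f"freedom; network has {len(comps)} connected components "
            f"(sizes {[len(c) for c in comps]})"
        )
    if near_zero == n_rigid and (
        len(vals) <= n_rigid or vals[n_rigid] > 1e6 * max(vals[n_rigid - 1], 1e-300)
    ):
        keep_vals = vals[n_rigid:]
        keep_vecs = vecs[:, n_rigid:].T
    else:
        # ambiguous gap: project the rigid subspace out explicitly
        P = np.eye(H.shape[0]) - rigid.T @ rigid
        vals_p, vecs_p = scipy.linalg.eigh(P @ H @ P)
        keep_vals = vals_p[n_rigid:]
        keep_vecs = vecs_p[:, n_rigid:].T
    if n_modes is not None:
        keep_vals = keep_vals[:n_modes]
        keep_vecs = keep_vecs[:n_modes]
    return ModeSet(
        eigenvalues=np.asarray(keep_vals, dtype=float),
        eigenvectors=np.asarray(keep_vecs, dtype=float),
        n_discarded=n_rigid,
        n_nodes=network.n_nodes,
    )


def _connected_components(network: ElasticNetwork) -> list[set[int]]:
    adj: dict[int, set[int]] = {i: set() for i in range(network.n_nodes)}
    for i, j in network.edges:
        adj[int(i)].add(int(j))
        adj[int(j)].add(int(i))
    seen: set[int] = set()
    comps = []
    for start in range(network.n_nodes):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        comps.append(comp)
    return comps


@dataclass
class FluctuationProfile:
    """Per-residue mean-square fluctuation from the first K modes, with
    hinge flags at rigid local minima."""

    msf: np.ndarray
    hinge_flags: np.ndarray
    n_modes_used: int
    smooth_window: int = 5
    percentile: float = 25.0


def residue_fluctuations(
    modes: ModeSet,
    n_modes: int = 20,
    temperature_scale: float = 1.0,
    smooth_window: int = 5,
    hinge_percentile: float = 25.0,
) -> FluctuationProfile:
    """MSF_i ∝ Σ_m |v_{m,i}|²/λ_m over the first ``n_modes`` modes.

    Values are in relative units unless a physical k_BT scale is supplied.
    Hinges -- the rigid pivots of the collective motions -- are flagged at
    local minima of the (window-smoothed) profile lying below the given
    percentile.
    """
    if n_modes < 1:
        raise ValidationError("n_modes must be >= 1")
    K = min(n_modes, modes.n_modes)
    msf = np.zeros(modes.n_nodes)
    for m in range(K):
        v = modes.eigenvectors[m].reshape(modes.n_nodes, 3)
        msf += np.sum(v**2, axis=1) / modes.eigenvalues[m]
    msf *= temperature_scale
    w = max(1, int(smooth_window))
    kernel = np.ones(w) / w
    smooth = np.convolve(msf, kernel, mode="same")
    thresh = np.percentile(smooth, hinge_percentile)
    flags = np.zeros(modes.n_nodes, dtype=bool)
    for i in range(modes.n_nodes):
        lo = max(0, i - 1)
        hi = min(modes.n_nodes, i + 2)
        if smooth[i] <= smooth[lo:hi].min() and smooth[i] <= thresh:
            flags[i] = True
    return FluctuationProfile(
        msf=msf,
        hinge_flags=flags,
        n_modes_used=K,
        smooth_window=w,
        percentile=hinge_percentile,
    )


def mode_overlap(v: np.ndarray, d: np.ndarray) -> float:
    """|cosine| between a (unit) mode and a transition vector: |v·d|/(‖v‖‖d‖)."""
    v = np.asarray(v, dtype=float).ravel()
    d = np.asarray(d, dtype=float).ravel()
    nd = np.linalg.norm(d)
    if nd == 0:
        raise DegenerateGeometryError("transition vector is zero")
    nv = np.linalg.norm(v)
    if nv == 0:
        raise DegenerateGeometryError("mode vector is zero")
    return float(abs(v @ d) / (nv * nd))


def cumulative_overlap(modes: ModeSet, d: np.ndarray, mode_indices=None) -> float:
    """Root-sum-square overlap of a mode subset with a transition vector.

    Bounded by 1 (Bessel); equals 1 when the subset spans the full non-rigid
    space and d has no rigid-body component.
    """
    indices = (
        list(range(1, modes.n_modes + 1)) if mode_indices is None else list(mode_indices)
    )
    total = 0.0
    for m in indices:
        total += mode_overlap(modes.eigenvectors[m - 1], d) ** 2
    return float(np.sqrt(total))


def overlap_table(modes: ModeSet, d: np.ndarray, n_modes: int | None = None):
    """Per-mode overlap with a transition vector, as a pandas DataFrame."""
    import pandas as pd

    K = min(n_modes or modes.n_modes, modes.n_modes)
    rows = []
    csum = 0.0
    for m in range(1, K + 1):
        o = mode_overlap(modes.eigenvectors[m - 1], d)
        csum += o**2
        rows.append(
            {"mode": m, "eigenvalue": modes.eigenvalues[m - 1], "overlap": o,
             "cumulative_overlap": float(np.sqrt(csum))}
        )
    return pd.DataFrame(rows)
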