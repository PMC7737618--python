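"""Transition-pathway generation and elevator-shift metrics.

Inward/outward endpoint models are generated by iterative normal-mode
climbing: at each step the elastic-network modes of the current conformer
are computed, the few modes best overlapping the remaining direction (the
PC1 axis, or the difference to an explicit target) are combined with
overlap weights, the structure is displaced by a fixed rmsd amplitude along
that combination, and the Cα virtual-bond lengths of the start structure
are restored to keep the chain physical.  Progress is monitored as the PC1
projection of each frame; the coverage of a path or model is its projection
relative to the target's, and the elevator shift is the membrane-normal
displacement of the binding-site centroid after scaffold superposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import pca as _pca
from .enm import ENMParams, ModeSet, build_network, compute_modes, rigid_body_basis
from .errors import (
    ConsistencyError,
    DegenerateGeometryError,
    EmptySelectionError,
    ValidationError,
)
from .structures import CalphaModel, DomainDefinition


@dataclass
class PathStep:
    """One iteration of the pathway generator (for the step log)."""

    iteration: int
    modes_used: list[int]
    best_overlap: float
    amplitude: float
    projection: float
    rmsd_to_target: float
    coverage: float


@dataclass
class TransitionPath:
    """Ordered conformer frames plus the per-frame progress log."""

    frames: list[CalphaModel]
    steps: list[PathStep]
    stop_reason: str

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def projections(self) -> np.ndarray:
        return np.array([s.projection for s in self.steps])

    @property
    def coverages(self) -> np.ndarray:
        return np.array([s.coverage for s in self.steps])

    def step_table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "iteration": s.iteration,
                    "modes": "+".join(str(m) for m in s.modes_used),
                    "best_overlap": s.best_overlap,
                    "amplitude": s.amplitude,
                    "projection": s.projection,
                    "rmsd_to_target": s.rmsd_to_target,
                    "coverage": s.coverage,
                }
                for s in self.steps
            ]
        )


@dataclass
class ElevatorMetrics:
    """Membrane-normal (elevator) and in-plane displacement of the
    binding-site centroid, plus an optional transition coverage."""

    shift: float
    in_plane: float
    coverage: float | None = None


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _restore_bonds(coords: np.ndarray, model: CalphaModel, ref_lengths: dict) -> np.ndarray:
    """One N→C pass re-projecting each successive Cα–Cα virtual bond back to
    its start-structure length (keeps the trace physical at Cα resolution)."""
    out = coords.copy()
    for start, stop in model.chain_slices():
        for i in range(start, stop - 1):
            b = out[i + 1] - out[i]
            L = np.linalg.norm(b)
            L0 = ref_lengths[i]
            if L > 0:
                out[i + 1] = out[i] + b * (L0 / L)
    return out


def generate_pathway(
    start: CalphaModel,
    target: CalphaModel | None = None,
    axis: np.ndarray | None = None,
    basis: _pca.PCABasis | None = None,
    enm_params: ENMParams | None = None,
    step_rmsd: float = 0.5,
    mode_pool: int = 20,
    modes_per_step: int = 3,
    stop_coverage: float = 0.95,
    max_iterations: int = 100,
    overlap_floor: float = 0.05,
    recompute_modes: bool = True,
    axis_amplitude: float | None = None,
    fit_mask: np.ndarray | None = None,
) -> TransitionPath:
    """Iterative normal-mode climbing from ``start`` toward a target.

    Exactly one of ``target`` (an explicit endpoint structure) or ``axis``
    (a 3M direction, e.g. PC1 of an experimental ensemble, with
    ``axis_amplitude`` the projection to reach in Å) drives the walk.
    ``basis`` only adds an independent PC1 projection to the step log when a
    target is supplied.  After every step the frame is superposed back onto
    the start over ``fit_mask`` (all residues if None; pass the scaffold
    mask to monitor progress in the dimerization-domain frame), and the
    rigid-body component of the remaining direction is projected out before
    mode overlaps are taken — internal modes cannot produce net
    translation or rotation, so leaving it in would only stall the walk.
    The generator is fully deterministic: identical inputs give identical
    step logs.
    """
    enm_params = enm_params or ENMParams()
    if (target is None) == (axis is None):
        raise ValidationError("supply exactly one of target or axis")
    M = len(start)
    coords = start.coords.copy()
    ref_lengths: dict[int, float] = {}
    for s0, s1 in start.chain_slices():
        for i in range(s0, s1 - 1):
            ref_lengths[i] = float(np.linalg.norm(start.coords[i + 1] - start.coords[i]))

    if target is not None:
        if len(target) != M:
            raise ConsistencyError("start and target differ in residue count")
        goal = target.coords
        d_total = (goal - start.coords).ravel()
        if np.linalg.norm(d_total) == 0:
            return TransitionPath(
                frames=[start], steps=[], stop_reason="target equals start"
            )
        axis_unit = d_total / np.linalg.norm(d_total)
        p_target = float(np.linalg.norm(d_total))
    else:
        axis = np.asarray(axis, dtype=float).ravel()
        if axis.shape[0] != 3 * M:
            raise ConsistencyError("axis length must be 3M")
        n = np.linalg.norm(axis)
        if n == 0:
            raise DegenerateGeometryError("axis vector is zero")
        axis_unit = axis / n
        if axis_amplitude is None or axis_amplitude <= 0:
            raise ValidationError("axis-driven walks need a positive axis_amplitude")
        p_target = float(axis_amplitude)

    def log_projection(x: np.ndarray) -> float:
        if basis is not None:
            return _pca.project(x, basis, start.coords, components=[1])[1]
        return float((x - start.coords).ravel() @ axis_unit)

    frames = [start]
    steps: list[PathStep] = [
        PathStep(
            iteration=0,
            modes_used=[],
            best_overlap=float("nan"),
            amplitude=0.0,
            projection=log_projection(coords),
            rmsd_to_target=_rmsd(coords, goal) if target is not None else float("nan"),
            coverage=0.0,
        )
    ]
    modes: ModeSet | None = None
    stop_reason = "max iterations reached"
    for it in range(1, max_iterations + 1):
        if target is not None:
            remaining = (goal - coords).ravel()
        else:
            done = float((coords - start.coords).ravel() @ axis_unit)
            remaining = axis_unit * (p_target - done)
        if modes is None or recompute_modes:
            net = build_network(CalphaModel(start.residues, coords), enm_params)
            modes = compute_modes(net, n_modes=mode_pool)
        # strip net translation/rotation: internal modes cannot produce it
        rb = rigid_body_basis(coords)
        remaining = remaining - rb.T @ (rb @ remaining)
        r_norm = np.linalg.norm(remaining)
        if r_norm < 1e-12:
            stop_reason = "target reached"
            break
        d_hat = remaining / r_norm
        signed = modes.eigenvectors[: mode_pool] @ d_hat
        order = np.argsort(-np.abs(signed))[:modes_per_step]
        best = float(np.abs(signed[order[0]]))
        if best < overlap_floor:
            stop_reason = (
                f"stalled: best mode overlap {best:.3f} below floor {overlap_floor}"
            )
            break
        disp = np.zeros(3 * M)
        for m in order:
            disp += signed[m] * modes.eigenvectors[m]
        disp_rmsd = np.linalg.norm(disp) / np.sqrt(M)
        if disp_rmsd == 0:
            stop_reason = "stalled: zero displacement"
            break
        # never overshoot the remaining distance
        amp = min(step_rmsd, r_norm / np.sqrt(M))
        disp *= amp / disp_rmsd
        coords = coords + disp.reshape(M, 3)
        coords = _restore_bonds(coords, start, ref_lengths)
        if not np.all(np.isfinite(coords)):
            raise DegenerateGeometryError("non-finite coordinates during pathway step")
        moved, _, _ = _pca.kabsch_superpose(
            start.with_coords(coords), start, fit_mask
        )
        coords = moved.coords
        proj = log_projection(coords)
        cov = proj / p_target if p_target != 0 else float("nan")
        frames.append(start.with_coords(coords.copy()))
        steps.append(
            PathStep(
                iteration=it,
                modes_used=[int(m) + 1 for m in order],
                best_overlap=best,
                amplitude=float(amp),
                projection=proj,
                rmsd_to_target=_rmsd(coords, goal) if target is not None else float("nan"),
                coverage=float(cov),
            )
        )
        if cov >= stop_coverage:
            stop_reason = f"coverage {cov:.3f} reached stop criterion {stop_coverage}"
            break
    return TransitionPath(frames=frames, steps=steps, stop_reason=stop_reason)


def coverage(
    model: CalphaModel | np.ndarray,
    start: CalphaModel,
    target: CalphaModel,
    basis: _pca.PCABasis | None = None,
    method: str = "projection",
) -> float:
    """Fraction of the start→target transition achieved by ``model``.

    ``projection`` (default): ratio of PC1 projections with the start as
    reference -- PC1 from ``basis`` if given, else the unit start→target
    difference vector.  ``rmsd``: 1 - rmsd(model, target)/rmsd(start, target).
    """
    x = model.coords if isinstance(model, CalphaModel) else np.asarray(model, dtype=float)
    if method == "rmsd":
        denom = _rmsd(start.coords, target.coords)
        if denom == 0:
            raise DegenerateGeometryError("start equals target; coverage undefined")
        return 1.0 - _rmsd(x, target.coords) / denom
    if method != "projection":
        raise ValidationError(f"unknown coverage method {method!r}")
    if basis is not None:
        p_model = _pca.project(x, basis, start.coords, components=[1])[1]
        p_target = _pca.project(target.coords, basis, start.coords, components=[1])[1]
    else:
        d = (target.coords - start.coords).ravel()
        n = np.linalg.norm(d)
        if n == 0:
            raise DegenerateGeometryError("start equals target; coverage undefined")
        u = d / n
        p_model = float((x - start.coords).ravel() @ u)
        p_target = float(n)
    if p_target == 0:
        raise DegenerateGeometryError("target projects to zero; coverage undefined")
    return p_model / p_target


def elevator_shift(
    model_a: CalphaModel,
    model_b: CalphaModel,
    domains: DomainDefinition,
) -> ElevatorMetrics:
    """Membrane-normal displacement of the binding-site centroid between two
    states, after superposing b onto a over the dimer (scaffold) domain.

    The decomposition is frame-invariant: any rigid transform applied
    jointly to both inputs cancels in the scaffold superposition.
    """
    if [r[:3] for r in model_a.residues] != [r[:3] for r in model_b.residues]:
        raise ConsistencyError("elevator_shift needs a shared residue set")
    fit_mask = domains.mask(model_a, "dimer_domain")
    site_mask = domains.mask(model_a, "binding_site")
    if not site_mask.any():
        raise EmptySelectionError("binding_site selects no residues of the model")
    moved, _, _ = _pca.kabsch_superpose(model_b, model_a, fit_mask)
    delta = moved.coords[site_mask].mean(axis=0) - model_a.coords[site_mask].mean(axis=0)
    n = domains.membrane_normal
    along = float(delta @ n)
    in_plane = float(np.linalg.norm(delta - along * n))
    return ElevatorMetrics(shift=abs(along), in_plane=in_plane)
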