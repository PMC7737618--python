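"""Structural-ensemble principal component analysis.

A matched ensemble of Cα structures is superposed onto a reference subdomain
(typically the static dimerization domain of the reference transporter) and
the 3M-dimensional coordinate covariance is diagonalized.  Each structure i
is then characterized by its scalar projections onto the leading principal
axes,

    p_{i,k} = |T_{i-0}| cos(PC_k, T_{i-0}) = T_{i-0} · PC_k,

where T_{i-0} is the coordinate-difference vector between structure i and a
chosen reference structure 0.  For elevator transporters PC1 is the
inward-outward conformational axis, so projections sort structures along the
transition pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConsistencyError,
    DegenerateGeometryError,
    FrameMismatchError,
    InsufficientDataError,
    ValidationError,
)
from .structures import CalphaModel, CorrespondenceTable


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition (Kabsch, via SVD).

    Returns (R, t, mobile_centroid) so that the optimal transform of a point
    x is ``R @ (x - mobile_centroid) + t`` with t the reference centroid.
    The rotation is proper (det = +1, never a reflection).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ConsistencyError("superposition needs two equal N x 3 coordinate sets")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    A = (mobile - cm).T @ (reference - cr)
    U, s, Vt = np.linalg.svd(A)
    # degenerate if the points carry < 2 independent directions
    if s[1] <= 1e-10 * max(s[0], 1e-300):
        raise DegenerateGeometryError(
            "fit atoms are collinear or coincident; superposition is ill-defined"
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cr, cm


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(
    mobile: CalphaModel, reference: CalphaModel, mask: np.ndarray | None = None
) -> tuple[CalphaModel, float, float]:
    """Superpose ``mobile`` onto ``reference`` over the masked residues.

    Returns the transformed model, the rmsd over the mask and the rmsd over
    all matched residues.  The fit is least-squares optimal over the masked
    atoms only (e.g. a scaffold-domain fit leaves genuine core-domain motion
    visible in the overall rmsd).
    """
    if len(mobile) != len(reference):
        raise ConsistencyError(
            f"mobile ({len(mobile)}) and reference ({len(reference)}) differ in size"
        )
    if mask is None:
        mask = np.ones(len(mobile), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (len(mobile),):
        raise ValidationError("mask length must equal the number of residues")
    if int(mask.sum()) < 3:
        raise DegenerateGeometryError("superposition mask needs >= 3 residues")
    R, t, c = kabsch_rotation(mobile.coords[mask], reference.coords[mask])
    moved = (mobile.coords - c) @ R.T + t
    out = mobile.with_coords(moved)
    return out, _rmsd(moved[mask], reference.coords[mask]), _rmsd(moved, reference.coords)


@dataclass
class SuperposedEnsemble:
    """Matched-residue coordinate stack after superposition on the fit mask."""

    structure_ids: list[str]
    coords: np.ndarray  # N x M x 3
    fit_mask: np.ndarray  # length M
    reference_id: str
    residues: list = field(default_factory=list)
    fit_rmsds: np.ndarray | None = None
    all_rmsds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.fit_mask = np.asarray(self.fit_mask, dtype=bool)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("ensemble coordinates must be N x M x 3")
        if self.fit_mask.shape != (self.coords.shape[1],):
            raise ValidationError("fit mask length must equal M")
        if int(self.fit_mask.sum()) < 3:
            raise ValidationError("fit mask needs >= 3 residues")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("ensemble coordinates must be finite")

    @property
    def n_structures(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def coords_of(self, sid: str) -> np.ndarray:
        return self.coords[self.structure_ids.index(sid)]

    @property
    def mean_fit_rmsd(self) -> float:
        return float(np.mean(self.fit_rmsds))

    @property
    def fit_rmsd_sd(self) -> float:
        return float(np.std(self.fit_rmsds))

    @property
    def mean_all_rmsd(self) -> float:
        return float(np.mean(self.all_rmsds))

    @property
    def all_rmsd_sd(self) -> float:
        return float(np.std(self.all_rmsds))


def build_ensemble(
    models: dict[str, CalphaModel],
    correspondence: CorrespondenceTable,
    reference_id: str,
    fit_mask: np.ndarray,
) -> SuperposedEnsemble:
    """Extract the matched core of every structure and superpose each onto
    the reference over the fit mask.

    The reported ensemble spread (mean ± s.d. of the all-residue rmsd to the
    reference) quantifies how structurally diverse the aligned set is.
    """
    if reference_id not in models:
        raise ConsistencyError(f"reference structure '{reference_id}' not supplied")
    for sid in correspondence.structure_ids:
        if sid not in models:
            raise ConsistencyError(
                f"structure '{sid}' in the correspondence table was not supplied"
            )
    matched = {
        sid: correspondence.matched_calpha(sid, models[sid])
        for sid in correspondence.structure_ids
    }
    ref = matched[reference_id]
    ids = list(correspondence.structure_ids)
    stack = np.empty((len(ids), len(ref), 3))
    fit_rmsds = np.empty(len(ids))
    all_rmsds = np.empty(len(ids))
    for i, sid in enumerate(ids):
        moved, r_fit, r_all = kabsch_superpose(matched[sid], ref, fit_mask)
        stack[i] = moved.coords
        fit_rmsds[i] = r_fit
        all_rmsds[i] = r_all
    return SuperposedEnsemble(
        structure_ids=ids,
        coords=stack,
        fit_mask=np.asarray(fit_mask, dtype=bool),
        reference_id=reference_id,
        residues=list(ref.residues),
        fit_rmsds=fit_rmsds,
        all_rmsds=all_rmsds,
    )


@dataclass
class PCABasis:
    """Principal axes of the coordinate covariance.

    ``eigenvectors`` has unit-norm rows (K x 3M); eigenvalues are sorted
    descending (Ų, population 1/N normalization); ``variance_fractions``
    are eigenvalue fractions of the total variance.
    """

    mean: np.ndarray  # 3M
    eigenvectors: np.ndarray  # K x 3M
    eigenvalues: np.ndarray  # K
    total_variance: float
    fit_mask: np.ndarray | None = None
    frame_coords: np.ndarray | None = None  # M x 3 reference frame anchor

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)

    @property
    def variance_fractions(self) -> np.ndarray:
        if self.total_variance == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / self.total_variance

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def covariance_pca(ensemble: SuperposedEnsemble, n_components: int | None = None) -> PCABasis:
    """Diagonalize the 3M x 3M coordinate covariance of the ensemble.

    Implemented through the SVD of the centered N x 3M coordinate matrix
    (covariance normalization 1/N); at most N-1 eigenvalues are nonzero.
    Eigenvector signs follow the convention that the largest-magnitude
    component of each axis is positive; use :func:`calibrate_signs` to pin
    PC1 to a designated outward-facing structure instead.
    """
    N = ensemble.n_structures
    if N < 2:
        raise InsufficientDataError("covariance PCA needs at least 2 structures")
    X = ensemble.coords.reshape(N, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / N
    total = float(np.sum(Xc**2) / N)
    K = min(n_components or len(eigvals), len(eigvals))
    vecs = Vt[:K].copy()
    for k in range(K):
        j = int(np.argmax(np.abs(vecs[k])))
        if vecs[k, j] < 0:
            vecs[k] = -vecs[k]
    return PCABasis(
        mean=mean,
        eigenvectors=vecs,
        eigenvalues=eigvals[:K].copy(),
        total_variance=total,
        fit_mask=ensemble.fit_mask.copy(),
        frame_coords=ensemble.coords_of(ensemble.reference_id).copy(),
    )


def calibrate_signs(
    basis: PCABasis,
    calibration_coords: np.ndarray,
    reference_coords: np.ndarray,
    components: list[int] | None = None,
) -> PCABasis:
    """Fix eigenvector signs so the designated calibration structure (e.g.
    an outward-facing homologue) projects positive.

    Principal axes are sign-ambiguous; pinning the sign to a structure of
    known conformation gives projections a physical direction (inward ->
    outward increases along PC1).  By default only PC1 is calibrated.
    """
    components = components if components is not None else [1]
    T = (np.asarray(calibration_coords, dtype=float) - np.asarray(reference_coords, dtype=float)).ravel()
    vecs = basis.eigenvectors.copy()
    for k in components:
        if not 1 <= k <= basis.n_components:
            raise ValidationError(f"component {k} out of range")
        p = float(vecs[k - 1] @ T)
        if p < 0:
            vecs[k - 1] = -vecs[k - 1]
    return PCABasis(
        mean=basis.mean,
        eigenvectors=vecs,
        eigenvalues=basis.eigenvalues,
        total_variance=basis.total_variance,
        fit_mask=basis.fit_mask,
        frame_coords=basis.frame_coords,
    )


def project(
    coords: np.ndarray,
    basis: PCABasis,
    reference_coords: np.ndarray,
    components: list[int] | None = None,
    frame_tolerance: float | None = None,
) -> dict[int, float]:
    """Scalar projections p_k = T · PC_k of one structure.

    T is the 3M difference vector between the structure and the chosen
    reference (projections of the reference itself are identically 0).
    If ``frame_tolerance`` is given, the structure must superpose onto the
    stored basis frame over the fit mask to within that rmsd, guarding
    against projecting coordinates that were never brought into the
    ensemble frame.
    """
    coords = np.asarray(coords, dtype=float)
    reference_coords = np.asarray(reference_coords, dtype=float)
    T = (coords - reference_coords).ravel()
    if T.shape[0] != basis.eigenvectors.shape[1]:
        raise ConsistencyError("coordinate size does not match the basis")
    if frame_tolerance is not None and basis.frame_coords is not None:
        mask = (
            basis.fit_mask
            if basis.fit_mask is not None
            else np.ones(len(basis.frame_coords), dtype=bool)
        )
        x = coords.reshape(-1, 3)
        d = float(np.sqrt(np.mean(np.sum((x[mask] - basis.frame_coords[mask]) ** 2, axis=1))))
        if d > frame_tolerance:
            raise FrameMismatchError(
                f"fit-mask rmsd to the basis frame is {d:.2f} Å "
                f"(> {frame_tolerance} Å); superpose first"
            )
    components = components if components is not None else list(range(1, basis.n_components + 1))
    out: dict[int, float] = {}
    for k in components:
        if not 1 <= k <= basis.n_components:
            raise ValidationError(f"component {k} out of range")
        out[k] = float(basis.eigenvectors[k - 1] @ T)
    return out


@dataclass
class ProjectionTable:
    """Per-structure scalar projections onto the leading components."""

    reference_id: str
    components: list[int]
    projections: dict[str, dict[int, float]]

    def to_frame(self):
        import pandas as pd

        rows = {
            sid: {f"PC{k}": v for k, v in p.items()}
            for sid, p in self.projections.items()
        }
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "structure_id"
        return df


def project_ensemble(
    ensemble: SuperposedEnsemble,
    basis: PCABasis,
    components: list[int] | None = None,
    reference_id: str | None = None,
) -> ProjectionTable:
    """Project every ensemble member; the reference projects to 0 on all
    components by construction."""
    ref_id = reference_id or ensemble.reference_id
    ref = ensemble.coords_of(ref_id)
    components = components or [1, 2, 3][: basis.n_components]
    table = {
        sid: project(ensemble.coords[i], basis, ref, components)
        for i, sid in enumerate(ensemble.structure_ids)
    }
    return ProjectionTable(reference_id=ref_id, components=list(components), projections=table)


def pc_interpolate(
    basis: PCABasis,
    template: CalphaModel,
    k: int,
    amplitudes: list[float],
) -> list[CalphaModel]:
    """Frames ``mean + a · PC_k`` for each amplitude a (Å), as Cα models.

    Writing the list with :func:`elevator.structures.write_models` yields a
    viewable pseudo-trajectory along one principal axis.
    """
    if not 1 <= k <= basis.n_components:
        raise ValidationError(f"component {k} out of range")
    amplitudes = [float(a) for a in amplitudes]
    if not all(np.isfinite(amplitudes)):
        raise ValidationError("amplitudes must be finite")
    axis = basis.eigenvectors[k - 1]
    frames = []
    for a in amplitudes:
        coords = (basis.mean + a * axis).reshape(-1, 3)
        frames.append(template.with_coords(coords))
    return frames
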