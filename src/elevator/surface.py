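"""Solvent-accessible surface, interface burial and conserved contacts.

Surface areas use the Shrake–Rupley rolling-probe algorithm (via biotite's
deterministic Fibonacci sphere sampling) with a single documented van der
Waals radius table.  Buried surface area between two residue groups follows
the interface convention BSA = (SASA(A) + SASA(B) - SASA(A∪B)) / 2, the
quantity interface servers report; a factor of 1 gives the total-buried
convention instead.

Contact analysis finds inter-domain residue pairs within a heavy-atom
distance cutoff whose evolutionary conservation grades (1 variable … 9
conserved) both reach a floor, and extracts the hydrophobic "gate" residues
sealing the ion pathway above and below the binding site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import biotite.structure as bst
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import EmptySelectionError, ValidationError
from .structures import AtomModel, DomainDefinition

# single documented vdW radius table (Å); hydrogens included only if present
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
}

HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}
)


def _to_atom_array(model: AtomModel) -> bst.AtomArray:
    arr = bst.AtomArray(model.n_atoms)
    arr.coord = np.asarray(model.coords, dtype=np.float32)
    arr.chain_id = model.chain.astype(str)
    arr.res_id = model.resnum.astype(int)
    arr.res_name = model.resname.astype(str)
    arr.atom_name = model.atomname.astype(str)
    arr.element = model.element.astype(str)
    return arr


def _radii_for(model: AtomModel, overrides: dict[str, float] | None) -> np.ndarray:
    table = dict(VDW_RADII)
    if overrides:
        table.update({k.upper(): float(v) for k, v in overrides.items()})
    radii = np.empty(model.n_atoms)
    unknown = []
    for i, el in enumerate(model.element):
        r = table.get(str(el).upper())
        if r is None:
            unknown.append(f"{model.chain[i]}:{model.resnum[i]}:{model.atomname[i]} ({el})")
            r = np.nan
        radii[i] = r
    if unknown:
        raise ValidationError(
            "no van der Waals radius for atoms: " + ", ".join(unknown[:10])
            + ("  …" if len(unknown) > 10 else "")
        )
    return radii


@dataclass
class SasaResult:
    """Per-atom and per-residue solvent-accessible surface area (Ų)."""

    per_atom: np.ndarray
    per_residue: pd.DataFrame  # chain, resnum, resname, sasa
    probe_radius: float
    point_number: int

    @property
    def total(self) -> float:
        return float(np.nansum(self.per_atom))


def sasa(
    model: AtomModel,
    probe_radius: float = 1.4,
    point_number: int = 960,
    radii_overrides: dict[str, float] | None = None,
) -> SasaResult:
    """Shrake–Rupley SASA with the package's vdW radius table.

    Deterministic for a fixed ``point_number``: the sphere points come from
    a fixed Fibonacci spiral, not random sampling.
    """
    if model.n_atoms == 0:
        raise EmptySelectionError("empty atom model")
    radii = _radii_for(model, radii_overrides)
    arr = _to_atom_array(model)
    per_atom = bst.sasa(
        arr,
        probe_radius=probe_radius,
        point_number=point_number,
        vdw_radii=radii,
        ignore_ions=False,
    )
    per_atom = np.nan_to_num(np.asarray(per_atom, dtype=float), nan=0.0)
    df = pd.DataFrame(
        {
            "chain": model.chain,
            "resnum": model.resnum,
            "resname": model.resname,
            "sasa": per_atom,
        }
    )
    per_res = (
        df.groupby(["chain", "resnum", "resname"], sort=False)["sasa"]
        .sum()
        .reset_index()
    )
    return SasaResult(
        per_atom=per_atom,
        per_residue=per_res,
        probe_radius=probe_radius,
        point_number=point_number,
    )


def _group_mask(model: AtomModel, group) -> np.ndarray:
    """A group is a boolean atom mask or a {chain: residue set} mapping."""
    if isinstance(group, np.ndarray) and group.dtype == bool:
        if group.shape != (model.n_atoms,):
            raise ValidationError("group mask length must equal the atom count")
        return group
    if isinstance(group, dict):
        return np.array(
            [int(n) in group.get(str(c), set())
             for c, n in zip(model.chain, model.resnum)],
            dtype=bool,
        )
    raise ValidationError("group must be a boolean atom mask or {chain: residues}")


def buried_area(
    model: AtomModel,
    group_a,
    group_b,
    probe_radius: float = 1.4,
    point_number: int = 960,
    convention: str = "interface",
    radii_overrides: dict[str, float] | None = None,
) -> float:
    """Buried surface area between two disjoint residue groups (Ų).

    BSA = (SASA(A alone) + SASA(B alone) - SASA(A∪B)) / 2 by default
    ("interface" convention); ``convention="total"`` omits the half.
    """
    mask_a = _group_mask(model, group_a)
    mask_b = _group_mask(model, group_b)
    if not mask_a.any() or not mask_b.any():
        raise EmptySelectionError("both groups must select at least one atom")
    if np.any(mask_a & mask_b):
        raise ValidationError("groups overlap; buried area is undefined")
    kw = dict(
        probe_radius=probe_radius,
        point_number=point_number,
        radii_overrides=radii_overrides,
    )
    sa = sasa(model.select(mask_a), **kw).total
    sb = sasa(model.select(mask_b), **kw).total
    sab = sasa(model.select(mask_a | mask_b), **kw).total
    bsa = sa + sb - sab
    if convention == "interface":
        return bsa / 2.0
    if convention == "total":
        return bsa
    raise ValidationError(f"unknown convention {convention!r}")


@dataclass
class ContactEdge:
    residue_a: tuple[str, int, str]  # chain, resnum, resname
    residue_b: tuple[str, int, str]
    min_distance: float
    domain_pair: str


@dataclass
class ContactNetwork:
    """Conservation-filtered inter-domain residue contacts."""

    edges: list[ContactEdge]
    grades: dict[tuple[str, int], int]
    residue_centroids: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    cutoff: float = 4.5
    grade_floor: int = 8

    def __len__(self) -> int:
        return len(self.edges)

    def participants(self) -> list[tuple[str, int, str]]:
        seen: dict[tuple[str, int, str], None] = {}
        for e in self.edges:
            seen.setdefault(e.residue_a, None)
            seen.setdefault(e.residue_b, None)
        return list(seen)

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chain_a": e.residue_a[0],
                    "resnum_a": e.residue_a[1],
                    "resname_a": e.residue_a[2],
                    "chain_b": e.residue_b[0],
                    "resnum_b": e.residue_b[1],
                    "resname_b": e.residue_b[2],
                    "min_distance": e.min_distance,
                    "domain_pair": e.domain_pair,
                }
                for e in self.edges
            ]
        )


def load_conservation(path: str | Path) -> dict[tuple[str, int], int]:
    """Read a per-residue conservation table (CSV ``chain,resnum,grade``)."""
    df = pd.read_csv(path)
    needed = {"chain", "resnum", "grade"}
    if not needed <= set(df.columns):
        raise ValidationError(
            f"conservation table needs columns {sorted(needed)}; got {list(df.columns)}"
        )
    out: dict[tuple[str, int], int] = {}
    for _, row in df.iterrows():
        grade = int(row["grade"])
        if not 1 <= grade <= 9:
            raise ValidationError(f"conservation grade {grade} outside 1–9")
        out[(str(row["chain"]), int(row["resnum"]))] = grade
    return out


def interdomain_contacts(
    model: AtomModel,
    domains: DomainDefinition,
    conservation: dict[tuple[str, int], int],
    cutoff: float = 4.5,
    grade_floor: int = 8,
    domain_a: str = "core_domain",
    domain_b: str = "dimer_domain",
) -> ContactNetwork:
    """Inter-domain residue pairs with min heavy-atom distance ≤ cutoff and
    both conservation grades ≥ the floor.

    Residues absent from the conservation table get grade 0 and are
    excluded, mirroring how unscored positions are treated upstream.
    """
    heavy = np.array([str(e).upper() != "H" for e in model.element], dtype=bool)
    mask_a = domains.atom_mask(model, domain_a) & heavy
    mask_b = domains.atom_mask(model, domain_b) & heavy
    if not mask_a.any() or not mask_b.any():
        raise EmptySelectionError("a domain selects no heavy atoms of the model")

    idx_a = np.where(mask_a)[0]
    idx_b = np.where(mask_b)[0]
    tree_b = cKDTree(model.coords[idx_b])
    pairs = tree_b.query_ball_point(model.coords[idx_a], cutoff)

    best: dict[tuple, float] = {}
    names: dict[tuple[str, int], str] = {}
    centroids: dict[tuple[str, int], list] = {}
    for i in range(model.n_atoms):
        key = (str(model.chain[i]), int(model.resnum[i]))
        names.setdefault(key, str(model.resname[i]))
        if heavy[i]:
            centroids.setdefault(key, []).append(model.coords[i])
    for ia, hits in zip(idx_a, pairs):
        ra = (str(model.chain[ia]), int(model.resnum[ia]))
        for j in hits:
            ib = idx_b[j]
            rb = (str(model.chain[ib]), int(model.resnum[ib]))
            if ra == rb:
                continue
            d = float(np.linalg.norm(model.coords[ia] - model.coords[ib]))
            pair = (ra, rb)
            if d < best.get(pair, np.inf):
                best[pair] = d

    edges = []
    for (ra, rb), d in sorted(best.items()):
        if conservation.get(ra, 0) < grade_floor or conservation.get(rb, 0) < grade_floor:
            continue
        edges.append(
            ContactEdge(
                residue_a=(ra[0], ra[1], names[ra]),
                residue_b=(rb[0], rb[1], names[rb]),
                min_distance=d,
                domain_pair=f"{domain_a}-{domain_b}",
            )
        )
    grades = {k: conservation.get(k, 0) for k in names}
    cent = {k: np.mean(v, axis=0) for k, v in centroids.items()}
    return ContactNetwork(
        edges=edges,
        grades=grades,
        residue_centroids=cent,
        cutoff=cutoff,
        grade_floor=grade_floor,
    )


@dataclass
class GateResidue:
    chain: str
    resnum: int
    resname: str
    side: str  # "above" (extracellular) or "below" (intracellular)
    n_contacts: int


def gate_residues(
    network: ContactNetwork,
    binding_site_centroid: np.ndarray,
    membrane_normal: np.ndarray = (0.0, 0.0, 1.0),
    hydrophobic_set: frozenset[str] = HYDROPHOBIC_RESIDUES,
) -> list[GateResidue]:
    """Hydrophobic residues participating in inter-domain contacts, grouped
    by which side of the binding site they sit along the membrane normal.

    These are the candidate hydrophobic gates sealing the ion pathway above
    (extracellular side) and below (intracellular side) the site.
    """
    n = np.asarray(membrane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    c0 = np.asarray(binding_site_centroid, dtype=float)
    counts: dict[tuple[str, int, str], int] = {}
    for e in network.edges:
        for r in (e.residue_a, e.residue_b):
            counts[r] = counts.get(r, 0) + 1
    out = []
    for (chain, resnum, resname), k in sorted(counts.items()):
        if resname not in hydrophobic_set:
            continue
        pos = network.residue_centroids.get((chain, resnum))
        height = float((pos - c0) @ n) if pos is not None else 0.0
        out.append(
            GateResidue(
                chain=chain,
                resnum=resnum,
                resname=resname,
                side="above" if height >= 0 else "below",
                n_contacts=k,
            )
        )
    return out
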