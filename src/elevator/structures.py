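"""Structure input/output and the shared configuration objects.

Coordinates enter the pipeline as PDB or mmCIF files (read with gemmi) and
leave it as multi-model PDB "trajectories".  Two light containers are the
structural currency of every downstream stage:

* :class:`AtomModel` -- all atoms of one model, with chain/residue/atom
  identity kept as parallel arrays;
* :class:`CalphaModel` -- one coordinate row per residue (the Cα trace), the
  node set for elastic networks and ensemble PCA.

Residue numbering is the author numbering found in the file; insertion codes
are kept alongside the number so identity is lossless.  Alternate locations
are resolved to the highest-occupancy conformer (ties broken by altloc
letter) at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import yaml

from .errors import (
    ConsistencyError,
    EmptySelectionError,
    FormatError,
    ValidationError,
)

logger = logging.getLogger(__name__)

ResidueKey = tuple[str, int, str]  # (chain id, residue number, insertion code)


@dataclass
class AtomModel:
    """All atoms of a single structural model.

    Parallel arrays, one entry per atom, in file order.  The triple
    (chain, residue number + insertion code, atom name) is unique within a
    model.
    """

    chain: np.ndarray
    resnum: np.ndarray
    icode: np.ndarray
    resname: np.ndarray
    atomname: np.ndarray
    element: np.ndarray
    coords: np.ndarray
    model_id: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("atom coordinates must be an N x 3 array")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("atom coordinates must be finite")
        keys = list(zip(self.chain, self.resnum, self.icode, self.atomname))
        if len(set(keys)) != len(keys):
            raise ValidationError(
                "duplicate (chain, residue, atom name) triple in model"
            )

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def residue_keys(self) -> list[ResidueKey]:
        """Ordered unique residue identities, in file order."""
        seen: dict[ResidueKey, None] = {}
        for c, n, i in zip(self.chain, self.resnum, self.icode):
            seen.setdefault((str(c), int(n), str(i)), None)
        return list(seen)

    def select(self, mask: np.ndarray) -> "AtomModel":
        mask = np.asarray(mask, dtype=bool)
        return AtomModel(
            chain=self.chain[mask],
            resnum=self.resnum[mask],
            icode=self.icode[mask],
            resname=self.resname[mask],
            atomname=self.atomname[mask],
            element=self.element[mask],
            coords=self.coords[mask],
            model_id=self.model_id,
        )


@dataclass
class CalphaModel:
    """Cα trace: one coordinate row per residue.

    ``residues`` is an ordered list of (chain, residue number, insertion
    code, residue name); ordering is stable (chains in file order, ascending
    residue number within a chain as read).
    """

    residues: list[tuple[str, int, str, str]]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.residues), 3):
            raise ValidationError(
                "one coordinate row per residue is required "
                f"({self.coords.shape[0]} rows, {len(self.residues)} residues)"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_keys(self) -> list[ResidueKey]:
        return [(c, n, i) for c, n, i, _ in self.residues]

    def with_coords(self, coords: np.ndarray) -> "CalphaModel":
        """Same residues, new coordinates (used by pathway generation)."""
        return CalphaModel(residues=list(self.residues), coords=np.array(coords, dtype=float))

    def index_of(self) -> dict[ResidueKey, int]:
        return {k: i for i, k in enumerate(self.residue_keys())}

    def chain_slices(self) -> list[tuple[int, int]]:
        """(start, stop) index ranges of consecutive same-chain residues."""
        out: list[tuple[int, int]] = []
        start = 0
        for i in range(1, len(self.residues) + 1):
            if i == len(self.residues) or self.residues[i][0] != self.residues[start][0]:
                out.append((start, i))
                start = i
        return out

    def select(self, mask: np.ndarray) -> "CalphaModel":
        mask = np.asarray(mask, dtype=bool)
        return CalphaModel(
            residues=[r for r, m in zip(self.residues, mask) if m],
            coords=self.coords[mask],
        )


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties broken by
    altloc letter order."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            continue
        if (-atom.occ, atom.altloc or "~") < (-prev.occ, prev.altloc or "~"):
            by_name[atom.name] = atom
    # preserve file order of first appearance
    seen: list[gemmi.Atom] = []
    names_done = set()
    for atom in residue:
        if atom.name in names_done:
            continue
        names_done.add(atom.name)
        seen.append(by_name[atom.name])
    return seen


def read_structure(
    path: str | Path,
    model_index: int = 0,
    chains: list[str] | None = None,
) -> AtomModel:
    """Read one model from a PDB or mmCIF file.

    Atoms come back in file order; alternate locations are resolved to the
    highest-occupancy conformer; hydrogens are retained if present.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: file contains no models")
    if model_index < 0 or model_index >= len(st):
        raise EmptySelectionError(
            f"{path}: model index {model_index} out of range (file has {len(st)} models)"
        )
    model = st[model_index]

    chain_f = set(chains) if chains is not None else None
    cols: dict[str, list] = {k: [] for k in
                             ("chain", "resnum", "icode", "resname", "atomname", "element")}
    xyz: list[tuple[float, float, float]] = []
    for chain in model:
        if chain_f is not None and chain.name not in chain_f:
            continue
        for residue in chain:
            for atom in _resolve_altlocs(residue):
                cols["chain"].append(chain.name)
                cols["resnum"].append(residue.seqid.num)
                icode = residue.seqid.icode
                cols["icode"].append("" if icode in (" ", "\0") else icode)
                cols["resname"].append(residue.name)
                cols["atomname"].append(atom.name)
                cols["element"].append(atom.element.name)
                xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if not xyz:
        raise EmptySelectionError(
            f"{path}: no atoms selected (chains={sorted(chain_f) if chain_f else 'all'})"
        )
    try:
        model_id = int(model.num)
    except (TypeError, ValueError, AttributeError):
        model_id = model_index + 1
    return AtomModel(
        chain=np.array(cols["chain"], dtype=object),
        resnum=np.array(cols["resnum"], dtype=int),
        icode=np.array(cols["icode"], dtype=object),
        resname=np.array(cols["resname"], dtype=object),
        atomname=np.array(cols["atomname"], dtype=object),
        element=np.array(cols["element"], dtype=object),
        coords=np.array(xyz, dtype=float),
        model_id=model_id,
    )


def extract_calpha(model: AtomModel) -> CalphaModel:
    """One Cα per residue; residues lacking a Cα are dropped (and logged)."""
    if model.n_atoms == 0:
        raise EmptySelectionError("empty atom model")
    residues: list[tuple[str, int, str, str]] = []
    coords: list[np.ndarray] = []
    order: list[ResidueKey] = model.residue_keys()
    # locate the CA atom of each residue (carbon only, to skip calcium ions)
    ca_pos: dict[ResidueKey, tuple[str, np.ndarray]] = {}
    for i in range(model.n_atoms):
        if model.atomname[i] == "CA" and model.element[i].upper() != "CA":
            key = (str(model.chain[i]), int(model.resnum[i]), str(model.icode[i]))
            ca_pos[key] = (str(model.resname[i]), model.coords[i])
    resname_of: dict[ResidueKey, str] = {}
    for i in range(model.n_atoms):
        key = (str(model.chain[i]), int(model.resnum[i]), str(model.icode[i]))
        resname_of.setdefault(key, str(model.resname[i]))
    for key in order:
        hit = ca_pos.get(key)
        if hit is None:
            logger.warning(
                "residue %s %s%s (%s) has no CA atom; dropped from Calpha trace",
                key[0], key[1], key[2], resname_of.get(key, "?"),
            )
            continue
        resname, pos = hit
        residues.append((key[0], key[1], key[2], resname))
        coords.append(pos)
    if not residues:
        raise EmptySelectionError("model contains no CA atoms")
    return CalphaModel(residues=residues, coords=np.array(coords))


def _calpha_to_atommodel(model: CalphaModel, model_id: int) -> AtomModel:
    n = len(model)
    return AtomModel(
        chain=np.array([r[0] for r in model.residues], dtype=object),
        resnum=np.array([r[1] for r in model.residues], dtype=int),
        icode=np.array([r[2] for r in model.residues], dtype=object),
        resname=np.array([r[3] for r in model.residues], dtype=object),
        atomname=np.array(["CA"] * n, dtype=object),
        element=np.array(["C"] * n, dtype=object),
        coords=model.coords,
        model_id=model_id,
    )


def _identity(model: AtomModel) -> tuple:
    return tuple(zip(model.chain, model.resnum, model.icode, model.resname, model.atomname))


def write_models(path: str | Path, models: list) -> None:
    """Write an ordered list of models as a multi-model PDB file.

    All models must carry the same residue/atom identity (a trajectory of
    one molecule).  Coordinates round-trip through :func:`read_structure`
    to PDB precision (0.001 Å); residue numbers above 9999 use the
    hybrid-36 convention.
    """
    if not models:
        raise ValidationError("write_models needs at least one model")
    atom_models = [
        m if isinstance(m, AtomModel) else _calpha_to_atommodel(m, i + 1)
        for i, m in enumerate(models)
    ]
    ref = _identity(atom_models[0])
    for i, m in enumerate(atom_models[1:], start=2):
        if _identity(m) != ref:
            raise ConsistencyError(
                f"model {i} has a different residue/atom set than model 1"
            )
    st = gemmi.Structure()
    st.name = "elevator"
    for i, m in enumerate(atom_models):
        gm = gemmi.Model(i + 1)
        chain_map: dict[str, gemmi.Chain] = {}
        cur_res_key = None
        cur_res = None
        for a in range(m.n_atoms):
            cname = str(m.chain[a])
            if cname not in chain_map:
                chain_map[cname] = gemmi.Chain(cname)
            key = (cname, int(m.resnum[a]), str(m.icode[a]))
            if key != cur_res_key:
                cur_res = gemmi.Residue()
                cur_res.name = str(m.resname[a])
                cur_res.seqid = gemmi.SeqId(int(m.resnum[a]), m.icode[a] or " ")
                cur_res.het_flag = "A"
                chain_map[cname].add_residue(cur_res)
                cur_res_key = key
            atom = gemmi.Atom()
            atom.name = str(m.atomname[a])
            atom.element = gemmi.Element(str(m.element[a]))
            atom.pos = gemmi.Position(*m.coords[a])
            atom.occ = 1.0
            atom.b_iso = 0.0
            # cur_res holds the residue the atom belongs to
            chain_map[cname][-1].add_atom(atom)
        for chain in chain_map.values():
            gm.add_chain(chain)
        st.add_model(gm)
    st.setup_entities()
    Path(path).write_text(st.make_pdb_string())


def read_models(path: str | Path, chains: list[str] | None = None) -> list[AtomModel]:
    """Read every model of a multi-model PDB file, in order."""
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse structure file {path}: {exc}") from exc
    return [read_structure(path, model_index=i, chains=chains) for i in range(len(st))]


# ---------------------------------------------------------------------------
# Domain definitions
# ---------------------------------------------------------------------------

_DOMDEF_KEYS = {"domains", "binding_site", "membrane_normal"}


def _expand_residue_spec(spec, where: str) -> set[int]:
    """Residue list entries are integers or [start, end] inclusive ranges."""
    out: set[int] = set()
    if not isinstance(spec, (list, tuple)):
        raise ValidationError(f"{where}: expected a list of residues/ranges")
    for item in spec:
        if isinstance(item, int):
            out.add(item)
        elif (
            isinstance(item, (list, tuple))
            and len(item) == 2
            and all(isinstance(v, int) for v in item)
        ):
            lo, hi = item
            if hi < lo:
                raise ValidationError(f"{where}: range [{lo}, {hi}] is reversed")
            out.update(range(lo, hi + 1))
        else:
            raise ValidationError(f"{where}: bad residue entry {item!r}")
    return out


@dataclass
class DomainDefinition:
    """Named residue sets per chain plus the membrane normal.

    At minimum a ``dimer_domain`` (static scaffold) and ``core_domain``
    (mobile transport domain); a ``binding_site`` set locates the ion
    site.  The membrane normal defaults to +z of the coordinate frame and
    is stored as a unit vector.
    """

    domains: dict[str, dict[str, set[int]]]
    membrane_normal: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )

    def __post_init__(self) -> None:
        v = np.asarray(self.membrane_normal, dtype=float)
        norm = float(np.linalg.norm(v))
        if norm == 0 or not np.all(np.isfinite(v)):
            raise ValidationError("membrane_normal must be a nonzero finite vector")
        self.membrane_normal = v / norm
        self._check_disjoint("dimer_domain", "core_domain")

    def _check_disjoint(self, a: str, b: str) -> None:
        if a not in self.domains or b not in self.domains:
            return
        clashes = []
        for chain, resa in self.domains[a].items():
            resb = self.domains[b].get(chain, set())
            for r in sorted(resa & resb):
                clashes.append(f"{chain}:{r}")
        if clashes:
            raise ValidationError(
                f"domains '{a}' and '{b}' overlap at residues: {', '.join(clashes)}"
            )

    def residues(self, name: str) -> dict[str, set[int]]:
        if name not in self.domains:
            raise ValidationError(f"unknown domain '{name}'")
        return self.domains[name]

    def mask(self, model: CalphaModel, name: str) -> np.ndarray:
        """Boolean per-residue mask of ``name`` on a Cα model."""
        sets = self.residues(name)
        return np.array(
            [r[1] in sets.get(r[0], set()) for r in model.residues], dtype=bool
        )

    def atom_mask(self, model: AtomModel, name: str) -> np.ndarray:
        sets = self.residues(name)
        return np.array(
            [int(n) in sets.get(str(c), set())
             for c, n in zip(model.chain, model.resnum)],
            dtype=bool,
        )

    def validate_against(self, model: CalphaModel) -> None:
        """Every referenced residue must exist in the bound model."""
        present: dict[str, set[int]] = {}
        for c, n, _i, _r in model.residues:
            present.setdefault(c, set()).add(n)
        missing = []
        for name, sets in self.domains.items():
            for chain, resset in sets.items():
                for r in sorted(resset - present.get(chain, set())):
                    missing.append(f"{name}:{chain}:{r}")
        if missing:
            raise ValidationError(
                "domain residues absent from model: " + ", ".join(missing[:20])
            )


def load_domain_definition(path: str | Path) -> DomainDefinition:
    """Load a YAML domain-definition file.

    Schema::

        domains:
          dimer_domain: {A: [[1, 50]]}
          core_domain:  {A: [[51, 120]]}
        binding_site:   {A: [90]}
        membrane_normal: [0, 0, 1]   # optional
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"cannot parse YAML {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _DOMDEF_KEYS
    if unknown:
        raise ValidationError(
            f"{path}: unknown keys {sorted(unknown)} (allowed: {sorted(_DOMDEF_KEYS)})"
        )
    domains: dict[str, dict[str, set[int]]] = {}
    for name, per_chain in (raw.get("domains") or {}).items():
        if not isinstance(per_chain, dict):
            raise ValidationError(f"{path}: domain '{name}' must map chain -> residues")
        domains[name] = {
            str(chain): _expand_residue_spec(spec, f"{path}:{name}:{chain}")
            for chain, spec in per_chain.items()
        }
    if "binding_site" in raw and raw["binding_site"] is not None:
        per_chain = raw["binding_site"]
        if not isinstance(per_chain, dict):
            raise ValidationError(f"{path}: binding_site must map chain -> residues")
        domains["binding_site"] = {
            str(chain): _expand_residue_spec(spec, f"{path}:binding_site:{chain}")
            for chain, spec in per_chain.items()
        }
    normal = raw.get("membrane_normal", [0.0, 0.0, 1.0])
    return DomainDefinition(domains=domains, membrane_normal=np.asarray(normal, dtype=float))


# ---------------------------------------------------------------------------
# Correspondence tables
# ---------------------------------------------------------------------------


@dataclass
class CorrespondenceTable:
    """Matched-residue table across N structures.

    One row per matched core position; each row holds exactly one
    (chain, residue number) entry per structure id.
    """

    structure_ids: list[str]
    rows: list[dict[str, tuple[str, int]]]

    def __post_init__(self) -> None:
        seen: dict[str, set[tuple[str, int]]] = {s: set() for s in self.structure_ids}
        for i, row in enumerate(self.rows):
            for sid in self.structure_ids:
                if sid not in row:
                    raise ValidationError(
                        f"correspondence row {i + 1} has no entry for structure '{sid}'"
                    )
                if row[sid] in seen[sid]:
                    raise ValidationError(
                        f"residue {row[sid]} of structure '{sid}' appears in two rows"
                    )
                seen[sid].add(row[sid])

    def __len__(self) -> int:
        return len(self.rows)

    def matched_calpha(self, sid: str, model: CalphaModel) -> CalphaModel:
        """Extract the matched residues of one structure, in row order."""
        if sid not in self.structure_ids:
            raise ValidationError(f"structure '{sid}' not in correspondence table")
        index: dict[tuple[str, int], int] = {}
        for i, (c, n, _ic, _rn) in enumerate(model.residues):
            index.setdefault((c, n), i)
        picks = []
        for row in self.rows:
            key = row[sid]
            if key not in index:
                raise ConsistencyError(
                    f"structure '{sid}': residue {key[0]}:{key[1]} from the "
                    "correspondence table is missing from the model"
                )
            picks.append(index[key])
        picks = np.array(picks, dtype=int)
        return CalphaModel(
            residues=[model.residues[i] for i in picks], coords=model.coords[picks]
        )


def _parse_cell(cell: str, row: int, sid: str) -> tuple[str, int]:
    cell = cell.strip()
    if not cell:
        raise ValidationError(
            f"correspondence row {row} is missing the cell for structure '{sid}'"
        )
    if ":" not in cell:
        raise ValidationError(
            f"correspondence row {row}, structure '{sid}': "
            f"cell {cell!r} is not 'chain:resnum'"
        )
    chain, resnum = cell.split(":", 1)
    try:
        return chain, int(resnum)
    except ValueError as exc:
        raise ValidationError(
            f"correspondence row {row}, structure '{sid}': bad residue number {resnum!r}"
        ) from exc


def load_correspondence(path: str | Path) -> CorrespondenceTable:
    """Load a TSV correspondence table (header: structure ids; cells
    ``chain:resnum``)."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty correspondence table")
    ids = [c.strip() for c in lines[0].split("\t")]
    if len(ids) < 2 or any(not i for i in ids):
        raise FormatError(f"{path}: header must list >= 2 structure ids")
    rows = []
    for r, line in enumerate(lines[1:], start=1):
        cells = line.split("\t")
        if len(cells) != len(ids):
            raise ValidationError(
                f"{path}: row {r} has {len(cells)} cells, expected {len(ids)}"
            )
        rows.append({sid: _parse_cell(cell, r, sid) for sid, cell in zip(ids, cells)})
    return CorrespondenceTable(structure_ids=ids, rows=rows)


def identity_correspondence(
    structure_ids: list[str], model: CalphaModel
) -> CorrespondenceTable:
    """Correspondence mapping each structure to the same residue list (used
    for synthetic ensembles where all members share one numbering)."""
    rows = [
        {sid: (c, n) for sid in structure_ids} for c, n, _i, _r in model.residues
    ]
    return CorrespondenceTable(structure_ids=list(structure_ids), rows=rows)


def write_correspondence(path: str | Path, table: CorrespondenceTable) -> None:
    lines = ["\t".join(table.structure_ids)]
    for row in table.rows:
        lines.append(
            "\t".join(f"{row[s][0]}:{row[s][1]}" for s in table.structure_ids)
        )
    Path(path).write_text("\n".join(lines) + "\n")
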