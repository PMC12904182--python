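"""Coordinate models, annotation, selections and residue correspondences.

The in-memory container is :class:`StructureModel`: column-oriented atom
records (numpy arrays) plus annotation attached by :func:`assign_roles` —
chain→subunit-role labels and a :class:`DomainDefinition` describing
per-role residue ranges (ECD, TMD, M2, ...) and the M2 gate positions
(Leu9' activation gate, Pro/Ala−2' desensitization gate).

Files are parsed with gemmi (PDB and mmCIF); the PDB writer is local so
synthetic fixtures round-trip byte-identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd
import yaml

from .errors import (
    AnnotationError,
    ConfigurationError,
    CorrespondenceError,
    EmptyStructureError,
    ParseError,
    SelectionError,
)

BACKBONE_NAMES = ("N", "CA", "C", "O")
RECEPTOR_ROLES = ("alpha1", "beta")

#: Residue names treated as non-receptor (hetero) even when given in ATOM records.
_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass
class Atom:
    """One atom record (coordinates in Å, occupancy as a fraction)."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    alt_loc: str
    occupancy: float
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.serial} {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0,1]")


@dataclass
class DomainDefinition:
    """Per-role residue ranges for named domains plus M2 gate positions.

    ``domains`` maps a domain name (``ECD``, ``TMD``, ``M2``, ``M1M2loop``,
    ``LoopC`` or any custom name) to ``{role: [(lo, hi), ...]}`` with
    1-based inclusive residue intervals, as in the source files. ``gates``
    maps ``prime9`` / ``primeMinus2`` to ``{role: residue_number}``.
    """

    domains: dict[str, dict[str, list[tuple[int, int]]]] = field(default_factory=dict)
    gates: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for dom, per_role in self.domains.items():
            for role, ivals in per_role.items():
                ivals = sorted((int(a), int(b)) for a, b in ivals)
                per_role[role] = ivals
                for (a, b) in ivals:
                    if a > b:
                        raise ConfigurationError(
                            f"domain {dom}/{role}: interval ({a},{b}) is inverted")
                for (_, b0), (a1, _) in zip(ivals, ivals[1:]):
                    if a1 <= b0:
                        raise ConfigurationError(
                            f"domain {dom}/{role}: overlapping intervals")
        for gate, per_role in self.gates.items():
            for role, resnum in per_role.items():
                tmd = self.domains.get("TMD", {}).get(role)
                if tmd is not None and not any(a <= resnum <= b for a, b in tmd):
                    raise ConfigurationError(
                        f"gate {gate}/{role}: residue {resnum} outside TMD range")

    def residues(self, name: str, role: str) -> list[tuple[int, int]]:
        if name not in self.domains:
            raise SelectionError(f"unknown domain {name!r}; have {sorted(self.domains)}")
        return self.domains[name].get(role, [])

    def contains(self, name: str, role: str, residue_number: int) -> bool:
        return any(a <= residue_number <= b for a, b in self.residues(name, role))


class StructureModel:
    """Annotated atomic coordinate set for one model (column-oriented)."""

    def __init__(self, label: str, atoms: list[Atom] | None = None):
        self.label = label
        atoms = atoms or []
        self.serial = np.array([a.serial for a in atoms], dtype=int)
        self.name = np.array([a.name for a in atoms], dtype=object)
        self.element = np.array([a.element for a in atoms], dtype=object)
        self.residue_name = np.array([a.residue_name for a in atoms], dtype=object)
        self.chain_id = np.array([a.chain_id for a in atoms], dtype=object)
        self.residue_number = np.array([a.residue_number for a in atoms], dtype=int)
        self.insertion_code = np.array([a.insertion_code for a in atoms], dtype=object)
        self.alt_loc = np.array([a.alt_loc for a in atoms], dtype=object)
        self.occupancy = np.array([a.occupancy for a in atoms], dtype=float)
        self.coords = (np.vstack([a.position for a in atoms])
                       if atoms else np.zeros((0, 3)))
        self.hetero = np.zeros(len(atoms), dtype=bool)
        self.roles: dict[str, str] = {}
        self.domains: DomainDefinition | None = None

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_arrays(cls, label: str, *, name, element, residue_name, chain_id,
                    residue_number, coords, insertion_code=None, alt_loc=None,
                    occupancy=None, serial=None, hetero=None) -> "StructureModel":
        m = cls(label)
        n = len(name)
        m.name = np.asarray(name, dtype=object)
        m.element = np.asarray(element, dtype=object)
        m.residue_name = np.asarray(residue_name, dtype=object)
        m.chain_id = np.asarray(chain_id, dtype=object)
        m.residue_number = np.asarray(residue_number, dtype=int)
        m.coords = np.asarray(coords, dtype=float).reshape(n, 3)
        m.insertion_code = (np.asarray(insertion_code, dtype=object)
                            if insertion_code is not None
                            else np.array([""] * n, dtype=object))
        m.alt_loc = (np.asarray(alt_loc, dtype=object) if alt_loc is not None
                     else np.array([""] * n, dtype=object))
        m.occupancy = (np.asarray(occupancy, dtype=float) if occupancy is not None
                       else np.ones(n))
        m.serial = (np.asarray(serial, dtype=int) if serial is not None
                    else np.arange(1, n + 1))
        m.hetero = (np.asarray(hetero, dtype=bool) if hetero is not None
                    else np.zeros(n, dtype=bool))
        if not np.all(np.isfinite(m.coords)):
            raise ValueError("non-finite coordinates")
        return m

    def __len__(self) -> int:
        return len(self.name)

    @property
    def n_atoms(self) -> int:
        return len(self.name)

    @property
    def is_hydrogen(self) -> np.ndarray:
        return np.isin(self.element, ("H", "D"))

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(c, None)
        return list(seen)

    def receptor_chains(self) -> list[str]:
        return [c for c in self.chains() if self.roles.get(c) in RECEPTOR_ROLES]

    @property
    def hetero_groups(self) -> list[tuple[str, str, int]]:
        out, seen = [], set()
        for i in np.nonzero(self.hetero)[0]:
            key = (self.residue_name[i], self.chain_id[i], int(self.residue_number[i]))
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def atom(self, i: int) -> Atom:
        return Atom(int(self.serial[i]), self.name[i], self.element[i],
                    self.residue_name[i], self.chain_id[i],
                    int(self.residue_number[i]), self.insertion_code[i],
                    self.alt_loc[i], float(self.occupancy[i]),
                    self.coords[i].copy())

    def subset(self, idx: np.ndarray, label: str | None = None) -> "StructureModel":
        m = StructureModel(label or self.label)
        for attr in ("serial", "name", "element", "residue_name", "chain_id",
                     "residue_number", "insertion_code", "alt_loc", "occupancy",
                     "hetero"):
            setattr(m, attr, getattr(self, attr)[idx].copy())
        m.coords = self.coords[idx].copy()
        m.roles = dict(self.roles)
        m.domains = self.domains
        return m

    def copy(self, label: str | None = None) -> "StructureModel":
        return self.subset(np.arange(self.n_atoms), label=label)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    label: str | None = None) -> "StructureModel":
        """Return a copy with ``x → R x + t`` applied to every atom."""
        m = self.copy(label=label)
        m.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return m

    def residue_role(self, chain: str) -> str:
        return self.roles.get(chain, "other")


# -- file I/O -----------------------------------------------------------------

def _from_gemmi_model(label: str, gmodel: gemmi.Model) -> StructureModel:
    cols: dict[str, list] = {k: [] for k in (
        "serial", "name", "element", "residue_name", "chain_id",
        "residue_number", "insertion_code", "alt_loc", "occupancy", "hetero")}
    xyz: list[tuple[float, float, float]] = []
    for chain in gmodel:
        for res in chain:
            het = res.het_flag == "H" or res.name in _WATER_NAMES
            # alt-loc collapse: highest occupancy wins, ties to the
            # lexicographically smallest alt_loc
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if (prev is None or at.occ > prev.occ
                        or (at.occ == prev.occ and at.altloc < prev.altloc)):
                    best[at.name] = at
            kept = {id(a) for a in best.values()}
            for at in res:
                if id(at) not in kept:
                    continue
                cols["serial"].append(at.serial)
                cols["name"].append(at.name)
                cols["element"].append(at.element.name)
                cols["residue_name"].append(res.name)
                cols["chain_id"].append(chain.name)
                cols["residue_number"].append(res.seqid.num)
                cols["insertion_code"].append(
                    (res.seqid.icode or "").replace("\x00", "").strip())
                cols["alt_loc"].append(
                    (at.altloc or "").replace("\x00", "").strip())
                cols["occupancy"].append(min(max(at.occ, 0.0), 1.0))
                cols["hetero"].append(het)
                xyz.append((at.pos.x, at.pos.y, at.pos.z))
    if not xyz:
        raise EmptyStructureError(f"{label}: no atoms")
    return StructureModel.from_arrays(label, coords=np.array(xyz), **cols)


def read_structure(path, dialect: str = "auto", model_index: int = 0,
                   label: str | None = None) -> StructureModel:
    """Read one coordinate model from a PDB or mmCIF file.

    Multi-model files yield model ``model_index`` (default: the first).
    Alt-loc duplicates are collapsed (highest occupancy, ties to the smallest
    alt_loc); hydrogens are kept and flagged via ``StructureModel.is_hydrogen``.
    """
    path = str(path)
    try:
        if dialect == "pdb":
            st = gemmi.read_pdb(path)
        elif dialect == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(path)[0])
        elif dialect == "auto":
            st = gemmi.read_structure(path)
        else:
            raise ConfigurationError(f"unknown dialect {dialect!r}")
    except (RuntimeError, ValueError, IndexError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    if model_index >= len(st):
        raise ParseError(f"{path}: model index {model_index} out of range "
                         f"({len(st)} models)")
    return _from_gemmi_model(label or st.name or path, st[model_index])


def read_frames(path, dialect: str = "auto") -> list[StructureModel]:
    """Read every model of a multi-model file (trajectory frames)."""
    path = str(path)
    try:
        st = (gemmi.read_pdb(path) if dialect == "pdb"
              else gemmi.read_structure(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    return [_from_gemmi_model(f"{path}#model{i + 1}", st[i]) for i in range(len(st))]


def _pdb_atom_name(name: str, element: str) -> str:
    # columns 13-16; single-letter elements start in column 14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(model: StructureModel, path, multi: list[np.ndarray] | None = None) -> None:
    """Write a model (optionally multiple coordinate frames) as PDB.

    Fixed-format writer kept local for byte-level determinism of synthetic
    fixtures. ``multi`` supplies per-frame coordinate arrays sharing the
    model's atom order; MODEL/ENDMDL records are then emitted.
    """
    frames = multi if multi is not None else [model.coords]
    lines: list[str] = []
    for fi, coords in enumerate(frames):
        if multi is not None:
            lines.append(f"MODEL     {fi + 1:4d}")
        for i in range(model.n_atoms):
            rec = "HETATM" if model.hetero[i] else "ATOM  "
            x, y, z = coords[i]
            lines.append(
                f"{rec}{min(int(model.serial[i]), 99999):5d} "
                f"{_pdb_atom_name(model.name[i], model.element[i])}"
                f"{model.alt_loc[i] or ' ':1.1s}"
                f"{model.residue_name[i]:>3.3s} "
                f"{model.chain_id[i]:1.1s}"
                f"{int(model.residue_number[i]):4d}"
                f"{model.insertion_code[i] or ' ':1.1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}"
                f"{model.occupancy[i]:6.2f}{0.0:6.2f}          "
                f"{model.element[i]:>2.2s}")
        if multi is not None:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# -- annotation ---------------------------------------------------------------

def assign_roles(model: StructureModel, roles: dict[str, str],
                 domain_def: DomainDefinition | None = None,
                 pentamer: bool = True) -> StructureModel:
    """Annotate chains with subunit roles and attach the domain definition.

    Validates that every receptor chain present is named in ``roles``, that a
    pentamer has exactly five receptor chains, and that every configured gate
    residue exists in its chain.
    """
    model = model.copy()
    present = [c for c in model.chains()
               if not np.all(model.hetero[model.chain_id == c])]
    unmapped = [c for c in present if c not in roles]
    if unmapped:
        raise ConfigurationError(
            f"chains {unmapped} present in {model.label!r} but absent from the "
            f"role config")
    for c, r in roles.items():
        if r not in RECEPTOR_ROLES + ("other",):
            raise ConfigurationError(f"chain {c}: unknown role {r!r}")
    model.roles = {c: roles[c] for c in present}
    receptor = [c for c in present if roles[c] in RECEPTOR_ROLES]
    if pentamer and len(receptor) != 5:
        raise AnnotationError(
            f"{model.label!r}: pentamer expected 5 receptor chains, found "
            f"{len(receptor)} ({receptor})")
    if domain_def is not None:
        model.domains = domain_def
        for gate, per_role in domain_def.gates.items():
            for c in receptor:
                resnum = per_role.get(roles[c])
                if resnum is None:
                    raise AnnotationError(f"gate {gate}: no residue for role "
                                          f"{roles[c]!r}")
                mask = (model.chain_id == c) & (model.residue_number == resnum)
                if not mask.any():
                    raise AnnotationError(
                        f"gate {gate}: residue {resnum} (role {roles[c]}) "
                        f"absent from chain {c}")
    return model


def select_atoms(model: StructureModel, *, roles=None, chains=None,
                 domain: str | None = None, atoms: str = "CA",
                 include_hydrogens: bool = False,
                 warn_empty: bool = True) -> np.ndarray:
    """Return sorted atom indices for a role/chain + domain + atom-class filter.

    ``atoms`` is one of ``CA``, ``backbone``, ``heavy``, ``all``. Order is
    deterministic: (chain, residue_number, insertion_code, atom name).
    """
    mask = ~model.hetero
    if chains is not None:
        mask &= np.isin(model.chain_id, list(chains))
    if roles is not None:
        ok = [c for c, r in model.roles.items() if r in roles]
        mask &= np.isin(model.chain_id, ok)
    if domain is not None:
        if model.domains is None:
            raise SelectionError("model has no domain definition; call assign_roles")
        dmask = np.zeros(model.n_atoms, dtype=bool)
        for c in model.receptor_chains():
            role = model.roles[c]
            for a, b in model.domains.residues(domain, role):
                dmask |= ((model.chain_id == c)
                          & (model.residue_number >= a)
                          & (model.residue_number <= b))
        mask &= dmask
    if atoms == "CA":
        mask &= model.name == "CA"
    elif atoms == "backbone":
        mask &= np.isin(model.name, BACKBONE_NAMES)
    elif atoms == "heavy":
        pass
    elif atoms != "all":
        raise SelectionError(f"unknown atom filter {atoms!r}")
    if atoms in ("CA", "backbone", "heavy") or not include_hydrogens:
        mask &= ~model.is_hydrogen
    idx = np.nonzero(mask)[0]
    if len(idx) == 0 and warn_empty:
        warnings.warn(f"empty selection on {model.label!r} "
                      f"(domain={domain}, atoms={atoms})", stacklevel=2)
    order = np.lexsort((model.name[idx].astype(str),
                        model.insertion_code[idx].astype(str),
                        model.residue_number[idx],
                        model.chain_id[idx].astype(str)))
    return idx[order]


# -- correspondences ----------------------------------------------------------

@dataclass
class CorrespondenceMap:
    """One-to-one C-α pairing between two models.

    ``idx_A``/``idx_B`` are atom indices of the paired C-α records in each
    model, aligned positionally.
    """

    pairs: list[tuple[str, int, str, int]]
    idx_A: np.ndarray
    idx_B: np.ndarray
    n_unmatched_A: int
    n_unmatched_B: int
    chain_mapping: dict[str, str]

    def __len__(self) -> int:
        return len(self.pairs)


def build_correspondence(model_A: StructureModel, model_B: StructureModel,
                         chain_mapping: dict[str, str] | None = None
                         ) -> CorrespondenceMap:
    """Pair residues by (mapped chain, residue_number, insertion_code).

    Only residues with a C-α in both models are paired; unmatched counts are
    reported. Residue-name mismatches warn (the α1/β subunits carry numbering
    offsets, so names may legitimately differ under an explicit mapping).
    """
    if chain_mapping is None:
        chain_mapping = {c: c for c in model_A.receptor_chains() or model_A.chains()}
    targets = list(chain_mapping.values())
    if len(set(targets)) != len(targets):
        raise ConfigurationError(f"chain mapping is not one-to-one: {chain_mapping}")

    def ca_index(model: StructureModel) -> dict[tuple[str, int, str], int]:
        idx = select_atoms(model, atoms="CA", warn_empty=False)
        return {(model.chain_id[i], int(model.residue_number[i]),
                 model.insertion_code[i]): int(i) for i in idx}

    ca_A, ca_B = ca_index(model_A), ca_index(model_B)
    pairs, ia, ib = [], [], []
    mismatched = 0
    for (ch_a, num, ic), i in ca_A.items():
        ch_b = chain_mapping.get(ch_a)
        if ch_b is None:
            continue
        j = ca_B.get((ch_b, num, ic))
        if j is None:
            continue
        if model_A.residue_name[i] != model_B.residue_name[j]:
            mismatched += 1
        pairs.append((ch_a, num, ch_b, num))
        ia.append(i)
        ib.append(j)
    if mismatched:
        warnings.warn(f"{mismatched} paired residues differ in residue name "
                      f"between {model_A.label!r} and {model_B.label!r}",
                      stacklevel=2)
    mapped_A = {k for k in ca_A if k[0] in chain_mapping}
    mapped_B = {k for k in ca_B if k[0] in targets}
    return CorrespondenceMap(
        pairs=pairs,
        idx_A=np.array(ia, dtype=int),
        idx_B=np.array(ib, dtype=int),
        n_unmatched_A=len(mapped_A) - len(pairs),
        n_unmatched_B=len(mapped_B) - len(pairs),
        chain_mapping=dict(chain_mapping),
    )


def restrict_correspondence(corr: CorrespondenceMap, model_A: StructureModel,
                            domain: str, roles=None) -> CorrespondenceMap:
    """Restrict a correspondence to pairs whose A-side residue lies in a domain."""
    if model_A.domains is None:
        raise SelectionError("model_A has no domain definition")
    keep = []
    for k, (ch, num, _, _) in enumerate(corr.pairs):
        role = model_A.roles.get(ch)
        if role not in RECEPTOR_ROLES:
            continue
        if roles is not None and role not in roles:
            continue
        if model_A.domains.contains(domain, role, num):
            keep.append(k)
    keep = np.array(keep, dtype=int)
    return CorrespondenceMap(
        pairs=[corr.pairs[k] for k in keep],
        idx_A=corr.idx_A[keep], idx_B=corr.idx_B[keep],
        n_unmatched_A=corr.n_unmatched_A, n_unmatched_B=corr.n_unmatched_B,
        chain_mapping=corr.chain_mapping)


# -- tabular output -----------------------------------------------------------

def write_table(records, path, format: str = "tsv") -> None:
    """Write tabular results as TSV or JSON with 6-significant-digit floats.

    ``records`` is a DataFrame or a list of dicts (column order = first-seen
    key order). An empty table writes its header only.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records))
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    elif format == "json":
        def conv(v):
            if isinstance(v, (np.floating, float)):
                return float(f"{float(v):.6g}")
            if isinstance(v, np.integer):
                return int(v)
            if isinstance(v, np.ndarray):
                return [conv(x) for x in v]
            return v
        payload = [{k: conv(v) for k, v in row.items()}
                   for row in df.to_dict(orient="records")]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
    else:
        raise ConfigurationError(f"unknown table format {format!r}")


# -- configuration ------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Parsed YAML config: roles, domains, gates, ligand, chain mapping."""

    roles: dict[str, str]
    domain_def: DomainDefinition
    ligand: dict
    chain_mapping: dict[str, str] | None = None
    pentamer: bool = True
    vdw_override: dict[str, float] | None = None

    def annotate(self, model: StructureModel) -> StructureModel:
        return assign_roles(model, self.roles, self.domain_def,
                            pentamer=self.pentamer)


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "roles" not in raw:
        raise ConfigurationError(f"{path}: config must be a mapping with 'roles'")
    domains = {
        dom: {role: [tuple(iv) for iv in ivals] for role, ivals in per.items()}
        for dom, per in (raw.get("domains") or {}).items()}
    gates = {g: dict(per) for g, per in (raw.get("gates") or {}).items()}
    return AnalysisConfig(
        roles=dict(raw["roles"]),
        domain_def=DomainDefinition(domains=domains, gates=gates),
        ligand=dict(raw.get("ligand") or {}),
        chain_mapping=raw.get("chain_mapping"),
        pentamer=bool(raw.get("pentamer", True)),
        vdw_override=raw.get("vdw"),
    )
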