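"""State-comparison metrics: domain COM shifts, tilt/rotation, projections.

All operations here assume the input models already share a reference frame
(deposited models aligned to their maps, or models superposed beforehand
with :func:`plgic.geometry.superpose_model`). The high-level pipeline in
:mod:`plgic.cli` performs that global superposition — over all shared
receptor C-α, unweighted — before calling into this module.

COM shifts are computed over heavy atoms of the domain by default (the
subunit domain moves as a body, and its centroid is best estimated from
every atom); pass ``ca_only=True`` to restrict to C-α. Tilt/rotation and
projections are C-α-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SelectionError, CorrespondenceError
from .geometry import Axis, kabsch_superpose, swing_twist_decompose
from .structures import (CorrespondenceMap, StructureModel,
                         restrict_correspondence, select_atoms)

#: residues whose closed→desensitized displacement is below this are reported
#: with fraction undefined rather than divided by near-zero (Å)
PROJECTION_EPSILON = 0.2


@dataclass
class DomainMotion:
    """Rigid-body motion of one subunit domain between two states."""

    chain: str
    role: str
    domain: str
    com_shift_vec: np.ndarray
    com_shift: float
    tilt_deg: float
    rotation_deg: float
    residual_rmsd: float
    n_atoms: int

    def as_record(self) -> dict:
        return {"chain": self.chain, "role": self.role, "domain": self.domain,
                "com_shift": self.com_shift,
                "com_dx": self.com_shift_vec[0],
                "com_dy": self.com_shift_vec[1],
                "com_dz": self.com_shift_vec[2],
                "tilt_deg": self.tilt_deg, "rotation_deg": self.rotation_deg,
                "residual_rmsd": self.residual_rmsd, "n_atoms": self.n_atoms}


@dataclass
class ProjectionProfile:
    """Per-residue projection of a query state onto the closed→desensitized axis."""

    records: list[dict]           # chain, residue_number, axis_length, projection,
                                  # fraction, defined
    query_label: str
    domain_means: dict[str, float]


@dataclass
class DisplacementReport:
    """Per-residue C-α displacements within a region, with the maximum flagged."""

    records: list[dict]
    region: str
    max_displacement: float
    max_chain: str
    max_residue: int


def _domain_atom_indices(model: StructureModel, chain: str, domain: str,
                         atoms: str) -> np.ndarray:
    return select_atoms(model, chains=[chain], domain=domain, atoms=atoms,
                        warn_empty=False)


def domain_com_shift(corr: CorrespondenceMap, model_A: StructureModel,
                     model_B: StructureModel, domain: str,
                     roles=None, ca_only: bool = False) -> list[DomainMotion]:
    """Per-subunit COM displacement of ``domain`` between two aligned states.

    The COM is the unweighted centroid of the selected atoms; the shift is
    COM(B) − COM(A). Returns one (COM-only) :class:`DomainMotion` per
    receptor chain, angles set to NaN.
    """
    atoms = "CA" if ca_only else "heavy"
    out = []
    for ch in model_A.receptor_chains():
        role = model_A.roles[ch]
        if roles is not None and role not in roles:
            continue
        ch_b = corr.chain_mapping.get(ch, ch)
        ia = _domain_atom_indices(model_A, ch, domain, atoms)
        ib = _domain_atom_indices(model_B, ch_b, domain, atoms)
        if len(ia) == 0 or len(ib) == 0:
            raise SelectionError(f"domain {domain!r} empty on chain {ch}/{ch_b}")
        vec = model_B.coords[ib].mean(axis=0) - model_A.coords[ia].mean(axis=0)
        out.append(DomainMotion(
            chain=ch, role=role, domain=domain, com_shift_vec=vec,
            com_shift=float(np.linalg.norm(vec)), tilt_deg=float("nan"),
            rotation_deg=float("nan"), residual_rmsd=float("nan"),
            n_atoms=min(len(ia), len(ib))))
    return out


def domain_tilt_rotation(corr: CorrespondenceMap, model_A: StructureModel,
                         model_B: StructureModel, domain: str, axis: Axis,
                         roles=None) -> list[DomainMotion]:
    """Per-subunit tilt (swing) and rotation (twist) of ``domain`` A→B.

    Each domain copy is centred on its own C-α centroid, the optimal rotation
    is found by least-squares superposition, and that rotation is decomposed
    against the reference state's pore axis. The residual RMSD after the
    rigid fit measures how non-rigid the domain motion is.
    """
    out = []
    for ch in model_A.receptor_chains():
        role = model_A.roles[ch]
        if roles is not None and role not in roles:
            continue
        sub = restrict_correspondence(corr, model_A, domain, roles=None)
        keep = [k for k, p in enumerate(sub.pairs) if p[0] == ch]
        if len(keep) < 3:
            raise SelectionError(f"domain {domain!r}: fewer than 3 paired C-α "
                                 f"on chain {ch}")
        ia = sub.idx_A[keep]
        ib = sub.idx_B[keep]
        a = model_A.coords[ia] - model_A.coords[ia].mean(axis=0)
        b = model_B.coords[ib] - model_B.coords[ib].mean(axis=0)
        tr = kabsch_superpose(b, a)  # rotation carrying state A onto state B
        st = swing_twist_decompose(tr.rotation, axis,
                                   residual_rmsd=tr.rmsd_after_fit)
        com_vec = model_B.coords[ib].mean(axis=0) - model_A.coords[ia].mean(axis=0)
        out.append(DomainMotion(
            chain=ch, role=role, domain=domain, com_shift_vec=com_vec,
            com_shift=float(np.linalg.norm(com_vec)),
            tilt_deg=st.tilt_deg, rotation_deg=st.rotation_deg,
            residual_rmsd=st.residual_rmsd, n_atoms=len(keep)))
    return out


def _three_way_pairs(corr_cd: CorrespondenceMap, corr_cq: CorrespondenceMap):
    """Intersect closed↔desensitized and closed↔query pairings on the closed side."""
    by_ca = {int(i): k for k, i in enumerate(corr_cq.idx_A)}
    rows = []
    for k, i in enumerate(corr_cd.idx_A):
        j = by_ca.get(int(i))
        if j is not None:
            rows.append((int(i), int(corr_cd.idx_B[k]), int(corr_cq.idx_B[j])))
    return rows


def projection_profile(closed: StructureModel, desensitized: StructureModel,
                       query: StructureModel, corr_cd: CorrespondenceMap,
                       corr_cq: CorrespondenceMap,
                       epsilon: float = PROJECTION_EPSILON,
                       min_coverage: float = 0.5) -> ProjectionProfile:
    """Project each query C-α onto its closed→desensitized displacement line.

    For residue i with closed position x_c, desensitized position x_d and
    query position x_q (all in one frame): v = x_d − x_c, projection =
    (x_q − x_c)·v̂ (Å) and fraction = projection/|v|. Residues with
    |v| < ``epsilon`` are emitted with ``defined=False`` (empty fraction).
    Fractions are not clipped — overshoot past the desensitized position is
    meaningful.
    """
    rows = _three_way_pairs(corr_cd, corr_cq)
    n_ca = len(select_atoms(closed, atoms="CA", warn_empty=False))
    if n_ca and len(rows) / n_ca <= min_coverage:
        raise CorrespondenceError(
            f"three-way pairing covers only {len(rows)}/{n_ca} closed-state "
            f"C-α (≤ {min_coverage:.0%})")
    records = []
    dom_acc: dict[str, list[float]] = {}
    domains = closed.domains.domains if closed.domains is not None else {}
    for ic, id_, iq in rows:
        v = desensitized.coords[id_] - closed.coords[ic]
        L = float(np.linalg.norm(v))
        chain = closed.chain_id[ic]
        resnum = int(closed.residue_number[ic])
        role = closed.roles.get(chain, "other")
        if L < epsilon:
            rec = {"chain": chain, "residue_number": resnum, "axis_length": L,
                   "projection": float("nan"), "fraction": float("nan"),
                   "defined": False}
        else:
            proj = float((query.coords[iq] - closed.coords[ic]) @ (v / L))
            rec = {"chain": chain, "residue_number": resnum, "axis_length": L,
                   "projection": proj, "fraction": proj / L, "defined": True}
            for dom in domains:
                if closed.domains.contains(dom, role, resnum):
                    dom_acc.setdefault(dom, []).append(proj / L)
        records.append(rec)
    means = {d: float(np.mean(v)) for d, v in sorted(dom_acc.items())}
    return ProjectionProfile(records=records, query_label=query.label,
                             domain_means=means)


def residue_displacement(corr: CorrespondenceMap, model_A: StructureModel,
                         model_B: StructureModel, region: str,
                         roles=None) -> DisplacementReport:
    """Euclidean C-α displacements over a region of two aligned states."""
    sub = restrict_correspondence(corr, model_A, region, roles=roles)
    if len(sub) == 0:
        raise SelectionError(f"region {region!r}: no paired residues")
    d = np.linalg.norm(model_B.coords[sub.idx_B] - model_A.coords[sub.idx_A],
                       axis=1)
    k = int(np.argmax(d))
    records = [{"chain": p[0], "residue_number": p[1],
                "displacement": float(di)} for p, di in zip(sub.pairs, d)]
    return DisplacementReport(records=records, region=region,
                              max_displacement=float(d[k]),
                              max_chain=sub.pairs[k][0],
                              max_residue=sub.pairs[k][1])


def export_projection_matrix(profiles: list[ProjectionProfile]):
    """Residues × query-models matrix of fractions (undefined cells empty).

    Per-domain mean summary rows are appended (the line-graph view of the
    same data). Raises if the profiles do not share a residue index.
    """
    import pandas as pd

    if not profiles:
        raise CorrespondenceError("no profiles to export")
    keys = [(r["chain"], r["residue_number"]) for r in profiles[0].records]
    for p in profiles[1:]:
        k2 = [(r["chain"], r["residue_number"]) for r in p.records]
        if k2 != keys:
            diff = next((a for a, b in zip(keys, k2) if a != b),
                        keys[min(len(keys), len(k2)) - 1] if keys else None)
            raise CorrespondenceError(
                f"profiles disagree on the residue index near {diff}")
    data = {"chain": [k[0] for k in keys],
            "residue_number": [k[1] for k in keys]}
    for p in profiles:
        data[p.query_label] = [r["fraction"] if r["defined"] else None
                               for r in p.records]
    df = pd.DataFrame(data)
    summary = []
    for p in profiles:
        for dom, mean in p.domain_means.items():
            summary.append({"chain": f"mean:{dom}", "residue_number": -1,
                            p.query_label: mean})
    if summary:
        sdf = pd.DataFrame(summary).groupby(
            ["chain", "residue_number"], as_index=False).first()
        df = pd.concat([df, sdf], ignore_index=True)
    return df
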