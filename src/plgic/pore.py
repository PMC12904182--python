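"""HOLE-style pore radius profile, gate radii, and pore-state classification.

At each axial position z the pore radius is the radius of the largest
sphere centred in that plane that touches no atom's van der Waals surface:

    r(z) = max_{c ∈ plane, |c−axis| ≤ L}  min_a ( |c − x_a| − vdw_a )

The plane-wise maximisation is deterministic: a fixed 9-point start grid
(seeded from the previous plane's optimum for continuity) followed by
Nelder–Mead refinement. No monotonicity of the profile is assumed.

Gate radii are the minimum of the profile inside an axial window around the
Leu9' (activation gate) and Pro/Ala−2' (desensitization gate) rings; they
are compared against the Born radius of Cl⁻ (2.3 Å) and the hydrated Cl⁻
radius (3.2 Å), the bounds bracketing the minimal radius compatible with
chloride permeation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import CoverageError, PlgicError, SelectionError
from .geometry import Axis
from .structures import BACKBONE_NAMES, StructureModel

BORN_RADIUS = 2.3          # Å, Born radius of Cl⁻
HYDRATED_CL_RADIUS = 3.2   # Å, Cl⁻ with its first hydration shell

#: van der Waals radii (Å); config-overridable, recorded in output metadata.
DEFAULT_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
VDW_DEFAULT_RADIUS = 1.70

#: atoms farther than this from a plane (axially) cannot bound a ≤ L-radius
#: sphere centred in it for any structure we profile; beyond it the slab is
#: reported empty rather than fabricating a radius
SLAB_REACH = 8.0


@dataclass
class PoreSample:
    z: float
    center: np.ndarray
    radius: float
    clamped: bool = False
    empty: bool = False


@dataclass
class PoreProfile:
    samples: list[PoreSample]
    z_step: float
    axis: Axis
    lateral_bound: float
    vdw_table: dict[str, float]

    @property
    def min_radius(self) -> tuple[float, float]:
        """(radius, z) of the tightest covered sample."""
        ok = [s for s in self.samples if not s.empty]
        if not ok:
            raise CoverageError("profile has no covered samples")
        s = min(ok, key=lambda s: s.radius)
        return s.radius, s.z

    def radii(self) -> np.ndarray:
        return np.array([s.radius for s in self.samples])

    def z_values(self) -> np.ndarray:
        return np.array([s.z for s in self.samples])

    def as_records(self) -> list[dict]:
        return [{"z": s.z, "cx": s.center[0], "cy": s.center[1],
                 "cz": s.center[2], "radius": s.radius,
                 "clamped": s.clamped, "empty": s.empty}
                for s in self.samples]


@dataclass
class GateReport:
    gate: str
    radius: float
    window: tuple[float, float]
    residues: list[tuple[str, int]]
    call: str
    born_radius: float = BORN_RADIUS
    hydrated_cl_radius: float = HYDRATED_CL_RADIUS
    profile_id: int = field(default=0, repr=False)

    def to_dict(self) -> dict:
        return {"gate": self.gate, "radius": self.radius,
                "window": list(self.window),
                "residues": [list(r) for r in self.residues],
                "thresholds": {"born_radius": self.born_radius,
                               "hydrated_cl_radius": self.hydrated_cl_radius},
                "call": self.call}


@dataclass
class PoreStateCall:
    state: str
    gate9_radius: float
    gate_minus2_radius: float
    rule_version: str = "born-gate-1"

    def to_dict(self) -> dict:
        return {"state": self.state, "gate9_radius": self.gate9_radius,
                "gate_minus2_radius": self.gate_minus2_radius,
                "rule_version": self.rule_version}


def vdw_radii(model: StructureModel, idx: np.ndarray,
              table: dict[str, float] | None = None) -> np.ndarray:
    tab = dict(DEFAULT_VDW)
    if table:
        tab.update(table)
    return np.array([tab.get(e, VDW_DEFAULT_RADIUS) for e in model.element[idx]])


def _pore_atom_indices(model: StructureModel, exclude_hetero: bool,
                       include_hydrogens: bool) -> np.ndarray:
    mask = np.ones(model.n_atoms, dtype=bool)
    if exclude_hetero:
        mask &= ~model.hetero
    if not include_hydrogens:
        mask &= ~model.is_hydrogen
    return np.nonzero(mask)[0]


def compute_pore_profile(model: StructureModel, axis: Axis | None = None,
                         z_range: tuple[float, float] | None = None,
                         z_step: float = 0.25, lateral_bound: float = 5.0,
                         exclude_hetero: bool = True,
                         include_hydrogens: bool = False,
                         vdw_table: dict[str, float] | None = None) -> PoreProfile:
    """Maximal-inscribed-sphere radius profile along the pore axis.

    ``z_range`` defaults to the axial extent of the model's TMD (falling back
    to all profiled atoms). Waters/ligands are excluded by default so a bound
    modulator never occludes the measurement. Negative optima (atom overlap
    at the plane) are clamped to 0 and flagged; planes with no atom within
    axial reach are flagged empty, never fabricated.
    """
    from .geometry import pore_axis as _pore_axis
    from .structures import select_atoms

    if axis is None:
        axis = _pore_axis(model)
    idx = _pore_atom_indices(model, exclude_hetero, include_hydrogens)
    if len(idx) == 0:
        raise SelectionError("no atoms available for pore profiling")
    coords = model.coords[idx]
    radii = vdw_radii(model, idx, vdw_table)
    zc = axis.coordinate(coords)
    if z_range is None:
        try:
            tmd = select_atoms(model, domain="TMD", atoms="heavy",
                               warn_empty=False)
        except (SelectionError, PlgicError):
            tmd = np.array([], dtype=int)
        zs = axis.coordinate(model.coords[tmd]) if len(tmd) else zc
        # pad so gate windows at the helix termini stay covered
        z_range = (float(zs.min() - 1.5), float(zs.max() + 1.5))
    z_lo, z_hi = z_range
    if z_hi - z_lo < 2 * z_step:
        raise CoverageError(f"z_range {z_range} spans fewer than 2 steps")

    # orthonormal in-plane basis
    d = axis.direction
    seed = np.array([1.0, 0.0, 0.0])
    if abs(d @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, seed)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)

    g = lateral_bound / 2.0
    start_grid = [(0.0, 0.0), (g, 0.0), (-g, 0.0), (0.0, g), (0.0, -g),
                  (g, g), (g, -g), (-g, g), (-g, -g)]

    n_steps = int(np.floor((z_hi - z_lo) / z_step + 1e-9)) + 1
    samples: list[PoreSample] = []
    prev_uv = (0.0, 0.0)
    for k in range(n_steps):
        z = z_lo + k * z_step
        near = np.abs(zc - z) <= max(SLAB_REACH, lateral_bound + radii.max())
        if not near.any():
            samples.append(PoreSample(z=z, center=axis.point + z * d,
                                      radius=0.0, empty=True))
            continue
        pc = coords[near]
        pr = radii[near]
        origin = axis.point + z * d

        def neg_radius(uv):
            u, v = uv
            rho = np.hypot(u, v)
            c = origin + u * e1 + v * e2
            r = np.min(np.linalg.norm(pc - c, axis=1) - pr)
            if rho > lateral_bound:
                r -= 10.0 * (rho - lateral_bound)
            return -r

        best_uv, best = None, np.inf
        for su, sv in [prev_uv] + start_grid:
            res = minimize(neg_radius, np.array([su, sv]),
                           method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-6,
                                    "maxiter": 400})
            if res.fun < best:
                best, best_uv = res.fun, res.x
        u, v = best_uv
        rho = np.hypot(u, v)
        if rho > lateral_bound:  # clamp the centre back onto the bound
            u, v = u * lateral_bound / rho, v * lateral_bound / rho
            best = neg_radius((u, v))
        radius = -best
        clamped = radius < 0
        samples.append(PoreSample(
            z=float(z), center=origin + u * e1 + v * e2,
            radius=float(max(radius, 0.0)), clamped=clamped))
        prev_uv = (float(u), float(v))
    return PoreProfile(samples=samples, z_step=z_step, axis=axis,
                       lateral_bound=lateral_bound,
                       vdw_table={**DEFAULT_VDW, **(vdw_table or {})})


def gate_radius(profile: PoreProfile, model: StructureModel, gate: str,
                window_pad: float = 1.0) -> GateReport:
    """Minimum profile radius within the axial window of a gate ring.

    The window spans the axial coordinates of the five gate residues'
    side-chain heavy atoms (C-α where no side chain is modelled) ± 1 Å.
    """
    if model.domains is None or gate not in model.domains.gates:
        raise SelectionError(f"gate {gate!r} not configured")
    per_role = model.domains.gates[gate]
    residues, zs = [], []
    for ch in model.receptor_chains():
        resnum = per_role[model.roles[ch]]
        mask = ((model.chain_id == ch) & (model.residue_number == resnum)
                & ~model.hetero & ~model.is_hydrogen)
        side = mask & ~np.isin(model.name, BACKBONE_NAMES)
        use = side if side.any() else (mask & (model.name == "CA"))
        if not use.any():
            raise SelectionError(f"gate {gate}: residue {resnum} has no heavy "
                                 f"atoms on chain {ch}")
        zs.append(profile.axis.coordinate(model.coords[use]))
        residues.append((ch, resnum))
    z_all = np.concatenate(zs)
    window = (float(z_all.min() - window_pad), float(z_all.max() + window_pad))
    zv = profile.z_values()
    in_win = [s for s in profile.samples
              if window[0] - 1e-9 <= s.z <= window[1] + 1e-9 and not s.empty]
    if not in_win or window[0] < zv.min() - profile.z_step \
            or window[1] > zv.max() + profile.z_step:
        raise CoverageError(f"gate {gate} window {window} not covered by the "
                            f"profile [{zv.min()}, {zv.max()}]")
    radius = min(s.radius for s in in_win)
    if radius < BORN_RADIUS:
        call = "below_born"
    elif radius < HYDRATED_CL_RADIUS:
        call = "between"
    else:
        call = "above_hydrated"
    return GateReport(gate=gate, radius=float(radius), window=window,
                      residues=residues, call=call, profile_id=id(profile))


def classify_pore_state(gate9: GateReport, gate_minus2: GateReport) -> PoreStateCall:
    """Closed / desensitized-like / open-like call from the two gate radii.

    closed: activation gate (9') below the Born radius; desensitized-like:
    9' permissive but the −2' desensitization gate below the Born radius;
    open-like: both at or above it.
    """
    if gate9.profile_id != gate_minus2.profile_id:
        raise PlgicError("gate reports come from different pore profiles")
    r9, rm2 = gate9.radius, gate_minus2.radius
    if not (np.isfinite(r9) and np.isfinite(rm2)):
        state = "indeterminate"
    elif r9 < BORN_RADIUS:
        state = "closed"
    elif rm2 < BORN_RADIUS:
        state = "desensitized_like"
    else:
        state = "open_like"
    return PoreStateCall(state=state, gate9_radius=r9, gate_minus2_radius=rm2)
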