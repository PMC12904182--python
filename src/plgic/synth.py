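"""Synthetic pentamer fixtures with known ground truth.

The generator emulates only what the metrics consume: a 5-fold symmetric
receptor with a separable ECD (rigid slab of pseudo-C-α points) and a TMD of
four ideal α-helices per subunit (rise 1.5 Å/residue, helical radius 2.3 Å,
100°/residue), M2 lining the pore, gate rings whose pseudo side-chain atoms
sit on circles of prescribed geometric radius, a rigid strychnine-sized
dummy ligand, and scripted stable/drift ligand trajectories. No chemistry,
no membrane, no force field — rigid-body structure and exact symmetry are
the point, because they make every downstream metric checkable against the
parameters used to build the input.

Default gate ring radii give pore radii of 1.3 Å at the 9' activation gate
and 1.8 Å at the −2' desensitization gate (geometric radius minus the
carbon vdW radius), the closed-state pattern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import SelectionError, SpecError
from .structures import (AnalysisConfig, DomainDefinition, StructureModel,
                         assign_roles, select_atoms)

# residue layout per subunit (1-based, inclusive)
ECD_RANGE = (1, 40)
LOOPC_RANGE = (26, 31)
M1_RANGE = (41, 67)
M1M2_LOOP_RANGE = (68, 71)
M2_RANGE = (72, 98)
M2M3_LOOP_RANGE = (99, 102)
M3_RANGE = (103, 129)
M3M4_LOOP_RANGE = (130, 133)
M4_RANGE = (134, 160)
TMD_RANGE = (41, 160)
GATE_PRIME9_RES = 87       # mid-M2 (M2 built descending: 9' sits mid-pore)
GATE_MINUS2_RES = 98       # intracellular end of M2

HELIX_RISE = 1.5           # Å/residue
HELIX_RADIUS = 2.3         # Å
HELIX_TURN_DEG = 100.0     # °/residue
TMD_Z0 = 2.5               # Å, intracellular end of the helix bundle

DEFAULT_RING_RADII = {"prime9": 3.0, "primeMinus2": 3.5}  # geometric, Å

CHAINS = ("A", "B", "C", "D", "E")
DEFAULT_ROLES = {"A": "alpha1", "B": "alpha1", "C": "alpha1", "D": "alpha1",
                 "E": "beta"}


def default_domain_definition() -> DomainDefinition:
    def both(rng):
        return {"alpha1": [rng], "beta": [rng]}
    return DomainDefinition(
        domains={"ECD": both(ECD_RANGE), "TMD": both(TMD_RANGE),
                 "M1": both(M1_RANGE), "M2": both(M2_RANGE),
                 "M3": both(M3_RANGE), "M4": both(M4_RANGE),
                 "M1M2loop": both(M1M2_LOOP_RANGE),
                 "LoopC": both(LOOPC_RANGE)},
        gates={"prime9": {"alpha1": GATE_PRIME9_RES, "beta": GATE_PRIME9_RES},
               "primeMinus2": {"alpha1": GATE_MINUS2_RES,
                               "beta": GATE_MINUS2_RES}})


def default_config() -> AnalysisConfig:
    return AnalysisConfig(roles=dict(DEFAULT_ROLES),
                          domain_def=default_domain_definition(),
                          ligand={"resname": "LIG"})


@dataclass
class PentamerSpec:
    """Geometry of the synthetic pentamer; defaults are the study conditions."""

    n_res_ecd: int = 40
    helix_rise: float = HELIX_RISE
    helix_radius: float = HELIX_RADIUS
    helix_turn_deg: float = HELIX_TURN_DEG
    ring_radii: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RING_RADII))
    roles: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ROLES))
    seed: int = 0
    label: str = "synthetic-pentamer"

    def __post_init__(self) -> None:
        if self.n_res_ecd != ECD_RANGE[1] - ECD_RANGE[0] + 1:
            raise SpecError("n_res_ecd must match the fixed residue layout")
        for g, r in self.ring_radii.items():
            if g not in ("prime9", "primeMinus2") or r <= 0:
                raise SpecError(f"bad ring radius {g}={r}")


@dataclass
class MotionSpec:
    """Ground-truth rigid motion for one subunit domain."""

    chain: str
    domain: str
    tilt_deg: float = 0.0
    rotation_deg: float = 0.0
    com_shift_vec: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise SpecError("noise_sigma must be ≥ 0")
        if not np.all(np.isfinite([self.tilt_deg, self.rotation_deg,
                                   *self.com_shift_vec])):
            raise SpecError("angles and shifts must be finite")


@dataclass
class TrajectorySpec:
    """Scripted ligand trajectory: stable jitter or drift to a target RMSD."""

    mode: str = "stable"               # stable | drift
    n_frames: int = 200
    noise_sigma: float = 0.1           # Å, iid per coordinate on the ligand
    drift_target_rmsd: float = 6.0     # Å reached at the final frame
    drift_onset_frame: int = 0
    contact_schedule: dict[tuple[str, int], set[int]] = field(
        default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("stable", "drift"):
            raise SpecError(f"unknown mode {self.mode!r}")
        if self.mode == "drift" and not (
                0 <= self.drift_onset_frame < self.n_frames):
            raise SpecError("drift_onset_frame outside the frame range")
        for res, frames in self.contact_schedule.items():
            bad = [f for f in frames if not 0 <= f < self.n_frames]
            if bad:
                raise SpecError(f"contact schedule for {res} has frames "
                                f"outside range: {bad[:3]}")


def _helix_block(res_lo: int, res_hi: int, axis_xy: np.ndarray, phase: float,
                 rise: float, radius: float, turn: float,
                 descending: bool) -> list[tuple[int, str, np.ndarray]]:
    """Backbone (N, CA, C, O) of one ideal vertical α-helix."""
    n = res_hi - res_lo + 1
    out = []
    # rigid intra-residue offsets: (radius scale, phase offset deg, z offset)
    atom_geom = {"N": (0.70, -28.0, -0.9), "CA": (1.00, 0.0, 0.0),
                 "C": (0.74, 26.0, 0.6), "O": (0.87, 44.0, 1.2)}
    for j in range(n):
        z = TMD_Z0 + rise * ((n - 1 - j) if descending else j)
        phi0 = phase + turn * j
        for name in ("N", "CA", "C", "O"):
            s, dphi, dz = atom_geom[name]
            phi = np.deg2rad(phi0 + dphi)
            pos = np.array([axis_xy[0] + s * radius * np.cos(phi),
                            axis_xy[1] + s * radius * np.sin(phi),
                            z + dz])
            out.append((res_lo + j, name, pos))
    return out


def _loop_block(res_lo: int, res_hi: int, start: np.ndarray, end: np.ndarray
                ) -> list[tuple[int, str, np.ndarray]]:
    n = res_hi - res_lo + 1
    return [(res_lo + j, "CA",
             start + (end - start) * (j + 1) / (n + 1))
            for j in range(n)]


def _subunit_template(spec: PentamerSpec) -> list[tuple[int, str, np.ndarray]]:
    """One subunit built at angular position 0° (+x toward the subunit)."""
    def polar(r, ang_deg):
        a = np.deg2rad(ang_deg)
        return np.array([r * np.cos(a), r * np.sin(a)])

    atoms: list[tuple[int, str, np.ndarray]] = []
    # ECD: rigid slab of pseudo-C-α on a cylindrical patch, z 48-76
    for j in range(spec.n_res_ecd):
        resnum = ECD_RANGE[0] + j
        if LOOPC_RANGE[0] <= resnum <= LOOPC_RANGE[1]:
            # Loop C dips inward toward the inter-subunit orthosteric site
            k = resnum - LOOPC_RANGE[0]
            ang = 26.0 + 4.0 * k
            atoms.append((resnum, "CA",
                          np.array([*polar(11.0, ang), 50.0 + 0.8 * k])))
        else:
            arc, pos = divmod(j, 10)
            ang = -24.0 + 48.0 * pos / 9.0
            atoms.append((resnum, "CA",
                          np.array([*polar(16.0 + 2.0 * arc, ang),
                                    48.0 + 7.0 * arc])))
    hr = spec.helix_rise
    rad = spec.helix_radius
    turn = spec.helix_turn_deg
    atoms += _helix_block(*M1_RANGE, polar(13.0, -22.0), 10.0, hr, rad, turn,
                          descending=False)
    atoms += _helix_block(*M2_RANGE, polar(8.0, 0.0), 180.0, hr, rad, turn,
                          descending=True)
    atoms += _helix_block(*M3_RANGE, polar(13.0, 22.0), 250.0, hr, rad, turn,
                          descending=False)
    atoms += _helix_block(*M4_RANGE, polar(17.0, 0.0), 320.0, hr, rad, turn,
                          descending=True)

    by_key = {(r, n): p for r, n, p in atoms}
    top_m1 = by_key[(M1_RANGE[1], "CA")]
    top_m2 = by_key[(M2_RANGE[0], "CA")]
    bot_m2 = by_key[(M2_RANGE[1], "CA")]
    bot_m3 = by_key[(M3_RANGE[0], "CA")]
    top_m3 = by_key[(M3_RANGE[1], "CA")]
    top_m4 = by_key[(M4_RANGE[0], "CA")]
    atoms += _loop_block(*M1M2_LOOP_RANGE, top_m1, top_m2)
    atoms += _loop_block(*M2M3_LOOP_RANGE, bot_m2, bot_m3)
    atoms += _loop_block(*M3M4_LOOP_RANGE, top_m3, top_m4)

    # gate pseudo side chains on circles of prescribed geometric pore radius
    for gate, resnum in (("prime9", GATE_PRIME9_RES),
                         ("primeMinus2", GATE_MINUS2_RES)):
        z = by_key[(resnum, "CA")][2]
        atoms.append((resnum, "CB",
                      np.array([*polar(spec.ring_radii[gate], 0.0), z])))
    return atoms


def build_ideal_pentamer(spec: PentamerSpec | None = None) -> StructureModel:
    """Deterministic C5-symmetric pentamer, annotated and ready for analysis.

    Subunit k is the 0° template rotated by exactly k·72° about z; the build
    axis is the z axis with the ECD on the positive side.
    """
    spec = spec or PentamerSpec()
    template = _subunit_template(spec)
    template.sort(key=lambda t: (t[0], t[1] != "N", t[1] != "CA",
                                 t[1] != "C", t[1]))
    base = np.array([p for _, _, p in template])
    resnums = [r for r, _, _ in template]
    names = [n for _, n, _ in template]
    cols = {k: [] for k in ("name", "element", "residue_name", "chain_id",
                            "residue_number")}
    coords = []
    for k, ch in enumerate(CHAINS):
        rot = Rotation.from_euler("z", 72.0 * k, degrees=True).as_matrix()
        xyz = base @ rot.T
        coords.append(xyz)
        cols["name"] += names
        cols["element"] += ["C" if n in ("CA", "C", "CB") else n[0]
                            for n in names]
        cols["residue_name"] += ["GLY"] * len(names)
        cols["chain_id"] += [ch] * len(names)
        cols["residue_number"] += resnums
    model = StructureModel.from_arrays(spec.label, coords=np.vstack(coords),
                                       **cols)
    return assign_roles(model, spec.roles, default_domain_definition())


def ligand_template() -> np.ndarray:
    """24 heavy atoms, rigid, roughly strychnine-sized (~8×6×4 Å), at origin."""
    pts = []
    for i in range(2):            # two stacked 8-rings
        for j in range(8):
            a = 2 * np.pi * j / 8
            pts.append([2.2 * np.cos(a), 2.2 * np.sin(a), 1.4 * i])
    for j in range(8):            # fused tail
        pts.append([3.0 + 0.6 * j, 0.8 * ((-1) ** j), 0.7])
    return np.array(pts) - np.mean(pts, axis=0)


def add_ligand(model: StructureModel, center=None, resname: str = "LIG",
               chain: str = "X") -> StructureModel:
    """Append the rigid dummy ligand at the orthosteric-like site (A/B interface)."""
    if center is None:
        a = np.deg2rad(126.0)     # between subunits A (90°) and B (162°)
        center = np.array([11.0 * np.cos(a), 11.0 * np.sin(a), 52.0])
    pts = ligand_template() + np.asarray(center, dtype=float)
    lig = StructureModel.from_arrays(
        "ligand", coords=pts,
        name=[f"C{i + 1}" for i in range(len(pts))],
        element=["C"] * len(pts),
        residue_name=[resname] * len(pts),
        chain_id=[chain] * len(pts),
        residue_number=[1] * len(pts),
        hetero=[True] * len(pts))
    out = StructureModel(model.label)
    for attr in ("serial", "name", "element", "residue_name", "chain_id",
                 "residue_number", "insertion_code", "alt_loc", "occupancy",
                 "hetero"):
        setattr(out, attr,
                np.concatenate([getattr(model, attr), getattr(lig, attr)]))
    out.coords = np.vstack([model.coords, lig.coords])
    out.serial = np.arange(1, out.n_atoms + 1)
    out.roles = dict(model.roles)
    out.domains = model.domains
    return out


def apply_domain_transform(model: StructureModel, motion: MotionSpec
                           ) -> StructureModel:
    """Move one subunit domain rigidly: twist about z, then swing, then shift.

    The rotation is composed about the domain's heavy-atom centroid as
    R = S(tilt) · T(rotation): twist about the build axis (z, ECD-ward,
    counterclockwise positive seen from the ECD) followed by a swing about
    the horizontal tangential direction at the domain centroid. Seeded iid
    Gaussian noise is added last, to the moved domain only; all other atoms
    are returned bit-identical.
    """
    idx = select_atoms(model, chains=[motion.chain], domain=motion.domain,
                       atoms="heavy", warn_empty=False)
    if len(idx) == 0:
        raise SelectionError(f"no atoms for chain {motion.chain!r} domain "
                             f"{motion.domain!r}")
    com = model.coords[idx].mean(axis=0)
    radial = np.array([com[0], com[1], 0.0])
    rn = np.linalg.norm(radial)
    tangent = (np.array([1.0, 0.0, 0.0]) if rn < 1e-9
               else np.array([-radial[1], radial[0], 0.0]) / rn)
    out = model.copy()
    moved = model.coords[idx]
    if motion.tilt_deg != 0.0 or motion.rotation_deg != 0.0:
        twist = Rotation.from_rotvec(np.deg2rad(motion.rotation_deg)
                                     * np.array([0.0, 0.0, 1.0]))
        swing = Rotation.from_rotvec(np.deg2rad(motion.tilt_deg) * tangent)
        R = (swing * twist).as_matrix()
        moved = (moved - com) @ R.T + com
    if any(c != 0.0 for c in motion.com_shift_vec):
        moved = moved + np.asarray(motion.com_shift_vec, dtype=float)
    if motion.noise_sigma > 0:
        rng = np.random.default_rng(motion.seed)
        moved = moved + rng.normal(0.0, motion.noise_sigma, moved.shape)
    out.coords[idx] = moved
    return out


def interpolate_states(model_A: StructureModel, model_B: StructureModel,
                       lam: float) -> StructureModel:
    """Per-atom linear blend x = (1−λ)x_A + λx_B over shared atoms.

    Atoms are matched by (chain, residue_number, insertion_code, name);
    unmatched atoms are dropped (count attached as ``n_dropped``).
    """
    key_b = {(model_B.chain_id[i], int(model_B.residue_number[i]),
              model_B.insertion_code[i], model_B.name[i]): i
             for i in range(model_B.n_atoms)}
    ia, ib = [], []
    for i in range(model_A.n_atoms):
        j = key_b.get((model_A.chain_id[i], int(model_A.residue_number[i]),
                       model_A.insertion_code[i], model_A.name[i]))
        if j is not None:
            ia.append(i)
            ib.append(j)
    if not ia:
        raise SelectionError("no shared atoms between the two models")
    ia = np.array(ia)
    ib = np.array(ib)
    out = model_A.subset(ia, label=f"{model_A.label}~lam{lam:g}")
    out.coords = (1.0 - lam) * model_A.coords[ia] + lam * model_B.coords[ib]
    out.n_dropped = (model_A.n_atoms - len(ia)) + (model_B.n_atoms - len(ib))
    return out


def synth_ligand_trajectory(pentamer: StructureModel,
                            spec: TrajectorySpec | None = None,
                            ligand_center=None):
    """Scripted trajectory of the dummy ligand on a frozen receptor.

    stable: pose + seeded Gaussian jitter. drift: rigid displacement ramping
    linearly from ``drift_onset_frame`` to ``drift_target_rmsd`` at the last
    frame (plus jitter). Contact schedules are enforced exactly with PRB
    marker atoms parked far away except in scheduled frames.

    Returns (TrajectoryEnsemble, ground_truth dict).
    """
    from .trajectory import TrajectoryEnsemble

    spec = spec or TrajectorySpec()
    top = add_ligand(pentamer, center=ligand_center)
    sched = sorted(spec.contact_schedule.items(),
                   key=lambda kv: (kv[0][0], kv[0][1]))
    parked = {}
    for i, ((ch, num), _) in enumerate(sched):
        if i > 8:
            raise SpecError("at most 9 scheduled contact residues supported")
        mask = (top.chain_id == ch) & (top.residue_number == num) \
            & (top.name == "CA")
        if not mask.any():
            raise SelectionError(f"scheduled residue {ch}{num} absent")
        anchor = top.coords[mask][0]
        probe = StructureModel.from_arrays(
            "probe", coords=[[150.0 + 10.0 * i, 0.0, 150.0]],
            name=[f"PRB{i + 1}"], element=["C"], residue_name=["LIG"],
            chain_id=["X"], residue_number=[1], hetero=[True])
        parked[(ch, num)] = (top.n_atoms, anchor)
        merged = StructureModel(top.label)
        for attr in ("serial", "name", "element", "residue_name", "chain_id",
                     "residue_number", "insertion_code", "alt_loc",
                     "occupancy", "hetero"):
            setattr(merged, attr, np.concatenate([getattr(top, attr),
                                                  getattr(probe, attr)]))
        merged.coords = np.vstack([top.coords, probe.coords])
        merged.serial = np.arange(1, merged.n_atoms + 1)
        merged.roles = dict(top.roles)
        merged.domains = top.domains
        top = merged

    rng = np.random.default_rng(spec.seed)
    lig_mask = (top.residue_name == "LIG") \
        & np.array([not n.startswith("PRB") for n in top.name])
    lig_idx = np.nonzero(lig_mask)[0]
    com = top.coords[lig_idx].mean(axis=0)
    radial = np.array([com[0], com[1], 0.0])
    drift_dir = radial / np.linalg.norm(radial) if np.linalg.norm(radial) > 1e-9 \
        else np.array([1.0, 0.0, 0.0])

    frames = np.repeat(top.coords[None], spec.n_frames, axis=0)
    for f in range(spec.n_frames):
        disp = np.zeros(3)
        if spec.mode == "drift" and f >= spec.drift_onset_frame:
            denom = max(spec.n_frames - 1 - spec.drift_onset_frame, 1)
            disp = drift_dir * spec.drift_target_rmsd \
                * (f - spec.drift_onset_frame) / denom
        jitter = (rng.normal(0.0, spec.noise_sigma, (len(lig_idx), 3))
                  if spec.noise_sigma > 0 and f > 0 else 0.0)
        frames[f, lig_idx] = top.coords[lig_idx] + disp + jitter
        for (res, schedule) in sched:
            pi, anchor = parked[res]
            if f in schedule:
                frames[f, pi] = anchor + np.array([0.0, 0.0, 2.0])
            # otherwise stays parked far away
    truth = {"mode": spec.mode, "n_frames": spec.n_frames,
             "noise_sigma": spec.noise_sigma,
             "drift_target_rmsd": spec.drift_target_rmsd,
             "drift_onset_frame": spec.drift_onset_frame,
             "seed": spec.seed,
             "contact_schedule": {f"{ch}:{num}": sorted(frames_)
                                  for (ch, num), frames_ in sched}}
    traj = TrajectoryEnsemble(topology=top, frames=frames,
                              ligand_resname="LIG")
    return traj, truth


def write_ground_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
        fh.write("\n")


def motion_ground_truth(motions: list[MotionSpec]) -> dict:
    return {"motions": [asdict(m) for m in motions]}
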