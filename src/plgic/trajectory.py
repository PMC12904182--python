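"""Trajectory-derived metrics: ligand RMSD and stability, RMSF, contacts, pockets.

The trajectory contract is deliberately simple: a topology
:class:`~plgic.structures.StructureModel` plus an (n_frames, n_atoms, 3)
coordinate array with fixed atom order (a multi-model PDB read by
:func:`read_trajectory`). Inputs are assumed whole/imaged — no periodic
boundary handling is done here.

The ligand stability call follows the two-regime picture seen in orthosteric
antagonist simulations: a stably bound ligand stays at or below 2 Å RMSD
from its starting pose, an unstable one drifts off to other binding modes
(~6 Å). The call is the mean ligand RMSD over the final 20% of frames
compared against the 2.0 Å threshold, boundary inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import SelectionError, SpecError, TrajectoryError
from .geometry import kabsch_superpose
from .pore import vdw_radii
from .structures import BACKBONE_NAMES, StructureModel, read_frames

STABILITY_THRESHOLD = 2.0   # Å; "at or below" ⇒ boundary inclusive
STABILITY_WINDOW = 0.2      # final fraction of frames the call averages over
CONTACT_CUTOFF = 4.0        # Å, heavy-atom pair distance

#: marker atoms the synthetic generator uses to script contacts; excluded
#: from RMSD pose measurements by default
MARKER_ATOM_PREFIX = "PRB"


@dataclass
class TrajectoryEnsemble:
    """Fixed-topology trajectory: topology model + per-frame coordinates."""

    topology: StructureModel
    frames: np.ndarray            # (n_frames, n_atoms, 3)
    ligand_resname: str = "LIG"
    frame_interval: float = 1.0   # metadata only, arbitrary time units

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TrajectoryError(f"frames must be (n, atoms, 3), got "
                                  f"{self.frames.shape}")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise TrajectoryError(
                f"frame atom count {self.frames.shape[1]} != topology "
                f"{self.topology.n_atoms}")
        if len(self.frames) < 2:
            raise TrajectoryError("a trajectory needs ≥ 2 frames")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def ligand_indices(self, include_markers: bool = False) -> np.ndarray:
        top = self.topology
        mask = (top.residue_name == self.ligand_resname) & ~top.is_hydrogen
        if not include_markers:
            mask &= np.array([not n.startswith(MARKER_ATOM_PREFIX)
                              for n in top.name])
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            raise SelectionError(f"no ligand atoms ({self.ligand_resname!r}) "
                                 f"in topology")
        return idx

    def protein_indices(self, atoms: str = "heavy") -> np.ndarray:
        top = self.topology
        mask = ~top.hetero & (top.residue_name != self.ligand_resname) \
            & ~top.is_hydrogen
        if atoms == "backbone":
            mask &= np.isin(top.name, BACKBONE_NAMES)
        elif atoms == "CA":
            mask &= top.name == "CA"
        return np.nonzero(mask)[0]


def read_trajectory(path, ligand_resname: str = "LIG") -> TrajectoryEnsemble:
    """Read a multi-model PDB as a trajectory (model 1 = topology)."""
    models = read_frames(path)
    top = models[0]
    frames = []
    for m in models:
        if m.n_atoms != top.n_atoms or not np.array_equal(m.name, top.name):
            raise TrajectoryError(f"{path}: frame atom order differs from "
                                  f"topology")
        frames.append(m.coords)
    return TrajectoryEnsemble(topology=top, frames=np.stack(frames),
                              ligand_resname=ligand_resname)


@dataclass
class RMSDSeries:
    rmsd: np.ndarray
    fit_selection: str
    measured_selection: str

    def __len__(self) -> int:
        return len(self.rmsd)


@dataclass
class StabilityCall:
    call: str                  # stable | unstable
    evidence: float            # mean RMSD over the decision window, Å
    threshold: float
    window_fraction: float
    n_window_frames: int


def _fit_and_measure(traj: TrajectoryEnsemble, fit_idx: np.ndarray,
                     measure_idx: np.ndarray, reference: int | np.ndarray
                     ) -> np.ndarray:
    """Superpose every frame on the reference by ``fit_idx``, measure RMSD
    over ``measure_idx`` without re-fitting on the measured atoms."""
    if len(fit_idx) < 3:
        raise SelectionError("fit selection needs ≥ 3 atoms")
    if isinstance(reference, (int, np.integer)):
        ref = traj.frames[int(reference)]
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != traj.frames[0].shape:
            raise TrajectoryError("external reference pose has wrong shape")
    out = np.empty(traj.n_frames)
    ref_fit = ref[fit_idx]
    ref_meas = ref[measure_idx]
    for f in range(traj.n_frames):
        tr = kabsch_superpose(ref_fit, traj.frames[f][fit_idx])
        moved = tr.apply(traj.frames[f][measure_idx])
        out[f] = np.sqrt(np.mean(np.sum((moved - ref_meas) ** 2, axis=1)))
    return out


def ligand_rmsd_series(traj: TrajectoryEnsemble, reference: int = 0,
                       fit_selection: np.ndarray | None = None,
                       binding_site_cutoff: float = 10.0) -> RMSDSeries:
    """Per-frame ligand heavy-atom RMSD after a binding-site backbone fit.

    The fit selection defaults to protein backbone atoms within
    ``binding_site_cutoff`` of any ligand heavy atom in the reference frame;
    the ligand itself is never re-fit, so real pose drift is measured.
    """
    lig = traj.ligand_indices()
    if fit_selection is None:
        bb = traj.protein_indices("backbone")
        ref = traj.frames[reference]
        tree = cKDTree(ref[lig])
        d, _ = tree.query(ref[bb])
        fit_selection = bb[d <= binding_site_cutoff]
        if len(fit_selection) < 3:
            fit_selection = bb
    rmsd = _fit_and_measure(traj, fit_selection, lig, reference)
    return RMSDSeries(rmsd=rmsd, fit_selection="binding-site backbone",
                      measured_selection=f"ligand {traj.ligand_resname} heavy")


def backbone_rmsd_series(traj: TrajectoryEnsemble,
                         measure_idx: np.ndarray | None = None,
                         reference: int = 0,
                         label: str = "all_backbone") -> RMSDSeries:
    """Backbone RMSD series: fit on whole-protein backbone, measure a subset.

    With ``measure_idx=None`` the whole backbone is measured; pass e.g. the
    Loop C backbone indices to track loop capping motions.
    """
    bb = traj.protein_indices("backbone")
    if measure_idx is None:
        measure_idx = bb
    rmsd = _fit_and_measure(traj, bb, np.asarray(measure_idx, dtype=int),
                            reference)
    return RMSDSeries(rmsd=rmsd, fit_selection="protein backbone",
                      measured_selection=label)


def classify_ligand_stability(series: RMSDSeries,
                              window_fraction: float = STABILITY_WINDOW,
                              threshold: float = STABILITY_THRESHOLD
                              ) -> StabilityCall:
    """Stable iff mean RMSD over the final window ≤ threshold (inclusive)."""
    n = len(series)
    k = int(round(n * window_fraction))
    if k < 1:
        raise SpecError(f"window_fraction {window_fraction} gives an empty "
                        f"window over {n} frames")
    evidence = float(np.mean(series.rmsd[n - k:]))
    call = "stable" if evidence <= threshold else "unstable"
    return StabilityCall(call=call, evidence=evidence, threshold=threshold,
                         window_fraction=window_fraction, n_window_frames=k)


def residue_rmsf(traj: TrajectoryEnsemble,
                 selection: np.ndarray | None = None) -> dict:
    """Per-residue C-α-aggregated RMSF after a protein-backbone superposition.

    RMSF_i = sqrt(mean_f |x_i(f) − ⟨x_i⟩|²) with every frame first superposed
    on frame 0 via the protein backbone. Returns
    {(chain, residue_number): rmsf} over the selected atoms (default: all
    protein heavy atoms), averaging atoms within a residue.
    """
    if traj.n_frames < 10:
        raise TrajectoryError(f"RMSF needs ≥ 10 frames, got {traj.n_frames}")
    bb = traj.protein_indices("backbone")
    if len(bb) < 3:
        raise SelectionError("no protein backbone to superpose on")
    sel = (traj.protein_indices("heavy") if selection is None
           else np.asarray(selection, dtype=int))
    ref = traj.frames[0][bb]
    aligned = np.empty((traj.n_frames, len(sel), 3))
    for f in range(traj.n_frames):
        tr = kabsch_superpose(ref, traj.frames[f][bb])
        aligned[f] = tr.apply(traj.frames[f][sel])
    mean_pos = aligned.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((aligned - mean_pos) ** 2, axis=2),
                               axis=0))
    top = traj.topology
    acc: dict[tuple[str, int], list[float]] = {}
    for a, r in zip(sel, per_atom):
        acc.setdefault((top.chain_id[a], int(top.residue_number[a])),
                       []).append(float(r))
    return {k: float(np.mean(v)) for k, v in acc.items()}


@dataclass
class ContactFingerprint:
    persistence: dict[tuple[str, int], float]
    cutoff: float
    n_frames: int
    rule: str = "any heavy-atom pair within cutoff"


def contact_persistence(traj: TrajectoryEnsemble,
                        residues: list[tuple[str, int]],
                        cutoff: float = CONTACT_CUTOFF) -> ContactFingerprint:
    """Fraction of frames with ≥ 1 ligand↔residue heavy-atom contact.

    Exact by construction: an integer frame count over the total frame
    count. Scripted marker atoms are counted (they exist to make schedules
    exact).
    """
    if not residues:
        raise SelectionError("empty residue list")
    top = traj.topology
    lig = traj.ligand_indices(include_markers=True)
    res_idx = {}
    for ch, num in residues:
        mask = ((top.chain_id == ch) & (top.residue_number == num)
                & ~top.is_hydrogen & (top.residue_name != traj.ligand_resname))
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            raise SelectionError(f"residue {ch}{num} not in topology")
        res_idx[(ch, num)] = idx
    counts = {k: 0 for k in res_idx}
    for f in range(traj.n_frames):
        lig_tree = cKDTree(traj.frames[f][lig])
        for k, idx in res_idx.items():
            d, _ = lig_tree.query(traj.frames[f][idx])
            if np.min(d) <= cutoff:
                counts[k] += 1
    return ContactFingerprint(
        persistence={k: c / traj.n_frames for k, c in counts.items()},
        cutoff=cutoff, n_frames=traj.n_frames)


@dataclass
class PocketVolumeResult:
    volume: float
    grid_spacing: float
    probe_radius: float
    seed_point: np.ndarray
    n_grid_points: int
    open_pocket: bool = False


#: 14 fixed buriedness ray directions: ±axes and the 8 cube diagonals
_RAY_DIRECTIONS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    + [[sx, sy, sz] for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)],
    dtype=float)
_RAY_DIRECTIONS /= np.linalg.norm(_RAY_DIRECTIONS, axis=1, keepdims=True)


def pocket_volume(model: StructureModel, seed_point, lining_residues=None,
                  grid_spacing: float = 0.5, probe_radius: float = 1.4,
                  buried_min_rays: int = 9, ray_length: float = 10.0,
                  box_pad: float = 2.0) -> PocketVolumeResult:
    """Grid flood-fill estimate of an accessible (buried) pocket volume.

    Grid points qualify when (a) at least vdW+probe from every heavy atom,
    (b) inside the bounding box of the lining residues (padded), and (c)
    buried — ≥ ``buried_min_rays`` of 14 fixed ray directions hit protein
    within ``ray_length``. The flood fill grows from the seed over
    face-adjacent qualifying points; escaping the box flags an open pocket
    and returns the truncated volume. This is a deterministic surrogate for
    alpha-sphere pocket finders, so absolute volumes are method-dependent.
    """
    seed_point = np.asarray(seed_point, dtype=float)
    heavy = np.nonzero(~model.is_hydrogen)[0]
    coords = model.coords[heavy]
    vdw = vdw_radii(model, heavy)
    tree = cKDTree(coords)
    max_vdw = float(vdw.max())

    def clearance(points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        neigh = tree.query_ball_point(pts, r=max_vdw + probe_radius + 1e-9)
        out = np.ones(len(pts), dtype=bool)
        for i, nb in enumerate(neigh):
            if nb and np.any(np.linalg.norm(coords[nb] - pts[i], axis=1)
                             - vdw[nb] < probe_radius):
                out[i] = False
        return out

    if not clearance(seed_point[None])[0]:
        raise SelectionError("seed point lies inside the protein probe shell")

    if lining_residues:
        lmask = np.zeros(model.n_atoms, dtype=bool)
        for ch, num in lining_residues:
            lmask |= (model.chain_id == ch) & (model.residue_number == num)
        if not lmask.any():
            raise SelectionError("no lining-residue atoms found")
        lo = model.coords[lmask].min(axis=0) - box_pad
        hi = model.coords[lmask].max(axis=0) + box_pad
    else:
        lo = seed_point - 12.0
        hi = seed_point + 12.0

    ray_steps = np.arange(grid_spacing, ray_length + 1e-9, grid_spacing)

    def buried(pt: np.ndarray) -> bool:
        hits = 0
        for d in _RAY_DIRECTIONS:
            samples = pt + np.outer(ray_steps, d)
            dist, j = tree.query(samples)
            if np.any(dist - vdw[j] <= 0.0):
                hits += 1
                if hits >= buried_min_rays:
                    return True
        return False

    # flood fill on the integer grid anchored at the seed
    seen = {(0, 0, 0)}
    stack = [(0, 0, 0)]
    accepted = 0
    open_pocket = False
    neighbors = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                 (0, 0, 1), (0, 0, -1)]
    while stack:
        cell = stack.pop()
        pt = seed_point + np.array(cell) * grid_spacing
        if np.any(pt < lo) or np.any(pt > hi):
            open_pocket = True
            continue
        if not clearance(pt[None])[0]:
            continue
        if not buried(pt):
            continue
        accepted += 1
        for d in neighbors:
            nxt = (cell[0] + d[0], cell[1] + d[1], cell[2] + d[2])
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return PocketVolumeResult(volume=accepted * grid_spacing ** 3,
                              grid_spacing=grid_spacing,
                              probe_radius=probe_radius,
                              seed_point=seed_point,
                              n_grid_points=accepted,
                              open_pocket=open_pocket)
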