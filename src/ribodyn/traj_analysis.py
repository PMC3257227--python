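"""Trajectory observables: RMSF, hydrogen-bond lifetimes, hydration grids
and probe-sphere atom depth.

Geometric conventions
---------------------
* All coordinates are Angstrom; cutoffs quoted in nm elsewhere are
  converted once at this module's boundary (0.35 nm -> 3.5 A).
* Hydrogen bonds: donor-acceptor heavy-atom distance <= 3.5 A and a 75 deg
  angular cutoff. The default angle convention reads the cutoff as the
  maximum deviation from linearity of D-H...A (i.e. the angle at the
  hydrogen must be >= 105 deg); the alternative reads it as the angle
  A-D-H at the donor being <= 75 deg. Both are available via
  ``convention``.
* Protein "surface" distance = distance to the nearest heavy atom minus
  that atom's van der Waals radius (shipped radii table).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .peakio import StructureModel, Trajectory

logger = logging.getLogger(__name__)

_VDW = None


def vdw_radius(element: str) -> float:
    global _VDW
    if _VDW is None:
        _VDW = yaml.safe_load(resources.files("ribodyn.data")
                              .joinpath("vdw_radii.yaml").read_text())
    return float(_VDW.get(element.upper(), _VDW["default"]))


@dataclass(frozen=True)
class HbondCriteria:
    distance_cut: float = 3.5    # A, donor-acceptor heavy atoms
    angle_cut: float = 75.0      # degrees

    def __post_init__(self) -> None:
        if self.distance_cut <= 0 or not (0 < self.angle_cut < 180):
            raise ValueError("invalid hydrogen-bond criteria")


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rotation R and translation t mapping mobile onto
    reference: x -> (x - mobile_centroid) @ R + reference_centroid."""
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.diag([1.0, 1.0, sign])
    rot = u @ d @ vt
    return rot, cm, cr


def _check_selection(ref_sel: np.ndarray) -> None:
    centered = ref_sel - ref_sel.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if len(ref_sel) < 3 or s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("superposition selection is degenerate (collinear)")


def superpose_frames(traj: Trajectory, selection: np.ndarray,
                     reference: Optional[np.ndarray] = None) -> np.ndarray:
    """Rigidly superpose every frame onto the reference using ``selection``
    (atom indices); returns the transformed frame array."""
    ref = traj.topology.coords if reference is None else np.asarray(reference)
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty superposition selection")
    _check_selection(ref[sel])
    out = np.empty_like(traj.frames)
    for f in range(traj.n_frames):
        rot, cm, cr = kabsch(traj.frames[f][sel], ref[sel])
        out[f] = (traj.frames[f] - cm) @ rot + cr
    return out


def rmsf(traj: Trajectory, selection: np.ndarray,
         reference: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation (A) about the mean structure
    after rigid superposition of each frame on the reference."""
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    frames = superpose_frames(traj, selection, reference)
    mean = frames.mean(axis=0)
    dev2 = np.sum((frames - mean) ** 2, axis=2)
    return np.sqrt(dev2.mean(axis=0))


def residue_rmsf(traj: Trajectory, selection: np.ndarray,
                 atom_names=("N",), reference=None) -> dict:
    """Aggregate :func:`rmsf` onto residues for the named atoms."""
    values = rmsf(traj, selection, reference)
    out = {}
    for i, atom in enumerate(traj.topology.atoms):
        if atom.name in atom_names:
            out[atom.residue] = float(values[i])
    return out


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _angles_deg(a, b, c):
    """Angle at b (degrees) for broadcastable coordinate arrays."""
    v1 = a - b
    v2 = c - b
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    cosang = np.einsum("...i,...i->...", v1, v2) / np.clip(n1 * n2, 1e-12, None)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def hbond_lifetimes(traj: Trajectory, donors: Sequence[tuple],
                    acceptors: Sequence[int],
                    criteria: HbondCriteria = HbondCriteria(),
                    convention: str = "dha") -> dict:
    """Hydrogen-bond percentage lifetime per donor.

    ``donors`` is a sequence of ``(donor_heavy_index, hydrogen_index)``;
    a donor whose hydrogen index is None is skipped with a warning.
    A frame counts for a donor when at least one acceptor satisfies both
    the distance and angle criteria. Returns
    ``{donor_heavy_index: percentage}``.
    """
    if convention not in ("dha", "adh"):
        raise ValueError(f"unknown angle convention {convention!r}")
    acc = np.asarray(acceptors, dtype=int)
    out = {}
    for d_idx, h_idx in donors:
        if h_idx is None:
            logger.warning("donor atom %d has no attached hydrogen — skipped",
                           d_idx)
            continue
        ok_acc = acc[acc != d_idx]
        if ok_acc.size == 0:
            out[d_idx] = 0.0
            continue
        dpos = traj.frames[:, d_idx]                      # (F, 3)
        hpos = traj.frames[:, h_idx]
        apos = traj.frames[:, ok_acc]                     # (F, A, 3)
        dist = np.linalg.norm(apos - dpos[:, None, :], axis=2)
        if convention == "dha":
            ang = _angles_deg(dpos[:, None, :], hpos[:, None, :], apos)
            ang_ok = ang >= 180.0 - criteria.angle_cut
        else:
            ang = _angles_deg(apos, dpos[:, None, :], hpos[:, None, :])
            ang_ok = ang <= criteria.angle_cut
        hit = np.any((dist <= criteria.distance_cut) & ang_ok, axis=1)
        out[d_idx] = 100.0 * int(hit.sum()) / traj.n_frames
    return out


def hbond_freedom(traj: Trajectory, donors, acceptors,
                  criteria: HbondCriteria = HbondCriteria(),
                  convention: str = "dha") -> dict:
    """Fractional freedom from intramolecular hydrogen bonding per residue:
    1 - lifetime/100, keyed by the donor atom's residue."""
    lifetimes = hbond_lifetimes(traj, donors, acceptors, criteria, convention)
    atoms = traj.topology.atoms
    return {atoms[d].residue: 1.0 - p / 100.0 for d, p in lifetimes.items()}


# ---------------------------------------------------------------------------
# hydration grid
# ---------------------------------------------------------------------------

class NormalizationError(ValueError):
    """Bulk shell contains no observations; density cannot be normalized."""


@dataclass
class HydrationGrid:
    origin: np.ndarray
    spacing: float
    counts: np.ndarray            # 3-D integer array
    shell1_max: float = 6.0
    shell2_max: float = 8.0
    bulk_mean: float = math.nan
    normalized: np.ndarray = None
    mdhs: list = field(default_factory=list)   # (xyz, normalized density)

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())


def _surface_distance(points: np.ndarray, protein: np.ndarray,
                      radii: np.ndarray) -> np.ndarray:
    """Distance from each point to the protein vdW surface (min over atoms
    of centre distance minus radius)."""
    tree = cKDTree(protein)
    rmax = float(radii.max())
    # nearest centres bound the answer; widen by the radius spread
    k = min(len(protein), 8)
    dist, idx = tree.query(points, k=k)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    cand = dist - radii[idx]
    best = cand.min(axis=1)
    # an unseen atom has centre distance >= dist[:, -1], so its surface
    # distance is >= dist[:, -1] - rmax; refine only where that could win
    far = dist[:, -1] < (best + rmax)
    if np.any(far) and k < len(protein):
        sub = np.nonzero(far)[0]
        full = np.linalg.norm(points[sub, None, :] - protein[None, :, :],
                              axis=2) - radii[None, :]
        best[sub] = full.min(axis=1)
    return best


def hydration_grid(traj: Trajectory, water_indices: Sequence[int],
                   protein_indices: Optional[Sequence[int]] = None,
                   spacing: float = 0.5, shell1_max: float = 6.0,
                   shell2_max: float = 8.0, site_threshold: float = 2.0,
                   superpose: bool = True) -> HydrationGrid:
    """Bin water positions on a 3-D grid and locate hydration sites.

    Frames are rigidly superposed on the topology first (protein atoms);
    water observations farther than ``shell2_max`` from the protein surface
    are not counted. Densities are normalized by the mean count per voxel
    in the bulk shell (``shell1_max``-``shell2_max``), and hydration sites
    are first-shell local maxima at or above ``site_threshold`` times bulk.
    """
    atoms = traj.topology.atoms
    wat = np.asarray(water_indices, dtype=int)
    if protein_indices is None:
        wset = set(wat.tolist())
        protein_indices = [i for i in range(len(atoms)) if i not in wset]
    prot = np.asarray(protein_indices, dtype=int)
    heavy = prot[[atoms[i].element != "H" for i in prot]]
    radii = np.array([vdw_radius(atoms[i].element) for i in heavy])

    frames = (superpose_frames(traj, heavy) if superpose
              else traj.frames)
    ref_prot = traj.topology.coords[heavy]
    lo = ref_prot.min(axis=0) - (shell2_max + 2.0 * spacing)
    hi = ref_prot.max(axis=0) + (shell2_max + 2.0 * spacing)
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    counts = np.zeros(shape, dtype=np.int64)

    for f in range(traj.n_frames):
        pw = frames[f][wat]
        sd = _surface_distance(pw, frames[f][heavy], radii)
        inside = sd <= shell2_max
        if not np.any(inside):
            continue
        ijk = np.floor((pw[inside] - lo) / spacing).astype(int)
        ijk = np.clip(ijk, 0, shape - 1)
        np.add.at(counts, (ijk[:, 0], ijk[:, 1], ijk[:, 2]), 1)

    # classify voxel centres against the reference structure
    centers_axes = [lo[k] + spacing * (np.arange(shape[k]) + 0.5)
                    for k in range(3)]
    gx, gy, gz = np.meshgrid(*centers_axes, indexing="ij")
    centers = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    sd_vox = _surface_distance(centers, ref_prot, radii).reshape(shape)
    bulk_mask = (sd_vox > shell1_max) & (sd_vox <= shell2_max)
    shell1_mask = (sd_vox >= -spacing) & (sd_vox <= shell1_max)
    if not np.any(bulk_mask) or counts[bulk_mask].sum() == 0:
        raise NormalizationError("bulk shell is empty")
    bulk_mean = float(counts[bulk_mask].mean())
    norm = counts / bulk_mean

    mdhs = []
    for ijk in np.argwhere(shell1_mask & (norm >= site_threshold)):
        i, j, k = ijk
        sl = norm[max(i - 1, 0): i + 2, max(j - 1, 0): j + 2,
                  max(k - 1, 0): k + 2]
        if norm[i, j, k] >= sl.max():
            xyz = lo + spacing * (ijk + 0.5)
            mdhs.append((tuple(float(v) for v in xyz),
                         float(norm[i, j, k])))
    mdhs.sort(key=lambda t: -t[1])
    return HydrationGrid(origin=lo, spacing=spacing, counts=counts,
                         shell1_max=shell1_max, shell2_max=shell2_max,
                         bulk_mean=bulk_mean, normalized=norm, mdhs=mdhs)


# ---------------------------------------------------------------------------
# atom depth
# ---------------------------------------------------------------------------

@dataclass
class DepthProfile:
    atom_indices: np.ndarray
    D: np.ndarray
    probe_radius: float = 8.0


def atom_depth(structure: StructureModel, probe_radius: float = 8.0,
               atom_indices: Optional[Sequence[int]] = None,
               grid_spacing: float = 0.5) -> DepthProfile:
    """Normalized exposed-volume depth index per atom.

    For each target atom a probe sphere of ``probe_radius`` is centred on
    it; the exposed volume is the part of the sphere outside every atom's
    van der Waals sphere, estimated by grid quadrature with voxel edge
    ``grid_spacing``. The index is normalized so that an isolated atom
    scores exactly 2 (on the same grid), hence 0 <= D <= 2 and D is
    non-increasing as neighbouring atoms are added.
    """
    atoms = structure.atoms
    coords = structure.coords
    radii = np.array([vdw_radius(a.element) for a in atoms])
    if probe_radius <= radii.max():
        raise ValueError("probe_radius must exceed the largest vdW radius")
    targets = (np.arange(len(atoms)) if atom_indices is None
               else np.asarray(atom_indices, dtype=int))

    # unit-sphere sample offsets, reused for every target
    n_side = int(math.ceil(2.0 * probe_radius / grid_spacing))
    ax = (np.arange(n_side) + 0.5) * grid_spacing - probe_radius
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    offsets = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    offsets = offsets[np.linalg.norm(offsets, axis=1) <= probe_radius]

    tree = cKDTree(coords)
    rmax = float(radii.max())
    D = np.empty(len(targets))
    for t, ti in enumerate(targets):
        pts = coords[ti] + offsets
        own_out = np.linalg.norm(offsets, axis=1) > radii[ti]
        n_ref = int(np.sum(own_out))
        neighbours = tree.query_ball_point(coords[ti],
                                           probe_radius + rmax)
        exposed = own_out.copy()
        for nb in neighbours:
            if nb == ti:
                continue
            exposed &= (np.linalg.norm(pts - coords[nb], axis=1)
                        > radii[nb])
        D[t] = 2.0 * float(np.sum(exposed)) / n_ref
    return DepthProfile(np.asarray(targets), D, probe_radius)
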