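"""Cyclodextrin cavity geometry, inclusion events, aggregation, hydration layer.

The inclusion criterion is a transparent cylinder test: a residue is
"included" in a CD cavity when its representative point (side-chain
heavy-atom centroid, CA for glycine or backbone-only models) lies within
``radial_max`` of the cavity axis and within ``axial_max`` of the cavity
centre along the axis.  The test is monotone in both thresholds, which
makes it directly checkable against a brute-force geometric oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .trajio import Frame, Topology, Trajectory, pairwise_min_image_distances

__all__ = [
    "CavityGeometry",
    "InclusionEvent",
    "ResidueFrequency",
    "cavity_geometry",
    "residue_representative_points",
    "detect_inclusions",
    "inclusion_frequency",
    "cd_aggregate_sizes",
    "hydration_layer_partition",
]

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA", "HN"})


@dataclass
class CavityGeometry:
    centroid: np.ndarray  # nm, midpoint of the two rim centroids
    axis: np.ndarray  # unit vector, primary rim -> secondary rim
    radius: float  # nm, mean distance of rim atoms from the axis


@dataclass(frozen=True)
class InclusionEvent:
    frame_index: int
    cd_id: int  # molecule id of the CD
    residue_index: int  # 1-based
    radial_offset: float
    axial_offset: float


@dataclass
class ResidueFrequency:
    frequency: dict[int, float]  # residue index -> fraction of frames included
    n_frames: int


def cavity_geometry(topology: Topology, frame: Frame, cd_mol: np.ndarray) -> CavityGeometry:
    """Centroid, axis and ring radius of one CD cavity from its rim atoms."""
    roles = topology.roles
    prim = cd_mol[roles[cd_mol] == "cd_primary_rim"]
    sec = cd_mol[roles[cd_mol] == "cd_secondary_rim"]
    if len(prim) == 0 or len(sec) == 0:
        raise ValueError("CD molecule is missing rim atoms")
    p = frame.coords[prim].mean(axis=0)
    s = frame.coords[sec].mean(axis=0)
    axis = s - p
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("degenerate rim geometry: coincident rim centroids")
    axis = axis / norm
    centroid = 0.5 * (p + s)
    rim = np.concatenate([prim, sec])
    rel = frame.coords[rim] - centroid
    axial = rel @ axis
    radial = np.linalg.norm(rel - axial[:, None] * axis, axis=1)
    return CavityGeometry(centroid=centroid, axis=axis, radius=float(radial.mean()))


def residue_representative_points(topology: Topology, frame: Frame):
    """(resids, points): one representative point per protein residue.

    Side-chain heavy-atom centroid; falls back to CA when the residue has
    no side-chain heavy atoms (GLY, or backbone-only fixtures).
    """
    names = topology.names
    elements = topology.elements
    resids, points = [], []
    for resid, idx in topology.protein_residues():
        side = [i for i in idx if names[i] not in BACKBONE_NAMES and elements[i] != "H"]
        if side:
            pt = frame.coords[side].mean(axis=0)
        else:
            ca = [i for i in idx if names[i] == "CA"]
            if not ca:
                continue
            pt = frame.coords[ca[0]]
        resids.append(resid)
        points.append(pt)
    return np.asarray(resids, dtype=int), np.asarray(points, dtype=float)


def detect_inclusions(
    trajectory: Trajectory,
    radial_max: float = 0.45,
    axial_max: float = 0.40,
) -> list[InclusionEvent]:
    """All (frame, CD, residue) cylinder-inclusion events in a trajectory."""
    top = trajectory.topology
    cd_mols = top.cd_molecules()
    molids = top.molids
    events: list[InclusionEvent] = []
    for fi, fr in enumerate(trajectory):
        resids, points = residue_representative_points(top, fr)
        if len(resids) == 0:
            continue
        for mol in cd_mols:
            cav = cavity_geometry(top, fr, mol)
            rel = points - cav.centroid
            axial = rel @ cav.axis
            radial = np.linalg.norm(rel - axial[:, None] * cav.axis, axis=1)
            hit = (radial < radial_max) & (np.abs(axial) < axial_max)
            for k in np.flatnonzero(hit):
                events.append(
                    InclusionEvent(
                        frame_index=fi,
                        cd_id=int(molids[mol[0]]),
                        residue_index=int(resids[k]),
                        radial_offset=float(radial[k]),
                        axial_offset=float(axial[k]),
                    )
                )
    return events


def inclusion_frequency(
    events: list[InclusionEvent], n_frames: int, residue_indices=None
) -> ResidueFrequency:
    """Per-residue fraction of frames with at least one inclusion event.

    Multiple CDs including the same residue in one frame count once.
    """
    seen: dict[int, set[int]] = {}
    for ev in events:
        seen.setdefault(ev.residue_index, set()).add(ev.frame_index)
    freq = {r: len(frames) / n_frames for r, frames in seen.items()}
    if residue_indices is not None:
        freq = {int(r): freq.get(int(r), 0.0) for r in residue_indices}
    return ResidueFrequency(frequency=freq, n_frames=n_frames)


def cd_aggregate_sizes(
    topology: Topology, frame: Frame, contact_cutoff: float = 0.35
):
    """Sizes of CD aggregates: connected components of the CD-CD contact graph.

    Two CDs are in contact when any heavy-atom pair is closer than
    ``contact_cutoff``.  Returns ``(sizes, mean_size)`` with sizes sorted
    descending; sizes always sum to the number of CDs.
    """
    cd_mols = topology.cd_molecules()
    n = len(cd_mols)
    if n == 0:
        raise ValueError("no CD molecules in topology")
    heavy = [m[topology.elements[m] != "H"] for m in cd_mols]
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_min_image_distances(
                frame.coords[heavy[i]], frame.coords[heavy[j]],
                frame.box, frame.periodic,
            )
            if d.min() < contact_cutoff:
                rows += [i, j]
                cols += [j, i]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.sort(np.bincount(labels, minlength=n_comp))[::-1]
    return sizes, float(sizes.mean())


def hydration_layer_partition(
    trajectory: Trajectory,
    shell_width: float = 0.6,
    *,
    mc_points: int = 10_000,
    seed: int = 0,
) -> float:
    """Hydration-layer partition coefficient of CDs around the protein.

    K = (n_CD_shell / n_water_shell) / (n_CD_bulk / n_water_bulk), averaged
    over frames; the shell is everything within ``shell_width`` of a protein
    heavy atom.  K > 1 reads as preferential inclusion of CDs in the
    hydration layer.  Frames with an empty shell or bulk are skipped with a
    warning.  Without water, water counts are replaced by Monte-Carlo
    estimates of the shell and bulk volumes (``mc_points`` seeded samples).
    """
    top = trajectory.topology
    prot = top.protein_indices
    prot = prot[top.elements[prot] != "H"]
    if len(prot) == 0:
        raise ValueError("no protein atoms")
    cd_mols = top.cd_molecules()
    if not cd_mols:
        # fall back: any non-water, non-protein molecules grouped by resid
        others = np.flatnonzero(
            ~np.isin(np.arange(top.n_atoms), np.concatenate([prot, top.water_indices]))
        )
        cd_mols = top.molecules(others) if len(others) else []
    if not cd_mols:
        raise ValueError("no CD (solute) molecules")
    waters = top.molecules(top.water_indices) if len(top.water_indices) else []
    rng = np.random.default_rng(seed)

    ratios = []
    for fr in trajectory:
        prot_xyz = fr.coords[prot]

        def min_dist(points):
            d = pairwise_min_image_distances(points, prot_xyz, fr.box, fr.periodic)
            return d.min(axis=1)

        cd_pts = np.array([fr.coords[m].mean(axis=0) for m in cd_mols])
        cd_shell = min_dist(cd_pts) < shell_width
        n_cd_s, n_cd_b = int(cd_shell.sum()), int((~cd_shell).sum())
        if waters:
            w_pts = np.array([fr.coords[m].mean(axis=0) for m in waters])
            w_shell = min_dist(w_pts) < shell_width
            n_w_s, n_w_b = int(w_shell.sum()), int((~w_shell).sum())
        else:
            pts = rng.uniform(size=(mc_points, 3)) * fr.box
            in_shell = min_dist(pts) < shell_width
            n_w_s, n_w_b = int(in_shell.sum()), int((~in_shell).sum())
        if n_w_s == 0 or n_w_b == 0 or (n_cd_s + n_cd_b) == 0 or n_cd_b == 0:
            warn("frame skipped: empty shell or bulk")
            continue
        ratios.append((n_cd_s / n_w_s) / (n_cd_b / n_w_b))
    if not ratios:
        raise ValueError("no usable frames")
    return float(np.mean(ratios))
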