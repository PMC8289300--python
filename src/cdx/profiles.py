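"""Interface location, density and rim-orientation profiles, proximity counts.

Profiles are taken along the interface normal (+z, non-periodic).  Number
densities are normalized by their mean over a designated liquid region, so
bulk reads as 1 and surface enrichment as > 1.  Molecule positions are
heavy-atom centres of mass, which makes the profiles insensitive to
hydrogen placement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajio import Frame, Topology, Trajectory, pairwise_min_image_distances

__all__ = [
    "DensityProfile",
    "OrientationProfile",
    "locate_interface",
    "density_profile",
    "rim_orientation_profile",
    "proximity_count",
    "molecule_groups",
]


@dataclass
class DensityProfile:
    bin_edges: np.ndarray  # nm along z
    density: np.ndarray  # normalized (liquid-region mean = 1)
    group: str
    n_frames: int
    counts: np.ndarray  # raw molecule counts per bin, summed over frames

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class OrientationProfile:
    bin_edges: np.ndarray
    mean_cos_theta: np.ndarray  # NaN where counts == 0
    counts: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def molecule_groups(topology: Topology, group: str) -> list[np.ndarray]:
    """Molecule atom-index groups for a named group: cd | protein | water."""
    if group == "cd":
        mols = topology.cd_molecules()
    elif group == "protein":
        prot = topology.protein_indices
        if len(prot) == 0:
            mols = []
        else:
            mols = topology.molecules(prot)
    elif group == "water":
        mols = topology.molecules(topology.water_indices)
    else:
        raise ValueError(f"unknown group {group!r}")
    if not mols:
        raise ValueError(f"group {group!r} is empty")
    return mols


def _heavy_com_z(topology: Topology, frame: Frame, mols: list[np.ndarray]) -> np.ndarray:
    elements = topology.elements
    masses = topology.masses
    out = np.empty(len(mols))
    for i, mol in enumerate(mols):
        heavy = mol[elements[mol] != "H"]
        if len(heavy) == 0:
            heavy = mol
        m = masses[heavy]
        out[i] = float(np.dot(m, frame.coords[heavy, 2]) / m.sum())
    return out


def _heavy_com(topology: Topology, frame: Frame, mol: np.ndarray) -> np.ndarray:
    heavy = mol[topology.elements[mol] != "H"]
    if len(heavy) == 0:
        heavy = mol
    m = topology.masses[heavy]
    return (m[:, None] * frame.coords[heavy]).sum(axis=0) / m.sum()


class InterfaceError(RuntimeError):
    """No density plateau could be detected; provide more frames or waters."""


def locate_interface(
    trajectory: Trajectory,
    water_group: np.ndarray | None = None,
    kind: str = "air",
    bin_width: float = 0.1,
) -> np.ndarray:
    """Interface position z0 per frame.

    ``air``: the z where the water density profile first falls to 50% of its
    bulk plateau, scanning upward; the crossing is interpolated between bin
    centres.  ``ice``: the maximum z of the frozen group.
    """
    top = trajectory.topology
    if kind == "ice":
        frozen = np.flatnonzero(top.frozen)
        if len(frozen) == 0:
            raise ValueError("kind='ice' requires a frozen-group tag on the topology")
        return np.array([float(fr.coords[frozen, 2].max()) for fr in trajectory])
    if kind != "air":
        raise ValueError(f"unknown interface kind {kind!r}")
    if water_group is None:
        water_group = top.water_indices[~top.frozen[top.water_indices]]
    water_group = np.asarray(water_group)
    if len(water_group) == 0:
        raise ValueError("water_group is empty")

    out = np.empty(len(trajectory))
    for fi, fr in enumerate(trajectory):
        z = fr.coords[water_group, 2]
        if len(z) < 50:
            raise InterfaceError("too few water sites to detect a plateau")
        n_bins = max(10, int(np.ceil(fr.box[2] / bin_width)))
        counts, edges = np.histogram(z, bins=n_bins, range=(0.0, fr.box[2]))
        centers = 0.5 * (edges[:-1] + edges[1:])
        occ = np.flatnonzero(counts > 0)
        zmin, zmax = centers[occ[0]], centers[occ[-1]]
        span = zmax - zmin
        core = (centers >= zmin + 0.2 * span) & (centers <= zmin + 0.6 * span)
        if counts[core].sum() < 20:
            raise InterfaceError("too few water sites in the plateau region")
        plateau = counts[core].mean()
        half = 0.5 * plateau
        # scan upward from the top of the core region for the half crossing
        start = int(np.flatnonzero(core)[-1])
        z0 = None
        for i in range(start, len(counts)):
            if counts[i] < half:
                c_hi, c_lo = counts[i], counts[i - 1]
                frac = (c_lo - half) / max(c_lo - c_hi, 1e-12)
                z0 = centers[i - 1] + frac * (centers[i] - centers[i - 1])
                break
        if z0 is None:
            raise InterfaceError("water density never falls below half its plateau")
        out[fi] = z0
    return out


def density_profile(
    trajectory: Trajectory,
    group: str | list[np.ndarray],
    n_bins: int | None = None,
    liquid_region: tuple[float, float] = (0.0, 5.0),
    bin_width: float = 0.1,
) -> DensityProfile:
    """Normalized number-density profile of molecule centres of mass along z.

    Counts are histogrammed over frames, converted to number density, and
    divided by the mean density over ``liquid_region`` so the bulk liquid
    averages to 1.
    """
    top = trajectory.topology
    mols = molecule_groups(top, group) if isinstance(group, str) else list(group)
    label = group if isinstance(group, str) else "custom"
    if not mols:
        raise ValueError("empty group")
    lz = float(trajectory.frames[0].box[2])
    if n_bins is None:
        n_bins = int(np.ceil(lz / bin_width))
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    edges = np.linspace(0.0, lz, n_bins + 1)
    counts = np.zeros(n_bins)
    for fr in trajectory:
        zc = _heavy_com_z(top, fr, mols)
        c, _ = np.histogram(zc, bins=edges)
        counts += c
    area = float(trajectory.frames[0].box[0] * trajectory.frames[0].box[1])
    dz = edges[1] - edges[0]
    dens = counts / (len(trajectory) * area * dz)
    centers = 0.5 * (edges[:-1] + edges[1:])
    liquid = (centers >= liquid_region[0]) & (centers < liquid_region[1])
    ref = dens[liquid].mean() if liquid.any() else 0.0
    if ref <= 0:
        raise ValueError("no density in the designated liquid region")
    return DensityProfile(edges, dens / ref, label, len(trajectory), counts)


def cd_rim_vectors(topology: Topology, frame: Frame):
    """(centers, cos_theta) of each CD: cavity centre and the cosine between
    the primary-to-secondary rim vector and +z."""
    roles = topology.roles
    centers, cos_t = [], []
    for mol in topology.cd_molecules():
        prim = mol[roles[mol] == "cd_primary_rim"]
        sec = mol[roles[mol] == "cd_secondary_rim"]
        if len(prim) == 0 or len(sec) == 0:
            raise ValueError("CD molecule missing rim atoms")
        p = frame.coords[prim].mean(axis=0)
        s = frame.coords[sec].mean(axis=0)
        axis = s - p
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("degenerate CD rim geometry")
        centers.append(0.5 * (p + s))
        cos_t.append(axis[2] / norm)
    return np.asarray(centers), np.asarray(cos_t)


def rim_orientation_profile(
    trajectory: Trajectory,
    n_bins: int | None = None,
    bin_width: float = 0.1,
) -> OrientationProfile:
    """Mean cos(theta) of the CD cavity axis vs +z, binned by cavity-centre z."""
    lz = float(trajectory.frames[0].box[2])
    if n_bins is None:
        n_bins = int(np.ceil(lz / bin_width))
    edges = np.linspace(0.0, lz, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for fr in trajectory:
        centers, cos_t = cd_rim_vectors(trajectory.topology, fr)
        idx = np.clip(np.digitize(centers[:, 2], edges) - 1, 0, n_bins - 1)
        np.add.at(sums, idx, cos_t)
        np.add.at(counts, idx, 1.0)
    mean = np.full(n_bins, np.nan)
    occ = counts > 0
    mean[occ] = sums[occ] / counts[occ]
    return OrientationProfile(edges, mean, counts)


def proximity_count(
    trajectory: Trajectory,
    group: str = "cd",
    reference: str | np.ndarray = "protein_surface",
    cutoff: float = 2.0,
) -> np.ndarray:
    """Per-frame count of group molecules whose minimum heavy-atom distance
    to the reference group is below ``cutoff`` (default 2 nm)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    top = trajectory.topology
    mols = molecule_groups(top, group) if isinstance(group, str) else list(group)
    if isinstance(reference, str):
        if reference == "protein_surface":
            ref = top.protein_indices
            ref = ref[top.elements[ref] != "H"]
        elif reference == "ice_surface":
            ref = np.flatnonzero(top.frozen)
        else:
            raise ValueError(f"unknown reference {reference!r}")
    else:
        ref = np.asarray(reference)
    if len(ref) == 0:
        raise ValueError("reference group is empty")

    out = np.empty(len(trajectory), dtype=int)
    for fi, fr in enumerate(trajectory):
        n = 0
        ref_xyz = fr.coords[ref]
        for mol in mols:
            heavy = mol[top.elements[mol] != "H"]
            if len(heavy) == 0:
                heavy = mol
            d = pairwise_min_image_distances(
                fr.coords[heavy], ref_xyz, fr.box, fr.periodic
            )
            if d.min() < cutoff:
                n += 1
        out[fi] = n
    return out
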