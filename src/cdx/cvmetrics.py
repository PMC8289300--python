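"""Collective variables: radius of gyration, alpha-helix content,
protein-interface distance and distance-RMSD (dRMSD).

dRMSD compares intramolecular pairwise distances of a frame with those of
a reference structure:

    dRMSD = sqrt( (1/P) * sum_{(i,j)} [ d(x_i, x_j) - d_ref(x_i, x_j) ]^2 )

where the pair list contains exactly the atom pairs whose *reference*
distance lies between a lower and an upper cutoff (defaults 0.1 and 3.0
nm); the frame's distances are never re-filtered.  Distances are
non-periodic (the molecule is whole).

The alpha-helix content scores every six-consecutive-residue backbone
segment against an ideal helical template with a smooth rational
switching function, so the CV is continuous in the coordinates and
ranges from 0 to (n_res - 5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import superposed_rmsd
from .trajio import Frame, Topology, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "DRMSDSpec",
    "radius_of_gyration",
    "drmsd",
    "alpha_helix_content",
    "interface_distance",
    "backbone_indices",
    "cv_series",
]


def backbone_indices(topology: Topology, include_o: bool = True) -> np.ndarray:
    """Protein backbone atom indices: N, CA, C and (optionally) carbonyl O."""
    idx = list(topology.backbone_indices(("N", "CA", "C")))
    if include_o:
        prot = set(topology.protein_indices.tolist())
        names = topology.names
        idx += [i for i in prot if names[i] == "O"]
    return np.array(sorted(idx), dtype=np.int64)


def radius_of_gyration(
    topology: Topology,
    frame: Frame,
    group: np.ndarray | None = None,
    mass_weighted: bool = True,
) -> float:
    """sqrt( sum m_i |r_i - r_com|^2 / sum m_i ), in nm."""
    idx = topology.protein_indices if group is None else np.asarray(group)
    if len(idx) == 0:
        raise ValueError("empty group")
    x = frame.coords[idx]
    m = topology.masses[idx] if mass_weighted else np.ones(len(idx))
    com = (m[:, None] * x).sum(axis=0) / m.sum()
    return float(np.sqrt(np.sum(m * np.sum((x - com) ** 2, axis=1)) / m.sum()))


@dataclass
class DRMSDSpec:
    """Reference pair list for dRMSD, built from the reference structure only."""

    atom_indices: np.ndarray  # indices into the topology (e.g. backbone)
    pair_i: np.ndarray  # local indices into atom_indices
    pair_j: np.ndarray
    ref_distances: np.ndarray
    lower_cutoff: float = 0.1
    upper_cutoff: float = 3.0

    @classmethod
    def from_reference(
        cls,
        reference: Frame,
        atom_indices: np.ndarray,
        lower_cutoff: float = 0.1,
        upper_cutoff: float = 3.0,
    ) -> "DRMSDSpec":
        if lower_cutoff >= upper_cutoff:
            raise ValueError("lower_cutoff must be < upper_cutoff")
        atom_indices = np.asarray(atom_indices)
        x = reference.coords[atom_indices]
        n = len(x)
        iu, ju = np.triu_indices(n, k=1)
        d = np.linalg.norm(x[iu] - x[ju], axis=1)
        keep = (d > lower_cutoff) & (d < upper_cutoff)
        if not keep.any():
            raise ValueError("cutoffs exclude every atom pair")
        return cls(atom_indices, iu[keep], ju[keep], d[keep],
                   lower_cutoff, upper_cutoff)

    @property
    def n_pairs(self) -> int:
        return len(self.ref_distances)


def drmsd(frame: Frame, spec: DRMSDSpec) -> float:
    """Distance-RMSD of a frame against the reference pair list, in nm."""
    x = frame.coords[spec.atom_indices]
    d = np.linalg.norm(x[spec.pair_i] - x[spec.pair_j], axis=1)
    return float(np.sqrt(np.mean((d - spec.ref_distances) ** 2)))


# ---------------------------------------------------------------------------
# Alpha-helix content
# ---------------------------------------------------------------------------

_TEMPLATE_CACHE: dict[int, np.ndarray] = {}


def _helix_template() -> np.ndarray:
    """Backbone (N, CA, C) coordinates of an ideal six-residue helix."""
    if 6 not in _TEMPLATE_CACHE:
        from .synthetic import make_ideal_helix

        top, fr = make_ideal_helix(6)
        idx = top.backbone_indices(("N", "CA", "C"))
        # keep per-residue N, CA, C order
        order = np.argsort(idx)
        _TEMPLATE_CACHE[6] = fr.coords[idx[order]]
    return _TEMPLATE_CACHE[6]


def _switching(x: float, exponents: tuple[int, int]) -> float:
    n, m = exponents
    if abs(x - 1.0) < 1e-9:
        return n / m
    return (1.0 - x**n) / (1.0 - x**m)


def alpha_helix_content(
    topology: Topology,
    frame: Frame,
    r0: float = 0.08,
    exponents: tuple[int, int] = (8, 12),
) -> float:
    """Smoothly-counted number of helical six-residue segments.

    Every window of six consecutive protein residues contributes
    S(RMSD/r0), where RMSD is the optimal-superposition backbone (N, CA, C)
    RMSD to the ideal helical template and S is the rational switching
    function with the given exponents (S(0) = 1, S -> 0 for large RMSD).
    Windows with missing backbone atoms are skipped with a warning.
    """
    residues = topology.protein_residues()
    if len(residues) < 6:
        raise ValueError("alpha content needs at least 6 protein residues")
    names = topology.names
    per_res = []
    for resid, idx in residues:
        trio = {}
        for i in idx:
            if names[i] in ("N", "CA", "C") and names[i] not in trio:
                trio[names[i]] = i
        per_res.append((resid, trio))
    template = _helix_template()
    total = 0.0
    n_skipped = 0
    for w in range(len(per_res) - 5):
        window = per_res[w:w + 6]
        resids = [r for r, _ in window]
        if any(resids[k + 1] != resids[k] + 1 for k in range(5)):
            continue  # chain break
        try:
            sel = [trio[nm] for _, trio in window for nm in ("N", "CA", "C")]
        except KeyError:
            n_skipped += 1
            continue
        seg = frame.coords[sel]
        rmsd = superposed_rmsd(seg, template)
        total += _switching(rmsd / r0, exponents)
    if n_skipped:
        logger.warning("%d six-residue windows skipped (missing backbone atoms)",
                       n_skipped)
    return total


def interface_distance(
    topology: Topology,
    frame: Frame,
    z0: float,
    group: np.ndarray | None = None,
) -> float:
    """|z_com(protein) - z0| in nm."""
    idx = topology.protein_indices if group is None else np.asarray(group)
    if len(idx) == 0:
        raise ValueError("empty group")
    m = topology.masses[idx]
    z_com = float(np.dot(m, frame.coords[idx, 2]) / m.sum())
    return abs(z_com - float(z0))


def cv_series(
    trajectory: Trajectory,
    drmsd_spec: DRMSDSpec | None = None,
    z0: np.ndarray | float | None = None,
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-frame CV table: time, rg, alpha, d_interface, drmsd, weight."""
    top = trajectory.topology
    n = len(trajectory)
    z0_arr = None
    if z0 is not None:
        z0_arr = np.broadcast_to(np.asarray(z0, float), (n,))
    rows = []
    for fi, fr in enumerate(trajectory):
        row = {
            "time": fr.time,
            "rg": radius_of_gyration(top, fr),
            "alpha": alpha_helix_content(top, fr),
        }
        row["d_interface"] = (
            interface_distance(top, fr, z0_arr[fi]) if z0_arr is not None else np.nan
        )
        row["drmsd"] = drmsd(fr, drmsd_spec) if drmsd_spec is not None else np.nan
        row["weight"] = 1.0 if weights is None else float(weights[fi])
        rows.append(row)
    return pd.DataFrame(rows)
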