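"""Conformational analysis: superposition, clustering, per-residue Q, patches.

The Daura (GROMOS) clustering algorithm greedily promotes the frame with
the most neighbours (pairwise superposed RMSD below a cutoff, default 0.1
nm on the N-CA-C backbone) to cluster centroid, removes it together with
its neighbours, and repeats.  Frame weights (e.g. from metadynamics
reweighting) enter only the reported cluster populations, not the
geometric neighbour counts.

Q_res scores the per-residue similarity of two conformations of the same
protein through their CA-CA distance patterns:

    q_i = (1/N_i) * sum_{j: |i-j| >= 2} exp( -(r_ij - r'_ij)^2 / (2 sigma_ij^2) ),
    sigma_ij^2 = |i - j|^0.15

with r and r' the CA-CA distances in the two structures.  q_i is 1 for
identical local distance patterns and approaches 0 for unrelated ones.
Residues with q below a threshold (default 0.5) form the "unstable
patches" of the protein.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .geometry import kabsch_rotation, superposed_rmsd

__all__ = [
    "ClusterResult",
    "QresProfile",
    "kabsch_superpose",
    "pairwise_rmsd_matrix",
    "daura_cluster",
    "daura_cluster_from_matrix",
    "qres",
    "unstable_patches",
    "patch_frequency",
    "parse_apr_ranges",
    "crossref_patches",
]


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal least-squares rigid superposition (rotation, translation, rmsd).

    ``mobile @ R.T + t`` best fits ``reference``; R is a proper rotation.
    Raises on degenerate (collinear) selections.
    """
    return kabsch_rotation(mobile, reference)


@dataclass
class ClusterResult:
    assignment: np.ndarray  # frame -> cluster id (0-based, by discovery order)
    centroids: np.ndarray  # one frame index per cluster
    populations: np.ndarray  # unweighted frame counts per cluster
    weighted_fractions: np.ndarray  # sum of frame weights per cluster, sum 1

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


def pairwise_rmsd_matrix(coords: list[np.ndarray]) -> np.ndarray:
    """Symmetric matrix of pairwise Kabsch-superposed RMSDs."""
    n = len(coords)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = superposed_rmsd(coords[i], coords[j])
    return m


def daura_cluster_from_matrix(
    rmsd: np.ndarray, cutoff: float, weights: np.ndarray | None = None
) -> ClusterResult:
    """Daura clustering on a precomputed RMSD matrix.

    Ties in the neighbour count are broken toward the lowest frame index,
    which makes the result deterministic.
    """
    rmsd = np.asarray(rmsd, float)
    n = len(rmsd)
    if n == 0:
        raise ValueError("empty frame set")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, float)
    neighbors = rmsd < cutoff
    np.fill_diagonal(neighbors, True)
    remaining = np.ones(n, dtype=bool)
    assignment = np.full(n, -1, dtype=int)
    centroids: list[int] = []
    while remaining.any():
        counts = (neighbors & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbors[center] & remaining)
        cid = len(centroids)
        assignment[members] = cid
        centroids.append(center)
        remaining[members] = False
    pops = np.bincount(assignment, minlength=len(centroids))
    wsum = np.array([weights[assignment == c].sum() for c in range(len(centroids))])
    return ClusterResult(
        assignment=assignment,
        centroids=np.array(centroids),
        populations=pops,
        weighted_fractions=wsum / wsum.sum(),
    )


def daura_cluster(
    frames: list[np.ndarray],
    cutoff: float = 0.1,
    weights: np.ndarray | None = None,
) -> ClusterResult:
    """Daura clustering of coordinate sets (e.g. N-CA-C backbones), in nm."""
    if len(frames) == 0:
        raise ValueError("empty frame set")
    return daura_cluster_from_matrix(pairwise_rmsd_matrix(frames), cutoff, weights)


# ---------------------------------------------------------------------------
# Q_res
# ---------------------------------------------------------------------------


@dataclass
class QresProfile:
    q: np.ndarray  # per residue, in [0, 1]
    resids: np.ndarray  # 1-based residue indices
    sigma_exponent: float = 0.15

    def as_dict(self) -> dict[int, float]:
        return {int(r): float(v) for r, v in zip(self.resids, self.q)}


def qres(
    ca_a: np.ndarray,
    ca_b: np.ndarray,
    resids: np.ndarray | None = None,
    sigma_exponent: float = 0.15,
    min_separation: int = 2,
) -> QresProfile:
    """Per-residue structural similarity of two CA coordinate sets.

    The score depends only on intramolecular CA-CA distances, so it is
    invariant under rigid motions of either structure and symmetric in its
    arguments.  ``min_separation`` excludes self and adjacent residues from
    each residue's sum.
    """
    ca_a = np.asarray(ca_a, float)
    ca_b = np.asarray(ca_b, float)
    if ca_a.shape != ca_b.shape or ca_a.ndim != 2:
        raise ValueError("CA coordinate sets must be (N, 3) with equal N")
    n = len(ca_a)
    if resids is None:
        resids = np.arange(1, n + 1)
    da = np.linalg.norm(ca_a[:, None, :] - ca_a[None, :, :], axis=-1)
    db = np.linalg.norm(ca_b[:, None, :] - ca_b[None, :, :], axis=-1)
    sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    mask = sep >= min_separation
    sigma2 = np.where(mask, sep.astype(float), 1.0) ** sigma_exponent
    contrib = np.exp(-((da - db) ** 2) / (2.0 * sigma2)) * mask
    with np.errstate(invalid="ignore"):
        q = contrib.sum(axis=1) / np.maximum(mask.sum(axis=1), 1)
    return QresProfile(q=q, resids=np.asarray(resids), sigma_exponent=sigma_exponent)


def unstable_patches(profile: QresProfile, threshold: float = 0.5) -> set[int]:
    """Residues with q below ``threshold`` (the conformationally unstable set)."""
    return {int(r) for r, v in zip(profile.resids, profile.q) if v < threshold}


def patch_frequency(
    patch_sets: list[set[int]],
    residue_range: tuple[int, int],
    labels: list[str] | None = None,
):
    """Fraction of systems in which each residue is unstable.

    Returns ``(resids, pooled)`` or, with ``labels`` (e.g. the excipient of
    each system), ``(resids, pooled, by_label)`` where ``by_label`` maps each
    label to its stratified frequency array.  The stratified frequencies
    average back to the pooled one, weighted by system counts.
    """
    if not patch_sets:
        raise ValueError("need at least one system")
    lo, hi = residue_range
    resids = np.arange(lo, hi + 1)
    for s in patch_sets:
        if s and (min(s) < lo or max(s) > hi):
            raise ValueError("patch set outside the stated residue range")
    mat = np.array([[r in s for r in resids] for s in patch_sets], dtype=float)
    pooled = mat.mean(axis=0)
    if labels is None:
        return resids, pooled
    by_label = {
        lab: mat[[i for i, l in enumerate(labels) if l == lab]].mean(axis=0)
        for lab in dict.fromkeys(labels)
    }
    return resids, pooled, by_label


_APR_RE = re.compile(r"([A-Z]{3})?(\d+)\s*(?:-\s*([A-Z]{3})?(\d+))?")


def parse_apr_ranges(text: str) -> list[tuple[int, int]]:
    """Parse aggregation-prone-region ranges like ``PHE13-CYS17, ILE56``.

    Accepts comma- or newline-separated entries; a bare residue is a
    one-residue range.
    """
    ranges = []
    for token in re.split(r"[,\n]+", text.strip()):
        token = token.strip()
        if not token or token.startswith("#"):
            continue
        m = _APR_RE.fullmatch(token)
        if not m:
            raise ValueError(f"cannot parse APR range {token!r}")
        start = int(m.group(2))
        end = int(m.group(4)) if m.group(4) else start
        if end < start:
            raise ValueError(f"inverted APR range {token!r}")
        ranges.append((start, end))
    return ranges


def crossref_patches(
    resids: np.ndarray,
    patch_freq: np.ndarray,
    inclusion_freq: dict[int, float],
    apr_ranges: list[tuple[int, int]],
):
    """Cross-reference unstable patches, cavity inclusions and APRs.

    Returns a dict with a per-residue table (resid, patch_freq,
    inclusion_freq, in_apr), the Spearman rank correlation between patch and
    inclusion frequencies, and the Jaccard overlap between the residues that
    are ever unstable and the APR residue set.
    """
    resids = np.asarray(resids)
    lo, hi = int(resids.min()), int(resids.max())
    apr_set: set[int] = set()
    for a, b in apr_ranges:
        if a < lo or b > hi:
            raise ValueError(f"APR range {a}-{b} outside residue span {lo}-{hi}")
        apr_set.update(range(a, b + 1))
    inc = np.array([inclusion_freq.get(int(r), 0.0) for r in resids])
    in_apr = np.array([int(r) in apr_set for r in resids])
    if np.ptp(patch_freq) == 0 or np.ptp(inc) == 0:
        rho = 1.0 if np.allclose(patch_freq, inc) else float("nan")
    else:
        rho = float(spearmanr(patch_freq, inc).statistic)
    patch_set = {int(r) for r, f in zip(resids, patch_freq) if f > 0}
    union = patch_set | apr_set
    jaccard = len(patch_set & apr_set) / len(union) if union else 1.0
    return {
        "resids": resids,
        "patch_freq": np.asarray(patch_freq, float),
        "inclusion_freq": inc,
        "in_apr": in_apr,
        "rank_correlation": rho,
        "jaccard_apr": jaccard,
    }
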