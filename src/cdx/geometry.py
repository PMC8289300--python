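"""Low-level rigid-body geometry shared across modules."""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch_rotation", "superposed_rmsd", "random_rotation"]


class DegenerateSelectionError(ValueError):
    """The atom selection does not span three dimensions (e.g. collinear)."""


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray, *, check_degenerate: bool = True):
    """Optimal least-squares rigid superposition of ``mobile`` onto ``reference``.

    Both arrays are (N, 3).  Returns ``(R, t, rmsd)`` such that
    ``mobile @ R.T + t`` minimises the RMSD to ``reference``; ``R`` is a
    proper rotation (det +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (N, 3) with equal N")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    x = mobile - cm
    y = reference - cr
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    if check_degenerate and s[1] <= 1e-12 * max(s[0], 1e-300):
        raise DegenerateSelectionError(
            "selection is (near-)collinear; rotation is not uniquely determined"
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cr - rot @ cm
    moved = x @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    return rot, trans, rmsd


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets over all rigid motions."""
    _, _, rmsd = kabsch_rotation(a, b, check_degenerate=False)
    return rmsd


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
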