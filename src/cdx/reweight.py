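"""Well-tempered metadynamics reweighting and convergence diagnostics.

A well-tempered (or parallel-bias) metadynamics run deposits Gaussian
hills whose heights decay with the accumulated bias; the biased ensemble
is turned back into unbiased statistics by assigning each frame the
weight

    w_t  ~  exp( (V(s_t, t) - c(t)) / kT )

where V is the instantaneous total bias at the frame and c(t) is the
time-dependent offset

    c(t) = kT * ln [ Int ds exp( gamma V / ((gamma-1) kT) )
                   / Int ds exp(       V / ((gamma-1) kT) ) ]

evaluated by quadrature on a grid at each deposition time.  Frames carry
the *total* applied bias (the value a COLVAR file stores), so the same
machinery reweights single-CV and parallel-bias runs.

Hills stored here carry already-tempered heights: V(s, t) is simply the
sum of the deposited Gaussians up to time t.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MetaDParams",
    "HillRecord",
    "WeightedDistribution",
    "bias_on_grid",
    "estimate_ct",
    "frame_weights",
    "weighted_distribution",
    "fes",
    "convergence_drift",
    "pool_walkers",
    "read_colvar",
    "write_colvar",
    "read_hills",
    "write_hills",
]

KT_300K = 2.494  # kJ/mol at 300 K


@dataclass(frozen=True)
class MetaDParams:
    """Well-tempered metadynamics parameters.

    ``initial_height = 0`` is allowed and means an unbiased control run.
    """

    bias_factor: float = 15.0
    initial_height: float = 2.0  # kJ/mol
    deposition_rate: float = 1.0  # hills per ps
    kT: float = KT_300K  # kJ/mol

    def __post_init__(self):
        if self.bias_factor <= 1:
            raise ValueError("bias_factor must be > 1")
        if self.initial_height < 0:
            raise ValueError("initial_height must be >= 0")
        if self.deposition_rate <= 0:
            raise ValueError("deposition_rate must be > 0")


@dataclass(frozen=True)
class HillRecord:
    """One deposited Gaussian; ``height`` is the tempered (deposited) height."""

    time: float  # ps
    center: float  # CV units
    width: float  # CV units (Gaussian sigma)
    height: float  # kJ/mol

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("hill width must be > 0")
        if self.height <= 0:
            raise ValueError("hill height must be > 0")


@dataclass
class WeightedDistribution:
    bin_edges: np.ndarray
    probability: np.ndarray  # mass per bin, sums to 1
    effective_sample_size: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def bias_on_grid(
    hills: list[HillRecord], grid: np.ndarray, t: float | None = None
) -> np.ndarray:
    """Total bias V(s, t) on ``grid``: sum of hills deposited up to time t."""
    grid = np.asarray(grid, float)
    v = np.zeros_like(grid)
    for h in hills:
        if t is not None and h.time > t:
            continue
        v += h.height * np.exp(-((grid - h.center) ** 2) / (2.0 * h.width**2))
    return v


def _log_trapz(log_f: np.ndarray, x: np.ndarray) -> float:
    m = float(np.max(log_f))
    return m + float(np.log(np.trapezoid(np.exp(log_f - m), x)))


def estimate_ct(
    hills: list[HillRecord],
    grid: np.ndarray,
    bias_factor: float,
    kT: float,
) -> tuple[np.ndarray, np.ndarray]:
    """c(t) at every deposition time, by trapezoid quadrature on ``grid``.

    Returns ``(times, ct)``.  Raises if the grid is too coarse to resolve
    the narrowest hill (quadrature would be unstable).
    """
    grid = np.asarray(grid, float)
    if len(grid) < 10:
        raise ValueError("grid too coarse for quadrature")
    dg = float(np.max(np.diff(grid)))
    if hills:
        min_w = min(h.width for h in hills)
        if dg > min_w:
            raise ValueError(
                f"grid spacing {dg:.3g} exceeds the narrowest hill width "
                f"{min_w:.3g}; refine the grid"
            )
    a = bias_factor / ((bias_factor - 1.0) * kT)
    b = 1.0 / ((bias_factor - 1.0) * kT)
    v = np.zeros_like(grid)
    times = np.empty(len(hills))
    ct = np.empty(len(hills))
    for i, h in enumerate(hills):
        v += h.height * np.exp(-((grid - h.center) ** 2) / (2.0 * h.width**2))
        times[i] = h.time
        ct[i] = kT * (_log_trapz(a * v, grid) - _log_trapz(b * v, grid))
    return times, ct


def frame_weights(
    frame_times: np.ndarray,
    bias_at_frame: np.ndarray,
    ct_times: np.ndarray,
    ct_values: np.ndarray,
    kT: float,
) -> np.ndarray:
    """Tiwary-Parrinello frame weights, normalized to mean 1.

    ``bias_at_frame`` is V(s_t, t) per frame; c(t) is interpolated as a
    step function (0 before the first deposition).
    """
    frame_times = np.asarray(frame_times, float)
    bias_at_frame = np.asarray(bias_at_frame, float)
    ct_times = np.asarray(ct_times, float)
    ct_values = np.asarray(ct_values, float)
    if frame_times.shape != bias_at_frame.shape:
        raise ValueError("frame_times and bias_at_frame are misaligned")
    if ct_times.shape != ct_values.shape:
        raise ValueError("ct series is misaligned")
    if np.any(np.diff(frame_times) < 0) or np.any(np.diff(ct_times) < 0):
        raise ValueError("time series must be sorted")
    if len(ct_times):
        idx = np.searchsorted(ct_times, frame_times, side="right") - 1
        c = np.where(idx >= 0, ct_values[np.clip(idx, 0, None)], 0.0)
    else:
        c = np.zeros_like(frame_times)
    logw = (bias_at_frame - c) / kT
    logw -= np.max(logw)
    w = np.exp(logw)
    return w / np.mean(w)


def weighted_distribution(
    cv_values: np.ndarray,
    weights: np.ndarray | None = None,
    bins: int | np.ndarray = 50,
    range: tuple[float, float] | None = None,
) -> WeightedDistribution:
    """Normalized weighted histogram (probability mass per bin, sum 1)."""
    cv_values = np.asarray(cv_values, float)
    if weights is None:
        weights = np.ones_like(cv_values)
    weights = np.asarray(weights, float)
    if weights.shape != cv_values.shape:
        raise ValueError("weights must match cv_values in length")
    total = float(np.sum(weights))
    if total <= 0:
        raise ValueError("weights sum to zero")
    hist, edges = np.histogram(cv_values, bins=bins, range=range, weights=weights)
    ess = total**2 / float(np.sum(weights**2))
    return WeightedDistribution(edges, hist / total, ess)


def fes(dist: WeightedDistribution, kT: float) -> np.ndarray:
    """Free-energy surface -kT ln p, shifted to min 0; empty bins are NaN."""
    p = dist.probability
    out = np.full_like(p, np.nan, dtype=float)
    mask = p > 0
    out[mask] = -kT * np.log(p[mask])
    out[mask] -= np.nanmin(out[mask])
    return out


def pool_walkers(
    walkers: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate (values, weights) from independent walkers.

    Each walker's weights are renormalized to mean 1 before pooling, so every
    walker contributes in proportion to its frame count (pooling before
    histogramming).
    """
    vals, wts = [], []
    for v, w in walkers:
        v = np.asarray(v, float)
        w = np.asarray(w, float)
        vals.append(v)
        wts.append(w / np.mean(w))
    return np.concatenate(vals), np.concatenate(wts)


def reweight_series(
    frame_times: np.ndarray,
    cv_values: np.ndarray,
    bias_at_frame: np.ndarray,
    hills: list[HillRecord],
    bias_factor: float,
    kT: float,
    grid: np.ndarray,
    bins: int | np.ndarray = 100,
    range: tuple[float, float] | None = None,
    discard_initial: float = 0.1,
) -> tuple[WeightedDistribution, np.ndarray, np.ndarray]:
    """Full reweighting pipeline for one biased series.

    Estimates c(t) on ``grid``, computes frame weights, discards the initial
    ``discard_initial`` fraction of frames (the filling transient, whose
    weights are the noisiest) and histograms the CV.  Returns
    ``(distribution, weights, fes)``; the returned weights cover the kept
    frames only.
    """
    times, ct = estimate_ct(hills, grid, bias_factor, kT)
    w = frame_weights(frame_times, bias_at_frame, times, ct, kT)
    n0 = int(discard_initial * len(w))
    w = w[n0:] / np.mean(w[n0:])
    dist = weighted_distribution(np.asarray(cv_values, float)[n0:], w,
                                 bins=bins, range=range)
    return dist, w, fes(dist, kT)


def fes_block_bootstrap(
    cv_values: np.ndarray,
    weights: np.ndarray,
    kT: float,
    bins: int | np.ndarray = 100,
    range: tuple[float, float] | None = None,
    n_blocks: int = 20,
    n_boot: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-bin standard error of the FES by circular block bootstrap.

    Frames are split into ``n_blocks`` contiguous blocks (preserving the
    serial correlation of the underlying trajectory); blocks are resampled
    with replacement ``n_boot`` times.  Bins that are empty in some
    replicate get NaN.
    """
    rng = np.random.default_rng(seed)
    cv_values = np.asarray(cv_values, float)
    weights = np.asarray(weights, float)
    idx_blocks = np.array_split(np.arange(len(cv_values)), n_blocks)
    fess = []
    for _ in np.arange(n_boot):
        pick = rng.integers(0, n_blocks, size=n_blocks)
        idx = np.concatenate([idx_blocks[b] for b in pick])
        dist = weighted_distribution(cv_values[idx], weights[idx],
                                     bins=bins, range=range)
        fess.append(fes(dist, kT))
    return np.nanstd(np.array(fess), axis=0)


def convergence_drift(
    series: np.ndarray, fraction: float = 0.10, n_blocks: int = 10
) -> tuple[float, float]:
    """Drift of a CV over the last ``fraction`` of a run.

    Returns ``(drift, block_se)`` where drift is |mean over the last window -
    mean over the preceding equal-length window| and ``block_se`` is the
    combined block standard error of the two window means.
    """
    series = np.asarray(series, float)
    n = len(series)
    nw = int(n * fraction)
    if nw < n_blocks or n < 2 * nw:
        raise ValueError("series too short for two windows of the given fraction")
    w2 = series[n - nw:]
    w1 = series[n - 2 * nw: n - nw]

    def block_se(x):
        blocks = np.array_split(x, n_blocks)
        means = np.array([b.mean() for b in blocks])
        return float(np.std(means, ddof=1) / np.sqrt(n_blocks))

    drift = abs(float(w2.mean()) - float(w1.mean()))
    se = float(np.hypot(block_se(w1), block_se(w2)))
    return drift, se


# ---------------------------------------------------------------------------
# PLUMED-style whitespace text I/O
# ---------------------------------------------------------------------------


def _read_plumed(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#!"):
        raise ValueError(f"{path}: missing '#! FIELDS' header")
    fields = first.split()[2:]
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.size and data.shape[1] != len(fields):
        raise ValueError(f"{path}: {data.shape[1]} columns but {len(fields)} fields")
    return pd.DataFrame(data, columns=fields)


def read_colvar(path: str | Path) -> pd.DataFrame:
    """Read a COLVAR-style file: '#! FIELDS time cv... bias' then columns."""
    df = _read_plumed(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: no 'time' field")
    return df


def write_colvar(path: str | Path, df: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(df.columns) + "\n")
        np.savetxt(fh, df.to_numpy(), fmt="%12.6f")


def read_hills(path: str | Path) -> list[HillRecord]:
    """Read a HILLS-style file (fields time, center, sigma_*, height, ...)."""
    df = _read_plumed(path)
    cols = list(df.columns)
    sigma_col = next((c for c in cols if c.startswith("sigma")), None)
    if sigma_col is None or "height" not in cols or "time" not in cols:
        raise ValueError(f"{path}: need time, sigma_*, height fields")
    center_col = next(
        c for c in cols if c not in ("time", "height", "biasf") and not c.startswith("sigma")
    )
    return [
        HillRecord(time=float(r["time"]), center=float(r[center_col]),
                   width=float(r[sigma_col]), height=float(r["height"]))
        for _, r in df.iterrows()
    ]


def write_hills(path: str | Path, hills: list[HillRecord], cv_name: str = "s",
                bias_factor: float | None = None) -> None:
    cols = ["time", cv_name, f"sigma_{cv_name}", "height"]
    if bias_factor is not None:
        cols.append("biasf")
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(cols) + "\n")
        for h in hills:
            row = [h.time, h.center, h.width, h.height]
            if bias_factor is not None:
                row.append(bias_factor)
            fh.write(" ".join(f"{x:14.8f}" for x in row) + "\n")
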