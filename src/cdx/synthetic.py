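"""Synthetic fixture generators.

Everything the analysis modules consume can be generated here with planted,
recoverable structure: ideal alpha-helices, stylized seven-unit
pseudo-cyclodextrins, slab trajectories with prescribed density and
orientation statistics, RMSD-controlled conformational perturbations, and a
one-dimensional double-well sampled with well-tempered metadynamics whose
unbiased Boltzmann distribution is known analytically.

All generators are pure functions of their arguments and the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .trajio import (
    AtomRecord,
    Frame,
    Topology,
    Trajectory,
    assign_roles,
)
from .reweight import HillRecord, MetaDParams

__all__ = [
    "ProfileSpec",
    "OrientationSpec",
    "ToyRun",
    "make_ideal_helix",
    "make_extended_chain",
    "make_cd_molecule",
    "make_slab_trajectory",
    "make_hydration_fixture",
    "perturb_to_rmsd",
    "sample_metad_double_well",
]

# Ideal alpha-helix backbone parametrisation: 100 deg twist and 0.15 nm rise
# per residue; backbone atoms ride helices of slightly different radii and
# fractional-residue phase so the geometry is smooth and self-consistent.
HELIX_TWIST_DEG = 100.0
HELIX_RISE_NM = 0.15
_HELIX_ATOMS = (  # (name, radius nm, fractional residue offset)
    ("N", 0.155, -0.33),
    ("CA", 0.230, 0.0),
    ("C", 0.160, 0.33),
    ("O", 0.300, 0.40),
)

CD_RING_RADIUS = 0.5  # nm, stylized pseudo-cyclodextrin
CD_RIM_OFFSET = 0.2  # nm along the cavity axis


def _helix_backbone(n_res: int) -> tuple[list[tuple[str, int]], np.ndarray]:
    omega = math.radians(HELIX_TWIST_DEG)
    names, coords = [], []
    for i in range(n_res):
        for name, radius, off in _HELIX_ATOMS:
            t = i + off
            coords.append(
                (radius * math.cos(omega * t), radius * math.sin(omega * t),
                 HELIX_RISE_NM * t)
            )
            names.append((name, i + 1))
    return names, np.asarray(coords)


def _structure_from(names_resids, coords, resname_of, box_margin=1.0):
    coords = np.asarray(coords, dtype=float)
    shift = 1.0 - coords.min(axis=0)
    coords = coords + shift
    box = coords.max(axis=0) + box_margin
    atoms = [
        AtomRecord(
            name=nm, resname=resname_of(rid), resid=rid, molid=1,
            element="N" if nm.startswith("N") else ("O" if nm.startswith("O") else "C"),
            mass=14.007 if nm.startswith("N") else (15.999 if nm.startswith("O") else 12.011),
        )
        for nm, rid in names_resids
    ]
    top = assign_roles(Topology(atoms))
    return top, Frame(coords=coords, box=box, time=0.0)


def make_ideal_helix(n_res: int, seed: int | None = None):
    """Backbone (N, CA, C, O) of an ideal alpha-helix of ``n_res`` residues.

    The helix axis lies along z; consecutive CA atoms are related by a 100
    degree twist and a 0.15 nm rise.  Requires ``n_res >= 6`` (the shortest
    helical segment the alpha-content CV can score).
    """
    if n_res < 6:
        raise ValueError("an alpha-helical segment needs at least 6 residues")
    names, coords = _helix_backbone(n_res)
    return _structure_from(names, coords, lambda rid: "ALA")


def make_extended_chain(n_res: int, spacing: float = 0.38):
    """Fully extended backbone: all CA collinear at ``spacing`` nm intervals."""
    names, coords = [], []
    for i in range(n_res):
        x = spacing * i
        for name, dx, dy in (("N", -0.12, 0.05), ("CA", 0.0, 0.0),
                             ("C", 0.12, -0.05), ("O", 0.15, -0.17)):
            names.append((name, i + 1))
            coords.append((x + dx, dy, 0.0))
    return _structure_from(names, coords, lambda rid: "GLY")


def _orthonormal_frame(axis: np.ndarray):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2, axis


def _cd_coords(center: np.ndarray, axis: np.ndarray) -> tuple[list[tuple[str, int]], np.ndarray]:
    """7 glucose pseudo-units on a ring; C6 on the primary rim (-axis side),
    C2/C3 on the secondary rim (+axis side), C1 anchoring the ring plane."""
    e1, e2, ez = _orthonormal_frame(axis)
    center = np.asarray(center, float)
    names, coords = [], []
    for k in range(7):
        phi = 2.0 * math.pi * k / 7.0

        def ring_point(dphi=0.0):
            a = phi + dphi
            return center + CD_RING_RADIUS * (math.cos(a) * e1 + math.sin(a) * e2)

        unit = [
            ("C1", ring_point()),
            ("C6", ring_point() - CD_RIM_OFFSET * ez),
            ("C2", ring_point(0.1) + CD_RIM_OFFSET * ez),
            ("C3", ring_point(-0.1) + CD_RIM_OFFSET * ez),
        ]
        for nm, xyz in unit:
            names.append((nm, k + 1))
            coords.append(xyz)
    return names, np.asarray(coords)


def make_cd_molecule(center=(0.0, 0.0, 0.0), axis_unit_vector=(0.0, 0.0, 1.0)):
    """A stylized seven-unit cyclodextrin: ring radius 0.5 nm, primary rim
    offset -0.2 nm and secondary rim +0.2 nm along the cavity axis."""
    axis = np.asarray(axis_unit_vector, float)
    if not math.isclose(float(np.linalg.norm(axis)), 1.0, rel_tol=1e-6):
        raise ValueError("axis_unit_vector must be normalized")
    names, coords = _cd_coords(np.asarray(center, float), axis)
    # keep absolute placement: box big enough around the given center
    lo = coords.min(axis=0)
    shift = np.where(lo < 1.0, 1.0 - lo, 0.0)
    coords = coords + shift
    box = coords.max(axis=0) + 1.0
    atoms = [
        AtomRecord(name=nm, resname="GLC", resid=rid, molid=1, element="C", mass=12.011)
        for nm, rid in names
    ]
    top = assign_roles(Topology(atoms))
    return top, Frame(coords=coords, box=box, time=0.0)


# ---------------------------------------------------------------------------
# Slab trajectories with planted structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProfileSpec:
    """Planted z-distribution of cyclodextrin centres in the liquid slab."""

    kind: str = "uniform"  # uniform | surface_peaked | bulk_only
    peak_z: float = 4.5
    peak_width: float = 0.3
    n_molecules: int = 11

    def __post_init__(self):
        if self.kind not in ("uniform", "surface_peaked", "bulk_only"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be > 0")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")


@dataclass(frozen=True)
class OrientationSpec:
    """Planted distribution of cos(theta) between the cavity axis and +z.

    ``isotropic`` draws axes uniformly on the sphere; ``fixed`` uses the
    given axis for every molecule; ``tilted`` draws cos(theta) from the
    exponentially tilted density p(c) ~ exp(lambda*c) on [-1, 1] with
    lambda solved so that <cos theta> equals ``mean_cos_theta``.
    """

    kind: str = "isotropic"  # isotropic | fixed | tilted
    mean_cos_theta: float = 0.0
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if self.kind not in ("isotropic", "fixed", "tilted"):
            raise ValueError(f"unknown orientation kind {self.kind!r}")
        if self.kind == "tilted" and not -0.995 < self.mean_cos_theta < 0.995:
            raise ValueError("tilted mean_cos_theta must lie in (-0.995, 0.995)")


def _tilt_lambda(mean: float) -> float:
    if abs(mean) < 1e-12:
        return 0.0

    def langevin(lam):
        return 1.0 / math.tanh(lam) - 1.0 / lam - mean

    lo, hi = (1e-8, 500.0) if mean > 0 else (-500.0, -1e-8)
    return brentq(langevin, lo, hi)


def _sample_cos_theta(spec: OrientationSpec, n: int, rng: np.random.Generator):
    if spec.kind == "isotropic":
        return rng.uniform(-1.0, 1.0, size=n)
    if spec.kind == "fixed":
        c = np.asarray(spec.axis, float)
        return np.full(n, c[2] / np.linalg.norm(c))
    lam = _tilt_lambda(spec.mean_cos_theta)
    if lam == 0.0:
        return rng.uniform(-1.0, 1.0, size=n)
    u = rng.uniform(0.0, 1.0, size=n)
    return np.log(np.exp(-lam) + u * (np.exp(lam) - np.exp(-lam))) / lam


def make_slab_trajectory(
    n_frames: int,
    profile_spec: ProfileSpec,
    orientation_spec: OrientationSpec | None = None,
    box=(6.0, 6.0, 10.0),
    seed: int = 0,
    *,
    liquid_depth: float = 5.0,
    n_water: int = 1500,
    ice_depth: float = 0.0,
    margin: float = 0.3,
) -> Trajectory:
    """Slab trajectory with planted density and orientation structure.

    The liquid occupies ``z in [ice_depth, ice_depth + liquid_depth]``; the
    region above is vacuum.  ``n_water`` single-site water pseudo-molecules
    are redrawn uniformly in the liquid each frame; cyclodextrin centres are
    drawn i.i.d. per frame from the profile spec and their cavity axes from
    the orientation spec.  If ``ice_depth > 0`` a frozen regular grid of
    water sites filling ``z in [0, ice_depth]`` is added and tagged frozen.
    Deterministic under ``seed``.
    """
    if orientation_spec is None:
        orientation_spec = OrientationSpec()
    box = np.asarray(box, float)
    z_lo = ice_depth
    z_hi = ice_depth + liquid_depth
    if z_hi + 1.0 > box[2]:
        raise ValueError("box z too small for liquid depth plus vacuum")
    if profile_spec.kind == "surface_peaked" and not (
        z_lo + margin < profile_spec.peak_z < z_hi
    ):
        raise ValueError("surface peak lies outside the liquid region")
    if profile_spec.kind == "bulk_only" and z_hi - 1.0 - margin <= z_lo + margin:
        raise ValueError("liquid region too shallow for a bulk-only spec")

    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    resid = 0
    # frozen ice grid (constant over frames)
    ice_coords = None
    if ice_depth > 0:
        nx = max(2, int(box[0] / 0.3))
        nz = max(1, int(ice_depth / 0.3))
        gx = (np.arange(nx) + 0.5) * box[0] / nx
        gy = (np.arange(nx) + 0.5) * box[1] / nx
        gz = (np.arange(nz) + 0.5) * ice_depth / nz
        ice_coords = np.array(np.meshgrid(gx, gy, gz)).reshape(3, -1).T
        for _ in range(len(ice_coords)):
            resid += 1
            atoms.append(AtomRecord("OW", "ICE", resid, 0, "O", 18.015))
    for _ in range(n_water):
        resid += 1
        atoms.append(AtomRecord("OW", "SOL", resid, 0, "O", 18.015))
    n_cd = profile_spec.n_molecules
    cd_names, _ = _cd_coords(np.zeros(3), np.array([0.0, 0.0, 1.0]))
    for _ in range(n_cd):
        for nm, rid in cd_names:
            atoms.append(AtomRecord(nm, "GLC", resid + rid, 0, "C", 12.011))
        resid += 7

    top = assign_roles(Topology(atoms))
    if ice_coords is not None:
        frozen = np.zeros(top.n_atoms, dtype=bool)
        frozen[: len(ice_coords)] = True
        top = Topology(top.atoms, top.roles, frozen=frozen)

    def draw_z(n):
        if profile_spec.kind == "uniform":
            return rng.uniform(z_lo + margin, z_hi - margin, size=n)
        if profile_spec.kind == "bulk_only":
            return rng.uniform(z_lo + margin, z_hi - 1.0, size=n)
        z = rng.normal(profile_spec.peak_z, profile_spec.peak_width, size=n)
        for _ in range(100):
            bad = (z < z_lo + margin) | (z > z_hi - 1e-9)
            if not bad.any():
                break
            z[bad] = rng.normal(profile_spec.peak_z, profile_spec.peak_width,
                                size=int(bad.sum()))
        return np.clip(z, z_lo + margin, z_hi - 1e-9)

    frames = []
    n_ice = 0 if ice_coords is None else len(ice_coords)
    for fi in range(n_frames):
        coords = np.empty((top.n_atoms, 3))
        if ice_coords is not None:
            coords[:n_ice] = ice_coords
        w = n_ice
        coords[w:w + n_water, 0] = rng.uniform(0, box[0], size=n_water)
        coords[w:w + n_water, 1] = rng.uniform(0, box[1], size=n_water)
        coords[w:w + n_water, 2] = rng.uniform(z_lo, z_hi, size=n_water)
        w += n_water
        zc = draw_z(n_cd)
        cos_t = _sample_cos_theta(orientation_spec, n_cd, rng)
        phi = rng.uniform(0, 2 * math.pi, size=n_cd)
        for m in range(n_cd):
            center = np.array(
                [rng.uniform(0, box[0]), rng.uniform(0, box[1]), zc[m]]
            )
            st = math.sqrt(max(0.0, 1.0 - cos_t[m] ** 2))
            axis = np.array(
                [st * math.cos(phi[m]), st * math.sin(phi[m]), cos_t[m]]
            )
            _, xyz = _cd_coords(center, axis)
            coords[w:w + 28] = xyz
            w += 28
        frames.append(Frame(coords=coords, box=box.copy(), time=float(fi)))
    return Trajectory(top, frames)


def make_hydration_fixture(
    n_frames: int = 40,
    enrichment: float = 1.0,
    seed: int = 0,
    *,
    n_cd: int = 150,
    n_water: int = 4000,
    box=(8.0, 8.0, 8.0),
    shell_width: float = 0.6,
    protein_radius: float = 1.2,
) -> Trajectory:
    """Protein sphere in a fully periodic box with waters and point CDs.

    Waters are uniform; CD sites are uniform but thinned so that the shell
    (within ``shell_width`` of the protein surface) is ``enrichment`` times
    more likely to keep a CD than the bulk, planting a hydration-layer
    partition coefficient K = ``enrichment``.  CDs here are single-site
    pseudo-molecules (density statistics only, no cavity geometry).
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(box, float)
    center = box / 2.0
    # protein: shell of CA-like sites on a sphere
    n_prot = 80
    u = rng.standard_normal((n_prot, 3))
    u /= np.linalg.norm(u, axis=1)[:, None]
    prot = center + protein_radius * u

    atoms: list[AtomRecord] = []
    for i in range(n_prot):
        atoms.append(AtomRecord("CA", "ALA", i + 1, 0, "C", 12.011))
    for i in range(n_water):
        atoms.append(AtomRecord("OW", "SOL", n_prot + i + 1, 0, "O", 18.015))
    for i in range(n_cd):
        # a single-site stand-in molecule; role stays 'other', grouped by resid
        atoms.append(AtomRecord("CX", "CDX", n_prot + n_water + i + 1, 0, "C", 12.011))
    top = assign_roles(Topology(atoms))

    def sample_sites(n, keep_ratio):
        pts = np.empty((0, 3))
        while len(pts) < n:
            cand = rng.uniform(0, 1, size=(4 * n, 3)) * box
            d = np.linalg.norm(cand - center, axis=1) - protein_radius
            in_shell = (d >= 0) & (d < shell_width)
            inside = d < 0
            keep = ~inside
            if keep_ratio != 1.0:
                p = np.where(in_shell, 1.0, 1.0 / keep_ratio)
                keep &= rng.uniform(size=len(cand)) < p
            pts = np.vstack([pts, cand[keep]])
        return pts[:n]

    frames = []
    for fi in range(n_frames):
        coords = np.empty((top.n_atoms, 3))
        coords[:n_prot] = prot
        coords[n_prot:n_prot + n_water] = sample_sites(n_water, 1.0)
        coords[n_prot + n_water:] = sample_sites(n_cd, enrichment)
        frames.append(
            Frame(coords=coords, box=box.copy(), time=float(fi),
                  periodic=(True, True, True))
        )
    return Trajectory(top, frames)


# ---------------------------------------------------------------------------
# RMSD-controlled perturbation
# ---------------------------------------------------------------------------


def perturb_to_rmsd(
    frame: Frame,
    target_rmsd: float,
    seed: int = 0,
    atom_indices: np.ndarray | None = None,
) -> Frame:
    """Displace coordinates by centred isotropic Gaussian noise rescaled so
    the coordinate RMSD to the input equals ``target_rmsd`` exactly.

    With ``atom_indices`` only that subset is displaced (and the RMSD is
    controlled over that subset), which plants localized unstable patches.
    """
    if target_rmsd < 0:
        raise ValueError("target_rmsd must be >= 0")
    coords = frame.coords.copy()
    if target_rmsd == 0:
        return Frame(coords=coords, box=frame.box.copy(), time=frame.time,
                     periodic=frame.periodic)
    idx = np.arange(len(coords)) if atom_indices is None else np.asarray(atom_indices)
    rng = np.random.default_rng(seed)
    delta = rng.standard_normal((len(idx), 3))
    delta -= delta.mean(axis=0)
    scale = target_rmsd / math.sqrt(float(np.mean(np.sum(delta**2, axis=1))))
    coords[idx] = coords[idx] + scale * delta
    return Frame(coords=coords, box=frame.box.copy(), time=frame.time,
                 periodic=frame.periodic)


# ---------------------------------------------------------------------------
# Toy well-tempered metadynamics on a double well
# ---------------------------------------------------------------------------


@dataclass
class ToyRun:
    """Record of a 1-D overdamped-Langevin well-tempered metadynamics run.

    ``positions``/``times``/``bias`` are per recorded frame (``bias`` is the
    instantaneous total bias V(s_t, t) in kJ/mol, the quantity a COLVAR file
    carries); ``hills`` are the deposited Gaussians with already-tempered
    heights; ``bias_snapshots`` holds V on ``grid`` after each deposition.
    """

    times: np.ndarray
    positions: np.ndarray
    bias: np.ndarray
    hills: list[HillRecord]
    grid: np.ndarray
    bias_snapshots: np.ndarray | None
    params: MetaDParams
    barrier_height: float
    dt: float
    friction: float

    def potential(self, s):
        return self.barrier_height * (np.asarray(s) ** 2 - 1.0) ** 2


def _metad_core():
    """Build (and cache) the JIT-compiled Langevin/metadynamics stepper."""
    import numba

    @numba.njit(cache=False)
    def run(seed, n_steps, dt, diffusion, kT, k4, hill_stride, h0, sigma,
            delta_kT, grid, record_stride, wt):
        np.random.seed(seed)
        ng = grid.shape[0]
        g0 = grid[0]
        dg = grid[1] - grid[0]
        v_grid = np.zeros(ng)
        f_grid = np.zeros(ng)  # bias force -dV/ds on grid
        n_hills = n_steps // hill_stride
        hills = np.zeros((n_hills, 3))  # time, center, height
        snapshots = np.zeros((n_hills, ng))
        n_rec = n_steps // record_stride
        rec_s = np.zeros(n_rec)
        rec_v = np.zeros(n_rec)
        rec_t = np.zeros(n_rec)
        s = 1.0
        pref = diffusion / kT * dt
        noise_amp = math.sqrt(2.0 * diffusion * dt)
        inv4dd = 1.0 / (4.0 * diffusion * dt)
        hi = 0
        ri = 0

        def interp(arr, x):
            y = (x - g0) / dg
            i0 = int(y)
            if i0 < 0:
                i0 = 0
            if i0 > ng - 2:
                i0 = ng - 2
            w = y - i0
            return arr[i0] * (1.0 - w) + arr[i0 + 1] * w

        # energy/force at the current point (bias interpolated from the grid)
        vs = interp(v_grid, s)
        es = k4 * (s * s - 1.0) ** 2 + vs
        fs = -4.0 * k4 * s * (s * s - 1.0) + interp(f_grid, s)
        for step in range(1, n_steps + 1):
            # Metropolis-adjusted Langevin proposal: the invariant
            # distribution is exactly exp(-(U+V)/kT) for the frozen bias
            sp = s + pref * fs + noise_amp * np.random.standard_normal()
            if not math.isfinite(sp):
                return (rec_t, rec_s, rec_v, hills, snapshots, hi, ri, 1)
            if grid[0] <= sp <= grid[ng - 1]:
                vp = interp(v_grid, sp)
                ep = k4 * (sp * sp - 1.0) ** 2 + vp
                fp = -4.0 * k4 * sp * (sp * sp - 1.0) + interp(f_grid, sp)
                log_a = -(ep - es) / kT - (
                    (s - sp - pref * fp) ** 2 - (sp - s - pref * fs) ** 2
                ) * inv4dd
                if log_a >= 0.0 or math.log(np.random.random()) < log_a:
                    s, es, fs, vs = sp, ep, fp, vp
            if step % hill_stride == 0 and hi < n_hills:
                if wt:
                    h = h0 * math.exp(-vs / delta_kT)
                else:
                    h = h0
                for j in range(ng):
                    d = grid[j] - s
                    g = h * math.exp(-d * d / (2.0 * sigma * sigma))
                    v_grid[j] += g
                    f_grid[j] += g * d / (sigma * sigma)
                hills[hi, 0] = step * dt
                hills[hi, 1] = s
                hills[hi, 2] = h
                snapshots[hi] = v_grid
                hi += 1
                # refresh the cached state: the bias just changed under us
                vs = interp(v_grid, s)
                es = k4 * (s * s - 1.0) ** 2 + vs
                fs = -4.0 * k4 * s * (s * s - 1.0) + interp(f_grid, s)
            if step % record_stride == 0 and ri < n_rec:
                rec_t[ri] = step * dt
                rec_s[ri] = s
                rec_v[ri] = vs
                ri += 1
        return (rec_t, rec_s, rec_v, hills, snapshots, hi, ri, 0)

    return run


_METAD_CORE = None


def sample_metad_double_well(
    params: MetaDParams,
    n_steps: int = 100_000,
    seed: int = 0,
    *,
    barrier_height: float = 8.0,
    dt: float = 0.01,
    friction: float = 0.5,
    hill_width: float = 0.15,
    grid=(-2.5, 2.5, 501),
    record_stride: int = 1,
) -> ToyRun:
    """Overdamped Langevin on U(s) = k (s^2 - 1)^2 with well-tempered hills.

    Gaussians of width ``hill_width`` are deposited at ``params.deposition_rate``
    with heights ``h0 * exp(-V/( (gamma-1) kT ))``; the accumulated bias and
    its force act on the walker.  Proposals are Metropolis-adjusted
    (MALA), so the invariant distribution between depositions is exactly
    ``exp(-(U+V)/kT)`` with no time-step discretization bias; with
    ``initial_height = 0`` the run samples the Boltzmann distribution of U.

    ``dt`` is in ps; ``friction`` sets the diffusion constant D = kT/friction
    (the default is small enough that a 1e5-step run crosses the barrier
    many times and converges).  Positions are recorded every
    ``record_stride`` steps.  Deterministic under ``seed``.
    """
    global _METAD_CORE
    if params.kT <= 0:
        raise ValueError("kT must be > 0")
    diffusion = params.kT / friction
    # MALA is exact for any step, but proposals far beyond the well curvature
    # scale are rejected almost surely and the walker effectively freezes
    if dt * diffusion / params.kT * 8.0 * barrier_height >= 5.0:
        raise ValueError("divergent step size: reduce dt or increase friction")
    grid_arr = np.linspace(grid[0], grid[1], int(grid[2]))
    hill_stride = max(1, int(round(1.0 / (params.deposition_rate * dt))))
    if _METAD_CORE is None:
        _METAD_CORE = _metad_core()
    wt = params.initial_height > 0
    delta_kT = (params.bias_factor - 1.0) * params.kT
    rec_t, rec_s, rec_v, hills_arr, snaps, n_hills, n_rec, err = _METAD_CORE(
        int(seed) % (2**31), int(n_steps), float(dt), float(diffusion),
        float(params.kT), float(barrier_height), int(hill_stride),
        float(params.initial_height), float(hill_width), float(delta_kT),
        grid_arr, int(record_stride), wt,
    )
    if err:
        raise RuntimeError("trajectory diverged (non-finite position)")
    hills = [
        HillRecord(time=float(t), center=float(c), width=float(hill_width),
                   height=float(h))
        for t, c, h in hills_arr[:n_hills]
        if h > 0
    ]
    return ToyRun(
        times=rec_t[:n_rec],
        positions=rec_s[:n_rec],
        bias=rec_v[:n_rec],
        hills=hills,
        grid=grid_arr,
        bias_snapshots=snaps[:n_hills] if wt else None,
        params=params,
        barrier_height=barrier_height,
        dt=dt,
        friction=friction,
    )
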