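"""Structures, trajectories, molecular roles and periodic geometry.

All coordinates are stored in nm, times in ps, masses in amu.  File I/O
(PDB, GRO, XTC, DCD, multi-model PDB) is delegated to MDAnalysis; this
module converts between MDAnalysis universes and the lightweight
containers (:class:`Topology`, :class:`Frame`, :class:`Trajectory`) the
analysis modules operate on.

Slab convention: the interface normal is +z and z is treated as
non-periodic in all interface analyses (the default
``Frame.periodic = (True, True, False)``), because the vacuum or ice
slab breaks the symmetry along z.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

ROLE_TAGS = frozenset(
    {
        "protein_backbone_N",
        "protein_backbone_CA",
        "protein_backbone_C",
        "cd_primary_rim",
        "cd_secondary_rim",
        "water",
        "other",
    }
)

#: Default naming scheme: CHARMM-style cyclodextrin glucose residues with a
#: primary rim of C6 atoms and a secondary rim of C2/C3 atoms, standard
#: amino-acid and water residue names.  Override via a YAML mapping with
#: the same keys.
DEFAULT_NAMING_SCHEME: dict[str, list[str]] = {
    "cd_resnames": ["GLC", "BGC", "BGLC", "AGLC", "HPG", "MGL"],
    "primary_rim_atoms": ["C6"],
    "secondary_rim_atoms": ["C2", "C3"],
    "water_resnames": ["SOL", "HOH", "TIP3", "TIP", "WAT", "SPC", "ICE"],
    "protein_resnames": [
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
        "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
        "TYR", "VAL", "HSD", "HSE", "HSP",
    ],
}

GLUCOSE_UNITS_PER_CD = 7  # beta-cyclodextrin: seven alpha-glucopyranose units

_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "X": 0.0,
}


class ParseError(ValueError):
    """A structure or trajectory file could not be parsed."""


class StructureError(ValueError):
    """A topology violates a structural invariant (e.g. a CD without 7 units)."""


def _guess_element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            up = ch.upper()
            # two-letter common cases are not needed for these systems
            return up if up in _ELEMENT_MASSES else "C"
    return "X"


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus the molecule it belongs to."""

    name: str
    resname: str
    resid: int  # 1-based
    molid: int
    element: str
    mass: float

    def __post_init__(self):
        if self.resid < 1:
            raise ValueError(f"resid must be >= 1, got {self.resid}")
        if self.mass <= 0:
            raise ValueError(f"mass must be > 0, got {self.mass}")


class Topology:
    """Ordered atom list plus per-atom role tags and an optional frozen mask.

    Roles are drawn from :data:`ROLE_TAGS`; they are mutually exclusive per
    atom.  The frozen mask marks atoms held fixed in the simulation (an ice
    slab); it is set explicitly, never inferred.
    """

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        roles: Sequence[str] | None = None,
        frozen: np.ndarray | None = None,
    ):
        self.atoms: list[AtomRecord] = list(atoms)
        n = len(self.atoms)
        if roles is None:
            roles = ["other"] * n
        roles = np.asarray(roles, dtype=object)
        if roles.shape != (n,):
            raise ValueError("one role per atom required")
        bad = set(roles) - ROLE_TAGS
        if bad:
            raise ValueError(f"unknown role tags: {sorted(bad)}")
        self.roles = roles
        if frozen is None:
            frozen = np.zeros(n, dtype=bool)
        self.frozen = np.asarray(frozen, dtype=bool)
        if self.frozen.shape != (n,):
            raise ValueError("frozen mask length mismatch")
        self._cache: dict[str, np.ndarray] = {}

    # -- array views ---------------------------------------------------
    def _arr(self, key: str, getter, dtype) -> np.ndarray:
        if key not in self._cache:
            self._cache[key] = np.array([getter(a) for a in self.atoms], dtype=dtype)
        return self._cache[key]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def names(self) -> np.ndarray:
        return self._arr("names", lambda a: a.name, object)

    @property
    def resnames(self) -> np.ndarray:
        return self._arr("resnames", lambda a: a.resname, object)

    @property
    def resids(self) -> np.ndarray:
        return self._arr("resids", lambda a: a.resid, np.int64)

    @property
    def molids(self) -> np.ndarray:
        return self._arr("molids", lambda a: a.molid, np.int64)

    @property
    def masses(self) -> np.ndarray:
        return self._arr("masses", lambda a: a.mass, np.float64)

    @property
    def elements(self) -> np.ndarray:
        return self._arr("elements", lambda a: a.element, object)

    # -- selections ----------------------------------------------------
    def indices_with_role(self, role: str) -> np.ndarray:
        if role not in ROLE_TAGS:
            raise ValueError(f"unknown role {role!r}")
        return np.flatnonzero(self.roles == role)

    @property
    def protein_indices(self) -> np.ndarray:
        scheme = DEFAULT_NAMING_SCHEME
        mask = np.isin(self.resnames, scheme["protein_resnames"])
        return np.flatnonzero(mask)

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.flatnonzero(self.elements != "H")

    @property
    def water_indices(self) -> np.ndarray:
        return self.indices_with_role("water")

    def backbone_indices(self, kinds: Iterable[str] = ("N", "CA", "C")) -> np.ndarray:
        tags = [f"protein_backbone_{k}" for k in kinds]
        return np.flatnonzero(np.isin(self.roles, tags))

    def molecules(self, indices: np.ndarray | None = None) -> list[np.ndarray]:
        """Atom-index arrays grouped by molecule id, in order of appearance."""
        molids = self.molids
        if indices is not None:
            molids = molids[indices]
        order: dict[int, list[int]] = {}
        src = indices if indices is not None else np.arange(self.n_atoms)
        for i, m in zip(src, molids):
            order.setdefault(int(m), []).append(int(i))
        return [np.array(v, dtype=np.int64) for v in order.values()]

    def cd_molecules(self) -> list[np.ndarray]:
        """Atom-index arrays of molecules carrying cyclodextrin rim roles."""
        rim = set(
            np.concatenate(
                [self.indices_with_role("cd_primary_rim"),
                 self.indices_with_role("cd_secondary_rim")]
            ).tolist()
        )
        out = []
        for mol in self.molecules():
            if rim.intersection(mol.tolist()):
                out.append(mol)
        return out

    def protein_residues(self) -> list[tuple[int, np.ndarray]]:
        """(resid, atom indices) for each protein residue, in order."""
        prot = self.protein_indices
        resids = self.resids
        out: dict[int, list[int]] = {}
        for i in prot:
            out.setdefault(int(resids[i]), []).append(int(i))
        return [(r, np.array(v, dtype=np.int64)) for r, v in out.items()]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Topology)
            and self.atoms == other.atoms
            and list(self.roles) == list(other.roles)
            and np.array_equal(self.frozen, other.frozen)
        )


@dataclass
class Frame:
    """Coordinates (nm), orthorhombic box lengths (nm), time (ps)."""

    coords: np.ndarray
    box: np.ndarray
    time: float = 0.0
    periodic: tuple[bool, bool, bool] = (True, True, False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")


@dataclass
class Trajectory:
    topology: Topology
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self):
        for f in self.frames:
            if f.coords.shape[0] != self.topology.n_atoms:
                raise ValueError("frame atom count does not match topology")
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)


# ---------------------------------------------------------------------------
# Role assignment
# ---------------------------------------------------------------------------

def load_naming_scheme(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        scheme = yaml.safe_load(fh)
    merged = dict(DEFAULT_NAMING_SCHEME)
    merged.update(scheme or {})
    return merged


def assign_roles(topology: Topology, naming_scheme: dict | None = None) -> Topology:
    """Tag every atom with a role and regroup molecule ids.

    Residues are classified by residue name (cyclodextrin glucose, protein,
    water, other).  Contiguous runs of CD glucose residues are grouped into
    molecules of exactly seven units (anything else is a
    :class:`StructureError`); contiguous protein residues form one molecule;
    every other residue is its own molecule.  Untaggable atoms inside CD or
    protein residues are tagged ``other`` with a logged warning.

    Idempotent: re-assigning roles on the result is a no-op.
    """
    scheme = dict(DEFAULT_NAMING_SCHEME)
    if naming_scheme:
        scheme.update(naming_scheme)

    # residues in order of appearance: (resid, resname, atom indices)
    residues: list[tuple[int, str, list[int]]] = []
    last_key = None
    for i, a in enumerate(topology.atoms):
        key = (a.resid, a.resname)
        if key != last_key:
            residues.append((a.resid, a.resname, []))
            last_key = key
        residues[-1][2].append(i)

    def classify(resname: str) -> str:
        if resname in scheme["cd_resnames"]:
            return "cd"
        if resname in scheme["protein_resnames"]:
            return "protein"
        if resname in scheme["water_resnames"]:
            return "water"
        return "other"

    kinds = [classify(rn) for _, rn, _ in residues]

    n = topology.n_atoms
    roles = np.array(["other"] * n, dtype=object)
    molids = np.zeros(n, dtype=np.int64)
    next_mol = 1
    n_untagged = 0

    i = 0
    while i < len(residues):
        kind = kinds[i]
        if kind == "cd":
            j = i
            while j < len(residues) and kinds[j] == "cd":
                j += 1
            run = residues[i:j]
            if len(run) % GLUCOSE_UNITS_PER_CD != 0:
                raise StructureError(
                    f"run of {len(run)} CD glucose residues starting at resid "
                    f"{run[0][0]} is not a multiple of {GLUCOSE_UNITS_PER_CD}"
                )
            for k in range(0, len(run), GLUCOSE_UNITS_PER_CD):
                for _, _, atom_idx in run[k:k + GLUCOSE_UNITS_PER_CD]:
                    for ai in atom_idx:
                        molids[ai] = next_mol
                        name = topology.atoms[ai].name
                        if name in scheme["primary_rim_atoms"]:
                            roles[ai] = "cd_primary_rim"
                        elif name in scheme["secondary_rim_atoms"]:
                            roles[ai] = "cd_secondary_rim"
                next_mol += 1
            i = j
        elif kind == "protein":
            j = i
            while j < len(residues) and kinds[j] == "protein":
                j += 1
            for _, _, atom_idx in residues[i:j]:
                for ai in atom_idx:
                    molids[ai] = next_mol
                    name = topology.atoms[ai].name
                    if name in ("N", "CA", "C"):
                        roles[ai] = f"protein_backbone_{name}"
                    else:
                        n_untagged += name not in ("O", "H", "HA", "HN", "CB", "OXT")
            next_mol += 1
            i = j
        else:
            _, _, atom_idx = residues[i]
            for ai in atom_idx:
                molids[ai] = next_mol
                if kind == "water":
                    roles[ai] = "water"
            next_mol += 1
            i += 1

    if n_untagged:
        logger.warning("%d atoms could not be tagged and were marked 'other'", n_untagged)

    atoms = [replace(a, molid=int(m)) for a, m in zip(topology.atoms, molids)]
    out = Topology(atoms, roles, frozen=topology.frozen.copy())
    _check_cd_invariants(out)
    return out


def _check_cd_invariants(topology: Topology) -> None:
    for mol in topology.cd_molecules():
        n_prim = int(np.sum(topology.roles[mol] == "cd_primary_rim"))
        n_sec = int(np.sum(topology.roles[mol] == "cd_secondary_rim"))
        if n_prim != 7 or n_sec != 14:
            raise StructureError(
                f"CD molecule {int(topology.molids[mol[0]])} has {n_prim} primary "
                f"and {n_sec} secondary rim atoms (expected 7 and 14)"
            )


# ---------------------------------------------------------------------------
# Periodic geometry
# ---------------------------------------------------------------------------

def minimum_image_displacement(
    d: np.ndarray, box: np.ndarray, periodic: Sequence[bool] = (True, True, False)
) -> np.ndarray:
    """Wrap displacement vectors into the minimum image, per periodic axis."""
    d = np.array(d, dtype=np.float64, copy=True)
    box = np.asarray(box, dtype=np.float64)
    for ax in range(3):
        if periodic[ax]:
            d[..., ax] -= box[ax] * np.round(d[..., ax] / box[ax])
    return d


def minimum_image_distance(
    a: np.ndarray,
    b: np.ndarray,
    frame: Frame | None = None,
    *,
    box: np.ndarray | None = None,
    periodic: Sequence[bool] | None = None,
):
    """Minimum-image Euclidean distance honouring periodicity per axis.

    Geometry can be given either via ``frame`` or via explicit ``box`` and
    ``periodic``.  Broadcasts over leading dimensions of ``a`` and ``b``.
    """
    if frame is not None:
        box = frame.box
        periodic = frame.periodic if periodic is None else periodic
    if box is None:
        raise ValueError("either frame or box must be given")
    if periodic is None:
        periodic = (True, True, False)
    d = minimum_image_displacement(np.asarray(a, float) - np.asarray(b, float), box, periodic)
    return np.sqrt(np.sum(d * d, axis=-1))


def pairwise_min_image_distances(
    xa: np.ndarray, xb: np.ndarray, box: np.ndarray,
    periodic: Sequence[bool] = (True, True, False),
) -> np.ndarray:
    """(len(xa), len(xb)) matrix of minimum-image distances."""
    d = np.asarray(xa, float)[:, None, :] - np.asarray(xb, float)[None, :, :]
    d = minimum_image_displacement(d, box, periodic)
    return np.sqrt(np.sum(d * d, axis=-1))


# ---------------------------------------------------------------------------
# File I/O via MDAnalysis
# ---------------------------------------------------------------------------

def _mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def _universe_to_topology(u) -> Topology:
    atoms = []
    for atom in u.atoms:
        name = str(atom.name)
        elem = _guess_element(name)
        mass = float(getattr(atom, "mass", 0.0) or 0.0)
        if mass <= 0:
            mass = _ELEMENT_MASSES.get(elem, 12.011) or 12.011
        atoms.append(
            AtomRecord(
                name=name,
                resname=str(atom.resname),
                resid=int(atom.resid) if int(atom.resid) >= 1 else 1,
                molid=int(atom.resindex) + 1,
                element=elem,
                mass=mass,
            )
        )
    return Topology(atoms)


def _box_from_dimensions(dims, coords: np.ndarray) -> np.ndarray:
    if dims is not None and np.all(np.asarray(dims[:3]) > 0):
        return np.asarray(dims[:3], dtype=float) / 10.0
    # no box in file: bounding box plus a small margin
    span = coords.max(axis=0) - coords.min(axis=0)
    return np.maximum(span + 0.2, 1.0)


def read_structure(path: str | Path, format: str | None = None):
    """Read a PDB or GRO structure into ``(Topology, Frame)``.

    Coordinates are converted to nm (PDB files are in Angstrom).  Atom order
    is preserved.  Roles are *not* assigned; call :func:`assign_roles`.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("pdb", "gro"):
        raise ValueError(f"unknown structure format {fmt!r} (expected pdb or gro)")
    mda = _mda()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=fmt)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ParseError(f"failed to parse {path}: {exc}") from exc
    top = _universe_to_topology(u)
    coords = u.atoms.positions.astype(np.float64) / 10.0
    box = _box_from_dimensions(u.dimensions, coords)
    return top, Frame(coords=coords, box=box, time=0.0)


def read_trajectory(
    structure: str | Path,
    trajectory: str | Path | None = None,
    format: str | None = None,
) -> Trajectory:
    """Read a trajectory (XTC/DCD with a topology file, or multi-model PDB)."""
    mda = _mda()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if trajectory is None:
                u = mda.Universe(str(structure))
            else:
                u = mda.Universe(str(structure), str(trajectory), format=format)
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"failed to parse {structure}: {exc}") from exc
    top = _universe_to_topology(u)
    frames = []
    prev_t = -np.inf
    for i, ts in enumerate(u.trajectory):
        coords = u.atoms.positions.astype(np.float64) / 10.0
        box = _box_from_dimensions(ts.dimensions, coords)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = float(ts.time) if ts.time is not None else float(i)
        if t <= prev_t:  # writers without time stamps: fall back to frame index
            t = prev_t + 1.0
        prev_t = t
        frames.append(Frame(coords=coords, box=box, time=t))
    return Trajectory(top, frames)


def _topology_to_universe(topology: Topology, mda):
    n = topology.n_atoms
    # residues in order of appearance
    keys: list[tuple[int, str]] = []
    resindex = np.zeros(n, dtype=int)
    for i, a in enumerate(topology.atoms):
        key = (a.resid, a.resname)
        if not keys or keys[-1] != key:
            keys.append(key)
        resindex[i] = len(keys) - 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n, n_residues=len(keys), atom_resindex=resindex, trajectory=True
        )
        u.add_TopologyAttr("names", [a.name for a in topology.atoms])
        u.add_TopologyAttr("resnames", [rn for _, rn in keys])
        u.add_TopologyAttr("resids", [ri for ri, _ in keys])
        u.add_TopologyAttr("masses", topology.masses)
    return u


def write_structure(topology: Topology, frame: Frame, path: str | Path) -> None:
    """Write a GRO or PDB structure (format from the file suffix)."""
    mda = _mda()
    u = _topology_to_universe(topology, mda)
    u.atoms.positions = frame.coords * 10.0
    u.dimensions = [*(frame.box * 10.0), 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB trajectory (text-only fallback format)."""
    mda = _mda()
    u = _topology_to_universe(traj.topology, mda)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.topology.n_atoms, multiframe=True) as w:
            for fr in traj.frames:
                u.atoms.positions = fr.coords * 10.0
                u.dimensions = [*(fr.box * 10.0), 90.0, 90.0, 90.0]
                w.write(u.atoms)
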