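"""Structure and trajectory analytics for calyx binding pockets.

Covers PDB ingestion (multi-model files are treated as trajectory frames),
calyx opening distances, Kabsch superposition RMSD, windowed RMSF, the
tyrosine-gate minimum distance, hydrogen-bond occupancy and grid-based
cavity volumes split into upper/lower sub-pockets by the gate plane.

Coordinates are in Å throughout (the PDB native unit); residues are
identified by (chain, residue number, insertion code).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist

#: Bundled van der Waals radii (Å); unknown elements fall back to 1.7 Å.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_RADIUS = 1.70

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


def element_radius(element: str) -> float:
    el = element.strip().upper()
    if el not in VDW_RADII:
        warnings.warn(f"unknown element {element!r}; using default radius "
                      f"{DEFAULT_RADIUS} Å", stacklevel=2)
        return DEFAULT_RADIUS
    return VDW_RADII[el]


@dataclass
class Structure:
    """Atoms with coordinates and vdW radii; one or more models.

    ``coords`` has shape (n_models, n_atoms, 3); multi-model structures are
    trajectory frames sharing the same topology.
    """

    names: np.ndarray
    elements: np.ndarray
    resnames: np.ndarray
    resnums: np.ndarray
    chains: np.ndarray
    icodes: np.ndarray
    serials: np.ndarray
    coords: np.ndarray
    radii: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(self.radii <= 0):
            raise ValueError("all atoms need a positive radius")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @classmethod
    def from_arrays(cls, names, elements, resnames, resnums, coords,
                    chains=None, icodes=None, serials=None) -> "Structure":
        n = len(names)
        elements = np.asarray(elements, dtype=object)
        return cls(
            names=np.asarray(names, dtype=object),
            elements=elements,
            resnames=np.asarray(resnames, dtype=object),
            resnums=np.asarray(resnums, dtype=int),
            chains=np.asarray(chains if chains is not None else ["A"] * n,
                              dtype=object),
            icodes=np.asarray(icodes if icodes is not None else [""] * n,
                              dtype=object),
            serials=np.asarray(serials if serials is not None
                               else np.arange(1, n + 1), dtype=int),
            coords=np.asarray(coords, dtype=float),
            radii=np.array([element_radius(e) for e in elements]),
        )

    def atom_indices(self, *, name=None, resnum=None, resname=None,
                     chain=None, element=None) -> np.ndarray:
        """Indices of atoms matching all given criteria."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if name is not None:
            mask &= self.names == name
        if resnum is not None:
            mask &= self.resnums == resnum
        if resname is not None:
            mask &= self.resnames == resname
        if chain is not None:
            mask &= self.chains == chain
        if element is not None:
            mask &= np.char.upper(self.elements.astype(str)) == element.upper()
        return np.flatnonzero(mask)


def read_structure(path) -> Structure:
    """Read a (possibly multi-model) PDB file.

    Alternate locations are resolved to the highest occupancy; missing
    element columns are inferred from the atom name; unknown elements get
    the default radius with a warning.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None, altloc="occupancy")
    except Exception as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    elements = []
    for el, name in zip(stack.element, stack.atom_name):
        el = str(el).strip()
        if not el:
            el = "".join(c for c in str(name) if c.isalpha())[:1]
        elements.append(el)
    return Structure.from_arrays(
        names=stack.atom_name, elements=elements, resnames=stack.res_name,
        resnums=stack.res_id, coords=stack.coord,
        chains=stack.chain_id, icodes=stack.ins_code,
    )


def write_structure(structure: Structure, path) -> None:
    """Write all models to a PDB file (coordinates at PDB 1e-3 Å precision)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = structure.n_atoms
    arrays = []
    for m in range(structure.n_models):
        arr = struc.AtomArray(n)
        arr.coord = structure.coords[m]
        arr.atom_name = structure.names.astype("U6")
        arr.element = structure.elements.astype("U2")
        arr.res_name = structure.resnames.astype("U5")
        arr.res_id = structure.resnums
        arr.chain_id = structure.chains.astype("U4")
        arr.ins_code = structure.icodes.astype("U1")
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack if structure.n_models > 1 else arrays[0])
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# distances and superposition
# ---------------------------------------------------------------------------

def ca_distance(structure: Structure, res_a: int, res_b: int,
                chain=None, model: int = 0) -> float:
    """Euclidean distance (Å) between the Cα atoms of two residues."""
    out = []
    for res in (res_a, res_b):
        idx = structure.atom_indices(name="CA", resnum=res, chain=chain)
        if idx.size == 0:
            raise ValueError(f"residue {res} has no CA atom")
        out.append(structure.coords[model, idx[0]])
    return float(np.linalg.norm(out[0] - out[1]))


def _kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal proper rotation R (right-multiplied: x @ R) mapping centered
    ``mobile`` onto centered ``reference``; improper reflections are
    excluded via the determinant correction."""
    C = mobile.T @ reference
    U, S, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    degenerate = S[1] < 1e-8 * max(S[0], 1e-30)
    return R, degenerate


def superpose_rmsd(reference: np.ndarray, mobile: np.ndarray,
                   selection=None):
    """Least-squares superposition (Kabsch) RMSD in Å.

    ``reference`` and ``mobile`` are (n, 3) coordinate arrays (optionally
    restricted by ``selection`` indices).  Returns ``(rmsd, rotation)``
    where ``rotation`` maps the centered mobile set onto the centered
    reference (``x @ R``).  Collinear selections are flagged by a warning.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if selection is not None:
        ref = ref[selection]
        mob = mob[selection]
    if ref.shape != mob.shape:
        raise ValueError("selections must have equal atom counts")
    if ref.shape[0] < 3:
        raise ValueError("need at least 3 atoms to superpose")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    R, degenerate = _kabsch(mob_c, ref_c)
    if degenerate:
        warnings.warn("degenerate (collinear) selection; rotation is not "
                      "unique", stacklevel=2)
    diff = mob_c @ R - ref_c
    rmsd = math.sqrt(float((diff ** 2).sum()) / ref.shape[0])
    return rmsd, R


def windowed_rmsf(structure: Structure, selection=None, n_windows: int = 1,
                  n_mean_iterations: int = 3):
    """Per-atom RMSF averaged over trajectory windows, with standard errors.

    Frames are split into ``n_windows`` equal blocks (remainder frames
    dropped); within each block all frames are superposed onto the
    iteratively refined block-mean structure and
    ``RMSF_i = sqrt(<|r_i - <r_i>|^2>)`` is computed per atom.  Returns
    ``(mean, se)`` arrays over windows (SE is 0 for a single window).
    """
    frames = structure.coords
    if selection is not None:
        frames = frames[:, selection]
    n_frames = frames.shape[0]
    if n_windows > n_frames:
        raise ValueError("more windows than frames")
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    m = n_frames // n_windows
    dropped = n_frames - m * n_windows
    if dropped:
        warnings.warn(f"dropping {dropped} trailing frames that do not fill "
                      "a window", stacklevel=2)
    per_window = []
    for w in range(n_windows):
        block = frames[w * m:(w + 1) * m]
        ref = block[0] - block[0].mean(axis=0)
        fitted = None
        for _ in range(n_mean_iterations):
            fitted = np.empty_like(block)
            for t in range(m):
                fc = block[t] - block[t].mean(axis=0)
                R, _ = _kabsch(fc, ref)
                fitted[t] = fc @ R
            ref = fitted.mean(axis=0)
        mean = fitted.mean(axis=0)
        rmsf = np.sqrt(((fitted - mean) ** 2).sum(axis=2).mean(axis=0))
        per_window.append(rmsf)
    per_window = np.stack(per_window)
    mean_rmsf = per_window.mean(axis=0)
    if n_windows > 1:
        se = per_window.std(axis=0, ddof=1) / math.sqrt(n_windows)
    else:
        se = np.zeros_like(mean_rmsf)
    return mean_rmsf, se


# ---------------------------------------------------------------------------
# gate and cavity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateSpec:
    """The residue pair whose side chains gate the lower sub-pocket.

    The partition plane passes through the midpoint of the two gate
    side-chain oxygen atoms, normal to the barrel axis (first principal
    axis of the Cα atoms).  The axis is oriented so that ``up_reference``
    (a point; default the Cα centroid) lies on the upper side.
    """

    gate_residues: tuple = (102, 147)
    chain: object = None
    up_reference: tuple | None = None


def _gate_atoms(structure: Structure, gate: GateSpec, model: int):
    out = []
    for res in gate.gate_residues:
        idx = structure.atom_indices(resnum=res, chain=gate.chain)
        if idx.size == 0:
            raise ValueError(f"gate residue {res} not present in structure")
        names = structure.names[idx]
        elements = np.char.upper(structure.elements[idx].astype(str))
        side = idx[(~np.isin(names, list(BACKBONE_NAMES))) & (elements != "H")]
        if side.size == 0:
            raise ValueError(f"gate residue {res} has no side-chain heavy atoms")
        out.append(side)
    return out


def barrel_axis(structure: Structure, model: int = 0) -> np.ndarray:
    """First principal axis of the Cα atoms (unit vector)."""
    ca = structure.atom_indices(name="CA")
    if ca.size < 3:
        raise ValueError("too few CA atoms to define a barrel axis")
    pts = structure.coords[model, ca]
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    return axis / np.linalg.norm(axis)


def gate_metrics(structure: Structure, gate: GateSpec = GateSpec(),
                 model: int = 0) -> dict:
    """Minimum side-chain heavy-atom distance between the gate residues and
    the partition-plane geometry."""
    side_a, side_b = _gate_atoms(structure, gate, model)
    xyz = structure.coords[model]
    dmin = float(cdist(xyz[side_a], xyz[side_b]).min())

    mids = []
    for side in (side_a, side_b):
        el = np.char.upper(structure.elements[side].astype(str))
        oxy = side[el == "O"]
        mids.append(xyz[oxy].mean(axis=0) if oxy.size else xyz[side].mean(axis=0))
    plane_point = 0.5 * (mids[0] + mids[1])

    axis = barrel_axis(structure, model)
    ca = structure.atom_indices(name="CA")
    up_ref = (np.asarray(gate.up_reference, dtype=float)
              if gate.up_reference is not None
              else xyz[ca].mean(axis=0))
    if np.dot(up_ref - plane_point, axis) < 0:
        axis = -axis
    return {
        "min_distance": dmin,
        "plane_point": plane_point,
        "axis": axis,
        "side_chain_midpoints": mids,
    }


@dataclass(frozen=True)
class CavityConfig:
    """Grid cavity-detection settings.

    A grid point belongs to the cavity when it lies outside every
    probe-inflated atom sphere, is buried (at least ``buriedness_min`` of
    the 26 lattice ray directions hit protein within ``ray_cutoff`` Å) and
    is 26-connected to the seed point.
    """

    grid: float = 0.5            # Å
    probe: float = 1.4           # Å
    buriedness_min: int = 18     # of the 26 ray directions
    ray_cutoff: float = 12.0     # Å
    seed_point: tuple | None = None
    extent: float = 16.0         # Å half-width of the grid box around the seed
    max_points: int = 200_000


@dataclass
class CavityResult:
    """Cavity volumes in Å³, split by the gate plane (total = upper + lower
    exactly in grid-point counts)."""

    total: float
    upper: float
    lower: float
    grid: float
    probe: float
    n_total: int
    n_upper: int
    n_lower: int
    axis: np.ndarray = field(repr=False, default=None)
    plane_point: np.ndarray = field(repr=False, default=None)
    points: np.ndarray = field(repr=False, default=None)


def cavity_volumes(structure: Structure, gate: GateSpec = GateSpec(),
                   config: CavityConfig = CavityConfig(), model: int = 0,
                   exclude_resnames=()) -> CavityResult:
    """Measure the enclosed pocket volume by grid counting.

    ``exclude_resnames`` removes, e.g., a bound ligand from the occupancy
    test so the holo pocket is measured.  The default seed point is the
    gate-plane midpoint; override it (``config.seed_point``) when the gate
    is closed or occupied.
    """
    gm = gate_metrics(structure, gate, model)
    plane_point, axis = gm["plane_point"], gm["axis"]
    seed = (np.asarray(config.seed_point, dtype=float)
            if config.seed_point is not None else plane_point)

    keep = ~np.isin(structure.resnames, list(exclude_resnames))
    xyz = structure.coords[model][keep]
    radii = structure.radii[keep]

    g = config.grid
    lo = np.maximum(xyz.min(axis=0) - g, seed - config.extent)
    hi = np.minimum(xyz.max(axis=0) + g, seed + config.extent)
    lo = np.minimum(lo, seed - g)
    hi = np.maximum(hi, seed + g)
    axes = [np.arange(lo[d], hi[d] + g / 2, g) for d in range(3)]
    shape = tuple(len(a) for a in axes)

    blocked = np.zeros(shape, dtype=bool)
    occupied = np.zeros(shape, dtype=bool)
    for pos, r in zip(xyz, radii):
        rb = r + config.probe
        sl, grids = [], []
        skip = False
        for d in range(3):
            a = axes[d]
            i0 = int(np.searchsorted(a, pos[d] - rb, side="left"))
            i1 = int(np.searchsorted(a, pos[d] + rb, side="right"))
            if i0 >= i1:
                skip = True
                break
            sl.append(slice(i0, i1))
            grids.append(a[i0:i1] - pos[d])
        if skip:
            continue
        dx, dy, dz = np.meshgrid(*grids, indexing="ij")
        d2 = dx * dx + dy * dy + dz * dz
        blocked[tuple(sl)] |= d2 <= rb * rb
        occupied[tuple(sl)] |= d2 <= r * r

    seed_idx = tuple(int(np.clip(round((seed[d] - axes[d][0]) / g), 0,
                                 shape[d] - 1)) for d in range(3))
    if occupied[seed_idx]:
        raise ValueError("seed point lies inside an atom; supply another seed")
    if blocked[seed_idx]:
        raise ValueError("seed point lies inside the probe-inflated surface; "
                         "supply another seed")

    buried_count = _ray_hit_counts(occupied, g, config.ray_cutoff)
    region = (~blocked) & (buried_count >= config.buriedness_min)
    labels, _ = ndimage.label(region, structure=np.ones((3, 3, 3), dtype=int))
    if labels[seed_idx] == 0:
        raise ValueError("seed point is not inside a buried cavity")
    component = labels == labels[seed_idx]
    n = int(component.sum())
    if n > config.max_points:
        raise RuntimeError("pocket not enclosed: flood fill exceeded the "
                           f"point cap ({config.max_points})")

    idx = np.argwhere(component)
    pts = np.stack([axes[d][idx[:, d]] for d in range(3)], axis=1)
    signed = (pts - plane_point) @ axis
    n_upper = int((signed >= 0).sum())
    n_lower = n - n_upper
    vol = g ** 3
    return CavityResult(
        total=n * vol, upper=n_upper * vol, lower=n_lower * vol,
        grid=g, probe=config.probe, n_total=n, n_upper=n_upper,
        n_lower=n_lower, axis=axis, plane_point=plane_point, points=pts,
    )


def _ray_hit_counts(occupied: np.ndarray, grid: float, cutoff: float):
    """For every grid point, count the 26 lattice directions along which an
    occupied cell is found within ``cutoff``."""
    dirs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
            for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    counts = np.zeros(occupied.shape, dtype=np.int8)
    for d in dirs:
        step_len = grid * math.sqrt(sum(c * c for c in d))
        n_steps = int(cutoff / step_len)
        hit = np.zeros(occupied.shape, dtype=bool)
        for s in range(1, n_steps + 1):
            hit |= _shift(occupied, tuple(c * s for c in d))
        counts += hit
    return counts


def _shift(arr: np.ndarray, offset):
    """Shift a 3-D boolean array; cells sampled beyond the box are False."""
    out = np.zeros_like(arr)
    src, dst = [], []
    for n, o in zip(arr.shape, offset):
        if o >= n or -o >= n:
            return out
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def hbond_occupancy(structure: Structure, donors, acceptors,
                    hydrogens: dict | None = None,
                    d_da: float = 3.5, angle_min: float = 150.0) -> pd.DataFrame:
    """Per donor--acceptor pair hydrogen-bond occupancy over all frames (%).

    A bond is present in a frame when the donor--acceptor distance is at
    most ``d_da`` Å and, if the donor has attached hydrogens (given
    explicitly or detected within 1.25 Å in the first frame), some
    D-H...A angle is at least ``angle_min`` degrees; without hydrogens the
    distance criterion alone is used (crystal-structure fallback).
    """
    donors = np.atleast_1d(np.asarray(donors, dtype=int))
    acceptors = np.atleast_1d(np.asarray(acceptors, dtype=int))
    if donors.size == 0 or acceptors.size == 0:
        raise ValueError("donor and acceptor selections must be non-empty")
    if hydrogens is None:
        hydrogens = {}
        h_idx = np.flatnonzero(
            np.char.upper(structure.elements.astype(str)) == "H")
        if h_idx.size:
            first = structure.coords[0]
            for d in donors:
                dist = np.linalg.norm(first[h_idx] - first[d], axis=1)
                hydrogens[int(d)] = h_idx[dist <= 1.25].tolist()

    rows = []
    n_frames = structure.n_models
    for d in donors:
        hs = hydrogens.get(int(d), [])
        for a in acceptors:
            if a == d:
                continue
            present = 0
            for m in range(n_frames):
                xyz = structure.coords[m]
                if np.linalg.norm(xyz[a] - xyz[d]) > d_da:
                    continue
                if hs:
                    ok = False
                    for h in hs:
                        v1 = xyz[d] - xyz[h]
                        v2 = xyz[a] - xyz[h]
                        c = np.dot(v1, v2) / (np.linalg.norm(v1)
                                              * np.linalg.norm(v2))
                        ang = math.degrees(math.acos(np.clip(c, -1, 1)))
                        if ang >= angle_min:
                            ok = True
                            break
                    if not ok:
                        continue
                present += 1
            rows.append({"donor": int(d), "acceptor": int(a),
                         "occupancy": 100.0 * present / n_frames})
    return pd.DataFrame(rows)
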