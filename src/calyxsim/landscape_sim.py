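"""Synthetic inputs for the unbinding pipeline.

This module generates every input the downstream analyses consume:

* one-dimensional model free-energy landscapes ``U(xi)`` standing in for the
  potential of mean force of ligand unbinding from a lipocalin calyx, with
  the reaction coordinate ``xi`` (nm) being the ligand--protein separation
  (bound state near 1 nm, free plateau at 3.3 nm);
* overdamped Langevin sampling of those landscapes, unbiased, under a fixed
  harmonic umbrella restraint, or under a constant-velocity moving spring
  (force-probe pulling);
* toy "calyx" pseudo-atom barrels with analytically known cavity volumes,
  used as oracles for the grid cavity algorithm;
* atom-pairwise force records with designed residue-level mean forces, used
  as oracles for the force-distribution aggregation.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.interpolate import PchipInterpolator

from .units import KB, PN_PER_KJ_MOL_NM, kt
from .wham_pmf import UmbrellaWindowData
from . import pocket_geometry as pg


# ---------------------------------------------------------------------------
# model landscape
# ---------------------------------------------------------------------------

@dataclass
class ModelLandscape:
    """Piecewise cubic-smooth 1-D free-energy profile.

    The profile is a shape-preserving (PCHIP) interpolant through ``knots``
    (xi in nm, U in kJ/mol), evaluated on ``domain`` and clamped to the
    outermost knot values beyond them.  Monotone knot sequences give a
    monotone interpolant, and runs of equal knot values give an exactly flat
    segment, which is how the free-state plateau is represented.
    """

    knots: tuple
    domain: tuple
    barrier_height: float | None = None
    plateau_start: float | None = None
    _interp: PchipInterpolator = field(init=False, repr=False, compare=False)
    _dinterp: PchipInterpolator = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        knots = sorted((float(x), float(u)) for x, u in self.knots)
        xs = np.array([x for x, _ in knots])
        us = np.array([u for _, u in knots])
        if len(xs) < 2:
            raise ValueError("need at least two knots")
        if np.any(np.diff(xs) <= 0):
            raise ValueError("knot positions must be strictly increasing")
        if not (np.all(np.isfinite(xs)) and np.all(np.isfinite(us))):
            raise ValueError("knots must be finite")
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError("empty domain")
        self.knots = tuple(knots)
        self._interp = PchipInterpolator(xs, us, extrapolate=False)
        self._dinterp = self._interp.derivative()
        self._xlo, self._xhi = xs[0], xs[-1]

    def potential(self, xi):
        """U(xi) in kJ/mol; clamped to edge knot values outside the knot span."""
        x = np.clip(np.asarray(xi, dtype=float), self._xlo, self._xhi)
        return self._interp(x)

    def gradient(self, xi):
        """dU/dxi in kJ/mol/nm (zero beyond the outermost knots)."""
        x = np.asarray(xi, dtype=float)
        inside = (x >= self._xlo) & (x <= self._xhi)
        g = np.where(inside, self._dinterp(np.clip(x, self._xlo, self._xhi)), 0.0)
        return g

    def gradient_table(self, n: int = 8192):
        """Dense (xi, dU/dxi) table for fast linear-interp force evaluation."""
        xs = np.linspace(self.domain[0], self.domain[1], n)
        return xs, np.asarray(self.gradient(xs), dtype=float)


def make_unbinding_landscape(
    barrier: float,
    bound_min: float = 1.0,
    plateau_start: float = 2.3,
    shoulder: tuple | None = None,
    domain: tuple | None = None,
) -> ModelLandscape:
    """Build an unbinding landscape: minimum U=0 at ``bound_min``, a smooth
    monotone rise to ``barrier`` kJ/mol at ``plateau_start``, exactly flat
    beyond it, and a repulsive inner wall left of the bound minimum.

    ``shoulder=(xi_s, depth)`` carves a local dip of ``depth`` kJ/mol at
    ``xi_s`` into the rising flank (an intermediate metastable state on the
    unbinding path).
    """
    if barrier < 0:
        raise ValueError("barrier must be >= 0")
    if not bound_min < plateau_start <= 3.3:
        raise ValueError("require bound_min < plateau_start <= 3.3")
    if domain is None:
        domain = (bound_min - 0.3, max(3.3, plateau_start) + 0.3)
    lo, hi = domain
    if not (lo < bound_min and hi > plateau_start):
        raise ValueError("domain must contain the bound minimum and plateau")

    span = plateau_start - bound_min
    rise = []
    for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
        u = frac * frac * (3.0 - 2.0 * frac)  # smoothstep
        rise.append((bound_min + frac * span, barrier * u))
    wall = barrier if barrier > 0 else 0.0
    knots = [(lo, wall), ((lo + bound_min) / 2.0, wall * 0.3)] + rise
    knots += [(plateau_start + 0.5 * (hi - plateau_start), barrier), (hi, barrier)]

    if shoulder is not None:
        xi_s, depth = shoulder
        if not (bound_min < xi_s < plateau_start):
            raise ValueError("shoulder must lie inside (bound_min, plateau_start)")
        base = ModelLandscape(tuple(knots), domain, barrier, plateau_start)
        w = min(0.08, (xi_s - bound_min) / 2, (plateau_start - xi_s) / 2)
        keep = [k for k in knots if abs(k[0] - xi_s) > w]
        keep += [
            (xi_s - w, float(base.potential(xi_s - w))),
            (xi_s, float(base.potential(xi_s)) - depth),
            (xi_s + w, float(base.potential(xi_s + w))),
        ]
        knots = keep

    return ModelLandscape(tuple(knots), domain, barrier_height=barrier,
                          plateau_start=plateau_start)


def make_double_well(
    well_a: float = 1.2, well_b: float = 2.0, barrier: float = 3.0,
    asymmetry: float = 0.0, domain: tuple = (0.9, 2.3),
) -> ModelLandscape:
    """Two-well test landscape: minima at ``well_a`` (U=0) and ``well_b``
    (U=``asymmetry``) separated by ``barrier`` kJ/mol; walls at the domain
    edges.  Used for detailed-balance checks."""
    mid = (well_a + well_b) / 2
    wall = barrier + 12.0
    knots = (
        (domain[0], wall), (well_a, 0.0), (mid, barrier),
        (well_b, asymmetry), (domain[1], wall),
    )
    return ModelLandscape(knots, domain)


# ---------------------------------------------------------------------------
# Langevin sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LangevinParams:
    """Overdamped-sampler parameters.

    temperature in K (default 310, physiological), diffusion_coefficient in
    nm^2/ns, timestep in ns, n_steps a count, seed for the RNG.
    """

    temperature: float = 310.0
    diffusion_coefficient: float = 1.0
    timestep: float = 1e-5
    n_steps: int = 100_000
    seed: int | None = None

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion coefficient must be >= 0")

    @property
    def kt(self) -> float:
        return kt(self.temperature)


@dataclass(frozen=True)
class BiasSpec:
    """Bias on the reaction coordinate: none, a fixed harmonic umbrella, or
    a harmonic spring whose anchor moves at constant velocity."""

    kind: str = "none"
    center: float = 0.0
    spring_k: float = 0.0       # kJ/mol/nm^2
    velocity: float = 0.0       # nm/ns, moving_spring only

    def __post_init__(self):
        if self.kind not in ("none", "umbrella", "moving_spring"):
            raise ValueError(f"unknown bias kind {self.kind!r}")
        if self.spring_k < 0:
            raise ValueError("spring_k must be >= 0")

    @staticmethod
    def none() -> "BiasSpec":
        return BiasSpec(kind="none")

    @staticmethod
    def umbrella(center: float, spring_k: float = 1000.0) -> "BiasSpec":
        return BiasSpec(kind="umbrella", center=center, spring_k=spring_k)

    @staticmethod
    def moving_spring(start: float, velocity: float = 0.01,
                      spring_k: float = 100.0) -> "BiasSpec":
        return BiasSpec(kind="moving_spring", center=start,
                        spring_k=spring_k, velocity=velocity)


@dataclass
class Trajectory:
    """Reaction-coordinate time series: times in ns, xi in nm."""

    times: np.ndarray
    xi: np.ndarray


@dataclass
class ForceExtensionTrace:
    """Constant-velocity pulling trace: spring force in pN vs time.

    ``force_pn`` is the raw instantaneous spring force
    ``k (anchor - xi)``; because the overdamped coordinate fluctuates
    thermally, the raw force carries noise of standard deviation
    ``sqrt(kT k)`` (about 27 pN at 310 K with k = 100 kJ/mol/nm^2), so the
    rupture force is read from a time-smoothed trace.
    """

    times: np.ndarray          # ns
    xi: np.ndarray             # nm
    force_pn: np.ndarray       # pN
    spring_center: np.ndarray  # nm

    def smoothed_force(self, window_ns: float | None = None) -> np.ndarray:
        """Moving-average force; the default window is one tenth of the
        trace duration (scale-free suppression of thermal fluctuations
        while preserving the rupture peak, which evolves on the pulling
        time scale)."""
        dt = float(self.times[1] - self.times[0]) if self.times.size > 1 else 1.0
        if window_ns is None:
            window_ns = (self.times[-1] - self.times[0]) / 10.0
        n = int(np.clip(round(window_ns / dt), 1, self.force_pn.size))
        return np.convolve(self.force_pn, np.ones(n) / n, mode="valid")

    @property
    def f_max(self) -> float:
        """Rupture (unbinding) force: peak of the smoothed spring force, pN."""
        return float(np.max(self.smoothed_force()))


def _check_stability(landscape, bias, params):
    xs, gs = landscape.gradient_table(2048)
    gmax = float(np.max(np.abs(gs)))
    # typical bias force scale: spring at a few thermal widths of extension
    if bias.spring_k > 0:
        gmax += bias.spring_k * max(0.3, 4 * math.sqrt(params.kt / bias.spring_k))
    d, dt = params.diffusion_coefficient, params.timestep
    step = (d / params.kt) * gmax * dt + math.sqrt(2 * d * dt)
    if step > 0.1:
        raise RuntimeError(
            f"unstable integration: expected step {step:.3g} nm exceeds 0.1 nm; "
            "reduce the timestep")
    curv = float(np.max(np.abs(np.gradient(gs, xs)))) + bias.spring_k
    if curv > 0 and d > 0 and dt >= 0.1 * params.kt / (d * curv):
        warnings.warn(
            "timestep close to the overdamped stability limit "
            f"(dt={dt:g}, limit~{0.1 * params.kt / (d * curv):.2g} ns)",
            RuntimeWarning, stacklevel=3)


def _integrate(landscape, bias, params, x0, sample_stride=1, chunk=20000):
    """Euler--Maruyama integration with reflecting domain boundaries.

    ``x0`` is an array of replica start positions; for umbrella batches each
    replica may use its own bias center (``bias.center`` array-valued).
    Returns (times, traj) with traj of shape (n_recorded, n_replicas).
    """
    lo, hi = landscape.domain
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    if np.any((x < lo) | (x > hi)):
        raise ValueError("initial position outside the landscape domain")
    _check_stability(landscape, bias, params)

    xs, gs = landscape.gradient_table()
    d, dt, beta = params.diffusion_coefficient, params.timestep, 1.0 / params.kt
    sigma = math.sqrt(2.0 * d * dt)
    # D = 0 is the zero-noise (zero-temperature) limit: the noise switches
    # off but the mobility keeps the Einstein value of the default
    # 1 nm^2/ns, giving deterministic gradient descent.
    mob = (d if d > 0 else 1.0) * beta * dt
    rng = np.random.default_rng(params.seed)
    centers = np.atleast_1d(np.asarray(bias.center, dtype=float))
    k, v = bias.spring_k, bias.velocity

    n_rec = params.n_steps // sample_stride
    traj = np.empty((n_rec, x.size))
    rec_steps = (np.arange(1, n_rec + 1) * sample_stride)
    times = rec_steps * dt

    step = 0
    irec = 0
    while step < params.n_steps:
        n = min(chunk, params.n_steps - step)
        noise = rng.standard_normal((n, x.size)) if sigma > 0 else None
        for i in range(n):
            g = np.interp(x, xs, gs)
            if bias.kind == "umbrella":
                g = g + k * (x - centers)
            elif bias.kind == "moving_spring":
                c = centers + v * (step + i) * dt
                g = g + k * (x - c)
            if noise is not None:
                x = x - mob * g + sigma * noise[i]
            else:
                x = x - mob * g
            # single reflection suffices for stable steps
            x = np.where(x < lo, 2 * lo - x, x)
            x = np.where(x > hi, 2 * hi - x, x)
            np.clip(x, lo, hi, out=x)
            if (step + i + 1) % sample_stride == 0:
                traj[irec] = x
                irec += 1
        step += n
    return times, traj


def simulate_overdamped(
    landscape: ModelLandscape,
    bias: BiasSpec,
    params: LangevinParams,
    x0: float | None = None,
    sample_stride: int = 1,
) -> Trajectory:
    """Sample xi(t) by overdamped Langevin dynamics on U + bias.

    Identical parameters and seed give a bitwise-identical trajectory.  The
    default start is the umbrella/spring center, else the landscape's global
    minimum.
    """
    if x0 is None:
        if bias.kind in ("umbrella", "moving_spring"):
            x0 = float(np.atleast_1d(bias.center)[0])
        else:
            xs = np.linspace(*landscape.domain, 2048)
            x0 = float(xs[np.argmin(landscape.potential(xs))])
    times, traj = _integrate(landscape, bias, params, [x0], sample_stride)
    return Trajectory(times=times, xi=traj[:, 0])


#: Default diffusion coefficient for pulling runs (nm^2/ns).  The frictional
#: relaxation time kT/(D k) must be commensurate with the pulling time per
#: barrier width for the rupture force to show its loading-rate dependence;
#: 0.01 nm^2/ns puts the 0.01-1 nm/ns velocity ladder across the
#: quasi-static to driven crossover (relaxation time ~2.6 ns at 310 K with
#: the 100 kJ/mol/nm^2 pulling spring).
PULL_DIFFUSION_DEFAULT = 0.01


def run_constant_velocity_pull(
    landscape: ModelLandscape,
    bias: BiasSpec,
    params: LangevinParams,
    pull_to: float | None = None,
    sample_stride: int = 10,
    n_replicas: int = 1,
):
    """Drag the spring anchor from ``bias.center`` to ``pull_to`` at constant
    velocity and record the spring force F(t) = k (anchor - xi) in pN.

    With ``n_replicas > 1`` a list of traces driven by independent noise
    streams (one batched integration) is returned.
    """
    if bias.kind != "moving_spring":
        raise ValueError("bias.kind must be 'moving_spring'")
    lo, hi = landscape.domain
    if pull_to is None:
        pull_to = hi
    if pull_to > hi or bias.center < lo:
        raise ValueError("spring anchor path leaves the landscape domain")
    if bias.velocity <= 0:
        raise ValueError("pulling velocity must be > 0")
    total_time = (pull_to - bias.center) / bias.velocity
    n_steps = int(math.ceil(total_time / params.timestep))
    params = replace(params, n_steps=n_steps)
    times, traj = _integrate(landscape, bias, params,
                             [bias.center] * n_replicas, sample_stride)
    anchor = bias.center + bias.velocity * times
    traces = [
        ForceExtensionTrace(
            times=times, xi=traj[:, j],
            force_pn=bias.spring_k * (anchor - traj[:, j]) * PN_PER_KJ_MOL_NM,
            spring_center=anchor)
        for j in range(n_replicas)
    ]
    return traces[0] if n_replicas == 1 else traces


def pull_rupture_forces(
    landscape: ModelLandscape,
    velocities: Sequence[float],
    n_replicas: int = 5,
    spring_k: float = 100.0,
    start: float = 1.0,
    pull_to: float = 3.3,
    temperature: float = 310.0,
    diffusion_coefficient: float = PULL_DIFFUSION_DEFAULT,
    timestep: float = 1e-4,
    seed: int | None = None,
) -> dict:
    """Median rupture force per pulling velocity over replica pulls."""
    out = {}
    for i, v in enumerate(velocities):
        bias = BiasSpec.moving_spring(start=start, velocity=v, spring_k=spring_k)
        params = LangevinParams(
            temperature=temperature,
            diffusion_coefficient=diffusion_coefficient,
            timestep=timestep,
            seed=None if seed is None else seed + i)
        traces = run_constant_velocity_pull(landscape, bias, params,
                                            pull_to=pull_to,
                                            n_replicas=n_replicas)
        if n_replicas == 1:
            traces = [traces]
        out[float(v)] = float(np.median([t.f_max for t in traces]))
    return out


def generate_umbrella_dataset(
    landscape: ModelLandscape,
    centers: Sequence[float],
    params: LangevinParams,
    spring_k: float = 1000.0,
    burn_in_fraction: float = 0.1,
    sample_stride: int = 10,
    overlap_warn: float = 0.02,
) -> list[UmbrellaWindowData]:
    """Run one umbrella window per center (all windows batched through the
    same integrator, jointly seeded), discard the burn-in fraction, and warn
    if adjacent window histograms do not overlap.

    Window starting structures are taken at the window centers, the
    desk-scale analogue of seeding umbrellas from a prior pulling run.  The
    default recording stride of 10 steps decimates the output to roughly
    the harmonic relaxation time scale, so retained samples are only weakly
    correlated.
    """
    centers = np.asarray(list(centers), dtype=float)
    if centers.size == 0:
        raise ValueError("need at least one center")
    if np.any(np.diff(centers) <= 0):
        raise ValueError("centers must be strictly increasing")
    if not 0 <= burn_in_fraction < 1:
        raise ValueError("burn_in_fraction must be in [0, 1)")

    bias = BiasSpec(kind="umbrella", center=centers, spring_k=spring_k)
    _, traj = _integrate(landscape, bias, params, centers, sample_stride)
    n_burn = int(round(burn_in_fraction * traj.shape[0]))
    kept = traj[n_burn:]
    windows = [
        UmbrellaWindowData(center=float(c), spring_k=spring_k,
                           samples=np.ascontiguousarray(kept[:, j]))
        for j, c in enumerate(centers)
    ]
    _warn_on_overlap_gaps(windows, overlap_warn)
    return windows


def _warn_on_overlap_gaps(windows, threshold):
    if len(windows) < 2:
        return
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    edges = np.linspace(lo, hi, 401)
    dens = [np.histogram(w.samples, bins=edges, density=False)[0] / w.n_samples
            for w in windows]
    for a, b in zip(range(len(windows) - 1), range(1, len(windows))):
        ov = float(np.minimum(dens[a], dens[b]).sum())
        if ov < threshold:
            warnings.warn(
                f"umbrella histograms for centers {windows[a].center:g} and "
                f"{windows[b].center:g} nm do not overlap (coefficient "
                f"{ov:.3g}); the WHAM chain may be broken there",
                RuntimeWarning, stacklevel=3)


def default_umbrella_centers(start: float = 1.0, stop: float = 3.3,
                             spacing: float = 0.05) -> np.ndarray:
    """Ladder of umbrella centers; the defaults give 47 windows over the
    bound-to-free range of the unbinding coordinate."""
    n = int(round((stop - start) / spacing)) + 1
    return start + spacing * np.arange(n)


# ---------------------------------------------------------------------------
# toy calyx fixture
# ---------------------------------------------------------------------------

@dataclass
class ToyCalyx:
    """Pseudo-atom barrel with a cylindrical interior cavity.

    ``cylinder_volume`` is the plain pi r^2 depth formula; ``free_volume*``
    are exact semi-analytic volumes of the probe-accessible interior that
    also account for the gate diaphragm intruding into the cylinder (they
    equal the cylinder value when the gate is fully recessed).  Volumes are
    the oracle for the grid cavity algorithm.
    """

    structure: "pg.Structure"
    cylinder_volume: float
    free_volume_total: float
    free_volume_upper: float
    free_volume_lower: float
    gate_residues: tuple
    gate_gap: float
    z_gate: float
    seed_point: np.ndarray
    probe_radius: float


def _chord_area(a: float, r: float) -> float:
    """Area of {x^2+y^2 < r^2, |x| < a}."""
    if a <= 0:
        return 0.0
    if a >= r:
        return math.pi * r * r
    return 2.0 * (a * math.sqrt(r * r - a * a) + r * r * math.asin(a / r))


def make_toy_calyx(
    n_strands: int = 8,
    cavity_radius: float = 4.0,
    cavity_depth: float = 10.0,
    gate_gap: float = 8.0,
    gate_height_fraction: float = 0.35,
    probe_radius: float = 1.4,
    bead_spacing: float = 1.0,
    open_top: bool = False,
) -> ToyCalyx:
    """Build a closed pseudo-atom barrel whose probe-accessible interior is a
    cylinder of ``cavity_radius`` x ``cavity_depth`` (Å), partially blocked
    by a two-residue gate diaphragm with a slit of width ``gate_gap`` between
    the two gate residues (Tyr-like, resnums 102 and 147).

    Wall/floor/lid beads are carbons named CA (so the barrel axis is the
    principal axis of the CA atoms); gate beads are oxygens named OH.  Bead
    centers are laid out so that the inflated (vdW + probe) surfaces are
    tangent to the ideal cavity boundary; with the default 1 Å bead spacing
    the residual scalloping is < 0.05 Å.
    """
    if n_strands < 6:
        raise ValueError("n_strands must be >= 6")
    if cavity_radius < probe_radius:
        raise ValueError("cavity_radius must be >= probe radius")
    if gate_gap < 0:
        raise ValueError("gate_gap must be >= 0")
    if cavity_depth <= 2 * bead_spacing:
        raise ValueError("cavity too shallow for the bead spacing")
    r_c = pg.VDW_RADII["C"] + probe_radius     # wall bead inflation
    r_o = pg.VDW_RADII["O"] + probe_radius     # gate bead inflation
    r_wall = cavity_radius + r_c
    if gate_gap / 2 > r_wall:
        raise ValueError("gate_gap places the gate outside the barrel wall")
    z_gate = gate_height_fraction * cavity_depth
    if not r_o < z_gate < cavity_depth - r_o:
        raise ValueError("gate diaphragm intersects the floor or the lid")

    names, elements, resnames, resnums, coords = [], [], [], [], []

    def add(x, y, z, name, element, resname, resnum):
        names.append(name); elements.append(element)
        resnames.append(resname); resnums.append(resnum)
        coords.append((x, y, z))

    # wall rings
    n_az = max(n_strands, int(math.ceil(2 * math.pi * r_wall / bead_spacing)))
    z_top = cavity_depth + (0.0 if open_top else 0.0)
    zs = np.arange(0.0, z_top + 1e-9, bead_spacing)
    for z in zs:
        for j in range(n_az):
            th = 2 * math.pi * j / n_az
            add(r_wall * math.cos(th), r_wall * math.sin(th), z,
                "CA", "C", "CAL", 1)
    # floor (and lid) discs of beads, centres one inflation radius outside
    def add_disc(zc):
        add(0.0, 0.0, zc, "CA", "C", "CAL", 1)
        for rho in np.arange(bead_spacing, r_wall + 1e-9, bead_spacing):
            m = max(6, int(math.ceil(2 * math.pi * rho / bead_spacing)))
            for j in range(m):
                th = 2 * math.pi * j / m
                add(rho * math.cos(th), rho * math.sin(th), zc,
                    "CA", "C", "CAL", 1)

    add_disc(-r_c)
    if not open_top:
        add_disc(cavity_depth + r_c)

    # gate diaphragm: two half-discs of O beads separated by gate_gap along x
    half = gate_gap / 2.0
    ys = np.arange(-r_wall, r_wall + 1e-9, bead_spacing)
    for sign, resnum in ((-1, 102), (+1, 147)):
        for y in ys:
            x = sign * half
            while x * x + y * y <= r_wall * r_wall:
                add(x, y, z_gate, "OH", "O", "TYR", resnum)
                x += sign * bead_spacing

    structure = pg.Structure.from_arrays(
        names=names, elements=elements, resnames=resnames,
        resnums=resnums, coords=np.array(coords)[None, :, :],
    )

    # semi-analytic free volumes (axisymmetric-in-slit chord-area integral)
    r = cavity_radius

    def area(z):
        dz = z - z_gate
        if abs(dz) >= r_o:
            return math.pi * r * r
        a = half - math.sqrt(r_o * r_o - dz * dz)
        return _chord_area(a, r)

    pts = [z_gate - r_o, z_gate + r_o]
    lower = quad(area, 0.0, z_gate, points=[p for p in pts if 0 < p < z_gate],
                 limit=200)[0]
    upper = quad(area, z_gate, cavity_depth,
                 points=[p for p in pts if z_gate < p < cavity_depth],
                 limit=200)[0]
    cyl = math.pi * r * r * cavity_depth
    seed = np.array([0.0, 0.0, (z_gate + cavity_depth) / 2.0])
    return ToyCalyx(
        structure=structure, cylinder_volume=cyl,
        free_volume_total=lower + upper, free_volume_upper=upper,
        free_volume_lower=lower, gate_residues=(102, 147),
        gate_gap=gate_gap, z_gate=z_gate, seed_point=seed,
        probe_radius=probe_radius,
    )


# ---------------------------------------------------------------------------
# pairwise-force fixture
# ---------------------------------------------------------------------------

@dataclass
class PairForceFixture:
    """Atom-pairwise force records with designed residue-level mean forces.

    ``records`` follows the pairwise-force table schema (frame, atom_i,
    atom_j, fx, fy, fz in kJ/mol/nm; the stored vector is the force on
    atom_i exerted by atom_j).  ``designed_means`` are the target
    time-averaged residue force magnitudes in pN.
    """

    records: pd.DataFrame
    ligand_atoms: frozenset
    atom_to_residue: dict
    designed_means: dict
    n_frames: int


def make_pairforce_fixture(
    designed_means: Mapping[str, float],
    n_frames: int,
    seed: int | None = None,
    noise_rel: float = 0.2,
    pairs_per_residue: int = 2,
    n_ligand_atoms: int = 3,
) -> PairForceFixture:
    """Generate per-frame ligand--residue atom-pair forces whose
    residue-aggregated, time-averaged vector-sum magnitudes equal
    ``designed_means`` (pN) up to relative noise ``noise_rel``.

    Each frame draws, per residue, a random direction and a magnitude
    ``mean * (1 + noise_rel * N(0,1))`` (clipped at zero), then splits the
    resulting vector over ``pairs_per_residue`` atom pairs with zero-sum
    perturbations, so the per-frame vector sum is exact by construction.
    """
    if any(m < 0 for m in designed_means.values()):
        raise ValueError("designed means must be >= 0")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    residues = list(designed_means)
    n_res, npr = len(residues), pairs_per_residue

    means = np.array([designed_means[r] for r in residues])
    mags = means[None, :] * (1.0 + noise_rel * rng.standard_normal((n_frames, n_res)))
    np.clip(mags, 0.0, None, out=mags)
    dirs = rng.standard_normal((n_frames, n_res, 3))
    dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
    total = (mags[..., None] * dirs) / PN_PER_KJ_MOL_NM   # kJ/mol/nm

    split = rng.standard_normal((n_frames, n_res, npr, 3)) * 0.25 \
        * np.linalg.norm(total, axis=-1)[..., None, None]
    split -= split.mean(axis=2, keepdims=True)
    pair_forces = total[:, :, None, :] / npr + split      # sums back to total

    ligand_atoms = frozenset(range(1, n_ligand_atoms + 1))
    atom_to_residue = {}
    prot_atoms = np.empty((n_res, npr), dtype=int)
    nxt = n_ligand_atoms + 1
    for i, res in enumerate(residues):
        for p in range(npr):
            atom_to_residue[nxt] = res
            prot_atoms[i, p] = nxt
            nxt += 1

    frames = np.repeat(np.arange(n_frames), n_res * npr)
    lig_cycle = np.array(sorted(ligand_atoms))[
        np.arange(n_res * npr) % n_ligand_atoms]
    records = pd.DataFrame({
        "frame": frames,
        "atom_i": np.tile(lig_cycle, n_frames),
        "atom_j": np.tile(prot_atoms.reshape(-1), n_frames),
        "fx": pair_forces[..., 0].reshape(-1),
        "fy": pair_forces[..., 1].reshape(-1),
        "fz": pair_forces[..., 2].reshape(-1),
    })
    return PairForceFixture(
        records=records, ligand_atoms=ligand_atoms,
        atom_to_residue=atom_to_residue,
        designed_means=dict(designed_means), n_frames=n_frames,
    )
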