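"""Synthetic cortices with known ground truth.

Every input the pipeline needs can be generated here: phantom gray-matter
ribbons whose equivolume bin boundaries are known in closed form, small
triangulated grid meshes with parcel labels, and cohort tables of
parcel x depth x subject T1w/T2w ratios that follow saturating growth
curves.  The generated trajectories encode the structure the pipeline is
meant to recover: plateau timing increases along a synthetic S-A axis and
with depth superficiality, deeper bins are steeper, macaque time runs at a
configurable multiple (default 4x) of human time, and observations carry
Gaussian noise, a sex contrast and (for the longitudinal arm) subject
random intercepts.

The growth-curve family is a saturating exponential

    mu(age) = baseline + amplitude * (1 - exp(-rate * age)),

the simplest monotone curve with a well-defined plateau.  This is a fixture
choice for testing, not a biological claim; real developmental trajectories
are not assumed to follow it.  "Plateau onset" ground truth is the age at
which the true derivative amplitude*rate*exp(-rate*age) first drops below
``PLATEAU_EPS_FRAC`` (1%) of its value at age 0, i.e. ``ln(100) / rate``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .axis import SurfaceMesh

#: plateau-onset definition: derivative has decayed to this fraction of its
#: age-0 value
PLATEAU_EPS_FRAC = 0.01

#: default observed age ranges (years); humans 5.5-36 y, macaques 1 mo-3 y
HUMAN_AGE_RANGE = (5.5, 36.0)
MACAQUE_AGE_RANGE = (1.0 / 12.0, 3.0)


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of one saturating growth trajectory.

    Units: ``baseline``, ``amplitude``, ``noise_sd``, ``sex_effect`` and
    ``subject_sd`` are in (arbitrary) ratio units; ``rate`` is 1/age-units.
    """

    baseline: float
    amplitude: float
    rate: float
    noise_sd: float = 0.0
    sex_effect: float = 0.0
    subject_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise ValueError("noise_sd and subject_sd must be >= 0")

    @property
    def plateau_onset(self) -> float:
        """Age at which the true derivative falls below eps = 1% of its
        initial value; satisfies amplitude*rate*exp(-rate*onset) = eps."""
        return -math.log(PLATEAU_EPS_FRAC) / self.rate

    def derivative(self, age):
        age = _check_age(age)
        return self.amplitude * self.rate * np.exp(-self.rate * age)


def _check_age(age):
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    return age


def growth_curve(params: GrowthParams, age):
    """Noise-free mean ratio at ``age`` (scalar or array).

    Monotone non-decreasing; tends to ``baseline + amplitude`` as
    ``age -> inf``.
    """
    age = _check_age(age)
    return params.baseline + params.amplitude * (1.0 - np.exp(-params.rate * age))


# ---------------------------------------------------------------------------
# cohort simulation


def default_axis_spec(n_parcels: int, onset_min: float = 10.0, onset_max: float = 30.0):
    """Per-parcel plateau onsets (human years), increasing along the axis.

    Parcel index 0 is the sensorimotor end (earliest plateau); the last
    parcel is the association end.
    """
    return np.linspace(onset_min, onset_max, n_parcels)


def default_depth_spec(n_depth_bins: int) -> dict:
    """Depth modifiers, bin 1 = deepest.

    Deeper bins get a larger rate (earlier onset) and a larger amplitude,
    so that deep bins are developmentally steeper over the observed window;
    baselines decrease deep -> superficial.
    """
    return {
        "rate_mult": np.linspace(1.1, 0.9, n_depth_bins),
        "amp_mult": np.linspace(1.5, 0.65, n_depth_bins),
        "baseline_shift": np.linspace(0.15, -0.15, n_depth_bins),
    }


def _validate_monotone(name, values, direction):
    values = np.asarray(values, dtype=float)
    diffs = np.diff(values)
    ok = np.all(diffs >= -1e-12) if direction == "increasing" else np.all(diffs <= 1e-12)
    if not ok:
        raise ValueError(f"{name} must be monotone {direction} across its index")
    return values


def simulate_cohort(
    n_subjects: int,
    n_parcels: int,
    n_depth_bins: int,
    axis_spec=None,
    depth_spec=None,
    species_scale: float = 1.0,
    seed: int = 0,
    *,
    species: str = "human",
    n_sessions: int = 1,
    age_range=None,
    baseline: float = 1.2,
    amplitude: float = 0.6,
    noise_sd: float = 0.06,
    sex_effect: float = 0.05,
    subject_sd: float = 0.05,
    growth_origin: float = 0.0,
):
    """Simulate a cohort of parcel x depth x subject ratio observations.

    Parameters
    ----------
    axis_spec
        Per-parcel plateau onsets in *human* years, monotone non-decreasing
        with parcel index (sensorimotor end first).  Default
        :func:`default_axis_spec`.
    depth_spec
        Dict with monotone per-bin arrays ``rate_mult`` (non-increasing,
        deep bins faster), ``amp_mult`` (non-increasing, deep bins steeper)
        and optional ``baseline_shift``.  Default :func:`default_depth_spec`.
    species_scale
        Time compression for the macaque arm: the macaque mean curve at age
        ``a`` equals the human mean curve at ``species_scale * a``.
    growth_origin
        Age (in *human* time) at which the saturating growth begins; the
        curve is flat at baseline before it.  The default 0 starts growth
        at birth, matching :func:`growth_curve` itself.  Setting it to the
        start of the human observed window makes faster-growing units both
        steeper *within the window* and earlier to plateau -- the joint
        structure reported for real cortex -- whereas with growth from
        birth a faster unit has largely finished before the window opens
        and its observed slope is *smaller*.  The macaque origin is
        ``growth_origin / species_scale``, preserving the time-compression
        identity exactly.
    species, n_sessions
        ``"human"`` (cross-sectional) or ``"macaque"`` (longitudinal;
        default 5 sessions per subject when ``n_sessions`` is left at 1
        is *not* applied automatically -- pass ``n_sessions=5``).

    Returns
    -------
    (cohort, ratios, truth)
        ``cohort``: one row per (subject, session) with ``subject_id, age,
        sex, species, session``.  ``ratios``: long table ``subject_id, age,
        sex, species, session, parcel, depth_bin, ratio``.  ``truth``: one
        row per (parcel, depth_bin) with the generating
        :class:`GrowthParams` fields and ``plateau_onset`` (in the
        species' own time).
    """
    if n_subjects < 10:
        raise ValueError("n_subjects must be >= 10")
    if species not in ("human", "macaque"):
        raise ValueError("species must be 'human' or 'macaque'")
    if species_scale <= 0:
        raise ValueError("species_scale must be > 0")

    rng = np.random.default_rng(seed)
    if axis_spec is None:
        axis_spec = default_axis_spec(n_parcels)
    axis_spec = _validate_monotone("axis_spec", axis_spec, "increasing")
    if len(axis_spec) != n_parcels:
        raise ValueError("axis_spec length must equal n_parcels")
    if depth_spec is None:
        depth_spec = default_depth_spec(n_depth_bins)
    rate_mult = _validate_monotone("depth_spec rate_mult", depth_spec["rate_mult"], "decreasing")
    amp_mult = _validate_monotone("depth_spec amp_mult", depth_spec["amp_mult"], "decreasing")
    baseline_shift = np.asarray(depth_spec.get("baseline_shift", np.zeros(n_depth_bins)), float)
    if not (len(rate_mult) == len(amp_mult) == len(baseline_shift) == n_depth_bins):
        raise ValueError("depth_spec arrays must have length n_depth_bins")

    scale = species_scale if species == "macaque" else 1.0
    if age_range is None:
        age_range = MACAQUE_AGE_RANGE if species == "macaque" else HUMAN_AGE_RANGE
    lo, hi = age_range
    if lo <= 0:
        raise ValueError("ages must be strictly positive")

    # per-subject covariates
    sex = rng.choice(["F", "M"], size=n_subjects)
    intercepts = rng.normal(0.0, subject_sd, size=n_subjects)
    if n_sessions == 1:
        ages = rng.uniform(lo, hi, size=(n_subjects, 1))
    else:
        first = rng.uniform(lo, lo + 0.25 * (hi - lo), size=n_subjects)
        span = rng.uniform(0.6 * (hi - lo), 0.9 * (hi - lo), size=n_subjects)
        span = np.minimum(span, hi - first)
        steps = np.linspace(0.0, 1.0, n_sessions)
        ages = first[:, None] + span[:, None] * steps[None, :]

    prefix = "mac" if species == "macaque" else "sub"
    subj_ids = np.array([f"{prefix}{i:04d}" for i in range(n_subjects)])
    cohort = pd.DataFrame(
        {
            "subject_id": np.repeat(subj_ids, n_sessions),
            "age": ages.ravel(),
            "sex": np.repeat(sex, n_sessions),
            "species": species,
            "session": np.tile(np.arange(1, n_sessions + 1), n_subjects),
        }
    )

    # ground-truth parameters per (parcel, depth); axis_spec gives absolute
    # plateau-onset ages in human time, so the growth-phase duration is
    # (onset - origin) and rate = ln(100) / duration
    if growth_origin < 0:
        raise ValueError("growth_origin must be >= 0")
    onsets_h = axis_spec  # human-years onset at the reference depth
    if np.any(onsets_h <= growth_origin):
        raise ValueError("axis_spec onsets must exceed the growth origin")
    t0 = growth_origin / scale  # species-time origin
    base_rate = -math.log(PLATEAU_EPS_FRAC) / (onsets_h - growth_origin)
    rates = scale * base_rate[:, None] * rate_mult[None, :]
    amps = amplitude * amp_mult[None, :] * np.ones((n_parcels, 1))
    bases = baseline + baseline_shift[None, :] * np.ones((n_parcels, 1))
    truth = pd.DataFrame(
        {
            "parcel": np.repeat(np.arange(n_parcels), n_depth_bins),
            "depth_bin": np.tile(np.arange(1, n_depth_bins + 1), n_parcels),
            "baseline": bases.ravel(),
            "amplitude": amps.ravel(),
            "rate": rates.ravel(),
            "growth_origin": t0,
            "plateau_onset": (t0 - math.log(PLATEAU_EPS_FRAC) / rates).ravel(),
            "noise_sd": noise_sd,
            "sex_effect": sex_effect,
            "subject_sd": subject_sd,
        }
    )

    # long ratio table: rows = (subject-session) x parcel x depth
    n_rows = len(cohort)
    age_col = cohort["age"].to_numpy()
    sex_contrast = np.where(cohort["sex"].to_numpy() == "M", 0.5, -0.5)
    subj_int = np.repeat(intercepts, n_sessions)

    eff_age = np.clip(age_col - t0, 0.0, None)  # flat at baseline before the origin
    mean = bases[None, :, :] + amps[None, :, :] * (
        1.0 - np.exp(-rates[None, :, :] * eff_age[:, None, None])
    )
    signal = mean + (sex_effect * sex_contrast + subj_int)[:, None, None]
    noise = rng.normal(0.0, noise_sd, size=signal.shape) if noise_sd > 0 else 0.0
    values = signal + noise

    idx = np.arange(n_rows)
    ratios = pd.DataFrame(
        {
            "subject_id": np.repeat(cohort["subject_id"].to_numpy(), n_parcels * n_depth_bins),
            "age": np.repeat(age_col, n_parcels * n_depth_bins),
            "sex": np.repeat(cohort["sex"].to_numpy(), n_parcels * n_depth_bins),
            "species": species,
            "session": np.repeat(cohort["session"].to_numpy(), n_parcels * n_depth_bins),
            "parcel": np.tile(np.repeat(np.arange(n_parcels), n_depth_bins), n_rows),
            "depth_bin": np.tile(np.arange(1, n_depth_bins + 1), n_rows * n_parcels),
            "ratio": values[idx].ravel(),
        }
    )
    return cohort, ratios, truth


# ---------------------------------------------------------------------------
# phantom ribbons


@dataclass
class PhantomRibbon:
    """Voxelized gray-matter phantom with analytically known geometry.

    ``geometry`` is one of ``slab`` (depth along z), ``annulus`` (radial in
    the x-y plane, extruded along z) or ``spherical_shell``.  Ribbon voxels
    are exactly those whose *center* depth/radius lies in
    ``[inner_radius, outer_radius)``.
    """

    label_volume: np.ndarray
    inner_radius: float
    outer_radius: float
    voxel_size: float
    geometry: str
    center_mm: np.ndarray = field(default=None)

    def _coord(self):
        """Per-voxel depth coordinate (slab z, annulus r, shell r) in mm."""
        shape = self.label_volume.shape
        ax = [(np.arange(n) + 0.5) * self.voxel_size for n in shape]
        if self.geometry == "slab":
            return np.broadcast_to(ax[2][None, None, :], shape)
        cx, cy, cz = self.center_mm
        if self.geometry == "annulus":
            xx, yy = np.meshgrid(ax[0] - cx, ax[1] - cy, indexing="ij")
            return np.broadcast_to(np.hypot(xx, yy)[:, :, None], shape)
        xx, yy, zz = np.meshgrid(ax[0] - cx, ax[1] - cy, ax[2] - cz, indexing="ij")
        return np.sqrt(xx**2 + yy**2 + zz**2)

    def alpha_volume(self) -> np.ndarray:
        """Exact cumulative volume fraction alpha in [0, 1) per ribbon voxel.

        alpha interpolates r (slab), r^2 (annulus) or r^3 (shell) between
        the inner and outer radii -- the exact equivolume coordinate for
        each geometry.  NaN outside the ribbon.
        """
        p = {"slab": 1, "annulus": 2, "spherical_shell": 3}[self.geometry]
        r = self._coord()
        alpha = (r**p - self.inner_radius**p) / (self.outer_radius**p - self.inner_radius**p)
        alpha = np.where(self.label_volume > 0, alpha, np.nan)
        return alpha

    def analytic_volume(self) -> float:
        """Ribbon volume in mm^3 (annulus: per full z-extent of the grid)."""
        ri, ro = self.inner_radius, self.outer_radius
        if self.geometry == "slab":
            nx, ny, _ = self.label_volume.shape
            return (ro - ri) * (nx * self.voxel_size) * (ny * self.voxel_size)
        if self.geometry == "annulus":
            nz = self.label_volume.shape[2]
            return math.pi * (ro**2 - ri**2) * nz * self.voxel_size
        return 4.0 / 3.0 * math.pi * (ro**3 - ri**3)


def make_phantom_ribbon(
    geometry: str,
    inner_radius: float,
    outer_radius: float,
    voxel_size: float,
    grid_shape=None,
) -> PhantomRibbon:
    """Build a :class:`PhantomRibbon` on a voxel grid.

    For ``slab`` the grid must be passed explicitly (x-y extent is free);
    for the radial geometries a grid just covering the outer radius is
    derived when ``grid_shape`` is None.
    """
    if geometry not in ("slab", "annulus", "spherical_shell"):
        raise ValueError(f"unknown geometry {geometry!r}")
    if not 0 <= inner_radius < outer_radius:
        raise ValueError("need 0 <= inner_radius < outer_radius")

    if grid_shape is None:
        n = int(math.ceil(2 * outer_radius / voxel_size)) + 4
        if geometry == "slab":
            nz = int(math.ceil(outer_radius / voxel_size)) + 2
            grid_shape = (n, n, nz)
        elif geometry == "annulus":
            grid_shape = (n, n, max(1, int(round(1.0 / voxel_size))))
        else:
            grid_shape = (n, n, n)
    grid_shape = tuple(int(s) for s in grid_shape)
    if geometry != "slab" and min(grid_shape[:2]) * voxel_size < 2 * outer_radius:
        raise ValueError("grid too small to contain outer_radius")

    center = 0.5 * voxel_size * np.asarray(grid_shape, dtype=float)
    ribbon = PhantomRibbon(
        label_volume=np.zeros(grid_shape, dtype=np.uint8),
        inner_radius=inner_radius,
        outer_radius=outer_radius,
        voxel_size=voxel_size,
        geometry=geometry,
        center_mm=center,
    )
    r = ribbon._coord()
    ribbon.label_volume = ((r >= inner_radius) & (r < outer_radius)).astype(np.uint8)
    return ribbon


# ---------------------------------------------------------------------------
# meshes


def make_grid_mesh(n_rows: int, n_cols: int, spacing: float = 1.0, parcel_grid=None) -> SurfaceMesh:
    """Planar right-triangulated lattice mesh.

    Vertex (r, c) sits at ``(r*spacing, c*spacing, 0)``; each lattice cell
    is split along its (r, c)-(r+1, c+1) diagonal, giving
    ``2*(n_rows-1)*(n_cols-1)`` triangles.  When ``parcel_grid = (pr, pc)``
    is given, vertices are labeled by block: parcel ids increase fastest
    along rows within a column of blocks, so ids are ordered
    column-block-major (parcel 0 at c = 0).
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("need n_rows, n_cols >= 2")
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    vertices = np.column_stack(
        [rr.ravel() * spacing, cc.ravel() * spacing, np.zeros(n_rows * n_cols)]
    )

    def vid(r, c):
        return r * n_cols + c

    tris = []
    for r in range(n_rows - 1):
        for c in range(n_cols - 1):
            tris.append([vid(r, c), vid(r + 1, c), vid(r + 1, c + 1)])
            tris.append([vid(r, c), vid(r + 1, c + 1), vid(r, c + 1)])
    triangles = np.asarray(tris, dtype=np.int64)

    labels = None
    if parcel_grid is not None:
        pr, pc = parcel_grid
        block_r = (rr.ravel() * pr) // n_rows
        block_c = (cc.ravel() * pc) // n_cols
        labels = block_c * pr + block_r
    return SurfaceMesh(vertices=vertices, triangles=triangles, vertex_parcel=labels)
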