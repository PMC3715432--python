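"""Ground-truthed synthetic dual-colour 3D FISH cohorts.

Emulates the statistical structure of super-resolution FISH measurements in
embryonic tissue sections: non-spherical (ellipsoidal) nuclei, one pair of
diffraction-limited probe spots per nucleus whose 3D separation follows a
Gaussian-chain polymer model, radial placement drawn from a parameterised
fractional-radius distribution, additive Gaussian noise on top of a
deterministic optical signal, and anisotropic voxels.

The chain model is the minimal generative model consistent with the
random-walk behaviour of interphase chromatin: the vector between two loci
separated by g kb is isotropic Gaussian with per-axis variance c*g/3, so the
mean squared physical distance is exactly E[d^2] = c*g, linear in genomic
separation with compaction coefficient c (µm²/kb).  Smaller c means more
compact chromatin.

Every generator is a pure function of (parameters, seed): the same seed
yields a bit-identical cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import ImageStack, NucleusROI, DEFAULT_CHANNELS

__all__ = [
    "ChainModel",
    "RadialModel",
    "NucleusGeometry",
    "ImagingModel",
    "NucleusModel",
    "RegionSpec",
    "CohortConfig",
    "PlacedPair",
    "PlacedNucleus",
    "StackBundle",
    "CohortDataset",
    "sample_chain_displacement",
    "sample_radial_fraction",
    "place_probe_pair",
    "render_stack",
    "iter_cohort",
    "generate_cohort",
    "sample_cohort_truth",
    "ellipse_edge_distance",
]

# Fraction of the z semi-axis within which probe-pair midpoints are placed
# (scaled by 1 - f so that f = 1 forces the 3D nucleus centre).
Z_BAND = 0.6

#: Default DAPI fill intensity as a fraction of the probe spot amplitude.
DAPI_LEVEL = 0.6


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainModel:
    """Gaussian-chain model of inter-locus physical distance.

    Parameters
    ----------
    c : float
        Compaction coefficient, µm² per kb (> 0).  E[d²] = c·g.
    g : float
        Genomic separation of the probe pair, kb (>= 0).
    """

    c: float
    g: float

    def __post_init__(self):
        if not self.c > 0:
            raise ValueError(f"compaction coefficient c must be > 0, got {self.c}")
        if self.g < 0:
            raise ValueError(f"genomic separation g must be >= 0, got {self.g}")

    @property
    def axis_sd(self) -> float:
        """Per-axis displacement standard deviation sqrt(c*g/3), µm."""
        return math.sqrt(self.c * self.g / 3.0)


@dataclass(frozen=True)
class RadialModel:
    """Generative distribution of nuclear fractional radius f in [0, 1].

    ``family="beta"`` draws f ~ Beta(a, b); ``family="uniform_volume"`` is
    the analytic reference of a point uniform in a sphere, for which
    P(f <= x) = 1 - (1 - x)^3 with f the distance-to-edge over radius.
    """

    family: str
    a: float = 1.0
    b: float = 1.0

    def __post_init__(self):
        if self.family not in ("beta", "uniform_volume"):
            raise ValueError(f"unknown radial family {self.family!r}")
        if self.family == "beta" and not (self.a > 0 and self.b > 0):
            raise ValueError("beta shape parameters must be positive")


@dataclass(frozen=True)
class NucleusGeometry:
    """An ellipsoidal nucleus: centre (z,y,x) µm, semi-axes (z,y,x) µm,
    rotation about the z axis (radians)."""

    centre: tuple
    semi_axes: tuple
    orientation: float = 0.0

    def __post_init__(self):
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("all semi-axes must be positive")

    def to_local(self, points_um: np.ndarray) -> np.ndarray:
        """Map stack-frame µm points (N,3) into the nucleus frame."""
        p = np.atleast_2d(points_um) - np.asarray(self.centre)
        ct, st = math.cos(self.orientation), math.sin(self.orientation)
        y = ct * p[:, 1] + st * p[:, 2]
        x = -st * p[:, 1] + ct * p[:, 2]
        return np.column_stack([p[:, 0], y, x])

    def to_lab(self, points_local: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points_local)
        ct, st = math.cos(self.orientation), math.sin(self.orientation)
        y = ct * p[:, 1] - st * p[:, 2]
        x = st * p[:, 1] + ct * p[:, 2]
        return np.column_stack([p[:, 0], y, x]) + np.asarray(self.centre)

    def contains(self, points_um: np.ndarray, shrink: float = 1.0) -> np.ndarray:
        loc = self.to_local(points_um) / np.asarray(self.semi_axes)
        return (loc ** 2).sum(axis=1) < shrink ** 2


@dataclass(frozen=True)
class ImagingModel:
    """Optical and detector model for stack rendering.

    voxel_size and psf_sigma are (z, y, x) in µm; spot_amplitude, background
    and noise_sd are detector counts; channel_shift maps probe channel name
    to its applied (y, x) offset in voxels (DAPI is the reference frame).
    """

    voxel_size: tuple = (0.125, 0.04, 0.04)
    psf_sigma: tuple = (0.15, 0.05, 0.05)
    spot_amplitude: float = 1100.0
    background: float = 100.0
    noise_sd: float = 100.0
    channel_shift: dict = field(default_factory=lambda: {"probeA": (0, 0),
                                                         "probeB": (0, 0)})

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size) or any(s <= 0 for s in self.psf_sigma):
            raise ValueError("voxel sizes and psf sigmas must be positive")
        if not self.spot_amplitude > self.background >= 0:
            raise ValueError("need spot_amplitude > background >= 0 "
                             "(spot undetectable by construction otherwise)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def snr(self) -> float:
        """(amplitude - background) / noise_sd; inf for noiseless."""
        if self.noise_sd == 0:
            return math.inf
        return (self.spot_amplitude - self.background) / self.noise_sd


@dataclass(frozen=True)
class NucleusModel:
    """Population model for nucleus shape: mean semi-axes (z, y, x) µm and a
    relative uniform jitter applied per axis; orientation uniform in [0, pi)."""

    semi_axes: tuple = (1.4, 2.2, 1.8)
    jitter: float = 0.12


@dataclass(frozen=True)
class RegionSpec:
    """One tissue region/condition arm of a cohort."""

    region: str
    condition: str
    chain: ChainModel
    radial: RadialModel


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort.

    The sampling design mirrors the study layout: ``n_nuclei`` nuclei per
    region in each of ``n_embryos`` embryos per condition (one stack per
    embryo x region).
    """

    regions: tuple
    n_embryos: int = 3
    n_nuclei: int = 50
    imaging: ImagingModel = field(default_factory=ImagingModel)
    nucleus: NucleusModel = field(default_factory=NucleusModel)
    seed: int = 0

    def __post_init__(self):
        if self.n_embryos < 1 or self.n_nuclei < 1:
            raise ValueError("n_embryos and n_nuclei must be >= 1")
        keys = [(r.region, r.condition) for r in self.regions]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate region/condition labels: {keys}")


# ---------------------------------------------------------------------------
# Geometry samplers
# ---------------------------------------------------------------------------

def sample_chain_displacement(model: ChainModel, n: int, seed) -> np.ndarray:
    """Draw n i.i.d. 3D inter-probe displacement vectors (µm).

    Isotropic Gaussian with per-axis variance c*g/3, so E[||v||^2] = c*g.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    if model.g == 0:
        return np.zeros((n, 3))
    return rng.normal(0.0, model.axis_sd, size=(n, 3))


def sample_radial_fraction(model: RadialModel, n: int, seed) -> np.ndarray:
    """Draw n fractional radii in [0, 1] from the radial placement model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    if model.family == "beta":
        return rng.beta(model.a, model.b, size=n)
    # uniform in sphere: radius r = U^(1/3); f = 1 - r  =>  P(f<=x) = 1-(1-x)^3
    return 1.0 - rng.uniform(0.0, 1.0, size=n) ** (1.0 / 3.0)


# -- exact point-to-ellipse distance ----------------------------------------

def ellipse_edge_distance(semi_y: float, semi_x: float, y: float, x: float) -> float:
    """Exact Euclidean distance from a point to the ellipse boundary
    (y/semi_y)^2 + (x/semi_x)^2 = 1, valid inside and outside.

    Uses the standard root-finding formulation on the Lagrange parameter,
    with closed forms on the axes.
    """
    # order axes so e0 >= e1
    if semi_y >= semi_x:
        e0, e1, p0, p1 = semi_y, semi_x, abs(y), abs(x)
    else:
        e0, e1, p0, p1 = semi_x, semi_y, abs(x), abs(y)
    if p0 == 0.0 and p1 == 0.0:
        return e1
    if abs(e0 - e1) <= 1e-12 * e0:  # circle
        return abs(e0 - math.hypot(p0, p1))
    if p1 == 0.0:
        # on the major axis; nearest point may be off-axis inside the evolute
        crit = (e0 * e0 - e1 * e1) / e0
        if p0 < crit:
            q0 = e0 * e0 * p0 / (e0 * e0 - e1 * e1)
            q1 = e1 * math.sqrt(max(0.0, 1.0 - (q0 / e0) ** 2))
            return math.hypot(q0 - p0, q1)
        return abs(e0 - p0)
    if p0 == 0.0:
        # on the minor axis the co-vertex is always the nearest point
        return abs(e1 - p1)

    def f(t):
        return ((e0 * p0 / (t + e0 * e0)) ** 2
                + (e1 * p1 / (t + e1 * e1)) ** 2 - 1.0)

    lo = -e1 * e1 + 1e-14 * e1 * e1 + 1e-300
    hi = e0 * p0 + e1 * p1  # f(hi) < 0 guaranteed (loose upper bound)
    while f(hi) > 0:
        hi = 2.0 * hi + e0
    for _ in range(120):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    q0 = e0 * e0 * p0 / (t + e0 * e0)
    q1 = e1 * e1 * p1 / (t + e1 * e1)
    return math.hypot(q0 - p0, q1 - p1)


def _slice_frac_radius(semi_y: float, semi_x: float, y: float, x: float) -> float:
    """In-slice fractional radius: edge distance over half the max Feret
    diameter (= the larger semi-axis) of the slice ellipse."""
    return ellipse_edge_distance(semi_y, semi_x, y, x) / max(semi_y, semi_x)


@dataclass
class PlacedPair:
    """A placed probe pair with its ground truth."""

    centroid_a: tuple   # (z, y, x) µm, stack frame
    centroid_b: tuple
    d_um: float
    d2_um2: float
    f_sampled: float    # fractional radius drawn from the radial model
    f_mid: float        # attained in-slice f at the pair midpoint
    f_probe_b: float    # analytic in-slice f at the probe-B centroid
    resamples: int


def _place_midpoint(nucleus: NucleusGeometry, radial: RadialModel,
                    rng: np.random.Generator):
    """Sample a pair midpoint at a radial-model draw of in-slice fractional
    radius (nucleus frame).  Returns (midpoint, f_sampled, f_attained)."""
    az, ay, ax = nucleus.semi_axes
    f = float(sample_radial_fraction(radial, 1, rng)[0])
    dz = float(rng.uniform(-1.0, 1.0)) * (1.0 - f) * Z_BAND * az
    scale = math.sqrt(max(0.0, 1.0 - (dz / az) ** 2))
    ey, ex = ay * scale, ax * scale
    f_max = min(ey, ex) / max(ey, ex)
    phi = float(rng.uniform(0.0, 2.0 * math.pi))
    if f >= f_max:
        py = px = 0.0
        f_mid = f_max
    elif abs(ey - ex) <= 1e-12 * max(ey, ex):
        # circular slice: edge distance is radial, invertible in closed form
        rho = (1.0 - f) * ey
        py, px = rho * math.sin(phi), rho * math.cos(phi)
        f_mid = f
    else:
        # bisect the ray towards the boundary point at parametric angle phi
        by, bx = ey * math.sin(phi), ex * math.cos(phi)
        lo, hi = 0.0, 1.0  # f(lo) = f_max > f, f(hi) = 0 < f
        for _ in range(60):
            s = 0.5 * (lo + hi)
            if _slice_frac_radius(ey, ex, s * by, s * bx) > f:
                lo = s
            else:
                hi = s
        s = 0.5 * (lo + hi)
        py, px = s * by, s * bx
        f_mid = f
    return np.array([dz, py, px]), f, f_mid


def place_probe_pair(nucleus: NucleusGeometry, chain: ChainModel,
                     radial: RadialModel, seed,
                     max_resamples: int = 100,
                     max_position_redraws: int = 50) -> PlacedPair:
    """Place one probe pair inside a nucleus.

    The pair midpoint is put where the in-slice fractional radius (edge
    distance over half the slice Feret diameter, the measurement definition)
    equals a draw from the radial model; the midpoint's z-offset from the
    equator shrinks with f so that f = 1 lands exactly at the nucleus centre.
    The displacement between the two probes is drawn from the chain model and
    resampled (up to ``max_resamples`` times) if either centroid would fall
    outside the nucleus.  A midpoint so close to the boundary that no drawn
    displacement fits (possible when the radial draw is ~0) is itself redrawn;
    total displacement redraws are reported in ``resamples``.

    Raises
    ------
    RuntimeError
        If no placement fits inside the nucleus within the resample budgets
        (the nucleus is too small for the sampled separation scale).
    """
    rng = _rng(seed)
    az, ay, ax = nucleus.semi_axes
    semi = np.asarray(nucleus.semi_axes)
    total_resamples = 0
    placed = False
    for _ in range(max_position_redraws):
        mid, f, f_mid = _place_midpoint(nucleus, radial, rng)
        for _ in range(max_resamples + 1):
            v = sample_chain_displacement(chain, 1, rng)[0]
            a = mid - v / 2.0
            b = mid + v / 2.0
            if ((a / semi) ** 2).sum() < 1.0 and ((b / semi) ** 2).sum() < 1.0:
                placed = True
                break
            total_resamples += 1
        if placed:
            break
    if not placed:
        raise RuntimeError(
            f"probe pair does not fit inside nucleus (semi-axes {nucleus.semi_axes} µm, "
            f"c*g = {chain.c * chain.g:.4g} µm²) after {total_resamples} resamples")
    attempt = total_resamples
    # analytic in-slice f at the probe-B position (what measurement estimates)
    sb = math.sqrt(max(1e-12, 1.0 - (b[0] / az) ** 2))
    f_b = _slice_frac_radius(ay * sb, ax * sb, b[1], b[2])
    a_lab = nucleus.to_lab(a[None, :])[0]
    b_lab = nucleus.to_lab(b[None, :])[0]
    d = float(np.linalg.norm(b_lab - a_lab))
    return PlacedPair(
        centroid_a=tuple(float(u) for u in a_lab),
        centroid_b=tuple(float(u) for u in b_lab),
        d_um=d, d2_um2=d * d,
        f_sampled=f, f_mid=f_mid, f_probe_b=f_b,
        resamples=attempt,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

@dataclass
class PlacedNucleus:
    nucleus_id: str
    embryo_id: str
    region: str
    condition: str
    geometry: NucleusGeometry
    pair: PlacedPair


def render_stack(nuclei: Sequence[PlacedNucleus], imaging: ImagingModel, seed,
                 shape: Optional[tuple] = None) -> ImageStack:
    """Render a 3-channel stack (dapi, probeA, probeB) from placed nuclei.

    The DAPI channel is the union of smoothed ellipsoid interiors; each probe
    channel holds one Gaussian spot per nucleus at its true centroid.  All
    channels get the constant background plus additive Gaussian noise and the
    probe channels are then translated by their configured (y, x) shift.
    Intensities are quantised to uint16.  Deterministic under ``seed``.
    """
    if not nuclei:
        raise ValueError("need at least one nucleus")
    rng = _rng(seed)
    vox = np.asarray(imaging.voxel_size)
    if shape is None:
        shape = _bounding_shape(nuclei, vox)
    for nuc in nuclei:
        c = np.asarray(nuc.geometry.centre)
        ext = _axis_extents(nuc.geometry)
        if (c - ext < 0).any() or ((c + ext) / vox >= np.asarray(shape)).any():
            raise ValueError(f"nucleus {nuc.nucleus_id} does not fit in stack bounds")
    chans = np.zeros((3,) + tuple(shape), dtype=np.float32)
    psf_vox = np.asarray(imaging.psf_sigma) / vox
    for nuc in nuclei:
        _paint_nucleus_dapi(chans[0], nuc.geometry, vox, psf_vox,
                            DAPI_LEVEL * imaging.spot_amplitude)
        _paint_spot(chans[1], np.asarray(nuc.pair.centroid_a) / vox, psf_vox,
                    imaging.spot_amplitude - imaging.background)
        _paint_spot(chans[2], np.asarray(nuc.pair.centroid_b) / vox, psf_vox,
                    imaging.spot_amplitude - imaging.background)
    out = np.empty_like(chans, dtype=np.uint16)
    noise = np.empty(chans.shape[1:], dtype=np.float32) if imaging.noise_sd > 0 else None
    for ci, name in enumerate(DEFAULT_CHANNELS):
        ch = chans[ci]
        ch += imaging.background
        if noise is not None:
            rng.standard_normal(out=noise, dtype=np.float32)
            np.multiply(noise, imaging.noise_sd, out=noise)
            ch += noise
        sy, sx = imaging.channel_shift.get(name, (0, 0))
        if (sy != 0 or sx != 0) and not (float(sy).is_integer()
                                         and float(sx).is_integer()):
            ch = ndimage.shift(ch, (0.0, float(sy), float(sx)), order=1,
                               mode="constant", cval=imaging.background)
            sy = sx = 0
        np.rint(ch, out=ch)
        np.clip(ch, 0, 65535, out=ch)
        buf = ch.astype(np.uint16)
        if sy != 0 or sx != 0:
            shifted = np.full_like(buf, int(round(imaging.background)))
            ny, nx = buf.shape[1], buf.shape[2]
            dy, dx = int(sy), int(sx)
            shifted[:, max(dy, 0):ny + min(dy, 0), max(dx, 0):nx + min(dx, 0)] = \
                buf[:, max(-dy, 0):ny + min(-dy, 0), max(-dx, 0):nx + min(-dx, 0)]
            buf = shifted
        out[ci] = buf
    return ImageStack(out, DEFAULT_CHANNELS, tuple(imaging.voxel_size))


def _axis_extents(geom: NucleusGeometry) -> np.ndarray:
    """Half-extent of the (z-rotated) ellipsoid along each lab axis, µm."""
    az, ay, ax = geom.semi_axes
    return np.array([az, max(ay, ax), max(ay, ax)])


def _bounding_shape(nuclei, vox):
    hi = np.zeros(3)
    for nuc in nuclei:
        c = np.asarray(nuc.geometry.centre)
        hi = np.maximum(hi, c + _axis_extents(nuc.geometry))
    return tuple(int(math.ceil(v)) for v in (hi + 0.6) / vox)


def _paint_nucleus_dapi(channel, geom: NucleusGeometry, vox, psf_vox, level):
    c = np.asarray(geom.centre)
    ext = _axis_extents(geom)
    pad = 4
    lo = np.maximum(((c - ext) / vox).astype(int) - pad, 0)
    hi = np.minimum(((c + ext) / vox).astype(int) + pad + 1, channel.shape)
    az, ay, ax = geom.semi_axes
    ct, st = math.cos(geom.orientation), math.sin(geom.orientation)
    dz = np.arange(lo[0], hi[0], dtype=np.float32) * vox[0] - c[0]
    dy = np.arange(lo[1], hi[1], dtype=np.float32) * vox[1] - c[1]
    dx = np.arange(lo[2], hi[2], dtype=np.float32) * vox[2] - c[2]
    ry = ct * dy[:, None] + st * dx[None, :]
    rx = -st * dy[:, None] + ct * dx[None, :]
    q_yx = (ry / ay) ** 2 + (rx / ax) ** 2
    inside = (dz / az)[:, None, None] ** 2 + q_yx[None, :, :] < 1.0
    blob = ndimage.gaussian_filter(inside.astype(np.float32) * np.float32(level),
                                   sigma=psf_vox)
    channel[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += blob


def _paint_spot(channel, centre_vox, psf_vox, amplitude):
    lo = np.maximum((centre_vox - 6 * psf_vox).astype(int), 0)
    hi = np.minimum((centre_vox + 6 * psf_vox).astype(int) + 2, channel.shape)
    axes = [np.arange(lo[a], hi[a], dtype=np.float64) for a in range(3)]
    q = [np.exp(-0.5 * ((ax - centre_vox[a]) / psf_vox[a]) ** 2)
         for a, ax in enumerate(axes)]
    spot = amplitude * q[0][:, None, None] * q[1][None, :, None] * q[2][None, None, :]
    channel[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += spot.astype(np.float32)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: ROI margins around the probe-pair bounding box, voxels.
ROI_MARGIN_Z = 5
ROI_MARGIN_YX = 14

#: Clearance between neighbouring nuclei in a rendered field, µm.
GRID_CLEARANCE = 2.2


@dataclass
class StackBundle:
    """One embryo x region field: rendered stack plus ROI and truth tables."""

    region: str
    condition: str
    embryo_id: str
    stack: Optional[ImageStack]
    rois: pd.DataFrame
    truth: pd.DataFrame


@dataclass
class CohortDataset:
    """An in-memory synthetic cohort."""

    config: CohortConfig
    bundles: List[StackBundle]

    @property
    def rois(self) -> pd.DataFrame:
        return pd.concat([b.rois for b in self.bundles], ignore_index=True)

    @property
    def truth(self) -> pd.DataFrame:
        return pd.concat([b.truth for b in self.bundles], ignore_index=True)


ROI_COLUMNS = ["nucleus_id", "embryo_id", "region", "condition",
               "z0", "z1", "y0", "y1", "x0", "x1"]
TRUTH_COLUMNS = ["nucleus_id", "embryo_id", "region", "condition",
                 "true_d_um", "true_d2_um2", "true_frac_radius", "f_sampled",
                 "resamples",
                 "a_z_um", "a_y_um", "a_x_um", "b_z_um", "b_y_um", "b_x_um",
                 "centre_z_um", "centre_y_um", "centre_x_um",
                 "semi_z_um", "semi_y_um", "semi_x_um", "orientation_rad"]


def iter_cohort(config: CohortConfig, render: bool = True) -> Iterator[StackBundle]:
    """Yield one StackBundle per embryo x region, deterministically.

    With ``render=False`` the stacks are omitted (geometry-level cohort:
    ground truth and ROI tables only), which is orders of magnitude faster
    and is the right substrate for statistical calibration experiments.
    """
    vox = np.asarray(config.imaging.voxel_size)
    for ri, spec in enumerate(config.regions):
        for ei in range(config.n_embryos):
            geom_rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(ri, ei, 0)))
            render_rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(ri, ei, 1)))
            embryo_id = f"e{ei + 1}"
            placed, shape = _layout_field(config, spec, embryo_id, geom_rng)
            rois, truth = _tables_for(placed, vox, shape)
            stack = render_stack(placed, config.imaging, render_rng,
                                 shape=shape) if render else None
            yield StackBundle(spec.region, spec.condition, embryo_id,
                              stack, rois, truth)


def _layout_field(config: CohortConfig, spec: RegionSpec, embryo_id: str,
                  rng: np.random.Generator):
    """Place n_nuclei jittered ellipsoid nuclei on a grid and fill each with
    one probe pair."""
    nm = config.nucleus
    base = np.asarray(nm.semi_axes)
    max_xy = base[1:].max() * (1.0 + nm.jitter)
    max_z = base[0] * (1.0 + nm.jitter)
    pitch = 2.0 * max_xy + GRID_CLEARANCE
    ncols = int(math.ceil(math.sqrt(config.n_nuclei)))
    nrows = int(math.ceil(config.n_nuclei / ncols))
    margin = max_xy + 0.8
    zc = max_z + 0.8
    size_um = np.array([2.0 * zc,
                        (nrows - 1) * pitch + 2.0 * margin,
                        (ncols - 1) * pitch + 2.0 * margin])
    vox = np.asarray(config.imaging.voxel_size)
    shape = tuple(int(math.ceil(s / v)) for s, v in zip(size_um, vox))
    placed = []
    for k in range(config.n_nuclei):
        row, col = divmod(k, ncols)
        semi = base * (1.0 + nm.jitter * rng.uniform(-1.0, 1.0, size=3))
        centre = np.array([zc + rng.uniform(-0.2, 0.2),
                           margin + row * pitch + rng.uniform(-0.3, 0.3),
                           margin + col * pitch + rng.uniform(-0.3, 0.3)])
        geom = NucleusGeometry(tuple(centre), tuple(semi),
                               float(rng.uniform(0.0, math.pi)))
        pair = place_probe_pair(geom, spec.chain, spec.radial, rng)
        nid = f"{spec.region}_{spec.condition}_{embryo_id}_n{k + 1:03d}"
        placed.append(PlacedNucleus(nid, embryo_id, spec.region,
                                    spec.condition, geom, pair))
    return placed, shape


def _tables_for(placed: Sequence[PlacedNucleus], vox, shape):
    roi_rows, truth_rows = [], []
    for nuc in placed:
        a = np.asarray(nuc.pair.centroid_a) / vox
        b = np.asarray(nuc.pair.centroid_b) / vox
        lo = np.floor(np.minimum(a, b)).astype(int)
        hi = np.ceil(np.maximum(a, b)).astype(int)
        m = np.array([ROI_MARGIN_Z, ROI_MARGIN_YX, ROI_MARGIN_YX])
        lo = np.maximum(lo - m, 0)
        hi = np.minimum(hi + m + 1, shape)
        roi_rows.append((nuc.nucleus_id, nuc.embryo_id, nuc.region, nuc.condition,
                         int(lo[0]), int(hi[0]), int(lo[1]), int(hi[1]),
                         int(lo[2]), int(hi[2])))
        g = nuc.geometry
        truth_rows.append((nuc.nucleus_id, nuc.embryo_id, nuc.region, nuc.condition,
                           nuc.pair.d_um, nuc.pair.d2_um2, nuc.pair.f_probe_b,
                           nuc.pair.f_sampled, nuc.pair.resamples,
                           *nuc.pair.centroid_a, *nuc.pair.centroid_b,
                           *g.centre, *g.semi_axes, g.orientation))
    rois = pd.DataFrame(roi_rows, columns=ROI_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return rois, truth


def generate_cohort(config: CohortConfig, render: bool = True) -> CohortDataset:
    """Materialise a full cohort in memory (see :func:`iter_cohort`).

    For large rendered cohorts prefer iterating :func:`iter_cohort` or
    writing to disk with :func:`fishloc.pipeline.write_cohort`; a rendered
    50-nucleus field is ~0.4 GB.
    """
    return CohortDataset(config, list(iter_cohort(config, render=render)))


def sample_cohort_truth(config: CohortConfig) -> pd.DataFrame:
    """Ground-truth measurement table of a cohort without rendering images."""
    return pd.concat([b.truth for b in iter_cohort(config, render=False)],
                     ignore_index=True)
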