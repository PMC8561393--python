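"""Synthetic inputs with known ground truth for every pipeline stage.

Generators for

* pinwheel colony geometries whose sector boundaries are logarithmic
  spirals of known chiral angle plus Brownian wander, and their
  rasterisation into two-channel images,
* linear fluorescence-recovery (twist) curves with known rate,
* bimodal cell-length samples with a known filamentous fraction,
* logistic growth curves with known maximal rate.

Everything is driven by `numpy.random.default_rng` under an explicit
seed and is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm

from .boundary import BoundaryTrace, ColonyImagePair, TraceSet

__all__ = [
    "SyntheticColonySpec",
    "GroundTruthBoundary",
    "TwistSimSpec",
    "LengthSampleSpec",
    "GrowthSimSpec",
    "generate_boundaries",
    "render_colony",
    "ground_truth_traceset",
    "generate_twist_curve",
    "generate_length_sample",
    "expected_fraction_above",
    "generate_growth_curve",
]


# ---------------------------------------------------------------------------
# Colony geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticColonySpec:
    """Ground-truth description of one synthetic pinwheel colony.

    Parameters
    ----------
    theta_true : float
        Chiral angle in degrees; positive bends boundaries clockwise
        when the colony is viewed from the top (air interface).
    n_sectors : int
        Number of sector boundaries launched at the homeland rim (>= 2;
        even numbers give strict channel alternation).
    r_i, r_max : float
        Homeland (initial) and final colony radius, um.
    wiggle_D : float
        Boundary-wander diffusion coefficient, rad^2 per unit ln(r).
    pixel_size : float
        um per pixel of the rendered image.
    image_px : int
        Side length of the (square) rendered image in pixels; must span
        the full colony (image_px * pixel_size >= 2 * r_max).
    seed : int
        RNG seed; all randomness derives from it.
    n_steps : int
        Samples per boundary, log-spaced in radius.
    """

    theta_true: float = 6.4
    n_sectors: int = 20
    r_i: float = 250.0
    r_max: float = 3000.0
    wiggle_D: float = 0.005
    pixel_size: float = 5.0
    image_px: int = 1250
    seed: int = 0
    n_steps: int = 600

    def __post_init__(self):
        if self.n_sectors < 2:
            raise ValueError("need at least 2 sector boundaries")
        if not 0 < self.r_i < self.r_max:
            raise ValueError("require 0 < r_i < r_max")
        if self.wiggle_D < 0:
            raise ValueError("wiggle_D must be >= 0")
        if self.image_px * self.pixel_size < 2 * self.r_max:
            raise ValueError("image must span at least 2 * r_max")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")


@dataclass(frozen=True)
class GroundTruthBoundary:
    """One sector boundary: ordered (r, phi) samples from r_i outward."""

    phi0: float
    r: np.ndarray
    phi: np.ndarray

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.r, self.phi])


def generate_boundaries(
    spec: SyntheticColonySpec, negate_wiggle: bool = False
) -> list[GroundTruthBoundary]:
    """Sector boundaries as noisy logarithmic spirals.

    Each boundary follows phi(r) = phi0 + s * ln(r / r_i) + W(ln(r / r_i))
    with s = tan(theta_true * pi / 180) and W a zero-mean Brownian path of
    variance wiggle_D per unit ln(r). Launch angles phi0 are equally
    spaced around the homeland rim. ``negate_wiggle`` flips the sign of
    every Brownian increment while keeping the seed, which together with
    negating theta_true produces the exact mirror colony.
    """
    rng = np.random.default_rng(spec.seed)
    u = np.linspace(0.0, np.log(spec.r_max / spec.r_i), spec.n_steps)
    r = spec.r_i * np.exp(u)
    s = np.tan(np.deg2rad(spec.theta_true))
    du = np.diff(u)
    boundaries = []
    for k in range(spec.n_sectors):
        phi0 = 2.0 * np.pi * k / spec.n_sectors
        if spec.wiggle_D > 0:
            dW = rng.normal(0.0, np.sqrt(spec.wiggle_D * du))
        else:
            dW = np.zeros_like(du)
        if negate_wiggle:
            dW = -dW
        W = np.concatenate([[0.0], np.cumsum(dW)])
        phi = phi0 + s * u + W
        boundaries.append(GroundTruthBoundary(phi0=phi0, r=r, phi=phi))
    return boundaries


def _check_ordering(boundaries: list[GroundTruthBoundary]) -> bool:
    """True when boundaries never cross (cyclic angular order preserved)."""
    phis = np.stack([b.phi for b in boundaries])  # (n_b, n_steps)
    rel = phis - phis[:1, :]  # relative to the first boundary
    # successive relative angles must stay strictly increasing
    return bool(np.all(np.diff(rel, axis=0) > 0))


def render_colony(
    boundaries: list[GroundTruthBoundary],
    spec: SyntheticColonySpec,
    blur_sigma: float = 0.0,
    level: int = 40000,
) -> ColonyImagePair:
    """Rasterise sector geometry into a registered two-channel image.

    The annulus r_i <= r <= r_max is partitioned into sectors of
    alternating channel identity: each pixel belongs to the sector of
    the boundary immediately behind it in angle at the pixel's radius
    (the bracketing rule, which for non-crossing boundaries equals the
    point-in-sector assignment; crossing boundaries trigger a warning
    and are resolved by the same deterministic rule). The homeland disk
    r < r_i is rendered with both channels on, mimicking the mixed
    central sector used for centre fitting; background is zero. Optional
    Gaussian blur emulates optical blur.
    """
    if len(boundaries) != spec.n_sectors:
        raise ValueError("boundary count does not match spec.n_sectors")
    if spec.n_sectors % 2 == 1:
        warnings.warn(
            "odd number of sectors: one adjacent pair shares a channel"
        )
    if not _check_ordering(boundaries):
        warnings.warn(
            "boundaries cross; ambiguous pixels assigned to the nearest "
            "preceding boundary in angle"
        )

    npx = spec.image_px
    c = (npx - 1) / 2.0
    coord = (np.arange(npx) - c) * spec.pixel_size
    xg, yg = np.meshgrid(coord, coord)  # yg indexes rows
    r_p = np.hypot(xg, yg)
    phi_p = np.arctan2(yg, xg)  # clockwise as displayed

    yfp = np.zeros((npx, npx), dtype=float)
    cfp = np.zeros((npx, npx), dtype=float)

    homeland = r_p < spec.r_i
    yfp[homeland] = 1.0
    cfp[homeland] = 1.0

    annulus = (r_p >= spec.r_i) & (r_p <= spec.r_max)
    lnr = np.log(r_p[annulus] / spec.r_i)
    pphi = phi_p[annulus]
    u = np.log(boundaries[0].r / spec.r_i)

    two_pi = 2.0 * np.pi
    best_delta = np.full(lnr.shape, np.inf)
    best_k = np.zeros(lnr.shape, dtype=np.int32)
    for k, b in enumerate(boundaries):
        phi_b = np.interp(lnr, u, b.phi)
        delta = np.mod(pphi - phi_b, two_pi)
        closer = delta < best_delta
        best_delta[closer] = delta[closer]
        best_k[closer] = k
    channel = best_k % 2
    ann_y = np.zeros(lnr.shape)
    ann_y[channel == 0] = 1.0
    yfp[annulus] = ann_y
    cfp[annulus] = 1.0 - ann_y
    cfp[homeland] = 1.0

    if blur_sigma > 0:
        import scipy.ndimage as ndi

        yfp = ndi.gaussian_filter(yfp, blur_sigma)
        cfp = ndi.gaussian_filter(cfp, blur_sigma)

    yfp16 = np.clip(yfp * level, 0, 65535).astype(np.uint16)
    cfp16 = np.clip(cfp * level, 0, 65535).astype(np.uint16)
    return ColonyImagePair(yfp16, cfp16, pixel_size=spec.pixel_size)


def ground_truth_traceset(
    boundaries: list[GroundTruthBoundary],
    colony_id: str = "ground-truth",
) -> TraceSet:
    """Package ground-truth boundaries as a TraceSet (radii in um).

    Lets the chirality estimator run directly on the generative curves,
    bypassing rendering and image analysis.
    """
    traces = [
        BoundaryTrace(b.r.copy(), b.phi.copy(), colony_id=colony_id,
                      trace_id=k)
        for k, b in enumerate(boundaries)
    ]
    return TraceSet(traces=traces, geometry=None,
                    r_min_used=float(boundaries[0].r[0]) if traces else 0.0)


# ---------------------------------------------------------------------------
# Twist-recovery curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwistSimSpec:
    """Linear fluorescence-recovery curve with known slope.

    lambda_true is the recovery rate per um of elongation on the
    prebleach-normalised scale; f_bleach is the normalised fluorescence
    immediately after the bleach (< 1).
    """

    lambda_true: float = 0.1
    dl_max: float = 5.0
    noise_sd: float = 0.0
    n_points: int = 25
    f_bleach: float = 0.3
    prebleach_F: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if self.lambda_true < 0:
            raise ValueError("lambda_true must be >= 0")
        if self.dl_max <= 0:
            raise ValueError("dl_max must be > 0")
        if self.n_points < 3:
            raise ValueError("need at least 3 points")
        if not 0 < self.f_bleach < 1:
            raise ValueError("f_bleach must lie in (0, 1)")


def generate_twist_curve(spec: TwistSimSpec, cell_id: str = "sim"):
    """Simulate one prebleach-normalised recovery curve.

    F(dl) = f_bleach + lambda_true * dl + noise, on the scale where the
    prebleach level is 1.
    """
    from .twist import TwistCurve

    rng = np.random.default_rng(spec.seed)
    dl = np.linspace(0.0, spec.dl_max, spec.n_points)
    F = spec.f_bleach + spec.lambda_true * dl
    if spec.noise_sd > 0:
        F = F + rng.normal(0.0, spec.noise_sd, size=dl.shape)
    return TwistCurve(delta_l=dl, F=F, prebleach_F=spec.prebleach_F,
                      cell_id=cell_id)


# ---------------------------------------------------------------------------
# Cell-length samples
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LengthSampleSpec:
    """Bimodal cell-length population: body mode plus filamentous tail.

    Non-filamentous lengths are Normal(body_mean, body_sd) truncated at
    zero. A ``filament_fraction`` of cells additionally carries a
    lognormal excess length with mean ``filament_scale`` um (ln-scale sd
    ``filament_shape``), so that for scales well above a division-length
    threshold essentially every filamentous cell exceeds it.
    """

    n_cells: int = 1000
    body_mean: float = 2.5
    body_sd: float = 0.4
    filament_fraction: float = 0.1
    filament_scale: float = 12.0
    filament_shape: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0 <= self.filament_fraction <= 1:
            raise ValueError("filament_fraction must lie in [0, 1]")
        if self.body_mean <= 0 or self.body_sd <= 0:
            raise ValueError("body mode parameters must be positive")
        if self.filament_scale <= 0 or self.filament_shape <= 0:
            raise ValueError("filament tail parameters must be positive")


def _lognormal_params(mean: float, shape: float) -> tuple[float, float]:
    """(mu, sigma) of ln X for a lognormal with given mean and ln-sd."""
    return np.log(mean) - 0.5 * shape**2, shape


def generate_length_sample(spec: LengthSampleSpec) -> np.ndarray:
    """Draw n_cells positive lengths from the body + filament mixture."""
    rng = np.random.default_rng(spec.seed)
    body = rng.normal(spec.body_mean, spec.body_sd, size=spec.n_cells)
    # truncate at zero by resampling (negligible for realistic params)
    bad = body <= 0
    while np.any(bad):
        body[bad] = rng.normal(spec.body_mean, spec.body_sd, size=bad.sum())
        bad = body <= 0
    is_fil = rng.random(spec.n_cells) < spec.filament_fraction
    mu, sig = _lognormal_params(spec.filament_scale, spec.filament_shape)
    excess = rng.lognormal(mu, sig, size=spec.n_cells)
    lengths = body + np.where(is_fil, excess, 0.0)
    return lengths


def expected_fraction_above(spec: LengthSampleSpec, threshold: float) -> float:
    """Mixture probability that a cell's length exceeds ``threshold``.

    P = (1 - f) * P(body > t) + f * P(body + excess > t), the second term
    evaluated by quadrature over the lognormal excess (truncation of the
    body mode at zero is ignored; it is negligible for body_mean several
    sd above zero).
    """
    f = spec.filament_fraction
    p_body = norm.sf(threshold, loc=spec.body_mean, scale=spec.body_sd)
    mu, sig = _lognormal_params(spec.filament_scale, spec.filament_shape)

    def integrand(x):
        # density of lognormal excess at x times P(body > t - x)
        pdf = np.exp(-((np.log(x) - mu) ** 2) / (2 * sig**2)) / (
            x * sig * np.sqrt(2 * np.pi)
        )
        return pdf * norm.sf(threshold - x, loc=spec.body_mean,
                             scale=spec.body_sd)

    p_fil, _ = quad(integrand, 1e-12, np.inf, limit=200)
    return float((1 - f) * p_body + f * p_fil)


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthSimSpec:
    """Logistic OD600 curve sampled at plate-reader cadence.

    rate is the intrinsic exponential rate in 1/min; the realised
    maximal slope of ln(OD) is rate * (1 - od0 / carrying_capacity),
    attained at the start of growth. carrying_capacity=inf gives a pure
    exponential. Multiplicative lognormal noise with sd ``noise_sd``
    emulates read noise.
    """

    rate: float = 0.02
    od0: float = 0.01
    carrying_capacity: float = 1.0
    t_max: float = 600.0
    dt: float = 7.5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.rate < 0 or self.od0 <= 0 or self.dt <= 0 or self.t_max <= 0:
            raise ValueError("invalid growth-curve parameters")
        if self.carrying_capacity <= self.od0:
            raise ValueError("carrying capacity must exceed od0")

    @property
    def max_lnod_slope(self) -> float:
        """Largest instantaneous d ln(OD)/dt of the noiseless curve, 1/min."""
        if np.isinf(self.carrying_capacity):
            return self.rate
        return self.rate * (1.0 - self.od0 / self.carrying_capacity)


def generate_growth_curve(spec: GrowthSimSpec) -> tuple[np.ndarray, np.ndarray]:
    """(times_min, od) arrays for one replicate of the logistic curve."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.t_max + 0.5 * spec.dt, spec.dt)
    if np.isinf(spec.carrying_capacity):
        od = spec.od0 * np.exp(spec.rate * t)
    else:
        K = spec.carrying_capacity
        od = K / (1.0 + (K - spec.od0) / spec.od0 * np.exp(-spec.rate * t))
    if spec.noise_sd > 0:
        od = od * np.exp(rng.normal(0.0, spec.noise_sd, size=t.shape))
    return t, od
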