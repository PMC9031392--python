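"""Ground-truth-annotated synthetic inputs for the degradation pipeline.

Two generators stand in for the wet-lab acquisitions:

* :func:`simulate_image_series` renders a time series of well photographs:
  bright polymer grains on darker agar, whose total pixel area follows a
  prescribed remaining-fraction trajectory exactly, while a white-ish
  filamentous mycelium spreads over the well.  Smooth multiplicative
  illumination and additive Gaussian noise are applied last, emulating the
  acquisition variability that makes threshold choice delicate in real
  imagery.
* :func:`simulate_spectrum` builds a 1H NMR spectrum with two resolved
  Lorentzian peaks — the hydroxy-acid monomer near 4.20 ppm and the intact
  polymer chain near 5.20 ppm — whose analytic integrals split a unit total
  as ``d : (1 - d)`` for a degradation fraction ``d``.

Every generator consumes one explicit integer seed and touches no global
random state, so identical calls are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .images import ImageSeries, circular_mask
from .kinetics import KineticCurve
from .nmr import Spectrum

__all__ = [
    "SceneParams",
    "TruthTrajectory",
    "SpectrumParams",
    "SimulatedImageSeries",
    "SimulatedSpectrum",
    "logistic_trajectory",
    "simulate_image_series",
    "simulate_kinetic_curves",
    "simulate_spectrum",
    "simulate_spectrum_series",
    "DEFAULT_BLEND_T50",
]

#: Default study design: nominal plasticizer content (w%) -> true t50 (h).
#: Higher plasticizer fractions degrade faster; the pure polymer is slowest.
DEFAULT_BLEND_T50: dict[str, float] = {
    "BDF00": 300.0,
    "BDF05": 220.0,
    "BDF20": 150.0,
    "BDF40": 100.0,
}


@dataclass
class SceneParams:
    """Rendering parameters for one synthetic well series.

    Intensities are grey levels in [0, 1] and must satisfy
    ``grain > mycelium > agar`` so that a threshold interval separating
    grains from everything else exists by construction.
    """

    image_size: tuple[int, int] = (512, 512)
    well_center: tuple[float, float] | None = None  # default: image centre
    well_radius: float | None = None  # default: 0.45 * min(image_size)
    n_grains: int = 40
    grain_radius_range: tuple[float, float] = (5.0, 9.0)
    grain_intensity: float = 0.9
    agar_intensity: float = 0.2
    mycelium_intensity: float = 0.55
    mycelium_growth_rate: float = 0.002  # fraction of well area per hour
    illumination_gradient: float = 0.1  # max relative deviation of the field
    noise_sd: float = 0.02  # additive Gaussian, grey levels
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if self.well_center is None:
            self.well_center = ((h - 1) / 2.0, (w - 1) / 2.0)
        if self.well_radius is None:
            self.well_radius = 0.45 * min(h, w)
        for name in ("grain_intensity", "agar_intensity", "mycelium_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.grain_intensity > self.mycelium_intensity > self.agar_intensity:
            raise ValueError("intensities must satisfy grain > mycelium > agar")
        cy, cx = self.well_center
        if (
            cy - self.well_radius < 0
            or cx - self.well_radius < 0
            or cy + self.well_radius > h - 1
            or cx + self.well_radius > w - 1
        ):
            raise ValueError("well does not fit inside the image")
        if self.grain_radius_range[0] <= 0 or self.grain_radius_range[0] > self.grain_radius_range[1]:
            raise ValueError("invalid grain radius range")
        if self.n_grains < 1:
            raise ValueError("need at least one grain")
        if self.mycelium_growth_rate < 0 or self.noise_sd < 0 or self.illumination_gradient < 0:
            raise ValueError("rates, noise and gradient must be non-negative")


@dataclass
class TruthTrajectory:
    """Prescribed remaining-polymer fraction over time.

    ``remaining_fraction`` starts at exactly 1 and lives in [0, 1];
    ``t50_true`` is the first time the (continuous) trajectory crosses 0.5,
    interpolated linearly on the grid when not supplied by the constructor.
    """

    times: np.ndarray
    remaining_fraction: np.ndarray
    t50_true: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.remaining_fraction = np.asarray(self.remaining_fraction, dtype=float)
        if self.times.size == 0:
            raise ValueError("trajectory must have at least one time point")
        if self.times.shape != self.remaining_fraction.shape:
            raise ValueError("times and remaining_fraction differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.remaining_fraction[0] != 1.0:
            raise ValueError("remaining_fraction must start at exactly 1")
        if np.any(self.remaining_fraction < 0) or np.any(self.remaining_fraction > 1):
            raise ValueError("remaining_fraction must lie in [0, 1]")
        if self.t50_true is None:
            self.t50_true = self._grid_t50()

    def _grid_t50(self) -> float | None:
        r, t = self.remaining_fraction, self.times
        below = np.nonzero(r <= 0.5)[0]
        if below.size == 0:
            return None
        i = int(below[0])
        if r[i] == 0.5 or i == 0:
            return float(t[i])
        # linear interpolation between the bracketing grid points
        frac = (r[i - 1] - 0.5) / (r[i - 1] - r[i])
        return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def logistic_trajectory(times: np.ndarray, t50: float, steepness: float = 0.03) -> TruthTrajectory:
    """Sigmoidal consumption trajectory crossing 0.5 exactly at ``t50``.

    A falling logistic ``L(t) = 1 / (1 + exp(k (t - m)))`` is renormalized
    to start at 1 at ``times[0]``; the midpoint ``m`` is solved so that the
    renormalized curve equals 0.5 at ``t50``.  ``steepness`` is the logistic
    rate ``k`` in 1/h (default 0.03/h: the 10-90% consumption transition
    spans roughly 150 h, comparable to a two-week incubation).
    """
    times = np.asarray(times, dtype=float)
    t = times - times[0]
    k, t50_rel = steepness, t50 - times[0]
    if k * t50_rel <= math.log(2.0):
        raise ValueError("t50 too early for this steepness: renormalized curve cannot cross 0.5")
    m = math.log(math.exp(k * t50_rel) - 2.0) / k
    raw = 1.0 / (1.0 + np.exp(k * (t - m)))
    r = raw / raw[0]
    r[0] = 1.0
    return TruthTrajectory(times=times, remaining_fraction=r, t50_true=float(t50))


@dataclass
class SimulatedImageSeries:
    """An image series plus the ground truth it was rendered from."""

    series: ImageSeries
    truth_masks: list[np.ndarray]
    truth_table: pd.DataFrame  # columns: time_h, true_grain_px
    params: SceneParams
    trajectory: TruthTrajectory


def _place_grains(params: SceneParams, rng: np.random.Generator):
    """Sample non-overlapping grain centres and radii inside the well."""
    cy, cx = params.well_center
    r_lo, r_hi = params.grain_radius_range
    centres: list[tuple[float, float]] = []
    radii: list[float] = []
    attempts = 0
    while len(centres) < params.n_grains:
        if attempts > 2000 * params.n_grains:
            raise ValueError("grains cannot fit in well: placement failed")
        attempts += 1
        r_grain = rng.uniform(r_lo, r_hi)
        margin = params.well_radius - r_grain - 1.0
        if margin <= 0:
            raise ValueError("grains cannot fit in well: grain larger than well")
        rho = margin * math.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * math.pi)
        gy, gx = cy + rho * math.sin(theta), cx + rho * math.cos(theta)
        if all(
            (gy - oy) ** 2 + (gx - ox) ** 2 > (r_grain + orad + 1.0) ** 2
            for (oy, ox), orad in zip(centres, radii)
        ):
            centres.append((gy, gx))
            radii.append(r_grain)
    return centres, radii


def _grain_pixels(shape, centre, radius):
    """Pixels of one grain ordered centre-outwards (for radial shrinkage)."""
    gy, gx = centre
    y0, y1 = int(math.floor(gy - radius)), int(math.ceil(gy + radius)) + 1
    x0, x1 = int(math.floor(gx - radius)), int(math.ceil(gx + radius)) + 1
    yy, xx = np.mgrid[max(y0, 0) : min(y1, shape[0]), max(x0, 0) : min(x1, shape[1])]
    d2 = (yy - gy) ** 2 + (xx - gx) ** 2
    inside = d2 <= radius**2
    order = np.argsort(d2[inside], kind="stable")
    return yy[inside][order], xx[inside][order]


def _mycelium_order(params: SceneParams, rng: np.random.Generator, n_target: int) -> np.ndarray:
    """Ordered unique in-well pixels visited by correlated random walks.

    Filaments start at random points in the well and wander with Gaussian
    turning angles; the visit order defines cumulative growth, so the
    colony at a later time is a superset of the colony at an earlier one.
    Returns flat (row-major) pixel indices, length >= ``n_target`` unless
    the walk budget is exhausted.
    """
    h, w = params.image_size
    cy, cx = params.well_center
    visited = np.zeros(h * w, dtype=bool)
    order: list[np.ndarray] = []
    n_found = 0
    step_budget = 200  # filaments per batch
    for _ in range(200):
        if n_found >= n_target:
            break
        for _ in range(step_budget):
            rho = 0.95 * params.well_radius * math.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            turns = rng.normal(0.0, 0.3, size=400)
            heading = rng.uniform(0.0, 2.0 * math.pi) + np.cumsum(turns)
            ys = cy + rho * math.sin(theta) + np.cumsum(np.sin(heading))
            xs = cx + rho * math.cos(theta) + np.cumsum(np.cos(heading))
            rr = np.round(ys).astype(np.int64)
            cc = np.round(xs).astype(np.int64)
            ok = (
                (rr >= 0)
                & (rr < h)
                & (cc >= 0)
                & (cc < w)
                & ((ys - cy) ** 2 + (xs - cx) ** 2 <= params.well_radius**2)
            )
            flat = rr[ok] * w + cc[ok]
            fresh = flat[~visited[flat]]
            # keep first occurrence only, preserving visit order
            _, first = np.unique(fresh, return_index=True)
            fresh = fresh[np.sort(first)]
            visited[fresh] = True
            order.append(fresh)
            n_found += fresh.size
            if n_found >= n_target:
                break
    return np.concatenate(order) if order else np.empty(0, dtype=np.int64)


def _illumination_field(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field with max relative deviation = gradient."""
    h, w = params.image_size
    if params.illumination_gradient == 0:
        return np.ones((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    u = 2.0 * yy / (h - 1) - 1.0
    v = 2.0 * xx / (w - 1) - 1.0
    a, b, c = rng.uniform(-1.0, 1.0, size=3)
    raw = a * u + b * v + c * u * v
    peak = np.abs(raw).max()
    if peak == 0:
        return np.ones((h, w))
    return 1.0 + params.illumination_gradient * raw / peak


def simulate_image_series(params: SceneParams, trajectory: TruthTrajectory) -> SimulatedImageSeries:
    """Render one well's time series with exact ground-truth grain areas.

    Grains shrink radially: at each time the ``round(n0 * f)`` pixels
    closest to a grain's centre remain, where ``n0`` is its initial pixel
    count and ``f`` the remaining fraction, so the total white area tracks
    the trajectory to within half a pixel per grain.  A grain whose target
    area falls below one pixel disappears.  Mycelium coverage grows to
    ``min(1, rate * t)`` of the well area along a fixed filament visit
    order.  Illumination and noise are applied after composition and the
    result is clipped to [0, 1].
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    if trajectory.remaining_fraction[0] != 1.0:
        raise ValueError("trajectory must start at remaining fraction 1")

    well = circular_mask((h, w), params.well_center, params.well_radius)
    well_area = int(well.sum())
    centres, radii = _place_grains(params, rng)
    grains = [_grain_pixels((h, w), c, r) for c, r in zip(centres, radii)]
    n0 = np.array([len(g[0]) for g in grains])

    # one fixed growth order shared by all frames -> monotone colonisation
    t_rel = trajectory.times - trajectory.times[0]
    cover_frac = np.minimum(1.0, params.mycelium_growth_rate * t_rel)
    cover_px = np.round(cover_frac * well_area).astype(int)
    myc_order = (
        _mycelium_order(params, rng, int(cover_px.max())) if cover_px.max() > 0 else np.empty(0, int)
    )

    illum = _illumination_field(params, rng)
    background = 0.25 * params.agar_intensity

    frames: list[np.ndarray] = []
    truth_masks: list[np.ndarray] = []
    counts: list[int] = []
    for f, k_myc in zip(trajectory.remaining_fraction, cover_px):
        base = np.full((h, w), background)
        base[well] = params.agar_intensity
        k_myc = min(k_myc, myc_order.size)
        if k_myc > 0:
            base.ravel()[myc_order[:k_myc]] = params.mycelium_intensity
        truth = np.zeros((h, w), dtype=bool)
        keep = np.round(n0 * f).astype(int)
        for (gy, gx), k in zip(grains, keep):
            if k >= 1:
                base[gy[:k], gx[:k]] = params.grain_intensity
                truth[gy[:k], gx[:k]] = True
        frame = base * illum
        if params.noise_sd > 0:
            frame = frame + rng.normal(0.0, params.noise_sd, size=(h, w))
        frames.append(np.clip(frame, 0.0, 1.0))
        truth_masks.append(truth)
        counts.append(int(truth.sum()))

    series = ImageSeries(frames=frames, times=trajectory.times.copy(), well_mask=well)
    table = pd.DataFrame({"time_h": trajectory.times, "true_grain_px": counts})
    return SimulatedImageSeries(
        series=series, truth_masks=truth_masks, truth_table=table, params=params, trajectory=trajectory
    )


def simulate_kinetic_curves(
    trajectory: TruthTrajectory,
    n_replicates: int = 3,
    noise_sd: float = 5.0,
    seed: int = 0,
    sample_id: str = "",
    blend_label: str = "",
) -> list[KineticCurve]:
    """Noisy remaining-% replicate curves drawn around a true trajectory.

    ``noise_sd`` is additive Gaussian noise in percentage points (default
    5, i.e. 5% of the initial signal).  The t0 value is pinned to exactly
    100, as the image pipeline's ratio statistic guarantees.
    """
    rng = np.random.default_rng(seed)
    truth = 100.0 * trajectory.remaining_fraction
    curves = []
    for rep in range(n_replicates):
        values = truth + rng.normal(0.0, noise_sd, size=truth.shape)
        values[0] = 100.0
        curves.append(
            KineticCurve(
                times=trajectory.times.copy(),
                values=values,
                sample_id=sample_id or blend_label,
                blend_label=blend_label,
                replicate=rep,
            )
        )
    return curves


@dataclass
class SpectrumParams:
    """Parameters of a synthetic two-peak 1H NMR spectrum.

    ``linewidth`` is the Lorentzian half-width at half-maximum (ppm).
    ``degradation_fraction`` ``d`` splits a unit total integral between the
    monomer peak (``d``) and the polymer peak (``1 - d``).
    """

    ppm_grid: np.ndarray = field(default_factory=lambda: np.arange(3.0, 6.5, 0.0005))
    monomer_center: float = 4.20
    polymer_center: float = 5.20
    linewidth: float = 0.015
    degradation_fraction: float = 0.0
    baseline_level: float = 0.02
    noise_sd: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        self.ppm_grid = np.asarray(self.ppm_grid, dtype=float)
        if self.linewidth <= 0:
            raise ValueError("linewidth must be positive")
        if not 0.0 <= self.degradation_fraction <= 1.0:
            raise ValueError("degradation_fraction must be in [0, 1]")
        lo, hi = self.ppm_grid.min(), self.ppm_grid.max()
        for c in (self.monomer_center, self.polymer_center):
            if not lo < c < hi:
                raise ValueError(f"peak centre {c} ppm outside the ppm grid [{lo}, {hi}]")
        if abs(self.monomer_center - self.polymer_center) < 3.0 * self.linewidth:
            raise ValueError("peaks overlap: centres closer than 3 linewidths")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SimulatedSpectrum:
    """A spectrum plus the analytic integrals it was built from."""

    spectrum: Spectrum
    true_monomer_integral: float
    true_polymer_integral: float
    params: SpectrumParams


def _lorentzian(x: np.ndarray, centre: float, hwhm: float) -> np.ndarray:
    """Unit-integral Lorentzian line."""
    return (hwhm / math.pi) / ((x - centre) ** 2 + hwhm**2)


def simulate_spectrum(params: SpectrumParams) -> SimulatedSpectrum:
    """Two-Lorentzian spectrum with analytic ground-truth integrals.

    intensity = baseline + noise + d * L(monomer) + (1 - d) * L(polymer),
    each ``L`` a unit-integral Lorentzian of the configured linewidth.
    """
    rng = np.random.default_rng(params.seed)
    d = params.degradation_fraction
    x = params.ppm_grid
    intensity = np.full_like(x, params.baseline_level)
    intensity = intensity + d * _lorentzian(x, params.monomer_center, params.linewidth)
    intensity = intensity + (1.0 - d) * _lorentzian(x, params.polymer_center, params.linewidth)
    if params.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, params.noise_sd, size=x.shape)
    spec = Spectrum(ppm=x.copy(), intensity=intensity)
    return SimulatedSpectrum(
        spectrum=spec,
        true_monomer_integral=d,
        true_polymer_integral=1.0 - d,
        params=params,
    )


def simulate_spectrum_series(
    times_h: np.ndarray,
    degradation_fractions: np.ndarray,
    base_params: SpectrumParams | None = None,
    seed: int = 0,
) -> list[Spectrum]:
    """One spectrum per time point following a degradation trajectory."""
    times_h = np.asarray(times_h, dtype=float)
    fractions = np.asarray(degradation_fractions, dtype=float)
    if times_h.shape != fractions.shape:
        raise ValueError("times and degradation fractions differ in length")
    base = base_params or SpectrumParams()
    rng = np.random.default_rng(seed)
    spectra = []
    for t, d in zip(times_h, fractions):
        p = SpectrumParams(
            ppm_grid=base.ppm_grid,
            monomer_center=base.monomer_center,
            polymer_center=base.polymer_center,
            linewidth=base.linewidth,
            degradation_fraction=float(d),
            baseline_level=base.baseline_level,
            noise_sd=base.noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        spec = simulate_spectrum(p).spectrum
        spec.time_h = float(t)
        spectra.append(spec)
    return spectra
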