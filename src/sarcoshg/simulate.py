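"""Ground-truthed synthetic SHG striation images, study cohorts and ranked gene lists.

The generative model is shared with the fitter (:mod:`sarcoshg.fit`): along a
fiber the SHG intensity is a periodic train of Gaussian peak *pairs*.  Each
sarcomere of length SL contributes two peaks (the two A-band segments) placed
ABL apart around the M-band at the sarcomere midpoint; the peak full width at
half maximum equals TTIL.  Z-discs carry no signal, so the gap between
consecutive sarcomeres is simply the dark space between peak pairs.

Units: lengths in µm, pixel pitch in nm, angles in degrees counterclockwise
from the +x (column) axis, pixel coordinates 0-based (x = column, y = row).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import IntensityProfile, SHGMImage

# FWHM of a Gaussian = 2 sqrt(2 ln 2) * sigma; the single width convention
# that converts TTIL (a FWHM) to the Gaussian sigma used everywhere.
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Default peak contrast in expected photon counts.  Calibrated so that the
#: full single-fiber pipeline recovers SL within the 20 nm accuracy of the
#: imaging technique (see docs/methods.md).
DEFAULT_CONTRAST = 12.0
DEFAULT_BACKGROUND = 2.0
DEFAULT_READ_SIGMA = 1.0


@dataclass(frozen=True)
class SarcomereParams:
    """True or estimated sarcomere geometry of one fiber (all in µm)."""

    sl_um: float
    abl_um: float
    ttil_um: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sl_um) and self.sl_um > 0):
            raise ValueError(f"sl_um must be positive and finite, got {self.sl_um}")
        if not (0 < self.abl_um < self.sl_um):
            raise ValueError(
                f"abl_um must lie in (0, sl_um), got abl={self.abl_um}, sl={self.sl_um}"
            )
        if not (0 < self.ttil_um < self.abl_um):
            raise ValueError(
                f"ttil_um must lie in (0, abl_um), got ttil={self.ttil_um}, abl={self.abl_um}"
            )

    @property
    def ratio(self) -> float:
        """SL/ABL, the quality-control ratio."""
        return self.sl_um / self.abl_um

    @property
    def sigma_um(self) -> float:
        """Gaussian sigma of one A-band peak (TTIL is its FWHM)."""
        return self.ttil_um / FWHM_PER_SIGMA

    @property
    def peak_gap_um(self) -> float:
        """Smallest distance between adjacent peak centers."""
        return min(self.abl_um, self.sl_um - self.abl_um)


@dataclass(frozen=True)
class FiberSpec:
    """Pose and geometry of one simulated fiber.

    ``center_xy_px`` is the fiber midpoint; the fiber spans
    ``n_sarcomeres * sl_um`` symmetrically about it along ``orientation_deg``.
    """

    params: SarcomereParams
    center_xy_px: tuple[float, float]
    orientation_deg: float
    n_sarcomeres: int
    contrast: float = DEFAULT_CONTRAST
    transverse_sigma_um: float = 0.5

    def __post_init__(self) -> None:
        if self.n_sarcomeres < 1:
            raise ValueError("n_sarcomeres must be >= 1")
        if self.contrast <= 0 or self.transverse_sigma_um <= 0:
            raise ValueError("contrast and transverse_sigma_um must be positive")

    @property
    def length_um(self) -> float:
        return self.n_sarcomeres * self.params.sl_um

    def direction(self) -> np.ndarray:
        th = np.deg2rad(self.orientation_deg)
        return np.array([np.cos(th), np.sin(th)])

    def endpoints_px(self, pixel_nm: float) -> np.ndarray:
        half = 0.5 * self.length_um * 1000.0 / pixel_nm
        c = np.asarray(self.center_xy_px, dtype=float)
        u = self.direction()
        return np.stack([c - half * u, c + half * u])

    def centerline_px(self, pixel_nm: float, step_px: float = 1.0) -> np.ndarray:
        """Ordered (x, y) points along the fiber axis at constant pitch."""
        p0, p1 = self.endpoints_px(pixel_nm)
        n = max(int(np.linalg.norm(p1 - p0) / step_px), 1)
        t = np.linspace(0.0, 1.0, n + 1)[:, None]
        return p0 + t * (p1 - p0)


@dataclass
class GroundTruth:
    """Per-fiber true geometry for one simulated image."""

    fibers: list[FiberSpec]
    pixel_nm: float
    image_id: str = ""
    background: float = DEFAULT_BACKGROUND

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.fibers):
            rows.append(
                {
                    "fiber_id": i,
                    "sl_um": f.params.sl_um,
                    "abl_um": f.params.abl_um,
                    "ttil_um": f.params.ttil_um,
                    "orientation_deg": f.orientation_deg % 180.0,
                    "n_sarcomeres": f.n_sarcomeres,
                    "center_x_px": f.center_xy_px[0],
                    "center_y_px": f.center_xy_px[1],
                    "contrast": f.contrast,
                }
            )
        return pd.DataFrame(rows)

    def centerline(self, fiber_id: int, step_px: float = 1.0) -> np.ndarray:
        return self.fibers[fiber_id].centerline_px(self.pixel_nm, step_px)


@dataclass(frozen=True)
class NoiseModel:
    """Photon (Poisson) noise plus additive Gaussian read noise.

    ``level`` scales the overall noise: photons are drawn with an exposure
    factor 1/level**2 (so the relative shot noise scales linearly with
    ``level``) and the read-noise sigma scales with ``level``.  ``level = 0``
    disables noise entirely.
    """

    level: float = 1.0
    read_sigma: float = DEFAULT_READ_SIGMA

    def apply(self, expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.level == 0:
            return np.asarray(expected, dtype=float)
        if self.level < 0:
            raise ValueError("noise level must be >= 0")
        exposure = 1.0 / self.level**2
        counts = rng.poisson(np.maximum(expected, 0.0) * exposure) / exposure
        return counts + rng.normal(0.0, self.read_sigma * self.level, expected.shape)


def axial_intensity(
    s_um: np.ndarray, params: SarcomereParams, n_sarcomeres: int
) -> np.ndarray:
    """Noise-free axial pattern (unit amplitude) at arc positions ``s_um``.

    The fiber occupies ``s in [0, n_sarcomeres * sl_um]`` with Z-discs at
    multiples of SL; each period holds two Gaussian peaks ABL apart around
    the period midpoint.
    """
    s = np.asarray(s_um, dtype=float)
    sl, abl = params.sl_um, params.abl_um
    sig = params.sigma_um
    length = n_sarcomeres * sl
    inside = (s >= 0.0) & (s <= length)
    u = np.mod(s, sl)
    p1 = 0.5 * (sl - abl)
    p2 = 0.5 * (sl + abl)
    out = np.exp(-((u - p1) ** 2) / (2 * sig**2)) + np.exp(
        -((u - p2) ** 2) / (2 * sig**2)
    )
    return np.where(inside, out, 0.0)


def _check_renderable(fiber: FiberSpec, shape: tuple[int, int], pixel_nm: float) -> None:
    p = fiber.params
    if p.ttil_um >= 0.5 * p.peak_gap_um:
        raise ValueError(
            "degenerate striation pattern: ttil_um "
            f"{p.ttil_um:.4f} >= half the inter-peak gap {0.5 * p.peak_gap_um:.4f}"
        )
    h, w = shape
    for x, y in fiber.endpoints_px(pixel_nm):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise ValueError(
                f"fiber endpoint ({x:.1f}, {y:.1f}) outside image of shape {shape}"
            )


def render_fibers(
    fibers: Sequence[FiberSpec],
    shape: tuple[int, int] = (512, 512),
    pixel_nm: float = 40.0,
    background: float = DEFAULT_BACKGROUND,
) -> np.ndarray:
    """Render the noise-free expected-photon image of the given fibers."""
    h, w = shape
    img = np.full(shape, float(background))
    px_um = pixel_nm / 1000.0
    for fiber in fibers:
        _check_renderable(fiber, shape, pixel_nm)
        c = np.asarray(fiber.center_xy_px, dtype=float)
        u = fiber.direction()
        nrm = np.array([-u[1], u[0]])
        half_px = 0.5 * fiber.length_um / px_um
        reach_t = 4.0 * fiber.transverse_sigma_um / px_um
        # bounding box of the fiber band
        corners = np.array(
            [
                c + s * half_px * u + t * reach_t * nrm
                for s in (-1, 1)
                for t in (-1, 1)
            ]
        )
        x0, y0 = np.clip(np.floor(corners.min(axis=0)).astype(int), 0, [w - 1, h - 1])
        x1, y1 = np.clip(np.ceil(corners.max(axis=0)).astype(int), 0, [w - 1, h - 1])
        xs = np.arange(x0, x1 + 1)
        ys = np.arange(y0, y1 + 1)
        gx, gy = np.meshgrid(xs, ys)
        dx = gx - c[0]
        dy = gy - c[1]
        s_um = (dx * u[0] + dy * u[1]) * px_um + 0.5 * fiber.length_um
        t_um = (dx * nrm[0] + dy * nrm[1]) * px_um
        ax = axial_intensity(s_um, fiber.params, fiber.n_sarcomeres)
        env = np.exp(-(t_um**2) / (2 * fiber.transverse_sigma_um**2))
        img[y0 : y1 + 1, x0 : x1 + 1] += fiber.contrast * ax * env
    return img


def simulate_fiber_image(
    fibers: Sequence[FiberSpec],
    *,
    shape: tuple[int, int] = (512, 512),
    pixel_nm: float = 40.0,
    background: float = DEFAULT_BACKGROUND,
    noise: float | NoiseModel = 1.0,
    seed: int = 0,
    image_id: str = "sim",
) -> tuple[SHGMImage, GroundTruth]:
    """Render fibers into a noisy SHG-like image; return it with its truth table."""
    model = noise if isinstance(noise, NoiseModel) else NoiseModel(level=float(noise))
    clean = render_fibers(fibers, shape=shape, pixel_nm=pixel_nm, background=background)
    rng = np.random.default_rng(seed)
    noisy = model.apply(clean, rng)
    image = SHGMImage(intensity=np.clip(noisy, 0.0, None), pixel_nm=pixel_nm, id=image_id)
    truth = GroundTruth(
        fibers=list(fibers), pixel_nm=pixel_nm, image_id=image_id, background=background
    )
    return image, truth


def simulate_fiber_profile(
    params: SarcomereParams,
    n_sarcomeres: int,
    *,
    spacing_nm: float = 40.0,
    contrast: float = DEFAULT_CONTRAST,
    background: float = DEFAULT_BACKGROUND,
    noise: float | NoiseModel = 1.0,
    seed: int = 0,
    phase_um: float = 0.0,
) -> IntensityProfile:
    """1-D axial profile of a single fiber with the image noise model applied.

    This is the profile-level shortcut past rendering/tracing: the same
    generative pattern and noise, sampled directly along the fiber axis.
    """
    model = noise if isinstance(noise, NoiseModel) else NoiseModel(level=float(noise))
    length_um = n_sarcomeres * params.sl_um
    n = int(np.floor(length_um * 1000.0 / spacing_nm)) + 1
    s = np.arange(n) * spacing_nm / 1000.0 + phase_um
    clean = background + contrast * axial_intensity(np.mod(s, length_um), params, n_sarcomeres)
    rng = np.random.default_rng(seed)
    return IntensityProfile(samples=model.apply(clean, rng), spacing_nm=spacing_nm)


# --------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class GroupLevels:
    """Heart-level distribution of one study group (means and SDs in µm).

    ``ratio_sd`` is the SD of the SL/ABL ratio across hearts.  Heart means
    are drawn as (SL, ratio, TTIL) with ABL = SL / ratio: SL and ABL covary
    tightly across hearts (the ratio is nearly constant), and this
    parameterisation reproduces the observed ABL spread.
    """

    sl_um: float
    sl_sd: float
    abl_um: float
    abl_sd: float
    ttil_um: float
    ttil_sd: float
    ratio_sd: float

    @property
    def ratio(self) -> float:
        return self.sl_um / self.abl_um

    def mean_params(self) -> SarcomereParams:
        return SarcomereParams(self.sl_um, self.abl_um, self.ttil_um)


#: Heart-level group configurations of the emulated study design: paired control/IUGR cohorts
#: at two ages (fetal = 30 gestational days, adult = 70 postnatal days).
STUDY_GROUPS: dict[tuple[str, str], GroupLevels] = {
    ("fetal", "control"): GroupLevels(1.658, 0.094, 0.772, 0.044, 0.104, 0.006, 0.02),
    ("fetal", "iugr"): GroupLevels(1.531, 0.114, 0.705, 0.060, 0.096, 0.007, 0.03),
    ("adult", "control"): GroupLevels(1.720, 0.068, 0.817, 0.036, 0.103, 0.005, 0.02),
    ("adult", "iugr"): GroupLevels(1.626, 0.084, 0.772, 0.041, 0.097, 0.005, 0.01),
}


@dataclass(frozen=True)
class WithinHeartSD:
    """Fiber-to-fiber SD around each heart's mean (SL and TTIL in µm)."""

    sl_um: float = 0.04
    ratio: float = 0.02
    ttil_um: float = 0.003


@dataclass
class CohortSpec:
    """Design of a simulated paired control/IUGR cohort.

    Control heart i and IUGR heart i share ``pair_id`` i (littermates); a
    ``pair_correlation`` of their heart-level deviations models the shared
    maternal environment.  With ``center_heart_means`` the drawn heart means
    are recentred so each group's truth mean equals its configured mean
    exactly, which pins the benchmark ground truth at the configured values
    (dispersion and pairing structure are preserved).
    """

    age: str = "fetal"
    groups: tuple[str, ...] = ("control", "iugr")
    levels: Mapping[str, GroupLevels] | None = None
    n_hearts: int = 7
    images_per_heart: int = 3
    fibers_per_image: int = 5
    n_sarcomeres: int = 14
    image_shape: tuple[int, int] = (512, 512)
    pixel_nm: float = 40.0
    orientation_deg: float = 45.0
    orientation_jitter_deg: float = 2.0  # image-to-image; within-image jitter is 0.5 deg
    fiber_spacing_um: float = 2.2
    contrast: float = DEFAULT_CONTRAST
    background: float = DEFAULT_BACKGROUND
    noise: float = 1.0
    within_heart_sd: WithinHeartSD = field(default_factory=WithinHeartSD)
    pair_correlation: float = 0.5
    center_heart_means: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hearts < 1:
            raise ValueError("n_hearts must be >= 1")
        if not 0 <= self.pair_correlation <= 1:
            raise ValueError("pair_correlation must be in [0, 1]")
        if self.levels is None:
            self.levels = {
                g: STUDY_GROUPS[(self.age, g)] for g in self.groups
            }
        for g in self.groups:
            lv = self.levels[g]
            if min(lv.sl_sd, lv.abl_sd, lv.ttil_sd, lv.ratio_sd) < 0:
                raise ValueError("group SDs must be >= 0")


@dataclass
class SimulatedHeart:
    heart_id: str
    group: str
    age: str
    pair_id: int
    true_params: SarcomereParams
    images: list[tuple[SHGMImage, GroundTruth]] = field(default_factory=list)
    profiles: list[tuple[IntensityProfile, SarcomereParams]] = field(default_factory=list)


@dataclass
class SimulatedCohort:
    spec: CohortSpec
    hearts: list[SimulatedHeart]
    mode: str = "image"

    def manifest(self) -> pd.DataFrame:
        rows = []
        for hh in self.hearts:
            if self.mode == "image":
                for img, _ in hh.images:
                    rows.append(
                        {
                            "heart_id": hh.heart_id,
                            "group": hh.group,
                            "age": hh.age,
                            "pair_id": hh.pair_id,
                            "image_id": img.id,
                        }
                    )
            else:
                rows.append(
                    {
                        "heart_id": hh.heart_id,
                        "group": hh.group,
                        "age": hh.age,
                        "pair_id": hh.pair_id,
                        "image_id": f"{hh.heart_id}_profiles",
                    }
                )
        return pd.DataFrame(rows)

    def heart_truth(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "heart_id": [h.heart_id for h in self.hearts],
                "group": [h.group for h in self.hearts],
                "age": [h.age for h in self.hearts],
                "pair_id": [h.pair_id for h in self.hearts],
                "sl_um": [h.true_params.sl_um for h in self.hearts],
                "abl_um": [h.true_params.abl_um for h in self.hearts],
                "ttil_um": [h.true_params.ttil_um for h in self.hearts],
            }
        )


def _draw_correlated(
    rng: np.random.Generator, n: int, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two standard-normal vectors with pairwise correlation rho."""
    z = rng.normal(size=n)
    a = np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.normal(size=n)
    b = np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.normal(size=n)
    return a, b


def _draw_heart_means(spec: CohortSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Heart-level (SL, ratio, TTIL) draws per group, recentred if requested."""
    n = spec.n_hearts
    draws: dict[str, dict[str, np.ndarray]] = {g: {} for g in spec.groups}
    for var in ("sl", "ratio", "ttil"):
        if len(spec.groups) == 2:
            a, b = _draw_correlated(rng, n, spec.pair_correlation)
            zs = {spec.groups[0]: a, spec.groups[1]: b}
        else:
            zs = {g: rng.normal(size=n) for g in spec.groups}
        for g in spec.groups:
            lv = spec.levels[g]
            mu, sd = {
                "sl": (lv.sl_um, lv.sl_sd),
                "ratio": (lv.ratio, lv.ratio_sd),
                "ttil": (lv.ttil_um, lv.ttil_sd),
            }[var]
            v = mu + sd * zs[g]
            if spec.center_heart_means and n > 1:
                v = v - v.mean() + mu
            draws[g][var] = v
    out = {}
    for g in spec.groups:
        sl = draws[g]["sl"]
        ratio = draws[g]["ratio"]
        ttil = draws[g]["ttil"]
        out[g] = np.column_stack([sl, sl / ratio, ttil])
    return out


def _draw_fiber_params(
    heart: SarcomereParams, sd: WithinHeartSD, rng: np.random.Generator, max_tries: int = 100
) -> SarcomereParams:
    for _ in range(max_tries):
        sl = heart.sl_um + rng.normal(0.0, sd.sl_um)
        ratio = heart.ratio + rng.normal(0.0, sd.ratio)
        ttil = heart.ttil_um + rng.normal(0.0, sd.ttil_um)
        try:
            p = SarcomereParams(sl, sl / ratio, ttil)
        except (ValueError, ZeroDivisionError):
            continue
        if p.ttil_um < 0.5 * p.peak_gap_um:
            return p
    raise RuntimeError("could not draw valid fiber parameters in 100 tries")


def parallel_fiber_layout(
    fiber_params: Sequence[SarcomereParams],
    *,
    shape: tuple[int, int] = (512, 512),
    pixel_nm: float = 40.0,
    orientation_deg: float = 45.0,
    spacing_um: float = 2.2,
    n_sarcomeres: int = 14,
    margin_px: float = 16.0,
    min_sarcomeres: int = 6,
    contrast: float = DEFAULT_CONTRAST,
    rng: np.random.Generator | None = None,
    orientation_jitter_deg: float = 0.5,
) -> list[FiberSpec]:
    """Place near-parallel fibers at constant transverse spacing.

    ``orientation_jitter_deg`` is deliberately small: myocardial fibers in a
    section are nearly parallel, and strongly diverging neighbors would merge
    at their ends.  Image-to-image orientation variation belongs to the
    caller (see :class:`CohortSpec`).

    Each fiber is clipped to the longest run of whole sarcomeres that fits
    inside the image (respecting ``margin_px``); fibers with fewer than
    ``min_sarcomeres`` periods are dropped.  A random sub-period phase shift
    decorrelates striation phases between fibers.
    """
    rng = rng or np.random.default_rng(0)
    h, w = shape
    px_um = pixel_nm / 1000.0
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    n_fib = len(fiber_params)
    offsets = (np.arange(n_fib) - (n_fib - 1) / 2.0) * spacing_um / px_um
    fibers = []
    for params, d in zip(fiber_params, offsets):
        theta = orientation_deg + (
            rng.normal(0.0, orientation_jitter_deg) if orientation_jitter_deg else 0.0
        )
        th = np.deg2rad(theta)
        u = np.array([np.cos(th), np.sin(th)])
        nrm = np.array([-u[1], u[0]])
        p0 = center + d * nrm
        lo = np.array([margin_px, margin_px])
        hi = np.array([w - 1 - margin_px, h - 1 - margin_px])
        smin, smax = -np.inf, np.inf
        ok = True
        for i in range(2):
            if abs(u[i]) < 1e-12:
                if not (lo[i] <= p0[i] <= hi[i]):
                    ok = False
                continue
            t1, t2 = (lo[i] - p0[i]) / u[i], (hi[i] - p0[i]) / u[i]
            smin = max(smin, min(t1, t2))
            smax = min(smax, max(t1, t2))
        if not ok or smax <= smin:
            continue
        sl_px = params.sl_um / px_um
        # reserve one period for the random phase shift
        avail = (smax - smin) - sl_px
        n_sarc = min(n_sarcomeres, int(avail / sl_px))
        if n_sarc < min_sarcomeres:
            continue
        mid = p0 + 0.5 * (smin + smax) * u
        shift = (rng.uniform(-0.5, 0.5) * sl_px) * u
        fibers.append(
            FiberSpec(
                params=params,
                center_xy_px=tuple(mid + shift),
                orientation_deg=theta % 180.0,
                n_sarcomeres=n_sarc,
                contrast=contrast,
            )
        )
    return fibers


def simulate_cohort(spec: CohortSpec, mode: str = "image") -> SimulatedCohort:
    """Simulate a paired cohort of hearts, each with images (or bare profiles).

    ``mode='image'`` renders full 2-D images; ``mode='profile'`` generates the
    per-fiber 1-D profiles directly (same geometry draws and noise model,
    skipping rendering/tracing) for fast large-replicate studies.
    """
    if mode not in ("image", "profile"):
        raise ValueError("mode must be 'image' or 'profile'")
    rng = np.random.default_rng(spec.seed)
    heart_means = _draw_heart_means(spec, rng)
    hearts: list[SimulatedHeart] = []
    for g in spec.groups:
        for i in range(spec.n_hearts):
            sl, abl, ttil = heart_means[g][i]
            heart = SimulatedHeart(
                heart_id=f"{spec.age}_{g}_{i:02d}",
                group=g,
                age=spec.age,
                pair_id=i,
                true_params=SarcomereParams(sl, abl, ttil),
            )
            for k in range(spec.images_per_heart):
                params = [
                    _draw_fiber_params(heart.true_params, spec.within_heart_sd, rng)
                    for _ in range(spec.fibers_per_image)
                ]
                if mode == "image":
                    image_angle = spec.orientation_deg + rng.normal(
                        0.0, spec.orientation_jitter_deg
                    )
                    fibers = parallel_fiber_layout(
                        params,
                        shape=spec.image_shape,
                        pixel_nm=spec.pixel_nm,
                        orientation_deg=image_angle,
                        spacing_um=spec.fiber_spacing_um,
                        n_sarcomeres=spec.n_sarcomeres,
                        contrast=spec.contrast,
                        rng=rng,
                    )
                    img, truth = simulate_fiber_image(
                        fibers,
                        shape=spec.image_shape,
                        pixel_nm=spec.pixel_nm,
                        background=spec.background,
                        noise=spec.noise,
                        seed=int(rng.integers(2**31)),
                        image_id=f"{heart.heart_id}_img{k}",
                    )
                    heart.images.append((img, truth))
                else:
                    for p in params:
                        prof = simulate_fiber_profile(
                            p,
                            spec.n_sarcomeres,
                            spacing_nm=spec.pixel_nm,
                            contrast=spec.contrast,
                            background=spec.background,
                            noise=spec.noise,
                            seed=int(rng.integers(2**31)),
                        )
                        heart.profiles.append((prof, p))
            hearts.append(heart)
    return SimulatedCohort(spec=spec, hearts=hearts, mode=mode)


# --------------------------------------------------------------------------
# ranked gene lists


def simulate_ranked_list(
    n_genes: int,
    block_term: str = "GO:0031430",
    frac_up: float = 0.016,
    frac_down: float = 0.0069,
    seed: int = 0,
    n_decoy_terms: int = 0,
    decoy_size: int = 50,
):
    """Ranked gene list with an annotation block enriched among up-regulated genes.

    The list is ordered by a simulated differential-expression statistic
    (most up-regulated first).  ``block_term`` annotates ``frac_up`` of the
    top half and ``frac_down`` of the bottom half (rounded to counts).
    Decoy terms annotate genes independently of rank.

    Returns ``(ranked, amap)``: a DataFrame (gene_id, stat) sorted by
    decreasing statistic, and an :class:`~sarcoshg.geneset.AnnotationMap`.
    """
    from .geneset import AnnotationMap

    if not (0 <= frac_down <= frac_up <= 1):
        raise ValueError("need 0 <= frac_down <= frac_up <= 1")
    rng = np.random.default_rng(seed)
    half = n_genes // 2
    n_up = int(round(frac_up * half))
    n_down = int(round(frac_down * (n_genes - half)))
    if (frac_up > 0 and n_up == 0) or (frac_down > 0 and n_down == 0):
        raise ValueError(
            f"n_genes={n_genes} too small to realize fractions "
            f"({frac_up}, {frac_down}) as nonzero counts"
        )
    stat = np.sort(rng.normal(size=n_genes))[::-1]
    genes = [f"g{i:05d}" for i in range(n_genes)]
    ranked = pd.DataFrame({"gene_id": genes, "stat": stat})
    gene_to_terms: dict[str, set[str]] = {g: set() for g in genes}
    top_idx = rng.choice(half, size=n_up, replace=False)
    bot_idx = half + rng.choice(n_genes - half, size=n_down, replace=False)
    for i in np.concatenate([top_idx, bot_idx]):
        gene_to_terms[genes[int(i)]].add(block_term)
    for t in range(n_decoy_terms):
        idx = rng.choice(n_genes, size=min(decoy_size, n_genes), replace=False)
        for i in idx:
            gene_to_terms[genes[int(i)]].add(f"DECOY:{t:04d}")
    return ranked, AnnotationMap(gene_to_terms=gene_to_terms, dag_edges=[])
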