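"""Synthetic scene generators with known ground truth.

Every analysis stage in this package is exercised on inputs generated here,
so parameter recovery can be asserted against the truth that produced the
images:

* lifetime-gated redox scenes — a smooth gut-autofluorescence field that
  bleeds into the 405-nm sensor channel with a fixed per-channel ratio, a
  biosensor signal whose true 488/405 ratio field is prescribed, and Poisson
  (optionally plus Gaussian read) noise;
* mitochondrial-network phantoms — dilated random-walk tubules under
  Gaussian PSF blur, with the true thresholded %-area known exactly;
* histology-stain scenes — red stain absorbing the green channel of an RGB
  brightfield image under a multiplicative vignette, with the true
  integrated density inside a circular ROI known exactly;
* lifespan cohorts — Gompertz-distributed death days rounded up to the
  scoring visit interval.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io import HYPER_LAYOUT, ChannelStack, ROI, ROISet

# Default photon-count levels for the redox scenes. The source images carry
# no intensity calibration, so these are engineering choices sized like
# typical confocal count data: sensor ~300 counts, autofluorescence blob
# peaks 50-150 counts, photon gain 1.
DEFAULT_SENSOR_MEAN = 300.0
DEFAULT_AF_AMP_RANGE = (50.0, 150.0)


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------


def _parse_noise(noise: str) -> tuple[bool, float]:
    """Parse a noise descriptor into (poisson?, gaussian sigma).

    Accepted: ``"none"``, ``"poisson"``, ``"poisson+gaussian:<sigma>"``.
    """
    if noise == "none":
        return False, 0.0
    if noise == "poisson":
        return True, 0.0
    if noise.startswith("poisson+gaussian"):
        _, _, sig = noise.partition(":")
        return True, float(sig or 1.0)
    raise ValueError(f"unknown noise spec {noise!r}")


def _apply_noise(expected: np.ndarray, noise: str, rng: np.random.Generator) -> np.ndarray:
    poisson, sigma = _parse_noise(noise)
    out = np.asarray(expected, dtype=float)
    if poisson:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if sigma > 0:
        out = out + rng.normal(0.0, sigma, size=out.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# Redox (biosensor) scenes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AFFieldSpec:
    """Smooth positive autofluorescence field: a sum of broad Gaussian blobs.

    ``mean_level``, when set, rescales the blob mixture so its volume mean
    equals that many counts — the unambiguous way to state "AF amplitude as a
    fraction of sensor amplitude".
    """

    n_blobs: int = 25
    amp_range: tuple[float, float] = DEFAULT_AF_AMP_RANGE
    sigma_range_px: tuple[float, float] = (6.0, 14.0)
    baseline: float = 20.0
    mean_level: float | None = None


@dataclass(frozen=True)
class RatioFieldSpec:
    """True 488/405 ratio field: constant, linear x-gradient, or two-region."""

    kind: str = "constant"  # constant | gradient | two_region
    value: float = 1.0
    value_hi: float = 2.0


@dataclass(frozen=True)
class HyperSceneParams:
    shape: tuple[int, int, int] = (7, 64, 64)
    r_true: dict = field(default_factory=lambda: {"405": 0.35, "488": 0.0})
    af_field_spec: AFFieldSpec = AFFieldSpec()
    sensor_mean: float = DEFAULT_SENSOR_MEAN
    ratio_field_spec: RatioFieldSpec = RatioFieldSpec()
    noise: str = "poisson"
    n_control_subjects: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.shape):
            raise ValueError("shape dims must be >= 1")
        if any(v < 0 for v in self.r_true.values()):
            raise ValueError("bleed ratios must be nonnegative")
        if self.sensor_mean <= 0:
            raise ValueError("sensor_mean must be positive")


@dataclass
class SyntheticScene:
    """Generated raw channels paired with the ground truth that produced them."""

    raw_stacks: dict  # channel name -> ChannelStack
    af_true: np.ndarray
    sensor_405_true: np.ndarray
    sensor_488_true: np.ndarray
    ratio_true: np.ndarray
    roi: ROISet
    params: HyperSceneParams


def _af_field(shape: tuple[int, int, int], spec: AFFieldSpec, rng: np.random.Generator) -> np.ndarray:
    nz, ny, nx = shape
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    fld = np.full(shape, float(spec.baseline))
    for _ in range(spec.n_blobs):
        amp = rng.uniform(*spec.amp_range)
        sig = rng.uniform(*spec.sigma_range_px)
        cz = rng.uniform(0, nz)
        cy = rng.uniform(0, ny)
        cx = rng.uniform(0, nx)
        d2 = ((zz - cz) * 2.0) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2  # blobs flatter in z
        fld += amp * np.exp(-d2 / (2.0 * sig * sig))
    if spec.mean_level is not None:
        m = fld.mean()
        if m > 0:
            fld *= spec.mean_level / m
    return fld


def _ratio_field(shape: tuple[int, int, int], spec: RatioFieldSpec) -> np.ndarray:
    nz, ny, nx = shape
    if spec.kind == "constant":
        return np.full(shape, float(spec.value))
    if spec.kind == "gradient":
        ramp = np.linspace(spec.value, spec.value_hi, nx)
        return np.broadcast_to(ramp, shape).copy()
    if spec.kind == "two_region":
        fld = np.full(shape, float(spec.value))
        fld[:, :, nx // 2 :] = spec.value_hi
        return fld
    raise ValueError(f"unknown ratio field kind {spec.kind!r}")


def _head_region(shape: tuple[int, int, int], rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sensor-expressing 'head' region: a disk in (y, x) with a soft z profile."""
    nz, ny, nx = shape
    cy = ny / 2 + rng.uniform(-ny / 12, ny / 12)
    cx = nx / 2 + rng.uniform(-nx / 12, nx / 12)
    radius = min(ny, nx) / 4.0
    ys, xs = np.ogrid[:ny, :nx]
    disk = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius * radius
    zprof = np.exp(-0.5 * ((np.arange(nz) - (nz - 1) / 2) / max(nz / 3.0, 1.0)) ** 2)
    region3d = zprof[:, None, None] * disk[None].astype(float)
    return region3d, disk


def make_hyper_scene(params: HyperSceneParams) -> tuple[SyntheticScene, list[SyntheticScene]]:
    """Generate one biosensor scene plus ``n_control_subjects`` control scenes.

    Control scenes carry autofluorescence only (sensor ≡ 0), emulating
    age-matched non-transgenic animals used to fit the bleed ratios. Each
    raw channel obeys the forward model
    ``raw = sensor_true + r_true * af_true (+ noise)`` voxel-wise; the 405-nm
    sensor channel carries the prescribed true ratio via
    ``sensor_488 = ratio_true * sensor_405``.
    """
    rng = np.random.default_rng(params.seed)

    def _render(sensor_on: bool, sub_rng: np.random.Generator, subject_id: str) -> SyntheticScene:
        af = _af_field(params.shape, params.af_field_spec, sub_rng)
        ratio = _ratio_field(params.shape, params.ratio_field_spec)
        if sensor_on:
            region3d, disk = _head_region(params.shape, sub_rng)
            s405 = params.sensor_mean * region3d
        else:
            disk = np.zeros(params.shape[1:], dtype=bool)
            s405 = np.zeros(params.shape)
        s488 = ratio * s405
        r405 = params.r_true.get("405", 0.0)
        r488 = params.r_true.get("488", 0.0)
        raws = {}
        for name, expected in (
            ("405", s405 + r405 * af),
            ("488", s488 + r488 * af),
            ("af", af),
        ):
            spec = next(c for c in HYPER_LAYOUT if c.name == name)
            raws[name] = ChannelStack(
                voxels=_apply_noise(expected, params.noise, sub_rng),
                channel=spec,
                subject_id=subject_id,
                group="hyper" if sensor_on else "control",
            )
        roi = ROISet([ROI(subject_id=subject_id, name="head", mask=disk)])
        return SyntheticScene(
            raw_stacks=raws,
            af_true=af,
            sensor_405_true=s405,
            sensor_488_true=s488,
            ratio_true=ratio,
            roi=roi,
            params=params,
        )

    scene = _render(True, rng, "worm_0")
    controls = [_render(False, rng, f"control_{i}") for i in range(params.n_control_subjects)]
    return scene, controls


# ---------------------------------------------------------------------------
# Mitochondrial-network phantoms
# ---------------------------------------------------------------------------


def make_mito_scene(
    shape: tuple[int, int, int] = (5, 128, 128),
    n_tubules: int = 12,
    tubule_radius_px: float = 1.5,
    psf_sigma_px: float = 1.0,
    noise: str = "poisson",
    seed: int = 0,
    amplitude: float = 1000.0,
    cell_mask: np.ndarray | None = None,
    steps_per_tubule: int = 60,
) -> tuple[ChannelStack, np.ndarray, float]:
    """Tubular mitochondrial phantom under PSF blur.

    Tubules are drawn as random walks in-plane (with occasional z moves)
    dilated to ``tubule_radius_px``; the stack is the binary mask scaled by
    ``amplitude``, blurred by a Gaussian PSF, and noised. Returns the stack,
    the true binary tubule mask (pre-blur), and the true percent area of the
    mask's max projection within ``cell_mask`` (whole frame by default).
    """
    if any(s < 1 for s in shape):
        raise ValueError("degenerate shape")
    if n_tubules > 0 and tubule_radius_px < 1:
        raise ValueError("tubule radius must be >= 1 px")
    nz, ny, nx = shape
    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_tubules):
        z = rng.integers(0, nz)
        y = float(rng.uniform(2, ny - 2))
        x = float(rng.uniform(2, nx - 2))
        ang = rng.uniform(0, 2 * np.pi)
        for _ in range(steps_per_tubule):
            mask[int(z), int(round(np.clip(y, 0, ny - 1))), int(round(np.clip(x, 0, nx - 1)))] = True
            ang += rng.normal(0, 0.3)
            y += np.sin(ang)
            x += np.cos(ang)
            if rng.uniform() < 0.05:
                z = int(np.clip(z + rng.integers(-1, 2), 0, nz - 1))
            if not (0 <= y < ny and 0 <= x < nx):
                break
    if mask.any() and tubule_radius_px > 1:
        struct = _disk_struct(tubule_radius_px)
        mask = np.stack([ndimage.binary_dilation(mask[k], structure=struct) for k in range(nz)])

    if cell_mask is None:
        cell_mask = np.ones((ny, nx), dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.shape != (ny, nx):
        raise ValueError("cell_mask shape must match (y, x)")
    proj = mask.any(axis=0)
    true_percent = 100.0 * np.count_nonzero(proj & cell_mask) / np.count_nonzero(cell_mask)

    expected = amplitude * mask.astype(float)
    if psf_sigma_px > 0:
        expected = ndimage.gaussian_filter(expected, sigma=(psf_sigma_px / 2.0, psf_sigma_px, psf_sigma_px))
    voxels = _apply_noise(expected, noise, rng)
    spec = HYPER_LAYOUT[1]  # 488 ex GFP-like channel
    stack = ChannelStack(voxels=voxels, channel=spec, subject_id="mito_0", group="sim")
    return stack, mask, true_percent


def _disk_struct(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    ys, xs = np.ogrid[-r : r + 1, -r : r + 1]
    return xs * xs + ys * ys <= radius * radius


# ---------------------------------------------------------------------------
# Stained RGB brightfield scenes
# ---------------------------------------------------------------------------

ORO_BACKGROUND_RGB = (235.0, 240.0, 235.0)  # bright, slightly warm slide background
CHANNEL_MAX = 255.0


def make_oro_scene(
    shape: tuple[int, int] = (256, 256),
    n_blobs: int = 8,
    stain_intensity: float = 160.0,
    vignette_range: tuple[float, float] = (0.6, 1.0),
    seed: int = 0,
    circle_center_xy: tuple[float, float] | None = None,
    circle_diameter_px: float = 40.0,
    blob_radius_range_px: tuple[float, float] = (4.0, 10.0),
    vignette_seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """RGB brightfield scene of red stain on a bright background under a vignette.

    Stain blobs are uniform disks that subtract ``stain_intensity`` from the
    green channel (red stain absorbs green) and a little from blue; a smooth
    multiplicative vignette ``V(y, x)`` spanning ``vignette_range`` (peak at
    its upper bound) multiplies all channels. Ground truth is computed
    pre-vignette: the true stain map ``S = G_background − G`` and the true
    integrated density = ΣS over stained pixels whose centers fall inside the
    specified circle. Returns ``(rgb float array in [0, 255], stain map,
    integrated density)``.

    ``vignette_seed`` decouples the vignette field from the stain pattern:
    the same ``seed`` with different ``vignette_seed`` values renders one
    stain layout under different illumination fields.
    """
    lo, hi = vignette_range
    if not (0 < lo <= hi <= 1):
        raise ValueError("vignette_range must lie within (0, 1]")
    if not (0 <= stain_intensity <= CHANNEL_MAX):
        raise ValueError("stain_intensity outside channel range")
    ny, nx = shape
    rng = np.random.default_rng(seed)
    rgb = np.empty((ny, nx, 3))
    for c, bg in enumerate(ORO_BACKGROUND_RGB):
        rgb[..., c] = bg
    if circle_center_xy is None:
        circle_center_xy = (nx / 2.0, ny / 2.0)
    cx0, cy0 = circle_center_xy
    ys, xs = np.ogrid[:ny, :nx]
    stain = np.zeros((ny, nx))
    # stain clusters around the measurement circle, as fat deposits cluster
    # in the anterior intestine the circle is placed over
    cluster_radius = max(1.5 * circle_diameter_px, max(blob_radius_range_px))
    for _ in range(n_blobs):
        r = rng.uniform(*blob_radius_range_px)
        ang = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(0, cluster_radius)
        cy = float(np.clip(cy0 + dist * np.sin(ang), r, ny - r))
        cx = float(np.clip(cx0 + dist * np.cos(ang), r, nx - r))
        disk = (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r
        stain[disk] = stain_intensity
    rgb[..., 1] = np.clip(rgb[..., 1] - stain, 0, CHANNEL_MAX)  # green absorbed
    rgb[..., 2] = np.clip(rgb[..., 2] - 0.3 * stain, 0, CHANNEL_MAX)

    radius = circle_diameter_px / 2.0
    in_circle = (xs - cx0) ** 2 + (ys - cy0) ** 2 <= radius * radius + 1e-12
    true_density = float(stain[in_circle & (stain > 0)].sum())

    # smooth vignette peaking at `hi` at a random bright spot
    vrng = rng if vignette_seed is None else np.random.default_rng(vignette_seed)
    vy = vrng.uniform(0, ny)
    vx = vrng.uniform(0, nx)
    # wide Gaussian falloff: illumination vignettes vary on the scale of the
    # whole field, much more slowly than any stained structure
    d2 = ((ys - vy) / ny) ** 2 + ((xs - vx) / nx) ** 2
    v = np.exp(-d2 / (2 * 0.5**2))
    v = lo + (hi - lo) * (v - v.min()) / (v.max() - v.min())
    rendered = np.clip(rgb * v[..., None], 0, CHANNEL_MAX)
    return rendered, stain, true_density


# ---------------------------------------------------------------------------
# Lifespan cohorts
# ---------------------------------------------------------------------------

#: Gompertz hazard h(t) = a·exp(b·t) sized to a wild-type cohort at 25 °C:
#: b = 0.25 /day and a = 0.002 /day give a mean lifespan near 17 days.
DEFAULT_GOMPERTZ = {"a": 0.002, "b": 0.25}


def sample_gompertz(n: int, a: float, b: float, rng: np.random.Generator) -> np.ndarray:
    """Draw lifetimes from the Gompertz distribution with hazard a·exp(b·t)."""
    if a <= 0 or b <= 0:
        raise ValueError("Gompertz parameters must be positive")
    # scipy's gompertz: S(x) = exp(-c (e^x - 1)) with x = t/scale
    return stats.gompertz.rvs(c=a / b, scale=1.0 / b, size=n, random_state=rng)


def make_lifespan_cohorts(
    n_per_group: int | dict,
    gompertz_params: dict,
    seed: int = 0,
    scoring_interval_days: float = 1.0,
    experiment_id: str = "exp1",
) -> pd.DataFrame:
    """Simulated death-day table for one or more groups.

    ``gompertz_params`` maps group label -> {"a": ..., "b": ...}. Death times
    are rounded UP to the next scoring visit (cohorts are checked every 1-3
    days, so a death is recorded at the first visit at which it is observed).
    Returns a cohort table with columns subject_id, experiment_id, group,
    value (death day), excluded.
    """
    if scoring_interval_days <= 0:
        raise ValueError("scoring interval must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for group, pars in gompertz_params.items():
        n = n_per_group[group] if isinstance(n_per_group, dict) else int(n_per_group)
        if n < 2:
            raise ValueError("need n >= 2 per group")
        t = sample_gompertz(n, pars["a"], pars["b"], rng)
        days = np.ceil(t / scoring_interval_days) * scoring_interval_days
        days = np.maximum(days, scoring_interval_days)
        for i, d in enumerate(days):
            rows.append(
                {
                    "subject_id": f"{group}_{i}",
                    "experiment_id": experiment_id,
                    "group": group,
                    "value": float(d),
                    "excluded": False,
                }
            )
    return pd.DataFrame(rows)
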