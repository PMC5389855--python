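"""Ratiometric H2O2-biosensor (HyPer) quantification with autofluorescence unmixing.

The biosensor is imaged in two lifetime-gated channels (405ex and 488ex,
500-550em, 1.5-5.5 ns) alongside a dedicated autofluorescence channel
(405ex, 450-470em, 7-11.5 ns) that contains no sensor signal. Gut
autofluorescence bleeds into each sensor channel in fixed proportion R to
the autofluorescence channel, so the correction is a pixel-wise channel
subtraction::

    F_sensor = F_raw - R * F_af

R is estimated per experimental group by pooling pixels from control
(non-transgenic) animals and fitting a straight line through the origin —
the correction formula has no offset term, so neither does the default fit.
The per-worm redox readout is the 488/405 ratio of the corrected channels at
the focal plane with the greatest combined in-ROI fluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib import colormaps

from .io import ChannelStack, ROI, logger

#: Fraction of the in-ROI 99th-percentile corrected 405 signal used as the
#: default ratio denominator floor; keeps dark pixels out of the ratio.
DENOM_FLOOR_FRACTION = 0.01


@dataclass(frozen=True)
class UnmixingModel:
    """Per-channel autofluorescence bleed ratio with fit diagnostics."""

    r: dict  # channel name -> bleed ratio
    n_pixels_fit: int
    rms_residual: float
    group: str = ""
    intercept: dict | None = None  # diagnostic only; never used in subtraction

    def __post_init__(self) -> None:
        if self.n_pixels_fit <= 0:
            raise ValueError("n_pixels_fit must be positive")
        for name, val in self.r.items():
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"bleed ratio for channel {name!r} must be finite and >= 0")


@dataclass
class RatioMap:
    ratio: np.ndarray
    valid: np.ndarray
    denom_floor: float

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.ratio.shape != self.valid.shape:
            raise ValueError("ratio and valid mask must share shape")
        if self.denom_floor <= 0:
            raise ValueError("denom_floor must be positive")


@dataclass(frozen=True)
class WormRedoxResult:
    subject_id: str
    group: str
    z_selected: int
    roi_ratio: float
    mode: str
    n_valid_pixels: int


# ---------------------------------------------------------------------------
# Bleed-ratio estimation
# ---------------------------------------------------------------------------


def estimate_af_ratio(
    control_stacks: list[tuple[ChannelStack, ChannelStack]],
    channel: str,
    mask: np.ndarray | ROI | None = None,
    group: str = "",
    fit_intercept: bool = False,
) -> UnmixingModel:
    """Fit the autofluorescence bleed ratio R for one sensor channel.

    ``control_stacks`` pairs the target-channel stack with the
    autofluorescence-channel stack for each control subject. Pixels are
    pooled across subjects and R minimizes sum((F_target - R*F_af)^2), i.e.
    the closed-form through-origin least squares
    R = sum(F_target*F_af) / sum(F_af^2). An optional 2-D mask restricts the
    fit to in-mask pixels of every slice. ``fit_intercept=True`` additionally
    reports a free-intercept fit as a diagnostic; the returned ``r`` is
    always the through-origin estimate used for subtraction.
    """
    if not control_stacks:
        raise ValueError("need at least one control subject")
    if isinstance(mask, ROI):
        mask = mask.mask
    targets, afs = [], []
    for tgt, af in control_stacks:
        if tgt.shape != af.shape:
            raise ValueError("paired stacks must share shape")
        t, a = tgt.voxels, af.voxels
        if mask is not None:
            if mask.shape != t.shape[1:]:
                raise ValueError("mask shape must match the (y, x) stack shape")
            if not mask.any():
                raise ValueError("empty mask")
            t = t[:, mask]
            a = a[:, mask]
        targets.append(t.ravel())
        afs.append(a.ravel())
    t = np.concatenate(targets)
    a = np.concatenate(afs)
    denom = float(np.dot(a, a))
    if denom == 0.0:
        raise ValueError("autofluorescence channel is all zero; R is undefined")
    r = float(np.dot(t, a) / denom)
    r = max(r, 0.0)
    resid = t - r * a
    rms = float(np.sqrt(np.mean(resid**2)))
    intercept = None
    if fit_intercept:
        X = np.column_stack([a, np.ones_like(a)])
        coef, *_ = np.linalg.lstsq(X, t, rcond=None)
        intercept = {"slope": float(coef[0]), "offset": float(coef[1])}
    return UnmixingModel(r={channel: r}, n_pixels_fit=t.size, rms_residual=rms, group=group, intercept=intercept)


def estimate_af_ratio_grid(
    control_stacks: list[tuple[ChannelStack, ChannelStack]],
    channel: str,
    r_max: float = 2.0,
    step: float = 1e-4,
) -> float:
    """Brute-force grid minimization of the unmixing residual (diagnostic oracle).

    Scans R over [0, r_max] in ``step`` increments and returns the
    minimizer of sum((F_target - R*F_af)^2). Exists to cross-check
    :func:`estimate_af_ratio`; O(grid x pixels), use on small inputs.
    """
    t = np.concatenate([s.voxels.ravel() for s, _ in control_stacks])
    a = np.concatenate([s.voxels.ravel() for _, s in control_stacks])
    grid = np.arange(0.0, r_max + step / 2, step)
    sse = np.array([np.sum((t - r * a) ** 2) for r in grid])
    return float(grid[int(np.argmin(sse))])


# ---------------------------------------------------------------------------
# Correction, plane selection, ratio
# ---------------------------------------------------------------------------


def subtract_autofluorescence(
    raw: ChannelStack,
    af: ChannelStack,
    r: float,
    clip_negative: bool = True,
) -> ChannelStack:
    """Pixel-wise autofluorescence subtraction: corrected = raw - r * af.

    Negative results are clipped to 0 by default (intensities are photon
    counts); the unclipped array is kept in ``extras["unclipped"]`` for
    diagnostics, and the r used is recorded in ``extras["r_used"]``.
    """
    if not np.isfinite(r) or r < 0:
        raise ValueError("r must be finite and nonnegative")
    if raw.shape != af.shape:
        raise ValueError(f"shape mismatch: raw {raw.shape} vs af {af.shape}")
    corrected = raw.voxels - r * af.voxels
    unclipped = corrected
    if clip_negative:
        corrected = np.clip(corrected, 0.0, None)
    return raw.with_voxels(corrected, unclipped=unclipped, r_used=float(r))


def select_focal_plane(
    corrected_405: ChannelStack,
    corrected_488: ChannelStack,
    roi: np.ndarray | ROI,
) -> int:
    """Index of the z-slice with the greatest combined in-ROI fluorescence.

    Combined fluorescence is the sum of both corrected sensor channels over
    the ROI; ties break toward the smallest z.
    """
    if isinstance(roi, ROI):
        roi = roi.mask
    roi = np.asarray(roi, dtype=bool)
    if corrected_405.shape != corrected_488.shape:
        raise ValueError("stacks must share shape")
    if roi.shape != corrected_405.shape[1:]:
        raise ValueError("ROI shape must match the (y, x) stack shape")
    if not roi.any():
        raise ValueError("empty ROI")
    combined = corrected_405.voxels + corrected_488.voxels
    per_z = combined[:, roi].sum(axis=1)
    return int(np.argmax(per_z))  # argmax returns the first (lowest-z) maximum


def compute_ratio_map(
    corrected_488: ChannelStack | np.ndarray,
    corrected_405: ChannelStack | np.ndarray,
    denom_floor: float,
) -> RatioMap:
    """Pixel-wise 488/405 redox ratio, valid where the 405 denominator >= floor."""
    f488 = corrected_488.voxels if isinstance(corrected_488, ChannelStack) else np.asarray(corrected_488, dtype=float)
    f405 = corrected_405.voxels if isinstance(corrected_405, ChannelStack) else np.asarray(corrected_405, dtype=float)
    if f488.shape != f405.shape:
        raise ValueError("channel shapes must match")
    if denom_floor <= 0:
        raise ValueError("denom_floor must be positive")
    valid = f405 >= denom_floor
    ratio = np.zeros_like(f405)
    np.divide(f488, f405, out=ratio, where=valid)
    return RatioMap(ratio=ratio, valid=valid, denom_floor=denom_floor)


def quantify_worm(
    corrected_405: ChannelStack,
    corrected_488: ChannelStack,
    roi: np.ndarray | ROI,
    mode: str = "ratio_of_sums",
    denom_floor: float | None = None,
) -> WormRedoxResult:
    """Per-worm redox value inside the (2-D) ROI at the selected focal plane.

    ``ratio_of_sums`` (default) = sum(F488)/sum(F405) over valid ROI pixels,
    robust to dim pixels; ``mean_of_ratios`` = mean of per-pixel ratios over
    the same pixels. When ``denom_floor`` is None it defaults to
    ``DENOM_FLOOR_FRACTION`` of the 99th percentile of the corrected 405
    signal within the ROI at the selected plane.
    """
    if mode not in ("ratio_of_sums", "mean_of_ratios"):
        raise ValueError(f"unknown mode {mode!r}")
    roi_mask = roi.mask if isinstance(roi, ROI) else np.asarray(roi, dtype=bool)
    z = select_focal_plane(corrected_405, corrected_488, roi_mask)
    f405 = corrected_405.voxels[z]
    f488 = corrected_488.voxels[z]
    if denom_floor is None:
        p99 = float(np.percentile(f405[roi_mask], 99))
        denom_floor = max(DENOM_FLOOR_FRACTION * p99, np.finfo(float).tiny)
    rmap = compute_ratio_map(f488, f405, denom_floor)
    sel = roi_mask & rmap.valid
    n_valid = int(np.count_nonzero(sel))
    if n_valid == 0:
        raise ValueError("no valid pixels in ROI at the selected plane")
    if mode == "ratio_of_sums":
        value = float(f488[sel].sum() / f405[sel].sum())
    else:
        value = float(rmap.ratio[sel].mean())
    return WormRedoxResult(
        subject_id=corrected_405.subject_id,
        group=corrected_405.group,
        z_selected=z,
        roi_ratio=value,
        mode=mode,
        n_valid_pixels=n_valid,
    )


# ---------------------------------------------------------------------------
# Intensity-normalized ratiometric rendering
# ---------------------------------------------------------------------------


def render_inr(
    ratio_map: RatioMap,
    intensity: np.ndarray,
    display_range: tuple[float, float],
    cmap: str = "viridis",
) -> np.ndarray:
    """Intensity-normalized ratiometric (INR) rendering of a 2-D ratio map.

    Hue encodes the ratio (clipped to ``display_range``, min-max scaled into
    a perceptually uniform colormap); brightness encodes combined intensity
    normalized to its in-image maximum. Invalid and zero-intensity pixels
    render black. Returns an (y, x, 3) float RGB image in [0, 1].
    """
    lo, hi = display_range
    if not lo < hi:
        raise ValueError("display range must satisfy lo < hi")
    ratio = np.asarray(ratio_map.ratio, dtype=float)
    if ratio.ndim != 2:
        raise ValueError("render_inr expects a 2-D ratio map")
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape != ratio.shape:
        raise ValueError("intensity shape must match ratio map")
    scaled = (np.clip(ratio, lo, hi) - lo) / (hi - lo)
    rgb = colormaps[cmap](scaled)[..., :3]
    imax = intensity.max()
    bright = intensity / imax if imax > 0 else np.zeros_like(intensity)
    rgb = rgb * bright[..., None]
    rgb[~ratio_map.valid] = 0.0
    return rgb


# ---------------------------------------------------------------------------
# Plate-reader assay variant
# ---------------------------------------------------------------------------


def platereader_hyper(wells: pd.DataFrame, background_group: str) -> pd.DataFrame:
    """Background-subtracted per-well 488/405 ratios for the plate-reader assay.

    ``wells`` needs columns ``group``, ``f405``, ``f488``. Per channel, the
    mean over the background group (non-transgenic animals) is subtracted
    from every well; corrected ratio = (f488 - bg488)/(f405 - bg405). Wells
    whose corrected denominator is <= 0 are flagged invalid and excluded
    from group means (left NaN).
    """
    required = {"group", "f405", "f488"}
    if not required.issubset(wells.columns):
        raise ValueError(f"wells table needs columns {sorted(required)}")
    bg = wells[wells["group"] == background_group]
    if bg.empty:
        raise ValueError(f"no background wells for group {background_group!r}")
    bg405 = float(bg["f405"].mean())
    bg488 = float(bg["f488"].mean())
    out = wells.copy()
    out["f405_corrected"] = out["f405"] - bg405
    out["f488_corrected"] = out["f488"] - bg488
    out["valid"] = out["f405_corrected"] > 0
    n_bad = int((~out["valid"]).sum() - (~out[out["group"] == background_group]["valid"]).sum())
    if n_bad > 0:
        logger.warning("%d non-background wells have corrected 405 <= 0; flagged invalid", n_bad)
    out["ratio"] = np.where(out["valid"], out["f488_corrected"] / out["f405_corrected"].where(out["valid"], 1.0), np.nan)
    return out


def platereader_group_means(corrected: pd.DataFrame) -> pd.DataFrame:
    """Group mean +/- s.e.m. of valid corrected plate-reader ratios."""
    valid = corrected[corrected["valid"]]
    g = valid.groupby("group")["ratio"]
    return pd.DataFrame({"mean": g.mean(), "sem": g.sem(), "n": g.count()}).reset_index()
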