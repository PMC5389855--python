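"""Image, ROI, table and config I/O.

Conventions used throughout the package:

* volumes are indexed ``(z, y, x)``; 2-D images ``(y, x)``; RGB images
  ``(y, x, 3)``;
* pixel coordinates are 0-based and a pixel belongs to a polygon or circle
  iff its integer center lies inside or on the boundary;
* channel identity travels with a :class:`ChannelSpec` name declared in the
  acquisition layout, never with plane order;
* tabular outputs are CSV with a header row; configuration is a single YAML
  file validated at load time.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
import tifffile
import yaml
from shapely.geometry import Point, Polygon

logger = logging.getLogger("wormquant")

_LOG_FORMAT = "%(asctime)s %(levelname)s %(name)s: %(message)s"


def setup_logging(level: str = "INFO") -> None:
    """Configure package logging to stderr at the given level name."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter(_LOG_FORMAT))
    logger.handlers[:] = [handler]
    logger.setLevel(getattr(logging, level.upper()))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelSpec:
    """One named excitation/emission/lifetime-gate acquisition channel.

    The three channels of the lifetime-gated redox acquisition are, e.g.::

        ChannelSpec("405", 405, (500, 550), (1.5, 5.5))
        ChannelSpec("488", 488, (500, 550), (1.5, 5.5))
        ChannelSpec("af",  405, (450, 470), (7.0, 11.5))
    """

    name: str
    excitation_nm: int
    emission_band_nm: tuple[float, float]
    lifetime_gate_ns: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("channel name must be nonempty")
        if self.excitation_nm <= 0:
            raise ValueError("excitation_nm must be positive")
        lo, hi = self.emission_band_nm
        if not (0 < lo < hi):
            raise ValueError(f"emission band must be strictly ordered, got {self.emission_band_nm}")
        glo, ghi = self.lifetime_gate_ns
        if not (0 <= glo < ghi):
            raise ValueError(f"lifetime gate must be strictly ordered, got {self.lifetime_gate_ns}")


# The standard three-channel redox acquisition layout.
HYPER_LAYOUT: tuple[ChannelSpec, ...] = (
    ChannelSpec("405", 405, (500, 550), (1.5, 5.5)),
    ChannelSpec("488", 488, (500, 550), (1.5, 5.5)),
    ChannelSpec("af", 405, (450, 470), (7.0, 11.5)),
)


@dataclass
class ChannelStack:
    """One subject's 3-D intensity volume in one named channel."""

    voxels: np.ndarray  # (z, y, x), nonnegative, real
    channel: ChannelSpec
    subject_id: str = ""
    group: str = ""
    experiment_id: str = ""
    z_step_um: float = 0.34
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D (z, y, x), got ndim={self.voxels.ndim}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite")
        if np.any(self.voxels < 0):
            raise ValueError("voxels must be nonnegative")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def with_voxels(self, voxels: np.ndarray, **extras) -> "ChannelStack":
        """Copy of this stack with new voxel data (metadata preserved)."""
        return ChannelStack(
            voxels=voxels,
            channel=self.channel,
            subject_id=self.subject_id,
            group=self.group,
            experiment_id=self.experiment_id,
            z_step_um=self.z_step_um,
            extras={**self.extras, **extras},
        )


@dataclass
class ROI:
    subject_id: str
    name: str
    mask: np.ndarray  # 2-D boolean, (y, x)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())


@dataclass
class ROISet:
    rois: list[ROI] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def for_subject(self, subject_id: str) -> list[ROI]:
        return [r for r in self.rois if r.subject_id == subject_id]


# ---------------------------------------------------------------------------
# Stacks
# ---------------------------------------------------------------------------


def write_stack(path, stacks: list[ChannelStack]) -> None:
    """Write one subject's channels to a multi-page TIFF, axis order (c, z, y, x).

    Integer-valued data round-trips losslessly through :func:`read_stack`.
    """
    if not stacks:
        raise ValueError("no stacks to write")
    shapes = {s.shape for s in stacks}
    if len(shapes) != 1:
        raise ValueError(f"channel stacks disagree in shape: {shapes}")
    arr = np.stack([s.voxels for s in stacks], axis=0)
    tifffile.imwrite(str(path), arr.astype(np.float32), metadata={"axes": "CZYX"})


def read_stack(
    path,
    layout: list[ChannelSpec] | tuple[ChannelSpec, ...],
    subject_id: str = "",
    group: str = "",
    experiment_id: str = "",
    z_step_um: float = 0.34,
) -> list[ChannelStack]:
    """Read a multi-channel TIFF z-stack into one :class:`ChannelStack` per channel.

    ``layout`` declares the channel order on the file's leading axis; a 3-D
    file is accepted for a single-channel layout. Raises on a missing file,
    on a channel-count mismatch, and on negative voxel values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(str(path))
    if arr.ndim == 3:
        if len(layout) != 1:
            raise ValueError(f"file holds one 3-D volume but layout declares {len(layout)} channels")
        arr = arr[None]
    if arr.ndim != 4:
        raise ValueError(f"expected a (c, z, y, x) stack, got ndim={arr.ndim}")
    if arr.shape[0] != len(layout):
        raise ValueError(f"layout declares {len(layout)} channels but file has {arr.shape[0]} planes on the channel axis")
    if np.any(arr < 0):
        raise ValueError("negative voxel values after cast; check dtype scaling in config")
    return [
        ChannelStack(
            voxels=np.asarray(arr[i], dtype=float),
            channel=spec,
            subject_id=subject_id,
            group=group,
            experiment_id=experiment_id,
            z_step_um=z_step_um,
        )
        for i, spec in enumerate(layout)
    ]


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------


def rasterize_polygon(xy: np.ndarray, image_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed polygon in (x, y) pixel coordinates to a boolean mask.

    A pixel is in the mask iff its integer center lies inside the polygon or
    on its boundary. Deterministic; raises on self-intersecting polygons.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 3:
        raise ValueError("polygon must be an (n>=3, 2) array of (x, y) vertices")
    poly = Polygon(xy)
    if not poly.is_valid or not poly.is_simple:
        raise ValueError("polygon is self-intersecting or otherwise invalid")
    ny, nx = image_shape
    # only test centers inside the polygon's bounding box
    minx, miny, maxx, maxy = poly.bounds
    x0, x1 = max(0, int(np.floor(minx))), min(nx - 1, int(np.ceil(maxx)))
    y0, y1 = max(0, int(np.floor(miny))), min(ny - 1, int(np.ceil(maxy)))
    mask = np.zeros((ny, nx), dtype=bool)
    if x0 > x1 or y0 > y1:
        return mask
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    pts = shapely.points(xs.ravel(), ys.ravel())
    inside = shapely.covers(poly, pts)  # covers = interior + boundary
    mask[ys.ravel()[inside], xs.ravel()[inside]] = True
    return mask


def rasterize_circle(center_xy: tuple[float, float], diameter_px: float, image_shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers lie within ``diameter_px/2`` of the center.

    Boundary-inclusive, clipped to image bounds.
    """
    if diameter_px <= 0:
        raise ValueError("diameter must be positive")
    cx, cy = center_xy
    r = diameter_px / 2.0
    ny, nx = image_shape
    ys, xs = np.ogrid[:ny, :nx]
    return (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r + 1e-12


def load_roi(path, image_shape: tuple[int, int]) -> ROISet:
    """Load ROIs from a JSON polygon file or a label-mask TIFF.

    JSON dialect: a list of ``{"subject": s, "name": n, "xy": [[x, y], ...]}``.
    Label-mask TIFF: each nonzero label becomes one ROI; an all-zero mask
    yields a single ROI flagged empty.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        rois = []
        for rec in records:
            mask = rasterize_polygon(np.asarray(rec["xy"]), image_shape)
            rois.append(ROI(subject_id=rec.get("subject", ""), name=rec.get("name", ""), mask=mask))
        return ROISet(rois)
    labels = tifffile.imread(str(path))
    if labels.shape != tuple(image_shape):
        raise ValueError(f"label mask shape {labels.shape} does not match image shape {tuple(image_shape)}")
    values = np.unique(labels)
    values = values[values != 0]
    if values.size == 0:
        empty = ROI(subject_id="", name="empty", mask=np.zeros(image_shape, dtype=bool))
        logger.warning("label mask %s contains no nonzero labels; returning an empty ROI", path)
        return ROISet([empty])
    return ROISet([ROI(subject_id="", name=str(int(v)), mask=labels == v) for v in values])


def save_roi_json(path, records: list[dict]) -> None:
    """Write polygon ROIs in the JSON dialect read by :func:`load_roi`."""
    Path(path).write_text(json.dumps(records, indent=1))


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    """Load and validate the pipeline's YAML configuration.

    The config must be a mapping; an optional ``channels`` section is parsed
    into :class:`ChannelSpec` objects (names must be unique) and dtype scaling
    must be declared explicitly when raw integer images are used.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    if "channels" in cfg:
        specs = [
            ChannelSpec(
                name=str(c["name"]),
                excitation_nm=int(c["excitation_nm"]),
                emission_band_nm=tuple(c["emission_band_nm"]),
                lifetime_gate_ns=tuple(c["lifetime_gate_ns"]),
            )
            for c in cfg["channels"]
        ]
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique within an acquisition")
        cfg["channels"] = specs
    return cfg
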