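"""Fluorescence-image morphometry of implant-host integration.

Three measurements quantify how a printed implant integrates into host
tissue on a 2-D fluorescence image with an annotated implant boundary:

* **process outgrowth** — the farthest distance beyond the boundary at which
  labelled signal stays at or above a detection threshold, read off a mean
  intensity profile taken normal to the boundary;
* **migrated-neuron count** — labelled somata (supra-threshold connected
  components of plausible soma area) whose centroid lies 200-400 um beyond
  the boundary and whose footprint overlaps a nuclear-channel blob, reported
  both as a raw count and as a density per 0.1 mm^2 of band area analysed;
* **labelled-area coverage** — percent supra-threshold pixels within a
  rectangular region (deep-layer coverage for printed two-layer tissue).

Distances are in micrometres, positive into the host; coordinates are
pixel-centred and 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .exceptions import GeometryError, InputError

__all__ = [
    "Boundary",
    "PolylineBoundary",
    "AnnotatedImage",
    "IntensityProfile",
    "MigrationResult",
    "MorphometryReport",
    "intensity_profile",
    "outgrowth_distance",
    "count_migrated_cells",
    "rfp_coverage",
]

DEFAULT_BAND_UM = (200.0, 400.0)
DEFAULT_SOMA_AREA_UM2 = (30.0, 300.0)
REFERENCE_FIELD_MM2 = 0.1


@dataclass(frozen=True)
class Boundary:
    """Straight implant-host boundary line, axis-aligned.

    ``orientation="vertical"`` is the line x = position_um, ``"horizontal"``
    the line y = position_um.  ``host_side=+1`` places the host at
    coordinates greater than the position (the fast path used throughout).
    """

    orientation: str = "vertical"
    position_um: float = 0.0
    host_side: int = 1

    def __post_init__(self) -> None:
        if self.orientation not in ("vertical", "horizontal"):
            raise GeometryError(f"unknown orientation {self.orientation!r}")
        if self.host_side not in (-1, 1):
            raise GeometryError("host_side must be +1 or -1")

    def signed_distance_um(self, x_um, y_um):
        """Signed distance to the boundary, positive into the host."""
        coord = np.asarray(x_um if self.orientation == "vertical" else y_um, dtype=float)
        return self.host_side * (coord - self.position_um)


class PolylineBoundary:
    """Implant-host boundary given as a polyline in um coordinates.

    Distance to the boundary is the Euclidean distance to the nearest
    segment; the sign (positive into the host) is fixed by a reference point
    known to lie on the host side.
    """

    def __init__(self, points_um: Sequence[Tuple[float, float]], host_point_um: Tuple[float, float]):
        pts = np.asarray(points_um, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
            raise GeometryError("polyline needs >= 2 (x, y) points")
        self._pts = pts
        self._host_point = np.asarray(host_point_um, dtype=float)
        if self._unsigned(self._host_point[None, 0:1], self._host_point[None, 1:2])[0] == 0:
            raise GeometryError("host reference point lies on the boundary")

    def _unsigned(self, x_um, y_um):
        x = np.asarray(x_um, dtype=float).ravel()
        y = np.asarray(y_um, dtype=float).ravel()
        p = np.stack([x, y], axis=1)  # (m, 2)
        a = self._pts[:-1]  # segment starts (s, 2)
        b = self._pts[1:]
        ab = b - a
        denom = np.maximum(np.sum(ab**2, axis=1), 1e-30)
        # project every point on every segment, clamp to [0, 1]
        ap = p[:, None, :] - a[None, :, :]  # (m, s, 2)
        t = np.clip(np.sum(ap * ab[None, :, :], axis=2) / denom[None, :], 0.0, 1.0)
        closest = a[None, :, :] + t[..., None] * ab[None, :, :]
        d = np.linalg.norm(p[:, None, :] - closest, axis=2)
        return d.min(axis=1)

    def signed_distance_um(self, x_um, y_um):
        x = np.asarray(x_um, dtype=float)
        shape = np.broadcast_shapes(x.shape, np.asarray(y_um, dtype=float).shape)
        xr = np.broadcast_to(np.asarray(x_um, dtype=float), shape).ravel()
        yr = np.broadcast_to(np.asarray(y_um, dtype=float), shape).ravel()
        d = self._unsigned(xr, yr)
        # sign: same side as host reference point, decided per point by the
        # nearest-segment cross product
        sign = np.sign(self._side(xr, yr)) * np.sign(self._side(*self._host_point))
        sign[sign == 0] = 0.0
        return (d * sign).reshape(shape)

    def _side(self, x_um, y_um):
        x = np.atleast_1d(np.asarray(x_um, dtype=float))
        y = np.atleast_1d(np.asarray(y_um, dtype=float))
        p = np.stack([x, y], axis=1)
        a = self._pts[:-1]
        b = self._pts[1:]
        ab = b - a
        denom = np.maximum(np.sum(ab**2, axis=1), 1e-30)
        ap = p[:, None, :] - a[None, :, :]
        t = np.clip(np.sum(ap * ab[None, :, :], axis=2) / denom[None, :], 0.0, 1.0)
        closest = a[None, :, :] + t[..., None] * ab[None, :, :]
        d = np.linalg.norm(p[:, None, :] - closest, axis=2)
        nearest = np.argmin(d, axis=1)
        seg = ab[nearest]
        off = p - closest[np.arange(p.shape[0]), nearest]
        cross = seg[:, 0] * off[:, 1] - seg[:, 1] * off[:, 0]
        return cross


@dataclass
class AnnotatedImage:
    """Grayscale image (plus optional nuclear channel) with scale and boundary.

    ``signal`` carries the labelled (RFP/HNCAM) channel, ``nuclei`` the DAPI
    channel when present; both share one shape.  ``detection_threshold`` is
    the grayscale level above which labelled signal counts as detected; when
    None, Otsu's threshold on the host-side signal is used.
    """

    signal: np.ndarray
    um_per_px: float
    boundary: Boundary
    nuclei: Optional[np.ndarray] = None
    detection_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise InputError("signal must be a 2-D grayscale array")
        if self.nuclei is not None:
            self.nuclei = np.asarray(self.nuclei, dtype=float)
            if self.nuclei.shape != self.signal.shape:
                raise InputError("nuclei channel shape differs from signal")
        if self.um_per_px <= 0:
            raise InputError("um_per_px must be > 0")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.signal.shape

    def pixel_centers_um(self) -> Tuple[np.ndarray, np.ndarray]:
        """(x, y) grids of pixel-centre coordinates in um (x along columns)."""
        h, w = self.signal.shape
        x = (np.arange(w) + 0.5) * self.um_per_px
        y = (np.arange(h) + 0.5) * self.um_per_px
        return np.meshgrid(x, y)

    def effective_threshold(self) -> float:
        """Detection threshold; Otsu on the host-side signal when unset."""
        if self.detection_threshold is not None:
            return float(self.detection_threshold)
        xg, yg = self.pixel_centers_um()
        host = self.boundary.signed_distance_um(xg, yg) > 0
        vals = self.signal[host]
        if vals.size == 0 or np.ptp(vals) == 0:
            return float(np.max(self.signal)) if vals.size == 0 else float(vals[0]) + 1.0
        return float(threshold_otsu(vals))


@dataclass
class IntensityProfile:
    """Mean intensity vs signed distance to the boundary (um, one pixel bins)."""

    distances_um: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.distances_um)


@dataclass
class MigrationResult:
    """Migrated-neuron count in the distance band, with analysed-area density."""

    count: int
    band_um: Tuple[float, float]
    band_area_mm2: float
    density_per_field: float  # per 0.1 mm^2
    centroids_um: List[Tuple[float, float]] = field(default_factory=list)


@dataclass
class MorphometryReport:
    """Bundle of the per-image integration metrics."""

    outgrowth_um: float
    migrated_count: int
    migrated_density_per_field: float
    band_um: Tuple[float, float] = DEFAULT_BAND_UM
    band_area_mm2: float = float("nan")
    rfp_coverage_pct: Optional[float] = None

    def summary(self) -> str:
        lines = [
            f"Process outgrowth: {self.outgrowth_um:.1f} um",
            f"Migrated neurons in {self.band_um[0]:.0f}-{self.band_um[1]:.0f} um band: "
            f"{self.migrated_count} "
            f"({self.migrated_density_per_field:.1f} per {REFERENCE_FIELD_MM2} mm^2, "
            f"band area {self.band_area_mm2:.3f} mm^2)",
        ]
        if self.rfp_coverage_pct is not None:
            lines.append(f"Labelled-area coverage: {self.rfp_coverage_pct:.1f}%")
        return "\n".join(lines)


def _box_to_px(image: AnnotatedImage, box_um: Tuple[float, float, float, float]):
    x0, x1, y0, y1 = box_um
    if not (x0 < x1 and y0 < y1):
        raise GeometryError("box must satisfy x0 < x1 and y0 < y1")
    h, w = image.shape
    s = image.um_per_px
    c0, c1 = int(np.floor(x0 / s)), int(np.ceil(x1 / s))
    r0, r1 = int(np.floor(y0 / s)), int(np.ceil(y1 / s))
    if c0 < 0 or r0 < 0 or c1 > w or r1 > h:
        raise GeometryError("box extends outside the image")
    return r0, r1, c0, c1


def intensity_profile(
    image: AnnotatedImage, box_um: Tuple[float, float, float, float]
) -> IntensityProfile:
    """Mean intensity profile along the boundary normal within a box.

    ``box_um = (x0, x1, y0, y1)``; the box must straddle the boundary.  The
    profile value at distance d is the mean signal over the box cross-section
    at that distance; bins are one pixel wide and distances are signed,
    positive into the host.
    """
    r0, r1, c0, c1 = _box_to_px(image, box_um)
    sub = image.signal[r0:r1, c0:c1]
    s = image.um_per_px
    if image.boundary.orientation == "vertical":
        coords = (np.arange(c0, c1) + 0.5) * s
        values = sub.mean(axis=0)
    else:
        coords = (np.arange(r0, r1) + 0.5) * s
        values = sub.mean(axis=1)
    dists = image.boundary.host_side * (coords - image.boundary.position_um)
    if dists.min() > 0 or dists.max() < 0:
        raise GeometryError("box does not intersect the boundary")
    order = np.argsort(dists)
    return IntensityProfile(distances_um=dists[order], values=values[order])


def outgrowth_distance(profile: IntensityProfile, threshold: float) -> float:
    """Farthest supra-threshold distance beyond the boundary, in um.

    Returns the largest d > 0 with profile value >= threshold, or 0 when no
    bin beyond the boundary reaches the threshold.
    """
    beyond = profile.distances_um > 0
    supra = beyond & (profile.values >= threshold)
    if not np.any(supra):
        return 0.0
    return float(np.max(profile.distances_um[supra]))


def _blob_labels(channel: np.ndarray, threshold: float):
    return cc_label(channel >= threshold, connectivity=2)


def count_migrated_cells(
    image: AnnotatedImage,
    band_um: Tuple[float, float] = DEFAULT_BAND_UM,
    soma_area_um2: Tuple[float, float] = DEFAULT_SOMA_AREA_UM2,
    threshold: Optional[float] = None,
    nuclei_threshold: Optional[float] = None,
) -> MigrationResult:
    """Count nucleus-colocalised labelled somata in a distance band.

    Supra-threshold connected components of the signal channel whose pixel
    footprint falls in the plausible soma-area range count as somata; a soma
    is a migrated neuron when its centroid lies ``band_um`` (default
    200-400 um) beyond the boundary on the host side and at least one of its
    pixels overlaps a nuclear-channel blob.  Density is the count normalised
    to 0.1 mm^2 of band area present in the image.
    """
    if image.nuclei is None:
        raise InputError("nuclei channel required for migrated-cell counting")
    lo, hi = band_um
    if not (0 <= lo < hi):
        raise InputError("band must satisfy 0 <= lo < hi")
    thr = image.effective_threshold() if threshold is None else float(threshold)
    if nuclei_threshold is None:
        nvals = image.nuclei[image.nuclei > 0]
        nuclei_threshold = float(threshold_otsu(image.nuclei)) if nvals.size and np.ptp(image.nuclei) > 0 else 0.5
    nuclei_mask = image.nuclei >= nuclei_threshold

    labels = _blob_labels(image.signal, thr)
    s = image.um_per_px
    px_area = s * s
    count = 0
    centroids: List[Tuple[float, float]] = []
    for region in regionprops(labels):
        area_um2 = region.area * px_area
        if not (soma_area_um2[0] <= area_um2 <= soma_area_um2[1]):
            continue
        cy, cx = region.centroid  # row, col
        x_um, y_um = (cx + 0.5) * s, (cy + 0.5) * s
        d = float(image.boundary.signed_distance_um(x_um, y_um))
        if not (lo <= d <= hi):
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        if not np.any(nuclei_mask[rr, cc]):
            continue
        count += 1
        centroids.append((x_um, y_um))

    xg, yg = image.pixel_centers_um()
    dgrid = image.boundary.signed_distance_um(xg, yg)
    band_px = int(np.count_nonzero((dgrid >= lo) & (dgrid <= hi)))
    band_area_mm2 = band_px * px_area / 1e6
    density = count * REFERENCE_FIELD_MM2 / band_area_mm2 if band_area_mm2 > 0 else float("nan")
    return MigrationResult(
        count=count,
        band_um=(lo, hi),
        band_area_mm2=band_area_mm2,
        density_per_field=density,
        centroids_um=centroids,
    )


def rfp_coverage(
    image: AnnotatedImage,
    region_um: Tuple[float, float, float, float],
    threshold: Optional[float] = None,
) -> float:
    """Percent supra-threshold labelled pixels within a rectangular region."""
    r0, r1, c0, c1 = _box_to_px(image, region_um)
    sub = image.signal[r0:r1, c0:c1]
    if sub.size == 0:
        raise GeometryError("empty region")
    thr = image.effective_threshold() if threshold is None else float(threshold)
    return 100.0 * float(np.count_nonzero(sub >= thr)) / sub.size
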