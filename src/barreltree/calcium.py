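"""Spontaneous-activity analysis of thalamocortical calcium movies.

Neonatal barrel-cortex L4 shows "patchwork" spontaneous activity: each
activated zone of a ΔF/F movie coincides with a single barrel.  This
module computes per-pixel ΔF/F against a quiescent-frame baseline,
segments activated zones (Gaussian smoothing, ΔF/F > 100%, 8-connected
components, 2500 µm² area filter), accumulates boundary heat maps, and
builds the ROI-grid analyses: 40 (5x8) circular ROIs of 20 µm diameter at
50 µm spacing, their ΔF/F traces, event rasters (ΔF/F > 50%), Pearson
correlation matrices and a principal-component ordering that groups
high-synchrony ROI blocks (barrels) contiguously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "CalciumMovie",
    "ActivatedZone",
    "RoiTraceSet",
    "CalciumError",
    "compute_f0",
    "compute_dff",
    "detect_activated_zones",
    "zones_from_movie",
    "zone_boundary_heatmap",
    "zone_area_stats",
    "default_roi_grid",
    "extract_roi_traces",
    "rasterize",
    "correlation_matrix",
    "pca_order",
]

EIGHT_CONN = np.ones((3, 3), dtype=int)


class CalciumError(ValueError):
    pass


@dataclass
class CalciumMovie:
    """T x H x W fluorescence stack with imaging metadata."""

    frames: np.ndarray
    um_per_px: float
    hz: float = 1.0
    excluded_frames: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise CalciumError("frames must be T x H x W")
        if np.any(self.frames < 0):
            raise CalciumError("intensities must be >= 0")

    def usable(self) -> np.ndarray:
        """Frames with motion-excluded ones dropped."""
        if not self.excluded_frames:
            return self.frames
        keep = np.ones(len(self.frames), bool)
        keep[list(self.excluded_frames)] = False
        return self.frames[keep]


@dataclass(frozen=True)
class ActivatedZone:
    """One connected supra-threshold region in one frame."""

    frame: int
    mask: np.ndarray              # H x W bool
    boundary: np.ndarray          # (k, 2) row/col contour vertices (px)
    area_um2: float

    @property
    def centroid_px(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        return float(rr.mean()), float(cc.mean())


@dataclass
class RoiTraceSet:
    """ΔF/F traces of the ROI grid plus the display ordering."""

    centers_px: np.ndarray        # (n, 2) row/col
    radius_px: float
    traces: np.ndarray            # (n, T)
    order: np.ndarray | None = None


# ---------------------------------------------------------------------------
# baseline and ΔF/F
# ---------------------------------------------------------------------------


def compute_f0(
    movie: CalciumMovie,
    quiescent_frames: np.ndarray | None = None,
    min_frames: int = 50,
    auto_fraction: float = 0.2,
) -> np.ndarray:
    """Per-pixel baseline F0 from quiescent frames.

    If no quiescent frames are given, the lowest-mean ``auto_fraction`` of
    usable frames (at least ``min_frames``) are used — the frames with the
    least field-wide activity.
    """
    frames = movie.usable()
    if quiescent_frames is None:
        means = frames.mean(axis=(1, 2))
        n = max(min_frames, int(np.ceil(auto_fraction * len(frames))))
        if len(frames) < n:
            raise CalciumError(
                f"need >= {n} usable frames for automatic F0, have {len(frames)}"
            )
        idx = np.argsort(means)[:n]
        sel = frames[idx]
    else:
        sel = frames[np.asarray(quiescent_frames, int)]
        if len(sel) < min_frames:
            raise CalciumError(f"need >= {min_frames} quiescent frames")
    f0 = sel.mean(axis=0)
    bad = int((f0 <= 0).sum())
    if bad:
        raise CalciumError(f"F0 has {bad} non-positive pixels")
    return f0


def compute_dff(movie: CalciumMovie, f0: np.ndarray) -> np.ndarray:
    """ΔF/F = (F - F0) / F0 per pixel per usable frame."""
    return (movie.usable() - f0) / f0


# ---------------------------------------------------------------------------
# activated-zone segmentation
# ---------------------------------------------------------------------------


def _zones_in_frame(
    img: np.ndarray,
    frame_idx: int,
    thresh: float,
    min_area_px: float,
    px_area_um2: float,
) -> list[ActivatedZone]:
    mask = img > thresh
    labels, n = ndimage.label(mask, structure=EIGHT_CONN)
    zones = []
    for lab in range(1, n + 1):
        comp = labels == lab
        npx = int(comp.sum())
        if npx < min_area_px:
            continue
        contours = measure.find_contours(comp.astype(float), 0.5)
        boundary = max(contours, key=len) if contours else np.empty((0, 2))
        zones.append(
            ActivatedZone(
                frame=frame_idx,
                mask=comp,
                boundary=boundary,
                area_um2=npx * px_area_um2,
            )
        )
    return zones


def detect_activated_zones(
    dff: np.ndarray,
    um_per_px: float,
    sigma_px: float = 10.0,
    thresh: float = 1.0,
    min_area_um2: float = 2500.0,
    smooth: bool = True,
) -> list[list[ActivatedZone]]:
    """Segment activated zones per ΔF/F frame.

    Each frame is Gaussian-smoothed (``sigma_px``, set ``smooth=False`` if
    the input stack was smoothed upstream), thresholded at ΔF/F >
    ``thresh`` (strict), 8-connected-component labeled, filtered at
    ``min_area_um2`` (zones smaller than the cutoff are noise; a zone of
    exactly the cutoff area is retained), and its boundary traced by
    marching squares.
    """
    px_area = um_per_px**2
    min_area_px = min_area_um2 / px_area
    out = []
    for t, img in enumerate(np.asarray(dff, float)):
        if smooth and sigma_px > 0:
            img = ndimage.gaussian_filter(img, sigma=sigma_px)
        out.append(_zones_in_frame(img, t, thresh, min_area_px, px_area))
    return out


def zones_from_movie(
    movie: CalciumMovie,
    quiescent_frames: np.ndarray | None = None,
    sigma_px: float = 10.0,
    thresh: float = 1.0,
    min_area_um2: float = 2500.0,
    smooth_raw_first: bool = True,
) -> list[list[ActivatedZone]]:
    """Movie -> activated zones pipeline.

    With ``smooth_raw_first`` (default) each raw frame is spatially
    smoothed before F0 and ΔF/F are computed; otherwise ΔF/F is computed
    on raw frames and the ΔF/F image is smoothed instead.  Both orders are
    near-equivalent for smooth baselines; the default follows the
    raw-image-first processing order.
    """
    if smooth_raw_first and sigma_px > 0:
        sm = np.stack(
            [ndimage.gaussian_filter(f, sigma=sigma_px) for f in movie.frames]
        )
        movie = CalciumMovie(
            frames=sm,
            um_per_px=movie.um_per_px,
            hz=movie.hz,
            excluded_frames=list(movie.excluded_frames),
        )
        f0 = compute_f0(movie, quiescent_frames)
        dff = compute_dff(movie, f0)
        return detect_activated_zones(
            dff, movie.um_per_px, sigma_px, thresh, min_area_um2, smooth=False
        )
    f0 = compute_f0(movie, quiescent_frames)
    dff = compute_dff(movie, f0)
    return detect_activated_zones(
        dff, movie.um_per_px, sigma_px, thresh, min_area_um2, smooth=True
    )


def zone_boundary_heatmap(
    zones: list[list[ActivatedZone]], shape: tuple[int, int]
) -> np.ndarray:
    """Count, per pixel, how often it lay on an activated-zone boundary."""
    heat = np.zeros(shape, dtype=int)
    for frame_zones in zones:
        for z in frame_zones:
            interior = ndimage.binary_erosion(z.mask, structure=EIGHT_CONN)
            heat[z.mask & ~interior] += 1
    return heat


def zone_area_stats(zones: list[list[ActivatedZone]]) -> dict:
    """Mean/SD area and event count over all single activated zones."""
    areas = np.array(
        [z.area_um2 for frame_zones in zones for z in frame_zones], float
    )
    return {
        "n_zones": int(len(areas)),
        "mean_area_um2": float(areas.mean()) if len(areas) else float("nan"),
        "sd_area_um2": float(areas.std(ddof=1)) if len(areas) > 1 else float("nan"),
    }


# ---------------------------------------------------------------------------
# ROI grid, rasters, correlation, PCA ordering
# ---------------------------------------------------------------------------


def default_roi_grid(
    shape: tuple[int, int],
    um_per_px: float,
    n_rows: int = 5,
    n_cols: int = 8,
    spacing_um: float = 50.0,
    diameter_um: float = 20.0,
) -> tuple[np.ndarray, float]:
    """Centered 5x8 grid of circular ROIs; returns (centers_px, radius_px)."""
    spacing = spacing_um / um_per_px
    radius = diameter_um / 2 / um_per_px
    h, w = shape
    r0 = (h - (n_rows - 1) * spacing) / 2
    c0 = (w - (n_cols - 1) * spacing) / 2
    centers = np.array(
        [
            (r0 + i * spacing, c0 + j * spacing)
            for i in range(n_rows)
            for j in range(n_cols)
        ]
    )
    if (centers - radius < 0).any() or (
        centers[:, 0] + radius > h
    ).any() or (centers[:, 1] + radius > w).any():
        raise CalciumError("ROI grid does not fit inside the field")
    return centers, radius


def extract_roi_traces(
    dff: np.ndarray,
    centers_px: np.ndarray,
    radius_px: float,
) -> RoiTraceSet:
    """Mean ΔF/F over each circular ROI per frame."""
    t, h, w = dff.shape
    rr, cc = np.mgrid[0:h, 0:w]
    traces = np.empty((len(centers_px), t))
    for i, (r, c) in enumerate(centers_px):
        disk = (rr - r) ** 2 + (cc - c) ** 2 <= radius_px**2
        if not disk.any():
            raise CalciumError(f"ROI {i} covers no pixels")
        traces[i] = dff[:, disk].mean(axis=1)
    return RoiTraceSet(centers_px=np.asarray(centers_px), radius_px=radius_px,
                       traces=traces)


def rasterize(traces: np.ndarray, thresh: float = 0.5) -> np.ndarray:
    """Boolean event raster: ΔF/F strictly above ``thresh``."""
    return np.asarray(traces) > thresh


def correlation_matrix(traces: np.ndarray) -> np.ndarray:
    """Pearson correlation of all ROI pairs.

    Zero-variance traces yield NaN rows/columns (undefined correlation);
    the diagonal stays 1 for well-defined traces.
    """
    tr = np.asarray(traces, float)
    sd = tr.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(tr)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    return corr


def pca_order(corr: np.ndarray) -> np.ndarray:
    """ROI ordering by first-principal-component score of the correlations.

    Rows of the correlation matrix are projected onto the first principal
    component; ROIs are ranked by ascending score.  The PC sign is fixed
    by requiring the first ROI's score to be non-negative.  NaN rows
    (zero-variance ROIs) are excluded from the fit and appended at the end
    in index order.
    """
    corr = np.asarray(corr, float)
    valid = ~np.isnan(corr).all(axis=1)
    idx = np.flatnonzero(valid)
    sub = corr[np.ix_(idx, idx)]
    centered = sub - sub.mean(axis=0)
    # first right singular vector = first PC of the rows
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    scores = centered @ vt[0]
    if scores[0] < 0:
        scores = -scores
    order_valid = idx[np.argsort(scores, kind="stable")]
    rest = np.flatnonzero(~valid)
    return np.concatenate([order_valid, rest]).astype(int)
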