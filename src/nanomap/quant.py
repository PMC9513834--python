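"""Quantification of cell behavior from fluorescence images.

Turns images into the discretized observations the mapping stage consumes:
segmented per-cell morphology (area, circularity, axis lengths), per-tile
mean intensities, structure-tensor orientation statistics, skeleton-based
neurite lengths, and CFSE/DAPI proliferation ratios.

Conventions: pixel size defaults to 0.65 um/px; objects are segmented with
a global Otsu threshold, 8-connected components, and an inclusive
[8, 80] px area filter; ``polarization`` is 1 - circularity.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology

log = logging.getLogger(__name__)

PIXEL_SIZE_UM = 0.65


def load_image(path) -> np.ndarray:
    """Read a TIFF/PNG image (8- or 16-bit) as a 2D array."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        return np.asarray(tifffile.imread(path))
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:  # collapse RGB(A) to grayscale
        img = img[..., :3].mean(axis=-1)
    return img


def subtract_background(image: np.ndarray, radius_px: int) -> np.ndarray:
    """Remove smooth illumination background by morphological opening.

    A grayscale opening with a disk of ``radius_px`` (larger than any
    object of interest) estimates the background, which is subtracted and
    the result clipped at zero — the rolling-ball-equivalent correction.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    if radius_px >= min(image.shape):
        raise ValueError("radius_px must be smaller than the image")
    img = np.asarray(image, dtype=float)
    # odd reflection continues linear trends across the border, so smooth
    # illumination gradients are estimated correctly up to the edge
    padded = np.pad(img, radius_px, mode="reflect", reflect_type="odd")
    bg = ndimage.grey_opening(padded, footprint=morphology.disk(radius_px))
    bg = bg[radius_px:-radius_px, radius_px:-radius_px]
    return np.clip(img - bg, 0.0, None)


@dataclass
class SegmentedObject:
    """One segmented cell with morphology and intensity readouts."""

    id: int
    x_um: float
    y_um: float
    area_px: int
    area_um2: float
    perimeter_px: float
    circularity: float
    major_axis_um: float
    minor_axis_um: float
    mean_intensity: float
    coords: np.ndarray = field(repr=False, default=None)

    @property
    def polarization(self) -> float:
        """Shape polarization, defined as 1 - circularity."""
        return 1.0 - self.circularity


def measure_shape(mask: np.ndarray) -> dict:
    """Area, perimeter, circularity (4 pi A / P^2) and ellipse axes of a mask.

    Perimeter follows the scikit-image contour convention; a single-pixel
    mask is assigned perimeter 1 and circularity clipped into (0, 1].
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    area = float(props.area)
    perim = float(props.perimeter)
    if perim <= 0:
        perim = 1.0  # single-pixel convention
    circ = float(np.clip(4.0 * math.pi * area / perim ** 2, 1e-9, 1.0))
    major = float(max(props.axis_major_length, 1.0))
    minor = float(max(props.axis_minor_length, 0.5))
    return {
        "area_px": area,
        "perimeter_px": perim,
        "circularity": circ,
        "major_axis_px": major,
        "minor_axis_px": minor,
        "polarization": 1.0 - circ,
    }


def detect_objects(image: np.ndarray,
                   min_area_px: int = 8,
                   max_area_px: int = 80,
                   pixel_size_um: float = PIXEL_SIZE_UM,
                   threshold: float | None = None,
                   origin_um: tuple = (0.0, 0.0)) -> list:
    """Segment fluorescent objects and keep those within the area filter.

    Global Otsu threshold (override with ``threshold``), 8-connected
    components, inclusive [min_area_px, max_area_px] filter.  Centroids are
    reported in um relative to ``origin_um``.  A blank image yields an
    empty list.
    """
    if min_area_px >= max_area_px:
        raise ValueError("min_area_px must be < max_area_px")
    img = np.asarray(image, dtype=float)
    if threshold is None:
        if np.ptp(img) == 0:
            return []
        threshold = filters.threshold_otsu(img)
    binary = img > threshold
    labels = measure.label(binary, connectivity=2)
    out = []
    oid = 0
    for props in measure.regionprops(labels, intensity_image=img):
        if not (min_area_px <= props.area <= max_area_px):
            continue
        perim = float(props.perimeter) or 1.0
        circ = float(np.clip(4.0 * math.pi * props.area / perim ** 2,
                             1e-9, 1.0))
        cy, cx = props.centroid
        out.append(SegmentedObject(
            id=oid,
            x_um=origin_um[0] + cx * pixel_size_um,
            y_um=origin_um[1] + cy * pixel_size_um,
            area_px=int(props.area),
            area_um2=float(props.area) * pixel_size_um ** 2,
            perimeter_px=perim,
            circularity=circ,
            major_axis_um=float(max(props.axis_major_length, 1.0)) * pixel_size_um,
            minor_axis_um=float(max(props.axis_minor_length, 0.5)) * pixel_size_um,
            mean_intensity=float(props.intensity_mean),
            coords=props.coords,
        ))
        oid += 1
    return out


def objects_to_dataframe(objects: list) -> pd.DataFrame:
    rows = [{
        "id": o.id, "x_um": o.x_um, "y_um": o.y_um, "area_px": o.area_px,
        "area_um2": o.area_um2, "perimeter_px": o.perimeter_px,
        "circularity": o.circularity, "polarization": o.polarization,
        "major_axis_um": o.major_axis_um, "minor_axis_um": o.minor_axis_um,
        "mean_intensity": o.mean_intensity,
    } for o in objects]
    return pd.DataFrame(rows)


@dataclass
class TileIntensity:
    """Mean intensity of one tile of the pixelized image."""

    index: int
    x_um: float
    y_um: float
    mean_intensity: float
    tile_px: tuple


def _grid_shape(n_tiles: int, aspect: float) -> tuple:
    """Factor n_tiles into (rows, cols) closest to the image aspect W/H."""
    best = None
    for r in range(1, n_tiles + 1):
        if n_tiles % r:
            continue
        c = n_tiles // r
        mis = abs(math.log((c / r) / aspect))
        if best is None or mis < best[0]:
            best = (mis, r, c)
    if best[0] > math.log(2.0) + 1e-9:
        raise ValueError(
            f"n_tiles={n_tiles} cannot form a grid within 2x of the image "
            f"aspect ratio {aspect:.2f}")
    return best[1], best[2]


def pixelize_intensity(image: np.ndarray,
                       n_tiles: int,
                       pixel_size_um: float = PIXEL_SIZE_UM,
                       background_radius_px: int | None = None,
                       origin_um: tuple = (0.0, 0.0)) -> list:
    """Partition the image into ``n_tiles`` tiles and average each.

    ``n_tiles`` must lie in [48, 576] (the screening-pipeline bound).  The
    tile grid covers the image exactly (tile edges from integer splits).
    If ``background_radius_px`` is given the image is background-subtracted
    first.
    """
    if not 48 <= n_tiles <= 576:
        raise ValueError(f"n_tiles={n_tiles} outside the allowed [48, 576]")
    img = np.asarray(image, dtype=float)
    if background_radius_px is not None:
        img = subtract_background(img, background_radius_px)
    H, W = img.shape
    rows, cols = _grid_shape(n_tiles, W / H)
    r_edges = np.linspace(0, H, rows + 1).round().astype(int)
    c_edges = np.linspace(0, W, cols + 1).round().astype(int)
    tiles = []
    k = 0
    for i in range(rows):
        for j in range(cols):
            sub = img[r_edges[i]:r_edges[i + 1], c_edges[j]:c_edges[j + 1]]
            cy = 0.5 * (r_edges[i] + r_edges[i + 1])
            cx = 0.5 * (c_edges[j] + c_edges[j + 1])
            tiles.append(TileIntensity(
                index=k,
                x_um=origin_um[0] + cx * pixel_size_um,
                y_um=origin_um[1] + cy * pixel_size_um,
                mean_intensity=float(sub.mean()),
                tile_px=(r_edges[i + 1] - r_edges[i],
                         c_edges[j + 1] - c_edges[j]),
            ))
            k += 1
    return tiles


def tiles_to_dataframe(tiles: list) -> pd.DataFrame:
    return pd.DataFrame([{
        "index": t.index, "x_um": t.x_um, "y_um": t.y_um,
        "mean_intensity": t.mean_intensity,
        "tile_rows_px": t.tile_px[0], "tile_cols_px": t.tile_px[1],
    } for t in tiles])


@dataclass
class OrientationHistogram:
    """Axial orientation distribution of image texture, in degrees."""

    bin_edges_deg: np.ndarray
    weights: np.ndarray
    dominant_angle_deg: float
    alignment_score: float
    flagged: bool = False

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_deg[:-1] + self.bin_edges_deg[1:])


def orientation_histogram(image: np.ndarray,
                          bin_width_deg: float = 2.0,
                          sigma_px: float = 2.0) -> OrientationHistogram:
    """Structure-tensor orientation analysis of fiber/axon texture.

    Local orientations (axial, in [-90, 90) degrees; 0 = horizontal) are
    estimated from the smoothed structure tensor, weighted by gradient
    energy times coherence, and binned.  ``alignment_score`` is one minus
    the circular variance on doubled angles (1 = perfectly parallel
    texture, 0 = isotropic); ``dominant_angle_deg`` is the axial circular
    mean around the modal bin.
    """
    img = np.asarray(image, dtype=float)
    if min(img.shape) < 8:
        raise ValueError("image too small for orientation analysis")
    # Gaussian derivative filters: near-isotropic, avoids the angular bias
    # of finite-difference gradients
    gx = ndimage.gaussian_filter(img, sigma_px * 0.5, order=(0, 1))
    gy = ndimage.gaussian_filter(img, sigma_px * 0.5, order=(1, 0))
    Jxx = ndimage.gaussian_filter(gx * gx, sigma_px)
    Jxy = ndimage.gaussian_filter(gx * gy, sigma_px)
    Jyy = ndimage.gaussian_filter(gy * gy, sigma_px)
    energy = Jxx + Jyy
    if not np.any(energy > 0):
        n_bins = int(round(180.0 / bin_width_deg))
        edges = np.linspace(-90.0, 90.0, n_bins + 1)
        warnings.warn("zero-gradient image: no orientation content")
        return OrientationHistogram(edges, np.full(n_bins, 1.0 / n_bins),
                                    0.0, 0.0, flagged=True)
    # gradient axial direction; the structure runs perpendicular to it
    theta_grad = 0.5 * np.arctan2(2.0 * Jxy, Jxx - Jyy)
    theta = theta_grad + np.pi / 2.0
    theta = np.mod(theta + np.pi / 2.0, np.pi) - np.pi / 2.0  # [-pi/2, pi/2)
    lam_diff = np.sqrt((Jxx - Jyy) ** 2 + 4.0 * Jxy ** 2)
    coherence = np.where(energy > 0, lam_diff / (energy + 1e-30), 0.0)
    w = (energy * coherence).ravel()
    ang = np.degrees(theta).ravel()
    n_bins = int(round(180.0 / bin_width_deg))
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    hist, _ = np.histogram(ang, bins=edges, weights=w)
    total = hist.sum()
    if total <= 0:
        warnings.warn("no coherent texture found")
        return OrientationHistogram(edges, np.full(n_bins, 1.0 / n_bins),
                                    0.0, 0.0, flagged=True)
    weights = hist / total
    # alignment: resultant length of doubled angles
    ang2 = np.radians(ang) * 2.0
    wsum = w.sum()
    C = float((w * np.cos(ang2)).sum() / wsum)
    S = float((w * np.sin(ang2)).sum() / wsum)
    alignment = float(np.hypot(C, S))
    # dominant angle: axial circular mean over the modal bin neighbourhood
    mode = int(np.argmax(weights))
    take = [(mode + d) % n_bins for d in (-2, -1, 0, 1, 2)]
    centers = 0.5 * (edges[:-1] + edges[1:])
    cw = weights[take]
    ca = np.radians(centers[take]) * 2.0
    dom = 0.5 * math.atan2(float((cw * np.sin(ca)).sum()),
                           float((cw * np.cos(ca)).sum()))
    dom_deg = math.degrees(dom)
    if dom_deg >= 90.0:
        dom_deg -= 180.0
    if dom_deg < -90.0:
        dom_deg += 180.0
    return OrientationHistogram(edges, weights, dom_deg, alignment)


def neurite_lengths(image: np.ndarray,
                    pixel_size_um: float = PIXEL_SIZE_UM,
                    threshold: float | None = None,
                    exclude_entangled: bool = True,
                    size_regime_map: np.ndarray | None = None) -> pd.DataFrame:
    """Skeleton path length per connected neurite, in um.

    The image is thresholded (Otsu default), skeletonized, and each
    8-connected skeleton component's length is measured as the sum of
    inter-pixel link lengths (1 px for orthogonal, sqrt(2) for diagonal
    steps).  Components whose skeleton contains a branch point are treated
    as entangled bundles and excluded when ``exclude_entangled``; if a
    per-column ``size_regime_map`` (integer regime id per image column) is
    supplied, components spanning more than one regime are excluded too.
    Returns a table with columns id, length_um, n_px, excluded, reason.
    """
    img = np.asarray(image, dtype=float)
    if np.ptp(img) == 0:
        return pd.DataFrame(columns=["id", "length_um", "n_px",
                                     "excluded", "reason"])
    if threshold is None:
        threshold = filters.threshold_otsu(img)
    skel = morphology.skeletonize(img > threshold)
    labels = measure.label(skel, connectivity=2)
    nbr_count = ndimage.convolve(skel.astype(int), np.ones((3, 3)),
                                 mode="constant") - skel.astype(int)
    rows = []
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        n_px = int(comp.sum())
        # link-count length: orthogonal and diagonal neighbour pairs
        length_px = 0.0
        for (dy, dx), wgt in (((0, 1), 1.0), ((1, 0), 1.0),
                              ((1, 1), math.sqrt(2)), ((1, -1), math.sqrt(2))):
            a = comp[max(dy, 0):comp.shape[0] - max(-dy, 0),
                     max(dx, 0):comp.shape[1] - max(-dx, 0)]
            b = comp[max(-dy, 0):comp.shape[0] - max(dy, 0),
                     max(-dx, 0):comp.shape[1] - max(dx, 0)]
            length_px += wgt * np.logical_and(a, b).sum()
        excluded, reason = False, ""
        if exclude_entangled and np.any(nbr_count[comp] > 2):
            excluded, reason = True, "entangled (branched skeleton)"
        if size_regime_map is not None and not excluded:
            cols = np.nonzero(comp.any(axis=0))[0]
            regimes = np.unique(np.asarray(size_regime_map)[cols])
            if len(regimes) > 1:
                excluded, reason = True, "spans multiple size regimes"
        rows.append({"id": lab, "length_um": length_px * pixel_size_um,
                     "n_px": n_px, "excluded": excluded, "reason": reason})
    df = pd.DataFrame(rows)
    n_excl = int(df["excluded"].sum()) if len(df) else 0
    if n_excl:
        log.info("neurite_lengths: excluded %d/%d components", n_excl, len(df))
    return df


def proliferation_ratio(cfse_image: np.ndarray,
                        dapi_image: np.ndarray,
                        objects: list,
                        background_radius_px: int | None = None) -> pd.DataFrame:
    """Per-object CFSE/DAPI mean-intensity ratio (dye-dilution readout).

    Invariant under common scaling of both channels.  Objects with
    (near-)zero DAPI signal are dropped with a log entry.
    """
    cfse = np.asarray(cfse_image, dtype=float)
    dapi = np.asarray(dapi_image, dtype=float)
    if cfse.shape != dapi.shape:
        raise ValueError("CFSE and DAPI images must have the same shape")
    if background_radius_px is not None:
        cfse = subtract_background(cfse, background_radius_px)
        dapi = subtract_background(dapi, background_radius_px)
    rows, dropped = [], 0
    for o in objects:
        rr, cc = o.coords[:, 0], o.coords[:, 1]
        denom = float(dapi[rr, cc].mean())
        if denom <= 1e-12:
            dropped += 1
            continue
        rows.append({"id": o.id, "x_um": o.x_um, "y_um": o.y_um,
                     "ratio": float(cfse[rr, cc].mean()) / denom})
    if dropped:
        log.info("proliferation_ratio: dropped %d objects with zero DAPI",
                 dropped)
    return pd.DataFrame(rows, columns=["id", "x_um", "y_um", "ratio"])
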