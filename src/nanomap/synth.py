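"""Synthetic cell observations and fluorescence-like images on a gradient array.

Real screens of this kind measure thousands of cells scattered over a 1 cm
gradient line array; each cell's behavior (adhesion area, proliferation,
differentiation intensity, axonal growth/alignment) depends on the local
feature size through a peaked response curve, and substantial parts of the
substrate are cell-free, which naively reads as "zero behavior" there.
This module generates such data with a *known* ground-truth response so the
quantification, mapping and scoring stages can be validated end to end:

* scattered (x, y) cell positions from a homogeneous Poisson process with
  rectangular cell-free voids,
* behavior values from a log-Gaussian size-response model plus Gaussian
  measurement noise (the true noiseless values are retained),
* rendered 16-bit images with soft-edged anisotropic cell blobs and
  oriented fiber textures for the orientation analysis.

Everything is reproducible bitwise from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from nanomap.optics import TopographyProfile

BEHAVIORS = ("adhesion", "proliferation", "differentiation",
             "axonal_growth", "axonal_alignment")

FULL_SCALE = 65535          # 16-bit rendering
BACKGROUND_FRAC = 0.05      # background level, fraction of full scale


@dataclass(frozen=True)
class ResponseModel:
    """Peaked log-Gaussian size-response of one behavior.

    mean(s) = baseline + amplitude * exp(-(log s - log s0)^2 / (2 sigma^2))

    with s the local feature size (um), s0 = ``peak_size_um`` and
    sigma = ``log_width`` in natural-log size units.  Monotone responses
    (e.g. adhesion favouring the largest pattern) are modelled by placing
    s0 at the edge of the size range.
    """

    behavior_name: str
    peak_size_um: float
    log_width: float = 1.0
    amplitude: float = 1.0
    baseline: float = 0.2
    noise_sd: float = 0.1

    def __post_init__(self):
        if self.behavior_name not in BEHAVIORS:
            raise ValueError(f"unknown behavior {self.behavior_name!r}")
        if self.peak_size_um <= 0 or self.log_width <= 0:
            raise ValueError("peak_size_um and log_width must be positive")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be >= 0")

    def mean(self, size_um) -> np.ndarray:
        s = np.asarray(size_um, dtype=float)
        z = (np.log(s) - np.log(self.peak_size_um)) / self.log_width
        return self.baseline + self.amplitude * np.exp(-0.5 * z * z)


def default_response_models(amplitude_scale: float = 1.0,
                            noise_sd: float = 0.1) -> dict:
    """Nominal response models for the five behaviors.

    Peak sizes follow the qualitative optima reported for neural stem
    cells on line gratings: adhesion favours the largest (20 um) lines,
    axonal growth peaks near 5 um, axonal alignment near 200 nm;
    proliferation and differentiation peaks are nominal mid-range choices.
    ``amplitude_scale`` < 1 emulates a mechano-insensitive cell type.
    """
    peaks = {"adhesion": 20.0, "proliferation": 1.0, "differentiation": 2.0,
             "axonal_growth": 5.0, "axonal_alignment": 0.2}
    return {b: ResponseModel(b, peaks[b], amplitude=amplitude_scale,
                             noise_sd=noise_sd) for b in BEHAVIORS}


@dataclass
class SyntheticScene:
    """A generated screen: topography + cells + voids, fully seeded."""

    topography: TopographyProfile
    cells: pd.DataFrame            # id, x_um, y_um, size_um, true_value, value, ...
    void_regions: list             # (x0, y0, x1, y1) um rectangles
    seed: int
    density_per_cm2: float
    height_um: float               # vertical extent of the array

    @property
    def bounds_um(self):
        x0 = float(self.topography.positions_um[0])
        x1 = float(self.topography.positions_um[-1])
        return x0, 0.0, x1, self.height_um

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


def _make_void_regions(x0, x1, y0, y1, void_fraction, rng,
                       grid=(6, 6)) -> list:
    """Non-overlapping rectangular voids covering ~void_fraction of the area.

    The domain is partitioned into a grid and whole grid cells are voided,
    so the void area is exact up to one cell.
    """
    if void_fraction == 0:
        return []
    nx, ny = grid
    n_void = int(round(void_fraction * nx * ny))
    n_void = min(n_void, nx * ny - 1)  # keep at least one populated cell
    idx = rng.choice(nx * ny, size=n_void, replace=False)
    xs = np.linspace(x0, x1, nx + 1)
    ys = np.linspace(y0, y1, ny + 1)
    out = []
    for k in sorted(idx):
        i, j = k % nx, k // nx
        out.append((xs[i], ys[j], xs[i + 1], ys[j + 1]))
    return out


def _in_void(x, y, voids):
    inside = np.zeros(len(x), dtype=bool)
    for (vx0, vy0, vx1, vy1) in voids:
        inside |= (x >= vx0) & (x < vx1) & (y >= vy0) & (y < vy1)
    return inside


def sample_cell_positions(topography: TopographyProfile,
                          density_per_cm2: float,
                          void_fraction: float = 0.0,
                          seed: int = 0,
                          height_um: float = 10000.0):
    """Homogeneous Poisson cell centers over the non-void array area.

    Returns (positions (n, 2) array in um, void_regions).  The expected
    count equals density * non-void area; identical seeds give identical
    positions.
    """
    if density_per_cm2 < 0:
        raise ValueError("density must be >= 0")
    if not 0 <= void_fraction < 1:
        raise ValueError("void_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    x0, x1 = float(topography.positions_um[0]), float(topography.positions_um[-1])
    voids = _make_void_regions(x0, x1, 0.0, height_um, void_fraction, rng)
    area_cm2 = (x1 - x0) * height_um / 1e8
    n = rng.poisson(density_per_cm2 * area_cm2)
    x = rng.uniform(x0, x1, n)
    y = rng.uniform(0.0, height_um, n)
    keep = ~_in_void(x, y, voids)
    return np.column_stack([x[keep], y[keep]]), voids


def sample_behavior_values(positions: np.ndarray,
                           topography: TopographyProfile,
                           model: ResponseModel,
                           seed: int = 0) -> pd.DataFrame:
    """Behavior value per cell from the size-response model plus noise.

    Columns: x_um, y_um, size_um, true_value (noiseless), value.
    """
    rng = np.random.default_rng(seed)
    x = positions[:, 0]
    sizes = topography.period_at(x)
    true = model.mean(sizes)
    noisy = true + rng.normal(0.0, model.noise_sd, len(x))
    return pd.DataFrame({
        "x_um": x, "y_um": positions[:, 1], "size_um": sizes,
        "true_value": true, "value": noisy,
    })


def make_scene(topography: TopographyProfile,
               model: ResponseModel,
               density_per_cm2: float = 10000.0,
               void_fraction: float = 0.3,
               seed: int = 0,
               height_um: float = 10000.0) -> SyntheticScene:
    """Generate a full scene: positions, behavior values, rendering shapes."""
    rng = np.random.default_rng(seed)
    pos_seed, val_seed, shape_seed = rng.integers(0, 2**31 - 1, 3)
    positions, voids = sample_cell_positions(
        topography, density_per_cm2, void_fraction, int(pos_seed), height_um)
    cells = sample_behavior_values(positions, topography, model, int(val_seed))
    srng = np.random.default_rng(int(shape_seed))
    n = len(cells)
    cells.insert(0, "id", np.arange(n))
    # rendered-shape parameters: pixel area within the 8-80 px screen window,
    # moderate elongation, uniform orientation
    cells["area_px"] = srng.uniform(15.0, 60.0, n)
    cells["aspect"] = np.exp(srng.uniform(0.0, np.log(3.0), n))
    cells["orientation_deg"] = srng.uniform(-90.0, 90.0, n)
    cells["behavior"] = model.behavior_name
    return SyntheticScene(topography, cells, voids, seed,
                          density_per_cm2, height_um)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _draw_ellipse(img, cx, cy, area_px, aspect, theta_deg, amplitude):
    """Additively draw a soft-edged elliptical blob of given pixel area."""
    a = np.sqrt(area_px * aspect / np.pi)   # semi-major, px
    b = np.sqrt(area_px / (np.pi * aspect))  # semi-minor
    r = int(np.ceil(max(a, b) + 3))
    x0, y0 = int(round(cx)), int(round(cy))
    H, W = img.shape
    if x0 + r < 0 or x0 - r >= W or y0 + r < 0 or y0 - r >= H:
        return
    yy, xx = np.mgrid[max(0, y0 - r):min(H, y0 + r + 1),
                      max(0, x0 - r):min(W, x0 + r + 1)]
    t = np.deg2rad(theta_deg)
    u = (xx - cx) * np.cos(t) + (yy - cy) * np.sin(t)
    v = -(xx - cx) * np.sin(t) + (yy - cy) * np.cos(t)
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    img[max(0, y0 - r):min(H, y0 + r + 1),
        max(0, x0 - r):min(W, x0 + r + 1)] += amplitude * mask


def render_fluorescence_image(scene: SyntheticScene, channel: str,
                              pixel_size_um: float = 0.65,
                              region_um: tuple | None = None,
                              noise: bool = True,
                              blur_px: float = 0.7) -> np.ndarray:
    """Render one 16-bit fluorescence channel of the scene.

    channel: ``actin`` (morphology, constant amplitude), ``tuj1_map2``
    (amplitude proportional to the behavior value), ``cfse`` (proportional),
    ``dapi`` (nuclear, constant).  ``region_um`` = (x0, y0, x1, y1) crops
    the rendered field; default renders the whole array (can be large).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if channel not in ("actin", "tuj1_map2", "cfse", "dapi"):
        raise ValueError(f"unknown channel {channel!r}")
    if region_um is None:
        bx0, by0, bx1, by1 = scene.bounds_um
    else:
        bx0, by0, bx1, by1 = region_um
    W = max(8, int(round((bx1 - bx0) / pixel_size_um)))
    H = max(8, int(round((by1 - by0) / pixel_size_um)))
    img = np.zeros((H, W), dtype=float)
    ref = max(float(np.max(np.abs(scene.cells["value"]))), 1e-12) \
        if len(scene.cells) else 1.0
    for row in scene.cells.itertuples():
        cx = (row.x_um - bx0) / pixel_size_um
        cy = (row.y_um - by0) / pixel_size_um
        if channel in ("tuj1_map2", "cfse"):
            amp = 0.55 * FULL_SCALE * max(row.value, 0.0) / ref
        else:
            amp = 0.55 * FULL_SCALE
        _draw_ellipse(img, cx, cy, row.area_px, row.aspect,
                      row.orientation_deg, amp)
    if blur_px > 0:
        img = ndimage.gaussian_filter(img, blur_px)
    img += BACKGROUND_FRAC * FULL_SCALE
    if noise:
        chan_idx = ("actin", "tuj1_map2", "cfse", "dapi").index(channel)
        rng = np.random.default_rng(scene.seed * 7919 + chan_idx)
        # shot-like noise: sd grows with the square root of the signal
        img = img + rng.normal(0.0, 1.0, img.shape) * np.sqrt(np.maximum(img, 0)) * 0.5
    return np.clip(img, 0, FULL_SCALE).astype(np.uint16)


def render_fiber_image(orientation_deg: float,
                       fiber_diameter_um: float,
                       pixel_size_um: float = 0.65,
                       seed: int = 0,
                       shape: tuple = (256, 256),
                       mean_gap_um: float | None = None) -> np.ndarray:
    """Parallel fiber/axon texture at a given orientation, 16-bit.

    Stripes of the given diameter run along ``orientation_deg`` (degrees,
    [-90, 90), 0 = horizontal), with Poisson-jittered spacing.  A
    non-positive diameter degenerates to an isotropic noise image (useful
    as a no-dominant-orientation control).
    """
    rng = np.random.default_rng(seed)
    H, W = shape
    if fiber_diameter_um <= 0:
        img = rng.normal(0.5, 0.15, shape)
        return np.clip(img * FULL_SCALE, 0, FULL_SCALE).astype(np.uint16)
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    t = np.deg2rad(orientation_deg)
    # signed distance across the fiber direction, in um
    d = (-np.sin(t) * xx + np.cos(t) * yy) * pixel_size_um
    gap = mean_gap_um if mean_gap_um is not None else 2.0 * fiber_diameter_um
    pitch_mean = fiber_diameter_um + gap
    span = float(d.max() - d.min())
    n_fibers = int(span / pitch_mean) + 4
    # Poisson-process fiber centerlines across the span
    centers = d.min() + np.sort(rng.uniform(0.0, span + 2 * pitch_mean,
                                            n_fibers)) - pitch_mean
    img = np.full(shape, BACKGROUND_FRAC * FULL_SCALE, dtype=float)
    half = fiber_diameter_um / 2.0
    for c in centers:
        img += 0.5 * FULL_SCALE * np.exp(-0.5 * ((d - c) / (0.6 * half + 1e-9)) ** 2)
    img += rng.normal(0.0, 0.02 * FULL_SCALE, shape)
    return np.clip(img, 0, FULL_SCALE).astype(np.uint16)
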