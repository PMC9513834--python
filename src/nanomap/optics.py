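"""Two-beam interference optics for gradient line-pattern arrays.

A collimated UV laser (default 325 nm He-Cd) illuminates the substrate
directly and, after reflection from a curved mirror standing at the edge of
the substrate, a second time at a position-dependent angle.  The two beams
interfere and expose a photoresist, producing a line grating whose local
period

    Lambda(x) = lambda / |sin(theta1) - s * sin(theta2(x))|

varies continuously along the substrate (theta measured from the substrate
normal; ``s`` is +1 when the beams arrive from the same azimuth and -1 when
they arrive from opposite sides).  A flat mirror (the Lloyd's-mirror limit,
realised here by a very long focal length) gives a constant period; a
curved mirror of radius R = 2f sweeps the reflected angle along the
substrate and produces a gradient of feature sizes spanning more than two
orders of magnitude.

The mirror is modelled as a circular arc in the 2D incidence plane, traced
exactly; the substrate coordinate ``x`` (micrometres, increasing away from
the mirror foot along the patterned side) is the position parameter that
downstream modules use to look up the local feature size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq


class PositionNotIlluminatedError(ValueError):
    """Raised when no mirror-reflected ray reaches the queried position."""

    def __init__(self, x_um: float):
        self.x_um = x_um
        super().__init__(
            f"position x={x_um:.3f} um is not illuminated by the "
            f"mirror-reflected beam under this geometry"
        )


@dataclass(frozen=True)
class InterferometerGeometry:
    """Optical configuration of the two-beam gradient interferometer.

    Parameters
    ----------
    wavelength_nm : laser wavelength (He-Cd line, 325 nm).
    beam_angle_deg : angle beta between the static beam and the substrate
        plane, in (0, 90).  The direct beam hits the substrate at beta from
        the plane, i.e. 90 - beta from the normal.
    focal_length_mm : focal length f of the curved mirror; the arc radius
        is R = 2 f.  Very large f approaches the flat Lloyd's mirror.
    mirror_curvature_sign : ``"concave"`` (default) or ``"convex"``, the
        side of the arc that faces the beam.
    substrate_length_mm : physical length of the substrate.
    mirror_offset_mm : signed distance of the mirror foot from the
        substrate origin along the patterned direction.
    """

    wavelength_nm: float = 325.0
    beam_angle_deg: float = 67.0
    focal_length_mm: float = 10.0
    mirror_curvature_sign: str = "concave"
    substrate_length_mm: float = 10.0
    mirror_offset_mm: float = 0.0

    def __post_init__(self):
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength_nm must be positive")
        if not 0.0 < self.beam_angle_deg < 90.0:
            raise ValueError("beam_angle_deg must lie in (0, 90)")
        if self.focal_length_mm <= 0:
            raise ValueError("focal_length_mm must be positive")
        if self.substrate_length_mm <= 0:
            raise ValueError("substrate_length_mm must be positive")
        if self.mirror_curvature_sign not in ("concave", "convex"):
            raise ValueError("mirror_curvature_sign must be 'concave' or 'convex'")

    @property
    def beta_rad(self) -> float:
        return math.radians(self.beam_angle_deg)

    @property
    def mirror_radius_mm(self) -> float:
        return 2.0 * self.focal_length_mm


# ---------------------------------------------------------------------------
# ray tracing against the circular-arc mirror (2D incidence plane)
# ---------------------------------------------------------------------------
# Physical frame: substrate along z=0, mirror foot at the origin with a
# vertical tangent.  The incoming collimated beam travels with direction
# d = (-cos(beta), -sin(beta)).  For the concave arc the reflected rays form
# a single-valued landing map on the x<0 side of the foot (the patterned
# strip used for gradient arrays); near the foot on the x>0 side lies a
# caustic fold which build_topography_profile avoids.


def _reflect(geometry: InterferometerGeometry, phi: float):
    """Mirror point, reflected direction and incidence dot at arc angle phi.

    Returns (P, d_refl, d_dot_n); the ray is physical only when
    d_dot_n < 0 (front-side incidence) and d_refl points downward.
    """
    b = geometry.beta_rad
    R = geometry.mirror_radius_mm
    d = np.array([-math.cos(b), -math.sin(b)])
    if geometry.mirror_curvature_sign == "concave":
        P = np.array([R - R * math.cos(phi), R * math.sin(phi)])
        n = np.array([math.cos(phi), -math.sin(phi)])
    else:
        P = np.array([-R + R * math.cos(phi), R * math.sin(phi)])
        n = np.array([math.cos(phi), math.sin(phi)])
    dn = float(d @ n)
    dp = d - 2.0 * dn * n
    return P, dp, dn


def _landing_mm(geometry: InterferometerGeometry, phi: float) -> float:
    """Substrate x (mm, physical frame) where the ray from arc angle phi lands."""
    P, dp, dn = _reflect(geometry, phi)
    if dn >= 0 or dp[1] >= -1e-15:
        return math.nan
    return float(P[0] - P[1] * dp[0] / dp[1])


def _phi_max(geometry: InterferometerGeometry) -> float:
    if geometry.mirror_curvature_sign == "concave":
        # beyond grazing incidence (beta + phi = 90 deg) the beam hits the
        # back of the arc
        return math.pi / 2 - geometry.beta_rad - 1e-12
    return math.radians(89.9)


@lru_cache(maxsize=32)
def _landing_table(geometry: InterferometerGeometry, n: int = 4000):
    """Dense (phi, landing) sweep used to bracket roots."""
    phis = np.linspace(1e-9, _phi_max(geometry), n)
    land = np.array([_landing_mm(geometry, p) for p in phis])
    return phis, land


def _patterned_side(geometry: InterferometerGeometry) -> int:
    """Side of the mirror foot carrying the usable interference strip.

    The concave arc patterns the x<0 strip (single-valued landing map)
    unless the strip is longer than the substrate itself, in which case the
    geometry is effectively a Lloyd's mirror and the uniform x>0 side is
    used.  The convex arc always patterns the x>0 side.
    """
    if geometry.mirror_curvature_sign == "convex":
        return +1
    near, far = _strip_extent_mm(geometry)
    return -1 if far <= geometry.substrate_length_mm * 10 else +1


def _strip_extent_mm(geometry: InterferometerGeometry):
    """(0, extent) of the single-branch gradient strip for a concave arc."""
    edge = _landing_mm(geometry, _phi_max(geometry))
    if math.isnan(edge):
        return 0.0, math.inf
    return 0.0, abs(edge)


def _phi_for_position(geometry: InterferometerGeometry, x_mm: float) -> float:
    """Smallest arc angle whose reflected ray lands at physical x (mm)."""
    phis, land = _landing_table(geometry)
    diff = land - x_mm
    roots = []
    for i in range(len(phis) - 1):
        a, b = diff[i], diff[i + 1]
        if math.isnan(a) or math.isnan(b):
            continue
        if a == 0.0:
            roots.append(phis[i])
        elif a * b < 0:
            roots.append(
                brentq(lambda p: _landing_mm(geometry, p) - x_mm,
                       phis[i], phis[i + 1], xtol=1e-15)
            )
    if not roots:
        raise PositionNotIlluminatedError(x_mm * 1000.0)
    return min(roots)


def _physical_x_mm(geometry: InterferometerGeometry, x_um: float) -> float:
    side = _patterned_side(geometry)
    return side * (x_um / 1000.0 + geometry.mirror_offset_mm)


def trace_reflected_angle(geometry: InterferometerGeometry, x_um: float) -> float:
    """Grazing angle (degrees from the substrate plane) of the
    mirror-reflected beam at substrate position ``x_um``.

    ``x_um`` is measured from the mirror foot along the patterned side.
    Raises :class:`PositionNotIlluminatedError` when no reflected ray
    reaches the position.
    """
    phi = _phi_for_position(geometry, _physical_x_mm(geometry, x_um))
    _, dp, _ = _reflect(geometry, phi)
    return math.degrees(math.atan2(-dp[1], abs(dp[0])))


def grating_period_nm(wavelength_nm: float, theta1_deg: float,
                      theta2_deg: float) -> float:
    """Closed-form two-beam fringe period lambda/(sin t1 + sin t2).

    Angles measured from the substrate normal, beams arriving from opposite
    azimuths (the symmetric Lloyd's-mirror convention).
    """
    s = math.sin(math.radians(theta1_deg)) + math.sin(math.radians(theta2_deg))
    if s <= 0:
        raise ValueError("degenerate beam pair: sin(t1) + sin(t2) must be > 0")
    return wavelength_nm / s


def local_period(geometry: InterferometerGeometry, x_um: float) -> float:
    """Local fringe period (um) at substrate position x (um).

    Computed from the in-plane wavevector mismatch of the direct and the
    traced mirror-reflected beam, which reduces to
    lambda/(sin t1 + sin t2) for opposite-azimuth beams.  Clamped below at
    the two-beam diffraction limit lambda/2.
    """
    phi = _phi_for_position(geometry, _physical_x_mm(geometry, x_um))
    _, dp, _ = _reflect(geometry, phi)
    b = geometry.beta_rad
    dkx = abs(dp[0] + math.cos(b))  # direct beam kx = -cos(beta)
    lam_um = geometry.wavelength_nm * 1e-3
    if dkx < 1e-12:
        warnings.warn("degenerate parallel beams at x=%.1f um; period unbounded"
                      % x_um)
        return math.inf
    period = lam_um / dkx
    floor = lam_um / 2.0
    if period < floor:  # numerically impossible for |dkx|<=2, kept as guard
        warnings.warn("period clamped at the lambda/2 diffraction limit")
        return floor
    return period


def fringe_duty_cycle(mean_dose: float, visibility: float, threshold: float,
                      resist_tone: str = "negative") -> float:
    """Duty cycle (linewidth/period) of the developed grating.

    The sinusoidal exposure dose D(u) = mean + visibility*cos(2 pi u)
    crosses the development threshold over a fraction

        d = arccos((threshold - mean) / visibility) / pi

    of each period.  Negative resist keeps the over-threshold fraction,
    positive resist the complement.
    """
    if resist_tone not in ("negative", "positive"):
        raise ValueError("resist_tone must be 'negative' or 'positive'")
    if visibility < 0:
        raise ValueError("visibility must be >= 0")
    if visibility == 0:
        warnings.warn("zero fringe visibility: uniform dose, duty cycle "
                      "degenerates to 0 or 1")
        d = 1.0 if mean_dose > threshold else 0.0
    else:
        arg = np.clip((threshold - mean_dose) / visibility, -1.0, 1.0)
        d = float(np.arccos(arg) / math.pi)
    if resist_tone == "positive":
        d = 1.0 - d
    return float(np.clip(d, 0.0, 1.0))


@dataclass
class TopographyProfile:
    """Per-position line-grating geometry along the substrate.

    All lengths in micrometres.  ``linewidth_um = duty_cycle * period_um``
    by construction; ``height_um`` is the (constant) resist thickness.
    """

    positions_um: np.ndarray
    period_um: np.ndarray
    linewidth_um: np.ndarray
    duty_cycle: np.ndarray
    height_um: float = 0.3

    def __post_init__(self):
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.period_um = np.asarray(self.period_um, dtype=float)
        self.linewidth_um = np.asarray(self.linewidth_um, dtype=float)
        self.duty_cycle = np.asarray(self.duty_cycle, dtype=float)
        if self.positions_um.ndim != 1 or len(self.positions_um) < 2:
            raise ValueError("profile needs at least 2 positions")
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValueError("positions_um must be strictly increasing")
        if np.any(self.period_um <= 0):
            raise ValueError("periods must be positive")
        if np.any((self.duty_cycle < 0) | (self.duty_cycle > 1)):
            raise ValueError("duty_cycle must lie in [0, 1]")
        if not np.allclose(self.linewidth_um,
                           self.duty_cycle * self.period_um, rtol=1e-9):
            raise ValueError("linewidth must equal duty_cycle * period")
        if self.height_um <= 0:
            raise ValueError("height_um must be positive")

    @property
    def span_ratio(self) -> float:
        """max(period) / min(period) over the profile."""
        return float(self.period_um.max() / self.period_um.min())

    def period_at(self, x_um) -> np.ndarray:
        """Local period at arbitrary positions by log-linear interpolation."""
        return np.exp(np.interp(np.asarray(x_um, dtype=float),
                                self.positions_um, np.log(self.period_um)))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "position_um": self.positions_um,
            "period_um": self.period_um,
            "linewidth_um": self.linewidth_um,
            "duty_cycle": self.duty_cycle,
            "height_um": np.full_like(self.positions_um, self.height_um),
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TopographyProfile":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["position_um"].to_numpy(), df["period_um"].to_numpy(),
                   df["linewidth_um"].to_numpy(), df["duty_cycle"].to_numpy(),
                   float(df["height_um"].iloc[0]))

    def render_preview(self, path, width_px: int = 800, height_px: int = 200):
        """AFM-like grayscale preview of the line grating (PNG/TIFF)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        x = np.linspace(self.positions_um[0], self.positions_um[-1], width_px)
        per = self.period_at(x)
        # phase accumulates as the integral of the local spatial frequency
        freq = 1.0 / per
        phase = 2 * np.pi * np.concatenate(
            [[0.0], np.cumsum(0.5 * (freq[1:] + freq[:-1]) * np.diff(x))])
        duty = np.interp(x, self.positions_um, self.duty_cycle)
        line = (np.mod(phase / (2 * np.pi), 1.0) < duty).astype(float)
        img = np.tile(line * self.height_um, (height_px, 1))
        plt.imsave(path, img, cmap="copper")
        return img


@dataclass
class ExposureParams:
    """Dose model of the development step; equal-amplitude beams by default."""

    mean_dose: float = 1.0
    visibility: float = 1.0
    threshold: float = 1.0
    resist_tone: str = "negative"


def build_topography_profile(geometry: InterferometerGeometry,
                             n_samples: int = 400,
                             exposure_params: ExposureParams | None = None,
                             margin_frac: float = 0.01) -> TopographyProfile:
    """Sample the illuminated strip of the substrate into a profile.

    For a curved mirror the usable strip runs from the mirror foot out to
    the position where the reflected beam becomes parallel to the direct
    beam (period diverges); ``margin_frac`` trims both singular ends.  For
    the flat-mirror (Lloyd's) limit the full substrate is sampled and the
    period is uniform.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    exposure = exposure_params or ExposureParams()
    side = _patterned_side(geometry)
    L_um = geometry.substrate_length_mm * 1000.0
    if side < 0:
        _, extent_mm = _strip_extent_mm(geometry)
        extent_um = min(extent_mm * 1000.0, L_um)
        lo, hi = margin_frac * extent_um, (1.0 - margin_frac) * extent_um
    else:
        lo, hi = margin_frac * L_um, (1.0 - margin_frac) * L_um
    if not hi > lo:
        raise ValueError("empty illuminated region under this geometry")
    xs = np.linspace(lo, hi, n_samples)
    periods = np.array([local_period(geometry, x) for x in xs])
    duty = fringe_duty_cycle(exposure.mean_dose, exposure.visibility,
                             exposure.threshold, exposure.resist_tone)
    duties = np.full(n_samples, duty)
    return TopographyProfile(xs, periods, duties * periods, duties)


def exponential_profile(size_min_um: float, size_max_um: float,
                        length_um: float = 10000.0, n_samples: int = 400,
                        duty_cycle: float = 0.5,
                        height_um: float = 0.3) -> TopographyProfile:
    """Idealised exactly log-linear gradient profile.

    Useful as a controlled topography for synthetic scenes and as the
    exact-recovery input for the calibration fit.
    """
    xs = np.linspace(0.0, length_um, n_samples)
    periods = size_min_um * np.exp(np.log(size_max_um / size_min_um)
                                   * xs / length_um)
    duties = np.full(n_samples, float(duty_cycle))
    return TopographyProfile(xs, periods, duties * periods, duties,
                             height_um=height_um)


@dataclass(frozen=True)
class SizeCalibration:
    """Log-linear position -> feature-size map: size = exp(a + b x)."""

    intercept: float
    slope: float
    r_squared: float
    valid_range_um: tuple

    def predict(self, x_um):
        return np.exp(self.intercept + self.slope * np.asarray(x_um, float))

    def invert(self, size_um):
        if self.slope == 0:
            raise ValueError("constant calibration cannot be inverted")
        return (np.log(np.asarray(size_um, float)) - self.intercept) / self.slope


def fit_size_calibration(profile: TopographyProfile,
                         central_fraction: float = 1.0) -> SizeCalibration:
    """Least-squares fit of log(period) against position.

    ``central_fraction`` < 1 restricts the fit to the central part of the
    position range (the edges of a gradient array sit near the optical
    singularities and bend away from log-linearity).
    """
    x = profile.positions_um
    p = profile.period_um
    if len(x) < 3:
        raise ValueError("need at least 3 samples to fit a calibration")
    bad = np.nonzero(~(p > 0) | ~np.isfinite(p))[0]
    if bad.size:
        raise ValueError(f"non-positive or non-finite period at sample "
                         f"index {bad[0]} (x={x[bad[0]]:.3f} um)")
    if not 0 < central_fraction <= 1:
        raise ValueError("central_fraction must lie in (0, 1]")
    if central_fraction < 1.0:
        span = x[-1] - x[0]
        edge = 0.5 * (1.0 - central_fraction)
        keep = (x >= x[0] + edge * span) & (x <= x[-1] - edge * span)
        x, p = x[keep], p[keep]
    logp = np.log(p)
    if np.ptp(logp) <= 1e-12 * max(1.0, float(np.abs(logp).max())):
        return SizeCalibration(float(logp[0]), 0.0, 0.0,
                               (float(x[0]), float(x[-1])))
    slope, intercept = np.polyfit(x, logp, 1)
    resid = logp - (intercept + slope * x)
    ss_tot = float(((logp - logp.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return SizeCalibration(float(intercept), float(slope), float(r2),
                           (float(x[0]), float(x[-1])))


def position_to_feature_size(calibration: SizeCalibration, x_um) -> np.ndarray:
    """Feature size (um) at substrate position(s) via the fitted calibration."""
    x = np.asarray(x_um, dtype=float)
    lo, hi = calibration.valid_range_um
    if np.any(x < lo) or np.any(x > hi):
        warnings.warn("position outside the calibrated range; extrapolating")
    return calibration.predict(x)


def feature_size_to_position(calibration: SizeCalibration, size_um) -> np.ndarray:
    """Inverse query: substrate position at which a feature size occurs."""
    return calibration.invert(size_um)
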