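"""Dense behavior maps from scattered cell observations via GPR.

Scattered (x, y, z) cell observations under-sample the substrate: cell-free
regions read as missing (or, naively, zero) behavior — the false-null
problem.  A Gaussian-process regression with an anisotropic squared-
exponential kernel plus white noise interpolates the scattered values into
a dense predictive surface with uncertainty, filling the voids.  Kernel
hyperparameters are tuned by Bayesian optimization of the negative log
marginal likelihood using an expected-improvement acquisition; model
quality is assessed on a 90/10 hold-out split; predictions are evaluated
on a grid of 250,000 points spanning the observation bounding box; and the
surface is finally marginalized through the position -> feature-size
calibration into a size-response curve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import warnings as _warnings

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, Matern, WhiteKernel

from nanomap.optics import SizeCalibration
from nanomap.scoring import SizeResponseCurve

log = logging.getLogger(__name__)

DEFAULT_GRID_POINTS = 250_000
DEFAULT_TEST_FRACTION = 0.10
MIN_ROWS = 10


@dataclass
class ObservationSet:
    """Scattered behavior observations of one metric for one cell type."""

    behavior_name: str
    data: pd.DataFrame  # columns x_um, y_um, z
    provenance: str = "per_cell"  # or "per_tile"
    cell_type: str = ""

    def __post_init__(self):
        req = {"x_um", "y_um", "z"}
        if not req.issubset(self.data.columns):
            raise ValueError(f"observation table needs columns {sorted(req)}")
        vals = self.data[["x_um", "y_um", "z"]].to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("observations must be finite")

    def __len__(self):
        return len(self.data)

    @property
    def X(self) -> np.ndarray:
        return self.data[["x_um", "y_um"]].to_numpy(float)

    @property
    def z(self) -> np.ndarray:
        return self.data["z"].to_numpy(float)

    @property
    def bounding_box(self):
        X = self.X
        return (X[:, 0].min(), X[:, 0].max(), X[:, 1].min(), X[:, 1].max())


def assemble_observations(records, metric: str,
                          behavior_name: str | None = None,
                          cell_type: str = "") -> ObservationSet:
    """Build an ObservationSet from segmented objects or intensity tiles.

    ``records`` is a homogeneous list of SegmentedObject or TileIntensity
    (mixing the two provenances is an error), or a DataFrame with x_um,
    y_um and the metric column.  Records with a missing/NaN metric are
    dropped with a logged count.
    """
    from nanomap.quant import SegmentedObject, TileIntensity

    if isinstance(records, pd.DataFrame):
        if metric not in records.columns:
            raise ValueError(f"metric {metric!r} missing from table")
        df = records.rename(columns={metric: "z"})[["x_um", "y_um", "z"]]
        provenance = "per_cell"
    else:
        kinds = {type(r) for r in records}
        if kinds == {SegmentedObject}:
            provenance = "per_cell"
        elif kinds == {TileIntensity}:
            provenance = "per_tile"
        elif not kinds:
            raise ValueError("no records given")
        else:
            raise ValueError("mixed per-cell and per-tile records")
        rows = []
        for r in records:
            val = getattr(r, metric, None)
            rows.append({"x_um": r.x_um, "y_um": r.y_um,
                         "z": np.nan if val is None else val})
        df = pd.DataFrame(rows)
    n0 = len(df)
    df = df.dropna().reset_index(drop=True)
    if len(df) < n0:
        log.info("assemble_observations: dropped %d records without %r",
                 n0 - len(df), metric)
    if len(df) < MIN_ROWS:
        raise ValueError(f"only {len(df)} usable rows; need >= {MIN_ROWS}")
    return ObservationSet(behavior_name or metric, df, provenance, cell_type)


def split_holdout(obs: ObservationSet,
                  test_fraction: float = DEFAULT_TEST_FRACTION,
                  seed: int = 0):
    """Uniform random train/test split (default 90/10), seed-reproducible.

    Test size is round(n * fraction), at least 1; the two sets are disjoint
    and exhaustive.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    n = len(obs)
    if n < MIN_ROWS:
        raise ValueError(f"need >= {MIN_ROWS} observations to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(n * test_fraction)))
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    mk = lambda idx: ObservationSet(obs.behavior_name,
                                    obs.data.iloc[idx].reset_index(drop=True),
                                    obs.provenance, obs.cell_type)
    train, test = mk(train_idx), mk(test_idx)
    train.indices, test.indices = train_idx, test_idx
    return train, test


@dataclass
class GPHyperparameters:
    """Anisotropic SE (or Matern 5/2) + white-noise kernel parameters."""

    length_scale_x: float
    length_scale_y: float
    signal_variance: float
    noise_variance: float
    kernel: str = "rbf"  # or "matern52"

    def __post_init__(self):
        for name in ("length_scale_x", "length_scale_y", "signal_variance",
                     "noise_variance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def build(self):
        ls = [self.length_scale_x, self.length_scale_y]
        base = RBF(ls) if self.kernel == "rbf" else Matern(ls, nu=2.5)
        return ConstantKernel(self.signal_variance) * base \
            + WhiteKernel(self.noise_variance)


@dataclass
class FittedSurface:
    """A conditioned GP posterior plus fit metadata."""

    hyperparameters: GPHyperparameters
    gpr: GaussianProcessRegressor = field(repr=False)
    y_mean: float
    train_bounding_box: tuple
    optimizer_trace: pd.DataFrame | None = None
    holdout_rmse: float | None = None
    holdout_r2: float | None = None

    def predict(self, X: np.ndarray, return_std: bool = False):
        if return_std:
            mu, sd = self.gpr.predict(np.asarray(X, float), return_std=True)
            return mu + self.y_mean, sd
        return self.gpr.predict(np.asarray(X, float)) + self.y_mean


def _hyperparameter_bounds(train: ObservationSet) -> dict:
    X, z = train.X, train.z
    span_x = max(np.ptp(X[:, 0]), 1e-6)
    span_y = max(np.ptp(X[:, 1]), 1e-6)
    n = len(train)
    # median nearest-neighbour spacing proxy: domain size / sqrt(n)
    dx = max(span_x / math.sqrt(n), 1e-6)
    dy = max(span_y / math.sqrt(n), 1e-6)
    var = max(float(np.var(z)), 1e-12)
    return {
        "length_scale_x": (dx, span_x),
        "length_scale_y": (dy, span_y),
        "signal_variance": (1e-6 * var, 10.0 * var),
        "noise_variance": (1e-6 * var, 10.0 * var),
    }


def _objective(train: ObservationSet, theta: np.ndarray,
               kernel: str) -> float:
    """Negative log marginal likelihood at exp(theta) (no refit of theta)."""
    hp = GPHyperparameters(*np.exp(theta), kernel=kernel)
    gpr = GaussianProcessRegressor(kernel=hp.build(), optimizer=None,
                                   alpha=1e-10)
    z = train.z - train.z.mean()
    try:
        gpr.fit(train.X, z)
        return -float(gpr.log_marginal_likelihood())
    except np.linalg.LinAlgError:
        return 1e10


def optimize_hyperparameters(train: ObservationSet,
                             n_iterations: int = 30,
                             seed: int = 0,
                             kernel: str = "rbf",
                             n_initial: int = 8) -> tuple:
    """Bayesian optimization of the GP marginal likelihood with EI.

    Searches log-scaled hyperparameter space (length scales bounded by
    [typical spacing, domain size]; variances by [1e-6, 10] x label
    variance).  A GP surrogate models the objective; each iteration
    evaluates the candidate maximizing expected improvement over the
    incumbent.  Returns (GPHyperparameters, trace DataFrame); the
    incumbent column of the trace is non-increasing.
    """
    if len(np.unique(train.X, axis=0)) < 2:
        raise ValueError("need >= 2 distinct positions to optimize")
    if np.ptp(train.z) == 0:
        import warnings

        warnings.warn("all labels identical: degenerate noise-only model")
        var = 1.0
        bounds = _hyperparameter_bounds(train)
        hp = GPHyperparameters(bounds["length_scale_x"][1],
                               bounds["length_scale_y"][1], 1e-6, var,
                               kernel=kernel)
        trace = pd.DataFrame({"iteration": [0], "objective": [0.0],
                              "incumbent": [0.0]})
        return hp, trace
    rng = np.random.default_rng(seed)
    bounds = _hyperparameter_bounds(train)
    lo = np.log([b[0] for b in bounds.values()])
    hi = np.log([b[1] for b in bounds.values()])

    thetas, objs = [], []
    for _ in range(n_initial):
        thetas.append(rng.uniform(lo, hi))
        objs.append(_objective(train, thetas[-1], kernel))

    for _ in range(max(0, n_iterations - n_initial)):
        T = np.array(thetas)
        y = np.array(objs)
        y_std = y.std() or 1.0
        yn = (y - y.mean()) / y_std
        surrogate = GaussianProcessRegressor(
            kernel=ConstantKernel(1.0) * Matern(np.full(4, 1.0), nu=2.5)
            + WhiteKernel(1e-6, noise_level_bounds=(1e-8, 1e-1)),
            normalize_y=False, n_restarts_optimizer=1,
            random_state=int(rng.integers(2**31 - 1)))
        Tn = (T - lo) / (hi - lo)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", ConvergenceWarning)
            surrogate.fit(Tn, yn)
        cand = rng.uniform(0.0, 1.0, size=(1024, 4))
        mu, sd = surrogate.predict(cand, return_std=True)
        best = yn.min()
        sd = np.maximum(sd, 1e-12)
        imp = best - mu
        zsc = imp / sd
        ei = imp * norm.cdf(zsc) + sd * norm.pdf(zsc)
        theta = lo + cand[int(np.argmax(ei))] * (hi - lo)
        thetas.append(theta)
        objs.append(_objective(train, theta, kernel))

    # local gradient polish from the EI incumbent: EI explores globally,
    # L-BFGS on the marginal likelihood sharpens the final estimate
    best_theta = thetas[int(np.argmin(objs))]
    sv, nv = np.exp(best_theta[2]), np.exp(best_theta[3])
    b = list(bounds.values())
    base = RBF(np.exp(best_theta[:2]),
               length_scale_bounds=[b[0], b[1]]) if kernel == "rbf" \
        else Matern(np.exp(best_theta[:2]),
                    length_scale_bounds=[b[0], b[1]], nu=2.5)
    kern = ConstantKernel(sv, b[2]) * base + WhiteKernel(nv, b[3])
    gpr = GaussianProcessRegressor(kernel=kern, alpha=1e-10)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        gpr.fit(train.X, train.z - train.z.mean())
    polished = -float(gpr.log_marginal_likelihood(gpr.kernel_.theta))
    if polished < min(objs):
        k1 = gpr.kernel_.k1
        ls = np.atleast_1d(k1.k2.length_scale)
        thetas.append(np.log([ls[0], ls[-1], k1.k1.constant_value,
                              gpr.kernel_.k2.noise_level]))
        objs.append(polished)

    objs = np.array(objs)
    incumbent = np.minimum.accumulate(objs)
    trace = pd.DataFrame({"iteration": np.arange(len(objs)),
                          "objective": objs, "incumbent": incumbent})
    best_theta = thetas[int(np.argmin(objs))]
    hp = GPHyperparameters(*np.exp(best_theta), kernel=kernel)
    return hp, trace


def fit_surface(train: ObservationSet,
                hyperparameters: GPHyperparameters,
                optimizer_trace: pd.DataFrame | None = None) -> FittedSurface:
    """Exact GP posterior conditioning on the training observations.

    The label mean is subtracted (GP prior mean = training mean); a small
    jitter is added to the kernel diagonal and increased on
    ill-conditioning, with a log entry.
    """
    y_mean = float(train.z.mean())
    z = train.z - y_mean
    jitter = 1e-10
    for attempt in range(6):
        gpr = GaussianProcessRegressor(kernel=hyperparameters.build(),
                                       optimizer=None, alpha=jitter)
        try:
            gpr.fit(train.X, z)
            break
        except np.linalg.LinAlgError:
            jitter *= 100.0
            log.info("fit_surface: ill-conditioned kernel, jitter -> %g",
                     jitter)
    else:
        raise np.linalg.LinAlgError("kernel matrix remained ill-conditioned")
    return FittedSurface(hyperparameters, gpr, y_mean,
                         train.bounding_box, optimizer_trace)


@dataclass
class BehaviorGrid:
    """Dense predicted behavior surface with pointwise uncertainty."""

    x_um: np.ndarray         # (nx,)
    y_um: np.ndarray         # (ny,)
    z_mean: np.ndarray       # (ny, nx)
    z_sd: np.ndarray         # (ny, nx)
    behavior_name: str = ""
    cell_type: str = ""

    @property
    def total_points(self) -> int:
        return self.z_mean.size

    def to_dataframe(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x_um, self.y_um)
        return pd.DataFrame({"x_um": xx.ravel(), "y_um": yy.ravel(),
                             "z_mean": self.z_mean.ravel(),
                             "z_sd": self.z_sd.ravel()})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def render_heatmap(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.pcolormesh(self.x_um, self.y_um, self.z_mean, shading="auto",
                           cmap="viridis")
        fig.colorbar(im, ax=ax, label=self.behavior_name or "behavior")
        ax.set_xlabel("x (um)")
        ax.set_ylabel("y (um)")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _grid_factorization(total_points: int, aspect: float) -> tuple:
    """(ny, nx) with ny*nx == total_points, closest to the box aspect W/H."""
    best = None
    for ny in range(1, int(math.isqrt(total_points)) + 1):
        if total_points % ny:
            continue
        for ny_, nx_ in ((ny, total_points // ny),
                         (total_points // ny, ny)):
            mis = abs(math.log((nx_ / ny_) / aspect))
            if best is None or mis < best[0]:
                best = (mis, ny_, nx_)
    return best[1], best[2]


def predict_grid(surface: FittedSurface,
                 bounding_box: tuple | None = None,
                 total_points: int = DEFAULT_GRID_POINTS,
                 behavior_name: str = "",
                 cell_type: str = "",
                 chunk: int = 20000) -> BehaviorGrid:
    """Posterior mean and sd on a rectangular grid of exactly
    ``total_points`` points spanning the observation bounding box.

    The factorization preserves the box aspect where the point count
    allows (250,000 on a square box -> 500 x 500); otherwise the nearest
    divisor pair is used and logged.  Evaluating over cell-free voids is
    precisely the false-null correction: the GP supplies finite predicted
    values where no cells were observed.
    """
    if bounding_box is None:
        bounding_box = surface.train_bounding_box
    x0, x1, y0, y1 = bounding_box
    aspect = max((x1 - x0), 1e-9) / max((y1 - y0), 1e-9)
    ny, nx = _grid_factorization(total_points, aspect)
    if nx != ny:
        log.info("predict_grid: factorized %d points as %d x %d",
                 total_points, ny, nx)
    xs = np.linspace(x0, x1, nx)
    ys = np.linspace(y0, y1, ny)
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    mu = np.empty(len(pts))
    sd = np.empty(len(pts))
    for i in range(0, len(pts), chunk):
        m, s = surface.predict(pts[i:i + chunk], return_std=True)
        mu[i:i + chunk] = m
        sd[i:i + chunk] = s
    return BehaviorGrid(xs, ys, mu.reshape(ny, nx), sd.reshape(ny, nx),
                        behavior_name, cell_type)


def holdout_error(surface: FittedSurface, test: ObservationSet):
    """(rmse, r2) of the posterior mean on held-out observations."""
    if len(test) == 0:
        raise ValueError("empty test set")
    pred = surface.predict(test.X)
    resid = test.z - pred
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(((test.z - test.z.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
    surface.holdout_rmse, surface.holdout_r2 = rmse, r2
    return rmse, r2


def marginalize_to_size_curve(grid: BehaviorGrid,
                              calibration: SizeCalibration,
                              n_size_bins: int = 8,
                              size_range_um: tuple | None = None
                              ) -> SizeResponseCurve:
    """Collapse the (x, y) behavior surface into a size-response curve.

    Each grid column maps to a feature size through the calibration; the
    column means (over y) are averaged within log-spaced size bins.  Bin
    edges default to the calibration's full valid size range, so curves
    from different scenes on the same array share identical bins; a bin
    not covered by this grid's columns is filled by log-size interpolation
    of the column-mean profile.
    """
    lo, hi = calibration.valid_range_um
    gx0, gx1 = grid.x_um.min(), grid.x_um.max()
    span = gx1 - gx0
    if gx0 < lo - 0.05 * span or gx1 > hi + 0.05 * span:
        raise ValueError(
            f"grid x-range [{gx0:.0f}, {gx1:.0f}] um exceeds the calibrated "
            f"range [{lo:.0f}, {hi:.0f}] um")
    sizes = np.asarray(calibration.predict(grid.x_um), dtype=float)
    col_mean = grid.z_mean.mean(axis=0)
    if size_range_um is None:
        ends = np.asarray(calibration.predict([lo, hi]), dtype=float)
        size_range_um = (float(ends.min()), float(ends.max()))
    edges = np.geomspace(size_range_um[0], size_range_um[1] * (1 + 1e-12),
                         n_size_bins + 1)
    idx = np.clip(np.searchsorted(edges, sizes, side="right") - 1,
                  0, n_size_bins - 1)
    order = np.argsort(sizes)
    centers = np.sqrt(edges[:-1] * edges[1:])
    means = np.empty(n_size_bins)
    disps = np.zeros(n_size_bins)
    for b in range(n_size_bins):
        sel = idx == b
        if sel.any():
            means[b] = float(col_mean[sel].mean())
            disps[b] = float(col_mean[sel].std())
        else:
            means[b] = float(np.interp(np.log(centers[b]),
                                       np.log(sizes[order]),
                                       col_mean[order]))
    return SizeResponseCurve(centers, means, disps, grid.behavior_name,
                             grid.cell_type, bin_edges_um=edges)
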