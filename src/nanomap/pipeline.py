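"""Configuration-driven end-to-end screening runs.

One YAML config drives optics -> synthetic screen -> quantification ->
GPR mapping -> scoring for several synthetic cell types and behaviors,
with a single master seed fanned out deterministically per stage, cell
type and behavior.  Every artifact written is listed in a run manifest
with its stage, seed and SHA-256 checksum, so identical config + seed
reproduce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from nanomap import mapping, optics, quant, scoring, synth

log = logging.getLogger(__name__)

DEFAULT_BEHAVIORS = list(synth.BEHAVIORS)


@dataclass
class RunConfig:
    """Validated parameters of a full screening run."""

    seed: int
    output_dir: str = "nanomap_run"
    # optics
    wavelength_nm: float = 325.0
    beam_angle_deg: float = 67.0
    focal_length_mm: float = 10.0
    mirror_curvature_sign: str = "concave"
    substrate_length_mm: float = 10.0
    profile_samples: int = 300
    margin_frac: float = 0.01
    calibration_central_fraction: float = 0.8
    # synthetic screen
    density_per_cm2: float = 10000.0
    void_fraction: float = 0.3
    noise_sd: float = 0.1
    height_um: float = 10000.0
    cell_types: dict = field(default_factory=lambda: {"wild_type": 1.0,
                                                      "patient": 0.5})
    behaviors: list = field(default_factory=lambda: list(DEFAULT_BEHAVIORS))
    # quantification
    min_area_px: int = 8
    max_area_px: int = 80
    pixel_size_um: float = 0.65
    n_tiles: int = 96
    # mapping
    test_fraction: float = 0.10
    bo_iterations: int = 30
    grid_points: int = 250_000
    max_observations: int = 600
    save_grids: bool = False
    # scoring
    n_levels: int = 5
    n_size_bins: int = 8

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def validate_config(config) -> dict:
    """Range-check every bound the pipeline stages rely on.

    ``config`` is a RunConfig, a dict, or a YAML path.  Returns
    {"ok": bool, "messages": [...]}.
    """
    if isinstance(config, (str, Path)):
        try:
            config = RunConfig.from_yaml(config)
        except Exception as exc:  # unparseable or unknown keys
            return {"ok": False, "messages": [f"config error: {exc}"]}
    elif isinstance(config, dict):
        try:
            if "seed" not in config:
                raise ValueError("config must set a seed")
            config = RunConfig(**config)
        except Exception as exc:
            return {"ok": False, "messages": [f"config error: {exc}"]}
    msgs = []
    c = config
    if not isinstance(c.seed, (int, np.integer)):
        msgs.append("seed: must be an integer")
    if not 0 < c.beam_angle_deg < 90:
        msgs.append("beam_angle_deg: must lie in (0, 90)")
    if c.wavelength_nm <= 0:
        msgs.append("wavelength_nm: must be positive")
    if c.focal_length_mm <= 0:
        msgs.append("focal_length_mm: must be positive")
    if c.profile_samples < 2:
        msgs.append("profile_samples: must be >= 2")
    if not 0 <= c.void_fraction < 1:
        msgs.append("void_fraction: must lie in [0, 1)")
    if c.density_per_cm2 < 0:
        msgs.append("density_per_cm2: must be >= 0")
    if not c.min_area_px < c.max_area_px:
        msgs.append("min_area_px must be < max_area_px")
    if not 48 <= c.n_tiles <= 576:
        msgs.append(f"n_tiles: {c.n_tiles} outside the allowed [48, 576]")
    if not 0 < c.test_fraction < 1:
        msgs.append("test_fraction: must lie in (0, 1)")
    if c.grid_points < 4:
        msgs.append("grid_points: must be >= 4")
    if c.n_levels < 2:
        msgs.append("n_levels: must be >= 2")
    if c.n_size_bins < 2:
        msgs.append("n_size_bins: must be >= 2")
    if not c.cell_types:
        msgs.append("cell_types: at least one required")
    bad = set(c.behaviors) - set(synth.BEHAVIORS)
    if bad:
        msgs.append(f"behaviors: unknown {sorted(bad)}")
    return {"ok": not msgs, "messages": msgs}


def _sub_seed(master: int, *key) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_screen(config: RunConfig) -> dict:
    """Execute the full pipeline and return the run manifest.

    Per cell type and behavior: synthesize a scene on the simulated
    gradient array, map its observations with GPR, marginalize to a
    size-response curve; then score each cell type's radar table and
    compare cell types.  A demonstrative image-quantification stage runs
    on a rendered crop of one scene per cell type.
    """
    report = validate_config(config)
    if not report["ok"]:
        raise ValueError("invalid config: " + "; ".join(report["messages"]))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": dataclasses.asdict(config), "artifacts": []}

    def add(path: Path, stage: str, seed=None):
        manifest["artifacts"].append({
            "path": str(path.relative_to(out)), "stage": stage,
            "seed": seed, "sha256": _sha256(path)})

    stage = "optics"
    try:
        t0 = time.time()
        geometry = optics.InterferometerGeometry(
            wavelength_nm=config.wavelength_nm,
            beam_angle_deg=config.beam_angle_deg,
            focal_length_mm=config.focal_length_mm,
            mirror_curvature_sign=config.mirror_curvature_sign,
            substrate_length_mm=config.substrate_length_mm)
        profile = optics.build_topography_profile(
            geometry, config.profile_samples, margin_frac=config.margin_frac)
        profile.to_csv(out / "profile.csv")
        add(out / "profile.csv", stage)
        profile.render_preview(out / "profile_preview.png")
        add(out / "profile_preview.png", stage)
        calibration = optics.fit_size_calibration(
            profile, central_fraction=config.calibration_central_fraction)
        (out / "calibration.json").write_text(json.dumps({
            "intercept": calibration.intercept, "slope": calibration.slope,
            "r_squared": calibration.r_squared,
            "valid_range_um": list(calibration.valid_range_um)}, indent=2))
        add(out / "calibration.json", stage)
        log.info("stage optics done in %.1fs (span ratio %.1f, R2 %.3f)",
                 time.time() - t0, profile.span_ratio,
                 calibration.r_squared)

        lo, hi = calibration.valid_range_um
        keep = ((profile.positions_um >= lo) & (profile.positions_um <= hi))
        mapped_profile = optics.TopographyProfile(
            profile.positions_um[keep], profile.period_um[keep],
            profile.linewidth_um[keep], profile.duty_cycle[keep],
            profile.height_um)

        curves_by_type: dict = {}
        for ci, (cell_type, amp) in enumerate(config.cell_types.items()):
            models = synth.default_response_models(
                amplitude_scale=float(amp), noise_sd=config.noise_sd)
            curves = []
            for bi, behavior in enumerate(config.behaviors):
                stage = f"synth[{cell_type}/{behavior}]"
                t0 = time.time()
                seed = _sub_seed(config.seed, 1, ci, bi)
                scene = synth.make_scene(
                    mapped_profile, models[behavior],
                    config.density_per_cm2, config.void_fraction, seed,
                    config.height_um)
                cells_csv = out / f"cells_{cell_type}_{behavior}.csv"
                scene.to_csv(cells_csv)
                add(cells_csv, stage, seed)
                log.info("%s: %d cells in %.1fs", stage, len(scene.cells),
                         time.time() - t0)

                stage = f"map[{cell_type}/{behavior}]"
                t0 = time.time()
                obs = mapping.ObservationSet(
                    behavior,
                    scene.cells.rename(columns={"value": "z"})[
                        ["x_um", "y_um", "z"]],
                    cell_type=cell_type)
                mseed = _sub_seed(config.seed, 2, ci, bi)
                if len(obs) > config.max_observations:
                    rng = np.random.default_rng(mseed)
                    idx = np.sort(rng.choice(len(obs),
                                             config.max_observations,
                                             replace=False))
                    obs = mapping.ObservationSet(
                        behavior, obs.data.iloc[idx].reset_index(drop=True),
                        cell_type=cell_type)
                train, test = mapping.split_holdout(
                    obs, config.test_fraction, mseed)
                hp, trace = mapping.optimize_hyperparameters(
                    train, config.bo_iterations, mseed)
                surface = mapping.fit_surface(train, hp, trace)
                rmse, r2 = mapping.holdout_error(surface, test)
                grid = mapping.predict_grid(
                    surface, obs.bounding_box, config.grid_points,
                    behavior, cell_type)
                if config.save_grids:
                    gcsv = out / f"grid_{cell_type}_{behavior}.csv"
                    grid.to_csv(gcsv)
                    add(gcsv, stage, mseed)
                png = out / f"map_{cell_type}_{behavior}.png"
                grid.render_heatmap(png)
                add(png, stage, mseed)
                curve = mapping.marginalize_to_size_curve(
                    grid, calibration, config.n_size_bins)
                ccsv = out / f"curve_{cell_type}_{behavior}.csv"
                curve_df = _curve_to_dataframe(curve)
                curve_df.to_csv(ccsv, index=False)
                add(ccsv, stage, mseed)
                curves.append(curve)
                log.info("%s: n=%d holdout RMSE %.3f R2 %.3f (%.1fs)",
                         stage, len(obs), rmse, r2, time.time() - t0)

            stage = f"quantify[{cell_type}]"
            t0 = time.time()
            qseed = _sub_seed(config.seed, 3, ci)
            demo_scene = synth.make_scene(
                mapped_profile, models[config.behaviors[0]],
                config.density_per_cm2 * 20, 0.0, qseed, config.height_um)
            x0 = float(mapped_profile.positions_um[0])
            region = (x0, 0.0, x0 + 333.0, 333.0)
            img = synth.render_fluorescence_image(
                demo_scene, "actin", config.pixel_size_um, region)
            objects = quant.detect_objects(
                img, config.min_area_px, config.max_area_px,
                config.pixel_size_um, origin_um=(region[0], region[1]))
            ocsv = out / f"objects_{cell_type}.csv"
            quant.objects_to_dataframe(objects).to_csv(ocsv, index=False)
            add(ocsv, stage, qseed)
            log.info("%s: %d objects from rendered crop (%.1fs)",
                     stage, len(objects), time.time() - t0)

            curves_by_type[cell_type] = curves

        stage = "score"
        # one shared level standard across cell types per behavior
        tables = scoring.build_radar_tables(curves_by_type, config.n_levels)
        for table in tables:
            rcsv = out / f"radar_{table.cell_type}.csv"
            table.to_csv(rcsv)
            add(rcsv, stage)
            rpng = out / f"radar_{table.cell_type}.png"
            table.render_radar(rpng)
            add(rpng, stage)

        stage = "compare"
        if len(tables) >= 2:
            report_obj = scoring.compare_cell_types(tables)
            (out / "comparison.md").write_text(report_obj.to_markdown())
            add(out / "comparison.md", stage)
            report_obj.sensitivity.to_csv(out / "sensitivity.csv")
            add(out / "sensitivity.csv", stage)
    except Exception as exc:
        partial = out / "manifest_partial.json"
        partial.write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    config.to_yaml(out / "config.yaml")
    add(out / "config.yaml", "config")
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return manifest


def scene_to_curve(scene, calibration, seed: int,
                   n_size_bins: int = 8,
                   max_observations: int = 250,
                   bo_iterations: int = 12,
                   grid_points: int = 2500,
                   test_fraction: float = 0.10):
    """Map one synthetic scene to its size-response curve via GPR.

    Runs the standard chain (subsample -> 90/10 split -> EI hyperparameter
    search -> GP fit -> dense grid -> marginalize through the calibration)
    at a configurable problem size.  Returns (curve, holdout_r2).
    """
    behavior = scene.cells["behavior"].iloc[0] if "behavior" in scene.cells \
        else ""
    obs = mapping.ObservationSet(
        behavior, scene.cells.rename(columns={"value": "z"})[
            ["x_um", "y_um", "z"]])
    if len(obs) > max_observations:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(obs), max_observations, replace=False))
        obs = mapping.ObservationSet(
            behavior, obs.data.iloc[idx].reset_index(drop=True))
    train, test = mapping.split_holdout(obs, test_fraction, seed)
    hp, trace = mapping.optimize_hyperparameters(train, bo_iterations, seed)
    surface = mapping.fit_surface(train, hp, trace)
    _, r2 = mapping.holdout_error(surface, test)
    grid = mapping.predict_grid(surface, obs.bounding_box, grid_points,
                                behavior)
    curve = mapping.marginalize_to_size_curve(grid, calibration, n_size_bins)
    return curve, r2


def _curve_to_dataframe(curve):
    return pd.DataFrame({"size_um": curve.size_bins_um,
                         "mean": curve.mean,
                         "dispersion": curve.dispersion})
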