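"""5-level phenotypic scoring, radar tables and cell-type comparison.

Size-response curves (behavior vs feature size) are discretized onto an
equal-width 5-level scale, stacked into a behavior x size-bin radar table
per cell type, and compared across cell types.  Equal-width (rather than
quantile) levels preserve amplitude differences between cell types, which
is what makes a mechano-insensitive line (flatter responses) score lower.
The mechanosensitivity index of a behavior is its level range (max - min
across size bins, 0..4); the overall index is the mean across behaviors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_LEVELS = 5


@dataclass
class SizeResponseCurve:
    """Mean behavior per log-spaced feature-size bin."""

    size_bins_um: np.ndarray      # bin centers, strictly increasing
    mean: np.ndarray
    dispersion: np.ndarray
    behavior_name: str = ""
    cell_type: str = ""
    bin_edges_um: np.ndarray | None = None

    def __post_init__(self):
        self.size_bins_um = np.asarray(self.size_bins_um, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.dispersion = np.asarray(self.dispersion, dtype=float)
        if np.any(np.diff(self.size_bins_um) <= 0):
            raise ValueError("size bins must be strictly increasing")
        if not (np.all(np.isfinite(self.size_bins_um))
                and np.all(np.isfinite(self.mean))):
            raise ValueError("curve values must be finite")

    def __len__(self):
        return len(self.size_bins_um)


def discretize_levels(curve: SizeResponseCurve,
                      n_levels: int = N_LEVELS,
                      value_range: tuple | None = None) -> np.ndarray:
    """Integer levels 1..n_levels by equal-width binning of the values.

    Level k covers the k-th equal-width slice of the value range; the
    maximum gets level n_levels.  ``value_range`` overrides the curve's own
    [min, max] — pass a range shared across cell types when tables will be
    compared (same-standards rule), otherwise a weak responder would be
    rescaled to span all levels and amplitude differences would vanish.
    A zero-range input maps entirely to level 1 with a warning.  Level
    assignment is monotone in the value.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    v = curve.mean
    if value_range is None:
        lo, hi = float(v.min()), float(v.max())
    else:
        lo, hi = map(float, value_range)
    if hi == lo:
        warnings.warn("zero-range curve: all bins assigned level 1")
        return np.ones(len(v), dtype=int)
    lev = np.floor((v - lo) / (hi - lo) * n_levels).astype(int) + 1
    return np.clip(lev, 1, n_levels)


def shared_value_ranges(curves_by_type: dict) -> dict:
    """Per-behavior [min, max] pooled across all cell types.

    ``curves_by_type`` maps cell type -> list of SizeResponseCurve.  The
    returned dict (behavior -> (lo, hi)) is the shared level standard for
    building comparable radar tables.
    """
    ranges: dict = {}
    for curves in curves_by_type.values():
        for c in curves:
            lo, hi = float(c.mean.min()), float(c.mean.max())
            if c.behavior_name in ranges:
                plo, phi = ranges[c.behavior_name]
                ranges[c.behavior_name] = (min(lo, plo), max(hi, phi))
            else:
                ranges[c.behavior_name] = (lo, hi)
    return ranges


@dataclass
class RadarTable:
    """behavior x size-bin matrix of integer levels for one cell type."""

    cell_type: str
    behaviors: list
    size_bins_um: np.ndarray
    levels: np.ndarray            # (n_behaviors, n_bins) ints
    n_levels: int = N_LEVELS

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=int)
        self.size_bins_um = np.asarray(self.size_bins_um, dtype=float)
        if self.levels.shape != (len(self.behaviors), len(self.size_bins_um)):
            raise ValueError("levels shape must be (behaviors, bins)")
        if np.any((self.levels < 1) | (self.levels > self.n_levels)):
            raise ValueError(f"levels must lie in 1..{self.n_levels}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.levels, index=self.behaviors,
                            columns=[f"{s:g}um" for s in self.size_bins_um])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def render_radar(self, path) -> None:
        """Radar (spider) chart: one polygon per behavior over size bins."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n = len(self.size_bins_um)
        ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
        fig, ax = plt.subplots(subplot_kw={"projection": "polar"},
                               figsize=(5, 5))
        for b, lev in zip(self.behaviors, self.levels):
            vals = np.append(lev, lev[0])
            ax.plot(np.append(ang, ang[0]), vals, label=b, lw=1.5)
        ax.set_xticks(ang)
        ax.set_xticklabels([f"{s:g}" for s in self.size_bins_um], fontsize=7)
        ax.set_ylim(0, self.n_levels)
        ax.set_title(f"{self.cell_type} (levels 1..{self.n_levels}, "
                     f"bins in um)", fontsize=9)
        ax.legend(loc="upper right", bbox_to_anchor=(1.35, 1.1), fontsize=7)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def build_radar_table(curves: list, cell_type: str | None = None,
                      n_levels: int = N_LEVELS,
                      value_ranges: dict | None = None) -> RadarTable:
    """Stack discretized size-response curves into a radar table.

    All curves must share identical size bins.  ``value_ranges`` (behavior
    -> (lo, hi), e.g. from :func:`shared_value_ranges`) applies one level
    standard across cell types; without it each curve is scaled to its own
    range, which is fine for a standalone table but not for comparison.
    """
    if not curves:
        raise ValueError("no curves given")
    ref = curves[0].size_bins_um
    for c in curves[1:]:
        if len(c.size_bins_um) != len(ref) or not np.allclose(
                c.size_bins_um, ref):
            raise ValueError("curves have mismatched size bins")
    levels = np.vstack([
        discretize_levels(c, n_levels,
                          None if value_ranges is None
                          else value_ranges.get(c.behavior_name))
        for c in curves])
    return RadarTable(cell_type or curves[0].cell_type,
                      [c.behavior_name for c in curves], ref, levels,
                      n_levels)


def build_radar_tables(curves_by_type: dict,
                       n_levels: int = N_LEVELS) -> list:
    """Radar tables for several cell types under one shared level standard."""
    ranges = shared_value_ranges(curves_by_type)
    return [build_radar_table(curves, ct, n_levels, ranges)
            for ct, curves in curves_by_type.items()]


def optimal_feature_size(curve: SizeResponseCurve,
                         n_levels: int = N_LEVELS) -> tuple:
    """(size_um, level) of the bin with the highest mean behavior.

    Ties break toward the smallest size.  Invariant under strictly
    monotone transforms of the behavior values.
    """
    if len(curve) == 0:
        raise ValueError("empty curve")
    i = int(np.argmax(curve.mean))  # argmax returns the first (smallest) tie
    level = int(discretize_levels(curve, n_levels)[i])
    return float(curve.size_bins_um[i]), level


def sensitivity_index(table: RadarTable) -> dict:
    """Mechanosensitivity: per-behavior level range and overall mean.

    A behavior whose level varies from 1 to 5 across sizes scores 4; a
    flat behavior scores 0.  Higher overall = more mechanosensitive.
    """
    per = {b: int(table.levels[i].max() - table.levels[i].min())
           for i, b in enumerate(table.behaviors)}
    per["overall"] = float(np.mean(list(per.values()))) if per else 0.0
    return per


@dataclass
class ComparisonReport:
    """Cross-cell-type comparison of radar tables."""

    cell_types: list
    optimal_bins: pd.DataFrame        # behavior x cell_type, size in um
    sensitivity: pd.DataFrame         # behavior (+ overall) x cell_type
    pairwise_level_diff: dict         # (type_a, type_b) -> level matrix

    def to_markdown(self) -> str:
        lines = ["# Cell-type comparison", "", "## Optimal feature size (um)",
                 self.optimal_bins.to_markdown(), "",
                 "## Mechanosensitivity index (level range)",
                 self.sensitivity.to_markdown(), ""]
        for (a, b), m in self.pairwise_level_diff.items():
            lines += [f"## Level difference: {a} - {b}",
                      pd.DataFrame(m).to_string(), ""]
        return "\n".join(lines)


def compare_cell_types(tables: list) -> ComparisonReport:
    """Rank cell types by optimal sizes, sensitivity and level differences.

    Requires >= 2 radar tables with identical behaviors and size bins.
    Ordering of rows/columns is deterministic (input order).
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 radar tables to compare")
    ref = tables[0]
    for t in tables[1:]:
        if t.behaviors != ref.behaviors or not np.allclose(
                t.size_bins_um, ref.size_bins_um):
            raise ValueError("radar tables have mismatched binning")
    cell_types = [t.cell_type for t in tables]
    opt = {}
    sens = {}
    for t in tables:
        # per-behavior argmax level, ties toward the smallest size
        opt[t.cell_type] = [float(t.size_bins_um[int(np.argmax(row))])
                            for row in t.levels]
        s = sensitivity_index(t)
        sens[t.cell_type] = [s[b] for b in t.behaviors] + [s["overall"]]
    optimal_bins = pd.DataFrame(opt, index=ref.behaviors)
    sensitivity = pd.DataFrame(sens, index=list(ref.behaviors) + ["overall"])
    diffs = {}
    for i in range(len(tables)):
        for j in range(i + 1, len(tables)):
            diffs[(cell_types[i], cell_types[j])] = (
                tables[i].levels - tables[j].levels)
    return ComparisonReport(cell_types, optimal_bins, sensitivity, diffs)
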