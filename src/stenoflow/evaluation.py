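"""Field-error metrics, regional error reports, and the consistency analysis.

Two per-sample metrics quantify prediction error against the oracle field:

* MRE, the mean relative error: (100/N) * sum |y_i − ŷ_i| / |y_i| over the
  included points.  The definition is singular at y_i = 0 (vessel walls for
  velocity, gauge-zero crossings for pressure), so points with
  |y_i| < guard_ratio · max|y| over the region are excluded and counted.
* NMAE, the normalized mean absolute error: (100/N) * sum |y_i − ŷ_i|
  divided by the range max|y| − min|y| of the truth magnitudes over the
  region.

Velocity metrics act on the speed (vector magnitude) per point.  Regional
reports cover the whole model, the stenotic windows, and a ball of
1.5 CCA radii around the bifurcation apex; the consistency analysis
correlates predicted vs oracle mean speeds in a thin slab at each stenosis
throat (postoperative twins are evaluated at the paired station of the
removed lesion).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedMetricError
from .config import CCA
from .datasets import DatasetBundle, Sample
from .geometry import VesselGeometry

__all__ = ["mre", "nmae", "RegionMask", "region_mask", "mean_stenotic_velocity",
           "ErrorReport", "build_error_report", "ConsistencyResult", "consistency",
           "REGIONS"]

REGIONS = ("whole", "stenosis", "bifurcation")
MRE_GUARD_RATIO = 1e-3


def mre(y, y_hat, *, guard_ratio: float = MRE_GUARD_RATIO,
        return_excluded: bool = False):
    """Mean relative error in percent over denominator-guarded points."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("y and y_hat must be equal-length non-empty arrays")
    mag = np.abs(y)
    if mag.max() == 0.0:
        raise UndefinedMetricError("all truth values are zero; MRE undefined")
    include = mag >= guard_ratio * mag.max()
    n_excluded = int((~include).sum())
    if not np.any(include):
        raise UndefinedMetricError("all points excluded by the MRE denominator guard")
    value = 100.0 * float(np.mean(np.abs(y[include] - y_hat[include]) / mag[include]))
    return (value, n_excluded) if return_excluded else value


def nmae(y, y_hat, region_values=None) -> float:
    """Normalized mean absolute error in percent; range from the truth magnitudes."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("y and y_hat must be equal-length non-empty arrays")
    ref = np.abs(np.asarray(region_values if region_values is not None else y,
                            dtype=float).ravel())
    value_range = float(ref.max() - ref.min())
    if value_range <= 0.0:
        raise UndefinedMetricError("zero magnitude range over the selected region")
    return 100.0 * float(np.mean(np.abs(y - y_hat))) / value_range


@dataclass(frozen=True)
class RegionMask:
    """Boolean fluid-point membership for one named region of one sample."""

    region: str
    mask: np.ndarray

    @property
    def count(self) -> int:
        return int(self.mask.sum())


def region_mask(sample: Sample, region: str,
                geom: VesselGeometry | None = None) -> RegionMask:
    """Fluid-point mask for 'whole', 'stenosis' or 'bifurcation'.

    The stenosis region uses effective (nonzero-severity) lesions only, so it
    is empty for postoperative samples.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    pts = sample.fluid_coords.points
    if region == "whole":
        return RegionMask(region, np.ones(len(pts), dtype=bool))
    geom = geom or VesselGeometry(sample.spec)
    if region == "bifurcation":
        radius = 1.5 * sample.spec.d_cca / 2.0
        mask = np.linalg.norm(pts - geom.apex, axis=1) <= radius
        return RegionMask(region, mask)
    mask = np.zeros(len(pts), dtype=bool)
    for st in sample.spec.effective_stenoses:
        inside = geom.contains(st.branch, pts, tol=1e-9)
        s, _ = geom.project(st.branch, pts)
        lo, hi = st.window
        mask |= inside & (s >= lo) & (s <= hi)
    return RegionMask(region, mask)


def mean_stenotic_velocity(sample: Sample, velocity: np.ndarray | None = None,
                           *, slab_factor: float = 0.05,
                           geom: VesselGeometry | None = None) -> float:
    """Mean speed over fluid points in thin slabs at the stenosis throats.

    Uses every stenosis record, including severity-zero records kept on
    postoperative twins, so the paired (pre, post) samples are evaluated at
    the same axial stations.  The slab thickness is ``slab_factor * length``
    centred at each throat; an empty slab is widened once before failing.
    """
    if not sample.spec.stenoses:
        raise UndefinedMetricError("sample has no stenosis record to locate a throat")
    v = sample.flow.velocity if velocity is None else np.asarray(velocity, dtype=float)
    speed = np.linalg.norm(v, axis=1) if v.ndim == 2 else np.abs(v)
    pts = sample.fluid_coords.points
    geom = geom or VesselGeometry(sample.spec)
    for factor in (slab_factor, 2.0 * slab_factor):
        mask = np.zeros(len(pts), dtype=bool)
        for st in sample.spec.stenoses:
            inside = geom.contains(st.branch, pts, tol=1e-9)
            s, _ = geom.project(st.branch, pts)
            half = factor * st.length / 2.0
            mask |= inside & (np.abs(s - st.center_s) <= half)
        if np.any(mask):
            return float(speed[mask].mean())
    raise UndefinedMetricError("throat slab contains no fluid points even after widening")


# ---------------------------------------------------------------------------
# Reports


@dataclass
class ErrorReport:
    """Per-(stage, region, parameter) mean ± s.d. of per-sample NMAE and MRE (%)."""

    table: pd.DataFrame  # columns: stage, region, parameter, nmae_mean, nmae_sd,
    #                                mre_mean, mre_sd, n_samples, excluded_points
    per_sample: pd.DataFrame  # one row per (sample, region) with raw metrics

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=2)


def _per_sample_metrics(bundle: DatasetBundle, predictions: list[np.ndarray],
                        split: str) -> pd.DataFrame:
    indices = bundle.split(split)
    if len(predictions) != len(indices):
        raise ValueError("one prediction per sample of the chosen split is required")
    rows = []
    for pred, i in zip(predictions, indices):
        sample = bundle.samples[int(i)]
        geom = VesselGeometry(sample.spec)
        truth = sample.target_field(bundle.target)
        if bundle.target == "velocity":
            y_all = np.linalg.norm(truth, axis=1)
            yh_all = np.linalg.norm(np.asarray(pred), axis=1)
        else:
            y_all = truth.ravel()
            yh_all = np.asarray(pred).ravel()
        for region in REGIONS:
            rmask = region_mask(sample, region, geom)
            if rmask.count == 0:
                continue
            y, y_hat = y_all[rmask.mask], yh_all[rmask.mask]
            mre_val, excl = mre(y, y_hat, return_excluded=True)
            rows.append({
                "sample": int(i), "stage": sample.stage, "region": region,
                "parameter": bundle.target,
                "nmae": nmae(y, y_hat), "mre": mre_val,
                "n_points": rmask.count, "excluded_points": excl,
            })
    return pd.DataFrame(rows)


def build_error_report(bundle: DatasetBundle, predictions: list[np.ndarray],
                       split: str = "test") -> ErrorReport:
    """Aggregate per-sample regional metrics into a Table-3-style report."""
    per_sample = _per_sample_metrics(bundle, predictions, split)
    rows = []
    for (stage, region, parameter), grp in per_sample.groupby(
            ["stage", "region", "parameter"], sort=False):
        rows.append({
            "stage": stage, "region": region, "parameter": parameter,
            "nmae_mean": float(grp["nmae"].mean()),
            "nmae_sd": float(grp["nmae"].std(ddof=0)),
            "mre_mean": float(grp["mre"].mean()),
            "mre_sd": float(grp["mre"].std(ddof=0)),
            "n_samples": int(len(grp)),
            "excluded_points": int(grp["excluded_points"].sum()),
        })
    return ErrorReport(pd.DataFrame(rows), per_sample)


@dataclass
class ConsistencyResult:
    """Oracle vs predicted mean throat speeds with their Pearson correlation."""

    oracle_speeds: np.ndarray
    predicted_speeds: np.ndarray
    r: float
    p_value: float

    def scatter_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"velocity_cfd": self.oracle_speeds,
                             "velocity_dl": self.predicted_speeds})


def consistency(bundle: DatasetBundle, predictions: list[np.ndarray],
                split: str = "test") -> ConsistencyResult:
    """Pearson correlation of mean stenotic-slab speeds, oracle vs predicted."""
    if bundle.target != "velocity":
        raise ValueError("consistency analysis requires a velocity bundle")
    indices = bundle.split(split)
    truth, pred = [], []
    for y_hat, i in zip(predictions, indices):
        sample = bundle.samples[int(i)]
        geom = VesselGeometry(sample.spec)
        truth.append(mean_stenotic_velocity(sample, geom=geom))
        pred.append(mean_stenotic_velocity(sample, velocity=np.asarray(y_hat),
                                           geom=geom))
    truth_arr, pred_arr = np.asarray(truth), np.asarray(pred)
    if len(truth_arr) < 2:  # correlation undefined for a single pair
        return ConsistencyResult(truth_arr, pred_arr, float("nan"), float("nan"))
    r, p = stats.pearsonr(truth_arr, pred_arr)
    return ConsistencyResult(truth_arr, pred_arr, float(r), float(p))
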