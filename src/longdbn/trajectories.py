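"""Cubic B-spline curves per subject/feature and uniform resampling."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline, make_interp_spline, make_smoothing_spline

from .core_io import Config, OmicsDataset

MIN_POINTS = 5


@dataclass
class Curve:
    """A fitted cubic spline for one subject/layer/feature time series."""

    subject: str
    layer: str
    feature: str
    spline: BSpline
    domain: tuple[float, float]
    n_observed: int

    @property
    def knots(self) -> np.ndarray:
        return self.spline.t

    @property
    def coefficients(self) -> np.ndarray:
        return self.spline.c

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t_arr = np.asarray(t, dtype=float)
        lo, hi = self.domain
        if np.any(t_arr < lo - 1e-9) or np.any(t_arr > hi + 1e-9):
            raise ValueError(
                f"evaluation outside curve domain [{lo}, {hi}]")
        out = self.spline(np.clip(t_arr, lo, hi))
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


@dataclass
class SampledSeries:
    """A curve evaluated on a uniform grid."""

    times: np.ndarray
    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        steps = np.diff(self.times)
        if len(steps) and (np.any(steps <= 0)
                           or not np.allclose(steps, steps[0])):
            raise ValueError("times must form a strictly increasing uniform grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite sampled value")


def fit_bspline(times: np.ndarray, values: np.ndarray,
                smoothing: str = "gcv", subject: str = "", layer: str = "",
                feature: str = "") -> Curve:
    """Fit a cubic spline to one time series.

    ``smoothing="interpolate"`` interpolates the data exactly;
    ``smoothing="gcv"`` picks the penalty by generalized cross-validation.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < MIN_POINTS:
        raise ValueError(f"need at least {MIN_POINTS} points, got {len(times)}")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if smoothing == "interpolate":
        spline = make_interp_spline(times, values, k=3)
    elif smoothing == "gcv":
        spline = make_smoothing_spline(times, values, lam=None)
    else:
        raise ValueError(f"unknown smoothing mode {smoothing!r}")
    return Curve(subject, layer, feature, spline,
                 (float(times[0]), float(times[-1])), len(times))


def resample(curve: Curve, rate_days: float, grid_origin: float,
             clip_negative: bool = False) -> SampledSeries:
    """Evaluate a curve on the grid {origin, origin+rate, ...} within its domain.

    No extrapolation: grid points outside the domain are discarded.
    ``clip_negative`` floors values at zero (relative-abundance mode).
    """
    if rate_days <= 0:
        raise ValueError("rate must be positive")
    lo, hi = curve.domain
    first = int(np.ceil((lo - grid_origin) / rate_days - 1e-9))
    last = int(np.floor((hi - grid_origin) / rate_days + 1e-9))
    if last < first:
        raise ValueError("empty resampling grid inside curve domain")
    times = grid_origin + rate_days * np.arange(first, last + 1)
    values = curve(times)
    if clip_negative:
        values = np.maximum(values, 0.0)
    return SampledSeries(times, values,
                         provenance=f"{curve.subject}/{curve.layer}/{curve.feature}")


@dataclass
class TrajectorySet:
    """Curves for every (subject, layer, feature) of a dataset."""

    curves: dict[tuple[str, str, str], Curve] = field(default_factory=dict)

    def get(self, subject: str, layer: str, feature: str) -> Curve:
        return self.curves[(subject, layer, feature)]

    def subject_domain(self, subject: str) -> tuple[float, float]:
        doms = [c.domain for key, c in self.curves.items() if key[0] == subject]
        return (max(d[0] for d in doms), min(d[1] for d in doms))


def fit_dataset(dataset: OmicsDataset, smoothing: str = "gcv") -> TrajectorySet:
    """Fit a curve to every dynamic feature trajectory of every subject."""
    traj = TrajectorySet()
    for name, layer in dataset.dynamic_layers().items():
        for subject, obs in layer.data.items():
            for j, feature in enumerate(layer.features):
                traj.curves[(subject, name, feature)] = fit_bspline(
                    obs.times, obs.values[:, j], smoothing=smoothing,
                    subject=subject, layer=name, feature=feature)
    return traj
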