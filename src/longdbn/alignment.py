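"""Linear temporal alignment of subjects against an optimal reference.

A warp tau(t) = a*t + b maps a subject's sample times onto the
reference time axis.  The alignment error between a warped subject and
the reference is the squared curve difference integrated (trapezoid
rule, 1-day grid) over the overlapping interval, divided by the overlap
length, summed over the alignment features.  Candidates are searched on
a grid (a in [0.5, 2] step 0.05, b in [-30, 30] step 1) and refined by
Nelder-Mead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core_io import Config, OmicsDataset
from .trajectories import Curve, TrajectorySet

log = logging.getLogger(__name__)


@dataclass
class TimeWarp:
    subject: str
    a: float
    b: float
    error: float
    reference_subject: str

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("warp slope must be positive")
        if self.error < 0:
            raise ValueError("alignment error must be nonnegative")

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.a * np.asarray(t, dtype=float) + self.b


@dataclass
class AlignmentResult:
    warps: dict[str, TimeWarp]
    reference: str
    mu: float = float("nan")
    delta: float = float("nan")
    dropped: list[str] = field(default_factory=list)


class AlignmentError(RuntimeError):
    """No candidate warp yields sufficient domain overlap."""


@dataclass
class _DenseCurves:
    """Curves of one subject pre-evaluated on a 1-day grid for fast lookup."""

    grid: np.ndarray
    values: np.ndarray            # (n_features, n_grid)
    domain: tuple[float, float]

    @classmethod
    def from_curves(cls, curves: list[Curve], step: float = 1.0) -> "_DenseCurves":
        lo = max(c.domain[0] for c in curves)
        hi = min(c.domain[1] for c in curves)
        if hi <= lo:
            raise AlignmentError("features share no common time domain")
        grid = np.arange(lo, hi + step / 2, step)
        grid[-1] = min(grid[-1], hi)
        values = np.vstack([c(grid) for c in curves])
        return cls(grid, values, (lo, hi))

    def at(self, t: np.ndarray) -> np.ndarray:
        return np.vstack([np.interp(t, self.grid, row) for row in self.values])


def _pair_error(sample: _DenseCurves, reference: _DenseCurves, a: float,
                b: float, min_overlap_frac: float, step: float = 1.0) -> float:
    """Error of warping ``sample`` by tau(t)=a*t+b onto ``reference``."""
    if a <= 0:
        return np.inf
    s0, s1 = sample.domain
    r0, r1 = reference.domain
    lo = max(r0, a * s0 + b)
    hi = min(r1, a * s1 + b)
    if hi - lo < min_overlap_frac * (r1 - r0):
        return np.inf
    n = max(int(np.ceil((hi - lo) / step)) + 1, 8)
    tau = np.linspace(lo, hi, n)
    diff = reference.at(tau) - sample.at((tau - b) / a)
    per_feature = np.trapezoid(diff ** 2, tau, axis=1) / (hi - lo)
    return float(per_feature.sum())


def align_pair(sample_curves: list[Curve], reference_curves: list[Curve],
               config: Config | None = None, subject: str = "",
               reference_subject: str = "") -> TimeWarp:
    """Find the warp minimizing the alignment error for one subject pair."""
    cfg = config or Config()
    sample = _DenseCurves.from_curves(sample_curves)
    reference = _DenseCurves.from_curves(reference_curves)
    min_frac = cfg["alignment.min_overlap_frac"]

    a_grid = np.arange(cfg["alignment.a_min"],
                       cfg["alignment.a_max"] + 1e-9, cfg["alignment.a_step"])
    b_grid = np.arange(cfg["alignment.b_min"],
                       cfg["alignment.b_max"] + 1e-9, cfg["alignment.b_step"])
    best: tuple[float, float, float] | None = None
    for a in a_grid:
        for b in b_grid:
            err = _pair_error(sample, reference, a, b, min_frac)
            if not np.isfinite(err):
                continue
            if best is None or err < best[0]:
                best = (err, float(a), float(b))
    if best is None:
        raise AlignmentError(
            f"no (a, b) candidate gives >= {min_frac:.0%} overlap for "
            f"subject {subject!r} vs reference {reference_subject!r}")
    err, a, b = best
    if cfg["alignment.refine"] and err > 0:
        res = optimize.minimize(
            lambda ab: _pair_error(sample, reference, ab[0], ab[1], min_frac),
            x0=[a, b], method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-12, "maxiter": 300})
        if np.isfinite(res.fun) and res.fun <= err:
            err, a, b = float(res.fun), float(res.x[0]), float(res.x[1])
    return TimeWarp(subject, a, b, err, reference_subject)


def alignment_features(dataset: OmicsDataset, layer_name: str,
                       n_features: int = 10) -> list[str]:
    """The alignment feature subset: highest pooled mean abundance."""
    layer = dataset.layers[layer_name]
    pooled = np.vstack([obs.values for obs in layer.data.values()])
    means = pooled.mean(axis=0)
    order = sorted(range(len(layer.features)),
                   key=lambda i: (-means[i], layer.features[i]))
    return [layer.features[i] for i in order[:n_features]]


def select_reference(trajectories: TrajectorySet, subjects: list[str],
                     layer_name: str, feature_subset: list[str],
                     config: Config | None = None
                     ) -> tuple[str, AlignmentResult]:
    """Pick the reference subject minimizing the total pairwise error."""
    cfg = config or Config()
    if len(subjects) < 2:
        raise ValueError("need at least two subjects to select a reference")
    curve_sets = {
        s: [trajectories.get(s, layer_name, f) for f in feature_subset]
        for s in subjects
    }
    candidates: list[tuple[float, str, dict[str, TimeWarp]]] = []
    for ref in sorted(subjects):
        warps = {ref: TimeWarp(ref, 1.0, 0.0, 0.0, ref)}
        total = 0.0
        try:
            for other in sorted(subjects):
                if other == ref:
                    continue
                warp = align_pair(curve_sets[other], curve_sets[ref],
                                  cfg, subject=other, reference_subject=ref)
                warps[other] = warp
                total += warp.error
        except AlignmentError as exc:
            log.info("reference candidate %s disqualified: %s", ref, exc)
            continue
        candidates.append((total, ref, warps))
    if not candidates:
        raise AlignmentError("every reference candidate was disqualified")
    total, ref, warps = min(candidates, key=lambda c: (c[0], c[1]))
    return ref, AlignmentResult(warps, ref)


def filter_aligned(result: AlignmentResult) -> AlignmentResult:
    """Drop subjects whose alignment error exceeds mu + 2*delta."""
    errors = {s: w.error for s, w in result.warps.items()
              if s != result.reference}
    if not errors:
        raise ValueError("need at least one non-reference warp")
    vals = np.array(list(errors.values()))
    mu, delta = float(vals.mean()), float(vals.std())
    dropped = sorted(s for s, e in errors.items() if e > mu + 2 * delta)
    warps = {s: w for s, w in result.warps.items() if s not in dropped}
    return AlignmentResult(warps, result.reference, mu, delta, dropped)


def propagate_warp(warp: TimeWarp, dataset: OmicsDataset) -> OmicsDataset:
    """Apply tau(t)=a*t+b to every dynamic layer of the warp's subject."""
    out = dataset.copy()
    for layer in out.dynamic_layers().values():
        if warp.subject in layer.data:
            obs = layer.data[warp.subject]
            obs.times = warp.a * obs.times + warp.b
    return out


def align_dataset(dataset: OmicsDataset, trajectories: TrajectorySet,
                  config: Config | None = None
                  ) -> tuple[OmicsDataset, AlignmentResult]:
    """Full alignment stage: reference selection, filtering, propagation."""
    cfg = config or Config()
    layer_name = cfg["alignment.layer"]
    features = alignment_features(dataset, layer_name,
                                  cfg["alignment.n_features"])
    ref, result = select_reference(trajectories, dataset.subjects,
                                   layer_name, features, cfg)
    result = filter_aligned(result)
    aligned = dataset.drop_subjects(result.dropped)
    for warp in result.warps.values():
        aligned = propagate_warp(warp, aligned)
    return aligned, result
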