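"""Seeded generator of longitudinal multi-omics datasets with a known
ground-truth network, subject time warps and validation databases.

Latent dynamics follow exactly the linear-Gaussian family the learner
assumes: each dynamic node at slice t+1 is a noisy linear function of
its inter-parents (previous slice) and intra-parents (same slice,
resolved in topological order).  Subjects observe the latent reference
trajectory through the inverse of their personal linear warp, with
optional sampling jitter and missingness.  Emission is either ``raw``
(latent values, log-ratio mode) or ``softmax`` (per-layer simplex,
relative mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment import TimeWarp
from .constraints import ConstraintMatrix, get_preset
from .core_io.types import (SLICE_T, SLICE_T1, DBNModel, DynamicSeries, Edge,
                            GaussianCPD, Layer, NodeRef, OmicsDataset)
from .dbn import DYNAMIC_KINDS, GriddedSubject
from .evaluate import ValidationDB

log = logging.getLogger(__name__)

_KIND_LAYER = {"taxon": "taxa", "gene": "genes", "metabolite": "metabolites",
               "host_gene": "host_genes"}
#: intra-slice resolution order implied by the constraint flow
_TOPO_KINDS = ("taxon", "gene", "metabolite")


@dataclass
class SimulationConfig:
    n_subjects: int = 50
    n_taxa: int = 5
    n_genes: int = 4
    n_metabolites: int = 4
    n_host_genes: int = 2
    grid_t0: float = 0.0
    grid_rate: float = 14.0
    grid_points: int = 25
    a_range: tuple[float, float] = (1.0, 1.0)
    b_range: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 0.1                  # process noise of every CPD
    obs_noise_sd: float = 0.0
    edge_density: float = 0.3
    coef_range: tuple[float, float] = (0.5, 1.0)
    self_coef_range: tuple[float, float] = (0.3, 0.6)
    jitter_days: float = 0.0
    missing_rate: float = 0.0
    emission: str = "raw"                  # raw | softmax
    constraints: str = "augmented"
    max_parents: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_taxa, self.n_genes,
               self.n_metabolites, self.n_host_genes) < 1:
            raise ValueError("all entity counts must be >= 1")
        if self.noise_sd < 0 or self.obs_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0 < self.a_range[0] <= self.a_range[1]:
            raise ValueError("warp slope range must be positive")
        if self.emission not in ("raw", "softmax"):
            raise ValueError(f"unknown emission mode {self.emission!r}")


@dataclass
class GroundTruth:
    model: DBNModel
    warps: dict[str, TimeWarp]
    constraints: ConstraintMatrix
    latent: list[GriddedSubject] = field(default_factory=list)

    def edges_of_kind(self, parent_kind: str,
                      child_kind: str) -> set[tuple[str, str]]:
        return {(e.parent.feature, e.child.feature) for e in self.model.edges
                if e.parent.kind == parent_kind and e.child.kind == child_kind
                and e.parent.feature != e.child.feature}


def _feature_names(config: SimulationConfig) -> dict[str, list[str]]:
    return {
        "taxon": [f"T{i:02d}" for i in range(config.n_taxa)],
        "gene": [f"G{i:02d}" for i in range(config.n_genes)],
        "metabolite": [f"M{i:02d}" for i in range(config.n_metabolites)],
        "host_gene": [f"H{i:02d}" for i in range(config.n_host_genes)],
    }


def _draw_model(config: SimulationConfig, constraints: ConstraintMatrix,
                rng: np.random.Generator) -> DBNModel:
    names = _feature_names(config)
    dyn_vars = [(k, f) for k in _TOPO_KINDS for f in names[k]]
    children = [NodeRef(k, f, SLICE_T1) for k, f in dyn_vars]
    nodes: set[NodeRef] = set(children)
    nodes |= {c.at(SLICE_T) for c in children}
    nodes |= {NodeRef("host_gene", f, s) for f in names["host_gene"]
              for s in (SLICE_T, SLICE_T1)}

    for _attempt in range(100):
        cpds: dict[NodeRef, GaussianCPD] = {}
        edges: list[Edge] = []
        for child in children:
            self_parent = child.at(SLICE_T)
            parents = [self_parent]
            betas = [rng.uniform(*config.self_coef_range)]
            candidates = []
            for lag in ("intra", "inter"):
                slice_ = SLICE_T1 if lag == "intra" else SLICE_T
                for kind in _TOPO_KINDS + ("host_gene",):
                    for feature in names[kind]:
                        parent = NodeRef(kind, feature, slice_)
                        if parent in (child, self_parent):
                            continue
                        if constraints.is_allowed(parent, child, lag):
                            candidates.append(parent)
            room = config.max_parents - 1
            n_extra = min(int(rng.binomial(len(candidates),
                                           config.edge_density)), room)
            if n_extra:
                for idx in rng.choice(len(candidates), size=n_extra,
                                      replace=False):
                    parent = candidates[idx]
                    parents.append(parent)
                    mag = rng.uniform(*config.coef_range)
                    betas.append(mag * rng.choice([-1.0, 1.0]))
            cpds[child] = GaussianCPD(child, parents, 0.0,
                                      np.array(betas), config.noise_sd ** 2
                                      if config.noise_sd > 0 else 1e-12)
            for parent, beta in zip(parents, betas):
                lag = "inter" if parent.slice_ == SLICE_T else "intra"
                edges.append(Edge(parent, child, lag, coefficient=float(beta)))
        if _stable(cpds, dyn_vars):
            model = DBNModel(nodes, edges, cpds, constraints.name)
            model.validate(max_parents=config.max_parents)
            return model
    raise RuntimeError("no stable coefficient draw in 100 attempts")


def _stable(cpds: dict[NodeRef, GaussianCPD], dyn_vars: list[tuple]) -> bool:
    # effective one-step matrix (I - B)^-1 A must have spectral radius < 1
    index = {v: i for i, v in enumerate(dyn_vars)}
    n = len(dyn_vars)
    A = np.zeros((n, n))
    B = np.zeros((n, n))
    for child, cpd in cpds.items():
        ci = index[(child.kind, child.feature)]
        for parent, beta in zip(cpd.parents, cpd.betas):
            key = (parent.kind, parent.feature)
            if key not in index:
                continue                        # static parent
            if parent.slice_ == SLICE_T:
                A[ci, index[key]] = beta
            else:
                B[ci, index[key]] = beta
    eff = np.linalg.solve(np.eye(n) - B, A)
    # strict stability for random draws; tolerate the unit-root boundary so
    # that beta=1 self-loops (an exact fixed point under zero noise) pass
    return float(np.max(np.abs(np.linalg.eigvals(eff)))) <= 1.0 + 1e-12


def _simulate_subject(model: DBNModel, config: SimulationConfig,
                      host: dict[tuple, float], subject: str,
                      rng: np.random.Generator) -> GriddedSubject:
    names = _feature_names(config)
    times = config.grid_t0 + config.grid_rate * np.arange(config.grid_points)
    order = [NodeRef(k, f, SLICE_T1) for k in _TOPO_KINDS for f in names[k]]
    series = {(c.kind, c.feature): np.zeros(config.grid_points) for c in order}
    for var in series:
        series[var][0] = rng.normal(0.0, 0.5)
    for i in range(config.grid_points - 1):
        for child in order:                    # topological within slice t+1
            cpd = model.cpds[child]
            total = cpd.beta0
            for parent, beta in zip(cpd.parents, cpd.betas):
                key = (parent.kind, parent.feature)
                if parent.kind == "host_gene":
                    total += beta * host[key]
                elif parent.slice_ == SLICE_T:
                    total += beta * series[key][i]
                else:
                    total += beta * series[key][i + 1]
            series[(child.kind, child.feature)][i + 1] = (
                total + rng.normal(0.0, config.noise_sd))
    return GriddedSubject(subject, times, series, dict(host))


def _softmax_rows(values: np.ndarray) -> np.ndarray:
    shifted = values - values.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def generate(config: SimulationConfig
             ) -> tuple[OmicsDataset, GroundTruth]:
    """Draw a ground-truth network and simulate every subject through it."""
    rng = np.random.default_rng(config.seed)
    constraints = get_preset(config.constraints)
    model = _draw_model(config, constraints, rng)
    names = _feature_names(config)
    subjects = [f"S{i:02d}" for i in range(config.n_subjects)]

    warps: dict[str, TimeWarp] = {}
    latent: list[GriddedSubject] = []
    layer_obs: dict[str, dict[str, DynamicSeries]] = {
        _KIND_LAYER[k]: {} for k in _TOPO_KINDS}
    host_data: dict[str, np.ndarray] = {}

    for subject in subjects:
        host = {("host_gene", f): rng.normal(0.0, 1.0)
                for f in names["host_gene"]}
        host_data[subject] = np.array([host[("host_gene", f)]
                                       for f in names["host_gene"]])
        gs = _simulate_subject(model, config, host, subject, rng)
        latent.append(gs)
        a = rng.uniform(*config.a_range)
        b = rng.uniform(*config.b_range)
        warps[subject] = TimeWarp(subject, a, b, 0.0, "latent")

        # subject-local observation times: tau^-1 of the latent grid
        obs_times = (gs.times - b) / a
        if config.jitter_days > 0:
            jitter = rng.uniform(-config.jitter_days, config.jitter_days,
                                 size=len(obs_times))
            jitter[0] = abs(jitter[0])
            obs_times = np.sort(obs_times + jitter)
        keep = np.ones(len(obs_times), dtype=bool)
        if config.missing_rate > 0:
            keep = rng.random(len(obs_times)) > config.missing_rate
            while keep.sum() < 5:
                keep[rng.integers(len(keep))] = True
        obs_times = obs_times[keep]
        latent_times = a * obs_times + b
        for kind in _TOPO_KINDS:
            cols = []
            for feature in names[kind]:
                traj = gs.dynamic[(kind, feature)]
                vals = np.interp(latent_times, gs.times, traj)
                if config.obs_noise_sd > 0:
                    vals = vals + rng.normal(0.0, config.obs_noise_sd,
                                             size=len(vals))
                cols.append(vals)
            values = np.column_stack(cols)
            if config.emission == "softmax":
                values = _softmax_rows(values)
            layer_obs[_KIND_LAYER[kind]][subject] = DynamicSeries(
                obs_times.copy(), values)

    layers = {
        "taxa": Layer("taxa", "taxon", True, names["taxon"],
                      layer_obs["taxa"]),
        "genes": Layer("genes", "gene", True, names["gene"],
                       layer_obs["genes"]),
        "metabolites": Layer("metabolites", "metabolite", True,
                             names["metabolite"], layer_obs["metabolites"]),
        "host_genes": Layer("host_genes", "host_gene", False,
                            names["host_gene"], host_data),
    }
    dataset = OmicsDataset(subjects, layers)
    truth = GroundTruth(model, warps, constraints, latent)
    return dataset, truth


def make_validation_db(truth: GroundTruth, kind: str,
                       extra_negative_fraction: float = 0.0,
                       seed: int = 0) -> ValidationDB:
    """Database of planted typed relations, optionally padded with decoys.

    Decoy features enlarge the universes (never the pair list), so a
    nonzero fraction dilutes precision of chance hits.
    """
    parent_kind, child_kind = {"T_G": ("taxon", "gene"),
                               "T_M": ("taxon", "metabolite")}[kind]
    pairs = truth.edges_of_kind(parent_kind, child_kind)
    parent_universe = {n.feature for n in truth.model.nodes
                       if n.kind == parent_kind}
    child_universe = {n.feature for n in truth.model.nodes
                      if n.kind == child_kind}
    if extra_negative_fraction > 0:
        n_extra = max(1, int(extra_negative_fraction * len(child_universe)))
        child_universe |= {f"decoy_{child_kind}{i:02d}" for i in range(n_extra)}
    return ValidationDB(kind, pairs, parent_universe, child_universe)
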