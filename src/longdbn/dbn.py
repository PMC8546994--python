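"""Two-slice conditional linear-Gaussian network learning.

Structure search is greedy hill climbing over constraint-valid edges,
scored by BIC = log-likelihood - (|Theta|/2) * log|D|, initialized with
an inter-slice self-loop for every dynamic node.  Per-child CPDs are
ordinary least squares (the Gaussian MLE) with sigma^2 = mean squared
residual.  Edge confidence comes from a subject-level bootstrap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constraints import ConstraintMatrix
from .core_io.types import (SLICE_T, SLICE_T1, DBNModel, Edge, GaussianCPD,
                            NodeRef, OmicsDataset)
from .trajectories import TrajectorySet, resample

log = logging.getLogger(__name__)

SIGMA2_FLOOR = 1e-9
DYNAMIC_KINDS = ("taxon", "gene", "metabolite")

Var = tuple[str, str]                      # (kind, feature)


@dataclass
class GriddedSubject:
    """One subject resampled on the common uniform grid."""

    subject: str
    times: np.ndarray                      # uniform grid, days
    dynamic: dict[Var, np.ndarray]         # var -> series over grid
    static: dict[Var, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for var, series in self.dynamic.items():
            if len(series) != len(self.times):
                raise ValueError(f"series length mismatch for {var}")


def resample_dataset(dataset: OmicsDataset, trajectories: TrajectorySet,
                     rate_days: float, origin: float | None = None,
                     clip_negative: bool = True) -> list[GriddedSubject]:
    """Evaluate all curves of each subject on the shared uniform grid.

    The grid is {origin + k*rate} intersected with each subject's common
    curve domain; subjects with fewer than two grid points are skipped.
    """
    out: list[GriddedSubject] = []
    for subject in dataset.subjects:
        lo, hi = trajectories.subject_domain(subject)
        base = 0.0 if origin is None else origin
        first = int(np.ceil((lo - base) / rate_days - 1e-9))
        last = int(np.floor((hi - base) / rate_days + 1e-9))
        if last - first < 1:
            log.warning("subject %s: fewer than 2 grid points, skipped", subject)
            continue
        times = base + rate_days * np.arange(first, last + 1)
        dynamic: dict[Var, np.ndarray] = {}
        for name, layer in dataset.dynamic_layers().items():
            if subject not in layer.data:
                continue
            for feature in layer.features:
                curve = trajectories.get(subject, name, feature)
                vals = np.asarray(curve(times), dtype=float)
                if clip_negative and layer.node_kind != "env":
                    vals = np.maximum(vals, 0.0)
                dynamic[(layer.node_kind, feature)] = vals
        static: dict[Var, float] = {}
        for layer in dataset.static_layers().values():
            if subject not in layer.data:
                continue
            for feature, value in zip(layer.features, layer.data[subject]):
                static[(layer.node_kind, feature)] = float(value)
        out.append(GriddedSubject(subject, times, dynamic, static))
    return out


class ObservationTable:
    """|D| rows, one per consecutive grid-time pair per subject.

    Columns hold every node's value at slice t and slice t+1; static
    nodes are repeated in both slices and the environmental ``week``
    node carries the aligned grid time (in weeks) of its slice.
    """

    def __init__(self, df: pd.DataFrame, nodes: list[NodeRef],
                 subjects_per_row: np.ndarray) -> None:
        self.df = df
        self.nodes = nodes
        self.subjects_per_row = subjects_per_row
        if df.isna().any().any():
            raise ValueError("observation table contains missing cells")

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def col(self, node: NodeRef) -> np.ndarray:
        return self.df[str(node)].to_numpy()

    def children(self) -> list[NodeRef]:
        return sorted(n for n in self.nodes
                      if n.slice_ == SLICE_T1 and n.kind in DYNAMIC_KINDS)

    def variables(self, slice_: str) -> list[NodeRef]:
        return sorted(n for n in self.nodes if n.slice_ == slice_)


def build_observations(subjects: Sequence[GriddedSubject],
                       include_week: bool = True) -> ObservationTable:
    """Assemble the two-slice design table from gridded subjects."""
    if not subjects:
        raise ValueError("no gridded subjects")
    dyn_vars = sorted(subjects[0].dynamic)
    stat_vars = sorted(subjects[0].static)
    rows: list[dict[str, float]] = []
    row_subjects: list[str] = []
    for gs in subjects:
        if sorted(gs.dynamic) != dyn_vars or sorted(gs.static) != stat_vars:
            raise ValueError(f"subject {gs.subject} has a different node set")
        for i in range(len(gs.times) - 1):
            row: dict[str, float] = {}
            for (kind, feature), series in gs.dynamic.items():
                row[f"{kind}:{feature}@{SLICE_T}"] = series[i]
                row[f"{kind}:{feature}@{SLICE_T1}"] = series[i + 1]
            for (kind, feature), value in gs.static.items():
                row[f"{kind}:{feature}@{SLICE_T}"] = value
                row[f"{kind}:{feature}@{SLICE_T1}"] = value
            if include_week:
                row[f"env:week@{SLICE_T}"] = gs.times[i] / 7.0
                row[f"env:week@{SLICE_T1}"] = gs.times[i + 1] / 7.0
            rows.append(row)
            row_subjects.append(gs.subject)
    df = pd.DataFrame(rows)
    nodes = [NodeRef(kind, feature, s)
             for (kind, feature) in dyn_vars + stat_vars
             for s in (SLICE_T, SLICE_T1)]
    if include_week:
        nodes += [NodeRef("env", "week", SLICE_T), NodeRef("env", "week", SLICE_T1)]
    return ObservationTable(df, nodes, np.asarray(row_subjects))


# ---------------------------------------------------------------------------
# CPD fitting and scoring


def fit_cpd(child: NodeRef, parents: Sequence[NodeRef],
            table: ObservationTable) -> GaussianCPD:
    """Gaussian MLE of a child given its parents (OLS; sigma^2 = RSS/|D|)."""
    y = table.col(child)
    n, k = len(y), len(parents)
    if n <= k + 1:
        raise ValueError(f"|D|={n} too small for {k} parents")
    design = np.column_stack([np.ones(n)] +
                             [table.col(p) for p in parents])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < k + 1:
        raise np.linalg.LinAlgError(
            f"rank-deficient design for child {child}")
    resid = y - design @ beta
    sigma2 = max(float(np.mean(resid ** 2)), SIGMA2_FLOOR)
    return GaussianCPD(child, list(parents), float(beta[0]), beta[1:], sigma2)


def cpd_loglik(cpd: GaussianCPD, table: ObservationTable) -> float:
    y = table.col(cpd.child)
    if cpd.parents:
        design = np.column_stack([table.col(p) for p in cpd.parents])
        mu = cpd.beta0 + design @ cpd.betas
    else:
        mu = cpd.beta0
    resid = y - mu
    n = len(y)
    return float(-0.5 * n * math.log(2 * math.pi * cpd.sigma2)
                 - np.sum(resid ** 2) / (2 * cpd.sigma2))


def bic_score(model: DBNModel, table: ObservationTable) -> float:
    """Sum of per-child Gaussian log-likelihoods minus (|Theta|/2)log|D|."""
    loglik = sum(cpd_loglik(cpd, table) for cpd in model.cpds.values())
    n_params = sum(len(cpd.parents) + 2 for cpd in model.cpds.values())
    return loglik - 0.5 * n_params * math.log(table.n_rows)


def normalized_weight(coefficient: float, parent: NodeRef, child: NodeRef,
                      table: ObservationTable) -> float:
    """Standardized coefficient: beta * sd(parent) / sd(child)."""
    sd_child = float(np.std(table.col(child)))
    if sd_child == 0:
        raise ValueError(f"zero variance child {child}")
    return coefficient * float(np.std(table.col(parent))) / sd_child


# ---------------------------------------------------------------------------
# Greedy structure search


def _intra_creates_cycle(parent: NodeRef, child: NodeRef,
                         intra_edges: set[tuple[NodeRef, NodeRef]]) -> bool:
    # DFS from parent back through existing intra edges
    adj: dict[NodeRef, list[NodeRef]] = {}
    for p, c in intra_edges | {(parent, child)}:
        adj.setdefault(p, []).append(c)
    stack, seen = [child], set()
    while stack:
        node = stack.pop()
        if node == parent:
            return True
        if node in seen:
            continue
        seen.add(node)
        stack.extend(adj.get(node, []))
    return False


def learn_structure(table: ObservationTable, constraints: ConstraintMatrix,
                    max_parents: int = 3,
                    bic_trace: list[float] | None = None) -> DBNModel:
    """Greedy hill climbing with additions only.

    Starts from a self-loop inter-edge on every dynamic node and
    repeatedly adds the single constraint-valid edge with the largest
    strictly positive BIC gain until none remains or every child is at
    ``max_parents`` (the self-loop counts toward the cap).  Ties break
    lexicographically by (child, parent, lag).
    """
    if table.n_rows == 0:
        raise ValueError("empty observation table")
    children = table.children()
    parents: dict[NodeRef, list[NodeRef]] = {}
    cpds: dict[NodeRef, GaussianCPD] = {}
    llik: dict[NodeRef, float] = {}
    for child in children:
        self_parent = child.at(SLICE_T)
        parents[child] = [self_parent]
        cpds[child] = fit_cpd(child, parents[child], table)
        llik[child] = cpd_loglik(cpds[child], table)

    # candidate parents per child, fixed by the constraint matrix
    candidates: dict[NodeRef, list[tuple[NodeRef, str]]] = {}
    for child in children:
        cand = []
        for lag in ("intra", "inter"):
            slice_ = SLICE_T1 if lag == "intra" else SLICE_T
            for node in table.variables(slice_):
                if node == child:
                    continue
                if constraints.is_allowed(node, child, lag):
                    cand.append((node, lag))
        candidates[child] = cand

    half_log_n = 0.5 * math.log(table.n_rows)
    gain_cache: dict[NodeRef, dict[tuple[NodeRef, str], float]] = {}
    intra_edges: set[tuple[NodeRef, NodeRef]] = set()

    def current_bic() -> float:
        n_params = sum(len(p) + 2 for p in parents.values())
        return sum(llik.values()) - n_params * half_log_n

    if bic_trace is not None:
        bic_trace.append(current_bic())

    def child_gains(child: NodeRef) -> dict[tuple[NodeRef, str], float]:
        gains = {}
        for parent, lag in candidates[child]:
            if parent in parents[child]:
                continue
            if lag == "intra" and _intra_creates_cycle(parent, child,
                                                       intra_edges):
                continue
            try:
                cpd = fit_cpd(child, parents[child] + [parent], table)
            except (np.linalg.LinAlgError, ValueError):
                continue                      # rank-deficient: gain -inf
            gains[(parent, lag)] = (cpd_loglik(cpd, table) - llik[child]
                                    - half_log_n)
        return gains

    while True:
        best = None
        for child in children:
            if len(parents[child]) >= max_parents:
                continue
            if child not in gain_cache:
                gain_cache[child] = child_gains(child)
            for (parent, lag), gain in gain_cache[child].items():
                if gain <= 0:
                    continue
                key = (gain, )
                tie = (str(child), str(parent), lag)
                if best is None or gain > best[0] or (
                        gain == best[0] and tie < best[1]):
                    best = (gain, tie, child, parent, lag)
        if best is None:
            break
        _, _, child, parent, lag = best
        parents[child].append(parent)
        cpds[child] = fit_cpd(child, parents[child], table)
        llik[child] = cpd_loglik(cpds[child], table)
        if lag == "intra":
            intra_edges.add((parent, child))
        gain_cache.pop(child, None)
        if bic_trace is not None:
            bic_trace.append(current_bic())

    edges: list[Edge] = []
    for child in children:
        cpd = cpds[child]
        for parent, beta in zip(cpd.parents, cpd.betas):
            lag = "inter" if parent.slice_ == SLICE_T else "intra"
            try:
                nw = normalized_weight(float(beta), parent, child, table)
            except ValueError:
                nw = math.nan
            edges.append(Edge(parent, child, lag, coefficient=float(beta),
                              normalized_weight=nw, bootstrap_support=1.0))
    model = DBNModel(set(table.nodes), edges, cpds, constraints.name)
    model.validate(max_parents=max_parents)
    return model


# ---------------------------------------------------------------------------
# Bootstrap


@dataclass
class BootstrapNetwork:
    """Union of edges over subject-resampled learning repetitions."""

    edges: list[Edge]
    n_reps: int
    seed: int
    constraints_id: str = "custom"

    def edge_keys(self) -> set[tuple]:
        return {e.key for e in self.edges}


def bootstrap_network(subjects: Sequence[GriddedSubject],
                      constraints: ConstraintMatrix, n_reps: int = 100,
                      seed: int = 0, max_parents: int = 3,
                      include_week: bool = True,
                      resample_subjects: bool = True) -> BootstrapNetwork:
    """Learn ``n_reps`` networks on subject-level bootstrap resamples.

    Each repetition draws as many subjects as exist, with replacement
    (duplicated subjects contribute duplicated rows), and the result is
    the union of edges with support = occurrences / n_reps and
    coefficients averaged over occurrences.  Per-repetition seeds are
    spawned from ``seed`` so the outcome is independent of execution
    order.
    """
    if len(subjects) < 2:
        raise ValueError("bootstrap needs at least two subjects")
    by_name = {gs.subject: gs for gs in subjects}
    names = sorted(by_name)
    rep_seeds = np.random.SeedSequence(seed).spawn(n_reps)
    acc: dict[tuple, dict[str, float]] = {}
    for rep, ss in enumerate(rep_seeds):
        if resample_subjects:
            rng = np.random.default_rng(ss)
            chosen = [by_name[n] for n in rng.choice(names, size=len(names))]
        else:
            chosen = [by_name[n] for n in names]
        table = build_observations(chosen, include_week=include_week)
        model = learn_structure(table, constraints, max_parents=max_parents)
        for edge in model.edges:
            if not constraints.is_allowed(edge.parent, edge.child, edge.lag):
                raise AssertionError(f"constraint violation: {edge.key}")
            rec = acc.setdefault(edge.key, {"n": 0, "coef": 0.0, "nw": 0.0})
            rec["n"] += 1
            rec["coef"] += edge.coefficient
            rec["nw"] += (edge.normalized_weight
                          if math.isfinite(edge.normalized_weight) else 0.0)
    edges = []
    for key in sorted(acc):
        parent_kind, parent_feature, child_kind, child_feature, lag = key
        rec = acc[key]
        parent_slice = SLICE_T if lag == "inter" else SLICE_T1
        edges.append(Edge(
            NodeRef(parent_kind, parent_feature, parent_slice),
            NodeRef(child_kind, child_feature, SLICE_T1), lag,
            coefficient=rec["coef"] / rec["n"],
            normalized_weight=rec["nw"] / rec["n"],
            bootstrap_support=rec["n"] / n_reps))
    return BootstrapNetwork(edges, n_reps, seed, constraints.name)


# ---------------------------------------------------------------------------
# Network summaries and comparisons


def per_slice_node_count(layer_sizes: Mapping[str, int]) -> int:
    """Number of nodes in one slice given per-layer entity counts."""
    return int(sum(layer_sizes.values()))


def max_edges_single_network(n_nodes_per_slice: int, max_parents: int) -> int:
    """Upper bound on edges a single learned network can contain."""
    return int(n_nodes_per_slice) * int(max_parents)


@dataclass
class NetworkSummary:
    n_edges: int
    n_inter: int
    n_intra: int
    n_negative: int

    @property
    def negative_percent(self) -> int:
        """Share of negative-coefficient edges, rounded down to a percent."""
        return int(math.floor(100 * self.n_negative / self.n_edges))


def summarize_network(edges: Iterable[Edge]) -> NetworkSummary:
    edges = list(edges)
    n_inter = sum(1 for e in edges if e.lag == "inter")
    n_neg = sum(1 for e in edges if e.coefficient < 0)
    return NetworkSummary(len(edges), n_inter, len(edges) - n_inter, n_neg)


def overlap_percent(edges_a: Iterable[Edge], edges_b: Iterable[Edge]) -> int:
    """Shared edges as a percentage of the first network, nearest integer."""
    keys_a = {e.key for e in edges_a}
    keys_b = {e.key for e in edges_b}
    if not keys_a:
        raise ValueError("empty first edge set")
    return int(round(100 * len(keys_a & keys_b) / len(keys_a)))
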