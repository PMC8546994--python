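"""Model evaluation: forward prediction with MAE and in-silico edge
validation against interaction databases with a Poisson-binomial null."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .constraints import ConstraintMatrix
from .core_io.types import SLICE_T, SLICE_T1, DBNModel, Edge, NodeRef
from .dbn import (GriddedSubject, ObservationTable, build_observations,
                  learn_structure)

log = logging.getLogger(__name__)

#: edge kinds understood by the validation databases
DB_KINDS = {"T_G": ("taxon", "gene"), "T_M": ("taxon", "metabolite")}


# ---------------------------------------------------------------------------
# Forward prediction


def _node_value(gs: GriddedSubject, node: NodeRef, grid_index: int) -> float:
    var = (node.kind, node.feature)
    if node.kind == "env" and node.feature == "week":
        return gs.times[grid_index] / 7.0
    if var in gs.dynamic:
        return float(gs.dynamic[var][grid_index])
    if var in gs.static:
        return gs.static[var]
    raise KeyError(f"subject {gs.subject} lacks a value for node {node}")


def predict_subject(model: DBNModel, subject: GriddedSubject,
                    target_kind: str = "taxon",
                    renormalize: bool = True
                    ) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Predict target-layer values at every grid time from the second on.

    Inter-parents take the subject's *observed* value at the previous
    grid time and intra-parents the observed value at the current one;
    previous predictions never feed later steps.  With ``renormalize``
    each predicted time point is scaled to sum to one.

    Returns (times, feature names, predictions) with one row per
    predicted time point.
    """
    targets = sorted(c for c in model.cpds if c.kind == target_kind)
    if not targets:
        raise ValueError(f"model has no {target_kind} children")
    n_steps = len(subject.times) - 1
    preds = np.zeros((n_steps, len(targets)))
    for i in range(n_steps):
        for j, child in enumerate(targets):
            cpd = model.cpds[child]
            total = cpd.beta0
            for parent, beta in zip(cpd.parents, cpd.betas):
                idx = i if parent.slice_ == SLICE_T else i + 1
                total += beta * _node_value(subject, parent, idx)
            preds[i, j] = total
    if renormalize:
        preds = np.maximum(preds, 0.0)
        sums = preds.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        preds = preds / sums
    return subject.times[1:], [c.feature for c in targets], preds


@dataclass
class PredictionReport:
    target_kind: str
    mae_per_feature: dict[str, float]
    mae_per_subject: dict[str, float]
    mae_overall: float
    predictions: dict[str, tuple[np.ndarray, list[str], np.ndarray]] = field(
        default_factory=dict)


def loocv_mae(subjects: Sequence[GriddedSubject],
              constraints: ConstraintMatrix, max_parents: int = 3,
              target_kind: str = "taxon", renormalize: bool = True,
              include_week: bool = True) -> PredictionReport:
    """Leave-one-subject-out forward prediction error.

    Each fold learns a single (non-bootstrap) structure on the
    remaining subjects, predicts the held-out subject and scores
    per-feature MAE over predicted time points; the overall MAE
    averages over features within a subject, then over subjects.
    """
    if len(subjects) < 3:
        raise ValueError("leave-one-out needs at least three subjects")
    per_subject: dict[str, float] = {}
    feature_errs: dict[str, list[float]] = {}
    predictions = {}
    for held in subjects:
        train = [gs for gs in subjects if gs.subject != held.subject]
        table = build_observations(train, include_week=include_week)
        model = learn_structure(table, constraints, max_parents=max_parents)
        times, features, preds = predict_subject(
            model, held, target_kind=target_kind, renormalize=renormalize)
        obs = np.column_stack([held.dynamic[(target_kind, f)][1:]
                               for f in features])
        errs = np.mean(np.abs(preds - obs), axis=0)
        for f, e in zip(features, errs):
            feature_errs.setdefault(f, []).append(float(e))
        per_subject[held.subject] = float(errs.mean())
        predictions[held.subject] = (times, features, preds)
    mae_per_feature = {f: float(np.mean(v)) for f, v in feature_errs.items()}
    overall = float(np.mean(list(per_subject.values())))
    return PredictionReport(target_kind, mae_per_feature, per_subject,
                            overall, predictions)


# ---------------------------------------------------------------------------
# In-silico edge validation


@dataclass
class ValidationDB:
    """Known (parent, child) interaction pairs of one typed kind."""

    kind: str                                  # T_G | T_M
    pairs: set[tuple[str, str]]
    parent_universe: set[str]
    child_universe: set[str]

    def __post_init__(self) -> None:
        if self.kind not in DB_KINDS:
            raise ValueError(f"unknown validation db kind {self.kind!r}")
        for p, c in self.pairs:
            if p not in self.parent_universe or c not in self.child_universe:
                raise ValueError(f"pair ({p}, {c}) outside the db universes")

    def covers(self, parent_feature: str, child_feature: str) -> bool:
        return (parent_feature in self.parent_universe
                and child_feature in self.child_universe)


def load_validation_db(path, kind: str) -> ValidationDB:
    """Read a two-column TSV of (parent_feature, child_feature) pairs."""
    import pandas as pd
    tab = pd.read_csv(path, sep="\t", dtype=str)
    pairs = {(p, c) for p, c in zip(tab["parent_feature"],
                                    tab["child_feature"])}
    return ValidationDB(kind, pairs, {p for p, _ in pairs},
                        {c for _, c in pairs})


def poisson_binomial_tail(probabilities: Sequence[float], k: int) -> float:
    """Exact P(X >= k) for X a sum of independent Bernoulli(p_i).

    Uses the O(n^2) convolution recursion; no normal approximation.
    """
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    n = len(p)
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    pmf = np.zeros(n + 1)
    pmf[0] = 1.0
    for i, pi in enumerate(p):
        pmf[1:i + 2] = pmf[1:i + 2] * (1 - pi) + pmf[:i + 1] * pi
        pmf[0] *= 1 - pi
    return float(pmf[k:].sum())


def edge_chance_probability(child_feature: str, db: ValidationDB) -> float:
    """Chance of a random in-universe parent validating for this child.

    The child's validated in-degree over the parent universe, capturing
    that promiscuous metabolites/genes validate against most taxa.
    """
    if child_feature not in db.child_universe:
        raise ValueError(f"child {child_feature!r} not in the db universe")
    indeg = sum(1 for _, c in db.pairs if c == child_feature)
    return indeg / len(db.parent_universe)


@dataclass
class ThresholdRow:
    threshold: float
    n_evaluable: int
    n_validated: int
    precision: float | None
    pb_tail: float | None


@dataclass
class ValidationReport:
    kind: str
    rows: list[ThresholdRow]
    random_precision_mean: float | None = None
    random_pb_mean: float | None = None


def _evaluable(edges: Iterable[Edge], db: ValidationDB,
               threshold: float) -> list[Edge]:
    pk, ck = DB_KINDS[db.kind]
    return [e for e in edges
            if e.parent.kind == pk and e.child.kind == ck
            and e.bootstrap_support > threshold
            and db.covers(e.parent.feature, e.child.feature)]


def validate_edges(edges: Iterable[Edge], db: ValidationDB,
                   thresholds: Sequence[float] = tuple(i / 10 for i in range(10))
                   ) -> ValidationReport:
    """Precision and Poisson-binomial tail across bootstrap thresholds.

    An edge is evaluable at threshold theta when its kind matches the
    database, support > theta and both endpoints are in the database
    universes; edges touching unknown features are ignored.
    """
    edges = list(edges)
    rows = []
    for theta in thresholds:
        ev = _evaluable(edges, db, theta)
        n_val = sum(1 for e in ev
                    if (e.parent.feature, e.child.feature) in db.pairs)
        if ev:
            precision = n_val / len(ev)
            probs = [edge_chance_probability(e.child.feature, db) for e in ev]
            pb = poisson_binomial_tail(probs, n_val)
        else:
            precision = pb = None
        rows.append(ThresholdRow(theta, len(ev), n_val, precision, pb))
    return ValidationReport(db.kind, rows)


def allowed_edge_list(nodes: Iterable[NodeRef],
                      constraints: ConstraintMatrix) -> list[Edge]:
    """Every constraint-valid (parent, child, lag) edge over a node set."""
    nodes = sorted(set(nodes))
    by_slice = {SLICE_T: [n for n in nodes if n.slice_ == SLICE_T],
                SLICE_T1: [n for n in nodes if n.slice_ == SLICE_T1]}
    out = []
    for child in by_slice[SLICE_T1]:
        for lag in ("intra", "inter"):
            for parent in by_slice[SLICE_T1 if lag == "intra" else SLICE_T]:
                if parent == child:
                    continue
                if constraints.is_allowed(parent, child, lag):
                    out.append(Edge(parent, child, lag))
    return out


def random_network_null(edges: Iterable[Edge], allowed: Sequence[Edge],
                        db: ValidationDB, n_random: int = 1000,
                        seed: int = 0) -> dict[str, float | None]:
    """Average precision/tail of size-matched random networks.

    Each run draws, without within-run duplicates, as many edges as the
    learned network holds, uniformly from the constraint-allowed list,
    and scores them against the database exactly like the real network.
    """
    edges = list(edges)
    if not allowed:
        raise ValueError("empty allowed-edge list")
    if len(edges) > len(allowed):
        raise ValueError("network has more edges than allowed pairs")
    rng = np.random.default_rng(seed)
    precisions, tails = [], []
    for _ in range(n_random):
        idx = rng.choice(len(allowed), size=len(edges), replace=False)
        drawn = [allowed[i] for i in idx]
        ev = _evaluable(drawn, db, threshold=-1.0)
        if not ev:
            continue
        n_val = sum(1 for e in ev
                    if (e.parent.feature, e.child.feature) in db.pairs)
        precisions.append(n_val / len(ev))
        probs = [edge_chance_probability(e.child.feature, db) for e in ev]
        tails.append(poisson_binomial_tail(probs, n_val))
    return {
        "precision_mean": float(np.mean(precisions)) if precisions else None,
        "pb_mean": float(np.mean(tails)) if tails else None,
        "n_runs_scored": len(precisions),
    }


def rank_mt_edges(edges: Iterable[Edge]) -> list[tuple[Edge, float]]:
    """Metabolite-to-taxon edges by confidence = |weight| * support."""
    mt = [e for e in edges
          if e.parent.kind == "metabolite" and e.child.kind == "taxon"]
    scored = [(e, abs(e.normalized_weight) * e.bootstrap_support) for e in mt]
    return sorted(scored, key=lambda pair: (-pair[1], pair[0].key))
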