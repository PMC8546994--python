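"""Domain types shared across the pipeline.

The dataset model distinguishes *dynamic* layers (taxa, microbial genes,
metabolites: per-subject time series) from *static* layers (host genes:
one vector per subject) and environmental variables (per-sample scalars,
stored as a dynamic layer of kind ``env``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

NODE_KINDS = ("taxon", "gene", "metabolite", "host_gene", "env")
#: node kinds that may never appear as a child of a learned CPD
STATIC_KINDS = ("host_gene", "env")
SLICE_T = "t"
SLICE_T1 = "t1"


@dataclass(frozen=True, order=True)
class NodeRef:
    """A typed node in one slice of the two-slice network."""

    kind: str
    feature: str
    slice_: str = SLICE_T1

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")
        if self.slice_ not in (SLICE_T, SLICE_T1):
            raise ValueError(f"unknown slice {self.slice_!r}")

    def at(self, slice_: str) -> "NodeRef":
        return NodeRef(self.kind, self.feature, slice_)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.kind}:{self.feature}@{self.slice_}"


@dataclass(frozen=True)
class Edge:
    """Directed dependency between two nodes.

    ``lag`` is ``intra`` when both endpoints sit in the same slice and
    ``inter`` when the parent is at slice t and the child at slice t+1.
    """

    parent: NodeRef
    child: NodeRef
    lag: str
    coefficient: float = math.nan
    normalized_weight: float = math.nan
    bootstrap_support: float = 1.0

    def __post_init__(self) -> None:
        if self.lag not in ("intra", "inter"):
            raise ValueError(f"unknown lag {self.lag!r}")
        if self.lag == "intra" and self.parent.slice_ != self.child.slice_:
            raise ValueError("intra edge endpoints must share a slice")
        if self.lag == "inter" and not (
            self.parent.slice_ == SLICE_T and self.child.slice_ == SLICE_T1
        ):
            raise ValueError("inter edge must run from slice t to slice t+1")
        if not (0.0 <= self.bootstrap_support <= 1.0):
            raise ValueError("bootstrap support must lie in [0, 1]")

    @property
    def key(self) -> tuple:
        """Identity of the edge irrespective of fitted values."""
        return (self.parent.kind, self.parent.feature, self.child.kind,
                self.child.feature, self.lag)


@dataclass
class GaussianCPD:
    """Linear-Gaussian conditional density of a child given its parents."""

    child: NodeRef
    parents: list[NodeRef]
    beta0: float
    betas: np.ndarray
    sigma2: float

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if len(self.betas) != len(self.parents):
            raise ValueError("one coefficient per parent required")
        if self.sigma2 <= 0:
            raise ValueError("residual variance must be positive")

    def mean(self, parent_values: np.ndarray) -> np.ndarray:
        parent_values = np.atleast_2d(np.asarray(parent_values, dtype=float))
        return self.beta0 + parent_values @ self.betas


@dataclass
class DBNModel:
    """Two-slice network: node set, edge set and per-child CPDs."""

    nodes: set[NodeRef]
    edges: list[Edge]
    cpds: dict[NodeRef, GaussianCPD] = field(default_factory=dict)
    constraints_id: str = "custom"

    def parents_of(self, child: NodeRef) -> list[NodeRef]:
        return [e.parent for e in self.edges if e.child == child]

    def edge_keys(self) -> set[tuple]:
        return {e.key for e in self.edges}

    def validate(self, max_parents: int | None = None) -> None:
        for child, cpd in self.cpds.items():
            if sorted(cpd.parents) != sorted(self.parents_of(child)):
                raise ValueError(f"CPD parents out of sync for {child}")
        if max_parents is not None:
            counts: dict[NodeRef, int] = {}
            for e in self.edges:
                counts[e.child] = counts.get(e.child, 0) + 1
            for child, k in counts.items():
                if k > max_parents:
                    raise ValueError(f"{child} exceeds parent cap {max_parents}")


@dataclass
class DynamicSeries:
    """Observations of one subject in one dynamic layer."""

    times: np.ndarray            # shape (T,), strictly increasing, days
    values: np.ndarray           # shape (T, F)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 2:
            raise ValueError("times must be 1-D and values 2-D")
        if len(self.times) != self.values.shape[0]:
            raise ValueError("one row of values per time point")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.times)):
            raise ValueError("non-finite time")


@dataclass
class Layer:
    """One omic layer of a dataset."""

    name: str
    node_kind: str
    dynamic: bool
    features: list[str]
    #: subject -> DynamicSeries (dynamic) or subject -> vector (static)
    data: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.node_kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {self.node_kind!r}")
        if len(set(self.features)) != len(self.features):
            raise ValueError(f"duplicate feature names in layer {self.name}")

    def n_timepoints(self, subject: str) -> int:
        if not self.dynamic:
            raise ValueError("static layers have no time points")
        return len(self.data[subject].times)


@dataclass
class OmicsDataset:
    """Longitudinal multi-omics dataset grouped by subject."""

    subjects: list[str]
    layers: dict[str, Layer]
    time_unit: str = "days"

    def __post_init__(self) -> None:
        self.check()

    def check(self) -> None:
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("duplicate subject ids")
        for layer in self.layers.values():
            for subject, obs in layer.data.items():
                if subject not in self.subjects:
                    raise ValueError(
                        f"layer {layer.name} references unknown subject {subject}")
                arr = obs.values if layer.dynamic else np.asarray(obs)
                if not np.all(np.isfinite(arr)):
                    raise ValueError(
                        f"non-finite value in layer {layer.name}, subject {subject}")

    def dynamic_layers(self) -> dict[str, Layer]:
        return {n: l for n, l in self.layers.items() if l.dynamic}

    def static_layers(self) -> dict[str, Layer]:
        return {n: l for n, l in self.layers.items() if not l.dynamic}

    def copy(self) -> "OmicsDataset":
        layers = {}
        for name, layer in self.layers.items():
            data = {}
            for subject, obs in layer.data.items():
                if layer.dynamic:
                    data[subject] = DynamicSeries(obs.times.copy(),
                                                  obs.values.copy())
                else:
                    data[subject] = np.asarray(obs, dtype=float).copy()
            layers[name] = Layer(layer.name, layer.node_kind, layer.dynamic,
                                 list(layer.features), data)
        return OmicsDataset(list(self.subjects), layers, self.time_unit)

    def drop_subjects(self, to_drop: Iterable[str]) -> "OmicsDataset":
        to_drop = set(to_drop)
        out = self.copy()
        out.subjects = [s for s in out.subjects if s not in to_drop]
        for layer in out.layers.values():
            layer.data = {s: v for s, v in layer.data.items()
                          if s not in to_drop}
        return out
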