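"""Constraint matrices restricting which typed edges the search may add.

A cell is (parent_kind, child_kind, lag, scope) where scope ``all``
admits any feature pair and scope ``self`` admits only same-feature
self-loops.  The Skeleton preset encodes the causal flow environment /
host genes -> taxa -> genes -> metabolites -> (next-slice) taxa, plus
inter-slice self-loops for every dynamic node.  Augmented additionally
allows direct taxon -> metabolite edges.  Environmental and host-gene
nodes never receive edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .core_io.types import SLICE_T, SLICE_T1, NodeRef

Cell = tuple[str, str, str, str]          # parent_kind, child_kind, lag, scope

_FORBIDDEN_CHILDREN = ("env", "host_gene")

_SKELETON: frozenset[Cell] = frozenset({
    ("env", "taxon", "intra", "all"),
    ("host_gene", "taxon", "intra", "all"),
    ("taxon", "gene", "intra", "all"),
    ("gene", "metabolite", "intra", "all"),
    ("metabolite", "taxon", "inter", "all"),
    ("taxon", "taxon", "inter", "self"),
    ("gene", "gene", "inter", "self"),
    ("metabolite", "metabolite", "inter", "self"),
})


@dataclass(frozen=True)
class ConstraintMatrix:
    allowed: frozenset[Cell]
    name: str = "custom"

    def __post_init__(self) -> None:
        for parent_kind, child_kind, lag, scope in self.allowed:
            if child_kind in _FORBIDDEN_CHILDREN:
                raise ValueError(
                    f"{child_kind} nodes cannot receive edges")
            if lag not in ("intra", "inter") or scope not in ("all", "self"):
                raise ValueError(
                    f"bad cell ({parent_kind}, {child_kind}, {lag}, {scope})")

    def is_allowed(self, parent: NodeRef, child: NodeRef, lag: str) -> bool:
        if child.kind in _FORBIDDEN_CHILDREN or child.slice_ != SLICE_T1:
            return False
        expected = SLICE_T if lag == "inter" else SLICE_T1
        if parent.slice_ != expected:
            return False
        if (parent.kind, child.kind, lag, "all") in self.allowed:
            return True
        if ((parent.kind, child.kind, lag, "self") in self.allowed
                and parent.feature == child.feature):
            return True
        return False

    def issubset(self, other: "ConstraintMatrix") -> bool:
        return self.allowed <= other.allowed

    def to_file(self, path: str | Path) -> None:
        tree: dict[str, dict[str, list[str]]] = {}
        for parent_kind, child_kind, lag, scope in sorted(self.allowed):
            tag = lag if scope == "all" else f"{lag}:self"
            tree.setdefault(parent_kind, {}).setdefault(child_kind, []).append(tag)
        Path(path).write_text(json.dumps({"name": self.name, "cells": tree},
                                         indent=2, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "ConstraintMatrix":
        obj = json.loads(Path(path).read_text())
        cells = set()
        for parent_kind, children in obj["cells"].items():
            for child_kind, tags in children.items():
                for tag in tags:
                    lag, _, scope = tag.partition(":")
                    cells.add((parent_kind, child_kind, lag, scope or "all"))
        return cls(frozenset(cells), obj.get("name", "custom"))


def skeleton_constraints() -> ConstraintMatrix:
    return ConstraintMatrix(_SKELETON, "skeleton")


def augmented_constraints(tm_intra: bool = True,
                          tm_inter: bool = True) -> ConstraintMatrix:
    cells = set(_SKELETON)
    if tm_intra:
        cells.add(("taxon", "metabolite", "intra", "all"))
    if tm_inter:
        cells.add(("taxon", "metabolite", "inter", "all"))
    return ConstraintMatrix(frozenset(cells), "augmented")


def get_preset(name: str, tm_intra: bool = True,
               tm_inter: bool = True) -> ConstraintMatrix:
    if name == "skeleton":
        return skeleton_constraints()
    if name == "augmented":
        return augmented_constraints(tm_intra, tm_inter)
    raise ValueError(f"unknown constraint preset {name!r}")
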