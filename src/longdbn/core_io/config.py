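"""Flat dotted-key configuration with strict unknown-key rejection."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import yaml

log = logging.getLogger(__name__)

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "out_dir": "longdbn_out",
    "normalization.mode": "relative",          # relative | alr
    "normalization.reference_feature": None,
    "filters.metabolite_min_mean": 0.001,
    "filters.min_timepoints": 5,
    "selection.top_k_per_layer": 20,
    "spline.smoothing": "gcv",                 # gcv | interpolate
    "resample.rate_days": 14.0,
    "resample.origin": None,
    "alignment.layer": "genes",
    "alignment.n_features": 10,
    "alignment.a_min": 0.5,
    "alignment.a_max": 2.0,
    "alignment.a_step": 0.05,
    "alignment.b_min": -30.0,
    "alignment.b_max": 30.0,
    "alignment.b_step": 1.0,
    "alignment.min_overlap_frac": 0.5,
    "alignment.refine": True,
    "dbn.constraints": "skeleton",             # skeleton | augmented | custom
    "dbn.max_parents": 3,
    "dbn.bootstrap_reps": 100,
    "dbn.augmented_tm_intra": True,
    "dbn.augmented_tm_inter": True,
    "dbn.env_week": True,
    "evaluate.thresholds": [i / 10 for i in range(10)],
    "evaluate.n_random": 1000,
    "evaluate.loocv_bootstrap": False,
}


def _flatten(tree: Mapping[str, Any], prefix: str = "") -> dict[str, Any]:
    flat: dict[str, Any] = {}
    for key, value in tree.items():
        dotted = f"{prefix}{key}"
        if isinstance(value, Mapping):
            flat.update(_flatten(value, f"{dotted}."))
        else:
            flat[dotted] = value
    return flat


class Config:
    """Effective configuration: defaults overlaid with user values."""

    def __init__(self, overrides: Mapping[str, Any] | None = None) -> None:
        self._values = dict(DEFAULTS)
        if overrides:
            flat = _flatten(overrides)
            unknown = set(flat) - set(DEFAULTS)
            if unknown:
                raise KeyError(f"unknown config keys: {sorted(unknown)}")
            self._values.update(flat)

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        path = Path(path)
        text = path.read_text()
        tree = (json.loads(text) if path.suffix == ".json"
                else yaml.safe_load(text)) or {}
        return cls(tree)

    def __getitem__(self, key: str) -> Any:
        return self._values[key]

    def get(self, key: str, default: Any = None) -> Any:
        return self._values.get(key, default)

    def as_dict(self) -> dict[str, Any]:
        return dict(self._values)

    def log_effective(self, logger: logging.Logger = log) -> None:
        for key in sorted(self._values):
            logger.info("config %s = %r", key, self._values[key])

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self._values, indent=2, sort_keys=True))
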