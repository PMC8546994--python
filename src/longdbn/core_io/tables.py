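"""Readers and writers for the tabular exchange formats.

Layer TSV: first column ``feature_id``, remaining columns sample ids,
values nonnegative reals (empty cell = missing, zero = observed zero).
Static layers (host genes) use subject ids as columns instead of sample
ids.  Metadata TSV: columns ``sample_id``, ``subject_id`` and either
``time`` (days) or ``week`` (converted as week*7).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .types import DynamicSeries, Layer, OmicsDataset

log = logging.getLogger(__name__)

#: %.12g keeps round trips lossless at 12 significant digits
_FLOAT_FMT = "%.12g"


class DataFormatError(ValueError):
    """Raised for malformed input tables; message names file and row."""


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str,
                                              "subject_id": str})
    for col in ("sample_id", "subject_id"):
        if col not in meta.columns:
            raise DataFormatError(f"{path}: missing metadata column {col!r}")
    if "time" not in meta.columns:
        if "week" in meta.columns:
            meta["time"] = meta["week"].astype(float) * 7.0
        else:
            raise DataFormatError(
                f"{path}: missing metadata column 'time' (or 'week')")
    meta["time"] = meta["time"].astype(float)
    dup = meta["sample_id"].duplicated()
    if dup.any():
        raise DataFormatError(
            f"{path}: duplicate sample_id {meta['sample_id'][dup].iloc[0]!r}")
    return meta


def read_dataset(
    layer_paths: Mapping[str, str | Path],
    metadata_path: str | Path,
    layer_kinds: Mapping[str, str],
    allow_negative: bool = False,
) -> OmicsDataset:
    """Load layer TSVs plus metadata into an :class:`OmicsDataset`.

    ``layer_kinds`` maps layer name to node kind; ``host_gene`` layers
    are read as static (subject-keyed) tables.  ``allow_negative``
    admits already-transformed (e.g. log-ratio) values.
    """
    meta = read_metadata(metadata_path)
    subjects = sorted(meta["subject_id"].unique())
    sample_subject = dict(zip(meta["sample_id"], meta["subject_id"]))
    sample_time = dict(zip(meta["sample_id"], meta["time"]))

    layers: dict[str, Layer] = {}
    for name, path in layer_paths.items():
        kind = layer_kinds[name]
        tab = pd.read_csv(path, sep="\t", index_col=0)
        tab.index = tab.index.astype(str)
        tab.columns = tab.columns.astype(str)
        if tab.index.duplicated().any():
            raise DataFormatError(f"{path}: duplicate feature id "
                                  f"{tab.index[tab.index.duplicated()][0]!r}")
        if not allow_negative and kind != "host_gene":
            vals = tab.to_numpy(dtype=float)
            bad = np.argwhere(np.nan_to_num(vals) < 0)
            if bad.size:
                i, j = bad[0]
                raise DataFormatError(
                    f"{path}: negative abundance at feature "
                    f"{tab.index[i]!r}, column {tab.columns[j]!r}")
        features = list(tab.index)
        if kind == "host_gene":
            data = {}
            for subj in tab.columns:
                if subj not in subjects:
                    raise DataFormatError(
                        f"{path}: column {subj!r} is not a known subject")
                data[subj] = tab[subj].to_numpy(dtype=float)
            layers[name] = Layer(name, kind, False, features, data)
            continue
        per_subject: dict[str, list[tuple[float, np.ndarray]]] = {}
        seen: set[tuple[str, float]] = set()
        for sample in tab.columns:
            if sample not in sample_subject:
                raise DataFormatError(
                    f"{path}: sample {sample!r} absent from metadata")
            subj, t = sample_subject[sample], sample_time[sample]
            if (subj, t) in seen:
                raise DataFormatError(
                    f"{path}: duplicate (subject={subj}, time={t}) sample "
                    f"{sample!r}")
            seen.add((subj, t))
            col = tab[sample].to_numpy(dtype=float)
            per_subject.setdefault(subj, []).append((t, col))
        data = {}
        for subj, obs in per_subject.items():
            obs.sort(key=lambda p: p[0])
            times = np.array([t for t, _ in obs])
            values = np.vstack([v for _, v in obs])
            data[subj] = DynamicSeries(times, values)
        layers[name] = Layer(name, kind, True, features, data)
    return OmicsDataset(subjects, layers)


def write_dataset(dataset: OmicsDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write canonical TSVs (sorted subjects/times) under ``out_dir``.

    Identical datasets serialize byte-identically.  Returns the paths
    written, keyed by layer name plus ``"metadata"``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects = sorted(dataset.subjects)

    # one canonical sample id per (subject, time) across dynamic layers
    sample_ids: dict[tuple[str, float], str] = {}
    rows = []
    for subj in subjects:
        times = sorted({t for layer in dataset.dynamic_layers().values()
                        if subj in layer.data
                        for t in layer.data[subj].times})
        for i, t in enumerate(times):
            sid = f"{subj}.s{i:03d}"
            sample_ids[(subj, t)] = sid
            rows.append((sid, subj, t))
    meta = pd.DataFrame(rows, columns=["sample_id", "subject_id", "time"])

    paths: dict[str, Path] = {}
    meta_path = out_dir / "metadata.tsv"
    meta.to_csv(meta_path, sep="\t", index=False, float_format=_FLOAT_FMT)
    paths["metadata"] = meta_path

    for name in sorted(dataset.layers):
        layer = dataset.layers[name]
        path = out_dir / f"{name}.tsv"
        if layer.dynamic:
            cols, colnames = [], []
            for subj in subjects:
                if subj not in layer.data:
                    continue
                obs = layer.data[subj]
                for t, row in zip(obs.times, obs.values):
                    colnames.append(sample_ids[(subj, float(t))])
                    cols.append(row)
            tab = pd.DataFrame(np.array(cols).T if cols else
                               np.empty((len(layer.features), 0)),
                               index=layer.features, columns=colnames)
        else:
            cols = {s: layer.data[s] for s in subjects if s in layer.data}
            tab = pd.DataFrame(cols, index=layer.features)
        tab.index.name = "feature_id"
        tab.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
        paths[name] = path
    return paths
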