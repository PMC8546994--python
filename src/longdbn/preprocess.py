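"""Normalization and filtering of longitudinal multi-omics layers.

Pipeline order is fixed: relative normalization -> metabolite filter ->
subject filter -> top-variance selection -> optional log-ratio
transform of the taxon layer.
"""

from __future__ import annotations

import logging

import numpy as np

from .core_io import Config, DynamicSeries, OmicsDataset

log = logging.getLogger(__name__)


def normalize_relative(dataset: OmicsDataset,
                       layer_names: list[str] | None = None) -> OmicsDataset:
    """Scale every sample of every dynamic layer to sum to one.

    Zeros are preserved; an all-zero sample is an error.  Idempotent.
    """
    out = dataset.copy()
    for name, layer in out.dynamic_layers().items():
        if layer.node_kind == "env":
            continue
        if layer_names is not None and name not in layer_names:
            continue
        for subject, obs in layer.data.items():
            sums = obs.values.sum(axis=1)
            zero = np.where(sums <= 0)[0]
            if zero.size:
                raise ValueError(
                    f"all-zero sample in layer {name}: subject {subject}, "
                    f"time {obs.times[zero[0]]}")
            obs.values /= sums[:, None]
    return out


def _pseudocount(layer_values: list[np.ndarray]) -> float:
    # half the smallest nonzero value pooled over the layer
    pooled = np.concatenate([v.ravel() for v in layer_values])
    nonzero = pooled[pooled > 0]
    if nonzero.size == 0:
        raise ValueError("layer has no positive values")
    return float(nonzero.min()) / 2.0


def normalize_alr(dataset: OmicsDataset, reference_feature: str,
                  layer_name: str = "taxa") -> OmicsDataset:
    """Additive log-ratio transform of a layer against a reference feature.

    Each value becomes log(x / x_ref) within its sample; the reference
    feature's transformed trajectory is identically zero.  Zeros are
    replaced by a pseudocount (half the smallest nonzero value of the
    layer) before taking logs, keeping all outputs finite.
    """
    out = dataset.copy()
    layer = out.layers[layer_name]
    if reference_feature not in layer.features:
        raise ValueError(f"reference feature {reference_feature!r} absent "
                         f"from layer {layer_name!r}")
    ref_idx = layer.features.index(reference_feature)
    pc = _pseudocount([obs.values for obs in layer.data.values()])
    for subject, obs in layer.data.items():
        vals = np.where(obs.values > 0, obs.values, pc)
        obs.values = np.log(vals / vals[:, [ref_idx]])
    return out


def filter_metabolites(dataset: OmicsDataset, min_mean: float = 0.001,
                       layer_name: str = "metabolites") -> OmicsDataset:
    """Drop metabolites with pooled mean < ``min_mean`` or zero variance.

    Statistics pool all originally sampled time points across subjects;
    the layer is expected to be relative-normalized so the default
    threshold reads as 0.1% of a sample.
    """
    out = dataset.copy()
    layer = out.layers[layer_name]
    pooled = np.vstack([obs.values for obs in layer.data.values()])
    means = pooled.mean(axis=0)
    variances = pooled.var(axis=0)
    keep = (means >= min_mean) & (variances > 0)
    for feat, m, v, k in zip(layer.features, means, variances, keep):
        if not k:
            log.info("dropping metabolite %s (mean=%.3g, var=%.3g)",
                     feat, m, v)
    if not keep.any():
        log.warning("metabolite filter removed every feature")
    layer.features = [f for f, k in zip(layer.features, keep) if k]
    for obs in layer.data.values():
        obs.values = obs.values[:, keep]
    return out


def filter_subjects(dataset: OmicsDataset,
                    min_timepoints: int = 5) -> OmicsDataset:
    """Keep subjects with >= ``min_timepoints`` samples in *every* dynamic layer."""
    drop = set()
    for name, layer in dataset.dynamic_layers().items():
        if layer.node_kind == "env":
            continue
        for subject in dataset.subjects:
            n = (layer.n_timepoints(subject) if subject in layer.data else 0)
            if n < min_timepoints:
                log.info("dropping subject %s: %d time points in layer %s",
                         subject, n, name)
                drop.add(subject)
    out = dataset.drop_subjects(drop)
    if not out.subjects:
        raise ValueError("subject filter removed every subject")
    return out


def select_top_variance(dataset: OmicsDataset, layer_name: str,
                        k: int = 20) -> OmicsDataset:
    """Reduce a layer to its k highest-variance features.

    Variance pools all subjects' samples; ties break lexicographically
    by feature name so the selection is deterministic.
    """
    out = dataset.copy()
    layer = out.layers[layer_name]
    if k > len(layer.features):
        raise ValueError(f"k={k} exceeds {len(layer.features)} features in "
                         f"layer {layer_name!r}")
    if layer.dynamic:
        pooled = np.vstack([obs.values for obs in layer.data.values()])
    else:
        pooled = np.vstack([layer.data[s] for s in sorted(layer.data)])
    variances = pooled.var(axis=0)
    order = sorted(range(len(layer.features)),
                   key=lambda i: (-variances[i], layer.features[i]))
    chosen = sorted(order[:k])
    layer.features = [layer.features[i] for i in chosen]
    for subject in layer.data:
        if layer.dynamic:
            layer.data[subject].values = layer.data[subject].values[:, chosen]
        else:
            layer.data[subject] = layer.data[subject][chosen]
    return out


def run_preprocess(dataset: OmicsDataset, config: Config) -> OmicsDataset:
    """Apply the documented pipeline order with config-driven parameters."""
    ds = normalize_relative(dataset)
    if "metabolites" in ds.layers:
        ds = filter_metabolites(ds, config["filters.metabolite_min_mean"])
    ds = filter_subjects(ds, config["filters.min_timepoints"])
    for name, layer in list(ds.layers.items()):
        if layer.node_kind == "host_gene":
            k = min(config["selection.top_k_per_layer"], len(layer.features))
            ds = select_top_variance(ds, name, k)
    if config["normalization.mode"] == "alr":
        ds = normalize_alr(ds, config["normalization.reference_feature"])
    return ds
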