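"""Experiment orchestration: the method-comparison benchmark, the alignment
impact experiment, epoch/learning-rate sweeps, and run-to-run variability
analyses.

The benchmark pipeline for every (dataset, method, seed) row is: align the
spikes to the middle of the window, min-max scale the whole set into [0, 1],
shuffle, extract features, run K-Means at k = number of ground-truth clusters
(synthetic) or a configured k, and score with the six metrics (internal
metrics on the ground-truth labels when they exist). Ground-truth labels
never touch feature extraction or clustering — only metric computation and
the choice of k.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import ica_embed, isomap_embed, pca_embed
from .cluster_eval import (
    METRIC_DIRECTIONS,
    borda_aggregate,
    kmeans_labels,
    metric_report,
)
from .datasets import LabeledSpikeSet, SimulationSpec, generate_labeled_spikes
from .models import VARIANTS, SpikeAutoencoder, variant_config
from .preprocessing import AlignmentSpec, align_spikes, scale_unit_interval, shuffle_spikes

logger = logging.getLogger(__name__)

__all__ = [
    "BenchmarkTable",
    "extract_features",
    "preprocess",
    "run_benchmark",
    "alignment_experiment",
    "hyperparameter_sweep",
    "variability_analysis",
    "METHODS",
]

METHODS = ("pca", "ica", "isomap") + VARIANTS

METRIC_COLS = ["ari", "ami", "vm", "dbs", "chs", "ss"]


@dataclass
class BenchmarkTable:
    """Per-(dataset, method, seed) metric rows plus Borda aggregation."""

    rows: pd.DataFrame
    loss_histories: dict = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        """Borda ranking over the per-method mean of each metric."""
        means = self.rows.groupby("method")[METRIC_COLS].mean()
        return borda_aggregate(means, METRIC_DIRECTIONS)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def preprocess(
    spikes: LabeledSpikeSet,
    align: bool = True,
    shuffle_seed: int | None = 0,
    alignment: AlignmentSpec | None = None,
) -> LabeledSpikeSet:
    """align -> scale to [0, 1] -> shuffle (the standard pipeline order)."""
    out = spikes
    if align:
        out = align_spikes(out, alignment or AlignmentSpec())
    out = scale_unit_interval(out)
    if shuffle_seed is not None:
        out = shuffle_spikes(out, shuffle_seed)
    return out


def extract_features(
    spikes: LabeledSpikeSet,
    method: str,
    seed: int = 0,
    epochs: int | None = None,
    learning_rate: float | None = None,
    n_neighbors: int = 30,
    collect_loss: dict | None = None,
    **overrides,
):
    """Run one registered feature-extraction method on preprocessed spikes."""
    if method == "pca":
        return pca_embed(spikes)
    if method == "ica":
        return ica_embed(spikes, seed=seed)
    if method == "isomap":
        return isomap_embed(spikes, n_neighbors=n_neighbors)
    if method not in VARIANTS:
        raise ValueError(f"unknown method {method!r}; registered: {METHODS}")
    kw = dict(overrides)
    if epochs is not None:
        kw["epochs"] = epochs
    if learning_rate is not None:
        kw["learning_rate"] = learning_rate
    cfg = variant_config(method, input_dim=spikes.n_samples, **kw)
    res = SpikeAutoencoder(spikes, cfg).fit(seed=seed)
    if collect_loss is not None:
        collect_loss[(method, seed)] = list(res.loss_history)
    return res.features(spikes)


def _evaluate_row(spikes, feats, seed: int, k: int | None):
    ok = np.all(np.isfinite(feats.features), axis=1)
    X = feats.features[ok]
    labels = spikes.labels[ok] if spikes.labels is not None else None
    if k is None:
        if labels is None:
            raise ValueError("k must be given for unlabeled data")
        k = len(np.unique(labels))
    from .models import FeatureSet

    res = kmeans_labels(FeatureSet(X, feats.method_tag), k=k, seed=seed)
    rep = metric_report(res.features, res.labels, true_labels=labels)
    return rep


def run_benchmark(
    datasets: dict,
    methods: list,
    seeds: list | None = None,
    epochs: int = 50,
    k: int | None = None,
    align: bool = True,
    **extract_kw,
) -> BenchmarkTable:
    """Full pipeline for every (dataset, method, seed) combination.

    ``datasets`` maps a name to a :class:`LabeledSpikeSet` or a
    :class:`SimulationSpec` (generated on the fly with the row seed).
    Failures are recorded per row and the run continues.
    """
    seeds = seeds or [0]
    rows = []
    losses: dict = {}
    for ds_name, ds in datasets.items():
        for seed in seeds:
            if isinstance(ds, SimulationSpec):
                raw = generate_labeled_spikes(ds, seed=seed)
            else:
                raw = ds
            sp = preprocess(raw, align=align, shuffle_seed=seed)
            for method in methods:
                t0 = time.perf_counter()
                row = {"dataset": ds_name, "method": method, "seed": seed}
                try:
                    feats = extract_features(
                        sp, method, seed=seed, epochs=epochs,
                        collect_loss=losses, **extract_kw,
                    )
                    rep = _evaluate_row(sp, feats, seed, k)
                    row.update(rep.as_dict())
                    row["error"] = ""
                except Exception as exc:  # recorded, run continues
                    logger.error("%s/%s/seed=%d failed: %s", ds_name, method, seed, exc)
                    row.update({m: np.nan for m in METRIC_COLS})
                    row["error"] = str(exc)
                row["runtime_s"] = time.perf_counter() - t0
                rows.append(row)
    return BenchmarkTable(rows=pd.DataFrame(rows), loss_histories=losses)


def alignment_experiment(
    dataset: LabeledSpikeSet | SimulationSpec,
    method: str,
    align_specs: list,
    seeds: list,
    epochs: int = 50,
) -> BenchmarkTable:
    """Identical pipeline once per alignment spec (None = no alignment)."""
    if isinstance(dataset, LabeledSpikeSet) and dataset.labels is None:
        raise ValueError("alignment experiment needs a labeled dataset")
    rows = []
    for seed in seeds:
        raw = (
            generate_labeled_spikes(dataset, seed=seed)
            if isinstance(dataset, SimulationSpec)
            else dataset
        )
        for spec in align_specs:
            name = "unaligned" if spec is None else (
                f"align@{spec.index_align if spec.index_align is not None else 'mid'}"
            )
            sp = preprocess(raw, align=spec is not None, alignment=spec, shuffle_seed=seed)
            feats = extract_features(sp, method, seed=seed, epochs=epochs)
            rep = _evaluate_row(sp, feats, seed, None)
            rows.append(
                {"alignment": name, "method": method, "seed": seed, **rep.as_dict()}
            )
    return BenchmarkTable(rows=pd.DataFrame(rows))


def hyperparameter_sweep(
    dataset: LabeledSpikeSet | SimulationSpec,
    variant: str,
    axis: str,
    values: list,
    seeds: list,
    epochs: int = 50,
) -> BenchmarkTable:
    """Sweep epochs or learning rate for one variant, tabulating all metrics."""
    if axis not in ("epochs", "learning_rate"):
        raise ValueError("axis must be 'epochs' or 'learning_rate'")
    if not values:
        raise ValueError("values must be non-empty")
    rows = []
    losses: dict = {}
    for seed in seeds:
        raw = (
            generate_labeled_spikes(dataset, seed=seed)
            if isinstance(dataset, SimulationSpec)
            else dataset
        )
        sp = preprocess(raw, shuffle_seed=seed)
        for v in values:
            kw = {"epochs": int(v)} if axis == "epochs" else {
                "epochs": epochs, "learning_rate": float(v)}
            try:
                feats = extract_features(
                    sp, variant, seed=seed, collect_loss=losses, **kw
                )
                rep = _evaluate_row(sp, feats, seed, None)
                row = {axis: v, "method": variant, "seed": seed, **rep.as_dict(),
                       "error": ""}
            except Exception as exc:
                row = {axis: v, "method": variant, "seed": seed,
                       **{m: np.nan for m in METRIC_COLS}, "error": str(exc)}
            rows.append(row)
    return BenchmarkTable(rows=pd.DataFrame(rows), loss_histories=losses)


def variability_analysis(
    dataset: LabeledSpikeSet,
    method: str,
    n_runs: int,
    stage: str = "clustering-only",
    epochs: int = 50,
    base_seed: int = 0,
    rescale_internal: bool = False,
) -> dict:
    """Distribution of the six metrics over repeated runs.

    ``clustering-only`` re-runs K-Means with fresh seeds on one fixed feature
    set; ``full`` re-trains the extractor each run. Returns per-metric
    min/median/mean/max plus the raw per-run table. DBS/CHS can optionally be
    rescaled to [0, 1] by their max across runs for comparability.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if stage not in ("clustering-only", "full"):
        raise ValueError("stage must be 'clustering-only' or 'full'")
    sp = preprocess(dataset, shuffle_seed=base_seed)
    rows = []
    if stage == "clustering-only":
        feats = extract_features(sp, method, seed=base_seed, epochs=epochs)
        for r in range(n_runs):
            rep = _evaluate_row(sp, feats, base_seed + r, None)
            rows.append({"run": r, "seed": base_seed + r, **rep.as_dict()})
    else:
        for r in range(n_runs):
            feats = extract_features(sp, method, seed=base_seed + r, epochs=epochs)
            rep = _evaluate_row(sp, feats, base_seed + r, None)
            rows.append({"run": r, "seed": base_seed + r, **rep.as_dict()})
    df = pd.DataFrame(rows)
    if rescale_internal:
        for col in ("dbs", "chs"):
            mx = df[col].abs().max()
            if mx > 0:
                df[col] = df[col] / mx
    summary = df[METRIC_COLS].agg(["min", "median", "mean", "max"])
    return {"runs": df, "summary": summary, "stage": stage}
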