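"""Reconstruction-accuracy (RA) evaluation against simulation ground truth.

Estimated components are matched to ground-truth sources by maximizing
summed single-trial R² under an injective (Hungarian) assignment; each
matched pair is then scored with four R² features:

- ``single_trial``: over the full concatenated single-trial timecourse;
- ``peak``: between per-trial amplitudes, each trial's amplitude being
  the mean over a 20-sample window centered on the source's mean peak
  latency — the feature used for single-trial amplitude inference;
- ``average``: between trial-averaged waveforms;
- ``topography``: between the true scalp map and the component's
  back-reconstructed scalp-map column.

R² is the squared Pearson correlation: invariant to the sign and scale
indeterminacies of ICA, and the conventional reading of "variance of the
source accounted for" by a component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .hybrid import HybridGroundTruth
from .pipeline import GroupResult, SubjectComponents

__all__ = [
    "FEATURES",
    "RAResult",
    "r_squared",
    "match_components",
    "ra_features",
    "evaluate_dataset",
    "evaluate_group_result",
    "build_report",
    "report_to_wide",
]

FEATURES = ("single_trial", "peak", "average", "topography")
DEFAULT_PEAK_WINDOW = 20  # samples


def r_squared(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation; 0 (with a warning) for constant input."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size != b.size:
        raise ValueError("vectors must have equal length")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        warnings.warn("constant vector in R^2; reporting 0", RuntimeWarning, stacklevel=2)
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


def match_components(truth: HybridGroundTruth, comps: SubjectComponents) -> np.ndarray:
    """Injective source→component assignment maximizing summed single-trial R².

    Returns an array ``match`` with ``match[k]`` the component index
    assigned to source ``k``. Solved by the Hungarian algorithm on the
    ``n_sources x N`` R² matrix; ties resolve to the lowest component
    index.
    """
    n_sources = truth.n_sources
    n_comps = comps.timecourses.shape[0]
    if n_comps < n_sources:
        raise ValueError(f"{n_comps} components cannot cover {n_sources} sources")
    r2 = np.empty((n_sources, n_comps))
    for k in range(n_sources):
        for j in range(n_comps):
            r2[k, j] = r_squared(truth.source_timecourses[k], comps.timecourses[j])
    rows, cols = linear_sum_assignment(-r2)
    match = np.empty(n_sources, dtype=int)
    match[rows] = cols
    return match


def _trial_peak_amplitudes(x: np.ndarray, samples: int, n_trials: int,
                           center: float, window: int) -> np.ndarray:
    """Per-trial mean over a ``window``-sample window centered on ``center``."""
    lo = int(round(center - window / 2.0))
    hi = lo + window
    lo, hi = max(lo, 0), min(hi, samples)
    if hi <= lo:
        raise ValueError(
            f"peak window centered at {center} lies outside the {samples}-sample epoch"
        )
    img = x.reshape(n_trials, samples)
    return img[:, lo:hi].mean(axis=1)


def ra_features(
    truth: HybridGroundTruth,
    comps: SubjectComponents,
    source_index: int,
    component_index: int,
    peak_window: int = DEFAULT_PEAK_WINDOW,
) -> dict[str, float]:
    """The four R² reconstruction-accuracy features for a matched pair."""
    k, j = source_index, component_index
    s = comps.samples_per_epoch
    t = comps.n_trials
    src = truth.source_timecourses[k]
    comp = comps.timecourses[j]
    if src.size != comp.size:
        raise ValueError("source and component timecourse lengths differ")
    out = {"single_trial": r_squared(src, comp)}
    center = float(truth.mean_latencies[k])
    out["peak"] = r_squared(
        _trial_peak_amplitudes(src, s, t, center, peak_window),
        _trial_peak_amplitudes(comp, s, t, center, peak_window),
    )
    out["average"] = r_squared(
        src.reshape(t, s).mean(axis=0), comp.reshape(t, s).mean(axis=0)
    )
    out["topography"] = r_squared(truth.topographies[:, k], comps.scalp_maps[:, j])
    return out


def evaluate_dataset(truth: HybridGroundTruth, comps: SubjectComponents,
                     peak_window: int = DEFAULT_PEAK_WINDOW) -> pd.DataFrame:
    """Match and score one dataset; one row per (source, feature)."""
    match = match_components(truth, comps)
    rows = []
    for k in range(truth.n_sources):
        feats = ra_features(truth, comps, k, int(match[k]), peak_window)
        for name, value in feats.items():
            rows.append({
                "source": f"S{k + 1}",
                "feature": name,
                "r2": value,
                "matched_component": int(match[k]),
            })
    return pd.DataFrame(rows)


def evaluate_group_result(result: GroupResult, truths: list[HybridGroundTruth],
                          peak_window: int = DEFAULT_PEAK_WINDOW) -> pd.DataFrame:
    """Score every subject of a group run against its ground truth."""
    if len(truths) != len(result.subjects):
        raise ValueError("number of ground truths must match number of subjects")
    frames = []
    for i, (truth, comps) in enumerate(zip(truths, result.subjects)):
        df = evaluate_dataset(truth, comps, peak_window)
        df.insert(0, "dataset", i)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["algorithm"] = result.config_snapshot.get("algorithm", "unknown")
    n = result.config_snapshot.get("N")
    if n is None:
        n = result.ica.n_components
    out["n_components"] = n
    return out


@dataclass
class RAResult:
    """Per-dataset RA records and their aggregation over datasets."""

    per_dataset: pd.DataFrame  # dataset, source, feature, r2, matched_component, ...
    aggregated: pd.DataFrame  # algorithm, n_components, source, feature, mean, sem, n


def build_report(runs: list[tuple[GroupResult, list[HybridGroundTruth]]],
                 peak_window: int = DEFAULT_PEAK_WINDOW) -> RAResult:
    """Evaluate several runs and aggregate RA as mean ± SEM over datasets.

    SEM is sd/sqrt(n_datasets); a single-dataset run reports SEM 0 with
    ``sem_defined = False``.
    """
    frames = [evaluate_group_result(res, truths, peak_window) for res, truths in runs]
    counts = {f["source"].nunique() for f in frames}
    if len(counts) > 1:
        raise ValueError(f"heterogeneous source counts across runs: {sorted(counts)}")
    per_dataset = pd.concat(frames, ignore_index=True)
    grouped = per_dataset.groupby(["algorithm", "n_components", "source", "feature"])["r2"]
    agg = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    agg["sem"] = np.where(agg["n"] > 1, agg["sd"] / np.sqrt(agg["n"]), 0.0)
    agg["sem_defined"] = agg["n"] > 1
    return RAResult(per_dataset=per_dataset, aggregated=agg.drop(columns="sd"))


def report_to_wide(ra: RAResult) -> pd.DataFrame:
    """Summary-table layout: one row per (algorithm, N), 12 value columns.

    Columns are feature × source means, ordered single-trial, peak,
    average, topography by S1..S3.
    """
    agg = ra.aggregated
    wide = agg.pivot_table(index=["algorithm", "n_components"],
                           columns=["feature", "source"], values="mean")
    sources = sorted(agg["source"].unique())
    cols = [(f, s) for f in FEATURES for s in sources]
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cols))
    wide.columns = [f"{f}_{s}" for f, s in wide.columns]
    return wide.reset_index()
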