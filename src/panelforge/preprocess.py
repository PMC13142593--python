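"""Preprocessing and cross-cohort harmonization.

The pipeline order is fixed: missingness filter -> quantile normalization
-> log2 transform -> (optional per-batch median centering) -> per-protein
z-scoring within the cohort.  After z-scoring, matrices from different
platforms share a common location/scale so panels can be transferred
across cohorts; the z stage is idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .matrix import CohortMatrix

__all__ = [
    "PreprocessConfig",
    "filter_missingness",
    "quantile_normalize",
    "log2_transform",
    "batch_center",
    "zscore_standardize",
    "preprocess",
]


@dataclass
class PreprocessConfig:
    """Knobs for the fixed preprocessing pipeline."""

    max_missing_fraction: float = 0.8
    pseudocount: float = 0.0
    batch_center: bool = False
    quantile_normalize: bool = True
    log2: bool = True
    zscore: bool = True
    drop_zero_variance: bool = True


def filter_missingness(m: CohortMatrix, max_missing_fraction: float = 0.8) -> CohortMatrix:
    """Drop proteins missing in strictly more than ``max_missing_fraction``
    of subjects.

    The boundary is retained: a protein missing in exactly 80% of subjects
    survives the default filter.
    """
    if not 0 <= max_missing_fraction < 1:
        raise ValueError("max_missing_fraction must be in [0, 1)")
    if m.data.size == 0:
        raise ValueError("empty matrix")
    frac = m.missing_fraction()
    removed = frac.index[frac > max_missing_fraction].tolist()
    kept = m.data.loc[frac <= max_missing_fraction]
    return m.with_data(
        kept,
        log_entry=(f"missingness filter (> {max_missing_fraction:g}): removed "
                   f"{len(removed)} proteins {removed if len(removed) <= 20 else ''}"),
    )


def quantile_normalize(m: CohortMatrix) -> CohortMatrix:
    """Force every subject column onto a common value distribution.

    The reference distribution is the across-column mean of order
    statistics; within-column ranks are preserved and ties receive the
    average of the reference values they span.  Missing entries stay
    missing and do not enter the reference.  Columns of unequal observed
    length are mapped through the reference by quantile interpolation.
    """
    X = m.data.to_numpy(dtype=float)
    n_prot, n_subj = X.shape
    if n_subj < 2:
        raise ValueError("quantile normalization needs >= 2 subjects")
    counts = (~np.isnan(X)).sum(axis=0)
    short = [m.subjects[j] for j in np.flatnonzero(counts < 2)]
    if short:
        raise ValueError(f"columns with < 2 observed values: {short}")

    # Reference: mean of available order statistics on a common grid.
    # With equal observed counts this is exactly the classic mean of the
    # j-th smallest values; otherwise each column's sorted values are
    # interpolated onto a grid of max observed length.
    L = int(counts.max())
    grid = np.linspace(0.0, 1.0, L)
    acc = np.zeros(L)
    for j in range(n_subj):
        col = np.sort(X[~np.isnan(X[:, j]), j])
        q = np.linspace(0.0, 1.0, col.size)
        acc += np.interp(grid, q, col)
    ref = acc / n_subj

    out = X.copy()
    for j in range(n_subj):
        obs = ~np.isnan(X[:, j])
        col = X[obs, j]
        k = col.size
        # average rank (1-based) -> reference quantile; ties share the mean
        # of the reference values their ranks span
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty(k)
        ranks[order] = np.arange(k)
        # handle ties: average the positional ranks of equal values
        sorted_col = col[order]
        ref_j = np.interp(np.linspace(0.0, 1.0, k), grid, ref) if k != L else ref
        vals = np.empty(k)
        i = 0
        while i < k:
            h = i
            while h + 1 < k and sorted_col[h + 1] == sorted_col[i]:
                h += 1
            vals[i:h + 1] = ref_j[i:h + 1].mean()
            i = h + 1
        new = np.empty(k)
        new[order] = vals
        out[obs, j] = new
    data = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return m.with_data(data, log_entry="quantile normalization (mean-of-order-statistics reference)")


def log2_transform(m: CohortMatrix, pseudocount: float = 0.0) -> CohortMatrix:
    """Element-wise log2(v + pseudocount); flips the scale flag to log2."""
    if m.scale != "raw":
        raise ValueError(f"log2_transform expects scale 'raw', got {m.scale!r}")
    X = m.data.to_numpy(dtype=float) + pseudocount
    bad = np.argwhere(np.nan_to_num(X, nan=1.0) <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive value for protein {m.proteins[i]!r}, subject "
            f"{m.subjects[j]!r} (value {m.data.iat[i, j]!r}, pseudocount {pseudocount})")
    data = pd.DataFrame(np.log2(X), index=m.data.index, columns=m.data.columns)
    return m.with_data(data, scale="log2", log_entry=f"log2 transform (pseudocount {pseudocount})")


def batch_center(m: CohortMatrix, batches: dict) -> CohortMatrix:
    """Per-batch median centering, per protein.

    A deliberately simple batch adjustment: within each batch, subtract
    each protein's batch median.  ``batches`` maps subject id -> batch
    label.
    """
    data = m.data.copy()
    labels = pd.Series({s: batches[s] for s in m.subjects})
    for batch in labels.unique():
        cols = labels.index[labels == batch]
        med = data[cols].median(axis=1)
        data[cols] = data[cols].sub(med, axis=0)
    return m.with_data(data, log_entry=f"batch median centering over {labels.nunique()} batches")


def zscore_standardize(m: CohortMatrix, on_error: str = "raise") -> CohortMatrix:
    """Per-protein standardization within the cohort (n-1 denominator).

    Harmonizes cohorts measured on different platforms onto a common
    scale.  Zero-variance proteins are an error by default
    (``on_error='drop'`` removes them instead, logged).
    """
    X = m.data.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(X, axis=1)
        sd = np.nanstd(X, axis=1, ddof=1)
    n_obs = (~np.isnan(X)).sum(axis=1)
    thin = [m.proteins[i] for i in np.flatnonzero(n_obs < 2)]
    if thin:
        raise ValueError(f"proteins with < 2 observed values: {thin}")
    flat = [m.proteins[i] for i in np.flatnonzero(sd == 0)]
    if flat:
        if on_error == "drop":
            keep = sd != 0
            data = pd.DataFrame(
                (X[keep] - mean[keep, None]) / sd[keep, None],
                index=m.data.index[keep], columns=m.data.columns)
            return m.with_data(data, scale="zscore",
                               log_entry=f"z-score; dropped zero-variance proteins {flat}")
        raise ValueError(f"zero-variance proteins: {flat}")
    data = pd.DataFrame((X - mean[:, None]) / sd[:, None],
                        index=m.data.index, columns=m.data.columns)
    return m.with_data(data, scale="zscore", log_entry="z-score standardization (within cohort, ddof=1)")


def preprocess(m: CohortMatrix, cfg: Optional[PreprocessConfig] = None,
               batches: Optional[dict] = None) -> CohortMatrix:
    """Run the fixed pipeline on a raw matrix.

    Matrices already on log2 scale (as distributed by several cohorts)
    skip the raw-only stages and go straight to harmonization.
    """
    cfg = cfg or PreprocessConfig()
    out = filter_missingness(m, cfg.max_missing_fraction)
    if out.scale == "raw":
        if cfg.quantile_normalize:
            out = quantile_normalize(out)
        if cfg.log2:
            out = log2_transform(out, cfg.pseudocount)
    if cfg.batch_center and batches is not None:
        out = batch_center(out, batches)
    if cfg.zscore and out.scale != "zscore":
        out = zscore_standardize(out, on_error="drop" if cfg.drop_zero_variance else "raise")
    return out
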