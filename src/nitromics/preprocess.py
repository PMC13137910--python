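"""Normalization, filtering, imputation and scale transformations.

Two preprocessing paths exist, matching the two acquisition styles the
pipeline emulates:

* a TMT-like path for complete reporter-intensity matrices:
  per-channel normalization to 100% total signal, then an all-valid filter
  and no imputation;
* a label-free path with missing values: a minimum-valid-count filter
  (default 16 of 32 samples), log2 transform, then down-shifted normal
  imputation (width 0.3, down-shift 1.8 SD, per column).

Statistical testing happens on the linear scale, so :func:`back_transform`
undoes the log2 transform after imputation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import IntensityMatrix

log = logging.getLogger(__name__)


def channel_normalize(m: IntensityMatrix) -> IntensityMatrix:
    """Scale each sample column to a total signal of 100.

    Mirrors isobaric-label reporter normalization to relative percentages;
    requires a complete (no missing cells) linear-scale matrix.
    """
    if m.scale_state != "linear":
        raise ValueError("channel_normalize requires linear-scale intensities")
    if m.mask.to_numpy().any():
        raise ValueError("channel_normalize requires a complete matrix; run "
                         "filter_complete (mode='all_valid') first")
    sums = m.values.sum(axis=0)
    zero = sums[sums == 0].index.tolist()
    if zero:
        raise ValueError(f"columns with zero total signal: {zero}")
    return m.with_values(m.values.div(sums, axis=1) * 100.0)


def filter_complete(m: IntensityMatrix, mode: str = "min_valid",
                    min_valid: int | None = None) -> IntensityMatrix:
    """Drop features with too few observed values.

    ``mode='all_valid'`` keeps only rows with zero missing cells;
    ``mode='min_valid'`` keeps rows with at least ``min_valid`` observed
    values (the boundary count itself is retained).
    """
    if mode not in ("all_valid", "min_valid"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "all_valid":
        min_valid = m.n_samples
    if min_valid is None:
        raise ValueError("min_valid is required for mode='min_valid'")
    if min_valid > m.n_samples:
        raise ValueError(f"min_valid={min_valid} exceeds the "
                         f"{m.n_samples} samples present")
    observed = m.n_samples - m.mask.sum(axis=1)
    keep = observed >= min_valid
    log.info("filter_complete(%s, %d): removed %d of %d features",
             mode, min_valid, int((~keep).sum()), m.n_features)
    return m.with_values(m.values.loc[keep])


def log2_transform(m: IntensityMatrix) -> IntensityMatrix:
    if m.scale_state != "linear":
        raise ValueError("log2_transform requires linear scale_state")
    arr = m.values.to_numpy()
    if np.any(arr[~np.isnan(arr)] <= 0):
        raise ValueError("log2 of non-positive observed value")
    return m.with_values(np.log2(m.values), scale_state="log2")


def back_transform(m: IntensityMatrix) -> IntensityMatrix:
    """Inverse of :func:`log2_transform`: intensity_linear = 2**intensity_log2."""
    if m.scale_state != "log2":
        raise ValueError("back_transform requires log2 scale_state")
    return m.with_values(np.power(2.0, m.values), scale_state="linear")


def impute_downshifted(m: IntensityMatrix, width: float = 0.3,
                       downshift: float = 1.8, seed: int = 0
                       ) -> IntensityMatrix:
    """Replace missing log2 values with draws from a down-shifted normal.

    For each sample column j with observed mean mu_j and sample SD sigma_j,
    missing cells are drawn from
    ``Normal(mu_j - downshift * sigma_j, (width * sigma_j)**2)``,
    emulating left-censored low-abundance signal.  Observed cells are
    untouched and the missingness mask is cleared.
    """
    if m.scale_state != "log2":
        raise ValueError("impute_downshifted operates on log2-scale values")
    rng = np.random.default_rng(seed)
    values = m.values.to_numpy().copy()
    for j, col in enumerate(m.sample_ids):
        column = values[:, j]
        observed = column[~np.isnan(column)]
        n_missing = int(np.isnan(column).sum())
        if n_missing == 0:
            continue
        if observed.size < 3:
            raise ValueError(f"column {col!r} has {observed.size} observed "
                             "values; need >= 3 to estimate the imputation SD")
        mu, sigma = observed.mean(), observed.std(ddof=1)
        column[np.isnan(column)] = rng.normal(
            mu - downshift * sigma, width * sigma, size=n_missing)
    frame = pd.DataFrame(values, index=m.values.index, columns=m.values.columns)
    return m.with_values(frame, scale_state="log2")


def row_zscore(m: IntensityMatrix) -> IntensityMatrix:
    """Standardize each feature row to mean 0, sample SD 1.

    Constant rows (SD 0) are undefined under this transform; they are
    dropped with a log entry.
    """
    if m.scale_state != "log2":
        raise ValueError("row_zscore operates on log2-scale values")
    if m.mask.to_numpy().any():
        raise ValueError("row_zscore requires a complete matrix")
    sd = m.values.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        log.info("row_zscore: dropped %d constant rows: %s",
                 int(constant.sum()), list(m.values.index[constant])[:5])
    values = m.values.loc[~constant]
    z = values.sub(values.mean(axis=1), axis=0).div(sd[~constant], axis=0)
    return m.with_values(z, scale_state="zscored")


def cap_zscores(m: IntensityMatrix, cap: float = 2.0) -> pd.DataFrame:
    """Display-only capping of z-scores at +/-cap for heatmap rendering.

    Returns a plain frame; analyzed values are never capped.
    """
    if m.scale_state != "zscored":
        raise ValueError("cap_zscores expects a z-scored matrix")
    return m.values.clip(lower=-cap, upper=cap)
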