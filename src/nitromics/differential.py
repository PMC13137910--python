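"""Per-feature differential statistics for a two-group contrast.

Intensity data are tested with two-tailed Welch t-tests on the linear
scale, with log2 fold changes taken as log2(mean_contrast / mean_ref) and
Benjamini-Hochberg adjustment across all tested features.  Count data are
tested with a deliberately simple negative-binomial Wald scheme:
median-of-ratios size factors, method-of-moments gene dispersions shrunk
50/50 toward a mean-dispersion trend, two-group log-link means, and a
normal-reference Wald statistic on the log2 fold change.  It is a reduced
form of the standard NB-GLM framework (no profile-likelihood dispersions,
no fold-change shrinkage, no outlier refitting), validated by parameter
recovery and type-I calibration on synthetic NB data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix, IntensityMatrix, select_samples

log = logging.getLogger(__name__)

DIFF_COLUMNS = ["gene_symbol", "log2fc", "p_raw", "p_adj",
                "mean_ref", "mean_contrast", "dataset_label"]

#: cap applied to the reported log2 fold change when one group mean is zero
LFC_CAP = 10.0


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison over the sample design.

    ``reference`` and ``contrast`` are column=value selectors; the reported
    log2 fold change is contrast over reference (e.g. iNOS_KO-stim over
    WT-stim: negative lfc means the feature is higher with NO present).
    """

    reference: dict = field(default_factory=dict)
    contrast: dict = field(default_factory=dict)
    label: str = ""

    def sample_ids(self, design: pd.DataFrame) -> tuple[list[str], list[str]]:
        ref = select_samples(design, **self.reference)
        con = select_samples(design, **self.contrast)
        if set(ref) & set(con):
            raise ValueError(f"contrast {self.label!r}: selectors overlap")
        if len(ref) < 2 or len(con) < 2:
            raise ValueError(f"contrast {self.label!r} selects {len(ref)} "
                             f"reference and {len(con)} contrast samples; "
                             "need >= 2 each")
        return ref, con


KO_STIM_VS_WT_STIM = Contrast(
    reference={"genotype": "WT", "stimulation": "stim", "donor": "none"},
    contrast={"genotype": "iNOS_KO", "stimulation": "stim", "donor": "none"},
    label="iNOS_KO_stim_vs_WT_stim")

WT_STIM_VS_WT_UNSTIM = Contrast(
    reference={"genotype": "WT", "stimulation": "unstim", "donor": "none"},
    contrast={"genotype": "WT", "stimulation": "stim", "donor": "none"},
    label="WT_stim_vs_WT_unstim")


# ------------------------------------------------------------------- Welch

def welch_test(x, y) -> tuple[float, float, float]:
    """Two-tailed Welch t-test.

    Returns (t, df, p) with t = (mean_x - mean_y) / sqrt(s2x/nx + s2y/ny),
    Welch-Satterthwaite degrees of freedom, and a two-sided Student-t
    p-value.  Both groups constant and equal gives (0, nan, 1) by
    convention; a zero standard error with unequal means is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_test needs >= 2 observations per group")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("welch_test requires finite values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if x.mean() == y.mean():
            return 0.0, float("nan"), 1.0
        raise ValueError("zero pooled standard error with unequal means")
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _welch_vectorized(X: np.ndarray, Y: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch test; same math as :func:`welch_test`."""
    nx, ny = X.shape[1], Y.shape[1]
    mx, my = X.mean(axis=1), Y.mean(axis=1)
    vx, vy = X.var(axis=1, ddof=1), Y.var(axis=1, ddof=1)
    se2 = vx / nx + vy / ny
    degenerate = se2 == 0.0
    if np.any(degenerate & (mx != my)):
        idx = int(np.argwhere(degenerate & (mx != my))[0][0])
        raise ValueError(f"zero pooled standard error with unequal means "
                         f"at row index {idx}")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, (mx - my) / np.sqrt(se2))
        df = np.where(degenerate, np.nan, se2 ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)))
    p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    return t, df, p


# ---------------------------------------------------------------------- BH

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_i = min_{j >= i} (m * p_(j) / j), capped at 1; this monotone-capped
    form guarantees q >= p pointwise.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("bh_adjust expects a non-empty 1-D array")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


# -------------------------------------------------------------- intensities

def diff_intensity(m: IntensityMatrix, contrast: Contrast,
                   dataset_label: str | None = None) -> pd.DataFrame:
    """Welch-test every feature for one contrast on linear intensities.

    Returns a table with columns gene_symbol, log2fc, p_raw, p_adj,
    mean_ref, mean_contrast, dataset_label, sorted by gene symbol.
    """
    if m.scale_state != "linear":
        raise ValueError("diff_intensity tests linear-scale intensities; "
                         "back_transform the matrix first")
    ref_ids, con_ids = contrast.sample_ids(m.design)
    X = m.values[con_ids].to_numpy()
    Y = m.values[ref_ids].to_numpy()
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("missing values in selected samples; filter or "
                         "impute before testing")
    t, df, p = _welch_vectorized(X, Y)
    mean_con, mean_ref = X.mean(axis=1), Y.mean(axis=1)
    with np.errstate(divide="ignore"):
        log2fc = np.log2(mean_con / mean_ref)
    result = pd.DataFrame({
        "gene_symbol": m.values.index,
        "log2fc": log2fc,
        "p_raw": p,
        "p_adj": bh_adjust(p),
        "mean_ref": mean_ref,
        "mean_contrast": mean_con,
        "dataset_label": dataset_label or contrast.label,
    })
    return result.sort_values("gene_symbol", kind="stable").reset_index(drop=True)


# ------------------------------------------------------------------- counts

def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios library-size factors.

    Per gene, a geometric-mean reference across samples (genes with any
    zero count are excluded from the reference set); each sample's factor
    is the median over genes of count / reference.
    """
    arr = counts.values.to_numpy()
    all_positive = (arr > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no gene with all-positive counts; a pseudo-reference "
                         "fallback is not implemented")
    reference = arr[all_positive]
    geomean = np.exp(np.log(reference).mean(axis=1, keepdims=True))
    sf = np.median(reference / geomean, axis=0)
    return pd.Series(sf, index=counts.sample_ids, name="size_factor")


def filter_low_counts(counts: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Drop genes with total counts below ``min_total`` across all samples."""
    totals = counts.values.sum(axis=1)
    keep = totals >= min_total
    log.info("filter_low_counts(%d): removed %d of %d genes",
             min_total, int((~keep).sum()), len(totals))
    return counts.with_values(counts.values.loc[keep])


def _dispersion_trend(mean: np.ndarray, disp: np.ndarray
                      ) -> tuple[float, float]:
    """Least-squares fit of disp ~ a0 + a1/mean, coefficients clipped >= 0."""
    ok = mean > 0
    if ok.sum() < 2:
        med = float(np.median(disp[ok])) if ok.any() else 0.0
        return max(med, 0.0), 0.0
    A = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
    coef, *_ = np.linalg.lstsq(A, disp[ok], rcond=None)
    return float(max(coef[0], 0.0)), float(max(coef[1], 0.0))


def estimate_dispersions(q: np.ndarray, groups: list[np.ndarray],
                         mean_inv_sf: float) -> np.ndarray:
    """Per-gene NB dispersions: method-of-moments shrunk toward a trend.

    On size-factor-normalized counts q the NB variance is approximately
    mu * E[1/s] + alpha * mu^2, giving the moment estimator
    alpha_g = max((var - mu * E[1/s]) / mu^2, 0) from the pooled
    within-group variance.  Gene estimates are averaged 50/50 with an
    a0 + a1/mu trend fitted across genes, then floored at 1e-8.
    """
    mu = q.mean(axis=1)
    within = np.mean([q[:, g].var(axis=1, ddof=1) for g in groups], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_g = np.where(mu > 0, (within - mu * mean_inv_sf) / mu ** 2, 0.0)
    alpha_g = np.maximum(alpha_g, 0.0)
    a0, a1 = _dispersion_trend(mu, alpha_g)
    alpha_trend = a0 + a1 / np.maximum(mu, 1e-8)
    return np.maximum(0.5 * alpha_g + 0.5 * alpha_trend, 1e-8)


def nb_wald(counts: CountMatrix, contrast: Contrast,
            dataset_label: str | None = None,
            pseudo_level: float = 0.5) -> pd.DataFrame:
    """Simplified negative-binomial Wald differential expression.

    Per gene: normalize by median-of-ratios size factors; estimate the
    dispersion (see :func:`estimate_dispersions`); take the two group means
    of normalized counts as the fitted log-link means; compute the Wald
    statistic lfc / SE(lfc) with the standard-error from the NB Fisher
    information (group means floored at ``pseudo_level`` inside the SE
    only), and a two-sided normal p-value; BH-adjust across genes.

    Genes with all-zero counts in the selected samples are excluded with a
    log entry.  A zero mean in exactly one group yields a sign-correct
    fold change capped at +/-10 and ``lfc_capped=True``.
    """
    ref_ids, con_ids = contrast.sample_ids(counts.design)
    sf = size_factors(counts)
    sub = counts.values[ref_ids + con_ids]
    arr = sub.to_numpy().astype(float)
    nonzero = arr.sum(axis=1) > 0
    if (~nonzero).any():
        log.info("nb_wald: excluded %d all-zero genes", int((~nonzero).sum()))
    arr = arr[nonzero]
    genes = sub.index[nonzero]

    sf_sel = sf[ref_ids + con_ids].to_numpy()
    q = arr / sf_sel[None, :]
    n_ref = len(ref_ids)
    g_ref = np.arange(n_ref)
    g_con = np.arange(n_ref, n_ref + len(con_ids))
    alpha = estimate_dispersions(q, [g_ref, g_con], float((1.0 / sf_sel).mean()))

    m_ref = q[:, g_ref].mean(axis=1)
    m_con = q[:, g_con].mean(axis=1)
    with np.errstate(divide="ignore"):
        log2fc = np.log2(m_con / m_ref)   # +/-inf when one group mean is 0
    capped = ~np.isfinite(log2fc)
    log2fc = np.clip(np.nan_to_num(log2fc, nan=0.0, posinf=LFC_CAP,
                                   neginf=-LFC_CAP), -LFC_CAP, LFC_CAP)

    # Fisher information of the log-mean in each group, with floored means
    mf_ref = np.maximum(m_ref, pseudo_level)
    mf_con = np.maximum(m_con, pseudo_level)
    mu_ref = sf_sel[None, g_ref] * mf_ref[:, None]
    mu_con = sf_sel[None, g_con] * mf_con[:, None]
    info_ref = (mu_ref / (1.0 + alpha[:, None] * mu_ref)).sum(axis=1)
    info_con = (mu_con / (1.0 + alpha[:, None] * mu_con)).sum(axis=1)
    se_log2 = np.sqrt(1.0 / info_ref + 1.0 / info_con) / np.log(2.0)

    wald = log2fc / se_log2
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    result = pd.DataFrame({
        "gene_symbol": genes,
        "log2fc": log2fc,
        "p_raw": p,
        "p_adj": bh_adjust(p),
        "mean_ref": m_ref,
        "mean_contrast": m_con,
        "dataset_label": dataset_label or contrast.label,
        "lfc_capped": capped,
    })
    return result.sort_values("gene_symbol", kind="stable").reset_index(drop=True)
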