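"""Cross-dataset agreement of differential results.

Given two differential tables (any pair of the two proteomes and the
transcriptome), genes are matched case-insensitively by symbol and each
pair is placed in one of five agreement categories from significance and
fold-change direction.  Stricter views are layered on top: strong-responder
quadrants (|lfc| above a cutoff and significant in both datasets) and the
triple-concordance ranking of genes significantly downregulated in all
three datasets -- the highest-confidence NO-induced targets, since loss of
iNOS lowers them everywhere.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

CONCORDANCE_CATEGORIES = ("both_concordant", "both_opposite",
                          "only_a", "only_b", "neither")


def _checked(table: pd.DataFrame, name: str) -> pd.DataFrame:
    out = table.copy()
    out["_key"] = out["gene_symbol"].str.upper()
    if out["_key"].duplicated().any():
        dup = out.loc[out["_key"].duplicated(), "gene_symbol"].tolist()[:5]
        raise ValueError(f"duplicate gene symbols in table {name}: {dup}")
    return out


def match_genes(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Case-insensitive inner join of two differential tables by symbol.

    The output keeps dataset a's symbol casing and carries lfc and adjusted
    p from both sides; unmatched counts on each side are logged.
    """
    ta, tb = _checked(a, "a"), _checked(b, "b")
    merged = ta.merge(tb, on="_key", suffixes=("_a", "_b"))
    log.info("match_genes: %d pairs (%d unmatched in a, %d in b)",
             len(merged), len(ta) - len(merged), len(tb) - len(merged))
    if merged.empty:
        log.warning("match_genes: no genes in common")
    return pd.DataFrame({
        "gene_symbol": merged["gene_symbol_a"],
        "lfc_a": merged["log2fc_a"],
        "lfc_b": merged["log2fc_b"],
        "padj_a": merged["p_adj_a"],
        "padj_b": merged["p_adj_b"],
    }).sort_values("gene_symbol", kind="stable").reset_index(drop=True)


def classify_concordance(paired: pd.DataFrame, alpha: float = 0.05
                         ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign each matched pair one of five agreement categories.

    both significant & same direction -> both_concordant; both significant
    & opposite -> both_opposite; exactly one significant -> only_a /
    only_b; neither -> neither.  A fold change of exactly 0 in one
    significant dataset is treated as agreeing with the other dataset's
    sign (logged); the categories partition the pairs.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if paired.empty:
        raise ValueError("empty paired table")
    sig_a = paired["padj_a"].to_numpy() < alpha
    sig_b = paired["padj_b"].to_numpy() < alpha
    sign_a = np.sign(paired["lfc_a"].to_numpy())
    sign_b = np.sign(paired["lfc_b"].to_numpy())
    zero = (sign_a == 0) | (sign_b == 0)
    if (zero & sig_a & sig_b).any():
        log.info("classify_concordance: %d zero-lfc significant pairs "
                 "treated as concordant", int((zero & sig_a & sig_b).sum()))
    same = (sign_a * sign_b > 0) | zero
    category = np.select(
        [sig_a & sig_b & same, sig_a & sig_b, sig_a, sig_b],
        ["both_concordant", "both_opposite", "only_a", "only_b"],
        default="neither")
    records = paired.copy()
    records["category"] = category
    counts = {c: int((category == c).sum()) for c in CONCORDANCE_CATEGORIES}
    return records, counts


def correlation_with_test(paired: pd.DataFrame) -> tuple[float, float, int]:
    """Pearson r of the paired log2 fold changes with its t-test p-value.

    p is two-sided from t = r * sqrt(n-2) / sqrt(1-r^2) on n-2 df.
    """
    x = paired["lfc_a"].to_numpy(dtype=float)
    y = paired["lfc_b"].to_numpy(dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 pairs for a correlation test")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one fold-change vector")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0, n
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p), n


def strong_responders(records: pd.DataFrame, lfc_cut: float = 0.5,
                      alpha: float = 0.05, top_k: int = 20) -> pd.DataFrame:
    """Strong-responder quadrants: |lfc| > cut and padj < alpha in BOTH
    datasets, split by shared direction.

    Within each quadrant genes are ranked by |lfc_a| + |lfc_b| descending
    and the top ``top_k`` flagged for labeling.
    """
    sig = (records["padj_a"] < alpha) & (records["padj_b"] < alpha)
    big = (records["lfc_a"].abs() > lfc_cut) & (records["lfc_b"].abs() > lfc_cut)
    up = sig & big & (records["lfc_a"] > 0) & (records["lfc_b"] > 0)
    down = sig & big & (records["lfc_a"] < 0) & (records["lfc_b"] < 0)
    out = records.loc[up | down,
                      ["gene_symbol", "lfc_a", "lfc_b", "padj_a", "padj_b"]].copy()
    out["quadrant"] = np.where(up[up | down], "both_up", "both_down")
    out["abs_lfc_sum"] = out["lfc_a"].abs() + out["lfc_b"].abs()
    out = out.sort_values(["quadrant", "abs_lfc_sum", "gene_symbol"],
                          ascending=[True, False, True], kind="stable")
    out["rank"] = out.groupby("quadrant").cumcount() + 1
    out["top"] = out["rank"] <= top_k
    return out.reset_index(drop=True)


def add_strong_quadrants(records: pd.DataFrame, lfc_cut: float = 0.5,
                         alpha: float = 0.05, top_k: int = 20) -> pd.DataFrame:
    """Concordance records with a ``strong_quadrant`` column
    (both_up / both_down / none)."""
    quads = strong_responders(records, lfc_cut, alpha, top_k)
    out = records.copy()
    out["strong_quadrant"] = "none"
    mapping = quads.set_index(quads["gene_symbol"].str.upper())["quadrant"]
    keys = out["gene_symbol"].str.upper()
    hit = keys.isin(mapping.index)
    out.loc[hit, "strong_quadrant"] = mapping.loc[keys[hit]].to_numpy()
    return out


def triple_concordance(a: pd.DataFrame, b: pd.DataFrame, c: pd.DataFrame,
                       wt_stim: pd.DataFrame, alpha: float = 0.05,
                       rank_on: str = "b") -> pd.DataFrame:
    """Genes significantly downregulated (padj < alpha, lfc < 0) in all
    three datasets, ranked most-to-least downregulated.

    ``rank_on`` names which dataset's fold change orders the table (rank 1
    = most negative; ties broken by gene symbol).  ``no_inducible`` flags
    genes also significantly induced by stimulation in WT cells
    (padj < alpha and lfc > 0 in ``wt_stim``); genes missing from
    ``wt_stim`` get a null flag with a log entry.
    """
    if rank_on not in ("a", "b", "c"):
        raise ValueError("rank_on must be one of 'a', 'b', 'c'")
    frames = {}
    for name, tbl in (("a", a), ("b", b), ("c", c)):
        t = _checked(tbl, name)
        frames[name] = t.set_index("_key")[["gene_symbol", "log2fc", "p_adj"]]
    common = frames["a"].index
    for name in ("b", "c"):
        common = common.intersection(frames[name].index)

    keep = pd.Series(True, index=common)
    for name in ("a", "b", "c"):
        f = frames[name].loc[common]
        keep &= (f["p_adj"] < alpha) & (f["log2fc"] < 0)
    hits = common[keep]

    wt = _checked(wt_stim, "wt_stim").set_index("_key")
    flag = pd.Series(pd.NA, index=hits, dtype="boolean")
    known = hits.intersection(wt.index)
    flag.loc[known] = ((wt.loc[known, "p_adj"] < alpha)
                       & (wt.loc[known, "log2fc"] > 0)).to_numpy()
    if len(known) < len(hits):
        log.info("triple_concordance: %d genes absent from the WT-stim "
                 "table; flag unknown", len(hits) - len(known))

    out = pd.DataFrame({
        "gene_symbol": frames["a"].loc[hits, "gene_symbol"].to_numpy(),
        "lfc_a": frames["a"].loc[hits, "log2fc"].to_numpy(),
        "lfc_b": frames["b"].loc[hits, "log2fc"].to_numpy(),
        "lfc_c": frames["c"].loc[hits, "log2fc"].to_numpy(),
        "no_inducible": flag.to_numpy(),
    })
    rank_col = {"a": "lfc_a", "b": "lfc_b", "c": "lfc_c"}[rank_on]
    out = out.sort_values([rank_col, "gene_symbol"],
                          ascending=[True, True], kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
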