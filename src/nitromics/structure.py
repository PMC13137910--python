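"""Sample-space structure and NO-dependence effect classification.

Covers principal component analysis with loading-based contributor
selection, Ward.D2 hierarchical clustering on Pearson correlation
distance, and the four-way z-score effect classifier that labels each
feature's response pattern across the genotype x stimulation design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .containers import IntensityMatrix, select_samples

log = logging.getLogger(__name__)

CATEGORIES = ("NO_dep_up", "NO_dep_down", "NO_independent", "under_threshold")


@dataclass
class PCAResult:
    """Scores (samples x components), loadings (features x components) and
    per-component variance explained (percent of total, sums to 100)."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: pd.Series


def run_pca(m: IntensityMatrix) -> PCAResult:
    """PCA with samples as observations and features as variables.

    Features are centered and scaled to unit (sample) variance;
    zero-variance features are removed first.  Components are oriented so
    the feature with the largest absolute loading on each component has a
    positive loading, making contributor signs reproducible.
    """
    if m.mask.to_numpy().any():
        raise ValueError("run_pca requires a complete matrix")
    if m.n_samples < 2:
        raise ValueError("run_pca needs at least 2 samples")
    X = m.values.to_numpy().T  # samples x features
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if (~keep).sum():
        log.info("run_pca: removed %d zero-variance features", int((~keep).sum()))
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    features = m.values.index[keep]

    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # features x components

    flip = np.where(loadings[np.abs(loadings).argmax(axis=0),
                             np.arange(loadings.shape[1])] < 0, -1.0, 1.0)
    loadings = loadings * flip
    scores = scores * flip

    comps = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.sample_ids, columns=comps),
        loadings=pd.DataFrame(loadings, index=features, columns=comps),
        variance_explained=pd.Series(pca.explained_variance_ratio_ * 100.0,
                                     index=comps, name="variance_explained"),
    )


def select_contributors(loadings: pd.Series | np.ndarray, k_sd: float = 2.0
                        ) -> tuple[list, list]:
    """Features whose loading lies beyond mean +/- k_sd * SD of all loadings.

    Returns (positive contributor ids, negative contributor ids).
    """
    values = pd.Series(loadings)
    if len(values) < 3:
        raise ValueError("need >= 3 loadings to estimate a threshold")
    sd = values.std(ddof=1)
    if sd == 0:
        log.warning("select_contributors: constant loadings, no contributors")
        return [], []
    mean = values.mean()
    positive = values.index[values > mean + k_sd * sd].tolist()
    negative = values.index[values < mean - k_sd * sd].tolist()
    return positive, negative


@dataclass
class ClusterResult:
    linkage: np.ndarray            # scipy linkage matrix
    leaf_order: list               # feature ids in dendrogram order
    feature_ids: list

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.feature_ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def correlation_distance(values: np.ndarray) -> np.ndarray:
    """Condensed pairwise 1 - Pearson r distance between rows."""
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values)
    if np.isnan(r).any():
        raise ValueError("constant row gives undefined correlation; drop "
                         "constant rows in preprocessing (row_zscore does)")
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    # clip tiny negative rounding noise before condensing
    return squareform(np.maximum(d, 0.0), checks=False)


def cluster_rows(m: IntensityMatrix) -> ClusterResult:
    """Agglomerative clustering of features: Pearson correlation distance
    with the Ward.D2 update rule.

    Ward linkage on a non-Euclidean dissimilarity is heuristic (the
    convention of the clustering software this mirrors); merge order for
    exactly tied distances is implementation-defined.
    """
    if m.n_features < 2:
        raise ValueError("cluster_rows needs >= 2 rows")
    condensed = correlation_distance(m.values.to_numpy())
    Z = hierarchy.linkage(condensed, method="ward")
    order = hierarchy.leaves_list(Z).tolist()
    ids = list(m.values.index)
    return ClusterResult(Z, [ids[i] for i in order], ids)


def classify_no_dependence(z: IntensityMatrix,
                           stim_threshold: float = 0.4,
                           no_threshold: float = 0.5,
                           rescale_condition_means: bool = False
                           ) -> pd.DataFrame:
    """Four-way NO-dependence classification from condition-mean z-scores.

    Per feature, condition means of row z-scores over the four donor-free
    design cells give

    * ``wt_stim_effect``  = mean(WT stim) - mean(WT unstim)
    * ``inos_stim_effect`` = mean(KO stim) - mean(KO unstim)
    * ``no_effect``       = wt_stim_effect - inos_stim_effect

    and the rules (thresholds in z-score units):

    * NO_dep_up:    wt_stim_effect >  stim_threshold and no_effect >  no_threshold
    * NO_dep_down:  wt_stim_effect < -stim_threshold and no_effect < -no_threshold
    * NO_independent: |wt_stim_effect| > stim_threshold and
      |inos_stim_effect| > stim_threshold and |no_effect| < no_threshold
    * under_threshold otherwise.

    The four rules partition every real-valued effect triple.  With
    ``rescale_condition_means`` the four condition means are re-standardized
    per feature before the effects are computed (the alternative reading of
    "effects from z-scores"; off by default).
    """
    if z.scale_state != "zscored":
        raise ValueError("classification operates on a row-z-scored matrix")
    cells = {}
    for geno in ("WT", "iNOS_KO"):
        for stim in ("unstim", "stim"):
            ids = select_samples(z.design, genotype=geno, stimulation=stim,
                                 donor="none")
            if not ids:
                raise ValueError(f"design lacks the donor-free cell "
                                 f"({geno}, {stim})")
            cells[(geno, stim)] = z.values[ids].mean(axis=1)

    means = pd.DataFrame(cells)
    if rescale_condition_means:
        means = means.sub(means.mean(axis=1), axis=0) \
                     .div(means.std(axis=1, ddof=1), axis=0)

    wt_eff = means[("WT", "stim")] - means[("WT", "unstim")]
    ko_eff = means[("iNOS_KO", "stim")] - means[("iNOS_KO", "unstim")]
    no_eff = wt_eff - ko_eff

    category = classify_effect_triples(wt_eff.to_numpy(), ko_eff.to_numpy(),
                                       stim_threshold, no_threshold)
    return pd.DataFrame({
        "gene_symbol": z.values.index,
        "wt_stim_effect": wt_eff.to_numpy(),
        "inos_stim_effect": ko_eff.to_numpy(),
        "no_effect": no_eff.to_numpy(),
        "category": category,
    }).reset_index(drop=True)


def classify_effect_triples(wt_eff: np.ndarray, ko_eff: np.ndarray,
                            stim_threshold: float = 0.4,
                            no_threshold: float = 0.5) -> np.ndarray:
    """Vectorized classification rules on (wt, ko) effect pairs.

    no_effect is wt_eff - ko_eff by definition, so the triple is determined
    by the pair; exposed separately so the partition property can be fuzzed
    directly.
    """
    no_eff = wt_eff - ko_eff
    up = (wt_eff > stim_threshold) & (no_eff > no_threshold)
    down = (wt_eff < -stim_threshold) & (no_eff < -no_threshold)
    indep = (np.abs(wt_eff) > stim_threshold) \
        & (np.abs(ko_eff) > stim_threshold) \
        & (np.abs(no_eff) < no_threshold)
    return np.select([up, down, indep],
                     ["NO_dep_up", "NO_dep_down", "NO_independent"],
                     default="under_threshold")


def component_silhouette(pca: PCAResult, design: pd.DataFrame,
                         column: str = "stimulation",
                         component: str = "PC1") -> float:
    """Silhouette of a design-factor split on one PC's score axis."""
    labels = design.set_index("sample_id").loc[pca.scores.index, column]
    return float(silhouette_score(pca.scores[[component]].to_numpy(),
                                  labels.to_numpy()))
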