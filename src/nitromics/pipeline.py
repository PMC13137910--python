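"""End-to-end orchestration: simulate -> preprocess -> differential ->
structure -> concordance -> enrichment -> report.

A run emulates the three-dataset study layout: a 32-sample label-free
proteome on the full genotype x stimulation x donor factorial (the
primary-macrophage-like arm), a 16-sample complete-matrix proteome on the
donor-free factorial (the cell-line-like arm), and a 12-sample RNA-seq
count set on the same donor-free factorial -- all measuring one shared
planted truth, so every downstream statistic can be scored against it.

The pipeline's recovered NO-dependent gene sets combine two stages: the
z-score effect classifier (pattern) intersected with robust-responder
evidence from the genotype contrasts (padj below alpha AND a
sign-consistent fold change beyond the magnitude cutoff, in at least one
proteome).  The classifier alone is deliberately liberal -- its thresholds
operate on variance-normalized z-scores, so with few replicates a sizeable
share of flat features crosses them by chance; the
significance-plus-magnitude filter supplies the error control, mirroring
how high-confidence NO-regulated calls are made on real data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import bmdm_design, raw_design
from .differential import (KO_STIM_VS_WT_STIM, WT_STIM_VS_WT_UNSTIM,
                           diff_intensity, filter_low_counts, nb_wald)
from .enrichment import enrich
from .io_tables import (GeneSet, collapse_to_genes, write_gmt,
                        write_matrix, write_table)
from .preprocess import (back_transform, channel_normalize, filter_complete,
                         impute_downshifted, log2_transform, row_zscore)
from .concordance import (add_strong_quadrants, classify_concordance,
                          correlation_with_test, match_genes,
                          triple_concordance)
from .simulate import (SimParams, generate_counts, generate_gene_sets,
                       generate_proteomics, plant_truth, truth_feature_map)
from .structure import (classify_no_dependence, cluster_rows,
                        component_silhouette, run_pca, select_contributors)

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised with every configuration problem collected into one message."""


@dataclass
class RunConfig:
    """All pipeline parameters in one validated, hashable object."""

    # simulation block
    n_features: int = 4000
    class_proportions: tuple[float, float, float, float] = (0.10, 0.10, 0.25, 0.55)
    effect_size_mean: float = 1.5
    effect_size_sd: float = 0.3
    rna_protein_coupling: float = 0.568
    missing_rate: float = 0.10
    censor_strength: float = 1.0
    nb_dispersion: float = 0.05
    noise_sd: float = 0.25
    bmdm_replicates: int = 4
    raw_replicates: int = 4
    rna_replicates: int = 3
    # stage parameters
    alpha: float = 0.05
    lfc_cut: float = 0.5
    stim_threshold: float = 0.4
    no_threshold: float = 0.5
    k_sd: float = 2.0
    component: int = 2
    min_valid: int = 16
    min_total: int = 10
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    top_k_quadrant: int = 20
    top_k_pathways: int = 15
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if self.n_features <= 0:
            errors.append("n_features must be positive")
        if not 0 < self.alpha < 1:
            errors.append("alpha must be in (0, 1)")
        if self.lfc_cut < 0:
            errors.append("lfc_cut must be >= 0")
        if self.stim_threshold < 0 or self.no_threshold < 0:
            errors.append("classification thresholds must be >= 0")
        if self.k_sd < 0:
            errors.append("k_sd must be >= 0")
        if self.component < 1:
            errors.append("component must be >= 1")
        if self.min_valid > 2 * 2 * 2 * self.bmdm_replicates:
            errors.append(f"min_valid={self.min_valid} exceeds the "
                          f"{8 * self.bmdm_replicates} samples of the design")
        if self.min_total < 0:
            errors.append("min_total must be >= 0")
        if self.impute_width <= 0:
            errors.append("impute_width must be > 0")
        if min(self.bmdm_replicates, self.raw_replicates,
               self.rna_replicates) < 2:
            errors.append("all replicate counts must be >= 2")
        try:
            self.sim_params()
        except ValueError as exc:
            errors.append(str(exc))
        if errors:
            raise ConfigError("invalid configuration: " + "; ".join(errors))

    def sim_params(self, **overrides) -> SimParams:
        kwargs = dict(
            n_features=self.n_features,
            class_proportions=tuple(self.class_proportions),
            effect_size_mean=self.effect_size_mean,
            effect_size_sd=self.effect_size_sd,
            rna_protein_coupling=self.rna_protein_coupling,
            missing_rate=self.missing_rate,
            censor_strength=self.censor_strength,
            nb_dispersion=self.nb_dispersion,
            noise_sd=self.noise_sd,
            seed=self.seed,
        )
        kwargs.update(overrides)
        return SimParams(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_proportions"] = list(d["class_proportions"])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "class_proportions" in d:
            d = {**d, "class_proportions": tuple(d["class_proportions"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


class _StageLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def record(self, stage: str, t0: float, **info) -> None:
        entry = {"stage": stage, "seconds": round(time.time() - t0, 3), **info}
        with open(self.path, "a", encoding="utf-8") as fh:
            fh.write(json.dumps(entry) + "\n")
        log.info("stage %s done in %.2fs", stage, entry["seconds"])


def score_recovery(classification: pd.DataFrame,
                   diff_genotype_tables: list[pd.DataFrame] | pd.DataFrame,
                   truth: pd.DataFrame, alpha: float = 0.05,
                   lfc_cut: float = 0.5) -> dict:
    """Precision/recall of recovered NO-dependent classes against the truth.

    A gene is recovered as NO-dependent when the z-score classifier assigns
    the category AND at least one genotype-contrast differential table
    supplies robust-responder evidence: padj < alpha with a sign-consistent
    fold change of magnitude > lfc_cut (NO-induced genes are LOWER in the
    knockout, so NO_dep_up pairs with lfc < -lfc_cut).  Requiring the
    magnitude cutoff on top of significance mirrors the robust-responder
    criterion used for high-confidence calls and suppresses the small
    systematic fold-change shifts that total-signal normalization imprints
    on unregulated genes.  Classifier-only precision/recall are included
    as diagnostics.
    """
    if isinstance(diff_genotype_tables, pd.DataFrame):
        diff_genotype_tables = [diff_genotype_tables]
    cls = classification.set_index(classification["gene_symbol"].str.upper())
    tru = truth.set_index(truth["gene_symbol"].str.upper())
    diffs = [t.set_index(t["gene_symbol"].str.upper())
             for t in diff_genotype_tables]
    common = cls.index.intersection(tru.index)
    for d in diffs:
        common = common.intersection(d.index)
    cls, tru = cls.loc[common], tru.loc[common]
    diffs = [d.loc[common] for d in diffs]

    def evidence(sign: int) -> pd.Series:
        ev = pd.Series(False, index=common)
        for d in diffs:
            ev |= (d["p_adj"] < alpha) & (sign * d["log2fc"] > lfc_cut)
        return ev

    calls = {
        "NO_dep_up": (cls["category"] == "NO_dep_up") & evidence(-1),
        "NO_dep_down": (cls["category"] == "NO_dep_down") & evidence(+1),
    }
    out = {}
    for label, called in calls.items():
        truth_set = tru["planted_class"] == label
        tp = int((called & truth_set).sum())
        out[f"precision_{label}"] = tp / max(int(called.sum()), 1)
        out[f"recall_{label}"] = tp / max(int(truth_set.sum()), 1)
        classifier_only = cls["category"] == label
        tp_c = int((classifier_only & truth_set).sum())
        out[f"classifier_precision_{label}"] = tp_c / max(int(classifier_only.sum()), 1)
        out[f"classifier_recall_{label}"] = tp_c / max(int(truth_set.sum()), 1)
    return out


def run(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline into ``outdir``; returns the key results.

    Every stage writes its table(s) with the config hash in a provenance
    header plus one JSONL log line; the returned dict carries the headline
    numbers (correlations, category counts, silhouette, recovery scores)
    and the paths of all artifacts.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    stage_log = _StageLog(outdir / "stages.jsonl")
    (outdir / "config.json").write_text(
        json.dumps({"version": __version__, "config_hash": chash,
                    **config.to_dict()}, indent=2))

    alpha = config.alpha
    results: dict = {"config_hash": chash, "outdir": str(outdir)}

    # ---- simulate ------------------------------------------------------
    t0 = time.time()
    params = config.sim_params()
    truth = plant_truth(params)
    design_bmdm = bmdm_design(config.bmdm_replicates)
    design_raw = raw_design(config.raw_replicates)
    design_rna = raw_design(config.rna_replicates)

    bmdm, _ = generate_proteomics(design_bmdm, params, truth=truth)
    raw, _ = generate_proteomics(
        design_raw, config.sim_params(missing_rate=0.0), truth=truth,
        noise_stream=7)  # complete TMT-like matrix, independent noise
    counts = generate_counts(design_rna, truth, params)
    library = {name: GeneSet(name, "planted", frozenset(g.upper() for g in mem))
               for name, mem in generate_gene_sets(truth, params).items()}

    # map accessions to gene symbols so all three datasets share one key
    fmap = truth_feature_map(truth)
    bmdm = collapse_to_genes(bmdm, fmap)
    raw = collapse_to_genes(raw, fmap)

    write_table(truth, outdir / "truth.tsv", chash)
    write_matrix(bmdm, outdir / "bmdm_intensity.tsv", chash)
    write_matrix(raw, outdir / "raw_intensity.tsv", chash)
    write_matrix(counts, outdir / "rna_counts.tsv", chash)
    write_gmt({n: s.members for n, s in library.items()},
              outdir / "gene_sets.gmt")
    stage_log.record("simulate", t0, n_features=config.n_features,
                     shapes={"bmdm": list(bmdm.values.shape),
                             "raw": list(raw.values.shape),
                             "rna": list(counts.values.shape)})

    # ---- preprocess ----------------------------------------------------
    t0 = time.time()
    bmdm_f = filter_complete(bmdm, "min_valid", config.min_valid)
    bmdm_log2 = impute_downshifted(log2_transform(bmdm_f),
                                   config.impute_width,
                                   config.impute_downshift, seed=config.seed)
    bmdm_linear = back_transform(bmdm_log2)

    raw_norm = channel_normalize(filter_complete(raw, "all_valid"))
    raw_log2 = log2_transform(raw_norm)
    raw_z = row_zscore(raw_log2)
    stage_log.record("preprocess", t0,
                     bmdm_kept=bmdm_f.n_features, raw_kept=raw_norm.n_features)

    # ---- differential --------------------------------------------------
    t0 = time.time()
    diff_bmdm = diff_intensity(bmdm_linear, KO_STIM_VS_WT_STIM, "bmdm_protein")
    diff_raw = diff_intensity(raw_norm, KO_STIM_VS_WT_STIM, "raw_protein")
    diff_raw_wtstim = diff_intensity(raw_norm, WT_STIM_VS_WT_UNSTIM,
                                     "raw_protein_wt_stim")
    counts_f = filter_low_counts(counts, config.min_total)
    diff_rna = nb_wald(counts_f, KO_STIM_VS_WT_STIM, "raw_rna")
    for name, tbl in (("diff_bmdm_protein", diff_bmdm),
                      ("diff_raw_protein", diff_raw),
                      ("diff_raw_protein_wt_stim", diff_raw_wtstim),
                      ("diff_raw_rna", diff_rna)):
        write_table(tbl, outdir / f"{name}.tsv", chash)
    stage_log.record("differential", t0, genes_rna=len(diff_rna),
                     sig_bmdm=int((diff_bmdm["p_adj"] < alpha).sum()),
                     sig_raw=int((diff_raw["p_adj"] < alpha).sum()),
                     sig_rna=int((diff_rna["p_adj"] < alpha).sum()))

    # ---- structure -----------------------------------------------------
    t0 = time.time()
    pca = run_pca(bmdm_log2)
    comp = f"PC{config.component}"
    pos, neg = select_contributors(pca.loadings[comp], config.k_sd)
    silhouette = component_silhouette(pca, design_bmdm, "stimulation", "PC1")
    classification = classify_no_dependence(raw_z, config.stim_threshold,
                                            config.no_threshold)
    contributors = [f for f in pos + neg if f in raw_z.values.index]
    cluster_input = raw_z.values.loc[contributors] if len(contributors) >= 2 \
        else raw_z.values
    clustering = cluster_rows(raw_z.with_values(cluster_input))
    (outdir / "contributors_dendrogram.nwk").write_text(clustering.to_newick())

    write_table(pca.scores.reset_index(names="sample_id"),
                outdir / "pca_scores.tsv", chash)
    write_table(pca.loadings.reset_index(names="feature_id"),
                outdir / "pca_loadings.tsv", chash)
    write_table(pca.variance_explained.reset_index()
                .set_axis(["component", "variance_explained"], axis=1),
                outdir / "pca_variance.tsv", chash)
    write_table(classification, outdir / "classification.tsv", chash)
    stage_log.record("structure", t0, pc1_stim_silhouette=silhouette,
                     contributors_pos=len(pos), contributors_neg=len(neg))
    results.update(pc1_stim_silhouette=silhouette,
                   variance_explained=pca.variance_explained.head(3).round(2).to_dict(),
                   n_contributors={"positive": len(pos), "negative": len(neg)},
                   category_counts=classification["category"]
                   .value_counts().to_dict())

    # ---- concordance ---------------------------------------------------
    t0 = time.time()
    cross_model = match_genes(diff_bmdm, diff_raw)
    cm_records, cm_counts = classify_concordance(cross_model, alpha)
    cm_records = add_strong_quadrants(cm_records, config.lfc_cut, alpha,
                                      config.top_k_quadrant)
    cm_r, cm_p, cm_n = correlation_with_test(cross_model)

    cross_omic = match_genes(diff_raw, diff_rna)
    co_records, co_counts = classify_concordance(cross_omic, alpha)
    co_r, co_p, co_n = correlation_with_test(cross_omic)

    triple = triple_concordance(diff_bmdm, diff_raw, diff_rna,
                                diff_raw_wtstim, alpha, rank_on="b")
    write_table(cm_records, outdir / "concordance_cross_model.tsv", chash)
    write_table(co_records, outdir / "concordance_cross_omic.tsv", chash)
    write_table(triple, outdir / "triple_concordance.tsv", chash)
    summary = {
        "cross_model": {"r": cm_r, "p": cm_p, "n": cm_n, "categories": cm_counts},
        "cross_omic": {"r": co_r, "p": co_p, "n": co_n, "categories": co_counts},
        "triple_concordant": len(triple),
    }
    (outdir / "concordance_summary.json").write_text(
        json.dumps(summary, indent=2))
    stage_log.record("concordance", t0, **{
        "cross_model_r": cm_r, "cross_omic_r": co_r,
        "triple_concordant": len(triple)})
    results.update(cross_model_r=cm_r, cross_omic_r=co_r,
                   concordance=summary)

    # ---- enrichment ----------------------------------------------------
    t0 = time.time()
    sig_up = classification.merge(diff_raw, on="gene_symbol")
    universe = diff_raw["gene_symbol"]
    query_up = sig_up.loc[(sig_up["category"] == "NO_dep_up")
                          & (sig_up["p_adj"] < alpha)
                          & (sig_up["log2fc"] < 0), "gene_symbol"]
    enr = enrich(query_up, library, universe, alpha, config.top_k_pathways)
    write_table(enr, outdir / "enrichment_no_dep_up.tsv", chash)
    stage_log.record("enrichment", t0, query_size=len(query_up),
                     hits=len(enr))
    results["enrichment_top"] = enr["set_name"].head(3).tolist()

    # ---- recovery vs planted truth ------------------------------------
    t0 = time.time()
    recovery = score_recovery(classification, [diff_raw, diff_bmdm], truth,
                              alpha, config.lfc_cut)
    results["recovery"] = recovery
    (outdir / "recovery.json").write_text(json.dumps(recovery, indent=2))
    stage_log.record("recovery", t0, **{k: round(v, 4)
                                        for k, v in recovery.items()})
    (outdir / "results.json").write_text(json.dumps(results, indent=2,
                                                    default=str))
    return results


def report(run_dir: str | Path) -> Path:
    """Assemble a run directory into a single markdown summary with plots.

    Refuses directories whose tables carry mixed config hashes.  Sections:
    PCA scores, classification category counts, strong-responder quadrants,
    triple-concordance top 15, enrichment bars.  A missing RNA table
    degrades the concordance section to cross-model only.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from .io_tables import read_table, read_table_hash

    run_dir = Path(run_dir)
    required = ["pca_scores.tsv", "classification.tsv",
                "concordance_cross_model.tsv"]
    missing = [f for f in required if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing stages: {missing}")

    hashes = {read_table_hash(run_dir / f)
              for f in run_dir.glob("*.tsv") if read_table_hash(run_dir / f)}
    if len(hashes) > 1:
        raise ValueError(f"mixed config hashes in run directory: {sorted(hashes)}")

    config = json.loads((run_dir / "config.json").read_text())
    scores = read_table(run_dir / "pca_scores.tsv")
    classification = read_table(run_dir / "classification.tsv")
    cross_model = read_table(run_dir / "concordance_cross_model.tsv")
    has_rna = (run_dir / "concordance_cross_omic.tsv").exists()

    # PCA scatter colored by stimulation (parsed from the sample id scheme)
    fig, ax = plt.subplots(figsize=(5, 4))
    stim = scores["sample_id"].str.contains(".stim.")
    for label, sel in (("stim", stim), ("unstim", ~stim)):
        ax.scatter(scores.loc[sel, "PC1"], scores.loc[sel, "PC2"],
                   label=label, alpha=0.8)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(run_dir / "pca_scores.png", dpi=120)
    plt.close(fig)

    lines = [f"# nitromics run report",
             f"",
             f"config hash `{config['config_hash']}`, "
             f"seed {config['seed']}, {config['n_features']} features",
             "",
             "## PCA", "",
             "![PCA scores](pca_scores.png)", "",
             "## NO-dependence categories", ""]
    counts = classification["category"].value_counts()
    lines += [f"- {cat}: {int(n)}" for cat, n in counts.items()]

    lines += ["", "## Strong-responder quadrants (cross-model)", ""]
    quads = cross_model[cross_model.get("strong_quadrant", "none") != "none"]
    lines += [f"- {q}: {int(n)}" for q, n
              in quads["strong_quadrant"].value_counts().items()] or ["- none"]

    lines += ["", "## Triple concordance", ""]
    if has_rna and (run_dir / "triple_concordance.tsv").exists():
        triple = read_table(run_dir / "triple_concordance.tsv")
        lines.append(f"{len(triple)} genes significantly down in all three "
                     "datasets; top 15 by cell-line protein fold change:")
        lines.append("")
        for _, row in triple.head(15).iterrows():
            lines.append(f"- #{int(row['rank'])} {row['gene_symbol']} "
                         f"(lfc {row['lfc_b']:.2f})")
    else:
        lines.append("cross-model only (no RNA dataset in this run)")

    lines += ["", "## Enrichment", ""]
    enr_path = run_dir / "enrichment_no_dep_up.tsv"
    if enr_path.exists():
        enr = read_table(enr_path)
        if len(enr):
            fig, ax = plt.subplots(figsize=(5, 0.5 + 0.4 * len(enr)))
            ax.barh(enr["set_name"], -np.log10(enr["p_adj"]))
            ax.set_xlabel("-log10(adjusted p)")
            ax.invert_yaxis()
            fig.tight_layout()
            fig.savefig(run_dir / "enrichment_bars.png", dpi=120)
            plt.close(fig)
            lines.append("![Enrichment](enrichment_bars.png)")
        else:
            lines.append("no enriched sets at the configured threshold")
    out_path = run_dir / "report.md"
    out_path.write_text("\n".join(lines) + "\n")
    return out_path
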