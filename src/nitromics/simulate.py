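"""Synthetic factorial multi-omic data with planted ground truth.

The generator emulates the statistical structure of paired macrophage
proteome/transcriptome experiments: a factorial design over genotype
(WT / iNOS_KO), stimulation and NO-donor treatment; features split into four
planted regulatory classes; left-censored missingness for label-free
intensities; and negative-binomial counts whose true effects are coupled to
the protein effects at a tunable correlation.

Planted classes and the conditions they respond to:

``NO_dep_up`` / ``NO_dep_down``
    respond (up / down on the log2 scale) whenever NO is present, i.e. in
    stimulated WT cells (endogenous iNOS-derived NO) or in any DETA-NONOate
    treated cell (exogenous donor, the "rescue" arm).
``NO_independent``
    respond to stimulation in both genotypes, donor or not.
``null``
    never respond; both true log2 fold changes are exactly 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (CountMatrix, IntensityMatrix, validate_design)

log = logging.getLogger(__name__)

PLANTED_CLASSES = ("NO_dep_up", "NO_dep_down", "NO_independent", "null")

# fixed per-matrix RNG sub-streams so proteome and transcriptome are
# independently reproducible from the one seed
_STREAM_PROTEIN = 0
_STREAM_RNA = 1
_STREAM_GENESETS = 2


class SimulationParameterError(ValueError):
    """Raised for out-of-range simulation parameters."""


@dataclass
class SimParams:
    """Parameters of the coupled proteome/transcriptome generator.

    Defaults are the package's reference study conditions: effect sizes of
    ~1.5 log2 units with the NO-independent stimulation program as the
    largest regulated class, protein-RNA true-effect coupling of 0.568,
    moderate left-censored missingness, and NB dispersion 0.05.
    """

    n_features: int = 4000
    class_proportions: tuple[float, float, float, float] = (0.10, 0.10, 0.25, 0.55)
    effect_size_mean: float = 1.5
    effect_size_sd: float = 0.3
    rna_protein_coupling: float = 0.568
    baseline_mean: float = 20.0     # log2 units
    baseline_sd: float = 2.0
    noise_sd: float = 0.25          # log2 measurement noise
    missing_rate: float = 0.10
    censor_strength: float = 1.0
    nb_dispersion: float = 0.05
    count_mean_log: float = float(np.log(100.0))
    count_mean_sdlog: float = 1.2
    library_size_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        if self.n_features <= 0:
            errors.append("n_features must be positive")
        props = np.asarray(self.class_proportions, dtype=float)
        if props.shape != (4,) or (props < 0).any():
            errors.append("class_proportions must be 4 non-negative reals")
        elif abs(props.sum() - 1.0) > 1e-9:
            errors.append(f"class_proportions sum to {props.sum()!r}, not 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            errors.append("missing_rate must be in [0, 1]")
        if self.censor_strength < 0:
            errors.append("censor_strength must be >= 0")
        if not -1.0 <= self.rna_protein_coupling <= 1.0:
            errors.append("rna_protein_coupling must be in [-1, 1]")
        if self.nb_dispersion < 0:
            errors.append("nb_dispersion must be >= 0")
        if self.effect_size_sd < 0 or self.noise_sd < 0 or self.baseline_sd < 0:
            errors.append("scale parameters must be >= 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            errors.append("library_size_range must be positive with lo <= hi")
        if errors:
            raise SimulationParameterError("; ".join(errors))

    def to_dict(self) -> dict:
        return asdict(self)

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng((int(self.seed), stream))


def _class_counts(n: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n features into the four classes."""
    raw = proportions * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts


def plant_truth(params: SimParams) -> pd.DataFrame:
    """Draw the truth table: planted class and true log2 effects per feature.

    RNA effects are coupled to the protein effects at
    ``rna_protein_coupling`` among non-null features:
    ``rna = rho * prot + sqrt(1 - rho^2) * sd(prot) * eps`` with standard
    normal ``eps``, so the population correlation of the true effects equals
    rho exactly.  Null features have both effects identically zero.
    """
    rng = params._rng(_STREAM_PROTEIN)
    n = params.n_features
    props = np.asarray(params.class_proportions, dtype=float)
    counts = _class_counts(n, props)
    classes = np.repeat(np.arange(4), counts)
    classes = classes[rng.permutation(n)]

    magnitude = np.abs(rng.normal(params.effect_size_mean,
                                  params.effect_size_sd, n))
    sign_indep = rng.choice([-1.0, 1.0], size=n)
    prot_lfc = np.select(
        [classes == 0, classes == 1, classes == 2],
        [magnitude, -magnitude, magnitude * sign_indep],
        default=0.0,
    )

    rho = params.rna_protein_coupling
    rna_lfc = np.zeros(n)
    nonnull = classes != 3
    if nonnull.any():
        p = prot_lfc[nonnull]
        sd_p = p.std(ddof=1) if p.size > 1 else 0.0
        eps = rng.standard_normal(p.size)
        rna_lfc[nonnull] = rho * p + np.sqrt(max(0.0, 1 - rho ** 2)) * sd_p * eps

    width = len(str(n))
    return pd.DataFrame({
        "feature_id": [f"P{i:0{width}d}" for i in range(n)],
        "gene_symbol": [f"G{i:0{width}d}" for i in range(n)],
        "planted_class": [PLANTED_CLASSES[c] for c in classes],
        "protein_lfc_true": prot_lfc,
        "rna_lfc_true": rna_lfc,
    })


def _response_indicator(truth: pd.DataFrame, design: pd.DataFrame) -> np.ndarray:
    """features x samples indicator of whether each feature's planted effect
    is active in each sample."""
    no_present = ((design["genotype"].to_numpy() == "WT")
                  & (design["stimulation"].to_numpy() == "stim")) \
        | (design["donor"].to_numpy() == "DETA")
    stim = design["stimulation"].to_numpy() == "stim"
    cls = truth["planted_class"].to_numpy()
    ind = np.zeros((len(truth), len(design)))
    is_no_dep = np.isin(cls, ["NO_dep_up", "NO_dep_down"])
    ind[is_no_dep] = no_present.astype(float)
    ind[cls == "NO_independent"] = stim.astype(float)
    return ind


def generate_proteomics(design: pd.DataFrame, params: SimParams,
                        truth: pd.DataFrame | None = None,
                        noise_stream: int = _STREAM_PROTEIN,
                        ) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Generate a linear-scale intensity matrix with planted effects.

    Latent model per feature f and sample j (log2 scale):
    ``baseline_f + lfc_f * active(f, j) + Normal(0, noise_sd)`` with
    ``baseline_f ~ Normal(baseline_mean, baseline_sd)``.  Missingness is
    left-censoring-like: cells go missing with probability proportional to
    ``Phi(censor_strength * (mu_low - x))`` where ``mu_low`` is the 20th
    percentile of the latent values, rescaled so the average missingness
    equals ``missing_rate``.

    Pass ``truth`` to reuse an existing truth table (e.g. to simulate a
    second model system measuring the same planted biology); a distinct
    ``noise_stream`` then keeps its measurement noise independent.
    """
    validate_design(design)
    if truth is None:
        truth = plant_truth(params)
    rng = params._rng(noise_stream + 10)  # offset: effects drawn in stream 0

    n, m = len(truth), len(design)
    baseline = rng.normal(params.baseline_mean, params.baseline_sd, size=(n, 1))
    delta = truth["protein_lfc_true"].to_numpy()[:, None] \
        * _response_indicator(truth, design)
    latent = baseline + delta + rng.normal(0.0, params.noise_sd, size=(n, m))

    values = np.power(2.0, latent)
    if params.missing_rate > 0:
        mu_low = np.quantile(latent, 0.20)
        phi = stats.norm.cdf(params.censor_strength * (mu_low - latent))
        p_miss = np.clip(params.missing_rate * phi / phi.mean(), 0.0, 1.0)
        values[rng.random(size=(n, m)) < p_miss] = np.nan

    frame = pd.DataFrame(values, index=truth["feature_id"].to_numpy(),
                         columns=design["sample_id"].to_numpy())
    frame.index.name = "feature_id"
    log.info("simulated %d x %d intensity matrix (%.1f%% missing)",
             n, m, 100 * np.isnan(values).mean())
    return IntensityMatrix(frame, design.copy(), "linear"), truth


def generate_counts(design: pd.DataFrame, truth: pd.DataFrame,
                    params: SimParams) -> CountMatrix:
    """Generate NB counts whose group means follow the planted RNA effects.

    Gene means are ``base_g * libsize_j * 2**(rna_lfc_true_g * active(g, j))``
    with log-normal base means and per-sample library-size factors drawn
    uniformly from ``library_size_range``; counts are negative binomial with
    dispersion ``nb_dispersion`` (Poisson in the dispersion -> 0 limit).
    """
    validate_design(design)
    required = {"gene_symbol", "planted_class", "rna_lfc_true"}
    if not required.issubset(truth.columns):
        raise SimulationParameterError(
            f"truth table lacks columns {sorted(required - set(truth.columns))};"
            " it must come from plant_truth/generate_proteomics")
    if truth["gene_symbol"].duplicated().any():
        raise SimulationParameterError("truth gene symbols are not unique")

    rng = params._rng(_STREAM_RNA)
    n, m = len(truth), len(design)
    base = rng.lognormal(params.count_mean_log, params.count_mean_sdlog, size=n)
    lo, hi = params.library_size_range
    libsize = rng.uniform(lo, hi, size=m)
    mu = base[:, None] * libsize[None, :] \
        * np.power(2.0, truth["rna_lfc_true"].to_numpy()[:, None]
                   * _response_indicator(truth, design))

    if params.nb_dispersion <= 1e-12:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / params.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))

    frame = pd.DataFrame(counts.astype(np.int64),
                         index=truth["gene_symbol"].to_numpy(),
                         columns=design["sample_id"].to_numpy())
    frame.index.name = "gene_symbol"
    return CountMatrix(frame, design.copy())


def truth_feature_map(truth: pd.DataFrame) -> pd.DataFrame:
    """Accession -> gene symbol mapping table implied by a truth table."""
    return truth[["feature_id", "gene_symbol"]].rename(
        columns={"feature_id": "accession"}).copy()


def generate_gene_sets(truth: pd.DataFrame, params: SimParams,
                       n_random_sets: int = 18, set_size: int = 50,
                       n_marker: int = 40) -> dict[str, set[str]]:
    """Build a synthetic gene-set library with two planted marker sets.

    ``planted_up_markers`` / ``planted_down_markers`` each contain
    ``n_marker`` genes of the corresponding NO-dependent class plus
    ``set_size - n_marker`` random genes; the remaining sets are uniform
    draws, so only the planted sets should enrich in recovered NO-dependent
    gene lists.
    """
    rng = params._rng(_STREAM_GENESETS)
    genes = truth["gene_symbol"].to_numpy()
    library: dict[str, set[str]] = {}
    for name, cls in (("planted_up_markers", "NO_dep_up"),
                      ("planted_down_markers", "NO_dep_down")):
        members = truth.loc[truth["planted_class"] == cls, "gene_symbol"].to_numpy()
        k = min(n_marker, len(members))
        chosen = rng.choice(members, size=k, replace=False) if k else np.array([])
        filler = rng.choice(genes, size=max(0, set_size - k), replace=False)
        library[name] = set(chosen) | set(filler)
    for i in range(n_random_sets):
        library[f"random_set_{i:02d}"] = set(
            rng.choice(genes, size=set_size, replace=False))
    return library
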