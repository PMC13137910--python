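"""In-memory containers shared across the pipeline.

Two matrix types carry the data: :class:`IntensityMatrix` for linear-scale
protein abundances (with explicit missingness) and :class:`CountMatrix` for
integer RNA-seq counts.  Both attach a sample design table describing the
factorial layout: genotype (WT vs iNOS knockout), stimulation (LPS/IFNg or
not) and NO-donor treatment (DETA-NONOate or none).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "iNOS_KO")
STIMULATIONS = ("unstim", "stim")
DONORS = ("none", "DETA")

DESIGN_COLUMNS = ["sample_id", "genotype", "stimulation", "donor", "replicate"]

#: allowed scale states for an IntensityMatrix and the transitions that
#: preprocessing operations perform between them.
SCALE_STATES = ("linear", "log2", "zscored")


class DesignError(ValueError):
    """Raised when a sample design table is malformed."""


def make_design(genotypes=GENOTYPES, stimulations=STIMULATIONS,
                donors=("none",), n_replicates: int = 4) -> pd.DataFrame:
    """Build a full-factorial sample design table.

    Sample ids are ``<genotype>.<stimulation>.<donor>.<replicate>``.
    """
    rows = []
    for g in genotypes:
        for s in stimulations:
            for d in donors:
                for r in range(1, n_replicates + 1):
                    rows.append((f"{g}.{s}.{d}.{r}", g, s, d, r))
    design = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    validate_design(design)
    return design


def bmdm_design(n_replicates: int = 4) -> pd.DataFrame:
    """32-sample primary-macrophage-like design: 2 genotypes x 2 stimulation
    x 2 donor x ``n_replicates``."""
    return make_design(donors=DONORS, n_replicates=n_replicates)


def raw_design(n_replicates: int = 4) -> pd.DataFrame:
    """16-sample cell-line-like design: 2 genotypes x 2 stimulation x
    ``n_replicates``; no donor arm."""
    return make_design(donors=("none",), n_replicates=n_replicates)


def validate_design(design: pd.DataFrame) -> None:
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise DesignError(f"design table lacks columns {missing}")
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].tolist()
        raise DesignError(f"duplicate sample ids: {dup}")
    for col, allowed in (("genotype", GENOTYPES), ("stimulation", STIMULATIONS),
                         ("donor", DONORS)):
        bad = set(design[col]) - set(allowed)
        if bad:
            raise DesignError(f"invalid {col} values {sorted(bad)}; allowed {allowed}")
    cell_sizes = design.groupby(["genotype", "stimulation", "donor"],
                                observed=True).size()
    if (cell_sizes < 2).any():
        small = cell_sizes[cell_sizes < 2].index.tolist()
        raise DesignError(f"design cells with fewer than 2 replicates: {small}")


def select_samples(design: pd.DataFrame, **criteria: str) -> list[str]:
    """Sample ids matching every ``column=value`` criterion."""
    mask = pd.Series(True, index=design.index)
    for col, val in criteria.items():
        mask &= design[col] == val
    return design.loc[mask, "sample_id"].tolist()


def _check_matrix_design(values: pd.DataFrame, design: pd.DataFrame) -> None:
    validate_design(design)
    if list(values.columns) != list(design["sample_id"]):
        if set(values.columns) != set(design["sample_id"]):
            raise DesignError("matrix columns and design sample_ids differ")
        raise DesignError("matrix column order differs from design order")
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()].tolist()[:5]
        raise DesignError(f"duplicate feature ids: {dup}")


@dataclass
class IntensityMatrix:
    """Protein abundance matrix (features x samples).

    ``values`` holds floats with NaN marking missing cells; ``design`` is a
    sample design table whose ``sample_id`` order matches the columns;
    ``scale_state`` tracks which preprocessing transformations have run.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    scale_state: str = "linear"

    def __post_init__(self) -> None:
        _check_matrix_design(self.values, self.design)
        if self.scale_state not in SCALE_STATES:
            raise ValueError(f"unknown scale_state {self.scale_state!r}")
        if self.scale_state == "linear":
            observed = self.values.to_numpy()
            if np.any(observed[~np.isnan(observed)] <= 0):
                raise ValueError("linear-scale intensities must be > 0 where observed")

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where the cell is missing."""
        return self.values.isna()

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, scale_state: str | None = None
                    ) -> "IntensityMatrix":
        return IntensityMatrix(values=values, design=self.design.copy(),
                               scale_state=scale_state or self.scale_state)


@dataclass
class CountMatrix:
    """Gene-level RNA count matrix (genes x samples) of non-negative integers."""

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        _check_matrix_design(self.values, self.design)
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr), atol=0, rtol=0):
                raise ValueError("counts must be integers")
            self.values = self.values.astype(np.int64)
            arr = self.values.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def with_values(self, values: pd.DataFrame) -> "CountMatrix":
        return CountMatrix(values=values, design=self.design.copy())
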