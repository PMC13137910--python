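"""Tabular IO: TSV matrices, GMT gene-set libraries, accession maps.

All tables are tab-delimited UTF-8 text with ``NA`` for missing values.
Result tables carry a single ``#`` comment header line recording the
package version and, when available, the run-configuration hash, so every
output is traceable to the parameters that produced it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import CountMatrix, IntensityMatrix

log = logging.getLogger(__name__)

NA_STRINGS = ("NA", "NaN", "")


class FormatError(ValueError):
    """Raised for malformed input tables, naming the offending location."""


# ---------------------------------------------------------------- matrices

def _read_tsv_frame(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                        na_values=list(NA_STRINGS), keep_default_na=False)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()].tolist()[:5]
        raise FormatError(f"{path}: duplicate feature ids {dup}")
    if frame.columns.duplicated().any():
        dup = frame.columns[frame.columns.duplicated()].tolist()[:5]
        raise FormatError(f"{path}: duplicate sample ids {dup}")
    return frame


def read_matrix(path: str | Path, kind: str, design: pd.DataFrame
                ) -> IntensityMatrix | CountMatrix:
    """Read a features x samples TSV as an intensity or count matrix.

    ``kind`` is ``"intensity"`` (positive reals, NA allowed) or ``"counts"``
    (non-negative integers).  ``design`` must cover the file's sample
    columns; it is subset and reordered to match them.
    """
    if kind not in ("intensity", "counts"):
        raise ValueError(f"kind must be 'intensity' or 'counts', got {kind!r}")
    frame = _read_tsv_frame(path)
    designed = design.set_index("sample_id", drop=False)
    missing = [c for c in frame.columns if c not in designed.index]
    if missing:
        raise FormatError(f"{path}: samples {missing[:5]} absent from design")
    sub = designed.loc[list(frame.columns)].reset_index(drop=True)

    try:
        values = frame.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc

    if kind == "counts":
        arr = values.to_numpy()
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise FormatError(f"{path}: missing count at row {frame.index[r]!r}"
                              f", column {frame.columns[c]!r}")
        if not np.array_equal(arr, np.round(arr)):
            r, c = np.argwhere(arr != np.round(arr))[0]
            raise FormatError(f"{path}: non-integer count {arr[r, c]!r} at row "
                              f"{frame.index[r]!r}, column {frame.columns[c]!r}")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise FormatError(f"{path}: negative count at row {frame.index[r]!r}"
                              f", column {frame.columns[c]!r}")
        log.info("read %d x %d count matrix from %s", *values.shape, path)
        return CountMatrix(values.astype(np.int64), sub)

    arr = values.to_numpy()
    bad = (arr <= 0) & ~np.isnan(arr)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(f"{path}: non-positive intensity at row "
                          f"{frame.index[r]!r}, column {frame.columns[c]!r}")
    log.info("read %d x %d intensity matrix from %s", *values.shape, path)
    return IntensityMatrix(values, sub, "linear")


def write_matrix(m: IntensityMatrix | CountMatrix, path: str | Path,
                 config_hash: str | None = None) -> None:
    """Write a matrix as TSV with ``NA`` for missing cells.

    With ``config_hash`` a provenance comment header is prepended (readers
    skip ``#`` lines).
    """
    if config_hash is None:
        m.values.to_csv(path, sep="\t", na_rep="NA")
        return
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# nitromics {__version__} config={config_hash}\n")
        m.values.to_csv(fh, sep="\t", na_rep="NA")


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    from .containers import validate_design
    design = pd.read_csv(path, sep="\t", comment="#",
                         dtype={"sample_id": str, "replicate": int})
    validate_design(design)
    return design


# ------------------------------------------------------------ result tables

def write_table(frame: pd.DataFrame, path: str | Path,
                config_hash: str | None = None, index: bool = False) -> None:
    """Write a result table with a provenance comment header."""
    header = f"# nitromics {__version__}"
    if config_hash:
        header += f" config={config_hash}"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        frame.to_csv(fh, sep="\t", na_rep="NA", index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       na_values=list(NA_STRINGS), keep_default_na=False)


def read_table_hash(path: str | Path) -> str | None:
    """Config hash recorded in a result table's provenance header, if any."""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("#") and "config=" in first:
        return first.split("config=", 1)[1].strip()
    return None


# ------------------------------------------------------------- feature map

def read_feature_map(path: str | Path) -> pd.DataFrame:
    """Read an ``accession<TAB>gene_symbol`` mapping table."""
    fmap = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(fmap.columns[:2]) != ["accession", "gene_symbol"]:
        raise FormatError(f"{path}: expected header 'accession\\tgene_symbol',"
                          f" got {list(fmap.columns[:2])}")
    if fmap["accession"].duplicated().any():
        dup = fmap.loc[fmap["accession"].duplicated(), "accession"].tolist()[:5]
        raise FormatError(f"{path}: duplicate accessions {dup}")
    if fmap["gene_symbol"].isna().any() or (fmap["gene_symbol"].str.len() == 0).any():
        raise FormatError(f"{path}: empty gene symbols")
    return fmap


# -------------------------------------------------------------------- GMT

@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]  # uppercased for case-insensitive matching


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Parse a GMT gene-set library.

    Each line is ``name TAB description TAB member TAB member ...``; members
    are uppercased (gene matching is case-insensitive throughout) and
    stored as a set, so duplicates within a line collapse.
    """
    library: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has "
                                  f"{len(fields)} fields, need >= 3")
            name, description = fields[0], fields[1]
            if name in library:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            library[name] = GeneSet(name, description, members)
    return library


def write_gmt(library: dict[str, set[str] | frozenset[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in library.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# --------------------------------------------------------- isoform collapse

def collapse_to_genes(m: IntensityMatrix, fmap: pd.DataFrame) -> IntensityMatrix:
    """Collapse isoform-level rows to one row per gene symbol.

    Each gene/sample cell is the arithmetic mean of the observed values of
    that gene's mapped isoform rows; a cell is missing only when every
    contributing cell is missing.  Unmapped features are dropped (count
    logged).  Operates on linear-scale intensities, before any log
    transform.
    """
    if fmap is None or len(fmap) == 0:
        raise FormatError("empty accession -> gene_symbol mapping")
    if m.scale_state != "linear":
        raise ValueError("collapse_to_genes expects linear-scale intensities")
    mapping = fmap.set_index("accession")["gene_symbol"]
    upper_to_original: dict[str, str] = {}
    for sym in mapping:
        upper_to_original.setdefault(sym.upper(), sym)

    mapped_mask = m.values.index.isin(mapping.index)
    n_dropped = int((~mapped_mask).sum())
    if n_dropped:
        log.info("collapse_to_genes: dropped %d unmapped features", n_dropped)
    values = m.values.loc[mapped_mask]
    genes_upper = mapping.loc[values.index].str.upper()
    collapsed = values.groupby(genes_upper.to_numpy()).mean()  # NaN-aware mean
    collapsed.index = [upper_to_original[g] for g in collapsed.index]
    collapsed.index.name = "gene_symbol"
    collapsed = collapsed.sort_index()
    return IntensityMatrix(collapsed, m.design.copy(), "linear")
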