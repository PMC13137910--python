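"""Local gene-set over-representation by the hypergeometric test.

Replaces web-service enrichment with an explicit, reproducible engine:
the universe (background) is always stated by the caller -- by default the
genes quantified in the analyzed dataset -- sets are trimmed to that
universe before testing (conditional-on-measured convention), and BH
adjustment runs across the sets of one library.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .io_tables import GeneSet, read_gmt

log = logging.getLogger(__name__)

ENRICH_COLUMNS = ["set_name", "overlap_count", "set_size", "query_size",
                  "universe_size", "p_raw", "p_adj", "overlap_members"]


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Drawing ``n`` genes from a universe of ``N`` containing ``K`` set
    members, the probability of an overlap of at least ``k``.  Exact via
    log-gamma accumulation (scipy's survival function); stable for
    N up to 1e6.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ValueError(f"invalid hypergeometric bounds k={k}, K={K}, "
                         f"n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(query, library: dict[str, GeneSet], universe,
           alpha: float = 0.05, top_k: int | None = 15,
           return_all: bool = False) -> pd.DataFrame:
    """Over-representation of ``query`` in each set of ``library``.

    Gene matching is case-insensitive; duplicate query genes collapse.
    Query genes outside the universe are dropped with a warning; each set
    is intersected with the universe before testing, and sets with no
    member in the universe are excluded (logged).  BH runs across the
    tested sets; by default only sets with p_adj < alpha are returned,
    ranked by p_adj ascending (ties by name) and truncated to ``top_k``.
    """
    if not library:
        raise ValueError("empty gene-set library")
    universe_set = {g.upper() for g in universe}
    if not universe_set:
        raise ValueError("empty universe")
    query_set = {g.upper() for g in query}
    outside = query_set - universe_set
    if outside:
        log.warning("enrich: dropped %d query genes outside the universe",
                    len(outside))
        query_set &= universe_set

    N, n = len(universe_set), len(query_set)
    rows = []
    for name, gene_set in sorted(library.items()):
        members = {m.upper() for m in gene_set.members} & universe_set
        if not members:
            log.info("enrich: set %r has no member in the universe", name)
            continue
        overlap = members & query_set
        rows.append({
            "set_name": name,
            "overlap_count": len(overlap),
            "set_size": len(members),
            "query_size": n,
            "universe_size": N,
            "p_raw": hypergeom_upper(len(overlap), len(members), n, N),
            "overlap_members": ";".join(sorted(overlap)),
        })
    if not rows:
        raise ValueError("no library set intersects the universe")
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    table = table[ENRICH_COLUMNS]
    table = table.sort_values(["p_adj", "set_name"],
                              kind="stable").reset_index(drop=True)
    if return_all:
        return table
    hits = table[table["p_adj"] < alpha].reset_index(drop=True)
    return hits.head(top_k) if top_k is not None else hits


def load_builtin_library(name: str = "macrophage_no_response"
                         ) -> dict[str, GeneSet]:
    """Load a gene-set library shipped with the package.

    ``macrophage_no_response`` carries curated mouse sets used throughout
    the analyses: ETC complexes I-V (structural subunits), the COX assembly
    chaperones as a separate set, the 13 mitochondrially encoded subunits,
    V-ATPase subunits, and the denitrosylase enzymes.
    """
    path = resources.files("nitromics.datasets") / f"{name}.gmt"
    if not path.is_file():
        raise FileNotFoundError(f"no built-in library named {name!r}")
    return read_gmt(path)
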