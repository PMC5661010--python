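"""Metabolite set enrichment analysis (MSEA).

Over-representation of a metabolite list in pathway membership sets is
tested with the EASE-score variant of the one-tailed Fisher exact test: one
member is removed from the list∩pathway overlap before computing the
hypergeometric upper tail, which makes single-compound overlaps
non-significant by construction and the statistic conservative relative to
Fisher.  P-values are corrected across pathways by the Benjamini–Hochberg
step-up procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .data_model import PathwayLibrary

__all__ = [
    "EnrichmentRecord",
    "ease_fisher",
    "fisher_tail",
    "bh_adjust",
    "msea",
    "rank_pathway_table",
    "write_enrichment_table",
]

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    pathway_id: str
    name: str
    universe_n: int     # N
    pathway_k: int      # K
    list_n: int         # n
    overlap: int        # k
    fold_enrichment: float
    p_ease: float
    q_bh: float
    members_hit: list[str]


def _check_counts(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= min(n, K) and n >= 1 and K >= 1 and n <= N and K <= N):
        raise ValueError(
            f"invalid contingency counts: k={k}, n={n}, K={K}, N={N} "
            "(need 0 <= k <= min(n, K) <= N, n >= 1, K >= 1)"
        )


def fisher_tail(k: int, n: int, K: int, N: int) -> float:
    """Unmodified one-tailed Fisher exact p: P(X ≥ k) for X ~ Hypergeom(N, K, n)."""
    _check_counts(k, n, K, N)
    if k == 0:
        return 1.0
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def ease_fisher(k: int, n: int, K: int, N: int) -> float:
    """EASE-score p-value: the Fisher upper tail after removing one overlap.

    ``p = P(X ≥ k − 1)`` for ``X ~ Hypergeom(N, K, n)``; overlaps of 0 or 1
    give p = 1 exactly (the penalty saturates), so single-compound hits can
    never drive enrichment.
    """
    _check_counts(k, n, K, N)
    if k <= 1:
        return 1.0
    return float(min(1.0, hypergeom.sf(k - 2, N, K, n)))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values.

    ``q_(i) = min_{j >= i} (m p_(j) / j)`` capped at 1; input order preserved.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def msea(
    metabolites: Iterable[str],
    library: PathwayLibrary,
    min_overlap: int = 1,
) -> list[EnrichmentRecord]:
    """Enrichment of a metabolite (compound-ID) list against a pathway library.

    IDs absent from the universe are dropped with a warning.  One record per
    pathway with overlap ≥ ``min_overlap``; BH correction spans all tested
    pathways.  Output order is fully deterministic: ascending q, then p, then
    descending overlap, then pathway ID.
    """
    query = set(metabolites)
    dropped = query - library.universe
    if dropped:
        logger.warning(
            "%d metabolite IDs not in the enrichment universe were dropped (e.g. %s)",
            len(dropped), sorted(dropped)[:3],
        )
    query &= library.universe
    if not query:
        raise ValueError("no queried metabolites are present in the universe")
    N = len(library.universe)
    n = len(query)
    records: list[EnrichmentRecord] = []
    for pid in sorted(library.pathways):
        name, members = library.pathways[pid]
        hit = query & members
        k = len(hit)
        if k < min_overlap:
            continue
        K = len(members)
        records.append(
            EnrichmentRecord(
                pathway_id=pid,
                name=name,
                universe_n=N,
                pathway_k=K,
                list_n=n,
                overlap=k,
                fold_enrichment=(k / n) / (K / N),
                p_ease=ease_fisher(k, n, K, N),
                q_bh=np.nan,
                members_hit=sorted(hit),
            )
        )
    if not records:
        return records
    q = bh_adjust([r.p_ease for r in records])
    for r, qv in zip(records, q):
        r.q_bh = float(qv)
    records.sort(key=lambda r: (r.q_bh, r.p_ease, -r.overlap, r.pathway_id))
    return records


def rank_pathway_table(
    records: Sequence[EnrichmentRecord],
    library: PathwayLibrary | None = None,
) -> pd.DataFrame:
    """Tabulate enrichment results, grouped and ranked by pathway type.

    When the library carries pathway-type metadata, pathways are grouped by
    type and ranked within each type by the number of list metabolites they
    contain; without type metadata a single global ranking by overlap (then
    q-value) is produced.
    """
    if not records:
        raise ValueError("no enrichment records to tabulate")
    types = (library.types if library is not None else {}) or {}
    rows = []
    for r in records:
        rows.append(
            {
                "pathway_type": types.get(r.pathway_id, ""),
                "pathway_id": r.pathway_id,
                "name": r.name,
                "overlap": r.overlap,
                "pathway_size": r.pathway_k,
                "fold_enrichment": r.fold_enrichment,
                "p_ease": r.p_ease,
                "q_bh": r.q_bh,
                "members_hit": ";".join(r.members_hit),
            }
        )
    df = pd.DataFrame(rows)
    if any(types.get(r.pathway_id) for r in records):
        df = df.sort_values(
            ["pathway_type", "overlap", "q_bh", "pathway_id"],
            ascending=[True, False, True, True],
        ).reset_index(drop=True)
    else:
        df = df.sort_values(
            ["overlap", "q_bh", "pathway_id"], ascending=[False, True, True]
        ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def write_enrichment_table(records: Sequence[EnrichmentRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in records],
            "name": [r.name for r in records],
            "universe_n": [r.universe_n for r in records],
            "pathway_size": [r.pathway_k for r in records],
            "list_size": [r.list_n for r in records],
            "overlap": [r.overlap for r in records],
            "fold_enrichment": [r.fold_enrichment for r in records],
            "p_ease": [r.p_ease for r in records],
            "q_bh": [r.q_bh for r in records],
            "members_hit": [";".join(r.members_hit) for r in records],
        }
    ).to_csv(path, sep="\t", index=False)
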