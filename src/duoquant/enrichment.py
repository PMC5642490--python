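"""Direction-aware over-representation analysis of the consolidated list.

Each user-supplied gene set is scored with a right-tailed Fisher exact test
(hypergeometric tail) against a *quantified background* universe — by
default, everything that passed the detection filter in either engine.  A
set is flagged significant only when p < alpha AND at least ``min_overlap``
(default 3) query molecules map to it.

The activation z-score here is a transparent direction-consistency
statistic, (up - down)/sqrt(up + down) over the set's overlapping members.
It deliberately does not reproduce knowledge-base-weighted commercial
activation scores, which depend on curated edge signs.
"""

from __future__ import annotations

import math

import pandas as pd
from scipy import stats

from .io import GeneSetCollection

ENRICH_COLUMNS = [
    "set_name",
    "k",
    "K",
    "n",
    "N",
    "p_value",
    "z_score",
    "significant",
    "up_members",
    "down_members",
]


def fisher_right_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) (right-tailed Fisher).

    *k* overlap, *K* set size in universe, *n* query size, *N* universe size.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def direction_zscore(up_count: int, down_count: int) -> float:
    """Direction-consistency score ``(up - down) / sqrt(up + down)``."""
    if up_count < 0 or down_count < 0:
        raise ValueError("counts must be >= 0")
    total = up_count + down_count
    if total == 0:
        raise ValueError("z-score undefined for zero overlapping members")
    return (up_count - down_count) / math.sqrt(total)


def enrich_table(
    query_directions: dict[str, str],
    gene_sets: GeneSetCollection,
    universe: set[str],
    alpha: float = 0.05,
    min_overlap: int = 3,
    mapping: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Over-representation records for every gene set overlapping the query.

    ``query_directions`` maps each query identifier to ``up``/``down``.  With
    *mapping* given, both query and universe are translated (accession ->
    gene symbol); unmapped identifiers are dropped from both.  Set members
    are intersected with the universe before counting.  Records are sorted by
    (p-value, set name) for a deterministic order; sets disjoint from the
    query are omitted.
    """
    if mapping is not None:
        dropped = sum(1 for p in universe if p not in mapping)
        universe = {mapping[p] for p in universe if p in mapping}
        query_directions = {mapping[p]: d for p, d in query_directions.items() if p in mapping}
        if dropped:
            import logging

            logging.getLogger(__name__).info("enrichment: %d universe identifier(s) unmapped and dropped", dropped)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_directions) & universe
    n, N = len(query), len(universe)

    records = []
    for gs in gene_sets:
        members = gs.members & universe
        overlap = members & query
        if not overlap:
            continue
        k, K = len(overlap), len(members)
        p = fisher_right_tail(k, K, n, N)
        up = sorted(m for m in overlap if query_directions[m] == "up")
        down = sorted(m for m in overlap if query_directions[m] == "down")
        records.append(
            {
                "set_name": gs.name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": p,
                "z_score": direction_zscore(len(up), len(down)),
                "significant": (p < alpha) and (k >= min_overlap),
                "up_members": ";".join(up),
                "down_members": ";".join(down),
            }
        )
    table = pd.DataFrame(records, columns=ENRICH_COLUMNS)
    if not table.empty:
        table = table.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    return table
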