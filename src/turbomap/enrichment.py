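"""One-tailed Fisher exact (hypergeometric) gene-set enrichment.

Over-representation only: for an overlap of k between a query list of size n
and a set of size K in a background of N, p = P(X >= k) for
X ~ Hypergeometric(N, K, n), with fold enrichment (k/n)/(K/N). BH correction
is applied across all sets of a collection for single-list runs, and within
each query row for grid outputs (matching how per-dataset FDR is reported
in module-enrichment heatmaps).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneSetCollection, normalize_ids

logger = logging.getLogger("turbomap")

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    for thr, s in STAR_THRESHOLDS:
        if p < thr:
            return s
    return ""


def fet_one_tailed(k: int, n: int, K: int, N: int) -> tuple[float, float]:
    """Upper-tail hypergeometric p and fold enrichment.

    k: overlap, n: query size, K: set size, N: background size.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N and k >= max(0, n + K - N)):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    fold = (k / n) / (K / N) if n > 0 and K > 0 else 0.0
    return p, fold


def enrich_against_collection(
    query: Sequence[str],
    background: Sequence[str],
    collection: GeneSetCollection,
    adjust: str = "bh",
) -> pd.DataFrame:
    """FET of one query list against every set of a collection.

    Query identifiers outside the background are trimmed with a warning; set
    members are intersected with the background; sets with no member in the
    background are dropped. Rows sorted by p ascending.
    """
    from .dea import bh_adjust

    bg = set(normalize_ids(background))
    if not bg:
        raise ValueError("empty background")
    q = set(normalize_ids(query))
    outside = q - bg
    if outside:
        logger.warning("trimmed %d query ids outside background", len(outside))
        q &= bg

    N, n = len(bg), len(q)
    rows = []
    for s in collection:
        members = set(s.members) & bg
        if not members:
            logger.info("set %s has no members in background; dropped", s.name)
            continue
        K = len(members)
        k = len(q & members)
        p, fold = fet_one_tailed(k, n, K, N)
        rows.append((s.name, k, n, K, N, p, fold))
    out = pd.DataFrame(rows, columns=["set_name", "k", "n", "K", "N",
                                      "p_one_tailed", "fold"])
    if adjust == "bh" and len(out):
        out["fdr_bh"] = bh_adjust(out["p_one_tailed"].to_numpy())
    else:
        out["fdr_bh"] = out["p_one_tailed"]
    out["neg_log10_fdr"] = -np.log10(out["fdr_bh"])
    out["stars"] = out["fdr_bh"].map(stars)
    return out.sort_values("p_one_tailed", kind="stable").reset_index(drop=True)


def fet_grid(
    queries: Mapping[str, Sequence[str]],
    partitions: Mapping[str, Sequence[str]],
    background: Sequence[str],
    adjust: str = "bh",
) -> dict[str, pd.DataFrame]:
    """Enrichment grid: rows = query lists, columns = partition classes.

    Each cell is a one-tailed FET of the query against that partition's
    membership, all restricted to the background. ``adjust='bh'`` applies BH
    within each query row (per-dataset FDR); ``adjust='none'`` reports raw p.

    Returns dict with 'p' (adjusted p), 'neg_log10' and 'stars' DataFrames,
    plus 'raw_p' and 'overlap' counts.
    """
    bg = set(normalize_ids(background))
    if not bg:
        raise ValueError("empty background")
    part = {name: set(normalize_ids(m)) & bg for name, m in partitions.items()}
    part = {name: mem for name, mem in part.items() if mem}
    N = len(bg)

    raw = pd.DataFrame(index=list(queries), columns=list(part), dtype=float)
    overlap = raw.copy()
    for qname, qlist in queries.items():
        q = set(normalize_ids(qlist)) & bg
        n = len(q)
        for mname, members in part.items():
            k = len(q & members)
            p, _ = fet_one_tailed(k, n, len(members), N)
            raw.loc[qname, mname] = p
            overlap.loc[qname, mname] = k

    if adjust == "bh":
        from .dea import bh_adjust
        adj = raw.copy()
        for qname in adj.index:
            adj.loc[qname] = bh_adjust(raw.loc[qname].to_numpy())
    elif adjust == "none":
        adj = raw.copy()
    else:
        raise ValueError(f"unknown adjust mode {adjust!r}")

    return {
        "p": adj,
        "raw_p": raw,
        "neg_log10": -np.log10(adj),
        "stars": adj.map(stars),
        "overlap": overlap.astype(int),
    }
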