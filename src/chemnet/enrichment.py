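"""Over-representation analysis of gene lists against gene-set collections.

The test is the exact hypergeometric upper tail: for a universe of N
genes, a set of K and a query of n, the p-value of observing an overlap
of at least k.  Rows report, per set:

* fold enrichment (k/n)/(K/N) — the literal observed/expected ratio,
* z — the standardised hypergeometric deviation (k − nK/N)/sd,
* combined score c = z × (−ln p), the Enrichr-style ranking statistic,
* BH-adjusted p across the collection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeom_test", "bh_adjust", "enrich", "enrich_communities"]


def hypergeom_test(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail overlap p-value P(X >= k), X ~ Hypergeom(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Iterable[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def _hypergeom_z(N: int, K: int, n: int, k: int) -> float:
    mean = n * K / N
    if N <= 1:
        return 0.0
    var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1)
    if var <= 0:
        return 0.0
    return (k - mean) / math.sqrt(var)


def enrich(query: Iterable[str], collection: Mapping[str, Iterable[str]],
           universe: Iterable[str], *, use_adjusted_in_combined: bool = False,
           ) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each set.

    Sets are intersected with the universe before testing; the query
    must be a subset of the universe.  Returns one row per set with
    columns set / N / K / n / k / fold / p / p_adj / z / combined and
    overlap genes, sorted by p_adj then combined score descending then
    set id.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValueError("universe is empty")
    if not query:
        raise ValueError("query is empty")
    if not query <= universe:
        raise ValueError(f"query has {len(query - universe)} genes outside the universe")

    N, n = len(universe), len(query)
    rows = []
    for name in sorted(collection):
        members = set(collection[name]) & universe
        K = len(members)
        overlap = members & query
        k = len(overlap)
        p = hypergeom_test(N, K, n, k) if K else 1.0
        fold = (k / n) / (K / N) if K else 0.0
        z = _hypergeom_z(N, K, n, k)
        rows.append((name, N, K, n, k, fold, p, z, ",".join(sorted(overlap))))
    df = pd.DataFrame(rows, columns=["set", "N", "K", "n", "k", "fold", "p",
                                     "z", "genes"])
    df["p_adj"] = bh_adjust(df["p"])
    p_for_score = df["p_adj"] if use_adjusted_in_combined else df["p"]
    df["combined"] = df["z"] * (-np.log(p_for_score))
    df = df.sort_values(["p_adj", "combined", "set"],
                        ascending=[True, False, True], kind="mergesort")
    return df.reset_index(drop=True)[
        ["set", "N", "K", "n", "k", "fold", "p", "p_adj", "z", "combined", "genes"]]


def enrich_communities(partition, collection: Mapping[str, Iterable[str]],
                       universe: Iterable[str], *, min_size: int = 3,
                       ) -> pd.DataFrame:
    """Per-community over-representation (long table for bubble plots).

    ``partition`` is a mapping node -> community id or a
    :class:`chemnet.mapeq.Partition`.  Communities smaller than
    ``min_size`` are skipped and listed with status ``too_small``.
    Returns columns community / set / k / K / fold / z / combined /
    p / p_adj / status.
    """
    membership = getattr(partition, "membership", partition)
    universe_set = set(universe)
    comms: dict[int, set[str]] = {}
    for node, cid in membership.items():
        comms.setdefault(cid, set()).add(node)

    frames = []
    for cid in sorted(comms):
        genes = comms[cid] & universe_set
        if len(genes) < min_size:
            frames.append(pd.DataFrame([{
                "community": cid, "set": "", "k": 0, "K": 0, "fold": np.nan,
                "z": np.nan, "combined": np.nan, "p": np.nan, "p_adj": np.nan,
                "status": "too_small"}]))
            continue
        res = enrich(genes, collection, universe_set)
        res.insert(0, "community", cid)
        res["status"] = "tested"
        frames.append(res[["community", "set", "k", "K", "fold", "z",
                           "combined", "p", "p_adj", "status"]])
    return pd.concat(frames, ignore_index=True)
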