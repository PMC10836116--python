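"""Hypergeometric over-representation analysis of gene sets."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

__all__ = ["GeneSetCollection", "hypergeom_ora", "read_gmt"]


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a common universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    restricted: dict[str, set[str]] = field(init=False)

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("universe must be non-empty")
        self.restricted = {name: s & self.universe for name, s in self.sets.items()}


def hypergeom_ora(
    query: set[str],
    collection: GeneSetCollection,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in every set.

    With universe size N, set size K, query size n and overlap k:
    p = P(X >= k) for X ~ Hypergeom(N, K, n); enrichment ratio =
    (k/n)/(K/N).  BH across sets; ``passes`` iff FDR <= ``fdr_threshold``
    (inclusive).
    """
    dropped = query - collection.universe
    if dropped:
        warnings.warn(
            f"{len(dropped)} query genes outside the universe were dropped",
            stacklevel=2,
        )
    query = query & collection.universe
    if not query:
        raise ValueError("query is empty after restriction to the universe")
    N = len(collection.universe)
    n = len(query)
    rows = []
    for name, members in collection.restricted.items():
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        ratio = (k / n) / (K / N) if K else float("nan")
        rows.append({"set_name": name, "set_size": K, "overlap": k,
                     "enrichment_ratio": ratio, "p": p})
    df = pd.DataFrame(rows)
    df["fdr"] = stats.false_discovery_control(df["p"].clip(upper=1.0), method="bh")
    df["passes"] = df["fdr"] <= fdr_threshold
    return df.sort_values("p", ignore_index=True)


def read_gmt(path: str) -> dict[str, set[str]]:
    """Read GMT gene sets: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets
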