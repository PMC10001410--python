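"""Hypergeometric over-representation analysis of gene lists in named sets.

Given a query list of genes (e.g. everything differentially expressed in a
contrast) and a collection of named gene sets over a universe, each set is
tested for over-representation with the upper-tail hypergeometric test and
the q-value is the Benjamini-Hochberg adjusted p-value across the sets of
the collection (conservative, parameter-free); sets with q <= 0.1 are called
significant by default.  The collection is structural — any named sets work;
no ontology topology or term redundancy handling is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de import adjust_bh

__all__ = [
    "GeneSetCollection",
    "hypergeom_test",
    "run_ora",
    "read_gmt",
    "write_gmt",
]

DEFAULT_Q_THRESHOLD = 0.1


@dataclass
class GeneSetCollection:
    """Named gene sets over a universe of gene ids."""

    sets: dict[str, list[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        for name, members in self.sets.items():
            extra = set(members) - uni
            if extra:
                raise ValueError(
                    f"set {name!r} has {len(extra)} members outside the universe "
                    f"(e.g. {sorted(extra)[:3]})"
                )


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    X counts the overlap between a query of size n and a set of size K when
    the query is drawn uniformly without replacement from a universe of N.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if K > N or n > N:
        raise ValueError("set and query must fit inside the universe")
    return float(hypergeom.sf(k - 1, N, K, n))


def run_ora(
    query: list[str],
    collection: GeneSetCollection,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each set of the collection.

    Returns one row per set with columns set, k (overlap), K (set size),
    n (query size after reconciliation), N (universe size), gene_ratio (k/n),
    pvalue, qvalue (BH across the collection) and significant
    (qvalue <= q_threshold), sorted by pvalue then set name.  Query genes
    outside the universe are reported with a warning and dropped.
    """
    if not collection.universe:
        raise ValueError("empty universe")
    uni = set(collection.universe)
    query_set = {g for g in dict.fromkeys(query)}
    outside = query_set - uni
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped "
            f"(e.g. {sorted(outside)[:5]})",
            stacklevel=2,
        )
        query_set &= uni
    n, N = len(query_set), len(uni)

    rows = []
    for name in sorted(collection.sets):
        members = set(collection.sets[name])
        K = len(members)
        k = len(members & query_set)
        rows.append(
            {
                "set": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "gene_ratio": k / n if n else 0.0,
                "pvalue": hypergeom_test(k, K, n, N),
            }
        )
    table = pd.DataFrame(rows)
    table["qvalue"] = adjust_bh(table["pvalue"])
    table["significant"] = table["qvalue"] <= q_threshold
    table = table.sort_values(["pvalue", "set"], kind="mergesort").reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# GMT I/O (one set per line: name <tab> description <tab> gene1 <tab> ...)
# ---------------------------------------------------------------------------


def read_gmt(path, universe: list[str] | None = None) -> GeneSetCollection:
    """Read gene sets from a GMT file.

    When no universe is given, it defaults to the union of all set members.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, _desc, *genes = fields
            if name in sets:
                raise ValueError(f"duplicate set name {name!r}")
            sets[name] = [g for g in genes if g]
    if universe is None:
        universe = sorted({g for members in sets.values() for g in members})
    return GeneSetCollection(sets=sets, universe=list(universe))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            fh.write("\t".join([name, "na", *collection.sets[name]]) + "\n")
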