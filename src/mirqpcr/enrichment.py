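"""Gene-set over-representation analysis (ORA).

Given a query gene list (the mapped targets of the significant miRNAs) and a
collection of gene sets (GO terms, KEGG pathways, ... in GMT format), each
set is tested for over-representation with the hypergeometric upper tail:
drawing n query genes from a universe of N, the probability of seeing k or
more members of a set of size K is

    P(X >= k) = sum_{j=k}^{min(K,n)} C(K,j) C(N-K, n-j) / C(N,n).

P values are adjusted with Benjamini–Hochberg across all tested sets.  The
default universe is the union of all genes in the collection; pipelines
should intersect it with the genes reachable through the target table so the
background matches what the query could ever contain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .differential_expression import benjamini_hochberg
from .errors import EnrichmentError, FormatError


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions; membership is deduplicated."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    @property
    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return out

    def __len__(self) -> int:
        return len(self.sets)


def load_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (per line: name, description, member genes...).

    Lines with fewer than three fields raise :class:`FormatError` with the
    line number; empty sets (after dedup) are dropped with a warning.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "expected name, description, >=1 gene"
                )
            name, desc, *genes = fields
            name = name.strip()
            if name in sets:
                raise FormatError(f"{path}: duplicate set name {name!r} at line {lineno}")
            members = {g.strip() for g in genes if g.strip()}
            if not members:
                warnings.warn(f"{path}: set {name!r} is empty; dropped", stacklevel=2)
                continue
            sets[name] = members
            descriptions[name] = desc.strip()
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def hypergeometric_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    k: overlap, K: set size, n: query size, N: universe size.  Computed via
    the survival function, which works in log space internally.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need K, n <= N; got K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    genes,
    collection: GeneSetCollection,
    universe=None,
    *,
    min_set_size: int = 2,
    max_set_size: int = 2000,
    report_all: bool = False,
) -> pd.DataFrame:
    """Test every eligible gene set for over-representation of ``genes``.

    Sets are restricted to the universe and tested when their intersected
    size lies in [min_set_size, max_set_size].  BH adjustment runs across
    all tested sets; rows with zero overlap are reported only when
    ``report_all``.  Result is sorted by p value.

    Raises
    ------
    EnrichmentError
        When the query does not intersect the universe.
    """
    universe = set(universe) if universe is not None else collection.all_genes
    query = set(genes) & universe
    if not query:
        raise EnrichmentError(
            "query genes do not intersect the universe; check the universe choice "
            "(default: all genes in the gene-set collection)"
        )
    n, N = len(query), len(universe)

    rows = []
    for name, members in collection.sets.items():
        inset = members & universe
        K = len(inset)
        if not min_set_size <= K <= max_set_size:
            continue
        overlap = sorted(query & inset)
        k = len(overlap)
        rows.append(
            {
                "set_name": name,
                "description": collection.descriptions.get(name, ""),
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "p_value": hypergeometric_pvalue(k, K, n, N),
                "genes": "|".join(overlap),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "set_name", "description", "overlap", "set_size", "query_size",
                "universe_size", "p_value", "adj_p_value", "genes",
            ]
        )
    out = pd.DataFrame(rows)
    out["adj_p_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    if not report_all:
        out = out[out["overlap"] > 0]
    out = out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    return out[
        [
            "set_name", "description", "overlap", "set_size", "query_size",
            "universe_size", "p_value", "adj_p_value", "genes",
        ]
    ]


def default_universe(collection: GeneSetCollection, target_genes=None) -> set[str]:
    """Collection-wide gene union, optionally intersected with the genes
    reachable through the target table."""
    uni = collection.all_genes
    if target_genes is not None:
        uni = uni & set(target_genes)
    return uni
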