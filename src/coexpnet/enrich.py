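"""Gene-set over-representation analysis (ORA) and cross-network
process-membership accounting.

Per term the test is the hypergeometric upper tail: with a universe of N
genes of which K belong to the term, a query of n genes overlapping the
term in k, p = P(X >= k) for X ~ Hypergeom(N, K, n).  P-values are
adjusted across all tested terms with Benjamini-Hochberg FDR and a term
is called significant at adjusted p below the threshold (default 0.05).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets, e.g. one GO library parsed from a GMT file."""

    name: str
    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, term: str) -> frozenset[str]:
        return self.sets[term][1]


@dataclass
class EnrichmentResult:
    """One term's over-representation statistics."""

    term: str
    description: str
    k: int  #: overlap |term & query|
    K: int  #: term size within the universe
    n: int  #: query size
    N: int  #: universe size
    p: float
    p_adj: float
    significant: bool
    overlap_genes: frozenset[str]


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Parse a GMT file (term <TAB> description <TAB> gene ...).

    Gene symbols are upper-cased and de-duplicated within a line; blank
    lines are ignored; a line with fewer than three fields is a format
    error reported with its line number.
    """
    path = Path(path)
    collection = GeneSetCollection(name if name is not None else path.stem)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs term, description and at "
                    f"least one gene ({len(fields)} field(s) found)"
                )
            term, description = fields[0], fields[1]
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise ValueError(f"{path}:{lineno}: term {term!r} has no genes")
            if term in collection.sets:
                raise ValueError(f"{path}:{lineno}: duplicate term id {term!r}")
            collection.sets[term] = (description, genes)
    return collection


def enrich(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str],
    threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric ORA of a gene set against every term of a library.

    Query genes outside the universe are dropped with a warning; terms
    with no gene in the universe are skipped; an empty query yields an
    empty result list.  BH adjustment runs over all tested terms.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    universe = {g.upper() for g in universe}
    query = {g.upper() for g in query}
    outside = query - universe
    if outside:
        logger.warning(
            "dropping %d query gene(s) outside the universe: %s%s",
            len(outside), sorted(outside)[:5], "..." if len(outside) > 5 else "",
        )
        query &= universe
    if not query:
        logger.info("empty query after universe restriction; no enrichment computed")
        return []

    big_n, small_n = len(universe), len(query)
    rows = []
    for term, (description, genes) in collection.sets.items():
        in_universe = genes & universe
        if not in_universe:
            continue
        overlap = in_universe & query
        big_k, k = len(in_universe), len(overlap)
        p = float(hypergeom.sf(k - 1, big_n, big_k, small_n))
        rows.append((term, description, k, big_k, p, frozenset(overlap)))
    if not rows:
        return []
    reject, p_adj, _, _ = multipletests(
        [r[4] for r in rows], alpha=threshold, method="fdr_bh"
    )
    results = [
        EnrichmentResult(
            term=term, description=desc, k=k, K=big_k, n=small_n, N=big_n,
            p=p, p_adj=float(q), significant=bool(q < threshold),
            overlap_genes=overlap,
        )
        for (term, desc, k, big_k, p, overlap), q in zip(rows, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adj, r.p, r.term))
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term, "description": r.description,
                "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                "p": r.p, "p_adj": r.p_adj, "significant": r.significant,
                "genes": ";".join(sorted(r.overlap_genes)),
            }
            for r in results
        ]
    )


def process_membership(
    results_by_network: dict[str, set[str]],
) -> tuple[dict[str, frozenset[str]], Counter]:
    """Which networks each significant term belongs to (UpSet-style).

    Returns per-term network membership and the count of terms for every
    observed network combination; combination counts sum to the number
    of distinct significant terms.
    """
    if not results_by_network:
        raise ValueError("need results for at least one network")
    membership: dict[str, frozenset[str]] = {}
    all_terms = set().union(*results_by_network.values())
    for term in all_terms:
        membership[term] = frozenset(
            net for net, terms in results_by_network.items() if term in terms
        )
    combo_counts = Counter(membership.values())
    return membership, combo_counts


def membership_frame(membership: dict[str, frozenset[str]]) -> pd.DataFrame:
    rows = [
        {"term": term, "n_networks": len(nets), "networks": ";".join(sorted(nets))}
        for term, nets in sorted(membership.items())
    ]
    return pd.DataFrame(rows)
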