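"""Conditional hypergeometric over-representation testing on a term DAG.

Terms annotate genes directly and, through the DAG, inherit the genes of
their descendants (effective gene set = union over the term and all its
descendants). The conditional test walks the DAG children-before-parents:
once a descendant term is significant, its genes are removed from every
ancestor's gene set and from that ancestor's universe copy before the
ancestor is tested, so parents are not called merely because a specific
child already explains the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

__all__ = ["TermAnnotation", "hypergeom_upper", "conditional_enrichment"]


class StructureError(ValueError):
    """Raised for cyclic or otherwise malformed term DAGs."""


@dataclass
class TermAnnotation:
    """Gene-to-term annotation with a term DAG.

    Attributes
    ----------
    direct : dict
        term id -> set of directly annotated genes.
    parents : dict
        term id -> set of parent term ids (DAG edges child -> parent).
    universe : set
        All genes under consideration; every annotated gene must belong.
    """

    direct: dict[str, set[str]]
    parents: dict[str, set[str]] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not self.universe:
            self.universe = set().union(*self.direct.values()) if self.direct else set()
        stray = set().union(*self.direct.values()) - self.universe if self.direct else set()
        if stray:
            raise ValueError(f"annotated genes outside the universe: {sorted(stray)[:5]}")

    def graph(self) -> nx.DiGraph:
        """Parent -> child digraph over all terms; raises on cycles."""
        g = nx.DiGraph()
        g.add_nodes_from(self.direct)
        for child, ps in self.parents.items():
            for p in ps:
                g.add_edge(p, child)
        if not nx.is_directed_acyclic_graph(g):
            raise StructureError("term DAG contains a cycle")
        return g

    def effective_genes(self, term: str, graph: nx.DiGraph | None = None) -> set[str]:
        """Union of the term's direct genes and those of all descendants."""
        g = graph if graph is not None else self.graph()
        genes = set(self.direct.get(term, set()))
        for d in nx.descendants(g, term):
            genes |= self.direct.get(d, set())
        return genes


def hypergeom_upper(k: int, n: int, K_term: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts query-term overlaps when ``n`` genes are drawn without
    replacement from a universe of ``N`` genes of which ``K_term`` carry
    the term.
    """
    if not (0 <= K_term <= N and 0 <= n <= N):
        raise ValueError(f"impossible margins: n={n}, K_term={K_term}, N={N}")
    if not (max(0, n + K_term - N) <= k <= min(n, K_term)):
        raise ValueError(
            f"impossible overlap k={k} for n={n}, K_term={K_term}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K_term, n))


def conditional_enrichment(
    query: set[str],
    annotation: TermAnnotation,
    child_cutoff: float = 0.05,
    bh: bool = False,
) -> pd.DataFrame:
    """Conditional hypergeometric over-representation of ``query``.

    Terms are processed children-before-parents. A term whose conditional p
    falls below ``child_cutoff`` is significant; its effective genes are
    excluded from each ancestor's gene set and universe copy before the
    ancestor is tested. Rows are returned for every term overlapping the
    query (raw k >= 1), sorted by conditional p.

    With ``bh=True`` a Benjamini-Hochberg adjusted column ``q`` is added
    (the raw over-representation report carries no correction by default).
    """
    query = set(query)
    stray = query - annotation.universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    graph = annotation.graph()
    order = list(reversed(list(nx.topological_sort(graph))))  # children first

    significant: dict[str, set[str]] = {}  # term -> its effective genes
    rows = []
    for term in order:
        eff = annotation.effective_genes(term, graph)
        k_raw = len(query & eff)
        p_raw = hypergeom_upper(
            k_raw, len(query), len(eff), len(annotation.universe)
        )
        # genes explained by already-significant descendants of this term
        removed: set[str] = set()
        for d in nx.descendants(graph, term):
            if d in significant:
                removed |= significant[d]
        term_genes = eff - removed
        universe_c = annotation.universe - removed
        query_c = query & universe_c
        k = len(query_c & term_genes)
        p_cond = hypergeom_upper(k, len(query_c), len(term_genes), len(universe_c))
        if p_cond < child_cutoff:
            significant[term] = eff
        if k_raw >= 1:
            rows.append(
                {
                    "term": term,
                    "k": k,
                    "n": len(query_c),
                    "K_term": len(term_genes),
                    "N": len(universe_c),
                    "p_raw": p_raw,
                    "p_conditional": p_cond,
                    "significant": p_cond < child_cutoff,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["term", "k", "n", "K_term", "N", "p_raw", "p_conditional", "significant"],
    )
    out = out.sort_values("p_conditional", kind="stable").reset_index(drop=True)
    if bh and len(out):
        from statsmodels.stats.multitest import multipletests

        out["q"] = multipletests(out["p_conditional"], method="fdr_bh")[1]
    return out
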