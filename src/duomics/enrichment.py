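"""Term over-representation analysis with kappa-based term grouping.

Right-sided hypergeometric tests per annotation term, Holm (Bonferroni
step-down) family-wise correction across the tested terms, and grouping of
redundant terms by Cohen's kappa agreement between their gene-membership
vectors: terms whose pairwise kappa reaches the threshold are linked, the
connected components form term groups, and each group is represented by
its most significant ("leading") term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TermSet:
    term_id: str
    term_name: str
    genes: frozenset
    ontology_source: str = ""

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"term {self.term_id!r} has no genes")


def read_gmt(path) -> list[TermSet]:
    """Read a GMT file (term, description, genes...)."""
    terms = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms.append(
                TermSet(term_id=parts[0], term_name=parts[1], genes=frozenset(g for g in parts[2:] if g))
            )
    return terms


def write_gmt(terms: list[TermSet], path) -> None:
    with open(path, "w") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, t.term_name, *sorted(t.genes)]) + "\n")


def hypergeom_right_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K marked, n drawn).

    Computed through the survival function (log-space internals), exact 1.0
    at k = 0.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def adjust_holm(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (original order kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def enrich_terms(
    query_genes,
    terms: list[TermSet],
    universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Right-sided hypergeometric over-representation of each term in the query.

    The universe defines N; term and query memberships are intersected with
    it.  Terms with no query overlap (k = 0) are skipped before correction,
    so m is the number of actually tested terms (logged).  Returns a
    DataFrame with one row per tested term and a ``significant`` flag at
    ``p_adj <= alpha``.
    """
    universe = frozenset(universe)
    query = frozenset(query_genes) & universe
    if not query:
        raise ValueError("query is empty (after intersecting with the universe)")
    N, n = len(universe), len(query)

    rows = []
    skipped = 0
    for t in terms:
        tg = t.genes & universe
        k = len(query & tg)
        if k == 0:
            skipped += 1
            continue
        K = len(tg)
        rows.append(
            {
                "term_id": t.term_id,
                "term_name": t.term_name,
                "ontology_source": t.ontology_source,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_raw": hypergeom_right_tail(k, K, n, N),
            }
        )
    if skipped:
        logger.info("%d terms with no query overlap skipped before correction", skipped)
    res = pd.DataFrame(rows)
    if res.empty:
        res = pd.DataFrame(columns=["term_id", "term_name", "ontology_source", "k", "K", "n", "N", "p_raw", "p_adj", "significant"])
        return res
    res["p_adj"] = adjust_holm(res["p_raw"].to_numpy())
    res["significant"] = res["p_adj"] <= alpha
    return res.sort_values(["p_adj", "p_raw", "term_id"]).reset_index(drop=True)


def kappa_score(term_a, term_b, universe) -> float:
    """Cohen's kappa between two terms' binary gene-membership vectors.

    kappa = (p_o - p_e) / (1 - p_e) over the universe; 1 for identical
    terms, negative for systematic disagreement.  When p_e = 1 (both terms
    equal the whole universe) kappa is defined as 1 for identical terms and
    an error otherwise.
    """
    universe = frozenset(universe)
    a = frozenset(term_a) & universe
    b = frozenset(term_b) & universe
    if not a or not b:
        raise ValueError("terms must be non-empty within the universe")
    N = len(universe)
    n11 = len(a & b)
    n00 = N - len(a | b)
    p_o = (n11 + n00) / N
    pa, pb = len(a) / N, len(b) / N
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e == 1.0:
        if a == b:
            return 1.0
        raise ValueError("kappa undefined: chance agreement is 1 for differing terms")
    return (p_o - p_e) / (1.0 - p_e)


def group_terms(
    results: pd.DataFrame,
    terms: list[TermSet],
    universe,
    kappa_threshold: float = 0.4,
) -> pd.DataFrame:
    """Group redundant terms by membership agreement.

    Builds a graph over the tested terms with an edge wherever pairwise
    kappa >= threshold; connected components become groups.  The leading
    term of a group is the one with smallest adjusted p (ties: larger term
    size K, then lexicographic term id).  Adds ``group_id`` and
    ``is_leading`` columns.
    """
    out = results.copy()
    if out.empty:
        out["group_id"] = []
        out["is_leading"] = []
        return out
    by_id = {t.term_id: t for t in terms}
    ids = list(out["term_id"])
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, ti in enumerate(ids):
        for tj in ids[i + 1 :]:
            if kappa_score(by_id[ti].genes, by_id[tj].genes, universe) >= kappa_threshold:
                g.add_edge(ti, tj)

    out = out.set_index("term_id")
    out["group_id"] = -1
    out["is_leading"] = False
    # deterministic group numbering: components ordered by their best term
    comps = []
    for comp in nx.connected_components(g):
        members = out.loc[sorted(comp)]
        lead = members.sort_values(
            ["p_adj", "K", "term_id"], ascending=[True, False, True]
        ).index[0]
        comps.append((out.at[lead, "p_adj"], lead, sorted(comp)))
    for gid, (_, lead, comp) in enumerate(sorted(comps, key=lambda c: (c[0], c[1]))):
        out.loc[comp, "group_id"] = gid
        out.at[lead, "is_leading"] = True
    return out.reset_index()


def barchart_table(results: pd.DataFrame) -> pd.DataFrame:
    """Significant terms with -log10(adjusted p), ready for bar plotting."""
    sig = results[results["significant"]].copy()
    with np.errstate(divide="ignore"):
        sig["neg_log10_p_adj"] = -np.log10(sig["p_adj"])
    return sig[["term_id", "term_name", "k", "neg_log10_p_adj"]]
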