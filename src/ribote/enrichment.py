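"""Hypergeometric term enrichment with kappa-score grouping of enriched terms.

Enrichment of a functional term (COG class, KEGG pathway, GO id) in a DEG
set is tested with the upper tail of the hypergeometric distribution over
the annotated universe, BH-adjusted across terms.  Enriched terms are then
grouped by chance-corrected agreement of their gene memberships: pairwise
Cohen's kappa over binary membership vectors, a graph with edges at
kappa >= 0.4, and connected components as groups.  A term that is an
articulation point of its component (removing it disconnects the
remaining terms) additionally carries the identities of the parts it
bridges — the analogue of a node shared by two groups in a term network.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from scipy import stats as sps

from .de import benjamini_hochberg
from .io_formats import ValidationError

DEFAULT_KAPPA_THRESHOLD = 0.4
DEFAULT_K_MIN = 3


def invert_annotation(gene_terms: dict[str, set]) -> dict[str, set]:
    """gene -> terms mapping inverted to term -> genes."""
    out: dict[str, set] = {}
    for gene, terms in gene_terms.items():
        for t in terms:
            out.setdefault(t, set()).add(gene)
    return out


def read_annotation_table(path) -> dict[str, set]:
    """Two-column TSV (gene_id, term_id) -> gene -> set of terms."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["gene_id", "term_id"], dtype=str)
    out: dict[str, set] = {}
    for r in df.itertuples():
        out.setdefault(r.gene_id, set()).add(r.term_id)
    return out


def hypergeom_enrich(deg_set, gene_terms: dict[str, set],
                     universe=None, k_min: int = DEFAULT_K_MIN) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term in the DEG set.

    ``universe`` defaults to all annotated genes in ``gene_terms``; the DEG
    set is intersected with it.  Terms annotating fewer than ``k_min``
    universe genes are excluded.  Columns follow the k/K/n/N convention:
    k DEGs with the term, K universe genes with the term, n DEGs, N
    universe size.
    """
    if universe is None:
        universe = set(gene_terms)
    universe = set(universe)
    degs = set(deg_set) & universe
    N, n = len(universe), len(degs)
    if N == 0:
        raise ValidationError("empty annotation universe")
    term_genes = invert_annotation(
        {g: t for g, t in gene_terms.items() if g in universe})
    rows = []
    for term in sorted(term_genes):
        members = term_genes[term]
        K = len(members)
        if K < k_min:
            continue
        k = len(members & degs)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    df = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p"])
    if len(df):
        df["p_adj"] = benjamini_hochberg(df["p"])
    else:
        df["p_adj"] = np.array([], dtype=float)
    return df


def cohens_kappa(genes_a: set, genes_b: set, universe: set) -> float:
    """Chance-corrected agreement of two binary gene memberships."""
    N = len(universe)
    if N == 0:
        raise ValidationError("empty universe for kappa")
    a = len(genes_a & genes_b)                       # in both
    b = len((genes_a - genes_b) & universe)          # only A
    c = len((genes_b - genes_a) & universe)          # only B
    d = N - a - b - c                                # in neither
    po = (a + d) / N
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (N * N)
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


def kappa_matrix(term_genes: dict[str, set], universe: set) -> pd.DataFrame:
    """Symmetric term x term Cohen's kappa matrix (diagonal 1)."""
    terms = sorted(term_genes)
    restricted = {t: term_genes[t] & universe for t in terms}
    m = np.eye(len(terms))
    for i, ti in enumerate(terms):
        for j in range(i + 1, len(terms)):
            k = cohens_kappa(restricted[ti], restricted[terms[j]], universe)
            m[i, j] = m[j, i] = k
    return pd.DataFrame(m, index=terms, columns=terms)


def kappa_cluster(term_genes: dict[str, set], universe: set,
                  kappa_threshold: float = DEFAULT_KAPPA_THRESHOLD
                  ) -> pd.DataFrame:
    """Group terms by connected components of the kappa >= threshold graph.

    Returns a table with ``term_id``, ``group_id`` (components numbered by
    their lexicographically smallest member; singletons allowed) and
    ``bridges`` — for articulation-point terms, the number of parts the
    term holds together (0 otherwise).  Group assignment is invariant to
    term order.
    """
    km = kappa_matrix(term_genes, universe)
    terms = list(km.index)
    graph = nx.Graph()
    graph.add_nodes_from(terms)
    for i, ti in enumerate(terms):
        for tj in terms[i + 1:]:
            if km.loc[ti, tj] >= kappa_threshold:
                graph.add_edge(ti, tj)
    components = sorted((sorted(c) for c in nx.connected_components(graph)),
                        key=lambda c: c[0])
    group_of = {}
    for gid, comp in enumerate(components):
        for t in comp:
            group_of[t] = gid
    articulation = set(nx.articulation_points(graph))
    rows = []
    for t in sorted(terms):
        n_bridged = 0
        if t in articulation:
            sub = graph.subgraph([x for x in graph if x != t])
            comp_members = [x for x in components[group_of[t]] if x != t]
            n_bridged = len({frozenset(nx.node_connected_component(sub, x))
                             for x in comp_members})
        rows.append({"term_id": t, "group_id": group_of[t],
                     "group_size": len(components[group_of[t]]),
                     "bridges": n_bridged})
    return pd.DataFrame(rows)
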