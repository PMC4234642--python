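"""Ranked-list gene-set enrichment: GO propagation, partition scan, BH-FDR.

Given a gene list ordered by differential expression, the scan slides a rank
cut across evenly spaced partitions and tests, for every GO term, the 2x2
table (annotated vs not) x (above vs below cut) with Fisher's exact test.
Annotations are first propagated up the GO DAG (a gene annotated to a term
is annotated to all its ancestors up to the root), and all term x partition
p-values are adjusted jointly with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class AnnotationMap:
    """Gene -> GO-term sets plus the GO DAG as a (child, parent) edge list."""

    gene_to_terms: dict[str, set[str]]
    dag_edges: list[tuple[str, str]] = field(default_factory=list)

    def terms(self) -> set[str]:
        out: set[str] = set()
        for s in self.gene_to_terms.values():
            out |= s
        return out


def propagate_annotations(amap: AnnotationMap) -> AnnotationMap:
    """Replace each gene's term set by its ancestral closure in the DAG.

    Raises on a cyclic ontology, naming one cycle.  Terms without recorded
    parents (including the root) propagate only to themselves.
    """
    g = nx.DiGraph()
    g.add_edges_from(amap.dag_edges)  # child -> parent
    if g.number_of_edges() and not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"annotation ontology contains a cycle: {cycle}")
    closure: dict[str, set[str]] = {}
    for node in nx.topological_sort(g.reverse()) if g.number_of_nodes() else []:
        anc = set()
        for parent in g.successors(node):
            anc.add(parent)
            anc |= closure.get(parent, set())
        closure[node] = anc
    new_map = {
        gene: set().union(terms, *(closure.get(t, set()) for t in terms))
        for gene, terms in amap.gene_to_terms.items()
    }
    return AnnotationMap(gene_to_terms=new_map, dag_edges=list(amap.dag_edges))


def rank_genes(table: pd.DataFrame, stat_col: str = "stat", id_col: str = "gene_id") -> pd.DataFrame:
    """Order a gene table by decreasing statistic, ties broken by gene id."""
    if table[id_col].duplicated().any():
        dups = table.loc[table[id_col].duplicated(), id_col].tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    return (
        table.sort_values([stat_col, id_col], ascending=[False, True])
        .reset_index(drop=True)
    )


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """(two-sided Fisher p, one-sided upper-tail hypergeometric p) for
    table [[a, b], [c, d]] with a = annotated above the cut."""
    _, p_two = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    n, big_k, cut = a + b + c + d, a + c, a + b
    p_one = float(sps.hypergeom.sf(a - 1, n, big_k, cut))
    return float(p_two), p_one


def partition_scan(
    ranked: pd.DataFrame,
    amap: AnnotationMap,
    n_partitions: int = 30,
    *,
    propagate: bool = True,
    stat_col: str = "stat",
    id_col: str = "gene_id",
) -> pd.DataFrame:
    """Fisher's exact test of every term at every sliding rank cut, BH-adjusted.

    Returns one row per (term, partition) with the 2x2 counts, direction of
    over-representation, percent annotated above/below the cut, raw two-sided
    and one-sided p, and the jointly BH-adjusted p.  Genes absent from the
    annotation map count as unannotated; terms annotating no list gene are
    skipped with a log entry.
    """
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")
    ranked = rank_genes(ranked, stat_col=stat_col, id_col=id_col)
    if propagate and amap.dag_edges:
        amap = propagate_annotations(amap)
    genes = ranked[id_col].tolist()
    n = len(genes)
    terms = sorted(amap.terms())
    ann = {
        t: np.array([t in amap.gene_to_terms.get(g, ()) for g in genes], dtype=bool)
        for t in terms
    }
    for t in terms:
        if not ann[t].any():
            log.info("term %s annotates no gene in the list; skipped", t)
    terms = [t for t in terms if ann[t].any()]
    cuts = sorted(
        {
            int(round(i * n / (n_partitions + 1)))
            for i in range(1, n_partitions + 1)
        }
    )
    cuts = [c for c in cuts if 1 <= c <= n - 1]
    rows = []
    for term in terms:
        v = ann[term]
        csum = np.concatenate([[0], np.cumsum(v)])
        big_k = int(v.sum())
        for j, cut in enumerate(cuts):
            a = int(csum[cut])
            b = cut - a
            c = big_k - a
            d = n - cut - c
            p_two, p_one = fisher_2x2(a, b, c, d)
            pct_above = 100.0 * a / cut
            pct_below = 100.0 * c / (n - cut)
            rows.append(
                {
                    "term": term,
                    "partition": j,
                    "cut_rank": cut,
                    "n_annotated_above": a,
                    "n_unannotated_above": b,
                    "n_annotated_below": c,
                    "n_unannotated_below": d,
                    "pct_annotated_above": pct_above,
                    "pct_annotated_below": pct_below,
                    "direction": "up" if pct_above >= pct_below else "down",
                    "p_raw": p_two,
                    "p_one_sided_up": p_one,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    return out


def summarize_terms(scan: pd.DataFrame) -> pd.DataFrame:
    """Per-term summary: the partition with the minimum adjusted p."""
    idx = scan.groupby("term")["p_adj"].idxmin()
    return scan.loc[idx].sort_values("p_adj").reset_index(drop=True)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# packaged fixtures


def load_mband_genes() -> pd.DataFrame:
    """The five M-band (GO:0031430) genes with their reported fold changes."""
    with resources.files("sarcoshg.data").joinpath("mband_genes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_synthetic_go_cc() -> list[tuple[str, str]]:
    """Synthetic miniature of the GO cellular-component hierarchy around the
    M-band term, as (child, parent) edges.  A stand-in for the real ontology,
    structured like the M-band lineage up to the cellular_component root."""
    with resources.files("sarcoshg.data").joinpath("synthetic_go_cc_edges.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return list(df.itertuples(index=False, name=None))
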