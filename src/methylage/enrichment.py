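"""GO-BP over-representation, ancestor collapsing and marker selection.

Enriched Biological Process terms (one-sided hypergeometric test with
Benjamini-Hochberg FDR) are collapsed onto high-level ancestor
"supra-categories" reached through ``is_a`` edges of the ontology DAG.
The ancestor x gene incidence table then drives the final candidate-marker
cascade: keep genes involved in at least ``min_functions`` processes, then
keep those with a differentially methylated window in a regulatory region
(promoter, first exon or first intron).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd
from scipy import stats

from .diff_expression import bh_adjust

MIN_FUNCTIONS = 4
DEFAULT_ANCESTOR_LEVEL = 2


# ---------------------------------------------------------------------------
# Ontology and annotation
# ---------------------------------------------------------------------------

@dataclass
class GOAnnotation:
    """Ontology DAG plus term -> gene annotation sets.

    ``dag`` is a directed graph with edges pointing child -> parent
    (``is_a`` only); annotations map term id -> set of gene symbols, with
    the convention that annotating a term annotates the term only (callers
    who want transitive annotation propagate it explicitly).
    """

    dag: nx.DiGraph
    term_genes: dict[str, set[str]]
    term_names: dict[str, str]

    def genes_for(self, term: str) -> set[str]:
        return self.term_genes.get(term, set())


def load_obo(path: str | Path) -> tuple[nx.DiGraph, dict[str, str]]:
    """Read an OBO ontology keeping only ``is_a`` edges (child -> parent)."""
    import obonet

    multi = obonet.read_obo(str(path))
    dag = nx.DiGraph()
    names = {}
    for node, data in multi.nodes(data=True):
        dag.add_node(node)
        names[node] = data.get("name", node)
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            dag.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("ontology is_a graph is cyclic")
    return dag, names


def load_annotation(
    path: str | Path, dag: nx.DiGraph, term_names: dict[str, str] | None = None
) -> GOAnnotation:
    """Read a GAF-like two-column TSV (gene, term) into a GOAnnotation."""
    df = pd.read_csv(path, sep="\t", comment="!", header=None, usecols=[0, 1])
    term_genes: dict[str, set[str]] = {}
    for gene, term in df.itertuples(index=False):
        term_genes.setdefault(str(term), set()).add(str(gene))
    return GOAnnotation(dag, term_genes, term_names or {})


def term_level(dag: nx.DiGraph, term: str, root: str) -> int:
    """Shortest is_a path length from term up to the root."""
    return nx.shortest_path_length(dag, term, root)


def find_root(dag: nx.DiGraph) -> str:
    roots = [n for n in dag.nodes if dag.out_degree(n) == 0]
    if len(roots) != 1:
        raise ValueError(f"expected a single ontology root, found {roots}")
    return roots[0]


# ---------------------------------------------------------------------------
# Over-representation
# ---------------------------------------------------------------------------

def hypergeometric_enrichment(
    gene_set: set[str],
    background: set[str],
    annotation: GOAnnotation,
    fdr_threshold: float | None = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term.

    With N background genes, K of them annotated to the term, and a query
    of n genes of which k are annotated, ``p = P(X >= k)`` for
    hypergeometric X.  Terms with no annotated background gene are
    skipped; BH FDR runs across all tested terms.  Returns all tested
    terms (filter on ``fdr`` afterwards, or pass ``fdr_threshold`` to get
    the significant slice via ``df[df.significant]``).
    """
    if not background:
        raise ValueError("empty background universe")
    extra = gene_set - background
    if extra:
        raise ValueError(f"gene set not contained in background: {sorted(extra)[:5]}")
    N = len(background)
    n = len(gene_set)
    rows = []
    for term in sorted(annotation.term_genes):
        annotated = annotation.term_genes[term] & background
        K = len(annotated)
        if K == 0:
            continue
        overlap = annotation.term_genes[term] & gene_set
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "name": annotation.term_names.get(term, term),
                "n_background": K,
                "n_overlap": k,
                "genes": ",".join(sorted(overlap)),
                "pvalue": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["fdr"] = bh_adjust(df["pvalue"].to_numpy())
    if fdr_threshold is not None:
        df["significant"] = df["fdr"] < fdr_threshold
    return df


# ---------------------------------------------------------------------------
# Ancestor collapsing
# ---------------------------------------------------------------------------

def ancestors_at_level(
    dag: nx.DiGraph, term: str, root: str, level: int
) -> set[str]:
    """Ancestors of ``term`` (inclusive) sitting at ``level`` below the root.

    A term's level is the shortest is_a path to the root; ancestors are all
    nodes reachable from the term by is_a edges, plus the term itself.
    """
    if term not in dag:
        return set()
    reach = nx.descendants(dag, term) | {term}
    return {
        t for t in reach if t != root and term_level(dag, t, root) == level
    }


def collapse_to_ancestors(
    enriched: pd.DataFrame,
    dag: nx.DiGraph,
    ancestor_level: int = DEFAULT_ANCESTOR_LEVEL,
    root: str | None = None,
    gene_directions: pd.Series | None = None,
    term_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Map enriched terms to supra-category ancestors; union genes per ancestor.

    Returns one row per ancestor with the union of contributing genes,
    sorted by descending gene count, with up/down splits when
    ``gene_directions`` is given.  Terms absent from the DAG are skipped
    with a warning.
    """
    if root is None:
        root = find_root(dag)
    ancestor_genes: dict[str, set[str]] = {}
    for r in enriched.itertuples():
        if r.term not in dag:
            warnings.warn(
                f"term {r.term} absent from ontology; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        genes = set(r.genes.split(",")) if r.genes else set()
        for anc in ancestors_at_level(dag, r.term, root, ancestor_level):
            ancestor_genes.setdefault(anc, set()).update(genes)
    rows = []
    for anc, genes in ancestor_genes.items():
        row = {
            "ancestor": anc,
            "name": (term_names or {}).get(anc, anc),
            "n_genes": len(genes),
            "genes": ",".join(sorted(genes)),
        }
        if gene_directions is not None:
            row["n_up"] = sum(gene_directions.get(g) == "up" for g in genes)
            row["n_down"] = sum(gene_directions.get(g) == "down" for g in genes)
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["n_genes", "ancestor"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Incidence table and marker selection
# ---------------------------------------------------------------------------

@dataclass
class IncidenceTable:
    """Process x gene membership with per-gene direction/regulatory flags."""

    membership: pd.DataFrame          # bool, rows = processes, cols = genes
    gene_direction: pd.Series         # gene -> up | down
    gene_regulatory: pd.Series        # gene -> bool

    @property
    def function_counts(self) -> pd.Series:
        """Number of processes per gene (column sums)."""
        return self.membership.sum(axis=0).astype(int)

    @property
    def process_counts(self) -> pd.Series:
        return self.membership.sum(axis=1).astype(int)


@dataclass(frozen=True)
class CandidateMarker:
    gene_symbol: str
    direction: str
    n_functions: int
    regulatory: bool


def build_incidence(
    ancestor_table: pd.DataFrame,
    genes: list[str],
    gene_direction: pd.Series,
    gene_regulatory: pd.Series,
) -> IncidenceTable:
    """Boolean incidence from an ancestor table restricted to ``genes``."""
    genes = sorted(genes)
    rows = {}
    for r in ancestor_table.itertuples():
        members = set(r.genes.split(",")) if r.genes else set()
        name = getattr(r, "name", r.ancestor)
        rows[name] = [g in members for g in genes]
    membership = pd.DataFrame.from_dict(
        rows, orient="index", columns=genes
    ).astype(bool)
    return IncidenceTable(
        membership,
        gene_direction.reindex(genes),
        gene_regulatory.reindex(genes, fill_value=False).astype(bool),
    )


def select_markers(
    incidence: IncidenceTable,
    min_functions: int = MIN_FUNCTIONS,
    require_regulatory: bool = True,
) -> list[CandidateMarker]:
    """Apply the multifunction then regulatory filters.

    Keeps genes with >= ``min_functions`` processes, then (optionally)
    those with a DM mark in a regulatory region, in a stable order of
    descending function count with alphabetical tie-break.
    """
    counts = incidence.function_counts
    keep = counts[counts >= min_functions]
    markers = []
    for gene in sorted(keep.index, key=lambda g: (-keep[g], g)):
        regulatory = bool(incidence.gene_regulatory.get(gene, False))
        if require_regulatory and not regulatory:
            continue
        markers.append(
            CandidateMarker(
                gene_symbol=gene,
                direction=str(incidence.gene_direction.get(gene, "")),
                n_functions=int(keep[gene]),
                regulatory=regulatory,
            )
        )
    return markers


def multifunction_genes(
    incidence: IncidenceTable, min_functions: int = MIN_FUNCTIONS
) -> list[str]:
    """Genes passing the multifunction filter, ordered as in selection."""
    counts = incidence.function_counts
    keep = counts[counts >= min_functions]
    return sorted(keep.index, key=lambda g: (-keep[g], g))
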