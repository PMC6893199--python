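"""GO over-representation testing against an expressed-gene universe.

Annotations are propagated up the ontology graph (true-path rule: a gene
annotated to a term is annotated to all its ancestors), then each term is
tested for over-representation of the study set in the universe with the
one-sided hypergeometric (Fisher) tail.  Raw p-values below a reporting
threshold (default 5%) are returned unadjusted; an optional `elim`
variant removes genes of significant child terms before testing parents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd
from scipy.stats import hypergeom

P_REPORT = 0.05
ELIM_CUTOFF = 0.01

_NAMESPACE_ABBREV = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
}


@dataclass
class OntologyGraph:
    """GO terms with ``is_a`` (and optionally ``part_of``) parent links."""

    terms: dict[str, tuple[str, str]]  # id -> (name, namespace abbrev)
    parents: dict[str, frozenset[str]]  # id -> parent ids
    _ancestors: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for term, ps in self.parents.items():
            unknown = ps - self.terms.keys()
            if unknown:
                raise ValueError(f"term {term} has unknown parents {sorted(unknown)}")
        g = nx.DiGraph((child, p) for child, ps in self.parents.items() for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology graph contains a cycle")

    def ancestors(self, term: str) -> frozenset[str]:
        """All strict ancestors of ``term`` (transitive parents)."""
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        for p in self.parents.get(term, ()):
            out.add(p)
            out |= self.ancestors(p)
        result = frozenset(out)
        self._ancestors[term] = result
        return result

    def children_map(self) -> dict[str, set[str]]:
        kids: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, ps in self.parents.items():
            for p in ps:
                kids[p].add(child)
        return kids


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_name: str
    namespace: str
    annotated_in_universe: int
    annotated_in_study: int
    expected: float
    p_value: float


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_obo(path: str, include_part_of: bool = True) -> OntologyGraph:
    """Read an OBO 1.2 ontology into an :class:`OntologyGraph`.

    ``is_a`` edges are always kept; ``relationship: part_of`` edges are
    treated like ``is_a`` unless ``include_part_of`` is False.
    """
    g = obonet.read_obo(path)
    terms: dict[str, tuple[str, str]] = {}
    parents: dict[str, set[str]] = {}
    for node, data in g.nodes(data=True):
        ns = _NAMESPACE_ABBREV.get(data.get("namespace", ""), data.get("namespace", ""))
        terms[node] = (data.get("name", node), ns)
        parents.setdefault(node, set())
    for child, parent, rel in g.edges(keys=True):
        if rel == "is_a" or (include_part_of and rel == "part_of"):
            if parent in terms:
                parents.setdefault(child, set()).add(parent)
    return OntologyGraph(terms=terms, parents={t: frozenset(p) for t, p in parents.items()})


def load_gene2go(path: str) -> dict[str, set[str]]:
    """Read gene-to-term annotation from 2-column TSV or GAF 2.x.

    GAF lines (detected by the ``!`` header or >= 15 columns) use columns 2
    (gene id) and 5 (term id).
    """
    gene2go: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("!", "#")):
                continue
            parts = line.split("\t")
            if len(parts) >= 15:  # GAF
                gene, term = parts[1], parts[4]
            elif len(parts) >= 2:
                gene, term = parts[0], parts[1]
            else:
                continue
            gene2go.setdefault(gene, set()).add(term)
    return gene2go


# ---------------------------------------------------------------------------
# propagation and testing
# ---------------------------------------------------------------------------


def propagate_annotations(
    gene2go: Mapping[str, Iterable[str]], graph: OntologyGraph
) -> dict[str, frozenset[str]]:
    """True-path propagation: annotate each gene to every ancestor of each
    of its direct terms.  Idempotent; unknown term ids are skipped with a
    warning."""
    out: dict[str, frozenset[str]] = {}
    unknown: set[str] = set()
    for gene, terms in gene2go.items():
        full: set[str] = set()
        for t in terms:
            if t not in graph.terms:
                unknown.add(t)
                continue
            full.add(t)
            full |= graph.ancestors(t)
        out[gene] = frozenset(full)
    if unknown:
        warnings.warn(f"unknown GO term ids skipped: {sorted(unknown)}", stacklevel=2)
    return out


def _term_gene_index(
    annotations: Mapping[str, frozenset[str]], genes: set[str]
) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for gene in genes:
        for term in annotations.get(gene, ()):
            index.setdefault(term, set()).add(gene)
    return index


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n): the one-sided Fisher p-value."""
    return float(hypergeom.sf(k - 1, N, K, n))


def fisher_enrichment(
    study: set[str],
    universe: set[str],
    annotations: Mapping[str, frozenset[str]],
    graph: OntologyGraph,
    p_report: float = P_REPORT,
    namespace: str | None = None,
    method: str = "classic",
    elim_cutoff: float = ELIM_CUTOFF,
    require_annotation: bool = True,
) -> list[EnrichmentRow]:
    """Per-term over-representation of ``study`` within ``universe``.

    p = P(X >= k) with N = |universe|, K = genes of the universe annotated
    to the term, n = |study|, k = study genes annotated to the term.  Rows
    with p < ``p_report`` are returned sorted ascending by p (ties by term
    id); no multiple-testing adjustment is applied.

    ``require_annotation`` drops universe genes without any annotation
    before testing (the default background).  ``method="elim"`` runs the
    bottom-up elim procedure: genes belonging to a child term whose own p
    fell below ``elim_cutoff`` are removed before testing the parents.
    """
    if not universe:
        raise ValueError("universe is empty")
    outside = study - universe
    if outside:
        warnings.warn(
            f"{len(outside)} study genes outside the universe dropped", stacklevel=2
        )
        study = study & universe
    if require_annotation:
        universe = {g for g in universe if annotations.get(g)}
        study = study & universe

    index = _term_gene_index(annotations, universe)
    if namespace is not None:
        index = {
            t: genes for t, genes in index.items() if graph.terms[t][1] == namespace
        }
    N, n = len(universe), len(study)
    if method == "classic":
        p_values = {
            term: hypergeom_upper_tail(N, len(genes), n, len(genes & study))
            for term, genes in index.items()
        }
        k_study = {term: len(genes & study) for term, genes in index.items()}
    elif method == "elim":
        p_values, k_study = _elim_pvalues(index, study, N, n, graph, elim_cutoff)
    else:
        raise ValueError(f"unknown method {method!r}")

    rows = []
    for term, p in p_values.items():
        if p < p_report:
            K = len(index[term])
            name, ns = graph.terms[term]
            rows.append(
                EnrichmentRow(
                    term_id=term,
                    term_name=name,
                    namespace=ns,
                    annotated_in_universe=K,
                    annotated_in_study=k_study[term],
                    expected=K * n / N,
                    p_value=p,
                )
            )
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows


def _elim_pvalues(
    index: dict[str, set[str]],
    study: set[str],
    N: int,
    n: int,
    graph: OntologyGraph,
    cutoff: float,
) -> tuple[dict[str, float], dict[str, int]]:
    """The published elim procedure: process terms bottom-up (leaves first);
    after a term tests significant at ``cutoff``, its universe genes are
    masked out of all its ancestors before those are tested."""
    terms = [t for t in index]
    # bottom-up: more ancestors = deeper; process deepest first
    terms.sort(key=lambda t: (-len(graph.ancestors(t)), t))
    masked: dict[str, set[str]] = {t: set() for t in index}
    p_values: dict[str, float] = {}
    k_study: dict[str, int] = {}
    for term in terms:
        genes = index[term] - masked[term]
        k = len(genes & study)
        p_values[term] = hypergeom_upper_tail(N, len(genes), n, k)
        k_study[term] = k
        if p_values[term] < cutoff:
            for anc in graph.ancestors(term):
                if anc in masked:
                    masked[anc] |= index[term]
    return p_values, k_study


def enrichment_table(rows: Iterable[EnrichmentRow]) -> pd.DataFrame:
    """Rows as the downloadable CSV layout: term_id, name, namespace,
    annotated, significant, expected, p_value."""
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "name": r.term_name,
                "namespace": r.namespace,
                "annotated": r.annotated_in_universe,
                "significant": r.annotated_in_study,
                "expected": round(r.expected, 4),
                "p_value": r.p_value,
            }
            for r in rows
        ],
        columns=["term_id", "name", "namespace", "annotated", "significant", "expected", "p_value"],
    )
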