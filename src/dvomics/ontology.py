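"""Ontology DAG with information content and Resnik semantic similarity.

Terms are connected by is_a links into a single-rooted acyclic graph.
Annotations are propagated to ancestors (true-path rule); the information
content of a term is IC(t) = -log2(n_t / N), where n_t is the number of
annotated genes whose (propagated) annotation set contains t and N is the
corpus size, so IC(root) = 0. The Resnik similarity of two genes is the
maximum IC over common ancestors of any pair of their annotated terms — i.e.
the maximum IC over the intersection of their ancestor-closed term sets.
"""

from __future__ import annotations

import warnings

import networkx as nx


class OntologyError(ValueError):
    pass


class OntologyDAG:
    """is_a DAG over terms plus a gene-annotation corpus."""

    def __init__(self, graph: nx.DiGraph, root: str):
        """``graph`` holds child -> parent (is_a) edges."""
        if not nx.is_directed_acyclic_graph(graph):
            raise OntologyError("is_a graph contains a cycle")
        roots = [t for t in graph if graph.out_degree(t) == 0]
        if roots != [root]:
            raise OntologyError(f"expected single root {root!r}, found {roots}")
        self.graph = graph
        self.root = root
        self._ancestors: dict[str, frozenset] = {}
        for term in nx.topological_sort(graph.reverse(copy=False)):
            anc = {term}
            for parent in graph.successors(term):
                anc |= self._ancestors[parent]
            self._ancestors[term] = frozenset(anc)
        self.ic: dict[str, float] = {}
        self.annotations: dict[str, frozenset] = {}
        self.direct_annotations: dict[str, frozenset] = {}
        self.namespace: dict[str, str] = {}

    # --- constructors -------------------------------------------------------

    @classmethod
    def from_parent_map(
        cls, terms: list[str], parents: dict[str, str], root: str
    ) -> "OntologyDAG":
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        g.add_edges_from(parents.items())
        return cls(g, root)

    @classmethod
    def from_obo(cls, path: str) -> "OntologyDAG":
        """Read an OBO file (is_a edges only)."""
        import obonet

        g = obonet.read_obo(path)
        dag = nx.DiGraph()
        dag.add_nodes_from(g.nodes)
        namespace = {}
        for child, parent, key in g.edges(keys=True):
            if key == "is_a":
                dag.add_edge(child, parent)
        for term, data in g.nodes(data=True):
            if "namespace" in data:
                namespace[term] = data["namespace"]
        roots = [t for t in dag if dag.out_degree(t) == 0]
        if len(roots) != 1:
            raise OntologyError(f"OBO file has {len(roots)} roots; expected 1")
        obj = cls(dag, roots[0])
        obj.namespace = namespace
        return obj

    # --- annotations and IC -------------------------------------------------

    def ancestors(self, term: str) -> frozenset:
        """Term plus all its is_a ancestors (ancestor closure)."""
        return self._ancestors[term]

    def set_annotations(self, gene_terms: dict[str, set]) -> None:
        """Attach the annotation corpus and recompute IC (base-2)."""
        from math import log2

        self.direct_annotations = {
            g: frozenset(ts) for g, ts in gene_terms.items() if ts
        }
        self.annotations = {}
        counts: dict[str, int] = {}
        for gene, terms in self.direct_annotations.items():
            closed = frozenset().union(*(self._ancestors[t] for t in terms))
            closed |= {self.root}  # every annotation implies the root
            self.annotations[gene] = closed
            for t in closed:
                counts[t] = counts.get(t, 0) + 1
        n = len(self.annotations)
        self.ic = {
            t: -log2(c / n) if n else 0.0 for t, c in counts.items()
        }
        self.ic[self.root] = 0.0

    def read_gmt(self, path: str) -> None:
        """Attach annotations from a GMT file (term <tab> desc <tab> genes...)."""
        gene_terms: dict[str, set] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                term = parts[0]
                for gene in parts[2:]:
                    if gene:
                        gene_terms.setdefault(gene, set()).add(term)
        self.set_annotations(gene_terms)

    # --- similarity ---------------------------------------------------------

    def resnik(self, gene_a: str, gene_b: str) -> float:
        """Resnik similarity: IC of the most informative common ancestor
        over all pairs of the two genes' annotated terms."""
        if gene_a not in self.annotations or gene_b not in self.annotations:
            warnings.warn(
                f"unannotated gene in Resnik query: {gene_a!r}/{gene_b!r}",
                stacklevel=2,
            )
            return float("nan")
        common = self.annotations[gene_a] & self.annotations[gene_b]
        if not common:
            return 0.0
        return max(self.ic.get(t, 0.0) for t in common)

    def term_genes(self, term: str) -> set:
        """Genes annotated (after propagation) to ``term``."""
        return {g for g, ts in self.annotations.items() if term in ts}
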