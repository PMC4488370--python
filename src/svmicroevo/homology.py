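"""Homology classification from tabular protein-vs-protein hit data.

Classes over the focal-species gene set (exhaustive and mutually
exclusive): one_to_one, singleton_with_homologs, with_paralogs_conserved,
orphan_singleton, orphan_with_paralogs.  "Best" is always decided on
bitscore; an inparalog of gene g is an intra-species partner scoring at
least as high as g's best inter-species hit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .core_io import HitRecord

__all__ = [
    "HomologyClass",
    "build_hit_graph",
    "find_inparalogs",
    "one_to_one_orthologs",
    "classify_genes",
    "classify_from_hits",
]

CLASS_NAMES = ("one_to_one", "singleton_with_homologs", "with_paralogs_conserved",
               "orphan_singleton", "orphan_with_paralogs")


@dataclass(frozen=True)
class HomologyClass:
    gene_id: str
    homology_class: str

    def __post_init__(self) -> None:
        if self.homology_class not in CLASS_NAMES:
            raise ValueError(f"bad class {self.homology_class!r}")


def build_hit_graph(hits: Sequence[HitRecord],
                    genes: Iterable[tuple[str, str]] = (),
                    max_evalue: float = 0.001) -> nx.Graph:
    """Undirected weighted graph of hits with evalue < max_evalue.

    Nodes carry a ``species`` attribute; redundant pairs keep the maximum
    bitscore.  ``genes`` adds isolated vertices for genes without hits.
    """
    g = nx.Graph()
    for gene_id, species in genes:
        g.add_node(gene_id, species=species)
    for h in hits:
        if not h.evalue < max_evalue:
            continue
        g.add_node(h.query_id, species=h.query_species)
        g.add_node(h.subject_id, species=h.subject_species)
        if g.has_edge(h.query_id, h.subject_id):
            if h.bitscore > g[h.query_id][h.subject_id]["weight"]:
                g[h.query_id][h.subject_id]["weight"] = h.bitscore
        else:
            g.add_edge(h.query_id, h.subject_id, weight=h.bitscore)
    return g


def _best_inter_score(graph: nx.Graph, gene: str, other_species: str) -> float:
    best = float("-inf")
    for nb in graph.neighbors(gene):
        if graph.nodes[nb]["species"] == other_species:
            best = max(best, graph[gene][nb]["weight"])
    return best


def find_inparalogs(graph: nx.Graph, species_pair: tuple[str, str],
                    strict: bool = False) -> dict[str, set[str]]:
    """Inparalog partners per gene within the two species of the pair.

    For gene g with best inter-species bitscore s(g), every intra-species
    neighbor h with weight(g,h) >= s(g) is an inparalog of g (strict=True
    uses >).  Genes with no inter-species hit take s = -inf, so every intra
    partner qualifies.  The relation is symmetric: an edge qualifying from
    either endpoint makes the two genes mutual inparalogs.
    """
    sp_a, sp_b = species_pair
    other = {sp_a: sp_b, sp_b: sp_a}
    best: dict[str, float] = {}
    out: dict[str, set[str]] = {}
    for gene, data in graph.nodes(data=True):
        sp = data["species"]
        if sp in other:
            best[gene] = _best_inter_score(graph, gene, other[sp])
            out[gene] = set()
    for g, h, attrs in graph.edges(data=True):
        if g not in best or h not in best:
            continue
        if graph.nodes[g]["species"] != graph.nodes[h]["species"]:
            continue
        w = attrs["weight"]
        qualifies = ((w > best[g] or w > best[h]) if strict
                     else (w >= best[g] or w >= best[h]))
        if qualifies:
            out[g].add(h)
            out[h].add(g)
    return out


def one_to_one_orthologs(graph: nx.Graph, species_pair: tuple[str, str],
                         strict_inparalogs: bool = False) -> list[tuple[str, str]]:
    """Reciprocal best inter-species hits where neither member has an
    inparalog.  A bitscore tie for a gene's top hit breaks reciprocity and
    no pair is emitted for it."""
    sp_a, sp_b = species_pair
    inpar = find_inparalogs(graph, species_pair, strict=strict_inparalogs)

    def unique_best(gene: str, target_sp: str) -> str | None:
        best_w = float("-inf")
        best_nb = None
        tied = False
        for nb in graph.neighbors(gene):
            if graph.nodes[nb]["species"] != target_sp:
                continue
            w = graph[gene][nb]["weight"]
            if w > best_w:
                best_w, best_nb, tied = w, nb, False
            elif w == best_w:
                tied = True
        return None if tied else best_nb

    pairs = []
    for gene, data in sorted(graph.nodes(data=True)):
        if data["species"] != sp_a:
            continue
        b = unique_best(gene, sp_b)
        if b is None:
            continue
        if unique_best(b, sp_a) != gene:
            continue
        if inpar.get(gene) or inpar.get(b):
            continue
        pairs.append((gene, b))
    return pairs


def classify_genes(graph: nx.Graph, pairs: Sequence[tuple[str, str]],
                   focal_species: str) -> list[HomologyClass]:
    """Classify every focal-species gene in the graph.

    Conserved = any hit to a non-focal species.  Within conserved and
    orphan groups, connected components of the intra-focal subgraph of
    size > 1 are "with paralogs", size 1 are singletons; conserved
    singletons in a one-to-one pair are one_to_one, other conserved
    singletons are singleton_with_homologs.
    """
    focal = [n for n, d in graph.nodes(data=True) if d["species"] == focal_species]
    intra = graph.subgraph(focal)
    comp_size = {}
    for comp in nx.connected_components(intra):
        for n in comp:
            comp_size[n] = len(comp)
    in_pair = {a for a, _ in pairs}
    out = []
    for gene in sorted(focal):
        conserved = any(graph.nodes[nb]["species"] != focal_species
                        for nb in graph.neighbors(gene))
        has_paralogs = comp_size.get(gene, 1) > 1
        if conserved and has_paralogs:
            cls = "with_paralogs_conserved"
        elif conserved:
            cls = "one_to_one" if gene in in_pair else "singleton_with_homologs"
        elif has_paralogs:
            cls = "orphan_with_paralogs"
        else:
            cls = "orphan_singleton"
        out.append(HomologyClass(gene_id=gene, homology_class=cls))
    return out


def classify_from_hits(hits: Sequence[HitRecord],
                       genes: Iterable[tuple[str, str]],
                       focal_species: str, ortholog_species: str,
                       max_evalue: float = 0.001) -> list[HomologyClass]:
    """Convenience wrapper: graph -> inparalog-aware 1:1 pairs -> classes."""
    graph = build_hit_graph(hits, genes=genes, max_evalue=max_evalue)
    pairs = one_to_one_orthologs(graph, (focal_species, ortholog_species))
    return classify_genes(graph, pairs, focal_species)
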