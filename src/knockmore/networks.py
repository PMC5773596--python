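"""Phenotype-linked regulatory gene networks.

Genes sharing an enriched MORE set under the same sub-phenotype (parameter,
sex, direction — e.g. "AUC-mh" = glucose-tolerance AUC, male, high tail)
are connected; knowledge-based edges from shared KEGG pathway membership
can be overlaid, and cassette-based phenotype prediction is validated with
Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


def build_more_network(set_memberships: pd.DataFrame) -> nx.Graph:
    """Gene network from shared MORE sets.

    ``set_memberships`` has one row per (set_id, sub_phenotype, gene);
    two genes are connected iff they share at least one MORE set under the
    same sub-phenotype. Edges carry the shared set ids and sub-phenotype
    tags; nodes carry their sub-phenotype groupings ("areas"). The result
    is independent of input row order.
    """
    required = {"set_id", "sub_phenotype", "gene"}
    if not required.issubset(set_memberships.columns):
        raise ValueError(f"membership table needs columns {required}")
    g = nx.Graph()
    for _, row in set_memberships.iterrows():
        gene = row["gene"]
        if not g.has_node(gene):
            g.add_node(gene, sub_phenotypes=set())
        g.nodes[gene]["sub_phenotypes"].add(row["sub_phenotype"])
    grouped = set_memberships.groupby(["set_id", "sub_phenotype"])
    for (set_id, tag), sub in sorted(grouped, key=lambda kv: kv[0]):
        genes = sorted(set(sub["gene"]))
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                if g.has_edge(a, b):
                    g[a][b]["more_sets"].add(set_id)
                    g[a][b]["sub_phenotypes"].add(tag)
                else:
                    g.add_edge(a, b, more_sets={set_id},
                               sub_phenotypes={tag}, provenance="more")
    return g


def map_to_pathways(genes, membership: pd.DataFrame,
                    metabolic_only: bool = False) -> dict[str, list[str]]:
    """Per-gene pathway ids from a membership table (gene, pathway_id,
    pathway_name, class); ``metabolic_only`` keeps the KEGG Metabolism
    class. Genes absent from the table map to an empty list."""
    required = {"gene", "pathway_id"}
    if not required.issubset(membership.columns):
        raise ValueError(f"membership table needs columns {required}")
    table = membership
    if metabolic_only:
        if "class" not in table.columns:
            raise ValueError("metabolic_only needs a 'class' column")
        table = table[table["class"] == "Metabolism"]
    lookup = table.groupby("gene")["pathway_id"].apply(
        lambda s: sorted(set(s))).to_dict()
    return {g: lookup.get(g, []) for g in genes}


def build_pathway_network(genes, membership: pd.DataFrame,
                          metabolic_only: bool = False) -> nx.Graph:
    """Gene network connecting genes that share a pathway."""
    mapping = map_to_pathways(genes, membership, metabolic_only)
    g = nx.Graph()
    g.add_nodes_from(mapping)
    by_pathway: dict[str, list[str]] = {}
    for gene, pathways in mapping.items():
        for pw in pathways:
            by_pathway.setdefault(pw, []).append(gene)
    for pw, members in sorted(by_pathway.items()):
        members = sorted(set(members))
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if g.has_edge(a, b):
                    g[a][b]["pathway_ids"].add(pw)
                else:
                    g.add_edge(a, b, pathway_ids={pw}, provenance="pathway")
    return g


def overlay_networks(more_net: nx.Graph, pathway_net: nx.Graph) -> nx.Graph:
    """Union of the MORE-derived and pathway-derived networks.

    Every edge is labelled with provenance 'more', 'pathway' or 'both';
    the graph attribute ``both_count`` reports how many edges are
    supported by both sources.
    """
    out = nx.Graph()
    out.add_nodes_from(more_net.nodes(data=True))
    out.add_nodes_from(pathway_net.nodes(data=True))
    for a, b, data in more_net.edges(data=True):
        out.add_edge(a, b, **{**data, "provenance": "more"})
    both = 0
    for a, b, data in pathway_net.edges(data=True):
        if out.has_edge(a, b):
            out[a][b].update({k: v for k, v in data.items()
                              if k != "provenance"})
            out[a][b]["provenance"] = "both"
            both += 1
        else:
            out.add_edge(a, b, **{**data, "provenance": "pathway"})
    out.graph["both_count"] = both
    return out


@dataclass(frozen=True)
class PredictionValidation:
    """2x2 contingency of cassette matches vs metabolic phenotype."""

    table: tuple[tuple[int, int], tuple[int, int]]
    fraction_matched: float
    fraction_unmatched: float
    odds_ratio: float
    p_value: float


def validate_prediction(match_counts: dict[str, int],
                        phenotype_flags: dict[str, bool],
                        ) -> PredictionValidation:
    """Does the presence of phenotype-associated cassettes in a promoter
    predict a metabolic phenotype?

    Genes are binned into >= 1 vs 0 cassette matches; the 2x2 table of
    (matched, unmatched) x (phenotype, no phenotype) is tested with the
    two-sided Fisher's exact test (sum of hypergeometric probabilities not
    exceeding that of the observed table).
    """
    genes = sorted(match_counts)
    missing = [g for g in genes if g not in phenotype_flags]
    if missing:
        raise ValueError(f"no phenotype flag for genes: {missing[:5]}...")
    matched = [g for g in genes if match_counts[g] >= 1]
    unmatched = [g for g in genes if match_counts[g] == 0]
    if not matched or not unmatched:
        raise ValueError("both match strata must be non-empty")
    a = sum(phenotype_flags[g] for g in matched)
    b = len(matched) - a
    c = sum(phenotype_flags[g] for g in unmatched)
    d = len(unmatched) - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return PredictionValidation(((a, b), (c, d)), a / len(matched),
                                c / len(unmatched), float(odds), float(p))


def fisher_two_sided(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table."""
    return float(stats.fisher_exact(np.asarray(table),
                                    alternative="two-sided")[1])


def network_to_edge_frame(g: nx.Graph) -> pd.DataFrame:
    """Edge-list table (gene_a, gene_b, provenance, more_set_ids,
    pathway_ids, sub_phenotypes); set-valued attributes are
    comma-joined."""
    rows = []
    for a, b in sorted(map(lambda e: tuple(sorted(e)), g.edges())):
        data = g[a][b]
        rows.append({
            "gene_a": a, "gene_b": b,
            "provenance": data.get("provenance", ""),
            "more_set_ids": ",".join(sorted(data.get("more_sets", []))),
            "pathway_ids": ",".join(sorted(data.get("pathway_ids", []))),
            "sub_phenotypes": ",".join(sorted(
                data.get("sub_phenotypes", []))),
        })
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "provenance",
                                       "more_set_ids", "pathway_ids",
                                       "sub_phenotypes"])


def write_graphml(g: nx.Graph, path) -> None:
    """GraphML writer; set-valued attributes are serialised comma-joined."""
    h = nx.Graph(**{k: v for k, v in g.graph.items()})
    for node, data in g.nodes(data=True):
        h.add_node(node, **{k: ",".join(sorted(v))
                            if isinstance(v, (set, frozenset)) else v
                            for k, v in data.items()})
    for a, b, data in g.edges(data=True):
        h.add_edge(a, b, **{k: ",".join(sorted(v))
                            if isinstance(v, (set, frozenset)) else v
                            for k, v in data.items()})
    nx.write_graphml(h, path)
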