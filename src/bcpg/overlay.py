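"""Population networks and cognate-set / genetic-cluster overlays.

Builds the minimum spanning tree of the pairwise differentiation matrix,
summarizes how strongly MST edges stay within language phyla (with a
label-permutation test), and cross-tabulates cognate-set presence against
genetic cluster membership with chi-squared tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    ClusterAssignment,
    CognateCatalog,
    DataModelError,
    LabeledMatrix,
    PopulationMetadata,
)

CHISQ_MODES = ("gof_half", "independence")


class OverlayError(ValueError):
    pass


def minimum_spanning_tree(
    d: LabeledMatrix,
    metadata: Sequence[PopulationMetadata] | None = None,
    phylum_of: Mapping[str, str] | None = None,
) -> nx.Graph:
    """MST of a complete differentiation matrix.

    Edges are considered in ascending weight with lexicographic label-pair
    tie-breaking, so duplicate weights still give a deterministic tree.
    Node attributes carry the phylum when ``phylum_of`` (or metadata with a
    resolvable phylum) is supplied.
    """
    n = len(d.labels)
    if n < 2:
        raise OverlayError("MST needs at least 2 nodes")
    if np.isnan(d.values).any():
        raise OverlayError("NaN edge weight")
    g = nx.Graph()
    g.add_nodes_from(d.labels)
    edges = sorted(
        (
            (min(a, b), max(a, b))
            for i, a in enumerate(d.labels)
            for b in d.labels[i + 1 :]
        )
    )
    for a, b in edges:
        g.add_edge(a, b, weight=d[a, b])
    # Kruskal with a stable sort keeps insertion (lexicographic) order for ties
    tree = nx.minimum_spanning_tree(g, algorithm="kruskal")
    if phylum_of:
        nx.set_node_attributes(tree, dict(phylum_of), "phylum")
    if metadata is not None:
        coords = {m.site: (m.latitude, m.longitude) for m in metadata}
        for node in tree.nodes:
            if node in coords:
                tree.nodes[node]["lat"], tree.nodes[node]["lon"] = coords[node]
    return tree


def phylum_edge_assortativity(
    tree: nx.Graph,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Fraction of MST edges joining same-phylum nodes, with permutation p.

    The null permutes phylum labels across nodes (fixed tree topology);
    upper-tailed p.  A single phylum in the tree is an error.
    """
    labels = nx.get_node_attributes(tree, "phylum")
    if len(labels) != tree.number_of_nodes():
        raise OverlayError("every node needs a 'phylum' attribute")
    if len(set(labels.values())) < 2:
        raise OverlayError("assortativity needs at least 2 phyla")
    nodes = list(tree.nodes)
    phyla = np.array([labels[n] for n in nodes])
    index = {n: i for i, n in enumerate(nodes)}
    pairs = np.array([(index[a], index[b]) for a, b in tree.edges], dtype=np.intp)
    observed = float(np.mean(phyla[pairs[:, 0]] == phyla[pairs[:, 1]]))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(phyla)
        if np.mean(perm[pairs[:, 0]] == perm[pairs[:, 1]]) >= observed - 1e-12:
            hits += 1
    return observed, (hits + 1) / (n_perm + 1)


@dataclass
class CognateClusterTable:
    """Cluster x cognate-set contingency of population counts."""

    counts: pd.DataFrame  # rows: cluster labels; columns: cognate sets
    row_sizes: pd.Series  # populations per cluster (n_r)

    @property
    def percentages(self) -> pd.DataFrame:
        return 100.0 * self.counts.div(self.row_sizes, axis=0)

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.insert(0, "n", self.row_sizes)
        return out.rename_axis("cluster")


def _cluster_sort_key(label: str) -> tuple[int, str]:
    return (label.startswith("admixed"), label)


def cognate_cluster_table(
    catalog: CognateCatalog, clusters: ClusterAssignment
) -> CognateClusterTable:
    """Count populations of each cluster (admixed categories kept separate)
    bearing each cognate set."""
    shared = [s for s in clusters.labels if s in catalog.presence.index]
    if not shared:
        raise OverlayError("no sites shared between cognate catalog and clusters")
    labels = clusters.cluster_labels()
    rows = sorted({labels[s] for s in shared}, key=_cluster_sort_key)
    presence = catalog.presence.loc[shared]
    member = pd.Series([labels[s] for s in shared], index=shared)
    counts = presence.groupby(member).sum().reindex(rows).astype(int)
    sizes = member.value_counts().reindex(rows).astype(int)
    return CognateClusterTable(counts=counts, row_sizes=sizes)


def cognate_chisq(table: CognateClusterTable, mode: str = "gof_half") -> pd.DataFrame:
    """Chi-squared tests of cognate distribution across clusters.

    ``gof_half``: per cognate, expected presence count per cluster is
    n_r / 2 (prior presence probability one half), chi2 = sum_r
    (O_r - n_r/2)^2 / (n_r/2) with df = rows - 1.  ``independence``: a
    presence/absence x cluster contingency test (df = rows - 1); zero
    expected cells there are an error suggesting gof_half.
    """
    if mode not in CHISQ_MODES:
        raise DataModelError(f"mode {mode!r} not in {CHISQ_MODES}")
    if len(table.counts.index) < 2:
        raise OverlayError("chi-squared needs at least 2 cluster rows")
    n_r = table.row_sizes.to_numpy(dtype=float)
    rows = []
    for cog in table.counts.columns:
        o = table.counts[cog].to_numpy(dtype=float)
        df = len(n_r) - 1
        if mode == "gof_half":
            expected = n_r / 2.0
            chi2 = float(((o - expected) ** 2 / expected).sum())
        else:
            cont = np.column_stack([o, n_r - o])
            if (cont.sum(axis=0) == 0).any():
                raise OverlayError(
                    f"cognate {cog!r}: zero expected cell in independence "
                    "mode; use gof_half"
                )
            chi2, _, df, _ = stats.chi2_contingency(cont, correction=False)
            chi2 = float(chi2)
        rows.append(
            {
                "cognate_set": cog,
                "chi2": chi2,
                "df": df,
                "p": float(stats.chi2.sf(chi2, df)),
                "mode": mode,
            }
        )
    return pd.DataFrame(rows)
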