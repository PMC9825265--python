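"""Spearman correlation matrices and threshold correlation graphs.

Variables are organized into groups by the scale of behavior they describe
(2D network topology, 2D single-cell morphology, 3D spheroid shape,
protrusions, dissemination). Pairwise Spearman rank correlations across
clones produce a symmetric matrix; thresholding |r| yields a correlation
graph whose edges carry the coefficient, its sign, and magnitude. A
restricted variant keeps only edges incident to the composite invasion3D
variable (a star graph), at a lower threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

DEFAULT_GROUPS = ("network2D", "singlecell2D", "spheroid_shape3D",
                  "protrusion3D", "dissemination3D")


@dataclass
class CorrelationGraph:
    graph: nx.Graph  # nodes: variables (group attr); edges: r, sign, weight=|r|
    threshold: float

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["r"]) for u, v, d in self.graph.edges(data=True)]

    def edge_set(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self.graph.edges()}


def spearman_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlation matrix over clones (rows).

    Uses mid-rank tie handling and pairwise-complete observations.
    Constant variables give undefined (NaN) correlations with all others;
    the diagonal is 1 for any non-constant variable. Requires >= 3 rows.
    """
    if len(table) < 3:
        raise ValueError("Spearman matrix requires at least 3 clones")
    r = table.corr(method="spearman", min_periods=3)
    np.fill_diagonal(r.values, [1.0 if table[c].nunique(dropna=True) > 1 else np.nan
                                for c in r.columns])
    return r


def correlation_graph(matrix: pd.DataFrame, threshold: float = 0.8,
                      groups: dict[str, str] | None = None) -> CorrelationGraph:
    """Graph with an edge for every off-diagonal pair with |r| > threshold.

    Edges carry the coefficient ``r``, ``sign`` ('positive'/'negative')
    and ``weight`` = |r|. Node ``group`` attributes are attached when a
    variable -> group mapping is given. Strict inequality: |r| exactly at
    the threshold yields no edge.
    """
    g = nx.Graph()
    for var in matrix.columns:
        g.add_node(str(var), group=(groups or {}).get(var, ""))
    cols = list(matrix.columns)
    for i, u in enumerate(cols):
        for v in cols[i + 1:]:
            r = matrix.loc[u, v]
            if pd.notna(r) and abs(r) > threshold:
                g.add_edge(str(u), str(v), r=float(r), weight=float(abs(r)),
                           sign="positive" if r >= 0 else "negative")
    return CorrelationGraph(graph=g, threshold=threshold)


def invasion_correlations(table: pd.DataFrame, threshold: float = 0.3,
                          invasion_column: str = "invasion3D",
                          groups: dict[str, str] | None = None) -> CorrelationGraph:
    """Star correlation graph around the composite invasion variable.

    Edges link ``invasion3D`` to every other (2D) variable with
    |Spearman r| > threshold; correlations among the 2D variables are
    not drawn.
    """
    if invasion_column not in table.columns:
        raise ValueError(f"table lacks the {invasion_column!r} column")
    matrix = spearman_matrix(table)
    full = correlation_graph(matrix, threshold=threshold, groups=groups)
    star = nx.Graph()
    star.add_nodes_from(full.graph.nodes(data=True))
    for u, v, d in full.graph.edges(data=True):
        if invasion_column in (u, v):
            star.add_edge(u, v, **d)
    return CorrelationGraph(graph=star, threshold=threshold)


def write_correlation_graph(cg: CorrelationGraph, path) -> None:
    """Persist as GraphML with group/sign/weight attributes."""
    nx.write_graphml(cg.graph, str(path))
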