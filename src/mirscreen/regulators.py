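"""miRNA -> phosphoprotein regulator networks and pathway-regulation scoring.

An miRNA is called a regulator of a phosphoprotein when the discretized
secondary screens show the same up (or down) state in at least
``min_lines`` of the cell lines; miRNAs regulating fewer than
``min_targets`` phosphoproteins are dropped from the display network.
Pathway regulation is scored per (miRNA, pathway) as the fraction of
measured pathway members the miRNA changes; an miRNA enters the pathway
network when it regulates at least half of them (configurable).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .screens import DiscreteScreen, PathwaySet

__all__ = [
    "RegulatorNetwork",
    "PathwayRegulation",
    "build_phospho_regulators",
    "pathway_fractions",
    "export_pathway_network",
]

logger = logging.getLogger(__name__)


@dataclass
class RegulatorNetwork:
    """Signed bipartite miRNA -> protein edges with cross-line evidence counts."""

    edges: pd.DataFrame   # columns: mirna, protein, sign, n_lines_support, cluster
    min_lines: int
    min_targets: int
    dropped_conflicts: list[tuple[str, str]] = field(default_factory=list)

    def to_edge_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "source": self.edges["mirna"],
            "target": self.edges["protein"],
            "score": self.edges["n_lines_support"].astype(float),
            "sign": self.edges["sign"],
            "cluster": self.edges["cluster"],
        })


@dataclass
class PathwayRegulation:
    """Per (miRNA, pathway) regulated fraction and inclusion flag."""

    table: pd.DataFrame   # columns: mirna, pathway, fraction, included
    threshold: float

    def included(self) -> pd.DataFrame:
        return self.table[self.table["included"]].reset_index(drop=True)


def build_phospho_regulators(
    screens: list[DiscreteScreen],
    phospho_ids: list[str],
    min_lines: int = 2,
    min_targets: int = 2,
    cluster_labels: dict[str, int] | None = None,
) -> tuple[RegulatorNetwork, RegulatorNetwork]:
    """Up- and down-regulator networks from per-line discretized screens.

    An edge (m, p, +1) requires state +1 in at least ``min_lines`` screens
    (analogously -1); pairs supported in both directions are dropped and
    logged.  miRNAs left with fewer than ``min_targets`` edges in a
    network are removed from it.  Returns (up network, down network),
    disjoint in (miRNA, protein) pairs by construction.
    """
    if len(screens) < min_lines:
        raise ValueError(f"need at least min_lines={min_lines} screens, got {len(screens)}")
    mirnas = set(screens[0].mirna_ids)
    proteins = set(phospho_ids)
    for s in screens:
        mirnas &= set(s.mirna_ids)
        proteins &= set(s.protein_ids)
    mirnas = [m for m in screens[0].mirna_ids if m in mirnas]
    proteins = [p for p in phospho_ids if p in proteins]
    subs = [s.subset(mirnas, proteins) for s in screens]
    stack = np.stack([s.states for s in subs])  # (lines, mirna, protein)
    n_up = (stack == 1).sum(axis=0)
    n_down = (stack == -1).sum(axis=0)
    up_hit = n_up >= min_lines
    down_hit = n_down >= min_lines
    # a pair called in both directions anywhere is ambiguous evidence and is
    # dropped outright; defining the conflict independently of min_lines also
    # keeps the edge set anti-monotone in min_lines
    conflict = (n_up >= 1) & (n_down >= 1) & (up_hit | down_hit)
    dropped = [(mirnas[i], proteins[j]) for i, j in np.argwhere(conflict)]
    for m, p in dropped:
        logger.warning("conflicting up/down support for (%s, %s); edge dropped", m, p)

    def build(hit: np.ndarray, support: np.ndarray, sign: int) -> RegulatorNetwork:
        hit = hit & ~conflict
        rows = [
            {"mirna": mirnas[i], "protein": proteins[j], "sign": sign,
             "n_lines_support": int(support[i, j]),
             "cluster": (cluster_labels or {}).get(mirnas[i], -1)}
            for i, j in np.argwhere(hit)
        ]
        df = pd.DataFrame(rows, columns=["mirna", "protein", "sign",
                                         "n_lines_support", "cluster"])
        if len(df):
            counts = df.groupby("mirna")["protein"].transform("count")
            df = df[counts >= min_targets].reset_index(drop=True)
            df = df.sort_values(["mirna", "protein"], kind="mergesort").reset_index(drop=True)
        return RegulatorNetwork(df, min_lines, min_targets, dropped)

    return build(up_hit, n_up, +1), build(down_hit, n_down, -1)


def pathway_fractions(
    discrete: DiscreteScreen,
    pathways: list[PathwaySet],
    threshold: float = 0.5,
) -> PathwayRegulation:
    """Fraction of measured pathway members each miRNA regulates.

    A member counts as regulated when its state is nonzero under the
    miRNA.  The denominator is the number of pathway members actually
    measured; pathways with no measured member are excluded with a
    warning.  ``included`` is exact: fraction >= threshold.
    """
    measured = set(discrete.protein_ids)
    col = {p: j for j, p in enumerate(discrete.protein_ids)}
    rows = []
    for ps in pathways:
        members = sorted(ps.members & measured)
        if not members:
            warnings.warn(f"pathway {ps.name!r} has no measured members; excluded")
            continue
        cols = [col[p] for p in members]
        nonzero = (discrete.states[:, cols] != 0).sum(axis=1)
        frac = nonzero / len(members)
        for i, m in enumerate(discrete.mirna_ids):
            rows.append({"mirna": m, "pathway": ps.name,
                         "fraction": float(frac[i]),
                         "included": bool(frac[i] >= threshold)})
    table = pd.DataFrame(rows, columns=["mirna", "pathway", "fraction", "included"])
    return PathwayRegulation(table, threshold)


def export_pathway_network(
    reg: PathwayRegulation,
    cluster_labels: dict[str, int] | None = None,
) -> nx.Graph:
    """Bipartite miRNA–pathway graph of the included pairs.

    Edge weight and miRNA node size carry the regulated fraction; miRNA
    node color carries the consensus cluster id.
    """
    g = nx.Graph()
    inc = reg.included().sort_values(["mirna", "pathway"], kind="mergesort")
    for row in inc.itertuples(index=False):
        cluster = (cluster_labels or {}).get(row.mirna, -1)
        if row.mirna not in g:
            g.add_node(row.mirna, kind="mirna", size=float(row.fraction),
                       color=int(cluster))
        else:
            g.nodes[row.mirna]["size"] = max(g.nodes[row.mirna]["size"],
                                             float(row.fraction))
        if row.pathway not in g:
            g.add_node(row.pathway, kind="pathway", size=1.0, color=-1)
        g.add_edge(row.mirna, row.pathway, weight=float(row.fraction))
    return g
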