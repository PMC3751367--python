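"""Impact degrees: weighting genes by their differentially expressed neighbors.

A gene regulatory network (GRN) is an undirected simple graph over gene
identifiers.  A gene is *significant* when a two-sided pooled-variance
two-sample t-test between the two conditions' replicate values gives
p < alpha at any timepoint.  A gene's *impact degree* is the number of its
GRN neighbors that are significant; it weights both the up and the down
item of the gene during mining.  Genes absent from the GRN have degree 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .transactions import ExpressionDataset, GeneItem

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


def build_grn(edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()) -> nx.Graph:
    """Build an undirected simple GRN from an edge list.

    Directed source edges collapse to undirected adjacency; self-loops and
    duplicate edges are dropped (counts logged).
    """
    g = nx.Graph()
    g.add_nodes_from(nodes)
    n_self = 0
    n_dup = 0
    for a, b in edges:
        if a == b:
            n_self += 1
            continue
        if g.has_edge(a, b):
            n_dup += 1
            continue
        g.add_edge(a, b)
    if n_self or n_dup:
        log.info("GRN cleanup: dropped %d self-loops, %d duplicate edges", n_self, n_dup)
    return g


def ttest_pvalues(dataset: ExpressionDataset, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Per-probe, per-timepoint two-sided pooled-variance t-test p-values.

    Cells where either condition has fewer than 2 non-missing replicate
    values are NaN (skipped, with a logged warning when a whole timepoint
    is affected).  When both groups have zero variance the p-value is 1 if
    the means agree and 0 otherwise — the limit of the statistic as the
    within-group variance vanishes.
    """
    c1, c2 = dataset.conditions
    cols = {}
    degenerate_hits = 0
    for tp in dataset.timepoints:
        a = dataset.matrix(c1, tp).to_numpy(dtype=float)
        b = dataset.matrix(c2, tp).to_numpy(dtype=float)
        n1 = np.sum(~np.isnan(a), axis=1)
        n2 = np.sum(~np.isnan(b), axis=1)
        if a.shape[1] < 2 or b.shape[1] < 2:
            log.warning(
                "timepoint %r skipped: <2 replicates (%d vs %d)", tp, a.shape[1], b.shape[1]
            )
            cols[tp] = np.full(len(dataset.probes), np.nan)
            continue
        valid = (n1 >= 2) & (n2 >= 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            m1 = np.nanmean(a, axis=1)
            m2 = np.nanmean(b, axis=1)
            v1 = np.nanvar(a, axis=1, ddof=1)
            v2 = np.nanvar(b, axis=1, ddof=1)
            df = n1 + n2 - 2
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / np.where(df > 0, df, 1)
            se = np.sqrt(sp2 * (1.0 / np.where(n1 > 0, n1, 1) + 1.0 / np.where(n2 > 0, n2, 1)))
            t = (m1 - m2) / se
            p = 2.0 * stats.t.sf(np.abs(t), np.where(df > 0, df, 1))
        zero_var = valid & (sp2 == 0)
        p = np.where(zero_var, np.where(m1 == m2, 1.0, 0.0), p)
        degenerate_hits += int(np.sum(zero_var & (m1 != m2)))
        p = np.where(valid, p, np.nan)
        cols[tp] = p
    if degenerate_hits:
        log.info(
            "t-test: %d probe/timepoint cells had zero variance in both groups "
            "with differing means; treated as significant (p=0)",
            degenerate_hits,
        )
    return pd.DataFrame(cols, index=dataset.probes)


def significant_probes(dataset: ExpressionDataset, alpha: float = DEFAULT_ALPHA) -> set[str]:
    """Probes with p < alpha at any timepoint."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    pv = ttest_pvalues(dataset, alpha)
    hit = (pv < alpha).any(axis=1)
    return set(pv.index[hit])


def significant_genes(
    dataset: ExpressionDataset,
    alpha: float = DEFAULT_ALPHA,
    probe_map: Mapping[str, str] | None = None,
) -> set[str]:
    """Genes with a significant probe.

    Tests run per probe; a gene is significant as soon as any of its mapped
    probes is significant at any timepoint.
    """
    probe_map = probe_map or {}
    probes = significant_probes(dataset, alpha)
    return {probe_map.get(p, p) for p in probes}


@dataclass(frozen=True)
class ImpactDegreeTable:
    """Gene -> impact degree, plus the significant-gene set that produced it.

    ``default`` is the degree reported for genes not in the table; the
    undifferentiation baseline uses an empty table with ``default=1``.
    """

    degrees: Mapping[str, int]
    significant: frozenset
    alpha: float | None = None
    default: int = 0

    def degree(self, gene: str) -> int:
        return self.degrees.get(gene, self.default)

    def item_degree(self, item: GeneItem) -> int:
        return self.degree(item.gene)

    def __len__(self) -> int:
        return len(self.degrees)


def build_impact_table(
    grn: nx.Graph, significant: Iterable[str], alpha: float | None = None
) -> ImpactDegreeTable:
    """Count each GRN gene's significant neighbors.

    The gene's own significance does not enter its own degree; genes
    outside the GRN get degree 0 via the table default.
    """
    sig = frozenset(significant)
    degrees = {g: sum(1 for nb in grn.adj[g] if nb in sig) for g in grn.nodes}
    return ImpactDegreeTable(degrees=degrees, significant=sig, alpha=alpha)


def constant_degree_table(table: ImpactDegreeTable) -> ImpactDegreeTable:
    """Baseline weighting: degree 1 wherever the real degree is positive."""
    degrees = {g: 1 for g, d in table.degrees.items() if d > 0}
    return ImpactDegreeTable(
        degrees=degrees, significant=table.significant, alpha=table.alpha
    )


def uniform_degree_table() -> ImpactDegreeTable:
    """Baseline weighting: every gene has degree 1 (undifferentiation mode)."""
    return ImpactDegreeTable(degrees={}, significant=frozenset(), alpha=None, default=1)
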