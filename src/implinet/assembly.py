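"""Assembly of the seed-gene multi-omics network.

Cross-cohort implication edges are filtered so that every retained non-seed
gene connects to at least ``min_seed_degree`` *distinct* seed genes (two of
the seven signature genes by default).  Nodes are (gene, layer) pairs with
seed/proliferation flags; the graph is a networkx MultiDiGraph whose edges
carry the winning rule type, layers, statistics and supporting cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .discretize import ExpressionMatrix
from .errors import InsufficientSamples
from .implication import ImplicationRule
from .survival import SEVEN_GENES, SurvivalTable

log = logging.getLogger(__name__)

DEFAULT_MIN_SEED_DEGREE = 2


@dataclass
class MultiOmicsNetwork:
    """Typed multi-omics network around an ordered seed gene list."""

    graph: nx.MultiDiGraph
    seeds: tuple[str, ...] = SEVEN_GENES

    @property
    def genes(self) -> set[str]:
        return {g for g, _layer in self.graph.nodes}

    @property
    def proliferation_genes(self) -> set[str]:
        return {g for (g, _l), d in self.graph.nodes(data=True) if d.get("is_proliferation")}

    def edge_rules(self) -> list[dict]:
        return [d for _, _, d in self.graph.edges(data=True)]


def _node(gene: str, layer: str) -> tuple[str, str]:
    return (gene, layer)


def seed_filter(
    edges: list[ImplicationRule],
    seeds: tuple[str, ...] = SEVEN_GENES,
    min_seed_degree: int = DEFAULT_MIN_SEED_DEGREE,
) -> MultiOmicsNetwork:
    """Build the network keeping genes linked to enough distinct seeds.

    Seed nodes are always retained.  A non-seed gene counts a seed once no
    matter how many layers or edges connect them.  Orphan edges (touching a
    dropped gene) are removed; an empty result is valid but logged.
    """
    seed_set = set(seeds)
    partners: dict[str, set[str]] = {}
    for rule in edges:
        a, b = rule.source, rule.target
        if a in seed_set and b not in seed_set:
            partners.setdefault(b, set()).add(a)
        elif b in seed_set and a not in seed_set:
            partners.setdefault(a, set()).add(b)
    kept = {g for g, s in partners.items() if len(s) >= min_seed_degree}

    graph = nx.MultiDiGraph()
    for s in seeds:
        graph.add_node(_node(s, "GE"), gene=s, layer="GE", is_seed=True, is_proliferation=False)
    for rule in edges:
        a_ok = rule.source in seed_set or rule.source in kept
        b_ok = rule.target in seed_set or rule.target in kept
        if not (a_ok and b_ok):
            continue
        for gene, layer in ((rule.source, rule.source_layer), (rule.target, rule.target_layer)):
            node = _node(gene, layer)
            if node not in graph:
                graph.add_node(node, gene=gene, layer=layer,
                               is_seed=gene in seed_set, is_proliferation=False)
        graph.add_edge(
            _node(rule.source, rule.source_layer),
            _node(rule.target, rule.target_layer),
            rule_type=rule.rule_type.name,
            scope=rule.scope_U,
            precision=rule.precision_del,
            z=rule.z,
            cohorts=",".join(rule.cohorts),
        )
    if graph.number_of_edges() == 0:
        log.warning("seed_filter produced an empty network")
    return MultiOmicsNetwork(graph=graph, seeds=tuple(seeds))


def annotate_proliferation(
    network: MultiOmicsNetwork, proliferation_genes: set[str]
) -> MultiOmicsNetwork:
    """Flag nodes whose gene is in the proliferation set (in place).

    Returns the same network; the number of flagged nodes is logged, with a
    warning when the flag set is disjoint from the network.
    """
    flagged = 0
    for node, data in network.graph.nodes(data=True):
        hit = data["gene"] in proliferation_genes
        data["is_proliferation"] = hit
        flagged += hit
    if proliferation_genes and not flagged:
        log.warning("no proliferation genes present in the network")
    else:
        log.info("flagged %d proliferation nodes", flagged)
    return network


@dataclass(frozen=True)
class GroupRule:
    """Selector for the short- vs long-survival radiotherapy contrast.

    Defaults follow the radiotherapy response analysis: stage III/IV patients
    who received radiotherapy, split at < ``short_max`` months (short
    survivors) vs > ``long_min`` months (long survivors).
    """

    short_max: float = 20.0
    long_min: float = 58.0
    stages: tuple[str, ...] = ("III", "IV")
    require_radiotherapy: bool = True

    def select(self, clinical: pd.DataFrame) -> tuple[pd.Index, pd.Index]:
        df = clinical
        if self.stages and "stage" in df.columns:
            df = df[df["stage"].isin(self.stages)]
        if self.require_radiotherapy and "radiotherapy" in df.columns:
            df = df[df["radiotherapy"] == 1]
        short = df.index[df["time"] < self.short_max]
        long = df.index[df["time"] > self.long_min]
        return short, long


def differential_expression_groups(
    expr: ExpressionMatrix,
    clinical: SurvivalTable,
    group_rule: GroupRule | None = None,
    *,
    equal_var: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene two-sample t-test between short and long survivors.

    Welch's t by default (``equal_var=True`` for the pooled variant).  Returns
    a table with t, two-sided p, group means and a ``significant`` flag at
    ``alpha``; raises :class:`InsufficientSamples` when a group has < 3
    patients.
    """
    rule = group_rule or GroupRule()
    short_idx, long_idx = rule.select(clinical.data)
    short_idx = short_idx.intersection(expr.values.columns)
    long_idx = long_idx.intersection(expr.values.columns)
    if len(short_idx) < 3 or len(long_idx) < 3:
        raise InsufficientSamples(
            f"groups too small: short={len(short_idx)}, long={len(long_idx)}"
        )
    a = expr.values[short_idx].to_numpy(dtype=float)
    b = expr.values[long_idx].to_numpy(dtype=float)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    return pd.DataFrame({
        "t": t,
        "p": p,
        "mean_short": np.nanmean(a, axis=1),
        "mean_long": np.nanmean(b, axis=1),
        "n_short": len(short_idx),
        "n_long": len(long_idx),
        "significant": p < alpha,
    }, index=expr.values.index)
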