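"""A-priori path analysis with standardized total effects.

The suspended-sediment pressure (SSC, proxied by turbidity) can impact coral
mortality directly, or indirectly by attenuating benthic light and by
increasing sedimentation; sedimentation can act directly or via sediment
cover on colonies (massive corals only — branching colonies were never
observed with sediment on their surfaces); thermal stress acts via bleaching
and directly.  These causal hypotheses form a recursive DAG whose sink is the
logit of site × survey mean proportional mortality.

Each node with parents is regressed on its parents by ordinary least squares
on standardized (zero-mean, unit-variance) variables; for a recursive path
model with uncorrelated errors these per-node regressions coincide with the
joint ML estimates.  The total standardized effect of a pressure is the sum
over all directed paths to the sink of the product of edge coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit
from sklearn.base import BaseEstimator

__all__ = ["PathDAG", "default_dag", "standardize", "PathAnalysis", "fit_paths", "total_effects"]


@dataclass
class PathDAG:
    """Directed acyclic graph of pressure pathways.

    ``edges`` is a list of (parent, child) tuples; ``sink`` is the response
    node (unique, no outgoing edges).
    """

    nodes: list
    edges: list
    sink: str = "mortality_logit"
    group: str = "massive"

    def __post_init__(self):
        for a, b in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a}, {b}) references unknown node")
        if any(a == self.sink for a, _ in self.edges):
            raise ValueError("sink must have no outgoing edges")
        if self._has_cycle():
            raise ValueError("path DAG contains a cycle")

    def _has_cycle(self) -> bool:
        color = {n: 0 for n in self.nodes}
        out = {}
        for a, b in self.edges:
            out.setdefault(a, []).append(b)

        def visit(n):
            color[n] = 1
            for m in out.get(n, []):
                if color[m] == 1 or (color[m] == 0 and visit(m)):
                    return True
            color[n] = 2
            return False

        return any(color[n] == 0 and visit(n) for n in self.nodes)

    def parents(self, node: str):
        return [a for a, b in self.edges if b == node]

    def children(self, node: str):
        return [b for a, b in self.edges if a == node]

    def paths_to_sink(self, source: str):
        """All directed paths from ``source`` to the sink."""
        paths = []

        def walk(node, edges_so_far):
            if node == self.sink:
                paths.append(tuple(edges_so_far))
                return
            for child in self.children(node):
                walk(child, edges_so_far + [(node, child)])

        walk(source, [])
        return paths


def default_dag(group: str = "massive") -> PathDAG:
    """The a-priori pressure-pathway DAG for a morphological group.

    SSC → {mortality, light, sedimentation}; light → mortality;
    sedimentation → {mortality, sediment_cover}; sediment_cover → mortality
    (massive only); temperature → {bleaching, mortality};
    bleaching → mortality.
    """
    nodes = ["ssc", "light", "sedimentation", "temperature", "bleaching", "mortality_logit"]
    edges = [
        ("ssc", "mortality_logit"),
        ("ssc", "light"),
        ("ssc", "sedimentation"),
        ("light", "mortality_logit"),
        ("sedimentation", "mortality_logit"),
        ("temperature", "bleaching"),
        ("temperature", "mortality_logit"),
        ("bleaching", "mortality_logit"),
    ]
    if group == "massive":
        nodes.insert(3, "sediment_cover")
        edges += [("sedimentation", "sediment_cover"), ("sediment_cover", "mortality_logit")]
    return PathDAG(nodes=nodes, edges=edges, group=group)


def standardize(
    table: pd.DataFrame, response: str | None = None, clip: float = 1e-4
) -> pd.DataFrame:
    """Zero-mean, unit-variance (sample SD) columns.

    If ``response`` names a column of mean proportional mortality it is first
    transformed as ``logit(clip(p, clip, 1 - clip))`` and renamed
    ``mortality_logit`` before standardization.
    """
    df = table.copy()
    if response is not None:
        p = np.clip(df[response].to_numpy(dtype=float), clip, 1 - clip)
        df = df.drop(columns=[response])
        df["mortality_logit"] = logit(p)
    for col in df.columns:
        v = df[col].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {col!r} has zero variance")
        df[col] = (v - v.mean()) / sd
    return df


class PathAnalysis(BaseEstimator):
    """Per-node OLS path analysis on standardized data.

    Fitted attributes: ``edge_coefs_`` (dict edge → standardized
    coefficient), ``total_effects_`` (dict pressure node → total standardized
    effect on the sink), ``n_obs_``.
    """

    def __init__(self, dag: PathDAG | None = None, max_condition: float = 1e8):
        self.dag = dag
        self.max_condition = max_condition

    def fit(self, data: pd.DataFrame, y=None):
        dag = self.dag or default_dag()
        missing = set(dag.nodes) - set(data.columns)
        if missing:
            raise ValueError(f"data missing DAG nodes: {sorted(missing)}")
        if len(data) <= len(dag.edges) + 5:
            raise ValueError("too few rows for the number of edges")
        coefs = {}
        for node in dag.nodes:
            parents = dag.parents(node)
            if not parents:
                continue
            X = data[parents].to_numpy(dtype=float)
            if np.linalg.cond(X.T @ X) > self.max_condition:
                raise ValueError(f"collinear parents for node {node!r}")
            yv = data[node].to_numpy(dtype=float)
            Xd = np.column_stack([np.ones(len(X)), X])
            beta, *_ = np.linalg.lstsq(Xd, yv, rcond=None)
            for p, b in zip(parents, beta[1:]):
                coefs[(p, node)] = float(b)
        self.dag_ = dag
        self.edge_coefs_ = coefs
        self.n_obs_ = len(data)
        self.total_effects_ = total_effects(coefs, dag)
        return self


def fit_paths(dag: PathDAG, data: pd.DataFrame) -> PathAnalysis:
    """Fit the path model (thin wrapper over :class:`PathAnalysis`)."""
    return PathAnalysis(dag=dag).fit(data)


def total_effects(edge_coefs: dict, dag: PathDAG) -> dict:
    """Total standardized effect per pressure node.

    Sum over directed paths from each non-sink source node to the sink of the
    product of edge coefficients along the path.
    """
    totals = {}
    for node in dag.nodes:
        if node == dag.sink:
            continue
        total = 0.0
        for path in dag.paths_to_sink(node):
            prod = 1.0
            for edge in path:
                prod *= edge_coefs[edge]
            total += prod
        totals[node] = total
    return totals
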