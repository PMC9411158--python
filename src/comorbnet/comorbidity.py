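"""Disease-pair comorbidity scoring and disease-network analytics.

Two diseases are scored by the Jaccard index of their MOA protein sets
(the J-score) with a one-sided hypergeometric p-value for observing an
overlap at least that large when one set is drawn at random from the
protein universe.  q-values control the FDR across the full pair family at
once; edges are emitted for every pair with a significance flag so global
counts are derivable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import sqrt
from typing import Mapping, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from . import stats
from .core_io import EDGE_COLUMNS, PipelineConfig, rank_edges
from .exceptions import DomainError, ValidationError
from .moa import MOAProfile

log = logging.getLogger(__name__)


class ComorbidityEdge(NamedTuple):
    """One unordered disease pair (disease_a < disease_b lexicographically)."""

    disease_a: str
    disease_b: str
    n_shared: int
    j_score: float
    p_value: float
    q_value: float
    significant: bool


def jscore(ns: int, nd1: int, nd2: int) -> float:
    """Jaccard index Ns / (ND1 + ND2 - Ns); 0 when both sets are empty."""
    if ns < 0 or ns > min(nd1, nd2):
        raise DomainError(f"overlap {ns} infeasible for set sizes ({nd1}, {nd2})")
    denom = nd1 + nd2 - ns
    return ns / denom if denom > 0 else 0.0


def pair_p_value(ns: int, nd1: int, nd2: int, nt: int) -> float:
    """P(overlap >= Ns) when an ND2-subset of the Nt-protein universe is
    drawn at random against a fixed ND1-set; 1.0 if either profile is empty."""
    if nd1 > nt or nd2 > nt:
        raise DomainError(f"profile sizes ({nd1}, {nd2}) exceed universe {nt}")
    if nd1 == 0 or nd2 == 0:
        return 1.0
    return stats.hypergeom_right_tail(ns, nd1, nd2, nt)


def all_pairs(
    profiles: Mapping[str, MOAProfile], n_t: int, config: PipelineConfig
) -> pd.DataFrame:
    """Score every unordered disease pair (self-pairs excluded).

    Returns a DataFrame with columns disease_a, disease_b, n_shared,
    j_score, p_value, q_value, significant — exactly n(n-1)/2 rows.  Pairs
    involving an empty profile carry J=0, p=1.
    """
    ids = sorted(profiles)
    n = len(ids)
    if n < 2:
        raise ValidationError("need at least 2 disease profiles")
    sizes = np.array([profiles[d].n_d for d in ids], dtype=np.int64)
    if sizes.max(initial=0) > n_t:
        raise ValidationError("a profile exceeds the protein universe size")

    iu_a, iu_b = np.triu_indices(n, k=1)
    union_proteins = sorted(set().union(*(profiles[d].moa_set for d in ids)))
    if union_proteins:
        pidx = {p: j for j, p in enumerate(union_proteins)}
        member = np.zeros((n, len(union_proteins)), dtype=np.int32)
        for i, d in enumerate(ids):
            for p in profiles[d].moa_set:
                member[i, pidx[p]] = 1
        overlap = member @ member.T
        ns = overlap[iu_a, iu_b].astype(np.int64)
    else:
        ns = np.zeros(iu_a.size, dtype=np.int64)

    nd1 = sizes[iu_a]
    nd2 = sizes[iu_b]
    denom = nd1 + nd2 - ns
    with np.errstate(invalid="ignore"):
        j = np.where(denom > 0, ns / np.maximum(denom, 1), 0.0)

    p = np.ones(ns.size, dtype=float)
    mask = (nd1 > 0) & (nd2 > 0)
    if mask.any():
        p[mask] = stats.hypergeom_right_tail_vec(ns[mask], nd1[mask], nd2[mask], n_t)
    q = stats.qvalues(p)

    id_arr = np.asarray(ids, dtype=object)
    frame = pd.DataFrame(
        {
            "disease_a": id_arr[iu_a],
            "disease_b": id_arr[iu_b],
            "n_shared": ns,
            "j_score": j,
            "p_value": p,
            "q_value": q,
            "significant": q < config.pair_q_cutoff,
        }
    )
    log.info(
        "scored %d disease pairs, %d significant at q<%g",
        len(frame),
        int(frame["significant"].sum()),
        config.pair_q_cutoff,
    )
    return frame


def edges_for(edges: pd.DataFrame, disease: str) -> pd.DataFrame:
    """Subset of the edge table touching one disease, with an `other` column."""
    sub = edges[(edges["disease_a"] == disease) | (edges["disease_b"] == disease)].copy()
    sub["other"] = np.where(sub["disease_a"] == disease, sub["disease_b"], sub["disease_a"])
    return sub


def geneset_query(
    genes: frozenset | set,
    profiles: Mapping[str, MOAProfile],
    n_t: int,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Score a user gene set as a pseudo-disease against every profile.

    q-values are computed across the queried diseases; the result is ranked
    by (q ascending, J descending, disease ascending).
    """
    genes = frozenset(genes)
    if not genes:
        raise ValidationError("query gene set is empty after universe intersection")
    ids = sorted(profiles)
    nq = len(genes)
    rows = []
    for d in ids:
        moa = profiles[d].moa_set
        ns = len(genes & moa)
        rows.append((d, ns, jscore(ns, nq, len(moa)), pair_p_value(ns, nq, len(moa), n_t)))
    frame = pd.DataFrame(rows, columns=["disease", "n_shared", "j_score", "p_value"])
    frame["q_value"] = stats.qvalues(frame["p_value"].to_numpy())
    frame["significant"] = frame["q_value"] < config.pair_q_cutoff
    return frame.sort_values(
        ["q_value", "j_score", "disease"],
        ascending=[True, False, True],
        kind="mergesort",
        ignore_index=True,
    )


def easy_pair_score(eff_a: frozenset | set, eff_b: frozenset | set) -> float:
    """Cosine-style overlap of two diseases' efficacious drug sets.

    Pairs scoring above the easy-pair cutoff are trivially comorbid by
    construction (nearly the same drugs treat both) and are excluded from
    benchmarking.
    """
    if not eff_a or not eff_b:
        raise DomainError("easy-pair score undefined for an empty drug set")
    return len(set(eff_a) & set(eff_b)) / sqrt(len(eff_a) * len(eff_b))


@dataclass
class NetworkReport:
    """Disease-network analytics at the significant-edge threshold."""

    degree: dict
    closeness: dict
    betweenness: dict
    giant_fraction: float
    curve: list  # [(j_cutoff, giant-component fraction), ...]

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "closeness": self.closeness,
            "betweenness": self.betweenness,
            "giant_fraction": self.giant_fraction,
            "curve": [[float(c), float(f)] for c, f in self.curve],
        }


def network_report(
    edges: pd.DataFrame, j_cutoff_grid, config: PipelineConfig
) -> NetworkReport:
    """Characterize the disease-disease network of significant edges.

    Nodes are every disease mentioned in the edge table (isolated nodes
    included).  Closeness is (number of other reachable nodes) / (sum of
    shortest hop distances to them), computed within the node's component;
    betweenness is the equal-split count of shortest paths through a node;
    the giant-component curve is the fraction of all nodes in the largest
    component as the J cutoff rises (q filter and J cutoff applied
    conjunctively).  Unweighted shortest paths throughout.
    """
    nodes = sorted(set(edges["disease_a"]) | set(edges["disease_b"]))
    sig = edges[edges["significant"]] if "significant" in edges else edges[
        edges["q_value"] < config.pair_q_cutoff
    ]
    if not nodes:
        return NetworkReport({}, {}, {}, 0.0, [(float(c), 0.0) for c in j_cutoff_grid])

    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(zip(sig["disease_a"], sig["disease_b"], ({"j": j} for j in sig["j_score"])))

    degree = dict(g.degree())
    closeness = nx.closeness_centrality(g, wf_improved=False)
    betweenness = nx.betweenness_centrality(g, normalized=False)
    n = g.number_of_nodes()
    giant = max((len(c) for c in nx.connected_components(g)), default=0)

    curve = []
    for cutoff in j_cutoff_grid:
        h = nx.Graph()
        h.add_nodes_from(nodes)
        h.add_edges_from(
            (a, b) for a, b, d in g.edges(data=True) if d["j"] >= cutoff
        )
        frac = max((len(c) for c in nx.connected_components(h)), default=0) / n
        curve.append((float(cutoff), frac))

    return NetworkReport(degree, closeness, betweenness, giant / n, curve)


def edge_table_from_frame(frame: pd.DataFrame) -> list[ComorbidityEdge]:
    """Materialize edge rows as named tuples (canonical order)."""
    ranked = rank_edges(frame)
    return [
        ComorbidityEdge(
            r.disease_a,
            r.disease_b,
            int(r.n_shared),
            float(r.j_score),
            float(r.p_value),
            float(r.q_value),
            bool(getattr(r, "significant", False)),
        )
        for r in ranked.itertuples(index=False)
    ]


__all__ = [
    "ComorbidityEdge",
    "NetworkReport",
    "all_pairs",
    "easy_pair_score",
    "edge_table_from_frame",
    "edges_for",
    "geneset_query",
    "jscore",
    "network_report",
    "pair_p_value",
    "EDGE_COLUMNS",
]
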