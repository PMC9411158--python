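"""Comorbidity-enriched MOA proteins and pathway over-representation.

A protein shared between a focal disease and one of its top comorbid
diseases contributes a weight min(1, -alpha * ln p), where p is the
comorbid disease's MOA p-value for that protein and alpha = 0.025.  The sum
of weights over the top-k comorbidities, normalized by k, is the
CoMOAenrich score; an implied p-value is exp(-total_weight / alpha), so a
single full-weight contribution (total weight 1) corresponds to
exp(-40) ~ 4.2e-18.  The natural log is forced by that correspondence.

Pathway over-representation on the top enriched proteins is a one-sided
hypergeometric test against user-supplied GMT gene sets over the protein
universe — a declared surrogate for the external pathway service the
published analysis used.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping

import pandas as pd

from . import stats
from .comorbidity import edges_for
from .core_io import GeneSetCollection, PipelineConfig, ProteinUniverse
from .exceptions import DomainError, ValidationError
from .moa import MOAProfile

log = logging.getLogger(__name__)

ENRICH_COLUMNS = ("protein", "total_weight", "score", "implied_p", "enriched")
PATHWAY_COLUMNS = ("pathway", "description", "overlap", "p_value", "q_value", "significant")


def comoa_weight(p: float, alpha: float) -> float:
    """Per-comorbidity weight min(1, -alpha * ln p), in [0, 1].

    Non-positive p is clamped to the package-wide floor before the log.
    """
    if alpha <= 0:
        raise DomainError("alpha must be positive")
    if p > 1.0:
        raise DomainError(f"p-value {p} exceeds 1")
    p = max(p, stats.P_FLOOR)
    return min(1.0, -alpha * math.log(p))


def score_to_p(total_weight: float, alpha: float) -> float:
    """Implied p-value exp(-total_weight / alpha) of an UNNORMALIZED weight."""
    if total_weight < 0:
        raise DomainError("total weight must be non-negative")
    if alpha <= 0:
        raise DomainError("alpha must be positive")
    return math.exp(-total_weight / alpha)


def comoa_enrich(
    focal: str,
    edges: pd.DataFrame,
    profiles: Mapping[str, MOAProfile],
    config: PipelineConfig,
) -> pd.DataFrame:
    """p-value-weighted frequency of the focal disease's MOA proteins across
    its top comorbidities.

    Takes the top k = min(top_k_comorbid, #significant comorbidities)
    comorbid diseases ranked by (q asc, J desc, id asc); for each protein in
    the focal MOA set sums comoa_weight over the comorbid diseases whose MOA
    set shares it; score = total_weight / k.  Records with score above the
    enrichment cutoff are flagged; sorted by score descending.
    """
    if focal not in profiles:
        raise ValidationError(f"unknown focal disease {focal!r}")
    sub = edges_for(edges, focal)
    sub = sub[sub["significant"]] if "significant" in sub else sub[
        sub["q_value"] < config.pair_q_cutoff
    ]
    if not len(sub):
        log.warning("disease %s has no significant comorbidities", focal)
        return pd.DataFrame(columns=list(ENRICH_COLUMNS))

    ranked = sub.sort_values(
        ["q_value", "j_score", "other"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    top = list(ranked["other"].head(config.top_k_comorbid))
    k_used = len(top)

    rows = []
    for protein in sorted(profiles[focal].moa_set):
        total = 0.0
        for other in top:
            prof = profiles[other]
            if protein in prof.moa_set:
                total += comoa_weight(prof.p_for(protein), config.alpha)
        score = total / k_used
        rows.append(
            (protein, total, score, score_to_p(total, config.alpha),
             score > config.enrich_score_cutoff)
        )
    frame = pd.DataFrame(rows, columns=list(ENRICH_COLUMNS))
    return frame.sort_values(
        ["score", "protein"], ascending=[False, True], kind="mergesort", ignore_index=True
    )


def top_enriched_proteins(enrich: pd.DataFrame, limit: int = 100) -> frozenset:
    """Up to the top ``limit`` enriched proteins, by score."""
    flagged = enrich[enrich["enriched"]]
    return frozenset(flagged["protein"].head(limit))


def pathway_ora(
    query: frozenset | set,
    collection: GeneSetCollection,
    universe: ProteinUniverse,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a query protein set.

    For each pathway, p = P(overlap >= observed) when |query| proteins are
    drawn from the universe against the pathway's in-universe members;
    q-values across the collection; pathways with p < 0.05 flagged; sorted
    by p ascending.
    """
    query = frozenset(query) & frozenset(universe.proteins)
    if not query:
        raise ValidationError("query has no proteins in the universe")
    if len(collection) == 0:
        return pd.DataFrame(columns=list(PATHWAY_COLUMNS))
    rows = []
    for name, (desc, genes) in collection.items():
        in_universe = universe.intersect(genes)
        k = len(query & in_universe)
        p = stats.hypergeom_right_tail(k, len(in_universe), len(query), universe.n_t)
        rows.append((name, desc, k, p))
    frame = pd.DataFrame(rows, columns=["pathway", "description", "overlap", "p_value"])
    frame["q_value"] = stats.qvalues(frame["p_value"].to_numpy())
    frame["significant"] = frame["p_value"] < 0.05
    return frame.sort_values(
        ["p_value", "pathway"], kind="mergesort", ignore_index=True
    )


def write_enrich_table(frame: pd.DataFrame, path) -> None:
    out = frame.copy()
    if "enriched" in out:
        out["enriched"] = out["enriched"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_pathway_table(frame: pd.DataFrame, path) -> None:
    out = frame.copy()
    if "significant" in out:
        out["significant"] = out["significant"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
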