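"""Clinical benchmarking: co-occurrence statistics, evaluation metrics and
permutation null models.

A disease pair is clinically comorbid (a true positive) when its claims
log relative risk is positive; the pipeline predicts a positive when the
pair's J-score q-value clears the FDR cutoff.  Easy pairs — whose
efficacious drug sets overlap almost completely — are excluded before any
metric.  Two permutation nulls rerun the whole pipeline after shuffling
either the drug->target map or the drug->indication score rows among
drugs; each observed metric is summarized against the null as
z = (observed - mean) / sd with a one-sided upper-tail normal p.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from . import stats
from .comorbidity import all_pairs, easy_pair_score
from .core_io import (
    DrugIndicationScoreMatrix,
    DrugTargetMap,
    PipelineConfig,
    WorldInputs,
)
from .exceptions import DomainError, ValidationError
from .moa import infer_moa_profiles

log = logging.getLogger(__name__)

METRIC_NAMES = ("cc_logrr", "cc_phi", "recall", "precision", "auroc", "auprc")


def log_rr(n_a: int, n_b: int, n_ab: int, n_tot: int) -> float:
    """Natural-log relative risk ln((n_ab/n_tot) / ((n_a/n_tot)(n_b/n_tot))).

    Positive iff the two diseases co-occur more often than independence
    predicts.  Undefined for n_ab = 0 (callers exclude such records).
    """
    if n_ab < 1:
        raise DomainError("log RR undefined for n_ab = 0")
    if n_a < 1 or n_b < 1:
        raise DomainError("log RR requires n_a, n_b >= 1")
    if n_tot < max(n_a, n_b):
        raise DomainError("n_tot smaller than a margin")
    return math.log((n_ab / n_tot) / ((n_a / n_tot) * (n_b / n_tot)))


def phi_score(n_a: int, n_b: int, n_ab: int, n_tot: int) -> float:
    """Pearson correlation of the two binary disease indicators over the cohort."""
    if not (0 < n_a < n_tot and 0 < n_b < n_tot):
        raise DomainError("phi undefined for degenerate margins")
    num = n_ab * n_tot - n_a * n_b
    den = math.sqrt(n_a * n_b * (n_tot - n_a) * (n_tot - n_b))
    return num / den


def auroc(scores, labels) -> float:
    """Tie-corrected rank AUROC of a continuous score against binary labels."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise DomainError("AUROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores, labels) -> float:
    """Step-wise precision-recall summation (average precision)."""
    labels = np.asarray(labels, dtype=bool)
    if not labels.any():
        raise DomainError("AUPRC needs at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class BenchmarkReport:
    """Table-1-style evaluation of predicted vs clinical comorbidity."""

    cc_logrr: float
    cc_logrr_p: float
    cc_phi: float
    cc_phi_p: float
    recall: float      # percent
    precision: float   # percent (nan when nothing is predicted positive)
    auroc: float
    auprc: float
    n_pairs_used: int
    n_excluded_easy: int

    def metrics(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _canonical_pairs(frame: pd.DataFrame, a: str, b: str) -> pd.DataFrame:
    frame = frame.copy()
    lo = np.minimum(frame[a], frame[b])
    hi = np.maximum(frame[a], frame[b])
    frame[a], frame[b] = lo, hi
    return frame


def evaluate(
    edges: pd.DataFrame,
    clinical: pd.DataFrame,
    config: PipelineConfig,
    eff_sets: dict[str, frozenset] | None = None,
) -> BenchmarkReport:
    """Score predictions against clinical co-occurrence counts.

    Joins the two tables on the unordered pair (pairs missing from either
    side are dropped), removes easy pairs when efficacious drug sets are
    supplied, drops records with n_ab = 0 (log RR undefined), then computes
    correlations of J with log RR and phi, recall/precision at the q
    cutoff, and AUROC/AUPRC with J as the continuous score.
    """
    if config.clinical_n_tot is None:
        raise ValidationError("clinical_n_tot must be set in the config")
    n_tot = config.clinical_n_tot

    pred = _canonical_pairs(edges, "disease_a", "disease_b")
    clin = _canonical_pairs(clinical, "disease_a", "disease_b")
    merged = pred.merge(clin, on=["disease_a", "disease_b"], how="inner")
    if not len(merged):
        raise ValidationError("no overlapping pairs between predictions and clinical table")

    n_excluded = 0
    if eff_sets is not None:
        keep = np.ones(len(merged), dtype=bool)
        for i, (da, db) in enumerate(zip(merged["disease_a"], merged["disease_b"])):
            ea, eb = eff_sets.get(da, frozenset()), eff_sets.get(db, frozenset())
            if not ea or not eb:
                log.warning("easy-pair score undefined for (%s, %s); pair retained", da, db)
                continue
            if easy_pair_score(ea, eb) > config.easy_pair_cutoff:
                keep[i] = False
        n_excluded = int((~keep).sum())
        merged = merged[keep]

    zero_ab = merged["n_ab"] == 0
    if zero_ab.any():
        log.warning("excluding %d pairs with n_ab = 0 (log RR undefined)", int(zero_ab.sum()))
        merged = merged[~zero_ab]

    if len(merged) < 10:
        raise ValidationError(f"only {len(merged)} evaluable pairs; need >= 10")

    logrr = np.array(
        [log_rr(r.n_a, r.n_b, r.n_ab, n_tot) for r in merged.itertuples(index=False)]
    )
    phi = np.array(
        [phi_score(r.n_a, r.n_b, r.n_ab, n_tot) for r in merged.itertuples(index=False)]
    )
    j = merged["j_score"].to_numpy()
    labels = logrr > 0
    if not labels.any():
        raise ValidationError("no true positives in the clinical table")
    predicted = (
        merged["significant"].to_numpy()
        if "significant" in merged
        else (merged["q_value"] < config.pair_q_cutoff).to_numpy()
    )

    tp = int((labels & predicted).sum())
    recall = 100.0 * tp / int(labels.sum())
    precision = 100.0 * tp / int(predicted.sum()) if predicted.any() else float("nan")

    def _cc(x, y):
        try:
            return stats.pearson_with_p(x, y)
        except DomainError:
            return float("nan"), float("nan")

    cc1, p1 = _cc(j, logrr)
    cc2, p2 = _cc(j, phi)
    try:
        roc = auroc(j, labels)
    except DomainError:
        roc = float("nan")
    ap = auprc(j, labels)

    return BenchmarkReport(
        cc_logrr=cc1, cc_logrr_p=p1, cc_phi=cc2, cc_phi_p=p2,
        recall=recall, precision=precision, auroc=roc, auprc=ap,
        n_pairs_used=len(merged), n_excluded_easy=n_excluded,
    )


# ---------------------------------------------------------------------------
# permutation nulls
# ---------------------------------------------------------------------------


def permute_drug_protein(targets: DrugTargetMap, drugs, seed: int) -> DrugTargetMap:
    """Reassign whole target SETS among drugs by a uniform random bijection.

    The multiset of target sets is preserved; only the drug->set pairing is
    broken.
    """
    drugs = list(drugs)
    if len(drugs) < 2:
        raise ValidationError("need at least 2 drugs to permute")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(drugs))
    return DrugTargetMap(
        {drugs[i]: targets.targets_of(drugs[perm[i]]) for i in range(len(drugs))}
    )


def permute_drug_disease(
    scores: DrugIndicationScoreMatrix, seed: int
) -> DrugIndicationScoreMatrix:
    """Reassign whole score ROWS (a drug's indication profile) among drugs by
    a uniform random bijection."""
    drugs = scores.drugs
    if len(drugs) < 2:
        raise ValidationError("need at least 2 drugs to permute")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(drugs))
    frame = pd.DataFrame(
        scores.frame.to_numpy()[perm], index=drugs, columns=scores.indications
    )
    return DrugIndicationScoreMatrix(frame)


@dataclass
class PermutationSummary:
    """One metric's observed value against its permutation null."""

    metric: str
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p: float


def _pipeline_metrics(inputs: WorldInputs, clinical: pd.DataFrame, config: PipelineConfig):
    profiles = infer_moa_profiles(inputs, config)
    edges = all_pairs(profiles, inputs.universe.n_t, config)
    eff = {d: p.eff_drugs for d, p in profiles.items()}
    report = evaluate(edges, clinical, config, eff_sets=eff)
    return report.metrics()


def permutation_test(
    inputs: WorldInputs,
    clinical: pd.DataFrame,
    config: PipelineConfig,
    which: str,
) -> list[PermutationSummary]:
    """Full-pipeline permutation null for ``which`` in {drug_protein, drug_disease}.

    Runs the observed pipeline once, then n_permutations permuted runs with
    seeds rng_seed+1 .. rng_seed+n.  For each metric reports the observed
    value, null mean/sd over runs (nan-aware: a null run can leave a metric
    undefined), z = (observed - mean)/sd and the one-sided upper-tail normal p.
    """
    if which not in ("drug_protein", "drug_disease"):
        raise ValidationError(f"unknown permutation kind {which!r}")

    observed = _pipeline_metrics(inputs, clinical, config)
    null_rows = []
    for i in range(1, config.n_permutations + 1):
        seed = config.rng_seed + i
        if which == "drug_protein":
            perm_inputs = dataclasses.replace(
                inputs,
                targets=permute_drug_protein(inputs.targets, inputs.scores.drugs, seed),
            )
        else:
            perm_inputs = dataclasses.replace(
                inputs, scores=permute_drug_disease(inputs.scores, seed)
            )
        null_rows.append(_pipeline_metrics(perm_inputs, clinical, config))

    summaries = []
    for name in METRIC_NAMES:
        null = np.array([row[name] for row in null_rows], dtype=float)
        mean = float(np.nanmean(null)) if np.isfinite(null).any() else float("nan")
        sd = float(np.nanstd(null, ddof=1)) if np.isfinite(null).sum() > 1 else float("nan")
        obs = observed[name]
        if sd and sd > 0 and math.isfinite(sd) and math.isfinite(obs):
            z = (obs - mean) / sd
            p = stats.normal_right_tail(z)
        else:
            z, p = float("nan"), float("nan")
        summaries.append(PermutationSummary(name, obs, mean, sd, z, p))
    return summaries


def write_permutation_table(summaries: list[PermutationSummary], path) -> None:
    frame = pd.DataFrame(
        [(s.metric, s.observed, s.null_mean, s.null_sd, s.z, s.p) for s in summaries],
        columns=["metric", "observed", "null_mean", "null_sd", "z", "p"],
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
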