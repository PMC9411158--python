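"""Per-disease mode-of-action (MOA) protein inference.

For every indication the probe-drug raw scores are standardized to
Z-scores over the whole drug library, the library is split into an
efficacious group (Z >= cutoff) and the rest, and each protein target is
tested for enrichment among the efficacious drugs' predicted targets with a
relative risk and a one-sided Fisher exact p-value.  Candidates that are
"not detected" (and never "uncertain") in every tissue related to the
disease are filtered out; the survivors with p below the cutoff form the
disease's MOA protein set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .core_io import (
    DiseaseTissueMap,
    PipelineConfig,
    TissueExpressionTable,
    WorldInputs,
)
from .exceptions import DomainError

log = logging.getLogger(__name__)

MOA_COLUMNS = ("protein", "n1t", "n2t", "rr", "p", "q", "passed_tissue_filter")


@dataclass(frozen=True)
class IndicationDrugPartition:
    """Split of the probe-drug library for one indication."""

    indication: str
    efficacious: frozenset
    rest: frozenset

    @property
    def n1(self) -> int:
        return len(self.efficacious)

    @property
    def n2(self) -> int:
        return len(self.rest)


@dataclass
class MOAProfile:
    """A disease's significant MOA protein set plus the full association table.

    ``moa_set`` membership is decided on the raw Fisher p (p < cutoff, after
    the tissue filter); per-disease q-values are carried in the table for
    ranking only.
    """

    disease: str
    moa_set: frozenset
    table: pd.DataFrame
    eff_drugs: frozenset = frozenset()
    _pmap: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._pmap and len(self.table):
            self._pmap = dict(zip(self.table["protein"], self.table["p"]))

    @property
    def n_d(self) -> int:
        return len(self.moa_set)

    def p_for(self, protein: str) -> float:
        """Fisher p of a protein's association with this disease (1.0 if untested)."""
        return self._pmap.get(protein, 1.0)


def empty_profile(disease: str, eff_drugs: frozenset = frozenset()) -> MOAProfile:
    table = pd.DataFrame(
        {c: pd.Series(dtype=(object if c == "protein" else float)) for c in MOA_COLUMNS}
    )
    return MOAProfile(disease, frozenset(), table, eff_drugs)


def standardize_scores(raw) -> np.ndarray:
    """Z-scores against the full drug library: (raw - mean) / population sd.

    The probe library is the whole population of interest, hence the
    divide-by-N standard deviation.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise DomainError("need at least 2 drug scores to standardize")
    sd = raw.std(ddof=0)
    if sd == 0.0:
        raise DomainError("constant raw scores: indication unusable")
    return (raw - raw.mean()) / sd


def partition_drugs(drugs, z, cutoff: float, indication: str = "") -> IndicationDrugPartition:
    """Boundary-inclusive split: a drug is efficacious iff z >= cutoff."""
    z = np.asarray(z, dtype=float)
    drugs = list(drugs)
    mask = z >= cutoff
    return IndicationDrugPartition(
        indication=indication,
        efficacious=frozenset(d for d, m in zip(drugs, mask) if m),
        rest=frozenset(d for d, m in zip(drugs, mask) if not m),
    )


def relative_risk(n1t: int, N1: int, n2t: int, N2: int) -> float:
    """RR = (n1t/N1) / (n2t/N2); 0 when no drug binds, +inf when only
    efficacious drugs bind."""
    if N1 < 1:
        raise DomainError("no efficacious drugs: partition unusable")
    if N2 < 1:
        raise DomainError("no non-efficacious drugs: partition unusable")
    if not (0 <= n1t <= N1 and 0 <= n2t <= N2):
        raise DomainError(f"counts out of range: ({n1t}/{N1}, {n2t}/{N2})")
    if n1t == 0 and n2t == 0:
        return 0.0
    if n2t == 0:
        return float("inf")
    return (n1t / N1) / (n2t / N2)


def moa_p_value(n1t: int, N1: int, n2t: int, N2: int) -> float:
    """One-sided Fisher p for the 2x2 table [[n1t, N1-n1t], [n2t, N2-n2t]]."""
    return stats.fisher_right_tail(n1t, N1 - n1t, n2t, N2 - n2t)


def tissue_filter(
    candidates: frozenset | set,
    expr: TissueExpressionTable | None,
    tissues: frozenset | set,
) -> frozenset:
    """Drop candidates called "not detected" in every related tissue.

    A candidate is removed iff it has at least one expression record in the
    related tissues, every such record has level "not detected", and none is
    flagged "uncertain".  Proteins untested in all related tissues are
    retained (absence of evidence is not a "not detected" call); an empty
    tissue set makes the filter a no-op.
    """
    candidates = frozenset(candidates)
    if expr is None or not tissues or not candidates:
        return candidates
    rec = expr.records
    sub = rec[rec["tissue"].isin(tissues) & rec["protein"].isin(candidates)]
    if not len(sub):
        return candidates
    flags = pd.DataFrame(
        {
            "protein": sub["protein"].to_numpy(),
            "detected": (sub["level"] != "not detected").to_numpy(),
            "uncertain": (sub["reliability"] == "uncertain").to_numpy(),
        }
    ).groupby("protein", sort=False).any()
    removed = set(flags.index[~flags["detected"] & ~flags["uncertain"]])
    return candidates - removed


def infer_moa_profiles(
    inputs: WorldInputs, config: PipelineConfig | None = None
) -> dict[str, MOAProfile]:
    """Run the full MOA stage for every indication in the score matrix.

    Indications whose scores have zero variance, or where the Z-cutoff puts
    every drug on one side, yield empty profiles with a logged warning.
    Deterministic: no randomness anywhere in this stage.
    """
    config = config or inputs.config
    scores = inputs.scores
    drugs = scores.drugs
    n_drugs = len(drugs)

    # drug x protein incidence restricted to proteins some drug binds
    bound_proteins = sorted({p for d in drugs for p in inputs.targets.targets_of(d)})
    prot_index = {p: j for j, p in enumerate(bound_proteins)}
    incidence = np.zeros((n_drugs, len(bound_proteins)), dtype=np.int32)
    for i, d in enumerate(drugs):
        for p in inputs.targets.targets_of(d):
            incidence[i, prot_index[p]] = 1
    totals = incidence.sum(axis=0)

    tissue_map = inputs.tissue_map or DiseaseTissueMap({})
    profiles: dict[str, MOAProfile] = {}
    drug_arr = np.asarray(drugs, dtype=object)

    for indication in scores.indications:
        raw = scores.column(indication)
        try:
            z = standardize_scores(raw)
        except DomainError:
            log.warning("indication %s: constant scores, empty profile", indication)
            profiles[indication] = empty_profile(indication)
            continue
        eff_mask = z >= config.z_cutoff
        N1 = int(eff_mask.sum())
        N2 = n_drugs - N1
        eff_drugs = frozenset(drug_arr[eff_mask])
        if N1 == 0 or N2 == 0:
            log.warning(
                "indication %s: degenerate partition (N1=%d), empty profile",
                indication,
                N1,
            )
            profiles[indication] = empty_profile(indication, eff_drugs)
            continue

        if not bound_proteins:
            profiles[indication] = empty_profile(indication, eff_drugs)
            continue

        n1t = eff_mask.astype(np.int32) @ incidence
        n2t = totals - n1t
        keep = totals > 0
        prots = np.asarray(bound_proteins, dtype=object)[keep]
        k1, k2 = n1t[keep], n2t[keep]

        with np.errstate(divide="ignore"):
            rr = (k1 / N1) / np.where(k2 > 0, k2 / N2, np.nan)
        rr = np.where(k2 == 0, np.inf, rr)
        rr = np.where((k1 == 0) & (k2 == 0), 0.0, rr)

        p = stats.hypergeom_right_tail_vec(k1, k1 + k2, N1, n_drugs)
        q = stats.qvalues(p)

        related = tissue_map.tissues_of(indication)
        passed = tissue_filter(frozenset(prots), inputs.tissue, related)
        passed_flag = np.fromiter((p_ in passed for p_ in prots), dtype=bool, count=len(prots))

        table = pd.DataFrame(
            {
                "protein": prots,
                "n1t": k1,
                "n2t": k2,
                "rr": rr,
                "p": p,
                "q": q,
                "passed_tissue_filter": passed_flag.astype(int),
            }
        ).sort_values(["p", "protein"], kind="mergesort", ignore_index=True)

        moa_set = frozenset(
            table.loc[
                (table["p"] < config.moa_p_cutoff)
                & (table["passed_tissue_filter"] == 1),
                "protein",
            ]
        )
        profiles[indication] = MOAProfile(indication, moa_set, table, eff_drugs)
        log.info(
            "indication %s: N1=%d, %d proteins tested, %d MOA",
            indication,
            N1,
            len(table),
            len(moa_set),
        )
    return profiles


def write_moa_tables(profiles: dict[str, MOAProfile], path) -> None:
    """Concatenated per-disease MOA association table as TSV."""
    frames = []
    for disease in sorted(profiles):
        t = profiles[disease].table.copy()
        t.insert(0, "disease", disease)
        frames.append(t)
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["disease", *MOA_COLUMNS])
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
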