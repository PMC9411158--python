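"""Seeded synthetic world with planted ground truth.

The generator emulates the upstream predictions the pipeline consumes —
probe-drug indication scores, drug->target maps, tissue expression calls
and clinical co-occurrence counts — with a known molecular truth planted
underneath: every disease owns a module of proteins, designated comorbid
pairs share a fixed fraction of their modules, each drug is focused on one
disease and binds mostly its module, and a drug's raw score for a disease
grows with the fraction of its targets inside that disease's module.
Clinical counts are binomial draws whose co-occurrence probability is
boosted above independence for planted pairs only, so the molecular and
clinical ground truths agree.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .benchmark import auroc
from .core_io import (
    DiseaseTissueMap,
    DrugIndicationScoreMatrix,
    DrugTargetMap,
    EXPRESSION_LEVELS,
    GeneSetCollection,
    PipelineConfig,
    ProteinUniverse,
    TissueExpressionTable,
    WorldInputs,
    write_clinical,
    write_gmt,
    write_score_matrix,
    write_target_map,
    write_tissue_map,
    write_tissue_table,
    write_universe,
)
from .exceptions import ValidationError

RELIABILITIES = ("approved", "enhanced", "supported", "uncertain")


@dataclass(frozen=True)
class WorldParams:
    """Generator knobs; the defaults are the package's reference study
    conditions (used by the test-suite's recovery checks).

    delta is the score effect size: a drug whose entire target set lies in a
    disease's module scores delta above background, against Gaussian noise
    of sd noise_sd.  Planted comorbid pairs share ``sharing_fraction`` of
    their modules and have their clinical co-occurrence probability boosted
    by ``planted_rr`` over independence.
    """

    n_drugs: int = 300
    n_proteins: int = 2000
    n_diseases: int = 40
    module_size: int = 25
    targets_from_module: int = 22
    background_targets: int = 3
    delta: float = 3.0
    noise_sd: float = 1.0
    n_planted_pairs: int = 8
    sharing_fraction: float = 0.5
    n_tissues: int = 10
    tissues_per_disease: int = 2
    clinical_n_tot: int = 1_000_000
    prevalence_low: float = 0.005
    prevalence_high: float = 0.05
    planted_rr: float = 5.0
    n_decoy_pathways: int = 40

    def validate(self) -> None:
        if self.module_size > self.n_proteins:
            raise ValidationError("module_size exceeds n_proteins")
        if self.n_diseases < 2:
            raise ValidationError("need at least 2 diseases")
        if 2 * self.n_planted_pairs > self.n_diseases:
            raise ValidationError("too many planted pairs for n_diseases")
        if not 0.0 <= self.sharing_fraction <= 1.0:
            raise ValidationError("sharing_fraction must lie in [0, 1]")
        if self.targets_from_module > self.module_size:
            raise ValidationError("targets_from_module exceeds module_size")


@dataclass
class WorldTruth:
    """Planted ground truth of a synthetic world."""

    modules: dict              # disease -> frozenset of module proteins
    planted_pairs: list        # [(disease_a, disease_b), ...] with a < b
    params: WorldParams
    seed: int

    def to_dict(self) -> dict:
        return {
            "modules": {d: sorted(m) for d, m in self.modules.items()},
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "params": dataclasses.asdict(self.params),
            "seed": self.seed,
        }


@dataclass
class WorldBundle:
    inputs: WorldInputs
    truth: WorldTruth


def _disease_id(i: int) -> str:
    return f"DIS{i:03d}"


def generate_world(
    params: WorldParams | None = None,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> WorldBundle:
    """Deterministic function of (params, seed): same arguments, same world."""
    params = params or WorldParams()
    params.validate()
    rng = np.random.default_rng(seed)

    proteins = [f"P{i:05d}" for i in range(params.n_proteins)]
    drugs = [f"DRG{i:04d}" for i in range(params.n_drugs)]
    diseases = [_disease_id(i) for i in range(params.n_diseases)]
    tissues = [f"TIS{i:02d}" for i in range(params.n_tissues)]
    prot_arr = np.asarray(proteins, dtype=object)

    # planted disease modules; designated pairs share an exact fraction
    planted_pairs = [
        (_disease_id(2 * i), _disease_id(2 * i + 1))
        for i in range(params.n_planted_pairs)
    ]
    n_shared = int(params.sharing_fraction * params.module_size)
    modules: dict[str, frozenset] = {}
    for i, disease in enumerate(diseases):
        pair_idx = i // 2
        if i % 2 == 1 and pair_idx < params.n_planted_pairs:
            partner = modules[_disease_id(i - 1)]
            shared = rng.choice(sorted(partner), size=n_shared, replace=False)
            pool = np.setdiff1d(prot_arr, np.asarray(sorted(partner), dtype=object))
            fresh = rng.choice(pool, size=params.module_size - n_shared, replace=False)
            modules[disease] = frozenset(shared) | frozenset(fresh)
        else:
            modules[disease] = frozenset(
                rng.choice(prot_arr, size=params.module_size, replace=False)
            )

    # drugs: focused on one disease, targets mostly inside its module.
    # The assignment is balanced (as in a designed probe library) so every
    # planted module is actually expressed in the drug collection.
    reps = -(-params.n_drugs // params.n_diseases)  # ceil
    primary = rng.permutation(
        np.tile(np.arange(params.n_diseases), reps)[: params.n_drugs]
    )
    target_sets: dict[str, frozenset] = {}
    for i, drug in enumerate(drugs):
        module = np.asarray(sorted(modules[diseases[primary[i]]]), dtype=object)
        from_module = rng.choice(module, size=params.targets_from_module, replace=False)
        background = rng.choice(prot_arr, size=params.background_targets, replace=False)
        target_sets[drug] = frozenset(from_module) | frozenset(background)
    targets = DrugTargetMap(target_sets)

    # raw scores: effect proportional to target-module overlap fraction
    raw = rng.normal(0.0, params.noise_sd, size=(params.n_drugs, params.n_diseases))
    for j, disease in enumerate(diseases):
        module = modules[disease]
        for i, drug in enumerate(drugs):
            ts = target_sets[drug]
            frac = len(ts & module) / len(ts)
            if frac:
                raw[i, j] += params.delta * frac
    scores = DrugIndicationScoreMatrix(
        pd.DataFrame(raw, index=drugs, columns=diseases)
    )

    # tissue expression: one record per (protein, tissue); "not detected" is
    # uncommon so the filter rarely bites (its logic is tested separately)
    level_p = (0.1, 0.3, 0.3, 0.3)
    rel_p = (0.4, 0.3, 0.2, 0.1)
    n_rec = params.n_proteins * params.n_tissues
    tissue_frame = pd.DataFrame(
        {
            "protein": np.repeat(prot_arr, params.n_tissues),
            "tissue": np.tile(np.asarray(tissues, dtype=object), params.n_proteins),
            "level": rng.choice(EXPRESSION_LEVELS, size=n_rec, p=level_p),
            "reliability": rng.choice(RELIABILITIES, size=n_rec, p=rel_p),
        }
    )
    tissue = TissueExpressionTable(tissue_frame)
    tissue_map = DiseaseTissueMap(
        {
            d: frozenset(rng.choice(tissues, size=params.tissues_per_disease, replace=False))
            for d in diseases
        }
    )

    # clinical counts: planted pairs boosted above independence
    n_tot = params.clinical_n_tot
    prevalence = rng.uniform(params.prevalence_low, params.prevalence_high, params.n_diseases)
    n_dis = np.maximum(1, (prevalence * n_tot).astype(np.int64))
    planted = set(planted_pairs)
    rows = []
    for a in range(params.n_diseases):
        for b in range(a + 1, params.n_diseases):
            da, db = diseases[a], diseases[b]
            rr = params.planted_rr if (da, db) in planted else 1.0
            p_ab = min(rr * (n_dis[a] / n_tot) * (n_dis[b] / n_tot),
                       min(n_dis[a], n_dis[b]) / n_tot)
            n_ab = int(min(rng.binomial(n_tot, p_ab), min(n_dis[a], n_dis[b])))
            rows.append((da, db, int(n_dis[a]), int(n_dis[b]), n_ab))
    clinical = pd.DataFrame(rows, columns=["disease_a", "disease_b", "n_a", "n_b", "n_ab"])

    # pathway collection: each planted module plus random decoys
    sets = {
        f"MOD_{d}": (f"planted module of {d}", modules[d]) for d in diseases
    }
    for i in range(params.n_decoy_pathways):
        sets[f"DECOY{i:03d}"] = (
            "random decoy set",
            frozenset(rng.choice(prot_arr, size=params.module_size, replace=False)),
        )
    gene_sets = GeneSetCollection(sets)

    config = (config or PipelineConfig()).with_overrides(
        clinical_n_tot=n_tot, rng_seed=seed
    )
    inputs = WorldInputs(
        universe=ProteinUniverse(proteins),
        scores=scores,
        targets=targets,
        tissue=tissue,
        tissue_map=tissue_map,
        clinical=clinical,
        gene_sets=gene_sets,
        config=config,
    )
    return WorldBundle(inputs, WorldTruth(modules, planted_pairs, params, seed))


# ---------------------------------------------------------------------------
# recovery evaluation against the planted truth
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    """How well pipeline outputs recover the planted truth."""

    moa_recall: float          # percent, mean over diseases
    moa_precision: float       # percent, mean over diseases with a non-empty MOA set
    comorbidity_auroc: float   # J-score separating planted from unplanted pairs
    pathway_ranks: dict = field(default_factory=dict)  # disease -> rank of own module

    def to_dict(self) -> dict:
        return {
            "moa_recall": self.moa_recall,
            "moa_precision": self.moa_precision,
            "comorbidity_auroc": self.comorbidity_auroc,
            "pathway_ranks": dict(self.pathway_ranks),
        }


def truth_eval(
    profiles: dict,
    edges: pd.DataFrame,
    truth: WorldTruth,
    gene_sets: GeneSetCollection | None = None,
    universe: ProteinUniverse | None = None,
) -> RecoveryReport:
    """Score recovered MOA sets and comorbidity ranking against the truth."""
    missing = set(truth.modules) - set(profiles)
    if missing:
        raise ValidationError(f"profiles missing for {sorted(missing)[:5]}")

    recalls, precisions = [], []
    for disease, module in truth.modules.items():
        moa = profiles[disease].moa_set
        hit = len(moa & module)
        recalls.append(100.0 * hit / len(module))
        if moa:
            precisions.append(100.0 * hit / len(moa))
    moa_recall = float(np.mean(recalls))
    moa_precision = float(np.mean(precisions)) if precisions else float("nan")

    planted = {tuple(sorted(p)) for p in truth.planted_pairs}
    labels = [
        (min(a, b), max(a, b)) in planted
        for a, b in zip(edges["disease_a"], edges["disease_b"])
    ]
    try:
        com_auroc = auroc(edges["j_score"].to_numpy(), labels)
    except Exception:
        com_auroc = float("nan")

    ranks: dict[str, int] = {}
    if gene_sets is not None and universe is not None:
        from .enrichment import pathway_ora

        for disease in truth.modules:
            moa = profiles[disease].moa_set
            if not moa:
                continue
            ora = pathway_ora(moa, gene_sets, universe)
            where = np.flatnonzero((ora["pathway"] == f"MOD_{disease}").to_numpy())
            if where.size:
                ranks[disease] = int(where[0]) + 1

    return RecoveryReport(moa_recall, moa_precision, com_auroc, ranks)


# ---------------------------------------------------------------------------
# bundle serialization (the `simulate` subcommand)
# ---------------------------------------------------------------------------

BUNDLE_FILES = {
    "universe": "universe.txt",
    "scores": "scores.tsv",
    "targets": "targets.tsv",
    "tissue": "tissue.tsv",
    "tissue_map": "tissue_map.tsv",
    "clinical": "clinical.tsv",
    "gmt": "pathways.gmt",
}


def write_bundle(bundle: WorldBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the world as the standard input files plus a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = bundle.inputs
    paths = {k: outdir / v for k, v in BUNDLE_FILES.items()}
    write_universe(inputs.universe, paths["universe"])
    write_score_matrix(inputs.scores, paths["scores"])
    write_target_map(inputs.targets, paths["targets"])
    write_tissue_table(inputs.tissue, paths["tissue"])
    write_tissue_map(inputs.tissue_map, paths["tissue_map"])
    write_clinical(inputs.clinical, paths["clinical"])
    write_gmt(inputs.gene_sets, paths["gmt"])
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(bundle.truth.to_dict(), indent=1, sort_keys=True))
    paths["truth"] = truth_path
    return paths
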