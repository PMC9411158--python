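"""Domain types and file I/O for the comorbidity pipeline.

All identifiers (drugs, proteins, diseases, tissues, pathways) are opaque
strings; ontology mapping is an input concern.  Tables are tab-separated
UTF-8 with a header row; a missing numeric cell is an error, never silently
imputed.  Gene-set collections use the standard GMT layout
(name TAB description TAB gene...).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import LoadError, ParseError, ValidationError

EXPRESSION_LEVELS = ("not detected", "low", "medium", "high")

EDGE_COLUMNS = ("disease_a", "disease_b", "n_shared", "j_score", "p_value", "q_value")

FLOAT_FORMAT = "%.17g"  # round-trips IEEE doubles exactly


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds of the whole pipeline.

    Defaults are the operating point of the published method: drugs are
    called efficacious at Z >= 1.65 (one-sided p ~ 0.05), proteins enter a
    disease's MOA set at Fisher p < 0.05, disease pairs are significant at
    q < 0.05, the CoMOAenrich weight coefficient alpha is 0.025 with an
    enrichment-score threshold of 0.01 over the top 100 comorbidities, easy
    pairs are excluded above 0.9 drug-set overlap, and permutation nulls use
    100 runs.
    """

    z_cutoff: float = 1.65
    moa_p_cutoff: float = 0.05
    pair_q_cutoff: float = 0.05
    alpha: float = 0.025
    top_k_comorbid: int = 100
    enrich_score_cutoff: float = 0.01
    easy_pair_cutoff: float = 0.9
    n_permutations: int = 100
    rng_seed: int = 0
    clinical_n_tot: int | None = None

    def __post_init__(self) -> None:
        for name in ("moa_p_cutoff", "pair_q_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name}={v} must lie in (0, 1)")
        for name in ("alpha", "enrich_score_cutoff", "easy_pair_cutoff"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("top_k_comorbid", "n_permutations"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if self.clinical_n_tot is not None and self.clinical_n_tot < 1:
            raise ValidationError("clinical_n_tot must be a positive integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.is_file():
            raise LoadError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        if not isinstance(data, dict):
            raise ParseError(f"config file {path} must contain a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParseError(f"unknown config keys in {path}: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class ProteinUniverse:
    """Ordered set of the protein identifiers the analysis may mention.

    Its size ``n_t`` is the background for every hypergeometric overlap test
    (the published analysis screened 32,584 human proteins including
    isoforms; whether the universe counts genes or isoforms is decided by
    the file the user supplies).
    """

    __slots__ = ("proteins", "_lookup")

    def __init__(self, proteins: Iterable[str]):
        proteins = tuple(proteins)
        seen = set(proteins)
        if len(seen) != len(proteins):
            raise ValidationError("protein universe contains duplicate identifiers")
        if not proteins:
            raise ValidationError("protein universe is empty")
        self.proteins = proteins
        self._lookup = frozenset(seen)

    @property
    def n_t(self) -> int:
        return len(self.proteins)

    def __len__(self) -> int:
        return len(self.proteins)

    def __contains__(self, protein: str) -> bool:
        return protein in self._lookup

    def __iter__(self):
        return iter(self.proteins)

    def intersect(self, proteins: Iterable[str]) -> frozenset:
        return self._lookup.intersection(proteins)


class DrugIndicationScoreMatrix:
    """Raw drug-by-indication score matrix (rows drugs, columns indications)."""

    __slots__ = ("frame",)

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            raise ValidationError("duplicate drug identifiers in score matrix")
        if frame.columns.has_duplicates:
            raise ValidationError("duplicate indication identifiers in score matrix")
        if frame.isna().any().any():
            raise ValidationError("score matrix contains missing cells")
        self.frame = frame.astype(float)

    @property
    def drugs(self) -> list[str]:
        return list(self.frame.index)

    @property
    def indications(self) -> list[str]:
        return list(self.frame.columns)

    def column(self, indication: str) -> np.ndarray:
        return self.frame[indication].to_numpy()


@dataclass(frozen=True)
class DrugTargetMap:
    """Map drug identifier -> set of predicted protein targets (may be empty)."""

    targets: Mapping[str, frozenset]

    def validate(self, universe: ProteinUniverse, drugs: Iterable[str]) -> None:
        drug_set = set(drugs)
        offenders = sorted(
            p for ts in self.targets.values() for p in ts if p not in universe
        )
        if offenders:
            raise ValidationError(
                f"{len(offenders)} target protein(s) absent from the universe: "
                f"{offenders[:10]}{'...' if len(offenders) > 10 else ''}"
            )
        unknown_drugs = sorted(set(self.targets) - drug_set)
        if unknown_drugs:
            raise ValidationError(
                f"target map names drugs absent from the score matrix: {unknown_drugs[:10]}"
            )

    def targets_of(self, drug: str) -> frozenset:
        return self.targets.get(drug, frozenset())


@dataclass(frozen=True)
class TissueExpressionTable:
    """Immunohistochemistry-style expression calls: (protein, tissue, level,
    reliability).  (protein, tissue) pairs may repeat (several cell types per
    tissue); filter logic must tolerate that."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(self.records["level"]) - set(EXPRESSION_LEVELS)
        if bad:
            raise ValidationError(f"unknown expression level(s): {sorted(bad)}")


@dataclass(frozen=True)
class DiseaseTissueMap:
    """Map disease identifier -> set of related tissue names (may be empty)."""

    tissues: Mapping[str, frozenset]

    def tissues_of(self, disease: str) -> frozenset:
        return self.tissues.get(disease, frozenset())


@dataclass(frozen=True)
class ClinicalComorbidityRecord:
    """Co-occurrence counts for one disease pair from a claims cohort."""

    disease_a: str
    disease_b: str
    n_a: int
    n_b: int
    n_ab: int

    def __post_init__(self) -> None:
        if min(self.n_a, self.n_b, self.n_ab) < 0:
            raise ValidationError("clinical counts must be non-negative")
        if self.n_ab > min(self.n_a, self.n_b):
            raise ValidationError(
                f"n_ab={self.n_ab} exceeds min(n_a={self.n_a}, n_b={self.n_b}) "
                f"for pair ({self.disease_a}, {self.disease_b})"
            )


class GeneSetCollection:
    """Pathway gene sets keyed by pathway identifier."""

    __slots__ = ("sets",)

    def __init__(self, sets: Mapping[str, tuple[str, frozenset]]):
        for name, (_desc, genes) in sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
        self.sets = dict(sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()

    def genes_of(self, name: str) -> frozenset:
        return self.sets[name][1]


@dataclass
class WorldInputs:
    """Validated bundle of everything the pipeline can consume."""

    universe: ProteinUniverse
    scores: DrugIndicationScoreMatrix
    targets: DrugTargetMap
    tissue: TissueExpressionTable | None = None
    tissue_map: DiseaseTissueMap | None = None
    clinical: pd.DataFrame | None = None
    gene_sets: GeneSetCollection | None = None
    config: PipelineConfig = field(default_factory=PipelineConfig)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _require(path: str | Path) -> Path:
    path = Path(path)
    if not path.is_file():
        raise LoadError(f"input file not found: {path}")
    return path


def _read_tsv(path: Path, columns: tuple[str, ...]) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ParseError(f"{path} is missing required column(s): {missing}")
    return frame


def _to_numeric(frame: pd.DataFrame, cols: Iterable[str], path: Path, kind=float):
    for col in cols:
        converted = pd.to_numeric(frame[col], errors="coerce")
        if converted.isna().any():
            row = int(converted.isna().idxmax()) + 2  # +1 header, +1 one-based
            raise ParseError(
                f"{path}: malformed numeric cell in column {col!r} at line {row}"
            )
        # numpy's string parser is correctly rounded (bit-exact round trips);
        # pandas' fast to_numeric path is not
        if kind is float:
            frame[col] = frame[col].to_numpy(dtype=object).astype(float)
        else:
            frame[col] = converted.astype(kind)
    return frame


def read_universe(path: str | Path) -> ProteinUniverse:
    """One protein identifier per line; blank lines ignored."""
    path = _require(path)
    ids = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not ids:
        raise ParseError(f"{path}: no protein identifiers found")
    return ProteinUniverse(ids)


def read_score_matrix(path: str | Path) -> DrugIndicationScoreMatrix:
    """TSV: first column drug identifiers, header row indication identifiers."""
    path = _require(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        if converted.isna().any():
            row = int(np.argmax(converted.isna().to_numpy())) + 2
            raise ParseError(
                f"{path}: malformed numeric cell in column {col!r} at line {row}"
            )
        # exact (correctly rounded) parse; see _to_numeric
        frame[col] = frame[col].to_numpy(dtype=object).astype(float)
    return DrugIndicationScoreMatrix(frame)


def read_target_map(path: str | Path) -> DrugTargetMap:
    """TSV with columns drug, protein; one pair per row."""
    path = _require(path)
    frame = _read_tsv(path, ("drug", "protein"))
    targets: dict[str, set] = {}
    for drug, protein in zip(frame["drug"], frame["protein"]):
        targets.setdefault(drug, set()).add(protein)
    return DrugTargetMap({d: frozenset(ts) for d, ts in targets.items()})


def read_tissue_table(path: str | Path) -> TissueExpressionTable:
    path = _require(path)
    frame = _read_tsv(path, ("protein", "tissue", "level", "reliability"))
    return TissueExpressionTable(frame[["protein", "tissue", "level", "reliability"]])


def read_tissue_map(path: str | Path) -> DiseaseTissueMap:
    path = _require(path)
    frame = _read_tsv(path, ("disease", "tissue"))
    tissues: dict[str, set] = {}
    for disease, tissue in zip(frame["disease"], frame["tissue"]):
        tissues.setdefault(disease, set()).add(tissue)
    return DiseaseTissueMap({d: frozenset(ts) for d, ts in tissues.items()})


def read_clinical(path: str | Path, n_tot: int | None = None) -> pd.DataFrame:
    """Clinical co-occurrence counts; one pair per row.

    Columns: disease_a, disease_b, n_a, n_b, n_ab.  The cohort size n_tot is
    a single number shared by every row and therefore lives in the config,
    not the file; when given here it is used to validate the margins.
    """
    path = _require(path)
    frame = _read_tsv(path, ("disease_a", "disease_b", "n_a", "n_b", "n_ab"))
    frame = _to_numeric(frame, ("n_a", "n_b", "n_ab"), path, kind=np.int64)
    for i, rec in enumerate(frame.itertuples(index=False)):
        if rec.n_ab > min(rec.n_a, rec.n_b):
            raise ValidationError(
                f"{path} line {i + 2}: n_ab exceeds min(n_a, n_b)"
            )
        if n_tot is not None and max(rec.n_a, rec.n_b) > n_tot:
            raise ValidationError(f"{path} line {i + 2}: margin exceeds n_tot={n_tot}")
    return frame[["disease_a", "disease_b", "n_a", "n_b", "n_ab"]]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Standard GMT: name TAB description TAB gene [TAB gene ...]."""
    path = _require(path)
    sets: dict[str, tuple[str, frozenset]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"{path} line {lineno}: GMT record needs name, description and "
                f"at least one gene ({len(fields)} field(s) found)"
            )
        name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        if not genes:
            raise ParseError(f"{path} line {lineno}: gene set {name!r} has no genes")
        if name in sets:
            raise ParseError(f"{path} line {lineno}: duplicate gene set {name!r}")
        sets[name] = (desc, frozenset(genes))
    if not sets:
        raise ParseError(f"{path}: no gene sets found")
    return GeneSetCollection(sets)


@dataclass(frozen=True)
class GeneListResult:
    genes: frozenset
    n_unknown: int


def load_gene_list(path: str | Path, universe: ProteinUniverse | None = None) -> GeneListResult:
    """One identifier per line, blank lines ignored, duplicates collapsed.

    When a universe is supplied, identifiers absent from it are dropped and
    counted (reported, never fatal); an empty usable set is an error.
    """
    path = _require(path)
    ids = {ln.strip() for ln in path.read_text().splitlines() if ln.strip()}
    if not ids:
        raise LoadError(f"{path}: no usable identifiers")
    n_unknown = 0
    if universe is not None:
        known = universe.intersect(ids)
        n_unknown = len(ids) - len(known)
        ids = known
        if not ids:
            raise LoadError(f"{path}: no identifiers overlap the protein universe")
    return GeneListResult(frozenset(ids), n_unknown)


def load_world(paths: Mapping[str, str | Path], config: PipelineConfig) -> WorldInputs:
    """Load and cross-validate a full input bundle.

    Required keys: ``universe``, ``scores``, ``targets``.  Optional:
    ``tissue``, ``tissue_map``, ``clinical``, ``gmt``.  Clinical diseases may
    be a subset of the score-matrix indications; target proteins must be a
    subset of the universe.
    """
    for key in ("universe", "scores", "targets"):
        if key not in paths:
            raise LoadError(f"required input {key!r} not supplied")
    universe = read_universe(paths["universe"])
    scores = read_score_matrix(paths["scores"])
    targets = read_target_map(paths["targets"])
    targets.validate(universe, scores.drugs)

    tissue = read_tissue_table(paths["tissue"]) if paths.get("tissue") else None
    tissue_map = read_tissue_map(paths["tissue_map"]) if paths.get("tissue_map") else None
    clinical = (
        read_clinical(paths["clinical"], n_tot=config.clinical_n_tot)
        if paths.get("clinical")
        else None
    )
    gene_sets = read_gmt(paths["gmt"]) if paths.get("gmt") else None
    return WorldInputs(
        universe=universe,
        scores=scores,
        targets=targets,
        tissue=tissue,
        tissue_map=tissue_map,
        clinical=clinical,
        gene_sets=gene_sets,
        config=config,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _write_frame(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    try:
        frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
    except OSError as exc:
        raise LoadError(f"cannot write {path}: {exc}") from exc


def rank_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Canonical edge ordering: q ascending, J descending, pair ascending."""
    return edges.sort_values(
        ["q_value", "j_score", "disease_a", "disease_b"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)


def write_edge_table(edges: pd.DataFrame, path: str | Path) -> None:
    """Write comorbidity edges as TSV in canonical order, full precision."""
    out = rank_edges(edges)[list(EDGE_COLUMNS)]
    _write_frame(out, path)


def read_edge_table(path: str | Path) -> pd.DataFrame:
    path = _require(path)
    frame = _read_tsv(path, EDGE_COLUMNS)
    frame = _to_numeric(frame, ("n_shared",), path, kind=np.int64)
    frame = _to_numeric(frame, ("j_score", "p_value", "q_value"), path)
    return frame[list(EDGE_COLUMNS)]


def write_score_matrix(scores: DrugIndicationScoreMatrix, path: str | Path) -> None:
    frame = scores.frame.copy()
    frame.index.name = "drug"
    _write_frame(frame, path, index=True)


def write_target_map(targets: DrugTargetMap, path: str | Path) -> None:
    rows = [
        {"drug": d, "protein": p}
        for d in sorted(targets.targets)
        for p in sorted(targets.targets[d])
    ]
    _write_frame(pd.DataFrame(rows, columns=["drug", "protein"]), path)


def write_universe(universe: ProteinUniverse, path: str | Path) -> None:
    Path(path).write_text("\n".join(universe.proteins) + "\n")


def write_tissue_table(tissue: TissueExpressionTable, path: str | Path) -> None:
    _write_frame(tissue.records, path)


def write_tissue_map(tissue_map: DiseaseTissueMap, path: str | Path) -> None:
    rows = [
        {"disease": d, "tissue": t}
        for d in sorted(tissue_map.tissues)
        for t in sorted(tissue_map.tissues[d])
    ]
    _write_frame(pd.DataFrame(rows, columns=["disease", "tissue"]), path)


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    _write_frame(clinical, path)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, desc, *sorted(genes)])
        for name, (desc, genes) in sorted(collection.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")
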