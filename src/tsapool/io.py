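"""Tabular input/output, domain containers and pipeline configuration.

All pipeline stages exchange a small set of validated containers:

* :class:`CountMatrix` — gene x sample read counts (raw or normalized);
* :class:`CohortMetadata` — sample class (tumor/normal) and normal-tissue labels;
* :class:`GeneAnnotation` — gene type and subcellular localization per gene;
* :class:`TissueWeightTable` — clinical-relevance weights w(t) in [0, 1] for
  non-essential tissues plus the set of "essential" tissues (brain, heart, lung)
  that are hard-filtered rather than weighted;
* :class:`PipelineConfig` — the numeric thresholds of the screen.

Files are UTF-8, tab-delimited with '.' decimal separator; weight tables and
configs are YAML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("tsapool")

__all__ = [
    "ParseError",
    "CountMatrix",
    "CohortMetadata",
    "GeneAnnotation",
    "TissueWeightTable",
    "PipelineConfig",
    "LOCALIZATION_CLASSES",
    "ESSENTIAL_TISSUES",
    "DEFAULT_TISSUE_WEIGHTS",
    "canonical_tissue",
    "default_weights",
    "read_count_matrix",
    "write_count_matrix",
    "read_metadata",
    "write_metadata",
    "read_annotation",
    "write_annotation",
    "read_weights",
    "write_weights",
    "read_config",
    "write_config",
    "write_target_report",
    "read_target_report",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Tissue vocabulary
# ---------------------------------------------------------------------------

#: Tissues where any appreciable expression disqualifies a candidate outright.
ESSENTIAL_TISSUES = frozenset({"brain", "heart", "lung"})

_TISSUE_ALIASES = {
    "leukocytes": "leukocyte",
    "lymph nodes": "lymph node",
    "lymphnode": "lymph node",
    "thyroid": "thyroid gland",
    "gallbladder": "gall bladder",
}


def canonical_tissue(name: str) -> str:
    """Normalize a tissue label: lowercase, collapsed whitespace, known aliases."""
    key = " ".join(str(name).strip().lower().split())
    return _TISSUE_ALIASES.get(key, key)


#: Default clinical-relevance weights for the adverse-event index, grouped by
#: severity of damage to the tissue (1.0 immediately life threatening ...
#: 0.0 no effect).  27 weighted non-essential tissues.
DEFAULT_TISSUE_WEIGHTS: dict[str, float] = {
    # immediately life threatening
    "bone marrow": 1.0,
    "kidney": 1.0,
    "liver": 1.0,
    "leukocyte": 1.0,
    # life threatening
    "colon": 0.8,
    "duodenum": 0.8,
    "esophagus": 0.8,
    "stomach": 0.8,
    "adipose tissue": 0.8,
    "small intestine": 0.8,
    "pancreas": 0.8,
    # not immediately life threatening
    "adrenal gland": 0.5,
    "bladder": 0.5,
    "skin": 0.5,
    "thyroid gland": 0.5,
    "salivary gland": 0.5,
    "skeletal muscle": 0.5,
    "lymph node": 0.5,
    # not life threatening
    "appendix": 0.3,
    "gall bladder": 0.3,
    "endometrium": 0.3,
    "breast": 0.3,
    "ovary": 0.3,
    "spleen": 0.3,
    "placenta": 0.3,
    # no effect
    "testis": 0.0,
    "prostate": 0.0,
}

LOCALIZATION_CLASSES = (
    "transmembrane_extracellular",
    "membrane_other",
    "intracellular",
    "secreted",
    "unknown",
)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene x sample expression matrix.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns.
    ``normalized`` distinguishes raw integer counts from size-factor scaled
    counts; raw matrices must be integral.
    """

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate gene ids: {dupes[:5]}")
        if v.columns.has_duplicates:
            dupes = v.columns[v.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample ids: {dupes[:5]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ParseError("count matrix body must be numeric")
        if np.isnan(arr).any():
            raise ParseError("count matrix contains missing values")
        if (arr < 0).any():
            gi, sj = np.argwhere(arr < 0)[0]
            raise ParseError(
                f"negative count at gene {v.index[gi]!r}, sample {v.columns[sj]!r}"
            )
        if not self.normalized and not np.allclose(arr, np.round(arr)):
            gi, sj = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ParseError(
                f"raw counts must be integers; non-integer value at gene "
                f"{v.index[gi]!r}, sample {v.columns[sj]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.values.loc[:, list(sample_ids)], self.normalized)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.normalized == other.normalized and self.values.equals(other.values)


@dataclass
class CohortMetadata:
    """Sample -> class/tissue assignment for a mixed tumor + normal cohort."""

    table: pd.DataFrame  # columns: sample_id, class, tissue

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample_id", "class", "tissue"}
        missing = required - set(t.columns)
        if missing:
            raise ParseError(f"metadata missing columns: {sorted(missing)}")
        if t["sample_id"].duplicated().any():
            dupes = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise ParseError(f"duplicate sample ids in metadata: {dupes[:5]}")
        bad = set(t["class"]) - {"tumor", "normal"}
        if bad:
            raise ParseError(f"unknown sample class values: {sorted(bad)}")
        if (t["class"] == "tumor").sum() == 0:
            raise ParseError("cohort contains no tumor sample")
        normals = t[t["class"] == "normal"]
        blank = normals["tissue"].isna() | (normals["tissue"].astype(str).str.strip() == "")
        if blank.any():
            bad_ids = normals.loc[blank, "sample_id"].tolist()
            raise ParseError(f"normal samples without tissue label: {bad_ids[:5]}")
        t = t.copy()
        t.loc[t["class"] == "normal", "tissue"] = normals["tissue"].map(canonical_tissue)
        t.loc[t["class"] == "tumor", "tissue"] = ""
        self.table = t.reset_index(drop=True)

    @property
    def tumor_samples(self) -> list[str]:
        t = self.table
        return t.loc[t["class"] == "tumor", "sample_id"].tolist()

    @property
    def normal_samples(self) -> list[str]:
        t = self.table
        return t.loc[t["class"] == "normal", "sample_id"].tolist()

    @property
    def n_tumor(self) -> int:
        return len(self.tumor_samples)

    @property
    def tissues(self) -> list[str]:
        t = self.table
        return sorted(t.loc[t["class"] == "normal", "tissue"].unique())

    def samples_of_tissue(self, tissue: str) -> list[str]:
        t = self.table
        mask = (t["class"] == "normal") & (t["tissue"] == canonical_tissue(tissue))
        return t.loc[mask, "sample_id"].tolist()

    def check_matches(self, counts: CountMatrix) -> None:
        meta_ids = set(self.table["sample_id"])
        mat_ids = set(counts.sample_ids)
        if meta_ids != mat_ids:
            only_meta = sorted(meta_ids - mat_ids)[:5]
            only_mat = sorted(mat_ids - meta_ids)[:5]
            raise ParseError(
                f"metadata and count matrix sample sets differ "
                f"(only in metadata: {only_meta}; only in matrix: {only_mat})"
            )


@dataclass
class GeneAnnotation:
    """Per-gene symbol, biotype and subcellular localization class."""

    table: pd.DataFrame  # columns: gene_id, symbol, gene_type, localization

    def __post_init__(self) -> None:
        t = self.table
        required = {"gene_id", "symbol", "gene_type", "localization"}
        missing = required - set(t.columns)
        if missing:
            raise ParseError(f"annotation missing columns: {sorted(missing)}")
        if t["gene_id"].duplicated().any():
            dupes = t.loc[t["gene_id"].duplicated(), "gene_id"].tolist()
            raise ParseError(f"duplicate gene ids in annotation: {dupes[:5]}")
        if (t["gene_type"].astype(str).str.strip() == "").any():
            raise ParseError("empty gene_type in annotation")
        bad = set(t["localization"]) - set(LOCALIZATION_CLASSES)
        if bad:
            raise ParseError(
                f"unknown localization values: {sorted(bad)}; "
                f"expected one of {LOCALIZATION_CLASSES}"
            )
        self.table = t.reset_index(drop=True)

    def get(self, gene_id: str) -> pd.Series | None:
        t = self.table
        hit = t[t["gene_id"] == gene_id]
        return None if hit.empty else hit.iloc[0]

    def as_dict(self) -> dict[str, dict]:
        return {
            row.gene_id: {
                "symbol": row.symbol,
                "gene_type": row.gene_type,
                "localization": row.localization,
            }
            for row in self.table.itertuples()
        }


@dataclass
class TissueWeightTable:
    """Weights w(t) in [0, 1] for non-essential tissues plus essential flags.

    Essential tissues carry no weight: they are screened by a hard expression
    cap, not folded into the adverse-event index.
    """

    weights: dict[str, float]
    essential: frozenset[str] = ESSENTIAL_TISSUES

    def __post_init__(self) -> None:
        canon: dict[str, float] = {}
        for tissue, w in self.weights.items():
            w = float(w)
            if not (0.0 <= w <= 1.0):
                raise ParseError(f"weight for {tissue!r} outside [0, 1]: {w}")
            canon[canonical_tissue(tissue)] = w
        self.weights = canon
        self.essential = frozenset(canonical_tissue(t) for t in self.essential)
        overlap = self.essential & set(self.weights)
        if overlap:
            raise ParseError(f"essential tissues must not carry weights: {sorted(overlap)}")

    def weight(self, tissue: str) -> float:
        return self.weights[canonical_tissue(tissue)]

    def is_essential(self, tissue: str) -> bool:
        return canonical_tissue(tissue) in self.essential

    def validate_against(
        self, tissues: Iterable[str], allow_unweighted: bool = False
    ) -> "TissueWeightTable":
        """Check coverage of the cohort's tissues.

        Tissues present in the data but missing from the table are an error
        unless ``allow_unweighted``, in which case they are assigned the
        maximally conservative weight 1.0.  Weight entries matching no cohort
        tissue are kept but logged (e.g. gall bladder when the cohort lacks
        one).
        """
        cohort = {canonical_tissue(t) for t in tissues}
        unweighted = sorted(cohort - set(self.weights) - self.essential)
        if unweighted:
            if not allow_unweighted:
                raise ParseError(
                    f"tissues without weight entries: {unweighted}; pass "
                    f"allow_unweighted (CLI --allow-unweighted) to treat them "
                    f"as weight 1.0"
                )
            logger.warning(
                "treating unweighted tissues as weight 1.0: %s", unweighted
            )
            new = dict(self.weights)
            new.update({t: 1.0 for t in unweighted})
            return TissueWeightTable(new, self.essential)
        unmatched = sorted(set(self.weights) - cohort)
        if unmatched:
            logger.warning("weight entries matching no cohort tissue: %s", unmatched)
        return self


def default_weights() -> TissueWeightTable:
    """Built-in tissue weight table (27 weighted tissues, 3 essential)."""
    return TissueWeightTable(dict(DEFAULT_TISSUE_WEIGHTS), ESSENTIAL_TISSUES)


@dataclass(frozen=True)
class PipelineConfig:
    """Numeric thresholds of the screen.

    t_none / t_high bound the none/low/high expression categories of normal
    tissue means; tumor_high_threshold is the per-sample count above which a
    tumor sample counts as covered; essential_max_avg caps the mean in
    essential tissues; max_ppae caps the number of predicted potential adverse
    events; the priority thresholds split the (1 - I_PPAE, I_TSCR) plane.
    """

    t_none: float = 10.0
    t_high: float = 50.0
    tumor_high_threshold: float = 50.0
    essential_max_avg: float = 10.0
    max_ppae: int = 6
    priority_ppae_threshold: float = 0.5
    priority_tscr_threshold: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.t_none < self.t_high):
            raise ValueError("require 0 <= t_none < t_high")
        if self.max_ppae < 0:
            raise ValueError("max_ppae must be >= 0")
        for name in ("priority_ppae_threshold", "priority_tscr_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_count_matrix(path: str | Path, normalized: bool = False) -> CountMatrix:
    """Read a tab-delimited count matrix (first column gene ids, header samples)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse count matrix: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            raise ParseError(
                f"{path}: non-numeric value in column {col!r}"
                + (f" at gene {bad[0]!r}" if len(bad) else "")
            )
    df = df.astype(float)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        return CountMatrix(df, normalized=normalized)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    df = matrix.values
    if not matrix.normalized:
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_metadata(path: str | Path) -> CohortMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    try:
        return CohortMetadata(df)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_metadata(meta: CohortMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    try:
        return GeneAnnotation(df)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_annotation(annot: GeneAnnotation, path: str | Path) -> None:
    annot.table.to_csv(path, sep="\t", index=False)


def read_weights(path: str | Path | None = None) -> TissueWeightTable:
    """Read a YAML weight table; with no path, return the built-in defaults."""
    if path is None:
        return default_weights()
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "weights" not in doc:
        raise ParseError(f"{path}: expected a mapping with a 'weights' key")
    essential = frozenset(doc.get("essential", sorted(ESSENTIAL_TISSUES)))
    try:
        return TissueWeightTable(dict(doc["weights"]), essential)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_weights(weights: TissueWeightTable, path: str | Path) -> None:
    doc = {
        "weights": {t: float(w) for t, w in sorted(weights.weights.items())},
        "essential": sorted(weights.essential),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_config(path: str | Path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    valid = {f.name for f in fields(PipelineConfig)}
    unknown = set(doc) - valid
    if unknown:
        raise ParseError(f"{path}: unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**doc)


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    doc = {f.name: getattr(cfg, f.name) for f in fields(cfg)}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# -- prioritized-target report ----------------------------------------------

_REPORT_COLUMNS = [
    "rank",
    "gene",
    "avg_expression",
    "tscr",
    "ppae",
    "dtpf",
    "priority",
    "target_type",
    "avg_expression_full",
    "i_tscr_full",
    "i_ppae_full",
    "dtpf_full",
    "covered_samples",
]


def write_target_report(targets: Sequence, path: str | Path) -> None:
    """Write ranked targets as TSV.

    Display columns follow the conventional rounding (average expression to
    the nearest integer, coverage ratio to 2 decimals, priority factor to 3);
    full-precision companions allow lossless round-trips.
    """
    rows = []
    for t in targets:
        rows.append(
            {
                "rank": t.rank,
                "gene": t.gene_id,
                "avg_expression": int(round(t.profile.avg_tumor_expression)),
                "tscr": f"{t.i_tscr:.2f}",
                "ppae": t.profile.ppae_count,
                "dtpf": f"{t.dtpf:.3f}",
                "priority": t.priority,
                "target_type": t.profile.target_type,
                "avg_expression_full": repr(float(t.profile.avg_tumor_expression)),
                "i_tscr_full": repr(float(t.i_tscr)),
                "i_ppae_full": repr(float(t.i_ppae)),
                "dtpf_full": repr(float(t.dtpf)),
                "covered_samples": int(t.profile.covered_count),
            }
        )
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_target_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: report missing columns: {sorted(missing)}")
    return df
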