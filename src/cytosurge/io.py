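"""Readers and writers for the pipeline's external formats.

Tables travel as :class:`pandas.DataFrame` wrapped in thin dataclasses that
carry the column contract:

* :class:`PanelTable` — serum multiplex panel, one row per sample, one column
  per cytokine (pg/mL), plus subject/visit metadata.
* event tables — one row per dated, categorised clinical diagnosis.
* :class:`ExpressionMatrix` — genes x samples abundance (TPM-like) with
  per-sample annotations.
* :class:`GeneSet` — named gene collections read from GMT.

Dates are ISO-8601 throughout; relative times are fractional years computed
as days / 365.25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("cytosurge")

DAYS_PER_YEAR = 365.25

METADATA_COLUMNS = ["sample_id", "subject_id", "visit_date", "age_at_sampling", "sex"]

EVENT_CATEGORIES = (
    "cancer_nmsc",
    "cancer_invasive",
    "cancer_other",
    "cardiovascular",
    "inflammatory",
    "other",
)

CANCER_CATEGORIES = ("cancer_nmsc", "cancer_invasive", "cancer_other")

_SEX_MAP = {
    "f": "F", "female": "F", "m": "M", "male": "M", "unknown": "unknown", "u": "unknown",
}


def years_between(later: pd.Series, earlier: pd.Series) -> pd.Series:
    """Signed difference ``later - earlier`` in fractional years."""
    return (pd.to_datetime(later) - pd.to_datetime(earlier)).dt.days / DAYS_PER_YEAR


# ---------------------------------------------------------------------------
# Panel


@dataclass
class PanelTable:
    """Samples x cytokines concentration table with sample metadata.

    ``data`` holds the metadata columns of :data:`METADATA_COLUMNS` followed by
    one nonnegative concentration column (pg/mL) per cytokine in ``cytokines``.
    Missing concentrations stay as NaN and are never zero-filled.
    """

    data: pd.DataFrame
    cytokines: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cytokines:
            self.cytokines = [c for c in self.data.columns if c not in METADATA_COLUMNS]
        self.validate()

    def validate(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"panel table missing metadata columns: {missing}")
        dup = self.data["sample_id"][self.data["sample_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample_id values: {sorted(dup.unique())}")
        if (self.data["age_at_sampling"] < 0).any():
            raise ValueError("age_at_sampling must be nonnegative")
        for cyt in self.cytokines:
            col = pd.to_numeric(self.data[cyt], errors="coerce")
            bad = self.data.index[col.notna() & (col < 0)]
            if len(bad):
                raise ValueError(
                    f"negative concentration for cytokine {cyt!r} at row(s) {list(bad[:5])}"
                )
        bad_sex = ~self.data["sex"].isin(["F", "M", "unknown"])
        if bad_sex.any():
            logger.warning("%d unknown sex codes mapped to 'unknown'", int(bad_sex.sum()))
            self.data.loc[bad_sex, "sex"] = "unknown"

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def concentrations(self) -> pd.DataFrame:
        """Cytokine columns only, indexed by sample_id."""
        return self.data.set_index("sample_id")[self.cytokines].astype(float)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def _parse_iso_dates(col: pd.Series, name: str) -> pd.Series:
    try:
        return pd.to_datetime(col, format="ISO8601")
    except ValueError as exc:
        raise ValueError(f"column {name!r} must contain ISO-8601 dates: {exc}") from exc


def _normalise_sex(col: pd.Series) -> pd.Series:
    out = col.astype(str).str.strip().str.lower().map(_SEX_MAP)
    n_bad = int(out.isna().sum())
    if n_bad:
        logger.warning("%d unknown sex codes mapped to 'unknown'", n_bad)
    return out.fillna("unknown")


def read_panel(path: str | Path, layout: str = "wide") -> PanelTable:
    """Read a cytokine panel from CSV/TSV.

    ``layout='wide'``: one row per sample, one column per cytokine.
    ``layout='long'``: columns (sample_id, cytokine, concentration) plus the
    metadata columns; pivoted to wide. Missing values are preserved as NaN.
    """
    df = _read_table(path)
    if layout == "long":
        needed = {"sample_id", "cytokine", "concentration"}
        if not needed.issubset(df.columns):
            raise ValueError(f"long layout requires columns {sorted(needed)}")
        meta = df[METADATA_COLUMNS].drop_duplicates("sample_id")
        wide = df.pivot(index="sample_id", columns="cytokine", values="concentration")
        wide.columns.name = None
        df = meta.merge(wide.reset_index(), on="sample_id", how="left")
    elif layout != "wide":
        raise ValueError(f"unknown layout {layout!r}")
    df = df.copy()
    df["visit_date"] = _parse_iso_dates(df["visit_date"], "visit_date")
    df["sex"] = _normalise_sex(df["sex"])
    df["age_at_sampling"] = pd.to_numeric(df["age_at_sampling"])
    cytokines = [c for c in df.columns if c not in METADATA_COLUMNS]
    df[cytokines] = df[cytokines].apply(pd.to_numeric)
    return PanelTable(df.reset_index(drop=True), cytokines)


def write_panel(panel: PanelTable, path: str | Path) -> None:
    df = panel.data.copy()
    df["visit_date"] = pd.to_datetime(df["visit_date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, sep="\t" if str(path).endswith(".tsv") else ",", index=False)


# ---------------------------------------------------------------------------
# Clinical events


def load_category_synonyms(path: str | Path | None = None) -> dict[str, str]:
    """Load the alias -> canonical-category map (editable text resource)."""
    if path is None:
        src = resources.files("cytosurge.data").joinpath("category_synonyms.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    mapping: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        alias, canon = line.split("\t")
        if canon not in EVENT_CATEGORIES:
            raise ValueError(f"synonym map target {canon!r} not a known category")
        mapping[alias.strip().lower()] = canon
    return mapping


def read_events(
    path: str | Path, synonyms: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a clinical event table (subject_id, category, diagnosis_date[, age_at_diagnosis]).

    Categories are normalised to the closed vocabulary through the synonym map;
    an unmappable category raises and names the offending values.
    """
    df = _read_table(path)
    return validate_events(df, synonyms)


def validate_events(df: pd.DataFrame, synonyms: dict[str, str] | None = None) -> pd.DataFrame:
    if synonyms is None:
        synonyms = load_category_synonyms()
    df = df.copy()
    needed = {"subject_id", "category", "diagnosis_date"}
    if not needed.issubset(df.columns):
        raise ValueError(f"event table requires columns {sorted(needed)}")
    if len(df):
        keys = df["category"].astype(str).str.strip().str.lower()
        mapped = keys.map(synonyms)
        bad = sorted(df.loc[mapped.isna(), "category"].unique())
        if bad:
            raise ValueError(f"unmappable event categories: {bad}")
        df["category"] = mapped
        df["diagnosis_date"] = _parse_iso_dates(df["diagnosis_date"], "diagnosis_date")
    else:
        df["diagnosis_date"] = pd.to_datetime(df["diagnosis_date"])
    if "age_at_diagnosis" in df.columns:
        df["age_at_diagnosis"] = pd.to_numeric(df["age_at_diagnosis"])
    return df.reset_index(drop=True)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    df = events.copy()
    if len(df):
        df["diagnosis_date"] = pd.to_datetime(df["diagnosis_date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, sep="\t" if str(path).endswith(".tsv") else ",", index=False)


# ---------------------------------------------------------------------------
# Expression matrices


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with per-sample annotations.

    ``values`` is indexed by gene ID (unique) with sample IDs as columns;
    ``annotations`` is indexed by sample ID and carries at least
    age, sex, cancer_type, stage. Every column of ``values`` is annotated.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("gene IDs must be unique")
        missing = [s for s in self.values.columns if s not in self.annotations.index]
        if missing:
            raise ValueError(f"samples lacking annotations: {missing[:5]}")
        self.annotations = self.annotations.loc[self.values.columns]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        ids = [s for s in self.values.columns if s in set(sample_ids)]
        return ExpressionMatrix(self.values[ids], self.annotations.loc[ids])


def read_expression(
    matrix_path: str | Path,
    annotations_path: str | Path,
    rows_path: str | Path | None = None,
    cols_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix (TSV genes-in-rows, or MTX triplet) + annotations.

    For MTX input, row/column name files default to ``<stem>.rows.txt`` and
    ``<stem>.cols.txt`` next to the matrix. Samples without an annotation row
    are dropped with a logged count; zero overlap is an error.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        from scipy.io import mmread

        mat = mmread(matrix_path)
        if hasattr(mat, "toarray"):
            mat = mat.toarray()
        mat = np.asarray(mat)
        rows_path = rows_path or matrix_path.with_suffix(".rows.txt")
        cols_path = cols_path or matrix_path.with_suffix(".cols.txt")
        genes = Path(rows_path).read_text().split()
        samples = Path(cols_path).read_text().split()
        values = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    annot = pd.read_csv(annotations_path, sep="\t" if str(annotations_path).endswith(".tsv") else ",")
    annot = annot.set_index(annot.columns[0]) if "sample_id" not in annot.columns else annot.set_index("sample_id")
    keep = [s for s in values.columns if s in annot.index]
    if not keep:
        raise ValueError("no overlapping sample IDs between matrix and annotations")
    dropped = values.shape[1] - len(keep)
    if dropped:
        logger.warning("dropped %d samples lacking annotations", dropped)
    return ExpressionMatrix(values[keep], annot.loc[keep])


def write_expression(expr: ExpressionMatrix, matrix_path: str | Path, annotations_path: str | Path) -> None:
    expr.values.to_csv(matrix_path, sep="\t")
    expr.annotations.rename_axis("sample_id").to_csv(annotations_path, sep="\t")


# ---------------------------------------------------------------------------
# Gene sets (GMT)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.genes)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from standard GMT (name, description, tab-separated members).

    Duplicate members within a set are deduplicated (order preserved); a line
    with fewer than three fields, or an effectively empty set, is rejected with
    its line number.
    """
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: expected >=3 tab-separated fields")
        name, desc, *members = fields
        genes = tuple(dict.fromkeys(m for m in members if m.strip()))
        if not genes:
            raise ValueError(f"GMT line {lineno}: set {name!r} has no members")
        sets.append(GeneSet(name, desc, genes))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    lines = ["\t".join([s.name, s.description, *s.genes]) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Pipeline-wide tunables; every threshold is validated into its range."""

    window_half_width_years: float = 2.0
    age_threshold_years: float = 80.0
    fdr_threshold: float = 0.05
    loess_span: float = 0.4
    bootstrap_reps: int = 200
    rng_seed: int = 0
    composite_variant: str = "geomean_then_standardize"

    def __post_init__(self) -> None:
        if self.window_half_width_years <= 0 or self.age_threshold_years <= 0:
            raise ValueError("window half-width and age threshold must be positive")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must lie in (0,1)")
        if not 0 < self.loess_span <= 1:
            raise ValueError("loess_span must lie in (0,1]")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be positive")
        if self.composite_variant not in {"geomean_then_standardize", "per_cytokine_z_mean"}:
            raise ValueError(f"unknown composite_variant {self.composite_variant!r}")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)
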