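"""Readers and writers for the tabular formats the pipeline touches.

Three input formats are supported:

* MAF-style mutation TSV (``Hugo_Symbol``, ``Variant_Classification``,
  ``Tumor_Sample_Barcode``, ...), optionally with cBioPortal ``#`` metadata
  header lines;
* cBioPortal-style clinical patient/sample TSV, joined into a single
  per-sample clinical table with normalized vocabularies;
* plain-text gene lists, one HGNC-style symbol per line.

All readers return plain :class:`pandas.DataFrame` objects with documented,
lower-case column names so downstream modules never touch raw headers.
Result tables are written as UTF-8 TSV with a header row; reals are written
with 12 significant digits so a write/read round trip is lossless at that
precision.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyPanelError, EmptyTableError, JoinError, SchemaError

# Controlled vocabulary: the MAF Variant_Classification values.
MAF_VARIANT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Splice_Region",
        "Translation_Start_Site",
        "Silent",
        "Intron",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "IGR",
        "RNA",
        "Targeted_Region",
        "De_novo_Start_InFrame",
        "De_novo_Start_OutOfFrame",
    }
)

#: Synonyms mapping free-text lesion descriptions onto the two strata.
LESION_SYNONYMS = {
    "primary": "primary",
    "primary tumor": "primary",
    "primary tumour": "primary",
    "localized": "primary",
    "metastasis": "metastasis",
    "metastatic": "metastasis",
    "metastatic tumor": "metastasis",
    "metastatic tumour": "metastasis",
    "metastatic recurrence": "metastasis",
    "met": "metastasis",
}

_GRADE_SYNONYMS = {
    "G1": "G1", "1": "G1", "I": "G1", "GRADE 1": "G1", "GRADE I": "G1",
    "G2": "G2", "2": "G2", "II": "G2", "GRADE 2": "G2", "GRADE II": "G2",
    "G3": "G3", "3": "G3", "III": "G3", "GRADE 3": "G3", "GRADE III": "G3",
}

# Accepted (lower-cased) header aliases for clinical fields.
_CLINICAL_ALIASES = {
    "patient_id": ("patient_id",),
    "sample_id": ("sample_id", "tumor_sample_barcode"),
    "lesion_type": ("lesion_type", "sample_type", "sample_class", "tumor_type"),
    "oncotree_or_diff": (
        "oncotree_code",
        "oncotree_or_diff",
        "differentiation",
        "histology",
        "cancer_type_detailed",
        "diagnosis",
    ),
    "grade": ("grade", "who_grade", "tumor_grade"),
    "os_months": ("os_months",),
    "os_status": ("os_status",),
    "sex": ("sex", "gender"),
    "race": ("race",),
    "country": ("country", "country_of_origin"),
    "study": ("study", "study_id", "cancer_study"),
}

MUTATION_COLUMNS = [
    "patient_id",
    "sample_id",
    "gene",
    "variant_classification",
    "protein_change",
    "unknown_classification",
]

CLINICAL_COLUMNS = [
    "patient_id",
    "sample_id",
    "lesion_type",
    "oncotree_or_diff",
    "grade",
    "os_months",
    "os_status",
    "sex",
    "race",
    "country",
    "study",
    "eligible_lesion",
]


@dataclass(frozen=True)
class GenePanel:
    """A named set of normalized gene symbols (e.g. a targeted panel)."""

    name: str
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.genes:
            raise EmptyPanelError(f"gene panel {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.genes


def normalize_symbol(symbol: str) -> str:
    """Uppercase + strip; no alias/HGNC remapping (hook: ``alias_table``)."""
    return str(symbol).strip().upper()


def _read_tsv(path, dialect: str) -> pd.DataFrame:
    comment = "#" if dialect == "cbioportal" else None
    try:
        return pd.read_csv(path, sep="\t", comment=comment, dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyTableError(f"{path}: no data rows") from None


def mutations_from_frame(df: pd.DataFrame, alias_table: dict | None = None) -> pd.DataFrame:
    """Normalize a raw MAF-style frame into the mutation-table schema.

    ``alias_table`` maps raw symbols to preferred symbols after the
    uppercase/strip normalization; it ships empty by design.
    """
    required = ["Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"mutation table is missing required column {col!r}")
    if len(df) == 0:
        raise EmptyTableError("mutation table has no variant rows")

    out = pd.DataFrame(
        {
            "patient_id": df["Patient_ID"].astype(str)
            if "Patient_ID" in df.columns
            else pd.Series([pd.NA] * len(df), dtype="string"),
            "sample_id": df["Tumor_Sample_Barcode"].astype(str).str.strip(),
            "gene": df["Hugo_Symbol"].map(normalize_symbol),
            "variant_classification": df["Variant_Classification"].astype(str).str.strip(),
            "protein_change": df["HGVSp_Short"].astype("string")
            if "HGVSp_Short" in df.columns
            else pd.Series([pd.NA] * len(df), dtype="string"),
        }
    )
    if alias_table:
        aliases = {normalize_symbol(k): normalize_symbol(v) for k, v in alias_table.items()}
        out["gene"] = out["gene"].map(lambda g: aliases.get(g, g))
    if (out["gene"] == "").any():
        raise SchemaError("mutation table contains empty gene symbols")
    # Unknown classes are retained but flagged, never silently dropped.
    out["unknown_classification"] = ~out["variant_classification"].isin(MAF_VARIANT_CLASSES)
    return out.reset_index(drop=True)


def read_mutations(path, dialect: str = "plain_tsv", alias_table: dict | None = None) -> pd.DataFrame:
    """Read a MAF-style mutation TSV.

    Parameters
    ----------
    path : path-like
        Tab-separated file with at least ``Hugo_Symbol``,
        ``Variant_Classification`` and ``Tumor_Sample_Barcode``.
    dialect : {"plain_tsv", "cbioportal"}
        Under ``cbioportal``, lines beginning ``#`` are metadata and skipped.
    """
    if dialect not in ("plain_tsv", "cbioportal"):
        raise ValueError(f"unknown dialect {dialect!r}")
    return mutations_from_frame(_read_tsv(path, dialect), alias_table=alias_table)


def _normalize_headers(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def _pick(df: pd.DataFrame, field_name: str) -> pd.Series | None:
    """Resolve a clinical field from its header aliases.

    Histology-ish aliases are concatenated (``|``-joined) rather than
    first-match so the carcinoma-exclusion substring check sees every
    provided field.
    """
    hits = [a for a in _CLINICAL_ALIASES[field_name] if a in df.columns]
    if not hits:
        return None
    if field_name == "oncotree_or_diff" and len(hits) > 1:
        joined = df[hits].apply(
            lambda row: "|".join(sorted({str(v) for v in row if pd.notna(v)})) or pd.NA,
            axis=1,
        )
        return joined.astype("string")
    return df[hits[0]]


def map_lesion_type(value) -> str | None:
    if pd.isna(value):
        return None
    return LESION_SYNONYMS.get(str(value).strip().lower())


def _map_grade(value) -> str:
    if pd.isna(value):
        return "unknown"
    return _GRADE_SYNONYMS.get(str(value).strip().upper(), "unknown")


def _map_os_status(value) -> str:
    if pd.isna(value):
        return "unknown"
    v = str(value).strip().upper()
    if "DECEASED" in v or v in ("DEAD", "1") or v.startswith("1:"):
        return "deceased"
    if "LIVING" in v or v in ("ALIVE", "0") or v.startswith("0:"):
        return "living"
    return "unknown"


def clinical_from_frames(patients: pd.DataFrame, samples: pd.DataFrame | None = None) -> pd.DataFrame:
    """Join patient and sample frames into one per-sample clinical table.

    Returns a frame with :data:`CLINICAL_COLUMNS`; ``eligible_lesion`` is
    False for samples whose lesion description cannot be resolved to
    primary/metastasis.
    """
    patients = _normalize_headers(patients)
    if "patient_id" not in patients.columns:
        raise SchemaError("patient table is missing required column 'PATIENT_ID'")
    if len(patients) == 0:
        raise EmptyTableError("patient table has no rows")
    patients = patients.copy()
    patients["patient_id"] = patients["patient_id"].astype(str).str.strip()

    if samples is None:
        # Single-table mode: each patient is its own sample.
        samples = patients.copy()
        if "sample_id" not in samples.columns:
            samples["sample_id"] = samples["patient_id"]
    else:
        samples = _normalize_headers(samples)
        for col in ("patient_id", "sample_id"):
            if col not in samples.columns:
                raise SchemaError(f"sample table is missing required column {col.upper()!r}")
        samples = samples.copy()
        samples["patient_id"] = samples["patient_id"].astype(str).str.strip()
        unknown = sorted(set(samples["patient_id"]) - set(patients["patient_id"]))
        if unknown:
            raise JoinError(
                f"{len(unknown)} sample(s) reference unknown patients: {', '.join(unknown[:10])}",
                offenders=unknown,
            )

    sample_level = {}
    for fld in ("sample_id", "lesion_type", "oncotree_or_diff", "grade"):
        col = _pick(samples, fld)
        if col is not None:
            sample_level[fld] = col
    sdf = pd.DataFrame(sample_level)
    sdf["patient_id"] = samples["patient_id"]

    patient_level = {"patient_id": patients["patient_id"]}
    for fld in ("os_months", "os_status", "sex", "race", "country", "study", "grade", "oncotree_or_diff", "lesion_type"):
        col = _pick(patients, fld)
        if col is not None:
            patient_level[fld] = col
    pdf = pd.DataFrame(patient_level)

    merged = sdf.merge(pdf, on="patient_id", how="left", suffixes=("", "_patient"))
    # Sample-level fields win; patient-level fills the gaps.
    for fld in ("lesion_type", "oncotree_or_diff", "grade"):
        pat = f"{fld}_patient"
        if pat in merged.columns:
            if fld in merged.columns:
                merged[fld] = merged[fld].fillna(merged[pat])
            else:
                merged[fld] = merged[pat]
            merged = merged.drop(columns=[pat])

    out = pd.DataFrame({"patient_id": merged["patient_id"].astype(str)})
    out["sample_id"] = merged["sample_id"].astype(str).str.strip()
    lesion_raw = merged["lesion_type"] if "lesion_type" in merged.columns else pd.Series([pd.NA] * len(merged))
    out["lesion_type"] = lesion_raw.map(map_lesion_type)
    out["oncotree_or_diff"] = (
        merged["oncotree_or_diff"].astype("string")
        if "oncotree_or_diff" in merged.columns
        else pd.Series([pd.NA] * len(merged), dtype="string")
    )
    out["grade"] = (
        merged["grade"].map(_map_grade) if "grade" in merged.columns else "unknown"
    )
    out["os_months"] = (
        pd.to_numeric(merged["os_months"], errors="coerce")
        if "os_months" in merged.columns
        else np.nan
    )
    if ((out["os_months"].dropna() < 0) if out["os_months"].notna().any() else pd.Series(dtype=bool)).any():
        raise SchemaError("negative OS_MONTHS encountered")
    out["os_status"] = (
        merged["os_status"].map(_map_os_status) if "os_status" in merged.columns else "unknown"
    )
    for fld in ("sex", "race", "country", "study"):
        out[fld] = merged[fld].astype("string") if fld in merged.columns else pd.NA
    out["eligible_lesion"] = out["lesion_type"].notna()
    return out[CLINICAL_COLUMNS].reset_index(drop=True)


def read_clinical(patient_path, sample_path=None, dialect: str = "cbioportal") -> pd.DataFrame:
    """Read cBioPortal-style clinical patient (and optional sample) TSVs."""
    patients = _read_tsv(patient_path, dialect)
    samples = _read_tsv(sample_path, dialect) if sample_path is not None else None
    return clinical_from_frames(patients, samples)


def read_gene_list(path, name: str | None = None) -> GenePanel:
    """Read a plain-text gene list: one symbol per line, ``#`` comments and
    blank lines ignored; symbols normalized and deduplicated."""
    symbols = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            symbols.append(normalize_symbol(line))
    if not symbols:
        raise EmptyPanelError(f"{path}: no gene symbols after filtering")
    return GenePanel(name=name or os.path.basename(str(path)), genes=frozenset(symbols))


def write_table(df: pd.DataFrame, path) -> None:
    """Write a result table as UTF-8 TSV with 12-significant-digit reals."""
    df.to_csv(path, sep="\t", index=False, float_format="%.12g", encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    """Re-read a result table written by :func:`write_table`."""
    try:
        return pd.read_csv(path, sep="\t", encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise EmptyTableError(f"{path}: no data rows") from None


def table_to_string(df: pd.DataFrame) -> str:
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format="%.12g")
    return buf.getvalue()
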