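"""Cohort harmonization: panel intersection, nonsynonymous filtering,
eligibility exclusions, representative-sample selection, and the binary
patient x gene cohort matrix.

Targeted-sequencing studies report different gene panels, so the aggregate
analysis is restricted to the intersection of the panels in play; a patient
contributes exactly one sample (the one with the highest nonsynonymous TMB
within the panel), and the result is a binary indicator matrix (1 = at
least one qualifying variant in that gene) with a primary/metastasis
stratum label per patient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyPanelError
from .io_tables import GenePanel

logger = logging.getLogger(__name__)

#: The conventional MAF protein-altering classes. "Nonsynonymous" is used in
#: the loose clinical-genomics sense: anything altering the protein product,
#: including truncations, frameshifts and splice disruption.
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)


@dataclass
class CohortMatrix:
    """Harmonized binary cohort: patients x genes with lesion-type strata.

    Attributes
    ----------
    indicator : pandas.DataFrame
        0/1 frame indexed by patient_id with one column per panel gene.
    stratum : pandas.Series
        Per-patient lesion type ("primary"/"metastasis"), same index.
    """

    indicator: pd.DataFrame
    stratum: pd.Series
    panel_name: str = "panel"

    def __post_init__(self):
        self.indicator = self.indicator.astype(np.int8)
        self.stratum = self.stratum.reindex(self.indicator.index)
        vals = self.indicator.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("cohort matrix entries must be 0/1")

    @property
    def patients(self) -> list[str]:
        return list(self.indicator.index)

    @property
    def genes(self) -> list[str]:
        return list(self.indicator.columns)

    def stratum_patients(self, stratum: str) -> pd.Index:
        return self.stratum.index[self.stratum == stratum]

    def mutated_genes(self, patient_id: str) -> frozenset[str]:
        row = self.indicator.loc[patient_id]
        return frozenset(row.index[row == 1])

    def to_frame(self) -> pd.DataFrame:
        out = self.indicator.copy()
        out.insert(0, "lesion_type", self.stratum)
        out.insert(0, "patient_id", out.index)
        return out.reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, panel_name: str = "panel") -> "CohortMatrix":
        df = df.set_index("patient_id")
        stratum = df.pop("lesion_type")
        return cls(indicator=df, stratum=stratum, panel_name=panel_name)


def intersect_panels(panels: list[GenePanel]) -> GenePanel:
    """Set intersection of >= 2 panels; the name records provenance."""
    if len(panels) < 2:
        raise ValueError("need at least two panels to intersect")
    genes = frozenset.intersection(*(p.genes for p in panels))
    name = " ∩ ".join(p.name for p in panels)
    if not genes:
        raise EmptyPanelError(f"panel intersection {name!r} is empty: no analyzable genes")
    return GenePanel(name=name, genes=genes)


def filter_nonsynonymous(muts: pd.DataFrame, classes: frozenset[str] = NONSYNONYMOUS_CLASSES) -> pd.DataFrame:
    """Keep protein-altering variant records only; log the removed count."""
    keep = muts["variant_classification"].isin(classes)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_nonsynonymous: removed %d synonymous/other records", n_removed)
    out = muts.loc[keep].reset_index(drop=True)
    out.attrs["n_removed"] = n_removed
    return out


def restrict_to_panel(muts: pd.DataFrame, panel: GenePanel) -> pd.DataFrame:
    """Keep variant records whose gene lies in the analysis panel."""
    out = muts.loc[muts["gene"].isin(panel.genes)].reset_index(drop=True)
    out.attrs["n_removed"] = len(muts) - len(out)
    return out


def apply_eligibility(clin: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove ineligible patients; return (eligible, exclusion log).

    A patient is excluded when any sample is grade G3 or any histology/
    differentiation field contains "carcinoma" (case-insensitive; "NEC" and
    frank carcinoma codes included via the substring), or when no sample's
    lesion type resolves to primary/metastasis. Patients with unknown grade
    or differentiation are retained: incomplete histopathology is the norm
    in aggregated cohorts and unknowns stay in the analysis.
    """
    clin = clin.copy()
    hist = clin["oncotree_or_diff"].fillna("").str.lower()
    is_carcinoma = hist.str.contains("carcinoma", regex=False)
    is_g3 = clin["grade"] == "G3"
    bad_lesion = ~clin["eligible_lesion"].astype(bool)

    reason = pd.Series("", index=clin.index, dtype=object)
    reason[bad_lesion] = "unresolvable lesion type"
    reason[is_carcinoma] = "carcinoma designation"
    reason[is_g3] = "grade G3"
    reason[is_g3 & is_carcinoma] = "grade G3; carcinoma designation"

    excluded_patients = set(clin.loc[reason != "", "patient_id"])
    excl_mask = clin["patient_id"].isin(excluded_patients)
    exclusions = clin.loc[excl_mask, ["patient_id", "sample_id"]].copy()
    exclusions["reason"] = reason[excl_mask].replace("", "co-sample of excluded patient")
    eligible = clin.loc[~excl_mask].reset_index(drop=True)
    if len(exclusions):
        logger.info("apply_eligibility: excluded %d patients", len(excluded_patients))
    return eligible, exclusions.reset_index(drop=True)


def sample_tmb(muts: pd.DataFrame) -> pd.Series:
    """Nonsynonymous TMB per sample = raw qualifying-variant count.

    Counted within whatever panel restriction has already been applied; the
    value is used only to rank a patient's samples, so no per-megabase
    normalization is performed.
    """
    return muts.groupby("sample_id").size()


def select_representative(
    muts: pd.DataFrame, clin: pd.DataFrame, assume_sequenced: bool = False
) -> pd.Series:
    """One sample per patient, maximizing nonsynonymous TMB.

    Expects ``muts`` already nonsynonymous- and panel-filtered. Ties break
    to the lexicographically smallest sample_id. Patients whose samples all
    lack mutation records are dropped with a warning, unless
    ``assume_sequenced`` declares every clinical sample sequenced (then a
    record-free patient is retained with TMB 0 — a sample can genuinely
    carry no nonsynonymous panel variant).
    """
    tmb = sample_tmb(muts)
    rows = []
    dropped = []
    for patient_id, grp in clin.groupby("patient_id", sort=True):
        counts = {s: int(tmb.get(s, 0)) for s in grp["sample_id"]}
        if not assume_sequenced and all(s not in tmb.index for s in counts):
            dropped.append(patient_id)
            continue
        best = min(counts, key=lambda s: (-counts[s], s))
        rows.append((patient_id, best, counts[best]))
    if dropped:
        logger.warning(
            "select_representative: dropped %d patients with no sequenced sample in the mutation table",
            len(dropped),
        )
    rep = pd.DataFrame(rows, columns=["patient_id", "sample_id", "tmb_nonsynonymous"])
    out = rep.set_index("patient_id")["sample_id"]
    out.attrs["tmb"] = rep.set_index("patient_id")["tmb_nonsynonymous"]
    out.attrs["dropped_patients"] = dropped
    return out


def build_cohort_matrix(
    muts: pd.DataFrame,
    clin: pd.DataFrame,
    panel: GenePanel,
    assume_sequenced: bool = False,
) -> CohortMatrix:
    """Binary indicator matrix over representative samples.

    ``indicator[p, g] = 1`` iff patient *p*'s representative sample carries
    >= 1 nonsynonymous variant in panel gene *g*; multiple variants in the
    same gene collapse to 1 and off-panel genes contribute nothing.
    Expects eligibility filtering already applied to ``clin``.
    """
    muts = filter_nonsynonymous(muts)
    muts = restrict_to_panel(muts, panel)
    rep = select_representative(muts, clin, assume_sequenced=assume_sequenced)

    sample_to_patient = pd.Series(rep.index.values, index=rep.values)
    keep = muts.loc[muts["sample_id"].isin(sample_to_patient.index)].copy()
    keep["patient_id"] = keep["sample_id"].map(sample_to_patient)

    genes = sorted(panel.genes)
    patients = sorted(rep.index)
    indicator = pd.DataFrame(0, index=pd.Index(patients, name="patient_id"), columns=genes, dtype=np.int8)
    if len(keep):
        hit = keep.groupby(["patient_id", "gene"]).size().index
        for p, g in hit:
            indicator.at[p, g] = 1

    lesion = (
        clin.drop_duplicates(subset="sample_id")
        .set_index("sample_id")["lesion_type"]
        .reindex(rep.values)
    )
    stratum = pd.Series(lesion.values, index=rep.index).reindex(patients)
    cm = CohortMatrix(indicator=indicator, stratum=stratum, panel_name=panel.name)
    cm.indicator.attrs["representative"] = rep
    return cm
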