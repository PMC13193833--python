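"""Rule-based molecular subgroup assignment.

Two schemes are shipped:

* ``ciobanu`` — the PanNEN classification of Ciobanu et al.: PanNEN2
  (MEN1 plus ATRX or DAXX), PanNEN1 (MEN1 alone), PanNEN4 (ATRX or DAXX
  alone), with PanNEN3/PanNEN5 pooled as the residual class (no defining
  somatic signature of their own).
* ``novel`` — a five-way scheme that first carves out tumors carrying
  TP53, KRAS or SMAD4 mutations (the PDAC/PNEC-like genotype) regardless
  of the rest of the profile, then applies the ATRX/DAXX/MEN1 ("ADM")
  logic: ADM-Mutant, ATRX/DAXX-Mutant, MEN1-Mutant, ADM-WT.

A scheme is an ordered list of rules (first match wins) plus a default
label, so every profile receives exactly one label and the firing rule is
recorded for audit. Schemes are declarative and can be overridden from a
YAML file, e.g. to extend a signature with additional genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

from .harmonize import CohortMatrix
from .penetrance import percent


@dataclass(frozen=True)
class Rule:
    """One subgroup rule: fires when the profile contains every gene in
    ``all_of`` and (if non-empty) at least one gene in ``any_of``."""

    label: str
    any_of: frozenset[str] = frozenset()
    all_of: frozenset[str] = frozenset()

    def matches(self, mutated: frozenset[str]) -> bool:
        if self.all_of and not self.all_of <= mutated:
            return False
        if self.any_of and not (self.any_of & mutated):
            return False
        return True

    def trace(self) -> str:
        parts = []
        if self.all_of:
            parts.append("all of {" + ",".join(sorted(self.all_of)) + "}")
        if self.any_of:
            parts.append("any of {" + ",".join(sorted(self.any_of)) + "}")
        return f"{self.label}: " + " and ".join(parts) if parts else f"{self.label}: default"


@dataclass(frozen=True)
class Scheme:
    name: str
    rules: tuple[Rule, ...]
    default_label: str

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.rules] + [self.default_label]


CIOBANU = Scheme(
    name="ciobanu",
    rules=(
        Rule("PanNEN2", all_of=frozenset({"MEN1"}), any_of=frozenset({"ATRX", "DAXX"})),
        Rule("PanNEN1", all_of=frozenset({"MEN1"})),
        Rule("PanNEN4", any_of=frozenset({"ATRX", "DAXX"})),
    ),
    default_label="PanNEN3/PanNEN5",
)

NOVEL = Scheme(
    name="novel",
    rules=(
        Rule("TP53/KRAS/SMAD4-Mutant", any_of=frozenset({"TP53", "KRAS", "SMAD4"})),
        Rule("ADM-Mutant", all_of=frozenset({"MEN1"}), any_of=frozenset({"ATRX", "DAXX"})),
        Rule("ATRX/DAXX-Mutant", any_of=frozenset({"ATRX", "DAXX"})),
        Rule("MEN1-Mutant", all_of=frozenset({"MEN1"})),
    ),
    default_label="ADM-WT",
)

SCHEMES = {"ciobanu": CIOBANU, "novel": NOVEL}


@dataclass(frozen=True)
class SubgroupAssignment:
    patient_id: str
    scheme: str
    label: str
    rule_fired: str


def classify(mutated_genes, scheme: Scheme) -> tuple[str, str]:
    """(label, rule trace) for one mutation profile; first match wins."""
    mutated = frozenset(mutated_genes)
    for rule in scheme.rules:
        if rule.matches(mutated):
            return rule.label, rule.trace()
    return scheme.default_label, f"{scheme.default_label}: default (no rule matched)"


def classify_ciobanu(patient_id: str, mutated_genes) -> SubgroupAssignment:
    label, trace = classify(mutated_genes, CIOBANU)
    return SubgroupAssignment(patient_id, "ciobanu", label, trace)


def classify_novel(patient_id: str, mutated_genes) -> SubgroupAssignment:
    label, trace = classify(mutated_genes, NOVEL)
    return SubgroupAssignment(patient_id, "novel", label, trace)


def classify_cohort(m: CohortMatrix, scheme: Scheme | str) -> pd.DataFrame:
    """Assign every patient of a cohort matrix; returns patient_id, label,
    rule_fired (one row per patient, exactly one label each)."""
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    rows = []
    mat = m.indicator
    cols = mat.columns.to_numpy()
    for patient_id, row in zip(mat.index, mat.to_numpy()):
        mutated = frozenset(cols[row == 1])
        label, trace = classify(mutated, scheme)
        rows.append({"patient_id": patient_id, "scheme": scheme.name, "label": label, "rule_fired": trace})
    return pd.DataFrame(rows)


def subgroup_distribution(assignments: pd.DataFrame, stratum: pd.Series, scheme: Scheme | str | None = None) -> pd.DataFrame:
    """Counts and percentages per label per lesion type.

    Percentages are of the lesion-type total and sum to 100 within
    rounding. All labels of the scheme appear even at count zero when the
    scheme is given.
    """
    df = assignments.merge(
        stratum.rename("lesion_type").rename_axis("patient_id").reset_index(),
        on="patient_id",
        how="left",
    )
    labels = None
    if scheme is not None:
        if isinstance(scheme, str):
            scheme = SCHEMES[scheme]
        labels = scheme.labels
    rows = []
    for lesion in sorted(df["lesion_type"].dropna().unique()):
        block = df.loc[df["lesion_type"] == lesion]
        total = len(block)
        counts = block["label"].value_counts()
        for label in labels if labels is not None else sorted(counts.index):
            n = int(counts.get(label, 0))
            rows.append(
                {
                    "label": label,
                    "lesion_type": lesion,
                    "n": n,
                    "n_total": total,
                    "pct": percent(n, total),
                }
            )
    return pd.DataFrame(rows)


def scheme_to_yaml(scheme: Scheme) -> str:
    doc = {
        "name": scheme.name,
        "default_label": scheme.default_label,
        "rules": [
            {"label": r.label, "any_of": sorted(r.any_of), "all_of": sorted(r.all_of)}
            for r in scheme.rules
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def scheme_from_yaml(text: str) -> Scheme:
    """Load a user-editable scheme (label, any_of, all_of, in precedence
    order) from YAML; lets users override the shipped signature tables."""
    doc = yaml.safe_load(text)
    rules = tuple(
        Rule(
            label=r["label"],
            any_of=frozenset(r.get("any_of") or ()),
            all_of=frozenset(r.get("all_of") or ()),
        )
        for r in doc["rules"]
    )
    return Scheme(name=doc["name"], rules=rules, default_label=doc["default_label"])
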