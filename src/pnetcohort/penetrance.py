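"""Per-gene mutational frequencies, the penetrance threshold, stratum
association tests (chi-squared / Fisher), and Benjamini-Hochberg FDR.

A gene is *penetrant* when it is mutated in at least 5% of tumors in some
analyzed stratum. Frequencies are exact proportions n_mutated / n_total;
human-readable output rounds to one decimal place of percent while machine
output keeps full precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .harmonize import CohortMatrix


def percent(n: int, total: int) -> float:
    """Share of ``n`` in ``total`` as a percentage rounded to 1 dp."""
    if total == 0:
        return float("nan")
    return round(100.0 * n / total, 1)


def _strata_map(m: CohortMatrix, stratify_by: str, groups: pd.Series | None) -> pd.Series:
    if stratify_by == "lesion_type":
        return m.stratum
    if stratify_by == "subgroup":
        if groups is None:
            raise ValueError("stratify_by='subgroup' requires a per-patient groups Series")
        return groups.reindex(m.indicator.index)
    if stratify_by == "none":
        return pd.Series("all", index=m.indicator.index)
    raise ValueError(f"unknown stratify_by {stratify_by!r}")


def gene_frequencies(
    m: CohortMatrix,
    stratify_by: str = "lesion_type",
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Long-format per-gene, per-stratum mutation frequencies.

    Returns columns ``gene, stratum, n_mutated, n_total, frequency,
    frequency_pct`` with ``frequency = n_mutated / n_total`` exactly. Empty
    strata yield ``n_total = 0`` rows flagged ``degenerate`` with NaN
    frequency rather than a division.
    """
    if m.indicator.shape[0] == 0:
        raise ValueError("cohort matrix is empty")
    strata = _strata_map(m, stratify_by, groups)
    rows = []
    for label in pd.unique(strata.dropna()):
        idx = strata.index[strata == label]
        block = m.indicator.loc[idx]
        n_total = len(idx)
        counts = block.sum(axis=0)
        for gene in m.genes:
            n_mut = int(counts[gene])
            freq = n_mut / n_total if n_total else np.nan
            rows.append(
                {
                    "gene": gene,
                    "stratum": label,
                    "n_mutated": n_mut,
                    "n_total": n_total,
                    "frequency": freq,
                    "frequency_pct": percent(n_mut, n_total),
                    "degenerate": n_total == 0,
                }
            )
    return pd.DataFrame(rows)


def penetrance_filter(
    freq: pd.DataFrame,
    min_freq: float = 0.05,
    threshold_scope: str = "any_stratum",
) -> list[str]:
    """Genes mutated in >= ``min_freq`` of tumors ("at least" is inclusive).

    ``any_stratum`` (default): the gene passes if it reaches the threshold
    in at least one stratum. ``pooled``: the threshold is applied to the
    frequency over all strata combined.
    """
    if threshold_scope == "any_stratum":
        ok = freq.loc[~freq["degenerate"]].groupby("gene")["frequency"].max() >= min_freq
    elif threshold_scope == "pooled":
        pooled = freq.groupby("gene").agg(n_mutated=("n_mutated", "sum"), n_total=("n_total", "sum"))
        ok = pooled["n_mutated"] / pooled["n_total"] >= min_freq
    else:
        raise ValueError(f"unknown threshold_scope {threshold_scope!r}")
    return sorted(ok.index[ok])


def fisher_exact_p(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (sum of hypergeometric
    probabilities <= the observed table's, the conventional definition)."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


@dataclass(frozen=True)
class StratumTest:
    gene: str
    table: tuple  # ((mut_a, wt_a), (mut_b, wt_b)) by stratum
    statistic: float
    p_value: float
    test_name: str  # "chi_squared" | "fisher_exact"
    degenerate: bool = False


def compare_strata(m: CohortMatrix, gene: str) -> StratumTest:
    """Test a gene's mutation frequency across the two lesion-type strata.

    Builds the mutated/WT x stratum 2x2 table; uses Fisher's exact test
    when any expected cell count is below 5, else Pearson's chi-squared
    without continuity correction (the selection rule is logged in the
    result so every choice is auditable). A table with a zero margin is
    degenerate: p = 1 with the flag set.
    """
    labels = [s for s in pd.unique(m.stratum.dropna())]
    if len(labels) != 2:
        raise ValueError("compare_strata requires exactly two non-empty strata")
    col = m.indicator[gene]
    table = []
    for label in sorted(labels):
        idx = m.stratum.index[m.stratum == label]
        n_mut = int(col.loc[idx].sum())
        table.append((n_mut, len(idx) - n_mut))
    arr = np.array(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return StratumTest(gene, tuple(map(tuple, table)), 0.0, 1.0, "fisher_exact", degenerate=True)
    expected = stats.contingency.expected_freq(arr)
    if (expected < 5).any():
        p = fisher_exact_p(arr)
        return StratumTest(gene, tuple(map(tuple, table)), float(stats.fisher_exact(arr)[0]), p, "fisher_exact")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return StratumTest(gene, tuple(map(tuple, table)), float(chi2), float(p), "chi_squared")


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (clipped to 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def frequency_table_with_tests(m: CohortMatrix, min_freq: float = 0.05) -> pd.DataFrame:
    """Wide per-gene summary over the two lesion strata with BH-corrected
    stratum-difference tests; ``penetrant`` marks genes passing the 5% rule."""
    freq = gene_frequencies(m, stratify_by="lesion_type")
    penetrant = set(penetrance_filter(freq, min_freq=min_freq))
    wide = freq.pivot(index="gene", columns="stratum", values=["n_mutated", "n_total", "frequency"])
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    tests = [compare_strata(m, g) for g in wide.index]
    wide["test_name"] = [t.test_name for t in tests]
    wide["statistic"] = [t.statistic for t in tests]
    wide["p_value"] = [t.p_value for t in tests]
    wide["q_value"] = adjust_bh(wide["p_value"].to_numpy())
    wide["degenerate"] = [t.degenerate for t in tests]
    wide["penetrant"] = [g in penetrant for g in wide.index]
    return wide.reset_index().sort_values("gene").reset_index(drop=True)
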