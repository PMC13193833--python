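"""Pairwise co-occurrence / mutual-exclusivity over penetrant genes.

Each unordered gene pair in a stratum gets a 2x2 table (both, a only,
b only, neither), a two-sided Fisher exact p, an odds ratio
(Haldane-Anscombe +0.5 when a cell is zero), and a signed z statistic:

    z = s * Phi^-1(1 - p/2),   s = +1 if observed co-mutation < expected
                                   under independence (exclusivity),
                               s = -1 otherwise (co-occurrence).

The sign convention follows the field's reporting style: positive z means
mutual exclusivity, negative z means co-occurrence. The construction is an
interpretation in terms of the Fisher p — a defined, reproducible statistic
with the standard sign semantics — not a reverse-engineered replication of
any specific published z table.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import CohortMatrix
from .penetrance import fisher_exact_p

_P_FLOOR = 1e-300  # clamp before the probit transform


def pair_counts(m: CohortMatrix, gene_a: str, gene_b: str, stratum: str) -> tuple[int, int, int, int]:
    """(both, a_only, b_only, neither) over the patients of a stratum."""
    for g in (gene_a, gene_b):
        if g not in m.indicator.columns:
            raise KeyError(f"gene {g!r} is not a column of the cohort matrix")
    idx = m.stratum_patients(stratum)
    a = m.indicator.loc[idx, gene_a].to_numpy()
    b = m.indicator.loc[idx, gene_b].to_numpy()
    both = int(((a == 1) & (b == 1)).sum())
    a_only = int(((a == 1) & (b == 0)).sum())
    b_only = int(((a == 0) & (b == 1)).sum())
    neither = int(((a == 0) & (b == 0)).sum())
    return both, a_only, b_only, neither


def odds_ratio(both: int, a_only: int, b_only: int, neither: int) -> float:
    """Cross-product odds ratio with Haldane-Anscombe correction on zeros."""
    cells = np.array([both, a_only, b_only, neither], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    return float(cells[0] * cells[3] / (cells[1] * cells[2]))


def signed_z(both: int, a_only: int, b_only: int, neither: int) -> tuple[float, float, bool]:
    """(z, p, degenerate) for one 2x2 co-mutation table.

    Degenerate margins (a gene mutated in none or all patients of the
    stratum) carry no pairwise information: z = 0, p = 1, flagged.
    """
    n = both + a_only + b_only + neither
    margin_a = both + a_only
    margin_b = both + b_only
    if n == 0 or margin_a in (0, n) or margin_b in (0, n):
        return 0.0, 1.0, True
    p = fisher_exact_p([[both, a_only], [b_only, neither]])
    expected_both = margin_a * margin_b / n
    s = 1.0 if both < expected_both else -1.0
    # isf is the numerically stable upper-tail form of Phi^-1(1 - p/2)
    z = s * stats.norm.isf(max(p, _P_FLOOR) / 2.0)
    # p = 1 (co-mutation at expectation) maps to z = 0 regardless of sign.
    return float(z), float(p), False


def pairwise_association(m: CohortMatrix, genes: list[str], stratum: str) -> pd.DataFrame:
    """Long-format pair table for every unordered pair of ``genes``.

    Symmetric by construction; genes are expected to have passed the
    penetrance filter but this is not enforced.
    """
    rows = []
    for gene_a, gene_b in combinations(sorted(genes), 2):
        both, a_only, b_only, neither = pair_counts(m, gene_a, gene_b, stratum)
        z, p, degenerate = signed_z(both, a_only, b_only, neither)
        rows.append(
            {
                "gene_a": gene_a,
                "gene_b": gene_b,
                "stratum": stratum,
                "n_both": both,
                "n_a_only": a_only,
                "n_b_only": b_only,
                "n_neither": neither,
                "odds_ratio": odds_ratio(both, a_only, b_only, neither),
                "p_value": p,
                "z": z,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
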