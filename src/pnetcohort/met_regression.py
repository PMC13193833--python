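"""Logistic regression of metastatic status on gene mutation indicators.

The model follows a two-stage covariate-removal protocol before fitting:

1. *aliased* covariates — columns exactly linearly determined by earlier
   retained columns (R² >= 1 - 1e-10, which covers perfect positive and
   negative correlation) — are dropped, keeping the earlier column;
2. the covariate with the highest variance inflation factor is removed
   recursively until every surviving covariate has VIF <= 4.

Covariates are the genes mutated in at least 5% of primary *or* metastatic
tumors; the outcome is 1 for metastasis. The maximum-likelihood fit is a
Newton/IRLS logistic regression (convergence when the coefficient update
falls below 1e-8, at most 25 iterations); per-covariate inference is the
Wald chi-squared test with Benjamini-Hochberg correction across covariates,
and 95% CIs are beta +/- 1.96*se exponentiated onto the odds-ratio scale.

Usage follows the Model/Results convention::

    model = MetastasisLogit.from_cohort(matrix, min_freq=0.05)
    res = model.fit(vif_threshold=4.0)
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import RegressionError
from .harmonize import CohortMatrix

_ALIAS_R2 = 1.0 - 1e-10
_SEPARATION_BETA = 10.0


@dataclass
class DesignMatrix:
    """Gene-indicator design: X (0/1 columns, no intercept) and binary y."""

    X: pd.DataFrame
    y: pd.Series

    @property
    def covariates(self) -> list[str]:
        return list(self.X.columns)


def build_design(m: CohortMatrix, min_freq: float = 0.05) -> DesignMatrix:
    """Design over genes meeting the 5%-in-either-stratum rule.

    Column order is descending pooled frequency with alphabetical
    tie-break; outcome is 1 for the metastasis stratum.
    """
    strata = m.stratum
    for lesion in ("primary", "metastasis"):
        if (strata == lesion).sum() == 0:
            raise RegressionError(f"no patients in stratum {lesion!r}")
    keep = []
    for gene in m.genes:
        col = m.indicator[gene]
        freqs = [
            col.loc[strata == lesion].mean() for lesion in ("primary", "metastasis")
        ]
        if max(freqs) >= min_freq:
            pooled = col.mean()
            keep.append((gene, pooled))
    if not keep:
        raise RegressionError("no covariates pass the frequency threshold")
    order = [g for g, _ in sorted(keep, key=lambda t: (-t[1], t[0]))]
    X = m.indicator[order].astype(float)
    y = (strata == "metastasis").astype(int)
    return DesignMatrix(X=X, y=y)


def _r_squared(target: np.ndarray, others: np.ndarray) -> float:
    """R² of a least-squares regression of ``target`` on ``others`` plus an
    intercept; 0 when the target is constant."""
    n = len(target)
    A = np.column_stack([np.ones(n), others]) if others.size else np.ones((n, 1))
    coef, _, _, _ = np.linalg.lstsq(A, target, rcond=None)
    resid = target - A @ coef
    ss_res = float(resid @ resid)
    centered = target - target.mean()
    ss_tot = float(centered @ centered)
    if ss_tot == 0.0:
        return 0.0
    return max(0.0, 1.0 - ss_res / ss_tot)


def drop_aliased(d: DesignMatrix) -> tuple[DesignMatrix, list[str]]:
    """Drop columns perfectly determined by earlier retained columns."""
    retained: list[str] = []
    removed: list[str] = []
    for col in d.X.columns:
        target = d.X[col].to_numpy(dtype=float)
        others = d.X[retained].to_numpy(dtype=float) if retained else np.empty((len(d.X), 0))
        if target.std() == 0.0 or _r_squared(target, others) >= _ALIAS_R2:
            removed.append(col)
        else:
            retained.append(col)
    return DesignMatrix(X=d.X[retained], y=d.y), removed


def vif(d: DesignMatrix, column: str) -> float:
    """VIF_j = 1 / (1 - R²_j), R²_j from regressing column j on the other
    covariates plus intercept; numerically singular designs report inf."""
    target = d.X[column].to_numpy(dtype=float)
    others = d.X.drop(columns=[column]).to_numpy(dtype=float)
    r2 = _r_squared(target, others)
    if r2 >= 1.0 - 1e-14:
        return float("inf")
    return 1.0 / (1.0 - r2)


def prune_by_vif(d: DesignMatrix, threshold: float = 4.0) -> tuple[DesignMatrix, list[tuple[str, float]]]:
    """Recursively remove the max-VIF covariate until all VIFs <= threshold.

    Argmax ties break alphabetically. Terminates in at most p - 1 rounds; a
    single covariate always has VIF 1 and is never removed.
    """
    removed: list[tuple[str, float]] = []
    current = d
    while len(current.X.columns) > 1:
        vifs = {c: vif(current, c) for c in current.X.columns}
        worst_value = max(vifs.values())
        if worst_value <= threshold:
            break
        worst = min(c for c, v in vifs.items() if v == worst_value)
        removed.append((worst, worst_value))
        current = DesignMatrix(X=current.X.drop(columns=[worst]), y=current.y)
    return current, removed


@dataclass
class MetastasisLogitResults:
    """Fitted-model results: per-covariate estimates, inference, removal
    logs and convergence diagnostics, statsmodels-results style."""

    table: pd.DataFrame  # covariate, beta, se, wald, p, q, OR, CI
    removed_aliased: list[str]
    removed_vif: list[tuple[str, float]]
    converged: bool
    iterations: int
    separation_flag: bool
    n_obs: int
    llf: float

    @property
    def params(self) -> pd.Series:
        return self.table.set_index("covariate")["beta"]

    @property
    def pvalues(self) -> pd.Series:
        return self.table.set_index("covariate")["p_value"]

    @property
    def qvalues(self) -> pd.Series:
        return self.table.set_index("covariate")["q_value"]

    @property
    def odds_ratios(self) -> pd.Series:
        return self.table.set_index("covariate")["odds_ratio"]

    def summary(self) -> str:
        lines = [
            "Metastasis logistic regression (gene indicators)",
            f"  n = {self.n_obs}, log-likelihood = {self.llf:.4f}",
            f"  converged: {self.converged} in {self.iterations} iterations"
            + ("  [separation warning]" if self.separation_flag else ""),
            f"  aliased removed: {', '.join(self.removed_aliased) or 'none'}",
            "  VIF removed: "
            + (", ".join(f"{g} (VIF={v:.2f})" for g, v in self.removed_vif) or "none"),
            "",
            self.table.to_string(
                index=False,
                float_format=lambda x: f"{x:.4g}",
            ),
        ]
        return "\n".join(lines)


class MetastasisLogit:
    """Metastasis-association model over a harmonized cohort matrix.

    Parameters
    ----------
    design : DesignMatrix
        Gene-indicator covariates plus binary metastasis outcome. Build
        from a cohort with :meth:`from_cohort`. Extra (clinical) covariate
        columns may be appended to ``design.X`` before fitting.
    """

    def __init__(self, design: DesignMatrix):
        if design.y.nunique() < 2:
            raise RegressionError("outcome must contain both classes")
        self.design = design

    @classmethod
    def from_cohort(cls, m: CohortMatrix, min_freq: float = 0.05) -> "MetastasisLogit":
        return cls(build_design(m, min_freq=min_freq))

    def fit(self, vif_threshold: float = 4.0, bh: bool = True) -> MetastasisLogitResults:
        pruned, removed_aliased = drop_aliased(self.design)
        pruned, removed_vif = prune_by_vif(pruned, threshold=vif_threshold)
        if len(pruned.X.columns) == 0:
            raise RegressionError("no covariates survive the removal stages")
        # Contract check: the surviving design must satisfy the threshold.
        max_vif = max(vif(pruned, c) for c in pruned.X.columns) if len(pruned.X.columns) > 1 else 1.0
        assert max_vif <= vif_threshold + 1e-9, "VIF pruning failed its contract"
        return fit_logistic(pruned, removed_aliased=removed_aliased, removed_vif=removed_vif, bh=bh)


def fit_logistic(
    d: DesignMatrix,
    removed_aliased: list[str] | None = None,
    removed_vif: list[tuple[str, float]] | None = None,
    bh: bool = True,
) -> MetastasisLogitResults:
    """Newton/IRLS maximum-likelihood logistic fit with Wald + BH inference.

    Expects removal stages already applied. Non-convergence or any
    |beta| > 10 raises the separation flag on the result instead of
    failing.
    """
    from .penetrance import adjust_bh

    X = sm.add_constant(d.X.astype(float), prepend=True, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(d.y.astype(float), X)
        try:
            res = model.fit(method="newton", maxiter=25, tol=1e-8, disp=0)
            converged = bool(res.mle_retvals.get("converged", False))
            iterations = int(res.mle_retvals.get("iterations", 0))
        except Exception:
            # Perfect separation makes the Hessian singular under Newton;
            # fall back to a gradient method and flag via the beta check.
            try:
                res = model.fit(method="bfgs", maxiter=200, disp=0)
            except Exception as exc:
                raise RegressionError(f"logistic fit failed: {exc}") from exc
            converged = False
            iterations = int(res.mle_retvals.get("iterations", 0) or 0)

    params = res.params
    bse = res.bse
    covariates = list(d.X.columns)
    wald = (params / bse) ** 2
    from scipy import stats as _st

    p = pd.Series(_st.chi2.sf(wald, df=1), index=params.index)
    gene_p = p.loc[covariates].to_numpy()
    q = adjust_bh(gene_p) if bh else gene_p
    qmap = dict(zip(covariates, q))

    rows = []
    with np.errstate(over="ignore"):  # separated fits may overflow to inf
        for name in params.index:
            beta = float(params[name])
            se = float(bse[name])
            rows.append(
                {
                    "covariate": name if name != "const" else "intercept",
                    "beta": beta,
                    "se": se,
                    "wald_statistic": float(wald[name]),
                    "p_value": float(p[name]),
                    "q_value": float(qmap.get(name, np.nan)),
                    "odds_ratio": float(np.exp(beta)),
                    "ci95_low": float(np.exp(beta - 1.96 * se)),
                    "ci95_high": float(np.exp(beta + 1.96 * se)),
                }
            )
    table = pd.DataFrame(rows)
    separation = (not converged) or bool(
        (table.loc[table["covariate"] != "intercept", "beta"].abs() > _SEPARATION_BETA).any()
    )
    return MetastasisLogitResults(
        table=table,
        removed_aliased=removed_aliased or [],
        removed_vif=removed_vif or [],
        converged=converged,
        iterations=iterations,
        separation_flag=separation,
        n_obs=len(d.y),
        llf=float(res.llf),
    )
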