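"""End-to-end orchestration: harmonize -> penetrance -> mutex -> subgroups
-> metastasis regression -> survival, with a machine-readable run manifest.

The analysis path is deterministic — only the synthetic generator consumes
a seed — and the manifest records input digests, every stage's counts, and
every design-decision setting in effect, so a run can be reproduced and
audited from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from . import harmonize, io_tables, met_regression, mutex, penetrance, subgroups, survival

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative run configuration; thresholds default to the protocol
    values (5% penetrance, VIF <= 4, BH correction)."""

    mutations_path: str
    clinical_patient_path: str
    clinical_sample_path: str | None
    panel_paths: list[str] = field(default_factory=list)
    out_dir: str = "results"
    dialect: str = "cbioportal"
    min_freq: float = 0.05
    threshold_scope: str = "any_stratum"
    vif_threshold: float = 4.0
    assume_sequenced: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, "rt", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> str:
    """Execute the full pipeline; returns the output directory.

    Emits cohort_matrix.tsv, exclusions.tsv, representative_samples.tsv,
    frequencies.tsv, mutex_<stratum>.tsv, subgroups_<scheme>.tsv,
    subgroup_distribution_<scheme>.tsv, regression.tsv,
    regression_removals.tsv, survival_curves_<scheme>.tsv,
    survival_summary.json and manifest.json.
    """
    t0 = time.time()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "settings": {
            "dialect": config.dialect,
            "min_freq": config.min_freq,
            "threshold_scope": config.threshold_scope,
            "vif_threshold": config.vif_threshold,
            "assume_sequenced": config.assume_sequenced,
            "nonsynonymous_classes": sorted(harmonize.NONSYNONYMOUS_CLASSES),
            "tmb_definition": "raw nonsynonymous variant count within the intersected panel",
            "tie_break": "lexicographically smallest sample_id",
        },
        "inputs": {},
        "stages": {},
    }
    for key, path in (
        ("mutations", config.mutations_path),
        ("clinical_patient", config.clinical_patient_path),
        ("clinical_sample", config.clinical_sample_path),
    ):
        if path:
            manifest["inputs"][key] = {"path": str(path), "sha256": _digest(path)}
    for i, path in enumerate(config.panel_paths):
        manifest["inputs"][f"panel_{i}"] = {"path": str(path), "sha256": _digest(path)}

    # --- io ---
    muts = io_tables.read_mutations(config.mutations_path, dialect=config.dialect)
    clin = io_tables.read_clinical(
        config.clinical_patient_path, config.clinical_sample_path, dialect=config.dialect
    )
    panels = [io_tables.read_gene_list(p) for p in config.panel_paths]
    if len(panels) >= 2:
        panel = harmonize.intersect_panels(panels)
    elif len(panels) == 1:
        panel = panels[0]
    else:
        panel = io_tables.GenePanel(name="observed", genes=frozenset(muts["gene"]))
    manifest["stages"]["io"] = {
        "n_variant_records": int(len(muts)),
        "n_clinical_samples": int(len(clin)),
        "n_patients": int(clin["patient_id"].nunique()),
        "panel_size": len(panel),
    }

    # --- harmonize ---
    eligible, exclusions = harmonize.apply_eligibility(clin)
    matrix = harmonize.build_cohort_matrix(
        muts, eligible, panel, assume_sequenced=config.assume_sequenced
    )
    rep = matrix.indicator.attrs["representative"]
    io_tables.write_table(matrix.to_frame(), os.path.join(config.out_dir, "cohort_matrix.tsv"))
    io_tables.write_table(exclusions, os.path.join(config.out_dir, "exclusions.tsv"))
    rep_df = rep.rename("sample_id").rename_axis("patient_id").reset_index()
    rep_df["tmb_nonsynonymous"] = rep.attrs["tmb"].reindex(rep_df["patient_id"]).to_numpy()
    io_tables.write_table(rep_df, os.path.join(config.out_dir, "representative_samples.tsv"))
    n_by_stratum = matrix.stratum.value_counts().to_dict()
    total = int(len(matrix.patients))
    manifest["stages"]["harmonize"] = {
        "n_excluded_patients": int(exclusions["patient_id"].nunique()),
        "n_dropped_unsequenced": len(rep.attrs["dropped_patients"]),
        "n_cohort_patients": total,
        "n_by_stratum": {k: int(v) for k, v in n_by_stratum.items()},
        "pct_by_stratum": {
            k: penetrance.percent(int(v), total) for k, v in n_by_stratum.items()
        },
    }

    # --- penetrance ---
    freq_table = penetrance.frequency_table_with_tests(matrix, min_freq=config.min_freq)
    io_tables.write_table(freq_table, os.path.join(config.out_dir, "frequencies.tsv"))
    penetrant = sorted(freq_table.loc[freq_table["penetrant"], "gene"])
    manifest["stages"]["penetrance"] = {
        "n_genes_tested": int(len(freq_table)),
        "n_penetrant": len(penetrant),
        "penetrant_genes": penetrant,
    }

    # --- mutex ---
    for stratum in ("primary", "metastasis"):
        pairs = mutex.pairwise_association(matrix, penetrant, stratum)
        io_tables.write_table(pairs, os.path.join(config.out_dir, f"mutex_{stratum}.tsv"))
    manifest["stages"]["mutex"] = {
        "n_pairs": int(len(penetrant) * (len(penetrant) - 1) // 2),
        "strata": ["primary", "metastasis"],
    }

    # --- subgroups (both schemes) ---
    assignments = {}
    for scheme_name in ("ciobanu", "novel"):
        asg = subgroups.classify_cohort(matrix, scheme_name)
        assignments[scheme_name] = asg
        io_tables.write_table(asg, os.path.join(config.out_dir, f"subgroups_{scheme_name}.tsv"))
        dist = subgroups.subgroup_distribution(asg, matrix.stratum, scheme_name)
        io_tables.write_table(
            dist, os.path.join(config.out_dir, f"subgroup_distribution_{scheme_name}.tsv")
        )
        manifest["stages"][f"subgroups_{scheme_name}"] = {
            "n_assigned": int(len(asg)),
            "labels": dist.groupby("label")["n"].sum().to_dict(),
        }

    # --- metastasis regression ---
    model = met_regression.MetastasisLogit.from_cohort(matrix, min_freq=config.min_freq)
    result = model.fit(vif_threshold=config.vif_threshold)
    io_tables.write_table(result.table, os.path.join(config.out_dir, "regression.tsv"))
    removals = pd.DataFrame(
        [("aliased", g, np.nan) for g in result.removed_aliased]
        + [("vif", g, v) for g, v in result.removed_vif],
        columns=["stage", "covariate", "vif_at_removal"],
    )
    io_tables.write_table(removals, os.path.join(config.out_dir, "regression_removals.tsv"))
    manifest["stages"]["met_regression"] = {
        "n_covariates_initial": len(model.design.covariates),
        "n_removed_aliased": len(result.removed_aliased),
        "n_removed_vif": len(result.removed_vif),
        "n_covariates_final": int(len(result.table) - 1),
        "converged": result.converged,
        "separation_flag": result.separation_flag,
    }

    # --- survival (per subgroup scheme) ---
    eligible_in_cohort = eligible.loc[eligible["patient_id"].isin(matrix.patients)]
    surv_summary = {}
    for scheme_name, asg in assignments.items():
        data = survival.survival_input(eligible_in_cohort, asg)
        curves, lr = survival.survival_by_group(data)
        io_tables.write_table(
            curves, os.path.join(config.out_dir, f"survival_curves_{scheme_name}.tsv")
        )
        medians = (
            curves.drop_duplicates("group").set_index("group")["median"].to_dict()
            if len(curves)
            else {}
        )
        surv_summary[scheme_name] = {
            "n_with_survival": int(len(data)),
            "n_excluded": int(data.attrs["n_excluded"]),
            "medians_months": {k: (None if pd.isna(v) else float(v)) for k, v in medians.items()},
            "logrank": None
            if lr is None
            else {"statistic": lr.statistic, "df": lr.df, "p_value": lr.p_value},
        }
    with open(os.path.join(config.out_dir, "survival_summary.json"), "wt", encoding="utf-8") as fh:
        json.dump(surv_summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["stages"]["survival"] = {
        k: {kk: v[kk] for kk in ("n_with_survival", "n_excluded")}
        for k, v in surv_summary.items()
    }

    manifest["runtime_seconds"] = round(time.time() - t0, 3)
    with open(os.path.join(config.out_dir, "manifest.json"), "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run_all finished in %.1fs -> %s", manifest["runtime_seconds"], config.out_dir)
    return config.out_dir
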