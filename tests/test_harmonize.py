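import numpy as np
import pandas as pd
import pytest

from pnetcohort import harmonize as hz
from pnetcohort.errors import EmptyPanelError
from pnetcohort.io_tables import GenePanel, clinical_from_frames, mutations_from_frame


def panel(*genes):
    return GenePanel(name="test", genes=frozenset(genes))


def maf(rows):
    """rows: (sample_id, gene, variant_class [, patient_id])"""
    df = pd.DataFrame(
        [
            {
                "Hugo_Symbol": g,
                "Variant_Classification": vc,
                "Tumor_Sample_Barcode": s,
                "Patient_ID": r[3] if len(r) > 3 else s.split("-")[0],
            }
            for r in rows
            for (s, g, vc) in [r[:3]]
        ]
    )
    return mutations_from_frame(df)


def clinical(rows):
    """rows: (patient_id, sample_id, lesion, grade, diff)"""
    patients = pd.DataFrame({"PATIENT_ID": sorted({r[0] for r in rows})})
    samples = pd.DataFrame(
        rows, columns=["PATIENT_ID", "SAMPLE_ID", "SAMPLE_TYPE", "GRADE", "HISTOLOGY"]
    )
    return clinical_from_frames(patients, samples)


class TestIntersectPanels:
    def test_set_identity(self):
        out = hz.intersect_panels([panel("A", "B", "C"), panel("B", "C", "D")])
        assert out.genes == frozenset({"B", "C"})

    def test_idempotence(self):
        p = panel("A", "B", "C")
        assert hz.intersect_panels([p, p]).genes == p.genes

    def test_empty_intersection_raises(self):
        with pytest.raises(EmptyPanelError):
            hz.intersect_panels([panel("A"), panel("B")])


class TestFilterNonsynonymous:
    @pytest.mark.parametrize(
        "classes,kept",
        [
            (["Missense_Mutation", "Silent"], 1),
            (["Nonsense_Mutation", "Frame_Shift_Del", "Splice_Site"], 3),
            (["Silent", "Silent"], 0),
        ],
    )
    def test_declared_set(self, classes, kept):
        muts = maf([(f"S{i}", "MEN1", vc) for i, vc in enumerate(classes)])
        assert len(hz.filter_nonsynonymous(muts)) == kept


class TestEligibility:
    def test_grade_and_carcinoma_rules(self):
        clin = clinical(
            [
                ("P1", "S1", "Primary", "G3", ""),
                ("P2", "S2", "Primary", "", "Neuroendocrine carcinoma"),
                ("P3", "S3", "Primary", "", ""),  # unknown grade: retained
                ("P4", "S4", "Primary", "G2", "PANET"),
            ]
        )
        eligible, exclusions = hz.apply_eligibility(clin)
        assert set(eligible["patient_id"]) == {"P3", "P4"}
        reasons = exclusions.set_index("patient_id")["reason"]
        assert reasons["P1"] == "grade G3"
        assert "carcinoma" in reasons["P2"]


class TestSelectRepresentative:
    def test_max_tmb_then_lexicographic_tie_break(self):
        muts = maf(
            [("P1-S1", "MEN1", "Missense_Mutation")] * 3
            + [("P1-S2", "MEN1", "Missense_Mutation")] * 5
            + [("P2-S2", "TP53", "Missense_Mutation")] * 4
            + [("P2-S1", "TP53", "Missense_Mutation")] * 4
            + [("P3-S1", "ATRX", "Missense_Mutation")]
        )
        clin = clinical(
            [
                ("P1", "P1-S1", "Primary", "", ""),
                ("P1", "P1-S2", "Primary", "", ""),
                ("P2", "P2-S1", "Primary", "", ""),
                ("P2", "P2-S2", "Primary", "", ""),
                ("P3", "P3-S1", "Primary", "", ""),
            ]
        )
        rep = hz.select_representative(muts, clin)
        assert rep["P1"] == "P1-S2"  # higher TMB wins
        assert rep["P2"] == "P2-S1"  # tie: lexicographically smaller
        assert rep["P3"] == "P3-S1"  # single sample

    def test_unsequenced_patient_dropped_unless_flagged(self):
        muts = maf([("P1-S1", "MEN1", "Missense_Mutation")])
        clin = clinical(
            [("P1", "P1-S1", "Primary", "", ""), ("P2", "P2-S1", "Primary", "", "")]
        )
        rep = hz.select_representative(muts, clin)
        assert "P2" not in rep.index and rep.attrs["dropped_patients"] == ["P2"]
        rep2 = hz.select_representative(muts, clin, assume_sequenced=True)
        assert rep2["P2"] == "P2-S1" and rep.attrs["tmb"]["P1"] == 1


FIXTURE_ROWS = [
    ("P01-S1", "MEN1", "Missense_Mutation"),
    ("P01-S1", "MEN1", "Nonsense_Mutation"),
    ("P01-S1", "MEN1", "Frame_Shift_Del"),  # 3 MEN1 hits -> indicator 1
    ("P02-S1", "DAXX", "Splice_Site"),
    ("P02-S1", "MEN1", "Missense_Mutation"),
    ("P03-S1", "ATRX", "Missense_Mutation"),
    ("P03-S1", "TTN", "Missense_Mutation"),  # off-panel: ignored
    ("P04-S1", "PTEN", "Silent"),  # synonymous: ignored
    ("P04-S1", "MEN1", "In_Frame_Del"),
    ("P05-S1", "TP53", "Missense_Mutation"),
    ("P05-S2", "TP53", "Missense_Mutation"),
    ("P05-S2", "KRAS", "Missense_Mutation"),  # S2 is representative
    ("P06-S1", "KRAS", "Missense_Mutation"),
    ("P07-S1", "TP53", "Nonstop_Mutation"),
    ("P08-S1", "MEN1", "Missense_Mutation"),
    ("P09-S1", "DAXX", "Missense_Mutation"),
    ("P10-S1", "SETD2", "Missense_Mutation"),
]

FIXTURE_CLIN = [
    ("P01", "P01-S1", "Primary", "", ""),
    ("P02", "P02-S1", "Primary", "", ""),
    ("P03", "P03-S1", "Primary", "", ""),
    ("P04", "P04-S1", "Primary", "", ""),
    ("P05", "P05-S1", "Metastatic", "", ""),
    ("P05", "P05-S2", "Metastatic", "", ""),
    ("P06", "P06-S1", "Metastatic", "", ""),
    ("P07", "P07-S1", "Metastatic", "", ""),
    ("P08", "P08-S1", "Metastatic", "", ""),
    ("P09", "P09-S1", "Primary", "", ""),
    ("P10", "P10-S1", "Primary", "", ""),
]

PANEL = ("ATRX", "DAXX", "KRAS", "MEN1", "PTEN", "SETD2", "TP53")


def brute_force_truth():
    """Hand tabulation of the fixture, independent of the pipeline."""
    nonsyn = hz.NONSYNONYMOUS_CLASSES
    by_sample = {}
    for s, g, vc in FIXTURE_ROWS:
        if vc in nonsyn and g in PANEL:
            by_sample.setdefault(s, []).append(g)
    rep = {}
    for p, s, *_ in FIXTURE_CLIN:
        n = len(by_sample.get(s, []))
        cur = rep.get(p)
        if cur is None or n > cur[1] or (n == cur[1] and s < cur[0]):
            rep[p] = (s, n)
    truth = {}
    for p, (s, _) in rep.items():
        truth[p] = {g: int(g in by_sample.get(s, [])) for g in PANEL}
    return truth


def test_cohort_matrix_matches_hand_tabulation():
    muts = maf(FIXTURE_ROWS)
    clin = clinical(FIXTURE_CLIN)
    m = hz.build_cohort_matrix(muts, clin, panel(*PANEL), assume_sequenced=True)
    truth = brute_force_truth()
    assert sorted(m.patients) == sorted(truth)
    for p, genes in truth.items():
        for g, v in genes.items():
            assert m.indicator.at[p, g] == v, (p, g)
    # binarization: 3 MEN1 variants collapse to 1
    assert m.indicator.at["P01", "MEN1"] == 1
    # off-panel gene contributes no column
    assert "TTN" not in m.indicator.columns
    # representative of P05 is the higher-TMB sample
    assert m.indicator.attrs["representative"]["P05"] == "P05-S2"


def test_filter_and_panel_restriction_commute():
    muts = maf(FIXTURE_ROWS)
    p = panel(*PANEL)
    a = hz.restrict_to_panel(hz.filter_nonsynonymous(muts), p)
    b = hz.filter_nonsynonymous(hz.restrict_to_panel(muts, p))
    pd.testing.assert_frame_equal(a, b)


def test_indicator_row_sum_bounded_by_tmb():
    muts = maf(FIXTURE_ROWS)
    clin = clinical(FIXTURE_CLIN)
    m = hz.build_cohort_matrix(muts, clin, panel(*PANEL), assume_sequenced=True)
    rep = m.indicator.attrs["representative"]
    tmb = rep.attrs["tmb"]
    for p in m.patients:
        assert m.indicator.loc[p].sum() <= tmb[p]


def test_harmonization_fixed_point():
    """Re-harmonizing a cohort reconstructed from the matrix reproduces it."""
    muts = maf(FIXTURE_ROWS)
    clin = clinical(FIXTURE_CLIN)
    m1 = hz.build_cohort_matrix(muts, clin, panel(*PANEL), assume_sequenced=True)

    rows = []
    clin_rows = []
    for p in m1.patients:
        s = f"{p}-R1"
        clin_rows.append((p, s, m1.stratum[p].capitalize(), "", ""))
        for g in sorted(m1.mutated_genes(p)):
            rows.append((s, g, "Missense_Mutation", p))
    m2 = hz.build_cohort_matrix(
        maf(rows), clinical(clin_rows), panel(*PANEL), assume_sequenced=True
    )
    assert (m1.indicator.to_numpy() == m2.indicator.to_numpy()).all()
    assert list(m1.stratum) == list(m2.stratum)
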