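"""Shared fixtures: reconstructed published tables and tiny cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from strokescore import (
    DOMINANT,
    RECESSIVE,
    Cohort,
    CountTable2x2,
    association_from_counts,
    build_score_model,
    reconstruct_counts,
)

DISCOVERY_N = {"case": 374, "control": 156}
REPLICATION_N = {"case": 242, "control": 547}

#: printed genotype-class percentages: snp -> (case %, control %) per arm
TABLE3_PCT = {
    "discovery": {"rs1800779": (22.4, 11.6), "rs2257073": (5.2, 10.5), "rs1205": (40.9, 51.3)},
    "replication": {"rs1800779": (21.6, 19.4), "rs2257073": (5.4, 7.8), "rs1205": (40.4, 45.7)},
}
ALLELES = {"rs1800779": ("A", "G"), "rs2257073": ("C", "T"), "rs1205": ("C", "T")}
# the printed class is the recessive-exposed class for the NOS3 SNPs (GG, TT)
# and the major-allele homozygote (complement of the carrier class) for rs1205


def printed_class_table(arm: str, snp: str) -> CountTable2x2:
    """2x2 with the printed genotype class as exposure, rebuilt from
    percentages and cohort sizes."""
    sizes = DISCOVERY_N if arm == "discovery" else REPLICATION_N
    pct_case, pct_ctrl = TABLE3_PCT[arm][snp]
    a = reconstruct_counts(pct_case, sizes["case"])
    c = reconstruct_counts(pct_ctrl, sizes["control"])
    return CountTable2x2(a, sizes["case"] - a, c, sizes["control"] - c)


def discovery_results():
    """Association results for the three discovery hits, with each SNP
    under the encoding whose exposed class is the printed class."""
    out = []
    for snp in ("rs1800779", "rs2257073"):
        out.append(association_from_counts(
            snp, RECESSIVE, printed_class_table("discovery", snp), alleles=ALLELES[snp]
        ))
    # rs1205 prints the CC class; under the dominant minor-allele (T)
    # encoding the exposed class is the carrier complement CT/TT
    t = printed_class_table("discovery", "rs1205")
    out.append(association_from_counts(
        "rs1205", DOMINANT, CountTable2x2(t.b, t.a, t.d, t.c), alleles=ALLELES["rs1205"]
    ))
    return out


@pytest.fixture
def eq1_model():
    """The published three-term score model, rebuilt from the printed
    discovery frequencies."""
    return build_score_model(discovery_results())


def make_cohort(genotype_rows, statuses, subtypes=None, panel_extra=None,
                snps=("rs1800779", "rs2257073", "rs1205"), name="toy",
                af=None) -> Cohort:
    """Tiny hand-built cohort from explicit genotype code rows."""
    n = len(genotype_rows)
    ids = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    if subtypes is None:
        subtypes = ["cardioembolic" if s == "case" else "none" for s in statuses]
    pheno = pd.DataFrame(
        {
            "status": statuses,
            "subtype": subtypes,
            "sex": ["female"] * n,
            "hypertension": ["no"] * n,
            "diabetes": ["no"] * n,
            "smoker": ["no"] * n,
            "dyslipidemia": ["no"] * n,
            "atrial_fibrillation": af if af is not None else ["no"] * n,
        },
        index=ids,
    )
    geno = pd.DataFrame(np.asarray(genotype_rows, dtype=np.int8), index=ids,
                        columns=list(snps))
    panel = pd.DataFrame(
        {
            "gene": ["NOS3", "NOS3", "CRP"][: len(snps)],
            "chromosome": ["7", "7", "1"][: len(snps)],
            "major_allele": [ALLELES[s][0] if s in ALLELES else "A" for s in snps],
            "minor_allele": [ALLELES[s][1] if s in ALLELES else "G" for s in snps],
        },
        index=pd.Index(list(snps), name="snp_id"),
    )
    if panel_extra:
        for col, vals in panel_extra.items():
            panel[col] = vals
    return Cohort(name=name, phenotypes=pheno, genotypes=geno, panel=panel)
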