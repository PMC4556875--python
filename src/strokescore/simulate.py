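"""Synthetic case-control cohorts with prescribed genotype-class and
covariate frequencies.

The generator emulates the two study arms of the inflammatory-
polymorphism stroke study: a discovery arm of 374 cardioembolic cases
and 156 controls, and a replication arm of 242 cases and 547 controls.
Published results report only collapsed genotype classes per group
(e.g. GG 22.4% of cases), so presets pin the printed class frequency
exactly and split the remaining probability mass between the other two
classes by Hardy-Weinberg proportions conditional on that class
frequency.  Genotypes are drawn independently across SNPs (no linkage
disequilibrium) and covariates are independent Bernoulli per group;
atrial fibrillation is flagged on 46.4% of cardioembolic cases,
independent of genotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import HOM_MAJOR, HOM_MINOR, MISSING, Cohort

# -- published per-group frequencies the presets reproduce --------------

#: SNP metadata and printed genotype-class frequencies.
#: "printed_class" is the genotype class whose frequency the source
#: table reports (codes: 0 hom-major, 1 het, 2 hom-minor).
TABLE3_SNPS: dict[str, dict] = {
    "rs1800779": {
        "gene": "NOS3", "chromosome": "7",
        "major": "A", "minor": "G",
        "printed_class": HOM_MINOR,  # GG
        "discovery": {"case": 0.224, "control": 0.116},
        "replication": {"case": 0.216, "control": 0.194},
    },
    "rs2257073": {
        "gene": "NOS3", "chromosome": "7",
        "major": "C", "minor": "T",
        "printed_class": HOM_MINOR,  # TT
        "discovery": {"case": 0.052, "control": 0.105},
        "replication": {"case": 0.054, "control": 0.078},
    },
    "rs1205": {
        "gene": "CRP", "chromosome": "1",
        "major": "C", "minor": "T",
        "printed_class": HOM_MAJOR,  # CC
        "discovery": {"case": 0.409, "control": 0.513},
        "replication": {"case": 0.404, "control": 0.457},
    },
}

#: Clinical risk-factor prevalences per arm and group (cases are the
#: cardioembolic group; "male" parameterizes the sex column).
TABLE2_COVARIATES: dict[str, dict[str, dict[str, float]]] = {
    "discovery": {
        "case": {"male": 0.504, "hypertension": 0.631, "smoker": 0.138,
                 "diabetes": 0.22, "dyslipidemia": 0.346},
        "control": {"male": 0.285, "hypertension": 0.40, "smoker": 0.146,
                    "diabetes": 0.146, "dyslipidemia": 0.277},
    },
    "replication": {
        "case": {"male": 0.475, "hypertension": 0.598, "smoker": 0.183,
                 "diabetes": 0.199, "dyslipidemia": 0.258},
        "control": {"male": 0.425, "hypertension": 0.442, "smoker": 0.126,
                    "diabetes": 0.082, "dyslipidemia": 0.287},
    },
}

#: Fraction of cardioembolic cases with atrial fibrillation before onset.
AF_RATE_CASES = 0.464

COHORT_SIZES = {
    "discovery": {"case": 374, "control": 156},
    "replication": {"case": 242, "control": 547},
}

PRESETS = ("discovery_table3", "replication_table3", "null_cohort")


def hwe_class_probs(printed_class: int, freq: float) -> tuple[float, float, float]:
    """(hom-major, het, hom-minor) probabilities pinning the printed
    homozygote class frequency exactly, with the other two classes in
    Hardy-Weinberg proportion.

    For a printed minor-homozygote frequency f: q = sqrt(f); for a
    printed major-homozygote frequency f: p = sqrt(f).
    """
    if not 0 < freq < 1:
        raise ValueError(f"class frequency must be in (0,1), got {freq}")
    if printed_class == HOM_MINOR:
        q = math.sqrt(freq)
        p = 1 - q
    elif printed_class == HOM_MAJOR:
        p = math.sqrt(freq)
        q = 1 - p
    else:
        raise ValueError("only homozygote classes are printed in the source tables")
    return (p * p, 2 * p * q, q * q)


@dataclass
class GroupSpec:
    """One simulated group: status/subtype, size, and per-SNP class
    probabilities over (hom-major, het, hom-minor)."""

    status: str
    subtype: str
    n: int
    genotype_probs: dict[str, tuple[float, float, float]]
    covariate_probs: dict[str, float] = field(default_factory=dict)
    af_rate: float = 0.0

    def __post_init__(self):
        for snp, probs in self.genotype_probs.items():
            if abs(sum(probs) - 1.0) > 1e-12:
                raise ValueError(f"{snp}: class probabilities sum to {sum(probs)}")


@dataclass
class SimulationSpec:
    name: str
    groups: list[GroupSpec]
    panel: pd.DataFrame  # snp_id-indexed: gene, chromosome, major/minor alleles
    missing_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"missing_rate must be in [0,1), got {self.missing_rate}")


def _table3_panel() -> pd.DataFrame:
    rows = {
        snp: {"gene": m["gene"], "chromosome": m["chromosome"],
              "major_allele": m["major"], "minor_allele": m["minor"]}
        for snp, m in TABLE3_SNPS.items()
    }
    panel = pd.DataFrame.from_dict(rows, orient="index")
    panel.index.name = "snp_id"
    return panel


def make_preset(name: str, scale: int = 1, seed: int | None = None) -> SimulationSpec:
    """Fully specified simulation matching one study arm.

    discovery_table3 / replication_table3 reproduce the printed
    genotype-class frequencies and covariate prevalences of the
    corresponding arm; null_cohort uses discovery sizes with the
    discovery-control frequencies in both groups (no association
    anywhere).  ``scale`` multiplies the group sizes.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESETS)}")
    arm = "replication" if name == "replication_table3" else "discovery"
    sizes = COHORT_SIZES[arm]
    groups = []
    for status, subtype in (("case", "cardioembolic"), ("control", "none")):
        freq_group = "control" if name == "null_cohort" else status
        probs = {
            snp: hwe_class_probs(m["printed_class"], m[arm][freq_group])
            for snp, m in TABLE3_SNPS.items()
        }
        cov = dict(TABLE2_COVARIATES[arm][freq_group])
        groups.append(
            GroupSpec(
                status=status,
                subtype=subtype,
                n=sizes[status] * scale,
                genotype_probs=probs,
                covariate_probs=cov,
                af_rate=AF_RATE_CASES if (status == "case" and name != "null_cohort") else 0.0,
            )
        )
    return SimulationSpec(name=name, groups=groups, panel=_table3_panel(), seed=seed)


def simulate_cohort(spec: SimulationSpec, seed: int | None = None) -> Cohort:
    """Draw a cohort from a simulation spec, fully reproducible from the
    seed (argument overrides ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    snps = list(spec.panel.index)
    pheno_rows = []
    geno_blocks = []
    ids = []
    for gi, grp in enumerate(spec.groups):
        n = grp.n
        ids.extend(f"{spec.name}-g{gi}-{i:06d}" for i in range(n))
        block = np.empty((n, len(snps)), dtype=np.int8)
        for j, snp in enumerate(snps):
            probs = grp.genotype_probs[snp]
            block[:, j] = rng.choice(3, size=n, p=probs).astype(np.int8)
        if spec.missing_rate > 0:
            miss = rng.random((n, len(snps))) < spec.missing_rate
            block[miss] = MISSING
        geno_blocks.append(block)

        male = rng.random(n) < grp.covariate_probs.get("male", 0.5)
        block_pheno = {
            "status": np.repeat(grp.status, n),
            "subtype": np.repeat(grp.subtype, n),
            "sex": np.where(male, "male", "female"),
        }
        for cov in ("hypertension", "diabetes", "smoker", "dyslipidemia"):
            p = grp.covariate_probs.get(cov, 0.0)
            block_pheno[cov] = np.where(rng.random(n) < p, "yes", "no")
        block_pheno["atrial_fibrillation"] = np.where(
            rng.random(n) < grp.af_rate, "yes", "no"
        )
        pheno_rows.append(pd.DataFrame(block_pheno))
    index = pd.Index(ids, name="sample_id")
    phenotypes = pd.concat(pheno_rows, ignore_index=True).set_index(index)
    genotypes = pd.DataFrame(
        np.vstack(geno_blocks), index=index, columns=snps
    ).astype(np.int8)
    return Cohort(
        name=spec.name,
        phenotypes=phenotypes,
        genotypes=genotypes,
        panel=spec.panel.copy(),
        meta={"simulated": True, "preset": spec.name},
    )
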