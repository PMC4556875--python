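"""Cohort data model: phenotype records plus a coded genotype matrix.

A :class:`Cohort` holds one study arm (e.g. discovery or replication):
an ordered phenotype table (case/control status, TOAST stroke subtype,
binary clinical risk factors), a sample x SNP genotype matrix coded as
small integers, and the SNP panel metadata including the major/minor
allele assignment used for coding.

Genotype coding
---------------
Each call is one of four states, stored as ``int8``:

====================  ====
state                 code
====================  ====
homozygous major      0
heterozygous          1
homozygous minor      2
missing               -1
====================  ====

Allele-pair strings are unordered ("AG" and "GA" are the same call).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOM_MAJOR = 0
HET = 1
HOM_MINOR = 2
MISSING = -1

GENOTYPE_CODES = (HOM_MAJOR, HET, HOM_MINOR)

STATUSES = ("case", "control")
SUBTYPES = ("cardioembolic", "atherothrombotic", "lacunar", "undetermined", "none")
SEXES = ("male", "female", "missing")
BINARY_COVARIATES = (
    "hypertension",
    "diabetes",
    "smoker",
    "dyslipidemia",
    "atrial_fibrillation",
)
YES_NO = ("yes", "no", "missing")

PHENOTYPE_COLUMNS = ("status", "subtype", "sex") + BINARY_COVARIATES


class CohortValidationError(ValueError):
    """A phenotype/genotype table violates a cohort invariant."""


@dataclass
class Cohort:
    """One study arm: phenotypes, coded genotypes and the SNP panel.

    Parameters
    ----------
    name
        Label for the arm, e.g. ``"discovery"``.
    phenotypes
        DataFrame indexed by unique ``sample_id`` with columns
        ``status, subtype, sex`` and the binary covariates.
    genotypes
        DataFrame indexed like ``phenotypes`` with one ``int8`` column
        per SNP holding the codes above.
    panel
        DataFrame indexed by ``snp_id`` with columns ``gene``,
        ``chromosome`` and (when alleles are known) ``major_allele``,
        ``minor_allele``.
    """

    name: str
    phenotypes: pd.DataFrame
    genotypes: pd.DataFrame
    panel: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        ph, gt = self.phenotypes, self.genotypes
        if ph.index.has_duplicates:
            dup = ph.index[ph.index.duplicated()][0]
            raise CohortValidationError(f"duplicate sample id {dup!r}")
        if not ph.index.equals(gt.index):
            missing = set(ph.index).symmetric_difference(gt.index)
            raise CohortValidationError(
                f"phenotype and genotype tables disagree on sample ids: {sorted(missing)[:5]}"
            )
        for col in PHENOTYPE_COLUMNS:
            if col not in ph.columns:
                raise CohortValidationError(f"phenotype table lacks column {col!r}")
        bad_status = ~ph["status"].isin(STATUSES)
        if bad_status.any():
            raise CohortValidationError(
                f"unknown status {ph.loc[bad_status, 'status'].iloc[0]!r}"
            )
        bad_sub = ~ph["subtype"].isin(SUBTYPES)
        if bad_sub.any():
            raise CohortValidationError(
                f"unknown subtype {ph.loc[bad_sub, 'subtype'].iloc[0]!r}"
            )
        ctrl_with_subtype = (ph["status"] == "control") & (ph["subtype"] != "none")
        if ctrl_with_subtype.any():
            sid = ph.index[ctrl_with_subtype][0]
            raise CohortValidationError(
                f"control {sid!r} has a stroke subtype; controls must have subtype 'none'"
            )
        case_without = (ph["status"] == "case") & (ph["subtype"] == "none")
        if case_without.any():
            sid = ph.index[case_without][0]
            raise CohortValidationError(f"case {sid!r} has subtype 'none'")
        unknown = [s for s in gt.columns if s not in self.panel.index]
        if unknown:
            raise CohortValidationError(
                f"genotype column(s) not in panel: {unknown[:5]}"
            )
        values = gt.to_numpy()
        ok = np.isin(values, (HOM_MAJOR, HET, HOM_MINOR, MISSING))
        if not ok.all():
            raise CohortValidationError("genotype matrix contains invalid codes")

    # -- basic summaries ----------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.phenotypes.index

    @property
    def snp_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    @property
    def n_samples(self) -> int:
        return len(self.phenotypes)

    @property
    def n_cases(self) -> int:
        return int((self.phenotypes["status"] == "case").sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotypes["status"] == "control").sum())

    def call_rate(self, snp_id: str) -> float:
        """Fraction of samples with a non-missing call at ``snp_id``."""
        col = self.genotypes[snp_id].to_numpy()
        return float((col != MISSING).mean())

    def counts_by_subtype(self) -> pd.Series:
        """Case counts per TOAST subtype plus the control count."""
        ph = self.phenotypes
        out = ph.loc[ph["status"] == "case", "subtype"].value_counts().sort_index()
        out.loc["control"] = self.n_controls
        return out

    # -- masks ---------------------------------------------------------
    def case_mask(self, subtype: str | None = None, af_only: bool = False) -> np.ndarray:
        """Boolean mask over samples selecting cases (optionally one subtype
        and optionally only those with atrial fibrillation)."""
        ph = self.phenotypes
        mask = (ph["status"] == "case").to_numpy()
        if subtype is not None:
            mask &= (ph["subtype"] == subtype).to_numpy()
        if af_only:
            mask &= (ph["atrial_fibrillation"] == "yes").to_numpy()
        return mask

    @property
    def control_mask(self) -> np.ndarray:
        return (self.phenotypes["status"] == "control").to_numpy()

    def alleles(self, snp_id: str) -> tuple[str, str] | None:
        """(major, minor) allele pair for a SNP, or None when unknown."""
        if "major_allele" not in self.panel.columns:
            return None
        row = self.panel.loc[snp_id]
        major, minor = row.get("major_allele"), row.get("minor_allele")
        if not isinstance(major, str) or not isinstance(minor, str) or major == "N":
            return None
        return major, minor

    def equals(self, other: "Cohort") -> bool:
        """Structural equality of phenotypes, genotypes and panel."""
        return (
            self.phenotypes.equals(other.phenotypes)
            and self.genotypes.equals(other.genotypes)
            and self.panel[["gene", "chromosome"]].equals(other.panel[["gene", "chromosome"]])
        )


def genotype_class_label(codes: frozenset[int] | set[int],
                         alleles: tuple[str, str] | None) -> str:
    """Render a set of genotype codes as the field's class notation.

    With known (major, minor) alleles, ``{HET, HOM_MINOR}`` for rs1205
    (C/T) renders as ``"CT/TT"``; ``{HOM_MINOR}`` for rs1800779 (A/G) as
    ``"GG"``.  Heterozygote first, then homozygotes.  Without alleles a
    symbolic fallback (``"het/hom_minor"``) is used.
    """
    order = {HET: 0, HOM_MINOR: 1, HOM_MAJOR: 2}
    codes = sorted(codes, key=lambda c: order[c])
    parts = []
    for c in codes:
        if alleles is None:
            parts.append({HOM_MAJOR: "hom_major", HET: "het", HOM_MINOR: "hom_minor"}[c])
        else:
            major, minor = alleles
            parts.append({HOM_MAJOR: major + major,
                          HET: major + minor,
                          HOM_MINOR: minor + minor}[c])
    return "/".join(parts)
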