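"""Per-SNP case-control association under dominant/recessive encodings.

Each SNP is collapsed to a binary exposure under a genetic model
(dominant: carrier of the minor allele; recessive: homozygous minor),
yielding a 2x2 exposure-by-status table.  Effect size is the
cross-product odds ratio with a Wald (log-normal) 95% CI; significance
is the uncorrected Pearson chi-square, or the two-sided Fisher exact
test when any expected cell is below 5.  A scan evaluates both
encodings for every SNP and either reports both ("all" policy) or the
encoding with the smaller chi-square p ("best-of-two", the default).

Published tables report genotype-class percentages rather than counts;
:func:`reconstruct_counts` rebuilds integer counts from a printed
percentage and a group size, and :func:`association_from_counts` turns
a rebuilt table into a full result, so worked examples from the
literature can be pushed through the same code path as raw cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import (
    GENOTYPE_CODES,
    HET,
    HOM_MAJOR,
    HOM_MINOR,
    MISSING,
    Cohort,
    genotype_class_label,
)

Z_ALPHA = {0.05: stats.norm.ppf(0.975)}


class DegenerateTableError(ValueError):
    """A 2x2 table with an empty margin (no exposed/unexposed or no
    genotyped subjects in one arm) where the statistic is undefined."""


class UndefinedOddsRatioError(ValueError):
    """Odds ratio undefined: two zero cells share a row or column."""


@dataclass(frozen=True)
class GeneticModel:
    """Binary genotype encoding.

    kind="dominant" counts carriers of the minor allele (het + hom
    minor) as exposed; kind="recessive" counts only minor-allele
    homozygotes; kind="custom" takes any explicit exposed class.  The
    exposed class and its complement always partition the three
    non-missing genotype classes.
    """

    kind: str
    exposed: frozenset | None = None

    def __post_init__(self):
        if self.kind not in ("dominant", "recessive", "custom"):
            raise ValueError(f"unknown genetic model {self.kind!r}")
        if self.kind == "custom":
            exp = frozenset(self.exposed or ())
            if not exp or not exp < frozenset(GENOTYPE_CODES):
                raise ValueError(
                    "custom model needs a non-empty proper subset of the genotype classes"
                )
            object.__setattr__(self, "exposed", exp)

    @property
    def exposed_codes(self) -> frozenset[int]:
        if self.kind == "custom":
            return self.exposed
        return frozenset({HET, HOM_MINOR}) if self.kind == "dominant" else frozenset({HOM_MINOR})

    @property
    def complement_codes(self) -> frozenset[int]:
        return frozenset(GENOTYPE_CODES) - self.exposed_codes


DOMINANT = GeneticModel("dominant")
RECESSIVE = GeneticModel("recessive")


@dataclass(frozen=True)
class CountTable2x2:
    """Exposure-by-status counts: a/b exposed/unexposed cases,
    c/d exposed/unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def min_expected(self) -> float:
        """Smallest expected cell count under independence."""
        arr = self.as_array()
        rows = arr.sum(axis=1, keepdims=True)
        cols = arr.sum(axis=0, keepdims=True)
        if self.n == 0:
            return 0.0
        return float((rows @ cols).min() / self.n)


@dataclass(frozen=True)
class OddsRatio:
    or_point: float
    ci_low: float
    ci_high: float
    haldane: bool = False  # 0.5 added to every cell because of a zero cell

    def __iter__(self):
        return iter((self.or_point, self.ci_low, self.ci_high))


@dataclass
class AssociationResult:
    """One SNP x contrast x encoding association."""

    snp_id: str
    contrast: str
    model: GeneticModel
    table: CountTable2x2 | None
    or_point: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    chi2: float = math.nan
    p_chi2: float = math.nan
    p_fisher: float = math.nan
    test_used: str = "chi-square"
    p_bonferroni: float = math.nan
    gene: str = ""
    alleles: tuple[str, str] | None = None
    haldane: bool = False
    degenerate: bool = False
    note: str = ""

    @property
    def p(self) -> float:
        """p-value of the test actually used."""
        return self.p_fisher if self.test_used == "fisher" else self.p_chi2

    @property
    def exposed_label(self) -> str:
        return genotype_class_label(self.model.exposed_codes, self.alleles)

    @property
    def complement_label(self) -> str:
        return genotype_class_label(self.model.complement_codes, self.alleles)


def reconstruct_counts(percent: float, n: int) -> int:
    """Integer count from a printed percentage and a group size.

    Rounds ``percent/100 * n`` to the nearest integer, ties away from
    zero — e.g. 22.4% of 374 -> 84.
    """
    if not 0 <= percent <= 100:
        raise ValueError(f"percent must be in [0, 100], got {percent}")
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    return int(math.floor(percent * n / 100 + 0.5))


def build_contingency(
    cohort: Cohort,
    snp_id: str,
    model: GeneticModel,
    contrast: str = "cardioembolic",
    af_only: bool = False,
) -> CountTable2x2:
    """2x2 exposure table for one SNP: cases of ``contrast`` subtype
    (optionally restricted to atrial-fibrillation cases) versus the full
    control arm.  Missing genotypes are excluded, never imputed.
    """
    if snp_id not in cohort.genotypes.columns:
        raise KeyError(f"SNP {snp_id!r} not in panel")
    codes = cohort.genotypes[snp_id].to_numpy()
    called = codes != MISSING
    cases = cohort.case_mask(subtype=contrast, af_only=af_only) & called
    controls = cohort.control_mask & called
    if cases.sum() == 0 or controls.sum() == 0:
        raise DegenerateTableError(
            f"{snp_id}: no genotyped {'cases' if cases.sum() == 0 else 'controls'} "
            f"for contrast {contrast!r}"
        )
    exposed = np.isin(codes, list(model.exposed_codes))
    a = int((cases & exposed).sum())
    b = int(cases.sum() - a)
    c = int((controls & exposed).sum())
    d = int(controls.sum() - c)
    return CountTable2x2(a, b, c, d)


def odds_ratio_ci(table: CountTable2x2, alpha: float = 0.05) -> OddsRatio:
    """Cross-product odds ratio with Wald CI on the log scale.

    A single zero cell triggers the Haldane-Anscombe correction (0.5
    added to every cell, flagged on the result); two zero cells in the
    same row or column leave the OR undefined.
    """
    a, b, c, d = table.cells
    zero_pairs = [(a, b), (c, d), (a, c), (b, d)]
    if any(x == 0 and y == 0 for x, y in zero_pairs):
        raise UndefinedOddsRatioError(f"odds ratio undefined for table {table.cells}")
    haldane = 0 in table.cells
    if haldane:
        a, b, c, d = (x + 0.5 for x in table.cells)
    or_point = (a * d) / (b * c)
    z = Z_ALPHA.get(alpha, stats.norm.ppf(1 - alpha / 2))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_point)
    return OddsRatio(
        or_point=or_point,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        haldane=haldane,
    )


def pearson_chi_square(table: CountTable2x2) -> tuple[float, float]:
    """Classical Pearson chi-square on the 2x2, df=1, no continuity
    correction."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError(f"zero margin in table {table.cells}")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), float(p)


def fisher_exact(table: CountTable2x2) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of
    all fixed-margin tables as or less probable than the observed one."""
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return float(p)


def association_from_counts(
    snp_id: str,
    model: GeneticModel,
    table: CountTable2x2,
    contrast: str = "cardioembolic",
    gene: str = "",
    alleles: tuple[str, str] | None = None,
) -> AssociationResult:
    """Full association result (OR, CI, chi-square, Fisher) from an
    explicit 2x2 table, e.g. one rebuilt from published percentages."""
    res = AssociationResult(
        snp_id=snp_id, contrast=contrast, model=model, table=table,
        gene=gene, alleles=alleles,
    )
    try:
        orr = odds_ratio_ci(table)
        res.or_point, res.ci_low, res.ci_high = orr
        res.haldane = orr.haldane
    except UndefinedOddsRatioError:
        res.note = "odds ratio undefined"
    try:
        res.chi2, res.p_chi2 = pearson_chi_square(table)
    except DegenerateTableError:
        res.degenerate = True
        res.note = (res.note + "; " if res.note else "") + "zero margin"
    res.p_fisher = fisher_exact(table)
    res.test_used = "fisher" if table.min_expected() < 5 else "chi-square"
    return res


def _selection_p(res: AssociationResult) -> float:
    """p used to pick the better of the two encodings: chi-square when
    defined, Fisher as fallback for degenerate margins."""
    if not math.isnan(res.p_chi2):
        return res.p_chi2
    if not math.isnan(res.p_fisher):
        return res.p_fisher
    return math.inf


def scan_codes(
    codes,
    outcome,
    policy: str = "best-of-two",
    contrast: str = "case",
    panel=None,
) -> list[AssociationResult]:
    """Dominant+recessive scan of a coded genotype matrix against a
    binary outcome.

    ``codes`` is a subject x SNP DataFrame of genotype codes (0/1/2,
    -1 missing); ``outcome`` a boolean/0-1 case vector.  Both encodings
    are always computed; ``policy="best-of-two"`` reports, per SNP, the
    one with the smaller chi-square p, ``policy="all"`` both.
    Bonferroni columns multiply the used p by the number of SNPs
    scanned (capped at 1).  Degenerate tables become flagged rows, not
    exceptions.  Results are sorted by p.
    """
    import pandas as pd

    if policy not in ("best-of-two", "all"):
        raise ValueError(f"unknown policy {policy!r}")
    if not isinstance(codes, pd.DataFrame):
        codes = pd.DataFrame(np.asarray(codes))
    y = np.asarray(outcome).astype(bool)
    rows: list[AssociationResult] = []
    for snp_id in codes.columns:
        col = codes[snp_id].to_numpy()
        called = col != MISSING
        gene, alleles = "", None
        if panel is not None and snp_id in panel.index:
            meta = panel.loc[snp_id]
            gene = str(meta.get("gene", ""))
            maj, mnr = meta.get("major_allele"), meta.get("minor_allele")
            if isinstance(maj, str) and isinstance(mnr, str) and maj != "N":
                alleles = (maj, mnr)
        per_model = []
        n_case = int((called & y).sum())
        n_ctrl = int((called & ~y).sum())
        for model in (DOMINANT, RECESSIVE):
            if n_case == 0 or n_ctrl == 0:
                per_model.append(
                    AssociationResult(
                        snp_id=str(snp_id), contrast=contrast, model=model,
                        table=None, gene=gene, alleles=alleles,
                        degenerate=True, note="no genotyped subjects in one arm",
                    )
                )
                continue
            exposed = np.isin(col, list(model.exposed_codes))
            a = int((exposed & y & called).sum())
            c = int((exposed & ~y & called).sum())
            table = CountTable2x2(a, n_case - a, c, n_ctrl - c)
            per_model.append(
                association_from_counts(
                    str(snp_id), model, table, contrast, gene=gene, alleles=alleles
                )
            )
        if policy == "all":
            rows.extend(per_model)
        else:
            rows.append(min(per_model, key=_selection_p))
    n_tests = codes.shape[1]
    for r in rows:
        if r.table is not None and not math.isnan(r.p):
            r.p_bonferroni = min(1.0, r.p * n_tests)
    rows.sort(
        key=lambda r: (r.table is None or math.isnan(r.p),
                       r.p if r.table is not None and not math.isnan(r.p) else math.inf)
    )
    return rows


def association_scan(
    cohort: Cohort,
    contrasts: list[str] | None = None,
    policy: str = "best-of-two",
    af_only: bool = False,
) -> list[AssociationResult]:
    """Scan every panel SNP against every case-subtype contrast.

    Cases are restricted to each contrast's subtype (optionally the
    atrial-fibrillation subset); controls are the full control arm in
    every contrast.  See :func:`scan_codes` for the per-contrast rules.
    """
    if contrasts is None:
        ph = cohort.phenotypes
        contrasts = sorted(ph.loc[ph["status"] == "case", "subtype"].unique())
    out: list[AssociationResult] = []
    for contrast in contrasts:
        mask = cohort.case_mask(subtype=contrast, af_only=af_only) | cohort.control_mask
        out.extend(
            scan_codes(
                cohort.genotypes.loc[mask],
                cohort.case_mask(subtype=contrast, af_only=af_only)[mask],
                policy=policy,
                contrast=contrast,
                panel=cohort.panel,
            )
        )
    return out


def results_to_frame(results: list[AssociationResult]):
    """Flatten results to the report table layout."""
    import pandas as pd

    rows = []
    for r in results:
        cells = r.table.cells if r.table is not None else (np.nan,) * 4
        rows.append(
            {
                "snp_id": r.snp_id,
                "gene": r.gene,
                "contrast": r.contrast,
                "model": r.model.kind,
                "exposed": r.exposed_label,
                "a": cells[0], "b": cells[1], "c": cells[2], "d": cells[3],
                "or": r.or_point,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "chi2": r.chi2,
                "p_chi2": r.p_chi2,
                "p_fisher": r.p_fisher,
                "test_used": r.test_used,
                "p_bonferroni": r.p_bonferroni,
                "haldane": r.haldane,
                "degenerate": r.degenerate,
                "note": r.note,
            }
        )
    cols = ["snp_id", "gene", "contrast", "model", "exposed", "a", "b", "c", "d",
            "or", "ci_low", "ci_high", "chi2", "p_chi2", "p_fisher", "test_used",
            "p_bonferroni", "haldane", "degenerate", "note"]
    return pd.DataFrame(rows, columns=cols)
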