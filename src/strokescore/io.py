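"""Reading and writing cohorts and pipeline reports.

Table dialects (all tab-separated, plain text):

* genotype TSV — header ``sample_id<TAB>rs...``; cells are unordered
  two-letter allele pairs ("AG" == "GA") or the missing code ("NN" by
  default).
* phenotype TSV — header ``sample_id status subtype sex hypertension
  diabetes smoker dyslipidemia atrial_fibrillation``.
* panel TSV — header ``snp_id gene chromosome`` (optionally
  ``major_allele minor_allele``).

A minimal VCF v4.2 reader (GT subfield only, biallelic records) is
provided for genotype input; reference/alternate alleles are mapped to
major/minor by observed frequency, ties keeping the reference as
major.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .chaid import Stratification
from .cohort import (
    HET,
    HOM_MAJOR,
    HOM_MINOR,
    MISSING,
    PHENOTYPE_COLUMNS,
    Cohort,
    CohortValidationError,
)
from .score import ScoreModel

logger = logging.getLogger("strokescore")

VALID_BASES = set("ACGT")


class GenotypeParseError(ValueError):
    """A genotype token is not two bases or the missing code."""


def packaged_panel_path() -> Path:
    """Path to the shipped 68-SNP inflammatory-gene panel table."""
    return Path(resources.files("strokescore").joinpath("data/panel_table1.tsv"))


def _read_phenotypes(phenotype_path) -> pd.DataFrame:
    ph = pd.read_csv(phenotype_path, sep="\t", dtype=str)
    if "sample_id" not in ph.columns:
        raise CohortValidationError(f"{phenotype_path}: missing sample_id column")
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in ph.columns]
    if missing_cols:
        raise CohortValidationError(f"{phenotype_path}: missing columns {missing_cols}")
    if ph["sample_id"].duplicated().any():
        dup = ph.loc[ph["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise CohortValidationError(f"{phenotype_path}: duplicate sample id {dup!r}")
    return ph.set_index("sample_id")[list(PHENOTYPE_COLUMNS)]


def _read_panel(panel_path) -> pd.DataFrame:
    panel = pd.read_csv(panel_path, sep="\t", dtype=str)
    if "snp_id" not in panel.columns:
        raise CohortValidationError(f"{panel_path}: missing snp_id column")
    return panel.set_index("snp_id")


def read_cohort(
    genotype_path,
    phenotype_path,
    panel_path,
    name: str = "cohort",
    missing_code: str = "NN",
) -> Cohort:
    """Read and validate a cohort from the three TSV tables.

    The two sample tables must agree exactly on sample ids.  Major and
    minor alleles are assigned per SNP by allele frequency — among
    controls when at least 50 controls are present, otherwise across
    all samples — with alphabetical tie-break (first allele = major).
    Missing genotypes are preserved, never dropped.
    """
    phenotypes = _read_phenotypes(phenotype_path)
    panel = _read_panel(panel_path)

    gt_raw = pd.read_csv(genotype_path, sep="\t", dtype=str)
    if "sample_id" not in gt_raw.columns:
        raise CohortValidationError(f"{genotype_path}: missing sample_id column")
    if gt_raw["sample_id"].duplicated().any():
        dup = gt_raw.loc[gt_raw["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise CohortValidationError(f"{genotype_path}: duplicate sample id {dup!r}")
    gt_raw = gt_raw.set_index("sample_id")

    unknown_in_geno = set(gt_raw.index) - set(phenotypes.index)
    unknown_in_pheno = set(phenotypes.index) - set(gt_raw.index)
    if unknown_in_geno or unknown_in_pheno:
        off = sorted(unknown_in_geno | unknown_in_pheno)
        raise CohortValidationError(
            f"sample ids present in only one table: {off[:5]}"
        )
    gt_raw = gt_raw.loc[phenotypes.index]

    snps = list(gt_raw.columns)
    absent = [s for s in snps if s not in panel.index]
    if absent:
        raise CohortValidationError(f"SNP column(s) absent from panel: {absent[:5]}")

    # token -> allele pair; validate with line numbers (header = line 1)
    pairs = np.empty((len(gt_raw), len(snps)), dtype=object)
    raw = gt_raw.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            tok = raw[i, j]
            tok = "" if tok is None or (isinstance(tok, float) and np.isnan(tok)) else str(tok).strip()
            if tok == missing_code:
                pairs[i, j] = None
                continue
            if len(tok) != 2 or any(b not in VALID_BASES for b in tok.upper()):
                raise GenotypeParseError(
                    f"{genotype_path}: line {i + 2}, SNP {snps[j]}: "
                    f"malformed genotype token {tok!r}"
                )
            pairs[i, j] = tok.upper()

    use_controls = (phenotypes["status"] == "control").sum() >= 50
    freq_mask = (phenotypes["status"] == "control").to_numpy() if use_controls \
        else np.ones(len(phenotypes), dtype=bool)

    codes = np.full(pairs.shape, MISSING, dtype=np.int8)
    major_allele, minor_allele = {}, {}
    for j, snp in enumerate(snps):
        col = pairs[:, j]
        counts: dict[str, int] = {}
        for i in np.flatnonzero(freq_mask):
            if col[i] is not None:
                for b in col[i]:
                    counts[b] = counts.get(b, 0) + 1
        if not counts:  # frequency arm all missing: fall back to all samples
            for p in col:
                if p is not None:
                    for b in p:
                        counts[b] = counts.get(b, 0) + 1
        alleles = sorted(counts)
        if len(alleles) > 2:
            raise CohortValidationError(
                f"SNP {snp}: more than two alleles observed ({alleles})"
            )
        if not alleles:
            major_allele[snp], minor_allele[snp] = "N", "N"
            continue
        if len(alleles) == 1:
            major, minor = alleles[0], alleles[0]
        else:
            # descending count, alphabetical tie-break -> major first
            major, minor = sorted(alleles, key=lambda b: (-counts[b], b))
        major_allele[snp], minor_allele[snp] = major, minor
        for i, p in enumerate(col):
            if p is None:
                continue
            n_minor = sum(1 for b in p if b == minor) if minor != major else 0
            if any(b not in (major, minor) for b in p):
                raise CohortValidationError(
                    f"SNP {snp}: allele outside inferred pair in token {p!r}"
                )
            codes[i, j] = (HOM_MAJOR, HET, HOM_MINOR)[n_minor]

    panel_used = panel.loc[snps].copy()
    panel_used["major_allele"] = [major_allele[s] for s in snps]
    panel_used["minor_allele"] = [minor_allele[s] for s in snps]
    genotypes = pd.DataFrame(codes, index=phenotypes.index, columns=snps)
    return Cohort(name=name, phenotypes=phenotypes, genotypes=genotypes, panel=panel_used)


def write_cohort(cohort: Cohort, out_dir, missing_code: str = "NN") -> dict[str, Path]:
    """Write the three TSV tables; inverse of :func:`read_cohort`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out_dir / "genotypes.tsv",
        "phenotypes": out_dir / "phenotypes.tsv",
        "panel": out_dir / "panel.tsv",
    }
    ph = cohort.phenotypes.reset_index()
    ph.to_csv(paths["phenotypes"], sep="\t", index=False)

    tokens = pd.DataFrame(index=cohort.sample_ids, columns=cohort.snp_ids, dtype=object)
    for snp in cohort.snp_ids:
        alleles = cohort.alleles(snp)
        major, minor = alleles if alleles else ("N", "N")
        mapping = {
            HOM_MAJOR: major + major,
            HET: "".join(sorted(major + minor)),
            HOM_MINOR: minor + minor,
            MISSING: missing_code,
        }
        tokens[snp] = cohort.genotypes[snp].map(mapping)
    tokens.index.name = "sample_id"
    tokens.reset_index().to_csv(paths["genotypes"], sep="\t", index=False)

    panel = cohort.panel.copy()
    panel.index.name = "snp_id"
    panel.reset_index().to_csv(paths["panel"], sep="\t", index=False)
    return paths


def read_vcf_subset(vcf_path, phenotype_path, name: str = "cohort") -> Cohort:
    """Cohort from a minimal VCF v4.2 (GT only) plus a phenotype TSV.

    Biallelic SNP records only: multiallelic records are skipped with a
    logged warning and counted in ``cohort.meta["skipped_multiallelic"]``.
    REF/ALT are mapped to major/minor by observed allele frequency in
    the file; on a tie the reference allele is the major one.
    """
    import pysam

    phenotypes = _read_phenotypes(phenotype_path)
    vcf = pysam.VariantFile(str(vcf_path))
    samples = list(vcf.header.samples)
    if set(samples) != set(phenotypes.index):
        off = sorted(set(samples).symmetric_difference(phenotypes.index))
        raise CohortValidationError(
            f"VCF and phenotype samples disagree: {off[:5]}"
        )

    snp_ids, panel_rows, code_cols = [], [], []
    skipped = 0
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            skipped += 1
            logger.warning("skipping multiallelic/invalid record %s:%s", rec.chrom, rec.pos)
            continue
        if "GT" not in rec.format:
            raise CohortValidationError(
                f"record {rec.chrom}:{rec.pos} lacks the GT format field"
            )
        ref, alt = rec.ref, rec.alts[0]
        col = np.full(len(samples), MISSING, dtype=np.int8)
        for k, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or None in gt:
                continue
            col[k] = int(gt[0] != 0) + int(gt[1] != 0)  # alt-allele dosage
        called = col != MISSING
        alt_freq = float(col[called].sum()) / (2 * called.sum()) if called.any() else 0.0
        if alt_freq > 0.5:  # alt is the major allele: flip coding
            col[called] = 2 - col[called]
            major, minor = alt, ref
        else:
            major, minor = ref, alt
        snp_id = rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}"
        snp_ids.append(snp_id)
        panel_rows.append({"gene": "", "chromosome": str(rec.chrom),
                           "major_allele": major, "minor_allele": minor})
        code_cols.append(col)

    genotypes = pd.DataFrame(
        np.column_stack(code_cols) if code_cols else np.empty((len(samples), 0), dtype=np.int8),
        index=pd.Index(samples, name="sample_id"),
        columns=snp_ids,
    ).loc[phenotypes.index]
    panel = pd.DataFrame(panel_rows, index=pd.Index(snp_ids, name="snp_id"))
    return Cohort(
        name=name, phenotypes=phenotypes, genotypes=genotypes, panel=panel,
        meta={"skipped_multiallelic": skipped},
    )


def config_hash(config: dict) -> str:
    """Deterministic short hash of a run configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_report(
    results,
    score: ScoreModel | None,
    strat: Stratification | None,
    out_dir,
    config: dict | None = None,
    extra: dict | None = None,
) -> dict[str, Path]:
    """Write the report bundle: association TSV, score-model JSON,
    stratification JSON and a run log.

    Field ordering is deterministic; re-running with identical inputs
    reproduces every file byte for byte except the log's timestamp
    line.
    """
    from .association import results_to_frame

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["results"] = out_dir / "association_results.tsv"
    results_to_frame(list(results)).to_csv(paths["results"], sep="\t", index=False)

    chash = config_hash(config or {})
    if score is not None:
        paths["score_model"] = out_dir / "score_model.json"
        payload = score.to_dict()
        payload["config_hash"] = chash
        paths["score_model"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    if strat is not None:
        paths["stratification"] = out_dir / "stratification.json"
        payload = strat.to_dict()
        payload["config_hash"] = chash
        paths["stratification"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    if extra:
        paths["summary"] = out_dir / "summary.json"
        payload = dict(extra)
        payload["config_hash"] = chash
        paths["summary"].write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")

    paths["log"] = out_dir / "run.log"
    lines = [
        f"# generated: {datetime.now(timezone.utc).isoformat()}",
        f"config_hash: {chash}",
    ]
    for key, value in sorted((config or {}).items()):
        lines.append(f"config.{key}: {value}")
    lines.append(f"n_results: {len(list(results))}")
    if score is not None:
        lines.append(f"score_formula: {score.formula()}")
        lines.append(f"max_score: {score.max_score}")
    if strat is not None:
        lines.append(f"n_risk_groups: {len(strat.groups)}")
        lines.append(f"adjusted_p: {strat.adjusted_p}")
    paths["log"].write_text("\n".join(lines) + "\n")
    return paths
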