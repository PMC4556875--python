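"""End-to-end pipeline: discovery scan -> score -> replication -> CHAID.

Stages, mirroring the study design:

1. per-SNP association scan on the discovery arm for the target stroke
   subtype (optionally restricted to atrial-fibrillation cases);
2. forward stepwise logistic gate over the significant SNPs;
3. OR-weighted score construction (optionally extended with binary
   clinical factors weighted by their univariate ORs);
4. scoring of both arms;
5. case-vs-control rank comparison of the score in each arm and a
   subtype-specificity table (every subtype's cases against the same
   controls);
6. CHAID stratification of the discovery scores into risk groups;
7. report bundle on disk.

Also houses the classical two-proportion sample-size utility.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from .association import CountTable2x2, odds_ratio_ci, pearson_chi_square
from .chaid import chaid_bin, summarize_groups
from .cohort import Cohort
from .estimators import GeneticRiskScorer
from .io import config_hash, read_cohort, write_report
from .score import (
    ScoreModel,
    ScoreTerm,
    _round_half_away,
    compare_score_distributions,
    score_subjects,
)
from .simulate import PRESETS, make_preset, simulate_cohort

#: the scoring level of each supported clinical factor
CLINICAL_RISK_LEVELS = {"sex": "male", "hypertension": "yes", "diabetes": "yes",
                        "smoker": "yes", "dyslipidemia": "yes",
                        "atrial_fibrillation": "yes"}


@dataclass
class RunConfig:
    """Configuration of one pipeline run (also the YAML schema)."""

    discovery: str | dict = "discovery_table3"  # preset name or path dict
    replication: str | dict | None = "replication_table3"
    target_subtype: str = "cardioembolic"
    model_policy: str = "best-of-two"
    p_threshold: float = 0.05
    p_enter: float = 0.05
    merge_alpha: float = 0.05
    min_group: int = 10
    missing_policy: str = "exclude"
    include_clinical: list[str] = field(default_factory=list)
    cases_filter: str | None = None  # e.g. "atrial_fibrillation=yes"
    simulate_scale: int = 1
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def _load_arm(source, name: str, scale: int, seed: int) -> Cohort:
    if isinstance(source, str):
        if source not in PRESETS:
            raise ValueError(f"{name}: unknown preset {source!r}")
        return simulate_cohort(make_preset(source, scale=scale), seed=seed)
    for key in ("genotypes", "phenotypes", "panel"):
        if key not in source:
            raise ValueError(f"{name}: cohort paths need key {key!r}")
        if not Path(source[key]).exists():
            raise FileNotFoundError(f"{name}: {source[key]} does not exist")
    return read_cohort(source["genotypes"], source["phenotypes"], source["panel"], name=name)


def clinical_terms(cohort: Cohort, factors: list[str], target_subtype: str,
                   alpha: float = 0.05) -> list[ScoreTerm]:
    """Univariate-OR-weighted terms for binary clinical factors,
    following the same risk-direction and rounding rules as SNP terms.
    Non-significant factors are dropped."""
    terms = []
    cases = cohort.case_mask(subtype=target_subtype)
    controls = cohort.control_mask
    for factor in factors:
        if factor not in CLINICAL_RISK_LEVELS:
            raise ValueError(f"unsupported clinical factor {factor!r}")
        level = CLINICAL_RISK_LEVELS[factor]
        col = cohort.phenotypes[factor].to_numpy()
        known = col != "missing"
        expo = col == level
        a = int((cases & known & expo).sum()); b = int((cases & known & ~expo).sum())
        c = int((controls & known & expo).sum()); d = int((controls & known & ~expo).sum())
        table = CountTable2x2(a, b, c, d)
        _, p = pearson_chi_square(table)
        if not p < alpha:
            continue
        orr = odds_ratio_ci(table).or_point
        if orr == 1.0:
            continue
        if orr > 1:
            weight, lvl = orr, level
        else:
            weight = 1.0 / orr
            lvl = {"male": "female"}.get(level, "no") if factor == "sex" else "no"
        terms.append(ScoreTerm(source=factor, weight=_round_half_away(weight, 1),
                               kind="clinical", level=lvl, label=lvl))
    return terms


@dataclass
class RunReport:
    config: RunConfig
    status: str
    scan_results: list
    model: ScoreModel | None
    stratification: object | None
    comparisons: dict
    specificity: list[dict]
    paths: dict | None = None


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full pipeline under one configuration and seed."""
    af_only = config.cases_filter == "atrial_fibrillation=yes"
    if config.cases_filter not in (None, "", "atrial_fibrillation=yes"):
        raise ValueError(f"unsupported cases_filter {config.cases_filter!r}")

    discovery = _load_arm(config.discovery, "discovery", config.simulate_scale, config.seed)
    replication = None
    if config.replication:
        replication = _load_arm(config.replication, "replication",
                                config.simulate_scale, config.seed + 1)

    # 1-3: scan + stepwise gate + score model, via the estimator
    target_cases = discovery.case_mask(subtype=config.target_subtype, af_only=af_only)
    sub = target_cases | discovery.control_mask
    scorer = GeneticRiskScorer(
        p_threshold=config.p_threshold, p_enter=config.p_enter,
        missing_policy=config.missing_policy, model_policy=config.model_policy,
    )
    scorer.fit(discovery.genotypes.loc[sub], target_cases[sub], panel=discovery.panel)
    scan_rows = scorer.scan_results_
    for r in scan_rows:
        r.contrast = config.target_subtype

    model = scorer.model_
    if config.include_clinical and model.terms:
        extra = clinical_terms(discovery, config.include_clinical,
                               config.target_subtype, config.p_threshold)
        terms = sorted(model.terms + extra, key=lambda t: (-t.weight, t.source))
        model = ScoreModel(terms=terms, kind="clinical-genetic")

    comparisons: dict[str, dict] = {}
    specificity: list[dict] = []
    strat = None
    if not model.terms:
        status = "no score constructed"
    else:
        status = "ok"
        # 4-5: score each arm, compare cases vs controls per subtype
        for arm_name, arm in (("discovery", discovery), ("replication", replication)):
            if arm is None:
                continue
            scored = score_subjects(arm, model, missing_policy=config.missing_policy)
            svals = scored["score"].to_numpy()
            ctrl = svals[arm.control_mask & ~np.isnan(svals)]
            subtypes = sorted(
                arm.phenotypes.loc[arm.phenotypes["status"] == "case", "subtype"].unique()
            )
            for subtype in subtypes:
                mask = arm.case_mask(subtype=subtype, af_only=af_only and subtype == config.target_subtype)
                cas = svals[mask & ~np.isnan(svals)]
                if cas.size == 0 or ctrl.size == 0:
                    continue
                cmp_res = compare_score_distributions([cas, ctrl])
                row = {
                    "arm": arm_name, "contrast": subtype,
                    "n_cases": int(cas.size), "n_controls": int(ctrl.size),
                    "mean_cases": cmp_res.means_rounded[0],
                    "mean_controls": cmp_res.means_rounded[1],
                    "statistic": cmp_res.statistic, "p": cmp_res.p,
                }
                specificity.append(row)
                if subtype == config.target_subtype:
                    comparisons[arm_name] = row
            if arm_name == "discovery":
                # 6: CHAID on target cases + controls
                mask = (arm.case_mask(subtype=config.target_subtype, af_only=af_only)
                        | arm.control_mask) & ~np.isnan(svals)
                strat = chaid_bin(
                    svals[mask],
                    (arm.phenotypes["status"].to_numpy() == "case")[mask],
                    merge_alpha=config.merge_alpha, min_group=config.min_group,
                )

    report = RunReport(
        config=config, status=status, scan_results=scan_rows, model=model,
        stratification=strat, comparisons=comparisons, specificity=specificity,
    )
    if config.out_dir:
        extra = {
            "status": status,
            "seed": config.seed,
            "comparisons": comparisons,
            "specificity": specificity,
        }
        if strat is not None:
            extra["risk_groups"] = summarize_groups(strat).to_dict(orient="records")
        report.paths = write_report(
            scan_rows, model if model.terms else None, strat,
            config.out_dir, config=config.to_dict(), extra=extra,
        )
    return report


def sample_size_two_proportions(
    p1: float, p2: float, power: float = 0.8, alpha: float = 0.05
) -> int:
    """Per-group n to detect p1 vs p2 with a two-sided normal-
    approximation test:

        n = (z_{1-a/2} sqrt(2 p̄ q̄) + z_{1-b} sqrt(p1 q1 + p2 q2))^2
            / (p1 - p2)^2,  rounded up.
    """
    if not (0 < p2 < p1 < 1):
        raise ValueError("need 0 < p2 < p1 < 1")
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    pbar = (p1 + p2) / 2
    qbar = 1 - pbar
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    num = (z_a * math.sqrt(2 * pbar * qbar)
           + z_b * math.sqrt(p1 * (1 - p1) + p2 * (1 - p2))) ** 2
    return math.ceil(num / (p1 - p2) ** 2)
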