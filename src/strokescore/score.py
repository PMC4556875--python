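"""Odds-ratio-weighted genetic (and clinical-genetic) risk scores.

Each score term is an indicator for a risk-conferring configuration —
a genotype class for a SNP term, or the risk level of a binary clinical
factor — weighted by the univariate odds ratio rounded to one decimal.
Protective associations (OR < 1) are flipped: the complementary
genotype class scores, with weight 1/OR, so every weight is >= 1 and a
subject's score is the sum of the weights of the configurations they
carry.

Weights carry exactly one decimal, so every attainable score lies on a
0.1-point grid; scoring is done in integer tenths internally, which
makes the linearity identity  mean(subject scores) ==
sum(weight_k * empirical frequency_k)  hold exactly on complete
cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationResult
from .cohort import MISSING, Cohort


@dataclass(frozen=True)
class ScoreTerm:
    """One additive term: `weight` points when the subject carries the
    indicator configuration.

    kind="snp": ``classes`` is the set of scoring genotype codes and
    ``label`` their allele rendering (e.g. "GG", "CT/TT").
    kind="clinical": ``level`` is the scoring value of the phenotype
    column named by ``source`` (e.g. hypertension "yes", sex "male").
    """

    source: str
    weight: float
    kind: str = "snp"
    classes: frozenset[int] | None = None
    label: str = ""
    level: str | None = None

    def __post_init__(self):
        if self.weight < 1.0:
            raise ValueError(
                f"term {self.source!r}: weight {self.weight} < 1; "
                "protective effects must be inverted before weighting"
            )
        if self.kind == "snp" and not self.classes:
            raise ValueError(f"SNP term {self.source!r} needs a genotype class set")

    @property
    def weight_tenths(self) -> int:
        return int(round(self.weight * 10))


@dataclass
class ScoreModel:
    """Ordered additive risk score; ``kind`` is "genetic" or
    "clinical-genetic"."""

    terms: list[ScoreTerm]
    kind: str = "genetic"

    @property
    def max_score(self) -> float:
        return sum(t.weight_tenths for t in self.terms) / 10.0

    def attainable_scores(self) -> list[float]:
        """All subset sums of the weights, sorted, with multiplicity
        collapsed."""
        vals = set()
        weights = [t.weight_tenths for t in self.terms]
        for k in range(len(weights) + 1):
            for comb in combinations(weights, k):
                vals.add(sum(comb))
        return [v / 10.0 for v in sorted(vals)]

    def formula(self) -> str:
        """Human-readable formula, terms ordered by source id (the
        convention used in print)."""
        parts = []
        for t in sorted(self.terms, key=lambda t: t.source):
            label = t.label or (t.level or "")
            parts.append(f"{t.weight:g}*{t.source}[{label}]")
        return " + ".join(parts)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "terms": [
                {
                    "source": t.source,
                    "kind": t.kind,
                    "indicator": t.label or (t.level or ""),
                    "weight": t.weight,
                }
                for t in self.terms
            ],
            "max_score": self.max_score,
            "formula": self.formula(),
        }


def _round_half_away(x: float, decimals: int = 1) -> float:
    f = 10 ** decimals
    return math.floor(abs(x) * f + 0.5) / f * (1 if x >= 0 else -1)


def term_from_association(res: AssociationResult, alpha: float = 0.05) -> ScoreTerm:
    """Risk-direction term from a univariate association result.

    OR > 1: the exposed genotype class scores with weight OR.
    OR < 1: the complementary class scores with weight 1/OR.
    Weights are rounded to one decimal, half away from zero.
    """
    if not (res.p < alpha):
        raise ValueError(
            f"{res.snp_id}: association not significant (p={res.p:.3g} >= {alpha})"
        )
    if math.isnan(res.or_point):
        raise ValueError(f"{res.snp_id}: no odds ratio available")
    if res.or_point == 1.0:
        raise ValueError(f"{res.snp_id}: OR exactly 1, no risk direction")
    if res.or_point > 1:
        classes = res.model.exposed_codes
        weight = res.or_point
        label = res.exposed_label
    else:
        classes = res.model.complement_codes
        weight = 1.0 / res.or_point
        label = res.complement_label
    return ScoreTerm(
        source=res.snp_id,
        weight=_round_half_away(weight, 1),
        kind="snp",
        classes=frozenset(classes),
        label=label,
    )


def build_score_model(
    results: list[AssociationResult],
    alpha: float = 0.05,
    kind: str = "genetic",
    extra_terms: list[ScoreTerm] | None = None,
) -> ScoreModel:
    """OR-weighted score from significant univariate associations.

    Terms are ordered by descending weight, then source id.  Clinical
    terms built elsewhere can be appended via ``extra_terms``.
    """
    terms = [term_from_association(r, alpha) for r in results]
    if extra_terms:
        terms = terms + list(extra_terms)
    terms.sort(key=lambda t: (-t.weight, t.source))
    return ScoreModel(terms=terms, kind=kind)


def _term_indicator(cohort: Cohort, term: ScoreTerm) -> np.ndarray:
    """Per-sample indicator (1/0) with NaN for missing data."""
    if term.kind == "snp":
        if term.source not in cohort.genotypes.columns:
            raise ValueError(f"score term references unknown SNP {term.source!r}")
        codes = cohort.genotypes[term.source].to_numpy()
        ind = np.isin(codes, list(term.classes)).astype(float)
        ind[codes == MISSING] = np.nan
        return ind
    if term.source not in cohort.phenotypes.columns:
        raise ValueError(f"score term references unknown factor {term.source!r}")
    col = cohort.phenotypes[term.source].to_numpy()
    ind = (col == term.level).astype(float)
    ind[col == "missing"] = np.nan
    return ind


def score_subjects(
    cohort: Cohort, model: ScoreModel, missing_policy: str = "exclude"
) -> pd.DataFrame:
    """Per-subject scores: DataFrame with columns ``score`` and
    ``complete`` indexed by sample id.

    missing_policy="exclude" (default): subjects missing any scored
    datum get ``score=NaN, complete=False``.  "zero": missing indicators
    count 0, ``complete=False`` still flags them.
    """
    if missing_policy not in ("exclude", "zero"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    n = cohort.n_samples
    tenths = np.zeros(n, dtype=np.int64)
    incomplete = np.zeros(n, dtype=bool)
    for term in model.terms:
        ind = _term_indicator(cohort, term)
        miss = np.isnan(ind)
        incomplete |= miss
        ind = np.nan_to_num(ind, nan=0.0)
        tenths += term.weight_tenths * ind.astype(np.int64)
    score = tenths / 10.0
    if missing_policy == "exclude":
        score = np.where(incomplete, np.nan, score)
    return pd.DataFrame(
        {"score": score, "complete": ~incomplete}, index=cohort.sample_ids
    )


def indicator_frequencies(cohort: Cohort, model: ScoreModel, mask=None) -> list[float]:
    """Empirical per-term indicator frequencies among complete subjects
    of the (optionally masked) cohort, term-aligned with the model."""
    inds = np.column_stack([_term_indicator(cohort, t) for t in model.terms])
    if mask is not None:
        inds = inds[np.asarray(mask)]
    complete = ~np.isnan(inds).any(axis=1)
    return [float(f) for f in inds[complete].mean(axis=0)]


def expected_score(class_frequencies, model: ScoreModel) -> float:
    """Expected score by linearity: sum of weight_k x frequency_k.

    Needs no independence assumption across terms; equals the mean of
    per-subject scores when the frequencies are the empirical indicator
    frequencies of a complete cohort.  ``class_frequencies`` is either
    term-aligned (sequence) or a mapping keyed by term source.
    """
    if hasattr(class_frequencies, "keys"):
        class_frequencies = [class_frequencies[t.source] for t in model.terms]
    freqs = np.asarray(list(class_frequencies), dtype=float)
    if len(freqs) != len(model.terms):
        raise ValueError(
            f"got {len(freqs)} frequencies for {len(model.terms)} terms"
        )
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    tenths = np.array([t.weight_tenths for t in model.terms], dtype=float)
    return float(np.dot(tenths, freqs) / 10.0)


@dataclass
class DistributionComparison:
    statistic: float
    p: float
    means: list[float]
    test: str

    @property
    def means_rounded(self) -> list[float]:
        return [_round_half_away(m, 1) for m in self.means]


def compare_score_distributions(
    scores_by_group: list, method: str = "asymptotic"
) -> DistributionComparison:
    """Rank test across k groups of scores.

    k=2: Mann-Whitney U (normal approximation with tie correction by
    default; ``method="exact"`` enumerates, valid without ties).
    k>2: Kruskal-Wallis H with tie correction.  Arithmetic group means
    are reported alongside, in the style of clinical tables.
    """
    groups = [np.asarray(g, dtype=float) for g in scores_by_group]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    means = [float(g.mean()) for g in groups]
    if len(groups) == 2:
        if method == "exact":
            res = stats.mannwhitneyu(groups[0], groups[1],
                                     alternative="two-sided", method="exact")
        else:
            res = stats.mannwhitneyu(groups[0], groups[1],
                                     alternative="two-sided",
                                     method="asymptotic", use_continuity=False)
        return DistributionComparison(float(res.statistic), float(res.pvalue),
                                      means, "mann-whitney")
    res = stats.kruskal(*groups)
    return DistributionComparison(float(res.statistic), float(res.pvalue),
                                  means, "kruskal-wallis")
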