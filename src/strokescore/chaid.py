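"""Ordinal CHAID binning of a discrete risk score into risk groups.

Kass-style chi-squared automatic interaction detection restricted to a
single ordinal predictor (the score): start with one category per
distinct score value, repeatedly test each adjacent pair of categories
on its 2x2 (pair x case/control) table with an uncorrected Pearson
chi-square, merge the pair with the largest p-value while that p
exceeds the merge threshold, and stop when every adjacent pair differs
significantly.  Undersized categories are folded into their most
similar neighbour before significance-driven merging.  The final
partition's significance is the overall chi-square p on the
r x 2 table times the ordinal Bonferroni multiplier C(c-1, r-1) for c
initial and r final categories, capped at 1.

Score values sit on a one-decimal grid (the weights carry one
decimal), so printed group bounds follow the midpoint convention: each
group's lower bound is the previous group's maximum plus 0.1, which is
how cut-offs such as "1.6" and "4.4" arise between attainable values
1.5/2.1 and 4.3/5.8.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import CountTable2x2, DegenerateTableError, pearson_chi_square


@dataclass
class RiskGroup:
    """One contiguous score interval (closed, printed bounds)."""

    lower: float
    upper: float
    n_subjects: int
    n_cases: int
    values: list[float] = field(default_factory=list)  # raw score values in group

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_subjects


@dataclass
class Stratification:
    groups: list[RiskGroup]
    merge_alpha: float
    adjusted_p: float
    n_initial_categories: int

    def to_dict(self) -> dict:
        return {
            "merge_alpha": self.merge_alpha,
            "adjusted_p": self.adjusted_p,
            "groups": [
                {
                    "lower": g.lower,
                    "upper": g.upper,
                    "n": g.n_subjects,
                    "n_cases": g.n_cases,
                    "case_fraction": g.case_fraction,
                }
                for g in self.groups
            ],
        }


def _pair_p(c1: tuple[int, int], c2: tuple[int, int]) -> float:
    """Chi-square p distinguishing two categories; degenerate tables
    (a shared empty outcome column) count as indistinguishable (p=1)."""
    try:
        _, p = pearson_chi_square(CountTable2x2(c1[0], c1[1], c2[0], c2[1]))
    except DegenerateTableError:
        return 1.0
    return p


class _Categories:
    """Ordered list of merged categories: per category the member score
    values and the (case, control) counts."""

    def __init__(self, values: np.ndarray, cases: np.ndarray, controls: np.ndarray):
        self.values = [[float(v)] for v in values]
        self.counts = [(int(a), int(b)) for a, b in zip(cases, controls)]

    def __len__(self) -> int:
        return len(self.counts)

    def merge(self, i: int) -> None:
        """Merge categories i and i+1."""
        self.values[i] = self.values[i] + self.values.pop(i + 1)
        a, b = self.counts[i]
        c, d = self.counts.pop(i + 1)
        self.counts[i] = (a + c, b + d)

    def adjacent_ps(self) -> list[float]:
        return [
            _pair_p(self.counts[i], self.counts[i + 1]) for i in range(len(self) - 1)
        ]

    def sizes(self) -> list[int]:
        return [a + b for a, b in self.counts]


def chaid_bin(
    scores,
    labels,
    merge_alpha: float = 0.05,
    min_group: int = 10,
) -> Stratification:
    """Bin scores against case/control labels by ordinal CHAID merging.

    Parameters
    ----------
    scores
        Per-subject score values (discrete; NaN entries are dropped).
    labels
        Parallel case indicator: 1/True for case, 0/False for control
        (or the strings "case"/"control").
    merge_alpha
        Adjacent pairs with chi-square p above this are merged.
    min_group
        Categories smaller than this are folded into their most
        similar neighbour before significance merging.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    if lab.dtype.kind in "UO":
        lab = lab == "case"
    lab = lab.astype(bool)
    keep = ~np.isnan(s)
    s, lab = s[keep], lab[keep]
    if s.size == 0:
        raise ValueError("no scored subjects")
    if not lab.any() or lab.all():
        raise ValueError("need both cases and controls")

    values, inv = np.unique(np.round(s, 6), return_inverse=True)
    cases = np.bincount(inv, weights=lab).astype(int)
    controls = np.bincount(inv, weights=~lab).astype(int)
    c_initial = len(values)

    if c_initial == 1:
        warnings.warn("single distinct score value; returning one group")
        g = RiskGroup(float(values[0]), float(values[0]),
                      int(cases[0] + controls[0]), int(cases[0]),
                      values=[float(values[0])])
        return Stratification([g], merge_alpha, 1.0, 1)

    cats = _Categories(values, cases, controls)

    # fold undersized categories into their most similar neighbour first
    while len(cats) > 1:
        sizes = cats.sizes()
        small = [i for i, n in enumerate(sizes) if n < min_group]
        if not small:
            break
        i = min(small, key=lambda i: (sizes[i], i))  # smallest first, leftmost tie-break
        if i == 0:
            cats.merge(0)
        elif i == len(cats) - 1:
            cats.merge(i - 1)
        else:
            p_left = _pair_p(cats.counts[i - 1], cats.counts[i])
            p_right = _pair_p(cats.counts[i], cats.counts[i + 1])
            cats.merge(i if p_right >= p_left else i - 1)

    # significance-driven merging of the most similar adjacent pair
    while len(cats) > 1:
        ps = cats.adjacent_ps()
        i = int(np.argmax(ps))  # leftmost maximum
        if ps[i] > merge_alpha:
            cats.merge(i)
        else:
            break

    r_final = len(cats)
    if r_final == 1:
        adjusted_p = 1.0
    else:
        table = np.array(cats.counts, dtype=float)
        _, p_overall, _, _ = stats.chi2_contingency(table, correction=False)
        adjusted_p = min(1.0, float(p_overall) * math.comb(c_initial - 1, r_final - 1))

    groups: list[RiskGroup] = []
    prev_upper: float | None = None
    for vals, (a, b) in zip(cats.values, cats.counts):
        lower = min(vals) if prev_upper is None else round(prev_upper + 0.1, 1)
        upper = max(vals)
        groups.append(RiskGroup(lower, upper, a + b, a, values=sorted(vals)))
        prev_upper = upper
    return Stratification(groups, merge_alpha, adjusted_p, c_initial)


def summarize_groups(strat: Stratification) -> pd.DataFrame:
    """Per-group table ordered low to high score: printed bounds, size,
    case count and case percentage."""
    if not strat.groups:
        raise ValueError("empty stratification")
    rows = [
        {
            "lower": g.lower,
            "upper": g.upper,
            "n": g.n_subjects,
            "n_cases": g.n_cases,
            "case_pct": 100.0 * g.case_fraction,
        }
        for g in strat.groups
    ]
    return pd.DataFrame(rows)
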