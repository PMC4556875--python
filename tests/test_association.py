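"""Association statistics: counts, odds ratios, chi-square, Fisher,
and the dominant/recessive scan."""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from strokescore import (
    DOMINANT,
    RECESSIVE,
    CountTable2x2,
    DegenerateTableError,
    UndefinedOddsRatioError,
    association_scan,
    build_contingency,
    fisher_exact,
    odds_ratio_ci,
    pearson_chi_square,
    reconstruct_counts,
)
from strokescore.association import scan_codes

from conftest import make_cohort, printed_class_table


# ---------------------------------------------------------------- counts
@pytest.mark.parametrize(
    "percent,n,expected",
    [
        (22.4, 374, 84),   # discovery-case GG count of the published table
        (0, 500, 0),
        (11.6, 156, 18),   # 18.096 -> nearest integer
        (100, 37, 37),
        (50, 3, 2),        # ties away from zero
    ],
)
def test_reconstruct_counts(percent, n, expected):
    assert reconstruct_counts(percent, n) == expected


@pytest.mark.parametrize("percent", [-0.1, 100.1])
def test_reconstruct_counts_domain(percent):
    with pytest.raises(ValueError):
        reconstruct_counts(percent, 100)


@given(st.integers(1, 2000), st.floats(0, 100, allow_nan=False))
@settings(max_examples=200, derandomize=True)
def test_reconstruct_counts_inverts_percentage(n, percent):
    count = reconstruct_counts(percent, n)
    assert 0 <= count <= n
    assert abs(count / n - percent / 100) <= 0.5 / n + 1e-12


# ----------------------------------------------------------- contingency
def test_build_contingency_counts_fixture():
    # 84/374 exposed (GG) cases, 18/156 exposed controls at rs1800779
    rows = []
    statuses = []
    for code, status, k in [(2, "case", 84), (0, "case", 290), (2, "control", 18), (0, "control", 138)]:
        rows += [[code, 0, 0]] * k
        statuses += [status] * k
    coh = make_cohort(rows, statuses)
    t = build_contingency(coh, "rs1800779", RECESSIVE)
    assert t.cells == (84, 290, 18, 138)


def test_build_contingency_excludes_missing_and_partitions():
    rows = [[2, 0, 0], [1, 0, 0], [0, 0, 0], [-1, 0, 0], [2, 0, 0], [1, 0, 0], [0, 0, 0]]
    statuses = ["case"] * 4 + ["control"] * 3
    coh = make_cohort(rows, statuses)
    t_dom = build_contingency(coh, "rs1800779", DOMINANT)
    t_rec = build_contingency(coh, "rs1800779", RECESSIVE)
    # missing case dropped from both
    assert t_dom.a + t_dom.b == 3 and t_rec.a + t_rec.b == 3
    # dominant exposed = recessive exposed + heterozygous cases
    het_cases = 1
    assert t_dom.a == t_rec.a + het_cases


def test_build_contingency_all_missing_is_degenerate():
    coh = make_cohort([[-1, 0, 0], [-1, 0, 0]], ["case", "control"])
    with pytest.raises(DegenerateTableError):
        build_contingency(coh, "rs1800779", DOMINANT)


# ------------------------------------------------------------ odds ratio
def test_odds_ratio_published_discovery_value():
    orr = odds_ratio_ci(CountTable2x2(84, 290, 18, 138))
    assert round(orr.or_point, 1) == 2.2
    assert orr.ci_low < orr.or_point < orr.ci_high


def test_odds_ratio_symmetric_table_is_one():
    orr = odds_ratio_ci(CountTable2x2(10, 10, 10, 10))
    assert orr.or_point == 1.0


def test_odds_ratio_reconstructed_protective():
    # cross-product oracle: 19*140 / (355*16) = 0.4683
    orr = odds_ratio_ci(CountTable2x2(19, 355, 16, 140))
    assert round(orr.or_point, 2) == 0.47


def test_odds_ratio_zero_cell_haldane():
    orr = odds_ratio_ci(CountTable2x2(5, 0, 3, 5))
    assert orr.haldane
    expected = (5.5 * 5.5) / (0.5 * 3.5)
    assert orr.or_point == pytest.approx(expected)


def test_odds_ratio_undefined_two_zeros():
    with pytest.raises(UndefinedOddsRatioError):
        odds_ratio_ci(CountTable2x2(0, 0, 3, 5))


# ------------------------------------------------------------ chi-square
def test_chi_square_matches_published_covariate_p():
    # replication-arm hypertension table
    chi2, p = pearson_chi_square(CountTable2x2(143, 96, 239, 302))
    assert p == pytest.approx(5.5e-5, rel=0.01)


def test_chi_square_null_table():
    chi2, p = pearson_chi_square(CountTable2x2(50, 50, 50, 50))
    assert chi2 == 0 and p == 1


@given(st.integers(1, 60), st.integers(1, 60), st.integers(1, 60), st.integers(1, 60))
@settings(max_examples=100, derandomize=True)
def test_chi_square_equals_squared_two_proportion_z(a, b, c, d):
    chi2, _ = pearson_chi_square(CountTable2x2(a, b, c, d))
    p1, p2 = a / (a + b), c / (c + d)
    pbar = (a + c) / (a + b + c + d)
    z = (p1 - p2) / math.sqrt(pbar * (1 - pbar) * (1 / (a + b) + 1 / (c + d)))
    assert chi2 == pytest.approx(z * z, rel=1e-9)


def test_chi_square_zero_margin_degenerate():
    with pytest.raises(DegenerateTableError):
        pearson_chi_square(CountTable2x2(0, 5, 0, 5))


# ---------------------------------------------------------------- fisher
def hypergeom_two_sided(a, b, c, d):
    """Independent oracle: enumerate all fixed-margin tables, sum
    probabilities <= that of the observed table."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def prob(x):
        return math.comb(r1, x) * math.comb(r2, c1 - x) / denom

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))


def test_fisher_fully_separated():
    assert fisher_exact(CountTable2x2(5, 0, 0, 5)) == pytest.approx(2 / 252)


def test_fisher_trivial_table():
    assert fisher_exact(CountTable2x2(1, 1, 1, 1)) == 1


@given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
@settings(max_examples=150, derandomize=True)
def test_fisher_matches_enumeration(a, b, c, d):
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return
    assert fisher_exact(CountTable2x2(a, b, c, d)) == pytest.approx(
        hypergeom_two_sided(a, b, c, d), rel=1e-9
    )


def test_fisher_chi2_asymptotic_agreement():
    """The exact and chi-square p converge: with all cells >= 500 they
    agree within 0.02 (at cells of only ~50 the gap can still reach
    ~0.1, so the asymptotic regime is asserted where it holds)."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        a, b, c, d = rng.integers(500, 2000, size=4)
        t = CountTable2x2(int(a), int(b), int(c), int(d))
        _, p_chi = pearson_chi_square(t)
        assert abs(fisher_exact(t) - p_chi) < 0.02


# ------------------------------------------------------------- invariants
@given(st.integers(1, 80), st.integers(1, 80), st.integers(1, 80), st.integers(1, 80))
@settings(max_examples=100, derandomize=True)
def test_table_symmetries(a, b, c, d):
    t = CountTable2x2(a, b, c, d)
    swapped = CountTable2x2(c, d, a, b)
    assert odds_ratio_ci(swapped).or_point == pytest.approx(1 / odds_ratio_ci(t).or_point)
    assert pearson_chi_square(swapped)[0] == pytest.approx(pearson_chi_square(t)[0])
    transposed = CountTable2x2(a, c, b, d)
    assert pearson_chi_square(transposed)[0] == pytest.approx(pearson_chi_square(t)[0])
    assert fisher_exact(transposed) == pytest.approx(fisher_exact(t), rel=1e-9)


# ------------------------------------------------------------------ scan
def test_scan_recessive_effect_reported_under_recessive_encoding():
    """A cohort generated with a pure minor-homozygote effect yields its
    top hit under the recessive encoding."""
    rng = np.random.default_rng(1)
    n_case, n_ctrl = 400, 400
    # cases enriched for hom-minor only; het frequency identical
    case_codes = rng.choice(3, size=n_case, p=[0.45, 0.30, 0.25])
    ctrl_codes = rng.choice(3, size=n_ctrl, p=[0.60, 0.30, 0.10])
    null = rng.choice(3, size=n_case + n_ctrl, p=[0.5, 0.4, 0.1])
    rows = np.column_stack([np.concatenate([case_codes, ctrl_codes]), null, null])
    coh = make_cohort(rows.tolist(), ["case"] * n_case + ["control"] * n_ctrl)
    results = association_scan(coh, contrasts=["cardioembolic"])
    top = results[0]
    assert top.snp_id == "rs1800779"
    assert top.model.kind == "recessive"


def test_scan_best_of_two_row_count_and_bonferroni():
    rng = np.random.default_rng(2)
    rows = rng.choice(3, size=(60, 3))
    coh = make_cohort(rows.tolist(), ["case"] * 30 + ["control"] * 30)
    best = association_scan(coh, contrasts=["cardioembolic"])
    assert len(best) == 3
    both = association_scan(coh, contrasts=["cardioembolic"], policy="all")
    assert len(both) == 6
    for r in best:
        assert r.p_bonferroni == pytest.approx(min(1.0, r.p * 3))


def test_scan_single_snp_row_per_contrast():
    rows = [[0], [1], [2], [0], [1], [2]]
    coh = make_cohort(rows, ["case"] * 3 + ["control"] * 3, snps=("rs1800779",))
    res = association_scan(coh, contrasts=["cardioembolic"])
    assert len(res) == 1


def test_scan_uses_fisher_for_sparse_tables():
    rows = [[2, 0, 0]] * 3 + [[0, 0, 0]] * 5 + [[0, 0, 0]] * 6
    coh = make_cohort(rows, ["case"] * 8 + ["control"] * 6)
    res = scan_codes(coh.genotypes, coh.phenotypes["status"] == "case")
    assert all(r.test_used == "fisher" for r in res if r.table is not None)


def test_printed_class_tables_match_hand_counts():
    # sanity of the shared fixture builder itself
    assert printed_class_table("discovery", "rs1800779").cells == (84, 290, 18, 138)
    assert printed_class_table("discovery", "rs2257073").cells == (19, 355, 16, 140)
    assert printed_class_table("discovery", "rs1205").cells == (153, 221, 80, 76)
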