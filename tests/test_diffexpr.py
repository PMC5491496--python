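"""Rank-sum testing and SAM-style permutation FDR."""

import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lcmirna.diffexpr import (
    SIGNIFICANCE_COLUMNS,
    build_significance_table,
    rank_test,
    sam_permutation_fdr,
)
from lcmirna.synthetic_data import table2_fixture

from conftest import make_ct, make_samples


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_rank_p(x, y):
    """Exact two-sided p by enumerating assignments and counting pairwise
    wins (the U statistic computed without rank sums)."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(idx):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        wins = 0.0
        for va in a:
            for vb in b:
                if va > vb:
                    wins += 1
                elif va == vb:
                    wins += 0.5
        return wins

    mu = n1 * (len(pooled) - n1) / 2.0
    obs = abs(u_of(tuple(range(n1))) - mu)
    assigns = list(combinations(range(len(pooled)), n1))
    hits = sum(1 for idx in assigns if abs(u_of(idx) - mu) >= obs - 1e-9)
    return hits / len(assigns)


def oracle_sam(X, n_case, fdr_ceiling):
    """Brute-force SAM on a tiny instance: exhaustive label assignments,
    plain python loops throughout."""
    n, p = X.shape
    ranks = np.array([stats.rankdata(X[:, j]) for j in range(p)]).T  # n x p
    mu = n_case * (n + 1) / 2.0

    def sigma(j):
        _, cnt = np.unique(ranks[:, j], return_counts=True)
        t = sum(c**3 - c for c in cnt)
        var = n_case * (n - n_case) / 12 * ((n + 1) - t / (n * (n - 1)))
        return math.sqrt(var) if var > 0 else math.inf

    sig = [sigma(j) for j in range(p)]

    def stats_for(case_idx):
        return [
            (sum(ranks[i, j] for i in case_idx) - mu) / sig[j] for j in range(p)
        ]

    obs = stats_for(tuple(range(n_case)))
    perms = [stats_for(idx) for idx in combinations(range(n), n_case)]
    dbar = [
        sum(sorted(pv)[i] for pv in perms) / len(perms) for i in range(p)
    ]
    d_sorted = sorted(obs)
    dev = [d_sorted[i] - dbar[i] for i in range(p)]
    cands = sorted(
        {0.0}
        | {dev[i] for i in range(p) if dbar[i] >= 0 and dev[i] > 0}
        | {-dev[i] for i in range(p) if dbar[i] <= 0 and dev[i] < 0}
    )
    rows = []
    eps = 1e-12
    for delta in cands:
        ups = [d_sorted[i] for i in range(p) if dbar[i] >= 0 and dev[i] >= delta - eps]
        los = [d_sorted[i] for i in range(p) if dbar[i] <= 0 and -dev[i] >= delta - eps]
        cutup = min(ups) if ups else math.inf
        cutlow = max(los) if los else -math.inf
        n_called = sum(1 for d in obs if d >= cutup - eps or d <= cutlow + eps)
        exceed = [
            sum(1 for d in pv if d >= cutup - eps or d <= cutlow + eps)
            for pv in perms
        ]
        fdr = min(100.0, float(np.mean(exceed)) / max(1, n_called) * 100.0)
        rows.append([delta, n_called, fdr])
    out = pd.DataFrame(rows, columns=["delta", "n_called", "fdr_percent"])
    out["fdr_percent"] = np.minimum.accumulate(out["fdr_percent"])
    return out


# ---------------------------------------------------------------------------
# rank test
# ---------------------------------------------------------------------------


def test_fully_separated_small_groups():
    res = rank_test([1, 2, 3], [4, 5, 6])
    assert res.method == "exact"
    assert res.pvalue == pytest.approx(0.1)


def test_identical_groups_degenerate():
    with pytest.warns(UserWarning, match="degenerate"):
        res = rank_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    assert res.pvalue == 1.0


def test_overlapping_identical_samples():
    res = rank_test([1, 2, 3], [1, 2, 3])
    assert res.pvalue == 1.0


def test_symmetry_in_arguments(rng):
    for _ in range(10):
        x = rng.normal(size=rng.integers(2, 9))
        y = rng.normal(size=rng.integers(2, 9))
        assert rank_test(x, y).pvalue == pytest.approx(rank_test(y, x).pvalue)


def test_exact_p_matches_enumeration_oracle_with_ties(rng):
    for _ in range(40):
        n1 = int(rng.integers(2, 7))
        n2 = int(rng.integers(2, 13 - n1))
        # integer draws force ties
        x = rng.integers(0, 5, size=n1).astype(float)
        y = rng.integers(0, 5, size=n2).astype(float)
        if np.ptp(np.concatenate([x, y])) == 0:
            continue
        assert rank_test(x, y).pvalue == pytest.approx(oracle_rank_p(x, y), abs=1e-12)


def test_large_groups_use_tie_corrected_normal(rng):
    x = rng.normal(size=15)
    y = rng.normal(size=18)
    res = rank_test(x, y)
    assert res.method == "asymptotic"
    ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert res.pvalue == pytest.approx(ref.pvalue, abs=0.02)


# ---------------------------------------------------------------------------
# SAM permutation FDR
# ---------------------------------------------------------------------------


def _delta_matrix(X):
    return make_ct(X, stage="delta_ct")


def test_tiny_instance_matches_exhaustive_oracle(rng):
    X = rng.normal(size=(8, 6))
    X[:4, 0] += 3.0
    ct = _delta_matrix(X)
    samples = make_samples(4, 4)
    res = sam_permutation_fdr(ct, samples, n_perm=200, seed=0, fdr_ceiling=10.0)
    assert res.exhaustive and res.n_perm_used == math.comb(8, 4)
    expected = oracle_sam(X, 4, 10.0)
    pd.testing.assert_frame_equal(
        res.curve.reset_index(drop=True), expected, atol=1e-10, check_dtype=False
    )


def test_same_seed_reproduces_call_set(rng):
    X = rng.normal(size=(20, 40))
    X[:10, :5] += 1.5
    ct = _delta_matrix(X)
    samples = make_samples(10, 10)
    a = sam_permutation_fdr(ct, samples, n_perm=300, seed=11)
    b = sam_permutation_fdr(ct, samples, n_perm=300, seed=11)
    assert a.called == b.called
    pd.testing.assert_frame_equal(a.curve, b.curve)


def test_fdr_curve_monotone_and_bounded(rng):
    X = rng.normal(size=(20, 60))
    res = sam_permutation_fdr(_delta_matrix(X), make_samples(10, 10), n_perm=300, seed=3)
    fdr = res.curve["fdr_percent"].to_numpy()
    assert np.all(np.diff(fdr) <= 1e-12)
    assert fdr.min() >= 0 and fdr.max() <= 100


def test_null_matrix_fdr_estimates_are_high_in_bulk():
    spurious = 0
    for seed in range(5):
        X = np.random.default_rng(500 + seed).normal(0, 0.5, size=(20, 200))
        res = sam_permutation_fdr(
            _delta_matrix(X), make_samples(10, 10), n_perm=300, seed=seed
        )
        big_sets = res.curve[res.curve["n_called"] >= 20]
        assert (big_sets["fdr_percent"] >= 30).all()
        spurious += len(res.called)
    # estimated-FDR noise at the extreme tail admits occasional null calls,
    # but they stay rare relative to 1000 assay-runs
    assert spurious <= 15


def test_planted_shift_recovered_at_low_fdr(rng):
    X = rng.normal(0, 0.5, size=(20, 120))
    X[:10, :10] += 2.0
    ct = _delta_matrix(X)
    res = sam_permutation_fdr(ct, make_samples(10, 10), n_perm=500, seed=1, fdr_ceiling=5.0)
    planted = {f"m{j + 1}" for j in range(10)}
    assert len(set(res.called) & planted) >= 9
    assert len(set(res.called) - planted) <= 2


def test_low_permutation_count_warns(rng):
    X = rng.normal(size=(8, 5))
    with pytest.warns(UserWarning, match="n_perm"):
        sam_permutation_fdr(_delta_matrix(X), make_samples(4, 4), n_perm=50, seed=0)


# ---------------------------------------------------------------------------
# significance table
# ---------------------------------------------------------------------------


def test_empty_table_has_header():
    annotations, _ = table2_fixture()
    results = pd.DataFrame(
        {"fold": [1.2], "raw_p": [0.5]}, index=["hsa-miR-17-5p"]
    )
    table = build_significance_table(results, annotations)
    assert list(table.columns) == list(SIGNIFICANCE_COLUMNS)
    assert len(table) == 0


def test_boundary_p_is_inclusive_and_direction_derived():
    annotations, _ = table2_fixture()
    results = pd.DataFrame(
        {"fold": [1.52, 0.8], "raw_p": [0.05, 0.02]},
        index=["hsa-miR-541-3p", "hsa-miR-409-5p"],
    )
    table = build_significance_table(results, annotations)
    assert len(table) == 2
    row = table.set_index("mirna").loc["hsa-miR-541-3p"]
    assert row["regulation"] == "↑"
    assert row["mirbase_acc"] == "MIMAT0004920"


def test_missing_annotation_yields_blank_row_with_warning():
    results = pd.DataFrame({"fold": [1.5], "raw_p": [0.01]}, index=["mystery"])
    with pytest.warns(UserWarning, match="mystery"):
        table = build_significance_table(results, [])
    assert table.loc[0, "mirbase_acc"] == ""
    assert table.loc[0, "regulation"] == "↑"
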