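"""Correlation matrices, edge criteria and network export."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lcmirna.coexpression import (
    CorrelationMatrices,
    critical_r,
    degree_summary,
    export_network,
    import_network,
    pairwise_pearson,
    select_differential_edges,
)

from conftest import make_ct, make_samples


def _centered(values, **kw):
    return make_ct(values, stage="global_centered", **kw)


def _corr_from(pairs: dict[tuple[str, str], tuple[float, float]], nodes):
    """Build CorrelationMatrices with prescribed (r_case, r_control) pairs."""
    rc = pd.DataFrame(np.eye(len(nodes)), index=nodes, columns=nodes)
    rk = rc.copy()
    for (i, j), (a, b) in pairs.items():
        rc.loc[i, j] = rc.loc[j, i] = a
        rk.loc[i, j] = rk.loc[j, i] = b
    return CorrelationMatrices(r_case=rc, r_control=rk, n_case=9, n_control=11)


# ---------------------------------------------------------------------------
# pairwise Pearson
# ---------------------------------------------------------------------------


def test_duplicated_assay_and_sign_flip(rng):
    x = rng.normal(size=8)
    values = np.column_stack([x, x, -x])
    corr = pairwise_pearson(_centered(values), make_samples(4, 4))
    assert corr.r_case.loc["m1", "m2"] == pytest.approx(1.0)
    assert corr.r_case.loc["m1", "m3"] == pytest.approx(-1.0)


def test_matches_double_loop_oracle(rng):
    values = rng.normal(size=(9, 30))
    samples = make_samples(4, 5)
    corr = pairwise_pearson(_centered(values), samples)
    case_rows = values[:4]
    for i in range(30):
        for j in range(i + 1, 30):
            expected, _ = stats.pearsonr(case_rows[:, i], case_rows[:, j])
            assert corr.r_case.iloc[i, j] == pytest.approx(expected, abs=1e-12)
            assert corr.r_case.iloc[j, i] == pytest.approx(
                corr.r_case.iloc[i, j], abs=1e-14
            )


def test_zero_variance_assay_excluded_with_warning(rng):
    values = rng.normal(size=(8, 3))
    values[:4, 0] = 5.0  # constant within the case group
    with pytest.warns(UserWarning, match="zero-variance"):
        corr = pairwise_pearson(_centered(values), make_samples(4, 4))
    assert corr.excluded_assays == ("m1",)
    assert list(corr.r_case.index) == ["m2", "m3"]


def test_small_group_rejected(rng):
    with pytest.raises(ValueError, match="fewer than 3"):
        pairwise_pearson(_centered(rng.normal(size=(5, 4))), make_samples(2, 3))


# ---------------------------------------------------------------------------
# critical correlation
# ---------------------------------------------------------------------------


def test_critical_r_examples():
    # the conventional "r = 0.7" at n ~ 9-11 is a rounding of these values
    assert critical_r(9, 0.05) == pytest.approx(0.666, abs=1e-3)
    assert critical_r(11, 0.05) == pytest.approx(0.602, abs=1e-3)
    assert critical_r(4, 1.0) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        critical_r(3)


def test_critical_r_monotone_to_zero():
    values = [critical_r(n) for n in (5, 10, 30, 100, 1000)]
    assert all(a > b for a, b in zip(values, values[1:]))
    assert values[-1] < 0.07


def test_critical_r_inverts_t_pvalue():
    for n in (6, 9, 11, 25):
        r = critical_r(n, 0.05)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(t, n - 2)
        assert p == pytest.approx(0.05, abs=1e-10)


# ---------------------------------------------------------------------------
# edge selection
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "r_case, r_control, is_edge",
    [
        (0.9, 0.0, True),  # all three criteria pass
        (0.75, 0.10, False),  # gap 0.65 <= 0.8
        (0.90, -0.75, False),  # control correlation outside (-0.7, 0.7)
        (0.71, -0.10, True),  # gap 0.81 > 0.8
        (0.70, -0.50, False),  # r_case not strictly > 0.7
    ],
)
def test_case_edge_criteria(r_case, r_control, is_edge):
    corr = _corr_from({("a", "b"): (r_case, r_control)}, ["a", "b", "c"])
    net = select_differential_edges(corr, "case_specific")
    assert (("a", "b") in {(u, v) for u, v, *_ in net.edges}) == is_edge


def test_control_direction_mirrors_criteria():
    corr = _corr_from({("a", "b"): (0.0, 0.9)}, ["a", "b"])
    net = select_differential_edges(corr, "control_specific")
    assert len(net.edges) == 1


def test_label_swap_exchanges_networks(rng):
    rc = rng.uniform(-1, 1, size=(12, 12))
    rc = np.clip((rc + rc.T) / 2, -1, 1)
    np.fill_diagonal(rc, 1)
    rk = rng.uniform(-1, 1, size=(12, 12))
    rk = np.clip((rk + rk.T) / 2, -1, 1)
    np.fill_diagonal(rk, 1)
    nodes = [f"m{i}" for i in range(12)]
    corr = CorrelationMatrices(
        r_case=pd.DataFrame(rc, index=nodes, columns=nodes),
        r_control=pd.DataFrame(rk, index=nodes, columns=nodes),
        n_case=9,
        n_control=11,
    )
    swapped = CorrelationMatrices(
        r_case=corr.r_control, r_control=corr.r_case, n_case=11, n_control=9
    )
    net_case = select_differential_edges(corr, "case_specific")
    net_swapped = select_differential_edges(swapped, "control_specific")
    assert {(u, v) for u, v, *_ in net_case.edges} == {
        (u, v) for u, v, *_ in net_swapped.edges
    }


def test_invalid_gap_rejected():
    corr = _corr_from({}, ["a", "b"])
    with pytest.raises(ValueError, match="r_gap"):
        select_differential_edges(corr, "case_specific", r_gap=0.0)


def test_null_false_edge_rate_is_small(rng):
    # independent data in both groups: the per-pair pass probability at the
    # default thresholds is ~0.8% (Monte-Carlo estimate 0.0081 at n=9/11)
    total_pairs = total_edges = 0
    for _ in range(6):
        values = rng.normal(size=(20, 40))
        corr = pairwise_pearson(_centered(values), make_samples(9, 11))
        net = select_differential_edges(corr, "case_specific")
        total_pairs += net.n_pairs_tested
        total_edges += len(net.edges)
    assert total_edges / total_pairs < 0.025


# ---------------------------------------------------------------------------
# degrees and export
# ---------------------------------------------------------------------------


def _net_from(pairs):
    corr = _corr_from({p: (0.95, 0.0) for p in pairs}, sorted({n for p in pairs for n in p}))
    return select_differential_edges(corr, "case_specific")


def test_triangle_and_star_degrees():
    tri = _net_from([("a", "b"), ("b", "c"), ("a", "c")])
    assert set(degree_summary(tri)["degrees"].values()) == {2}
    star = _net_from([("hub", leaf) for leaf in "abcde"])
    summary = degree_summary(star)
    assert summary["max"] == 5 and summary["min"] == 1
    assert summary["hubs"] == ["hub"]


def test_handshake_lemma(rng):
    pairs = {tuple(sorted(p)) for p in rng.choice([f"n{i}" for i in range(10)], size=(15, 2)) if p[0] != p[1]}
    net = _net_from(sorted(pairs))
    summary = degree_summary(net)
    assert sum(summary["degrees"].values()) == 2 * net.graph.number_of_edges()


def test_empty_network_summary_and_export(tmp_path):
    net = _net_from([])
    assert degree_summary(net)["degrees"] == {}
    path = export_network(net, tmp_path / "empty.tsv", "edge_tsv")
    assert import_network(path, "edge_tsv").graph.number_of_edges() == 0


@pytest.mark.parametrize("fmt,name", [("graphml", "net.graphml"), ("edge_tsv", "net.tsv")])
def test_export_round_trip_preserves_attributes(fmt, name, tmp_path):
    corr = _corr_from(
        {("a", "b"): (0.912345, -0.123456), ("b", "c"): (0.95, 0.05)}, ["a", "b", "c"]
    )
    net = select_differential_edges(corr, "case_specific")
    path = export_network(net, tmp_path / name, fmt)
    back = import_network(path, fmt)
    for (u1, v1, rc1, rk1), (u2, v2, rc2, rk2) in zip(net.edges, back.edges):
        assert (u1, v1) == (u2, v2)
        assert rc1 == pytest.approx(rc2, abs=1e-6)
        assert rk1 == pytest.approx(rk2, abs=1e-6)
    with pytest.raises(ValueError, match="format"):
        export_network(net, tmp_path / "x.bin", "binary")
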