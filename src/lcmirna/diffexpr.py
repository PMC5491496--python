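"""Two-group nonparametric testing and SAM-style permutation FDR.

The per-miRNA test is the two-sample Wilcoxon rank-sum (Mann-Whitney) test:
the design is two independent groups of unequal size, for which the
rank-sum form is the defined Wilcoxon test (the signed-rank form requires
paired observations).  Exact two-sided p-values are computed by complete
enumeration of group assignments for small problems; larger problems use
the tie-corrected normal approximation.

Multiple testing is handled SAM-style: the per-assay standardised rank
statistic is compared against its permutation-expected order statistic,
a threshold Delta defines the called set, and the FDR at Delta is the
median number of permutation exceedances divided by the number of calls.
No fudge-factor s0 is applied (it is undefined for a rank statistic), and
no pi0 estimate is used, making the estimate conservative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CtMatrix, MiRNAAnnotation, SampleInfo, samples_to_frame
from .preprocess import UP, DOWN

__all__ = [
    "RankTestResult",
    "SamResult",
    "rank_test",
    "sam_permutation_fdr",
    "build_significance_table",
    "SIGNIFICANCE_COLUMNS",
]

# exact enumeration is used when the number of distinct group assignments
# is at most this; C(14,7)=3432 keeps all n1+n2<=14 designs exact
MAX_EXACT_ASSIGNMENTS = 5000


class RankTestResult(NamedTuple):
    statistic: float  # Mann-Whitney U for the first sample
    pvalue: float
    method: str  # "exact" or "asymptotic"


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def _tie_sigma(pooled_ranks: np.ndarray, n1: int, n2: int) -> float:
    n = n1 + n2
    _, counts = np.unique(pooled_ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    return math.sqrt(max(var, 0.0))


def rank_test(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum / Mann-Whitney test.

    Exact enumeration of all C(n, n1) group assignments when feasible
    (two-sided p = proportion of assignments whose U deviates from its
    null mean by at least the observed deviation — U is symmetric about
    n1*n2/2 under exchangeability, ties included); otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("rank_test requires at least 2 observations per group")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("rank_test input contains missing values")

    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w_x = float(ranks[:n1].sum())
    u_x = w_x - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    if np.ptp(pooled) == 0:
        warnings.warn("degenerate data: all values identical across groups", stacklevel=2)
        return RankTestResult(u_x, 1.0, "degenerate")

    n = n1 + n2
    n_assign = math.comb(n, n1)
    obs_dev = abs(u_x - mu)
    if n_assign <= MAX_EXACT_ASSIGNMENTS:
        hits = 0
        const = n1 * (n1 + 1) / 2.0
        for idx in combinations(range(n), n1):
            u = ranks[list(idx)].sum() - const
            if abs(u - mu) >= obs_dev - 1e-9:
                hits += 1
        return RankTestResult(u_x, hits / n_assign, "exact")

    sigma = _tie_sigma(ranks, n1, n2)
    if sigma == 0:
        return RankTestResult(u_x, 1.0, "degenerate")
    z = (obs_dev - 0.5) / sigma  # continuity-corrected
    p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
    return RankTestResult(u_x, p, "asymptotic")


# ---------------------------------------------------------------------------
# SAM-style permutation FDR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SamResult:
    """Permutation-FDR output.

    Attributes
    ----------
    scores : per-assay standardised rank statistic d_i (Ct scale: positive
        means higher dCt in cases, i.e. *lower* expression).
    expected_order : permutation-expected order statistics dbar_(i).
    curve : DataFrame (delta, n_called, fdr_percent) - monotone
        non-increasing FDR in delta after cumulative-minimum adjustment.
    called : assay ids called at the requested FDR ceiling.
    table : per-assay DataFrame (score, diff, called).
    """

    scores: pd.Series
    expected_order: np.ndarray
    curve: pd.DataFrame
    called: tuple[str, ...]
    table: pd.DataFrame
    fdr_ceiling: float
    n_perm_used: int
    exhaustive: bool
    dropped_incomplete: tuple[str, ...] = ()


def _distinct_label_choices(
    n: int, n_case: int, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Boolean indicator matrix (n x B) of distinct case-label assignments."""
    total = math.comb(n, n_case)
    if total <= n_perm:
        combos = list(combinations(range(n), n_case))
        exhaustive = True
    else:
        seen: set[tuple[int, ...]] = set()
        while len(seen) < n_perm:
            pick = tuple(sorted(rng.choice(n, size=n_case, replace=False).tolist()))
            seen.add(pick)
        combos = sorted(seen)
        exhaustive = False
    ind = np.zeros((n, len(combos)), dtype=float)
    for b, idx in enumerate(combos):
        ind[list(idx), b] = 1.0
    return ind, exhaustive


def sam_permutation_fdr(
    delta: CtMatrix,
    samples: Sequence[SampleInfo],
    n_perm: int = 5000,
    seed: int | None = None,
    fdr_ceiling: float = 5.0,
) -> SamResult:
    """SAM-type two-class unpaired analysis with the Wilcoxon statistic.

    For every assay the standardised rank-sum statistic d_i is computed;
    label permutations (distinct assignments, drawn uniformly without
    replacement, or exhaustively when fewer exist than ``n_perm``) yield
    the expected order statistics dbar_(i).  A threshold Delta on the
    deviation of the ordered d_(i) from dbar_(i) induces cut points on
    the statistic scale:

        cutup(Delta)  = smallest d_(i) with dbar_(i) >= 0 and
                        d_(i) - dbar_(i) >= Delta          (else +inf)
        cutlow(Delta) = largest  d_(i) with dbar_(i) <= 0 and
                        dbar_(i) - d_(i) >= Delta          (else -inf)

    The called set is {assays : d_i >= cutup or d_i <= cutlow}, and

        FDR(Delta) = mean_b #{j : d_j^b >= cutup or d_j^b <= cutlow}
                     / max(1, #called) * 100

    (the expected number of falsely called assays over permutations, the
    original formulation; the median variant collapses to zero for small
    call sets whose cut is the observed extreme statistic),

    clipped to [0, 100] and made monotone non-increasing in Delta by a
    cumulative minimum.  ``called`` is the largest call set whose FDR is
    at or below ``fdr_ceiling``.
    """
    if delta.stage != "delta_ct":
        raise ValueError("sam_permutation_fdr expects a delta_ct matrix")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low for FDR estimation", stacklevel=2)
    meta = samples_to_frame(samples)
    case_ids = [s for s in delta.samples if meta.at[s, "group"] == "case"]
    ctrl_ids = [s for s in delta.samples if meta.at[s, "group"] == "control"]
    if len(case_ids) < 3 or len(ctrl_ids) < 3:
        raise ValueError("both groups need at least 3 samples")

    order = case_ids + ctrl_ids
    X = delta.values.loc[order].to_numpy(dtype=float).T  # assays x samples
    assays = np.array(delta.assays)
    complete = ~np.isnan(X).any(axis=1)
    dropped = tuple(assays[~complete])
    if dropped:
        warnings.warn(
            f"{len(dropped)} assays with missing dCt excluded from SAM", stacklevel=2
        )
    X, assays = X[complete], assays[complete]
    p, n = X.shape
    n_case = len(case_ids)

    R = stats.rankdata(X, axis=1, method="average")
    mu = n_case * (n + 1) / 2.0
    sigma = np.array([_tie_sigma(R[i], n_case, n - n_case) for i in range(p)])
    sigma[sigma == 0] = np.inf  # constant assays score 0

    w_obs = R[:, :n_case].sum(axis=1)
    d_obs = (w_obs - mu) / sigma

    rng = np.random.default_rng(seed)
    ind, exhaustive = _distinct_label_choices(n, n_case, n_perm, rng)
    B = ind.shape[1]
    D = (R @ ind - mu) / sigma[:, None]  # assays x perms
    dbar = np.sort(D, axis=0).mean(axis=1)

    order_obs = np.argsort(d_obs, kind="stable")
    d_sorted = d_obs[order_obs]
    dev = d_sorted - dbar  # positive where observed exceeds expectation
    upper = dbar >= 0
    lower = dbar <= 0

    cands = np.unique(
        np.concatenate([[0.0], dev[upper & (dev > 0)], -dev[lower & (dev < 0)]])
    )

    eps = 1e-12
    K = len(cands)
    cutups = np.empty(K)
    cutlows = np.empty(K)
    n_called = np.empty(K, dtype=int)
    called_masks = []
    for k, delta_k in enumerate(cands):
        up_ok = upper & (dev >= delta_k - eps)
        lo_ok = lower & (-dev >= delta_k - eps)
        cutups[k] = d_sorted[up_ok].min() if up_ok.any() else np.inf
        cutlows[k] = d_sorted[lo_ok].max() if lo_ok.any() else -np.inf
        mask = (d_obs >= cutups[k] - eps) | (d_obs <= cutlows[k] + eps)
        called_masks.append(mask)
        n_called[k] = int(mask.sum())

    # exceedances per permutation against the same cut points
    D_perm_sorted = np.sort(D, axis=0)
    exceed = np.empty((B, K))
    for b in range(B):
        col = D_perm_sorted[:, b]
        hi = p - np.searchsorted(col, cutups - eps, side="left")
        lo = np.searchsorted(col, cutlows + eps, side="right")
        exceed[b] = hi + lo
    mean_exceed = exceed.mean(axis=0)

    raw_fdr = np.clip(mean_exceed / np.maximum(n_called, 1) * 100.0, 0.0, 100.0)
    # cumulative min from small Delta upward => monotone non-increasing FDR
    fdr = np.minimum.accumulate(raw_fdr)

    curve = pd.DataFrame({"delta": cands, "n_called": n_called, "fdr_percent": fdr})

    ok = curve[(curve["fdr_percent"] <= fdr_ceiling) & (curve["n_called"] > 0)]
    if len(ok):
        called_mask = called_masks[int(ok["n_called"].idxmax())]
    else:
        called_mask = np.zeros(p, dtype=bool)
    called = tuple(assays[called_mask])

    diff_by_assay = np.empty(p)
    diff_by_assay[order_obs] = dev
    table = pd.DataFrame(
        {"score": d_obs, "deviation": diff_by_assay, "called": called_mask},
        index=assays,
    )
    return SamResult(
        scores=pd.Series(d_obs, index=assays),
        expected_order=dbar,
        curve=curve,
        called=called,
        table=table,
        fdr_ceiling=fdr_ceiling,
        n_perm_used=B,
        exhaustive=exhaustive,
        dropped_incomplete=dropped,
    )


# ---------------------------------------------------------------------------
# Table-2-shaped significance report
# ---------------------------------------------------------------------------

SIGNIFICANCE_COLUMNS = (
    "mirbase_acc",
    "plate",
    "mirna",
    "fold_change",
    "p_value",
    "regulation",
    "chromosome",
    "strand",
    "seed",
)


def _chromosome_key(label: str) -> tuple[int, str]:
    s = str(label).removeprefix("Chromosome").strip()
    try:
        return (int(s), "")
    except ValueError:
        return (1000, s)


def build_significance_table(
    results: pd.DataFrame,
    annotations: Sequence[MiRNAAnnotation],
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Assemble the per-miRNA significance report.

    ``results`` must be indexed by assay id with columns ``fold`` and
    ``raw_p`` (and optionally ``direction``).  Rows are assays with
    raw_p <= p_cut (boundary inclusive), sorted by plate then chromosome;
    missing annotations yield blank fields with a warning.
    """
    ann = {a.assay_id: a for a in annotations}
    rows = []
    for assay, r in results.iterrows():
        if not (r["raw_p"] <= p_cut):
            continue
        a = ann.get(assay)
        if a is None:
            warnings.warn(f"no annotation for significant assay {assay!r}", stacklevel=2)
        direction = r.get("direction")
        if not direction:
            direction = UP if r["fold"] > 1 else (DOWN if r["fold"] < 1 else "=")
        rows.append(
            {
                "mirbase_acc": a.mirbase_acc if a else "",
                "plate": a.plate if a else "",
                "mirna": assay,
                "fold_change": float(r["fold"]),
                "p_value": float(r["raw_p"]),
                "regulation": direction,
                "chromosome": a.chromosome if a else "",
                "strand": a.strand if a else "",
                "seed": (a.seed or "") if a else "",
            }
        )
    df = pd.DataFrame(rows, columns=list(SIGNIFICANCE_COLUMNS))
    if len(df):
        df = df.sort_values(
            by=["plate", "chromosome", "mirna"],
            key=lambda col: col.map(_chromosome_key) if col.name == "chromosome" else col,
        ).reset_index(drop=True)
    return df
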