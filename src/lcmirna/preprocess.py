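"""Detectability filtering, normalisation and ddCt fold-change computation.

The processing chain for a two-card TLDA experiment:

1. :func:`filter_detectable` drops assays whose Ct exceeds the reliability
   threshold (default Ct 35) in too many samples, evaluated within each
   diagnostic group separately, and always drops the plant negative control.
2. :func:`median_normalize` forms dCt = Ct - per-sample median Ct (per plate
   by default, plates having been run as replicates), the input to
   differential expression and hierarchical clustering.
3. :func:`global_mean_center` subtracts each sample's global mean Ct (plates
   pooled) - the normalisation used for co-expression, removing differences
   among individuals in overall miRNA content.
4. :func:`fold_change` computes ddCt = mean dCt(case) - mean dCt(control)
   and fold = 2**(-ddCt); on the Ct scale a *positive* ddCt means *lower*
   expression in cases.

:func:`endo_control_check` verifies that the geometric-mean Ct of the
endogenous small-RNA controls (U6, RNU44, RNU48) does not differ between
groups, per plate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CtMatrix, EndoControlSet, SampleInfo, samples_to_frame

__all__ = [
    "FilterResult",
    "NormalizationReport",
    "filter_detectable",
    "median_normalize",
    "global_mean_center",
    "endo_control_check",
    "fold_change",
]

UP, DOWN, FLAT = "↑", "↓", "="


@dataclass(frozen=True)
class FilterResult:
    """Detectability-filter output: the reduced matrix plus an audit trail."""

    matrix: CtMatrix
    retained_assays: tuple[str, ...]
    dropped_assays: tuple[str, ...]
    threshold: float
    min_fraction: float

    @property
    def n_retained(self) -> int:
        return len(self.retained_assays)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_assays)


@dataclass(frozen=True)
class NormalizationReport:
    """Endogenous-control summary per plate and group, with group t-tests.

    ``per_group`` maps (plate, group) -> dict(mean, sd, n) of the per-sample
    geometric-mean control Ct; ``t_tests`` maps plate -> dict(t, df, p).
    """

    per_group: dict[tuple[str, str], dict[str, float]]
    t_tests: dict[str, dict[str, float]]
    n_assays_retained: int
    n_assays_dropped: int
    warnings: tuple[str, ...] = ()


def _group_index(samples: Sequence[SampleInfo], ct: CtMatrix) -> dict[str, list[str]]:
    meta = samples_to_frame(samples)
    missing = set(ct.samples) - set(meta.index)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)}")
    groups: dict[str, list[str]] = {}
    for s in ct.samples:
        groups.setdefault(str(meta.at[s, "group"]), []).append(s)
    return groups


def filter_detectable(
    ct: CtMatrix,
    threshold: float = 35.0,
    min_fraction: float = 1.0,
    samples: Sequence[SampleInfo] | None = None,
    negative_control_ids: Iterable[str] = (),
) -> FilterResult:
    """Retain assays detectable (Ct <= threshold) in enough samples per group.

    An assay is kept iff, within *every* group, the fraction of samples with
    a detectable Ct <= ``threshold`` is at least ``min_fraction``.  With no
    metadata all samples form one group.  Negative-control assays are always
    dropped.
    """
    if ct.stage != "raw":
        raise ValueError("detectability filtering applies to raw Ct matrices")
    if not 0 < threshold < 45:
        raise ValueError(f"Ct threshold {threshold} outside (0, 45)")
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction {min_fraction} outside (0, 1]")

    if samples is None:
        group_samples = {"all": ct.samples}
    else:
        group_samples = _group_index(samples, ct)

    ok = ct.detect_mask.to_numpy() & (ct.values.to_numpy(dtype=float) <= threshold)
    ok = pd.DataFrame(ok, index=ct.values.index, columns=ct.values.columns)
    keep = pd.Series(True, index=ct.values.columns)
    for _, members in group_samples.items():
        frac = ok.loc[members].mean(axis=0)
        keep &= frac >= min_fraction
    negatives = set(negative_control_ids)
    keep[keep.index.isin(negatives)] = False

    retained = tuple(a for a in ct.assays if keep[a])
    dropped = tuple(a for a in ct.assays if not keep[a])
    return FilterResult(
        matrix=ct.subset_assays(list(retained)),
        retained_assays=retained,
        dropped_assays=dropped,
        threshold=threshold,
        min_fraction=min_fraction,
    )


def _center(ct: CtMatrix, stat: str, per_plate: bool, stage: str) -> CtMatrix:
    values = ct.values.copy()
    plate_groups = (
        values.columns.groupby(ct.plate_of_assay.loc[values.columns])
        if per_plate
        else {"pooled": values.columns}
    )
    for plate, cols in plate_groups.items():
        block = values.loc[:, list(cols)]
        center = block.median(axis=1) if stat == "median" else block.mean(axis=1)
        empty = center.index[center.isna()]
        if len(empty):
            raise ValueError(
                f"sample {empty[0]!r} has no detectable assay"
                + (f" on plate {plate}" if per_plate else "")
            )
        values.loc[:, list(cols)] = block.sub(center, axis=0)
    return ct.derive(values, stage)


def median_normalize(ct: CtMatrix, per_plate: bool = True) -> CtMatrix:
    """dCt = Ct - per-sample median Ct over retained assays (per plate)."""
    if ct.stage != "raw":
        raise ValueError("median_normalize expects a raw (filtered) matrix")
    return _center(ct, "median", per_plate, "delta_ct")


def global_mean_center(ct: CtMatrix) -> CtMatrix:
    """Subtract each sample's global mean Ct, plates pooled (co-expression)."""
    if ct.stage != "raw":
        raise ValueError("global_mean_center expects a raw (filtered) matrix")
    return _center(ct, "mean", per_plate=False, stage="global_centered")


def endo_control_check(
    ct: CtMatrix,
    controls: EndoControlSet,
    samples: Sequence[SampleInfo],
) -> NormalizationReport:
    """Compare per-sample geometric-mean control Ct between groups, per plate.

    The geometric mean is taken on the Ct scale, exp(mean(ln Ct)).  Missing
    control assays raise a warning and are skipped; if no control assay is
    present at all this is an error.
    """
    present = [a for a in controls.normalizers if a in ct.assays]
    absent = [a for a in controls.normalizers if a not in ct.assays]
    warns = tuple(f"control assay {a!r} not in matrix" for a in absent)
    for w in warns:
        warnings.warn(w, stacklevel=2)
    if not present:
        raise ValueError("no endogenous control assay present in the matrix")

    groups = _group_index(samples, ct)
    per_group: dict[tuple[str, str], dict[str, float]] = {}
    t_tests: dict[str, dict[str, float]] = {}
    plates = sorted(set(ct.plate(a) for a in present))
    for plate in plates:
        cols = [a for a in present if ct.plate(a) == plate]
        geo = np.exp(np.log(ct.values.loc[:, cols]).mean(axis=1))
        by_group: dict[str, np.ndarray] = {}
        for g, members in groups.items():
            x = geo.loc[members].dropna().to_numpy()
            by_group[g] = x
            per_group[(plate, g)] = {
                "mean": float(np.mean(x)) if len(x) else math.nan,
                "sd": float(np.std(x, ddof=1)) if len(x) > 1 else math.nan,
                "n": int(len(x)),
            }
        if len(by_group) == 2:
            (x, y) = by_group.values()
            if np.ptp(np.concatenate([x, y])) == 0:
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(x, y, equal_var=True)
            t_tests[plate] = {
                "t": float(t),
                "df": float(len(x) + len(y) - 2),
                "p": float(p),
            }

    return NormalizationReport(
        per_group=per_group,
        t_tests=t_tests,
        n_assays_retained=len(ct.assays),
        n_assays_dropped=0,
        warnings=warns,
    )


def fold_change(delta: CtMatrix, samples: Sequence[SampleInfo]) -> pd.DataFrame:
    """Per-assay ddCt fold change between case and control groups.

    ddCt = mean dCt(case) - mean dCt(control) over detectable cells;
    fold = 2**(-ddCt); direction is up if fold > 1, down if fold < 1.
    Assays with no detectable cell in a group get NaN fold and are flagged.

    Returns a DataFrame indexed by assay with columns
    ``ddct, fold, direction, n_case, n_control, flagged``.
    """
    if delta.stage != "delta_ct":
        raise ValueError("fold_change expects a delta_ct matrix")
    groups = _group_index(samples, delta)
    for g in ("case", "control"):
        if not groups.get(g):
            raise ValueError(f"group {g!r} is empty")

    masked = delta.values.where(delta.detect_mask)
    mean_case = masked.loc[groups["case"]].mean(axis=0)
    mean_ctrl = masked.loc[groups["control"]].mean(axis=0)
    n_case = masked.loc[groups["case"]].notna().sum(axis=0)
    n_ctrl = masked.loc[groups["control"]].notna().sum(axis=0)

    ddct = mean_case - mean_ctrl
    fold = np.power(2.0, -ddct)
    direction = pd.Series(FLAT, index=fold.index, dtype=object)
    direction[fold > 1] = UP
    direction[fold < 1] = DOWN
    flagged = (n_case == 0) | (n_ctrl == 0)
    direction[flagged] = ""
    return pd.DataFrame(
        {
            "ddct": ddct,
            "fold": fold,
            "direction": direction,
            "n_case": n_case,
            "n_control": n_ctrl,
            "flagged": flagged,
        }
    )
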