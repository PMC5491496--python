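"""Synthetic two-card TLDA experiment generator plus packaged fixtures.

The generator emulates the data regime of a 754-assay (2 x 377) TLDA
miRNA screen on postmortem brain tissue from two small diagnostic groups
(11 controls, 9 cases by default):

* per-assay baseline Ct uniform on [18, 33];
* per-sample global shifts (overall miRNA content differences);
* group effects injected on the Ct scale as -log2(fold) for planted
  differentially expressed assays, so the ddCt pipeline recovers the
  configured fold exactly in expectation (default planted folds mirror
  the 0.49-1.58x range typical of such screens);
* group-specific co-expression via latent single-factor blocks: block
  members of one group share ``loading * factor(sample)``, giving
  pairwise correlation loading^2 / (loading^2 + noise_sd^2);
* random dropout pushing wells past the Ct-35 reliability limit, stored
  as undetectable;
* endogenous small-RNA controls (U6, RNU44, RNU48 per plate) with no
  group effect, and a plant negative control (ath-miR-159a) that never
  amplifies.

Demographic covariates are drawn to match the subject table moments but
independent of expression (a coupling knob exists for power tests of the
confound screen).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    CtMatrix,
    EndoControlSet,
    MiRNAAnnotation,
    SampleInfo,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_experiment",
    "table1_fixture",
    "table2_fixture",
    "DEFAULT_PLANTED_FOLDS",
]

# magnitudes mirroring a typical significant-hit table (0.486x .. 1.577x)
DEFAULT_PLANTED_FOLDS = (
    1.261, 1.248, 1.231, 1.403, 0.780, 1.520, 1.430, 1.336,
    0.565, 1.399, 1.577, 1.551, 0.486,
)

_CONTROL_RNAS = ("U6", "RNU44", "RNU48")
_NEGATIVE = "ath-miR-159a"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic TLDA experiment."""

    seed: int  # mandatory: the experiment is fully reproducible
    n_control: int = 11
    n_case: int = 9
    n_assays_per_plate: int = 377
    baseline_ct_range: tuple[float, float] = (18.0, 33.0)
    sample_offset_sd: float = 0.5  # cycles
    noise_sd: float = 0.5  # cycles
    # planted DE: assay index (over miRNA assays) -> fold (case/control);
    # None = 13 assays spread over the panel with the default fold magnitudes
    planted_de: tuple[tuple[int, float], ...] | None = None
    # planted co-expression blocks: (group, assay indices, latent loading);
    # None = one 10-assay case block and one 10-assay control block at r=0.85
    planted_blocks: tuple[tuple[str, tuple[int, ...], float], ...] | None = None
    dropout: float = 0.02
    covariate_coupling: float = 0.0  # slope of age on the first assay's Ct

    def __post_init__(self) -> None:
        if self.sample_offset_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be a probability")
        n_assays = 2 * self.n_assays_per_plate
        if self.planted_de is None:
            step = max(1, n_assays // (len(DEFAULT_PLANTED_FOLDS) + 1))
            object.__setattr__(
                self,
                "planted_de",
                tuple(
                    (min((i + 1) * step, n_assays - 1), f)
                    for i, f in enumerate(DEFAULT_PLANTED_FOLDS)
                ),
            )
        if self.planted_blocks is None:
            # loading 1.19 with noise_sd 0.5 gives pairwise r = 0.85
            loading = 2.3805 * self.noise_sd
            size = min(10, max(2, n_assays // 6))
            object.__setattr__(
                self,
                "planted_blocks",
                (
                    ("case", tuple(range(size)), loading),
                    ("control", tuple(range(size, 2 * size)), loading),
                ),
            )
        if len({i for i, _ in self.planted_de}) != len(self.planted_de):
            raise ValueError("duplicate planted DE assay indices")
        for idx, fold in self.planted_de:
            if not 0 <= idx < n_assays:
                raise ValueError(f"planted DE index {idx} out of range")
            if fold <= 0:
                raise ValueError("planted folds must be positive")
        seen: dict[str, set[int]] = {}
        for group, idxs, loading in self.planted_blocks:
            if group not in ("case", "control"):
                raise ValueError(f"unknown block group {group!r}")
            for i in idxs:
                if not 0 <= i < n_assays:
                    raise ValueError(f"planted block index {i} out of range")
            prior = seen.setdefault(group, set())
            if prior & set(idxs):
                raise ValueError("planted block assay sets must be disjoint per group")
            prior |= set(idxs)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of a simulated experiment, for recovery tests."""

    de_assays: dict[str, float]  # assay_id -> planted fold (case/control)
    block_pairs: dict[str, tuple[tuple[str, str], ...]]  # group -> pairs
    block_members: dict[str, tuple[str, ...]]
    sample_offsets: dict[str, float]
    expected_block_r: dict[str, float]  # group -> loading^2/(loading^2+noise^2)


def _simulate_metadata(cfg: SimulationConfig, rng: np.random.Generator) -> list[SampleInfo]:
    # moments match the packaged subject table
    spec = {
        "control": (cfg.n_control, "C", 66.9, 13.9, 3.95, 1.65, 6.82, 0.14, 7.31, 0.21, 2 / 11),
        "case": (cfg.n_case, "S", 45.2, 14.8, 5.78, 4.05, 6.79, 0.17, 7.39, 0.20, 3 / 9),
    }
    out = []
    for group, (n, pre, am, asd, pm, psd, hm, hsd, rm, rsd, pf) in spec.items():
        for i in range(n):
            out.append(
                SampleInfo(
                    sample_id=f"{pre}{i + 1:02d}",
                    group=group,  # type: ignore[arg-type]
                    age=float(np.clip(rng.normal(am, asd), 18, 95)),
                    sex="F" if rng.random() < pf else "M",
                    pmi=float(np.clip(rng.normal(pm, psd), 0.5, 24)),
                    ph=float(np.clip(rng.normal(hm, hsd), 6.0, 7.4)),
                    rin=float(np.clip(rng.normal(rm, rsd), 5.0, 10.0)),
                )
            )
    return out


def simulate_experiment(
    cfg: SimulationConfig,
) -> tuple[CtMatrix, list[SampleInfo], list[MiRNAAnnotation], SimulationTruth, EndoControlSet]:
    """Generate a raw CtMatrix, metadata, annotations and ground truth.

    Ct(sample, assay) = baseline(assay) + offset(sample)
                        - log2(fold) * [case & planted]
                        + loading * factor(sample) * [block member, block group]
                        + noise,
    with dropout cells recorded as undetectable.  Deterministic given
    ``cfg.seed`` (byte-identical outputs for equal configs).
    """
    rng = np.random.default_rng(cfg.seed)
    samples = _simulate_metadata(cfg, rng)
    sample_ids = [s.sample_id for s in samples]
    is_case = np.array([s.group == "case" for s in samples])

    p = 2 * cfg.n_assays_per_plate
    mirna_ids = [
        f"miR-sim-{chr(65 + i // cfg.n_assays_per_plate)}{i % cfg.n_assays_per_plate + 1:04d}"
        for i in range(p)
    ]
    plates = ["A" if i < cfg.n_assays_per_plate else "B" for i in range(p)]

    lo, hi = cfg.baseline_ct_range
    baseline = rng.uniform(lo, hi, size=p)
    offsets = rng.normal(0.0, cfg.sample_offset_sd, size=len(samples))

    ct = baseline[None, :] + offsets[:, None]
    de_truth: dict[str, float] = {}
    for idx, fold in cfg.planted_de:
        ct[is_case, idx] -= np.log2(fold)
        de_truth[mirna_ids[idx]] = fold

    block_pairs: dict[str, tuple[tuple[str, str], ...]] = {}
    block_members: dict[str, tuple[str, ...]] = {}
    expected_r: dict[str, float] = {}
    for group, idxs, loading in cfg.planted_blocks:
        in_group = is_case if group == "case" else ~is_case
        factor = rng.normal(0.0, 1.0, size=len(samples))
        for i in idxs:
            ct[in_group, i] += loading * factor[in_group]
        names = tuple(mirna_ids[i] for i in idxs)
        block_members[group] = names
        block_pairs[group] = tuple(
            (names[a], names[b]) for a in range(len(names)) for b in range(a + 1, len(names))
        )
        denom = loading**2 + cfg.noise_sd**2
        expected_r[group] = float(loading**2 / denom) if denom else 1.0

    ct += rng.normal(0.0, cfg.noise_sd, size=ct.shape)
    if cfg.covariate_coupling:
        ages = np.array([s.age for s in samples])
        ct[:, 0] += cfg.covariate_coupling * (ages - ages.mean())

    # endogenous controls: stable, no group effect; negative control: never amplifies
    ctrl_ids, ctrl_plates, ctrl_cols = [], [], []
    for plate in ("A", "B"):
        for name in _CONTROL_RNAS:
            ctrl_ids.append(f"{name}_{plate}")
            ctrl_plates.append(plate)
            ctrl_cols.append(22.0 + offsets + rng.normal(0.0, 0.3, size=len(samples)))
        ctrl_ids.append(f"{_NEGATIVE}_{plate}")
        ctrl_plates.append(plate)
        ctrl_cols.append(np.full(len(samples), np.nan))

    values = np.concatenate([ct, np.column_stack(ctrl_cols)], axis=1)
    assay_ids = mirna_ids + ctrl_ids
    plate_of_assay = pd.Series(plates + ctrl_plates, index=assay_ids)

    drop = rng.random(size=(len(samples), p)) < cfg.dropout
    values[:, :p][drop] = np.nan

    frame = pd.DataFrame(values, index=sample_ids, columns=assay_ids)
    matrix = CtMatrix(
        values=frame,
        detect_mask=frame.notna(),
        plate_of_assay=plate_of_assay,
        stage="raw",
    )

    annotations = [
        MiRNAAnnotation(
            assay_id=mirna_ids[i],
            mirbase_acc=f"MIMATSIM{i:07d}",
            plate=plates[i],
            chromosome=str(1 + i % 22),
            strand="sense" if i % 2 == 0 else "antisense",
        )
        for i in range(p)
    ]
    truth = SimulationTruth(
        de_assays=de_truth,
        block_pairs=block_pairs,
        block_members=block_members,
        sample_offsets=dict(zip(sample_ids, offsets.tolist())),
        expected_block_r=expected_r,
    )
    controls = EndoControlSet(
        normalizers=tuple(c for c in ctrl_ids if not c.startswith(_NEGATIVE)),
        negative_control_id=f"{_NEGATIVE}_A",
    )
    return matrix, samples, annotations, truth, controls


def negative_control_ids(controls: EndoControlSet) -> tuple[str, ...]:
    """All plate copies of the negative control (id or id with plate suffix)."""
    base = controls.negative_control_id.split("_")[0]
    return (controls.negative_control_id, f"{base}_A", f"{base}_B", base)


# ---------------------------------------------------------------------------
# packaged fixtures (subject table; significant-miRNA table)
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return importlib.resources.files("lcmirna.data").joinpath(name)


def table1_fixture() -> list[SampleInfo]:
    """The packaged 20-subject demographic table (11 controls, 9 cases)."""
    from .data_model import read_sample_table

    with importlib.resources.as_file(_data_path("table1_subjects.csv")) as p:
        return read_sample_table(p)


def table2_fixture() -> tuple[list[MiRNAAnnotation], pd.DataFrame]:
    """The packaged 13-row significant-miRNA table.

    Returns annotations plus a DataFrame (assay_id, mirbase_acc, plate,
    fold, raw_p, direction) with direction as the display arrow.
    """
    with importlib.resources.as_file(_data_path("table2_significant_mirnas.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"chromosome": str})
    annotations = [
        MiRNAAnnotation(
            assay_id=r.assay_id,
            mirbase_acc=r.mirbase_acc,
            plate=r.plate,
            chromosome=str(r.chromosome),
            strand=r.strand,
            seed=r.seed,
        )
        for r in df.itertuples()
    ]
    results = pd.DataFrame(
        {
            "assay_id": df["assay_id"],
            "mirbase_acc": df["mirbase_acc"],
            "plate": df["plate"],
            "fold": df["fold_change"].astype(float),
            "raw_p": df["p_value"].astype(float),
            "direction": df["regulation"].map({"up": "↑", "down": "↓"}),
        }
    )
    return annotations, results
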