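"""End-to-end orchestration: simulate/load -> preprocess -> DE -> networks.

:func:`run_pipeline` sequences the analysis in method order and writes a
report bundle: the significance table, the FDR curve, dendrogram +
leaf-ordered heatmap TSV, genomic-cluster JSON, case/control-specific
GraphML networks with degree summaries, the confound report, and a run
manifest (package version, seed, config hash).  Every stage logs its
assay in/out counts so the detectability funnel is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .coexpression import (
    degree_summary,
    export_network,
    pairwise_pearson,
    select_differential_edges,
)
from .confounds import confound_correlations, demographic_comparisons, sex_effect
from .data_model import CtMatrix, EndoControlSet, MiRNAAnnotation, SampleInfo
from .diffexpr import build_significance_table, rank_test, sam_permutation_fdr
from .preprocess import (
    endo_control_check,
    filter_detectable,
    fold_change,
    global_mean_center,
    median_normalize,
)
from .structure_analysis import genomic_clusters, heatmap_export, hierarchical_cluster

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and knobs for a full run; echoed into every manifest."""

    seed: int
    output_dir: str = "lcmirna_out"
    ct_threshold: float = 35.0
    min_fraction: float = 1.0
    p_cut: float = 0.05
    fdr_ceiling: float = 5.0
    n_perm: int = 1000
    r_sig: float = 0.7
    r_gap: float = 0.8
    alpha: float = 0.05
    per_plate_normalization: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.ct_threshold < 45:
            raise ValueError("ct_threshold outside (0, 45)")
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction outside (0, 1]")
        if not 0 < self.p_cut <= 1 or not 0 < self.alpha <= 1:
            raise ValueError("p_cut and alpha must be in (0, 1]")
        if self.r_gap <= 0:
            raise ValueError("r_gap must be positive")

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the destination path excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(
    cfg: PipelineConfig,
    ct: CtMatrix,
    samples: Sequence[SampleInfo],
    annotations: Sequence[MiRNAAnnotation],
    controls: EndoControlSet | None = None,
    negative_control_ids: Sequence[str] = (),
) -> dict[str, Path]:
    """Run the full analysis and write the report bundle to cfg.output_dir.

    Returns a dict mapping artifact names to paths.  Refuses to resume
    into a directory whose existing manifest carries a different config
    hash.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        prior = json.loads(manifest_path.read_text())
        if prior.get("config_hash") != cfg_hash:
            raise PipelineError(
                "manifest",
                f"output dir {out} holds results for config {prior.get('config_hash')}, "
                f"current config is {cfg_hash}; refusing to mix runs",
            )
    artifacts: dict[str, Path] = {}

    def _write_json(name: str, payload: dict) -> None:
        path = out / name
        payload = {"config_hash": cfg_hash, **payload}
        path.write_text(json.dumps(payload, indent=2, default=str))
        artifacts[name.removesuffix(".json")] = path

    # ---- preprocess -------------------------------------------------------
    try:
        de_filter = filter_detectable(
            ct,
            threshold=cfg.ct_threshold,
            min_fraction=cfg.min_fraction,
            samples=samples,
            negative_control_ids=negative_control_ids,
        )
        log.info(
            "detectability filter: %d assays in, %d retained, %d dropped",
            len(ct.assays), de_filter.n_retained, de_filter.n_dropped,
        )
        if controls is not None:
            present = [a for a in controls.normalizers if a in ct.assays]
            if present:
                endo = endo_control_check(ct.subset_assays(present), controls, samples)
                _write_json(
                    "endo_controls.json",
                    {
                        "per_group": {f"{k[0]}|{k[1]}": v for k, v in endo.per_group.items()},
                        "t_tests": endo.t_tests,
                    },
                )
        # strip control assays from the analysis matrix
        control_ids = set(controls.normalizers) if controls else set()
        analysis = de_filter.matrix.subset_assays(
            [a for a in de_filter.matrix.assays if a not in control_ids]
        )
        delta = median_normalize(analysis, per_plate=cfg.per_plate_normalization)
        centered = global_mean_center(analysis)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise PipelineError("preprocess", str(e)) from e

    # ---- differential expression -----------------------------------------
    try:
        fc = fold_change(delta, samples)
        meta = {s.sample_id: s.group for s in samples}
        case = [s for s in delta.samples if meta[s] == "case"]
        ctrl = [s for s in delta.samples if meta[s] == "control"]
        masked = delta.values.where(delta.detect_mask)
        pvals = {}
        for assay in delta.assays:
            x = masked.loc[case, assay].dropna()
            y = masked.loc[ctrl, assay].dropna()
            if len(x) < 2 or len(y) < 2:
                pvals[assay] = float("nan")
                continue
            pvals[assay] = rank_test(x, y).pvalue
        results = fc.assign(raw_p=pd.Series(pvals))
        sam = sam_permutation_fdr(
            delta, samples, n_perm=cfg.n_perm, seed=cfg.seed, fdr_ceiling=cfg.fdr_ceiling
        )
        results["called_significant"] = results.index.isin(sam.called)
        table = build_significance_table(results, annotations, p_cut=cfg.p_cut)
        sig_path = out / "significance_table.tsv"
        table.to_csv(sig_path, sep="\t", index=False)
        artifacts["significance_table"] = sig_path
        curve_path = out / "fdr_curve.csv"
        sam.curve.to_csv(curve_path, index=False)
        artifacts["fdr_curve"] = curve_path
        log.info("DE: %d/%d assays at p<=%.3g; %d called at FDR<=%.3g%%",
                 len(table), len(results), cfg.p_cut, len(sam.called), cfg.fdr_ceiling)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("diffexpr", str(e)) from e

    # ---- clustering -------------------------------------------------------
    try:
        dendros = hierarchical_cluster(delta, axis="both")
        tsv, png = heatmap_export(delta, dendros, out / "heatmap_ordered.tsv")
        artifacts["heatmap_tsv"], artifacts["heatmap_png"] = tsv, png
        sig_records = table.rename(columns={"mirna": "assay_id", "regulation": "direction"})
        clusters = genomic_clusters(sig_records, annotations)
        _write_json(
            "genomic_clusters.json",
            {
                "clusters": [
                    {
                        "chromosome": c.chromosome,
                        "members": list(c.members),
                        "strands": list(c.strands),
                        "directions": list(c.directions),
                        "concordance": c.concordance,
                    }
                    for c in clusters
                ]
            },
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("structure_analysis", str(e)) from e

    # ---- co-expression networks ------------------------------------------
    try:
        complete = centered.values.columns[centered.values.notna().all()]
        corr = pairwise_pearson(centered.subset_assays(list(complete)), samples)
        nets = {}
        for direction in ("case_specific", "control_specific"):
            net = select_differential_edges(
                corr, direction, r_sig=cfg.r_sig, r_gap=cfg.r_gap
            )
            nets[direction] = net
            gpath = export_network(net, out / f"network_{direction}.graphml", "graphml")
            export_network(net, out / f"network_{direction}.tsv", "edge_tsv")
            artifacts[f"network_{direction}"] = gpath
        _write_json(
            "degree_summaries.json",
            {d: degree_summary(n) for d, n in nets.items()},
        )
        log.info(
            "co-expression: %d/%d assays complete; case net %d nodes/%d edges, "
            "control net %d nodes/%d edges",
            len(complete), len(centered.assays),
            nets["case_specific"].graph.number_of_nodes(),
            nets["case_specific"].graph.number_of_edges(),
            nets["control_specific"].graph.number_of_nodes(),
            nets["control_specific"].graph.number_of_edges(),
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("coexpression", str(e)) from e

    # ---- confounds --------------------------------------------------------
    try:
        comparisons = demographic_comparisons(samples)
        demo = pd.DataFrame([c.__dict__ for c in comparisons])
        cors = confound_correlations(delta, samples, alpha=cfg.alpha)
        sexes = {s.sex for s in samples}
        sex = (
            sex_effect(delta, samples, alpha=cfg.alpha)
            if sexes == {"F", "M"}
            else pd.DataFrame()
        )
        conf_path = out / "confounds.tsv"
        with open(conf_path, "w") as fh:
            fh.write("# group comparisons (pooled t)\n")
            demo.to_csv(fh, sep="\t", index=False)
            fh.write("# covariate correlations\n")
            cors.to_csv(fh, sep="\t", index=False)
            fh.write("# sex effects\n")
            sex.to_csv(fh, sep="\t", index=False)
        artifacts["confounds"] = conf_path
    except Exception as e:  # noqa: BLE001
        raise PipelineError("confounds", str(e)) from e

    manifest = {
        "config_hash": cfg_hash,
        "config": asdict(cfg),
        "version": __version__,
        "python": platform.python_version(),
        "n_samples": len(samples),
        "n_assays_input": len(ct.assays),
        "n_assays_retained": de_filter.n_retained,
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest"] = manifest_path
    return artifacts
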