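"""End-to-end orchestration: PSM tables -> filters -> quantification ->
differential statistics -> panel selection -> PLS-DA ROC.

The pipeline mirrors the computational arm of the TMT glycoproteomics
workflow: per peptide class, PSMs pass the PIF / PEP-2D quality gates and
the 0% peptide-level target-decoy FDR filter, are summed into features and
median-normalized on the log2 scale.  An outlier channel is detected by PCA
on the intact-glycopeptide log2 matrix *before* per-channel centering (a
globally shifted channel is exactly what centering would mask) and removed
from every class.  Moderated-t contrasts are fitted per class, the panel
cascade is applied to the intact N-glycopeptides, and the panel is evaluated
by leave-one-out PLS-DA ROC at the requested panel sizes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import multivariate as mv
from . import panel as panel_mod
from . import quant, stats

logger = logging.getLogger("glycopanel")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All thresholds of the analysis in one place; defaults are the
    published operating points."""

    design: dict[str, str]  # channel label -> "case" | "control"
    tables: dict[str, pd.DataFrame] | None = None
    input_paths: dict[str, str] | None = None
    pif_min: float = 0.75
    pep2d_max: float = 0.001
    peptide_fdr_max: float = 0.0
    q_max: float = 0.25
    fc_up: float = 1.3
    fc_down: float = 0.77
    tol_ppm: float = 10.0
    normalization_center: str = "median"
    outlier_handling: str | list[str] = "auto"  # "auto", "none" or explicit channel list
    k_mad: float = 3.0
    panel_sizes: tuple[int, ...] = (3, 5, 10, 20, 28, 56)
    whitelist: frozenset[str] | None = None
    output_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pif_min", "pep2d_max"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not (0 <= self.peptide_fdr_max < 1) or not (0 < self.q_max <= 1):
            raise ValueError("FDR thresholds out of range")
        if not (self.fc_down < 1 < self.fc_up):
            raise ValueError("fold-change gates must bracket 1")
        if not self.design:
            raise ValueError("design must map channels to groups")


@dataclass
class PipelineResult:
    matrices: dict[str, quant.QuantMatrix]
    normalized: dict[str, quant.QuantMatrix]
    diff: dict[str, pd.DataFrame]
    class_shares: pd.DataFrame | None
    outliers: list[str]
    pca: mv.PcaResult | None
    panel: pd.DataFrame
    roc: list[mv.RocResult]
    manifest: dict = field(default_factory=dict)


def _load_tables(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    if config.tables is not None:
        return config.tables
    if config.input_paths is None:
        raise ValueError("PipelineConfig needs either tables or input_paths")
    return {cls: quant.read_psm_table(path) for cls, path in config.input_paths.items()}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis; deterministic given the config (and its seed).

    When ``config.output_dir`` is set, every stage's table is written as
    tab-separated text together with a ``manifest.json`` recording the
    thresholds and stage outputs.
    """
    tables = _load_tables(config)
    channels = tuple(config.design)
    manifest: dict = {
        "thresholds": {
            "pif_min": config.pif_min, "pep2d_max": config.pep2d_max,
            "peptide_fdr_max": config.peptide_fdr_max, "q_max": config.q_max,
            "fc_up": config.fc_up, "fc_down": config.fc_down,
            "normalization_center": config.normalization_center,
            "outlier_handling": str(config.outlier_handling), "k_mad": config.k_mad,
            "panel_sizes": list(config.panel_sizes), "seed": config.seed,
        },
        "stages": [],
    }

    matrices: dict[str, quant.QuantMatrix] = {}
    for cls, table in tables.items():
        try:
            filtered = quant.filter_psms(
                table, pif_min=config.pif_min, pep2d_max=config.pep2d_max,
                apply_pep2d=(cls != "nonmod"),
            )
            filtered = quant.fdr_filter(filtered, peptide_fdr_max=config.peptide_fdr_max)
            matrices[cls] = quant.aggregate_to_features(
                filtered, peptide_class=cls, groups=config.design, channels=channels
            )
        except Exception as exc:
            raise RuntimeError(f"stage quantify[{cls}] failed: {exc}") from exc
        logger.info("quantify[%s]: %d PSMs -> %d features", cls, len(table), len(matrices[cls].values))
        manifest["stages"].append(
            {"stage": f"quantify[{cls}]", "n_psms_in": len(table), "n_features": len(matrices[cls].values)}
        )

    # Outlier-channel detection on log2 intensities before per-channel
    # centering (centering would absorb a global channel shift).
    outliers: list[str] = []
    pca_res: mv.PcaResult | None = None
    if config.outlier_handling == "auto":
        intact = matrices["intact_n"]
        log2 = np.log2(intact.values.where(intact.values > 0))
        pca_res = mv.pca(log2.T)
        outliers = mv.detect_outlier_samples(pca_res, k_mad=config.k_mad)
    elif isinstance(config.outlier_handling, (list, tuple)):
        outliers = list(config.outlier_handling)
    manifest["stages"].append({"stage": "outlier_detection", "removed_channels": outliers})
    logger.info("outlier channels removed: %s", outliers or "none")
    if outliers:
        matrices = {cls: m.drop_channels(outliers) for cls, m in matrices.items()}

    normalized = {
        cls: quant.normalize(m, center=config.normalization_center) for cls, m in matrices.items()
    }

    diff: dict[str, pd.DataFrame] = {}
    for cls, m in normalized.items():
        try:
            diff[cls] = stats.fit_moderated_t(m)
        except Exception as exc:
            raise RuntimeError(f"stage diff[{cls}] failed: {exc}") from exc
        manifest["stages"].append({"stage": f"diff[{cls}]", "n_tested": len(diff[cls])})

    class_shares = None
    if "intact_n" in matrices and len(matrices["intact_n"].values):
        class_shares, _ = stats.summarize_glyco_classes(matrices["intact_n"])

    corr = panel_mod.corroborate_sites(matrices["intact_n"].meta, matrices["de_n"].meta)
    panel = panel_mod.select_panel(
        diff["intact_n"], matrices["intact_n"].meta, corroboration=corr,
        whitelist=config.whitelist, q_max=config.q_max, fc_up=config.fc_up, fc_down=config.fc_down,
    )
    panel = panel_mod.crossref_protein_level(panel, diff["nonmod"], matrices["nonmod"].meta)
    manifest["stages"].append({"stage": "panel_selection", "n_entries": len(panel)})
    logger.info("panel: %d entries", len(panel))

    ranking = mv.rank_features(diff["intact_n"])
    sizes = [s for s in config.panel_sizes if s <= len(ranking)]
    roc_matrix = normalized["intact_n"].values.T  # samples x features
    labels = {c: g for c, g in config.design.items() if c not in set(outliers)}
    roc = mv.plsda_roc(roc_matrix, labels, sizes, ranking)
    manifest["stages"].append(
        {"stage": "plsda_roc", "aucs": {str(r.panel_size): r.auc for r in roc}}
    )

    result = PipelineResult(
        matrices=matrices, normalized=normalized, diff=diff, class_shares=class_shares,
        outliers=outliers, pca=pca_res, panel=panel, roc=roc, manifest=manifest,
    )
    if config.output_dir is not None:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    float_fmt = "%.6g"
    for cls, m in result.normalized.items():
        m.to_tsv(out / f"quant_{cls}.tsv")
    for cls, d in result.diff.items():
        d.to_csv(out / f"diff_{cls}.tsv", sep="\t", float_format=float_fmt)
    result.panel.to_csv(out / "panel.tsv", sep="\t", float_format=float_fmt)
    if result.class_shares is not None:
        result.class_shares.to_csv(out / "glycan_class_shares.tsv", sep="\t", float_format=float_fmt)
    roc_table = pd.DataFrame(
        [{"panel_size": r.panel_size, "auc": r.auc} for r in result.roc]
    )
    roc_table.to_csv(out / "roc.tsv", sep="\t", index=False, float_format=float_fmt)
    if result.pca is not None:
        result.pca.scores.to_csv(out / "pca_scores.tsv", sep="\t", float_format=float_fmt)
    result.manifest["outputs"] = sorted(p.name for p in out.glob("*.tsv"))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=str))
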