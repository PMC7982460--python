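"""End-to-end orchestration of the gene-pair prognostic analysis.

``fit`` mode rebuilds a risk model from an expression matrix and clinical
table: differential expression -> per-sample immune/stromal scoring ->
co-expression modules -> immune-module gene screen -> pair construction and
imbalance filter -> univariate Cox screen -> lasso-Cox selection -> ROC
cutoff -> risk stratification.  ``score`` mode applies an existing model
(e.g. the packaged published one) to a new cohort without any fitting.

Every stage writes its table to the output directory, and a JSON manifest
records the filter funnel (DEG count, module-gene count, built / balanced /
screened / selected pair counts), the parameters used, and the seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpr, dge, signatures, survival
from .pairs import build_pairs, filter_pairs
from .survival import RiskModel

__all__ = ["PipelineConfig", "run_pipeline", "read_expression", "read_clinical"]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples TSV, first column = gene identifiers."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Per-sample clinical TSV indexed by sample_id (time, event, covariates)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "time" not in df.columns or "event" not in df.columns:
        raise ValueError("clinical table needs 'time' and 'event' columns")
    return df


@dataclass
class PipelineConfig:
    expression: str
    clinical: str
    gene_sets: str  # GMT with at least an 'immune' set (and optionally 'stromal')
    outdir: str
    seed: int
    mode: str = "fit"  # 'fit' or 'score'
    model_file: str | None = None  # required in score mode
    group_col: str = "group"
    # stage parameters (defaults mirror each module's)
    fc_threshold: float = 0.5
    de_alpha: float = 0.05
    ssgsea_exponent: float = 0.25
    r2_target: float = 0.9
    min_module_size: int = 30
    cut_height: float = 0.7
    mm_min: float = 0.5
    gs_min: float = 0.5
    min_minority_fraction: float = 0.2
    cox_alpha: float = 0.05
    lasso_repeats: int = 1000
    lasso_folds: int = 10
    roc_horizon: float = 60.0  # same unit as the clinical time column
    signature_matrix: str | None = None
    edge_list: str | None = None
    deconv_permutations: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for key in ("expression", "clinical", "gene_sets"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"{key} path does not exist: {p}")
        if self.mode not in ("fit", "score"):
            raise ValueError("mode must be 'fit' or 'score'")
        if self.mode == "score" and not self.model_file:
            raise ValueError("score mode requires model_file")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured analysis; returns the manifest dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr = read_expression(config.expression)
    clinical = read_clinical(config.clinical)
    clinical = clinical.loc[[s for s in expr.columns if s in clinical.index]]
    expr = expr[clinical.index]
    sets = signatures.read_gmt(config.gene_sets)

    manifest: dict = {
        "mode": config.mode,
        "seed": config.seed,
        "parameters": asdict(config),
        "counts": {},
        "outputs": {},
    }

    def _write(name: str, obj) -> None:
        path = outdir / name
        if isinstance(obj, pd.DataFrame) or isinstance(obj, pd.Series):
            obj.to_csv(path, sep="\t")
        manifest["outputs"][name.split(".")[0]] = str(path)

    # per-sample immune/stromal scores (used as WGCNA traits in fit mode and
    # available as covariates in both modes)
    scores = signatures.ssgsea_score(expr, sets, exponent=config.ssgsea_exponent)
    _write("sample_scores.tsv", scores)

    if config.mode == "score":
        model = RiskModel.from_json(config.model_file)
        rs = survival.score_expression(model, expr)
    else:
        model, rs = _fit_model(config, expr, clinical, scores, manifest, _write)

    _write("risk_scores.tsv", rs.to_frame())
    if model.cutoff is None:
        raise RuntimeError("model has no dichotomization cutoff")
    groups = survival.assign_risk_groups(rs, model.cutoff)
    _write("risk_groups.tsv", groups.to_frame())
    manifest["counts"]["high_risk"] = int((groups == "high").sum())
    manifest["counts"]["low_risk"] = int((groups == "low").sum())

    if groups.nunique() == 2:
        _, chi2, p = survival.km_logrank(clinical, groups)
        manifest["km_logrank"] = {"chi2": chi2, "p": p}
    else:
        warnings.warn("single risk group at this cutoff; log-rank skipped")
        manifest["km_logrank"] = None

    if config.signature_matrix and groups.nunique() == 2:
        from . import deconv as _deconv

        sig = pd.read_csv(config.signature_matrix, sep="\t", index_col=0)
        dec = _deconv.deconvolve(
            expr, sig, n_perm=config.deconv_permutations,
            seed=config.seed, from_log2=True,
        )
        confident = _deconv.filter_confident(dec)
        manifest["counts"]["confident_samples"] = len(confident.samples)
        _write("cell_fractions.tsv", confident.fractions)
        kept_groups = groups.loc[confident.samples]
        if kept_groups.nunique() == 2:
            diff = _deconv.group_difference(confident, kept_groups)
            _write("cell_fraction_tests.tsv", diff)

    if config.edge_list and groups.nunique() == 2:
        from . import enrich as _enrich

        ranking = _enrich.rank_by_group_log2fc(expr, groups, positive_label="high")
        gsea = _enrich.gsea_preranked(ranking, sets, n_perm=1000, seed=config.seed)
        _write("gsea.tsv", gsea)
        hubs = _enrich.hub_genes(_enrich.read_edge_list(config.edge_list))
        _write("hub_genes.tsv", hubs.to_frame())
        manifest["key_genes"] = _enrich.intersect_key_genes(hubs, model)

    model_path = outdir / "risk_model.json"
    model.to_json(model_path)
    manifest["outputs"]["risk_model"] = str(model_path)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    manifest["outputs"]["manifest"] = str(outdir / "manifest.json")
    return manifest


def _fit_model(config, expr, clinical, scores, manifest, _write):
    if config.group_col not in clinical.columns:
        raise ValueError(f"clinical table lacks group column {config.group_col!r}")
    de = dge.moderated_de(
        expr, clinical[config.group_col], config.fc_threshold, config.de_alpha
    )
    _write("dge.tsv", de.table)
    de_genes = de.de_genes
    manifest["counts"]["de_genes"] = len(de_genes)
    if len(de_genes) < config.min_module_size:
        raise RuntimeError("too few differentially expressed genes for module detection")

    deg_expr = expr.loc[de_genes]
    scan = coexpr.pick_soft_threshold(deg_expr, r2_target=config.r2_target)
    manifest["soft_threshold"] = {
        "chosen_power": scan.chosen_power,
        "scale_free_r2": float(scan.table.loc[scan.chosen_power, "scale_free_r2"]),
    }
    adj = coexpr.adjacency_matrix(deg_expr, scan.chosen_power)
    tom = coexpr.topological_overlap(adj)
    assign = coexpr.detect_modules(
        tom, deg_expr, traits=scores,
        min_module_size=config.min_module_size, cut_height=config.cut_height,
    )
    _write("modules.tsv", assign.to_frame())
    mt = coexpr.module_trait(assign, scores)
    _write("module_trait.tsv", mt.set_index(["module", "trait"]))
    if not assign.modules:
        raise RuntimeError("no co-expression module detected")
    immune_rows = mt[mt["trait"] == "immune"]
    target = immune_rows.loc[immune_rows["correlation"].abs().idxmax(), "module"]
    manifest["immune_module"] = str(target)

    screened = coexpr.screen_genes(
        assign, target, trait="immune", mm_min=config.mm_min, gs_min=config.gs_min
    )
    manifest["counts"]["module_genes"] = int((assign.module_labels == target).sum())
    manifest["counts"]["screened_genes"] = len(screened)
    if len(screened) < 2:
        raise RuntimeError("fewer than 2 screened genes; cannot build pairs")

    pim = build_pairs(expr, screened)
    manifest["counts"]["built_pairs"] = len(pim.pairs)
    pim = filter_pairs(pim, config.min_minority_fraction)
    manifest["counts"]["balanced_pairs"] = len(pim.pairs)
    _write("pairs.tsv", pim.indicators)

    screen_tab = survival.univariate_cox_screen(pim, clinical, alpha=config.cox_alpha)
    _write("cox_screen.tsv", screen_tab)
    manifest["counts"]["screened_pairs"] = len(screen_tab)
    if len(screen_tab) == 0:
        raise RuntimeError("no pair passed the univariate Cox screen")

    kept = pim.indicators.loc[screen_tab.index]
    model = survival.lasso_cox_select(
        kept, clinical,
        n_repeats=config.lasso_repeats, n_folds=config.lasso_folds, seed=config.seed,
    )
    manifest["counts"]["selected_pairs"] = len(model.pairs)
    if not model.pairs:
        raise RuntimeError("lasso selected an empty model")

    rs = survival.risk_score(model, kept)
    roc = survival.time_roc(rs, clinical, horizon=config.roc_horizon)
    model.cutoff = roc.best_cutoff
    manifest["time_roc"] = {"horizon": config.roc_horizon, "auc": roc.auc,
                            "best_cutoff": roc.best_cutoff}
    return model, rs
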