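"""End-to-end orchestration: simulate/screen/pair/fit/evaluate with a
single config, structured logging, and a reproducibility manifest.

Every stage reads its inputs from the output directory when not run in the
same process, so stages can be skipped or resumed. The manifest records
package version, seed, thresholds, input checksums and per-stage output
paths; identical configs and seeds give identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (
    clinical_association,
    four_group_analysis,
    independent_prognostic,
    km_estimate,
    logrank,
    multi_marker_roc,
    optimal_cutoff,
    time_roc,
)
from .io import (
    ClinicalTable,
    DataError,
    ExpressionMatrix,
    read_clinical,
    read_expression,
    read_gene_list,
    screen_results_frame,
    split_by_biotype,
    write_clinical,
    write_expression,
)
from .modeling import (
    RiskModel,
    RiskScores,
    assign_groups,
    fit_expression_model,
    fit_multicox,
    lasso_select,
    risk_score,
    unicox_pairs,
)
from .pairing import build_pair_matrix, write_pair_matrix
from .screening import (
    core_set,
    cox_fits_frame,
    differential_screen,
    identify_irlncrnas,
    unicox_screen,
)
from .simulate import SimulationConfig, ground_truth, simulate_cohort

logger = logging.getLogger("irlncpair")

ALL_STAGES = ("simulate", "screen", "pair", "fit", "evaluate")


@dataclass
class PipelineConfig:
    """Paths, thresholds and seed for a full pipeline run.

    Threshold defaults are the method's canonical values: immune
    co-expression r > 0.5 at p < 0.001, differential |logFC| > 2 at
    p < 0.05, univariate Cox p < 0.05, pair-validity frequency window
    (0.2, 0.8), lasso selection frequency > 0.5, ROC horizons 1/5/10
    years with the cutoff taken on the 5-year curve.
    """

    outdir: str = "irlncpair_out"
    expression: str | None = None
    annotation: str | None = None
    clinical: str | None = None
    immune_list: str | None = None
    labels: str | None = None
    simulate: dict | None = None  # SimulationConfig overrides; None = real inputs

    r_min: float = 0.5
    corr_p: float = 0.001
    logfc_min: float = 2.0
    de_p: float = 0.05
    unicox_p: float = 0.05
    pair_p: float = 0.05
    pair_freq_min: float = 0.2
    lasso_repeats: int = 1000
    lasso_folds: int = 10
    lasso_freq_threshold: float = 0.5
    roc_horizons: tuple = (1.0, 5.0, 10.0)
    cutoff_horizon: float = 5.0
    time_unit: str = "years"
    alpha: float = 0.05
    seed: int = 0
    plots: bool = False

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("r_min", 0, 1), ("corr_p", 0, 1), ("de_p", 0, 1),
            ("unicox_p", 0, 1), ("pair_p", 0, 1), ("pair_freq_min", 0, 0.5),
            ("lasso_freq_threshold", 0, 1), ("alpha", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise DataError(f"{name}={v} outside [{lo}, {hi}]")
        if self.lasso_repeats < 1 or self.lasso_folds < 2:
            raise DataError("lasso_repeats >= 1 and lasso_folds >= 2 required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config key(s): {sorted(unknown)}")
        if "roc_horizons" in raw:
            raw["roc_horizons"] = tuple(float(h) for h in raw["roc_horizons"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roc_horizons"] = list(self.roc_horizons)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _sim_config(cfg: PipelineConfig) -> SimulationConfig:
    overrides = dict(cfg.simulate or {})
    if "planted_pairs" in overrides:
        overrides["planted_pairs"] = [tuple(p) for p in overrides["planted_pairs"]]
    overrides.setdefault("seed", cfg.seed)
    return SimulationConfig(**overrides)


# ---------------------------------------------------------------------------
# stage implementations (each loads inputs from outdir when needed)
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: PipelineConfig, out: Path, ctx: dict) -> list:
    sim = _sim_config(cfg)
    expr, clin, immune = simulate_cohort(sim)
    truth = ground_truth(sim)
    write_expression(expr, out / "expression.tsv")
    expr.sample_class.to_csv(out / "sample_labels.tsv", sep="\t", header=False)
    expr.gene_biotype.to_csv(out / "gene_biotypes.tsv", sep="\t", header=False)
    write_clinical(clin, out / "clinical.tsv")
    (out / "immune_genes.txt").write_text("\n".join(sorted(immune.members)) + "\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "immune_coupled": truth["immune_coupled"],
                "de_genes": truth["de_genes"],
                "planted_pairs": [list(p) for p in truth["planted_pairs"]],
            },
            fh, indent=1,
        )
    ctx.update(expr=expr, clin=clin, immune=immune)
    return ["expression.tsv", "sample_labels.tsv", "gene_biotypes.tsv",
            "clinical.tsv", "immune_genes.txt", "truth.json"]


def _load_inputs(cfg: PipelineConfig, out: Path, ctx: dict) -> None:
    if "expr" in ctx:
        return
    if cfg.simulate is not None or cfg.expression is None:
        # resume from a prior simulate stage
        values = pd.read_csv(out / "expression.tsv", sep="\t", index_col=0,
                             float_precision="round_trip")
        biotype = pd.read_csv(out / "gene_biotypes.tsv", sep="\t", header=None,
                              index_col=0).iloc[:, 0]
        labels = pd.read_csv(out / "sample_labels.tsv", sep="\t", header=None,
                             index_col=0).iloc[:, 0]
        ctx["expr"] = ExpressionMatrix(values, biotype, labels)
        ctx["clin"] = read_clinical(out / "clinical.tsv", time_unit=cfg.time_unit)
        ctx["immune"] = read_gene_list(out / "immune_genes.txt")
    else:
        for name, p in (("expression", cfg.expression),
                        ("annotation", cfg.annotation),
                        ("clinical", cfg.clinical),
                        ("immune list", cfg.immune_list)):
            if p is None or not Path(p).exists():
                raise DataError(f"missing {name} file: {p!r}")
        ctx["expr"] = read_expression(cfg.expression, cfg.annotation, cfg.labels)
        ctx["clin"] = read_clinical(cfg.clinical, time_unit=cfg.time_unit)
        ctx["immune"] = read_gene_list(cfg.immune_list)


def _stage_screen(cfg: PipelineConfig, out: Path, ctx: dict) -> list:
    _load_inputs(cfg, out, ctx)
    lnc, mrna = split_by_biotype(ctx["expr"])
    corr = identify_irlncrnas(lnc, mrna, ctx["immune"], cfg.r_min, cfg.corr_p)
    ir_ids = [r.feature_id for r in corr if r.passed]
    if not ir_ids:
        raise DataError("no immune-related lncRNAs passed the correlation screen")
    irlnc = lnc.subset_genes(ir_ids)
    de = differential_screen(irlnc, cfg.logfc_min, cfg.de_p)
    risk = unicox_screen(irlnc, ctx["clin"], cfg.unicox_p)
    core = core_set(de, risk)
    screen_results_frame(corr).to_csv(out / "screen_correlation.tsv", sep="\t")
    screen_results_frame(de).to_csv(out / "screen_differential.tsv", sep="\t")
    cox_fits_frame(risk).to_csv(out / "screen_unicox.tsv", sep="\t")
    (out / "core_irlncrnas.txt").write_text("\n".join(sorted(core.members)) + "\n")
    ctx.update(lnc=lnc, core=core)
    return ["screen_correlation.tsv", "screen_differential.tsv",
            "screen_unicox.tsv", "core_irlncrnas.txt"]


def _load_core(cfg: PipelineConfig, out: Path, ctx: dict) -> None:
    _load_inputs(cfg, out, ctx)
    if "core" not in ctx:
        ctx["core"] = read_gene_list(out / "core_irlncrnas.txt", name="core_irlncRNA")
    if "lnc" not in ctx:
        ctx["lnc"], _ = split_by_biotype(ctx["expr"])


def _stage_pair(cfg: PipelineConfig, out: Path, ctx: dict) -> list:
    _load_core(cfg, out, ctx)
    expr, clin = ctx["expr"], ctx["clin"]
    cohort = [s for s in expr.tumor_samples() if s in clin.sample_ids]
    core_expr = ctx["lnc"].subset_genes(sorted(ctx["core"].members))
    pm = build_pair_matrix(core_expr, cfg.pair_freq_min, samples=cohort)
    write_pair_matrix(pm, out / "pair_matrix.tsv", out / "pair_matrix.json")
    ctx["pm"] = pm
    return ["pair_matrix.tsv", "pair_matrix.json"]


def _load_pairs(cfg: PipelineConfig, out: Path, ctx: dict) -> None:
    if "pm" in ctx:
        return
    _load_core(cfg, out, ctx)
    _stage_pair(cfg, out, ctx)  # cheap and deterministic; rebuild from core


def _stage_fit(cfg: PipelineConfig, out: Path, ctx: dict) -> list:
    _load_pairs(cfg, out, ctx)
    pm, clin = ctx["pm"], ctx["clin"]
    pair_fits = unicox_pairs(pm, clin, cfg.pair_p)
    cox_fits_frame(pair_fits).to_csv(out / "pair_unicox.tsv", sep="\t")
    candidates = pm.indicators.loc[[f.feature_id for f in pair_fits if f.passed]]
    if candidates.shape[0] < 2:
        raise DataError("fewer than 2 prognostic pairs; cannot run lasso")
    sel = lasso_select(
        candidates, clin,
        n_repeats=cfg.lasso_repeats, k_folds=cfg.lasso_folds,
        freq_threshold=cfg.lasso_freq_threshold, seed=cfg.seed,
    )
    sel.frequencies.to_csv(out / "lasso_frequencies.tsv", sep="\t",
                           header=["frequency"])
    model = fit_multicox(pm.indicators.loc[sel.selected], clin, kind="pair")
    model.to_json(out / "pair_model.json")
    scores = risk_score(model, pm.indicators)
    roc = time_roc(scores, clin, cfg.cutoff_horizon)
    cut = optimal_cutoff(roc)
    scores = assign_groups(scores, cut, rule="roc_optimal")

    sig_genes = model.signature_genes()
    sig_expr = ctx["lnc"].values.loc[sig_genes, pm.sample_ids]
    exp_model, exp_scores = fit_expression_model(sig_expr, clin)
    exp_model.to_json(out / "expression_model.json")

    for name, sc in (("pair", scores), ("expression", exp_scores)):
        pd.DataFrame({"score": sc.scores, "group": sc.group}).to_csv(
            out / f"{name}_scores.tsv", sep="\t", index_label="sample_id"
        )
    ctx.update(pair_model=model, pair_scores=scores,
               exp_model=exp_model, exp_scores=exp_scores)
    return ["pair_unicox.tsv", "lasso_frequencies.tsv", "pair_model.json",
            "pair_scores.tsv", "expression_model.json", "expression_scores.tsv"]


def _load_fit(cfg: PipelineConfig, out: Path, ctx: dict) -> None:
    if "pair_scores" in ctx:
        return
    _load_pairs(cfg, out, ctx)
    ctx["pair_model"] = RiskModel.from_json(out / "pair_model.json")
    ctx["exp_model"] = RiskModel.from_json(out / "expression_model.json")
    for key, name in (("pair_scores", "pair"), ("exp_scores", "expression")):
        df = pd.read_csv(out / f"{name}_scores.tsv", sep="\t", index_col=0)
        ctx[key] = RiskScores(df["score"], df["group"])


def _stage_evaluate(cfg: PipelineConfig, out: Path, ctx: dict) -> list:
    _load_fit(cfg, out, ctx)
    clin = ctx["clin"]
    scores, exp_scores = ctx["pair_scores"], ctx["exp_scores"]
    shared = [s for s in scores.sample_ids if s in clin.sample_ids]
    sub = clin.data.loc[shared]

    summary: dict = {"horizons": {}}
    for h in cfg.roc_horizons:
        try:
            roc = time_roc(scores, clin, h)
            summary["horizons"][str(h)] = {"auc": roc.auc,
                                           "optimal_cutoff": optimal_cutoff(roc)}
        except DataError as exc:
            summary["horizons"][str(h)] = {"error": str(exc)}
    grp = scores.group.loc[shared].to_numpy()
    chi2, p = logrank(grp, sub["os_time"], sub["os_event"])
    summary["km_logrank"] = {"chi2": chi2, "p_value": p,
                             "n_high": int((grp == "high").sum()),
                             "n_low": int((grp == "low").sum())}
    mroc = multi_marker_roc(scores, clin, cfg.cutoff_horizon)
    summary["multi_marker_auc"] = {k: v.auc for k, v in mroc.items()}

    assoc = clinical_association(scores, clin)
    assoc.to_csv(out / "clinical_association.tsv", sep="\t")
    uni, multi = independent_prognostic(scores, clin)
    uni.to_csv(out / "prognostic_unicox.tsv", sep="\t")
    multi.to_csv(out / "prognostic_multicox.tsv", sep="\t")

    fg = four_group_analysis(scores, exp_scores, clin)
    summary["four_group"] = {
        "global_chi2": fg.global_test[0], "global_p": fg.global_test[1],
        "sizes": {g: int((fg.labels == g).sum()) for g in fg.curves},
        "empty_subgroups": fg.empty_subgroups,
    }
    fg.pairwise.to_csv(out / "four_group_pairwise.tsv", sep="\t", index=False)

    with open(out / "evaluation.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    files = ["clinical_association.tsv", "prognostic_unicox.tsv",
             "prognostic_multicox.tsv", "four_group_pairwise.tsv",
             "evaluation.json"]
    if cfg.plots:
        files += _write_plots(cfg, out, ctx)
    ctx["evaluation"] = summary
    return files


def _write_plots(cfg: PipelineConfig, out: Path, ctx: dict) -> list:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    clin, scores = ctx["clin"], ctx["pair_scores"]
    fig, ax = plt.subplots()
    for h in cfg.roc_horizons:
        try:
            roc = time_roc(scores, clin, h)
        except DataError:
            continue
        order = np.argsort(1 - roc.spec)
        ax.plot((1 - roc.spec)[order], roc.sens[order],
                label=f"{h:g}y AUC={roc.auc:.3f}")
    ax.plot([0, 1], [0, 1], "k:", lw=0.5)
    ax.set_xlabel("1 - specificity"); ax.set_ylabel("sensitivity"); ax.legend()
    fig.savefig(out / "roc.png", dpi=120); plt.close(fig)

    fig, ax = plt.subplots()
    shared = [s for s in scores.sample_ids if s in clin.sample_ids]
    sub = clin.data.loc[shared]
    for lab in ("high", "low"):
        m = (scores.group.loc[shared] == lab).to_numpy()
        km = km_estimate(sub.loc[m, "os_time"], sub.loc[m, "os_event"], lab)
        ax.step(np.concatenate([[0], km.times]), np.concatenate([[1], km.surv]),
                where="post", label=lab)
    ax.set_xlabel(f"time ({cfg.time_unit})"); ax.set_ylabel("S(t)"); ax.legend()
    fig.savefig(out / "km.png", dpi=120); plt.close(fig)

    fig, ax = plt.subplots()
    rank = scores.scores.loc[shared].sort_values()
    colors = np.where(sub.loc[rank.index, "os_event"] == 1, "tab:red", "tab:blue")
    ax.scatter(range(len(rank)), rank.to_numpy(), c=colors, s=4)
    ax.axhline(scores.cutoff, color="k", lw=0.5)
    ax.set_xlabel("patients ranked by risk score"); ax.set_ylabel("risk score")
    fig.savefig(out / "risk_scatter.png", dpi=120); plt.close(fig)
    return ["roc.png", "km.png", "risk_scatter.png"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "screen": _stage_screen,
    "pair": _stage_pair,
    "fit": _stage_fit,
    "evaluate": _stage_evaluate,
}


def run_pipeline(cfg: PipelineConfig, stages=None) -> dict:
    """Run the requested stages (default: all applicable) and write a manifest.

    Returns the manifest dict. A stage failure is recorded in the manifest
    before the error propagates.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if stages is None:
        stages = list(ALL_STAGES) if cfg.simulate is not None or cfg.expression is None \
            else [s for s in ALL_STAGES if s != "simulate"]
    bad = set(stages) - set(ALL_STAGES)
    if bad:
        raise DataError(f"unknown stage(s): {sorted(bad)}")

    manifest: dict = {
        "package": "irlncpair",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": {},
    }
    input_files = [p for p in (cfg.expression, cfg.annotation, cfg.clinical,
                               cfg.immune_list, cfg.labels) if p]
    manifest["input_checksums"] = {
        p: _sha256(Path(p)) for p in input_files if Path(p).exists()
    }
    ctx: dict = {}
    try:
        for stage in [s for s in ALL_STAGES if s in stages]:
            logger.info("=== stage %s ===", stage)
            files = _STAGE_FUNCS[stage](cfg, out, ctx)
            manifest["stages"][stage] = {
                "outputs": {f: _sha256(out / f) for f in files}
            }
    except Exception as exc:
        manifest["error"] = {"stage": stage, "message": str(exc)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
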