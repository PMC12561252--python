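"""End-to-end orchestration: simulate/load -> QC -> maps -> stats -> model.

One :func:`run_pipeline` call reproduces the whole workflow on a synthetic
or file cohort and writes diffable CSV/TFQ-1 artifacts.  A single global
seed fans out to every stochastic stage by fixed offsets, so one number
reproduces everything.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tfq_io
from .core import Cohort, TearFilmMap
from .mapping import (
    DEFAULT_ZONE_RADIUS,
    build_pivot_layout,
    difference_map,
    extract_pivots,
    global_mean,
    group_mean_map,
    lowpass_filter,
    make_standard_grid,
    record_qc,
    record_passes_qc,
    resample_to_grid,
)
from .nn import TrainOptions, evaluate, grid_search, init_model, split_data, train_lm
from .stats import group_correlation, pointwise_signed_rank_map, summarize_distribution
from .synth import default_params, generate_cohort

logger = logging.getLogger("tearmap")

GROUPS = ("G1", "G2", "G3")

#: Default pre-extraction smoothing (mm, degrees); mild, noise-oriented.
DEFAULT_SMOOTHING = (0.25, 10.0)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; defaults reproduce the packaged study."""

    seed: int = 0
    manifest: str | None = None          # load a file cohort instead of simulating
    generator_overrides: dict = field(default_factory=dict)
    grid_spec: tuple = (5.0, 50, 180)    # max_radius, n_rings, n_meridians
    min_coverage: float = 1.0
    zone_radius: float = DEFAULT_ZONE_RADIUS
    alpha: float = 0.05
    smoothing: tuple = DEFAULT_SMOOTHING
    architecture: tuple = (5, 8)
    train_opts: TrainOptions = field(default_factory=lambda: TrainOptions(max_epochs=200))
    run_grid_search: bool = False
    grid_search_opts: TrainOptions = field(
        default_factory=lambda: TrainOptions(max_epochs=20))
    n_boot: int = 10_000
    eyes: tuple = ("OD", "OS")
    outdir: str | None = None


@dataclass
class RunReport:
    config: RunConfig
    global_means: pd.DataFrame          # per eye x group summaries
    correlations: pd.DataFrame          # per eye x group Spearman R + CI
    significance: dict                  # (eye, group) -> SignificanceMap
    significance_summary: pd.DataFrame  # rejected fractions per annulus
    mean_maps: dict                     # (eye, group, session) -> TearFilmMap
    difference_maps: dict               # (eye, group) -> TearFilmMap
    models: dict                        # eye -> MLPModel
    model_eval: pd.DataFrame            # per eye x partition R / RMSE
    grid_search_tables: dict            # eye -> DataFrame (when enabled)
    qc_excluded: pd.DataFrame           # one row per excluded map
    cohorts: dict                       # eye -> Cohort (QC-passing records)


def _derived_seed(seed: int, offset: int) -> int:
    return int((seed * 1_000_003 + offset) % (2**31))


def build_pivot_dataset(cohort: Cohort, eye: str, smoothing=DEFAULT_SMOOTHING,
                        min_coverage: float = 1.0):
    """Per-eye supervised dataset: wear days -> 121 post-treatment pivot values.

    Maps are mildly low-pass filtered before extraction; records with any
    missing pivot are dropped (logged) so LM sees complete residuals.
    """
    layout = build_pivot_layout(eye, max_radius=cohort.records[0].pre_map.grid.max_radius)
    X, Y, kept = [], [], []
    for rec in cohort:
        if rec.eye != eye or not record_passes_qc(rec, min_coverage):
            continue
        smoothed = lowpass_filter(rec.post_map, *smoothing)
        piv = extract_pivots(smoothed, layout)
        if not np.all(np.isfinite(piv.values)):
            logger.warning("dropping %s/%s from NN dataset: missing pivots",
                           rec.subject_id, rec.eye)
            continue
        X.append(float(rec.wear_days))
        Y.append(piv.values)
        kept.append(rec)
    return np.asarray(X), np.asarray(Y), layout, kept


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full workflow; idempotent given a seed."""
    grid = make_standard_grid(*config.grid_spec)

    # --- stage 1: cohort ---------------------------------------------------
    cohorts: dict[str, Cohort] = {}
    if config.manifest is not None:
        full = tfq_io.load_cohort(config.manifest, logger=logger)
        for eye in config.eyes:
            cohorts[eye] = full.filter(eye=eye)
    else:
        params = default_params(grid=grid, seed=config.seed)
        for k, v in config.generator_overrides.items():
            setattr(params, k, v)
        for eye in config.eyes:
            cohorts[eye], _ = generate_cohort(params, eye)

    # --- stage 2: QC + resampling ------------------------------------------
    excluded_rows = []
    for eye in config.eyes:
        kept = []
        for rec in cohorts[eye]:
            resampled = {}
            for name in ("pre_map", "post_map", "pre_curvature", "post_curvature"):
                tfm = getattr(rec, name)
                if tfm is not None and tfm.grid != grid and tfm.modality == "tear_quality":
                    setattr(rec, name, resample_to_grid(tfm, grid))
            qc = record_qc(rec, config.min_coverage)
            bad = {s: r for s, r in qc.items() if not r.passed}
            if bad:
                for sess, res in bad.items():
                    excluded_rows.append({
                        "subject": rec.subject_id, "eye": rec.eye,
                        "session": sess, "reasons": "|".join(sorted(res.reasons)),
                        "central_coverage": res.central_coverage,
                    })
                    logger.info("QC excluded %s/%s %s: %s", rec.subject_id,
                                rec.eye, sess, sorted(res.reasons))
                continue
            kept.append(rec)
        cohorts[eye] = Cohort(records=kept, provenance=cohorts[eye].provenance)
    qc_excluded = pd.DataFrame(
        excluded_rows,
        columns=["subject", "eye", "session", "reasons", "central_coverage"])

    # --- stage 3: group means, differences, global means --------------------
    mean_maps, diff_maps = {}, {}
    gm_rows, corr_rows = [], []
    for eye in config.eyes:
        for gi, group in enumerate(GROUPS):
            pre_mean = group_mean_map(cohorts[eye], group, "pre", config.min_coverage)
            post_mean = group_mean_map(cohorts[eye], group, "post", config.min_coverage)
            mean_maps[(eye, group, "pre")] = pre_mean
            mean_maps[(eye, group, "post")] = post_mean
            diff_maps[(eye, group)] = difference_map(post_mean, pre_mean)
            recs = [r for r in cohorts[eye] if r.group == group]
            for session in ("pre", "post"):
                vals = [
                    global_mean(getattr(r, f"{session}_map"), config.zone_radius)
                    for r in recs
                ]
                s = summarize_distribution(vals)
                gm_rows.append({
                    "eye": eye, "group": group, "session": session,
                    "n": len(vals), "mean": s.mean, "median": s.median,
                    "mode": s.mode, "sd": s.sd, "min": s.min, "max": s.max,
                })
            corr_rows.append(group_correlation(
                cohorts[eye], group, config.zone_radius, n_boot=config.n_boot,
                rng=_derived_seed(config.seed, 100 + 10 * gi + (eye == "OS")),
                min_coverage=config.min_coverage) | {"eye": eye})

    # --- stage 4: significance maps -----------------------------------------
    significance, sig_rows = {}, []
    annuli = ((0.0, 1.0), (1.0, 2.5), (2.5, 3.5), (3.5, 4.5), (4.5, np.inf))
    for eye in config.eyes:
        for group in GROUPS:
            sig = pointwise_signed_rank_map(cohorts[eye], group, config.alpha,
                                            config.min_coverage)
            significance[(eye, group)] = sig
            row = {"eye": eye, "group": group,
                   "rejected_fraction": sig.rejected_fraction()}
            for lo, hi in annuli:
                label = f"frac_{lo:g}_{'inf' if np.isinf(hi) else f'{hi:g}'}mm"
                row[label] = sig.rejected_fraction(lo, hi)
            sig_rows.append(row)

    # --- stage 5: NN dataset, optional grid search, final model -------------
    models, eval_rows, gs_tables = {}, [], {}
    for eye in config.eyes:
        X, Y, layout, _ = build_pivot_dataset(cohorts[eye], eye, config.smoothing,
                                              config.min_coverage)
        split = split_data(len(X), rng=_derived_seed(config.seed, 7))
        if config.run_grid_search:
            gs = grid_search(X, Y, split, seed=_derived_seed(config.seed, 11),
                             opts=config.grid_search_opts)
            gs_tables[eye] = gs.as_table()
        sizes = (1,) + tuple(config.architecture) + (Y.shape[1],)
        model = init_model(sizes, seed=_derived_seed(config.seed, 13))
        model, train_rec = train_lm(model, X, Y, split, config.train_opts)
        models[eye] = model
        for part, metrics in evaluate(model, X, Y, split).items():
            eval_rows.append({"eye": eye, "partition": part, **metrics,
                              "epochs": train_rec.epochs,
                              "stop_reason": train_rec.stop_reason})

    report = RunReport(
        config=config,
        global_means=pd.DataFrame(gm_rows),
        correlations=pd.DataFrame(corr_rows),
        significance=significance,
        significance_summary=pd.DataFrame(sig_rows),
        mean_maps=mean_maps,
        difference_maps=diff_maps,
        models=models,
        model_eval=pd.DataFrame(eval_rows),
        grid_search_tables=gs_tables,
        qc_excluded=qc_excluded,
        cohorts=cohorts,
    )
    if config.outdir is not None:
        write_report_tables(report, config.outdir)
    return report


def write_report_tables(report: RunReport, outdir: str | Path) -> None:
    """CSV artifacts: every reported number traces back to one of these files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.global_means.to_csv(outdir / "global_means.csv", index=False)
    report.correlations.to_csv(outdir / "correlations.csv", index=False)
    report.significance_summary.to_csv(outdir / "significance_summary.csv", index=False)
    report.model_eval.to_csv(outdir / "model_eval.csv", index=False)
    report.qc_excluded.to_csv(outdir / "qc_excluded.csv", index=False)
    for eye, table in report.grid_search_tables.items():
        table.to_csv(outdir / f"grid_search_{eye}.csv", index=False)
    for eye, model in report.models.items():
        (outdir / f"model_{eye}.json").write_text(
            json.dumps(model.to_json_dict()) + "\n")


def render_reports(report: RunReport, outdir: str | Path) -> list[Path]:
    """Figures: six-map layouts per group/eye, significance overlays, violins, scatters."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def polar_panel(ax, tfm: TearFilmMap, title: str, cmap="RdYlGn_r"):
        grid = tfm.grid
        th = np.deg2rad(np.concatenate([grid.meridian_angles,
                                        [grid.meridian_angles[0] + 360.0]]))
        r = grid.ring_radii
        vals = np.concatenate([tfm.values, tfm.values[:, :1]], axis=1)
        tt, rr = np.meshgrid(th, r)
        pc = ax.pcolormesh(tt, rr, np.ma.masked_invalid(vals), cmap=cmap,
                           shading="auto")
        ax.set_title(title, fontsize=8)
        ax.set_xticks([])
        ax.set_yticks([])
        return pc

    for eye in report.config.eyes:
        for group in GROUPS:
            if (eye, group) not in report.difference_maps:
                logger.warning("render: no maps for %s %s, skipping", eye, group)
                continue
            fig, axes = plt.subplots(2, 3, figsize=(9, 6),
                                     subplot_kw={"projection": "polar"})
            pre = report.mean_maps[(eye, group, "pre")]
            post = report.mean_maps[(eye, group, "post")]
            diff = report.difference_maps[(eye, group)]
            panels = [
                (pre, "pre tear quality"), (post, "post tear quality"),
                (diff, "difference (post-pre)"),
            ]
            for ax, (tfm, title) in zip(axes[0], panels):
                polar_panel(ax, tfm, f"{eye} {group} {title}")
            sig = report.significance[(eye, group)]
            overlay = TearFilmMap.__new__(TearFilmMap)
            overlay.grid = sig.grid
            overlay.values = np.where(np.isfinite(sig.p_adj), sig.p_adj, np.nan)
            overlay.modality = "tear_quality"
            overlay.session = "post"
            overlay.artefact_flags = frozenset()
            polar_panel(axes[1][0], overlay, "adjusted p-values", cmap="viridis")
            mask_map = TearFilmMap.__new__(TearFilmMap)
            mask_map.grid = sig.grid
            mask_map.values = sig.reject.astype(float)
            mask_map.modality = "tear_quality"
            mask_map.session = "post"
            mask_map.artefact_flags = frozenset()
            polar_panel(axes[1][1], mask_map, f"rejected at q={sig.alpha}",
                        cmap="Reds")
            axes[1][2].axis("off")
            path = outdir / f"sixmap_{eye}_{group}.png"
            fig.savefig(path, dpi=110)
            plt.close(fig)
            written.append(path)

    # violin-style distribution export + figure
    gm = report.global_means
    fig, ax = plt.subplots(figsize=(6, 4))
    data, labels = [], []
    for eye in report.config.eyes:
        for group in GROUPS:
            recs = [r for r in report.cohorts[eye] if r.group == group]
            vals = [global_mean(r.post_map, report.config.zone_radius) for r in recs]
            data.append(vals)
            labels.append(f"{eye}\n{group}")
    ax.violinplot(data, showmeans=True, showmedians=True)
    ax.set_xticks(range(1, len(labels) + 1), labels, fontsize=7)
    ax.set_ylabel("post global mean tear-quality factor")
    path = outdir / "violin_global_means.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    written.append(path)

    # predicted vs observed scatter per eye
    from .nn import forward
    for eye, model in report.models.items():
        X, Y, _, _ = build_pivot_dataset(report.cohorts[eye], eye,
                                         report.config.smoothing,
                                         report.config.min_coverage)
        split = split_data(len(X), rng=_derived_seed(report.config.seed, 7))
        fig, axes = plt.subplots(1, 3, figsize=(10, 3.2), sharex=True, sharey=True)
        for ax, (part, idx) in zip(axes, (("train", split.train),
                                          ("val", split.val), ("test", split.test))):
            pred = forward(model, X[idx]).ravel()
            obs = Y[idx].ravel()
            ax.plot(obs, pred, ".", ms=2, alpha=0.4)
            lim = [min(obs.min(), pred.min()), max(obs.max(), pred.max())]
            ax.plot(lim, lim, "k--", lw=0.7)
            ax.set_title(f"{eye} {part}", fontsize=8)
            ax.set_xlabel("observed")
        axes[0].set_ylabel("predicted")
        path = outdir / f"pred_vs_obs_{eye}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written
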