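"""End-to-end pipeline orchestration and report rendering.

``run_analysis`` drives: read (or generate) → inclusion filters → left-eye
mirroring → per-zone, per-path prediction → centroid/ellipse/cumulative
statistics → subtype subgroups → covariate regression, and renders table and
double-angle-plot analogues of a clinical astigmatism-outcome report.

Renderer purity: every number in the tables comes from a ``stats`` output
and every figure can be re-rendered byte-identically from the saved per-eye
error CSV (figures are SVG with a fixed hash salt and no timestamp).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import stats as czs
from .io import InclusionCriteria, apply_inclusion_filters, read_cohort
from .prediction import (
    DEFAULT_VERTEX_DISTANCE,
    PATH_POSTOP_K,
    PATH_PREOP_SIA,
    PcaModel,
    build_prediction_records,
    eye_anterior_ca,
    get_pca_model,
)
from .types import Cohort
from .vectors import AstigmatismType, DoubleAngleVector, classify_astigmatism

logger = logging.getLogger(__name__)

plt.rcParams["svg.hashsalt"] = "astigzone"

DEFAULT_THRESHOLDS = (0.5, 1.0, 1.5, 2.0)


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything needed to run (and exactly reproduce) one analysis."""

    input: Optional[str] = None          # cohort CSV; None -> generate synthetically
    n_eyes: int = 101                    # generator size when input is None
    seed: int = 0
    zones: tuple[float, ...] = (2.4, 3.3)
    path: str = "both"                   # preop_sia | postop_k | both
    pca_model: str = "fixed_atr"
    pca_params: dict = field(default_factory=dict)
    vertex_distance: float = DEFAULT_VERTEX_DISTANCE
    ellipse_level: float = 0.95
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.zones:
            raise ValueError("zones must be non-empty")
        if any(b < a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be ascending")
        if self.path not in (PATH_PREOP_SIA, PATH_POSTOP_K, "both"):
            raise ValueError(f"unknown path {self.path!r}")

    @property
    def paths(self) -> tuple[str, ...]:
        if self.path == "both":
            return (PATH_PREOP_SIA, PATH_POSTOP_K)
        return (self.path,)

    def make_pca(self) -> PcaModel:
        return get_pca_model(self.pca_model, **self.pca_params)


@dataclass
class ReportBundle:
    """All tables, per-eye errors and figure paths produced by one run."""

    config: AnalysisConfig
    pca: PcaModel
    n_eyes: int
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    per_eye_errors: pd.DataFrame
    regressions: dict
    exclusion_log: dict
    figures: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# table builders (every number traceable to a stats/prediction output)

def _build_table1(cohort: Cohort, labels_by_zone: dict[float, list[AstigmatismType]],
                  zone: float) -> pd.DataFrame:
    ages = [e.age for e in cohort]
    als = [e.axial_length for e in cohort]
    iols = [e.iol_power for e in cohort]
    pre_ca = [eye_anterior_ca(e, "preop", zone).magnitude for e in cohort]
    n = len(cohort.eyes)
    labels = labels_by_zone[zone]
    counts = {t: labels.count(t) for t in AstigmatismType}
    males = sum(1 for e in cohort if e.sex == "M")
    od = sum(1 for e in cohort if e.laterality == "OD")

    def ms(vals):
        a = np.asarray(vals)
        return f"{a.mean():.1f} ± {a.std(ddof=1):.1f} ({a.min():.2f}–{a.max():.2f})"

    rows = [
        ("Eyes (n)", str(n)),
        ("Age (years)", ms(ages)),
        ("Sex (M:F)", f"{males} ({100*males/n:.1f}%):{n-males} ({100*(n-males)/n:.1f}%)"),
        ("Laterality (OD:OS)", f"{od} ({100*od/n:.1f}%):{n-od} ({100*(n-od)/n:.1f}%)"),
        ("Axial length (mm)", ms(als)),
        ("IOL power (D)", ms(iols)),
        ("Preoperative corneal astigmatism (D)", ms(pre_ca)),
        ("Astigmatism type WTR:ATR:oblique",
         ":".join(f"{counts[t]} ({100*counts[t]/n:.1f}%)" for t in
                  (AstigmatismType.WTR, AstigmatismType.ATR, AstigmatismType.OBLIQUE))),
    ]
    return pd.DataFrame(rows, columns=["parameter", "value"])


def _build_table2(cohort: Cohort, zones: Sequence[float],
                  thresholds: Sequence[float]) -> pd.DataFrame:
    rows = []
    for epoch in ("preop", "postop"):
        for zone in zones:
            readings = [e.keratometry(epoch, zone) for e in cohort]
            avg = np.array([k.average_k for k in readings])
            flat = np.array([k.flat_k for k in readings])
            steep = np.array([k.steep_k for k in readings])
            ca = np.array([eye_anterior_ca(e, epoch, zone).magnitude for e in cohort])
            counts = czs.cumulative_magnitude_table(ca, thresholds)
            row = {
                "epoch": epoch,
                "zone_mm": zone,
                "mean_average_k": avg.mean(),
                "sd_average_k": avg.std(ddof=1),
                "mean_flat_k": flat.mean(),
                "sd_flat_k": flat.std(ddof=1),
                "mean_steep_k": steep.mean(),
                "sd_steep_k": steep.std(ddof=1),
                "mean_abs_ca": ca.mean(),
                "sd_abs_ca": ca.std(ddof=1),
            }
            for t, c in zip(thresholds, counts):
                row[f"n_ca_le_{t:g}D"] = c
            rows.append(row)
    return pd.DataFrame(rows)


def _table3_rows(group: str, n: int, zones: Sequence[float],
                 summaries: dict[float, czs.CentroidSummary],
                 comparison: Optional[czs.PairedComparison]) -> list[dict]:
    rows = []
    for zone in zones:
        s = summaries[zone]
        rows.append({
            "group": group,
            "n": n,
            "zone_mm": zone,
            "mean_abs": s.mean_abs,
            "sd_abs": s.sd_abs,
            "centroid_magnitude": s.centroid_magnitude,
            "centroid_axis": s.centroid_axis,
            "combined_sd": s.combined_sd,
            "mean_x": s.mean_x,
            "sd_x": s.sd_x,
            "mean_y": s.mean_y,
            "sd_y": s.sd_y,
            "p_x": comparison.p_x if comparison else math.nan,
            "p_y": comparison.p_y if comparison else math.nan,
            "p_abs": comparison.p_abs if comparison else math.nan,
        })
    return rows


# ---------------------------------------------------------------------------
# figures

def render_double_angle_plot(
    errors: Sequence[DoubleAngleVector],
    dataset_ellipse: Optional[czs.EllipseSpec],
    centroid_ellipse: Optional[czs.EllipseSpec],
    out_path: str | Path,
    title: str = "",
) -> None:
    """Polar-style doubled-angle chart: magnitude rings, points, both 95%
    confidence ellipses (blue dataset, red centroid) and a square centroid
    marker, with an n / centroid caption.  Written as deterministic SVG."""
    xs = [v.x for v in errors]
    ys = [v.y for v in errors]
    rmax = max([1.0] + [math.hypot(x, y) for x, y in zip(xs, ys)])
    if dataset_ellipse is not None:
        rmax = max(rmax, dataset_ellipse.semi_major + math.hypot(*dataset_ellipse.center))
    rmax = math.ceil(rmax * 2.0) / 2.0

    fig, ax = plt.subplots(figsize=(5, 5))
    rings = np.arange(0.5, rmax + 0.25, 0.5)
    theta = np.linspace(0, 2 * np.pi, 241)
    for r in rings:
        ax.plot(r * np.cos(theta), r * np.sin(theta), color="0.85", lw=0.6, zorder=0)
        ax.annotate(f"{r:g} D", (r * math.cos(math.radians(100)),
                                 r * math.sin(math.radians(100))),
                    fontsize=6, color="0.5")
    for axis_deg in (0, 45, 90, 135):
        t = math.radians(2 * axis_deg)
        ax.plot([-rmax * math.cos(t), rmax * math.cos(t)],
                [-rmax * math.sin(t), rmax * math.sin(t)],
                color="0.9", lw=0.5, zorder=0)
        ax.annotate(f"{axis_deg}°", (1.06 * rmax * math.cos(t), 1.06 * rmax * math.sin(t)),
                    fontsize=7, ha="center", va="center", color="0.4")

    ax.scatter(xs, ys, s=12, color="0.2", zorder=2)
    caption = f"n = {len(xs)}"
    if dataset_ellipse is not None:
        b = dataset_ellipse.boundary()
        ax.plot(b[:, 0], b[:, 1], color="tab:blue", lw=1.2, zorder=3,
                label=f"{dataset_ellipse.confidence:.0%} dataset ellipse")
    if centroid_ellipse is not None:
        b = centroid_ellipse.boundary()
        ax.plot(b[:, 0], b[:, 1], color="tab:red", lw=1.2, zorder=4,
                label=f"{centroid_ellipse.confidence:.0%} centroid ellipse")
    if len(xs) >= 2:
        s = czs.centroid_summary(list(errors))
        ax.plot([s.mean_x], [s.mean_y], marker="s", color="tab:red", ms=5, zorder=5)
        caption += f"; centroid {s.format_centroid()}"

    ax.set_xlim(-1.15 * rmax, 1.15 * rmax)
    ax.set_ylim(-1.15 * rmax, 1.15 * rmax)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title, fontsize=9)
    ax.annotate(caption, (0, -1.12 * rmax), ha="center", fontsize=7)
    if dataset_ellipse is not None or centroid_ellipse is not None:
        ax.legend(loc="upper right", fontsize=6, frameon=False)
    fig.savefig(out_path, format="svg", metadata={"Date": None})
    plt.close(fig)


def _render_cumulative_figure(per_eye: pd.DataFrame, thresholds: Sequence[float],
                              out_path: str | Path) -> None:
    """Cumulative share of eyes with |error| at or below each threshold,
    one bar group per (zone, path)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    groups = sorted(per_eye.groupby(["zone_mm", "path"]).groups)
    width = 0.8 / max(len(groups), 1)
    xs = np.arange(len(thresholds))
    for j, (zone, path) in enumerate(groups):
        sub = per_eye[(per_eye.zone_mm == zone) & (per_eye.path == path)]
        mags = np.hypot(sub.error_x, sub.error_y)
        counts = czs.cumulative_magnitude_table(mags, thresholds)
        frac = [100.0 * c / len(sub) for c in counts]
        ax.bar(xs + j * width, frac, width=width, label=f"{zone} mm, {path}")
    ax.set_xticks(xs + 0.4 - width / 2)
    ax.set_xticklabels([f"≤ {t:g} D" for t in thresholds])
    ax.set_ylabel("Eyes (%)")
    ax.set_ylim(0, 105)
    ax.set_title("Cumulative astigmatism prediction error")
    ax.legend(fontsize=7, frameon=False)
    fig.savefig(out_path, format="svg", metadata={"Date": None})
    plt.close(fig)


# ---------------------------------------------------------------------------
# markdown rendering

def _markdown_table(df: pd.DataFrame, floatfmt: str = "{:.3f}") -> str:
    def fmt(v):
        if isinstance(v, float):
            return "" if (isinstance(v, float) and math.isnan(v)) else floatfmt.format(v)
        return str(v)

    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    lines = [header, sep]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(fmt(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# the pipeline

def _load_cohort(config: AnalysisConfig) -> tuple[Cohort, dict]:
    if config.input is not None:
        cohort, rejects = read_cohort(config.input)
        if rejects:
            logger.warning("%d rejected row(s) while reading %s", len(rejects), config.input)
        cohort, flog = apply_inclusion_filters(cohort, InclusionCriteria())
        exclusion_log = {"excluded": flog.excluded, "skipped_rules": flog.skipped_rules,
                         "rejected_rows": len(rejects)}
    else:
        from .synthetic import GeneratorConfig, generate_cohort
        gen = GeneratorConfig(n_eyes=config.n_eyes, seed=config.seed)
        cohort, _ = generate_cohort(gen)
        exclusion_log = {"excluded": {}, "skipped_rules": [], "rejected_rows": 0}
    if not cohort.eyes:
        raise ValueError("no eyes left after inclusion filtering")
    available = cohort.zones
    missing = [z for z in config.zones if z not in available]
    if missing:
        raise ValueError(
            f"requested zone(s) {missing} not present in the input "
            f"(available: {list(available)})"
        )
    return cohort, exclusion_log


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run the full pipeline; deterministic given the config (and seed)."""
    cohort, exclusion_log = _load_cohort(config)
    pca = config.make_pca()
    zones = tuple(config.zones)
    n = len(cohort.eyes)
    logger.info("analysing %d eyes at zone(s) %s with posterior model %r",
                n, zones, pca.name)

    # subtype labels from the preoperative keratometric axis, per zone
    labels_by_zone = {
        z: [classify_astigmatism(eye_anterior_ca(e, "preop", z).axis) for e in cohort]
        for z in zones
    }
    if len(zones) == 2:
        discordant = sum(
            1 for a, b in zip(labels_by_zone[zones[0]], labels_by_zone[zones[1]]) if a != b
        )
        logger.info("subtype label discordance between zones: %d of %d eyes", discordant, n)

    records = {
        (z, p): build_prediction_records(cohort, z, p, pca, config.vertex_distance)
        for z in zones for p in config.paths
    }

    per_eye_rows = []
    for (zone, path), recs in records.items():
        for r in recs:
            per_eye_rows.append({
                "eye_id": r.eye_id, "zone_mm": zone, "path": path,
                "predicted_magnitude": r.predicted.magnitude,
                "predicted_axis": r.predicted.axis,
                "actual_magnitude": r.actual.magnitude,
                "actual_axis": r.actual.axis,
                "error_x": r.error.x, "error_y": r.error.y,
            })
    per_eye = pd.DataFrame(per_eye_rows)

    table1 = _build_table1(cohort, labels_by_zone, zones[0])
    table2 = _build_table2(cohort, zones, config.thresholds)

    table3_rows: list[dict] = []
    for path in config.paths:
        errors_by_zone = {z: [r.error for r in records[(z, path)]] for z in zones}
        comparison = (czs.paired_zone_comparison(errors_by_zone[zones[0]],
                                                 errors_by_zone[zones[1]])
                      if len(zones) == 2 else None)
        if len(zones) < 2:
            logger.warning("single zone %s: no between-zone paired comparison", zones)
        summaries = {z: czs.centroid_summary(errors_by_zone[z]) for z in zones}
        for row in _table3_rows(f"Total ({path})", n, zones, summaries, comparison):
            table3_rows.append(row)
        # per-subtype rows, each zone labelled by its own preoperative axis
        for label in AstigmatismType:
            idx_by_zone = {z: [i for i, lab in enumerate(labels_by_zone[z]) if lab == label]
                           for z in zones}
            if any(len(idx_by_zone[z]) < 2 for z in zones):
                logger.info("subgroup %s omitted for path %s (too few eyes)",
                            label.value, path)
                continue
            sub_summaries = {
                z: czs.centroid_summary([errors_by_zone[z][i] for i in idx_by_zone[z]])
                for z in zones
            }
            sub_comparison = None
            if len(zones) == 2:
                concordant = [i for i in idx_by_zone[zones[0]] if i in idx_by_zone[zones[1]]]
                if len(concordant) >= 2:
                    sub_comparison = czs.paired_zone_comparison(
                        [errors_by_zone[zones[0]][i] for i in concordant],
                        [errors_by_zone[zones[1]][i] for i in concordant],
                    )
            n_label = {z: len(idx_by_zone[z]) for z in zones}
            for z in zones:
                row = _table3_rows(f"{label.value} ({path})", n_label[z], [z],
                                   sub_summaries, sub_comparison)[0]
                table3_rows.append(row)
    table3 = pd.DataFrame(table3_rows)

    # covariate regression on the postop-K path when available, else the only path
    reg_path = PATH_POSTOP_K if PATH_POSTOP_K in config.paths else config.paths[0]
    regressions = {}
    for zone in zones:
        recs = records[(zone, reg_path)]
        df = pd.DataFrame({
            "age": [e.age for e in cohort],
            "sex": [e.sex for e in cohort],
            "axial_length": [e.axial_length for e in cohort],
            "iol_power": [e.iol_power for e in cohort],
            "preop_astigmatism": [eye_anterior_ca(e, "preop", zone).magnitude for e in cohort],
            "corneal_irregularity": [e.corneal_irregularity for e in cohort],
            "abs_error": [r.error.magnitude for r in recs],
            "x_error": [r.error.x for r in recs],
            "y_error": [r.error.y for r in recs],
        })
        try:
            regressions[zone] = {
                "multivariate": czs.covariate_regression(df, response="abs_error"),
                "univariate": czs.covariate_regression(df, response="abs_error",
                                                       mode="univariate"),
            }
        except ValueError as exc:
            logger.warning("regression skipped at zone %s: %s", zone, exc)

    bundle = ReportBundle(
        config=config, pca=pca, n_eyes=n,
        table1=table1, table2=table2, table3=table3,
        per_eye_errors=per_eye, regressions=regressions,
        exclusion_log=exclusion_log,
    )
    if config.output_dir is not None:
        _write_bundle(bundle)
    return bundle


def render_figures_from_errors(per_eye: pd.DataFrame, out_dir: Path,
                               ellipse_level: float = 0.95,
                               thresholds: Sequence[float] = DEFAULT_THRESHOLDS) -> list[str]:
    """Render all figures from a per-eye error table (the saved CSV is the
    single source for figures, so re-rendering is exactly reproducible)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    figures = []
    fig1 = out_dir / "fig1_cumulative_error.svg"
    _render_cumulative_figure(per_eye, thresholds, fig1)
    figures.append(str(fig1))
    for (zone, path), sub in sorted(per_eye.groupby(["zone_mm", "path"]).groups.items()):
        subdf = per_eye.loc[sub]
        errors = [DoubleAngleVector(x, y) for x, y in zip(subdf.error_x, subdf.error_y)]
        de = ce = None
        if len(errors) >= 3:
            de = czs.confidence_ellipse(errors, ellipse_level, "dataset")
            ce = czs.confidence_ellipse(errors, ellipse_level, "centroid")
        fig_path = out_dir / f"fig2_double_angle_{str(zone).replace('.', 'p')}mm_{path}.svg"
        render_double_angle_plot(errors, de, ce, fig_path,
                                 title=f"Prediction error, {zone:g}-mm zone ({path})")
        figures.append(str(fig_path))
    return figures


def _write_bundle(bundle: ReportBundle) -> None:
    out = Path(bundle.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.table1.to_csv(out / "table1_characteristics.csv", index=False)
    bundle.table2.to_csv(out / "table2_keratometry.csv", index=False, float_format="%.4f")
    bundle.table3.to_csv(out / "table3_prediction_error.csv", index=False, float_format="%.4f")
    bundle.per_eye_errors.to_csv(out / "per_eye_errors.csv", index=False, float_format="%.9f")

    md = ["# Astigmatism prediction-error report", "",
          f"Posterior-cornea model: **{bundle.pca.name}** {bundle.pca.parameters} "
          "(explicit stand-in; predictions are not from any proprietary toric calculator).",
          "", f"Eyes analysed: {bundle.n_eyes}", "",
          "## Cohort characteristics", "", _markdown_table(bundle.table1),
          "## Keratometry by zone", "", _markdown_table(bundle.table2),
          "## Prediction error by zone and subtype", "", _markdown_table(bundle.table3),
          "",
          "_p-values are uncorrected for multiple testing; two eyes of one "
          "patient are treated as independent._",
          ]
    (out / "report.md").write_text("\n".join(md))

    echo = dataclasses.asdict(bundle.config)
    echo["pca_resolved"] = {"name": bundle.pca.name, "parameters": bundle.pca.parameters}
    echo["exclusion_log"] = bundle.exclusion_log
    (out / "config_echo.json").write_text(json.dumps(echo, indent=2, default=str))

    # render from the CSV just written (not the in-memory frame) so that a
    # later re-render from the same file is byte-identical
    saved = pd.read_csv(out / "per_eye_errors.csv")
    bundle.figures = render_figures_from_errors(
        saved, out, bundle.config.ellipse_level, bundle.config.thresholds
    )
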