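"""Tortuosity computation, aggregation and the group-comparison battery.

Tortuosity is the arc-to-chord ratio T = L_curve / L_straight: 1 for a
perfectly straight vessel, larger the more the vessel twists.  In
pixel-count arc mode (default, matching the source pseudocode) L_curve is
the number of path pixels and L_straight the rounded Euclidean chord, so T
can fall below 1 for near-diagonal vessels (a diagonal step advances
sqrt(2) toward the chord but counts as one pixel); the lower bound is
1/sqrt(2).  Geometric mode uses the subsampled polyline arc against the
exact chord and satisfies T >= 1.

The comparison battery mirrors a standard two-group workflow: Shapiro-Wilk
normality on each sample gates a parametric branch (Pearson r,
single-predictor regression R^2 = r^2, Cohen's d with pooled SD) versus a
nonparametric branch (Spearman rho, Mann-Whitney U, Wilcoxon signed-rank
on image-paired means).  The unit of analysis is the per-image mean
tortuosity per vessel class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tracing import TracedPath

logger = logging.getLogger(__name__)

__all__ = [
    "TortuosityRecord",
    "ComparisonReport",
    "tortuosity",
    "records_from_paths",
    "aggregate",
    "compare_groups",
    "cohens_d",
    "build_report",
]


def tortuosity(l_curve: float, l_straight: float) -> float:
    """Arc-to-chord tortuosity T = L_curve / L_straight."""
    if l_straight == 0:
        raise ValueError("l_straight is zero; record is invalid")
    return l_curve / l_straight


@dataclass
class TortuosityRecord:
    """One traced vessel with its tortuosity value."""

    image_id: str
    vessel_class: str  # artery | vein
    traced: TracedPath
    t: float


def records_from_paths(
    image_id: str,
    paths: list[TracedPath],
    arc_mode: str = "pixel",
    stride: int = 5,
) -> list[TortuosityRecord]:
    """Build tortuosity records from traced paths, skipping invalid ones.

    ``arc_mode='pixel'``: T = pixel count / rounded chord.
    ``arc_mode='geometric'``: T = subsampled polyline length / exact chord.
    Unreachable paths and zero-length chords are excluded with a warning.
    """
    if arc_mode not in ("pixel", "geometric"):
        raise ValueError(f"unknown arc_mode: {arc_mode!r}")
    records = []
    for tp in paths:
        if tp.l_curve is None:
            logger.warning("%s: unreachable pair %s; skipped", image_id, tp.pair)
            continue
        if arc_mode == "pixel":
            if tp.l_straight == 0:
                logger.warning("%s: zero straight length for %s; skipped", image_id, tp.pair)
                continue
            t = tortuosity(tp.l_curve, tp.l_straight)
        else:
            chord = tp.chord
            if chord == 0:
                logger.warning("%s: zero chord for %s; skipped", image_id, tp.pair)
                continue
            t = tortuosity(tp.geometric_length(stride), chord)
        records.append(
            TortuosityRecord(image_id=image_id, vessel_class=tp.pair.vessel_class,
                             traced=tp, t=t)
        )
    return records


def aggregate(records: list[TortuosityRecord]) -> pd.DataFrame:
    """Per-image, per-class mean tortuosity and segment counts.

    Returns a frame with columns image_id, vessel_class, mean_t, n_segments.
    Classes with zero records are simply absent (a warning is logged when a
    class present elsewhere is missing for an image).
    """
    if not records:
        raise ValueError("no records to aggregate")
    df = records_frame(records)
    out = (
        df.groupby(["image_id", "vessel_class"], as_index=False)
        .agg(mean_t=("t", "mean"), n_segments=("t", "size"))
    )
    classes = set(out["vessel_class"])
    for image_id, grp in out.groupby("image_id"):
        missing = classes - set(grp["vessel_class"])
        if missing:
            logger.warning("image %s has no records for class(es) %s", image_id, missing)
    return out


def records_frame(records: list[TortuosityRecord]) -> pd.DataFrame:
    """Flat per-segment table of tortuosity records."""
    return pd.DataFrame(
        {
            "image_id": [r.image_id for r in records],
            "vessel_class": [r.vessel_class for r in records],
            "start_x": [r.traced.pair.start_xy[0] for r in records],
            "start_y": [r.traced.pair.start_xy[1] for r in records],
            "end_x": [r.traced.pair.end_xy[0] for r in records],
            "end_y": [r.traced.pair.end_xy[1] for r in records],
            "l_curve": [r.traced.l_curve for r in records],
            "l_straight": [r.traced.l_straight for r in records],
            "t": [r.t for r in records],
        }
    )


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference (a minus b) with pooled SD."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = len(a), len(b)
    pooled = math.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


@dataclass
class ComparisonReport:
    """Full comparison of two labeled samples of per-image mean tortuosity."""

    label: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    segments_a: int
    segments_b: int
    mean_a: float
    mean_b: float
    shapiro_p_a: float
    shapiro_p_b: float
    branch: str  # parametric | nonparametric
    cohens_d: float
    pearson_r: float = math.nan
    pearson_p: float = math.nan
    r_squared: float = math.nan
    spearman_r: float = math.nan
    spearman_p: float = math.nan
    mannwhitney_p: float = math.nan
    wilcoxon_p: float = math.nan
    extra: dict = field(default_factory=dict)


def compare_groups(
    a,
    b,
    paired: bool = True,
    alpha: float = 0.05,
    label: str = "",
    group_a: str = "artery",
    group_b: str = "vein",
    segments_a: int | None = None,
    segments_b: int | None = None,
) -> ComparisonReport:
    """Shapiro-gated comparison of two samples of per-image means.

    Both samples must have n >= 3 (Shapiro-Wilk minimum).  If both
    Shapiro-Wilk p-values exceed ``alpha`` the branch is parametric;
    otherwise nonparametric.  All statistics that the sample sizes permit
    are computed regardless of branch, so reports can show either set.
    Paired statistics (Pearson/Spearman/Wilcoxon) require equal sample
    sizes; with unequal sizes they are left as NaN with a warning.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs n >= 3 for the Shapiro-Wilk gate")

    sw_a = float(sps.shapiro(a).pvalue)
    sw_b = float(sps.shapiro(b).pvalue)
    branch = "parametric" if (sw_a > alpha and sw_b > alpha) else "nonparametric"

    rep = ComparisonReport(
        label=label, group_a=group_a, group_b=group_b,
        n_a=len(a), n_b=len(b),
        segments_a=int(segments_a) if segments_a is not None else len(a),
        segments_b=int(segments_b) if segments_b is not None else len(b),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        shapiro_p_a=sw_a, shapiro_p_b=sw_b,
        branch=branch, cohens_d=cohens_d(a, b),
    )

    if len(a) == len(b):
        if np.ptp(a) > 0 and np.ptp(b) > 0:
            pr = sps.pearsonr(a, b)
            rep.pearson_r, rep.pearson_p = float(pr.statistic), float(pr.pvalue)
            rep.r_squared = rep.pearson_r**2
            sr = sps.spearmanr(a, b)
            rep.spearman_r, rep.spearman_p = float(sr.statistic), float(sr.pvalue)
        else:
            logger.warning("constant sample: correlation statistics undefined")
        if np.any(a != b):
            rep.wilcoxon_p = float(sps.wilcoxon(a, b).pvalue)
    elif paired:
        logger.warning("unequal sample sizes (%d vs %d): paired statistics skipped",
                       len(a), len(b))
    rep.mannwhitney_p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return rep


_REPORT_COLUMNS = [
    "Dataset", "Group", "Total", "Mean tortuosity", "Shapiro-Wilk p-value",
    "Pearson r", "Spearman r", "Pearson p-value", "Linear regression R2",
    "Cohen's d", "Mann-Whitney U p", "Wilcoxon p",
]


def build_report(reports: list[ComparisonReport]) -> pd.DataFrame:
    """Tabular summary, one row per group, branch-inapplicable cells blank."""
    rows = []
    for rep in reports:
        parametric = rep.branch == "parametric"
        stat_cells = {
            "Pearson r": _fmt(rep.pearson_r) if parametric else "",
            "Spearman r": "" if parametric else _fmt(rep.spearman_r),
            "Pearson p-value": _fmt(rep.pearson_p if parametric else rep.spearman_p),
            "Linear regression R2": _fmt(rep.r_squared) if parametric else "",
            "Cohen's d": _fmt(rep.cohens_d) if parametric else "",
            "Mann-Whitney U p": "" if parametric else _fmt(rep.mannwhitney_p),
            "Wilcoxon p": "" if parametric else _fmt(rep.wilcoxon_p),
        }
        rows.append({
            "Dataset": rep.label, "Group": rep.group_a, "Total": rep.segments_a,
            "Mean tortuosity": _fmt(rep.mean_a),
            "Shapiro-Wilk p-value": _fmt(rep.shapiro_p_a), **stat_cells,
        })
        rows.append({
            "Dataset": rep.label, "Group": rep.group_b, "Total": rep.segments_b,
            "Mean tortuosity": _fmt(rep.mean_b),
            "Shapiro-Wilk p-value": _fmt(rep.shapiro_p_b),
            **{k: "" for k in stat_cells},
        })
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)


def _fmt(x: float):
    return round(float(x), 4) if np.isfinite(x) else ""


def plot_tortuosity_boxplot(records: pd.DataFrame, path, by: str = "vessel_class") -> None:
    """Plain grouped boxplot of per-segment tortuosity (PNG/PDF by suffix).

    ``records`` is a flat table with a ``t`` column and the grouping column
    (default ``vessel_class``).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted(records[by].unique())
    data = [records.loc[records[by] == g, "t"].to_numpy() for g in groups]
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(groups), 4))
    ax.boxplot(data, tick_labels=groups)
    ax.set_ylabel("tortuosity (arc / chord)")
    ax.set_xlabel(by.replace("_", " "))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
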