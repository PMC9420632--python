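"""Per-metabolite ROC analysis, Youden-optimal cut-points, and the ranked
biomarker report.

Each candidate metabolite is treated as a single-variable classifier of its
raw intensity. The ROC curve is evaluated at midpoints between consecutive
distinct pooled values (plus infinite sentinels); AUC is computed by the
rank method — identical to trapezoidal integration, with half credit for
ties — and the direction is auto-oriented so AUC >= 0.5. The "critical
point" is the threshold maximizing the Youden index
J = sensitivity + specificity - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import FeatureTable
from .univariate import UnivariateRecord

__all__ = [
    "RocRecord",
    "BiomarkerReport",
    "roc_curve",
    "youden_optimal",
    "youden_index",
    "build_report",
    "plot_roc",
]


def youden_index(sensitivity: float, specificity: float) -> float:
    """J = sensitivity + specificity - 1."""
    return sensitivity + specificity - 1.0


@dataclass
class RocRecord:
    feature_id: str
    auc: float
    direction: str  # "up_in_case" | "down_in_case"
    critical_point: float
    sensitivity: float
    specificity: float
    youden: float
    curve: list = field(default_factory=list)  # (threshold, sens, spec)


def roc_curve(values_case, values_control, feature_id: str = "") -> RocRecord:
    """Single-metabolite ROC with rank-method AUC and Youden cut-point.

    The direction is chosen so AUC >= 0.5: ``up_in_case`` classifies a
    sample as case when its value is >= the threshold, ``down_in_case``
    when it is <= the threshold.
    """
    case = np.asarray(values_case, dtype=float)
    control = np.asarray(values_control, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = case.size, control.size

    pooled = np.concatenate([case, control])
    ranks = stats.rankdata(pooled)
    u_case = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    auc_up = u_case / (n1 * n2)
    if auc_up >= 0.5:
        direction, auc = "up_in_case", auc_up
    else:
        direction, auc = "down_in_case", 1.0 - auc_up

    distinct = np.unique(pooled)
    mids = (distinct[:-1] + distinct[1:]) / 2.0 if distinct.size > 1 else np.empty(0)
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    curve = []
    for th in thresholds:
        if direction == "up_in_case":
            sens = float((case >= th).mean())
            spec = float((control < th).mean())
        else:
            sens = float((case <= th).mean())
            spec = float((control > th).mean())
        curve.append((float(th), sens, spec))

    rec = RocRecord(
        feature_id=feature_id,
        auc=auc,
        direction=direction,
        critical_point=float("nan"),
        sensitivity=float("nan"),
        specificity=float("nan"),
        youden=float("nan"),
        curve=curve,
    )
    cp, sens, spec, j = youden_optimal(rec, case_median=float(np.median(case)),
                                       control_median=float(np.median(control)))
    rec.critical_point, rec.sensitivity, rec.specificity, rec.youden = cp, sens, spec, j
    return rec


def youden_optimal(
    record: RocRecord,
    case_median: float | None = None,
    control_median: float | None = None,
) -> tuple[float, float, float, float]:
    """Threshold maximizing J over the curve; returns (cut, sens, spec, J).

    Ties in J are broken toward the finite threshold nearest the midpoint of
    the two group medians (when those are supplied), a neutral anchor between
    the typical case and control levels.
    """
    if not record.curve:
        raise ValueError("empty ROC curve")
    js = np.array([s + sp - 1.0 for _, s, sp in record.curve])
    best = np.flatnonzero(js >= js.max() - 1e-12)
    if best.size > 1 and case_median is not None and control_median is not None:
        mid = (case_median + control_median) / 2.0
        finite = [i for i in best if np.isfinite(record.curve[i][0])]
        pool = finite if finite else list(best)
        idx = min(pool, key=lambda i: abs(record.curve[i][0] - mid))
    else:
        idx = int(best[0])
    th, sens, spec = record.curve[idx]
    return float(th), float(sens), float(spec), float(sens + spec - 1.0)


@dataclass
class BiomarkerReport:
    """Final per-comparison report joining univariate and ROC records."""

    comparison_name: str
    records: list  # (UnivariateRecord, RocRecord | None) per candidate
    selected: list  # ordered feature ids
    selection_rule: dict
    validity: object = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for uni, roc in self.records:
            rows.append(
                {
                    "Metabolites": uni.feature_id,
                    "Fold change": uni.fold_change,
                    "VIP": uni.vip,
                    "p Value": uni.p_value,
                    "AUC of ROC": roc.auc if roc else float("nan"),
                    "Critical point": roc.critical_point if roc else float("nan"),
                    "Sensitivity": roc.sensitivity if roc else float("nan"),
                    "Specificity": roc.specificity if roc else float("nan"),
                    "Youden index": roc.youden if roc else float("nan"),
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")


def build_report(
    table: FeatureTable,
    univariate: list[UnivariateRecord],
    top_k: int = 4,
    groups=None,
    case_label: str | None = None,
    comparison_name: str = "comparison",
) -> BiomarkerReport:
    """Rank candidates (VIP > 1 and significant p) and annotate with ROC.

    Candidates are sorted by descending VIP, then ascending p, then feature
    id, and the first ``top_k`` are selected. ROC records are computed on
    the table's raw imputed intensities for two-group comparisons; for
    multi-group comparisons they are left empty (no binary contrast exists).
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    g = np.asarray(table.groups if groups is None else groups)
    labels = sorted(set(g.tolist()))
    two_group = len(labels) == 2
    if two_group:
        case = case_label if case_label is not None else labels[0]
        control = [lab for lab in labels if lab != case][0]

    candidates = [u for u in univariate if u.passes_vip and u.passes_p]
    if not candidates:
        import warnings

        warnings.warn(f"{comparison_name}: no feature passes both VIP and p", stacklevel=2)
    ranked = sorted(candidates, key=lambda u: (-u.vip, u.p_value, u.feature_id))
    chosen = ranked[: int(top_k)]

    records = []
    for uni in chosen:
        roc = None
        if two_group:
            col = table.intensities[uni.feature_id].to_numpy(dtype=float)
            roc = roc_curve(col[g == case], col[g == control], feature_id=uni.feature_id)
        records.append((uni, roc))
    return BiomarkerReport(
        comparison_name=comparison_name,
        records=records,
        selected=[u.feature_id for u in chosen],
        selection_rule={
            "vip_cut": 1.0,
            "p_rule": "Bonferroni-corrected",
            "ranking": ("-vip", "p", "feature_id"),
            "top_k": int(top_k),
            "case_label": case if two_group else None,
            "scale": "raw imputed intensities",
        },
    )


def plot_roc(record: RocRecord, path) -> None:
    """Standard ROC plot (1 - specificity vs sensitivity) for one metabolite."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = sorted(((1.0 - sp, s) for _, s, sp in record.curve))
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(xs, ys, drawstyle="steps-post", color="tab:red")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"{record.feature_id}  AUC={record.auc:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
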