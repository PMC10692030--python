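"""Confusion-matrix metrics, published-table verification, group statistics.

Metrics follow the standard multi-class definitions on a counts matrix
indexed [predicted class][actual class]:

    accuracy  = trace / grand total
    recall_X  = correct X / actual X   (column total)
    precision_X = correct X / predicted X (row total)
    F1_X      = harmonic mean of precision and recall

Macro averages are unweighted means over the three classes; with equal
actual-class totals (SMOTE-balanced data) accuracy equals macro recall.
Percentages are formatted to 3 decimals with half-up rounding, matching the
published tables, whose counts are embedded here for verification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionMatrix", "ClassReport", "precision", "recall", "accuracy",
    "f1_score", "report", "render_report", "group_compare",
    "PUBLISHED_TABLES", "KNOWN_DISCREPANCIES", "verify_printed_tables",
]


def round3(x: float) -> float:
    """Half-up rounding to 3 decimals (the published tables' convention)."""
    if not np.isfinite(x):
        return float("nan")
    return float(Decimal(repr(float(x))).quantize(Decimal("0.001"), ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """3x3 integer counts indexed [predicted class][actual class]."""

    counts: np.ndarray
    labels: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts must be square and match the labels")
        if (self.counts < 0).any() or self.counts.sum() == 0:
            raise ValueError("counts must be non-negative with a positive total")

    def _idx(self, cls: int) -> int:
        return self.labels.index(cls)


def _as_cm(cm) -> ConfusionMatrix:
    return cm if isinstance(cm, ConfusionMatrix) else ConfusionMatrix(np.asarray(cm))


def precision(cm, cls: int) -> float:
    """Percent of predictions of ``cls`` that are correct (row total denominator)."""
    cm = _as_cm(cm)
    i = cm._idx(cls)
    denom = cm.counts[i, :].sum()
    if denom == 0:
        warnings.warn(f"no predictions of class {cls}; precision undefined", stacklevel=2)
        return float("nan")
    return 100.0 * cm.counts[i, i] / denom


def recall(cm, cls: int) -> float:
    """Percent of actual ``cls`` members predicted correctly (column denominator)."""
    cm = _as_cm(cm)
    i = cm._idx(cls)
    denom = cm.counts[:, i].sum()
    if denom == 0:
        warnings.warn(f"no actual members of class {cls}; recall undefined", stacklevel=2)
        return float("nan")
    return 100.0 * cm.counts[i, i] / denom


def accuracy(cm) -> float:
    cm = _as_cm(cm)
    return 100.0 * np.trace(cm.counts) / cm.counts.sum()


def f1_score(p: float, r: float) -> float:
    """Harmonic mean of precision and recall (percent in, percent out)."""
    if not (np.isfinite(p) and np.isfinite(r)) or p + r == 0:
        return float("nan")
    return 2.0 * p * r / (p + r)


@dataclass
class ClassReport:
    """Per-class and macro-averaged metrics of one confusion matrix (percent)."""

    per_class: dict[int, dict[str, float]]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float
    labels: tuple[int, ...] = (1, 2, 3)
    notes: list[str] = field(default_factory=list)


def report(cm) -> ClassReport:
    """Full metric report; undefined per-class metrics are excluded from macros."""
    cm = _as_cm(cm)
    per_class: dict[int, dict[str, float]] = {}
    notes: list[str] = []
    for cls in cm.labels:
        p = precision(cm, cls)
        r = recall(cm, cls)
        f = f1_score(p, r)
        per_class[cls] = {"precision": p, "recall": r, "f1": f}
        if not np.isfinite(p) or not np.isfinite(r):
            notes.append(f"class {cls}: undefined metric excluded from macro averages")
    return ClassReport(
        per_class=per_class,
        macro_precision=float(np.nanmean([m["precision"] for m in per_class.values()])),
        macro_recall=float(np.nanmean([m["recall"] for m in per_class.values()])),
        macro_f1=float(np.nanmean([m["f1"] for m in per_class.values()])),
        accuracy=accuracy(cm),
        labels=cm.labels,
        notes=notes,
    )


def render_report(cm, title: str = "") -> str:
    """Markdown table in the published layout (predicted rows x actual columns)."""
    cm = _as_cm(cm)
    rep = report(cm)
    lines = []
    if title:
        lines.append(f"### {title}")
    head = " | ".join(f"Group {c} (n)" for c in cm.labels)
    lines.append(f"| Predicted | {head} | Precision | Recall | F1-score |")
    lines.append("|" + "---|" * (len(cm.labels) + 4))
    for i, cls in enumerate(cm.labels):
        cnt = " | ".join(str(int(v)) for v in cm.counts[i])
        m = rep.per_class[cls]
        lines.append(
            f"| Group {cls} | {cnt} | {round3(m['precision']):.3f} "
            f"| {round3(m['recall']):.3f} | {round3(m['f1']):.3f} |"
        )
    lines.append(
        f"| Average | {' | '.join([''] * len(cm.labels))} "
        f"| {round3(rep.macro_precision):.3f} | {round3(rep.macro_recall):.3f} "
        f"| {round3(rep.macro_f1):.3f} |"
    )
    lines.append(f"Accuracy: {round3(rep.accuracy):.3f}%")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Published confusion matrices (six models: DT/RF x Dataset1/2/3) with the
# metrics as printed, for bit-exact verification of the arithmetic.
# counts: rows = predicted Group 1..3, columns = actual Group 1..3.

PUBLISHED_TABLES: dict[int, dict] = {
    6: {
        "model": "DT", "dataset": 1,
        "counts": [[152, 29, 22], [49, 210, 13], [48, 10, 214]],
        "printed": {
            1: (74.877, 61.044, 67.257),
            2: (77.206, 84.337, 80.614),
            3: (78.677, 85.944, 82.150),
            "average": (76.920, 77.108, 76.674),
        },
    },
    7: {
        "model": "DT", "dataset": 2,
        "counts": [[150, 22, 24], [53, 217, 12], [46, 10, 213]],
        "printed": {
            1: (76.531, 60.241, 67.416),
            2: (76.950, 87.149, 81.733),
            3: (79.182, 85.542, 82.239),
            "average": (77.644, 77.554, 77.129),
        },
    },
    8: {
        "model": "DT", "dataset": 3,
        "counts": [[155, 30, 24], [39, 215, 4], [55, 4, 221]],
        "printed": {
            1: (74.163, 62.249, 67.686),
            2: (83.333, 86.345, 84.812),
            3: (78.929, 88.755, 83.554),
            "average": (78.808, 79.116, 78.684),
        },
    },
    9: {
        "model": "RF", "dataset": 1,
        "counts": [[194, 10, 11], [29, 234, 1], [26, 5, 237]],
        "printed": {
            1: (90.233, 77.912, 85.521),
            2: (88.636, 94.000, 91.239),
            3: (88.433, 95.181, 91.683),
            "average": (89.101, 89.031, 89.481),
        },
    },
    10: {
        "model": "RF", "dataset": 2,
        "counts": [[190, 6, 5], [34, 241, 3], [25, 2, 241]],
        "printed": {
            1: (94.527, 76.305, 84.444),
            2: (86.691, 96.787, 91.461),
            3: (89.925, 96.787, 93.230),
            "average": (90.381, 89.960, 89.712),
        },
    },
    11: {
        "model": "RF", "dataset": 3,
        "counts": [[204, 7, 9], [29, 239, 4], [16, 3, 236]],
        "printed": {
            1: (92.727, 81.928, 86.994),
            2: (87.868, 95.984, 91.747),
            3: (92.549, 94.779, 93.651),
            "average": (91.048, 90.897, 90.797),
        },
    },
}

# Printed cells that do not follow from their own table's counts (audited by
# recomputing every cell). Keys: (table, row, metric); row is a class label
# or "average". These are *reported* as diffs, never silently corrected.
KNOWN_DISCREPANCIES: dict[tuple, str] = {
    (6, 3, "precision"): "prints 78.677; counts give 214/272 = 78.676",
    (7, "average", "precision"): "average precision/recall printed swapped (computed 77.554)",
    (7, "average", "recall"): "average precision/recall printed swapped (computed 77.644)",
    (8, 2, "f1"): "prints 84.812; computed 84.813 (rounding slip)",
    (9, 1, "f1"): "prints 85.521; printed precision/recall give 83.621",
    (9, 2, "recall"): "prints 94.000; counts give 234/249 = 93.976",
    (9, 2, "f1"): "prints 91.239; computed 91.228",
    (9, "average", "recall"): "prints 89.031; consistent only with the 94.000 cell (computed 89.023)",
    (9, "average", "f1"): "prints 89.481; computed 88.844",
}

# Headline summary figures that differ from the table they cite: the abstract
# quotes accuracy/average recall 90.900 (Table 11 computes 90.897) and
# F1 90.897 (Table 11 prints and computes 90.797).
ABSTRACT_HEADLINE = {"accuracy": 90.900, "precision": 91.048,
                     "recall": 90.900, "f1": 90.897}

_METRICS = ("precision", "recall", "f1")


def verify_printed_tables() -> list[dict]:
    """Recompute every printed metric of the six published confusion tables.

    Returns one record per printed cell that disagrees with the value
    recomputed from the table's own counts (3-decimal, half-up comparison).
    An empty intersection with :data:`KNOWN_DISCREPANCIES` would indicate an
    implementation defect; extra diffs beyond the known list likewise.
    """
    diffs: list[dict] = []
    for tab, spec in PUBLISHED_TABLES.items():
        cm = ConfusionMatrix(np.array(spec["counts"]))
        rep = report(cm)
        for cls in cm.labels:
            computed = (rep.per_class[cls]["precision"], rep.per_class[cls]["recall"],
                        rep.per_class[cls]["f1"])
            for metric, comp, printed in zip(_METRICS, computed, spec["printed"][cls]):
                if round3(comp) != printed:
                    diffs.append({
                        "table": tab, "row": cls, "metric": metric,
                        "printed": printed, "computed": round3(comp),
                        "known": (tab, cls, metric) in KNOWN_DISCREPANCIES,
                    })
        computed = (rep.macro_precision, rep.macro_recall, rep.macro_f1)
        for metric, comp, printed in zip(_METRICS, computed, spec["printed"]["average"]):
            if round3(comp) != printed:
                diffs.append({
                    "table": tab, "row": "average", "metric": metric,
                    "printed": printed, "computed": round3(comp),
                    "known": (tab, "average", metric) in KNOWN_DISCREPANCIES,
                })
    return diffs


# ---------------------------------------------------------------------------
# Group-comparison statistics


def _mqq(x: np.ndarray) -> tuple[float, float, float]:
    """Median with first and third quartiles, linear-interpolation convention."""
    return (float(np.median(x)),
            float(np.percentile(x, 25)),
            float(np.percentile(x, 75)))


def _holm(pvals: list[float]) -> list[float]:
    """Holm step-down adjusted p-values."""
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def group_compare(
    table: pd.DataFrame,
    features: list[str],
    group_col: str = "group",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Three-group nonparametric comparison of continuous features.

    Per feature: Kruskal-Wallis omnibus statistic (chi-square distributed,
    the 3-group extension of the rank-sum test) with its P value, per-group
    median (Q1, Q3), and pairwise Mann-Whitney U tests driving the
    significance flags (vs Group 1 and vs Group 2, at ``alpha``). A
    Holm-adjusted omnibus P column is included for transparency; the primary
    P values are unadjusted, matching common clinical reporting.
    """
    groups = sorted(table[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs_all = {g: table.loc[table[group_col] == g] for g in groups}
    if any(len(v) < 3 for v in arrs_all.values()):
        raise ValueError("each group needs at least 3 members")
    rows = []
    omnibus_p = []
    for feat in features:
        arrs = [arrs_all[g][feat].to_numpy(dtype=float) for g in groups]
        row: dict = {"feature": feat}
        for g, x in zip(groups, arrs):
            m, q1, q3 = _mqq(x)
            row[f"group{g}"] = f"{m:.3f} ({q1:.3f}, {q3:.3f})"
        if all(np.ptp(x) == 0 for x in arrs) and len({x[0] for x in arrs}) == 1:
            row.update(chi2=np.nan, p=np.nan, note="constant feature, test skipped")
            rows.append(row)
            omnibus_p.append(1.0)
            continue
        h, p = stats.kruskal(*arrs)
        row["chi2"] = float(h)
        row["p"] = float(p)
        for (i, gi), (j, gj) in [((0, groups[0]), (1, groups[1])),
                                 ((0, groups[0]), (2, groups[2])),
                                 ((1, groups[1]), (2, groups[2]))] if len(groups) == 3 else []:
            _, pij = stats.mannwhitneyu(arrs[i], arrs[j], alternative="two-sided")
            row[f"p_{gi}v{gj}"] = float(pij)
        row["significant"] = bool(p < alpha)
        omnibus_p.append(float(p))
        rows.append(row)
    holm = _holm(omnibus_p)
    out = pd.DataFrame(rows)
    out["p_holm"] = holm
    return out


def compare_categorical(
    table: pd.DataFrame, column: str, group_col: str = "group"
) -> dict:
    """Chi-square test of independence for a categorical covariate (e.g. sex)."""
    ct = pd.crosstab(table[column], table[group_col])
    chi2, p, dof, _ = stats.chi2_contingency(ct)
    return {"column": column, "chi2": float(chi2), "p": float(p), "dof": int(dof)}
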