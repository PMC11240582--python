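"""Six-metric segmentation evaluation and the paired statistical comparison.

Per label, per patient, on a per-voxel basis over the whole 3D volume:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    IoU       = TP / (TP + FP + FN)
    DSC       = 2 TP / (2 TP + FP + FN)
    HD        = max( h(G, P), h(P, G) ),   h(A, B) = max_{a in A} min_{b in B} ||a - b||

Hausdorff distance is computed over the *full* label sets (voxel centres in
physical mm), not boundaries only — the two differ when one set has an
interior cavity.  Undefined ratios (zero denominator) are reported as NaN
with a warning, never coerced to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

from .errors import ShapeMismatchError, ValidationError, ZeroVarianceError
from .volume_io import FALSE_LUMEN, LabelVolume, TRUE_LUMEN

OVERLAP_METRICS = ("accuracy", "precision", "recall", "iou", "dsc")
ALL_METRICS = OVERLAP_METRICS + ("hd",)


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-voxel confusion counts for one label in one volume pair."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricSet:
    """The six evaluation metrics; fractions in [0, 1], ``hd`` a length.

    Undefined values (zero denominators, empty label sets) are ``nan``;
    ``hd`` is ``inf`` when the label is absent from one volume.
    """

    accuracy: float
    precision: float
    recall: float
    iou: float
    dsc: float
    hd: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def _check_matched(gt: LabelVolume, pred: LabelVolume) -> None:
    if gt.shape != pred.shape:
        raise ShapeMismatchError(
            f"volume shapes differ: gt {gt.shape} vs pred {pred.shape}"
        )
    if not np.allclose(gt.spacing, pred.spacing):
        raise ShapeMismatchError(
            f"voxel spacings differ: gt {gt.spacing} vs pred {pred.spacing}"
        )


def confusion_counts(gt: LabelVolume, pred: LabelVolume, label: int) -> ConfusionCounts:
    """Voxel-wise TP/TN/FP/FN for one label over the whole volume."""
    _check_matched(gt, pred)
    g = gt.voxels == label
    p = pred.voxels == label
    tp = int(np.count_nonzero(g & p))
    fp = int(np.count_nonzero(~g & p))
    fn = int(np.count_nonzero(g & ~p))
    tn = g.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Apply the five overlap formulas to confusion counts (HD left NaN)."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    return MetricSet(
        accuracy=_ratio(tp + tn, counts.total, "accuracy"),
        precision=_ratio(tp, tp + fp, "precision"),
        recall=_ratio(tp, tp + fn, "recall"),
        iou=_ratio(tp, tp + fp + fn, "IoU"),
        dsc=_ratio(2 * tp, 2 * tp + fp + fn, "DSC"),
    )


def _directed_max(source: np.ndarray, target_edt: np.ndarray) -> float:
    return float(target_edt[source].max())


def hausdorff_distance(
    gt: LabelVolume, pred: LabelVolume, label: int, units: str = "mm"
) -> float:
    """Symmetric Hausdorff distance between the two label voxel sets.

    Point sets are voxel centres in physical coordinates (``units="mm"``) or
    index coordinates (``units="voxel"``).  Computed exactly via one
    Euclidean distance transform per direction, sampled on the opposite set.
    Returns ``inf`` with a warning when the label is absent from either
    volume.
    """
    _check_matched(gt, pred)
    if units not in ("mm", "voxel"):
        raise ValidationError(f"units must be 'mm' or 'voxel', got {units!r}")
    sampling = gt.spacing if units == "mm" else (1.0, 1.0, 1.0)
    g = gt.voxels == label
    p = pred.voxels == label
    if not g.any() or not p.any():
        warnings.warn(
            f"label {label} absent from {'gt' if not g.any() else 'pred'}; "
            "Hausdorff distance is undefined (reporting inf)"
        )
        return float("inf")
    edt_to_p = ndi.distance_transform_edt(~p, sampling=sampling)
    edt_to_g = ndi.distance_transform_edt(~g, sampling=sampling)
    return max(_directed_max(g, edt_to_p), _directed_max(p, edt_to_g))


def patient_metrics(
    gt: LabelVolume,
    pred: LabelVolume,
    labels: tuple[int, ...] = (TRUE_LUMEN, FALSE_LUMEN),
    hd_units: str = "mm",
) -> dict[int, MetricSet]:
    """Whole-volume (slices gathered, per-voxel) metrics for each label."""
    out: dict[int, MetricSet] = {}
    for label in labels:
        ms = compute_metrics(confusion_counts(gt, pred, label))
        ms.hd = hausdorff_distance(gt, pred, label, units=hd_units)
        out[label] = ms
    return out


# ---------------------------------------------------------------------------
# cross-validation layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVLayout:
    """Random equal-as-possible partition of patients into k folds."""

    patient_ids: tuple
    fold_assignment: dict
    k: int
    seed: int

    def fold(self, i: int) -> list:
        return [p for p in self.patient_ids if self.fold_assignment[p] == i]

    def folds(self) -> list[list]:
        return [self.fold(i) for i in range(self.k)]


def make_cv_layout(patient_ids, k: int = 4, seed: int = 0) -> CVLayout:
    """Shuffle patients (seeded) and deal them round-robin into ``k`` folds."""
    ids = list(patient_ids)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > len(ids):
        raise ValidationError(f"k={k} exceeds number of patients ({len(ids)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {ids[int(j)]: int(i % k) for i, j in enumerate(order)}
    return CVLayout(
        patient_ids=tuple(ids), fold_assignment=assignment, k=k, seed=seed
    )


# ---------------------------------------------------------------------------
# paired statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedComparison:
    """Shapiro–Wilk normality check and two-sided paired t-test on a - b."""

    metric_name: str
    differences: np.ndarray
    shapiro_w: float
    shapiro_p: float
    t_statistic: float
    t_p: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.t_p < self.alpha

    @property
    def normal(self) -> bool:
        return self.shapiro_p >= self.alpha


def paired_comparison(
    values_a, values_b, metric_name: str = "", alpha: float = 0.05
) -> PairedComparison:
    """Paired comparison of two per-patient series (NaN pairs dropped).

    Differences ``d = a - b`` are tested for normality (Shapiro–Wilk) and
    against zero mean with the two-sided paired t-test, ``t = mean(d) /
    (sd(d)/sqrt(n))`` on n-1 degrees of freedom.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValidationError(f"need >= 3 finite pairs, got {a.size}")
    d = a - b
    if np.ptp(d) == 0:
        raise ZeroVarianceError(
            "all paired differences are identical; t statistic undefined"
        )
    sw = stats.shapiro(d)
    tt = stats.ttest_rel(a, b)
    return PairedComparison(
        metric_name=metric_name,
        differences=d,
        shapiro_w=float(sw.statistic),
        shapiro_p=float(sw.pvalue),
        t_statistic=float(tt.statistic),
        t_p=float(tt.pvalue),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# tabulation helpers
# ---------------------------------------------------------------------------

LABEL_NAMES = {TRUE_LUMEN: "TL", FALSE_LUMEN: "FL"}


def metrics_frame(per_patient: dict[object, dict[int, MetricSet]]) -> pd.DataFrame:
    """Long-form table: one row per (patient, label) with the six metrics."""
    rows = []
    for pid, by_label in per_patient.items():
        for label, ms in by_label.items():
            row = {"patient_id": pid, "label": LABEL_NAMES.get(label, str(label))}
            row.update(ms.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_metrics(frame: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of each metric per label (undefined values excluded)."""
    agg = frame.groupby("label")[list(ALL_METRICS)].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()


def compare_conditions(
    frame_a: pd.DataFrame, frame_b: pd.DataFrame, label: str
) -> dict[str, PairedComparison]:
    """Paired t-tests per metric between two conditions on matched patients."""
    a = frame_a[frame_a["label"] == label].set_index("patient_id").sort_index()
    b = frame_b[frame_b["label"] == label].set_index("patient_id").sort_index()
    if not a.index.equals(b.index):
        raise ValidationError("patient sets differ between conditions")
    out = {}
    for m in ALL_METRICS:
        try:
            out[m] = paired_comparison(a[m].values, b[m].values, metric_name=m)
        except (ValidationError, ZeroVarianceError):
            continue
    return out
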