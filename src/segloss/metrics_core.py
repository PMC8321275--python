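"""Per-class confusion counting and segmentation metrics.

Segmentation quality is evaluated by comparing a groundtruth labelmap (GND)
with a predicted labelmap (SEG), both 2-D integer grids where each pixel
holds a class id (0 = background by convention).  Because the background
class is both huge and easy, metrics computed over all pixels at once are
dominated by it; every metric here is therefore computed *per class* from
per-class confusion counts TPc / FPc / FNc / TNc, and aggregated as an
arithmetic mean over classes, with or without the background class.

A metric whose denominator is zero (e.g. IoU of a class absent from both
maps) is *undefined*, represented as NaN, and excluded from class means --
it is never silently coerced to 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClassSet",
    "LabelMap",
    "ConfusionCounts",
    "per_class_confusion",
    "metric_suite",
    "dice_from_iou",
    "mean_over_classes",
    "METRIC_NAMES",
]

#: Columns of the metric table, in reporting order.
METRIC_NAMES = (
    "accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "fpr",
    "iou",
    "dice",
)


@dataclass(frozen=True)
class ClassSet:
    """An ordered set of integer class ids with a designated background.

    Parameters
    ----------
    labels : tuple of int
        Distinct class ids, at least two.
    background_id : int
        The id treated as background (default 0).  Must be a member of
        ``labels``.
    """

    labels: tuple[int, ...]
    background_id: int = 0

    def __post_init__(self) -> None:
        labels = tuple(int(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate class ids in {labels}")
        if len(labels) < 2:
            raise ValueError("a class set needs at least two classes")
        if self.background_id not in labels:
            raise ValueError(
                f"background id {self.background_id} not in labels {labels}"
            )

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    @property
    def foreground(self) -> tuple[int, ...]:
        return tuple(c for c in self.labels if c != self.background_id)

    def index_of(self, label: int) -> int:
        return self.labels.index(label)

    @classmethod
    def from_count(cls, n_classes: int, background_id: int = 0) -> "ClassSet":
        """Class set {0, 1, ..., n_classes-1}."""
        return cls(tuple(range(n_classes)), background_id)


@dataclass(frozen=True)
class LabelMap:
    """A 2-D grid of class labels with its class set.

    ``values`` is an integer array of shape (height, width); every entry
    must belong to ``class_set``.
    """

    values: np.ndarray
    class_set: ClassSet

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2 or arr.size < 1:
            raise ValueError(f"labelmap must be 2-D and non-empty, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"labelmap must be integer-valued, got dtype {arr.dtype}")
        present = np.unique(arr)
        allowed = set(self.class_set.labels)
        bad = [int(v) for v in present if int(v) not in allowed]
        if bad:
            raise ValueError(f"labels {bad} not in class set {self.class_set.labels}")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class ConfusionCounts:
    """Per-class TP/FP/FN/TN pixel tallies.

    Arrays are aligned with ``class_set.labels``; for every class,
    TPc + FPc + FNc + TNc equals the total pixel count.
    """

    class_set: ClassSet
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    n_pixels: int = field(init=False)

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if arr.shape != (self.class_set.n_classes,):
                raise ValueError(
                    f"{name} must have one entry per class, got shape {arr.shape}"
                )
            if (arr < 0).any():
                raise ValueError(f"negative {name} counts")
            setattr(self, name, arr)
        totals = self.tp + self.fp + self.fn + self.tn
        if len(set(totals.tolist())) != 1:
            raise ValueError("per-class counts do not sum to a common pixel total")
        self.n_pixels = int(totals[0])

    def for_class(self, label: int) -> dict[str, int]:
        i = self.class_set.index_of(label)
        return {
            "tp": int(self.tp[i]),
            "fp": int(self.fp[i]),
            "fn": int(self.fn[i]),
            "tn": int(self.tn[i]),
        }


def _check_pair(gnd: LabelMap, seg: LabelMap) -> None:
    if gnd.shape != seg.shape:
        raise ValueError(f"shape mismatch: gnd {gnd.shape} vs seg {seg.shape}")
    if gnd.class_set != seg.class_set:
        raise ValueError("gnd and seg must share a class set")


def per_class_confusion(gnd: LabelMap, seg: LabelMap) -> ConfusionCounts:
    """Count TPc, FPc, FNc, TNc for every class in one pass.

    For a class c: TPc counts pixels labelled c in both maps, FNc pixels
    labelled c in GND only, FPc pixels labelled c in SEG only, and TNc the
    remainder, so the four counts partition the image for each class.
    """
    _check_pair(gnd, seg)
    cs = gnd.class_set
    # Dense confusion matrix via a single bincount over joint codes.
    lut = np.full(max(cs.labels) + 1, -1, dtype=np.int64)
    for i, lab in enumerate(cs.labels):
        lut[lab] = i
    gi = lut[gnd.values.ravel()]
    si = lut[seg.values.ravel()]
    C = cs.n_classes
    cm = np.bincount(gi * C + si, minlength=C * C).reshape(C, C)
    tp = np.diag(cm).copy()
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = cm.sum() - tp - fn - fp
    return ConfusionCounts(cs, tp, fp, fn, tn)


def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with 0-denominators mapped to NaN (undefined)."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(num.shape, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def dice_from_iou(ji: float | np.ndarray) -> float | np.ndarray:
    """Convert a Jaccard index to the Dice coefficient: DSC = 2·JI/(JI+1)."""
    ji_arr = np.asarray(ji, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((ji_arr < 0) | (ji_arr > 1)):
            raise ValueError("Jaccard index must lie in [0, 1]")
    out = 2.0 * ji_arr / (ji_arr + 1.0)
    return float(out) if np.isscalar(ji) or ji_arr.ndim == 0 else out


def metric_suite(counts: ConfusionCounts) -> pd.DataFrame:
    """Compute the per-class metric table from confusion counts.

    Returns a DataFrame indexed by class id with columns
    ``accuracy, sensitivity, specificity, precision, fpr, iou, dice``,
    plus aggregate rows ``mean`` (over all classes) and ``mean_noBK``
    (over non-background classes).  Undefined values are NaN and are
    excluded from the aggregate rows.
    """
    tp, fp, fn, tn = (a.astype(float) for a in (counts.tp, counts.fp, counts.fn, counts.tn))
    table = pd.DataFrame(
        {
            "accuracy": _ratio(tp + tn, tp + tn + fp + fn),
            "sensitivity": _ratio(tp, tp + fn),
            "specificity": _ratio(tn, tn + fp),
            "precision": _ratio(tp, tp + fp),
            "fpr": _ratio(fp, fp + tn),
            "iou": _ratio(tp, tp + fp + fn),
            "dice": _ratio(2 * tp, 2 * tp + fp + fn),
        },
        index=pd.Index(counts.class_set.labels, name="class"),
    )
    bg = counts.class_set.background_id
    table.attrs["background_id"] = bg
    mean_all = table.mean(axis=0, skipna=True)
    mean_nobk = table.drop(index=bg).mean(axis=0, skipna=True)
    table.loc["mean"] = mean_all
    table.loc["mean_noBK"] = mean_nobk
    return table


def mean_over_classes(
    table: pd.DataFrame, metric: str, include_background: bool = True
) -> float:
    """Mean of one metric over classes with defined values.

    ``table`` is a per-class metric table from :func:`metric_suite` (the
    aggregate rows, if present, are ignored).  With
    ``include_background=False`` the background row is dropped before
    averaging.  Raises if no class has a defined value after exclusion.
    """
    if metric not in table.columns:
        raise KeyError(f"unknown metric {metric!r}; choose from {list(table.columns)}")
    rows = table.loc[[i for i in table.index if isinstance(i, (int, np.integer))]]
    if not include_background:
        # Background id is whichever integer row equals 0 unless the caller
        # built the table from a custom class set -- recover it from attrs.
        bg = table.attrs.get("background_id", 0)
        rows = rows.drop(index=bg, errors="ignore")
    vals = rows[metric].dropna()
    if vals.empty:
        raise ValueError(f"no class has a defined value for {metric!r}")
    return float(vals.mean())


def write_metric_csv(table: pd.DataFrame, path) -> None:
    """Write a metric table as CSV, one row per class plus aggregate rows."""
    table.to_csv(path, index_label="class")
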