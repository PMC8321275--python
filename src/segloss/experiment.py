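"""Experimental protocol: patient-wise cross-validation, uniclass problem
derivation, the alpha sensitivity sweep, and fold-level statistics.

The protocol mirrors a standard loss-comparison study: patients are split
into k folds (whole patients, never slices, so no leakage), each loss
condition is trained/evaluated once per fold on identical fold plans, and
conditions are compared through per-fold mean-IoU values summarised as
mean, sample standard deviation, a 90% Student-t confidence interval and
a two-sided pooled-variance two-sample t-test against a reference
condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics_core import ClassSet, LabelMap

__all__ = [
    "FoldPlan",
    "FoldStats",
    "SweepResult",
    "make_folds",
    "to_uniclass",
    "alpha_sweep",
    "fold_stats",
    "fold_stats_table",
    "comparison_report",
    "fn_direction_trial",
    "nobk_direction_trial",
]


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of patients to k cross-validation folds."""

    k: int
    assignment: dict[int, int]  # patient id -> fold index
    seed: int

    def __post_init__(self) -> None:
        folds = set(self.assignment.values())
        if not folds.issubset(range(self.k)):
            raise ValueError("fold indices out of range")
        sizes = self.fold_sizes()
        if max(sizes) - min(sizes) > 1:
            raise ValueError(f"fold sizes differ by more than 1: {sizes}")

    def fold_sizes(self) -> list[int]:
        return [sum(1 for f in self.assignment.values() if f == i) for i in range(self.k)]

    def test_patients(self, fold: int) -> list[int]:
        return sorted(p for p, f in self.assignment.items() if f == fold)

    def train_patients(self, fold: int) -> list[int]:
        return sorted(p for p, f in self.assignment.items() if f != fold)


@dataclass
class FoldStats:
    """Summary of one condition's per-fold scores.

    ``ci_low``/``ci_high`` are the 90% Student-t confidence bounds,
    mean ± t(0.95, n−1)·s/√n.  ``p_value`` is the two-sided
    pooled-variance two-sample t-test against the reference condition's
    fold values (None when no reference was given).
    """

    values: np.ndarray
    mean: float
    stdev: float
    ci_low: float
    ci_high: float
    p_value: float | None = None


def make_folds(patient_ids: Sequence[int], k: int = 5, seed: int = 0) -> FoldPlan:
    """Randomly partition patients into k folds of near-equal size.

    Deterministic under ``seed``; fold sizes differ by at most one; every
    patient belongs to exactly one fold, so for every split the train and
    test patients are disjoint.
    """
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    if len(ids) < k:
        raise ValueError(f"cannot split {len(ids)} patients into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {ids[int(j)]: int(i % k) for i, j in enumerate(order)}
    return FoldPlan(k=k, assignment=assignment, seed=seed)


def to_uniclass(labelmap: LabelMap, target: int) -> LabelMap:
    """Reduce a multiclass labelmap to the binary problem for one class.

    Every class other than ``target`` is relabelled background; the
    target's pixels are preserved.  The result's class set is
    {background, target}.
    """
    cs = labelmap.class_set
    if target == cs.background_id:
        raise ValueError("target class must not be the background")
    if target not in cs.labels:
        raise ValueError(f"class {target} not in class set {cs.labels}")
    values = np.where(labelmap.values == target, target, cs.background_id)
    out_cs = ClassSet((cs.background_id, target), background_id=cs.background_id)
    return LabelMap(values.astype(labelmap.values.dtype), out_cs)


@dataclass
class SweepResult:
    """Result of an alpha sensitivity sweep: (alpha, score) pairs, beta = 2−alpha."""

    alphas: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.alphas) > 0):
            raise ValueError("alphas must be strictly increasing")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"alpha": self.alphas, "beta": 2.0 - self.alphas, "mean_iou": self.scores}
        )


def alpha_sweep(
    evaluate: Callable[[float, float], float], step: float = 0.25
) -> SweepResult:
    """Evaluate a condition over the alpha grid {0, step, ..., 2}, beta = 2−alpha.

    ``evaluate(alpha, beta)`` returns the score for one weighting (e.g.
    mean IoU of a model trained with that weighted loss).  ``step`` must
    divide 2 evenly; step 0.25 yields the canonical 9-point grid.  A
    callback failure is re-raised annotated with the offending alpha.
    """
    n_steps = 2.0 / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"step {step} does not divide the [0, 2] range evenly")
    alphas = np.array([i * step for i in range(int(round(n_steps)) + 1)])
    scores = []
    for a in alphas:
        try:
            scores.append(float(evaluate(float(a), float(2.0 - a))))
        except Exception as exc:
            raise RuntimeError(f"sweep evaluation failed at alpha={a:g}") from exc
    return SweepResult(alphas=alphas, scores=np.array(scores))


def fold_stats(
    values: Sequence[float],
    reference: Sequence[float] | None = None,
    confidence: float = 0.90,
) -> FoldStats:
    """Summarise per-fold scores: mean, sample stdev, t-CI, p-value.

    The confidence interval is mean ± t(1−(1−confidence)/2, n−1)·s/√n.
    With a ``reference``, the p-value is a two-sided two-sample
    pooled-variance t-test of the condition's fold values against the
    reference's (equal_var=True).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two folds")
    mean = float(x.mean())
    stdev = float(x.std(ddof=1))
    tcrit = float(stats.t.ppf(1.0 - (1.0 - confidence) / 2.0, df=x.size - 1))
    half = tcrit * stdev / np.sqrt(x.size)
    p_value = None
    if reference is not None:
        y = np.asarray(reference, dtype=float)
        if y.size != x.size:
            raise ValueError("reference must have the same number of folds")
        p_value = float(stats.ttest_ind(x, y, equal_var=True).pvalue)
    return FoldStats(
        values=x, mean=mean, stdev=stdev,
        ci_low=mean - half, ci_high=mean + half, p_value=p_value,
    )


def comparison_report(
    per_class_tables: dict[str, pd.DataFrame],
    metric: str = "iou",
) -> pd.DataFrame:
    """Tabulate one metric per class across conditions, plus a mean row.

    ``per_class_tables`` maps condition name -> per-class metric table
    (from ``metrics_core.metric_suite``).  All conditions must cover the
    same classes — they are expected to come from identical fold plans.
    Rows are the class ids followed by 'mean'; columns are conditions.
    """
    if not per_class_tables:
        raise ValueError("no conditions to report")
    class_rows = None
    columns = {}
    for name, table in per_class_tables.items():
        rows = [i for i in table.index if isinstance(i, (int, np.integer))]
        if class_rows is None:
            class_rows = rows
        elif rows != class_rows:
            raise ValueError(
                f"condition {name!r} covers classes {rows}, expected {class_rows}"
            )
        col = table.loc[class_rows, metric].tolist()
        col.append(float(table.loc[class_rows, metric].dropna().mean()))
        columns[name] = col
    index = pd.Index([*class_rows, "mean"], name="class")
    return pd.DataFrame(columns, index=index)


def _foreground_mean(table: pd.DataFrame, metric: str) -> float:
    fg = [i for i in table.index if isinstance(i, (int, np.integer)) and i != 0]
    vals = table.loc[fg, metric].dropna()
    return float(vals.mean()) if len(vals) else 0.0


def fn_direction_trial(
    seed: int,
    size: tuple[int, int] = (32, 32),
    background_fraction: float = 0.90,
    noise_sd: float = 0.15,
    epochs: int = 40,
    learning_rate: float = 0.5,
) -> dict[str, float]:
    """One trial of the FP/FN-weighting direction experiment.

    Regime: small foreground, erosion-biased initialisation.  A crossE
    model is warm-started on *eroded* groundtruths, so the initial
    segmenter under-segments (false negatives dominate).  From that
    common warm start, the weighted IoU loss is fine-tuned on the true
    labels twice — once FN-heavy (alpha=0.5, beta=1.5), once FP-heavy
    (alpha=1.5, beta=0.5).  Penalising false negatives more should
    preserve or expand the predicted regions, i.e. yield the higher
    foreground sensitivity; penalising false positives more should
    shrink them.

    Returns ``{'sensitivity_beta15': ..., 'sensitivity_beta05': ...}``
    measured on held-out patients.
    """
    from .losses import PRESETS, LossSpec
    from .synthetic_data import PerturbSpec, PhantomSpec, generate_patient_series, perturb
    from .training_harness import TrainConfig, evaluate, train

    spec = PhantomSpec(
        size=size, n_classes=2, background_fraction=background_fraction,
        noise_sd=noise_sd, seed=1000 + seed,
    )
    records = generate_patient_series(7, 2, spec)
    train_recs, test_recs = records[:10], records[10:]
    eroded = [
        (p, img, perturb(lab, PerturbSpec(erode={1: 2}, seed=0)))
        for p, img, lab in train_recs
    ]
    warm = train(
        eroded,
        TrainConfig(loss=PRESETS["crossE"], epochs=30, batch_size=4,
                    learning_rate=1.0, seed=seed),
    ).model
    out = {}
    for key, (a, b) in (("sensitivity_beta15", (0.5, 1.5)),
                        ("sensitivity_beta05", (1.5, 0.5))):
        tc = TrainConfig(loss=LossSpec("iou", alpha=a, beta=b), epochs=epochs,
                         batch_size=4, learning_rate=learning_rate, seed=seed)
        result = train(train_recs, tc, warm_start=warm)
        table = evaluate(result.model, test_recs)
        out[key] = float(table.loc[1, "sensitivity"])
    return out


def nobk_direction_trial(
    seed: int,
    size: tuple[int, int] = (32, 32),
    background_fraction: float = 0.96,
    noise_sd: float = 0.15,
    epochs: int = 60,
    learning_rate: float = 0.5,
) -> dict[str, float]:
    """One trial of the background-exclusion direction experiment.

    Regime: tiny foreground classes on a dominant background.  Training
    dice with the background in the class average rewards sharpening the
    (easy, huge) background term; dropping it (dice noBK) spends the
    whole loss budget on the small structures, which should give equal
    or better foreground IoU.

    Returns ``{'fg_iou_nobk': ..., 'fg_iou_withbk': ...}`` (foreground
    mean IoU on held-out patients).
    """
    from .losses import PRESETS
    from .synthetic_data import PhantomSpec, generate_patient_series
    from .training_harness import TrainConfig, evaluate, train

    spec = PhantomSpec(
        size=size, n_classes=3, background_fraction=background_fraction,
        noise_sd=noise_sd, seed=2000 + seed,
    )
    records = generate_patient_series(7, 2, spec)
    train_recs, test_recs = records[:10], records[10:]
    out = {}
    for key, preset in (("fg_iou_nobk", "dice_noBK"), ("fg_iou_withbk", "dice")):
        tc = TrainConfig(loss=PRESETS[preset], epochs=epochs, batch_size=4,
                         learning_rate=learning_rate, seed=seed)
        result = train(train_recs, tc)
        out[key] = _foreground_mean(evaluate(result.model, test_recs), "iou")
    return out


def fold_stats_table(
    per_condition_values: dict[str, Sequence[float]],
    reference_condition: str | None = None,
) -> pd.DataFrame:
    """Summary table across conditions: per-fold values, Avg, stdev, CI, p.

    One row per condition with columns CV1..CVk, avg, stdev, ci_low,
    ci_high and p_value (vs ``reference_condition``; the reference's own
    p-value is NaN).
    """
    if reference_condition is not None and reference_condition not in per_condition_values:
        raise KeyError(f"reference condition {reference_condition!r} not present")
    ref = (
        per_condition_values[reference_condition]
        if reference_condition is not None
        else None
    )
    rows = {}
    for name, vals in per_condition_values.items():
        is_ref = name == reference_condition
        st = fold_stats(vals, None if (is_ref or ref is None) else ref)
        row = {f"CV{i + 1}": v for i, v in enumerate(st.values)}
        row.update(
            avg=st.mean, stdev=st.stdev, ci_low=st.ci_low, ci_high=st.ci_high,
            p_value=np.nan if st.p_value is None else st.p_value,
        )
        rows[name] = row
    return pd.DataFrame(rows).T
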