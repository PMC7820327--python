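"""Evaluation protocol: repeated stratified CV, operating-point metrics,
paired t-tests and score repeatability.

The protocol mirrors a screening-study design: ten runs of ten-fold
stratified cross-validation (each run with its own shuffling seed), a single
stratified 90/10 hold-out validation split inside every training set,
accuracy / AUC / sensitivity / specificity at the operating threshold where
sensitivity and specificity are most similar, a paired-sample t-test between
pipeline variants at alpha = 0.001, and image-wise relative standard
deviation (RSD = 100 * sd / mean) of test scores across runs as a
repeatability measure.

``run_comparison`` executes the whole protocol for the 7-standard-field
versus central-fields (F1-F2) crop variants on a common dataset with shared
fold assignments, so all per-fold metric differences are paired.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

from .errors import DegenerateTestError, ValidationError

METRICS = ("accuracy", "auc", "sensitivity", "specificity")


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValidationError("confusion counts must be nonnegative")


@dataclass
class CVPlan:
    n_runs: int = 10
    n_folds: int = 10
    stratified: bool = True
    val_folds: int = 10  # hold-out = 1/val_folds of each training set
    seed: int = 0

    def run_seeds(self) -> List[int]:
        rng = np.random.default_rng(self.seed)
        return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=self.n_runs)]


@dataclass
class FoldAssignment:
    run: int
    fold: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


def make_cv_plan(labels: Sequence[int], plan: CVPlan) -> List[List[FoldAssignment]]:
    """Stratified fold assignments for every run, with inner hold-out splits.

    Every sample appears in exactly one test fold per run; within each
    training set a stratified ``1/val_folds`` hold-out (default 10%) is
    reserved for validation.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("need both classes present")
    if counts.min() < plan.n_folds:
        raise ValidationError(
            f"smallest class has {counts.min()} samples; needs >= n_folds = {plan.n_folds}")
    runs = []
    for run, run_seed in enumerate(plan.run_seeds()):
        outer = StratifiedKFold(n_splits=plan.n_folds, shuffle=True, random_state=run_seed)
        folds = []
        for fold, (train_all, test_idx) in enumerate(outer.split(np.zeros(len(labels)), labels)):
            inner = StratifiedKFold(n_splits=plan.val_folds, shuffle=True,
                                    random_state=run_seed + fold + 1)
            tr_rel, val_rel = next(inner.split(np.zeros(len(train_all)), labels[train_all]))
            folds.append(FoldAssignment(
                run=run, fold=fold,
                train_idx=train_all[tr_rel], val_idx=train_all[val_rel],
                test_idx=test_idx))
        runs.append(folds)
    return runs


def compute_metrics(counts: ConfusionCounts) -> Tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) from confusion counts."""
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    if pos == 0 or neg == 0:
        raise ValidationError("need at least one positive and one negative")
    return (counts.tp / pos, counts.tn / neg,
            (counts.tp + counts.tn) / (pos + neg))


def confusion_at(scores: Sequence[float], labels: Sequence[int],
                 threshold: float) -> ConfusionCounts:
    """Counts with the convention score >= threshold => predicted positive."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = s >= threshold
    return ConfusionCounts(
        tp=int((pred & (y == 1)).sum()), fn=int((~pred & (y == 1)).sum()),
        tn=int((~pred & (y == 0)).sum()), fp=int((pred & (y == 0)).sum()))


def pick_operating_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Threshold where sensitivity and specificity are most similar.

    Candidates are midpoints between consecutive sorted unique scores plus
    one below the minimum and one above the maximum.  Ties are broken by the
    larger sensitivity + specificity sum, then by the lower threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValidationError("need both classes present")
    uniq = np.unique(s)
    cands = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    best = None
    for thr in cands:
        sens, spec, _ = compute_metrics(confusion_at(s, y, thr))
        key = (abs(sens - spec), -(sens + spec), thr)
        if best is None or key < best[0]:
            best = (key, thr)
    return float(best[1])


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank (Mann-Whitney) AUC: P(random positive outscores random negative),
    ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("need both classes present")
    ranks = sps.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def paired_t_test(metric_a: Sequence[float], metric_b: Sequence[float],
                  alpha: float = 0.001) -> Tuple[float, float, int]:
    """Two-sided paired-sample t-test; returns (t, p, H) with H = 1 iff p < alpha."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValidationError("metric lists must be equal-length 1-D with n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise DegenerateTestError("paired differences have zero variance")
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p), int(p < alpha)


def compute_rsd(per_image_scores: Sequence[Sequence[float]],
                ) -> Tuple[List[Optional[float]], float]:
    """Image-wise relative standard deviation of scores across runs.

    ``RSD_i = 100 * sd_i / mean_i`` (sample sd).  Images whose mean score is
    zero get ``None`` and are excluded from the average.
    """
    rsds: List[Optional[float]] = []
    valid = []
    for scores in per_image_scores:
        s = np.asarray(scores, dtype=float)
        if len(s) < 2:
            raise ValidationError("each image needs >= 2 scores")
        mean = s.mean()
        if mean == 0.0:
            rsds.append(None)
            continue
        rsd = 100.0 * s.std(ddof=1) / mean
        rsds.append(float(rsd))
        valid.append(rsd)
    if not valid:
        raise ValidationError("no image has a nonzero mean score")
    return rsds, float(np.mean(valid))


@dataclass
class CVReport:
    """Per-(run, fold) metric table plus summaries for one pipeline variant."""

    variant: str
    table: pd.DataFrame  # columns: run, fold, accuracy, auc, sensitivity, specificity, threshold
    per_image_scores: np.ndarray  # (n_images, n_runs)
    roc_points: Dict[Tuple[int, int], pd.DataFrame] = field(default_factory=dict)

    def summary(self) -> Dict[str, Tuple[float, float]]:
        """mean +- sample SD per metric over all (run, fold) cells."""
        return {m: (float(self.table[m].mean()), float(self.table[m].std(ddof=1)))
                for m in METRICS}

    def rsd(self) -> Tuple[List[Optional[float]], float]:
        return compute_rsd(list(self.per_image_scores))


def evaluate_fold(scores: np.ndarray, labels: np.ndarray) -> Dict[str, float]:
    thr = pick_operating_threshold(scores, labels)
    sens, spec, acc = compute_metrics(confusion_at(scores, labels, thr))
    return {"accuracy": acc, "auc": compute_auc(scores, labels),
            "sensitivity": sens, "specificity": spec, "threshold": thr}


@dataclass
class ComparisonResult:
    report_a: CVReport
    report_b: CVReport
    t_tests: pd.DataFrame  # rows: metric; columns: t, p, H
    rsd_a: float
    rsd_b: float
    excluded: List[Tuple[int, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "summary": {self.report_a.variant: {k: list(v) for k, v in self.report_a.summary().items()},
                        self.report_b.variant: {k: list(v) for k, v in self.report_b.summary().items()}},
            "t_tests": self.t_tests.to_dict(orient="index"),
            "rsd": {self.report_a.variant: self.rsd_a, self.report_b.variant: self.rsd_b},
            "n_excluded": len(self.excluded),
        }


def compare_scored_variants(labels: Sequence[int],
                            scores_a: np.ndarray, scores_b: np.ndarray,
                            folds: List[List[FoldAssignment]],
                            names: Tuple[str, str] = ("SF7", "F1F2"),
                            alpha: float = 0.001) -> ComparisonResult:
    """Assemble paired reports + t-tests from per-(run, image) score matrices.

    ``scores_*`` have shape (n_runs, n_images); entry (r, i) is the test score
    of image i in run r (each image is in exactly one test fold per run).
    """
    labels = np.asarray(labels).astype(int)
    reports = []
    for name, scores in zip(names, (scores_a, scores_b)):
        rows = []
        for run_folds in folds:
            for fa in run_folds:
                y = labels[fa.test_idx]
                s = scores[fa.run, fa.test_idx]
                rows.append({"run": fa.run, "fold": fa.fold, **evaluate_fold(s, y)})
        table = pd.DataFrame(rows)
        reports.append(CVReport(variant=name, table=table, per_image_scores=scores.T))
    rep_a, rep_b = reports
    t_rows = {}
    for m in METRICS:
        try:
            t, p, h = paired_t_test(rep_a.table[m].values, rep_b.table[m].values, alpha)
        except DegenerateTestError:
            t, p, h = 0.0, 1.0, 0  # identical variants: no difference
        t_rows[m] = {"t": t, "p": p, "H": h}
    if scores_a.shape[0] >= 2:
        _, rsd_a = rep_a.rsd()
        _, rsd_b = rep_b.rsd()
    else:  # repeatability is undefined for a single run
        rsd_a = rsd_b = float("nan")
    return ComparisonResult(report_a=rep_a, report_b=rep_b,
                            t_tests=pd.DataFrame(t_rows).T,
                            rsd_a=rsd_a, rsd_b=rsd_b)


def run_comparison(items: Sequence, plan: CVPlan, *,
                   cls_config=None, landmark_stats=None,
                   variant_a: str = "SF7", variant_b: str = "F1F2",
                   geometry=None, alpha: float = 0.001,
                   use_ground_truth_landmarks: bool = False,
                   log=None) -> ComparisonResult:
    """Full paired protocol: crops -> repeated CV training -> metrics/t-test/RSD.

    ``items`` are labeled images (``LabeledImage`` or (image, label) tuples,
    optionally with ground-truth landmarks).  Landmarks come from the
    heuristic detector unless ``use_ground_truth_landmarks`` is set; images
    failing detection or crop extraction for either variant are excluded from
    both and listed in ``ComparisonResult.excluded``.  Both variants share
    fold assignments and training seeds, so per-fold differences are paired.
    """
    from . import classifier as clf
    from . import field_geometry as fg
    from . import landmarks as lmk

    cls_config = cls_config or clf.ClsTrainConfig(depth="reduced", input_size=32)
    cls_config.validate()

    crops: Dict[str, list] = {variant_a: [], variant_b: []}
    labels: List[int] = []
    excluded: List[Tuple[int, str]] = []
    out_px = cls_config.input_size
    out_sizes = {"SF7": (out_px * 7, out_px * 8), "F1F2": (out_px * 7, out_px * 10)}
    for i, item in enumerate(items):
        if hasattr(item, "image"):
            image, label = item.image, item.label
            truth = getattr(item, "landmarks", None)
        else:
            image, label = item[0], item[1]
            truth = item[2] if len(item) > 2 else None
        try:
            if use_ground_truth_landmarks:
                if truth is None:
                    raise ValidationError("no ground-truth landmarks supplied")
                lm = truth
            else:
                if landmark_stats is None:
                    raise ValidationError("landmark_stats required for detection")
                lm = lmk.detect_landmarks(image, landmark_stats)
            img2, lm2, _ = fg.normalize_laterality(image, lm)
            rot, lm3, _ = fg.align_rotation(img2, lm2)
            pair = {kind: fg.extract_field_crop(rot, lm3, kind, geometry,
                                                out_size=out_sizes[kind])
                    for kind in (variant_a, variant_b)}
        except Exception as exc:  # noqa: BLE001 - exclusion mirrors manual QC
            excluded.append((i, str(exc)))
            continue
        for kind in (variant_a, variant_b):
            crops[kind].append(pair[kind])
        labels.append(int(label))
        if log is not None and (i + 1) % 50 == 0:
            log(f"prepared {i + 1}/{len(items)} images")

    labels_arr = np.asarray(labels)
    folds = make_cv_plan(labels_arr, plan)
    X = {kind: clf.prepare_inputs(crops[kind], cls_config.input_size)
         for kind in (variant_a, variant_b)}

    scores = {kind: np.zeros((plan.n_runs, len(labels_arr))) for kind in (variant_a, variant_b)}
    for run_folds in folds:
        for fa in run_folds:
            for kind in (variant_a, variant_b):
                cfg = clf.ClsTrainConfig(**{**cls_config.__dict__})
                cfg.seed = cls_config.seed + 1000 * fa.run + fa.fold
                model = clf._train_on_tensors(X[kind][fa.train_idx],
                                              labels_arr[fa.train_idx], cfg)
                scores[kind][fa.run, fa.test_idx] = clf._scores_on_tensors(
                    model, X[kind][fa.test_idx])
            if log is not None:
                log(f"run {fa.run} fold {fa.fold} done")

    result = compare_scored_variants(labels_arr, scores[variant_a], scores[variant_b],
                                     folds, names=(variant_a, variant_b), alpha=alpha)
    result.excluded = excluded
    return result
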