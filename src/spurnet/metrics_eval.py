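"""Segmentation metrics, the (K, θ) parameter sweep, and k-fold CV.

Metrics come in two formula modes. ``paper`` reproduces the printed
equations of the source protocol verbatim:

    PA    = (TP+TN) / (TP+TN+FP+FN)
    MPA   = ½ · [ TP/(TP+FP) + TN/(TN+FN) ]          (precision-like)
    MIoU  = ½ · [ TP/(TP+FP+FN) + TN/(TN+FN+FP) ]
    FWIoU = (TP+FN)/total · TP/(TP+FP+FN)            (tongue term only)

``standard`` uses the conventional definitions instead: recall-based MPA
and the two-class frequency-weighted IoU sum. A 0/0 per-class term (class
absent from both prediction and truth) is dropped from the average and
recorded in the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold

from .io_formats import SegMask
from .refine import RefineParams, refine_mask
from .slic import SlicParams, slic

METRIC_NAMES = ("PA", "MPA", "MIoU", "FWIoU")


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP, self.FN + other.FN, self.TN + other.TN
        )


@dataclass
class MetricsReport:
    PA: float
    MPA: float
    MIoU: float
    FWIoU: float
    formula_mode: str = "paper"
    dropped_terms: tuple = ()  # names of 0/0 class terms omitted from means

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion(pred: SegMask, truth: SegMask) -> ConfusionCounts:
    """Pixel tallies of a binary prediction against ground truth."""
    if pred.shape != truth.shape:
        raise ValueError(f"prediction {pred.shape} vs truth {truth.shape}")
    p = pred.labels.astype(np.int64).ravel()
    t = truth.labels.astype(np.int64).ravel()
    counts = np.bincount(2 * t + p, minlength=4)
    tn, fp, fn, tp = counts
    return ConfusionCounts(int(tp), int(fp), int(fn), int(tn))


def _safe_terms(pairs):
    """Average the defined num/den terms; report which were 0/0."""
    vals, dropped = [], []
    for name, num, den in pairs:
        if den == 0:
            dropped.append(name)
        else:
            vals.append(num / den)
    mean = float(np.mean(vals)) if vals else float("nan")
    return mean, tuple(dropped)


def metrics(c: ConfusionCounts, formula_mode: str = "paper") -> MetricsReport:
    """Compute PA/MPA/MIoU/FWIoU from confusion counts."""
    if formula_mode not in ("paper", "standard"):
        raise ValueError("formula_mode must be 'paper' or 'standard'")
    tp, fp, fn, tn = c.TP, c.FP, c.FN, c.TN
    total = c.total
    pa = (tp + tn) / total if total else float("nan")
    dropped: list[str] = []
    if formula_mode == "paper":
        mpa, d1 = _safe_terms(
            [("tongue_precision", tp, tp + fp), ("background_precision", tn, tn + fn)]
        )
        fwiou_terms = [("tongue_fwiou", (tp + fn) / total * tp, tp + fp + fn)] if total else []
        fwiou, d3 = _safe_terms(fwiou_terms)
    else:
        mpa, d1 = _safe_terms(
            [("tongue_recall", tp, tp + fn), ("background_recall", tn, tn + fp)]
        )
        terms = []
        if total:
            terms = [
                ("tongue_fwiou", (tp + fn) / total * tp, tp + fp + fn),
                ("background_fwiou", (tn + fp) / total * tn, tn + fn + fp),
            ]
        # frequency-weighted sum, not mean
        vals = [num / den for _, num, den in terms if den]
        d3 = tuple(name for name, _, den in terms if not den)
        fwiou = float(np.sum(vals)) if vals else float("nan")
    miou, d2 = _safe_terms(
        [("tongue_iou", tp, tp + fp + fn), ("background_iou", tn, tn + fn + fp)]
    )
    dropped = tuple(d1) + tuple(d2) + tuple(d3)
    return MetricsReport(pa, mpa, miou, fwiou, formula_mode, dropped)


def evaluate_pair(pred: SegMask, truth: SegMask, formula_mode: str = "paper") -> MetricsReport:
    return metrics(confusion(pred, truth), formula_mode)


# ---------------------------------------------------------------------------
# parameter sweep


@dataclass
class SweepResult:
    K_grid: tuple
    theta_grid: tuple
    surface: np.ndarray  # (len(K_grid), len(theta_grid)) mean MIoU
    best_K: int
    best_theta: float

    def to_csv(self, path) -> None:
        lines = ["K,theta,mean_MIoU"]
        for i, k in enumerate(self.K_grid):
            for j, t in enumerate(self.theta_grid):
                lines.append(f"{k},{t},{self.surface[i, j]:.6f}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def sweep_params(
    scenes: list,
    K_grid,
    theta_grid,
    m: float = 10.0,
    mode: str = "retain",
    formula_mode: str = "paper",
) -> SweepResult:
    """Mean-MIoU surface over superpixel count K and coverage threshold θ.

    ``scenes`` is a list of (image, coarse mask, truth mask) triples. The
    superpixel labeling is computed once per (K, scene) and reused for every
    θ. The argmax breaks ties toward smaller K, then smaller θ.
    """
    K_grid, theta_grid = tuple(K_grid), tuple(theta_grid)
    if not K_grid or not theta_grid:
        raise ValueError("K_grid and theta_grid must be nonempty")
    surface = np.zeros((len(K_grid), len(theta_grid)))
    for i, K in enumerate(K_grid):
        sp_params = SlicParams(K=K, m=m)
        labelings = [slic(img, sp_params) for img, _, _ in scenes]
        for j, theta in enumerate(theta_grid):
            rp = RefineParams(theta=theta, mode=mode, slic_params=sp_params)
            mious = []
            for (img, coarse, truth), sp in zip(scenes, labelings):
                refined = refine_mask(coarse, sp, rp)
                mious.append(evaluate_pair(refined, truth, formula_mode).MIoU)
            surface[i, j] = float(np.mean(mious))
    bi, bj = 0, 0
    for i in range(len(K_grid)):
        for j in range(len(theta_grid)):
            if surface[i, j] > surface[bi, bj]:  # strict: earlier cell wins ties
                bi, bj = i, j
    return SweepResult(K_grid, theta_grid, surface, K_grid[bi], theta_grid[bj])


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CvResult:
    fold_reports_coarse: list
    fold_reports_refined: list
    seed: int

    def _stats(self, reports):
        out = {}
        for name in METRIC_NAMES:
            vals = np.array([getattr(r, name) for r in reports], dtype=float)
            out[name] = (
                float(vals.mean()),
                float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            )
        return out

    def summary(self) -> dict:
        """{'coarse'|'refined': {metric: (mean, sample std)}}"""
        return {
            "coarse": self._stats(self.fold_reports_coarse),
            "refined": self._stats(self.fold_reports_refined),
        }

    def to_markdown(self) -> str:
        """Mean ± std table, one row per stage, best value per column bold."""
        s = self.summary()
        lines = ["| Stage | " + " | ".join(METRIC_NAMES) + " |",
                 "|---|" + "---|" * len(METRIC_NAMES)]
        best = {n: max(s[row][n][0] for row in s) for n in METRIC_NAMES}
        for row in ("coarse", "refined"):
            cells = []
            for n in METRIC_NAMES:
                mean, sd = s[row][n]
                cell = f"{mean:.4f} ± {sd:.4f}"
                if mean == best[n]:
                    cell = f"**{cell}**"
                cells.append(cell)
            lines.append(f"| {row} | " + " | ".join(cells) + " |")
        return "\n".join(lines)


def kfold_cv(
    dataset: list,
    trainer,
    refine_params: RefineParams | None = None,
    k: int = 10,
    seed: int = 0,
    formula_mode: str = "paper",
) -> CvResult:
    """k-fold cross-validation of the full two-stage pipeline.

    ``dataset`` is a list of (normalized image, truth mask) pairs.
    ``trainer`` maps a list of training pairs to a callable
    ``predict(img) -> SegMask`` producing the coarse mask. Per fold, the
    confusion counts of the held-out images are pooled (micro-average)
    before the metrics are computed; means and sample standard deviations
    are then taken across folds.
    """
    if len(dataset) < k:
        raise ValueError(f"dataset of {len(dataset)} items cannot be split into {k} folds")
    refine_params = refine_params or RefineParams()
    coarse_reports, refined_reports = [], []
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in splitter.split(np.arange(len(dataset))):
        predict = trainer([dataset[i] for i in train_idx])
        c_coarse = ConfusionCounts(0, 0, 0, 0)
        c_refined = ConfusionCounts(0, 0, 0, 0)
        for i in test_idx:
            img, truth = dataset[i]
            coarse = predict(img)
            sp = slic(img, refine_params.slic_params)
            refined = refine_mask(coarse, sp, refine_params)
            c_coarse = c_coarse + confusion(coarse, truth)
            c_refined = c_refined + confusion(refined, truth)
        coarse_reports.append(metrics(c_coarse, formula_mode))
        refined_reports.append(metrics(c_refined, formula_mode))
    return CvResult(coarse_reports, refined_reports, seed)
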