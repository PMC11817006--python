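"""Z-score composite scoring, ROC/Youden thresholding, and evaluation.

Features are put on a common scale with Z-scores, combined by a positive
weighted sum, and thresholded at the Youden-optimal point of the in-sample
ROC curve. Weights come either from the caller or from a seeded random
search over an integer grid with Youden / accuracy / recall selection
criteria. All metrics are kept at full precision internally; rounding
(half-up, two decimals) happens only at presentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

FEATURES = ["trv", "ade_s", "adi_s", "trr"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), used only for presentation."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def zscale(
    values, ddof: int = 0, name: str | None = None
) -> tuple[np.ndarray, float, float]:
    """Z-scores of a column plus the fitted (mu, sigma).

    ``ddof=0`` (population sigma) is the default convention; set ``ddof=1``
    for the sample estimator.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("zscale needs at least 2 values")
    mu = float(values.mean())
    sigma = float(values.std(ddof=ddof))
    if sigma == 0:
        label = f" '{name}'" if name else ""
        raise ValueError(f"feature column{label} is constant (sigma = 0); cannot Z-scale")
    return (values - mu) / sigma, mu, sigma


def composite_score(z, w) -> float | np.ndarray:
    """Weighted sum of z-values over the active feature subset."""
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    if z.shape[-1] != w.shape[0]:
        raise ValueError(
            f"z-values and weights must align on the active subset "
            f"({z.shape[-1]} vs {w.shape[0]})"
        )
    return z @ w


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(FPR, TPR, threshold) triples under the score >= threshold rule.

    Thresholds are the distinct score values in descending order, preceded by
    a finite sentinel (max + 1) that classifies nothing as positive, so the
    curve starts at (0, 0) and ends at (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    _check_two_classes(labels)
    uniq = np.unique(scores)[::-1]
    thresholds = np.concatenate([[uniq[0] + 1.0], uniq])
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        pred = scores >= t
        tpr[i] = (pred & labels).sum() / n_pos
        fpr[i] = (pred & ~labels).sum() / n_neg
    return fpr, tpr, thresholds


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_two_classes(labels)
    ranks = stats.rankdata(scores)
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def youden_threshold(scores, labels) -> tuple[float, float]:
    """Threshold maximizing J = TPR - FPR; ties favor higher specificity."""
    fpr, tpr, thr = roc_curve(scores, labels)
    j = tpr - fpr
    # lexicographic: maximize J, then specificity (minimize FPR), then take
    # the higher threshold (earliest point on the descending-threshold path)
    best = 0
    for i in range(1, len(thr)):
        if (j[i], -fpr[i]) > (j[best], -fpr[best]):
            best = i
    return float(thr[best]), float(j[best])


def classify(scores, threshold: float):
    """Boundary-inclusive rule: score >= threshold -> positive (COPD)."""
    scores = np.asarray(scores, dtype=float)
    return scores >= threshold


@dataclass
class EvaluationReport:
    """Confusion counts and every derived rate, COPD as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "EvaluationReport":
        y_true = np.asarray(y_true, dtype=bool)
        y_pred = np.asarray(y_pred, dtype=bool)
        if y_true.shape != y_pred.shape:
            raise ValueError("prediction and truth vectors must have equal length")
        _check_two_classes(y_true)
        return cls(
            tp=int((y_pred & y_true).sum()),
            fn=int((~y_pred & y_true).sum()),
            tn=int((~y_pred & ~y_true).sum()),
            fp=int((y_pred & ~y_true).sum()),
        )

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def precision_pos(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall_pos(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1_pos(self) -> float:
        p, r = self.precision_pos, self.recall_pos
        return 2 * p * r / (p + r) if p + r else 0.0

    @property
    def precision_neg(self) -> float:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else 0.0

    @property
    def recall_neg(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def f1_neg(self) -> float:
        p, r = self.precision_neg, self.recall_neg
        return 2 * p * r / (p + r) if p + r else 0.0

    @property
    def sensitivity(self) -> float:
        return self.recall_pos

    @property
    def specificity(self) -> float:
        return self.recall_neg

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    def to_dict(self, rounded: bool = False) -> dict:
        d = {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "precision_pos": self.precision_pos,
            "recall_pos": self.recall_pos,
            "f1_pos": self.f1_pos,
            "precision_neg": self.precision_neg,
            "recall_neg": self.recall_neg,
            "f1_neg": self.f1_neg,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "youden": self.youden,
        }
        if rounded:
            for k, v in d.items():
                if not isinstance(v, int):
                    d[k] = round_half_up(v, 2)
        return d

    def confusion_text(self) -> str:
        return (
            "            pred COPD  pred non-patient\n"
            f"COPD        {self.tp:9d}  {self.fn:16d}\n"
            f"non-patient {self.fp:9d}  {self.tn:16d}\n"
        )


def evaluate(y_true, y_pred) -> EvaluationReport:
    """Confusion counts and derived rates for predicted vs true labels."""
    return EvaluationReport.from_predictions(y_true, y_pred)


@dataclass
class ScoreModel:
    """Fitted Z-scaling parameters, weights, and classification threshold."""

    mu: dict
    sigma: dict
    weights: dict
    threshold: float
    feature_subset: list = field(default_factory=lambda: list(FEATURES))
    ddof: int = 0
    youden: float | None = None
    accuracy: float | None = None
    below_criteria: bool = False
    rng_seed: int | None = None

    def score(self, table: pd.DataFrame) -> np.ndarray:
        """Composite scores for a feature table using the fitted parameters."""
        z = np.column_stack(
            [(table[f].to_numpy(float) - self.mu[f]) / self.sigma[f] for f in self.feature_subset]
        )
        w = np.array([self.weights[f] for f in self.feature_subset], dtype=float)
        return composite_score(z, w)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return classify(self.score(table), self.threshold)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "mu": self.mu,
                    "sigma": self.sigma,
                    "weights": self.weights,
                    "threshold": self.threshold,
                    "feature_subset": self.feature_subset,
                    "ddof": self.ddof,
                    "youden": self.youden,
                    "accuracy": self.accuracy,
                    "below_criteria": self.below_criteria,
                    "rng_seed": self.rng_seed,
                    "note": "z-scaling fitted in-sample on the full cohort (no held-out split)",
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "ScoreModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mu=d["mu"],
            sigma=d["sigma"],
            weights=d["weights"],
            threshold=d["threshold"],
            feature_subset=d["feature_subset"],
            ddof=d.get("ddof", 0),
            youden=d.get("youden"),
            accuracy=d.get("accuracy"),
            below_criteria=d.get("below_criteria", False),
            rng_seed=d.get("rng_seed"),
        )


def fit_scaling(
    table: pd.DataFrame, feature_subset: list[str] | None = None, ddof: int = 0
) -> tuple[np.ndarray, dict, dict]:
    """Z-scale each active column of a cohort table; returns (Z, mu, sigma)."""
    subset = feature_subset or FEATURES
    if table[subset].isna().any().any():
        raise ValueError("missing feature values must be resolved before fitting")
    cols, mus, sigmas = [], {}, {}
    for f in subset:
        z, mu, sd = zscale(table[f].to_numpy(float), ddof=ddof, name=f)
        cols.append(z)
        mus[f], sigmas[f] = mu, sd
    return np.column_stack(cols), mus, sigmas


def fit_model(
    table: pd.DataFrame,
    labels,
    weights: dict,
    feature_subset: list[str] | None = None,
    ddof: int = 0,
) -> tuple[ScoreModel, EvaluationReport]:
    """Fit Z-scaling and the Youden threshold for a fixed weight vector."""
    subset = feature_subset or FEATURES
    labels = np.asarray(labels, dtype=bool)
    z, mu, sigma = fit_scaling(table, subset, ddof=ddof)
    w = np.array([weights[f] for f in subset], dtype=float)
    scores = composite_score(z, w)
    thr, j = youden_threshold(scores, labels)
    report = evaluate(labels, classify(scores, thr))
    model = ScoreModel(
        mu=mu,
        sigma=sigma,
        weights={f: float(weights[f]) for f in subset},
        threshold=thr,
        feature_subset=list(subset),
        ddof=ddof,
        youden=j,
        accuracy=report.accuracy,
    )
    return model, report


def weight_search(
    table: pd.DataFrame,
    labels,
    n_iter: int = 1000,
    weight_range: tuple[int, int] = (1, 50),
    rng_seed: int = 0,
    youden_min: float = 0.70,
    min_specificity: float = 0.5,
    feature_subset: list[str] | None = None,
    ddof: int = 0,
) -> tuple[ScoreModel, pd.DataFrame]:
    """Random integer-weight search with Youden / accuracy / recall selection.

    Samples ``n_iter`` weight vectors uniformly from the integer grid
    ``[weight_range[0], weight_range[1]]`` per active feature. Candidates
    must exceed ``youden_min`` and reach ``min_specificity`` (the balance
    filter); among them the selection maximizes accuracy, then positive-class
    recall, then Youden, then earliest draw. If no candidate qualifies the
    best-Youden model is returned flagged ``below_criteria``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    subset = feature_subset or FEATURES
    labels = np.asarray(labels, dtype=bool)
    _check_two_classes(labels)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need at least 2 subjects per class")
    z, mu, sigma = fit_scaling(table, subset, ddof=ddof)
    rng = np.random.default_rng(rng_seed)
    lo, hi = weight_range
    draws = rng.integers(lo, hi + 1, size=(n_iter, len(subset)))

    log_rows = []
    best_key, best = None, None
    best_fallback_key, best_fallback = None, None
    for it in range(n_iter):
        w = draws[it].astype(float)
        scores = composite_score(z, w)
        thr, j = youden_threshold(scores, labels)
        rep = evaluate(labels, classify(scores, thr))
        log_rows.append(
            {
                "iteration": it,
                **{f"w_{f}": int(draws[it][k]) for k, f in enumerate(subset)},
                "threshold": thr,
                "youden": j,
                "accuracy": rep.accuracy,
                "recall_pos": rep.recall_pos,
                "specificity": rep.specificity,
            }
        )
        candidate = (it, w, thr, j, rep)
        if j > youden_min and rep.specificity >= min_specificity:
            key = (rep.accuracy, rep.recall_pos, j, -it)
            if best_key is None or key > best_key:
                best_key, best = key, candidate
        fb_key = (j, rep.accuracy, rep.recall_pos, -it)
        if best_fallback_key is None or fb_key > best_fallback_key:
            best_fallback_key, best_fallback = fb_key, candidate

    below = best is None
    it, w, thr, j, rep = best_fallback if below else best
    model = ScoreModel(
        mu=mu,
        sigma=sigma,
        weights={f: float(w[k]) for k, f in enumerate(subset)},
        threshold=thr,
        feature_subset=list(subset),
        ddof=ddof,
        youden=j,
        accuracy=rep.accuracy,
        below_criteria=below,
        rng_seed=rng_seed,
    )
    return model, pd.DataFrame(log_rows)


def auc_difference_table(
    table: pd.DataFrame,
    labels,
    composite_scores,
    mcid_thresholds: dict,
    feature_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Per-feature AUC vs composite AUC with user-supplied MCID bounds.

    ``observed_difference`` = composite AUC - single-feature AUC;
    ``mcid_met`` flags differences exceeding the supplied threshold.
    """
    subset = feature_subset or FEATURES
    labels = np.asarray(labels, dtype=bool)
    composite_auc = auc(composite_scores, labels)
    rows = []
    for f in subset:
        f_auc = auc(table[f].to_numpy(float), labels)
        diff = composite_auc - f_auc
        thr = mcid_thresholds.get(f)
        rows.append(
            {
                "feature": f,
                "feature_auc": f_auc,
                "composite_auc": composite_auc,
                "observed_difference": diff,
                "mcid_threshold": thr,
                "mcid_met": bool(diff > thr) if thr is not None else None,
            }
        )
    return pd.DataFrame(rows)


def pearson_correlation(values, labels) -> float:
    """Point-biserial correlation between a feature and the binary label."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(values) == 0 or np.ptp(labels) == 0:
        raise ValueError("correlation undefined for constant input")
    r, _p = stats.pearsonr(values, labels)
    return float(r)
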