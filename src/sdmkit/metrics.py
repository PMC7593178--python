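"""Model evaluation: AUC, TSS, AICc, cross-validated scoring, thresholds.

Background records are treated as the negative class in AUC/TSS — the
standard presence-background convention. AICc is defined only for the
Maxent-style method and uses all observation locations (no partition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .models import HyperCombo, TrainedModel, train
from .swd import FoldSpec, SWDTable

__all__ = [
    "EvalResult",
    "auc",
    "tss",
    "aicc",
    "evaluate",
    "fit_and_score",
    "select_threshold",
    "metric_value",
]

METRICS = ("auc", "tss", "aicc")


@dataclass
class EvalResult:
    """Train/validation values of one metric, per fold when applicable."""

    metric: str
    train_value: float
    validation_value: float | None = None
    per_fold_train: list[float] | None = None
    per_fold_validation: list[float] | None = None

    @property
    def higher_is_better(self) -> bool:
        return self.metric != "aicc"


def _check_scores(presence_scores, contrast_scores):
    p = np.asarray(presence_scores, dtype=float).ravel()
    c = np.asarray(contrast_scores, dtype=float).ravel()
    if len(p) == 0 or len(c) == 0:
        raise ValueError("presence and contrast score vectors must be nonempty")
    return p, c


def auc(presence_scores, contrast_scores) -> float:
    """Rank-based (Mann-Whitney) AUC: P(presence score > contrast score),
    ties counting one half."""
    p, c = _check_scores(presence_scores, contrast_scores)
    ranks = rankdata(np.concatenate([p, c]))
    u = ranks[: len(p)].sum() - len(p) * (len(p) + 1) / 2
    return float(u / (len(p) * len(c)))


def tss(presence_scores, contrast_scores) -> tuple[float, float]:
    """Maximum true skill statistic and its threshold.

    TSS(t) = sensitivity + specificity - 1 with 'score >= t' predicting
    presence; t ranges over the distinct observed scores. Ties break
    toward higher sensitivity, then the lower threshold.
    """
    p, c = _check_scores(presence_scores, contrast_scores)
    best = (-np.inf, -np.inf, np.inf)  # (tss, sens, -(-t)) comparator below
    best_t, best_tss = np.inf, -np.inf
    best_sens = -np.inf
    for t in np.unique(np.concatenate([p, c])):
        sens = float((p >= t).mean())
        spec = float((c < t).mean())
        value = sens + spec - 1.0
        if (value, sens, -t) > (best_tss, best_sens, -best_t):
            best_tss, best_sens, best_t = value, sens, float(t)
    return best_tss, best_t


def aicc(model: TrainedModel, full_table: SWDTable | None = None,
         extent_raw: np.ndarray | None = None) -> float:
    """Small-sample-corrected AIC for a Maxent-style model.

    k counts the non-zero fitted coefficients; the log-likelihood sums
    ln(raw) over presence records with raw renormalised to sum 1 over
    the evaluation extent — every cell of a prediction raster when
    ``extent_raw`` is given, otherwise the table's background records.
    Returns NaN (flagged, not raised) when n - k - 1 <= 0.
    """
    if model.method != "Maxent":
        raise ValueError("AICc is defined only for the Maxent-style method")
    table = full_table if full_table is not None else model.table
    k = int(np.sum(model.coefs != 0))
    pres = table.subset(table.presence_idx)
    n = pres.n_records
    if n - k - 1 <= 0:
        return float("nan")
    raw_pres = model.predict(pres, output="raw")
    if extent_raw is not None:
        denom = float(np.nansum(extent_raw))
    else:
        bg = table.subset(table.contrast_idx)
        denom = float(model.predict(bg, output="raw").sum())
    lnl = float(np.log(raw_pres / denom).sum())
    return 2 * k - 2 * lnl + (2 * k * (k + 1)) / (n - k - 1)


def metric_value(metric: str, model: TrainedModel, table: SWDTable) -> float:
    """Evaluate one metric for a fitted model on one table."""
    metric = metric.lower()
    if metric == "aicc":
        return aicc(model, table)
    scores = model.predict(table)
    p = scores[table.labels == 1]
    c = scores[table.labels == 0]
    if metric == "auc":
        return auc(p, c)
    if metric == "tss":
        return tss(p, c)[0]
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def fit_and_score(
    table: SWDTable,
    combo: HyperCombo,
    metric: str,
    fold: FoldSpec | None = None,
    validation: SWDTable | None = None,
):
    """Train under a validation design and score train + validation.

    Returns ``(EvalResult, models)`` where ``models`` holds one fitted
    model per fold (or a single model). With k folds the reported
    values are arithmetic means across folds.
    """
    metric = metric.lower()
    if metric == "aicc":
        if fold is not None:
            raise ValueError("AICc uses all observations; no fold design applies")
        model = train(table, combo)
        return EvalResult("aicc", aicc(model, table)), [model]
    if fold is not None:
        tr_vals, va_vals, models = [], [], []
        for train_part, val_part in fold.iter_splits(table):
            model = train(train_part, combo)
            tr_vals.append(metric_value(metric, model, train_part))
            va_vals.append(metric_value(metric, model, val_part))
            models.append(model)
        return (
            EvalResult(
                metric,
                float(np.mean(tr_vals)),
                float(np.mean(va_vals)),
                per_fold_train=tr_vals,
                per_fold_validation=va_vals,
            ),
            models,
        )
    model = train(table, combo)
    result = EvalResult(metric, metric_value(metric, model, table))
    if validation is not None:
        result.validation_value = metric_value(metric, model, validation)
    return result, [model]


def evaluate(
    model_or_combo,
    table: SWDTable,
    metric: str,
    fold: FoldSpec | None = None,
    validation: SWDTable | None = None,
) -> EvalResult:
    """Evaluate a fitted model (or train-and-evaluate a HyperCombo)."""
    if isinstance(model_or_combo, HyperCombo):
        return fit_and_score(table, model_or_combo, metric, fold, validation)[0]
    model = model_or_combo
    metric = metric.lower()
    if metric == "aicc":
        if fold is not None:
            raise ValueError("AICc uses all observations; no fold design applies")
        return EvalResult("aicc", aicc(model, table))
    result = EvalResult(metric, metric_value(metric, model, table))
    if validation is not None:
        result.validation_value = metric_value(metric, model, validation)
    return result


def select_threshold(presence_scores, contrast_scores, rule: str = "max_tss") -> float:
    """Threshold for binary maps.

    ``max_tss``: the TSS-maximising threshold; ``equal_sens_spec``: the
    observed score minimising |sensitivity - specificity| (smallest
    qualifying score on ties); ``min_training_presence``: the minimum
    presence score.
    """
    p, c = _check_scores(presence_scores, contrast_scores)
    if rule == "max_tss":
        return tss(p, c)[1]
    if rule == "min_training_presence":
        return float(p.min())
    if rule == "equal_sens_spec":
        best_t, best_gap = np.inf, np.inf
        for t in np.unique(np.concatenate([p, c])):
            gap = abs(float((p >= t).mean()) - float((c < t).mean()))
            if gap < best_gap or (gap == best_gap and t < best_t):
                best_gap, best_t = gap, float(t)
        return best_t
    raise ValueError(f"unknown threshold rule {rule!r}")
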