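"""Data-driven variable selection.

Two complementary algorithms, each removing exactly one variable per
step:

* :func:`var_sel` removes collinearity — among each group of highly
  correlated variables it discards the member whose removal hurts the
  *training* metric least, until all pairwise rank correlations fall
  below the threshold.
* :func:`reduce_var` increases parsimony — it strips variables of low
  permutation importance, optionally (jackknife mode) only when the
  *validation* metric does not drop.

The training/validation asymmetry is deliberate: collinearity removal
should preserve the information captured from the data, while
parsimony pruning guards generalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr, pearsonr

from .importance import jackknife_drop, permutation_importance
from .metrics import fit_and_score, metric_value
from .models import TrainedModel, train
from .swd import FoldSpec, SWDTable

__all__ = ["SelectionTrace", "spearman_matrix", "var_sel", "reduce_var"]

log = logging.getLogger("sdmkit.selection")

DEFAULT_COR_THRESHOLD = 0.7
DEFAULT_COR_SAMPLE = 30_000


@dataclass
class SelectionStep:
    removed: str
    reason: str  # collinear | low_importance
    metric_before: float
    metric_after: float


@dataclass
class SelectionTrace:
    """Ordered record of removals; replaces the interactive chart."""

    initial: list[str]
    steps: list[SelectionStep] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    @property
    def removed(self) -> list[str]:
        return [s.removed for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": i + 1,
                    "removed": s.removed,
                    "reason": s.reason,
                    "metric_before": s.metric_before,
                    "metric_after": s.metric_after,
                }
                for i, s in enumerate(self.steps)
            ]
        )


def spearman_matrix(
    table: SWDTable,
    sample: int | None = DEFAULT_COR_SAMPLE,
    seed: int = 0,
    method: str = "spearman",
) -> pd.DataFrame:
    """Pairwise rank correlations of the covariates over contrast records.

    ``sample`` caps how many contrast records are used (seeded, without
    replacement); larger requests fall back to using all of them.
    """
    if len(table.variable_names) < 2:
        raise ValueError("need at least two variables for a correlation matrix")
    idx = table.contrast_idx
    if len(idx) == 0:
        idx = np.arange(table.n_records)
    if sample is not None and sample < len(idx):
        rng = np.random.default_rng(seed)
        idx = rng.choice(idx, size=sample, replace=False)
    data = table.data.iloc[idx]
    corr = data.corr(method="spearman" if method == "spearman" else "pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def _max_offdiag(corr: pd.DataFrame) -> float:
    a = np.abs(corr.to_numpy(copy=True))
    np.fill_diagonal(a, 0.0)
    return float(a.max()) if a.size else 0.0


def var_sel(
    table: SWDTable,
    combo,
    metric: str = "auc",
    fold: FoldSpec | None = None,
    cor_threshold: float = DEFAULT_COR_THRESHOLD,
    sample: int | None = DEFAULT_COR_SAMPLE,
    seed: int = 0,
    n_permutations: int = 10,
    cor_method: str = "spearman",
    protect_focal: bool = False,
) -> tuple[TrainedModel, SelectionTrace]:
    """Remove highly correlated variables, one per step.

    Each round ranks the current model's variables by permutation
    importance, finds the most important one still correlated (|rho| >=
    ``cor_threshold``) with any other, jackknifes the correlated group
    on the *training* data, and removes the group member whose absence
    costs the least training performance (with ``protect_focal=True``
    the focal variable itself is never the removal candidate). Stops
    when all pairwise correlations are below the threshold.
    """
    if not 0 < cor_threshold <= 1:
        raise ValueError("cor_threshold must be in (0, 1]")
    current = table
    trace = SelectionTrace(initial=list(table.variable_names))
    model = train(current, combo)
    while len(current.variable_names) > 1:
        corr = spearman_matrix(current, sample=sample, seed=seed, method=cor_method)
        if _max_offdiag(corr) < cor_threshold:
            break
        imp = permutation_importance(
            model, current, metric=metric, n_permutations=n_permutations, seed=seed
        )
        rank = imp.ranked()
        imp_of = imp.as_dict()
        focal = None
        for name, _ in rank:
            others = [v for v in current.variable_names if v != name]
            if any(abs(corr.loc[name, o]) >= cor_threshold for o in others):
                focal = name
                break
        if focal is None:  # matrix says correlated but none reaches threshold
            break
        group = [focal] + [
            v
            for v in current.variable_names
            if v != focal and abs(corr.loc[focal, v]) >= cor_threshold
        ]
        candidates = group[1:] if protect_focal else group
        before = metric_value(metric, model, current)
        scores = jackknife_drop(model, current, metric, candidates, score_on="train")
        # remove the member whose absence decreases training performance
        # least; ties -> lower permutation importance, then name order
        sense = 1.0 if metric.lower() != "aicc" else -1.0
        best = sorted(scores, key=lambda s: (-sense * s[1], imp_of[s[0]], s[0]))[0]
        removed, after = best[0], best[1]
        log.info("var_sel: removing %s (train %s %.4f -> %.4f)", removed, metric, before, after)
        current = current.drop_variables([removed])
        model = train(current, combo)
        trace.steps.append(SelectionStep(removed, "collinear", before, after))
    trace.retained = list(current.variable_names)
    return model, trace


def reduce_var(
    model: TrainedModel,
    table: SWDTable,
    metric: str = "auc",
    fold: FoldSpec | None = None,
    validation: SWDTable | None = None,
    threshold: float = 2.0,
    use_jackknife: bool = True,
    seed: int = 0,
    n_permutations: int = 10,
) -> tuple[TrainedModel, SelectionTrace]:
    """Prune low-importance variables, one per step.

    Without the jackknife, the lowest-importance variable is removed
    while its importance sits below ``threshold`` (percent), re-ranking
    after each removal. With ``use_jackknife=True`` a sub-threshold
    variable is removed only if the retrained model's *validation*
    metric does not fall below the current model's; the scan continues
    until every sub-threshold variable is removed or proven necessary.
    """
    if not 0 <= threshold <= 100:
        raise ValueError("threshold is a percentage in [0, 100]")
    if use_jackknife and fold is None and validation is None:
        raise ValueError("jackknife mode needs a validation design (folds or table)")
    combo = model.combo
    current = table
    trace = SelectionTrace(initial=list(table.variable_names))

    def val_metric(tbl: SWDTable) -> float:
        result, _ = fit_and_score(
            tbl, combo, metric,
            fold=fold if fold is None or len(fold.assignments) == tbl.n_records else None,
            validation=validation.select_variables(tbl.variable_names) if validation is not None else None,
        )
        return float(result.validation_value if result.validation_value is not None else result.train_value)

    exhausted: set[str] = set()  # proven necessary under the jackknife
    if use_jackknife:
        current_val = val_metric(current)
    while len(current.variable_names) > 1:
        imp = permutation_importance(
            model, current, metric=metric, n_permutations=n_permutations, seed=seed
        )
        below = [
            (name, value)
            for name, value in sorted(imp.entries, key=lambda e: (e[1], e[0]))
            if value < threshold and name not in exhausted
        ]
        if not below:
            break
        name, value = below[0]
        if not use_jackknife:
            before = metric_value(metric, model, current)
            current = current.drop_variables([name])
            model = train(current, combo)
            after = metric_value(metric, model, current)
            trace.steps.append(SelectionStep(name, "low_importance", before, after))
            log.info("reduce_var: removed %s (importance %.2f%%)", name, value)
            continue
        candidate_tbl = current.drop_variables([name])
        candidate_val = val_metric(candidate_tbl)
        if candidate_val >= current_val:
            trace.steps.append(
                SelectionStep(name, "low_importance", current_val, candidate_val)
            )
            log.info(
                "reduce_var: removed %s (validation %s %.4f -> %.4f)",
                name, metric, current_val, candidate_val,
            )
            current = candidate_tbl
            current_val = candidate_val
            model = train(current, combo)
        else:
            exhausted.add(name)
    trace.retained = list(current.variable_names)
    return model, trace
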