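"""Permutation importance and the leave-one-out variable jackknife."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import metric_value
from .models import TrainedModel, train
from .swd import FoldSpec, SWDTable

__all__ = ["ImportanceTable", "permutation_importance", "jackknife_drop"]

DEFAULT_N_PERMUTATIONS = 10


@dataclass
class ImportanceTable:
    """Per-variable permutation importance, normalised to sum 100."""

    entries: list[tuple[str, float]]
    n_permutations: int
    seed: int

    def as_dict(self) -> dict[str, float]:
        return dict(self.entries)

    def ranked(self) -> list[tuple[str, float]]:
        """Most important first; name order breaks ties for stability."""
        return sorted(self.entries, key=lambda e: (-e[1], e[0]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["variable", "importance"])


def permutation_importance(
    model: TrainedModel,
    table: SWDTable,
    metric: str = "auc",
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> ImportanceTable:
    """Importance = mean drop of the training metric when one covariate
    is shuffled (presences and contrasts jointly), clamped at zero and
    normalised so the importances sum to 100.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    base = metric_value(metric, model, table)
    sign = -1.0 if metric.lower() == "aicc" else 1.0
    raws = []
    for v in model.variable_names:
        drops = []
        for _ in range(n_permutations):
            shuffled = table.data.copy()
            shuffled[v] = rng.permutation(shuffled[v].to_numpy())
            perturbed = SWDTable(
                species=table.species,
                coords=table.coords,
                labels=table.labels,
                data=shuffled,
                contrast_kind=table.contrast_kind,
            )
            drops.append(sign * (base - metric_value(metric, model, perturbed)))
        raws.append(max(float(np.mean(drops)), 0.0))
    total = sum(raws)
    if total > 0:
        scaled = [100.0 * r / total for r in raws]
    else:
        scaled = [100.0 / len(raws)] * len(raws)  # uninformative model: flat
    return ImportanceTable(
        entries=list(zip(model.variable_names, scaled)),
        n_permutations=n_permutations,
        seed=seed,
    )


def jackknife_drop(
    model: TrainedModel,
    table: SWDTable,
    metric: str,
    candidates: list[str],
    score_on: str = "train",
    fold: FoldSpec | None = None,
    validation: SWDTable | None = None,
) -> list[tuple[str, float]]:
    """Leave-one-variable-out retraining.

    For each candidate, retrain with the same hyperparameters minus
    that variable and report the chosen metric, scored on the training
    data (``score_on="train"``) or on the validation design
    (``score_on="validation"`` with either a hold-out table or folds).
    """
    unknown = [c for c in candidates if c not in model.variable_names]
    if unknown:
        raise KeyError(f"candidates not in model: {unknown}")
    if score_on not in ("train", "validation"):
        raise ValueError("score_on must be 'train' or 'validation'")
    out = []
    for v in candidates:
        reduced = table.drop_variables([v])
        if score_on == "validation" and fold is not None:
            from .metrics import fit_and_score

            result, _ = fit_and_score(reduced, model.combo, metric, fold=fold)
            out.append((v, float(result.validation_value)))
            continue
        sub = train(reduced, model.combo)
        if score_on == "validation":
            if validation is None:
                raise ValueError("score_on='validation' needs folds or a validation table")
            out.append((v, metric_value(metric, sub, validation.drop_variables([v]))))
        else:
            out.append((v, metric_value(metric, sub, reduced)))
    return out
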