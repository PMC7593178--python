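"""The four model families behind a uniform train/predict contract.

Each method is exposed statsmodels-style: a model class constructed
from an SWD table plus hyperparameters, whose ``fit()`` returns a
:class:`TrainedModel` results object carrying the fitted state,
prediction methods and a ``summary()``.

Methods and their tunable hyperparameters (defaults in parentheses):

======  =========================================================
ANN     size of hidden layer (n variables), weight decay (0),
        initial random weight range (0.7), iterations (100)
BRT     number of trees (100), interaction depth (1),
        shrinkage (0.1), bag fraction (0.5)
Maxent  feature classes over l/q/p/h ("lqph"),
        regularization multiplier (1), iterations (500)
RF      variables sampled per split (floor(sqrt(p))),
        number of trees (500), minimum node size (1)
======  =========================================================

The Maxent-style method is implemented natively (no Java runtime): a
presence-vs-background binomial likelihood on the expanded feature set
with an L1 penalty per feature scaled by the regularization
multiplier. The other three delegate to scikit-learn estimators (the
ANN is a direct single-hidden-layer implementation so that the initial
weight range is an honest, settable hyperparameter).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .features import DEFAULT_HINGE_KNOTS, FeatureMap, build_feature_map
from .swd import SWDTable

__all__ = [
    "METHODS",
    "HYPER_SCHEMAS",
    "HyperCombo",
    "TrainedModel",
    "Maxent",
    "ANN",
    "BRT",
    "RF",
    "train",
    "BACKGROUND_CAP",
]

METHODS = ("ANN", "BRT", "Maxent", "RF")

#: presence-background tables larger than this are downsampled (seeded)
BACKGROUND_CAP = 10_000

HYPER_SCHEMAS: dict[str, dict[str, object]] = {
    "ANN": {"size": None, "decay": 0.0, "rang": 0.7, "maxit": 100},
    "BRT": {"n_trees": 100, "interaction_depth": 1, "shrinkage": 0.1, "bag_fraction": 0.5},
    "Maxent": {"fc": "lqph", "reg": 1.0, "maxit": 500},
    "RF": {"n_trees": 500, "mtry": None, "min_node_size": 1},
}


@dataclass(frozen=True)
class HyperCombo:
    """One concrete hyperparameter assignment for one method.

    Unset hyperparameters take the method defaults; ``ANN.size = None``
    resolves to the number of variables at fit time and ``RF.mtry =
    None`` to floor(sqrt(p)).
    """

    method: str
    values: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in HYPER_SCHEMAS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        schema = HYPER_SCHEMAS[self.method]
        unknown = set(self.values) - set(schema)
        if unknown:
            raise ValueError(
                f"hyperparameters {sorted(unknown)} not in the {self.method} schema "
                f"({sorted(schema)})"
            )
        merged = {**schema, **self.values}
        if self.method == "Maxent":
            if float(merged["reg"]) <= 0:
                raise ValueError("regularization multiplier must be > 0")
        object.__setattr__(self, "values", merged)

    def __getitem__(self, name: str):
        return self.values[name]

    def with_seed(self, seed: int) -> "HyperCombo":
        return HyperCombo(self.method, dict(self.values), seed)

    def key(self) -> tuple:
        """Hashable identity used for tuning caches (seed excluded)."""
        return (self.method, tuple(sorted(self.values.items())))

    def to_dict(self) -> dict:
        return {"method": self.method, "values": dict(self.values), "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "HyperCombo":
        return cls(d["method"], dict(d.get("values", {})), int(d.get("seed", 0)))


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------

class TrainedModel:
    """Fitted model: hyperparameters + backend state + training table.

    Prediction outputs
    ------------------
    ``raw``      Maxent relative occurrence rate, normalised to sum 1
                 over the training background.
    ``cloglog``  1 - exp(-exp(H) * raw) with H the entropy of the raw
                 distribution over the training background (Maxent only).
    ``logistic`` exp(H)*raw / (1 + exp(H)*raw) (Maxent only).
    ``default``  cloglog for Maxent, positive-class probability for the
                 other methods.
    """

    def __init__(self, combo: HyperCombo, table: SWDTable, backend, *,
                 feature_map: FeatureMap | None = None,
                 coefs: np.ndarray | None = None,
                 intercept: float = 0.0,
                 normalizer: float = 1.0,
                 entropy: float = 0.0,
                 warnings_: list[str] | None = None):
        self.combo = combo
        self.table = table
        self.backend = backend
        self.feature_map = feature_map
        self.coefs = coefs
        self.intercept = intercept
        self.normalizer = normalizer
        self.entropy = entropy
        self.warnings = list(warnings_ or [])

    @property
    def method(self) -> str:
        return self.combo.method

    @property
    def variable_names(self) -> list[str]:
        return self.table.variable_names

    @property
    def converged(self) -> bool:
        return not self.warnings

    # -- prediction ---------------------------------------------------------
    def _check_variables(self, data: pd.DataFrame) -> pd.DataFrame:
        for v in self.variable_names:
            if v not in data.columns:
                raise KeyError(f"prediction data lacks variable {v!r}")
        return data[self.variable_names]

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        if self.method != "Maxent":
            raise ValueError("linear predictor is defined for Maxent models only")
        X = self.feature_map.transform(self._check_variables(data))
        # per-row pairwise sum: bit-identical no matter how points are
        # batched (raster projection vs point prediction)
        return (X * self.coefs).sum(axis=1) + self.intercept

    def predict(self, data, output: str = "default") -> np.ndarray:
        """Score points; ``data`` is an SWDTable or a covariate DataFrame."""
        if isinstance(data, SWDTable):
            data = data.data
        data = self._check_variables(data)
        if self.method == "Maxent":
            raw = np.exp(self.linear_predictor(data)) / self.normalizer
            if output == "raw":
                return raw
            scaled = np.exp(self.entropy) * raw
            if output in ("default", "cloglog"):
                return 1.0 - np.exp(-scaled)
            if output == "logistic":
                return scaled / (1.0 + scaled)
            raise ValueError(f"unknown output {output!r}")
        if output not in ("default",):
            raise ValueError(f"output {output!r} is Maxent-specific; use 'default'")
        return self._predict_prob(data)

    def _predict_prob(self, data: pd.DataFrame) -> np.ndarray:
        X = data.to_numpy(float)
        if self.method == "ANN":
            return self.backend.forward(X)
        proba = self.backend.predict_proba(X)
        pos = list(self.backend.classes_).index(1)
        return proba[:, pos]

    # -- presentation --------------------------------------------------------
    def summary(self) -> str:
        lines = [
            f"{self.method} species distribution model",
            f"  species:    {self.table.species}",
            f"  records:    {self.table.n_presence} presence / "
            f"{self.table.n_contrast} {self.table.contrast_kind}",
            f"  variables:  {', '.join(self.variable_names)}",
            "  hyperparameters:",
        ]
        for k, v in self.combo.values.items():
            lines.append(f"    {k} = {v}")
        if self.method == "Maxent":
            nz = int(np.sum(self.coefs != 0))
            lines.append(f"  non-zero features: {nz} of {len(self.coefs)}")
            lines.append(f"  entropy of raw distribution: {self.entropy:.4f}")
        if self.warnings:
            lines.append("  warnings: " + "; ".join(self.warnings))
        return "\n".join(lines)

    # -- persistence (Maxent archive is pure JSON) ---------------------------
    def save(self, path) -> None:
        if self.method != "Maxent":
            import joblib

            joblib.dump(self, path)
            return
        fm = self.feature_map
        payload = {
            "combo": self.combo.to_dict(),
            "species": self.table.species,
            "contrast_kind": self.table.contrast_kind,
            "variables": self.variable_names,
            "var_ranges": {k: list(v) for k, v in fm.var_ranges.items()},
            "features": [
                {
                    "kind": f.kind,
                    "variables": list(f.variables),
                    "knot": f.knot,
                    "lo": f.lo,
                    "hi": f.hi,
                }
                for f in fm.features
            ],
            "classes": fm.classes,
            "coefs": self.coefs.tolist(),
            "intercept": self.intercept,
            "normalizer": self.normalizer,
            "entropy": self.entropy,
            "warnings": self.warnings,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path) -> "TrainedModel":
        text = Path(path).read_text() if str(path).endswith(".json") else None
        if text is None:
            import joblib

            return joblib.load(path)
        from .features import Feature

        payload = json.loads(text)
        fm = FeatureMap(
            classes=payload["classes"],
            features=[
                Feature(
                    kind=f["kind"],
                    variables=tuple(f["variables"]),
                    knot=f["knot"],
                    lo=f["lo"],
                    hi=f["hi"],
                )
                for f in payload["features"]
            ],
            var_ranges={k: tuple(v) for k, v in payload["var_ranges"].items()},
        )
        # minimal stand-in training table: variables + one record per class
        data = pd.DataFrame(
            {v: [lo, hi] for v, (lo, hi) in fm.var_ranges.items()}
        )
        table = SWDTable(
            species=payload["species"],
            coords=np.zeros((2, 2)),
            labels=np.array([1, 0]),
            data=data,
            contrast_kind=payload["contrast_kind"],
        )
        return cls(
            HyperCombo.from_dict(payload["combo"]),
            table,
            backend=None,
            feature_map=fm,
            coefs=np.asarray(payload["coefs"], float),
            intercept=float(payload["intercept"]),
            normalizer=float(payload["normalizer"]),
            entropy=float(payload["entropy"]),
            warnings_=payload.get("warnings", []),
        )


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------

class SDMModel:
    """Base model: an SWD table plus a hyperparameter assignment."""

    method: str = ""

    def __init__(self, table: SWDTable, seed: int = 0, **hyperparams):
        table.validate_for_training()
        self.table = table
        self.combo = HyperCombo(self.method, hyperparams, seed)

    @classmethod
    def from_combo(cls, table: SWDTable, combo: HyperCombo) -> "SDMModel":
        obj = cls.__new__(cls)
        table.validate_for_training()
        obj.table = table
        obj.combo = combo
        return obj

    def fit(self) -> TrainedModel:
        raise NotImplementedError


class Maxent(SDMModel):
    """Native Maxent-style presence/background model.

    Fits coefficients by a penalized presence-vs-background binomial
    likelihood on the expanded l/q/p/h features, with per-feature L1
    penalty lambda_j = reg * sd_j(presences) / sqrt(n_presences)
    (hinge features share a flat per-variable budget of
    reg * 0.5 / sqrt(n_presences) per knot). Raw output is
    exp(eta) normalised to sum 1 over the training background.
    """

    method = "Maxent"

    def fit(self) -> TrainedModel:
        table = self.table
        if table.contrast_kind != "background":
            raise ValueError(
                "the Maxent-style method requires background contrast records; "
                f"got contrast_kind={table.contrast_kind!r}"
            )
        combo = self.combo
        if table.n_contrast > BACKGROUND_CAP:
            rng = np.random.default_rng(combo.seed)
            keep_bg = rng.choice(table.contrast_idx, size=BACKGROUND_CAP, replace=False)
            table = table.subset(np.concatenate([table.presence_idx, np.sort(keep_bg)]))

        fmap = build_feature_map(table.data, str(combo["fc"]), DEFAULT_HINGE_KNOTS)
        X = fmap.transform(table.data)
        y = table.labels
        n_pres = table.n_presence
        reg = float(combo["reg"])

        sd_pres = X[y == 1].std(axis=0)
        lam = reg * np.maximum(sd_pres, 1e-3) / np.sqrt(n_pres)
        hinge = np.array([f.kind.startswith("hinge") for f in fmap.features])
        lam[hinge] = reg * 0.5 / np.sqrt(n_pres)

        # realise the per-feature L1 penalty sum(lam_j * |beta_j|) with a
        # single-C solver: the mean level goes into C, the O(1) relative
        # weights into the feature scaling (keeps the problem well
        # conditioned for any multiplier)
        lam_mean = float(lam.mean())
        rel = lam / lam_mean
        recorded: list[str] = []
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            clf = LogisticRegression(
                l1_ratio=1.0,
                C=1.0 / lam_mean,
                solver="liblinear",
                max_iter=int(combo["maxit"]),
                tol=1e-4,
                intercept_scaling=10.0,
                random_state=combo.seed,
            )
            clf.fit(X / rel, y)
        for w in caught:
            if issubclass(w.category, ConvergenceWarning):
                recorded.append(
                    f"did not converge within {combo['maxit']} iterations"
                )
                break

        coefs = clf.coef_.ravel() / rel
        intercept = float(clf.intercept_[0])
        eta_bg = (X[y == 0] * coefs).sum(axis=1) + intercept
        # normalise in a numerically safe way, then rescale Z
        shift = eta_bg.max()
        z_shifted = np.exp(eta_bg - shift).sum()
        normalizer = float(z_shifted * np.exp(shift))
        raw_bg = np.exp(eta_bg - shift) / z_shifted
        nonzero = raw_bg > 0
        entropy = float(-(raw_bg[nonzero] * np.log(raw_bg[nonzero])).sum())
        return TrainedModel(
            combo,
            table,
            backend=None,
            feature_map=fmap,
            coefs=coefs,
            intercept=intercept,
            normalizer=normalizer,
            entropy=entropy,
            warnings_=recorded,
        )


class _SingleLayerNet:
    """nnet-style single-hidden-layer network (sigmoid units).

    Weights start uniform on (-rang, rang); training minimises the
    binomial cross-entropy plus decay * sum of squared weights with
    L-BFGS-B, capped at ``maxit`` iterations.
    """

    def __init__(self, n_in: int, size: int, decay: float, rang: float, seed: int):
        self.n_in, self.size, self.decay = n_in, size, float(decay)
        rng = np.random.default_rng(seed)
        self.theta = rng.uniform(-rang, rang, size=self._n_params())
        self.success = True

    def _n_params(self) -> int:
        return self.n_in * self.size + self.size + self.size + 1

    def _unpack(self, theta):
        p, h = self.n_in, self.size
        i = 0
        W1 = theta[i : i + p * h].reshape(p, h); i += p * h
        b1 = theta[i : i + h]; i += h
        W2 = theta[i : i + h]; i += h
        b2 = theta[i]
        return W1, b1, W2, b2

    def _loss_grad(self, theta, X, y):
        W1, b1, W2, b2 = self._unpack(theta)
        Z = expit(X @ W1 + b1)
        p = expit(Z @ W2 + b2)
        eps = 1e-12
        loss = -(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)).sum()
        loss += self.decay * (theta @ theta)
        d_out = p - y
        gW2 = Z.T @ d_out + 2 * self.decay * W2
        gb2 = d_out.sum() + 2 * self.decay * b2
        dZ = np.outer(d_out, W2) * Z * (1 - Z)
        gW1 = X.T @ dZ + 2 * self.decay * W1
        gb1 = dZ.sum(axis=0) + 2 * self.decay * b1
        grad = np.concatenate([gW1.ravel(), gb1, gW2, [gb2]])
        return loss, grad

    def fit(self, X, y, maxit: int):
        res = minimize(
            self._loss_grad,
            self.theta,
            args=(X, y),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": int(maxit)},
        )
        self.theta = res.x
        self.success = bool(res.success)
        return self

    def forward(self, X) -> np.ndarray:
        W1, b1, W2, b2 = self._unpack(self.theta)
        # batch-size-independent accumulation keeps point and raster
        # predictions bit-identical
        Z = expit((X[:, :, None] * W1[None, :, :]).sum(axis=1) + b1)
        return expit((Z * W2).sum(axis=1) + b2)


class ANN(SDMModel):
    """Single-hidden-layer artificial neural network (presence/absence)."""

    method = "ANN"

    def fit(self) -> TrainedModel:
        table, combo = self.table, self.combo
        size = combo["size"]
        size = int(size) if size is not None else len(table.variable_names)
        net = _SingleLayerNet(
            len(table.variable_names), size, combo["decay"], combo["rang"], combo.seed
        )
        net.fit(table.data.to_numpy(float), table.labels.astype(float), combo["maxit"])
        recorded = [] if net.success else [
            f"did not converge within {combo['maxit']} iterations"
        ]
        return TrainedModel(combo, table, backend=net, warnings_=recorded)


class BRT(SDMModel):
    """Boosted regression trees (gradient boosting)."""

    method = "BRT"

    def fit(self) -> TrainedModel:
        table, combo = self.table, self.combo
        clf = GradientBoostingClassifier(
            n_estimators=int(combo["n_trees"]),
            max_depth=int(combo["interaction_depth"]),
            learning_rate=float(combo["shrinkage"]),
            subsample=float(combo["bag_fraction"]),
            random_state=combo.seed,
        )
        clf.fit(table.data.to_numpy(float), table.labels)
        return TrainedModel(combo, table, backend=clf)


class RF(SDMModel):
    """Random forest classifier."""

    method = "RF"

    def fit(self) -> TrainedModel:
        table, combo = self.table, self.combo
        p = len(table.variable_names)
        mtry = combo["mtry"]
        mtry = int(mtry) if mtry is not None else int(np.floor(np.sqrt(p)))
        clf = RandomForestClassifier(
            n_estimators=int(combo["n_trees"]),
            max_features=min(mtry, p),
            min_samples_leaf=int(combo["min_node_size"]),
            random_state=combo.seed,
        )
        clf.fit(table.data.to_numpy(float), table.labels)
        return TrainedModel(combo, table, backend=clf)


_MODEL_CLASSES = {"Maxent": Maxent, "ANN": ANN, "BRT": BRT, "RF": RF}


def train(table: SWDTable, combo: HyperCombo) -> TrainedModel:
    """Train any method from a HyperCombo (the tuners' entry point)."""
    cls = _MODEL_CLASSES[combo.method]
    return cls.from_combo(table, combo).fit()


def resolved_mtry(combo: HyperCombo, n_variables: int) -> int:
    """RF default: floor(sqrt(#variables)) when mtry is unset."""
    mtry = combo["mtry"]
    return int(mtry) if mtry is not None else int(np.floor(np.sqrt(n_variables)))
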