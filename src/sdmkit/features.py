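"""Maxent-style feature expansion: linear, quadratic, product, hinge.

All derived columns are min-max scaled to [0, 1] using the training
ranges; at prediction time covariates are clamped to those ranges
before the features are evaluated, the standard treatment of novel
environments in presence-background modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureMap", "build_feature_map", "DEFAULT_HINGE_KNOTS"]

VALID_CLASSES = set("lqph")
DEFAULT_HINGE_KNOTS = 20


@dataclass
class Feature:
    kind: str          # linear | quadratic | product | hinge_fwd | hinge_rev
    variables: tuple   # 1 or 2 source variable names
    knot: float | None
    lo: float          # training min of the raw derived value
    hi: float          # training max of the raw derived value

    def raw(self, cols: dict[str, np.ndarray]) -> np.ndarray:
        if self.kind == "linear":
            return cols[self.variables[0]]
        if self.kind == "quadratic":
            return cols[self.variables[0]] ** 2
        if self.kind == "product":
            return cols[self.variables[0]] * cols[self.variables[1]]
        x = cols[self.variables[0]]
        if self.kind == "hinge_fwd":
            span = self.hi - self.knot
            return np.clip((x - self.knot) / span, 0.0, 1.0) if span > 0 else np.zeros_like(x)
        if self.kind == "hinge_rev":
            span = self.knot - self.lo
            return np.clip((self.knot - x) / span, 0.0, 1.0) if span > 0 else np.zeros_like(x)
        raise ValueError(self.kind)


@dataclass
class FeatureMap:
    """Frozen expansion recipe fitted on a training table."""

    classes: str
    features: list[Feature]
    var_ranges: dict[str, tuple[float, float]]

    @property
    def names(self) -> list[str]:
        out = []
        for f in self.features:
            if f.kind == "product":
                out.append(f"{f.variables[0]}*{f.variables[1]}")
            elif f.kind in ("hinge_fwd", "hinge_rev"):
                out.append(f"{f.kind}({f.variables[0]},{f.knot:.6g})")
            elif f.kind == "quadratic":
                out.append(f"{f.variables[0]}^2")
            else:
                out.append(f.variables[0])
        return out

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        """Design matrix in [0, 1]; inputs clamped to training ranges."""
        missing = [v for v in self.var_ranges if v not in data.columns]
        if missing:
            raise KeyError(f"missing variables: {missing}")
        cols = {
            v: np.clip(data[v].to_numpy(float), lo, hi)
            for v, (lo, hi) in self.var_ranges.items()
        }
        out = np.empty((len(data), len(self.features)))
        for j, f in enumerate(self.features):
            raw = f.raw(cols)
            if f.kind in ("hinge_fwd", "hinge_rev"):
                out[:, j] = raw  # hinge already lives in [0, 1]
            else:
                span = f.hi - f.lo
                out[:, j] = (raw - f.lo) / span if span > 0 else 0.0
        return out


def build_feature_map(
    data: pd.DataFrame, classes: str, hinge_knots: int = DEFAULT_HINGE_KNOTS
) -> FeatureMap:
    """Fit the expansion on training covariates (presence + contrast).

    Hinge knots sit at equally spaced empirical quantiles of the
    combined training values, ``hinge_knots`` per variable and
    direction (forward and reverse).
    """
    classes = "".join(dict.fromkeys(classes))  # dedupe, keep order
    unknown = set(classes) - VALID_CLASSES
    if unknown or not classes:
        raise ValueError(f"feature classes must be a nonempty subset of 'lqph', got {classes!r}")
    variables = list(data.columns)
    cols = {v: data[v].to_numpy(float) for v in variables}
    var_ranges = {
        v: (float(np.nanmin(cols[v])), float(np.nanmax(cols[v]))) for v in variables
    }
    features: list[Feature] = []

    def add(kind, vars_, knot=None):
        f = Feature(kind=kind, variables=tuple(vars_), knot=knot, lo=0.0, hi=1.0)
        if kind in ("hinge_fwd", "hinge_rev"):
            lo, hi = var_ranges[vars_[0]]
            f.lo, f.hi = lo, hi
        else:
            raw = f.raw(cols)
            f.lo, f.hi = float(np.nanmin(raw)), float(np.nanmax(raw))
        features.append(f)

    if "l" in classes:
        for v in variables:
            add("linear", (v,))
    if "q" in classes:
        for v in variables:
            add("quadratic", (v,))
    if "p" in classes:
        for a in range(len(variables)):
            for b in range(a + 1, len(variables)):
                add("product", (variables[a], variables[b]))
    if "h" in classes:
        qs = (np.arange(hinge_knots) + 0.5) / hinge_knots
        for v in variables:
            knots = np.quantile(cols[v][~np.isnan(cols[v])], qs)
            for t in knots:
                add("hinge_fwd", (v,), knot=float(t))
            for t in knots:
                add("hinge_rev", (v,), knot=float(t))
    return FeatureMap(classes=classes, features=features, var_ranges=var_ranges)
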