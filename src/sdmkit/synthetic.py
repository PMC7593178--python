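"""Virtual-species simulator: correlated environmental layers and samples.

Generates smooth random environmental surfaces, a known logistic
suitability truth, and presence / absence / background samples drawn
from it — the ground-truth test bed for every model, metric and
selection algorithm in the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import RasterStack
from .swd import SWDTable

__all__ = [
    "VirtualSpeciesConfig",
    "generate_layers",
    "true_suitability",
    "sample_species",
    "simulate",
]


@dataclass
class VirtualSpeciesConfig:
    """Configuration of one virtual species and its landscape.

    ``informative`` maps layer index -> additive coefficient on the
    logistic scale; ``duplicate_of`` entries (new, source, sd) overwrite
    layer *new* with layer *source* plus Gaussian noise of the given sd,
    producing the collinear pairs the selection algorithms must untangle.
    ``smoothness`` is the Gaussian autocorrelation length in cells.
    """

    grid_shape: tuple[int, int] = (60, 60)
    n_layers: int = 4
    informative: list[tuple[int, float]] = field(default_factory=lambda: [(0, 3.0), (1, -2.0)])
    intercept: float = 0.0
    duplicate_of: list[tuple[int, int, float]] = field(default_factory=list)
    smoothness: float = 5.0
    n_presence: int = 400
    n_absence: int = 400
    n_background: int = 1000
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("grid_shape must be positive")
        if self.n_layers <= 0:
            raise ValueError("n_layers must be positive")
        for j, _ in self.informative:
            if not 0 <= j < self.n_layers:
                raise ValueError(f"informative layer index {j} out of range")
        for new, src, sd in self.duplicate_of:
            if not (0 <= new < self.n_layers and 0 <= src < self.n_layers):
                raise ValueError("duplicate indices out of range")
            if sd < 0:
                raise ValueError("duplicate noise sd must be >= 0")


def _smooth_field(rng: np.random.Generator, shape, smoothness: float) -> np.ndarray:
    field_ = rng.standard_normal(shape)
    if smoothness > 0:
        field_ = ndimage.gaussian_filter(field_, sigma=smoothness, mode="wrap")
    field_ -= field_.mean()
    sd = field_.std()
    if sd > 0:
        field_ /= sd
    return field_


def generate_layers(config: VirtualSpeciesConfig) -> RasterStack:
    """Build the environmental stack: standardized smooth random fields.

    Base layers are white noise convolved with an isotropic Gaussian
    kernel (width = ``smoothness`` cells) and standardized to mean 0,
    sd 1. Duplicate layers are source + Gaussian noise, re-standardized.
    Bit-identical under a fixed config seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    grids = np.stack(
        [_smooth_field(rng, config.grid_shape, config.smoothness)
         for _ in range(config.n_layers)]
    )
    for new, src, sd in config.duplicate_of:
        noisy = grids[src] + (rng.standard_normal(config.grid_shape) * sd if sd > 0 else 0.0)
        if sd > 0:
            noisy = (noisy - noisy.mean()) / noisy.std()
        grids[new] = noisy
    names = [f"layer_{i}" for i in range(config.n_layers)]
    return RasterStack(names=names, grids=grids)


def true_suitability(stack: RasterStack, config: VirtualSpeciesConfig) -> np.ndarray:
    """Cellwise logistic suitability s = 1/(1+exp(-(b0 + sum b_j z_j)))."""
    config.validate()
    eta = np.full(stack.shape, float(config.intercept))
    for j, coef in config.informative:
        eta = eta + coef * stack.grids[j]
    return 1.0 / (1.0 + np.exp(-eta))


def _weighted_sample_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, size: int
) -> np.ndarray:
    """Indices drawn without replacement, probability proportional to weight.

    Uses the Gumbel/exponential trick: keys u_i^(1/w_i) reduce to
    log(u)/w ordering, exact for successive weighted draws.
    """
    w = np.asarray(weights, dtype=float)
    positive = w > 0
    if positive.sum() < size:
        # not enough positive-weight cells; fill the remainder uniformly
        keys = np.where(positive, np.log(rng.uniform(size=len(w))) / np.where(positive, w, 1.0), -np.inf)
        chosen = np.argsort(keys)[::-1][: positive.sum()]
        rest = np.setdiff1d(np.arange(len(w)), chosen)
        extra = rng.choice(rest, size=size - len(chosen), replace=False)
        return np.concatenate([chosen, extra])
    keys = np.full(len(w), -np.inf)
    keys[positive] = np.log(rng.uniform(size=int(positive.sum()))) / w[positive]
    return np.argsort(keys)[::-1][:size]


def sample_species(
    stack: RasterStack,
    suitability: np.ndarray,
    config: VirtualSpeciesConfig,
    species: str = "virtual_species",
) -> dict[str, SWDTable]:
    """Draw presence, absence and background samples from the truth.

    Presences: weighted without replacement with weight s; absences with
    weight (1 - s); background uniform without replacement. Returns the
    two standard study designs as SWD tables under keys
    ``"presence_background"`` and ``"presence_absence"``.
    """
    config.validate()
    rows, cols = stack.shape
    n_cells = rows * cols
    for n in (config.n_presence, config.n_absence, config.n_background):
        if n > n_cells:
            raise ValueError("requested sample count exceeds cell count")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    s = np.asarray(suitability, dtype=float).ravel()

    def draw(weights, n, uniform=False):
        if n == 0:
            return np.array([], dtype=int)
        if uniform:
            return rng.choice(n_cells, size=n, replace=False)
        return _weighted_sample_without_replacement(rng, weights, n)

    pres = draw(s, config.n_presence)
    absc = draw(1.0 - s, config.n_absence)
    bg = draw(None, config.n_background, uniform=True)

    def to_table(idx_pos, idx_neg, contrast_kind):
        cells = np.concatenate([idx_pos, idx_neg])
        r, c = np.unravel_index(cells, (rows, cols))
        return SWDTable(
            species=species,
            coords=stack.cell_coords(r, c),
            labels=np.concatenate(
                [np.ones(len(idx_pos), int), np.zeros(len(idx_neg), int)]
            ),
            data=stack.table_at(r, c),
            contrast_kind=contrast_kind,
        )

    return {
        "presence_background": to_table(pres, bg, "background"),
        "presence_absence": to_table(pres, absc, "absence"),
    }


def simulate(config: VirtualSpeciesConfig):
    """One-call convenience: (stack, suitability grid, samples dict)."""
    stack = generate_layers(config)
    suit = true_suitability(stack, config)
    return stack, suit, sample_species(stack, suit, config)
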