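"""Samples-with-data (SWD) tables and train/validation partitioning.

The SWD table is the universal currency of the toolkit: one row per
presence or contrast (background / absence) location, carrying the
species label, X/Y coordinates and the environmental covariate values
sampled at that location.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SWDTable",
    "FoldSpec",
    "SWDFormatError",
    "read_swd",
    "write_swd",
    "split_holdout",
    "random_folds",
    "import_folds",
]

#: token written for a missing covariate cell
MISSING_TOKEN = "NA"


class SWDFormatError(ValueError):
    """Raised when an SWD file violates the expected layout."""


def _round_half_down(x: float) -> int:
    """Round to nearest integer, ties going down (documented split rule)."""
    return int(np.ceil(x - 0.5))


@dataclass
class SWDTable:
    """Presence + contrast records with coordinates and covariates.

    Parameters
    ----------
    species : str
        Free-text species label.
    coords : ndarray of shape (n, 2)
        X/Y coordinates. Carried as metadata; never used in modelling.
    labels : ndarray of shape (n,)
        1 for presence, 0 for the contrast class.
    data : pandas.DataFrame of shape (n, p)
        Covariate values, one column per environmental variable.
    contrast_kind : {"background", "absence"}
        Whether the 0-labelled records are background locations
        (presence-only design) or confirmed absences.
    """

    species: str
    coords: np.ndarray
    labels: np.ndarray
    data: pd.DataFrame
    contrast_kind: str = "background"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if self.contrast_kind not in ("background", "absence"):
            raise ValueError(f"unknown contrast_kind {self.contrast_kind!r}")
        n = len(self.labels)
        if self.coords.shape[0] != n or len(self.data) != n:
            raise ValueError("coords, labels and data must have equal length")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate variable names")
        self.data = self.data.reset_index(drop=True)

    # -- basic introspection -------------------------------------------------
    @property
    def variable_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_records(self) -> int:
        return len(self.labels)

    @property
    def n_presence(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_contrast(self) -> int:
        return int((self.labels == 0).sum())

    @property
    def presence_idx(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 1)

    @property
    def contrast_idx(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 0)

    def validate_for_training(self) -> None:
        if len(self.variable_names) == 0:
            raise SWDFormatError("table has no covariates")
        if self.n_presence == 0 or self.n_contrast == 0:
            raise ValueError(
                "training requires at least one presence and one contrast record"
            )

    # -- derived tables ------------------------------------------------------
    def subset(self, idx: np.ndarray | list[int]) -> "SWDTable":
        """Row subset preserving order of ``idx``."""
        idx = np.asarray(idx, dtype=int)
        return SWDTable(
            species=self.species,
            coords=self.coords[idx],
            labels=self.labels[idx],
            data=self.data.iloc[idx].reset_index(drop=True),
            contrast_kind=self.contrast_kind,
        )

    def select_variables(self, names: list[str]) -> "SWDTable":
        missing = [v for v in names if v not in self.data.columns]
        if missing:
            raise KeyError(f"unknown variables: {missing}")
        return replace(self, data=self.data[list(names)].copy())

    def drop_variables(self, names: list[str]) -> "SWDTable":
        keep = [v for v in self.variable_names if v not in set(names)]
        return self.select_variables(keep)

    def concat(self, other: "SWDTable") -> "SWDTable":
        """Stack two tables (same variables), e.g. train + validation merge."""
        if self.variable_names != other.variable_names:
            raise ValueError("variable sets differ")
        return SWDTable(
            species=self.species,
            coords=np.vstack([self.coords, other.coords]),
            labels=np.concatenate([self.labels, other.labels]),
            data=pd.concat([self.data, other.data], ignore_index=True),
            contrast_kind=self.contrast_kind,
        )

    def equals(self, other: "SWDTable") -> bool:
        return (
            self.species == other.species
            and self.contrast_kind == other.contrast_kind
            and np.array_equal(self.labels, other.labels)
            and np.allclose(self.coords, other.coords, equal_nan=True)
            and self.variable_names == other.variable_names
            and np.allclose(
                self.data.to_numpy(float),
                other.data.to_numpy(float),
                equal_nan=True,
            )
        )


@dataclass
class FoldSpec:
    """Assignment of SWD records to train/validation partitions.

    ``kind="holdout"`` uses fold ids {0: train, 1: validation};
    ``kind="kfold"`` uses ids 0..k-1, each fold serving once as the
    validation part.
    """

    kind: str
    assignments: np.ndarray
    k: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int).ravel()
        if self.kind not in ("holdout", "kfold"):
            raise ValueError(f"unknown fold kind {self.kind!r}")

    def validate(self, table: SWDTable) -> None:
        if len(self.assignments) != table.n_records:
            raise ValueError(
                f"fold assignments ({len(self.assignments)}) do not match "
                f"record count ({table.n_records})"
            )
        for fold in range(self.k):
            if self.kind == "kfold":
                val = self.assignments == fold
            else:
                val = self.assignments == 1
            labels = table.labels[val]
            if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
                raise ValueError(
                    f"fold {fold} lacks a presence or a contrast record"
                )
            if self.kind == "holdout":
                break

    def iter_splits(self, table: SWDTable):
        """Yield (train_table, validation_table) per fold."""
        if self.kind == "holdout":
            yield (
                table.subset(np.flatnonzero(self.assignments == 0)),
                table.subset(np.flatnonzero(self.assignments == 1)),
            )
        else:
            for fold in range(self.k):
                val = self.assignments == fold
                yield (
                    table.subset(np.flatnonzero(~val)),
                    table.subset(np.flatnonzero(val)),
                )


# ---------------------------------------------------------------------------
# delimited-text I/O (SWD dialect: species,pa,X,Y,var1,... ; missing = NA)
# ---------------------------------------------------------------------------

def read_swd(
    path,
    contrast_kind: str = "background",
    presence_path=None,
) -> SWDTable:
    """Read an SWD table from delimited text.

    Two layouts are accepted: a single file with a binary ``pa`` label
    column, or a two-file layout where ``presence_path`` holds the
    presences and ``path`` the contrast records (both without ``pa``).
    Empty cells become NaN (the missing marker).
    """
    if presence_path is not None:
        pres = _read_one(presence_path)
        cont = _read_one(path)
        if list(pres.columns) != list(cont.columns):
            raise SWDFormatError("presence and contrast files have different headers")
        pres["pa"] = 1
        cont["pa"] = 0
        frame = pd.concat([pres, cont], ignore_index=True)
    else:
        frame = _read_one(path)
        if "pa" not in frame.columns:
            raise SWDFormatError(
                f"{path}: single-file layout requires a 'pa' label column"
            )
    cols = [c for c in frame.columns if c not in ("species", "pa", "X", "Y")]
    if not cols:
        raise SWDFormatError(f"{path}: no covariate columns found")
    species = str(frame["species"].iloc[0]) if len(frame) else ""
    return SWDTable(
        species=species,
        coords=frame[["X", "Y"]].to_numpy(float),
        labels=frame["pa"].to_numpy(int),
        data=frame[cols].astype(float),
        contrast_kind=contrast_kind,
    )


def _read_one(path) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise SWDFormatError(f"{path}: empty file")
    header = [h.strip() for h in lines[0].split(",")]
    for required in ("species", "X", "Y"):
        if required not in header:
            raise SWDFormatError(f"{path}: header lacks required column {required!r}")
    ncol = len(header)
    for i, ln in enumerate(lines[1:], start=2):
        if len(ln.split(",")) != ncol:
            raise SWDFormatError(f"{path}: line {i} has wrong number of columns")
    frame = pd.read_csv(
        io.StringIO(text), na_values=[MISSING_TOKEN, ""], keep_default_na=False
    )
    frame.columns = header
    return frame


def write_swd(table: SWDTable, path) -> None:
    """Write a table in the single-file SWD dialect (re-readable by read_swd)."""
    if len(table.variable_names) == 0:
        raise SWDFormatError("refusing to write a table with no covariates")
    frame = pd.DataFrame(
        {
            "species": table.species,
            "pa": table.labels,
            "X": table.coords[:, 0],
            "Y": table.coords[:, 1],
        }
    )
    for v in table.variable_names:
        frame[v] = table.data[v].to_numpy()
    frame.to_csv(path, index=False, na_rep=MISSING_TOKEN)


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

def split_holdout(
    table: SWDTable, test_fraction: float, seed: int
) -> tuple[SWDTable, SWDTable]:
    """Stratified random hold-out split into (train, test).

    Presences and contrasts are split independently; the per-class test
    size is round(n_class * fraction) with ties rounding down, so counts
    are exactly reproducible.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    table.validate_for_training()
    rng = np.random.default_rng(seed)
    test_mask = np.zeros(table.n_records, dtype=bool)
    for idx in (table.presence_idx, table.contrast_idx):
        n_test = _round_half_down(len(idx) * test_fraction)
        chosen = rng.permutation(idx)[:n_test]
        test_mask[chosen] = True
    return (
        table.subset(np.flatnonzero(~test_mask)),
        table.subset(np.flatnonzero(test_mask)),
    )


def random_folds(table: SWDTable, k: int, seed: int) -> FoldSpec:
    """Random k folds, stratified by class (near-equal sizes within class)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    table.validate_for_training()
    if table.n_presence < k or table.n_contrast < k:
        raise ValueError(f"each class needs at least k={k} records")
    rng = np.random.default_rng(seed)
    assignments = np.empty(table.n_records, dtype=int)
    for idx in (table.presence_idx, table.contrast_idx):
        shuffled = rng.permutation(idx)
        # round-robin keeps within-class fold sizes within 1 of each other
        assignments[shuffled] = np.arange(len(shuffled)) % k
    spec = FoldSpec(kind="kfold", assignments=assignments, k=k, seed=seed)
    spec.validate(table)
    return spec


def import_folds(table: SWDTable, fold_ids) -> FoldSpec:
    """Wrap externally constructed folds (e.g. spatial blocks) as a FoldSpec."""
    ids = np.asarray(fold_ids, dtype=int).ravel()
    if len(ids) != table.n_records:
        raise ValueError(
            f"got {len(ids)} fold ids for {table.n_records} records"
        )
    uniq = np.unique(ids)
    remap = {u: i for i, u in enumerate(uniq)}
    assignments = np.array([remap[i] for i in ids])
    spec = FoldSpec(kind="kfold", assignments=assignments, k=len(uniq))
    spec.validate(table)
    return spec


def holdout_spec(table: SWDTable, validation_fraction: float, seed: int) -> FoldSpec:
    """Hold-out FoldSpec splitting off a validation partition."""
    train, val = split_holdout(table, validation_fraction, seed)
    # reconstruct the mask from split_holdout's deterministic choice
    rng = np.random.default_rng(seed)
    mask = np.zeros(table.n_records, dtype=bool)
    for idx in (table.presence_idx, table.contrast_idx):
        n_test = _round_half_down(len(idx) * validation_fraction)
        chosen = rng.permutation(idx)[:n_test]
        mask[chosen] = True
    spec = FoldSpec(kind="holdout", assignments=mask.astype(int), k=2, seed=seed)
    spec.validate(table)
    return spec
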