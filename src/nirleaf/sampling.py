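"""Calibration/test splitting and venetian-blinds cross-validation folds.

The calibration/test split is performed *per class* with the Kennard-Stone
algorithm (or uniformly at random): within each class, Kennard-Stone greedily
picks a maximally spread, representative calibration subset, which then never
leaks into the test set.  Cross-validation uses venetian blinds: calibration
samples, ordered by class then original order, are dealt into ``n_splits``
folds in blinds of fixed ``thickness``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .exceptions import ValidationError
from .spectra import SpectraSet

SPLIT_METHODS = ("kennard_stone", "random")


@dataclass
class SplitIndex:
    """Disjoint calibration/test sample-id sets."""

    calibration_ids: np.ndarray
    test_ids: np.ndarray
    method: str
    fraction: float

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        rows = [(sid, "calibration") for sid in self.calibration_ids]
        rows += [(sid, "test") for sid in self.test_ids]
        pd.DataFrame(rows, columns=["sample_id", "assignment"]).to_csv(
            path, index=False
        )
        return path

    @classmethod
    def from_csv(cls, path: str | Path, method: str = "kennard_stone",
                 fraction: float = 0.7) -> "SplitIndex":
        df = pd.read_csv(path, dtype=str)
        return cls(
            calibration_ids=df.loc[df["assignment"] == "calibration",
                                   "sample_id"].to_numpy(),
            test_ids=df.loc[df["assignment"] == "test", "sample_id"].to_numpy(),
            method=method,
            fraction=fraction,
        )


@dataclass
class CVFolds:
    """Venetian-blinds fold assignment for the calibration samples."""

    fold_of: dict
    n_splits: int
    thickness: int

    def fold_ids(self, k: int) -> list:
        return [sid for sid, f in self.fold_of.items() if f == k]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {"sample_id": list(self.fold_of), "assignment": list(self.fold_of.values())}
        ).to_csv(path, index=False)
        return path


def kennard_stone_select(X: np.ndarray, k: int) -> np.ndarray:
    """Kennard-Stone max-min selection of ``k`` rows of ``X``.

    Deterministic: start from the two points at maximal Euclidean distance,
    then repeatedly add the point whose minimum distance to the selected set
    is largest.  Ties break toward the lowest row index.  Returns indices in
    selection order.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k < 2:
        raise ValidationError("Kennard-Stone requires k >= 2")
    if k > n:
        raise ValidationError(f"cannot select {k} of {n} samples")
    d = cdist(X, X)
    # first pair: row-major argmax gives lowest (i, j) on ties
    i, j = np.unravel_index(np.argmax(d), d.shape)
    selected = [min(i, j), max(i, j)]
    remaining = np.ones(n, dtype=bool)
    remaining[selected] = False
    min_d = np.minimum(d[selected[0]], d[selected[1]])
    while len(selected) < k:
        cand = np.where(remaining)[0]
        best = cand[np.argmax(min_d[cand])]  # argmax -> first = lowest index
        selected.append(best)
        remaining[best] = False
        min_d = np.minimum(min_d, d[best])
    return np.array(selected)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_per_class(
    spectra: SpectraSet,
    fraction: float = 0.7,
    method: str = "kennard_stone",
    seed: int | None = None,
) -> SplitIndex:
    """Per-class calibration/test split on the given (preprocessed) spectra.

    Kennard-Stone distances are computed on ``spectra.values`` as supplied;
    the pipeline passes SNV+SG-preprocessed, *uncentered* spectra so the
    selection geometry matches the modelled space without depending on the
    split itself.  The per-class calibration count is
    ``round(fraction * class_size)`` (half-up).
    """
    if method not in SPLIT_METHODS:
        raise ValidationError(f"unknown split method {method!r}")
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    cal, test = [], []
    for cls in spectra.classes():
        idx = np.where(spectra.labels == cls)[0]
        n = idx.size
        if n < 3:
            raise ValidationError(f"class {cls!r} has fewer than 3 samples")
        k = _round_half_up(fraction * n)
        k = min(max(k, 2), n)
        if method == "kennard_stone":
            chosen = idx[kennard_stone_select(spectra.values[idx], k)]
        else:
            chosen = rng.choice(idx, size=k, replace=False)
        chosen_set = set(chosen.tolist())
        cal.extend(spectra.sample_id[i] for i in idx if i in chosen_set)
        test.extend(spectra.sample_id[i] for i in idx if i not in chosen_set)
    if not test:
        warnings.warn("fraction leaves an empty test set", stacklevel=2)
    return SplitIndex(
        calibration_ids=np.array(cal, dtype=object),
        test_ids=np.array(test, dtype=object),
        method=method,
        fraction=fraction,
    )


def ordered_calibration_ids(spectra: SpectraSet, split: SplitIndex) -> list:
    """Calibration ids sorted by class (order of appearance) then original order."""
    cal = set(split.calibration_ids.tolist())
    out = []
    for cls in spectra.classes():
        for i in np.where(spectra.labels == cls)[0]:
            if spectra.sample_id[i] in cal:
                out.append(spectra.sample_id[i])
    return out


def venetian_blinds(
    calibration_ids, n_splits: int = 10, thickness: int = 1
) -> CVFolds:
    """Deal ordered calibration samples into folds in fixed-size blinds.

    Sample at ordered position ``i`` goes to fold ``(i // thickness) mod
    n_splits``.
    """
    if n_splits < 2:
        raise ValidationError("n_splits must be >= 2")
    if thickness < 1:
        raise ValidationError("thickness must be >= 1")
    ids = list(calibration_ids)
    if len(ids) < n_splits:
        raise ValidationError(
            f"{len(ids)} calibration samples cannot fill {n_splits} folds"
        )
    fold_of = {sid: (i // thickness) % n_splits for i, sid in enumerate(ids)}
    return CVFolds(fold_of=fold_of, n_splits=n_splits, thickness=thickness)
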