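"""Spectra container and CSV input/output.

A :class:`SpectraSet` holds a sample x wavenumber matrix together with the
wavenumber axis (cm^-1, strictly monotone, descending by instrument
convention), per-sample class labels and sampling metadata (tree, leaf,
instrument replicate).  The same container is reused throughout the pipeline
for raw reflectance, absorbance (log10(1/R)) and preprocessed spectra; the
``kind`` attribute records which one it currently holds.

CSV layout (one row per spectrum)::

    sample_id,class,tree_id,replicate_id,sample_type,<wn_1>,<wn_2>,...

where ``<wn_i>`` are wavenumber column headers such as ``12000``, ``11996``.
Values are written at full double precision so a write/read round trip is
bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DomainError, FormatError, ValidationError

META_COLUMNS = ("sample_id", "class", "tree_id", "replicate_id", "sample_type")

#: recognised sample types (how the leaves were presented to the instrument)
SAMPLE_TYPES = ("fresh", "dried")


@dataclass
class SpectraSet:
    """Sample x wavenumber spectra with class labels and sampling metadata.

    Parameters
    ----------
    values
        ``(n_samples, n_wavenumbers)`` float matrix.
    axis
        Wavenumbers in cm^-1, strictly monotone (descending by convention).
    labels
        Class (variety) per sample.
    sample_id
        Identifier of the physical leaf; instrument replicates of the same
        leaf share a ``sample_id``.
    tree_id, replicate_id
        Optional sampling hierarchy metadata; ``None`` when not applicable
        (e.g. after replicate averaging).
    sample_type
        ``"fresh"`` or ``"dried"``.
    kind
        What the matrix currently holds: ``"absorbance"``, ``"reflectance"``
        or ``"derivative"`` (after Savitzky-Golay preprocessing).
    """

    values: np.ndarray
    axis: np.ndarray
    labels: np.ndarray
    sample_id: np.ndarray
    tree_id: np.ndarray | None = None
    replicate_id: np.ndarray | None = None
    sample_type: str = "dried"
    kind: str = "absorbance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        self.labels = np.asarray(self.labels)
        self.sample_id = np.asarray(self.sample_id)
        if self.values.ndim != 2:
            raise FormatError("values must be a 2-D sample x wavenumber matrix")
        n, p = self.values.shape
        if self.axis.shape != (p,):
            raise FormatError(
                f"axis length {self.axis.shape} does not match {p} spectral columns"
            )
        for name in ("labels", "sample_id"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise FormatError(f"{name} must have one entry per sample")
        for name in ("tree_id", "replicate_id"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                setattr(self, name, arr)
                if arr.shape != (n,):
                    raise FormatError(f"{name} must have one entry per sample")
        diffs = np.diff(self.axis)
        if len(self.axis) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise FormatError("wavenumber axis must be strictly monotone")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("spectra contain missing or non-finite values")
        if self.sample_type not in SAMPLE_TYPES:
            raise ValidationError(f"unknown sample_type {self.sample_type!r}")

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.values.shape[1]

    def classes(self) -> list[str]:
        """Class labels in order of first appearance."""
        return list(pd.unique(self.labels))

    def subset(self, mask_or_index) -> "SpectraSet":
        """Row subset preserving metadata alignment."""
        idx = np.asarray(mask_or_index)
        return replace(
            self,
            values=self.values[idx],
            labels=self.labels[idx],
            sample_id=self.sample_id[idx],
            tree_id=None if self.tree_id is None else self.tree_id[idx],
            replicate_id=None
            if self.replicate_id is None
            else self.replicate_id[idx],
        )

    def with_values(self, values: np.ndarray, axis: np.ndarray | None = None,
                    kind: str | None = None) -> "SpectraSet":
        """Copy with a new matrix (and optionally a new axis / kind)."""
        return replace(
            self,
            values=values,
            axis=self.axis if axis is None else axis,
            kind=self.kind if kind is None else kind,
        )


# ---------------------------------------------------------------------------
# CSV input / output
# ---------------------------------------------------------------------------

def write_spectra(spectra: SpectraSet, path: str | Path) -> Path:
    """Write a SpectraSet to the documented CSV layout."""
    path = Path(path)
    meta = {
        "sample_id": spectra.sample_id,
        "class": spectra.labels,
        "tree_id": spectra.tree_id
        if spectra.tree_id is not None
        else [""] * spectra.n_samples,
        "replicate_id": spectra.replicate_id
        if spectra.replicate_id is not None
        else [""] * spectra.n_samples,
        "sample_type": [spectra.sample_type] * spectra.n_samples,
    }
    headers = [f"{w:.10g}" for w in spectra.axis]
    df = pd.concat(
        [pd.DataFrame(meta),
         pd.DataFrame(spectra.values, columns=headers)],
        axis=1,
    )
    # 17 significant digits round-trip float64 exactly
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_spectra(path: str | Path, expected_type: str = "any") -> SpectraSet:
    """Read a spectra CSV written by :func:`write_spectra`.

    ``expected_type`` may be ``"fresh"``, ``"dried"`` or ``"any"``; a mismatch
    raises :class:`ValidationError`.  Missing ``tree_id``/``replicate_id``
    columns are tolerated (treated as a single replicate per leaf).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={"sample_id": str, "class": str},
                     float_precision="round_trip")
    if "sample_id" not in df.columns or "class" not in df.columns:
        raise FormatError("CSV must contain sample_id and class columns")
    spectral_cols = [c for c in df.columns if c not in META_COLUMNS]
    try:
        axis = np.array([float(c) for c in spectral_cols])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavenumber column: {exc}") from exc
    values = df[spectral_cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise FormatError("spectra contain missing values")
    sample_type_col = df.get("sample_type")
    if sample_type_col is not None and len(df):
        types = set(sample_type_col.astype(str))
        if len(types) > 1:
            raise ValidationError(f"mixed sample types in file: {sorted(types)}")
        sample_type = types.pop()
    else:
        sample_type = expected_type if expected_type != "any" else "dried"
    if expected_type != "any" and sample_type != expected_type:
        raise ValidationError(
            f"expected sample_type {expected_type!r}, file contains {sample_type!r}"
        )

    def _optional(col: str) -> np.ndarray | None:
        if col not in df.columns:
            return None
        vals = df[col]
        if vals.isna().all() or (vals.astype(str) == "").all():
            return None
        return vals.to_numpy()

    return SpectraSet(
        values=values,
        axis=axis,
        labels=df["class"].to_numpy(),
        sample_id=df["sample_id"].to_numpy(),
        tree_id=_optional("tree_id"),
        replicate_id=_optional("replicate_id"),
        sample_type=sample_type,
    )


# ---------------------------------------------------------------------------
# Reflectance <-> absorbance and replicate averaging
# ---------------------------------------------------------------------------

def reflectance_to_absorbance(spectra: SpectraSet) -> SpectraSet:
    """Convert reflectance to absorbance, A = log10(1/R).

    Raises :class:`DomainError` naming the first offending sample if any
    reflectance value is <= 0.
    """
    bad = np.where((spectra.values <= 0).any(axis=1))[0]
    if bad.size:
        raise DomainError(
            f"non-positive reflectance in sample {spectra.sample_id[bad[0]]!r}; "
            "log10(1/R) undefined"
        )
    return spectra.with_values(np.log10(1.0 / spectra.values), kind="absorbance")


def absorbance_to_reflectance(spectra: SpectraSet) -> SpectraSet:
    """Inverse of :func:`reflectance_to_absorbance`: R = 10**(-A)."""
    return spectra.with_values(10.0 ** (-spectra.values), kind="reflectance")


def average_replicates(spectra: SpectraSet) -> SpectraSet:
    """Collapse instrument replicates to one mean spectrum per leaf.

    Rows sharing a ``sample_id`` are averaged arithmetically; metadata is
    carried over and ``replicate_id`` is dropped.  The class label (and tree)
    must be consistent within each replicate group.
    """
    order = pd.unique(spectra.sample_id)
    pos = {sid: i for i, sid in enumerate(order)}
    n_groups = len(order)
    sums = np.zeros((n_groups, spectra.n_wavenumbers))
    counts = np.zeros(n_groups)
    labels = np.empty(n_groups, dtype=object)
    trees = np.empty(n_groups, dtype=object)
    labels[:] = None
    for i in range(spectra.n_samples):
        g = pos[spectra.sample_id[i]]
        if labels[g] is None:
            labels[g] = spectra.labels[i]
            trees[g] = spectra.tree_id[i] if spectra.tree_id is not None else None
        elif labels[g] != spectra.labels[i]:
            raise ValidationError(
                f"inconsistent class label within replicate group "
                f"{spectra.sample_id[i]!r}"
            )
        sums[g] += spectra.values[i]
        counts[g] += 1
    return SpectraSet(
        values=sums / counts[:, None],
        axis=spectra.axis,
        labels=labels.astype(str),
        sample_id=order,
        tree_id=None if spectra.tree_id is None else trees.astype(str),
        replicate_id=None,
        sample_type=spectra.sample_type,
        kind=spectra.kind,
    )
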