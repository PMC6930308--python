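"""Variable importance: VIP, target-projection selectivity ratio, regression
vector, and importance-driven spectral truncation.

Three indicators of per-wavenumber importance are computed from a fitted
PLS-DA model:

* **VIP** (variable importance in projection):
  ``VIP_j = sqrt(p * sum_a SSY_a w_aj^2 / sum_a SSY_a)`` with unit-norm
  weight vectors ``w_a`` and ``SSY_a = (t_a't_a)(q_a'q_a)`` the Y-variance
  explained by component ``a`` summed over the dummy columns.  By
  construction the mean squared VIP is 1; scores near or above 1 are
  conventionally considered relevant.
* **Selectivity ratio** (target projection): the spectra are projected onto
  the direction of a class's regression vector, and each wavenumber's ratio
  of explained to residual variance on that single predictive component is
  reported.  Per-class vectors are aggregated across classes by the
  elementwise maximum.
* **Regression vector**: the magnitude of each wavenumber's coefficient in B.

Truncation keeps the low-wavenumber side of the axis up to a configured cut
point (defaults: 6700 cm^-1 dried, 7500 cm^-1 fresh) — the high-wavenumber
region carries no important variables in either sample type.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ComputationError, ValidationError
from .plsda import PLSDAModel
from .spectra import SpectraSet

#: ceiling applied to the selectivity ratio when the residual vanishes
SR_CAP = 1e12

#: VIP relevance convention
VIP_RELEVANCE_CUTOFF = 1.0

#: default truncation points (cm^-1) per sample type
DEFAULT_CUTS = {"dried": 6700.0, "fresh": 7500.0}


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """VIP score per wavenumber; satisfies ``sum(VIP^2) = p``."""
    d = model.decomposition
    a = model.n_lv
    W = d.x_weights[:, :a]
    ssy = np.array([
        (d.x_scores[:, i] @ d.x_scores[:, i])
        * (d.y_loadings[:, i] @ d.y_loadings[:, i])
        for i in range(a)
    ])
    total = ssy.sum()
    if total <= 0:
        raise ComputationError("model explains no Y variance; VIP undefined")
    norms = np.linalg.norm(W, axis=0)
    Wn = W / norms
    p = W.shape[0]
    return np.sqrt(p * (Wn ** 2) @ ssy / total)


def selectivity_ratio(model: PLSDAModel, Xc: np.ndarray,
                      class_index: int) -> np.ndarray:
    """Per-wavenumber selectivity ratio on the target-projected component.

    ``Xc`` are the centred (training) spectra.  With ``b`` the class's
    regression-coefficient column: ``t_tp = Xc b / |b|``,
    ``p_tp = Xc' t_tp / (t_tp' t_tp)``; the explained part of column ``j`` is
    ``t_tp p_tp_j`` and SR_j is its variance over the residual variance.
    Residuals below ``1e-12`` of the column total cap SR at ``SR_CAP``.
    """
    if not 0 <= class_index < len(model.class_order):
        raise ValidationError(f"invalid class_index {class_index}")
    b = model.coef[:, class_index]
    nb = np.linalg.norm(b)
    if nb == 0:
        raise ComputationError("zero regression vector; target projection undefined")
    t = Xc @ (b / nb)
    p_tp = Xc.T @ t / (t @ t)
    explained = np.outer(t, p_tp)
    residual = Xc - explained
    ev = (explained ** 2).sum(axis=0)
    rv = (residual ** 2).sum(axis=0)
    total = ev + rv
    sr = np.full(ev.shape, 0.0)
    degenerate = rv <= 1e-12 * np.maximum(total, np.finfo(float).tiny)
    np.divide(ev, rv, out=sr, where=~degenerate)
    sr[degenerate & (ev > 0)] = SR_CAP
    return np.minimum(sr, SR_CAP)


def regression_vector(model: PLSDAModel, class_index: int) -> np.ndarray:
    """The class's column of the coefficient matrix B."""
    if not 0 <= class_index < len(model.class_order):
        raise ValidationError(f"invalid class_index {class_index}")
    return model.coef[:, class_index]


@dataclass
class ImportanceProfile:
    """Per-wavenumber importance indicators aligned with the model axis."""

    axis: np.ndarray
    vip: np.ndarray
    selectivity_ratio: np.ndarray       # (p, n_classes)
    sr_aggregated: np.ndarray           # elementwise max across classes
    reg_vector: np.ndarray              # (p, n_classes)
    class_order: tuple
    cut_wavenumber: float | None = None

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame({"wavenumber": self.axis, "vip": self.vip,
                           "sr_aggregated": self.sr_aggregated})
        for j, cls in enumerate(self.class_order):
            df[f"sr_{cls}"] = self.selectivity_ratio[:, j]
            df[f"abs_b_{cls}"] = np.abs(self.reg_vector[:, j])
        df.to_csv(path, index=False)
        return path


def importance_profile(
    model: PLSDAModel,
    train: SpectraSet,
    cut_wavenumber: float | None = None,
) -> ImportanceProfile:
    """All three indicators for a fitted model and its training spectra.

    ``train`` is the preprocessed, uncentered training set; it is centred
    here with the model's stored training means.
    """
    Xc = train.values - model.centering.column_means
    n_classes = len(model.class_order)
    sr = np.column_stack([
        selectivity_ratio(model, Xc, j) for j in range(n_classes)
    ])
    reg = np.column_stack([
        regression_vector(model, j) for j in range(n_classes)
    ])
    return ImportanceProfile(
        axis=model.axis.copy(),
        vip=vip_scores(model),
        selectivity_ratio=sr,
        sr_aggregated=sr.max(axis=1),
        reg_vector=reg,
        class_order=model.class_order,
        cut_wavenumber=cut_wavenumber,
    )


def truncate_spectra(spectra: SpectraSet, cut_wavenumber: float) -> SpectraSet:
    """Keep wavenumbers <= ``cut_wavenumber`` (the informative low side)."""
    keep = spectra.axis <= cut_wavenumber
    if not keep.any():
        raise ValidationError(
            f"cut at {cut_wavenumber} cm^-1 retains no wavenumbers"
        )
    return spectra.with_values(spectra.values[:, keep], axis=spectra.axis[keep])
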