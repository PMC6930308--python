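"""Spectral pre-treatment: SNV, Savitzky-Golay derivative, mean centering.

The optimized chain applies, in order:

1. **SNV** (standard normal variate): each spectrum is centred to zero mean
   and scaled to unit sample standard deviation (n-1 denominator), removing
   additive offsets and multiplicative scatter.
2. **Savitzky-Golay first derivative**: a smoothed derivative via local
   least-squares polynomial fits (default 15-point window, 2nd-order
   polynomial), removing residual baseline drift and sharpening band
   structure.  The derivative is per index step; the axis is uniform so this
   is a constant rescaling of d/d(cm^-1).  The (window-1)/2 edge points on
   each side are trimmed rather than extrapolated.
3. **Mean centering**: per-column training means are subtracted; test spectra
   are always centred with the *training* means.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .exceptions import ConfigurationError, DegenerateSpectrumError, ValidationError
from .spectra import SpectraSet


@dataclass
class PreprocessConfig:
    """Pre-treatment chain settings (defaults are the optimized chain)."""

    apply_snv: bool = True
    apply_sg: bool = True
    sg_window: int = 15
    sg_polyorder: int = 2
    sg_deriv: int = 1
    mean_center: bool = True

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ConfigurationError(
                "sg_window must be odd and greater than sg_polyorder"
            )
        if self.sg_deriv > self.sg_polyorder:
            raise ConfigurationError("sg_deriv must not exceed sg_polyorder")


@dataclass
class CenteringModel:
    """Per-column training means (stored with their wavenumber axis)."""

    axis: np.ndarray
    column_means: np.ndarray

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {"wavenumber": self.axis, "mean": self.column_means}
        ).to_csv(path, index=False, float_format="%.17g")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "CenteringModel":
        df = pd.read_csv(path)
        return cls(axis=df["wavenumber"].to_numpy(),
                   column_means=df["mean"].to_numpy())


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate: row-wise zero mean, unit sample SD (n-1).

    Raises :class:`DegenerateSpectrumError` naming the first constant row.
    """
    x = spectra.values
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    bad = np.where(sd[:, 0] == 0)[0]
    if bad.size:
        raise DegenerateSpectrumError(
            f"constant spectrum {spectra.sample_id[bad[0]]!r} cannot be "
            "SNV-normalized"
        )
    return spectra.with_values((x - mean) / sd)


def sg_derivative(spectra: SpectraSet, config: PreprocessConfig) -> SpectraSet:
    """Savitzky-Golay derivative, edge points trimmed.

    Every retained point equals the derivative of the local least-squares
    polynomial fit over the centred window (derivative taken per index step).
    """
    if spectra.n_wavenumbers < config.sg_window:
        raise ConfigurationError(
            f"sg_window {config.sg_window} exceeds axis length "
            f"{spectra.n_wavenumbers}"
        )
    full = savgol_filter(
        spectra.values,
        window_length=config.sg_window,
        polyorder=config.sg_polyorder,
        deriv=config.sg_deriv,
        delta=1.0,
        axis=1,
    )
    h = (config.sg_window - 1) // 2
    sl = slice(h, spectra.n_wavenumbers - h)
    return spectra.with_values(full[:, sl], axis=spectra.axis[sl],
                               kind="derivative")


def fit_mean_center(train: SpectraSet) -> CenteringModel:
    """Column means of the training spectra."""
    return CenteringModel(axis=train.axis.copy(),
                          column_means=train.values.mean(axis=0))


def apply_center(spectra: SpectraSet, model: CenteringModel) -> SpectraSet:
    """Subtract the model's (training) column means."""
    if spectra.axis.shape != model.axis.shape or not np.allclose(
        spectra.axis, model.axis
    ):
        raise ValidationError("centering model axis does not match spectra axis")
    return spectra.with_values(spectra.values - model.column_means)


def preprocess_chain(
    spectra: SpectraSet,
    config: PreprocessConfig | None = None,
    centering: CenteringModel | None = None,
) -> tuple[SpectraSet, CenteringModel | None]:
    """SNV -> SG derivative -> mean centering, in that fixed order.

    When ``centering`` is ``None`` and ``config.mean_center`` is set, a
    :class:`CenteringModel` is fitted on the input (training use) and
    returned; otherwise the supplied model is applied (test use).
    """
    config = config or PreprocessConfig()
    out = spectra
    if config.apply_snv:
        out = snv(out)
    if config.apply_sg:
        out = sg_derivative(out, config)
    model = centering
    if config.mean_center:
        if model is None:
            model = fit_mean_center(out)
        out = apply_center(out, model)
    return out, model
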