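"""Synthetic NIR leaf-spectrum generator.

Emulates a six-variety almond (*Prunus dulcis*) leaf study design: for each
variety, leaves are collected from several trees and each leaf is scanned in
triplicate on an FT-NIR instrument over 12000-3800 cm^-1 at 4 cm^-1 steps.
Spectra are built as sums of Gaussian absorption bands (in wavenumber) on a
random linear baseline, with a hierarchical variance structure:

* a per-class amplitude multiplier on the informative bands (the varietal
  signal; varieties are genetically close, so multipliers sit near 1),
* a tree effect shared by all leaves of a tree (random band-amplitude shift),
* a leaf effect shared by a leaf's replicate scans,
* independent replicate noise, a per-spectrum multiplicative gain
  (scatter, which SNV is meant to correct) and a random linear baseline.

Fresh-mode spectra are dominated by two broad water bands near 5000 and
7000 cm^-1 (O-H combination and first overtone) plus a C-H combination band
near 4000-4500 cm^-1.  Dried-powdered spectra instead show richer, narrower
band structure across 4000-7500 cm^-1 (C-H/N-H/O-H combinations and first
overtones) and only a weak C-H second-overtone band near 8000-9000 cm^-1,
leaving 7500-10000 cm^-1 a low-information zone in both modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError
from .spectra import SpectraSet

#: the six commercial varieties the study design emulates
DEFAULT_CLASS_NAMES = (
    "Avijor", "Guara", "Isabelona", "Marta", "Pentacebas", "Soleta",
)


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band.

    ``class_multipliers`` holds one relative amplitude factor per class
    (near 1; the varietal signal).  Bands with all multipliers equal to 1
    carry no class information.
    """

    center: float            # cm^-1
    width: float             # Gaussian sigma, cm^-1
    base_amplitude: float    # absorbance units
    class_multipliers: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigurationError("band width must be > 0")
        if self.base_amplitude < 0:
            raise ConfigurationError("band base_amplitude must be >= 0")
        if any(m <= 0 for m in self.class_multipliers):
            raise ConfigurationError("class_multipliers must be > 0")


# (center, sigma, amplitude, informative) per sample type.  Informative bands
# receive per-class multipliers; all of them sit below the documented cut
# points (7500 cm^-1 fresh, 6700 cm^-1 dried) so spectral truncation keeps
# the varietal signal.
_FRESH_BANDS = (
    (5000.0, 220.0, 1.00, True),    # O-H combination (water), broad
    (7000.0, 260.0, 0.65, True),    # O-H first overtone (water), broad
    (4300.0, 90.0, 0.35, True),     # C-H combination (carbohydrates)
    (5600.0, 150.0, 0.15, True),    # weak C-H/O-H shoulder
    (8500.0, 250.0, 0.04, False),   # weak C-H second overtone
)
_DRIED_BANDS = (
    (4350.0, 60.0, 0.40, True),     # C-H combination
    (4750.0, 70.0, 0.45, True),     # N-H / O-H stretching combination
    (5200.0, 80.0, 0.30, True),     # O-H related combination
    (5800.0, 70.0, 0.35, True),     # C-H first overtone
    (6600.0, 90.0, 0.25, True),     # N-H / O-H first overtone
    (7300.0, 80.0, 0.15, False),    # C-H combination, above the dried cut
    (8500.0, 150.0, 0.06, False),   # C-H second overtone, low-information zone
)


def default_band_table(
    sample_type: str,
    n_classes: int = 6,
    class_effect: float = 0.08,
    seed: int = 0,
) -> list[BandSpec]:
    """Band table for one sample type, with per-class multipliers.

    Multipliers for the informative bands are assigned once per class,
    deterministically from ``seed``: each class receives a distinct binary
    contrast pattern over the informative bands, with the multiplier at
    ``1 - class_effect`` or ``1 + class_effect`` per band.  Patterns are
    even-weight binary codewords (pairwise Hamming distance >= 2), drawn at
    random from the code, so every pair of varieties differs on at least two
    bands and — because hypercube vertices are never convex combinations of
    other vertices — no variety is masked by lying between two others, a
    known failure mode of linear indicator regression.  The effect stays
    small (multipliers within ``[1 - class_effect, 1 + class_effect]``),
    emulating genetically close varieties.  ``class_effect=0`` yields
    identical classes (no varietal signal), the chance-level control.
    """
    if sample_type == "fresh":
        layout = _FRESH_BANDS
    elif sample_type == "dried":
        layout = _DRIED_BANDS
    else:
        raise ConfigurationError(f"unknown sample_type {sample_type!r}")
    rng = np.random.default_rng(seed)
    informative_idx = [i for i, (_, _, _, inf) in enumerate(layout) if inf]
    codes = _class_codewords(len(informative_idx), n_classes, rng)
    table = []
    for i, (center, width, amp, informative) in enumerate(layout):
        if informative and class_effect > 0:
            bi = informative_idx.index(i)
            mult = tuple(
                1.0 + class_effect * (1.0 if codes[c][bi] else -1.0)
                for c in range(n_classes)
            )
        else:
            mult = (1.0,) * n_classes
        table.append(BandSpec(center, width, amp, mult))
    return table


def _class_codewords(k: int, n_classes: int, rng) -> list[tuple[int, ...]]:
    """Distinct binary patterns over ``k`` informative bands, one per class.

    Drawn from the even-weight code (pairwise Hamming distance >= 2) when it
    is large enough, otherwise from all distinct vertices.
    """
    import itertools

    vertices = list(itertools.product((0, 1), repeat=k))
    even = [v for v in vertices if sum(v) % 2 == 0]
    pool = even if len(even) >= n_classes else vertices
    if len(pool) < n_classes:
        raise ConfigurationError(
            f"{k} informative bands support at most {len(pool)} classes"
        )
    order = rng.permutation(len(pool))
    return [pool[i] for i in order[:n_classes]]


@dataclass
class GeneratorConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the emulated sampling design: 6 varieties x 50 leaves
    (10 trees, 5 leaves per tree) x 3 instrument replicates, spectra over
    12000-3800 cm^-1 at 4 cm^-1 resolution (2051 points).  Variance
    components are in absorbance units.
    """

    sample_type: str = "dried"
    n_classes: int = 6
    n_trees_per_class: int = 10
    n_leaves_per_class: int = 50
    n_replicates: int = 3
    axis_max: float = 12000.0
    axis_min: float = 3800.0
    axis_step: float = 4.0
    band_table: list[BandSpec] | None = None
    class_effect: float = 0.08     # half-width of the multiplier range
    tree_sd: float = 0.006         # band-amplitude shift shared within a tree
    leaf_sd: float = 0.008         # band-amplitude shift shared within a leaf
    replicate_sd: float = 0.003    # white noise per spectral point
    gain_sd: float = 0.03          # per-spectrum multiplicative scatter
    baseline_offset_sd: float = 0.05
    baseline_slope_sd: float = 0.02
    class_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.axis_max <= self.axis_min:
            raise ConfigurationError("axis_max must exceed axis_min")
        if self.axis_step <= 0:
            raise ConfigurationError("axis_step must be > 0")
        for name in ("tree_sd", "leaf_sd", "replicate_sd", "gain_sd",
                     "baseline_offset_sd", "baseline_slope_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_leaves_per_class % self.n_trees_per_class:
            raise ConfigurationError(
                "n_leaves_per_class must be divisible by n_trees_per_class"
            )
        if self.n_replicates < 1 or self.n_classes < 1:
            raise ConfigurationError("counts must be positive")
        if self.class_names is None:
            if self.n_classes <= len(DEFAULT_CLASS_NAMES):
                self.class_names = DEFAULT_CLASS_NAMES[: self.n_classes]
            else:
                self.class_names = tuple(
                    f"class{i + 1}" for i in range(self.n_classes)
                )
        elif len(self.class_names) != self.n_classes:
            raise ConfigurationError("class_names length must equal n_classes")

    def axis(self) -> np.ndarray:
        """Descending wavenumber axis."""
        return np.arange(self.axis_max, self.axis_min - self.axis_step / 2,
                         -self.axis_step)


def generate(config: GeneratorConfig) -> SpectraSet:
    """Generate replicate-level absorbance spectra for one sample type.

    Returns ``n_classes * n_leaves_per_class * n_replicates`` rows; the same
    seed always produces bit-identical output.
    """
    axis = config.axis()
    bands = config.band_table
    if bands is None:
        bands = default_band_table(
            config.sample_type, config.n_classes, config.class_effect,
            seed=config.seed,
        )
    for b in bands:
        if len(b.class_multipliers) != config.n_classes:
            raise ConfigurationError(
                "every band needs one class multiplier per class"
            )
    rng = np.random.default_rng(config.seed)
    n_bands = len(bands)
    # Gaussian profile of each band over the axis: (n_bands, p)
    profiles = np.stack([
        np.exp(-0.5 * ((axis - b.center) / b.width) ** 2) for b in bands
    ])
    base_amp = np.array([b.base_amplitude for b in bands])
    mult = np.array([b.class_multipliers for b in bands])  # (n_bands, n_classes)
    # normalised axis position for the baseline slope term
    s = (axis - axis.min()) / (axis.max() - axis.min())

    leaves_per_tree = config.n_leaves_per_class // config.n_trees_per_class
    rows, labels, sample_ids, tree_ids, rep_ids = [], [], [], [], []
    for c, cname in enumerate(config.class_names):
        for t in range(config.n_trees_per_class):
            tree_dev = rng.normal(0.0, config.tree_sd, size=n_bands)
            for l_in_tree in range(leaves_per_tree):
                leaf = t * leaves_per_tree + l_in_tree
                leaf_dev = rng.normal(0.0, config.leaf_sd, size=n_bands)
                amps = base_amp * mult[:, c] + tree_dev + leaf_dev
                signal = amps @ profiles
                for r in range(config.n_replicates):
                    gain = 1.0 + rng.normal(0.0, config.gain_sd)
                    offset = rng.normal(0.0, config.baseline_offset_sd)
                    slope = rng.normal(0.0, config.baseline_slope_sd)
                    noise = rng.normal(0.0, config.replicate_sd, size=axis.size)
                    rows.append(gain * signal + offset + slope * s + noise)
                    labels.append(cname)
                    sample_ids.append(f"{cname}-l{leaf + 1:03d}")
                    tree_ids.append(f"{cname}-t{t + 1:02d}")
                    rep_ids.append(r + 1)
    return SpectraSet(
        values=np.array(rows),
        axis=axis,
        labels=np.array(labels),
        sample_id=np.array(sample_ids),
        tree_id=np.array(tree_ids),
        replicate_id=np.array(rep_ids),
        sample_type=config.sample_type,
        kind="absorbance",
    )


def to_reflectance(spectra: SpectraSet) -> SpectraSet:
    """Convert generated absorbance to reflectance, R = 10**(-A)."""
    from .spectra import absorbance_to_reflectance

    return absorbance_to_reflectance(spectra)
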