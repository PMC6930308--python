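"""End-to-end orchestration of the varietal-discrimination study.

One invocation handles one sample type (fresh or dried) and runs:

generate (or load) replicate spectra -> average replicates -> preprocess
(SNV, SG first derivative, mean centering) -> per-class Kennard-Stone 70/30
split -> venetian-blinds CV latent-variable selection -> full-spectrum
PLS-DA -> variable importance (VIP, selectivity ratio, regression vector) ->
spectral truncation at the configured cut point -> independent refit on the
truncated spectra -> combined per-class report for both models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import importance as imp
from . import metrics as met
from . import plsda
from .exceptions import ConfigurationError
from .preprocess import PreprocessConfig, preprocess_chain
from .sampling import (
    SplitIndex,
    ordered_calibration_ids,
    split_per_class,
    venetian_blinds,
)
from .simulate import GeneratorConfig, generate
from .spectra import SpectraSet, average_replicates, read_spectra, write_spectra

log = logging.getLogger("nirleaf")


@dataclass
class PipelineConfig:
    """All settings of one end-to-end run."""

    sample_type: str = "dried"
    input_csv: str | None = None      # load instead of generating when set
    seed: int = 0
    fraction: float = 0.70
    split_method: str = "kennard_stone"
    cv_splits: int = 10
    cv_thickness: int = 1
    max_lv: int = 20
    cut_wavenumber: float | None = None   # default per sample type
    out_dir: str = "nirleaf_run"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    generator: GeneratorConfig | None = None
    write_spectra_csv: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ConfigurationError("fraction must be in (0, 1]")
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise ConfigurationError(f"input file not found: {self.input_csv}")
        if self.cut_wavenumber is None:
            self.cut_wavenumber = imp.DEFAULT_CUTS[self.sample_type]

    # -- flat YAML-style config file ----------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        pp_keys = {f for f in PreprocessConfig.__dataclass_fields__}
        pp = {k: raw.pop(k) for k in list(raw) if k in pp_keys}
        known = {f for f in cls.__dataclass_fields__} - {"preprocess", "generator"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(preprocess=PreprocessConfig(**pp), **raw)

    def to_yaml(self, path: str | Path) -> Path:
        d = {k: v for k, v in asdict(self).items()
             if k not in ("preprocess", "generator")}
        d.update(asdict(self.preprocess))
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
        return Path(path)


@dataclass
class ModelRun:
    """One fitted model (full-spectrum or truncated) and its evaluations."""

    model: plsda.PLSDAModel
    selection: plsda.CVSelection
    folds: "object"
    cv_confusion: met.ConfusionMatrix
    test_confusion: met.ConfusionMatrix
    cv_metrics: pd.DataFrame
    test_metrics: pd.DataFrame


@dataclass
class RunResult:
    """Everything run_all produced."""

    config: PipelineConfig
    spectra: SpectraSet              # replicate-level absorbance
    leaves: SpectraSet               # replicate-averaged
    split: SplitIndex
    full: ModelRun
    truncated: ModelRun
    profile: imp.ImportanceProfile
    report: pd.DataFrame
    out_dir: Path


def _fit_and_evaluate(
    leaves: SpectraSet,
    split: SplitIndex,
    config: PipelineConfig,
    class_order: tuple,
) -> ModelRun:
    """Preprocess, select LVs, fit and evaluate one model on given leaves."""
    pp_nc = PreprocessConfig(**{**asdict(config.preprocess),
                                "mean_center": False})
    pre, _ = preprocess_chain(leaves, pp_nc)
    cal_mask = np.isin(leaves.sample_id, split.calibration_ids)
    test_mask = np.isin(leaves.sample_id, split.test_ids)
    cal = pre.subset(cal_mask)
    test = pre.subset(test_mask)

    ordered = ordered_calibration_ids(pre, split)
    folds = venetian_blinds(ordered, config.cv_splits, config.cv_thickness)
    selection = plsda.select_n_lv(cal, folds, config.max_lv, class_order)
    log.info("selected %d latent variables (CV error %.4f)",
             selection.n_lv, selection.errors[selection.n_lv - 1])

    model = plsda.fit_plsda(cal, selection.n_lv, class_order)
    cal_pred = plsda.predict(model, cal)
    plsda.estimate_thresholds(model, cal_pred, cal.labels)

    cv_cm = met.confusion(selection.true_labels, selection.assignments_at(),
                          class_order)
    test_pred = plsda.predict(model, test)
    test_cm = met.confusion(test.labels, test_pred.assigned, class_order)
    return ModelRun(
        model=model,
        selection=selection,
        folds=folds,
        cv_confusion=cv_cm,
        test_confusion=test_cm,
        cv_metrics=met.per_class_metrics(cv_cm),
        test_metrics=met.per_class_metrics(test_cm),
    )


def run_all(config: PipelineConfig) -> RunResult:
    """Run the complete study for one sample type; write all artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_all(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_all(config: PipelineConfig, out: Path) -> RunResult:
    log.info("run-all: sample_type=%s seed=%d fraction=%.2f max_lv=%d cut=%s",
             config.sample_type, config.seed, config.fraction, config.max_lv,
             config.cut_wavenumber)
    if config.input_csv:
        spectra = read_spectra(config.input_csv, expected_type=config.sample_type)
        log.info("loaded %d spectra from %s", spectra.n_samples,
                 config.input_csv)
    else:
        gen = config.generator or GeneratorConfig(
            sample_type=config.sample_type, seed=config.seed
        )
        spectra = generate(gen)
        log.info("generated %d replicate spectra (%d classes)",
                 spectra.n_samples, gen.n_classes)
    if config.write_spectra_csv:
        write_spectra(spectra, out / "spectra.csv")

    leaves = average_replicates(spectra)
    log.info("averaged replicates: %d leaf spectra", leaves.n_samples)
    class_order = tuple(leaves.classes())

    # split on the SNV+SG (uncentered) full-spectrum representation
    pp_nc = PreprocessConfig(**{**asdict(config.preprocess),
                                "mean_center": False})
    pre_nc, _ = preprocess_chain(leaves, pp_nc)
    split = split_per_class(pre_nc, config.fraction, config.split_method,
                            seed=config.seed)
    split.to_csv(out / "split.csv")
    log.info("split (%s): %d calibration / %d test", split.method,
             len(split.calibration_ids), len(split.test_ids))

    full = _fit_and_evaluate(leaves, split, config, class_order)
    full.folds.to_csv(out / "cv_folds.csv")
    plsda.save_model(full.model, out / "model_full")
    log.info("full-spectrum model: %d variables, %d LVs",
             full.model.n_variables, full.model.n_lv)

    # variable importance on the full-spectrum model
    cal_mask = np.isin(leaves.sample_id, split.calibration_ids)
    cal_pre = pre_nc.subset(cal_mask)
    profile = imp.importance_profile(full.model, cal_pre,
                                     cut_wavenumber=config.cut_wavenumber)
    profile.to_csv(out / "importance.csv")

    # truncate the raw leaf spectra and refit the whole chain independently
    leaves_cut = imp.truncate_spectra(leaves, config.cut_wavenumber)
    log.info("truncated at %.0f cm^-1: %d of %d wavenumbers retained",
             config.cut_wavenumber, leaves_cut.n_wavenumbers,
             leaves.n_wavenumbers)
    truncated = _fit_and_evaluate(leaves_cut, split, config, class_order)
    plsda.save_model(truncated.model, out / "model_truncated")
    log.info("truncated model: %d variables, %d LVs",
             truncated.model.n_variables, truncated.model.n_lv)

    report = met.build_report(
        {
            "full_spectrum": {"cross_validation": full.cv_metrics,
                              "test": full.test_metrics},
            "truncated": {"cross_validation": truncated.cv_metrics,
                          "test": truncated.test_metrics},
        },
        n_lv={"full_spectrum": full.model.n_lv,
              "truncated": truncated.model.n_lv},
        n_variables={"full_spectrum": full.model.n_variables,
                     "truncated": truncated.model.n_variables},
    )
    met.write_report(report, out / "report.csv")
    (out / "report.txt").write_text(met.format_report(report) + "\n")
    log.info("report written: %d rows", len(report))
    return RunResult(
        config=config,
        spectra=spectra,
        leaves=leaves,
        split=split,
        full=full,
        truncated=truncated,
        profile=profile,
        report=report,
        out_dir=out,
    )
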