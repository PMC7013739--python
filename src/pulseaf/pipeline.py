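"""End-to-end orchestration: simulate -> preprocess -> beats -> features ->
rank -> classify, with artifacts written to disk.

One seed controls the simulated cohort, the train/test split and the model
fit; a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .classify import SplitSpec, TrainResult, build_feature_table, evaluate_classifier, train_classifier
from .containers import WaveformSignal
from .errors import ConfigurationError, PulseAFError
from .estimators import FeatureExtractor
from .io import (
    read_signal_csv,
    write_feature_table_csv,
    write_manifest_csv,
    write_report_json,
)
from .preprocess import PreprocessConfig
from .select import rank_features
from .simulate import generate_dataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one full pipeline run."""

    n_per_class: int = 200
    fs: float = 100.0
    window_length: float = 60.0
    noise_sd: float = 0.02
    baseline_amp: float = 0.1
    feature_group: str = "Group3"
    model: str = "gradient_boosting"
    ranking_method: str = "correlation"
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    split: SplitSpec | None = None

    def __post_init__(self) -> None:
        if not self.window_length > 0:
            raise ConfigurationError("window_length must be positive")


def split_windows(signal: WaveformSignal, window_length: float) -> list[WaveformSignal]:
    """Cut a record into non-overlapping fixed-length analysis windows.

    Partial trailing windows are dropped; a record shorter than one window
    yields nothing.
    """
    n_win = int(window_length * signal.fs)
    windows = []
    for k in range(int(len(signal) // n_win)):
        chunk = signal.samples[k * n_win : (k + 1) * n_win + 1]
        rid = f"{signal.record_id}_w{k}" if signal.record_id else None
        windows.append(WaveformSignal(chunk, signal.fs, record_id=rid))
    return windows


def read_signal(path, format: str = "csv") -> WaveformSignal:
    """Read a waveform record from disk. Supported format: ``csv``."""
    if format == "csv":
        return read_signal_csv(path)
    if format == "wfdb":
        raise ConfigurationError(
            "WFDB input is not supported by this build; convert the record to "
            "two-column CSV (time_s,amplitude)"
        )
    raise ConfigurationError(f"unknown signal format {format!r}")


def run_pipeline(config: RunConfig, outdir) -> "PipelineResult":
    """Run the whole pipeline and write the four artifacts.

    Artifacts: ``manifest.csv`` (record_id,label), ``features.csv`` (feature
    table incl. Vt), ``ranking.csv`` (feature scores), ``report.json``
    (classification report + effective parameters of every stage).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        records = generate_dataset(
            config.n_per_class,
            fs=config.fs,
            seed=config.seed,
            duration=config.window_length,
            noise_sd=config.noise_sd,
            baseline_amp=config.baseline_amp,
        )
    except PulseAFError as exc:
        raise type(exc)(f"simulate stage: {exc}") from exc
    write_manifest_csv(
        [(wave.record_id, truth.rhythm_label) for wave, truth in records],
        outdir / "manifest.csv",
    )
    extractor = FeatureExtractor(
        target_fs=config.preprocess.target_fs,
        band_low=config.preprocess.band_low,
        band_high=config.preprocess.band_high,
        filter_order=config.preprocess.filter_order,
        norm_percentile=config.preprocess.norm_percentile,
    )
    try:
        table = build_feature_table(
            [(w, t.rhythm_label) for w, t in records],
            group=config.feature_group,
            extractor=extractor,
        )
    except PulseAFError as exc:
        raise type(exc)(f"features stage: {exc}") from exc
    write_feature_table_csv(table, outdir / "features.csv")
    try:
        ranking = rank_features(table, method=config.ranking_method)
    except PulseAFError as exc:
        raise type(exc)(f"rank stage: {exc}") from exc
    ranking.to_frame().to_csv(outdir / "ranking.csv", index=False)
    split = config.split or SplitSpec(seed=config.seed)
    try:
        result = train_classifier(table, model=config.model, split=split)
    except PulseAFError as exc:
        raise type(exc)(f"classify stage: {exc}") from exc
    report = evaluate_classifier(result.labels, result.scores)
    payload = {
        "report": report.to_dict(),
        "run_config": {
            **{k: v for k, v in asdict(config).items() if k not in ("preprocess", "split")},
            "preprocess": asdict(config.preprocess),
            "split": asdict(split),
        },
        "train_manifest": result.manifest,
        "n_dropped_records": len(extractor.failed_indices_),
    }
    write_report_json(payload, outdir / "report.json")
    logger.info(
        "pipeline done: %d rows, accuracy %.4f, AUC %.4f",
        len(table), report.accuracy, report.roc_auc,
    )
    return PipelineResult(report=report, train_result=result, table=table, outdir=outdir)


@dataclass
class PipelineResult:
    report: object
    train_result: TrainResult
    table: object
    outdir: Path
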