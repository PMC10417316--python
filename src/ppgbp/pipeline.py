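"""End-to-end pipeline: configuration, record adapters, and stage orchestration.

``run_pipeline`` executes generate/load -> QC -> denoise -> segment ->
resample -> label -> filter -> standardize -> split -> (optional grid
search) -> train -> evaluate, logging per-stage counts, and writes every
artifact (segment container, split manifest, grid table, model checkpoints,
evaluation reports) into the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ChannelNotFoundError, FormatError, InvalidArgumentError
from .evaluation import EvalReport, evaluation_report
from .models import ModelSpec, TrainConfig, build_model, predict_bp, save_model, train_model
from .preprocessing import (
    record_to_segments,
    segments_to_arrays,
    write_segments_text,
)
from .selection import (
    DEFAULT_BATCH_SIZES,
    DEFAULT_LEARNING_RATES,
    HyperParams,
    enumerate_grid,
    grid_search,
    split_dataset,
)
from .synthetic import SignalRecord, SyntheticConfig, synth_record

__all__ = ["PipelineConfig", "load_wfdb_record", "run_pipeline"]

logger = logging.getLogger("ppgbp.pipeline")


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the study's settings as defaults.

    ``n_records`` synthetic subjects are generated unless ``record_paths``
    names text records to load instead.  The defaults reproduce the study
    conditions (125 Hz, 300 s records, the 4 x 4 x 3 hyperparameter grid,
    80/20 split with a fifth of the train share for validation) at whatever
    scale ``n_records`` dictates.
    """

    # data source
    n_records: int = 8
    record_paths: list[str] = field(default_factory=list)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    # preprocessing
    target_length: int = 200
    hr_bounds: tuple[float, float] = (40.0, 180.0)
    min_flat_duration: float = 1.0
    slope_tolerance: float = 0.0
    # split
    train_fraction: float = 0.8
    test_fraction: float = 0.2
    val_fraction_of_train: float = 0.2
    subject_level_split: bool = False
    # model / training
    model: ModelSpec = field(default_factory=ModelSpec)
    train: TrainConfig = field(default_factory=lambda: TrainConfig(max_epochs=20))
    # grid search
    run_grid_search: bool = False
    grid_optimizers: tuple[str, ...] = ("sgd", "rmsprop", "adam", "adadelta")
    grid_learning_rates: tuple[float, ...] = DEFAULT_LEARNING_RATES
    grid_batch_sizes: tuple[int, ...] = DEFAULT_BATCH_SIZES
    grid_folds: int = 5
    grid_epochs: int = 3
    grid_subset: int = 0          # cap on segments used during CV (0 = all)
    seed: int = 0

    def validate(self) -> None:
        if not self.record_paths and self.n_records < 1:
            raise InvalidArgumentError("need n_records >= 1 or record_paths")
        for frac in (self.train_fraction, self.test_fraction, self.val_fraction_of_train):
            if not 0 < frac < 1:
                raise InvalidArgumentError("split fractions must lie in (0, 1)")
        if self.train_fraction + self.test_fraction > 1 + 1e-12:
            raise InvalidArgumentError("train_fraction + test_fraction must be <= 1")
        self.synthetic.validate()
        self.model.validate()
        self.train.validate()

    # -- config file round trip -------------------------------------------
    def to_yaml(self, path) -> None:
        def plain(obj):
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            return obj

        with open(str(path), "w") as fh:
            yaml.safe_dump(plain(dataclasses.asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(str(path)) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(dc_cls, data):
            names = {f.name: f for f in dataclasses.fields(dc_cls)}
            unknown = set(data) - set(names)
            if unknown:
                raise InvalidArgumentError(
                    f"unknown config keys for {dc_cls.__name__}: {sorted(unknown)}"
                )
            kwargs = {}
            for key, value in data.items():
                f = names[key]
                if dataclasses.is_dataclass(f.type) or key in ("synthetic", "model", "train"):
                    sub_cls = {"synthetic": SyntheticConfig, "model": ModelSpec, "train": TrainConfig}[key]
                    kwargs[key] = build(sub_cls, value)
                elif isinstance(value, list):
                    # sequence fields are tuples except explicit path lists
                    kwargs[key] = list(value) if key == "record_paths" else tuple(value)
                else:
                    kwargs[key] = value
            return dc_cls(**kwargs)

        return build(cls, raw)


def load_wfdb_record(path, ppg_channel: str = "PLETH", abp_channel: str = "ABP") -> SignalRecord:
    """Read one waveform record through the WFDB library (optional adapter).

    Requires the ``wfdb`` package.  Both channels must be present and share
    the record's sampling rate; no resampling is attempted.
    """
    try:
        import wfdb
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "the optional WFDB adapter requires the 'wfdb' package"
        ) from exc
    rec = wfdb.rdrecord(str(path))
    names = list(rec.sig_name)
    for channel in (ppg_channel, abp_channel):
        if channel not in names:
            raise ChannelNotFoundError(f"channel {channel!r} not in record ({names})")
    ppg = rec.p_signal[:, names.index(ppg_channel)]
    abp = rec.p_signal[:, names.index(abp_channel)]
    if ppg.shape != abp.shape:
        raise FormatError("PPG and ABP channels differ in length")
    return SignalRecord(
        subject_id=str(Path(str(path)).name),
        sampling_rate=float(rec.fs),
        ppg=ppg,
        abp=abp,
        beats=[],
    )


def _generate_records(config: PipelineConfig) -> list[SignalRecord]:
    from .synthetic import read_record

    if config.record_paths:
        return [read_record(p) for p in config.record_paths]
    records = []
    base = dataclasses.replace(config.synthetic)
    for i in range(config.n_records):
        records.append(synth_record(dataclasses.replace(base, seed=config.seed * 10_000 + i)))
    return records


def run_pipeline(config: PipelineConfig, out_dir) -> dict[str, EvalReport]:
    """Execute the full pipeline and write artifacts under ``out_dir``.

    Returns the evaluation reports, keyed by target ('sbp', 'dbp').
    """
    config.validate()
    out = Path(str(out_dir))
    out.mkdir(parents=True, exist_ok=True)

    records = _generate_records(config)
    logger.info("stage=input records=%d", len(records))

    segments = []
    kept_records = 0
    for rec in records:
        segs = record_to_segments(
            rec,
            hr_bounds=config.hr_bounds,
            target_length=config.target_length,
            min_flat_duration=config.min_flat_duration,
            slope_tolerance=config.slope_tolerance,
        )
        if segs:
            kept_records += 1
        segments.extend(segs)
    logger.info(
        "stage=preprocess records_in=%d records_kept=%d segments=%d",
        len(records), kept_records, len(segments),
    )
    if len(segments) < 20:
        raise InvalidArgumentError("too few segments survived preprocessing")
    write_segments_text(segments, out / "segments.tsv")

    subject_ids = [s.subject_id for s in segments] if config.subject_level_split else None
    train_idx, val_idx, test_idx = split_dataset(
        len(segments),
        config.train_fraction,
        config.test_fraction,
        config.val_fraction_of_train,
        seed=config.seed,
        subject_ids=subject_ids,
    )
    logger.info(
        "stage=split train=%d val=%d test=%d discarded=%d",
        len(train_idx), len(val_idx), len(test_idx),
        len(segments) - len(train_idx) - len(val_idx) - len(test_idx),
    )
    with open(out / "split.json", "w") as fh:
        json.dump(
            {
                "train": np.asarray(train_idx).tolist(),
                "val": np.asarray(val_idx).tolist(),
                "test": np.asarray(test_idx).tolist(),
            },
            fh,
        )

    reports: dict[str, EvalReport] = {}
    for target in ("sbp", "dbp"):
        X, y = segments_to_arrays(segments, target)
        hp = HyperParams(
            config.train.optimizer, config.train.learning_rate, config.train.batch_size
        )
        if config.run_grid_search:
            cv_idx = np.asarray(train_idx)
            if config.grid_subset and len(cv_idx) > config.grid_subset:
                cv_idx = cv_idx[: config.grid_subset]
            result = grid_search(
                config.model.architecture,
                X[cv_idx],
                y[cv_idx],
                grid=enumerate_grid(
                    config.grid_optimizers,
                    config.grid_learning_rates,
                    config.grid_batch_sizes,
                ),
                k=config.grid_folds,
                budget=TrainConfig(max_epochs=config.grid_epochs, early_stop_patience=config.grid_epochs),
                seed=config.seed,
                spec=config.model,
            )
            result.table.to_csv(out / f"grid_{target}.csv", index=False)
            hp = result.best
            logger.info(
                "stage=gridsearch target=%s cells=%d runs=%d best=%s",
                target, len(result.table), result.runs, hp,
            )
        train_config = dataclasses.replace(
            config.train,
            optimizer=hp.optimizer,
            learning_rate=hp.learning_rate,
            batch_size=hp.batch_size,
            seed=config.seed,
        )
        model = build_model(config.model, seed=config.seed)
        trained = train_model(
            model,
            (X[train_idx], y[train_idx]),
            (X[val_idx], y[val_idx]),
            train_config,
            spec=config.model,
        )
        save_model(trained, out / f"model_{target}")
        pred = predict_bp(trained, X[test_idx])
        report = evaluation_report(pred, y[test_idx])
        report.to_json(out / f"eval_{target}.json")
        (out / f"eval_{target}.txt").write_text(report.to_text() + "\n")
        logger.info(
            "stage=evaluate target=%s n=%d mad=%.3f sd=%.3f ieee=%s bhs=%s aami=%s",
            target, report.n, report.mad, report.sd,
            report.ieee_grade, report.bhs_grade, report.aami_pass,
        )
        reports[target] = report
    return reports
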