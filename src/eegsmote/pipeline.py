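"""End-to-end seizure-detection pipeline and its on-disk artifacts.

``run_pipeline`` binds the stages together: load (or accept) a record,
bandpass-filter it, optionally subset channels, window it, then
benchmark a resampler with leakage-safe cross-validation.  Every run
writes a JSON report and a manifest (config, seed, package versions)
sufficient to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .edf import read_edf
from .evaluation import EvalReport, cross_validate
from .preprocessing import EEGRecord, bandpass, segment, select_channels
from .resampling import RESAMPLERS, ResampleConfig

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "read_annotations",
           "write_annotations"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs.

    Either ``edf_path`` (+ optional ``annotations_path``) or an in-memory
    record passed to :func:`run_pipeline` supplies the input.  The global
    ``seed`` propagates to every stochastic component.
    """

    edf_path: str | None = None
    annotations_path: str | None = None
    resampler: str = "bnnsmote"
    resample_cfg: ResampleConfig = field(default_factory=ResampleConfig)
    classifier: str = "1nn"
    low_hz: float = 0.5
    high_hz: float = 50.0
    filter_order: int = 4
    window_s: float = 4.0
    step_s: float = 2.0
    label_rule: str = "majority-overlap"
    keep_channels: tuple[str, ...] | None = None
    n_folds: int = 5
    test_frac: float = 0.2
    out_dir: str = "pipeline_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resampler not in RESAMPLERS:
            raise ValueError(f"unknown resampler {self.resampler!r}")


def read_annotations(path: str | Path) -> list[tuple[float, float]]:
    """Seizure intervals from a TSV with columns record_id, start_s, end_s.

    Intervals are half-open seconds; they must be sorted and
    non-overlapping.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"record_id", "start_s", "end_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation TSV must have columns {sorted(required)}")
    ivals = [(float(a), float(b))
             for a, b in zip(df["start_s"], df["end_s"])]
    prev = -np.inf
    for a, b in ivals:
        if b <= a:
            raise ValueError(f"empty or inverted interval [{a}, {b})")
        if a < prev:
            raise ValueError("intervals must be sorted and non-overlapping")
        prev = b
    return ivals


def write_annotations(intervals: list[tuple[float, float]],
                      path: str | Path, record_id: str = "record") -> None:
    pd.DataFrame({"record_id": record_id,
                  "start_s": [a for a, _ in intervals],
                  "end_s": [b for _, b in intervals]}
                 ).to_csv(path, sep="\t", index=False)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def _manifest(cfg: RunConfig) -> dict:
    import eegsmote

    cfg_dict = asdict(cfg)
    blob = json.dumps(cfg_dict, sort_keys=True, default=str)
    return {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": cfg.seed,
        "versions": {"eegsmote": eegsmote.__version__,
                     "numpy": np.__version__,
                     "python": platform.python_version()},
    }


def run_pipeline(cfg: RunConfig, record: EEGRecord | None = None
                 ) -> EvalReport:
    """Execute read -> filter -> channel-select -> segment -> evaluate.

    ``record`` overrides ``cfg.edf_path`` for in-memory use.  Artifacts
    written to ``cfg.out_dir``: report.json, manifest.json.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if record is None:
        if cfg.edf_path is None:
            raise PipelineError("stage 'read' failed: no input "
                                "(edf_path and record both missing)")
        ivals = (read_annotations(cfg.annotations_path)
                 if cfg.annotations_path else None)
        record = _stage("read")(read_edf)(cfg.edf_path, ivals)

    record = _stage("bandpass")(bandpass)(
        record, cfg.low_hz, cfg.high_hz, cfg.filter_order)
    if cfg.keep_channels:
        record = _stage("select_channels")(select_channels)(
            record, list(cfg.keep_channels))
    segs = _stage("segment")(segment)(
        record, cfg.window_s, cfg.step_s, cfg.label_rule)
    report = _stage("evaluate")(cross_validate)(
        segs, resampler=cfg.resampler, classifier=cfg.classifier,
        n_folds=cfg.n_folds, test_frac=cfg.test_frac, seed=cfg.seed,
        cfg=cfg.resample_cfg)

    report.to_json(out / "report.json")
    (out / "manifest.json").write_text(json.dumps(_manifest(cfg), indent=2,
                                                  default=str))
    return report
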