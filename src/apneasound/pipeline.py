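"""End-to-end pipeline: (simulate | load) -> cancel -> detect -> score.

Stage order: adaptive cancellation runs first on the raw two-channel
audio; the detector's band-pass then operates on the cancelled output.
Every run writes its parameters, seed, and library versions to a
provenance record so deterministic stages reproduce bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .adaptive import DEFAULT_NLMS, NLMSConfig, nlms_cancel
from .apnea import ApneaEvent, detect_apneas
from .audio import AudioSignal, read_wav, write_wav
from .detector import (
    BreathEvent,
    DetectorConfig,
    bandpass,
    compute_threshold,
    detect_breaths,
    log_variance,
)
from .events import events_to_frame, read_apneas, write_events
from .scoring import MetricsReport, build_contingency, compute_metrics
from .synth import SynthProtocol, generate

__all__ = ["PipelineConfig", "PipelineResult", "detect_events", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and options for one pipeline run.

    Either ``simulate`` is set (a synthetic protocol generates the
    channels and reference annotations) or ``primary_wav`` names a
    recording, with ``reference_wav`` required when ``apply_af`` and
    ``reference_events`` naming the gold-standard apnea table.
    """

    outdir: Path
    simulate: SynthProtocol | None = None
    primary_wav: Path | None = None
    reference_wav: Path | None = None
    reference_events: Path | None = None
    apply_af: bool = True
    nlms: NLMSConfig = field(default_factory=NLMSConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    apnea_min_gap: float = 15.0
    tn_quantum: float = 15.0
    min_overlap: float = 0.0
    write_audio: bool = False


@dataclass(frozen=True)
class PipelineResult:
    breaths: list[BreathEvent]
    apneas: list[ApneaEvent]
    threshold: float
    metrics: MetricsReport | None
    artifacts: dict[str, Path]


def detect_events(
    audio: AudioSignal,
    config: DetectorConfig = DetectorConfig(),
    apnea_min_gap: float = 15.0,
) -> tuple[list[BreathEvent], list[ApneaEvent], float]:
    """Band-pass, log-var, threshold, breath runs, then the >15 s gap rule."""
    filtered = bandpass(audio, config)
    series = log_variance(filtered, config)
    threshold = compute_threshold(series, config)
    breaths = detect_breaths(series, threshold, config)
    apneas = detect_apneas(breaths, 0.0, audio.duration, apnea_min_gap)
    return breaths, apneas, threshold


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    try:
        if config.simulate is not None:
            record = generate(config.simulate)
            primary, reference = record.primary, record.reference
            reference_apneas: list[ApneaEvent] | None = record.true_apneas
            truth_path = outdir / "truth.csv"
            truth = pd.concat(
                [
                    events_to_frame(record.true_breaths, "breath"),
                    events_to_frame(record.true_apneas, "apnea"),
                ],
                ignore_index=True,
            )
            write_events(truth_path, truth)
            artifacts["truth"] = truth_path
            if config.write_audio:
                for name, sig in (("primary", primary), ("reference", reference),
                                  ("clean", record.clean)):
                    path = outdir / f"{name}.wav"
                    write_wav(path, sig)
                    artifacts[name] = path
        elif config.primary_wav is not None:
            primary = read_wav(config.primary_wav)
            reference = read_wav(config.reference_wav) if config.reference_wav else None
            reference_apneas = (
                read_apneas(config.reference_events) if config.reference_events else None
            )
        else:
            raise StageError("config: neither a simulation protocol nor a primary WAV given")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"input: {exc}") from exc

    if config.apply_af:
        if reference is None:
            raise StageError("adaptive-filter: reference channel required when AF is on")
        try:
            denoised = nlms_cancel(primary, reference, config.nlms)
        except Exception as exc:
            raise StageError(f"adaptive-filter: {exc}") from exc
    else:
        denoised = primary

    try:
        breaths, apneas, threshold = detect_events(
            denoised, config.detector, config.apnea_min_gap
        )
    except Exception as exc:
        raise StageError(f"detection: {exc}") from exc

    breaths_path = outdir / "breaths.csv"
    apneas_path = outdir / "apneas.csv"
    write_events(breaths_path, events_to_frame(breaths, "breath"))
    write_events(apneas_path, events_to_frame(apneas, "apnea"))
    artifacts["breaths"] = breaths_path
    artifacts["apneas"] = apneas_path

    metrics = None
    if reference_apneas is not None:
        try:
            table = build_contingency(
                apneas,
                reference_apneas,
                record_duration=primary.duration,
                tn_quantum=config.tn_quantum,
                min_overlap=config.min_overlap,
            )
            metrics = compute_metrics(table)
        except Exception as exc:
            raise StageError(f"scoring: {exc}") from exc
        metrics_path = outdir / "metrics.json"
        payload = {"table": asdict(table), "metrics": asdict(metrics)}
        metrics_path.write_text(json.dumps(payload, indent=2))
        artifacts["metrics"] = metrics_path

    provenance = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "apply_af": config.apply_af,
        "nlms": asdict(config.nlms),
        "detector": asdict(config.detector),
        "apnea_min_gap": config.apnea_min_gap,
        "tn_quantum": config.tn_quantum,
        "min_overlap": config.min_overlap,
        "simulate": asdict(config.simulate) if config.simulate else None,
        "threshold_logvar": threshold,
    }
    run_path = outdir / "run.json"
    run_path.write_text(json.dumps(provenance, indent=2, default=str))
    artifacts["provenance"] = run_path

    return PipelineResult(
        breaths=breaths,
        apneas=apneas,
        threshold=threshold,
        metrics=metrics,
        artifacts=artifacts,
    )
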