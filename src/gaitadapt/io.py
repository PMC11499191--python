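"""Delimited-text I/O, run manifests, and the end-to-end pipeline.

All interchange is plain CSV with a header; series files carry a small
``# key: value`` metadata preamble.  A run manifest lists one input file
per subject x trial — either a raw recording (columns ``time_s,
lheel_ap_m, rheel_ap_m, lgrf_n, rgrf_n``) or a stride table (columns
``side, time_s, step_length_m, step_time_s``) — and ``run_pipeline``
executes detection, asymmetry computation, filtering, segmentation, PSO
fitting of both models, AIC selection, decay-table assembly and the
nonparametric battery, persisting every intermediate table with
provenance (input and config hashes, seeds) in a run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .events import (
    AsymmetrySeries,
    StrideSeries,
    asymmetry_series,
    detect_steps,
    filter_asymmetry,
)
from .fitting import PSOConfig, pso_fit
from .protocol import TrialProtocol, TrialType, build_protocol
from .selection import compare_models
from .stats import (
    DECAY_TABLE_COLUMNS,
    adaptation_window,
    post_window,
    run_battery,
    segment_stages,
)
from .synthetic import GaitRecording

__all__ = [
    "read_recording",
    "write_recording",
    "read_strides",
    "write_strides",
    "read_asymmetry",
    "write_asymmetry",
    "PipelineConfig",
    "ManifestEntry",
    "RunManifest",
    "ResultBundle",
    "run_pipeline",
]

logger = logging.getLogger("gaitadapt")

RECORDING_COLUMNS = ("time_s", "lheel_ap_m", "rheel_ap_m", "lgrf_n",
                     "rgrf_n")
STRIDE_COLUMNS = ("side", "time_s", "step_length_m", "step_time_s")


def _read_metadata(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    return meta


def _write_csv(path, frame: pd.DataFrame, metadata: Optional[dict] = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, index=False)


def _read_csv(path) -> tuple[pd.DataFrame, dict]:
    meta = _read_metadata(Path(path))
    frame = pd.read_csv(path, comment="#")
    return frame, meta


def write_recording(path, recording: GaitRecording) -> None:
    frame = pd.DataFrame({
        "time_s": recording.time,
        "lheel_ap_m": recording.lheel_ap,
        "rheel_ap_m": recording.rheel_ap,
        "lgrf_n": recording.lgrf,
        "rgrf_n": recording.rgrf,
    })
    meta = {"body_weight_n": recording.body_weight,
            "sampling_rate_hz": recording.sampling_rate}
    if recording.stride_time_hint is not None:
        meta["stride_time_s"] = recording.stride_time_hint
    _write_csv(path, frame, meta)


def read_recording(path) -> GaitRecording:
    """Read and validate a recording table.

    Columns are header-keyed (order-independent).  The sampling rate is
    inferred from the timestamps and checked uniform within 1e-6 s.
    """
    frame, meta = _read_csv(path)
    missing = [c for c in RECORDING_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing recording column(s) {missing}")
    time = frame["time_s"].to_numpy(dtype=float)
    if len(time) < 2:
        raise ValidationError(f"{path}: recording too short")
    dt = np.diff(time)
    if np.any(np.abs(dt - dt[0]) > 1e-6) or dt[0] <= 0:
        raise ValidationError(f"{path}: non-uniform sampling")
    body_weight = float(meta.get("body_weight_n", 700.0))
    hint = meta.get("stride_time_s")
    return GaitRecording(
        sampling_rate=1.0 / dt[0],
        time=time,
        lheel_ap=frame["lheel_ap_m"].to_numpy(dtype=float),
        rheel_ap=frame["rheel_ap_m"].to_numpy(dtype=float),
        lgrf=frame["lgrf_n"].to_numpy(dtype=float),
        rgrf=frame["rgrf_n"].to_numpy(dtype=float),
        body_weight=body_weight,
        stride_time_hint=float(hint) if hint is not None else None,
    )


def write_strides(path, strides: StrideSeries) -> None:
    _write_csv(path, strides.to_frame())


def read_strides(path) -> StrideSeries:
    frame, _ = _read_csv(path)
    missing = [c for c in STRIDE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing stride column(s) {missing}")
    return StrideSeries(
        frame["side"].to_numpy(dtype=object),
        frame["time_s"].to_numpy(dtype=float),
        frame["step_length_m"].to_numpy(dtype=float),
        frame["step_time_s"].to_numpy(dtype=float),
        stage=frame["stage"].to_numpy(dtype=object)
        if "stage" in frame.columns else None,
    )


def write_asymmetry(path, series: AsymmetrySeries) -> None:
    frame = pd.DataFrame({"t_s": series.t,
                          "asymmetry_pct": series.asymmetry})
    if series.stage is not None:
        frame["stage"] = series.stage
    _write_csv(path, frame, {"parameter": series.parameter,
                             "filtered": series.filtered})


def read_asymmetry(path) -> AsymmetrySeries:
    frame, meta = _read_csv(path)
    if "parameter" not in meta:
        raise ValidationError(f"{path}: missing '# parameter:' metadata")
    return AsymmetrySeries(
        meta["parameter"],
        frame["t_s"].to_numpy(dtype=float),
        frame["asymmetry_pct"].to_numpy(dtype=float),
        filtered=meta.get("filtered", "False") == "True",
        stage=frame["stage"].to_numpy(dtype=object)
        if "stage" in frame.columns else None,
    )


@dataclass
class PipelineConfig:
    """Everything tunable in the analysis pipeline, with the defaults used
    throughout the package."""

    force_threshold_fraction: float = 0.05
    filter_order: int = 1
    filter_cutoff: float = 1.0     # fraction of stride-sequence Nyquist
    pso: PSOConfig = field(default_factory=PSOConfig)
    parameters: tuple[str, ...] = ("step_length", "step_time")
    master_seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        pso_doc = doc.pop("pso", None)
        cfg = cls(**doc)
        if pso_doc:
            if pso_doc.get("bounds") is not None:
                pso_doc["bounds"] = tuple(
                    tuple(b) for b in pso_doc["bounds"])
            cfg.pso = PSOConfig(**pso_doc)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)


@dataclass(frozen=True)
class ManifestEntry:
    subject: str
    trial_type: TrialType
    path: str
    comfortable_speed: float = 1.1        # m/s
    comfortable_stride_time: float = 1.1  # s


@dataclass
class RunManifest:
    entries: tuple[ManifestEntry, ...]
    output_dir: str
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("manifest has no entries")
        keys = [(e.subject, e.trial_type) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValidationError(
                "duplicate (subject, trial) pairs in manifest")

    @classmethod
    def from_yaml(cls, path) -> "RunManifest":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        entries = tuple(
            ManifestEntry(
                subject=str(e["subject"]),
                trial_type=TrialType(e["trial_type"]),
                path=str(e["path"]),
                comfortable_speed=float(e.get("comfortable_speed_mps", 1.1)),
                comfortable_stride_time=float(
                    e.get("comfortable_stride_time_s", 1.1)),
            )
            for e in doc["entries"]
        )
        return cls(entries, str(doc["output_dir"]),
                   int(doc.get("master_seed", 0)))


@dataclass
class ResultBundle:
    fits: pd.DataFrame
    decay_table: pd.DataFrame
    battery: pd.DataFrame
    failures: list[tuple[str, str]]   # (entry id, error message)
    run_log: dict


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_strides(entry: ManifestEntry,
                  config: PipelineConfig) -> StrideSeries:
    meta = _read_metadata(Path(entry.path))
    with open(entry.path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line
                break
        else:
            raise ValidationError(f"{entry.path}: empty file")
    if "lgrf_n" in header:
        recording = read_recording(entry.path)
        return detect_steps(recording, config.force_threshold_fraction)
    return read_strides(entry.path)


def _fit_windows(series: AsymmetrySeries, protocol: TrialProtocol,
                 entry: ManifestEntry, config: PipelineConfig,
                 seed: int) -> tuple[list[dict], list[dict]]:
    """Fit both models on the adaptation and post windows of one series."""
    fit_rows, decay_rows = [], []
    windows = {
        "adaptation": adaptation_window(entry.trial_type, series, protocol),
        "post": post_window(series, protocol),
    }
    for stage_name, window in windows.items():
        fits = {}
        for kind in ("single", "double"):
            cfg = dataclasses.replace(config.pso, seed=seed)
            fits[kind] = pso_fit(window, kind, cfg)
            seed += 1
        comparison = compare_models(fits["single"], fits["double"])
        for kind, fit in fits.items():
            row = fit.as_dict()
            row.update(subject=entry.subject,
                       trial=entry.trial_type.value,
                       stage=stage_name, parameter=series.parameter,
                       aic=(comparison.aic_single if kind == "single"
                            else comparison.aic_double),
                       chosen=comparison.chosen == kind)
            fit_rows.append(row)
            if not fit.converged:
                logger.warning(
                    "unconverged %s fit: %s %s %s %s", kind, entry.subject,
                    entry.trial_type.value, stage_name, series.parameter)
        explicit, implicit = (fits["double"].explicit_constant,
                              fits["double"].implicit_constant)
        for component, value in (("explicit", explicit),
                                 ("implicit", implicit)):
            decay_rows.append(dict(
                subject=entry.subject, trial=entry.trial_type.value,
                stage=stage_name, parameter=series.parameter,
                component=component, value=value))
    return fit_rows, decay_rows


def run_pipeline(manifest: RunManifest,
                 config: Optional[PipelineConfig] = None) -> ResultBundle:
    """Execute the full analysis over a manifest of input files.

    Per-entry failures are logged and collected without aborting the rest
    of the manifest; the comparison battery runs only when the decay table
    covers all planned conditions.  Deterministic under a fixed master
    seed: every fit's PSO seed is derived from it and the entry order.
    """
    if config is None:
        config = PipelineConfig(master_seed=manifest.master_seed)
    out_dir = Path(manifest.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    fit_rows, decay_rows, failures = [], [], []
    input_hashes = {}
    for i, entry in enumerate(manifest.entries):
        entry_id = f"{entry.subject}/{entry.trial_type.value}"
        try:
            input_hashes[entry.path] = _sha256(entry.path)
            protocol = build_protocol(entry.trial_type,
                                      entry.comfortable_speed,
                                      entry.comfortable_stride_time)
            strides = _load_strides(entry, config)
            for j, parameter in enumerate(config.parameters):
                series = asymmetry_series(strides, parameter)
                series = filter_asymmetry(series, config.filter_order,
                                          config.filter_cutoff)
                series = segment_stages(series, protocol)
                seed = (config.master_seed + 1000 * i + 100 * j) % (2**31)
                f_rows, d_rows = _fit_windows(series, protocol, entry,
                                              config, seed)
                fit_rows.extend(f_rows)
                decay_rows.extend(d_rows)
        except Exception as exc:  # noqa: BLE001 - per-file isolation
            logger.error("entry %s failed: %s", entry_id, exc)
            failures.append((entry_id, str(exc)))

    fits = pd.DataFrame(fit_rows)
    decay_table = pd.DataFrame(decay_rows, columns=DECAY_TABLE_COLUMNS)

    battery_rows = []
    if not decay_table.empty:
        try:
            for report in run_battery(decay_table):
                battery_rows.append(dict(
                    test=report.test, statistic=report.statistic,
                    df=report.df, p=report.p,
                    conditions="|".join(report.conditions),
                    **report.context))
        except ValidationError as exc:
            logger.warning("battery skipped: %s", exc)
            failures.append(("battery", str(exc)))
    battery = pd.DataFrame(battery_rows)

    run_log = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "input_hashes": input_hashes,
        "master_seed": config.master_seed,
        "n_entries": len(manifest.entries),
        "failures": failures,
    }
    _write_csv(out_dir / "fits.csv", fits)
    _write_csv(out_dir / "decay_table.csv", decay_table)
    _write_csv(out_dir / "battery.csv", battery)
    with open(out_dir / "runlog.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
    return ResultBundle(fits, decay_table, battery, failures, run_log)
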